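"""The 27-class taxonomy of (TF, M, T) sign-pattern triplets.

Each fitted triplet carries a correlation-indicator (CI) triple
``(ci_a2, ci_b1, ci_b2)`` over the alphabet ``{+, -, 0}``: the signs of the
modulator main effect (a2), the TF main effect (b1), and the TF x M
interaction (b2), each zeroed when not significant.  The 3^3 = 27 possible
triples map bijectively onto named regulatory behaviours — e.g. a
significant positive b1 with a significant negative b2 means the TF
activates the target but the modulator antagonizes that activation.

The map is data, defined once here and never computed.
"""

from __future__ import annotations

SIGNS = ("+", "-", "0")

#: class_index -> (ci_a2, ci_b1, ci_b2)
CLASS_SIGNS: dict[int, tuple[str, str, str]] = {
    1: ("0", "+", "0"),
    2: ("0", "-", "0"),
    3: ("+", "+", "0"),
    4: ("+", "-", "0"),
    5: ("-", "+", "0"),
    6: ("-", "-", "0"),
    7: ("0", "+", "+"),
    8: ("0", "+", "-"),
    9: ("0", "-", "+"),
    10: ("0", "-", "-"),
    11: ("+", "+", "+"),
    12: ("+", "+", "-"),
    13: ("+", "-", "+"),
    14: ("+", "-", "-"),
    15: ("-", "+", "+"),
    16: ("-", "+", "-"),
    17: ("-", "-", "+"),
    18: ("-", "-", "-"),
    19: ("+", "0", "0"),
    20: ("-", "0", "0"),
    21: ("0", "0", "+"),
    22: ("0", "0", "-"),
    23: ("+", "0", "+"),
    24: ("+", "0", "-"),
    25: ("-", "0", "+"),
    26: ("-", "0", "-"),
    27: ("0", "0", "0"),
}

#: class_index -> human-readable behaviour label
CLASS_LABELS: dict[int, str] = {
    1: "TF (Ind. Activator)",
    2: "TF (Ind. Repressor)",
    3: "TF (Ind. Activator) and M (Ind. Activator)",
    4: "TF (Ind. Repressor) and M (Ind. Activator)",
    5: "TF (Ind. Activator) and M (Ind. Repressor)",
    6: "TF (Ind. Repressor) and M (Ind. Repressor)",
    7: "TF (Activator) and M (Agonist)",
    8: "TF (Activator) and M (Antagonist)",
    9: "TF (Repressor) and M (Antagonist)",
    10: "TF (Repressor) and M (Agonist)",
    11: "TF (Activator) and M (Agonist & Ind. Activator)",
    12: "TF (Activator) and M (Antagonist & Ind. Activator)",
    13: "TF (Repressor) and M (Antagonist & Ind. Activator)",
    14: "TF (Repressor) and M (Agonist & Ind. Activator)",
    15: "TF (Activator) and M (Agonist & Ind. Repressor)",
    16: "TF (Activator) and M (Antagonist & Ind. Repressor)",
    17: "TF (Repressor) and M (Antagonist & Ind. Repressor)",
    18: "TF (Repressor) and M (Agonist & Ind. Repressor)",
    19: "M (Ind. Activator)",
    20: "M (Ind. Repressor)",
    21: "M (Activator Agonist)",
    22: "M (Repressor Agonist)",
    23: "M (Activator Agonist & Ind. Activator)",
    24: "M (Repressor Agonist & Ind. Activator)",
    25: "M (Activator Agonist & Ind. Repressor)",
    26: "M (Repressor Agonist & Ind. Repressor)",
    27: "No Function",
}

#: inverse map: sign triple -> class_index
SIGNS_TO_CLASS: dict[tuple[str, str, str], int] = {
    v: k for k, v in CLASS_SIGNS.items()
}


def classify_triplet(ci: tuple[str, str, str]) -> tuple[int, str]:
    """Map a CI sign triple ``(ci_a2, ci_b1, ci_b2)`` to its class.

    Returns ``(class_index, class_label)``.  Total on the 27 triples;
    anything else raises ``ValueError``.
    """
    key = tuple(ci)
    if len(key) != 3 or any(s not in SIGNS for s in key):
        raise ValueError(f"invalid sign triple {ci!r}; each sign must be one of {SIGNS}")
    idx = SIGNS_TO_CLASS[key]  # total by construction once validated
    return idx, CLASS_LABELS[idx]


def modulator_involving_classes() -> frozenset[int]:
    """Classes in which the modulator participates in regulation.

    A class involves the modulator when the interaction indicator is
    nonzero, or when both main-effect indicators (modulator and TF) are
    nonzero.  These are exactly the 22 behaviours for which connection
    counts are meaningful; the remaining 5 (TF-only effects and the null
    class) say nothing about the modulator acting on the TF-target link.
    """
    out = set()
    for idx, (a2, b1, b2) in CLASS_SIGNS.items():
        if b2 != "0" or (a2 != "0" and b1 != "0"):
            out.add(idx)
    return frozenset(out)
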