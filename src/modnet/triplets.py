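"""Interaction-model fitting and classification of (TF, M, T) triplets.

For every candidate modulator M and target T the target's expression course
is regressed on the TF course, the dichotomized modulator status, and their
interaction:

    T = a1 + a2*M + b1*TF + b2*TF*M + e

over the J samples of the time course.  b2 measures how the modulator's
high/low status changes the TF's effect on the target; a2 and b1 are the
modulator and TF main effects.  Each of (a2, b1, b2) is reduced to a
correlation indicator in {+, -, 0} — its sign when the two-sided t-test is
significant at alpha, 0 otherwise — and the indicator triple places the
triplet into one of the 27 behaviour classes (see :mod:`modnet.classes`).

Class-level false-discovery rates come from a sample-permutation null:
target rows are independently permuted over samples, destroying any link
between T and (TF, M) while preserving each target's marginal distribution,
and the scan is re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .classes import CLASS_LABELS, CLASS_SIGNS, classify_triplet
from .io_prep import ExpressionMatrix, dichotomize_modulator

logger = logging.getLogger(__name__)

N_PARAMS = 4  # intercept, M, TF, TF*M


class DegenerateDesignError(ValueError):
    """Design matrix unusable for this triplet; carries a reason code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class TripletFit:
    """One fitted (TF, M, T) regression with its class assignment."""

    tf_id: str
    modulator_id: str
    target_id: str
    a1: float
    a2: float
    b1: float
    b2: float
    p_a2: float
    p_b1: float
    p_b2: float
    ci: tuple[str, str, str] | None = None
    class_index: int | None = None
    class_label: str | None = None
    saturated: bool = False

    def classify(self, alpha: float = 0.05) -> "TripletFit":
        """Return a copy with CI triple and class filled in at level alpha."""
        ci = (
            correlation_indicator(self.a2, self.p_a2, alpha),
            correlation_indicator(self.b1, self.p_b1, alpha),
            correlation_indicator(self.b2, self.p_b2, alpha),
        )
        idx, label = classify_triplet(ci)
        return replace(self, ci=ci, class_index=idx, class_label=label)


def _design(tf: np.ndarray, m: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(tf), m.astype(float), tf, tf * m])


def fit_triplet(
    t: np.ndarray,
    tf: np.ndarray,
    m: np.ndarray,
    tf_id: str = "TF",
    modulator_id: str = "M",
    target_id: str = "T",
) -> TripletFit:
    """Ordinary-least-squares fit of the interaction model for one triplet.

    ``t`` and ``tf`` are length-J expression vectors, ``m`` a binary 0/1
    vector.  Needs J >= 5 (one residual degree of freedom) and a full-rank
    design; otherwise :class:`DegenerateDesignError` is raised with a
    reason code.  P-values for a2, b1, b2 are two-sided t-tests with J - 4
    degrees of freedom.  A perfect fit (zero residual variance) yields
    p-values 0 and ``saturated=True``.
    """
    t = np.asarray(t, dtype=float)
    tf = np.asarray(tf, dtype=float)
    m = np.asarray(m)
    J = t.size
    if not (t.size == tf.size == m.size):
        raise ValueError("t, tf, m must have equal length")
    if J < N_PARAMS + 1:
        raise DegenerateDesignError("too_few_samples")
    if np.all(m == m[0]):
        raise DegenerateDesignError("constant_modulator")
    if np.all(tf == tf[0]):
        raise DegenerateDesignError("constant_tf")
    X = _design(tf, m)
    if np.linalg.matrix_rank(X) < N_PARAMS:
        raise DegenerateDesignError("rank_deficient")

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ t)
    resid = t - X @ beta
    df = J - N_PARAMS
    ss = float(resid @ resid)
    sigma2 = ss / df
    if sigma2 <= np.finfo(float).eps * max(1.0, float(t @ t)):
        pvals = np.zeros(N_PARAMS)
        saturated = True
    else:
        se = np.sqrt(sigma2 * np.diag(XtX_inv))
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        saturated = False
    return TripletFit(
        tf_id=tf_id,
        modulator_id=modulator_id,
        target_id=target_id,
        a1=float(beta[0]),
        a2=float(beta[1]),
        b1=float(beta[2]),
        b2=float(beta[3]),
        p_a2=float(pvals[1]),
        p_b1=float(pvals[2]),
        p_b2=float(pvals[3]),
        saturated=saturated,
    )


def correlation_indicator(coef: float, p: float, alpha: float = 0.05) -> str:
    """Sign symbol for a coefficient: its sign if significant, else '0'.

    '+' iff p < alpha and coef > 0; '-' iff p < alpha and coef < 0;
    '0' otherwise (including the measure-zero case of an exactly zero
    significant coefficient, whose sign is undefined).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < alpha:
        if coef > 0:
            return "+"
        if coef < 0:
            return "-"
    return "0"


@dataclass
class ScanResult:
    """Classified fits from a modulator x target scan, plus skip bookkeeping."""

    fits: list[TripletFit]
    skipped: list[tuple[str, str, str]]  # (modulator, target, reason)

    def __len__(self) -> int:
        return len(self.fits)

    def __iter__(self):
        return iter(self.fits)

    def __getitem__(self, i):
        return self.fits[i]

    def to_frame(self) -> pd.DataFrame:
        """Triplet table: one row per fit, CI triple joined into a string."""
        rows = [
            {
                "tf": f.tf_id,
                "modulator": f.modulator_id,
                "target": f.target_id,
                "a1": f.a1,
                "a2": f.a2,
                "b1": f.b1,
                "b2": f.b2,
                "p_a2": f.p_a2,
                "p_b1": f.p_b1,
                "p_b2": f.p_b2,
                "ci": "".join(f.ci) if f.ci else "",
                "class_index": f.class_index,
                "class_label": f.class_label,
            }
            for f in self.fits
        ]
        cols = [
            "tf", "modulator", "target", "a1", "a2", "b1", "b2",
            "p_a2", "p_b1", "p_b2", "ci", "class_index", "class_label",
        ]
        return pd.DataFrame(rows, columns=cols)


def _batch_fit_for_modulator(
    Y: np.ndarray, tf: np.ndarray, m: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | None:
    """Fit all target rows of Y against one fixed (tf, m) design.

    Returns (beta, pvals), each (n_targets x 4), or None if the design is
    rank deficient.  The per-modulator design is shared across targets, so
    the normal equations are solved once.
    """
    X = _design(tf, m)
    if np.linalg.matrix_rank(X) < N_PARAMS:
        return None
    J = tf.size
    df = J - N_PARAMS
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = (XtX_inv @ (X.T @ Y.T)).T  # n_targets x 4
    resid = Y - beta @ X.T
    ss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = ss / df
    scale = np.finfo(float).eps * np.maximum(1.0, np.einsum("ij,ij->i", Y, Y))
    saturated = sigma2 <= scale
    se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals[saturated] = 0.0
    return beta, pvals


def scan_triplets(
    em: ExpressionMatrix,
    tf_id: str,
    modulators: set[str],
    targets: set[str],
    alpha: float = 0.05,
) -> ScanResult:
    """Fit and classify every (modulator, target) pair against the TF.

    Pairs with m == t are excluded, as are the TF itself on either side.
    Modulators whose expression cannot be dichotomized (constant) or whose
    design is rank deficient skip all their pairs with a reason code.
    Output order is deterministic: modulators then targets, lexicographic.
    """
    if not modulators or not targets:
        raise ValueError("modulator and target sets must be non-empty")
    missing = (set(modulators) | set(targets) | {tf_id}) - set(em.gene_ids)
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)[:5]}")

    tf = em.vector(tf_id)
    mod_ids = sorted(set(modulators) - {tf_id})
    tgt_ids = sorted(set(targets) - {tf_id})

    fits: list[TripletFit] = []
    skipped: list[tuple[str, str, str]] = []
    if np.all(tf == tf[0]):
        for m_id in mod_ids:
            for t_id in tgt_ids:
                if t_id != m_id:
                    skipped.append((m_id, t_id, "constant_tf"))
        return ScanResult(fits, skipped)

    tgt_index = {g: i for i, g in enumerate(em.gene_ids)}
    all_values = em.values

    for m_id in mod_ids:
        t_ids = [t for t in tgt_ids if t != m_id]
        if not t_ids:
            continue
        m_bin, degenerate = dichotomize_modulator(em.vector(m_id))
        if degenerate:
            skipped.extend((m_id, t, "constant_modulator") for t in t_ids)
            continue
        Y = all_values[[tgt_index[t] for t in t_ids]]
        res = _batch_fit_for_modulator(Y, tf, m_bin)
        if res is None:
            skipped.extend((m_id, t, "rank_deficient") for t in t_ids)
            continue
        beta, pvals = res
        for i, t_id in enumerate(t_ids):
            fit = TripletFit(
                tf_id=tf_id,
                modulator_id=m_id,
                target_id=t_id,
                a1=float(beta[i, 0]),
                a2=float(beta[i, 1]),
                b1=float(beta[i, 2]),
                b2=float(beta[i, 3]),
                p_a2=float(pvals[i, 1]),
                p_b1=float(pvals[i, 2]),
                p_b2=float(pvals[i, 3]),
                saturated=bool(pvals[i].max() == 0.0 and pvals[i].min() == 0.0),
            ).classify(alpha)
            fits.append(fit)
    if skipped:
        logger.info("scan skipped %d degenerate pairs", len(skipped))
    return ScanResult(fits, skipped)


def _class_counts(fits) -> dict[int, int]:
    counts: dict[int, int] = {}
    for f in fits:
        counts[f.class_index] = counts.get(f.class_index, 0) + 1
    return counts


def category_summary(fits) -> pd.DataFrame:
    """Per-class unique-modulator/target and connection counts.

    One row per class 1-27 with its sign triple and label; classes with no
    connections show zeros.
    """
    rows = []
    by_class: dict[int, list[TripletFit]] = {}
    for f in fits:
        by_class.setdefault(f.class_index, []).append(f)
    for idx in range(1, 28):
        members = by_class.get(idx, [])
        a2, b1, b2 = CLASS_SIGNS[idx]
        rows.append(
            {
                "class_index": idx,
                "class_label": CLASS_LABELS[idx],
                "ci_a2": a2,
                "ci_b1": b1,
                "ci_b2": b2,
                "n_unique_modulators": len({f.modulator_id for f in members}),
                "n_unique_targets": len({f.target_id for f in members}),
                "n_connections": len(members),
            }
        )
    return pd.DataFrame(rows).set_index("class_index")


def category_fdr(
    fits,
    em: ExpressionMatrix,
    tf_id: str,
    modulators: set[str],
    targets: set[str],
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation FDR per behaviour class.

    For each permutation, every target row is independently shuffled over
    samples (modulator and TF rows untouched), the scan is re-run, and the
    per-class connection counts recorded.  fdr(class) = min(1, mean null
    count / observed count); classes with no observed connections get NaN.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = _class_counts(fits)
    null_totals: dict[int, float] = {idx: 0.0 for idx in range(1, 28)}

    perm_targets = sorted(set(targets) - {tf_id})
    for _ in range(n_perm):
        perm_data = em.data.copy()
        for t_id in perm_targets:
            row = perm_data.loc[t_id].to_numpy()
            perm_data.loc[t_id] = rng.permutation(row)
        perm_em = ExpressionMatrix(perm_data)
        perm_fits = scan_triplets(perm_em, tf_id, modulators, targets, alpha)
        for idx, n in _class_counts(perm_fits).items():
            null_totals[idx] += n

    summary = category_summary(fits)
    fdr = []
    for idx in summary.index:
        obs = observed.get(idx, 0)
        if obs == 0:
            fdr.append(np.nan)
        else:
            fdr.append(min(1.0, (null_totals[idx] / n_perm) / obs))
    summary["fdr"] = fdr
    return summary
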