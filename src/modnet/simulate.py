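"""Seeded synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design the method targets: a hormone
stimulation time course of J samples (default 12) measured on a log2-ratio
expression scale, a TF whose trajectory drives a subset of targets, planted
(modulator, target) triplets following the interaction model

    T = a1 + a2*M + b1*TF + b2*TF*M + eps,   eps ~ N(0, noise_sd^2)

with M the dichotomized modulator status, and multi-caller peak files whose
caller/time-point agreement is controllable.  Everything is driven by a
single integer seed; regeneration from (parameters, seed) is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import Gene, Peak
from .classes import SIGNS_TO_CLASS
from .io_prep import MODULATOR_CLASSES, ExpressionMatrix, dichotomize_modulator

#: hours of the default 12-sample stimulation course
DEFAULT_TIMEPOINTS = (0, 1, 2, 4, 6, 8, 12, 16, 20, 24, 28, 32)

#: default proportions of the seven modulator functional classes, matching
#: the empirical composition of candidate-modulator sets in breast-cancer
#: expression profiles (kinases and TFs dominate; deacetylases are rare)
DEFAULT_CLASS_COUNTS = dict(
    zip(MODULATOR_CLASSES, (162, 43, 8, 1, 57, 156, 58))
)


def _sign(x: float) -> str:
    return "+" if x > 0 else ("-" if x < 0 else "0")


@dataclass(frozen=True)
class PlantedTriplet:
    """A ground-truth (modulator, target) effect to embed in the matrix."""

    modulator_id: str
    target_id: str
    a1: float = 0.0
    a2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    @property
    def expected_class(self) -> int:
        """Class the triplet converges to as noise vanishes."""
        return SIGNS_TO_CLASS[(_sign(self.a2), _sign(self.b1), _sign(self.b2))]


@dataclass
class SyntheticTruth:
    """Serializable record of everything the generator planted."""

    seed: int
    planted: list[PlantedTriplet] = field(default_factory=list)
    genomic: set[str] = field(default_factory=set)
    non_genomic: set[str] = field(default_factory=set)
    ambiguous: set[str] = field(default_factory=set)
    parameters: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted": [asdict(p) for p in self.planted],
            "genomic": sorted(self.genomic),
            "non_genomic": sorted(self.non_genomic),
            "ambiguous": sorted(self.ambiguous),
            "parameters": self.parameters,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            planted=[PlantedTriplet(**p) for p in d["planted"]],
            genomic=set(d["genomic"]),
            non_genomic=set(d["non_genomic"]),
            ambiguous=set(d["ambiguous"]),
            parameters=d["parameters"],
        )


def tf_trajectory(n_samples: int, rng: np.random.Generator, degree: int = 3) -> np.ndarray:
    """Smooth seeded TF expression course, standardized to mean 0, sd 1.

    A random low-order polynomial over scaled time gives a non-constant,
    smooth regressor resembling a stimulation response; the exact shape is
    irrelevant to the method, only non-degeneracy matters.
    """
    x = np.linspace(-1.0, 1.0, n_samples)
    coeffs = rng.normal(size=degree + 1)
    coeffs[1] += 1.0  # guarantee a linear component; never near-constant
    y = np.polyval(coeffs, x)
    return (y - y.mean()) / y.std()


def simulate_expression(
    n_genes: int,
    n_samples: int = 12,
    tf_profile: np.ndarray | None = None,
    planted: list[PlantedTriplet] | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    tf_id: str = "ESR1",
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a gene x sample log2-ratio matrix with planted triplets.

    Gene IDs are ``G0001 ...``; the TF gets its own row under ``tf_id``.
    Modulator rows are i.i.d. Gaussian and dichotomized internally exactly
    as the analysis does; planted target rows follow the interaction model
    with Gaussian noise; all other genes are independent noise.
    """
    if n_samples < 5:
        raise ValueError("need at least 5 samples")
    planted = list(planted or [])
    pairs = [(p.modulator_id, p.target_id) for p in planted]
    if len(pairs) != len(set(pairs)):
        raise ValueError("duplicate planted (modulator, target) pairs")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    known = set(gene_ids) | {tf_id}
    for p in planted:
        if p.modulator_id not in known or p.target_id not in known:
            raise ValueError(
                f"planted triplet ({p.modulator_id}, {p.target_id}) references "
                f"genes outside the simulated universe"
            )

    if n_samples == len(DEFAULT_TIMEPOINTS):
        labels = [str(h) for h in DEFAULT_TIMEPOINTS]
    else:
        labels = [str(i) for i in range(n_samples)]

    tf = np.asarray(tf_profile, dtype=float) if tf_profile is not None else tf_trajectory(n_samples, rng)
    if tf.size != n_samples:
        raise ValueError("tf_profile length does not match n_samples")

    # background: every non-TF gene independent noise
    data = pd.DataFrame(
        rng.normal(0.0, noise_sd, size=(n_genes, n_samples)),
        index=gene_ids, columns=labels,
    )
    target_rows = {p.target_id for p in planted}
    # planted targets overwritten by the generative model
    for p in planted:
        m_vec = data.loc[p.modulator_id].to_numpy()
        m_bin, degenerate = dichotomize_modulator(m_vec)
        if degenerate:  # astronomically unlikely for continuous draws
            raise RuntimeError("generated constant modulator row")
        eps = rng.normal(0.0, p.noise_sd, size=n_samples)
        data.loc[p.target_id] = p.a1 + p.a2 * m_bin + p.b1 * tf + p.b2 * tf * m_bin + eps

    full = pd.concat(
        [pd.DataFrame([tf], index=[tf_id], columns=labels), data]
    )
    truth = SyntheticTruth(
        seed=seed,
        planted=planted,
        parameters={
            "n_genes": n_genes,
            "n_samples": n_samples,
            "noise_sd": noise_sd,
            "tf_id": tf_id,
            "n_planted_targets": len(target_rows),
        },
    )
    return ExpressionMatrix(full), truth


def simulate_annotation(
    gene_ids: list[str],
    chrom: str = "chr1",
    spacing: int = 100_000,
    gene_length: int = 10_000,
) -> list[Gene]:
    """Deterministic non-overlapping gene placement along one chromosome.

    Genes are spaced far enough apart that a promoter window on one can
    never reach a neighbour; strands alternate.
    """
    genes = []
    for i, gid in enumerate(sorted(gene_ids)):
        start = 50_000 + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        genes.append(Gene(gid, chrom, start, start + gene_length, strand))
    return genes


def simulate_peaks(
    true_genomic: set[str],
    ann: list[Gene],
    callers: list[str] | None = None,
    timepoints: list[float] | None = None,
    dropout_rate: float = 0.0,
    ambiguous: set[str] | None = None,
    mcs_range: tuple[float, float] = (0.96, 1.0),
    decoy_mcs_range: tuple[float, float] = (0.0, 1.0),
    seed: int = 0,
) -> tuple[dict[tuple[str, float], list[Peak]], SyntheticTruth]:
    """Generate per-(caller, timepoint) peak sets with known partition truth.

    Every true genomic gene receives one peak per (caller, timepoint)
    inside its gene body with an MCS drawn from ``mcs_range`` (above the
    intended cut).  ``ambiguous`` decoy genes receive peaks from a random
    strict subset of callers only.  All remaining annotated genes get no
    peaks and form the true non-genomic set.  ``dropout_rate`` then deletes
    peaks independently at random, to probe consensus robustness.
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must be in [0, 1)")
    callers = list(callers or ["cisgenome", "genetrack", "macs", "sissrs"])
    timepoints = list(timepoints or [0.0, 0.5, 1.0, 24.0])
    ambiguous = set(ambiguous or ())
    ann_by_id = {g.gene_id: g for g in ann}
    unknown = (true_genomic | ambiguous) - set(ann_by_id)
    if unknown:
        raise ValueError(f"genes missing from annotation: {sorted(unknown)[:5]}")
    if true_genomic & ambiguous:
        raise ValueError("genomic and ambiguous gene sets overlap")

    rng = np.random.default_rng(seed)
    peaks: dict[tuple[str, float], list[Peak]] = {
        (c, tp): [] for c in callers for tp in timepoints
    }

    def add_peak(gene: Gene, caller: str, tp: float, lo: float, hi: float) -> None:
        width = min(200, gene.end - gene.start)
        start = int(rng.integers(gene.start, gene.end - width + 1))
        mcs = float(rng.uniform(lo, hi))
        peaks[(caller, tp)].append(
            Peak(gene.chrom, start, start + width, caller, tp, mcs)
        )

    for gid in sorted(true_genomic):
        for c in callers:
            for tp in timepoints:
                add_peak(ann_by_id[gid], c, tp, *mcs_range)
    for gid in sorted(ambiguous):
        k = int(rng.integers(1, len(callers)))  # strict subset, never all
        subset = sorted(rng.choice(callers, size=k, replace=False))
        for c in subset:
            for tp in timepoints:
                add_peak(ann_by_id[gid], c, tp, *decoy_mcs_range)

    if dropout_rate > 0:
        for key in peaks:
            kept = [p for p in peaks[key] if rng.random() >= dropout_rate]
            peaks[key] = kept

    non_genomic = set(ann_by_id) - true_genomic - ambiguous
    truth = SyntheticTruth(
        seed=seed,
        genomic=set(true_genomic),
        non_genomic=non_genomic,
        ambiguous=ambiguous,
        parameters={
            "callers": callers,
            "timepoints": timepoints,
            "dropout_rate": dropout_rate,
            "mcs_range": list(mcs_range),
        },
    )
    return peaks, truth


def simulate_catalog(
    n_modulators: int,
    class_proportions: dict[str, float] | None = None,
    seed: int = 0,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Assign modulator genes to the seven functional classes.

    ``class_proportions`` defaults to the empirical class composition
    (see :data:`DEFAULT_CLASS_COUNTS`); counts are allocated by largest
    remainder so they always sum to ``n_modulators``.  Gene IDs are drawn
    from ``gene_ids`` when given (without replacement), else synthesized
    as ``M0001 ...``.
    """
    if class_proportions is None:
        total = sum(DEFAULT_CLASS_COUNTS.values())
        class_proportions = {k: v / total for k, v in DEFAULT_CLASS_COUNTS.items()}
    if abs(sum(class_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")

    labels = list(class_proportions)
    quotas = np.array([class_proportions[c] * n_modulators for c in labels])
    counts = np.floor(quotas).astype(int)
    remainder = n_modulators - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    if gene_ids is not None:
        if len(gene_ids) < n_modulators:
            raise ValueError("not enough gene_ids for requested modulator count")
        ids = list(rng.choice(sorted(gene_ids), size=n_modulators, replace=False))
    else:
        ids = [f"M{i:04d}" for i in range(1, n_modulators + 1)]

    rows = []
    k = 0
    for label, n in zip(labels, counts):
        for _ in range(n):
            rows.append({"gene_id": ids[k], "function_class": label})
            k += 1
    return pd.DataFrame(rows)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    """Write a catalog DataFrame in the 2-column TSV dialect io_prep reads."""
    catalog.to_csv(path, sep="\t", header=False, index=False)


def simulate_dataset(
    outdir: str | Path,
    n_genes: int = 300,
    n_modulators: int = 40,
    n_genomic: int = 12,
    n_ambiguous: int = 10,
    n_planted: int = 10,
    noise_sd: float = 0.25,
    effect_size: float = 4.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
    tf_id: str = "ESR1",
) -> SyntheticTruth:
    """Write a complete synthetic input set for a pipeline run.

    Produces, under ``outdir``: ``expression.tsv``, ``catalog.tsv``,
    ``annotation.bed``, one BED per (caller, timepoint) in ``peaks/``, and
    ``truth.json`` recording everything planted.  The first genes serve as
    modulators, the next blocks as genomic and ambiguous targets; planted
    triplets pair modulators with genomic and non-genomic targets in
    alternation, with interaction coefficients of standardized size
    ``effect_size`` (|b2| = effect_size * noise_sd, the TF course having
    unit variance) and random signs.
    """
    from .binding import write_annotation, write_peaks
    from .io_prep import write_expression

    if n_modulators + n_genomic + n_ambiguous > n_genes:
        raise ValueError("gene blocks exceed n_genes")
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gene_ids = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    modulators = gene_ids[:n_modulators]
    genomic = set(gene_ids[n_modulators:n_modulators + n_genomic])
    ambiguous = set(
        gene_ids[n_modulators + n_genomic:n_modulators + n_genomic + n_ambiguous]
    )
    non_genomic = [
        g for g in gene_ids[n_modulators + n_genomic + n_ambiguous:]
    ]

    planted: list[PlantedTriplet] = []
    tgt_pool = sorted(genomic) + non_genomic
    for i in range(n_planted):
        m = modulators[i % n_modulators]
        t = tgt_pool[i % len(tgt_pool)]
        if (m, t) in {(p.modulator_id, p.target_id) for p in planted}:
            continue
        b1 = float(rng.choice([-1.0, 1.0]))
        b2 = float(rng.choice([-1.0, 1.0])) * effect_size * noise_sd
        planted.append(
            PlantedTriplet(m, t, a1=0.0, a2=0.0, b1=b1, b2=b2, noise_sd=noise_sd)
        )

    em, truth = simulate_expression(
        n_genes, 12, None, planted, noise_sd, seed=seed, tf_id=tf_id
    )
    write_expression(em, outdir / "expression.tsv")

    catalog = simulate_catalog(
        n_modulators, seed=seed, gene_ids=modulators
    )
    write_catalog(catalog, outdir / "catalog.tsv")

    ann = simulate_annotation(gene_ids)
    write_annotation(ann, outdir / "annotation.bed")

    peaks, peak_truth = simulate_peaks(
        genomic, ann, dropout_rate=dropout_rate, ambiguous=ambiguous, seed=seed
    )
    for (caller, tp), plist in peaks.items():
        write_peaks(plist, outdir / "peaks" / f"{caller}_{tp:g}.bed")

    truth.genomic = peak_truth.genomic
    truth.non_genomic = peak_truth.non_genomic
    truth.ambiguous = peak_truth.ambiguous
    truth.parameters.update(peak_truth.parameters)
    truth.parameters["effect_size"] = effect_size
    truth.to_json(outdir / "truth.json")
    return truth
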