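"""Consensus TF-binding evidence and the genomic / non-genomic partition.

Peak files from several peak callers at several time points are intersected
with a gene annotation.  A gene is a *genomic* target when every required
caller reports at least one qualifying peak at every required time point —
the strictest consensus, robust to any single caller's false positives.  A
gene with no peak from any caller at any time point is a *non-genomic*
target: its response to the TF cannot run through direct DNA binding.
Everything in between is *ambiguous* and excluded from both analyses
rather than forced into either set.

Peaks may carry a motif conservation score (MCS) in [0, 1]; a quantile (or
absolute) MCS cut filters peaks before the consensus test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """One called binding site, 0-based half-open, tagged with provenance."""

    chrom: str
    start: int
    end: int
    caller: str
    timepoint: float
    mcs: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if not self.chrom or not self.caller:
            raise ValueError("chrom and caller must be non-empty")
        if self.mcs is not None and not (0.0 <= self.mcs <= 1.0):
            raise ValueError(f"MCS {self.mcs} outside [0, 1]")


@dataclass(frozen=True)
class Gene:
    """Gene annotation record: strand-aware 0-based half-open body."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class TargetPartition:
    """Disjoint genomic / non-genomic / ambiguous gene sets."""

    genomic: set[str]
    non_genomic: set[str]
    ambiguous: set[str]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genomic & self.non_genomic or self.genomic & self.ambiguous or (
            self.non_genomic & self.ambiguous
        ):
            raise ValueError("partition sets must be pairwise disjoint")


def load_peaks(
    path: str | Path,
    caller: str,
    timepoint: float,
    mcs_col: int | None = None,
) -> list[Peak]:
    """Read a BED3+ peak file for one (caller, timepoint).

    ``mcs_col`` is the 0-based column index holding the motif conservation
    score, if present.  Records with start >= end are rejected with their
    line number; comment/track lines are skipped.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            mcs = None
            if mcs_col is not None and mcs_col < len(fields) and fields[mcs_col] not in ("", "."):
                mcs = float(fields[mcs_col])
            peaks.append(Peak(chrom, start, end, caller, timepoint, mcs))
    return peaks


def write_peaks(peaks: list[Peak], path: str | Path, mcs_col: int = 4) -> None:
    """Write peaks as BED with the MCS in column ``mcs_col`` (0-based)."""
    with open(path, "w") as fh:
        for p in peaks:
            fields = [p.chrom, str(p.start), str(p.end)]
            while len(fields) < mcs_col:
                fields.append(".")
            fields.append("" if p.mcs is None else f"{p.mcs:.6g}")
            fh.write("\t".join(fields) + "\n")


def load_annotation(path: str | Path) -> list[Gene]:
    """Read a BED6 gene annotation (chrom, start, end, gene_id, score, strand)."""
    genes: list[Gene] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 annotation needs 6 columns")
            gid = fields[3]
            if gid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(Gene(gid, fields[0], int(fields[1]), int(fields[2]), fields[5]))
    return genes


def write_annotation(genes: list[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n")


def mcs_threshold(peaks: list[Peak], quantile: float = 0.95) -> float:
    """Empirical quantile of MCS values over peaks that carry one.

    Linear-interpolation quantile.  With no scored peak at all there is
    nothing to threshold on; run without an MCS filter instead.
    """
    scores = np.array([p.mcs for p in peaks if p.mcs is not None], dtype=float)
    if scores.size == 0:
        raise ValueError(
            "no peak carries a motif conservation score; use --no-mcs mode"
        )
    return float(np.quantile(scores, quantile))


def assign_peaks_to_genes(
    peaks: list[Peak],
    genes: list[Gene],
    upstream_window: int = 10_000,
) -> dict[str, list[Peak]]:
    """Map each gene to the peaks overlapping its body or upstream window.

    The search interval is the gene body extended ``upstream_window`` bp
    upstream of the transcription start: [start - w, end) for + strand,
    [start, end + w) for - strand.  Half-open interval intersection; a
    peak may hit multiple genes.  Peak chromosomes absent from the
    annotation are logged once.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if g.strand == "+":
            lo, hi = max(0, g.start - upstream_window), g.end
        else:
            lo, hi = g.start, g.end + upstream_window
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)

    out: dict[str, list[Peak]] = {g.gene_id: [] for g in genes}
    unmatched: set[str] = set()
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            unmatched.add(p.chrom)
            continue
        for iv in tree.overlap(p.start, p.end):
            out[iv.data].append(p)
    if unmatched:
        logger.info("peak chromosomes absent from annotation: %s", sorted(unmatched))
    return {g: ps for g, ps in out.items() if ps}


def partition_targets(
    assignments: dict[tuple[str, float], dict[str, list[Peak]]],
    universe: set[str],
    required_callers: list[str],
    required_timepoints: list[float],
    mcs_cut: float | None = None,
) -> TargetPartition:
    """Partition the gene universe by consensus binding evidence.

    ``assignments`` maps each (caller, timepoint) to its gene -> peaks map.
    Genomic: >= 1 qualifying peak (MCS >= cut, when a cut is given) for
    EVERY required caller at EVERY required timepoint.  Non-genomic: zero
    peaks from ANY caller at ANY timepoint (regardless of MCS).  Ambiguous:
    everything else.  All sets are restricted to ``universe``.
    """
    if not universe:
        raise ValueError("empty gene universe")
    required = [(c, tp) for c in required_callers for tp in required_timepoints]
    missing = [key for key in required if key not in assignments]
    if missing:
        raise KeyError(f"no peak assignments for (caller, timepoint) pairs: {missing}")

    def qualifies(p: Peak) -> bool:
        return mcs_cut is None or (p.mcs is not None and p.mcs >= mcs_cut)

    genomic: set[str] = set()
    for gene in universe:
        if all(
            any(qualifies(p) for p in assignments[key].get(gene, []))
            for key in required
        ):
            genomic.add(gene)

    bound_anywhere: set[str] = set()
    for gene_map in assignments.values():
        bound_anywhere.update(g for g, ps in gene_map.items() if ps)
    non_genomic = universe - bound_anywhere
    ambiguous = universe - genomic - non_genomic

    return TargetPartition(
        genomic=genomic,
        non_genomic=non_genomic,
        ambiguous=ambiguous,
        parameters={
            "required_callers": list(required_callers),
            "required_timepoints": list(required_timepoints),
            "mcs_cut": mcs_cut,
        },
    )


def write_partition(part: TargetPartition, path: str | Path, header_comment: str | None = None) -> None:
    """Write the partition as 2-column TSV (gene_id, class)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for label, genes in (
            ("genomic", part.genomic),
            ("non_genomic", part.non_genomic),
            ("ambiguous", part.ambiguous),
        ):
            for g in sorted(genes):
                fh.write(f"{g}\t{label}\n")
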