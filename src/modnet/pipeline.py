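"""End-to-end orchestration: preprocess -> targets -> triplets -> networks.

The pipeline mirrors the method's analytic workflow: expression
preprocessing and modulator selection, genomic / non-genomic target
selection from consensus binding evidence, interaction-model scans over
(modulator, target) pairs for each target set, and degree-filtered network
construction.  Every stage writes its artifacts plus a machine-readable
manifest; a single seed drives all randomness, so reruns with the same
config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .binding import (
    assign_peaks_to_genes,
    load_annotation,
    load_peaks,
    mcs_threshold,
    partition_targets,
    write_partition,
)
from .classes import modulator_involving_classes
from .io_prep import (
    ExpressionMatrix,
    ProbeTable,
    collapse_duplicate_probes,
    cv_filter,
    filter_absent_probes,
    load_expression,
    load_modulator_catalog,
    write_expression,
)
from .network import build_network, degree_null, export_network, filter_modulators
from .triplets import category_fdr, scan_triplets

logger = logging.getLogger(__name__)


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is absent; the message names the stage."""


@dataclass
class RunConfig:
    """All paths and parameters of one pipeline run."""

    workdir: str
    expression: str
    catalog: str
    annotation: str
    peaks_dir: str
    tf_id: str
    probe_map: str | None = None
    absent_calls: str | None = None
    alpha: float = 0.05
    cv_threshold: float = 0.15
    cv_scale: str = "linear"
    mcs_mode: str = "quantile"  # quantile | absolute | none
    mcs_value: float = 0.95
    mcs_col: int = 4
    upstream_window: int = 10_000
    required_callers: list[str] = field(
        default_factory=lambda: ["cisgenome", "genetrack", "macs", "sissrs"]
    )
    required_timepoints: list[float] = field(
        default_factory=lambda: [0.0, 0.5, 1.0, 24.0]
    )
    keep_classes: list[int] | None = None  # None -> modulator-involving set
    n_perm: int = 100
    n_shuffles: int = 1000
    quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.cv_threshold < 0:
            raise ValueError("cv_threshold must be >= 0")
        if self.mcs_mode not in ("quantile", "absolute", "none"):
            raise ValueError("mcs_mode must be quantile, absolute or none")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if self.n_perm < 1 or self.n_shuffles < 1:
            raise ValueError("n_perm and n_shuffles must be >= 1")
        if self.upstream_window < 0:
            raise ValueError("upstream_window must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header(self) -> str:
        return f"config={self.config_hash()} seed={self.seed} modnet={__version__}"


def _discover_peak_files(peaks_dir: str | Path) -> dict[tuple[str, float], Path]:
    """Peak files named ``<caller>_<timepoint>.bed`` in one directory."""
    out: dict[tuple[str, float], Path] = {}
    for p in sorted(Path(peaks_dir).glob("*.bed")):
        caller, _, tp = p.stem.rpartition("_")
        if not caller:
            raise ValueError(f"peak file {p.name} not named <caller>_<timepoint>.bed")
        out[(caller, float(tp))] = p
    if not out:
        raise MissingArtifactError(
            f"no .bed peak files in {peaks_dir}; run the 'simulate' stage or "
            f"point peaks_dir at caller output"
        )
    return out


def stage_preprocess(config: RunConfig) -> ExpressionMatrix:
    """Load expression, apply absent-probe, duplicate and CV filters."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if not Path(config.expression).exists():
        raise MissingArtifactError(
            f"expression matrix {config.expression} not found; provide it or run "
            f"the 'simulate' stage"
        )
    loaded = load_expression(config.expression, config.probe_map, config.absent_calls)
    if isinstance(loaded, ProbeTable):
        if loaded.absent_flags is not None:
            loaded = filter_absent_probes(loaded)
        em = collapse_duplicate_probes(loaded)
    else:
        em = loaded
    n_before = em.n_genes
    em, n_removed = cv_filter(em, config.cv_threshold, config.cv_scale)
    logger.info("CV filter removed %d of %d genes", n_removed, n_before)
    if config.tf_id not in set(em.gene_ids):
        raise ValueError(
            f"TF {config.tf_id!r} not present after preprocessing; lower "
            f"cv_threshold or check inputs"
        )
    write_expression(em, workdir / "expression_preprocessed.tsv", config.header())
    return em


def stage_targets(config: RunConfig, em: ExpressionMatrix):
    """Partition expression genes into genomic / non-genomic / ambiguous."""
    workdir = Path(config.workdir)
    if not Path(config.annotation).exists():
        raise MissingArtifactError(f"annotation {config.annotation} not found")
    genes = load_annotation(config.annotation)
    peak_files = _discover_peak_files(config.peaks_dir)

    all_peaks = []
    assignments = {}
    for (caller, tp), path in peak_files.items():
        peaks = load_peaks(path, caller, tp, mcs_col=config.mcs_col)
        all_peaks.extend(peaks)
        assignments[(caller, tp)] = assign_peaks_to_genes(
            peaks, genes, config.upstream_window
        )

    if config.mcs_mode == "none":
        cut = None
    elif config.mcs_mode == "absolute":
        cut = config.mcs_value
    else:
        cut = mcs_threshold(all_peaks, config.mcs_value)

    universe = set(em.gene_ids) - {config.tf_id}
    part = partition_targets(
        assignments,
        universe,
        config.required_callers,
        config.required_timepoints,
        mcs_cut=cut,
    )
    write_partition(part, workdir / "target_partition.tsv", config.header())
    logger.info(
        "partition: %d genomic, %d non-genomic, %d ambiguous",
        len(part.genomic), len(part.non_genomic), len(part.ambiguous),
    )
    return part


def stage_triplets(config: RunConfig, em: ExpressionMatrix, part) -> dict:
    """Scan triplets and estimate category FDRs for both target sets."""
    workdir = Path(config.workdir)
    catalog = load_modulator_catalog(config.catalog).restrict_to(set(em.gene_ids))
    modulators = catalog.gene_ids - {config.tf_id}
    if not modulators:
        raise ValueError("no catalog modulator is present in the expression matrix")

    results = {}
    for name, targets in (("genomic", part.genomic), ("non_genomic", part.non_genomic)):
        targets = set(targets) & set(em.gene_ids)
        if not targets:
            logger.warning("no %s targets in expression matrix; scan skipped", name)
            continue
        scan = scan_triplets(em, config.tf_id, modulators, targets, config.alpha)
        summary = category_fdr(
            scan, em, config.tf_id, modulators, targets,
            alpha=config.alpha, n_perm=config.n_perm, seed=config.seed,
        )
        table_path = workdir / f"triplets_{name}.tsv"
        with open(table_path, "w") as fh:
            fh.write(f"# {config.header()}\n")
            scan.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")
        with open(workdir / f"categories_{name}.tsv", "w") as fh:
            fh.write(f"# {config.header()}\n")
            summary.to_csv(fh, sep="\t", float_format="%.10g")
        results[name] = scan
    return results


def stage_network(config: RunConfig, scans: dict) -> dict:
    """Build, degree-filter and export a network per target set."""
    workdir = Path(config.workdir)
    keep = (
        frozenset(config.keep_classes)
        if config.keep_classes is not None
        else modulator_involving_classes()
    )
    nets = {}
    for name, scan in scans.items():
        net = build_network(scan, tf_id=config.tf_id, keep_classes=keep)
        if net.n_edges > 0:
            null = degree_null(
                net, n_shuffles=config.n_shuffles,
                quantile=config.quantile, seed=config.seed,
            )
            filtered = filter_modulators(net, null)
        else:
            filtered = net
        export_network(net, workdir / f"network_{name}_full.tsv", "tsv", config.header())
        export_network(filtered, workdir / f"network_{name}.tsv", "tsv", config.header())
        export_network(filtered, workdir / f"network_{name}.graphml", "graphml")
        nets[name] = filtered
    return nets


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in workflow order and write a run manifest."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    (workdir / "run_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    em = stage_preprocess(config)
    part = stage_targets(config, em)
    scans = stage_triplets(config, em, part)
    nets = stage_network(config, scans)
    manifest = {
        "modnet_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": em.n_genes,
        "n_samples": em.n_samples,
        "partition": {
            "genomic": len(part.genomic),
            "non_genomic": len(part.non_genomic),
            "ambiguous": len(part.ambiguous),
        },
        "triplets": {name: len(scan) for name, scan in scans.items()},
        "networks": {
            name: {
                "modulators": len(net.modulator_nodes),
                "targets": len(net.target_nodes),
                "edges": net.n_edges,
            }
            for name, net in nets.items()
        },
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
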