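"""Peak parsing, MCS thresholds, gene assignment, consensus partition."""

import itertools

import numpy as np
import pytest

from modnet.binding import (
    Gene,
    Peak,
    assign_peaks_to_genes,
    load_annotation,
    load_peaks,
    mcs_threshold,
    partition_targets,
    write_annotation,
    write_peaks,
)
from modnet.simulate import simulate_annotation, simulate_peaks


class TestLoadPeaks:
    def test_parses_plain_bed3(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        peaks = load_peaks(p, "macs", 0.5)
        assert peaks == [Peak("chr1", 100, 200, "macs", 0.5)]

    def test_inverted_interval_rejected_with_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(ValueError, match=":2"):
            load_peaks(p, "macs", 0.5)

    def test_round_trip_of_random_peaks(self, tmp_path, rng):
        peaks = []
        for _ in range(50):
            s = int(rng.integers(0, 10_000))
            w = int(rng.integers(1, 500))
            peaks.append(
                Peak("chr2", s, s + w, "sissrs", 1.0, float(rng.random()))
            )
        path = tmp_path / "rt.bed"
        write_peaks(peaks, path, mcs_col=4)
        back = load_peaks(path, "sissrs", 1.0, mcs_col=4)
        assert len(back) == 50
        for a, b in zip(peaks, back):
            assert (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end)
            assert b.mcs == pytest.approx(a.mcs, abs=1e-6)

    def test_mcs_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            Peak("chr1", 0, 10, "macs", 0.0, mcs=1.5)


class TestMcsThreshold:
    def test_order_statistic_of_ten_values(self):
        peaks = [
            Peak("chr1", i, i + 1, "c", 0.0, mcs=(i + 1) / 10.0) for i in range(10)
        ]
        thr = mcs_threshold(peaks, 0.95)
        assert thr >= 0.9
        assert thr == pytest.approx(np.quantile(np.arange(0.1, 1.05, 0.1), 0.95))

    def test_constant_scores_return_that_constant(self):
        peaks = [Peak("chr1", i, i + 1, "c", 0.0, mcs=0.42) for i in range(5)]
        assert mcs_threshold(peaks) == pytest.approx(0.42)

    def test_matches_sorted_quantile_oracle(self, rng):
        scores = rng.random(1000)
        peaks = [Peak("chr1", i, i + 1, "c", 0.0, mcs=float(s)) for i, s in enumerate(scores)]
        assert mcs_threshold(peaks, 0.95) == pytest.approx(
            float(np.quantile(scores, 0.95))
        )

    def test_no_scores_anywhere_is_an_error(self):
        peaks = [Peak("chr1", 0, 10, "c", 0.0)]
        with pytest.raises(ValueError, match="no-mcs"):
            mcs_threshold(peaks)


class TestAssignment:
    def test_containment_overlap(self):
        g = Gene("g", "chr1", 100, 200, "+")
        p = Peak("chr1", 150, 160, "c", 0.0)
        assert assign_peaks_to_genes([p], [g]) == {"g": [p]}

    def test_upstream_window_catches_promoter_peak(self):
        g = Gene("g", "chr1", 100, 200, "+")
        p = Peak("chr1", 0, 50, "c", 0.0)
        assert "g" in assign_peaks_to_genes([p], [g], upstream_window=10_000)
        assert assign_peaks_to_genes([p], [g], upstream_window=0) == {}

    def test_minus_strand_window_extends_downstream_coordinate(self):
        g = Gene("g", "chr1", 100, 200, "-")
        upstream = Peak("chr1", 250, 260, "c", 0.0)   # 3' in coordinates = 5' of gene
        outside = Peak("chr1", 0, 50, "c", 0.0)
        got = assign_peaks_to_genes([upstream, outside], [g], upstream_window=100)
        assert got == {"g": [upstream]}

    def test_matches_brute_force_overlap_scan(self, rng):
        genes = [
            Gene(
                f"g{i}",
                "chr1",
                int(s := rng.integers(0, 50_000)),
                int(s + rng.integers(100, 2000)),
                "+" if rng.random() < 0.5 else "-",
            )
            for i in range(20)
        ]
        peaks = []
        for i in range(200):
            s = int(rng.integers(0, 55_000))
            peaks.append(Peak("chr1", s, s + int(rng.integers(1, 300)), "c", 0.0))
        w = 500
        got = assign_peaks_to_genes(peaks, genes, upstream_window=w)
        # O(n*m) oracle
        expected: dict[str, list[Peak]] = {}
        for g in genes:
            lo = max(0, g.start - w) if g.strand == "+" else g.start
            hi = g.end if g.strand == "+" else g.end + w
            for p in peaks:
                if p.start < hi and lo < p.end:
                    expected.setdefault(g.gene_id, []).append(p)
        assert {g: set(map(id, ps)) for g, ps in got.items()} == {
            g: set(map(id, ps)) for g, ps in expected.items()
        }


def _toy_assignments(bound: dict[str, list[tuple[str, float]]], mcs=1.0):
    """Build an assignments dict for genes bound at given (caller, tp) keys."""
    callers = ["c1", "c2", "c3", "c4"]
    tps = [0.0, 0.5, 1.0, 24.0]
    out = {}
    for c, tp in itertools.product(callers, tps):
        gene_map = {}
        for gene, keys in bound.items():
            if (c, tp) in keys:
                gene_map[gene] = [Peak("chr1", 0, 10, c, tp, mcs)]
        out[(c, tp)] = gene_map
    return out, callers, tps


class TestPartition:
    def test_full_consensus_gene_is_genomic(self):
        allkeys = list(itertools.product(["c1", "c2", "c3", "c4"], [0.0, 0.5, 1.0, 24.0]))
        assignments, callers, tps = _toy_assignments({"gA": allkeys})
        part = partition_targets(assignments, {"gA", "gB"}, callers, tps, mcs_cut=0.95)
        assert part.genomic == {"gA"}
        assert part.non_genomic == {"gB"}
        assert part.ambiguous == set()

    def test_three_of_four_callers_is_ambiguous(self):
        keys = list(itertools.product(["c1", "c2", "c3"], [0.0, 0.5, 1.0, 24.0]))
        assignments, callers, tps = _toy_assignments({"gA": keys})
        part = partition_targets(assignments, {"gA"}, callers, tps)
        assert part.ambiguous == {"gA"}
        assert part.genomic == set() and part.non_genomic == set()

    def test_no_peaks_anywhere_is_non_genomic(self):
        assignments, callers, tps = _toy_assignments({})
        part = partition_targets(assignments, {"gX"}, callers, tps)
        assert part.non_genomic == {"gX"}

    def test_mcs_cut_is_anti_monotone_on_genomic_set(self, rng):
        allkeys = list(itertools.product(["c1", "c2", "c3", "c4"], [0.0, 0.5, 1.0, 24.0]))
        callers = ["c1", "c2", "c3", "c4"]
        tps = [0.0, 0.5, 1.0, 24.0]
        assignments = {}
        genes = [f"g{i}" for i in range(30)]
        for c, tp in allkeys:
            assignments[(c, tp)] = {
                g: [Peak("chr1", 0, 10, c, tp, float(rng.random()))] for g in genes
            }
        prev = None
        for cut in (0.0, 0.25, 0.5, 0.75):
            part = partition_targets(assignments, set(genes), callers, tps, mcs_cut=cut)
            if prev is not None:
                assert part.genomic <= prev
            prev = part.genomic

    def test_dropping_a_required_caller_never_shrinks_genomic(self, rng):
        keys3 = list(itertools.product(["c1", "c2", "c3"], [0.0, 0.5, 1.0, 24.0]))
        assignments, callers, tps = _toy_assignments({"gA": keys3})
        full = partition_targets(assignments, {"gA"}, callers, tps)
        reduced = partition_targets(assignments, {"gA"}, ["c1", "c2", "c3"], tps)
        assert full.genomic <= reduced.genomic
        assert reduced.genomic == {"gA"}

    def test_partition_is_a_disjoint_cover_of_universe(self):
        keys = list(itertools.product(["c1", "c2"], [0.0, 0.5]))
        assignments, callers, tps = _toy_assignments({"gA": keys})
        part = partition_targets(assignments, {"gA", "gB", "gC"}, callers, tps)
        union = part.genomic | part.non_genomic | part.ambiguous
        assert union == {"gA", "gB", "gC"}

    def test_empty_universe_rejected(self):
        assignments, callers, tps = _toy_assignments({})
        with pytest.raises(ValueError):
            partition_targets(assignments, set(), callers, tps)


class TestSyntheticPeaks:
    def _recover(self, peaks, ann, universe, mcs_cut=0.95):
        assignments = {
            key: assign_peaks_to_genes(plist, ann, upstream_window=0)
            for key, plist in peaks.items()
        }
        callers = sorted({c for c, _ in peaks})
        tps = sorted({tp for _, tp in peaks})
        return partition_targets(assignments, universe, callers, tps, mcs_cut=mcs_cut)

    def test_zero_dropout_recovers_truth_exactly(self):
        genes = [f"g{i:02d}" for i in range(30)]
        ann = simulate_annotation(genes)
        genomic = set(genes[:6])
        ambiguous = set(genes[6:12])
        peaks, truth = simulate_peaks(genomic, ann, ambiguous=ambiguous, seed=4)
        part = self._recover(peaks, ann, set(genes))
        assert part.genomic == truth.genomic
        assert part.non_genomic == truth.non_genomic
        assert part.ambiguous == truth.ambiguous

    def test_decoy_with_partial_callers_lands_ambiguous(self):
        genes = [f"g{i}" for i in range(5)]
        ann = simulate_annotation(genes)
        peaks, _ = simulate_peaks(set(), ann, ambiguous={"g1"}, seed=0)
        part = self._recover(peaks, ann, set(genes))
        assert "g1" in part.ambiguous

    def test_dropout_only_loses_genomic_genes(self):
        genes = [f"g{i:02d}" for i in range(20)]
        ann = simulate_annotation(genes)
        genomic = set(genes[:8])
        peaks, truth = simulate_peaks(genomic, ann, dropout_rate=0.5, seed=8)
        part = self._recover(peaks, ann, set(genes))
        assert part.genomic <= truth.genomic
        assert truth.non_genomic <= part.non_genomic

    def test_partition_invariant_to_peak_order(self, rng):
        genes = [f"g{i:02d}" for i in range(15)]
        ann = simulate_annotation(genes)
        peaks, _ = simulate_peaks(set(genes[:3]), ann, ambiguous=set(genes[3:6]), seed=1)
        shuffled = {
            k: list(rng.permutation(np.array(v, dtype=object))) for k, v in peaks.items()
        }
        a = self._recover(peaks, ann, set(genes))
        b = self._recover(shuffled, ann, set(genes))
        assert (a.genomic, a.non_genomic, a.ambiguous) == (
            b.genomic, b.non_genomic, b.ambiguous,
        )


class TestAnnotationIO:
    def test_round_trip(self, tmp_path):
        genes = simulate_annotation([f"g{i}" for i in range(10)])
        path = tmp_path / "ann.bed"
        write_annotation(genes, path)
        back = load_annotation(path)
        assert back == genes

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "ann.bed"
        p.write_text("chr1\t0\t10\tg1\t.\t+\nchr1\t20\t30\tg1\t.\t-\n")
        with pytest.raises(ValueError, match="g1"):
            load_annotation(p)
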