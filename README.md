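# modnet

Modulator-based regulatory network inference for a transcription factor
(TF) signaling pathway, from an expression time course plus multi-caller
ChIP-seq binding evidence.

## Scientific problem

A TF such as ERα does not act alone: kinases, phosphatases,
acetyl-/deacetylases, methyltransferases, other TFs and cofactors can
modulate how strongly it drives each of its targets. Given expression
profiles over a time course of J samples, `modnet` asks, for every
candidate modulator gene M and candidate target gene T, whether M
changes the TF→T relationship. It fits the interaction model

    T = a1 + a2·M + b1·TF + b2·TF·M + ε

where M is the modulator's expression dichotomized at its median
(0 = low, 1 = high). Each coefficient among (a2, b1, b2) gets a
two-sided t-test; its *correlation indicator* is `+` (significantly
positive), `-` (significantly negative) or `0`. The sign triple
(a2, b1, b2) places each (M, T) triplet into one of 27 regulation
classes — e.g. `(0, +, +)` is "TF (Activator) and M (Agonist)"; 22 of
the 27 classes involve the modulator (non-zero interaction, or both
main effects non-zero).

Targets are first partitioned by ChIP-seq evidence into **genomic**
(a consensus binding peak from every peak caller at every timepoint,
with motif/confidence score above a cutoff), **non-genomic** (no peak
anywhere) and **ambiguous** (everything else); separate networks are
built for the genomic and non-genomic routes. Modulator–target edges
(restricted to the 22 modulator-involving classes) are then filtered by
a degree null model: edges are rewired uniformly at random 1000 times,
and only modulators whose degree reaches the 95% quantile of the pooled
null degree distribution are kept. Per-class false discovery rates are
estimated by permuting target profiles across samples.

## Worked example

Everything below is seeded and reproducible. First generate a synthetic
dataset with known ground truth:

```sh
$ modnet simulate --outdir demo/data --n-genes 120 --n-modulators 12 \
    --n-genomic 6 --n-ambiguous 5 --n-planted 8 --seed 7
wrote synthetic dataset to demo/data: 8 planted triplets, 6 genomic, 109 non-genomic, 5 ambiguous genes
```

This writes `expression.tsv` (121 genes × 12 samples, including the TF
`ESR1`), `catalog.tsv` (modulator candidates with function classes),
`annotation.bed`, 16 peak files (`peaks/<caller>_<timepoint>.bed` for 4
callers × 4 timepoints) and `truth.json`. Then run the pipeline from a
YAML config:

```yaml
# demo/config.yaml
workdir: out
expression: data/expression.tsv
catalog: data/catalog.tsv
annotation: data/annotation.bed
peaks_dir: data/peaks
tf_id: ESR1
mcs_mode: absolute      # synthetic peak scores carry an absolute scale
mcs_value: 0.95
cv_threshold: 0.0       # synthetic data needs no expression filtering
n_perm: 20
n_shuffles: 1000
seed: 7
```

```sh
$ cd demo && modnet run --config config.yaml
INFO modnet.pipeline: CV filter removed 0 of 121 genes
INFO modnet.pipeline: partition: 6 genomic, 109 non-genomic, 5 ambiguous
INFO modnet.network: degree threshold 3: 1/10 modulators kept (null expectation 1.61, FDR-style ratio 1.610)
INFO modnet.network: degree threshold 8: 1/12 modulators kept (null expectation 0.89, FDR-style ratio 0.893)
run complete (seed 7): genomic network 1M/3T/3E, non_genomic network 1M/8T/8E
```

The filtered non-genomic network is a plain edge list:

```sh
$ head -5 out/network_non_genomic.tsv
# config=b470e81134ed seed=7 modnet=0.1.0
# tf=ESR1
modulator	target	class_index	class_label
G0006	G0005	22	M (Repressor Agonist)
G0006	G0025	26	M (Repressor Agonist & Ind. Repressor)
```

and `categories_non_genomic.tsv` summarizes all 27 classes with
connection counts and permutation FDRs:

```sh
$ head -6 out/categories_non_genomic.tsv
# config=b470e81134ed seed=7 modnet=0.1.0
class_index	class_label	ci_a2	ci_b1	ci_b2	n_unique_modulators	n_unique_targets	n_connections	fdr
1	TF (Ind. Activator)	0	+	0	11	13	39	0.4666666667
2	TF (Ind. Repressor)	0	-	0	8	5	10	1
3	TF (Ind. Activator) and M (Ind. Activator)	+	+	0	3	4	4	0.3
4	TF (Ind. Repressor) and M (Ind. Activator)	+	-	0	0	0	0
```

Per-triplet fits (`triplets_*.tsv`), the target partition, GraphML
exports and a `manifest.json` with a config hash land in the same
directory; rerunning the identical config is bit-identical. Use
`modnet compare A.tsv B.tsv` to report the edge overlap between two
networks (e.g. genomic vs non-genomic routes).

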