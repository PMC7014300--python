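# rcspipe

Network-assisted functional characterization of proteins identified in
small-scale proteomics experiments.

2-DE/MALDI-TOF experiments and co-immunoprecipitation screens typically
yield short lists of candidate proteins — too few for gene-set statistics
on their own. `rcspipe` expands each candidate into a **Ranked Correlated
Set (RCS)**: the seed protein together with its highest-confidence
interaction partners from a STRING protein-links table, built at a fixed
size so that every seed's enrichment test has the same statistical power.
Each RCS is then characterized by over-representation analysis against
gene-set collections (GO slices, MSigDB hallmark, any GMT file), and
enriched terms are pooled across all RCSs to expose global functional
tendencies. The package also implements the two companion statistics such
studies use: Spearman correlation of total-count-normalized, log2-
transformed spectral counts against a reference protein across tumor
samples, and per-spot differential testing of 2-DE spot volumes.

It is aimed at computational biologists who have seed-protein lists, a
STRING `protein.links` file and GMT collections, and want a deterministic,
scriptable version of this workflow — plus a synthetic-data module that
generates all inputs with planted ground truth, so the whole pipeline is
testable without downloading anything.

## Method

**RCS construction.** Edges with STRING combined score strictly greater
than a threshold (default 700) are retained. For a seed with *m* eligible
neighbors: if *m* < 10 the seed is discarded (too few interactors for a
powered test); otherwise the RCS is the seed plus its top
min(*m*, 14) neighbors by combined score (ties broken lexicographically),
giving sets of 15 proteins whenever the neighborhood allows.

**Over-representation.** For an RCS with *n* members inside a collection
universe of *N* genes, a term annotating *K* universe genes and *k* RCS
members is scored with the exact hypergeometric upper tail

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ k),&nbsp; X ~ Hypergeom(N, K, n),

terms with k = 0 are not tested, p-values are Benjamini–Hochberg adjusted
per (RCS, collection) block, and a term is significant iff p ≤ 0.05 **and**
q ≤ 0.05. Collections are size-filtered before testing (default 10–2000
genes per term). Aggregation counts, per term, the number of RCSs in whose
significant list it appears.

**Quantitative statistics.** Spectral counts are normalized by per-sample
totals (with a pseudocount, default 0.5, so zeros are loggable),
log2-transformed, and rank-correlated: rho is the Pearson correlation of
mid-ranks; the p-value is the exact permutation probability for n < 10
(untied data) and the t-approximation t = rho·√((n−2)/(1−rho²)) otherwise.
Spot volumes are background-subtracted, normalized to the total valid-spot
quantity per gel, and compared between two replicate groups with a
two-sided pooled-variance Student t-test at p ≤ 0.05.

## Worked example

```python
from rcspipe import *

truth = simulate_all("demo", rng_seed=7)          # synthetic inputs + truth.json
net = read_string_edges("demo/network.tsv", score_threshold=700)
catalog = build_catalog(net, read_seed_list("demo/seeds.txt"))
print("retained:", catalog.n_retained,
      "discarded:", [s for s, n in catalog.discard_report])

col = filter_by_size(read_gmt("demo/genesets.gmt", name="synthetic"))
results = [enrich_rcs(r, col) for r in catalog.rcs_list]
print(aggregate_enrichments(results).head(5).to_string(index=False))

m = normalize_counts(CountMatrix.read_tsv("demo/counts.tsv"))
for r in correlate_with_reference(m, "GENE0001", ["GENE0002", "GENE0003"]):
    print(f"{r.protein_a}~{r.protein_b}: rho={r.rho:.3f} p={r.p_value:.2e}")
```

prints

```
retained: 7 discarded: ['GENE0008', 'GENE0009', 'GENE0010']
collection          term_id               description  frequency supporting_seeds
 synthetic PLANTED_GENE0001 planted term for GENE0001          1         GENE0001
 synthetic PLANTED_GENE0002 planted term for GENE0002          1         GENE0002
 synthetic PLANTED_GENE0003 planted term for GENE0003          1         GENE0003
 synthetic PLANTED_GENE0004 planted term for GENE0004          1         GENE0004
 synthetic PLANTED_GENE0005 planted term for GENE0005          1         GENE0005
GENE0001~GENE0002: rho=0.525 p=4.58e-08
GENE0001~GENE0003: rho=-0.151 p=1.45e-01
```

The three discarded seeds are exactly the synthetic seeds planted with
9-member modules — below the 10-interactor minimum. Each retained seed's
planted annotation term is recovered as its top enrichment, and the
protein pair planted at rank correlation 0.6 is estimated at 0.525 over 95
samples (within sampling error), while the independent pair is near zero
and non-significant.

The same stages are available from the shell:

```sh
rcspipe simulate --outdir demo --rng-seed 7
rcspipe run-all --config config.yaml --outdir demo_out
rcspipe enrich --network demo/network.tsv --seeds demo/seeds.txt \
    --gmt synthetic=demo/genesets.gmt --outdir demo_out
```

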