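# spongenet

Inference of miRNA-mediated ceRNA ("miRNA sponge") interaction networks
from paired expression profiles, with an isoform-level titration analysis
of when and why a sponge stops working.

## The problem

Competing endogenous RNAs (ceRNAs) regulate each other indirectly: a
lncRNA carrying binding sites for a miRNA can sequester that miRNA and
thereby de-repress the miRNA's mRNA targets. Two transcripts sharing a
miRNA are then co-expressed even though neither regulates the other
directly. `spongenet` detects such sponge interactions from matched
normal/tumour FPKM profiles of mRNAs, lncRNAs and miRNAs, and analyses
the *titration* side of the mechanism: sponging only works while the
sponge transcript and the miRNA have comparable concentrations, so a
large miRNA over-expression (or the loss of the site-bearing isoform)
breaks the program.

The package is for computational biologists who have expression matrices
and transcript sequences and want a tested, reproducible implementation
of the sensitivity-correlation approach — plus a synthetic-data generator
that provides ground truth for every stage, so the whole pipeline can be
validated without controlled-access patient data.

## The method

For a candidate triplet — mRNA *X*, lncRNA *Y*, miRNA *Z* — compute the
Pearson correlation ρ<sub>XY</sub> and the first-order partial
correlation

ρ<sub>XY|Z</sub> = (ρ<sub>XY</sub> − ρ<sub>XZ</sub>ρ<sub>ZY</sub>) / √((1 − ρ<sub>XZ</sub>²)(1 − ρ<sub>ZY</sub>²))

The **sensitivity correlation** is S = ρ<sub>XY</sub> − ρ<sub>XY|Z</sub>:
the drop in X–Y correlation when the miRNA is conditioned out. The
pipeline:

1. **Filter** — drop entities with > 10 % missing values; drop mRNAs whose
   3'UTR is shorter than 500 nt.
2. **Top pairs** — keep mRNA/lncRNA pairs above the 99th percentile of
   the overall correlation distribution.
3. **Triplet scan** — for each pair × miRNA compute S; keep S > 0.3.
4. **Seed-match enrichment** — scan 3'UTRs and lncRNA transcripts for the
   reverse complement of the miRNA's 6-mer seed (mature positions 2–7);
   keep triplets enriched in the shared miRNA's sites (one-sided
   hypergeometric test over 6-mer windows, p < 0.01, at least one site on
   each side).
5. **Network** — an undirected multigraph: nodes are mRNAs/lncRNAs, each
   edge is labelled by its mediating miRNA. Degree, hubs, per-miRNA edge
   fractions, neighbourhoods and normal-vs-cancer rewiring summaries are
   provided.

The isoform module takes paired per-patient isoform FPKM tables and
computes: a paired Student's t-test filter (p < 0.05), each isoform's
share of total gene abundance, the variation matrix (per-patient
cancer − normal differences; observations = isoforms, variables =
patients), its covariance PCA (classical scores and factors), isoform /
miRNA abundance ratios with paired tests, and a per-exon usage
comparison.

## Worked example

Generate a synthetic dataset (72 matched patients, 50 planted sponge
triplets, 50 confounded pairs, 50+50 background entities, 60 miRNAs),
infer the network, and inspect it:

```bash
spongenet simulate --out demo/data --seed 1
# wrote dataset with 150 mRNAs, 150 lncRNAs, 60 miRNAs to demo/data
spongenet infer --dataset demo/data --out demo/net
# network: 100 nodes, 50 edges
```

`demo/net/` now holds the sensitivity matrix, the triplet table, the
edge list, GraphML, and a JSON summary. All 50 edges connect planted
sponge pairs through their true mediating miRNA; the 50 confounded pairs
— just as strongly co-expressed, but through a shared transcriptional
factor rather than a miRNA — are rejected by the S > 0.3 filter.

The isoform analysis, in Python:

```python
from spongenet import SynthParams, simulate_isoform_titration
from spongenet.pipeline import run_isoform_analysis

ds = simulate_isoform_titration(SynthParams(random_seed=1))
res = run_isoform_analysis(ds.table, ds.mirna, reference_mirna="miR-ref")
print(res["report"].round(3))
```

```
            mean_normal  mean_cancer  fold_change  ttest_p  ratio_to_miR-ref_normal  ratio_to_miR-ref_cancer
isoform_id
iso-dom          47.787      151.044        3.161    0.000                    3.137                    1.448
iso-site         15.129       19.834        1.311    0.000                    0.993                    0.190
iso-bg06          4.657        5.370        1.153    0.002                    0.306                    0.051
```

Reading the numbers: the t-test filter retained the two planted
changing isoforms (plus one borderline background isoform). The
site-bearing isoform `iso-site` rises only 1.3-fold while the miRNA
rises ~5-fold, so its isoform/miRNA ratio collapses from ≈ 1 in normal
tissue to ≈ 0.19 in cancer — the titration signature of a sponge
overwhelmed by its miRNA. The dominant no-site isoform drives the
gene-level up-regulation but cannot sponge anything.

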