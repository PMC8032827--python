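# npstools

Statistics for asking whether chromatin-bound protein clusters co-localize
genome-wide and are enriched at natural replication-pausing sites (NPSs) —
tRNA genes, centromeres (CENs) and replication-termination regions (TERs) —
in a budding-yeast-scale genome. The package also quantifies ChIP-qPCR
enrichment (percent input by the 2^(−ΔCt) method) and classifies
electron-microscopy DNA replication intermediates (forks, bubbles, reversed
forks, double Holliday Junctions, hemicatenanes) from measured branch
lengths.

It is aimed at analyses of ChIP-on-chip / ChIP-seq *cluster sets* — per-
protein sets of genomic intervals of significant enrichment — where the
question is not peak calling but whether two binding landscapes share more
of the genome than chance allows.

## The statistics

**Co-localization score.** For cluster sets *A* and *B* on a genome of *G*
bases, the score is the shared footprint |A ∩ B| in bp. Significance comes
two ways, and reports always carry both:

* **Monte-Carlo null** — per iteration, one set's clusters are re-placed
  uniformly at random (per chromosome, preserving the number of clusters
  and their lengths, placements kept disjoint) and the score recomputed;
  the empirical p is the add-one estimator
  (1 + #{null ≥ observed}) / (n<sub>iter</sub> + 1).
* **One-tailed Fisher's exact test** on the 2×2 base-count table
  (|A∩B|, |A|−|A∩B|, |B|−|A∩B|, G−|A∪B|): the hypergeometric upper tail
  P(X ≥ |A∩B|). Bases within a cluster are autocorrelated, so this is
  anti-conservative; the empirical p is the recommended headline number.

**Enrichment at features.** Fold increase = observed overlap with a feature
class / overlap expected for random binding (analytic independence
expectation |A|·|F|/G, or the Monte-Carlo mean). A discrete feature counts
as *bound* when overlapped by ≥ 1 bp (adjustable); co-occupancy tables give
per-combination counts and percentages across proteins.

**EM joint molecules.** Molecules recorded as junction counts plus branch
lengths (nm; 180 nm ≙ 500 bp) are classified by ordered geometric rules —
equal daughter arms with a shorter regressed arm ⇒ reversed fork; two
four-way junctions ⇒ dHJ; opposite branch-sums equal (two filaments of the
same size) ⇒ hemicatenane — then tabulated per genotype.

**ChIP-qPCR.** percent input = 100 · 2^((Ct_input − log2(dilution)) − Ct_IP),
summarized as mean ± SEM with unpaired two-tailed Student's t-tests.

A synthetic-data module generates every input at yeast scale (16
chromosomes, ~12.07 Mb, 71 TERs, 16 CENs, 275 tRNA genes) with one
interpretable co-localization knob: the fraction *f* of clusters anchored
on feature midpoints.

## Worked example

```python
from npstools.simulate import make_genome, place_features, make_cluster_set
from npstools.coloc import colocalization_test, genome_coverage_percent
from npstools.enrichment import cooccupancy, fold_increase

genome = make_genome()                      # 16 chromosomes, 12,071,326 bp
feats = place_features(genome, seed=1)      # 71 TERs, 16 CENs, 275 tRNAs
top3 = make_cluster_set(genome, protein="Top3", n_clusters=300,
                        anchors=feats["TER"], anchor_fraction=0.5, seed=2)
smc6 = make_cluster_set(genome, protein="Smc6", n_clusters=300,
                        anchors=feats["TER"], anchor_fraction=0.5, seed=3)

r = colocalization_test(top3, smc6, n_iterations=1000, seed=4)
print(f"overlap: {r.observed_overlap_bp} bp (expected {r.expected_overlap_bp:.0f} bp)")
print(f"fold: {r.fold:.2f}  empirical p: {r.empirical_p:.4g}  Fisher p: {r.fisher_p:.3g}")
print(f"Top3 genome coverage: {genome_coverage_percent(top3):.2f}%")

fr = fold_increase(top3, feats["TER"])
print(f"Top3 fold increase at TERs: {fr.fold:.2f} (Fisher p {fr.fisher_p:.3g})")

m = cooccupancy({"Top3": top3, "Smc6": smc6}, feats["TER"])
print(f"TERs bound by both: {m.bound_count(('Top3','Smc6'))}/{m.n_features} "
      f"({m.bound_percent(('Top3','Smc6')):.1f}%)")
```

prints

```
overlap: 67375 bp (expected 5790 bp)
fold: 11.64  empirical p: 0.000999  Fisher p: 2.23e-308
Top3 genome coverage: 2.18%
Top3 fold increase at TERs: 13.53 (Fisher p 2.23e-308)
TERs bound by both: 57/71 (80.3%)
```

Both cluster sets put half their clusters at the 71 TERs, so they overlap
~11.6-fold more than random placement predicts; the empirical p of
0.000999 = 1/1001 is the smallest value 1000 iterations can report. The
Fisher p on raw base counts is far smaller — that inflation is why the
empirical p is the headline statistic. With a 2 kb anchor jitter/length
scale, 57 of the 71 TERs end up bound by both proteins.

The same analyses run from the shell: `npstools simulate|coloc|enrich|
cooccupancy|coverage|classify-jm|qpcr --help`. Every stochastic subcommand
requires `--seed`, and each run writes a JSON manifest that reproduces it.

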