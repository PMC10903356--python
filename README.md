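# tici — a taxon-independent community index for eDNA biomonitoring

`tici` implements a taxon-independent community index (TICI) for assessing
the ecological health of rivers and streams from environmental DNA (eDNA)
metabarcoding surveys. Instead of relying on a curated list of indicator
taxa — as the New Zealand macroinvertebrate community index (MCI) does —
the method assigns a health indicator value to every commonly encountered
amplicon sequence variant (ASV), regardless of whether it can be named.
This opens bioassessment to the whole tree of life captured by
multi-marker metabarcoding (bacteria, fungi, algae, plants, invertebrates,
vertebrates) and removes the taxonomist bottleneck.

It is intended for ecologists and environmental managers working with
replicated eDNA surveys: many sites, each sampled with several replicate
water samples, sequenced with one or more metabarcoding assays.

## The method

Let `prev(j, i)` be the number of site *i*'s replicate samples in which ASV
*j* is detected (reads ≥ 5), ranging 0–16 in a 16-replicate design. Given a
site condition ranking *R*, each ASV gets an indicator value on a 0–10
scale from the tie-aware Spearman rank correlation ρ between *R* and its
site-prevalence ranking:

    v_j = (ρ(R, prev_j) + 1) × 5

so 10 means "found preferentially at high-condition sites", 0 the reverse,
5 no association. A sample's score is the mean `v_j` over the indicator
ASVs detected in it; a site's score is the mean over its replicates; and
the final TICI multiplies by 20, giving a 0–200 scale commensurate with
the MCI.

Training is unsupervised (the Chessman iterative process): start from a
random site ranking, compute indicator values, score samples and sites,
re-rank sites by ascending score, and repeat until the indicator values
reach a fixed point (with cycle detection and an iteration cap as safety
rails). The loop finds the dominant monotone gradient in the detection
data but cannot tell which end is "healthy", so the trained model is
*oriented* against an external reference index (e.g. a 5-year median MCI):
if the correlation is negative, every value is mirrored `v ↦ 10 − v`.

Scoring includes condition categories (Very poor < 80 ≤ Poor < 90 ≤
Average < 100 ≤ Good < 110 ≤ Excellent ≤ 120 < Pristine), a low-coverage
flag for samples detecting fewer than 100 indicator ASVs, and a two-sigma
negative-control contamination check. A synthetic-survey generator with a
known latent condition gradient makes the whole pipeline testable without
sequencing data.

## Worked example

Everything below runs from a seed alone — the demo simulates a 30-site ×
8-replicate × 1,000-ASV survey, trains a 500-ASV indicator model, orients
it, scores the survey and validates against the simulated reference index:

```sh
tici pipeline --seed 7 --workdir demo/
```

prints

```
converged_by    fixed_point
iterations      4
orientation     inverted
accuracy_r2     0.9853
adj_r_squared   0.9848
mean_cv 0.0300
```

The training loop reached an exact fixed point after 4 value-changing
iterations; the learned gradient came out anti-correlated with the
reference, so the model was inverted (this happens with probability ~1/2
and is expected). Site-averaged TICI explains 98.5% of the variance in the
simulated reference condition scores, and replicate TICI values vary by
only 3% around their site means. `demo/report.tsv` then holds per-sample
and per-site scores:

```
sample_id   site_id  tici    n_indicator_asvs  low_coverage  category
ST001_R01   ST001    115.22  224               false         Excellent
...
site_id  tici_mean  tici_sd  cv      category
ST001    116.79     3.3415   0.0286  Excellent
ST004    73.39      3.7433   0.0510  Very poor
```

The same stages are available separately (`tici simulate`, `tici train`,
`tici score`, `tici validate`, `tici optimize-n`) and as library functions
(`tici.generate_survey`, `tici.chessman_train`, `tici.orient_model`,
`tici.score_survey`, `tici.regress_vs_reference`, ...). See
`docs/methods.md` for the model's assumptions and design choices.

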