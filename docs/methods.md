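# Methods

## Model

The package computes a taxon-independent community index (TICI) for
replicated eDNA metabarcoding surveys. The underlying assumption is the
classic one behind biotic indices: the community present at a site
reflects the site's ecological condition, and individual taxa — here,
anonymous amplicon sequence variants (ASVs) — respond monotonically
(positively, negatively, or not at all) to a single dominant condition
gradient.

All computation is presence-based. An ASV is *detected* in a sample when
its aggregated read count reaches the detection threshold (`min_count`,
default 5 reads — the same floor normally applied during ASV denoising).
The per-site signal for ASV *j* is its **prevalence**: the number of the
site's field replicates in which it is detected (0–16 in a 16-replicate
design). Abundance beyond the threshold is deliberately ignored; read
counts are too sensitive to amplification bias to compare across assays
and taxa, while replicate detection frequency is a robust ordinal signal.

Given a site condition ranking, ASV *j*'s **indicator value** is

    v_j = (rho_j + 1) * 5   in [0, 10],

where `rho_j` is the tie-aware Spearman correlation (average-rank
transform, then Pearson) between the condition ranking and the ranking of
sites by the ASV's prevalence. A sample's raw score is the unweighted mean
of the indicator values of the indicator ASVs it contains; a site's score
is the mean over its replicates; the reported TICI multiplies by 20
(range 0–200, commensurate with the macroinvertebrate community index).

## Training (the Chessman iterative process)

Training alternates until a fixed point:

1. compute all `v_j` from the current site ranking;
2. score samples, then sites;
3. re-rank sites by ascending site score (ties get average ranks).

The initial ranking is either a uniformly random permutation (`random`
init; the unsupervised mode) or the ranking of an external reference score
(`guided` init). Convergence is declared when the maximum absolute change
in indicator values is ≤ `tol` (default 0 — an exact fixed point). Two
safety rails exist because iterated rank maps need not contract: if a
previously visited site ranking recurs the run stops with
`converged_by = cycle` (the model from the final iteration is returned),
and `max_iter` (default 100) caps the loop. In practice, on surveys with
any appreciable gradient, the loop reaches an exact fixed point within a
handful of iterations.

`training_meta.iterations` counts the iterations that changed the
indicator values; the final evaluation that merely confirms the fixed
point is not counted. A completely uninformative survey (every ASV equally
prevalent at all sites) therefore converges in one iteration with every
value exactly 5: a zero-variance prevalence ranking has an undefined
Spearman correlation, which is defined here as 0 (the neutral value), so
degenerate ASVs neither raise nor lower any sample's score.

The learned gradient's *direction* is unidentifiable from detection data
alone — training from a reversed initial ranking yields the exactly
mirrored model (`v ↦ 10 − v`), an invariance the test suite checks on a
noiseless fixture. **Orientation** resolves the ambiguity: site scores are
correlated (Spearman) against an external reference index over at least 3
shared sites, and the model is mirrored if the correlation is negative.
Orientation is idempotent, and scoring with a mirrored model maps every
sample TICI to `200 − TICI` exactly.

When sites have unequal replicate counts, prevalence is converted to the
fraction of replicates before ranking (identical to raw counts in a
balanced design). Site-ranking ties take average ranks, keeping the loop
deterministic. The only stochastic element in training is the seed of the
random initial permutation.

## Indicator-set selection

The indicator set is the `n` (default 3,000) ASVs detected in the largest
number of field samples; negative controls never count. Boundary ties are
broken by total read count, then lexicographic ASV id, so a selection is
reproducible bit-for-bit. Counting detection over *samples* rather than
sites weights consistently-detected ASVs upward; the alternative (site
grain) is not exposed because sample grain already determines a unique
deterministic ranking.

## Scoring, categories and QC

- Sample TICI = 20 × mean indicator value of model ASVs detected in the
  sample; a sample containing no model ASVs has an undefined score,
  reported as missing (never 0) and excluded from its site's mean.
- Site statistics use the sample mean and the n−1 standard deviation; the
  coefficient of variation (CV = sd/mean) is the replicate-precision
  measure.
- Condition categories are half-open intervals on the TICI scale:
  (−∞, 80) Very poor, [80, 90) Poor, [90, 100) Average, [100, 110) Good,
  [110, 120] Excellent, (120, ∞) Pristine. The published category table
  prints overlapping endpoints ("80–90", "90–100"), so a convention had to
  be imposed; lower-inclusive bounds were chosen, with 120 kept in
  Excellent to respect the printed "&gt;120" for Pristine.
- Samples detecting fewer than 100 indicator ASVs are flagged
  `low_coverage`: below that coverage, replicate scores scatter visibly
  more around the site mean.
- Negative controls: a run's control is compared against
  `mean + 2 sd` (n−1 sd) of the indicator-ASV counts of previous runs'
  controls; *exceeding* the threshold fails QC (equality passes). A
  nonzero baseline in controls is normal (airborne microbes), hence the
  history-calibrated threshold. The check flags; it never drops data —
  repeating the run is an operator decision.

## Validation machinery

Accuracy is the ordinary least squares fit of the reference condition
score on site-averaged TICI (site averages, to avoid pseudo-replication),
reporting slope, intercept, R², adjusted R² = 1 − (1−R²)(n−1)/(n−2), and
the two-sided slope p-value on n−2 df (delegated to statsmodels). The
regression direction is cosmetic — R² is symmetric — but fixed. Precision
is the unweighted mean per-site CV over sites with ≥ 2 scored replicates.
Inter-model agreement is the OLS R² between two models' indicator-value
vectors over a shared ASV set. `optimize_indicator_count` sweeps the
indicator-set size over a user grid and reports both criteria per size;
the "best" size maximises accuracy, with precision reported alongside
rather than folded into a composite, since the trade-off is an operator
choice.

## Synthetic surveys

The generator emulates a multi-site, multi-replicate eDNA survey with a
known latent gradient. Site conditions are uniform on [0, 1]; a fraction
`frac_informative` (default 0.5) of ASVs receives a signed logit slope
with magnitude `effect_scale × U(0.5, 1)` (default scale 6, a strong
gradient: detection probability swings from rare to near-certain across
the condition range); occurrence probability is

    p_ij = logistic(baseline_j + effect_j (condition_i − 1/2) + eps_ij),

`baseline_j ~ U(−2.5, 0.5)` (site occupancy roughly 8–60% for neutral
ASVs) and `eps_ij ~ N(0, 0.25)` site-level noise. Centring the condition
keeps positive- and negative-responding ASVs symmetric in overall
occupancy; it is the same monotone model as an uncentred logit with a
shifted baseline. Replicate detections are independent Bernoulli draws;
detected entries get negative-binomial read counts floored at the
detection threshold (counts are cosmetic — the index is presence-based —
but exercise the thresholding path). Negative controls receive contaminant
detections at `contamination_rate` (default 0.005). Reference scores are
emitted on an MCI-like scale, `60 + 80 × condition + N(0, 2)`. Default
survey shape is 53 sites × 16 replicates × 3,000 ASVs with eight assay
codes attached round-robin as metadata.

What the simulator does *not* emulate: spatial autocorrelation between
sites, assay-specific detection biases, PCR/sequencing error, chimeras,
between-replicate dependence, and multi-gradient community structure.
Passing recovery tests therefore shows the algorithm extracts a monotone
occupancy gradient when one dominates; it does not show how the index
behaves when several environmental gradients compete, which on real data
is resolved by the external orientation/validation step.

## Numerical choices and degenerate inputs

- Spearman: average ranks throughout (prevalence data are heavily tied);
  zero-variance vectors → rho 0; results clipped to [−1, 1] against
  floating-point drift.
- Convergence tolerance defaults to 0 (exact fixed point on indicator
  values); site-ranking fingerprints (MD5 of the rank vector) drive cycle
  detection.
- Undefined sample scores propagate as NaN and are excluded from site
  means; a site with no scorable samples is an error during training and
  a missing site score when scoring.
- Model serialisation keeps 6 decimal places (round-trip error ≤ 1e-6);
  report files print TICI to 2 and CV to 4 decimal places.
- Training problem sizes in the test suite (20–40 sites, 6–16 replicates,
  400–2,000 ASVs) were chosen as the smallest surveys on which recovery
  and reproducibility are comfortably stable; the algorithm itself is
  vectorised and handles the full-survey scale (50+ sites, 3,000
  indicators, ~800 samples) in seconds.

## Known limitations

- A trained model transfers only to samples processed with a comparable
  assay panel and detection pipeline; indicator values are tied to the
  ASV identifiers they were trained on.
- Orientation needs an external reference over ≥ 3 sites; without one the
  model's direction is arbitrary (flagged via the `orientation` field).
- Sites scored from few replicates or low-coverage samples carry wider
  uncertainty than the point TICI suggests; use the CV and the
  low-coverage flag.
- The two-sigma QC rule needs a history of negative-control counts from
  previous runs; a fresh laboratory has no calibration.
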