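"""Synthetic replicated eDNA surveys with a known latent condition gradient.

The generator emulates the kind of survey the index is trained on: many
sites, each sampled with a fixed number of replicate water samples, and a
large ASV pool in which some fraction of ASVs responds monotonically —
positively or negatively — to an unobserved ecological-condition gradient.
Occurrence follows the simplest monotone link: per site i and ASV j,

    p_ij = logistic(baseline_j + effect_j * (condition_i - 1/2) + eps_ij)

with eps_ij ~ Normal(0, detection_noise), and each replicate's detection is
an independent Bernoulli(p_ij) draw. Detected entries receive an
over-dispersed (negative-binomial) read count floored at the detection
threshold, so thresholding paths are exercised even though the index itself
is presence-based. The ground truth (site conditions and signed per-ASV
effects) is returned so that recovery can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_MIN_COUNT
from .io import (
    ASVTable,
    NEGATIVE_CONTROL_SITE,
    ROLE_FIELD_SAMPLE,
    ROLE_NEGATIVE_CONTROL,
    SiteDesign,
    SiteInfo,
)

#: Assay codes carried as metadata, mirroring an 8-assay multi-marker panel
#: spanning bacteria to vertebrates.
ASSAY_CODES = ("BE", "BU", "CI", "MZ", "RV", "TP", "UM", "WV")


@dataclass
class SyntheticConfig:
    """Survey-generator settings.

    Defaults emulate the training-survey design the index was developed on:
    53 sites × 16 replicates, a 3,000-ASV pool with half the ASVs
    responding to the gradient, a strong effect scale, and mild site-level
    detection noise.
    """

    n_sites: int = 53
    replicates_per_site: int = 16
    n_asvs: int = 3000
    frac_informative: float = 0.5
    effect_scale: float = 6.0
    baseline_logit_range: tuple[float, float] = (-2.5, 0.5)
    detection_noise: float = 0.25
    read_count_mean: float = 60.0
    read_count_dispersion: float = 1.0
    n_negative_controls: int = 2
    contamination_rate: float = 0.005
    reference_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.replicates_per_site < 1 or self.n_asvs < 1:
            raise ValueError("site, replicate and ASV counts must be >= 1")
        if not 0.0 <= self.frac_informative <= 1.0:
            raise ValueError("frac_informative must be in [0, 1]")
        if self.effect_scale < 0 or self.detection_noise < 0:
            raise ValueError("effect_scale and detection_noise must be >= 0")
        if not 0.0 <= self.contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.read_count_mean <= 0 or self.read_count_dispersion <= 0:
            raise ValueError("read-count law parameters must be positive")
        lo, hi = self.baseline_logit_range
        if lo > hi:
            raise ValueError("baseline_logit_range must be (low, high)")


@dataclass
class GroundTruth:
    """Latent state behind a generated survey."""

    site_condition: dict[str, float]
    asv_effect: dict[str, float]    # signed logit slope; 0 for uninformative
    asv_baseline: dict[str, float]  # centred occurrence logit at condition 0.5

    @property
    def n_informative(self) -> int:
        return sum(1 for e in self.asv_effect.values() if e != 0.0)


def expected_indicator(truth: GroundTruth, asv_id: str) -> int:
    """Sign of the expected deviation of an ASV's trained indicator from 5.

    +1 for a positive effect (prevalence rises with condition, indicator
    above 5 after orientation), −1 for a negative effect, 0 for an
    uninformative ASV. A direction oracle only, not a quantitative one.
    """
    effect = truth.asv_effect[asv_id]
    return int(np.sign(effect))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_survey(config: SyntheticConfig,
                    ) -> tuple[ASVTable, SiteDesign, GroundTruth]:
    """Generate one replicated survey; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_sites, reps, n_asvs = (config.n_sites, config.replicates_per_site,
                             config.n_asvs)
    width = max(3, len(str(n_sites)))
    site_ids = [f"ST{i + 1:0{width}d}" for i in range(n_sites)]
    asv_width = max(4, len(str(n_asvs)))
    asv_ids = [f"asv{j + 1:0{asv_width}d}" for j in range(n_asvs)]
    assays = {a: ASSAY_CODES[j % len(ASSAY_CODES)]
              for j, a in enumerate(asv_ids)}

    condition = rng.uniform(0.0, 1.0, n_sites)
    n_informative = round(config.frac_informative * n_asvs)
    effects = np.zeros(n_asvs)
    if n_informative:
        informative = rng.choice(n_asvs, size=n_informative, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_informative)
        magnitudes = config.effect_scale * rng.uniform(0.5, 1.0, n_informative)
        effects[informative] = signs * magnitudes
    lo, hi = config.baseline_logit_range
    baselines = rng.uniform(lo, hi, n_asvs)

    logit = (baselines[None, :]
             + np.outer(condition - 0.5, effects)
             + rng.normal(0.0, config.detection_noise, (n_sites, n_asvs)))
    p = _sigmoid(logit)

    # Replicate-level Bernoulli detections: (site, replicate, asv).
    detected = rng.random((n_sites, reps, n_asvs)) < p[:, None, :]

    samples: dict[str, tuple[str, str]] = {}
    records: list[pd.DataFrame] = []
    min_count = DEFAULT_MIN_COUNT

    def _counts(n: int) -> np.ndarray:
        mean_excess = max(config.read_count_mean - min_count, 1.0)
        k = config.read_count_dispersion
        return min_count + rng.negative_binomial(
            k, k / (k + mean_excess), size=n)

    for i, site in enumerate(site_ids):
        for r in range(reps):
            sample_id = f"{site}_R{r + 1:02d}"
            samples[sample_id] = (site, ROLE_FIELD_SAMPLE)
            hits = np.flatnonzero(detected[i, r])
            if hits.size:
                records.append(pd.DataFrame({
                    "sample_id": sample_id,
                    "asv_id": [asv_ids[j] for j in hits],
                    "assay": [assays[asv_ids[j]] for j in hits],
                    "count": _counts(hits.size),
                }))

    for c in range(config.n_negative_controls):
        sample_id = f"NC{c + 1:02d}"
        samples[sample_id] = (NEGATIVE_CONTROL_SITE, ROLE_NEGATIVE_CONTROL)
        hits = np.flatnonzero(rng.random(n_asvs) < config.contamination_rate)
        if hits.size:
            records.append(pd.DataFrame({
                "sample_id": sample_id,
                "asv_id": [asv_ids[j] for j in hits],
                "assay": [assays[asv_ids[j]] for j in hits],
                "count": _counts(hits.size),
            }))

    if records:
        long = pd.concat(records, ignore_index=True)
    else:
        long = pd.DataFrame(columns=["sample_id", "asv_id", "assay", "count"])
    table = ASVTable.from_records(long)

    # Reference scores on an MCI-like scale, monotone in condition with
    # small observation noise.
    reference = 60.0 + 80.0 * condition + rng.normal(
        0.0, config.reference_noise_sd, n_sites)
    sites = {site: SiteInfo(reference_score=round(float(ref), 2))
             for site, ref in zip(site_ids, reference)}
    design = SiteDesign(samples=samples, sites=sites)

    truth = GroundTruth(
        site_condition=dict(zip(site_ids, condition.tolist())),
        asv_effect=dict(zip(asv_ids, effects.tolist())),
        asv_baseline=dict(zip(asv_ids, baselines.tolist())),
    )
    return table, design, truth


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialise ground truth as TSV (one block of sites, one of ASVs)."""
    rows = [{"kind": "site", "id": s, "condition": repr(c), "effect": "",
             "baseline": ""} for s, c in truth.site_condition.items()]
    rows += [{"kind": "asv", "id": a, "condition": "",
              "effect": repr(truth.asv_effect[a]),
              "baseline": repr(truth.asv_baseline[a])}
             for a in truth.asv_effect]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sites = df[df["kind"] == "site"]
    asvs = df[df["kind"] == "asv"]
    return GroundTruth(
        site_condition={r["id"]: float(r["condition"])
                        for _, r in sites.iterrows()},
        asv_effect={r["id"]: float(r["effect"]) for _, r in asvs.iterrows()},
        asv_baseline={r["id"]: float(r["baseline"])
                      for _, r in asvs.iterrows()},
    )
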