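"""Apply a trained indicator model: sample/site TICI, categories, QC.

A sample's TICI is 20 × the mean indicator value of the model ASVs detected
in it, giving a 0–200 scale deliberately commensurate with the
macroinvertebrate community index (MCI) used for stream condition reporting.
Site scores are the mean over field replicates, with a coefficient of
variation as the precision estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_MIN_COUNT, presence_matrix
from .exceptions import ValidationError
from .io import ASVTable, IndicatorModel, SiteDesign, TICIReport

#: Samples detecting fewer than this many indicator ASVs score with
#: noticeably lower precision and are flagged as low coverage.
LOW_COVERAGE_THRESHOLD = 100

#: Final scale factor from the 0–10 indicator mean to the 0–200 TICI scale.
TICI_SCALE = 20.0


@dataclass(frozen=True)
class CategoryScheme:
    """Condition-category thresholds on the TICI scale.

    The printed category ranges overlap at their endpoints, so a half-open
    convention is imposed: lower bounds are inclusive except that the top
    threshold still belongs to the second-highest category (a score of
    exactly 120 is Excellent; Pristine is strictly above).
    """

    thresholds: tuple[float, ...] = (80.0, 90.0, 100.0, 110.0, 120.0)
    labels: tuple[str, ...] = ("Very poor", "Poor", "Average", "Good",
                               "Excellent", "Pristine")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValidationError("need exactly one more label than threshold")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValidationError("thresholds must be strictly increasing")


DEFAULT_SCHEME = CategoryScheme()


def categorize(tici: float, scheme: CategoryScheme = DEFAULT_SCHEME) -> str:
    """Condition category for a TICI value.

    With the default scheme: (−∞, 80) Very poor; [80, 90) Poor; [90, 100)
    Average; [100, 110) Good; [110, 120] Excellent; (120, ∞) Pristine.
    """
    if math.isnan(tici):
        return ""
    if tici < 0:
        raise ValueError(f"tici {tici} < 0")
    top = scheme.thresholds[-1]
    if tici > top:
        return scheme.labels[-1]
    for threshold, label in zip(scheme.thresholds, scheme.labels):
        if tici < threshold:
            return label
    return scheme.labels[-2]  # tici == top boundary


def score_sample(sample_presence: np.ndarray, model: IndicatorModel,
                 ) -> tuple[float, int, bool]:
    """Score one sample against a model.

    ``sample_presence`` is a boolean vector aligned to ``model.asv_ids``.
    Returns (tici, n_indicator_asvs, low_coverage); tici is NaN when no
    model ASV is present (an undefined score, not zero).
    """
    if model.n_indicators == 0:
        raise ValidationError("cannot score with an empty model")
    sample_presence = np.asarray(sample_presence, dtype=bool)
    values = model.values_series().to_numpy()
    if sample_presence.shape != values.shape:
        raise ValueError("presence vector length != model size")
    n = int(sample_presence.sum())
    if n == 0:
        return float("nan"), 0, True
    tici = TICI_SCALE * float(values[sample_presence].mean())
    return tici, n, n < LOW_COVERAGE_THRESHOLD


def score_site(sample_scores: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample (n−1) SD, and CV of a site's defined replicate scores.

    SD and CV are NaN with a single replicate; the mean is NaN if no
    replicate has a defined score.
    """
    scores = np.asarray([s for s in sample_scores if not math.isnan(s)],
                        dtype=float)
    if scores.size == 0:
        return float("nan"), float("nan"), float("nan")
    mean = float(scores.mean())
    if scores.size < 2:
        return mean, float("nan"), float("nan")
    sd = float(scores.std(ddof=1))
    cv = sd / mean if mean != 0 else float("nan")
    return mean, sd, cv


def qc_negative_control(control_indicator_count: int,
                        history: Sequence[int]) -> tuple[bool, float]:
    """Two-sigma contamination rule for a sequencing run's negative control.

    The threshold is mean(history) + 2 × sd(history) over the indicator-ASV
    counts of previous runs' controls; the run passes unless the current
    control *exceeds* the threshold (equality passes). A base level of
    detections in controls is normal (airborne microbes), hence a history-
    calibrated rather than zero threshold. Failing flags the run for repeat;
    nothing is dropped automatically.
    """
    history = np.asarray(history, dtype=float)
    if history.size < 2:
        raise ValidationError("negative-control history needs >= 2 runs")
    threshold = float(history.mean() + 2.0 * history.std(ddof=1))
    return control_indicator_count <= threshold, threshold


def score_survey(table: ASVTable, design: SiteDesign, model: IndicatorModel,
                 min_count: int = DEFAULT_MIN_COUNT,
                 scheme: CategoryScheme = DEFAULT_SCHEME) -> TICIReport:
    """Score every sample and site of a survey against a trained model.

    Model ASVs absent from the table are treated as undetected everywhere.
    Undefined sample scores are reported as missing and excluded from the
    site mean. Negative controls are scored as samples (their indicator-ASV
    counts feed the two-sigma QC) but never enter site aggregates.
    """
    pm = presence_matrix(table, min_count=min_count)
    asv_idx = {a: j for j, a in enumerate(pm.asvs)}
    model_cols = np.array([asv_idx.get(a, -1) for a in model.asv_ids])
    in_table = model_cols >= 0

    sample_rows = []
    site_scores: dict[str, list[float]] = {}
    for sample_id in pm.samples:
        if sample_id not in design.samples:
            raise ValidationError(f"sample {sample_id!r} missing from design")
        row = pm.sample_row(sample_id)
        presence_vec = np.zeros(model.n_indicators, dtype=bool)
        presence_vec[in_table] = row[model_cols[in_table]]
        tici, n, low = score_sample(presence_vec, model)
        site_id, role = design.samples[sample_id]
        sample_rows.append({
            "sample_id": sample_id, "site_id": site_id, "tici": tici,
            "n_indicator_asvs": n, "low_coverage": low,
            "category": categorize(tici, scheme),
        })
        if role == "field_sample":
            site_scores.setdefault(site_id, []).append(tici)

    site_rows = []
    for site_id in sorted(site_scores):
        mean, sd, cv = score_site(site_scores[site_id])
        site_rows.append({
            "site_id": site_id, "tici_mean": mean, "tici_sd": sd, "cv": cv,
            "n_samples": len(site_scores[site_id]),
            "category": categorize(mean, scheme) if not math.isnan(mean) else "",
        })

    per_sample = pd.DataFrame(
        sample_rows, columns=["sample_id", "site_id", "tici",
                              "n_indicator_asvs", "low_coverage", "category"])
    per_site = pd.DataFrame(
        site_rows, columns=["site_id", "tici_mean", "tici_sd", "cv",
                            "n_samples", "category"])
    return TICIReport(per_sample=per_sample, per_site=per_site)
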