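"""Evaluation machinery: accuracy vs an external reference index, replicate
precision, inter-model agreement, and indicator-set-size optimisation.

Accuracy is judged by ordinary least squares of the reference condition
score (e.g. a 5-year median MCI) on site-averaged TICI — site averages, not
individual replicates, to avoid pseudo-replication. Precision is the mean
coefficient of variation of replicate TICI values within sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import presence_matrix, select_indicators
from .exceptions import ValidationError
from .io import ASVTable, IndicatorModel, SiteDesign, TICIReport
from .scoring import score_survey
from .training import chessman_train, orient_model, random_init

logger = logging.getLogger("tici.validation")


@dataclass
class ValidationReport:
    """OLS fit of reference vs site-averaged TICI, plus replicate precision."""

    n_sites: int
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    mean_cv: float
    per_site: pd.DataFrame  # columns: site_id, tici, reference


def regress_vs_reference(site_tici: Mapping[str, float],
                         reference: Mapping[str, float],
                         mean_cv: float = float("nan")) -> ValidationReport:
    """OLS of reference score on site-averaged TICI over the common sites.

    Reports slope, intercept, R², adjusted R² (1 − (1−R²)(n−1)/(n−2)), and
    the two-sided slope p-value from the t distribution on n−2 df.
    """
    sites = sorted(set(site_tici) & set(reference))
    sites = [s for s in sites if not np.isnan(site_tici[s])]
    if len(sites) < 3:
        raise ValidationError(f"regression needs >= 3 sites, got {len(sites)}")
    x = np.array([site_tici[s] for s in sites])
    y = np.array([reference[s] for s in sites])
    if np.ptp(x) == 0:
        raise ValidationError("zero-variance predictor (all site TICI equal)")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    per_site = pd.DataFrame({"site_id": sites, "tici": x, "reference": y})
    return ValidationReport(
        n_sites=len(sites),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]),
        mean_cv=mean_cv,
        per_site=per_site,
    )


def mean_replicate_cv(report: TICIReport) -> float:
    """Unweighted mean of per-site CV over sites with >= 2 scored replicates."""
    cv = report.per_site["cv"].to_numpy(float)
    cv = cv[~np.isnan(cv)]
    if cv.size == 0:
        raise ValidationError("no site has >= 2 scored replicates")
    return float(cv.mean())


def compare_models(a: IndicatorModel, b: IndicatorModel,
                   ) -> tuple[float, bool]:
    """Pairwise agreement of two models trained on the same indicator set.

    Returns the OLS R² between the two indicator-value vectors and whether
    they are exactly identical.
    """
    if set(a.asv_ids) != set(b.asv_ids):
        raise ValidationError("models cover different ASV sets")
    va = a.values_series()
    vb = b.values_series().reindex(va.index)
    delta = float(np.abs(va.to_numpy() - vb.to_numpy()).max())
    if delta == 0.0:
        return 1.0, True
    if va.std() == 0 or vb.std() == 0:
        return 0.0, False
    fit = sm.OLS(vb.to_numpy(), sm.add_constant(va.to_numpy())).fit()
    return float(fit.rsquared), False


def optimize_indicator_count(table: ASVTable, design: SiteDesign,
                             reference: Mapping[str, float],
                             grid: Sequence[int], seed: int,
                             min_count: int = 5,
                             max_iter: int = 100) -> tuple[pd.DataFrame, int]:
    """Sweep the indicator-set size and measure accuracy and precision.

    For each n in ``grid``: select the top-n most commonly encountered ASVs,
    train from the same seeded random initial ranking, orient against the
    reference, score the survey, and record accuracy (R² of reference vs
    site-averaged TICI) and precision (mean replicate CV). Returns the table
    and the n with the best accuracy (precision reported alongside for the
    operator's trade-off).
    """
    if any(n < 10 for n in grid):
        raise ValueError("grid values must be >= 10")
    if len([s for s in reference]) < 3:
        raise ValidationError("reference must cover >= 3 sites")
    pm = presence_matrix(table, min_count=min_count)
    rows = []
    for n in grid:
        indicators = select_indicators(pm, design, n)
        init = random_init(sorted(design.site_ids), seed)
        model, trace = chessman_train(pm, design, indicators, init,
                                      max_iter=max_iter)
        model = orient_model(model, trace.final_site_scores, reference)
        report = score_survey(table, design, model, min_count=min_count)
        site_tici = dict(zip(report.per_site["site_id"],
                             report.per_site["tici_mean"]))
        val = regress_vs_reference(site_tici, reference)
        rows.append({"n": n, "accuracy_r2": val.r_squared,
                     "precision_mean_cv": mean_replicate_cv(report)})
        logger.info("n=%d: accuracy R2=%.4f, mean CV=%.4f",
                    n, rows[-1]["accuracy_r2"], rows[-1]["precision_mean_cv"])
    result = pd.DataFrame(rows, columns=["n", "accuracy_r2",
                                         "precision_mean_cv"])
    best_n = int(result.loc[result["accuracy_r2"].idxmax(), "n"])
    return result, best_n


def precision_by_coverage(report: TICIReport, threshold: int = 100,
                          ) -> tuple[float, float, pd.DataFrame]:
    """Replicate precision stratified by indicator-ASV coverage.

    Each sample's deviation is |sample TICI − its site's mean TICI|.
    Returns the overall fractions of samples within 4 and within 3 TICI
    units of the site mean, and a table stratified by whether the sample
    detected at least ``threshold`` indicator ASVs.
    """
    sample = report.per_sample
    site_mean = dict(zip(report.per_site["site_id"],
                         report.per_site["tici_mean"]))
    rows = sample[sample["site_id"].isin(site_mean)
                  & ~sample["tici"].isna()].copy()
    if rows.empty:
        raise ValidationError("no scored replicate samples in report")
    dev = np.abs(rows["tici"].to_numpy(float)
                 - rows["site_id"].map(site_mean).to_numpy(float))
    high = rows["n_indicator_asvs"].to_numpy(int) >= threshold
    frac4 = float((dev <= 4).mean())
    frac3 = float((dev <= 3).mean())
    groups = []
    for label, mask in (("high_coverage", high), ("low_coverage", ~high)):
        if mask.any():
            groups.append({"group": label, "n_samples": int(mask.sum()),
                           "frac_within_4": float((dev[mask] <= 4).mean()),
                           "frac_within_3": float((dev[mask] <= 3).mean())})
        else:
            groups.append({"group": label, "n_samples": 0,
                           "frac_within_4": float("nan"),
                           "frac_within_3": float("nan")})
    return frac4, frac3, pd.DataFrame(groups)
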