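"""Unsupervised training of per-ASV indicator values (the Chessman process).

The algorithm alternates between two half-steps until it reaches a fixed
point:

1. Given a site condition ranking, assign each ASV an indicator value
   ``5 * (rho + 1)`` where ``rho`` is the tie-aware Spearman correlation
   between the site ranking and the ASV's site-prevalence ranking.
2. Given indicator values, score every sample (mean indicator value of the
   ASVs detected in it), average samples into site scores, and re-rank the
   sites by ascending score.

Starting from a random site ranking, the loop extracts the dominant
monotone gradient in the detection data without any a priori condition
information. The sign of that gradient is unidentifiable — the converged
model may be positively or negatively associated with true condition, with
equal probability — so a trained model is oriented afterwards against an
external reference index (:func:`orient_model`).

Iterated rank maps are not guaranteed to contract, so besides the exact
fixed point the loop also terminates on a recurring site-ranking
(a cycle) or on ``max_iter``, and records which of the three happened.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import PresenceMatrix, prevalence
from .exceptions import ValidationError
from .io import (
    IndicatorEntry,
    IndicatorModel,
    SiteDesign,
    TrainingMeta,
)

logger = logging.getLogger("tici.training")

INIT_RANDOM = "random_init"
INIT_GUIDED = "guided_init"
INIT_TICI_UPDATE = "tici_update"


@dataclass
class SiteRanking:
    """A (possibly tied, average-rank) condition ranking over sites.

    Rank 1 is the lowest condition. ``basis`` records whether the ranking
    came from a random permutation, an external reference score, or a
    TICI update inside the training loop.
    """

    sites: list[str]
    ranks: np.ndarray
    basis: str = INIT_RANDOM
    seed: int | None = None

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if len(self.sites) != self.ranks.size:
            raise ValidationError("ranking length mismatch")
        n = self.ranks.size
        if n and not np.isclose(self.ranks.sum(), n * (n + 1) / 2):
            raise ValidationError("ranks are not a valid average-rank ranking")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sites, self.ranks.tolist()))

    def aligned_to(self, sites: Sequence[str]) -> np.ndarray:
        d = self.as_dict()
        missing = [s for s in sites if s not in d]
        if missing or len(sites) != len(self.sites):
            raise ValidationError("ranking does not cover exactly the training sites")
        return np.array([d[s] for s in sites], dtype=float)


@dataclass
class TrainingTrace:
    """Per-iteration diagnostics of a training run."""

    iterations: list[tuple[int, str, float]] = field(default_factory=list)
    converged_by: str = "max_iter"
    final_site_scores: dict[str, float] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.iterations,
                            columns=["iteration", "site_ranking_fingerprint",
                                     "max_abs_indicator_change"])


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman rank correlation.

    Computed as the Pearson correlation of average-rank-transformed vectors.
    If either vector has zero variance the correlation is undefined; this
    returns 0 (the neutral value) in that case, so a uniformly prevalent ASV
    receives the neutral indicator value 5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    sx = np.sqrt((dx ** 2).sum())
    sy = np.sqrt((dy ** 2).sum())
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.clip((dx @ dy) / (sx * sy), -1.0, 1.0))


def indicator_from_rho(rho: float) -> float:
    """Map a correlation on [-1, 1] to the 0–10 indicator scale: (rho + 1) * 5."""
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho {rho} outside [-1, 1]")
    return (rho + 1.0) * 5.0


def sample_raw_score(sample_presence: np.ndarray, values: np.ndarray) -> float:
    """Mean indicator value of the indicator ASVs present in one sample.

    Returns NaN — the undefined-score signal, distinct from a numeric 0 —
    when no indicator ASV is present.
    """
    sample_presence = np.asarray(sample_presence, dtype=bool)
    values = np.asarray(values, dtype=float)
    if sample_presence.shape != values.shape:
        raise ValueError("presence/values length mismatch")
    if not sample_presence.any():
        return float("nan")
    return float(values[sample_presence].mean())


def random_init(site_ids: Sequence[str], seed: int) -> SiteRanking:
    """Uniform random permutation ranking (a naive initial condition ranking)."""
    site_ids = list(site_ids)
    if len(site_ids) < 2:
        raise ValidationError("need at least 2 sites to rank")
    rng = np.random.default_rng(seed)
    ranks = rng.permutation(len(site_ids)) + 1
    return SiteRanking(sites=site_ids, ranks=ranks.astype(float),
                       basis=INIT_RANDOM, seed=seed)


def guided_init(site_ids: Sequence[str],
                reference_scores: Mapping[str, float]) -> SiteRanking:
    """Ranking from a priori condition scores (ascending; ties → average ranks)."""
    site_ids = list(site_ids)
    missing = [s for s in site_ids if s not in reference_scores]
    if missing:
        raise ValidationError(
            f"reference score missing for site(s): {', '.join(missing[:5])}")
    scores = np.array([reference_scores[s] for s in site_ids], dtype=float)
    return SiteRanking(sites=site_ids, ranks=rankdata(scores), basis=INIT_GUIDED)


# ---------------------------------------------------------------------------
# The iterative loop
# ---------------------------------------------------------------------------

def _rho_against_columns(site_ranks: np.ndarray, col_ranks: np.ndarray) -> np.ndarray:
    """Spearman of one site ranking against every pre-ranked matrix column.

    Zero-variance columns (and a zero-variance site ranking) get rho = 0.
    """
    dx = site_ranks - site_ranks.mean()
    sx = np.sqrt((dx ** 2).sum())
    dY = col_ranks - col_ranks.mean(axis=0)
    sy = np.sqrt((dY ** 2).sum(axis=0))
    rho = np.zeros(col_ranks.shape[1])
    ok = (sx > 0) & (sy > 0)
    if sx > 0:
        rho[ok] = (dx @ dY[:, ok]) / (sx * sy[ok])
    return np.clip(rho, -1.0, 1.0)


def _fingerprint(ranks: np.ndarray) -> str:
    return hashlib.md5(np.round(ranks, 9).tobytes()).hexdigest()[:12]


def chessman_train(presence: PresenceMatrix, design: SiteDesign,
                   indicator_asvs: Sequence[str], init: SiteRanking,
                   max_iter: int = 100, tol: float = 0.0,
                   ) -> tuple[IndicatorModel, TrainingTrace]:
    """Run the iterative indicator-value assignment until convergence.

    Each iteration: rank sites by per-ASV prevalence, correlate against the
    current site condition ranking, convert to 0–10 indicator values, score
    samples and sites, and re-rank sites by ascending site score (ties →
    average ranks). Terminates when indicator values stop changing
    (``fixed_point``, max absolute change ≤ ``tol``), when a previously seen
    site ranking recurs (``cycle``), or at ``max_iter``.

    ``training_meta.iterations`` counts the iterations that changed the
    indicator values; the final evaluation that merely confirms a fixed
    point is not counted, so a constant prevalence matrix converges with
    ``iterations == 1`` and every value exactly 5.

    Prevalence is ranked as the raw replicate count when all sites have the
    same number of replicates, and as the fraction of replicates otherwise.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    sub = presence.subset_asvs(list(indicator_asvs))
    prev = prevalence(sub, design)
    if len(prev.sites) < 3:
        raise ValidationError("training needs at least 3 sites")
    by_site = design.samples_by_site()
    in_presence = set(presence.samples)
    for site in prev.sites:
        if not any(s in in_presence for s in by_site[site]):
            raise ValidationError(f"site {site!r} has no samples in the data")

    reps = set(prev.replicates_per_site.values())
    prev_mat = prev.prevalence.astype(float) if len(reps) == 1 else prev.fractions()
    col_ranks = rankdata(prev_mat, axis=0)   # fixed across iterations

    # Field-sample presence over the indicator set, grouped by site.
    field_samples = [s for s in sub.samples
                     if design.samples[s][1] == "field_sample"]
    P = sub.present[[sub._sample_index[s] for s in field_samples]]
    n_present = P.sum(axis=1)
    site_index = {site: i for i, site in enumerate(prev.sites)}
    sample_site = np.array([site_index[design.site_of(s)] for s in field_samples])

    site_ranks = init.aligned_to(prev.sites)
    trace = TrainingTrace()
    seen = {_fingerprint(site_ranks)}
    values: np.ndarray | None = None
    site_scores = np.full(len(prev.sites), np.nan)
    converged_by = "max_iter"
    iterations = max_iter

    for it in range(1, max_iter + 1):
        rho = _rho_against_columns(site_ranks, col_ranks)
        new_values = (rho + 1.0) * 5.0
        change = float("inf") if values is None else float(
            np.abs(new_values - values).max())
        fp = _fingerprint(site_ranks)
        trace.iterations.append((it, fp, change))
        logger.info("iteration %d: ranking %s, max indicator change %s",
                    it, fp, "n/a" if values is None else f"{change:.6g}")
        values = new_values
        if change <= tol:
            converged_by = "fixed_point"
            iterations = it - 1
            break

        # Steps 2–4: sample scores -> site scores -> new ascending ranking.
        with np.errstate(invalid="ignore"):
            sample_scores = np.where(n_present > 0, (P @ values) / n_present,
                                     np.nan)
        sums = np.zeros(len(prev.sites))
        counts = np.zeros(len(prev.sites))
        defined = ~np.isnan(sample_scores)
        np.add.at(sums, sample_site[defined], sample_scores[defined])
        np.add.at(counts, sample_site[defined], 1)
        if (counts == 0).any():
            bad = prev.sites[int(np.flatnonzero(counts == 0)[0])]
            raise ValidationError(f"site {bad!r} has no scorable samples")
        site_scores = sums / counts
        new_ranks = rankdata(site_scores)
        fpn = _fingerprint(new_ranks)
        if fpn in seen and fpn != fp:
            converged_by = "cycle"
            iterations = it
            site_ranks = new_ranks
            break
        seen.add(fpn)
        site_ranks = new_ranks

    trace.converged_by = converged_by
    trace.final_site_scores = dict(zip(prev.sites, site_scores.tolist()))

    field_rows = [sub._sample_index[s] for s in field_samples]
    sel_prev = sub.present[field_rows].sum(axis=0)
    assays = _assay_lookup(sub)
    entries = {
        asv: IndicatorEntry(indicator_value=float(values[j]),
                            assay=assays.get(asv, ""),
                            selection_prevalence=int(sel_prev[j]))
        for j, asv in enumerate(sub.asvs)
    }
    init_mode = {INIT_RANDOM: "random", INIT_GUIDED: "guided"}.get(
        init.basis, init.basis)
    meta = TrainingMeta(seed=init.seed, init_mode=init_mode,
                        iterations=iterations, converged_by=converged_by)
    return IndicatorModel(entries=entries, training_meta=meta), trace


def _assay_lookup(presence: PresenceMatrix) -> dict[str, str]:
    # PresenceMatrix does not carry assay labels; callers that want them in
    # the model attach them afterwards (the CLI does). Kept as a hook.
    return {}


def attach_assays(model: IndicatorModel, assay_of: Mapping[str, str]) -> IndicatorModel:
    """Return a copy of the model with assay labels filled in from a mapping."""
    entries = {a: IndicatorEntry(e.indicator_value, assay_of.get(a, e.assay),
                                 e.selection_prevalence)
               for a, e in model.entries.items()}
    return IndicatorModel(entries=entries, orientation=model.orientation,
                          training_meta=model.training_meta)


def orient_model(model: IndicatorModel, site_scores: Mapping[str, float],
                 reference_scores: Mapping[str, float]) -> IndicatorModel:
    """Resolve the sign ambiguity of a trained model against a reference index.

    If the Spearman correlation between model-derived site scores and the
    reference is negative over the (≥ 3) overlapping sites, every indicator
    value is mirrored (v ↦ 10 − v) and the orientation flag flipped;
    otherwise the model is returned unchanged. Idempotent for any model with
    a nonzero correlation.
    """
    overlap = sorted(set(site_scores) & set(reference_scores))
    if len(overlap) < 3:
        raise ValidationError(
            f"orientation needs >= 3 overlapping sites, got {len(overlap)}")
    rho = spearman_rho([site_scores[s] for s in overlap],
                       [reference_scores[s] for s in overlap])
    if rho < 0:
        return model.inverted()
    return model
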