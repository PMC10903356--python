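"""Presence/absence, per-site replicate prevalence, and indicator-set selection.

The index works entirely on detection (presence/absence at a read-count
threshold), not abundance: an ASV's signal at a site is the number of that
site's replicate samples in which it was detected (0–16 in a 16-replicate
design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ASVTable, SiteDesign

#: Detection threshold: minimum read count for an ASV to count as present
#: in a sample.
DEFAULT_MIN_COUNT = 5

#: Default size of the indicator ASV set.
DEFAULT_N_INDICATORS = 3000


@dataclass
class PresenceMatrix:
    """Boolean sample × ASV detection matrix, with the underlying counts.

    Derived deterministically from an :class:`~tici.io.ASVTable` and a
    detection threshold; ``counts`` is kept so that selection tie-breaks can
    use total read depth.
    """

    samples: list[str]
    asvs: list[str]
    present: np.ndarray   # bool, (n_samples, n_asvs)
    counts: np.ndarray    # int64, (n_samples, n_asvs)
    min_count: int = DEFAULT_MIN_COUNT

    def __post_init__(self) -> None:
        if self.present.shape != (len(self.samples), len(self.asvs)):
            raise ValidationError("presence matrix dimensions inconsistent")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._asv_index = {a: j for j, a in enumerate(self.asvs)}

    def sample_row(self, sample_id: str) -> np.ndarray:
        return self.present[self._sample_index[sample_id]]

    def subset_asvs(self, asv_ids: list[str]) -> "PresenceMatrix":
        """Restrict to the given ASVs, in the given order."""
        idx = [self._asv_index[a] for a in asv_ids]
        return PresenceMatrix(samples=self.samples, asvs=list(asv_ids),
                              present=self.present[:, idx],
                              counts=self.counts[:, idx],
                              min_count=self.min_count)


@dataclass
class PrevalenceMatrix:
    """Integer site × ASV matrix of replicate detection counts.

    ``prevalence[i, j]`` is the number of site i's field replicates in which
    ASV j was detected, bounded by ``replicates_per_site[site]``.
    """

    sites: list[str]
    asvs: list[str]
    prevalence: np.ndarray  # int64, (n_sites, n_asvs)
    replicates_per_site: dict[str, int]

    def __post_init__(self) -> None:
        if self.prevalence.shape != (len(self.sites), len(self.asvs)):
            raise ValidationError("prevalence matrix dimensions inconsistent")
        reps = np.array([self.replicates_per_site[s] for s in self.sites])
        if (self.prevalence < 0).any() or (self.prevalence > reps[:, None]).any():
            raise ValidationError("prevalence outside [0, replicates_per_site]")

    def fractions(self) -> np.ndarray:
        """Prevalence as the fraction of replicates, for unequal designs."""
        reps = np.array([self.replicates_per_site[s] for s in self.sites],
                        dtype=float)
        return self.prevalence / reps[:, None]


def presence_matrix(table: ASVTable, min_count: int = DEFAULT_MIN_COUNT) -> PresenceMatrix:
    """Threshold read counts into a boolean detection matrix.

    A sample/ASV pair is *present* iff its aggregated read count is at least
    ``min_count`` (default 5, the detection threshold also applied upstream
    during ASV calling).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    samples = table.sample_ids
    asvs = table.asv_ids
    counts = np.zeros((len(samples), len(asvs)), dtype=np.int64)
    if table.n_records:
        si = pd.Categorical(table.records["sample_id"], categories=samples).codes
        ai = pd.Categorical(table.records["asv_id"], categories=asvs).codes
        counts[si, ai] = table.records["count"].to_numpy(np.int64)
    return PresenceMatrix(samples=samples, asvs=asvs,
                          present=counts >= min_count, counts=counts,
                          min_count=min_count)


def prevalence(presence: PresenceMatrix, design: SiteDesign) -> PrevalenceMatrix:
    """Count, per site and ASV, the replicates in which the ASV is present.

    Negative controls never contribute; every field sample in the presence
    matrix must be covered by the design.
    """
    known = set(design.samples)
    missing = [s for s in presence.samples if s not in known]
    if missing:
        raise ValidationError(
            f"sample(s) missing from site design: {', '.join(missing[:5])}"
        )
    by_site = design.samples_by_site()
    present_samples = set(presence.samples)
    sites = sorted(by_site)
    prev = np.zeros((len(sites), len(presence.asvs)), dtype=np.int64)
    reps: dict[str, int] = {}
    for i, site in enumerate(sites):
        members = [s for s in by_site[site] if s in present_samples]
        reps[site] = len(by_site[site])
        if members:
            rows = [presence._sample_index[s] for s in members]
            prev[i] = presence.present[rows].sum(axis=0)
    return PrevalenceMatrix(sites=sites, asvs=list(presence.asvs),
                            prevalence=prev, replicates_per_site=reps)


def select_indicators(presence: PresenceMatrix, design: SiteDesign,
                      n: int = DEFAULT_N_INDICATORS) -> list[str]:
    """Pick the ``n`` most commonly encountered ASVs as the indicator set.

    Commonness is the number of field samples in which the ASV passes the
    detection threshold (negative controls excluded). Ties at the selection
    boundary are broken by higher total read count, then lexicographic
    asv_id, so the selection is deterministic. If fewer than ``n`` ASVs
    exist, all are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    field = [s for s in presence.samples
             if design.samples.get(s, ("", ""))[1] == "field_sample"]
    rows = [presence._sample_index[s] for s in field]
    occupancy = presence.present[rows].sum(axis=0)
    reads = presence.counts[rows].sum(axis=0)
    order = sorted(range(len(presence.asvs)),
                   key=lambda j: (-occupancy[j], -reads[j], presence.asvs[j]))
    if len(order) < n:
        warnings.warn(
            f"only {len(order)} ASVs available; requested {n} indicators",
            stacklevel=2)
    return [presence.asvs[j] for j in order[:n]]
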