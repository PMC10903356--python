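"""Tabular interchange formats for eDNA survey data, indicator models and score reports.

All formats are UTF-8 TSV ('.' decimal separator, no thousands separators):

* **ASV table** — long format with columns ``sample_id, asv_id, assay, count``;
  a wide sample × ASV CSV is accepted as a convenience dialect.
* **Site design** — columns ``sample_id, site_id, role`` plus optional
  site-level ``reference_score`` and ``substrate`` columns.
* **Indicator model** — ``#``-prefixed metadata preamble followed by a body
  with columns ``asv_id, assay, indicator_value, selection_prevalence``.
* **Score report** — a per-sample block and a per-site block separated by a
  blank line.

ASV identifiers are opaque strings (a sequence or a sequence hash are both
fine); nothing in the package interprets DNA content.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: Reserved pseudo-site that all negative-control samples are mapped to, so
#: that controls can never enter a field site's replicate set.
NEGATIVE_CONTROL_SITE = "__negative_control__"

ROLE_FIELD_SAMPLE = "field_sample"
ROLE_NEGATIVE_CONTROL = "negative_control"
VALID_ROLES = frozenset({ROLE_FIELD_SAMPLE, ROLE_NEGATIVE_CONTROL})

VALID_SUBSTRATES = frozenset({"hard", "soft"})

ASV_TABLE_COLUMNS = ["sample_id", "asv_id", "assay", "count"]


# ---------------------------------------------------------------------------
# ASV count tables
# ---------------------------------------------------------------------------

@dataclass
class ASVTable:
    """Long-form read counts per (sample, ASV, assay).

    ``records`` holds one row per (sample_id, asv_id) pair after aggregation,
    with non-negative integer ``count``. ``asv_metadata`` optionally maps
    asv_id to (sequence, assay).
    """

    records: pd.DataFrame
    asv_metadata: dict[str, tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in ASV_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"ASV table missing column(s): {', '.join(missing)}")
        self.records = df[ASV_TABLE_COLUMNS].reset_index(drop=True)
        if len(df) and (df["asv_id"].astype(str).str.len() == 0).any():
            raise ValidationError("empty asv_id in ASV table")
        if len(df) and int((df["count"] < 0).sum()):
            raise ValidationError("negative count in ASV table")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    @property
    def asv_ids(self) -> list[str]:
        return sorted(self.records["asv_id"].unique())

    @classmethod
    def from_records(cls, df: pd.DataFrame,
                     asv_metadata: dict[str, tuple[str, str]] | None = None) -> "ASVTable":
        """Validate, coerce and duplicate-aggregate a raw long-format frame."""
        missing = [c for c in ASV_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"ASV table missing column(s): {', '.join(missing)}")
        df = df.loc[:, ASV_TABLE_COLUMNS].copy()
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = counts.isna() | (counts != np.floor(counts)) | (counts < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row + 1}: count {df['count'].iloc[row]!r} is not a "
                "non-negative integer"
            )
        df["count"] = counts.astype(np.int64)
        for col in ("sample_id", "asv_id", "assay"):
            df[col] = df[col].astype(str)
        # Sum duplicate (sample, asv) rows; keep the first assay label seen.
        df = (df.groupby(["sample_id", "asv_id"], sort=True, as_index=False)
                .agg(assay=("assay", "first"), count=("count", "sum")))
        return cls(records=df[ASV_TABLE_COLUMNS], asv_metadata=asv_metadata)


def read_asv_table(path: str | Path, dialect: str = "long_tsv") -> ASVTable:
    """Read an ASV count table.

    ``long_tsv`` expects columns sample_id, asv_id, assay, count; duplicate
    (sample, asv) rows are summed. ``wide_csv`` expects a sample_id column
    followed by one column per ASV; assay labels are then unknown and left
    empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long_tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise FormatError(f"{path}: empty file, expected a header row") from None
        return ASVTable.from_records(df)
    if dialect == "wide_csv":
        wide = pd.read_csv(path, sep=",")
        if "sample_id" not in wide.columns:
            raise FormatError("ASV table missing column(s): sample_id")
        long = wide.melt(id_vars="sample_id", var_name="asv_id", value_name="count")
        long = long[pd.to_numeric(long["count"], errors="coerce").fillna(0) > 0]
        long["assay"] = ""
        return ASVTable.from_records(long)
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_asv_table(table: ASVTable, path: str | Path) -> None:
    """Write an ASV table in the long TSV dialect."""
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteInfo:
    reference_score: float | None = None
    substrate: str | None = None


@dataclass
class SiteDesign:
    """Sample → site grouping with replicate roles.

    ``samples`` maps sample_id to (site_id, role); negative controls are
    always attached to :data:`NEGATIVE_CONTROL_SITE`. ``sites`` carries
    optional per-site metadata (an external reference condition score such as
    a 5-year median MCI, and the substrate class).
    """

    samples: dict[str, tuple[str, str]]
    sites: dict[str, SiteInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample_id, (site_id, role) in self.samples.items():
            if role not in VALID_ROLES:
                raise ValidationError(f"sample {sample_id!r}: unknown role {role!r}")
            if role == ROLE_FIELD_SAMPLE and not site_id:
                raise ValidationError(f"field sample {sample_id!r} has no site")
        for site_id in self.site_ids:
            self.sites.setdefault(site_id, SiteInfo())

    @property
    def site_ids(self) -> list[str]:
        """Field-site identifiers (sorted; excludes the control pseudo-site)."""
        return sorted({s for s, r in self.samples.values() if r == ROLE_FIELD_SAMPLE})

    def field_samples(self) -> list[str]:
        return sorted(s for s, (_, r) in self.samples.items() if r == ROLE_FIELD_SAMPLE)

    def negative_controls(self) -> list[str]:
        return sorted(s for s, (_, r) in self.samples.items()
                      if r == ROLE_NEGATIVE_CONTROL)

    def samples_by_site(self) -> dict[str, list[str]]:
        """Field samples grouped by site, each list sorted."""
        out: dict[str, list[str]] = {site: [] for site in self.site_ids}
        for sample_id, (site_id, role) in sorted(self.samples.items()):
            if role == ROLE_FIELD_SAMPLE:
                out[site_id].append(sample_id)
        return out

    def site_of(self, sample_id: str) -> str:
        return self.samples[sample_id][0]

    def reference_scores(self) -> dict[str, float]:
        """Per-site reference scores, omitting sites without one."""
        return {site: info.reference_score for site, info in self.sites.items()
                if info.reference_score is not None
                and site != NEGATIVE_CONTROL_SITE}


def read_site_design(path: str | Path) -> SiteDesign:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "site_id", "role"):
        if col not in df.columns:
            raise FormatError(f"site design missing column(s): {col}")
    samples: dict[str, tuple[str, str]] = {}
    site_info: dict[str, dict] = {}
    for _, row in df.iterrows():
        sample_id = str(row["sample_id"])
        role = str(row["role"])
        if role not in VALID_ROLES:
            raise ValidationError(f"sample {sample_id!r}: unknown role {role!r}")
        site_id = (NEGATIVE_CONTROL_SITE if role == ROLE_NEGATIVE_CONTROL
                   else str(row["site_id"]))
        if sample_id in samples and samples[sample_id] != (site_id, role):
            raise ValidationError(
                f"sample {sample_id!r} listed twice with conflicting assignments"
            )
        samples[sample_id] = (site_id, role)
        if role == ROLE_FIELD_SAMPLE:
            info = site_info.setdefault(site_id, {})
            ref = str(row.get("reference_score", "")).strip()
            if ref:
                info["reference_score"] = float(ref)
            sub = str(row.get("substrate", "")).strip()
            if sub:
                if sub not in VALID_SUBSTRATES:
                    raise ValidationError(f"site {site_id!r}: unknown substrate {sub!r}")
                info["substrate"] = sub
    sites = {site: SiteInfo(**info) for site, info in site_info.items()}
    return SiteDesign(samples=samples, sites=sites)


def write_site_design(design: SiteDesign, path: str | Path) -> None:
    rows = []
    for sample_id in sorted(design.samples):
        site_id, role = design.samples[sample_id]
        info = design.sites.get(site_id, SiteInfo())
        rows.append({
            "sample_id": sample_id,
            "site_id": "" if site_id == NEGATIVE_CONTROL_SITE else site_id,
            "role": role,
            "reference_score": ("" if info.reference_score is None
                                else repr(float(info.reference_score))),
            "substrate": info.substrate or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Indicator models
# ---------------------------------------------------------------------------

ORIENTATION_AS_TRAINED = "as_trained"
ORIENTATION_INVERTED = "inverted"


@dataclass(frozen=True)
class TrainingMeta:
    """Provenance of a training run."""

    seed: int | None = None
    init_mode: str = "random"          # random | guided
    iterations: int = 0
    converged_by: str = "fixed_point"  # fixed_point | cycle | max_iter


@dataclass(frozen=True)
class IndicatorEntry:
    indicator_value: float
    assay: str = ""
    selection_prevalence: int = 0


@dataclass
class IndicatorModel:
    """Per-ASV ecological-health indicator values on the 0–10 scale.

    An ASV's indicator value encodes how its site prevalence tracks the
    learned condition gradient: 10 for a perfect positive rank correlation,
    0 for a perfect inverse one, 5 for no association.
    """

    entries: dict[str, IndicatorEntry]
    orientation: str = ORIENTATION_AS_TRAINED
    training_meta: TrainingMeta = field(default_factory=TrainingMeta)

    def __post_init__(self) -> None:
        for asv_id, entry in self.entries.items():
            v = entry.indicator_value
            if not (0.0 <= v <= 10.0) or math.isnan(v):
                raise ValidationError(
                    f"indicator value {v} for {asv_id!r} outside [0, 10]"
                )
        if self.orientation not in (ORIENTATION_AS_TRAINED, ORIENTATION_INVERTED):
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def n_indicators(self) -> int:
        return len(self.entries)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.entries)

    def values_series(self) -> pd.Series:
        """Indicator values indexed by asv_id, in entry order."""
        return pd.Series({a: e.indicator_value for a, e in self.entries.items()},
                         name="indicator_value", dtype=float)

    def inverted(self) -> "IndicatorModel":
        """Mirror every indicator value (v ↦ 10 − v) and flip the orientation flag."""
        flipped = {a: IndicatorEntry(10.0 - e.indicator_value, e.assay,
                                     e.selection_prevalence)
                   for a, e in self.entries.items()}
        new_orientation = (ORIENTATION_INVERTED
                           if self.orientation == ORIENTATION_AS_TRAINED
                           else ORIENTATION_AS_TRAINED)
        return IndicatorModel(entries=flipped, orientation=new_orientation,
                              training_meta=self.training_meta)


def write_indicator_model(model: IndicatorModel, path: str | Path) -> None:
    """Serialise a model as TSV with a ``#``-prefixed metadata preamble."""
    meta = model.training_meta
    lines = [
        f"# n_indicators={model.n_indicators}",
        f"# seed={'none' if meta.seed is None else meta.seed}",
        f"# init_mode={meta.init_mode}",
        f"# iterations={meta.iterations}",
        f"# converged_by={meta.converged_by}",
        f"# orientation={model.orientation}",
        "asv_id\tassay\tindicator_value\tselection_prevalence",
    ]
    for asv_id, e in model.entries.items():
        lines.append(f"{asv_id}\t{e.assay}\t{e.indicator_value:.6f}\t"
                     f"{e.selection_prevalence}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_indicator_model(path: str | Path) -> IndicatorModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    required = {"n_indicators", "seed", "init_mode", "iterations",
                "converged_by", "orientation"}
    if not required.issubset(meta):
        raise FormatError(
            f"model file missing metadata: {', '.join(sorted(required - set(meta)))}"
        )
    if not body_lines:
        raise FormatError("model file has no body")
    header = body_lines[0].split("\t")
    expected = ["asv_id", "assay", "indicator_value", "selection_prevalence"]
    if header != expected:
        raise FormatError(f"model body header {header!r} != {expected!r}")
    entries: dict[str, IndicatorEntry] = {}
    for line in body_lines[1:]:
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"malformed model body row: {line!r}")
        asv_id, assay, value, prev = parts
        if asv_id in entries:
            raise FormatError(f"duplicate asv_id {asv_id!r} in model body")
        entries[asv_id] = IndicatorEntry(float(value), assay, int(prev))
    if len(entries) != int(meta["n_indicators"]):
        raise FormatError(
            f"model declares n_indicators={meta['n_indicators']} but body has "
            f"{len(entries)} rows"
        )
    seed = None if meta["seed"] == "none" else int(meta["seed"])
    return IndicatorModel(
        entries=entries,
        orientation=meta["orientation"],
        training_meta=TrainingMeta(seed=seed, init_mode=meta["init_mode"],
                                   iterations=int(meta["iterations"]),
                                   converged_by=meta["converged_by"]),
    )


# ---------------------------------------------------------------------------
# Score reports
# ---------------------------------------------------------------------------

SAMPLE_REPORT_COLUMNS = ["sample_id", "site_id", "tici", "n_indicator_asvs",
                         "low_coverage", "category"]
SITE_REPORT_COLUMNS = ["site_id", "tici_mean", "tici_sd", "cv", "category"]


@dataclass
class TICIReport:
    """Per-sample and per-site TICI scores with categories and QC flags.

    ``per_sample`` columns: sample_id, site_id, tici, n_indicator_asvs,
    low_coverage, category. ``per_site`` columns: site_id, tici_mean,
    tici_sd, cv, n_samples, category. Undefined quantities (a sample with no
    indicator ASVs, a single-replicate CV) are NaN with an empty category.
    """

    per_sample: pd.DataFrame
    per_site: pd.DataFrame

    def __post_init__(self) -> None:
        tici = self.per_sample["tici"].to_numpy(float)
        defined = tici[~np.isnan(tici)]
        if defined.size and (defined.min() < 0 or defined.max() > 200):
            raise ValidationError("sample TICI outside [0, 200]")


def write_report(report: TICIReport, path: str | Path) -> None:
    """Write the two report blocks (samples, then sites) to one TSV file."""
    sample = report.per_sample.copy()
    sample["tici"] = sample["tici"].map(
        lambda v: "" if pd.isna(v) else f"{v:.2f}")
    sample["low_coverage"] = sample["low_coverage"].map(
        lambda b: "true" if b else "false")
    site = report.per_site[SITE_REPORT_COLUMNS].copy()
    site["tici_mean"] = site["tici_mean"].map(
        lambda v: "" if pd.isna(v) else f"{v:.2f}")
    for col in ("tici_sd", "cv"):
        site[col] = site[col].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    with open(path, "w", encoding="utf-8") as fh:
        sample[SAMPLE_REPORT_COLUMNS].to_csv(fh, sep="\t", index=False)
        fh.write("\n")
        site.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> TICIReport:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    try:
        sample_block, site_block = text.split("\n\n", 1)
    except ValueError:
        raise FormatError("report file lacks the blank-line block separator") from None

    def _parse(block: str, numeric: list[str]) -> pd.DataFrame:
        lines = [ln for ln in block.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        rows = [ln.split("\t") for ln in lines[1:]]
        df = pd.DataFrame(rows, columns=header)
        for col in numeric:
            df[col] = pd.to_numeric(df[col].replace("", np.nan))
        return df

    sample = _parse(sample_block, ["tici"])
    if list(sample.columns) != SAMPLE_REPORT_COLUMNS:
        raise FormatError("unexpected sample-block columns in report")
    sample["n_indicator_asvs"] = sample["n_indicator_asvs"].astype(int)
    sample["low_coverage"] = sample["low_coverage"] == "true"
    site = _parse(site_block, ["tici_mean", "tici_sd", "cv"])
    if list(site.columns) != SITE_REPORT_COLUMNS:
        raise FormatError("unexpected site-block columns in report")
    n_samples = sample.groupby("site_id").size()
    site["n_samples"] = site["site_id"].map(n_samples).fillna(0).astype(int)
    site = site[["site_id", "tici_mean", "tici_sd", "cv", "n_samples", "category"]]
    return TICIReport(per_sample=sample, per_site=site)
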