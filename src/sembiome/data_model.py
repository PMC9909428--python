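"""Count/metadata table IO and cohort group assignment.

Samples are partitioned, per sex, into four mutually exclusive analysis
groups derived from self-reported questionnaire metadata:

* ``NC`` — normal controls: disease-free and passing a battery of thirteen
  health/lifestyle conditions (medication, BMI, depression scale, smoking,
  defecation and alcohol habits, and — for females — menstrual status).
* ``AS`` — atopic dermatitis only, with no other disease marker.
* ``AM`` — atopic dermatitis plus at least one other disease marker.
* ``OD`` — no atopic dermatitis but at least one other disease marker.

Anything else (medication use, pregnancy, the opposite sex, ...) is
``excluded``.  "Other disease marker" means: any reported non-atopic disease,
BMI < 18.5 or >= 25, a CES-D depression score >= 16, or a history of
colorectal cancer/polyp surgery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "MetadataTable",
    "GroupAssignment",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "assign_groups",
    "GROUP_LABELS",
]

GROUP_LABELS = ("NC", "AS", "AM", "OD")

#: Closed category sets for the questionnaire fields that the normal-control
#: criteria consult.  The first tuple entries are the NC-compatible levels.
DEFECATION_LEVELS = (
    "1-2_per_day",
    "4-6_per_week",
    "3_or_more_per_day",
    "1-3_per_week",
    "less_than_weekly",
)
NC_DEFECATION = frozenset(DEFECATION_LEVELS[:2])

ALCOHOL_LEVELS = ("none", "moderate_le5_per_week", "heavy_or_gt5_per_week")
NC_ALCOHOL = frozenset(ALCOHOL_LEVELS[:2])

MENSTRUAL_LEVELS = ("regular", "irregular", "menopause")
SEX_LEVELS = ("female", "male")

_BOOL_FIELDS = (
    "atopic_dermatitis",
    "other_disease",
    "medication",
    "hospitalization_or_surgery",
    "helicobacter_treatment",
    "insomnia_consultation",
    "smoking_history",
    "menstruating_now",
    "pregnant_or_breastfeeding",
    "colorectal_surgery_history",
)
_CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS,
    "defecation_frequency": DEFECATION_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "menstrual_status": MENSTRUAL_LEVELS,
}
#: Fields that may be missing per-sample (female-only fields for males,
#: unanswered numeric items).
_NULLABLE = {
    "bmi",
    "cesd",
    "age",
    "menstrual_status",
    "menstruating_now",
    "pregnant_or_breastfeeding",
}

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "sex",
    "atopic_dermatitis",
    "other_disease",
    "medication",
    "bmi",
    "cesd",
    "age",
    "hospitalization_or_surgery",
    "helicobacter_treatment",
    "insomnia_consultation",
    "defecation_frequency",
    "alcohol",
    "smoking_history",
    "menstrual_status",
    "menstruating_now",
    "pregnant_or_breastfeeding",
    "colorectal_surgery_history",
)


class MetadataError(ValueError):
    """Raised for malformed metadata tables or unknown categorical levels."""


class MissingFieldError(ValueError):
    """A group criterion could not be evaluated because a value is missing."""


@dataclass
class CountTable:
    """Genus x sample table of non-negative integer read counts."""

    genera: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_genera, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genera), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genera)} genera x {len(self.samples)} samples"
            )
        if len(set(self.genera)) != len(self.genera):
            raise ValueError("duplicate genus labels")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(self.genera) < 2 or len(self.samples) < 2:
            raise ValueError("need at least 2 genera and 2 samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at {self.genera[g]}, {self.samples[s]}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genera, columns=self.samples)

    def subset_samples(self, sample_ids: list[str]) -> "CountTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountTable(list(self.genera), list(sample_ids), self.counts[:, idx])


@dataclass
class MetadataTable:
    """Per-sample questionnaire metadata with a validated schema."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns and c != "sample_id"]
        if missing:
            raise MetadataError(f"missing required metadata columns: {missing}")
        if df.index.has_duplicates:
            raise MetadataError("duplicate sample ids in metadata")
        for col, levels in _CATEGORICAL_LEVELS.items():
            vals = df[col].dropna().unique()
            bad = [v for v in vals if v not in levels]
            if bad:
                raise MetadataError(f"unknown level {bad[0]!r} in column {col!r}")
        for col in _BOOL_FIELDS:
            vals = df[col].dropna().unique()
            bad = [v for v in vals if not isinstance(v, (bool, np.bool_))]
            if bad:
                raise MetadataError(f"non-boolean value {bad[0]!r} in column {col!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def row(self, sample_id: str) -> pd.Series:
        return self.table.loc[sample_id]


@dataclass
class GroupAssignment:
    """Mapping sample id -> group label plus failed-criterion diagnostics."""

    labels: dict[str, str]
    failed: dict[str, list[str]] = field(default_factory=dict)

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.labels), "group": list(self.labels.values())}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_count_table(path) -> CountTable:
    """Read a tab-separated genus x sample count table.

    First row holds sample ids, first column genus labels.  Duplicate genus
    rows are summed element-wise; duplicate sample ids are an error; any
    non-integer or negative cell raises naming the offending genus and sample.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for sid in header:
        if sid in seen:
            raise ValueError(f"duplicate sample id {sid!r} in {path}")
        seen.add(sid)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = header
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                v = int(raw)
                if v < 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"invalid count {raw!r} at {df.index[i]}, {col} in {path}"
                ) from None
            values[i, j] = v
    frame = pd.DataFrame(values, index=df.index, columns=df.columns)
    if frame.index.has_duplicates:
        frame = frame.groupby(level=0, sort=False).sum()
    return CountTable(list(frame.index), list(frame.columns), frame.to_numpy())


def write_count_table(table: CountTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def read_metadata(path) -> MetadataTable:
    """Read the comma-separated questionnaire metadata table.

    Boolean fields accept yes/no, true/false or 1/0 (case-insensitive); empty
    cells become missing values, never zeros.
    """
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise MetadataError("missing required metadata columns: ['sample_id']")
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"missing required metadata columns: {missing}")
    df = df.set_index("sample_id")

    def _to_bool(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return pd.NA
        s = str(v).strip().lower()
        if s in {"yes", "true", "1"}:
            return True
        if s in {"no", "false", "0"}:
            return False
        raise MetadataError(f"unknown boolean value {v!r}")

    for col in _BOOL_FIELDS:
        df[col] = df[col].map(_to_bool).astype("boolean")
    for col in ("bmi", "cesd", "age"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in _CATEGORICAL_LEVELS:
        df[col] = df[col].where(~df[col].isna(), other=pd.NA)
    return MetadataTable(df)


def write_metadata(meta: MetadataTable, path) -> None:
    out = meta.table.copy()
    for col in _BOOL_FIELDS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else ("yes" if v else "no"))
    out.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Group criteria
# ---------------------------------------------------------------------------

def _val(row: pd.Series, fld: str, criterion: str, sample: str):
    v = row[fld]
    if pd.isna(v):
        raise MissingFieldError(
            f"criterion {criterion} requires field {fld!r} for sample {sample!r}"
        )
    return v


def _other_disease_marker(row: pd.Series, criterion: str, sample: str) -> bool:
    """Any non-atopic disease marker: reported disease, out-of-range BMI,
    CES-D >= 16, or colorectal cancer/polyp surgery history.

    Missing items only raise when the determination cannot be short-circuited
    by a known positive marker.
    """
    unknown = False
    for fld in ("other_disease", "colorectal_surgery_history"):
        v = row[fld]
        if pd.isna(v):
            unknown = True
        elif v:
            return True
    bmi = row["bmi"]
    if pd.isna(bmi):
        unknown = True
    elif bmi < 18.5 or bmi >= 25:
        return True
    cesd = row["cesd"]
    if pd.isna(cesd):
        unknown = True
    elif cesd >= 16:
        return True
    if unknown:
        raise MissingFieldError(
            f"criterion {criterion} cannot be decided for sample {sample!r}: "
            "missing disease-marker fields"
        )
    return False


def _nc_failures(row: pd.Series, sample: str, female: bool) -> list[str]:
    failed: list[str] = []

    def check(name: str, ok: bool) -> None:
        if not ok:
            failed.append(name)

    check("NC1", not _val(row, "atopic_dermatitis", "NC1", sample)
          and not _val(row, "other_disease", "NC1", sample)
          and not _val(row, "colorectal_surgery_history", "NC1", sample))
    check("NC2", not _val(row, "medication", "NC2", sample))
    bmi = _val(row, "bmi", "NC3", sample)
    check("NC3", 18.5 <= bmi < 25)
    check("NC4", _val(row, "cesd", "NC4", sample) < 16)
    check("NC5", not _val(row, "hospitalization_or_surgery", "NC5", sample))
    check("NC6", not _val(row, "helicobacter_treatment", "NC6", sample))
    check("NC7", not _val(row, "insomnia_consultation", "NC7", sample))
    check("NC8", _val(row, "defecation_frequency", "NC8", sample) in NC_DEFECATION)
    check("NC9", _val(row, "alcohol", "NC9", sample) in NC_ALCOHOL)
    check("NC10", not _val(row, "smoking_history", "NC10", sample))
    if female:
        status = _val(row, "menstrual_status", "NC11", sample)
        if status == "regular":
            ok11 = True
        elif status == "menopause":
            ok11 = _val(row, "age", "NC11", sample) >= 40
        else:
            ok11 = False
        check("NC11", ok11)
        check("NC12", not _val(row, "menstruating_now", "NC12", sample))
        check("NC13", not _val(row, "pregnant_or_breastfeeding", "NC13", sample))
    return failed


def _patient_failures(
    row: pd.Series, sample: str, female: bool, prefix: str, want_atopic: bool,
    want_other: bool,
) -> list[str]:
    """Shared evaluator for the AS / AM / OD criterion quadruples."""
    failed: list[str] = []
    atopic = _val(row, "atopic_dermatitis", f"{prefix}1", sample)
    if bool(atopic) != want_atopic:
        failed.append(f"{prefix}1")
    other = _other_disease_marker(row, f"{prefix}2", sample)
    if other != want_other:
        failed.append(f"{prefix}2")
    if _val(row, "medication", f"{prefix}3", sample):
        failed.append(f"{prefix}3")
    if female and _val(row, "pregnant_or_breastfeeding", f"{prefix}4", sample):
        failed.append(f"{prefix}4")
    return failed


def assign_groups(meta: MetadataTable, sex: str) -> GroupAssignment:
    """Assign every sample to exactly one of NC/AS/AM/OD or ``excluded``.

    Criteria are evaluated in the order NC, AS, AM, OD; the first group whose
    criteria are all satisfied wins.  Samples of the other sex are excluded
    without evaluation.  A missing value that a consulted criterion needs
    raises :class:`MissingFieldError` naming the criterion.
    """
    if sex not in SEX_LEVELS:
        raise ValueError(f"sex must be one of {SEX_LEVELS}, got {sex!r}")
    female = sex == "female"
    labels: dict[str, str] = {}
    failed: dict[str, list[str]] = {}
    for sample in meta.samples:
        row = meta.row(sample)
        if row["sex"] != sex:
            labels[sample] = "excluded"
            failed[sample] = ["sex"]
            continue
        evaluations = [
            ("NC", _nc_failures(row, sample, female)),
            ("AS", _patient_failures(row, sample, female, "AS", True, False)),
            ("AM", _patient_failures(row, sample, female, "AM", True, True)),
            ("OD", _patient_failures(row, sample, female, "OD", False, True)),
        ]
        for label, fails in evaluations:
            if not fails:
                labels[sample] = label
                failed[sample] = []
                break
        else:
            labels[sample] = "excluded"
            failed[sample] = sorted({f for _, fl in evaluations for f in fl})
    return GroupAssignment(labels, failed)
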