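"""Measurement tables: subjects × ROI values for one modality.

A :class:`MeasurementTable` holds regional volumes (mm³) or regional FDG
uptake (SUV) for a cohort, together with per-subject group/sex metadata and a
whole-brain scalar (whole-brain volume, or whole-brain mean uptake, in the
same units as the regional values).  It is the substrate for all downstream
normalization and network analysis.

CSV layout: ``subject_id,group,sex,whole_brain,<region_1>,...,<region_k>``
with region columns in atlas order.  Missing values are rejected, never
imputed: across-subject correlation requires complete columns, and silent
pairwise deletion would change the effective n per edge.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .errors import SchemaError, ValidationError

MODALITIES = ("volume_mm3", "suv")
GROUPS = ("ich", "sham")
SEXES = ("male", "female")

_META_COLS = ["subject_id", "group", "sex", "whole_brain"]


@dataclass
class MeasurementTable:
    """Validated subjects × regions measurements for one modality."""

    modality: str
    subjects: pd.DataFrame  # columns: subject_id, group, sex
    values: pd.DataFrame  # index: subject_id; columns: regions (atlas order)
    whole_brain: pd.Series  # index: subject_id

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])

    def matrix(self) -> np.ndarray:
        """Values as a float (n_subjects, n_regions) array."""
        return self.values.to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Single flat DataFrame in the CSV column layout."""
        meta = self.subjects.copy()
        meta["whole_brain"] = self.whole_brain.to_numpy()
        vals = self.values.reset_index(drop=True)
        return pd.concat([meta.reset_index(drop=True), vals], axis=1)


def _validate(
    modality: str,
    subjects: pd.DataFrame,
    values: pd.DataFrame,
    whole_brain: pd.Series,
    atlas: RoiAtlas | None,
) -> MeasurementTable:
    if modality not in MODALITIES:
        raise ValidationError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    ids = subjects["subject_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValidationError(f"duplicate subject ids: {dupes}")
    bad_groups = sorted(set(subjects["group"]) - set(GROUPS))
    if bad_groups:
        raise ValidationError(f"unknown group label(s) {bad_groups}; expected one of {GROUPS}")
    bad_sex = sorted(set(subjects["sex"]) - set(SEXES))
    if bad_sex:
        raise ValidationError(f"unknown sex label(s) {bad_sex}; expected one of {SEXES}")

    if atlas is not None:
        missing = [n for n in atlas.names if n not in values.columns]
        if missing:
            raise SchemaError(f"missing region column(s): {missing}")
        extra = [c for c in values.columns if c not in atlas.names]
        if extra:
            raise SchemaError(f"unexpected region column(s): {extra}")
        values = values[atlas.names]  # canonicalize column order

    if values.isna().any().any():
        cells = [
            (str(ids.iloc[i]), values.columns[j])
            for i, j in zip(*np.where(values.isna().to_numpy()))
        ]
        raise ValidationError(f"missing value(s) at {cells[:5]}")
    neg = values.to_numpy(dtype=float) < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"negative value for subject {ids.iloc[i]!r}, region {values.columns[j]!r}: "
            f"{values.iloc[i, j]}"
        )
    wb = whole_brain.to_numpy(dtype=float)
    if np.isnan(wb).any() or (wb <= 0).any():
        bad = ids.iloc[int(np.argmax(~(wb > 0)))]
        raise ValidationError(f"whole_brain must be > 0 for every subject (subject {bad!r})")

    subjects = subjects.reset_index(drop=True)
    subjects["subject_id"] = ids.to_numpy()
    values = values.reset_index(drop=True)
    values.index = pd.Index(subjects["subject_id"], name="subject_id")
    whole_brain = pd.Series(wb, index=values.index, name="whole_brain")
    return MeasurementTable(modality, subjects, values, whole_brain)


def make_measurement_table(
    modality: str,
    subjects: pd.DataFrame,
    values: pd.DataFrame,
    whole_brain,
    atlas: RoiAtlas | None = None,
) -> MeasurementTable:
    """Build and validate a table from its components.

    ``subjects`` needs columns subject_id/group/sex; ``values`` one column per
    region; ``whole_brain`` anything coercible to a per-subject Series.
    """
    wb = pd.Series(np.asarray(whole_brain, dtype=float))
    return _validate(modality, subjects.copy(), values.copy(), wb, atlas)


def read_measurement_table(
    path: str | Path, atlas: RoiAtlas, modality: str
) -> MeasurementTable:
    """Read a measurement CSV and validate it against ``atlas``.

    Region columns are canonicalized to atlas order regardless of file order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_meta = [c for c in _META_COLS if c not in df.columns]
    if missing_meta:
        raise SchemaError(f"{path}: missing metadata column(s): {missing_meta}")
    missing_regions = [n for n in atlas.names if n not in df.columns]
    if missing_regions:
        raise SchemaError(f"{path}: missing region column(s): {missing_regions}")
    subjects = df[["subject_id", "group", "sex"]].copy()
    subjects["subject_id"] = subjects["subject_id"].astype(str)
    values = df[atlas.names].astype(float)
    return _validate(modality, subjects, values, df["whole_brain"].astype(float), atlas)


def write_measurement_table(table: MeasurementTable, path: str | Path) -> None:
    """Write to CSV with full float precision (round-trips exactly)."""
    table.to_frame().to_csv(path, index=False)


def split_by_group(table: MeasurementTable, group: str) -> MeasurementTable:
    """Subset to one group, preserving subject order."""
    mask = (table.subjects["group"] == group).to_numpy()
    if not mask.any():
        raise ValidationError(f"no subjects with group {group!r}")
    return MeasurementTable(
        modality=table.modality,
        subjects=table.subjects.loc[mask].reset_index(drop=True),
        values=table.values.loc[mask],
        whole_brain=table.whole_brain.loc[mask],
    )


@dataclass
class HematomaSeries:
    """Hematoma volume of one animal at days 0, 3 and 7 post-induction."""

    subject_id: str
    volumes_mm3: dict[int, float] = field(default_factory=dict)  # keys: 0, 3, 7
    died_before_mri: bool = False

    DAYS = (0, 3, 7)

    def __post_init__(self) -> None:
        extra = set(self.volumes_mm3) - set(self.DAYS)
        if extra:
            raise ValidationError(f"hematoma series day labels must be in {self.DAYS}, got {sorted(extra)}")
        for d, v in self.volumes_mm3.items():
            if v < 0:
                raise ValidationError(f"subject {self.subject_id!r}: negative volume at day {d}")

    @property
    def complete(self) -> bool:
        return all(d in self.volumes_mm3 for d in self.DAYS)


def read_hematoma_csv(path: str | Path) -> list[HematomaSeries]:
    """CSV layout: ``subject_id,day0_mm3,day3_mm3,day7_mm3,died_before_mri``."""
    df = pd.read_csv(path)
    needed = ["subject_id", "day0_mm3", "day3_mm3", "day7_mm3"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {missing}")
    out = []
    for _, row in df.iterrows():
        vols = {}
        for d in HematomaSeries.DAYS:
            v = row[f"day{d}_mm3"]
            if pd.notna(v):
                vols[d] = float(v)
        out.append(
            HematomaSeries(
                subject_id=str(row["subject_id"]),
                volumes_mm3=vols,
                died_before_mri=bool(row.get("died_before_mri", False)),
            )
        )
    return out


def write_hematoma_csv(series: list[HematomaSeries], path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "day0_mm3": s.volumes_mm3.get(0),
            "day3_mm3": s.volumes_mm3.get(3),
            "day7_mm3": s.volumes_mm3.get(7),
            "died_before_mri": s.died_before_mri,
        }
        for s in series
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
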