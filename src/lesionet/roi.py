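"""Per-subject ROI derivations: lateralization, normalization, SUVw, filters.

Morphometry side: the lateralization index of a bilateral pair is the
ipsilateral volume divided by the contralateral volume (< 1 means ipsilateral
atrophy); for network analysis each region volume is normalized by the
subject's whole-brain volume.  Metabolism side: regional uptake is expressed
as SUVw — SUV divided by the subject's whole-brain mean uptake — after
averaging the acquisition frames.  Cohort level: the hematoma resorption
course over days 0/3/7, percent volume change, and the inclusion filters
(deaths first, then lesions below 10 mm³; strict '<', so exactly 10 mm³ is
included; sham animals bypass the volume filter).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .behavior import group_compare, paired_compare
from .errors import (
    InsufficientDataError,
    SchemaError,
    ValidationError,
)
from .tables import HematomaSeries, MeasurementTable

MIN_LESION_VOLUME_MM3 = 10.0


def lateralization_index(table: MeasurementTable, atlas: RoiAtlas) -> pd.DataFrame:
    """Ipsilateral/contralateral volume ratio per subject per bilateral pair.

    Returns a subjects × pairs DataFrame (columns = pair_ids, atlas order);
    midline/unpaired regions are skipped.  Zero ipsilateral volume is allowed
    (a lesion cavity can obliterate a structure); zero contralateral volume is
    a division error.
    """
    if table.modality != "volume_mm3":
        raise ValidationError(
            f"lateralization_index expects volume tables, got modality {table.modality!r}"
        )
    pairs = atlas.pairs()
    if not pairs:
        raise ValidationError("atlas has no complete bilateral pairs")
    out = {}
    for pid, ipsi_name, contra_name in pairs:
        ipsi = table.values[ipsi_name].to_numpy(dtype=float)
        contra = table.values[contra_name].to_numpy(dtype=float)
        zero = contra <= 0
        if zero.any():
            bad = table.subject_ids[int(np.argmax(zero))]
            raise ValidationError(
                f"zero contralateral volume for subject {bad!r}, pair {pid!r}"
            )
        out[pid] = ipsi / contra
    return pd.DataFrame(out, index=table.values.index)


def normalize_by_whole_brain(table: MeasurementTable) -> pd.DataFrame:
    """Region volume as a fraction of the subject's whole-brain volume."""
    if table.modality != "volume_mm3":
        raise ValidationError(
            f"normalize_by_whole_brain expects volume tables, got {table.modality!r}"
        )
    vals = table.matrix()
    wb = table.whole_brain.to_numpy(dtype=float)
    over = vals > wb[:, None]
    if over.any():
        i, j = np.argwhere(over)[0]
        raise ValidationError(
            f"region volume exceeds whole-brain volume for subject "
            f"{table.subject_ids[i]!r}, region {table.regions[j]!r}"
        )
    return pd.DataFrame(vals / wb[:, None], index=table.values.index, columns=table.regions)


def suvw_normalize(table: MeasurementTable) -> pd.DataFrame:
    """Regional SUV divided by the subject's whole-brain mean uptake (SUVw)."""
    if table.modality != "suv":
        raise ValidationError(
            f"suvw_normalize expects SUV tables, got modality {table.modality!r}"
        )
    wb = table.whole_brain.to_numpy(dtype=float)
    if (wb <= 0).any():
        bad = table.subject_ids[int(np.argmax(wb <= 0))]
        raise ValidationError(f"non-positive whole-brain uptake for subject {bad!r}")
    return pd.DataFrame(
        table.matrix() / wb[:, None], index=table.values.index, columns=table.regions
    )


def average_frames(frames) -> pd.Series | np.ndarray:
    """Arithmetic mean across acquisition frames, region by region.

    ``frames`` is a sequence of per-region uptake vectors (pandas Series keyed
    by region name, or plain arrays).  All frames must cover the same region
    set.
    """
    frames = list(frames)
    if not frames:
        raise SchemaError("average_frames needs at least one frame")
    if isinstance(frames[0], pd.Series):
        ref = list(frames[0].index)
        for k, f in enumerate(frames[1:], start=2):
            if not isinstance(f, pd.Series) or list(f.index) != ref:
                raise SchemaError(f"frame {k} region set differs from frame 1")
        return pd.Series(
            np.mean([f.to_numpy(dtype=float) for f in frames], axis=0), index=ref
        )
    arrs = [np.asarray(f, dtype=float) for f in frames]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise SchemaError("frames have mismatched region sets")
    return np.mean(arrs, axis=0)


def percent_change(v_from: float, v_to: float) -> float:
    """Percent decrease from ``v_from`` to ``v_to`` (positive = shrinkage)."""
    if v_from <= 0:
        raise ValidationError(f"v_from must be > 0, got {v_from}")
    return 100.0 * (v_from - v_to) / v_from


@dataclass
class HematomaCourse:
    """Per-day summary of hematoma volumes plus day-vs-day paired tests."""

    summary: pd.DataFrame  # index: day; columns: mean, sd, n
    comparisons: pd.DataFrame  # day_a, day_b, mean_diff, test, statistic, p
    excluded: list[str]  # subject ids with incomplete series

    @property
    def mean_resorption_percent(self) -> float:
        """Mean per-animal percent volume loss from day 0 to day 7."""
        return float(self._resorption.mean())

    _resorption: pd.Series = None  # set by hematoma_course


def hematoma_course(series: list[HematomaSeries]) -> HematomaCourse:
    """Summarize the acute hematoma volume course (days 0, 3, 7).

    Animals with incomplete series are excluded with a diagnostic, not an
    error.  Day-vs-day changes (0 vs 3, 0 vs 7) are tested on the paired
    per-animal differences with the distribution-gated one-sample test.
    """
    complete = [s for s in series if s.complete]
    excluded = [s.subject_id for s in series if not s.complete]
    if len(complete) < 3:
        raise InsufficientDataError(
            f"hematoma_course needs >= 3 complete series, got {len(complete)}"
        )
    days = HematomaSeries.DAYS
    mat = pd.DataFrame(
        {d: [s.volumes_mm3[d] for s in complete] for d in days},
        index=[s.subject_id for s in complete],
    )
    summary = pd.DataFrame(
        {
            "mean": mat.mean(),
            "sd": mat.std(ddof=1),
            "n": [len(complete)] * len(days),
        }
    )
    summary.index.name = "day"
    rows = []
    for day_b in (3, 7):
        diffs = mat[0] - mat[day_b]
        test, statistic, p = paired_compare(diffs)
        rows.append(
            {
                "day_a": 0,
                "day_b": day_b,
                "mean_diff": float(diffs.mean()),
                "test": test,
                "statistic": statistic,
                "p": p,
            }
        )
    course = HematomaCourse(summary=summary, comparisons=pd.DataFrame(rows), excluded=excluded)
    v0 = mat[0].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        course._resorption = pd.Series(100.0 * (v0 - mat[7].to_numpy()) / v0, index=mat.index)
    return course


@dataclass
class InclusionDecision:
    subject_id: str
    included: bool
    reason: str  # "included" | "died_before_mri" | "volume_below_threshold"


def apply_inclusion_filters(
    cohort,
    min_volume: float = MIN_LESION_VOLUME_MM3,
) -> tuple[list[InclusionDecision], list[InclusionDecision]]:
    """Apply the cohort inclusion filters; returns (included, excluded).

    ``cohort`` is an iterable of records with fields ``subject_id``,
    ``v0_mm3`` (initial lesion volume; may be None for deaths),
    ``died_before_mri`` and optionally ``group`` (default "ich").  Deaths are
    excluded first, then lesioned animals with v0 strictly below
    ``min_volume``; sham animals bypass the volume filter.
    """
    included: list[InclusionDecision] = []
    excluded: list[InclusionDecision] = []
    for rec in cohort:
        if isinstance(rec, dict):
            sid = str(rec["subject_id"])
            v0 = rec.get("v0_mm3")
            died = bool(rec.get("died_before_mri", False))
            group = rec.get("group", "ich")
        else:  # tuple-like (subject_id, v0, died[, group])
            sid = str(rec[0])
            v0 = rec[1]
            died = bool(rec[2])
            group = rec[3] if len(rec) > 3 else "ich"
        if died:
            excluded.append(InclusionDecision(sid, False, "died_before_mri"))
            continue
        if group == "ich" and v0 is not None and float(v0) < min_volume:
            excluded.append(InclusionDecision(sid, False, "volume_below_threshold"))
            continue
        included.append(InclusionDecision(sid, True, "included"))
    return included, excluded


def contralateral_check(
    table: MeasurementTable, atlas: RoiAtlas
) -> pd.DataFrame:
    """Per-region sanity check: raw contralateral volumes, lesioned vs sham.

    The lesion should leave the contralateral hemisphere structurally intact,
    so these comparisons are expected to be non-significant; a significant row
    flags a registration or segmentation problem.
    """
    contra_side = "left" if atlas.lesion_side == "right" else "right"
    contra_regions = [r.name for r in atlas.regions if r.hemisphere == contra_side]
    groups = table.subjects["group"].to_numpy()
    rows = []
    for region in contra_regions:
        vals = table.values[region].to_numpy(dtype=float)
        a = vals[groups == "ich"]
        b = vals[groups == "sham"]
        test, statistic, p = group_compare(a, b)
        rows.append(
            {
                "region": region,
                "ich_mean": float(a.mean()),
                "sham_mean": float(b.mean()),
                "test": test,
                "statistic": statistic,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
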