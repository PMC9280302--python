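"""Synthetic cohorts with the statistical structure the analysis assumes.

Regional volumes/uptake are drawn from a multivariate normal on the log
scale and exponentiated, giving strictly positive (lognormal) values; group
effects are multiplicative factors on the regional mean, which makes atrophy
ratios exact on the log scale (the analysis reports ratios, which are natural
there).  Group-specific interregional correlation is planted on the latent
log-scale Gaussian; the Pearson correlation of the exponentiated values is
very slightly attenuated, which is tolerated because recovery tests compare
against pipeline estimates on the same scale the pipeline analyzes.

Behavioral sequences are Markovian: at each Y-maze step the animal moves to
one of the two arms other than the current one, choosing the least recently
visited of the two with probability ``p_alternate`` (a never-visited arm
counts as least recently visited, time -inf).  For long chains the
spontaneous-alternation score estimates ``100 * p_alternate``.

The calibrated cohort preset encodes the study conditions this generator
emulates: lesioned animals carry an ipsilateral striatal volume factor of
0.66 and shams 0.97, so the expected lateralization indices match the group
means of 0.66 and 0.97; hematoma series default to a day-0 mean of
23.35 mm³ (sd 9.50) with a day-7 residual fraction of 0.596 (mean resorption
about 40%).

One root integer seed drives everything; per-group and per-subject
sub-streams are derived deterministically from it, so cohorts are
reproducible and extensible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .atlas import RoiAtlas, default_atlas
from .behavior import VisitSequence
from .errors import CohortSpecError, ValidationError
from .tables import HematomaSeries, MeasurementTable, make_measurement_table

PSD_TOLERANCE = -1e-10
WHOLE_BRAIN_OVERHEAD = 1.6  # whole brain = overhead x sum of atlas regions

# per-hemisphere baseline volumes (mm3) for the default 9-pair atlas
_DEFAULT_PAIR_VOLUMES = {
    "striatum": 45.0,
    "thalamus": 55.0,
    "hippocampus": 50.0,
    "amygdala": 20.0,
    "frontal": 90.0,
    "parietal": 70.0,
    "temporal": 80.0,
    "occipital": 60.0,
    "cingulate": 35.0,
}

STRIATAL_INDEX_ICH = 0.66
STRIATAL_INDEX_SHAM = 0.97
HEMATOMA_V0_MEAN = 23.35
HEMATOMA_V0_SD = 9.50
HEMATOMA_DAY7_FRACTION = 0.596  # day-7 mean 13.91 / day-0 mean 23.35


@dataclass
class CohortSpec:
    """Generative description of a synthetic two-group cohort."""

    atlas: RoiAtlas
    n_per_group: dict[str, int]  # {"ich": n, "sham": n}
    baseline_log_mean: dict[str, float]  # per region
    baseline_log_sd: dict[str, float]  # per region, > 0
    group_effects: list[tuple[str, str, float]] = field(default_factory=list)
    # (group, region, multiplicative mean factor > 0)
    planted_edges: list[tuple[str, str, str, float]] = field(default_factory=list)
    # (region_a, region_b, group, latent correlation in (-1, 1))
    whole_brain_overhead: float = WHOLE_BRAIN_OVERHEAD
    seed: int = 0

    def validate(self) -> None:
        names = set(self.atlas.names)
        for g, n in self.n_per_group.items():
            if g not in ("ich", "sham"):
                raise CohortSpecError(f"unknown group {g!r}")
            if n < 1:
                raise CohortSpecError(f"n_per_group[{g!r}] must be >= 1")
        for region in self.atlas.names:
            if region not in self.baseline_log_mean:
                raise CohortSpecError(f"baseline_log_mean missing region {region!r}")
            sd = self.baseline_log_sd.get(region)
            if sd is None or sd <= 0:
                raise CohortSpecError(f"baseline_log_sd for {region!r} must be > 0")
        for g, region, f in self.group_effects:
            if region not in names:
                raise CohortSpecError(f"group effect names unknown region {region!r}")
            if f <= 0:
                raise CohortSpecError(f"effect factor for {region!r} must be > 0, got {f}")
        for ra, rb, g, r in self.planted_edges:
            if ra not in names or rb not in names:
                raise CohortSpecError(f"planted edge names unknown region ({ra!r}, {rb!r})")
            if ra == rb:
                raise CohortSpecError(f"planted edge must join distinct regions ({ra!r})")
            if not -1 < r < 1:
                raise CohortSpecError(f"planted correlation must be in (-1, 1), got {r}")

    def correlation_matrix(self, group: str) -> np.ndarray:
        """Latent correlation matrix for one group (identity + planted edges)."""
        names = self.atlas.names
        idx = {n: i for i, n in enumerate(names)}
        corr = np.eye(len(names))
        edges = []
        for ra, rb, g, r in self.planted_edges:
            if g != group:
                continue
            i, j = idx[ra], idx[rb]
            corr[i, j] = corr[j, i] = r
            edges.append((ra, rb))
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < PSD_TOLERANCE:
            raise CohortSpecError(
                f"planted edges {edges} for group {group!r} give a non-PSD "
                f"correlation matrix (min eigenvalue {eig.min():.3g})"
            )
        if eig.min() < 0:  # numerically negative within tolerance: project
            w, v = np.linalg.eigh(corr)
            corr = (v * np.clip(w, 0, None)) @ v.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
        return corr


def default_cohort_spec(
    atlas: RoiAtlas | None = None,
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    baseline_log_sd: float = 0.05,
    group_effects: list[tuple[str, str, float]] | None = None,
    planted_edges: list[tuple[str, str, str, float]] | None = None,
) -> CohortSpec:
    """A neutral cohort spec over the default atlas (no effects, no edges)."""
    atlas = atlas or default_atlas()
    log_mean = {}
    for r in atlas.regions:
        base = _DEFAULT_PAIR_VOLUMES.get(r.pair_id or r.name, 50.0)
        log_mean[r.name] = float(np.log(base))
    return CohortSpec(
        atlas=atlas,
        n_per_group=dict(n_per_group or {"ich": 20, "sham": 20}),
        baseline_log_mean=log_mean,
        baseline_log_sd={n: baseline_log_sd for n in atlas.names},
        group_effects=list(group_effects or []),
        planted_edges=list(planted_edges or []),
        seed=seed,
    )


def calibrated_cohort_spec(
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    atlas: RoiAtlas | None = None,
) -> CohortSpec:
    """Volumetry preset calibrated to the study's striatal atrophy ratios.

    The ipsilateral striatum carries a multiplicative factor of 0.66 in the
    lesioned group and 0.97 in shams, so the expected lateralization index
    matches the corresponding group mean (up to a lognormal correction of
    exp(sigma^2) ~ 1.003 at the default log-sd of 0.05).
    """
    atlas = atlas or default_atlas()
    ipsi_striatum = next(
        r.name
        for r in atlas.regions
        if r.pair_id == "striatum" and r.hemisphere == atlas.lesion_side
    )
    return default_cohort_spec(
        atlas=atlas,
        n_per_group=n_per_group or {"ich": 32, "sham": 32},
        seed=seed,
        group_effects=[
            ("ich", ipsi_striatum, STRIATAL_INDEX_ICH),
            ("sham", ipsi_striatum, STRIATAL_INDEX_SHAM),
        ],
    )


def make_cohort(spec: CohortSpec, modality: str = "volume_mm3") -> MeasurementTable:
    """Draw a cohort table from a spec (lognormal, group-structured).

    Whole-brain values are the per-subject region sum times the overhead
    factor (regions cover only part of the brain).  Sexes alternate within
    group, matching the 1:1 design.
    """
    spec.validate()
    names = spec.atlas.names
    k = len(names)
    root = np.random.SeedSequence(spec.seed)
    group_seeds = dict(zip(("ich", "sham"), root.spawn(2)))

    sub_frames = []
    subj_rows = []
    for group in ("ich", "sham"):
        n = spec.n_per_group.get(group, 0)
        if n == 0:
            continue
        rng = np.random.default_rng(group_seeds[group])
        corr = spec.correlation_matrix(group)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
        mu = np.array([spec.baseline_log_mean[nm] for nm in names])
        sd = np.array([spec.baseline_log_sd[nm] for nm in names])
        for g, region, f in spec.group_effects:
            if g == group:
                mu = mu.copy()
                mu[names.index(region)] += np.log(f)
        z = rng.standard_normal((n, k)) @ chol.T
        values = np.exp(mu + z * sd)
        sub_frames.append(pd.DataFrame(values, columns=names))
        for i in range(n):
            subj_rows.append(
                {
                    "subject_id": f"{group}_{i + 1:03d}",
                    "group": group,
                    "sex": "male" if i % 2 == 0 else "female",
                }
            )
    values = pd.concat(sub_frames, ignore_index=True)
    subjects = pd.DataFrame(subj_rows)
    whole_brain = values.sum(axis=1) * spec.whole_brain_overhead
    return make_measurement_table(modality, subjects, values, whole_brain, spec.atlas)


@dataclass
class BehaviorSimSpec:
    """Markov Y-maze walk: alternate to the least-recent arm w.p. p_alternate."""

    n_visits: int = 30
    p_alternate: float = 0.7
    arms: tuple[str, str, str] = ("A", "B", "C")
    mean_dwell_s: float = 15.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_visits < 1:
            raise ValidationError("n_visits must be >= 1")
        if not 0 <= self.p_alternate <= 1:
            raise ValidationError("p_alternate must be in [0, 1]")
        if len(set(self.arms)) != 3:
            raise ValidationError("arms must be 3 distinct labels")


def make_visit_sequence(spec: BehaviorSimSpec, subject_id: str = "sim") -> VisitSequence:
    """Simulate one Y-maze session.

    First arm uniform; each later entry picks between the two arms different
    from the current one: the least recently visited of the two with
    probability ``p_alternate`` (never-visited = least recent; the visit-2
    tie between two unvisited arms is broken uniformly), otherwise the other.
    Inter-visit times are exponential, so timestamps strictly increase.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    arms = list(spec.arms)
    last: dict[str, float] = {a: -np.inf for a in arms}
    seq: list[str] = []
    current = arms[rng.integers(3)]
    seq.append(current)
    last[current] = 0
    for i in range(1, spec.n_visits):
        candidates = [a for a in arms if a != current]
        t0, t1 = last[candidates[0]], last[candidates[1]]
        if t0 == t1:  # both unvisited (only possible at visit 2)
            least = candidates[int(rng.integers(2))]
        else:
            least = candidates[0] if t0 < t1 else candidates[1]
        other = candidates[1] if least == candidates[0] else candidates[0]
        current = least if rng.random() < spec.p_alternate else other
        seq.append(current)
        last[current] = i
    gaps = rng.exponential(spec.mean_dwell_s, size=spec.n_visits)
    times = np.cumsum(gaps)
    return VisitSequence(subject_id=subject_id, visits=list(zip(times.tolist(), seq)))


def make_exploration_trial(
    preference: float, total_s: float, seed: int
) -> tuple[float, float]:
    """Split ``total_s`` of object exploration between novel and familiar.

    The novel share b is Beta-distributed with mean ``preference`` and
    concentration 20, clamped to (0, 1); expected discrimination index is
    ``2 * preference - 1``.
    """
    if total_s <= 0:
        raise ValidationError("total_s must be > 0")
    if not 0 <= preference <= 1:
        raise ValidationError("preference must be in [0, 1]")
    rng = np.random.default_rng(seed)
    eps = 1e-9
    p = min(max(preference, eps), 1 - eps)
    b = rng.beta(20.0 * p, 20.0 * (1.0 - p))
    b = min(max(b, eps), 1 - eps)
    novel = total_s * b
    return novel, total_s - novel


def make_hematoma_series(
    v0_mean: float = HEMATOMA_V0_MEAN,
    v0_sd: float = HEMATOMA_V0_SD,
    day7_fraction: float = HEMATOMA_DAY7_FRACTION,
    n: int = 64,
    seed: int = 0,
    min_volume: float = 0.5,
) -> list[HematomaSeries]:
    """Simulate hematoma volume series at days 0/3/7.

    Day-0 volumes are truncated-normal (>= ``min_volume``); day 3 stays at
    the initial volume up to 5% multiplicative noise; day 7 shrinks to
    ``day7_fraction`` of day 0, again with 5% noise.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 < day7_fraction <= 1:
        raise ValidationError("day7_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    a = (min_volume - v0_mean) / v0_sd
    v0 = truncnorm.rvs(a, np.inf, loc=v0_mean, scale=v0_sd, size=n, random_state=rng)
    f3 = np.clip(rng.normal(1.0, 0.05, size=n), 0, None)
    f7 = np.clip(rng.normal(day7_fraction, 0.05, size=n), 0, None)
    return [
        HematomaSeries(
            subject_id=f"ich_{i + 1:03d}",
            volumes_mm3={0: float(v0[i]), 3: float(v0[i] * f3[i]), 7: float(v0[i] * f7[i])},
        )
        for i in range(n)
    ]


# acute-phase locomotion group means (distance cm, rearings, resting s) per
# session day: severe day-0 impairment with recovery by day 7
LOCOMOTION_PRESETS = {
    0: {"ich": (961.0, 6.7, 430.0), "sham": (3168.0, 57.3, 250.0)},
    3: {"ich": (3069.0, 46.1, 253.0), "sham": (3548.0, 60.9, 222.0)},
    7: {"ich": (3662.0, 56.0, 215.0), "sham": (3844.0, 59.0, 226.0)},
}


def make_locomotion_table(
    subjects: pd.DataFrame, seed: int = 0, cv: float = 0.15
) -> pd.DataFrame:
    """Open-field summaries per subject per acute-phase day.

    Columns ``subject_id,day,distance_cm,rearings,resting_s``; values are
    the group-day preset means with multiplicative noise (coefficient of
    variation ``cv``), floored at 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, row in subjects.iterrows():
        for day, presets in LOCOMOTION_PRESETS.items():
            dist, rear, rest = presets[row["group"]]
            noise = rng.normal(1.0, cv, size=3).clip(min=0.0)
            rows.append(
                {
                    "subject_id": str(row["subject_id"]),
                    "day": day,
                    "distance_cm": dist * noise[0],
                    "rearings": rear * noise[1],
                    "resting_s": rest * noise[2],
                }
            )
    return pd.DataFrame(rows)


# study-condition behavioral presets: group means of the emulated cohort
BEHAVIOR_PRESETS = {
    "p_alternate": {"ich": 0.581, "sham": 0.707},
    "novel_arm_fraction": {"ich": 0.487, "sham": 0.64},
    "object_preference": {"ich": 0.57, "sham": 0.665},  # (DI + 1) / 2
    "open_arm_fraction": {"ich": 0.132, "sham": 0.150},
}


def make_behavior_tables(
    subjects: pd.DataFrame,
    seed: int = 0,
    n_visits: int = 30,
    session_s: float = 600.0,
    presets: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Simulate the full behavioral battery for a cohort.

    Returns CSV-shaped frames: ``visits`` (subject_id, t_s, arm), ``arm_time``
    (subject_id, start_s, novel_s, other_s), ``exploration`` (subject_id,
    sample_total_s, test_novel_s, test_familiar_s) and ``open_arm``
    (subject_id, open_s, total_s).  Per-subject parameters come from the
    group presets (Beta-jittered around the group mean).
    """
    presets = presets or BEHAVIOR_PRESETS
    root = np.random.SeedSequence(seed)
    visit_rows, arm_rows, expl_rows, open_rows = [], [], [], []
    for (_, row), ss in zip(subjects.iterrows(), root.spawn(len(subjects))):
        sid, group = str(row["subject_id"]), row["group"]
        child = ss.spawn(4)
        rng = np.random.default_rng(child[0])

        p_alt = presets["p_alternate"][group]
        seq = make_visit_sequence(
            BehaviorSimSpec(
                n_visits=n_visits,
                p_alternate=float(np.clip(rng.beta(40 * p_alt, 40 * (1 - p_alt)), 0, 1)),
                seed=child[1].generate_state(1)[0] % (2**31),
            ),
            subject_id=sid,
        )
        visit_rows += [{"subject_id": sid, "t_s": t, "arm": a} for t, a in seq.visits]

        nf = presets["novel_arm_fraction"][group]
        fracs = rng.dirichlet([30 * (1 - nf) / 2, 30 * nf, 30 * (1 - nf) / 2])
        arm_time = fracs * 300.0  # 5-min test trial
        arm_rows.append(
            {
                "subject_id": sid,
                "start_s": arm_time[0],
                "novel_s": arm_time[1],
                "other_s": arm_time[2],
            }
        )

        pref = presets["object_preference"][group]
        novel, familiar = make_exploration_trial(
            pref, total_s=30.0, seed=int(child[2].generate_state(1)[0] % (2**31))
        )
        expl_rows.append(
            {
                "subject_id": sid,
                "sample_total_s": float(rng.uniform(12.0, 60.0)),
                "test_novel_s": novel,
                "test_familiar_s": familiar,
            }
        )

        oa = presets["open_arm_fraction"][group]
        open_rows.append(
            {
                "subject_id": sid,
                "open_s": float(np.clip(rng.beta(60 * oa, 60 * (1 - oa)), 0, 1)) * session_s,
                "total_s": session_s,
            }
        )
    return {
        "visits": pd.DataFrame(visit_rows),
        "arm_time": pd.DataFrame(arm_rows),
        "exploration": pd.DataFrame(expl_rows),
        "open_arm": pd.DataFrame(open_rows),
    }
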