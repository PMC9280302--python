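"""Interregional correlation networks and their permutation-based comparison.

Within each group, the network is the matrix of Pearson correlations of a
regional measure (SUVw for metabolic connectivity, whole-brain-normalized
volumes for the atrophy-related network) computed *across subjects* for every
region pair.  Correlations are mapped to Fisher Z (arctanh) and the two
groups are compared edge-wise on dZ = Z_A - Z_B.  The null distribution of dZ
is built by pooling all subjects and re-splitting them into pseudo-groups of
the original sizes, recomputing both correlation matrices per relabeling;
the two-sided p-value per edge uses the add-one estimator
``p = (1 + #{|dZ_null| >= |dZ_obs|}) / (n_used + 1)``, which cannot be 0 and
is exact under exchangeability.  Edges with p below alpha are classified
increased/decreased by the sign of the observed dZ.

The engine is exposed as a scikit-learn style estimator
(:class:`PermutationEdgeTest`) fitting on a pooled (n_subjects, n_regions)
matrix with a two-level group label vector, plus thin functional wrappers
operating on :class:`~lesionet.tables.MeasurementTable` / DataFrames.

Implementation notes: relabelings are drawn over a canonical (lexicographic)
ordering of the pooled rows, so results are invariant to subject order and to
swapping the two groups.  ``mode="exact"`` enumerates all distinct splits
when feasible (the observed split enters through the add-one term);
Monte-Carlo mode samples splits uniformly with replacement.  A region that
becomes constant inside a permutation replicate gets correlation 0 for its
edges (with a warning counter) rather than aborting the run; zero variance in
the *observed* data is a hard error.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control
from sklearn.base import BaseEstimator

from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .tables import MeasurementTable

EXACT_ENUMERATION_LIMIT = 20_000
_CLAMP = 1.0 - 1e-7


@dataclass
class GroupCorrelationMatrix:
    """Across-subject Pearson correlations of one group's regional measures."""

    group: str
    regions: list[str]
    r: np.ndarray  # symmetric, unit diagonal
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.regions, columns=self.regions)


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, MeasurementTable):
        return data.matrix(), data.regions
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(c) for c in data.columns]
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D subjects x regions array")
    return arr, [f"region_{j}" for j in range(arr.shape[1])]


def _canon_rows(x: np.ndarray) -> np.ndarray:
    """Rows in lexicographic order (deterministic, order-insensitive)."""
    return x[np.lexsort(x.T[::-1])]


def _pearson(x: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of columns; constant columns map to r=0.

    Batched: ``x`` may be (n, k) or (m, n, k); correlation is over axis -2.
    """
    x = x - x.mean(axis=-2, keepdims=True)
    norm = np.sqrt((x * x).sum(axis=-2, keepdims=True))
    zero = norm == 0
    norm = np.where(zero, 1.0, norm)
    xs = x / norm
    r = np.swapaxes(xs, -1, -2) @ xs
    if zero.any():
        # a constant column yields r=0 off-diagonal (its xs column is 0)
        k = r.shape[-1]
        diag = np.eye(k, dtype=bool)
        r[..., diag] = 1.0
    np.clip(r, -1.0, 1.0, out=r)
    return r


def group_correlation(table, group: str | None = None) -> GroupCorrelationMatrix:
    """Across-subject correlation matrix for one group's table.

    Zero-variance regions in the observed data are a hard error (the
    correlation is undefined and would silently distort the network).
    """
    x, regions = _as_matrix(table)
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError(f"group correlation needs >= 3 subjects, got {n}")
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [regions[j] for j in np.flatnonzero(sd == 0)]
        raise DegenerateDataError(f"zero-variance region(s): {bad}")
    if group is None:
        if isinstance(table, MeasurementTable):
            labels = set(table.subjects["group"])
            group = labels.pop() if len(labels) == 1 else "mixed"
        else:
            group = "all"
    r = _pearson(x)
    return GroupCorrelationMatrix(group=group, regions=regions, r=r, n_subjects=n)


def fisher_z(r) -> np.ndarray:
    """Elementwise Fisher transform z = arctanh(r), clamped at |r| = 1 - 1e-7.

    Accepts a matrix or a :class:`GroupCorrelationMatrix`; the diagonal is
    masked to NaN (self-correlation carries no information).
    """
    if isinstance(r, GroupCorrelationMatrix):
        r = r.r
    r = np.asarray(r, dtype=float)
    z = np.arctanh(np.clip(r, -_CLAMP, _CLAMP))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        z = z.copy()
        np.fill_diagonal(z, np.nan)
    return z


@dataclass
class NetworkComparison:
    """Edge-wise permutation comparison of two groups' correlation networks."""

    regions: list[str]
    groups: tuple[str, str]  # (A, B); delta_z = Z_A - Z_B
    delta_z: np.ndarray  # (k, k), NaN diagonal
    p: np.ndarray  # (k, k), NaN diagonal
    alpha: float
    n_used: int  # relabelings actually in the null
    mode: str  # "montecarlo" | "exact"
    seed: int | None
    n_degenerate_replicates: int = 0
    p_fdr: np.ndarray | None = None

    def direction(self, alpha: float | None = None) -> np.ndarray:
        """Edge classification matrix: 'increased' | 'decreased' | 'ns'."""
        alpha = self.alpha if alpha is None else alpha
        p = self.p_fdr if self.p_fdr is not None else self.p
        out = np.full(self.delta_z.shape, "ns", dtype=object)
        sig = (p < alpha) & ~np.isnan(self.delta_z)
        out[sig & (self.delta_z > 0)] = "increased"
        out[sig & (self.delta_z < 0)] = "decreased"
        return out

    def edges(self) -> pd.DataFrame:
        """One row per unordered region pair, in atlas order."""
        k = len(self.regions)
        direction = self.direction()
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "region_a": self.regions[i],
                        "region_b": self.regions[j],
                        "delta_z": float(self.delta_z[i, j]),
                        "p": float(self.p[i, j]),
                        "direction": direction[i, j],
                    }
                )
        return pd.DataFrame(rows)


class PermutationEdgeTest(BaseEstimator):
    """Permutation test for edge-wise differences between two groups' networks.

    Parameters
    ----------
    n_permutations : int, default=10000
        Relabelings drawn in Monte-Carlo mode.
    alpha : float, default=0.05
        Per-edge significance level for classification (no correction across
        edges by default, matching the per-edge reporting convention; set
        ``fdr=True`` for Benjamini-Hochberg adjusted classification).
    mode : {"auto", "montecarlo", "exact"}, default="auto"
        "exact" enumerates all distinct splits (identity excluded); "auto"
        picks exact when the split count is at most 20,000.
    statistic : {"dz", "dz_standardized"}, default="dz"
        "dz" is the raw Z_A - Z_B; "dz_standardized" divides by
        sqrt(1/(n_A-3) + 1/(n_B-3)).  With equal group sizes the two are
        equivalent under permutation.
    fdr : bool, default=False
        Apply Benjamini-Hochberg correction across edges before classifying.
    random_state : int or None
        Seed for the Monte-Carlo null.

    Attributes
    ----------
    regions_ : list of region names
    groups_ : (label_a, label_b), order of first appearance in ``y``
    r_a_, r_b_ : observed per-group correlation matrices
    delta_z_ : observed Z_A - Z_B (statistic scale), NaN diagonal
    p_values_ : two-sided add-one permutation p per edge, NaN diagonal
    direction_ : 'increased'/'decreased'/'ns' per edge at ``alpha``
    n_used_ : number of relabelings in the null
    mode_ : "montecarlo" or "exact" (resolved)
    """

    def __init__(
        self,
        n_permutations: int = 10_000,
        alpha: float = 0.05,
        mode: str = "auto",
        statistic: str = "dz",
        fdr: bool = False,
        random_state: int | None = None,
        batch_size: int = 2_000,
    ):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.mode = mode
        self.statistic = statistic
        self.fdr = fdr
        self.random_state = random_state
        self.batch_size = batch_size

    # -- internals ---------------------------------------------------------

    def _null_delta_z(self, pooled: np.ndarray, idx_a: np.ndarray) -> tuple[np.ndarray, int, str, int]:
        """Null |dZ| samples over relabelings of canonically ordered rows.

        Exact mode enumerates every split except the observed one, whose
        statistic the add-one term represents; Monte-Carlo mode samples splits
        uniformly (duplicates and the observed split allowed), the standard
        construction for which the add-one p estimates the exact p without
        bias.  The null therefore depends only on the pooled data and the
        group sizes — not on which group is labelled A.
        """
        n, k = pooled.shape
        n_a = idx_a.size
        n_splits = comb(n, n_a)
        mode = self.mode
        if mode == "auto":
            mode = "exact" if n_splits <= EXACT_ENUMERATION_LIMIT else "montecarlo"
        if mode not in ("exact", "montecarlo"):
            raise ValidationError(f"unknown mode {self.mode!r}")

        if mode == "exact":
            if n_splits > EXACT_ENUMERATION_LIMIT:
                raise ValidationError(
                    f"exact mode infeasible: {n_splits} splits > {EXACT_ENUMERATION_LIMIT}"
                )
            a_set = frozenset(idx_a.tolist())
            splits = [c for c in combinations(range(n), n_a) if frozenset(c) != a_set]
            sel_a = np.array(splits, dtype=np.intp)
        else:
            rng = np.random.default_rng(self.random_state)
            m = int(self.n_permutations)
            if m < 1:
                raise ValidationError("n_permutations must be >= 1")
            base = np.tile(np.arange(n, dtype=np.intp), (m, 1))
            sel_a = rng.permuted(base, axis=1)[:, :n_a]

        m = sel_a.shape[0]
        mask = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask, sel_a, True, axis=1)

        degenerate = 0
        abs_null = np.empty((m, k, k))
        bs = max(1, int(self.batch_size))
        for start in range(0, m, bs):
            stop = min(start + bs, m)
            sub_mask = mask[start:stop]
            mm = stop - start
            a_rows = pooled[np.nonzero(sub_mask)[1].reshape(mm, n_a)]
            b_rows = pooled[np.nonzero(~sub_mask)[1].reshape(mm, n - n_a)]
            for rows in (a_rows, b_rows):
                sd = rows.std(axis=1)
                degenerate += int((sd == 0).any(axis=1).sum())
            dz = fisher_z(_pearson(a_rows)) - fisher_z(_pearson(b_rows))
            abs_null[start:stop] = np.abs(dz)
        n_used = m
        return abs_null, n_used, mode, degenerate

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y):
        """Fit the comparison: X is pooled subjects × regions, y group labels.

        ``y`` must contain exactly two distinct labels; group A is the label
        appearing first in ``y`` and the statistic is Z_A - Z_B.
        """
        x, regions = _as_matrix(X)
        y = np.asarray(y)
        if y.shape[0] != x.shape[0]:
            raise ValidationError(
                f"y length {y.shape[0]} does not match {x.shape[0]} subjects"
            )
        labels = list(dict.fromkeys(y.tolist()))  # order of first appearance
        if len(labels) != 2:
            raise ValidationError(f"y must contain exactly 2 groups, got {labels}")
        label_a, label_b = labels
        # canonical within-group row order: bit-identical results regardless
        # of the order subjects arrive in
        xa = _canon_rows(x[y == label_a])
        xb = _canon_rows(x[y == label_b])
        if xa.shape[0] < 3 or xb.shape[0] < 3:
            raise InsufficientDataError(
                f"each group needs >= 3 subjects, got {xa.shape[0]} and {xb.shape[0]}"
            )
        corr_a = group_correlation(pd.DataFrame(xa, columns=regions), group=str(label_a))
        corr_b = group_correlation(pd.DataFrame(xb, columns=regions), group=str(label_b))
        dz_obs = fisher_z(corr_a) - fisher_z(corr_b)

        # canonical pooled order: the null is invariant to a group-label swap
        pooled = np.vstack([xa, xb])
        order = np.lexsort(pooled.T[::-1])
        pooled_canon = pooled[order]
        rank = np.empty_like(order)
        rank[order] = np.arange(order.size)
        idx_a = np.sort(rank[: xa.shape[0]])

        abs_null, n_used, mode, degenerate = self._null_delta_z(pooled_canon, idx_a)

        scale = 1.0
        if self.statistic == "dz_standardized":
            scale = 1.0 / np.sqrt(1.0 / (xa.shape[0] - 3) + 1.0 / (xb.shape[0] - 3))
        elif self.statistic != "dz":
            raise ValidationError(f"unknown statistic {self.statistic!r}")

        count = (abs_null >= np.abs(dz_obs)[None, :, :]).sum(axis=0)
        p = (1.0 + count) / (n_used + 1.0)
        p = p.astype(float)
        np.fill_diagonal(p, np.nan)

        if degenerate:
            warnings.warn(
                f"{degenerate} permutation replicate group(s) contained a "
                "constant region; its edges were scored with r=0",
                stacklevel=2,
            )

        self.regions_ = regions
        self.groups_ = (str(label_a), str(label_b))
        self.r_a_ = corr_a
        self.r_b_ = corr_b
        self.delta_z_ = dz_obs * scale
        self.p_values_ = p
        self.n_used_ = n_used
        self.mode_ = mode
        self.n_degenerate_replicates_ = degenerate
        self.p_fdr_ = self._bh(p) if self.fdr else None
        self.comparison_ = NetworkComparison(
            regions=regions,
            groups=self.groups_,
            delta_z=self.delta_z_,
            p=p,
            alpha=self.alpha,
            n_used=n_used,
            mode=mode,
            seed=self.random_state,
            n_degenerate_replicates=degenerate,
            p_fdr=self.p_fdr_,
        )
        self.direction_ = self.comparison_.direction()
        return self

    @staticmethod
    def _bh(p: np.ndarray) -> np.ndarray:
        k = p.shape[0]
        iu = np.triu_indices(k, 1)
        adj = false_discovery_control(p[iu], method="bh")
        out = np.full_like(p, np.nan)
        out[iu] = adj
        out[(iu[1], iu[0])] = adj
        return out


def permutation_edge_test(
    table_a,
    table_b,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    mode: str = "auto",
    statistic: str = "dz",
    fdr: bool = False,
    group_labels: tuple[str, str] = ("a", "b"),
) -> NetworkComparison:
    """Functional wrapper: compare two groups' tables edge-wise.

    ``table_a``/``table_b`` may be MeasurementTables, DataFrames or arrays
    over the same regions; the statistic is Z(table_a) - Z(table_b).
    """
    xa, regions_a = _as_matrix(table_a)
    xb, regions_b = _as_matrix(table_b)
    if regions_a != regions_b:
        raise ValidationError("tables cover different region sets")
    if isinstance(table_a, MeasurementTable):
        la = set(table_a.subjects["group"])
        lb = set(table_b.subjects["group"])
        if len(la) == 1 and len(lb) == 1 and la != lb:
            group_labels = (la.pop(), lb.pop())
    la, lb = group_labels
    if la == lb:
        la, lb = f"{la}_a", f"{lb}_b"
    y = np.array([la] * xa.shape[0] + [lb] * xb.shape[0], dtype=object)
    est = PermutationEdgeTest(
        n_permutations=n_permutations,
        alpha=alpha,
        mode=mode,
        statistic=statistic,
        fdr=fdr,
        random_state=seed,
    )
    est.fit(pd.DataFrame(np.vstack([xa, xb]), columns=regions_a), y)
    return est.comparison_


def classify_edges(
    comparison: NetworkComparison, alpha: float | None = None
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Partition significant edges into (increased, decreased) pair lists.

    Deterministic ordering: atlas region order, then pair.
    """
    direction = comparison.direction(alpha)
    k = len(comparison.regions)
    increased, decreased = [], []
    for i in range(k):
        for j in range(i + 1, k):
            pair = (comparison.regions[i], comparison.regions[j])
            if direction[i, j] == "increased":
                increased.append(pair)
            elif direction[i, j] == "decreased":
                decreased.append(pair)
    return increased, decreased
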