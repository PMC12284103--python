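"""Spin-permutation nulls, FDR, and class-level inference on region maps.

Spin nulls draw uniform random 3-D rotations, rotate the left-hemisphere
parcel centroids (the right hemisphere is reflected across the midline,
rotated with the same matrix, then reflected back), and reassign each
original parcel to its nearest rotated parcel.  Permutation p-values use
the add-one rule (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthetic_cortex import ClassAtlas, ParcelGeometry, RegionMap

__all__ = [
    "SpinNull",
    "TestResult",
    "PairwiseTable",
    "spin_assignment",
    "spin_permutations",
    "spin_test_correlation",
    "fdr_bh",
    "anova_oneway",
    "tukey_hsd",
    "class_adjusted_r2",
    "tertile_contrast",
]


@dataclass
class SpinNull:
    permutations: np.ndarray  # (n_perm, n_parcels) int indices
    seed: int
    bilateral: bool
    duplication_rate: float  # mean fraction of parcels not hit per spin

    @property
    def n_perm(self) -> int:
        return self.permutations.shape[0]

    def apply(self, values: np.ndarray) -> np.ndarray:
        """(n_perm, n_parcels) null maps for a region value vector."""
        return np.asarray(values)[self.permutations]


@dataclass
class TestResult:
    statistic: float
    p: float
    alternative: str = "two-sided"
    n_perm: int | None = None
    p_fdr: float | None = None
    flag: str | None = None


@dataclass
class PairwiseTable:
    pairs: list  # (class_i, class_j) names
    mean_differences: np.ndarray
    q_statistics: np.ndarray
    p_adjusted: np.ndarray


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix (QR with sign fix, det forced to +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def spin_assignment(
    geom: ParcelGeometry, rotation: np.ndarray, bilateral: bool = True
) -> np.ndarray:
    """Nearest-rotated-parcel assignment for one rotation matrix.

    ``out[i] = j`` means parcel i takes parcel j's value; j is the parcel
    whose rotated centroid is nearest to i's original centroid, searched
    within i's hemisphere.  In bilateral mode the right hemisphere is
    reflected across the midline before and after the rotation.
    """
    cent = geom.parcel_centroid
    left = geom.hemisphere == "L"
    mirror = np.diag([-1.0, 1.0, 1.0])
    out = np.empty(geom.n_parcels, dtype=int)
    for idx, rot in (
        (np.flatnonzero(left), rotation),
        (np.flatnonzero(~left), mirror @ rotation @ mirror if bilateral else rotation),
    ):
        rotated = cent[idx] @ rot.T
        dots = np.clip(cent[idx] @ rotated.T, -1.0, 1.0)
        out[idx] = idx[np.argmin(np.arccos(dots), axis=1)]
    return out


def spin_permutations(
    geom: ParcelGeometry, n_perm: int, seed: int, bilateral: bool = True
) -> SpinNull:
    """Nearest-rotated-parcel spin permutation ensemble (random rotations)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, geom.n_parcels), dtype=int)
    for k in range(n_perm):
        perms[k] = spin_assignment(geom, _random_rotation(rng), bilateral)
    hit = np.array([np.unique(row).size for row in perms])
    rate = float(1.0 - hit.mean() / geom.n_parcels)
    return SpinNull(perms, seed, bilateral, rate)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _perm_pvalue(observed: float, null: np.ndarray, alternative: str) -> float:
    n = null.size
    if alternative == "greater":
        return (1 + int(np.sum(null >= observed))) / (1 + n)
    if alternative == "less":
        return (1 + int(np.sum(null <= observed))) / (1 + n)
    if alternative == "two-sided":
        return (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (1 + n)
    raise ValueError(f"unknown alternative {alternative!r}")


def spin_test_correlation(
    x: RegionMap, y: RegionMap, null: SpinNull, alternative: str = "two-sided"
) -> TestResult:
    """Pearson correlation with a spin-permutation null (x rotated, y fixed)."""
    xv, yv = x.values, y.values
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise ValueError("spin_test_correlation: maps contain NaN")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("spin_test_correlation: zero-variance map")
    obs = _pearson(xv, yv)
    Xp = null.apply(xv)  # (n_perm, n)
    Xp = (Xp - Xp.mean(axis=1, keepdims=True)) / Xp.std(axis=1, keepdims=True)
    yz = (yv - yv.mean()) / yv.std()
    null_r = (Xp @ yz) / yv.size
    return TestResult(obs, _perm_pvalue(obs, null_r, alternative), alternative,
                      null.n_perm)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("fdr_bh: empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    p_adj = np.empty(m)
    p_adj[order] = adj
    # step-up rejection: largest k with p_(k) <= k q / m, reject 1..k
    thresh = p[order] <= q * np.arange(1, m + 1) / m
    reject = np.zeros(m, dtype=bool)
    if thresh.any():
        kmax = np.max(np.flatnonzero(thresh))
        reject[order[: kmax + 1]] = True
    return reject, p_adj


def _class_groups(map_: RegionMap, atlas: ClassAtlas, min_size: int = 2):
    groups, names = [], []
    for c in range(atlas.n_classes):
        vals = map_.values[atlas.labels == c]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_size:
            warnings.warn(
                f"class {atlas.class_names[c]!r} has < {min_size} regions, excluded",
                RuntimeWarning, stacklevel=3,
            )
            continue
        groups.append(vals)
        names.append(atlas.class_names[c])
    return groups, names


def anova_oneway(map_: RegionMap, atlas: ClassAtlas) -> TestResult:
    """One-way ANOVA of region values across atlas classes."""
    groups, _ = _class_groups(map_, atlas)
    if len(groups) < 2:
        raise ValueError("anova_oneway needs >= 2 usable classes")
    allv = np.concatenate(groups)
    if allv.var() == 0:
        return TestResult(float("nan"), float("nan"), "two-sided",
                          flag="degenerate: zero variance")
    f, p = stats.f_oneway(*groups)
    return TestResult(float(f), float(p), "two-sided")


def tukey_hsd(map_: RegionMap, atlas: ClassAtlas) -> PairwiseTable:
    """Tukey-Kramer studentized-range pairwise comparisons across classes."""
    groups, names = _class_groups(map_, atlas)
    if len(groups) < 2:
        raise ValueError("tukey_hsd needs >= 2 usable classes")
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (ns.sum() - len(groups))
    if msw == 0:
        res = None  # degenerate: identical values within classes
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.tukey_hsd(*groups)
    pairs, diffs, qs, ps = [], [], [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = means[i] - means[j]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            pairs.append((names[i], names[j]))
            diffs.append(diff)
            if res is None:
                qs.append(0.0 if diff == 0 else float("inf"))
                ps.append(1.0 if diff == 0 else 0.0)
            else:
                qs.append(abs(diff) / se if se > 0 else float("nan"))
                ps.append(float(res.pvalue[i, j]))
    return PairwiseTable(pairs, np.array(diffs), np.array(qs), np.array(ps))


def class_adjusted_r2(map_: RegionMap, atlas: ClassAtlas) -> float:
    """Adjusted R^2 (in percent) of the map regressed on class indicators."""
    y = map_.values
    ok = np.isfinite(y)
    y = y[ok]
    labels = atlas.labels[ok]
    n = y.size
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("class_adjusted_r2 needs >= 2 classes present")
    fitted = np.empty_like(y)
    for c in classes:
        fitted[labels == c] = y[labels == c].mean()
    sst = ((y - y.mean()) ** 2).sum()
    if sst == 0:
        return 0.0
    r2 = 1.0 - ((y - fitted) ** 2).sum() / sst
    k = classes.size  # parameters incl. intercept (one mean per class)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    return 100.0 * adj


def tertile_contrast(
    map_: RegionMap, axis: RegionMap, tertile_size: int, welch: bool = True
) -> TestResult:
    """Welch t-test between top- and bottom-ranked regions of an axis.

    Regions are ranked by the axis map (ties broken by region id); the
    ``tertile_size`` highest-ranked are contrasted against the
    ``tertile_size`` lowest-ranked.
    """
    n = map_.n_parcels
    if tertile_size > n // 2:
        raise ValueError("tertile_size must be <= n/2")
    order = np.argsort(axis.values, kind="stable")  # stable = ties by region id
    low = map_.values[order[:tertile_size]]
    high = map_.values[order[-tertile_size:]]
    if low.std(ddof=1) == 0 and high.std(ddof=1) == 0:
        flag = "degenerate: zero variance in both tertiles"
        stat = 0.0 if high.mean() == low.mean() else float("inf")
        return TestResult(stat, 1.0 if stat == 0.0 else 0.0, "two-sided", flag=flag)
    t, p = stats.ttest_ind(high, low, equal_var=not welch)
    return TestResult(float(t), float(p), "two-sided")
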