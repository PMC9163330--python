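"""Nonparametric statistical battery with seedable permutation machinery.

The cohort comparisons are deliberately distribution-free: group sizes in
museum collections are small and heavily unbalanced, so the pipeline relies
on rank tests (Mann–Whitney, Kruskal–Wallis, Dunn with Benjamini–Hochberg
correction), a robust Brown–Forsythe Levene-type variance test (median
deviations, optionally with O'Brien's correction factor and structural
zero removal), and permutation tests on distance matrices (PERMANOVA,
multivariate dispersion via principal coordinates). Every permutation test
takes an explicit seed and reports ``p = (exceedances + 1) / (n_perm + 1)``;
exact enumeration replaces sampling when the label-arrangement count is
small.

Proportions (relative facet areas) pass through the arcsine-square-root
transform before variance/location testing; unlike the logit it is finite
at 0 and 1, which matters because absent facets produce exact zeros.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 999
_EXACT_ENUM_LIMIT = 10_000


class DegenerateDataError(ValueError):
    """The statistic is undefined on this input (e.g. constant distances)."""


@dataclass
class TestResult:
    method: str
    statistic: float
    pvalue: float
    df: tuple | float | None = None
    n_perm: int | None = None
    seed: int | None = None
    group_sizes: tuple = ()
    extra: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # compact, log-friendly
        df = f", df={self.df}" if self.df is not None else ""
        perm = f", n_perm={self.n_perm}, seed={self.seed}" if self.n_perm else ""
        return (f"TestResult({self.method}: stat={self.statistic:.6g}, "
                f"p={self.pvalue:.6g}{df}{perm}, n={self.group_sizes})")


# ---------------------------------------------------------------------------
# transforms and univariate tests

def arcsine_transform(p):
    """arcsin(sqrt(p)) in radians; finite at both 0 and 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("arcsine transform is defined on proportions in [0, 1]")
    out = np.arcsin(np.sqrt(p))
    return float(out) if out.ndim == 0 else out


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Null distribution of the Mann-Whitney U (no ties): counts[u] over 0..n*m.

    Recurrence on the largest pooled element: if it belongs to x it beats all
    m y's, else it contributes nothing.
    """
    size = n * m + 1
    prev = [np.zeros(size) for _ in range(m + 1)]
    for j in range(m + 1):
        prev[j][0] = 1.0
    for _ in range(1, n + 1):
        cur = [np.zeros(size) for _ in range(m + 1)]
        cur[0][0] = 1.0
        for j in range(1, m + 1):
            shifted = np.zeros(size)
            shifted[j:] = prev[j][: size - j]
            cur[j] = shifted + cur[j - 1]
        prev = cur
    return prev[m]


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-tailed Mann-Whitney U test on two independent samples.

    U counts (x, y) pairs with y < x, ties counted half (midranks). The
    exact two-tailed p comes from the full null distribution of U when the
    samples are tie-free and n_x * n_y <= 2000; otherwise a normal
    approximation with tie and continuity corrections is used. ``mode`` can
    force ``"exact"`` or ``"asymptotic"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:n].sum()
    u_x = r_x - n * (n + 1) / 2.0  # pairs where x beats y (ties half)
    has_ties = len(np.unique(pooled)) < n + m
    if mode not in {"auto", "exact", "asymptotic"}:
        raise ValueError("mode must be auto, exact or asymptotic")
    use_exact = mode == "exact" or (mode == "auto" and not has_ties and n * m <= 2000)
    if use_exact and has_ties:
        raise ValueError("exact Mann-Whitney p is only defined without ties")
    if use_exact:
        counts = _exact_u_counts(n, m)
        total = counts.sum()
        u = int(round(u_x))
        lo = counts[: u + 1].sum() / total
        hi = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(lo, hi))
        method = "mann-whitney (exact)"
    else:
        mu = n * m / 2.0
        nt = n + m
        tie = _tie_term(pooled)
        var = n * m / 12.0 * ((nt + 1) - tie / (nt * (nt - 1)))
        if var <= 0:
            return TestResult("mann-whitney (asymptotic)", u_x, 1.0, group_sizes=(n, m))
        z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * sps.norm.sf(z))
        method = "mann-whitney (asymptotic)"
    return TestResult(method, float(u_x), float(p), group_sizes=(n, m))


def levene_brown_forsythe(groups, zero_removal: bool = True,
                          correction: bool = True) -> TestResult:
    """Brown-Forsythe Levene-type test of equal spread (deviations from medians).

    One-way ANOVA F on d_ij = |x_ij - median_j|. Options mirror the robust
    variant used for unbalanced morphometric samples:

    * ``zero_removal`` — structural zero removal: the median of an odd-sized
      group is one of its points, so one deviation is structurally zero;
      that single zero is removed per odd-sized group.
    * ``correction`` — O'Brien's small-sample correction factor
      sqrt(n_j / (n_j - 1)) multiplying each group's deviations (n_j is the
      group size entering the ANOVA).

    Both default on, matching the combined robust procedure; disabling both
    gives the plain Brown-Forsythe test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    devs = []
    for g in groups:
        d = np.abs(g - np.median(g))
        if zero_removal and len(g) % 2 == 1:
            zero_at = int(np.argmin(d))  # the structural zero (exact for odd n)
            d = np.delete(d, zero_at)
        if correction:
            nj = len(d)
            if nj < 2:
                raise ValueError("zero removal left a group with < 2 deviations")
            d = d * math.sqrt(nj / (nj - 1.0))
        devs.append(d)
    k = len(devs)
    ns = np.array([len(d) for d in devs])
    total_n = int(ns.sum())
    grand = np.concatenate(devs).mean()
    means = np.array([d.mean() for d in devs])
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((d - mu) ** 2).sum() for d, mu in zip(devs, means)))
    df1, df2 = k - 1, total_n - k
    if ssw <= 0 and ssb <= 0:
        return TestResult("levene (brown-forsythe)", 0.0, 1.0, df=(df1, df2),
                          group_sizes=tuple(len(g) for g in groups))
    if ssw <= 0:
        return TestResult("levene (brown-forsythe)", math.inf, 0.0, df=(df1, df2),
                          group_sizes=tuple(len(g) for g in groups))
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("levene (brown-forsythe)", float(f), p, df=(df1, df2),
                      group_sizes=tuple(len(g) for g in groups))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with midrank tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = sps.rankdata(pooled)
    k = len(groups)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n_total + 1) / 2.0) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    tie = _tie_term(pooled)
    denom = 1.0 - tie / (n_total ** 3 - n_total)
    if denom <= 0:  # every observation identical
        return TestResult("kruskal-wallis", 0.0, 1.0, df=k - 1,
                          group_sizes=tuple(len(g) for g in groups))
    h /= denom
    p = float(sps.chi2.sf(h, k - 1))
    return TestResult("kruskal-wallis", float(h), p, df=k - 1,
                      group_sizes=tuple(len(g) for g in groups))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def dunn_posthoc(groups, labels=None, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z tests on pooled midranks with BH correction.

    Returns a tidy frame with one row per group pair: z, raw p, adjusted p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group in Dunn post-hoc")
    if labels is None:
        labels = [str(i) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    tie = _tie_term(pooled)
    base_var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        rows.append({"group1": labels[i], "group2": labels[j], "z": z, "pvalue": p})
    table = pd.DataFrame(rows)
    if adjust == "bh":
        table["p_adjusted"] = bh_adjust(table["pvalue"].to_numpy())
    elif adjust in (None, "none"):
        table["p_adjusted"] = table["pvalue"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


# ---------------------------------------------------------------------------
# distance-matrix machinery

@dataclass
class DistanceMatrix:
    data: np.ndarray
    ids: list

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(d)).max(initial=0.0) > 1e-12 or (d < -1e-12).any():
            raise ValueError("distances must be nonnegative with zero diagonal")
        self.data = d
        self.ids = list(self.ids)
        if len(self.ids) != d.shape[0]:
            raise ValueError("ids length must match matrix size")

    def __len__(self) -> int:
        return self.data.shape[0]

    def submatrix(self, index) -> "DistanceMatrix":
        index = np.asarray(index)
        return DistanceMatrix(self.data[np.ix_(index, index)], [self.ids[i] for i in index])


def euclidean_distance_matrix(rows, ids=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between complete observation vectors.

    Rows containing missing values are dropped entirely (complete-case),
    with a log record — pairwise deletion would break the metric.
    """
    x = np.asarray(rows, dtype=float)
    if x.ndim != 2:
        raise ValueError("rows must form a 2-D array")
    if ids is None:
        ids = list(range(len(x)))
    complete = ~np.isnan(x).any(axis=1)
    if not complete.all():
        dropped = [ids[i] for i in np.where(~complete)[0]]
        log.info("dropping %d incomplete rows from the distance matrix: %s",
                 len(dropped), dropped)
    x = x[complete]
    kept = [ids[i] for i in np.where(complete)[0]]
    if len(x) < 2:
        raise ValueError("fewer than 2 complete rows; distance matrix undefined")
    return DistanceMatrix(squareform(pdist(x, metric="euclidean")), kept)


def _group_codes(groups):
    groups = np.asarray(groups)
    uniq, codes = np.unique(groups, return_inverse=True)
    counts = np.bincount(codes)
    if (counts == 0).any():
        raise ValueError("every group must be nonempty")
    return uniq, codes, counts


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from squared distances (Gower decomposition)."""
    n = len(codes)
    k = len(counts)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        idx = np.where(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * counts[g])
    ss_among = ss_total - ss_within
    if ss_within <= 1e-30:
        return math.inf if ss_among > 1e-30 else math.nan
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def _n_arrangements(counts) -> float:
    total = math.factorial(int(sum(counts)))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def _distinct_assignments(counts):
    """Yield every distinct assignment of group codes to n positions."""
    n = int(sum(counts))
    positions = set(range(n))

    def rec(remaining, g):
        if g == len(counts) - 1:
            out = np.empty(n, dtype=int)
            for gg, idxs in enumerate(assigned):
                out[list(idxs)] = gg
            out[sorted(remaining)] = g
            yield out
            return
        for combo in itertools.combinations(sorted(remaining), int(counts[g])):
            assigned.append(combo)
            yield from rec(remaining - set(combo), g + 1)
            assigned.pop()

    assigned: list = []
    yield from rec(positions, 0)


def permanova(dist: DistanceMatrix, groups, n_perm: int = DEFAULT_N_PERM,
              seed: int = 0) -> TestResult:
    """One-way PERMANOVA: pseudo-F on a distance matrix, p by label permutation.

    SS terms follow the Gower-centred decomposition (total from all squared
    distances over n, within from within-group squared distances over group
    sizes). When the number of distinct label arrangements is at most
    10,000 the permutation null is enumerated exactly (p = as-extreme
    fraction, identity included); otherwise ``n_perm`` seeded shuffles give
    ``p = (b + 1) / (n_perm + 1)``.
    """
    uniq, codes, counts = _group_codes(groups)
    if len(codes) != len(dist):
        raise ValueError("group labels must match the distance matrix")
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    d2 = dist.data ** 2
    if d2.max() <= 0:
        raise DegenerateDataError("constant (zero) distance matrix: pseudo-F undefined")
    f_obs = _pseudo_f(d2, codes, counts)
    if math.isnan(f_obs):
        raise DegenerateDataError("no variation within or among groups: pseudo-F undefined")
    total = _n_arrangements(counts)
    eps = 1e-12 * max(1.0, abs(f_obs) if math.isfinite(f_obs) else 1.0)
    if total <= _EXACT_ENUM_LIMIT:
        hits = 0
        for assign in _distinct_assignments(counts):
            f = _pseudo_f(d2, assign, counts)
            if (math.isinf(f) and math.isinf(f_obs)) or f >= f_obs - eps:
                hits += 1
        p = hits / total
        n_used, method = int(total), "permanova (exact enumeration)"
    else:
        rng = np.random.default_rng(seed)
        b = 0
        perm = codes.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            f = _pseudo_f(d2, perm, counts)
            if (math.isinf(f) and math.isinf(f_obs)) or f >= f_obs - eps:
                b += 1
        p = (b + 1) / (n_perm + 1)
        n_used, method = n_perm, "permanova"
    return TestResult(method, float(f_obs), float(p),
                      df=(len(uniq) - 1, len(codes) - len(uniq)),
                      n_perm=n_used, seed=seed, group_sizes=tuple(int(c) for c in counts))


@dataclass
class DispersionResult:
    """Multivariate dispersion: distance of each observation to its group
    centroid in the principal-coordinates embedding of the distance matrix."""

    distances: np.ndarray
    groups: np.ndarray
    ids: list
    eigenvalues: np.ndarray
    group_means: dict

    def group_arrays(self):
        uniq = list(self.group_means)
        return uniq, [self.distances[self.groups == g] for g in uniq]


def betadisper(dist: DistanceMatrix, groups) -> DispersionResult:
    """Distances to group centroids in principal coordinates.

    The Gower-centred matrix is eigen-decomposed; axes with negative
    eigenvalues (non-Euclidean distances) are kept as imaginary axes and
    their contribution is subtracted: d^2 = d^2_real - d^2_imag, clipped at
    zero. On a plainly Euclidean matrix this reduces to distances to the
    ordinary group mean.
    """
    groups = np.asarray(groups)
    if len(groups) != len(dist):
        raise ValueError("group labels must match the distance matrix")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    n = len(dist)
    a = -0.5 * dist.data ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh(g)
    tol = 1e-8 * max(np.abs(evals).max(), 1.0)
    keep = np.abs(evals) > tol
    lam = evals[keep]
    coords = evecs[:, keep] * np.sqrt(np.abs(lam))
    pos = lam > 0
    d2 = np.zeros(n)
    group_means = {}
    for grp in uniq:
        mask = groups == grp
        if mask.sum() == 1:
            log.warning("group %r has a single member; its dispersion is 0", grp)
        centroid = coords[mask].mean(axis=0)
        delta2 = (coords[mask] - centroid) ** 2
        d2[mask] = delta2[:, pos].sum(axis=1) - delta2[:, ~pos].sum(axis=1)
    d2 = np.clip(d2, 0.0, None)
    distances = np.sqrt(d2)
    for grp in uniq:
        group_means[grp] = float(distances[groups == grp].mean())
    return DispersionResult(distances=distances, groups=groups, ids=list(dist.ids),
                            eigenvalues=evals, group_means=group_means)


def _anova_f(values: np.ndarray, codes: np.ndarray, counts: np.ndarray):
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(len(counts)):
        v = values[codes == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    df1, df2 = len(counts) - 1, len(values) - len(counts)
    if ssw <= 1e-30:
        return (math.inf if ssb > 1e-30 else math.nan), df1, df2
    return (ssb / df1) / (ssw / df2), df1, df2


def permutest_dispersion(disp: DispersionResult, n_perm: int = DEFAULT_N_PERM,
                         seed: int = 0) -> TestResult:
    """Permutation F test for homogeneity of multivariate dispersions.

    The one-way ANOVA F on distances-to-centroid is recomputed under random
    relabelling of the observations.
    """
    uniq, codes, counts = _group_codes(disp.groups)
    f_obs, df1, df2 = _anova_f(disp.distances, codes, counts)
    if math.isnan(f_obs):
        log.warning("all dispersions identical; permutation test degenerate, p = 1")
        return TestResult("permutest (dispersion)", 0.0, 1.0, df=(df1, df2),
                          n_perm=n_perm, seed=seed, group_sizes=tuple(int(c) for c in counts))
    rng = np.random.default_rng(seed)
    b = 0
    perm = codes.copy()
    eps = 1e-12 * max(1.0, abs(f_obs) if math.isfinite(f_obs) else 1.0)
    for _ in range(n_perm):
        rng.shuffle(perm)
        f, _, _ = _anova_f(disp.distances, perm, counts)
        if (math.isinf(f) and math.isinf(f_obs)) or f >= f_obs - eps:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return TestResult("permutest (dispersion)", float(f_obs), float(p), df=(df1, df2),
                      n_perm=n_perm, seed=seed, group_sizes=tuple(int(c) for c in counts))


def tukey_hsd_dispersion(disp: DispersionResult) -> pd.DataFrame:
    """Tukey HSD on the distances-to-centroid (studentized-range intervals)."""
    labels, arrays = disp.group_arrays()
    if any(len(a) < 2 for a in arrays):
        raise ValueError("Tukey HSD needs >= 2 observations per group")
    res = sps.tukey_hsd(*arrays)
    ci = res.confidence_interval()
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        rows.append({"group1": labels[i], "group2": labels[j],
                     "diff": float(np.mean(arrays[i]) - np.mean(arrays[j])),
                     "pvalue": float(res.pvalue[i, j]),
                     "ci_low": float(ci.low[i, j]), "ci_high": float(ci.high[i, j])})
    return pd.DataFrame(rows)


def pairwise_permanova(dist: DistanceMatrix, groups, n_perm: int = DEFAULT_N_PERM,
                       seed: int = 0, adjust: str = "bh") -> pd.DataFrame:
    """PERMANOVA on every pair of groups, BH-adjusted across pairs."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 3:
        raise ValueError("pairwise PERMANOVA needs >= 3 groups (use permanova for 2)")
    rows = []
    for a, b in itertools.combinations(uniq, 2):
        idx = np.where((groups == a) | (groups == b))[0]
        sub = dist.submatrix(idx)
        res = permanova(sub, groups[idx], n_perm=n_perm, seed=seed)
        rows.append({"group1": a, "group2": b, "pseudo_F": res.statistic,
                     "pvalue": res.pvalue, "n_perm": res.n_perm})
    table = pd.DataFrame(rows)
    if adjust == "bh":
        table["p_adjusted"] = bh_adjust(table["pvalue"].to_numpy())
    elif adjust in (None, "none"):
        table["p_adjusted"] = table["pvalue"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table
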