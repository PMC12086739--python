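"""One-way PERMANOVA on Euclidean distances between per-sample metrics.

Distance-based sums of squares (for N points in ``a`` groups):

    SS_total  = (1/N) Σ_{i<j} d²ᵢⱼ
    SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²ᵢⱼ
    SS_among  = SS_total − SS_within
    pseudo-F  = (SS_among / (a−1)) / (SS_within / (N−a))

The permutation p-value uses add-one smoothing,
p = (1 + #{permuted F ≥ observed F}) / (1 + m), so p > 0 always and the
observed labelling enters only through the +1 terms.  ``exact=True``
enumerates every distinct labelling of the group-size multiset instead
(feasible for N ≲ 10) and reports the exact proportion with F ≥ F_obs.

Degenerate conventions: if all points coincide (SS_total = 0) the result
is p = 1 with F = 0; if the groups separate perfectly (SS_within = 0)
F is +inf and the p-value still comes from the permutation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import ValidationError


@dataclass(frozen=True)
class PermanovaResult:
    f_stat: float
    p_value: float
    n_permutations: int
    group_sizes: tuple[int, ...]
    ss_total: float
    ss_among: float
    ss_within: float
    seed: int | None
    exact: bool = False


def euclidean_distances(points: np.ndarray) -> np.ndarray:
    """Symmetric N × N Euclidean distance matrix for N × d points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2:
        raise ValidationError("points must be an N x d matrix")
    if not np.isfinite(pts).all():
        raise ValidationError("points contain non-finite values")
    return squareform(pdist(pts, metric="euclidean"))


def _sums_of_squares(d2: np.ndarray, codes: np.ndarray, n_groups: int
                     ) -> tuple[float, float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)  # full matrix counts each pair twice
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        if ng > 1:
            ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return ss_total, ss_total - ss_within, ss_within


def _pseudo_f(ss_among: float, ss_within: float, n: int, a: int) -> float:
    num = ss_among / (a - 1)
    if ss_within <= 0:
        return np.inf if num > 0 else 0.0
    return num / (ss_within / (n - a))


def permanova_oneway(
    dist: np.ndarray,
    groups,
    n_permutations: int = 9999,
    seed: int | None = 0,
    exact: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against group labels."""
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(list(groups))
    n = d.shape[0]
    if d.shape != (n, n) or len(labels) != n:
        raise ValidationError("distance matrix and labels have inconsistent shapes")
    if n < 3:
        raise ValidationError("need at least 3 observations")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("need at least 2 groups")
    group_sizes = tuple(int((codes == g).sum()) for g in range(a))
    d2 = d ** 2

    ss_total, ss_among, ss_within = _sums_of_squares(d2, codes, a)
    if ss_total <= 1e-300:
        return PermanovaResult(0.0, 1.0, 0, group_sizes, ss_total, ss_among, ss_within,
                               seed, exact)
    f_obs = _pseudo_f(ss_among, ss_within, n, a)

    if exact:
        from sympy.utilities.iterables import multiset_permutations

        count_ge = 0
        total = 0
        for perm in multiset_permutations(list(codes)):
            _, ssa, ssw = _sums_of_squares(d2, np.asarray(perm), a)
            if _pseudo_f(ssa, ssw, n, a) >= f_obs - 1e-12:
                count_ge += 1
            total += 1
        return PermanovaResult(float(f_obs), count_ge / total, total, group_sizes,
                               ss_total, ss_among, ss_within, seed, True)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm_codes = rng.permutation(codes)
        _, ssa, ssw = _sums_of_squares(d2, perm_codes, a)
        if _pseudo_f(ssa, ssw, n, a) >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), p, n_permutations, group_sizes,
                           ss_total, ss_among, ss_within, seed, False)


def permanova_metric(
    summary, metric: str, group_col: str = "supply_class",
    n_permutations: int = 9999, seed: int | None = 0,
    log_transform: bool = False, epsilon: float = 1e-9,
) -> PermanovaResult:
    """PERMANOVA on a single per-sample metric column (1-D Euclidean).

    ``log_transform`` applies log10(x + epsilon) first, offered because
    heavily right-skewed cumulative quotients can dominate raw-scale
    distances; the default is raw values.
    """
    vals = summary[metric].to_numpy(dtype=float)
    if log_transform:
        vals = np.log10(vals + epsilon)
    dist = euclidean_distances(vals[:, None])
    return permanova_oneway(dist, summary[group_col].to_numpy(), n_permutations, seed)
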