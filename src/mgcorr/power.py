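"""Monte-Carlo power estimation and required-sample-size search.

Power is estimated against a simulated relationship by drawing ``r`` dataset
pairs under the alternative (the relationship itself) and ``r`` under the
null (X and Y drawn independently from their marginals, obtained by pairing
the X of one draw with the Y of another), computing the test statistic on
each, taking the empirical ``1 - alpha`` quantile of the null statistics as
the critical value, and reporting the fraction of alternative statistics
that exceed it. This null-sampling scheme is far cheaper than running a
permutation test per replicate and estimates the same power.

The sample-size search scans an increasing grid of ``n`` and reports the
smallest grid value whose estimated power reaches the target. Ratio tables
normalize each method's required ``n`` by MGC's, so a ratio of 2 means the
method needs twice the data MGC needs for the same power.

Comparison statistics: Dcorr (double centering), Mcorr (U-centering), Mantel,
Hsic (Gaussian kernel, median-heuristic bandwidth, Dcorr-style centering of
the kernel matrices), and the absolute Pearson correlation (scalar data only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import center_distance_matrix, pairwise_distances, rank_matrix
from .localcorr import global_correlation
from .simulations import (
    NONMONOTONE_TYPES,
    SimulationSpec,
    sample_relationship,
    y_dimension,
)
from .statistic import mgc_statistic

__all__ = [
    "PowerEstimate",
    "SampleSizeResult",
    "METHODS",
    "estimate_power",
    "estimate_power_multi",
    "permutation_rejection_rate",
    "required_sample_size",
    "joint_required_sample_sizes",
    "median_sample_size_ratios",
    "relative_power_table",
]

METHODS = ("mgc", "dcorr", "mcorr", "mantel", "hsic", "pearson")

DEFAULT_GRID = tuple(range(10, 201, 10))


@dataclass
class PowerEstimate:
    method: str
    spec: SimulationSpec
    alpha: float
    r: int
    power: float
    critical_value: float


@dataclass
class SampleSizeResult:
    method: str
    type_id: int
    p: int
    kappa: float | None
    target_power: float
    alpha: float
    n_star: int | None  # smallest grid n reaching target power; None = beyond grid
    ratio_to_mgc: float | None = None

    @property
    def exceeded_grid(self) -> bool:
        return self.n_star is None


# ---------------------------------------------------------------------------
# test statistics on a shared dataset
# ---------------------------------------------------------------------------

def _hsic_stat(Dx, Dy) -> float:
    Ks = []
    for D in (Dx, Dy):
        off = D[~np.eye(D.shape[0], dtype=bool)]
        sigma = np.median(off) if off.size else 0.0
        if sigma <= 0:
            return 0.0
        Ks.append(np.exp(-(D**2) / (2 * sigma**2)))
    Kx, Ky = Ks
    row = Kx.mean(axis=1, keepdims=True)
    A = Kx - row - Kx.mean(axis=0, keepdims=True) + Kx.mean()
    row = Ky.mean(axis=1, keepdims=True)
    B = Ky - row - Ky.mean(axis=0, keepdims=True) + Ky.mean()
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(B, 0.0)
    return global_correlation(A, B)


def _mgc_stat(Dx, Dy) -> float:
    # operative MGC default: X centered by column, Y by row
    A = center_distance_matrix(Dx, "single_column")
    B = center_distance_matrix(Dy, "single_row")
    ra = rank_matrix(Dx, axis="column")
    rb = rank_matrix(Dy, axis="row")
    c_star, _, _, _ = mgc_statistic(A, B, ra, rb)
    return c_star


def compute_statistic(method: str, X, Y, Dx=None, Dy=None) -> float:
    """Evaluate one test statistic on a paired sample.

    Distance matrices may be passed to avoid recomputation when several
    methods share a dataset.
    """
    if method == "pearson":
        X = np.asarray(X).reshape(len(X), -1)
        Y = np.asarray(Y).reshape(len(Y), -1)
        if X.shape[1] != 1 or Y.shape[1] != 1:
            raise ValueError("the Pearson comparison statistic is defined for scalar X and Y only")
        r = np.corrcoef(X[:, 0], Y[:, 0])[0, 1]
        return float(abs(r)) if np.isfinite(r) else 0.0
    if Dx is None:
        Dx = pairwise_distances(X)
    if Dy is None:
        Dy = pairwise_distances(Y)
    if method == "mgc":
        return _mgc_stat(Dx, Dy)
    if method == "hsic":
        return _hsic_stat(Dx, Dy)
    scheme = {"dcorr": "double", "mcorr": "unbiased", "mantel": "mantel"}.get(method)
    if scheme is None:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    A = center_distance_matrix(Dx, scheme)
    B = center_distance_matrix(Dy, scheme)
    return global_correlation(A, B)


# ---------------------------------------------------------------------------
# power estimation
# ---------------------------------------------------------------------------

def _needs_distances(methods) -> bool:
    return any(m != "pearson" for m in methods)


def estimate_power_multi(methods, spec: SimulationSpec, alpha: float = 0.05,
                         r: int = 1000, seed=None) -> dict:
    """Estimate power for several methods on shared Monte-Carlo datasets.

    Returns ``{method: PowerEstimate}``. Sharing the simulated datasets (and
    their distance matrices) across methods removes simulation noise from
    method comparisons and amortizes the dominant cost.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if r < 1:
        raise ValueError("number of Monte-Carlo replicates must be >= 1")
    methods = list(methods)
    rng = np.random.default_rng(seed)
    null_stats = {m: np.empty(r) for m in methods}
    alt_stats = {m: np.empty(r) for m in methods}
    use_dist = _needs_distances(methods)
    for t in range(r):
        alt = sample_relationship(spec, rng)
        indep = sample_relationship(spec, rng)  # its Y is independent of alt.X
        Dx = pairwise_distances(alt.X) if use_dist else None
        for stats, Y in ((alt_stats, alt.Y), (null_stats, indep.Y)):
            Dy = pairwise_distances(Y) if use_dist else None
            for m in methods:
                stats[m][t] = compute_statistic(m, alt.X, Y, Dx, Dy)
    out = {}
    for m in methods:
        crit = float(np.quantile(null_stats[m], 1 - alpha))
        power = float(np.mean(alt_stats[m] > crit))
        out[m] = PowerEstimate(method=m, spec=spec, alpha=alpha, r=r,
                               power=power, critical_value=crit)
    return out


def estimate_power(method: str, spec: SimulationSpec, alpha: float = 0.05,
                   r: int = 1000, seed=None) -> PowerEstimate:
    """Monte-Carlo power of one test against one simulated relationship."""
    if r < 100:
        raise ValueError("use at least 100 Monte-Carlo replicates for a stable power estimate")
    return estimate_power_multi([method], spec, alpha=alpha, r=r, seed=seed)[method]


def permutation_rejection_rate(spec: SimulationSpec, alpha: float = 0.05,
                               n_datasets: int = 500, n_permutations: int = 200,
                               seed=None, scheme: str = "unbiased") -> float:
    """Fraction of simulated datasets on which the MGC permutation test rejects.

    Runs the full permutation test (not null-distribution sampling) on each of
    ``n_datasets`` independent draws; under the independence relationship this
    estimates the empirical size of the test.
    """
    from .statistic import permutation_test

    ss = np.random.SeedSequence([0 if seed is None else int(seed), 1])
    seeds = ss.generate_state(2 * n_datasets) % (2**31)
    rejections = 0
    for i in range(n_datasets):
        pair = sample_relationship(spec, np.random.default_rng(int(seeds[2 * i])))
        Dx = pairwise_distances(pair.X)
        Dy = pairwise_distances(pair.Y)
        p = permutation_test(Dx, Dy, n_permutations, seed=int(seeds[2 * i + 1]), scheme=scheme)
        rejections += p <= alpha
    return rejections / n_datasets


# ---------------------------------------------------------------------------
# required sample size
# ---------------------------------------------------------------------------

def joint_required_sample_sizes(methods, type_id: int, p: int = 1, kappa=None,
                                target_power: float = 0.85, alpha: float = 0.05,
                                grid=DEFAULT_GRID, r: int = 500, seed=None) -> dict:
    """Smallest grid ``n`` reaching target power, for several methods at once.

    Scans ``grid`` upward; at each ``n`` the same ``r`` null and alternative
    datasets are used for every still-unresolved method, and a method is
    resolved at the first ``n`` whose estimated power meets the target.
    Returns ``{method: n or None}``.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty sample-size grid")
    if sorted(grid) != grid:
        raise ValueError("sample-size grid must be increasing")
    unresolved = list(methods)
    n_star = {m: None for m in methods}
    base = 0 if seed is None else int(seed)
    for n in grid:
        if not unresolved:
            break
        spec = SimulationSpec(type_id=type_id, n=n, p=p, kappa=kappa)
        sub_seed = int(np.random.SeedSequence([base, type_id, p, n]).generate_state(1)[0] % (2**31))
        powers = estimate_power_multi(unresolved, spec, alpha=alpha, r=r, seed=sub_seed)
        for m in list(unresolved):
            if powers[m].power >= target_power:
                n_star[m] = n
                unresolved.remove(m)
    return n_star


def required_sample_size(method: str, type_id: int, p: int = 1, kappa=None,
                         target_power: float = 0.85, alpha: float = 0.05,
                         grid=DEFAULT_GRID, r: int = 500, seed=None) -> SampleSizeResult:
    """Required sample size for one method, with its ratio to MGC's.

    MGC's own required ``n`` is computed on the same datasets so the ratio is
    comparable; for ``method="mgc"`` the ratio is 1 by definition.
    """
    methods = [method] if method == "mgc" else [method, "mgc"]
    n_star = joint_required_sample_sizes(methods, type_id, p=p, kappa=kappa,
                                         target_power=target_power, alpha=alpha,
                                         grid=grid, r=r, seed=seed)
    ratio = None
    if method == "mgc":
        ratio = 1.0 if n_star["mgc"] is not None else None
    elif n_star["mgc"] is not None:
        ratio = np.inf if n_star[method] is None else n_star[method] / n_star["mgc"]
    return SampleSizeResult(method=method, type_id=type_id, p=p, kappa=kappa,
                            target_power=target_power, alpha=alpha,
                            n_star=n_star[method], ratio_to_mgc=ratio)


def median_sample_size_ratios(methods, type_groups: dict, dims=(1,),
                              target_power: float = 0.85, alpha: float = 0.05,
                              grid=DEFAULT_GRID, r: int = 500, seed=None,
                              kappa_rule=None) -> dict:
    """Median required-sample-size ratios, per method x type-group x dimension.

    ``type_groups`` maps a group label to an iterable of relationship ids
    (e.g. monotone 1-5 vs non-monotone 6-19). For each relationship the
    required ``n`` of every method and of MGC is found on shared datasets;
    the table entry is the median over the group of ``n*(method)/n*(mgc)``.
    Relationships where MGC itself never reaches the target on the grid are
    excluded (the ratio is undefined); a method that never reaches it where
    MGC does contributes ``inf``, mirroring the ">grid" convention.

    ``kappa_rule(p)`` may override the default noise convention (1 for p=1,
    0 otherwise). Returns ``{(method, group, p): median_ratio}``.
    """
    methods = list(methods)
    all_methods = methods if "mgc" in methods else methods + ["mgc"]
    table = {}
    per_type = {}
    for group, types in type_groups.items():
        for p in dims:
            ratios = {m: [] for m in methods}
            for type_id in types:
                kappa = kappa_rule(p) if kappa_rule is not None else None
                use = [m for m in all_methods
                       if not (m == "pearson" and max(p, y_dimension(type_id, p)) > 1)]
                n_star = joint_required_sample_sizes(
                    use, type_id, p=p, kappa=kappa, target_power=target_power,
                    alpha=alpha, grid=grid, r=r, seed=seed)
                per_type[(group, p, type_id)] = dict(n_star)
                if n_star.get("mgc") is None:
                    continue
                for m in methods:
                    if m not in use:
                        continue
                    ratio = 1.0 if m == "mgc" else (
                        np.inf if n_star[m] is None else n_star[m] / n_star["mgc"])
                    ratios[m].append(ratio)
            for m in methods:
                table[(m, group, p)] = float(np.median(ratios[m])) if ratios[m] else np.nan
    table["per_type"] = per_type
    return table


def relative_power_table(methods, type_id: int, dims, n: int = 100,
                         alpha: float = 0.05, r: int = 500, seed=None) -> dict:
    """Power of each method minus the power of MGC, per dimension.

    Uses the high-dimensional benchmark convention (noiseless, fixed ``n``)
    unless the dimension is 1. Returns ``{(method, p): power_difference}``.
    """
    methods = list(methods)
    all_methods = methods if "mgc" in methods else methods + ["mgc"]
    out = {}
    base = 0 if seed is None else int(seed)
    for p in dims:
        use = [m for m in all_methods
               if not (m == "pearson" and max(p, y_dimension(type_id, p)) > 1)]
        spec = SimulationSpec(type_id=type_id, n=n, p=p)
        sub_seed = int(np.random.SeedSequence([base, type_id, p]).generate_state(1)[0] % (2**31))
        powers = estimate_power_multi(use, spec, alpha=alpha, r=r, seed=sub_seed)
        for m in methods:
            if m in use:
                out[(m, p)] = powers[m].power - powers["mgc"].power
    return out
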