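"""Regional strain extraction and healthy-vs-injured statistical comparison.

Per-region maximum principal (in-plane Green-Lagrange) strains are sampled at
an odd number of area-weighted random elements with a fixed seed, and the two
scenarios are compared region by region with a classical one-way
fixed-effects ANOVA at a 5% significance level.  Elements adjacent to the
detached lesion nodes can be excluded, because the immediate neighbourhood
of a detachment carries a local strain artefact that is not representative
of the band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import CapsuleMesh
from .solver import StrainField

__all__ = [
    "RegionStrainSummary",
    "ComparisonResult",
    "region_strains",
    "one_way_anova",
    "exclusion_elements",
    "compare_scenarios",
]


@dataclass(frozen=True)
class RegionStrainSummary:
    region: str
    samples: np.ndarray
    mean: float
    max: float
    count: int
    fallback_all_elements: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


@dataclass(frozen=True)
class ComparisonResult:
    region: str
    f_statistic: float
    p_value: float
    group_means: tuple[float, float]
    degenerate_variance: bool = False
    observed_power: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.f_statistic < 0.0:
            raise ValueError("F statistic cannot be negative")


def region_strains(
    field: StrainField,
    region: str,
    n: int = 25,
    seed: int = 0,
    element_subset: np.ndarray | None = None,
) -> RegionStrainSummary:
    """Area-weighted random sample of element max-principal strains in a region.

    ``n`` must be odd (no tied duplicate sampling of a location); if the
    region has fewer than ``n`` elements all of them are used and the
    summary is flagged.  The mean/max reported are region-wide, not
    sample-only.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError("sample count n must be a positive odd number")
    idx = np.flatnonzero(field.region_of_element == region)
    if element_subset is not None:
        idx = np.intersect1d(idx, np.asarray(element_subset, dtype=np.int64))
    if len(idx) == 0:
        raise ValueError(f"region {region!r} has no (non-excluded) elements")
    strains = field.max_principal[idx]
    areas = field.element_areas[idx]
    fallback = len(idx) < n
    if fallback:
        samples = strains.copy()
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(idx), size=n, replace=False, p=areas / areas.sum())
        samples = strains[chosen]
    return RegionStrainSummary(
        region=region,
        samples=samples,
        mean=float(np.average(strains, weights=areas)),
        max=float(strains.max()),
        count=len(samples),
        fallback_all_elements=fallback,
    )


def one_way_anova(group_a, group_b, region: str = "") -> ComparisonResult:
    """Classical one-way fixed-effects ANOVA for two groups.

    F = (between-group SS / (k-1)) / (within-group SS / (N-k)) with k = 2;
    the p-value is the upper tail of the F(k-1, N-k) distribution.  Zero
    within-group variance with unequal means is flagged and reported as
    F = inf -> p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    N = len(a) + len(b)
    grand = (a.sum() + b.sum()) / N
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
    df_between, df_within = 1, N - 2
    degenerate = False
    if ss_within == 0.0:
        if ss_between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            degenerate = True
            f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))
    power = None
    if np.isfinite(f_stat) and ss_within > 0.0:
        power = _posthoc_power(f_stat, len(a), len(b))
    return ComparisonResult(
        region=region,
        f_statistic=float(f_stat),
        p_value=p,
        group_means=(float(a.mean()), float(b.mean())),
        degenerate_variance=degenerate,
        observed_power=power,
    )


def _posthoc_power(f_stat: float, na: int, nb: int) -> float | None:
    """Descriptive post-hoc power of the observed effect at alpha = 0.05."""
    try:
        from statsmodels.stats.power import FTestAnovaPower

        n = na + nb
        effect = np.sqrt(max(f_stat, 0.0) / n)
        return float(
            FTestAnovaPower().power(effect_size=effect, nobs=n, alpha=0.05, k_groups=2)
        )
    except Exception:
        return None


def exclusion_elements(
    mesh: CapsuleMesh, released_nodes: np.ndarray, hops: int = 2
) -> np.ndarray:
    """Elements sharing a node within ``hops`` edge-hops of released nodes."""
    released = np.asarray(released_nodes, dtype=np.int64)
    if len(released) == 0:
        return np.empty(0, dtype=np.int64)
    adjacency: dict[int, set[int]] = {}
    for tri in mesh.triangles:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            adjacency.setdefault(int(a), set()).add(int(b))
            adjacency.setdefault(int(b), set()).add(int(a))
    frontier = set(released.tolist())
    reached = set(frontier)
    for _ in range(hops):
        frontier = {m for n in frontier for m in adjacency.get(n, ())} - reached
        reached |= frontier
    mask = np.isin(mesh.triangles, list(reached)).any(axis=1)
    return np.flatnonzero(mask)


def compare_scenarios(
    healthy: list[StrainField],
    injured: list[StrainField],
    mesh: CapsuleMesh,
    regions: list[str] | None = None,
    n: int = 25,
    seed: int = 0,
    released_nodes: np.ndarray | None = None,
    exclusion_hops: int = 2,
) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Per-region ANOVA comparison of two solved runs at the final step.

    Both runs must come from the same mesh and schedule.  The same seeded,
    area-weighted element sample is evaluated in both strain fields.  When
    ``released_nodes`` is given, elements within ``exclusion_hops`` edge-hops
    of the detachment are excluded from sampling in both scenarios.
    """
    if len(healthy) == 0 or len(injured) == 0:
        raise ValueError("need at least one solved step per scenario")
    fh, fi = healthy[-1], injured[-1]
    if fh.max_principal.shape != fi.max_principal.shape or len(
        fh.max_principal
    ) != mesh.n_elements:
        raise ValueError("scenarios were not solved on the same mesh")
    if regions is None:
        regions = [r for r in mesh.regions()]
    subset = None
    if released_nodes is not None and len(released_nodes) > 0:
        excluded = exclusion_elements(mesh, released_nodes, hops=exclusion_hops)
        subset = np.setdiff1d(np.arange(mesh.n_elements), excluded)
    results = []
    rows = []
    for region in regions:
        sh = region_strains(fh, region, n=n, seed=seed, element_subset=subset)
        si = region_strains(fi, region, n=n, seed=seed, element_subset=subset)
        res = one_way_anova(sh.samples, si.samples, region=region)
        results.append(res)
        rows.append(
            {
                "region": region,
                "mean_healthy": sh.mean,
                "max_healthy": sh.max,
                "mean_injured": si.mean,
                "max_injured": si.max,
                "f_statistic": res.f_statistic,
                "p_value": res.p_value,
                "observed_power": res.observed_power,
            }
        )
    return results, pd.DataFrame(rows)
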