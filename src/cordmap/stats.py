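"""Two-sample positional and count statistics.

The positional comparison is a two-sample Hotelling T² on pooled
normalized cell coordinates:

    T² = (n1·n2 / (n1+n2)) · dᵀ S⁻¹ d

with d the mean-difference vector and S the pooled sample covariance
(divisor n1+n2−2).  The parametric p-value uses the exact F transform
F = T²·(n1+n2−p−1) / ((n1+n2−2)·p) with df (p, n1+n2−p−1); a
large-sample χ²(p) approximation and a label-permutation variant are
also provided.  Per-axis annotation runs independent pooled-variance
t-tests on each projected axis and maps p-values to star strings, as a
descriptive companion to the multivariate p.

The count workflow averages counts per hemi-section within each animal
and compares the per-animal means between genotypes with an unpaired
pooled-variance Student t-test (one- or two-tailed as declared).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import PooledSample
from .synthetic import CohortConfig, pooled_points

__all__ = [
    "HotellingResult",
    "AxisFlag",
    "CountResult",
    "SingularCovarianceError",
    "hotelling_t2",
    "permutation_hotelling",
    "axis_annotation",
    "count_analysis",
    "calibration_sim",
    "star_string",
    "DEFAULT_STAR_LEVELS",
    "AXIS_NAMES",
]

#: default star map; legends elsewhere sometimes use p < 0.005 for "**",
#: so the thresholds are overridable everywhere they are consumed
DEFAULT_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

AXIS_NAMES = ("ML_x", "DV_y")

_COND_LIMIT = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is numerically singular.

    The parametric test is unavailable; use
    :func:`permutation_hotelling`, which falls back to a mean-distance
    statistic in this case.
    """


@dataclass(frozen=True)
class AxisFlag:
    """Descriptive per-axis significance annotation."""

    axis: str
    t_stat: float
    p_value: float
    stars: str


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    mean_diff: tuple[float, ...]
    n1: int
    n2: int
    method: str = "f"
    axis_flags: tuple[AxisFlag, ...] = ()


@dataclass(frozen=True)
class CountResult:
    per_animal_means: dict[str, dict[str, float]]
    group_means: dict[str, float]
    group_sems: dict[str, float]
    n_animals: dict[str, int]
    t_stat: float
    df: int
    p_value: float
    tails: str


def star_string(
    p: float, levels: Sequence[tuple[float, str]] = DEFAULT_STAR_LEVELS
) -> str:
    """Map a p-value to a star annotation given (threshold, label) pairs."""
    for threshold, stars in sorted(levels):
        if p < threshold:
            return stars
    return ""


def _as_points(sample) -> np.ndarray:
    if isinstance(sample, PooledSample):
        pts = sample.points
    else:
        pts = np.asarray(sample, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2:
        raise ValueError(f"sample must be an (n, p) array, got shape {pts.shape}")
    return pts


def _pooled_cov(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    n1, n2 = len(x1), len(x2)
    s1 = np.cov(x1, rowvar=False, ddof=1).reshape(x1.shape[1], -1)
    s2 = np.cov(x2, rowvar=False, ddof=1).reshape(x2.shape[1], -1)
    return ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)


def _t2_stat(x1: np.ndarray, x2: np.ndarray, max_condition: float) -> float:
    n1, n2 = len(x1), len(x2)
    d = x1.mean(axis=0) - x2.mean(axis=0)
    s = _pooled_cov(x1, x2)
    if not np.all(np.isfinite(s)) or np.linalg.cond(s) > max_condition:
        raise SingularCovarianceError(
            "pooled covariance is singular or ill-conditioned; "
            "use permutation_hotelling instead"
        )
    return float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s, d))


def hotelling_t2(
    sample1,
    sample2,
    method: str = "f",
    max_condition: float = _COND_LIMIT,
    star_levels: Sequence[tuple[float, str]] = DEFAULT_STAR_LEVELS,
    annotate_axes: bool = True,
) -> HotellingResult:
    """Two-sample Hotelling T² comparing mean position vectors.

    Parameters
    ----------
    sample1, sample2
        :class:`~cordmap.geometry.PooledSample` or ``(n, p)`` arrays.
    method
        ``"f"`` for the exact F transform (default) or ``"chi2"`` for
        the large-sample χ²(p) approximation.
    max_condition
        Condition-number threshold above which the pooled covariance is
        declared singular.

    Raises
    ------
    SingularCovarianceError
        If the pooled covariance is singular; use the permutation test.
    ValueError
        If sample sizes are insufficient (n1, n2 ≥ 2 and
        n1 + n2 ≥ p + 2 required).
    """
    x1, x2 = _as_points(sample1), _as_points(sample2)
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("samples must share dimensionality")
    p = x1.shape[1]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need n1, n2 >= 2, got {n1}, {n2}")
    if n1 + n2 < p + 2:
        raise ValueError(f"need n1 + n2 >= p + 2 = {p + 2}, got {n1 + n2}")
    if method not in ("f", "chi2"):
        raise ValueError(f"method must be 'f' or 'chi2', got {method!r}")
    t2 = _t2_stat(x1, x2, max_condition)
    df1 = p
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    if method == "f":
        p_value = float(sps.f.sf(f_stat, df1, df2))
    else:
        p_value = float(sps.chi2.sf(t2, p))
    d = x1.mean(axis=0) - x2.mean(axis=0)
    flags: tuple[AxisFlag, ...] = ()
    if annotate_axes:
        flags = tuple(axis_annotation(x1, x2, star_levels=star_levels))
    return HotellingResult(
        t2=t2,
        f_stat=float(f_stat),
        df1=df1,
        df2=df2,
        p_value=p_value,
        mean_diff=tuple(float(v) for v in d),
        n1=n1,
        n2=n2,
        method=method,
        axis_flags=flags,
    )


def permutation_hotelling(
    sample1,
    sample2,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    max_condition: float = _COND_LIMIT,
) -> float:
    """Label-permutation p-value for the mean-position difference.

    Uses the T² kernel when the pooled covariance is well conditioned,
    otherwise the squared Euclidean distance between means.  The
    add-one estimator p = (1 + #{T²_perm ≥ T²_obs}) / (1 + n_perm)
    avoids p = 0.
    """
    if n_perm < 99:
        raise ValueError(f"need n_perm >= 99, got {n_perm}")
    x1, x2 = _as_points(sample1), _as_points(sample2)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need n1, n2 >= 2, got {n1}, {n2}")
    pooled = np.vstack([x1, x2])
    try:
        def stat(a: np.ndarray, b: np.ndarray) -> float:
            return _t2_stat(a, b, max_condition)

        observed = stat(x1, x2)
    except SingularCovarianceError:
        def stat(a: np.ndarray, b: np.ndarray) -> float:
            d = a.mean(axis=0) - b.mean(axis=0)
            return float(d @ d)

        observed = stat(x1, x2)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_extreme = 0
    for _ in range(n_perm):
        idx = rng.permutation(n1 + n2)
        try:
            t = stat(pooled[idx[:n1]], pooled[idx[n1:]])
        except SingularCovarianceError:
            t = np.inf
        if t >= observed:
            n_extreme += 1
    return (1 + n_extreme) / (1 + n_perm)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Unpaired pooled-variance t statistic and its df."""
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    v1 = a.var(ddof=1) if n1 > 1 else 0.0
    v2 = b.var(ddof=1) if n2 > 1 else 0.0
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), df


def _t_pvalue(t: float, df: int, tails: str) -> float:
    if tails == "two-sided":
        return float(2.0 * sps.t.sf(abs(t), df))
    if tails == "greater":
        return float(sps.t.sf(t, df))
    if tails == "less":
        return float(sps.t.cdf(t, df))
    raise ValueError(f"tails must be two-sided|greater|less, got {tails!r}")


def axis_annotation(
    sample1,
    sample2,
    star_levels: Sequence[tuple[float, str]] = DEFAULT_STAR_LEVELS,
) -> list[AxisFlag]:
    """Per-axis two-sided pooled-variance t-tests with star strings.

    Each axis of the two samples is tested independently; the result is
    descriptive and is reported alongside the multivariate p-value, not
    in place of it.  Axes are labelled ML_x then DV_y for 2D input.
    """
    x1, x2 = _as_points(sample1), _as_points(sample2)
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("samples must share dimensionality")
    flags = []
    for axis in range(x1.shape[1]):
        a, b = x1[:, axis], x2[:, axis]
        name = AXIS_NAMES[axis] if x1.shape[1] == 2 else f"axis{axis}"
        t, df = _pooled_t(a, b)
        if np.isinf(t):
            warnings.warn(
                f"axis {name}: zero variance in both samples with unequal "
                "means; p-value reported as 0",
                stacklevel=2,
            )
            p = 0.0
        elif t == 0.0 and a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            p = 1.0
        else:
            p = _t_pvalue(t, df, "two-sided")
        flags.append(
            AxisFlag(axis=name, t_stat=t, p_value=p, stars=star_string(p, star_levels))
        )
    return flags


def count_analysis(
    dataset: pd.DataFrame,
    marker: str,
    tails: str = "two-sided",
    groups: tuple[str, str] = ("control", "mutant"),
    sections: pd.DataFrame | None = None,
    min_sections: int = 4,
) -> CountResult:
    """Per-animal count comparison between genotypes for one marker.

    Counts per hemi-section are averaged within each animal; the
    per-animal means are compared with an unpaired pooled-variance
    Student t-test.  ``tails`` is ``"two-sided"`` or a declared
    direction on (first group − second group): ``"greater"`` or
    ``"less"``.  Direction is never inferred from the data.

    ``sections`` (the section inventory) is needed to credit zero-cell
    sections; without it counts are derived from the cell table alone
    and sections absent from it are unseen.
    """
    cells = dataset[dataset["marker"] == marker]
    if sections is not None:
        inv = sections[sections["marker"] == marker] if "marker" in sections else sections
        counts = (
            cells.groupby(["genotype", "animal_id", "section_id"], observed=True)
            .size()
            .reindex(
                pd.MultiIndex.from_frame(
                    inv[["genotype", "animal_id", "section_id"]]
                ),
                fill_value=0,
            )
        )
    else:
        counts = cells.groupby(
            ["genotype", "animal_id", "section_id"], observed=True
        ).size()
    per_animal = counts.groupby(level=["genotype", "animal_id"]).mean()
    sections_per_animal = counts.groupby(level=["genotype", "animal_id"]).size()
    if (sections_per_animal < min_sections).any():
        low = sections_per_animal[sections_per_animal < min_sections]
        warnings.warn(
            f"animal(s) with fewer than {min_sections} sections: "
            f"{sorted(low.index.get_level_values('animal_id'))}",
            stacklevel=2,
        )
    means: dict[str, np.ndarray] = {}
    for g in groups:
        if g not in per_animal.index.get_level_values("genotype"):
            raise ValueError(f"no animals found for genotype {g!r}")
        vals = per_animal.xs(g, level="genotype").to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"genotype {g!r} has fewer than 2 animals")
        means[g] = vals
    a, b = means[groups[0]], means[groups[1]]
    t, df = _pooled_t(a, b)
    p = _t_pvalue(t, df, tails)
    return CountResult(
        per_animal_means={
            g: {
                str(aid): float(v)
                for aid, v in per_animal.xs(g, level="genotype").items()
            }
            for g in groups
        },
        group_means={g: float(v.mean()) for g, v in means.items()},
        group_sems={
            g: float(v.std(ddof=1) / np.sqrt(len(v))) for g, v in means.items()
        },
        n_animals={g: len(v) for g, v in means.items()},
        t_stat=t,
        df=df,
        p_value=p,
        tails=tails,
    )


def _animal_centroids(points: np.ndarray, animal: np.ndarray) -> np.ndarray:
    return np.vstack(
        [points[animal == a].mean(axis=0) for a in np.unique(animal)]
    )


def calibration_sim(
    config_grid: Mapping[str, CohortConfig] | Iterable[tuple[str, CohortConfig]],
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    units: Sequence[str] = ("cells", "animals"),
) -> pd.DataFrame:
    """Monte-Carlo rejection rates of the positional test per setting.

    For each named :class:`CohortConfig`, ``n_reps`` cohorts are
    simulated and tested in the requested units: ``"cells"`` pools
    every cell (the study's procedure) and ``"animals"`` reduces each
    animal to its centroid first.  Returns one row per setting × unit
    with the fraction of replicates rejecting at ``alpha``.
    """
    if isinstance(config_grid, Mapping):
        grid = list(config_grid.items())
    else:
        grid = list(config_grid)
    rows = []
    rng = np.random.default_rng(seed)
    for label, config in grid:
        rejections = {u: 0 for u in units}
        valid = {u: 0 for u in units}
        for _ in range(n_reps):
            rep_seed = int(rng.integers(0, 2**63 - 1))
            data = pooled_points(dataclasses.replace(config, seed=rep_seed))
            x1, x2 = data["control"], data["mutant"]
            if "cells" in units:
                try:
                    res = hotelling_t2(x1, x2, annotate_axes=False)
                    valid["cells"] += 1
                    if res.p_value < alpha:
                        rejections["cells"] += 1
                except (ValueError, SingularCovarianceError):
                    pass
            if "animals" in units:
                c1 = _animal_centroids(x1, data["control_animal"])
                c2 = _animal_centroids(x2, data["mutant_animal"])
                try:
                    res = hotelling_t2(c1, c2, annotate_axes=False)
                    valid["animals"] += 1
                    if res.p_value < alpha:
                        rejections["animals"] += 1
                except (ValueError, SingularCovarianceError):
                    pass
        for u in units:
            rows.append(
                {
                    "setting": label,
                    "unit": u,
                    "n_reps": n_reps,
                    "n_valid": valid[u],
                    "alpha": alpha,
                    "rejection_rate": rejections[u] / valid[u] if valid[u] else np.nan,
                }
            )
    return pd.DataFrame(rows)
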