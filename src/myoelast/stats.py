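"""Group statistics: Mann-Whitney comparisons, t/F tests, width analysis.

The nonparametric two-group comparison is the Mann-Whitney U test with an
exact small-sample mode (full enumeration of rank assignments) and a
tie-corrected, continuity-corrected normal approximation for larger groups.
Myotube widths get a per-group Gaussian histogram fit and a pooled-median
thin/wide cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

EXACT_LIMIT = 20  # full enumeration cap on n_x + n_y

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for level, stars in SIGNIFICANCE_LEVELS:
        if p < level:
            return stars
    return "ns"


def _u_statistics(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    nx, ny = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    ux = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    uy = nx * ny - ux
    return ux, uy


def mann_whitney_u(x, y, mode: str = "normal_approx"
                   ) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(Ux, Uy).

    ``exact`` enumerates every C(nx+ny, nx) assignment of the pooled ranks
    (handles ties through midranks); the two-sided p-value is the null
    probability that min(Ux, Uy) is at most the observed U. Enumeration is
    limited to nx + ny <= 20. ``normal_approx`` uses the tie-corrected
    normal approximation with continuity correction and requires at least
    3 observations per group.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ux, uy = _u_statistics(x, y)
    u_obs = min(ux, uy)

    if mode == "exact":
        nx, ny = x.size, y.size
        if nx + ny > EXACT_LIMIT:
            raise ValueError(f"exact mode limited to nx + ny <= {EXACT_LIMIT}")
        ranks = sps.rankdata(np.concatenate([x, y]))
        total = 0
        hits = 0
        base = nx * (nx + 1) / 2.0
        for idx in combinations(range(nx + ny), nx):
            ux_perm = ranks[list(idx)].sum() - base
            uy_perm = nx * ny - ux_perm
            total += 1
            if min(ux_perm, uy_perm) <= u_obs + 1e-9:
                hits += 1
        return u_obs, hits / total

    if mode == "normal_approx":
        if x.size < 3 or y.size < 3:
            raise ValueError("normal approximation needs n >= 3 per group")
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        return u_obs, float(min(res.pvalue, 1.0))

    raise ValueError(f"unknown mode {mode!r}")


def welch_t_and_f(x, y, alpha: float = 0.05
                  ) -> Tuple[float, float, float, float]:
    """Two-stage mean comparison: F-test for equal variance, then t-test.

    Returns (t, p_t, F, p_F). The variance F-test (two-sided) at ``alpha``
    selects between the pooled-variance t-test (variances compatible) and
    Welch's t-test (variances differ); all p-values two-sided.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("both groups have zero variance")
    F = vx / vy if vy > 0 else np.inf
    dfx, dfy = x.size - 1, y.size - 1
    cdf = sps.f.cdf(F, dfx, dfy)
    p_F = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    equal_var = p_F > alpha
    t, p_t = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p_t), float(F), p_F


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_histogram(values, bins: str | int = "fd"
                           ) -> Tuple[float, float]:
    """Least-squares single-Gaussian fit on a histogram; returns (mu, sigma)."""
    v = np.asarray(values, dtype=float).reshape(-1)
    counts, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [float(counts.max()), float(v.mean()), max(float(v.std()), 1e-6)]
    popt, _ = curve_fit(_gaussian, centers, counts, p0=p0,
                        bounds=([0, edges[0], 1e-9],
                                [np.inf, edges[-1], edges[-1] - edges[0]]))
    return float(popt[1]), float(abs(popt[2]))


@dataclass
class ThicknessDataset:
    """Per-group diameters with Gaussian fits and a thin/wide split."""

    diameters_um: Dict[str, np.ndarray]
    gaussian_fits: Dict[str, Tuple[float, float]]  # group -> (mu, sigma)
    median_um: float
    classification: Dict[str, np.ndarray]  # group -> "thin"/"wide" labels
    counts: pd.DataFrame


def thickness_analysis(diameters_per_group: Dict[str, Sequence[float]],
                       pooled_median: bool = True) -> ThicknessDataset:
    """Width analysis of myotubes: Gaussian fits and median cut-off labels.

    Each group's diameter histogram gets a least-squares Gaussian fit; the
    thin/wide cut-off is the median of the pooled sample (or per-group
    medians when ``pooled_median`` is False). Ties at the median go to
    "thin" (<= rule), which splits the data into near-equal halves.
    """
    groups = {g: np.asarray(v, dtype=float).reshape(-1)
              for g, v in diameters_per_group.items()}
    for g, v in groups.items():
        if v.size < 10:
            raise ValueError(f"group {g!r} needs >= 10 diameters")
        if np.any(v <= 0):
            raise ValueError(f"group {g!r} has non-positive diameters")
        if np.ptp(v) == 0:
            raise ValueError(f"group {g!r} diameters are constant")
    fits = {g: fit_gaussian_histogram(v) for g, v in groups.items()}
    pooled = np.concatenate(list(groups.values()))
    median = float(np.median(pooled))
    classification = {}
    rows = []
    for g, v in groups.items():
        cut = median if pooled_median else float(np.median(v))
        labels = np.where(v <= cut, "thin", "wide")
        classification[g] = labels
        rows.append({"group": g, "n": v.size,
                     "n_thin": int((labels == "thin").sum()),
                     "n_wide": int((labels == "wide").sum()),
                     "gaussian_mu_um": fits[g][0],
                     "gaussian_sigma_um": fits[g][1],
                     "cutoff_um": cut})
    return ThicknessDataset(groups, fits, median, classification,
                            pd.DataFrame(rows))


#: The comparison grid of the myotube study: thin vs thick within genotype
#: and genotype vs genotype within thickness class.
DEFAULT_COMPARISON_PLAN = (
    ("WT-thin", "WT-thick"),
    ("SOD1-thin", "SOD1-thick"),
    ("WT-thin", "SOD1-thin"),
    ("WT-thick", "SOD1-thick"),
)


def compare_cohort(summaries: Dict[str, "GroupSummary"],
                   plan: Sequence[Tuple[str, str]] = DEFAULT_COMPARISON_PLAN,
                   alpha: float = 0.05, mode: str = "auto"
                   ) -> pd.DataFrame:
    """Run the per-peak Mann-Whitney comparison grid over group summaries.

    For each planned pair, Peak 1 and Peak 2 per-map values are compared
    with the Mann-Whitney test (``mode="auto"`` picks full enumeration for
    small pairs, the tie-corrected normal approximation otherwise); a pair
    is flagged significant when either peak differs at ``alpha``. Returns a
    tidy table with U, p and stars per peak. No multiple-testing correction
    is applied; the number of comparisons is in the table for the reader.
    """
    rows = []
    for ga, gb in plan:
        if ga not in summaries or gb not in summaries:
            missing = ga if ga not in summaries else gb
            raise KeyError(f"comparison plan references unknown group {missing!r}")
        sa, sb = summaries[ga], summaries[gb]
        rec = {"group_a": ga, "group_b": gb,
               "n_a": sa.n_maps, "n_b": sb.n_maps}
        pair_mode = mode
        if mode == "auto":
            pair_mode = ("exact" if sa.n_maps + sb.n_maps <= EXACT_LIMIT
                         else "normal_approx")
        sig = False
        for peak, va, vb in (("peak1", sa.peak1_values_Pa, sb.peak1_values_Pa),
                             ("peak2", sa.peak2_values_Pa, sb.peak2_values_Pa)):
            u, p = mann_whitney_u(va, vb, mode=pair_mode)
            rec[f"{peak}_U"] = u
            rec[f"{peak}_p"] = p
            rec[f"{peak}_stars"] = significance_stars(p)
            sig = sig or (p < alpha)
        rec["significant"] = sig
        rows.append(rec)
    table = pd.DataFrame(rows)
    table.attrs["n_comparisons"] = len(rows)
    table.attrs["alpha"] = alpha
    return table
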