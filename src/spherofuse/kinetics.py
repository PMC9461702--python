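"""Population-level fusion kinetics: normalization, model fits, statistics.

The doublet roundness response is summarized by a bounded exponential,

    roundness(t) = plateau + b * exp(-t / tau),

where the plateau is the steady-state roundness (fusion quality), b < 0 the
initial offset, and tau the time constant in hours — the time at which the
response has closed ~63.2% (1 - 1/e) of the gap to the plateau, an inverse
measure of fusion rate.  Physical boxes are imposed on the parameters:
plateau in [0.5, 1] (two tangent equal disks have roundness 0.5; a circle 1)
and b in [-0.6, -0.1].  The early normalized contact length is summarized by
a bounded straight line, intercept in [0.05, 1.4] and slope in [0, 1] per
hour, fitted only on the first 5 h where the response is linear.

Group comparisons follow a normality/equal-variance decision tree: one-way
ANOVA with Tukey-Kramer post hoc when every group passes Shapiro-Wilk and
Bartlett's test accepts equal variances, otherwise Kruskal-Wallis with
Dunn-Sidak post hoc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["FusionFit", "LinearFit", "normalize_series", "fit_exponential",
           "fit_linear_contact", "population_curves", "compare_groups",
           "PLATEAU_BOUNDS", "B_BOUNDS", "INTERCEPT_BOUNDS", "SLOPE_BOUNDS"]

PLATEAU_BOUNDS = (0.5, 1.0)
B_BOUNDS = (-0.6, -0.1)
INTERCEPT_BOUNDS = (0.05, 1.4)
SLOPE_BOUNDS = (0.0, 1.0)
LINEAR_WINDOW_H = 5.0
TAU_STARTS = (0.5, 2.0, 8.0, 24.0)


@dataclass
class FusionFit:
    """Bounded-exponential fit of a roundness time series."""

    plateau: float
    b: float
    tau: float          # hours
    rss: float
    n_points: int
    converged: bool

    def predict(self, times: np.ndarray | float) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        return self.plateau + self.b * np.exp(-t / self.tau)

    def summary(self) -> str:
        return (f"roundness(t) = {self.plateau:.4f} + ({self.b:.4f})"
                f" * exp(-t / {self.tau:.3f} h)   "
                f"[rss={self.rss:.3e}, n={self.n_points}, "
                f"converged={self.converged}]")


@dataclass
class LinearFit:
    """Bounded linear fit of the early normalized contact length."""

    intercept: float
    slope: float        # per hour
    rss: float
    n_points: int

    def predict(self, times: np.ndarray | float) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(times, dtype=float)

    def summary(self) -> str:
        return (f"norm_contact(t) = {self.intercept:.4f} + {self.slope:.4f}"
                f" * t   [rss={self.rss:.3e}, n={self.n_points}, "
                f"t <= {LINEAR_WINDOW_H} h]")


class NormalizationError(ValueError):
    pass


def normalize_series(records) -> pd.DataFrame:
    """Normalize a doublet's feature matrix for population-level analysis.

    Area is normalized to the frame-0 area; contact length is normalized to
    the average initial spheroid width — the mean over the first 10
    timepoints of (width_left + width_right)/2.  Returns the feature frame
    with ``norm_area`` and ``norm_contact`` columns added.
    """
    from .features import records_to_frame
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    if len(df) < 10:
        raise NormalizationError("need at least 10 frames to normalize")
    area0 = df["area"].iloc[0]
    if not np.isfinite(area0) or area0 == 0:
        raise NormalizationError("invalid initial area")
    width = (df["width_left"] + df["width_right"]) / 2.0
    width0 = width.iloc[:10].mean()
    if not np.isfinite(width0) or width0 == 0:
        raise NormalizationError("invalid initial spheroid width")
    df["norm_area"] = df["area"] / area0
    df["norm_contact"] = df["contact_length"] / width0
    return df


def fit_exponential(times: np.ndarray, roundness: np.ndarray) -> FusionFit:
    """Bounded least-squares fit of ``plateau + b * exp(-t/tau)``.

    Multi-start over tau in {0.5, 2, 8, 24} h guards against the flat
    likelihood at large tau; the best residual sum of squares wins.  The
    plateau and b boxes are enforced exactly by the optimizer; tau is only
    constrained positive (no printed upper bound exists for it).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(roundness, dtype=float)
    if t.size != y.size:
        raise ValueError("times and roundness must align")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in fit input")
    if t.size < 10:
        raise ValueError("need at least 10 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    lo = np.array([PLATEAU_BOUNDS[0], B_BOUNDS[0], 1e-6])
    hi = np.array([PLATEAU_BOUNDS[1], B_BOUNDS[1], np.inf])

    def resid(p):
        plateau, b, tau = p
        return plateau + b * np.exp(-t / tau) - y

    p0_plateau = float(np.clip(y[-1], *PLATEAU_BOUNDS))
    p0_b = float(np.clip(y[0] - y[-1], *B_BOUNDS))
    best = None
    converged = False
    for tau0 in TAU_STARTS:
        x0 = np.clip([p0_plateau, p0_b, tau0], lo, hi)
        try:
            sol = optimize.least_squares(resid, x0, bounds=(lo, hi))
        except Exception:
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol.x, rss)
            converged = converged or bool(sol.success)
        else:
            converged = converged or bool(sol.success)
    if best is None:
        return FusionFit(plateau=p0_plateau, b=p0_b, tau=TAU_STARTS[1],
                         rss=float("inf"), n_points=t.size, converged=False)
    (plateau, b, tau), rss = best
    return FusionFit(plateau=float(plateau), b=float(b), tau=float(tau),
                     rss=rss, n_points=t.size, converged=converged)


def fit_linear_contact(times: np.ndarray, norm_contact: np.ndarray
                       ) -> LinearFit:
    """Bounded linear fit of normalized contact length on the first 5 h."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(norm_contact, dtype=float)
    sel = (t <= LINEAR_WINDOW_H) & np.isfinite(y) & np.isfinite(t)
    t, y = t[sel], y[sel]
    if t.size < 5:
        raise ValueError("need at least 5 usable points within 5 h")
    A = np.column_stack([np.ones_like(t), t])
    sol = optimize.lsq_linear(A, y, bounds=([INTERCEPT_BOUNDS[0], SLOPE_BOUNDS[0]],
                                            [INTERCEPT_BOUNDS[1], SLOPE_BOUNDS[1]]))
    rss = float(np.sum((A @ sol.x - y) ** 2))
    return LinearFit(intercept=float(sol.x[0]), slope=float(sol.x[1]),
                     rss=rss, n_points=t.size)


def population_curves(samples: list[np.ndarray],
                      dropout_threshold: float = 0.30
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Mean +/- SEM over doublet samples, truncated at 30% dropout.

    ``samples`` are per-doublet series of possibly different lengths (a
    shorter series means the sample dropped out at its end).  Returns
    ``(mean, sem, n_surviving, truncation_index)``: statistics per timepoint
    over surviving samples, up to (excluding) the first timepoint where the
    dropped-out fraction reaches ``dropout_threshold``.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    n_total = len(samples)
    lengths = np.array([len(s) for s in samples])
    t_max = int(lengths.max())
    trunc = t_max
    for t in range(t_max):
        dropped = np.sum(lengths <= t)
        if dropped / n_total >= dropout_threshold:
            trunc = t
            break
    mean = np.empty(trunc)
    sem = np.empty(trunc)
    n_surv = np.empty(trunc, dtype=int)
    for t in range(trunc):
        vals = np.array([s[t] for s in samples if len(s) > t], dtype=float)
        mean[t] = vals.mean()
        sem[t] = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
        n_surv[t] = len(vals)
    return mean, sem, n_surv, trunc


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupComparison:
    """Omnibus + post-hoc comparison of a kinetic parameter across groups."""

    branch: str                     # 'anova_tukey' | 'kruskal_dunn_sidak'
    omnibus_p: float
    pairwise: pd.DataFrame          # group1, group2, p_adj, stars
    normality_p: dict[str, float]
    bartlett_p: float
    degenerate: bool = False

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        sel = self.pairwise[self.pairwise["p_adj"] < alpha]
        return list(zip(sel["group1"], sel["group2"]))


def _dunn_sidak(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-sum pairwise z-tests with Sidak adjustment."""
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_tot = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_rank: dict[str, float] = {}
    i = 0
    for g in names:
        n = len(groups[g])
        mean_rank[g] = ranks[i:i + n].mean()
        i += n
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = np.sum(counts ** 3 - counts) / (12.0 * (n_tot - 1)) if n_tot > 1 else 0.0
    var_base = n_tot * (n_tot + 1) / 12.0 - tie
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = names[a], names[b]
            se = math.sqrt(var_base * (1.0 / len(groups[ga])
                                       + 1.0 / len(groups[gb])))
            z = abs(mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
            p = 2.0 * (1.0 - stats.norm.cdf(z))
            p_adj = 1.0 - (1.0 - p) ** m
            rows.append({"group1": ga, "group2": gb, "p_adj": min(p_adj, 1.0),
                         "stars": _stars(min(p_adj, 1.0))})
    return pd.DataFrame(rows)


def _tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    vals = np.concatenate([groups[g] for g in groups])
    labs = np.concatenate([[g] * len(groups[g]) for g in groups])
    res = pairwise_tukeyhsd(vals, labs)
    df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    out = pd.DataFrame({"group1": df["group1"], "group2": df["group2"],
                        "p_adj": df["p-adj"].astype(float)})
    out["stars"] = out["p_adj"].map(_stars)
    return out


def compare_groups(groups: dict[str, np.ndarray],
                   alpha_normality: float = 0.05) -> GroupComparison:
    """Compare a kinetic parameter (tau, plateau, slope, ...) across groups.

    Each group is tested for normality (Shapiro-Wilk) and the set for equal
    variances (Bartlett).  If all pass, one-way ANOVA with Tukey-Kramer post
    hoc; otherwise Kruskal-Wallis with Dunn-Sidak post hoc.  Constant
    (zero-variance) groups force the nonparametric branch and are flagged.
    """
    groups = {str(g): np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
    degenerate = any(np.ptp(v) == 0 for v in groups.values())
    normality_p: dict[str, float] = {}
    for g, v in groups.items():
        if np.ptp(v) == 0:
            normality_p[g] = 0.0
        else:
            normality_p[g] = float(stats.shapiro(v).pvalue)
    if degenerate:
        bartlett_p = 0.0
    else:
        bartlett_p = float(stats.bartlett(*groups.values()).pvalue)
    parametric = (not degenerate
                  and all(p >= alpha_normality for p in normality_p.values())
                  and bartlett_p >= alpha_normality)
    if parametric:
        omnibus = float(stats.f_oneway(*groups.values()).pvalue)
        pairwise = _tukey(groups)
        branch = "anova_tukey"
    else:
        if degenerate and all(np.ptp(v) == 0 for v in groups.values()) \
                and len({v[0] for v in groups.values()}) == 1:
            omnibus = 1.0  # all observations identical across all groups
            pairwise = pd.DataFrame(
                [{"group1": a, "group2": b, "p_adj": 1.0, "stars": ""}
                 for i, a in enumerate(groups) for b in list(groups)[i + 1:]])
        else:
            omnibus = float(stats.kruskal(*groups.values()).pvalue)
            pairwise = _dunn_sidak(groups)
        branch = "kruskal_dunn_sidak"
    return GroupComparison(branch=branch, omnibus_p=omnibus, pairwise=pairwise,
                           normality_p=normality_p, bartlett_p=bartlett_p,
                           degenerate=degenerate)
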