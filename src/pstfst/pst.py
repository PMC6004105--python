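"""Quantitative trait differentiation: variance components and P_ST.

P_ST is a field-data surrogate for Q_ST: for a trait with
between-population variance component ``sigma2_B`` and within-population
component ``sigma2_W``,

    P_ST = c * sigma2_B / (c * sigma2_B + 2 * h2 * sigma2_W)

where ``h2`` is the narrow-sense heritability and ``c`` the fraction of the
between-population variance that is additive-genetic. Only the ratio
``r = c/h2`` matters, so robustness of a P_ST-F_ST comparison is probed by
sweeping ``r`` over (0, 1] (null assumption c = h2, i.e. r = 1) and asking
for the smallest ratio at which P_ST would still exceed the lower 95%
confidence bound of F_ST (the critical ratio r*).

Components come from a one-way random-effects ANOVA with the
unequal-sample-size coefficient n0; pairwise P_ST uses the two populations
of each pair only. The population-pair comparison of the 45 pairwise P_ST
values against the 45 pairwise F_ST values is a two-group one-way ANOVA.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from pstfst.io import LabelledDistanceMatrix, TraitTable

logger = logging.getLogger(__name__)

DEFAULT_R_GRID = np.round(np.arange(0.01, 1.0001, 0.01), 10)


@dataclass
class VarianceComponents:
    trait: str
    groups: list[str]
    n_i: list[int]
    MS_B: float
    MS_W: float
    n0: float
    sigma2_B: float  # truncated at 0
    sigma2_B_raw: float
    sigma2_W: float


def variance_components(values, groups, trait: str = "") -> VarianceComponents:
    """One-way random-effects ANOVA variance components.

    Groups with fewer than 2 non-missing values are excluded with a
    warning; at least 2 usable groups are required. ``sigma2_B`` is
    ``max(0, (MS_B - MS_W)/n0)`` with
    ``n0 = (N - sum(n_i^2)/N) / (k - 1)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    by_group: dict = {}
    for g in dict.fromkeys(groups):
        v = values[groups == g]
        v = v[np.isfinite(v)]
        if v.size < 2:
            logger.warning("group %s has < 2 values for %s; excluded", g, trait or "trait")
            continue
        by_group[g] = v
    k = len(by_group)
    if k < 2:
        raise ValueError(f"fewer than 2 usable groups for {trait or 'trait'}")
    n_i = np.array([v.size for v in by_group.values()], dtype=float)
    N = n_i.sum()
    means = np.array([v.mean() for v in by_group.values()])
    grand = sum(v.sum() for v in by_group.values()) / N
    ss_w = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    ss_b = float((n_i * (means - grand) ** 2).sum())
    ms_w = ss_w / (N - k)
    ms_b = ss_b / (k - 1)
    n0 = (N - (n_i**2).sum() / N) / (k - 1)
    raw = (ms_b - ms_w) / n0
    return VarianceComponents(
        trait=trait,
        groups=list(by_group),
        n_i=[int(x) for x in n_i],
        MS_B=ms_b,
        MS_W=ms_w,
        n0=n0,
        sigma2_B=max(0.0, raw),
        sigma2_B_raw=raw,
        sigma2_W=ms_w,
    )


def pst(sigma2_B: float, sigma2_W: float, c: float = 1.0, h2: float = 1.0) -> float:
    """P_ST = c*sigma2_B / (c*sigma2_B + 2*h2*sigma2_W)."""
    if sigma2_B < 0 or sigma2_W < 0:
        raise ValueError("variance components must be non-negative")
    if not (0 < c <= 1) or not (0 < h2 <= 1):
        raise ValueError("c and h2 must lie in (0, 1]")
    denom = c * sigma2_B + 2 * h2 * sigma2_W
    if denom == 0:
        raise ValueError("both variance components are zero: P_ST undefined")
    return c * sigma2_B / denom


# ---------------------------------------------------------------------------
# pairwise P_ST
# ---------------------------------------------------------------------------


def _suff_stats(t: TraitTable):
    """Per-population per-trait (n, mean, within-SS) with missing removed."""
    pops = t.populations
    labels = t.population_labels
    out = {}
    for p in pops:
        sub = t.values[labels == p]
        fin = np.isfinite(sub)
        n = fin.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            mean = np.nansum(sub, axis=0) / np.where(n > 0, n, np.nan)
            ssw = np.nansum((sub - mean) ** 2, axis=0)
        out[p] = (n, mean, ssw)
    return pops, out


def _pair_pst_from_stats(n1, m1, ss1, n2, m2, ss2, r):
    """Vectorised pairwise P_ST (c = r, h2 = 1) from sufficient statistics.

    Inputs may carry a leading bootstrap axis. Pairs/traits with fewer
    than 2 values in either population, or with zero total variance, are
    NaN.
    """
    ok = (n1 >= 2) & (n2 >= 2)
    N = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = (n1 * m1 + n2 * m2) / N
        ss_b = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
        ms_w = (ss1 + ss2) / (N - 2)
        n0 = (N - (n1**2 + n2**2) / N)  # k - 1 = 1
        sigma_b = np.maximum(0.0, (ss_b - ms_w) / n0)  # MS_B = SS_B / 1
        denom = r * sigma_b + 2 * ms_w
        val = np.where(denom > 0, r * sigma_b / denom, np.nan)
    return np.where(ok, val, np.nan)


@dataclass
class PstResult:
    c: float
    h2: float
    traits: list[str]
    pairs: list[tuple[str, str]]
    pairwise_by_trait: dict[str, LabelledDistanceMatrix]
    pair_average: LabelledDistanceMatrix
    pairwise_mean: float  # mean over the pair-level trait-averages
    per_trait_overall: dict[str, float]  # all-population P_ST per trait
    overall: float  # mean over traits of the all-population P_ST
    ci95: tuple[float, float]
    n_draw: int
    seed: int | None


def pairwise_pst(
    t: TraitTable,
    c: float = 1.0,
    h2: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PstResult:
    """Pairwise and overall P_ST with a 95% confidence interval.

    For each population pair and trait the variance components come from
    the two populations only; the per-pair value averages the traits with
    defined values and ``pairwise_mean`` averages the pairs (the quantity
    entering the pairwise P_ST-F_ST comparison).

    The headline ``overall`` P_ST instead uses the one-way random-effects
    components across *all* populations per trait, averaged over traits.
    Pairwise components have a single between-group degree of freedom, so
    the mean of the concave P_ST transform over pairs systematically
    underestimates the generating differentiation; the all-population
    components are consistent for it. Its CI comes from the exact F-pivot
    of the one-way ANOVA: per trait, draws of the variance ratio are taken
    from the confidence distribution ``F_obs / F(k-1, N-k)``, mapped
    through the P_ST formula and averaged over traits (``n_boot`` draws).
    This interval is exact for a single trait and captures the
    between-population sampling of population effects, which a bootstrap
    over individuals cannot.
    """
    if not (0 < c <= 1) or not (0 < h2 <= 1):
        raise ValueError("c and h2 must lie in (0, 1]")
    r = c / h2
    pops, stats = _suff_stats(t)
    if len(pops) < 2:
        raise ValueError("pairwise P_ST needs >= 2 populations")
    pairs = list(itertools.combinations(pops, 2))
    k = len(pops)
    T = len(t.trait_ids)
    per_trait = np.full((len(pairs), T), np.nan)
    for ip, (p1, p2) in enumerate(pairs):
        n1, m1, ss1 = stats[p1]
        n2, m2, ss2 = stats[p2]
        per_trait[ip] = _pair_pst_from_stats(n1, m1, ss1, n2, m2, ss2, r)
    dropped = int(np.isnan(per_trait).sum())
    if dropped:
        logger.info("%d pair/trait P_ST values undefined and omitted", dropped)
    with np.errstate(invalid="ignore"):
        pair_avg = np.nanmean(per_trait, axis=1)
    pairwise_mean = float(np.nanmean(pair_avg))

    # matrices
    def mat(vals):
        M = np.zeros((k, k))
        for (p1, p2), v in zip(pairs, vals):
            i, j = pops.index(p1), pops.index(p2)
            M[i, j] = M[j, i] = v
        return LabelledDistanceMatrix(labels=pops, values=M)

    pairwise_by_trait = {
        trait: mat(per_trait[:, it]) for it, trait in enumerate(t.trait_ids)
    }
    pair_average = mat(pair_avg)

    per_trait_overall, overall, ci = _overall_pst(t, r, n_boot, seed)
    return PstResult(
        c=c,
        h2=h2,
        traits=list(t.trait_ids),
        pairs=pairs,
        pairwise_by_trait=pairwise_by_trait,
        pair_average=pair_average,
        pairwise_mean=pairwise_mean,
        per_trait_overall=per_trait_overall,
        overall=overall,
        ci95=ci,
        n_draw=n_boot,
        seed=seed,
    )


def _overall_pst(t: TraitTable, r: float, n_draw: int, seed: int | None):
    """All-population P_ST per trait plus the F-pivot confidence interval."""
    labels = t.population_labels
    rng = np.random.default_rng(seed)
    per_trait: dict[str, float] = {}
    draw_cols = []
    for it, trait in enumerate(t.trait_ids):
        try:
            vc = variance_components(t.values[:, it], labels, trait=trait)
        except ValueError:
            logger.warning("trait %s: overall components undefined; omitted", trait)
            continue
        per_trait[trait] = pst(vc.sigma2_B, vc.sigma2_W, c=r, h2=1.0)
        if n_draw > 0:
            k, N = len(vc.groups), sum(vc.n_i)
            f_obs = vc.MS_B / vc.MS_W
            f_star = rng.f(k - 1, N - k, n_draw)
            lam = f_obs / f_star  # confidence draws of n0*rho + 1
            rho = np.maximum(0.0, (lam - 1.0) / vc.n0)
            draw_cols.append(r * rho / (r * rho + 2.0))
    if not per_trait:
        raise ValueError("no trait has defined all-population components")
    overall = float(np.mean(list(per_trait.values())))
    ci = (np.nan, np.nan)
    if draw_cols:
        dm = np.column_stack(draw_cols).mean(axis=1)
        ci = tuple(np.percentile(dm, [2.5, 97.5]))
    return per_trait, overall, ci


# ---------------------------------------------------------------------------
# sensitivity in c/h2 and the P_ST-F_ST comparison
# ---------------------------------------------------------------------------


@dataclass
class SensitivityCurve:
    r_grid: np.ndarray
    pst_values: np.ndarray
    fst_ci_lower: float
    r_star: float | None  # None when no crossing within (0, 1]


def sensitivity_curve(
    sigma2_B: float,
    sigma2_W: float,
    fst_ci_lower: float,
    r_grid: np.ndarray | None = None,
) -> SensitivityCurve:
    """P_ST as a function of r = c/h2 and the critical ratio r*.

    ``P_ST(r) = r*sigma2_B / (r*sigma2_B + 2*sigma2_W)`` is non-decreasing
    in r; the critical ratio solving ``P_ST(r*) = F`` against the lower
    95% bound F of F_ST is ``r* = 2*sigma2_W*F / ((1 - F)*sigma2_B)``,
    reported as None when it exceeds 1 (no ratio within (0, 1] makes P_ST
    reach F) or when ``sigma2_B = 0``.
    """
    if not (0 < fst_ci_lower < 1):
        raise ValueError("fst_ci_lower must lie in (0, 1)")
    if r_grid is None:
        r_grid = DEFAULT_R_GRID
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid <= 0) or np.any(r_grid > 1):
        raise ValueError("r grid must lie in (0, 1]")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = r_grid * sigma2_B / (r_grid * sigma2_B + 2 * sigma2_W)
    vals = np.nan_to_num(vals)
    if sigma2_B <= 0:
        r_star = None
    else:
        F = fst_ci_lower
        r_star = 2 * sigma2_W * F / ((1 - F) * sigma2_B)
        if r_star > 1:
            r_star = None
    return SensitivityCurve(
        r_grid=r_grid, pst_values=vals, fst_ci_lower=fst_ci_lower, r_star=r_star
    )


def overall_sensitivity_curve(
    t: TraitTable, fst_ci_lower: float, r_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Overall P_ST (mean over traits, all-population components) along r."""
    if r_grid is None:
        r_grid = DEFAULT_R_GRID
    r_grid = np.asarray(r_grid, dtype=float)
    labels = t.population_labels
    comps = []
    for it, trait in enumerate(t.trait_ids):
        try:
            vc = variance_components(t.values[:, it], labels, trait=trait)
        except ValueError:
            continue
        comps.append((vc.sigma2_B, vc.sigma2_W))
    if not comps:
        raise ValueError("no trait has defined all-population components")
    sb = np.array([c[0] for c in comps])
    sw = np.array([c[1] for c in comps])
    rows = []
    for r in r_grid:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = r * sb / (r * sb + 2 * sw)
        overall = float(np.mean(np.nan_to_num(vals)))
        rows.append(
            {
                "r": r,
                "pst_overall": overall,
                "exceeds_fst_lower": overall > fst_ci_lower,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PstFstComparison:
    F: float
    df: tuple[int, int]
    p: float
    mean_pst: float
    mean_fst: float
    classification: str  # drift | directional | stabilising
    degenerate: bool = False


def pst_fst_comparison(
    pst_pairwise, fst_pairwise, alpha: float = 0.05
) -> PstFstComparison:
    """One-way two-group ANOVA of pairwise P_ST against pairwise F_ST.

    Classification follows the comparison of quantitative and neutral
    differentiation: significantly lower P_ST indicates stabilising
    (convergent) selection, significantly higher indicates directional
    selection, and no significant difference is compatible with drift.
    """
    x = np.asarray(pst_pairwise, dtype=float)
    y = np.asarray(fst_pairwise, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both pairwise sets must be non-empty")
    if x.size != y.size:
        raise ValueError("mismatched pair sets between P_ST and F_ST")
    n1, n2 = x.size, y.size
    df = (1, n1 + n2 - 2)
    grand = (x.sum() + y.sum()) / (n1 + n2)
    ss_b = n1 * (x.mean() - grand) ** 2 + n2 * (y.mean() - grand) ** 2
    ss_w = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    degenerate = ss_w == 0
    if degenerate:
        F = np.inf if ss_b > 0 else 0.0
        p = 0.0 if ss_b > 0 else 1.0
        logger.warning("zero within-group variance: F statistic degenerate")
    else:
        F = (ss_b / df[0]) / (ss_w / df[1])
        p = float(sps.f.sf(F, *df))
    if p < alpha:
        cls = "stabilising" if x.mean() < y.mean() else "directional"
    else:
        cls = "drift"
    return PstFstComparison(
        F=float(F),
        df=df,
        p=p,
        mean_pst=float(x.mean()),
        mean_fst=float(y.mean()),
        classification=cls,
        degenerate=degenerate,
    )
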