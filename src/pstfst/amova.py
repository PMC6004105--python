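"""Hierarchical analysis of molecular variance (AMOVA) on binary profiles.

AMOVA partitions the total sum of squared molecular distances among
hierarchical strata (regions, populations within regions, individuals
within populations), converts the mean squares into variance components
through the expected-mean-square equations with unequal-sample-size
coefficients, and expresses differentiation as Phi-statistics. For 0/1
band data the squared Euclidean distance between two profiles is simply
the number of mismatching loci, so the one-level decomposition is exactly
the locus-wise ANOVA summed over loci.

Significance is assessed by permutation: individuals among populations
(Phi_ST), individuals among populations within regions (Phi_SC), and whole
populations among regions (Phi_RT), with p = (#{stat >= observed} + 1) /
(n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pstfst.io import LabelledDistanceMatrix, MarkerMatrix

logger = logging.getLogger(__name__)


def pairwise_sq_euclidean(m: MarkerMatrix) -> LabelledDistanceMatrix:
    """Squared Euclidean (= mismatch count) distances between individuals.

    Missing cells are handled by rescaling: the mismatch count over the
    loci scored in both individuals is multiplied by
    ``n_loci / n_shared_non_missing``, so profiles with missing data remain
    comparable to complete ones.
    """
    X = np.nan_to_num(m.bands)
    Mfin = np.isfinite(m.bands).astype(float)
    # x(1-y) + (1-x)y over loci scored in both individuals
    mism = X @ (Mfin - X).T + (Mfin - X) @ X.T
    shared = Mfin @ Mfin.T
    if np.any((shared == 0) & ~np.eye(len(shared), dtype=bool)):
        raise ValueError("a pair of individuals shares no scored loci")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = mism * (m.n_loci / shared)
    np.fill_diagonal(D, 0.0)
    return LabelledDistanceMatrix(labels=list(m.individual_ids), values=D)


@dataclass
class AmovaResult:
    """Variance components, Phi-statistics and permutation p-values."""

    levels: str  # "pops" or "regions/pops"
    table: pd.DataFrame  # stratum, df, SS, MS
    sigma2_a: float  # among regions (0 for one-level)
    sigma2_b: float  # among populations [within regions]
    sigma2_c: float  # within populations
    sigma2_raw: tuple[float, float, float]
    percentages: dict[str, float]
    phi_st: float
    phi_sc: float | None
    phi_rt: float | None
    p_values: dict[str, float]
    n_perm: int
    seed: int | None


def _group_ss(D2: np.ndarray, groups: list[np.ndarray]) -> float:
    """Sum over groups of (sum of squared distances within group) / n_g."""
    total = 0.0
    for ix in groups:
        if len(ix) < 2:
            continue
        sub = D2[np.ix_(ix, ix)]
        total += sub.sum() / (2.0 * len(ix))
    return total


def _components_one_level(D2, pop_groups, N):
    k = len(pop_groups)
    ss_total = D2.sum() / (2.0 * N)
    ss_within = _group_ss(D2, pop_groups)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, N - k
    ms_among = ss_among / df_among if df_among else np.nan
    ms_within = ss_within / df_within if df_within else np.nan
    sizes = np.array([len(ix) for ix in pop_groups], dtype=float)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    sigma_c = ms_within
    sigma_b = (ms_among - ms_within) / n0
    return ss_total, ss_among, ss_within, ms_among, ms_within, sigma_b, sigma_c


def _phi_from_raw(sigma_a, sigma_b, sigma_c):
    tot = sigma_a + sigma_b + sigma_c
    if tot <= 0:
        return np.nan
    return (sigma_a + sigma_b) / tot


def amova(
    d: LabelledDistanceMatrix,
    pops: dict[str, str],
    regions: dict[str, str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA from a matrix of squared molecular distances.

    ``d`` holds squared distances between individuals (the output of
    :func:`pairwise_sq_euclidean`); ``pops`` maps individual -> population
    and the optional ``regions`` maps population -> region. Negative
    variance components are truncated to 0 for reporting after the
    Phi-statistics have been computed on the raw algebra.
    """
    labels = d.labels
    N = len(labels)
    missing = [i for i in labels if i not in pops]
    if missing:
        raise ValueError(f"individuals without population: {missing[:5]}")
    pop_label = np.array([pops[i] for i in labels])
    pop_names = list(dict.fromkeys(pop_label))
    if len(pop_names) < 2:
        raise ValueError("AMOVA needs >= 2 populations")
    singletons = [p for p in pop_names if (pop_label == p).sum() < 2]
    if singletons:
        logger.warning("populations of size 1: %s", singletons)
    D2 = d.values
    pop_groups = [np.flatnonzero(pop_label == p) for p in pop_names]
    rng = np.random.default_rng(seed)

    if regions is None or len(set(regions.values())) == 1:
        two_level = False
    else:
        two_level = True
        for p in pop_names:
            if p not in regions:
                raise ValueError(f"population {p!r} has no region assignment")

    (
        ss_total,
        ss_among_pop,
        ss_within,
        ms_among,
        ms_within,
        sigma_b1,
        sigma_c,
    ) = _components_one_level(D2, pop_groups, N)
    k = len(pop_names)

    if not two_level:
        sigma_a_raw, sigma_b_raw, sigma_c_raw = 0.0, sigma_b1, sigma_c
        phi_st = _phi_from_raw(0.0, sigma_b_raw, sigma_c_raw)
        phi_sc = phi_rt = None
        table = pd.DataFrame(
            {
                "stratum": ["among_populations", "within_populations", "total"],
                "df": [k - 1, N - k, N - 1],
                "SS": [ss_among_pop, ss_within, ss_total],
                "MS": [ms_among, ms_within, np.nan],
            }
        )
        levels = "pops"
    else:
        region_label = np.array([regions[p] for p in pop_label])
        region_names = list(dict.fromkeys(region_label))
        r = len(region_names)
        region_groups = [np.flatnonzero(region_label == g) for g in region_names]
        ss_within_regions = _group_ss(D2, region_groups)
        ss_among_regions = ss_total - ss_within_regions
        ss_among_pop_within = ss_within_regions - ss_within
        df_a, df_b, df_c = r - 1, k - r, N - k
        ms_a = ss_among_regions / df_a
        ms_b = ss_among_pop_within / df_b if df_b else np.nan
        ms_c = ms_within
        sizes = {p: (pop_label == p).sum() for p in pop_names}
        Ng = {g: (region_label == g).sum() for g in region_names}
        region_of_pop = {p: regions[p] for p in pop_names}
        sum_npsq_over_Ng = sum(
            sum(sizes[p] ** 2 for p in pop_names if region_of_pop[p] == g) / Ng[g]
            for g in region_names
        )
        sum_npsq_over_N = sum(sizes[p] ** 2 for p in pop_names) / N
        sum_Ngsq_over_N = sum(Ng[g] ** 2 for g in region_names) / N
        n1 = (N - sum_npsq_over_Ng) / df_b if df_b else np.nan
        n2 = (sum_npsq_over_Ng - sum_npsq_over_N) / df_a
        n3 = (N - sum_Ngsq_over_N) / df_a
        sigma_c_raw = ms_c
        sigma_b_raw = (ms_b - ms_c) / n1 if df_b else 0.0
        sigma_a_raw = (ms_a - ms_c - n2 * sigma_b_raw) / n3
        phi_st = _phi_from_raw(sigma_a_raw, sigma_b_raw, sigma_c_raw)
        tot = sigma_a_raw + sigma_b_raw + sigma_c_raw
        phi_sc = (
            sigma_b_raw / (sigma_b_raw + sigma_c_raw)
            if (sigma_b_raw + sigma_c_raw) > 0
            else np.nan
        )
        phi_rt = sigma_a_raw / tot if tot > 0 else np.nan
        sigma_a, sigma_b1 = sigma_a_raw, sigma_b_raw
        table = pd.DataFrame(
            {
                "stratum": [
                    "among_regions",
                    "among_populations_within_regions",
                    "within_populations",
                    "total",
                ],
                "df": [df_a, df_b, df_c, N - 1],
                "SS": [ss_among_regions, ss_among_pop_within, ss_within, ss_total],
                "MS": [ms_a, ms_b, ms_c, np.nan],
            }
        )
        levels = "regions/pops"

    raw = (sigma_a_raw if two_level else 0.0, sigma_b_raw if two_level else sigma_b1, sigma_c_raw if two_level else sigma_c)
    trunc = tuple(max(0.0, s) for s in raw)
    total_trunc = sum(trunc)
    if total_trunc > 0:
        pct = {
            "among_regions": 100 * trunc[0] / total_trunc,
            "among_populations": 100 * trunc[1] / total_trunc,
            "within_populations": 100 * trunc[2] / total_trunc,
        }
    else:
        pct = {
            "among_regions": np.nan,
            "among_populations": np.nan,
            "within_populations": np.nan,
        }
        logger.warning("all-identical profiles: components 0, Phi undefined")

    # ------------------------------------------------------------------ perms
    p_values: dict[str, float] = {}
    if n_perm > 0 and np.isfinite(phi_st):
        p_values["phi_st"] = _perm_p_individuals(
            D2, pop_label, pop_names, phi_st, n_perm, rng, within_region=None
        )
        if two_level:
            region_of = {p: regions[p] for p in pop_names}
            p_values["phi_sc"] = _perm_p_individuals(
                D2, pop_label, pop_names, phi_sc, n_perm, rng,
                within_region=region_of, stat="phi_sc", regions=regions,
            )
            p_values["phi_rt"] = _perm_p_populations(
                D2, pop_label, pop_names, regions, phi_rt, n_perm, rng
            )

    return AmovaResult(
        levels=levels,
        table=table,
        sigma2_a=trunc[0],
        sigma2_b=trunc[1],
        sigma2_c=trunc[2],
        sigma2_raw=raw,
        percentages=pct,
        phi_st=phi_st,
        phi_sc=phi_sc,
        phi_rt=phi_rt,
        p_values=p_values,
        n_perm=n_perm,
        seed=seed,
    )


def _phi_st_stats_for_perms(D2, perm_labels, pop_names, sizes_by_pop):
    """Vectorised Phi_ST for a batch of permuted population labelings.

    ``perm_labels`` is ``n_perm x N``. Group sizes are preserved by
    construction (labels are permuted), so the EMS coefficients are fixed.
    """
    n_perm, N = perm_labels.shape
    k = len(pop_names)
    ss_total = D2.sum() / (2.0 * N)
    ss_within = np.zeros(n_perm)
    for p in pop_names:
        Z = (perm_labels == p).astype(float)
        quad = np.einsum("pi,pi->p", Z @ D2, Z)
        ss_within += quad / (2.0 * sizes_by_pop[p])
    ss_among = ss_total - ss_within
    ms_w = ss_within / (N - k)
    ms_a = ss_among / (k - 1)
    sizes = np.array([sizes_by_pop[p] for p in pop_names], dtype=float)
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    sigma_b = (ms_a - ms_w) / n0
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = sigma_b / (sigma_b + ms_w)
    return phi


def _perm_p_individuals(
    D2, pop_label, pop_names, observed, n_perm, rng,
    within_region=None, stat="phi_st", regions=None,
):
    N = len(pop_label)
    sizes = {p: int((pop_label == p).sum()) for p in pop_names}
    perm_labels = np.empty((n_perm, N), dtype=pop_label.dtype)
    if within_region is None:
        for b in range(n_perm):
            perm_labels[b] = pop_label[rng.permutation(N)]
    else:
        region_label = np.array([regions[p] for p in pop_label])
        for b in range(n_perm):
            row = pop_label.copy()
            for g in set(region_label):
                ix = np.flatnonzero(region_label == g)
                row[ix] = row[ix[rng.permutation(len(ix))]]
            perm_labels[b] = row
    if stat == "phi_st" and within_region is None:
        stats = _phi_st_stats_for_perms(D2, perm_labels, pop_names, sizes)
    else:
        stats = np.empty(n_perm)
        for b in range(n_perm):
            groups = [np.flatnonzero(perm_labels[b] == p) for p in pop_names]
            res = _amova_stat_two_level(D2, perm_labels[b], pop_names, regions)
            stats[b] = res[stat]
    count = int(np.sum(stats[np.isfinite(stats)] >= observed))
    return (count + 1) / (n_perm + 1)


def _amova_stat_two_level(D2, pop_label, pop_names, regions):
    """Phi statistics of a two-level AMOVA for one labelling (no p-values)."""
    labels = [str(i) for i in range(len(pop_label))]
    d = LabelledDistanceMatrix(labels=labels, values=D2)
    pops_map = {l: p for l, p in zip(labels, pop_label)}
    res = amova(d, pops_map, regions={p: regions[p] for p in set(pop_label)}, n_perm=0)
    return {"phi_st": res.phi_st, "phi_sc": res.phi_sc, "phi_rt": res.phi_rt}


def _perm_p_populations(D2, pop_label, pop_names, regions, observed, n_perm, rng):
    """Permute whole populations among regions for Phi_RT."""
    region_names = list(dict.fromkeys(regions[p] for p in pop_names))
    assignment = [regions[p] for p in pop_names]
    stats = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = [assignment[i] for i in rng.permutation(len(assignment))]
        reg_map = dict(zip(pop_names, shuffled))
        res = _amova_stat_two_level(D2, pop_label, pop_names, reg_map)
        stats[b] = res["phi_rt"] if res["phi_rt"] is not None else np.nan
    count = int(np.sum(stats[np.isfinite(stats)] >= observed))
    return (count + 1) / (n_perm + 1)
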