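"""Allele-frequency estimation and F-statistics for dominant markers.

Dominant fingerprinting markers (ISSR, AFLP) score each locus only as band
present (1) or absent (0). Under Hardy-Weinberg equilibrium the band-absent
phenotype is the recessive homozygote, so the null-allele frequency ``q``
at a locus must be inferred from the band-absence frequency ``x = q**2``.
Three estimators are provided:

``sqrt``
    the naive HWE estimator ``q_hat = sqrt(m/n)``;
``lynch_milligan``
    the Taylor bias-corrected estimator
    ``q_hat = sqrt(x) / (1 - Var(x)/(8 x**2))`` with ``Var(x) = x(1-x)/n``,
    applied only where the band-absent count is at least 3 (below that the
    correction is unstable and the square-root path is used, flagged);
``bayes_nonuniform``
    an empirical-Bayes posterior mean: with a Beta(a, b) prior on
    ``x = q**2`` fitted across loci, the posterior after observing ``m``
    absences in ``n`` individuals is Beta(a+m, b+n-m) and
    ``q_hat = E[sqrt(x)] = B(a+m+1/2, b+n-m) / B(a+m, b+n-m)``.

On top of the frequencies the module computes per-population diversity
(percent polymorphic loci, Nei gene diversity and its unbiased variant,
private bands), the Nei gene-diversity partition (H_T, H_S, G_ST, Nm), a
Wright-style F_ST with locus-bootstrap confidence intervals and a
permutation test, and Nei-Li (one minus Dice) distances between individual
band profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from pstfst.io import LabelledDistanceMatrix, MarkerMatrix

logger = logging.getLogger(__name__)

METHODS = ("sqrt", "lynch_milligan", "bayes_nonuniform")

# Band-absent counts below this use the square-root path instead of the
# Lynch-Milligan variance correction, which is unstable near x = 0.
LM_MIN_ABSENT = 3


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def band_frequencies(m: MarkerMatrix):
    """Per-population per-locus band-presence frequency and sample size.

    Returns ``(populations, freq, n_eff)`` where ``freq`` and ``n_eff`` are
    ``n_pops x n_loci`` arrays; cells with no non-missing observation are
    NaN in ``freq`` and 0 in ``n_eff`` and are excluded downstream.
    """
    pops = m.populations
    idx = m.population_indices()
    k, L = len(pops), m.n_loci
    freq = np.full((k, L), np.nan)
    n_eff = np.zeros((k, L), dtype=int)
    for i, p in enumerate(pops):
        sub = m.bands[idx[p]]
        n_eff[i] = np.isfinite(sub).sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq[i] = np.nansum(sub, axis=0) / np.where(n_eff[i] > 0, n_eff[i], np.nan)
    return pops, freq, n_eff


def fit_beta_prior(band_absent_freqs: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta prior for the band-absence frequency.

    This parameterises the non-uniform prior of the empirical-Bayes
    estimator from the across-locus distribution of observed band-absence
    frequencies. Parameters are clipped to >= 0.01.
    """
    x = np.asarray(band_absent_freqs, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 valid frequencies to fit a prior")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    if var <= 0:
        raise ValueError(
            "zero variance across loci: fall back to the uniform prior (a=b=1)"
        )
    if not 0 < mean < 1:
        raise ValueError("mean band-absence frequency must lie strictly in (0,1)")
    ratio = mean * (1 - mean) / var - 1
    a = max(mean * ratio, 0.01)
    b = max((1 - mean) * ratio, 0.01)
    return a, b


def estimate_null_freq(
    m,
    n,
    method: str = "bayes_nonuniform",
    prior: tuple[float, float] | None = None,
):
    """Estimate the null (band-absence) allele frequency q from counts.

    ``m`` is the band-absent count and ``n`` the sample size (scalars or
    arrays). For ``bayes_nonuniform`` a Beta prior ``(a, b)`` on ``x = q**2``
    must be supplied (fit one with :func:`fit_beta_prior`).
    """
    m_arr = np.asarray(m, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(m_arr > n_arr):
        raise ValueError("band-absent count m cannot exceed sample size n")
    if np.any(n_arr < 1):
        raise ValueError("sample size n must be >= 1")
    if method == "sqrt":
        with np.errstate(invalid="ignore"):
            q = np.sqrt(m_arr / n_arr)
    elif method == "lynch_milligan":
        with np.errstate(invalid="ignore", divide="ignore"):
            x = m_arr / n_arr
            var = x * (1 - x) / n_arr
            corr = 1.0 - var / (8.0 * x**2)
            q = np.where(m_arr >= LM_MIN_ABSENT, np.sqrt(x) / corr, np.sqrt(x))
        q = np.minimum(q, 1.0)
    elif method == "bayes_nonuniform":
        if prior is None:
            raise ValueError("bayes_nonuniform requires a (a, b) prior")
        a, b = prior
        if a <= 0 or b <= 0:
            raise ValueError("Beta prior parameters must be positive")
        apost = a + m_arr
        bpost = b + n_arr - m_arr
        q = np.exp(special.betaln(apost + 0.5, bpost) - special.betaln(apost, bpost))
    else:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return q if q.ndim else float(q)


def _posterior_var_q(m, n, prior):
    """Posterior variance of q = sqrt(x) under the Beta posterior on x."""
    a, b = prior
    apost = a + np.asarray(m, dtype=float)
    bpost = b + np.asarray(n, dtype=float) - np.asarray(m, dtype=float)
    e_x = apost / (apost + bpost)
    e_q = np.exp(special.betaln(apost + 0.5, bpost) - special.betaln(apost, bpost))
    return np.maximum(e_x - e_q**2, 0.0)


def _sampling_var_q(m, n):
    """Delta-method sampling variance of q_hat = sqrt(m/n)."""
    x = np.asarray(m, dtype=float) / np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (1 - x) / (4 * np.asarray(n, dtype=float))
    return np.where(x > 0, v, 0.0)


@dataclass
class AlleleFreqTable:
    """Per-population per-locus null-allele frequency estimates.

    ``var_q`` carries the per-cell uncertainty used by the F_ST estimator:
    the posterior variance of q for the Bayesian method, the delta-method
    sampling variance otherwise. ``pruned`` flags Lynch-Milligan cells that
    fell back to the square-root path.
    """

    populations: list[str]
    loci: list[str]
    q_hat: np.ndarray
    n_eff: np.ndarray
    method: str
    var_q: np.ndarray
    prior_a: float | None = None
    prior_b: float | None = None
    pruned: np.ndarray | None = None

    @property
    def p_hat(self) -> np.ndarray:
        return 1.0 - self.q_hat

    @property
    def H_locus(self) -> np.ndarray:
        """Per-population per-locus gene diversity 2*p*q."""
        return 2.0 * self.p_hat * self.q_hat


def allele_frequencies(
    m: MarkerMatrix,
    method: str = "bayes_nonuniform",
    prior: tuple[float, float] | None = None,
) -> AlleleFreqTable:
    """Estimate q for every population/locus cell of a marker matrix."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    pops, freq, n_eff = band_frequencies(m)
    absent = (1.0 - freq) * n_eff  # band-absent counts, NaN where no data
    a = b = None
    if method == "bayes_nonuniform":
        if prior is None:
            x = (1.0 - freq).ravel()
            try:
                prior = fit_beta_prior(x)
            except ValueError:
                logger.warning("prior fit failed; using the uniform prior a=b=1")
                prior = (1.0, 1.0)
        a, b = prior
    q = np.full_like(freq, np.nan)
    var_q = np.full_like(freq, np.nan)
    pruned = None
    ok = n_eff > 0
    m_counts = np.where(ok, np.round(absent), 0.0)
    n_counts = np.where(ok, n_eff, 1.0)
    if method == "bayes_nonuniform":
        q_all = estimate_null_freq(m_counts, n_counts, method, prior)
        v_all = _posterior_var_q(m_counts, n_counts, prior)
    else:
        q_all = estimate_null_freq(m_counts, n_counts, method)
        v_all = _sampling_var_q(m_counts, n_counts)
        if method == "lynch_milligan":
            pruned = ok & (m_counts < LM_MIN_ABSENT)
    q[ok] = np.asarray(q_all)[ok]
    var_q[ok] = np.asarray(v_all)[ok]
    return AlleleFreqTable(
        populations=pops,
        loci=list(m.locus_ids),
        q_hat=q,
        n_eff=n_eff,
        method=method,
        var_q=var_q,
        prior_a=a,
        prior_b=b,
        pruned=pruned,
    )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def diversity_summary(
    m: MarkerMatrix, method: str = "sqrt", polymorphism_criterion: float = 1.0
) -> pd.DataFrame:
    """Per-population diversity table (percent polymorphic, H, UH, private bands).

    ``%P`` counts loci whose band-presence frequency lies strictly between
    ``1 - polymorphism_criterion`` and ``polymorphism_criterion`` when the
    criterion is below 1 (the 95%/99% convention); with the default 1.0 a
    locus is polymorphic whenever 0 < frequency < 1. ``H`` is the mean over
    loci of 2*p*q from the chosen frequency estimator; ``UH`` applies the
    allele-sample-size correction 2n/(2n-1) per locus. Private bands are
    loci present in exactly one population. The last row holds the
    species-level mean and standard deviation across populations.
    """
    freqs = allele_frequencies(m, method=method)
    pops, presence, n_eff = band_frequencies(m)
    H = freqs.H_locus
    rows = []
    present_any = np.nan_to_num(presence) > 0
    private_ok = present_any.sum(axis=0) == 1
    idx = m.population_indices()
    for i, p in enumerate(pops):
        f = presence[i]
        valid = np.isfinite(f)
        if polymorphism_criterion >= 1.0:
            poly = valid & (f > 0) & (f < 1)
        else:
            lo = 1.0 - polymorphism_criterion
            poly = valid & (f > lo) & (f < polymorphism_criterion)
        pctP = 100.0 * poly.sum() / m.n_loci
        h = float(np.nanmean(H[i]))
        n_l = n_eff[i].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            uh_locus = H[i] * 2 * n_l / (2 * n_l - 1)
        single = n_l < 1.5  # UH undefined for single-individual cells
        uh = float(np.nanmean(np.where(single, np.nan, uh_locus)))
        if np.all(single):
            uh = np.nan
            logger.warning("population %s: single individual, UH undefined", p)
        n_private = int((private_ok & present_any[i]).sum())
        rows.append(
            {
                "population": p,
                "n": len(idx[p]),
                "pct_polymorphic": pctP,
                "H_nei": h,
                "UH_nei": uh,
                "n_private_bands": n_private,
            }
        )
    df = pd.DataFrame(rows)
    mean_row = {
        "population": "MEAN(SD)",
        "n": df["n"].mean(),
        "pct_polymorphic": df["pct_polymorphic"].mean(),
        "H_nei": df["H_nei"].mean(),
        "UH_nei": df["UH_nei"].mean(),
        "n_private_bands": df["n_private_bands"].mean(),
    }
    df.attrs["sd"] = {
        c: float(df[c].std(ddof=1))
        for c in ("n", "pct_polymorphic", "H_nei", "UH_nei", "n_private_bands")
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


@dataclass
class GeneDiversityPartition:
    """Nei partition of gene diversity into within/among components."""

    H_T: float
    H_S: float
    G_ST: float
    Nm: float | None  # None when G_ST = 0 (undefined)


def gst_partition(
    freqs: AlleleFreqTable, weights: str = "equal"
) -> GeneDiversityPartition:
    """Nei gene-diversity partition and the derived gene-flow estimate.

    Per locus ``H_S`` is the (weighted) mean over populations of 2*p*q and
    ``H_T = 2*p_bar*q_bar`` from the mean frequency. G_ST aggregates as a
    ratio of locus sums; ``Nm = 0.5 (1 - G_ST)/G_ST`` (island-model
    equilibrium for the allele sample size of dominant data).
    """
    if len(freqs.populations) < 2:
        raise ValueError("gene-diversity partition needs >= 2 populations")
    q = freqs.q_hat
    if weights == "equal":
        w = np.where(np.isfinite(q), 1.0, 0.0)
    elif weights == "by_n":
        w = np.where(np.isfinite(q), freqs.n_eff.astype(float), 0.0)
    else:
        raise ValueError("weights must be 'equal' or 'by_n'")
    wsum = w.sum(axis=0)
    usable = wsum > 0
    qz = np.nan_to_num(q)
    q_bar = (w * qz).sum(axis=0)[usable] / wsum[usable]
    H_locus = 2 * qz * (1 - qz)
    H_S = (w * H_locus).sum(axis=0)[usable] / wsum[usable]
    H_T = 2 * q_bar * (1 - q_bar)
    ht, hs = float(H_T.sum()), float(H_S.sum())
    if ht <= 0:
        return GeneDiversityPartition(H_T=0.0, H_S=0.0, G_ST=np.nan, Nm=None)
    gst = (ht - hs) / ht
    nm = None if gst <= 0 else 0.5 * (1 - gst) / gst
    n_loci = int(usable.sum())
    return GeneDiversityPartition(H_T=ht / n_loci, H_S=hs / n_loci, G_ST=gst, Nm=nm)


# ---------------------------------------------------------------------------
# Wright-style F_ST
# ---------------------------------------------------------------------------

FST_METHODS = ("beta_fmodel",) + METHODS


def _fmodel_q0(A, nu):
    """Ancestral frequency solving E[q^2] = (nu q0^2 + q0)/(nu + 1) = A."""
    A = np.clip(A, 0.0, 1.0)
    return (-1.0 + np.sqrt(1.0 + 4.0 * nu * (nu + 1.0) * A)) / (2.0 * nu)


def _fmodel_var_x(A, F):
    """Model among-population variance of x = q^2 at mean A and dispersion F.

    Population null-allele frequencies are Beta(q0*nu, (1-q0)*nu) with
    nu = (1-F)/F, so E[q^(2r)] follows from the Beta rising factorials;
    Var(x) = E[q^4] - E[q^2]^2 with q0 chosen so that E[q^2] = A.
    """
    nu = (1.0 - F) / F
    q0 = _fmodel_q0(A, nu)
    alpha = q0 * nu
    e2 = (alpha * (alpha + 1.0)) / (nu * (nu + 1.0))
    e4 = e2 * ((alpha + 2.0) * (alpha + 3.0)) / ((nu + 2.0) * (nu + 3.0))
    return e4 - e2**2


def _fit_fmodel_fst(A, V_hat, var_A=None, tol=1e-10, max_iter=80):
    """Solve sum_l VarModel(A_l, F) = sum_l V_hat_l for F by bisection.

    ``var_A`` is the per-locus sampling variance of the plug-in mean
    ``A_l``; when given, the model variance is corrected for the concavity
    of VarModel in A (second-order Taylor term), which otherwise biases
    the fitted F upwards. ``A`` and ``V_hat`` may carry a leading
    bootstrap axis; the fit is then vectorised over replicates. Returns F
    clipped to [0, 1].
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    V = np.atleast_2d(np.asarray(V_hat, dtype=float))
    ok = np.isfinite(A) & np.isfinite(V)
    target = np.where(ok, V, 0.0).sum(axis=1)
    delta = 1e-4
    Az = np.clip(np.where(ok, A, 0.5), delta, 1.0 - delta)
    vA = None
    if var_A is not None:
        vA = np.where(ok, np.atleast_2d(np.asarray(var_A, dtype=float)), 0.0)

    def gap(F):
        Fb = F[:, None]
        model = _fmodel_var_x(Az, Fb)
        if vA is not None:
            curv = (
                _fmodel_var_x(Az + delta, Fb)
                - 2.0 * model
                + _fmodel_var_x(Az - delta, Fb)
            ) / delta**2
            model = model - 0.5 * vA * curv
        return np.where(ok, model, 0.0).sum(axis=1) - target

    lo = np.full(target.shape, 1e-9)
    hi = np.full(target.shape, 1.0 - 1e-9)
    g_lo, g_hi = gap(lo), gap(hi)
    out = np.full(target.shape, np.nan)
    out[g_lo >= 0] = 0.0  # no excess dispersion beyond sampling noise
    out[g_hi <= 0] = 1.0  # dispersion at or beyond the model maximum
    active = ~np.isfinite(out)
    for _ in range(max_iter):
        if not active.any():
            break
        mid = (lo + hi) / 2.0
        g_mid = gap(mid)
        take_hi = active & (g_mid < 0)
        lo = np.where(take_hi, mid, lo)
        hi = np.where(active & ~take_hi, mid, hi)
        if np.max(hi[active] - lo[active]) < tol:
            break
    out[active] = ((lo + hi) / 2.0)[active]
    return out if out.size > 1 else float(out[0])


def _fmodel_terms(m_counts, n_counts):
    """Per-locus (A, V_hat, var_A): mean band-absence frequency, the
    unbiased among-population variance of x (sample variance minus the
    mean unbiased binomial sampling variance x(1-x)/(n-1)), and the
    sampling variance of the mean A itself."""
    ok = n_counts >= 2
    nsafe = np.where(ok, n_counts, 2.0)
    x = np.where(ok, m_counts / nsafe, 0.0)
    k = ok.sum(axis=0).astype(float)
    usable = k >= 2
    ksafe = np.where(usable, k, 2.0)
    A = x.sum(axis=0) / ksafe
    s2 = (np.where(ok, (x - A) ** 2, 0.0)).sum(axis=0) / (ksafe - 1.0)
    sv = (np.where(ok, x * (1.0 - x) / (nsafe - 1.0), 0.0)).sum(axis=0) / ksafe
    A = np.where(usable, A, np.nan)
    V_hat = np.where(usable, s2 - sv, np.nan)
    var_A = np.where(usable, s2 / ksafe, np.nan)
    return A, V_hat, var_A


@dataclass
class FstResult:
    fst_overall: float
    fst_raw: float
    fst_pairwise: LabelledDistanceMatrix
    fst_pairwise_raw: np.ndarray
    ci95: tuple[float, float]
    n_boot: int
    perm_p: float | None
    n_perm: int
    method: str
    seed: int | None
    prior: tuple[float, float] | None = None


def _fst_terms(m_counts, n_counts, method, prior):
    """Per-locus numerator/denominator of the moment F_ST estimator.

    ``m_counts``/``n_counts`` are k x L band-absent counts and sample
    sizes (NaN/0 where a cell has no data). The numerator estimates the
    among-population variance of q, correcting for estimation noise in
    q_hat: posterior means underdisperse by the mean posterior variance
    (added back), frequentist estimates overdisperse by the sampling
    variance (subtracted). The denominator estimates q_bar(1-q_bar), the
    total gene diversity scale, with a finite-number-of-populations
    correction. F_ST is the ratio of locus sums.
    """
    ok = n_counts > 0
    msafe = np.where(ok, m_counts, 0.0)
    nsafe = np.where(ok, n_counts, 1.0)
    if method == "bayes_nonuniform":
        q = np.asarray(estimate_null_freq(msafe, nsafe, method, prior))
        v = np.asarray(_posterior_var_q(msafe, nsafe, prior))
        sign = +1.0
    else:
        q = np.asarray(estimate_null_freq(msafe, nsafe, method))
        v = np.asarray(_sampling_var_q(msafe, nsafe))
        sign = -1.0
    q = np.where(ok, q, np.nan)
    v = np.where(ok, v, np.nan)
    k = ok.sum(axis=0).astype(float)  # populations with data per locus
    usable = k >= 2
    q_bar = np.nanmean(np.where(ok, q, np.nan), axis=0)
    s2 = np.nanvar(np.where(ok, q, np.nan), axis=0, ddof=1)
    v_bar = np.nanmean(np.where(ok, v, np.nan), axis=0)
    num = s2 + sign * v_bar
    den = q_bar * (1 - q_bar) + s2 / k
    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)
    return num, den


def _counts(m: MarkerMatrix):
    """Band-absent counts and sample sizes per population per locus."""
    _, freq, n_eff = band_frequencies(m)
    absent = np.where(n_eff > 0, np.round((1.0 - np.nan_to_num(freq)) * n_eff), 0.0)
    return absent, n_eff.astype(float)


def _ratio_of_sums(num, den):
    d = np.nansum(den)
    if d <= 0:
        return np.nan
    return float(np.nansum(num) / d)


def _point_fst(absent, n_eff, method, prior):
    """Point estimate (raw, possibly negative for partition methods)."""
    if method == "beta_fmodel":
        A, V, vA = _fmodel_terms(absent, n_eff)
        if not np.any(np.isfinite(A)):
            return np.nan
        return _fit_fmodel_fst(A, V, vA)
    num, den = _fst_terms(absent, n_eff, method, prior)
    return _ratio_of_sums(num, den)


def fst_wright(
    m: MarkerMatrix,
    method: str = "beta_fmodel",
    n_boot: int = 1000,
    n_perm: int = 10000,
    seed: int | None = None,
    prior: tuple[float, float] | None = None,
) -> FstResult:
    """Wright-style F_ST from dominant band data.

    The default ``beta_fmodel`` method assumes Hardy-Weinberg equilibrium
    and a non-uniform (Beta) distribution of allele frequencies across
    populations, and fits the Beta dispersion parameter — which is F_ST
    under that model — by matching the among-population variance of the
    band-absence frequency to its model expectation, after removing the
    unbiased binomial sampling variance. Working on the directly observed
    ``x = q**2`` scale keeps every moment unbiasedly estimable, which the
    square-root transform of per-population ``q_hat`` estimates does not
    (its small-sample curvature inflates the among-population variance).
    The classical gene-diversity-partition estimators remain available by
    passing one of the allele-frequency methods (``sqrt``,
    ``lynch_milligan``, ``bayes_nonuniform``); they carry that known
    small-sample bias.

    The pairwise matrix applies the same estimator to each population pair
    (negative raw partition values truncated to 0 for reporting, raw
    retained); the 95% CI is a percentile bootstrap over loci; the p-value
    permutes individuals among populations. A single seed governs both
    resampling streams (bootstrap first, then permutation).
    """
    if method not in FST_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {FST_METHODS}")
    pops = m.populations
    if len(pops) < 2:
        raise ValueError("F_ST needs >= 2 populations")
    sizes = {p: len(ix) for p, ix in m.population_indices().items()}
    small = [p for p, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"populations with < 2 individuals: {small}")
    if m.n_loci < 10:
        logger.warning("fewer than 10 loci: bootstrap CI will be unstable")
    if method == "bayes_nonuniform" and prior is None:
        _, freq, _ = band_frequencies(m)
        try:
            prior = fit_beta_prior((1.0 - freq).ravel())
        except ValueError:
            logger.warning("prior fit failed; using the uniform prior a=b=1")
            prior = (1.0, 1.0)

    absent, n_eff = _counts(m)
    raw = _point_fst(absent, n_eff, method, prior)
    point = float(np.clip(raw, 0.0, 1.0)) if np.isfinite(raw) else np.nan
    if not np.isfinite(raw):
        logger.warning("degenerate total diversity: F_ST undefined")

    # pairwise
    k = len(pops)
    pw_raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pw_raw[i, j] = pw_raw[j, i] = _point_fst(
                absent[[i, j]], n_eff[[i, j]], method, prior
            )
    pw = LabelledDistanceMatrix(
        labels=pops, values=np.clip(np.nan_to_num(pw_raw), 0.0, 1.0), signed=False
    )

    rng = np.random.default_rng(seed)
    boot_rng, perm_rng = rng.spawn(2)

    # bootstrap over loci
    ci = (np.nan, np.nan)
    if n_boot > 0 and np.isfinite(raw):
        if method == "beta_fmodel":
            A, V, vA = _fmodel_terms(absent, n_eff)
            ok = np.isfinite(A) & np.isfinite(V)
            A_ok, V_ok, vA_ok = A[ok], V[ok], vA[ok]
            picks = boot_rng.integers(0, A_ok.size, size=(n_boot, A_ok.size))
            stats = np.asarray(
                _fit_fmodel_fst(A_ok[picks], V_ok[picks], vA_ok[picks])
            )
        else:
            num, den = _fst_terms(absent, n_eff, method, prior)
            ok = np.isfinite(num) & np.isfinite(den)
            num_ok, den_ok = num[ok], den[ok]
            picks = boot_rng.integers(0, num_ok.size, size=(n_boot, num_ok.size))
            b_num = num_ok[picks].sum(axis=1)
            b_den = den_ok[picks].sum(axis=1)
            stats = np.where(b_den > 0, b_num / b_den, np.nan)
        stats = np.clip(stats[np.isfinite(stats)], 0.0, 1.0)
        if stats.size:
            ci = tuple(np.percentile(stats, [2.5, 97.5]))

    # permutation test: shuffle individuals among populations
    perm_p = None
    if n_perm > 0 and np.isfinite(raw):
        labels = m.population_labels
        Z = np.array([labels == p for p in pops], dtype=float)  # k x N
        X = np.nan_to_num(m.bands)  # zeros at missing
        Mfin = np.isfinite(m.bands).astype(float)
        count = 0
        N = m.n_individuals
        for _ in range(n_perm):
            perm = perm_rng.permutation(N)
            Zp = Z[:, perm]
            # permuting the columns of Z reassigns individuals to populations
            n_eff_p = Zp @ Mfin
            present_p = Zp @ X
            absent_p = np.where(n_eff_p > 0, n_eff_p - present_p, 0.0)
            stat = _point_fst(absent_p, n_eff_p, method, prior)
            if np.isfinite(stat) and stat >= raw:
                count += 1
        perm_p = (count + 1) / (n_perm + 1)

    return FstResult(
        fst_overall=point,
        fst_raw=raw,
        fst_pairwise=pw,
        fst_pairwise_raw=pw_raw,
        ci95=ci,
        n_boot=n_boot,
        perm_p=perm_p,
        n_perm=n_perm,
        method=method,
        seed=seed,
        prior=prior,
    )


# ---------------------------------------------------------------------------
# Nei-Li distance
# ---------------------------------------------------------------------------


def nei_li_distance(m: MarkerMatrix) -> LabelledDistanceMatrix:
    """Nei-Li distance (1 - Dice similarity) between individual profiles.

    ``D(x, y) = 1 - 2 n_xy / (n_x + n_y)`` with ``n_xy`` the number of
    shared bands and ``n_x``, ``n_y`` the band counts of each profile,
    restricted to loci non-missing in both individuals.
    """
    X = np.nan_to_num(m.bands)
    Mfin = np.isfinite(m.bands).astype(float)
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if zero.size:
        bad = [m.individual_ids[i] for i in zero]
        raise ValueError(f"individuals with no bands (distance undefined): {bad}")
    shared = X @ X.T
    n_x = X @ Mfin.T  # bands of row-individual at loci scored in both
    n_y = Mfin @ X.T
    tot = n_x + n_y
    if np.any((tot == 0) & ~np.eye(len(tot), dtype=bool)):
        raise ValueError("a pair of individuals shares no scored bands")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - 2.0 * shared / tot
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, 1.0)
    return LabelledDistanceMatrix(labels=list(m.individual_ids), values=D)
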