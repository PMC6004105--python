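"""Permutation and multiple-testing utilities: Mantel, Holm, Evanno delta-K."""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from pstfst.io import LabelledDistanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class MantelResult:
    r_M: float
    p: float
    n_perm: int
    seed: int | None
    tail: str
    exact: bool = False


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    A: LabelledDistanceMatrix,
    B: LabelledDistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "two-sided",
    method: str = "auto",
) -> MantelResult:
    """Mantel matrix-correlation test.

    ``r_M`` is the Pearson correlation of the off-diagonal upper-triangle
    entries after aligning ``B`` to the label order of ``A``. The null
    distribution permutes rows and columns of ``B`` simultaneously;
    ``p = (#{r_perm >= r_obs} + 1)/(n_perm + 1)`` for ``tail="greater"``,
    or the analogous count on ``|r|`` for the default two-sided test.
    ``method="exact"`` enumerates all n! permutations (n <= 7) and reports
    the exact proportion; ``"auto"`` switches to exact when n! <= n_perm.
    """
    if set(A.labels) != set(B.labels):
        raise ValueError("matrices have different label sets")
    n = A.n
    if n < 4:
        raise ValueError("Mantel test needs n >= 4")
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    Bv = B.reordered(A.labels).values
    Av = A.values
    a = _upper(Av)
    if np.std(a) == 0 or np.std(_upper(Bv)) == 0:
        raise ValueError("constant matrix: Mantel correlation undefined")
    iu = np.triu_indices(n, k=1)
    a_std = (a - a.mean()) / a.std()

    def corr(perms: np.ndarray) -> np.ndarray:
        # perms: n_perm x n index rows; permuted upper-triangle of B
        b = Bv[perms[:, iu[0]], perms[:, iu[1]]]
        b_mean = b.mean(axis=1, keepdims=True)
        b_std = b.std(axis=1, keepdims=True)
        return ((b - b_mean) * a_std).mean(axis=1) / b_std[:, 0]

    r_obs = float(corr(np.arange(n)[None, :])[0])

    if method == "auto":
        method = "exact" if math.factorial(n) <= max(n_perm, 1) else "sampled"
    if method == "exact":
        if math.factorial(n) > 40320:  # 8! guards memory/time
            raise ValueError("exact enumeration supported only for n <= 7")
        perms = np.array(list(itertools.permutations(range(n))))
        r_null = corr(perms)
        if tail == "greater":
            p = float(np.mean(r_null >= r_obs - 1e-12))
        else:
            p = float(np.mean(np.abs(r_null) >= abs(r_obs) - 1e-12))
        return MantelResult(
            r_M=r_obs, p=p, n_perm=perms.shape[0], seed=seed, tail=tail, exact=True
        )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    r_null = corr(perms)
    if tail == "greater":
        count = int(np.sum(r_null >= r_obs - 1e-12))
    else:
        count = int(np.sum(np.abs(r_null) >= abs(r_obs) - 1e-12))
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r_M=r_obs, p=p, n_perm=n_perm, seed=seed, tail=tail)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down family-wise error adjustment, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="holm")
    return adj


@dataclass
class EvannoTable:
    table: pd.DataFrame  # K, n_runs, mean_lnP, sd_lnP, L1, L2, delta_K
    best_K: int | None


def evanno_delta_k(runs: pd.DataFrame) -> EvannoTable:
    """Evanno delta-K model-selection statistic from clustering log-likelihoods.

    ``runs`` has columns ``K`` and ``lnP`` (one row per replicate run; an
    optional ``replicate`` column fixes the alignment of replicates across
    K, otherwise input order within each K is used). For each interior K,

        delta_K = mean over replicates |L(K-1) - 2 L(K) + L(K+1)| / sd[L(K)]

    delta_K is undefined (flagged NaN) where the replicate standard
    deviation is zero. Requires >= 3 consecutive K values with >= 2
    replicates each.
    """
    if not {"K", "lnP"}.issubset(runs.columns):
        raise ValueError("runs must have columns 'K' and 'lnP'")
    df = runs.copy()
    if "replicate" in df.columns:
        df = df.sort_values(["K", "replicate"])
    ks = sorted(df["K"].unique())
    if len(ks) < 3:
        raise ValueError("need >= 3 K values")
    if any(b - a != ks[1] - ks[0] for a, b in zip(ks, ks[1:])) or ks[1] - ks[0] != 1:
        raise ValueError("K values must be consecutive integers")
    series = {k: df.loc[df["K"] == k, "lnP"].to_numpy(dtype=float) for k in ks}
    counts = {k: len(v) for k, v in series.items()}
    if min(counts.values()) < 2:
        raise ValueError("need >= 2 replicates per K")
    aligned = min(counts.values()) == max(counts.values())
    rows = []
    for i, k in enumerate(ks):
        v = series[k]
        sd = float(np.std(v, ddof=1))
        mean = float(np.mean(v))
        if 0 < i < len(ks) - 1:
            if aligned:
                second = series[ks[i - 1]] - 2 * v + series[ks[i + 1]]
                l2 = float(np.mean(np.abs(second)))
            else:  # unequal replicate counts: fall back to means
                l2 = abs(
                    np.mean(series[ks[i - 1]]) - 2 * mean + np.mean(series[ks[i + 1]])
                )
            if sd == 0:
                delta = np.nan
                logger.warning("zero sd at K=%s: delta-K undefined", k)
            else:
                delta = l2 / sd
        else:
            l2, delta = np.nan, np.nan
        l1 = mean - float(np.mean(series[ks[i - 1]])) if i > 0 else np.nan
        rows.append(
            {
                "K": k,
                "n_runs": counts[k],
                "mean_lnP": mean,
                "sd_lnP": sd,
                "L1": l1,
                "L2": l2,
                "delta_K": delta,
            }
        )
    table = pd.DataFrame(rows)
    interior = table["delta_K"].dropna()
    best = int(table.loc[interior.idxmax(), "K"]) if interior.size else None
    return EvannoTable(table=table, best_K=best)
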