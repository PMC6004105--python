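"""Synthetic dominant-marker and trait datasets with known ground truth.

Markers follow an F-model (island-model stand-in): each locus draws an
ancestral null-allele frequency ``q0`` from a Beta distribution with mean
``q_bar``; each population then draws its own frequency

    q_i ~ Beta(q0 (1-F)/F, (1-q0) (1-F)/F),

whose mean is ``q0`` and whose variance is ``F q0 (1-q0)``, so the
expected differentiation among populations equals ``F`` exactly.
Individuals are band-absent with probability ``q_i**2`` (Hardy-Weinberg,
dominant scoring). No migration history or linkage is modelled: the
estimators under test only ever see frequencies, and the F-model pins the
target F they should recover.

Traits are Gaussian random-effects draws: per trait, population effects
~ Normal(0, sigma2_B) and individual deviations ~ Normal(0, sigma2_W), so
the expected P_ST at c = h2 = 1 is sigma2_B/(sigma2_B + 2*sigma2_W).
Heritability enters analysis only through the ratio r = c/h2; simulated
phenotypes are not decomposed into additive and environmental parts.

Defaults mirror the field study the pipeline is shaped around: 10
populations with 8-20 sampled individuals (151 in total), 171 binary loci,
F = 0.365, and 7 traits whose variance ratio puts the expected overall
P_ST near 0.17.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from pstfst.io import (
    LabelledDistanceMatrix,
    MarkerMatrix,
    TraitTable,
    write_marker_matrix,
    write_square_matrix,
    write_trait_table,
)

#: per-population sample sizes of the default study layout (sum = 151)
DEFAULT_POP_SIZES = (18, 8, 10, 15, 14, 13, 20, 13, 20, 20)

DEFAULT_TRAIT_NAMES = (
    "Pl_H",
    "Lat_spr",
    "N_leav",
    "Infl_sz",
    "Comp_umb",
    "Simp_umb",
    "SW",
)

#: per-trait baseline (in within-population sd units) and scale, so the
#: seven traits live on distinct, plant-like scales; P_ST is scale-free.
_TRAIT_BASE = 8.0
_TRAIT_SCALES = (7.5, 5.5, 1.3, 0.8, 0.45, 3.8, 0.0025)


@dataclass
class SimulationConfig:
    """Ground-truth parameters for the synthetic datasets."""

    n_pops: int = 10
    n_ind: int | tuple[int, ...] = DEFAULT_POP_SIZES
    n_loci: int = 171
    F: float = 0.365
    q_bar: float = 0.75
    theta: float = 2.0  # dispersion of the ancestral Beta (moderate)
    sigma2_B: float = 0.41
    sigma2_W: float = 1.0
    h2: float = 1.0
    n_traits: int = 7
    env_corr: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.F < 1:
            raise ValueError("F must lie in (0, 1)")
        if not 0 < self.q_bar < 1:
            raise ValueError("q_bar must lie in (0, 1)")
        if self.sigma2_B < 0 or self.sigma2_W < 0:
            raise ValueError("variance components must be >= 0")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must lie in (0, 1]")
        if not 0 <= self.env_corr <= 1:
            raise ValueError("env_corr must lie in [0, 1]")
        if self.n_pops < 1 or self.n_loci < 1 or self.n_traits < 1:
            raise ValueError("sizes must be >= 1")

    @property
    def pop_sizes(self) -> np.ndarray:
        if np.isscalar(self.n_ind):
            sizes = np.full(self.n_pops, int(self.n_ind))
        else:
            sizes = np.asarray(self.n_ind, dtype=int)
            if sizes.size != self.n_pops:
                raise ValueError("n_ind list length must equal n_pops")
        if np.any(sizes < 1):
            raise ValueError("population sizes must be >= 1")
        return sizes

    @property
    def expected_pst(self) -> float:
        """Expected overall P_ST at c = h2 = 1 under the generative model."""
        return self.sigma2_B / (self.sigma2_B + 2 * self.sigma2_W)

    def pop_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_pops)]


@dataclass
class SimulatedDataset:
    markers: MarkerMatrix
    traits: TraitTable
    coordinates: pd.DataFrame  # population, x, y
    geo_distance: LabelledDistanceMatrix
    env_distance: LabelledDistanceMatrix
    truth: dict


def _population_frequencies(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-locus ancestral q0 and per-population q_i under the F-model."""
    a0 = cfg.q_bar * cfg.theta
    b0 = (1 - cfg.q_bar) * cfg.theta
    q0 = rng.beta(a0, b0, size=cfg.n_loci)
    q0 = np.clip(q0, 1e-6, 1 - 1e-6)
    scale = (1 - cfg.F) / cfg.F
    q_i = rng.beta(
        np.tile(q0 * scale, (cfg.n_pops, 1)),
        np.tile((1 - q0) * scale, (cfg.n_pops, 1)),
    )
    return q0, np.clip(q_i, 1e-9, 1 - 1e-9)


def simulate_markers(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> MarkerMatrix:
    """Simulate a dominant binary marker matrix with target differentiation F."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    _, q_i = _population_frequencies(cfg, rng)
    sizes = cfg.pop_sizes
    pops = cfg.pop_names()
    ids, pop_of, rows = [], {}, []
    for i, (p, n_p) in enumerate(zip(pops, sizes)):
        absent = rng.random((n_p, cfg.n_loci)) < q_i[i] ** 2
        rows.append(1.0 - absent)
        for j in range(n_p):
            ind = f"{p}_{j + 1:02d}"
            ids.append(ind)
            pop_of[ind] = p
    return MarkerMatrix(
        individual_ids=ids,
        population_of=pop_of,
        bands=np.vstack(rows),
        locus_ids=[f"L{j + 1:03d}" for j in range(cfg.n_loci)],
    )


def simulate_traits(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> TraitTable:
    """Simulate quantitative traits with known variance components."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sizes = cfg.pop_sizes
    pops = cfg.pop_names()
    names = list(DEFAULT_TRAIT_NAMES[: cfg.n_traits]) + [
        f"T{i + 1}" for i in range(len(DEFAULT_TRAIT_NAMES), cfg.n_traits)
    ]
    scales = [
        _TRAIT_SCALES[i % len(_TRAIT_SCALES)] for i in range(cfg.n_traits)
    ]
    pop_eff = rng.normal(0.0, np.sqrt(cfg.sigma2_B), size=(cfg.n_pops, cfg.n_traits))
    ids, pop_of, blocks = [], {}, []
    for i, (p, n_p) in enumerate(zip(pops, sizes)):
        dev = rng.normal(0.0, np.sqrt(cfg.sigma2_W), size=(n_p, cfg.n_traits))
        vals = (_TRAIT_BASE + pop_eff[i] + dev) * np.asarray(scales)
        blocks.append(vals)
        for j in range(n_p):
            ind = f"{p}_{j + 1:02d}"
            ids.append(ind)
            pop_of[ind] = p
    return TraitTable(
        individual_ids=ids,
        population_of=pop_of,
        values=np.vstack(blocks),
        trait_ids=names,
    )


def _distances_from_points(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def simulate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Markers, traits, coordinates and an environmental distance matrix.

    ``env_corr`` couples geography/environment to the genetic divergence of
    the simulated populations: at 0 they are independent, at 1 the
    environmental distance is exactly a monotone (linear) function of the
    between-population allele-frequency distance, and the coordinates are a
    planar embedding of it.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    marker_rng, trait_rng, geo_rng = rng.spawn(3)
    markers = simulate_markers(cfg, marker_rng)
    traits = simulate_traits(cfg, trait_rng)
    pops = cfg.pop_names()

    # between-population divergence of realised band frequencies
    from pstfst.markers import band_frequencies

    _, freq, _ = band_frequencies(markers)
    G = _distances_from_points(np.nan_to_num(freq))
    gmax = G.max()
    g_unit = G / gmax if gmax > 0 else G

    # random geography, blended with a planar embedding of g_unit
    random_pts = geo_rng.random((cfg.n_pops, 2)) * 10.0
    embed = _classical_mds(g_unit, 2)
    coords_pts = cfg.env_corr * embed + (1 - cfg.env_corr) * random_pts
    geo = _distances_from_points(coords_pts)

    noise_pts = geo_rng.random((cfg.n_pops, 2)) * 10.0
    noise_d = _distances_from_points(noise_pts)
    nmax = noise_d.max()
    env = cfg.env_corr * g_unit + (1 - cfg.env_corr) * (
        noise_d / nmax if nmax > 0 else noise_d
    )
    np.fill_diagonal(env, 0.0)

    coordinates = pd.DataFrame(
        {"population": pops, "x": coords_pts[:, 0], "y": coords_pts[:, 1]}
    )
    truth = asdict(cfg)
    truth["n_ind"] = [int(s) for s in cfg.pop_sizes]
    truth["expected_pst"] = cfg.expected_pst
    return SimulatedDataset(
        markers=markers,
        traits=traits,
        coordinates=coordinates,
        geo_distance=LabelledDistanceMatrix(labels=pops, values=geo),
        env_distance=LabelledDistanceMatrix(labels=pops, values=env),
        truth=truth,
    )


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bm = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(Bm)
    order = np.argsort(w)[::-1][:k]
    w_pos = np.clip(w[order], 0, None)
    return V[:, order] * np.sqrt(w_pos)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write the bundle through the standard formats, plus a truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_marker_matrix(ds.markers, outdir / "markers.tsv")
    write_trait_table(ds.traits, outdir / "traits.tsv")
    write_square_matrix(ds.geo_distance, outdir / "geo_distance.phy")
    write_square_matrix(ds.env_distance, outdir / "env_distance.phy")
    ds.coordinates.to_csv(outdir / "coordinates.tsv", sep="\t", index=False)
    truth = pd.DataFrame(
        [(k, str(v)) for k, v in ds.truth.items()], columns=["parameter", "value"]
    )
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
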