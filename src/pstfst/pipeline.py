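"""End-to-end orchestration: diversity -> F_ST -> AMOVA -> P_ST -> Mantel.

One :class:`RunConfig` drives the whole analysis and every stage writes its
table into the output directory, mirroring the layout of a population
study report: a per-population diversity table, the gene-diversity
partition with the gene-flow estimate, the Wright-style F_ST summary and
pairwise matrix, the AMOVA table, the Nei-Li individual distance matrix,
the P_ST report with its c/h2 sensitivity curve and selection
classification, and Mantel tests with Holm-corrected p-values. A JSON
manifest records the package version, the seed and every statistical
option in effect, so a run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pstfst import __version__, markers, stats
from pstfst.amova import amova as run_amova, pairwise_sq_euclidean
from pstfst.pst import (
    overall_sensitivity_curve,
    pairwise_pst,
    pst_fst_comparison,
)
from pstfst.io import (
    LabelledDistanceMatrix,
    MarkerMatrix,
    TraitTable,
    read_marker_matrix,
    read_run_config,
    read_square_matrix,
    read_trait_table,
    write_result_table,
    write_square_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    markers: str | None = None
    traits: str | None = None
    distance_matrices: dict[str, str] = field(default_factory=dict)
    regions: dict[str, str] | None = None
    fst_method: str = "beta_fmodel"
    diversity_method: str = "sqrt"
    polymorphism_criterion: float = 1.0
    c: float = 1.0
    h2: float = 1.0
    n_boot: int = 1000
    n_perm_fst: int = 1000
    n_perm_amova: int = 999
    n_perm_mantel: int = 9999
    mantel_tail: str = "two-sided"
    holm_families: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "pstfst_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = read_run_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name):
    """Wrap a stage so failures carry the stage name and input pointer."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-raise with context
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_full_analysis(
    cfg: RunConfig,
    marker_matrix: MarkerMatrix | None = None,
    trait_table: TraitTable | None = None,
    extra_distances: dict[str, LabelledDistanceMatrix] | None = None,
) -> dict:
    """Run every applicable stage and write the report bundle.

    Inputs may be passed as in-memory objects (e.g. straight from the
    simulator) or read from the paths in ``cfg``. Trait stages are skipped
    with an explicit notice when no trait table is available.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.seed)
    results: dict = {"skipped": []}

    if marker_matrix is None:
        if cfg.markers is None:
            raise RuntimeError("stage 'input' failed: no marker matrix given")
        marker_matrix = _stage("read_markers")(read_marker_matrix)(cfg.markers)
    if trait_table is None and cfg.traits is not None:
        trait_table = _stage("read_traits")(read_trait_table)(cfg.traits)
    distances = dict(extra_distances or {})
    for name, path in cfg.distance_matrices.items():
        distances[name] = _stage(f"read_distance[{name}]")(read_square_matrix)(path)

    # ----------------------------------------------------------- diversity
    div = _stage("diversity")(markers.diversity_summary)(
        marker_matrix,
        method=cfg.diversity_method,
        polymorphism_criterion=cfg.polymorphism_criterion,
    )
    write_result_table(div, outdir / "diversity.tsv", seed=seed)
    results["diversity"] = div

    freqs = _stage("allele_frequencies")(markers.allele_frequencies)(
        marker_matrix, method=cfg.diversity_method
    )
    part = _stage("gst_partition")(markers.gst_partition)(freqs)
    part_df = pd.DataFrame(
        [
            {
                "H_T": part.H_T,
                "H_S": part.H_S,
                "G_ST": part.G_ST,
                "Nm": np.nan if part.Nm is None else part.Nm,
                "method": cfg.diversity_method,
            }
        ]
    )
    write_result_table(part_df, outdir / "gene_diversity_partition.tsv", seed=seed)
    results["partition"] = part

    # ----------------------------------------------------------------- Fst
    fst = _stage("fst")(markers.fst_wright)(
        marker_matrix,
        method=cfg.fst_method,
        n_boot=cfg.n_boot,
        n_perm=cfg.n_perm_fst,
        seed=seed,
    )
    results["fst"] = fst
    write_square_matrix(fst.fst_pairwise, outdir / "fst_pairwise.phy")
    fst_df = pd.DataFrame(
        [
            {
                "fst": fst.fst_overall,
                "fst_raw": fst.fst_raw,
                "ci95_low": fst.ci95[0],
                "ci95_high": fst.ci95[1],
                "perm_p": fst.perm_p,
                "n_boot": fst.n_boot,
                "n_perm": fst.n_perm,
                "method": fst.method,
            }
        ]
    )
    write_result_table(fst_df, outdir / "fst_summary.tsv", seed=seed)

    # --------------------------------------------------------------- AMOVA
    d2 = _stage("pairwise_sq_euclidean")(pairwise_sq_euclidean)(marker_matrix)
    pops_of = marker_matrix.population_of
    regions = cfg.regions if cfg.regions else marker_matrix.region_of
    am = _stage("amova")(run_amova)(
        d2, pops_of, regions=regions, n_perm=cfg.n_perm_amova, seed=seed
    )
    results["amova"] = am
    am_table = am.table.copy()
    comp = {
        "among_regions": am.sigma2_a,
        "among_populations": am.sigma2_b,
        "among_populations_within_regions": am.sigma2_b,
        "within_populations": am.sigma2_c,
    }
    am_table["variance_component"] = [
        comp.get(s, np.nan) for s in am_table["stratum"]
    ]
    pctmap = dict(am.percentages)
    pctmap["among_populations_within_regions"] = pctmap.get("among_populations")
    am_table["pct_of_total"] = [pctmap.get(s, np.nan) for s in am_table["stratum"]]
    phis = {"phi_st": am.phi_st, "phi_sc": am.phi_sc, "phi_rt": am.phi_rt}
    extra = pd.DataFrame(
        [
            {
                "stratum": f"Phi:{k}",
                "df": np.nan,
                "SS": np.nan,
                "MS": np.nan,
                "variance_component": v,
                "pct_of_total": am.p_values.get(k, np.nan),
            }
            for k, v in phis.items()
            if v is not None
        ]
    )
    write_result_table(
        pd.concat([am_table, extra], ignore_index=True),
        outdir / "amova.tsv",
        seed=seed,
    )

    # ------------------------------------------------------------- Nei-Li
    nl = _stage("nei_li")(markers.nei_li_distance)(marker_matrix)
    write_square_matrix(nl, outdir / "nei_li_individuals.phy", fmt="%.6f")
    results["nei_li"] = nl

    # ----------------------------------------------------------------- Pst
    if trait_table is None:
        logger.warning("no trait table: P_ST stages skipped")
        results["skipped"].append("pst")
        (outdir / "SKIPPED_pst.txt").write_text(
            "P_ST stages skipped: no trait table provided\n"
        )
        pst_res = None
    else:
        pst_res = _stage("pst")(pairwise_pst)(
            trait_table, c=cfg.c, h2=cfg.h2, n_boot=cfg.n_boot, seed=seed
        )
        results["pst"] = pst_res
        rows = []
        for it, trait in enumerate(pst_res.traits):
            Mt = pst_res.pairwise_by_trait[trait]
            for p1, p2 in pst_res.pairs:
                i, j = Mt.labels.index(p1), Mt.labels.index(p2)
                rows.append(
                    {"trait": trait, "pop1": p1, "pop2": p2, "pst": Mt.values[i, j]}
                )
        for p1, p2 in pst_res.pairs:
            i = pst_res.pair_average.labels.index(p1)
            j = pst_res.pair_average.labels.index(p2)
            rows.append(
                {
                    "trait": "AVERAGE",
                    "pop1": p1,
                    "pop2": p2,
                    "pst": pst_res.pair_average.values[i, j],
                }
            )
        write_result_table(pd.DataFrame(rows), outdir / "pst_pairwise.tsv", seed=seed)

        fst_cond = fst.fst_pairwise.condensed()
        pst_cond = pst_res.pair_average.condensed()
        comparison = _stage("pst_fst_comparison")(pst_fst_comparison)(
            pst_cond, fst_cond
        )
        results["comparison"] = comparison

        fst_lower = fst.ci95[0]
        curve = None
        r_star = None
        if np.isfinite(fst_lower) and 0 < fst_lower < 1:
            curve = _stage("sensitivity")(overall_sensitivity_curve)(
                trait_table, fst_lower
            )
            crossing = curve.loc[curve["exceeds_fst_lower"], "r"]
            r_star = float(crossing.min()) if not crossing.empty else None
            write_result_table(curve, outdir / "pst_sensitivity_curve.tsv", seed=seed)
        results["r_star"] = r_star
        summary = pd.DataFrame(
            [
                {
                    "pst_total": pst_res.overall,
                    "ci95_low": pst_res.ci95[0],
                    "ci95_high": pst_res.ci95[1],
                    "pst_pairwise_mean": pst_res.pairwise_mean,
                    "anova_F": comparison.F,
                    "df1": comparison.df[0],
                    "df2": comparison.df[1],
                    "p": comparison.p,
                    "classification": comparison.classification,
                    "critical_ratio": np.nan if r_star is None else r_star,
                    "c": cfg.c,
                    "h2": cfg.h2,
                }
            ]
        )
        write_result_table(summary, outdir / "pst_summary.tsv", seed=seed)

    # -------------------------------------------------------------- Mantel
    mantel_rows = []
    mats: dict[str, LabelledDistanceMatrix] = {}
    fst_signed = LabelledDistanceMatrix(
        labels=fst.fst_pairwise.labels,
        values=fst.fst_pairwise.values,
        signed=True,
    )
    mats["FST"] = fst_signed
    if pst_res is not None:
        mats["PST"] = LabelledDistanceMatrix(
            labels=pst_res.pair_average.labels,
            values=np.nan_to_num(pst_res.pair_average.values),
            signed=True,
        )
    mats.update(distances)
    names = list(mats)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            try:
                mr = stats.mantel(
                    mats[n1],
                    mats[n2],
                    n_perm=cfg.n_perm_mantel,
                    seed=seed,
                    tail=cfg.mantel_tail,
                )
            except ValueError as exc:
                logger.warning("Mantel %s~%s skipped: %s", n1, n2, exc)
                continue
            mantel_rows.append(
                {"pair": f"{n1}~{n2}", "r_M": mr.r_M, "p": mr.p, "tail": mr.tail}
            )
    mantel_df = pd.DataFrame(mantel_rows)
    if not mantel_df.empty:
        families = cfg.holm_families or {"all": list(mantel_df["pair"])}
        mantel_df["family"] = "-"
        mantel_df["p_holm"] = np.nan
        for fam, members in families.items():
            mask = mantel_df["pair"].isin(members)
            if mask.any():
                mantel_df.loc[mask, "family"] = fam
                mantel_df.loc[mask, "p_holm"] = stats.holm_adjust(
                    mantel_df.loc[mask, "p"].to_numpy()
                )
        write_result_table(mantel_df, outdir / "mantel.tsv", seed=seed)
    results["mantel"] = mantel_df

    # ------------------------------------------------------------ manifest
    manifest = {
        "package": "pstfst",
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "stages_skipped": results["skipped"],
        "flags": {
            "fst_aggregation": "sum_over_loci_moment_match",
            "negative_fst_truncated": True,
            "pst_overall": "mean_over_traits_of_all_population_components",
            "pst_ci": "f_pivot_confidence_distribution",
            "mantel_tail": cfg.mantel_tail,
            "polymorphism_criterion": cfg.polymorphism_criterion,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
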