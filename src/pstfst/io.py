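"""Tabular input/output for marker matrices, trait tables and distance matrices.

All tables are individual-major (rows are individuals). Marker and trait
tables are delimited text with a header row; the first column is the
individual id, the second the population label, and an optional third
column named ``region`` assigns each population to a region. Square
distance matrices are read and written in Phylip style (first line ``n``,
then one label plus ``n`` values per row) or as a labelled delimited grid.

No statistics live here: this module only enforces the structural
invariants of the containers and round-trips them through text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: sentinel used for missing band scores / trait values in memory
MISSING = np.nan

_DELIMITERS = ("\t", ",")


def _sniff_delimiter(first_line: str, delimiter: str | None) -> str:
    """Auto-detection is deliberately limited to tab and comma."""
    if delimiter is not None:
        if delimiter not in _DELIMITERS:
            raise ValueError(
                f"unsupported delimiter {delimiter!r}: only tab and comma are handled"
            )
        return delimiter
    if "\t" in first_line:
        return "\t"
    return ","


@dataclass
class MarkerMatrix:
    """Binary band scores (presence/absence) per individual per locus.

    ``bands`` is an ``n_individuals x n_loci`` float array holding 0.0, 1.0
    or NaN (missing). Every individual belongs to exactly one population;
    if ``region_of`` is given, every population belongs to exactly one
    region.
    """

    individual_ids: list[str]
    population_of: dict[str, str]
    bands: np.ndarray
    locus_ids: list[str]
    region_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        n, L = self.bands.shape
        if n < 2:
            raise ValueError("a marker matrix needs at least 2 individuals")
        if L < 1:
            raise ValueError("a marker matrix needs at least 1 locus")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match bands rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match bands columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids")
        missing_assign = [i for i in self.individual_ids if i not in self.population_of]
        if missing_assign:
            raise ValueError(f"individuals without population: {missing_assign[:5]}")
        finite = self.bands[np.isfinite(self.bands)]
        if not np.all((finite == 0) | (finite == 1)):
            raise ValueError("bands must contain only 0, 1 or missing")
        if self.region_of is not None:
            for p in self.populations:
                if p not in self.region_of:
                    raise ValueError(f"population {p!r} has no region assignment")

    @property
    def n_individuals(self) -> int:
        return self.bands.shape[0]

    @property
    def n_loci(self) -> int:
        return self.bands.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for i in self.individual_ids:
            seen.setdefault(self.population_of[i], None)
        return list(seen)

    @property
    def population_labels(self) -> np.ndarray:
        """Per-individual population label, aligned with ``bands`` rows."""
        return np.array([self.population_of[i] for i in self.individual_ids])

    def population_indices(self) -> dict[str, np.ndarray]:
        labels = self.population_labels
        return {p: np.flatnonzero(labels == p) for p in self.populations}

    def subset_populations(self, pops: list[str]) -> "MarkerMatrix":
        keep = [
            i for i in self.individual_ids if self.population_of[i] in set(pops)
        ]
        rows = [self.individual_ids.index(i) for i in keep]
        return MarkerMatrix(
            individual_ids=keep,
            population_of={i: self.population_of[i] for i in keep},
            bands=self.bands[rows],
            locus_ids=list(self.locus_ids),
            region_of=self.region_of,
        )


@dataclass
class TraitTable:
    """Quantitative trait values per individual, with population labels."""

    individual_ids: list[str]
    population_of: dict[str, str]
    values: np.ndarray
    trait_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, t = self.values.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match values rows")
        if len(self.trait_ids) != t:
            raise ValueError("trait_ids length does not match values columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.trait_ids)) != t:
            raise ValueError("duplicate trait ids")
        for i in self.individual_ids:
            if i not in self.population_of:
                raise ValueError(f"individual {i!r} has no population assignment")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for i in self.individual_ids:
            seen.setdefault(self.population_of[i], None)
        return list(seen)

    @property
    def population_labels(self) -> np.ndarray:
        return np.array([self.population_of[i] for i in self.individual_ids])


@dataclass
class LabelledDistanceMatrix:
    """Square symmetric matrix with labels; optionally signed entries.

    ``signed=True`` marks a pairwise-statistic matrix (e.g. pairwise F_ST,
    whose raw estimates may be negative); otherwise entries must be >= 0.
    """

    labels: list[str]
    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix is not square or does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0, equal_nan=True):
            raise ValueError("matrix is asymmetric beyond tolerance 1e-9")
        if not np.allclose(np.diag(self.values), 0, atol=1e-9):
            raise ValueError("matrix diagonal is not zero")
        if not self.signed and np.nanmin(self.values) < -1e-9:
            raise ValueError("negative entries in an unsigned distance matrix")
        # exact symmetry and zero diagonal after validation
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy ``squareform`` order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reordered(self, labels: list[str]) -> "LabelledDistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return LabelledDistanceMatrix(
            labels=list(labels), values=self.values[np.ix_(idx, idx)], signed=self.signed
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty table")
    return df


def read_marker_matrix(
    path: str | Path, missing_code: str = "?", delimiter: str | None = None
) -> MarkerMatrix:
    """Read a binary band-score table.

    Layout: header row of locus ids; first column individual id, second
    column population label, optional third column ``region``. Cells must
    be 0, 1 or the missing code. Loci that are entirely missing are dropped
    with a logged warning.
    """
    df = _read_table(path, delimiter)
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError(f"{path}: need id, population and at least one locus column")
    has_region = cols[2].strip().lower() == "region"
    first_locus = 3 if has_region else 2
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate individual ids {dupes}")
    pops = df.iloc[:, 1].astype(str).tolist()
    population_of = dict(zip(ids, pops))
    region_of = None
    if has_region:
        region_of = {}
        for p, r in zip(pops, df.iloc[:, 2].astype(str)):
            if p in region_of and region_of[p] != r:
                raise ValueError(f"{path}: population {p!r} assigned to two regions")
            region_of[p] = r
    locus_ids = [str(c) for c in cols[first_locus:]]
    raw = df.iloc[:, first_locus:].to_numpy(dtype=object)
    bands = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell == missing_code or cell.lower() in ("nan", ""):
                bands[i, j] = MISSING
            elif cell in ("0", "1"):
                bands[i, j] = float(cell)
            else:
                raise ValueError(
                    f"{path}: cell {cell!r} at individual {ids[i]!r}, "
                    f"locus {locus_ids[j]!r} is not 0, 1 or {missing_code!r}"
                )
    all_missing = ~np.isfinite(bands).any(axis=0)
    if all_missing.any():
        dropped = [l for l, m in zip(locus_ids, all_missing) if m]
        logger.warning("%s: dropping %d entirely-missing loci: %s", path, len(dropped), dropped)
        bands = bands[:, ~all_missing]
        locus_ids = [l for l, m in zip(locus_ids, all_missing) if not m]
    return MarkerMatrix(
        individual_ids=ids,
        population_of=population_of,
        bands=bands,
        locus_ids=locus_ids,
        region_of=region_of,
    )


def write_marker_matrix(
    m: MarkerMatrix, path: str | Path, missing_code: str = "?", delimiter: str = "\t"
) -> None:
    with open(path, "w") as fh:
        header = ["id", "population"]
        if m.region_of is not None:
            header.append("region")
        header += m.locus_ids
        fh.write(delimiter.join(header) + "\n")
        for i, ind in enumerate(m.individual_ids):
            pop = m.population_of[ind]
            row = [ind, pop]
            if m.region_of is not None:
                row.append(m.region_of[pop])
            for v in m.bands[i]:
                row.append(missing_code if not np.isfinite(v) else str(int(v)))
            fh.write(delimiter.join(row) + "\n")


def read_trait_table(path: str | Path, delimiter: str | None = None) -> TraitTable:
    """Read a quantitative trait table; non-numeric cells become missing."""
    df = _read_table(path, delimiter)
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError(f"{path}: need id, population and at least one trait column")
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate individual ids")
    pops = df.iloc[:, 1].astype(str).tolist()
    trait_ids = [str(c) for c in cols[2:]]
    raw = df.iloc[:, 2:]
    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    n_coerced = int((~np.isfinite(values) & raw.notna().to_numpy()).sum())
    if n_coerced:
        logger.info("%s: %d non-numeric trait cells treated as missing", path, n_coerced)
    all_missing = [t for t, m in zip(trait_ids, (~np.isfinite(values)).all(axis=0)) if m]
    if all_missing:
        logger.warning("%s: traits with no data (retained, flagged): %s", path, all_missing)
    return TraitTable(
        individual_ids=ids,
        population_of=dict(zip(ids, pops)),
        values=values,
        trait_ids=trait_ids,
    )


def write_trait_table(t: TraitTable, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(delimiter.join(["id", "population"] + t.trait_ids) + "\n")
        for i, ind in enumerate(t.individual_ids):
            row = [ind, t.population_of[ind]]
            row += ["" if not np.isfinite(v) else repr(float(v)) for v in t.values[i]]
            fh.write(delimiter.join(row) + "\n")


def read_square_matrix(
    path: str | Path, signed: bool = False, delimiter: str | None = None
) -> LabelledDistanceMatrix:
    """Read a Phylip-style square matrix or a labelled delimited grid."""
    path = Path(path)
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    first_tokens = lines[0].split()
    if len(first_tokens) == 1 and first_tokens[0].isdigit():
        n = int(first_tokens[0])
        if len(lines) - 1 != n:
            raise ValueError(f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
        labels, rows = [], []
        for line in lines[1:]:
            toks = line.split()
            if len(toks) != n + 1:
                raise ValueError(f"{path}: row {toks[0]!r} does not have {n} values")
            labels.append(toks[0])
            rows.append([float(v) for v in toks[1:]])
        values = np.array(rows)
    else:
        sep = _sniff_delimiter(lines[0], delimiter)
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        labels = [str(l) for l in df.index]
        if [str(c) for c in df.columns] != labels:
            raise ValueError(f"{path}: row and column labels differ (matrix not square)")
        values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    if not np.allclose(values, values.T, atol=1e-9, rtol=0, equal_nan=True):
        raise ValueError(f"{path}: matrix is asymmetric beyond tolerance 1e-9")
    return LabelledDistanceMatrix(labels=labels, values=values, signed=signed)


def write_square_matrix(
    m: LabelledDistanceMatrix, path: str | Path, fmt: str = "%.10g"
) -> None:
    """Write in Phylip style; round-trip is value-exact at printed precision."""
    with open(path, "w") as fh:
        fh.write(f"{m.n}\n")
        for label, row in zip(m.labels, m.values):
            fh.write(label + "\t" + "\t".join(fmt % v for v in row) + "\n")


def write_result_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, index: bool = False
) -> None:
    """Write a result table as TSV with a header comment recording provenance."""
    from pstfst import __version__

    with open(path, "w") as fh:
        fh.write(f"# pstfst {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run configuration must be a mapping")
    return cfg
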