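"""Shared in-memory containers for phased haplotype data and window scaffolding.

The substrate of every scan in this package is a phased binary haplotype
matrix (2N haplotypes x S segregating sites) plus a sample-to-population map.
Coordinates follow the two standard dialects: VCF positions are 1-based;
windows and BED intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

PHENOTYPE_CLASSES = (
    "resident_continent",
    "short_SW",
    "med_NW",
    "med_SW",
    "med_SE",
    "long_SE",
    "island_azores",
    "island_canary",
    "island_capeverde",
    "outgroup",
)


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 alleles, haplotypes x segregating sites.

    alleles
        int8 array of shape (2N, S); 0 = REF, 1 = ALT, -1 = missing.
        Haplotypes come in consecutive pairs per diploid sample:
        sample i owns rows 2i and 2i+1.
    positions
        1-based physical coordinate per site, strictly increasing within
        a scaffold.
    scaffold
        sequence name per site (sites from the same scaffold contiguous).
    ref_alt
        (S, 2) array of REF/ALT allele strings.
    sample_ids
        N diploid sample names, in row-pair order.
    """

    alleles: np.ndarray
    positions: np.ndarray
    scaffold: np.ndarray
    ref_alt: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scaffold = np.asarray(self.scaffold, dtype=object)
        self.ref_alt = np.asarray(self.ref_alt, dtype=object)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[0] % 2 != 0:
            raise ValueError("haplotypes must come in diploid pairs")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ValueError("positions length must match number of sites")
        if not np.isin(self.alleles, (0, 1, MISSING)).all():
            raise ValueError("alleles must be 0, 1 or -1 (missing)")
        for scaf in np.unique(self.scaffold):
            pos = self.positions[self.scaffold == scaf]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on scaffold {scaf}"
                )

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def take_sites(self, index) -> "HaplotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        index = np.asarray(index)
        return replace(
            self,
            alleles=self.alleles[:, index],
            positions=self.positions[index],
            scaffold=self.scaffold[index],
            ref_alt=self.ref_alt[index],
        )

    def take_haplotypes(self, rows, sample_ids=None) -> "HaplotypeMatrix":
        rows = np.asarray(rows)
        return replace(
            self,
            alleles=self.alleles[rows],
            sample_ids=list(sample_ids) if sample_ids is not None else [],
        )

    def scaffolds(self):
        """Scaffold names in order of first appearance."""
        _, idx = np.unique(self.scaffold, return_index=True)
        return [self.scaffold[i] for i in np.sort(idx)]


@dataclass
class PopulationMap:
    """Sample -> population/phenotype assignment.

    Backed by a DataFrame with columns sample_id, population,
    phenotype_class and (optionally) distance_code (ordinal 1-3).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "population", "phenotype_class")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"population map missing column {col!r}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids in population map: {list(dups)}")
        bad = set(self.table["phenotype_class"]) - set(PHENOTYPE_CLASSES)
        if bad:
            raise ValueError(f"unknown phenotype_class values: {sorted(bad)}")

    @classmethod
    def from_records(cls, records) -> "PopulationMap":
        return cls(pd.DataFrame.from_records(
            records, columns=["sample_id", "population", "phenotype_class", "distance_code"]
        ))

    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        return cls(df)

    def write_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self):
        return list(self.table["sample_id"])

    def populations(self, include_outgroup: bool = False):
        t = self.table
        if not include_outgroup:
            t = t[t["phenotype_class"] != "outgroup"]
        return list(dict.fromkeys(t["population"]))

    def outgroup_populations(self):
        t = self.table[self.table["phenotype_class"] == "outgroup"]
        return list(dict.fromkeys(t["population"]))

    def samples_in(self, population):
        t = self.table
        return list(t.loc[t["population"] == population, "sample_id"])

    def population_of(self, sample_id):
        t = self.table
        row = t.loc[t["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in population map")
        return row["population"].iloc[0]

    def shuffled(self, rng) -> "PopulationMap":
        """Permute population labels across individuals, preserving sizes."""
        t = self.table.copy()
        ingroup = t["phenotype_class"] != "outgroup"
        idx = np.flatnonzero(ingroup.to_numpy())
        perm = rng.permutation(idx)
        for col in ("population", "phenotype_class", "distance_code"):
            if col in t.columns:
                t.iloc[idx, t.columns.get_loc(col)] = t.iloc[perm][col].to_numpy()
        return PopulationMap(t)


def haplotype_index(matrix: HaplotypeMatrix, popmap: PopulationMap) -> dict:
    """Map population label -> haplotype row indices in `matrix`.

    Raises if a mapped sample is absent from the matrix.
    """
    if not matrix.sample_ids:
        raise ValueError("matrix carries no sample ids")
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    out = {}
    for pop in popmap.populations(include_outgroup=True):
        rows = []
        for s in popmap.samples_in(pop):
            if s not in col:
                raise KeyError(f"sample {s!r} in population map absent from VCF/matrix")
            i = col[s]
            rows.extend((2 * i, 2 * i + 1))
        out[pop] = np.array(rows, dtype=np.intp)
    return out


def allele_frequencies(matrix: HaplotypeMatrix, rows=None):
    """Per-site ALT frequency and non-missing haplotype count over `rows`."""
    a = matrix.alleles if rows is None else matrix.alleles[np.asarray(rows)]
    ok = a != MISSING
    n = ok.sum(axis=0)
    cnt = np.where(ok, a, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, cnt / np.maximum(n, 1), np.nan)
    return p, n


def filter_site_index(
    matrix: HaplotypeMatrix,
    popmap: PopulationMap,
    maf_min: float = 0.05,
    min_individuals: int = 5,
) -> np.ndarray:
    """Indices of sites surviving the MAF/completeness filter."""
    hidx = haplotype_index(matrix, popmap)
    ingroup_pops = popmap.populations(include_outgroup=False)
    pooled = np.concatenate([hidx[p] for p in ingroup_pops])
    p, n = allele_frequencies(matrix, pooled)
    maf = np.minimum(p, 1 - p)
    keep = (n > 0) & (maf >= maf_min)
    for pop in ingroup_pops:
        rows = hidx[pop]
        a = matrix.alleles[rows]
        ok = (a != MISSING).reshape(len(rows) // 2, 2, -1).all(axis=1)
        keep &= ok.sum(axis=0) >= min_individuals
    if not keep.any():
        raise ValueError(
            "all sites removed by filter_sites; review maf_min/min_individuals"
        )
    return np.flatnonzero(keep)


def filter_sites(
    matrix: HaplotypeMatrix,
    popmap: PopulationMap,
    maf_min: float = 0.05,
    min_individuals: int = 5,
) -> HaplotypeMatrix:
    """Site inclusion filter: global MAF and per-population completeness.

    Keeps sites with pooled-ingroup minor-allele frequency >= `maf_min`
    (outgroup samples excluded from the pool) and at least
    `min_individuals` diploid individuals fully genotyped in every
    non-outgroup population. Idempotent.
    """
    return matrix.take_sites(
        filter_site_index(matrix, popmap, maf_min=maf_min, min_individuals=min_individuals)
    )


@dataclass
class WindowTable:
    """Fixed-width half-open windows tiling each scaffold.

    `table` has columns scaffold, start, end (0-based half-open) plus one
    column per statistic added downstream. Width is constant except for
    terminal windows.
    """

    table: pd.DataFrame
    width: int

    def __len__(self):
        return len(self.table)

    def site_window(self, matrix: HaplotypeMatrix) -> np.ndarray:
        """Row index into `table` for each site of `matrix` (-1 if outside)."""
        key = {}
        for i, row in enumerate(self.table.itertuples(index=False)):
            key[(row.scaffold, row.start // self.width)] = i
        out = np.full(matrix.n_sites, -1, dtype=np.intp)
        for j in range(matrix.n_sites):
            k = (matrix.scaffold[j], (int(matrix.positions[j]) - 1) // self.width)
            out[j] = key.get(k, -1)
        return out


def make_windows(
    matrix: HaplotypeMatrix, width: int = 2500, scaffold_lengths: dict | None = None
) -> WindowTable:
    """Tile each scaffold with half-open windows of `width` bp.

    Scaffold extent defaults to the last site position; a terminal window
    is truncated at the scaffold end. Site at 1-based position x maps to
    the window containing x-1.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for scaf in matrix.scaffolds():
        pos = matrix.positions[matrix.scaffold == scaf]
        length = int(scaffold_lengths[scaf]) if scaffold_lengths else int(pos.max())
        start = 0
        while start < length:
            rows.append((scaf, start, min(start + width, length)))
            start += width
    return WindowTable(
        pd.DataFrame(rows, columns=["scaffold", "start", "end"]), width=width
    )


@dataclass
class RegionCall:
    """A run of adjacent windows above a calling threshold."""

    scaffold: str
    start: int
    end: int
    statistic: str
    population: str
    peak_value: float
    windows: list  # row indices of member windows

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    def to_bed6(self) -> str:
        score = int(np.clip(round(self.peak_value * 1000), 0, 1000))
        name = f"{self.statistic}:{self.population}"
        return f"{self.scaffold}\t{self.start}\t{self.end}\t{name}\t{score}\t."
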