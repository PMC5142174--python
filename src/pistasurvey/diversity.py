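"""SSR diversity statistics: per-locus allele metrics, cross-species marker
transferability, and species-level summaries.

Conventions follow the tools SSR studies commonly report with: expected
heterozygosity is the plug-in (biased) form He = 1 - sum(p_i^2); PIC is the
Botstein form 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2; Ho counts
heterozygous individuals among typed individuals only. A "null" call marks
species-level non-amplification (a marker that does not transfer to that
species), distinct from sporadically missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "NULL",
    "GenotypeTable",
    "LocusStats",
    "SpeciesSummary",
    "allele_freqs",
    "locus_stats",
    "transferability",
    "species_summary",
    "universal_loci",
    "summarize_locus_table",
]

MISSING = -1  # sporadic missing call
NULL = -2     # species-level non-amplification


class GenotypeTable:
    """Diploid allele-size calls for individuals (with species labels) x loci.

    Internally two int arrays ``a1``/``a2`` of shape (n_individuals, n_loci)
    holding allele sizes in bp, or the sentinels MISSING (-1) / NULL (-2).
    Both allele slots of a call always share sentinel status.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        species: Sequence[str],
        loci: Sequence[str],
        a1: np.ndarray,
        a2: np.ndarray,
    ) -> None:
        self.individuals = list(individuals)
        self.species = list(species)
        self.loci = list(loci)
        self.a1 = np.asarray(a1, dtype=np.int64)
        self.a2 = np.asarray(a2, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if len(self.species) != n:
            raise ValueError("species labels must match individuals")
        if self.a1.shape != (n, L) or self.a2.shape != (n, L):
            raise ValueError(f"allele arrays must have shape {(n, L)}")
        if np.any((self.a1 < 0) != (self.a2 < 0)):
            raise ValueError("half-missing calls are not representable")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s)
        return list(seen)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def species_rows(self, species: str) -> np.ndarray:
        rows = np.array([i for i, s in enumerate(self.species) if s == species])
        if rows.size == 0:
            raise KeyError(f"unknown species {species!r}")
        return rows

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): call present (neither missing nor null)."""
        return self.a1 >= 0

    def validate_null_consistency(self) -> None:
        """A locus null for one individual of a species must be null for all."""
        for sp in self.species_names:
            rows = self.species_rows(sp)
            isnull = self.a1[rows] == NULL
            bad = np.any(isnull, axis=0) & ~np.all(isnull, axis=0)
            if np.any(bad):
                names = [self.loci[j] for j in np.flatnonzero(bad)]
                raise ValueError(f"inconsistent null calls for {sp}: {names}")

    def subset(
        self,
        individuals: Sequence[int] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        cols = (
            np.arange(self.n_loci)
            if loci is None
            else np.array([self.locus_index(l) for l in loci])
        )
        return GenotypeTable(
            [self.individuals[i] for i in rows],
            [self.species[i] for i in rows],
            [self.loci[j] for j in cols],
            self.a1[np.ix_(rows, cols)],
            self.a2[np.ix_(rows, cols)],
        )

    # -- CSV dialect -----------------------------------------------------
    # columns: id, species, then "<locus>.a1","<locus>.a2" per locus;
    # missing = empty cell, species-null = "NULL".
    def to_csv(self, path) -> None:
        def cell(v: int) -> str:
            if v == MISSING:
                return ""
            if v == NULL:
                return "NULL"
            return str(v)

        with open(path, "w") as fh:
            header = ["id", "species"]
            for locus in self.loci:
                header += [f"{locus}.a1", f"{locus}.a2"]
            fh.write(",".join(header) + "\n")
            for i, (ind, sp) in enumerate(zip(self.individuals, self.species)):
                row = [ind, sp]
                for j in range(self.n_loci):
                    row += [cell(self.a1[i, j]), cell(self.a2[i, j])]
                fh.write(",".join(row) + "\n")

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if list(df.columns[:2]) != ["id", "species"]:
            raise ValueError("genotype CSV must start with 'id,species' columns")
        allele_cols = list(df.columns[2:])
        loci: list[str] = []
        for c in allele_cols[::2]:
            if not c.endswith(".a1"):
                raise ValueError(f"expected '<locus>.a1' column, got {c!r}")
            loci.append(c[:-3])

        def parse(v: str) -> int:
            if v == "":
                return MISSING
            if v.upper() == "NULL":
                return NULL
            return int(v)

        vals = df[allele_cols].map(parse).to_numpy(dtype=np.int64)
        return cls(
            df["id"].tolist(), df["species"].tolist(), loci, vals[:, 0::2], vals[:, 1::2]
        )


def allele_freqs(
    table: GenotypeTable, locus: str, individuals: Sequence[int] | None = None
) -> dict[int, float]:
    """Allele frequencies over the 2n gene copies of typed individuals."""
    j = table.locus_index(locus)
    rows = np.arange(table.n_individuals) if individuals is None else np.asarray(individuals)
    a1, a2 = table.a1[rows, j], table.a2[rows, j]
    typed = a1 >= 0
    if not np.any(typed):
        raise ValueError(f"locus {locus!r} not amplified in subset")
    copies = np.concatenate([a1[typed], a2[typed]])
    alleles, counts = np.unique(copies, return_counts=True)
    freqs = counts / counts.sum()
    return {int(a): float(f) for a, f in zip(alleles, freqs)}


@dataclass(frozen=True)
class LocusStats:
    """Diversity metrics for one locus (one row of a marker table)."""

    locus: str
    allele_range: tuple[int, int]
    na: int       # observed allele count
    ne: float     # effective allele count, 1 / sum(p^2)
    ho: float     # observed heterozygosity
    he: float     # expected heterozygosity, 1 - sum(p^2)
    pic: float    # polymorphism information content (Botstein)
    n_typed: int


def _pic(p: np.ndarray) -> float:
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - (s2**2 - s4)


def locus_stats(
    table: GenotypeTable, locus: str, individuals: Sequence[int] | None = None
) -> LocusStats:
    freqs = allele_freqs(table, locus, individuals)
    j = table.locus_index(locus)
    rows = np.arange(table.n_individuals) if individuals is None else np.asarray(individuals)
    a1, a2 = table.a1[rows, j], table.a2[rows, j]
    typed = a1 >= 0
    n_typed = int(typed.sum())
    het = np.sum(a1[typed] != a2[typed])
    p = np.array(list(freqs.values()))
    s2 = float(np.sum(p**2))
    alleles = list(freqs)
    return LocusStats(
        locus=locus,
        allele_range=(min(alleles), max(alleles)),
        na=len(alleles),
        ne=1.0 / s2,
        ho=float(het / n_typed),
        he=1.0 - s2,
        pic=_pic(p),
        n_typed=n_typed,
    )


def transferability(table: GenotypeTable, species: str) -> float:
    """Percent of loci with at least one non-missing call in the species,
    reported to 1 decimal (the cross-species amplification rate)."""
    rows = table.species_rows(species)
    amplified = np.any(table.typed_mask()[rows], axis=0)
    return round(100.0 * amplified.sum() / table.n_loci, 1)


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-species marker panel summary: transferability plus means of the
    diversity metrics over loci polymorphic within the species."""

    species: str
    n_individuals: int
    n_amplified_loci: int
    transferability_percent: float
    n_polymorphic_loci: int
    total_polymorphic_alleles: int
    mean_na: float | None
    mean_ne: float | None
    mean_ho: float | None
    mean_he: float | None
    mean_pic: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def species_summary(table: GenotypeTable, species: str) -> SpeciesSummary:
    rows = table.species_rows(species)
    typed = table.typed_mask()[rows]
    amplified = np.flatnonzero(np.any(typed, axis=0))
    stats = [locus_stats(table, table.loci[j], rows) for j in amplified]
    poly = [s for s in stats if s.na >= 2]
    if poly:
        means = {
            f"mean_{k}": round(float(np.mean([getattr(s, k) for s in poly])), 2)
            for k in ("na", "ne", "ho", "he", "pic")
        }
    else:
        means = {f"mean_{k}": None for k in ("na", "ne", "ho", "he", "pic")}
    return SpeciesSummary(
        species=species,
        n_individuals=len(rows),
        n_amplified_loci=len(amplified),
        transferability_percent=transferability(table, species),
        n_polymorphic_loci=len(poly),
        total_polymorphic_alleles=sum(s.na for s in poly),
        **means,
    )


def universal_loci(table: GenotypeTable) -> tuple[list[str], list[str]]:
    """Loci amplified in every species, and loci polymorphic (Na >= 2)
    within every species."""
    amplified_all: list[str] = []
    polymorphic_all: list[str] = []
    species_rows = {sp: table.species_rows(sp) for sp in table.species_names}
    typed = table.typed_mask()
    for j, locus in enumerate(table.loci):
        amp = all(np.any(typed[rows, j]) for rows in species_rows.values())
        if not amp:
            continue
        amplified_all.append(locus)
        poly = True
        for rows in species_rows.values():
            if len(allele_freqs(table, locus, rows)) < 2:
                poly = False
                break
        if poly:
            polymorphic_all.append(locus)
    return amplified_all, polymorphic_all


def summarize_locus_table(
    stats: Sequence[LocusStats] | pd.DataFrame,
) -> dict[str, float]:
    """Column totals/means of a per-locus stats table: total allele count and
    unweighted means of Na, Ne, Ho, He, PIC, rounded to 2 decimals."""
    if isinstance(stats, pd.DataFrame):
        df = stats
    else:
        if not stats:
            raise ValueError("empty stats list")
        df = pd.DataFrame(
            {
                "na": [s.na for s in stats],
                "ne": [s.ne for s in stats],
                "ho": [s.ho for s in stats],
                "he": [s.he for s in stats],
                "pic": [s.pic for s in stats],
            }
        )
    if df.empty:
        raise ValueError("empty stats table")
    return {
        "n_loci": int(len(df)),
        "total_alleles": int(df["na"].sum()),
        "mean_na": round(float(df["na"].mean()), 2),
        "mean_ne": round(float(df["ne"].mean()), 2),
        "mean_ho": round(float(df["ho"].mean()), 2),
        "mean_he": round(float(df["he"].mean()), 2),
        "mean_pic": round(float(df["pic"].mean()), 2),
    }
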