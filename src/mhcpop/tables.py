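"""Genotype table containers shared across the analysis modules.

Two marker classes flow through the pipeline:

* multi-allele MHC amplicon genotypes, where an individual carries a *set*
  of 2-5 alleles that cannot be ascribed to loci (co-amplifying paralogs),
  and
* codominant diploid microsatellite genotypes with an unordered allele
  pair per locus.

Both containers are thin wrappers over plain-text tables so that every
intermediate of the pipeline stays inspectable with standard shell tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

MISSING = "./."


@dataclass
class MHCGenotypeTable:
    """Rows of (individual, population, allele-id set)."""

    individuals: list[str]
    populations: dict[str, str]
    allele_sets: dict[str, frozenset[str]]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, Iterable[str]]]
    ) -> "MHCGenotypeTable":
        inds, pops, sets_ = [], {}, {}
        for ind, pop, alleles in records:
            inds.append(ind)
            pops[ind] = pop
            sets_[ind] = frozenset(alleles)
        return cls(inds, pops, sets_)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def individuals_in(self, population: str) -> list[str]:
        return [i for i in self.individuals if self.populations[i] == population]

    def subset(self, individuals: Sequence[str]) -> "MHCGenotypeTable":
        keep = [i for i in self.individuals if i in set(individuals)]
        return MHCGenotypeTable(
            keep,
            {i: self.populations[i] for i in keep},
            {i: self.allele_sets[i] for i in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": self.individuals,
                "population": [self.populations[i] for i in self.individuals],
                "alleles": [
                    ";".join(sorted(self.allele_sets[i])) for i in self.individuals
                ],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MHCGenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_records(
            (r.individual, r.population, r.alleles.split(";"))
            for r in df.itertuples()
        )

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass
class MicrosatGenotypeTable:
    """Diploid genotypes: individual -> locus -> unordered allele pair.

    Allele labels are integers (fragment sizes or arbitrary codes); a
    missing genotype is ``None`` in memory and ``./.`` on disk.
    """

    individuals: list[str]
    populations: dict[str, str]
    loci: list[str]
    genotypes: dict[str, dict[str, tuple[int, int] | None]] = field(repr=False)

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def individuals_in(self, population: str) -> list[str]:
        return [i for i in self.individuals if self.populations[i] == population]

    def subset(self, individuals: Sequence[str]) -> "MicrosatGenotypeTable":
        keep = [i for i in self.individuals if i in set(individuals)]
        return MicrosatGenotypeTable(
            keep,
            {i: self.populations[i] for i in keep},
            list(self.loci),
            {i: self.genotypes[i] for i in keep},
        )

    def allele_counts(
        self, population: str, locus: str
    ) -> dict[int, int]:
        """Gene-copy counts of each allele at one locus in one population."""
        counts: dict[int, int] = {}
        for ind in self.individuals_in(population):
            pair = self.genotypes[ind].get(locus)
            if pair is None:
                continue
            for a in pair:
                counts[a] = counts.get(a, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            row: dict[str, str] = {
                "individual": ind,
                "population": self.populations[ind],
            }
            for locus in self.loci:
                pair = self.genotypes[ind].get(locus)
                row[locus] = MISSING if pair is None else f"{pair[0]}/{pair[1]}"
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MicrosatGenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        loci = [c for c in df.columns if c not in ("individual", "population")]
        inds, pops, geno = [], {}, {}
        for r in df.itertuples(index=False):
            d = r._asdict() if hasattr(r, "_asdict") else dict(zip(df.columns, r))
            ind = d["individual"]
            inds.append(ind)
            pops[ind] = d["population"]
            g: dict[str, tuple[int, int] | None] = {}
            for locus in loci:
                cell = d[locus]
                if cell == MISSING or pd.isna(cell):
                    g[locus] = None
                else:
                    a, b = cell.split("/")
                    g[locus] = (int(a), int(b))
            geno[ind] = g
        return cls(inds, pops, loci, geno)

    def __len__(self) -> int:
        return len(self.individuals)


def square_matrix_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a labelled square matrix (populations on both axes) as CSV."""
    df.to_csv(path)


def square_matrix_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
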