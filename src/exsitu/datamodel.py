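"""Core containers for diploid multilocus codominant genotype data.

The pipeline's universal currency is the :class:`GenotypeDataset`: a set of
individuals typed at a shared list of microsatellite loci, each carrying a
population label ("unknown" for captive individuals of unresolved origin),
optional sex/source metadata, an optional mtDNA control-region sequence and,
for synthetic data, a known-origin ground-truth label.

Internally genotypes are stored as an ``(n_individuals, n_loci, 2)`` integer
array of *registry indices* (``-1`` marks a missing locus); each
:class:`Locus` keeps the registry mapping indices back to allele codes
(fragment sizes). Allele frequencies are summarised per population in an
:class:`AlleleFrequencyTable`, which parameterises assignment, simulation and
relatedness downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING = -1

UNKNOWN_POP = "unknown"


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus and its dataset-wide allele registry.

    ``alleles`` holds the distinct allele codes (integers, typically fragment
    sizes) observed anywhere in the dataset, in sorted order; the number of
    allelic states ``k`` used by the assignment likelihood is its length.
    """

    locus_id: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate allele codes at locus {self.locus_id}")

    @property
    def k(self) -> int:
        return len(self.alleles)

    def index_of(self, code: int) -> int:
        try:
            return self.alleles.index(code)
        except ValueError:
            raise KeyError(
                f"allele code {code} not in registry of locus {self.locus_id}"
            ) from None


class Genotype:
    """Per-locus ordered pairs of allele registry indices; -1 = missing.

    Both alleles at a locus are present or both are missing (GENEPOP
    convention); half-missing genotypes are rejected.
    """

    __slots__ = ("indices",)

    def __init__(self, indices: np.ndarray):
        arr = np.asarray(indices, dtype=np.int32)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("genotype array must have shape (n_loci, 2)")
        half = (arr == MISSING).sum(axis=1) == 1
        if half.any():
            raise ValueError(
                f"half-missing genotype at locus index {int(np.nonzero(half)[0][0])}"
            )
        self.indices = arr

    @property
    def n_loci(self) -> int:
        return self.indices.shape[0]

    def is_missing(self) -> np.ndarray:
        """Boolean mask over loci, True where the locus is untyped."""
        return self.indices[:, 0] == MISSING

    @property
    def n_typed(self) -> int:
        return int((~self.is_missing()).sum())

    def codes(self, loci: Sequence[Locus]) -> list[tuple[int, int] | None]:
        out: list[tuple[int, int] | None] = []
        for l, locus in enumerate(loci):
            a, b = self.indices[l]
            if a == MISSING:
                out.append(None)
            else:
                out.append((locus.alleles[a], locus.alleles[b]))
        return out

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genotype) and np.array_equal(
            self.indices, other.indices
        )


@dataclass
class Individual:
    individual_id: str
    genotype: Genotype
    sex: str = "unknown"  # {M, F, unknown}
    source_collection: str = ""
    mtdna_sequence: str | None = None
    known_origin: str | None = None  # ground truth, synthetic data only


class GenotypeDataset:
    """Individuals x loci diploid allele calls with population labels.

    Parameters
    ----------
    loci
        Shared locus list; every genotype row spans it.
    ids
        Individual identifiers, unique.
    genotypes
        ``(n, n_loci, 2)`` int array of registry indices, -1 missing.
    populations
        Per-individual population label; ``"unknown"`` for query individuals.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        ids: Sequence[str],
        genotypes: np.ndarray,
        populations: Sequence[str],
        sex: Sequence[str] | None = None,
        source: Sequence[str] | None = None,
        mtdna: Sequence[str | None] | None = None,
        known_origin: Sequence[str | None] | None = None,
    ):
        self.loci = list(loci)
        self.ids = list(ids)
        G = np.asarray(genotypes, dtype=np.int32)
        n = len(self.ids)
        if G.shape != (n, len(self.loci), 2):
            raise ValueError(
                f"genotype array shape {G.shape} != ({n}, {len(self.loci)}, 2)"
            )
        if len(set(self.ids)) != n:
            raise ValueError("individual ids are not unique")
        half = (G == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = map(int, np.argwhere(half)[0])
            raise ValueError(
                f"half-missing genotype: individual {self.ids[i]}, locus "
                f"{self.loci[l].locus_id}"
            )
        for l, locus in enumerate(self.loci):
            if G[:, l, :].max(initial=MISSING) >= locus.k:
                raise ValueError(f"allele index out of registry at {locus.locus_id}")
        self.G = G
        self.populations = list(populations)
        if len(self.populations) != n:
            raise ValueError("populations length mismatch")
        self.sex = list(sex) if sex is not None else ["unknown"] * n
        self.source = list(source) if source is not None else [""] * n
        self.mtdna = list(mtdna) if mtdna is not None else [None] * n
        self.known_origin = (
            list(known_origin) if known_origin is not None else [None] * n
        )
        self._index = {iid: i for i, iid in enumerate(self.ids)}

    # -- basic views ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, individual_id: str) -> int:
        return self._index[individual_id]

    def genotype(self, individual_id: str) -> Genotype:
        return Genotype(self.G[self.row(individual_id)])

    def individual(self, individual_id: str) -> Individual:
        i = self.row(individual_id)
        return Individual(
            individual_id=individual_id,
            genotype=Genotype(self.G[i]),
            sex=self.sex[i],
            source_collection=self.source[i],
            mtdna_sequence=self.mtdna[i],
            known_origin=self.known_origin[i],
        )

    def population_of(self, individual_id: str) -> str:
        return self.populations[self.row(individual_id)]

    @property
    def population_ids(self) -> list[str]:
        """Distinct non-"unknown" population labels, in first-seen order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            if p != UNKNOWN_POP:
                seen.setdefault(p)
        return list(seen)

    @property
    def unknown_ids(self) -> list[str]:
        return [i for i, p in zip(self.ids, self.populations) if p == UNKNOWN_POP]

    def missing_fraction(self) -> float:
        if self.n_individuals == 0 or self.n_loci == 0:
            return 0.0
        return float((self.G[:, :, 0] == MISSING).mean())

    # -- manipulation --------------------------------------------------

    def subset(self, individual_ids: Iterable[str]) -> "GenotypeDataset":
        rows = [self.row(i) for i in individual_ids]
        return GenotypeDataset(
            self.loci,
            [self.ids[r] for r in rows],
            self.G[rows],
            [self.populations[r] for r in rows],
            sex=[self.sex[r] for r in rows],
            source=[self.source[r] for r in rows],
            mtdna=[self.mtdna[r] for r in rows],
            known_origin=[self.known_origin[r] for r in rows],
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.loci,
            list(self.ids),
            self.G.copy(),
            list(self.populations),
            sex=list(self.sex),
            source=list(self.source),
            mtdna=list(self.mtdna),
            known_origin=list(self.known_origin),
        )

    @staticmethod
    def concat(a: "GenotypeDataset", b: "GenotypeDataset") -> "GenotypeDataset":
        """Stack two datasets sharing an identical locus list/registries."""
        if [(l.locus_id, l.alleles) for l in a.loci] != [
            (l.locus_id, l.alleles) for l in b.loci
        ]:
            raise ValueError("datasets do not share locus registries")
        return GenotypeDataset(
            a.loci,
            a.ids + b.ids,
            np.concatenate([a.G, b.G], axis=0),
            a.populations + b.populations,
            sex=a.sex + b.sex,
            source=a.source + b.source,
            mtdna=a.mtdna + b.mtdna,
            known_origin=a.known_origin + b.known_origin,
        )

    @staticmethod
    def from_codes(
        locus_ids: Sequence[str],
        ids: Sequence[str],
        calls: Sequence[Sequence[tuple[int, int] | None]],
        populations: Sequence[str],
        **meta,
    ) -> "GenotypeDataset":
        """Build a dataset from raw allele-code calls.

        ``calls[i][l]`` is an ``(allele, allele)`` code pair or None for
        missing. Registries are the union of observed codes per locus.
        """
        n, L = len(ids), len(locus_ids)
        registries: list[list[int]] = []
        for l in range(L):
            codes = sorted(
                {c for row in calls for c in (row[l] if row[l] else ())}
            )
            registries.append(codes)
        loci = [Locus(locus_ids[l], tuple(registries[l])) for l in range(L)]
        G = np.full((n, L, 2), MISSING, dtype=np.int32)
        for i in range(n):
            for l in range(L):
                pair = calls[i][l]
                if pair is not None:
                    G[i, l, 0] = loci[l].index_of(pair[0])
                    G[i, l, 1] = loci[l].index_of(pair[1])
        return GenotypeDataset(loci, ids, G, populations, **meta)


class AlleleFrequencyTable:
    """Per (population, locus) allele counts and frequencies.

    ``counts[p, l, a]`` is the number of observed gene copies of allele index
    ``a`` at locus ``l`` in population ``p``; ``n[p, l]`` the total gene count
    (0 where the population has no typed genotypes at the locus, in which case
    the frequency row is all zero).
    """

    def __init__(
        self,
        populations: Sequence[str],
        loci: Sequence[Locus],
        counts: np.ndarray,
    ):
        self.populations = list(populations)
        self.loci = list(loci)
        counts = np.asarray(counts, dtype=np.int64)
        A = max((l.k for l in self.loci), default=0)
        if counts.shape != (len(self.populations), len(self.loci), A):
            raise ValueError("counts array has wrong shape")
        if (counts < 0).any():
            raise ValueError("negative allele count")
        self.counts = counts
        self.n = counts.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.freqs = np.where(
                self.n[:, :, None] > 0, counts / np.maximum(self.n[:, :, None], 1), 0.0
            )
        # mask of valid registry slots per locus
        self.valid = np.zeros((len(self.loci), A), dtype=bool)
        for l, locus in enumerate(self.loci):
            self.valid[l, : locus.k] = True
        self._pop_index = {p: i for i, p in enumerate(self.populations)}

    @property
    def max_alleles(self) -> int:
        return self.counts.shape[2]

    def pop_row(self, population: str) -> int:
        return self._pop_index[population]

    def freq_map(self, population: str, locus_id: str) -> dict[int, float]:
        """Allele-code -> frequency map at one (population, locus) cell."""
        p = self.pop_row(population)
        l = [loc.locus_id for loc in self.loci].index(locus_id)
        locus = self.loci[l]
        return {
            locus.alleles[a]: float(self.freqs[p, l, a]) for a in range(locus.k)
        }

    def count_map(self, population: str, locus_id: str) -> dict[int, int]:
        p = self.pop_row(population)
        l = [loc.locus_id for loc in self.loci].index(locus_id)
        locus = self.loci[l]
        return {locus.alleles[a]: int(self.counts[p, l, a]) for a in range(locus.k)}


def compute_allele_frequencies(
    dataset: GenotypeDataset,
    subset: Iterable[str] | None = None,
    populations: Sequence[str] | None = None,
) -> AlleleFrequencyTable:
    """Count alleles per (population, locus) and derive frequencies.

    Missing genotypes contribute nothing; a population with zero typed genes
    at a locus carries n = 0 and a zero frequency row. ``subset`` restricts
    counting to the named individuals (e.g. putatively unrelated reference
    animals); individuals labelled "unknown" are never counted.
    """
    if subset is not None:
        subset = set(subset)
        missing_ids = subset - set(dataset.ids)
        if missing_ids:
            raise KeyError(f"subset ids not in dataset: {sorted(missing_ids)}")
    pops = list(populations) if populations is not None else dataset.population_ids
    pop_index = {p: i for i, p in enumerate(pops)}
    A = max((l.k for l in dataset.loci), default=0)
    counts = np.zeros((len(pops), len(dataset.loci), A), dtype=np.int64)
    for i, iid in enumerate(dataset.ids):
        pop = dataset.populations[i]
        if pop == UNKNOWN_POP or pop not in pop_index:
            continue
        if subset is not None and iid not in subset:
            continue
        p = pop_index[pop]
        g = dataset.G[i]
        typed = g[:, 0] != MISSING
        for c in (0, 1):
            ll = np.nonzero(typed)[0]
            np.add.at(counts[p], (ll, g[ll, c]), 1)
    return AlleleFrequencyTable(pops, dataset.loci, counts)


def single_pop_frequencies(table: AlleleFrequencyTable, population: str) -> np.ndarray:
    """(n_loci, max_alleles) frequency matrix for one population."""
    return table.freqs[table.pop_row(population)]
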