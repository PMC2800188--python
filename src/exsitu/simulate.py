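"""Synthetic archipelago generator: reference populations, captive pens,
hybrids and pedigrees with known ground truth.

The real study system is a panel of island tortoise populations genotyped at
nine microsatellite loci plus a captive colony of unknown-origin animals.
Those specimen genotypes are not deposited, so every downstream stage is
exercised against synthetic data generated here:

* per-population allele frequencies drawn from a symmetric Dirichlet around a
  shared ancestral frequency vector — a single concentration scalar controls
  divergence (expected FST ~ 1/(1 + concentration));
* Hardy-Weinberg genotype sampling with independent per-(individual, locus)
  missingness;
* optional hidden null alleles per (population, locus): null homozygotes
  appear as missing data, null heterozygotes as visible-allele homozygotes
  (the standard genotyping-artifact model that heterozygote-deficit
  screening assumes);
* captive colonies mixing purebred, F1/F2/backcross and pedigree-related
  individuals, each carrying true ancestry fractions, recorded parents and a
  maternally inherited mtDNA haplotype in a :class:`TruthTable`.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    Locus,
    UNKNOWN_POP,
)
from .mtdna import HaplotypeDB, HaplotypeRecord

HYBRID_LABELS = ("parental", "F1", "F2", "B1", "B2", "B3")

#: expected ancestry fraction of the recurrent parent per class
RECURRENT_FRACTION = {
    "parental": 1.0,
    "F1": 0.5,
    "F2": 0.5,
    "B1": 0.75,
    "B2": 0.875,
    "B3": 0.9375,
}


@dataclass
class ArchipelagoConfig:
    """Study-condition defaults mirror the real reference panel's scale:
    17 populations genotyped at 9 loci, moderate differentiation, ~2.8%
    missing data, 20-40 reference animals per population (30 used)."""

    n_populations: int = 17
    n_loci: int = 9
    alleles_per_locus: int = 10
    ref_sample_size: int = 30
    differentiation: float = 4.0  # Dirichlet concentration; E[FST] ~ 1/(1+c)
    missing_rate: float = 0.028
    null_allele_spec: list[tuple[str, str, float]] = field(default_factory=list)
    haplotypes_per_population: int = 2
    mtdna_length: int = 695
    nonnative_haplotypes: list[tuple[str, str]] = field(default_factory=list)
    # ^ (host_population, source_population): one of source's haplotypes is
    #   also sampled in host and flagged non-native there
    seed: int = 0

    def __post_init__(self) -> None:
        if self.differentiation <= 0:
            raise ValueError("differentiation must be > 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.n_populations, self.n_loci, self.alleles_per_locus,
               self.ref_sample_size) < 1:
            raise ValueError("all sizes must be >= 1")

    @property
    def population_names(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_populations)]

    @property
    def locus_names(self) -> list[str]:
        return [f"LOC{i + 1}" for i in range(self.n_loci)]


@dataclass
class ReferencePanel:
    """A generated reference panel: dataset + ground-truth frequencies."""

    dataset: GenotypeDataset
    populations: list[str]
    loci: list[Locus]
    true_freqs: np.ndarray  # (P, L, A)
    haplotype_db: HaplotypeDB
    pop_haplotypes: dict[str, list[str]]
    island_of: dict[str, str]

    def truth_table(self) -> AlleleFrequencyTable:
        """True frequencies repackaged as a (pseudo-count) frequency table
        for code that wants the tabular interface; counts are frequencies
        scaled to a large even gene count."""
        counts = np.rint(self.true_freqs * 10**6).astype(np.int64)
        return AlleleFrequencyTable(self.populations, self.loci, counts)


class TruthTable:
    """Ground truth for generated colony individuals."""

    def __init__(self, populations: Sequence[str]):
        self.populations = list(populations)
        self.rows: dict[str, dict] = {}

    def add(
        self,
        individual_id: str,
        class_label: str,
        fractions: dict[str, float],
        parent1: str | None = None,
        parent2: str | None = None,
        mtdna_haplotype: str | None = None,
    ) -> None:
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"ancestry fractions sum to {total}, not 1")
        for p in (parent1, parent2):
            if p is not None and p not in self.rows:
                raise ValueError(f"pedigree parent {p} not generated yet")
        self.rows[individual_id] = {
            "individual_id": individual_id,
            "class_label": class_label,
            "parent1": parent1,
            "parent2": parent2,
            "mtdna_haplotype": mtdna_haplotype,
            **{f"frac_{p}": fractions.get(p, 0.0) for p in self.populations},
        }

    def fractions(self, individual_id: str) -> dict[str, float]:
        row = self.rows[individual_id]
        return {p: row[f"frac_{p}"] for p in self.populations}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows.values()))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# -- primitives ----------------------------------------------------------


def sample_genotype(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one diploid genotype: two independent alleles per locus from the
    (n_loci, n_alleles) frequency matrix. Rows must be normalised."""
    return sample_genotypes(freqs, 1, rng)[0]


def sample_genotypes(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised batch of :func:`sample_genotype`; returns (n, L, 2) indices."""
    freqs = np.asarray(freqs, dtype=float)
    row_sums = freqs.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = int(np.nonzero(row_sums <= 0)[0][0])
        raise ValueError(f"empty frequency map at locus index {bad}")
    cum = np.cumsum(freqs / row_sums[:, None], axis=1)
    u = rng.random((n, freqs.shape[0], 2))
    idx = (u[..., None] > cum[None, :, None, :]).sum(axis=-1)
    return np.minimum(idx, freqs.shape[1] - 1).astype(np.int32)


def cross(parent1: np.ndarray, parent2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mendelian cross: one uniformly chosen allele from each parent per
    locus. The offspring is missing wherever either parent is untyped."""
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    if p1.shape != p2.shape:
        raise ValueError(f"locus-length mismatch: {p1.shape} vs {p2.shape}")
    L = p1.shape[0]
    pick = rng.integers(0, 2, size=(L, 2))
    child = np.empty((L, 2), dtype=np.int32)
    child[:, 0] = p1[np.arange(L), pick[:, 0]]
    child[:, 1] = p2[np.arange(L), pick[:, 1]]
    untyped = (p1[:, 0] == MISSING) | (p2[:, 0] == MISSING)
    child[untyped] = MISSING
    return child


def realized_fst(true_freqs: np.ndarray) -> float:
    """Multi-locus variance-partition FST over the true frequencies:
    sum over loci/alleles of Var_pop(p) divided by the corresponding
    sum of p_bar (1 - p_bar)."""
    p = np.asarray(true_freqs, dtype=float)
    var = p.var(axis=0)  # across populations
    pbar = p.mean(axis=0)
    denom = (pbar * (1 - pbar)).sum()
    return float(var.sum() / denom) if denom > 0 else 0.0


# -- panel generation ------------------------------------------------------


def _draw_population_freqs(cfg: ArchipelagoConfig, rng: np.random.Generator) -> np.ndarray:
    P, L, A = cfg.n_populations, cfg.n_loci, cfg.alleles_per_locus
    ancestral = rng.dirichlet(np.full(A, 1.5), size=L)  # (L, A)
    freqs = np.empty((P, L, A))
    for l in range(L):
        alpha = np.maximum(cfg.differentiation * ancestral[l], 1e-6)
        freqs[:, l, :] = rng.dirichlet(alpha, size=P)
    return freqs


def _generate_haplotype_db(
    cfg: ArchipelagoConfig, rng: np.random.Generator
) -> tuple[HaplotypeDB, dict[str, list[str]], dict[str, str]]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ancestral = rng.choice(bases, size=cfg.mtdna_length)
    pops = cfg.population_names
    island_of = {p: f"I-{p}" for p in pops}
    records: list[HaplotypeRecord] = []
    pop_haps: dict[str, list[str]] = {p: [] for p in pops}
    hid = 0
    by_pop_first: dict[str, str] = {}
    for p in pops:
        backbone = ancestral.copy()
        sites = rng.choice(cfg.mtdna_length, size=8, replace=False)
        for s in sites:
            backbone[s] = rng.choice(bases[bases != backbone[s]])
        for _ in range(cfg.haplotypes_per_population):
            hid += 1
            seq = backbone.copy()
            for s in rng.choice(cfg.mtdna_length, size=2, replace=False):
                seq[s] = rng.choice(bases[bases != seq[s]])
            rec = HaplotypeRecord(
                haplotype_id=str(hid),
                sequence=seq.tobytes().decode(),
                sampled_populations={(p, island_of[p])},
                native_status={p: "native"},
            )
            records.append(rec)
            pop_haps[p].append(rec.haplotype_id)
            by_pop_first.setdefault(p, rec.haplotype_id)
    for host, source in cfg.nonnative_haplotypes:
        if host not in pop_haps or source not in by_pop_first:
            raise ValueError(f"nonnative_haplotypes names unknown population: {(host, source)}")
        rec = next(r for r in records if r.haplotype_id == by_pop_first[source])
        rec.sampled_populations.add((host, island_of[host]))
        rec.native_status[host] = "non-native"
        pop_haps[host].append(rec.haplotype_id)
    return HaplotypeDB(records), pop_haps, island_of


def _allele_codes(a: int) -> tuple[int, ...]:
    # fragment-size-like even codes, 3-digit
    return tuple(100 + 2 * j for j in range(a))


def _apply_nulls_and_missing(
    genos: np.ndarray,
    null_idx: int | None,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Transform raw draws: null homozygotes -> missing, null heterozygotes
    -> visible homozygotes, then independent missingness."""
    g = genos.copy()
    if null_idx is not None:
        a_null = g[:, :, 0] == null_idx
        b_null = g[:, :, 1] == null_idx
        both = a_null & b_null
        g[both] = MISSING
        only_a = a_null & ~both
        only_b = b_null & ~both
        g[:, :, 0][only_a] = g[:, :, 1][only_a]
        g[:, :, 1][only_b] = g[:, :, 0][only_b]
    if missing_rate > 0:
        drop = rng.random(g.shape[:2]) < missing_rate
        g[drop] = MISSING
    return g


def generate_reference_panel(config: ArchipelagoConfig) -> ReferencePanel:
    """Generate the reference populations with known true frequencies.

    Returns a :class:`ReferencePanel` whose dataset has one labelled block
    per population and whose ``true_freqs`` are the generating frequencies.
    """
    rng = np.random.default_rng(config.seed)
    pops = config.population_names
    true_freqs = _draw_population_freqs(config, rng)
    db, pop_haps, island_of = _generate_haplotype_db(config, rng)
    loci = [
        Locus(name, _allele_codes(config.alleles_per_locus))
        for name in config.locus_names
    ]
    null_by_cell = {}
    for pop, locus, f in config.null_allele_spec:
        if pop not in pops or locus not in config.locus_names:
            raise ValueError(f"null_allele_spec names unknown cell: {(pop, locus)}")
        null_by_cell[(pops.index(pop), config.locus_names.index(locus))] = f

    ids: list[str] = []
    labels: list[str] = []
    mtdna: list[str | None] = []
    known: list[str | None] = []
    blocks = []
    A = config.alleles_per_locus
    for p, pop in enumerate(pops):
        # sampling frequencies, possibly extended with a hidden null allele
        samp = np.zeros((config.n_loci, A + 1))
        samp[:, :A] = true_freqs[p]
        null_idx = None
        for l in range(config.n_loci):
            f = null_by_cell.get((p, l))
            if f:
                samp[l, :A] *= 1 - f
                samp[l, A] = f
                null_idx = A
        raw = sample_genotypes(samp, config.ref_sample_size, rng)
        g = _apply_nulls_and_missing(raw, null_idx, config.missing_rate, rng)
        blocks.append(g)
        for j in range(config.ref_sample_size):
            ids.append(f"{pop}_r{j + 1:03d}")
            labels.append(pop)
            hap = pop_haps[pop][int(rng.integers(len(pop_haps[pop])))]
            mtdna.append(db.get(hap).sequence)
            known.append(pop)
    G = np.concatenate(blocks, axis=0)
    dataset = GenotypeDataset(
        loci, ids, G, labels, mtdna=mtdna, known_origin=known,
        source=["reference"] * len(ids),
    )
    return ReferencePanel(
        dataset=dataset,
        populations=pops,
        loci=loci,
        true_freqs=true_freqs,
        haplotype_db=db,
        pop_haplotypes=pop_haps,
        island_of=island_of,
    )


# -- captive colony --------------------------------------------------------


@dataclass
class ClassGroup:
    """``count`` independent individuals of one ancestry class.

    ``pops`` is (pop,) for parental or (recurrent, other) for hybrid classes;
    backcrosses Bn are serial crosses back to the recurrent (first) parent.
    Unpedigreed simulants have unrecorded (null) parents; their mtDNA
    haplotype comes from the maternal-line pool — the second population for
    hybrid classes, the population itself for parentals.
    """

    label: str
    pops: tuple[str, ...]
    count: int

    def __post_init__(self) -> None:
        if self.label not in HYBRID_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        need = 1 if self.label == "parental" else 2
        if len(self.pops) != need:
            raise ValueError(f"{self.label} needs {need} population(s)")


@dataclass
class Family:
    """A pedigree directive: recorded parents plus their offspring.

    kinds: ``full_sib`` (n offspring share both recorded parents),
    ``half_sib`` (shared dam, distinct unrecorded sires), ``parent_offspring``
    (a recorded dam-offspring chain of length n), ``grandparent`` (dam chain
    of depth 2: grandmother -> mother -> n grandchildren).
    """

    kind: str
    pop: str
    n_offspring: int = 3

    def __post_init__(self) -> None:
        if self.kind not in {"full_sib", "half_sib", "parent_offspring", "grandparent"}:
            raise ValueError(f"unknown family kind {self.kind!r}")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")


def simulate_class_genotype(
    label: str,
    freqs_A: np.ndarray,
    freqs_B: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """One genotype of an ancestry class from per-locus parental frequency
    pools; A is the recurrent parent for backcrosses."""
    if label == "parental":
        return sample_genotype(freqs_A, rng)
    if freqs_B is None:
        raise ValueError(f"class {label} needs two parental pools")
    f1 = cross(sample_genotype(freqs_A, rng), sample_genotype(freqs_B, rng), rng)
    if label == "F1":
        return f1
    if label == "F2":
        other = cross(sample_genotype(freqs_A, rng), sample_genotype(freqs_B, rng), rng)
        return cross(f1, other, rng)
    if label in ("B1", "B2", "B3"):
        depth = int(label[1])
        g = f1
        for _ in range(depth):
            g = cross(g, sample_genotype(freqs_A, rng), rng)
        return g
    raise ValueError(f"unknown class label {label!r}")


def _class_fractions(label: str, pops: tuple[str, ...]) -> dict[str, float]:
    if label == "parental":
        return {pops[0]: 1.0}
    fa = RECURRENT_FRACTION[label]
    return {pops[0]: fa, pops[1]: 1.0 - fa}


def generate_captive_colony(
    panel: ReferencePanel,
    directives: Sequence[ClassGroup | Family],
    seed: int,
    missing_rate: float = 0.0,
    id_prefix: str = "CAP",
) -> tuple[GenotypeDataset, TruthTable]:
    """Generate a captive pen with known ancestry classes and pedigrees.

    Every individual's true ancestry fractions, recorded parents and mtDNA
    haplotype land in the returned :class:`TruthTable`; haplotypes are
    transmitted maternally along every pedigree. Missingness (if any) masks
    the observed dataset only — inheritance uses the full genotypes.
    """
    rng = np.random.default_rng(seed)
    pop_index = {p: i for i, p in enumerate(panel.populations)}
    truth = TruthTable(panel.populations)
    ids: list[str] = []
    genos: list[np.ndarray] = []
    mtdna_hap: list[str] = []
    sexes: list[str] = []
    known: list[str | None] = []
    counter = 0

    def freqs_of(pop: str) -> np.ndarray:
        if pop not in pop_index:
            raise ValueError(f"directive references unknown population {pop!r}")
        return panel.true_freqs[pop_index[pop]]

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{id_prefix}{counter:03d}"

    def pick_hap(pop: str) -> str:
        pool = panel.pop_haplotypes[pop]
        return pool[int(rng.integers(len(pool)))]

    def add(
        g: np.ndarray,
        label: str,
        fractions: dict[str, float],
        hap: str,
        sex: str | None = None,
        parent1: str | None = None,
        parent2: str | None = None,
        origin: str | None = None,
    ) -> str:
        iid = new_id()
        ids.append(iid)
        genos.append(g)
        mtdna_hap.append(hap)
        sexes.append(sex or ("F" if rng.random() < 0.5 else "M"))
        known.append(origin)
        truth.add(iid, label, fractions, parent1=parent1, parent2=parent2,
                  mtdna_haplotype=hap)
        return iid

    for d in directives:
        if isinstance(d, ClassGroup):
            fa = freqs_of(d.pops[0])
            fb = freqs_of(d.pops[1]) if len(d.pops) > 1 else None
            maternal_pop = d.pops[-1]
            fractions = _class_fractions(d.label, d.pops)
            for _ in range(d.count):
                g = simulate_class_genotype(d.label, fa, fb, rng)
                add(
                    g,
                    d.label if d.label == "parental" else f"{d.label}({d.pops[0]},{d.pops[1]})",
                    fractions,
                    pick_hap(maternal_pop),
                    origin=d.pops[0] if d.label == "parental" else None,
                )
        elif isinstance(d, Family):
            fp = freqs_of(d.pop)
            pure = {d.pop: 1.0}
            if d.kind == "full_sib":
                dam_g, sire_g = sample_genotype(fp, rng), sample_genotype(fp, rng)
                dam_hap = pick_hap(d.pop)
                dam = add(dam_g, "parental", pure, dam_hap, sex="F", origin=d.pop)
                sire = add(sire_g, "parental", pure, pick_hap(d.pop), sex="M", origin=d.pop)
                for _ in range(d.n_offspring):
                    add(cross(sire_g, dam_g, rng), "parental", pure, dam_hap,
                        parent1=sire, parent2=dam, origin=d.pop)
            elif d.kind == "half_sib":
                dam_g = sample_genotype(fp, rng)
                dam_hap = pick_hap(d.pop)
                dam = add(dam_g, "parental", pure, dam_hap, sex="F", origin=d.pop)
                for _ in range(d.n_offspring):
                    sire_g = sample_genotype(fp, rng)  # unrecorded sire
                    add(cross(sire_g, dam_g, rng), "parental", pure, dam_hap,
                        parent2=dam, origin=d.pop)
            elif d.kind == "parent_offspring":
                g = sample_genotype(fp, rng)
                hap = pick_hap(d.pop)
                prev = add(g, "parental", pure, hap, sex="F", origin=d.pop)
                for _ in range(d.n_offspring):
                    g = cross(sample_genotype(fp, rng), g, rng)
                    prev = add(g, "parental", pure, hap, sex="F",
                               parent2=prev, origin=d.pop)
            elif d.kind == "grandparent":
                g0 = sample_genotype(fp, rng)
                hap = pick_hap(d.pop)
                grandma = add(g0, "parental", pure, hap, sex="F", origin=d.pop)
                g1 = cross(sample_genotype(fp, rng), g0, rng)
                mother = add(g1, "parental", pure, hap, sex="F",
                             parent2=grandma, origin=d.pop)
                for _ in range(d.n_offspring):
                    add(cross(sample_genotype(fp, rng), g1, rng), "parental",
                        pure, hap, parent2=mother, origin=d.pop)
        else:
            raise TypeError(f"unknown directive {d!r}")

    G = np.stack(genos, axis=0) if genos else np.empty((0, panel.dataset.n_loci, 2), np.int32)
    if missing_rate > 0:
        drop = rng.random(G.shape[:2]) < missing_rate
        G = G.copy()
        G[drop] = MISSING
    dataset = GenotypeDataset(
        panel.loci,
        ids,
        G,
        [UNKNOWN_POP] * len(ids),
        sex=sexes,
        source=["colony"] * len(ids),
        mtdna=[panel.haplotype_db.get(h).sequence for h in mtdna_hap],
        known_origin=known,
    )
    return dataset, truth
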