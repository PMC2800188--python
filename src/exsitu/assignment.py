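"""Partial-Bayesian multilocus population assignment with Monte-Carlo
exclusion, in the GeneClass tradition.

An individual's genotype is scored against each candidate reference
population by its posterior-predictive probability under a uniform Dirichlet
prior on allele frequencies. With n sampled gene copies at a locus in the
population, n_a copies of allele a, and k distinct allelic states at that
locus dataset-wide:

    P(a, b | a != b) = 2 (n_a + 1/k)(n_b + 1/k) / [(n + 1)(n + 2)]
    P(a, a)          =   (n_a + 1/k)(n_a + 1/k + 1) / [(n + 1)(n + 2)]

The multilocus probability is the product over typed loci, and the reported
score is -log10 of it (smaller = more likely). L1 and L2 are the best and
second-best populations by score. The exclusion test simulates genotypes
from a population's observed frequencies, scores them the same way, and
reports p = the proportion of simulated genotypes scoring as bad or worse
than the query; the population is excluded as an origin when p falls below
the threshold (0.01 against 10,000 simulated genotypes by default).

k is counted dataset-wide per locus, including unknown-origin individuals:
captive animals may carry alleles absent from every reference sample, and
the registry must cover them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, AlleleFrequencyTable, GenotypeDataset
from .simulate import sample_genotypes


def genotype_probability_table(
    counts: np.ndarray, k: np.ndarray, valid: np.ndarray
) -> np.ndarray:
    """Posterior-predictive genotype probabilities for one population.

    Parameters
    ----------
    counts
        (L, A) observed allele counts.
    k
        (L,) dataset-wide allelic states per locus.
    valid
        (L, A) registry mask.

    Returns
    -------
    (L, A, A) array; entry [l, a, b] is the probability of unordered
    genotype (a, b) — off-diagonal entries carry the factor 2, so each
    locus plane sums to 1 over {a <= b}.
    """
    counts = np.asarray(counts, dtype=float)
    L, A = counts.shape
    x = np.where(valid, counts + 1.0 / k[:, None], 0.0)
    n = counts.sum(axis=1)
    denom = (n + 1.0) * (n + 2.0)
    table = 2.0 * x[:, :, None] * x[:, None, :]
    diag = x * (x + 1.0)
    ii = np.arange(A)
    table[:, ii, ii] = diag
    return table / denom[:, None, None]


def genotype_score(
    genotype: np.ndarray, counts: np.ndarray, k: np.ndarray, valid: np.ndarray
) -> float:
    """-log10 multilocus posterior-predictive probability of one genotype
    against one population; missing loci are skipped. A population with
    n = 0 at a locus contributes the pure-prior predictive."""
    g = np.asarray(genotype)
    table = genotype_probability_table(counts, np.asarray(k), valid)
    typed = g[:, 0] != MISSING
    if not typed.any():
        raise ValueError("genotype has no typed loci")
    for l in np.nonzero(typed)[0]:
        if not (valid[l, g[l, 0]] and valid[l, g[l, 1]]):
            raise ValueError(f"allele index outside registry at locus {l}")
    ll = np.nonzero(typed)[0]
    return float(-np.log10(table[ll, g[ll, 0], g[ll, 1]]).sum())


@dataclass
class AssignmentRecord:
    individual_id: str
    scores: dict[str, float]  # population -> -log10 probability
    ranked: list[tuple[str, float]]
    l1_pop: str
    l1_score: float
    l2_pop: str | None
    l2_score: float | None
    tie: bool = False
    p_values: dict[str, float] | None = None
    excluded: set[str] = field(default_factory=set)


class AssignmentResults:
    """Ranked assignment scores (and optional exclusion p-values) for a
    batch of query individuals."""

    def __init__(self, records: list[AssignmentRecord], threshold: float | None):
        self.records = records
        self.threshold = threshold
        self._by_id = {r.individual_id: r for r in records}

    def __getitem__(self, individual_id: str) -> AssignmentRecord:
        return self._by_id[individual_id]

    def __iter__(self):
        return iter(self.records)

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "individual_id": r.individual_id,
                "L1_pop": r.l1_pop,
                "L1_score": r.l1_score,
                "L2_pop": r.l2_pop,
                "L2_score": r.l2_score,
                "tie": r.tie,
            }
            if r.p_values is not None:
                row.update({f"p_{p}": v for p, v in r.p_values.items()})
                row["excluded"] = ",".join(sorted(r.excluded))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


class AssignmentModel:
    """Assignment scorer built from a reference allele-frequency table.

    The table supplies per-(population, locus) counts; allelic-state counts k
    come from the locus registries, which are dataset-wide by construction.
    """

    def __init__(self, table: AlleleFrequencyTable):
        self.table = table
        self.populations = list(table.populations)
        self.k = np.array([l.k for l in table.loci], dtype=float)
        P, L, A = table.counts.shape
        self._tables = np.stack(
            [
                genotype_probability_table(table.counts[p], self.k, table.valid)
                for p in range(P)
            ]
        )  # (P, L, A, A)
        with np.errstate(divide="ignore"):
            self._log10 = np.log10(self._tables)

    # -- scoring ---------------------------------------------------------

    def score_genotypes(self, G: np.ndarray) -> np.ndarray:
        """(N, P) matrix of -log10 multilocus probabilities; missing loci
        skipped per individual."""
        G = np.asarray(G)
        if G.ndim == 2:
            G = G[None]
        N, L, _ = G.shape
        scores = np.zeros((N, len(self.populations)))
        for l in range(L):
            typed = G[:, l, 0] != MISSING
            if not typed.any():
                continue
            a = G[typed, l, 0]
            b = G[typed, l, 1]
            if not (self.table.valid[l, a].all() and self.table.valid[l, b].all()):
                raise ValueError(f"allele index outside registry at locus {l}")
            scores[typed] -= self._log10[:, l, a, b].T
        return scores

    def assign(
        self,
        G: np.ndarray,
        ids: list[str],
        exclusion: bool = False,
        n_sim: int = 10_000,
        threshold: float = 0.01,
        seed: int = 0,
    ) -> AssignmentResults:
        """Score and rank every query genotype against every population.

        Ties on the best score are broken lexicographically by population id
        and flagged. With ``exclusion=True`` a Monte-Carlo null score
        distribution is simulated once per population and per-population
        exclusion p-values are attached.
        """
        G = np.asarray(G)
        if G.ndim == 2:
            G = G[None]
        if (G[:, :, 0] == MISSING).all(axis=1).any():
            raise ValueError("an individual has no typed loci")
        scores = self.score_genotypes(G)
        nulls = None
        if exclusion:
            if n_sim < 100:
                raise ValueError("n_sim must be >= 100")
            rng = np.random.default_rng(seed)
            nulls = {
                pop: self._null_scores(pop, n_sim, rng) for pop in self.populations
            }
        records = []
        for i, iid in enumerate(ids):
            order = sorted(zip(self.populations, scores[i]), key=lambda t: (t[1], t[0]))
            l1_pop, l1 = order[0]
            l2_pop, l2 = order[1] if len(order) > 1 else (None, None)
            tie = l2 is not None and abs(l1 - l2) < 1e-9
            pvals = None
            excluded: set[str] = set()
            if nulls is not None:
                pvals = {}
                for p_idx, pop in enumerate(self.populations):
                    p = float((nulls[pop] >= scores[i, p_idx] - 1e-12).mean())
                    pvals[pop] = p
                    if p < threshold:
                        excluded.add(pop)
            records.append(
                AssignmentRecord(
                    individual_id=iid,
                    scores=dict(zip(self.populations, scores[i])),
                    ranked=order,
                    l1_pop=l1_pop,
                    l1_score=float(l1),
                    l2_pop=l2_pop,
                    l2_score=None if l2 is None else float(l2),
                    tie=tie,
                    p_values=pvals,
                    excluded=excluded,
                )
            )
        return AssignmentResults(records, threshold if exclusion else None)

    def assign_dataset(self, dataset: GenotypeDataset, ids=None, **kw) -> AssignmentResults:
        ids = list(ids) if ids is not None else dataset.unknown_ids
        rows = [dataset.row(i) for i in ids]
        return self.assign(dataset.G[rows], ids, **kw)

    # -- exclusion ---------------------------------------------------------

    def _null_scores(self, population: str, n_sim: int, rng: np.random.Generator) -> np.ndarray:
        p = self.table.pop_row(population)
        freqs = self.table.freqs[p]  # (L, A), zero rows where n = 0
        typed_loci = np.nonzero(self.table.n[p] > 0)[0]
        if typed_loci.size == 0:
            raise ValueError(f"population {population} has no typed loci")
        sims = sample_genotypes(freqs[typed_loci], n_sim, rng)
        scores = np.zeros(n_sim)
        for j, l in enumerate(typed_loci):
            scores -= self._log10[p, l, sims[:, j, 0], sims[:, j, 1]]
        return scores

    def exclusion_test(
        self,
        genotype: np.ndarray,
        population: str,
        n_sim: int = 10_000,
        threshold: float = 0.01,
        seed: int = 0,
    ) -> tuple[float, bool]:
        """p-value of the query's score against the population's simulated
        score distribution; (p, excluded). Simulated genotypes span only the
        loci where the population has observed data, and the query's score
        is computed on the same loci for comparability."""
        if n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        rng = np.random.default_rng(seed)
        null = self._null_scores(population, n_sim, rng)
        p_idx = self.table.pop_row(population)
        g = np.asarray(genotype)
        typed = (g[:, 0] != MISSING) & (self.table.n[p_idx] > 0)
        if not typed.any():
            raise ValueError("no loci shared between genotype and population data")
        ll = np.nonzero(typed)[0]
        obs = float(-self._log10[p_idx, ll, g[ll, 0], g[ll, 1]].sum())
        p = float((null >= obs - 1e-12).mean())
        return p, p < threshold
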