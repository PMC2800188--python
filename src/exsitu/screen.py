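"""Target-lineage screening by exact likelihood ratio.

Given a target population t (e.g. an extinct lineage re-entered into the
reference panel) the screen asks, for each unknown individual: is its
multilocus genotype better explained as an F1 between t and the
individual's best non-target population c than as a purebred of c?

    LR = log P(g | F1(t, c)) - log P(g | pure c)

with per-locus genotype probabilities under Hardy-Weinberg:
pure: P(a,b) = 2 p_c(a) p_c(b) (a != b), p_c(a)^2 (a == b);
F1:   P(a,b) = p_t(a) p_c(b) + p_t(b) p_c(a) (one allele from each pool;
      p_t(a) p_c(a) when a == b). Frequencies are posterior-mean smoothed
with the same 1/k pseudo-count the assignment likelihood uses, so alleles
unseen in a reference sample stay possible but expensive.

This is the Neyman-Pearson statistic for exactly the contrast that matters
when hunting F1 descendants of a target lineage, and it needs no MCMC. A
purebred of t also scores high (the F1 model contains the t pool), so the
screen catches both purebred and first-generation target ancestry.

Calibration: the no-target-ancestry null is the LR distribution of pure-c
individuals. Two sources are combined and the cutoff is their maximum:

* a parametric bootstrap — genotypes simulated from Dirichlet-posterior
  frequency draws around c's observed counts (covering frequency-estimation
  uncertainty), summarised at a high percentile on each query's typed loci;
* the leave-one-out LRs of c's real reference individuals — each scored
  against counts excluding itself — which anchor the null to the true
  dispersion of real genotypes (rare alleles, missing-data patterns) that
  the parametric bootstrap under-represents. The *second-largest* LOO value
  is used, so a single aberrant reference individual cannot inflate the
  cutoff for its whole population.

An unknown is flagged when its LR exceeds that cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MISSING, AlleleFrequencyTable, GenotypeDataset


def smoothed_frequencies(counts: np.ndarray, k: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Posterior-mean frequencies (counts + 1/k) / (n + 1) per locus."""
    c = counts.astype(float)
    n = c.sum(axis=1, keepdims=True)
    return np.where(valid, (c + 1.0 / k[:, None]) / (n + 1.0), 0.0)


def lr_contributions(ft: np.ndarray, fc: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Per-locus log-LR contributions, (n, L); zero at missing loci."""
    G = np.asarray(G)
    n, L, _ = G.shape
    out = np.zeros((n, L))
    for l in range(L):
        typed = G[:, l, 0] != MISSING
        if not typed.any():
            continue
        a, b = G[typed, l, 0], G[typed, l, 1]
        p1 = ft[l, a] * fc[l, b] + np.where(a == b, 0.0, ft[l, b] * fc[l, a])
        p0 = np.where(a == b, fc[l, a] * fc[l, b], 2.0 * fc[l, a] * fc[l, b])
        out[typed, l] = np.log(np.maximum(p1, 1e-300)) - np.log(
            np.maximum(p0, 1e-300)
        )
    return out


def posterior_pure_sims(
    counts: np.ndarray,
    k: np.ndarray,
    valid: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parametric-bootstrap purebred genotypes: per simulant, frequencies
    drawn from the Dirichlet posterior (counts + 1/k), then two alleles per
    locus. Loci with no data come out missing."""
    L, A = counts.shape
    alpha = np.where(valid, counts + 1.0 / k[:, None], 0.0)
    g = rng.standard_gamma(np.broadcast_to(alpha, (n, L, A)))
    tot = g.sum(axis=2, keepdims=True)
    f = np.divide(g, tot, out=np.zeros_like(g), where=tot > 0)
    cum = np.cumsum(f, axis=2)
    G = np.empty((n, L, 2), dtype=np.int32)
    for c in (0, 1):
        u = rng.random((n, L, 1))
        G[:, :, c] = np.minimum((cum < u).sum(axis=2), A - 1)
    empty = counts.sum(axis=1) == 0
    G[:, empty, :] = MISSING
    return G


@dataclass
class ScreenResult:
    target: str
    table: pd.DataFrame  # individual_id, companion, lr, cutoff, flagged

    def flagged_ids(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "individual_id"].tolist()


def target_ancestry_screen(
    dataset: GenotypeDataset,
    table: AlleleFrequencyTable,
    companions: dict[str, str],
    target: str,
    n_null: int = 5000,
    percentile: float = 99.5,
    seed: int = 0,
) -> ScreenResult:
    """Screen unknowns for target ancestry against per-individual companions.

    Parameters
    ----------
    companions
        individual id -> its best non-target population (from the
        assignment ranking).
    """
    if target not in table.populations:
        raise ValueError(f"target population {target!r} not in panel")
    k = np.array([l.k for l in table.loci], dtype=float)
    ft = smoothed_frequencies(table.counts[table.pop_row(target)], k, table.valid)
    rng = np.random.default_rng(seed)

    ref_rows: dict[str, list[int]] = {}
    for i, p in enumerate(dataset.populations):
        ref_rows.setdefault(p, []).append(i)

    def counts_of_row(i: int) -> np.ndarray:
        g = dataset.G[i]
        c = np.zeros_like(table.counts[0])
        typed = np.nonzero(g[:, 0] != MISSING)[0]
        for col in (0, 1):
            np.add.at(c, (typed, g[typed, col]), 1)
        return c

    cache: dict[str, tuple[np.ndarray, float, np.ndarray]] = {}

    def null_for(pop: str):
        if pop not in cache:
            ci = table.pop_row(pop)
            fc = smoothed_frequencies(table.counts[ci], k, table.valid)
            sims = posterior_pure_sims(table.counts[ci], k, table.valid, n_null, rng)
            par = lr_contributions(ft, fc, sims)  # (n_null, L)
            loo = []
            for row in ref_rows.get(pop, []):
                cc = table.counts[ci] - counts_of_row(row)
                fc_loo = smoothed_frequencies(cc, k, table.valid)
                g = dataset.G[row][None]
                typed = g[0, :, 0] != MISSING
                loo.append(float(lr_contributions(ft, fc_loo, g)[0, typed].sum()))
            loo_stat = sorted(loo)[-2] if len(loo) >= 2 else -np.inf
            cache[pop] = (par, loo_stat, fc)
        return cache[pop]

    rows = []
    for iid, comp in companions.items():
        par, loo_stat, fc = null_for(comp)
        g = dataset.G[dataset.row(iid)][None]
        typed = g[0, :, 0] != MISSING
        if not typed.any():
            rows.append(dict(individual_id=iid, companion=comp, lr=np.nan,
                             cutoff=np.nan, flagged=False))
            continue
        lr = float(lr_contributions(ft, fc, g)[0, typed].sum())
        cut = max(float(np.percentile(par[:, typed].sum(axis=1), percentile)), loo_stat)
        rows.append(dict(individual_id=iid, companion=comp, lr=lr,
                         cutoff=cut, flagged=lr > cut))
    return ScreenResult(target, pd.DataFrame(rows))
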