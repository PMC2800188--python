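"""Supervised Bayesian admixture estimation by Gibbs sampling.

Each unknown-origin individual i receives a membership vector q_i over the K
reference populations — the fraction of its sampled genome with ancestry in
each population. The model is the standard admixture model with independent
allele-frequency priors, run *supervised*: reference individuals are pinned
to their populations, so the population labels anchor the components and no
label switching can occur.

    q_i ~ Dirichlet(alpha * 1_K)
    z_ilc | q_i ~ Categorical(q_i)           (origin of each allele copy)
    allele a_ilc | z_ilc = k ~ f_kl          (population-k frequencies)
    f_kl ~ Dirichlet(lambda * 1_A + reference counts at (k, l))

Frequencies are conditioned on the reference samples only: letting the
unknowns' assigned allele copies feed back into f would let a large query
batch (e.g. hundreds of simulated hybrids scored against tens of reference
animals per population) drag the population frequencies toward the batch
mixture and bias every q. Conditioning on the references keeps query
individuals exchangeable and independent given f — the natural supervised
analysis when the references are the trusted sample.

One Gibbs sweep resamples f, then every z | q, f, then every q | z. Missing
loci contribute no z variables. Draws after burn-in are retained every
``thin`` sweeps; reported summaries are the posterior mean and an
equal-tailed interval from order statistics of the retained draws.

The q-prior concentration defaults to alpha = 0.2: with nine typed loci an
individual contributes only 18 allele copies, and a Dirichlet(1) prior would
shrink posterior-mean q toward uniform by a factor of roughly
(18)/(18 + K). alpha = 0.2 keeps the posterior mean of simulated purebreds
and F1/B1/B2/B3 hybrids within a few hundredths of the Mendelian ancestry
expectations while retaining a proper prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeDataset,
    compute_allele_frequencies,
)


@dataclass
class McmcParams:
    """Sampler settings. ``reps`` counts post-burn-in sweeps (the STRUCTURE
    convention); desk-scale defaults are 5,000/25,000 — the study-scale
    500,000/1,000,000 remains available through configuration."""

    burn_in: int = 5_000
    reps: int = 25_000
    alpha: float = 0.2  # Dirichlet concentration of the q prior
    lam: float = 1.0  # Dirichlet concentration of the frequency prior
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.reps > self.burn_in >= 0):
            raise ValueError("need reps > burn_in >= 0")
        if self.alpha <= 0 or self.lam <= 0:
            raise ValueError("alpha and lambda must be > 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def posterior_summary(
    draws: np.ndarray, mass: float = 0.9
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and equal-tailed interval of retained draws.

    ``draws`` is (n_draws, ...); the interval bounds are the order statistics
    at the (1-mass)/2 and 1-(1-mass)/2 ranks. Requires >= 50 draws.
    """
    draws = np.asarray(draws)
    n = draws.shape[0]
    if n < 50:
        raise ValueError(
            f"only {n} retained draws; run the sampler longer (need >= 50)"
        )
    tail = (1.0 - mass) / 2.0
    srt = np.sort(draws, axis=0)
    lo = srt[int(np.floor(tail * (n - 1) + 1e-9))]
    hi = srt[min(n - 1, int(np.ceil((1.0 - tail) * (n - 1) - 1e-9)))]
    return draws.mean(axis=0), lo, hi


class AdmixtureResults:
    """Posterior membership coefficients for the fitted unknowns."""

    def __init__(
        self,
        ids: list[str],
        populations: list[str],
        draws: np.ndarray,  # (n_retained, N, K)
        params: McmcParams,
        interval_mass: float = 0.9,
        excluded_ids: list[str] | None = None,
    ):
        self.ids = ids
        self.populations = populations
        self.draws = draws
        self.params = params
        self.interval_mass = interval_mass
        self.excluded_ids = excluded_ids or []
        self.mean_q, self.q_lo, self.q_hi = posterior_summary(draws, interval_mass)
        self._by_id = {iid: i for i, iid in enumerate(ids)}

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def q(self, individual_id: str) -> np.ndarray:
        return self.mean_q[self._by_id[individual_id]]

    def interval(self, individual_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self._by_id[individual_id]
        return self.q_lo[i], self.q_hi[i]

    def best_population(self, individual_id: str) -> str:
        return self.populations[int(np.argmax(self.q(individual_id)))]

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, iid in enumerate(self.ids):
            row = {"individual_id": iid}
            for k, pop in enumerate(self.populations):
                row[f"q_{pop}"] = self.mean_q[i, k]
                row[f"q_{pop}_lo"] = self.q_lo[i, k]
                row[f"q_{pop}_hi"] = self.q_hi[i, k]
            row["best_pop"] = self.populations[int(np.argmax(self.mean_q[i]))]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


class AdmixtureModel:
    """Supervised admixture model: fixed reference counts + query genotypes.

    Build from a labelled dataset with :meth:`from_dataset`, or directly from
    an :class:`AlleleFrequencyTable` and a query genotype array (used when
    scoring simulated hybrid genotypes against the same panel).
    """

    def __init__(
        self,
        ref_table: AlleleFrequencyTable,
        G_unknown: np.ndarray,
        unknown_ids: list[str],
    ):
        if len(ref_table.populations) < 2:
            raise ValueError("need K >= 2 reference populations")
        G = np.asarray(G_unknown, dtype=np.int32)
        if G.ndim == 2:
            G = G[None]
        typed_counts = (G[:, :, 0] != MISSING).sum(axis=1)
        keep = typed_counts > 0
        dropped = [iid for iid, k in zip(unknown_ids, keep) if not k]
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} unknown(s) with zero typed loci: {dropped}"
            )
        self.table = ref_table
        self.populations = list(ref_table.populations)
        self.ids = [iid for iid, k in zip(unknown_ids, keep) if k]
        self.excluded_ids = dropped
        self.G = G[keep]
        if len(self.ids) == 0:
            raise ValueError("no usable unknown individuals")

    @classmethod
    def from_dataset(
        cls,
        dataset: GenotypeDataset,
        unknowns: list[str] | None = None,
        populations: list[str] | None = None,
        freq_subset: list[str] | None = None,
    ) -> "AdmixtureModel":
        """References = labelled individuals of ``dataset`` (optionally
        restricted to ``populations`` / to the ``freq_subset`` ids);
        unknowns default to every "unknown"-labelled individual."""
        unknowns = list(unknowns) if unknowns is not None else dataset.unknown_ids
        # references are the labelled individuals, minus anything passed as
        # an unknown (an individual is never its own reference)
        subset = freq_subset
        if subset is None:
            subset = [i for i in dataset.ids if i not in set(unknowns)]
        table = compute_allele_frequencies(
            dataset,
            subset=subset,
            populations=populations,
        )
        rows = [dataset.row(i) for i in unknowns]
        return cls(table, dataset.G[rows], unknowns)

    # -- sampler -----------------------------------------------------------

    def fit(self, params: McmcParams | None = None, interval_mass: float = 0.9) -> AdmixtureResults:
        params = params or McmcParams()
        rng = np.random.default_rng(params.seed)
        K = len(self.populations)
        N, L, _ = self.G.shape
        valid = self.table.valid  # (L, A)
        ref_counts = self.table.counts.astype(float)  # (K, L, A)
        prior = params.lam * valid[None, :, :] + ref_counts  # Dirichlet params sans z-counts

        X = self.G
        typed = X[:, :, 0] != MISSING  # (N, L)
        typed2 = np.repeat(typed[:, :, None], 2, axis=2)  # (N, L, 2)
        Xc = np.where(typed2, X, 0)
        t_i, t_l, t_c = np.nonzero(typed2)
        l_range = np.arange(L)

        q = rng.dirichlet(np.full(K, params.alpha), size=N)

        total_sweeps = params.burn_in + params.reps
        retained = []
        gamma = rng.standard_gamma
        for sweep in range(total_sweeps):
            # f ~ Dirichlet posterior from the reference counts
            g = gamma(prior) * valid[None, :, :]
            f = g / g.sum(axis=2, keepdims=True)

            # z | q, f
            f_t = f.transpose(1, 2, 0)  # (L, A, K)
            pz = f_t[l_range[None, :, None], Xc] * q[:, None, None, :]  # (N, L, 2, K)
            cum = np.cumsum(pz, axis=3)
            u = rng.random((N, L, 2, 1)) * cum[:, :, :, -1:]
            z = np.minimum((cum < u).sum(axis=3), K - 1)

            # q | z
            m = np.bincount(
                t_i * K + z[t_i, t_l, t_c], minlength=N * K
            ).reshape(N, K).astype(float)
            gq = gamma(params.alpha + m)
            q = gq / gq.sum(axis=1, keepdims=True)

            if sweep >= params.burn_in and (sweep - params.burn_in) % params.thin == 0:
                retained.append(q.copy())

        draws = np.stack(retained)
        return AdmixtureResults(
            self.ids,
            self.populations,
            draws,
            params,
            interval_mass,
            excluded_ids=self.excluded_ids,
        )


def run_admixture(
    dataset: GenotypeDataset,
    unknowns: list[str] | None = None,
    params: McmcParams | None = None,
    populations: list[str] | None = None,
) -> AdmixtureResults:
    """Convenience wrapper: build the supervised model from a labelled
    dataset and fit it."""
    model = AdmixtureModel.from_dataset(dataset, unknowns, populations=populations)
    return model.fit(params)
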