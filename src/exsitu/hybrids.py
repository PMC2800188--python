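"""Hybrid-class simulation and q-based classification.

To decide whether an unknown individual is a purebred or some class of
hybrid between two populations, genotypes of known ancestry classes are
simulated from the parental allele-frequency pools (parental, F1, F2 and
first- to third-generation backcrosses in both directions), run through the
same supervised admixture model as real queries, and their posterior-mean q
vectors collected per class. An observed q is then classified by

* its *compatible set*: every class whose empirical 2.5-97.5 percentile
  envelope covers q component-wise (overlap between classes is expected and
  reported, never hidden), and
* its *point class*: the class whose median q is nearest in Euclidean
  distance.

Backcross Bn means the nth serial cross back to one recurrent parental
line; the expected recurrent-parent ancestry is 0.75, 0.875, 0.9375 for
B1, B2, B3. For three-population comparisons the admixture runs with K = 3
on the pair-plus-third panel subset, and q vectors embed into the
2-simplex (triangle plot) via barycentric coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .admixture import AdmixtureModel, McmcParams
from .datamodel import AlleleFrequencyTable, GenotypeDataset, compute_allele_frequencies
from .simulate import simulate_class_genotype

CLASS_LABELS = (
    "parental_A",
    "parental_B",
    "F1",
    "F2",
    "B1_A",
    "B1_B",
    "B2_A",
    "B2_B",
    "B3_A",
    "B3_B",
)


def _base_and_recurrent(label: str) -> tuple[str, bool]:
    """(base class, recurrent-parent-is-A) for a distribution label."""
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {label!r}")
    if label in ("F1", "F2"):
        return label, True
    base, direction = label.split("_")
    return ("parental" if base == "parental" else base), direction == "A"


def simulate_class(
    label: str,
    freqs_A: np.ndarray,
    freqs_B: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate ``n`` genotypes of one ancestry class between pools A and B.

    Returns an (n, n_loci, 2) index array. For ``*_A`` labels A is the
    parental pool (or the recurrent parent of the backcross series), and
    symmetrically for ``*_B``. Loci where *either* pool has no frequency
    data (e.g. culled by QC) come out as missing in every simulant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base, to_A = _base_and_recurrent(label)
    fa, fb = (freqs_A, freqs_B) if to_A else (freqs_B, freqs_A)
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    empty = (fa.sum(axis=1) <= 0) | (fb.sum(axis=1) <= 0)
    if empty.any():
        # placeholder uniform rows keep the sampler happy; masked below
        fa = fa.copy()
        fb = fb.copy()
        fa[empty] = 1.0
        fb[empty] = 1.0
    G = np.stack([simulate_class_genotype(base, fa, fb, rng) for _ in range(n)])
    if empty.any():
        from .datamodel import MISSING

        G[:, empty, :] = MISSING
    return G


@dataclass
class ClassDistributions:
    """Empirical q distributions per ancestry class for one population pair."""

    pair: tuple[str, str]
    populations: list[str]  # q component order used by the admixture run
    q_samples: dict[str, np.ndarray]  # label -> (n, K)
    envelopes: dict[str, np.ndarray] = field(init=False)  # label -> (K, 2)
    medians: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.envelopes = {}
        self.medians = {}
        for label, qs in self.q_samples.items():
            lo = np.percentile(qs, 2.5, axis=0)
            hi = np.percentile(qs, 97.5, axis=0)
            self.envelopes[label] = np.stack([lo, hi], axis=1)
            self.medians[label] = np.median(qs, axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, qs in self.q_samples.items():
            for j, q in enumerate(qs):
                row = {"pair": f"{self.pair[0]}-{self.pair[1]}", "class": label,
                       "simulant": j}
                row.update({f"q_{p}": q[k] for k, p in enumerate(self.populations)})
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ClassAssignment:
    individual_id: str
    pair: tuple[str, str]
    point_class: str
    compatible_classes: list[str]
    distances: dict[str, float]
    barycentric: tuple[float, float] | None = None


def build_class_distributions(
    panel: GenotypeDataset,
    pairs: list[tuple[str, str]],
    n_per_class: int = 500,
    mcmc: McmcParams | None = None,
    labels: tuple[str, ...] = CLASS_LABELS,
    third_population: str | None = None,
    table: AlleleFrequencyTable | None = None,
) -> dict[tuple[str, str], ClassDistributions]:
    """Simulate every ancestry class for each pair and collect posterior q.

    Simulation frequencies are the observed parental frequencies of the
    panel; every simulant is run through the supervised admixture model
    against the panel restricted to the pair (plus ``third_population`` for
    the K = 3 triangle view), matching how real unknowns are displayed.
    All simulants of one pair share a single Gibbs chain.
    """
    mcmc = mcmc or McmcParams()
    if table is None:
        table = compute_allele_frequencies(panel)
    out: dict[tuple[str, str], ClassDistributions] = {}
    seeds = np.random.SeedSequence(mcmc.seed).spawn(len(pairs))
    for pair, seed_seq in zip(pairs, seeds):
        A, B = pair
        pops = [A, B] + (
            [third_population] if third_population and third_population not in pair else []
        )
        for p in pops:
            if p not in table.populations:
                raise ValueError(f"population {p!r} not in panel")
        fa = table.freqs[table.pop_row(A)]
        fb = table.freqs[table.pop_row(B)]
        rng = np.random.default_rng(seed_seq)
        sims, sim_ids, owners = [], [], []
        for label in labels:
            G = simulate_class(label, fa, fb, n_per_class, rng)
            sims.append(G)
            sim_ids.extend(f"{label}#{j}" for j in range(n_per_class))
            owners.extend([label] * n_per_class)
        G_all = np.concatenate(sims, axis=0)
        sub_table = _restrict_table(table, pops)
        run_params = McmcParams(
            burn_in=mcmc.burn_in, reps=mcmc.reps, alpha=mcmc.alpha,
            lam=mcmc.lam, thin=mcmc.thin,
            seed=int(seed_seq.generate_state(1)[0] % (2**31)),
        )
        res = AdmixtureModel(sub_table, G_all, sim_ids).fit(run_params)
        kept = set(res.ids)
        owners_kept = [o for o, iid in zip(owners, sim_ids) if iid in kept]
        q_samples = {
            label: res.mean_q[[i for i, o in enumerate(owners_kept) if o == label]]
            for label in labels
        }
        out[pair] = ClassDistributions(pair, res.populations, q_samples)
    return out


def _restrict_table(table: AlleleFrequencyTable, pops: list[str]) -> AlleleFrequencyTable:
    rows = [table.pop_row(p) for p in pops]
    return AlleleFrequencyTable(pops, table.loci, table.counts[rows])


def classify_by_q(
    q: np.ndarray,
    dists: ClassDistributions,
    individual_id: str = "query",
    atol: float = 1e-9,
) -> ClassAssignment:
    """Classify one simplex q vector against a pair's class distributions.

    The compatible set may be empty (reported as such); the point class is
    always the nearest class median.
    """
    q = np.asarray(q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-6 or (q < -1e-9).any():
        raise ValueError("q must lie on the simplex")
    compatible = []
    distances = {}
    for label, env in dists.envelopes.items():
        if np.all((q >= env[:, 0] - atol) & (q <= env[:, 1] + atol)):
            compatible.append(label)
        distances[label] = float(np.linalg.norm(q - dists.medians[label]))
    point = min(distances, key=lambda l: (distances[l], l))
    bary = barycentric_coordinates(q) if q.size == 3 else None
    return ClassAssignment(
        individual_id=individual_id,
        pair=dists.pair,
        point_class=point,
        compatible_classes=compatible,
        distances=distances,
        barycentric=bary,
    )


def barycentric_coordinates(q: np.ndarray) -> tuple[float, float]:
    """Standard 2-simplex embedding of a 3-component q vector, with vertices
    at (0,0), (1,0) and (1/2, sqrt(3)/2)."""
    q = np.asarray(q, dtype=float)
    if q.size != 3:
        raise ValueError("barycentric coordinates need exactly 3 components")
    x = q[1] + q[2] / 2.0
    y = q[2] * np.sqrt(3.0) / 2.0
    return float(x), float(y)
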