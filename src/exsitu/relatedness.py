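"""Marker-based pairwise relatedness, simulated dyad nulls and Mendelian
parentage checks.

The estimator is the variance-weighted regression relatedness of Lynch &
Ritland. For reference individual x with alleles (a, b) and proband y with
(c, d) at one locus, with S_ij = 1 when alleles i and j are identical in
state and p_a, p_b the reference-sample frequencies of x's alleles:

    r_locus = [p_a (S_bc + S_bd) + p_b (S_ac + S_ad) - 4 p_a p_b]
              / [(1 + S_ab)(p_a + p_b) - 4 p_a p_b]
    weight  = [(1 + S_ab)(p_a + p_b) - 4 p_a p_b] / (2 p_a p_b)

The multilocus estimate is the weight-averaged r over informative loci
(zero-denominator loci — e.g. a biallelic heterozygote at p = 0.5 — are
skipped), and the reported r_xy averages the two reciprocal estimates, which
makes the matrix exactly symmetric. Expectations: 0 for unrelateds, 0.25 for
half-siblings, 0.5 for full siblings and parent-offspring.

Relationship classification compares an observed r against distributions of
r simulated for known dyad classes from the same allele frequencies;
first-order classes overlap heavily and the ambiguity is always surfaced.
Parentage screening is by direct allele transmission: a candidate parent is
Mendelian-compatible when it shares at least one allele in state with the
offspring at every commonly typed locus, optionally also requiring an
identical mtDNA haplotype for maternity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset, Individual
from .simulate import cross, sample_genotype

DYAD_CLASSES = ("unrelated", "half_sib", "full_sib", "parent_offspring")

_EXPECTED_R = {
    "unrelated": 0.0,
    "half_sib": 0.25,
    "full_sib": 0.5,
    "parent_offspring": 0.5,
}


def _directional(
    x: np.ndarray, y: np.ndarray, freqs: np.ndarray, floor: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus numerator/(2 pa pb), weights, and informative mask for
    r(x -> y). Loci not typed in both are already excluded by the caller."""
    a, b = x[:, 0], x[:, 1]
    c, d = y[:, 0], y[:, 1]
    L = x.shape[0]
    ll = np.arange(L)
    pa = np.maximum(freqs[ll, a], floor)
    pb = np.maximum(freqs[ll, b], floor)
    Sab = (a == b).astype(float)
    num = (
        pa * ((b == c).astype(float) + (b == d).astype(float))
        + pb * ((a == c).astype(float) + (a == d).astype(float))
        - 4.0 * pa * pb
    )
    den = (1.0 + Sab) * (pa + pb) - 4.0 * pa * pb
    informative = np.abs(den) > 1e-12
    w = den / (2.0 * pa * pb)
    wr = num / (2.0 * pa * pb)  # = w * (num / den)
    return wr, w, informative


def lr_relatedness(
    x: np.ndarray,
    y: np.ndarray,
    freqs: np.ndarray,
    freq_floor: float | np.ndarray = 0.0,
) -> tuple[float, int]:
    """Reciprocal-averaged Lynch-Ritland relatedness of two genotypes.

    Parameters
    ----------
    x, y
        (n_loci, 2) allele-index arrays; -1 marks missing loci.
    freqs
        (n_loci, n_alleles) reference allele frequencies.
    freq_floor
        Lower bound applied to the frequencies of carried alleles (scalar or
        per-locus); alleles absent from the frequency sample would otherwise
        give division by zero. 0 disables flooring.

    Returns
    -------
    (r_xy, n_loci_used) where n_loci_used counts commonly typed loci
    informative in at least one direction.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("genotypes span different locus lists")
    common = (x[:, 0] != MISSING) & (y[:, 0] != MISSING)
    if not common.any():
        raise ValueError("no commonly typed loci; pair not assessable")
    xs, ys = x[common], y[common]
    fr = np.asarray(freqs)[common]
    floor = np.broadcast_to(np.asarray(freq_floor, dtype=float), (x.shape[0],))[common]
    zero = fr[np.arange(xs.shape[0])[:, None], np.concatenate([xs, ys], axis=1)] <= 0
    if zero.any() and not (floor > 0).any():
        raise ValueError(
            "a carried allele has zero frequency in the reference sample; "
            "supply freq_floor or frequencies covering the pair"
        )
    estimates = []
    used = np.zeros(xs.shape[0], dtype=bool)
    for ref, pro in ((xs, ys), (ys, xs)):
        wr, w, ok = _directional(ref, pro, fr, floor)
        if not ok.any():
            continue
        estimates.append(float(wr[ok].sum() / w[ok].sum()))
        used |= ok
    if not estimates:
        raise ValueError("zero informative loci; pair not assessable")
    return float(np.mean(estimates)), int(used.sum())


@dataclass
class RelatednessMatrix:
    ids: list[str]
    r: np.ndarray  # (n, n), nan diagonal, symmetric
    n_loci: np.ndarray  # (n, n) informative locus counts

    @property
    def mean_pairwise(self) -> float:
        iu = np.triu_indices(len(self.ids), k=1)
        vals = self.r[iu]
        return float(np.nanmean(vals))

    def value(self, id1: str, id2: str) -> float:
        i, j = self.ids.index(id1), self.ids.index(id2)
        return float(self.r[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def relatedness_matrix(
    ids: list[str],
    dataset: GenotypeDataset,
    freq_source: list[str],
    leave_one_out: bool = True,
) -> RelatednessMatrix:
    """Pairwise r over a set of individuals.

    Allele frequencies come from the ``freq_source`` individuals (e.g. the
    putatively unrelated animals of a parental pen). With ``leave_one_out``
    the frequencies for pair (x, y) are recomputed from the source minus the
    pair, so a pair's own alleles never bias the reference frequencies;
    alleles thereby absent from the reduced sample are floored at
    1/(2 n_genes + 2).
    """
    if not freq_source:
        raise ValueError("freq_source is empty")
    L = dataset.n_loci
    A = max(l.k for l in dataset.loci)
    counts = np.zeros((L, A), dtype=np.int64)

    def counts_of(iid: str) -> np.ndarray:
        g = dataset.G[dataset.row(iid)]
        c = np.zeros((L, A), dtype=np.int64)
        typed = g[:, 0] != MISSING
        ll = np.nonzero(typed)[0]
        for col in (0, 1):
            np.add.at(c, (ll, g[ll, col]), 1)
        return c

    source_set = set(freq_source)
    for iid in freq_source:
        counts += counts_of(iid)

    n = len(ids)
    r = np.full((n, n), np.nan)
    nl = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            c = counts.copy()
            if leave_one_out:
                for iid in (ids[i], ids[j]):
                    if iid in source_set:
                        c -= counts_of(iid)
            tot = c.sum(axis=1)
            if (tot == 0).all():
                raise ValueError("frequency source minus the pair is empty")
            with np.errstate(divide="ignore", invalid="ignore"):
                fr = np.where(tot[:, None] > 0, c / np.maximum(tot[:, None], 1), 0.0)
            floor = 1.0 / (2.0 * np.maximum(tot, 1) + 2.0)
            rij, used = lr_relatedness(
                dataset.G[dataset.row(ids[i])],
                dataset.G[dataset.row(ids[j])],
                fr,
                freq_floor=floor,
            )
            r[i, j] = r[j, i] = rij
            nl[i, j] = nl[j, i] = used
    return RelatednessMatrix(list(ids), r, nl)


# -- simulated dyad nulls --------------------------------------------------


@dataclass
class DyadDistributions:
    """Simulated r distributions per relationship class."""

    samples: dict[str, np.ndarray]
    means: dict[str, float] = field(init=False)
    envelopes: dict[str, tuple[float, float]] = field(init=False)

    def __post_init__(self) -> None:
        self.means = {k: float(np.mean(v)) for k, v in self.samples.items()}
        self.envelopes = {
            k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for k, v in self.samples.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": k, "replicate": i, "r": float(x)}
            for k, v in self.samples.items()
            for i, x in enumerate(v)
        ]
        return pd.DataFrame(rows)


def simulate_dyad_pair(
    relationship: str, freqs: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One dyad of known relationship drawn from HW genotypes at ``freqs``."""
    if relationship == "unrelated":
        return sample_genotype(freqs, rng), sample_genotype(freqs, rng)
    if relationship == "parent_offspring":
        parent = sample_genotype(freqs, rng)
        other = sample_genotype(freqs, rng)
        return parent, cross(parent, other, rng)
    if relationship == "full_sib":
        p1, p2 = sample_genotype(freqs, rng), sample_genotype(freqs, rng)
        return cross(p1, p2, rng), cross(p1, p2, rng)
    if relationship == "half_sib":
        shared = sample_genotype(freqs, rng)
        return (
            cross(shared, sample_genotype(freqs, rng), rng),
            cross(shared, sample_genotype(freqs, rng), rng),
        )
    raise ValueError(f"unknown relationship {relationship!r}")


def simulate_dyads(
    relationship: str,
    freqs: np.ndarray,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """r values for ``n`` simulated dyads of one relationship class,
    estimated against the same frequencies that generated them."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n)
    for i in range(n):
        x, y = simulate_dyad_pair(relationship, freqs, rng)
        out[i], _ = lr_relatedness(x, y, freqs)
    return out


def build_dyad_distributions(
    freqs: np.ndarray, n: int = 1000, seed: int = 0
) -> DyadDistributions:
    rng = np.random.default_rng(seed)
    return DyadDistributions(
        {cls: simulate_dyads(cls, freqs, n, rng) for cls in DYAD_CLASSES}
    )


def classify_dyad(r: float, dists: DyadDistributions) -> tuple[str, list[str]]:
    """(best class by nearest simulated mean, classes whose 2.5-97.5
    envelope contains r). Full-sib / parent-offspring overlap is expected;
    both typically appear in the compatible set."""
    best = min(dists.means, key=lambda k: (abs(r - dists.means[k]), k))
    compatible = [
        k for k, (lo, hi) in dists.envelopes.items() if lo <= r <= hi
    ]
    return best, compatible


# -- parentage -------------------------------------------------------------


def parentage_compatible(
    candidate_parent: Individual,
    offspring: Individual,
    require_mtdna_for_maternity: bool = False,
    mismatch_tolerance: int = 0,
) -> tuple[bool, list[int]]:
    """Mendelian parentage check by direct allele transmission.

    Compatible iff candidate and offspring share at least one allele in
    state at every commonly typed locus (up to ``mismatch_tolerance``
    mismatching loci). When the candidate is female and
    ``require_mtdna_for_maternity`` is set, both must additionally carry the
    same mtDNA haplotype (checked only when both are sequenced). Returns the
    compatibility flag and the list of mismatching locus indices.
    """
    gp = candidate_parent.genotype.indices
    go = offspring.genotype.indices
    if gp.shape != go.shape:
        raise ValueError("genotypes span different locus lists")
    common = (gp[:, 0] != MISSING) & (go[:, 0] != MISSING)
    if not common.any():
        raise ValueError("no commonly typed loci; pair not assessable")
    share = (
        (gp[:, 0:1] == go[:, 0:2]) | (gp[:, 1:2] == go[:, 0:2])
    ).any(axis=1)
    mismatches = [int(l) for l in np.nonzero(common & ~share)[0]]
    ok = len(mismatches) <= mismatch_tolerance
    if (
        ok
        and require_mtdna_for_maternity
        and candidate_parent.sex == "F"
        and candidate_parent.mtdna_sequence
        and offspring.mtdna_sequence
    ):
        ok = candidate_parent.mtdna_sequence == offspring.mtdna_sequence
    return ok, mismatches
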