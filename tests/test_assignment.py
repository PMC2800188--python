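import itertools

import numpy as np
import pytest

from exsitu import AssignmentModel, compute_allele_frequencies, genotype_score
from exsitu.assignment import genotype_probability_table
from exsitu.datamodel import AlleleFrequencyTable, GenotypeDataset, Locus


def table_from_counts(pop_counts: dict[str, list[list[int]]], n_alleles: int):
    """Build an AlleleFrequencyTable directly from per-pop (L, A) counts."""
    pops = list(pop_counts)
    L = len(next(iter(pop_counts.values())))
    loci = [Locus(f"L{l}", tuple(range(1, n_alleles + 1))) for l in range(L)]
    counts = np.array([pop_counts[p] for p in pops])
    return AlleleFrequencyTable(pops, loci, counts)


def brute_force_total(counts: np.ndarray, k: int) -> float:
    """Independent oracle: sum P(g) over all unordered genotypes by direct
    evaluation of the predictive formula."""
    n = counts.sum()
    x = counts + 1.0 / k
    total = 0.0
    for a in range(k):
        total += x[a] * (x[a] + 1) / ((n + 1) * (n + 2))
    for a, b in itertools.combinations(range(k), 2):
        total += 2 * x[a] * x[b] / ((n + 1) * (n + 2))
    return total


class TestPredictiveProbabilities:
    def test_prior_only_closed_form(self):
        # n = 0, k = 2: P(het) = 0.25, P(hom) = 0.375 each, total 1
        t = genotype_probability_table(
            np.zeros((1, 2)), np.array([2.0]), np.ones((1, 2), bool)
        )[0]
        assert t[0, 1] == pytest.approx(0.25)
        assert t[0, 0] == pytest.approx(0.375)
        assert t[1, 1] == pytest.approx(0.375)

    def test_worked_heterozygote_value(self):
        # counts {a:3, b:1}, k=2: P(a,b) = 2 * 3.5 * 1.5 / (5 * 6) = 0.35
        t = genotype_probability_table(
            np.array([[3.0, 1.0]]), np.array([2.0]), np.ones((1, 2), bool)
        )[0]
        assert t[0, 1] == pytest.approx(0.35)

    @pytest.mark.parametrize("seed", range(10))
    def test_probabilities_sum_to_one_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 11))
        counts = rng.integers(0, 40, size=k).astype(float)
        table = genotype_probability_table(
            counts[None, :], np.array([float(k)]), np.ones((1, k), bool)
        )[0]
        upper = np.triu(table).sum()
        assert upper == pytest.approx(1.0, abs=1e-12)
        assert upper == pytest.approx(brute_force_total(counts, k), abs=1e-12)

    def test_two_locus_additivity(self):
        counts = np.array([[3, 1], [2, 2]], dtype=float)
        k = np.array([2.0, 2.0])
        valid = np.ones((2, 2), bool)
        g = np.array([[0, 1], [0, 0]])
        both = genotype_score(g, counts, k, valid)
        l0 = genotype_score(np.array([[0, 1], [-1, -1]]), counts, k, valid)
        l1 = genotype_score(np.array([[-1, -1], [0, 0]]), counts, k, valid)
        assert both == pytest.approx(l0 + l1)

    def test_missing_loci_skipped_and_all_missing_errors(self):
        counts = np.array([[3.0, 1.0]])
        with pytest.raises(ValueError, match="no typed loci"):
            genotype_score(np.array([[-1, -1]]), counts, np.array([2.0]),
                           np.ones((1, 2), bool))


class TestAssignment:
    def test_forced_separation(self):
        t = table_from_counts(
            {"A": [[40, 0]], "B": [[0, 40]]}, n_alleles=2
        )
        model = AssignmentModel(t)
        res = model.assign(np.array([[[0, 0]]]), ["x"])
        assert res["x"].l1_pop == "A"
        assert res["x"].l2_pop == "B"
        assert res["x"].l1_score < res["x"].l2_score

    def test_tied_populations_break_lexicographically(self):
        t = table_from_counts(
            {"zeta": [[10, 10]], "alpha": [[10, 10]]}, n_alleles=2
        )
        res = AssignmentModel(t).assign(np.array([[[0, 1]]]), ["x"])
        assert res["x"].l1_pop == "alpha"
        assert res["x"].tie

    def test_score_invariant_to_locus_and_allele_order(self):
        counts = np.array([[3, 1, 0], [5, 2, 1]], dtype=float)
        k = np.array([3.0, 3.0])
        valid = np.ones((2, 3), bool)
        g = np.array([[0, 1], [2, 1]])
        s1 = genotype_score(g, counts, k, valid)
        s2 = genotype_score(g[::-1], counts[::-1], k, valid)  # loci permuted
        s3 = genotype_score(g[:, ::-1], counts, k, valid)  # alleles swapped
        assert s1 == pytest.approx(s2) == pytest.approx(s3)

    def test_self_assignment_improves_with_differentiation(self):
        from exsitu import ArchipelagoConfig, generate_reference_panel, sample_genotypes

        accs = []
        for diff in (50.0, 2.0):
            panel = generate_reference_panel(
                ArchipelagoConfig(n_populations=6, ref_sample_size=40,
                                  missing_rate=0.0, differentiation=diff, seed=17)
            )
            model = AssignmentModel(compute_allele_frequencies(panel.dataset))
            rng = np.random.default_rng(3)
            hits = total = 0
            for p, pop in enumerate(panel.populations):
                G = sample_genotypes(panel.true_freqs[p], 30, rng)
                res = model.assign(G, [f"{pop}:{i}" for i in range(30)])
                hits += sum(r.l1_pop == pop for r in res)
                total += 30
            accs.append(hits / total)
        assert accs[1] > accs[0]  # lower concentration = higher FST = better


@pytest.fixture(scope="module")
def model(small_table):
    return AssignmentModel(small_table)


class TestExclusion:

    def test_modal_genotype_not_excluded(self, small_panel, model):
        # most-common-allele homozygote at every locus: a typical genotype
        p = 0
        modal = np.argmax(small_panel.true_freqs[p], axis=1)
        g = np.stack([modal, modal], axis=1).astype(np.int32)
        pval, excluded = model.exclusion_test(g, "P01", n_sim=2000, seed=5)
        assert pval > 0.01
        assert not excluded

    def test_alien_genotype_excluded(self, small_panel, model):
        # alleles at the *lowest* frequency in P01 at every locus
        freqs = model.table.freqs[model.table.pop_row("P01")].copy()
        freqs[freqs == 0] = np.inf
        rare = np.argmin(freqs, axis=1)
        g = np.stack([rare, rare], axis=1).astype(np.int32)
        pval, excluded = model.exclusion_test(g, "P01", n_sim=5000, seed=5)
        assert pval < 0.01 and excluded

    def test_n_sim_floor(self, model):
        with pytest.raises(ValueError, match="n_sim"):
            model.exclusion_test(np.array([[0, 0]] * 6), "P01", n_sim=50)
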