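import numpy as np
import pytest

from exsitu import (
    ArchipelagoConfig,
    ClassGroup,
    Family,
    cross,
    generate_captive_colony,
    generate_reference_panel,
    realized_fst,
    sample_genotype,
    sample_genotypes,
)
from exsitu.datamodel import MISSING


class TestPanel:
    def test_seeded_determinism(self):
        cfg = ArchipelagoConfig(n_populations=3, ref_sample_size=10, seed=5)
        a = generate_reference_panel(cfg)
        b = generate_reference_panel(cfg)
        assert np.array_equal(a.dataset.G, b.dataset.G)
        assert np.array_equal(a.true_freqs, b.true_freqs)
        assert a.dataset.mtdna == b.dataset.mtdna

    def test_differentiation_limits(self):
        high = generate_reference_panel(
            ArchipelagoConfig(n_populations=8, differentiation=1e6, seed=2)
        )
        low = generate_reference_panel(
            ArchipelagoConfig(n_populations=8, differentiation=0.5, seed=2)
        )
        assert realized_fst(high.true_freqs) < 0.01
        assert realized_fst(low.true_freqs) > 0.3

    def test_missing_rate_realised(self):
        panel = generate_reference_panel(
            ArchipelagoConfig(missing_rate=0.1, seed=3)
        )
        assert abs(panel.dataset.missing_fraction() - 0.1) < 0.02

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ArchipelagoConfig(differentiation=0.0)
        with pytest.raises(ValueError):
            ArchipelagoConfig(missing_rate=1.0)


class TestSamplingPrimitives:
    def test_point_mass(self, rng):
        freqs = np.array([[1.0, 0.0], [0.0, 1.0]])
        g = sample_genotype(freqs, rng)
        assert g.tolist() == [[0, 0], [1, 1]]

    def test_law_of_large_numbers(self, rng):
        freqs = np.array([[0.7, 0.2, 0.1]])
        G = sample_genotypes(freqs, 10_000, rng)
        draws = G.ravel()
        props = np.bincount(draws, minlength=3) / draws.size
        # 3 sigma binomial envelope at n = 20,000 gene copies
        se = np.sqrt(freqs[0] * (1 - freqs[0]) / draws.size)
        assert np.all(np.abs(props - freqs[0]) < 3 * se + 1e-12)

    def test_empty_frequency_row_errors(self, rng):
        with pytest.raises(ValueError, match="empty frequency"):
            sample_genotype(np.array([[0.0, 0.0]]), rng)


class TestCross:
    def test_forced_outcome(self, rng):
        p1 = np.array([[0, 0]])
        p2 = np.array([[1, 1]])
        child = cross(p1, p2, rng)
        assert sorted(child[0].tolist()) == [0, 1]

    def test_mendelian_distribution(self, rng):
        p = np.array([[0, 1]])
        counts = {"aa": 0, "ab": 0, "bb": 0}
        for _ in range(4000):
            c = sorted(cross(p, p, rng)[0].tolist())
            counts[{(0, 0): "aa", (0, 1): "ab", (1, 1): "bb"}[tuple(c)]] += 1
        assert abs(counts["aa"] / 4000 - 0.25) < 0.03
        assert abs(counts["ab"] / 4000 - 0.50) < 0.03
        assert abs(counts["bb"] / 4000 - 0.25) < 0.03

    def test_offspring_shares_allele_with_each_parent(self, rng):
        freqs = np.full((5, 4), 0.25)
        for _ in range(50):
            p1, p2 = sample_genotype(freqs, rng), sample_genotype(freqs, rng)
            c = cross(p1, p2, rng)
            for l in range(5):
                assert c[l, 0] in p1[l] or c[l, 1] in p1[l]
                assert c[l, 0] in p2[l] or c[l, 1] in p2[l]

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cross(np.zeros((2, 2), int), np.zeros((3, 2), int), rng)

    def test_missing_parent_locus_gives_missing_offspring(self, rng):
        p1 = np.array([[MISSING, MISSING]])
        p2 = np.array([[0, 1]])
        assert cross(p1, p2, rng)[0, 0] == MISSING


class TestColony:
    def test_full_sibs_share_parents_and_mtdna(self, small_panel):
        colony, truth = generate_captive_colony(
            small_panel, [Family("full_sib", "P01", n_offspring=3)], seed=4
        )
        df = truth.to_frame()
        kids = df[df["parent1"].notna()]
        assert len(kids) == 3
        assert kids["parent1"].nunique() == 1 and kids["parent2"].nunique() == 1
        dam_hap = df.set_index("individual_id").loc[kids["parent2"].iloc[0], "mtdna_haplotype"]
        assert (kids["mtdna_haplotype"] == dam_hap).all()

    def test_f1_truth_fractions(self, small_panel):
        colony, truth = generate_captive_colony(
            small_panel, [ClassGroup("F1", ("P01", "P02"), 2)], seed=5
        )
        fr = truth.fractions(colony.ids[0])
        assert fr["P01"] == 0.5 and fr["P02"] == 0.5

    def test_b2_recurrent_fraction(self, small_panel):
        _, truth = generate_captive_colony(
            small_panel, [ClassGroup("B2", ("P01", "P02"), 1)], seed=6
        )
        fr = truth.fractions(list(truth.rows)[0])
        assert fr["P01"] == 0.875  # 1/2 + 1/2 * (1/2 + 1/2 * 1/2)

    def test_fractions_always_sum_to_one(self, small_panel):
        directives = [
            ClassGroup(lbl, ("P01", "P02"), 2)
            for lbl in ("F1", "F2", "B1", "B2", "B3")
        ] + [ClassGroup("parental", ("P03",), 2), Family("grandparent", "P04")]
        _, truth = generate_captive_colony(small_panel, directives, seed=7)
        df = truth.to_frame()
        frac_cols = [c for c in df.columns if c.startswith("frac_")]
        assert np.allclose(df[frac_cols].sum(axis=1), 1.0)

    def test_maternal_mtdna_along_pedigree(self, small_panel):
        colony, truth = generate_captive_colony(
            small_panel, [Family("grandparent", "P02", n_offspring=2)], seed=8
        )
        df = truth.to_frame().set_index("individual_id")
        assert df["mtdna_haplotype"].nunique() == 1  # whole maternal line

    def test_unknown_population_rejected(self, small_panel):
        with pytest.raises(ValueError, match="unknown population"):
            generate_captive_colony(
                small_panel, [ClassGroup("parental", ("NOPE",), 1)], seed=9
            )

    def test_seeded_determinism(self, small_panel):
        d = [ClassGroup("F1", ("P01", "P02"), 3), Family("half_sib", "P03")]
        c1, t1 = generate_captive_colony(small_panel, d, seed=10)
        c2, t2 = generate_captive_colony(small_panel, d, seed=10)
        assert np.array_equal(c1.G, c2.G)
        assert t1.to_frame().equals(t2.to_frame())
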