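import warnings

import numpy as np
import pytest

from exsitu import AdmixtureModel, McmcParams, posterior_summary
from exsitu.datamodel import AlleleFrequencyTable, GenotypeDataset, Locus

FAST = dict(burn_in=300, reps=2300, thin=4)


def two_pop_table(counts_a, counts_b, n_alleles):
    loci = [Locus(f"L{l}", tuple(range(n_alleles))) for l in range(len(counts_a))]
    return AlleleFrequencyTable(
        ["A", "B"], loci, np.array([counts_a, counts_b], dtype=np.int64)
    )


class TestParams:
    @pytest.mark.parametrize(
        "kw", [dict(reps=10, burn_in=20), dict(alpha=0), dict(thin=0), dict(lam=-1)]
    )
    def test_invalid_params(self, kw):
        with pytest.raises(ValueError):
            McmcParams(**kw)


class TestGibbs:
    def test_forced_separation(self):
        # disjoint point-mass alleles: pop A owns allele 0, pop B allele 1
        t = two_pop_table([[60, 0]] * 6, [[0, 60]] * 6, 2)
        G = np.zeros((1, 6, 2), dtype=np.int32)  # carries only pop-A alleles
        fit = AdmixtureModel(t, G, ["x"]).fit(McmcParams(seed=1, **FAST))
        assert fit.q("x")[0] >= 0.95

    def test_symmetric_uninformative_locus(self):
        # one typed locus, identical frequencies in both pops -> q ~ (.5, .5)
        t = two_pop_table([[30, 30]], [[30, 30]], 2)
        G = np.array([[[0, 1]]], dtype=np.int32)
        fit = AdmixtureModel(t, G, ["x"]).fit(
            McmcParams(seed=2, burn_in=500, reps=10500, thin=5)
        )
        assert abs(fit.q("x")[0] - 0.5) < 0.06

    def test_seeded_determinism(self):
        t = two_pop_table([[40, 5, 15]] * 4, [[5, 40, 15]] * 4, 3)
        rng = np.random.default_rng(9)
        G = rng.integers(0, 3, size=(5, 4, 2)).astype(np.int32)
        p = McmcParams(seed=7, **FAST)
        f1 = AdmixtureModel(t, G, list("abcde")).fit(p)
        f2 = AdmixtureModel(t, G, list("abcde")).fit(p)
        assert np.array_equal(f1.draws, f2.draws)

    def test_draws_on_simplex(self):
        t = two_pop_table([[40, 5]] * 4, [[5, 40]] * 4, 2)
        G = np.array([[[0, 1]] * 4, [[0, 0]] * 4], dtype=np.int32)
        fit = AdmixtureModel(t, G, ["x", "y"]).fit(McmcParams(seed=3, **FAST))
        assert np.allclose(fit.draws.sum(axis=2), 1.0, atol=1e-9)
        assert (fit.draws >= 0).all()

    def test_unknown_order_does_not_change_posteriors(self, small_panel, small_table):
        from exsitu import sample_genotypes

        rng = np.random.default_rng(4)
        G = np.concatenate(
            [sample_genotypes(small_panel.true_freqs[p], 4, rng) for p in range(2)]
        )
        ids = [f"u{i}" for i in range(8)]
        params = McmcParams(seed=5, burn_in=500, reps=8500, thin=4)
        f_fwd = AdmixtureModel(small_table, G, ids).fit(params)
        order = np.arange(8)[::-1]
        f_rev = AdmixtureModel(small_table, G[order], [ids[i] for i in order]).fit(params)
        for iid in ids:
            assert np.all(np.abs(f_fwd.q(iid) - f_rev.q(iid)) < 0.05)

    def test_zero_typed_unknown_excluded_with_warning(self):
        t = two_pop_table([[40, 5]] * 3, [[5, 40]] * 3, 2)
        G = np.array([[[0, 0]] * 3, [[-1, -1]] * 3], dtype=np.int32)
        with pytest.warns(UserWarning, match="zero typed loci"):
            model = AdmixtureModel(t, G, ["ok", "empty"])
        fit = model.fit(McmcParams(seed=6, **FAST))
        assert fit.ids == ["ok"]
        assert fit.excluded_ids == ["empty"]

    def test_needs_two_populations(self):
        loci = [Locus("L0", (0, 1))]
        t = AlleleFrequencyTable(["A"], loci, np.array([[[10, 10]]]))
        with pytest.raises(ValueError, match="K >= 2"):
            AdmixtureModel(t, np.zeros((1, 1, 2), np.int32), ["x"])


class TestPosteriorSummary:
    def test_constant_draws_collapse(self):
        draws = np.full((100, 2), 0.5)
        mean, lo, hi = posterior_summary(draws)
        assert np.all(mean == 0.5) and np.all(lo == 0.5) and np.all(hi == 0.5)

    def test_mean_matches_definition(self, rng):
        draws = rng.random((200, 3))
        mean, _, _ = posterior_summary(draws)
        assert np.allclose(mean, draws.mean(axis=0))

    def test_interval_bounds_are_order_statistics(self, rng):
        draws = rng.random(101)
        _, lo, hi = posterior_summary(draws[:, None], mass=0.9)
        srt = np.sort(draws)
        assert lo == srt[int(np.floor(0.05 * 100))]
        assert hi == srt[int(np.ceil(0.95 * 100))]

    def test_too_few_draws_error(self):
        with pytest.raises(ValueError, match="longer"):
            posterior_summary(np.zeros((10, 2)))
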