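import numpy as np
import pytest

from exsitu import (
    McmcParams,
    barycentric_coordinates,
    build_class_distributions,
    classify_by_q,
    simulate_class,
)
from exsitu.hybrids import CLASS_LABELS, ClassDistributions

FAST = McmcParams(burn_in=300, reps=2300, thin=4, seed=1)


def disjoint_pools(L=8, A=4):
    """Pool A owns alleles 0..A-1 of the first half, pool B the second."""
    fa = np.zeros((L, 2 * A))
    fb = np.zeros((L, 2 * A))
    fa[:, :A] = 1.0 / A
    fb[:, A:] = 1.0 / A
    return fa, fb


class TestBarycentric:
    @pytest.mark.parametrize(
        "q,xy",
        [
            ((1, 0, 0), (0.0, 0.0)),
            ((0, 1, 0), (1.0, 0.0)),
            ((0, 0, 1), (0.5, 0.8660)),
            ((1 / 3, 1 / 3, 1 / 3), (0.5, 0.2887)),
        ],
    )
    def test_vertices_and_centroid(self, q, xy):
        x, y = barycentric_coordinates(np.array(q))
        assert (x, y) == pytest.approx(xy, abs=5e-5)

    def test_wrong_dimension(self):
        with pytest.raises(ValueError):
            barycentric_coordinates(np.array([0.5, 0.5]))


class TestSimulateClass:
    def test_f1_heterozygous_across_pools(self, rng):
        fa, fb = disjoint_pools()
        G = simulate_class("F1", fa, fb, 50, rng)
        assert ((G[:, :, 0] < 4) & (G[:, :, 1] >= 4)).all()

    def test_parental_draws_from_one_pool(self, rng):
        fa, fb = disjoint_pools()
        assert (simulate_class("parental_A", fa, fb, 20, rng) < 4).all()
        assert (simulate_class("parental_B", fa, fb, 20, rng) >= 4).all()

    def test_b2_minor_pool_fraction(self, rng):
        # B2 to A: expected fraction of B-pool alleles = 0.125
        fa, fb = disjoint_pools()
        G = simulate_class("B2_A", fa, fb, 500, rng)
        frac_b = (G >= 4).mean()
        n = G.size
        se = np.sqrt(0.125 * 0.875 / n)
        assert abs(frac_b - 0.125) < 4 * se

    def test_f2_more_variable_than_f1(self, rng):
        fa, fb = disjoint_pools()
        f1 = simulate_class("F1", fa, fb, 500, rng)
        f2 = simulate_class("F2", fa, fb, 500, rng)
        share_f1 = (f1 >= 4).mean(axis=(1, 2))
        share_f2 = (f2 >= 4).mean(axis=(1, 2))
        assert abs(share_f2.mean() - 0.5) < 0.03
        assert share_f2.var() > share_f1.var()

    def test_unknown_label(self, rng):
        with pytest.raises(ValueError, match="unknown class label"):
            simulate_class("B4_A", *disjoint_pools(), 5, rng)


@pytest.fixture(scope="module")
def pair_dists(small_panel, small_table):
    return build_class_distributions(
        small_panel.dataset,
        pairs=[("P01", "P02")],
        n_per_class=40,
        mcmc=McmcParams(burn_in=500, reps=5500, thin=5, seed=2),
        table=small_table,
    )[("P01", "P02")]


class TestDistributionsAndClassification:
    def test_all_classes_present_on_simplex(self, pair_dists):
        assert set(pair_dists.q_samples) == set(CLASS_LABELS)
        for qs in pair_dists.q_samples.values():
            assert np.allclose(qs.sum(axis=1), 1.0, atol=1e-6)

    def test_envelope_orientation(self, pair_dists):
        for env in pair_dists.envelopes.values():
            assert (env[:, 0] <= env[:, 1]).all()

    def test_parental_envelope_excludes_half(self, pair_dists):
        env = pair_dists.envelopes["parental_A"]
        assert env[0, 0] > 0.5  # q_A of pure A stays well above 0.5

    def test_f1_envelope_contains_half(self, pair_dists):
        env = pair_dists.envelopes["F1"]
        assert env[0, 0] <= 0.5 <= env[0, 1]

    def test_median_self_classifies(self, pair_dists):
        for label in ("parental_A", "F1", "parental_B"):
            ca = classify_by_q(pair_dists.medians[label], pair_dists)
            assert ca.point_class == label
            assert label in ca.compatible_classes

    def test_out_of_envelope_q_reports_empty_compatible_set(self, pair_dists):
        # q far outside every envelope: negative-ish corner never simulated
        ca = classify_by_q(np.array([0.0, 1.0]), pair_dists)
        assert ca.point_class  # still reported
        if ca.compatible_classes:
            assert set(ca.compatible_classes) <= {"parental_B"}

    def test_degenerate_single_simulant_envelope(self):
        qs = {"F1": np.array([[0.5, 0.5]])}
        d = ClassDistributions(("A", "B"), ["A", "B"], qs)
        assert np.allclose(d.envelopes["F1"][:, 0], d.envelopes["F1"][:, 1])

    def test_envelopes_widen_with_lower_differentiation(self):
        from exsitu import ArchipelagoConfig, compute_allele_frequencies, generate_reference_panel

        widths = []
        for diff in (2.0, 20.0):
            panel = generate_reference_panel(
                ArchipelagoConfig(n_populations=2, n_loci=6, ref_sample_size=30,
                                  missing_rate=0.0, differentiation=diff, seed=21)
            )
            d = build_class_distributions(
                panel.dataset, [("P01", "P02")], n_per_class=40,
                mcmc=McmcParams(burn_in=400, reps=4400, thin=5, seed=3),
                labels=("parental_A", "F1"),
            )[("P01", "P02")]
            env = d.envelopes["parental_A"]
            widths.append(float(env[0, 1] - env[0, 0]))
        assert widths[1] > widths[0]  # high concentration = low FST = wider
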