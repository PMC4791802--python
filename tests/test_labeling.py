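import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from flux13c import network as nw
from flux13c import synthetic as sy
from flux13c.labeling import (
    MassIsotopomerDistribution,
    MeasurementSet,
    add_noise,
    apply_derivatization_background,
    correct_natural_abundance,
    default_fragments,
    fragment_mdvs,
    make_tracer,
    parse_formula,
    simulate_labeling,
)


class TestTracers:
    def test_u13c_mixture_fractions(self):
        tr = make_tracer("20pct-U13C")
        assert tr.pools[0][0] == pytest.approx(0.20)
        assert tr.pools[1][0] == pytest.approx(0.80)
        assert all(p == pytest.approx(0.99) for p in tr.pools[0][1])

    def test_positional_tracer_purity(self):
        tr = make_tracer("1-13C")
        enr = tr.pools[0][1]
        assert enr[0] == pytest.approx(0.99)
        assert all(p == pytest.approx(0.0107) for p in enr[1:])

    def test_unlabeled_is_natural_everywhere(self):
        tr = make_tracer("unlabeled")
        assert all(p == pytest.approx(0.0107) for p in tr.pools[0][1])

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown tracer"):
            make_tracer("2-13C")

    def test_fractions_must_sum_to_one(self):
        from flux13c.emu import PositionalLabeling

        with pytest.raises(ValueError, match="sum"):
            PositionalLabeling([(0.5, (0.99,) * 6), (0.4, (0.0107,) * 6)])


class TestFragments:
    def test_full_molecule_fragment_equals_precursor_mdv(
        self, yeast_net, reference_fluxes
    ):
        frags = default_fragments()
        sol = simulate_labeling(
            yeast_net, reference_fluxes, make_tracer("1-13C"),
            extra_emus=[(f.precursor, f.retained_carbons) for f in frags.values()],
        )
        mdvs = fragment_mdvs(sol, [frags["Ala_M57"]])
        assert np.allclose(mdvs["Ala_M57"].fractions, sol.mdv("pyr_m"), atol=1e-12)

    def test_glycine_fragment_is_serine_marginal(self, yeast_net, reference_fluxes):
        """Gly inherits serine C1-C2; the network routes it through SHMT."""
        sol = simulate_labeling(
            yeast_net, reference_fluxes, make_tracer("1-13C"),
            extra_emus=[("ser", (1, 2)), ("gly", (1, 2))],
        )
        # with the reference strain's threonine-aldolase share, glycine is a
        # mixture of ser C1-C2 and thr C1-C2; check the SHMT-only case
        spec = sy.StrainSpec(name="shmt-only", glyt_frac=0.0)
        v = sy.build_strain_fluxes(yeast_net, spec)
        sol2 = simulate_labeling(
            yeast_net, v, make_tracer("1-13C"),
            extra_emus=[("ser", (1, 2))],
        )
        assert np.allclose(sol2.mdv("gly"), sol2.mdv("ser", (1, 2)), atol=1e-10)

    def test_unlabeled_tracer_gives_binomial_fragment(self, yeast_net, reference_fluxes):
        frags = default_fragments()
        sol = simulate_labeling(
            yeast_net, reference_fluxes, make_tracer("unlabeled"),
            extra_emus=[(f.precursor, f.retained_carbons) for f in frags.values()],
        )
        mdv = fragment_mdvs(sol, [frags["Ala_M57"]])["Ala_M57"]
        assert np.allclose(mdv.fractions, binom.pmf(range(4), 3, 0.0107), atol=1e-10)

    def test_formula_parsing(self):
        assert parse_formula("C8H26NO2Si2") == {"C": 8, "H": 26, "N": 1, "O": 2, "Si": 2}
        with pytest.raises(ValueError):
            parse_formula("C8H26#bad")


class TestDerivatization:
    def test_empty_formula_is_identity(self):
        mdv = MassIsotopomerDistribution("x", 3, np.array([0.7, 0.2, 0.08, 0.02]))
        out = apply_derivatization_background(mdv, {})
        assert np.allclose(out.fractions, mdv.fractions, atol=1e-12)

    def test_single_derivative_carbon_adds_natural_m1(self):
        """Closed form: unlabeled 2-carbon skeleton + 1 background carbon."""
        a = 0.0107
        skel = binom.pmf(range(3), 2, a)
        mdv = MassIsotopomerDistribution("x", 2, skel)
        out = apply_derivatization_background(mdv, {"C": 1})
        conv = np.convolve(skel, [1 - a, a])[:3]
        assert np.allclose(out.fractions, conv / conv.sum(), atol=1e-12)
        assert out.fractions[1] > skel[1]

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=7),
        st.integers(0, 12),
        st.integers(0, 3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_property(self, raw, n_c, n_si):
        """correct(apply(x)) == x for random MDVs and formulas."""
        x = np.array(raw)
        x /= x.sum()
        mdv = MassIsotopomerDistribution("x", len(x) - 1, x)
        formula = {"C": n_c, "H": 2 * n_c, "N": 1, "O": 2, "Si": n_si}
        back = apply_derivatization_background(mdv, formula)
        rec = correct_natural_abundance(back, formula)
        assert np.abs(rec.fractions - x).max() < 1e-8


class TestNoise:
    def test_zero_sd_returns_input(self):
        mdvs = {"f": MassIsotopomerDistribution("f", 2, np.array([0.5, 0.3, 0.2]))}
        ms = add_noise(mdvs, 0.0, seed=1)
        assert np.array_equal(ms.get("f").mdv.fractions, [0.5, 0.3, 0.2])

    def test_same_seed_is_deterministic(self):
        mdvs = {"f": MassIsotopomerDistribution("f", 2, np.array([0.5, 0.3, 0.2]))}
        a = add_noise(mdvs, 0.004, seed=7)
        b = add_noise(mdvs, 0.004, seed=7)
        assert np.array_equal(a.get("f").mdv.fractions, b.get("f").mdv.fractions)

    def test_empirical_channel_sd_matches_nominal(self):
        """1e4 replicates: empirical channel sd within 10 % of the
        first-order expectation (additive sigma reshaped by the
        renormalization: var_i = sigma^2 (1 - 2 x_i + n x_i^2))."""
        x = np.array([0.5, 0.3, 0.2])
        sigma = 0.004
        mdvs = {"f": MassIsotopomerDistribution("f", 2, x)}
        draws = np.array(
            [add_noise(mdvs, sigma, seed=k).get("f").mdv.fractions for k in range(10000)]
        )
        sd = draws.std(axis=0)
        expected = sigma * np.sqrt(1 - 2 * x + len(x) * x ** 2)
        assert np.all(np.abs(sd - expected) / expected < 0.10)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            add_noise({}, -0.1, seed=0)


class TestMeasurementTable:
    def test_tsv_round_trip(self, reference_measurements):
        ms = reference_measurements[0]
        back = MeasurementSet.from_tsv(ms.to_tsv())
        assert back.tracer_id == ms.tracer_id
        assert back.seed == ms.seed
        for a, b in zip(ms, back):
            assert a.fragment_id == b.fragment_id
            assert np.allclose(a.mdv.fractions, b.mdv.fractions, atol=1e-7)
            assert a.sd == pytest.approx(b.sd, abs=1e-6)

    def test_missing_trailing_channels_become_absent(self):
        text = (
            "# tracer: 1-13C\n"
            "fragment_id\tn_carbons\tm0\tm1\tm2\tm3\tsd\n"
            "Ala_M57\t3\t0.5\t0.3\t\t\t0.004\n"
        )
        ms = MeasurementSet.from_tsv(text)
        vals = ms.get("Ala_M57").mdv.fractions
        assert np.isnan(vals[2]) and np.isnan(vals[3])
        assert vals[0] == 0.5
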