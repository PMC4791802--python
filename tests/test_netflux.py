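import numpy as np
import pytest

from flux13c import network as nw
from flux13c import synthetic as sy
from flux13c.netflux import (
    ExtracellularRates,
    FluxDistribution,
    InfeasibleConstraintsError,
    UnderdeterminedError,
    chemostat_rates,
    compare_strains,
    estimate_net_fluxes,
    monte_carlo_ci,
    normalize,
)
from flux13c.ratios import (
    FluxRatioSet,
    RatioConstraint,
    RatioEstimate,
    TrioseProbe,
    ratios_to_constraints,
)
from conftest import toy_path


def exact_ratio_set(truth, me_halfwidth=0.05, sds=None):
    """Ratio set from a true flux vector; sd=None makes equalities hard."""
    ests = {}
    for name in (
        "oaa_cyt_from_pyr_cyt",
        "oaa_mit_from_anaplerosis",
        "pep_from_oaa_cyt",
        "ser_from_glycolysis",
        "gly_to_ser_contribution",
        "ser_to_gly_contribution",
    ):
        sd = sds.get(name) if sds else None
        ests[name] = RatioEstimate(name, truth[name], sd, truth[name], truth[name], (), "determined")
    me = truth["pyr_mit_from_malic_enzyme_lb"]
    ests["pyr_mit_from_malic_enzyme"] = RatioEstimate(
        "pyr_mit_from_malic_enzyme", None, None,
        max(0.0, me - me_halfwidth), min(1.0, me + me_halfwidth), (), "interval",
    )
    return FluxRatioSet(ests)


def true_probe(v):
    s = v["PGI"] / (v["PGI"] + v["TAL"] + v["TKL2"])
    return TrioseProbe(s * v["TPI"] / v["GAPD"], 0.01)


class TestChemostatRates:
    def test_zero_concentration_gives_zero_rate(self):
        r = chemostat_rates(0.04, {"3hp": (0.0, 0.0)}, biomass=1.0)
        assert r.rates["3hp"][0] == 0.0

    def test_hand_arithmetic_3hp_secretion(self):
        """D = 0.04/h, 1 g/L 3HP (M = 90.08), X = 1 gDW/L -> 0.444."""
        r = chemostat_rates(
            0.04, {"3hp": (1.0, 0.05)}, biomass=1.0, molar_masses={"3hp": 90.08}
        )
        assert r.rates["3hp"][0] == pytest.approx(0.04 * 1000 / 90.08, rel=1e-12)
        assert r.rates["3hp"][0] == pytest.approx(0.444, abs=5e-4)

    def test_growth_rate_equals_dilution_rate(self):
        r = chemostat_rates(0.04, {}, biomass=2.0)
        assert r.growth_rate[0] == 0.04

    def test_residual_glucose_above_feed_rejected(self):
        with pytest.raises(ValueError, match="residual"):
            chemostat_rates(0.04, {}, biomass=1.0, feed_glucose=5.0,
                            residual_glucose=(6.0, 0.0))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            chemostat_rates(0.04, {"acetate": (-1.0, 0.0)}, biomass=1.0)


class TestEstimateNetFluxes:
    def test_toy_system_noise_free_exact_recovery(self):
        """Fully determined toy: forward-generated rates invert exactly."""
        net = nw.load_network_file(toy_path("cycle"))
        v_true = {"RCS": 1.0, "RDC": 1.0, "RKD": 0.6, "RAN": 0.4, "RKX": 0.4}
        rates = ExtracellularRates(
            (0.4, 0.01), {"glucose": (1.0, 0.01), "pyruvate": (0.4, 0.01)}
        )
        fd = estimate_net_fluxes(
            net, rates, (),
            rate_reactions={"glucose": "RCS", "growth": "RKX", "pyruvate": "RAN"},
        )
        for rid, val in v_true.items():
            assert fd.values[rid] == pytest.approx(val, abs=1e-8)
        assert fd.residual <= 1e-10

    def test_yeast_noise_free_exact_recovery(self, yeast_net, reference_fluxes):
        truth = sy.true_ratios(reference_fluxes)
        rates = sy.rates_from_fluxes(yeast_net, reference_fluxes, 0.04)
        cons = ratios_to_constraints(exact_ratio_set(truth), yeast_net)
        fd = estimate_net_fluxes(
            yeast_net, rates, cons, triose_probe=true_probe(reference_fluxes)
        )
        err = max(abs(fd.values[r] - reference_fluxes.get(r, 0.0)) for r in fd.values)
        assert err < 1e-8
        assert fd.residual <= 1e-10

    def test_balances_hold_for_any_estimate(self, yeast_net, reference_fluxes):
        truth = sy.true_ratios(reference_fluxes)
        rates = sy.rates_from_fluxes(yeast_net, reference_fluxes, 0.04, seed=2)
        cons = ratios_to_constraints(exact_ratio_set(truth), yeast_net)
        fd = estimate_net_fluxes(
            yeast_net, rates, cons, triose_probe=true_probe(reference_fluxes)
        )
        S = yeast_net.stoichiometric_matrix()
        v = np.array([fd.values[r.id] for r in yeast_net.reactions])
        assert np.abs(S @ v).max() < 1e-6

    def test_glucose_forced_to_zero_is_infeasible(self, yeast_net, reference_fluxes):
        truth = sy.true_ratios(reference_fluxes)
        rates = sy.rates_from_fluxes(yeast_net, reference_fluxes, 0.04)
        cons = list(ratios_to_constraints(exact_ratio_set(truth), yeast_net))
        cons.append(RatioConstraint({"GLK": 1.0}, 0.0, "equality", "forced-zero"))
        with pytest.raises(InfeasibleConstraintsError, match="glucose"):
            estimate_net_fluxes(
                yeast_net, rates, cons, triose_probe=true_probe(reference_fluxes)
            )

    def test_without_pp_probe_system_is_underdetermined(
        self, yeast_net, reference_fluxes
    ):
        """The eight branch-point ratios leave the oxidative-PP split free;
        the estimator must say so rather than silently pick a solution."""
        truth = sy.true_ratios(reference_fluxes)
        rates = sy.rates_from_fluxes(yeast_net, reference_fluxes, 0.04)
        cons = ratios_to_constraints(exact_ratio_set(truth), yeast_net)
        with pytest.raises(UnderdeterminedError) as exc:
            estimate_net_fluxes(yeast_net, rates, cons)
        assert any("ZWF" in d for d in exc.value.directions)

    def test_estimate_invariant_to_constraint_order_and_weight_scale(
        self, yeast_net, reference_fluxes
    ):
        truth = sy.true_ratios(reference_fluxes)
        sds = {k: 0.02 for k in truth}
        rates = sy.rates_from_fluxes(yeast_net, reference_fluxes, 0.04, seed=5)
        cons = ratios_to_constraints(exact_ratio_set(truth, sds=sds), yeast_net)
        probe = true_probe(reference_fluxes)
        fd1 = estimate_net_fluxes(yeast_net, rates, cons, triose_probe=probe)
        fd2 = estimate_net_fluxes(
            yeast_net, rates, list(reversed(cons)), triose_probe=probe
        )
        for r in fd1.values:
            assert fd1.values[r] == pytest.approx(fd2.values[r], abs=1e-8)


class TestNormalize:
    def test_normalized_glucose_is_exactly_one(self, yeast_net, reference_fluxes):
        fd = FluxDistribution(dict(reference_fluxes))
        nf = normalize(fd)
        assert nf.values["GLK"] == 1.0
        assert nf.normalized

    def test_idempotent(self, reference_fluxes):
        fd = FluxDistribution(dict(reference_fluxes))
        once = normalize(fd)
        twice = normalize(once)
        assert once.values == twice.values

    def test_flux_ratios_unchanged(self, reference_fluxes):
        fd = FluxDistribution(dict(reference_fluxes))
        nf = normalize(fd)
        assert nf.values["CS"] / nf.values["ZWF"] == pytest.approx(
            fd.values["CS"] / fd.values["ZWF"], rel=1e-12
        )

    def test_zero_uptake_rejected(self):
        with pytest.raises(ValueError):
            normalize(FluxDistribution({"GLK": 0.0}))


class TestMonteCarloCI:
    def _setup(self, yeast_net, reference_fluxes, rate_sd, ratio_sd):
        truth = sy.true_ratios(reference_fluxes)
        rates = ExtracellularRates(
            (0.04, rate_sd),
            {
                sp: (reference_fluxes.get(rid, 0.0), max(rate_sd, 1e-9))
                for sp, rid in (
                    ("glucose", "GLK"), ("glycerol", "GLYX"), ("acetate", "ACCX"),
                    ("pyruvate", "PYRX"), ("ethanol", "ETOHX"),
                )
            },
        )
        sds = {k: ratio_sd for k in truth}
        return rates, exact_ratio_set(truth, sds=sds)

    def test_zero_sds_collapse_ci_to_point(self, yeast_net, reference_fluxes):
        rates, ratios = self._setup(yeast_net, reference_fluxes, 1e-12, 1e-12)
        fd = monte_carlo_ci(
            yeast_net, rates, ratios, n_draws=16, seed=0,
            triose_probe=TrioseProbe(true_probe(reference_fluxes).value, 1e-12),
        )
        for rid, (lb, ub) in fd.ci.items():
            assert ub - lb < 1e-6
            assert lb - 1e-6 <= fd.values[rid] <= ub + 1e-6

    def test_same_seed_gives_identical_intervals(self, yeast_net, reference_fluxes):
        rates, ratios = self._setup(yeast_net, reference_fluxes, 0.005, 0.02)
        probe = true_probe(reference_fluxes)
        a = monte_carlo_ci(yeast_net, rates, ratios, n_draws=16, seed=3,
                           triose_probe=probe)
        b = monte_carlo_ci(yeast_net, rates, ratios, n_draws=16, seed=3,
                           triose_probe=probe)
        assert a.ci == b.ci

    def test_too_few_draws_rejected(self, yeast_net, reference_fluxes):
        rates, ratios = self._setup(yeast_net, reference_fluxes, 0.005, 0.02)
        with pytest.raises(ValueError):
            monte_carlo_ci(yeast_net, rates, ratios, n_draws=1, seed=0)


class TestCompareStrains:
    def test_identical_distributions_give_zero_change(self, reference_fluxes):
        nf = normalize(FluxDistribution(dict(reference_fluxes)))
        changes = compare_strains(nf, nf)
        assert all(c == 0.0 for c in changes.values())

    def test_plus_23_percent_arithmetic(self):
        a = FluxDistribution({"GLK": 1.0, "ZWF": 0.2, "CS": 1.0}, normalized=True)
        b = FluxDistribution({"GLK": 1.0, "ZWF": 0.246, "CS": 1.0}, normalized=True)
        changes = compare_strains(a, b)
        assert changes["PP"] == pytest.approx(23.0, abs=1e-9)

    def test_requires_normalized_inputs(self, reference_fluxes):
        fd = FluxDistribution(dict(reference_fluxes))
        with pytest.raises(ValueError, match="normalized"):
            compare_strains(fd, fd)

    def test_zero_reference_group_rejected(self):
        a = FluxDistribution({"ZWF": 0.0, "CS": 1.0}, normalized=True)
        b = FluxDistribution({"ZWF": 0.1, "CS": 1.0}, normalized=True)
        with pytest.raises(ZeroDivisionError):
            compare_strains(a, b)
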