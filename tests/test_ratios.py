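import numpy as np
import pytest

from flux13c import network as nw
from flux13c import synthetic as sy
from flux13c.labeling import (
    MassIsotopomerDistribution,
    MeasurementSet,
    add_noise,
    apply_derivatization_background,
    default_fragments,
    make_tracer,
)
from flux13c.ratios import (
    FluxRatioSet,
    RatioEstimate,
    compute_ratios,
    ratios_to_constraints,
    standard_ratio_definitions,
    triose_intact_fraction,
)


def _measurements(net, fluxes, seed, sd=0.004):
    return [
        sy.generate_measurements(net, fluxes, make_tracer("1-13C"), seed=seed, sd=sd),
        sy.generate_measurements(
            net, fluxes, make_tracer("20pct-U13C"), seed=seed + 999, sd=sd
        ),
    ]


class TestComputeRatios:
    def test_zero_pck_truth_recovers_zero_ratio(self, yeast_net):
        """Data simulated without PEP carboxykinase flux must give
        pep_from_oaa_cyt = 0 within 3 propagated sd."""
        spec = sy.StrainSpec(name="no-pck", pck_frac=0.0)
        v = sy.build_strain_fluxes(yeast_net, spec)
        rs = compute_ratios(_measurements(yeast_net, v, seed=3))
        est = rs["pep_from_oaa_cyt"]
        assert est.status == "determined"
        assert abs(est.value - 0.0) <= 3 * est.sd + 1e-12

    def test_serine_exclusively_glycolytic_recovers_one(self, yeast_net):
        spec = sy.StrainSpec(name="no-shmr", shmr_frac=0.0)
        v = sy.build_strain_fluxes(yeast_net, spec)
        rs = compute_ratios(_measurements(yeast_net, v, seed=4))
        est = rs["ser_from_glycolysis"]
        assert est.status == "determined"
        assert abs(est.value - 1.0) <= 3 * est.sd + 1e-12

    def test_mixture_identity_gives_ratio_one(self, yeast_net):
        """Degenerate least squares: product MDV equals source A exactly."""
        frags = default_fragments()
        rdef = next(
            d for d in standard_ratio_definitions() if d.name == "oaa_cyt_from_pyr_cyt"
        )
        skeletons = {
            "Thr_f302": np.array([0.6, 0.3, 0.1]),
            "Val_f302": np.array([0.6, 0.3, 0.1]),   # == product
            "Asp_f302": np.array([0.2, 0.5, 0.3]),   # != product
        }
        entries = {}
        for fid, skel in skeletons.items():
            mdv = MassIsotopomerDistribution(fid, 2, skel)
            entries[fid] = apply_derivatization_background(mdv, frags[fid].formula)
        # remaining fragments: anything valid
        for fid, f in frags.items():
            if fid not in entries:
                n = f.n_carbons
                mdv = MassIsotopomerDistribution(fid, n, np.ones(n + 1) / (n + 1))
                entries[fid] = apply_derivatization_background(mdv, f.formula)
        ms = add_noise(entries, 0.0, seed=0, tracer_id="1-13C")
        rs = compute_ratios(ms, definitions=[rdef])
        assert rs["oaa_cyt_from_pyr_cyt"].value == pytest.approx(1.0, abs=1e-6)

    def test_row_order_invariance(self, yeast_net, reference_measurements):
        rs1 = compute_ratios(reference_measurements)
        shuffled = [
            MeasurementSet(list(reversed(ms.entries)), ms.tracer_id, ms.seed)
            for ms in reference_measurements
        ]
        rs2 = compute_ratios(shuffled)
        for a, b in zip(rs1, rs2):
            if a.value is None:
                assert b.value is None
            else:
                assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_indistinguishable_sources_marked_undetermined(
        self, yeast_net, reference_fluxes
    ):
        """Unlabeled glucose carries no routing information at all."""
        ms = sy.generate_measurements(
            yeast_net, reference_fluxes, make_tracer("unlabeled"), seed=5
        )
        rs = compute_ratios(ms)
        for est in rs:
            assert est.status == "undetermined"
            assert (est.lb, est.ub) == (0.0, 1.0)

    def test_missing_fragment_is_named(self, reference_measurements):
        trimmed = [
            MeasurementSet(
                [e for e in ms.entries if e.fragment_id != "Asp_M57"],
                ms.tracer_id,
                ms.seed,
            )
            for ms in reference_measurements
        ]
        with pytest.raises(KeyError, match="Asp_M57"):
            compute_ratios(trimmed)

    def test_malic_enzyme_reported_as_interval(self, reference_measurements):
        est = compute_ratios(reference_measurements)["pyr_mit_from_malic_enzyme"]
        assert est.status in ("interval", "undetermined")
        assert 0.0 <= est.lb <= est.ub <= 1.0


class TestTrioseProbe:
    def test_probe_tracks_pp_split(self, yeast_net):
        """A higher oxidative-PP split lowers the intact-triose fraction."""
        lo = sy.build_strain_fluxes(yeast_net, sy.StrainSpec(name="lo", zwf_frac=0.10))
        hi = sy.build_strain_fluxes(
            yeast_net, sy.StrainSpec(name="hi", zwf_frac=0.40, cs_frac=0.80)
        )
        probes = []
        for v in (lo, hi):
            ms = _measurements(yeast_net, v, seed=6, sd=0.0)
            probes.append(triose_intact_fraction(ms, compute_ratios(ms)).value)
        assert probes[0] > probes[1]

    def test_probe_requires_positional_tracer(self, yeast_net, reference_fluxes):
        ms = sy.generate_measurements(
            yeast_net, reference_fluxes, make_tracer("20pct-U13C"), seed=7
        )
        rs_dummy = None
        assert triose_intact_fraction([ms], rs_dummy) is None


class TestRatioConstraints:
    def _full_set(self, values=None):
        values = values or {}
        ests = {}
        for name in (
            "oaa_cyt_from_pyr_cyt",
            "oaa_mit_from_anaplerosis",
            "pep_from_oaa_cyt",
            "ser_from_glycolysis",
            "gly_to_ser_contribution",
            "ser_to_gly_contribution",
        ):
            r = values.get(name, 0.5)
            ests[name] = RatioEstimate(name, r, 0.02, r, r, ("1-13C",), "determined")
        ests["pyr_mit_from_malic_enzyme"] = RatioEstimate(
            "pyr_mit_from_malic_enzyme", None, None, 0.0, 0.3, ("1-13C",), "interval"
        )
        return FluxRatioSet(ests)

    def test_full_ratio_set_emits_exactly_eight_constraints(self, yeast_net):
        cons = ratios_to_constraints(self._full_set(), yeast_net)
        assert len(cons) == 8
        assert sum(c.kind == "equality" for c in cons) == 6
        assert sum(c.kind == "inequality" for c in cons) == 2

    def test_half_ratio_means_equal_fluxes(self, yeast_net):
        cons = ratios_to_constraints(self._full_set(), yeast_net)
        c = next(c for c in cons if c.provenance == "oaa_cyt_from_pyr_cyt")
        assert c.coefficients == {"PYC": 0.5, "OAT2": -0.5}

    def test_zero_ratio_forces_route_a_to_zero(self, yeast_net):
        cons = ratios_to_constraints(
            self._full_set({"pep_from_oaa_cyt": 0.0}), yeast_net
        )
        c = next(c for c in cons if c.provenance == "pep_from_oaa_cyt")
        assert c.coefficients == {"PCK": 1.0, "ENO": 0.0}

    def test_constraints_are_flux_scale_homogeneous(self, yeast_net, reference_fluxes):
        cons = ratios_to_constraints(self._full_set(), yeast_net)
        v1 = dict(reference_fluxes)
        v2 = {k: 3.5 * x for k, x in v1.items()}
        for c in cons:
            r1 = sum(coeff * v1.get(r, 0.0) for r, coeff in c.coefficients.items())
            r2 = sum(coeff * v2.get(r, 0.0) for r, coeff in c.coefficients.items())
            assert r2 == pytest.approx(3.5 * r1, abs=1e-12)

    def test_unknown_route_reaction_raises(self):
        from conftest import toy_path

        net = nw.load_network_file(toy_path("linear"))
        with pytest.raises(nw.NetworkError, match="absent"):
            ratios_to_constraints(self._full_set(), net)
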