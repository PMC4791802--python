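"""Synthetic ground truths and measurement generation.

The study this package models characterized two strains in glucose-limited
chemostats at dilution rate D = 0.04 1/h: a non-producing reference and a
3HP producer carrying the malonyl-CoA reductase pathway.  No raw GC–MS data
were deposited, so this module builds the stand-in: balanced "true" flux
vectors for both strains, steady-state labeling simulated under the two
tracer designs, TBDMS derivatization background and Gaussian channel noise.

The strain parameters are the study's own macroscopic observations where
stated — biomass yields 0.50 (reference) and 0.40 (producer) g DW per g
glucose, a producer 3HP yield of 0.02 g per g glucose, a 23 % higher
normalized oxidative PP-pathway split and a 12 % higher TCA flux in the
producer, lower acetate secretion in the producer — and field-typical
values for the remaining free fluxes (small anaplerotic/cataplerotic
cycling, trace ethanol, minor serine/glycine interconversion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .labeling import (
    DEFAULT_NOISE_SD,
    MeasurementSet,
    TracerSpec,
    add_noise,
    apply_derivatization_background,
    default_fragments,
    fragment_emu_list,
    fragment_mdvs,
    simulate_labeling,
)
from .network import AtomTransitionNetwork

__all__ = [
    "StrainSpec",
    "REFERENCE_STRAIN",
    "PRODUCER_STRAIN",
    "build_strain_fluxes",
    "default_exchange",
    "true_ratios",
    "generate_measurements",
]

GLUCOSE_MW = 180.156  # g/mol
HP3_MW = 90.078

#: relative measurement error of extracellular rates (chemostat HPLC/dry
#: weight accuracy); the growth rate is the dilution rate and is set more
#: precisely by the pump
RATE_REL_SD = 0.03
GROWTH_REL_SD = 0.01

#: label-exchange defaults as fractions of the glucose uptake flux; zero for
#: all other reversible steps (net-flux reversibility is absorbed by the
#: flux-ratio formalism); non-oxidative PP pathway and fumarase exchange
#: fast enough to matter for labeling.
EXCHANGE_FRACTIONS = {
    "RPE": 0.3,
    "RPI": 0.3,
    "TKL1": 0.3,
    "TKL2": 0.3,
    "TAL": 0.3,
    "FUMR": 0.5,
}


@dataclass(frozen=True)
class StrainSpec:
    """Free parameters of a chemostat steady state (mmol/gDW/h unless noted).

    Fractions marked ``*_frac`` are relative to the glucose uptake flux.
    The remaining fluxes follow from the carbon balances of the bundled
    network (see :func:`build_strain_fluxes`).
    """

    name: str
    mu: float = 0.04              # dilution rate = growth rate, 1/h
    biomass_yield: float = 0.50   # g DW per g glucose
    zwf_frac: float = 0.25        # oxidative PP split
    cs_frac: float = 0.90         # citrate synthase (TCA) flux
    gpd_frac: float = 0.045       # glycerol formation
    etoh_frac: float = 0.004      # trace ethanol secretion
    acc_frac: float = 0.0225      # acetate secretion
    mcr_frac: float = 0.0         # 3HP formation (mol/mol glucose)
    oat2_frac: float = 0.045      # mitochondrial OAA export
    pck_frac: float = 0.023       # PEP carboxykinase
    mae_frac: float = 0.023       # malic enzyme
    shmr_frac: float = 0.009      # glycine -> serine (reverse SHMT)
    glyt_frac: float = 0.014      # threonine aldolase glycine supply

    @property
    def q_glc(self) -> float:
        return self.mu / (self.biomass_yield * GLUCOSE_MW / 1000.0)


REFERENCE_STRAIN = StrainSpec(name="reference")
#: producer: lower biomass yield, 3HP formation, +23 % PP split, +12 % TCA,
#: acetate secretion dropped, glycerol roughly tracking 3HP
PRODUCER_STRAIN = StrainSpec(
    name="producer",
    biomass_yield=0.40,
    zwf_frac=0.25 * 1.23,
    cs_frac=0.90 * 1.12,
    mcr_frac=0.02 * GLUCOSE_MW / HP3_MW,
    acc_frac=0.009,
    gpd_frac=0.047,
)


def build_strain_fluxes(net: AtomTransitionNetwork, spec: StrainSpec) -> dict[str, float]:
    """Exact balanced flux vector for a strain on the bundled network.

    Walks the network's balance equations: the free parameters of *spec*
    determine every remaining flux; pyruvate secretion absorbs the residual
    of the pyruvate node.  Anaplerosis (pyruvate carboxylase) is fixed by
    cataplerosis plus biosynthetic drains, which the mal/fum chain requires.
    Raises if the resulting vector is infeasible (negative irreversible
    flux) or off balance.
    """
    q = spec.q_glc
    mu = spec.mu
    bio_rxn = net.reaction(net.biomass_reaction_id)
    bio = {m: -c * mu for m, c in bio_rxn.stoichiometry.items() if c < 0}

    v: dict[str, float] = {}
    v["GLK"] = q
    v["BIO"] = mu
    v["ZWF"] = v["SOL"] = v["GND"] = spec.zwf_frac * q
    tkl1 = (v["ZWF"] - bio["r5p"] + bio["e4p"]) / 3.0
    v["TKL1"] = v["TAL"] = tkl1
    v["TKL2"] = tkl1 - bio["e4p"]
    v["RPI"] = tkl1 + bio["r5p"]
    v["RPE"] = v["TKL1"] + v["TKL2"]
    v["PGI"] = q - v["ZWF"] - bio["g6p"]
    v["PFK"] = v["FBA"] = v["PGI"] + v["TAL"] + v["TKL2"] - bio.get("f6p", 0.0)
    v["GPD"] = v["GPP"] = v["GLYX"] = spec.gpd_frac * q
    v["TPI"] = v["FBA"] - v["GPD"]
    v["GAPD"] = v["PGK"] = (
        v["FBA"] + v["TPI"] + v["TKL1"] + v["TKL2"] - v["TAL"] - bio.get("g3p", 0.0)
    )
    v["SHMR"] = spec.shmr_frac * q
    v["GLYT"] = spec.glyt_frac * q
    v["SHMF"] = v["SHMR"] + bio["gly"] - v["GLYT"]
    v["SERS"] = v["SHMF"] + bio["ser"] - v["SHMR"]
    v["THRS"] = v["GLYT"] + bio["thr"]
    v["PGM"] = v["ENO"] = v["PGK"] - v["SERS"] - bio["3pg"]
    v["PCK"] = spec.pck_frac * q
    v["PYK"] = v["ENO"] + v["PCK"] - bio["pep"]
    mcr = spec.mcr_frac * q
    if mcr > 0:
        if not net.has_reaction("MCR"):
            raise ValueError("strain produces 3HP but network lacks the MCR pathway")
        v["ACC"] = v["MCR"] = v["HPX"] = mcr
    v["ACS"] = bio["accoa"] + mcr
    v["ACCX"] = spec.acc_frac * q
    v["ALD"] = v["ACS"] + v["ACCX"]
    v["ADH"] = v["ETOHX"] = spec.etoh_frac * q
    v["PDC"] = v["ADH"] + v["ALD"] - v["GLYT"]
    v["MAE"] = spec.mae_frac * q
    v["PYC"] = v["MAE"] + bio["akg"] + v["PCK"] + v["THRS"] + bio["oaa"]
    cs = spec.cs_frac * q
    v["CS"] = v["ACO"] = v["IDH"] = v["PDH"] = cs
    v["PYT"] = cs - v["MAE"] + bio["pyr_m"]
    v["PYRX"] = v["PYK"] - v["PYT"] - v["PYC"] - v["PDC"] - bio["pyr"]
    v["OAT2"] = spec.oat2_frac * q
    v["OAT1"] = v["MAE"] + bio["akg"] + v["OAT2"]
    v["MDH"] = cs + v["OAT2"] - v["OAT1"]
    v["KGD"] = v["SCS"] = v["SDH"] = v["FUMR"] = cs - bio["akg"]

    S = net.stoichiometric_matrix()
    vec = np.array([v.get(r.id, 0.0) for r in net.reactions])
    resid = np.abs(S @ vec).max()
    if resid > 1e-9:
        raise AssertionError(f"strain walk out of balance (|S v| = {resid:.3g})")
    for r in net.reactions:
        if not r.reversible and v.get(r.id, 0.0) < -1e-12:
            raise ValueError(f"infeasible strain spec: {r.id} = {v[r.id]:.4g} < 0")
    return v


def default_exchange(net: AtomTransitionNetwork, fluxes: Mapping[str, float]) -> dict[str, float]:
    """Label-exchange fluxes scaled to the strain's glucose uptake."""
    q = fluxes.get("GLK", 1.0)
    return {rid: frac * q for rid, frac in EXCHANGE_FRACTIONS.items() if net.has_reaction(rid)}


def true_ratios(fluxes: Mapping[str, float]) -> dict[str, float]:
    """The eight branch-point flux ratios implied by a flux vector."""
    v = fluxes

    def frac(a, b):
        return a / (a + b) if (a + b) > 0 else float("nan")

    me = frac(v.get("MAE", 0.0), v.get("PYT", 0.0))
    return {
        "oaa_cyt_from_pyr_cyt": frac(v.get("PYC", 0.0), v.get("OAT2", 0.0)),
        "oaa_mit_from_anaplerosis": frac(v.get("OAT1", 0.0), max(v.get("MDH", 0.0), 0.0)),
        "pep_from_oaa_cyt": frac(v.get("PCK", 0.0), max(v.get("ENO", 0.0), 0.0)),
        "ser_from_glycolysis": frac(v.get("SERS", 0.0), v.get("SHMR", 0.0)),
        "pyr_mit_from_malic_enzyme_lb": me,
        "pyr_mit_from_malic_enzyme_ub": me,
        "gly_to_ser_contribution": frac(v.get("SHMR", 0.0), v.get("SERS", 0.0)),
        "ser_to_gly_contribution": frac(v.get("SHMF", 0.0), v.get("GLYT", 0.0)),
    }


def rates_from_fluxes(
    net: AtomTransitionNetwork,
    fluxes: Mapping[str, float],
    mu: float,
    seed: int | None = None,
    rel_sd: float = RATE_REL_SD,
    growth_rel_sd: float = GROWTH_REL_SD,
):
    """Extracellular-rate table implied by a flux vector, optionally noisy.

    ``seed=None`` returns the exact rates (sds still attached); otherwise
    each rate is perturbed by its Gaussian sd.
    """
    from .netflux import SPECIES_REACTIONS, ExtracellularRates

    rng = np.random.default_rng(seed) if seed is not None else None
    floor = 1e-4 * fluxes.get("GLK", 1.0)

    def noisy(val, sd):
        if rng is None:
            return val, sd
        return val + rng.normal() * sd, sd

    rates = {}
    for species, rid in SPECIES_REACTIONS.items():
        if species == "growth" or not net.has_reaction(rid):
            continue
        val = fluxes.get(rid, 0.0)
        sd = max(rel_sd * abs(val), floor)
        rates[species] = noisy(val, sd)
    growth = noisy(mu, growth_rel_sd * mu)
    return ExtracellularRates(growth, rates)


def generate_measurements(
    net: AtomTransitionNetwork,
    fluxes: Mapping[str, float],
    tracer: TracerSpec,
    seed: int,
    sd: float = DEFAULT_NOISE_SD,
    exchange: Mapping[str, float] | None = None,
    fragments=None,
) -> MeasurementSet:
    """Simulate one tracer experiment: labeling, fragments, background, noise."""
    fragments = fragments or default_fragments()
    if exchange is None:
        exchange = default_exchange(net, fluxes)
    sol = simulate_labeling(
        net, fluxes, tracer, exchange=exchange, extra_emus=fragment_emu_list(fragments.values())
    )
    skel = fragment_mdvs(sol, fragments.values())
    raw = {
        fid: apply_derivatization_background(mdv, fragments[fid].formula)
        for fid, mdv in skel.items()
    }
    return add_noise(raw, sd, seed, tracer_id=tracer.name)
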