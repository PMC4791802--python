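"""Genome-scale integration: 13C-derived bounds and parsimonious FBA.

The central-carbon flux distribution (with Monte-Carlo confidence
intervals) constrains a genome-scale model: each mapped reaction's bounds
are set to the scaled, sign-adjusted interval endpoints, and the residual
flux distribution is computed by parsimonious FBA — maximize the objective,
fix it at its optimum, then minimize the total absolute flux.  Unlike the
central-carbon stage, the genome-scale model balances every metabolite it
declares, including the redox cofactors.

SBML I/O goes through COBRApy; both LPs are solved with the HiGHS solver
from scipy (the L1 stage by the standard split into nonnegative forward and
reverse parts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .netflux import FluxDistribution

__all__ = [
    "BoundMapping",
    "load_sbml",
    "toy_yeast_gsm",
    "default_bound_mapping",
    "apply_13c_bounds",
    "fba",
    "pfba",
    "PfbaResult",
]

DEFAULT_BOUND = 1000.0

#: objective-fixing slack in stage 2, relative
OBJECTIVE_SLACK = 1e-6


@dataclass(frozen=True)
class BoundMapping:
    """central-carbon reaction id -> genome-scale reaction id with a sign."""

    entries: tuple[tuple[str, str, int], ...]

    def __post_init__(self):
        for cc, gsm, sign in self.entries:
            if sign not in (1, -1):
                raise ValueError(f"mapping {cc}->{gsm}: sign must be +1 or -1")

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_tsv(cls, text: str) -> "BoundMapping":
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("cc_reaction"):
                continue
            cc, gsm, sign = line.split("\t")
            rows.append((cc, gsm, int(sign)))
        return cls(tuple(rows))

    def to_tsv(self) -> str:
        lines = ["cc_reaction\tgsm_reaction\tsign"]
        lines += [f"{cc}\t{gsm}\t{sign:+d}" for cc, gsm, sign in self.entries]
        return "\n".join(lines) + "\n"


def load_sbml(path, objective: str | None = None):
    """Read an SBML model (Level 2/3, FBC bounds) into a cobra model.

    Reactions without explicit bounds receive the documented defaults
    (+-1000).  A model without an objective is an error unless *objective*
    names the reaction to maximize.
    """
    import cobra.io

    model = cobra.io.read_sbml_model(str(path))
    for rxn in model.reactions:
        if rxn.lower_bound is None:
            rxn.lower_bound = -DEFAULT_BOUND
        if rxn.upper_bound is None:
            rxn.upper_bound = DEFAULT_BOUND
    if objective is not None:
        model.objective = model.reactions.get_by_id(objective)
    else:
        coeffs = {
            r for r in model.reactions if r.objective_coefficient
        }
        if not coeffs:
            raise ValueError(
                "SBML model declares no objective; pass objective=<reaction id> "
                "(CLI: --objective) to choose one"
            )
    return model


def toy_yeast_gsm():
    """A self-contained miniature yeast-style model with explicit redox.

    Lumped glycolysis, PP pathway (flux variable = g6p oxidized, returning
    5/6 of the carbon as hexose equivalents), PDH and the cytosolic
    PDH-bypass (the NADPH-producing acetyl-CoA route), TCA, oxidative
    phosphorylation, glycerol formation, the malonyl-CoA route to 3HP, an
    ATP maintenance sink and a biomass objective.  Small enough for
    brute-force LP cross-checks yet carrying NADH/NADPH/ATP balances so
    redox enforcement is meaningful, and lumped consistently with the
    atom-mapped central-carbon network so 13C-derived bounds transfer.
    Purely synthetic: not a published genome-scale model.
    """
    import cobra
    from cobra import Metabolite, Reaction

    model = cobra.Model("toy_yeast_gsm")
    mets = {
        mid: Metabolite(mid, compartment="c")
        for mid in (
            "glc", "g6p", "pyr", "accoa", "malcoa", "hp3", "nadh", "nadph",
            "atp", "o2", "co2", "glyc",
        )
    }

    def rxn(rid, stoich, lb, ub):
        r = Reaction(rid)
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        r.lower_bound, r.upper_bound = lb, ub
        model.add_reactions([r])
        return r

    rxn("EX_glc", {"glc": 1}, 0, 10)
    rxn("GLYCT", {"glc": -1, "g6p": 1, "atp": -1}, 0, DEFAULT_BOUND)
    rxn("EMP", {"g6p": -1, "pyr": 2, "nadh": 2, "atp": 3}, 0, DEFAULT_BOUND)
    # one flux unit = one g6p through the oxidative branch; 5/6 of the
    # carbon returns to the hexose pool via the non-oxidative reactions
    rxn("PPP_LUMP", {"g6p": -1 / 6, "nadph": 2, "co2": 1}, 0, DEFAULT_BOUND)
    rxn("PDH_LUMP", {"pyr": -1, "accoa": 1, "nadh": 1, "co2": 1}, 0, DEFAULT_BOUND)
    rxn("BYPASS", {"pyr": -1, "accoa": 1, "nadph": 1, "co2": 1, "atp": -2}, 0, DEFAULT_BOUND)
    rxn("TCA_LUMP", {"accoa": -1, "nadh": 4, "co2": 2, "atp": 1}, 0, DEFAULT_BOUND)
    rxn("OXPHOS", {"nadh": -1, "o2": -0.5, "atp": 1.5}, 0, DEFAULT_BOUND)
    rxn("ACC_MCR", {"accoa": -1, "co2": -1, "malcoa": 1, "atp": -1}, 0, DEFAULT_BOUND)
    rxn("MCR_RED", {"malcoa": -1, "hp3": 1, "nadph": -2}, 0, DEFAULT_BOUND)
    rxn("GLYC_LUMP", {"g6p": -0.5, "glyc": 1, "nadh": -1, "atp": -0.5}, 0, DEFAULT_BOUND)
    rxn("ATPM", {"atp": -1}, 0, DEFAULT_BOUND)
    rxn(
        "BIOMASS",
        {"g6p": -3.0, "pyr": -3.0, "accoa": -1.5, "atp": -40.0,
         "nadph": -8.0, "nadh": 2.0},
        0,
        DEFAULT_BOUND,
    )
    rxn("EX_o2", {"o2": 1}, 0, DEFAULT_BOUND)
    rxn("EX_co2", {"co2": -1}, 0, DEFAULT_BOUND)
    rxn("EX_hp3", {"hp3": -1}, 0, DEFAULT_BOUND)
    rxn("EX_glyc", {"glyc": -1}, 0, DEFAULT_BOUND)
    model.objective = "BIOMASS"
    return model


def default_bound_mapping() -> BoundMapping:
    """Mapping from bundled central-carbon reactions onto the toy GSM."""
    return BoundMapping(
        (
            ("GLK", "EX_glc", 1),
            ("ZWF", "PPP_LUMP", 1),
            ("CS", "TCA_LUMP", 1),
            ("HPX", "EX_hp3", 1),
            ("GLYX", "GLYC_LUMP", 1),
            ("BIO", "BIOMASS", 1),
        )
    )


def apply_13c_bounds(
    model,
    fluxes: FluxDistribution,
    mapping: BoundMapping,
    uptake_scale: float = 1.0,
    relax: float = 0.0,
):
    """Copy of *model* with mapped reactions bound to scaled 13C intervals.

    For each mapped reaction the interval is the Monte-Carlo CI of the
    central-carbon flux (the point value when no CI is attached), scaled by
    *uptake_scale* (the measured glucose uptake when the fluxes are
    normalized) and sign-adjusted.  *relax* widens every interval by that
    fraction of the scaled glucose uptake on both sides — an explicit
    escape hatch when the 13C ranges and the genome-scale stoichiometry
    (whose lumping never matches the central-carbon network exactly) have
    no common feasible point.  The input model is not mutated.
    """
    out = model.copy()
    pad = abs(relax * uptake_scale)
    for cc_id, gsm_id, sign in mapping:
        if cc_id not in fluxes.values:
            continue
        try:
            rxn = out.reactions.get_by_id(gsm_id)
        except KeyError:
            raise KeyError(
                f"mapping references reaction {gsm_id!r} absent from the model"
            ) from None
        if fluxes.ci and cc_id in fluxes.ci:
            lo, hi = fluxes.ci[cc_id]
        else:
            lo = hi = fluxes.values[cc_id]
        a, b = sorted((sign * lo * uptake_scale, sign * hi * uptake_scale))
        if a > b:
            raise ValueError(f"inverted interval for {gsm_id!r}")
        rxn.lower_bound, rxn.upper_bound = a - pad, b + pad
    return out


def _lp_arrays(model):
    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    midx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxns)))
    lb = np.zeros(len(rxns))
    ub = np.zeros(len(rxns))
    c = np.zeros(len(rxns))
    for j, r in enumerate(model.reactions):
        for met, coeff in r.metabolites.items():
            S[midx[met.id], j] = coeff
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        c[j] = r.objective_coefficient
    return S, lb, ub, c, rxns


def fba(model) -> FluxDistribution:
    """Plain flux balance analysis (objective maximization) via HiGHS."""
    S, lb, ub, c, rxns = _lp_arrays(model)
    res = linprog(
        -c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs"
    )
    if res.status == 2:
        raise ValueError("FBA infeasible: " + res.message)
    if res.status == 3:
        raise ValueError("FBA unbounded: " + res.message)
    if not res.success:
        raise RuntimeError("FBA failed: " + res.message)
    return FluxDistribution(dict(zip(rxns, map(float, res.x))))


@dataclass
class PfbaResult:
    fluxes: FluxDistribution
    objective_value: float
    total_flux: float


def pfba(model, objective: str | None = None) -> PfbaResult:
    """Parsimonious FBA: fix the optimal objective, minimize total |flux|.

    Stage 2 uses the standard reformulation v = p - q with p, q >= 0 and
    minimizes sum(p + q) subject to the stoichiometric balances (all
    metabolites, cofactors included), the original bounds, and the
    objective fixed at its stage-1 optimum within a relative slack of
    1e-6.
    """
    if objective is not None:
        model = model.copy()
        model.objective = model.reactions.get_by_id(objective)
    S, lb, ub, c, rxns = _lp_arrays(model)
    n = len(rxns)
    res1 = linprog(
        -c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs"
    )
    if res1.status == 2:
        raise ValueError(
            "pFBA stage 1 infeasible — the injected 13C bounds may conflict "
            "with the genome-scale stoichiometry; consider apply_13c_bounds("
            "..., relax=...): " + res1.message
        )
    if res1.status == 3:
        raise ValueError("pFBA stage 1 unbounded: " + res1.message)
    if not res1.success:
        raise RuntimeError("pFBA stage 1 failed: " + res1.message)
    opt = float(c @ res1.x)

    # split v = p - q, p,q >= 0; p <= max(ub,0), q <= max(-lb,0)
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    bounds = [(0.0, max(u, 0.0)) for u in ub] + [(0.0, max(-l, 0.0)) for l in lb]
    # v within [lb, ub]
    A_ub_rows = []
    b_ub = []
    eye = np.eye(n)
    A_ub_rows.append(np.hstack([eye, -eye]))      # v <= ub
    b_ub.extend(ub)
    A_ub_rows.append(np.hstack([-eye, eye]))      # -v <= -lb
    b_ub.extend(-lb)
    slack = OBJECTIVE_SLACK * max(abs(opt), 1.0)
    cc = np.hstack([c, -c])
    A_ub_rows.append(-cc.reshape(1, -1))          # c v >= opt - slack
    b_ub.append(-(opt - slack))
    A_ub_rows.append(cc.reshape(1, -1))           # c v <= opt + slack
    b_ub.append(opt + slack)
    res2 = linprog(
        np.ones(2 * n),
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=np.vstack(A_ub_rows),
        b_ub=np.array(b_ub),
        bounds=bounds,
        method="highs",
    )
    if not res2.success:
        raise RuntimeError("pFBA stage 2 failed: " + res2.message)
    v = res2.x[:n] - res2.x[n:]
    fluxes = FluxDistribution(dict(zip(rxns, map(float, v))))
    return PfbaResult(fluxes, float(c @ v), float(np.abs(v).sum()))
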