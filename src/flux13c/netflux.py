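"""Net intracellular flux estimation from rates and ratio constraints.

The estimator solves a weighted least-squares reconciliation::

    min || W (A v - b) ||^2   subject to   S v = 0,  G v <= h,  lb <= v

where the rows of ``A``/``b`` are the measured extracellular rates and the
flux-ratio equalities (each weighted by the inverse of its standard
deviation), ``S`` contains the mass balances of the balanced metabolites
only — no CO2, O2, ATP or NADPH rows exist by construction — and the
inequalities are the malic-enzyme ratio bounds plus irreversibility.  The
equality-constrained problem is solved exactly in the null space of ``S``;
active inequalities are handled by an active-set loop with a
sequential-quadratic fallback.  Units are mmol/gDW/h (the growth rate in
1/h); :func:`normalize` rescales to glucose uptake = 1 for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import null_space

from .network import AtomTransitionNetwork
from .ratios import FluxRatioSet, RatioConstraint, TrioseProbe, ratios_to_constraints

__all__ = [
    "ExtracellularRates",
    "FluxDistribution",
    "UnderdeterminedError",
    "InfeasibleConstraintsError",
    "SPECIES_REACTIONS",
    "chemostat_rates",
    "estimate_net_fluxes",
    "normalize",
    "monte_carlo_ci",
    "compare_strains",
    "DEFAULT_REACTION_GROUPS",
]

#: measured species -> exchange reaction in the bundled network
SPECIES_REACTIONS = {
    "glucose": "GLK",
    "growth": "BIO",
    "3hp": "HPX",
    "glycerol": "GLYX",
    "acetate": "ACCX",
    "pyruvate": "PYRX",
    "ethanol": "ETOHX",
}

#: flux groups used for strain comparison: oxidative PP-pathway entry and
#: TCA (citrate synthase) flux
DEFAULT_REACTION_GROUPS = {"PP": ("ZWF",), "TCA": ("CS",)}

MOLAR_MASSES = {  # g/mol
    "glucose": 180.156,
    "3hp": 90.078,
    "glycerol": 92.094,
    "acetate": 60.052,
    "pyruvate": 88.062,
    "ethanol": 46.068,
}


class UnderdeterminedError(ValueError):
    """The system leaves free flux directions; carries them for inspection."""

    def __init__(self, dof: int, n_informed: int, directions):
        self.dof = dof
        self.n_informed = n_informed
        self.directions = directions
        names = ", ".join(sorted({r for d in directions for r in d})) or "?"
        super().__init__(
            f"underdetermined system: {dof} degrees of freedom, only "
            f"{n_informed} informed; uninformed directions involve: {names}"
        )


class InfeasibleConstraintsError(ValueError):
    pass


@dataclass
class ExtracellularRates:
    """Specific rates at chemostat steady state, each value with an sd.

    ``growth_rate`` in 1/h; uptake/secretion in mmol/gDW/h, positive for
    the direction the corresponding exchange reaction carries (glucose
    uptake positive, products positive).
    """

    growth_rate: tuple[float, float]
    rates: dict[str, tuple[float, float]]

    def __post_init__(self):
        glc = self.rates.get("glucose")
        if glc is None or glc[0] <= 0:
            raise ValueError("glucose uptake must be present and > 0")
        for name, (val, sd) in list(self.rates.items()) + [("growth", self.growth_rate)]:
            if sd < 0:
                raise ValueError(f"{name}: negative sd")

    def items(self):
        yield "growth", self.growth_rate
        yield from self.rates.items()


def chemostat_rates(
    dilution_rate: float,
    concentrations: Mapping[str, tuple[float, float]],
    biomass: float,
    molar_masses: Mapping[str, float] | None = None,
    feed_glucose: float = 10.0,
    residual_glucose: tuple[float, float] = (0.0, 0.0),
    biomass_sd: float = 0.0,
) -> ExtracellularRates:
    """Specific rates from chemostat concentrations.

    Secretion of species i: ``q_i = D * c_i * 1000 / (M_i * X)`` in
    mmol/gDW/h; glucose uptake uses feed minus residual concentration;
    the growth rate equals the dilution rate at steady state.  Standard
    deviations are propagated first-order from the concentration and
    biomass sds.
    """
    if dilution_rate <= 0:
        raise ValueError("dilution rate must be > 0")
    if biomass <= 0:
        raise ValueError("biomass concentration must be > 0")
    mm = dict(MOLAR_MASSES)
    if molar_masses:
        mm.update(molar_masses)
    if residual_glucose[0] < 0 or residual_glucose[0] > feed_glucose:
        raise ValueError("residual glucose must lie in [0, feed]")

    def rate(c, sd_c, M):
        q = dilution_rate * c * 1000.0 / (M * biomass)
        dq_dc = dilution_rate * 1000.0 / (M * biomass)
        dq_dX = -q / biomass
        return q, float(np.hypot(dq_dc * sd_c, dq_dX * biomass_sd))

    rates: dict[str, tuple[float, float]] = {}
    c_up = feed_glucose - residual_glucose[0]
    rates["glucose"] = rate(c_up, residual_glucose[1], mm["glucose"])
    for name, (c, sd_c) in concentrations.items():
        if name == "glucose":
            continue
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}")
        rates[name] = rate(c, sd_c, mm[name])
    mu_sd = dilution_rate * (biomass_sd / biomass) if biomass_sd else 0.0
    return ExtracellularRates((dilution_rate, mu_sd), rates)


@dataclass
class FluxDistribution:
    """Reaction -> net flux, optionally normalized to glucose uptake = 1."""

    values: dict[str, float]
    normalized: bool = False
    ci: dict[str, tuple[float, float]] | None = None
    residual: float | None = None
    dof: int | None = None

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def get(self, rid: str, default: float = 0.0) -> float:
        return self.values.get(rid, default)

    def to_tsv(self) -> str:
        lines = ["reaction\tflux\tlb\tub\tnormalized"]
        for rid, v in self.values.items():
            if self.ci and rid in self.ci:
                lb, ub = self.ci[rid]
                lines.append(f"{rid}\t{v:.10g}\t{lb:.10g}\t{ub:.10g}\t{int(self.normalized)}")
            else:
                lines.append(f"{rid}\t{v:.10g}\t\t\t{int(self.normalized)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "FluxDistribution":
        values: dict[str, float] = {}
        ci: dict[str, tuple[float, float]] = {}
        normalized = False
        for i, line in enumerate(text.splitlines()):
            if not line.strip() or line.startswith("#") or line.startswith("reaction\t"):
                continue
            parts = line.split("\t")
            values[parts[0]] = float(parts[1])
            if len(parts) >= 4 and parts[2] and parts[3]:
                ci[parts[0]] = (float(parts[2]), float(parts[3]))
            if len(parts) >= 5 and parts[4]:
                normalized = bool(int(parts[4]))
        return cls(values, normalized, ci or None)


# ---------------------------------------------------------------------------
# core solver
# ---------------------------------------------------------------------------

def _solve_wls(C, d, Gz, h, z0_dim):
    """min ||C z - d||^2 s.t. Gz z <= h; KKT-based active set, SLSQP fallback."""
    z, *_ = np.linalg.lstsq(C, d, rcond=None)
    if Gz is None or Gz.size == 0 or np.all(Gz @ z <= h + 1e-9):
        return z
    dim = C.shape[1]
    CtC2 = 2.0 * (C.T @ C)
    Ctd2 = 2.0 * (C.T @ d)

    def solve_eq(active):
        if not active:
            return np.linalg.lstsq(C, d, rcond=None)[0], np.array([])
        E = Gz[active]
        k = len(active)
        K = np.zeros((dim + k, dim + k))
        K[:dim, :dim] = CtC2
        K[:dim, dim:] = E.T
        K[dim:, :dim] = E
        rhs = np.concatenate([Ctd2, h[active]])
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        return sol[:dim], sol[dim:]

    active: list[int] = []
    ok = False
    for _ in range(4 * len(h) + 10):
        z, lam = solve_eq(active)
        viol = Gz @ z - h
        worst = int(np.argmax(viol))
        if viol[worst] <= 1e-9:
            if lam.size and np.min(lam) < -1e-7:
                active.pop(int(np.argmin(lam)))
                continue
            ok = True
            break
        if worst in active:
            break  # cycling; fall through to SLSQP
        active.append(worst)
    if ok:
        return z
    from scipy.optimize import minimize

    res = minimize(
        lambda zz: float(np.sum((C @ zz - d) ** 2)),
        z,
        jac=lambda zz: 2 * C.T @ (C @ zz - d),
        constraints=[{"type": "ineq", "fun": lambda zz: h - Gz @ zz, "jac": lambda zz: -Gz}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x


_NULLSPACE_CACHE: dict[bytes, np.ndarray] = {}


def _cached_null_space(H: np.ndarray) -> np.ndarray:
    key = H.tobytes()
    N = _NULLSPACE_CACHE.get(key)
    if N is None:
        N = null_space(H)
        if len(_NULLSPACE_CACHE) > 32:
            _NULLSPACE_CACHE.clear()
        _NULLSPACE_CACHE[key] = N
    return N


TRIOSE_PROBE_REACTIONS = {
    "gapdh": "GAPD", "tpi": "TPI", "pgi": "PGI", "tal": "TAL", "tkl2": "TKL2"
}


def estimate_net_fluxes(
    network: AtomTransitionNetwork,
    rates: ExtracellularRates,
    constraints: Sequence[RatioConstraint] = (),
    weights: Mapping[str, float] | None = None,
    rate_reactions: Mapping[str, str] | None = None,
    check_determined: bool = True,
    triose_probe: TrioseProbe | tuple[float, float] | None = None,
    probe_reactions: Mapping[str, str] | None = None,
    on_underdetermined: str = "raise",
) -> FluxDistribution:
    """Weighted least-squares net fluxes under balances and constraints.

    Rate measurements and ratio equalities with an sd enter as soft rows
    weighted 1/sd; ratio equalities without an sd are enforced exactly.
    The optional *triose_probe* (see
    :func:`flux13c.ratios.triose_intact_fraction`) measures
    ``s * v_TPI / v_GAPDH`` with ``s = v_PGI / (v_PGI + v_TAL + v_TKL2)``;
    it enters as a soft row linearized in ``s`` and re-solved to a fixed
    point, and supplies the pentose-phosphate split the branch-point
    ratios do not constrain.  Raises :class:`UnderdeterminedError` when
    free directions remain (``on_underdetermined="min-norm"`` instead
    falls back to the minimum-norm solution along the uninformed
    directions, logged as a warning — used by the Monte-Carlo resampler so
    that a single trial with an undetermined ratio does not abort a whole
    uncertainty analysis) and :class:`InfeasibleConstraintsError` when the
    constraints contradict a positive glucose uptake.
    """
    rate_reactions = rate_reactions or SPECIES_REACTIONS
    rids = network.reaction_ids()
    idx = {r: i for i, r in enumerate(rids)}
    n = len(rids)
    S = network.stoichiometric_matrix()

    hard_rows = [S]
    soft_rows, soft_vals, soft_w = [], [], []
    glc_rid = rate_reactions.get("glucose", "GLK")
    q_glc = rates.rates["glucose"][0]

    for species, (val, sd) in rates.items():
        rid = rate_reactions.get(species)
        if rid is None or not network.has_reaction(rid):
            continue
        row = np.zeros(n)
        row[idx[rid]] = 1.0
        w = 1.0 / sd if sd > 0 else 1.0 / (1e-3 * max(abs(val), q_glc))
        if weights and species in weights:
            w = weights[species]
        soft_rows.append(row)
        soft_vals.append(val)
        soft_w.append(w)

    for c in constraints:
        row = np.zeros(n)
        for rid, coeff in c.coefficients.items():
            if rid not in idx:
                raise InfeasibleConstraintsError(
                    f"constraint {c.provenance!r} references unknown reaction {rid!r}"
                )
            row[idx[rid]] = coeff
        if c.kind == "equality":
            if c.sd and c.sd > 0:
                soft_rows.append(row)
                soft_vals.append(c.rhs)
                # a ratio sd is dimensionless; scale by glucose uptake to
                # express it in flux units
                soft_w.append(1.0 / (c.sd * q_glc))
            else:
                hard_rows.append(row.reshape(1, -1))
                if abs(c.rhs) > 1e-12:
                    raise NotImplementedError("hard constraints must be homogeneous")
        elif c.kind == "inequality":
            pass  # handled below
        else:
            raise ValueError(f"unknown constraint kind {c.kind!r}")

    H = np.vstack(hard_rows)
    N = _cached_null_space(H)
    dof = N.shape[1]
    if dof == 0:
        raise InfeasibleConstraintsError(
            "hard constraints leave no feasible flux direction"
        )

    probe_ids = dict(TRIOSE_PROBE_REACTIONS)
    if probe_reactions:
        probe_ids.update(probe_reactions)
    rt = None
    if triose_probe is not None:
        rt, rt_sd = (
            (triose_probe.value, triose_probe.sd)
            if isinstance(triose_probe, TrioseProbe)
            else triose_probe
        )
        for key in ("gapdh", "tpi", "pgi", "tal", "tkl2"):
            if probe_ids[key] not in idx:
                raise InfeasibleConstraintsError(
                    f"triose probe needs reaction {probe_ids[key]!r}"
                )
        soft_rows.append(np.zeros(n))  # placeholder, rewritten per iteration
        soft_vals.append(0.0)
        soft_w.append(1.0 / (max(rt_sd, 1e-6) * q_glc))

    A = np.array(soft_rows)
    b = np.array(soft_vals)
    W = np.array(soft_w)

    def probe_row(s_hex: float) -> np.ndarray:
        row = np.zeros(n)
        row[idx[probe_ids["gapdh"]]] = rt
        row[idx[probe_ids["tpi"]]] = -s_hex
        return row

    s_hex = 0.8  # initial non-PPP hexose share; refined to a fixed point
    if rt is not None:
        A[-1] = probe_row(s_hex)
    C = (A * W[:, None]) @ N
    d = W * b

    if check_determined:
        rank = np.linalg.matrix_rank(C, tol=1e-8)
        if rank < dof:
            _, _, Vt = np.linalg.svd(C)
            free = Vt[rank:]
            dirs = []
            for row in free:
                vdir = N @ row
                dirs.append(
                    {rids[i]: round(float(vdir[i]), 4) for i in np.argsort(-np.abs(vdir))[:5]}
                )
            if on_underdetermined == "raise":
                raise UnderdeterminedError(dof, rank, dirs)
            import logging

            logging.getLogger("flux13c").warning(
                "underdetermined system (%d of %d directions informed); "
                "reporting the minimum-norm solution", rank, dof,
            )

    # inequalities: ratio bounds plus irreversibility
    G_rows, h_vals = [], []
    for c in constraints:
        if c.kind != "inequality":
            continue
        row = np.zeros(n)
        for rid, coeff in c.coefficients.items():
            row[idx[rid]] = coeff
        G_rows.append(row)
        h_vals.append(c.rhs)
    for i, r in enumerate(network.reactions):
        if not r.reversible:
            row = np.zeros(n)
            row[i] = -1.0
            G_rows.append(row)
            h_vals.append(0.0)
    G = np.array(G_rows)
    h = np.array(h_vals)
    Gz = G @ N if G.size else None

    if rt is None:
        z = _solve_wls(C, d, Gz, h, dof)
        v = N @ z
    else:
        # the probe row is linear only for a fixed hexose share s; the
        # self-consistent s is found by a bracketed scalar root solve
        def solve_for(s_val):
            A[-1] = probe_row(s_val)
            Cs = (A * W[:, None]) @ N
            return N @ _solve_wls(Cs, d, Gz, h, dof)

        def mismatch(s_val):
            vv = solve_for(s_val)
            denom = (
                vv[idx[probe_ids["pgi"]]]
                + vv[idx[probe_ids["tal"]]]
                + vv[idx[probe_ids["tkl2"]]]
            )
            if denom <= 1e-12:
                return 1.0 - s_val
            return min(max(vv[idx[probe_ids["pgi"]]] / denom, 0.0), 1.0) - s_val

        from scipy.optimize import brentq

        def resid_at(s_val):
            vv = solve_for(s_val)
            A[-1] = probe_row(s_val)
            return float(np.sum((W * (A @ vv - b)) ** 2)), vv

        # the consistency equation can have several roots (the probe row is
        # only piecewise informative once irreversibility constraints
        # activate); keep every bracketed root and pick the one that fits
        # the measurements best
        grid = [0.02, 0.35, 0.65, 0.98]
        fs = [mismatch(g) for g in grid]
        roots = [g for g, f in zip(grid, fs) if f == 0.0]
        for (g1, f1), (g2, f2) in zip(zip(grid, fs), zip(grid[1:], fs[1:])):
            if f1 * f2 < 0:
                roots.append(brentq(mismatch, g1, g2, xtol=1e-8))
        if not roots:
            roots = [grid[int(np.argmin(np.abs(fs)))]]
        best = min(roots, key=lambda g: resid_at(g)[0])
        v = resid_at(best)[1]

    if v[idx[glc_rid]] < 1e-6 * q_glc:
        raise InfeasibleConstraintsError(
            "constraints force the glucose uptake to zero although the "
            "measured uptake is positive"
        )
    resid = float(np.sum((W * (A @ v - b)) ** 2))
    return FluxDistribution(dict(zip(rids, map(float, v))), residual=resid, dof=dof)


def normalize(fluxes: FluxDistribution, glucose_reaction_id: str = "GLK") -> FluxDistribution:
    """Rescale so the glucose uptake flux is exactly 1."""
    q = fluxes.values.get(glucose_reaction_id)
    if not q:
        raise ValueError(f"zero or missing glucose uptake {glucose_reaction_id!r}")
    values = {rid: val / q for rid, val in fluxes.values.items()}
    ci = None
    if fluxes.ci:
        ci = {rid: (lb / q, ub / q) for rid, (lb, ub) in fluxes.ci.items()}
    return FluxDistribution(values, True, ci, fluxes.residual, fluxes.dof)


def monte_carlo_ci(
    network: AtomTransitionNetwork,
    rates: ExtracellularRates,
    ratios: FluxRatioSet,
    n_draws: int = 100,
    seed: int = 0,
    **estimate_kwargs,
) -> FluxDistribution:
    """Percentile confidence intervals by resampling rates and ratios.

    Rates and determined ratio values are perturbed by their Gaussian sds,
    the estimation repeated, and the 2.5/97.5 percentiles reported per
    reaction.  Deterministic for a fixed seed; aborts if more than half of
    the draws are infeasible.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    probe = estimate_kwargs.pop("triose_probe", None)
    estimate_kwargs.setdefault("on_underdetermined", "min-norm")
    point = estimate_net_fluxes(
        network, rates, ratios_to_constraints(ratios, network),
        triose_probe=probe, **estimate_kwargs
    )
    rids = network.reaction_ids()
    draws = np.zeros((n_draws, len(rids)))
    failures = 0
    for k in range(n_draws):
        pr = ExtracellularRates(
            (rates.growth_rate[0] + rng.normal() * rates.growth_rate[1], rates.growth_rate[1]),
            {
                s: (val + rng.normal() * sd, sd)
                for s, (val, sd) in rates.rates.items()
            },
        )
        pratios = FluxRatioSet(
            {
                name: (
                    replace(
                        est,
                        value=float(np.clip(est.value + rng.normal() * (est.sd or 0.0), 0, 1)),
                    )
                    if est.status == "determined"
                    else est
                )
                for name, est in ratios.estimates.items()
            }
        )
        pprobe = probe
        if probe is not None:
            val, psd = (
                (probe.value, probe.sd) if isinstance(probe, TrioseProbe) else probe
            )
            pprobe = TrioseProbe(float(np.clip(val + rng.normal() * psd, 0, 1)), psd)
        try:
            fd = estimate_net_fluxes(
                network, pr, ratios_to_constraints(pratios, network),
                triose_probe=pprobe, **estimate_kwargs
            )
            draws[k] = [fd.values[r] for r in rids]
        except (InfeasibleConstraintsError, ValueError):
            failures += 1
            draws[k] = np.nan
    if failures > n_draws // 2:
        raise RuntimeError(
            f"{failures}/{n_draws} Monte-Carlo draws infeasible; check the "
            "measured rates and ratio constraints for consistency"
        )
    lo = np.nanpercentile(draws, 2.5, axis=0)
    hi = np.nanpercentile(draws, 97.5, axis=0)
    ci = {rid: (float(lo[i]), float(hi[i])) for i, rid in enumerate(rids)}
    return FluxDistribution(point.values, False, ci, point.residual, point.dof)


def compare_strains(
    fluxes_a: FluxDistribution,
    fluxes_b: FluxDistribution,
    reaction_groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Percent change of grouped fluxes, strain b relative to strain a.

    Both distributions must be normalized to glucose uptake = 1 so the
    comparison is of flux partitioning, not of absolute rates.
    """
    groups = reaction_groups or DEFAULT_REACTION_GROUPS
    if not (fluxes_a.normalized and fluxes_b.normalized):
        raise ValueError("both flux distributions must be normalized first")
    out = {}
    for name, rids in groups.items():
        ga = sum(fluxes_a.get(r) for r in rids)
        gb = sum(fluxes_b.get(r) for r in rids)
        if abs(ga) < 1e-12:
            raise ZeroDivisionError(f"group {name!r} has zero flux in the reference")
        out[name] = 100.0 * (gb - ga) / ga
    return out
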