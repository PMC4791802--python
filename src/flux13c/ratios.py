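"""Metabolic flux ratios from corrected fragment MDVs.

Each branch-point ratio expresses the measured MDV of a product fragment as
a two-source mixture, ``m = r * a + (1 - r) * b``, where the candidate
source MDVs ``a`` and ``b`` are constructed from *other* measured fragments
through the network's atom maps (carbon-subset selection, convolution with
the CO2/one-carbon pools, deconvolution of single carbons).  The mixture
fraction is obtained by bounded least squares on [0, 1] over all channels
of every tracer experiment in which the two sources are distinguishable;
its standard deviation is propagated from the measurement noise by
first-order (finite-difference) error propagation through the full
estimator, including the natural-abundance correction.

The eight ratio quantities of the yeast branch points:

======================================  ==========================================
oaa_cyt_from_pyr_cyt                    pyruvate carboxylase vs mitochondrial
                                        OAA export into cytosolic OAA
oaa_mit_from_anaplerosis                OAA transport (anaplerosis) vs malate
                                        dehydrogenase into mitochondrial OAA
pep_from_oaa_cyt                        PEP carboxykinase vs enolase into PEP
ser_from_glycolysis                     3PG route vs glycine condensation into
                                        serine
pyr_mit_from_malic_enzyme (lb, ub)      malic enzyme vs pyruvate import into
                                        mitochondrial pyruvate — an interval,
                                        because the positional labeling of the
                                        malate carbon lost on decarboxylation is
                                        not observable
gly_to_ser_contribution                 reverse serine hydroxymethyltransferase
                                        share of serine synthesis
ser_to_gly_contribution                 serine (SHMT) vs threonine aldolase
                                        share of glycine synthesis
======================================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .constants import NATURAL_13C
from .labeling import (
    FragmentDef,
    MeasurementSet,
    correct_vector,
    default_fragments,
)
from .network import AtomTransitionNetwork, NetworkError

__all__ = [
    "TrioseProbe",
    "triose_intact_fraction",
    "RatioEstimate",
    "FluxRatioSet",
    "RatioConstraint",
    "RatioDefinition",
    "standard_ratio_definitions",
    "compute_ratios",
    "ratios_to_constraints",
]

#: sources must differ by at least this multiple of the channel noise
MIN_SEPARATION_SD = 5.0

POINT_RATIOS = (
    "oaa_cyt_from_pyr_cyt",
    "oaa_mit_from_anaplerosis",
    "pep_from_oaa_cyt",
    "ser_from_glycolysis",
    "gly_to_ser_contribution",
    "ser_to_gly_contribution",
)


@dataclass
class RatioEstimate:
    name: str
    value: float | None
    sd: float | None
    lb: float
    ub: float
    tracers_used: tuple[str, ...]
    status: str  # "determined" | "interval" | "undetermined"


@dataclass
class FluxRatioSet:
    """The eight ratio quantities (six point ratios + the ME interval)."""

    estimates: dict[str, RatioEstimate]

    def __getitem__(self, name: str) -> RatioEstimate:
        return self.estimates[name]

    def __iter__(self):
        return iter(self.estimates.values())

    @property
    def n_quantities(self) -> int:
        """Point ratios count one each; the malic-enzyme bounds count two."""
        n = 0
        for est in self.estimates.values():
            n += 2 if est.name == "pyr_mit_from_malic_enzyme" else 1
        return n

    def to_tsv(self) -> str:
        lines = ["ratio\tvalue\tsd\tlb\tub\ttracer_used\tstatus"]
        for est in self.estimates.values():
            val = "" if est.value is None else f"{est.value:.4f}"
            sd = "" if est.sd is None else f"{est.sd:.4f}"
            lines.append(
                f"{est.name}\t{val}\t{sd}\t{est.lb:.4f}\t{est.ub:.4f}\t"
                f"{'+'.join(est.tracers_used) or '-'}\t{est.status}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# MDV algebra on corrected fragment vectors
# ---------------------------------------------------------------------------

def _convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.convolve(a, b)


def _singleton(p: float) -> np.ndarray:
    p = min(max(p, 0.0), 1.0)
    return np.array([1.0 - p, p])


def _strip_carbon(vec: np.ndarray, p: float) -> np.ndarray:
    """Deconvolve one carbon with enrichment *p* (independence assumption)."""
    n = len(vec) - 1
    T = np.zeros((n, n))
    s = _singleton(p)
    for i in range(n):
        T[i, i] = s[0]
        if i > 0:
            T[i, i - 1] = s[1]
    out = solve_triangular(T, vec[:n], lower=True)
    out = np.clip(out, 0.0, None)
    tot = out.sum()
    return out / tot if tot > 0 else out


def _mean_shift(vec: np.ndarray) -> float:
    return float(np.arange(len(vec)) @ vec)


Corrected = Mapping[str, np.ndarray]  # fragment_id -> corrected MDV


@dataclass(frozen=True)
class RatioDefinition:
    """How one ratio is probed: fragments, source constructions, flux routes."""

    name: str
    product_fragment: str
    fragments: tuple[str, ...]  # all fragments the builders read
    product: Callable[[Corrected], np.ndarray]
    source_a: Callable[[Corrected], np.ndarray]
    source_b: Callable[[Corrected], np.ndarray]
    routes_a: tuple[str, ...]
    routes_b: tuple[str, ...]
    # for interval ratios: alternative (source_a, source_b) builder pairs
    # spanning the unobservable positional assumptions
    variants: tuple[tuple[Callable[[Corrected], np.ndarray],
                          Callable[[Corrected], np.ndarray]], ...] = ()
    # tracers whose labeling physics the source constructions are valid
    # under (None = any); probes that extend fragments by single-carbon
    # convolution assume positional independence, which holds for the
    # positionally labeled glucose design but not for the uniformly
    # labeled mixture with its correlated intact carbon units
    valid_tracers: tuple[str, ...] | None = None

    @property
    def is_interval(self) -> bool:
        return bool(self.variants)


def standard_ratio_definitions(natural_13c: float = NATURAL_13C) -> list[RatioDefinition]:
    """Ratio probes for the bundled yeast network and fragment set."""
    co2 = _singleton(natural_13c)

    def take(fid):
        return lambda c: c[fid]

    # -- helper probes built from measured fragments --------------------
    def p3_from_ala(c: Corrected) -> float:
        # glycolytic C3 enrichment via mitochondrial pyruvate (Ala)
        return _mean_shift(c["Ala_M57"]) - _mean_shift(c["Ala_f302"])

    def p3_from_ser(c: Corrected) -> float:
        return _mean_shift(c["Ser_M57"]) - _mean_shift(c["Ser_f302"])

    def pep_full_ala(c: Corrected) -> np.ndarray:
        # three-carbon glycolytic unit: PEP C1-C2 extended by a C3 probe
        return _convolve(c["Phe_f302"], _singleton(p3_from_ala(c)))

    def pep_full_ser(c: Corrected) -> np.ndarray:
        return _convolve(c["Phe_f302"], _singleton(p3_from_ser(c)))

    def ser_from_gly_route(c: Corrected) -> np.ndarray:
        # glycine condensed with the one-carbon pool (natural abundance)
        return _convolve(c["Gly_M57"], co2)

    # malic-enzyme sources, under extreme positional assumptions:
    # malate == akg C2-C5 (Glu M-85); the carbon lost on decarboxylation is
    # unobservable, so drop a terminal carbon assumed either unlabeled or
    # carrying twice the mean per-carbon enrichment
    def mal_123_unlabeled_end(c: Corrected) -> np.ndarray:
        return _strip_carbon(c["Glu_M85"], 0.0)

    def mal_123_enriched_end(c: Corrected) -> np.ndarray:
        p = min(1.0, _mean_shift(c["Glu_M85"]) / 2.0)
        return _strip_carbon(c["Glu_M85"], p)

    def pyr_cyt_full_ser(c: Corrected) -> np.ndarray:
        return _convolve(c["Val_f302"], _singleton(p3_from_ser(c)))

    def pyr_cyt_full_ala(c: Corrected) -> np.ndarray:
        return _convolve(c["Val_f302"], _singleton(p3_from_ala(c)))

    defs = [
        RatioDefinition(
            "oaa_cyt_from_pyr_cyt",
            "Thr_f302",
            ("Thr_f302", "Val_f302", "Asp_f302"),
            take("Thr_f302"),
            take("Val_f302"),
            take("Asp_f302"),
            routes_a=("PYC",),
            routes_b=("OAT2",),
        ),
        RatioDefinition(
            "oaa_mit_from_anaplerosis",
            "Asp_M57",
            ("Asp_M57", "Thr_M57", "Glu_M85"),
            take("Asp_M57"),
            take("Thr_M57"),
            take("Glu_M85"),
            routes_a=("OAT1",),
            routes_b=("MDH",),
        ),
        RatioDefinition(
            "pep_from_oaa_cyt",
            "Phe_f302",
            ("Phe_f302", "Thr_f302", "Ser_f302"),
            take("Phe_f302"),
            take("Thr_f302"),
            take("Ser_f302"),
            routes_a=("PCK",),
            routes_b=("ENO",),
        ),
        RatioDefinition(
            "ser_from_glycolysis",
            "Ser_M57",
            ("Ser_M57", "Phe_f302", "Gly_M57", "Ala_M57", "Ala_f302"),
            take("Ser_M57"),
            pep_full_ala,
            ser_from_gly_route,
            routes_a=("SERS",),
            routes_b=("SHMR",),
            valid_tracers=("1-13C",),
        ),
        RatioDefinition(
            "pyr_mit_from_malic_enzyme",
            "Ala_M57",
            ("Ala_M57", "Ala_f302", "Glu_M85", "Val_f302", "Ser_M57", "Ser_f302"),
            take("Ala_M57"),
            mal_123_unlabeled_end,
            pyr_cyt_full_ser,
            routes_a=("MAE",),
            routes_b=("PYT",),
            valid_tracers=("1-13C",),
            variants=(
                (mal_123_unlabeled_end, pyr_cyt_full_ser),
                (mal_123_unlabeled_end, pyr_cyt_full_ala),
                (mal_123_enriched_end, pyr_cyt_full_ser),
                (mal_123_enriched_end, pyr_cyt_full_ala),
            ),
        ),
        RatioDefinition(
            "gly_to_ser_contribution",
            "Ser_M57",
            ("Ser_M57", "Gly_M57", "Phe_f302", "Ala_M57", "Ala_f302"),
            take("Ser_M57"),
            ser_from_gly_route,
            pep_full_ala,
            routes_a=("SHMR",),
            routes_b=("SERS",),
            valid_tracers=("1-13C",),
        ),
        RatioDefinition(
            "ser_to_gly_contribution",
            "Gly_M57",
            ("Gly_M57", "Ser_f302", "Thr_f302"),
            take("Gly_M57"),
            take("Ser_f302"),
            take("Thr_f302"),
            routes_a=("SHMF",),
            routes_b=("GLYT",),
        ),
    ]
    return defs


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _mixture_fraction(stacks: list[tuple[np.ndarray, np.ndarray, np.ndarray]]) -> float | None:
    """Closed-form least squares for m = r a + (1-r) b over stacked channels."""
    num = 0.0
    den = 0.0
    for m, a, b in stacks:
        d = a - b
        num += float(d @ (m - b))
        den += float(d @ d)
    if den <= 0:
        return None
    return num / den  # unclipped; callers clip to [0, 1] for reporting


class _RawData:
    """Raw (uncorrected) measurement channels, flattened for perturbation."""

    def __init__(self, sets: Sequence[MeasurementSet], fragments: Mapping[str, FragmentDef]):
        from .labeling import _background_matrix

        self.fragments = fragments
        self.tracers = [ms.tracer_id for ms in sets]
        self.raw: dict[tuple[str, str], np.ndarray] = {}
        self.sds: dict[tuple[str, str], float] = {}
        #: channel sd after background deconvolution (the triangular solve
        #: amplifies noise; identifiability checks must use this scale)
        self.corrected_sds: dict[tuple[str, str], float] = {}
        for ms in sets:
            for e in ms:
                if e.fragment_id not in fragments:
                    continue
                vals = e.mdv.fractions
                if not np.all(np.isfinite(vals)):
                    continue  # entries with absent channels are not usable
                key = (ms.tracer_id, e.fragment_id)
                self.raw[key] = vals.copy()
                self.sds[key] = e.sd
                T = _background_matrix(fragments[e.fragment_id].formula, len(vals))
                # worst-case per-channel noise gain of the deconvolution
                amp = float(np.sqrt((np.linalg.inv(T) ** 2).sum(axis=1)).max())
                self.corrected_sds[key] = e.sd * amp

    def corrected(self, overrides: Mapping[tuple[str, str], np.ndarray] | None = None
                  ) -> dict[str, dict[str, np.ndarray]]:
        out: dict[str, dict[str, np.ndarray]] = {t: {} for t in self.tracers}
        for (tracer, fid), vals in self.raw.items():
            if overrides and (tracer, fid) in overrides:
                vals = overrides[(tracer, fid)]
            corr, _ = correct_vector(np.clip(vals, 0, None), self.fragments[fid].formula)
            out[tracer][fid] = corr
        return out


def _estimate_point(
    rdef: RatioDefinition,
    data: _RawData,
    sources: tuple[Callable, Callable] | None = None,
    min_separation_sd: float = MIN_SEPARATION_SD,
    overrides=None,
) -> tuple[float | None, tuple[str, ...]]:
    source_a, source_b = sources or (rdef.source_a, rdef.source_b)
    corrected = data.corrected(overrides)
    stacks = []
    used = []
    for tracer in data.tracers:
        if rdef.valid_tracers is not None and tracer not in rdef.valid_tracers:
            continue
        c = corrected[tracer]
        missing = [f for f in rdef.fragments if f not in c]
        if missing:
            raise KeyError(
                f"ratio {rdef.name!r}: fragment(s) {missing} missing from tracer "
                f"{tracer!r} measurements"
            )
        m, a, b = rdef.product(c), source_a(c), source_b(c)
        k = min(len(m), len(a), len(b))
        m, a, b = m[:k], a[:k], b[:k]
        # both source vectors carry (correction-amplified) noise
        sd = np.sqrt(2.0) * max(data.corrected_sds[(tracer, f)] for f in rdef.fragments)
        if np.abs(a - b).max() > min_separation_sd * sd:
            stacks.append((m, a, b))
            used.append(tracer)
    if not stacks:
        return None, ()
    return _mixture_fraction(stacks), tuple(used)


def compute_ratios(
    measurements: MeasurementSet | Sequence[MeasurementSet],
    network: AtomTransitionNetwork | None = None,
    fragments: Mapping[str, FragmentDef] | None = None,
    definitions: Sequence[RatioDefinition] | None = None,
    min_separation_sd: float = MIN_SEPARATION_SD,
) -> FluxRatioSet:
    """Estimate the eight flux ratios from one or more tracer experiments.

    A point ratio is computed from every tracer under which its two source
    MDVs differ by more than ``min_separation_sd`` times the channel noise;
    if no tracer separates the sources the ratio is reported undetermined
    with the full [0, 1] interval.  Estimation is invariant to the row
    order of the measurement tables.
    """
    if isinstance(measurements, MeasurementSet):
        measurements = [measurements]
    fragments = fragments or default_fragments()
    definitions = definitions or standard_ratio_definitions()
    data = _RawData(measurements, fragments)

    estimates: dict[str, RatioEstimate] = {}
    for rdef in definitions:
        if rdef.is_interval:
            vals, used_all = [], []
            for pair in rdef.variants:
                r, used = _estimate_point(rdef, data, pair, min_separation_sd)
                if r is not None:
                    vals.append(min(max(r, 0.0), 1.0))
                    used_all.extend(used)
            if not vals:
                estimates[rdef.name] = RatioEstimate(
                    rdef.name, None, None, 0.0, 1.0, (), "undetermined"
                )
                continue
            lb, ub = min(vals), max(vals)
            estimates[rdef.name] = RatioEstimate(
                rdef.name, None, None, lb, ub, tuple(dict.fromkeys(used_all)), "interval"
            )
            continue

        r, used = _estimate_point(rdef, data, None, min_separation_sd)
        if r is None:
            estimates[rdef.name] = RatioEstimate(
                rdef.name, None, None, 0.0, 1.0, (), "undetermined"
            )
            continue
        # first-order error propagation by finite differences over every
        # raw channel of the fragments this ratio reads
        var = 0.0
        eps = 1e-6
        for key in list(data.raw):
            tracer, fid = key
            if fid not in rdef.fragments or tracer not in used:
                continue
            base = data.raw[key]
            sd_ch = data.sds[key]
            for ch in range(len(base)):
                pert = base.copy()
                pert[ch] += eps
                r2, _ = _estimate_point(
                    rdef, data, None, min_separation_sd, overrides={key: pert}
                )
                if r2 is None:
                    continue
                var += ((r2 - r) / eps) ** 2 * sd_ch ** 2
        sd_r = float(np.sqrt(var))
        # the sd is propagated through the unclipped linear estimator;
        # the reported value is clipped to the physical range
        rc = min(max(float(r), 0.0), 1.0)
        estimates[rdef.name] = RatioEstimate(
            rdef.name, rc, sd_r, max(0.0, rc - sd_r), min(1.0, rc + sd_r),
            used, "determined",
        )
    return FluxRatioSet(estimates)


# ---------------------------------------------------------------------------
# linear constraints
# ---------------------------------------------------------------------------

@dataclass
class RatioConstraint:
    """Linear constraint on net fluxes derived from one ratio quantity.

    ``equality``: sum(coefficients * v) = 0, with the ratio's sd attached
    for weighting; ``inequality``: sum(coefficients * v) <= 0.
    """

    coefficients: dict[str, float]
    rhs: float
    kind: str  # "equality" | "inequality"
    provenance: str
    sd: float | None = None


def ratios_to_constraints(
    ratios: FluxRatioSet,
    network: AtomTransitionNetwork,
    definitions: Sequence[RatioDefinition] | None = None,
) -> list[RatioConstraint]:
    """Turn a full ratio set into the eight linear flux constraints.

    A point ratio r over routes A and B into a pool gives
    ``(1 - r) * sum(v_A) - r * sum(v_B) = 0``; the malic-enzyme interval
    gives the two one-sided inequalities.  Undetermined ratios yield the
    trivially satisfied full-interval inequalities.
    """
    definitions = definitions or standard_ratio_definitions()
    out: list[RatioConstraint] = []
    for rdef in definitions:
        for rid in rdef.routes_a + rdef.routes_b:
            if not network.has_reaction(rid):
                raise NetworkError(
                    f"ratio {rdef.name!r} references reaction {rid!r} absent from network"
                )
        est = ratios[rdef.name]
        if rdef.is_interval or est.status != "determined":
            lb, ub = est.lb, est.ub
            coeffs_lb = {rid: lb for rid in rdef.routes_b}
            coeffs_lb.update({rid: lb - 1.0 for rid in rdef.routes_a})
            out.append(
                RatioConstraint(coeffs_lb, 0.0, "inequality", f"{rdef.name}_lb")
            )
            coeffs_ub = {rid: 1.0 - ub for rid in rdef.routes_a}
            coeffs_ub.update({rid: -ub for rid in rdef.routes_b})
            out.append(
                RatioConstraint(coeffs_ub, 0.0, "inequality", f"{rdef.name}_ub")
            )
        else:
            r = est.value
            coeffs = {rid: 1.0 - r for rid in rdef.routes_a}
            coeffs.update({rid: -r for rid in rdef.routes_b})
            out.append(
                RatioConstraint(coeffs, 0.0, "equality", rdef.name, sd=est.sd)
            )
    return out


# ---------------------------------------------------------------------------
# auxiliary oxidative-PPP probe
# ---------------------------------------------------------------------------

@dataclass
class TrioseProbe:
    """Fraction of the triose (3PG) pool carrying an intact glucose C1-C3
    unit, estimated from the positionally labeled (1-13C) design.

    Oxidative decarboxylation in the PP pathway removes glucose C1, the only
    labeled position of that tracer, so trioses that passed the PP pathway
    (and the unlabeled C4-C6 halves) are indistinguishable from natural
    background while intact upper halves carry the C1 label at their C3.
    The fitted intact fraction, divided by the serine-from-glycolysis ratio
    to undo the glycine-route dilution of the serine reporter, measures
    ``s * v_TPI / v_GAPDH`` with ``s = v_PGI / (v_PGI + v_TAL + v_TKL2)``
    the non-PPP share of the hexose-phosphate pool — the one flux direction
    the eight branch-point ratios leave open.
    """

    value: float
    sd: float


def triose_intact_fraction(
    measurements: MeasurementSet | Sequence[MeasurementSet],
    ratio_set: FluxRatioSet | None = None,
    fragments: Mapping[str, FragmentDef] | None = None,
    tracer_purity: float = 0.99,
    natural_13c: float = NATURAL_13C,
    definitions: Sequence[RatioDefinition] | None = None,
    model_sd: float = 0.02,
) -> TrioseProbe | None:
    """Estimate the intact-triose fraction from the 1-13C experiment.

    The raw intact fraction read off the Ser M-57 reporter is divided by
    the serine-from-glycolysis ratio to undo the glycine-route dilution of
    the serine pool.  Both quantities are functions of the same measured
    channels, so the measurement standard deviation is propagated jointly
    by finite differences through the combined estimator.  The two-source
    model behind the probe neglects label redistribution by reversible
    non-oxidative PP-pathway carbon exchange, whose magnitude is not
    observable from the fragment data; *model_sd* is an uncertainty floor
    for that approximation, combined in quadrature with the propagated
    measurement noise.  Returns None when no 1-13C measurement (or no
    Ser M-57 fragment) is available, or when the serine-from-glycolysis
    ratio is undetermined.
    """
    if isinstance(measurements, MeasurementSet):
        measurements = [measurements]
    fragments = fragments or default_fragments()
    definitions = definitions or standard_ratio_definitions()
    ser_def = next(d for d in definitions if d.name == "ser_from_glycolysis")
    data = _RawData(measurements, fragments)
    if ("1-13C", "Ser_M57") not in data.raw:
        return None

    nat = _singleton(natural_13c)
    a = _convolve(_convolve(nat, nat), _singleton(tracer_purity))  # intact half
    b = _convolve(_convolve(nat, nat), nat)                        # everything else
    d_ab = a - b
    dd = float(d_ab @ d_ab)

    def evaluate(overrides=None) -> float | None:
        corr = data.corrected(overrides)["1-13C"].get("Ser_M57")
        if corr is None:
            return None
        r_raw = float(d_ab @ (corr - b)) / dd
        r4, _ = _estimate_point(ser_def, data, None, MIN_SEPARATION_SD, overrides)
        if r4 is None or r4 <= 1e-6:
            return None
        return r_raw / r4

    rt = evaluate()
    if rt is None:
        return None
    var = 0.0
    eps = 1e-6
    frags = set(ser_def.fragments) | {"Ser_M57"}
    for key in list(data.raw):
        tracer, fid = key
        if fid not in frags or tracer != "1-13C":
            continue
        base = data.raw[key]
        sd_ch = data.sds[key]
        for ch in range(len(base)):
            pert = base.copy()
            pert[ch] += eps
            rt2 = evaluate({key: pert})
            if rt2 is None:
                continue
            var += ((rt2 - rt) / eps) ** 2 * sd_ch ** 2
    return TrioseProbe(
        float(np.clip(rt, 0.0, 1.0)),
        max(float(np.sqrt(var + model_sd ** 2)), 1e-6),
    )
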