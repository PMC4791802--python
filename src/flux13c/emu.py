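"""Steady-state isotope labeling simulation by elementary metabolite units.

An elementary metabolite unit (EMU) is a subset of a metabolite's carbon
atoms.  At isotopic steady state the mass-isotopomer distribution (MDV) of
every EMU obeys a flux-weighted balance: the MDV of an EMU of pool M,
weighted by the total labeled inflow of M, equals the flux-weighted sum of
the MDVs of the source EMUs that each producing reaction maps onto it.  A
source spanning several substrate molecules contributes the convolution of
the corresponding substrate EMU MDVs.  Grouping EMUs by size and solving the
resulting linear systems in order of increasing size yields exact
steady-state MDVs at a cost far below full positional-isotopomer balancing.

Reversible reactions are simulated with an exchange flux ``x >= 0``: a net
flux ``v`` becomes a forward labeling flux ``max(v, 0) + x`` and a reverse
labeling flux ``max(-v, 0) + x`` with the inverted atom map.  Scrambling
through symmetric intermediates enters through weighted atom-map variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import NATURAL_13C
from .network import AtomTransitionNetwork

__all__ = [
    "Emu",
    "PositionalLabeling",
    "EmuSolution",
    "ImbalancedFluxError",
    "SingularLabelingError",
    "simulate_emus",
]


class ImbalancedFluxError(ValueError):
    """The supplied flux vector violates the balanced-metabolite steady state."""


class SingularLabelingError(ValueError):
    """The EMU system is singular; carries the pools without labeled inflow."""

    def __init__(self, pools):
        self.pools = sorted(set(pools))
        super().__init__(
            "labeling system is singular; pools without positive inflow: "
            + ", ".join(self.pools)
        )


@dataclass(frozen=True)
class Emu:
    """A metabolite id plus a sorted tuple of 0-based carbon indices."""

    met: str
    carbons: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.carbons)


class PositionalLabeling:
    """Positional 13C enrichment model for an unbalanced input pool.

    A mixture of pools, each a fraction with an independent per-carbon 13C
    probability; the MDV of any carbon subset is the mixture of convolutions
    of single-carbon distributions.
    """

    def __init__(self, pools: Sequence[tuple[float, Sequence[float]]]):
        total = sum(f for f, _ in pools)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool fractions sum to {total}, expected 1")
        for _, enr in pools:
            if any(not (0.0 <= p <= 1.0) for p in enr):
                raise ValueError("positional enrichments must lie in [0, 1]")
        self.pools = [(float(f), tuple(float(p) for p in enr)) for f, enr in pools]

    @classmethod
    def uniform(cls, n_carbons: int, enrichment: float = NATURAL_13C) -> "PositionalLabeling":
        return cls([(1.0, (enrichment,) * n_carbons)])

    @property
    def n_carbons(self) -> int:
        return len(self.pools[0][1])

    def emu_mdv(self, carbons: Sequence[int]) -> np.ndarray:
        out = np.zeros(len(carbons) + 1)
        for frac, enr in self.pools:
            vec = np.array([1.0])
            for c in carbons:
                p = enr[c]
                vec = np.convolve(vec, [1.0 - p, p])
            out += frac * vec
        return out


@dataclass
class _LabelingFlux:
    value: float
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    # (product_instance, product_carbon) -> (substrate_instance, substrate_carbon)
    source_of: dict[tuple[int, int], tuple[int, int]]


def _labeling_fluxes(
    net: AtomTransitionNetwork,
    fluxes: Mapping[str, float],
    exchange: Mapping[str, float] | None,
) -> list[_LabelingFlux]:
    exchange = exchange or {}
    out: list[_LabelingFlux] = []
    for r in net.reactions:
        v = float(fluxes.get(r.id, 0.0))
        if not r.reversible and v < -1e-9:
            raise ImbalancedFluxError(f"irreversible reaction {r.id!r} has negative flux {v}")
        x = float(exchange.get(r.id, 0.0))
        if x < 0:
            raise ValueError(f"negative exchange flux for {r.id!r}")
        if not r.reversible:
            x = 0.0
        fwd = max(v, 0.0) + x
        rev = max(-v, 0.0) + x
        for variant in r.atom_maps:
            src = variant.source_of()
            if fwd > 0:
                out.append(
                    _LabelingFlux(fwd * variant.weight, variant.substrates, variant.products, src)
                )
            if rev > 0:
                inv = {s: p for p, s in src.items()}
                out.append(
                    _LabelingFlux(
                        rev * variant.weight, variant.products, variant.substrates, inv
                    )
                )
    return [lf for lf in out if lf.value > 0.0]


class EmuSolution:
    """Solved EMU MDVs; query with :meth:`mdv`."""

    def __init__(self, mdvs: dict[Emu, np.ndarray], balanced: set[str]):
        self._mdvs = mdvs
        self._balanced = balanced

    def mdv(self, met: str, carbons: Sequence[int] | None = None) -> np.ndarray:
        """MDV of a carbon subset (1-based indices; None = whole molecule)."""
        if carbons is None:
            sizes = [e for e in self._mdvs if e.met == met]
            if not sizes:
                raise KeyError(f"no solved EMU for {met!r}")
            e = max(sizes, key=lambda e: e.size)
        else:
            e = Emu(met, tuple(sorted(c - 1 for c in carbons)))
        return self._mdvs[e].copy()

    def metabolite_mdvs(self) -> dict[str, np.ndarray]:
        """Whole-molecule MDVs for every solved balanced metabolite."""
        out = {}
        for e, v in self._mdvs.items():
            if e.met in self._balanced and e.carbons == tuple(range(len(v) - 1)):
                cur = out.get(e.met)
                if cur is None or len(v) > len(cur):
                    out[e.met] = v.copy()
        return out

    def __contains__(self, emu: Emu) -> bool:
        return emu in self._mdvs


def simulate_emus(
    net: AtomTransitionNetwork,
    fluxes: Mapping[str, float],
    input_labeling: Mapping[str, PositionalLabeling],
    exchange: Mapping[str, float] | None = None,
    extra_emus: Sequence[tuple[str, Sequence[int]]] = (),
    balance_tol: float = 1e-8,
) -> EmuSolution:
    """Solve steady-state EMU MDVs for every carbon-bearing balanced pool.

    Parameters
    ----------
    fluxes
        Net flux per reaction id; must satisfy the balanced steady state
        (``max |S v| < balance_tol`` relative to the largest flux).
    input_labeling
        Positional labeling of every unbalanced pool that feeds the mapped
        network (e.g. the glucose tracer, CO2, the one-carbon pool).
    exchange
        Nonnegative exchange flux per reversible reaction id.
    extra_emus
        Additional (metabolite, 1-based carbon indices) EMUs to solve, e.g.
        amino-acid fragment precursors.
    """
    S = net.stoichiometric_matrix()
    v = np.array([fluxes.get(r.id, 0.0) for r in net.reactions])
    scale = max(1.0, np.abs(v).max())
    resid = np.abs(S @ v).max()
    if resid > balance_tol * scale:
        raise ImbalancedFluxError(
            f"flux vector violates steady state (max |S v| = {resid:.3g})"
        )

    balanced = set(net.balanced_metabolites)
    lfs = _labeling_fluxes(net, fluxes, exchange)
    producers: dict[str, list[tuple[_LabelingFlux, int]]] = {}
    for lf in lfs:
        for pi, met in enumerate(lf.products):
            producers.setdefault(met, []).append((lf, pi))

    def is_internal(met: str) -> bool:
        return met in balanced

    # --- collect required EMUs by backward traversal ----------------------
    requested: list[Emu] = []
    for mid in net.balanced_metabolites:
        n = net.metabolites[mid].carbon_count
        if n > 0:
            requested.append(Emu(mid, tuple(range(n))))
    for met, carbons in extra_emus:
        requested.append(Emu(met, tuple(sorted(c - 1 for c in carbons))))

    # terms[emu] = list of (flux_value, [part emus across substrates])
    terms: dict[Emu, list[tuple[float, list[Emu]]]] = {}
    stack = [e for e in requested if is_internal(e.met)]
    seen = set(stack)
    unreachable: list[str] = []
    while stack:
        emu = stack.pop()
        prods = producers.get(emu.met, [])
        tlist: list[tuple[float, list[Emu]]] = []
        for lf, pi in prods:
            by_sub: dict[int, list[int]] = {}
            for c in emu.carbons:
                si, sc = lf.source_of[(pi, c)]
                by_sub.setdefault(si, []).append(sc)
            parts = [
                Emu(lf.substrates[si], tuple(sorted(cs))) for si, cs in sorted(by_sub.items())
            ]
            tlist.append((lf.value, parts))
            for p in parts:
                if is_internal(p.met) and p not in seen:
                    seen.add(p)
                    stack.append(p)
        if not tlist:
            unreachable.append(emu.met)
        terms[emu] = tlist
    if unreachable:
        raise SingularLabelingError(unreachable)

    # --- solve size tiers in increasing order -----------------------------
    solved: dict[Emu, np.ndarray] = {}

    def known_mdv(e: Emu) -> np.ndarray | None:
        if e in solved:
            return solved[e]
        if not is_internal(e.met):
            lab = input_labeling.get(e.met)
            if lab is None:
                raise KeyError(
                    f"no input labeling given for unbalanced pool {e.met!r}"
                )
            return lab.emu_mdv(e.carbons)
        return None

    by_size: dict[int, list[Emu]] = {}
    for e in terms:
        by_size.setdefault(e.size, []).append(e)

    for size in sorted(by_size):
        emus = sorted(by_size[size], key=lambda e: (e.met, e.carbons))
        index = {e: i for i, e in enumerate(emus)}
        n = len(emus)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for e in emus:
            i = index[e]
            for f, parts in terms[e]:
                A[i, i] -= f
                if len(parts) == 1 and is_internal(parts[0].met) and parts[0].size == size:
                    A[i, index[parts[0]]] += f
                else:
                    vec = np.array([1.0])
                    for p in parts:
                        pv = known_mdv(p)
                        if pv is None:
                            raise RuntimeError(
                                f"EMU ordering error: {p} not solved before size {size}"
                            )
                        vec = np.convolve(vec, pv)
                    B[i] -= f * vec
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError:
            zero_rows = [emus[i].met for i in range(n) if np.abs(A[i]).max() < 1e-12]
            raise SingularLabelingError(zero_rows or [e.met for e in emus]) from None
        for e in emus:
            mdv = X[index[e]]
            mdv = np.clip(mdv, 0.0, None)
            s = mdv.sum()
            if not np.isfinite(s) or s <= 0:
                raise SingularLabelingError([e.met])
            solved[e] = mdv / s

    return EmuSolution(solved, balanced)
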