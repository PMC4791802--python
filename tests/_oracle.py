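"""Independent brute-force oracles used only by the test suite.

``isotopomer_mdvs`` solves steady-state labeling by balancing *all*
2^n positional isotopomers of every balanced pool with damped fixed-point
iteration — no EMU decomposition, no size tiers.  ``enumerate_vertices``
lists the vertices of a small flux polytope by basis enumeration for LP
cross-checks.  Both are deliberately naive.
"""

from __future__ import annotations

import itertools

import numpy as np


def _oracle_labeling_fluxes(net, fluxes, exchange):
    """(value, substrates, products, source_of) tuples, independently derived."""
    out = []
    exchange = exchange or {}
    for r in net.reactions:
        v = float(fluxes.get(r.id, 0.0))
        x = float(exchange.get(r.id, 0.0)) if r.reversible else 0.0
        directions = []
        fwd = max(v, 0.0) + x
        rev = max(-v, 0.0) + x
        for variant in r.atom_maps:
            src = variant.source_of()
            if fwd > 0:
                directions.append((fwd * variant.weight, variant.substrates, variant.products, src))
            if rev > 0:
                inv = {s: p for p, s in src.items()}
                directions.append((rev * variant.weight, variant.products, variant.substrates, inv))
        out.extend(d for d in directions if d[0] > 0)
    return out


def isotopomer_mdvs(net, fluxes, input_labeling, exchange=None, tol=1e-14, max_iter=200000):
    """Steady-state MDVs of all carbon-bearing balanced pools, exhaustively.

    ``input_labeling`` maps unbalanced pool ids to objects exposing
    ``pools`` (fraction, per-carbon enrichment) as in PositionalLabeling.
    """
    balanced = [
        m.id for m in net.metabolites.values() if m.balanced and m.carbon_count > 0
    ]
    ncar = {m.id: m.carbon_count for m in net.metabolites.values()}

    def input_iso(met):
        lab = input_labeling[met]
        n = ncar[met]
        dist = np.zeros(2 ** n)
        for frac, enr in lab.pools:
            for pattern in range(2 ** n):
                p = frac
                for c in range(n):
                    bit = (pattern >> c) & 1
                    p *= enr[c] if bit else (1.0 - enr[c])
                dist[pattern] += p
        return dist

    lfs = _oracle_labeling_fluxes(net, fluxes, exchange)
    state = {m: input_iso_natural(ncar[m]) for m in balanced}
    fixed = {}
    for m in net.metabolites.values():
        if not m.balanced and m.carbon_count > 0 and m.id in (input_labeling or {}):
            fixed[m.id] = input_iso(m.id)

    producers = {}
    for lf in lfs:
        value, subs, prods, src = lf
        for pi, met in enumerate(prods):
            if met in state:
                producers.setdefault(met, []).append(lf + (pi,))

    for _ in range(max_iter):
        delta = 0.0
        new_state = {}
        for met in balanced:
            total = 0.0
            acc = np.zeros(2 ** ncar[met])
            for value, subs, prods, src, pi in producers.get(met, []):
                total += value
                sub_dists = [
                    state[s] if s in state else fixed[s] for s in subs
                ]
                sizes = [ncar[s] for s in subs]
                for combo in itertools.product(*[range(2 ** n) for n in sizes]):
                    p = value
                    for d, pat in zip(sub_dists, combo):
                        p *= d[pat]
                    if p == 0.0:
                        continue
                    out_pat = 0
                    for c in range(ncar[met]):
                        si, sc = src[(pi, c)]
                        if (combo[si] >> sc) & 1:
                            out_pat |= 1 << c
                    acc[out_pat] += p
            if total <= 0:
                raise ValueError(f"pool {met!r} has no labeled inflow")
            nx = acc / total
            delta = max(delta, np.abs(nx - state[met]).max())
            new_state[met] = nx
        state = new_state
        if delta < tol:
            break
    else:  # pragma: no cover - convergence guard
        raise RuntimeError("isotopomer fixed point did not converge")

    mdvs = {}
    for met, dist in state.items():
        n = ncar[met]
        mdv = np.zeros(n + 1)
        for pattern, p in enumerate(dist):
            mdv[bin(pattern).count("1")] += p
        mdvs[met] = mdv
    return mdvs


def input_iso_natural(n, a=0.0107):
    dist = np.zeros(2 ** n)
    for pattern in range(2 ** n):
        k = bin(pattern).count("1")
        dist[pattern] = a ** k * (1 - a) ** (n - k)
    return dist


def marginal_mdv(iso_dist, carbons):
    """MDV of a 0-based carbon subset from a full isotopomer distribution."""
    n = int(np.log2(len(iso_dist)))
    mdv = np.zeros(len(carbons) + 1)
    for pattern, p in enumerate(iso_dist):
        k = sum((pattern >> c) & 1 for c in carbons)
        mdv[k] += p
    return mdv


def enumerate_vertices(A_eq, b_eq, lb, ub, tol=1e-9):
    """Vertices of {x : A_eq x = b_eq, lb <= x <= ub} by basis enumeration."""
    n = len(lb)
    m = A_eq.shape[0] if A_eq is not None else 0
    vertices = []
    # a vertex has >= n - rank active constraints: try all choices of n - m
    # variables pinned at a bound, solving A_eq for the rest
    rank = np.linalg.matrix_rank(A_eq) if m else 0
    free_count = rank
    for free in itertools.combinations(range(n), free_count):
        bound_vars = [i for i in range(n) if i not in free]
        for bounds_choice in itertools.product(*[(lb[i], ub[i]) for i in bound_vars]):
            x = np.zeros(n)
            for i, val in zip(bound_vars, bounds_choice):
                x[i] = val
            if free_count:
                Af = A_eq[:, list(free)]
                rhs = b_eq - A_eq[:, bound_vars] @ np.array(bounds_choice)
                sol, res, rk, _ = np.linalg.lstsq(Af, rhs, rcond=None)
                if rk < free_count:
                    continue
                x[list(free)] = sol
            if m and np.abs(A_eq @ x - b_eq).max() > tol:
                continue
            if np.all(x >= lb - tol) and np.all(x <= ub + tol):
                if not any(np.abs(x - v).max() < 1e-7 for v in vertices):
                    vertices.append(x)
    return vertices
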