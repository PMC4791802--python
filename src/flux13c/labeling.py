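"""Tracers, amino-acid fragments, GC–MS effects and measurement tables.

This module turns a flux distribution into the kind of data a GC–MS
measurement of TBDMS-derivatized proteinogenic amino acids would produce:

1. :func:`make_tracer` builds the glucose labeling designs (100 % 1-13C
   glucose at 99 % isotopic purity, or 20 % uniformly labeled glucose mixed
   with 80 % naturally labeled glucose).
2. :func:`simulate_labeling` solves steady-state EMU MDVs of the network.
3. :func:`fragment_mdvs` projects precursor labeling onto amino-acid
   fragment carbon skeletons (amino acids inherit the labeling of their
   biosynthetic precursor pools).
4. :func:`apply_derivatization_background` convolves a skeleton MDV with
   the natural-isotope background of the derivatization atoms (H, N, O, Si
   and derivative carbons); :func:`correct_natural_abundance` inverts it.
5. :func:`add_noise` applies additive Gaussian channel noise.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .constants import ISOTOPE_SHIFT, NATURAL_13C
from .emu import EmuSolution, PositionalLabeling, simulate_emus
from .network import AtomTransitionNetwork

__all__ = [
    "TracerSpec",
    "make_tracer",
    "MassIsotopomerDistribution",
    "FragmentDef",
    "default_fragments",
    "load_fragments",
    "simulate_labeling",
    "fragment_mdvs",
    "background_distribution",
    "apply_derivatization_background",
    "correct_natural_abundance",
    "add_noise",
    "MeasurementSet",
    "DEFAULT_NOISE_SD",
]

#: default GC-MS channel noise, mole-fraction units
DEFAULT_NOISE_SD = 0.004

TRACER_NAMES = ("1-13C", "20pct-U13C", "unlabeled")


@dataclass
class TracerSpec:
    """A glucose isotopologue mixture feeding the network."""

    name: str
    labeling: PositionalLabeling
    substrate: str = "glc_ext"
    natural_13c: float = NATURAL_13C

    @property
    def pools(self):
        return self.labeling.pools


def make_tracer(name: str, substrate: str = "glc_ext", purity: float = 0.99,
                natural_13c: float = NATURAL_13C) -> TracerSpec:
    """Build one of the supported glucose tracer designs.

    ``"1-13C"``: all glucose 99 % 13C at C1, natural elsewhere.
    ``"20pct-U13C"``: 20 % (n/n) uniformly 99 % labeled + 80 % natural.
    ``"unlabeled"``: natural abundance at every position.
    """
    a = natural_13c
    if name == "1-13C":
        lab = PositionalLabeling([(1.0, (purity, a, a, a, a, a))])
    elif name == "20pct-U13C":
        lab = PositionalLabeling([(0.2, (purity,) * 6), (0.8, (a,) * 6)])
    elif name == "unlabeled":
        lab = PositionalLabeling([(1.0, (a,) * 6)])
    else:
        raise ValueError(f"unknown tracer {name!r}; expected one of {TRACER_NAMES}")
    return TracerSpec(name, lab, substrate, a)


# ---------------------------------------------------------------------------
# MDVs
# ---------------------------------------------------------------------------

@dataclass
class MassIsotopomerDistribution:
    """Fractions of molecules with 0..n heavy carbons for one fragment."""

    fragment_id: str
    n_carbons: int
    fractions: np.ndarray
    clipped: bool = False

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.fractions) != self.n_carbons + 1:
            raise ValueError(
                f"{self.fragment_id}: {len(self.fractions)} channels for "
                f"{self.n_carbons} carbons"
            )
        finite = self.fractions[np.isfinite(self.fractions)]
        if finite.size and (finite.min() < -1e-9):
            raise ValueError(f"{self.fragment_id}: negative fraction")
        if finite.size == len(self.fractions) and abs(finite.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"{self.fragment_id}: fractions sum to {finite.sum():.6f}"
            )

    def mean_shift(self) -> float:
        """First moment (average number of heavy carbons)."""
        return float(np.nansum(np.arange(len(self.fractions)) * self.fractions))


def _mdv(fragment_id: str, fractions: np.ndarray, clipped=False) -> MassIsotopomerDistribution:
    return MassIsotopomerDistribution(fragment_id, len(fractions) - 1, fractions, clipped)


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"bad formula {text!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text):
        raise ValueError(f"bad formula {text!r}")
    return out


@dataclass(frozen=True)
class FragmentDef:
    """A GC–MS fragment: which precursor carbons it retains and what
    derivatization atoms (excluding the retained carbons) ride along."""

    amino_acid: str
    fragment_id: str
    precursor: str
    retained_carbons: tuple[int, ...]  # 1-based indices on the precursor
    formula: dict[str, int]

    def __post_init__(self):
        if not self.retained_carbons:
            raise ValueError(f"{self.fragment_id}: no retained carbons")
        if any(n < 0 for n in self.formula.values()):
            raise ValueError(f"{self.fragment_id}: negative element count")

    @property
    def n_carbons(self) -> int:
        return len(self.retained_carbons)


def _fragments_path() -> str:
    from importlib.resources import files

    return str(files("flux13c").joinpath("data/fragments.tsv"))


def load_fragments(path=None) -> dict[str, FragmentDef]:
    """Read a tab-separated fragment definition table."""
    path = path or _fragments_path()
    out: dict[str, FragmentDef] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, frag, precursor, carbons, formula = line.split("\t")
            out[frag] = FragmentDef(
                aa,
                frag,
                precursor,
                tuple(int(c) for c in carbons.split(",")),
                parse_formula(formula),
            )
    return out


def default_fragments() -> dict[str, FragmentDef]:
    """The bundled TBDMS fragment set for the yeast network."""
    return load_fragments()


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_labeling(
    network: AtomTransitionNetwork,
    fluxes: Mapping[str, float],
    tracer: TracerSpec,
    exchange: Mapping[str, float] | None = None,
    extra_emus: Sequence[tuple[str, Sequence[int]]] = (),
    input_labeling: Mapping[str, PositionalLabeling] | None = None,
) -> EmuSolution:
    """Steady-state EMU solution for the network under a glucose tracer.

    Unbalanced carbon pools that feed mapped reactions but have no explicit
    labeling (CO2, the one-carbon pool) default to natural abundance.
    """
    inputs: dict[str, PositionalLabeling] = {}
    balanced = set(network.balanced_metabolites)
    for r in network.reactions:
        for v in r.atom_maps:
            for mid in v.substrates:
                if mid not in balanced and mid not in inputs:
                    n = network.metabolites[mid].carbon_count
                    inputs[mid] = PositionalLabeling.uniform(n, tracer.natural_13c)
    inputs[tracer.substrate] = tracer.labeling
    if input_labeling:
        inputs.update(input_labeling)
    return simulate_emus(network, fluxes, inputs, exchange=exchange, extra_emus=extra_emus)


def fragment_emu_list(fragments: Iterable[FragmentDef]) -> list[tuple[str, tuple[int, ...]]]:
    return [(f.precursor, f.retained_carbons) for f in fragments]


def fragment_mdvs(
    solution: EmuSolution,
    fragments: Iterable[FragmentDef],
) -> dict[str, MassIsotopomerDistribution]:
    """Skeleton MDVs of fragments from a solved EMU system."""
    out = {}
    for f in fragments:
        vec = solution.mdv(f.precursor, f.retained_carbons)
        out[f.fragment_id] = _mdv(f.fragment_id, vec)
    return out


# ---------------------------------------------------------------------------
# derivatization background and its inversion
# ---------------------------------------------------------------------------

def background_distribution(formula: Mapping[str, int], length: int) -> np.ndarray:
    """Mass-shift distribution of the non-skeleton atoms, truncated to *length*."""
    vec = np.array([1.0])
    for elem, count in formula.items():
        if elem not in ISOTOPE_SHIFT:
            raise ValueError(f"no isotope data for element {elem!r}")
        single = np.asarray(ISOTOPE_SHIFT[elem])
        for _ in range(int(count)):
            vec = np.convolve(vec, single)
            if len(vec) > length:
                vec = vec[:length]
    if len(vec) < length:
        vec = np.pad(vec, (0, length - len(vec)))
    return vec


def _background_matrix(formula: Mapping[str, int], n: int) -> np.ndarray:
    b = background_distribution(formula, n)
    T = np.zeros((n, n))
    for i in range(n):
        T[i, : i + 1] = b[: i + 1][::-1]
    return T


def apply_derivatization_background(
    mdv: MassIsotopomerDistribution, formula: Mapping[str, int]
) -> MassIsotopomerDistribution:
    """Convolve a carbon-skeleton MDV with the derivatization isotope
    background (truncated to the skeleton channel count, renormalized)."""
    n = len(mdv.fractions)
    T = _background_matrix(formula, n)
    raw = T @ mdv.fractions
    return _mdv(mdv.fragment_id, raw / raw.sum())


def correct_natural_abundance(
    raw: MassIsotopomerDistribution, formula: Mapping[str, int], clip_tol: float = 1e-3
) -> MassIsotopomerDistribution:
    """Deconvolve the derivatization background from a measured MDV.

    Exactly inverts :func:`apply_derivatization_background` (the background
    matrix is lower-triangular, so truncation does not break invertibility;
    renormalization only rescales).  Noise can push corrected channels
    slightly negative; they are clipped and the result renormalized, with
    ``clipped=True`` when the clipped mass exceeds *clip_tol*.
    """
    x, clipped_mass = correct_vector(raw.fractions, formula)
    return _mdv(raw.fragment_id, x, clipped=clipped_mass > clip_tol)


def correct_vector(fractions: np.ndarray, formula: Mapping[str, int]) -> tuple[np.ndarray, float]:
    """Array-level background deconvolution; returns (corrected, clipped mass)."""
    fractions = np.asarray(fractions, dtype=float)
    T = _background_matrix(formula, len(fractions))
    x = solve_triangular(T, fractions, lower=True)
    clipped_mass = float(-x[x < 0].sum()) if np.any(x < 0) else 0.0
    x = np.clip(x, 0.0, None)
    s = x.sum()
    if s <= 0:
        raise ValueError("correction annihilated the MDV")
    return x / s, clipped_mass


# ---------------------------------------------------------------------------
# noise and measurement tables
# ---------------------------------------------------------------------------

@dataclass
class MeasurementEntry:
    fragment_id: str
    mdv: MassIsotopomerDistribution
    sd: float


@dataclass
class MeasurementSet:
    """Noisy fragment MDVs from one tracer experiment."""

    entries: list[MeasurementEntry]
    tracer_id: str
    seed: int | None = None

    def __iter__(self):
        return iter(self.entries)

    def get(self, fragment_id: str) -> MeasurementEntry:
        for e in self.entries:
            if e.fragment_id == fragment_id:
                return e
        raise KeyError(f"fragment {fragment_id!r} not measured")

    def __contains__(self, fragment_id: str) -> bool:
        return any(e.fragment_id == fragment_id for e in self.entries)

    def to_tsv(self) -> str:
        lines = ["# tracer: %s" % self.tracer_id]
        if self.seed is not None:
            lines.append("# seed: %d" % self.seed)
        width = max(e.mdv.n_carbons for e in self.entries) + 1
        lines.append(
            "fragment_id\tn_carbons\t" + "\t".join(f"m{i}" for i in range(width)) + "\tsd"
        )
        for e in self.entries:
            vals = [f"{v:.8f}" for v in e.mdv.fractions]
            vals += [""] * (width - len(vals))
            lines.append(f"{e.fragment_id}\t{e.mdv.n_carbons}\t" + "\t".join(vals) + f"\t{e.sd:.6f}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "MeasurementSet":
        tracer = "unknown"
        seed = None
        entries = []
        header: list[str] | None = None
        for line in io.StringIO(text):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = re.match(r"#\s*tracer:\s*(\S+)", line)
            if m:
                tracer = m.group(1)
                continue
            m = re.match(r"#\s*seed:\s*(\d+)", line)
            if m:
                seed = int(m.group(1))
                continue
            if line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            parts = line.split("\t")
            frag, nc = parts[0], int(parts[1])
            sd = float(parts[-1])
            chans = parts[2:-1]
            vals = np.full(nc + 1, np.nan)
            for i in range(nc + 1):
                if i < len(chans) and chans[i].strip() != "":
                    vals[i] = float(chans[i])
            entries.append(
                MeasurementEntry(frag, MassIsotopomerDistribution(frag, nc, vals), sd)
            )
        return cls(entries, tracer, seed)


def add_noise(
    measurements: Mapping[str, MassIsotopomerDistribution] | Iterable[MeasurementEntry],
    sd: float,
    seed: int,
    tracer_id: str = "unknown",
) -> MeasurementSet:
    """Additive Gaussian channel noise, clipped at zero and renormalized.

    Deterministic for a fixed seed; ``sd=0`` returns the input unchanged.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if isinstance(measurements, Mapping):
        items = [(k, v) for k, v in measurements.items()]
    else:
        items = [(e.fragment_id, e.mdv) for e in measurements]
    entries = []
    for frag, mdv in items:
        vals = mdv.fractions.copy()
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, size=len(vals))
            vals = np.clip(vals, 0.0, None)
            vals = vals / vals.sum()
        entries.append(
            MeasurementEntry(frag, _mdv(frag, vals), sd if sd > 0 else 1e-6)
        )
    return MeasurementSet(entries, tracer_id, seed)
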