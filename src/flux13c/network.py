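"""Atom-mapped stoichiometric model of yeast central carbon metabolism.

The model is a set of :class:`Metabolite` pools and :class:`Reaction` records
with per-carbon atom transitions.  Mass balances are written only for pools
flagged as *balanced*; CO2, the one-carbon (methylene-THF) pool, extracellular
species and the biomass sink are unbalanced, so no mass balance rows exist for
them and carbons routed there simply leave the balanced system.  Cofactor
stoichiometries (NADH, NADPH, FADH2, ATP) are carried as annotations and are
never balanced here: the net-flux estimation operates on carbon balances and
labeling information alone.

Model file grammar (line oriented, UTF-8, ``#`` comments)::

    # reactions: 48                      <- optional declared reaction count
    # METABOLITES
    # id  name  compartment  nC  balanced
    g6p   glucose-6-phosphate  cytosol  6  yes
    ...
    # REACTIONS
    GND : 1 6pgc -> 1 ru5p + 1 co2 | irr | cofactors NADPH:1 \
          | map 6pgc#abcdef -> co2#a + ru5p#bcdef
    SDH : 1 succ -> 1 fum | irr | map succ#abcd -> fum#abcd @0.5 ; \
          succ#abcd -> fum#dcba @0.5
    # BIOMASS
    biomass_reaction: BIO

Fields within a metabolite line are whitespace-delimited (names therefore
contain no spaces).  Atom maps label substrate carbons with letters in C1..Cn
order, counted from the most-oxidized end (C1 of glucose is the aldehyde
carbon); the product side must use every letter exactly once.  A reaction may
carry several weighted atom-map variants (``@w``, separated by ``;``) to
express scrambling through symmetric intermediates such as succinate and
fumarate.  Reactions flagged ``sink`` (the biomass drain) are exempt from the
carbon-balance audit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "AtomMapVariant",
    "Reaction",
    "AtomTransitionNetwork",
    "ValidationReport",
    "NetworkError",
    "ModelSyntaxError",
    "load_network",
    "load_network_file",
    "serialize_network",
    "stoichiometric_matrix",
    "add_3hp_pathway",
    "validate",
    "load_yeast_network",
    "bundled_model_path",
]

COMPARTMENTS = ("cytosol", "mitochondrion", "extracellular")

#: default bounds for reactions that do not declare any (normalized units)
DEFAULT_BOUND = 1000.0


class NetworkError(ValueError):
    """Any structural error in a metabolic network definition."""


class ModelSyntaxError(NetworkError):
    """Parse error in a model file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", col {column}" if column is not None else "") + ")"
        super().__init__(message + loc)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    compartment: str
    carbon_count: int
    balanced: bool

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )
        if self.carbon_count < 0:
            raise NetworkError(f"metabolite {self.id!r}: negative carbon count")


@dataclass(frozen=True)
class AtomMapVariant:
    """One atom-transition alternative of a reaction.

    ``substrates``/``products`` list one entry per molecule instance (a
    stoichiometric coefficient of 2 appears as two instances); the label
    tuples give one letter per carbon in C1..Cn order.
    """

    weight: float
    substrates: tuple[str, ...]
    substrate_labels: tuple[tuple[str, ...], ...]
    products: tuple[str, ...]
    product_labels: tuple[tuple[str, ...], ...]

    def source_of(self) -> dict[tuple[int, int], tuple[int, int]]:
        """Map (product_instance, product_carbon_index0) -> (substrate_instance, carbon_index0)."""
        origin: dict[str, tuple[int, int]] = {}
        for si, labels in enumerate(self.substrate_labels):
            for ci, lab in enumerate(labels):
                origin[lab] = (si, ci)
        out: dict[tuple[int, int], tuple[int, int]] = {}
        for pi, labels in enumerate(self.product_labels):
            for ci, lab in enumerate(labels):
                out[(pi, ci)] = origin[lab]
        return out

    def as_tuples(self) -> list[tuple[str, int, str, int]]:
        """Spec-style listing (substrate_id, substrate_carbon, product_id, product_carbon), 1-based."""
        rows = []
        for (pi, ci), (si, sci) in sorted(self.source_of().items()):
            rows.append((self.substrates[si], sci + 1, self.products[pi], ci + 1))
        return rows


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    atom_maps: list[AtomMapVariant] = field(default_factory=list)
    cofactors: dict[str, float] = field(default_factory=dict)
    lower_bound: float | None = None
    upper_bound: float | None = None
    sink: bool = False

    @property
    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def bounds(self) -> tuple[float, float]:
        lb = self.lower_bound
        ub = self.upper_bound
        if lb is None:
            lb = -DEFAULT_BOUND if self.reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        return lb, ub


@dataclass
class ValidationFinding:
    kind: str
    subject: str
    message: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.subject}: {self.message}"


@dataclass
class ValidationReport:
    ok: bool
    findings: list[ValidationFinding]
    reaction_status: dict[str, dict[str, str]]
    metabolite_status: dict[str, dict[str, int]]

    def __str__(self):  # pragma: no cover - cosmetic
        head = "PASS" if self.ok else "FAIL"
        return "\n".join([head] + [str(f) for f in self.findings])


class AtomTransitionNetwork:
    """Ordered collection of metabolites and reactions with atom maps."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_reaction_id: str | None = None,
        declared_reaction_count: int | None = None,
    ):
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise NetworkError(f"duplicate metabolite id {m.id!r}")
            self.metabolites[m.id] = m
        self.reactions: list[Reaction] = []
        self._rxn_index: dict[str, int] = {}
        for r in reactions:
            if r.id in self._rxn_index:
                raise NetworkError(f"duplicate reaction id {r.id!r}")
            self._rxn_index[r.id] = len(self.reactions)
            self.reactions.append(r)
        self.biomass_reaction_id = biomass_reaction_id
        self.declared_reaction_count = declared_reaction_count
        self._check_structure()

    # -- basic access -----------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rid]]
        except KeyError:
            raise NetworkError(f"unknown reaction id {rid!r}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def balanced_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.balanced]

    # -- structural checks ------------------------------------------------
    def _check_structure(self):
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self.metabolites:
                    raise NetworkError(f"reaction {r.id!r} references unknown metabolite {mid!r}")
            has_neg = any(c < 0 for c in r.stoichiometry.values())
            has_pos = any(c > 0 for c in r.stoichiometry.values())
            if not (has_neg and has_pos):
                raise NetworkError(
                    f"reaction {r.id!r} must have at least one substrate and one product"
                )
            for amap in r.atom_maps:
                self._check_atom_map(r, amap)
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in self._rxn_index:
            raise NetworkError(f"biomass reaction {self.biomass_reaction_id!r} not defined")

    def _check_atom_map(self, r: Reaction, amap: AtomMapVariant):
        # instance multiplicity must match integer stoichiometry for carbon species
        def _expect(side: Mapping[str, float], instances: Sequence[str], what: str):
            counts: dict[str, int] = {}
            for mid in instances:
                counts[mid] = counts.get(mid, 0) + 1
            for mid, coeff in side.items():
                met = self.metabolites[mid]
                if met.carbon_count == 0:
                    continue
                n = counts.pop(mid, 0)
                if abs(coeff - round(coeff)) > 1e-9 or n != round(coeff):
                    raise NetworkError(
                        f"reaction {r.id!r}: atom map lists {n} instance(s) of "
                        f"{what} {mid!r} but stoichiometric coefficient is {coeff}"
                    )
            if counts:
                raise NetworkError(
                    f"reaction {r.id!r}: atom map references {sorted(counts)} "
                    f"not present as {what}"
                )

        _expect(r.substrates, amap.substrates, "substrate")
        _expect(r.products, amap.products, "product")
        for mid, labels in zip(
            amap.substrates + amap.products, amap.substrate_labels + amap.product_labels
        ):
            declared = self.metabolites[mid].carbon_count
            if len(labels) != declared:
                raise NetworkError(
                    f"reaction {r.id!r}: atom map gives {len(labels)} carbons for "
                    f"{mid!r} but it declares {declared}"
                )
        subs = [lab for labels in amap.substrate_labels for lab in labels]
        prods = [lab for labels in amap.product_labels for lab in labels]
        if len(set(subs)) != len(subs):
            raise NetworkError(f"reaction {r.id!r}: repeated substrate carbon label")
        if sorted(subs) != sorted(prods):
            raise NetworkError(
                f"reaction {r.id!r}: substrate carbons {sorted(subs)} do not match "
                f"product carbons {sorted(prods)} (carbon-count mismatch; route lost "
                f"carbons to the CO2 sink explicitly)"
            )

    # -- matrix -----------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Balanced-metabolite x reaction coefficient matrix (declaration order)."""
        rows = self.balanced_metabolites
        idx = {m: i for i, m in enumerate(rows)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for mid, coeff in r.stoichiometry.items():
                i = idx.get(mid)
                if i is not None:
                    S[i, j] += coeff
        return S

    def copy(self) -> "AtomTransitionNetwork":
        return AtomTransitionNetwork(
            list(self.metabolites.values()),
            [
                Reaction(
                    r.id,
                    dict(r.stoichiometry),
                    r.reversible,
                    list(r.atom_maps),
                    dict(r.cofactors),
                    r.lower_bound,
                    r.upper_bound,
                    r.sink,
                )
                for r in self.reactions
            ],
            self.biomass_reaction_id,
            self.declared_reaction_count,
        )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^#\s*(METABOLITES|REACTIONS|BIOMASS)\s*$")
_COUNT_RE = re.compile(r"^#\s*reactions:\s*(\d+)\s*$")


def _parse_bool(tok: str, line: int) -> bool:
    t = tok.lower()
    if t in ("yes", "true", "1"):
        return True
    if t in ("no", "false", "0"):
        return False
    raise ModelSyntaxError(f"expected yes/no, got {tok!r}", line)


def _parse_term_list(side: str, line: int) -> list[tuple[float, str]]:
    terms = []
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ModelSyntaxError("empty stoichiometric term", line)
        parts = term.split()
        if len(parts) == 1:
            coeff, mid = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coeff = float(parts[0])
            except ValueError:
                raise ModelSyntaxError(f"bad coefficient {parts[0]!r}", line) from None
            mid = parts[1]
        else:
            raise ModelSyntaxError(f"bad stoichiometric term {term!r}", line)
        terms.append((coeff, mid))
    return terms


def _parse_map_side(side: str, line: int) -> tuple[tuple[str, ...], tuple[tuple[str, ...], ...]]:
    mets, labels = [], []
    for term in side.split("+"):
        term = term.strip()
        m = re.fullmatch(r"([A-Za-z0-9_]+)#([A-Za-z]+)", term)
        if not m:
            raise ModelSyntaxError(f"bad atom-map term {term!r} (expected met#letters)", line)
        mets.append(m.group(1))
        labels.append(tuple(m.group(2)))
    return tuple(mets), tuple(labels)


def _parse_atom_maps(text: str, line: int) -> list[AtomMapVariant]:
    variants = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        weight = 1.0
        wm = re.search(r"@([0-9.eE+-]+)\s*$", chunk)
        if wm:
            weight = float(wm.group(1))
            chunk = chunk[: wm.start()].strip()
        if "->" not in chunk:
            raise ModelSyntaxError("atom map needs '->'", line)
        lhs, rhs = chunk.split("->", 1)
        smet, slab = _parse_map_side(lhs, line)
        pmet, plab = _parse_map_side(rhs, line)
        variants.append(AtomMapVariant(weight, smet, slab, pmet, plab))
    total = sum(v.weight for v in variants)
    if abs(total - 1.0) > 1e-9:
        raise ModelSyntaxError(f"atom map variant weights sum to {total}, expected 1", line)
    return variants


def load_network(text: str) -> AtomTransitionNetwork:
    """Parse a model file (see module docstring for the grammar)."""
    metabolites: list[Metabolite] = []
    met_ids: set[str] = set()
    reactions: list[Reaction] = []
    biomass_id: str | None = None
    declared_count: int | None = None
    section = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        sec = _SECTION_RE.match(line.strip())
        if sec:
            section = sec.group(1)
            continue
        cnt = _COUNT_RE.match(line.strip())
        if cnt:
            declared_count = int(cnt.group(1))
            continue
        if line.lstrip().startswith("#"):
            continue
        if section == "METABOLITES":
            parts = line.split()
            if len(parts) != 5:
                raise ModelSyntaxError(
                    f"metabolite line needs 5 fields (id name compartment nC balanced), got {len(parts)}",
                    lineno,
                )
            mid, name, comp, nc, bal = parts
            if mid in met_ids:
                raise ModelSyntaxError(f"duplicate metabolite id {mid!r}", lineno)
            met_ids.add(mid)
            try:
                nc_i = int(nc)
            except ValueError:
                raise ModelSyntaxError(f"bad carbon count {nc!r}", lineno) from None
            try:
                metabolites.append(Metabolite(mid, name, comp, nc_i, _parse_bool(bal, lineno)))
            except NetworkError as e:
                raise ModelSyntaxError(str(e), lineno) from None
        elif section == "REACTIONS":
            if ":" not in line:
                raise ModelSyntaxError("reaction line needs 'id : stoichiometry'", lineno,
                                       column=len(line.split()[0]) + 1 if line.split() else 1)
            rid, rest = line.split(":", 1)
            rid = rid.strip()
            if not re.fullmatch(r"[A-Za-z0-9_]+", rid):
                raise ModelSyntaxError(f"bad reaction id {rid!r}", lineno, column=1)
            fields = [f.strip() for f in rest.split("|")]
            stoich_text = fields[0]
            if "->" not in stoich_text:
                raise ModelSyntaxError("stoichiometry needs '->'", lineno)
            lhs, rhs = stoich_text.split("->", 1)
            stoich: dict[str, float] = {}
            for coeff, mid in _parse_term_list(lhs, lineno):
                stoich[mid] = stoich.get(mid, 0.0) - coeff
            for coeff, mid in _parse_term_list(rhs, lineno):
                stoich[mid] = stoich.get(mid, 0.0) + coeff
            reversible = False
            cofactors: dict[str, float] = {}
            atom_maps: list[AtomMapVariant] = []
            sink = False
            lb = ub = None
            for fld in fields[1:]:
                if not fld:
                    continue
                if fld == "rev":
                    reversible = True
                elif fld == "irr":
                    reversible = False
                elif fld == "sink":
                    sink = True
                elif fld.startswith("cofactors"):
                    for tok in fld[len("cofactors"):].split():
                        if ":" not in tok:
                            raise ModelSyntaxError(f"bad cofactor term {tok!r}", lineno)
                        name, val = tok.split(":", 1)
                        if name not in ("NADH", "NADPH", "FADH2", "ATP"):
                            raise ModelSyntaxError(f"unknown cofactor {name!r}", lineno)
                        cofactors[name] = float(val)
                elif fld.startswith("map"):
                    atom_maps = _parse_atom_maps(fld[len("map"):].strip(), lineno)
                elif fld.startswith("bounds"):
                    toks = fld.split()
                    if len(toks) != 3:
                        raise ModelSyntaxError("bounds needs two numbers", lineno)
                    lb, ub = float(toks[1]), float(toks[2])
                else:
                    raise ModelSyntaxError(f"unknown reaction field {fld!r}", lineno)
            reactions.append(
                Reaction(rid, stoich, reversible, atom_maps, cofactors, lb, ub, sink)
            )
        elif section == "BIOMASS":
            m = re.fullmatch(r"biomass_reaction:\s*([A-Za-z0-9_]+)", line.strip())
            if not m:
                raise ModelSyntaxError("expected 'biomass_reaction: ID'", lineno)
            biomass_id = m.group(1)
        else:
            raise ModelSyntaxError("content outside of any section", lineno)

    try:
        return AtomTransitionNetwork(metabolites, reactions, biomass_id, declared_count)
    except NetworkError:
        raise


def load_network_file(path) -> AtomTransitionNetwork:
    with open(path, encoding="utf-8") as fh:
        return load_network(fh.read())


def serialize_network(net: AtomTransitionNetwork) -> str:
    """Canonical, bit-stable text form; load(serialize(n)) round-trips."""
    out = [f"# reactions: {len(net.reactions)}", "# METABOLITES"]
    for m in net.metabolites.values():
        out.append(
            f"{m.id}\t{m.name}\t{m.compartment}\t{m.carbon_count}\t{'yes' if m.balanced else 'no'}"
        )
    out.append("# REACTIONS")

    def fmt_coeff(c: float) -> str:
        return f"{c:g}"

    for r in net.reactions:
        lhs = " + ".join(
            f"{fmt_coeff(-c)} {m}" for m, c in r.stoichiometry.items() if c < 0
        )
        rhs = " + ".join(
            f"{fmt_coeff(c)} {m}" for m, c in r.stoichiometry.items() if c > 0
        )
        parts = [f"{r.id} : {lhs} -> {rhs}", "rev" if r.reversible else "irr"]
        if r.cofactors:
            parts.append(
                "cofactors " + " ".join(f"{k}:{fmt_coeff(v)}" for k, v in sorted(r.cofactors.items()))
            )
        if r.atom_maps:
            chunks = []
            for v in r.atom_maps:
                lhs_m = " + ".join(
                    f"{m}#{''.join(lab)}" for m, lab in zip(v.substrates, v.substrate_labels)
                )
                rhs_m = " + ".join(
                    f"{m}#{''.join(lab)}" for m, lab in zip(v.products, v.product_labels)
                )
                chunk = f"{lhs_m} -> {rhs_m}"
                if len(r.atom_maps) > 1 or v.weight != 1.0:
                    chunk += f" @{v.weight:g}"
                chunks.append(chunk)
            parts.append("map " + " ; ".join(chunks))
        if r.lower_bound is not None or r.upper_bound is not None:
            lb, ub = r.bounds()
            parts.append(f"bounds {lb:g} {ub:g}")
        if r.sink:
            parts.append("sink")
        out.append(" | ".join(parts))
    if net.biomass_reaction_id:
        out.append("# BIOMASS")
        out.append(f"biomass_reaction: {net.biomass_reaction_id}")
    return "\n".join(out) + "\n"


def stoichiometric_matrix(net: AtomTransitionNetwork) -> np.ndarray:
    return net.stoichiometric_matrix()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate(net: AtomTransitionNetwork) -> ValidationReport:
    """Audit carbon balance, atom-map completeness and pool connectivity."""
    findings: list[ValidationFinding] = []
    rxn_status: dict[str, dict[str, str]] = {}
    for r in net.reactions:
        status = {}
        carbon = sum(
            coeff * net.metabolites[mid].carbon_count for mid, coeff in r.stoichiometry.items()
        )
        if r.sink:
            status["carbon_balance"] = "exempt (sink)"
        elif abs(carbon) > 1e-9:
            status["carbon_balance"] = f"off by {carbon:g}"
            findings.append(
                ValidationFinding("carbon-balance", r.id, f"net carbon {carbon:g} != 0")
            )
        else:
            status["carbon_balance"] = "ok"
        if r.atom_maps:
            try:
                for v in r.atom_maps:
                    net._check_atom_map(r, v)
                status["atom_map"] = "complete"
            except NetworkError as e:
                status["atom_map"] = "invalid"
                findings.append(ValidationFinding("atom-map", r.id, str(e)))
        else:
            carbons = any(
                net.metabolites[mid].carbon_count > 0 for mid in r.stoichiometry
            )
            status["atom_map"] = "absent" if carbons and not r.sink else "n/a"
            if carbons and not r.sink:
                findings.append(
                    ValidationFinding("atom-map", r.id, "carbon-carrying reaction lacks atom map")
                )
        rxn_status[r.id] = status

    met_status: dict[str, dict[str, int]] = {}
    for m in net.metabolites.values():
        produced = sum(
            1
            for r in net.reactions
            if r.stoichiometry.get(m.id, 0) > 0 or (r.reversible and r.stoichiometry.get(m.id, 0) < 0)
        )
        consumed = sum(
            1
            for r in net.reactions
            if r.stoichiometry.get(m.id, 0) < 0 or (r.reversible and r.stoichiometry.get(m.id, 0) > 0)
        )
        met_status[m.id] = {"producers": produced, "consumers": consumed}
        if m.balanced and (produced == 0 or consumed == 0):
            findings.append(
                ValidationFinding(
                    "connectivity",
                    m.id,
                    f"balanced metabolite has {produced} producer(s) and {consumed} consumer(s)",
                )
            )
    return ValidationReport(not findings, findings, rxn_status, met_status)


# ---------------------------------------------------------------------------
# 3HP pathway extension
# ---------------------------------------------------------------------------

def add_3hp_pathway(net: AtomTransitionNetwork) -> AtomTransitionNetwork:
    """Return a copy of *net* extended with the malonyl-CoA route to 3HP.

    Adds acetyl-CoA carboxylase (ACC: accoa + CO2 + ATP -> malonyl-CoA, the
    carboxyl carbon coming from the CO2 pool), the bifunctional malonyl-CoA
    reductase (MCR: malonyl-CoA -> 3HP consuming two NADPH) and 3HP export.
    Raises if the pathway is already present or precursors are missing.
    """
    for rid in ("ACC", "MCR", "HPX"):
        if net.has_reaction(rid):
            raise NetworkError(f"3HP pathway already present (reaction {rid!r} exists)")
    for mid in ("accoa", "co2"):
        if mid not in net.metabolites:
            raise NetworkError(f"cannot add 3HP pathway: missing precursor {mid!r}")

    new = net.copy()
    mets = list(new.metabolites.values())
    existing = set(new.metabolites)
    for m in (
        Metabolite("malcoa", "malonyl-CoA", "cytosol", 3, True),
        Metabolite("3hp", "3-hydroxypropionate", "cytosol", 3, True),
        Metabolite("3hp_ext", "3-hydroxypropionate-extracellular", "extracellular", 3, False),
    ):
        if m.id in existing:
            raise NetworkError(f"3HP pathway already present (metabolite {m.id!r} exists)")
        mets.append(m)
    rxns = list(new.reactions)
    rxns.append(
        Reaction(
            "ACC",
            {"accoa": -1, "co2": -1, "malcoa": 1},
            cofactors={"ATP": -1},
            atom_maps=[
                AtomMapVariant(1.0, ("accoa", "co2"), (("a", "b"), ("c",)), ("malcoa",), (("a", "b", "c"),))
            ],
        )
    )
    rxns.append(
        Reaction(
            "MCR",
            {"malcoa": -1, "3hp": 1},
            cofactors={"NADPH": -2},
            atom_maps=[AtomMapVariant(1.0, ("malcoa",), (("a", "b", "c"),), ("3hp",), (("a", "b", "c"),))],
        )
    )
    rxns.append(
        Reaction(
            "HPX",
            {"3hp": -1, "3hp_ext": 1},
            atom_maps=[AtomMapVariant(1.0, ("3hp",), (("a", "b", "c"),), ("3hp_ext",), (("a", "b", "c"),))],
        )
    )
    return AtomTransitionNetwork(mets, rxns, new.biomass_reaction_id, None)


# ---------------------------------------------------------------------------
# bundled model
# ---------------------------------------------------------------------------

def bundled_model_path() -> str:
    from importlib.resources import files

    return str(files("flux13c").joinpath("data/yeast_cc.txt"))


def load_yeast_network(with_3hp: bool = False) -> AtomTransitionNetwork:
    """Load the bundled yeast central-carbon model, optionally 3HP-extended."""
    net = load_network_file(bundled_model_path())
    if with_3hp:
        net = add_3hp_pathway(net)
    return net
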