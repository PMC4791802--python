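"""End-to-end orchestration: measurements -> ratios -> net fluxes -> pFBA.

A run is described by a YAML config (:class:`RunConfig`).  In synthetic
mode the measurement tables are generated from a true flux vector (a named
bundled strain or a flux TSV); in measured mode they are read from disk.
Every stage writes a plain-text artifact with a header naming the stage and
the config hash, and a JSON manifest records seeds and checksums, so a
rerun with the same config reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import network as nw
from . import synthetic as sy
from .gsm import BoundMapping, apply_13c_bounds, default_bound_mapping, load_sbml, pfba, toy_yeast_gsm
from .labeling import DEFAULT_NOISE_SD, MeasurementSet, make_tracer
from .netflux import (
    ExtracellularRates,
    FluxDistribution,
    compare_strains,
    monte_carlo_ci,
    normalize,
)
from .ratios import FluxRatioSet, RatioEstimate, TrioseProbe, compute_ratios, triose_intact_fraction

log = logging.getLogger("flux13c")

__all__ = ["RunConfig", "run", "make_demo_configs", "run_demo"]


@dataclass
class RunConfig:
    """Declarative description of one analysis run."""

    outdir: str
    mode: str = "synthetic"                 # "synthetic" | "measured"
    model: str = "bundled"                  # path or "bundled"
    add_3hp: bool = False
    tracers: tuple[str, ...] = ("1-13C", "20pct-U13C")
    truth: str | None = None                # strain name or flux TSV (synthetic)
    measurements: tuple[str, ...] = ()      # measurement TSVs (measured)
    rates: str | None = None                # rates file; None = derive from truth
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    mc_draws: int = 100
    mu: float = 0.04
    compare_to: str | None = None           # normalized flux TSV of a reference run
    sbml: Mapping[str, Any] | None = None   # {model, mapping, uptake_scale, relax, objective}

    def __post_init__(self):
        if self.mode not in ("synthetic", "measured"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and not self.truth:
            raise ValueError("synthetic mode requires a true flux vector ('truth')")
        if self.mode == "measured" and not self.measurements:
            raise ValueError("measured mode requires measurement tables")
        if self.mode == "measured" and not self.rates:
            raise ValueError("measured mode requires a rates file")
        self.tracers = tuple(self.tracers)
        self.measurements = tuple(self.measurements)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "mode": self.mode,
            "model": self.model,
            "add_3hp": self.add_3hp,
            "tracers": list(self.tracers),
            "truth": self.truth,
            "measurements": list(self.measurements),
            "rates": self.rates,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "mc_draws": self.mc_draws,
            "mu": self.mu,
            "compare_to": self.compare_to,
            "sbml": dict(self.sbml) if self.sbml else None,
        }

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (the output location is
        excluded so identical analyses hash identically wherever written)."""
        data = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write(path: Path, stage: str, cfg_hash: str, body: str) -> str:
    text = f"# flux13c stage: {stage}\n# config: {cfg_hash}\n" + body
    path.write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _read_rates_file(path) -> ExtracellularRates:
    """Key-value rates file: ``species  value  sd  unit`` per line."""
    growth = None
    rates = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        species, value, sd = parts[0], float(parts[1]), float(parts[2])
        if species == "growth":
            growth = (value, sd)
        else:
            rates[species] = (value, sd)
    if growth is None:
        raise ValueError(f"rates file {path} lacks a 'growth' line")
    return ExtracellularRates(growth, rates)


def _rates_to_text(rates: ExtracellularRates) -> str:
    lines = ["# species  value  sd  unit"]
    lines.append(f"growth  {rates.growth_rate[0]:.6f}  {rates.growth_rate[1]:.6f}  1/h")
    for sp, (val, sd) in rates.rates.items():
        lines.append(f"{sp}  {val:.6f}  {sd:.6f}  mmol/gDW/h")
    return "\n".join(lines) + "\n"


def _ratio_report(ratios: FluxRatioSet, probe: TrioseProbe | None) -> str:
    body = ratios.to_tsv()
    if probe is not None:
        body += (
            f"triose_intact_fraction\t{probe.value:.4f}\t{probe.sd:.4f}\t"
            f"{max(0, probe.value - probe.sd):.4f}\t{min(1, probe.value + probe.sd):.4f}\t"
            f"1-13C\taux\n"
        )
    return body


def read_ratio_report(path) -> tuple[FluxRatioSet, TrioseProbe | None]:
    """Parse a ratio report TSV back into a ratio set and optional probe."""
    estimates: dict[str, RatioEstimate] = {}
    probe = None
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("ratio\t"):
            continue
        name, value, sd, lb, ub, tracers, status = line.split("\t")
        value_f = float(value) if value else None
        sd_f = float(sd) if sd else None
        tr = tuple(t for t in tracers.split("+") if t and t != "-")
        if status == "aux":
            probe = TrioseProbe(value_f, sd_f)
            continue
        estimates[name] = RatioEstimate(
            name, value_f, sd_f, float(lb), float(ub), tr, status
        )
    return FluxRatioSet(estimates), probe


def _load_truth(config: RunConfig, net) -> dict[str, float]:
    if config.truth in ("reference", "producer"):
        spec = sy.REFERENCE_STRAIN if config.truth == "reference" else sy.PRODUCER_STRAIN
        return sy.build_strain_fluxes(net, spec)
    fd = FluxDistribution.from_tsv(Path(config.truth).read_text())
    return fd.values


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    checksums: dict[str, str] = {}
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "artifacts": checksums,
    }

    net = nw.load_network_file(
        nw.bundled_model_path() if config.model == "bundled" else config.model
    )
    if config.add_3hp:
        net = nw.add_3hp_pathway(net)
    report = nw.validate(net)
    if not report.ok:
        raise RuntimeError(f"model failed validation:\n{report}")

    # --- stage: measurements -------------------------------------------
    t0 = time.time()
    msets: list[MeasurementSet] = []
    truth = None
    if config.mode == "synthetic":
        truth = _load_truth(config, net)
        for k, tracer_name in enumerate(config.tracers):
            tracer = make_tracer(tracer_name)
            ms = sy.generate_measurements(
                net, truth, tracer, seed=config.seed + 1000 * (k + 1), sd=config.noise_sd
            )
            msets.append(ms)
    else:
        for path in config.measurements:
            msets.append(MeasurementSet.from_tsv(Path(path).read_text()))
    for ms in msets:
        fn = outdir / f"measurements_{ms.tracer_id}.tsv"
        checksums[fn.name] = _write(fn, "measurements", cfg_hash, ms.to_tsv())
    log.info("stage measurements: %d tracer set(s) in %.2fs", len(msets), time.time() - t0)

    # --- stage: rates ----------------------------------------------------
    if config.rates:
        rates = _read_rates_file(config.rates)
    else:
        rates = sy.rates_from_fluxes(net, truth, config.mu, seed=config.seed + 77)
    fn = outdir / "rates.txt"
    checksums[fn.name] = _write(fn, "rates", cfg_hash, _rates_to_text(rates))

    # --- stage: ratios ---------------------------------------------------
    t0 = time.time()
    ratios = compute_ratios(msets, net)
    probe = triose_intact_fraction(msets, ratios)
    fn = outdir / "ratios.tsv"
    checksums[fn.name] = _write(fn, "ratios", cfg_hash, _ratio_report(ratios, probe))
    log.info("stage ratios: %d quantities in %.2fs", ratios.n_quantities, time.time() - t0)

    # --- stage: netflux --------------------------------------------------
    t0 = time.time()
    fluxes = monte_carlo_ci(
        net, rates, ratios, n_draws=config.mc_draws, seed=config.seed + 101,
        triose_probe=probe,
    )
    fn = outdir / "fluxes.tsv"
    checksums[fn.name] = _write(fn, "netflux", cfg_hash, fluxes.to_tsv())
    fluxes_norm = normalize(fluxes)
    fn = outdir / "fluxes_normalized.tsv"
    checksums[fn.name] = _write(fn, "netflux", cfg_hash, fluxes_norm.to_tsv())
    log.info("stage netflux: dof=%s residual=%.3g in %.2fs",
             fluxes.dof, fluxes.residual, time.time() - t0)

    # --- stage: compare --------------------------------------------------
    if config.compare_to:
        ref = FluxDistribution.from_tsv(Path(config.compare_to).read_text())
        changes = compare_strains(ref, fluxes_norm)
        body = "group\tpercent_change\n" + "".join(
            f"{g}\t{c:+.2f}\n" for g, c in changes.items()
        )
        fn = outdir / "comparison.tsv"
        checksums[fn.name] = _write(fn, "compare", cfg_hash, body)
        manifest["comparison"] = changes
        log.info("stage compare: %s", changes)

    # --- stage: pFBA (optional) -----------------------------------------
    if config.sbml:
        t0 = time.time()
        scfg = dict(config.sbml)
        model_spec = scfg.get("model", "toy")
        model = toy_yeast_gsm() if model_spec == "toy" else load_sbml(
            model_spec, scfg.get("objective")
        )
        mapping_spec = scfg.get("mapping", "default")
        mapping = (
            default_bound_mapping()
            if mapping_spec == "default"
            else BoundMapping.from_tsv(Path(mapping_spec).read_text())
        )
        scale = scfg.get("uptake_scale", "measured")
        if scale == "measured":
            scale = rates.rates["glucose"][0]
        bounded = apply_13c_bounds(
            model, fluxes_norm, mapping, uptake_scale=float(scale),
            relax=float(scfg.get("relax", 0.05)),
        )
        res = pfba(bounded)
        fn = outdir / "pfba.tsv"
        checksums[fn.name] = _write(fn, "pfba", cfg_hash, res.fluxes.to_tsv())
        manifest["pfba"] = {
            "objective_value": res.objective_value,
            "total_flux": res.total_flux,
        }
        log.info("stage pfba: objective %.4f, total flux %.3f in %.2fs",
                 res.objective_value, res.total_flux, time.time() - t0)

    manifest["seed"] = config.seed
    from importlib.metadata import version

    try:
        manifest["version"] = version("flux13c")
    except Exception:  # pragma: no cover - not installed
        manifest["version"] = "unknown"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("run complete in %.2fs -> %s", time.time() - t_start, outdir)
    return manifest


# ---------------------------------------------------------------------------
# demo configs: the two-strain chemostat comparison
# ---------------------------------------------------------------------------

def make_demo_configs(outdir, seed: int = 1) -> tuple[Path, Path]:
    """Write reference/producer configs plus their true-flux tables.

    The two truths mirror a glucose-limited chemostat comparison at
    D = 0.04 1/h: the producer carries flux through the malonyl-CoA
    reductase pathway and elevated PP-pathway and TCA flux; the reference
    does not.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for strain, add_3hp in ((sy.REFERENCE_STRAIN, False), (sy.PRODUCER_STRAIN, True)):
        net = nw.load_yeast_network(with_3hp=add_3hp)
        truth = sy.build_strain_fluxes(net, strain)
        truth_path = outdir / f"truth_{strain.name}.tsv"
        truth_path.write_text(FluxDistribution(truth).to_tsv())
        cfg = {
            "outdir": str(outdir / strain.name),
            "mode": "synthetic",
            "model": "bundled",
            "add_3hp": add_3hp,
            "tracers": ["1-13C", "20pct-U13C"],
            "truth": str(truth_path),
            "noise_sd": DEFAULT_NOISE_SD,
            "seed": seed if strain.name == "reference" else seed + 500,
            "mc_draws": 100,
            "mu": strain.mu,
        }
        if strain.name == "producer":
            cfg["compare_to"] = str(outdir / "reference" / "fluxes_normalized.tsv")
            cfg["sbml"] = {"model": "toy", "mapping": "default", "uptake_scale": "measured"}
        cfg_path = outdir / f"{strain.name}.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        paths.append(cfg_path)
    return tuple(paths)


def run_demo(outdir, seed: int = 1) -> dict:
    """Generate the demo configs and execute both runs; returns the
    producer manifest (which includes the strain comparison)."""
    ref_cfg, prod_cfg = make_demo_configs(outdir, seed=seed)
    run(RunConfig.from_yaml(ref_cfg))
    return run(RunConfig.from_yaml(prod_cfg))
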