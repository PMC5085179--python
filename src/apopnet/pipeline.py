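"""End-to-end orchestration: dose response → sensitivity → HD → feedback scan.

``run_full_analysis`` wires the modules together under a single validated
configuration, writes every intermediate table as CSV, and leaves a
machine-readable ``summary.json`` (config hash, seed, package version, stage
results, per-stage failures) in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dose_response import find_critical_dose, scan_doses
from .feedback import (
    FeedbackSpec,
    calibrate_range,
    default_strength_grid,
    hd_strength_scan,
)
from .model_io import load_network_tsv, load_sbml, load_toy, ModelManifest
from .network import ReactionNetwork
from .sensitivity import SensitivityConfig, build_spectrum
from .spectra import (
    MUTATION_TYPES,
    binarize,
    combine,
    hamming,
    parse_mutation_table,
    project_to_parameters,
    read_gene_parameter_map,
)

logger = logging.getLogger("apopnet")

__all__ = ["RunConfig", "run_full_analysis", "load_model"]


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    model_source: str = "builtin-toy"  # 'builtin-toy', or a path to .xml / TSV dir
    key_species_map: dict[str, str] = field(default_factory=dict)
    dose_max: float = 1e-2
    tol: float | None = None
    perturb_fraction: float = 0.20
    sensitive_cutoff: float = 0.10
    mutation_table: str | None = None  # TSV path; None -> synthetic, concordance 0.9
    cancer_type: str = "synthetic"
    combine_rule: str = "three_at_least_2"
    gene_parameter_map: str | None = None
    feedback_source: str = "caspase3_active"
    feedback_sign: str = "negative"
    feedback_points_per_decade: int = 3
    run_feedback_scan: bool = True
    out_dir: str = "apopnet_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_model(config: RunConfig):
    """Resolve the configured model source to (network, manifest, toy-or-None)."""
    if config.model_source == "builtin-toy":
        from .synthetic import ToyModelConfig, make_toy_network

        toy = make_toy_network(ToyModelConfig(seed=config.seed or None))
        net, manifest = load_toy(toy.config)
        return net, manifest, toy
    path = Path(config.model_source)
    if path.is_dir():
        net = load_network_tsv(path)
        manifest = ModelManifest(source="sbml-file", species_count=len(net.species),
                                 reaction_count=len(net.reactions),
                                 parameter_count=len(net.parameters),
                                 key_species_map=dict(config.key_species_map))
        manifest.validate_against(net)
        return net, manifest, None
    net, manifest = load_sbml(path, key_species_map=config.key_species_map)
    return net, manifest, None


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return (and persist) the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    cfg_hash = config.content_hash()
    summary: dict = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "apopnet_version": __version__,
        "stages": {},
        "failures": {},
    }
    (out / f"config_{cfg_hash}.json").write_text(json.dumps(asdict(config), indent=2))

    net, manifest, toy = load_model(config)
    executioner = manifest.key_species_map["caspase3_active"]
    sens_cfg = SensitivityConfig(
        perturb_fraction=config.perturb_fraction,
        sensitive_cutoff=config.sensitive_cutoff,
        dose_max=config.dose_max, tol=config.tol, executioner_id=executioner,
    )

    t0 = time.time()
    grid = np.concatenate([[0.0], np.geomspace(config.dose_max / 300, config.dose_max, 25)])
    curve = scan_doses(net, grid, executioner)
    curve.to_frame().assign(config_hash=cfg_hash).to_csv(
        out / f"dose_response_{cfg_hash}.csv", index=False)
    cd = find_critical_dose(net, executioner, dose_max=config.dose_max, tol=config.tol)
    summary["stages"]["dose_response"] = {
        "critical_dose_amol": cd.cd,
        "apoptosis_achievable": cd.apoptosis_achievable,
        "low_plateau": cd.low_plateau, "high_plateau": cd.high_plateau,
        "seconds": round(time.time() - t0, 2),
    }
    logger.info("critical dose: %s amol", cd.cd)

    t0 = time.time()
    spectrum = build_spectrum(net, config=sens_cfg)
    spectrum.to_frame().assign(config_hash=cfg_hash).to_csv(
        out / f"sensitivity_spectrum_{cfg_hash}.csv", index=False)
    summary["stages"]["sensitivity"] = {
        "n_parameters": len(spectrum.parameter_ids),
        "n_sensitive": int(spectrum.flags.sum()),
        "errors": {r.parameter_id: r.error for r in spectrum.records if r.error},
        "seconds": round(time.time() - t0, 2),
    }

    # ---- mutation spectra and HD
    t0 = time.time()
    if config.mutation_table is not None:
        table = parse_mutation_table(config.mutation_table, config.cancer_type)
        if config.gene_parameter_map is None:
            raise ValueError("a gene_parameter_map is required with a mutation_table")
        gmap = read_gene_parameter_map(config.gene_parameter_map)
    elif toy is not None:
        from .synthetic import (
            SyntheticSpectrumConfig,
            make_synthetic_mutations,
            toy_gene_parameter_map,
        )

        base_map = toy_gene_parameter_map()
        mapped = [p for p in net.parameter_ids if p not in base_map.excluded]
        table, gmap = make_synthetic_mutations(
            spectrum.as_boolean_spectrum().restrict(mapped),
            SyntheticSpectrumConfig(concordance=0.9, seed=config.seed,
                                    excluded_parameter_ids=tuple(base_map.excluded)),
        )
    else:
        raise ValueError("no mutation_table configured for an external model")

    sens_bool = spectrum.as_boolean_spectrum()
    hd_rows = {}
    for mt in MUTATION_TYPES:
        proj = project_to_parameters(binarize(table, mt), gmap, net.parameter_ids)
        hd_rows[mt] = hamming(sens_bool.restrict(proj.ids), proj).hd
    for rule in ("two_of:missense,nonsense", "three_at_least_2", "three_at_least_1"):
        proj = project_to_parameters(combine(table, rule), gmap, net.parameter_ids)
        hd_rows[rule] = hamming(sens_bool.restrict(proj.ids), proj).hd
    summary["stages"]["hamming"] = {
        "cancer_type": table.cancer_type, "n_compared": len(proj.ids),
        "hd": hd_rows, "seconds": round(time.time() - t0, 2),
    }
    import pandas as pd

    pd.Series(hd_rows, name="hd").rename_axis("spectrum").to_csv(
        out / f"hd_table_{cfg_hash}.csv")

    # ---- feedback calibration + HD-vs-strength scan
    if config.run_feedback_scan:
        t0 = time.time()
        try:
            tmpl = FeedbackSpec(source_role=config.feedback_source,
                                sign=config.feedback_sign, strength=0.0)
            thr = 0.5 * (cd.low_plateau + cd.high_plateau)
            cal_grid = default_strength_grid(-4, 2, config.feedback_points_per_decade)
            rng = calibrate_range(net, tmpl, manifest.key_species_map, executioner,
                                  thr, cal_grid, probe_dose=config.dose_max)
            mut_rule = combine(table, config.combine_rule)
            proj = project_to_parameters(mut_rule, gmap, net.parameter_ids)
            if rng.hi > rng.lo > 0:
                n_pts = max(
                    2, int(np.ceil(np.log10(rng.hi / rng.lo)
                                   * config.feedback_points_per_decade)) + 1)
                strengths = np.geomspace(rng.lo, rng.hi, n_pts)
            else:
                strengths = np.array([0.0])
            scan = hd_strength_scan(net, tmpl, strengths, proj,
                                    manifest.key_species_map, sens_cfg)
            scan.to_frame().assign(config_hash=cfg_hash).to_csv(
                out / f"feedback_hd_scan_{cfg_hash}.csv", index=False)
            summary["stages"]["feedback"] = {
                "sign": config.feedback_sign, "source": config.feedback_source,
                "strength_range": [rng.lo, rng.hi], "metric": rng.metric,
                "baseline_hd": scan.baseline_hd,
                "min_hd": int(scan.hd_values[scan.hd_values >= 0].min()),
                "min_hd_strength": scan.min_hd_strength,
                "errors": scan.errors, "seconds": round(time.time() - t0, 2),
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            summary["failures"]["feedback"] = f"{type(exc).__name__}: {exc}"

    (out / f"summary_{cfg_hash}.json").write_text(json.dumps(summary, indent=2))
    return summary
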