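"""Configuration-driven orchestration of the two analysis tracks.

``run_binding_pipeline`` composes the synthetic particle field, the
projection measurements and the occlusion correction into a reproducible
artifact set (observations CSV, binned/corrected series CSV, summary JSON).

``run_vesicle_pipeline`` builds, relaxes and analyses a series of CG
vesicles (PDBs, relaxation reports, SASA series, curvature-trend JSON).

Every stochastic stage receives an explicit seed derived from the run seed
via ``numpy.random.SeedSequence``; identical configs produce identical
outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .field import (
    NoiseModel,
    ParticleClassSpec,
    PRESET_CLASSES,
    project_particle,
    sample_population,
    write_observations,
)
from .occlusion import VisibilityModel, correct_binned_counts, correction_table
from .relax import ForceField, RelaxConfig, minimize
from .sasa import SASAConfig, average_fraction, curvature_trend
from .stats import (
    MeasurementRecord,
    aspect_ratio,
    binding_fraction_summary,
    build_histogram,
    fit_polynomial,
    geometric_mean_diameter,
    mean_count_by_diameter,
)
from .vesicle import build_vesicle, write_pdb

log = logging.getLogger("lipocurv")

__all__ = ["RunConfig", "load_config", "run_binding_pipeline", "run_vesicle_pipeline"]


_DEFAULTS: dict = {
    "track": "binding",
    "seed": 0,
    "outdir": "lipocurv_out",
    "binding": {
        "class_preset": "liposome",
        "class_spec": None,  # full ParticleClassSpec dict overrides the preset
        "n_particles": 10000,
        "noise": {"cv": 0.05, "ar_mean": 1.1, "ar_sd": 0.08},
        "bin_step": 2.17,
        "bin_origin": 0.0,
        "correction_length": None,  # None -> class protrusion mean
        "p_floor": 0.05,
        "min_visible_length": 0.0,
        "fit_degree": 6,
    },
    "vesicle": {
        "diameters_nm": [12.0],
        "area_per_lipid": 65.0,
        "thickness": 36.8,
        "pore_fraction": 0.13,
        "forcefield": {},  # ForceField field overrides
        "relax": {},  # RelaxConfig field overrides
        "sasa": {"probe_radius": 2.35, "n_sphere_points": 960, "surface": "all"},
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Resolved, validated run configuration."""

    data: dict

    @property
    def track(self) -> str:
        return self.data["track"]

    @property
    def seed(self) -> int:
        return self.data["seed"]

    @property
    def outdir(self) -> Path:
        return Path(self.data["outdir"])

    def hash(self) -> str:
        payload = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self.data == other.data


def _merge_defaults(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict) and defaults[key] and not key.endswith(("forcefield", "relax", "class_spec")):
            if not isinstance(val, dict):
                raise ValueError(f"config key {here!r} must be a mapping")
            out[key] = _merge_defaults(defaults[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def resolve_config(user: dict) -> RunConfig:
    """Fill defaults and validate a raw config mapping."""
    data = _merge_defaults(_DEFAULTS, user)
    if data["track"] not in ("binding", "vesicle"):
        raise ValueError(f"track must be 'binding' or 'vesicle', got {data['track']!r}")
    if not isinstance(data["seed"], int):
        raise ValueError("seed must be an integer")
    return RunConfig(data=data)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run config, fill defaults, reject unknown keys.

    The resolved config is echoed to the module logger.
    """
    import yaml

    path = Path(path)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = resolve_config(user)
    log.info("resolved config (hash %s): %s", cfg.hash(), json.dumps(cfg.data, sort_keys=True))
    return cfg


def _particle_spec(bcfg: dict) -> ParticleClassSpec:
    if bcfg["class_spec"]:
        d = bcfg["class_spec"]
        return ParticleClassSpec(
            label=d["label"],
            diameter_law=tuple(d["diameter_law"]),
            diameter_bounds=tuple(d["diameter_bounds"]),
            protrusion_length_law=tuple(d.get("protrusion_length_law", (8.5, 0.6))),
            beta0=d.get("beta0", 8.4),
            beta1=d.get("beta1", 0.2),
        )
    return PRESET_CLASSES[bcfg["class_preset"]]


def _prepare_outdir(cfg: RunConfig) -> Path:
    outdir = cfg.outdir
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise OSError(f"output directory {outdir} is not writable: {e}") from e
    return outdir


def _write_manifest(outdir: Path, cfg: RunConfig, stages: dict) -> None:
    from . import __version__

    manifest = {
        "package": "lipocurv",
        "version": __version__,
        "config": cfg.data,
        "config_hash": cfg.hash(),
        "stage_seconds": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_binding_pipeline(cfg: RunConfig) -> dict:
    """Synthetic field → projection measurements → occlusion correction.

    Writes ``observations.csv``, ``diameter_histogram.csv``,
    ``corrected_series.csv``, ``summary.json`` and ``manifest.json`` into the
    configured output directory and returns the artifact paths plus the key
    in-memory results.
    """
    if cfg.track != "binding":
        raise ValueError("config track is not 'binding'")
    outdir = _prepare_outdir(cfg)
    bcfg = cfg.data["binding"]
    spec = _particle_spec(bcfg)
    stages: dict = {}

    t0 = time.perf_counter()
    ss = np.random.SeedSequence(cfg.seed)
    s_pop, s_view, s_noise = ss.spawn(3)
    particles = sample_population(spec, bcfg["n_particles"], seed=s_pop)
    stages["sample"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    nz = bcfg["noise"]
    noise = NoiseModel(cv=nz["cv"], ar_mean=nz["ar_mean"], ar_sd=nz["ar_sd"])
    rng_view = np.random.default_rng(s_view)
    axes = rng_view.normal(size=(len(particles), 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    noise_seeds = s_noise.spawn(len(particles))
    obs = [
        project_particle(p, axes[i], noise=noise, seed=noise_seeds[i],
                         min_visible_length=bcfg["min_visible_length"])
        for i, p in enumerate(particles)
    ]
    write_observations(obs, outdir / "observations.csv")
    stages["project"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    records = [
        MeasurementRecord(
            diameter=geometric_mean_diameter(o.d_long, o.d_perp),
            shape=aspect_ratio(o.d_long, o.d_perp),
            n_visible=o.n_visible,
        )
        for o in obs
    ]
    step, origin = bcfg["bin_step"], bcfg["bin_origin"]
    hist = build_histogram([r.diameter for r in records], step, origin)
    observed = mean_count_by_diameter(records, step, origin)
    l_corr = bcfg["correction_length"] or spec.protrusion_length_law[0]
    model = VisibilityModel(l=l_corr, min_visible_length=bcfg["min_visible_length"])
    corrected = correct_binned_counts(observed, model, p_floor=bcfg["p_floor"])

    import pandas as pd

    pd.DataFrame(
        {"bin_center_nm": hist.bin_centers, "count": hist.n_per_bin}
    ).to_csv(outdir / "diameter_histogram.csv", index=False)
    correction_table(observed, corrected, model).to_csv(
        outdir / "corrected_series.csv", index=False
    )

    fractions = binding_fraction_summary(records)
    try:
        fit = fit_polynomial(corrected, bcfg["fit_degree"])
        fit_json = {
            "degree": fit.degree,
            "coefficients": fit.coefficients.tolist(),
            "domain": list(fit.domain),
            "residual_norm": fit.residual_norm,
        }
    except ValueError as e:  # too few occupied bins (tiny runs)
        fit_json = {"error": str(e)}
    summary = {
        "n_particles": len(particles),
        "class_label": spec.label,
        "correction_length_nm": l_corr,
        "binding_fractions": {
            str(k): (None if np.isnan(v) else float(v))
            for k, v in fractions["fraction"].items()
        },
        "mean_diameter_nm": float(np.mean([r.diameter for r in records])),
        "corrected_fit": fit_json,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    stages["analyze"] = time.perf_counter() - t0
    _write_manifest(outdir, cfg, stages)
    return {
        "outdir": outdir,
        "observations": obs,
        "records": records,
        "histogram": hist,
        "observed_series": observed,
        "corrected_series": corrected,
        "summary": summary,
    }


def run_vesicle_pipeline(cfg: RunConfig) -> dict:
    """Build → relax → SASA for a series of vesicle diameters, then the
    curvature–hydrophobicity trend.

    Per-diameter artifacts: ``vesicle_<D>nm.pdb`` (relaxed),
    ``relax_<D>nm.json`` (report incl. energy trace length, pore and
    sphericity diagnostics).  Series artifacts: ``sasa_series.csv`` and
    ``trend.json``.  A relaxation failure for one diameter is recorded and
    the pipeline continues.
    """
    if cfg.track != "vesicle":
        raise ValueError("config track is not 'vesicle'")
    outdir = _prepare_outdir(cfg)
    vcfg = cfg.data["vesicle"]
    ff = ForceField(**vcfg["forcefield"])
    scfg = SASAConfig(**vcfg["sasa"])
    stages: dict = {}
    rows = []
    failures = {}
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(len(vcfg["diameters_nm"]))
    for D, seed_d in zip(vcfg["diameters_nm"], seeds):
        t0 = time.perf_counter()
        tag = f"{D:g}nm"
        try:
            v0 = build_vesicle(
                D,
                area_per_lipid=vcfg["area_per_lipid"],
                thickness=vcfg["thickness"],
                pore_fraction=vcfg["pore_fraction"],
                seed=int(seed_d % (2**31)),
            )
            rcfg = RelaxConfig(**{"seed": int(seed_d % (2**31)), **vcfg["relax"]})
            relaxed, report = minimize(v0, ff, rcfg)
            write_pdb(relaxed, outdir / f"vesicle_{tag}.pdb")
            mean_frac, sd_frac = average_fraction(report.snapshots, scfg)
            rows.append(
                {
                    "diameter_nm": report.final_diameter_nm,
                    "initial_diameter_nm": D,
                    "fraction_pct": mean_frac,
                    "sd": sd_frac,
                    "pore_closed": report.pore_closed,
                    "sphericity": report.rdf_sphericity,
                }
            )
            (outdir / f"relax_{tag}.json").write_text(
                json.dumps(
                    {
                        "initial_diameter_nm": D,
                        "final_diameter_nm": report.final_diameter_nm,
                        "n_steps": report.n_steps,
                        "converged": report.converged,
                        "termination": report.termination,
                        "energy_initial": float(report.energy_trace[0]),
                        "energy_final": float(report.energy_trace[-1]),
                        "pore_closed": bool(report.pore_closed),
                        "rdf_sphericity": report.rdf_sphericity,
                        "hydrophobic_fraction_pct": mean_frac,
                        "hydrophobic_fraction_sd": sd_frac,
                    },
                    indent=2,
                )
            )
            np.savetxt(
                outdir / f"energy_{tag}.csv",
                report.energy_trace,
                header="energy",
                comments="",
            )
        except Exception as e:  # record and continue with the next diameter
            log.error("diameter %s failed: %s", D, e)
            failures[tag] = str(e)
        stages[tag] = time.perf_counter() - t0

    import pandas as pd

    series = pd.DataFrame(rows)
    series.to_csv(outdir / "sasa_series.csv", index=False)
    trend = None
    if len(rows) >= 3:
        trend = curvature_trend(series["diameter_nm"], series["fraction_pct"])
        (outdir / "trend.json").write_text(
            json.dumps(
                {
                    "vs_diameter": vars(trend["vs_diameter"]),
                    "vs_reciprocal": vars(trend["vs_reciprocal"]),
                    "monotone_decreasing": trend["monotone_decreasing"],
                },
                indent=2,
            )
        )
    if failures:
        (outdir / "failures.json").write_text(json.dumps(failures, indent=2))
    _write_manifest(outdir, cfg, stages)
    return {"outdir": outdir, "series": series, "trend": trend, "failures": failures}
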