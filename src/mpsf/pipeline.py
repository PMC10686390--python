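"""End-to-end pipeline: simulate -> register -> extract -> fit -> report.

The pipeline consumes a configuration (YAML or JSON; every default is
printed by :func:`reference_config`) and a master seed, and produces the
stage artifacts under an output directory: en-face lesion maps (TIFF with
a JSON geometry sidecar), keypoint and stimulus-record CSVs, transform
and model-fit JSONs, and a run manifest tying them together.  Re-running
with the same configuration and seed reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enface import QuantConfig, extract_spot_features
from .geometry import ScanGeometry
from .grid import StimulusGrid, generate_default_grid, sector_table
from .registration import estimate_affine_from_table, map_grid_to_oct
from .stats import fit_presence_model, fit_volume_model, learning_sensitivity
from .synth import (CohortBundle, CohortConfig, ConfigurationError,
                    DrusenFieldParams, HRFFieldParams, ObserverParams,
                    RegistrationTruthParams, TrueEffects, simulate_cohort)

log = logging.getLogger("mpsf")

STAGES = ("simulate", "register", "extract", "fit", "report")

SPOT_RECORD_COLUMNS = [
    "patient_id", "eye_id", "laterality", "visit", "spot_id", "x_deg", "y_deg",
    "ecc_deg", "sector", "x_px", "y_px", "in_raster", "sensitivity_db",
    "drusen_vol_e3mm3", "hrf_vol_e3mm3", "drusen_mean_um", "hrf_mean_um",
    "drusen_present", "hrf_present",
]


@dataclass
class PipelineConfig:
    """Validated top-level configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    master_seed: int = 0
    registration_rms_threshold_px: float = 2.0
    grid_csv: str | None = None

    def grid(self) -> StimulusGrid:
        if self.grid_csv:
            return StimulusGrid.from_csv(self.grid_csv)
        return generate_default_grid()


def config_to_dict(c: PipelineConfig) -> dict:
    """Serialise a configuration to a plain nested dict."""
    return {
        "master_seed": c.master_seed,
        "registration_rms_threshold_px": c.registration_rms_threshold_px,
        "grid_csv": c.grid_csv,
        "cohort": {
            "n_patients": c.cohort.n_patients,
            "n_eyes": c.cohort.n_eyes,
            "n_visits": c.cohort.n_visits,
            "growth_noise_sd": c.cohort.growth_noise_sd,
            "geometry": c.cohort.geometry.to_dict(),
            "drusen": dataclasses.asdict(c.cohort.drusen),
            "hrf": dataclasses.asdict(c.cohort.hrf),
            "effects": dataclasses.asdict(c.cohort.effects),
            "observer": dataclasses.asdict(c.cohort.observer),
            "registration": dataclasses.asdict(c.cohort.registration),
            "quant": dataclasses.asdict(c.cohort.quant),
        },
    }


def reference_config() -> dict:
    """Every configurable default, as a plain nested dict."""
    return config_to_dict(PipelineConfig())


def config_from_dict(d: dict) -> PipelineConfig:
    """Build a validated config from a (possibly partial) nested dict."""
    d = dict(d or {})
    ch = dict(d.get("cohort") or {})

    def block(key, cls):
        sub = dict(ch.get(key) or {})
        if key == "registration" and "fovea_cfp_centre" in sub:
            sub["fovea_cfp_centre"] = tuple(sub["fovea_cfp_centre"])
        return cls(**sub)

    cohort = CohortConfig(
        n_patients=int(ch.get("n_patients", 35)),
        n_eyes=int(ch.get("n_eyes", 51)),
        n_visits=int(ch.get("n_visits", 5)),
        growth_noise_sd=float(ch.get("growth_noise_sd", 0.0)),
        geometry=ScanGeometry.from_dict(ch["geometry"]) if "geometry" in ch
        else ScanGeometry(),
        drusen=block("drusen", DrusenFieldParams),
        hrf=block("hrf", HRFFieldParams),
        effects=block("effects", TrueEffects),
        observer=block("observer", ObserverParams),
        registration=block("registration", RegistrationTruthParams),
        quant=block("quant", QuantConfig),
    )
    return PipelineConfig(
        cohort=cohort,
        master_seed=int(d.get("master_seed", 0)),
        registration_rms_threshold_px=float(
            d.get("registration_rms_threshold_px", 2.0)),
        grid_csv=d.get("grid_csv"),
    )


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    return config_from_dict(data)


def validate_config(d: dict) -> dict:
    """Report-only schema and sanity validation of a raw config dict.

    Returns ``{"errors": [...], "warnings": [...]}`` without raising.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    try:
        cfg = config_from_dict(d)
    except (ConfigurationError, ValueError, TypeError) as exc:
        return {"errors": [str(exc)], "warnings": []}
    q = cfg.cohort.quant
    if q.hrf_min_volume_mm3 > 1e-2:
        warnings_.append(
            "hrf_min_volume_mm3 looks large; the floor is expressed in mm^3")
    if cfg.cohort.n_eyes < cfg.cohort.n_patients:
        errors.append("n_eyes must be >= n_patients")
    if cfg.cohort.n_eyes > cfg.cohort.n_patients:
        pass
    if cfg.cohort.n_eyes == cfg.cohort.n_patients:
        warnings_.append("every patient contributes a single eye")
    if cfg.cohort.drusen.mean_bumps == 0 and cfg.cohort.hrf.blob_rate > 0 \
            and cfg.cohort.hrf.colocalization_weight > 100:
        warnings_.append("HRF strongly colocalized with drusen but no drusen "
                         "are generated; HRF coverage will be near zero")
    return {"errors": errors, "warnings": warnings_}


# ---------------------------------------------------------------------------
# extraction


def extract_cohort_table(bundle: CohortBundle,
                         rms_threshold_px: float = 2.0) -> pd.DataFrame:
    """Build the full stimulus-record table from a simulated cohort.

    Per eye: estimate the fundus-to-OCT affine from the (noisy) keypoint
    table, project the stimulus grid into the raster, and quantify both
    lesion ROIs at every visit.  The measured staircase sensitivities are
    joined in from the simulation record.  An eye whose registration RMS
    exceeds ``rms_threshold_px`` is flagged (column ``registration_ok``)
    but still extracted.
    """
    grid = bundle.grid
    grid_df = grid.to_frame()
    ecc = grid.eccentricities_deg
    frames = []
    for eye in bundle.eyes:
        st = eye.state
        fit = estimate_affine_from_table(eye.keypoints)
        mapped = map_grid_to_oct(grid, st.fovea_cfp, st.cfp_scale_px_per_deg,
                                 fit.transform, bundle.config.geometry)
        sectors = sector_table(grid, st.laterality,
                               bundle.config.geometry.mm_per_degree)
        for vr in eye.visits:
            feats = extract_spot_features(vr.drusen_map, vr.hrf_map, mapped,
                                          bundle.config.quant)
            df = grid_df.merge(mapped, on="spot_id").merge(
                sectors, on="spot_id").merge(feats, on="spot_id")
            df.insert(0, "patient_id", st.patient_id)
            df.insert(1, "eye_id", st.eye_id)
            df.insert(2, "laterality", st.laterality)
            df.insert(3, "visit", vr.visit)
            df["ecc_deg"] = ecc
            df["sensitivity_db"] = vr.measured_sensitivity_db
            df["registration_ok"] = fit.rms_px <= rms_threshold_px
            df["registration_rms_px"] = fit.rms_px
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return table[SPOT_RECORD_COLUMNS + ["registration_ok", "registration_rms_px"]]


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _hash_config(cfg_dict: dict) -> str:
    payload = json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    stages=STAGES,
    write_maps: bool = False,
) -> RunManifest:
    """Execute the requested stages in order under ``out_dir``.

    Each stage writes its outputs before the next starts; a failure
    halts the run with the manifest recording the failed stage.  Lesion
    maps are bulky and only written when ``write_maps`` is set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in set(stages)]
    manifest = RunManifest(config_hash=_hash_config(config_to_dict(config)),
                           seed=config.master_seed, version=__version__)
    bundle = None
    table = None
    try:
        if "simulate" in stages:
            t0 = time.time()
            bundle = simulate_cohort(config.cohort, config.master_seed,
                                     grid=config.grid())
            kp_path = out / "keypoints.csv"
            bundle.keypoint_table().to_csv(kp_path, index=False)
            truth_path = out / "truth.csv"
            bundle.truth_table().to_csv(truth_path, index=False)
            config.grid().to_csv(out / "grid.csv")
            config.cohort.geometry.to_json(out / "geometry.json")
            if write_maps:
                maps_dir = out / "maps"
                maps_dir.mkdir(exist_ok=True)
                for eye in bundle.eyes:
                    for vr in eye.visits:
                        tag = f"eye{eye.state.eye_id:03d}_v{vr.visit}"
                        vr.drusen_map.to_tiff(maps_dir / f"drusen_{tag}.tiff")
                        vr.hrf_map.to_tiff(maps_dir / f"hrf_{tag}.tiff")
            manifest.stages["simulate"] = {
                "keypoints": str(kp_path), "truth": str(truth_path),
                "n_eyes": len(bundle.eyes), "seconds": round(time.time() - t0, 2)}
            log.info("simulate: %d eyes", len(bundle.eyes))

        if "register" in stages or "extract" in stages:
            if bundle is None:
                raise ConfigurationError(
                    "register/extract require the simulate stage in this run")
            t0 = time.time()
            transforms = {}
            for eye in bundle.eyes:
                fit = estimate_affine_from_table(eye.keypoints)
                transforms[eye.state.eye_id] = {
                    **fit.transform.to_dict(), "rms_px": fit.rms_px,
                    "n_points": fit.n_points,
                    "ok": fit.rms_px <= config.registration_rms_threshold_px}
            tpath = out / "transforms.json"
            with open(tpath, "w") as fh:
                json.dump(transforms, fh, indent=2)
            manifest.stages["register"] = {
                "transforms": str(tpath), "n_eyes": len(transforms),
                "seconds": round(time.time() - t0, 2)}

        if "extract" in stages:
            t0 = time.time()
            table = extract_cohort_table(
                bundle, rms_threshold_px=config.registration_rms_threshold_px)
            spath = out / "spot_records.csv"
            table.to_csv(spath, index=False)
            manifest.stages["extract"] = {
                "spot_records": str(spath), "n_rows": len(table),
                "seconds": round(time.time() - t0, 2)}
            log.info("extract: %d spot records", len(table))

        if "fit" in stages:
            if table is None:
                spath = out / "spot_records.csv"
                if not spath.exists():
                    raise ConfigurationError(
                        "fit stage needs spot_records.csv from a prior extract")
                table = pd.read_csv(spath)
            t0 = time.time()
            volume_fit = fit_volume_model(table)
            presence_fit = fit_presence_model(table)
            learning = learning_sensitivity(table) \
                if table["visit"].nunique() >= 3 else []
            report = {
                "volume_model": volume_fit.to_dict(),
                "presence_model": presence_fit.to_dict(),
                "learning_effect": [dataclasses.asdict(r) for r in learning],
            }
            fpath = out / "fits.json"
            with open(fpath, "w") as fh:
                json.dump(report, fh, indent=2)
            manifest.stages["fit"] = {"fits": str(fpath),
                                      "seconds": round(time.time() - t0, 2)}
            log.info("fit: volume-model drusen coefficient %.3f",
                     volume_fit.coef("drusen_vol_e3mm3"))

        if "report" in stages:
            fpath = out / "fits.json"
            if not fpath.exists():
                raise ConfigurationError("report stage needs fits.json")
            with open(fpath) as fh:
                fits = json.load(fh)
            rpath = out / "report.md"
            rpath.write_text(_render_report(fits))
            manifest.stages["report"] = {"report": str(rpath)}
    except Exception:
        done = set(manifest.stages)
        manifest.failed_stage = next((s for s in stages if s not in done), None)
        manifest.to_json(out / "manifest.json")
        raise
    manifest.to_json(out / "manifest.json")
    return manifest


def _render_report(fits: dict) -> str:
    lines = ["# Structure-function model report", ""]
    for key, title in (("volume_model", "Volume model"),
                       ("presence_model", "Presence model")):
        f = fits[key]
        lines += [f"## {title}", "",
                  f"n = {f['n_obs']} stimuli, {f['n_eyes']} eyes, "
                  f"{f['n_patients']} patients; "
                  f"converged: {f['converged']}", "",
                  "| term | estimate | 95% CI | p |", "|---|---|---|---|"]
        for t in f["terms"]:
            lines.append(
                f"| {t['term']} | {t['estimate']:.3f} | "
                f"[{t['ci_low']:.3f}, {t['ci_high']:.3f}] | {t['p']:.3g} |")
        vc = f["variance_components"]
        lines += ["", "Variance components (dB^2): "
                  + ", ".join(f"{k} = {v:.3f}" for k, v in vc.items()), ""]
    if fits.get("learning_effect"):
        lines += ["## Learning effect (visit coefficient)", ""]
        for r in fits["learning_effect"]:
            if r["estimable"]:
                lines.append(f"- {r['label']}: {r['estimate']:.3f} dB/visit "
                             f"[{r['ci_low']:.3f}, {r['ci_high']:.3f}], "
                             f"p = {r['p']:.3g}")
            else:
                lines.append(f"- {r['label']}: not estimable")
        lines.append("")
    return "\n".join(lines)
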