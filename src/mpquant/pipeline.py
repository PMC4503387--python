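"""Multi-stage analysis pipeline with provenance logging.

Runs the enabled stages (tracks → spatial → contraction) over file inputs
and aggregates every module output into a single JSON-serialisable report.
A stage failure is recorded in the report without stopping later stages.
Reports are byte-identical across repeated runs of the same inputs and
config: all randomness flows from config seeds and no timestamps are
embedded.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import metadata

from . import contraction as ct
from . import io as mio
from . import spatial as sp
from . import tracks as tk
from .config import RunConfig


@dataclass
class PipelineInputs:
    tracks_csv: str | None = None
    nuclei_csv: str | None = None
    stack_tiff: str | None = None


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.canonical_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _run_tracks(config: RunConfig, path: str) -> dict:
    cfg = config.tracks
    rule = tk.RegionRule(centre=tuple(config.geometry.centre),
                         radial_threshold=cfg.radial_threshold)
    tracks = [tk.assign_region(t, rule) for t in mio.read_tracks_csv(path)]
    fits = []
    for tr in tracks:
        fit = tk.PRWModel.from_track(tr, cfg.max_lag_fraction).fit()
        fits.append(tk.classify_migration(fit, cfg.mu_threshold, cfg.gof_threshold))
    summary = tk.summarize_cohort(tracks, fits)
    return {
        "n_tracks": len(tracks),
        "summary": summary.to_dict(),
        "per_cell": [
            {
                "cell_id": str(tr.cell_id),
                "region": tr.region,
                "persistence_time": round(ft.persistence_time, 9),
                "speed": round(ft.speed, 9),
                "motility_coefficient": round(ft.motility_coefficient, 9),
                "classification": ft.classification,
                "converged": ft.converged,
            }
            for tr, ft in zip(tracks, fits)
        ],
    }


def _run_spatial(config: RunConfig, path: str) -> dict:
    geom = sp.PatternGeometry(centre=tuple(config.geometry.centre),
                              diameter=config.geometry.diameter,
                              annulus_width=config.geometry.annulus_width)
    rule = tk.RegionRule(centre=geom.centre,
                         radial_threshold=config.tracks.radial_threshold)
    nuclei = mio.read_nuclei_csv(path)
    dmap = sp.annulus_density_map(nuclei, geom)
    out = {
        "n_nuclei": int(len(nuclei)),
        "n_outside": dmap.n_outside,
        "annuli": dmap.table.round(9).to_dict(orient="records"),
        "spatial_density_ratio": round(sp.spatial_density_ratio(dmap, rule), 9),
    }
    markers = [c for c in nuclei.columns if nuclei[c].dtype == bool]
    out["marker_fractions"] = {
        m: {k: round(v, 9) for k, v in
            sp.marker_positive_fraction(nuclei, m, geom, by_region=True,
                                        region_rule=rule).items()}
        for m in markers
    }
    if {"major_um", "minor_um"}.issubset(nuclei.columns):
        _, shape_summary, rejected = sp.nucleus_shape_index(nuclei, rule, geom)
        out["shape_index"] = shape_summary.round(9).reset_index().to_dict(
            orient="records")
        out["n_rejected_nuclei"] = int(len(rejected))
    return out


def _run_contraction(config: RunConfig, path: str) -> dict:
    cfg = config.contraction
    stack = ct.ImageStack.from_tiff(path, cfg.frame_rate, cfg.pixel_size)
    field = ct.block_match_motion(stack, cfg.block_size, cfg.search_radius,
                                  cfg.step, cfg.min_std)
    wf = ct.detect_beats(ct.motion_waveform(field), cfg.min_prominence,
                         cfg.min_separation, cfg.min_peak_speed)
    heat = ct.contraction_heatmap(field)
    return {
        "n_frames": stack.n_frames,
        "beat_frequency_hz": round(wf.beat_frequency, 9),
        "max_contraction_velocity_um_per_s": round(wf.max_contraction_velocity, 9),
        "n_contraction_peaks": int(len(wf.contraction_peak_times)),
        "quiescent": bool(wf.quiescent),
        "heatmap_max_um_per_s": round(float(heat.max()), 9),
    }


_STAGES = {
    "tracks": ("tracks_csv", _run_tracks),
    "spatial": ("nuclei_csv", _run_spatial),
    "contraction": ("stack_tiff", _run_contraction),
}


def run_pipeline(config: RunConfig, inputs: PipelineInputs) -> dict:
    """Execute the enabled stages and return the aggregate report.

    The report's ``ok`` flag is False when any enabled stage failed; the CLI
    maps that to a nonzero exit code.
    """
    try:
        version = metadata.version("mpquant")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    report: dict = {
        "provenance": {
            "config_sha256": _config_hash(config),
            "seed": config.seed,
            "mpquant_version": version,
        },
        "stages": {},
        "ok": True,
    }
    for name in config.stages:
        if name not in _STAGES:
            report["stages"][name] = {"status": "failed",
                                      "error": f"unknown stage {name!r}"}
            report["ok"] = False
            continue
        attr, fn = _STAGES[name]
        path = getattr(inputs, attr)
        if path is None:
            report["stages"][name] = {"status": "skipped", "reason": "no input"}
            continue
        try:
            report["stages"][name] = {"status": "ok", "result": fn(config, path)}
        except Exception as exc:  # failure isolated per stage
            report["stages"][name] = {"status": "failed",
                                      "error": f"{type(exc).__name__}: {exc}"}
            report["ok"] = False
    return report


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON encoding; non-finite floats become null."""
    return json.dumps(_sanitize(report), sort_keys=True, indent=2,
                      allow_nan=False)
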