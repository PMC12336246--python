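"""Fit -> predict -> measure -> compare orchestration and statistics.

ANOVA and Shapiro-Wilk come from scipy; only the grouping logic
(left/right, per-section) is bespoke.  Significance is reported at the
two tiers 0.05 and 0.005.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from PIL import Image
from scipy import stats

from . import __version__
from .continuum_model import (
    DEFAULT_DAMPING,
    DEFAULT_DT,
    DEFAULT_FORCING_HZ,
    DynamicSystem,
    TissueModel,
    contact_area_m2,
    predict_sections,
    simulate_dynamic,
)
from .errors import InvalidInputError, StageError
from .fabric_mechanics import estimate_fabric_properties, read_records_csv
from .scan_geometry import (
    deformation_profile,
    extract_contour,
    profile_from_points,
)
from .synthetic_data import section_geometries, write_fixture_battery

logger = logging.getLogger("compresscan")

SIGNIFICANCE_TIERS = (0.05, 0.005)


@dataclass
class ComparisonReport:
    """Predicted-vs-measured deformation with deviation and group statistics."""

    predicted: dict  # (section, side) -> mm
    measured: dict  # (section, side) -> mm
    deviation_static: float  # mean |predicted - measured| mm
    deviation_dynamic: Optional[float] = None
    normality: dict = field(default_factory=dict)  # group -> p-value or None
    anova: dict = field(default_factory=dict)  # comparison -> {F, p, significance, n}
    group_sizes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def keyed(d):
            return {f"s{sec}_{side}": v for (sec, side), v in d.items()}

        return {
            "predicted_mm": keyed(self.predicted),
            "measured_mm": keyed(self.measured),
            "deviation_static_mm": self.deviation_static,
            "deviation_dynamic_mm": self.deviation_dynamic,
            "normality_p": self.normality,
            "anova": self.anova,
            "group_sizes": self.group_sizes,
        }


def significance_tier(p: float) -> str:
    """Two-tier verdict: 'p < 0.005', 'p < 0.05', or 'p > 0.05'."""
    if p < SIGNIFICANCE_TIERS[1]:
        return "p < 0.005"
    if p < SIGNIFICANCE_TIERS[0]:
        return "p < 0.05"
    return "p > 0.05"


def _shapiro_or_none(values, group_name: str):
    if len(values) < 3:
        warnings.warn(
            f"group {group_name!r} has n={len(values)} < 3: normality test skipped",
            stacklevel=3,
        )
        return None
    return float(stats.shapiro(values).pvalue)


def anova_oneway(groups: list) -> tuple[float, float]:
    """One-way ANOVA F and p over >= 2 groups."""
    if len(groups) < 2:
        raise InvalidInputError("ANOVA needs >= 2 groups")
    res = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def compare(
    predicted: dict,
    measured: dict,
    dynamic_predicted: Optional[dict] = None,
    dynamic_measured: Optional[dict] = None,
) -> ComparisonReport:
    """Compare per-(section, side) predictions against measurements.

    Both dicts must share keys ``(section_id, side)``.  Left-vs-right
    ANOVA uses the measured left/right groups; across-sections ANOVA
    groups measured values by section.
    """
    if set(predicted) != set(measured):
        raise InvalidInputError(
            f"key mismatch: predicted-only {sorted(set(predicted) - set(measured))}, "
            f"measured-only {sorted(set(measured) - set(predicted))}"
        )
    keys = sorted(measured)
    dev = float(np.mean([abs(predicted[k] - measured[k]) for k in keys]))

    dev_dyn = None
    if dynamic_predicted is not None and dynamic_measured is not None:
        common = sorted(set(dynamic_predicted) & set(dynamic_measured))
        if common:
            dev_dyn = float(
                np.mean([abs(dynamic_predicted[k] - dynamic_measured[k]) for k in common])
            )

    left = [measured[k] for k in keys if k[1] == "left"]
    right = [measured[k] for k in keys if k[1] == "right"]
    sections = sorted({k[0] for k in keys})
    by_section = [[measured[k] for k in keys if k[0] == s] for s in sections]

    normality = {
        "left": _shapiro_or_none(left, "left"),
        "right": _shapiro_or_none(right, "right"),
        "all": _shapiro_or_none([measured[k] for k in keys], "all"),
    }
    anova = {}
    if left and right:
        F, p = anova_oneway([left, right])
        anova["left_vs_right"] = {
            "F": F, "p": p, "significance": significance_tier(p),
            "n": [len(left), len(right)],
        }
    if len(sections) >= 2 and all(len(g) >= 1 for g in by_section):
        F, p = anova_oneway(by_section)
        anova["across_sections"] = {
            "F": F, "p": p, "significance": significance_tier(p),
            "n": [len(g) for g in by_section],
        }
    return ComparisonReport(
        predicted=dict(predicted),
        measured=dict(measured),
        deviation_static=dev,
        deviation_dynamic=dev_dyn,
        normality=normality,
        anova=anova,
        group_sizes={"left": len(left), "right": len(right)},
    )


# ---------------------------------------------------------------------------
# pipeline driver

DEFAULT_CONFIG = {
    "version": 1,
    "seed": 0,
    "synth": True,
    "sample": 4,
    "inflation": 1.10,
    "tissue": {"Es": 15000.0, "vs": 0.3},
    "measure": {"n_angles": 360, "resample": 720, "image_size": 512},
    "dynamic": {
        "enabled": True,
        "damping": DEFAULT_DAMPING,
        "mass": 0.2,
        "forcing_amplitude_n": 5.0,
        "forcing_frequency_hz": DEFAULT_FORCING_HZ,
        "dt": DEFAULT_DT,
        "t_end": 0.05,
    },
}


def load_config(path=None, overrides: Optional[dict] = None) -> dict:
    """Merge YAML config over defaults (shallow per top-level key)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                logger.info("stage %s: done", name)
                return out
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise StageError(name, str(exc)) from exc

        return wrapper

    return deco


@_stage("fit-fabric")
def fit_fabric_stage(csv_path, mass: float):
    records = read_records_csv(csv_path)
    return estimate_fabric_properties(records, mass=mass, label=Path(csv_path).stem)


@_stage("predict")
def predict_stage(fabric, tissue, sample: int, inflation: float):
    geoms = section_geometries(sample, inflation)
    preds, mean = predict_sections(fabric, geoms, tissue)
    return geoms, preds, mean


@_stage("measure")
def measure_stage(fixture_dir, condition: str, n_angles: int, resample: int) -> dict:
    fixture_dir = Path(fixture_dir)
    with open(fixture_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    images = manifest["images"]
    controls = {
        (e["section"], e["side"]): e for e in images if e["condition"] == "control"
    }
    garments = [e for e in images if e["condition"] == condition]
    if not garments:
        raise InvalidInputError(f"no images for condition {condition!r}")
    measured = {}
    for entry in garments:
        key = (entry["section"], entry["side"])
        if key not in controls:
            raise InvalidInputError(
                f"missing control (baseline) image for section {key[0]}/{key[1]}: "
                "net deformation requires the no-garment condition"
            )
        prof = {}
        for role, e in (("control", controls[key]), ("garment", entry)):
            img = Image.open(fixture_dir / e["path"])
            pts = extract_contour(img, pixel_scale=e["pixel_scale"])
            prof[role] = profile_from_points(
                pts, key[0], key[1], role, n_angles=n_angles, resample_to=resample,
                pixel_scale=e["pixel_scale"],
            )
        dp = deformation_profile(prof["control"], prof["garment"])
        measured[key] = dp.mean
    return measured


@_stage("simulate-dynamic")
def dynamic_stage(cfg_dyn: dict, fabric, geoms, preds, tissue) -> dict:
    amp = float(cfg_dyn["forcing_amplitude_n"])
    freq = float(cfg_dyn["forcing_frequency_hz"])
    out = {}
    for geom, pred in zip(geoms, preds):
        sysd = DynamicSystem(
            mass=float(cfg_dyn.get("mass", fabric.mass)),
            damping=float(cfg_dyn["damping"]),
            forcing=lambda t, a=amp, f=freq: a * np.sin(2 * np.pi * f * t),
            static_pressure=pred.pressure,
            contact_area=contact_area_m2(geom.limb_radius, geom.section_height),
            forcing_frequency=freq,
        )
        trace = simulate_dynamic(
            sysd, geom.limb_radius, tissue,
            t_end=float(cfg_dyn["t_end"]), dt=float(cfg_dyn["dt"]),
        )
        out[geom.section_id] = {
            "mean_mm": float(np.mean(trace.cycle_summary["mean"])),
            "max_mm": float(np.max(trace.cycle_summary["max"])),
            "min_mm": float(np.min(trace.cycle_summary["min"])),
        }
    return out


def run_pipeline(config: dict, out_dir) -> ComparisonReport:
    """Execute the full pipeline and write versioned artifacts to out_dir.

    Stages: (synth) -> fit-fabric -> predict -> measure -> simulate-dynamic
    -> compare.  Any stage failure raises :class:`StageError` naming the
    stage.  Identical config + seed give identical numerical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    sample = int(config.get("sample", 4))
    tissue = TissueModel(**config["tissue"])

    fixture_dir = Path(config.get("fixture_dir") or (out / "fixtures"))
    if config.get("synth", True):
        logger.info("stage synth: writing fixture battery to %s", fixture_dir)
        write_fixture_battery(fixture_dir, seed=seed, tissue=tissue, samples=(sample,))

    mass = float(config.get("dynamic", {}).get("mass", 0.2))
    fabric = fit_fabric_stage(
        fixture_dir / "stress_strain" / f"sample_{sample}.csv", mass
    )
    geoms, preds, pred_mean = predict_stage(
        fabric, tissue, sample, float(config.get("inflation", 1.10))
    )
    mcfg = config.get("measure", {})
    measured = measure_stage(
        fixture_dir,
        f"legging_{sample}",
        int(mcfg.get("n_angles", 360)),
        int(mcfg.get("resample", 720)),
    )

    predicted = {}
    for pred in preds:
        for key in measured:
            if key[0] == pred.section_id:
                predicted[key] = pred.deformation

    dynamic = None
    if config.get("dynamic", {}).get("enabled", False):
        dynamic = dynamic_stage(config["dynamic"], fabric, geoms, preds, tissue)

    report = compare(predicted, measured)

    result = {
        "schema_version": 1,
        "software_version": __version__,
        "seed": seed,
        "sample": sample,
        "fabric": {
            "Ex": fabric.Ex, "Ey": fabric.Ey, "Gxy": fabric.Gxy, "vxy": fabric.vxy,
        },
        "predicted_section_mean_mm": pred_mean,
        "report": report.to_dict(),
        "dynamic": dynamic,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    with open(out / "measured.csv", "w") as fh:
        fh.write("section,side,measured_mm,predicted_mm\n")
        for key in sorted(measured):
            fh.write(
                f"{key[0]},{key[1]},{measured[key]:.6f},{predicted[key]:.6f}\n"
            )
    logger.info(
        "pipeline complete: static deviation %.4f mm", report.deviation_static
    )
    return report
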