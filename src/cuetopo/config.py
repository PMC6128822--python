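"""Pipeline configuration: defaults, validation, unit normalization."""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .synthetic import DEFAULT_MIXTURE, DEFAULT_N_PER_GROUP, DEFAULT_RESPONDER_RATE, MixtureSpec

__all__ = ["PipelineConfig", "validate_config", "load_config"]

_DEFAULTS: dict = {
    "mode": "coordinate",
    "seed": None,
    "cohort": {
        "n_per_group": dict(DEFAULT_N_PER_GROUP),
        "responder_rate": DEFAULT_RESPONDER_RATE,
        "amplitude": 1.0,
    },
    "mixture": {
        "centroids": DEFAULT_MIXTURE.centroids.tolist(),
        "weights": DEFAULT_MIXTURE.weights.tolist(),
        "dispersion_mm": DEFAULT_MIXTURE.dispersion_mm,
    },
    "paradigm": {
        "n_epochs": 6,
        "block_s": 24.0,
        "epoch_s": 120.0,
        "epoch_fill": "rest_gap",
    },
    "acquisition": {
        "tr_s": 2.2,
        "voxel_mm": 3.0,
        "noise_sd": 1.0,
        "smoothness_fwhm_mm": 8.0,
        "blob_fwhm_mm": 14.4,
    },
    "thresholding": {
        "voxel_p": 0.005,
        "cluster_alpha": 0.05,
        "n_iterations": 1000,
        "connectivity": 6,
    },
    "kmeans": {
        "k_min": 2,
        "k_max": 10,
        "n_restarts": 1000,
    },
    "coverage": {
        "radii": [20.0, 30.0, 40.0, 50.0],
        "electrodes": "builtin",
        "rounding": "integer",
    },
    "out_dir": None,
}


@dataclass
class PipelineConfig:
    mode: str
    seed: int
    cohort: dict
    mixture_spec: MixtureSpec
    paradigm: dict
    acquisition: dict
    thresholding: dict
    kmeans: dict
    radii_mm: tuple[float, ...]
    electrodes: str
    rounding: str
    out_dir: str | None

    def as_dict(self) -> dict:
        d = {
            "mode": self.mode, "seed": self.seed, "cohort": self.cohort,
            "mixture": {"centroids": self.mixture_spec.centroids.tolist(),
                        "weights": self.mixture_spec.weights.tolist(),
                        "dispersion_mm": self.mixture_spec.dispersion_mm},
            "paradigm": self.paradigm, "acquisition": self.acquisition,
            "thresholding": self.thresholding, "kmeans": self.kmeans,
            "coverage": {"radii": list(self.radii_mm), "electrodes": self.electrodes,
                         "rounding": self.rounding},
            "out_dir": self.out_dir,
        }
        return d


def _parse_radii(raw) -> tuple[float, ...]:
    """Accept mm lists or strings like '2,3,4,5 cm' (cm converted to mm)."""
    if isinstance(raw, str):
        m = re.fullmatch(r"\s*([\d.,\s\-]+?)\s*(cm|mm)\s*", raw)
        if not m:
            raise ValueError(f"cannot parse radii {raw!r}; expected e.g. '2,3,4,5 cm'")
        values = [float(v) for v in re.split(r"[,\s]+", m.group(1).strip()) if v]
        factor = 10.0 if m.group(2) == "cm" else 1.0
        radii = tuple(v * factor for v in values)
    else:
        radii = tuple(float(v) for v in raw)
    if not radii or any(r <= 0 for r in radii) or list(radii) != sorted(radii):
        raise ValueError("radii must be positive and sorted ascending")
    return radii


def _merge(defaults: dict, user: dict, path: str, strict: bool) -> dict:
    out = dict(defaults)
    for key, val in user.items():
        if key not in defaults:
            if strict:
                raise ValueError(f"unknown config key {path + key!r}")
            continue
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge(defaults[key], val, f"{path}{key}.", strict)
        else:
            out[key] = val
    return out


def validate_config(raw: dict | None = None, strict: bool = True) -> PipelineConfig:
    """Fill defaults, check constraints, and normalize units.

    Strict mode rejects unknown keys and requires an explicit seed (every
    random stage must be reproducible).
    """
    merged = _merge(_DEFAULTS, raw or {}, "", strict)

    if merged["mode"] not in ("coordinate", "image"):
        raise ValueError("mode must be 'coordinate' or 'image'")
    seed = merged["seed"]
    if seed is None:
        if strict:
            raise ValueError("seed is required (strict mode)")
        seed = 0
    seed = int(seed)

    cohort = merged["cohort"]
    n_total = sum(int(v) for v in cohort["n_per_group"].values())
    if n_total <= 0:
        raise ValueError("cohort has zero subjects")
    if not 0 <= float(cohort["responder_rate"]) <= 1:
        raise ValueError("responder_rate must be in [0, 1]")

    mix = merged["mixture"]
    spec = MixtureSpec(centroids=np.asarray(mix["centroids"], dtype=float),
                       weights=np.asarray(mix["weights"], dtype=float),
                       dispersion_mm=float(mix["dispersion_mm"]))

    km = merged["kmeans"]
    if int(km["k_max"]) < int(km["k_min"]):
        raise ValueError("empty k range (k_max < k_min)")
    thr = merged["thresholding"]
    if not (0 < float(thr["voxel_p"]) < 1 and 0 < float(thr["cluster_alpha"]) <= 1):
        raise ValueError("voxel_p and cluster_alpha must be probabilities")
    if int(thr["connectivity"]) not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")

    radii = _parse_radii(merged["coverage"]["radii"])
    electrodes = merged["coverage"]["electrodes"]
    if electrodes != "builtin" and not Path(electrodes).exists():
        raise ValueError(f"electrode table not found: {electrodes}")

    return PipelineConfig(
        mode=merged["mode"], seed=seed, cohort=cohort, mixture_spec=spec,
        paradigm=merged["paradigm"], acquisition=merged["acquisition"],
        thresholding=thr, kmeans=km, radii_mm=radii,
        electrodes=electrodes, rounding=merged["coverage"]["rounding"],
        out_dir=merged["out_dir"],
    )


def load_config(path, strict: bool = True, **overrides) -> PipelineConfig:
    """Parse a YAML/JSON config file and validate it."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    return validate_config(raw, strict=strict)
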