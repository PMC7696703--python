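"""Synthetic matched case-control cohorts with a planted early effect.

The generator emulates the structure of a prospective matched
repeated-sampling metabolomics study: 64 case-control pairs, each
subject sampled at baseline and again closer to (the case's) diagnosis,
with 142 measured variables.  A small panel of variables carries a
case-specific increase in the *repeated* case sample only, confined to
a rectangular region of the (time to diagnosis, time between samples)
plane — the pattern the scan is designed to recover.  Within-subject
correlation is induced by a subject-level random effect per variable,
which the baseline subtraction removes, mirroring why the paired design
gains sensitivity.

All randomness flows from a single integer seed; identical configs
produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from smartscan.data_model import SampleTable


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    ``effect_size`` is expressed in units of the measurement noise sd;
    the planted increase enters the repeated case sample of every pair
    whose (ttd, tbs) falls inside ``roi = (ttd_max, tbs_max)``, with a
    linear taper to zero over ``taper_margin`` years at the region
    boundary (margin 0 gives a hard rectangle).
    """

    n_pairs: int = 64
    n_variables: int = 142
    panel_size: int = 15
    effect_size: float = 1.5
    roi: tuple[float, float] = (8.0, 7.0)
    ttd_range: tuple[float, float] = (0.5, 16.0)
    tbs_range: tuple[float, float] = (0.5, 12.0)
    subject_sd: float = 1.0
    noise_sd: float = 1.0
    baseline_level: float = 10.0
    taper_margin: float = 1.0
    panel: tuple[str, ...] | None = None  # explicit panel ids; default: drawn from seed
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subject_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.panel_size <= self.n_variables):
            raise ValueError("panel_size must be in (0, n_variables]")
        if self.roi[0] > self.ttd_range[1] or self.roi[1] > self.tbs_range[1]:
            raise ValueError("roi must lie within the sampling ranges")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["roi"] = list(self.roi)
        d["ttd_range"] = list(self.ttd_range)
        d["tbs_range"] = list(self.tbs_range)
        return d


@dataclass
class GroundTruth:
    """What was planted: panel, region, and per-pair effect magnitude."""

    panel: list[str]
    roi: tuple[float, float]
    effect_size: float
    pair_effects: dict[str, float] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"panel": self.panel, "roi": list(self.roi),
                 "effect_size": self.effect_size, "pair_effects": self.pair_effects},
                fh, indent=2,
            )


def _taper(x: np.ndarray, x_max: float, margin: float) -> np.ndarray:
    """1 well inside the boundary, linear ramp to 0 at x_max, 0 outside."""
    x = np.asarray(x, dtype=float)
    if margin <= 0:
        return (x < x_max).astype(float)
    return np.clip((x_max - x) / margin, 0.0, 1.0)


def _variable_ids(n: int) -> list[str]:
    return [f"m{j + 1:03d}" for j in range(n)]


def _resolve_panel(config: GeneratorConfig, var_ids: list[str], rng) -> tuple[np.ndarray, list[str]]:
    if config.panel is not None:
        missing = [v for v in config.panel if v not in var_ids]
        if missing:
            raise ValueError(f"panel variable(s) not generated: {missing}")
        idx = np.array([var_ids.index(v) for v in config.panel])
        return idx, list(config.panel)
    idx = np.sort(rng.choice(len(var_ids), size=config.panel_size, replace=False))
    return idx, [var_ids[j] for j in idx]


def generate_cohort(config: GeneratorConfig) -> tuple[SampleTable, GroundTruth]:
    """Draw a repeated-time-point cohort with the planted panel effect.

    Per pair: (ttd, tbs) uniform over the configured ranges, shared by
    case and control (samples of a matched pair are drawn on the same
    dates).  Per subject and variable: value = baseline level + subject
    effect + noise; the case's repeated sample additionally receives
    ``effect_size × noise_sd × taper(ttd) × taper(tbs)`` on the panel
    variables.  Controls never receive the effect.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_variables
    var_ids = _variable_ids(p)
    panel_idx, panel = _resolve_panel(config, var_ids, rng)

    ttd = rng.uniform(*config.ttd_range, size=config.n_pairs)
    tbs = rng.uniform(*config.tbs_range, size=config.n_pairs)
    base_time = rng.uniform(0.0, 20.0, size=config.n_pairs)
    rep_time = base_time + tbs
    diag_time = rep_time + ttd
    effect = (
        config.effect_size * config.noise_sd
        * _taper(ttd, config.roi[0], config.taper_margin)
        * _taper(tbs, config.roi[1], config.taper_margin)
    )

    values_rows, meta_rows, index = [], [], []
    truth = GroundTruth(panel=panel, roi=config.roi, effect_size=config.effect_size)
    for i in range(config.n_pairs):
        pair_id = f"pair{i + 1:03d}"
        truth.pair_effects[pair_id] = float(effect[i])
        for role in ("case", "control"):
            subject_id = f"{pair_id}_{role}"
            subj = rng.normal(0.0, config.subject_sd, size=p)
            for timepoint, t_sample in (("baseline", base_time[i]), ("repeated", rep_time[i])):
                vals = config.baseline_level + subj + rng.normal(0.0, config.noise_sd, size=p)
                if role == "case" and timepoint == "repeated":
                    vals[panel_idx] += effect[i]
                sample_id = f"{subject_id}_{timepoint}"
                index.append(sample_id)
                values_rows.append(vals)
                meta_rows.append(
                    {
                        "subject_id": subject_id, "pair_id": pair_id, "group": role,
                        "timepoint": timepoint, "sampling_time": t_sample,
                        "diagnosis_time": diag_time[i] if role == "case" else np.nan,
                    }
                )
    values = pd.DataFrame(values_rows, index=index, columns=var_ids)
    meta = pd.DataFrame(meta_rows, index=index)
    values.index.name = meta.index.name = "sample_id"
    return SampleTable(values=values, meta=meta), truth


def generate_validation(config: GeneratorConfig) -> tuple[SampleTable, GroundTruth]:
    """Draw a single-time-point cohort with the same planted mechanism.

    Each subject contributes one sample; the case sample receives the
    panel effect whenever ttd < ttd_max (tapered on ttd only, since no
    between-sample interval exists).
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_variables
    var_ids = _variable_ids(p)
    panel_idx, panel = _resolve_panel(config, var_ids, rng)

    ttd = rng.uniform(*config.ttd_range, size=config.n_pairs)
    sample_time = rng.uniform(0.0, 20.0, size=config.n_pairs)
    diag_time = sample_time + ttd
    effect = config.effect_size * config.noise_sd * _taper(ttd, config.roi[0], config.taper_margin)

    values_rows, meta_rows, index = [], [], []
    truth = GroundTruth(panel=panel, roi=config.roi, effect_size=config.effect_size)
    for i in range(config.n_pairs):
        pair_id = f"vpair{i + 1:03d}"
        truth.pair_effects[pair_id] = float(effect[i])
        for role in ("case", "control"):
            subject_id = f"{pair_id}_{role}"
            subj = rng.normal(0.0, config.subject_sd, size=p)
            vals = config.baseline_level + subj + rng.normal(0.0, config.noise_sd, size=p)
            if role == "case":
                vals[panel_idx] += effect[i]
            sample_id = f"{subject_id}_single"
            index.append(sample_id)
            values_rows.append(vals)
            meta_rows.append(
                {
                    "subject_id": subject_id, "pair_id": pair_id, "group": role,
                    "timepoint": "single", "sampling_time": sample_time[i],
                    "diagnosis_time": diag_time[i] if role == "case" else np.nan,
                }
            )
    values = pd.DataFrame(values_rows, index=index, columns=var_ids)
    meta = pd.DataFrame(meta_rows, index=index)
    values.index.name = meta.index.name = "sample_id"
    return SampleTable(values=values, meta=meta), truth
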