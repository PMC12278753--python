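"""Configuration objects for the synthetic cohort and plate generators.

All distributions and effect sizes used by :mod:`lipotrace.cohort` and
:mod:`lipotrace.plates` are collected here so that a whole simulated study is
reproducible from a single config file plus a seed.  Defaults emulate the
study conditions of the source cohort: 135 controls, 133 statin-monotherapy
recipients of whom 39 take a high-intensity statin (HIS), four wells per
culture condition in each of two independent experiments, and two shared
PBMC standard samples per analysis batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a generator configuration is rejected."""


@dataclass
class CohortConfig:
    """Settings for subject-level synthetic data.

    Lipid values are in mmol/L (ApoB/ApoA1 in g/L).  ``intensity_effect_*``
    is the maximal fractional on-statin LDL-C reduction reached at latent
    uptake capacity 1; its arm mean (effect x E[latent] = effect/2) matches
    the observed mean reductions (statin ~28%, HIS >40%).
    """

    n_control: int = 135
    n_statin: int = 133
    n_his: int = 39
    sampling_date: str = "2012-07-01"

    # lipid panel (control marginals; statin values derive from the effect model)
    ldl_c_control_mean: float = 3.48
    ldl_c_sigma: float = 0.25        # lognormal spread of baseline LDL-C
    ldl_c_noise_sigma: float = 0.15  # residual on-treatment noise
    hdl_c_mean: float = 1.49
    tg_control_mean: float = 1.50
    tg_statin_mean: float = 1.65
    tg_his_mean: float = 1.70
    apoa1_mean: float = 1.60

    # treatment effect model: on-statin LDL-C = baseline * (1 - effect * latent_uptake)
    intensity_effect_statin: float = 0.56
    intensity_effect_his: float = 0.84

    # latent traits: Beta(a, b) marginals with a Gaussian-copula correlation
    latent_alpha: float = 2.0
    latent_beta: float = 2.0
    mobilization_uptake_corr: float = 0.3

    # polygenic score coupling (log-scale slope of baseline LDL-C per SD of PRS)
    prs_beta: float = 0.08

    # CVD event model: logistic, decreasing in latent mobilization
    cvd_base_rate_control: float = 0.06
    cvd_base_rate_statin: float = 0.12
    cvd_base_rate_his: float = 0.13
    cvd_mobilization_slope_control: float = 1.0
    cvd_mobilization_slope_statin: float = 1.8
    cvd_mobilization_slope_his: float = 3.0

    # pharmacy record structure
    purchase_interval_days: float = 115.0
    purchase_interval_sd: float = 12.0
    tablets_per_package: int = 100
    n_purchases_before_sampling: int = 6
    window_days: int = 183
    window_inclusive: bool = False   # whether a purchase on the sampling day counts

    def validate(self) -> None:
        for name in ("n_control", "n_statin", "n_his"):
            if getattr(self, name) < 5:
                raise ConfigError(f"{name} must be >= 5")
        if self.n_his > self.n_statin:
            raise ConfigError("n_his must not exceed n_statin (HIS is a statin subset)")
        for name in ("intensity_effect_statin", "intensity_effect_his"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1)")
        for name in ("ldl_c_sigma", "ldl_c_noise_sigma", "prs_beta",
                     "mobilization_uptake_corr"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.latent_alpha <= 0 or self.latent_beta <= 0:
            raise ConfigError("latent Beta parameters must be positive")


@dataclass
class PlateConfig:
    """Settings for plate-structured single-cell readout generation.

    A subject belongs to exactly one plate batch; within it, every culture
    condition is measured in ``wells_per_condition`` wells in each of
    ``experiments`` independent experiments.  Each (plate batch, experiment)
    pair forms a normalization batch with its own multiplicative effect and
    its own wells of the two shared standard samples.  ``noise_scale = 0``
    switches every stochastic draw to its expectation (deterministic mode).
    """

    wells_per_condition: int = 4
    experiments: int = 2
    n_plate_batches: int = 4
    cells_per_well_mean: float = 1200.0
    lymphocyte_fraction: float = 0.8

    # morphology: lognormal cell areas (um^2); the 115 um^2 gate separates modes
    lymphocyte_area_median: float = 70.0
    monocyte_area_median: float = 180.0
    area_sigma: float = 0.18

    # LDL-uptake assay
    organelle_base_lymphocyte: float = 3.0
    organelle_base_monocyte: float = 10.0
    uptake_gain: float = 1.0           # rate factor = 0.5 + gain * latent_uptake
    poor_condition_factor: float = 1.8  # LDLR upregulation under lipid starvation
    intensity_base_lymphocyte: float = 400.0
    intensity_base_monocyte: float = 800.0
    intensity_cv: float = 0.3

    # lipid-droplet assay (lipid-poor baseline; rich:poor ratio = 1 + gain * latent)
    ld_base_lymphocyte: float = 0.6
    ld_base_monocyte: float = 1.2
    ld_ratio_gain: float = 2.0
    droplet_area_um2: float = 0.5
    droplet_area_cv: float = 0.3

    # nuisance structure
    batch_effect_sd: float = 0.15   # lognormal sigma of per-batch multipliers
    well_effect_sd: float = 0.05
    batch_effects: dict[str, float] | None = None  # explicit override per batch_id
    noise_scale: float = 1.0

    standard_ids: tuple[str, ...] = ("STD-1", "STD-2")
    standard_latent: float = 0.5

    def validate(self) -> None:
        if self.wells_per_condition < 1 or self.experiments < 1:
            raise ConfigError("at least one well per condition and one experiment required")
        if self.n_plate_batches < 1:
            raise ConfigError("need at least one plate batch")
        if self.cells_per_well_mean <= 0:
            raise ConfigError("cells_per_well_mean must be positive")
        if not 0.0 <= self.lymphocyte_fraction <= 1.0:
            raise ConfigError("lymphocyte_fraction must be in [0, 1]")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be non-negative")
        if self.batch_effects is not None:
            if any(v <= 0 for v in self.batch_effects.values()):
                raise ConfigError("batch multipliers must be positive")
        for name in ("organelle_base_lymphocyte", "organelle_base_monocyte",
                     "intensity_base_lymphocyte", "intensity_base_monocyte",
                     "ld_base_lymphocyte", "ld_base_monocyte",
                     "poor_condition_factor", "droplet_area_um2"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.ld_ratio_gain < 0 or self.uptake_gain < 0:
            raise ConfigError("gain parameters must be non-negative")


def _from_mapping(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    obj = cls(**mapping)
    obj.validate()
    return obj


def load_config(path: str | Path) -> tuple[CohortConfig, PlateConfig]:
    """Read a ``key: value`` YAML config with optional ``cohort:``/``plate:`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = _from_mapping(CohortConfig, raw.get("cohort", {}))
    plate_raw = raw.get("plate", {})
    if "standard_ids" in plate_raw:
        plate_raw["standard_ids"] = tuple(plate_raw["standard_ids"])
    plate = _from_mapping(PlateConfig, plate_raw)
    return cohort, plate


def dump_config(cohort: CohortConfig, plate: PlateConfig, path: str | Path) -> None:
    plate_d = asdict(plate)
    plate_d["standard_ids"] = list(plate_d["standard_ids"])
    Path(path).write_text(
        yaml.safe_dump({"cohort": asdict(cohort), "plate": plate_d}, sort_keys=False)
    )
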