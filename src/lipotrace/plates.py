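"""Plate-structured single-cell readout simulation.

Emits one row per segmented cell, mirroring the table a high-content
screening pipeline would export: LDL-uptake assay wells carry per-cell mean
DiI-LDL intensity and LDL-filled-organelle counts; lipid-storage assay wells
carry lipid-droplet count, total droplet area, and droplet positivity.
Cell areas come from a two-component size mixture so the 115 um^2 gate
separates lymphocytes from monocytes.  Every (plate batch, experiment) pair
is a normalization batch with a shared multiplicative effect and its own
wells of the standard pseudo-subjects, whose latent traits are fixed so that
standard-based normalization cancels the batch effects.

With ``noise_scale = 0`` every stochastic quantity collapses to its
expectation, which makes batch-effect cancellation exact and is used by the
invariance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PlateConfig

_CONDITIONS = ("R", "P")
_ASSAYS = ("uptake", "storage")

CELL_COLUMNS = [
    "subject_id", "group", "plate_batch", "batch_id", "experiment", "well_id",
    "condition", "assay", "cell_area", "ldl_intensity", "ldl_organelles",
    "ld_count", "ld_area", "ld_positive",
]


def generate_plate_readouts(subjects: pd.DataFrame, config: PlateConfig,
                            seed: int) -> pd.DataFrame:
    """Simulate the single-cell readout table for a cohort.

    ``subjects`` needs ``subject_id``, ``latent_uptake`` and
    ``latent_mobilization`` columns (``group`` is carried through when
    present).  Each subject lands in exactly one plate batch; standards are
    re-measured in every normalization batch.  Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    noise = config.noise_scale

    subj = subjects.reset_index(drop=True)
    n_subj = len(subj)
    if n_subj == 0:
        raise ValueError("no subjects to plate")
    groups = (
        subj["group"].to_numpy() if "group" in subj.columns
        else np.full(n_subj, "subject", dtype=object)
    )

    # partition subjects over plate batches (balanced, randomized)
    order = rng.permutation(n_subj)
    plate_of = np.empty(n_subj, dtype=int)
    plate_of[order] = np.arange(n_subj) % config.n_plate_batches

    # one multiplicative effect per normalization batch (plate batch x experiment)
    batch_ids = [
        f"B{b}E{e}"
        for b in range(config.n_plate_batches)
        for e in range(config.experiments)
    ]
    if config.batch_effects is not None:
        missing = set(batch_ids) - set(config.batch_effects)
        if missing:
            raise ValueError(f"batch_effects missing entries for {sorted(missing)}")
        batch_eff = {k: float(config.batch_effects[k]) for k in batch_ids}
    else:
        draws = np.exp(config.batch_effect_sd * noise * rng.standard_normal(len(batch_ids)))
        batch_eff = dict(zip(batch_ids, draws))

    frames = []
    for b in range(config.n_plate_batches):
        rows = np.flatnonzero(plate_of == b)
        ids = np.concatenate([subj["subject_id"].to_numpy()[rows],
                              np.asarray(config.standard_ids, dtype=object)])
        grp = np.concatenate([groups[rows],
                              np.full(len(config.standard_ids), "standard", dtype=object)])
        lat_u = np.concatenate([subj["latent_uptake"].to_numpy()[rows],
                                np.full(len(config.standard_ids), config.standard_latent)])
        lat_m = np.concatenate([subj["latent_mobilization"].to_numpy()[rows],
                                np.full(len(config.standard_ids), config.standard_latent)])
        for e in range(config.experiments):
            bid = f"B{b}E{e}"
            frames.append(
                _batch_cells(rng, config, bid, b, e, batch_eff[bid],
                             ids, grp, lat_u, lat_m)
            )
    cells = pd.concat(frames, ignore_index=True)
    return cells[CELL_COLUMNS]


def _batch_cells(rng, config: PlateConfig, batch_id: str, plate_batch: int,
                 experiment: int, batch_mult: float, ids, grp, lat_u, lat_m):
    noise = config.noise_scale
    n_ent = len(ids)
    w = config.wells_per_condition
    n_wells = n_ent * len(_CONDITIONS) * len(_ASSAYS) * w

    # well-level layout: entity x condition x assay x well-index
    ent_idx = np.repeat(np.arange(n_ent), len(_CONDITIONS) * len(_ASSAYS) * w)
    cond = np.tile(np.repeat(np.array(_CONDITIONS, dtype=object), len(_ASSAYS) * w), n_ent)
    assay = np.tile(np.repeat(np.array(_ASSAYS, dtype=object), w), n_ent * len(_CONDITIONS))
    widx = np.tile(np.arange(w), n_ent * len(_CONDITIONS) * len(_ASSAYS))

    well_subject = ids[ent_idx]
    well_group = grp[ent_idx]
    well_ids = np.array(
        [f"{batch_id}-{s}-{c}-{a}-W{k}"
         for s, c, a, k in zip(well_subject, cond, assay, widx)],
        dtype=object,
    )

    well_eff = np.exp(config.well_effect_sd * noise * rng.standard_normal(n_wells))
    if noise == 0:
        n_cells = np.full(n_wells, int(round(config.cells_per_well_mean)))
    else:
        n_cells = rng.poisson(config.cells_per_well_mean, n_wells)
    total = int(n_cells.sum())

    cell_well = np.repeat(np.arange(n_wells), n_cells)
    starts = np.concatenate([[0], np.cumsum(n_cells)[:-1]])
    idx_in_well = np.arange(total) - np.repeat(starts, n_cells)

    # cell type mixture
    if noise == 0:
        n_lymph = np.round(config.lymphocyte_fraction * n_cells).astype(int)
        is_lymph = idx_in_well < np.repeat(n_lymph, n_cells)
    else:
        is_lymph = rng.random(total) < config.lymphocyte_fraction

    area_median = np.where(is_lymph, config.lymphocyte_area_median,
                           config.monocyte_area_median)
    if noise == 0:
        cell_area = area_median.astype(float)
    else:
        cell_area = area_median * np.exp(
            config.area_sigma * rng.standard_normal(total)
        )

    u = lat_u[ent_idx][cell_well]
    m = lat_m[ent_idx][cell_well]
    eff = batch_mult * well_eff[cell_well]
    is_poor = (cond[cell_well] == "P")
    is_uptake = (assay[cell_well] == "uptake")

    # LDL-uptake assay: organelle count and mean intensity scale with latent
    # uptake, boosted in lipid-poor conditions (LDLR upregulation)
    org_base = np.where(is_lymph, config.organelle_base_lymphocyte,
                        config.organelle_base_monocyte)
    int_base = np.where(is_lymph, config.intensity_base_lymphocyte,
                        config.intensity_base_monocyte)
    drive = (0.5 + config.uptake_gain * u) * np.where(is_poor, config.poor_condition_factor, 1.0)
    lam_org = org_base * drive * eff
    if noise == 0:
        organelles = lam_org
        intensity = int_base * drive * eff
    else:
        organelles = rng.poisson(lam_org).astype(float)
        intensity = int_base * drive * eff * np.exp(
            config.intensity_cv * rng.standard_normal(total)
        )

    # lipid-storage assay: droplet load higher in lipid-rich conditions with a
    # rich:poor ratio of 1 + ld_ratio_gain * latent_mobilization
    ld_base = np.where(is_lymph, config.ld_base_lymphocyte, config.ld_base_monocyte)
    ratio = 1.0 + config.ld_ratio_gain * m
    lam_ld = ld_base * np.where(is_poor, 1.0, ratio) * eff
    if noise == 0:
        ld_count = lam_ld
        ld_area = lam_ld * config.droplet_area_um2
        ld_pos = (lam_ld > 0).astype(float)
    else:
        ld_count = rng.poisson(lam_ld).astype(float)
        per_droplet = config.droplet_area_um2 * np.exp(
            config.droplet_area_cv * rng.standard_normal(total)
        )
        ld_area = ld_count * per_droplet
        ld_pos = (ld_count > 0).astype(float)

    nan = np.nan
    df = pd.DataFrame(
        {
            "subject_id": well_subject[cell_well],
            "group": well_group[cell_well],
            "plate_batch": plate_batch,
            "batch_id": batch_id,
            "experiment": experiment,
            "well_id": well_ids[cell_well],
            "condition": cond[cell_well],
            "assay": assay[cell_well],
            "cell_area": cell_area,
            "ldl_intensity": np.where(is_uptake, intensity, nan),
            "ldl_organelles": np.where(is_uptake, organelles, nan),
            "ld_count": np.where(is_uptake, nan, ld_count),
            "ld_area": np.where(is_uptake, nan, ld_area),
            "ld_positive": np.where(is_uptake, nan, ld_pos),
        }
    )
    return df
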