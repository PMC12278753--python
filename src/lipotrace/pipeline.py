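"""From single-cell records to per-subject standard-normalized readouts.

Processing order follows the high-content screening convention:

1. per-well outlier removal (cell area / mean intensity beyond 5 SD of the
   unfiltered well mean, single pass),
2. cell-type gating at 115 um^2 (strictly below = lymphocyte),
3. per-well, per-cell-type summaries with a >= 50-cell QC gate,
4. division by the batch's standard-sample well means (per readout, cell
   type and condition),
5. unweighted averaging of the QC-passing replicate wells (up to
   4 wells x 2 experiments = 8) into the subject readout.

The five readouts are LDL-Int, LDL-No (uptake assay) and LD-No, LD-Area,
LD-Pos (storage assay), each measured in lipid-rich (R) and lipid-poor (P)
conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: strict gate: cells under this area (um^2) are lymphocytes, the rest monocytes
LYMPHOCYTE_AREA_CUTOFF = 115.0

#: wells contributing fewer cells than this (per cell type) fail QC
MIN_CELLS_PER_WELL = 50

OUTLIER_SD_CUTOFF = 5.0

#: readout name -> cell-table column
READOUT_COLUMNS = {
    "LDL-Int": "ldl_intensity",
    "LDL-No": "ldl_organelles",
    "LD-No": "ld_count",
    "LD-Area": "ld_area",
    "LD-Pos": "ld_positive",
}

READOUT_NAMES = tuple(
    f"{name}-{cond}" for name in READOUT_COLUMNS for cond in ("R", "P")
)


def filter_outlier_cells(cells: pd.DataFrame, sd_cutoff: float = OUTLIER_SD_CUTOFF) -> pd.DataFrame:
    """Drop cells deviating more than ``sd_cutoff`` x SD from their well mean.

    The mean and (sample) SD are computed once on the unfiltered well, for
    cell area always and for mean LDL intensity where the assay measures it.
    Wells with fewer than two cells pass through unchanged (their SD is
    undefined), as do zero-SD wells (all deviations are zero).
    """
    if len(cells) == 0:
        return cells
    keep = np.ones(len(cells), dtype=bool)
    grouped = cells.groupby("well_id", sort=False, observed=True)
    for col in ("cell_area", "ldl_intensity"):
        mean = grouped[col].transform("mean")
        sd = grouped[col].transform("std")
        dev = (cells[col] - mean).abs()
        bad = dev > sd_cutoff * sd  # NaN sd/value compares False -> retained
        keep &= ~bad.to_numpy()
    return cells[keep]


def classify_cell_type(cell_area) -> np.ndarray:
    """Gate cells into lymphocytes (< 115 um^2) and monocytes (>= 115 um^2)."""
    area = np.asarray(cell_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("cell areas must be positive")
    out = np.where(area < LYMPHOCYTE_AREA_CUTOFF, "lymphocyte", "monocyte")
    return out if out.ndim else out[()]


def summarize_wells(cells: pd.DataFrame, min_cells: int = MIN_CELLS_PER_WELL) -> pd.DataFrame:
    """Per-well, per-cell-type arithmetic means with the cell-count QC gate.

    ``ld_positive`` summarizes to the fraction of droplet-positive cells;
    everything else to a plain mean.  ``qc_pass`` is False below
    ``min_cells`` cells.
    """
    cells = cells.assign(cell_type=classify_cell_type(cells["cell_area"]))
    keys = ["batch_id", "well_id", "subject_id", "group", "condition", "assay", "cell_type"]
    keys = [k for k in keys if k in cells.columns]
    agg = cells.groupby(keys, sort=False, observed=True).agg(
        n_cells=("cell_area", "size"),
        mean_area=("cell_area", "mean"),
        ldl_intensity=("ldl_intensity", "mean"),
        ldl_organelles=("ldl_organelles", "mean"),
        ld_count=("ld_count", "mean"),
        ld_area=("ld_area", "mean"),
        ld_positive=("ld_positive", "mean"),
    ).reset_index()
    agg["qc_pass"] = agg["n_cells"] >= min_cells
    return agg


def normalize_to_standards(wells: pd.DataFrame,
                           standard_ids: tuple[str, ...] | None = None,
                           standard_label: str = "standard") -> pd.DataFrame:
    """Divide well means by the batch's standard-sample well means.

    Standards are identified by ``subject_id`` membership in ``standard_ids``
    or, if not given, by ``group == standard_label``.  The divisor is the
    mean over all QC-passing standard wells of the same batch, cell type,
    condition and assay, computed per readout.  Wells of a batch with no
    valid standard come out missing (NaN).
    """
    if standard_ids is not None:
        is_std = wells["subject_id"].isin(standard_ids)
    else:
        is_std = wells["group"] == standard_label
    readouts = ["ldl_intensity", "ldl_organelles", "ld_count", "ld_area", "ld_positive"]
    keys = ["batch_id", "cell_type", "condition", "assay"]

    std = wells[is_std & wells["qc_pass"]]
    factors = std.groupby(keys, sort=False, observed=True)[readouts].mean()
    factors = factors.rename(columns={c: f"_std_{c}" for c in readouts}).reset_index()

    out = wells[~is_std].merge(factors, on=keys, how="left")
    for c in readouts:
        divisor = out[f"_std_{c}"].where(out[f"_std_{c}"] > 0)
        out[f"norm_{c}"] = out[c] / divisor
    return out.drop(columns=[f"_std_{c}" for c in readouts])


def average_replicates(norm_wells: pd.DataFrame) -> pd.DataFrame:
    """Average QC-passing normalized wells into per-subject readouts.

    Returns a tidy frame with one row per subject x cell type x condition x
    readout, the unweighted mean over contributing wells and their number.
    A readout is missing when no well passed QC.
    """
    passing = norm_wells[norm_wells["qc_pass"]]
    norm_cols = {
        "norm_ldl_intensity": "LDL-Int",
        "norm_ldl_organelles": "LDL-No",
        "norm_ld_count": "LD-No",
        "norm_ld_area": "LD-Area",
        "norm_ld_positive": "LD-Pos",
    }
    long = passing.melt(
        id_vars=["subject_id", "cell_type", "condition"],
        value_vars=list(norm_cols),
        var_name="readout", value_name="value",
    ).dropna(subset=["value"])
    long["readout"] = long["readout"].map(norm_cols)
    agg = long.groupby(
        ["subject_id", "cell_type", "condition", "readout"], sort=False, observed=True
    )["value"].agg(["mean", "size"]).reset_index()
    return agg.rename(columns={"mean": "value", "size": "n_wells"})


def subject_readout_table(readouts_long: pd.DataFrame,
                          cell_type: str = "monocyte") -> pd.DataFrame:
    """Pivot tidy readouts to one row per subject, columns like ``LDL-No-P``."""
    sel = readouts_long[readouts_long["cell_type"] == cell_type].copy()
    sel["column"] = sel["readout"] + "-" + sel["condition"]
    wide = sel.pivot_table(index="subject_id", columns="column", values="value",
                           aggfunc="first")
    wide.columns.name = None
    return wide.reindex(columns=[c for c in READOUT_NAMES if c in wide.columns])


def process_cells(cells: pd.DataFrame,
                  standard_ids: tuple[str, ...] | None = None,
                  standard_label: str = "standard",
                  cell_type: str = "monocyte",
                  min_cells: int = MIN_CELLS_PER_WELL,
                  sd_cutoff: float = OUTLIER_SD_CUTOFF) -> pd.DataFrame:
    """Full pipeline: cells -> per-subject normalized readout table (wide)."""
    filtered = filter_outlier_cells(cells, sd_cutoff=sd_cutoff)
    wells = summarize_wells(filtered, min_cells=min_cells)
    norm = normalize_to_standards(wells, standard_ids=standard_ids,
                                  standard_label=standard_label)
    tidy = average_replicates(norm)
    return subject_readout_table(tidy, cell_type=cell_type)
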