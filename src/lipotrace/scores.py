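"""Composite cellular scores: uptake (UPT), lipid mobilization (LiM),
lipid trafficking (LT) and polygenic-score integration.

Score hierarchy (all on standard-normalized subject readouts):

* ``UPT-R/P``  = mean(LDL-Int, LDL-No) within each condition,
* ``LiM``      = mean of the rich:poor fold changes of LD-No, LD-Area, LD-Pos,
* dataset-wide min-max rescaling of the uptake and mobilization scores to
  [0, 1],
* ``LT-R/P``   = mean(rescaled LiM, rescaled UPT-R/P),
* ``LT``       = mean(rescaled LiM, rescaled UPT-R, rescaled UPT-P),
* ``LDL-PRS``  = min-max rescaled raw polygenic score, inverted so that a
  higher value means a lower genetic LDL-C burden (same orientation as LT),
* ``LDL-PRS-LT`` = mean(LT, LDL-PRS).

An alternative composition (``lt_composition="raw_readouts"``) rescales the
four raw uptake readouts individually and averages them with LiM instead of
going through the UPT composites; both variants are kept because the two
plausible readings of the score definition differ on this point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: denominator guard for fold changes
EPSILON = 1e-12

LT_COMPOSITIONS = ("upt_composite", "raw_readouts")


def compute_uptake_score(ldl_int, ldl_no):
    """UPT = mean of the normalized intensity and organelle-count readouts."""
    return (_as_float(ldl_int) + _as_float(ldl_no)) / 2.0


def compute_lim(ld_no_r, ld_no_p, ld_area_r, ld_area_p, ld_pos_r, ld_pos_p,
                eps: float = EPSILON):
    """Lipid mobilization: mean rich:poor fold change of the droplet readouts.

    Any lipid-poor denominator at or below ``eps`` leaves the subject's LiM
    missing; nothing is imputed.
    """
    num = [_as_float(v) for v in (ld_no_r, ld_area_r, ld_pos_r)]
    den = [_as_float(v) for v in (ld_no_p, ld_area_p, ld_pos_p)]
    ratios = [n / np.where(d > eps, d, np.nan) for n, d in zip(num, den)]
    return sum(ratios) / 3.0


def minmax_rescale(values):
    """Map a dataset-level vector onto [0, 1] by (x - min) / (max - min).

    Missing values stay missing and do not enter the range.  A constant (or
    all-missing) vector has a degenerate range and is rejected.
    """
    x = _as_float(values)
    finite = x[np.isfinite(x)]
    if finite.size < 2 or finite.min() == finite.max():
        raise ValueError("min-max rescaling needs at least two distinct finite values")
    out = (x - finite.min()) / (finite.max() - finite.min())
    return _like(values, out)


def compute_lt_scores(upt_r_rescaled, upt_p_rescaled, lim_rescaled):
    """(LT-R, LT-P, LT) from rescaled constituents; missing propagates."""
    r = _as_float(upt_r_rescaled)
    p = _as_float(upt_p_rescaled)
    lim = _as_float(lim_rescaled)
    lt_r = (lim + r) / 2.0
    lt_p = (lim + p) / 2.0
    lt = (lim + r + p) / 3.0
    return lt_r, lt_p, lt


def normalize_and_invert_prs(raw_prs):
    """Min-max rescale the raw polygenic score and flip its orientation.

    The raw score rises with genetic LDL-C burden; after ``1 - rescale(x)``
    a higher value means lower burden, matching the LT orientation.
    """
    rescaled = minmax_rescale(raw_prs)
    return _like(raw_prs, 1.0 - _as_float(rescaled))


def combine_prs_lt(lt, ldl_prs_norm, lt_weight: float = 0.5):
    """Combined genetic + cellular score; default is the unweighted mean."""
    if not 0.0 <= lt_weight <= 1.0:
        raise ValueError("lt_weight must be in [0, 1]")
    return lt_weight * _as_float(lt) + (1.0 - lt_weight) * _as_float(ldl_prs_norm)


def build_score_panel(readouts: pd.DataFrame, prs: pd.Series | None = None,
                      lt_composition: str = "upt_composite") -> pd.DataFrame:
    """Assemble the per-subject score panel from a wide readout table.

    ``readouts`` has one row per subject and columns ``LDL-Int-R/P``,
    ``LDL-No-R/P``, ``LD-No-R/P``, ``LD-Area-R/P``, ``LD-Pos-R/P``;
    ``prs`` is the raw polygenic score aligned on the same subject index.
    """
    if lt_composition not in LT_COMPOSITIONS:
        raise ValueError(f"lt_composition must be one of {LT_COMPOSITIONS}")
    r = readouts
    panel = pd.DataFrame(index=r.index)
    panel["UPT-R"] = compute_uptake_score(r["LDL-Int-R"], r["LDL-No-R"])
    panel["UPT-P"] = compute_uptake_score(r["LDL-Int-P"], r["LDL-No-P"])
    panel["LiM"] = compute_lim(
        r["LD-No-R"], r["LD-No-P"], r["LD-Area-R"], r["LD-Area-P"],
        r["LD-Pos-R"], r["LD-Pos-P"],
    )
    lim_s = minmax_rescale(panel["LiM"])
    if lt_composition == "upt_composite":
        upt_r_s = minmax_rescale(panel["UPT-R"])
        upt_p_s = minmax_rescale(panel["UPT-P"])
        lt_r, lt_p, lt = compute_lt_scores(upt_r_s, upt_p_s, lim_s)
    else:
        parts = {c: minmax_rescale(r[c]) for c in
                 ("LDL-Int-R", "LDL-No-R", "LDL-Int-P", "LDL-No-P")}
        lt_r = (lim_s + parts["LDL-Int-R"] + parts["LDL-No-R"]) / 3.0
        lt_p = (lim_s + parts["LDL-Int-P"] + parts["LDL-No-P"]) / 3.0
        lt = (lim_s + parts["LDL-Int-R"] + parts["LDL-No-R"]
              + parts["LDL-Int-P"] + parts["LDL-No-P"]) / 5.0
    panel["LT-R"], panel["LT-P"], panel["LT"] = lt_r, lt_p, lt
    if prs is not None:
        prs = prs.reindex(panel.index)
        panel["LDL-PRS"] = normalize_and_invert_prs(prs)
        panel["LDL-PRS-LT"] = combine_prs_lt(panel["LT"], panel["LDL-PRS"])
    return panel


def _as_float(v):
    if isinstance(v, (pd.Series, pd.DataFrame)):
        return v.to_numpy(dtype=float)
    return np.asarray(v, dtype=float)


def _like(template, values):
    if isinstance(template, pd.Series):
        return pd.Series(values, index=template.index, name=template.name)
    return values
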