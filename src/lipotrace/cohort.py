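"""Synthetic study cohort: subjects, lipid panels, pharmacy records, diagnoses.

The generator emulates the statistical structure the downstream analysis
relies on: a latent per-subject LDL-uptake capacity that is negatively
coupled to achieved on-statin LDL-C (more strongly under high-intensity
statins, HIS), a latent lipid-mobilization capacity that lowers the
probability of a cardiovascular event, a polygenic score positively coupled
to LDL-C, and register-style purchase/diagnosis tables from which the group
definitions (6-month purchase window, last-two-purchase medication type,
HIS dose ranges, I2X/I6X event codes) can be re-derived.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .config import CohortConfig, ConfigError

STATIN_TYPES = ("simvastatin", "atorvastatin", "rosuvastatin")

#: inclusive dose ranges (mg) with >40% LDL-C-reduction potential
HIS_DOSE_RANGES = {"rosuvastatin": (5.0, 40.0), "atorvastatin": (10.0, 80.0)}

CVD_CODE_PREFIXES = ("I2", "I6")
_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")

NMR_SUBCLASSES = (
    "XXL-VLDL", "XL-VLDL", "L-VLDL", "M-VLDL", "S-VLDL", "XS-VLDL",
    "IDL", "L-LDL", "M-LDL", "S-LDL",
    "XL-HDL", "L-HDL", "M-HDL", "S-HDL",
)
NMR_MEASURES = ("PT", "CE", "TG", "CE_pct", "TG_pct")


@dataclass
class Cohort:
    """Generated study tables (one row per subject / purchase / diagnosis)."""

    subjects: pd.DataFrame
    purchases: pd.DataFrame
    diagnoses: pd.DataFrame
    sampling_date: pd.Timestamp

    def write_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(outdir / "subjects.csv", index=False)
        self.purchases.to_csv(outdir / "purchases.csv", index=False)
        self.diagnoses.to_csv(outdir / "diagnoses.csv", index=False)


def _correlated_betas(rng, n: int, a: float, b: float, rho: float):
    """Two Beta(a, b) latents with a Gaussian-copula correlation rho."""
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    u = stats.beta.ppf(stats.norm.cdf(z1), a, b)
    m = stats.beta.ppf(stats.norm.cdf(z2), a, b)
    return u, m


def _lognormal_mean(rng, mean: float, sigma: float, n: int):
    """Lognormal draws with exact arithmetic mean ``mean``."""
    return mean * np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma**2)


def _nmr_panel(rng, ldl_c, tg, hdl_c) -> pd.DataFrame:
    """Plausible lipoprotein-subclass concentrations tied to the lipid panel.

    ApoB-particle classes (VLDL..LDL) scale with LDL-C and triglycerides,
    HDL classes with HDL-C; this reproduces the gross covariance the
    correlation panels exercise, not the real NMR covariance structure.
    """
    n = len(ldl_c)
    ldl_f = np.asarray(ldl_c) / 3.48
    tg_f = np.asarray(tg) / 1.50
    hdl_f = np.asarray(hdl_c) / 1.49
    cols: dict[str, np.ndarray] = {}
    for sub in NMR_SUBCLASSES:
        if "HDL" in sub:
            driver, ce_share, tg_share, base = hdl_f, 0.55, 0.10, 0.9
        elif "VLDL" in sub:
            w = {"XXL": 0.9, "XL": 0.8, "L": 0.7, "M": 0.6, "S": 0.45, "XS": 0.3}[sub.split("-")[0]]
            driver = tg_f**w * ldl_f ** (1 - w)
            ce_share, tg_share, base = 0.30, 0.45, 0.5
        else:  # IDL and LDL fractions
            driver, ce_share, tg_share, base = ldl_f, 0.60, 0.12, 1.2
        noise = np.exp(0.15 * rng.standard_normal(n))
        total_lipid = base * driver * noise
        ce = ce_share * total_lipid * np.exp(0.05 * rng.standard_normal(n))
        tg_c = tg_share * total_lipid * np.exp(0.05 * rng.standard_normal(n))
        other = np.maximum(total_lipid - ce - tg_c, 0.05 * total_lipid)
        pt = total_lipid / 2.5
        denom = ce + tg_c + other
        cols[f"{sub}_PT"] = pt
        cols[f"{sub}_CE"] = ce
        cols[f"{sub}_TG"] = tg_c
        cols[f"{sub}_CE_pct"] = 100.0 * ce / denom
        cols[f"{sub}_TG_pct"] = 100.0 * tg_c / denom
    return pd.DataFrame(cols)


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Draw a full synthetic study population.

    Deterministic for a fixed seed.  On-statin LDL-C follows
    ``baseline * (1 - effect * latent_uptake) * noise`` with a larger
    ``effect`` in the HIS arm, so the within-arm Spearman correlation of
    latent uptake with achieved LDL-C is negative and more negative for HIS.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    sampling = pd.Timestamp(config.sampling_date)

    n = config.n_control + config.n_statin
    subject_id = np.array([f"S{i:04d}" for i in range(1, n + 1)])
    group = np.array(["control"] * config.n_control + ["statin"] * config.n_statin)
    statin_rows = np.flatnonzero(group == "statin")
    his_rows = rng.choice(statin_rows, size=config.n_his, replace=False)
    his = np.zeros(n, dtype=bool)
    his[his_rows] = True

    age = np.clip(rng.normal(55.0, 8.0, n), 25.0, 74.0).round(1)
    sex = rng.choice(["F", "M"], size=n)
    bmi = _lognormal_mean(rng, 27.0, 0.15, n).round(1)

    latent_uptake, latent_mob = _correlated_betas(
        rng, n, config.latent_alpha, config.latent_beta, config.mobilization_uptake_corr
    )

    prs = rng.standard_normal(n)
    baseline_sigma = config.ldl_c_sigma
    baseline = config.ldl_c_control_mean * np.exp(
        config.prs_beta * prs
        + baseline_sigma * rng.standard_normal(n)
        - 0.5 * (baseline_sigma**2 + config.prs_beta**2)
    )
    effect = np.zeros(n)
    effect[group == "statin"] = config.intensity_effect_statin
    effect[his] = config.intensity_effect_his
    noise = np.exp(
        config.ldl_c_noise_sigma * rng.standard_normal(n)
        - 0.5 * config.ldl_c_noise_sigma**2
    )
    on_treatment = np.where(group == "statin", noise, 1.0)
    ldl_c = baseline * (1.0 - effect * latent_uptake) * on_treatment

    tg_mean = np.where(
        group == "control", config.tg_control_mean,
        np.where(his, config.tg_his_mean, config.tg_statin_mean),
    )
    tg = tg_mean * np.exp(0.30 * rng.standard_normal(n) - 0.5 * 0.30**2)
    hdl_c = _lognormal_mean(rng, config.hdl_c_mean, 0.18, n)
    total_chol = ldl_c + hdl_c + 0.45 * tg
    apob = 0.12 + 0.24 * ldl_c * np.exp(0.08 * rng.standard_normal(n))
    apoa1 = _lognormal_mean(rng, config.apoa1_mean, 0.12, n)

    # statin type and dose; HIS membership is consistent with the dose rule
    statin_type = np.full(n, "", dtype=object)
    dose = np.full(n, np.nan)
    is_statin = group == "statin"
    non_his = is_statin & ~his
    statin_type[non_his] = "simvastatin"
    dose[non_his] = rng.choice([10.0, 20.0, 40.0], size=int(non_his.sum()))
    his_type = rng.choice(["atorvastatin", "rosuvastatin"], size=int(his.sum()), p=[0.64, 0.36])
    statin_type[his] = his_type
    dose[his] = np.where(
        his_type == "atorvastatin",
        rng.choice([10.0, 20.0, 40.0, 80.0], size=len(his_type)),
        rng.choice([5.0, 10.0, 20.0, 40.0], size=len(his_type)),
    )

    # CVD events: logistic-decreasing in latent mobilization
    base_rate = np.where(
        group == "control", config.cvd_base_rate_control,
        np.where(his, config.cvd_base_rate_his, config.cvd_base_rate_statin),
    )
    slope = np.where(
        group == "control", config.cvd_mobilization_slope_control,
        np.where(his, config.cvd_mobilization_slope_his, config.cvd_mobilization_slope_statin),
    )
    p_event = expit(logit(base_rate) - slope * (latent_mob - 0.5))
    cvd_event = rng.random(n) < p_event
    span_days = (pd.Timestamp("2019-12-31") - pd.Timestamp("2002-01-01")).days
    event_offset = rng.integers(0, span_days + 1, n)
    event_date = pd.Timestamp("2002-01-01") + pd.to_timedelta(event_offset, unit="D")
    event_date = pd.Series(event_date).where(cvd_event, pd.NaT)

    nmr = _nmr_panel(rng, ldl_c, tg, hdl_c)

    subjects = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "his": his,
                    "statin_type": statin_type,
                    "statin_dose_mg": dose,
                    "age": age,
                    "sex": sex,
                    "bmi": bmi,
                    "latent_uptake": latent_uptake,
                    "latent_mobilization": latent_mob,
                    "ldl_prs_raw": prs,
                    "ldl_c": ldl_c,
                    "total_cholesterol": total_chol,
                    "triglycerides": tg,
                    "hdl_c": hdl_c,
                    "apob": apob,
                    "apoa1": apoa1,
                    "cvd_event": cvd_event,
                    "cvd_event_date": event_date.dt.date,
                }
            ),
            nmr,
        ],
        axis=1,
    )

    purchases = _generate_purchases(rng, subjects, config, sampling)
    diagnoses = _generate_diagnoses(rng, subjects)
    return Cohort(subjects=subjects, purchases=purchases, diagnoses=diagnoses,
                  sampling_date=sampling)


def _generate_purchases(rng, subjects: pd.DataFrame, config: CohortConfig,
                        sampling: pd.Timestamp) -> pd.DataFrame:
    rows = []
    statin = subjects[subjects["group"] == "statin"]
    for sid, stype, dose in zip(statin["subject_id"], statin["statin_type"],
                                statin["statin_dose_mg"]):
        k = config.n_purchases_before_sampling
        last_gap = rng.uniform(5.0, 120.0)
        intervals = np.clip(
            rng.normal(config.purchase_interval_days, config.purchase_interval_sd, k),
            30.0, None,
        )
        offsets = last_gap + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
        dates = [sampling - pd.Timedelta(days=round(o)) for o in offsets]
        # one refill after sampling so adherence of the last package is defined
        dates.insert(0, sampling + pd.Timedelta(days=round(intervals[-1] - last_gap)))
        for d in sorted(dates):
            rows.append((sid, d.date(), stype, dose, config.tablets_per_package))
    return pd.DataFrame(
        rows, columns=["subject_id", "purchase_date", "atc_drug", "dose_mg", "tablets"]
    )


_BACKGROUND_CODES = ("J45.0", "E11.9", "K21.9", "M54.5", "E78.0")
_CVD_CODES = ("I21.0", "I21.4", "I21.9", "I22.8", "I63.9", "I61.1")


def _generate_diagnoses(rng, subjects: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, s in subjects.iterrows():
        if s["cvd_event"]:
            rows.append((s["subject_id"], rng.choice(_CVD_CODES), s["cvd_event_date"]))
        if rng.random() < 0.30:
            offset = int(rng.integers(0, 6574))
            d = (pd.Timestamp("2002-01-01") + pd.Timedelta(days=offset)).date()
            rows.append((s["subject_id"], rng.choice(_BACKGROUND_CODES), d))
    return pd.DataFrame(rows, columns=["subject_id", "icd10_code", "date"])


# ---------------------------------------------------------------------------
# cohort-derivation rules


@dataclass(frozen=True)
class MedicationGroup:
    """Medication classification from the purchase register."""

    category: str                 # "none" | "statin-monotherapy" | "other-combination"
    statin_type: str | None = None


def select_medication_group(
    purchases: pd.DataFrame,
    sampling_date,
    window_days: int = 183,
    window_inclusive: bool = False,
) -> MedicationGroup:
    """Classify one subject's lipid-lowering medication at sampling time.

    Subjects with no purchase in the ``window_days`` before sampling are
    unmedicated; otherwise the last two purchases before sampling define the
    type (a single in-window purchase stands alone).  Two different active
    ingredients, or any non-statin product, map to other/combination.
    """
    sampling = pd.Timestamp(sampling_date)
    if len(purchases) == 0:
        return MedicationGroup("none")
    dates = pd.to_datetime(purchases["purchase_date"])
    delta = (sampling - dates).dt.days
    lower = 0 if window_inclusive else 1
    in_window = purchases[(delta >= lower) & (delta <= window_days)]
    if len(in_window) == 0:
        return MedicationGroup("none")
    last = in_window.assign(_d=pd.to_datetime(in_window["purchase_date"])) \
                    .sort_values("_d").tail(2)
    drugs = set(last["atc_drug"])
    if len(drugs) > 1 or not drugs.issubset(STATIN_TYPES):
        return MedicationGroup("other-combination")
    return MedicationGroup("statin-monotherapy", statin_type=drugs.pop())


def classify_statin_intensity(statin_type: str, dose_mg: float) -> str:
    """``"HIS"`` iff the statin/dose has >40% LDL-C-reduction potential.

    That is rosuvastatin 5-40 mg or atorvastatin 10-80 mg (inclusive);
    simvastatin is never high-intensity at marketed doses.
    """
    if statin_type not in STATIN_TYPES:
        raise ValueError(f"unknown statin type: {statin_type!r}")
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    rng_ = HIS_DOSE_RANGES.get(statin_type)
    if rng_ is not None and rng_[0] <= dose_mg <= rng_[1]:
        return "HIS"
    return "non-HIS"


def compute_adherence(tablets_in_last_package: int, days_until_next_purchase: float) -> float:
    """Tablets in the package bought before sampling / days to the next refill."""
    if days_until_next_purchase <= 0:
        raise ValueError("days_until_next_purchase must be positive")
    if tablets_in_last_package < 1:
        raise ValueError("a package contains at least one tablet")
    return tablets_in_last_package / days_until_next_purchase


def flag_cvd_event(diagnoses) -> tuple[bool, object]:
    """Whether any diagnosis code is an I2X/I6X event, plus the earliest date.

    Accepts a DataFrame with ``icd10_code``/``date`` columns or a plain
    sequence of code strings.  Malformed codes are skipped with a warning.
    Both prevalent and incident events count.
    """
    if isinstance(diagnoses, pd.DataFrame):
        codes = list(diagnoses["icd10_code"])
        dates = list(diagnoses["date"])
    else:
        codes = list(diagnoses)
        dates = [None] * len(codes)
    hits = []
    for code, date in zip(codes, dates):
        if not isinstance(code, str) or not _ICD10_RE.match(code):
            warnings.warn(f"skipping malformed ICD-10 code: {code!r}", stacklevel=2)
            continue
        if code.startswith(CVD_CODE_PREFIXES):
            hits.append(date)
    if not hits:
        return False, None
    known = [pd.Timestamp(d) for d in hits if d is not None and not pd.isna(d)]
    return True, (min(known).date() if known else None)
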