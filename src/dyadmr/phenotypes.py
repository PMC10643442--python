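"""Sleep-trait encoding: questionnaire codings, accelerometer QC, conventions.

Two questionnaire dialects are supported.  The UK-Biobank-style dialect
codes chronotype on a 1-5 ordinal scale ("Do not know" kept as the
intermediate category 3), ease of waking 1-4, insomnia frequency 1-3 and
snoring 0/1, with "Prefer not to say" (and "Do not know" outside
chronotype) treated as missing.  The 23andMe-style dialect yields binary
morningness, insomnia-diagnosis and snoring variables plus integer sleep
hours with extremes (<3 h or >12 h) excluded.

Accelerometer records are filtered by device QC flags and by an outlier
rule on recording-error counts (drop above Q3 + 1.5 * IQR, quartiles by
linear interpolation, computed over flag-clean records).

L5 timing (midpoint of the least-active 5 h) is stored as hours elapsed
from the previous midnight on a linear 12-36 h axis and only converted to
clock time for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UKB_CHRONOTYPE_LEVELS = [
    "Definitely an 'evening' person",
    "More an 'evening' than a 'morning' person",
    "Do not know",
    "More a 'morning' than 'evening' person",
    "Definitely a 'morning' person",
]
UKB_EASE_LEVELS = ["Not at all easy", "Not very easy", "Fairly easy", "Very easy"]
UKB_INSOMNIA_LEVELS = ["Never/rarely", "Sometimes", "Usually"]
_MISSING = ("Prefer not to say", "Do not know")


def _map_series(s: pd.Series, mapping: dict, missing: tuple, trait: str) -> pd.Series:
    out = pd.Series(np.nan, index=s.index, dtype=float)
    mask_missing = s.isin(missing) | s.isna()
    known = s.isin(mapping.keys())
    bad = s[~(mask_missing | known)]
    if len(bad):
        raise ValueError(
            f"unknown {trait} responses: {sorted(set(bad.astype(str)))[:10]}"
        )
    out[known] = s[known].map(mapping).astype(float)
    return out


def encode_ukb_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Encode UK-Biobank-style questionnaire responses to analysis codes.

    Expects columns chronotype, ease_of_waking, sleep_duration, insomnia,
    snoring (extra columns pass through).  Adds the derived binaries:
    evening-vs-morning chronotype (``Do not know`` excluded) and
    usually-vs-never/sometimes insomnia.
    """
    out = pd.DataFrame({"individual_id": raw["individual_id"]})
    out["chronotype"] = _map_series(
        raw["chronotype"],
        {lev: i + 1 for i, lev in enumerate(UKB_CHRONOTYPE_LEVELS)},
        ("Prefer not to say",),
        "chronotype",
    )
    out["ease_of_waking"] = _map_series(
        raw["ease_of_waking"],
        {lev: i + 1 for i, lev in enumerate(UKB_EASE_LEVELS)},
        _MISSING,
        "ease_of_waking",
    )
    dur = pd.to_numeric(
        raw["sleep_duration"].replace({m: np.nan for m in _MISSING}), errors="raise"
    )
    out["sleep_duration_h"] = dur.astype(float)
    out["insomnia"] = _map_series(
        raw["insomnia"],
        {lev: i + 1 for i, lev in enumerate(UKB_INSOMNIA_LEVELS)},
        _MISSING,
        "insomnia",
    )
    out["snoring"] = _map_series(
        raw["snoring"], {"No": 0, "Yes": 1}, _MISSING, "snoring"
    )
    out["chronotype_binary"] = out["chronotype"].map(
        {1: 0.0, 2: 0.0, 3: np.nan, 4: 1.0, 5: 1.0}
    )
    out["insomnia_binary"] = out["insomnia"].map({1: 0.0, 2: 0.0, 3: 1.0})
    out["dialect"] = "ukb"
    return out


def decode_ukb_traits(encoded: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`encode_ukb_traits` on non-missing codes."""
    out = pd.DataFrame({"individual_id": encoded["individual_id"]})
    out["chronotype"] = encoded["chronotype"].map(
        {i + 1: lev for i, lev in enumerate(UKB_CHRONOTYPE_LEVELS)}
    )
    out["ease_of_waking"] = encoded["ease_of_waking"].map(
        {i + 1: lev for i, lev in enumerate(UKB_EASE_LEVELS)}
    )
    out["sleep_duration"] = encoded["sleep_duration_h"]
    out["insomnia"] = encoded["insomnia"].map(
        {i + 1: lev for i, lev in enumerate(UKB_INSOMNIA_LEVELS)}
    )
    out["snoring"] = encoded["snoring"].map({0: "No", 1: "Yes"})
    return out


def encode_23andme_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Encode 23andMe-style survey responses.

    Binary morningness ("Morning person" vs "Night person"; "Neither",
    "It depends" and "I'm not sure" missing), insomnia diagnosis, snoring,
    and integer sleep hours restricted to [3, 12].
    """
    out = pd.DataFrame({"individual_id": raw["individual_id"]})
    out["morning_person"] = _map_series(
        raw["morning_person"],
        {"Morning person": 1, "Night person": 0},
        ("Neither", "It depends", "I'm not sure"),
        "morning_person",
    )
    out["insomnia_diagnosis"] = _map_series(
        raw["insomnia_diagnosis"],
        {"Yes": 1, "No": 0},
        ("I'm not sure",),
        "insomnia_diagnosis",
    )
    out["snoring"] = _map_series(
        raw["snoring"], {"Yes": 1, "No": 0}, ("I'm not sure",), "snoring"
    )
    hours = pd.to_numeric(raw["sleep_hours"], errors="coerce").astype(float)
    hours[(hours < 3) | (hours > 12)] = np.nan
    out["sleep_duration_h"] = hours
    out["dialect"] = "23andme"
    return out


# ---------------------------------------------------------------------------
# Accelerometer QC
# ---------------------------------------------------------------------------

QC_FLAG_COLUMNS = (
    "data_problem",
    "poor_wear",
    "poor_calibration",
    "calibration_other_data",
)
QC_COUNT_COLUMNS = ("recording_errors", "interrupted_periods", "interrupted_duration")


@dataclass
class QcResult:
    retained: pd.DataFrame
    dropped: pd.DataFrame  # individual_id, rule
    thresholds: dict


def accelerometer_qc(records: pd.DataFrame) -> QcResult:
    """Device-flag and outlier QC for accelerometer summaries.

    Flagged records are dropped first; the Q3 + 1.5*IQR outlier thresholds
    for the error-count variables are then computed over the flag-clean
    records (linear-interpolation quartiles) and exceeders dropped.
    """
    for c in QC_FLAG_COLUMNS + QC_COUNT_COLUMNS:
        if c not in records.columns:
            raise KeyError(f"accelerometer table is missing QC column {c!r}")
    drops: list[dict] = []
    df = records.copy()
    for c in QC_FLAG_COLUMNS:
        hit = df[c].astype(bool)
        drops.extend(
            dict(individual_id=i, rule=c) for i in df.loc[hit, "individual_id"]
        )
        df = df[~hit]
    thresholds = {}
    keep = np.ones(len(df), dtype=bool)
    for c in QC_COUNT_COLUMNS:
        vals = df[c].to_numpy(dtype=float)
        if len(vals) == 0:
            continue
        q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation
        thr = q3 + 1.5 * (q3 - q1)
        thresholds[c] = float(thr)
        over = vals > thr
        for i in df.loc[over, "individual_id"]:
            drops.append(dict(individual_id=i, rule=c))
        keep &= ~over
    retained = df[keep].reset_index(drop=True)
    return QcResult(
        retained, pd.DataFrame(drops, columns=["individual_id", "rule"]), thresholds
    )


# ---------------------------------------------------------------------------
# L5 clock convention and standardisation
# ---------------------------------------------------------------------------


def l5_to_clock(hours_from_midnight: float) -> tuple[int, int, str]:
    """Render an L5 midpoint (hours from the previous midnight) as clock time.

    Values >= 24 wrap into the following morning; minutes are rounded to
    the nearest whole minute.  27.3 -> (3, 18, 'am').
    """
    h = float(hours_from_midnight)
    if not 12.0 <= h < 36.0:
        raise ValueError("L5 timing must lie in [12, 36) hours from previous midnight")
    t = h - 24.0 if h >= 24.0 else h
    minutes = int(round(t * 60))
    hh, mm = divmod(minutes, 60)
    hh %= 24
    ampm = "am" if hh < 12 else "pm"
    display = hh % 12
    if display == 0:
        display = 12
    return display, mm, ampm


def format_l5(hours_from_midnight: float) -> str:
    h, m, ampm = l5_to_clock(hours_from_midnight)
    return f"{h}:{m:02d} {ampm}"


def standardize_traits(values) -> np.ndarray:
    """Z-score a trait vector over its non-missing entries (sample SD).

    Computed on the analysis sample after pairing and complete-case
    restriction, so regression slopes are in SD-per-SD units.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: trait cannot be standardized")
    return (x - obs.mean()) / sd
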