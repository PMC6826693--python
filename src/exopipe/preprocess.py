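"""CT preprocessing: reliability filtering, global-mean normalization,
detection-rate filtering, imputation and the CV diagnostic.

The fixed stage order is reliability filter → global-mean normalization →
detection filter → imputation.  Detection uses strict CT < ceiling while
the reliability window keeps CT == ct_max; the two boundaries are
configurable independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CTMatrix, NormalizedMatrix, split_sample_id


def filter_reliable_ct(
    ct: CTMatrix, ct_min: float = 14.0, ct_max: float = 32.0
) -> CTMatrix:
    """Mask unreliable wells: CT > ct_max or CT < ct_min become missing.

    CT values at the window boundaries are kept.  Mirrors instrument
    guidance that very late or very early threshold cycles are
    experiment failures rather than measurements.
    """
    if ct_min >= ct_max:
        raise ValueError("ct_min must be < ct_max")
    vals = ct.ct.copy()
    unreliable = (vals > ct_max) | (vals < ct_min)
    return CTMatrix(vals.mask(unreliable))


def normalize_global_mean(
    ct: CTMatrix, detection_ceiling: float = 32.0
) -> NormalizedMatrix:
    """Global-mean normalization: ΔCT = CT − mean of the sample's detected CTs.

    A well is detected when its CT is strictly below ``detection_ceiling``;
    only detected wells enter the per-sample global mean.  Missing wells
    stay missing.  A sample with fewer than two detected assays makes the
    global mean degenerate and is a hard error naming the sample.
    """
    vals = ct.ct
    detected = vals.notna() & (vals < detection_ceiling)
    n_det = detected.sum(axis=1)
    bad = n_det[n_det < 2]
    if len(bad):
        raise ValueError(
            f"sample {bad.index[0]!r} has {int(bad.iloc[0])} detected assays; "
            "at least 2 are required for global-mean normalization"
        )
    global_mean = vals.where(detected).mean(axis=1)
    delta = vals.sub(global_mean, axis=0)
    imputed = pd.DataFrame(False, index=vals.index, columns=vals.columns)
    # undetected-but-measured wells (CT >= ceiling) keep their ΔCT but are
    # flagged neither detected nor imputed; downstream stages ignore them
    return NormalizedMatrix(delta.fillna(np.nan), detected, imputed)


def count_detected(norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-sample detected-assay counts plus per-timepoint mean and SD.

    Returns columns ``sample, timepoint, n_detected``; the per-timepoint
    summary (mean, SD across samples) is attached as ``.attrs["by_timepoint"]``.
    """
    counts = norm.detected.sum(axis=1)
    tps = [split_sample_id(s)[1] for s in norm.samples]
    out = pd.DataFrame(
        {"sample": norm.samples, "timepoint": tps, "n_detected": counts.to_numpy()}
    )
    summary = (
        out.groupby("timepoint")["n_detected"].agg(["mean", "std"]).reset_index()
    )
    out.attrs["by_timepoint"] = summary
    return out


def detection_filter(
    norm: NormalizedMatrix, detection_fraction: float = 0.80
) -> tuple[NormalizedMatrix, list[str]]:
    """Keep assays detected in at least ``detection_fraction`` of samples.

    The fraction is computed over all samples pooled (both timepoints);
    the boundary is inclusive (exactly 80% is kept).  Returns the reduced
    matrix and the list of dropped assays.
    """
    if not (0 < detection_fraction <= 1):
        raise ValueError("detection_fraction must be in (0, 1]")
    frac = norm.detected.mean(axis=0)
    keep = frac[frac >= detection_fraction].index
    dropped = [m for m in norm.mirnas if m not in set(keep)]
    reduced = NormalizedMatrix(
        norm.delta_ct[keep].copy(), norm.detected[keep].copy(), norm.imputed[keep].copy()
    )
    return reduced, dropped


def impute_missing(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Impute undetected wells at the assay's lowest expression minus one
    log2 unit, i.e. one ΔCT unit above that miRNA's highest observed ΔCT.

    Observed (detected) values are never modified.  An assay with no
    detected value anywhere has no reference level and is a hard error —
    the detection filter should have removed it.
    """
    delta = norm.delta_ct.copy()
    detected = norm.detected
    n_obs = detected.sum(axis=0)
    empty = n_obs[n_obs == 0]
    if len(empty):
        raise ValueError(
            f"miRNA {empty.index[0]!r} has no detected value to impute from; "
            "run detection_filter first"
        )
    ceiling = delta.where(detected).max(axis=0) + 1.0
    fill = ~detected
    delta = delta.where(detected, ceiling, axis=1)
    imputed = norm.imputed | fill
    return NormalizedMatrix(delta, detected.copy(), imputed)


@dataclass
class CVReport:
    """Per-assay coefficients of variation and the raw-vs-normalized
    Kolmogorov–Smirnov comparison."""

    cv_raw: pd.Series
    cv_normalized: pd.Series
    ks_statistic: float
    ks_pvalue: float


def cv(values) -> float:
    """Coefficient of variation sd/|mean| (sample SD) of a 1-D collection."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return float("nan")
    mean = v.mean()
    if mean == 0:
        warnings.warn("zero mean; CV undefined", stacklevel=2)
        return float("nan")
    return float(v.std(ddof=1) / abs(mean))


def _cv_of_frame(values: pd.DataFrame) -> pd.Series:
    """Per-column CV = sample SD / |mean| over observed entries.

    Columns with < 2 observed values, or a mean of zero, yield NaN
    (with a warning for the zero-mean case — possible on the ΔCT scale).
    """
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    n = values.notna().sum(axis=0)
    cv = sd / mean.abs()
    cv[n < 2] = np.nan
    zero_mean = (mean == 0) & (n >= 2)
    if zero_mean.any():
        warnings.warn(
            f"{int(zero_mean.sum())} assay(s) have zero mean; CV undefined",
            stacklevel=2,
        )
        cv[zero_mean] = np.nan
    return cv


def coefficient_of_variation(
    raw: CTMatrix, norm: NormalizedMatrix, scale: str = "linear"
) -> CVReport:
    """CV diagnostic for normalization quality.

    Computes per-assay CVs before and after normalization (observed wells
    only) and compares the two CV distributions with a two-sample
    Kolmogorov–Smirnov test; effective normalization shifts the
    normalized CV distribution toward zero.

    With the default ``scale="linear"``, CVs are taken on relative
    quantities (2^−CT and 2^−ΔCT) — the convention of the global-mean
    normalization literature, and the scale on which per-assay means
    cannot vanish.  ``scale="ct"`` computes CVs directly on CT/ΔCT,
    where a near-zero ΔCT mean makes the CV undefined.
    """
    raw_vals = raw.ct
    norm_vals = norm.delta_ct.where(norm.detected)
    if scale == "linear":
        raw_vals = np.exp2(-raw_vals)
        norm_vals = np.exp2(-norm_vals)
    elif scale != "ct":
        raise ValueError(f"unknown scale {scale!r}; expected 'linear' or 'ct'")
    cv_raw = _cv_of_frame(raw_vals)
    cv_norm = _cv_of_frame(norm_vals)
    a = cv_raw.dropna().to_numpy()
    b = cv_norm.dropna().to_numpy()
    if len(a) and len(b):
        ks = stats.ks_2samp(a, b)
        stat, p = float(ks.statistic), float(ks.pvalue)
    else:
        stat, p = np.nan, np.nan
    return CVReport(cv_raw, cv_norm, stat, p)
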