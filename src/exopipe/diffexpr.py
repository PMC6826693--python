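"""Paired onset-vs-end differential expression on the ΔCT scale.

Fold change is reported as −ΔΔCT = −(mean ΔCT_end − mean ΔCT_onset), so a
negative fold change means the miRNA is downregulated after induction
chemotherapy.  Relative quantity RQ = 2^(−ΔCT) is the linear-scale
expression relative to the sample's global mean.  Significance combines a
per-miRNA paired (or unpaired) t-test with Benjamini–Hochberg adjustment
and a |−ΔΔCT| >= log2(1.5) magnitude rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import NormalizedMatrix, split_sample_id


def fold_change(mean_dct_onset, mean_dct_end):
    """−ΔΔCT = −(mean ΔCT_end − mean ΔCT_onset); negative = downregulated
    after therapy."""
    return -(np.asarray(mean_dct_end, dtype=float) - np.asarray(mean_dct_onset, dtype=float))


def relative_quantity(delta_ct):
    """RQ = 2^(−ΔCT); strictly decreasing in ΔCT."""
    return np.exp2(-np.asarray(delta_ct, dtype=float))


def _timepoint_frames(norm: NormalizedMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔCT frames (patients x miRNAs) at onset and end; wells that are
    neither detected nor imputed are masked out."""
    usable = norm.delta_ct.where(norm.detected | norm.imputed)
    frames = {}
    for tp in ("onset", "end"):
        samples = norm.samples_at(tp)
        sub = usable.loc[samples]
        sub.index = [split_sample_id(s)[0] for s in samples]
        frames[tp] = sub
    return frames["onset"], frames["end"]


def paired_test(
    norm: NormalizedMatrix, paired: bool = True, min_pairs: int = 3
) -> pd.Series:
    """Per-miRNA two-sided t-test of ΔCT(end) vs ΔCT(onset).

    Paired mode tests end − onset across patients with both timepoints
    (patients missing either are excluded per miRNA); unpaired mode is a
    Welch test across all samples at each timepoint.  miRNAs with fewer
    than ``min_pairs`` complete pairs (or per-group observations) get a
    missing p with a warning.  Zero-variance, zero-difference data yield
    p = 1.
    """
    onset, end = _timepoint_frames(norm)
    pvals = {}
    short = []
    for m in norm.mirnas:
        if paired:
            both = onset.index.intersection(end.index)
            a = onset.loc[both, m].to_numpy(dtype=float)
            b = end.loc[both, m].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(b)
            a, b = a[ok], b[ok]
            if len(a) < min_pairs:
                pvals[m] = np.nan
                short.append(m)
                continue
            d = b - a
            if np.allclose(d, 0):
                pvals[m] = 1.0
                continue
            res = stats.ttest_rel(b, a)
        else:
            a = onset[m].dropna().to_numpy(dtype=float)
            b = end[m].dropna().to_numpy(dtype=float)
            if min(len(a), len(b)) < min_pairs:
                pvals[m] = np.nan
                short.append(m)
                continue
            if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                pvals[m] = 1.0
                continue
            res = stats.ttest_ind(b, a, equal_var=False)
        p = float(res.pvalue)
        pvals[m] = 1.0 if not np.isfinite(p) else p
    if short:
        warnings.warn(
            f"{len(short)} assay(s) had too few complete observations for a "
            f"t-test (first: {short[0]!r})",
            stacklevel=2,
        )
    return pd.Series(pvals, name="p_raw")


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (monotone, capped at 1).

    NaN entries propagate and do not count toward the number of tests.
    """
    p = np.asarray(p_raw, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def differential_expression(
    norm: NormalizedMatrix, paired: bool = True, min_pairs: int = 3
) -> pd.DataFrame:
    """Per-miRNA differential-expression table.

    Mean ΔCTs at each timepoint are computed over all patients with data
    at that timepoint; the t-test uses complete pairs (paired mode).
    Columns: mean_dct_onset, mean_dct_end, rq_onset, rq_end, fold_change,
    p_raw, p_adj.
    """
    onset, end = _timepoint_frames(norm)
    mean_onset = onset.mean(axis=0)
    mean_end = end.mean(axis=0)
    table = pd.DataFrame(
        {
            "mean_dct_onset": mean_onset,
            "mean_dct_end": mean_end,
            "rq_onset": relative_quantity(mean_onset),
            "rq_end": relative_quantity(mean_end),
            "fold_change": fold_change(mean_onset, mean_end),
        }
    )
    table["p_raw"] = paired_test(norm, paired=paired, min_pairs=min_pairs)
    table["p_adj"] = bh_adjust(table["p_raw"])
    table.index.name = "mirna"
    return table


def significance_filter(
    table: pd.DataFrame,
    fc_threshold_log2: float = 0.58,
    alpha: float = 0.05,
    adjusted: bool = True,
) -> pd.DataFrame:
    """Keep miRNAs with |fold_change| >= threshold (inclusive) and
    adjusted p < alpha; adds a ``direction`` column (up/down)."""
    pcol = "p_adj" if adjusted else "p_raw"
    keep = (table["fold_change"].abs() >= fc_threshold_log2) & (table[pcol] < alpha)
    out = table.loc[keep.fillna(False)].copy()
    out["direction"] = np.where(out["fold_change"] > 0, "up", "down")
    return out


def round_display(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Display rounding (half away from zero) for RQ/FC columns, mirroring
    the conventional published layout of such tables."""

    def _round(x: float) -> float:
        scale = 10**decimals
        return np.sign(x) * np.floor(np.abs(x) * scale + 0.5) / scale

    out = table.copy()
    for col in ("mean_dct_onset", "mean_dct_end", "rq_onset", "rq_end"):
        if col in out:
            out[col] = out[col].map(_round)
    if "fold_change" in out:
        out["fold_change"] = out["fold_change"].map(
            lambda x: np.sign(x) * np.floor(np.abs(x) * 10 + 0.5) / 10
        )
    return out
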