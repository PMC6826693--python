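"""Batch-effect assessment: PCA and principal variance component analysis.

PVCA decomposes the variance of the leading principal components of the
expression matrix into contributions from a technical batch factor (here
the center/country of origin), biological factors (age, INSS stage, MYCN
status) and their pairwise interactions, by fitting a random-effects
variance-components model to each retained PC.  The per-factor
proportions are averaged across PCs with eigenvalue weights, giving the
weighted average proportion variance (WAPV).  A batch WAPV below 5% is
conventionally treated as a negligible batch effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import NormalizedMatrix, split_sample_id

DEFAULT_BIO_FACTORS = ("age", "inss_stage", "mycn")


def _require_complete(norm: NormalizedMatrix) -> pd.DataFrame:
    known = norm.detected | norm.imputed
    if not known.to_numpy().all():
        raise ValueError(
            "matrix has wells that are neither detected nor imputed; "
            "run impute_missing before PCA/PVCA"
        )
    return norm.delta_ct


def run_pca(norm: NormalizedMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the samples on centered ΔCT.

    Returns (scores, eigenvalues): scores is samples x PCs, eigenvalues
    are the variances of the covariance of the column-centered matrix,
    nonincreasing; their sum equals the total centered variance.
    """
    delta = _require_complete(norm)
    x = delta.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / max(n - 1, 1)
    scores = pd.DataFrame(
        u * s,
        index=delta.index,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return scores, eigenvalues


@dataclass
class PVCAResult:
    """Weighted average proportion variance per factor.

    ``wapv`` sums to 1 across factors + interactions + residual.
    ``fallback_pcs`` lists PCs whose variance-components fit fell back to
    the method-of-moments estimator.
    """

    factors: list[str]
    wapv: pd.Series
    n_components: int
    retained_variance_fraction: float
    per_pc_proportions: pd.DataFrame | None = None
    fallback_pcs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = float(self.wapv.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"WAPV proportions must sum to 1, got {total}")
        if ((self.wapv < -1e-12) | (self.wapv > 1 + 1e-12)).any():
            raise ValueError("WAPV proportions must lie in [0, 1]")


def _factor_frame(
    norm: NormalizedMatrix,
    clinical: pd.DataFrame,
    factors: list[str],
    age_bins: int = 3,
) -> pd.DataFrame:
    """Per-sample factor levels as strings; missing levels become "NA".

    Continuous age (months) is binned into quantile groups so it can act
    as a random-effect grouping factor.
    """
    patients = [split_sample_id(s)[0] for s in norm.samples]
    missing = sorted(set(patients) - set(clinical.index.astype(str)))
    if missing:
        raise ValueError(f"patients absent from clinical table: {missing[:5]}")
    rows = clinical.loc[patients]
    out = pd.DataFrame(index=norm.samples)
    for f in factors:
        if f == "timepoint":
            # design factor derived from the sample id, not the clinical table
            out[f] = [split_sample_id(s)[1] for s in norm.samples]
            continue
        if f not in rows.columns:
            raise ValueError(f"factor {f!r} not in clinical table")
        col = rows[f]
        if f == "age":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                binned = pd.qcut(col.astype(float), q=age_bins, duplicates="drop")
            col = binned.astype(str)
        vals = col.astype(str).to_numpy()
        vals = np.where(pd.isna(col.to_numpy()) | (vals == "nan"), "NA", vals)
        out[f] = vals
    return out


def _vc_method_of_moments(y: np.ndarray, levels) -> float:
    """One-way ANOVA estimate of a factor's variance component, clamped
    at zero.  Used as a per-factor fallback when REML fails."""
    s = pd.Series(np.asarray(y, dtype=float))
    lab = np.asarray(levels, dtype=object)
    n = len(s)
    k = len(pd.unique(lab))
    if k < 2 or n <= k:
        return 0.0
    grand = s.mean()
    g = s.groupby(lab)
    sizes = g.size().to_numpy(dtype=float)
    means = g.mean()
    ssb = float((sizes * (means.to_numpy() - grand) ** 2).sum())
    ssw = float(((s.to_numpy() - means.loc[lab].to_numpy()) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    return float(max(0.0, (msb - msw) / n0))


def _fit_pc_variance_components(
    y: np.ndarray, design: pd.DataFrame, terms: list[str]
) -> tuple[dict[str, float], float, bool]:
    """Variance components of one PC under independent random effects.

    Returns (per-term variance, residual variance, used_fallback).
    REML via a mixed model with each term as a variance component; on
    failure or non-convergence, per-factor method-of-moments estimates.
    """
    df = design.copy()
    df["_y"] = y
    df["_all"] = 1
    vc: dict[str, str] = {}
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            vc[t] = f"0 + C({a}):C({b})"
        else:
            vc[t] = f"0 + C({t})"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                "_y ~ 1", groups="_all", vc_formula=vc, data=df
            )
            fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        if not np.all(np.isfinite(fit.params)):
            raise RuntimeError("non-finite parameters")
        # vcomp follows the model's (sorted) component names, not dict order
        comps = {
            name: max(0.0, float(fit.vcomp[i]))
            for i, name in enumerate(model.exog_vc.names)
        }
        resid = max(0.0, float(fit.scale))
        return comps, resid, False
    except Exception:
        comps = {}
        for t in terms:
            if ":" in t:
                a, b = t.split(":")
                levels = (design[a].astype(str) + ":" + design[b].astype(str)).to_numpy()
            else:
                levels = design[t].astype(str).to_numpy()
            comps[t] = _vc_method_of_moments(y, levels)
        resid = max(float(np.var(y, ddof=1)) - sum(comps.values()), 1e-12)
        return comps, resid, True


def run_pvca(
    norm: NormalizedMatrix,
    clinical: pd.DataFrame,
    batch_factor: str = "origin",
    bio_factors: tuple[str, ...] = DEFAULT_BIO_FACTORS,
    pc_variance_target: float = 0.6,
    include_interactions: bool = True,
) -> PVCAResult:
    """Principal variance component analysis.

    Retains the smallest set of leading PCs reaching
    ``pc_variance_target`` cumulative variance, fits a
    variance-components model to each (all factors and eligible pairwise
    interactions as independent random effects), converts the components
    of each PC to proportions, and averages proportions over PCs with
    eigenvalue weights, renormalizing to sum to one.
    """
    scores, eigenvalues = run_pca(norm)
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("matrix has no variance")
    cum = np.cumsum(eigenvalues) / total
    k = int(np.searchsorted(cum, pc_variance_target) + 1)
    k = min(k, len(eigenvalues))

    factors = [batch_factor, *bio_factors]
    design = _factor_frame(norm, clinical, factors)

    n_levels = {f: design[f].nunique() for f in factors}
    terms = []
    single_level = [f for f in factors if n_levels[f] < 2]
    for f in single_level:
        warnings.warn(
            f"factor {f!r} has a single level; its variance component is 0",
            stacklevel=2,
        )
    terms.extend(f for f in factors if n_levels[f] >= 2)
    if include_interactions:
        multi = [f for f in factors if n_levels[f] >= 2]
        for i, a in enumerate(multi):
            for b in multi[i + 1 :]:
                cells = (design[a] + ":" + design[b]).nunique()
                if cells >= 2 and cells < len(design):
                    terms.append(f"{a}:{b}")

    all_terms = terms + single_level
    weights = eigenvalues[:k] / eigenvalues[:k].sum()
    per_pc = []
    fallback_pcs = []
    for i in range(k):
        pc = f"PC{i + 1}"
        y = scores[pc].to_numpy(dtype=float)
        comps, resid, fell_back = _fit_pc_variance_components(y, design, terms)
        if fell_back:
            fallback_pcs.append(pc)
        for f in single_level:
            comps[f] = 0.0
        denom = sum(comps.values()) + resid
        props = {t: comps.get(t, 0.0) / denom for t in all_terms}
        props["residual"] = resid / denom
        per_pc.append(pd.Series(props, name=pc))

    per_pc_df = pd.DataFrame(per_pc)
    wapv = per_pc_df.mul(weights, axis=0).sum(axis=0)
    wapv = wapv / wapv.sum()
    return PVCAResult(
        factors=list(wapv.index),
        wapv=wapv,
        n_components=k,
        retained_variance_fraction=float(cum[k - 1]),
        per_pc_proportions=per_pc_df,
        fallback_pcs=fallback_pcs,
    )


def assess_batch_effect(
    result: PVCAResult, batch_factor: str = "origin", threshold: float = 0.05
) -> str:
    """Classify the batch contribution: "negligible" if WAPV(batch) is
    strictly below the threshold, "significant" otherwise (the boundary
    counts as significant — a conservative reading)."""
    if batch_factor not in result.wapv.index:
        raise ValueError(f"batch factor {batch_factor!r} not in PVCA result")
    return "negligible" if result.wapv[batch_factor] < threshold else "significant"
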