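"""Elastic-net selection of response-discriminating exo-miRNAs.

Patients with clearly poor (MR) and clearly good (VGPR) induction
response are contrasted on per-patient fold changes (−ΔΔCT, end vs
onset).  An elastic-net-penalized linear model (squared-error loss,
mixing 0.7) is fit along a log-spaced penalty grid; the penalty is chosen
by leave-one-out cross-validated mean squared prediction error, and the
assays with nonzero coefficients at that penalty form the signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path

from .datatypes import NormalizedMatrix
from .diffexpr import fold_change


def patient_fold_changes(norm: NormalizedMatrix) -> pd.DataFrame:
    """Per-patient, per-miRNA −ΔΔCT (end vs onset).

    Only patients with both timepoints contribute; wells that are
    neither detected nor imputed are treated as missing.
    """
    usable = norm.delta_ct.where(norm.detected | norm.imputed)
    onset_samples = {s.rsplit(":", 1)[0]: s for s in norm.samples_at("onset")}
    end_samples = {s.rsplit(":", 1)[0]: s for s in norm.samples_at("end")}
    patients = [p for p in onset_samples if p in end_samples]
    rows = {}
    for p in patients:
        rows[p] = fold_change(
            usable.loc[onset_samples[p]], usable.loc[end_samples[p]]
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=norm.mirnas)


def build_design(
    norm: NormalizedMatrix,
    clinical: pd.DataFrame,
    groups: tuple[str, str] = ("MR", "VGPR"),
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Design matrix for response-group contrast.

    One row per patient in either group (patients outside the two groups,
    e.g. PR or unannotated, are excluded); features are per-miRNA fold
    changes standardized to zero mean / unit variance (constant features
    dropped with a warning); labels are 1 for the first group (poor
    response) and 0 for the second.  Returns (X, y, scaling) where
    scaling holds the per-feature mean and SD used.
    """
    fc = patient_fold_changes(norm)
    resp = clinical["induction_response"]
    chosen = [p for p in fc.index if p in resp.index and resp[p] in groups]
    fc = fc.loc[chosen].dropna(axis=1)
    y = pd.Series(
        [1.0 if resp[p] == groups[0] else 0.0 for p in chosen],
        index=chosen,
        name="label",
    )
    for g, val in zip(groups, (1.0, 0.0)):
        if int((y == val).sum()) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 patients")
    mean = fc.mean(axis=0)
    sd = fc.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant feature(s) (first: "
            f"{constant[0]!r})",
            stacklevel=2,
        )
        fc = fc.drop(columns=constant)
        mean = mean.drop(constant)
        sd = sd.drop(constant)
    X = (fc - mean) / sd
    scaling = pd.DataFrame({"mean": mean, "sd": sd})
    return X, y, scaling


@dataclass
class SignatureResult:
    """Selected features and the LOOCV penalty path behind them."""

    selected_mirnas: list[str]
    coefficients: pd.Series
    penalty_grid: np.ndarray
    chosen_penalty: float
    loocv_mse_per_penalty: np.ndarray
    intercept: float


def make_penalty_grid(
    X: np.ndarray, y: np.ndarray, mixing: float, n_penalties: int = 100,
    decades: float = 4.0,
) -> np.ndarray:
    """Log-spaced penalty grid from λ_max (the smallest penalty zeroing
    every coefficient) down ``decades`` orders of magnitude."""
    n = X.shape[0]
    yc = y - y.mean()
    xc = X - X.mean(axis=0)
    lam_max = np.max(np.abs(xc.T @ yc)) / (n * mixing)
    if lam_max <= 0:
        raise ValueError("labels are constant; no penalty grid exists")
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_penalties)


def fit_elastic_net_loocv(
    X,
    y,
    mixing: float = 0.7,
    penalty_grid: np.ndarray | None = None,
) -> SignatureResult:
    """Elastic net with the penalty chosen by leave-one-out CV.

    The model minimizes ||y − Xw − b||²/(2n) + λ[mixing·||w||₁ +
    (1−mixing)/2·||w||²].  For each λ on the grid, leave-one-out
    predictions are computed (via the coordinate-descent path per fold);
    λ minimizing the mean squared prediction error is kept, ties broken
    toward the larger (sparser) penalty, and the model refit on all data.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations for LOOCV selection")
    if not (0 < mixing <= 1):
        raise ValueError("mixing must be in (0, 1]")
    if np.ptp(y) == 0:
        raise ValueError("all labels identical; nothing to separate")
    if penalty_grid is None:
        penalty_grid = make_penalty_grid(X, y, mixing)
    penalty_grid = np.asarray(penalty_grid, dtype=float)
    if penalty_grid.size == 0:
        raise ValueError("empty penalty grid")
    order = np.argsort(penalty_grid)[::-1]  # enet_path wants decreasing alphas
    grid = penalty_grid[order]

    sq_err = np.zeros((n, len(grid)))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        _, coefs, _ = enet_path(
            Xtr - xm, ytr - ym, l1_ratio=mixing, alphas=grid
        )
        pred = (X[i] - xm) @ coefs + ym
        sq_err[i] = (pred - y[i]) ** 2
    mse = sq_err.mean(axis=0)
    # ties toward the larger penalty = earliest index in the decreasing grid
    best = int(np.flatnonzero(mse <= mse.min() + 1e-12)[0])
    lam = float(grid[best])

    model = ElasticNet(
        alpha=lam, l1_ratio=mixing, fit_intercept=True, max_iter=100_000, tol=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    coef = pd.Series(model.coef_, index=feature_names)
    selected = list(coef.index[coef != 0])
    # report the curve on the caller's grid order
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return SignatureResult(
        selected_mirnas=selected,
        coefficients=coef[coef != 0],
        penalty_grid=penalty_grid,
        chosen_penalty=lam,
        loocv_mse_per_penalty=mse[inv],
        intercept=float(model.intercept_),
    )


def select_signature(
    norm: NormalizedMatrix,
    clinical: pd.DataFrame,
    groups: tuple[str, str] = ("MR", "VGPR"),
    mixing: float = 0.7,
) -> tuple[SignatureResult, pd.DataFrame]:
    """End-to-end signature selection from a normalized matrix; returns
    the result plus the feature scaling used."""
    X, y, scaling = build_design(norm, clinical, groups)
    result = fit_elastic_net_loocv(X, y, mixing=mixing)
    return result, scaling


def mannwhitney_by_group(values: pd.Series, groups: pd.Series) -> float:
    """Two-sided Mann–Whitney U p value between the two groups defined by
    a binary label series (aligned on index)."""
    common = values.index.intersection(groups.index)
    v = values.loc[common]
    g = groups.loc[common]
    labels = pd.unique(g.dropna())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    a = v[g == labels[0]].dropna()
    b = v[g == labels[1]].dropna()
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def evaluate_signature_separation(
    norm: NormalizedMatrix,
    clinical: pd.DataFrame,
    signature: list[str],
    groups: tuple[str, str] = ("MR", "VGPR"),
) -> dict:
    """Project patients onto the signature and report group separation.

    Returns a dict with the per-patient PCA scores of the signature
    fold-change submatrix, per-miRNA group means and medians, and a
    standardized two-group separation statistic (Cohen's d on PC1).
    """
    if not signature:
        raise ValueError("signature is empty")
    fc = patient_fold_changes(norm)[signature]
    resp = clinical["induction_response"]
    chosen = [p for p in fc.index if p in resp.index and resp[p] in groups]
    fc = fc.loc[chosen].dropna()
    labels = resp.loc[fc.index]

    x = fc.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = pd.DataFrame(
        u * s, index=fc.index, columns=[f"PC{i + 1}" for i in range(len(s))]
    )
    pc1 = scores["PC1"]
    a = pc1[labels == groups[0]]
    b = pc1[labels == groups[1]]
    pooled = np.sqrt((a.var(ddof=1) * (len(a) - 1) + b.var(ddof=1) * (len(b) - 1))
                     / max(len(a) + len(b) - 2, 1))
    diff = abs(a.mean() - b.mean())
    if pooled > 0:
        separation = float(diff / pooled)
    else:
        separation = 0.0 if diff < 1e-12 else float("inf")
    group_medians = fc.groupby(labels.to_numpy()).median()
    group_means = fc.groupby(labels.to_numpy()).mean()
    return {
        "scores": scores,
        "labels": labels,
        "group_means": group_means,
        "group_medians": group_medians,
        "separation": separation,
    }
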