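"""Chemoresistance index (CI), patient stratification and survival.

For each patient and drug, the CI is the Laplace-smoothed fraction of the
drug's literature-linked miRNAs whose post-treatment modulation direction
(sign of the patient-level −ΔΔCT) matches the resistance-associated
direction: CI = (m + 1) / (M + 2) with m concordant out of M listed.
Patients are then stratified by k-means on their drug-CI profile, the
cluster with the higher mean CI on carboplatin/cisplatin/doxorubicin is
labeled poor-responder-like, and the clusters are tested for association
with clinical covariates (two-proportion z-tests) and 3-year event-free
survival (Kaplan–Meier + log-rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.proportion import proportions_ztest

from .datatypes import (
    PROGNOSTIC_DRUGS,
    ChemoresistanceList,
    NormalizedMatrix,
    canonical_mirna,
)
from .signature import patient_fold_changes


def modulation_directions(
    norm: NormalizedMatrix, magnitude_threshold: float = 0.0
) -> pd.DataFrame:
    """Per (patient, miRNA) modulation upon treatment: "up", "down" or "none".

    Direction is the sign of the patient-level −ΔΔCT; exactly zero (or an
    unevaluable well) is "none".  An optional magnitude threshold turns
    sub-threshold modulation into "none" (strict mode).  Patients missing
    a timepoint are excluded with a warning.
    """
    fc = patient_fold_changes(norm)
    all_patients = norm.patients
    excluded = [p for p in all_patients if p not in fc.index]
    if excluded:
        warnings.warn(
            f"{len(excluded)} patient(s) lack one timepoint and were "
            f"excluded (first: {excluded[0]!r})",
            stacklevel=2,
        )
    vals = fc.to_numpy(dtype=float)
    out = np.full(vals.shape, "none", dtype=object)
    out[np.isfinite(vals) & (vals > magnitude_threshold)] = "up"
    out[np.isfinite(vals) & (vals < -magnitude_threshold)] = "down"
    return pd.DataFrame(out, index=fc.index, columns=fc.columns)


@dataclass
class CIMatrix:
    """Patient x drug chemoresistance probabilities with their counts.

    ``ci`` holds (m+1)/(M+2) per cell; ``concordant`` and ``list_size``
    hold m and M.  Drugs with an empty miRNA list are excluded (their
    smoothed value would be the uninformative 1/2) and reported in
    ``excluded_drugs``.
    """

    ci: pd.DataFrame
    concordant: pd.DataFrame
    list_size: pd.DataFrame
    excluded_drugs: list[str] = field(default_factory=list)
    unmatched_mirnas: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.concordant.to_numpy(dtype=float)
        M = self.list_size.to_numpy(dtype=float)
        expect = (m + 1) / (M + 2)
        if not np.allclose(self.ci.to_numpy(dtype=float), expect):
            raise ValueError("ci must equal (m+1)/(M+2) cell-wise")
        if np.any(m > M):
            raise ValueError("concordant count cannot exceed list size")


def chemoresistance_index(
    directions: pd.DataFrame, clist: ChemoresistanceList
) -> CIMatrix:
    """Laplace-smoothed chemoresistance probability per patient and drug.

    m counts the drug's listed miRNAs whose patient direction matches the
    listed resistance direction; listed miRNAs absent from the expression
    matrix are excluded from both m and M (logged per drug).
    """
    from .datatypes import DRUGS

    if not clist.drugs_with_entries():
        raise ValueError("chemoresistance list has no drug with entries")
    col_by_key = {canonical_mirna(c): c for c in directions.columns}
    ci = {}
    mm = {}
    MM = {}
    unmatched: dict[str, list[str]] = {}
    excluded: list[str] = []
    for drug in DRUGS:
        wanted = clist.by_drug(drug)
        present = {k: v for k, v in wanted.items() if k in col_by_key}
        absent = sorted(set(wanted) - set(present))
        if absent:
            unmatched[drug] = absent
        M = len(present)
        if M == 0:
            excluded.append(drug)
            continue
        cols = [col_by_key[k] for k in present]
        target = np.array([present[k] for k in present], dtype=object)
        m = (directions[cols].to_numpy(dtype=object) == target).sum(axis=1)
        m = pd.Series(m, index=directions.index)
        mm[drug] = m
        MM[drug] = pd.Series(M, index=directions.index)
        ci[drug] = (m + 1) / (M + 2)
    if not ci:
        raise ValueError("no listed miRNA is present in the expression matrix")
    return CIMatrix(
        ci=pd.DataFrame(ci),
        concordant=pd.DataFrame(mm),
        list_size=pd.DataFrame(MM),
        excluded_drugs=excluded,
        unmatched_mirnas=unmatched,
    )


@dataclass
class ClusterAssignment:
    """Two-way patient stratification on the drug-CI profile.

    Cluster labels are 1/2 with cluster 1 the poor-responder-like group
    (higher mean CI on the prognostic drugs).
    """

    labels: pd.Series
    centroids: pd.DataFrame
    poor_responder_cluster: int = 1
    inertia: float = float("nan")


def kmeans_stratify(
    ci: CIMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
    prognostic_drugs: tuple[str, ...] = PROGNOSTIC_DRUGS,
) -> ClusterAssignment:
    """Euclidean k-means on the raw CI profiles (already on a common
    (0,1) scale), best of ``n_restarts`` random initializations.

    For k = 2 the cluster with higher mean CI on the prognostic drugs
    (carboplatin/cisplatin/doxorubicin, where available) is relabeled
    cluster 1 ("poor-responder-like")."""
    X = ci.ci.to_numpy(dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available patients")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)
    centroids = pd.DataFrame(km.cluster_centers_, columns=ci.ci.columns)
    if k == 2:
        cols = [d for d in prognostic_drugs if d in centroids.columns]
        score = centroids[cols].mean(axis=1) if cols else centroids.mean(axis=1)
        poor_raw = int(score.idxmax())
        mapping = {poor_raw: 1, 1 - poor_raw: 2}
        labels = pd.Series([mapping[r] for r in raw], index=ci.ci.index)
        centroids = centroids.loc[[poor_raw, 1 - poor_raw]].reset_index(drop=True)
        centroids.index = [1, 2]
    else:
        labels = pd.Series(raw + 1, index=ci.ci.index)
        centroids.index = range(1, k + 1)
    return ClusterAssignment(
        labels=labels,
        centroids=centroids,
        poor_responder_cluster=1,
        inertia=float(km.inertia_),
    )


def two_proportion_ztest(
    x1: int, n1: int, x2: int, n2: int
) -> tuple[float, float, bool]:
    """Pooled two-proportion z-test; falls back to Fisher's exact test on
    degenerate tables (a pooled proportion of 0 or 1).

    Returns (statistic, p, used_exact)."""
    if min(n1, n2) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        table = [[x1, n1 - x1], [x2, n2 - x2]]
        _, p = stats.fisher_exact(table)
        return 0.0, float(p), True
    if x1 / n1 == x2 / n2:
        return 0.0, 1.0, False
    z, p = proportions_ztest([x1, x2], [n1, n2])
    return float(z), float(p), False


DEFAULT_DICHOTOMIES = {
    "inss_stage": ("stage 4", lambda c: c["inss_stage"].astype(str) == "4"),
    "induction_response": ("MR", lambda c: c["induction_response"] == "MR"),
    "mycn": ("amplified", lambda c: c["mycn"] == "AMPL"),
}


def association_tests(
    assign: ClusterAssignment,
    clinical: pd.DataFrame,
    horizon_months: float = 36.0,
) -> pd.DataFrame:
    """Cluster x covariate association via two-proportion z-tests.

    Categorical covariates are dichotomized (INSS: stage 4 vs other;
    response: MR vs other; MYCN: amplified vs other) and EFS as
    event-by-horizon vs event-free.  Patients with an unevaluable level
    ("NA") are excluded for that covariate.  Returns one row per
    covariate with the per-cluster proportions, statistic and p.
    """
    patients = assign.labels.index
    cl = clinical.loc[patients]
    in1 = assign.labels == 1
    in2 = assign.labels == 2
    if int(in1.sum()) < 2 or int(in2.sum()) < 2:
        raise ValueError("each cluster needs at least 2 patients")
    rows = []

    def add_row(name, flags, valid):
        f = flags[valid]
        v1 = f[in1[valid]]
        v2 = f[in2[valid]]
        z, p, exact = two_proportion_ztest(
            int(v1.sum()), len(v1), int(v2.sum()), len(v2)
        )
        rows.append(
            {
                "covariate": name,
                "prop_cluster1": v1.mean() if len(v1) else np.nan,
                "prop_cluster2": v2.mean() if len(v2) else np.nan,
                "statistic": z,
                "p_value": p,
                "exact_fallback": exact,
            }
        )

    for cov, (label, fn) in DEFAULT_DICHOTOMIES.items():
        valid = cl[cov].astype(str) != "NA"
        add_row(f"{cov}:{label}", fn(cl), valid.to_numpy())
    efs_flag = (cl["efs_event"] == 1) & (cl["efs_time"] <= horizon_months)
    add_row("efs:event_by_horizon", efs_flag, np.ones(len(cl), dtype=bool))
    return pd.DataFrame(rows)


@dataclass
class SurvivalResult:
    """KM curves per cluster at the analysis horizon plus log-rank test."""

    km_curves: dict[int, pd.DataFrame]
    logrank_statistic: float
    logrank_p: float
    horizon_months: float
    n_per_cluster: dict[int, int]


def logrank_efs(
    assign: ClusterAssignment,
    clinical: pd.DataFrame,
    horizon_months: float = 36.0,
) -> SurvivalResult:
    """3-year event-free survival comparison between the two clusters.

    Follow-up is administratively censored at the horizon; KM curves are
    estimated per cluster and compared with the standard log-rank test
    (hypergeometric variance).  An event is relapse, progression or
    death, encoded upstream as efs_event = 1.
    """
    patients = assign.labels.index
    cl = clinical.loc[patients]
    time = cl["efs_time"].to_numpy(dtype=float)
    event = cl["efs_event"].to_numpy(dtype=int)
    over = time > horizon_months
    time = np.where(over, horizon_months, time)
    event = np.where(over, 0, event)

    curves: dict[int, pd.DataFrame] = {}
    n_per = {}
    for c in sorted(assign.labels.unique()):
        sel = (assign.labels == c).to_numpy()
        n_per[int(c)] = int(sel.sum())
        if sel.sum() and event[sel].sum() == 0 and time[sel].sum() == 0:
            raise ValueError(
                f"cluster {c} has zero events and zero follow-up time"
            )
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=f"cluster{c}")
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves[int(c)] = curve
    sel1 = (assign.labels == 1).to_numpy()
    res = logrank_test(time[sel1], time[~sel1], event[sel1], event[~sel1])
    return SurvivalResult(
        km_curves=curves,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        horizon_months=horizon_months,
        n_per_cluster=n_per,
    )
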