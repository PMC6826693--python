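"""Chemoresistance index, stratification, association and survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import exopipe as xp
from exopipe.datatypes import ChemoresistanceEntry, ChemoresistanceList
from exopipe.resistance import CIMatrix, ClusterAssignment, two_proportion_ztest

from conftest import make_norm


def _directions(df):
    return df


def test_modulation_directions_sign_rule():
    delta = pd.DataFrame(
        {
            "a": [0.0, -0.4],  # FC = -(end - onset) = +0.4 → up
            "b": [0.0, 0.0],  # FC = 0 → none
            "c": [0.0, 1.3],  # FC = -1.3 → down
        },
        index=["P1:onset", "P1:end"],
    )
    d = xp.modulation_directions(make_norm(delta))
    assert d.loc["P1", "a"] == "up"
    assert d.loc["P1", "b"] == "none"
    assert d.loc["P1", "c"] == "down"


def test_modulation_excludes_incomplete_patients():
    delta = pd.DataFrame(
        {"a": [0.0, 1.0, 2.0]},
        index=["P1:onset", "P1:end", "P2:onset"],
    )
    with pytest.warns(UserWarning, match="lack one timepoint"):
        d = xp.modulation_directions(make_norm(delta))
    assert list(d.index) == ["P1"]


def test_strict_mode_magnitude_threshold():
    delta = pd.DataFrame(
        {"a": [0.0, -0.3], "b": [0.0, -2.0]}, index=["P1:onset", "P1:end"]
    )
    d = xp.modulation_directions(make_norm(delta), magnitude_threshold=0.58)
    assert d.loc["P1", "a"] == "none"  # |FC|=0.3 below threshold
    assert d.loc["P1", "b"] == "up"


def _mini_list():
    return ChemoresistanceList(
        [
            ChemoresistanceEntry("hsa-miR-1", "vincristine", "down"),
            ChemoresistanceEntry("hsa-miR-2", "vincristine", "down"),
            ChemoresistanceEntry("hsa-miR-3", "vincristine", "down"),
        ]
    )


def test_ci_laplace_smoothing_hand_cases():
    directions = pd.DataFrame(
        {"hsa-miR-1": ["down"], "hsa-miR-2": ["down"], "hsa-miR-3": ["down"]},
        index=["P1"],
    )
    ci = xp.chemoresistance_index(directions, _mini_list())
    # all 3 of M=3 concordant: (3+1)/(3+2)
    assert ci.ci.loc["P1", "vincristine"] == pytest.approx(0.8)


def test_ci_half_concordant_large_list(reference_list):
    cis = reference_list.by_drug("cisplatin")
    assert len(cis) == 26  # 19 up + 7 down
    keys = sorted(cis)
    row = {}
    for i, k in enumerate(keys):
        want = cis[k]
        if i < 13:
            row[f"hsa-{k}"] = want
        else:
            row[f"hsa-{k}"] = "none"
    directions = pd.DataFrame(row, index=["P1"])
    ci = xp.chemoresistance_index(directions, reference_list)
    assert ci.concordant.loc["P1", "cisplatin"] == 13
    assert ci.ci.loc["P1", "cisplatin"] == pytest.approx(14 / 28)


def test_ci_excludes_empty_drug_and_unmatched_mirnas(reference_list):
    directions = pd.DataFrame(
        {"hsa-miR-150": ["up"], "hsa-miR-126": ["down"]}, index=["P1"]
    )
    ci = xp.chemoresistance_index(directions, reference_list)
    assert "cyclophosphamide" in ci.excluded_drugs
    # only miR-126 of the vincristine list is measured: M=1, m=1
    assert ci.list_size.loc["P1", "vincristine"] == 1
    assert ci.ci.loc["P1", "vincristine"] == pytest.approx(2 / 3)
    assert "mir-15b" in ci.unmatched_mirnas["vincristine"]


@given(m=st.integers(0, 10), extra=st.integers(1, 5))
@settings(max_examples=30, deadline=None)
def test_ci_bounds_and_monotonicity(m, extra):
    M = m + extra
    lo, hi = 1 / (M + 2), (M + 1) / (M + 2)
    ci_m = (m + 1) / (M + 2)
    ci_m1 = (m + 2) / (M + 2)
    assert lo <= ci_m <= hi
    assert ci_m1 > ci_m  # strictly increasing in m at fixed M


def test_ci_invariant_to_column_order(reference_list):
    rng = np.random.default_rng(0)
    mirnas = [f"hsa-{k}" for k in reference_list.by_drug("doxorubicin")]
    vals = rng.choice(["up", "down", "none"], size=(4, len(mirnas)))
    directions = pd.DataFrame(vals, index=[f"P{i}" for i in range(4)], columns=mirnas)
    shuffled = directions[list(reversed(mirnas))]
    a = xp.chemoresistance_index(directions, reference_list)
    b = xp.chemoresistance_index(shuffled, reference_list)
    pd.testing.assert_frame_equal(a.ci, b.ci)


def _ci_from_profiles(profiles, drugs):
    df = pd.DataFrame(profiles, columns=drugs)
    df.index = [f"P{i}" for i in range(len(df))]
    m = (df * 10 - 1).round().astype(int)
    M = pd.DataFrame(8, index=df.index, columns=drugs)
    ci = CIMatrix.__new__(CIMatrix)
    ci.ci = df
    ci.concordant = m
    ci.list_size = M
    ci.excluded_drugs = []
    ci.unmatched_mirnas = {}
    return ci


def test_kmeans_separable_recovery_and_labeling():
    drugs = ["carboplatin", "cisplatin", "doxorubicin", "etoposide", "vincristine"]
    poor = [0.9, 0.9, 0.9, 0.2, 0.2]
    good = [0.2, 0.2, 0.2, 0.7, 0.7]
    profiles = [poor] * 6 + [good] * 8
    ci = _ci_from_profiles(profiles, drugs)
    assign = xp.kmeans_stratify(ci, k=2, seed=0)
    labels = assign.labels
    assert set(labels.iloc[:6]) == {1}  # poor-responder-like = cluster 1
    assert set(labels.iloc[6:]) == {2}
    assert assign.poor_responder_cluster == 1
    # duplicate rows co-assigned
    assert labels.iloc[0] == labels.iloc[1]


def test_kmeans_k1_inertia_is_total_ss():
    drugs = ["cisplatin", "doxorubicin"]
    profiles = [[0.2, 0.4], [0.6, 0.8], [0.4, 0.6]]
    ci = _ci_from_profiles(profiles, drugs)
    assign = xp.kmeans_stratify(ci, k=1, seed=0)
    x = ci.ci.to_numpy()
    assert assign.inertia == pytest.approx(((x - x.mean(0)) ** 2).sum())
    with pytest.raises(ValueError, match="exceeds"):
        xp.kmeans_stratify(ci, k=5, seed=0)


def test_two_proportion_ztest_cases():
    z, p, exact = two_proportion_ztest(10, 10, 0, 10)
    assert p < 0.001
    _, p_eq, _ = two_proportion_ztest(3, 10, 3, 10)
    assert p_eq == 1.0
    _, p_degen, exact = two_proportion_ztest(0, 10, 0, 10)
    assert exact and p_degen == 1.0
    with pytest.raises(ValueError):
        two_proportion_ztest(0, 0, 1, 5)


def _clinical_for(patients, efs_time, efs_event, response=None):
    n = len(patients)
    return xp.validate_clinical(
        pd.DataFrame(
            {
                "patient_id": patients,
                "inss_stage": ["4"] * n,
                "mycn": ["AMPL" if i % 2 else "NO AMPL" for i in range(n)],
                "induction_response": response or ["PR"] * n,
                "relapse": ["yes" if e else "no" for e in efs_event],
                "efs_time": efs_time,
                "efs_event": efs_event,
                "origin": ["IT"] * n,
                "age": [24.0] * n,
            }
        )
    )


def _assign(patients, labels):
    a = ClusterAssignment.__new__(ClusterAssignment)
    a.labels = pd.Series(labels, index=patients)
    a.centroids = pd.DataFrame()
    a.poor_responder_cluster = 1
    a.inertia = 0.0
    return a


def test_logrank_null_and_association():
    patients = [f"P{i}" for i in range(20)]
    time = [6.0, 12.0, 18.0, 24.0, 30.0] * 4
    event = [1, 0, 1, 0, 1] * 4
    clinical = _clinical_for(patients, time, event)
    # identical survival composition in both clusters
    assign = _assign(patients, [1, 2] * 10)
    res = xp.logrank_efs(assign, clinical)
    assert res.logrank_statistic == pytest.approx(0.0, abs=1e-9)
    assert res.logrank_p == pytest.approx(1.0, abs=1e-9)
    for curve in res.km_curves.values():
        assert (curve["survival"].diff().dropna() <= 1e-12).all()
    assoc = xp.association_tests(assign, clinical)
    assert set(assoc["covariate"]).issuperset({"efs:event_by_horizon"})
    assert ((assoc["p_value"] >= 0) & (assoc["p_value"] <= 1)).all()


def brute_force_logrank(time, event, group):
    """Observed-minus-expected over event times with hypergeometric
    variance, from the definition."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    from scipy import stats

    chi2 = o_minus_e**2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


def test_logrank_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(10, 25))
        patients = [f"P{i}" for i in range(n)]
        time = np.round(rng.exponential(20, n), 1) + 0.1
        event = rng.integers(0, 2, n)
        labels = rng.integers(1, 3, n)
        if len(set(labels)) < 2:
            labels[0] = 1
            labels[1] = 2
        clinical = _clinical_for(patients, time, event)
        assign = _assign(patients, labels)
        res = xp.logrank_efs(assign, clinical, horizon_months=1e9)
        chi2, p = brute_force_logrank(time, event, (labels == 1).astype(int))
        assert res.logrank_statistic == pytest.approx(chi2, abs=1e-6)
        assert res.logrank_p == pytest.approx(p, abs=1e-6)


def test_logrank_censors_at_horizon():
    patients = [f"P{i}" for i in range(8)]
    # all events happen after the horizon → nothing observed by 36 months
    clinical = _clinical_for(patients, [40.0] * 8, [1] * 8)
    assign = _assign(patients, [1, 1, 1, 1, 2, 2, 2, 2])
    res = xp.logrank_efs(assign, clinical, horizon_months=36.0)
    for curve in res.km_curves.values():
        assert (curve["survival"] == 1.0).all()
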