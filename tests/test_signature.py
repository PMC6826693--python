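"""Elastic-net signature selection and its oracles."""

import numpy as np
import pandas as pd
import pytest

import exopipe as xp
from exopipe.signature import fit_elastic_net_loocv, make_penalty_grid, mannwhitney_by_group

from conftest import make_norm


def _two_group_cohort(rng, n_mr=6, n_vgpr=8, n_pr=3, p=20, mr_shift=None):
    """NormalizedMatrix + clinical with planted MR-vs-VGPR fold changes."""
    patients, resp = [], []
    for i in range(n_mr):
        patients.append(f"MR{i}")
        resp.append("MR")
    for i in range(n_vgpr):
        patients.append(f"VG{i}")
        resp.append("VGPR")
    for i in range(n_pr):
        patients.append(f"PR{i}")
        resp.append("PR")
    mirnas = [f"m{j}" for j in range(p)]
    rows = {}
    for pid, r in zip(patients, resp):
        onset = rng.normal(0, 0.5, p)
        end = onset + rng.normal(0, 0.5, p)
        if r == "MR" and mr_shift is not None:
            end = end + mr_shift
        rows[f"{pid}:onset"] = onset
        rows[f"{pid}:end"] = end
    delta = pd.DataFrame.from_dict(rows, orient="index", columns=mirnas)
    clinical = xp.validate_clinical(
        pd.DataFrame(
            {
                "patient_id": patients,
                "inss_stage": "4",
                "mycn": "NO AMPL",
                "induction_response": resp,
                "relapse": "no",
                "efs_time": 36.0,
                "efs_event": 0,
                "origin": "IT",
                "age": 24.0,
            }
        )
    )
    return make_norm(delta), clinical


def test_build_design_shape_and_exclusions():
    rng = np.random.default_rng(0)
    norm, clinical = _two_group_cohort(rng)
    X, y, scaling = xp.build_design(norm, clinical)
    assert X.shape[0] == 14  # 6 MR + 8 VGPR; PR excluded
    assert y.sum() == 6
    assert not any(p.startswith("PR") for p in X.index)
    np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-9)


def test_build_design_drops_constant_feature():
    rng = np.random.default_rng(1)
    norm, clinical = _two_group_cohort(rng)
    norm.delta_ct["m0"] = 1.0  # same ΔCT at both timepoints → FC constant 0
    with pytest.warns(UserWarning, match="constant"):
        X, _, _ = xp.build_design(norm, clinical)
    assert "m0" not in X.columns


def test_build_design_needs_two_per_group():
    rng = np.random.default_rng(2)
    norm, clinical = _two_group_cohort(rng, n_mr=1)
    with pytest.raises(ValueError, match="MR"):
        xp.build_design(norm, clinical)


def test_huge_penalty_selects_nothing():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(0, 1, (10, 5)))
    y = np.array([1.0] * 5 + [0.0] * 5)
    res = fit_elastic_net_loocv(X, y, mixing=0.7, penalty_grid=np.array([1e6, 2e6]))
    assert res.selected_mirnas == []


def test_small_penalty_matches_ols_on_orthonormal_design():
    rng = np.random.default_rng(4)
    n, p = 12, 4
    X = rng.normal(0, 1, (n, p))
    beta = np.array([1.0, -2.0, 0.5, 3.0])
    y = X @ beta + rng.normal(0, 0.01, n)
    grid = np.array([1e-8])
    res = fit_elastic_net_loocv(pd.DataFrame(X), y, mixing=0.7, penalty_grid=grid)
    ols = np.linalg.lstsq(
        np.column_stack([np.ones(n), X]), y, rcond=None
    )[0][1:]
    np.testing.assert_allclose(res.coefficients.to_numpy(), ols, atol=1e-5)


def test_lasso_matches_soft_threshold_oracle():
    """With mixing 1 on a centered orthonormal design the solution is the
    closed-form soft-thresholding of the OLS coefficients."""
    rng = np.random.default_rng(5)
    n, p = 16, 5
    A = rng.normal(0, 1, (n, p))
    A = A - A.mean(axis=0)
    X, _ = np.linalg.qr(A)  # centered, orthonormal columns
    beta = np.array([2.0, -1.0, 0.05, 0.0, 1.5])
    y = X @ beta
    y = y - y.mean()
    lam = 0.02
    res = fit_elastic_net_loocv(
        pd.DataFrame(X), y + 1.0, mixing=1.0, penalty_grid=np.array([lam])
    )
    gram = X.T @ X  # ~identity up to centering
    z = X.T @ y / n
    expected = np.sign(z) * np.maximum(np.abs(z) - lam, 0) / np.diag(gram / n)
    np.testing.assert_allclose(res.coefficients.reindex(range(p), fill_value=0.0),
                               expected, atol=1e-3)


def test_near_ridge_limit():
    """mixing → 0⁺ approaches the ridge closed form."""
    rng = np.random.default_rng(6)
    n, p = 20, 4
    X = rng.normal(0, 1, (n, p))
    X = X - X.mean(0)
    y = X @ np.array([1.0, -1.0, 0.5, 0.0]) + rng.normal(0, 0.1, n)
    y = y - y.mean()
    lam, mixing = 0.5, 1e-4
    res = fit_elastic_net_loocv(
        pd.DataFrame(X), y + 2.0, mixing=mixing, penalty_grid=np.array([lam])
    )
    ridge = np.linalg.solve(
        X.T @ X / n + lam * (1 - mixing) * np.eye(p), X.T @ y / n
    )
    np.testing.assert_allclose(res.coefficients.to_numpy(), ridge, atol=2e-3)


def test_chosen_penalty_attains_min_loocv_mse():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(0, 1, (12, 8)))
    y = np.array([1.0] * 5 + [0.0] * 7)
    res = fit_elastic_net_loocv(X, y, mixing=0.7)
    i = int(np.argwhere(np.isclose(res.penalty_grid, res.chosen_penalty))[0][0])
    assert res.loocv_mse_per_penalty[i] <= res.loocv_mse_per_penalty.min() + 1e-12


def test_selection_invariant_to_feature_rescaling():
    """Standardization makes selection invariant to per-feature affine
    rescaling of the raw fold changes."""
    rng = np.random.default_rng(8)
    raw = rng.normal(0, 1, (14, 10))
    raw[:6, :2] += 3.0
    y = np.array([1.0] * 6 + [0.0] * 8)

    def standardize(a):
        return (a - a.mean(0)) / a.std(0, ddof=1)

    rescaled = raw * np.array([5.0] + [1.0] * 9) + 7.0
    r1 = fit_elastic_net_loocv(pd.DataFrame(standardize(raw)), y, mixing=0.7)
    r2 = fit_elastic_net_loocv(pd.DataFrame(standardize(rescaled)), y, mixing=0.7)
    assert r1.selected_mirnas == r2.selected_mirnas


def test_grid_requires_varying_labels():
    X = np.ones((6, 3))
    with pytest.raises(ValueError):
        make_penalty_grid(X, np.ones(6), 0.7)
    with pytest.raises(ValueError, match="identical"):
        fit_elastic_net_loocv(pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3))),
                              np.ones(6), mixing=0.7)


def test_signature_separation_reproduces_planted_medians():
    """Group medians of the planted signature reproduce the construction:
    a strong median FC contrast on the designated assays in MR patients."""
    rng = np.random.default_rng(9)
    shift = np.zeros(20)
    shift[0] = 6.52 - 1.57  # extra MR downregulation on top of a shared one
    norm, clinical = _two_group_cohort(rng, mr_shift=shift, n_pr=0)
    norm.delta_ct.iloc[:, 0] += 0.0
    report = xp.evaluate_signature_separation(norm, clinical, ["m0"])
    med = report["group_medians"]["m0"]
    assert med["MR"] == pytest.approx(-(6.52 - 1.57), abs=0.8)
    assert med["VGPR"] == pytest.approx(0.0, abs=0.8)
    assert report["separation"] > 1.0


def test_signature_separation_null():
    rng = np.random.default_rng(10)
    norm, clinical = _two_group_cohort(rng, n_pr=0)
    report = xp.evaluate_signature_separation(norm, clinical, ["m1", "m2"])
    assert report["separation"] < 1.5  # no planted signal: weak separation


def test_mannwhitney_by_group():
    values = pd.Series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], index=list("abcdef"))
    groups = pd.Series(["x"] * 3 + ["y"] * 3, index=list("abcdef"))
    assert mannwhitney_by_group(values, groups) < 0.2
    with pytest.raises(ValueError, match="2 groups"):
        mannwhitney_by_group(values, pd.Series(["x"] * 6, index=list("abcdef")))
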