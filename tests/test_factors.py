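"""Factor model: adequacy statistics, varimax, group assignment, scores."""

import numpy as np
import pandas as pd
import pytest

import csfmetals.views as V
from csfmetals import (CohortConfig, bartlett_sphericity, assign_groups,
                       fit_factors, generate_cohort, kmo, regress_on_factors,
                       varimax)
from csfmetals.cohort import FactorBlock
from csfmetals.factors import FactorSolution, SingularCorrelationMatrix


def _orthogonal_columns(n=60, p=4, seed=0):
    """Columns with exactly zero sample correlation (QR construction)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    return Q


def test_bartlett_identity_correlation_gives_zero_chi2():
    X = _orthogonal_columns()
    chi2, dof, p = bartlett_sphericity(X)
    assert chi2 == pytest.approx(0.0, abs=1e-8)
    assert p == pytest.approx(1.0, abs=1e-8)
    assert dof == 4 * 3 // 2


def test_bartlett_perfectly_correlated_columns_flagged_singular():
    rng = np.random.default_rng(1)
    a = rng.normal(size=100)
    X = np.column_stack([a, 2 * a + 1, rng.normal(size=100)])
    with pytest.raises(SingularCorrelationMatrix):
        bartlett_sphericity(X)


def test_bartlett_matches_direct_formula_oracle():
    rng = np.random.default_rng(123)
    X = rng.normal(size=(193, 5))
    chi2, dof, p = bartlett_sphericity(X)
    n, pp = X.shape
    R = np.corrcoef(X, rowvar=False)
    chi2_oracle = -(n - 1 - (2 * pp + 5) / 6) * np.log(np.linalg.det(R))
    assert chi2 == pytest.approx(chi2_oracle, abs=1e-8)


def test_kmo_matches_anti_image_oracle():
    rng = np.random.default_rng(42)
    g = rng.normal(size=(150, 1))
    X = g + 0.8 * rng.normal(size=(150, 6))
    overall, per_var = kmo(X)
    # independently coded oracle via explicit anti-image matrix
    R = np.corrcoef(X, rowvar=False)
    Rinv = np.linalg.inv(R)
    D = np.diag(1.0 / np.sqrt(np.diag(Rinv)))
    Q = -D @ Rinv @ D
    np.fill_diagonal(Q, 0.0)
    R0 = R - np.eye(len(R))
    oracle = (R0 ** 2).sum() / ((R0 ** 2).sum() + (Q ** 2).sum())
    assert overall == pytest.approx(oracle, abs=1e-8)
    assert len(per_var) == 6 and np.all((per_var > 0) & (per_var <= 1))


def test_kmo_two_variables_is_half():
    # with two variables the anti-image partial equals the correlation
    # itself, so KMO = r^2 / (r^2 + r^2) = 0.5 for any r != 0
    rng = np.random.default_rng(3)
    a = rng.normal(size=200)
    X = np.column_stack([a + 0.5 * rng.normal(size=200), a])
    overall, _ = kmo(X)
    assert overall == pytest.approx(0.5, abs=1e-10)


def test_kmo_block_design_above_half():
    rng = np.random.default_rng(9)
    g1, g2 = rng.normal(size=(200, 1)), rng.normal(size=(200, 1))
    X = np.column_stack([g1 + 0.4 * rng.normal(size=(200, 3)),
                         g2 + 0.4 * rng.normal(size=(200, 3))])
    overall, _ = kmo(X)
    assert overall > 0.5


def test_varimax_orthogonality_and_fixed_point():
    # already simple structure: rotation leaves it unchanged up to
    # permutation and sign
    L = np.array([[0.9, 0.0], [0.85, 0.0], [0.0, 0.8], [0.0, 0.95]])
    Lr, T = varimax(L)
    assert np.allclose(T.T @ T, np.eye(2), atol=1e-10)
    recovered = np.abs(Lr)
    assert np.allclose(np.sort(recovered, axis=None),
                       np.sort(np.abs(L), axis=None), atol=1e-8)


def _six_block_config(seed):
    elements = [V.csf_col(e) for e in V.CSF_ELEMENTS]
    blocks = tuple(
        FactorBlock("csf_elements", tuple(elements[i * 4:(i + 1) * 4]), 0.8)
        for i in range(6))
    return CohortConfig(factor_blocks=blocks, missingness={}, seed=seed), blocks


def test_six_planted_blocks_recovered():
    cfg, blocks = _six_block_config(17)
    ds = generate_cohort(cfg)
    sol = fit_factors(ds, "csf_elements", n_factors=6, drop=[])
    got = {frozenset(e for e, _ in members)
           for members in sol.groups.values() if members}
    want = {frozenset(b.attributes) for b in blocks}
    assert got == want
    assert not sol.unassigned


def test_rotation_preserves_communalities_and_variance():
    ds = generate_cohort(CohortConfig(missingness={}, seed=4))
    sol = fit_factors(ds, "csf_elements")
    L0 = sol.loadings_unrotated.to_numpy()
    Lr = sol.loadings.to_numpy()
    assert np.allclose((L0 ** 2).sum(axis=1), (Lr ** 2).sum(axis=1), atol=1e-8)
    assert np.isclose((L0 ** 2).sum(), (Lr ** 2).sum(), atol=1e-10)
    T = sol.rotation
    assert np.allclose(T.T @ T, np.eye(T.shape[1]), atol=1e-10)
    # reduced-rank reconstruction error identical before/after rotation
    X = ds.view("csf_elements").drop(columns=["P_csf"]).dropna()
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    e0 = np.linalg.norm(R - L0 @ L0.T)
    e1 = np.linalg.norm(R - Lr @ Lr.T)
    assert e0 == pytest.approx(e1, abs=1e-10)


def test_assign_groups_threshold_rule():
    loadings = pd.DataFrame(
        {"F1": [0.845, 0.1, -0.505], "F2": [0.1, 0.39, 0.3]},
        index=["Ca", "Tl", "Hg"])
    groups, unassigned = assign_groups(loadings, threshold=0.4)
    assert ("Ca", 0.845) in groups["F1"]
    assert ("Hg", -0.505) in groups["F1"]       # magnitude assigns, sign kept
    assert unassigned == [("Tl", 0.39)]
    assigned = {e for mem in groups.values() for e, _ in mem}
    assert assigned | {e for e, _ in unassigned} == {"Ca", "Tl", "Hg"}


def test_csf_view_drops_sparse_phosphorus_by_default(default_cohort):
    sol = fit_factors(default_cohort, "csf_elements")
    assert "P_csf" not in sol.loadings.index
    assert len(sol.loadings) == 23


def test_factor_regression_recovers_planted_coefficient():
    ds = generate_cohort(CohortConfig(missingness={}, seed=21))
    sol = fit_factors(ds, "csf_elements")
    rng = np.random.default_rng(0)
    y = 0.5 * sol.scores["F1"] + np.sqrt(1 - 0.25) * rng.normal(size=len(sol.scores))
    ds.data["synthetic_marker"] = y
    ds.view_columns["csf_biomarkers"].append("synthetic_marker")
    regs = regress_on_factors(ds, sol, "synthetic_marker")
    by_factor = {r.factor: r for r in regs}
    r1 = by_factor["F1"]
    assert abs(r1.beta_std - 0.5) < 3 * r1.se / np.std(y)
    for fac, r in by_factor.items():
        if fac != "F1":
            assert abs(r.beta_std) < 0.2


def test_orthonormal_scores_give_beta_equal_correlation():
    rng = np.random.default_rng(8)
    n = 200
    M = rng.normal(size=(n, 3))
    M -= M.mean(axis=0)
    S = np.linalg.qr(M)[0] * np.sqrt(n - 1)
    scores = pd.DataFrame(S, columns=["F1", "F2", "F3"],
                          index=pd.Index([f"P{i}" for i in range(n)],
                                         name="patient_id"))
    y = 0.4 * S[:, 0] - 0.2 * S[:, 2] + rng.normal(size=n)
    frame = pd.DataFrame({"m": y}, index=scores.index)
    from csfmetals import CohortDataset
    ds = CohortDataset(frame, view_columns={"csf_biomarkers": ["m"]},
                       categorical_levels={})
    sol = FactorSolution(
        view="csf_elements", n_factors=3, loadings=pd.DataFrame(),
        variance_explained_total=1.0, bartlett=(0, 0, 1), kmo_overall=0.5,
        kmo_per_variable=pd.Series(dtype=float), groups={}, unassigned=[],
        scores=scores)
    regs = regress_on_factors(ds, sol, "m")
    for r in regs:
        simple = np.corrcoef(scores[r.factor], y)[0, 1]
        assert r.beta_std == pytest.approx(simple, abs=1e-10)


def test_factor_regression_type_one_error_calibrated():
    """A biomarker independent of all factor scores rejects each factor
    at roughly the nominal 5% rate."""
    ds = generate_cohort(CohortConfig(missingness={}, seed=30))
    sol = fit_factors(ds, "csf_elements")
    rng = np.random.default_rng(1)
    ds.view_columns["csf_biomarkers"].append("noise_marker")
    rejections = total = 0
    for _ in range(200):
        ds.data["noise_marker"] = rng.normal(size=ds.n)
        for r in regress_on_factors(ds, sol, "noise_marker"):
            total += 1
            rejections += r.p <= 0.05
    rate = rejections / total
    assert 0.025 <= rate <= 0.075, rate


def test_kaiser_rule_and_factor_count_errors(default_cohort):
    sol = fit_factors(default_cohort, "csf_elements", n_factors="kaiser")
    assert 1 <= sol.n_factors <= 23
    with pytest.raises(ValueError):
        fit_factors(default_cohort, "csf_elements", n_factors=99)
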