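"""Dimensionality reduction of element views: PCA with varimax rotation.

The element concentrations of one view (CSF or plasma) are standardized,
reduced to ``n_factors`` principal components, and varimax-rotated (with
Kaiser row normalization) to simple structure.  Sampling adequacy is
assessed with Bartlett's test of sphericity and the Kaiser-Meyer-Olkin
index.  Elements are assigned to the factor of their largest absolute
loading when it reaches the threshold (default 0.4); per-patient factor
scores (regression method) feed multiple linear regressions of each CSF
biomarker on all factors simultaneously.

The CSF view excludes P by default because it is the sparsest
measurement, which would otherwise collapse the complete-case sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import views as V
from .cohort import CohortDataset


class SingularCorrelationMatrix(ValueError):
    """Correlation matrix is (near-)singular; remove collinear columns."""


def _correlation_matrix(X: np.ndarray) -> np.ndarray:
    if np.isnan(X).any():
        raise ValueError("matrix must be complete-case (no missing cells)")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise SingularCorrelationMatrix("constant column in input")
    return np.corrcoef(X, rowvar=False)


def bartlett_sphericity(X) -> tuple[float, int, float]:
    """Bartlett's chi-square test that the correlation matrix is identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), dof = p(p-1)/2.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    R = _correlation_matrix(X)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet) or logdet < -500:
        raise SingularCorrelationMatrix(
            "correlation matrix is singular (det -> 0); remove perfectly "
            "correlated or constant columns")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    dof = p * (p - 1) // 2
    return float(chi2), int(dof), float(stats.chi2.sf(chi2, dof))


def kmo(X) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    Compares squared correlations to squared anti-image partial
    correlations; returns (overall MSA, per-variable MSA).
    """
    X = np.asarray(X, dtype=float)
    R = _correlation_matrix(X)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as err:
        raise SingularCorrelationMatrix(str(err)) from err
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    np.fill_diagonal(partial, 0.0)
    R0 = R.copy()
    np.fill_diagonal(R0, 0.0)
    r2 = R0 ** 2
    q2 = partial ** 2
    overall = r2.sum() / (r2.sum() + q2.sum())
    per_var = r2.sum(axis=0) / (r2.sum(axis=0) + q2.sum(axis=0))
    return float(overall), per_var


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000
            ) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix T)
    with T orthogonal and rotated = loadings @ T."""
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    h = np.sqrt((L ** 2).sum(axis=1))
    if kaiser_normalize:
        h = np.where(h == 0, 1.0, h)
        L = L / h[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ T
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p))
        T = u @ vt
        d_new = s.sum()
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    Lr = L @ T
    if kaiser_normalize:
        Lr = Lr * h[:, None]
    return Lr, T


@dataclass
class FactorSolution:
    view: str
    n_factors: int
    loadings: pd.DataFrame            # element x factor, rotated
    variance_explained_total: float   # fraction of total variance
    bartlett: tuple[float, int, float]
    kmo_overall: float
    kmo_per_variable: pd.Series
    groups: dict[str, list[tuple[str, float]]]
    unassigned: list[tuple[str, float]]
    scores: pd.DataFrame              # complete-case patients x factor
    loadings_unrotated: pd.DataFrame = None
    rotation: np.ndarray = None
    variance_per_factor: pd.Series = None

    def to_dict(self) -> dict:
        return {
            "view": self.view,
            "n_factors": self.n_factors,
            "variance_explained_total": self.variance_explained_total,
            "bartlett": {"chi2": self.bartlett[0], "dof": self.bartlett[1],
                         "p": self.bartlett[2]},
            "kmo_overall": self.kmo_overall,
            "kmo_per_variable": {
                k: float(v) for k, v in self.kmo_per_variable.items()},
            "loadings": {
                f: {e: float(x) for e, x in self.loadings[f].items()}
                for f in self.loadings.columns},
            "groups": {f: [[e, float(l)] for e, l in members]
                       for f, members in self.groups.items()},
            "unassigned": [[e, float(l)] for e, l in self.unassigned],
            "variance_per_factor": {
                k: float(v) for k, v in self.variance_per_factor.items()},
        }


def assign_groups(loadings: pd.DataFrame, threshold: float = 0.4
                  ) -> tuple[dict[str, list[tuple[str, float]]],
                             list[tuple[str, float]]]:
    """Assign each element to the factor of its max |loading| when that
    |loading| >= threshold; otherwise list it unassigned with its best
    (signed) loading.  Negative loadings assign by magnitude and keep
    their sign in the report."""
    groups: dict[str, list[tuple[str, float]]] = {
        f: [] for f in loadings.columns}
    unassigned: list[tuple[str, float]] = []
    for element, row in loadings.iterrows():
        best = row.abs().idxmax()
        val = float(row[best])
        if abs(val) >= threshold:
            groups[best].append((element, val))
        else:
            unassigned.append((element, val))
    return groups, unassigned


def n_factors_kaiser(X: np.ndarray) -> int:
    """Opt-in extraction rule: number of correlation-matrix eigenvalues
    exceeding 1."""
    w = np.linalg.eigvalsh(_correlation_matrix(X))
    return int((w > 1.0).sum())


DROP_FROM_PCA = {"csf_elements": [V.csf_col("P")], "plasma_elements": []}


def fit_factors(dataset: CohortDataset, view: str, n_factors: int | str = 6,
                threshold: float = 0.4, drop: list[str] | None = None
                ) -> FactorSolution:
    """PCA + varimax factor solution of one element view.

    Complete-case rows of the view (after dropping the configured sparse
    columns) are standardized; the first ``n_factors`` components are
    extracted and varimax-rotated.  ``n_factors="kaiser"`` uses the
    eigenvalue > 1 rule.  Scores use the regression (Thompson) method.
    """
    if drop is None:
        drop = DROP_FROM_PCA.get(view, [])
    cols = [c for c in dataset.view_columns[view] if c not in set(drop)]
    sub = dataset.data[cols].dropna()
    X = sub.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"complete-case submatrix has {n} rows for {p} columns")
    if n_factors == "kaiser":
        n_factors = n_factors_kaiser(X)
    n_factors = int(n_factors)
    if n_factors > p:
        raise ValueError(f"n_factors={n_factors} exceeds {p} elements")

    R = _correlation_matrix(X)
    w, vecs = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, vecs = w[order], vecs[:, order]
    w = np.clip(w, 0.0, None)
    L0 = vecs[:, :n_factors] * np.sqrt(w[:n_factors])
    Lr, T = varimax(L0)

    # deterministic presentation: factors ordered by explained variance,
    # sign fixed so each factor's largest-|loading| entry is positive
    ssq = (Lr ** 2).sum(axis=0)
    forder = np.argsort(-ssq, kind="stable")
    Lr = Lr[:, forder]
    T = T[:, forder]
    for j in range(n_factors):
        i = np.argmax(np.abs(Lr[:, j]))
        if Lr[i, j] < 0:
            Lr[:, j] = -Lr[:, j]
            T[:, j] = -T[:, j]

    factor_names = [f"F{j + 1}" for j in range(n_factors)]
    loadings = pd.DataFrame(Lr, index=cols, columns=factor_names)
    loadings_unrot = pd.DataFrame(L0, index=cols, columns=factor_names)
    var_per_factor = pd.Series((Lr ** 2).sum(axis=0) / p, index=factor_names)
    variance_total = float((Lr ** 2).sum() / p)

    chi2, dof, p_bart = bartlett_sphericity(X)
    kmo_overall, kmo_per_var = kmo(X)

    groups, unassigned = assign_groups(loadings, threshold)

    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    scores = pd.DataFrame(
        Z @ np.linalg.solve(R, Lr), index=sub.index, columns=factor_names)

    return FactorSolution(
        view=view, n_factors=n_factors, loadings=loadings,
        variance_explained_total=variance_total,
        bartlett=(chi2, dof, p_bart), kmo_overall=kmo_overall,
        kmo_per_variable=pd.Series(kmo_per_var, index=cols),
        groups=groups, unassigned=unassigned, scores=scores,
        loadings_unrotated=loadings_unrot, rotation=T,
        variance_per_factor=var_per_factor)


@dataclass
class FactorRegression:
    biomarker: str
    factor: str
    members: list[str]
    beta: float        # unstandardized coefficient
    beta_std: float    # standardized coefficient
    se: float          # SE of the unstandardized coefficient
    p: float
    ci_low: float
    ci_high: float
    n: int


def regress_on_factors(dataset: CohortDataset, solution: FactorSolution,
                       biomarker: str) -> list[FactorRegression]:
    """One multiple linear regression of the biomarker on all factor
    scores simultaneously; reports standardized beta, the SE of the
    unstandardized coefficient, p, and a 95% CI per factor."""
    y_all = dataset.data[biomarker]
    common = solution.scores.index.intersection(y_all.dropna().index)
    if len(common) < 10:
        raise ValueError(
            f"only {len(common)} complete cases for {biomarker!r}")
    S = solution.scores.loc[common]
    y = y_all.loc[common].to_numpy(dtype=float)
    Xd = sm.add_constant(S.to_numpy(dtype=float))
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("rank-deficient factor-score design")
    fit = sm.OLS(y, Xd).fit()
    ci = fit.conf_int(alpha=0.05)
    sy = y.std(ddof=1)
    out = []
    for j, fac in enumerate(S.columns, start=1):
        sx = S[fac].to_numpy().std(ddof=1)
        members = [e for e, _ in solution.groups.get(fac, [])]
        out.append(FactorRegression(
            biomarker=biomarker, factor=fac, members=members,
            beta=float(fit.params[j]),
            beta_std=float(fit.params[j] * sx / sy),
            se=float(fit.bse[j]), p=float(fit.pvalues[j]),
            ci_low=float(ci[j, 0]), ci_high=float(ci[j, 1]),
            n=len(common)))
    return out


def regressions_to_frame(regs: list[FactorRegression]) -> pd.DataFrame:
    return pd.DataFrame([{
        "biomarker": r.biomarker, "factor": r.factor,
        "members": "+".join(r.members), "beta": r.beta,
        "beta_std": r.beta_std, "se": r.se, "p": r.p,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "n": r.n,
    } for r in regs])
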