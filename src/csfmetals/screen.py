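"""Biomarker x element correlation screen with confounder adjustment.

Every CSF biomarker (plus the Abeta42/p-tau181 ratio) is correlated with
every element concentration on pairwise-complete observations.  Because
multiple-comparison control is operationalized as a hard significance
gate, a record "passes" when p <= gate (default 0.001).  Gate-passing
associations can then be re-tested as partial correlations adjusted for
clinical confounders (age, gender, diagnosis, disease duration);
categorical covariates are one-hot encoded and, for Spearman, all numeric
quantities are rank-transformed before residualization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import views as V
from .cohort import CohortDataset


class SkippedPair(ValueError):
    """Fewer than 3 complete pairs: the correlation is not reported."""


class UndefinedCorrelation(ValueError):
    """Zero variance in one of the vectors."""


class CollinearCovariates(ValueError):
    """Covariate design matrix is rank deficient."""


@dataclass
class AdjustedResult:
    covariates: tuple[str, ...]
    r_partial: float
    p_partial: float
    n: int
    retained: bool


@dataclass
class CorrelationRecord:
    biomarker: str
    element: str
    element_view: str  # "CSF" or "plasma"
    method: str
    r: float
    n: int
    p: float
    passes_gate: bool
    r_pearson: float | None = None
    p_pearson: float | None = None
    adjusted_results: list[AdjustedResult] = field(default_factory=list)


def _t_pvalue(r: float, df: int) -> float:
    """Two-sided p from the t-approximation with the given residual df."""
    if df <= 0:
        return np.nan
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def correlate(x, y, method: str = "spearman") -> tuple[float, float, int]:
    """Correlation on pairwise-complete observations.

    Returns ``(r, p, n)`` with p from the two-sided t-approximation on
    n - 2 degrees of freedom (Spearman = Pearson on average ranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        raise SkippedPair(f"only {n} complete pairs")
    if method == "spearman":
        xs = stats.rankdata(xs)
        ys = stats.rankdata(ys)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise UndefinedCorrelation("zero variance after filtering")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, _t_pvalue(r, n - 2), n


def _element_pairs(dataset: CohortDataset):
    bios = dataset.view_columns["csf_biomarkers"]
    for view, label in (("csf_elements", "CSF"), ("plasma_elements", "plasma")):
        for bm, el in itertools.product(bios, dataset.view_columns[view]):
            yield bm, el, label


def screen(dataset: CohortDataset, gate: float = 0.001,
           method: str = "spearman") -> list[CorrelationRecord]:
    """One record per (biomarker, element, view) pair with >= 3 complete
    pairs; Spearman is primary, Pearson reported alongside.  Pairs using
    plasma elements are automatically restricted to the plasma subset by
    missingness."""
    records: list[CorrelationRecord] = []
    other = "pearson" if method == "spearman" else "spearman"
    for bm, el, view_label in _element_pairs(dataset):
        x = dataset.data[bm].to_numpy(dtype=float)
        y = dataset.data[el].to_numpy(dtype=float)
        try:
            r, p, n = correlate(x, y, method)
        except (SkippedPair, UndefinedCorrelation):
            continue
        try:
            r2, p2, _ = correlate(x, y, other)
        except (SkippedPair, UndefinedCorrelation):
            r2 = p2 = None
        rec = CorrelationRecord(
            biomarker=bm, element=el, element_view=view_label,
            method=method, r=r, n=n, p=p, passes_gate=bool(p <= gate))
        if method == "spearman":
            rec.r_pearson, rec.p_pearson = r2, p2
        records.append(rec)
    return records


def _design(dataset: CohortDataset, covariates, rows) -> np.ndarray:
    """Covariate design matrix (one-hot categoricals, no intercept column;
    the intercept is implicit in centering during residualization)."""
    cols = []
    names = []
    for cov in covariates:
        s = dataset.data.loc[rows, cov]
        if cov in dataset.categorical_levels:
            levels = dataset.categorical_levels[cov]
            for lv in levels[1:]:  # drop first level as reference
                cols.append((s == lv).to_numpy(dtype=float))
                names.append(f"{cov}={lv}")
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
    if not cols:
        return np.empty((len(rows), 0)), []
    return np.column_stack(cols), names


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    Z1 = np.column_stack([np.ones(len(v)), Z])
    beta, *_ = np.linalg.lstsq(Z1, v, rcond=None)
    return v - Z1 @ beta


def partial_correlation(dataset: CohortDataset, x_col: str, y_col: str,
                        covariates, method: str = "spearman"
                        ) -> tuple[float, float, int]:
    """Residual-on-residual partial correlation.

    For Spearman, x, y and numeric covariates are rank-transformed first.
    p is two-sided from the t-approximation with n - 2 - k degrees of
    freedom, k the number of covariate design columns.
    """
    covariates = tuple(covariates)
    needed = [x_col, y_col] + [c for c in covariates]
    sub = dataset.data[needed].dropna()
    n = len(sub)
    if not covariates:
        return correlate(dataset.data[x_col], dataset.data[y_col], method)
    rows = sub.index
    Z, names = _design(dataset, covariates, rows)
    k = Z.shape[1]
    if n < k + 3:
        raise SkippedPair(f"only {n} complete cases for {k} covariate columns")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Z])) < k + 1:
        bad = ", ".join(names)
        raise CollinearCovariates(f"collinear covariate design: {bad}")
    x = sub[x_col].to_numpy(dtype=float)
    y = sub[y_col].to_numpy(dtype=float)
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        Zr = Z.copy()
        for j, name in enumerate(names):
            if "=" not in name:  # leave one-hot indicators as-is
                Zr[:, j] = stats.rankdata(Z[:, j])
        Z = Zr
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise UndefinedCorrelation("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    return r, _t_pvalue(r, n - 2 - k), n


def adjust(record: CorrelationRecord, dataset: CohortDataset,
           covariates, gate: float = 0.001) -> CorrelationRecord:
    """Append a confounder-adjusted re-test to the record.

    ``retained`` is True when the partial correlation still meets the
    gate.  Complete-case per model: patients missing any of x, y or the
    covariates are dropped from this fit only.
    """
    covariates = tuple(covariates)
    r, p, n = partial_correlation(
        dataset, record.biomarker, record.element, covariates, record.method)
    record.adjusted_results.append(AdjustedResult(
        covariates=covariates, r_partial=r, p_partial=p, n=n,
        retained=bool(p <= gate)))
    return record


DEFAULT_COVARIATES = ("age", "gender", "diagnosis", "disease_duration")


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        base = dict(
            biomarker=rec.biomarker, element=rec.element,
            element_view=rec.element_view, method=rec.method,
            r=rec.r, n=rec.n, p=rec.p, passes_gate=rec.passes_gate,
            r_pearson=rec.r_pearson, p_pearson=rec.p_pearson,
        )
        if not rec.adjusted_results:
            rows.append({**base, "covariates": "", "r_partial": np.nan,
                         "p_partial": np.nan, "n_partial": np.nan,
                         "retained": ""})
        for adj in rec.adjusted_results:
            rows.append({**base, "covariates": "+".join(adj.covariates),
                         "r_partial": adj.r_partial, "p_partial": adj.p_partial,
                         "n_partial": adj.n, "retained": adj.retained})
    return pd.DataFrame(rows)
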