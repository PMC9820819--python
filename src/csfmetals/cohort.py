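"""Seed-reproducible synthetic multi-view cohort generator.

Emulates a memory-clinic cohort of AD, MCI and healthy-control patients
with CSF biomarker, CSF element and plasma element measurements:

* element concentrations are log-normal (ICP-MS concentration data are
  right-skewed) with correlated blocks induced by a Gaussian copula — one
  latent factor per configured block plus independent noise;
* biomarkers derive from a latent disease-severity score shifted by
  diagnosis (AD > MCI > HC) plus a loading on the dominant CSF element
  block, so the correlation screen and factor regressions have
  recoverable signal with the canonical sign structure (amyloid down,
  tau up);
* ground-truth patient subgroups ("planted redescriptions") receive
  values inside configured cross-view intervals, with a controlled leak
  fraction of accidental non-member matches per view;
* missingness is applied completely at random per attribute, after
  planting; patients outside the plasma subset have the whole plasma
  view missing.

Identical config + seed produce a bit-identical dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import views as V


class CohortConfigError(ValueError):
    """Raised for infeasible or inconsistent cohort configurations."""


class CohortParseError(ValueError):
    """Raised when a cohort file fails validation on read."""


@dataclass(frozen=True)
class FactorBlock:
    """A correlated block of element attributes within one view."""

    view: str
    attributes: tuple[str, ...]
    correlation: float

    def __post_init__(self):
        if not 0.0 <= self.correlation < 1.0:
            raise CohortConfigError(
                f"block correlation must be in [0, 1), got {self.correlation}"
            )


@dataclass(frozen=True)
class PlantedRedescription:
    """Ground-truth subgroup satisfying interval conditions in >= 2 views.

    ``member_fraction`` of the cohort is placed inside every condition
    interval; each non-member falls inside the conditions of each view
    independently with probability ``leak_fraction``.
    """

    member_fraction: float
    conditions: tuple[tuple[str, str, float, float], ...]  # (view, attr, lo, hi)
    leak_fraction: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.member_fraction < 1.0:
            raise CohortConfigError("member_fraction must be in (0, 1)")
        if not 0.0 <= self.leak_fraction < 1.0:
            raise CohortConfigError("leak_fraction must be in [0, 1)")
        if len({view for view, *_ in self.conditions}) < 2:
            raise CohortConfigError(
                "a planted redescription needs conditions in >= 2 distinct views"
            )
        for view, attr, low, high in self.conditions:
            if not low < high:
                raise CohortConfigError(
                    f"planted interval for {attr!r} must have low < high"
                )


def _default_blocks() -> tuple[FactorBlock, ...]:
    """Default correlation structure: a dominant CSF block of 16 elements
    plus smaller CSF and plasma blocks, mirroring the grouping a varimax
    factor analysis of such data typically yields."""
    c = V.csf_col
    p = V.plasma_col
    return (
        FactorBlock("csf_elements", tuple(c(e) for e in (
            "As", "Ba", "Ca", "Co", "Cu", "Fe", "K", "Mg",
            "Mn", "Na", "Ni", "S", "Se", "Sr", "Tl", "Zn")), 0.55),
        FactorBlock("csf_elements", tuple(c(e) for e in ("Al", "Cd", "Pb")), 0.50),
        FactorBlock("csf_elements", tuple(c(e) for e in ("B", "Li")), 0.50),
        FactorBlock("csf_elements", tuple(c(e) for e in ("Hg", "Mo")), 0.50),
        FactorBlock("plasma_elements", tuple(p(e) for e in (
            "Ca", "Co", "Cu", "Mg", "Mn", "Na", "P", "S", "Se", "Tl", "Zn")), 0.50),
        FactorBlock("plasma_elements", tuple(p(e) for e in (
            "B", "Cd", "Li", "Mo", "Pb")), 0.45),
        FactorBlock("plasma_elements", tuple(p(e) for e in ("As", "Hg")), 0.50),
    )


def _default_scales() -> tuple[dict[str, float], dict[str, float]]:
    log_mean: dict[str, float] = {}
    log_sd: dict[str, float] = {}
    for e, (med, gsd) in V.CSF_ELEMENT_SCALE.items():
        log_mean[V.csf_col(e)] = float(np.log(med))
        log_sd[V.csf_col(e)] = gsd
    for e, (med, gsd) in V.PLASMA_ELEMENT_SCALE.items():
        log_mean[V.plasma_col(e)] = float(np.log(med))
        log_sd[V.plasma_col(e)] = gsd
    return log_mean, log_sd


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the study conditions: 124 AD / 50 MCI / 19 HC
    (193 patients) with plasma collected from a 143-patient subset.
    """

    n_ad: int = 124
    n_mci: int = 50
    n_hc: int = 19
    plasma_subset_n: int = 143
    missingness: dict[str, float] = field(
        default_factory=lambda: dict(V.DEFAULT_MISSINGNESS))
    element_log_mean: dict[str, float] = field(
        default_factory=lambda: _default_scales()[0])
    element_log_sd: dict[str, float] = field(
        default_factory=lambda: _default_scales()[1])
    factor_blocks: tuple[FactorBlock, ...] = field(default_factory=_default_blocks)
    planted_redescriptions: tuple[PlantedRedescription, ...] = ()
    # coupling of biomarker log-concentration to the latent severity score
    # is per-biomarker (views.BIOMARKER_SCALE); this is the extra loading
    # of every biomarker on the dominant CSF element block factor.
    biomarker_element_coupling: float = 0.30
    # loading of every biomarker on the dominant plasma element block, so
    # plasma elements carry recoverable (weaker) signal as well
    biomarker_plasma_coupling: float = 0.30
    # correlation between the dominant CSF and plasma element blocks
    # (shared exposure/physiology across compartments), needed for
    # three-view subgroups to exist at all
    cross_compartment_coupling: float = 0.45
    # coupling of the dominant CSF element block factor to severity, which
    # makes some biomarker x element associations diagnosis-confounded.
    element_severity_coupling: float = 0.25
    seed: int = 0

    @property
    def n_total(self) -> int:
        return self.n_ad + self.n_mci + self.n_hc

    def validate(self) -> None:
        if min(self.n_ad, self.n_mci, self.n_hc) < 0 or self.n_total <= 0:
            raise CohortConfigError("group sizes must be nonnegative, total > 0")
        if not 0 <= self.plasma_subset_n <= self.n_total:
            raise CohortConfigError(
                f"plasma_subset_n={self.plasma_subset_n} exceeds cohort "
                f"size {self.n_total}")
        all_cols = {c for cols in V.VIEW_COLUMNS.values() for c in cols}
        for attr, frac in self.missingness.items():
            if attr not in all_cols:
                raise CohortConfigError(f"missingness refers to unknown attribute {attr!r}")
            if not 0.0 <= frac <= 1.0:
                raise CohortConfigError(f"missingness[{attr!r}] not in [0, 1]")
        for block in self.factor_blocks:
            if block.view not in V.VIEW_COLUMNS:
                raise CohortConfigError(f"unknown view {block.view!r} in factor block")
            for a in block.attributes:
                if a not in V.VIEW_COLUMNS[block.view]:
                    raise CohortConfigError(
                        f"attribute {a!r} not in view {block.view!r}")
        for plant in self.planted_redescriptions:
            for view, attr, low, high in plant.conditions:
                if view not in V.VIEW_COLUMNS:
                    raise CohortConfigError(f"unknown view {view!r} in planted redescription")
                if attr not in V.VIEW_COLUMNS[view]:
                    raise CohortConfigError(
                        f"attribute {attr!r} not in view {view!r}")
                if attr == V.RATIO:
                    raise CohortConfigError(
                        f"cannot plant on derived attribute {attr!r}")


@dataclass
class CohortDataset:
    """Per-patient multi-view table with missing cells.

    ``data`` is a flat DataFrame indexed by patient id; ``view_columns``
    maps view names to their column lists; ``categorical_levels`` declares
    the admissible levels of categorical columns.
    """

    data: pd.DataFrame
    view_columns: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(c) for k, c in V.VIEW_COLUMNS.items()})
    categorical_levels: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in V.CATEGORICAL_LEVELS.items()})
    #: ground truth, populated by generate_cohort only (not serialized)
    planted_members: list | None = None
    plasma_subset: list | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    def view(self, name: str) -> pd.DataFrame:
        if name not in self.view_columns:
            raise KeyError(f"unknown view {name!r}")
        return self.data[self.view_columns[name]]

    def equals(self, other: "CohortDataset") -> bool:
        return (
            self.view_columns == other.view_columns
            and self.categorical_levels == other.categorical_levels
            and self.data.equals(other.data)
        )


# -- generation ---------------------------------------------------------

_SEVERITY_MEAN = {"AD": 0.9, "MCI": 0.0, "HC": -1.3}
_MMSE_MEAN = {"AD": 19.0, "MCI": 25.5, "HC": 28.5}
_MMSE_SD = {"AD": 4.0, "MCI": 2.0, "HC": 1.2}
_AGE_MEAN = {"AD": 72.0, "MCI": 70.0, "HC": 66.0}
_APOE_P = {
    "AD": [0.06, 0.03, 0.36, 0.40, 0.15],
    "MCI": [0.08, 0.02, 0.50, 0.32, 0.08],
    "HC": [0.10, 0.01, 0.62, 0.24, 0.03],
}

#: plausible hard supports for clinical attributes used when forcing
#: planted non-member values outside an interval
_CLINICAL_SUPPORT = {"age": (49.0, 90.0), "MMSE": (0.0, 30.0),
                     "disease_duration": (0.0, 20.0)}


def _lognormal_quantiles(mu: float, sd: float) -> tuple[float, float]:
    # 0.1%..99.9% support of the base log-normal
    from scipy.stats import norm
    z = norm.ppf(0.999)
    return float(np.exp(mu - z * sd)), float(np.exp(mu + z * sd))


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Draw one synthetic cohort; identical config + seed => identical data."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20467]))
    n = config.n_total

    diagnosis = np.array(
        ["AD"] * config.n_ad + ["MCI"] * config.n_mci + ["HC"] * config.n_hc)
    ids = [f"P{i + 1:03d}" for i in range(n)]

    # clinical view
    age = np.empty(n)
    mmse = np.empty(n)
    apoe = np.empty(n, dtype=object)
    duration = np.empty(n)
    for dx in V.DIAGNOSES:
        m = diagnosis == dx
        k = int(m.sum())
        age[m] = np.clip(np.round(rng.normal(_AGE_MEAN[dx], 8.0, k)), 49, 90)
        mmse[m] = np.clip(np.round(rng.normal(_MMSE_MEAN[dx], _MMSE_SD[dx], k)), 0, 30)
        apoe[m] = rng.choice(V.APOE_GENOTYPES, size=k, p=_APOE_P[dx])
        if dx == "HC":
            duration[m] = 0.0
        else:
            scale = 1.5 if dx == "AD" else 1.0
            duration[m] = np.round(rng.gamma(2.0, scale, k), 1)
    gender = rng.choice(V.GENDERS, size=n, p=[0.6, 0.4])

    severity = rng.normal(0.0, 1.0, n) + np.array(
        [_SEVERITY_MEAN[d] for d in diagnosis])
    sev_std = (severity - severity.mean()) / severity.std(ddof=0)

    # element views: Gaussian copula on the log scale
    data: dict[str, np.ndarray] = {}
    block_of = {a: b for b in config.factor_blocks for a in b.attributes}
    block_latent: dict[int, np.ndarray] = {}
    dominant = config.factor_blocks[0] if config.factor_blocks else None
    seen_views: set[str] = set()
    for i, block in enumerate(config.factor_blocks):
        g = rng.normal(0.0, 1.0, n)
        # the first (dominant) block of each view tracks disease severity
        if block.view not in seen_views and config.element_severity_coupling > 0:
            c = config.element_severity_coupling
            g = c * sev_std + np.sqrt(1.0 - c * c) * g
            # the dominant plasma block additionally tracks the dominant
            # CSF block (shared exposure across compartments)
            x = config.cross_compartment_coupling
            if (x > 0 and block is not dominant and dominant is not None
                    and block.view != dominant.view):
                g = x * block_latent[id(dominant)] + np.sqrt(1.0 - x * x) * g
        seen_views.add(block.view)
        block_latent[id(block)] = g

    for view in ("csf_elements", "plasma_elements"):
        for col in V.VIEW_COLUMNS[view]:
            mu = config.element_log_mean[col]
            sd = config.element_log_sd[col]
            eps = rng.normal(0.0, 1.0, n)
            block = block_of.get(col)
            if block is not None:
                rho = block.correlation
                z = np.sqrt(rho) * block_latent[id(block)] + np.sqrt(1 - rho) * eps
            else:
                z = eps
            data[col] = np.exp(mu + sd * z)

    # biomarkers from severity + dominant CSF and plasma element blocks
    g1 = (block_latent[id(dominant)]
          if dominant is not None else np.zeros(n))
    bf = config.biomarker_element_coupling if dominant is not None else 0.0
    plasma_dominant = next(
        (b for b in config.factor_blocks if b.view == "plasma_elements"), None)
    g2 = (block_latent[id(plasma_dominant)]
          if plasma_dominant is not None else np.zeros(n))
    bp = (config.biomarker_plasma_coupling
          if plasma_dominant is not None else 0.0)
    for bm in V.BIOMARKERS:
        med, gsd, bs = V.BIOMARKER_SCALE[bm]
        resid = max(1.0 - bs * bs - bf * bf - bp * bp, 0.05)
        z = (bs * sev_std + bf * g1 + bp * g2
             + np.sqrt(resid) * rng.normal(0.0, 1.0, n))
        data[bm] = np.exp(np.log(med) + gsd * z)

    frame = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "age": age,
            "gender": gender,
            "MMSE": mmse,
            "APOE": apoe,
            "disease_duration": duration,
            **data,
        },
        index=pd.Index(ids, name="patient_id"),
    )

    # plant ground-truth subgroups (before missingness)
    membership: list[np.ndarray] = []
    for plant in config.planted_redescriptions:
        members = _plant(frame, plant, config, rng)
        membership.append(members)

    # missingness: MCAR per attribute, then plasma subset restriction
    for attr, frac in sorted(config.missingness.items()):
        if frac > 0:
            mask = rng.random(n) < frac
            frame.loc[mask, attr] = np.nan

    plasma_rows = np.sort(rng.choice(n, size=config.plasma_subset_n, replace=False))
    outside = np.setdiff1d(np.arange(n), plasma_rows)
    frame.iloc[outside, [frame.columns.get_loc(c)
                         for c in V.VIEW_COLUMNS["plasma_elements"]]] = np.nan

    # derived ratio: defined wherever both parents are present
    frame[V.RATIO] = frame["Abeta42"] / frame["p-tau181"]

    frame = frame[[c for cols in V.VIEW_COLUMNS.values() for c in cols]]
    return CohortDataset(
        frame,
        planted_members=[frame.index[m].tolist() for m in membership],
        plasma_subset=frame.index[plasma_rows].tolist(),
    )


def _support_of(attr: str, config: CohortConfig) -> tuple[float, float]:
    if attr in config.element_log_mean:
        return _lognormal_quantiles(
            config.element_log_mean[attr], config.element_log_sd[attr])
    if attr in V.BIOMARKER_SCALE:
        med, gsd, _ = V.BIOMARKER_SCALE[attr]
        return _lognormal_quantiles(np.log(med), gsd)
    if attr in _CLINICAL_SUPPORT:
        return _CLINICAL_SUPPORT[attr]
    raise CohortConfigError(f"cannot plant on non-numeric attribute {attr!r}")


def _plant(frame: pd.DataFrame, plant: PlantedRedescription,
           config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    n = len(frame)
    m = int(round(plant.member_fraction * n))
    members = np.zeros(n, dtype=bool)
    members[rng.choice(n, size=m, replace=False)] = True

    # feasibility: the interval must leave room on at least one side
    sides: dict[str, list[tuple[str, float, float]]] = {}
    for view, attr, low, high in plant.conditions:
        lo_sup, hi_sup = _support_of(attr, config)
        if low <= lo_sup and high >= hi_sup:
            raise CohortConfigError(
                f"planted interval [{low}, {high}] for {attr!r} covers the "
                f"whole attribute support [{lo_sup:.4g}, {hi_sup:.4g}]")
        sides.setdefault(view, []).append((attr, low, high))

    integer_valued = {"age", "MMSE"}

    def draw_inside(attr, low, high, size):
        vals = rng.uniform(low, high, size)
        if attr in integer_valued:
            vals = np.round(vals)
            vals = np.clip(vals, np.ceil(low), np.floor(high))
        return vals

    def draw_outside(attr, low, high, size):
        lo_sup, hi_sup = _support_of(attr, config)
        left = max(low - lo_sup, 0.0)
        right = max(hi_sup - high, 0.0)
        pick_left = rng.random(size) < (left / (left + right) if left + right else 0.5)
        vals = np.where(
            pick_left,
            rng.uniform(lo_sup, max(low, lo_sup + 1e-12), size),
            rng.uniform(min(high, hi_sup - 1e-12), hi_sup, size),
        )
        if left == 0.0:
            vals = rng.uniform(min(high, hi_sup), hi_sup, size)
        elif right == 0.0:
            vals = rng.uniform(lo_sup, max(low, lo_sup), size)
        if attr in integer_valued:
            vals = np.where(pick_left, np.floor(vals), np.ceil(vals))
        # nudge off the closed endpoints
        vals = np.where(np.isclose(vals, low), low - abs(low) * 1e-9 - 1e-12, vals)
        vals = np.where(np.isclose(vals, high), high + abs(high) * 1e-9 + 1e-12, vals)
        return vals

    for view, conds in sides.items():
        nonmembers = np.flatnonzero(~members)
        leak = rng.random(nonmembers.size) < plant.leak_fraction
        # the "spoiled" condition per non-leaking non-member
        spoil_idx = rng.integers(0, len(conds), nonmembers.size)
        for ci, (attr, low, high) in enumerate(conds):
            col = frame[attr].to_numpy(dtype=float, copy=True)
            col[members] = draw_inside(attr, low, high, int(members.sum()))
            inside_nm = leak | (spoil_idx != ci)
            rows_in = nonmembers[inside_nm]
            rows_out = nonmembers[~inside_nm]
            col[rows_in] = draw_inside(attr, low, high, rows_in.size)
            col[rows_out] = draw_outside(attr, low, high, rows_out.size)
            frame[attr] = col
    return members


# -- IO -----------------------------------------------------------------

def default_views_path(path: str) -> str:
    return str(path) + ".views.yaml"


def write_cohort(dataset: CohortDataset, path, views_path=None, sep=",") -> None:
    """Write the cohort as delimited text plus a YAML view-mapping config.

    Missing cells are written empty; floats round-trip exactly (shortest
    repr)."""
    dataset.data.to_csv(path, sep=sep, na_rep="")
    mapping = {
        "views": {k: list(c) for k, c in dataset.view_columns.items()},
        "categorical_levels": {
            k: list(v) for k, v in dataset.categorical_levels.items()},
    }
    vp = views_path or default_views_path(path)
    with open(vp, "w", encoding="utf-8") as fh:
        yaml.safe_dump(mapping, fh, sort_keys=True)


def read_cohort(path, views_path=None, sep=None) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort`; validates levels.

    ``sep=None`` auto-detects comma vs tab from the header line."""
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    vp = views_path or default_views_path(path)
    with open(vp, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    view_columns = {k: list(v) for k, v in mapping["views"].items()}
    levels = {k: list(v) for k, v in mapping.get("categorical_levels", {}).items()}

    frame = pd.read_csv(path, sep=sep, index_col="patient_id", dtype={"patient_id": str})
    frame.index = pd.Index(frame.index.astype(str), name="patient_id")

    known = [c for cols in view_columns.values() for c in cols]
    unknown = [c for c in known if c not in frame.columns]
    if unknown:
        raise CohortParseError(
            "view mapping names columns absent from the file: "
            + ", ".join(sorted(unknown)))

    for col, lv in levels.items():
        if col not in frame.columns:
            continue
        vals = frame[col].dropna()
        bad = vals[~vals.isin(lv)]
        if len(bad):
            row = bad.index[0]
            raise CohortParseError(
                f"invalid level {bad.iloc[0]!r} for {col!r} at row {row!r}; "
                f"expected one of {lv}")
        frame[col] = frame[col].astype(object).where(frame[col].notna(), np.nan)

    if len(frame) == 0:
        # 0-row files lose dtypes; coerce numeric columns for consistency
        for col in frame.columns:
            if col not in levels:
                frame[col] = frame[col].astype(float)
    frame = frame[known]
    return CohortDataset(frame, view_columns, levels)


def config_to_yaml(config: CohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["factor_blocks"] = [
        {"view": b.view, "attributes": list(b.attributes),
         "correlation": b.correlation} for b in config.factor_blocks]
    d["planted_redescriptions"] = [
        {"member_fraction": p.member_fraction,
         "leak_fraction": p.leak_fraction,
         "conditions": [list(c) for c in p.conditions]}
        for p in config.planted_redescriptions]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path) -> CohortConfig:
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if "factor_blocks" in d:
        d["factor_blocks"] = tuple(
            FactorBlock(b["view"], tuple(b["attributes"]), b["correlation"])
            for b in d["factor_blocks"])
    if "planted_redescriptions" in d:
        d["planted_redescriptions"] = tuple(
            PlantedRedescription(
                member_fraction=p["member_fraction"],
                conditions=tuple(tuple(c) for c in p["conditions"]),
                leak_fraction=p.get("leak_fraction", 0.05))
            for p in d["planted_redescriptions"])
    return CohortConfig(**d)
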