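"""Multi-view redescription mining over patient cohorts.

A redescription is a pair (or triple) of AND-only conjunctive queries on
distinct attribute views — e.g. one over CSF biomarkers and one over CSF
element concentrations — that describe nearly the same set of patients.
Accuracy is the Jaccard index of the query supports; statistical
significance is the probability that uniformly random patient subsets of
the same sizes intersect at least as much.

The miner alternates tree-based rule induction between views
(CLUS-RM-style): an initial k-means clustering of the first view seeds
multi-target regression trees (variance-reduction splits) whose
root-to-node paths become interval queries; each view's trees predict
the current rule supports of the other view, a bootstrap forest adds
rule diversity, and a greedy conjunctive-refinement step ANDs extra
conditions into near-threshold candidates.  Emitted redescriptions
satisfy support bounds, a minimum Jaccard and a maximum p-value, and are
deduplicated over runs.

Intervals are closed on both ends and reported at observed data values
(tree thresholds are snapped to the nearest attained value), so a rule
like ``VILIP-1 (121.28, 366.14)`` reads directly off the data.  A patient
with a missing measurement is never described by a rule that uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.tree import DecisionTreeRegressor

from .cohort import CohortDataset

SPECIFICITY_LABELS = ("AD", "AD&MCI", "MCI", "HC&MCI", "HC", "none")

#: per-view-combination support bounds (min, max)
SUPPORT_BOUNDS = {
    ("csf_biomarkers", "csf_elements"): (30, 155),
    ("csf_biomarkers", "plasma_elements"): (30, 115),
    ("csf_biomarkers", "csf_elements", "plasma_elements"): (20, 110),
}


@dataclass(frozen=True)
class Condition:
    attribute: str
    kind: str = "interval"          # "interval" | "categorical"
    low: float | None = None        # closed interval [low, high]
    high: float | None = None
    level: str | None = None

    def __post_init__(self):
        if self.kind == "interval":
            if self.low is None or self.high is None or self.low > self.high:
                raise ValueError(
                    f"interval condition on {self.attribute!r} needs low <= high")
        elif self.kind == "categorical":
            if self.level is None:
                raise ValueError("categorical condition needs a level")
        else:
            raise ValueError(f"unknown condition kind {self.kind!r}")

    def text(self) -> str:
        name = self.attribute
        if name.endswith("_csf"):
            name = f"{name[:-4]} in CSF"
        elif name.endswith("_plasma"):
            name = f"{name[:-7]} in plasma"
        if self.kind == "categorical":
            return f"{name} = {self.level}"
        return f"{name} ({self.low:g}–{self.high:g})"


def _merge_conditions(conds) -> tuple[Condition, ...]:
    """Intersect same-attribute constraints into single closed intervals."""
    by_attr: dict[tuple, Condition] = {}
    for c in conds:
        key = (c.attribute, c.kind, c.level)
        prev = by_attr.get(key)
        if prev is None:
            by_attr[key] = c
        elif c.kind == "interval":
            lo = max(prev.low, c.low)
            hi = min(prev.high, c.high)
            if lo > hi:
                raise EmptyQuery(f"contradictory intervals on {c.attribute!r}")
            by_attr[key] = Condition(c.attribute, "interval", lo, hi)
    return tuple(sorted(by_attr.values(), key=lambda c: (
        c.attribute, c.kind, c.low if c.low is not None else 0.0,
        c.level or "")))


class EmptyQuery(ValueError):
    pass


@dataclass(frozen=True)
class Query:
    view: str
    conditions: tuple[Condition, ...]

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("a query needs at least one condition")
        object.__setattr__(self, "conditions", _merge_conditions(self.conditions))

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(c.attribute for c in self.conditions)

    def text(self) -> str:
        return " AND ".join(c.text() for c in self.conditions)


@dataclass
class Redescription:
    queries: tuple[Query, ...]
    support: frozenset
    union_size: int
    jaccard: float
    p_value: float
    p_method: str = "exact"
    per_diagnosis_pct: dict[str, float] = field(default_factory=dict)
    specificity_label: str = "none"

    @property
    def support_size(self) -> int:
        return len(self.support)

    def attributes(self) -> tuple[str, ...]:
        return tuple(sorted(a for q in self.queries for a in q.attributes))

    def text(self) -> str:
        return " <=> ".join(q.text() for q in self.queries)

    def to_dict(self) -> dict:
        return {
            "queries": [
                {"view": q.view, "text": q.text(),
                 "conditions": [
                     {"attribute": c.attribute, "kind": c.kind,
                      "low": c.low, "high": c.high, "level": c.level}
                     for c in q.conditions]}
                for q in self.queries],
            "support": sorted(self.support),
            "support_size": self.support_size,
            "union_size": self.union_size,
            "jaccard": self.jaccard,
            "p_value": self.p_value,
            "p_method": self.p_method,
            "per_diagnosis_pct": self.per_diagnosis_pct,
            "specificity_label": self.specificity_label,
        }


@dataclass
class MinerParams:
    n_runs: int = 10
    n_iterations: int = 30
    forest_size: int = 20
    min_support: int = 30
    max_support: int = 155
    min_jaccard: float = 0.5
    max_p: float = 0.01
    max_rule_length: int = 8
    initial_clusters: int = 8
    tree_max_depth: int = 4
    seed: int = 0
    # implementation knobs: target-matrix width per tree, per-view rule
    # archive cap (distinct support sets kept per run), scored candidates
    # refined per run, refinement condition-pool width, and Monte Carlo
    # draws for the 3-view significance fallback
    max_targets: int = 48
    pool_cap: int = 4000
    max_candidates: int = 1500
    refine_pool_cap: int = 200
    mc_samples: int = 100000
    # individual queries broader than this fraction of the cohort are
    # near-tautological: at such support the Jaccard threshold is within
    # reach of chance alone (given the millions of rule pairs a run
    # scores) and the random-subset significance model has no power
    # against it, so broader rules are not kept as candidates
    max_query_support_frac: float = 0.45

    def max_query_support(self, n: int) -> int:
        return min(self.max_support, int(self.max_query_support_frac * n))

    def validate(self, n: int | None = None) -> None:
        if not 0 < self.min_support <= self.max_support:
            raise ValueError("need 0 < min_support <= max_support")
        if n is not None and self.max_support > n:
            raise ValueError("max_support exceeds cohort size")
        if not 0 < self.min_jaccard <= 1:
            raise ValueError("min_jaccard must be in (0, 1]")
        if not 0 < self.max_p <= 1:
            raise ValueError("max_p must be in (0, 1]")


# -- query evaluation ---------------------------------------------------

def evaluate_query(query: Query, dataset: CohortDataset) -> frozenset:
    """Patients satisfying every condition on non-missing values."""
    mask = np.ones(dataset.n, dtype=bool)
    for cond in query.conditions:
        if cond.attribute not in dataset.data.columns:
            raise KeyError(f"unknown attribute {cond.attribute!r}")
        col = dataset.data[cond.attribute]
        if cond.kind == "categorical":
            m = (col == cond.level).to_numpy()
        else:
            v = col.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                m = (v >= cond.low) & (v <= cond.high)
        mask &= np.asarray(m, dtype=bool)
    return frozenset(dataset.patient_ids[mask])


def jaccard(supports) -> tuple[int, int, float]:
    """(intersection size, union size, Jaccard index); 0/0 defined as 0."""
    sets = [set(s) for s in supports]
    if not 2 <= len(sets) <= 3:
        raise ValueError("jaccard takes 2 or 3 support sets")
    inter = set.intersection(*sets)
    union = set.union(*sets)
    j = len(inter) / len(union) if union else 0.0
    return len(inter), len(union), j


# -- significance model -------------------------------------------------

def redescription_pvalue(support_sizes, intersection: int, n: int,
                         mc_samples: int = 100000, seed: int = 0
                         ) -> tuple[float, str]:
    """P(random subsets of the given sizes intersect in >= ``intersection``
    patients), under independent uniform subsets of an ``n``-patient
    universe.  Exact for two sets (hypergeometric upper tail) and for
    three sets with n <= 500 (convolution of conditional hypergeometrics);
    seeded Monte Carlo otherwise.
    """
    sizes = sorted(int(s) for s in support_sizes)
    if not 2 <= len(sizes) <= 3:
        raise ValueError("need 2 or 3 support sizes")
    if any(s < 0 or s > n for s in sizes):
        raise ValueError("support sizes must be within [0, n]")
    if intersection > min(sizes):
        raise ValueError(
            f"intersection {intersection} exceeds smallest support {min(sizes)}")
    if intersection <= 0:
        return 1.0, "exact"
    if len(sizes) == 2:
        a, b = sizes
        return float(stats.hypergeom.sf(intersection - 1, n, a, b)), "exact"
    a, b, c = sizes
    if n <= 500:
        j = np.arange(max(0, a + b - n), min(a, b) + 1)
        pmf_ab = stats.hypergeom.pmf(j, n, a, b)
        tail_c = stats.hypergeom.sf(intersection - 1, n, j, c)
        return float(np.dot(pmf_ab, tail_c)), "exact"
    rng = np.random.default_rng(seed)
    j = rng.hypergeometric(a, n - a, b, size=mc_samples)
    t = rng.hypergeometric(j, n - j, c)
    return float(np.mean(t >= intersection)), "monte_carlo"


# -- internal view representation --------------------------------------

class _ViewData:
    """Numeric feature matrix for one view: one-hot categoricals, per-
    feature sorted observed values, fast conjunctive support evaluation."""

    def __init__(self, df: pd.DataFrame, view: str,
                 categorical_levels: dict[str, list[str]]):
        self.view = view
        self.index = df.index
        feats = {}
        self.catmap: dict[str, tuple[str, str]] = {}
        for col in df.columns:
            if col in categorical_levels or df[col].dtype == object:
                levels = categorical_levels.get(
                    col, sorted(df[col].dropna().unique()))
                for lv in levels:
                    name = f"{col}={lv}"
                    feats[name] = (df[col] == lv).astype(float).where(
                        df[col].notna(), np.nan)
                    self.catmap[name] = (col, lv)
            else:
                feats[name := col] = df[col].astype(float)
        self.frame = pd.DataFrame(feats, index=df.index)
        self.X = self.frame.to_numpy(dtype=float)
        self.features = list(self.frame.columns)
        self.sorted_values = [
            np.unique(self.X[:, j][~np.isnan(self.X[:, j])])
            for j in range(self.X.shape[1])]
        self._cond_cache: dict[Condition, np.ndarray] = {}

    def condition_mask(self, cond: Condition) -> np.ndarray:
        m = self._cond_cache.get(cond)
        if m is not None:
            return m
        if cond.kind == "categorical":
            j = self.features.index(f"{cond.attribute}={cond.level}")
            v = self.X[:, j]
            with np.errstate(invalid="ignore"):
                m = v == 1.0
        else:
            j = self.features.index(cond.attribute)
            v = self.X[:, j]
            with np.errstate(invalid="ignore"):
                m = (v >= cond.low) & (v <= cond.high)
        m = np.asarray(m, dtype=bool)
        self._cond_cache[cond] = m
        return m

    def query_mask(self, query: Query) -> np.ndarray:
        m = np.ones(len(self.index), dtype=bool)
        for c in query.conditions:
            m &= self.condition_mask(c)
        return m


def _view_frame(dataset: CohortDataset, view: str,
                include_clinical=("MMSE", "age", "APOE")) -> pd.DataFrame:
    """Raw attribute frame of a mining view.  Clinical covariates ride
    along with the biomarker view, where they appear in reported rules."""
    cols = list(dataset.view_columns[view])
    if view == "csf_biomarkers" and include_clinical:
        cols = cols + [c for c in include_clinical
                       if c in dataset.data.columns]
    return dataset.data[cols]


# -- rule induction -----------------------------------------------------

def _harvest_tree(tree: DecisionTreeRegressor, vd: _ViewData,
                  max_rule_length: int) -> list[tuple[Condition, ...]]:
    """Convert every root-to-node path (depth >= 1) into merged, closed,
    data-snapped interval conditions."""
    t = tree.tree_
    out: list[tuple[Condition, ...]] = []
    # constraints: feature -> [low_raw (exclusive), high_raw (inclusive)]
    stack: list[tuple[int, dict]] = [(0, {})]
    while stack:
        node, constr = stack.pop()
        if node != 0:
            conds = _constraints_to_conditions(constr, vd)
            if conds is not None and 0 < len(conds) <= max_rule_length:
                out.append(conds)
        left = t.children_left[node]
        if left == -1:
            continue
        right = t.children_right[node]
        f, thr = int(t.feature[node]), float(t.threshold[node])
        lo, hi = constr.get(f, (-np.inf, np.inf))
        cl = dict(constr)
        cl[f] = (lo, min(hi, thr))
        cr = dict(constr)
        cr[f] = (max(lo, thr), hi)
        stack.append((right, cr))
        stack.append((left, cl))
    return out


def _constraints_to_conditions(constr: dict, vd: _ViewData):
    conds = []
    for f, (lo_raw, hi_raw) in sorted(constr.items()):
        name = vd.features[f]
        if name in vd.catmap:
            attr, level = vd.catmap[name]
            if lo_raw > -np.inf and lo_raw >= 0.5:
                conds.append(Condition(attr, "categorical", level=level))
            # the <= 0.5 branch is a negation; AND-only rules drop it,
            # which only widens the candidate query
            continue
        u = vd.sorted_values[f]
        if u.size == 0:
            return None
        i = np.searchsorted(u, lo_raw, side="right")   # first value > lo_raw
        k = np.searchsorted(u, hi_raw, side="right") - 1  # last value <= hi_raw
        if i > k:
            return None
        conds.append(Condition(name, "interval", float(u[i]), float(u[k])))
    return tuple(conds)


def induce_rules(view_df: pd.DataFrame, target_memberships, params: MinerParams,
                 view: str = "view", categorical_levels: dict | None = None,
                 seed: int | None = None) -> list[Query]:
    """Grow a multi-target variance-reduction tree (plus a bootstrap
    forest with random feature subsets) on the view's attributes
    predicting the membership-indicator matrix, and return the
    deduplicated path queries whose support size lies within the
    configured bounds."""
    if view_df.shape[1] == 0:
        raise ValueError("empty view")
    vd = _ViewData(view_df, view, categorical_levels or {})
    if isinstance(target_memberships, np.ndarray) and target_memberships.ndim == 2:
        target_memberships = [target_memberships[:, j]
                              for j in range(target_memberships.shape[1])]
    cols = []
    for t in target_memberships:
        if isinstance(t, (set, frozenset)):
            cols.append(view_df.index.isin(list(t)).astype(float))
        else:
            cols.append(np.asarray(t, dtype=float))
    if not cols:
        raise ValueError("need at least one target membership")
    Y = np.column_stack(cols)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pairs = _induce(vd, Y, params, rng)
    return [q for q, _ in pairs]


def _induce(vd: _ViewData, Y: np.ndarray, params: MinerParams,
            rng: np.random.Generator) -> list[tuple[Query, np.ndarray]]:
    n, _ = vd.X.shape
    # leaves below the minimal rule support cannot produce valid rules;
    # coarser trees also keep the alternation from carving spurious
    # alignments out of noise
    min_leaf = max(2, params.min_support)
    trees = []
    # main multi-target tree on all rows and a bounded target subset
    main_cols = (np.arange(Y.shape[1]) if Y.shape[1] <= 8
                 else np.sort(rng.choice(Y.shape[1], size=8, replace=False)))
    t0 = DecisionTreeRegressor(
        max_depth=params.tree_max_depth, min_samples_leaf=min_leaf,
        random_state=int(rng.integers(2 ** 31)))
    trees.append((t0, np.arange(n), main_cols))
    # bootstrap forest: random feature subsets and 1-2 random targets per
    # tree, so individual trees specialise on single memberships
    for _ in range(params.forest_size):
        rows = rng.integers(0, n, n)
        k = int(rng.integers(1, min(2, Y.shape[1]) + 1))
        tcols = rng.choice(Y.shape[1], size=k, replace=False)
        tf = DecisionTreeRegressor(
            max_depth=params.tree_max_depth, min_samples_leaf=min_leaf,
            max_features=0.6, random_state=int(rng.integers(2 ** 31)))
        trees.append((tf, rows, np.sort(tcols)))

    seen: dict[tuple, None] = {}
    out: list[tuple[Query, np.ndarray]] = []
    for tree, rows, tcols in trees:
        Xf = vd.X[rows]
        Yf = Y[np.ix_(rows, tcols)]
        if np.all(Yf.std(axis=0) == 0):
            continue
        tree.fit(Xf, Yf)
        for conds in _harvest_tree(tree, vd, params.max_rule_length):
            if conds in seen:
                continue
            seen[conds] = None
            try:
                q = Query(vd.view, conds)
            except (EmptyQuery, ValueError):
                continue
            mask = vd.query_mask(q)
            s = int(mask.sum())
            if params.min_support <= s <= params.max_query_support(n):
                out.append((q, mask))
    return out


# -- labelling & counting ----------------------------------------------

def label_specificity(redescription: Redescription, dataset: CohortDataset,
                      dominance: float = 1.5) -> Redescription:
    """Per-diagnosis percentages (of each diagnosis group described) and a
    dominance-based specificity label.  A single group wins when its
    percentage is >= dominance x each other group's; the adjacent pairs
    AD&MCI / HC&MCI win when both top groups are >= dominance x the
    third; otherwise 'none'."""
    if "diagnosis" not in dataset.data.columns:
        redescription.per_diagnosis_pct = {}
        redescription.specificity_label = "none"
        return redescription
    dx = dataset.data["diagnosis"]
    pct = {}
    for g in ("HC", "MCI", "AD"):
        members = set(dataset.patient_ids[(dx == g).to_numpy()])
        denom = len(members)
        pct[g] = 100.0 * len(redescription.support & members) / denom if denom else 0.0
    if not redescription.support:
        redescription.per_diagnosis_pct = pct
        redescription.specificity_label = "none"
        return redescription
    label = "none"
    order = sorted(pct, key=lambda g: -pct[g])
    top, second, third = order
    if all(pct[top] >= dominance * pct[g] for g in (second, third)):
        label = top
    elif (pct[top] >= dominance * pct[third]
          and pct[second] >= dominance * pct[third]):
        pair = frozenset((top, second))
        if pair == frozenset(("AD", "MCI")):
            label = "AD&MCI"
        elif pair == frozenset(("HC", "MCI")):
            label = "HC&MCI"
    redescription.per_diagnosis_pct = pct
    redescription.specificity_label = label
    return redescription


def count_cooccurrence(redescriptions, attr_a: str, attr_b: str) -> int:
    """Number of redescriptions whose combined queries use both attributes."""
    count = 0
    for rd in redescriptions:
        attrs = set(rd.attributes())
        if attr_a in attrs and attr_b in attrs:
            count += 1
    return count


# -- refinement ---------------------------------------------------------

def _score(masks: list[np.ndarray]) -> tuple[int, int, float]:
    inter = masks[0].copy()
    union = masks[0].copy()
    for m in masks[1:]:
        inter &= m
        union |= m
    i, u = int(inter.sum()), int(union.sum())
    return i, u, (i / u if u else 0.0)


def _refine_masks(queries: list[Query], masks: list[np.ndarray],
                  cond_pools, params: MinerParams):
    """Greedy conjunctive refinement on bitmasks; returns possibly
    improved (queries, masks).  ``cond_pools`` holds, per view, a pair
    (condition list, boolean condition x patient matrix)."""
    queries = list(queries)
    masks = [m.copy() for m in masks]
    _, _, jac = _score(masks)
    for _ in range(params.max_rule_length * len(queries)):
        best = None
        for vi, (conds, C) in enumerate(cond_pools):
            if not conds or len(queries[vi].conditions) >= params.max_rule_length:
                continue
            others = [m for k, m in enumerate(masks) if k != vi]
            inter_o = np.logical_and.reduce(others)
            union_o = np.logical_or.reduce(others)
            base_i = (inter_o & masks[vi]).astype(np.float32)
            base_u = (masks[vi] & ~union_o).astype(np.float32)
            ni = C @ base_i                       # |∩| after ANDing each cond
            nu = float(union_o.sum()) + C @ base_u
            with np.errstate(invalid="ignore", divide="ignore"):
                nj = np.where(nu > 0, ni / nu, 0.0)
            nj[ni < params.min_support] = -1.0
            k = int(np.argmax(nj))
            if nj[k] > jac + 1e-12 and (best is None or nj[k] > best[0]):
                best = (float(nj[k]), vi, conds[k])
        if best is None:
            break
        jac, vi, cond = best
        try:
            queries[vi] = Query(queries[vi].view,
                                queries[vi].conditions + (cond,))
        except (EmptyQuery, ValueError):
            break
        masks[vi] = masks[vi] & (cond_pools[vi][1][
            cond_pools[vi][0].index(cond)] > 0)
    return queries, masks


def refine_conjunctive(redescription: Redescription, rule_pool,
                       dataset: CohortDataset, params: MinerParams
                       ) -> Redescription:
    """AND single conditions from same-view pool rules into the
    redescription's queries while the Jaccard index strictly increases
    and the support stays >= min_support."""
    ids = dataset.patient_ids
    masks = [np.asarray(ids.isin(list(evaluate_query(q, dataset))))
             for q in redescription.queries]
    pools = []
    for q in redescription.queries:
        seen = set(); conds = []; rows = []
        for rq in rule_pool:
            if rq.view != q.view:
                continue
            for c in rq.conditions:
                if c not in seen:
                    seen.add(c)
                    conds.append(c)
                    rows.append(np.asarray(ids.isin(list(evaluate_query(
                        Query(q.view, (c,)), dataset)))))
        C = (np.array(rows, dtype=np.float32) if rows
             else np.zeros((0, dataset.n), dtype=np.float32))
        pools.append((conds, C))
    queries, masks = _refine_masks(list(redescription.queries), masks, pools, params)
    i, u, j = _score(masks)
    p, meth = redescription_pvalue(
        [int(m.sum()) for m in masks], i, dataset.n,
        mc_samples=params.mc_samples, seed=params.seed)
    sup = frozenset(ids[np.logical_and.reduce(masks)])
    return Redescription(tuple(queries), sup, u, j, p, meth,
                         dict(redescription.per_diagnosis_pct),
                         redescription.specificity_label)


# -- the miner ----------------------------------------------------------

def mine(dataset: CohortDataset, views, params: MinerParams | None = None,
         include_clinical=("MMSE", "age", "APOE")) -> list[Redescription]:
    """Alternating multi-view redescription mining.

    For each seeded run: an initial k-means clustering of the first
    view's standardized complete-case data seeds the targets; for
    ``n_iterations`` alternations, rules are induced on each view with
    the other view's current rule supports as tree targets (round-robin
    for three views); all cross-view combinations are scored by Jaccard,
    near-threshold candidates are conjunctively refined, and survivors of
    the support / Jaccard / significance filters are pooled over runs,
    deduplicated and sorted by p-value.
    """
    views = tuple(views)
    if len(set(views)) != len(views) or not 2 <= len(views) <= 3:
        raise ValueError("need 2 or 3 distinct views")
    if params is None:
        params = default_params(views)
    params.validate(dataset.n)

    # mining universe: patients with at least one measurement in every
    # participating view (a patient with an entirely missing view can
    # never be described there and would only inflate unions, distorting
    # both the Jaccard index and the significance model's universe size)
    universe = np.ones(dataset.n, dtype=bool)
    for view in views:
        universe &= dataset.view(view).notna().any(axis=1).to_numpy()
    vds = []
    for vi, view in enumerate(views):
        df = _view_frame(dataset, view,
                         include_clinical if vi == 0 else ())
        vds.append(_ViewData(df.loc[universe], view, dataset.categorical_levels))
    n = int(universe.sum())
    ids = dataset.patient_ids[universe]
    if n < params.min_support:
        import warnings
        warnings.warn("fewer patients than min_support; no redescriptions")
        return []
    seed_rules = [_marginal_rules(vd, params) for vd in vds]

    found: dict[tuple, Redescription] = {}
    master = np.random.SeedSequence(params.seed)
    run_seeds = master.spawn(params.n_runs)
    for run, seed_seq in enumerate(run_seeds):
        rng = np.random.default_rng(seed_seq)
        cluster_targets = _initial_clusters(vds[0], params, rng)
        # archive of distinct support sets per view (shortest query kept),
        # seeded with the marginal quantile rules
        archives: list[dict[bytes, tuple[Query, np.ndarray]]] = [
            {m.tobytes(): (q, m) for q, m in rules} for rules in seed_rules]
        latest: list[list[np.ndarray]] = [
            [cluster_targets[:, j] for j in range(cluster_targets.shape[1])]
            + [m for _, m in rules]
            for rules in seed_rules]

        for _ in range(params.n_iterations):
            for vi in range(len(views)):
                src = (vi + 1) % len(views)   # round-robin target source
                Y = _pick_targets(latest[src], params, rng)
                produced: list[np.ndarray] = []
                fresh: list[np.ndarray] = []
                for q, m in _induce(vds[vi], Y, params, rng):
                    key = m.tobytes()
                    prev = archives[vi].get(key)
                    if prev is None:
                        if len(archives[vi]) < params.pool_cap:
                            archives[vi][key] = (q, m)
                            fresh.append(m)
                            produced.append(m)
                    else:
                        produced.append(m)
                        if len(q.conditions) < len(prev[0].conditions):
                            archives[vi][key] = (q, m)
                if produced:
                    # a couple of best-matching rules keep the alternation
                    # chain alive; the bulk is random fresh exploration
                    elite = _best_matching(produced, Y, 2)
                    pool = fresh or produced
                    k = min(len(pool), params.max_targets - len(elite))
                    idx = rng.choice(len(pool), size=k, replace=False)
                    latest[vi] = elite + [pool[i] for i in sorted(idx)]

        _score_and_collect(archives, vds, views, params, n, ids, dataset, found)

    out = sorted(found.values(),
                 key=lambda r: (r.p_value, -r.jaccard, r.text()))
    for rd in out:
        label_specificity(rd, dataset)
    return out


def default_params(views, seed: int = 0) -> MinerParams:
    bounds = SUPPORT_BOUNDS.get(tuple(views))
    p = MinerParams(seed=seed)
    if bounds:
        p.min_support, p.max_support = bounds
    return p


def _marginal_rules(vd: _ViewData, params: MinerParams
                    ) -> list[tuple[Query, np.ndarray]]:
    """Systematic one-condition seed rules: every contiguous quartile
    interval of every numeric attribute (plus each categorical level),
    support-bound filtered.  These are ordinary queries of the view; they
    seed the alternation alongside the k-means partition and give the
    scoring stage a complete single-condition baseline."""
    out: list[tuple[Query, np.ndarray]] = []
    seen: set[bytes] = set()
    qs = np.linspace(0.0, 1.0, 11)
    for j, name in enumerate(vd.features):
        u = vd.sorted_values[j]
        if u.size < 4:
            continue
        if name in vd.catmap:
            attr, level = vd.catmap[name]
            conds = [Condition(attr, "categorical", level=level)]
        else:
            vals = vd.X[:, j]
            vals = vals[~np.isnan(vals)]
            cuts = np.quantile(vals, qs)
            conds = []
            for a in range(len(cuts) - 1):
                for b in range(a + 2, len(cuts)):  # width >= 2 deciles
                    lo = u[np.searchsorted(u, cuts[a], side="left")]
                    hi = u[np.searchsorted(u, cuts[b], side="right") - 1]
                    if lo <= hi:
                        conds.append(Condition(name, "interval",
                                               float(lo), float(hi)))
        for c in conds:
            m = vd.condition_mask(c)
            s = int(m.sum())
            if params.min_support <= s <= params.max_query_support(len(vd.index)):
                key = m.tobytes()
                if key not in seen:
                    seen.add(key)
                    out.append((Query(vd.view, (c,)), m))
    return out


def _initial_clusters(vd: _ViewData, params: MinerParams,
                      rng: np.random.Generator) -> np.ndarray:
    cc = ~np.isnan(vd.X).any(axis=1)
    Xc = vd.X[cc]
    k = min(params.initial_clusters, max(2, len(Xc) // 5))
    if len(Xc) < k or k < 2:
        return np.ones((vd.X.shape[0], 1))
    mu = Xc.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    km = KMeans(n_clusters=k, n_init=4,
                random_state=int(rng.integers(2 ** 31)))
    lab = km.fit_predict((Xc - mu) / sd)
    Y = np.zeros((vd.X.shape[0], k))
    Y[np.flatnonzero(cc), lab] = 1.0
    return Y


def _best_matching(produced: list[np.ndarray], Y: np.ndarray,
                   k: int) -> list[np.ndarray]:
    """The k produced rule supports with the highest Jaccard against any
    of the target columns they were induced to predict."""
    if k <= 0 or not produced:
        return []
    M = np.array(produced, dtype=np.float32)
    T = (Y > 0.5).astype(np.float32).T          # targets x n
    inter = M @ T.T
    union = M.sum(axis=1)[:, None] + T.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    best = jac.max(axis=1)
    order = np.argsort(-best, kind="stable")[:k]
    return [produced[i] for i in sorted(order)]


def _pick_targets(latest: list[np.ndarray], params: MinerParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Target matrix for the next alternation: the other view's most
    recently induced rule supports, subsampled to max_targets."""
    masks = latest
    if len(masks) > params.max_targets:
        idx = rng.choice(len(masks), size=params.max_targets, replace=False)
        masks = [masks[i] for i in sorted(idx)]
    return np.column_stack([np.asarray(m, dtype=float) for m in masks])


def _score_and_collect(pools, vds, views, params, n, ids, dataset, found):
    mats = []
    entries = []
    for pool in pools:
        qs = [q for q, _ in pool.values()]
        ms = np.array([m for _, m in pool.values()], dtype=bool) \
            if pool else np.zeros((0, n), dtype=bool)
        entries.append(qs)
        mats.append(ms)
    if any(len(e) == 0 for e in entries):
        return

    refine_floor = 0.8 * params.min_jaccard
    cond_pools = _condition_pools(entries, vds, cap=params.refine_pool_cap)

    A, B = mats[0], mats[1]
    sizes_a = A.sum(axis=1)
    sizes_b = B.sum(axis=1)
    inter = A.astype(np.float32) @ B.astype(np.float32).T
    union = sizes_a[:, None] + sizes_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / union, 0.0)
    # candidate priority: Jaccard excess over the chance level of
    # independent subsets of the same sizes (broad rules overlap a lot by
    # chance alone and would otherwise crowd out genuine subgroups)
    exp_inter = sizes_a[:, None] * sizes_b[None, :] / float(n)
    exp_jac = exp_inter / np.maximum(
        sizes_a[:, None] + sizes_b[None, :] - exp_inter, 1.0)
    excess = jac - exp_jac

    if len(mats) == 2:
        ok = ((inter >= params.min_support) & (inter <= params.max_support)
              & (jac >= refine_floor))
        cand = np.argwhere(ok)
        order = np.argsort(-excess[ok.nonzero()], kind="stable")
        # keep the best-Jaccard candidate per distinct intersection set,
        # so near-duplicate pairs do not crowd out distinct subgroups
        seen_inter: set[bytes] = set()
        taken = 0
        for i, j in cand[order]:
            key = (A[i] & B[j]).tobytes()
            if key in seen_inter:
                continue
            seen_inter.add(key)
            _consider([entries[0][i], entries[1][j]],
                      [A[i], B[j]], cond_pools, params, n, ids, found, vds)
            taken += 1
            if taken >= params.max_candidates:
                break
    else:
        C = mats[2]
        sizes_c = C.sum(axis=1)
        pair_ok = (inter >= params.min_support) & (jac >= refine_floor)
        pairs = np.argwhere(pair_ok)
        order = np.argsort(-excess[pair_ok.nonzero()], kind="stable")
        pairs = pairs[order][: max(200, params.max_candidates // 5)]
        Cf = C.astype(np.float32)
        budget = params.max_candidates
        for i, j in pairs:
            if budget <= 0:
                break
            ab = A[i] & B[j]
            ab_u = A[i] | B[j]
            i3 = ab.astype(np.float32) @ Cf.T
            u3 = ab_u.sum() + sizes_c - ab_u.astype(np.float32) @ Cf.T
            with np.errstate(invalid="ignore", divide="ignore"):
                j3 = np.where(u3 > 0, i3 / u3, 0.0)
            e_i3 = float(ab.sum()) * sizes_c / float(n)
            e_u3 = np.maximum(float(ab_u.sum()) + sizes_c - e_i3, 1.0)
            excess3 = j3 - e_i3 / e_u3
            ks = np.flatnonzero(
                (i3 >= params.min_support) & (i3 <= params.max_support)
                & (j3 >= refine_floor))
            ks = ks[np.argsort(-excess3[ks], kind="stable")][:20]
            for k in ks:
                if budget <= 0:
                    break
                budget -= 1
                _consider([entries[0][i], entries[1][j], entries[2][k]],
                          [A[i], B[j], C[k]], cond_pools, params, n, ids, found, vds)


def _condition_pools(entries, vds, cap: int = 200):
    pools = []
    for qs, vd in zip(entries, vds):
        seen = set(); conds = []; rows = []
        for q in qs:
            for c in q.conditions:
                if c not in seen:
                    seen.add(c)
                    conds.append(c)
                    rows.append(vd.condition_mask(c))
                    if len(conds) >= cap:
                        break
            if len(conds) >= cap:
                break
        C = (np.array(rows, dtype=np.float32) if rows
             else np.zeros((0, len(vds[0].index)), dtype=np.float32))
        pools.append((conds, C))
    return pools


def _tighten(queries, masks, vds, params):
    """Shrink interval bounds to the value range attained on the current
    intersection; kept only when the Jaccard index improves.  This
    reports data-valued endpoints and, for well-separated subgroups,
    recovers the exact planted intervals."""
    inter = np.logical_and.reduce(masks)
    if int(inter.sum()) < params.min_support:
        return queries, masks
    _, _, j0 = _score(masks)
    rows = np.flatnonzero(inter)
    newq, newm = [], []
    for q, m, vd in zip(queries, masks, vds):
        conds = []
        for c in q.conditions:
            if c.kind == "interval" and c.attribute in vd.features:
                col = vd.X[rows, vd.features.index(c.attribute)]
                col = col[~np.isnan(col)]
                if col.size:
                    c = Condition(c.attribute, "interval",
                                  max(c.low, float(col.min())),
                                  min(c.high, float(col.max())))
            conds.append(c)
        try:
            q2 = Query(q.view, tuple(conds))
        except (EmptyQuery, ValueError):
            return queries, masks
        newq.append(q2)
        newm.append(vd.query_mask(q2))
    i1, _, j1 = _score(newm)
    if j1 > j0 + 1e-12 and i1 >= params.min_support:
        return newq, newm
    return queries, masks


def _consider(queries, masks, cond_pools, params, n, ids, found, vds=None):
    queries, masks = _refine_masks(queries, masks, cond_pools, params)
    # tightening only polishes already-valid redescriptions; letting it
    # rescue sub-threshold candidates would reopen the noise channel the
    # Jaccard filter exists to close
    if vds is not None and _score(masks)[2] >= params.min_jaccard:
        queries, masks = _tighten(queries, masks, vds, params)
    i, u, j = _score(masks)
    if not (params.min_support <= i <= params.max_support):
        return
    if j < params.min_jaccard:
        return
    p, meth = redescription_pvalue(
        [int(m.sum()) for m in masks], i, n,
        mc_samples=params.mc_samples, seed=params.seed)
    if p > params.max_p:
        return
    support = frozenset(ids[np.logical_and.reduce(masks)])
    rd = Redescription(tuple(queries), support, u, j, p, meth)
    key = (support, rd.attributes())
    prev = found.get(key)
    if prev is None or _better(rd, prev):
        found[key] = rd


def _better(a: Redescription, b: Redescription) -> bool:
    ka = (-a.jaccard, sum(len(q.conditions) for q in a.queries), a.text())
    kb = (-b.jaccard, sum(len(q.conditions) for q in b.queries), b.text())
    return ka < kb
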