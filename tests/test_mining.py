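"""Redescription mining: rule semantics, Jaccard, significance, search."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from csfmetals import (CohortConfig, Condition, MinerParams, Query,
                       count_cooccurrence, evaluate_query, generate_cohort,
                       induce_rules, jaccard, label_specificity, mine,
                       redescription_pvalue, refine_conjunctive)
from csfmetals.cohort import PlantedRedescription
from csfmetals.mining import Redescription


# -- query semantics ----------------------------------------------------

def test_closed_endpoints_and_missing_semantics(toy_two_view):
    ds = toy_two_view
    q = Query("v1", (Condition("A", low=2.0, high=2.0),))
    assert evaluate_query(q, ds) == {"P2"}
    q = Query("v1", (Condition("A", low=0.0, high=10.0),))
    assert "P5" not in evaluate_query(q, ds)  # missing A => not described


def test_query_support_matches_brute_force_scan(toy_two_view):
    ds = toy_two_view
    q = Query("v1", (Condition("A", low=1.0, high=3.0),
                     Condition("B", low=0.0, high=5.0)))
    expected = set()
    for pid, row in ds.data.iterrows():
        if (not pd.isna(row["A"]) and 1.0 <= row["A"] <= 3.0
                and not pd.isna(row["B"]) and 0.0 <= row["B"] <= 5.0):
            expected.add(pid)
    assert evaluate_query(q, ds) == expected


def test_unknown_attribute_named(toy_two_view):
    q = Query("v1", (Condition("nope", low=0.0, high=1.0),))
    with pytest.raises(KeyError, match="nope"):
        evaluate_query(q, toy_two_view)


def test_same_attribute_conditions_merge_to_interval():
    q = Query("v1", (Condition("A", low=2.0, high=100.0),
                     Condition("A", low=0.0, high=7.0)))
    assert len(q.conditions) == 1
    assert (q.conditions[0].low, q.conditions[0].high) == (2.0, 7.0)


def test_jaccard_identities():
    assert jaccard([{1, 2}, {1, 2}]) == (2, 2, 1.0)
    assert jaccard([{1, 2}, {3, 4}]) == (0, 4, 0.0)
    assert jaccard([set(), set()]) == (0, 0, 0.0)
    assert jaccard([{1, 2, 3}, {2, 3, 4}, {3, 4, 5}]) == (1, 5, 0.2)


# -- significance model -------------------------------------------------

def enum_pvalue_two(n, a, b, k):
    """Exhaustive oracle: fix A, enumerate all subsets B via bitmasks."""
    amask = (1 << a) - 1
    total = hits = 0
    for bits in itertools.combinations(range(n), b):
        bm = 0
        for i in bits:
            bm |= 1 << i
        total += 1
        if bin(bm & amask).count("1") >= k:
            hits += 1
    return hits / total


def test_pvalue_trivial_cases():
    assert redescription_pvalue([5, 5], 0, 10)[0] == 1.0
    p, _ = redescription_pvalue([5, 5], 5, 10)
    assert p == pytest.approx(1 / math.comb(10, 5), abs=1e-15)
    with pytest.raises(ValueError):
        redescription_pvalue([3, 5], 4, 10)


def test_pvalue_matches_enumeration_small():
    for (n, a, b) in [(8, 3, 5), (10, 4, 4), (12, 6, 5)]:
        for k in range(0, min(a, b) + 1):
            p, meth = redescription_pvalue([a, b], k, n)
            assert meth == "exact"
            assert p == pytest.approx(enum_pvalue_two(n, a, b, k), abs=1e-12)


def test_pvalue_three_sets_matches_enumeration():
    n, a, b, c = 8, 4, 3, 5
    amask = (1 << a) - 1
    subsets_b = list(itertools.combinations(range(n), b))
    subsets_c = list(itertools.combinations(range(n), c))
    for k in range(0, 4):
        hits = total = 0
        for bb in subsets_b:
            bmask = 0
            for i in bb:
                bmask |= 1 << i
            ab = bmask & amask
            for cc in subsets_c:
                cmask = 0
                for i in cc:
                    cmask |= 1 << i
                total += 1
                if bin(ab & cmask).count("1") >= k:
                    hits += 1
        p, _ = redescription_pvalue([a, b, c], k, n)
        assert p == pytest.approx(hits / total, abs=1e-12)


def test_pvalue_monotone_in_intersection():
    ps = [redescription_pvalue([40, 50], k, 193)[0] for k in range(0, 41)]
    assert all(ps[i] >= ps[i + 1] - 1e-15 for i in range(40))


def test_pvalue_monte_carlo_close_to_exact():
    exact, _ = redescription_pvalue([60, 50, 40], 12, 400)
    n_big = 501  # force the Monte Carlo path
    mc, meth = redescription_pvalue([75, 63, 50], 15, n_big,
                                    mc_samples=200000, seed=3)
    assert meth == "monte_carlo"
    ex2 = redescription_pvalue([75, 63, 50], 15, 500)[0]  # nearby exact
    assert mc == pytest.approx(ex2, rel=0.2, abs=0.002)


# -- rule induction -----------------------------------------------------

def _sep_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    frame = pd.DataFrame({"X": x, "Z": rng.normal(size=n)},
                         index=[f"P{i}" for i in range(n)])
    target = x > 0.2
    return frame, target


def test_induce_rules_finds_separating_threshold():
    frame, target = _sep_frame()
    params = MinerParams(min_support=5, max_support=50, seed=0,
                         max_query_support_frac=1.0)
    queries = induce_rules(frame, [target.astype(float)], params, view="v")
    supports = [frozenset(frame.index[[bool(
        all(c.low <= frame.loc[i, c.attribute] <= c.high
            for c in q.conditions)) for i in frame.index]])
        for q in queries]
    want = frozenset(frame.index[target])
    assert want in supports


def test_induce_rules_constant_attributes_yield_nothing():
    frame = pd.DataFrame({"X": np.ones(40)}, index=[f"P{i}" for i in range(40)])
    target = np.zeros(40)
    target[:20] = 1
    params = MinerParams(min_support=5, max_support=30, seed=0)
    assert induce_rules(frame, [target], params, view="v") == []


def test_path_conditions_on_same_attribute_become_one_interval():
    # a path X > 2 then X <= 7 must evaluate like the snapped interval
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 10, 80)
    frame = pd.DataFrame({"X": x}, index=[f"P{i}" for i in range(80)])
    target = ((x > 2) & (x <= 7)).astype(float)
    params = MinerParams(min_support=5, max_support=70, tree_max_depth=3,
                         seed=1, max_query_support_frac=1.0)
    queries = induce_rules(frame, [target], params, view="v")
    assert all(len(q.conditions) == 1 for q in queries)  # merged per attribute
    want = {f"P{i}" for i in range(80) if 2 < x[i] <= 7}
    sups = []
    for q in queries:
        c = q.conditions[0]
        sups.append({f"P{i}" for i in range(80) if c.low <= x[i] <= c.high})
    assert want in sups


# -- refinement, labelling, counting ------------------------------------

def _mk_rd(ds, q1, q2):
    s1, s2 = evaluate_query(q1, ds), evaluate_query(q2, ds)
    i, u, j = jaccard([s1, s2])
    p, meth = redescription_pvalue([len(s1), len(s2)], i, ds.n)
    return Redescription((q1, q2), s1 & s2, u, j, p, meth)


def test_refine_fixed_point_and_improvement(clean_cohort):
    ds = clean_cohort
    q1 = Query("csf_biomarkers", (Condition("VILIP-1", low=0.0, high=1e9),))
    q2 = Query("csf_elements", (Condition("Se_csf", low=1.2, high=1e9),))
    rd = _mk_rd(ds, q1, q2)
    params = MinerParams(min_support=10, max_support=193, seed=0)
    # empty pool: nothing to add, redescription unchanged
    same = refine_conjunctive(rd, [], ds, params)
    assert same.jaccard == pytest.approx(rd.jaccard)
    assert same.queries == rd.queries
    # pool with a condition that trims only union-side patients
    helper = Query("csf_biomarkers",
                   (Condition("VILIP-1", low=90.0, high=1e9),))
    better = refine_conjunctive(rd, [helper], ds, params)
    assert better.jaccard >= rd.jaccard
    assert better.support_size >= params.min_support


def test_label_specificity_dominance_rule(default_cohort):
    dx = default_cohort.data["diagnosis"]
    ad = set(default_cohort.patient_ids[(dx == "AD").to_numpy()][:45])
    mci = set(default_cohort.patient_ids[(dx == "MCI").to_numpy()][:3])
    hc = set(default_cohort.patient_ids[(dx == "HC").to_numpy()][:1])
    rd = Redescription((), frozenset(ad | mci | hc), 86, 0.57, 1e-7)
    label_specificity(rd, default_cohort)
    assert rd.specificity_label == "AD"
    assert rd.per_diagnosis_pct["AD"] == pytest.approx(100 * 45 / 124, abs=0.01)
    # two-group dominance
    rd2 = Redescription((), frozenset(
        set(list(ad)[:40])
        | set(default_cohort.patient_ids[(dx == "MCI").to_numpy()][:20])), 1, 1.0, 1.0)
    label_specificity(rd2, default_cohort)
    assert rd2.specificity_label in {"AD&MCI", "AD"}
    # empty support
    rd3 = Redescription((), frozenset(), 0, 0.0, 1.0)
    label_specificity(rd3, default_cohort)
    assert rd3.specificity_label == "none"
    assert set(rd3.per_diagnosis_pct.values()) == {0.0}


def test_count_cooccurrence():
    q1 = Query("csf_biomarkers", (Condition("VILIP-1", low=1, high=2),))
    q2 = Query("csf_elements", (Condition("Se_csf", low=1, high=2),))
    rd = Redescription((q1, q2), frozenset(), 0, 0.0, 1.0)
    assert count_cooccurrence([], "VILIP-1", "Se_csf") == 0
    assert count_cooccurrence([rd], "VILIP-1", "Se_csf") == 1
    assert count_cooccurrence([rd], "VILIP-1", "Cu_csf") == 0


# -- miner --------------------------------------------------------------

def test_mine_zero_leak_plant_emits_perfect_redescription():
    plant = PlantedRedescription(0.26, (
        ("csf_biomarkers", "VILIP-1", 150.0, 400.0),
        ("csf_elements", "Se_csf", 2.0, 3.6)), leak_fraction=0.0)
    ds = generate_cohort(CohortConfig(
        planted_redescriptions=(plant,), missingness={}, seed=2))
    params = MinerParams(seed=0, n_runs=2, n_iterations=6)
    rds = mine(ds, ("csf_biomarkers", "csf_elements"), params)
    planted = frozenset(ds.planted_members[0])
    perfect = [rd for rd in rds if rd.jaccard == 1.0 and rd.support == planted]
    assert perfect, "zero-leak plant should surface with Jaccard 1"


def test_mine_three_view_planted_recovery():
    plant = PlantedRedescription(0.30, (
        ("csf_biomarkers", "VILIP-1", 150.0, 400.0),
        ("csf_elements", "Se_csf", 2.0, 3.6),
        ("plasma_elements", "Li_plasma", 60.0, 200.0)), 0.05)
    ds = generate_cohort(CohortConfig(planted_redescriptions=(plant,), seed=5))
    params = MinerParams(seed=0, n_runs=2, n_iterations=8,
                         min_support=20, max_support=110)
    rds = mine(ds, ("csf_biomarkers", "csf_elements", "plasma_elements"), params)
    assert rds
    assert all(len(rd.queries) == 3 for rd in rds)
    mem = set(ds.planted_members[0])
    assert max(jaccard([rd.support, mem])[2] for rd in rds) >= 0.6


def test_mine_deterministic(clean_cohort):
    params = MinerParams(seed=3, n_runs=2, n_iterations=4)
    a = mine(clean_cohort, ("csf_biomarkers", "csf_elements"), params)
    b = mine(clean_cohort, ("csf_biomarkers", "csf_elements"), params)
    assert [rd.to_dict() for rd in a] == [rd.to_dict() for rd in b]


def test_mine_sorted_by_pvalue_and_filters_hold(clean_cohort):
    params = MinerParams(seed=1, n_runs=2, n_iterations=4)
    rds = mine(clean_cohort, ("csf_biomarkers", "csf_elements"), params)
    ps = [rd.p_value for rd in rds]
    assert ps == sorted(ps)
    for rd in rds:
        assert params.min_support <= rd.support_size <= params.max_support
        assert rd.jaccard >= params.min_jaccard
        assert rd.p_value <= params.max_p


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3))
def test_support_antimonotone_under_conjunction(seed, extra):
    """Adding AND-conditions can only shrink a query's support."""
    rng = np.random.default_rng(seed)
    n = 40
    frame = pd.DataFrame(
        {f"a{j}": rng.normal(size=n) for j in range(4)},
        index=pd.Index([f"P{i}" for i in range(n)], name="patient_id"))
    from csfmetals import CohortDataset
    ds = CohortDataset(frame, view_columns={"v": list(frame.columns)},
                       categorical_levels={})
    def rand_cond():
        j = rng.integers(0, 4)
        lo, hi = sorted(rng.normal(size=2) * 2)
        return Condition(f"a{j}", low=float(lo), high=float(hi))
    base = Query("v", (rand_cond(),))
    s0 = evaluate_query(base, ds)
    q = base
    for _ in range(extra):
        try:
            q = Query("v", q.conditions + (rand_cond(),))
        except ValueError:
            return  # contradictory same-attribute intervals: empty anyway
        s1 = evaluate_query(q, ds)
        assert s1 <= s0
        s0 = s1


def test_mine_beats_single_condition_enumeration_on_tiny_instance():
    """On a tiny exhaustively-searchable instance the miner must do at
    least as well as the best single-condition-per-view redescription."""
    rng = np.random.default_rng(0)
    n = 12
    vals = {f"a{j}": np.round(rng.uniform(0, 4, n)) for j in range(2)}
    vals.update({f"b{j}": np.round(rng.uniform(0, 4, n)) for j in range(2)})
    vals["b0"][:6] = vals["a0"][:6]  # induce some cross-view dependence
    frame = pd.DataFrame(vals, index=pd.Index(
        [f"P{i}" for i in range(n)], name="patient_id"))
    from csfmetals import CohortDataset
    ds = CohortDataset(frame,
                       view_columns={"va": ["a0", "a1"], "vb": ["b0", "b1"]},
                       categorical_levels={})
    params = MinerParams(seed=0, n_runs=2, n_iterations=5, min_support=3,
                         max_support=12, min_jaccard=0.05, max_p=1.0,
                         initial_clusters=3, max_query_support_frac=1.0)
    rds = mine(ds, ("va", "vb"), params)
    best_mined = max((rd.jaccard for rd in rds), default=0.0)
    # exhaustive single-condition enumeration
    best_enum = 0.0
    for av in ("a0", "a1"):
        for bv in ("b0", "b1"):
            ua = np.unique(vals[av]); ub = np.unique(vals[bv])
            for lo_a, hi_a in itertools.combinations_with_replacement(ua, 2):
                sa = set(frame.index[(vals[av] >= lo_a) & (vals[av] <= hi_a)])
                if not 3 <= len(sa) <= 12:
                    continue
                for lo_b, hi_b in itertools.combinations_with_replacement(ub, 2):
                    sb = set(frame.index[(vals[bv] >= lo_b) & (vals[bv] <= hi_b)])
                    if not 3 <= len(sb) <= 12:
                        continue
                    j = jaccard([sa, sb])[2]
                    best_enum = max(best_enum, j)
    assert best_mined >= best_enum - 1e-12
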