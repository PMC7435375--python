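"""Mamdani FIS: membership evaluation, rule firing, defuzzification, config I/O."""

import itertools

import numpy as np
import pytest

from drowsemeter.errors import ConfigError, NoRuleFiredError
from drowsemeter.fuzzy import (TERMS, FISConfig, FuzzyVariable, MembershipFunction,
                               RuleBase, completed_rule_base, default_config,
                               defuzzify_min_of_max, evaluate_rules, infer,
                               load_fis_config, save_fis_config)


@pytest.fixture(scope="module")
def cfg():
    return default_config()


# -- membership functions ---------------------------------------------

def test_trapezoid_core_and_slopes():
    mf = MembershipFunction("trapezoidal", (0.0, 1.0, 2.0, 4.0))
    assert mf(1.5) == 1.0
    assert mf(0.5) == pytest.approx(0.5)
    assert mf(3.0) == pytest.approx(0.5)
    assert mf(-1.0) == 0.0 and mf(5.0) == 0.0


def test_triangular_is_a_degenerate_trapezoid():
    tri = MembershipFunction("triangular", (0.0, 1.0, 2.0))
    assert tri(1.0) == 1.0
    assert tri(0.5) == pytest.approx(0.5)


def test_shoulder_trapezoid_is_one_at_the_edge():
    mf = MembershipFunction("trapezoidal", (0.0, 0.0, 0.1, 0.2))
    assert mf(0.0) == 1.0


def test_crossover_degrees_are_equal(cfg):
    var = cfg.variables["perclos"]
    d = var.fuzzify(0.15)  # Low/Medium crossover of the default config
    assert d["Low"] == pytest.approx(d["Medium"])
    assert d["Low"] == pytest.approx(0.5)


def test_fuzzify_clamps_out_of_universe(cfg):
    var = cfg.variables["perclos"]
    assert var.fuzzify(-0.3) == var.fuzzify(0.0)
    assert var.fuzzify(2.0) == var.fuzzify(1.0)


def test_core_point_is_crisp(cfg):
    for var in cfg.variables.values():
        for term in TERMS:
            d = var.fuzzify(var.core_point(term))
            assert d[term] == 1.0
            assert all(v == 0.0 for k, v in d.items() if k != term)


# -- rule evaluation and defuzzification ------------------------------

def crisp_degrees(p_term, e_term, a_term):
    mk = lambda term: {t: 1.0 if t == term else 0.0 for t in TERMS}
    return {"perclos": mk(p_term), "ecd": mk(e_term), "aot": mk(a_term)}


def test_all_low_concludes_low(cfg):
    agg = evaluate_rules(crisp_degrees("Low", "Low", "Low"), cfg.rule_base)
    assert agg == {"Low": 1.0, "Medium": 0.0, "High": 0.0}


@pytest.mark.parametrize("combo,expected", [
    (("High", "Low", "Low"), "Medium"),    # one eye indicator High
    (("Low", "High", "Low"), "Medium"),
    (("Medium", "Medium", "Low"), "Medium"),  # two eye indicators Medium
    (("Low", "Medium", "High"), "Medium"),    # AOT High + another Medium
    (("Medium", "Low", "High"), "Medium"),
    (("Low", "Low", "High"), "Low"),          # AOT alone stays inert
])
def test_prose_anchored_rules(cfg, combo, expected):
    agg = evaluate_rules(crisp_degrees(*combo), cfg.rule_base)
    assert max(agg, key=agg.get) == expected


def test_defuzzify_unique_maximum():
    lvl = defuzzify_min_of_max({"Low": 0.2, "Medium": 0.7, "High": 0.4},
                               cfg_singletons())
    assert lvl.label == "Medium" and lvl.crisp == 0.5


def test_defuzzify_tie_breaks_to_smaller_singleton():
    # brute-force over orderings: min-of-max must pick the smallest singleton
    # among the maximal-degree terms
    for degs in itertools.permutations([0.2, 0.7, 0.7]):
        agg = dict(zip(TERMS, degs))
        winners = [t for t in TERMS if agg[t] == max(degs)]
        expect = min(winners, key=lambda t: cfg_singletons()[t])
        assert defuzzify_min_of_max(agg, cfg_singletons()).label == expect


def test_defuzzify_all_zero_raises():
    with pytest.raises(NoRuleFiredError):
        defuzzify_min_of_max({t: 0.0 for t in TERMS}, cfg_singletons())


def cfg_singletons():
    return {"Low": 0.0, "Medium": 0.5, "High": 1.0}


# -- end-to-end inference ---------------------------------------------

def test_zero_inputs_are_normal(cfg):
    assert infer(0.0, 0.0, 0.0, cfg).label == "Low"
    assert infer(0.0, 0.0, 0.0, cfg).state == "Normal"


def test_crisp_inputs_reduce_to_rule_table(cfg):
    """At term cores the FIS must agree with the plain rule-table lookup."""
    for combo in itertools.product(TERMS, repeat=3):
        x = [cfg.variables[v].core_point(t)
             for v, t in zip(("perclos", "ecd", "aot"), combo)]
        assert infer(*x, cfg).label == cfg.rule_base[combo], combo


def test_output_monotone_on_grid(cfg):
    """Raising any one indicator never lowers the output level (20^3 grid)."""
    grids = [np.linspace(*cfg.variables[v].universe, 20) for v in ("perclos", "ecd", "aot")]
    idx = np.empty((20, 20, 20), dtype=int)
    for i, p in enumerate(grids[0]):
        for j, e in enumerate(grids[1]):
            for k, a in enumerate(grids[2]):
                idx[i, j, k] = infer(p, e, a, cfg).index
    assert (np.diff(idx, axis=0) >= 0).all()
    assert (np.diff(idx, axis=1) >= 0).all()
    assert (np.diff(idx, axis=2) >= 0).all()


def test_aot_alone_is_inert(cfg):
    x = infer(cfg.variables["perclos"].core_point("Low"),
              cfg.variables["ecd"].core_point("Low"),
              cfg.variables["aot"].core_point("High"), cfg)
    assert x.label == "Low"


# -- configuration ----------------------------------------------------

def test_default_rule_table_equals_completion(cfg):
    assert dict(cfg.rule_base.rules) == dict(completed_rule_base().rules)


def test_config_round_trip(tmp_path, cfg):
    p = tmp_path / "fis.yaml"
    save_fis_config(cfg, p)
    cfg2 = load_fis_config(p)
    assert dict(cfg2.rule_base.rules) == dict(cfg.rule_base.rules)
    assert cfg2.output_singletons == dict(cfg.output_singletons)
    for v in ("perclos", "ecd", "aot"):
        assert cfg2.variables[v].universe == cfg.variables[v].universe
        for t in TERMS:
            assert cfg2.variables[v].terms[t] == cfg.variables[v].terms[t]


def test_missing_rule_is_a_totality_error():
    rules = dict(completed_rule_base().rules)
    del rules[("Low", "Medium", "High")]
    with pytest.raises(ConfigError, match="Medium"):
        RuleBase(rules)


def test_non_monotone_rule_base_names_the_pair():
    rules = dict(completed_rule_base().rules)
    rules[("High", "High", "High")] = "Low"
    with pytest.raises(ConfigError, match="not monotone"):
        RuleBase(rules)


def test_unordered_singletons_rejected(cfg):
    with pytest.raises(ConfigError):
        FISConfig(variables=cfg.variables, rule_base=cfg.rule_base,
                  output_singletons={"Low": 0.5, "Medium": 0.5, "High": 1.0})


def test_uncovered_universe_rejected():
    with pytest.raises(ConfigError, match="covers"):
        FuzzyVariable("perclos", (0.0, 1.0), {
            "Low": MembershipFunction("trapezoidal", (0.0, 0.0, 0.1, 0.2)),
            "Medium": MembershipFunction("trapezoidal", (0.3, 0.4, 0.45, 0.5)),
            "High": MembershipFunction("trapezoidal", (0.6, 0.7, 1.0, 1.0)),
        })
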