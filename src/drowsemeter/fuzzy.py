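"""Mamdani fuzzy inference mapping (PERCLOS, ECD, AOT) to a drowsiness level.

Each input indicator is a fuzzy variable with three terms (Low, Medium,
High) given by piecewise-linear (triangular/trapezoidal) membership
functions; the output drowsiness level has singleton consequents.  The AND
connective and the implication are the minimum, aggregation is the
maximum, and defuzzification is minimum-of-maximum: among the output terms
attaining the maximal aggregated degree, the one with the smallest
singleton value wins.  With a total rule base and input clamping the
system returns a label for every input point.

The rule base encodes that the eye indicators carry the drowsiness signal
while AOT (yawning) only corroborates: a Medium output needs two eye
indicators at Medium, one of them at High, or AOT High combined with some
other indicator at Medium; AOT High on its own stays Low (talking and
singing open the mouth without drowsiness); a High output needs both eye
indicators High, or one High and the other Medium with AOT High.

Membership breakpoints and singletons ship as tunable defaults (see
``data/default_fis.yaml``); nothing in the inference code depends on the
specific numbers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Tuple

import yaml

from .errors import ConfigError, NoRuleFiredError

TERMS = ("Low", "Medium", "High")
VARIABLES = ("perclos", "ecd", "aot")
#: output label -> driver-state name
LABEL_STATE = {"Low": "Normal", "Medium": "Drowsy", "High": "Severe"}
STATES = ("Normal", "Drowsy", "Severe")


@dataclass(frozen=True)
class MembershipFunction:
    """Triangular or trapezoidal membership function.

    ``points`` are 3 (triangular) or 4 (trapezoidal) non-decreasing
    abscissae; membership rises linearly from the first to the start of
    the core, is 1 on the core, and falls linearly to 0 at the last.
    """

    shape: str
    points: Tuple[float, ...]

    def __post_init__(self):
        pts = tuple(float(p) for p in self.points)
        n_expected = {"triangular": 3, "trapezoidal": 4}.get(self.shape)
        if n_expected is None:
            raise ConfigError(f"unknown membership shape {self.shape!r}")
        if len(pts) != n_expected:
            raise ConfigError(f"{self.shape} MF needs {n_expected} points, got {len(pts)}")
        if any(b < a for a, b in zip(pts, pts[1:])):
            raise ConfigError(f"MF breakpoints must be non-decreasing: {pts}")
        object.__setattr__(self, "points", pts)

    @property
    def core(self) -> Tuple[float, float]:
        p = self.points
        return (p[1], p[1]) if self.shape == "triangular" else (p[1], p[2])

    def __call__(self, x: float) -> float:
        if self.shape == "triangular":
            a, b, c = self.points
            d = c
            c = b
        else:
            a, b, c, d = self.points
        if b <= x <= c:
            return 1.0
        if x < b:
            if x <= a:
                return 0.0
            return (x - a) / (b - a)
        if x >= d:
            return 0.0
        return (d - x) / (d - c)


@dataclass(frozen=True)
class FuzzyVariable:
    """A named input variable with ordered Low/Medium/High terms."""

    name: str
    universe: Tuple[float, float]
    terms: Mapping[str, MembershipFunction]

    def __post_init__(self):
        lo, hi = self.universe
        if not lo < hi:
            raise ConfigError(f"{self.name}: universe must satisfy lo < hi")
        if tuple(self.terms) != TERMS:
            raise ConfigError(f"{self.name}: terms must be exactly {TERMS} in order")
        cores = [self.terms[t].core for t in TERMS]
        for (lo1, hi1), (lo2, hi2), t1, t2 in zip(cores, cores[1:], TERMS, TERMS[1:]):
            if not hi1 < lo2:
                raise ConfigError(f"{self.name}: core of {t1} must lie below core of {t2}")
        # coverage: every universe point must activate at least one term
        n = 201
        for i in range(n):
            x = lo + (hi - lo) * i / (n - 1)
            if max(mf(x) for mf in self.terms.values()) <= 0.0:
                raise ConfigError(f"{self.name}: no term covers x={x:g}")

    def fuzzify(self, x: float) -> Dict[str, float]:
        """Degrees per term; values outside the universe clamp to its bounds."""
        lo, hi = self.universe
        x = min(max(float(x), lo), hi)
        return {t: mf(x) for t, mf in self.terms.items()}

    def core_point(self, term: str) -> float:
        """Midpoint of a term's core (a crisp representative of the term)."""
        lo, hi = self.terms[term].core
        return 0.5 * (lo + hi)


def fuzzify(x: float, var: FuzzyVariable) -> Dict[str, float]:
    """Functional alias for :meth:`FuzzyVariable.fuzzify`."""
    return var.fuzzify(x)


@dataclass(frozen=True)
class RuleBase:
    """Total mapping (perclos term, ecd term, aot term) -> output term."""

    rules: Mapping[Tuple[str, str, str], str]

    def __post_init__(self):
        missing = [k for k in itertools.product(TERMS, repeat=3) if k not in self.rules]
        if missing:
            raise ConfigError(f"rule base incomplete; missing antecedents {missing[:3]}"
                              + ("..." if len(missing) > 3 else ""))
        extra = [k for k in self.rules if k not in set(itertools.product(TERMS, repeat=3))]
        if extra:
            raise ConfigError(f"rule base has invalid antecedents {extra}")
        idx = {t: i for i, t in enumerate(TERMS)}
        for key, out in self.rules.items():
            if out not in idx:
                raise ConfigError(f"rule {key} concludes unknown term {out!r}")
        # monotonicity: raising any single antecedent never lowers the output
        for key in self.rules:
            for pos in range(3):
                i = idx[key[pos]]
                if i < 2:
                    nxt = list(key)
                    nxt[pos] = TERMS[i + 1]
                    if idx[self.rules[tuple(nxt)]] < idx[self.rules[key]]:
                        raise ConfigError(
                            f"rule base not monotone: {key} -> {self.rules[key]} but "
                            f"{tuple(nxt)} -> {self.rules[tuple(nxt)]}")

    def __getitem__(self, key: Tuple[str, str, str]) -> str:
        return self.rules[key]


def completed_rule_base() -> RuleBase:
    """The default 27-entry rule table.

    Anchored cells: (L,L,L) -> L; a single eye indicator at High with the
    others Low -> M; both eye indicators Medium -> M; AOT High plus any
    other indicator Medium -> M; AOT High alone -> L.  Every remaining cell
    takes the smallest output consistent with those anchors and
    monotonicity: High requires both eye indicators High, or one High and
    the other Medium with AOT High.
    """
    rules = {}
    for p, e, a in itertools.product(range(3), repeat=3):
        eyes_hi, eyes_lo = max(p, e), min(p, e)
        if (p == 2 and e == 2) or (eyes_hi == 2 and eyes_lo >= 1 and a == 2):
            out = 2
        elif eyes_hi == 2 or eyes_lo >= 1 or (a == 2 and eyes_hi >= 1):
            out = 1
        else:
            out = 0
        rules[(TERMS[p], TERMS[e], TERMS[a])] = TERMS[out]
    return RuleBase(rules)


@dataclass(frozen=True)
class FISConfig:
    """Complete Mamdani FIS: variables, rule base and output singletons."""

    variables: Mapping[str, FuzzyVariable]
    rule_base: RuleBase
    output_singletons: Mapping[str, float] = field(
        default_factory=lambda: {"Low": 0.0, "Medium": 0.5, "High": 1.0})

    def __post_init__(self):
        if tuple(self.variables) != VARIABLES:
            raise ConfigError(f"variables must be exactly {VARIABLES} in order")
        vals = [self.output_singletons[t] for t in TERMS]
        if not (vals[0] < vals[1] < vals[2]):
            raise ConfigError("output singletons must be strictly increasing Low < Medium < High")


@dataclass(frozen=True)
class DrowsinessLevel:
    """Defuzzified output: label, crisp singleton value and degree vector."""

    label: str
    crisp: float
    memberships: Mapping[str, float]

    @property
    def state(self) -> str:
        """Driver-state name: Normal / Drowsy / Severe."""
        return LABEL_STATE[self.label]

    @property
    def index(self) -> int:
        return TERMS.index(self.label)


def evaluate_rules(degrees: Mapping[str, Mapping[str, float]],
                   rb: RuleBase) -> Dict[str, float]:
    """Aggregated output degrees: min over antecedents, max over rules."""
    agg = {t: 0.0 for t in TERMS}
    dp, de, da = (degrees[v] for v in VARIABLES)
    for (tp, te, ta), out in rb.rules.items():
        firing = min(dp[tp], de[te], da[ta])
        if firing > agg[out]:
            agg[out] = firing
    return agg


def defuzzify_min_of_max(aggregated: Mapping[str, float],
                         singletons: Mapping[str, float]) -> DrowsinessLevel:
    """Minimum-of-maximum defuzzification over singleton consequents.

    Among the output terms attaining the maximal aggregated degree, the one
    with the smallest singleton value is selected.
    """
    peak = max(aggregated.values())
    if peak <= 0.0:
        raise NoRuleFiredError("all aggregated output degrees are zero")
    winners = [t for t in TERMS if aggregated[t] >= peak - 1e-12]
    label = min(winners, key=lambda t: singletons[t])
    return DrowsinessLevel(label=label, crisp=float(singletons[label]),
                           memberships=dict(aggregated))


def infer(perclos: float, ecd: float, aot: float, cfg: FISConfig) -> DrowsinessLevel:
    """Full inference: fuzzify each input, fire the rules, defuzzify."""
    degrees = {name: cfg.variables[name].fuzzify(x)
               for name, x in zip(VARIABLES, (perclos, ecd, aot))}
    return defuzzify_min_of_max(evaluate_rules(degrees, cfg.rule_base),
                                cfg.output_singletons)


# -- configuration plumbing -------------------------------------------


def default_config() -> FISConfig:
    """The shipped default FIS (see ``data/default_fis.yaml``).

    PERCLOS crossovers sit near 0.15 and 0.30 (bracketing the 0.15-0.4
    thresholds reported across the PERCLOS literature), ECD crossovers near
    1 s and 4 s, AOT crossovers near 2 s and 6 s on [0, 60] s universes.
    These are tunable defaults, not measured constants.
    """
    with resources.files("drowsemeter.data").joinpath("default_fis.yaml").open() as fh:
        return _config_from_mapping(yaml.safe_load(fh), "<packaged default>")


def load_fis_config(path) -> FISConfig:
    """Load and fully validate a FIS config from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _config_from_mapping(data, str(path))


def _config_from_mapping(data, source: str) -> FISConfig:
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: FIS config must be a mapping")
    try:
        variables = {}
        for name in VARIABLES:
            vspec = data["variables"][name]
            terms = {t: MembershipFunction(shape=mspec["shape"],
                                           points=tuple(mspec["points"]))
                     for t, mspec in ((t, vspec["terms"][t]) for t in TERMS)}
            variables[name] = FuzzyVariable(name=name,
                                            universe=tuple(vspec["universe"]),
                                            terms=terms)
        rules = {}
        for row in data["rules"]:
            p, e, a, out = row
            key = (str(p), str(e), str(a))
            if key in rules:
                raise ConfigError(f"{source}: duplicate rule for antecedent {key}")
            rules[key] = str(out)
        singletons = {t: float(data["singletons"][t]) for t in TERMS}
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{source}: malformed FIS config ({exc!r})") from exc
    return FISConfig(variables=variables, rule_base=RuleBase(rules),
                     output_singletons=singletons)


def save_fis_config(cfg: FISConfig, path) -> None:
    """Write a FIS config as YAML; ``load_fis_config`` round-trips it."""
    data = {
        "variables": {
            name: {
                "universe": list(var.universe),
                "terms": {t: {"shape": mf.shape, "points": list(mf.points)}
                          for t, mf in var.terms.items()},
            }
            for name, var in cfg.variables.items()
        },
        "rules": [[p, e, a, cfg.rule_base[(p, e, a)]]
                  for p, e, a in itertools.product(TERMS, repeat=3)],
        "singletons": {t: float(cfg.output_singletons[t]) for t in TERMS},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
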