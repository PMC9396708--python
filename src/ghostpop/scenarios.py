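"""Demographic scenario specification and prior sampling.

A :class:`ScenarioSpec` describes a set of demes (with diploid effective
sizes and diploid sample counts; ghost demes are demes that are never
sampled) and a list of events expressed *backwards in time*, in
generations:

``merge(t, child, parent)``
    at time ``t`` all lineages of ``child`` move to ``parent``
    (forwards: ``child`` was founded from ``parent`` at ``t``);
``admixture(t, recipient, donor, rate)``
    each lineage in ``recipient`` moves to ``donor`` with probability
    ``rate`` (forwards: a fraction ``rate`` of ``recipient`` ancestry
    came from ``donor`` at ``t``);
``size_change(t, pop, ne)``
    the effective size of ``pop`` becomes ``ne`` for all older times.

Founder bottlenecks are expressed as a ``size_change`` to the founder
size ``Nf`` at time ``t - db`` followed by the founding ``merge`` at
``t`` (forwards: the deme spends its first ``db`` generations at size
``Nf``).

Numeric fields may instead hold parameter names or simple arithmetic
expressions in those names (e.g. ``"t_eau - db_eau"``); ``bind`` turns a
symbolic spec plus a parameter draw into a concrete one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Union

import numpy as np

from .errors import PriorError, ScenarioValidationError

Number = Union[int, float, str]


@dataclass(frozen=True)
class Deme:
    name: str
    ne: Number
    samples: int = 0
    ghost: bool = False


@dataclass(frozen=True)
class Merge:
    time: Number
    child: str
    parent: str


@dataclass(frozen=True)
class Admixture:
    time: Number
    recipient: str
    donor: str
    rate: Number


@dataclass(frozen=True)
class SizeChange:
    time: Number
    pop: str
    ne: Number


Event = Union[Merge, Admixture, SizeChange]


@dataclass
class ScenarioSpec:
    label: str
    demes: List[Deme]
    events: List[Event] = field(default_factory=list)

    def deme(self, name: str) -> Deme:
        for d in self.demes:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def sampled_demes(self) -> List[str]:
        return [d.name for d in self.demes if d.samples > 0]

    def parameter_names(self) -> List[str]:
        """Free symbols appearing in any symbolic field, in order."""
        names: List[str] = []

        def visit(v):
            if isinstance(v, str):
                for tok in _symbols(v):
                    if tok not in names:
                        names.append(tok)

        for d in self.demes:
            visit(d.ne)
        for e in self.events:
            visit(e.time)
            if isinstance(e, Admixture):
                visit(e.rate)
            if isinstance(e, SizeChange):
                visit(e.ne)
        return names

    def bind(self, draw: Dict[str, float]) -> "ScenarioSpec":
        """Substitute a parameter draw into every symbolic field."""

        def ev(v):
            return _eval_field(v, draw)

        demes = [replace(d, ne=ev(d.ne)) for d in self.demes]
        events: List[Event] = []
        for e in self.events:
            if isinstance(e, Merge):
                events.append(replace(e, time=ev(e.time)))
            elif isinstance(e, Admixture):
                events.append(replace(e, time=ev(e.time), rate=ev(e.rate)))
            else:
                events.append(replace(e, time=ev(e.time), ne=ev(e.ne)))
        return ScenarioSpec(label=self.label, demes=demes, events=events)

    def population_map(self, grouping: Optional[Dict[str, str]] = None):
        """PopulationMap for the samples simulate_snps will produce."""
        from .genotypes import PopulationMap

        assignment = {}
        for d in self.demes:
            for i in range(d.samples):
                assignment[f"{d.name}_{i}"] = d.name
        return PopulationMap(assignment=assignment, grouping=grouping or {})


def _symbols(expr: str) -> List[str]:
    import re

    return [
        t
        for t in re.findall(r"[A-Za-z_][A-Za-z0-9_]*", expr)
        if t not in ("min", "max")
    ]


def _eval_field(v: Number, draw: Dict[str, float]) -> float:
    if not isinstance(v, str):
        return float(v)
    try:
        return float(
            eval(  # noqa: S307 - restricted namespace, config-owned strings
                v, {"__builtins__": {}}, {**draw, "min": min, "max": max}
            )
        )
    except Exception as exc:
        raise ScenarioValidationError(
            f"cannot evaluate field {v!r} with draw {sorted(draw)}: {exc}"
        ) from exc


def validate_scenario(spec: ScenarioSpec) -> ScenarioSpec:
    """Check causal ordering and reachability of a concrete scenario.

    Verifies: unique deme names; no samples from ghost demes; positive
    sizes; event times non-negative; events reference demes that are
    still active at their time (a merged-away deme is inactive for all
    older events); admixture rates within [0, 1]; and all demes funnel
    into a single ancestral deme so every genealogy can coalesce.
    """
    names = [d.name for d in spec.demes]
    if len(set(names)) != len(names):
        raise ScenarioValidationError(f"duplicate deme names in {spec.label}")
    for d in spec.demes:
        if d.ghost and d.samples > 0:
            raise ScenarioValidationError(
                f"ghost deme {d.name!r} cannot have samples"
            )
        if not isinstance(d.ne, str) and d.ne <= 0:
            raise ScenarioValidationError(f"deme {d.name!r} has Ne <= 0")
    if spec.parameter_names():
        raise ScenarioValidationError(
            f"scenario {spec.label!r} still has unbound parameters "
            f"{spec.parameter_names()}; call bind() first"
        )
    active = set(names)
    merged_into: Dict[str, str] = {}
    for e in sorted(spec.events, key=lambda e: float(e.time)):
        t = float(e.time)
        if t < 0:
            raise ScenarioValidationError(f"event at negative time {t}")
        if isinstance(e, Merge):
            for nm, role in ((e.child, "child"), (e.parent, "parent")):
                if nm not in names:
                    raise ScenarioValidationError(f"unknown deme {nm!r}")
                if nm not in active:
                    raise ScenarioValidationError(
                        f"deme inactive at event time: {role} {nm!r} "
                        f"already merged before t={t}"
                    )
            if e.child == e.parent:
                raise ScenarioValidationError("merge child == parent")
            active.discard(e.child)
            merged_into[e.child] = e.parent
        elif isinstance(e, Admixture):
            ra = float(e.rate)
            if not 0.0 <= ra <= 1.0:
                raise ScenarioValidationError(
                    f"admixture rate {ra} outside [0, 1]"
                )
            for nm in (e.recipient, e.donor):
                if nm not in active:
                    raise ScenarioValidationError(
                        f"deme inactive at event time: {nm!r} at t={t}"
                    )
        else:  # SizeChange
            if e.pop not in active:
                raise ScenarioValidationError(
                    f"deme inactive at event time: {e.pop!r} at t={t}"
                )
            if float(e.ne) <= 0:
                raise ScenarioValidationError("size change to Ne <= 0")
    if len(active) != 1:
        raise ScenarioValidationError(
            f"scenario {spec.label!r} does not funnel to a single "
            f"ancestral deme; still active: {sorted(active)}"
        )
    # every sampled deme must reach the root through merges
    root = next(iter(active))
    for d in spec.demes:
        if d.samples == 0:
            continue
        cur = d.name
        seen = set()
        while cur != root:
            if cur in seen or cur not in merged_into:
                raise ScenarioValidationError(
                    f"sampled deme {d.name!r} cannot reach the ancestor"
                )
            seen.add(cur)
            cur = merged_into[cur]
    return spec


def to_demography(spec: ScenarioSpec):
    """Convert a concrete, validated spec to an msprime Demography.

    Merges and admixture pulses are expressed as (mass) lineage
    movements so that demes may stay active as ancestors of later
    splits while also being sampled at time 0.
    """
    import msprime

    dem = msprime.Demography()
    for d in spec.demes:
        dem.add_population(name=d.name, initial_size=float(d.ne))
    for e in sorted(spec.events, key=lambda e: float(e.time)):
        if isinstance(e, Merge):
            dem.add_mass_migration(
                time=float(e.time), source=e.child, dest=e.parent, proportion=1.0
            )
        elif isinstance(e, Admixture):
            dem.add_mass_migration(
                time=float(e.time),
                source=e.recipient,
                dest=e.donor,
                proportion=float(e.rate),
            )
        else:
            dem.add_population_parameters_change(
                time=float(e.time), population=e.pop, initial_size=float(e.ne)
            )
    dem.sort_events()
    return dem


# ----------------------------------------------------------------------
# priors
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class Prior:
    """Marginal prior for one scenario parameter.

    ``dist`` is ``"uniform"`` or ``"loguniform"``; integer priors draw
    uniformly over the inclusive integer range.
    """

    dist: str
    low: float
    high: float
    integer: bool = False

    def __post_init__(self):
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise PriorError("prior bounds must be finite")
        if self.high < self.low:
            raise PriorError("prior high < low")
        if self.dist not in ("uniform", "loguniform"):
            raise PriorError(f"unknown prior distribution {self.dist!r}")
        if self.dist == "loguniform" and self.low <= 0:
            raise PriorError("loguniform prior needs low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.integer:
            return float(rng.integers(int(self.low), int(self.high) + 1))
        if self.dist == "loguniform":
            return float(
                np.exp(rng.uniform(np.log(self.low), np.log(self.high)))
            )
        return float(rng.uniform(self.low, self.high))


@dataclass
class PriorSet:
    """Named marginal priors plus cross-parameter constraints.

    Constraints are boolean expressions over parameter names (e.g.
    ``"t_eau > t_wau"``, ``"db_eau < t_eau"``) enforced by rejection.
    """

    priors: Dict[str, Prior]
    constraints: List[str] = field(default_factory=list)

    MAX_REJECT = 100_000

    def sample(self, rng: np.random.Generator) -> Dict[str, float]:
        for _ in range(self.MAX_REJECT):
            draw = {k: p.sample(rng) for k, p in self.priors.items()}
            if all(self._holds(c, draw) for c in self.constraints):
                return draw
        raise PriorError(
            "constraint rejection rate too high (>99.9%); revise the priors"
        )

    @staticmethod
    def _holds(constraint: str, draw: Dict[str, float]) -> bool:
        try:
            return bool(
                eval(  # noqa: S307 - restricted namespace
                    constraint, {"__builtins__": {}}, dict(draw)
                )
            )
        except Exception as exc:
            raise PriorError(
                f"cannot evaluate constraint {constraint!r}: {exc}"
            ) from exc


def draw_parameters(
    priors: PriorSet, seed: Optional[int] = None, rng=None
) -> Dict[str, float]:
    """Draw one parameter set respecting bounds, rounding, constraints."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return priors.sample(rng)


# ----------------------------------------------------------------------
# structured text (YAML) configuration
# ----------------------------------------------------------------------

def scenario_from_dict(cfg: dict) -> ScenarioSpec:
    demes = [
        Deme(
            name=d["name"],
            ne=d["ne"],
            samples=int(d.get("samples", 0)),
            ghost=bool(d.get("ghost", False)),
        )
        for d in cfg["demes"]
    ]
    events: List[Event] = []
    for e in cfg.get("events", []):
        kind = e["kind"]
        if kind == "merge":
            events.append(Merge(e["time"], e["child"], e["parent"]))
        elif kind == "admixture":
            events.append(
                Admixture(e["time"], e["recipient"], e["donor"], e["rate"])
            )
        elif kind == "size_change":
            events.append(SizeChange(e["time"], e["pop"], e["ne"]))
        else:
            raise ScenarioValidationError(f"unknown event kind {kind!r}")
    return ScenarioSpec(label=cfg["label"], demes=demes, events=events)


def priors_from_dict(cfg: dict) -> PriorSet:
    priors = {
        name: Prior(
            dist=p.get("dist", "uniform"),
            low=float(p["low"]),
            high=float(p["high"]),
            integer=bool(p.get("integer", False)),
        )
        for name, p in cfg.get("priors", {}).items()
    }
    return PriorSet(priors=priors, constraints=list(cfg.get("constraints", [])))


def load_config(path):
    """Load scenarios and priors from a YAML file.

    Layout: a top-level ``scenarios`` list (each entry a scenario dict)
    and optional top-level ``priors`` / ``constraints`` shared by all
    scenarios.  Returns (list of ScenarioSpec, PriorSet).
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    scenarios = [scenario_from_dict(s) for s in cfg.get("scenarios", [])]
    return scenarios, priors_from_dict(cfg)
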