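"""Demographic scenarios: divergence/admixture graphs with parameter priors.

A :class:`Scenario` describes, backward in time, how sampled populations
merge into a single root population through divergence events (all lineages
of a derived population move into its source) and point admixture events
(lineages of an admixed population move to one of two sources with
probability ``r``).  Event times, admixture proportions and per-branch
effective sizes are named parameters drawn from a :class:`PriorSpec`.

The twelve scenarios of the grapevine east-to-west dissemination study ship
as fixtures (:func:`study_scenarios`), grouped into four competing-hypothesis
sets of three.  The study itself does not publish its prior bounds; the
defaults here (log-uniform Ne in [100, 10000] diploids, divergence times in
generations with t2 > t1) are this package's documented choice and are fully
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml


@dataclass(frozen=True)
class DivergenceEvent:
    """Backward in time at ``time``: lineages of ``derived`` join ``source``."""

    time: str  # parameter name
    derived: str
    source: str


@dataclass(frozen=True)
class AdmixtureEvent:
    """Backward in time at ``time``: each lineage of ``target`` moves to
    ``source_a`` with probability ``proportion``, else to ``source_b``."""

    time: str
    target: str
    source_a: str
    source_b: str
    proportion: str  # parameter name


@dataclass(frozen=True)
class Prior:
    """One-parameter prior: ``uniform`` or ``loguniform`` on [low, high]."""

    dist: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if self.low > self.high:
            raise ValueError("prior low bound exceeds high bound")
        if self.dist == "loguniform" and self.low <= 0:
            raise ValueError("loguniform prior needs a positive low bound")

    def sample(self, rng: np.random.Generator) -> float:
        if self.low == self.high:
            return float(self.low)
        if self.dist == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


@dataclass
class PriorSpec:
    """Priors for every parameter plus time-ordering constraints.

    ``constraints`` is a list of (earlier, later) parameter-name pairs
    meaning value(earlier) < value(later).
    """

    priors: dict[str, Prior]
    constraints: list[tuple[str, str]] = field(default_factory=list)


#: A concrete assignment of every scenario parameter.
ParameterDraw = dict


@dataclass
class Scenario:
    """A demographic model over named populations.

    ``populations`` lists the sampled leaves; ``events`` is the backward-time
    event list in ascending time order; ``ne_params`` maps every population
    (including purely ancestral sources) to the name of its effective-size
    parameter (diploid individuals).
    """

    id: str
    populations: list[str]
    events: list[DivergenceEvent | AdmixtureEvent]
    ne_params: dict[str, str]

    def parameter_names(self) -> list[str]:
        names = list(dict.fromkeys(self.ne_params.values()))
        for ev in self.events:
            if ev.time not in names:
                names.append(ev.time)
            if isinstance(ev, AdmixtureEvent) and ev.proportion not in names:
                names.append(ev.proportion)
        return names

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        events = []
        for ev in self.events:
            if isinstance(ev, DivergenceEvent):
                events.append(
                    {"type": "divergence", "time": ev.time,
                     "derived": ev.derived, "source": ev.source}
                )
            else:
                events.append(
                    {"type": "admixture", "time": ev.time, "target": ev.target,
                     "source_a": ev.source_a, "source_b": ev.source_b,
                     "proportion": ev.proportion}
                )
        return {
            "id": self.id,
            "populations": list(self.populations),
            "events": events,
            "ne_params": dict(self.ne_params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        events: list[DivergenceEvent | AdmixtureEvent] = []
        for ev in d["events"]:
            if ev["type"] == "divergence":
                events.append(
                    DivergenceEvent(ev["time"], ev["derived"], ev["source"])
                )
            elif ev["type"] == "admixture":
                events.append(
                    AdmixtureEvent(ev["time"], ev["target"], ev["source_a"],
                                   ev["source_b"], ev["proportion"])
                )
            else:
                raise ValueError(f"unknown event type {ev['type']!r}")
        return cls(
            id=d["id"],
            populations=list(d["populations"]),
            events=events,
            ne_params=dict(d["ne_params"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_scenario(
    s: Scenario, priors: PriorSpec | None = None, draw: ParameterDraw | None = None
) -> list[str]:
    """Structural and (optionally) numerical checks; empty list means valid.

    Structural rules: every event references known populations; the
    backward-time process deactivates each merged/admixed population exactly
    once and ends with a single root.  With ``priors`` or ``draw`` supplied,
    event times must be strictly positive and admixture proportions strictly
    inside (0, 1).
    """
    violations: list[str] = []
    active = set(s.populations)
    known = set(s.populations) | {
        p for ev in s.events
        for p in ([ev.source, ev.derived] if isinstance(ev, DivergenceEvent)
                  else [ev.target, ev.source_a, ev.source_b])
    }
    missing_ne = known - set(s.ne_params)
    if missing_ne:
        violations.append(f"populations without Ne parameter: {sorted(missing_ne)}")
    for ev in s.events:
        if isinstance(ev, DivergenceEvent):
            if ev.derived not in active:
                violations.append(
                    f"divergence at {ev.time}: {ev.derived} is not active"
                )
            active.discard(ev.derived)
            active.add(ev.source)
        else:
            if ev.target not in active:
                violations.append(f"admixture at {ev.time}: {ev.target} is not active")
            active.discard(ev.target)
            active.update([ev.source_a, ev.source_b])
    if len(active) != 1:
        violations.append(f"disconnected: process ends with populations {sorted(active)}")

    def _bounds(name: str) -> tuple[float, float] | None:
        if draw is not None and name in draw:
            return (draw[name], draw[name])
        if priors is not None and name in priors.priors:
            pr = priors.priors[name]
            return (pr.low, pr.high)
        return None

    for ev in s.events:
        b = _bounds(ev.time)
        if b is not None and b[0] <= 0 and b[1] <= 0:
            violations.append(f"event time {ev.time} not strictly positive")
        if isinstance(ev, AdmixtureEvent):
            b = _bounds(ev.proportion)
            if b is not None and (b[0] >= 1.0 or b[1] <= 0.0):
                violations.append(
                    f"degenerate admixture: proportion {ev.proportion} outside (0, 1)"
                )
    return violations


# ---------------------------------------------------------------------------
# prior sampling
# ---------------------------------------------------------------------------


class PriorInfeasibleError(RuntimeError):
    pass


def draw_parameters(
    s: Scenario,
    priors: PriorSpec,
    rng: np.random.Generator | int,
    max_attempts: int = 10_000,
) -> ParameterDraw:
    """Draw one concrete parameter set respecting bounds and orderings.

    Ordering constraints are enforced by resampling only the violating
    parameters; after ``max_attempts`` rounds a
    :class:`PriorInfeasibleError` is raised.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    names = s.parameter_names()
    missing = [n for n in names if n not in priors.priors]
    if missing:
        raise ValueError(f"no prior for parameters {missing}")
    draw = {n: priors.priors[n].sample(rng) for n in names}
    for _ in range(max_attempts):
        bad: set[str] = set()
        for lo, hi in priors.constraints:
            if lo in draw and hi in draw and not draw[lo] < draw[hi]:
                bad.update((lo, hi))
        if not bad:
            return draw
        for n in bad:
            draw[n] = priors.priors[n].sample(rng)
    raise PriorInfeasibleError(
        f"ordering constraints unsatisfied after {max_attempts} resampling rounds"
    )


def default_priors(s: Scenario) -> PriorSpec:
    """Package-default priors: Ne ~ log-uniform[100, 10000] diploids,
    t1 ~ U[10, 500], t2 ~ U[10, 2000] with t2 > t1, r ~ U[0.05, 0.95]."""
    priors: dict[str, Prior] = {}
    for name in dict.fromkeys(s.ne_params.values()):
        priors[name] = Prior("loguniform", 100.0, 10_000.0)
    priors["t1"] = Prior("uniform", 10.0, 500.0)
    priors["t2"] = Prior("uniform", 10.0, 2_000.0)
    for ev in s.events:
        if isinstance(ev, AdmixtureEvent):
            priors[ev.proportion] = Prior("uniform", 0.05, 0.95)
    priors = {n: priors[n] for n in priors if n in s.parameter_names()}
    return PriorSpec(priors=priors, constraints=[("t1", "t2")])


def point_priors(s: Scenario, values: ParameterDraw) -> PriorSpec:
    """Degenerate priors pinning every parameter to the given point values."""
    priors = {}
    for name in s.parameter_names():
        v = float(values[name])
        priors[name] = Prior("uniform", v, v)
    return PriorSpec(priors=priors, constraints=[])


def separated_point_values(
    s: Scenario, t1: float = 100.0, t2: float = 600.0
) -> ParameterDraw:
    """Benchmark point parameters: Ne = 1000 diploids on every branch,
    divergence times ``t1``/``t2`` in generations, admixture proportion 0.5."""
    values: ParameterDraw = {}
    for name in s.parameter_names():
        if name.startswith("N_"):
            values[name] = 1000.0
        elif name == "t1":
            values[name] = float(t1)
        elif name == "t2":
            values[name] = float(t2)
        else:
            values[name] = 0.5
    return values


# ---------------------------------------------------------------------------
# study fixtures
# ---------------------------------------------------------------------------

#: Short code for the Eastern Mediterranean / Caucasus, Middle & Far East,
#: Russia & Ukraine germplasm group.
EMR = "E-M-R"


def _serial(sid: str, leaf_far: str, mid: str, root: str) -> Scenario:
    """root -> mid at t2, mid -> leaf_far at t1 (forward-time flow)."""
    pops = sorted({leaf_far, mid, root})
    return Scenario(
        id=sid,
        populations=pops,
        events=[
            DivergenceEvent("t1", derived=leaf_far, source=mid),
            DivergenceEvent("t2", derived=mid, source=root),
        ],
        ne_params={p: f"N_{p}" for p in pops},
    )


def _admixed(sid: str, target: str, src_a: str, src_b: str, root: str) -> Scenario:
    """target formed at t1 by admixture of src_a and src_b; the non-root
    source diverged from the root at t2."""
    pops = sorted({target, src_a, src_b})
    derived_src = src_a if src_b == root else src_b
    return Scenario(
        id=sid,
        populations=pops,
        events=[
            AdmixtureEvent("t1", target=target, source_a=src_a,
                           source_b=src_b, proportion="r1"),
            DivergenceEvent("t2", derived=derived_src, source=root),
        ],
        ne_params={p: f"N_{p}" for p in pops},
    )


def study_scenarios() -> dict[str, list[Scenario]]:
    """The twelve dissemination scenarios, in four hypothesis groups of three.

    Hypothesis 1 — origin of the Southern Italian germplasm (BALK,
    ITAP-south, ITAP-north-center): serial flow via the south (S1), serial
    flow via the north-center (S2), or two independent derivations from the
    Balkans (S3).

    Hypothesis 2 — flow from Italy into Western/Central Europe (ITAP-south,
    ITAP-north-center, WCEUR): serial south -> north-center -> WCEUR (S4),
    serial south -> WCEUR -> north-center (S5), or ITAP-north-center as an
    admixture of ITAP-south and WCEUR (S6).

    Hypothesis 3 — flow from Southern Italy to WCEUR via Iberia
    (ITAP-south, IBER, WCEUR): serial via IBER (S7), WCEUR as an admixture
    of ITAP-south and IBER (S8), or the reverse serial route (S9).

    Hypothesis 4 — flow from the Middle/Far East to Iberia via Northern
    Africa (E-M-R, MAGH, IBER): serial via MAGH (S10), IBER as an admixture
    of MAGH and E-M-R (S11), or the reverse serial route (S12).
    """
    s3_pops = sorted({"BALK", "ITAP-south", "ITAP-north-center"})
    s3 = Scenario(
        id="S3",
        populations=s3_pops,
        events=[
            DivergenceEvent("t1", derived="ITAP-north-center", source="BALK"),
            DivergenceEvent("t2", derived="ITAP-south", source="BALK"),
        ],
        ne_params={p: f"N_{p}" for p in s3_pops},
    )
    return {
        "hypothesis_1": [
            _serial("S1", "ITAP-north-center", "ITAP-south", "BALK"),
            _serial("S2", "ITAP-south", "ITAP-north-center", "BALK"),
            s3,
        ],
        "hypothesis_2": [
            _serial("S4", "WCEUR", "ITAP-north-center", "ITAP-south"),
            _serial("S5", "ITAP-north-center", "WCEUR", "ITAP-south"),
            _admixed("S6", "ITAP-north-center", "ITAP-south", "WCEUR",
                     root="ITAP-south"),
        ],
        "hypothesis_3": [
            _serial("S7", "WCEUR", "IBER", "ITAP-south"),
            _admixed("S8", "WCEUR", "ITAP-south", "IBER", root="ITAP-south"),
            _serial("S9", "ITAP-south", "IBER", "WCEUR"),
        ],
        "hypothesis_4": [
            _serial("S10", "IBER", "MAGH", EMR),
            _admixed("S11", "IBER", "MAGH", EMR, root=EMR),
            _serial("S12", EMR, "MAGH", "IBER"),
        ],
    }
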