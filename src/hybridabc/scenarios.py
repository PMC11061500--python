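"""The six competing demographic scenarios and their priors.

Five sampled demes are modelled: the northern and southern groups of the
maternal-range parent (``PAM_N``, ``PAM_S``), the northern and southern
hybrid groups (``HYB_N``, ``HYB_S``), and the second parental species
(``HIM``), plus three ancestral lineages (``PAM_anc``, ``HYB_anc``, ``ANC``).
Backward in time every scenario reduces the sampled demes to the single
ancestral deme ``ANC`` at the deep parental split (t5).

Scenarios 1-3 are *multiple-event* origins: the two geographic hybrid groups
form by independent admixture pulses (one per region, sharing the admixture
fraction r1) after the PAM north/south split, so hybrids inherit the parental
spatial structure.  Scenarios 4-6 are *single-event* origins: one admixture
pulse creates a single hybrid lineage which later diversifies north/south on
its own, in parallel with the parental split.  Within each triplet the
scenarios differ in whether diversification and hybridization fall after the
regional Last Glacial Maximum (t1/t2 priors, 10-25,000 generations) or within
it (t3/t4 priors, 25,000-50,000 generations):

========  ==============  ===============
scenario  hybridization   diversification
========  ==============  ===============
1         t1 (post-LGM)   t2 (post-LGM)
2         t3 (LGM)        t4 (LGM)
3         t2 (post-LGM)   t4 (LGM)
4         t2 (post-LGM)   t1 (post-LGM)
5         t4 (LGM)        t3 (LGM)
6         t4 (LGM)        t2 (post-LGM)
========  ==============  ===============

All priors are uniform.  Effective sizes (diploids) are drawn independently
per lineage; event times are in generations, converted to calendar years with
a generation time of 2 years by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

LEAF_DEMES = ("PAM_N", "PAM_S", "HYB_N", "HYB_S", "HIM")
ANCESTRAL_DEMES = ("PAM_anc", "HYB_anc", "ANC")
ALL_DEMES = LEAF_DEMES + ANCESTRAL_DEMES

#: scenario id -> (hybridization-time parameter, diversification-time parameter)
_SCENARIO_TIMES = {
    1: ("t1", "t2"),
    2: ("t3", "t4"),
    3: ("t2", "t4"),
    4: ("t2", "t1"),
    5: ("t4", "t3"),
    6: ("t4", "t2"),
}

MULTI_EVENT_SCENARIOS = frozenset({1, 2, 3})
SINGLE_EVENT_SCENARIOS = frozenset({4, 5, 6})


def is_multi_event(scenario_id: int) -> bool:
    """True for scenarios with independent per-region hybridization pulses."""
    if scenario_id not in _SCENARIO_TIMES:
        raise ValueError(f"unknown scenario {scenario_id}")
    return scenario_id in MULTI_EVENT_SCENARIOS


def scenario_lineages(scenario_id: int) -> tuple[str, ...]:
    """Lineages whose effective sizes the scenario uses."""
    base = ("PAM_N", "PAM_S", "HYB_N", "HYB_S", "HIM", "PAM_anc", "ANC")
    if is_multi_event(scenario_id):
        return base
    return base + ("HYB_anc",)


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior ranges for every scenario parameter.

    Time ranges are in generations; ``n_range`` applies independently to
    every lineage's diploid effective size.  The deep-split upper bound
    (``t5[1]``) may be widened to 750,000 or 1,250,000 generations to allow
    an older parental divergence.
    """

    t1: tuple[float, float] = (10.0, 25_000.0)
    t2: tuple[float, float] = (10.0, 25_000.0)
    t3: tuple[float, float] = (25_000.0, 50_000.0)
    t4: tuple[float, float] = (25_000.0, 50_000.0)
    t5: tuple[float, float] = (100_000.0, 200_000.0)
    r1: tuple[float, float] = (0.01, 0.99)
    n_range: tuple[int, int] = (10, 100_000)
    generation_time_years: float = 2.0

    def __post_init__(self) -> None:
        for name in ("t1", "t2", "t3", "t4", "t5", "r1"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"degenerate prior range for {name}: ({lo}, {hi})")
        if not 0 < self.n_range[0] < self.n_range[1]:
            raise ValueError("degenerate effective-size prior range")

    def with_t5_upper(self, upper: float) -> "PriorSpec":
        return replace(self, t5=(self.t5[0], float(upper)))

    def range_of(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def to_dict(self) -> dict:
        return {
            "t1": list(self.t1), "t2": list(self.t2), "t3": list(self.t3),
            "t4": list(self.t4), "t5": list(self.t5), "r1": list(self.r1),
            "n_range": list(self.n_range),
            "generation_time_years": self.generation_time_years,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        kwargs = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d.items()}
        return cls(**kwargs)


@dataclass(frozen=True)
class ParameterVector:
    """One draw of scenario parameters.

    ``times`` holds only the event-time parameters the scenario uses
    (generations); ``sizes`` maps lineage name to diploid effective size.
    """

    times: dict[str, float]
    r1: float
    sizes: dict[str, int]
    generation_time_years: float = 2.0

    def __post_init__(self) -> None:
        for name, v in self.times.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if "t1" in self.times and "t2" in self.times and not self.times["t1"] < self.times["t2"]:
            raise ValueError("t1 < t2 required when both are present")
        if "t3" in self.times and "t4" in self.times and not self.times["t3"] < self.times["t4"]:
            raise ValueError("t3 < t4 required when both are present")
        for lin, n in self.sizes.items():
            if not (isinstance(n, (int, np.integer)) and n > 0):
                raise ValueError(f"effective size of {lin} must be a positive integer, got {n}")

    def as_flat_dict(self) -> dict[str, float]:
        """Flatten to ``{t*: .., r1: .., N_<lineage>: ..}`` for table rows."""
        out: dict[str, float] = dict(self.times)
        out["r1"] = self.r1
        for lin, n in self.sizes.items():
            out[f"N_{lin}"] = float(n)
        return out


@dataclass(frozen=True)
class DemoEvent:
    """One instantaneous backward-in-time event.

    ``kind="merge"``: all lineages of the demes in ``children`` move into
    ``dest`` (the merged ancestral deme, with its own effective size).
    ``kind="admixture"``: each lineage of ``child`` moves to ``parent_a``
    with probability ``fraction_a``, else to ``parent_b``.
    """

    time: float
    kind: str
    children: tuple[str, ...] = ()
    dest: str = ""
    child: str = ""
    parent_a: str = ""
    parent_b: str = ""
    fraction_a: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("event time must be non-negative")
        if self.kind not in ("merge", "admixture"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "admixture" and not 0.0 <= self.fraction_a <= 1.0:
            raise ValueError("fraction_a must lie in [0, 1]")


@dataclass(frozen=True)
class DemographicScenario:
    """A backward-in-time event list over named demes with per-deme sizes.

    ``leaf_demes`` are sampled at time 0; ``events`` are sorted by increasing
    time (ties resolved in list order, admixtures listed before merges).
    """

    scenario_id: int
    leaf_demes: tuple[str, ...]
    sizes: dict[str, int]
    events: tuple[DemoEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be sorted by increasing time")
        for e in self.events:
            demes = e.children + (e.dest,) if e.kind == "merge" else (e.child, e.parent_a, e.parent_b)
            for d in demes:
                if d not in self.sizes:
                    raise ValueError(f"deme {d!r} referenced by an event has no size")
        self.validate_reduction()

    def validate_reduction(self) -> None:
        """Check that the event list funnels all leaf demes into one deme."""
        alive = set(self.leaf_demes)
        for e in self.events:
            if e.kind == "merge":
                for c in e.children:
                    alive.discard(c)
                alive.add(e.dest)
            else:
                if e.child in alive:
                    alive.discard(e.child)
                    alive.update({e.parent_a, e.parent_b})
        if len(alive) != 1:
            raise ValueError(f"scenario does not reduce to a single deme: {sorted(alive)}")


def draw_parameters(
    prior: PriorSpec, scenario_id: int, rng_seed: int | np.random.Generator
) -> ParameterVector:
    """Draw one parameter vector from the scenario's uniform priors.

    Only the parameters the scenario uses are drawn.  Ordering constraints
    (t1 < t2, t3 < t4 when jointly used) are enforced by rejection.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    t_hyb, t_div = _SCENARIO_TIMES[scenario_id]  # validates scenario_id
    needed = sorted({t_hyb, t_div})
    ordered_pair = needed in (["t1", "t2"], ["t3", "t4"])
    while True:
        times = {name: rng.uniform(*prior.range_of(name)) for name in needed}
        if not ordered_pair:
            break
        a, b = needed
        if times[a] < times[b]:
            break
    times["t5"] = rng.uniform(*prior.t5)
    r1 = rng.uniform(*prior.r1)
    lo, hi = prior.n_range
    sizes = {lin: int(rng.integers(lo, hi + 1)) for lin in scenario_lineages(scenario_id)}
    return ParameterVector(times, r1, sizes, prior.generation_time_years)


def build_scenario(
    scenario_id: int,
    theta: ParameterVector,
    prior: PriorSpec | None = None,
    validate: bool = True,
) -> DemographicScenario:
    """Assemble the event list of a scenario from a parameter vector.

    With ``validate=True`` (default) every used time must fall inside its
    prior box and the admixture fraction inside the r1 prior; pass
    ``validate=False`` for boundary studies (for example r1 = 1, which
    degenerates the admixture into a pure merge).
    """
    prior = prior or PriorSpec()
    t_hyb_name, t_div_name = _SCENARIO_TIMES[scenario_id]
    try:
        t_hyb = theta.times[t_hyb_name]
        t_div = theta.times[t_div_name]
        t5 = theta.times["t5"]
    except KeyError as e:
        raise ValueError(f"scenario {scenario_id} needs parameter {e.args[0]}") from None

    if validate:
        for name, v in ((t_hyb_name, t_hyb), (t_div_name, t_div), ("t5", t5)):
            lo, hi = prior.range_of(name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside its prior range [{lo}, {hi}]")
        if not prior.r1[0] <= theta.r1 <= prior.r1[1]:
            raise ValueError(f"r1={theta.r1} outside [{prior.r1[0]}, {prior.r1[1]}]")

    multi = is_multi_event(scenario_id)
    if multi and not t_hyb < t_div:
        raise ValueError(
            f"scenario {scenario_id}: hybridization ({t_hyb_name}={t_hyb}) must be more "
            f"recent than the parental split it draws on ({t_div_name}={t_div})"
        )
    if not multi and not t_div < t_hyb:
        raise ValueError(
            f"scenario {scenario_id}: hybrid/parental diversification ({t_div_name}={t_div}) "
            f"must be more recent than the founding hybridization ({t_hyb_name}={t_hyb})"
        )

    r1 = theta.r1
    if multi:
        # Per-region admixture pulses, then the parental north/south merge.
        events = [
            DemoEvent(t_hyb, "admixture", child="HYB_N", parent_a="PAM_N", parent_b="HIM", fraction_a=r1),
            DemoEvent(t_hyb, "admixture", child="HYB_S", parent_a="PAM_S", parent_b="HIM", fraction_a=r1),
            DemoEvent(t_div, "merge", children=("PAM_S", "PAM_N"), dest="PAM_anc"),
            DemoEvent(t5, "merge", children=("PAM_anc", "HIM"), dest="ANC"),
        ]
    else:
        # Simultaneous hybrid and parental north/south merges, then one pulse.
        events = [
            DemoEvent(t_div, "merge", children=("HYB_S", "HYB_N"), dest="HYB_anc"),
            DemoEvent(t_div, "merge", children=("PAM_S", "PAM_N"), dest="PAM_anc"),
            DemoEvent(t_hyb, "admixture", child="HYB_anc", parent_a="PAM_anc", parent_b="HIM", fraction_a=r1),
            DemoEvent(t5, "merge", children=("PAM_anc", "HIM"), dest="ANC"),
        ]
    sizes = dict(theta.sizes)
    return DemographicScenario(scenario_id, LEAF_DEMES, sizes, tuple(events))


def generations_to_years(theta: ParameterVector) -> dict[str, float]:
    """Convert every event time to calendar years (generations x generation time)."""
    g = theta.generation_time_years
    return {name: t * g for name, t in theta.times.items()}


def single_deme_scenario(n_diploid: int, deme: str = "A") -> DemographicScenario:
    """A panmictic deme of constant diploid size (no events).

    Convenience model for neutral-coalescent baselines (pairwise
    coalescence, TMRCA, site-frequency spectrum).
    """
    return DemographicScenario(0, (deme,), {deme: int(n_diploid)}, ())


def split_scenario(
    t_split: float, n_a: int, n_b: int, n_anc: int | None = None,
    demes: tuple[str, str] = ("A", "B"),
) -> DemographicScenario:
    """Two demes merging into a common ancestor ``t_split`` generations ago.

    Convenience model for drift/differentiation baselines (FST against
    divergence time) and reduction checks of admixture scenarios.
    """
    a, b = demes
    sizes = {a: int(n_a), b: int(n_b), "ANC": int(n_anc if n_anc is not None else n_a)}
    events = (DemoEvent(float(t_split), "merge", children=(a, b), dest="ANC"),)
    return DemographicScenario(0, demes, sizes, events)
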