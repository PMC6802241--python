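"""Annual-cycle individual-level simulation of ED life courses.

Each simulated person is followed from birth to age 40.  Within each yearly
cycle, death is resolved first from the start-of-year state (background
mortality for healthy persons, SMR-scaled mortality in an ED state);
survivors then resolve a single multinomial draw:

* healthy, no ED history — naive incidence of each ED type;
* healthy, with history — relapse into the most recent ED, with a
  declining-exponential hazard in years since remission;
* in an ED state — remission (boosted by a rate ratio if treated that year),
  direct crossover to another ED, or persistence.

All scenarios of a run share one pre-drawn uniform array indexed by
(person, age, decision channel): common random numbers, so counterfactual
contrasts are paired at the person level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .parameters import ParameterSet, validate_parameter_set
from .states import ED_INDEX, ED_STATES, N_AGES, EDState, Sex, parse_ed, parse_sex

__all__ = [
    "ScenarioSpec",
    "RandomStreams",
    "PersonHistory",
    "CohortHistories",
    "relapse_probability",
    "treated_remission_probability",
    "ed_mortality_probability",
    "annual_outcome_distribution",
    "simulate_cohort",
    "run_counterfactuals",
    "BASELINE",
    "NO_TREATMENT",
    "FULL_TREATMENT",
    "NO_INCIDENCE",
    "paper_scenarios",
]

_TREAT_MODES = {"current": _kernel.TREAT_CURRENT,
                "none": _kernel.TREAT_NONE,
                "full": _kernel.TREAT_FULL}


@dataclass(frozen=True)
class ScenarioSpec:
    """A counterfactual switch setting.

    ``treatment_mode``: 'current' (annual Bernoulli(coverage) assignment),
    'none' (nobody treated) or 'full' (every prevalent case treated).
    ``incidence_on``: False zeroes all naive incidence (prevention scenario).
    """

    name: str
    treatment_mode: str = "current"
    incidence_on: bool = True

    def __post_init__(self):
        if self.treatment_mode not in _TREAT_MODES:
            raise ValueError(f"unknown treatment_mode: {self.treatment_mode!r}")


BASELINE = ScenarioSpec("baseline", "current", True)
NO_TREATMENT = ScenarioSpec("no_treatment", "none", True)
FULL_TREATMENT = ScenarioSpec("full_treatment", "full", True)
NO_INCIDENCE = ScenarioSpec("no_incidence", "current", False)


def paper_scenarios() -> tuple:
    """The four analysis scenarios: baseline plus the three counterfactuals."""
    return (BASELINE, NO_TREATMENT, FULL_TREATMENT, NO_INCIDENCE)


@dataclass(frozen=True)
class RandomStreams:
    """Per-(person, age, channel) uniform substreams from one master seed.

    The whole uniform block is drawn up-front and indexed positionally, so a
    decision at (person, age) consumes the same uniform in every scenario —
    the common-random-numbers guarantee is structural, not stream-order based.
    """

    master_seed: int
    n_persons: int

    def uniforms(self) -> np.ndarray:
        rng = np.random.default_rng(self.master_seed)
        return rng.random((self.n_persons, N_AGES, 5), dtype=np.float32)

    @staticmethod
    def sexes(n_persons: int) -> np.ndarray:
        """50/50 deterministic sex assignment by person id (first half male)."""
        if n_persons % 2:
            raise ValueError("n_persons must be even for a 50/50 cohort")
        sexes = np.zeros(n_persons, dtype=np.int8)
        sexes[n_persons // 2:] = 1
        return sexes


# ---------------------------------------------------------------------------
# closed-form transition probabilities
# ---------------------------------------------------------------------------


def relapse_probability(p_first: float, decay: float,
                        years_since_remission: int) -> float:
    """Annual relapse probability ``p_first * exp(-decay * (years - 1))``.

    Year 1 (the first year after remission) returns ``p_first`` exactly; the
    hazard is nonincreasing in years since remission.
    """
    if years_since_remission < 1:
        raise ValueError("years_since_remission must be >= 1")
    if not 0 <= p_first <= 1 or not 0 <= decay <= 1:
        raise ValueError("p_first and decay must be in [0, 1]")
    return p_first * float(np.exp(-decay * (years_since_remission - 1)))


def treated_remission_probability(p_base: float, efficacy_rr: float) -> float:
    """Apply a rate ratio to an annual remission probability.

    Probability -> rate -> scale -> probability: ``1 - (1 - p_base)**rr``.
    Always >= p_base and <= 1.
    """
    if not 0 <= p_base <= 1:
        raise ValueError("p_base must be in [0, 1]")
    if efficacy_rr < 1:
        raise ValueError("efficacy_rr must be >= 1")
    if p_base == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_base) ** efficacy_rr


def ed_mortality_probability(q_bg: float, smr: float) -> float:
    """SMR-scaled annual death probability ``1 - (1 - q_bg)**smr``.

    Multiplication happens on the rate scale so the result stays below 1;
    equals ``q_bg`` when ``smr == 1``.
    """
    if not 0 <= q_bg < 1:
        raise ValueError("q_bg must be in [0, 1)")
    if smr < 1:
        raise ValueError("smr must be >= 1")
    return 1.0 - (1.0 - q_bg) ** smr


# ---------------------------------------------------------------------------
# reference transition distribution (pure Python; oracle for the kernel)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersonContext:
    """The history a transition depends on."""

    has_history: bool = False
    last_ed: EDState | None = None
    years_since_remission: int = 1


def annual_outcome_distribution(state, sex, age: int, history, ps: ParameterSet,
                                scenario: ScenarioSpec,
                                treated: bool | None = None) -> dict:
    """Distribution over next-year states for one (state, sex, age, history).

    ``treated=None`` marginalizes over the annual treatment draw under the
    scenario's treatment mode; passing a bool conditions on the draw.  This is
    the slow reference implementation the compiled kernel is tested against.
    """
    state, sex = EDState(state), parse_sex(sex)
    if state is EDState.DECEASED:
        raise ValueError("no transitions out of the deceased state")
    history = history or PersonContext()
    i = int(sex)
    q_bg = ps.life_table.prob(sex, age)
    dist = {s: 0.0 for s in EDState}

    if state is EDState.HEALTHY:
        dist[EDState.DECEASED] = q_bg
        surv = 1.0 - q_bg
        if history.has_history:
            last = parse_ed(history.last_ed)
            pr = relapse_probability(ps.relapse_p_first[i, ED_INDEX[last]],
                                     ps.relapse_decay[i, ED_INDEX[last]],
                                     history.years_since_remission)
            dist[last] = surv * pr
            dist[EDState.HEALTHY] = surv * (1.0 - pr)
        else:
            inc = ps.incidence[i, :, age] if scenario.incidence_on else np.zeros(4)
            for ed in ED_STATES:
                dist[ed] = surv * inc[ED_INDEX[ed]]
            dist[EDState.HEALTHY] = surv * (1.0 - inc.sum())
        return dist

    j = ED_INDEX[state]
    q_ed = ed_mortality_probability(q_bg, ps.smr[i, j])
    dist[EDState.DECEASED] = q_ed
    surv = 1.0 - q_ed
    p_b = ps.remission[i, j]
    p_t = treated_remission_probability(p_b, ps.efficacy[i, j])
    if treated is None:
        if scenario.treatment_mode == "none":
            p_rem = p_b
        elif scenario.treatment_mode == "full":
            p_rem = p_t
        else:
            cov = ps.coverage[i, j]
            p_rem = cov * p_t + (1.0 - cov) * p_b
    else:
        p_rem = p_t if treated else p_b
    dist[EDState.HEALTHY] = surv * p_rem
    cross = ps.crossover[i, j]
    cross_sum = 0.0
    for ed in ED_STATES:
        if ed is state:
            continue
        dist[ed] = surv * cross[ED_INDEX[ed]]
        cross_sum += cross[ED_INDEX[ed]]
    dist[state] = surv * (1.0 - p_rem - cross_sum)
    if dist[state] < -1e-12:
        raise ValueError("invalid parameter set: outgoing probabilities exceed 1")
    return dist


# ---------------------------------------------------------------------------
# histories container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersonHistory:
    """One simulated individual's annual record."""

    id: int
    sex: Sex
    state_by_age: np.ndarray       # (41,) EDState codes
    ever_ed: dict                  # EDState -> bool
    age_first_onset: int | None
    years_since_remission: int     # relapse-clock value at end of follow-up
    episode_count: int             # maximal contiguous runs in any ED state
    episode_counts_by_ed: dict     # EDState -> per-ED episode count
    treated_by_age: np.ndarray     # (40,) bool
    age_at_death: int | None


@dataclass
class Counts:
    """Per-age tallies accumulated during simulation (first axis sex)."""

    alive: np.ndarray           # (2, 41)
    in_state: np.ndarray        # (2, 4, 41)
    ever_any: np.ndarray        # (2, 41) cumulative onsets, deaths retained
    ever_any_alive: np.ndarray  # (2, 41) survivor-conditioned variant
    ever_ed: np.ndarray         # (2, 4, 41)
    onsets: np.ndarray          # (2, 41) first onsets manifesting at age


@dataclass
class CohortHistories:
    """Vectorized container of simulated person histories.

    Indexing returns a :class:`PersonHistory`; the arrays are the efficient
    interface the outcomes module works on.
    """

    sex: np.ndarray              # (n,) int8
    states: np.ndarray           # (n, 41) int8
    first_onset: np.ndarray      # (n,) int16, -1 if never
    first_entry: np.ndarray      # (n, 4) int16, first age in each ED state
    n_episodes: np.ndarray       # (n,) int16
    n_episodes_ed: np.ndarray    # (n, 4) int16
    age_at_death: np.ndarray     # (n,) int16, -1 if alive at 40
    treated: np.ndarray          # (n, 40) bool
    years_since_remission: np.ndarray  # (n,) int16
    counts: Counts | None = None
    scenario: ScenarioSpec | None = None
    master_seed: int | None = None

    def __len__(self) -> int:
        return self.sex.shape[0]

    def __getitem__(self, i: int) -> PersonHistory:
        fo = int(self.first_onset[i])
        dage = int(self.age_at_death[i])
        return PersonHistory(
            id=i,
            sex=Sex(int(self.sex[i])),
            state_by_age=self.states[i].copy(),
            ever_ed={ed: bool(self.first_entry[i, ED_INDEX[ed]] >= 0)
                     for ed in ED_STATES},
            age_first_onset=fo if fo >= 0 else None,
            years_since_remission=int(self.years_since_remission[i]),
            episode_count=int(self.n_episodes[i]),
            episode_counts_by_ed={ed: int(self.n_episodes_ed[i, ED_INDEX[ed]])
                                  for ed in ED_STATES},
            treated_by_age=self.treated[i].copy(),
            age_at_death=dage if dage >= 0 else None,
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def deaths_by_40(self) -> int:
        return int((self.age_at_death >= 0).sum())

    @classmethod
    def from_states(cls, states, sex, treated=None, scenario=None) -> "CohortHistories":
        """Derive all bookkeeping from a raw state matrix.

        Used to hand-build cohorts in tests and as an independent re-derivation
        of the kernel's episode/onset bookkeeping.
        """
        states = np.asarray(states, dtype=np.int8)
        sex = np.asarray(sex, dtype=np.int8)
        n, w = states.shape
        if w != N_AGES + 1:
            raise ValueError(f"state matrix must have {N_AGES + 1} age columns")
        is_ed = (states >= 1) & (states <= 4)
        prev_ed = np.zeros_like(is_ed)
        prev_ed[:, 1:] = is_ed[:, :-1]
        entries_any = is_ed & ~prev_ed
        n_episodes = entries_any.sum(axis=1).astype(np.int16)
        first_onset = np.where(is_ed.any(axis=1),
                               is_ed.argmax(axis=1), -1).astype(np.int16)
        first_entry = np.full((n, 4), -1, dtype=np.int16)
        n_episodes_ed = np.zeros((n, 4), dtype=np.int16)
        for e in range(4):
            in_e = states == e + 1
            prev_e = np.zeros_like(in_e)
            prev_e[:, 1:] = in_e[:, :-1]
            ent = in_e & ~prev_e
            n_episodes_ed[:, e] = ent.sum(axis=1)
            first_entry[:, e] = np.where(in_e.any(axis=1), in_e.argmax(axis=1), -1)
        dead = states == int(EDState.DECEASED)
        # death during year a manifests as DECEASED at a+1
        age_at_death = np.where(dead.any(axis=1),
                                dead.argmax(axis=1) - 1, -1).astype(np.int16)
        if treated is None:
            treated = np.zeros((n, N_AGES), dtype=bool)
        return cls(sex=sex, states=states, first_onset=first_onset,
                   first_entry=first_entry, n_episodes=n_episodes,
                   n_episodes_ed=n_episodes_ed, age_at_death=age_at_death,
                   treated=np.asarray(treated, dtype=bool),
                   years_since_remission=np.zeros(n, dtype=np.int16),
                   counts=_counts_from_persons(sex, states, first_onset, first_entry),
                   scenario=scenario)

    def to_long_frame(self):
        """Long-format export: one row per person-year (id, sex, age, state,
        treated)."""
        import pandas as pd

        n = len(self)
        ages = np.tile(np.arange(N_AGES + 1), n)
        ids = np.repeat(np.arange(n), N_AGES + 1)
        treated = np.zeros((n, N_AGES + 1), dtype=bool)
        treated[:, :N_AGES] = self.treated
        return pd.DataFrame({
            "id": ids,
            "sex": np.where(np.repeat(self.sex, N_AGES + 1) == 0, "M", "F"),
            "age": ages,
            "state": [EDState(s).name for s in self.states.ravel()],
            "treated": treated.ravel(),
        })

    def to_summary_frame(self):
        """Per-person summary export."""
        import pandas as pd

        return pd.DataFrame({
            "id": np.arange(len(self)),
            "sex": np.where(self.sex == 0, "M", "F"),
            "age_first_onset": self.first_onset,
            "n_episodes": self.n_episodes,
            **{f"n_episodes_{ed.name}": self.n_episodes_ed[:, ED_INDEX[ed]]
               for ed in ED_STATES},
            "age_at_death": self.age_at_death,
            "years_treated": self.treated.sum(axis=1),
        })


def _counts_from_persons(sex, states, first_onset, first_entry) -> Counts:
    """Recompute the per-age tallies from per-person arrays (numpy route)."""
    n_ages1 = N_AGES + 1
    alive = np.zeros((2, n_ages1), dtype=np.int64)
    in_state = np.zeros((2, 4, n_ages1), dtype=np.int64)
    ever_any = np.zeros((2, n_ages1), dtype=np.int64)
    ever_any_alive = np.zeros((2, n_ages1), dtype=np.int64)
    ever_ed = np.zeros((2, 4, n_ages1), dtype=np.int64)
    onsets = np.zeros((2, n_ages1), dtype=np.int64)
    ages = np.arange(n_ages1)
    for sx in (0, 1):
        m = sex == sx
        st = states[m]
        alive[sx] = (st != int(EDState.DECEASED)).sum(axis=0)
        for e in range(4):
            in_state[sx, e] = (st == e + 1).sum(axis=0)
        fo = first_onset[m]
        onset_mask = fo[:, None] >= 0
        everm = (fo[:, None] <= ages[None, :]) & onset_mask
        ever_any[sx] = everm.sum(axis=0)
        ever_any_alive[sx] = (everm & (st != int(EDState.DECEASED))).sum(axis=0)
        for e in range(4):
            fe = first_entry[m, e]
            ever_ed[sx, e] = ((fe[:, None] >= 0)
                              & (fe[:, None] <= ages[None, :])).sum(axis=0)
        valid = fo[fo >= 0]
        np.add.at(onsets[sx], valid, 1)
    return Counts(alive, in_state, ever_any, ever_any_alive, ever_ed, onsets)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _kernel_inputs(ps: ParameterSet, scenario: ScenarioSpec):
    q_bg = ps.life_table.q
    q_ed = 1.0 - (1.0 - q_bg[:, None, :]) ** ps.smr[:, :, None]
    inc = ps.incidence if scenario.incidence_on else np.zeros_like(ps.incidence)
    p_any = inc.sum(axis=1)
    p_rem_t = 1.0 - (1.0 - ps.remission) ** ps.efficacy
    return (np.ascontiguousarray(q_bg), np.ascontiguousarray(q_ed),
            np.ascontiguousarray(inc), np.ascontiguousarray(p_any),
            ps.relapse_p_first, ps.relapse_decay, ps.remission,
            np.ascontiguousarray(p_rem_t), ps.coverage, ps.crossover,
            _TREAT_MODES[scenario.treatment_mode])


def simulate_cohort(ps: ParameterSet, scenario: ScenarioSpec, n_persons: int,
                    master_seed: int, *, uniforms: np.ndarray | None = None,
                    sexes: np.ndarray | None = None,
                    check: bool = True) -> CohortHistories:
    """Simulate a 50/50-sex birth cohort under one scenario.

    Deterministic given ``master_seed``; pass ``uniforms`` (and matching
    ``sexes``) to share one random-number block across scenarios or across
    repeated evaluations of different parameter sets.
    """
    if check:
        violations = validate_parameter_set(ps)
        if violations:
            raise ValueError("invalid parameter set: "
                             + "; ".join(str(v) for v in violations))
    if sexes is None:
        sexes = RandomStreams.sexes(n_persons)
    if uniforms is None:
        uniforms = RandomStreams(master_seed, n_persons).uniforms()
    n = sexes.shape[0]

    states = np.zeros((n, N_AGES + 1), dtype=np.int8)
    first_onset = np.full(n, -1, dtype=np.int16)
    first_entry = np.full((n, 4), -1, dtype=np.int16)
    n_ep = np.zeros(n, dtype=np.int16)
    n_ep_ed = np.zeros((n, 4), dtype=np.int16)
    death_age = np.full(n, -1, dtype=np.int16)
    treated = np.zeros((n, N_AGES), dtype=np.bool_)
    ysr = np.zeros(n, dtype=np.int16)
    alive = np.zeros((2, N_AGES + 1), dtype=np.int64)
    in_state = np.zeros((2, 4, N_AGES + 1), dtype=np.int64)
    ever_any = np.zeros((2, N_AGES + 1), dtype=np.int64)
    ever_any_alive = np.zeros((2, N_AGES + 1), dtype=np.int64)
    ever_ed = np.zeros((2, 4, N_AGES + 1), dtype=np.int64)
    onsets = np.zeros((2, N_AGES + 1), dtype=np.int64)

    _kernel.run_cohort(sexes, uniforms, *_kernel_inputs(ps, scenario),
                       states, first_onset, first_entry, n_ep, n_ep_ed,
                       death_age, treated, ysr,
                       alive, in_state, ever_any, ever_any_alive, ever_ed, onsets)

    return CohortHistories(
        sex=sexes, states=states, first_onset=first_onset,
        first_entry=first_entry, n_episodes=n_ep, n_episodes_ed=n_ep_ed,
        age_at_death=death_age, treated=treated, years_since_remission=ysr,
        counts=Counts(alive, in_state, ever_any, ever_any_alive, ever_ed, onsets),
        scenario=scenario, master_seed=master_seed)


def run_counterfactuals(ps: ParameterSet, scenarios, n_persons: int,
                        master_seed: int) -> dict:
    """Run >= 2 scenarios under shared random streams; person ids align."""
    scenarios = list(scenarios)
    if len(scenarios) < 2:
        raise ValueError("need at least 2 scenarios for a counterfactual run")
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate scenario names: {names}")
    violations = validate_parameter_set(ps)
    if violations:
        raise ValueError("invalid parameter set: "
                         + "; ".join(str(v) for v in violations))
    sexes = RandomStreams.sexes(n_persons)
    u = RandomStreams(master_seed, n_persons).uniforms()
    return {s.name: simulate_cohort(ps, s, n_persons, master_seed,
                                    uniforms=u, sexes=sexes, check=False)
            for s in scenarios}
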