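"""Population statistics computed from simulated histories.

Measures mirror the standard epidemiological definitions:

* **annual (12-month) prevalence** at age *a*: share of persons alive during
  year *a* who occupy a matching ED state that year;
* **lifetime prevalence** at age *a*: cumulative incidence — share of the
  birth cohort with a first matching onset at or before *a* (the deceased
  remain in the denominator so the curve is nondecreasing; a
  survivor-conditioned variant, closer to what cross-sectional surveys
  measure, is available via ``conditional_on_survival=True``);
* **naive-incidence CDF**: distribution of the age of first-ever onset among
  those ever affected;
* **episode distribution**: number of ED episodes by age 40 among persons
  with any history, binned 1, 2, 3, 4, 5+ (an overall episode is a maximal
  contiguous run in *any* ED state — crossover does not end it);
* **deaths averted**: difference in cumulative deaths by 40 between two
  common-random-number paired scenario runs, per 100,000 persons.

Uncertainty across simulation runs is summarized by the mean, median and the
2.5th/97.5th empirical percentiles (95% uncertainty interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .microsim import CohortHistories
from .states import ED_STATES, N_AGES, EDState, parse_ed, parse_sex

__all__ = [
    "PrevalenceCurve",
    "EnsembleResult",
    "annual_prevalence",
    "lifetime_prevalence",
    "prevalence_curve",
    "naive_incidence_cdf",
    "episode_distribution",
    "deaths_averted",
    "ensemble_statistics",
    "EPISODE_BINS",
]

#: episode-count bins: 1, 2, 3, 4, 5+
EPISODE_BINS = ("1", "2", "3", "4", "5+")


def _ed_codes(ed_filter):
    """State codes matching an ED filter ('ANY', an EDState, or iterable)."""
    if isinstance(ed_filter, str) and ed_filter.upper() == "ANY":
        return [int(ed) for ed in ED_STATES]
    if isinstance(ed_filter, (EDState, str)):
        return [int(parse_ed(ed_filter))]
    return [int(parse_ed(e)) for e in ed_filter]


def _sex_mask(h: CohortHistories, sex):
    if sex is None:
        return np.ones(len(h), dtype=bool)
    return h.sex == int(parse_sex(sex))


def annual_prevalence(h: CohortHistories, ed_filter, sex, age: int) -> float:
    """Share of sex-matched persons alive during year ``age`` occupying a
    matching ED state."""
    if len(h) == 0:
        raise ValueError("empty cohort")
    m = _sex_mask(h, sex)
    col = h.states[m, age]
    alive = col != int(EDState.DECEASED)
    denom = int(alive.sum())
    if denom == 0:
        raise ValueError(f"no persons alive at age {age}")
    codes = _ed_codes(ed_filter)
    num = int(np.isin(col, codes).sum())
    return num / denom


def lifetime_prevalence(h: CohortHistories, ed_filter, sex, age: int,
                        conditional_on_survival: bool = False) -> float:
    """Share of the sex-matched cohort with a first matching onset at or
    before ``age`` (cumulative incidence; deaths retained in the denominator
    unless ``conditional_on_survival``)."""
    m = _sex_mask(h, sex)
    codes = _ed_codes(ed_filter)
    if len(codes) == 4:
        onset = h.first_onset[m]
        ever = (onset >= 0) & (onset <= age)
    else:
        fe = h.first_entry[m][:, [c - 1 for c in codes]]
        ever = ((fe >= 0) & (fe <= age)).any(axis=1)
    if conditional_on_survival:
        alive = h.states[m, age] != int(EDState.DECEASED)
        denom = int(alive.sum())
        num = int((ever & alive).sum())
    else:
        denom = int(m.sum())
        num = int(ever.sum())
    if denom == 0:
        raise ValueError("empty denominator")
    return num / denom


@dataclass(frozen=True)
class PrevalenceCurve:
    """Prevalence by age, ages 0..40."""

    measure: str   # "annual" | "lifetime"
    ed_filter: object
    sex: object
    value: np.ndarray  # (41,)

    def __post_init__(self):
        v = np.asarray(self.value, dtype=float)
        if v.shape != (N_AGES + 1,):
            raise ValueError("curve must cover ages 0..40")
        object.__setattr__(self, "value", v)


def prevalence_curve(h: CohortHistories, measure: str, ed_filter, sex,
                     conditional_on_survival: bool = False) -> PrevalenceCurve:
    fn = {"annual": annual_prevalence, "lifetime": lifetime_prevalence}[measure]
    kw = {"conditional_on_survival": conditional_on_survival} \
        if measure == "lifetime" else {}
    vals = np.array([fn(h, ed_filter, sex, a, **kw) for a in range(N_AGES + 1)])
    return PrevalenceCurve(measure, ed_filter, sex, vals)


def naive_incidence_cdf(h: CohortHistories, sex=None) -> np.ndarray:
    """F(a) = share of first-ever onsets occurring at or before age a,
    among persons with any onset.  F(40) == 1."""
    m = _sex_mask(h, sex)
    onset = h.first_onset[m]
    onset = onset[onset >= 0]
    if onset.size == 0:
        raise ValueError("no onsets in the selected group")
    counts = np.bincount(onset, minlength=N_AGES + 1)
    return np.cumsum(counts) / onset.size


def episode_distribution(h: CohortHistories, sex=None, ed_filter="ANY") -> np.ndarray:
    """Shares over episode counts {1, 2, 3, 4, 5+}, conditional on >= 1
    episode.  For a specific ED the per-ED episode count is used (a maximal
    contiguous run in that state)."""
    m = _sex_mask(h, sex)
    codes = _ed_codes(ed_filter)
    if len(codes) == 4:
        counts = h.n_episodes[m]
    elif len(codes) == 1:
        counts = h.n_episodes_ed[m][:, codes[0] - 1]
    else:
        raise ValueError("ed_filter must be 'ANY' or a single ED")
    counts = counts[counts >= 1]
    if counts.size == 0:
        raise ValueError("no persons with a matching episode")
    binned = np.minimum(counts, 5)
    return np.bincount(binned, minlength=6)[1:6] / counts.size


def deaths_averted(histories_a: CohortHistories, histories_b: CohortHistories,
                   scale: float = 100_000.0) -> float:
    """Deaths by 40 in scenario *a* minus scenario *b*, per ``scale`` persons.

    Positive when scenario *b* averts deaths relative to *a*.  The two runs
    must be common-random-number paired with equal cohort size.
    """
    if len(histories_a) != len(histories_b):
        raise ValueError("paired runs must have equal cohort sizes")
    n = len(histories_a)
    return (histories_a.deaths_by_40 - histories_b.deaths_by_40) * scale / n


@dataclass(frozen=True)
class EnsembleStatistics:
    mean: float
    median: float
    ui_lo: float
    ui_hi: float


def ensemble_statistics(per_run_values) -> EnsembleStatistics:
    """Mean, median and 95% UI (2.5/97.5 empirical percentiles, linear
    interpolation) of a statistic across simulation runs."""
    v = np.asarray(per_run_values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one run")
    lo, hi = np.percentile(v, [2.5, 97.5])
    return EnsembleStatistics(float(v.mean()), float(np.median(v)),
                              float(lo), float(hi))


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------

#: ED axis order in EnsembleResult arrays: ANY first, then the four EDs
ED_AXIS = ("ANY",) + tuple(ed.name for ed in ED_STATES)

#: deaths-averted comparisons reported by the ensemble (a vs b; positive
#: numbers mean b averts deaths relative to a)
AVERTED_COMPARISONS = {
    "current_vs_none": ("no_treatment", "baseline"),
    "full_vs_none": ("no_treatment", "full_treatment"),
    "prevention_vs_baseline": ("baseline", "no_incidence"),
}


@dataclass
class EnsembleResult:
    """Per-run summary statistics across an ensemble of simulations.

    Axis conventions: run, sex (M, F), ED (ANY, AN, BN, BED, OSFED), age.
    """

    annual: np.ndarray        # (runs, 2, 5, 41) annual prevalence, baseline
    lifetime: np.ndarray      # (runs, 2, 5, 41) cumulative incidence, baseline
    cdf_pooled: np.ndarray    # (runs, 41) naive-onset CDF, sexes pooled
    episodes: np.ndarray      # (runs, 2, 5) overall episode-count shares
    deaths: dict              # scenario name -> (runs,) deaths by 40
    averted: dict             # comparison name -> (runs,) per 100,000
    n_persons: int = 0
    parameter_index: np.ndarray | None = None  # which ensemble member per run

    @property
    def n_runs(self) -> int:
        return self.annual.shape[0]

    def _ed_idx(self, ed) -> int:
        name = "ANY" if (isinstance(ed, str) and ed.upper() == "ANY") \
            else parse_ed(ed).name
        return ED_AXIS.index(name)

    def mean_lifetime(self, sex, age: int, ed="ANY") -> float:
        return float(self.lifetime[:, int(parse_sex(sex)),
                                   self._ed_idx(ed), age].mean())

    def peak_annual(self, sex, ed="ANY"):
        """(peak value of the mean annual-prevalence curve, argmax age)."""
        curve = self.annual[:, int(parse_sex(sex)), self._ed_idx(ed), :].mean(axis=0)
        a = int(np.argmax(curve))
        return float(curve[a]), a

    def mean_cdf_at(self, age: int) -> float:
        return float(self.cdf_pooled[:, age].mean())

    def episode_share(self, sex, n_episodes: int = 1) -> float:
        """Mean share of affected persons with the given episode count
        (5 means 5 or more)."""
        return float(self.episodes[:, int(parse_sex(sex)), n_episodes - 1].mean())

    def averted_stats(self, comparison: str) -> EnsembleStatistics:
        return ensemble_statistics(self.averted[comparison])

    def statistic(self, name: str, **kw) -> EnsembleStatistics:
        """Ensemble statistics for a named per-run quantity."""
        per_run = {
            "lifetime": lambda: self.lifetime[:, int(parse_sex(kw["sex"])),
                                              self._ed_idx(kw.get("ed", "ANY")),
                                              kw["age"]],
            "annual": lambda: self.annual[:, int(parse_sex(kw["sex"])),
                                          self._ed_idx(kw.get("ed", "ANY")),
                                          kw["age"]],
            "cdf": lambda: self.cdf_pooled[:, kw["age"]],
            "episodes": lambda: self.episodes[:, int(parse_sex(kw["sex"])),
                                              kw["n_episodes"] - 1],
            "averted": lambda: self.averted[kw["comparison"]],
            "deaths": lambda: self.deaths[kw["scenario"]],
        }[name]()
        return ensemble_statistics(per_run)

    # ------------------------------------------------------------------ I/O
    def to_tidy_frame(self):
        """One row per (statistic, ed, sex, age, run)."""
        import pandas as pd

        rows = []
        runs = np.arange(self.n_runs)
        for measure, arr in (("annual_prevalence", self.annual),
                             ("lifetime_prevalence", self.lifetime)):
            for si, sx in enumerate("MF"):
                for ei, ed in enumerate(ED_AXIS):
                    for age in range(arr.shape[3]):
                        vals = arr[:, si, ei, age]
                        rows.append(pd.DataFrame(
                            {"statistic": measure, "ed": ed, "sex": sx,
                             "age": age, "run_id": runs, "value": vals}))
        for si, sx in enumerate("MF"):
            for b, label in enumerate(EPISODE_BINS):
                rows.append(pd.DataFrame(
                    {"statistic": "episode_share", "ed": f"ANY/{label}",
                     "sex": sx, "age": 40, "run_id": runs,
                     "value": self.episodes[:, si, b]}))
        for age in range(self.cdf_pooled.shape[1]):
            rows.append(pd.DataFrame(
                {"statistic": "naive_incidence_cdf", "ed": "ANY", "sex": "all",
                 "age": age, "run_id": runs, "value": self.cdf_pooled[:, age]}))
        for name, vals in self.averted.items():
            rows.append(pd.DataFrame(
                {"statistic": "deaths_averted", "ed": name, "sex": "all",
                 "age": 40, "run_id": runs, "value": vals}))
        for name, vals in self.deaths.items():
            rows.append(pd.DataFrame(
                {"statistic": "deaths_by_40", "ed": name, "sex": "all",
                 "age": 40, "run_id": runs, "value": vals}))
        return pd.concat(rows, ignore_index=True)

    def summary_frame(self):
        """Mean/median/95% UI per (statistic, ed, sex, age)."""
        tidy = self.to_tidy_frame()
        g = tidy.groupby(["statistic", "ed", "sex", "age"])["value"]
        out = g.agg(mean="mean", median="median",
                    ui_lo=lambda v: np.percentile(v, 2.5),
                    ui_hi=lambda v: np.percentile(v, 97.5)).reset_index()
        return out
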