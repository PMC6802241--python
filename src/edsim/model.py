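"""Model/Results interface tying the pipeline together.

:class:`EDCohortModel` is built from data (calibration targets, prior search
bounds, incidence shapes, a life table); ``fit()`` runs the restart
simulated-annealing calibration and returns an :class:`EDCalibrationResults`
object carrying the kept parameter ensemble, its per-parameter means and 95%
uncertainty intervals (``summary()``), and diagnostics.  Scenario simulation
(``simulate_ensemble``) hangs off the results object and propagates both
first-order (stochastic) and second-order (parameter) uncertainty by
re-drawing a kept parameter set for every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    AnnealConfig,
    AnnealResult,
    CalibrationTarget,
    calibrate,
    default_anchor_targets,
    simulate_targets,
    summarize_ensemble,
)
from .microsim import run_counterfactuals, paper_scenarios
from .outcomes import (
    AVERTED_COMPARISONS,
    EnsembleResult,
    deaths_averted,
    episode_distribution,
    naive_incidence_cdf,
)
from .parameters import LifeTable, SearchBounds, table1_bounds, table1_means
from .states import ED_INDEX, ED_STATES, N_AGES

__all__ = ["EDCohortModel", "EDCalibrationResults"]


class EDCohortModel:
    """An ED life-course cohort model to be calibrated to prevalence targets.

    Parameters
    ----------
    targets : list of CalibrationTarget
        Prevalence targets (with SEs) driving the loss.
    bounds : SearchBounds
        Uniform priors over the free parameters; fixed parameters, incidence
        shapes and the life table ride along inside.
    """

    def __init__(self, targets, bounds: SearchBounds):
        self.targets = list(targets)
        self.bounds = bounds
        if not self.targets:
            raise ValueError("need at least one calibration target")

    @classmethod
    def from_printed_anchors(cls, shapes: dict, life_table: LifeTable,
                             incidence_bounds: dict,
                             targets=None) -> "EDCohortModel":
        """The packaged reproduction setup: every published scalar parameter
        is fixed at its printed calibrated mean, leaving the 8 naive-incidence
        multipliers free, targeted at the printed headline prevalence anchors
        (or a caller-supplied target list)."""
        bounds = table1_bounds(shapes, life_table,
                               incidence_bounds=incidence_bounds,
                               fixed=table1_means())
        return cls(targets if targets is not None else default_anchor_targets(),
                   bounds)

    def fit(self, config: AnnealConfig | None = None, seed: int = 0,
            profile: str = "desk", progress: bool = False) -> "EDCalibrationResults":
        """Calibrate and return the results object.

        ``profile`` ('paper' or 'desk') selects a default
        :class:`AnnealConfig` when ``config`` is not given.
        """
        if config is None:
            config = AnnealConfig.paper() if profile == "paper" else AnnealConfig.desk()
        ensemble = calibrate(self.bounds, self.targets, config, seed,
                             progress=progress)
        return EDCalibrationResults(self, ensemble, config, seed)


@dataclass
class EDCalibrationResults:
    """Calibrated ensemble plus everything computed from it."""

    model: EDCohortModel
    ensemble: list            # AnnealResult, ascending score
    config: AnnealConfig
    seed: int

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.ensemble])

    @property
    def parameter_names(self) -> list:
        return self.model.bounds.names

    def summary(self):
        """Per-parameter mean and 95% UI over the kept ensemble, plus the
        score distribution — the calibrated-values table."""
        summ = summarize_ensemble(self.ensemble, names=self.parameter_names)
        frame = summ.to_frame()
        frame["prior_lo"] = self.model.bounds.lower()
        frame["prior_hi"] = self.model.bounds.upper()
        return frame

    def fitted_targets(self, sim_size: int | None = None, seed: int | None = None):
        """Ensemble-mean simulated value of each calibration target."""
        sim_size = sim_size or self.config.sim_size
        base = self.seed if seed is None else seed
        est = np.stack([
            simulate_targets(r.params, self.model.targets, sim_size,
                             (base + 7919 * (i + 1)) % 2**31)
            for i, r in enumerate(self.ensemble)])
        return est.mean(axis=0)

    def simulate_ensemble(self, n_runs: int, n_persons: int, seed: int = 0,
                          scenarios=None) -> EnsembleResult:
        """Run ``n_runs`` simulations of ``n_persons`` each, sampling one
        kept parameter set per run (uniform with replacement) and running all
        scenarios under common random numbers."""
        scenarios = list(scenarios) if scenarios is not None else list(paper_scenarios())
        ss = np.random.SeedSequence(seed)
        pick_rng = np.random.default_rng(ss.spawn(1)[0])
        run_seeds = [int(s) % 2**31 for s in ss.generate_state(n_runs)]
        picks = pick_rng.integers(0, len(self.ensemble), size=n_runs)

        annual = np.zeros((n_runs, 2, 5, N_AGES + 1))
        lifetime = np.zeros((n_runs, 2, 5, N_AGES + 1))
        cdf = np.zeros((n_runs, N_AGES + 1))
        episodes = np.zeros((n_runs, 2, 5))
        deaths = {s.name: np.zeros(n_runs) for s in scenarios}
        comparisons = {name: (a, b) for name, (a, b) in AVERTED_COMPARISONS.items()
                       if a in deaths and b in deaths}
        averted = {name: np.zeros(n_runs) for name in comparisons}

        for r in range(n_runs):
            ps = self.ensemble[picks[r]].params
            runs = run_counterfactuals(ps, scenarios, n_persons, run_seeds[r])
            base = runs.get("baseline", runs[scenarios[0].name])
            c = base.counts
            with np.errstate(invalid="ignore", divide="ignore"):
                for si in (0, 1):
                    alive = c.alive[si].astype(float)
                    cohort = float(c.alive[si, 0])
                    any_annual = c.in_state[si].sum(axis=0) / alive
                    annual[r, si, 0] = any_annual
                    lifetime[r, si, 0] = c.ever_any[si] / cohort
                    for ed in ED_STATES:
                        e = ED_INDEX[ed]
                        annual[r, si, 1 + e] = c.in_state[si, e] / alive
                        lifetime[r, si, 1 + e] = c.ever_ed[si, e] / cohort
                    if (base.n_episodes[base.sex == si] >= 1).any():
                        episodes[r, si] = episode_distribution(
                            base, sex=("M", "F")[si])
            if (base.first_onset >= 0).any():
                cdf[r] = naive_incidence_cdf(base)
            for s in scenarios:
                deaths[s.name][r] = runs[s.name].deaths_by_40
            for name, (a, b) in comparisons.items():
                averted[name][r] = deaths_averted(runs[a], runs[b])

        return EnsembleResult(annual=np.nan_to_num(annual),
                              lifetime=lifetime, cdf_pooled=cdf,
                              episodes=episodes, deaths=deaths,
                              averted=averted, n_persons=n_persons,
                              parameter_index=picks)
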