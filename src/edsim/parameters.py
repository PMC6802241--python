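"""Model parameters: types, prior search bounds, sampling, validation, repair.

Every quantity the disease model needs is collected in a :class:`ParameterSet`:

* age- and sex-specific *naive incidence* curves (annual probability of a
  first-ever onset of each ED),
* relapse parameters ``(p_first, decay)`` for the declining-exponential
  relapse hazard,
* annual remission probabilities without treatment,
* treatment coverage and treatment efficacy (a rate ratio on remission),
* annual ED-to-ED crossover probabilities,
* standardized mortality ratios (SMRs) applied to a background life table.

Calibration draws parameter sets from independent uniform priors described by
a :class:`SearchBounds` object.  Since the age profile of naive incidence is
supplied as a fixed *shape* (peak normalized to 1), the free incidence
parameter per (ED, sex) is a single scalar multiplier.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .states import (
    ED_INDEX,
    ED_STATES,
    N_AGES,
    SEXES,
    EDState,
    Sex,
    parse_ed,
    parse_sex,
    sex_label,
)

__all__ = [
    "IncidenceCurve",
    "RelapseParams",
    "RemissionParams",
    "TreatmentParams",
    "CrossoverMatrix",
    "MortalityParams",
    "LifeTable",
    "ParameterSet",
    "SearchBounds",
    "Violation",
    "build_incidence_curve",
    "calibrate_multiplier_to_cumulative",
    "sample_parameter_set",
    "validate_parameter_set",
    "repair_bounds",
    "sample_valid_parameter_set",
    "load_table1",
    "table1_means",
    "table1_bounds",
    "param_name",
]

# ---------------------------------------------------------------------------
# parameter naming
# ---------------------------------------------------------------------------

#: scalar parameter blocks keyed by (ed, sex)
SCALAR_BLOCKS = (
    "incidence_mult",
    "relapse_p_first",
    "relapse_decay",
    "remission",
    "coverage",
    "efficacy",
    "smr",
)


def param_name(block: str, ed, sex, to_ed=None) -> str:
    """Canonical flat name of one scalar parameter, e.g. ``remission:AN:F``
    or ``crossover:AN>BED:M``."""
    sx = sex_label(parse_sex(sex))
    if block == "crossover":
        return f"crossover:{parse_ed(ed).name}>{parse_ed(to_ed).name}:{sx}"
    return f"{block}:{parse_ed(ed).name}:{sx}"


def all_param_names() -> list[str]:
    names = []
    for block in SCALAR_BLOCKS:
        for ed in ED_STATES:
            for sex in SEXES:
                names.append(param_name(block, ed, sex))
    for f in ED_STATES:
        for t in ED_STATES:
            if f is t:
                continue
            for sex in SEXES:
                names.append(param_name("crossover", f, sex, to_ed=t))
    return names


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IncidenceCurve:
    """Annual probability of first-ever onset of ``ed``, by age 0..39."""

    ed: EDState
    sex: Sex
    p_naive: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p_naive, dtype=float)
        if p.shape != (N_AGES,):
            raise ValueError(f"incidence curve must have {N_AGES} ages")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("incidence probabilities must be in [0, 1]")
        object.__setattr__(self, "p_naive", p)


@dataclass(frozen=True)
class RelapseParams:
    """Declining-exponential relapse hazard after remission.

    ``p_first`` is the relapse probability in the first year after remission;
    subsequent years decay as ``exp(-decay * (years - 1))``.
    """

    ed: EDState
    sex: Sex
    p_first: float
    decay: float

    def __post_init__(self):
        if not 0.0 <= self.p_first <= 1.0:
            raise ValueError("p_first must be in [0, 1]")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must be in [0, 1]")


@dataclass(frozen=True)
class RemissionParams:
    ed: EDState
    sex: Sex
    p_base: float

    def __post_init__(self):
        if not 0.0 <= self.p_base <= 1.0:
            raise ValueError("p_base must be in [0, 1]")


@dataclass(frozen=True)
class TreatmentParams:
    """Annual treatment coverage and efficacy (rate ratio on remission)."""

    ed: EDState
    sex: Sex
    coverage: float
    efficacy_rr: float

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if self.efficacy_rr < 1.0:
            raise ValueError("efficacy_rr must be >= 1")


@dataclass(frozen=True)
class CrossoverMatrix:
    """Annual ED-to-ED direct transition probabilities, 4x4 with zero diagonal."""

    sex: Sex
    c: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if c.shape != (4, 4):
            raise ValueError("crossover matrix must be 4x4")
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError("crossover probabilities must be in [0, 1]")
        if np.any(np.diag(c) != 0):
            raise ValueError("crossover diagonal must be zero")
        object.__setattr__(self, "c", c)

    def prob(self, from_ed: EDState, to_ed: EDState) -> float:
        return float(self.c[ED_INDEX[from_ed], ED_INDEX[to_ed]])


@dataclass(frozen=True)
class MortalityParams:
    """Standardized mortality ratios per ED state (healthy implicitly 1)."""

    sex: Sex
    smr: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.smr, dtype=float)
        if s.shape != (4,):
            raise ValueError("smr must have 4 entries (AN, BN, BED, OSFED)")
        if np.any(s < 1):
            raise ValueError("SMR must be >= 1")
        object.__setattr__(self, "smr", s)


@dataclass(frozen=True)
class LifeTable:
    """Background annual probability of death q(sex, age), ages 0..39."""

    q: np.ndarray  # shape (2, N_AGES)

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (2, N_AGES):
            raise ValueError(f"life table must cover both sexes for ages 0..{N_AGES - 1}")
        if np.any(q < 0) or np.any(q >= 1):
            raise ValueError("background death probabilities must be in [0, 1)")
        object.__setattr__(self, "q", q)

    def prob(self, sex: Sex, age: int) -> float:
        return float(self.q[int(sex), int(age)])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        q = np.full((2, N_AGES), np.nan)
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"sex", "age", "q"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(f"{path}: life table CSV needs header columns sex,age,q")
            for i, row in enumerate(reader, start=2):
                try:
                    sex = parse_sex(row["sex"])
                    age = int(row["age"])
                    val = float(row["q"])
                except (ValueError, KeyError) as exc:
                    raise ValueError(f"{path}: line {i}: {exc}") from None
                if 0 <= age < N_AGES:
                    q[int(sex), age] = val
        if np.isnan(q).any():
            raise ValueError(f"{path}: life table must cover ages 0..{N_AGES - 1} for both sexes")
        return cls(q)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sex", "age", "q"])
            for sex in SEXES:
                for age in range(N_AGES):
                    w.writerow([sex_label(sex), age, repr(float(self.q[int(sex), age]))])


@dataclass(frozen=True)
class ParameterSet:
    """One complete, sex-specific draw of all model parameters.

    Internally array-backed (first axis sex, second axis ED in AN, BN, BED,
    OSFED order) for the simulation kernel; typed per-cell views are available
    through the accessor methods.
    """

    incidence: np.ndarray        # (2, 4, N_AGES)
    relapse_p_first: np.ndarray  # (2, 4)
    relapse_decay: np.ndarray    # (2, 4)
    remission: np.ndarray        # (2, 4)
    coverage: np.ndarray         # (2, 4)
    efficacy: np.ndarray         # (2, 4)
    crossover: np.ndarray        # (2, 4, 4), zero diagonal
    smr: np.ndarray              # (2, 4)
    life_table: LifeTable

    def __post_init__(self):
        shapes = {
            "incidence": (2, 4, N_AGES),
            "relapse_p_first": (2, 4),
            "relapse_decay": (2, 4),
            "remission": (2, 4),
            "coverage": (2, 4),
            "efficacy": (2, 4),
            "crossover": (2, 4, 4),
            "smr": (2, 4),
        }
        for name, shape in shapes.items():
            arr = np.ascontiguousarray(np.asarray(getattr(self, name), dtype=float))
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            object.__setattr__(self, name, arr)

    # typed views -----------------------------------------------------------
    def incidence_curve(self, ed, sex) -> IncidenceCurve:
        ed, sex = parse_ed(ed), parse_sex(sex)
        return IncidenceCurve(ed, sex, self.incidence[int(sex), ED_INDEX[ed]])

    def relapse(self, ed, sex) -> RelapseParams:
        ed, sex = parse_ed(ed), parse_sex(sex)
        i, j = int(sex), ED_INDEX[ed]
        return RelapseParams(ed, sex, float(self.relapse_p_first[i, j]),
                             float(self.relapse_decay[i, j]))

    def remission_params(self, ed, sex) -> RemissionParams:
        ed, sex = parse_ed(ed), parse_sex(sex)
        return RemissionParams(ed, sex, float(self.remission[int(sex), ED_INDEX[ed]]))

    def treatment(self, ed, sex) -> TreatmentParams:
        ed, sex = parse_ed(ed), parse_sex(sex)
        i, j = int(sex), ED_INDEX[ed]
        return TreatmentParams(ed, sex, float(self.coverage[i, j]),
                               float(self.efficacy[i, j]))

    def crossover_matrix(self, sex) -> CrossoverMatrix:
        return CrossoverMatrix(parse_sex(sex), self.crossover[int(parse_sex(sex))])

    def mortality(self, sex) -> MortalityParams:
        return MortalityParams(parse_sex(sex), self.smr[int(parse_sex(sex))])

    def get(self, name: str) -> float:
        """Value of one flat-named scalar parameter (incidence multipliers
        are not stored; use the curves)."""
        block, mid, sx = name.split(":")
        sex = int(parse_sex(sx))
        if block == "crossover":
            f, t = mid.split(">")
            return float(self.crossover[sex, ED_INDEX[parse_ed(f)], ED_INDEX[parse_ed(t)]])
        attr = {"relapse_p_first": "relapse_p_first", "relapse_decay": "relapse_decay",
                "remission": "remission", "coverage": "coverage",
                "efficacy": "efficacy", "smr": "smr"}[block]
        return float(getattr(self, attr)[sex, ED_INDEX[parse_ed(mid)]])


@dataclass
class Violation:
    """One validity violation: the probabilities leaving a state row can
    exceed 1 at some age."""

    kind: str          # "ed_row" | "healthy_row"
    sex: Sex
    ed: EDState | None  # None for healthy_row
    age: int           # worst offending age
    total: float       # offending probability sum
    names: tuple       # flat names of the sampled parameters in the sum

    def __str__(self):
        who = self.ed.name if self.ed is not None else "HEALTHY"
        return (f"{who}/{sex_label(self.sex)} age {self.age}: "
                f"outgoing probabilities sum to {self.total:.4f} > 1")


@dataclass
class SearchBounds:
    """Uniform prior search bounds over free scalar parameters.

    ``entries`` maps flat parameter names to ``(lower, upper)``.  Parameters
    not listed there take their value from ``fixed``.  ``shapes`` supplies the
    fixed age profile of naive incidence per (ED, sex) — the free incidence
    parameter is the scalar multiplier ``incidence_mult:<ED>:<sex>``.
    """

    entries: dict
    shapes: dict          # (EDState, Sex) -> (N_AGES,) array, peak == 1
    life_table: LifeTable
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.entries.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"{name}: invalid bounds ({lo}, {hi})")
        known = set(all_param_names())
        for name in list(self.entries) + list(self.fixed):
            if name not in known:
                raise ValueError(f"unknown parameter name: {name}")
        missing = known - set(self.entries) - set(self.fixed)
        if missing:
            raise ValueError(f"parameters neither free nor fixed: {sorted(missing)[:5]} ...")

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def lower(self) -> np.ndarray:
        return np.array([self.entries[n][0] for n in self.entries])

    def upper(self) -> np.ndarray:
        return np.array([self.entries[n][1] for n in self.entries])

    def copy(self) -> "SearchBounds":
        return SearchBounds(dict(self.entries), dict(self.shapes),
                            self.life_table, dict(self.fixed))

    # vector <-> ParameterSet ----------------------------------------------
    def build(self, values) -> ParameterSet:
        """Assemble a ParameterSet from free-parameter values (array in
        ``names`` order, or a name->value mapping) plus the fixed values."""
        if not isinstance(values, dict):
            values = dict(zip(self.entries, np.asarray(values, dtype=float)))
        merged = dict(self.fixed)
        merged.update(values)
        arrs = {b: np.zeros((2, 4)) for b in
                ("relapse_p_first", "relapse_decay", "remission",
                 "coverage", "efficacy", "smr")}
        mult = np.zeros((2, 4))
        cross = np.zeros((2, 4, 4))
        for name, val in merged.items():
            block, mid, sx = name.split(":")
            sex = int(parse_sex(sx))
            if block == "crossover":
                f, t = mid.split(">")
                cross[sex, ED_INDEX[parse_ed(f)], ED_INDEX[parse_ed(t)]] = val
            elif block == "incidence_mult":
                mult[sex, ED_INDEX[parse_ed(mid)]] = val
            else:
                arrs[block][sex, ED_INDEX[parse_ed(mid)]] = val
        inc = np.zeros((2, 4, N_AGES))
        for (ed, sex), shape in self.shapes.items():
            curve = build_incidence_curve(shape, mult[int(sex), ED_INDEX[ed]],
                                          ed=ed, sex=sex)
            inc[int(sex), ED_INDEX[ed]] = curve.p_naive
        return ParameterSet(
            incidence=inc,
            relapse_p_first=arrs["relapse_p_first"],
            relapse_decay=arrs["relapse_decay"],
            remission=arrs["remission"],
            coverage=arrs["coverage"],
            efficacy=arrs["efficacy"],
            crossover=cross,
            smr=arrs["smr"],
            life_table=self.life_table,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_incidence_curve(shape, multiplier: float, ed=EDState.AN,
                          sex=Sex.FEMALE) -> IncidenceCurve:
    """Scale a fixed age shape (peak value 1) by a scalar multiplier.

    ``p_naive[a] = clip(multiplier * shape[a], 0, 1)``; the curve peak equals
    the multiplier whenever ``multiplier <= 1``.
    """
    shape = np.asarray(shape, dtype=float)
    if shape.shape != (N_AGES,):
        raise ValueError(f"shape must have {N_AGES} ages")
    if np.any(shape < 0):
        raise ValueError("shape entries must be nonnegative")
    if shape.max() > 0 and not math.isclose(shape.max(), 1.0, rel_tol=1e-9):
        raise ValueError("shape must be normalized to peak value 1")
    if multiplier < 0:
        raise ValueError("multiplier must be nonnegative")
    return IncidenceCurve(parse_ed(ed), parse_sex(sex),
                          np.clip(multiplier * shape, 0.0, 1.0))


def calibrate_multiplier_to_cumulative(shape, age_window, cumulative_target: float,
                                       tol: float = 1e-10) -> float:
    """Solve for the multiplier m with
    ``1 - prod_{a in window} (1 - m * shape[a]) == cumulative_target``.

    This anchors a whole incidence curve to a published cumulative-incidence
    figure over an age window (e.g. an 8-year cumulative incidence among
    adolescent girls)."""
    shape = np.asarray(shape, dtype=float)
    a0, a1 = int(age_window[0]), int(age_window[1])
    if not (0 <= a0 <= a1 < N_AGES):
        raise ValueError("age window out of range")
    if not 0.0 <= cumulative_target < 1.0:
        raise ValueError("cumulative_target must be in [0, 1)")
    window = shape[a0:a1 + 1]
    if cumulative_target == 0.0:
        return 0.0
    if window.max() <= 0:
        raise ValueError("shape is zero over the age window; target unreachable")
    # the multiplier must keep the whole curve a valid probability (no
    # clipping anywhere), so it is capped by the global shape peak
    m_max = 1.0 / shape.max()

    def f(m):
        return 1.0 - np.prod(1.0 - m * window) - cumulative_target

    reach = f(m_max)
    if reach < 0:
        raise ValueError(
            f"target {cumulative_target} unreachable: window admits at most "
            f"{reach + cumulative_target:.6f} without probabilities exceeding 1")
    return float(brentq(f, 0.0, m_max, xtol=tol, rtol=8.9e-16))


def sample_parameter_set(bounds: SearchBounds, rng) -> ParameterSet:
    """Draw each free scalar independently Uniform(lower, upper)."""
    lo, hi = bounds.lower(), bounds.upper()
    x = rng.uniform(lo, hi)
    # uniform(l, l) returns l; keep exact for degenerate bounds
    x = np.where(lo == hi, lo, x)
    return bounds.build(x)


def validate_parameter_set(ps: ParameterSet) -> list[Violation]:
    """Check every state row admits a valid outcome distribution at all ages.

    For each (ED, sex, age): death probability (SMR-scaled) plus the treated
    remission probability plus all outgoing crossovers must not exceed 1.
    For the healthy row: total naive incidence plus background death must not
    exceed 1 at any age.  Returns an empty list iff the set is valid.
    """
    out: list[Violation] = []
    q = ps.life_table.q
    for sex in SEXES:
        i = int(sex)
        for ed in ED_STATES:
            j = ED_INDEX[ed]
            p_rem_t = 1.0 - (1.0 - ps.remission[i, j]) ** ps.efficacy[i, j]
            q_ed = 1.0 - (1.0 - q[i]) ** ps.smr[i, j]
            cross_sum = ps.crossover[i, j].sum()
            totals = q_ed + p_rem_t + cross_sum
            worst = int(np.argmax(totals))
            if totals[worst] > 1.0 + 1e-12:
                names = ([param_name("remission", ed, sex),
                          param_name("efficacy", ed, sex),
                          param_name("smr", ed, sex)]
                         + [param_name("crossover", ed, sex, to_ed=t)
                            for t in ED_STATES if t is not ed])
                out.append(Violation("ed_row", sex, ed, worst,
                                     float(totals[worst]), tuple(names)))
        inc_tot = ps.incidence[i].sum(axis=0) + q[i]
        worst = int(np.argmax(inc_tot))
        if inc_tot[worst] > 1.0 + 1e-12:
            names = [param_name("incidence_mult", ed, sex) for ed in ED_STATES]
            out.append(Violation("healthy_row", sex, None, worst,
                                 float(inc_tot[worst]), tuple(names)))
    return out


def repair_bounds(bounds: SearchBounds, violation: Violation,
                  factor: float = 0.9) -> SearchBounds:
    """Multiplicatively lower the lower bounds of the parameters in the
    violated sum (upper bounds untouched).  Returns a new SearchBounds."""
    new = bounds.copy()
    touched = False
    for name in violation.names:
        if name in new.entries:
            lo, hi = new.entries[name]
            new.entries[name] = (lo * factor, hi)
            touched = True
    if not touched:
        raise ValueError(
            f"violation involves no free parameter; cannot repair: {violation}")
    return new


def sample_valid_parameter_set(bounds: SearchBounds, rng,
                               max_repairs: int = 100):
    """Sample-validate-repair loop: if a draw is invalid the relevant lower
    bounds are iteratively lowered until a valid set is sampled.

    Returns ``(parameter_set, bounds)`` with the possibly-repaired bounds.
    """
    for _ in range(max_repairs):
        ps = sample_parameter_set(bounds, rng)
        violations = validate_parameter_set(ps)
        if not violations:
            return ps, bounds
        bounds = repair_bounds(bounds, violations[0])
    raise RuntimeError(
        f"no valid parameter set after {max_repairs} repair iterations; "
        "search bounds are degenerate")


# ---------------------------------------------------------------------------
# shipped prior-bounds fixture
# ---------------------------------------------------------------------------


def load_table1() -> list[dict]:
    """The shipped prior-bounds/calibrated-values fixture, one dict per row.

    Percent-unit rows keep their printed scale; use :func:`table1_bounds` /
    :func:`table1_means` for proportion-scale values.
    """
    ref = importlib.resources.files("edsim.data").joinpath("table1.csv")
    with ref.open(newline="") as fh:
        rows = []
        for row in csv.DictReader(fh):
            for k in ("lower", "upper", "calibrated_mean", "ui_lo", "ui_hi"):
                row[k] = float(row[k]) if row[k] != "" else math.nan
            rows.append(row)
    return rows


def _row_name(row: dict) -> str:
    if row["block"] == "crossover":
        f, t = row["ed"].split(">")
        return param_name("crossover", f, row["sex"], to_ed=t)
    return param_name(row["block"], row["ed"], row["sex"])


def _to_proportion(row: dict, value: float) -> float:
    return value / 100.0 if row["unit"] == "percent" else value


def table1_means() -> dict:
    """Printed calibrated means on the proportion scale, keyed by flat name.

    Note: a few printed means lie outside the printed prior bounds; they are
    returned as printed.
    """
    out = {}
    for row in load_table1():
        if row["block"] == "naive_incidence":
            continue
        out[_row_name(row)] = _to_proportion(row, row["calibrated_mean"])
    return out


def table1_bounds(shapes: dict, life_table: LifeTable,
                  incidence_bounds: dict | None = None,
                  fixed: dict | None = None) -> SearchBounds:
    """SearchBounds from the shipped fixture.

    ``incidence_bounds`` maps (EDState, Sex) or EDState to (lo, hi) bounds
    for the incidence multipliers (the printed table defers these to external
    age-specific curves, so they must be supplied; see
    :func:`edsim.synthetic_data.default_incidence_bounds`).  Names listed in
    ``fixed`` are removed from the free set and pinned at the given values.
    """
    entries: dict = {}
    for row in load_table1():
        if row["block"] == "naive_incidence":
            continue
        entries[_row_name(row)] = (_to_proportion(row, row["lower"]),
                                   _to_proportion(row, row["upper"]))
    incidence_bounds = incidence_bounds or {}
    for ed in ED_STATES:
        for sex in SEXES:
            b = incidence_bounds.get((ed, sex), incidence_bounds.get(ed))
            if b is None:
                raise ValueError(f"no incidence multiplier bounds for {ed.name}")
            entries[param_name("incidence_mult", ed, sex)] = tuple(b)
    fixed = dict(fixed or {})
    for name in fixed:
        entries.pop(name, None)
    return SearchBounds(entries=entries, shapes=shapes,
                        life_table=life_table, fixed=fixed)
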