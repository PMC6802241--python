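"""Optional matplotlib views of ensemble results (prevalence curves with
uncertainty bands, episode-count distributions, deaths averted by scenario).
"""

from __future__ import annotations

import numpy as np

from .outcomes import EPISODE_BINS, EnsembleResult, ensemble_statistics
from .states import N_AGES


def plot_prevalence(ens: EnsembleResult, measure: str = "annual", ed="ANY", ax=None):
    """Mean (solid), median (dashed) and 95% UI band by age, per sex."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    arr = ens.annual if measure == "annual" else ens.lifetime
    ei = ens._ed_idx(ed)
    ages = np.arange(N_AGES + 1)
    for si, (label, color) in enumerate((("male", "C0"), ("female", "C1"))):
        runs = arr[:, si, ei, :]
        lo, hi = np.percentile(runs, [2.5, 97.5], axis=0)
        ax.fill_between(ages, 100 * lo, 100 * hi, alpha=0.2, color=color)
        ax.plot(ages, 100 * runs.mean(axis=0), color=color, label=label)
        ax.plot(ages, 100 * np.median(runs, axis=0), color=color, ls="--")
    ax.set_xlabel("age, years")
    ax.set_ylabel(f"{measure} prevalence, %")
    ax.legend()
    return ax


def plot_episodes(ens: EnsembleResult, sex, ax=None):
    """Episode-count shares (mean dot, 95% UI line) among affected persons."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    from .states import parse_sex

    si = int(parse_sex(sex))
    x = np.arange(len(EPISODE_BINS))
    for b in x:
        st = ensemble_statistics(ens.episodes[:, si, b])
        ax.plot([b, b], [100 * st.ui_lo, 100 * st.ui_hi], color="C0")
        ax.plot(b, 100 * st.mean, "o", color="C0")
    ax.set_xticks(x, EPISODE_BINS)
    ax.set_xlabel("number of ED episodes by age 40")
    ax.set_ylabel("share of affected persons, %")
    return ax


def plot_deaths_averted(ens: EnsembleResult, ax=None):
    """Deaths averted per 100,000 by scenario comparison (mean, 95% UI)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = list(ens.averted)
    for i, name in enumerate(names):
        st = ensemble_statistics(ens.averted[name])
        ax.plot([i, i], [st.ui_lo, st.ui_hi], color="C2")
        ax.plot(i, st.mean, "s", color="C2")
    ax.set_xticks(range(len(names)), names, rotation=20)
    ax.set_ylabel("deaths averted per 100,000 by age 40")
    return ax
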