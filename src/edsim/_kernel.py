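"""Numba-compiled annual-cycle simulation kernel.

One call advances a whole cohort from birth (age 0) through the transition
out of age 39.  All randomness enters through a pre-drawn uniform array
``u[person, age, channel]`` so that common random numbers hold exactly across
scenarios and across repeated evaluations of different parameter sets: a
given (person, age, decision) always consumes the same uniform.

Channels: 0 death, 1 onset/relapse, 2 ED-type pick, 3 treatment assignment,
4 remission/crossover outcome.

Within each cycle, death is resolved first from the start-of-year state;
survivors resolve a single multinomial (remission / crossover / persist for
ED states; naive onset or relapse for healthy states).
"""

import numpy as np
from numba import njit

N_AGES = 40
DEAD = 5

CH_DEATH = 0
CH_ONSET = 1
CH_TYPE = 2
CH_TREAT = 3
CH_OUTCOME = 4

TREAT_CURRENT = 0
TREAT_NONE = 1
TREAT_FULL = 2


@njit(cache=True)
def run_cohort(sexes, u,
               q_bg, q_ed, inc, p_any,
               p_first, decay, p_rem, p_rem_t, cov, cross,
               tmode,
               states, first_onset, first_entry, n_ep, n_ep_ed,
               death_age, treated, ysr_out,
               alive, in_state, ever_any, ever_any_alive, ever_ed, onsets):
    """Simulate all persons; fills per-person outputs and per-age counts.

    Count arrays (first axis sex): ``alive[sx, a]`` persons alive during year
    ``a``; ``in_state[sx, e, a]`` persons in ED ``e`` during year ``a``;
    ``ever_any`` / ``ever_ed`` cumulative-onset counts including the deceased;
    ``ever_any_alive`` the survivor-conditioned variant; ``onsets[sx, a]``
    first-ever onsets manifesting at age ``a``.
    """
    n = sexes.shape[0]
    for p in range(n):
        sx = sexes[p]
        s = 0               # current state code
        has_hist = False
        last = -1           # most recent ED index
        ysr = 0             # years since remission (relapse clock)
        states[p, 0] = 0
        for a in range(N_AGES):
            alive[sx, a] += 1
            if s >= 1:
                in_state[sx, s - 1, a] += 1
            # --- death from start-of-year state ---
            if s == 0:
                q = q_bg[sx, a]
            else:
                q = q_ed[sx, s - 1, a]
            if u[p, a, CH_DEATH] < q:
                death_age[p] = a
                for aa in range(a + 1, N_AGES + 1):
                    states[p, aa] = DEAD
                s = DEAD
                break
            # --- survivors: one multinomial ---
            if s == 0:
                if has_hist:
                    pr = p_first[sx, last] * np.exp(-decay[sx, last] * (ysr - 1))
                    if u[p, a, CH_ONSET] < pr:
                        s = last + 1
                        n_ep[p] += 1
                        n_ep_ed[p, last] += 1
                        if first_entry[p, last] < 0:
                            first_entry[p, last] = a + 1
                    else:
                        ysr += 1
                else:
                    pa = p_any[sx, a]
                    if u[p, a, CH_ONSET] < pa:
                        r = u[p, a, CH_TYPE] * pa
                        c = 0.0
                        e = 3
                        for t in range(4):
                            c += inc[sx, t, a]
                            if r < c:
                                e = t
                                break
                        s = e + 1
                        has_hist = True
                        last = e
                        first_onset[p] = a + 1
                        onsets[sx, a + 1] += 1
                        n_ep[p] += 1
                        n_ep_ed[p, e] += 1
                        first_entry[p, e] = a + 1
            else:
                e = s - 1
                is_tr = False
                if tmode == TREAT_FULL:
                    is_tr = True
                elif tmode == TREAT_CURRENT:
                    is_tr = u[p, a, CH_TREAT] < cov[sx, e]
                if is_tr:
                    treated[p, a] = True
                    prem = p_rem_t[sx, e]
                else:
                    prem = p_rem[sx, e]
                r = u[p, a, CH_OUTCOME]
                if r < prem:
                    s = 0
                    ysr = 1
                else:
                    r -= prem
                    for t in range(4):
                        if t == e:
                            continue
                        ct = cross[sx, e, t]
                        if r < ct:
                            s = t + 1
                            last = t
                            n_ep_ed[p, t] += 1
                            if first_entry[p, t] < 0:
                                first_entry[p, t] = a + 1
                            break
                        r -= ct
            states[p, a + 1] = s
        # --- person-level wrap-up ---
        if s != DEAD:
            alive[sx, N_AGES] += 1
            if s >= 1:
                in_state[sx, s - 1, N_AGES] += 1
        ysr_out[p] = ysr
        fo = first_onset[p]
        if fo >= 0:
            for aa in range(fo, N_AGES + 1):
                ever_any[sx, aa] += 1
                if states[p, aa] != DEAD:
                    ever_any_alive[sx, aa] += 1
            for t in range(4):
                fe = first_entry[p, t]
                if fe >= 0:
                    for aa in range(fe, N_AGES + 1):
                        ever_ed[sx, t, aa] += 1
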