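"""Independent brute-force oracles: naive enumeration, no shared code paths."""

import math

import numpy as np


def cox_loss_bruteforce(h, times, events, rule="geq"):
    """Negative mean log partial likelihood by explicit risk-set enumeration."""
    h = list(map(float, h))
    n = len(h)
    total = 0.0
    for i in range(n):
        if events[i] != 1:
            continue
        if rule == "geq":
            risk = [j for j in range(n) if times[j] >= times[i]]
        else:
            risk = [j for j in range(n) if times[j] > times[i]]
        if not risk:
            raise ValueError("empty risk set")
        total += h[i] - math.log(sum(math.exp(h[j]) for j in risk))
    return -total / n


def concordance_bruteforce(h, times, events):
    """Harrell's C by explicit pair enumeration."""
    num, den = 0.0, 0
    n = len(h)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if h[i] > h[j]:
                    num += 1.0
                elif h[i] == h[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def auc_bruteforce_uncensored(h, times, horizon):
    """Case/control pair rate at a horizon; valid only without censoring."""
    cases = [i for i in range(len(h)) if times[i] <= horizon]
    controls = [j for j in range(len(h)) if times[j] > horizon]
    num = 0.0
    for i in cases:
        for j in controls:
            if h[i] > h[j]:
                num += 1.0
            elif h[i] == h[j]:
                num += 0.5
    return num / (len(cases) * len(controls))


def random_survival_instance(rng, n, tie_times=False, all_events=False):
    h = rng.normal(size=n)
    if tie_times:
        times = rng.integers(1, 4, size=n).astype(float)
    else:
        times = rng.exponential(1.0, size=n) + 0.05
    events = np.ones(n, dtype=int) if all_events else (rng.random(n) < 0.6).astype(int)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    return h, times, events
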