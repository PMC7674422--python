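"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities through a different code path than
the package: per-lineage event-queue simulation instead of the jitted count
process, vectorized pure-birth rejection sampling for conditioned tree
shapes, and closed forms where they exist.
"""

from __future__ import annotations

import numpy as np


def naive_bd_history(rng, lam, mu, t):
    """Explicit per-lineage birth–death simulation.

    Every lineage is an object with its own birth time; S is the summed
    lifespan of all lineages (alive or extinct) clipped to [0, t].
    Returns (n_alive_at_t, S).
    """
    # each lineage: birth_time; simulate sequentially with a stack
    s_total = 0.0
    n_alive = 0
    stack = [0.0]  # birth times of lineages awaiting simulation
    total = lam + mu
    while stack:
        now = stack.pop()
        while True:
            if total == 0:
                s_total += t - now
                n_alive += 1
                break
            wait = rng.exponential(1.0 / total)
            if now + wait >= t:
                s_total += t - now
                n_alive += 1
                break
            now += wait
            s_total += wait
            if rng.random() < lam / total:
                stack.append(now)  # child lineage; parent lineage continues
            else:
                break  # death of this lineage
    return n_alive, s_total


def naive_conditioned_mean_integrand(rng, lam, mu, psi, t, n_reps):
    """E[psi N e^{-psi S} | N >= 1] via per-lineage simulation.

    Returns (estimate, standard_error) over accepted replicates.
    """
    vals = []
    while len(vals) < n_reps:
        n, s = naive_bd_history(rng, lam, mu, t)
        if n >= 1:
            vals.append(psi * n * np.exp(-psi * s))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))


def yule_3tip_node_ages(rng, lam, root_age, n_samples):
    """Non-root node ages of pure-birth trees with exactly 3 tips.

    Forward simulation from the root (2 lineages): one split within the root
    age, then no further split.  Vectorized rejection sampling; returns node
    ages (root_age - split time).
    """
    out = []
    while len(out) < n_samples:
        m = 4 * n_samples
        w1 = rng.exponential(1.0 / (2 * lam), size=m)
        w2 = rng.exponential(1.0 / (3 * lam), size=m)
        ok = (w1 < root_age) & (w1 + w2 > root_age)
        out.extend((root_age - w1[ok]).tolist())
    return np.asarray(out[:n_samples])


def yule_4tip_node_ages(rng, lam, root_age, n_samples):
    """Node-age pairs of exactly-4-tip pure-birth trees, split by topology.

    Returns (balanced_pairs, caterpillar_pairs); each row is the (older,
    younger) non-root internal node ages.  Topology: after the first split
    (producing lineages x1, x2 alongside the untouched root child y), the
    second split hits x1/x2 (caterpillar) with probability 2/3 or y
    (balanced) with probability 1/3.
    """
    bal, cat = [], []
    need = n_samples
    while min(len(bal), len(cat)) < need:
        m = 8 * need
        w1 = rng.exponential(1.0 / (2 * lam), size=m)
        w2 = rng.exponential(1.0 / (3 * lam), size=m)
        w3 = rng.exponential(1.0 / (4 * lam), size=m)
        t2 = w1 + w2
        ok = (t2 < root_age) & (t2 + w3 > root_age)
        second_on_new = rng.random(m) < 2.0 / 3.0
        older = root_age - w1[ok]
        younger = root_age - t2[ok]
        on_new = second_on_new[ok]
        cat.extend(zip(older[on_new], younger[on_new]))
        bal.extend(zip(older[~on_new], younger[~on_new]))
    return (
        np.asarray(bal[:need]),
        np.asarray(cat[:need]),
    )
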