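"""Metropolis–Hastings node dating on a fixed rooted topology.

The sampler updates internal-node ages (and optionally a strict-clock rate)
while the topology stays fixed.  The target is

    p(ages) ∝ birth–death node-age prior × Π_c calibration density_c(age_c)
              [ × pruning likelihood of the alignment, for the posterior ]

Calibration densities are evaluated by interpolating precomputed tables;
ages outside a density's support score −inf and the proposal is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import ConstraintMappingError, TaxonMappingError
from .bd_process import BDParams, derive_rates, _node_age_logkernel, _node_age_cdf
from .calibration import (
    CladeConstraint,
    GridSpec,
    calibration_density_for_constraint,
)
from .trees import TimeTree

__all__ = [
    "MCMCConfig",
    "Trace",
    "sample_prior",
    "sample_posterior",
    "ess",
    "hpd_interval",
    "count_mode_switches",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-length, thinning and proposal settings."""

    iterations: int = 200_000
    thinning: int = 10
    burn_in_fraction: float = 0.1
    operator_weights: dict = field(
        default_factory=lambda: {
            "node_slide": 3.0,
            "subtree_scale": 1.0,
            "root_scale": 1.0,
            "root_slide": 1.0,
        }
    )
    scale_factor: float = 0.75       # scale draws s ~ U(k, 1/k)
    root_slide_window: Optional[float] = None  # default: half the start root age
    tune: bool = False               # adapt windows during burn-in only
    seed: int = 0

    def __post_init__(self):
        if not self.iterations >= self.thinning >= 1:
            raise ValueError("need iterations >= thinning >= 1")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if not 0 < self.scale_factor < 1:
            raise ValueError("scale_factor must lie in (0, 1)")


@dataclass
class Trace:
    """Thinned MCMC samples with per-column access and burn-in handling."""

    data: pd.DataFrame
    thinning: int
    seed: int
    burn_in_fraction: float = 0.1

    def __len__(self):
        return len(self.data)

    @property
    def n_burn_in(self) -> int:
        return int(np.floor(self.burn_in_fraction * len(self.data)))

    def retained(self, column: str) -> np.ndarray:
        """Post-burn-in samples of one column."""
        return self.data[column].to_numpy()[self.n_burn_in:]

    def columns(self):
        return list(self.data.columns)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for col in self.data.columns:
            if col == "iteration":
                continue
            x = self.retained(col)
            lo, hi = hpd_interval(x, level) if len(x) >= 100 else (np.nan, np.nan)
            rows.append(
                {
                    "parameter": col,
                    "mean": float(np.mean(x)),
                    "median": float(np.median(x)),
                    f"hpd{int(level * 100)}_low": lo,
                    f"hpd{int(level * 100)}_high": hi,
                    "ess": ess(x) if len(x) >= 10 else np.nan,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trace summaries
# ---------------------------------------------------------------------------


def ess(series) -> float:
    """Effective sample size via Geyer's initial monotone sequence estimator.

    Pairs successive autocovariances, truncates at the first non-positive
    pair sum, and enforces monotonicity, giving a conservative estimate of
    the integrated autocorrelation time.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("ESS needs at least 10 samples")
    x = x - x.mean()
    var0 = float(np.dot(x, x) / n)
    if var0 <= 1e-300 or not np.isfinite(var0):
        warnings.warn("degenerate (constant) series; reporting ESS = length")
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real / n
    pair = acov[0:-1:2] + acov[1::2]
    sigma2 = -acov[0]
    prev = np.inf
    for g in pair:
        if g <= 0:
            break
        g = min(g, prev)
        prev = g
        sigma2 += 2.0 * g
    sigma2 = max(sigma2, acov[0] / n)
    return float(min(n, n * acov[0] / sigma2))


def hpd_interval(series, level: float = 0.95):
    """Shortest interval containing ``ceil(level * n)`` sorted samples."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    x = np.sort(np.asarray(series, dtype=float))
    n = len(x)
    if n < 100:
        raise ValueError("HPD interval needs at least 100 samples")
    k = int(np.ceil(level * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def count_mode_switches(samples, valley: float) -> int:
    """Number of crossings of the inter-mode valley along a trace."""
    side = np.asarray(samples) > valley
    return int(np.sum(side[1:] != side[:-1]))


# ---------------------------------------------------------------------------
# Sampler core
# ---------------------------------------------------------------------------


class _Target:
    """Unnormalized log target over internal-node ages (+ optional log rate)."""

    def __init__(self, tree, lam, mu, root_model, cal_nodes, cal_densities,
                 loglik_fn=None, log_rate_bounds=(np.log(1e-8), np.log(1e2))):
        self.tree = tree
        self.lam = lam
        self.mu = mu
        self.root_model = root_model
        self.cal_nodes = cal_nodes
        self.cal_densities = cal_densities
        self.loglik_fn = loglik_fn
        self.log_rate_bounds = log_rate_bounds
        self.free = np.array(
            [nd for nd in tree.internal_nodes if nd != tree.root], dtype=int
        )

    def __call__(self, ages, log_rate=None) -> float:
        tree = self.tree
        tree.ages = ages
        if not tree.ages_valid():
            return -np.inf
        lp = 0.0
        t_root = ages[tree.root]
        if self.root_model is not None:
            lp += float(self.root_model.logpdf(t_root))
        if self.lam > self.mu and len(self.free):
            lp += float(
                np.sum(_node_age_logkernel(ages[self.free], self.lam, self.mu))
                - len(self.free) * np.log(_node_age_cdf(t_root, self.lam, self.mu))
            )
        for nd, dens in zip(self.cal_nodes, self.cal_densities):
            lp += dens.logpdf(ages[nd])
            if not np.isfinite(lp):
                return -np.inf
        if self.loglik_fn is not None:
            lo, hi = self.log_rate_bounds
            if not lo <= log_rate <= hi:
                return -np.inf
            lp += self.loglik_fn(ages, np.exp(log_rate))
        return lp if np.isfinite(lp) else -np.inf


def _run_chain(target, tree, config, sample_rate=False, log_rate0=None,
               extra_columns=None):
    rng = np.random.default_rng(config.seed)
    ages = tree.ages.copy()
    log_rate = log_rate0
    lp = target(ages.copy(), log_rate)
    if not np.isfinite(lp):
        raise ValueError(
            "initial state has zero posterior density; check that the "
            "starting ages are compatible with the calibration densities"
        )
    internals = tree.internal_nodes
    non_root = [nd for nd in internals if nd != tree.root]
    root = tree.root
    kappa = config.scale_factor
    window = config.root_slide_window
    if window is None:
        window = 0.5 * ages[root]
    ops = dict(config.operator_weights)
    if not non_root:
        ops.pop("node_slide", None)
    if sample_rate:
        ops.setdefault("rate_scale", 1.0)
        # joint up/down move along the rate-time ridge: ages up, rate down
        ops.setdefault("rate_age_scale", 2.0)
    names = list(ops)
    probs = np.array([ops[k] for k in names], dtype=float)
    probs /= probs.sum()
    n_out = config.iterations // config.thinning
    records = np.empty((n_out, 2 + len(internals) + (1 if sample_rate else 0)))
    children = tree.children
    parent = tree.parent
    burn_end = int(config.burn_in_fraction * config.iterations)
    acc = {k: [0, 0] for k in names}
    op_draws = rng.choice(len(names), size=config.iterations, p=probs)
    for it in range(config.iterations):
        op = names[op_draws[it]]
        hastings = 0.0
        new_ages = ages
        new_log_rate = log_rate
        if op == "node_slide":
            nd = non_root[int(rng.integers(len(non_root)))]
            lo = max(ages[c] for c in children[nd])
            hi = ages[parent[nd]]
            new_ages = ages.copy()
            new_ages[nd] = rng.uniform(lo, hi)
        elif op == "subtree_scale":
            nd = internals[int(rng.integers(len(internals)))]
            sub = tree.subtree_internal_nodes(nd)
            s = rng.uniform(kappa, 1.0 / kappa)
            new_ages = ages.copy()
            new_ages[sub] = ages[sub] * s
            hastings = (len(sub) - 2) * np.log(s)
        elif op == "root_scale":
            s = rng.uniform(kappa, 1.0 / kappa)
            new_ages = ages.copy()
            new_ages[root] = ages[root] * s
            hastings = -np.log(s)
        elif op == "root_slide":
            new_ages = ages.copy()
            new_ages[root] = ages[root] + rng.uniform(-window, window)
        elif op == "rate_scale":
            # symmetric additive move on log(rate): no Hastings correction
            new_log_rate = log_rate + rng.uniform(np.log(kappa), -np.log(kappa))
        elif op == "rate_age_scale":
            s = rng.uniform(kappa, 1.0 / kappa)
            new_ages = ages.copy()
            new_ages[internals] = ages[internals] * s
            new_log_rate = log_rate - np.log(s)
            hastings = (len(internals) - 2) * np.log(s)
        new_lp = target(new_ages, new_log_rate)
        acc[op][1] += 1
        if np.log(rng.random()) < new_lp - lp + hastings:
            ages = new_ages
            log_rate = new_log_rate
            lp = new_lp
            acc[op][0] += 1
        if config.tune and it < burn_end and op == "root_slide" and acc[op][1] % 50 == 0:
            rate = acc[op][0] / acc[op][1]
            window *= 1.25 if rate > 0.3 else (0.8 if rate < 0.15 else 1.0)
        if (it + 1) % config.thinning == 0:
            row = records[(it + 1) // config.thinning - 1]
            row[0] = it + 1
            row[1] = lp
            row[2: 2 + len(internals)] = ages[internals]
            if sample_rate:
                row[-1] = np.exp(log_rate)
    tree.ages = ages
    cols = ["iteration", "log_posterior"] + [f"age_node{nd}" for nd in internals]
    if sample_rate:
        cols.append("clock_rate")
    df = pd.DataFrame(records, columns=cols)
    if extra_columns:
        df = df.rename(columns=extra_columns)
    return df, acc


def _prepare(tree, constraints, bd, densities, grid_spec, n_reps, seed):
    """Map constraints to nodes and make sure densities exist."""
    tree = tree.copy()
    cal_nodes, cal_densities, labels = [], [], {}
    for i, c in enumerate(constraints):
        nd = tree.monophyletic_mrca(c.tip_set)
        if nd < tree.n_tips:
            raise ConstraintMappingError(
                f"clade {c.clade_label!r} maps to a single tip; calibrations "
                "apply to internal nodes"
            )
        if densities is not None and c.clade_label in densities:
            dens = densities[c.clade_label]
        else:
            dens = calibration_density_for_constraint(
                c, bd, grid_spec, n_reps, seed + 1000 + i
            )
        cal_nodes.append(nd)
        cal_densities.append(dens)
        labels[f"age_node{nd}"] = f"age_{c.clade_label}"
    return tree, cal_nodes, cal_densities, labels


def _initialize_ages(tree, cal_nodes, cal_densities):
    """Start from density medians, then raise ancestors to restore ordering."""
    for nd, dens in zip(cal_nodes, cal_densities):
        tree.ages[nd] = dens.quantile(0.5)
    for nd in tree.postorder:
        if nd >= tree.n_tips:
            top = max(tree.ages[c] for c in tree.children[nd])
            if tree.ages[nd] <= top:
                tree.ages[nd] = top * 1.001 + 1e-3


def sample_prior(
    tree: TimeTree,
    constraints: Sequence[CladeConstraint],
    bd: BDParams,
    config: MCMCConfig,
    root_model=None,
    densities: Optional[dict] = None,
    grid_spec: Optional[GridSpec] = None,
    density_reps: int = 100_000,
) -> Trace:
    """Sample node ages from the tree prior times the calibration densities.

    ``densities`` may carry precomputed :class:`CalibrationDensity` tables
    keyed by clade label; missing ones are computed from ``bd``.
    The topology of ``tree`` is never altered.
    """
    tree, cal_nodes, cal_densities, labels = _prepare(
        tree, constraints, bd, densities, grid_spec, density_reps, config.seed
    )
    mid = bd.midpoint()
    d = mid.net_diversification[0]
    eps = mid.turnover[0]
    lam, mu = derive_rates(d, eps) if d > 0 else (0.0, 0.0)
    target = _Target(tree.copy(), lam, mu, root_model, cal_nodes, cal_densities)
    _initialize_ages(tree, cal_nodes, cal_densities)
    df, _ = _run_chain(target, tree, config, extra_columns=labels)
    return Trace(df, config.thinning, config.seed, config.burn_in_fraction)


def sample_posterior(
    tree: TimeTree,
    alignment,
    subst_model,
    clock_rate: float,
    constraints: Sequence[CladeConstraint],
    bd: BDParams,
    config: MCMCConfig,
    root_model=None,
    densities: Optional[dict] = None,
    grid_spec: Optional[GridSpec] = None,
    density_reps: int = 100_000,
    sample_clock_rate: bool = True,
) -> Trace:
    """Posterior over node ages (and the strict-clock rate) given sequences.

    The likelihood is the pruning likelihood of ``alignment`` under
    ``subst_model`` with branch lengths ``clock_rate × duration``; the clock
    rate gets a broad log-uniform prior and its own scale operator.
    ``clock_rate`` is the starting value.
    """
    from .seq_likelihood import TreeLikelihood

    if clock_rate <= 0:
        raise ValueError("clock_rate must be > 0")
    tree, cal_nodes, cal_densities, labels = _prepare(
        tree, constraints, bd, densities, grid_spec, density_reps, config.seed
    )
    missing = set(alignment.names) - set(tree.tip_names)
    if missing:
        raise TaxonMappingError(
            f"alignment taxa absent from the tree: {sorted(missing)}"
        )
    mid = bd.midpoint()
    d = mid.net_diversification[0]
    eps = mid.turnover[0]
    lam, mu = derive_rates(d, eps) if d > 0 else (0.0, 0.0)
    lik = TreeLikelihood(alignment, tree, subst_model)
    target = _Target(
        tree.copy(), lam, mu, root_model, cal_nodes, cal_densities,
        loglik_fn=lik.loglik_for_ages,
    )
    _initialize_ages(tree, cal_nodes, cal_densities)
    df, _ = _run_chain(
        target, tree, config, sample_rate=sample_clock_rate,
        log_rate0=float(np.log(clock_rate)), extra_columns=labels,
    )
    if not sample_clock_rate:
        df["clock_rate"] = clock_rate
    return Trace(df, config.thinning, config.seed, config.burn_in_fraction)
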