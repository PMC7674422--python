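"""Synthetic-data generators and the bimodality/convergence experiment.

The bimodality experiment probes MCMC behaviour under two-fossil mixture
priors of increasing component separation: two simulated point-age fossils
with equal weights calibrate the root of a minimal two-tip tree, the chain
samples from the prior alone, and the report records how close the sampled
node ages are to the specified mixture density and how often the chain
crosses the inter-mode valley.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_1samp

from .bd_process import BDParams
from .calibration import (
    FossilRecord,
    CladeConstraint,
    GridSpec,
    mixture_calibration_density,
    single_calibration_density,
)
from .dating_mcmc import MCMCConfig, count_mode_switches, sample_prior
from .marker_filter import FilterReport
from .trees import TimeTree

__all__ = [
    "teleost_bd_params",
    "two_tip_tree",
    "BimodalityReport",
    "bimodality_experiment",
    "MarkerFixtureSpec",
    "generate_marker_fixture",
]


def teleost_bd_params() -> BDParams:
    """Published teleost diversification and fossil-sampling rate ranges.

    Net diversification 0.041–0.081 and turnover 0.0011–0.37 (per lineage
    per Myr), fossil sampling rate 0.0066–0.01806 per lineage per Myr.
    """
    return BDParams(
        net_diversification=(0.041, 0.081),
        turnover=(0.0011, 0.37),
        sampling_rate=(0.0066, 0.01806),
    )


def two_tip_tree(root_age: float = 100.0, names=("A", "B")) -> TimeTree:
    """Minimal tree whose only internal node (the root) can be calibrated."""
    return TimeTree(list(names), [2, 2, -1], [0.0, 0.0, root_age])


@dataclass
class BimodalityReport:
    """Per-separation outcome of the mixture-prior MCMC experiment."""

    rows: pd.DataFrame
    densities: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.rows


def _valley_between_modes(density):
    """Location and density of the minimum between the two largest modes."""
    modes = density.modes(rel_prominence=0.05)
    if len(modes) < 2:
        return None
    # two most prominent modes by density value
    vals = [density.evaluate(m) for m in modes]
    order = np.argsort(vals)[::-1]
    m1, m2 = sorted([modes[order[0]], modes[order[1]]])
    grid = density.age_grid
    sel = (grid > m1) & (grid < m2)
    if not sel.any():
        return None
    i = np.argmin(density.density_values[sel])
    return float(grid[sel][i])


def bimodality_experiment(
    separations: Sequence[float] = (30.0, 60.0, 90.0, 120.0),
    bd: Optional[BDParams] = None,
    config: Optional[MCMCConfig] = None,
    younger_age: float = 50.0,
    density_reps: int = 100_000,
    grid_spec: Optional[GridSpec] = None,
    seed: int = 1,
) -> BimodalityReport:
    """Prior-only MCMC under two-fossil mixture priors of growing separation.

    For each separation the two simulated fossils are point-aged (the younger
    at ``younger_age`` Ma) with equal weights; the mixture density calibrates
    the root of a two-tip tree with an otherwise flat root prior, so the
    sampled root ages should reproduce the mixture density exactly.
    """
    for s in separations:
        if s < 0:
            raise ValueError("separations must be >= 0")
    bd = (bd or teleost_bd_params()).midpoint()
    rows = []
    densities, traces = {}, {}
    for k, sep in enumerate(separations):
        younger = FossilRecord("sim_younger", younger_age, younger_age, 0.5)
        older = FossilRecord(
            "sim_older", younger_age + sep, younger_age + sep, 0.5
        )
        if sep == 0:
            density = single_calibration_density(
                bd, younger, grid_spec, density_reps, seed + 7 * k
            )
        else:
            density = mixture_calibration_density(
                younger, older, bd, grid_spec, density_reps, seed + 7 * k
            )
        cfg = config or MCMCConfig(iterations=1_000_000, thinning=10)
        cfg = MCMCConfig(
            iterations=cfg.iterations,
            thinning=cfg.thinning,
            burn_in_fraction=cfg.burn_in_fraction,
            operator_weights=cfg.operator_weights,
            scale_factor=cfg.scale_factor,
            root_slide_window=younger_age + sep + 60.0,
            tune=False,
            seed=seed + 1000 + k,
        )
        tree = two_tip_tree(root_age=float(density.quantile(0.5)))
        constraint = CladeConstraint(
            f"sep{int(sep)}", frozenset(tree.tip_names), (younger, older)
            if sep > 0 else (younger,),
        )
        trace = sample_prior(
            tree, [constraint], bd, cfg,
            densities={constraint.clade_label: density},
        )
        samples = trace.retained(f"age_{constraint.clade_label}")
        ks = float(ks_1samp(samples, density.cdf).statistic)
        valley = _valley_between_modes(density)
        bimodal = valley is not None
        if bimodal:
            switches = count_mode_switches(samples, valley)
        else:
            switches = 0
        rows.append(
            {
                "separation_myr": sep,
                "ks_distance": ks,
                "n_retained": len(samples),
                "bimodal": bimodal,
                "valley_age": valley if valley is not None else np.nan,
                "switch_count": switches,
                "switches_per_million_iterations": switches
                * 1e6 / cfg.iterations,
            }
        )
        densities[sep] = density
        traces[sep] = trace
    return BimodalityReport(pd.DataFrame(rows), densities, traces)


# ---------------------------------------------------------------------------
# Marker-filter fixtures with planted violations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerFixtureSpec:
    """Counts and planted violations for a synthetic exon metric table."""

    n_genes: int = 3
    exons_per_gene: int = 3
    n_species: int = 15
    bitscore_violations: int = 0   # sequences below 90% of the exon's best
    dnds_violations: int = 0       # sequences with dN/dS above 0.25
    missing_exon_violations: int = 0  # exons with > max_missing absent species

    def __post_init__(self):
        if min(self.n_genes, self.exons_per_gene, self.n_species) < 1:
            raise ValueError("counts must be >= 1")
        for f in ("bitscore_violations", "dnds_violations",
                  "missing_exon_violations"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def generate_marker_fixture(spec: MarkerFixtureSpec, seed: int,
                            max_missing: int = 10):
    """Exon table with exactly the planted violations, plus its expected report.

    Clean sequences carry bitscore 100 (so the 90% rule keeps them) and
    dN/dS 0.1.  Violations are planted in distinct exons so the cascade steps
    do not interact: a bitscore violation lowers one sequence to 80, a dN/dS
    violation raises one sequence to 0.4, and a missing-exon violation leaves
    an exon with too few species present.  The returned
    :class:`~cladecal.marker_filter.FilterReport` is what
    :func:`~cladecal.marker_filter.apply_sequence_filters` must produce on
    the table (the generators are self-verifying in the test suite).
    """
    rng = np.random.default_rng(seed)
    n_exons = spec.n_genes * spec.exons_per_gene
    n_violation_exons = (
        spec.bitscore_violations + spec.dnds_violations
        + spec.missing_exon_violations
    )
    if n_violation_exons > n_exons:
        raise ValueError(
            f"cannot plant {n_violation_exons} violations in {n_exons} exons "
            "(one violation per exon)"
        )
    present_at_missing = spec.n_species - max_missing - 1
    if present_at_missing < 1:
        raise ValueError(
            "n_species too small to express a missing-species violation"
        )
    exon_ids = [
        (f"g{g}", f"e{x}")
        for g in range(spec.n_genes)
        for x in range(spec.exons_per_gene)
    ]
    chosen = rng.permutation(n_exons)[:n_violation_exons]
    kinds = (
        ["bitscore"] * spec.bitscore_violations
        + ["dnds"] * spec.dnds_violations
        + ["missing"] * spec.missing_exon_violations
    )
    violation = {exon_ids[i]: kind for i, kind in zip(chosen, kinds)}
    rows = []
    species = [f"sp{i}" for i in range(spec.n_species)]
    for gene, exon in exon_ids:
        kind = violation.get((gene, exon))
        panel = species
        if kind == "missing":
            panel = list(rng.choice(species, present_at_missing, replace=False))
        victim = rng.choice(panel) if kind in ("bitscore", "dnds") else None
        for sp in panel:
            bitscore = 100.0
            dnds = 0.1
            if sp == victim and kind == "bitscore":
                bitscore = 80.0
            if sp == victim and kind == "dnds":
                dnds = 0.4
            rows.append(
                {
                    "gene": gene, "exon": exon, "species": sp,
                    "bitscore": bitscore, "bitscore_threshold": 50.0,
                    "dnds": dnds, "gc": 0.45, "present": True,
                    "length": 300, "ref_start": 0, "ref_end": 300,
                }
            )
    table = pd.DataFrame(rows)
    n_rows = len(table)
    expected = FilterReport()
    expected.add("relative_bitscore", "sequences", n_rows,
                 spec.bitscore_violations)
    expected.add("dnds", "sequences", n_rows - spec.bitscore_violations,
                 spec.dnds_violations)
    expected.add("missing_species", "exons", n_exons,
                 spec.missing_exon_violations)
    return table, expected
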