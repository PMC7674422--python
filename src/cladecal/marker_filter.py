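"""Deterministic ortholog / alignment / gene-set filter cascade.

The cascade consumes precomputed metric tables (TBLASTN bitscores, codeml
dN/dS, per-codon entropy scores, per-gene clock metrics) and applies the
selection rules in a fixed order, recording per-step removal counts in an
audit report.  External tool runs (TBLASTN, MAFFT, codeml, BMGE, tree
concordance tests) are out of scope: their outputs enter as table columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import SchemaError

__all__ = [
    "ExonAlignment",
    "FilterReport",
    "apply_sequence_filters",
    "apply_alignment_filters",
    "select_gene_sets",
    "EXON_TABLE_COLUMNS",
]

EXON_TABLE_COLUMNS = [
    "gene", "exon", "species", "bitscore", "bitscore_threshold",
    "dnds", "gc", "present", "length", "ref_start", "ref_end",
]

GENE_METRICS_COLUMNS = ["gene", "min_ess", "rate", "rate_cv"]


@dataclass
class FilterReport:
    """Ordered audit trail: (step, unit, before, removed, after) per step."""

    steps: list = field(default_factory=list)

    def add(self, name: str, unit: str, before: int, removed: int):
        after = before - removed
        self.steps.append(
            {"step": name, "unit": unit, "before": before,
             "removed": removed, "after": after}
        )
        return after

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "unit", "before", "removed", "after"]
        )

    def removed(self, step: str) -> int:
        for s in self.steps:
            if s["step"] == step:
                return s["removed"]
        raise KeyError(step)

    def __eq__(self, other):
        return isinstance(other, FilterReport) and self.steps == other.steps


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns {missing}")


def apply_sequence_filters(
    table: pd.DataFrame,
    relative_bitscore_fraction: float = 0.9,
    dnds_max: float = 0.25,
    max_missing: int = 10,
    n_species: Optional[int] = None,
):
    """Sequence-level ortholog filters on a per-(gene, exon, species) table.

    Steps, in order: (1) drop sequences whose bitscore is below
    ``relative_bitscore_fraction`` of the best bitscore any ingroup sequence
    achieved for the same exon; (2) drop sequences with dN/dS strictly above
    ``dnds_max`` (a sequence at exactly the threshold is retained); (3) drop
    whole exons with more than ``max_missing`` missing species.

    ``n_species`` is the size of the species panel used to count missing
    sequences; by default it is the number of distinct species in the table.
    Rows with ``present == False`` denote sequences absent from the start.
    """
    _require_columns(table, ["gene", "exon", "species", "bitscore", "dnds"],
                     "exon table")
    if table.empty:
        raise SchemaError("exon table is empty")
    if relative_bitscore_fraction <= 0 or dnds_max <= 0:
        raise ValueError("thresholds must be positive")
    if n_species is None:
        n_species = table["species"].nunique()
    report = FilterReport()
    df = table.copy()
    if "present" in df.columns:
        df = df[df["present"].astype(bool)]

    # (1) relative bitscore, per exon
    best = df.groupby(["gene", "exon"])["bitscore"].transform("max")
    keep = df["bitscore"] >= relative_bitscore_fraction * best
    report.add("relative_bitscore", "sequences", len(df), int((~keep).sum()))
    df = df[keep]

    # (2) dN/dS strictly greater than the threshold
    keep = ~(df["dnds"] > dnds_max)
    report.add("dnds", "sequences", len(df), int((~keep).sum()))
    df = df[keep]

    # (3) exons with too many missing species
    present_counts = df.groupby(["gene", "exon"])["species"].nunique()
    bad_exons = present_counts[n_species - present_counts > max_missing].index
    n_exons = len(present_counts)
    report.add("missing_species", "exons", n_exons, len(bad_exons))
    if len(bad_exons):
        idx = pd.MultiIndex.from_frame(df[["gene", "exon"]])
        df = df[~idx.isin(bad_exons)]
    return df.reset_index(drop=True), report


@dataclass
class ExonAlignment:
    """One exon alignment plus the metadata the cascade filters need."""

    gene: str
    exon: str
    taxa: list
    sequences: list
    ref_start: int = 0   # 0-based half-open position on the reference genome
    ref_end: int = 0
    codon_entropy: Optional[np.ndarray] = None  # smoothed score per codon

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"exon {self.gene}/{self.exon}: ragged alignment")
        if self.n_sites % 3 != 0:
            raise ValueError(
                f"exon {self.gene}/{self.exon}: length {self.n_sites} is not "
                "divisible by 3 (codon frame required)"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return self.n_sites // 3

    def site_matrix(self) -> np.ndarray:
        return np.array([list(s.upper()) for s in self.sequences])


def _missing_fraction_per_site(mat: np.ndarray) -> np.ndarray:
    return np.isin(mat, ["-", "N", "?"]).mean(axis=0)


def _gc_per_sequence(mat: np.ndarray) -> np.ndarray:
    counted = ~np.isin(mat, ["-", "N", "?"])
    gc = np.isin(mat, ["G", "C"])
    with np.errstate(invalid="ignore"):
        return gc.sum(axis=1) / np.maximum(counted.sum(axis=1), 1)


def apply_alignment_filters(
    alignments: Sequence[ExonAlignment],
    min_length: int = 150,
    missing_site_max: float = 0.20,
    entropy_max: float = 0.5,
    gc_sd_max: float = 0.04,
    min_exons: int = 3,
    max_exon_span: int = 100_000,
    concordant: Optional[dict] = None,
    manual_exclude: Optional[Sequence[str]] = None,
):
    """Alignment-level filter cascade over exon alignments.

    Steps, in order: (4) mask whole codons in which any site exceeds
    ``missing_site_max`` missing data or whose entropy-like score exceeds
    ``entropy_max``; (5) drop alignments shorter than ``min_length`` bp after
    masking; (6) drop alignments whose among-sequence SD in GC content
    exceeds ``gc_sd_max``; (7) drop all exons of genes with fewer than
    ``min_exons`` surviving exons or whose exons span more than
    ``max_exon_span`` bp on the reference genome; (8, optional) drop exons
    flagged discordant in ``concordant`` (a ``(gene, exon) -> bool`` map)
    and re-apply the ``min_exons`` rule; (9, optional) drop genes listed in
    ``manual_exclude``.

    Returns ``(surviving alignments, codon masks, FilterReport)``; masked
    alignments keep whole codon triplets only.
    """
    report = FilterReport()
    masks = {}
    masked = []
    total_codons = sum(a.n_codons for a in alignments)
    removed_codons = 0
    for aln in alignments:
        mat = aln.site_matrix()
        miss = _missing_fraction_per_site(mat).reshape(-1, 3)
        bad = (miss > missing_site_max).any(axis=1)
        if aln.codon_entropy is not None:
            ent = np.asarray(aln.codon_entropy, dtype=float)
            if len(ent) != aln.n_codons:
                raise ValueError(
                    f"exon {aln.gene}/{aln.exon}: entropy scores per codon "
                    f"({len(ent)}) do not match codon count ({aln.n_codons})"
                )
            bad |= ent > entropy_max
        removed_codons += int(bad.sum())
        keep_sites = np.repeat(~bad, 3)
        masks[(aln.gene, aln.exon)] = ~bad
        masked.append(
            ExonAlignment(
                aln.gene, aln.exon, list(aln.taxa),
                ["".join(np.array(list(s))[keep_sites]) for s in aln.sequences],
                aln.ref_start, aln.ref_end,
                None if aln.codon_entropy is None
                else np.asarray(aln.codon_entropy)[~bad],
            )
        )
    report.add("codon_mask", "codons", total_codons, removed_codons)

    # (5) length after masking
    n = len(masked)
    survivors = [a for a in masked if a.n_sites >= min_length]
    report.add("min_length", "alignments", n, n - len(survivors))

    # (6) among-sequence GC standard deviation
    n = len(survivors)
    kept = []
    for aln in survivors:
        gc = _gc_per_sequence(aln.site_matrix())
        if np.std(gc, ddof=1) <= gc_sd_max:
            kept.append(aln)
    report.add("gc_sd", "alignments", n, n - len(kept))
    survivors = kept

    # (7) gene structure: exon count and reference span
    n = len(survivors)
    by_gene = {}
    for aln in survivors:
        by_gene.setdefault(aln.gene, []).append(aln)
    good_genes = set()
    for gene, alns in by_gene.items():
        span = max(a.ref_end for a in alns) - min(a.ref_start for a in alns)
        if len(alns) >= min_exons and span <= max_exon_span:
            good_genes.add(gene)
    survivors = [a for a in survivors if a.gene in good_genes]
    report.add("gene_structure", "exons", n, n - len(survivors))

    # (8) concordance (consumed as a boolean table, not recomputed)
    if concordant is not None:
        n = len(survivors)
        survivors = [
            a for a in survivors if concordant.get((a.gene, a.exon), True)
        ]
        counts = {}
        for a in survivors:
            counts[a.gene] = counts.get(a.gene, 0) + 1
        survivors = [a for a in survivors if counts[a.gene] >= min_exons]
        report.add("concordance", "exons", n, n - len(survivors))

    # (9) manual visual-check exclusions
    if manual_exclude is not None:
        n = len(survivors)
        excl = set(manual_exclude)
        survivors = [a for a in survivors if a.gene not in excl]
        report.add("manual_exclusion", "exons", n, n - len(survivors))

    return survivors, masks, report


def select_gene_sets(metrics: pd.DataFrame) -> dict:
    """Permissive and strict gene sets from per-gene clock metrics.

    permissive: minimum ESS > 100, substitution rate < 1.6e-9 per year and
    site, coefficient of rate variation < 0.7.  strict: ESS > 200,
    rate < 1.4e-9, CV < 0.6.  The strict set is a subset of the permissive
    set by construction.
    """
    _require_columns(metrics, GENE_METRICS_COLUMNS, "gene metrics table")
    permissive = metrics[
        (metrics["min_ess"] > 100)
        & (metrics["rate"] < 1.6e-9)
        & (metrics["rate_cv"] < 0.7)
    ]["gene"]
    strict = metrics[
        (metrics["min_ess"] > 200)
        & (metrics["rate"] < 1.4e-9)
        & (metrics["rate_cv"] < 0.6)
    ]["gene"]
    return {"permissive": set(permissive), "strict": set(strict)}
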