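"""Readers and writers: trees, constraint configurations, densities, traces.

All text outputs carry a provenance header (tool version, seed, config hash)
as ``#``-prefixed comment lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import pandas as pd
import yaml

from . import __version__
from ._errors import InvalidWeightsError, SchemaError
from .bd_process import BDParams
from .calibration import CalibrationDensity, CladeConstraint, FossilRecord
from .trees import TimeTree

__all__ = [
    "read_tree",
    "write_tree",
    "read_constraints",
    "write_density_tsv",
    "read_density_tsv",
    "write_trace_tsv",
    "provenance_header",
]


def provenance_header(seed=None, config=None) -> str:
    lines = [f"# cladecal {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_hash: {digest}")
    return "\n".join(lines) + "\n"


def read_tree(path, schema: str = "newick") -> TimeTree:
    """Read a rooted binary ultrametric time tree (Newick or NEXUS).

    Node labels are allowed and square-bracket comments are ignored (both
    dropped); branch lengths are Myr durations, so node ages follow from the
    tip-down depths.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError("schema must be 'newick' or 'nexus'")
    tree = dendropy.Tree.get(
        path=str(path), schema=schema, rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    return TimeTree.from_dendropy(tree)


def write_tree(tree: TimeTree, path, schema: str = "newick"):
    if schema not in ("newick", "nexus"):
        raise ValueError("schema must be 'newick' or 'nexus'")
    tree.to_dendropy().write(
        path=str(path), schema=schema,
        suppress_rooting=(schema == "newick"),
    )


def _fossil_from_mapping(m, clade_label):
    try:
        return FossilRecord(
            name=str(m["name"]),
            age_min=float(m["age_min"]),
            age_max=float(m["age_max"]),
            weight=float(m.get("weight", 1.0)),
        )
    except KeyError as e:
        raise SchemaError(
            f"clade {clade_label!r}: fossil entry missing key {e}"
        ) from None


def read_constraints(path):
    """Read a constraint configuration file (YAML or JSON).

    Layout::

        bd:
          net_diversification: [0.041, 0.081]   # or a single number
          turnover: [0.0011, 0.37]
          sampling_rate: [0.0066, 0.01806]
        clades:
          - label: Tetraodontiformes
            tips: [takifugu, mola]
            fossils:
              - {name: Cretatriacanthus, age_min: 83.0, age_max: 89.8, weight: 0.667}
              - {name: Plectocretacicus, age_min: 98.0, age_max: 100.3, weight: 0.333}

    Returns ``(constraints, bd)`` where ``bd`` is ``None`` when the file has
    no parameter block.  Per clade, one fossil defaults to weight 1; two
    fossils must have weights summing to 1; more than two are rejected (the
    mixture model is explicitly a two-fossil model).
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or "clades" not in cfg:
        raise SchemaError("constraint file needs a top-level 'clades' list")
    bd = None
    if "bd" in cfg:
        block = cfg["bd"]
        try:
            bd = BDParams(
                net_diversification=block["net_diversification"],
                turnover=block["turnover"],
                sampling_rate=block["sampling_rate"],
            )
        except KeyError as e:
            raise SchemaError(f"bd block missing key {e}") from None
    constraints = []
    for entry in cfg["clades"]:
        label = str(entry.get("label", f"clade{len(constraints)}"))
        if "tips" not in entry or not entry["tips"]:
            raise SchemaError(f"clade {label!r} has no tip set")
        fossils = entry.get("fossils", [])
        if len(fossils) > 2:
            raise InvalidWeightsError(
                f"clade {label!r} lists {len(fossils)} fossils; the mixture "
                "model supports at most two candidate first records"
            )
        records = tuple(_fossil_from_mapping(f, label) for f in fossils)
        try:
            constraints.append(
                CladeConstraint(label, frozenset(entry["tips"]), records)
            )
        except InvalidWeightsError as e:
            raise InvalidWeightsError(f"clade {label!r}: {e}") from None
    return constraints, bd


def write_density_tsv(density: CalibrationDensity, path, seed=None, config=None):
    """Two-column (age, density) TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        fh.write("age\tdensity\n")
        for a, f in density.to_table():
            fh.write(f"{a:.10g}\t{f:.10g}\n")


def read_density_tsv(path) -> CalibrationDensity:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"age", "density"} <= set(df.columns):
        raise SchemaError("density TSV needs 'age' and 'density' columns")
    return CalibrationDensity(
        df["age"].to_numpy(), df["density"].to_numpy()
    )


def write_trace_tsv(trace, path, seed=None, config=None):
    """Tab-separated trace (iteration, log posterior, node ages...)."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        trace.data.to_csv(fh, sep="\t", index=False)


def read_trace_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
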