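"""Readers and writers for the plain-text formats of the pipeline.

All tables are delimited text with explicit headers (TSV, or CSV for
peak lists by extension); networks additionally export GraphML.  Readers
validate against the type invariants of the objects they build and
report malformed rows with line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .association import AssociationNetwork
from .chemodiversity import (
    ClassBoundaries,
    DOMProfile,
    TurnoverSets,
    WeightedSummary,
    normalize_intensities,
)
from .community import OTUTable
from .errors import DuplicateIdError, SchemaError, ValidationError
from .formula import (
    AssignedPeak,
    MolecularFormula,
    Peak,
    dbe,
    monoisotopic_mass,
    theoretical_mz,
)

__all__ = [
    "read_peaks",
    "read_otu_table",
    "read_boundaries",
    "read_newick",
    "read_profile_table",
    "write_assignments",
    "read_assignments",
    "write_summary_table",
    "write_composition_table",
    "write_turnover_table",
    "write_network",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_peaks(path) -> list[Peak]:
    """Read a peak list (columns ``mz``, ``intensity``; extras ignored).

    Delimiter is auto-detected from the extension (.tsv/.txt tab,
    otherwise comma).  Non-numeric rows are reported with their
    1-based file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in ("mz", "intensity") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    bad_lines = []
    for col in ("mz", "intensity"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] + 2  # header + 1-based
        bad_lines.extend(int(i) for i in bad)
        df[col] = coerced
    if bad_lines:
        raise SchemaError(f"{path}: non-numeric mz/intensity at line(s) {sorted(set(bad_lines))}")
    if df[["mz", "intensity"]].isna().any().any():
        bad = (df.index[df[["mz", "intensity"]].isna().any(axis=1)] + 2).tolist()
        raise SchemaError(f"{path}: empty mz/intensity at line(s) {bad}")
    return [Peak(mz=float(r.mz), intensity=float(r.intensity)) for r in df.itertuples()]


def read_otu_table(path, tree_path=None) -> OTUTable:
    """Read a TSV OTU table: first column ``otu_id``, optional trailing
    ``taxonomy`` column, remaining columns are samples."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "otu_id":
        raise SchemaError(f"{path}: first column must be 'otu_id', got {df.columns[0]!r}")
    if df["otu_id"].duplicated().any():
        dups = df["otu_id"][df["otu_id"].duplicated()].unique().tolist()
        raise DuplicateIdError(f"{path}: duplicate otu_id values: {dups}")
    df = df.set_index("otu_id")
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"].astype(str)
        df = df.drop(columns=["taxonomy"])
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad = (np.flatnonzero(coerced.isna().to_numpy()) + 2).tolist()
            raise SchemaError(f"{path}: non-numeric counts in sample {col!r} at line(s) {bad}")
        df[col] = coerced
    tree = read_newick(tree_path) if tree_path is not None else None
    return OTUTable(counts=df, taxonomy=taxonomy, tree=tree)


def read_boundaries(path) -> ClassBoundaries:
    """Read class rectangles from TSV (label, hc_min, hc_max, oc_min,
    oc_max; precedence = row order) or from a YAML list of the same."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        rows = tuple(
            (str(r["label"]), float(r["hc_min"]), float(r["hc_max"]),
             float(r["oc_min"]), float(r["oc_max"]))
            for r in data
        )
        return ClassBoundaries(rows=rows)
    df = pd.read_csv(path, sep="\t")
    needed = ["label", "hc_min", "hc_max", "oc_min", "oc_max"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    rows = tuple(
        (str(r.label), float(r.hc_min), float(r.hc_max), float(r.oc_min), float(r.oc_max))
        for r in df.itertuples()
    )
    return ClassBoundaries(rows=rows)


def read_newick(path) -> TreeNode:
    """Read a Newick phylogeny."""
    return TreeNode.read(str(path), format="newick")


def read_profile_table(path) -> dict[str, DOMProfile]:
    """Read a pre-assigned formula table (columns formula, intensity,
    sample_id, optional group) into per-sample profiles."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    needed = ["formula", "intensity", "sample_id"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out: dict[str, DOMProfile] = {}
    for sid, sub in df.groupby("sample_id", sort=True):
        group = str(sub["group"].iloc[0]) if "group" in sub.columns else None
        records = [
            (MolecularFormula.from_string(str(r.formula)), float(r.intensity))
            for r in sub.itertuples()
        ]
        out[str(sid)] = normalize_intensities(records, sample_id=str(sid), group=group)
    return out


# -- writers ----------------------------------------------------------------


def assignments_frame(
    assigned: Sequence[AssignedPeak], unassigned: Sequence[Peak] = ()
) -> pd.DataFrame:
    """Assignment table: one row per peak, formula columns empty for
    unassigned peaks."""
    rows = []
    for ap in assigned:
        f = ap.formula
        rows.append(
            {
                "mz": ap.peak.mz,
                "intensity": ap.peak.intensity,
                "formula": f.hill(),
                "c": f.c, "h": f.h, "n": f.n, "o": f.o, "s": f.s,
                "neutral_mass": monoisotopic_mass(f),
                "error_ppm": ap.error_ppm,
                "hc": f.hc, "oc": f.oc, "dbe": dbe(f),
            }
        )
    for p in unassigned:
        rows.append({"mz": p.mz, "intensity": p.intensity, "formula": ""})
    df = pd.DataFrame(
        rows,
        columns=["mz", "intensity", "formula", "c", "h", "n", "o", "s",
                 "neutral_mass", "error_ppm", "hc", "oc", "dbe"],
    )
    return df.sort_values("mz", kind="stable").reset_index(drop=True)


def write_assignments(path, assigned, unassigned=()) -> None:
    assignments_frame(assigned, unassigned).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> tuple[list[AssignedPeak], list[Peak]]:
    """Round-trip reader for :func:`write_assignments` output."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    assigned, unassigned = [], []
    for r in df.itertuples():
        peak = Peak(mz=float(r.mz), intensity=float(r.intensity))
        if isinstance(r.formula, str) and r.formula:
            assigned.append(
                AssignedPeak(
                    peak=peak,
                    formula=MolecularFormula.from_string(r.formula),
                    error_ppm=float(r.error_ppm),
                )
            )
        else:
            unassigned.append(peak)
    return assigned, unassigned


def summary_frame(summaries: dict[str, WeightedSummary],
                  groups: dict[str, str] | None = None) -> pd.DataFrame:
    rows = {}
    for sid, ws in summaries.items():
        rows[sid] = {
            "group": (groups or {}).get(sid, ""),
            "oc_wa": ws.oc_wa, "hc_wa": ws.hc_wa, "dbe_wa": ws.dbe_wa,
            "mz_wa": ws.mz_wa, "shannon": ws.shannon, "pielou": ws.pielou,
            "richness": ws.richness,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def write_summary_table(path, summaries, groups=None) -> None:
    df = summary_frame(summaries, groups)
    path = Path(path)
    df.to_csv(path, sep="\t")
    path.with_suffix(".json").write_text(
        json.dumps(df.reset_index().to_dict(orient="records"), indent=2, default=float)
    )


def write_composition_table(path, compositions: dict[str, dict[str, float]]) -> None:
    pd.DataFrame.from_dict(compositions, orient="index").rename_axis("sample_id").to_csv(
        path, sep="\t"
    )


def write_turnover_table(path, turnover: TurnoverSets) -> None:
    rows = (
        [(f.hill(), "disappeared") for f in sorted(turnover.disappeared, key=lambda f: f.hill())]
        + [(f.hill(), "unchanged") for f in sorted(turnover.unchanged, key=lambda f: f.hill())]
        + [(f.hill(), "new") for f in sorted(turnover.new, key=lambda f: f.hill())]
    )
    pd.DataFrame(rows, columns=["formula", "status"]).to_csv(path, sep="\t", index=False)


def write_network(prefix, network: AssociationNetwork) -> None:
    """Write ``<prefix>_edges.tsv``, ``<prefix>.graphml`` and
    ``<prefix>_summary.json``."""
    prefix = Path(prefix)
    network.edges.to_csv(prefix.with_name(prefix.name + "_edges.tsv"), sep="\t", index=False)
    network.write_graphml(str(prefix.with_suffix(".graphml")))
    summary = dict(network.summary)
    summary.update(
        {"top_n_dom": network.top_n_dom, "top_n_otu": network.top_n_otu,
         "alpha": network.alpha, "fdr": network.fdr}
    )
    prefix.with_name(prefix.name + "_summary.json").write_text(json.dumps(summary, indent=2))
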