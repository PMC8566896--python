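"""End-to-end pipeline driver and the simulate-to-disk writer.

``run_pipeline`` composes the analysis stages on a directory of
per-sample peak lists plus an OTU table:

assign -> summarize -> classify -> compare (each older age group vs the
youngest) -> alphadiv -> network -> mantel

and writes plain-text outputs, a verbatim config echo and a
machine-readable run manifest.  With fixed inputs and seeds a rerun is
bit-identical for every deterministic stage (permutation tests are
seeded, so in practice for all of them).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import build_network, distance_matrix, mantel, partial_mantel
from .chemodiversity import (
    DEFAULT_BOUNDARIES,
    ClassBoundaries,
    DOMProfile,
    class_composition,
    compare_samples,
    normalize_intensities,
    summarize,
)
from .community import alpha_diversity_table, relative_abundance
from .errors import DomChemodivError, ValidationError
from .formula import AssignmentConfig, assign_peaks
from .io import (
    read_boundaries,
    read_otu_table,
    read_peaks,
    write_assignments,
    write_composition_table,
    write_network,
    write_summary_table,
    write_turnover_table,
)
from .synthetic import SyntheticDataset

__all__ = ["PipelineConfig", "run_pipeline", "write_simulation"]

logger = logging.getLogger(__name__)

STAGES = ("assign", "summarize", "classify", "compare", "alphadiv", "network", "mantel")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one full run needs.

    ``input_dir`` must contain ``samples.tsv`` (columns sample_id, group,
    peaks_path relative to the directory) and ``otu_table.tsv`` — the
    layout :func:`write_simulation` produces.
    """

    input_dir: str
    out_dir: str
    assignment: AssignmentConfig = AssignmentConfig()
    boundaries_path: str | None = None
    top_n_dom: int = 100
    top_n_otu: int = 100
    alpha: float = 0.01
    fdr: bool = False
    mantel_metric: str = "bray_curtis"
    n_perm: int = 999
    seed: int = 0
    control_path: str | None = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["assignment"] = dataclasses.asdict(self.assignment)
        return d


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # hash identifies the analysis, not its destination
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a result dict and writes the output
    bundle (tables, config echo, manifest) under ``config.out_dir``.

    Any stage failure aborts with the stage name and cause.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    samples_file = indir / "samples.tsv"
    otu_file = indir / "otu_table.tsv"
    for p in (samples_file, otu_file):
        if not p.exists():
            raise ValidationError(f"required input {p} not found")
    samples = pd.read_csv(samples_file, sep="\t", dtype=str)
    for col in ("sample_id", "group", "peaks_path"):
        if col not in samples.columns:
            raise ValidationError(f"{samples_file}: missing column {col!r}")

    boundaries = (
        read_boundaries(config.boundaries_path)
        if config.boundaries_path
        else DEFAULT_BOUNDARIES
    )
    (outdir / "config_echo.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    completed: list[str] = []
    results: dict = {}
    stage = "assign"
    try:
        t0 = time.perf_counter()
        profiles: dict[str, DOMProfile] = {}
        groups: dict[str, str] = {}
        for row in samples.itertuples(index=False):
            peaks = read_peaks(indir / row.peaks_path)
            assigned, unassigned = assign_peaks(peaks, config.assignment)
            write_assignments(outdir / f"assignments_{row.sample_id}.tsv", assigned, unassigned)
            profiles[row.sample_id] = DOMProfile.from_assigned_peaks(
                row.sample_id, assigned, group=row.group
            )
            groups[row.sample_id] = row.group
        results["profiles"] = profiles
        completed.append(stage)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "summarize"
        t0 = time.perf_counter()
        summaries = {sid: summarize(p) for sid, p in profiles.items()}
        write_summary_table(outdir / "dom_summary.tsv", summaries, groups)
        results["summaries"] = summaries
        completed.append(stage)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "classify"
        t0 = time.perf_counter()
        comps = {sid: class_composition(p, boundaries) for sid, p in profiles.items()}
        write_composition_table(outdir / "class_composition.tsv", comps)
        results["compositions"] = comps
        completed.append(stage)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "compare"
        t0 = time.perf_counter()
        group_order = list(dict.fromkeys(samples["group"]))
        merged: dict[str, DOMProfile] = {}
        for g in group_order:
            records: list = []
            for sid, p in profiles.items():
                if groups[sid] == g:
                    records.extend(zip(p.formulas, p.intensity))
            merged[g] = normalize_intensities(records, sample_id=f"group_{g}", group=g)
        reference = group_order[0]
        turnover = {}
        for g in group_order[1:]:
            ts = compare_samples(merged[reference], merged[g])
            write_turnover_table(outdir / f"turnover_{reference}_vs_{g}.tsv", ts)
            turnover[g] = ts
        results["turnover"] = turnover
        completed.append(stage)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "alphadiv"
        t0 = time.perf_counter()
        otu = read_otu_table(otu_file)
        alpha = alpha_diversity_table(otu)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
        results["alpha"] = alpha
        completed.append(stage)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "network"
        t0 = time.perf_counter()
        dom_matrix = pd.DataFrame(
            {sid: pd.Series(p.weight, index=[f.hill() for f in p.formulas])
             for sid, p in profiles.items()}
        ).fillna(0.0)
        otu_rel = relative_abundance(otu)
        common = [s for s in dom_matrix.columns if s in otu_rel.columns]
        net = build_network(
            dom_matrix[common],
            otu_rel[common],
            top_n_dom=config.top_n_dom,
            top_n_otu=config.top_n_otu,
            alpha=config.alpha,
            fdr=config.fdr,
        )
        write_network(outdir / "network", net)
        results["network"] = net
        completed.append(stage)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "mantel"
        t0 = time.perf_counter()
        d_dom = distance_matrix(dom_matrix[common], metric=config.mantel_metric)
        d_otu = distance_matrix(otu_rel[common], metric=config.mantel_metric)
        if config.control_path:
            env = pd.read_csv(config.control_path, sep="\t", index_col=0)
            d_env = distance_matrix(env[common], metric="euclidean")
            mres = partial_mantel(
                d_otu, d_dom, d_env, n_perm=config.n_perm, seed=config.seed,
                controlled="environment",
            )
        else:
            mres = mantel(d_otu, d_dom, n_perm=config.n_perm, seed=config.seed)
        (outdir / "mantel.json").write_text(
            json.dumps(
                {"r": mres.r, "p": mres.p, "n_perm": mres.n_perm,
                 "controlled": mres.controlled, "metric": config.mantel_metric},
                indent=2,
            )
        )
        results["mantel"] = mres
        completed.append(stage)
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    except DomChemodivError as exc:
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "stages_completed": completed,
            "failed_stage": stage,
            "error": str(exc),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise DomChemodivError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages_completed": completed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results


def write_simulation(dataset: SyntheticDataset, out_dir) -> None:
    """Write a synthetic dataset in the on-disk layout ``run_pipeline``
    consumes: per-sample peak CSVs, ground-truth TSVs, the OTU table,
    the planted-link ledger and a design echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in dataset.dom.sample_ids:
        peaks_name = f"peaks_{sid}.csv"
        dataset.dom.peaks[sid].to_csv(out / peaks_name, index=False)
        dataset.dom.truth[sid].to_csv(out / f"truth_{sid}.tsv", sep="\t", index=False)
        rows.append(
            {"sample_id": sid, "group": dataset.dom.sample_groups[sid],
             "peaks_path": peaks_name}
        )
    pd.DataFrame(rows).to_csv(out / "samples.tsv", sep="\t", index=False)
    counts = dataset.otu.counts.copy()
    if dataset.otu.taxonomy is not None:
        counts = counts.assign(taxonomy=dataset.otu.taxonomy)
    counts.rename_axis("otu_id").to_csv(out / "otu_table.tsv", sep="\t")
    dataset.planted.to_csv(out / "planted_links.tsv", sep="\t", index=False)
    design = dataclasses.asdict(dataset.design)
    design["planted_links"] = [list(t) for t in dataset.design.planted_links]
    (out / "design.yaml").write_text(yaml.safe_dump(design, sort_keys=True))
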