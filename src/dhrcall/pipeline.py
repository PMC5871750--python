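"""Pipeline orchestration: simulate and run stages with deterministic outputs.

Sample grouping is supplied by a manifest TSV (sample_id, path, group,
individual) rather than filename conventions.  Every output file carries a
header comment echoing the parameters that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import associate_genes, read_genes, summarize_annotation, write_annotation
from .differential import DifferentialResult, run_differential
from .genome import (
    FragmentSet,
    GenomeLayout,
    WindowCountMatrix,
    build_count_matrix,
    make_windows,
)
from .simulate import SimulationSpec, simulate_fragments, simulate_truth, write_truth
from .sites import (
    AnalysisParams,
    SiteSet,
    call_conserved_sites,
    call_dhrs,
    call_individual_sites,
    intersect_core_sites,
    qualifying_windows,
    sweep_dhr_thresholds,
    window_venn,
)

__all__ = ["cmd_simulate", "cmd_run", "load_params", "load_simulation_spec", "read_manifest"]

log = logging.getLogger("dhrcall")

DEFAULT_SWEEP = (1e-4, 1e-5, 1e-6, 1e-7, 1e-8)


def _params_echo(params: AnalysisParams) -> str:
    return "dhrcall params: " + " ".join(
        f"{k}={v}" for k, v in dataclasses.asdict(params).items()
    )


def load_params(path: str | Path | None, **overrides) -> AnalysisParams:
    """AnalysisParams from an optional YAML file, with flag overrides winning."""
    values = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(AnalysisParams)}
        values.update({k: v for k, v in loaded.items() if k in known})
    values.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisParams(**values)


def load_simulation_spec(path: str | Path | None, **overrides) -> SimulationSpec:
    values = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(SimulationSpec)}
        for k, v in loaded.items():
            if k in known:
                if k in ("fragment_length", "exposure_groups") and isinstance(v, list):
                    v = tuple(v)
                values[k] = v
    values.update({k: v for k, v in overrides.items() if v is not None})
    return SimulationSpec(**values)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def cmd_simulate(outdir: str | Path, spec: SimulationSpec) -> dict:
    """Generate chrom.sizes, truth BEDs, per-sample fragment BEDs, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = spec.layout
    layout.to_chrom_sizes(outdir / "chrom.sizes")
    truth = simulate_truth(spec)
    write_truth(truth, outdir)
    frags = simulate_fragments(truth, spec)
    rows = []
    for sample_id, group in spec.sample_ids():
        path = outdir / f"{sample_id}.bed"
        frags[sample_id].to_bed(path)
        rows.append((sample_id, path.name, group, sample_id))
        log.info("simulated %s (%s): %d fragments", sample_id, group, len(frags[sample_id]))
    manifest = pd.DataFrame(rows, columns=["sample_id", "path", "group", "individual"])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return {"outdir": outdir, "truth": truth, "manifest": manifest}


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path", "group"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return manifest


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def cmd_run(
    chrom_sizes: str | Path,
    manifest_path: str | Path,
    outdir: str | Path,
    params: AnalysisParams | None = None,
    genes_path: str | Path | None = None,
    control_group: str = "control",
    exposure_group: str = "exposure",
    phi: float | None = None,
    sweep_thresholds: Sequence[float] = DEFAULT_SWEEP,
    count_mode: str = "overlap",
) -> dict:
    """Full analysis: count, test, call sites, sweep, Venn, annotate.

    Returns the in-memory results; writes every artifact under ``outdir``.
    """
    params = params or AnalysisParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    echo = _params_echo(params)

    layout = GenomeLayout.from_chrom_sizes(chrom_sizes)
    tiling = make_windows(layout, params.window_size)
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    frag_sets = []
    groups = {}
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        frag_sets.append(FragmentSet.from_bed(p, sample_id=row["sample_id"]))
        groups[row["sample_id"]] = row["group"]
        log.info("loaded %s: %d fragments", row["sample_id"], len(frag_sets[-1]))

    matrix = build_count_matrix(tiling, frag_sets, groups, mode=count_mode)
    matrix.to_tsv(outdir / "window_counts.tsv", header_comment=echo)
    for sid, total in matrix.library_sizes().items():
        if total == 0:
            log.warning("sample %s has zero counted fragments", sid)

    diff = run_differential(
        matrix, control_group=control_group, exposure_group=exposure_group, phi=phi
    )
    log.info("common dispersion phi = %.5f", diff.phi)
    diff.to_tsv(outdir / "differential.tsv", header_comment=f"{echo} phi={diff.phi:.6g}")

    dhrs = call_dhrs(diff, params)
    dhrs.to_bed(outdir / "dhrs.bed", header_comment=echo)
    dhrs.to_tsv(outdir / "dhrs.tsv", header_comment=echo)
    log.info("called %d DHRs at p < %g", len(dhrs), params.dhr_p_threshold)

    sweep = sweep_dhr_thresholds(diff, list(sweep_thresholds), params)
    sweep.to_csv(outdir / "dhr_threshold_sweep.tsv", sep="\t", index=False)

    conserved = {}
    for group in (control_group, exposure_group):
        cs = call_conserved_sites(matrix, group, params)
        cs.to_bed(outdir / f"conserved_{group}.bed", header_comment=echo)
        conserved[group] = cs
        log.info("group %s: %d conserved sites at depth >= %d", group, len(cs), params.depth_threshold)
    core = intersect_core_sites(
        [conserved[control_group], conserved[exposure_group]], representative=control_group
    )
    core.to_bed(outdir / "core_sites.bed", header_comment=echo)

    sample_ids = matrix.sample_ids[:7]
    venn = window_venn(
        [qualifying_windows(matrix, sid, params.depth_threshold) for sid in sample_ids],
        labels=sample_ids,
    )
    venn_rows = [(k, v) for k, v in venn["region_counts"].items()]
    venn_rows += [
        ("union", venn["union"]),
        ("intersection", venn["intersection"]),
        ("fraction_common", venn["fraction_common"]),
    ]
    pd.DataFrame(venn_rows, columns=["region", "count"]).to_csv(
        outdir / "window_venn.tsv", sep="\t", index=False
    )

    annotation_summary = None
    if genes_path is not None:
        genes = read_genes(genes_path)
        ann = associate_genes(dhrs, genes, params.gene_dist, known_chroms=layout.names)
        write_annotation(ann, outdir / "dhr_genes.tsv", header_comment=echo)
        annotation_summary = summarize_annotation(dhrs, ann)
        ann_core = associate_genes(core, genes, params.gene_dist, known_chroms=layout.names)
        write_annotation(ann_core, outdir / "core_genes.tsv", header_comment=echo)

    return {
        "matrix": matrix,
        "differential": diff,
        "dhrs": dhrs,
        "sweep": sweep,
        "conserved": conserved,
        "core": core,
        "venn": venn,
        "annotation_summary": annotation_summary,
    }
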