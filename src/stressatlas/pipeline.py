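"""Run-directory pipeline stages.

Each stage reads the plain-text outputs of earlier stages from a run
directory and writes its own tables there, so the whole analysis can be
driven file-by-file from the command line or from scripts.  Layout:

    run/
      expression.tsv, samples.tsv        (simulate)
      de/<condition>_vs_<batch>.tsv      (simulate)
      mercator.txt, tfs.tsv              (simulate)
      families_a.tsv, families_b.tsv, reference_edges.tsv, truth.json
      degsets.json                       (degs)
      metrics.tsv                        (metrics)
      bins.tsv, bin_classes.tsv, robust_bins.tsv      (pathways)
      models.tsv, union_edges.tsv, hc_grn.tsv, quality_curve.tsv  (grn)
      robust_tfs.tsv, tfrn_edges.tsv, cutoff.json, tf_bin_links.tsv  (tfrn)
      compare.json                       (compare)
      cells.tsv, global_fit.json, per_stress_fits.tsv, ranking.txt  (additivity)
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import additivity as addmod
from . import compare as cmpmod
from . import degs as degmod
from . import grn as grnmod
from . import pathways as pathmod
from . import set_metrics as metmod
from . import tfrn as tfrnmod
from .design import make_design
from .io import (
    read_de_table,
    read_degsets,
    read_edge_list,
    read_expression,
    read_family_map,
    read_mercator,
    read_tf_table,
    write_de_table,
    write_degsets,
    write_edge_list,
    write_expression,
    write_family_map,
    write_json,
    write_tf_table,
)
from .synthetic import (
    generate_bundle,
    plant_module_bins,
    plant_orthology,
    plant_reference_network,
)

log = logging.getLogger("stressatlas")


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.1fs", stage, time.perf_counter() - self.t0)

    return _Timer()


def _de_path(run: Path, cond: str, batch: str) -> Path:
    return run / "de" / f"{cond}_vs_{batch}.tsv"


def load_de_tables(run: Path) -> dict[tuple[str, str], pd.DataFrame]:
    out = {}
    for path in sorted((run / "de").glob("*_vs_*.tsv")):
        cond, batch = path.stem.rsplit("_vs_", 1)
        out[(cond, batch)] = read_de_table(path, strip_isoform_suffix=False)
    return out


def stage_simulate(run: Path, seed: int = 1, **generator_kwargs) -> None:
    """Generate a synthetic atlas and write the full input bundle."""
    run = Path(run)
    (run / "de").mkdir(parents=True, exist_ok=True)
    with _timed("simulate"):
        design, truth, lfc, matrix, de_tables = generate_bundle(seed=seed, **generator_kwargs)
        write_expression(matrix, run / "expression.tsv", run / "samples.tsv")
        for (cond, batch), df in de_tables.items():
            write_de_table(df, _de_path(run, cond, batch))
        # functional bins aligned with the planted regulatory modules, so
        # pathway activity has real signal to find
        ann = plant_module_bins(truth)
        _write_mercator(ann, run / "mercator.txt")
        write_tf_table(ann, run / "tfs.tsv")
        fam_a, fam_b = plant_orthology(truth)
        write_family_map(fam_a, run / "families_a.tsv")
        write_family_map(fam_b, run / "families_b.tsv")
        ref = plant_reference_network(truth, fam_a, fam_b, n_noise_edges=len(truth.grn_edges) // 2)
        write_edge_list(ref, run / "reference_edges.tsv")
        write_json(
            {
                "seed": truth.seed,
                "noise_sd": truth.noise_sd,
                "n_tfs": len(truth.tfs),
                "n_genes": len(truth.genes),
                "edges": [list(e) for e in truth.grn_edges],
                "tf_activation": truth.tf_activation,
                "additivity_params": {k: list(v) for k, v in truth.additivity_params.items()},
                "log2fc": {c: [float(v) for v in vec] for c, vec in lfc.items()},
            },
            run / "truth.json",
        )


def _write_mercator(ann, path: Path) -> None:
    rows = ["\t".join(f"'{c}'" for c in ("BINCODE", "NAME", "IDENTIFIER", "DESCRIPTION", "TYPE"))]
    for gene in sorted(ann.gene_to_bins):
        for b in sorted(ann.gene_to_bins[gene]):
            rows.append("\t".join(f"'{v}'" for v in (b, f"bin.{b}", gene.lower(), "", "T")))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def stage_degs(run: Path, padj_max: float = 0.05, lfc_min: float = 1.0) -> None:
    run = Path(run)
    with _timed("degs"):
        design = make_design()
        de_tables = load_de_tables(run)
        degsets = degmod.consolidate_de_tables(
            de_tables, design.stress_conditions, padj_max, lfc_min
        )
        write_degsets(degsets, run / "degsets.json")


def stage_metrics(run: Path) -> None:
    run = Path(run)
    with _timed("metrics"):
        design = make_design()
        degsets = read_degsets(run / "degsets.json")
        table = metmod.all_pair_metrics(degsets, design.combined_codes)
        table.to_csv(run / "metrics.tsv", sep="\t", index=False)


def stage_pathways(run: Path, n_perm: int = 1000, seed: int = 0, alpha: float = 0.05) -> None:
    run = Path(run)
    with _timed("pathways"):
        design = make_design()
        degsets = read_degsets(run / "degsets.json")
        ann = read_mercator(run / "mercator.txt", strip_isoform_suffix=False)
        expr = read_expression(
            run / "expression.tsv", run / "samples.tsv", strip_isoform_suffix=False
        )
        universe = set(expr.genes) & set(ann.gene_to_bins)
        enriched = []
        classified = {}
        for i, cond in enumerate(design.stress_conditions):
            per_dir = {}
            for j, direction in enumerate(("up", "down")):
                df = pathmod.enrich_bins(
                    degsets[cond][direction] & universe,
                    ann,
                    universe,
                    n_perm=n_perm,
                    seed=seed + 7 * i + j,
                )
                df.insert(0, "condition", cond)
                df.insert(1, "direction", direction)
                enriched.append(df)
                per_dir[direction] = df
            classified[cond] = pathmod.classify_bins(per_dir["up"], per_dir["down"], alpha)
        pd.concat(enriched, ignore_index=True).to_csv(run / "bins.tsv", sep="\t", index=False)
        matrix = pathmod.activity_matrix(classified)
        matrix.to_csv(run / "bin_classes.tsv", sep="\t", index_label="condition")
        robust = []
        for stress in design.single_codes:
            df = pathmod.robust_bins(classified, design.stress_group(stress))
            df.insert(0, "stress", stress)
            robust.append(df)
        pd.concat(robust, ignore_index=True).to_csv(run / "robust_bins.tsv", sep="\t", index=False)


def stage_grn(run: Path, seed: int = 0, r2_min: float = 0.8, min_experiments: int = 5) -> None:
    run = Path(run)
    with _timed("grn"):
        design = make_design()
        expr = read_expression(
            run / "expression.tsv", run / "samples.tsv", strip_isoform_suffix=False
        )
        degsets = read_degsets(run / "degsets.json")
        tf_map = read_tf_table(run / "tfs.tsv", strip_isoform_suffix=False)
        slices = grnmod.prepare_slices(
            expr, degsets, set(tf_map.gene_to_tf_family), design, min_experiments
        )
        models = []
        for name in sorted(slices):
            models.extend(grnmod.fit_slice(slices[name], seed=seed))
        edges, union = grnmod.build_networks(models, r2_min=r2_min)
        grnmod.models_to_frame(models).to_csv(run / "models.tsv", sep="\t", index=False)
        union.to_csv(run / "union_edges.tsv", sep="\t", index=False)
        grnmod.select_high_confidence(union).to_csv(run / "hc_grn.tsv", sep="\t", index=False)
        grnmod.model_quality_curve(models).to_csv(
            run / "quality_curve.tsv", sep="\t", index=False
        )
        write_json({"n_models": len(models), "n_kept": int(len(edges))}, run / "grn_summary.json")


def stage_tfrn(run: Path, sweep_step: float = 0.01) -> None:
    run = Path(run)
    with _timed("tfrn"):
        design = make_design()
        degsets = read_degsets(run / "degsets.json")
        tf_map = read_tf_table(run / "tfs.tsv", strip_isoform_suffix=False)
        tf_genes = set(tf_map.gene_to_tf_family)
        union = pd.read_csv(run / "union_edges.tsv", sep="\t")
        hc = pd.read_csv(run / "hc_grn.tsv", sep="\t")
        robust = tfrnmod.robust_tfs(degsets, tf_genes, design)
        robust.to_csv(run / "robust_tfs.tsv", sep="\t", index=False)
        status = tfrnmod.tf_status(robust)
        edges = tfrnmod.build_tfrn(union, tf_genes, status)
        edges.to_csv(run / "tfrn_edges.tsv", sep="\t", index=False)
        cutoff, ratio, n_tfs, sweep = tfrnmod.optimize_cutoff(edges, step=sweep_step)
        sweep.to_csv(run / "cutoff_sweep.tsv", sep="\t", index=False)
        write_json(
            {"cutoff": cutoff, "expected_ratio": ratio, "n_tfs_connected": n_tfs},
            run / "cutoff.json",
        )
        ann = read_mercator(run / "mercator.txt", strip_isoform_suffix=False)
        # bin codes are dot-separated strings ("12.1"), not decimals
        robust_bin_table = pd.read_csv(run / "robust_bins.tsv", sep="\t", dtype={"bin": str})
        expr = read_expression(
            run / "expression.tsv", run / "samples.tsv", strip_isoform_suffix=False
        )
        links = tfrnmod.tf_bin_links(
            hc, ann, robust_bin_table, robust, set(expr.genes) & set(ann.gene_to_bins)
        )
        links.to_csv(run / "tf_bin_links.tsv", sep="\t", index=False)


def stage_compare(run: Path, n_perm: int = 1000, seed: int = 0) -> None:
    run = Path(run)
    with _timed("compare"):
        union = pd.read_csv(run / "union_edges.tsv", sep="\t")
        fam_a = read_family_map(run / "families_a.tsv", strip_isoform_suffix=False)
        fam_b = read_family_map(run / "families_b.tsv", strip_isoform_suffix=False)
        ref = read_edge_list(run / "reference_edges.tsv", strip_isoform_suffix=False)
        observed, dropped = cmpmod.to_ortho_edges(
            set(zip(union["tf"], union["target"])), fam_a
        )
        res = cmpmod.permute_reference(observed, ref, fam_b, n=n_perm, seed=seed)
        write_json(
            {
                "ji": res["ji"],
                "p": res["p"],
                "n_observed_tuples": len(observed),
                "n_dropped_edges": dropped,
            },
            run / "compare.json",
        )


def stage_additivity(run: Path, orientation: str = "focal") -> None:
    run = Path(run)
    with _timed("additivity"):
        design = make_design()
        degsets = read_degsets(run / "degsets.json")
        de_tables = load_de_tables(run)
        lfc = addmod.condition_log2fc(de_tables, design.stress_conditions)
        long = addmod.assemble(lfc, degsets, design, orientation=orientation)
        cells = addmod.average_cells(long)
        cells.to_csv(run / "cells.tsv", sep="\t", index=False)
        gfit = addmod.fit_global(cells)
        write_json(vars(gfit), run / "global_fit.json")
        fits = addmod.fit_all_stresses(long)
        pd.DataFrame(
            [{"stress": s, **vars(f)} for s, f in fits.items()]
        ).to_csv(run / "per_stress_fits.tsv", sep="\t", index=False)
        ranking, tied = addmod.dominance_ranking(fits)
        (run / "ranking.txt").write_text(
            " > ".join(ranking) + ("  (ties broken alphabetically)\n" if tied else "\n"),
            encoding="utf-8",
        )
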