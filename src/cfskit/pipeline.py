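"""End-to-end orchestration: simulate -> interactome -> enrichment ->
QIBC -> cytogenetic statistics, with a reproducible run report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from cfskit import cytostats
from cfskit.config import RunConfig
from cfskit.enrichment import (
    annotation_universe,
    build_network,
    enrichment_to_frame,
    hypergeom_enrichment,
    read_annotations,
    read_edges,
    write_graphml,
)
from cfskit.errors import PipelineError
from cfskit.imaging import costes_test, quantify_cells, records_to_frame
from cfskit.interactome import (
    classify_interactors,
    read_protein_groups,
    tier_counts,
    write_calls,
)
from cfskit.simulate import make_fixture

logger = logging.getLogger(__name__)


@dataclass
class StageRecord:
    name: str
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    seed: int | None = None


@dataclass
class RunReport:
    seed: int
    stages: list[StageRecord] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    def stage(self, name: str) -> StageRecord:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_outputs(paths) -> dict:
    return {str(p): _sha256(p) for p in paths}


def run_pipeline(config: RunConfig) -> RunReport:
    """Run all stages in dependency order and emit ``report.json``.

    Rerunning with an identical config reproduces identical output
    hashes: every source of randomness derives from ``config.seed``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    # --- stage 1: synthetic inputs -------------------------------------
    stage = "simulate"
    try:
        fixdir = outdir / "fixture"
        paths = make_fixture(
            fixdir,
            seed=config.seed,
            proteomics=config.proteomics,
            imaging=config.imaging,
            cyto=config.cyto,
        )
        report.stages.append(
            StageRecord(
                name=stage,
                counts={"files": len(paths)},
                outputs=_hash_outputs(paths.values()),
                seed=config.seed,
            )
        )
    except Exception as exc:
        raise PipelineError(stage, "generation_failed", str(exc)) from exc

    # --- stage 2: interactor calling -----------------------------------
    stage = "interactome"
    try:
        design = config.proteomics.design(fold_threshold=config.fold_threshold)
        table = read_protein_groups(paths["protein_groups"], design)
        calls = classify_interactors(table)
        calls_path = outdir / "interactor_calls.tsv"
        write_calls(calls, calls_path)
        report.stages.append(
            StageRecord(
                name=stage,
                counts=tier_counts(calls),
                outputs=_hash_outputs([calls_path]),
            )
        )
    except Exception as exc:
        raise PipelineError(stage, "classification_failed", str(exc)) from exc

    # --- stage 3: enrichment + network ---------------------------------
    stage = "enrichment_network"
    try:
        terms = read_annotations(paths["annotation"])
        universe = annotation_universe(terms)
        selection = {
            c.gene
            for c in calls
            if c.tier in ("potential_interactor", "aph_induced") and c.gene in universe
        }
        results = hypergeom_enrichment(
            selection, universe, terms, alpha=config.enrichment.alpha
        )
        enr_path = outdir / "enrichment.tsv"
        enrichment_to_frame(results).to_csv(enr_path, sep="\t", index=False)
        graph = build_network(
            calls, read_edges(paths["edges"]), min_score=config.enrichment.min_score
        )
        graph_path = outdir / "network.graphml"
        write_graphml(graph, graph_path)
        report.stages.append(
            StageRecord(
                name=stage,
                counts={
                    "terms_tested": len(results),
                    "terms_significant": sum(r.significant for r in results),
                    "nodes": graph.number_of_nodes(),
                    "edges": graph.number_of_edges(),
                },
                outputs=_hash_outputs([enr_path, graph_path]),
            )
        )
    except Exception as exc:
        raise PipelineError(stage, "enrichment_failed", str(exc)) from exc

    # --- stage 4: QIBC -------------------------------------------------
    stage = "qibc"
    try:
        q = config.qibc
        per_condition = {}
        coloc_summaries = {}
        for label in ("vehicle", "aph"):
            chans = {
                name: tifffile.imread(paths[f"image_{label}_{name}"]).astype(float)
                for name in ("dapi", "edu", "chan_a", "chan_b")
            }
            records, mask = quantify_cells(
                chans["dapi"],
                chans["edu"],
                chan_a=chans["chan_a"],
                chan_b=chans["chan_b"],
                min_area=q.min_area,
                max_area=q.max_area,
                spot_sigma=q.spot_sigma,
                rel_threshold=q.rel_threshold,
                overlap_radius=q.overlap_radius,
                max_mn_area=q.max_mn_area,
                search_radius=q.search_radius,
            )
            df = records_to_frame(records)
            df.insert(0, "condition", label)
            per_condition[label] = df
            coloc_summaries[label] = _costes_on_g2(
                chans, records, mask, config, label
            )
        cells_path = outdir / "cells.csv"
        pd.concat(per_condition.values()).to_csv(cells_path, index=False)
        coloc_path = outdir / "coloc.json"
        with open(coloc_path, "w") as fh:
            json.dump(coloc_summaries, fh, indent=2)
        report.stages.append(
            StageRecord(
                name=stage,
                counts={
                    lab: int(len(df)) for lab, df in per_condition.items()
                },
                outputs=_hash_outputs([cells_path, coloc_path]),
                seed=config.seed,
            )
        )
    except Exception as exc:
        raise PipelineError(stage, "qibc_failed", str(exc)) from exc

    # --- stage 5: cytogenetic statistics -------------------------------
    stage = "stats"
    try:
        breaks = cytostats.read_break_table(paths["breaks"])
        locus = cytostats.read_locus_contingency(paths["fra16d"])
        summary = cytostats.group_summary(breaks)
        summary_path = outdir / "break_summary.csv"
        summary.to_csv(summary_path, index=False)
        midas = cytostats.midas_proportions(breaks)
        midas_path = outdir / "midas.csv"
        midas.to_csv(midas_path, index=False)

        groups = sorted(breaks["group"].unique())
        tests = {}
        ref = groups[0]
        ref_vals = breaks.loc[breaks["group"] == ref, "breaks_total"]
        for g in groups[1:]:
            t, dof, p = cytostats.unpaired_t(
                breaks.loc[breaks["group"] == g, "breaks_total"], ref_vals
            )
            tests[f"t_{g}_vs_{ref}"] = {"t": t, "df": dof, "p": p}
        chi2, dof, p = cytostats.chisq_independence(locus)
        tests["chi2_locus"] = {"chi2": chi2, "df": dof, "p": p}
        stats_path = outdir / "stats.json"
        with open(stats_path, "w") as fh:
            json.dump(tests, fh, indent=2)
        report.stages.append(
            StageRecord(
                name=stage,
                counts={"groups": len(groups), "tests": len(tests)},
                outputs=_hash_outputs([summary_path, midas_path, stats_path]),
            )
        )
    except Exception as exc:
        raise PipelineError(stage, "stats_failed", str(exc)) from exc

    report.to_json(outdir / "report.json")
    return report


def _costes_on_g2(chans, records, mask, config: RunConfig, label: str) -> dict:
    """Costes test per G2 nucleus (bounding-box crop), summarized."""
    g2 = [r for r in records if r.stage == "G2"][: config.coloc.n_cells]
    results = []
    for r in g2:
        sel = mask.labels == r.cell_id
        rows = np.where(sel.any(axis=1))[0]
        cols = np.where(sel.any(axis=0))[0]
        sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
        try:
            res = costes_test(
                chans["chan_a"][sl],
                chans["chan_b"][sl],
                mask=sel[sl],
                block_px=config.coloc.block_px,
                n_rand=config.coloc.n_rand,
                seed=config.seed + r.cell_id,
            )
        except ValueError:
            continue  # constant channel in this nucleus
        results.append(
            {
                "cell_id": r.cell_id,
                "pearson_r": res.pearson_r,
                "p_value": res.p_value,
                "fold_over_random": res.fold_over_random,
            }
        )
    if not results:
        return {"n_cells": 0}
    r_vals = [x["pearson_r"] for x in results]
    p_vals = [x["p_value"] for x in results]
    return {
        "n_cells": len(results),
        "median_pearson_r": float(np.median(r_vals)),
        "frac_significant": float(np.mean([p <= 0.05 for p in p_vals])),
        "cells": results,
    }
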