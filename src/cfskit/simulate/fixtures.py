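"""Composite fixtures: the margin-exact cascade table and full file sets.

:func:`cascade_fixture` constructs a protein-group table whose filter
cascade margins are exact by design — 894 groups of which 229 are
single-peptide (665 retained), 226 passing the bait-versus-IgG majority
rule and 45 of those also passing the APH-versus-untreated rule — with
every ratio drawn on the correct side of the 1.5-fold threshold.  It is
the deterministic companion to the stochastic generators.

:func:`make_fixture` writes one complete demo input set (protein
groups, channel TIFFs, cytogenetic CSVs, term annotations and a scored
edge table) for the CLI and the end-to-end pipeline.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from cfskit.interactome import ExperimentDesign
from cfskit.simulate.cytogenetics import CytoSimParams, gen_cyto_counts
from cfskit.simulate.imaging import ImageSimParams, gen_foci_images, truth_to_frame
from cfskit.simulate.proteomics import (
    ProteomicsSimParams,
    gen_protein_groups,
    write_protein_groups,
)

# Genes planted among the APH-induced recruits so the fixture's top of
# the ranking looks like a real CFS interactome (bait and partner first).
_KNOWN_APH_GENES = ("FANCD2", "FANCI", "BLM", "BRCA1", "ATRX", "RAD50", "MRE11")


def cascade_fixture(
    n_total: int = 894,
    n_single_peptide: int = 229,
    n_tier1: int = 226,
    n_tier2: int = 45,
    fold_threshold: float = 1.5,
    seed: int = 20190610,
) -> tuple[pd.DataFrame, ExperimentDesign]:
    """Protein-group table with exact, construction-forced cascade margins.

    Three experiments carry H/M; the first two also carry H/L.  Jitter
    is drawn away from the threshold so the margins are seed-independent
    facts of the construction, not sampling accidents.
    """
    if not n_tier2 <= n_tier1 <= n_total - n_single_peptide:
        raise ValueError("margins must nest: tier2 <= tier1 <= multi-peptide rows")
    rng = np.random.default_rng(seed)
    n_multi = n_total - n_single_peptide
    n_bg_multi = n_multi - n_tier1

    params = ProteomicsSimParams()  # for the experiment/channel layout
    design = params.design(fold_threshold=fold_threshold)

    def passing(n):  # comfortably above threshold
        return fold_threshold * 2 ** rng.uniform(0.3, 2.0, n)

    def failing(n):  # comfortably below threshold
        return fold_threshold * 2 ** rng.uniform(-1.5, -0.3, n)

    classes = (
        ["tier2"] * n_tier2
        + ["tier1"] * (n_tier1 - n_tier2)
        + ["multi_bg"] * n_bg_multi
        + ["single_bg"] * n_single_peptide
    )
    k_named = min(len(_KNOWN_APH_GENES), n_tier2)
    genes = list(_KNOWN_APH_GENES[:k_named]) + [
        f"SIM{i:05d}" for i in range(n_total - k_named)
    ]
    n = n_total
    cls = np.array(classes)
    tier1 = cls == "tier1"
    tier2 = cls == "tier2"

    # Tier-2 rows get well-separated, descending log2 enrichment levels so
    # the bait-like genes rank first regardless of the jitter draw.
    tier2_level = np.concatenate(
        [
            np.linspace(6.0, 4.0, k_named),
            np.linspace(3.5, 0.5, n_tier2 - k_named),
        ]
    )

    data = {
        "Protein IDs": [f"Q{i:05d}" for i in range(n)],
        "Gene names": genes,
        "Razor + unique peptides": np.where(
            cls == "single_bg", 1, 2 + rng.integers(0, 12, n)
        ),
        "Potential contaminant": [""] * n,
        "Reverse": [""] * n,
    }
    for j, exp in enumerate(params.experiment_ids):
        hm = failing(n)
        hm[tier1] = passing(int(tier1.sum()))
        hm[tier2] = fold_threshold * 2.0 ** (
            tier2_level + rng.uniform(-0.05, 0.05, n_tier2)
        )
        data[f"Ratio H/M normalized {exp}"] = hm
        if j < params.n_experiments_hl:
            data[f"Ratio H/L normalized {exp}"] = np.where(
                tier2, passing(n), failing(n)
            )
    df = pd.DataFrame(data)

    order = rng.permutation(n)
    return df.iloc[order].reset_index(drop=True), design


def gen_annotation_and_edges(
    truth: pd.DataFrame, seed: int = 0, n_extra_genes: int = 2000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic gene->term annotation and scored edge tables.

    Interactor genes are preferentially annotated to repair/chromosome
    terms and densely connected; background genes fall into neutral
    terms with sparse low-confidence edges.  The universe is padded with
    unobserved genes so enrichment runs against a genome-like reference.
    """
    rng = np.random.default_rng(seed)
    interactors = truth.loc[truth["class"] != "background", "gene"].tolist()
    background = truth.loc[truth["class"] == "background", "gene"].tolist()
    extra = [f"GEN{i:05d}" for i in range(n_extra_genes)]

    rows = []

    def annotate(term, genes, prob):
        for g in genes:
            if rng.random() < prob:
                rows.append({"gene": g, "term": term})

    annotate("GO:DNA_REPAIR", interactors, 0.5)
    annotate("GO:DNA_REPAIR", background + extra, 0.03)
    annotate("GO:CHROMOSOME_ORG", interactors, 0.4)
    annotate("GO:CHROMOSOME_ORG", background + extra, 0.04)
    annotate("GO:DNA_REPLICATION", interactors, 0.25)
    annotate("GO:DNA_REPLICATION", background + extra, 0.03)
    annotate("GO:RIBOSOME", background + extra, 0.08)
    annotate("GO:METABOLISM", interactors + background + extra, 0.15)
    annotation = pd.DataFrame(rows).drop_duplicates()

    edge_rows = []
    for a, b in itertools.combinations(interactors, 2):
        if rng.random() < 0.05:
            edge_rows.append(
                {"gene_a": a, "gene_b": b, "score": round(rng.uniform(0.15, 0.99), 3)}
            )
    all_obs = interactors + background
    for _ in range(len(background)):
        a, b = rng.choice(all_obs, size=2, replace=False)
        edge_rows.append(
            {"gene_a": a, "gene_b": b, "score": round(rng.uniform(0.05, 0.6), 3)}
        )
    edges = pd.DataFrame(edge_rows)
    return annotation, edges


def make_fixture(
    outdir,
    seed: int = 0,
    proteomics: ProteomicsSimParams | None = None,
    imaging: ImageSimParams | None = None,
    imaging_stressed: ImageSimParams | None = None,
    cyto: CytoSimParams | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic input set under ``outdir``.

    Two imaging conditions are emitted (vehicle and replication-stressed,
    the latter with 1.5-fold per-stage foci rates by default) so that the
    stage-resolved foci comparison can be exercised.  Returns a mapping
    of logical names to written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    proteomics = proteomics or ProteomicsSimParams(seed=seeds[0])
    table, truth = gen_protein_groups(proteomics)
    paths: dict[str, Path] = {}

    paths["protein_groups"] = outdir / "proteinGroups.txt"
    write_protein_groups(table, paths["protein_groups"])
    paths["proteomics_truth"] = outdir / "proteomics_truth.tsv"
    truth.to_csv(paths["proteomics_truth"], sep="\t", index=False)
    paths["design"] = outdir / "design.yaml"
    proteomics.design().to_yaml(paths["design"])

    annotation, edges = gen_annotation_and_edges(truth, seed=seeds[1])
    paths["annotation"] = outdir / "annotation.tsv"
    annotation.to_csv(paths["annotation"], sep="\t", index=False, header=False)
    paths["edges"] = outdir / "edges.tsv"
    edges.to_csv(paths["edges"], sep="\t", index=False, header=False)

    imaging = imaging or ImageSimParams(seed=seeds[2])
    if imaging_stressed is None:
        rates = {k: 1.5 * v for k, v in imaging.foci_rate_per_stage.items()}
        imaging_stressed = ImageSimParams(
            **{
                **imaging.__dict__,
                "foci_rate_per_stage": rates,
                "seed": seeds[2] + 1,
            }
        )
    for label, p in (("vehicle", imaging), ("aph", imaging_stressed)):
        images, truths = gen_foci_images(p)
        for chan, img in images.as_dict().items():
            key = f"image_{label}_{chan}"
            paths[key] = outdir / f"{label}_{chan}.tiff"
            tifffile.imwrite(paths[key], img.astype(np.float32))
        key = f"image_{label}_truth"
        paths[key] = outdir / f"{label}_truth.tsv"
        truth_to_frame(truths).to_csv(paths[key], sep="\t", index=False)

    cyto = cyto or CytoSimParams(seed=seeds[3])
    breaks, locus, cyto_truth = gen_cyto_counts(cyto)
    paths["breaks"] = outdir / "breaks.csv"
    breaks.to_csv(paths["breaks"], index=False)
    paths["fra16d"] = outdir / "fra16d.csv"
    locus.reset_index().to_csv(paths["fra16d"], index=False)
    paths["cyto_truth"] = outdir / "cyto_truth.yaml"
    with open(paths["cyto_truth"], "w") as fh:
        yaml.safe_dump(cyto_truth, fh)

    return paths
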