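# cfskit

Analysis toolkit for experiments that probe **common fragile site (CFS)
stability**: quantitative SILAC ChIP-MS interactome calling, quantitative
image-based cytometry (QIBC) with colocalization statistics, and
cytogenetic break statistics — each exercisable end to end on synthetic
data with known ground truth.

## Who this is for

Labs that map the protein neighbourhood of challenged CFSs by
immunoprecipitating a CFS-resident bait (FANCD2) from replication-stressed
cells and quantifying co-purifying proteins by triple-SILAC MS, then
validate candidates by high-content microscopy (nuclear foci, 53BP1
bodies, micronuclei) and metaphase-spread scoring (gaps/breaks, MiDAS,
fragile-locus FISH).

## The statistics at the core

**Interactor cascade.** Each protein group carries per-experiment SILAC
ratios H/M (bait ChIP vs IgG ChIP, both APH-treated) and H/L (bait ChIP
from stressed synchronized cells vs untreated asynchronous cells).
After requiring ≥ 2 supporting peptides and discarding contaminants and
decoys, a protein is a *potential CFS interactor* if

&nbsp;&nbsp;&nbsp;&nbsp; H/M ≥ 1.5 in strictly more than half of the experiments
in which H/M was quantified,

and an *APH-induced recruit* if the same majority rule also holds for
H/L. Calls are ranked by median log2(H/M).

**Enrichment and network.** Term over-representation in the called set
is the upper-tail hypergeometric probability P[X ≥ k] for k hits among n
selected genes given K term members in a universe of N, with
Benjamini–Hochberg control across terms; the functional network keeps
edges from a user-supplied confidence-scored table at score ≥ 0.4
between called genes.

**QIBC.** Nuclei are segmented from DAPI (Otsu + hole filling + size
filter); cells are gated into G1 / early-, mid-, late-S / G2 from the
EdU split and the 2N–4N DAPI modes; per-cell foci are counted by
difference-of-Gaussians detection with per-nucleus relative thresholds.
Object colocalization separates *overlapping* (distance ≤ r) from
*adjacent* (r–2r) focus pairs; pixel colocalization significance uses a
Costes-style block-randomization null with empirical p-value
(1 + #{r_rand ≥ r_obs}) / (n_rand + 1).

**Cytogenetics.** Mean ± SEM of per-spread gap+break counts, Welch
unpaired t-tests between conditions, pooled MiDAS (EdU-positive break)
fractions with Wilson 95% intervals, and Pearson chi-square on
broken/intact fragile-locus contingency tables.

## Worked example

Build a protein-group table whose cascade margins are forced by
construction and classify it:

```python
from cfskit.simulate import cascade_fixture
from cfskit.simulate.proteomics import write_protein_groups

df, design = cascade_fixture()
write_protein_groups(df, "proteinGroups.txt")
design.to_yaml("design.yaml")
```

```bash
cfs call-interactors --protein-groups proteinGroups.txt \
    --design design.yaml --fold 1.5 --out calls.tsv
```

prints the cascade counts:

```
{"total": 894, "identified": 665, "potential_interactor": 226, "aph_induced": 45}
```

894 protein groups enter; 665 survive the ≥2-peptide identification
filter; 226 pass the 1.5-fold bait-vs-IgG majority rule; 45 of those are
additionally enriched upon replication stress. The top of `calls.tsv`
(APH-induced tier, ranked by median log2 H/M):

```
  gene  median_log2_hm  median_log2_hl        tier
FANCD2        6.594325        1.524809 aph_induced
 FANCI        6.271381        1.869994 aph_induced
   BLM        5.920337        1.351693 aph_induced
 BRCA1        5.609949        1.682425 aph_induced
  ATRX        5.290967        2.333277 aph_induced
```

The bait (FANCD2) and its constitutive partner FANCI rank first, with
known repair factors and the chromatin remodeler ATRX among the
stress-induced recruits — the structure a successful screen shows.

`cfs demo --outdir run --seed 1` runs the whole pipeline (generator →
interactome → enrichment/network → QIBC → break statistics) and writes a
`report.json` with per-stage counts and output hashes; rerunning with
the same seed reproduces the hashes.

## Layout

| module | contents |
| --- | --- |
| `cfskit.interactome` | `proteinGroups.txt` dialect parser, identification filter, majority rule, two-tier classification, ranking |
| `cfskit.enrichment` | hypergeometric term enrichment, BH correction, confidence-filtered network, GraphML export |
| `cfskit.imaging` | nucleus/micronucleus segmentation, cell-cycle gating, foci detection, object & Costes colocalization |
| `cfskit.cytostats` | break summaries, Welch t, chi-square, MiDAS Wilson intervals |
| `cfskit.simulate` | seeded generators for all three modalities + composite fixtures |
| `cfskit.pipeline` / `cfskit.cli` | YAML-configured orchestration, `cfs` command |
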