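"""Triple-SILAC protein-group table generator.

Channel semantics follow the ChIP-MS design being emulated: light =
untreated asynchronous FANCD2 ChIP, medium = APH-treated IgG ChIP,
heavy = APH-treated FANCD2 ChIP.  Hence log2(H/M) measures bait-over-
background enrichment and log2(H/L) measures APH-induced recruitment.
Ratio noise is modelled as Normal on the log2 scale (log-normal ratios),
the standard error model for SILAC ratio distributions; missingness is
missing-completely-at-random per protein per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cfskit.errors import ParameterError
from cfskit.interactome import Experiment, ExperimentDesign


@dataclass(frozen=True)
class ProteomicsSimParams:
    """Conditions of the simulated ChIP-MS screen.

    Defaults mirror the study design being emulated: 668 background
    groups plus 226 spiked interactors of which 45 respond to APH
    (894 groups total), ~26% single-peptide identifications, three
    experiments with an H/M channel of which the first two (the
    biological replicates) also carry H/L — the third is the pilot,
    which contributes H/M only.
    """

    n_background: int = 668
    n_interactors: int = 226
    n_aph_responsive: int = 45
    log2_effect_bait_vs_igg: float = 1.5
    log2_effect_aph_vs_untreated: float = 1.5
    ratio_noise_sd: float = 0.3
    n_experiments_hm: int = 3
    n_experiments_hl: int = 2
    missing_prob: float = 0.2
    single_peptide_frac: float = 229 / 894
    seed: int = 0

    def __post_init__(self):
        for name in ("n_background", "n_interactors", "n_aph_responsive",
                     "n_experiments_hm", "n_experiments_hl"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_aph_responsive > self.n_interactors:
            raise ParameterError("n_aph_responsive cannot exceed n_interactors")
        if self.n_experiments_hl > self.n_experiments_hm:
            raise ParameterError("every H/L experiment must also have H/M")
        if self.n_experiments_hm < 1:
            raise ParameterError("need at least one H/M experiment")
        for name in ("missing_prob", "single_peptide_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.ratio_noise_sd < 0:
            raise ParameterError("ratio_noise_sd must be >= 0")

    @property
    def experiment_ids(self) -> tuple[str, ...]:
        return tuple(f"exp{i + 1}" for i in range(self.n_experiments_hm))

    def design(self, fold_threshold: float = 1.5) -> ExperimentDesign:
        return ExperimentDesign(
            experiments=tuple(
                Experiment(id=e, has_hm=True, has_hl=i < self.n_experiments_hl)
                for i, e in enumerate(self.experiment_ids)
            ),
            fold_threshold=fold_threshold,
        )


def gen_protein_groups(
    params: ProteomicsSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a ``proteinGroups.txt``-dialect table plus truth labels.

    Returns
    -------
    table : DataFrame
        Columns "Protein IDs", "Gene names", "Razor + unique peptides",
        "Potential contaminant", "Reverse" and one
        "Ratio H/M normalized <exp>" / "Ratio H/L normalized <exp>"
        column per channel; missing ratios are NaN.
    truth : DataFrame
        One row per protein group: gene, class in
        {background, interactor, aph_responsive}, peptide_count.
    """
    rng = np.random.default_rng(params.seed)
    n_int, n_aph = params.n_interactors, params.n_aph_responsive
    n_total = params.n_background + n_int

    classes = np.array(
        ["aph_responsive"] * n_aph
        + ["interactor"] * (n_int - n_aph)
        + ["background"] * params.n_background
    )
    genes = np.array([f"SIM{i:05d}" for i in range(n_total)])
    accs = np.array([f"P{i:05d}" for i in range(n_total)])

    hm_mu = np.where(classes != "background", params.log2_effect_bait_vs_igg, 0.0)
    hl_mu = np.where(classes == "aph_responsive",
                     params.log2_effect_aph_vs_untreated, 0.0)

    sd = params.ratio_noise_sd
    data: dict[str, object] = {}
    for j, exp in enumerate(params.experiment_ids):
        vals = 2.0 ** rng.normal(hm_mu, sd, size=n_total)
        vals[rng.random(n_total) < params.missing_prob] = np.nan
        data[f"Ratio H/M normalized {exp}"] = vals
        if j < params.n_experiments_hl:
            vals = 2.0 ** rng.normal(hl_mu, sd, size=n_total)
            vals[rng.random(n_total) < params.missing_prob] = np.nan
            data[f"Ratio H/L normalized {exp}"] = vals

    single = rng.random(n_total) < params.single_peptide_frac
    peptides = np.where(single, 1, 2 + rng.poisson(6, size=n_total))

    order = rng.permutation(n_total)
    table = pd.DataFrame(
        {
            "Protein IDs": accs,
            "Gene names": genes,
            "Razor + unique peptides": peptides,
            "Potential contaminant": "",
            "Reverse": "",
            **data,
        }
    ).iloc[order].reset_index(drop=True)
    truth = pd.DataFrame(
        {"gene": genes, "class": classes, "peptide_count": peptides}
    ).iloc[order].reset_index(drop=True)
    return table, truth


def write_protein_groups(table: pd.DataFrame, path) -> None:
    """Write in the tab-delimited dialect (missing ratios as empty cells)."""
    table.to_csv(path, sep="\t", index=False, na_rep="")
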