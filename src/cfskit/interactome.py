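"""SILAC ChIP-MS interactor calling from MaxQuant-style protein-group tables.

The experimental design this module quantifies is a triple-SILAC ChIP-MS:
light = untreated asynchronous cells, FANCD2 ChIP; medium = aphidicolin
(APH)-treated synchronized cells, IgG control ChIP; heavy = APH-treated
synchronized cells, FANCD2 ChIP.  Two per-protein ratios carry the signal:

* ``H/M`` — FANCD2 pull-down versus IgG background under replication
  stress.  Proteins at least ``fold_threshold``-fold enriched in more
  than half of the experiments in which the ratio was quantified are
  *potential CFS interactors*.
* ``H/L`` — FANCD2 pull-down from stressed synchronized cells versus
  untreated asynchronous cells.  Potential interactors that also pass
  the same majority rule on H/L are *APH-induced* recruits.

A pilot experiment may contribute only the H/M channel; the
:class:`ExperimentDesign` declares per experiment which channels exist.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from cfskit.errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

TIERS = ("excluded", "identified", "potential_interactor", "aph_induced")


@dataclass(frozen=True)
class Experiment:
    """One SILAC MS experiment and which ratio channels it measured."""

    id: str
    has_hm: bool = True
    has_hl: bool = False


@dataclass(frozen=True)
class ExperimentDesign:
    """Declared experiments plus the fold-change threshold (default 1.5)."""

    experiments: tuple[Experiment, ...]
    fold_threshold: float = 1.5

    def __post_init__(self):
        if self.fold_threshold <= 1:
            raise ConfigError(
                f"fold_threshold must exceed 1, got {self.fold_threshold}"
            )
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"duplicate experiment ids: {ids}")
        if not any(e.has_hm for e in self.experiments):
            raise ConfigError("at least one experiment must have an H/M channel")

    @property
    def hm_experiments(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.experiments if e.has_hm)

    @property
    def hl_experiments(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.experiments if e.has_hl)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        exps = tuple(
            Experiment(
                id=str(e["id"]),
                has_hm=bool(e.get("has_hm", True)),
                has_hl=bool(e.get("has_hl", False)),
            )
            for e in raw["experiments"]
        )
        return cls(experiments=exps, fold_threshold=float(raw.get("fold_threshold", 1.5)))

    def to_yaml(self, path) -> None:
        payload = {
            "fold_threshold": self.fold_threshold,
            "experiments": [
                {"id": e.id, "has_hm": e.has_hm, "has_hl": e.has_hl}
                for e in self.experiments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class ProteinGroupTable:
    """Canonicalized protein-group quantifications.

    ``data`` has one row per protein group with columns ``protein_ids``,
    ``gene_names``, ``gene`` (primary uppercase symbol), ``peptide_count``,
    ``is_contaminant``, ``is_decoy`` and one ``hm_<exp>`` / ``hl_<exp>``
    float column per declared channel (NaN = not quantified).
    """

    data: pd.DataFrame
    design: ExperimentDesign

    def __len__(self) -> int:
        return len(self.data)

    def hm_columns(self) -> list[str]:
        return [f"hm_{e}" for e in self.design.hm_experiments]

    def hl_columns(self) -> list[str]:
        return [f"hl_{e}" for e in self.design.hl_experiments]


class MajorityResult(NamedTuple):
    n_quantified: int
    n_passing: int
    passes: bool


@dataclass
class InteractorCall:
    """Per-protein classification with the evidence behind it."""

    protein_ids: str
    gene_names: str
    gene: str
    passed_id_filter: bool
    n_quantified_hm: int
    n_passing_hm: int
    n_quantified_hl: int
    n_passing_hl: int
    median_log2_hm: float  # NaN when nothing quantified
    median_log2_hl: float
    tier: str = field(default="excluded")

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")


_FLAG_TRUE = {"+", "true", "yes", "1"}


def _truthy_flag(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return str(value).strip().lower() in _FLAG_TRUE


def _find_column(lower_map: Mapping[str, str], *names: str) -> str | None:
    for name in names:
        hit = lower_map.get(name.lower())
        if hit is not None:
            return hit
    return None


def _ratio_column(lower_map: Mapping[str, str], channel: str, exp: str) -> str | None:
    """Locate a ratio column, preferring the normalized variant."""
    return _find_column(
        lower_map,
        f"ratio {channel} normalized {exp}",
        f"ratio {channel} {exp}",
    )


def read_protein_groups(path, design: ExperimentDesign) -> ProteinGroupTable:
    """Parse a tab-delimited ``proteinGroups.txt``-dialect file.

    Ratio columns are matched case-insensitively by the patterns
    ``Ratio H/M [normalized] <exp>`` and ``Ratio H/L [normalized] <exp>``;
    when raw and normalized variants coexist the normalized one is used.
    Unparseable or sentinel ratio cells (empty, ``NaN``, zero or negative)
    become missing.  Contaminants/decoys are recognized both via ``+``
    flag columns and via ``CON__`` / ``REV__`` accession prefixes.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns.size == 0 or len(raw.columns) == 1:
        raise FormatError(f"{path}: not a tab-delimited table with a header row")
    lower_map = {c.lower().strip(): c for c in raw.columns}

    id_col = _find_column(lower_map, "protein ids", "majority protein ids")
    if id_col is None:
        raise FormatError(f"{path}: missing required column 'Protein IDs'")
    gene_col = _find_column(lower_map, "gene names")
    pep_col = _find_column(
        lower_map, "razor + unique peptides", "peptides", "peptide counts (all)"
    )
    if pep_col is None:
        raise FormatError(
            f"{path}: missing peptide-count column 'Razor + unique peptides'"
        )
    cont_col = _find_column(lower_map, "potential contaminant", "contaminant")
    rev_col = _find_column(lower_map, "reverse")

    out = pd.DataFrame(index=raw.index)
    out["protein_ids"] = raw[id_col].astype(str)
    out["gene_names"] = raw[gene_col].astype(str) if gene_col else ""
    out["gene"] = [
        primary_gene(g, pid) for g, pid in zip(out["gene_names"], out["protein_ids"])
    ]
    pep = pd.to_numeric(raw[pep_col], errors="coerce").fillna(0)
    out["peptide_count"] = pep.astype(int)
    cont_flag = (
        raw[cont_col].map(_truthy_flag) if cont_col else pd.Series(False, index=raw.index)
    )
    rev_flag = (
        raw[rev_col].map(_truthy_flag) if rev_col else pd.Series(False, index=raw.index)
    )
    out["is_contaminant"] = cont_flag | out["protein_ids"].str.contains("CON__")
    out["is_decoy"] = rev_flag | out["protein_ids"].str.contains("REV__")

    for channel, exps, prefix in (
        ("h/m", design.hm_experiments, "hm"),
        ("h/l", design.hl_experiments, "hl"),
    ):
        for exp in exps:
            col = _ratio_column(lower_map, channel, exp)
            if col is None:
                raise FormatError(
                    f"{path}: no column matching "
                    f"'Ratio {channel.upper()} [normalized] {exp}'"
                )
            vals = pd.to_numeric(raw[col], errors="coerce")
            vals[vals <= 0] = np.nan  # 0 is MaxQuant's "not quantified" sentinel
            out[f"{prefix}_{exp}"] = vals.astype(float)

    return ProteinGroupTable(data=out, design=design)


def primary_gene(gene_names: str, protein_ids: str = "") -> str:
    """First gene symbol, uppercase; falls back to the first accession."""
    for token in re.split(r"[;,]", str(gene_names)):
        token = token.strip()
        if token and token.lower() not in {"nan", "none"}:
            return token.upper()
    return str(protein_ids).split(";")[0].strip().upper()


def filter_identifications(table: ProteinGroupTable) -> ProteinGroupTable:
    """Keep groups with >=2 supporting peptides, non-contaminant, non-decoy."""
    d = table.data
    keep = (d["peptide_count"] >= 2) & ~d["is_contaminant"] & ~d["is_decoy"]
    return ProteinGroupTable(data=d[keep].copy(), design=table.design)


def majority_pass(
    ratios: Mapping[str, float] | Iterable[float], threshold: float
) -> MajorityResult:
    """Majority rule: pass iff the ratio meets ``threshold`` in strictly
    more than half of the experiments in which it was quantified.

    Missing values (``None``/NaN) do not count as quantified.  A protein
    quantified in no experiment never passes (and never errors).  Note
    the strictness: 1 of 2 fails, 2 of 3 passes, 1 of 1 passes.
    """
    if threshold <= 1:
        raise ConfigError(f"threshold must exceed 1, got {threshold}")
    values = list(ratios.values()) if isinstance(ratios, Mapping) else list(ratios)
    quantified = [v for v in values if v is not None and not math.isnan(v)]
    n_q = len(quantified)
    n_p = sum(1 for v in quantified if v >= threshold)
    return MajorityResult(n_q, n_p, n_q >= 1 and n_p > n_q / 2)


def _median_log2(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(np.median(np.log2(arr))) if arr.size else float("nan")


def classify_interactors(
    table: ProteinGroupTable, design: ExperimentDesign | None = None
) -> list[InteractorCall]:
    """Apply the two-tier filter cascade and rank the calls.

    Rows failing the identification filter get ``tier='excluded'``;
    identification-filtered rows passing the H/M majority rule become
    ``potential_interactor``; of those, rows also passing the H/L
    majority rule (over experiments with an H/L channel) become
    ``aph_induced``.  Output is sorted by median log2(H/M) descending,
    NaN last, ties broken by gene name.
    """
    design = design or table.design
    d = table.data
    for exp in design.hm_experiments:
        if f"hm_{exp}" not in d.columns:
            raise ConfigError(f"table lacks H/M ratios for declared experiment {exp!r}")
    for exp in design.hl_experiments:
        if f"hl_{exp}" not in d.columns:
            raise ConfigError(f"table lacks H/L ratios for declared experiment {exp!r}")

    hm_cols = [f"hm_{e}" for e in design.hm_experiments]
    hl_cols = [f"hl_{e}" for e in design.hl_experiments]
    thr = design.fold_threshold

    calls: list[InteractorCall] = []
    for row in d.itertuples(index=False):
        rd = row._asdict()
        passed_id = (
            rd["peptide_count"] >= 2
            and not rd["is_contaminant"]
            and not rd["is_decoy"]
        )
        hm = majority_pass([rd[c] for c in hm_cols], thr)
        hl = majority_pass([rd[c] for c in hl_cols], thr) if hl_cols else MajorityResult(0, 0, False)
        if not passed_id:
            tier = "excluded"
        elif hm.passes and hl.passes:
            tier = "aph_induced"
        elif hm.passes:
            tier = "potential_interactor"
        else:
            tier = "identified"
        calls.append(
            InteractorCall(
                protein_ids=rd["protein_ids"],
                gene_names=rd["gene_names"],
                gene=rd["gene"],
                passed_id_filter=passed_id,
                n_quantified_hm=hm.n_quantified,
                n_passing_hm=hm.n_passing,
                n_quantified_hl=hl.n_quantified,
                n_passing_hl=hl.n_passing,
                median_log2_hm=_median_log2([rd[c] for c in hm_cols]),
                median_log2_hl=_median_log2([rd[c] for c in hl_cols]),
                tier=tier,
            )
        )

    def sort_key(c: InteractorCall):
        nan = math.isnan(c.median_log2_hm)
        return (nan, -c.median_log2_hm if not nan else 0.0, c.gene)

    return sorted(calls, key=sort_key)


def top_n(
    calls: Sequence[InteractorCall], n: int, tier: str = "aph_induced"
) -> list[InteractorCall]:
    """First ``n`` calls of ``tier`` under the classification ordering."""
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}")
    return [c for c in calls if c.tier == tier][: max(n, 0)]


def tier_counts(calls: Sequence[InteractorCall]) -> dict[str, int]:
    """Cumulative cascade counts: identified >= potential >= aph_induced."""
    n_identified = sum(c.passed_id_filter for c in calls)
    n_potential = sum(c.tier in ("potential_interactor", "aph_induced") for c in calls)
    n_aph = sum(c.tier == "aph_induced" for c in calls)
    return {
        "total": len(calls),
        "identified": n_identified,
        "potential_interactor": n_potential,
        "aph_induced": n_aph,
    }


def calls_to_frame(calls: Sequence[InteractorCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def write_calls(calls: Sequence[InteractorCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
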