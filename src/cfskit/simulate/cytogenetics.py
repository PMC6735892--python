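"""Metaphase-spread count generator.

Per-spread total gap+break counts are Poisson with a per-group mean;
each break is independently EdU-positive (MiDAS) with a per-group
probability; fragile-locus scoring is Bernoulli per scored locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cfskit.errors import ParameterError


def _default_break_rates() -> dict[str, float]:
    # siRNA x treatment conditions of a CFS fragility experiment:
    # depletion of the factor under study and mild APH both raise breakage.
    return {
        "siCtrl_DMSO": 0.3,
        "siCtrl_APH": 1.0,
        "siATRX_DMSO": 1.0,
        "siATRX_APH": 3.0,
    }


def _default_midas() -> dict[str, float]:
    return {
        "siCtrl_DMSO": 0.2,
        "siCtrl_APH": 0.45,
        "siATRX_DMSO": 0.35,
        "siATRX_APH": 0.6,
    }


def _default_locus() -> dict[str, float]:
    return {
        "siCtrl_DMSO": 0.05,
        "siCtrl_APH": 0.15,
        "siATRX_DMSO": 0.10,
        "siATRX_APH": 0.35,
    }


@dataclass(frozen=True)
class CytoSimParams:
    """Defaults: 40 spreads per condition and 120 scored fragile loci."""

    n_spreads_per_group: int = 40
    break_rate: dict[str, float] = field(default_factory=_default_break_rates)
    midas_pos_prob: dict[str, float] = field(default_factory=_default_midas)
    locus_break_prob: dict[str, float] = field(default_factory=_default_locus)
    n_loci: int = 120
    seed: int = 0

    def __post_init__(self):
        if self.n_spreads_per_group < 0 or self.n_loci < 0:
            raise ParameterError("counts must be >= 0")
        if set(self.break_rate) != set(self.midas_pos_prob) or set(
            self.break_rate
        ) != set(self.locus_break_prob):
            raise ParameterError("group keys must match across rate maps")
        if any(v < 0 for v in self.break_rate.values()):
            raise ParameterError("break rates must be >= 0")
        for m in (self.midas_pos_prob, self.locus_break_prob):
            if any(not 0 <= v <= 1 for v in m.values()):
                raise ParameterError("probabilities must lie in [0, 1]")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.break_rate)


def gen_cyto_counts(
    params: CytoSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (break table, locus contingency, truth).

    break table: spread_id, group, breaks_total, breaks_edu_pos.
    locus contingency: group-indexed broken/intact counts.
    truth: the parameter maps actually used (ground truth for recovery).
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for group in params.groups:
        lam = params.break_rate[group]
        p_mid = params.midas_pos_prob[group]
        totals = rng.poisson(lam, size=params.n_spreads_per_group)
        edu_pos = rng.binomial(totals, p_mid)
        for i, (t, e) in enumerate(zip(totals, edu_pos)):
            rows.append(
                {
                    "spread_id": f"{group}_s{i + 1}",
                    "group": group,
                    "breaks_total": int(t),
                    "breaks_edu_pos": int(e),
                }
            )
    breaks = pd.DataFrame(rows)

    locus_rows = []
    for group in params.groups:
        broken = int(rng.binomial(params.n_loci, params.locus_break_prob[group]))
        locus_rows.append(
            {"group": group, "broken": broken, "intact": params.n_loci - broken}
        )
    locus = pd.DataFrame(locus_rows).set_index("group")

    truth = {
        "break_rate": dict(params.break_rate),
        "midas_pos_prob": dict(params.midas_pos_prob),
        "locus_break_prob": dict(params.locus_break_prob),
        "n_spreads_per_group": params.n_spreads_per_group,
        "n_loci": params.n_loci,
    }
    return breaks, locus, truth
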