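"""DAPI/EdU cell-cycle gating of per-cell QIBC records.

The gate reproduces the standard QIBC logic: cells are split into
EdU-positive (replicating) and EdU-negative by a two-component
intensity-model threshold; the 2N and 4N DNA-content modes are located
on the EdU-negative population; EdU-negative cells near 2N are G1 and
near 4N are G2; EdU-positive cells are divided into early/mid/late S by
DAPI terciles of the 2N-4N interval.  An optional Cyclin A gate defines
G1 as Cyclin A-negative (and EdU-negative), the selection used for
scoring G1-specific structures such as 53BP1 nuclear bodies.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

from cfskit.errors import GatingError
from cfskit.imaging.records import CellRecord

logger = logging.getLogger(__name__)

_EPS = 1e-12


def two_component_threshold(values: np.ndarray) -> float:
    """Threshold between the two components of a 1D intensity mixture.

    Fits a two-component Gaussian mixture and returns the point between
    the component means where the weighted densities cross; falls back
    to Otsu when the fit degenerates.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4 or np.ptp(x) == 0:
        raise GatingError("not enough spread in intensities to find a threshold")
    try:
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(
            x.reshape(-1, 1)
        )
        means = gm.means_.ravel()
        order = np.argsort(means)
        lo, hi = means[order]
        if hi - lo > _EPS:
            grid = np.linspace(lo, hi, 512).reshape(-1, 1)
            resp = gm.predict_proba(grid)[:, order[1]]
            cross = np.searchsorted(resp, 0.5)
            cross = min(max(cross, 0), len(grid) - 1)
            return float(grid[cross, 0])
    except Exception:  # fall through to Otsu
        pass
    return float(threshold_otsu(x))


def _dapi_modes(dapi: np.ndarray) -> tuple[float, float]:
    """Locate the 2N and 4N modes of an EdU-negative DAPI distribution."""
    x = np.asarray(dapi, dtype=float)
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3).fit(
        x.reshape(-1, 1)
    )
    means = np.sort(gm.means_.ravel())
    sds = np.sqrt(gm.covariances_.ravel())[np.argsort(gm.means_.ravel())]
    m2, m4 = float(means[0]), float(means[1])
    if (m4 - m2) < 2 * float(max(sds)):
        raise GatingError(
            "DAPI distribution looks unimodal; supply manual 2N/4N thresholds"
        )
    return m2, m4


def gate_cell_cycle(
    records: list[CellRecord],
    use_cyclin_a: bool = False,
    log_edu: bool = True,
) -> list[CellRecord]:
    """Assign exactly one stage (G1/earlyS/midS/lateS/G2) per cell.

    Mutates and returns ``records``.  With ``use_cyclin_a``, G1 is the
    Cyclin A-negative, EdU-negative population and EdU-negative Cyclin
    A-positive cells are called G2 irrespective of DAPI.
    """
    if not records:
        return records
    if len(records) < 50:
        logger.warning(
            "gating %d cells; >=50 recommended for stable mode detection",
            len(records),
        )
    edu = np.array([r.edu_mean for r in records], dtype=float)
    dapi = np.array([r.dapi_integrated for r in records], dtype=float)

    edu_feature = np.log10(edu + max(edu.max(), _EPS) * 1e-4) if log_edu else edu
    if np.ptp(edu_feature) < 1e-9:
        # degenerate channel (e.g. no replicating cells): all EdU-negative
        edu_pos = np.zeros(len(records), dtype=bool)
    else:
        edu_pos = edu_feature > two_component_threshold(edu_feature)

    if (~edu_pos).sum() < 4:
        raise GatingError("too few EdU-negative cells to locate DAPI modes")
    m2, m4 = _dapi_modes(dapi[~edu_pos])
    b1 = m2 + (m4 - m2) / 3
    b2 = m2 + 2 * (m4 - m2) / 3

    cyc_neg = None
    if use_cyclin_a:
        cyc = np.array(
            [r.cyclinA_mean if r.cyclinA_mean is not None else np.nan for r in records]
        )
        if np.isnan(cyc).any():
            raise GatingError("cyclin A gate requested but cyclinA_mean missing")
        cyc_neg = cyc <= two_component_threshold(cyc)

    for i, r in enumerate(records):
        if edu_pos[i]:
            if dapi[i] < b1:
                r.stage = "earlyS"
            elif dapi[i] < b2:
                r.stage = "midS"
            else:
                r.stage = "lateS"
        elif cyc_neg is not None:
            r.stage = "G1" if cyc_neg[i] else "G2"
        else:
            r.stage = "G1" if abs(dapi[i] - m2) <= abs(dapi[i] - m4) else "G2"
    return records
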