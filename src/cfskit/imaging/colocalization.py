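"""Object- and pixel-level colocalization between two foci channels.

Object level: greedy nearest-pair matching between channel-A and
channel-B foci of the same cell, each focus used at most once.  Matched
pairs at centroid distance <= ``overlap_radius`` are *overlapping*;
pairs in ``(overlap_radius, 2*overlap_radius]`` are *adjacent* — the two
colocalization classes seen in micrographs of CFS factors (complete
overlap versus side-by-side foci).

Pixel level: a Costes-style randomization test.  The observed Pearson
correlation over mask pixels is compared with correlations obtained
after shuffling channel B in blocks of ``block_px`` (approximately the
PSF size), preserving local pixel structure while destroying the
spatial registration between channels.  The empirical upper-tail
p-value has the usual add-one form, so its floor is 1/(n_rand+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cfskit.imaging.segmentation import NucleusMask


@dataclass(frozen=True)
class ColocResult:
    pearson_r: float
    n_randomizations: int
    rand_mean_r: float
    rand_sd_r: float
    p_value: float
    fold_over_random: float  # NaN when rand_mean_r <= 0


def object_colocalization(
    a, b, overlap_radius: float
) -> pd.DataFrame:
    """Per-cell (overlap, adjacent) matched-pair counts.

    Candidate pairs up to 2*overlap_radius apart are matched greedily by
    increasing distance (ties broken by channel-A then channel-B index);
    each focus participates in at most one pair.
    """
    if overlap_radius <= 0:
        raise ValueError("overlap_radius must be positive")
    cells = sorted(set(a.data["cell_id"]) | set(b.data["cell_id"]))
    rows = []
    for cid in cells:
        pa = a.positions(cid)
        pb = b.positions(cid)
        overlap = adjacent = 0
        if len(pa) and len(pb):
            d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
            pairs = [
                (d[i, j], i, j)
                for i in range(len(pa))
                for j in range(len(pb))
                if d[i, j] <= 2 * overlap_radius
            ]
            pairs.sort()
            used_a: set[int] = set()
            used_b: set[int] = set()
            for dist, i, j in pairs:
                if i in used_a or j in used_b:
                    continue
                used_a.add(i)
                used_b.add(j)
                if dist <= overlap_radius:
                    overlap += 1
                else:
                    adjacent += 1
        rows.append({"cell_id": cid, "overlap": overlap, "adjacent": adjacent})
    return pd.DataFrame(rows, columns=["cell_id", "overlap", "adjacent"])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    return float((x * y).sum() / denom)


def _block_views(arr: np.ndarray, block: int) -> np.ndarray:
    """(n_tiles, block, block) array of tiles covering a padded copy."""
    h, w = arr.shape
    ph = (-h) % block
    pw = (-w) % block
    padded = np.pad(arr, ((0, ph), (0, pw)), mode="reflect")
    H, W = padded.shape
    tiles = padded.reshape(H // block, block, W // block, block).swapaxes(1, 2)
    return tiles.reshape(-1, block, block), (H, W)


def costes_test(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | NucleusMask | None = None,
    block_px: int = 5,
    n_rand: int = 1000,
    seed: int = 0,
) -> ColocResult:
    """Costes-style block-randomization significance of colocalization."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel images must share a shape")
    if block_px < 1:
        raise ValueError("block_px must be >= 1")
    if n_rand < 99:
        raise ValueError("n_rand must be >= 99 for a meaningful empirical p")
    if isinstance(mask, NucleusMask):
        mask = mask.labels > 0
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")

    # crop to the mask bounding box; randomization tiles that region
    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    a_sub, b_sub, m_sub = a[sl], b[sl], mask[sl]

    av = a_sub[m_sub]
    bv = b_sub[m_sub]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("constant channel within mask: Pearson r undefined")
    r_obs = _pearson(av, bv)

    tiles, (H, W) = _block_views(b_sub, block_px)
    n_tiles = tiles.shape[0]
    rng = np.random.default_rng(seed)
    r_rand = np.empty(n_rand)
    nh, nw = H // block_px, W // block_px
    for it in range(n_rand):
        perm = rng.permutation(n_tiles)
        shuffled = (
            tiles[perm]
            .reshape(nh, nw, block_px, block_px)
            .swapaxes(1, 2)
            .reshape(H, W)[: b_sub.shape[0], : b_sub.shape[1]]
        )
        r_rand[it] = _pearson(av, shuffled[m_sub])

    n_ge = int((r_rand >= r_obs).sum())
    p = (1 + n_ge) / (n_rand + 1)
    mean_r = float(r_rand.mean())
    return ColocResult(
        pearson_r=r_obs,
        n_randomizations=n_rand,
        rand_mean_r=mean_r,
        rand_sd_r=float(r_rand.std(ddof=1)),
        p_value=float(p),
        fold_over_random=float(r_obs / mean_r) if mean_r > 0 else float("nan"),
    )
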