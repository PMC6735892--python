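"""QIBC image generator: nuclei, stage-dependent intensities, planted foci.

Geometry is deliberately minimal — nuclei are non-overlapping disks and
foci are isotropic Gaussian spots — so that every downstream measurement
(segmentation, gating, spot detection, colocalization) has an analytic
ground truth.  Stage-dependent DAPI integrated intensity interpolates
between the 2N and 4N modes across S phase; EdU per-pixel intensity is
high in S stages only; channel-B foci are planted on top of channel-A
foci with probability ``coloc_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cfskit.errors import GenerationError, ParameterError

STAGES = ("G1", "earlyS", "midS", "lateS", "G2")

# Position of each stage along the 2N -> 4N DNA-content axis.
_STAGE_FRACTION = {"G1": 0.0, "earlyS": 0.25, "midS": 0.5, "lateS": 0.75, "G2": 1.0}
_S_STAGES = ("earlyS", "midS", "lateS")


def _default_stage_mix() -> dict[str, float]:
    # Asynchronous cycling population: large G1, modest S compartments, G2 bulge.
    return {"G1": 0.40, "earlyS": 0.12, "midS": 0.12, "lateS": 0.11, "G2": 0.25}


def _default_foci_rates() -> dict[str, float]:
    # FANCD2/ATRX-like pattern: foci rise through S and peak in late S / G2.
    return {"G1": 1.0, "earlyS": 2.0, "midS": 3.0, "lateS": 5.0, "G2": 6.0}


@dataclass(frozen=True)
class ImageSimParams:
    n_cells: int = 700
    stage_mix: dict[str, float] = field(default_factory=_default_stage_mix)
    dapi_2n_mean: float = 1000.0  # integrated intensity (a.u. * px)
    dapi_4n_mean: float = 2000.0
    dapi_cv: float = 0.06
    edu_pos_mean: float = 1.0  # per-pixel within the nucleus
    edu_neg_mean: float = 0.05
    foci_rate_per_stage: dict[str, float] = field(default_factory=_default_foci_rates)
    coloc_fraction: float = 0.3
    spot_sigma_px: float = 1.5
    spot_amplitude: float = 1.0
    min_focus_sep_px: float = 5.0  # planted foci are optically resolvable
    noise_sd: float = 0.02
    image_shape: tuple[int, int] = (2048, 2048)
    nucleus_radius_px: float = 16.0
    micronucleus_prob: float = 0.0
    micronucleus_radius_px: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if set(self.stage_mix) != set(STAGES):
            raise ParameterError(f"stage_mix must cover exactly {STAGES}")
        total = sum(self.stage_mix.values())
        if not np.isclose(total, 1.0):
            raise ParameterError(f"stage_mix must sum to 1, got {total}")
        if any(v < 0 for v in self.stage_mix.values()):
            raise ParameterError("stage_mix proportions must be >= 0")
        if self.dapi_4n_mean <= self.dapi_2n_mean:
            raise ParameterError("dapi_4n_mean must exceed dapi_2n_mean")
        if not 0 <= self.coloc_fraction <= 1:
            raise ParameterError("coloc_fraction must lie in [0, 1]")
        if not 0 <= self.micronucleus_prob <= 1:
            raise ParameterError("micronucleus_prob must lie in [0, 1]")
        if set(self.foci_rate_per_stage) != set(STAGES):
            raise ParameterError(f"foci_rate_per_stage must cover exactly {STAGES}")
        if any(v < 0 for v in self.foci_rate_per_stage.values()):
            raise ParameterError("foci rates must be >= 0")
        if self.noise_sd < 0 or self.spot_sigma_px <= 0:
            raise ParameterError("noise_sd >= 0 and spot_sigma_px > 0 required")


@dataclass
class NucleusTruth:
    """Ground truth for one generated nucleus."""

    cell_id: int
    center: tuple[float, float]  # (row, col)
    radius: float
    stage: str
    dapi_total: float
    edu_level: float
    a_foci: np.ndarray  # (n, 2) planted centroids, (row, col)
    b_foci: np.ndarray
    b_coloc: np.ndarray  # bool per B focus: planted on an A focus
    micronucleus_center: tuple[float, float] | None = None


@dataclass
class ChannelImages:
    dapi: np.ndarray
    edu: np.ndarray
    chan_a: np.ndarray
    chan_b: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "dapi": self.dapi,
            "edu": self.edu,
            "chan_a": self.chan_a,
            "chan_b": self.chan_b,
        }


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    radius: float,
    margin: float,
    max_tries_per_cell: int = 400,
) -> np.ndarray:
    """Rejection-sample non-overlapping disk centers."""
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise GenerationError("image_shape too small for the nucleus radius")
    centers: list[tuple[float, float]] = []
    min_dist = 2 * radius + 4
    tries = 0
    while len(centers) < n:
        tries += 1
        if tries > max_tries_per_cell * max(n, 1):
            raise GenerationError(
                f"could not place {n} non-overlapping nuclei in {shape}"
            )
        cand = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if all(
            (cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_dist**2
            for r, c in centers
        ):
            centers.append(cand)
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _disk_patch(shape, center, radius):
    """Boolean disk and its (row, col) slice, clipped to the image."""
    r0 = max(int(np.floor(center[0] - radius)) - 1, 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 2, shape[0])
    c0 = max(int(np.floor(center[1] - radius)) - 1, 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 2, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return disk, (slice(r0, r1), slice(c0, c1))


def _add_gaussian_spot(img, center, sigma, amplitude):
    half = int(np.ceil(4 * sigma))
    r0 = max(int(round(center[0])) - half, 0)
    r1 = min(int(round(center[0])) + half + 1, img.shape[0])
    c0 = max(int(round(center[1])) - half, 0)
    c1 = min(int(round(center[1])) + half + 1, img.shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


def gen_foci_images(
    params: ImageSimParams,
) -> tuple[ChannelImages, list[NucleusTruth]]:
    """Render DAPI/EdU/channel-A/channel-B rasters plus per-cell truth."""
    rng = np.random.default_rng(params.seed)
    shape = tuple(params.image_shape)
    radius = params.nucleus_radius_px

    margin = radius + 4 * params.micronucleus_radius_px + 6
    centers = _place_centers(rng, params.n_cells, shape, radius, margin)

    stage_names = list(STAGES)
    probs = np.array([params.stage_mix[s] for s in stage_names])
    stages = rng.choice(stage_names, size=params.n_cells, p=probs)

    dapi = np.zeros(shape)
    edu = np.zeros(shape)
    chan_a = np.zeros(shape)
    chan_b = np.zeros(shape)

    truths: list[NucleusTruth] = []
    for i in range(params.n_cells):
        center = tuple(centers[i])
        stage = str(stages[i])
        frac = _STAGE_FRACTION[stage]
        dapi_mean = params.dapi_2n_mean + frac * (
            params.dapi_4n_mean - params.dapi_2n_mean
        )
        dapi_total = dapi_mean * max(
            1.0 + params.dapi_cv * rng.standard_normal(), 0.1
        )
        edu_mean = params.edu_pos_mean if stage in _S_STAGES else params.edu_neg_mean
        edu_level = edu_mean * max(1.0 + 0.1 * rng.standard_normal(), 0.05)

        disk, sl = _disk_patch(shape, center, radius)
        area = int(disk.sum())
        dapi[sl][disk] += dapi_total / area
        edu[sl][disk] += edu_level

        rate = params.foci_rate_per_stage[stage]
        inner = max(radius - 3 * params.spot_sigma_px, 1.0)

        def _spots(k):
            # uniform in the inner disk with a minimum pairwise separation
            # (best effort: after bounded retries a crowded spot is accepted)
            placed: list[tuple[float, float]] = []
            min_sep2 = params.min_focus_sep_px**2
            for _ in range(k):
                for _try in range(60):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = inner * np.sqrt(rng.uniform())
                    cand = (center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang))
                    if all(
                        (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_sep2
                        for p in placed
                    ):
                        break
                placed.append(cand)
            return np.asarray(placed, dtype=float).reshape(len(placed), 2)

        a_foci = _spots(rng.poisson(rate))
        n_b = rng.poisson(rate)
        b_coloc = np.zeros(n_b, dtype=bool)
        b_foci = _spots(n_b)
        if len(a_foci):
            take = rng.random(n_b) < params.coloc_fraction
            idx = rng.integers(0, len(a_foci), size=n_b)
            b_foci[take] = a_foci[idx[take]]
            b_coloc = take
        for pos in a_foci:
            _add_gaussian_spot(chan_a, pos, params.spot_sigma_px, params.spot_amplitude)
        for pos in b_foci:
            _add_gaussian_spot(chan_b, pos, params.spot_sigma_px, params.spot_amplitude)

        mn_center = None
        if rng.random() < params.micronucleus_prob:
            ang = rng.uniform(0, 2 * np.pi)
            dist = radius + 2 * params.micronucleus_radius_px + 2
            mn_center = (
                center[0] + dist * np.sin(ang),
                center[1] + dist * np.cos(ang),
            )
            mn_disk, mn_sl = _disk_patch(shape, mn_center, params.micronucleus_radius_px)
            dapi[mn_sl][mn_disk] += dapi_total / area  # same per-pixel brightness

        truths.append(
            NucleusTruth(
                cell_id=i + 1,
                center=center,
                radius=radius,
                stage=stage,
                dapi_total=dapi_total,
                edu_level=edu_level,
                a_foci=a_foci,
                b_foci=b_foci,
                b_coloc=b_coloc,
                micronucleus_center=mn_center,
            )
        )

    if params.noise_sd > 0:
        for img in (dapi, edu, chan_a, chan_b):
            img += rng.normal(0, params.noise_sd, size=shape)
            np.clip(img, 0, None, out=img)

    return ChannelImages(dapi=dapi, edu=edu, chan_a=chan_a, chan_b=chan_b), truths


def truth_to_frame(truths: list[NucleusTruth]):
    """Per-cell truth summary as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in truths],
            "row": [t.center[0] for t in truths],
            "col": [t.center[1] for t in truths],
            "stage": [t.stage for t in truths],
            "dapi_total": [t.dapi_total for t in truths],
            "edu_level": [t.edu_level for t in truths],
            "n_a_foci": [len(t.a_foci) for t in truths],
            "n_b_foci": [len(t.b_foci) for t in truths],
            "n_b_coloc": [int(t.b_coloc.sum()) for t in truths],
            "has_micronucleus": [t.micronucleus_center is not None for t in truths],
        }
    )
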