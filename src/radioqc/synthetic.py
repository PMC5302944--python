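"""Synthetic-data generators with ground truth for every pipeline stage.

The generators emulate the study conditions of a clinical-beam QC
experiment: clonogenic survival tables with Poisson colony noise, a
right-skewed nuclear cross-sectional area sample (mean ~90 um^2), FNTD
track-spot planes at clinical fluences (~2.8-3.8e6 particles/cm^2) with a
bimodal primary/fragment count-rate distribution, a two-channel cell layer
(nuclear stain + DNA-damage foci placed along tracks after a global ~3 um
nuclear translation), and gamma-H2AX focus time courses with an
LET-dependent residual fraction.

Every generator is deterministic given a seed and supports a noise-free
mode that emits exact expected values, so downstream estimators can be
tested against closed forms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from radioqc.beams import BeamQuality
from radioqc.fntd import FntdImage
from radioqc.survival import SurvivalData

__all__ = [
    "FNTD_PIXEL_SIZE_UM",
    "FNTD_FIELD_UM",
    "FNTD_DWELL_TIME_US",
    "CELL_PIXEL_SIZE_UM",
    "DEFAULT_RATE_DISTRIBUTIONS",
    "SyntheticGroundTruth",
    "CellLayerScenario",
    "generate_survival_table",
    "generate_nuclear_areas",
    "generate_fntd_image",
    "generate_cell_layer",
    "generate_timecourse",
    "expected_timecourse",
]

# FNTD read-out geometry: 212.55 x 212.55 um^2 imaged as 1800 x 1800 pixels,
# 7.2 us pixel dwell time in photon-counting mode.
FNTD_FIELD_UM = 212.55
FNTD_PIXEL_SIZE_UM = FNTD_FIELD_UM / 1800.0
FNTD_DWELL_TIME_US = 7.2

# Widefield cell-layer quantification geometry (foci scoring): 322 nm pixels.
CELL_PIXEL_SIZE_UM = 0.322

# Primary / fragment APD count-rate Gaussians (mean MHz, sd MHz) calibrated so
# the between-class-variance split of the mixture lands at the clinical
# classification thresholds (5.3 MHz carbon, 4.4 MHz oxygen).
DEFAULT_RATE_DISTRIBUTIONS = {
    "carbon": {"primary": (7.2, 0.7), "fragment": (3.4, 0.7)},
    "oxygen": {"primary": (6.0, 0.6), "fragment": (2.8, 0.6)},
}
DEFAULT_FRAGMENT_FRACTION = 0.08
DEFAULT_BACKGROUND_FOCI = 0.16  # background foci per nucleus
DEFAULT_NUCLEAR_MEAN_AREA = 89.5  # um^2
DEFAULT_NUCLEAR_CV = 0.3


@dataclass
class SyntheticGroundTruth:
    """Ground truth emitted by the image generators.

    All positions are in um in the same frame as the rendered images
    (pixel-centre convention).  ``focus_sources`` holds, per ground-truth
    focus, the index of the originating track spot or -1 for background foci.
    """

    spot_positions: np.ndarray | None = None  # (n, 2) x, y um
    spot_classes: list | None = None  # "primary" | "fragment"
    spot_rates: np.ndarray | None = None  # MHz
    nucleus_masks: np.ndarray | None = None  # label image
    focus_positions: np.ndarray | None = None  # (m, 2) x, y um
    focus_nucleus_ids: np.ndarray | None = None
    focus_sources: np.ndarray | None = None
    translation: tuple | None = None  # (dx, dy) um
    survival_params: dict | None = None
    residual_fraction: float | None = None

    def __post_init__(self):
        if self.residual_fraction is not None and not (0.0 <= self.residual_fraction <= 1.0):
            raise ValueError("residual_fraction must be in [0, 1]")


@dataclass
class CellLayerScenario:
    """Two-channel synthetic cell-layer stack with ground truth."""

    dapi: np.ndarray  # (n_planes, H, W) nuclear stain
    foci: np.ndarray  # (n_planes, H, W) damage-focus channel
    pixel_size: float
    truth: SyntheticGroundTruth
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# clonogenic survival
# ---------------------------------------------------------------------------

def generate_survival_table(
    alpha: float,
    beta: float,
    doses,
    cells_seeded=None,
    plating_efficiency: float = 0.7,
    n_replicates: int = 3,
    seed=None,
    noise: bool = True,
    quality: BeamQuality | None = None,
) -> SurvivalData:
    """Simulate a clonogenic-survival table under the LQ model.

    Expected colonies per well are ``cells_seeded * PE * exp(-a*D - b*D**2)``;
    with ``noise=True`` counts are Poisson (colonies with > 50 cells counted
    as survivors: pure counting statistics), and surviving fractions are
    normalised to the observed plating efficiency of the 0 Gy control wells.
    Wells with zero colonies are replaced by half a colony with a warning so
    log-survival stays finite.

    ``cells_seeded`` may be a scalar, a per-dose sequence, or ``None`` for
    automatic per-dose seeding targeting ~150 colonies per well (seeding
    more cells at higher doses, as the assay is run in practice).
    """
    for name, v in (("alpha", alpha), ("beta", beta), ("plating_efficiency", plating_efficiency)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    if not (0 < plating_efficiency <= 1):
        raise ValueError("plating_efficiency must be in (0, 1]")
    doses = np.asarray(doses, dtype=float)
    if doses.ndim != 1 or doses.size == 0 or np.any(doses < 0) or not np.all(np.isfinite(doses)):
        raise ValueError("doses must be finite and >= 0")
    if 0.0 not in doses:
        doses = np.concatenate([[0.0], doses])
    doses = np.sort(doses)
    sf_true = np.exp(-alpha * doses - beta * doses**2)

    if not noise:
        dose_col = np.repeat(doses, n_replicates)
        sf_col = np.repeat(sf_true, n_replicates)
        rep_col = np.tile(np.arange(n_replicates), doses.size)
        return SurvivalData(dose_col, sf_col, rep_col, quality=quality)

    rng = np.random.default_rng(seed)
    if cells_seeded is None:
        cells = np.ceil(150.0 / (plating_efficiency * sf_true)).astype(int)
        cells = np.maximum(cells, 50)
    else:
        cells = np.broadcast_to(np.asarray(cells_seeded, dtype=int), doses.shape).copy()
        if np.any(cells < 1):
            raise ValueError("cells_seeded must be >= 1")

    expected = cells * plating_efficiency * sf_true
    colonies = rng.poisson(np.repeat(expected, n_replicates)).reshape(doses.size, n_replicates)
    ctrl = colonies[doses == 0.0]
    pe_hat = ctrl.mean() / cells[doses == 0.0].mean()
    if pe_hat <= 0:
        raise ValueError("no colonies in the 0 Gy control wells: cannot normalise")
    denom = cells[:, None] * pe_hat
    zero = colonies == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} wells with zero colonies replaced by 0.5 colonies",
            stacklevel=2,
        )
    sf = np.where(zero, 0.5, colonies) / denom
    dose_col = np.repeat(doses, n_replicates)
    rep_col = np.tile(np.arange(n_replicates), doses.size)
    return SurvivalData(dose_col, sf.ravel(), rep_col, quality=quality)


# ---------------------------------------------------------------------------
# nuclear areas
# ---------------------------------------------------------------------------

def generate_nuclear_areas(
    n: int,
    mean_area: float = DEFAULT_NUCLEAR_MEAN_AREA,
    cv: float = DEFAULT_NUCLEAR_CV,
    seed=None,
) -> np.ndarray:
    """Sample nuclear cross-sectional areas (um^2) from a log-normal law.

    The log-normal is parameterised by its arithmetic mean and coefficient of
    variation: ``sigma^2 = ln(1 + cv^2)``, ``mu = ln(mean) - sigma^2/2``.
    ``cv = 0`` degenerates to a point mass at ``mean_area``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_area <= 0 or not math.isfinite(mean_area):
        raise ValueError("mean_area must be finite and > 0")
    if cv < 0 or not math.isfinite(cv) or cv > 10:
        raise ValueError("cv must be finite, >= 0 and modest (<= 10)")
    if cv == 0:
        return np.full(n, float(mean_area))
    sigma2 = math.log1p(cv**2)
    mu = math.log(mean_area) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


# ---------------------------------------------------------------------------
# FNTD plane
# ---------------------------------------------------------------------------

def _render_gaussian_spots(shape, positions_px, amplitudes, sigma_px):
    """Additively render isotropic Gaussian blobs in local windows."""
    img = np.zeros(shape, dtype=float)
    half = max(int(np.ceil(4 * sigma_px)), 2)
    h, w = shape
    for (cx, cy), amp in zip(positions_px, amplitudes):
        r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        r0c, r1c = max(r0, 0), min(r1, h)
        c0c, c1c = max(c0, 0), min(c1, w)
        if r0c >= r1c or c0c >= c1c:
            continue
        rr = np.arange(r0c, r1c)[:, None]
        cc = np.arange(c0c, c1c)[None, :]
        img[r0c:r1c, c0c:c1c] += amp * np.exp(
            -((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * sigma_px**2)
        )
    return img


def generate_fntd_image(
    fluence: float,
    field_um: tuple[float, float] = (FNTD_FIELD_UM, FNTD_FIELD_UM),
    pixel_size: float = FNTD_PIXEL_SIZE_UM,
    spot_sigma: float = 0.3,
    primary_rate_dist: tuple[float, float] | None = None,
    fragment_rate_dist: tuple[float, float] | None = None,
    fragment_fraction: float = DEFAULT_FRAGMENT_FRACTION,
    species: str = "carbon",
    dwell_time: float = FNTD_DWELL_TIME_US,
    background_offset: float = 5.0,
    noise_sigma: float = 2.5,
    seed=None,
    noise: bool = True,
    positions=None,
) -> tuple[FntdImage, SyntheticGroundTruth]:
    """Render a synthetic FNTD track-spot plane with ground truth.

    The number of spots is Poisson(fluence x field area); positions are
    uniform over the field.  Each spot is an isotropic Gaussian blob whose
    peak photon count encodes its APD count rate (rate [MHz] x dwell time
    [us]), with class-specific rate Gaussians (defaults per ``species``,
    calibrated to the clinical classification thresholds).  ``positions``
    (um) overrides the Poisson placement for constructed test scenes.
    ``noise=False`` renders the exact expected image (no pixel noise).
    """
    if fluence < 0:
        raise ValueError("fluence must be >= 0")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    fx, fy = field_um
    w, h = int(round(fx / pixel_size)), int(round(fy / pixel_size))
    if w < 1 or h < 1:
        raise ValueError("field smaller than one pixel")
    if primary_rate_dist is None:
        primary_rate_dist = DEFAULT_RATE_DISTRIBUTIONS[species]["primary"]
    if fragment_rate_dist is None:
        fragment_rate_dist = DEFAULT_RATE_DISTRIBUTIONS[species]["fragment"]
    for mean, sd in (primary_rate_dist, fragment_rate_dist):
        if mean < 0 or sd < 0:
            raise ValueError("rate distributions must be non-negative")
    if not (0 <= fragment_fraction <= 1):
        raise ValueError("fragment_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    if positions is None:
        area_cm2 = (fx * 1e-4) * (fy * 1e-4)
        n_spots = int(rng.poisson(fluence * area_cm2))
        pos = np.column_stack([rng.uniform(0, fx, n_spots), rng.uniform(0, fy, n_spots)])
    else:
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        n_spots = len(pos)

    is_fragment = rng.random(n_spots) < fragment_fraction
    rates = np.where(
        is_fragment,
        rng.normal(*fragment_rate_dist, n_spots),
        rng.normal(*primary_rate_dist, n_spots),
    )
    rates = np.clip(rates, 0.1, None)
    classes = ["fragment" if f else "primary" for f in is_fragment]

    amplitudes = rates * dwell_time  # peak photon counts
    img = background_offset + _render_gaussian_spots(
        (h, w), pos / pixel_size, amplitudes, spot_sigma / pixel_size
    )
    if noise:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
        img = np.clip(img, 0.0, None)

    image = FntdImage(
        data=img,
        pixel_size=pixel_size,
        dwell_time=dwell_time,
        tags={"species": species, "fluence_per_cm2": fluence},
    )
    truth = SyntheticGroundTruth(
        spot_positions=pos,
        spot_classes=classes,
        spot_rates=rates,
    )
    return image, truth


# ---------------------------------------------------------------------------
# cell layer
# ---------------------------------------------------------------------------

def _place_ellipses(rng, areas, field_um, max_retries=1000):
    """Rejection-sample non-overlapping axis-aligned ellipses.

    Eccentricity is uniform in [0, 0.6]; ellipses are kept fully inside the
    field.  Raises if a nucleus cannot be placed within ``max_retries``.
    """
    fx, fy = field_um
    placed = []  # (cx, cy, a, b)
    for i, area in enumerate(areas):
        ecc = rng.uniform(0.0, 0.6)
        axis_ratio = math.sqrt(1.0 - ecc**2)
        a = math.sqrt(area / (math.pi * axis_ratio))
        b = a * axis_ratio
        if 2 * a >= min(fx, fy):
            raise ValueError(f"nucleus {i} larger than the field")
        for _ in range(max_retries):
            cx = rng.uniform(a, fx - a)
            cy = rng.uniform(a, fy - a)
            ok = all(
                (cx - px) ** 2 + (cy - py) ** 2 > (a + pa) ** 2
                for px, py, pa, _ in placed
            )
            if ok:
                placed.append((cx, cy, a, b))
                break
        else:
            raise ValueError(
                f"could not place nucleus {i + 1}/{len(areas)} without overlap "
                f"after {max_retries} retries; reduce count or enlarge field"
            )
    return placed


def generate_cell_layer(
    nuclei,
    field_um: tuple[float, float] = (100.0, 100.0),
    tracks: SyntheticGroundTruth | None = None,
    foci_per_track: float = 1.0,
    focus_radius: float = 0.5,
    background_foci_rate: float = DEFAULT_BACKGROUND_FOCI,
    translation: tuple[float, float] = (3.0, 0.0),
    pixel_size: float = CELL_PIXEL_SIZE_UM,
    n_planes: int = 5,
    focus_jitter: float = 0.0,
    nucleus_mean_area: float = DEFAULT_NUCLEAR_MEAN_AREA,
    nucleus_cv: float = DEFAULT_NUCLEAR_CV,
    seed=None,
    noise: bool = True,
    poisson_foci: bool = True,
    nucleus_centers=None,
) -> CellLayerScenario:
    """Render a two-channel cell-layer stack registered to a track plane.

    ``nuclei`` is either a nucleus count (areas drawn log-normally) or an
    explicit area list (um^2); ``nucleus_centers`` optionally pins the
    centres (um) instead of random non-overlapping placement.  The nuclear-stain channel contains
    non-overlapping ellipses; the focus channel contains disc-like foci at
    ``track position + translation`` for each primary track landing inside a
    nucleus (focus count per track ~ Poisson(``foci_per_track``)), plus
    Poisson background foci per nucleus.  The translation models the nuclear
    movement (~3 um) between detector and cell-layer read-out.
    """
    if foci_per_track < 0 or background_foci_rate < 0:
        raise ValueError("rates must be >= 0")
    if focus_radius <= 0:
        raise ValueError("focus_radius must be > 0")
    rng = np.random.default_rng(seed)
    if np.isscalar(nuclei):
        areas = generate_nuclear_areas(int(nuclei), nucleus_mean_area, nucleus_cv,
                                       seed=rng.integers(2**31))
    else:
        areas = np.asarray(nuclei, dtype=float)
    if nucleus_centers is None:
        ellipses = _place_ellipses(rng, areas, field_um)
    else:
        centers = np.atleast_2d(np.asarray(nucleus_centers, dtype=float))
        if len(centers) != len(areas):
            raise ValueError("nucleus_centers must match the number of nuclei")
        ellipses = []
        for (cx, cy), area in zip(centers, areas):
            ecc = rng.uniform(0.0, 0.6)
            axis_ratio = math.sqrt(1.0 - ecc**2)
            a = math.sqrt(area / (math.pi * axis_ratio))
            ellipses.append((cx, cy, a, a * axis_ratio))

    fx, fy = field_um
    w, h = int(round(fx / pixel_size)), int(round(fy / pixel_size))
    xx = np.arange(w)[None, :] * pixel_size
    yy = np.arange(h)[:, None] * pixel_size
    labels = np.zeros((h, w), dtype=np.int32)
    for lab, (cx, cy, a, b) in enumerate(ellipses, start=1):
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        labels[inside] = lab

    # nuclear-stain channel
    dapi_amp = 100.0 * rng.uniform(0.8, 1.2, len(ellipses)) if noise else np.full(len(ellipses), 100.0)
    plane = np.zeros((h, w), dtype=float)
    for lab in range(1, len(ellipses) + 1):
        plane[labels == lab] = dapi_amp[lab - 1]
    plane = gaussian_filter(plane, 1.0)
    z_profile = _z_profile(n_planes)
    dapi = plane[None, :, :] * z_profile[:, None, None] + 10.0
    if noise:
        dapi = dapi + rng.normal(0.0, 2.0, dapi.shape)
        dapi = np.clip(dapi, 0.0, None)

    # foci: track-induced + background
    focus_pos: list[tuple[float, float]] = []
    focus_nuc: list[int] = []
    focus_src: list[int] = []
    dx, dy = translation
    if tracks is not None and tracks.spot_positions is not None and foci_per_track > 0:
        for idx, (sx, sy) in enumerate(np.atleast_2d(tracks.spot_positions)):
            if tracks.spot_classes is not None and tracks.spot_classes[idx] == "fragment":
                continue
            qx, qy = sx + dx, sy + dy
            col, row = int(round(qx / pixel_size)), int(round(qy / pixel_size))
            if not (0 <= row < h and 0 <= col < w):
                continue
            lab = int(labels[row, col])
            if lab == 0:
                continue
            n_f = rng.poisson(foci_per_track) if poisson_foci else int(round(foci_per_track))
            for _ in range(n_f):
                jx, jy = (rng.normal(0.0, focus_jitter, 2) if focus_jitter > 0 else (0.0, 0.0))
                focus_pos.append((qx + jx, qy + jy))
                focus_nuc.append(lab)
                focus_src.append(idx)
    if background_foci_rate > 0 and noise:
        for lab, (cx, cy, a, b) in enumerate(ellipses, start=1):
            for _ in range(rng.poisson(background_foci_rate)):
                while True:
                    px = rng.uniform(cx - a, cx + a)
                    py = rng.uniform(cy - b, cy + b)
                    if ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 <= 0.8:
                        break
                focus_pos.append((px, py))
                focus_nuc.append(lab)
                focus_src.append(-1)

    foci_plane = np.zeros((h, w), dtype=float)
    r_px = focus_radius / pixel_size
    for fx_um, fy_um in focus_pos:
        c0, r0 = fx_um / pixel_size, fy_um / pixel_size
        half = int(np.ceil(r_px)) + 2
        rr0, rr1 = max(int(r0) - half, 0), min(int(r0) + half + 1, h)
        cc0, cc1 = max(int(c0) - half, 0), min(int(c0) + half + 1, w)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        rr = np.arange(rr0, rr1)[:, None]
        cc = np.arange(cc0, cc1)[None, :]
        amp = 80.0 * (rng.uniform(0.8, 1.2) if noise else 1.0)
        foci_plane[rr0:rr1, cc0:cc1] += amp * (
            ((rr - r0) ** 2 + (cc - c0) ** 2) <= r_px**2
        )
    foci_plane = gaussian_filter(foci_plane, 0.5)
    foci_z = _z_profile(n_planes, sharp=True)
    foci_stack = foci_plane[None, :, :] * foci_z[:, None, None] + 5.0
    if noise:
        foci_stack = foci_stack + rng.normal(0.0, 1.5, foci_stack.shape)
        foci_stack = np.clip(foci_stack, 0.0, None)

    truth = SyntheticGroundTruth(
        spot_positions=None if tracks is None else tracks.spot_positions,
        spot_classes=None if tracks is None else tracks.spot_classes,
        nucleus_masks=labels,
        focus_positions=np.asarray(focus_pos, dtype=float).reshape(-1, 2),
        focus_nucleus_ids=np.asarray(focus_nuc, dtype=int),
        focus_sources=np.asarray(focus_src, dtype=int),
        translation=(dx, dy),
    )
    params = {
        "field_um": tuple(field_um),
        "pixel_size": pixel_size,
        "foci_per_track": foci_per_track,
        "focus_radius": focus_radius,
        "background_foci_rate": background_foci_rate,
    }
    return CellLayerScenario(dapi=dapi, foci=foci_stack, pixel_size=pixel_size,
                             truth=truth, params=params)


def _z_profile(n_planes: int, sharp: bool = False) -> np.ndarray:
    """Axial intensity profile across the stack (central plane brightest)."""
    z = np.arange(n_planes) - (n_planes - 1) / 2.0
    width = (n_planes / 6.0) if sharp else (n_planes / 3.0)
    return np.exp(-(z**2) / (2.0 * max(width, 0.5) ** 2))


# ---------------------------------------------------------------------------
# repair time course
# ---------------------------------------------------------------------------

def expected_timecourse(initial_mean_foci, residual_fraction, halflife, t):
    """Expected foci per nucleus at time t (hours) post irradiation.

    A fraction ``residual_fraction`` of initial foci never resolves; the rest
    decays exponentially with the given half-life:
    ``initial * (r + (1 - r) * 2**(-t / halflife))``.
    """
    t = np.asarray(t, dtype=float)
    return initial_mean_foci * (
        residual_fraction + (1.0 - residual_fraction) * 2.0 ** (-t / halflife)
    )


def generate_timecourse(
    initial_mean_foci: float = 20.0,
    residual_fraction: float = 0.153,
    halflife: float = 6.0,
    timepoints=(0.5, 12.0, 24.0, 72.0),
    n_nuclei: int = 150,
    background_per_nucleus: float = DEFAULT_BACKGROUND_FOCI,
    seed=None,
    noise: bool = True,
) -> dict[float, np.ndarray]:
    """Per-nucleus focus counts at each timepoint of a repair time course.

    Counts are Poisson around the expected radiation-induced value plus an
    independent Poisson background per nucleus.  ``noise=False`` returns the
    exact expected values instead of counts.  The default residual fraction
    corresponds to a high-LET carbon-like beam.
    """
    if not (0.0 <= residual_fraction <= 1.0):
        raise ValueError("residual_fraction must be in [0, 1]")
    if halflife <= 0:
        raise ValueError("halflife must be > 0")
    if initial_mean_foci < 0 or background_per_nucleus < 0:
        raise ValueError("means must be >= 0")
    timepoints = np.asarray(timepoints, dtype=float)
    if np.any(timepoints < 0):
        raise ValueError("timepoints must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[float, np.ndarray] = {}
    for t in timepoints:
        mu = float(expected_timecourse(initial_mean_foci, residual_fraction, halflife, t))
        if noise:
            counts = rng.poisson(mu, n_nuclei) + rng.poisson(background_per_nucleus, n_nuclei)
            out[float(t)] = counts
        else:
            out[float(t)] = np.full(n_nuclei, mu + background_per_nucleus)
    return out
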