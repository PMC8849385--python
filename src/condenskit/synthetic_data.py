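"""Synthetic microscopy inputs with known ground truth.

Every analysis stage in this package consumes data this module can generate:
Brownian single-molecule trajectories with localization error (optionally
confined to a spherical microdomain, emulating a polar condensate), fields of
round condensates over a diffuse background, FRAP movies with a bleached and
a control condensate, two-channel images of condensates containing demixed
sub-clusters, and phase-contrast-like fields of rod-shaped bacterial cells
with an optional filamentous subpopulation.

All generators are pure functions of their parameter object (which carries
the seed): identical parameters give bit-identical outputs, and noise-free
renders equal their analytic expected images exactly.

Default parameters mirror the acquisition geometry of the experiments being
emulated: 20-ms framing with ~30 nm lateral localization precision for
tracking, and 100 frames at 1-s intervals with the bleach between the third
and fourth captures for FRAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ImageStack, Roi, RoiSet, TrajectorySet

__all__ = [
    "SphereConfinement",
    "DiffusionSimParams",
    "FieldSimParams",
    "FrapSimParams",
    "PopulationSimParams",
    "TrajectorySimulation",
    "FieldSimulation",
    "FrapSimulation",
    "PopulationSimulation",
    "DemixSimulation",
    "simulate_trajectories",
    "render_condensate_field",
    "simulate_frap_movie",
    "render_cell_population",
    "render_demixed_condensates",
    "sample_cell_lengths",
    "expected_frap_trace",
]


@dataclass(frozen=True)
class SphereConfinement:
    """Elastic reflecting spherical boundary (center in μm, radius in μm)."""

    center: tuple[float, ...]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("confinement radius must be > 0")


@dataclass(frozen=True)
class DiffusionSimParams:
    """Brownian-mixture trajectory simulation parameters.

    ``d_coeffs`` lists one diffusion coefficient (μm²/s) per mixture
    component and ``fractions`` the corresponding track-level probabilities.
    ``sigma_loc_um`` is the per-axis localization error added to reported
    positions (scalar, or one value per axis).
    """

    d_coeffs: tuple[float, ...] = (0.01,)
    fractions: tuple[float, ...] = (1.0,)
    dims: int = 2
    n_tracks: int = 2000
    track_length: int = 10
    frame_interval: float = 0.02
    sigma_loc_um: float | tuple[float, ...] = 0.03
    confinement: SphereConfinement | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.d_coeffs):
            raise ValueError("diffusion coefficients must be >= 0")
        if len(self.fractions) != len(self.d_coeffs):
            raise ValueError("fractions and d_coeffs must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.track_length < 2:
            raise ValueError("track_length must be >= 2")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def sigma_per_axis(self) -> np.ndarray:
        s = np.atleast_1d(np.asarray(self.sigma_loc_um, dtype=float))
        if s.size == 1:
            s = np.full(self.dims, s[0])
        if s.size != self.dims:
            raise ValueError("sigma_loc_um must be scalar or one value per axis")
        return s


@dataclass
class TrajectorySimulation:
    """Simulated tracks plus ground truth."""

    trajectories: TrajectorySet
    component_labels: np.ndarray  # per track, index into d_coeffs
    true_positions: np.ndarray  # (n_tracks, track_length, dims), μm


def simulate_trajectories(params: DiffusionSimParams) -> TrajectorySimulation:
    """Simulate Brownian-mixture trajectories with localization error.

    Per-axis increments are independent Gaussians of variance ``2 D Δt`` for
    the track's component.  Reported positions add independent Gaussian
    localization error per axis; confined tracks reflect elastically at the
    sphere boundary.
    """
    rng = np.random.default_rng(params.seed)
    n, length, dims = params.n_tracks, params.track_length, params.dims
    labels = rng.choice(len(params.d_coeffs), size=n, p=params.fractions)
    step_sd = np.sqrt(2.0 * np.asarray(params.d_coeffs) * params.frame_interval)
    steps = rng.standard_normal((n, length - 1, dims)) * step_sd[labels, None, None]

    conf = params.confinement
    if conf is None:
        start = np.zeros((n, dims))
        true = np.concatenate(
            [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1
        )
    else:
        center = np.asarray(conf.center, dtype=float)
        if center.size != dims:
            raise ValueError("confinement center dimensionality must match dims")
        # uniform starting points inside the sphere, by rejection
        start = np.empty((n, dims))
        filled = 0
        while filled < n:
            cand = rng.uniform(-conf.radius, conf.radius, size=(2 * (n - filled), dims))
            ok = cand[np.linalg.norm(cand, axis=1) <= conf.radius]
            take = min(len(ok), n - filled)
            start[filled : filled + take] = center + ok[:take]
            filled += take
        true = np.empty((n, length, dims))
        true[:, 0] = start
        for i in range(1, length):
            pos = true[:, i - 1] + steps[:, i - 1]
            pos = _reflect_sphere(pos, center, conf.radius)
            true[:, i] = pos

    sigma = params.sigma_per_axis
    reported = true + rng.standard_normal(true.shape) * sigma

    frames = np.tile(np.arange(length), n)
    track_ids = np.repeat(np.arange(n), length)
    cols = {
        "track_id": track_ids,
        "frame": frames,
        "t_s": frames * params.frame_interval,
        "x_um": reported[:, :, 0].ravel(),
        "y_um": reported[:, :, 1].ravel(),
    }
    if dims == 3:
        cols["z_um"] = reported[:, :, 2].ravel()
    for axis, name in zip(range(dims), ("sx_um", "sy_um", "sz_um")):
        cols[name] = np.full(n * length, sigma[axis])
    trajs = TrajectorySet(
        data=pd.DataFrame(cols), frame_interval=params.frame_interval
    )
    return TrajectorySimulation(trajs, labels, true)


def _reflect_sphere(pos: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Radially reflect positions that left the sphere back inside."""
    pos = pos.copy()
    for _ in range(64):
        rel = pos - center
        r = np.linalg.norm(rel, axis=1)
        out = r > radius
        if not out.any():
            break
        pos[out] = center + rel[out] * ((2 * radius - r[out]) / r[out])[:, None]
    return pos


# ---------------------------------------------------------------------------
# condensate fields


@dataclass(frozen=True)
class FieldSimParams:
    """Parameters for rendering a field of round condensates.

    The expected intensity inside condensate *i* is
    ``background * (1 + E_i)`` and ``background`` outside, so the configured
    enrichment equals the analysis-side score exactly on the truth mask of a
    noise-free render.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    n_condensates: int = 50
    radius_range_um: tuple[float, float] = (0.4, 0.9)
    background: float = 100.0
    enrichment: float | tuple[float, ...] = 3.0
    poisson_noise: bool = True
    read_noise_sd: float = 0.0
    seed: int = 0
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if not self.background > 0:
            raise ValueError("background must be > 0")
        e = np.atleast_1d(np.asarray(self.enrichment, dtype=float))
        if np.any(e < -1):
            raise ValueError("enrichment must be >= -1")
        rmax_px = self.radius_range_um[1] / self.pixel_size_um
        if 2 * rmax_px >= min(self.image_size):
            raise ValueError("condensate radii do not fit in the field")


@dataclass
class FieldSimulation:
    stack: ImageStack
    label_mask: np.ndarray  # int labels, 0 = background
    table: pd.DataFrame  # label, cy_px, cx_px, radius_um, enrichment_true


def _place_disks(
    rng: np.random.Generator,
    image_size: tuple[int, int],
    radii_px: np.ndarray,
    max_tries: int,
    margin_px: float = 2.0,
) -> np.ndarray:
    """Sample non-overlapping disk centers; raises if placement fails."""
    ny, nx = image_size
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii_px):
        for attempt in range(max_tries):
            cy = rng.uniform(r + 1, ny - r - 1)
            cx = rng.uniform(r + 1, nx - r - 1)
            ok = all(
                np.hypot(cy - oy, cx - ox) > r + radii_px[j] + margin_px
                for j, (oy, ox) in enumerate(centers)
            )
            if ok:
                centers.append((cy, cx))
                break
        else:
            raise RuntimeError(
                f"could not place condensate {i} without overlap "
                f"after {max_tries} tries; lower n_condensates or radii"
            )
    return np.asarray(centers)


def _apply_noise(
    expected: np.ndarray,
    rng: np.random.Generator,
    poisson: bool,
    read_noise_sd: float,
) -> np.ndarray:
    out = rng.poisson(expected).astype(float) if poisson else expected.astype(float)
    if read_noise_sd > 0:
        out = out + rng.normal(0.0, read_noise_sd, size=out.shape)
    return out


def render_condensate_field(params: FieldSimParams) -> FieldSimulation:
    """Render one field of non-overlapping condensate disks with noise."""
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_size
    n = params.n_condensates
    radii_um = rng.uniform(*params.radius_range_um, size=n)
    radii_px = radii_um / params.pixel_size_um
    centers = _place_disks(rng, params.image_size, radii_px, params.max_place_tries)

    e = np.atleast_1d(np.asarray(params.enrichment, dtype=float))
    e_true = np.full(n, e[0]) if e.size == 1 else e
    if e_true.size != n:
        raise ValueError("enrichment must be scalar or one value per condensate")

    yy, xx = np.mgrid[0:ny, 0:nx]
    labels = np.zeros((ny, nx), dtype=np.int32)
    expected = np.full((ny, nx), params.background, dtype=float)
    for i in range(n):
        cy, cx = centers[i]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radii_px[i] ** 2
        labels[disk] = i + 1
        expected[disk] = params.background * (1.0 + e_true[i])

    img = _apply_noise(expected, rng, params.poisson_noise, params.read_noise_sd)
    stack = ImageStack(pixels=img, pixel_size=params.pixel_size_um)
    table = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "cy_px": centers[:, 0],
            "cx_px": centers[:, 1],
            "radius_um": radii_um,
            "enrichment_true": e_true,
        }
    )
    return FieldSimulation(stack, labels, table)


# ---------------------------------------------------------------------------
# FRAP movies


@dataclass(frozen=True)
class FrapSimParams:
    """Parameters for a two-condensate FRAP movie.

    One condensate is bleached to depth ``bleach_depth`` between frames
    ``bleach_frame - 1`` and ``bleach_frame`` (0-based; the first post-bleach
    frame is ``bleach_frame``) and recovers a fraction ``mobile_fraction``
    with time constant ``recovery_time_s``; the other condensate carries only
    acquisition fade and serves as the control region.  The whole field sits
    on a constant camera offset.
    """

    condensate_radius_um: float = 1.0
    prebleach_level: float = 1000.0
    background_offset: float = 50.0
    bleach_depth: float = 0.9
    mobile_fraction: float = 0.6
    recovery_time_s: float = 10.0
    bleach_frame: int = 3
    n_frames: int = 100
    frame_interval: float = 1.0
    fade_rate: float = 0.0  # acquisition photobleaching, 1/s
    noise_sd: float = 0.0
    pixel_size_um: float = 0.1
    image_size: tuple[int, int] = (48, 96)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in [0, 1]")
        if not self.recovery_time_s > 0:
            raise ValueError("recovery_time_s must be > 0")
        if self.bleach_frame < 1:
            raise ValueError("bleach_frame must be >= 1 (need prebleach frames)")
        if self.bleach_frame >= self.n_frames:
            raise ValueError("bleach_frame must lie before the end of the movie")


@dataclass
class FrapSimulation:
    stack: ImageStack
    rois: RoiSet
    mobile_fraction: float
    recovery_time_s: float

    def expected_bleached_trace(self, params: FrapSimParams) -> np.ndarray:
        """Analytic expected trace of the bleached condensate (offset-free)."""
        return _frap_bleached_trace(params)


def expected_frap_trace(p: FrapSimParams) -> np.ndarray:
    """Analytic expected trace of the bleached condensate (offset-free)."""
    return _frap_bleached_trace(p)


def _frap_bleached_trace(p: FrapSimParams) -> np.ndarray:
    t = np.arange(p.n_frames) * p.frame_interval
    t_b = p.bleach_frame * p.frame_interval
    fade = np.exp(-p.fade_rate * t)
    trace = np.where(
        t < t_b,
        1.0,
        (1.0 - p.bleach_depth)
        + p.bleach_depth
        * p.mobile_fraction
        * (1.0 - np.exp(-np.clip(t - t_b, 0, None) / p.recovery_time_s)),
    )
    return p.prebleach_level * trace * fade


def simulate_frap_movie(params: FrapSimParams) -> FrapSimulation:
    """Render a FRAP movie with bleached + control condensates and its ROIs."""
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_size
    r_px = params.condensate_radius_um / params.pixel_size_um
    if 2 * r_px + 4 >= min(ny, nx / 2):
        raise ValueError("condensate does not fit in the FRAP field")
    c_bleach = (ny / 2.0, nx / 4.0)
    c_ctrl = (ny / 2.0, 3 * nx / 4.0)

    yy, xx = np.mgrid[0:ny, 0:nx]
    disk_b = (yy - c_bleach[0]) ** 2 + (xx - c_bleach[1]) ** 2 <= r_px**2
    disk_c = (yy - c_ctrl[0]) ** 2 + (xx - c_ctrl[1]) ** 2 <= r_px**2
    spot = (yy - c_bleach[0]) ** 2 + (xx - c_bleach[1]) ** 2 <= (0.6 * r_px) ** 2

    t = np.arange(params.n_frames) * params.frame_interval
    fade = np.exp(-params.fade_rate * t)
    bleached_trace = _frap_bleached_trace(params)
    control_trace = params.prebleach_level * fade

    expected = np.full((params.n_frames, ny, nx), params.background_offset)
    expected = expected + disk_b[None] * bleached_trace[:, None, None]
    expected = expected + disk_c[None] * control_trace[:, None, None]
    movie = expected.astype(float)
    if params.noise_sd > 0:
        movie = movie + rng.normal(0.0, params.noise_sd, size=movie.shape)

    bg_mask = np.zeros((ny, nx), dtype=bool)
    bg_mask[1 : max(2, ny // 8), 1 : max(2, nx // 8)] = True
    rois = RoiSet()
    rois.add("bleached", Roi(role="bleached", mask=spot))
    rois.add("whole", Roi(role="whole_condensate", mask=disk_b))
    rois.add("control", Roi(role="control", mask=disk_c))
    rois.add("background", Roi(role="background", mask=bg_mask))

    stack = ImageStack(
        pixels=movie[:, None],
        pixel_size=params.pixel_size_um,
        frame_interval=params.frame_interval,
    )
    return FrapSimulation(
        stack, rois, params.mobile_fraction, params.recovery_time_s
    )


# ---------------------------------------------------------------------------
# cell populations


@dataclass(frozen=True)
class PopulationSimParams:
    """Parameters for a phase-contrast + fluorescence cell-population field.

    Body lengths are lognormal around a ~2 μm median (typical for
    *Caulobacter*-like rods); a fraction ``filamentous_fraction`` of cells
    instead draw from a lognormal around ``filamentous_median_um`` ≫ 4 μm,
    emulating the division-defective subpopulation.  Fluorescent clusters are
    Gaussian spots at the cell poles whose peak is ``cluster_fold`` times the
    diffuse cytoplasmic level.
    """

    n_cells: int = 100
    body_median_um: float = 2.2
    body_sigma_log: float = 0.18
    filamentous_fraction: float = 0.0
    filamentous_median_um: float = 8.0
    filamentous_sigma_log: float = 0.25
    cluster_count_dist: tuple[tuple[int, float], ...] = ((1, 1.0),)
    cluster_fold: float = 5.0
    cluster_sd_px: float = 2.0
    diffuse_level: float = 100.0
    fluor_background: float = 10.0
    phase_background: float = 200.0
    phase_cell_level: float = 80.0
    cell_width_um: float = 0.7
    pixel_size_um: float = 0.1
    noise_sd: float = 0.0
    image_size: tuple[int, int] | None = None  # None = sized to fit
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.filamentous_fraction <= 1.0:
            raise ValueError("filamentous_fraction must be in [0, 1]")
        probs = [p for _, p in self.cluster_count_dist]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValueError("cluster_count_dist probabilities must sum to 1")


@dataclass
class PopulationSimulation:
    phase: ImageStack
    fluorescence: ImageStack
    cell_mask: np.ndarray  # int labels, 0 = background
    table: pd.DataFrame  # cell_id, length_um, n_clusters, ratio_true


def sample_cell_lengths(
    n: int,
    filamentous_fraction: float = 0.0,
    *,
    body_median_um: float = 2.2,
    body_sigma_log: float = 0.18,
    filamentous_median_um: float = 8.0,
    filamentous_sigma_log: float = 0.25,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Draw cell lengths (μm) from the body/filamentous lognormal mixture."""
    if rng is None:
        rng = np.random.default_rng(seed)
    fil = rng.random(n) < filamentous_fraction
    lengths = rng.lognormal(np.log(body_median_um), body_sigma_log, size=n)
    n_fil = int(fil.sum())
    if n_fil:
        lengths[fil] = rng.lognormal(
            np.log(filamentous_median_um), filamentous_sigma_log, size=n_fil
        )
    return lengths


def render_cell_population(params: PopulationSimParams) -> PopulationSimulation:
    """Render non-overlapping horizontal rod cells on a regular row layout."""
    rng = np.random.default_rng(params.seed)
    lengths = sample_cell_lengths(
        params.n_cells,
        params.filamentous_fraction,
        body_median_um=params.body_median_um,
        body_sigma_log=params.body_sigma_log,
        filamentous_median_um=params.filamentous_median_um,
        filamentous_sigma_log=params.filamentous_sigma_log,
        rng=rng,
    )
    counts, probs = zip(*params.cluster_count_dist)
    n_clusters = rng.choice(counts, size=params.n_cells, p=probs)

    px = params.pixel_size_um
    width_px = params.cell_width_um / px
    len_px = lengths / px
    gap = 6.0  # px between cells and rows
    row_h = width_px + gap

    if params.image_size is not None:
        ny, nx = params.image_size
    else:
        # size the field to fit all cells on rows of ~equal total length
        total = float(np.sum(len_px + gap))
        nx = int(max(np.max(len_px) + 2 * gap, np.sqrt(total * row_h) + 2 * gap))
        rows_needed = 0
        cursor = gap
        for L in len_px:
            if cursor + L + gap > nx:
                rows_needed += 1
                cursor = gap
            cursor += L + gap
        ny = int((rows_needed + 2) * row_h + gap)

    # lay out cells left-to-right, wrapping rows
    placements: list[tuple[float, float, float]] = []  # (cy, x0, x1) in px
    cy = gap + width_px / 2
    cursor = gap
    for L in len_px:
        if cursor + L + gap > nx:
            cy += row_h
            cursor = gap
        if cy + width_px / 2 + gap > ny or L + 2 * gap > nx:
            raise ValueError(
                "field too small to place all cells; enlarge image_size"
            )
        placements.append((cy, cursor + width_px / 2, cursor + L - width_px / 2))
        cursor += L + gap

    yy, xx = np.mgrid[0:int(ny), 0:int(nx)]
    labels = np.zeros((int(ny), int(nx)), dtype=np.int32)
    fluor = np.full((int(ny), int(nx)), params.fluor_background, dtype=float)
    spot_amp = (params.cluster_fold - 1.0) * params.diffuse_level
    records = []
    for i, ((cy_i, x0, x1), L, k) in enumerate(zip(placements, len_px, n_clusters)):
        # rod = segment (x0..x1, cy) dilated by width/2 (rectangle + caps)
        xs = np.clip(xx, x0, x1)
        dist2 = (yy - cy_i) ** 2 + (xx - xs) ** 2
        cell = dist2 <= (width_px / 2) ** 2
        labels[cell] = i + 1
        fluor[cell] = params.diffuse_level
        # clusters sit at the poles (spot centers at the segment endpoints);
        # centers snap to pixel centers so the rendered peak is exact
        spot_centers = []
        if k >= 1:
            spot_centers.append((round(cy_i), round(x0)))
        if k >= 2:
            spot_centers.append((round(cy_i), round(x1)))
        for j in range(2, k):  # extra clusters spaced along the axis
            frac = (j - 1) / max(k - 1, 1)
            spot_centers.append((round(cy_i), round(x0 + frac * (x1 - x0))))
        cluster_mask = np.zeros_like(cell)
        for (sy, sx) in spot_centers:
            g = np.exp(-(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * params.cluster_sd_px**2)))
            fluor += cell * spot_amp * g
            cluster_mask |= cell & (
                (yy - sy) ** 2 + (xx - sx) ** 2 <= (2 * params.cluster_sd_px) ** 2
            )
        mean_cell = fluor[cell].mean()
        if cluster_mask.any() and (~cluster_mask & cell).any():
            ratio_true = (
                fluor[cluster_mask].mean() - fluor[cell & ~cluster_mask].mean()
            ) / mean_cell
        else:
            ratio_true = 0.0
        records.append(
            {
                "cell_id": i + 1,
                "length_um": lengths[i],
                "n_clusters": int(k),
                "ratio_true": ratio_true,
            }
        )

    phase = np.full(labels.shape, params.phase_background, dtype=float)
    phase[labels > 0] = params.phase_cell_level
    if params.noise_sd > 0:
        phase = phase + rng.normal(0.0, params.noise_sd, size=phase.shape)
        fluor = fluor + rng.normal(0.0, params.noise_sd, size=fluor.shape)

    phase_stack = ImageStack(pixels=phase, pixel_size=px)
    fluor_stack = ImageStack(pixels=fluor, pixel_size=px)
    return PopulationSimulation(
        phase_stack, fluor_stack, labels, pd.DataFrame(records)
    )


# ---------------------------------------------------------------------------
# two-channel demixed condensates


@dataclass
class DemixSimulation:
    stack: ImageStack  # channels: ("condensate", "client")
    label_mask: np.ndarray
    table: pd.DataFrame  # label, k_true


def render_demixed_condensates(
    k_distribution: Mapping[int, float] | Sequence[tuple[int, float]],
    spot_sd_um: float,
    separation_um: float,
    params: FieldSimParams,
) -> DemixSimulation:
    """Render condensate disks (channel A) holding k Gaussian client spots
    (channel B), k drawn per condensate from ``k_distribution``.

    Spots are placed inside each disk with pairwise distance at least
    ``separation_um``; requires ``separation_um > 2 * spot_sd_um`` so that
    adjacent spots are resolvable.
    """
    if not separation_um > 2 * spot_sd_um:
        raise ValueError("separation_um must exceed 2 * spot_sd_um")
    if isinstance(k_distribution, Mapping):
        items = sorted(k_distribution.items())
    else:
        items = sorted(k_distribution)
    ks, probs = zip(*items)
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError("k_distribution probabilities must sum to 1")

    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_size
    n = params.n_condensates
    px = params.pixel_size_um
    radii_um = rng.uniform(*params.radius_range_um, size=n)
    radii_px = radii_um / px
    centers = _place_disks(rng, params.image_size, radii_px, params.max_place_tries)
    k_true = rng.choice(ks, size=n, p=probs)

    e = float(np.atleast_1d(np.asarray(params.enrichment, dtype=float))[0])
    yy, xx = np.mgrid[0:ny, 0:nx]
    labels = np.zeros((ny, nx), dtype=np.int32)
    chan_a = np.full((ny, nx), params.background, dtype=float)
    chan_b = np.full((ny, nx), params.background, dtype=float)
    spot_sd_px = spot_sd_um / px
    sep_px = separation_um / px
    spot_amp = 5.0 * params.background

    for i in range(n):
        cy, cx = centers[i]
        r = radii_px[i]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        labels[disk] = i + 1
        chan_a[disk] = params.background * (1.0 + e)
        r_inner = r - 2.0 * spot_sd_px
        if r_inner <= 0:
            raise ValueError(
                f"condensate {i} (radius {radii_um[i]:.2f} μm) too small for "
                f"spots of sd {spot_sd_um} μm"
            )
        spots = _place_spots(rng, (cy, cx), r_inner, int(k_true[i]), sep_px)
        for (sy, sx) in spots:
            chan_b += spot_amp * np.exp(
                -(((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * spot_sd_px**2))
            )

    img_a = _apply_noise(chan_a, rng, params.poisson_noise, params.read_noise_sd)
    img_b = _apply_noise(chan_b, rng, params.poisson_noise, params.read_noise_sd)
    stack = ImageStack(
        pixels=np.stack([img_a, img_b])[None],
        pixel_size=px,
        channel_names=("condensate", "client"),
    )
    table = pd.DataFrame({"label": np.arange(1, n + 1), "k_true": k_true})
    return DemixSimulation(stack, labels, table)


def _place_spots(
    rng: np.random.Generator,
    center: tuple[float, float],
    r_inner: float,
    k: int,
    sep_px: float,
    max_tries: int = 500,
) -> list[tuple[float, float]]:
    """Rejection-sample k spot centers inside a disk with min pairwise spacing."""
    cy, cx = center
    if k == 0:
        return []
    if sep_px / 2.0 > r_inner and k > 1:
        raise ValueError("spots cannot satisfy the separation inside the radius")
    for _ in range(max_tries):
        pts: list[tuple[float, float]] = []
        ok = True
        for _ in range(k):
            for _ in range(max_tries):
                ang = rng.uniform(0, 2 * np.pi)
                rad = r_inner * np.sqrt(rng.uniform())
                p = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
                if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= sep_px for q in pts):
                    pts.append(p)
                    break
            else:
                ok = False
                break
        if ok:
            return pts
    raise ValueError("spots cannot be placed with the required separation")
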