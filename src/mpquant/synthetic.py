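"""Synthetic inputs with known ground truth.

Three generators emulate the study conditions of a micropatterned
stem-cell colony experiment:

* :func:`simulate_prw_track` — single-cell trajectories whose velocity is an
  Ornstein–Uhlenbeck (OU) process, so the ensemble mean-square displacement
  follows the persistent-random-walk closed form exactly at the sampling
  interval (default 30-min sampling, 49 frames, i.e. a 24-h time lapse).
* :func:`simulate_colony` — nuclei scattered on a circular pattern with an
  annular high-density band near the perimeter, region-dependent marker
  positivity and nucleus elongation (perimeter nuclei tangentially
  oriented), mimicking the condensation ring that forms during
  epithelial–mesenchymal transition under geometric confinement.
* :func:`simulate_beating_stack` — a textured tissue disc undergoing
  periodic radial displacement (default 20 frames/s, 500 frames), returned
  together with the true per-frame displacement so downstream motion
  estimators can be checked against ground truth.

All generators are deterministic given their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .contraction import ImageStack
from .exceptions import ConfigurationError, NyquistError
from .tracks import CellTrack

NUCLEI_COLUMNS = ["nucleus_id", "x_um", "y_um", "major_um", "minor_um",
                  "orientation_rad", "region"]

# typical hiPSC nucleus minor axis on a dense colony (μm)
_NUCLEUS_MINOR_UM = 6.0
# packing bound: reject configurations denser than one nucleus per 4 μm²
_MIN_AREA_PER_NUCLEUS = 4.0


# ---------------------------------------------------------------------------
# PRW tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTrackConfig:
    """Ground-truth parameters of one simulated PRW track.

    ``persistence_time`` (min) and ``speed`` (root-mean-square speed,
    μm/min) are the P and S of the PRW model; ``dt`` and ``n_frames``
    default to the 30-min / 49-frame time-lapse design.
    """

    persistence_time: float
    speed: float
    dt: float = 30.0
    n_frames: int = 49
    origin: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if not self.persistence_time > 0:
            raise ConfigurationError("persistence_time", "must be > 0")
        if self.speed < 0:
            raise ConfigurationError("speed", "must be >= 0")
        if not self.dt > 0:
            raise ConfigurationError("dt", "must be > 0")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames", "must be >= 2")


def simulate_prw_track(config: SyntheticTrackConfig, cell_id="sim") -> CellTrack:
    """Simulate one PRW track by exact OU discretisation.

    The 2D velocity is a stationary OU process with correlation time P and
    per-component variance S²/2 (so E|v|² = S²).  Each step draws the
    velocity at the next sample time and the *integrated* displacement over
    the interval from their exact joint Gaussian law, so the expected MSD
    equals 2S²P[t − P(1 − e^{−t/P})] at every lag, not only in the Δt → 0
    limit.
    """
    rng = np.random.default_rng(config.seed)
    n, h, P = config.n_frames, config.dt, config.persistence_time
    times = np.arange(n) * h
    if config.speed == 0.0:
        pos = np.tile(np.asarray(config.origin, float), (n, 1))
        return CellTrack(cell_id=cell_id, times=times, positions=pos)

    sigma2 = config.speed**2 / 2.0           # per-component velocity variance
    em = -math.expm1(-h / P)                 # 1 - exp(-h/P), cancellation-safe
    em2 = -math.expm1(-2 * h / P)            # 1 - exp(-2h/P)
    a = 1.0 - em
    var_eta = sigma2 * em2
    cov = sigma2 * P * em**2
    var_zeta = 2.0 * sigma2 * P * (h - 2.0 * P * em + 0.5 * P * em2)
    resid_var = max(var_zeta - cov**2 / var_eta, 0.0)

    v = rng.normal(0.0, math.sqrt(sigma2), size=2)     # stationary start
    eta = rng.normal(0.0, math.sqrt(var_eta), size=(n - 1, 2))
    zeta = (cov / var_eta) * eta + rng.normal(
        0.0, math.sqrt(resid_var), size=(n - 1, 2)
    )
    pos = np.empty((n, 2))
    pos[0] = config.origin
    for k in range(n - 1):
        pos[k + 1] = pos[k] + v * P * em + zeta[k]
        v = a * v + eta[k]
    return CellTrack(cell_id=cell_id, times=times, positions=pos)


def simulate_track_cohort(configs, prefix="cell") -> list[CellTrack]:
    """Simulate a list of tracks, one per config, with sequential ids."""
    return [simulate_prw_track(c, cell_id=f"{prefix}{i}")
            for i, c in enumerate(configs)]


# ---------------------------------------------------------------------------
# colonies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticColonyConfig:
    """Radially structured nuclei field on a circular pattern.

    Nuclei are sampled with density ``band_density_multiplier`` times the
    background inside the annulus [band_inner_radius, band_outer_radius);
    marker positivity and nucleus elongation are drawn per region.  Band
    nuclei are oriented tangentially (their long axis along the pattern
    edge), as confined, mechanically stressed perimeter cells are.
    """

    pattern_diameter: float = 400.0
    n_cells: int = 2000
    band_inner_radius: float = 150.0
    band_outer_radius: float = 200.0
    band_density_multiplier: float = 3.0
    marker_prob_band: float = 0.9
    marker_prob_elsewhere: float = 0.1
    nucleus_axis_ratio_band: float = 2.0
    nucleus_axis_ratio_centre: float = 1.2
    marker_name: str = "OCT4"
    seed: int = 0

    def __post_init__(self):
        R = self.pattern_diameter / 2.0
        if not self.pattern_diameter > 0:
            raise ConfigurationError("pattern_diameter", "must be > 0")
        if not 0 <= self.band_inner_radius < self.band_outer_radius <= R:
            raise ConfigurationError(
                "band_inner_radius",
                "need 0 <= band_inner_radius < band_outer_radius <= radius",
            )
        if self.band_density_multiplier < 1:
            raise ConfigurationError("band_density_multiplier", "must be >= 1")
        for fld in ("marker_prob_band", "marker_prob_elsewhere"):
            if not 0 <= getattr(self, fld) <= 1:
                raise ConfigurationError(fld, "must be a probability in [0, 1]")
        for fld in ("nucleus_axis_ratio_band", "nucleus_axis_ratio_centre"):
            if getattr(self, fld) < 1:
                raise ConfigurationError(fld, "must be >= 1")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells", "must be >= 1")
        if self.n_cells * _MIN_AREA_PER_NUCLEUS > math.pi * R**2:
            raise ConfigurationError(
                "n_cells",
                f"{self.n_cells} nuclei exceed the packing bound for a "
                f"{self.pattern_diameter}-um pattern",
            )

    @property
    def band_probability(self) -> float:
        """Expected fraction of nuclei falling inside the band."""
        R = self.pattern_diameter / 2.0
        a_band = math.pi * (self.band_outer_radius**2 - self.band_inner_radius**2)
        a_rest = math.pi * R**2 - a_band
        m = self.band_density_multiplier
        return m * a_band / (m * a_band + a_rest)


def _sample_radius_uniform(rng, r_in, r_out, size):
    """Radii uniform by area on the annulus [r_in, r_out)."""
    u = rng.random(size)
    return np.sqrt(u * (r_out**2 - r_in**2) + r_in**2)


def simulate_colony(config: SyntheticColonyConfig) -> pd.DataFrame:
    """Sample a nuclei table with the configured annular structure.

    Returns a DataFrame with columns ``nucleus_id, x_um, y_um, major_um,
    minor_um, orientation_rad, region`` plus one boolean marker column named
    ``config.marker_name``.  Coordinates are relative to the pattern centre;
    ``region`` is ``inner`` / ``band`` / ``outer`` by centroid radius.
    """
    rng = np.random.default_rng(config.seed)
    R = config.pattern_diameter / 2.0
    r1, r2 = config.band_inner_radius, config.band_outer_radius
    n = config.n_cells

    in_band = rng.random(n) < config.band_probability
    n_band = int(in_band.sum())
    r = np.empty(n)
    r[in_band] = _sample_radius_uniform(rng, r1, r2, n_band)
    # complement: union of [0, r1) and [r2, R], uniform by area
    n_rest = n - n_band
    a_inner = r1**2
    a_outer = R**2 - r2**2
    pick_inner = rng.random(n_rest) < a_inner / (a_inner + a_outer)
    rest = np.empty(n_rest)
    rest[pick_inner] = _sample_radius_uniform(rng, 0.0, r1, int(pick_inner.sum()))
    rest[~pick_inner] = _sample_radius_uniform(rng, r2, R, int((~pick_inner).sum()))
    r[~in_band] = rest

    theta = rng.uniform(0.0, 2 * math.pi, n)
    x = r * np.cos(theta)
    y = r * np.sin(theta)

    p_marker = np.where(in_band, config.marker_prob_band, config.marker_prob_elsewhere)
    marker = rng.random(n) < p_marker

    ratio = np.where(in_band, config.nucleus_axis_ratio_band,
                     config.nucleus_axis_ratio_centre)
    minor = _NUCLEUS_MINOR_UM * np.exp(rng.normal(0.0, 0.08, n))
    major = minor * ratio * np.exp(rng.normal(0.0, 0.05, n))
    major = np.maximum(major, minor)
    orientation = np.where(
        in_band,
        np.mod(theta + math.pi / 2, math.pi),          # tangential
        rng.uniform(0.0, math.pi, n),
    )
    region = np.where(r < r1, "inner", np.where(r < r2, "band", "outer"))
    # radii sampled in [r1, r2) belong to the band even when labelled by radius
    region[in_band] = "band"

    table = pd.DataFrame({
        "nucleus_id": np.arange(n),
        "x_um": x, "y_um": y,
        "major_um": major, "minor_um": minor,
        "orientation_rad": orientation,
        "region": region,
        config.marker_name: marker,
    })
    return table


def render_colony(nuclei: pd.DataFrame, pattern_diameter: float,
                  pixel_size: float = 1.0) -> np.ndarray:
    """Rasterise a nuclei table into a label image (uint16, 0 = background).

    Each nucleus is drawn as a filled ellipse at its centroid with its
    recorded axes and orientation.  Overlapping nuclei overwrite in id
    order; intended for sparse fields in end-to-end image-path tests.
    """
    from skimage.draw import ellipse

    R = pattern_diameter / 2.0
    size = int(math.ceil(pattern_diameter / pixel_size)) + 4
    img = np.zeros((size, size), dtype=np.uint16)
    c0 = size / 2.0
    for _, row in nuclei.iterrows():
        rr, cc = ellipse(
            c0 + row.y_um / pixel_size,
            c0 + row.x_um / pixel_size,
            row.major_um / 2.0 / pixel_size,
            row.minor_um / 2.0 / pixel_size,
            shape=img.shape,
            rotation=-(row.orientation_rad - math.pi / 2),
        )
        img[rr, cc] = int(row.nucleus_id) + 1
    return img


def nuclei_from_labels(label_image: np.ndarray, pixel_size: float = 1.0,
                       centre_px: tuple[float, float] | None = None) -> pd.DataFrame:
    """Recover a nuclei table from a label image via region properties.

    The inverse of :func:`render_colony` for non-overlapping nuclei:
    centroids, major/minor axis lengths and orientations are measured with
    ``skimage.measure.regionprops`` and converted to μm relative to
    ``centre_px`` (default: image centre).
    """
    from skimage.measure import regionprops

    if centre_px is None:
        centre_px = (label_image.shape[0] / 2.0, label_image.shape[1] / 2.0)
    rows = []
    for prop in regionprops(label_image):
        cy, cx = prop.centroid
        rows.append({
            "nucleus_id": prop.label - 1,
            "x_um": (cx - centre_px[1]) * pixel_size,
            "y_um": (cy - centre_px[0]) * pixel_size,
            "major_um": prop.axis_major_length * pixel_size,
            "minor_um": prop.axis_minor_length * pixel_size,
            "orientation_rad": float(np.mod(math.pi / 2 - prop.orientation, math.pi)),
        })
    return pd.DataFrame(rows)


def otsu_positive_flags(intensities: np.ndarray) -> np.ndarray:
    """Otsu-threshold per-nucleus intensities into boolean positivity flags.

    A convenience for the synthetic raster path only; thresholding real
    micrographs is out of scope.
    """
    from skimage.filters import threshold_otsu

    intensities = np.asarray(intensities, dtype=float)
    return intensities > threshold_otsu(intensities)


# ---------------------------------------------------------------------------
# beating stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticBeatConfig:
    """Beating-tissue video parameters.

    A textured disc is displaced radially by δ(t) = A·sin(2π f t) with the
    amplitude A chosen so that the peak displacement rate equals
    ``peak_velocity`` (A = peak_velocity / 2πf).  Defaults follow the
    20 frames/s, 500-frame recording design.
    """

    frame_rate: float = 20.0
    n_frames: int = 500
    beat_frequency: float = 1.0
    peak_velocity: float = 10.0
    image_size: int = 64
    pixel_size: float = 0.5
    noise_sd: float = 1.0
    disc_radius_fraction: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if not self.frame_rate > 0:
            raise ConfigurationError("frame_rate", "must be > 0")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames", "must be >= 2")
        if not self.beat_frequency > 0:
            raise ConfigurationError("beat_frequency", "must be > 0")
        if self.beat_frequency >= self.frame_rate / 2.0:
            raise NyquistError(
                "beat_frequency",
                f"{self.beat_frequency} Hz is not below the Nyquist limit "
                f"{self.frame_rate / 2.0} Hz",
            )
        if self.peak_velocity < 0:
            raise ConfigurationError("peak_velocity", "must be >= 0")
        if self.peak_velocity > 0:
            duration = self.n_frames / self.frame_rate
            if duration * self.beat_frequency < 2.0:
                raise ConfigurationError(
                    "n_frames", "recording must span at least 2 full beat periods"
                )
        if self.image_size < 16:
            raise ConfigurationError("image_size", "must be >= 16")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size", "must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd", "must be >= 0")

    @property
    def amplitude_um(self) -> float:
        """Displacement amplitude A = peak_velocity / (2π f), μm."""
        return self.peak_velocity / (2 * math.pi * self.beat_frequency)


@dataclass
class SyntheticBeatResult:
    """A simulated beating stack plus its ground truth.

    ``true_mean_speed`` is the exact mean speed of the moving tissue between
    consecutive frames (μm/s, length n_frames − 1), the oracle for
    downstream waveform estimates.
    """

    stack: ImageStack
    displacement_um: np.ndarray     # δ(t) per frame, μm
    true_mean_speed: np.ndarray     # |δ(t+1) − δ(t)| · fps, μm/s
    disc_radius_px: float
    core_radius_px: float
    config: SyntheticBeatConfig


def simulate_beating_stack(config: SyntheticBeatConfig) -> SyntheticBeatResult:
    """Render a periodically displacing textured disc.

    The texture is fixed-seed band-limited noise (Gaussian-smoothed white
    noise), present only inside the tissue disc; every texture point at
    radius r > core moves radially with the common magnitude δ(t), tapering
    linearly to zero inside a small core where the radial direction is
    ill-defined.  Frames are produced by bilinear resampling of the base
    image along the analytic inverse displacement, then Gaussian pixel noise
    of ``noise_sd`` is added.
    """
    rng = np.random.default_rng(config.seed)
    N = config.image_size
    fps = config.frame_rate

    tex = gaussian_filter(rng.standard_normal((N, N)), sigma=2.0)
    tex = 120.0 + 60.0 * tex / tex.std()

    c = (N - 1) / 2.0
    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx)
    disc_r = config.disc_radius_fraction * N
    core_r = 5.0
    edge = np.clip((disc_r - r) / 2.0 + 0.5, 0.0, 1.0)   # soft 2-px rim
    base = 100.0 + (tex - 100.0) * edge

    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / r, 0.0)
        uy = np.where(r > 0, dy / r, 0.0)
    taper = np.clip(r / core_r, 0.0, 1.0)

    t = np.arange(config.n_frames) / fps
    delta_um = config.amplitude_um * np.sin(
        2 * math.pi * config.beat_frequency * t
    )
    delta_px = delta_um / config.pixel_size

    frames = np.empty((config.n_frames, N, N), dtype=np.float32)
    for i, d in enumerate(delta_px):
        # content at radius rho came from radius rho - d (same angle)
        src_y = yy - d * taper * uy
        src_x = xx - d * taper * ux
        frames[i] = map_coordinates(base, [src_y, src_x], order=1, mode="nearest")
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, frames.shape).astype(np.float32)

    true_speed = np.abs(np.diff(delta_um)) * fps
    stack = ImageStack(frames=frames, frame_rate=fps, pixel_size=config.pixel_size)
    return SyntheticBeatResult(
        stack=stack, displacement_um=delta_um, true_mean_speed=true_speed,
        disc_radius_px=disc_r, core_radius_px=core_r, config=config,
    )
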