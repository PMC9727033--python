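"""Synthetic ground-truth generator for PALM movies and puncta images.

The simulator produces three kinds of artifacts, all tied to an explicit
ground-truth record so downstream stages can be scored against it:

* cluster-level ground truth (birth/death times, true lifetimes drawn from
  a two-component exponential mixture, subcellular region),
* per-molecule emitter traces with photoswitching (activation, blinking,
  bleaching) and the rendered EMCCD movie,
* a fast-path localization table that bypasses image rendering, and
* confocal-style spot fields for the puncta-quantification stage.

Coordinates are continuous nanometres with the origin at the upper-left
corner of the ROI; pixel (row i, col j) spans
[j*px, (j+1)*px) x [i*px, (i+1)*px), half-open, 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

logger = logging.getLogger(__name__)

REGION_LABELS = {0: "outside", 1: "plasma_membrane", 2: "cytoplasm", 3: "nucleus"}

LOC_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "photons",
    "background",
    "sigma_nm",
    "uncertainty_nm",
]


class SimConfigError(ValueError):
    """Raised when a simulation configuration fails validation."""


@dataclass
class SimConfig:
    """Parameters of a synthetic PALM acquisition.

    Defaults reproduce the acquisition geometry the analysis targets:
    a 2400-frame stream at 20 Hz over a 256 px ROI with 160 nm pixels.
    Photophysics defaults are chosen so the median single-molecule track
    is ~3-5 frames; they are free parameters, not measured constants.
    """

    n_frames: int = 2400
    frame_rate: float = 20.0  # Hz
    roi_size: int = 256  # pixels (square ROI)
    pixel_size: float = 160.0  # nm / pixel
    psf_sigma: float = 1.3  # pixels
    cluster_birth_rate: float = 0.5  # clusters / s over the whole ROI
    short_lifetime_mean: float = 6.8  # s
    long_lifetime_mean: float = 300.0  # s
    long_fraction: float = 0.15
    molecules_per_cluster: float = 20.0  # Poisson mean of the per-cluster pool
    spatial_spread: float = 50.0  # nm, isotropic Gaussian scatter of members
    photon_budget: float = 500.0  # photons / frame while ON
    background_photons: float = 10.0  # photons / pixel / frame
    activation_rate: float = 0.05  # 1/s per molecule, from cluster birth
    bleach_rate: float = 5.0  # 1/s while ON
    blink_off_rate: float = 1.0  # 1/s while ON
    blink_on_rate: float = 5.0  # 1/s while dark (recovery)
    background_monomers: int = 0  # free monomers scattered over the ROI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise SimConfigError("n_frames must be >= 1")
        if self.frame_rate <= 0:
            raise SimConfigError("frame_rate must be > 0")
        if self.roi_size < 8:
            raise SimConfigError("roi_size must be >= 8 pixels")
        if self.pixel_size <= 0:
            raise SimConfigError("pixel_size must be > 0")
        if self.psf_sigma <= 0:
            raise SimConfigError("psf_sigma must be > 0")
        if not (0.0 <= self.long_fraction <= 1.0):
            raise SimConfigError("long_fraction must lie in [0, 1]")
        for name in (
            "cluster_birth_rate",
            "short_lifetime_mean",
            "long_lifetime_mean",
            "molecules_per_cluster",
            "photon_budget",
            "background_photons",
            "activation_rate",
            "bleach_rate",
            "blink_off_rate",
            "blink_on_rate",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.background_monomers < 0:
            raise SimConfigError("background_monomers must be >= 0")

    @property
    def duration(self) -> float:
        """Movie duration in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate

    @property
    def roi_nm(self) -> float:
        return self.roi_size * self.pixel_size

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class CameraModel:
    """EMCCD camera response.

    EM-gain excess noise is modeled as a gamma multiplication of the
    photoelectron count (excess-noise factor ~= 2), the standard EMCCD
    approximation.
    """

    em_gain: float = 1000.0  # output counts per photoelectron
    baseline_offset: float = 100.0  # counts
    read_noise: float = 10.0  # counts RMS
    quantum_efficiency: float = 0.9

    def __post_init__(self) -> None:
        if self.em_gain < 1:
            raise SimConfigError("em_gain must be >= 1")
        if not (0.0 < self.quantum_efficiency <= 1.0):
            raise SimConfigError("quantum_efficiency must lie in (0, 1]")
        if self.read_noise < 0:
            raise SimConfigError("read_noise must be >= 0")

    @property
    def effective_gain(self) -> float:
        """Counts per incident photon (gain x QE)."""
        return self.em_gain * self.quantum_efficiency


@dataclass
class GroundTruthCluster:
    cluster_id: int
    center: tuple  # (x_nm, y_nm)
    birth_time: float  # s
    death_time: float  # s, uncensored (may exceed movie end)
    region: str
    spatial_spread: float  # nm

    @property
    def lifetime(self) -> float:
        return self.death_time - self.birth_time


@dataclass
class EmitterTrace:
    molecule_id: int
    cluster_id: Optional[int]  # None for free background monomers
    position: tuple  # (x_nm, y_nm)
    on_intervals: list  # [(start_frame, end_frame)] inclusive, non-overlapping
    photons_per_frame: float

    def on_frames(self) -> np.ndarray:
        if not self.on_intervals:
            return np.empty(0, dtype=np.int64)
        parts = [np.arange(a, b + 1) for a, b in self.on_intervals]
        return np.concatenate(parts)


@dataclass
class SpotFieldTruth:
    """Planted-spot ground truth for confocal-style puncta images."""

    shape: tuple = (256, 256)
    centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # (row, col) px
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    widths: np.ndarray = field(default_factory=lambda: np.empty(0))  # sigma, px
    background: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 2)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        n = len(self.centers)
        if len(self.amplitudes) != n or len(self.widths) != n:
            raise SimConfigError("centers, amplitudes and widths must have equal length")
        h, w = self.shape
        if n and (
            (self.centers[:, 0] < 0).any()
            or (self.centers[:, 1] < 0).any()
            or (self.centers[:, 0] >= h).any()
            or (self.centers[:, 1] >= w).any()
        ):
            raise SimConfigError("all spot centers must lie inside the image bounds")

    @property
    def n_spots(self) -> int:
        return len(self.centers)


# ---------------------------------------------------------------------------
# seed handling: one master seed expands to fixed per-stage child streams so
# each artifact is reproducible independently of which others were generated.

_STAGE_CHILD = {"ground_truth": 0, "render": 1, "table": 2, "mask": 3}


def _stage_rng(config: SimConfig, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STAGE_CHILD))
    return np.random.default_rng(children[_STAGE_CHILD[stage]])


# ---------------------------------------------------------------------------
# region geometry


def default_cell_geometry(config: SimConfig, pm_band_px: int = 2) -> np.ndarray:
    """Label image for a synthetic cell: disk cell, disk nucleus, PM band.

    Labels: 0 outside, 1 plasma membrane, 2 cytoplasm, 3 nucleus.
    """
    n = config.roi_size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    cell_r = 0.45 * n
    nuc_r = 0.18 * n
    labels = np.zeros((n, n), dtype=np.uint8)
    cell = r <= cell_r
    labels[cell] = 2
    labels[cell & (r > cell_r - pm_band_px)] = 1
    labels[r <= nuc_r] = 3
    return labels


def region_at(labels: np.ndarray, x_nm: float, y_nm: float, pixel_size: float) -> str:
    i = int(y_nm // pixel_size)
    j = int(x_nm // pixel_size)
    if i < 0 or j < 0 or i >= labels.shape[0] or j >= labels.shape[1]:
        return "outside"
    return REGION_LABELS[int(labels[i, j])]


# ---------------------------------------------------------------------------
# ground truth


def simulate_ground_truth(
    config: SimConfig,
    region_labels: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Simulate cluster births/deaths and per-molecule emitter traces.

    Cluster births follow a homogeneous Poisson process at
    ``cluster_birth_rate`` over the movie duration; each lifetime is drawn
    from the two-component exponential mixture. Molecules activate at
    exponential times after cluster birth, then alternate ON/OFF with
    geometric frame counts until bleaching, cluster death or movie end.

    Returns
    -------
    (clusters, traces) : (list[GroundTruthCluster], list[EmitterTrace])
    """
    rng = _stage_rng(config, "ground_truth") if rng is None else rng
    if region_labels is None:
        region_labels = default_cell_geometry(config)

    duration = config.duration
    n_clusters = rng.poisson(config.cluster_birth_rate * duration)
    births = np.sort(rng.uniform(0.0, duration, size=n_clusters))

    # sample centers uniformly inside the cell (labels > 0)
    inside = np.argwhere(region_labels > 0)
    if inside.size == 0:
        raise SimConfigError("region label image contains no cell pixels")

    clusters: list[GroundTruthCluster] = []
    traces: list[EmitterTrace] = []
    mol_id = 0
    for cid in range(n_clusters):
        is_long = rng.random() < config.long_fraction
        mean = config.long_lifetime_mean if is_long else config.short_lifetime_mean
        lifetime = rng.exponential(mean) if mean > 0 else 0.0
        birth = births[cid]
        death = birth + lifetime

        ij = inside[rng.integers(len(inside))]
        # uniform within the pixel, in nm
        y_nm = (ij[0] + rng.random()) * config.pixel_size
        x_nm = (ij[1] + rng.random()) * config.pixel_size
        region = REGION_LABELS[int(region_labels[ij[0], ij[1]])]

        cluster = GroundTruthCluster(
            cluster_id=cid,
            center=(x_nm, y_nm),
            birth_time=birth,
            death_time=death,
            region=region,
            spatial_spread=config.spatial_spread,
        )
        clusters.append(cluster)

        # molecules that ever activate: Binomial thinning of the pool, with
        # truncated-exponential activation times inside the observed life
        n_mol = rng.poisson(config.molecules_per_cluster)
        stop = min(death, duration)
        live = stop - birth
        if n_mol > 0 and config.activation_rate > 0 and live > 0:
            p_act = -math.expm1(-config.activation_rate * live)
            n_act = rng.binomial(n_mol, p_act)
            if n_act > 0:
                u = rng.random(n_act)
                t_acts = birth - np.log1p(-u * p_act) / config.activation_rate
                offsets = rng.normal(0.0, config.spatial_spread, size=(n_act, 2))
                for t_act, (dx, dy) in zip(np.sort(t_acts), offsets):
                    intervals = _blink_intervals(rng, config, float(t_act), stop)
                    if intervals:
                        traces.append(
                            EmitterTrace(
                                molecule_id=mol_id,
                                cluster_id=cid,
                                position=(x_nm + dx, y_nm + dy),
                                on_intervals=intervals,
                                photons_per_frame=config.photon_budget,
                            )
                        )
                        mol_id += 1

    for _ in range(config.background_monomers):
        pos = (rng.uniform(0, config.roi_nm), rng.uniform(0, config.roi_nm))
        t_act = (
            rng.exponential(1.0 / config.activation_rate)
            if config.activation_rate > 0
            else math.inf
        )
        if t_act >= duration:
            continue
        intervals = _blink_intervals(rng, config, t_act, duration)
        if intervals:
            traces.append(
                EmitterTrace(
                    molecule_id=mol_id,
                    cluster_id=None,
                    position=pos,
                    on_intervals=intervals,
                    photons_per_frame=config.photon_budget,
                )
            )
            mol_id += 1

    return clusters, traces


def _blink_intervals(
    rng: np.random.Generator, config: SimConfig, t_on: float, t_stop: float
) -> list:
    """ON intervals (inclusive frame pairs) between activation and t_stop.

    Per-frame hazards derive from the configured rates; the molecule
    alternates ON/dark runs and terminates on bleaching.
    """
    fr = config.frame_rate
    p_bleach = min(1.0, config.bleach_rate / fr)
    p_off = min(1.0, config.blink_off_rate / fr)
    p_on = min(1.0, config.blink_on_rate / fr) if config.blink_on_rate > 0 else 0.0

    f = int(t_on * fr)
    f_stop = min(int(math.ceil(t_stop * fr)), config.n_frames) - 1
    if f > f_stop or f >= config.n_frames:
        return []

    intervals = []
    start = f
    on = True
    while f <= f_stop:
        if on:
            u = rng.random()
            if u < p_bleach:
                intervals.append((start, f))
                return intervals
            if u < p_bleach + p_off:
                intervals.append((start, f))
                on = False
        else:
            if p_on == 0.0:
                return intervals
            if rng.random() < p_on:
                on = True
                start = f + 1
        f += 1
    if on and start <= f_stop:
        intervals.append((start, f_stop))
    # the final interval may have been appended already by a blink at f_stop
    return [iv for iv in intervals if iv[0] <= iv[1]]


# ---------------------------------------------------------------------------
# rendering


def _integrated_gaussian_1d(edges_px: np.ndarray, center_px: float, sigma_px: float) -> np.ndarray:
    """Integral of a unit Gaussian over [edges[k], edges[k+1]) pixel bins."""
    z = (edges_px - center_px) / (math.sqrt(2.0) * sigma_px)
    c = 0.5 * erf(z)
    return np.diff(c)


def _emitter_patch(shape, x_px, y_px, photons, sigma_px, window=None):
    """Windowed expected-photon patch of one emitter (integrated Gaussian).

    Returns ``(patch, (i0, i1, j0, j1))``; the default 5-sigma window keeps
    truncation loss well under 1%.
    """
    h, w = shape
    if window is None:
        window = int(math.ceil(5.0 * sigma_px))
    i0 = max(0, int(math.floor(y_px)) - window)
    i1 = min(h, int(math.floor(y_px)) + window + 1)
    j0 = max(0, int(math.floor(x_px)) - window)
    j1 = min(w, int(math.floor(x_px)) + window + 1)
    if i0 >= i1 or j0 >= j1:
        return np.zeros((0, 0)), (i0, i0, j0, j0)
    ey = _integrated_gaussian_1d(np.arange(i0, i1 + 1, dtype=float), y_px, sigma_px)
    ex = _integrated_gaussian_1d(np.arange(j0, j1 + 1, dtype=float), x_px, sigma_px)
    return photons * np.outer(ey, ex), (i0, i1, j0, j1)


def emitter_image(shape, x_px, y_px, photons, sigma_px, window=None) -> np.ndarray:
    """Expected photon image of one emitter over the full frame."""
    img = np.zeros(shape)
    patch, (i0, i1, j0, j1) = _emitter_patch(shape, x_px, y_px, photons, sigma_px, window)
    img[i0:i1, j0:j1] = patch
    return img


def render_frames(
    traces: Sequence[EmitterTrace],
    camera: CameraModel,
    config: SimConfig,
    apply_noise: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render emitter traces into a camera-count movie.

    Each ON emitter contributes an integrated 2D Gaussian of
    ``photons_per_frame`` photons. With ``apply_noise`` the chain is
    Poisson shot noise on photoelectrons, gamma EM multiplication,
    Gaussian read noise and the baseline offset, quantized to uint16.
    Without it, the expected count image (float) is returned.

    Emitters outside the ROI are skipped with a logged warning.
    """
    rng = _stage_rng(config, "render") if rng is None else rng
    n = config.roi_size
    # float32 keeps a default-scale movie (~2400x256x256) near 0.6 GB
    expected = np.full((config.n_frames, n, n), config.background_photons, dtype=np.float32)
    roi_nm = config.roi_nm
    for tr in traces:
        x_nm, y_nm = tr.position
        if not (0 <= x_nm < roi_nm and 0 <= y_nm < roi_nm):
            logger.warning("emitter %s outside ROI, skipped", tr.molecule_id)
            continue
        patch, (i0, i1, j0, j1) = _emitter_patch(
            (n, n), x_nm / config.pixel_size, y_nm / config.pixel_size,
            tr.photons_per_frame, config.psf_sigma,
        )
        for a, b in tr.on_intervals:
            a = max(a, 0)
            b = min(b, config.n_frames - 1)
            if a > b:
                continue
            expected[a : b + 1, i0:i1, j0:j1] += patch[None, :, :]

    if not apply_noise:
        return expected.astype(np.float64) * camera.effective_gain + camera.baseline_offset

    out = np.empty(expected.shape, dtype=np.uint16)
    chunk = max(1, int(2e7 // (n * n)))  # frames per noise block
    for a in range(0, config.n_frames, chunk):
        b = min(a + chunk, config.n_frames)
        mu = expected[a:b].astype(np.float64) * camera.quantum_efficiency
        pe = rng.poisson(mu)
        if camera.em_gain > 1:
            counts = rng.standard_gamma(np.maximum(pe, 1)) * camera.em_gain
            counts[pe == 0] = 0.0
        else:
            counts = pe.astype(float)
        if camera.read_noise > 0:
            counts += rng.normal(0.0, camera.read_noise, size=counts.shape)
        counts += camera.baseline_offset
        out[a:b] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)
    return out


# ---------------------------------------------------------------------------
# fast-path localization table


def emit_localization_table(
    traces: Sequence[EmitterTrace],
    config: SimConfig,
    localization_noise_sd: float = 20.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """One localization row per emitter per ON frame, bypassing rendering.

    Positions are jittered by isotropic Gaussian noise of the given SD.
    Truth columns (``true_cluster_id``, ``molecule_id``) are appended for
    scoring; the leading columns follow the standard table schema.
    """
    if localization_noise_sd < 0:
        raise SimConfigError("localization_noise_sd must be >= 0")
    rng = _stage_rng(config, "table") if rng is None else rng

    frames, xs, ys, cids, mids = [], [], [], [], []
    for tr in traces:
        f = tr.on_frames()
        f = f[(f >= 0) & (f < config.n_frames)]
        if f.size == 0:
            continue
        frames.append(f)
        xs.append(np.full(f.size, tr.position[0]))
        ys.append(np.full(f.size, tr.position[1]))
        cids.append(np.full(f.size, -1 if tr.cluster_id is None else tr.cluster_id))
        mids.append(np.full(f.size, tr.molecule_id))

    if not frames:
        return pd.DataFrame(
            {c: pd.Series(dtype=float) for c in LOC_COLUMNS}
            | {
                "true_cluster_id": pd.Series(dtype=np.int64),
                "molecule_id": pd.Series(dtype=np.int64),
            }
        ).astype({"frame": np.int64})

    frame = np.concatenate(frames)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if localization_noise_sd > 0:
        x = x + rng.normal(0.0, localization_noise_sd, size=x.size)
        y = y + rng.normal(0.0, localization_noise_sd, size=y.size)

    df = pd.DataFrame(
        {
            "frame": frame.astype(np.int64),
            "x_nm": x,
            "y_nm": y,
            "photons": np.full(frame.size, config.photon_budget),
            "background": np.full(frame.size, config.background_photons),
            "sigma_nm": np.full(frame.size, config.psf_sigma * config.pixel_size),
            "uncertainty_nm": np.full(frame.size, float(localization_noise_sd)),
            "true_cluster_id": np.concatenate(cids).astype(np.int64),
            "molecule_id": np.concatenate(mids).astype(np.int64),
        }
    )
    return df.sort_values(["frame", "molecule_id"], kind="stable").reset_index(drop=True)


def clusters_to_frame(clusters: Sequence[GroundTruthCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "center_x_nm": [c.center[0] for c in clusters],
            "center_y_nm": [c.center[1] for c in clusters],
            "birth_time_s": [c.birth_time for c in clusters],
            "death_time_s": [c.death_time for c in clusters],
            "lifetime_s": [c.lifetime for c in clusters],
            "region": [c.region for c in clusters],
            "spatial_spread_nm": [c.spatial_spread for c in clusters],
        }
    )


# ---------------------------------------------------------------------------
# puncta fixtures


def synth_puncta_image(truth: SpotFieldTruth, rng: Optional[np.random.Generator] = None):
    """Render a spot field: background + Gaussian spots + Gaussian noise.

    Returns ``(image, label_mask)`` where the mask labels pixels within
    2 sigma of each planted center (1-based labels, 0 = background).
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    img = np.full(truth.shape, float(truth.background))
    labels = np.zeros(truth.shape, dtype=np.int32)
    yy, xx = np.mgrid[0 : truth.shape[0], 0 : truth.shape[1]]
    for k in range(truth.n_spots):
        cy, cx = truth.centers[k]
        amp = truth.amplitudes[k]
        s = truth.widths[k]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img += amp * np.exp(-d2 / (2.0 * s * s))
        labels[d2 <= (2.0 * s) ** 2] = k + 1
    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
    return img, labels


def synth_two_channel(
    truth: SpotFieldTruth,
    b_scale: float | Sequence[float] = 2.0,
    b_background: float = 0.0,
    rng: Optional[np.random.Generator] = None,
):
    """Two registered channels: B spot amplitudes = b_scale x A per spot."""
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    img_a, labels = synth_puncta_image(truth, rng=rng)
    scale = np.broadcast_to(np.asarray(b_scale, dtype=float), (truth.n_spots,))
    truth_b = SpotFieldTruth(
        shape=truth.shape,
        centers=truth.centers.copy(),
        amplitudes=truth.amplitudes * scale,
        widths=truth.widths.copy(),
        background=b_background,
        noise_sd=truth.noise_sd,
        seed=truth.seed,
    )
    img_b, _ = synth_puncta_image(truth_b, rng=rng)
    return img_a, img_b, labels
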