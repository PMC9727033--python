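"""Frame-wise single-molecule detection and subpixel localization.

The stage mirrors the classical multi-target tracing detection scheme:

1. a pixelwise generalized-likelihood-ratio (GLR) test of
   ``Gaussian spot + background`` against ``background only`` in a sliding
   window flags candidate pixels at a configured per-pixel false-alarm
   probability,
2. each candidate is refined by maximum-likelihood fitting of an
   integrated-Gaussian + constant-background model (Gauss-Newton /
   Fisher scoring on the Poisson likelihood), and
3. a deflation loop subtracts fitted spots and re-runs detection on the
   residual so dimmer emitters overshadowed by bright neighbours are not
   missed.

All fitting operates on gain-corrected photon counts; conversion from raw
camera counts is handled by :func:`counts_to_photons`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import t as t_dist

from .simkit import CameraModel, _integrated_gaussian_1d

logger = logging.getLogger(__name__)

LOC_TABLE_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "photons",
    "background",
    "sigma_nm",
    "uncertainty_nm",
    "detection_round",
]


class DetectionError(ValueError):
    pass


@dataclass
class DetectionParams:
    """Parameters of the detection-localization stage."""

    psf_sigma: float = 1.3  # px
    window_radius: Optional[int] = None  # default: ceil(3 sigma), min 2 sigma
    pfa: float = 1e-6  # per-pixel false-alarm probability
    max_iterations: int = 50
    convergence_tol: float = 1e-3  # px, step norm in (x, y)
    max_deflation_rounds: int = 2
    min_photons: float = 30.0
    fit_sigma: bool = False  # fit the PSF width instead of fixing it

    def __post_init__(self) -> None:
        if not (0.0 < self.pfa < 1.0):
            raise DetectionError("pfa must lie in (0, 1)")
        if self.convergence_tol <= 0:
            raise DetectionError("convergence_tol must be > 0")
        if self.psf_sigma <= 0:
            raise DetectionError("psf_sigma must be > 0")
        if self.window_radius is None:
            self.window_radius = max(int(math.ceil(3.0 * self.psf_sigma)), 2)
        if self.window_radius < 2 * self.psf_sigma:
            raise DetectionError("window_radius must be >= 2 * psf_sigma")
        if self.max_iterations < 1 or self.max_deflation_rounds < 0:
            raise DetectionError("iteration counts must be positive")


@dataclass
class Localization:
    """One fitted emitter detection."""

    frame: int
    x: float  # nm
    y: float  # nm
    photons: float
    background: float  # photons / px
    sigma_fit: float  # nm
    uncertainty: float  # nm, CRLB-based
    detection_round: int = 0  # 0 = first pass, >=1 = found by deflation

    # fitted position in pixels, kept for model reconstruction
    x_px: float = 0.0
    y_px: float = 0.0
    sigma_px: float = 0.0


def counts_to_photons(frame: np.ndarray, camera: CameraModel) -> np.ndarray:
    """Convert raw camera counts to (non-negative) expected photon counts."""
    photons = (frame.astype(np.float64) - camera.baseline_offset) / camera.effective_gain
    return np.clip(photons, 0.0, None)


# ---------------------------------------------------------------------------
# candidate detection


def _glr_template(psf_sigma: float, radius: int) -> np.ndarray:
    """Zero-mean integrated-Gaussian template over a (2r+1)^2 window."""
    edges = np.arange(-radius, radius + 2, dtype=float) - 0.5
    e = _integrated_gaussian_1d(edges, 0.0, psf_sigma)
    k = np.outer(e, e)
    return k - k.mean()


def glr_statistic(image: np.ndarray, params: DetectionParams):
    """Per-pixel GLR statistic map and its detection threshold.

    For each pixel the window model is ``I = b + alpha * g + noise`` with
    ``g`` the centred PSF template. Under Gaussian noise with the variance
    estimated from the window residual, the statistic
    ``T = alpha_hat * sqrt(sum g^2) / sigma_hat`` follows a Student-t
    distribution with ``n - 2`` dof under the null, which sets the
    threshold at the configured ``pfa``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise DetectionError("expected a 2D image")
    r = params.window_radius
    size = 2 * r + 1
    if min(image.shape) < size:
        raise DetectionError("image smaller than the fitting window")

    g = _glr_template(params.psf_sigma, r)
    s_gg = float((g * g).sum())
    n = size * size

    gi = ndimage.correlate(image, g, mode="reflect")
    local_sum = ndimage.uniform_filter(image, size=size, mode="reflect") * n
    local_sq = ndimage.uniform_filter(image * image, size=size, mode="reflect") * n

    alpha = gi / s_gg
    sse = local_sq - local_sum**2 / n - alpha**2 * s_gg
    dof = n - 2
    sigma2 = np.clip(sse, 0.0, None) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = alpha * math.sqrt(s_gg) / np.sqrt(sigma2)
    stat[~np.isfinite(stat)] = 0.0
    threshold = float(t_dist.ppf(1.0 - params.pfa, dof))
    return stat, threshold


def detect_candidates(frame_image: np.ndarray, params: DetectionParams) -> list:
    """Candidate pixel positions ``(row, col)`` sorted by decreasing GLR.

    Local maxima of the GLR map above threshold, restricted to the image
    interior (a full fitting window must fit), with an exclusion radius of
    2 sigma so one spot yields one candidate. Ties break row-major.
    """
    stat, threshold = glr_statistic(frame_image, params)
    r = params.window_radius
    excl = max(1, int(math.ceil(2.0 * params.psf_sigma)))
    footprint = np.ones((2 * excl + 1, 2 * excl + 1), dtype=bool)
    local_max = stat >= ndimage.maximum_filter(stat, footprint=footprint, mode="reflect")

    mask = (stat > threshold) & local_max
    mask[:r, :] = mask[-r:, :] = False
    mask[:, :r] = mask[:, -r:] = False

    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows, -stat[rows, cols]))
    out, taken = [], []
    for k in order:
        rc = (int(rows[k]), int(cols[k]))
        if any((rc[0] - a) ** 2 + (rc[1] - b) ** 2 <= excl * excl for a, b in taken):
            continue  # plateau duplicates within the exclusion radius
        taken.append(rc)
        out.append(rc)
    return out


# ---------------------------------------------------------------------------
# ML fitting


def _model_and_grads(win: np.ndarray, x: float, y: float, n_ph: float, b: float, sigma: float,
                     fit_sigma: bool):
    """Integrated-Gaussian model over the window and parameter gradients.

    Window coordinates: pixel (i, j) spans [j, j+1) x [i, i+1); ``x`` is the
    column coordinate, ``y`` the row coordinate, both in pixels.
    """
    h, w = win.shape
    sq2 = math.sqrt(2.0) * sigma
    jE = np.arange(w + 1, dtype=float)
    iE = np.arange(h + 1, dtype=float)
    ex = _integrated_gaussian_1d(jE, x, sigma)
    ey = _integrated_gaussian_1d(iE, y, sigma)

    def gauss(z, c):
        return np.exp(-((z - c) ** 2) / (2.0 * sigma * sigma)) / (sigma * math.sqrt(2.0 * math.pi))

    # d/dx of the bin integral = phi(lo) - phi(hi)
    dex = gauss(jE[:-1], x) - gauss(jE[1:], x)
    dey = gauss(iE[:-1], y) - gauss(iE[1:], y)

    E = np.outer(ey, ex)
    mu = b + n_ph * E
    grads = [
        n_ph * np.outer(ey, dex),  # d mu / dx
        n_ph * np.outer(dey, ex),  # d mu / dy
        E,  # d mu / dN
        np.ones_like(win),  # d mu / db
    ]
    if fit_sigma:
        # d(bin integral)/d sigma via the erf chain rule
        zx_hi, zx_lo = (jE[1:] - x) / sq2, (jE[:-1] - x) / sq2
        zy_hi, zy_lo = (iE[1:] - y) / sq2, (iE[:-1] - y) / sq2
        c = 1.0 / (math.sqrt(math.pi) * sigma)
        dex_s = -c * (zx_hi * np.exp(-zx_hi**2) - zx_lo * np.exp(-zx_lo**2))
        dey_s = -c * (zy_hi * np.exp(-zy_hi**2) - zy_lo * np.exp(-zy_lo**2))
        grads.append(n_ph * (np.outer(ey, dex_s) + np.outer(dey_s, ex)))
    return mu, grads


def _fit_spots_window(win: np.ndarray, spots: list, b0: float, params: DetectionParams):
    """Joint Poisson ML fit of one or more spots over one window.

    ``spots`` is a list of ``[x, y, N, sigma]`` initial values in window
    coordinates; all spot parameters and a shared background float.
    Returns ``(spots, b, crlb_px_per_spot)`` or ``None`` on
    non-convergence, divergence, or a fit leaving the window.
    """
    n_spots = len(spots)
    spots = [list(s) for s in spots]
    b = max(b0, 1e-3)
    per_spot = 3 + (1 if params.fit_sigma else 0)  # x, y, N (+ sigma)
    size = win.shape[0]

    def assemble():
        mu = np.full_like(win, b)
        grads = []
        for x, y, n_ph, sigma in spots:
            m, g = _model_and_grads(win, x, y, n_ph, b, sigma, params.fit_sigma)
            mu += m - b
            grads.extend([g[0], g[1], g[2]] + ([g[4]] if params.fit_sigma else []))
        grads.append(np.ones_like(win))  # shared background
        return np.clip(mu, 1e-9, None), grads

    prev_step = math.inf
    grow = 0
    converged = False
    for _ in range(params.max_iterations):
        mu, grads = assemble()
        wgt = 1.0 / mu
        res = win - mu
        g = np.array([(gr * res * wgt).sum() for gr in grads])
        k = len(grads)
        fisher = np.empty((k, k))
        for a in range(k):
            for c in range(a, k):
                fisher[a, c] = fisher[c, a] = (grads[a] * grads[c] * wgt).sum()
        try:
            delta = np.linalg.solve(fisher, g)
        except np.linalg.LinAlgError:
            return None

        pos_step = 0.0
        for s in range(n_spots):
            d = delta[s * per_spot : (s + 1) * per_spot]
            step = math.hypot(d[0], d[1])
            if step > 1.0:  # damp unreasonable jumps
                d = d / step
                step = 1.0
            pos_step = max(pos_step, step)
            spots[s][0] += d[0]
            spots[s][1] += d[1]
            spots[s][2] = max(spots[s][2] + d[2], 1e-3)
            if params.fit_sigma:
                spots[s][3] = min(max(spots[s][3] + d[3], 0.3), size)
            # candidate spot must stay inside; nuisance spots get slack
            lo, hi = (0.0, size) if s == 0 else (-3.0, size + 3.0)
            if not (lo <= spots[s][0] <= hi and lo <= spots[s][1] <= hi):
                return None
        b = max(b + delta[-1], 1e-6)

        grow = grow + 1 if pos_step > prev_step else 0
        if grow >= 3:
            return None
        prev_step = pos_step
        if pos_step < params.convergence_tol:
            converged = True
            break
    if not converged:
        return None

    mu, grads = assemble()
    k = len(grads)
    fisher = np.empty((k, k))
    for a in range(k):
        for c in range(a, k):
            fisher[a, c] = fisher[c, a] = (grads[a] * grads[c] / mu).sum()
    crlb = []
    try:
        cov = np.linalg.inv(fisher)
        for s in range(n_spots):
            i = s * per_spot
            crlb.append(math.sqrt(max(0.5 * (cov[i, i] + cov[i + 1, i + 1]), 1e-12)))
    except np.linalg.LinAlgError:
        crlb = [float("nan")] * n_spots
    return spots, b, crlb


def fit_emitter(
    frame_image: np.ndarray,
    candidate: tuple,
    params: DetectionParams,
    pixel_size: float = 1.0,
    frame_index: int = 0,
    detection_round: int = 0,
    neighbors: Sequence[Localization] = (),
) -> Optional[Localization]:
    """Fit one candidate by Poisson maximum likelihood (Fisher scoring).

    ``frame_image`` must be in photon units. Already-fitted ``neighbors``
    falling inside the window are refit jointly as nuisance parameters
    (their reported records are never modified); only the candidate's spot
    is returned. Returns ``None`` when the fit does not converge,
    diverges, leaves the window, or lands below ``min_photons``
    (discards are logged at debug level).
    """
    image = np.asarray(frame_image, dtype=np.float64)
    r = params.window_radius
    ci, cj = candidate
    if ci < r or cj < r or ci >= image.shape[0] - r or cj >= image.shape[1] - r:
        logger.debug("candidate %s too close to the border, discarded", candidate)
        return None
    win = image[ci - r : ci + r + 1, cj - r : cj + r + 1]

    b0 = max(float(np.percentile(win, 20)), 1e-3)
    n0 = max(float((win - b0).sum()), 10.0)
    spots = [[float(r) + 0.5, float(r) + 0.5, n0, params.psf_sigma]]
    for nb in neighbors:
        wx, wy = nb.x_px - (cj - r), nb.y_px - (ci - r)
        if -1.0 <= wx <= 2 * r + 2 and -1.0 <= wy <= 2 * r + 2:
            spots.append([wx, wy, nb.photons, nb.sigma_px])

    result = _fit_spots_window(win, spots, b0, params)
    if result is None:
        logger.debug("fit failed at %s, discarded", candidate)
        return None
    fitted, b, crlb = result
    x, y, n_ph, sigma = fitted[0]
    if n_ph < params.min_photons:
        logger.debug("fit below min_photons at %s, discarded", candidate)
        return None

    x_px = cj - r + x
    y_px = ci - r + y
    return Localization(
        frame=frame_index,
        x=x_px * pixel_size,
        y=y_px * pixel_size,
        photons=n_ph,
        background=b,
        sigma_fit=sigma * pixel_size,
        uncertainty=crlb[0] * pixel_size,
        detection_round=detection_round,
        x_px=x_px,
        y_px=y_px,
        sigma_px=sigma,
    )


def spot_model(shape: tuple, loc: Localization) -> np.ndarray:
    """Expected photon image of a fitted spot (no background term)."""
    from .simkit import emitter_image

    return emitter_image(shape, loc.x_px, loc.y_px, loc.photons, loc.sigma_px)


def deflate_and_redetect(
    frame_image: np.ndarray,
    fitted: Sequence[Localization],
    params: DetectionParams,
    pixel_size: float = 1.0,
    frame_index: int = 0,
) -> list:
    """Find additional emitters in the residual after subtracting fits.

    First-pass localizations are never altered (append-only); each new
    detection carries the deflation round that found it. Terminates after
    ``max_deflation_rounds`` or when a round adds nothing.
    """
    image = np.asarray(frame_image, dtype=np.float64)
    existing = list(fitted)
    new: list[Localization] = []
    excl2 = (2.0 * params.psf_sigma) ** 2

    for rnd in range(1, params.max_deflation_rounds + 1):
        residual = image.copy()
        for loc in existing + new:
            residual -= spot_model(residual.shape, loc)
        candidates = detect_candidates(np.clip(residual, 0.0, None), params)
        added = 0
        for cand in candidates:
            ci, cj = cand
            near = any(
                (ci - l.y_px) ** 2 + (cj - l.x_px) ** 2 <= excl2 for l in existing + new
            )
            if near:
                continue
            # fit on the original image; nearby earlier fits float as
            # nuisance parameters but their records are left untouched
            loc = fit_emitter(
                image, cand, params, pixel_size=pixel_size,
                frame_index=frame_index, detection_round=rnd,
                neighbors=existing + new,
            )
            if loc is None:
                continue
            new.append(loc)
            added += 1
        if added == 0:
            break
    return new


def localize_frame(
    frame_image: np.ndarray,
    params: DetectionParams,
    pixel_size: float = 1.0,
    frame_index: int = 0,
) -> list:
    """First-pass detection + fitting + deflation for one photon image."""
    first = []
    for cand in detect_candidates(frame_image, params):
        near = any(
            (cand[0] - l.y_px) ** 2 + (cand[1] - l.x_px) ** 2 <= (2 * params.psf_sigma) ** 2
            for l in first
        )
        if near:
            continue
        loc = fit_emitter(
            frame_image, cand, params, pixel_size=pixel_size, frame_index=frame_index
        )
        if loc is not None:
            first.append(loc)
    extra = deflate_and_redetect(
        frame_image, first, params, pixel_size=pixel_size, frame_index=frame_index
    )
    return first + extra


def localize_stack(
    stack: np.ndarray,
    params: DetectionParams,
    pixel_size: float,
    camera: Optional[CameraModel] = None,
) -> pd.DataFrame:
    """Localize every frame of a movie and return the localization table.

    ``camera`` triggers count-to-photon conversion; pass ``None`` when the
    stack is already in photon units. Per-frame failures are logged and
    skipped, never aborting the run.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise DetectionError("expected a 3D stack (frames, y, x)")
    rows = []
    for f in range(stack.shape[0]):
        frame = stack[f]
        if camera is not None:
            frame = counts_to_photons(frame, camera)
        try:
            locs = localize_frame(frame, params, pixel_size=pixel_size, frame_index=f)
        except DetectionError:
            raise
        except Exception:  # pragma: no cover - defensive skip
            logger.exception("frame %d failed, skipped", f)
            continue
        rows.extend(locs)
    return localizations_to_frame(rows)


def localizations_to_frame(locs: Sequence[Localization]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "frame": [l.frame for l in locs],
            "x_nm": [l.x for l in locs],
            "y_nm": [l.y for l in locs],
            "photons": [l.photons for l in locs],
            "background": [l.background for l in locs],
            "sigma_nm": [l.sigma_fit for l in locs],
            "uncertainty_nm": [l.uncertainty for l in locs],
            "detection_round": [l.detection_round for l in locs],
        }
    )
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_TABLE_COLUMNS})
        df = df.astype({"frame": np.int64, "detection_round": np.int64})
    return df
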