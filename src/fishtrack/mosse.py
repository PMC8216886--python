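"""MOSSE adaptive correlation-filter tracking.

A Minimum Output Sum of Squared Error (MOSSE) tracker learns, in the
Fourier domain, a filter ``H`` whose correlation with the target patch
produces a narrow Gaussian peak at the target location.  With per-frame
patch spectra ``F_i`` and desired-response spectrum ``G``, the filter is

    conj(H) = A / B,   A = sum_i G * conj(F_i),   B = sum_i F_i * conj(F_i)

and is updated online by an exponential moving average with a learning
rate.  Tracking a new frame correlates the filter with the patch at the
previous location; the response-peak offset from the patch centre is the
target displacement, and the peak-to-sidelobe ratio (PSR) of the response
measures tracking quality (low PSR signals occlusion or loss).

The tracker is translation-only: the detection box is resampled to a fixed
square correlation window and output boxes keep the original width and
height.  All randomness (the small affine perturbations used to seed the
initial filter) flows through one seeded generator, so runs are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import BoundingBox

__all__ = ["MosseConfig", "MosseState", "mosse_init", "mosse_step", "to_grayscale"]


@dataclass(frozen=True)
class MosseConfig:
    """MOSSE hyperparameters (defaults follow the original formulation)."""

    window_size: int = 64  # square correlation window, px
    patch_padding: float = 2.0  # search region = box scaled by this factor
    sigma: float = 2.0  # Gaussian response peak width, px
    learning_rate: float = 0.125  # EMA weight of the newest frame
    eps: float = 1e-5  # regularisation added to the filter denominator
    n_perturbations: int = 8  # random affine warps used at initialisation
    max_rotation_deg: float = 10.0
    max_scale_delta: float = 0.05
    psr_threshold: float = 5.7  # below this the step reports track-lost
    psr_exclusion: int = 11  # side of the square masked around the peak

    def __post_init__(self) -> None:
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.window_size < 8:
            raise ValueError("window_size too small")
        if self.patch_padding < 1.0:
            raise ValueError("patch_padding must be >= 1")


@dataclass
class MosseState:
    """Online state of one MOSSE track."""

    numerator: np.ndarray  # A: complex spectrum, window_size^2
    denominator: np.ndarray  # B: complex spectrum, window_size^2
    target_spectrum: np.ndarray  # G: spectrum of the Gaussian response
    current_box: BoundingBox
    config: MosseConfig
    lost: bool = False


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) colour frame to luma (ITU-R 601 weights)."""
    if frame.ndim == 2:
        return np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = np.asarray(frame[..., :3], dtype=np.float64)
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"cannot interpret frame of shape {frame.shape} as an image")


def _extract_patch(frame: np.ndarray, box: BoundingBox, size: int) -> np.ndarray:
    """Resample the box region of a grayscale frame to a size x size patch.

    Bilinear sampling at cell centres; coordinates outside the frame take
    the nearest edge value, so partially visible targets stay usable.
    """
    ys = box.y + (np.arange(size) + 0.5) * box.h / size - 0.5
    xs = box.x + (np.arange(size) + 0.5) * box.w / size - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return ndimage.map_coordinates(
        np.asarray(frame, dtype=np.float64), [yy, xx], order=1, mode="nearest"
    )


def _preprocess(patch: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Log-compress, normalise to zero mean / unit norm, apply Hann window."""
    p = np.log1p(patch - patch.min())
    p -= p.mean()
    norm = np.linalg.norm(p)
    if norm > 0:
        p /= norm
    return p * window


def _hann2d(size: int) -> np.ndarray:
    w = np.hanning(size)
    return np.outer(w, w)


def _gaussian_response(size: int, sigma: float) -> np.ndarray:
    c = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2.0 * sigma**2))


def _random_affine(patch: np.ndarray, rng: np.random.Generator, cfg: MosseConfig) -> np.ndarray:
    """Small random rotation/scale of a patch about its centre."""
    theta = np.deg2rad(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg))
    scale = 1.0 + rng.uniform(-cfg.max_scale_delta, cfg.max_scale_delta)
    c, s = np.cos(theta), np.sin(theta)
    # output -> input mapping: rotate by -theta and divide by scale
    mat = np.array([[c, -s], [s, c]]) / scale
    centre = (np.array(patch.shape) - 1) / 2.0
    offset = centre - mat @ centre
    return ndimage.affine_transform(patch, mat, offset=offset, order=1, mode="nearest")


def _padded_box(box: BoundingBox, padding: float) -> BoundingBox:
    """Search region: the box scaled about its centre.

    Tracking correlates over a region larger than the target so the
    target's own edges (its most discriminative structure when the body
    is smooth) sit in the window interior rather than under the tapering
    flank of the Hann window.
    """
    pw, ph = box.w * padding, box.h * padding
    return BoundingBox(
        box.x - (pw - box.w) / 2.0, box.y - (ph - box.h) / 2.0, pw, ph
    )


def _box_inside_frame(box: BoundingBox, shape: tuple[int, int]) -> bool:
    h, w = shape[:2]
    return box.x2 > 0 and box.y2 > 0 and box.x < w and box.y < h


def mosse_init(
    frame: np.ndarray,
    box: BoundingBox,
    config: MosseConfig | None = None,
    seed: int = 0,
) -> MosseState:
    """Train a fresh MOSSE filter on the patch under ``box``.

    The initial filter averages the patch spectrum over ``n_perturbations``
    small random affine warps (plus the unwarped patch), which regularises
    the filter against pose change.  Deterministic for a fixed ``seed``.
    """
    cfg = config or MosseConfig()
    gray = to_grayscale(frame)
    if not _box_inside_frame(box, gray.shape):
        raise ValueError(f"box {box.as_xywh()} lies fully outside the frame")
    rng = np.random.default_rng(seed)
    size = cfg.window_size
    window = _hann2d(size)
    g_spec = np.fft.fft2(_gaussian_response(size, cfg.sigma))

    patch = _extract_patch(gray, _padded_box(box, cfg.patch_padding), size)
    A = np.zeros((size, size), dtype=np.complex128)
    B = np.zeros((size, size), dtype=np.complex128)
    variants = [patch] + [
        _random_affine(patch, rng, cfg) for _ in range(cfg.n_perturbations)
    ]
    for p in variants:
        F = np.fft.fft2(_preprocess(p, window))
        A += g_spec * np.conj(F)
        B += F * np.conj(F)
    return MosseState(
        numerator=A, denominator=B, target_spectrum=g_spec, current_box=box, config=cfg
    )


def _peak_subpixel(resp: np.ndarray) -> tuple[float, float, tuple[int, int]]:
    """Peak location with quadratic sub-pixel refinement (wrap-aware)."""
    size = resp.shape[0]
    py, px = np.unravel_index(int(np.argmax(resp)), resp.shape)

    def refine(axis_vals: np.ndarray) -> float:
        lo, c, hi = axis_vals
        denom = lo - 2.0 * c + hi
        if denom >= 0:  # not a strict local max; skip refinement
            return 0.0
        delta = 0.5 * (lo - hi) / denom
        return float(np.clip(delta, -0.5, 0.5))

    dy = refine(resp[[(py - 1) % size, py, (py + 1) % size], px])
    dx = refine(resp[py, [(px - 1) % size, px, (px + 1) % size]])
    return py + dy, px + dx, (py, px)


def _psr(resp: np.ndarray, peak: tuple[int, int], exclusion: int) -> float:
    py, px = peak
    size = resp.shape[0]
    half = exclusion // 2
    mask = np.ones_like(resp, dtype=bool)
    ys = (np.arange(py - half, py + half + 1)) % size
    xs = (np.arange(px - half, px + half + 1)) % size
    mask[np.ix_(ys, xs)] = False
    side = resp[mask]
    sd = side.std()
    if sd == 0:
        return 0.0
    return float((resp[py, px] - side.mean()) / sd)


def mosse_step(
    state: MosseState, frame: np.ndarray
) -> tuple[MosseState, BoundingBox, float]:
    """Advance the track one frame.

    Correlates the current filter with the patch at the previous box,
    translates the box to the (sub-pixel refined) response peak, updates
    the filter by EMA at the new location, and returns the new state, the
    new box, and the response PSR.  The returned state's ``lost`` flag is
    set when the PSR falls below the failure threshold or the box drifts
    fully outside the frame.
    """
    cfg = state.config
    size = cfg.window_size
    gray = to_grayscale(frame)
    window = _hann2d(size)

    search = _padded_box(state.current_box, cfg.patch_padding)
    patch = _extract_patch(gray, search, size)
    F = np.fft.fft2(_preprocess(patch, window))
    H_conj = state.numerator / (state.denominator + cfg.eps)
    resp = np.real(np.fft.ifft2(F * H_conj))

    peak_y, peak_x, peak_idx = _peak_subpixel(resp)
    psr = _psr(resp, peak_idx, cfg.psr_exclusion)

    centre = size // 2
    # displacement in window px, wrapped into [-size/2, size/2)
    dy = (peak_y - centre + size / 2) % size - size / 2
    dx = (peak_x - centre + size / 2) % size - size / 2
    box = state.current_box
    new_box = BoundingBox(
        box.x + dx * search.w / size, box.y + dy * search.h / size, box.w, box.h
    )

    lost = psr < cfg.psr_threshold or not _box_inside_frame(new_box, gray.shape)

    new_patch = _extract_patch(gray, _padded_box(new_box, cfg.patch_padding), size)
    Fn = np.fft.fft2(_preprocess(new_patch, window))
    lr = cfg.learning_rate
    new_state = MosseState(
        numerator=lr * state.target_spectrum * np.conj(Fn) + (1 - lr) * state.numerator,
        denominator=lr * Fn * np.conj(Fn) + (1 - lr) * state.denominator,
        target_spectrum=state.target_spectrum,
        current_box=new_box,
        config=cfg,
        lost=lost,
    )
    return new_state, new_box, psr
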