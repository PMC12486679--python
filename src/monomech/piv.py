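"""Window cross-correlation particle image velocimetry.

Single-pass PIV: each interrogation window pair is zero-mean FFT
cross-correlated, the integer peak refined by a three-point Gaussian fit,
and outliers removed by a normalized-median test against the
8-neighbourhood.  Cell velocities use 64 px windows on consecutive
phase-contrast frames; bead displacements use 32 px windows of each frame
against the relaxed reference (both at 0.5 overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

from functools import lru_cache

import numpy as np
from scipy.fft import fft2, ifft2
from scipy.signal.windows import tukey

from .fields import ImageStack, ReferenceImage, VectorField2D


@dataclass(frozen=True)
class PIVConfig:
    """Interrogation settings.

    window: square window side in px (power of two, >= 16).
    overlap: fractional window overlap; 0.5 gives grid pitch window/2.
    subpixel: peak interpolation scheme ("gaussian-3pt").
    outlier_mad_k: normalized-median test threshold multiplier.
    """

    window: int = 64
    overlap: float = 0.5
    subpixel: str = "gaussian-3pt"
    outlier_mad_k: float = 2.0
    passes: int = 1

    def __post_init__(self) -> None:
        w = self.window
        if w < 16 or (w & (w - 1)) != 0:
            raise ValueError("window must be a power of two >= 16")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")

    @property
    def step(self) -> int:
        return max(1, int(round(self.window * (1.0 - self.overlap))))


def _subpixel_offset(c: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """3-point Gaussian (parabolic fallback) refinement along each axis."""
    out = []
    for axis in (0, 1):
        i = peak[axis]
        if i == 0 or i == c.shape[axis] - 1:
            out.append(0.0)
            continue
        sl = [peak[0], peak[1]]
        sl[axis] = slice(i - 1, i + 2)  # type: ignore[call-overload]
        cm, c0, cp = c[tuple(sl)]
        if cm > 0 and c0 > 0 and cp > 0:
            lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        else:
            lm, l0, lp = cm, c0, cp
        den = lm + lp - 2.0 * l0
        out.append(0.0 if den >= 0 or abs(den) < 1e-12
                   else 0.5 * (lm - lp) / den)
    return out[0], out[1]


@lru_cache(maxsize=8)
def _taper_and_norm(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Tukey taper applied to each window, and the unbiased normalization.

    Window content is not periodic, so the raw circular correlation is
    damped by the autocorrelation of the effective weighting, which biases
    the subpixel fit toward zero; dividing by that autocorrelation (floored
    away from zero at large lags) removes the bias.  The taper suppresses
    the edge-discontinuity noise that otherwise wobbles the peak fit.
    """
    wy = tukey(shape[0], 0.5, sym=False)
    wx = tukey(shape[1], 0.5, sym=False)
    W = np.outer(wy, wx)
    auto = np.fft.fftshift(ifft2(np.abs(fft2(W)) ** 2).real)
    norm = np.maximum(auto / auto.max(), 0.05)
    return W, norm


def _correlate_window(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Displacement of b relative to a from the circular correlation peak."""
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0, 0.0, False
    W, norm = _taper_and_norm(a.shape)
    a = (a - a.mean()) * W
    b = (b - b.mean()) * W
    c = ifft2(fft2(b) * np.conj(fft2(a))).real
    c = np.fft.fftshift(c) / norm
    iy, ix = np.unravel_index(np.argmax(c), c.shape)
    dy_s, dx_s = _subpixel_offset(c, (iy, ix))
    dy = iy - a.shape[0] // 2 + dy_s
    dx = ix - a.shape[1] // 2 + dx_s
    return dx, dy, True


def _neighbour_median_filter(u: np.ndarray, v: np.ndarray, valid: np.ndarray,
                             k: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized-median outlier test; outliers replaced by local median."""
    ny, nx = u.shape
    # edge-repeat padding: a one-sided (NaN-padded) neighbourhood median
    # is biased by the field's slope and falsely flags correct border
    # vectors in sheared fields
    pu = np.pad(u, 1, mode="symmetric")
    pv = np.pad(v, 1, mode="symmetric")
    pw = np.pad(np.where(valid, 1.0, np.nan), 1, mode="symmetric")
    nbu = np.empty((8, ny, nx))
    nbv = np.empty((8, ny, nx))
    idx = 0
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            w = pw[1 + dy:1 + dy + ny, 1 + dx:1 + dx + nx]
            nbu[idx] = pu[1 + dy:1 + dy + ny, 1 + dx:1 + dx + nx] * w
            nbv[idx] = pv[1 + dy:1 + dy + ny, 1 + dx:1 + dx + nx] * w
            idx += 1
    import warnings as _warnings
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        med_u = np.nanmedian(nbu, axis=0)
        med_v = np.nanmedian(nbv, axis=0)
        resid = np.hypot(nbu - med_u, nbv - med_v)
        mad = np.nanmedian(resid, axis=0)
        dev = np.hypot(u - med_u, v - med_v)
        bad = valid & np.isfinite(dev) & (dev > k * (mad + 0.1))
    out_valid = valid & ~bad
    fill = bad | ~valid
    u2 = np.where(fill & np.isfinite(med_u), med_u, u)
    v2 = np.where(fill & np.isfinite(med_v), med_v, v)
    return u2, v2, out_valid


def _interp_to_pixels(u: np.ndarray, v: np.ndarray, gy: np.ndarray,
                      gx: np.ndarray, shape: tuple[int, int]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation of a vector grid onto the pixel raster,
    clamped at the grid hull."""
    from scipy.interpolate import RegularGridInterpolator

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    yy = np.clip(yy, gy[0], gy[-1])
    xx = np.clip(xx, gx[0], gx[-1])
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    out = []
    for comp in (u, v):
        it = RegularGridInterpolator((gy, gx), comp, method="linear")
        out.append(it(pts).reshape(shape))
    return out[0], out[1]


def _warp_image(image: np.ndarray, du: np.ndarray, dv: np.ndarray
                ) -> np.ndarray:
    """Sample ``image`` at (y + dv, x + du): undoes the displacement so the
    residual motion against the first frame is small."""
    from scipy.ndimage import map_coordinates

    H, W = image.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    return map_coordinates(image, [yy + dv, xx + du], order=1,
                           mode="nearest")


def piv_pair(image_a: np.ndarray, image_b: np.ndarray,
             config: PIVConfig) -> VectorField2D:
    """PIV between two frames; returns per-window displacement in px.

    The vector at each node is the motion of ``image_b`` relative to
    ``image_a``, anchored at the window centre.  Flat windows and
    normalized-median outliers are flagged invalid (and filled by the
    local median so downstream interpolation never sees NaNs).
    """
    image_a = np.asarray(image_a, dtype=float)
    image_b = np.asarray(image_b, dtype=float)
    if image_a.shape != image_b.shape:
        raise ValueError("frames must share one shape")
    w, step = config.window, config.step
    H, W = image_a.shape
    if H < w or W < w:
        raise ValueError("image smaller than one interrogation window")
    ys = np.arange(0, H - w + 1, step)
    xs = np.arange(0, W - w + 1, step)
    centre = (w - 1) / 2.0
    u = np.zeros((len(ys), len(xs)))
    v = np.zeros_like(u)
    valid = np.zeros(u.shape, dtype=bool)
    # predictor passes with window deformation: image_b is warped by the
    # previous pass's interpolated field, so later passes correlate only
    # the small residual displacement — the peak sits near zero lag where
    # the estimator is most accurate and in-window gradients are removed
    for p in range(config.passes):
        if p == 0:
            b_use = image_b
            pred_u = np.zeros((H, W))
            pred_v = np.zeros((H, W))
        else:
            pred_u, pred_v = _interp_to_pixels(u, v, ys + centre, xs + centre,
                                               (H, W))
            b_use = _warp_image(image_b, pred_u, pred_v)
        for i, y0 in enumerate(ys):
            for j, x0 in enumerate(xs):
                dx, dy, ok = _correlate_window(
                    image_a[y0:y0 + w, x0:x0 + w],
                    b_use[y0:y0 + w, x0:x0 + w])
                ic = (int(round(y0 + centre)), int(round(x0 + centre)))
                u[i, j] = dx + pred_u[ic]
                v[i, j] = dy + pred_v[ic]
                valid[i, j] = ok
        u, v, valid = _neighbour_median_filter(u, v, valid,
                                               config.outlier_mad_k)
    centre = (w - 1) / 2.0
    return VectorField2D(u, v, spacing=float(step), units="px",
                         origin=(float(ys[0] + centre), float(xs[0] + centre)),
                         valid=valid)


def velocity_from_phase(stack: ImageStack, config: PIVConfig | None = None
                        ) -> list[VectorField2D]:
    """Cell velocity fields (µm/h) from consecutive phase-contrast frames."""
    config = config or PIVConfig(window=64, overlap=0.5)
    if len(stack) < 2:
        raise ValueError("need at least two frames")
    px2um = stack.pixel_size
    per_hour = 60.0 / stack.frame_interval
    fields = []
    for a, b in zip(stack.frames[:-1], stack.frames[1:]):
        f = piv_pair(a, b, config)
        fields.append(VectorField2D(
            f.u * px2um * per_hour, f.v * px2um * per_hour,
            spacing=f.spacing * px2um, units="um/h",
            origin=(f.origin[0] * px2um, f.origin[1] * px2um), valid=f.valid))
    return fields


def displacement_from_beads(stack: ImageStack, reference: ReferenceImage,
                            config: PIVConfig | None = None
                            ) -> list[VectorField2D]:
    """Bead displacement fields (µm): each frame against the relaxed reference."""
    config = config or PIVConfig(window=32, overlap=0.5)
    px2um = stack.pixel_size
    fields = []
    for frame in stack.frames:
        f = piv_pair(reference.image, frame, config)
        fields.append(VectorField2D(
            f.u * px2um, f.v * px2um, spacing=f.spacing * px2um, units="um",
            origin=(f.origin[0] * px2um, f.origin[1] * px2um), valid=f.valid))
    return fields
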