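"""Collective spreading, speed, and directionality readouts."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fields import MaskSequence, PrincipalStressField, VectorField2D


def collective_spreading(masks: MaskSequence) -> np.ndarray:
    """Normalised mask area A(t)/A(0) — unitless, pixel size cancels."""
    areas = masks.areas()
    if areas[0] <= 0:
        raise ValueError("initial mask is empty")
    return areas / areas[0]


def relative_spreading_slope(series_a: np.ndarray, series_b: np.ndarray,
                             times: np.ndarray,
                             split_time: float = 4.0) -> tuple[float, float]:
    """OLS slopes of series_b against series_a, before and after the split.

    Mirrors the relative-spreading readout: the normalised area of one
    condition regressed on the other over a common time grid, with the
    early/late phases (default boundary 4 h) fitted separately.
    """
    series_a = np.asarray(series_a, float)
    series_b = np.asarray(series_b, float)
    times = np.asarray(times, float)
    if not (len(series_a) == len(series_b) == len(times)):
        raise ValueError("series and times must share a grid")
    out = []
    for sel in (times < split_time, times >= split_time):
        if sel.sum() < 3:
            raise ValueError("need >= 3 points per regression segment")
        x, y = series_a[sel], series_b[sel]
        if np.ptp(x) == 0:
            raise ValueError("degenerate x-variance in regression segment")
        out.append(float(np.polyfit(x, y, 1)[0]))
    return out[0], out[1]


def speed_field(velocity: VectorField2D) -> np.ndarray:
    """Per-node speed: Euclidean norm of the velocity vector (µm/h)."""
    return velocity.magnitude()


def sample_at_pixels(field: VectorField2D, shape: tuple[int, int],
                     pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a gridded field onto the full pixel raster.

    Values outside the field's node hull are held at the nearest edge so
    mask-based statistics never see NaNs.
    """
    gy = (field.grid_y - 0.0) / pixel_size   # node positions in px
    gx = (field.grid_x - 0.0) / pixel_size
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    yy = np.clip(yy, gy[0], gy[-1])
    xx = np.clip(xx, gx[0], gx[-1])
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    out = []
    for comp in (field.u, field.v):
        it = RegularGridInterpolator((gy, gx), comp, method="linear")
        out.append(it(pts).reshape(shape))
    return out[0], out[1]


def directionality_histogram(field: VectorField2D | PrincipalStressField,
                             mask: np.ndarray | None = None,
                             bin_width: float = 10.0,
                             fold: bool = True,
                             pixel_size: float | None = None
                             ) -> tuple[np.ndarray, np.ndarray, int]:
    """Angular distribution of a vector field or principal orientation.

    For vector fields the per-pixel angle is atan2 of (v up, u right)
    measured from the +x migration axis in (-180, 180]; with ``fold``
    negative angles are flipped to [0, 180].  Principal-stress input uses
    the native smax orientation in [0, 180).  Returns (bin_edges,
    fractions, n_excluded) where fractions sum to 1 and ``n_excluded``
    counts zero-magnitude (angle-undefined) pixels.

    When ``mask`` and ``pixel_size`` are given for a vector field, the
    field is sampled at pixel resolution inside the mask; otherwise grid
    nodes (inside ``mask`` if provided on the node grid) are pooled.
    """
    if isinstance(field, PrincipalStressField):
        m = field.mask if mask is None else (field.mask & mask)
        if not m.any():
            raise ValueError("empty mask")
        sel = m & ~field.isotropic
        angles = field.alpha[sel]
        lo, hi = 0.0, 180.0
        n_excluded = int(m.sum() - sel.sum())
    else:
        if mask is not None and pixel_size is not None:
            u, v = sample_at_pixels(field, mask.shape, pixel_size)
            m = mask
        else:
            u, v = field.u, field.v
            m = np.ones(u.shape, bool) if mask is None else mask
        if not m.any():
            raise ValueError("empty mask")
        mag = np.hypot(u, v)
        sel = m & (mag > 0)
        n_excluded = int(m.sum() - sel.sum())
        # y axis points down in image convention; report angles with y up
        angles = np.degrees(np.arctan2(-v[sel], u[sel]))
        angles = np.where(angles == -180.0, 180.0, angles)   # range (-180, 180]
        if fold:
            angles = np.abs(angles)
            lo, hi = 0.0, 180.0
        else:
            lo, hi = -180.0, 180.0
    span = hi - lo
    nbins = span / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin_width must divide the angular range")
    edges = lo + np.arange(round(nbins) + 1) * bin_width
    counts, _ = np.histogram(np.clip(angles, lo, np.nextafter(hi, lo)),
                             bins=edges)
    if counts.sum() == 0:
        raise ValueError("no nonzero vectors inside the mask")
    return edges, counts / counts.sum(), n_excluded
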