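"""Fourier-transform traction cytometry on a finite-thickness gel.

Inverts measured substrate displacements to the cell-substrate traction
field by inverting the surface compliance tensor of `monomech.elastic`
wavevector by wavevector, with optional Tikhonov regularisation.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import fft2, ifft2
from scipy.interpolate import griddata

from .elastic import greens_tensor_fourier, _padded_shape
from .fields import SubstrateSpec, TractionField, VectorField2D


def _fill_invalid(field: VectorField2D) -> tuple[np.ndarray, np.ndarray]:
    """Replace invalid vectors by nearest/linear interpolation from valid ones."""
    valid = field.all_valid() & np.isfinite(field.u) & np.isfinite(field.v)
    if valid.all():
        return field.u, field.v
    if not valid.any():
        raise ValueError("displacement field contains no valid vectors")
    yy, xx = np.mgrid[0:field.shape[0], 0:field.shape[1]]
    pts = np.column_stack([yy[valid], xx[valid]])
    tgt = np.column_stack([yy[~valid], xx[~valid]])
    out = []
    for comp in (field.u, field.v):
        filled = comp.copy()
        vals = griddata(pts, comp[valid], tgt, method="linear")
        nn = griddata(pts, comp[valid], tgt, method="nearest")
        vals = np.where(np.isfinite(vals), vals, nn)
        filled[~valid] = vals
        out.append(filled)
    return out[0], out[1]


def fttc_invert(displacement: VectorField2D, substrate: SubstrateSpec,
                regularization: float = 0.0, pad: int = 2) -> TractionField:
    """Recover the traction field (Pa) from a displacement field (µm).

    Per nonzero wavevector solves ``u(k) = G(k) T(k)`` for T.  With
    ``regularization`` (Tikhonov parameter λ, µm/Pa units of G) the solve
    becomes ``T = (G^T G + λ² I)^{-1} G^T u``, which damps the noise-
    amplifying high wavenumbers; λ = 0 is the plain inverse.  The
    zero-wavevector traction is set to zero (no net force convention).

    The field is mean-subtracted and zero-padded ``pad``× before the FFT
    (pad=1 disables padding and makes the operator the exact inverse of
    :func:`monomech.elastic.forward_displacement` at the same pad).
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if displacement.units not in ("um",):
        raise ValueError("displacement field must carry units 'um'")
    ux, uy = _fill_invalid(displacement)
    ny, nx = ux.shape
    if pad > 1:
        ux = ux - ux.mean()
        uy = uy - uy.mean()
    py, px = _padded_shape(ny, pad), _padded_shape(nx, pad)

    G = greens_tensor_fourier(py, px, displacement.spacing, substrate)
    ukx = fft2(ux, s=(py, px))
    uky = fft2(uy, s=(py, px))

    # G(k) is symmetric; diagonalise it analytically per wavevector and
    # apply the Tikhonov filter g/(g^2 + lam^2) to each eigenvalue.  At
    # lam=0 this is the plain (numerically exact) inverse of the forward
    # operator on the same grid.
    a, b, c = G[..., 0, 0], G[..., 1, 1], G[..., 0, 1]
    half_tr = 0.5 * (a + b)
    rad = np.hypot(0.5 * (a - b), c)
    g1, g2 = half_tr + rad, half_tr - rad
    theta = 0.5 * np.arctan2(2.0 * c, a - b)
    e1x, e1y = np.cos(theta), np.sin(theta)
    lam2 = regularization**2

    def filt(g: np.ndarray) -> np.ndarray:
        den = np.where(g > 0, g * g + lam2, 1.0)
        return np.where(g > 0, g, 0.0) / den

    u1 = ukx * e1x + uky * e1y
    u2 = -ukx * e1y + uky * e1x
    t1, t2 = filt(g1) * u1, filt(g2) * u2
    tkx = t1 * e1x - t2 * e1y
    tky = t1 * e1y + t2 * e1x

    Tx = ifft2(tkx).real[:ny, :nx]
    Ty = ifft2(tky).real[:ny, :nx]
    return TractionField(Tx, Ty, spacing=displacement.spacing, units="Pa",
                         origin=displacement.origin)


def denoise_displacement(field: VectorField2D,
                         noise_sigma: float | None = None) -> VectorField2D:
    """Wiener-style spectral shrinkage of a measured displacement field.

    PIV noise is close to white while the elastic displacement of a cell
    collective is spectrally concentrated at low wavenumber, so shrinking
    each Fourier mode by ``max(0, 1 - N sigma^2 / |u(k)|^2)`` suppresses
    the noise-dominated modes that traction inversion would otherwise
    amplify.  ``noise_sigma`` (same units as the field) is estimated from
    the local detrended residual (field minus 3x3 moving average) when not
    given.  Purely a pre-filter: the inversion itself is unchanged.
    """
    from scipy.ndimage import uniform_filter

    u, v = field.u, field.v
    if noise_sigma is None:
        ru = u - uniform_filter(u, 3)
        rv = v - uniform_filter(v, 3)
        # 3x3 mean removal keeps 8/9 of white noise variance
        sigma2 = 0.5 * (ru.var() + rv.var()) / (1.0 - 1.0 / 9.0)
    else:
        sigma2 = float(noise_sigma) ** 2
    npow = u.size * sigma2
    out = []
    for comp in (u, v):
        ck = fft2(comp)
        shrink = np.maximum(0.0, 1.0 - npow / (np.abs(ck) ** 2 + 1e-300))
        out.append(ifft2(ck * shrink).real)
    return field.with_components(out[0], out[1])


def traction_magnitude(traction: TractionField) -> np.ndarray:
    """Per-node Euclidean norm of the traction vector (Pa)."""
    return traction.magnitude()
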