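"""Surface elasticity of a finite-thickness gel in Fourier space.

The gel is a laterally infinite, linear elastic layer of thickness ``h``
bonded to a rigid base.  A tangential traction applied at the free surface
(with zero normal surface stress) produces an in-plane surface displacement
whose Fourier transform is the traction transform multiplied by a 2x2
compliance tensor ``G(k)``.  By in-plane isotropy the tensor is diagonal in
the (longitudinal, transverse) basis of each wavevector:

    u_l(k) = G_l(|k|) T_l(k),   u_t(k) = G_t(|k|) T_t(k)

with, for s = |k| h and c = 3 - 4 nu,

    G_l = 2 (1 - nu^2) / (E |k|) * 2 (2 s + c sinh 2s)
                                   / (4 s^2 + c^2 + 1 + 2 c cosh 2s)
    G_t = 2 (1 + nu)   / (E |k|) * tanh(s)

As h -> inf both reduce to the classical Boussinesq half-space factors
2(1-nu^2)/(E|k|) and 2(1+nu)/(E|k|), i.e. the standard FTTC tensor.  The
expressions are finite at nu = 1/2 (incompressible gel), so no special
casing is needed there.

These factors were obtained by solving the plane-strain (longitudinal) and
antiplane (transverse) boundary-value problems for the bonded layer in
closed form; the half-space limits above serve as the independent check.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import fft2, ifft2, fftfreq

from .fields import SubstrateSpec, VectorField2D


def longitudinal_compliance(k: np.ndarray, substrate: SubstrateSpec) -> np.ndarray:
    """G_l(|k|): response along the wavevector, per unit traction.

    ``k`` in rad/µm, modulus in Pa -> compliance in µm/Pa.  ``k`` must be
    nonzero; vectorised over arrays.
    """
    E, nu, h = substrate.youngs_modulus, substrate.poisson, substrate.thickness
    k = np.asarray(k, dtype=float)
    base = 2.0 * (1.0 - nu**2) / (E * k)
    if not np.isfinite(h):
        return base
    c = 3.0 - 4.0 * nu
    s = k * h
    # divide through by cosh(2s) for overflow-free evaluation at large s
    sech = 1.0 / np.cosh(np.minimum(2.0 * s, 700.0))
    num = 2.0 * (2.0 * s * sech + c * np.tanh(2.0 * s))
    den = (4.0 * s**2 + c**2 + 1.0) * sech + 2.0 * c
    return base * num / den


def transverse_compliance(k: np.ndarray, substrate: SubstrateSpec) -> np.ndarray:
    """G_t(|k|): response perpendicular to the wavevector (antiplane shear)."""
    E, nu, h = substrate.youngs_modulus, substrate.poisson, substrate.thickness
    k = np.asarray(k, dtype=float)
    base = 2.0 * (1.0 + nu) / (E * k)
    if not np.isfinite(h):
        return base
    return base * np.tanh(k * h)


def _wavevectors(ny: int, nx: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    ky = 2.0 * np.pi * fftfreq(ny, d=spacing)
    kx = 2.0 * np.pi * fftfreq(nx, d=spacing)
    return np.meshgrid(ky, kx, indexing="ij")


def compliance_eigenbasis(ny: int, nx: int, spacing: float,
                          substrate: SubstrateSpec
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition of G(k) on the FFT grid.

    Returns ``(gl, gt, ex, ey)``: longitudinal and transverse compliances
    (µm/Pa) and the unit-wavevector components.  The compliances at the
    zero wavevector are set to zero: a uniform traction on an unbounded
    surface has no finite displacement, and balanced fields carry no DC
    component anyway.
    """
    kyy, kxx = _wavevectors(ny, nx, spacing)
    kmag = np.hypot(kxx, kyy)
    kmag_safe = np.where(kmag == 0, 1.0, kmag)
    gl = np.where(kmag == 0, 0.0, longitudinal_compliance(kmag_safe, substrate))
    gt = np.where(kmag == 0, 0.0, transverse_compliance(kmag_safe, substrate))
    ex, ey = kxx / kmag_safe, kyy / kmag_safe
    return gl, gt, ex, ey


def greens_tensor_fourier(ny: int, nx: int, spacing: float,
                          substrate: SubstrateSpec) -> np.ndarray:
    """Assemble G(k) as a (ny, nx, 2, 2) array in (x, y) component order.

    On the Nyquist rows/columns of an even-sized grid the sign of the
    wavevector is ambiguous (k and -k alias to the same bin), which makes
    the odd cross term ``(gl-gt) ex ey`` ill-defined there; it is set to
    zero so the tensor is even in k and the spatial operator maps real
    fields to real fields exactly.
    """
    gl, gt, ex, ey = compliance_eigenbasis(ny, nx, spacing, substrate)
    cross = (gl - gt) * ex * ey
    nyq = np.zeros((ny, nx), dtype=bool)
    if ny % 2 == 0:
        nyq[ny // 2, :] = True
    if nx % 2 == 0:
        nyq[:, nx // 2] = True
    cross = np.where(nyq, 0.0, cross)
    G = np.empty((ny, nx, 2, 2))
    G[..., 0, 0] = gl * ex * ex + gt * ey * ey
    G[..., 1, 1] = gl * ey * ey + gt * ex * ex
    G[..., 0, 1] = G[..., 1, 0] = cross
    return G


def _padded_shape(n: int, pad: int) -> int:
    from scipy.fft import next_fast_len
    return next_fast_len(n * pad) if pad > 1 else n


def forward_displacement(traction: VectorField2D, substrate: SubstrateSpec,
                         pad: int = 2) -> VectorField2D:
    """Surface displacement (µm) produced by a traction field (Pa).

    Multiplies the traction transform by the finite-thickness surface
    compliance tensor.  ``pad`` >= 2 zero-pads the field before the FFT to
    suppress periodic wrap-around (the traction is physically zero outside
    a compactly supported scene); ``pad=1`` applies the bare periodic
    operator, which is the exact algebraic partner of the inversion.
    """
    if traction.units != "Pa":
        raise ValueError("traction field must carry units 'Pa'")
    Tx, Ty = traction.u, traction.v
    if not (np.all(np.isfinite(Tx)) and np.all(np.isfinite(Ty))):
        raise ValueError("traction contains non-finite values")
    ny, nx = Tx.shape
    py, px = _padded_shape(ny, pad), _padded_shape(nx, pad)

    G = greens_tensor_fourier(py, px, traction.spacing, substrate)
    tkx = fft2(Tx, s=(py, px))
    tky = fft2(Ty, s=(py, px))
    ukx = G[..., 0, 0] * tkx + G[..., 0, 1] * tky
    uky = G[..., 1, 0] * tkx + G[..., 1, 1] * tky
    ux = ifft2(ukx).real[:ny, :nx]
    uy = ifft2(uky).real[:ny, :nx]
    return VectorField2D(ux, uy, spacing=traction.spacing, units="um",
                         origin=traction.origin)
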