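"""Monolayer stress microscopy: intercellular stress from traction fields.

The cell sheet is treated as a thin elastic plate of height ``h`` in
mechanical equilibrium with the substrate reaction: the tractions ``T``
the cells exert on the gel enter the sheet as the distributed reaction
``-T``, so the in-plane stress tensor satisfies

    h * d(sigma_ij)/d(x_j) = T_i     inside the mask,
    sigma . n = 0                    on the mask boundary (free margin).

The balance is closed by linear-elastic compatibility with Poisson ratio
``poisson_m`` (the recovered stresses are only weakly sensitive to it; the
sheet modulus drops out entirely).  Discretisation is bilinear Q4 plane-
stress finite elements on the traction grid, one element per grid cell
whose four corners lie in the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .fields import (MonolayerSpec, PrincipalStressField, StressTensorField,
                     TractionField)

# 2x2 Gauss points on the bi-unit square
_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
# Q4 node local coordinates, counter-clockwise from (-1,-1)
_XI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def _q4_b_matrix(xi: float, eta: float, a: float) -> np.ndarray:
    """Strain-displacement matrix of a square Q4 element with side a."""
    dN = np.empty((4, 2))
    for i, (xn, yn) in enumerate(_XI):
        dN[i, 0] = 0.25 * xn * (1 + eta * yn) * (2.0 / a)
        dN[i, 1] = 0.25 * yn * (1 + xi * xn) * (2.0 / a)
    B = np.zeros((3, 8))
    for i in range(4):
        B[0, 2 * i] = dN[i, 0]
        B[1, 2 * i + 1] = dN[i, 1]
        B[2, 2 * i] = dN[i, 1]
        B[2, 2 * i + 1] = dN[i, 0]
    return B


def _plane_stress_D(poisson: float) -> np.ndarray:
    # unit sheet modulus: recovered stress is independent of its value
    nu = poisson
    return (1.0 / (1.0 - nu * nu)) * np.array([
        [1.0, nu, 0.0],
        [nu, 1.0, 0.0],
        [0.0, 0.0, (1.0 - nu) / 2.0]])


def _element_matrices(a: float, poisson: float) -> tuple[np.ndarray, list[np.ndarray]]:
    """Stiffness (unit thickness/modulus) and per-Gauss-point D@B blocks."""
    D = _plane_stress_D(poisson)
    K = np.zeros((8, 8))
    DBs = []
    detJ = (a / 2.0) ** 2
    for gx, gy in _GP:
        B = _q4_b_matrix(gx, gy, a)
        K += B.T @ D @ B * detJ
        DBs.append(D @ B)
    return K, DBs


@dataclass
class StressRecoveryResult:
    """Recovered stress plus solver diagnostics."""

    stress: StressTensorField
    residual: float            # max |h div(sigma) - T| / max |T|, discrete
    net_force: tuple[float, float]
    components: int


def recover_stress(traction: TractionField, mask: np.ndarray,
                   spec: MonolayerSpec | None = None,
                   balance_tol: float = 0.05,
                   project_balance: bool = True) -> StressTensorField:
    """Recover the in-plane stress tensor (Pa) over the mask.

    ``traction`` is the cell-on-gel field on a regular grid; ``mask`` a
    boolean array on the same grid marking the monolayer.  Disconnected
    mask islands are solved independently.  If the masked traction carries
    a net force or torque larger than ``balance_tol`` (relative to the
    total absolute load), it is projected out when ``project_balance`` is
    true, otherwise an error is raised.
    """
    return recover_stress_full(traction, mask, spec, balance_tol,
                               project_balance).stress


def recover_stress_full(traction: TractionField, mask: np.ndarray,
                        spec: MonolayerSpec | None = None,
                        balance_tol: float = 0.05,
                        project_balance: bool = True) -> StressRecoveryResult:
    spec = spec or MonolayerSpec()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != traction.shape:
        raise ValueError("mask and traction grids must match")
    ny, nx = mask.shape
    a = traction.spacing            # element side, µm
    h = spec.height

    # elements: grid cells with all four corner nodes inside the mask
    cell = mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]
    if not cell.any():
        raise ValueError("mask too thin: no complete grid cell inside")
    labels, ncomp = ndimage.label(cell)

    Ke, DBs = _element_matrices(a, spec.poisson_m)

    sxx = np.zeros((ny, nx))
    syy = np.zeros((ny, nx))
    sxy = np.zeros((ny, nx))
    wsum = np.zeros((ny, nx))
    worst_resid = 0.0
    net = np.zeros(2)

    if ncomp > 1:
        warnings.warn(f"mask has {ncomp} disconnected islands; "
                      "solving each independently")

    Tx, Ty = traction.u, traction.v
    for comp in range(1, ncomp + 1):
        cells = np.argwhere(labels == comp)          # (ne, 2) of (cy, cx)
        cy, cx = cells[:, 0], cells[:, 1]
        # corner nodes in local ccw order (x0,y0),(x1,y0),(x1,y1),(x0,y1)
        corner_y = np.stack([cy, cy, cy + 1, cy + 1], axis=1)
        corner_x = np.stack([cx, cx + 1, cx + 1, cx], axis=1)
        node_id = -np.ones((ny, nx), dtype=np.int64)
        node_pix = np.unique(
            np.stack([corner_y.ravel(), corner_x.ravel()], axis=1), axis=0)
        node_id[node_pix[:, 0], node_pix[:, 1]] = np.arange(len(node_pix))
        nodes = node_pix
        nn = len(node_pix)
        ids = node_id[corner_y, corner_x]            # (ne, 4)
        dofs = np.empty((len(cells), 8), dtype=np.int64)
        dofs[:, 0::2] = 2 * ids
        dofs[:, 1::2] = 2 * ids + 1

        # lumped nodal load: reaction -T, a^2/4 per element corner
        F = np.zeros(2 * nn)
        np.add.at(F, 2 * ids, -Tx[corner_y, corner_x] * a * a / 4.0)
        np.add.at(F, 2 * ids + 1, -Ty[corner_y, corner_x] * a * a / 4.0)

        total = np.abs(F).sum() + 1e-300
        netF = np.array([F[0::2].sum(), F[1::2].sum()])
        ypos = nodes[:, 0] * a
        xpos = nodes[:, 1] * a
        xc, yc = xpos.mean(), ypos.mean()
        torque = np.sum((xpos - xc) * F[1::2] - (ypos - yc) * F[0::2])
        rel = np.linalg.norm(netF) / total
        if rel > balance_tol and not project_balance:
            raise ValueError(f"unbalanced traction (net force {rel:.1%} of "
                             "total load); pass project_balance=True")
        # project net force and torque out of the load
        F[0::2] -= netF[0] / nn
        F[1::2] -= netF[1] / nn
        rx, ry = xpos - xc, ypos - yc
        r2 = np.sum(rx * rx + ry * ry) + 1e-300
        F[0::2] -= torque * (-ry) / r2
        F[1::2] -= torque * rx / r2
        net += netF

        # assemble stiffness (identical Ke for every square element)
        rows = np.repeat(dofs, 8, axis=1).ravel()
        cols = np.tile(dofs, (1, 8)).ravel()
        vals = np.tile(Ke.ravel(), len(cells))
        K = sparse.csr_matrix((vals, (rows, cols)), shape=(2 * nn, 2 * nn))

        # pin three dofs to remove rigid-body modes; the load is balanced,
        # so the pin reactions vanish and the stress field is unaffected
        ia = 0
        far = np.argmax((xpos - xpos[ia])**2 + (ypos - ypos[ia])**2)
        pins = [2 * ia, 2 * ia + 1,
                2 * far + (0 if abs(ypos[far] - ypos[ia]) >
                           abs(xpos[far] - xpos[ia]) else 1)]
        keep = np.setdiff1d(np.arange(2 * nn), pins)
        Kred = K[keep][:, keep].tocsc()
        d = np.zeros(2 * nn)
        d[keep] = spsolve(Kred, F[keep])

        resid = np.abs(K @ d - F).max() / (np.abs(F).max() + 1e-300)
        worst_resid = max(worst_resid, resid)

        # element stresses: average of Gauss-point values, scattered to nodes
        DBmean = np.mean(DBs, axis=0)                # (3, 8)
        sig = (d[dofs] @ DBmean.T) / h               # (ne, 3)
        for c in range(4):
            np.add.at(sxx, (corner_y[:, c], corner_x[:, c]), sig[:, 0])
            np.add.at(syy, (corner_y[:, c], corner_x[:, c]), sig[:, 1])
            np.add.at(sxy, (corner_y[:, c], corner_x[:, c]), sig[:, 2])
            np.add.at(wsum, (corner_y[:, c], corner_x[:, c]), 1.0)

    node_mask = wsum > 0
    w = np.where(node_mask, wsum, 1.0)
    field = StressTensorField(sxx / w, syy / w, sxy / w,
                              spacing=traction.spacing, mask=node_mask)
    return StressRecoveryResult(field, worst_resid,
                                (float(net[0]), float(net[1])), ncomp)


def principal_stresses(tensor: StressTensorField,
                       iso_tol: float = 1e-9) -> PrincipalStressField:
    """Per-node eigen-decomposition of the stress tensor.

    smax/smin = (sxx+syy)/2 ± sqrt(((sxx-syy)/2)^2 + sxy^2); alpha is the
    orientation of smax from the x-axis, mapped to [0, 180) degrees.
    Isotropic nodes (smax == smin) have no defined orientation and are
    flagged.
    """
    mean = 0.5 * (tensor.sxx + tensor.syy)
    rad = np.hypot(0.5 * (tensor.sxx - tensor.syy), tensor.sxy)
    smax, smin = mean + rad, mean - rad
    alpha = np.degrees(0.5 * np.arctan2(2.0 * tensor.sxy,
                                        tensor.sxx - tensor.syy))
    alpha = np.mod(alpha, 180.0)
    scale = np.maximum(np.abs(smax), np.abs(smin)) + 1e-300
    isotropic = rad / scale < iso_tol
    return PrincipalStressField(smax, smin, alpha, mask=tensor.mask,
                                isotropic=isotropic)


def average_normal_stress(p: PrincipalStressField) -> np.ndarray:
    """ANS = (smax + smin)/2; positive = intercellular tension."""
    return 0.5 * (p.smax + p.smin)


def maximum_shear_stress(p: PrincipalStressField,
                         mode: str = "half-difference") -> np.ndarray:
    """MSS: 'half-difference' (smax - smin)/2 (mechanical maximum shear)
    or the 'difference' smax - smin."""
    if mode == "half-difference":
        return 0.5 * (p.smax - p.smin)
    if mode == "difference":
        return p.smax - p.smin
    raise ValueError(f"unknown MSS mode {mode!r}")


def stress_anisotropy(p: PrincipalStressField,
                      mode: str = "eccentricity") -> np.ndarray:
    """Anisotropy of the principal-stress ellipse.

    'eccentricity' (default): e = sqrt(1 - smin^2/smax^2), 0 for an
    isotropic (circular) state and 1 for a degenerate (line) one.
    'ratio': the literal printed form sqrt(smin^2/smax^2) = |smin/smax|,
    kept for audit.  Nodes with smax == 0 are returned as NaN.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio2 = np.where(p.smax != 0, (p.smin / np.where(p.smax == 0, 1, p.smax))**2,
                          np.nan)
    if mode == "eccentricity":
        return np.sqrt(np.clip(1.0 - ratio2, 0.0, None))
    if mode == "ratio":
        return np.sqrt(ratio2)
    raise ValueError(f"unknown anisotropy mode {mode!r}")
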