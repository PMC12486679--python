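"""Strain energy and migration-efficiency metrics.

The work a cell collective does on its elastic substrate is

    U  = 1/2 ∫_A T(x,y) · u(x,y) dA        (joules)

with T the traction (Pa) and u the substrate displacement (m).  If T and
u were perfectly aligned everywhere, the same magnitudes would store the
upper bound

    U* = 1/2 ∫_A |T| |u| dA,

and the ratio eta = U/U* is the total efficiency of directed migration:
1 for a perfectly aligned (maximally efficient) collective.  The local
alignment cos(theta) = T·u / (|T||u|) plays the same role pointwise.
eta is mathematically in [-1, 1]; negative values (net antagonistic
traction) are reported as-is, with a flag, rather than clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fields import TractionField, VectorField2D

_UM2_TO_M2 = 1e-12   # grid-cell area µm² -> m²
_UM_TO_M = 1e-6


def _check_pair(traction: TractionField, displacement: VectorField2D,
                mask: np.ndarray | None) -> np.ndarray:
    if traction.units != "Pa":
        raise ValueError("traction must carry units 'Pa'")
    if displacement.units != "um":
        raise ValueError("displacement must carry units 'um'")
    if traction.shape != displacement.shape:
        raise ValueError("fields must be co-registered on one grid")
    if traction.spacing != displacement.spacing:
        raise ValueError("fields must share grid spacing")
    if mask is None:
        return np.ones(traction.shape, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != traction.shape:
        raise ValueError("mask must live on the field grid")
    return mask


def strain_energy(traction: TractionField, displacement: VectorField2D,
                  mask: np.ndarray | None = None) -> float:
    """U = 1/2 Σ_mask (T·u) Δx Δy, in joules."""
    m = _check_pair(traction, displacement, mask)
    dA = (traction.spacing ** 2) * _UM2_TO_M2
    dot = traction.u * displacement.u + traction.v * displacement.v
    return float(0.5 * np.sum(dot[m]) * _UM_TO_M * dA)


def ideal_strain_energy(traction: TractionField, displacement: VectorField2D,
                        mask: np.ndarray | None = None) -> float:
    """U* = 1/2 Σ_mask |T||u| Δx Δy — the perfect-alignment bound."""
    m = _check_pair(traction, displacement, mask)
    dA = (traction.spacing ** 2) * _UM2_TO_M2
    prod = traction.magnitude() * displacement.magnitude()
    return float(0.5 * np.sum(prod[m]) * _UM_TO_M * dA)


def total_efficiency(traction: TractionField, displacement: VectorField2D,
                     mask: np.ndarray | None = None) -> float:
    """eta = U / U*; NaN (with a warning) when U* = 0."""
    u = strain_energy(traction, displacement, mask)
    u_star = ideal_strain_energy(traction, displacement, mask)
    if u_star == 0.0:
        warnings.warn("U* = 0: efficiency undefined on this field pair")
        return float("nan")
    eta = u / u_star
    if eta < 0:
        warnings.warn(f"eta = {eta:.3f} < 0: net antagonistic traction")
    return eta


def local_efficiency(traction: TractionField, displacement: VectorField2D,
                     mask: np.ndarray | None = None,
                     magnitude_floor: str | tuple[float, float] = "auto"
                     ) -> np.ndarray:
    """cos(theta) per node; NaN where either vector is (near) zero.

    ``magnitude_floor``: ("auto") the 5th percentile of |T| and |u| outside
    the mask (the background noise level), or an explicit (T_floor,
    u_floor) pair, or (0, 0) to disable.  Nodes below the floor have no
    meaningful direction and are excluded from the map.
    """
    m = _check_pair(traction, displacement, mask)
    tmag = traction.magnitude()
    umag = displacement.magnitude()
    if magnitude_floor == "auto":
        outside = ~m
        if outside.any() and mask is not None:
            tfloor = float(np.percentile(tmag[outside], 5))
            ufloor = float(np.percentile(umag[outside], 5))
        else:
            tfloor = ufloor = 0.0
    else:
        tfloor, ufloor = magnitude_floor
    dot = traction.u * displacement.u + traction.v * displacement.v
    ok = m & (tmag > tfloor) & (umag > ufloor) & (tmag > 0) & (umag > 0)
    out = np.full(traction.shape, np.nan)
    out[ok] = dot[ok] / (tmag[ok] * umag[ok])
    return out


@dataclass(frozen=True)
class EnergyRecord:
    """Per-timepoint energy summary."""

    t: float        # hours
    U: float        # joules
    U_star: float   # joules
    eta: float

    def __post_init__(self) -> None:
        if self.U_star < 0:
            raise ValueError("U* must be non-negative")


def energy_series(tractions: list[TractionField],
                  displacements: list[VectorField2D],
                  masks, times: np.ndarray) -> list[EnergyRecord]:
    """Energy metrics for a whole timelapse (one record per timepoint)."""
    recs = []
    for i, (T, u) in enumerate(zip(tractions, displacements)):
        m = masks.masks[i] if hasattr(masks, "masks") else masks[i]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs.append(EnergyRecord(
                t=float(times[i]),
                U=strain_energy(T, u, m),
                U_star=ideal_strain_energy(T, u, m),
                eta=total_efficiency(T, u, m)))
    return recs
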