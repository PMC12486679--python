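"""Gridded field containers shared by every pipeline stage.

All fields live on regular 2D grids in image convention: arrays are
``(ny, nx)``, index ``[row, col]`` = ``(y, x)``, origin at the top-left,
y increasing downward.  Physical coordinates are in micrometres; the
migration axis is x.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class VectorField2D:
    """A 2-component vector field on a regular grid.

    Parameters
    ----------
    u, v : ndarray, shape (ny, nx)
        x- and y-components.
    spacing : float
        Grid pitch in µm (same in x and y).
    units : str
        One of ``"um"``, ``"um/h"``, ``"Pa"``, ``"px"``.
    origin : (float, float)
        (y0, x0) of grid node [0, 0] in µm.
    valid : ndarray of bool or None
        Per-vector validity flags (True = measured, False = interpolated
        or rejected).  ``None`` means all valid.
    """

    u: np.ndarray
    v: np.ndarray
    spacing: float
    units: str
    origin: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share one shape")
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if not self.units:
            raise ValueError("units tag is required")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.u.shape:
                raise ValueError("valid mask must match component shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @property
    def grid_y(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.shape[0]) * self.spacing

    @property
    def grid_x(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.shape[1]) * self.spacing

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def all_valid(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid

    def with_components(self, u: np.ndarray, v: np.ndarray,
                        units: str | None = None) -> "VectorField2D":
        return replace(self, u=u, v=v, units=units or self.units)

    def to_dataframe(self) -> pd.DataFrame:
        yy, xx = np.meshgrid(self.grid_y, self.grid_x, indexing="ij")
        return pd.DataFrame({
            "x_um": xx.ravel(), "y_um": yy.ravel(),
            "u": self.u.ravel(), "v": self.v.ravel(),
            "valid": self.all_valid().ravel(),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, units: str) -> "VectorField2D":
        df = pd.read_csv(path)
        xs = np.unique(df["x_um"].to_numpy())
        ys = np.unique(df["y_um"].to_numpy())
        nx, ny = len(xs), len(ys)
        order = np.lexsort((df["x_um"].to_numpy(), df["y_um"].to_numpy()))
        u = df["u"].to_numpy()[order].reshape(ny, nx)
        v = df["v"].to_numpy()[order].reshape(ny, nx)
        valid = df["valid"].to_numpy()[order].reshape(ny, nx).astype(bool)
        spacing = float(xs[1] - xs[0]) if nx > 1 else float(ys[1] - ys[0])
        return cls(u, v, spacing=spacing, units=units,
                   origin=(float(ys[0]), float(xs[0])), valid=valid)


# A traction field is a VectorField2D with units "Pa"; the alias keeps
# signatures readable.
TractionField = VectorField2D


@dataclass
class StressTensorField:
    """Symmetric in-plane stress tensor per node, defined inside a mask."""

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    spacing: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.sxx = np.asarray(self.sxx, dtype=float)
        self.syy = np.asarray(self.syy, dtype=float)
        self.sxy = np.asarray(self.sxy, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        shapes = {self.sxx.shape, self.syy.shape, self.sxy.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("tensor components and mask must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.sxx.shape

    def to_dataframe(self) -> pd.DataFrame:
        yy, xx = np.mgrid[0:self.shape[0], 0:self.shape[1]]
        m = self.mask
        return pd.DataFrame({
            "x_um": xx[m] * self.spacing, "y_um": yy[m] * self.spacing,
            "sxx_Pa": self.sxx[m], "syy_Pa": self.syy[m], "sxy_Pa": self.sxy[m],
        })


@dataclass
class PrincipalStressField:
    """Principal values and orientation of an in-plane stress tensor.

    ``alpha`` is the angle of the maximum principal direction relative
    to the x-axis, in degrees in [0, 180).  Where the tensor is isotropic
    the orientation is undefined; ``isotropic`` flags those nodes.
    """

    smax: np.ndarray
    smin: np.ndarray
    alpha: np.ndarray
    mask: np.ndarray
    isotropic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.isotropic is None:
            self.isotropic = np.zeros(np.shape(self.smax), dtype=bool)
        if not np.all(self.smax[self.mask] >= self.smin[self.mask] - 1e-9):
            raise ValueError("smax must dominate smin inside the mask")


@dataclass
class ImageStack:
    """Timelapse image stack with physical calibration.

    ``pixel_size`` is µm/px and ``frame_interval`` minutes between frames.
    """

    frames: np.ndarray            # (nt, ny, nx)
    pixel_size: float
    frame_interval: float
    channel: str = "phase"        # {"phase", "beads"}

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (nt, ny, nx) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_hours(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval / 60.0


@dataclass
class ReferenceImage:
    """Cell-free relaxed bead image used as the zero-displacement state."""

    image: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("reference must be a single 2D image")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class MaskSequence:
    """Binary collective masks per timepoint; x is the migration axis."""

    masks: np.ndarray             # (nt, ny, nx) bool
    times: np.ndarray             # hours
    position_id: str = "pos0"

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        self.times = np.asarray(self.times, dtype=float)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (nt, ny, nx)")
        if len(self.times) != self.masks.shape[0]:
            raise ValueError("one time per mask required")
        if not self.masks.reshape(len(self.times), -1).any(axis=1).all():
            raise ValueError("every mask needs at least one on-pixel")

    def __len__(self) -> int:
        return self.masks.shape[0]

    def areas(self) -> np.ndarray:
        return self.masks.sum(axis=(1, 2)).astype(float)


@dataclass(frozen=True)
class SubstrateSpec:
    """Linear elastic gel: Young's modulus (Pa), Poisson ratio, thickness (µm).

    ``thickness=np.inf`` selects the elastic half-space (Boussinesq) limit.
    """

    youngs_modulus: float = 10400.0
    poisson: float = 0.457
    thickness: float = 50.0

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.thickness <= 0:
            raise ValueError("gel thickness must be positive")


@dataclass(frozen=True)
class MonolayerSpec:
    """Effective monolayer sheet used by stress recovery.

    ``height`` (µm) converts in-plane line tension to a stress in Pa;
    ``poisson_m`` is the compatibility closure of the elastic-sheet model.
    """

    height: float = 5.0
    poisson_m: float = 0.5

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("monolayer height must be positive")
        if not 0.0 <= self.poisson_m <= 0.5:
            raise ValueError("poisson_m must lie in [0, 0.5]")
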