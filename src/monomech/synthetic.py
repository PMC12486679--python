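"""Ground-truth scene generation for end-to-end pipeline validation.

Emulates the experimental geometry the pipeline targets: a long
rectangular cell monolayer strip (the micropatterned collective) on a soft
elastic gel, pulling the substrate inward along the migration axis x.  A
scene bundles a traction truth, the exact forward elastic displacement it
produces, rendered fluorescent-bead images (reference + deformed), and a
binary collective mask — so every analysis stage can be checked against
known truth without any experimental data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import erf

from . import elastic
from .fields import MaskSequence, SubstrateSpec, VectorField2D

#: default bead image size used by packaged demo scenes (px)
DEFAULT_SHAPE = (192, 192)


@dataclass(frozen=True)
class NoiseModel:
    """Imaging noise for bead rendering.

    bead_density in beads/µm²; spot_sigma in px; photon_noise_sd in
    intensity units; displacement_noise_sd adds Gaussian jitter (µm) to
    the truth sampled at each bead.
    """

    bead_density: float = 0.15
    spot_sigma: float = 0.8
    photon_noise_sd: float = 0.02
    displacement_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.bead_density, self.spot_sigma,
               self.photon_noise_sd, self.displacement_noise_sd) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class GroundTruthScene:
    """Synthetic bundle tying every pipeline stage to a known truth."""

    traction_truth: VectorField2D       # Pa, on the pixel grid
    displacement_truth: VectorField2D   # µm, forward solution of the truth
    masks: MaskSequence
    substrate: SubstrateSpec
    pixel_size: float                   # µm/px
    frame_interval: float = 10.0        # minutes
    rng_seed: int = 0
    bead_reference: np.ndarray | None = None
    bead_frames: np.ndarray | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)

    def export(self, outdir: str | Path) -> None:
        """Write the scene as TIFFs + CSV field dumps + a JSON manifest."""
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traction_truth.to_csv(outdir / "traction_truth.csv")
        self.displacement_truth.to_csv(outdir / "displacement_truth.csv")
        tifffile.imwrite(outdir / "masks.tif",
                         self.masks.masks.astype(np.uint8))
        if self.bead_reference is not None:
            tifffile.imwrite(outdir / "beads_reference.tif",
                             self.bead_reference.astype(np.float32))
        if self.bead_frames is not None:
            tifffile.imwrite(outdir / "beads.tif",
                             self.bead_frames.astype(np.float32))
        manifest = {
            "rng_seed": self.rng_seed,
            "pixel_size_um": self.pixel_size,
            "frame_interval_min": self.frame_interval,
            "substrate": {"youngs_modulus_Pa": self.substrate.youngs_modulus,
                          "poisson": self.substrate.poisson,
                          "thickness_um": self.substrate.thickness},
            "noise": {"bead_density_per_um2": self.noise.bead_density,
                      "spot_sigma_px": self.noise.spot_sigma,
                      "photon_noise_sd": self.noise.photon_noise_sd,
                      "displacement_noise_sd_um": self.noise.displacement_noise_sd},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def forward_displacement(traction: VectorField2D, substrate: SubstrateSpec,
                         pad: int = 2) -> VectorField2D:
    """Forward elastic solution; see :func:`monomech.elastic.forward_displacement`."""
    return elastic.forward_displacement(traction, substrate, pad=pad)


def _strip_mask(shape: tuple[int, int], half_width_px: float,
                half_length_px: float) -> np.ndarray:
    ny, nx = shape
    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    return (np.abs(x)[None, :] <= half_width_px) & \
           (np.abs(y)[:, None] <= half_length_px)


def make_contractile_strip_scene(strip_width: float = 300.0,
                                 peak_traction: float = 100.0,
                                 profile: str = "edge-localised",
                                 substrate: SubstrateSpec | None = None,
                                 seed: int = 0,
                                 shape: tuple[int, int] = DEFAULT_SHAPE,
                                 pixel_size: float = 2.0,
                                 edge_band_um: float = 60.0,
                                 strip_length: float | None = None,
                                 noise: NoiseModel | None = None,
                                 n_frames: int = 2,
                                 render_beads: bool = True) -> GroundTruthScene:
    """Build a contractile-strip scene with exact force balance.

    The monolayer occupies a vertical strip of width ``strip_width`` (µm)
    centred in the field; tractions point inward along x (toward the strip
    midline), antisymmetric about it, and vanish outside the mask, so the
    net in-plane force is exactly zero.  The strip is capped in y at
    ``strip_length`` (default 80% of the field height) with a smooth
    taper, keeping the traction compactly supported inside the field —
    the laboratory strip is far longer than any imaging window, and the
    taper stands in for the content beyond it.

    profile "edge-localised" confines the pull to bands of width
    ``edge_band_um`` at the two strip edges (a smooth raised-cosine bump);
    "uniform-inward" applies a constant magnitude across each half-strip.
    """
    substrate = substrate or SubstrateSpec()
    noise = noise or NoiseModel()
    ny, nx = shape
    if strip_width >= nx * pixel_size:
        raise ValueError("strip wider than the field of view")
    if strip_length is None:
        strip_length = 0.8 * ny * pixel_size
    if strip_length > ny * pixel_size:
        raise ValueError("strip longer than the field of view")
    if peak_traction <= 0:
        raise ValueError("peak_traction must be positive")

    half_w = strip_width / 2.0
    half_l = strip_length / 2.0
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size   # µm from midline
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size
    inward = -np.sign(x)                                # pull toward midline
    dist_from_edge = half_w - np.abs(x)                 # >=0 inside strip
    inside = dist_from_edge >= 0
    if profile == "uniform-inward":
        mag = np.where(inside, peak_traction, 0.0)
    elif profile == "edge-localised":
        t = np.clip(dist_from_edge / edge_band_um, 0.0, 1.0)
        bump = 0.5 * (1.0 + np.cos(np.pi * t))          # 1 at edge -> 0 inside
        mag = np.where(inside, peak_traction * bump, 0.0)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    # smooth cap in y so the traction is compact inside the field
    taper_um = min(20.0, 0.1 * strip_length)
    ydist = half_l - np.abs(y)
    ty = np.clip(ydist / taper_um, 0.0, 1.0)
    ywin = np.where(ydist >= 0, 0.5 * (1.0 - np.cos(np.pi * ty)), 0.0)
    Tx = (mag * inward)[None, :] * ywin[:, None]
    Ty = np.zeros_like(Tx)
    traction = VectorField2D(Tx, Ty, spacing=pixel_size, units="Pa")
    displacement = forward_displacement(traction, substrate, pad=2)

    mask = _strip_mask((ny, nx), half_w / pixel_size, half_l / pixel_size)
    frame_interval = 10.0
    times = np.arange(n_frames) * frame_interval / 60.0
    masks = MaskSequence(np.broadcast_to(mask, (n_frames, ny, nx)).copy(), times)

    scene = GroundTruthScene(traction, displacement, masks, substrate,
                             pixel_size=pixel_size,
                             frame_interval=frame_interval,
                             rng_seed=seed, noise=noise)
    if render_beads:
        ref, frames = render_bead_images(scene, noise, n_frames=n_frames)
        scene.bead_reference = ref
        scene.bead_frames = frames
    return scene


def _render_spots(shape: tuple[int, int], xs: np.ndarray, ys: np.ndarray,
                  amps: np.ndarray, sigma: float) -> np.ndarray:
    """Pixel-integrated Gaussian spots at continuous (subpixel) centres."""
    ny, nx = shape
    img = np.zeros((ny, nx))
    r = max(2, int(np.ceil(4 * sigma)))
    s = sigma * np.sqrt(2.0)
    for xc, yc, a in zip(xs, ys, amps):
        x0, y0 = int(np.floor(xc)), int(np.floor(yc))
        xi = np.arange(max(0, x0 - r), min(nx, x0 + r + 1))
        yi = np.arange(max(0, y0 - r), min(ny, y0 + r + 1))
        if len(xi) == 0 or len(yi) == 0:
            continue
        fx = 0.5 * (erf((xi + 0.5 - xc) / s) - erf((xi - 0.5 - xc) / s))
        fy = 0.5 * (erf((yi + 0.5 - yc) / s) - erf((yi - 0.5 - yc) / s))
        img[np.ix_(yi, xi)] += a * np.outer(fy, fx)
    return img


def render_bead_images(scene: GroundTruthScene, noise: NoiseModel | None = None,
                       n_frames: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Render the reference bead image and deformed frames.

    Beads are laid down uniformly at random (seeded), imaged as pixel-
    integrated Gaussian spots; each deformed frame shows the same beads
    displaced by the displacement truth interpolated at the bead
    positions, plus Gaussian photon noise.
    """
    import warnings

    noise = noise or scene.noise
    ny, nx = scene.displacement_truth.shape
    px = scene.pixel_size
    rng = np.random.default_rng(scene.rng_seed)

    area_um2 = ny * nx * px * px
    n_beads = rng.poisson(noise.bead_density * area_um2)
    beads_per_window = noise.bead_density * (32 * px) ** 2
    if beads_per_window < 5:
        warnings.warn(f"bead density gives {beads_per_window:.1f} beads per "
                      "32 px window (< 5); PIV may be unreliable")
    bx = rng.uniform(0, nx, size=n_beads)   # px coordinates
    by = rng.uniform(0, ny, size=n_beads)
    amps = rng.uniform(0.5, 1.0, size=n_beads)

    ref = _render_spots((ny, nx), bx, by, amps, noise.spot_sigma)

    interp_u = RegularGridInterpolator(
        (np.arange(ny), np.arange(nx)), scene.displacement_truth.u,
        bounds_error=False, fill_value=0.0)
    interp_v = RegularGridInterpolator(
        (np.arange(ny), np.arange(nx)), scene.displacement_truth.v,
        bounds_error=False, fill_value=0.0)
    pts = np.column_stack([by, bx])
    du = interp_u(pts) / px                 # µm -> px
    dv = interp_v(pts) / px

    frames = np.empty((n_frames, ny, nx))
    for t in range(n_frames):
        jx = jy = 0.0
        if noise.displacement_noise_sd > 0:
            jx = rng.normal(0, noise.displacement_noise_sd / px, size=n_beads)
            jy = rng.normal(0, noise.displacement_noise_sd / px, size=n_beads)
        img = _render_spots((ny, nx), bx + du + jx, by + dv + jy,
                            amps, noise.spot_sigma)
        if noise.photon_noise_sd > 0:
            img = img + rng.normal(0, noise.photon_noise_sd, size=img.shape)
        frames[t] = img
    if noise.photon_noise_sd > 0:
        ref = ref + rng.normal(0, noise.photon_noise_sd, size=ref.shape)
    return ref, frames


def make_expanding_mask_sequence(initial_width: float = 300.0,
                                 n_frames: int = 91,
                                 growth: float = 2.7,
                                 seed: int = 0,
                                 shape: tuple[int, int] = (128, 512),
                                 pixel_size: float = 2.0,
                                 frame_interval: float = 10.0,
                                 roughness: float = 0.0) -> MaskSequence:
    """Monotonically widening rectangular strip masks along ±x.

    The strip widens so that the final/initial pixel-area ratio equals
    ``growth`` (within rounding); ``roughness`` adds seeded per-row edge
    jitter in px without breaking monotonicity.
    """
    if growth < 1:
        raise ValueError("growth must be >= 1")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    half0 = initial_width / 2.0 / pixel_size
    if half0 < 1:
        raise ValueError("initial strip narrower than 2 px")
    if half0 * growth > (nx - 1) / 2.0:
        raise ValueError("final mask would exceed the frame")

    cx = (nx - 1) / 2.0
    x = np.arange(nx) - cx
    rough_l = rng.uniform(0, roughness, size=ny) if roughness > 0 else np.zeros(ny)
    rough_r = rng.uniform(0, roughness, size=ny) if roughness > 0 else np.zeros(ny)

    masks = np.zeros((n_frames, ny, nx), dtype=bool)
    for t in range(n_frames):
        frac = t / max(1, n_frames - 1)
        half = half0 * (1.0 + (growth - 1.0) * frac)
        for row in range(ny):
            lo = -half - rough_l[row]
            hi = half + rough_r[row]
            masks[t, row] = (x >= lo) & (x <= hi)
    times = np.arange(n_frames) * frame_interval / 60.0
    return MaskSequence(masks, times)
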