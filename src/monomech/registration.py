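"""Image I/O, reference registration, and tile stitching.

Timelapse frames are aligned to the cell-free reference bead image by
integer rigid translation (the stage is fixed; subpixel motion is left to
PIV), then everything is cropped to the common overlap.  Tiled
acquisitions along x are merged by correlating the nominal overlap band.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.fft import fft2, ifft2

from .fields import ImageStack, ReferenceImage


def read_stack(path: str | Path, channel: str = "phase",
               pixel_size: float | None = None,
               frame_interval: float | None = None) -> ImageStack:
    """Read a (multi-page) TIFF stack; calibration from args or JSON sidecar.

    The sidecar ``<stem>.json`` may provide ``pixel_size_um`` and
    ``frame_interval_min``; explicit arguments win.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    dt = (frame_interval if frame_interval is not None
          else meta.get("frame_interval_min"))
    if px is None or dt is None:
        raise ValueError(
            f"pixel size / frame interval missing for {path.name}: supply "
            "them explicitly or in a JSON sidecar")
    return ImageStack(frames.astype(float), pixel_size=float(px),
                      frame_interval=float(dt), channel=channel)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    path.with_suffix(".json").write_text(json.dumps(
        {"pixel_size_um": stack.pixel_size,
         "frame_interval_min": stack.frame_interval,
         "channel": stack.channel}))


@dataclass
class RegistrationResult:
    stack: ImageStack
    reference: ReferenceImage
    offsets: np.ndarray          # (nt, 2) integer (dy, dx) per frame
    confidence: np.ndarray       # correlation peak per frame, in [0, 1]
    flagged: np.ndarray          # frames whose peak fell below threshold

    def offsets_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.offsets)),
                             "dy": self.offsets[:, 0],
                             "dx": self.offsets[:, 1],
                             "confidence": self.confidence,
                             "flagged": self.flagged})


def _ncc_shift(reference: np.ndarray, frame: np.ndarray
               ) -> tuple[int, int, float]:
    """Integer shift of frame vs reference maximising the (global,
    circular) normalized cross-correlation; returns (dy, dx, peak)."""
    a = reference - reference.mean()
    b = frame - frame.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0, 0, 0.0
    c = ifft2(fft2(b) * np.conj(fft2(a))).real / denom
    iy, ix = np.unravel_index(np.argmax(c), c.shape)
    ny, nx = c.shape
    dy = iy - ny if iy > ny // 2 else iy
    dx = ix - nx if ix > nx // 2 else ix
    return int(dy), int(dx), float(c[iy, ix])


def register_to_reference(stack: ImageStack, reference: ReferenceImage,
                          confidence_threshold: float = 0.1
                          ) -> RegistrationResult:
    """Align every frame to the reference by integer translation, then crop
    all frames and the reference to the common overlap.

    The per-frame offset (dy, dx) is the displacement of the frame content
    relative to the reference; a frame whose correlation peak falls below
    ``confidence_threshold`` keeps a zero offset and is flagged.
    """
    if stack.pixel_size != reference.pixel_size:
        raise ValueError("stack and reference pixel sizes differ")
    if min(stack.frame_shape) < 64 or min(reference.image.shape) < 64:
        raise ValueError("frames must be at least 64 x 64 px")
    if stack.frame_shape != reference.image.shape:
        raise ValueError("frames and reference must share one shape")

    nt = len(stack)
    offsets = np.zeros((nt, 2), dtype=int)
    conf = np.zeros(nt)
    flagged = np.zeros(nt, dtype=bool)
    for t, frame in enumerate(stack.frames):
        dy, dx, peak = _ncc_shift(reference.image, frame)
        conf[t] = peak
        if peak < confidence_threshold:
            flagged[t] = True
            warnings.warn(f"frame {t}: correlation peak {peak:.3f} below "
                          f"threshold {confidence_threshold}; left unshifted")
            continue
        offsets[t] = (dy, dx)

    H, W = stack.frame_shape
    # aligned frame t occupies reference rows [-dy, H-dy); intersect all
    y0 = int(max(0, -offsets[:, 0].min()))
    y1 = int(min(H, H - offsets[:, 0].max()))
    x0 = int(max(0, -offsets[:, 1].min()))
    x1 = int(min(W, W - offsets[:, 1].max()))
    if y1 <= y0 or x1 <= x0:
        raise ValueError("no common overlap after registration")

    aligned = np.empty((nt, y1 - y0, x1 - x0))
    for t, frame in enumerate(stack.frames):
        dy, dx = offsets[t]
        aligned[t] = frame[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
    ref_crop = reference.image[y0:y1, x0:x1]
    new_stack = ImageStack(aligned, pixel_size=stack.pixel_size,
                           frame_interval=stack.frame_interval,
                           channel=stack.channel)
    return RegistrationResult(new_stack,
                              ReferenceImage(ref_crop, reference.pixel_size),
                              offsets, conf, flagged)


def _best_overlap(left: np.ndarray, right: np.ndarray, nominal: int
                  ) -> tuple[int, float]:
    """Overlap width (columns) maximising the NCC between the right band
    of `left` and the left band of `right`; searched around nominal."""
    lo = max(2, nominal // 2)
    hi = min(left.shape[1], right.shape[1], 2 * nominal)
    best, best_c = nominal, -np.inf
    for o in range(lo, hi + 1):
        a = left[:, -o:] - left[:, -o:].mean()
        b = right[:, :o] - right[:, :o].mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        if denom == 0:
            continue
        c = float(np.sum(a * b) / denom)
        if c > best_c:
            best, best_c = o, c
    return best, best_c


def stitch_tiles(tiles: list[ImageStack], overlap_fraction: float = 0.10,
                 min_correlation: float = 0.5) -> ImageStack:
    """Merge tiles ordered along x into one stack, blending the seams.

    The true overlap of each neighbouring pair is found by correlating the
    nominal overlap band (measured on the first frame and reused for all
    timepoints so the merged geometry is constant in time); intensities are
    blended with a linear ramp across the seam.  A pair whose correlation
    peak stays below ``min_correlation`` falls back to the nominal overlap
    with a warning.
    """
    if not tiles:
        raise ValueError("no tiles given")
    if len(tiles) == 1:
        return tiles[0]
    if not 0.0 < overlap_fraction < 0.5:
        raise ValueError("overlap_fraction must lie in (0, 0.5)")
    shapes = {t.frames.shape for t in tiles}
    if len(shapes) != 1:
        raise ValueError("tiles must share frame count and shape")
    nt, H, W = tiles[0].frames.shape

    nominal = int(round(overlap_fraction * W))
    overlaps = []
    for a, b in zip(tiles[:-1], tiles[1:]):
        o, c = _best_overlap(a.frames[0], b.frames[0], nominal)
        if c < min_correlation:
            warnings.warn(f"overlap correlation {c:.2f} below "
                          f"{min_correlation}; using nominal overlap")
            o = nominal
        overlaps.append(o)

    width = W + sum(W - o for o in overlaps)
    out = np.zeros((nt, H, width))
    wsum = np.zeros((nt, H, width))
    x0 = 0
    for i, tile in enumerate(tiles):
        w = np.ones(W)
        if i > 0:
            w[:overlaps[i - 1]] = np.linspace(0, 1, overlaps[i - 1] + 2)[1:-1]
        if i < len(tiles) - 1:
            w[-overlaps[i]:] = np.linspace(1, 0, overlaps[i] + 2)[1:-1]
        out[:, :, x0:x0 + W] += tile.frames * w
        wsum[:, :, x0:x0 + W] += w
        if i < len(tiles) - 1:
            x0 += W - overlaps[i]
    merged = out / np.where(wsum == 0, 1.0, wsum)
    return ImageStack(merged, pixel_size=tiles[0].pixel_size,
                      frame_interval=tiles[0].frame_interval,
                      channel=tiles[0].channel)
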