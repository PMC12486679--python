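"""Post-processing geometry: temporal summaries, zonal splits, kymographs.

All routines take scalar quantity fields co-registered with the binary
collective masks; the migration axis is x, so "edge" always means the
±x margins of the strip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .fields import MaskSequence

logger = logging.getLogger(__name__)

_STRUCT_X = np.array([[1, 1, 1]], dtype=bool)     # 1x3: erode along ±x only
_STRUCT_ISO = ndimage.generate_binary_structure(2, 1)


def temporal_summary(fields_by_position: dict[str, list[np.ndarray]],
                     masks_by_position: dict[str, MaskSequence]
                     ) -> pd.DataFrame:
    """Median-inside-mask per position, then mean ± SEM across positions.

    Returns a tidy frame (t_hours, mean, sem, n).  A position whose mask
    is empty at some timepoint is excluded there (and logged).  SEM is 0
    for a single position.
    """
    if set(fields_by_position) != set(masks_by_position):
        raise ValueError("positions of fields and masks must match")
    per_t: dict[float, list[float]] = {}
    for pos, fields in fields_by_position.items():
        seq = masks_by_position[pos]
        if len(fields) != len(seq):
            raise ValueError(f"position {pos}: fields/masks length mismatch")
        for i, f in enumerate(fields):
            m = seq.masks[i]
            sel = m & np.isfinite(f)
            if not sel.any():
                logger.info("position %s excluded at t=%.2f h (empty mask)",
                            pos, seq.times[i])
                continue
            per_t.setdefault(float(seq.times[i]), []).append(
                float(np.median(f[sel])))
    rows = []
    for t in sorted(per_t):
        vals = np.array(per_t[t])
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"t_hours": t, "mean": float(vals.mean()),
                     "sem": sem, "n": n})
    return pd.DataFrame(rows)


def zonal_split(mask: np.ndarray, direction: str = "x") -> np.ndarray:
    """Centre/edge partition by iterative 1-px erosion along the migration axis.

    Erodes the mask by one pixel from each ±x margin per iteration (or
    isotropically with ``direction="iso"`` for confined geometries) until
    the remaining central zone holds fewer than half of the original
    pixels.  Returns an int8 label map: 0 outside, 1 centre, 2 edge.
    """
    mask = np.asarray(mask, bool)
    total = int(mask.sum())
    if total == 0:
        raise ValueError("empty mask")
    widths = mask.any(axis=0).sum()
    if widths < 2:
        raise ValueError("mask thinner than 2 px along x")
    struct = _STRUCT_X if direction == "x" else _STRUCT_ISO
    centre = mask.copy()
    while centre.sum() >= total / 2.0:
        nxt = ndimage.binary_erosion(centre, structure=struct)
        if not nxt.any():
            break
        centre = nxt
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask] = 2
    labels[centre] = 1
    return labels


def centre_fraction(mask: np.ndarray, direction: str = "x") -> float:
    """Fraction of mask pixels assigned to the central zone."""
    labels = zonal_split(mask, direction)
    return float((labels == 1).sum() / (labels > 0).sum())


@dataclass
class Kymograph:
    """Space × time matrix of a quantity vs distance from the strip edge.

    matrix[t, d] is the median of the quantity over the 1-px-wide vertical
    line at distance d (px) from the current mask edge at timepoint t;
    NaN where the line has no in-mask pixels.  ``side`` is "left", "right"
    or "averaged".
    """

    matrix: np.ndarray
    quantity: str
    side: str

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix).to_csv(path, index_label="t_index")


def _rank_from_edges(mask_row_or_col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row rank of in-mask pixels from the left and right edges."""
    n = len(mask_row_or_col)
    idx = np.flatnonzero(mask_row_or_col)
    left = np.full(n, -1)
    right = np.full(n, -1)
    left[idx] = np.arange(len(idx))
    right[idx] = np.arange(len(idx))[::-1]
    return left, right


def kymograph(fields: list[np.ndarray], masks: MaskSequence,
              quantity: str = "value", side: str = "averaged",
              max_depth: int | None = None) -> Kymograph:
    """Edge-anchored kymograph of a scalar quantity.

    For each timepoint, vertical 1-px lines are peeled from the mask edge
    toward the centre along the migration axis; the cell value is the
    median over the in-mask pixels of that line.  Distance d is kept in
    absolute px from the current edge.
    """
    if side not in ("left", "right", "averaged"):
        raise ValueError("side must be left, right or averaged")
    if len(fields) != len(masks):
        raise ValueError("one field per mask required")
    nt = len(fields)
    half_width = int(np.ceil(masks.masks.any(axis=1).sum(axis=1).max() / 2))
    depth = half_width if max_depth is None else min(max_depth, half_width)

    out = {s: np.full((nt, depth), np.nan) for s in ("left", "right")}
    for t in range(nt):
        f, m = fields[t], masks.masks[t]
        if f.shape != m.shape:
            raise ValueError("field and mask shapes differ")
        ny, nx = m.shape
        lrank = np.full((ny, nx), -1)
        rrank = np.full((ny, nx), -1)
        for row in range(ny):
            lrank[row], rrank[row] = _rank_from_edges(m[row])
        # a pixel belongs to the side whose edge is nearer (ties to both),
        # so each side's lines run from its edge to the strip centre
        left_side = (lrank >= 0) & (lrank <= rrank)
        right_side = (rrank >= 0) & (rrank <= lrank)
        for d in range(depth):
            for name, rank, sidemask in (("left", lrank, left_side),
                                         ("right", rrank, right_side)):
                sel = (rank == d) & sidemask & np.isfinite(f)
                if sel.any():
                    out[name][t, d] = np.median(f[sel])
    if side == "averaged":
        with np.errstate(all="ignore"):
            mat = np.nanmean(np.stack([out["left"], out["right"]]), axis=0)
    else:
        mat = out[side]
    return Kymograph(matrix=mat, quantity=quantity, side=side)


def zonal_summary(fields_by_position: dict[str, list[np.ndarray]],
                  masks_by_position: dict[str, MaskSequence],
                  split_time: float = 4.0,
                  direction: str = "x") -> pd.DataFrame:
    """Per-position, per-zone, per-window mean of per-timepoint medians.

    Zones: centre, edge (from :func:`zonal_split`, recomputed each frame)
    and whole; windows: early (t < split_time) and late (t >= split_time).
    Returns tidy rows (position, zone, window, mean, sem, n) where n is
    the timepoint count entering the mean.
    """
    rows = []
    for pos, fields in fields_by_position.items():
        seq = masks_by_position[pos]
        vals: dict[tuple[str, str], list[float]] = {}
        for i, f in enumerate(fields):
            m = seq.masks[i]
            labels = zonal_split(m, direction)
            window = "early" if seq.times[i] < split_time else "late"
            for zone, sel in (("centre", labels == 1),
                              ("edge", labels == 2),
                              ("whole", labels > 0)):
                sel = sel & np.isfinite(f)
                if sel.any():
                    vals.setdefault((zone, window), []).append(
                        float(np.median(f[sel])))
        for (zone, window), v in sorted(vals.items()):
            arr = np.array(v)
            sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
            rows.append({"position": pos, "zone": zone, "window": window,
                         "mean": float(arr.mean()), "sem": sem, "n": len(arr)})
    return pd.DataFrame(rows)


def correlation_trajectory(series_a: np.ndarray, series_b: np.ndarray
                           ) -> np.ndarray:
    """Ordered (a(t), b(t)) pairs for correlation-in-time plots."""
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape:
        raise ValueError("series must share a time grid")
    return np.column_stack([a, b])
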