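"""End-to-end orchestration: register → PIV → TFM → MSM → metrics → post.

Every intermediate field is written to the output directory, together
with a manifest recording versions, parameters and solver residuals, so
a run is reproducible from its config alone.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig, validate_config
from .energetics import energy_series, local_efficiency
from .fields import ImageStack, MaskSequence, ReferenceImage, VectorField2D
from .kinematics import collective_spreading, directionality_histogram
from .piv import displacement_from_beads, velocity_from_phase
from .registration import read_stack, register_to_reference
from .spatiotemporal import kymograph, temporal_summary, zonal_summary
from .stress import (average_normal_stress, maximum_shear_stress,
                     principal_stresses, recover_stress_full,
                     stress_anisotropy)
from .traction import fttc_invert, traction_magnitude


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure; partial outputs are kept on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _mask_on_grid(mask: np.ndarray, field: VectorField2D,
                  pixel_size: float) -> np.ndarray:
    """Sample a pixel-resolution mask at the field's grid nodes."""
    iy = np.clip(np.round(field.grid_y / pixel_size).astype(int),
                 0, mask.shape[0] - 1)
    ix = np.clip(np.round(field.grid_x / pixel_size).astype(int),
                 0, mask.shape[1] - 1)
    return mask[np.ix_(iy, ix)]


def run_pipeline(config: RunConfig, base_dir: str | Path = ".") -> Path:
    """Execute the full analysis described by ``config``.

    Returns the output directory.  Any stage failure raises
    :class:`PipelineError` tagged with the stage name; outputs written
    before the failure are retained for inspection.
    """
    base = Path(base_dir)
    issues = validate_config(config, base_dir=base)
    if issues:
        raise PipelineError("validate", ValueError("; ".join(issues)))

    out = base / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(),
                      "stages": {}}

    def _stage(name):
        def deco(fn):
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:
                _write_manifest()
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = "ok"
            return result
        return deco

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))

    # --- load inputs -----------------------------------------------------
    @_stage("load")
    def _loaded():
        beads = read_stack(base / config.beads, channel="beads",
                           pixel_size=config.pixel_size,
                           frame_interval=config.frame_interval)
        ref_img = tifffile.imread(base / config.reference)
        reference = ReferenceImage(np.asarray(ref_img, float),
                                   pixel_size=config.pixel_size)
        mask_arr = tifffile.imread(base / config.masks).astype(bool)
        if mask_arr.ndim == 2:
            mask_arr = mask_arr[None]
        times = np.arange(len(beads)) * config.frame_interval / 60.0
        masks = MaskSequence(mask_arr[:len(beads)], times[:mask_arr.shape[0]])
        phase = None
        if config.phase is not None:
            phase = read_stack(base / config.phase, channel="phase",
                               pixel_size=config.pixel_size,
                               frame_interval=config.frame_interval)
        return beads, reference, masks, phase

    beads, reference, masks, phase = _loaded

    # --- registration ----------------------------------------------------
    @_stage("register")
    def _registered():
        reg = register_to_reference(beads, reference)
        reg.offsets_frame().to_csv(out / "offsets.csv", index=False)
        return reg

    reg = _registered

    # --- PIV -------------------------------------------------------------
    @_stage("piv")
    def _displacements():
        disp = displacement_from_beads(reg.stack, reg.reference,
                                       config.piv_beads)
        for t, f in enumerate(disp):
            f.to_csv(out / f"displacement_t{t:03d}.csv")
        return disp

    displacements = _displacements

    velocities = None
    if phase is not None:
        @_stage("piv-phase")
        def _velocities():
            vel = velocity_from_phase(phase, config.piv_phase)
            for t, f in enumerate(vel):
                f.to_csv(out / f"velocity_t{t:03d}.csv")
            return vel
        velocities = _velocities

    # --- TFM -------------------------------------------------------------
    @_stage("tfm")
    def _tractions():
        tr = [fttc_invert(d, config.substrate, config.regularization)
              for d in displacements]
        for t, f in enumerate(tr):
            f.to_csv(out / f"traction_t{t:03d}.csv")
        return tr

    tractions = _tractions
    grid_masks = MaskSequence(
        np.stack([_mask_on_grid(masks.masks[min(t, len(masks) - 1)],
                                tractions[t], config.pixel_size)
                  for t in range(len(tractions))]),
        masks.times[:len(tractions)])

    # --- MSM -------------------------------------------------------------
    @_stage("msm")
    def _stress():
        rows = []
        per_t = []
        for t, T in enumerate(tractions):
            res = recover_stress_full(T, grid_masks.masks[t], config.monolayer)
            p = principal_stresses(res.stress)
            ans = average_normal_stress(p)
            mss = maximum_shear_stress(p, mode=config.mss_mode)
            ecc = stress_anisotropy(p, mode=config.ecc_mode)
            per_t.append((res, p, ans, mss, ecc))
            m = res.stress.mask
            rows.append({
                "t_hours": grid_masks.times[t],
                "residual": res.residual,
                "ans_median_Pa": float(np.median(ans[m])),
                "mss_median_Pa": float(np.median(mss[m])),
                "ecc_median": float(np.nanmedian(ecc[m])),
            })
        pd.DataFrame(rows).to_csv(out / "stress_summary.csv", index=False)
        return per_t

    stress_per_t = _stress

    # --- energetics ------------------------------------------------------
    @_stage("efficiency")
    def _energy():
        recs = energy_series(tractions, displacements, grid_masks,
                             grid_masks.times)
        df = pd.DataFrame([{"t_hours": r.t, "U_J": r.U,
                            "Ustar_J": r.U_star, "eta": r.eta}
                           for r in recs])
        df.to_csv(out / "energy.csv", index=False)
        cos0 = local_efficiency(tractions[0], displacements[0],
                                grid_masks.masks[0])
        tifffile.imwrite(out / "cos_theta_t000.tif", cos0.astype(np.float32))
        return recs

    records = _energy

    # --- post-processing -------------------------------------------------
    @_stage("postprocess")
    def _post():
        spreading = collective_spreading(masks)
        pd.DataFrame({"t_hours": masks.times,
                      "norm_area": spreading}).to_csv(
            out / "spreading.csv", index=False)

        tmag = [traction_magnitude(T) for T in tractions]
        summary = temporal_summary({"pos0": tmag}, {"pos0": grid_masks})
        summary.to_csv(out / "traction_magnitude_in_time.csv", index=False)

        kymo = kymograph(tmag, grid_masks, quantity="traction_magnitude",
                         side=config.kymo_side)
        kymo.to_csv(out / "kymograph_traction.csv")
        tifffile.imwrite(out / "kymograph_traction.tif",
                         kymo.matrix.astype(np.float32))

        zonal = zonal_summary({"pos0": tmag}, {"pos0": grid_masks},
                              split_time=config.split_time,
                              direction=config.erosion_direction)
        zonal.to_csv(out / "zonal_traction.csv", index=False)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            edges, frac, _ = directionality_histogram(
                tractions[0], grid_masks.masks[0], fold=True)
        pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                      "fraction": frac}).to_csv(
            out / "traction_directionality.csv", index=False)

        if velocities is not None:
            smag = [np.hypot(v.u, v.v) for v in velocities]
            vel_masks = MaskSequence(
                np.stack([_mask_on_grid(masks.masks[t], velocities[t],
                                        config.pixel_size)
                          for t in range(len(velocities))]),
                masks.times[:len(velocities)])
            temporal_summary({"pos0": smag}, {"pos0": vel_masks}).to_csv(
                out / "speed_in_time.csv", index=False)

    _post
    manifest["eta_range"] = [float(min(r.eta for r in records)),
                             float(max(r.eta for r in records))]
    manifest["max_equilibrium_residual"] = float(
        max(r[0].residual for r in stress_per_t))
    _write_manifest()
    return out
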