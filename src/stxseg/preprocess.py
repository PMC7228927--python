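"""Study preprocessing: drift correction, B0 correction, T1/T2 mapping,
normalization, and mask erosion.

The output of :func:`preprocess_study` is a :class:`PreprocessedStudy`
whose ``feature_images`` hold the normalized inputs of the segmentation
stage: ``t1_norm`` and ``t2_norm`` (observed T1 and T2 divided by 4000 and
300 ms so they share the 0-1 range of the Z values) and one image per
(B1, offset) saturation measurement, each expressed as Z = S/S0 with S0
the per-voxel drift-corrected reference signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .core_data import RelaxationMaps, StudyDataset, ppm_to_angular, b1_to_omega1

__all__ = [
    "PreprocessedStudy",
    "T1_NORM_MS",
    "T2_NORM_MS",
    "feature_name",
    "drift_correct",
    "fit_wassr_b0",
    "b0_correct_low_b1",
    "fit_t1_map",
    "steady_state_de_signal",
    "fit_t2_from_wassr",
    "normalize_relaxation_maps",
    "erode_mask",
    "reference_s0_map",
    "preprocess_study",
]

#: Normalization constants for the relaxation maps (ms).
T1_NORM_MS = 4000.0
T2_NORM_MS = 300.0


def feature_name(b1_uT: float, offset_ppm: float) -> str:
    """Canonical feature-image name for one saturation measurement."""
    return f"z_{b1_uT:g}uT_{offset_ppm:+.3f}ppm"


@dataclass
class PreprocessedStudy:
    """Drift/B0-corrected, normalized feature images plus maps and masks."""

    subject_id: str
    feature_images: dict  # name -> 2D array
    relaxation: RelaxationMaps
    b0_map_ppm: np.ndarray
    eroded_mask: np.ndarray
    schedule: object = None
    qc: dict = field(default_factory=dict)

    def feature_matrix(self, names: list[str]) -> np.ndarray:
        """Stack named features into an (n_voxels, n_features) array over the
        eroded mask, in mask raster order."""
        missing = [n for n in names if n not in self.feature_images]
        if missing:
            raise KeyError(f"missing feature image(s): {missing}")
        m = self.eroded_mask
        return np.column_stack([self.feature_images[n][m] for n in names])


# ---------------------------------------------------------------------------
# drift


def drift_correct(dataset: StudyDataset) -> StudyDataset:
    """Remove linear signal drift using the interleaved reference scans.

    A straight line is fit (least squares) to the mean in-mask reference
    intensity versus acquisition order; every frame is divided by the line
    normalized to its value at order 0.  Both Z-spectrum and reference
    frames are corrected; references are retained for audit.
    """
    refs = dataset.reference_series
    if len(refs) < 2:
        raise ValueError("drift correction requires at least 2 reference frames")
    mask = dataset.tissue_mask
    orders = np.array([r.acq_order for r in refs], dtype=float)
    means = np.array([r.image.pixels[mask].mean() for r in refs])
    slope, intercept = np.polyfit(orders, means, 1)
    line0 = intercept  # value at order 0
    if line0 <= 0:
        raise ValueError("fitted reference line is non-positive at order 0")

    def factor(order):
        val = (intercept + slope * order) / line0
        if val <= 0:
            raise ValueError("fitted reference line non-positive within series")
        return val

    out = dataset.copy()
    for fr in out.zspec_series:
        fr.image.pixels = fr.image.pixels / factor(fr.acq_order)
    for fr in out.reference_series:
        fr.image.pixels = fr.image.pixels / factor(fr.acq_order)
    return out


def reference_s0_map(dataset: StudyDataset) -> np.ndarray:
    """Per-voxel unsaturated signal: mean over all reference frames."""
    stack = np.stack([r.image.pixels for r in dataset.reference_series])
    return stack.mean(axis=0)


# ---------------------------------------------------------------------------
# B0


def _lorentzian(offsets, amp, width, center):
    return amp * width**2 / (width**2 + (offsets - center) ** 2)


def _lorentzian_grad(offsets, amp, width, center):
    """Partial derivatives of the Lorentzian wrt (amp, width, center)."""
    x = offsets - center
    d = width**2 + x**2
    return (
        width**2 / d,
        2.0 * amp * width * x**2 / d**2,
        2.0 * amp * width**2 * x / d**2,
    )


def fit_wassr_b0(dataset: StudyDataset, s0_map: np.ndarray | None = None):
    """Per-voxel B0 map (ppm) from a single-Lorentzian fit to the WASSR dip.

    Fits Z(dw) = 1 - A*G^2/(G^2 + (dw - d0)^2) over the WASSR offsets and
    returns ``(b0_map_ppm, n_flagged)``; voxels whose fitted dip amplitude
    is negligible are flagged and assigned d0 = 0.
    """
    bi = dataset.schedule.wassr_block_index
    offsets = np.asarray(dataset.schedule.blocks[bi].offsets_ppm)
    zstack = dataset.zspec_array(bi)
    if s0_map is None:
        s0_map = reference_s0_map(dataset)
    mask = dataset.tissue_mask
    b0 = np.zeros(mask.shape)
    n_flagged = 0
    max_shift = float(np.abs(offsets).max())
    for iy, ix in zip(*np.nonzero(mask)):
        z = zstack[:, iy, ix] / s0_map[iy, ix]
        d0_init = float(offsets[np.argmin(z)])
        a_init = float(np.clip(1.0 - z.min(), 0.0, 2.0))

        def resid(theta):
            return 1.0 - _lorentzian(offsets, *theta) - z

        def jac(theta):
            da, dg, dc = _lorentzian_grad(offsets, *theta)
            return -np.column_stack([da, dg, dc])

        fit = least_squares(
            resid, [a_init, 0.3, np.clip(d0_init, -max_shift, max_shift)],
            jac=jac,
            bounds=([0.0, 0.01, -max_shift], [2.0, 5.0, max_shift]),
            xtol=1e-10, ftol=1e-10, max_nfev=200,
        )
        amp = fit.x[0]
        if amp < 1e-3:
            n_flagged += 1
            b0[iy, ix] = 0.0
        else:
            b0[iy, ix] = fit.x[2]
    return b0, n_flagged


_TWOLOR_LB = np.array([0.5, 0.0, 0.2, 0.0, 10.0, -1.0])
_TWOLOR_UB = np.array([1.5, 2.0, 5.0, 1.0, 200.0, 1.0])


def _two_lorentzian_center(offsets, z, d0_init, theta0=None):
    """DE centre from a two-Lorentzian (DE + MT) fit; raises on failure.

    Parameters are (baseline, A_de, width_de, A_mt, width_mt, shared
    centre).  ``theta0`` allows warm-starting from a neighbouring voxel's
    solution.  Returns ``(centre_ppm, theta)``.
    """
    def resid(theta):
        base, a_de, g_de, a_mt, g_mt, c = theta
        return (base - _lorentzian(offsets, a_de, g_de, c)
                - _lorentzian(offsets, a_mt, g_mt, c) - z)

    def jac(theta):
        base, a_de, g_de, a_mt, g_mt, c = theta
        da1, dg1, dc1 = _lorentzian_grad(offsets, a_de, g_de, c)
        da2, dg2, dc2 = _lorentzian_grad(offsets, a_mt, g_mt, c)
        ones = np.ones_like(offsets)
        return np.column_stack([ones, -da1, -dg1, -da2, -dg2, -(dc1 + dc2)])

    if theta0 is None:
        theta0 = [1.0, float(np.clip(1.0 - z.min(), 0.05, 1.5)), 1.0, 0.1, 50.0, d0_init]
    fit = least_squares(resid, theta0, jac=jac, bounds=(_TWOLOR_LB, _TWOLOR_UB),
                        xtol=1e-9, ftol=1e-9, max_nfev=100)
    if not fit.success or fit.x[1] < 1e-3:
        raise RuntimeError("two-Lorentzian fit failed")
    return float(fit.x[5]), fit.x


def b0_correct_low_b1(dataset: StudyDataset, b0_map_ppm: np.ndarray | None = None):
    """Recentre the low-B1 spectra on the direct-effect peak, per voxel.

    A sum of two Lorentzians (narrow DE + broad MT, shared centre) is fit
    to each voxel's normalized low-B1 spectrum; the spectrum is shifted by
    the DE centre and linearly interpolated back onto the original offset
    grid (edge values held).  High-B1 blocks are untouched — their offsets
    (3-300 ppm) make the shift negligible.  When the fit fails for a voxel
    the WASSR-derived shift from ``b0_map_ppm`` is used instead.

    Returns ``(corrected_dataset, n_fallback)``.
    """
    out = dataset.copy()
    s0_map = reference_s0_map(dataset)
    mask = dataset.tissue_mask
    n_fallback = 0
    for bi in dataset.schedule.blocks_with_role("low_b1"):
        offsets = np.asarray(dataset.schedule.blocks[bi].offsets_ppm)
        order = np.argsort(offsets)
        zstack = dataset.zspec_array(bi)
        frames = sorted((fr for fr in out.zspec_series if fr.block == bi),
                        key=lambda fr: fr.offset_index)
        corrected = zstack.copy()
        prev_theta = None
        for iy, ix in zip(*np.nonzero(mask)):
            s0 = s0_map[iy, ix]
            z = zstack[:, iy, ix] / s0
            d0_init = (float(b0_map_ppm[iy, ix]) if b0_map_ppm is not None
                       else float(offsets[np.argmin(z)]))
            theta0 = None
            if prev_theta is not None:
                theta0 = np.clip(prev_theta, _TWOLOR_LB + 1e-6, _TWOLOR_UB - 1e-6)
                theta0[5] = np.clip(d0_init, -1.0 + 1e-6, 1.0 - 1e-6)
            try:
                center, prev_theta = _two_lorentzian_center(
                    offsets[order], z[order], d0_init, theta0)
            except RuntimeError:
                n_fallback += 1
                prev_theta = None
                center = float(b0_map_ppm[iy, ix]) if b0_map_ppm is not None else 0.0
            # corrected(dw) = measured(dw + center); edge-hold via np.interp
            z_shift = np.interp(offsets[order] + center, offsets[order], z[order])
            corrected[order, iy, ix] = z_shift * s0
        for oi, fr in enumerate(frames):
            fr.image.pixels = corrected[oi]
    return out, n_fallback


# ---------------------------------------------------------------------------
# relaxometry


def fit_t1_map(ir_series, mask: np.ndarray):
    """Per-voxel T1 from the signed inversion-recovery series.

    Fits S(TI) = a + b*exp(-TI/T1); returns ``(RelaxationMaps(t1, s0=a),
    n_flagged)``.  Degenerate voxels (no recovery contrast, |b| ~ 0) are
    flagged and left at 0.
    """
    if len(ir_series) < 3:
        raise ValueError("T1 fit requires at least 3 inversion times")
    tis = np.array([ti for ti, _ in ir_series], dtype=float)
    stack = np.stack([img.pixels for _, img in ir_series])
    t1 = np.zeros(mask.shape)
    s0 = np.zeros(mask.shape)
    n_flagged = 0
    for iy, ix in zip(*np.nonzero(mask)):
        s = stack[:, iy, ix]
        a0 = s[-1]
        b0 = s[0] - a0
        if abs(b0) < 1e-9 * max(abs(a0), 1.0):
            n_flagged += 1
            continue
        # zero-crossing heuristic for the T1 start value
        sign_change = np.nonzero(np.diff(np.sign(s)))[0]
        t1_0 = tis[sign_change[0]] / np.log(2.0) if sign_change.size else 1000.0

        def resid(theta):
            a, b, tau = theta
            return a + b * np.exp(-tis / tau) - s

        def jac(theta):
            _a, b, tau = theta
            e = np.exp(-tis / tau)
            return np.column_stack([np.ones_like(tis), e, b * e * tis / tau**2])

        fit = least_squares(resid, [a0, b0, np.clip(t1_0, 10.0, 8000.0)], jac=jac,
                            bounds=([-np.inf, -np.inf, 1.0], [np.inf, np.inf, 20000.0]),
                            xtol=1e-10, ftol=1e-10, max_nfev=200)
        if not fit.success:
            n_flagged += 1
            continue
        t1[iy, ix] = fit.x[2]
        s0[iy, ix] = fit.x[0]
    return RelaxationMaps(t1_obs_ms=t1, s0=s0), n_flagged


def steady_state_de_signal(dw_rad_s, t1_s, t2_s, w1_rad_s, s0=1.0):
    """Steady-state direct water saturation signal.

    S = S0 * R1 (R2^2 + dw^2) / (R1 (R2^2 + dw^2) + w1^2 R2), with
    R1 = 1/T1, R2 = 1/T2 (times in seconds, frequencies rad/s).
    """
    t1_s = np.asarray(t1_s, dtype=float)
    t2_s = np.asarray(t2_s, dtype=float)
    if np.any(t1_s <= 0) or np.any(t2_s <= 0):
        raise ValueError("T1 and T2 must be > 0")
    r1 = 1.0 / t1_s
    r2 = 1.0 / t2_s
    dw = np.asarray(dw_rad_s, dtype=float)
    core = r1 * (r2**2 + dw**2)
    return s0 * core / (core + np.asarray(w1_rad_s, float) ** 2 * r2)


def fit_t2_from_wassr(dataset: StudyDataset, t1_obs_ms: np.ndarray,
                      b0_map_ppm: np.ndarray | None = None,
                      s0_map: np.ndarray | None = None):
    """Per-voxel T2 map (ms) from the WASSR dip with R1 fixed by the T1 map.

    Fits the steady-state direct-saturation model over the WASSR offsets
    (recentred by the B0 map when given) with free R2 and scale.  Returns
    ``(t2_ms_map, n_flagged)``; voxels with no dip are flagged.
    """
    bi = dataset.schedule.wassr_block_index
    blk = dataset.schedule.blocks[bi]
    if blk.b1_uT <= 0:
        raise ValueError("WASSR block has zero B1: no saturation information")
    offsets = np.asarray(blk.offsets_ppm)
    w1 = float(b1_to_omega1(blk.b1_uT))
    field = dataset.schedule.field_T
    zstack = dataset.zspec_array(bi)
    if s0_map is None:
        s0_map = reference_s0_map(dataset)
    mask = dataset.tissue_mask
    t2 = np.zeros(mask.shape)
    n_flagged = 0
    for iy, ix in zip(*np.nonzero(mask)):
        z = zstack[:, iy, ix] / s0_map[iy, ix]
        if z.min() > 1.0 - 1e-3:
            n_flagged += 1
            continue
        t1_s = t1_obs_ms[iy, ix] / 1000.0
        if t1_s <= 0:
            n_flagged += 1
            continue
        d0 = float(b0_map_ppm[iy, ix]) if b0_map_ppm is not None else 0.0
        dw = ppm_to_angular(offsets - d0, field)

        def resid(theta):
            t2_s, scale = theta
            return steady_state_de_signal(dw, t1_s, t2_s, w1, scale) - z

        def jac(theta):
            t2_s, scale = theta
            r1 = 1.0 / t1_s
            r2 = 1.0 / t2_s
            core = r1 * (r2**2 + dw**2)
            den = core + w1**2 * r2
            d_scale = core / den
            d_r2 = scale * w1**2 * r1 * (r2**2 - dw**2) / den**2
            return np.column_stack([d_r2 * (-1.0 / t2_s**2), d_scale])

        fit = least_squares(resid, [0.05, 1.0], jac=jac,
                            bounds=([1e-4, 0.1], [2.0, 2.0]),
                            xtol=1e-12, ftol=1e-12, max_nfev=200)
        if not fit.success:
            n_flagged += 1
            continue
        t2[iy, ix] = fit.x[0] * 1000.0
    return t2, n_flagged


def normalize_relaxation_maps(maps: RelaxationMaps):
    """(T1/4000 ms, T2/300 ms) — puts the maps on the Z-value 0-1 scale."""
    t1_norm = maps.t1_obs_ms / T1_NORM_MS
    t2_norm = maps.t2_ms / T2_NORM_MS if maps.t2_ms is not None else None
    return t1_norm, t2_norm


def erode_mask(mask: np.ndarray) -> np.ndarray:
    """Binary erosion with the rank-2, all-neighbour 3x3 structuring element."""
    return ndimage.binary_erosion(np.asarray(mask, bool), structure=np.ones((3, 3), bool))


# ---------------------------------------------------------------------------
# full pipeline


def preprocess_study(dataset: StudyDataset) -> PreprocessedStudy:
    """Run the full preprocessing chain on one study.

    Order: drift correction -> WASSR B0 map -> low-B1 recentring -> T1 fit
    -> T2 fit (R1 fixed) -> normalization -> feature-image assembly ->
    mask erosion.  QC counters (flagged voxels, drift slope) are recorded
    in ``PreprocessedStudy.qc``.
    """
    refs = dataset.reference_series
    mask = dataset.tissue_mask
    orders = np.array([r.acq_order for r in refs], dtype=float)
    means = np.array([r.image.pixels[mask].mean() for r in refs])
    slope_rel = float(np.polyfit(orders, means, 1)[0] / means[0])

    ds = drift_correct(dataset)
    b0_map, n_b0_flagged = fit_wassr_b0(ds)
    ds, n_fallback = b0_correct_low_b1(ds, b0_map)
    relax, n_t1_flagged = fit_t1_map(ds.ir_series, mask)
    t2_map, n_t2_flagged = fit_t2_from_wassr(ds, relax.t1_obs_ms, b0_map)
    relax.t2_ms = t2_map
    t1_norm, t2_norm = normalize_relaxation_maps(relax)

    s0_map = reference_s0_map(ds)
    features = {"t1_norm": t1_norm, "t2_norm": t2_norm}
    with np.errstate(divide="ignore", invalid="ignore"):
        for bi, blk in enumerate(ds.schedule.blocks):
            if blk.role == "wassr":
                continue  # WASSR is a calibration block, not a feature
            zstack = ds.zspec_array(bi)
            for oi, off in enumerate(blk.offsets_ppm):
                z = np.where(s0_map > 0, zstack[oi] / np.where(s0_map > 0, s0_map, 1.0), 0.0)
                features[feature_name(blk.b1_uT, off)] = z

    return PreprocessedStudy(
        subject_id=dataset.subject_id,
        feature_images=features,
        relaxation=relax,
        b0_map_ppm=b0_map,
        eroded_mask=erode_mask(mask),
        schedule=ds.schedule,
        qc={
            "drift_slope_per_frame": slope_rel,
            "b0_flagged": n_b0_flagged,
            "b0_fallback": n_fallback,
            "t1_flagged": n_t1_flagged,
            "t2_flagged": n_t2_flagged,
        },
    )


def save_preprocessed(study: PreprocessedStudy, path) -> None:
    """Write a preprocessed study directory (NIfTI stacks + JSON metadata)."""
    import json
    from pathlib import Path
    import nibabel as nib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    names = sorted(study.feature_images)
    stack = np.stack([study.feature_images[n] for n in names], axis=-1)[:, :, None, :]
    nib.save(nib.Nifti1Image(stack, np.eye(4)), str(path / "features.nii.gz"))
    maps = np.stack([study.relaxation.t1_obs_ms,
                     study.relaxation.t2_ms if study.relaxation.t2_ms is not None
                     else np.zeros_like(study.relaxation.t1_obs_ms),
                     study.b0_map_ppm], axis=-1)[:, :, None, :]
    nib.save(nib.Nifti1Image(maps, np.eye(4)), str(path / "maps.nii.gz"))
    nib.save(nib.Nifti1Image(study.eroded_mask.astype(np.uint8), np.eye(4)),
             str(path / "eroded_mask.nii.gz"))
    from .core_data import _schedule_to_dict
    meta = {"subject_id": study.subject_id, "feature_names": names,
            "qc": study.qc,
            "schedule": _schedule_to_dict(study.schedule) if study.schedule else None}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def load_preprocessed(path) -> PreprocessedStudy:
    """Read a directory written by :func:`save_preprocessed`."""
    import json
    from pathlib import Path
    import nibabel as nib

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    stack = np.asarray(nib.load(str(path / "features.nii.gz")).dataobj)[:, :, 0, :]
    names = meta["feature_names"]
    features = {n: stack[:, :, i] for i, n in enumerate(names)}
    maps = np.asarray(nib.load(str(path / "maps.nii.gz")).dataobj)[:, :, 0, :]
    mask = np.asarray(nib.load(str(path / "eroded_mask.nii.gz")).dataobj).astype(bool)
    from .core_data import RelaxationMaps, _schedule_from_dict
    schedule = (_schedule_from_dict(meta["schedule"])
                if meta.get("schedule") else None)
    return PreprocessedStudy(
        subject_id=meta["subject_id"], feature_images=features,
        relaxation=RelaxationMaps(maps[:, :, 0], maps[:, :, 1]),
        b0_map_ppm=maps[:, :, 2], eroded_mask=mask, schedule=schedule,
        qc=meta.get("qc", {}),
    )
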