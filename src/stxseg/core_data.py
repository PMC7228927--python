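"""Domain types, unit conversions, and on-disk study container I/O.

A *study* is one subject's saturation-transfer MRI session: a stack of
single-slice saturation-weighted frames indexed by (B1 amplitude, frequency
offset, acquisition order), interleaved unsaturated reference frames at a
very large offset, an inversion-recovery series for T1 mapping, and a tissue
mask.  On disk a study is a directory with NIfTI volumes plus a JSON
schedule sidecar (see :func:`save_study`).

Units convention: frequency offsets are stored in ppm, B1 in microtesla,
relaxation times in ms.  Physics code converts to rad/s and seconds via
:func:`ppm_to_angular` and :func:`b1_to_omega1`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
import nibabel as nib
import numpy as np

__all__ = [
    "GAMMA_MHZ_PER_T",
    "ScheduleBlock",
    "AcquisitionSchedule",
    "ImageVolume",
    "StudyDataset",
    "RelaxationMaps",
    "StudyIOError",
    "default_schedule",
    "ppm_to_angular",
    "angular_to_ppm",
    "b1_to_omega1",
    "load_study",
    "save_study",
]

#: Proton gyromagnetic ratio over 2*pi, MHz/T.
GAMMA_MHZ_PER_T = 42.577

VALID_ROLES = ("wassr", "low_b1", "high_b1")


class StudyIOError(RuntimeError):
    """Raised when a study directory cannot be read or is inconsistent."""


def ppm_to_angular(offset_ppm, b0_T: float):
    """Convert a chemical-shift offset (ppm) to angular frequency (rad/s).

    offset_hz = offset_ppm * gamma/2pi (MHz/T) * B0 (T); angular = 2*pi*offset_hz.
    """
    offset_hz = np.asarray(offset_ppm, dtype=float) * GAMMA_MHZ_PER_T * b0_T
    return 2.0 * math.pi * offset_hz


def angular_to_ppm(angular_rad_s, b0_T: float):
    """Inverse of :func:`ppm_to_angular`."""
    return np.asarray(angular_rad_s, dtype=float) / (2.0 * math.pi * GAMMA_MHZ_PER_T * b0_T)


def b1_to_omega1(b1_uT):
    """Convert a saturation amplitude B1 (µT) to omega_1 = gamma*B1 (rad/s)."""
    return 2.0 * math.pi * GAMMA_MHZ_PER_T * np.asarray(b1_uT, dtype=float)


@dataclass(frozen=True)
class ScheduleBlock:
    """One saturation block: a B1 amplitude and its ordered offset list."""

    b1_uT: float
    offsets_ppm: tuple
    role: str  # "wassr" | "low_b1" | "high_b1"

    def __post_init__(self):
        if self.b1_uT < 0:
            raise ValueError("b1_uT must be >= 0")
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}, got {self.role!r}")
        offs = tuple(float(o) for o in self.offsets_ppm)
        if not all(math.isfinite(o) for o in offs):
            raise ValueError("offsets must be finite")
        object.__setattr__(self, "offsets_ppm", offs)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Full acquisition schedule of a saturation-transfer study.

    The default (:func:`default_schedule`) mirrors a 7 T small-animal
    protocol: two 66-offset Z-spectra at 0.5 and 2 µT within ±5 ppm, two
    11-offset log-spaced spectra (300 -> 3 ppm) at 3 and 6 µT, a 21-offset
    WASSR spectrum at 0.1 µT within ±0.5 ppm, unsaturated references at
    667 ppm interleaved between every five Z-spectrum measurements, and a
    five-point inversion-recovery series.
    """

    blocks: tuple
    field_T: float = 7.0
    reference_offset_ppm: float = 667.0
    reference_interleave: int = 5
    inversion_times_ms: tuple = (30.0, 110.0, 390.0, 1400.0, 5000.0)
    saturation_duration_ms: float = 490.0

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(
            self, "inversion_times_ms", tuple(float(t) for t in self.inversion_times_ms)
        )
        if self.reference_interleave < 1:
            raise ValueError("reference_interleave must be >= 1")
        tis = self.inversion_times_ms
        if not all(t2 > t1 for t1, t2 in zip(tis, tis[1:])):
            raise ValueError("inversion_times_ms must be strictly increasing")
        n_wassr = sum(1 for b in self.blocks if b.role == "wassr")
        if n_wassr != 1:
            raise ValueError(f"exactly one WASSR block required, found {n_wassr}")

    @property
    def wassr_block_index(self) -> int:
        return next(i for i, b in enumerate(self.blocks) if b.role == "wassr")

    def blocks_with_role(self, role: str) -> list[int]:
        return [i for i, b in enumerate(self.blocks) if b.role == role]

    def n_measurements(self) -> int:
        return sum(len(b.offsets_ppm) for b in self.blocks)

    def frame_plan(self) -> list[tuple]:
        """Acquisition-ordered frame plan.

        Returns a list of ``("ref", block, None)`` / ``("zspec", block, offset_idx)``
        entries: for each block, a reference frame first, a reference after every
        ``reference_interleave`` measurements, and a closing reference.
        """
        plan: list[tuple] = []
        for bi, blk in enumerate(self.blocks):
            plan.append(("ref", bi, None))
            for oi in range(len(blk.offsets_ppm)):
                plan.append(("zspec", bi, oi))
                if (oi + 1) % self.reference_interleave == 0 and oi + 1 < len(blk.offsets_ppm):
                    plan.append(("ref", bi, None))
            plan.append(("ref", bi, None))
        return plan


def default_schedule(field_T: float = 7.0) -> AcquisitionSchedule:
    """The study acquisition schedule (7 T defaults)."""
    sym66 = tuple(np.round(np.linspace(-5.0, 5.0, 66), 6))
    high11 = tuple(np.round(np.logspace(np.log10(300.0), np.log10(3.0), 11), 6))
    wassr21 = tuple(np.round(np.linspace(-0.5, 0.5, 21), 6))
    blocks = (
        ScheduleBlock(0.5, sym66, "low_b1"),
        ScheduleBlock(2.0, sym66, "low_b1"),
        ScheduleBlock(3.0, high11, "high_b1"),
        ScheduleBlock(6.0, high11, "high_b1"),
        ScheduleBlock(0.1, wassr21, "wassr"),
    )
    return AcquisitionSchedule(blocks=blocks, field_T=field_T)


@dataclass
class ImageVolume:
    """A single 2D image with a role tag."""

    pixels: np.ndarray
    role: str = "zspec"  # zspec|reference|ir|t1_map|t2_map|b0_map|mask|label

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")
        if self.role in ("mask", "label") and not np.issubdtype(self.pixels.dtype, np.integer):
            if not np.allclose(self.pixels, np.round(self.pixels)):
                raise ValueError(f"{self.role} volume must be integer-valued")
            self.pixels = self.pixels.astype(np.int32)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class ZspecFrame:
    block: int
    offset_index: int
    acq_order: int
    image: ImageVolume


@dataclass
class ReferenceFrame:
    acq_order: int
    image: ImageVolume


@dataclass
class StudyDataset:
    """One subject's full saturation-transfer study, in memory."""

    subject_id: str
    schedule: AcquisitionSchedule
    zspec_series: list  # of ZspecFrame
    reference_series: list  # of ReferenceFrame
    ir_series: list  # of (ti_ms, ImageVolume)
    tissue_mask: np.ndarray

    def __post_init__(self):
        self.tissue_mask = np.asarray(self.tissue_mask).astype(bool)
        self.validate()

    def validate(self) -> None:
        shape = self.tissue_mask.shape
        seen = set()
        for fr in self.zspec_series:
            if fr.image.shape != shape:
                raise ValueError("all images must share one shape")
            seen.add((fr.block, fr.offset_index))
        expected = {
            (bi, oi)
            for bi, blk in enumerate(self.schedule.blocks)
            for oi in range(len(blk.offsets_ppm))
        }
        if seen != expected:
            missing = expected - seen
            extra = seen - expected
            raise ValueError(
                f"schedule/image mismatch: {len(missing)} missing, {len(extra)} unexpected"
            )
        for fr in self.reference_series:
            if fr.image.shape != shape:
                raise ValueError("all images must share one shape")
        if len(self.reference_series) >= 1 and len(self.zspec_series) >= 1:
            orders = sorted(fr.acq_order for fr in self.reference_series)
            zorders = [fr.acq_order for fr in self.zspec_series]
            if orders and zorders and not (orders[0] < min(zorders)):
                raise ValueError("reference frames must bracket the z-spectrum frames")

    @property
    def n_voxels(self) -> int:
        """Number of non-background voxels (q_i for this subject)."""
        return int(self.tissue_mask.sum())

    def zspec_array(self, block: int) -> np.ndarray:
        """Stack of one block's frames ordered by offset index, shape (n_offsets, *img)."""
        frames = sorted(
            (fr for fr in self.zspec_series if fr.block == block),
            key=lambda fr: fr.offset_index,
        )
        return np.stack([fr.image.pixels for fr in frames])

    def copy(self) -> "StudyDataset":
        return StudyDataset(
            subject_id=self.subject_id,
            schedule=self.schedule,
            zspec_series=[
                ZspecFrame(f.block, f.offset_index, f.acq_order,
                           ImageVolume(f.image.pixels.copy(), f.image.role))
                for f in self.zspec_series
            ],
            reference_series=[
                ReferenceFrame(f.acq_order, ImageVolume(f.image.pixels.copy(), f.image.role))
                for f in self.reference_series
            ],
            ir_series=[(ti, ImageVolume(img.pixels.copy(), img.role)) for ti, img in self.ir_series],
            tissue_mask=self.tissue_mask.copy(),
        )


@dataclass
class RelaxationMaps:
    """Observed T1, T2 and equilibrium-signal maps (ms / arbitrary units)."""

    t1_obs_ms: np.ndarray
    t2_ms: np.ndarray | None = None
    s0: np.ndarray | None = None

    def __post_init__(self):
        self.t1_obs_ms = np.asarray(self.t1_obs_ms, dtype=float)
        if self.t2_ms is not None:
            self.t2_ms = np.asarray(self.t2_ms, dtype=float)
        if self.s0 is not None:
            self.s0 = np.asarray(self.s0, dtype=float)


# ---------------------------------------------------------------------------
# serialization


def _schedule_to_dict(s: AcquisitionSchedule) -> dict:
    return {
        "field_T": s.field_T,
        "reference_offset_ppm": s.reference_offset_ppm,
        "reference_interleave": s.reference_interleave,
        "inversion_times_ms": list(s.inversion_times_ms),
        "saturation_duration_ms": s.saturation_duration_ms,
        "blocks": [
            {"b1_uT": b.b1_uT, "offsets_ppm": list(b.offsets_ppm), "role": b.role}
            for b in s.blocks
        ],
    }


def _schedule_from_dict(d: dict) -> AcquisitionSchedule:
    return AcquisitionSchedule(
        blocks=tuple(
            ScheduleBlock(b["b1_uT"], tuple(b["offsets_ppm"]), b["role"]) for b in d["blocks"]
        ),
        field_T=d["field_T"],
        reference_offset_ppm=d["reference_offset_ppm"],
        reference_interleave=d["reference_interleave"],
        inversion_times_ms=tuple(d["inversion_times_ms"]),
        saturation_duration_ms=d["saturation_duration_ms"],
    )


def _write_nifti(path: Path, data: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data), affine=np.eye(4))
    nib.save(img, str(path))


def _read_nifti(path: Path) -> np.ndarray:
    if not path.exists():
        raise StudyIOError(f"missing image file: {path}")
    arr = np.asanyarray(nib.load(str(path)).dataobj)
    if not np.all(np.isfinite(arr)):
        raise StudyIOError(f"non-finite pixels in {path}")
    return np.asarray(arr)


def save_study(dataset: StudyDataset, path) -> None:
    """Write a study directory: zspec.nii.gz, ir.nii.gz, mask.nii.gz, schedule.json.

    All saturation and reference frames are stacked into a single 4D volume
    in acquisition order; ``schedule.json`` carries the frame -> (block,
    offset)/reference map so acquisition order is explicit, not inferred.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frames = [(f.acq_order, "zspec", f.block, f.offset_index, f.image.pixels)
              for f in dataset.zspec_series]
    frames += [(f.acq_order, "reference", None, None, f.image.pixels)
               for f in dataset.reference_series]
    frames.sort(key=lambda t: t[0])
    stack = np.stack([f[4] for f in frames], axis=-1)[:, :, None, :]  # x,y,1,frame
    _write_nifti(path / "zspec.nii.gz", stack.astype(np.float64))
    frame_map = [
        {"acq_order": int(o), "kind": kind, "block": blk, "offset_index": oi}
        for o, kind, blk, oi, _ in frames
    ]
    ir_stack = np.stack([img.pixels for _, img in dataset.ir_series], axis=-1)[:, :, None, :]
    _write_nifti(path / "ir.nii.gz", ir_stack.astype(np.float64))
    _write_nifti(path / "mask.nii.gz", dataset.tissue_mask.astype(np.uint8))
    sidecar = {
        "subject_id": dataset.subject_id,
        "schedule": _schedule_to_dict(dataset.schedule),
        "frame_map": frame_map,
        "ir_times_ms": [float(ti) for ti, _ in dataset.ir_series],
    }
    (path / "schedule.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_study(path) -> StudyDataset:
    """Read a study directory written by :func:`save_study`."""
    path = Path(path)
    sidecar_path = path / "schedule.json"
    if not sidecar_path.exists():
        raise StudyIOError(f"missing schedule sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    schedule = _schedule_from_dict(sidecar["schedule"])
    stack = _read_nifti(path / "zspec.nii.gz")
    if stack.ndim == 4:
        stack = stack[:, :, 0, :]
    frame_map = sidecar["frame_map"]
    if stack.shape[-1] != len(frame_map):
        raise StudyIOError(
            f"frame count mismatch: sidecar lists {len(frame_map)} frames, "
            f"volume has {stack.shape[-1]}"
        )
    zspec, refs = [], []
    for i, fm in enumerate(frame_map):
        img = ImageVolume(stack[:, :, i], role="zspec" if fm["kind"] == "zspec" else "reference")
        if fm["kind"] == "zspec":
            zspec.append(ZspecFrame(fm["block"], fm["offset_index"], fm["acq_order"], img))
        else:
            refs.append(ReferenceFrame(fm["acq_order"], img))
    ir_stack = _read_nifti(path / "ir.nii.gz")
    if ir_stack.ndim == 4:
        ir_stack = ir_stack[:, :, 0, :]
    tis = sidecar["ir_times_ms"]
    if ir_stack.shape[-1] != len(tis):
        raise StudyIOError("inversion-recovery frame count mismatch")
    ir_series = [(float(ti), ImageVolume(ir_stack[:, :, i], role="ir"))
                 for i, ti in enumerate(tis)]
    mask = _read_nifti(path / "mask.nii.gz").astype(bool)
    try:
        return StudyDataset(
            subject_id=sidecar["subject_id"],
            schedule=schedule,
            zspec_series=zspec,
            reference_series=refs,
            ir_series=ir_series,
            tissue_mask=mask,
        )
    except ValueError as e:
        raise StudyIOError(str(e)) from e
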