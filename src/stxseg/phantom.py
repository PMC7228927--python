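"""Synthetic xenograft phantom cohorts with known tissue truth.

The generator emulates a single-slice mouse-leg tumour study: an elliptical
leg cross-section of muscle wrapped in a connective sheath, containing a
tumour with a necrotic/apoptotic core and optional blood/edema pockets.
Every voxel carries biophysical parameters (observed T1, liquid T2, MT pool
parameters, CEST/NOE pools) jittered around class means, and the simulator
produces the full saturation-transfer acquisition — Z-spectrum frames in
acquisition order with interleaved references, multiplicative linear signal
drift, a smooth B0 off-resonance field, Gaussian receiver noise, and an
inversion-recovery series — as a :class:`~stxseg.core_data.StudyDataset`.

Class means default to the cohort-mean relaxation/MT parameters of the five
tissue classes (tumour, necrosis/apoptosis, blood/edema, muscle/connective,
muscle); only the product R*M0B is constrained by those values, and the
per-class exchange rates default to literature-range values chosen so the
classes form the graded MT/relaxation continuum observed in vivo.  A smooth
free-fluid partial-volume field (raising T1/T2 and diluting the semisolid
and solute pools together) reproduces the dominant within-tissue
"brightness" variation of real tumour tissue; the blood/edema class gets
extra parameter spread to mimic its mixed composition.  CEST pool defaults
place more amide (3.5 ppm) signal in active tumour than in necrosis, so
exchange-weighted contrasts have a known direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core_data import (
    AcquisitionSchedule,
    ImageVolume,
    ReferenceFrame,
    StudyDataset,
    ZspecFrame,
    default_schedule,
    ppm_to_angular,
    b1_to_omega1,
)
from .qmt import ExchangePool, absorption_lineshape, R1B_DEFAULT

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "TissueParams",
    "PhantomTruth",
    "default_tissue_params",
    "make_phantom",
    "make_cohort",
    "simulate_zspectra",
    "simulate_ir_series",
    "simulate_study",
    "simulate_tunel_image",
]

LABELS = {
    "background": 0,
    "active_tumour": 1,
    "necrosis_apoptosis": 2,
    "blood_edema": 3,
    "muscle_connective": 4,
    "muscle": 5,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: TUNEL blue-channel threshold separating tumour (<) from necrosis (>=).
TUNEL_BLUE_THRESHOLD = 0.78


@dataclass
class TissueParams:
    """Class-mean biophysical parameters for one tissue type."""

    name: str
    t1_obs_ms: float
    t2a_ms: float
    r_exchange_per_s: float
    m0b: float
    t2b_us: float
    lineshape: str = "super_lorentzian"
    cest_pools: tuple = ()  # of ExchangePool

    def __post_init__(self):
        if min(self.t1_obs_ms, self.t2a_ms, self.t2b_us) <= 0:
            raise ValueError("relaxation times must be > 0")
        if not 0.0 <= self.m0b < 1.0:
            raise ValueError("m0b must be in [0, 1)")
        if any(p.fraction < 0 for p in self.cest_pools):
            raise ValueError("cest pool fractions must be >= 0")


def _pool(offset, fraction, k, t2_ms):
    return ExchangePool(fraction=fraction, k_per_s=k, t2_s=t2_ms / 1000.0,
                        offset_ppm=offset, lineshape="lorentzian")


#: Default semisolid-to-liquid exchange rates (1/s) per class.  Only the
#: product R*M0B is pinned by the class MT effect; the rates themselves
#: differ between tissue types (literature range ~5-70 1/s) and are chosen
#: so the classes form the graded MT/relaxation continuum seen in vivo.
DEFAULT_EXCHANGE_RATES = {
    LABELS["active_tumour"]: 60.0,
    LABELS["necrosis_apoptosis"]: 25.0,
    LABELS["blood_edema"]: 25.0,
    LABELS["muscle_connective"]: 8.0,
    LABELS["muscle"]: 15.0,
}


def default_tissue_params(exchange_rates: dict | float | None = None) -> dict:
    """Default class parameters keyed by label.

    MT-effect products (R*M0B): tumour 1.2, necrosis 1.1, blood/edema 0.9,
    muscle/connective 1.5, muscle 3.8; blood/edema uses a Lorentzian
    semisolid lineshape, all others super-Lorentzian.  CEST pools are
    (offset ppm, fraction, exchange 1/s, T2 ms) for amide 3.5 / amine 2 /
    NOE -3.5; amide is higher in active tumour than in necrosis.
    ``exchange_rates`` may be a per-label dict or a single rate applied to
    every class; M0B is derived as (R*M0B)/R either way.
    """
    if exchange_rates is None:
        rates = dict(DEFAULT_EXCHANGE_RATES)
    elif isinstance(exchange_rates, dict):
        rates = {**DEFAULT_EXCHANGE_RATES, **exchange_rates}
    else:
        rates = {l: float(exchange_rates) for l in DEFAULT_EXCHANGE_RATES}
    r = rates[LABELS["active_tumour"]]
    params = {
        LABELS["active_tumour"]: TissueParams(
            "active_tumour", 2200.0, 53.0, r, 1.2 / r, 8.2,
            cest_pools=(
                _pool(3.5, 0.0012, 50.0, 10.0),
                _pool(2.0, 0.0008, 700.0, 4.0),
                _pool(-3.5, 0.0040, 20.0, 1.0),
            ),
        ),
        LABELS["necrosis_apoptosis"]: TissueParams(
            "necrosis_apoptosis", 2600.0, 80.0,
            rates[LABELS["necrosis_apoptosis"]],
            1.1 / rates[LABELS["necrosis_apoptosis"]], 7.8,
            cest_pools=(
                _pool(3.5, 0.0005, 50.0, 10.0),
                _pool(2.0, 0.0008, 700.0, 4.0),
                _pool(-3.5, 0.0030, 20.0, 1.0),
            ),
        ),
        LABELS["blood_edema"]: TissueParams(
            "blood_edema", 2800.0, 130.0,
            rates[LABELS["blood_edema"]],
            0.9 / rates[LABELS["blood_edema"]], 100.0, lineshape="lorentzian",
            cest_pools=(
                _pool(3.5, 0.0003, 50.0, 10.0),
                _pool(-3.5, 0.0010, 20.0, 1.0),
            ),
        ),
        LABELS["muscle_connective"]: TissueParams(
            "muscle_connective", 1810.0, 31.0,
            rates[LABELS["muscle_connective"]],
            1.5 / rates[LABELS["muscle_connective"]], 7.4,
            cest_pools=(
                _pool(3.5, 0.0008, 50.0, 10.0),
                _pool(2.0, 0.0010, 800.0, 4.0),
                _pool(-3.5, 0.0040, 20.0, 1.0),
            ),
        ),
        LABELS["muscle"]: TissueParams(
            "muscle", 1840.0, 27.0,
            rates[LABELS["muscle"]],
            3.8 / rates[LABELS["muscle"]], 7.2,
            cest_pools=(
                _pool(3.5, 0.0008, 50.0, 10.0),
                _pool(2.0, 0.0012, 800.0, 4.0),
                _pool(-3.5, 0.0045, 20.0, 1.0),
            ),
        ),
    }
    return params


DEFAULT_CLASS_FRACTIONS = {
    "muscle": 0.30,
    "muscle_connective": 0.07,
    "tumour": 0.13,  # tumour + necrotic core together
    "blood_edema": 0.025,
}

#: Extra relative parameter spread for the mixed-composition blood/edema
#: class (its in-vivo parameter uncertainties are an order of magnitude
#: larger than the parenchymal classes').
BLOOD_EDEMA_JITTER_SD = 0.15


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject."""

    label_map: np.ndarray
    maps: dict  # per-voxel parameter maps, keys below
    tissue_params: dict  # label -> TissueParams (subject means)
    b0_field_ppm: np.ndarray
    drift_per_frame: float
    noise_sd: float
    seed: int
    subject_id: str = "phantom"

    # maps keys: t1_obs_ms, t2a_ms, r_per_s, m0b, t2b_us, s0, cest_scale

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map, dtype=np.int32)
        if not set(np.unique(self.label_map)) <= set(range(6)):
            raise ValueError("label values must be in 0..5")
        if np.abs(self.b0_field_ppm).max() > 0.3 + 1e-12:
            raise ValueError("b0 field must be within +/-0.3 ppm")

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    @property
    def true_necrosis_fraction(self) -> float:
        n_nec = int((self.label_map == LABELS["necrosis_apoptosis"]).sum())
        n_tum = int((self.label_map == LABELS["active_tumour"]).sum())
        if n_nec + n_tum == 0:
            return float("nan")
        return n_nec / (n_nec + n_tum)


def _ellipse_mask(shape, center, semi_axes, angle_rad):
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx]
    xc = (x - center[1]) / 1.0
    yc = (y - center[0]) / 1.0
    ca, sa = math.cos(angle_rad), math.sin(angle_rad)
    u = ca * xc + sa * yc
    v = -sa * xc + ca * yc
    return (u / semi_axes[1]) ** 2 + (v / semi_axes[0]) ** 2 <= 1.0


def make_phantom(shape=(64, 64), class_fractions=None, necrosis_fraction: float = 0.25,
                 jitter_sd: float = 0.03, seed: int = 0, tissue_params=None,
                 b0_amplitude_ppm: float = 0.10, drift_per_frame: float = 1e-4,
                 noise_sd: float = 0.01, fluid_amplitude: float = 0.12,
                 fluid_jitter_sd: float = 0.04,
                 subject_id: str | None = None) -> PhantomTruth:
    """Generate one phantom subject.

    Parameters
    ----------
    class_fractions : dict, optional
        Image-area fractions for ``muscle``, ``muscle_connective``,
        ``tumour`` (tumour + necrosis together) and ``blood_edema``;
        remaining area is background.  Fractions must be >= 0 and sum <= 1.
    necrosis_fraction : float
        Requested necrotic-core share of the tumour region.
    jitter_sd : float
        Relative SD of per-voxel Gaussian jitter on the parameter maps
        (the blood/edema class additionally gets ``BLOOD_EDEMA_JITTER_SD``).
    fluid_amplitude, fluid_jitter_sd : float
        Peak value and voxel jitter of the smooth free-fluid
        partial-volume field.  Each voxel's parameters are mixed toward
        free-fluid values (T1 3500 ms, T2 250 ms, no semisolid or solute
        pools) by its fluid fraction, emulating the dominant within-tissue
        water-content variation of real tumours.
    """
    shape = tuple(shape)
    if min(shape) < 16:
        raise ValueError("shape must be at least 16x16")
    fr = dict(DEFAULT_CLASS_FRACTIONS)
    if class_fractions:
        fr.update(class_fractions)
    if any(v < 0 for v in fr.values()) or sum(fr.values()) > 1.0:
        raise ValueError("class fractions must be >= 0 and sum to <= 1")
    if not 0.0 <= necrosis_fraction <= 1.0:
        raise ValueError("necrosis_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    params = dict(tissue_params or default_tissue_params())

    ny, nx = shape
    npix = ny * nx
    leg_frac = fr["muscle"] + fr["muscle_connective"] + fr["tumour"] + fr["blood_edema"]

    # leg ellipse
    aspect = rng.uniform(1.15, 1.4)
    ang = rng.uniform(0, math.pi)
    b_leg = math.sqrt(leg_frac * npix / (math.pi * aspect))
    a_leg = aspect * b_leg
    center = (ny / 2 + rng.uniform(-1, 1), nx / 2 + rng.uniform(-1, 1))
    leg = _ellipse_mask(shape, center, (b_leg, a_leg), ang)

    labels = np.zeros(shape, dtype=np.int32)
    labels[leg] = LABELS["muscle"]

    # connective sheath: outer shell of the leg ellipse
    if fr["muscle_connective"] > 0:
        s = math.sqrt(max(1.0 - fr["muscle_connective"] / leg_frac, 0.0))
        inner = _ellipse_mask(shape, center, (b_leg * s, a_leg * s), ang)
        labels[leg & ~inner] = LABELS["muscle_connective"]

    # tumour ellipse inside the leg, offset from centre
    tum_frac = fr["tumour"] + fr["blood_edema"]
    t_aspect = rng.uniform(1.0, 1.25)
    t_ang = rng.uniform(0, math.pi)
    b_t = math.sqrt(tum_frac * npix / (math.pi * t_aspect))
    a_t = t_aspect * b_t
    direction = rng.uniform(0, 2 * math.pi)
    off = 0.35 * b_leg
    t_center = (center[0] + off * math.sin(direction) * 0.6,
                center[1] + off * math.cos(direction))
    tumour = _ellipse_mask(shape, t_center, (b_t, a_t), t_ang) & leg
    labels[tumour] = LABELS["active_tumour"]

    # necrotic core, concentric with slight jitter
    if necrosis_fraction > 0:
        sc = math.sqrt(necrosis_fraction)
        n_center = (t_center[0] + rng.uniform(-1, 1), t_center[1] + rng.uniform(-1, 1))
        core = _ellipse_mask(shape, n_center, (b_t * sc, a_t * sc), t_ang) & tumour
        labels[core] = LABELS["necrosis_apoptosis"]

    # blood/edema pockets at the tumour rim
    if fr["blood_edema"] > 0 and tumour.any():
        n_pockets = 2
        r_pocket = math.sqrt(fr["blood_edema"] * npix / (math.pi * n_pockets))
        for _ in range(n_pockets):
            phi = rng.uniform(0, 2 * math.pi)
            pc = (t_center[0] + 0.7 * b_t * math.sin(phi),
                  t_center[1] + 0.7 * a_t * math.cos(phi))
            pocket = _ellipse_mask(shape, pc, (r_pocket, r_pocket), 0.0) & tumour
            labels[pocket] = LABELS["blood_edema"]

    # per-voxel parameter maps: class mean * (1 + jitter)
    maps = {k: np.zeros(shape) for k in
            ("t1_obs_ms", "t2a_ms", "r_per_s", "m0b", "t2b_us", "s0",
             "cest_scale", "fluid_fraction")}
    for lbl, tp in params.items():
        sel = labels == lbl
        n = int(sel.sum())
        if n == 0:
            continue
        sd = jitter_sd
        if lbl == LABELS["blood_edema"]:
            sd = math.hypot(jitter_sd, BLOOD_EDEMA_JITTER_SD)
        jit = lambda mean: mean * np.clip(1.0 + rng.normal(0, sd, n), 0.5, 1.6)
        maps["t1_obs_ms"][sel] = jit(tp.t1_obs_ms)
        maps["t2a_ms"][sel] = jit(tp.t2a_ms)
        maps["r_per_s"][sel] = tp.r_exchange_per_s
        maps["m0b"][sel] = np.clip(jit(tp.m0b), 0.0, 0.5)
        maps["t2b_us"][sel] = jit(tp.t2b_us)
        maps["cest_scale"][sel] = np.clip(1.0 + rng.normal(0, sd, n), 0.5, 1.6)

    # smooth free-fluid partial-volume field: water content rises, semisolid
    # and solute pools dilute together.  A smoothed Gaussian random field
    # gives near-Gaussian per-voxel marginals, so each tissue cluster stays
    # unimodal while carrying realistic spatially-correlated variation.
    if fluid_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        fld = gaussian_filter(rng.normal(0, 1, shape), sigma=3.0)
        sd = fld.std()
        fld = (fld - fld.mean()) / (sd if sd > 0 else 1.0)
        fld = fluid_amplitude / 2.0 + (fluid_amplitude / 4.0) * fld
        fld = np.clip(fld + rng.normal(0, fluid_jitter_sd, shape), 0.0, 0.5)
        fld = np.where(labels > 0, fld, 0.0)
        maps["fluid_fraction"] = fld
        maps["t1_obs_ms"] += fld * (3500.0 - maps["t1_obs_ms"])
        maps["t2a_ms"] += fld * (250.0 - maps["t2a_ms"])
        maps["m0b"] *= 1.0 - fld
        maps["cest_scale"] *= 1.0 - fld

    # smooth receive-coil-like S0 profile, arbitrary units
    y, x = np.mgrid[0:ny, 0:nx]
    profile = 1.0 + 0.10 * np.sin(math.pi * x / nx) * np.sin(math.pi * y / ny)
    maps["s0"] = np.where(labels > 0, 4000.0 * profile, 0.0)

    # low-order polynomial B0 field, capped at +/-0.3 ppm
    xn = (x - nx / 2) / nx
    yn = (y - ny / 2) / ny
    coeffs = rng.normal(0, 1, 6)
    b0 = (coeffs[0] + coeffs[1] * xn + coeffs[2] * yn + coeffs[3] * xn * yn
          + coeffs[4] * xn**2 + coeffs[5] * yn**2)
    peak = np.abs(b0).max()
    if peak > 0:
        b0 = b0 / peak * min(b0_amplitude_ppm, 0.3)

    return PhantomTruth(
        label_map=labels, maps=maps, tissue_params=params, b0_field_ppm=b0,
        drift_per_frame=drift_per_frame, noise_sd=noise_sd, seed=int(seed),
        subject_id=subject_id or f"phantom{seed:04d}",
    )


def make_cohort(n_subjects: int, shape=(64, 64), seed: int = 0,
                between_subject_sd: float = 0.04,
                necrosis_fraction_range=(0.05, 0.45), **kwargs) -> list:
    """Generate a cohort with between-subject parameter variation.

    Each subject's class-mean T1/T2A/M0B/T2B are scaled by a subject-level
    factor ``1 + N(0, between_subject_sd)`` and the requested necrotic
    fraction is drawn uniformly from ``necrosis_fraction_range``, so
    necrosis burden varies across the cohort as it does between animals.
    """
    rng = np.random.default_rng(seed)
    base = kwargs.pop("tissue_params", None) or default_tissue_params()
    cohort = []
    for i in range(n_subjects):
        sub_params = {}
        for lbl, tp in base.items():
            f = lambda: float(np.clip(1.0 + rng.normal(0, between_subject_sd), 0.7, 1.3))
            sub_params[lbl] = replace(
                tp,
                t1_obs_ms=tp.t1_obs_ms * f(),
                t2a_ms=tp.t2a_ms * f(),
                m0b=min(tp.m0b * f(), 0.5),
                t2b_us=tp.t2b_us * f(),
            )
        nf = float(rng.uniform(*necrosis_fraction_range))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(
            make_phantom(shape=shape, necrosis_fraction=nf, seed=sub_seed,
                         tissue_params=sub_params,
                         subject_id=f"phantom{i:03d}", **kwargs)
        )
    return cohort


# ---------------------------------------------------------------------------
# signal simulation


def _frame_z(truth: PhantomTruth, offset_ppm: float, b1_uT: float,
             field_T: float, apply_b0: bool = True, de_only: bool = False) -> np.ndarray:
    """Steady-state Z for every in-mask voxel at one (B1, nominal offset).

    Vectorized multi-pool closed form: water + semisolid MT pool (+ CEST
    pools per class).  With ``apply_b0`` the local off-resonance shifts the
    effective offset, exactly as the scanner's B0 inhomogeneity would.
    With ``de_only`` only direct water saturation acts (used for the WASSR
    block, which by definition probes the direct effect alone).
    """
    mask = truth.mask
    idx = np.flatnonzero(mask)
    lbl = truth.label_map.ravel()[idx]
    m = {k: v.ravel()[idx] for k, v in truth.maps.items()}
    shift = truth.b0_field_ppm.ravel()[idx] if apply_b0 else np.zeros(idx.shape)
    off_eff_ppm = offset_ppm - shift
    dw = ppm_to_angular(off_eff_ppm, field_T)
    w1 = float(b1_to_omega1(b1_uT))
    r1b = R1B_DEFAULT

    t1 = m["t1_obs_ms"] / 1000.0
    t2a = m["t2a_ms"] / 1000.0
    r = m["r_per_s"]
    f_b = m["m0b"]
    t2b = m["t2b_us"] * 1e-6
    r1_obs = 1.0 / t1
    denom = r1b - r1_obs + r
    r1a = r1_obs - r * f_b * (r1b - r1_obs) / denom

    w_a = w1**2 * t2a / (1.0 + (dw * t2a) ** 2)
    if de_only:
        z = np.zeros(truth.label_map.size)
        z[idx] = r1_obs / (r1_obs + w_a)
        return z.reshape(truth.label_map.shape)
    num = r1a.copy()
    den = r1a + w_a

    # semisolid MT pool; lineshape depends on class
    g = np.zeros_like(dw)
    is_lor = np.zeros_like(dw, dtype=bool)
    for l, tp in truth.tissue_params.items():
        if tp.lineshape == "lorentzian":
            is_lor |= lbl == l
    if np.any(~is_lor):
        g[~is_lor] = absorption_lineshape(dw[~is_lor], t2b[~is_lor], "super_lorentzian")
    if np.any(is_lor):
        g[is_lor] = absorption_lineshape(dw[is_lor], t2b[is_lor], "lorentzian")
    w_b = math.pi * w1**2 * g
    d_b = r1b + r + w_b
    num += r * f_b * r1b / d_b
    den += r * f_b * (1.0 - r / d_b)

    # CEST/NOE pools, class-defined, scaled by the per-voxel jitter map
    for l, tp in truth.tissue_params.items():
        sel = lbl == l
        if not np.any(sel):
            continue
        for p in tp.cest_pools:
            dwp = dw[sel] - float(ppm_to_angular(p.offset_ppm, field_T))
            w_i = math.pi * w1**2 * absorption_lineshape(dwp, p.t2_s, "lorentzian")
            d_i = p.r1_per_s + p.k_per_s + w_i
            frac = p.fraction * m["cest_scale"][sel]
            num[sel] += p.k_per_s * frac * p.r1_per_s / d_i
            den[sel] += p.k_per_s * frac * (1.0 - p.k_per_s / d_i)

    z = np.zeros(truth.label_map.size)
    z[idx] = num / den
    return z.reshape(truth.label_map.shape)


def simulate_zspectra(truth: PhantomTruth, schedule: AcquisitionSchedule | None = None,
                      apply_b0: bool = True, apply_drift: bool = True,
                      apply_noise: bool = True) -> StudyDataset:
    """Simulate all saturation and reference frames of one study.

    Frames follow the schedule's acquisition plan (references bracketing
    and interleaved between every ``reference_interleave`` measurements);
    a multiplicative linear drift ``1 + slope*order`` and additive Gaussian
    receiver noise (SD = noise_sd x mean in-mask S0, spatially uniform) are
    applied in acquisition order.  The switches exist so tests can isolate
    single corruption mechanisms; defaults simulate everything.
    """
    schedule = schedule or default_schedule()
    rng = np.random.default_rng([int(truth.seed), 1])
    s0 = truth.maps["s0"]
    noise_scale = truth.noise_sd * float(s0[truth.mask].mean()) if apply_noise else 0.0
    slope = truth.drift_per_frame if apply_drift else 0.0

    # reference frames: saturation parked at 667 ppm leaves the water
    # unsaturated to within machine precision, so they are simulated as
    # unsaturated acquisitions (keeps the reference chain exact)
    ref_z = _frame_z(truth, schedule.reference_offset_ppm, 0.0,
                     schedule.field_T, apply_b0=apply_b0)

    zspec, refs = [], []
    for order, (kind, bi, oi) in enumerate(schedule.frame_plan()):
        if kind == "ref":
            z = ref_z
        else:
            blk = schedule.blocks[bi]
            z = _frame_z(truth, blk.offsets_ppm[oi], blk.b1_uT, schedule.field_T,
                         apply_b0=apply_b0, de_only=(blk.role == "wassr"))
        sig = z * s0 * (1.0 + slope * order)
        if noise_scale > 0:
            sig = sig + rng.normal(0.0, noise_scale, sig.shape)
        img = ImageVolume(sig, role="reference" if kind == "ref" else "zspec")
        if kind == "ref":
            refs.append(ReferenceFrame(order, img))
        else:
            zspec.append(ZspecFrame(bi, oi, order, img))
    return StudyDataset(
        subject_id=truth.subject_id, schedule=schedule, zspec_series=zspec,
        reference_series=refs, ir_series=[], tissue_mask=truth.mask,
    )


def simulate_ir_series(truth: PhantomTruth, schedule: AcquisitionSchedule | None = None,
                       apply_noise: bool = True) -> list:
    """Inversion-recovery frames: S(TI) = S0 (1 - 2 exp(-TI/T1)), signed."""
    schedule = schedule or default_schedule()
    rng = np.random.default_rng([int(truth.seed), 2])
    s0 = truth.maps["s0"]
    t1 = truth.maps["t1_obs_ms"]
    noise_scale = truth.noise_sd * float(s0[truth.mask].mean()) if apply_noise else 0.0
    frames = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for ti in schedule.inversion_times_ms:
            sig = np.where(truth.mask, s0 * (1.0 - 2.0 * np.exp(-ti / np.maximum(t1, 1e-9))), 0.0)
            if noise_scale > 0:
                sig = sig + rng.normal(0.0, noise_scale, sig.shape)
            frames.append((float(ti), ImageVolume(sig, role="ir")))
    return frames


def simulate_study(truth: PhantomTruth, schedule: AcquisitionSchedule | None = None,
                   **kwargs) -> StudyDataset:
    """Full simulated study: Z-spectrum + reference frames + IR series."""
    schedule = schedule or default_schedule()
    ds = simulate_zspectra(truth, schedule, **kwargs)
    apply_noise = kwargs.get("apply_noise", True)
    ds.ir_series = simulate_ir_series(truth, schedule, apply_noise=apply_noise)
    return ds


def simulate_tunel_image(truth: PhantomTruth, upscale: int = 4, seed: int | None = None):
    """Synthetic TUNEL-like RGB histology image and its tumour crop mask.

    In-crop pixels are drawn so the blue channel separates the classes at
    the 0.78 threshold with margin: tumour (haematoxylin-dominated) blue
    below, necrosis/apoptosis blue at or above.  Returns ``(rgb, crop)``
    with ``rgb`` float in [0, 1], shape ``(H*u, W*u, 3)``.
    """
    rng = np.random.default_rng([int(truth.seed if seed is None else seed), 3])
    lab = np.kron(truth.label_map, np.ones((upscale, upscale), dtype=np.int32))
    crop = (lab == LABELS["active_tumour"]) | (lab == LABELS["necrosis_apoptosis"])
    h, w = lab.shape
    rgb = np.zeros((h, w, 3))
    # background slide: near-white
    rgb[..., :] = 0.92
    tissue = lab > 0
    rgb[tissue] = [0.75, 0.55, 0.65]  # generic eosin-pink tissue
    tum = lab == LABELS["active_tumour"]
    nec = lab == LABELS["necrosis_apoptosis"]
    n_t, n_n = int(tum.sum()), int(nec.sum())
    thr = TUNEL_BLUE_THRESHOLD
    if n_t:
        rgb[tum, 0] = np.clip(0.45 + rng.normal(0, 0.05, n_t), 0, 1)
        rgb[tum, 1] = np.clip(0.35 + rng.normal(0, 0.05, n_t), 0, 1)
        rgb[tum, 2] = np.clip(0.55 + rng.normal(0, 0.06, n_t), 0.0, thr - 0.02)
    if n_n:
        rgb[nec, 0] = np.clip(0.55 + rng.normal(0, 0.05, n_n), 0, 1)
        rgb[nec, 1] = np.clip(0.45 + rng.normal(0, 0.05, n_n), 0, 1)
        rgb[nec, 2] = np.clip(0.88 + rng.normal(0, 0.04, n_n), thr, 1.0)
    return np.clip(rgb, 0.0, 1.0), crop
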