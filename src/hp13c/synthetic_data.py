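"""Digital phantoms and synthetic multi-site hyperpolarized pyruvate studies.

Real traveling-volunteer data are not publicly depositable, so every
downstream stage of the pipeline is exercised on synthetic exams that carry
the same statistical and physical structure the analysis assumes:

* a brain-like label phantom with whole-brain, cortex, deep-white-matter and
  vessel regions plus a guaranteed noise region outside the head;
* gamma-variate pyruvate bolus input, forward-only pyruvate-to-lactate
  exchange with T1 decay, one RF excitation per metabolite per frame
  (signal = M_z sin(theta), depletion by cos(theta));
* optional per-metabolite T2* attenuation exp(-TE/T2*) so echo-time
  harmonization can be tested against known truth;
* additive Gaussian (optionally Rician) acquisition noise;
* between-subject, between-site and residual variance components on k_PL,
  so the generating intraclass correlation of a study is known exactly.

The forward ODEs per tissue voxel are

    dP/dt = input(t) - P/T1_pyr - k_PL * P
    dL/dt = k_PL * P - L/T1_lac

integrated with classical RK4 on a fine grid (default 0.1 s); vessel voxels
receive a 10x pyruvate input and convert nothing (k_PL = 0), mimicking the
large intravascular pyruvate pool.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import PROTOCOL_1, PROTOCOL_2, DynamicSeries, ProtocolSpec

__all__ = [
    "BACKGROUND",
    "BRAIN",
    "CORTEX",
    "DEEP_WM",
    "VESSEL",
    "ROI_NAMES",
    "PhantomVolume",
    "KineticParams",
    "VarianceComponents",
    "ExamSlot",
    "StudyDesign",
    "StudyDataset",
    "SizingError",
    "make_phantom",
    "gamma_variate_bolus",
    "simulate_traces",
    "simulate_exam",
    "draw_kpl_table",
    "simulate_study",
    "default_study_design",
    "write_exam",
    "read_exam",
    "write_phantom",
    "read_phantom",
    "write_study",
]

# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

BACKGROUND = 0
BRAIN = 1  # unlabeled brain tissue (the whole-brain mask is labels >= 1)
CORTEX = 2
DEEP_WM = 3
VESSEL = 4

ROI_NAMES = {BRAIN: "whole_brain", CORTEX: "cortex", DEEP_WM: "deep_white_matter", VESSEL: "vessel"}

VESSEL_INPUT_SCALE = 10.0  # intravascular pyruvate pool relative to tissue
FINE_GRID_DT_S = 0.1  # simulation step; >= 30x finer than the 3 s frame spacing

#: default acquisition noise SD (signal units); chosen so the time-summed
#: pyruvate SNR of a default tissue voxel under protocol 1 (volume coil,
#: T2* decay included) lands near the in-vivo value of ~11
DEFAULT_NOISE_SD = 0.068

#: per-protocol noise defaults: the variable-resolution protocol was acquired
#: with a far more sensitive 24-channel receive array, emulated as lower
#: noise calibrated to the same time-summed pyruvate SNR of ~11
DEFAULT_NOISE_SD_BY_PROTOCOL = {"protocol1": 0.068, "protocol2": 0.012}


class SizingError(ValueError):
    """Phantom extents too small to place all tissue labels."""


@dataclass
class PhantomVolume:
    """Integer label volume defining the ROIs of a synthetic head.

    Labels: 0 background, 1 brain tissue, 2 cortex, 3 deep white matter,
    4 vessel.  Cortex, deep WM and vessel are disjoint subsets of the whole
    brain (labels >= 1).  ``noise_mask`` marks a contiguous background region
    well outside the head, used as the noise reference for SNR.
    """

    label_grid: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    noise_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.label_grid >= BRAIN

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.label_grid == CORTEX

    @property
    def deep_wm_mask(self) -> np.ndarray:
        return self.label_grid == DEEP_WM

    @property
    def vessel_mask(self) -> np.ndarray:
        return self.label_grid == VESSEL

    @property
    def tissue_mask(self) -> np.ndarray:
        """Brain voxels that convert pyruvate (everything but the vessel)."""
        return self.brain_mask & ~self.vessel_mask

    def roi_mask(self, roi: str) -> np.ndarray:
        if roi == "whole_brain":
            return self.brain_mask
        if roi == "cortex":
            return self.cortex_mask
        if roi == "deep_white_matter":
            return self.deep_wm_mask
        if roi == "vessel":
            return self.vessel_mask
        if roi == "noise":
            return self.noise_mask
        raise KeyError(f"unknown ROI {roi!r}")


def make_phantom(
    shape: tuple[int, int, int] = (24, 24, 8),
    voxel_size_mm: tuple[float, float, float] = (15.0, 15.0, 15.0),
    seed: int = 0,
) -> PhantomVolume:
    """Build a deterministic ellipsoidal head phantom with labeled ROIs.

    The brain is an ellipsoid whose semi-axes are jittered a few percent by
    ``seed``; the cortex is its outer shell, deep white matter a central
    blob at mid-ventricle level, and the vessel a one-voxel-wide midline
    channel in the superior half (a sagittal-sinus stand-in).  The noise
    region is all background farther than 1.25 brain radii from the center.
    """
    nx, ny, nz = (int(s) for s in shape)
    if nx < 16 or ny < 16 or nz < 4:
        raise SizingError(f"shape {shape} too small: need >= 16x16 in-plane and >= 4 slices")
    rng = np.random.default_rng(seed)
    jitter = 1.0 + 0.05 * rng.uniform(-1.0, 1.0, size=3)
    semi = np.array([0.36 * nx, 0.36 * ny, 0.36 * nz]) * jitter
    center = (np.array([nx, ny, nz]) - 1) / 2.0

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r2 = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    )
    r = np.sqrt(r2)

    labels = np.zeros(shape, dtype=np.int16)
    brain = r <= 1.0
    labels[brain] = BRAIN
    labels[brain & (r >= 0.8)] = CORTEX
    mid_z = int(round(center[2]))
    r_xy = np.sqrt(((ii - center[0]) / semi[0]) ** 2 + ((jj - center[1]) / semi[1]) ** 2)
    deep = brain & (r_xy <= 0.35) & (np.abs(kk - center[2]) <= 1.0)
    labels[deep] = DEEP_WM
    mid_x = int(round(center[0]))
    vessel = np.zeros(shape, dtype=bool)
    vessel[mid_x, :, :] = True
    vessel &= brain & (r > 0.45) & (r < 0.95) & (kk >= mid_z)
    labels[vessel] = VESSEL

    noise_mask = r > 1.25
    if not brain.any():
        raise SizingError("phantom brain is empty")
    for name, m in (("cortex", labels == CORTEX), ("deep white matter", labels == DEEP_WM), ("vessel", labels == VESSEL)):
        if not m.any():
            raise SizingError(f"phantom too small to place the {name} label")
    if noise_mask.sum() < 100:
        raise SizingError("phantom too small to hold a >= 100-voxel noise region")
    return PhantomVolume(label_grid=labels, voxel_size_mm=tuple(float(v) for v in voxel_size_mm), noise_mask=noise_mask)


# ---------------------------------------------------------------------------
# Kinetic parameters and bolus input
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth kinetic quantities of one exam.

    ``k_pl`` is the forward conversion rate (the reverse reaction is not
    modeled).  The bolus is a normalized gamma-variate arriving at
    ``bolus_t0`` and peaking at ``bolus_t0 + bolus_alpha * bolus_beta`` with
    peak input rate ``bolus_amplitude``.
    """

    k_pl: float = 0.024  # s^-1, typical healthy-brain whole-brain mean
    t1_pyr: float = 30.0  # s
    t1_lac: float = 25.0  # s
    bolus_t0: float = 4.0  # s; imaging starts before bolus arrival
    bolus_alpha: float = 2.0
    bolus_beta: float = 3.5  # s
    bolus_amplitude: float = 1.0

    def __post_init__(self) -> None:
        vals = dataclasses.asdict(self)
        if not all(math.isfinite(v) for v in vals.values()):
            raise ValueError(f"non-finite kinetic parameter in {vals}")
        if self.k_pl < 0:
            raise ValueError("k_pl must be >= 0 (forward reaction only)")
        for name in ("t1_pyr", "t1_lac", "bolus_beta", "bolus_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def gamma_variate_bolus(t: np.ndarray, params: KineticParams) -> np.ndarray:
    """Normalized gamma-variate input rate.

    ``rate(t) = A * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)``
    for t > t0 and 0 before; the peak equals ``A`` at ``t0 + alpha*beta``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("bolus times must be finite")
    if np.any(np.diff(t) < 0):
        raise ValueError("bolus times must be non-decreasing")
    tau = t - params.bolus_t0
    out = np.zeros_like(t)
    pos = tau > 0
    x = tau[pos] / params.bolus_beta
    out[pos] = params.bolus_amplitude * (x / params.bolus_alpha) ** params.bolus_alpha * np.exp(
        params.bolus_alpha - x
    )
    return out


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------


def _rk4_step(p: float, l: float, t: float, h: float, params: KineticParams, k_pl: float, input_scale: float):
    """One RK4 step of the two-pool exchange ODE."""

    def deriv(pi, li, ti):
        inp = input_scale * float(gamma_variate_bolus(np.array([ti]), params)[0])
        dp = inp - pi / params.t1_pyr - k_pl * pi
        dl = k_pl * pi - li / params.t1_lac
        return dp, dl

    k1p, k1l = deriv(p, l, t)
    k2p, k2l = deriv(p + h / 2 * k1p, l + h / 2 * k1l, t + h / 2)
    k3p, k3l = deriv(p + h / 2 * k2p, l + h / 2 * k2l, t + h / 2)
    k4p, k4l = deriv(p + h * k3p, l + h * k3l, t + h)
    return p + h / 6 * (k1p + 2 * k2p + 2 * k3p + k4p), l + h / 6 * (k1l + 2 * k2l + 2 * k3l + k4l)


def simulate_traces(
    protocol: ProtocolSpec,
    params: KineticParams,
    k_pl: float | None = None,
    input_scale: float = 1.0,
    t2star_pyr_ms: float | None = None,
    t2star_lac_ms: float | None = None,
    fine_dt: float = FINE_GRID_DT_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free signal traces of a single voxel under a protocol.

    Integrates the exchange ODEs on a fine grid; at every frame time records
    ``S = M_z * sin(theta) * exp(-TE/T2*)`` per metabolite and applies RF
    depletion ``M_z *= cos(theta)``.  Returns (pyruvate, lactate) signal
    arrays of length ``n_frames``.
    """
    if k_pl is None:
        k_pl = params.k_pl
    if k_pl < 0:
        raise ValueError("k_pl must be >= 0")
    sin_p, cos_p = np.sin(np.deg2rad(protocol.flip_pyr_deg)), np.cos(np.deg2rad(protocol.flip_pyr_deg))
    sin_l, cos_l = np.sin(np.deg2rad(protocol.flip_lac_deg)), np.cos(np.deg2rad(protocol.flip_lac_deg))
    atten_p = 1.0 if t2star_pyr_ms is None else math.exp(-protocol.te_ms / t2star_pyr_ms)
    atten_l = 1.0 if t2star_lac_ms is None else math.exp(-protocol.te_ms / t2star_lac_ms)

    dt_frame = protocol.frame_interval_s
    n_sub = max(1, int(math.ceil(dt_frame / fine_dt)))
    h = dt_frame / n_sub

    p, l = 0.0, 0.0
    pyr_sig = np.empty(protocol.n_frames)
    lac_sig = np.empty(protocol.n_frames)
    for n in range(protocol.n_frames):
        t_frame = n * dt_frame
        pyr_sig[n] = p * sin_p * atten_p
        lac_sig[n] = l * sin_l * atten_l
        p *= cos_p
        l *= cos_l
        if n < protocol.n_frames - 1:
            for s in range(n_sub):
                p, l = _rk4_step(p, l, t_frame + s * h, h, params, k_pl, input_scale)
    return pyr_sig, lac_sig


def simulate_exam(
    phantom: PhantomVolume,
    protocol: ProtocolSpec,
    params: KineticParams,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    t2star_pyr_ms: float | None = None,
    t2star_lac_ms: float | None = None,
    rician: bool = False,
    subject_id: str = "",
    site_id: str = "",
    exam_id: str = "",
) -> DynamicSeries:
    """Simulate one complete dynamic exam on a phantom.

    All converting (tissue) voxels share the exam's kinetics; vessel voxels
    get a 10x pyruvate input and no conversion; background is pure noise.
    Gaussian noise of SD ``noise_sd`` is added to every voxel-frame (Rician
    magnitude noise optionally instead).  Deterministic given ``seed``.
    """
    if protocol.n_frames < 3:
        raise ValueError("protocol must have at least 3 frames")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    tissue_p, tissue_l = simulate_traces(
        protocol, params, t2star_pyr_ms=t2star_pyr_ms, t2star_lac_ms=t2star_lac_ms
    )
    vessel_p, vessel_l = simulate_traces(
        protocol,
        params,
        k_pl=0.0,
        input_scale=VESSEL_INPUT_SCALE,
        t2star_pyr_ms=t2star_pyr_ms,
        t2star_lac_ms=t2star_lac_ms,
    )

    shape4 = (*phantom.shape, protocol.n_frames)
    pyr = np.zeros(shape4)
    lac = np.zeros(shape4)
    pyr[phantom.tissue_mask] = tissue_p
    lac[phantom.tissue_mask] = tissue_l
    pyr[phantom.vessel_mask] = vessel_p
    lac[phantom.vessel_mask] = vessel_l

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        if rician:
            pyr = np.hypot(pyr + rng.normal(0, noise_sd, shape4), rng.normal(0, noise_sd, shape4))
            lac = np.hypot(lac + rng.normal(0, noise_sd, shape4), rng.normal(0, noise_sd, shape4))
        else:
            pyr = pyr + rng.normal(0, noise_sd, shape4)
            lac = lac + rng.normal(0, noise_sd, shape4)
    return DynamicSeries(
        pyruvate=pyr,
        lactate=lac,
        protocol=protocol,
        subject_id=subject_id,
        site_id=site_id,
        exam_id=exam_id,
        noise_sd=float(noise_sd),
        seed=int(seed),
        t2star_pyr_ms=t2star_pyr_ms,
        t2star_lac_ms=t2star_lac_ms,
    )


# ---------------------------------------------------------------------------
# Study-level generation
# ---------------------------------------------------------------------------

KPL_FLOOR = 1e-4  # s^-1; draws truncated here to keep rate constants physical


@dataclass(frozen=True)
class VarianceComponents:
    """Generating SDs (s^-1) of the k_PL random-effects decomposition."""

    between_subject_sd: float
    between_site_sd: float
    residual_sd: float

    def __post_init__(self) -> None:
        for name in ("between_subject_sd", "between_site_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def implied_icc(self) -> float:
        """ICC(A,1) implied by the components: var_subject / total var."""
        tot = self.between_subject_sd**2 + self.between_site_sd**2 + self.residual_sd**2
        if tot == 0:
            return 1.0
        return self.between_subject_sd**2 / tot


@dataclass(frozen=True)
class ExamSlot:
    subject_id: str
    site_id: str
    protocol_id: str


@dataclass
class StudyDesign:
    """Who is scanned where, with what protocol, and the generating kinetics."""

    subjects: list[str]
    sites: list[str]
    protocols: dict[str, ProtocolSpec]
    exam_plan: list[ExamSlot]
    variance: VarianceComponents
    mean_kpl: float = 0.024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_kpl <= 0:
            raise ValueError("mean_kpl must be > 0")
        for slot in self.exam_plan:
            if slot.protocol_id not in self.protocols:
                raise ValueError(f"exam references unknown protocol {slot.protocol_id!r}")
            if slot.subject_id not in self.subjects or slot.site_id not in self.sites:
                raise ValueError(f"exam references unknown subject/site in {slot}")

    @property
    def implied_icc(self) -> float:
        return self.variance.implied_icc


def default_study_design(
    mean_kpl: float = 0.024,
    between_subject_sd: float = 0.0018,
    between_site_sd: float = 0.0004,
    residual_sd: float = 0.0007,
    seed: int = 0,
    n_frames: int = 20,
) -> StudyDesign:
    """The two-site, two-protocol traveling-volunteer layout.

    Three subjects, two sites; eight single-resolution (protocol 1) exams
    split across both sites (3/3/2 per subject) plus four variable-resolution
    (protocol 2) exams at site 1, for 3/4/5 exams per subject and 12 total.
    The default variance components imply a site-to-site ICC of ~0.83.
    """
    p1 = dataclasses.replace(PROTOCOL_1, n_frames=n_frames)
    p2 = dataclasses.replace(PROTOCOL_2, n_frames=n_frames)
    plan = [
        ExamSlot("sub1", "site1", "protocol1"),
        ExamSlot("sub1", "site1", "protocol1"),
        ExamSlot("sub1", "site2", "protocol1"),
        ExamSlot("sub2", "site1", "protocol1"),
        ExamSlot("sub2", "site2", "protocol1"),
        ExamSlot("sub2", "site2", "protocol1"),
        ExamSlot("sub3", "site1", "protocol1"),
        ExamSlot("sub3", "site2", "protocol1"),
        ExamSlot("sub2", "site1", "protocol2"),
        ExamSlot("sub3", "site1", "protocol2"),
        ExamSlot("sub3", "site1", "protocol2"),
        ExamSlot("sub3", "site1", "protocol2"),
    ]
    return StudyDesign(
        subjects=["sub1", "sub2", "sub3"],
        sites=["site1", "site2"],
        protocols={"protocol1": p1, "protocol2": p2},
        exam_plan=plan,
        variance=VarianceComponents(between_subject_sd, between_site_sd, residual_sd),
        mean_kpl=mean_kpl,
        seed=seed,
    )


def draw_kpl_table(design: StudyDesign, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the ground-truth k_PL of every exam from the variance components.

    ``k_pl = mean + b_subject + c_site + e_exam`` with independent zero-mean
    Gaussian components, truncated below at a small positive floor.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    b = {s: rng.normal(0.0, design.variance.between_subject_sd) for s in design.subjects}
    c = {s: rng.normal(0.0, design.variance.between_site_sd) for s in design.sites}
    rows = []
    for i, slot in enumerate(design.exam_plan):
        e = rng.normal(0.0, design.variance.residual_sd)
        kpl = max(design.mean_kpl + b[slot.subject_id] + c[slot.site_id] + e, KPL_FLOOR)
        rows.append(
            {
                "exam_id": f"exam{i:02d}",
                "subject_id": slot.subject_id,
                "site_id": slot.site_id,
                "protocol_id": slot.protocol_id,
                "true_kpl": kpl,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StudyDataset:
    """A complete simulated study: exams plus the generating truth."""

    exams: list[DynamicSeries]
    true_kpl_per_exam: dict[str, float]
    design: StudyDesign
    phantom: PhantomVolume

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.true_kpl_per_exam.values()):
            raise ValueError("true k_PL values must all be > 0")


def simulate_study(
    design: StudyDesign,
    phantom: PhantomVolume | None = None,
    base_params: KineticParams | None = None,
    noise_sd: float | dict[str, float] = DEFAULT_NOISE_SD,
    t2star_by_protocol: dict[str, tuple[float, float]] | None = None,
) -> StudyDataset:
    """Simulate every exam in a design; deterministic given ``design.seed``.

    ``noise_sd`` may be a single SD or a per-protocol mapping (different
    coils have different sensitivity).  ``t2star_by_protocol`` optionally
    maps protocol_id to ground-truth (T2*_pyr, T2*_lac) in ms, enabling
    echo-time harmonization studies.
    """
    if phantom is None:
        phantom = make_phantom(seed=design.seed)
    if base_params is None:
        base_params = KineticParams()
    rng = np.random.default_rng(design.seed)
    table = draw_kpl_table(design, rng)
    exams: list[DynamicSeries] = []
    truth: dict[str, float] = {}
    for row in table.itertuples(index=False):
        params = dataclasses.replace(base_params, k_pl=row.true_kpl)
        t2p, t2l = (None, None)
        if t2star_by_protocol and row.protocol_id in t2star_by_protocol:
            t2p, t2l = t2star_by_protocol[row.protocol_id]
        exam_seed = int(rng.integers(0, 2**31 - 1))
        sd = noise_sd[row.protocol_id] if isinstance(noise_sd, dict) else noise_sd
        series = simulate_exam(
            phantom,
            design.protocols[row.protocol_id],
            params,
            noise_sd=sd,
            seed=exam_seed,
            t2star_pyr_ms=t2p,
            t2star_lac_ms=t2l,
            subject_id=row.subject_id,
            site_id=row.site_id,
            exam_id=row.exam_id,
        )
        exams.append(series)
        truth[row.exam_id] = float(row.true_kpl)
    return StudyDataset(exams=exams, true_kpl_per_exam=truth, design=design, phantom=phantom)


# ---------------------------------------------------------------------------
# On-disk layout: paired NIfTI volumes + JSON sidecar + CSV manifest
# ---------------------------------------------------------------------------


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag([*voxel_size_mm, 1.0])


def write_phantom(phantom: PhantomVolume, path: str | Path) -> None:
    import nibabel as nib

    path = Path(path)
    nib.save(nib.Nifti1Image(phantom.label_grid.astype(np.int16), _affine(phantom.voxel_size_mm)), str(path))
    noise_path = path.with_name(path.name.replace(".nii", "_noise.nii"))
    nib.save(nib.Nifti1Image(phantom.noise_mask.astype(np.uint8), _affine(phantom.voxel_size_mm)), str(noise_path))


def read_phantom(path: str | Path, voxel_size_mm=(15.0, 15.0, 15.0)) -> PhantomVolume:
    import nibabel as nib

    path = Path(path)
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int16)
    noise_path = path.with_name(path.name.replace(".nii", "_noise.nii"))
    noise = np.asarray(nib.load(str(noise_path)).dataobj).astype(bool)
    return PhantomVolume(label_grid=labels, voxel_size_mm=tuple(voxel_size_mm), noise_mask=noise)


def write_exam(series: DynamicSeries, out_dir: str | Path) -> dict:
    """Write one exam as paired 4D NIfTIs plus a JSON sidecar; returns paths."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = series.exam_id or "exam"
    aff = _affine(series.protocol.voxel_size_lac_mm)
    paths = {
        "pyruvate": str(out_dir / f"{stem}_pyruvate.nii"),
        "lactate": str(out_dir / f"{stem}_lactate.nii"),
        "sidecar": str(out_dir / f"{stem}.json"),
    }
    nib.save(nib.Nifti1Image(series.pyruvate, aff), paths["pyruvate"])
    nib.save(nib.Nifti1Image(series.lactate, aff), paths["lactate"])
    sidecar = {
        "protocol": series.protocol.to_dict(),
        "subject_id": series.subject_id,
        "site_id": series.site_id,
        "exam_id": series.exam_id,
        "noise_sd": series.noise_sd,
        "seed": series.seed,
        "t2star_pyr_ms": series.t2star_pyr_ms,
        "t2star_lac_ms": series.t2star_lac_ms,
    }
    Path(paths["sidecar"]).write_text(json.dumps(sidecar, indent=2))
    return paths


def read_exam(sidecar_path: str | Path) -> DynamicSeries:
    import nibabel as nib

    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    stem = meta["exam_id"] or "exam"
    pyr = np.asarray(nib.load(str(sidecar_path.with_name(f"{stem}_pyruvate.nii"))).dataobj, dtype=float)
    lac = np.asarray(nib.load(str(sidecar_path.with_name(f"{stem}_lactate.nii"))).dataobj, dtype=float)
    return DynamicSeries(
        pyruvate=pyr,
        lactate=lac,
        protocol=ProtocolSpec.from_dict(meta["protocol"]),
        subject_id=meta["subject_id"],
        site_id=meta["site_id"],
        exam_id=meta["exam_id"],
        noise_sd=meta["noise_sd"],
        seed=meta["seed"],
        t2star_pyr_ms=meta["t2star_pyr_ms"],
        t2star_lac_ms=meta["t2star_lac_ms"],
    )


def write_study(dataset: StudyDataset, out_dir: str | Path) -> Path:
    """Write all exams, the phantom, truth and a CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_phantom(dataset.phantom, out_dir / "phantom.nii")
    rows = []
    for series in dataset.exams:
        paths = write_exam(series, out_dir)
        rows.append(
            {
                "subject_id": series.subject_id,
                "site_id": series.site_id,
                "exam_id": series.exam_id,
                "protocol_id": series.protocol.protocol_id,
                "pyruvate_path": paths["pyruvate"],
                "lactate_path": paths["lactate"],
                "sidecar_path": paths["sidecar"],
                "true_kpl": dataset.true_kpl_per_exam[series.exam_id],
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
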