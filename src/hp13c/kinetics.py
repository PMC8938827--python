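"""Inputless two-site exchange modeling of pyruvate-to-lactate conversion.

The primary quantitative readout of a hyperpolarized [1-13C]pyruvate exam is
k_PL, the apparent first-order rate constant of pyruvate-to-lactate
conversion.  It is estimated voxel-wise from the dynamic metabolite signals
with a forward-only two-site exchange model that treats the *measured*
pyruvate signal as the driving input ("inputless" fitting): no parametric
arterial input function is assumed, and the reverse reaction k_LP is ignored.

Signal model per excitation
---------------------------
At every dynamic frame each metabolite is excited once with its own flip
angle theta.  The detected signal is ``M_z * sin(theta)`` and the remaining
longitudinal magnetization is ``M_z * cos(theta)`` (RF depletion).  Between
frames, lactate magnetization relaxes with T1 and accrues converted
pyruvate magnetization at rate k_PL.  The discrete propagation used for
fitting is

    L-(n+1) = L+(n) * E1 + k_PL * dt * (P+(n) * E1 + P-(n+1)) / 2

with ``E1 = exp(-dt / T1_lac)``, where ``-``/``+`` denote magnetization just
before/after the RF pulse of a frame, and the trapezoid term integrates the
pyruvate magnetization inferred from the measured signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ProtocolSpec",
    "DynamicSeries",
    "KplFit",
    "KplMap",
    "PROTOCOL_1",
    "PROTOCOL_2",
    "UnidentifiableFitError",
    "EmptyMapError",
    "predict_lactate",
    "fit_kpl",
    "fit_kpl_map",
    "write_kpl_map",
]

DEFAULT_T1_LAC_S = 25.0  # assumed lactate T1; not identifiable from single-bolus data
DEFAULT_KPL_INIT = 0.02  # s^-1, standard initial estimate
DEFAULT_KPL_BOUNDS = (0.0, 0.3)  # s^-1, forward-only with a generous ceiling
DEFAULT_PYR_SNR_GATE = 3.0  # voxels below this time-summed pyruvate SNR are not fitted


class UnidentifiableFitError(ValueError):
    """The pyruvate trace carries no signal, so k_PL is unidentifiable."""


class EmptyMapError(ValueError):
    """No voxel passed the mask and SNR gate."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Acquisition parameters of one dynamic 13C imaging protocol.

    Flip angles are per metabolite (pyruvate is excited with a low angle to
    preserve the substrate pool; lactate with a higher one for SNR).  ``te_ms``
    is the echo time, which sets the T2* signal loss the harmonization module
    corrects for.
    """

    protocol_id: str
    flip_pyr_deg: float
    flip_lac_deg: float
    te_ms: float
    frame_interval_s: float
    n_frames: int
    voxel_size_pyr_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    voxel_size_lac_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)

    def __post_init__(self) -> None:
        for name, ang in (("flip_pyr_deg", self.flip_pyr_deg), ("flip_lac_deg", self.flip_lac_deg)):
            if not 0.0 < ang <= 90.0:
                raise ValueError(f"{name} must be in (0, 90] degrees, got {ang}")
        if self.te_ms < 0:
            raise ValueError(f"te_ms must be >= 0, got {self.te_ms}")
        if self.frame_interval_s <= 0:
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if self.n_frames < 3:
            raise ValueError(f"n_frames must be >= 3, got {self.n_frames}")

    @property
    def frame_times(self) -> np.ndarray:
        """Times of the dynamic frames in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        for k in ("voxel_size_pyr_mm", "voxel_size_lac_mm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


#: Single-resolution EPI protocol used at both sites.
PROTOCOL_1 = ProtocolSpec(
    protocol_id="protocol1",
    flip_pyr_deg=10.0,
    flip_lac_deg=40.0,
    te_ms=21.7,
    frame_interval_s=3.0,
    n_frames=20,
    voxel_size_pyr_mm=(15.0, 15.0, 15.0),
    voxel_size_lac_mm=(15.0, 15.0, 15.0),
)

#: Variable-resolution EPI protocol (finer pyruvate grid, longer echo time).
PROTOCOL_2 = ProtocolSpec(
    protocol_id="protocol2",
    flip_pyr_deg=20.0,
    flip_lac_deg=30.0,
    te_ms=30.7,
    frame_interval_s=3.0,
    n_frames=20,
    voxel_size_pyr_mm=(7.5, 7.5, 15.0),
    voxel_size_lac_mm=(15.0, 15.0, 15.0),
)


@dataclass
class DynamicSeries:
    """Dynamic per-metabolite image series of one exam.

    ``pyruvate`` and ``lactate`` are 4D arrays (x, y, z, frame) of detected
    signal.  Exam identity and acquisition metadata travel with the data so
    downstream metric tables can be built without a side channel.
    """

    pyruvate: np.ndarray
    lactate: np.ndarray
    protocol: ProtocolSpec
    subject_id: str = ""
    site_id: str = ""
    exam_id: str = ""
    noise_sd: float = 0.0
    seed: int | None = None
    #: ground-truth T2* used by the simulator, if any (ms); None = no decay applied
    t2star_pyr_ms: float | None = None
    t2star_lac_ms: float | None = None

    def __post_init__(self) -> None:
        self.pyruvate = np.asarray(self.pyruvate, dtype=float)
        self.lactate = np.asarray(self.lactate, dtype=float)
        if self.pyruvate.ndim != 4 or self.lactate.ndim != 4:
            raise ValueError("pyruvate and lactate must be 4D (x, y, z, frame)")
        if self.pyruvate.shape[-1] != self.protocol.n_frames:
            raise ValueError(
                f"pyruvate has {self.pyruvate.shape[-1]} frames, protocol expects {self.protocol.n_frames}"
            )
        if self.lactate.shape[-1] != self.protocol.n_frames:
            raise ValueError(
                f"lactate has {self.lactate.shape[-1]} frames, protocol expects {self.protocol.n_frames}"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.lactate.shape[:3]

    @property
    def frame_times(self) -> np.ndarray:
        return self.protocol.frame_times

    def get_channel(self, metabolite: str) -> np.ndarray:
        if metabolite == "pyruvate":
            return self.pyruvate
        if metabolite == "lactate":
            return self.lactate
        raise KeyError(f"unknown metabolite {metabolite!r}; expected 'pyruvate' or 'lactate'")

    def with_scaled_channels(self, factor_pyr: float, factor_lac: float) -> "DynamicSeries":
        """Return a copy with each metabolite channel globally rescaled."""
        out = dataclasses.replace(self)
        out.pyruvate = self.pyruvate * float(factor_pyr)
        out.lactate = self.lactate * float(factor_lac)
        return out


@dataclass
class KplFit:
    """Result of a single-voxel (or single-trace) k_PL fit."""

    k_pl_hat: float
    residual_ss: float
    converged: bool
    n_iter: int
    init_k_pl: float


@dataclass
class KplMap:
    """Voxel-wise k_PL map; values are NaN outside ``fit_mask``."""

    values: np.ndarray
    fit_mask: np.ndarray
    snr_threshold_used: float

    def defined_values(self) -> np.ndarray:
        return self.values[self.fit_mask]


def predict_lactate(
    pyr_signal: np.ndarray,
    k_pl: float,
    t1_lac: float,
    protocol: ProtocolSpec,
    lac0: float = 0.0,
) -> np.ndarray:
    """Predict the lactate signal trace from a measured pyruvate trace.

    The measured pyruvate signal is converted to pre-excitation longitudinal
    magnetization by division with sin(theta_P); lactate magnetization is then
    propagated frame to frame (T1 decay, RF depletion, trapezoidal accrual of
    the conversion term) and read out through sin(theta_L).

    Parameters
    ----------
    pyr_signal : measured pyruvate signal per frame (negative values clipped).
    k_pl : conversion rate constant, 1/s.
    t1_lac : assumed lactate T1, s.
    protocol : acquisition parameters (flip angles, frame interval).
    lac0 : lactate longitudinal magnetization before the first excitation.
    """
    pyr_signal = np.clip(np.asarray(pyr_signal, dtype=float), 0.0, None)
    if pyr_signal.shape[-1] != protocol.n_frames:
        raise ValueError(
            f"pyr_signal has {pyr_signal.shape[-1]} frames, protocol expects {protocol.n_frames}"
        )
    sin_p = np.sin(np.deg2rad(protocol.flip_pyr_deg))
    if sin_p < 1e-9:
        raise ZeroDivisionError("sin(flip_pyr) too small to infer pyruvate magnetization")
    sin_l = np.sin(np.deg2rad(protocol.flip_lac_deg))
    cos_p = np.cos(np.deg2rad(protocol.flip_pyr_deg))
    cos_l = np.cos(np.deg2rad(protocol.flip_lac_deg))
    dt = protocol.frame_interval_s
    e1 = np.exp(-dt / t1_lac)

    p_minus = pyr_signal / sin_p  # pyruvate M_z just before each excitation
    lac = np.empty_like(p_minus)
    lac[..., 0] = lac0
    for n in range(protocol.n_frames - 1):
        accrual = k_pl * dt * (p_minus[..., n] * cos_p * e1 + p_minus[..., n + 1]) / 2.0
        lac[..., n + 1] = lac[..., n] * cos_l * e1 + accrual
    return lac * sin_l


def fit_kpl(
    pyr_signal: np.ndarray,
    lac_signal: np.ndarray,
    protocol: ProtocolSpec,
    init_k_pl: float = DEFAULT_KPL_INIT,
    t1_lac: float = DEFAULT_T1_LAC_S,
    bounds: tuple[float, float] = DEFAULT_KPL_BOUNDS,
) -> KplFit:
    """Bounded least-squares estimate of k_PL for one voxel trace.

    The initial lactate magnetization is fixed from the first measured
    lactate frame (imaging starts before bolus arrival, so frame 0 is
    essentially noise), leaving k_PL as the only free parameter.
    """
    from scipy.optimize import least_squares

    pyr_signal = np.asarray(pyr_signal, dtype=float)
    lac_signal = np.asarray(lac_signal, dtype=float)
    if pyr_signal.shape != (protocol.n_frames,) or lac_signal.shape != (protocol.n_frames,):
        raise ValueError("pyr_signal and lac_signal must be 1D with length n_frames")
    if not np.any(np.abs(pyr_signal) > 0):
        raise UnidentifiableFitError("all-zero pyruvate trace: k_PL is unidentifiable")

    sin_l = np.sin(np.deg2rad(protocol.flip_lac_deg))
    lac0 = lac_signal[0] / sin_l

    def residual(k: np.ndarray) -> np.ndarray:
        pred = predict_lactate(pyr_signal, float(k[0]), t1_lac, protocol, lac0=lac0)
        return pred - lac_signal

    x0 = float(np.clip(init_k_pl, bounds[0], bounds[1]))
    sol = least_squares(
        residual,
        x0=[x0],
        bounds=([bounds[0]], [bounds[1]]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return KplFit(
        k_pl_hat=float(sol.x[0]),
        residual_ss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        init_k_pl=x0,
    )


def fit_kpl_map(
    series: DynamicSeries,
    mask: np.ndarray,
    pyr_snr_threshold: float = DEFAULT_PYR_SNR_GATE,
    noise_sd: float | None = None,
    init_k_pl: float = DEFAULT_KPL_INIT,
    t1_lac: float = DEFAULT_T1_LAC_S,
    bounds: tuple[float, float] = DEFAULT_KPL_BOUNDS,
) -> KplMap:
    """Fit k_PL in every masked voxel whose summed-pyruvate SNR clears the gate.

    The per-voxel SNR of the time-summed pyruvate signal is
    ``AUC / (noise_sd * sqrt(n_frames))`` (the SD of a sum of n i.i.d. noise
    samples).  With ``noise_sd`` None or 0 (noise-free data) every masked
    voxel with positive pyruvate AUC is fitted.  Voxels failing the gate are
    excluded from ``fit_mask``, not zero-filled.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} != series spatial shape {series.spatial_shape}")
    if noise_sd is None:
        noise_sd = series.noise_sd

    auc = series.pyruvate.sum(axis=-1)
    if noise_sd and noise_sd > 0:
        snr = auc / (noise_sd * np.sqrt(series.protocol.n_frames))
    else:
        snr = np.where(auc > 0, np.inf, 0.0)
    fit_mask = mask & (snr > pyr_snr_threshold)
    if not np.any(fit_mask):
        raise EmptyMapError("no voxel passed the mask and pyruvate SNR gate")

    values = np.full(series.spatial_shape, np.nan)
    for idx in np.argwhere(fit_mask):
        i, j, k = idx
        fit = fit_kpl(
            series.pyruvate[i, j, k],
            series.lactate[i, j, k],
            series.protocol,
            init_k_pl=init_k_pl,
            t1_lac=t1_lac,
            bounds=bounds,
        )
        values[i, j, k] = fit.k_pl_hat
    return KplMap(values=values, fit_mask=fit_mask, snr_threshold_used=float(pyr_snr_threshold))


def write_kpl_map(kpl_map: KplMap, path: str | Path, voxel_size_mm=(15.0, 15.0, 15.0)) -> None:
    """Write a k_PL map and its fit mask as NIfTI files (``<stem>_mask.nii``)."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.nan_to_num(kpl_map.values), affine), str(path))
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    nib.save(nib.Nifti1Image(kpl_map.fit_mask.astype(np.uint8), affine), str(mask_path))
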