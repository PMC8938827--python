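"""Echo-time (T2*) harmonization of quantification across protocols.

The two protocols differ in echo time (21.7 vs 30.7 ms), and the metabolite
T2* values are short enough (roughly 8-18 ms in vivo) that the signal decay
between excitation and echo differs materially by metabolite, coil and
protocol.  A global per-metabolite T2* is estimated from the linewidth of
the non-localized post-imaging spectrum (Lorentzian convention
``T2* = 1/(pi * FWHM)``), and each channel is rescaled to its TE = 0 value:

    S0 = S * exp(TE / T2*)

Because the corrected signal cannot be smaller than the observed, decayed
signal, the correction factor is always >= 1.  When an exam lacks a
spectrum, the mean factor of the other exams under the same protocol is
used.  The lactate Z-score consumes the uncorrected lactate channel: it is
scale-invariant, so the correction would cancel anyway.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import DynamicSeries

__all__ = [
    "SpectrumInfo",
    "CorrectionFactors",
    "UnharmonizableExamError",
    "t2star_from_fwhm",
    "te_correction_factor",
    "factors_for_exam",
    "correct_exam",
    "protocol_average_factors",
    "read_spectra_csv",
    "write_factors_csv",
]


class UnharmonizableExamError(ValueError):
    """No spectrum for this exam and no protocol-average fallback provided."""


@dataclass(frozen=True)
class SpectrumInfo:
    """Linewidths (FWHM, Hz) from the non-localized post-imaging spectrum."""

    exam_id: str
    fwhm_pyr_hz: float | None = None
    fwhm_lac_hz: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("fwhm_pyr_hz", self.fwhm_pyr_hz), ("fwhm_lac_hz", self.fwhm_lac_hz)):
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when present, got {v}")

    @property
    def complete(self) -> bool:
        return self.fwhm_pyr_hz is not None and self.fwhm_lac_hz is not None


@dataclass(frozen=True)
class CorrectionFactors:
    """Per-metabolite TE correction of one exam; provenance records whether
    the factors come from the exam's own spectrum or a protocol average."""

    exam_id: str
    t2star_pyr_ms: float
    t2star_lac_ms: float
    factor_pyr: float
    factor_lac: float
    provenance: str  # "measured" | "protocol_average"

    def __post_init__(self) -> None:
        if self.factor_pyr < 1.0 or self.factor_lac < 1.0:
            raise ValueError("correction factors must be >= 1 for TE >= 0")


def t2star_from_fwhm(fwhm_hz: float) -> float:
    """T2* in ms from a Lorentzian linewidth: ``T2* = 1000 / (pi * FWHM)``."""
    if fwhm_hz <= 0:
        raise ValueError(f"FWHM must be > 0 Hz, got {fwhm_hz}")
    return 1000.0 / (math.pi * fwhm_hz)


def te_correction_factor(te_ms: float, t2star_ms: float) -> float:
    """Multiplicative factor restoring the TE = 0 signal: ``exp(TE/T2*)``."""
    if te_ms < 0:
        raise ValueError(f"TE must be >= 0 ms, got {te_ms}")
    if t2star_ms <= 0:
        raise ValueError(f"T2* must be > 0 ms, got {t2star_ms}")
    return math.exp(te_ms / t2star_ms)


def factors_for_exam(series: DynamicSeries, spectrum: SpectrumInfo) -> CorrectionFactors:
    """Correction factors of one exam from its own measured linewidths."""
    if not spectrum.complete:
        raise UnharmonizableExamError(f"spectrum for exam {spectrum.exam_id!r} is incomplete")
    t2p = t2star_from_fwhm(spectrum.fwhm_pyr_hz)
    t2l = t2star_from_fwhm(spectrum.fwhm_lac_hz)
    te = series.protocol.te_ms
    return CorrectionFactors(
        exam_id=series.exam_id,
        t2star_pyr_ms=t2p,
        t2star_lac_ms=t2l,
        factor_pyr=te_correction_factor(te, t2p),
        factor_lac=te_correction_factor(te, t2l),
        provenance="measured",
    )


def correct_exam(
    series: DynamicSeries,
    spectrum: SpectrumInfo | None = None,
    fallback: CorrectionFactors | None = None,
) -> tuple[DynamicSeries, CorrectionFactors]:
    """Rescale both metabolite channels to their TE = 0 amplitudes.

    Uses the exam's own spectrum when available, otherwise the supplied
    protocol-average fallback factors.  Returns the corrected series and the
    factors actually applied.
    """
    if spectrum is not None and spectrum.complete:
        factors = factors_for_exam(series, spectrum)
    elif fallback is not None:
        factors = replace(fallback, exam_id=series.exam_id)
    else:
        raise UnharmonizableExamError(
            f"exam {series.exam_id!r} has no usable spectrum and no fallback factors"
        )
    corrected = series.with_scaled_channels(factors.factor_pyr, factors.factor_lac)
    return corrected, factors


def protocol_average_factors(factors: list[CorrectionFactors]) -> CorrectionFactors:
    """Arithmetic mean of measured factors under one protocol (the fallback
    used for an exam whose spectrum was not acquired)."""
    if not factors:
        raise ValueError("need at least one measured CorrectionFactors entry")
    return CorrectionFactors(
        exam_id="",
        t2star_pyr_ms=float(np.mean([f.t2star_pyr_ms for f in factors])),
        t2star_lac_ms=float(np.mean([f.t2star_lac_ms for f in factors])),
        factor_pyr=float(np.mean([f.factor_pyr for f in factors])),
        factor_lac=float(np.mean([f.factor_lac for f in factors])),
        provenance="protocol_average",
    )


def read_spectra_csv(path: str | Path) -> dict[str, SpectrumInfo]:
    """Read spectra linewidths from CSV (exam_id, fwhm_pyr_hz, fwhm_lac_hz);
    blank cells mean the value was not measured."""
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        fp = None if pd.isna(row.fwhm_pyr_hz) else float(row.fwhm_pyr_hz)
        fl = None if pd.isna(row.fwhm_lac_hz) else float(row.fwhm_lac_hz)
        out[str(row.exam_id)] = SpectrumInfo(exam_id=str(row.exam_id), fwhm_pyr_hz=fp, fwhm_lac_hz=fl)
    return out


def write_factors_csv(factors: list[CorrectionFactors], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "exam_id": f.exam_id,
                "t2star_pyr_ms": f.t2star_pyr_ms,
                "t2star_lac_ms": f.t2star_lac_ms,
                "factor_pyr": f.factor_pyr,
                "factor_lac": f.factor_lac,
                "provenance": f.provenance,
            }
            for f in factors
        ]
    ).to_csv(path, index=False)
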