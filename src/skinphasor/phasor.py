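"""Harmonic phasor transform, reference-dye calibration, and phase lifetime.

The phasor transform maps each pixel's periodic fluorescence decay to a
point (g, s) per harmonic n — the cosine and sine Fourier coefficients at
n times the laser repetition rate, normalized by the pixel's total photon
count.  All single-exponential decays fall on the universal semicircle
g^2 + s^2 = g; mixtures fall inside it, at the photon-weighted mean of
their components' phasors.

Calibration follows the reference-dye workflow: a standard of known
mono-exponential lifetime (Coumarin 6, 2.5 ns, or dimethyl-POPOP,
1.45 ns, in ethanol) is imaged in the same session; the complex factor
mapping its pooled measured phasor onto the analytic single-exponential
phasor corrects the instrument's phase shift and modulation loss at each
harmonic.  Both harmonics used for unmixing are calibrated from the same
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .synthetic import AcquisitionModel, DecayStack, continuous_harmonic

logger = logging.getLogger(__name__)

DEFAULT_HARMONICS = (1, 2)


@dataclass
class PhasorField:
    """Per-pixel (g, s) coordinates per harmonic plus photon intensity.

    ``g`` and ``s`` map harmonic number -> 2-D float array; pixels with
    zero photons are undefined and carry NaN coordinates (never a silent
    zero).  ``intensity`` equals the time-sum of the source stack exactly.
    """

    g: dict[int, np.ndarray]
    s: dict[int, np.ndarray]
    intensity: np.ndarray
    harmonics: tuple[int, ...]
    acquisition: AcquisitionModel
    calibrated: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def defined(self) -> np.ndarray:
        """Boolean map of pixels with a defined phasor (any photons)."""
        ok = self.intensity > 0
        for n in self.harmonics:
            ok = ok & np.isfinite(self.g[n]) & np.isfinite(self.s[n])
        return ok

    def complex(self, n: int) -> np.ndarray:
        """Phasor as the complex number g + i*s at harmonic n."""
        return self.g[n] + 1j * self.s[n]


@dataclass(frozen=True)
class CalibrationFactors:
    """Per-harmonic modulation and phase corrections from a reference dye.

    Applying the calibration multiplies each phasor by
    ``modulation[n] * exp(i * phase[n])``.
    """

    modulation: dict[int, float]
    phase: dict[int, float]
    reference_name: str = "reference"
    reference_tau: float = float("nan")

    def __post_init__(self) -> None:
        for n, m in self.modulation.items():
            if not m > 0:
                raise ValueError(f"modulation correction for harmonic {n} must be > 0")
        for n, p in self.phase.items():
            if not (-np.pi < p <= np.pi):
                raise ValueError(f"phase correction for harmonic {n} outside (-pi, pi]")

    def to_dict(self) -> dict:
        return {
            "reference_name": self.reference_name,
            "reference_tau_ns": self.reference_tau,
            "harmonics": sorted(self.modulation),
            "modulation": {str(n): self.modulation[n] for n in self.modulation},
            "phase_rad": {str(n): self.phase[n] for n in self.phase},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationFactors":
        return cls(
            modulation={int(n): v for n, v in d["modulation"].items()},
            phase={int(n): v for n, v in d["phase_rad"].items()},
            reference_name=d.get("reference_name", "reference"),
            reference_tau=d.get("reference_tau_ns", float("nan")),
        )


def phasor_transform(
    stack: DecayStack, harmonics: tuple[int, ...] = DEFAULT_HARMONICS
) -> PhasorField:
    """Uncalibrated per-pixel phasor transform of a decay stack.

    For each pixel and harmonic n, with bin-center timestamps t_k,
    ``g_n = sum_k c_k cos(n w t_k) / sum_k c_k`` and
    ``s_n = sum_k c_k sin(n w t_k) / sum_k c_k``; intensity is
    ``sum_k c_k``.  Zero-photon pixels are marked undefined (NaN).
    """
    acq = stack.acquisition
    harmonics = tuple(sorted(set(int(n) for n in harmonics)))
    for n in harmonics:
        if n < 1 or n > acq.max_harmonic:
            raise ValueError(
                f"harmonic {n} outside the usable range 1..{acq.max_harmonic} "
                f"for {acq.n_bins} time bins"
            )
    counts = np.asarray(stack.counts, dtype=float)
    intensity = counts.sum(axis=2)
    tk = acq.bin_centers
    g: dict[int, np.ndarray] = {}
    s: dict[int, np.ndarray] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(intensity != 0, intensity, np.nan)
        for n in harmonics:
            phase = n * acq.omega * tk
            g[n] = (counts @ np.cos(phase)) / denom
            s[n] = (counts @ np.sin(phase)) / denom
    # preserve exact integer intensity for integer input
    intensity = stack.counts.sum(axis=2)
    return PhasorField(
        g=g,
        s=s,
        intensity=intensity,
        harmonics=harmonics,
        acquisition=acq,
        calibrated=False,
    )


def analytic_phasor(tau: float, n: int, acq: AcquisitionModel) -> tuple[float, float]:
    """Continuous-model phasor of a single-exponential decay.

    ``g = 1 / (1 + (n w tau)^2)``, ``s = n w tau / (1 + (n w tau)^2)``;
    the point lies exactly on the universal circle g^2 + s^2 = g.
    ``tau = 0`` gives (1, 0); ``tau -> inf`` tends to (0, 0).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    z = continuous_harmonic(tau, n, acq.omega)
    return float(z.real), float(z.imag)


def pooled_phasor(stack: DecayStack, n: int) -> complex:
    """Phasor of all photons in a stack pooled into a single decay."""
    pooled = np.asarray(stack.counts, dtype=float).sum(axis=(0, 1))
    total = pooled.sum()
    if total <= 0:
        raise ValueError("stack contains no photons")
    tk = stack.acquisition.bin_centers
    phase = n * stack.acquisition.omega * tk
    return complex((pooled @ np.cos(phase)) / total, (pooled @ np.sin(phase)) / total)


def compute_calibration(
    reference: DecayStack,
    nominal_tau: float,
    harmonics: tuple[int, ...] = DEFAULT_HARMONICS,
    reference_name: str = "reference",
) -> CalibrationFactors:
    """Calibration factors from a reference stack of known lifetime.

    All reference photons are pooled into one decay; per harmonic the
    returned (m_n, phi_n) rotate/scale the measured pooled phasor onto
    ``analytic_phasor(nominal_tau, n)``.  The correction absorbs the
    instrument's phase shift and modulation loss (and any residual
    discretization bias) by construction.
    """
    modulation: dict[int, float] = {}
    phase: dict[int, float] = {}
    for n in harmonics:
        measured = pooled_phasor(reference, n)
        if abs(measured) < 1e-12:
            raise ValueError(
                f"reference unmodulated at harmonic {n}: pooled phasor at origin"
            )
        target = complex(*analytic_phasor(nominal_tau, n, reference.acquisition))
        c = target / measured
        modulation[n] = abs(c)
        phase[n] = float(np.angle(c))
    return CalibrationFactors(
        modulation=modulation,
        phase=phase,
        reference_name=reference_name,
        reference_tau=nominal_tau,
    )


def apply_calibration(field: PhasorField, cal: CalibrationFactors) -> PhasorField:
    """Rotate and scale each pixel's phasor by the calibration factors.

    Treats (g, s) as ``g + i*s`` and multiplies by ``m_n * exp(i*phi_n)``
    per harmonic; intensity is unchanged and the calibrated flag is set.
    """
    if field.calibrated:
        raise ValueError("field is already calibrated")
    missing = [n for n in field.harmonics if n not in cal.modulation]
    if missing:
        raise ValueError(f"calibration lacks factors for harmonics {missing}")
    g: dict[int, np.ndarray] = {}
    s: dict[int, np.ndarray] = {}
    for n in field.harmonics:
        z = field.complex(n) * (cal.modulation[n] * np.exp(1j * cal.phase[n]))
        g[n] = z.real
        s[n] = z.imag
    return PhasorField(
        g=g,
        s=s,
        intensity=field.intensity,
        harmonics=field.harmonics,
        acquisition=field.acquisition,
        calibrated=True,
    )


def phase_lifetime(field: PhasorField, n: int = 1) -> np.ndarray:
    """Per-pixel phase lifetime map (ns) from harmonic n.

    Projects each phasor onto the universal circle along its phase angle:
    ``tau_phase = tan(atan2(s, g)) / (n w)`` — the lifetime of the
    single-exponential decay with the same phase shift as the measured
    signal.  Pixels with ``g <= 0`` (beyond the quarter turn, where the
    projection has no physical intersection) or with an undefined phasor
    are returned as NaN rather than extrapolated.
    """
    if not field.calibrated:
        raise ValueError("phase lifetime requires a calibrated field")
    if n not in field.harmonics:
        raise ValueError(f"harmonic {n} not present in field")
    g, s = field.g[n], field.s[n]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.tan(np.arctan2(s, g)) / (n * field.acquisition.omega)
    tau = np.where((g > 0) & np.isfinite(tau), tau, np.nan)
    return tau
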