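"""Electrode stimulation charge-safety arithmetic.

For a voltage-controlled biphasic pulse the per-phase charge is
estimated from the scalar electrode impedance magnitude as
Q = (V / Z) * t_phase; dividing by the geometric electrode area gives
the charge density D.  The Shannon criterion summarises both on a log
scale,

    k = log10(D [uC/cm^2]) + log10(Q [uC]),

with tissue damage empirically associated with k above ~1.5.  The
reference pulse modelled here (0.3 V across a ~9 kOhm nanostructured
platinum electrode, 200 us phases, 30 um site diameter) yields
Q ≈ 6.67 nC and D ≈ 0.94 mC/cm^2, comfortably inside the safe region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

DEFAULT_K_LIMIT = 1.5


@dataclass(frozen=True)
class StimPulseSpec:
    """Biphasic pulse and electrode parameters (SI units)."""

    amplitude_v: float
    impedance_ohm: float
    phase_width_s: float
    electrode_diameter_m: float
    frequency_hz: float = 0.0
    n_pulses: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_v < 0:
            raise ValidationError("amplitude_v must be >= 0")
        for name in ("impedance_ohm", "phase_width_s", "electrode_diameter_m"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


@dataclass(frozen=True)
class SafetyReport:
    charge_nc: float
    density_mc_cm2: float
    k: float
    k_limit: float
    safe: bool

    def __str__(self) -> str:
        verdict = "SAFE" if self.safe else "UNSAFE"
        return (
            f"charge/phase = {self.charge_nc:.3g} nC; "
            f"charge density = {self.density_mc_cm2:.3g} mC/cm^2 "
            f"(Q in uC and D in uC/cm^2 enter the Shannon sum); "
            f"Shannon k = {self.k:.3g} vs limit {self.k_limit:g} -> {verdict}"
        )


def charge_per_phase(spec: StimPulseSpec) -> float:
    """Per-phase charge Q = (V / Z) * t_phase, in nC."""
    if spec.impedance_ohm <= 0:
        raise ValidationError("impedance must be positive")
    q_coulomb = spec.amplitude_v / spec.impedance_ohm * spec.phase_width_s
    return q_coulomb * 1e9


def charge_density(charge_nc: float, diameter_m: float) -> float:
    """Geometric charge density D = Q / (pi (d/2)^2), in mC/cm^2."""
    if diameter_m <= 0:
        raise ValidationError("diameter must be positive")
    area_cm2 = math.pi * (diameter_m / 2.0) ** 2 * 1e4  # m^2 -> cm^2
    return (charge_nc * 1e-6) / area_cm2  # nC -> mC


def shannon_k(charge_nc: float, density_mc_cm2: float) -> float:
    """Shannon criterion k = log10(D in uC/cm^2) + log10(Q in uC)."""
    if charge_nc <= 0 or density_mc_cm2 <= 0:
        raise ValidationError("charge and density must be positive")
    d_uc_cm2 = density_mc_cm2 * 1e3
    q_uc = charge_nc * 1e-3
    return math.log10(d_uc_cm2) + math.log10(q_uc)


def safety_report(spec: StimPulseSpec, k_limit: float = DEFAULT_K_LIMIT) -> SafetyReport:
    """Full safety verdict; SAFE iff k <= k_limit (boundary inclusive)."""
    q = charge_per_phase(spec)
    d = charge_density(q, spec.electrode_diameter_m)
    k = shannon_k(q, d)
    return SafetyReport(
        charge_nc=q, density_mc_cm2=d, k=k, k_limit=k_limit, safe=k <= k_limit
    )


def fold_reduction(before: float, after: float) -> float:
    """Fold change between two positive scalar quantities, e.g. the
    electrode impedance magnitude before and after surface
    modification."""
    if before <= 0 or after <= 0:
        raise ValidationError("fold change requires positive inputs")
    return before / after
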