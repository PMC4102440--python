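"""Whole-cell I-V ramp analysis: reversal potentials, GHK permeability
ratios, chord conductance and current density.

The experimental design analyzed here is the classic anion-substitution
protocol: a voltage ramp (-100 to +100 mV) is applied in whole-cell
configuration, first in a chloride bath and again after replacing most
extracellular chloride with a test anion X (e.g. bicarbonate).  The shift
in reversal potential between the two ramps encodes the bi-ionic
permeability ratio P_X/P_Cl through the Goldman-Hodgkin-Katz (GHK) voltage
equation; the slope of the I-V relation over a window just positive of the
reversal potential gives the outward chord conductance for each anion.

For monovalent anions the bi-ionic GHK relation used here is

    P_X/P_Cl = ([Cl]'_o * exp(-dE * F / RT) - [Cl]_o) / [X]_o

with dE = E_rev(X) - E_rev(Cl), [Cl]'_o the control bath chloride,
[Cl]_o the residual chloride of the substituted bath and [X]_o the test
anion concentration.  A channel less permeable to X than to Cl produces a
positive shift dE under these conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RampTrace",
    "BathSolution",
    "ReversalEstimate",
    "PermeabilityResult",
    "ConductanceResult",
    "find_reversal",
    "ghk_reversal_shift",
    "permeability_ratio_ghk",
    "chord_conductance",
    "chord_conductance_ratio",
    "normalize_current_density",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)
DEFAULT_TEMPERATURE_K = 298.15


@dataclass
class RampTrace:
    """A sampled voltage-ramp recording.

    voltage_mv / current_pa are parallel arrays over the ramp; voltages must
    be monotone.  ``junction_offset_mv`` is the liquid-junction potential to
    subtract from the command voltage before analysis.
    """

    voltage_mv: np.ndarray
    current_pa: np.ndarray
    capacitance_pf: float
    time_ms: np.ndarray | None = None
    junction_offset_mv: float = 0.0
    rmp_mv: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.voltage_mv.shape != self.current_pa.shape:
            raise ValueError("voltage and current must be the same length")
        if self.voltage_mv.size < 50:
            raise ValueError("a ramp trace needs at least 50 samples")
        dv = np.diff(self.voltage_mv)
        if not (np.all(dv >= 0) or np.all(dv <= 0)):
            raise ValueError("ramp voltages must be monotone")
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")

    @property
    def corrected_voltage_mv(self) -> np.ndarray:
        return self.voltage_mv - self.junction_offset_mv


@dataclass
class BathSolution:
    """Anion concentrations (mM) by species plus bath temperature (K)."""

    anions_mm: dict[str, float]
    temperature_k: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.anions_mm.values()):
            raise ValueError("concentrations must be non-negative")

    def __getitem__(self, species: str) -> float:
        return self.anions_mm.get(species, 0.0)


#: The control bath of the substitution protocol: 150 mM total chloride
#: (146 NMDG-Cl + 1 CaCl2 + 1 MgCl2).
CONTROL_BATH = BathSolution({"Cl": 150.0})
#: The high-bicarbonate bath: 140 mM NMDG-Cl replaced by choline-HCO3,
#: leaving 10 mM residual chloride.
BICARBONATE_BATH = BathSolution({"Cl": 10.0, "HCO3": 140.0})


@dataclass
class ReversalEstimate:
    e_rev_mv: float
    window_mv: tuple[float, float]
    method: str = "ramp-interpolation"
    multiple_crossings: bool = False


@dataclass
class PermeabilityResult:
    ratio: float
    delta_e_rev_mv: float
    temperature_k: float
    species: str


@dataclass
class ConductanceResult:
    g_x_ns: float
    g_cl_ns: float
    ratio: float
    window_mv: float


def find_reversal(
    trace: RampTrace, refine_window_mv: float = 30.0
) -> ReversalEstimate:
    """Reversal potential from the zero-current crossing of the ramp.

    The junction offset is applied first.  The crossing is located by
    linear interpolation on a lightly smoothed copy of the current (a short
    moving average, ~2% of the ramp), which suppresses spurious
    noise-induced crossings; the estimate is then refined by a
    least-squares line fitted to the raw samples within
    ``refine_window_mv`` of the crossing, whose root is E_rev.  For a
    noise-free trace both steps are exact.  If the smoothed ramp still
    crosses zero more than once, the crossing closest to 0 mV is used and
    the estimate is flagged.
    """
    v = trace.corrected_voltage_mv
    i = trace.current_pa
    width = max(1, i.size // 50)
    kernel = np.ones(width) / width
    smooth = np.convolve(i, kernel, mode="same")
    sign_change = np.flatnonzero(np.diff(np.signbit(smooth).astype(int)) != 0)
    crossings = []
    for k in sign_change:
        di = smooth[k + 1] - smooth[k]
        if di == 0.0:
            continue
        crossings.append(v[k] - smooth[k] * (v[k + 1] - v[k]) / di)
    crossings.extend(v[smooth == 0.0].tolist())
    if not crossings:
        raise ValueError("no reversal in ramp window")
    crossings = sorted(set(crossings), key=abs)
    multiple = len(crossings) > 1
    if multiple:
        warnings.warn(
            f"{len(crossings)} zero-current crossings; using the one nearest "
            "0 mV",
            UserWarning,
            stacklevel=2,
        )
    e_rev = float(crossings[0])
    local = np.abs(v - e_rev) <= refine_window_mv
    if np.count_nonzero(local) >= 5:
        slope, intercept = np.polyfit(v[local], i[local], 1)
        if slope != 0.0:
            root = -intercept / slope
            if abs(root - e_rev) <= refine_window_mv:
                e_rev = float(root)
    return ReversalEstimate(
        e_rev_mv=e_rev,
        window_mv=(float(v.min()), float(v.max())),
        multiple_crossings=multiple,
    )


def _rt_over_f_mv(temperature_k: float) -> float:
    return 1000.0 * GAS_CONSTANT * temperature_k / FARADAY


def ghk_reversal_shift(
    p_ratio: float,
    control: BathSolution,
    substituted: BathSolution,
    species: str = "HCO3",
) -> float:
    """Forward GHK map: reversal-potential shift (mV) for a permeability ratio.

    dE = -(RT/F) * ln(([Cl]_o + P_X/P_Cl * [X]_o) / [Cl]'_o).
    """
    if p_ratio <= 0:
        raise ValueError("permeability ratio must be positive")
    rt_f = _rt_over_f_mv(control.temperature_k)
    return -rt_f * np.log(
        (substituted["Cl"] + p_ratio * substituted[species]) / control["Cl"]
    )


def permeability_ratio_ghk(
    erev_cl_mv: float,
    erev_x_mv: float,
    control: BathSolution,
    substituted: BathSolution,
    species: str = "HCO3",
) -> PermeabilityResult:
    """Invert the GHK voltage equation for the bi-ionic permeability ratio."""
    if substituted[species] <= 0:
        raise ValueError(f"substituted solution contains no {species}")
    if control.temperature_k != substituted.temperature_k:
        raise ValueError("solution temperatures must match")
    delta = erev_x_mv - erev_cl_mv
    rt_f = _rt_over_f_mv(control.temperature_k)
    ratio = (
        control["Cl"] * np.exp(-delta / rt_f) - substituted["Cl"]
    ) / substituted[species]
    if ratio < 0:
        raise ValueError(
            "reversal shift inconsistent with solutions: negative ratio"
        )
    return PermeabilityResult(
        ratio=float(ratio),
        delta_e_rev_mv=float(delta),
        temperature_k=control.temperature_k,
        species=species,
    )


def chord_conductance(trace: RampTrace, window_mv: float = 25.0) -> float:
    """Outward chord conductance (nS): least-squares I-V slope over
    [E_rev, E_rev + window]."""
    est = find_reversal(trace)
    v = trace.corrected_voltage_mv
    mask = (v >= est.e_rev_mv) & (v <= est.e_rev_mv + window_mv)
    if np.count_nonzero(mask) < 5:
        raise ValueError(
            f"fewer than 5 samples in [{est.e_rev_mv:.1f}, "
            f"{est.e_rev_mv + window_mv:.1f}] mV"
        )
    slope = np.polyfit(v[mask], trace.current_pa[mask], 1)[0]
    return float(slope)  # pA/mV == nS


def chord_conductance_ratio(
    trace_x: RampTrace, trace_cl: RampTrace, window_mv: float = 25.0
) -> ConductanceResult:
    """G_X / G_Cl from the outward chord conductances of the two ramps."""
    g_x = chord_conductance(trace_x, window_mv)
    g_cl = chord_conductance(trace_cl, window_mv)
    return ConductanceResult(
        g_x_ns=g_x, g_cl_ns=g_cl, ratio=g_x / g_cl, window_mv=window_mv
    )


def normalize_current_density(trace: RampTrace) -> RampTrace:
    """Divide every current by the cell capacitance (result in pA/pF).

    Current density removes cell-size dependence so recordings from
    different cells are comparable.  The returned trace reuses the voltage
    axis; its ``capacitance_pf`` is set to 1 so repeated normalization is
    idempotent.
    """
    out = RampTrace(
        voltage_mv=trace.voltage_mv.copy(),
        current_pa=trace.current_pa / trace.capacitance_pf,
        capacitance_pf=1.0,
        time_ms=None if trace.time_ms is None else trace.time_ms.copy(),
        junction_offset_mv=trace.junction_offset_mv,
        rmp_mv=trace.rmp_mv,
        label=f"{trace.label} (pA/pF)" if trace.label else "(pA/pF)",
    )
    return out
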