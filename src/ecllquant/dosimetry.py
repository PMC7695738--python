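"""Electrochemical dosimetry back-calculations for ECLL.

During electrochemical lipolysis (ECLL), charge passed through needle
electrodes electrolyses injected saline; the acid/base fronts lyse adipocyte
membranes and saponify triglycerides (TGs). Three inversions quantify the
dose–response from bulk assays:

* **Charge and water budget** — the trapezoidal integral of the monitored
  current gives total charge Q; Faraday's law converts Q to the mass of water
  consumed by electrolysis (2 H₂O → 2 H₂ + O₂ consumes one water molecule per
  two electrons, i.e. 0.5 H₂O/e⁻ net).

* **Membrane lysis from potassium release.** Cytoplasmic [K⁺] (~130 mM,
  determined from fully homogenized/sonicated tissue) dwarfs the
  extracellular level, so K⁺ released per mL of tissue divided by 130 mM is
  the volume fraction of lysed tissue. With the damage modeled as uniform
  cylinders around each of n electrodes inserted to depth d, the per-electrode
  treated volume V gives a damage radius r = sqrt(V / (π d)).

* **TG saponification from free glycerol.** Glycerol is the direct product of
  base-driven TG ester hydrolysis. The measured glycerol concentration of a
  treated sample, divided by the positive-control concentration (total
  saponifiable glycerol) scaled by the fraction of the sample volume actually
  treated, is the fraction of liberated TGs that were hydrolyzed.

Instrument readings enter through ordinary least-squares calibration curves
(e.g. ICP-OES potassium standards at 0.50 / 2.0 / 10 ppm; glycerol standards
from known dilutions) and a 1:10 dilution correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

FARADAY_C_PER_MOL = 96485.0
WATER_G_PER_MOL = 18.015

#: Geometry and reference constants of the potentiostat assays.
DEFAULT_N_ELECTRODES = 3
DEFAULT_ELECTRODE_DEPTH_MM = 12.0
DEFAULT_ELECTRODE_SPACING_MM = 3.0
DEFAULT_INTRACELLULAR_K_MM = 130.0
DEFAULT_DILUTION_FACTOR = 10.0
DEFAULT_SAMPLE_VOLUME_UL = 1000.0  # 1 cm³ glycerol-assay samples
DEFAULT_TISSUE_VOLUME_UL = 3000.0  # 3 cm³ potassium-assay samples


@dataclass
class CurrentTrace:
    times_s: np.ndarray
    current_A: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.current_A = np.asarray(self.current_A, dtype=float)
        if self.times_s.size != self.current_A.size or self.times_s.size < 2:
            raise ValueError("trace needs >= 2 matching (time, current) points")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.current_A < 0):
            raise ValueError("currents must be nonnegative")


@dataclass
class DoseRecord:
    voltage_V: float
    duration_s: float
    charge_C: float
    n_electrodes: int = DEFAULT_N_ELECTRODES
    electrode_depth_mm: float = DEFAULT_ELECTRODE_DEPTH_MM
    electrode_spacing_mm: float = DEFAULT_ELECTRODE_SPACING_MM
    sample_id: str = ""


@dataclass
class CalibrationCurve:
    """OLS fit reading = slope × concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    standards: list[tuple[float, float]] = field(default_factory=list)

    def predict_reading(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def invert(self, reading: float) -> float:
        """Concentration producing a given reading."""
        if self.slope == 0:
            raise ZeroDivisionError("flat calibration curve cannot be inverted")
        return (reading - self.intercept) / self.slope


@dataclass
class KReleaseMeasurement:
    """Potassium released per mL tissue, plus assay bookkeeping."""

    conc_released_mM: float
    intracellular_mM: float = DEFAULT_INTRACELLULAR_K_MM
    tissue_volume_uL: float = DEFAULT_TISSUE_VOLUME_UL
    n_electrodes: int = DEFAULT_N_ELECTRODES
    dilution_factor: float = DEFAULT_DILUTION_FACTOR

    def __post_init__(self) -> None:
        if self.conc_released_mM < 0:
            raise ValueError("released concentration must be nonnegative")
        if not self.intracellular_mM > 0:
            raise ValueError("intracellular concentration must be positive")
        if self.conc_released_mM > self.intracellular_mM:
            warnings.warn(
                "released K+ exceeds intracellular reference; fraction will exceed 1",
                stacklevel=3,
            )


@dataclass
class LysisEstimate:
    fraction_lysed: float
    treated_volume_total_uL: float
    treated_volume_per_electrode_uL: float
    cylinder_radius_mm: float


@dataclass
class GlycerolMeasurement:
    conc_treated_mgL: float
    conc_untreated_mgL: float
    conc_positive_mgL: float
    sample_volume_uL: float = DEFAULT_SAMPLE_VOLUME_UL

    def __post_init__(self) -> None:
        if min(self.conc_treated_mgL, self.conc_untreated_mgL, self.conc_positive_mgL) < 0:
            raise ValueError("concentrations must be nonnegative")
        if not self.conc_positive_mgL > 0:
            raise ValueError("positive-control concentration must be positive")
        if not self.sample_volume_uL > 0:
            raise ValueError("sample volume must be positive")


@dataclass
class SaponificationEstimate:
    fraction_hydrolyzed: float
    exceeds_unity: bool = False
    background_subtracted: bool = False


def integrate_charge(trace: CurrentTrace) -> float:
    """Total charge in coulombs: trapezoidal integral of current over time."""
    return float(np.trapezoid(trace.current_A, trace.times_s))


def water_consumed_ug(charge_C: float, waters_per_electron: float = 0.5) -> float:
    """Mass of water consumed by electrolysis for a given charge, in µg.

    The net overall reaction 2 H₂O → 2 H₂ + O₂ consumes two waters per four
    electrons (waters_per_electron = 0.5). Pass 1.0 for the cathode-only
    half-reaction bookkeeping (2 H₂O + 2 e⁻ → H₂ + 2 OH⁻).
    """
    if charge_C < 0:
        raise ValueError("charge must be nonnegative")
    mol_water = charge_C / FARADAY_C_PER_MOL * waters_per_electron
    return mol_water * WATER_G_PER_MOL * 1e6


def charge_for_water_ug(mass_ug: float, waters_per_electron: float = 0.5) -> float:
    """Inverse of :func:`water_consumed_ug`: charge that consumes ``mass_ug``."""
    if mass_ug < 0:
        raise ValueError("mass must be nonnegative")
    return mass_ug * 1e-6 / WATER_G_PER_MOL / waters_per_electron * FARADAY_C_PER_MOL


def fit_calibration(standards: list[tuple[float, float]]) -> CalibrationCurve:
    """OLS line through (concentration, instrument reading) standards."""
    concs = np.array([s[0] for s in standards], dtype=float)
    readings = np.array([s[1] for s in standards], dtype=float)
    if concs.size < 2 or np.unique(concs).size < 2:
        raise ValueError("need >= 2 distinct standard concentrations")
    res = sstats.linregress(concs, readings)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standards=list(standards),
    )


def correct_dilution(conc_measured: float, dilution_factor: float) -> float:
    """Undo a sample dilution (e.g. the 1:10 nitric-acid dilution)."""
    if not dilution_factor > 0:
        raise ValueError("dilution factor must be positive")
    return conc_measured * dilution_factor


def lysed_fraction(meas: KReleaseMeasurement) -> float:
    """Fraction of tissue volume lysed: released [K⁺] over intracellular [K⁺]."""
    return meas.conc_released_mM / meas.intracellular_mM


def treated_volume(meas: KReleaseMeasurement) -> LysisEstimate:
    """Total and per-electrode treated volumes and the implied cylinder radius."""
    if meas.n_electrodes < 1:
        raise ValueError("n_electrodes must be >= 1")
    frac = lysed_fraction(meas)
    total = frac * meas.tissue_volume_uL
    per_electrode = total / meas.n_electrodes
    radius = cylinder_radius(per_electrode, DEFAULT_ELECTRODE_DEPTH_MM) if per_electrode > 0 else 0.0
    return LysisEstimate(
        fraction_lysed=frac,
        treated_volume_total_uL=total,
        treated_volume_per_electrode_uL=per_electrode,
        cylinder_radius_mm=radius,
    )


def cylinder_radius(per_electrode_volume_uL: float, depth_mm: float) -> float:
    """Radius of a uniform damage cylinder of volume V (µL = mm³) and height d."""
    if not (per_electrode_volume_uL > 0 and depth_mm > 0):
        raise ValueError("volume and depth must be positive")
    return float(np.sqrt(per_electrode_volume_uL / (np.pi * depth_mm)))


def saponified_fraction(gm: GlycerolMeasurement, per_electrode_volume_uL: float,
                        subtract_background: bool = False) -> SaponificationEstimate:
    """Fraction of liberated TGs hydrolyzed, from free-glycerol concentrations.

    The positive control (homogenized, KOH-saponified) gives the glycerol
    yield of complete hydrolysis of the whole sample; scaling it by the
    treated volume fraction gives the yield if every liberated TG were
    hydrolyzed. The headline number does not subtract the untreated-tissue
    background; set ``subtract_background`` to remove it from both numerator
    and denominator.
    """
    volume_fraction = per_electrode_volume_uL / gm.sample_volume_uL
    if volume_fraction <= 0:
        raise ValueError("treated volume fraction must be positive")
    if subtract_background:
        num = gm.conc_treated_mgL - gm.conc_untreated_mgL
        den = (gm.conc_positive_mgL - gm.conc_untreated_mgL) * volume_fraction
    else:
        num = gm.conc_treated_mgL
        den = gm.conc_positive_mgL * volume_fraction
    frac = num / den
    return SaponificationEstimate(
        fraction_hydrolyzed=float(frac),
        exceeds_unity=frac > 1.0,
        background_subtracted=subtract_background,
    )


def dose_report(records: list[DoseRecord],
                k_release: dict[str, KReleaseMeasurement] | None = None,
                glycerol: dict[str, GlycerolMeasurement] | None = None,
                waters_per_electron: float = 0.5) -> pd.DataFrame:
    """One tidy row per sample combining dose and assay-derived estimates.

    ``k_release`` / ``glycerol`` map sample ids to measurements; missing
    assays leave NaN columns. Rows are sorted by sample id for deterministic
    output.
    """
    k_release = k_release or {}
    glycerol = glycerol or {}
    rows = []
    for rec in records:
        row: dict = {
            "sample_id": rec.sample_id,
            "voltage_V": rec.voltage_V,
            "duration_s": rec.duration_s,
            "charge_C": rec.charge_C,
            "water_consumed_ug": water_consumed_ug(rec.charge_C, waters_per_electron),
            "fraction_lysed": np.nan,
            "volume_per_electrode_uL": np.nan,
            "cylinder_radius_mm": np.nan,
            "fraction_tg_hydrolyzed": np.nan,
        }
        km = k_release.get(rec.sample_id)
        if km is not None:
            est = treated_volume(km)
            row["fraction_lysed"] = est.fraction_lysed
            row["volume_per_electrode_uL"] = est.treated_volume_per_electrode_uL
            row["cylinder_radius_mm"] = (
                cylinder_radius(est.treated_volume_per_electrode_uL, rec.electrode_depth_mm)
                if est.treated_volume_per_electrode_uL > 0 else 0.0
            )
            gmeas = glycerol.get(rec.sample_id)
            if gmeas is not None:
                row["fraction_tg_hydrolyzed"] = saponified_fraction(
                    gmeas, est.treated_volume_per_electrode_uL
                ).fraction_hydrolyzed
        rows.append(row)
    columns = [
        "sample_id", "voltage_V", "duration_s", "charge_C", "water_consumed_ug",
        "fraction_lysed", "volume_per_electrode_uL", "cylinder_radius_mm",
        "fraction_tg_hydrolyzed",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("sample_id", kind="stable").reset_index(drop=True)
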