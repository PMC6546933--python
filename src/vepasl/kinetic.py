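"""Single-compartment ASL kinetic model and M0 calibration.

The ASL difference signal from one feeding artery follows the standard
continuous-labeling solution of the general kinetic model: labeled blood
arrives at the voxel after the arterial transit time (ATT), accumulates for
the labeling duration while decaying with the blood T1, and washes out /
relaxes with an apparent tissue T1 afterwards.  Flow enters in
ml/100 g/min and is converted to 1/s by dividing by 6000.

Absolute quantification needs the equilibrium magnetization of arterial
blood (M0b), obtained from the CSF signal in a calibration image via T2
corrections and the blood/water spin-density ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class KineticConstants:
    """Relaxation and calibration constants (conventional 3 T values)."""

    t1_blood_s: float = 1.65
    t1_tissue_apparent_s: float = 1.6
    labeling_efficiency: float = 0.85
    blood_water_density_ratio: float = 0.87
    t2_csf_s: float = 0.75
    t2_blood_s: float = 0.15
    echo_time_s: float = 0.014

    def __post_init__(self) -> None:
        for name in (
            "t1_blood_s",
            "t1_tissue_apparent_s",
            "blood_water_density_ratio",
            "t2_csf_s",
            "t2_blood_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling efficiency must be in (0, 1]")
        if self.echo_time_s < 0:
            raise ValueError("echo time must be non-negative")


@dataclass(frozen=True)
class ArteryComponentParams:
    """Per-voxel parameters of one arterial component.

    Fields may be scalars or broadcastable arrays: cbf in ml/100 g/min,
    att in seconds, m0_blood in image signal units.
    """

    cbf: float | np.ndarray
    att: float | np.ndarray
    m0_blood: float | np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.cbf) < 0):
            raise ValueError("cbf must be non-negative")
        if np.any(np.asarray(self.att) < 0):
            raise ValueError("att must be non-negative")
        if np.any(np.asarray(self.m0_blood) <= 0):
            raise ValueError("m0_blood must be positive")


def delta_m(
    t: float | np.ndarray,
    params: ArteryComponentParams,
    tau: float,
    constants: KineticConstants,
) -> np.ndarray:
    """ASL difference signal of one arterial component at time ``t``.

    ``t`` is measured from the start of the labeling pulse train; the readout
    of a given slice happens at t = tau + PLD(slice).  Returns 0 before the
    labeled bolus arrives, an inflow ramp during delivery, and exponential
    decay after the trailing edge has arrived.  Continuous in t.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    f = np.asarray(params.cbf, dtype=float) / 6000.0  # 1/s
    att = np.asarray(params.att, dtype=float)
    t1p = constants.t1_tissue_apparent_s
    prefactor = (
        2.0
        * np.asarray(params.m0_blood, dtype=float)
        * constants.labeling_efficiency
        * f
        * t1p
        * np.exp(-att / constants.t1_blood_s)
    )
    t, att, prefactor = np.broadcast_arrays(t, att, prefactor)
    during = prefactor * -np.expm1(-(t - att) / t1p)
    after = prefactor * -np.expm1(-tau / t1p) * np.exp(-(t - att - tau) / t1p)
    out = np.where(t < att, 0.0, np.where(t < att + tau, during, after))
    return out if out.ndim else float(out)


def delta_m_unit(
    t: np.ndarray,
    att: np.ndarray,
    m0_blood: float,
    tau: float,
    constants: KineticConstants,
) -> np.ndarray:
    """Difference signal per unit CBF (ml/100 g/min); linear-in-flow kernel."""
    params = ArteryComponentParams(cbf=1.0, att=att, m0_blood=m0_blood)
    return delta_m(t, params, tau, constants)


def calibrate_m0_blood(csf_signal: float, constants: KineticConstants) -> float:
    """Convert the equilibrium CSF signal into equilibrium blood magnetization.

    Corrects for the T2 difference between CSF and blood at the echo time and
    scales by the blood/water spin-density ratio.
    """
    if csf_signal <= 0:
        raise ValueError("CSF calibration signal must be positive")
    te = constants.echo_time_s
    t2_corr = np.exp(te * (1.0 / constants.t2_csf_s - 1.0 / constants.t2_blood_s))
    return float(csf_signal * t2_corr * constants.blood_water_density_ratio)


def mean_csf_signal(
    calibration_volume: np.ndarray,
    ventricle_mask: np.ndarray,
    trim_fraction: float = 0.1,
) -> float:
    """Robust mean of calibration voxels inside the ventricle mask.

    A two-sided trimmed mean (10% per tail by default) guards against
    partial-volume voxels at the mask edge.
    """
    calibration_volume = np.asarray(calibration_volume, dtype=float)
    ventricle_mask = np.asarray(ventricle_mask, dtype=bool)
    if calibration_volume.shape != ventricle_mask.shape:
        raise ValueError("calibration volume and ventricle mask shapes differ")
    values = calibration_volume[ventricle_mask]
    if values.size == 0:
        raise ValueError("ventricle mask is empty")
    return float(stats.trim_mean(values, trim_fraction))
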