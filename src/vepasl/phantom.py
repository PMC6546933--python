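"""Digital phantom for vessel-encoded multi-PLD ASL of acute stroke.

Generates aligned, ground-truth-known inputs mimicking the study setting:
four-artery vascular territories on an ellipsoidal brain, a hypoperfused MCA
lesion with optional collateral (Indirect) supply, spatially varying arterial
transit times with a peri-lesional delay, a matched ADC map with a
low-diffusivity ischemic core, a stochastically generated final-infarct mask
driven by total CBF, a gray-matter partial-volume map, and the vessel-encoded
ASL time series itself with additive Gaussian noise.

The contralateral hemisphere is built mirror-symmetric about the mid-sagittal
plane so that mirrored-ROI code is exactly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .kinetic import ArteryComponentParams, KineticConstants, delta_m
from .protocol import AcquisitionProtocol, EncodingMatrix, slice_pld, volume_schedule

SCENARIOS = ("normal", "no-collateral", "collateral", "ica-occlusion")


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of one synthetic patient scan."""

    shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size_mm: tuple[float, float, float] = (3.4, 3.4, 5.0)
    scenario: str = "collateral"
    seed: int = 0

    # baseline physiology
    gm_cbf: float = 50.0          # ml/100 g/min
    wm_cbf: float = 20.0
    ica_att_s: float = 1.2        # carotid-territory transit time at brain center
    va_att_s: float = 1.4         # posterior circulation arrives later
    att_radial_gradient_s: float = 0.2   # extra delay towards the cortical surface
    territory_mix_width_mm: float = 10.0  # watershed softness between territories

    # lesion model (ignored for the "normal" scenario)
    lesion_center_mm: tuple[float, float, float] = (-55.0, 10.0, 0.0)
    lesion_radius_mm: float = 30.0
    direct_reduction: float = 0.25        # multiplier on the ipsilateral-ICA supply
    collateral_cbf_max: float = 80.0      # peak collateral CBF, ml/100 g/min
    collateral_onset: float = 0.35        # ramp start as a fraction of lesion extent
    collateral_full: float = 0.75         # ramp saturation fraction
    peri_lesion_att_delay_s: float = 0.3
    peri_lesion_margin_mm: float = 20.0

    # core / infarct generation
    core_cbf_threshold: float = 15.0      # total CBF below which tissue is core
    adc_normal: float = 800e-6            # mm^2/s
    adc_core: float = 500e-6
    adc_csf: float = 3000e-6
    survival_slope: float = 0.15          # logistic slope per ml/100 g/min
    survival_midpoint: float = 20.0       # total CBF at 50% survival

    # signal model
    m0_blood: float = 1000.0
    static_scale: float = 100.0           # static tissue as multiple of peak dM
    target_snr: float = 5.0               # SNR of the non-selective difference

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid shape too small")
        if self.gm_cbf < 0 or self.wm_cbf < 0 or self.collateral_cbf_max < 0:
            raise ValueError("CBF values must be non-negative")
        fov = [n * v / 2 for n, v in zip(self.shape, self.voxel_size_mm)]
        if any(abs(c) > f for c, f in zip(self.lesion_center_mm, fov)):
            raise ValueError("lesion center lies outside the image grid")


@dataclass
class PhantomTruth:
    """Ground truth maps underlying a synthetic scan."""

    artery_ids: tuple[str, ...]
    cbf: np.ndarray            # (n_arteries, nx, ny, nz), ml/100 g/min
    att: np.ndarray            # (n_arteries, nx, ny, nz), s
    core_mask: np.ndarray      # bool
    infarct_mask: np.ndarray   # bool
    gm_pv: np.ndarray          # [0, 1]
    adc: np.ndarray            # mm^2/s
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    midline_index: float       # mid-sagittal plane in voxel (i) coordinates
    m0_blood: float
    spec: PhantomSpec

    def total_cbf(self) -> np.ndarray:
        return self.cbf.sum(axis=0)

    def n_supplying(self, threshold_fraction: float = 0.05) -> np.ndarray:
        """Number of arteries contributing more than a fraction of total CBF."""
        total = self.total_cbf()
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(total > 0, self.cbf / total, 0.0)
        return (share > threshold_fraction).sum(axis=0)


def _grid_coords(shape, voxel_size):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def generate_truth(spec: PhantomSpec) -> PhantomTruth:
    """Build the ground-truth per-artery CBF/ATT maps and companion volumes."""
    x, y, z = _grid_coords(spec.shape, spec.voxel_size_mm)
    # brain ellipsoid scaled to the field of view (83% / 92% / 92% of the
    # half-FOV; 90 x 100 x 55 mm on the default 64x64x24 grid)
    half_fov = [n * v_ / 2.0 for n, v_ in zip(spec.shape, spec.voxel_size_mm)]
    semi = (0.83 * half_fov[0], 0.92 * half_fov[1], 0.92 * half_fov[2])
    rho = np.sqrt((x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2)
    brain = rho <= 1.0
    ventricles = rho <= 0.15

    # gray matter: thick cortical/deep-GM compartment; central white matter
    gm_pv = np.where(rho >= 0.4, 0.85, 0.25) * brain
    gm_pv[ventricles] = 0.0
    gm = gm_pv > 0.5

    # soft territory weights: anterior (ICAs) vs posterior (VAs), right vs left;
    # the posterior watershed sits at 37% of the half-FOV behind center
    # (-40 mm on the default grid)
    w = spec.territory_mix_width_mm
    y_post = -0.37 * half_fov[1]
    w_post = expit((y_post - y) / w)
    w_left = expit(x / w)
    artery_ids = ("RICA", "LICA", "RVA", "LVA")
    weights = np.stack(
        [
            (1 - w_post) * (1 - w_left),
            (1 - w_post) * w_left,
            w_post * (1 - w_left),
            w_post * w_left,
        ]
    )

    total_baseline = np.where(gm, spec.gm_cbf, spec.wm_cbf) * brain
    total_baseline[ventricles] = 0.0
    cbf = weights * total_baseline[None]

    # transit times: per-artery baseline plus a radial (distal) gradient
    base_att = np.array([spec.ica_att_s, spec.ica_att_s, spec.va_att_s, spec.va_att_s])
    att = base_att[:, None, None, None] + spec.att_radial_gradient_s * rho[None]

    lc = spec.lesion_center_mm
    r_lesion = np.sqrt((x - lc[0]) ** 2 + (y - lc[1]) ** 2 + (z - lc[2]) ** 2)
    lesion = (r_lesion <= spec.lesion_radius_mm) & brain
    at_risk = (r_lesion <= spec.lesion_radius_mm + spec.peri_lesion_margin_mm) & brain

    if spec.scenario != "normal":
        # collateral supply ramps up across the lesion (zero near the core,
        # saturating towards the lesion margin), with a smooth deterministic
        # in-plane modulation so intermediate levels are well represented
        frac = (y - (lc[1] - spec.lesion_radius_mm)) / (2 * spec.lesion_radius_mm)
        ramp = np.clip(
            (frac - spec.collateral_onset) / (spec.collateral_full - spec.collateral_onset),
            0.0,
            1.0,
        )
        modulation = (
            0.25 * spec.collateral_cbf_max
            * np.sin(2 * np.pi * x / 70.0) * np.sin(2 * np.pi * z / 50.0)
        )
        collateral = np.where(
            frac > spec.collateral_onset,
            np.clip(spec.collateral_cbf_max * ramp + modulation, 0.0, spec.collateral_cbf_max),
            0.0,
        )
        collateral *= lesion * (total_baseline > 0)

        if spec.scenario == "ica-occlusion":
            # occluded RICA supplies nothing anywhere; the LICA takes over its
            # territory (cross-filling), reduced inside the lesion, while the
            # posterior circulation provides the collateral ramp
            takeover = cbf[0] * 0.8
            takeover[lesion] *= spec.direct_reduction
            cbf[1] += takeover
            cbf[0] = 0.0
            cbf[2][lesion] += collateral[lesion]
        else:
            cbf[0][lesion] *= spec.direct_reduction
            if spec.scenario == "collateral":
                cbf[1][lesion] += collateral[lesion]

        att += spec.peri_lesion_att_delay_s * at_risk[None]

    total = cbf.sum(axis=0)
    core = lesion & (total < spec.core_cbf_threshold) & (total_baseline > 0)

    adc = np.full(spec.shape, spec.adc_normal)
    adc[ventricles] = spec.adc_csf
    adc[core] = spec.adc_core

    rng = np.random.default_rng(spec.seed)
    if spec.scenario == "normal":
        infarct = core.copy()
    else:
        survive_p = expit(spec.survival_slope * (total - spec.survival_midpoint))
        draws = rng.random(spec.shape)
        infarct = (at_risk & (total_baseline > 0) & (draws > survive_p)) | core

    return PhantomTruth(
        artery_ids=artery_ids,
        cbf=cbf,
        att=att,
        core_mask=core,
        infarct_mask=infarct,
        gm_pv=gm_pv,
        adc=adc,
        brain_mask=brain,
        ventricle_mask=ventricles,
        voxel_size_mm=spec.voxel_size_mm,
        midline_index=(spec.shape[0] - 1) / 2.0,
        m0_blood=spec.m0_blood,
        spec=spec,
    )


def _delta_m_stack(
    truth: PhantomTruth,
    protocol: AcquisitionProtocol,
    constants: KineticConstants,
) -> np.ndarray:
    """Per-artery difference signals at every (PLD, slice): (A, P, nx, ny, nz)."""
    n_art = len(truth.artery_ids)
    out = np.zeros((n_art, protocol.n_plds, *truth.cbf.shape[1:]))
    tau = protocol.label_duration_s
    for a in range(n_art):
        for p in range(protocol.n_plds):
            for k in range(truth.cbf.shape[3]):
                t = tau + slice_pld(protocol, p, k)
                cbf_sl = truth.cbf[a, :, :, k]
                mask = cbf_sl > 0
                if not mask.any():
                    continue
                params = ArteryComponentParams(
                    cbf=cbf_sl[mask], att=truth.att[a, :, :, k][mask],
                    m0_blood=truth.m0_blood,
                )
                out[a, p, :, :, k][mask] = delta_m(t, params, tau, constants)
    return out


def noise_sd_for_snr(
    truth: PhantomTruth,
    protocol: AcquisitionProtocol,
    constants: KineticConstants,
    snr: float,
) -> float:
    """Per-volume noise SD giving the requested temporal SNR on the
    repeat-averaged non-selective (control minus label) difference signal
    in normally perfused gray matter."""
    dm = _delta_m_stack(truth, protocol, constants)
    diff = 2.0 * dm.sum(axis=0)          # control - label contrast
    peak = diff.max(axis=0)              # best PLD per voxel
    gm = (truth.gm_pv > 0.5) & (truth.total_cbf() >= 0.9 * truth.spec.gm_cbf)
    if not gm.any():
        raise ValueError("phantom has no normally perfused gray matter")
    ref = float(np.median(peak[gm]))
    # the difference of two repeat-averaged volumes has SD equal to the
    # per-volume SD: sd/sqrt(2) per average, times sqrt(2) for the difference
    return ref / snr


def synthesize_series(
    truth: PhantomTruth,
    protocol: AcquisitionProtocol,
    matrix: EncodingMatrix,
    constants: KineticConstants,
    noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Simulate the 4D vessel-encoded series (nx, ny, nz, n_volumes).

    Each volume is static tissue minus the encoding-weighted sum of arterial
    difference signals, S_e = static - sum_a (1 - w_ea) * dM_a(t_slice), plus
    white Gaussian noise.  With this convention the all-control minus
    all-label volume equals 2 * sum_a dM_a.  Returns the data plus a sidecar
    dict describing protocol, encoding matrix and volume ordering.
    """
    if matrix.artery_ids != truth.artery_ids:
        raise ValueError("encoding matrix arteries do not match phantom arteries")
    if noise_sd is None:
        noise_sd = noise_sd_for_snr(truth, protocol, constants, truth.spec.target_snr)

    dm = _delta_m_stack(truth, protocol, constants)  # (A, P, nx, ny, nz)
    static_value = truth.spec.static_scale * float(dm.max()) if dm.max() > 0 else 1.0
    static = static_value * truth.brain_mask.astype(float)

    schedule = volume_schedule(protocol)
    shape = truth.cbf.shape[1:]
    data = np.empty((*shape, len(schedule)))
    rng = np.random.default_rng(seed)
    one_minus_w = 1.0 - matrix.weights  # (E, A)
    for vol in schedule:
        p, e = vol["pld_index"], vol["cycle_index"]
        signal = static - np.tensordot(one_minus_w[e], dm[:, p], axes=(0, 0))
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=shape)
        data[..., vol["index"]] = signal

    sidecar = {
        "protocol": {
            "label_duration_s": protocol.label_duration_s,
            "nominal_plds_s": list(protocol.nominal_plds_s),
            "tr_s": protocol.tr_s,
            "n_slices": protocol.n_slices,
            "readout_duration_ms": protocol.readout_duration_ms,
            "n_repeats": protocol.n_repeats,
            "encoding_cycle_names": list(protocol.encoding_cycle_names),
        },
        "artery_ids": list(truth.artery_ids),
        "encoding_matrix": matrix.weights.tolist(),
        "volumes": schedule,
        "voxel_size_mm": list(truth.voxel_size_mm),
        "noise_sd": float(noise_sd),
        "seed": int(seed),
        "scenario": truth.spec.scenario,
    }
    return data, sidecar


def make_calibration_volume(
    truth: PhantomTruth,
    constants: KineticConstants,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Calibration image: equilibrium CSF signal in the ventricles such that
    the CSF-based calibration chain recovers the phantom's true M0 of blood."""
    t2_corr = np.exp(
        constants.echo_time_s * (1.0 / constants.t2_csf_s - 1.0 / constants.t2_blood_s)
    )
    m0_csf = truth.m0_blood / (t2_corr * constants.blood_water_density_ratio)
    vol = 0.6 * m0_csf * truth.brain_mask.astype(float)
    vol[truth.ventricle_mask] = m0_csf
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, size=vol.shape)
    return vol
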