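"""End-to-end orchestration: phantom -> decode -> fit -> maps/ROIs -> stats.

Every stage reads its inputs from and writes its outputs to the working
directory, so stages can be re-run individually from the CLI; outputs are
deterministic under a fixed seed.  Each run writes a provenance record
(config hash, package version) alongside the results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decode import decode_series
from .fit import FitSettings, fit_maps
from .io import load_yaml, read_nifti, save_yaml, write_nifti
from .kinetic import KineticConstants, calibrate_m0_blood, mean_csf_signal
from .maps import build_roi_set, core_from_adc, direct_indirect, mirror_artery
from .phantom import PhantomSpec, generate_truth, make_calibration_volume, synthesize_series
from .protocol import (
    AcquisitionProtocol,
    ArteryGeometry,
    EncodingMatrix,
    build_encoding_matrix,
)
from .stats import (
    binomial_split_test,
    indirect_fraction,
    mean_weighted_att,
    survival_table,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "decode", "fit", "maps", "rois", "stats")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs: inputs, protocol and thresholds."""

    output_dir: str = "vepasl_out"
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    geometry: ArteryGeometry = field(default_factory=ArteryGeometry)
    constants: KineticConstants = field(default_factory=KineticConstants)
    fit_settings: FitSettings = field(default_factory=FitSettings)
    ideal_encoding: bool = False
    ipsilateral: str = "auto"       # artery id, or "auto" from the lesion side
    adc_threshold: float = 620e-6   # mm^2/s
    direct_cutoff: float = 25.0     # ml/100 g/min
    surviving_radius_mm: float = 10.0
    peri_core_radius_mm: float = 20.0
    gm_threshold: float = 0.5
    bin_width: float = 10.0
    max_bin: float = 80.0
    split: float = 25.0
    survival_axis: str = "indirect"     # bin survival by "indirect" or "direct" CBF
    apply_direct_cutoff: bool = True    # exclude voxels with direct CBF > cutoff

    def __post_init__(self) -> None:
        for name in ("adc_threshold", "direct_cutoff", "surviving_radius_mm",
                     "peri_core_radius_mm", "gm_threshold", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d))  # plain lists/scalars only

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("phantom", PhantomSpec),
            ("protocol", AcquisitionProtocol),
            ("geometry", ArteryGeometry),
            ("constants", KineticConstants),
            ("fit_settings", FitSettings),
        ):
            if key in d and isinstance(d[key], dict):
                sub = d[key]
                for f in dataclasses.fields(typ):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = _as_tuple(sub[f.name])
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(load_yaml(path))

    def to_yaml(self, path: str | Path) -> Path:
        return save_yaml(path, self.to_dict())

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


def _as_tuple(x):
    return tuple(_as_tuple(v) if isinstance(v, list) else v for v in x)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "vepasl_version": __version__}


def stage_simulate(config: PipelineConfig, out: Path) -> dict:
    truth = generate_truth(config.phantom)
    matrix = build_encoding_matrix(config.geometry, ideal=config.ideal_encoding)
    series, sidecar = synthesize_series(
        truth, config.protocol, matrix, config.constants, seed=config.seed
    )
    calib = make_calibration_volume(truth, config.constants)
    vx = truth.voxel_size_mm
    write_nifti(out / "asl_series.nii.gz", series, vx)
    write_nifti(out / "calibration.nii.gz", calib, vx)
    write_nifti(out / "adc.nii.gz", truth.adc, vx)
    write_nifti(out / "gm_pv.nii.gz", truth.gm_pv, vx)
    write_nifti(out / "infarct.nii.gz", truth.infarct_mask.astype(float), vx)
    write_nifti(out / "ventricles.nii.gz", truth.ventricle_mask.astype(float), vx)
    write_nifti(out / "brain_mask.nii.gz", truth.brain_mask.astype(float), vx)
    write_nifti(out / "truth_cbf.nii.gz", np.moveaxis(truth.cbf, 0, -1), vx)
    write_nifti(out / "truth_att.nii.gz", np.moveaxis(truth.att, 0, -1), vx)
    sidecar["provenance"] = _provenance(config)
    sidecar["midline_index"] = truth.midline_index
    save_yaml(out / "sidecar.yaml", sidecar)

    gm = truth.gm_pv > config.gm_threshold
    summary = pd.DataFrame(
        {
            "region": ["brain", "gray_matter", "core", "infarct"],
            "n_voxels": [
                int(truth.brain_mask.sum()), int(gm.sum()),
                int(truth.core_mask.sum()), int(truth.infarct_mask.sum()),
            ],
            "mean_total_cbf": [
                float(truth.total_cbf()[m].mean()) if m.any() else np.nan
                for m in (truth.brain_mask, gm, truth.core_mask, truth.infarct_mask)
            ],
        }
    )
    summary.to_csv(out / "truth_summary.csv", index=False)
    return {"truth": truth, "matrix": matrix, "series": series, "sidecar": sidecar}


def stage_decode(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "series" in state:
        series, sidecar, matrix = state["series"], state["sidecar"], state["matrix"]
    else:
        series, _ = read_nifti(out / "asl_series.nii.gz")
        sidecar = load_yaml(out / "sidecar.yaml")
        matrix = EncodingMatrix(
            weights=np.array(sidecar["encoding_matrix"]),
            artery_ids=tuple(sidecar["artery_ids"]),
            cycle_descriptions=tuple(sidecar["protocol"]["encoding_cycle_names"]),
        )
    brain, _ = read_nifti(out / "brain_mask.nii.gz")
    decoded = decode_series(
        series, config.protocol, matrix,
        sidecar_volumes=sidecar["volumes"], mask=brain > 0.5,
    )
    vx = config.phantom.voxel_size_mm
    write_nifti(out / "decoded_dm.nii.gz",
                np.moveaxis(decoded.dm.reshape(-1, *decoded.class_map.shape,), 0, -1), vx)
    write_nifti(out / "territories.nii.gz", decoded.territory_labels().astype(float), vx)
    write_nifti(out / "class_map.nii.gz", decoded.class_map.astype(float), vx)
    write_nifti(out / "noise_sd.nii.gz", decoded.noise_sd, vx)
    return {"decoded": decoded, "matrix": matrix}


def _reload_decoded(config: PipelineConfig, out: Path):
    from .decode import DecodedSignals, default_classes

    sidecar = load_yaml(out / "sidecar.yaml")
    artery_ids = tuple(sidecar["artery_ids"])
    dm_flat, _ = read_nifti(out / "decoded_dm.nii.gz")
    n_art = len(artery_ids)
    shape = dm_flat.shape[:3]
    dm = np.moveaxis(dm_flat, -1, 0).reshape(n_art, config.protocol.n_plds, *shape)
    class_map, _ = read_nifti(out / "class_map.nii.gz")
    noise_sd, _ = read_nifti(out / "noise_sd.nii.gz")
    return DecodedSignals(
        artery_ids=artery_ids,
        classes=default_classes(n_art),
        dm=dm,
        class_map=np.rint(class_map).astype(int),
        static=np.zeros((config.protocol.n_plds, *shape)),
        noise_sd=noise_sd,
    )


def stage_fit(config: PipelineConfig, out: Path, state: dict) -> dict:
    decoded = state.get("decoded")
    if decoded is None:
        decoded = _reload_decoded(config, out)
    calib, _ = read_nifti(out / "calibration.nii.gz")
    ventricles, _ = read_nifti(out / "ventricles.nii.gz")
    csf = mean_csf_signal(calib, ventricles > 0.5)
    m0_blood = calibrate_m0_blood(csf, config.constants)
    per_artery = fit_maps(
        decoded, config.protocol, m0_blood, config.constants, config.fit_settings
    )
    vx = config.phantom.voxel_size_mm
    write_nifti(out / "cbf_per_artery.nii.gz", np.moveaxis(per_artery.cbf, 0, -1), vx)
    write_nifti(out / "att_per_artery.nii.gz", np.moveaxis(per_artery.att, 0, -1), vx)
    write_nifti(out / "fit_flags.nii.gz", np.moveaxis(per_artery.flags.astype(float), 0, -1), vx)
    save_yaml(out / "calibration.yaml",
              {"csf_signal": float(csf), "m0_blood": float(m0_blood),
               "provenance": _provenance(config)})
    return {"per_artery": per_artery, "m0_blood": m0_blood}


def _resolve_ipsilateral(config: PipelineConfig, core: np.ndarray, midline: float,
                         artery_ids) -> str:
    if config.ipsilateral != "auto":
        return config.ipsilateral
    from scipy import ndimage
    if core.any():
        com_x = float(ndimage.center_of_mass(core)[0])
    else:
        com_x = midline - 1  # default to the right hemisphere
    return "RICA" if com_x < midline else "LICA"


def _reload_per_artery(config: PipelineConfig, out: Path):
    from .fit import PerArteryMaps

    sidecar = load_yaml(out / "sidecar.yaml")
    artery_ids = tuple(sidecar["artery_ids"])
    cbf, _ = read_nifti(out / "cbf_per_artery.nii.gz")
    att, _ = read_nifti(out / "att_per_artery.nii.gz")
    flags, _ = read_nifti(out / "fit_flags.nii.gz")
    cbf = np.moveaxis(cbf, -1, 0)
    att = np.moveaxis(att, -1, 0)
    flags = np.rint(np.moveaxis(flags, -1, 0)).astype(int)
    return PerArteryMaps(
        artery_ids=artery_ids, cbf=cbf, att=att,
        residual_norm=np.zeros_like(cbf), flags=flags,
        fitted=cbf > -1,
    )


def stage_maps(config: PipelineConfig, out: Path, state: dict) -> dict:
    per_artery = state.get("per_artery")
    if per_artery is None:
        per_artery = _reload_per_artery(config, out)
    adc, _ = read_nifti(out / "adc.nii.gz")
    core = core_from_adc(adc, config.adc_threshold)
    midline = (per_artery.cbf.shape[1] - 1) / 2.0
    ipsi = _resolve_ipsilateral(config, core, midline, per_artery.artery_ids)
    derived = direct_indirect(per_artery, ipsi)
    vx = config.phantom.voxel_size_mm
    write_nifti(out / "total_cbf.nii.gz", derived.total_cbf, vx)
    write_nifti(out / "direct_cbf.nii.gz", derived.direct_cbf, vx)
    write_nifti(out / "indirect_cbf.nii.gz", derived.indirect_cbf, vx)
    write_nifti(out / "weighted_att.nii.gz", derived.weighted_att, vx)
    derived_contra = direct_indirect(per_artery, mirror_artery(ipsi))
    return {"derived": derived, "derived_contra": derived_contra,
            "core": core, "midline": midline}


def stage_rois(config: PipelineConfig, out: Path, state: dict) -> dict:
    core = state.get("core")
    if core is None:
        adc, _ = read_nifti(out / "adc.nii.gz")
        core = core_from_adc(adc, config.adc_threshold)
        state["midline"] = (core.shape[0] - 1) / 2.0
    infarct, _ = read_nifti(out / "infarct.nii.gz")
    gm_pv, _ = read_nifti(out / "gm_pv.nii.gz")
    rois = build_roi_set(
        core, infarct > 0.5, gm_pv, state["midline"], config.phantom.voxel_size_mm,
        config.surviving_radius_mm, config.peri_core_radius_mm, config.gm_threshold,
    )
    vx = config.phantom.voxel_size_mm
    for name in ("ischemic_core", "surviving_tissue", "peri_core",
                 "contralateral_surviving", "contralateral_peri_core"):
        write_nifti(out / f"roi_{name}.nii.gz", getattr(rois, name).astype(float), vx)
    save_yaml(out / "roi_report.yaml", {
        "n_voxels": {
            name: int(getattr(rois, name).sum())
            for name in ("ischemic_core", "final_infarct", "surviving_tissue",
                         "peri_core", "contralateral_surviving", "contralateral_peri_core")
        },
        "provenance": _provenance(config),
    })
    return {"rois": rois}


def stage_stats(config: PipelineConfig, out: Path, state: dict) -> dict:
    derived = state.get("derived")
    if derived is None:
        state.update(stage_maps(config, out, state))
        derived = state["derived"]
    rois = state.get("rois")
    if rois is None:
        state.update(stage_rois(config, out, state))
        rois = state["rois"]
    infarct = rois.final_infarct

    cutoff = config.direct_cutoff if config.apply_direct_cutoff else None
    table = survival_table(
        derived.direct_cbf, derived.indirect_cbf, infarct, rois.peri_core,
        direct_cutoff=cutoff, bin_width=config.bin_width,
        axis=config.survival_axis, max_bin=config.max_bin,
    )
    table.to_csv(out / "survival_table.csv", index=False)
    # finer binning so the split coincides with a bin edge
    fine = survival_table(
        derived.direct_cbf, derived.indirect_cbf, infarct, rois.peri_core,
        direct_cutoff=cutoff, axis=config.survival_axis,
        bin_edges=np.arange(0.0, config.max_bin + 1e-9, config.split / 5.0),
        min_count=1,
    )
    try:
        p_lo, p_hi, p_val = binomial_split_test(fine, config.split)
        split_note = "ok"
    except ValueError as exc:
        p_lo = p_hi = p_val = float("nan")
        split_note = str(exc)
        logger.warning("split test not computable: %s", exc)

    report = {
        "ipsilateral_artery": derived.ipsilateral_artery_id,
        "indirect_fraction_surviving": float(
            indirect_fraction(derived, rois.surviving_tissue)
        ),
        "indirect_fraction_contralateral": float(
            indirect_fraction(state["derived_contra"], rois.contralateral_surviving)
        ),
        "mean_weighted_att_surviving_s": mean_weighted_att(derived, rois.surviving_tissue),
        "mean_weighted_att_contralateral_s": mean_weighted_att(
            state["derived_contra"], rois.contralateral_surviving
        ),
        "survival_fraction_below_split": float(p_lo),
        "survival_fraction_above_split": float(p_hi),
        "split_cbf": config.split,
        "split_p_value": float(p_val),
        "split_test_note": split_note,
        "provenance": _provenance(config),
    }
    save_yaml(out / "stats_report.yaml", report)
    return {"survival_table": table, "report": report}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute pipeline stages in order; returns the accumulated result bundle.

    Stage failures are re-raised as :class:`StageError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    file_handler = logging.FileHandler(out / "pipeline.log")
    file_handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    file_handler.setLevel(logging.INFO)
    pkg_logger = logging.getLogger("vepasl")
    prev_level = pkg_logger.level
    pkg_logger.addHandler(file_handler)
    pkg_logger.setLevel(logging.INFO)
    state: dict = {}
    runners = {
        "simulate": lambda: stage_simulate(config, out),
        "decode": lambda: stage_decode(config, out, state),
        "fit": lambda: stage_fit(config, out, state),
        "maps": lambda: stage_maps(config, out, state),
        "rois": lambda: stage_rois(config, out, state),
        "stats": lambda: stage_stats(config, out, state),
    }
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.time()
            try:
                state.update(runners[stage]())
            except StageError:
                raise
            except FileNotFoundError as exc:
                raise StageError(stage, f"missing input: {exc.filename}") from exc
            except Exception as exc:
                raise StageError(stage, str(exc)) from exc
            logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
    finally:
        pkg_logger.removeHandler(file_handler)
        pkg_logger.setLevel(prev_level)
        file_handler.close()
    return state
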