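"""Derived perfusion maps and stroke regions of interest.

Direct CBF is the flow reaching a voxel from the ipsilateral internal
carotid artery; Indirect CBF is the summed flow from every other feeding
artery and is the collateral-perfusion measure.  The weighted ATT is the
CBF-weighted average of the per-artery transit times, so a voxel fed by one
artery inherits that artery's ATT directly.

ROIs: the ischemic core is the low-ADC region at presentation; the final
infarct is consumed as a mask.  "Surviving tissue" is a 10 mm spherical
shell around the final infarct (dilation minus the mask); "Peri-core" is a
20 mm shell around the core.  Contralateral equivalents are built from
masks mirrored about the mid-sagittal plane.  All ROIs are restricted to
gray matter (partial volume strictly greater than 0.5) and clipped to their
hemisphere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fit import PerArteryMaps

logger = logging.getLogger(__name__)

ADC_CORE_THRESHOLD = 620e-6  # mm^2/s, externally validated ischemic-core cutoff


@dataclass
class DerivedMaps:
    """Total / Direct / Indirect CBF and the weighted ATT."""

    total_cbf: np.ndarray
    weighted_att: np.ndarray   # NaN where total CBF is zero
    direct_cbf: np.ndarray
    indirect_cbf: np.ndarray
    ipsilateral_artery_id: str


def weighted_att(per_artery: PerArteryMaps) -> np.ndarray:
    """CBF-weighted mean transit time: sum_a CBF_a ATT_a / sum_a CBF_a.

    Masked (NaN) where the total CBF is zero.
    """
    total = per_artery.cbf.sum(axis=0)
    weighted = (per_artery.cbf * per_artery.att).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, weighted / np.where(total > 0, total, 1.0), np.nan)
    return out


def direct_indirect(per_artery: PerArteryMaps, ipsilateral: str) -> DerivedMaps:
    """Split per-artery CBF into Direct (ipsilateral ICA) and Indirect
    (all other arteries) components."""
    if ipsilateral not in per_artery.artery_ids:
        raise ValueError(f"unknown artery id {ipsilateral!r}")
    idx = per_artery.artery_ids.index(ipsilateral)
    direct = per_artery.cbf[idx].copy()
    indirect = per_artery.cbf.sum(axis=0) - per_artery.cbf[idx]
    return DerivedMaps(
        total_cbf=direct + indirect,
        weighted_att=weighted_att(per_artery),
        direct_cbf=direct,
        indirect_cbf=indirect,
        ipsilateral_artery_id=ipsilateral,
    )


def mirror_artery(artery_id: str) -> str:
    """Contralateral counterpart of an artery id (leading R <-> L).

    Used when evaluating contralateral ROIs: their "Direct" supply is the
    ICA of their own hemisphere, i.e. the mirror of the stroke-side ICA.
    """
    if artery_id.startswith("R"):
        return "L" + artery_id[1:]
    if artery_id.startswith("L"):
        return "R" + artery_id[1:]
    raise ValueError(f"cannot mirror artery id {artery_id!r}")


def core_from_adc(
    adc: np.ndarray,
    threshold: float = ADC_CORE_THRESHOLD,
    largest_component_only: bool = True,
) -> np.ndarray:
    """Ischemic-core mask: ADC strictly below the threshold.

    The manual editing step of semi-automated delineation is replaced by
    keeping the largest 26-connected component (small spurious islands are
    dropped); pass ``largest_component_only=False`` for the raw threshold.
    """
    adc = np.asarray(adc, dtype=float)
    if np.any(adc <= 0):
        raise ValueError("ADC map must be positive")
    mask = adc < threshold
    if largest_component_only and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def spherical_structure(radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Voxel offsets whose center-to-center distance is <= radius (inclusive),
    honouring anisotropic voxel sizes."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    half = [int(np.floor(radius_mm / v)) for v in voxel_size_mm]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * v for h, v in zip(half, voxel_size_mm)], indexing="ij"
    )
    dist2 = sum(g**2 for g in grids)
    return dist2 <= radius_mm**2 + 1e-9


def shell_roi(mask: np.ndarray, radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Spherical-kernel dilation of a mask minus the mask itself."""
    mask = np.asarray(mask, dtype=bool)
    structure = spherical_structure(radius_mm, voxel_size_mm)
    dilated = ndimage.binary_dilation(mask, structure=structure)
    return dilated & ~mask


def mirror_mask(mask: np.ndarray, midline: float) -> np.ndarray:
    """Reflect a mask about the mid-sagittal plane x = midline (voxel units).

    Reflected positions are rounded to the nearest voxel; reflections that
    land outside the volume are dropped (and counted in the log).
    """
    mask = np.asarray(mask, dtype=bool)
    nx = mask.shape[0]
    if not 0 <= midline <= nx - 1:
        raise ValueError("midline lies outside the image grid")
    i, j, k = np.nonzero(mask)
    i_ref = np.rint(2.0 * midline - i).astype(int)
    inside = (i_ref >= 0) & (i_ref < nx)
    dropped = int((~inside).sum())
    if dropped:
        logger.info("mirror_mask: %d voxels reflected outside the volume", dropped)
    out = np.zeros_like(mask)
    out[i_ref[inside], j[inside], k[inside]] = True
    return out


def restrict_to_gm(mask: np.ndarray, gm_pv: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Keep only voxels with gray-matter partial volume strictly above the
    threshold."""
    mask = np.asarray(mask, dtype=bool)
    gm_pv = np.asarray(gm_pv, dtype=float)
    if mask.shape != gm_pv.shape:
        raise ValueError("mask and partial-volume map shapes differ")
    return mask & (gm_pv > threshold)


@dataclass
class ROISet:
    """Stroke analysis regions on the ASL grid."""

    ischemic_core: np.ndarray
    final_infarct: np.ndarray
    surviving_tissue: np.ndarray
    peri_core: np.ndarray
    contralateral_core: np.ndarray
    contralateral_infarct: np.ndarray
    contralateral_surviving: np.ndarray
    contralateral_peri_core: np.ndarray
    gray_matter: np.ndarray


def _hemisphere(shape, midline: float, side: int) -> np.ndarray:
    """Boolean hemisphere mask; side=-1 for x below midline, +1 above.
    Voxels exactly on the midline belong to neither hemisphere."""
    i = np.arange(shape[0], dtype=float)
    col = (i - midline) * side > 0
    return np.broadcast_to(col[:, None, None], shape).copy()


def build_roi_set(
    core: np.ndarray,
    infarct: np.ndarray,
    gm_pv: np.ndarray,
    midline: float,
    voxel_size_mm,
    surviving_radius_mm: float = 10.0,
    peri_core_radius_mm: float = 20.0,
    gm_threshold: float = 0.5,
) -> ROISet:
    """Construct the full ROI set from core and final-infarct masks.

    The ipsilateral hemisphere is taken from the infarct's (or, if empty, the
    core's) center of mass; every ROI is clipped to its own hemisphere, which
    automates the manual no-opposite-hemisphere check.  Contralateral ROIs
    are built from the mirrored masks first and GM-restricted afterwards.
    """
    core = np.asarray(core, dtype=bool)
    infarct = np.asarray(infarct, dtype=bool)
    if core.shape != infarct.shape or core.shape != gm_pv.shape:
        raise ValueError("core, infarct and GM maps must share one grid")

    ref = infarct if infarct.any() else core
    if ref.any():
        com_x = float(ndimage.center_of_mass(ref)[0])
        side = -1 if com_x < midline else 1
    else:
        side = -1
    ipsi = _hemisphere(core.shape, midline, side)
    contra = _hemisphere(core.shape, midline, -side)

    def finish(mask, hemisphere):
        clipped = mask & ~hemisphere
        if clipped.any():
            logger.info("hemisphere clipping removed %d voxels", int(clipped.sum()))
        return restrict_to_gm(mask & hemisphere, gm_pv, gm_threshold)

    surviving = finish(shell_roi(infarct, surviving_radius_mm, voxel_size_mm), ipsi)
    peri = finish(shell_roi(core, peri_core_radius_mm, voxel_size_mm), ipsi)

    m_core = mirror_mask(core, midline)
    m_infarct = mirror_mask(infarct, midline)
    c_surviving = finish(shell_roi(m_infarct, surviving_radius_mm, voxel_size_mm), contra)
    c_peri = finish(shell_roi(m_core, peri_core_radius_mm, voxel_size_mm), contra)

    return ROISet(
        ischemic_core=core,
        final_infarct=infarct,
        surviving_tissue=surviving,
        peri_core=peri,
        contralateral_core=m_core,
        contralateral_infarct=m_infarct,
        contralateral_surviving=c_surviving,
        contralateral_peri_core=c_peri,
        gray_matter=gm_pv > gm_threshold,
    )
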