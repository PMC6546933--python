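"""Voxel-level tissue-survival analysis and patient-level comparisons.

The voxel-level analysis asks whether collateral (Indirect) CBF at
presentation predicts tissue fate: within the Peri-Core ROI, voxels
receiving more than 25 ml/100 g/min of Direct CBF are excluded (they were
never at risk), the remainder are binned by Indirect CBF in 10 ml/100 g/min
ranges, and the fraction falling outside the final infarct ("surviving") is
computed per bin.  A pooled two-proportion z-test compares survival above
and below an Indirect CBF of 25 ml/100 g/min.

The patient-level analysis compares the Indirect CBF fraction and the mean
weighted ATT between the Surviving-Tissue ROI and its contralateral mirror
across timepoints with a two-way ANOVA (Type-II sums of squares for
unbalanced designs), followed by per-timepoint unpaired t-tests when the
ROI effect is significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.proportion import proportions_ztest

from .maps import DerivedMaps


@dataclass(frozen=True)
class PatientSummary:
    """One ROI measurement for one patient at one timepoint."""

    patient_id: str
    timepoint: str
    roi: str                      # "surviving" or "contralateral"
    indirect_fraction: float
    mean_weighted_att_s: float
    reperfusion: str = "unknown"  # "reperfuser" / "non-reperfuser"

    def __post_init__(self) -> None:
        if not 0.0 <= self.indirect_fraction <= 1.0:
            raise ValueError("indirect fraction must lie in [0, 1]")


def summaries_to_frame(summaries: list[PatientSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in summaries],
            "timepoint": [s.timepoint for s in summaries],
            "roi": [s.roi for s in summaries],
            "indirect_fraction": [s.indirect_fraction for s in summaries],
            "mean_weighted_att_s": [s.mean_weighted_att_s for s in summaries],
            "reperfusion": [s.reperfusion for s in summaries],
        }
    )


def indirect_fraction(derived: DerivedMaps, roi: np.ndarray, method: str = "sum-ratio") -> float:
    """Indirect CBF within an ROI as a proportion of the total CBF.

    ``sum-ratio`` (default) divides the ROI-summed Indirect CBF by the
    ROI-summed total CBF, which is robust to near-zero-flow voxels;
    ``voxel-mean`` averages the voxelwise ratio over voxels with flow.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    total = derived.total_cbf[roi]
    indirect = derived.indirect_cbf[roi]
    if method == "sum-ratio":
        denom = float(total.sum())
        if denom <= 0:
            raise ValueError("ROI has no total CBF")
        return float(indirect.sum() / denom)
    if method == "voxel-mean":
        ok = total > 0
        if not ok.any():
            raise ValueError("ROI has no total CBF")
        return float(np.mean(indirect[ok] / total[ok]))
    raise ValueError(f"unknown method {method!r}")


def mean_weighted_att(derived: DerivedMaps, roi: np.ndarray) -> float:
    """Mean weighted ATT over ROI voxels with defined (flowing) ATT."""
    roi = np.asarray(roi, dtype=bool)
    vals = derived.weighted_att[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI has no voxels with defined weighted ATT")
    return float(vals.mean())


def survival_table(
    direct: np.ndarray,
    indirect: np.ndarray,
    infarct: np.ndarray,
    peri_core: np.ndarray,
    direct_cutoff: float | None = 25.0,
    bin_width: float = 10.0,
    bin_edges: np.ndarray | None = None,
    axis: str = "indirect",
    max_bin: float = 80.0,
    min_count: int = 10,
    group_label: str = "all",
) -> pd.DataFrame:
    """Per-bin tissue-survival fractions.

    Voxels inside the Peri-Core ROI are kept; with ``direct_cutoff`` set,
    voxels receiving strictly more than the cutoff of Direct CBF are
    excluded (a voxel at exactly the cutoff is retained).  The remaining
    voxels are binned by the ``axis`` CBF ("indirect" or "direct"); the top
    bin is open-ended at ``max_bin``.  Survival means lying outside the
    final-infarct mask.  Fractions for bins with fewer than ``min_count``
    voxels are reported as NaN (counts are still given).

    Set ``direct_cutoff=None`` for the all-voxels variant used when
    comparing the effect of Direct vs Indirect CBF.
    """
    direct = np.asarray(direct, dtype=float)
    indirect = np.asarray(indirect, dtype=float)
    infarct = np.asarray(infarct, dtype=bool)
    peri_core = np.asarray(peri_core, dtype=bool)

    keep = peri_core.copy()
    if direct_cutoff is not None:
        keep &= ~(direct > direct_cutoff)  # strictly "more than" is excluded
    values = {"indirect": indirect, "direct": direct}[axis][keep]
    survived = ~infarct[keep]

    if bin_edges is None:
        bin_edges = np.arange(0.0, max_bin + bin_width / 2, bin_width)
    bin_edges = np.asarray(bin_edges, dtype=float)
    lefts = bin_edges[:-1].tolist() + [bin_edges[-1]]
    rights = bin_edges[1:].tolist() + [np.inf]

    rows = []
    for left, right in zip(lefts, rights):
        in_bin = (values >= left) & (values < right)
        total = int(in_bin.sum())
        surv = int(survived[in_bin].sum())
        frac = surv / total if total >= min_count else np.nan
        rows.append(
            {
                "bin_left": left,
                "bin_right": right,
                "surviving": surv,
                "total": total,
                "fraction": frac,
                "group": group_label,
            }
        )
    return pd.DataFrame(rows)


def binomial_split_test(table: pd.DataFrame, split: float = 25.0) -> tuple[float, float, float]:
    """Two-proportion z-test of survival below vs above a CBF split.

    The split must coincide with a bin edge of the table (build the table
    with ``bin_edges`` including the split, or a bin width dividing it).
    Returns (proportion_below, proportion_above, two-sided p).
    """
    below = table[table["bin_right"] <= split]
    above = table[table["bin_left"] >= split]
    if len(below) + len(above) != len(table):
        raise ValueError(f"split {split} falls inside a bin; rebuild the table "
                         "with a compatible bin edge")
    n_lo, n_hi = int(below["total"].sum()), int(above["total"].sum())
    if n_lo == 0 or n_hi == 0:
        raise ValueError("one side of the split contains no voxels")
    s_lo, s_hi = int(below["surviving"].sum()), int(above["surviving"].sum())
    _, p = proportions_ztest([s_lo, s_hi], [n_lo, n_hi], alternative="two-sided")
    return s_lo / n_lo, s_hi / n_hi, float(p)


def relative_increase(table: pd.DataFrame, low_bin: float = 0.0, high_bin: float = 70.0) -> float:
    """Relative change (percent) in survival fraction between two bins,
    identified by their left edges."""
    def frac(left):
        row = table[table["bin_left"] == left]
        if row.empty or row["total"].iloc[0] == 0:
            raise ValueError(f"bin starting at {left} is empty")
        f = row["fraction"].iloc[0]
        if np.isnan(f):
            raise ValueError(f"bin starting at {left} has too few voxels")
        return float(f)

    f_lo, f_hi = frac(low_bin), frac(high_bin)
    if f_lo == 0:
        raise ValueError("low-bin survival fraction is zero; relative increase undefined")
    return 100.0 * (f_hi - f_lo) / f_lo


def two_way_anova(
    summaries: pd.DataFrame | list[PatientSummary],
    response: str = "indirect_fraction",
    alpha: float = 0.05,
) -> dict:
    """Two-way ANOVA of an ROI measure with factors ROI and timepoint.

    Uses an OLS fit with interaction and Type-II sums of squares (robust to
    the unbalanced designs produced by patient dropout).  When the ROI main
    effect is significant at ``alpha``, per-timepoint unpaired two-sample
    t-tests compare the two ROIs; otherwise the post-hoc table is empty.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = summaries_to_frame(summaries)
    for factor in ("roi", "timepoint"):
        if summaries[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")
    data = summaries.rename(columns={response: "y"})
    model = smf.ols("y ~ C(roi) + C(timepoint) + C(roi):C(timepoint)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    roi_p = float(anova.loc["C(roi)", "PR(>F)"])

    posthoc = []
    if roi_p < alpha:
        rois = sorted(summaries["roi"].unique())
        for tp, grp in summaries.groupby("timepoint", sort=False):
            a = grp.loc[grp["roi"] == rois[0], response]
            b = grp.loc[grp["roi"] == rois[1], response]
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = sps.ttest_ind(a, b)
            posthoc.append(
                {"timepoint": tp, "t": float(t), "p": float(p),
                 "mean_" + rois[0]: float(a.mean()), "mean_" + rois[1]: float(b.mean())}
            )
    return {
        "anova": anova,
        "roi_p": roi_p,
        "posthoc": pd.DataFrame(posthoc),
        "response": response,
    }
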