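"""Phenotype formulas used alongside the transcriptome pipeline: derived
plasma lipids, tolerance-test AUC, ddCt relative expression, and daily dose
from fluid intake."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import round_half_away

__all__ = [
    "LipidPanel",
    "ToleranceCurve",
    "derive_lipids",
    "auc_trapezoid",
    "ddct_fold_change",
    "daily_dose",
]


@dataclass
class LipidPanel:
    """Measured and derived plasma lipids, all mg/dl.

    VLDL-C = TG / 5; LDL-C = total cholesterol - HDL-C - VLDL-C. A negative
    derived LDL-C (pathological or inconsistent inputs) is flagged, not
    clipped, since the formula is defined unconditionally.
    """

    triglycerides: float
    total_cholesterol: float
    hdl_c: float
    vldl_c: float
    ldl_c: float
    ldl_negative: bool

    def rounded(self) -> dict[str, float]:
        """One-decimal report values."""
        return {
            "VLDL-C": round_half_away(self.vldl_c, 1),
            "LDL-C": round_half_away(self.ldl_c, 1),
        }


def derive_lipids(tg: float, tot_chol: float, hdl_c: float) -> LipidPanel:
    """Friedewald-style derivation of VLDL-C and LDL-C from TG, total
    cholesterol and HDL-C (all mg/dl)."""
    if min(tg, tot_chol, hdl_c) < 0:
        raise ValueError("lipid inputs must be non-negative")
    vldl = tg / 5.0
    ldl = tot_chol - hdl_c - vldl
    return LipidPanel(
        triglycerides=tg,
        total_cholesterol=tot_chol,
        hdl_c=hdl_c,
        vldl_c=vldl,
        ldl_c=ldl,
        ldl_negative=ldl < 0,
    )


@dataclass
class ToleranceCurve:
    """Glucose concentration (mg/dl) sampled at strictly increasing
    timepoints (min) during a tolerance test."""

    timepoints: list[float]
    glucose: list[float]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.glucose):
            raise ValueError("timepoints and glucose must have equal length")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        t = np.asarray(self.timepoints, dtype=float)
        if not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if (np.asarray(self.glucose, dtype=float) < 0).any():
            raise ValueError("glucose concentrations must be non-negative")


def auc_trapezoid(curve: ToleranceCurve, baseline: float = 0.0) -> float:
    """Composite trapezoidal AUC of a tolerance curve, in mg/dl x min.

    Total area above zero by default; pass a baseline (e.g. the t = 0
    glucose) for incremental area, in which case the integrand is clipped
    at the baseline.
    """
    g = np.asarray(curve.glucose, dtype=float)
    if baseline:
        g = np.maximum(g - baseline, 0.0)
    return float(np.trapezoid(g, np.asarray(curve.timepoints, dtype=float)))


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the ddCt method: 2^(-ddCt) with
    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator."""
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))


def daily_dose(volume_ml_per_day: float, conc_ug_per_ml: float = 200.0) -> float:
    """Daily solute dose (mg/day) from fluid intake and concentration.

    Default concentration 200 ug/mL (nicotine hydrogen tartrate in drinking
    water); the dose refers to the salt as dissolved.
    """
    if volume_ml_per_day < 0:
        raise ValueError("volume must be non-negative")
    return volume_ml_per_day * conc_ug_per_ml / 1000.0
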