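"""Internal-standard calibration and bioanalytical method-validation math.

Implements the quantification QC arithmetic of a targeted LC-MS amino-acid
assay: least-squares calibration of analyte/IS peak-area ratios against
standard concentrations, LLOQ as the lowest level with signal-to-noise
strictly above 10, precision (RSD%) and accuracy (RE%) with the +/-15%
acceptance windows, and recovery / matrix-effect ratios with the 85-115%
matrix-effect window.  Inputs begin at integrated peak areas; no
chromatogram handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RSD_LIMIT = 15.0  # % precision acceptance
RE_LIMIT = 15.0  # % accuracy acceptance
MATRIX_EFFECT_RANGE = (85.0, 115.0)  # % window for no ionization bias
SN_LLOQ = 10.0  # signal-to-noise must exceed this


@dataclass
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    r2: float
    conc_range: tuple  # (lowest, highest) calibration level
    lloq: float | None = None  # set via lloq(); None = not determined


def fit_calibration(
    concentrations, analyte_areas, is_areas, analyte: str = ""
) -> CalibrationCurve:
    """OLS of analyte/IS peak-area ratio on standard concentration.

    r2 is the coefficient of determination of the simple linear fit
    (identical to squared Pearson r of fitted vs observed ratios).
    """
    conc = np.asarray(concentrations, dtype=float)
    areas = np.asarray(analyte_areas, dtype=float)
    is_areas = np.asarray(is_areas, dtype=float)
    if len(conc) < 3:
        raise ValueError("calibration needs at least 3 levels")
    if (is_areas <= 0).any():
        bad = np.nonzero(is_areas <= 0)[0]
        raise ValueError(f"non-positive IS area at level index {bad.tolist()}")
    ratio = areas / is_areas
    res = stats.linregress(conc, ratio)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue ** 2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def lloq(concentrations, sn_values):
    """Lowest concentration with signal-to-noise strictly above 10.

    Returns ``(value, found)``; ``(nan, False)`` when no level qualifies
    (S/N exactly 10 does not qualify).
    """
    conc = np.asarray(concentrations, dtype=float)
    sn = np.asarray(sn_values, dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration series")
    ok = sn > SN_LLOQ
    if not ok.any():
        return float("nan"), False
    return float(conc[ok].min()), True


def quantify(analyte_areas, is_areas, curve: CalibrationCurve):
    """Back-calculate concentrations: (area ratio - intercept) / slope.

    Returns ``(concentrations, below_lloq flags)``; flags are all-False
    when the curve carries no LLOQ.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    ratio = np.asarray(analyte_areas, dtype=float) / np.asarray(is_areas, dtype=float)
    conc = (ratio - curve.intercept) / curve.slope
    if curve.lloq is not None and np.isfinite(curve.lloq):
        flags = conc < curve.lloq
    else:
        flags = np.zeros_like(conc, dtype=bool)
    return conc, flags


def precision_accuracy(replicates, nominal: float) -> dict:
    """RSD% (precision) and RE% (accuracy) of replicate QC measurements.

    RSD% = 100 SD/mean (sample SD), RE% = 100 (mean - nominal)/nominal.
    Pass flags: RSD <= 15 and |RE| <= 15.  A zero mean leaves RSD
    undefined (NaN, flagged).
    """
    reps = np.asarray(replicates, dtype=float)
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    mean = reps.mean()
    sd = reps.std(ddof=1)
    if mean == 0:
        rsd = float("nan")
        rsd_defined = False
    else:
        rsd = 100.0 * sd / abs(mean)
        rsd_defined = True
    re = 100.0 * (mean - nominal) / nominal
    return {
        "mean": float(mean),
        "rsd_pct": float(rsd),
        "re_pct": float(re),
        "rsd_defined": rsd_defined,
        "precision_pass": bool(rsd_defined and rsd <= RSD_LIMIT),
        "accuracy_pass": bool(abs(re) <= RE_LIMIT),
    }


def recovery_matrix_effect(extracted_areas, post_spiked_areas, neat_areas) -> pd.DataFrame:
    """Recovery% and matrix effect% against neat standards.

    recovery% = 100 extracted/neat; matrix_effect% = 100 post-spiked/neat;
    matrix-effect pass iff within [85, 115].
    """
    ext = np.atleast_1d(np.asarray(extracted_areas, dtype=float))
    post = np.atleast_1d(np.asarray(post_spiked_areas, dtype=float))
    neat = np.atleast_1d(np.asarray(neat_areas, dtype=float))
    if (neat <= 0).any():
        raise ValueError("neat standard areas must be positive")
    recovery = 100.0 * ext / neat
    me = 100.0 * post / neat
    lo, hi = MATRIX_EFFECT_RANGE
    return pd.DataFrame(
        {
            "recovery_pct": recovery,
            "matrix_effect_pct": me,
            "matrix_effect_pass": (me >= lo) & (me <= hi),
        }
    )


def stability(replicates, nominal: float, condition: str) -> dict:
    """Stability under one storage condition = precision/accuracy + label.

    Conditions are labels (short-term, long-term, freeze-thaw,
    post-preparative); stable iff both QC windows pass.
    """
    qc = precision_accuracy(replicates, nominal)
    qc["condition"] = condition
    qc["stable"] = qc["precision_pass"] and qc["accuracy_pass"]
    return qc
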