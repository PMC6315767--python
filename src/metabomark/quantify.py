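"""External-calibration quantification of targeted compounds.

A calibration line (peak response vs standard concentration, ordinary least
squares) is inverted to convert sample responses to µg/mL of extract, then to
µg per gram of dry faeces through explicit extraction parameters (extract
volume, dilution factor, dry mass).  Group summaries (mean, SD, SEM) and a
two-sample comparison of the resulting concentrations complete the targeted
workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "ConcentrationRecord",
    "GroupSummary",
    "fit_calibration",
    "quantify_sample",
    "group_summary",
    "compare_groups",
]


@dataclass
class CalibrationCurve:
    """Least-squares line ``response = slope·conc + intercept`` with its R²
    and the concentration range (µg/mL) over which it was established;
    inverse predictions outside that range are flagged, not clipped."""

    slope: float
    intercept: float
    r2: float
    conc_min: float
    conc_max: float
    analyte: str = ""

    @property
    def degenerate(self) -> bool:
        return self.slope == 0 or np.isnan(self.r2)


@dataclass
class ConcentrationRecord:
    sample_id: str
    analyte: str
    response: float
    conc_ug_per_ml: float
    conc_ug_per_g: float
    below_range: bool
    above_range: bool

    @property
    def in_range(self) -> bool:
        return not (self.below_range or self.above_range)


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float
    sem: float


def fit_calibration(
    concentrations, responses, analyte: str = ""
) -> CalibrationCurve:
    """Fit a straight calibration line through standards.

    Needs at least two distinct concentration levels.  A flat response set
    yields slope 0 with an undefined (NaN) R², flagged via ``degenerate``.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("calibration needs at least two distinct concentration levels")
    if np.ptp(r) == 0:
        return CalibrationCurve(0.0, float(r[0]), float("nan"), c.min(), c.max(), analyte)
    res = stats.linregress(c, r)
    return CalibrationCurve(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(c.min()),
        float(c.max()),
        analyte,
    )


def quantify_sample(
    curve: CalibrationCurve,
    response: float,
    dry_mass_g: float,
    extract_volume_ml: float = 1.0,
    dilution_factor: float = 1.0,
    sample_id: str = "",
) -> ConcentrationRecord:
    """Inverse-predict a sample's concentration in µg/g of dry faeces.

    ``conc(µg/mL) = (response − intercept)/slope`` and
    ``µg/g = conc × extract_volume_ml × dilution_factor / dry_mass_g``.
    Predictions outside the calibrated range (including negatives) are
    flagged rather than silently altered.
    """
    if curve.degenerate:
        raise ValueError("cannot invert a degenerate (zero-slope) calibration curve")
    if dry_mass_g <= 0:
        raise ValueError("dry mass must be positive")
    conc = (response - curve.intercept) / curve.slope
    ug_per_g = conc * extract_volume_ml * dilution_factor / dry_mass_g
    return ConcentrationRecord(
        sample_id=sample_id,
        analyte=curve.analyte,
        response=float(response),
        conc_ug_per_ml=float(conc),
        conc_ug_per_g=float(ug_per_g),
        below_range=bool(conc < curve.conc_min),
        above_range=bool(conc > curve.conc_max),
    )


def group_summary(values) -> GroupSummary:
    """Mean, sample SD (n−1 denominator) and SEM = SD/√n of one group."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("group summary needs at least two values")
    sd = float(v.std(ddof=1))
    return GroupSummary(int(v.size), float(v.mean()), sd, sd / np.sqrt(v.size))


def compare_groups(
    group_a, group_b, variant: str = "welch", log_scale: bool = False
) -> float:
    """Two-sided two-sample t-test p-value between concentration groups.

    The default — Welch's test on the concentrations as given — is the
    variant calibrated to reproduce the reference fatty-acid comparison this
    package ships (see docs/methods.md); set ``log_scale=True`` to test on
    log2-transformed concentrations instead (requires positive values).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if log_scale:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log-scale comparison needs strictly positive values")
        a, b = np.log2(a), np.log2(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.pvalue)
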