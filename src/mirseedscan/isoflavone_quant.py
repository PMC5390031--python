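"""HPLC-style isoflavone quantification.

Linear calibration (peak area vs ppm, ordinary least squares with a free
intercept) per aglycone standard, inversion of sample peak areas to ppm,
conversion to ug per g dry weight through the extraction constants
(extract volume, dilution, sample mass), and per-sample totals as the sum
of the three aglycones (daidzein, glycitein, genistein).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy import stats as _sstats

ANALYTES = ("daidzein", "glycitein", "genistein")


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float          # area per ppm
    intercept: float      # area
    r2: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: non-positive calibration slope")


@dataclass(frozen=True)
class IsoflavoneProfile:
    genotype: str
    stage: str
    daidzein: float
    glycitein: float
    genistein: float

    def __post_init__(self) -> None:
        if min(self.daidzein, self.glycitein, self.genistein) < 0:
            raise ValueError("negative concentration")

    @property
    def total(self) -> float:
        return self.daidzein + self.glycitein + self.genistein


def fit_calibration(points, analyte: str = "") -> CalibrationCurve:
    """OLS line through >= 3 (ppm, area) standard points."""
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need >= 3 calibration points")
    ppm = [p for p, _ in pts]
    area = [a for _, a in pts]
    if len(set(ppm)) < 2:
        raise ValueError("degenerate ppm values")
    res = _sstats.linregress(ppm, area)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
    )


def quantify(
    area: float,
    curve: CalibrationCurve,
    dilution: float = 1.0,
    sample_mass_g: float = 0.125,
    extract_volume_ml: float = 6.0,
) -> float:
    """Peak area -> ug analyte per g dry weight.

    ppm (ug/ml) = (area - intercept)/slope; ug/g = ppm * extract volume *
    dilution / sample mass. Defaults follow the extraction recipe of
    0.125 g flour in 5 ml ethanol + 1 ml HCl. Areas below the intercept
    clip to zero with a warning.
    """
    ppm = (area - curve.intercept) / curve.slope
    if ppm < 0:
        warnings.warn(
            f"{curve.analyte or 'analyte'}: area below calibration intercept; "
            "clipping to 0",
            stacklevel=2,
        )
        ppm = 0.0
    return ppm * extract_volume_ml * dilution / sample_mass_g


def profile_totals(
    genotype: str, stage: str, concentrations: dict
) -> IsoflavoneProfile:
    """Assemble a per-sample profile; total is the sum of the aglycones."""
    missing = set(ANALYTES) - set(concentrations)
    if missing:
        raise ValueError(f"missing analyte(s) {sorted(missing)}")
    return IsoflavoneProfile(
        genotype=genotype,
        stage=stage,
        daidzein=concentrations["daidzein"],
        glycitein=concentrations["glycitein"],
        genistein=concentrations["genistein"],
    )
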