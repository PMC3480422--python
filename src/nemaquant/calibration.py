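"""Ct-to-abundance calibration: Ct = a * log10(N) + b per assay.

Each assay is calibrated on dilution series of hand-picked, microscopically
identified nematodes (1, 5, 10, 50, 100 individuals per vial by protocol;
fractional N is allowed for sub-individual dilution series). Ordinary least
squares of Ct on log10(N) gives the slope a (cycles per tenfold abundance),
the intercept b (Ct of a single individual) and R². The fitted line inverts
to N = 10^((Ct - b)/a) for density estimation; amplification efficiency
derives from the slope as 10^(-1/a) - 1 (perfect per-cycle doubling
corresponds to a = -1/log10(2) ≈ -3.32).

Family-level assays pool the raw points of the constituent genus series —
restricted to genera actually observed in the microscopy samples — and refit
a single line, so the family R² reflects between-genus spread in rDNA dosage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: protocol cycle count; Ct at/above this is no signal (below detection)
NO_SIGNAL_CT = 60.0


@dataclass(frozen=True)
class CalibrationSeries:
    """Dilution-series Ct readings for one assay on one genus."""

    assay: str
    genus: str
    points: tuple[tuple[float, float], ...]  # (n_nematodes, ct)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a calibration series needs at least 2 points")
        for n, ct in self.points:
            if n <= 0:
                raise ValueError(f"nematode count must be positive, got {n}")
            if not 0 < ct <= NO_SIGNAL_CT:
                raise ValueError(f"Ct out of range (0, {NO_SIGNAL_CT}]: {ct}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted Ct = a*log10(N) + b line for one assay."""

    assay: str
    a: float  # slope, cycles per log10 individual; negative for a valid assay
    b: float  # intercept, Ct at N = 1
    r2: float
    n_points: int
    genera_pooled: tuple[str, ...] = ()
    valid: bool = True

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency derived from the slope."""
        return 10.0 ** (-1.0 / self.a) - 1.0


@dataclass(frozen=True)
class DensityEstimate:
    """Back-calculated nematode count; censored when below detection."""

    value: float
    censored: bool = False

    def __float__(self) -> float:
        return float(self.value)


def fit_calibration(
    series: CalibrationSeries | Sequence[tuple[float, float]],
    assay: str | None = None,
    genera: Sequence[str] = (),
) -> CalibrationCurve:
    """Ordinary least squares of Ct on log10(N).

    R² is the squared Pearson correlation of observed and fitted Ct. A
    non-negative slope is physically invalid (more template must amplify
    earlier) — the curve is returned flagged invalid with a warning, never
    silently used downstream.
    """
    if isinstance(series, CalibrationSeries):
        points = series.points
        assay = assay or series.assay
        genera = genera or (series.genus,)
    else:
        points = tuple(series)
        if len(points) < 2:
            raise ValueError("a calibration series needs at least 2 points")
    n = np.array([p[0] for p in points], dtype=float)
    ct = np.array([p[1] for p in points], dtype=float)
    x = np.log10(n)
    if np.unique(x).size < 2:
        raise ValueError("all nematode counts identical; slope is undefined")
    res = stats.linregress(x, ct)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 0.0
    valid = res.slope < 0
    if not valid:
        warnings.warn(
            f"calibration slope {res.slope:.3g} >= 0 for assay {assay!r}: "
            "curve flagged invalid",
            stacklevel=2,
        )
    return CalibrationCurve(
        assay=assay or "",
        a=float(res.slope),
        b=float(res.intercept),
        r2=r2,
        n_points=len(points),
        genera_pooled=tuple(genera),
        valid=valid,
    )


def predict_ct(curve: CalibrationCurve, n: float) -> float:
    """Expected Ct for a sample holding ``n`` target nematodes."""
    if n <= 0:
        raise ValueError(f"nematode count must be positive, got {n}")
    return curve.a * math.log10(n) + curve.b


def estimate_density(
    curve: CalibrationCurve, ct: float, no_signal_ct: float = NO_SIGNAL_CT
) -> DensityEstimate:
    """Invert the calibration line: N = 10^((Ct - b)/a).

    Ct at or above the no-signal cutoff (the protocol's cycle count) yields a
    censored zero rather than an extrapolated trace density.
    """
    if not curve.valid:
        raise ValueError(f"calibration curve for {curve.assay!r} is invalid")
    if ct >= no_signal_ct or math.isnan(ct):
        return DensityEstimate(0.0, censored=True)
    return DensityEstimate(10.0 ** ((ct - curve.b) / curve.a))


def pool_family_curve(
    genus_series: Iterable[CalibrationSeries],
    observed_genera: Iterable[str],
    assay: str | None = None,
) -> CalibrationCurve:
    """Refit one family line on the pooled points of observed genus series.

    Only series whose genus was seen in the microscopy samples contribute;
    the fitted curve records which genera were pooled.
    """
    observed = set(observed_genera)
    retained = [s for s in genus_series if s.genus in observed]
    if not retained:
        raise ValueError("no calibration series for any observed genus")
    points: list[tuple[float, float]] = []
    for s in retained:
        points.extend(s.points)
    return fit_calibration(
        points,
        assay=assay or retained[0].assay,
        genera=tuple(dict.fromkeys(s.genus for s in retained)),
    )


def read_series_csv(path) -> list[CalibrationSeries]:
    """Read calibration input CSV with columns assay, genus, n, ct."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    out = []
    for (assay, genus), sub in df.groupby(["assay", "genus"], sort=True):
        out.append(
            CalibrationSeries(
                assay=str(assay),
                genus=str(genus),
                points=tuple(zip(sub["n"].astype(float), sub["ct"].astype(float))),
            )
        )
    return out


def curves_to_frame(curves: Iterable[CalibrationCurve]):
    """Curve table mirroring the packaged assay-table columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "assay": c.assay,
                "a": c.a,
                "b": c.b,
                "r2": c.r2,
                "n_points": c.n_points,
                "n_genera": len(c.genera_pooled),
                "valid": c.valid,
            }
            for c in curves
        ]
    )
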