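"""Environmental-sample quantification: Ct panels to community profiles.

A soil sample contributes one Ct per assay plus the Ct of a spiked internal
standard (mammalian DNA) that tracks lysis/purification recovery. Densities
in individuals per 100 ml of elutriated soil come from inverting the per-
assay calibration line, scaled by the extraction-recovery correction and by
the dilution bookkeeping between calibration lysates (assayed at 1000x) and
field lysates (assayed at 50x), a factor of 20 by default — exposed in
configuration because the exact arithmetic is a modelling choice, not a
protocol constant.

Coverage against microscopy totals is diagnosed with a log-log regression:
the slope should be statistically indistinguishable from 1 and samples
should fall within ±0.5 log10 (half an order of magnitude) of the fitted
trend, measured as vertical distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import (
    NO_SIGNAL_CT,
    CalibrationCurve,
    DensityEstimate,
    estimate_density,
)

#: (calibration lysate dilution) / (field lysate dilution) = 1000 / 50
DEFAULT_DILUTION_ADJUSTMENT = 20.0


@dataclass
class SampleRecord:
    """One environmental sample's Ct panel."""

    sample_id: str
    site: str  # "field" | "forest"
    week: int  # weeks after the first sampling date
    cts: dict[str, float]  # assay -> Ct; NaN/None = no signal
    internal_standard_ct: float | None = None
    soil_volume_ml: float = 100.0

    def __post_init__(self) -> None:
        if self.site not in ("field", "forest"):
            raise ValueError(f"site must be field or forest, got {self.site!r}")
        if not 1 <= self.week <= 40:
            raise ValueError(f"week must be in [1, 40], got {self.week}")


@dataclass
class CommunityProfile:
    """Per-taxon density estimates for one sample (per 100 ml soil)."""

    sample_id: str
    densities: dict[str, float]
    censored: frozenset[str] = frozenset()
    correction_factor: float = 1.0

    @property
    def total(self) -> float:
        return float(sum(self.densities.values()))


@dataclass
class CoverageReport:
    slope: float
    intercept: float
    slope_se: float
    fraction_within_band: float
    studentized_residuals: np.ndarray
    n_used: int
    band_halfwidth: float = 0.5

    @property
    def flagged_outliers(self) -> np.ndarray:
        """Indices of samples with |externally studentized residual| > 2."""
        return np.flatnonzero(np.abs(self.studentized_residuals) > 2.0)


def correct_for_extraction(
    sample: SampleRecord,
    reference_standard_ct: float,
    efficiency_base: float = 2.0,
) -> float:
    """Fold-recovery correction from the internal-standard Ct.

    With perfect per-cycle doubling, each cycle of delay of the sample's
    internal standard relative to the reference preparation means half the
    DNA was recovered, so the correction factor is
    ``efficiency_base ** (internal_ct - reference_ct)``. A missing internal
    standard yields factor 1 with a warning.
    """
    if sample.internal_standard_ct is None or math.isnan(
        sample.internal_standard_ct
    ):
        warnings.warn(
            f"sample {sample.sample_id!r} lacks an internal-standard Ct; "
            "no extraction correction applied",
            stacklevel=2,
        )
        return 1.0
    if math.isnan(reference_standard_ct):
        raise ValueError("reference standard Ct must be finite")
    return float(
        efficiency_base ** (sample.internal_standard_ct - reference_standard_ct)
    )


def quantify_sample(
    sample: SampleRecord,
    curves: Mapping[str, CalibrationCurve],
    reference_standard_ct: float | None = None,
    dilution_adjustment: float = DEFAULT_DILUTION_ADJUSTMENT,
    efficiency_base: float = 2.0,
) -> CommunityProfile:
    """Convert one sample's Ct panel to per-taxon densities.

    density(taxon) = correction x dilution_adjustment x 10^((Ct - b)/a).
    No-signal readings (missing/NaN or Ct at the 60-cycle protocol limit)
    become censored zeros that still appear in the profile.
    """
    missing = sorted(set(sample.cts) - set(curves))
    if missing:
        raise KeyError(f"no calibration curve for assay(s): {missing}")
    factor = (
        correct_for_extraction(sample, reference_standard_ct, efficiency_base)
        if reference_standard_ct is not None
        else 1.0
    )
    densities: dict[str, float] = {}
    censored: set[str] = set()
    for assay in sorted(sample.cts):
        ct = sample.cts[assay]
        if ct is None or (isinstance(ct, float) and math.isnan(ct)):
            est = DensityEstimate(0.0, censored=True)
        else:
            est = estimate_density(curves[assay], float(ct))
        if est.censored:
            censored.add(assay)
            densities[assay] = 0.0
        else:
            densities[assay] = factor * dilution_adjustment * est.value
    return CommunityProfile(
        sample_id=sample.sample_id,
        densities=densities,
        censored=frozenset(censored),
        correction_factor=factor,
    )


def aggregate_guilds(
    profile: CommunityProfile, taxon_guilds: Mapping[str, str]
) -> dict[str, float]:
    """Sum densities into feeding guilds; guild sums conserve the total."""
    unmapped = sorted(set(profile.densities) - set(taxon_guilds))
    if unmapped:
        raise KeyError(f"taxa without a guild assignment: {unmapped}")
    sums: dict[str, float] = {}
    for taxon, density in profile.densities.items():
        guild = taxon_guilds[taxon]
        sums[guild] = sums.get(guild, 0.0) + density
    return sums


def coverage_check(
    pairs: Sequence[tuple[float, float]],
    band_halfwidth: float = 0.5,
) -> CoverageReport:
    """Log-log regression of qPCR totals on microscopy totals.

    Fits log10(qPCR) = slope * log10(microscopy) + intercept by OLS, reports
    the slope standard error, the fraction of samples within
    ±``band_halfwidth`` log10 units of the fitted line (vertical distance),
    and externally studentized residuals (|.| > 2 flags an outlier).
    Non-positive totals are excluded with a warning.
    """
    import statsmodels.api as sm

    clean = [(m, q) for m, q in pairs if m > 0 and q > 0]
    dropped = len(pairs) - len(clean)
    if dropped:
        warnings.warn(
            f"excluded {dropped} pair(s) with non-positive totals", stacklevel=2
        )
    if len(clean) < 3:
        raise ValueError("coverage check needs at least 3 positive pairs")
    x = np.log10([m for m, _ in clean])
    y = np.log10([q for _, q in clean])
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    resid = y - fit.fittedvalues
    if np.allclose(resid, 0.0):
        # a perfect fit has zero residual variance; studentization degenerates
        student = np.zeros_like(resid)
    elif len(clean) < 4:
        # external studentization needs a leave-one-out residual variance
        student = np.full_like(resid, np.nan)
    else:
        student = fit.get_influence().resid_studentized_external
    within = np.abs(resid) <= band_halfwidth
    return CoverageReport(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        fraction_within_band=float(within.mean()),
        studentized_residuals=np.asarray(student, dtype=float),
        n_used=len(clean),
        band_halfwidth=band_halfwidth,
    )


def profiles_to_frame(profiles: Iterable[CommunityProfile]):
    """Long-format DataFrame (sample_id, taxon, density, censored)."""
    import pandas as pd

    rows = []
    for p in profiles:
        for taxon, density in p.densities.items():
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "taxon": taxon,
                    "density": density,
                    "censored": taxon in p.censored,
                }
            )
    return pd.DataFrame(rows)
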