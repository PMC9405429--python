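"""δ¹³C measurement corrections: lipid normalisation and the Suess effect.

Skin lipids are depleted in ¹³C, so bulk-tissue δ¹³C of lipid-rich samples
(C:N mass ratio > 3.5) is biased low.  The correction here is calibrated on
a subset of samples measured both bulk and after chemical lipid extraction:
a bootstrapped ordinary-least-squares regression of the extraction offset

    Δδ¹³C = δ¹³C_lipid-extracted − δ¹³C_bulk  ~  β₀ + β₁ · C:N

whose across-replicate mean coefficients form the correction model.  Samples
at or below the C:N threshold keep their bulk value; δ¹⁵N is never altered
(lipid extraction perturbs nitrogen).

Separately, the oceanic Suess effect — the secular decline of δ¹³C from
fossil-fuel CO₂ — is removed by shifting each sample by a fixed per-year
rate to a common reference year.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .samples import IsotopeSample

__all__ = [
    "CalibrationPair",
    "CorrectionModel",
    "SuessParameters",
    "CalibrationError",
    "delta_from_ratio",
    "fit_lipid_correction",
    "apply_lipid_correction",
    "suess_correct",
    "correct_samples",
]

DEFAULT_CN_THRESHOLD = 3.5
DEFAULT_SUESS_RATE = -0.022  # ‰ per year, oceanic δ¹³C decline
DEFAULT_REFERENCE_YEAR = 2021


class CalibrationError(ValueError):
    """Calibration data are too few or degenerate to fit a correction."""


@dataclass(frozen=True)
class CalibrationPair:
    """Paired bulk / lipid-extracted δ¹³C measurement of one sample."""

    d13C_bulk: float
    d13C_lipid_extracted: float
    cn_ratio: float

    def __post_init__(self):
        if not self.cn_ratio > 0:
            raise ValueError(f"cn_ratio must be > 0, got {self.cn_ratio}")
        if not (np.isfinite(self.d13C_bulk) and np.isfinite(self.d13C_lipid_extracted)):
            raise ValueError("calibration δ values must be finite")

    @property
    def delta(self) -> float:
        return self.d13C_lipid_extracted - self.d13C_bulk


@dataclass
class CorrectionModel:
    """Bootstrap-averaged lipid-normalisation coefficients.

    ``beta0`` and ``beta1`` are the means of ``coefficient_draws``; the
    correction ``d13C_bulk + beta0 + beta1·cn_ratio`` applies only above
    ``cn_threshold``.
    """

    beta0: float
    beta1: float
    cn_threshold: float = DEFAULT_CN_THRESHOLD
    n_bootstrap: int = 10_000
    coefficient_draws: np.ndarray | None = None  # shape (n_bootstrap, 2)
    seed: int | None = None


@dataclass(frozen=True)
class SuessParameters:
    rate: float = DEFAULT_SUESS_RATE  # ‰ per year
    reference_year: int = DEFAULT_REFERENCE_YEAR


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Isotope delta notation: (R_sample/R_standard − 1) × 1000, in ‰."""
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS (intercept, slope)."""
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    return ym - slope * xm, slope


def fit_lipid_correction(
    pairs: Sequence[CalibrationPair],
    n_bootstrap: int = 10_000,
    seed: int = 0,
    cn_threshold: float = DEFAULT_CN_THRESHOLD,
) -> CorrectionModel:
    """Fit the lipid correction by averaged bootstrapped linear regression.

    Each replicate resamples the calibration pairs with replacement and fits
    Δδ¹³C on C:N by OLS; replicates whose resample has zero C:N variance are
    redrawn.  The model's coefficients are the across-replicate means.

    Requires ≥ 3 pairs spanning ≥ 2 distinct C:N values.
    """
    if len(pairs) < 3:
        raise CalibrationError(f"need >= 3 calibration pairs, got {len(pairs)}")
    x = np.array([p.cn_ratio for p in pairs])
    y = np.array([p.delta for p in pairs])
    if np.unique(x).size < 2:
        raise CalibrationError("calibration C:N ratios are all identical")

    rng = np.random.default_rng(seed)
    n = len(pairs)
    draws = np.empty((n_bootstrap, 2))
    filled = 0
    while filled < n_bootstrap:
        idx = rng.integers(0, n, size=(n_bootstrap - filled, n))
        xb = x[idx]
        ok = xb.min(axis=1) < xb.max(axis=1)  # redraw zero-variance resamples
        xb, yb = xb[ok], y[idx[ok]]
        if xb.shape[0] == 0:
            continue
        xm = xb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        slope = ((xb - xm) * (yb - ym)).sum(axis=1) / ((xb - xm) ** 2).sum(axis=1)
        inter = ym[:, 0] - slope * xm[:, 0]
        m = xb.shape[0]
        draws[filled : filled + m, 0] = inter
        draws[filled : filled + m, 1] = slope
        filled += m

    b0, b1 = draws.mean(axis=0)
    return CorrectionModel(
        beta0=float(b0),
        beta1=float(b1),
        cn_threshold=cn_threshold,
        n_bootstrap=n_bootstrap,
        coefficient_draws=draws,
        seed=seed,
    )


def apply_lipid_correction(sample: IsotopeSample, model: CorrectionModel) -> float:
    """Lipid-normalised δ¹³C for one sample.

    Above the C:N threshold (strictly) the fitted offset is added; at or
    below it the bulk value passes through unchanged.  δ¹⁵N is untouched by
    construction — this function only ever returns a carbon value.
    """
    if sample.cn_ratio > model.cn_threshold:
        return sample.d13C_bulk + model.beta0 + model.beta1 * sample.cn_ratio
    return sample.d13C_bulk


def suess_correct(d13C: float, year: int, params: SuessParameters = SuessParameters()) -> float:
    """Standardise δ¹³C to the reference year at the configured annual rate.

    With the default rate of −0.022‰ yr⁻¹ a sample from an earlier year is
    shifted downward by rate × (reference_year − year), aligning it with the
    reference-year oceanic baseline.
    """
    if year > params.reference_year:
        raise ValueError(f"sample year {year} is after reference year {params.reference_year}")
    return d13C + params.rate * (params.reference_year - year)


def correct_samples(
    samples: Sequence[IsotopeSample],
    model: CorrectionModel,
    suess: SuessParameters = SuessParameters(),
) -> list[IsotopeSample]:
    """Run both corrections in order (lipid, then Suess) and populate
    ``d13C_corrected`` on copies of the input records."""
    out = []
    for s in samples:
        lipid_free = apply_lipid_correction(s, model)
        out.append(replace(s, d13C_corrected=suess_correct(lipid_free, s.year, suess)))
    return out
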