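"""Allometric length–weight relationship W = a * L^b.

Fitted by ordinary least squares on (log10 L, log10 W) — the universal
fisheries convention. The exponent b classifies growth: isometric when b is
not significantly different from 3, otherwise positive (b > 3) or negative
(b < 3) allometric.

Lengths are fork lengths in mm by default (the unit measured at sea); the
coefficient ``a`` therefore carries units g * mm^-b. Refitting in cm
rescales ``a`` by exactly 10^b and leaves b and r-squared unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import DataError
from .simulate import FishRecord

__all__ = [
    "LengthWeightModel",
    "LengthWeightResults",
    "fit_length_weight",
    "classify_allometry",
    "format_equation",
]


@dataclass(frozen=True)
class LengthWeightResults:
    a: float
    b: float
    r_squared: float
    n: int
    se_b: float
    p_value_b_eq_3: float
    length_unit: str = "mm"

    def growth_type(self, alpha_level: float = 0.05) -> str:
        return classify_allometry(self, alpha_level)

    def summary(self) -> str:
        lines = [
            "Length-weight fit (log10 OLS)",
            f"  {format_equation(self.a, self.b)}   [L in {self.length_unit}]",
            f"  r^2 = {self.r_squared:.4f}, n = {self.n}",
            f"  H0 b=3: p = {self.p_value_b_eq_3:.4g} -> {self.growth_type()}",
        ]
        return "\n".join(lines)


class LengthWeightModel:
    """OLS model for the allometric length–weight relationship.

    Parameters
    ----------
    lengths, weights : sequences of positive floats
        Paired fork lengths and wet weights.
    length_unit : str
        Unit label carried through to reporting (default mm).
    """

    def __init__(self, lengths: Sequence[float], weights: Sequence[float],
                 length_unit: str = "mm"):
        lengths = np.asarray(lengths, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if lengths.shape != weights.shape or lengths.ndim != 1:
            raise DataError("lengths and weights must be 1-D and paired")
        if lengths.size < 3:
            raise DataError("need at least 3 records")
        if np.any(lengths <= 0) or np.any(weights <= 0):
            raise DataError("lengths and weights must be positive")
        if np.ptp(lengths) == 0:
            raise DataError("zero length variance: fit is degenerate")
        self.lengths = lengths
        self.weights = weights
        self.length_unit = length_unit

    @classmethod
    def from_records(cls, records: Iterable[FishRecord], **kwargs) -> "LengthWeightModel":
        records = list(records)
        return cls([r.fork_length_mm for r in records],
                   [r.weight_g for r in records], **kwargs)

    def fit(self) -> LengthWeightResults:
        x = sm.add_constant(np.log10(self.lengths))
        res = sm.OLS(np.log10(self.weights), x).fit()
        b = float(res.params[1])
        se_b = float(res.bse[1])
        if se_b > 0:
            t = (b - 3.0) / se_b
            p = float(2.0 * stats.t.sf(abs(t), df=res.df_resid))
        else:
            p = 0.0 if b != 3.0 else 1.0
        return LengthWeightResults(
            a=float(10.0 ** res.params[0]),
            b=b,
            r_squared=float(res.rsquared),
            n=int(self.lengths.size),
            se_b=se_b,
            p_value_b_eq_3=p,
            length_unit=self.length_unit,
        )


def fit_length_weight(records: Iterable[FishRecord], **kwargs) -> LengthWeightResults:
    """Convenience wrapper: fit from :class:`FishRecord` objects."""
    return LengthWeightModel.from_records(records, **kwargs).fit()


def classify_allometry(fit: LengthWeightResults, alpha_level: float = 0.05) -> str:
    """Growth-type label from the b = 3 significance test."""
    if fit.p_value_b_eq_3 >= alpha_level or fit.b == 3.0:
        return "isometric"
    return "positive allometric" if fit.b > 3.0 else "negative allometric"


def format_equation(a: float, b: float) -> str:
    """Render ``W = a L^b`` the way assessment reports print it, e.g.
    ``W = 2.67e-07 * L^3.00``."""
    return f"W = {a:.2e} * L^{b:.2f}"
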