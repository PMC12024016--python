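"""Mortality estimation: catch curve Z, empirical M, F = Z - M, E = F/Z.

The length-converted catch curve maps length bins to relative ages through
the inverse VBGF, t(L) = t0 - (1/K) ln(1 - L/Linf), and regresses
ln(N_i / dt_i) on the age at the bin midpoint over the descending limb;
total mortality Z is minus the slope. Natural mortality M comes from the
empirical regression on Linf, K and the mean water temperature T:

    ln M = -0.0152 - 0.279 ln Linf + 0.654 ln K + 0.463 ln T
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DataError, ParameterError
from .growth import VBGFParams
from .tables import LengthFrequencyTable

__all__ = [
    "CatchCurveResults",
    "CatchCurveModel",
    "MortalityEstimates",
    "length_converted_catch_curve",
    "pauly_natural_mortality",
    "fishing_mortality",
    "exploitation_rate",
    "estimate_mortality",
]


@dataclass
class CatchCurveResults:
    """Catch-curve regression: Z = -slope over the descending limb."""

    z: float
    intercept_c: float
    slope_d: float
    t_mid: np.ndarray  # relative age per usable bin
    ln_n_dt: np.ndarray  # ln(N_i / dt_i) per usable bin
    used_mask: np.ndarray  # which of the usable points entered the regression
    r_squared: float

    def summary(self) -> str:
        return (
            "Length-converted catch curve\n"
            f"  Z = {self.z:.3f} /yr (slope {self.slope_d:.3f}, "
            f"intercept {self.intercept_c:.3f}, r^2 = {self.r_squared:.3f})\n"
            f"  points used: {int(self.used_mask.sum())}/{self.used_mask.size}"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t_mid[~self.used_mask], self.ln_n_dt[~self.used_mask], "o",
                mfc="none", color="grey", label="excluded")
        ax.plot(self.t_mid[self.used_mask], self.ln_n_dt[self.used_mask], "o",
                color="C0", label="used")
        tt = np.linspace(self.t_mid.min(), self.t_mid.max(), 50)
        ax.plot(tt, self.intercept_c + self.slope_d * tt, "C1-",
                label=f"Z = {self.z:.2f}")
        ax.set_xlabel("relative age (yr)")
        ax.set_ylabel("ln(N / dt)")
        ax.legend()
        return ax


class CatchCurveModel:
    """Length-converted catch curve for one table and growth parameter set.

    Descending-limb selection (both knobs configurable): bins up to and
    including the modal ln(N/dt) point, plus ``drop_after_peak`` further
    bins, are excluded as not fully selected; bins with midpoint above
    ``max_length_frac * Linf`` are excluded because the age conversion
    becomes unstable near Linf.
    """

    def __init__(self, table: LengthFrequencyTable, params: VBGFParams):
        self.table = table
        self.params = params

    def fit(self, drop_after_peak: int = 1, max_length_frac: float = 0.95
            ) -> CatchCurveResults:
        linf, k, t0 = self.params.linf, self.params.k, self.params.t0
        edges = self.table.edges_cm
        counts = self.table.counts.astype(float)
        mids = self.table.mid_cm
        usable = (edges[1:] < linf) & (counts > 0) & (mids <= max_length_frac * linf)
        n_excluded = int(((edges[1:] >= linf) & (counts > 0)).sum())
        if n_excluded:
            warnings.warn(
                f"{n_excluded} non-empty bins at or above Linf excluded from the "
                "catch curve", stacklevel=2)
        if usable.sum() < 3:
            raise DataError("fewer than 3 usable catch-curve points")

        def t_of(length):
            return t0 - np.log(1.0 - length / linf) / k

        t_mid = t_of(mids[usable])
        dt = t_of(edges[1:][usable]) - t_of(edges[:-1][usable])
        y = np.log(counts[usable] / dt)
        used = np.ones(t_mid.size, dtype=bool)
        peak = int(np.argmax(y))
        used[: min(peak + 1 + drop_after_peak, t_mid.size)] = False
        if used.sum() < 3:
            raise DataError("fewer than 3 points on the descending limb")
        reg = stats.linregress(t_mid[used], y[used])
        return CatchCurveResults(
            z=float(-reg.slope),
            intercept_c=float(reg.intercept),
            slope_d=float(reg.slope),
            t_mid=t_mid,
            ln_n_dt=y,
            used_mask=used,
            r_squared=float(reg.rvalue**2),
        )


def length_converted_catch_curve(
    table: LengthFrequencyTable, params: VBGFParams, **kwargs
) -> CatchCurveResults:
    """Functional wrapper around :class:`CatchCurveModel`."""
    return CatchCurveModel(table, params).fit(**kwargs)


def pauly_natural_mortality(linf: float, k: float, temp_c: float) -> float:
    """Empirical natural mortality M(Linf, K, T); increasing in K and T,
    decreasing in Linf."""
    if not (linf > 0 and k > 0 and temp_c > 0):
        raise ParameterError("linf, k and temp_c must be positive")
    return float(np.exp(-0.0152 - 0.279 * np.log(linf) + 0.654 * np.log(k)
                        + 0.463 * np.log(temp_c)))


def fishing_mortality(z: float, m: float) -> float:
    """F = Z - M. A negative value (estimation noise) is returned as-is but
    flagged with a warning rather than silently clipped."""
    if not (np.isfinite(z) and np.isfinite(m)):
        raise ParameterError("z and m must be finite")
    f = z - m
    if f < 0:
        warnings.warn(f"negative fishing mortality F = {f:.3f} (Z < M); "
                      "likely estimation noise", stacklevel=2)
    return float(f)


def exploitation_rate(f: float, z: float) -> float:
    """E = F/Z; the classical E < 0.5 'not overfished' heuristic is exactly
    F < M."""
    if not z > 0:
        raise ParameterError("z must be positive")
    return float(f / z)


@dataclass(frozen=True)
class MortalityEstimates:
    """Bundle of Z, M, F, E for one year (T in deg C used for M)."""

    z: float
    m: float
    f: float
    e: float
    mean_temp: float


def estimate_mortality(
    table: LengthFrequencyTable,
    params: VBGFParams,
    temp_c: float,
    **catch_curve_kwargs,
) -> tuple[MortalityEstimates, CatchCurveResults]:
    """Catch-curve Z, empirical M, then F and E, in one call."""
    cc = length_converted_catch_curve(table, params, **catch_curve_kwargs)
    m = pauly_natural_mortality(params.linf, params.k, temp_c)
    f = fishing_mortality(cc.z, m)
    e = exploitation_rate(f, cc.z)
    return MortalityEstimates(z=cc.z, m=m, f=f, e=e, mean_temp=temp_c), cc
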