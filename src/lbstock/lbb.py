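"""Length-based Bayesian biomass estimation (LBB) and per-recruit reference
points.

Model
-----
LBB fits an equilibrium length-structure model to one year's catch
length-frequency sample. With a logistic retention ogive
``S(L) = 1 / (1 + exp(-alpha * (L - Lc)))``, the relative number of fish
surviving to the lower edge of bin i+1 follows the master recursion

    N_{i+1} = N_i * ((Linf - L_{i+1}) / (Linf - L_i)) ** (M/K + F/K * S(L_i))

and the expected catch proportion in bin i is ``C_i = N_i * S(L_i)``
normalized to sum to one. The five free parameters (Linf, Lc, alpha, M/K,
F/K) are estimated by Metropolis-Hastings sampling of a multinomial
likelihood under log-normal priors; the posterior point estimate is the
median, intervals are central 95%.

Reference points
----------------
From the posterior (Linf, Lc, M/K, F/K) the Beverton-Holt relative
per-recruit system gives, with x = 1 - Lc/Linf, Z/K = M/K + F/K and
F/M = (F/K)/(M/K):

    Y'/R    = F/M / (1 + F/M) * x**(M/K)
              * [1 - 3x/(1 + 1/(Z/K)) + 3x^2/(1 + 2/(Z/K)) - x^3/(1 + 3/(Z/K))]
    CPUE'/R = Y'/R / (F/M)          (the bracket form directly when F = 0)
    B0'/R   = x**(M/K) * [same bracket with Z/K replaced by M/K]
    B/B0    = CPUE'/R / B0'/R

``Bmsy/B0`` is the B/B0 obtained under the proxy assumptions F = M and
Lc = Lc-opt, and B/Bmsy = (B/B0) / (Bmsy/B0). Length-based optima:

    Lopt   = Linf * 3 / (3 + M/K)
    Lc-opt = Linf * (2 + 3 F/M) / ((1 + F/M) * (3 + M/K))

Length indicators (L95th/Linf, Lmean/Lc-opt, Lc/Lc-opt) and a four-way
status label (healthy / fully exploited / overfished / collapsed) complete
the assessment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .exceptions import ConvergenceWarning, DataError, ParameterError
from .simulate import logistic_selectivity
from .tables import LengthFrequencyTable

__all__ = [
    "LBBPriors",
    "LBBModel",
    "LBBResults",
    "ReferencePoints",
    "LengthIndicators",
    "expected_catch_proportions",
    "fit_lbb",
    "l_opt",
    "lc_opt",
    "relative_yield_per_recruit",
    "bmsy_proxy",
    "b_over_bmsy",
    "compute_reference_points",
    "length_indicators",
    "classify_status",
]

_PARAM_NAMES = ("linf", "lc", "alpha", "mk", "fk")


# ---------------------------------------------------------------------------
# expected catch composition
# ---------------------------------------------------------------------------


def expected_catch_proportions(
    linf: float, lc: float, alpha: float, mk: float, fk: float,
    bin_edges_cm: np.ndarray,
) -> np.ndarray:
    """Expected catch proportion per bin under the LBB master recursion.

    ``bin_edges_cm`` are the ``n_bins + 1`` ascending edges; every edge must
    lie below Linf. Output is non-negative and sums to 1.
    """
    edges = np.asarray(bin_edges_cm, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ParameterError("bin edges must be strictly ascending")
    if edges[-1] >= linf:
        raise ParameterError("all bin edges must lie below linf")
    if not (mk > 0 and fk >= 0 and alpha > 0 and 0 <= lc < linf):
        raise ParameterError("invalid LBB parameters")
    lower, upper = edges[:-1], edges[1:]
    sel = logistic_selectivity(lower, lc, alpha)
    expo = mk + fk * sel
    log_ratio = np.log((linf - upper) / (linf - lower))
    log_n = np.concatenate([[0.0], np.cumsum(expo * log_ratio)[:-1]])
    catch = np.exp(log_n) * sel
    total = catch.sum()
    if not total > 0:
        raise ParameterError("expected catch vanishes everywhere (check lc, alpha)")
    return catch / total


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LBBPriors:
    """Log-normal prior means and CVs for the five LBB parameters.

    CVs default to 10% for the length parameters (Linf, Lc) and 30% for the
    shape/mortality parameters (alpha, M/K, F/K). A CV of exactly 0 pins the
    parameter at its prior mean (it is excluded from sampling).
    """

    linf_prior: float
    lc_prior: float
    alpha_prior: float = 10.0
    mk_prior: float = 1.5
    fk_prior: float = 0.5
    linf_cv: float = 0.10
    lc_cv: float = 0.10
    alpha_cv: float = 0.30
    mk_cv: float = 0.30
    fk_cv: float = 0.30

    def __post_init__(self) -> None:
        for name in ("linf_prior", "lc_prior", "alpha_prior", "mk_prior", "fk_prior"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("linf_cv", "lc_cv", "alpha_cv", "mk_cv", "fk_cv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @classmethod
    def from_table(cls, table: LengthFrequencyTable, **overrides) -> "LBBPriors":
        """Data-driven defaults: Linf prior at max observed length / 0.95 and
        Lc prior at the mode of the sample; the rest at generic values."""
        nz = table.counts > 0
        linf0 = float(table.mid_cm[nz].max() / 0.95)
        lc0 = float(table.mid_cm[int(np.argmax(table.counts))])
        defaults = dict(linf_prior=linf0, lc_prior=min(lc0, 0.9 * linf0))
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def means(self) -> np.ndarray:
        return np.array([self.linf_prior, self.lc_prior, self.alpha_prior,
                         self.mk_prior, self.fk_prior])

    @property
    def cvs(self) -> np.ndarray:
        return np.array([self.linf_cv, self.lc_cv, self.alpha_cv,
                         self.mk_cv, self.fk_cv])


# ---------------------------------------------------------------------------
# posterior sampling
# ---------------------------------------------------------------------------


@dataclass
class LBBResults:
    """Posterior summary of an LBB fit.

    Point estimates are posterior medians; ``ci`` maps parameter names to
    central 95% intervals. Derived ratios: Z/K = M/K + F/K,
    F/M = (F/K)/(M/K), E = (F/K)/(Z/K) = F/M / (1 + F/M).
    """

    linf: float
    lc: float
    alpha: float
    mk: float
    fk: float
    ci: dict[str, tuple[float, float]]
    acceptance_rate: float
    ess: dict[str, float]
    converged: bool
    priors: LBBPriors
    samples: np.ndarray = field(repr=False)  # (n_kept, 5), original scale
    year: int | None = None

    @property
    def zk(self) -> float:
        return self.mk + self.fk

    @property
    def fm(self) -> float:
        return self.fk / self.mk

    @property
    def e(self) -> float:
        return self.fk / self.zk

    def reference_points(self) -> "ReferencePoints":
        return compute_reference_points(self.linf, self.lc, self.mk, self.fk)

    def length_indicators(self, table: LengthFrequencyTable) -> "LengthIndicators":
        return length_indicators(table, self.linf, self.lc,
                                 self.reference_points().lc_opt)

    def status(self, **kwargs) -> str:
        rp = self.reference_points()
        return classify_status(rp.bb0, rp.bbmsy, self.fm, **kwargs)

    def summary(self) -> str:
        rp = self.reference_points()
        rows = [
            ("Linf (cm)", self.linf, self.ci["linf"]),
            ("Lc (cm)", self.lc, self.ci["lc"]),
            ("alpha (1/cm)", self.alpha, self.ci["alpha"]),
            ("M/K", self.mk, self.ci["mk"]),
            ("F/K", self.fk, self.ci["fk"]),
        ]
        head = f"LBB fit{f' (year {self.year})' if self.year is not None else ''}"
        lines = [head, "  parameter        median   95% interval"]
        for name, med, (lo, hi) in rows:
            lines.append(f"  {name:<15} {med:8.3f}   [{lo:.3f}, {hi:.3f}]")
        lines += [
            f"  Z/K = {self.zk:.2f}, F/M = {self.fm:.2f}, E = {self.e:.2f}",
            f"  Lopt = {rp.l_opt:.0f} cm, Lc-opt = {rp.lc_opt:.0f} cm",
            f"  B/B0 = {rp.bb0:.2f}, Bmsy/B0 = {rp.bmsy_b0:.3f}, "
            f"B/Bmsy = {rp.bbmsy:.1f}",
            f"  status: {self.status()}",
            f"  acceptance {self.acceptance_rate:.2f}, "
            f"min ESS {min(self.ess.values()):.0f}"
            + ("" if self.converged else "  [NOT CONVERGED]"),
        ]
        return "\n".join(lines)

    def plot_fit(self, table: LengthFrequencyTable, ax=None):
        """Observed proportions vs posterior-median expected proportions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        obs = table.counts / table.counts.sum()
        ax.bar(table.mid_cm, obs, width=table.bin_width / 10.0 * 0.9,
               color="lightsteelblue", label="observed")
        ok = table.edges_cm[-1] < self.linf
        edges = table.edges_cm if ok else table.edges_cm[table.edges_cm < self.linf]
        exp = expected_catch_proportions(self.linf, self.lc, self.alpha,
                                         self.mk, self.fk, edges)
        mids = 0.5 * (edges[:-1] + edges[1:])
        ax.plot(mids, exp * (obs.sum() / exp.sum()), "C1-", lw=2, label="LBB fit")
        ax.set_xlabel("fork length (cm)")
        ax.set_ylabel("proportion")
        ax.legend()
        return ax


class LBBModel:
    """Bayesian length-based biomass model for one year's LF table.

    Parameters
    ----------
    table : LengthFrequencyTable
        Catch length composition; at least 10 non-empty bins are required
        (length-based estimates degrade badly below that).
    priors : LBBPriors, optional
        When omitted, data-driven defaults are derived from the table
        (:meth:`LBBPriors.from_table`) and the choice is logged.
    """

    def __init__(self, table: LengthFrequencyTable, priors: LBBPriors | None = None):
        if int((table.counts > 0).sum()) < 10:
            raise DataError("LBB needs at least 10 non-empty length bins")
        self.table = table
        if priors is None:
            priors = LBBPriors.from_table(table)
            import logging

            logging.getLogger(__name__).info(
                "no priors supplied; data-driven defaults: Linf=%.1f, Lc=%.1f",
                priors.linf_prior, priors.lc_prior)
        self.priors = priors

    # -- log-posterior ------------------------------------------------------
    def _log_posterior(self, log_theta: np.ndarray, free: np.ndarray,
                       log_mu: np.ndarray, sigma: np.ndarray,
                       counts: np.ndarray, edges: np.ndarray) -> float:
        theta = np.exp(log_theta)
        linf, lc, alpha, mk, fk = theta
        if not (lc < linf and edges[-1] < linf):
            return -np.inf
        lp = -0.5 * np.sum(((log_theta[free] - log_mu[free]) / sigma[free]) ** 2)
        try:
            p = expected_catch_proportions(linf, lc, alpha, mk, fk, edges)
        except ParameterError:
            return -np.inf
        p = np.clip(p, 1e-300, None)
        return float(lp + np.sum(counts * np.log(p)))

    def fit(
        self,
        chains: int = 3,
        iterations: int = 20_000,
        burn_in: int = 5_000,
        seed: int = 0,
        thin: int = 5,
        ess_floor: float = 200.0,
    ) -> LBBResults:
        """Adaptive random-walk Metropolis-Hastings fit.

        The proposal is a Gaussian step on log-parameters. During burn-in the
        proposal covariance is adapted: first a diagonal scale tuned toward a
        30% acceptance rate, then the empirical covariance of the burn-in
        draws (the posterior has a strong Linf-M/K ridge that a diagonal
        proposal cannot traverse). The proposal is frozen at the end of
        burn-in, so the retained chain is a valid fixed-kernel MH sampler.
        Deterministic given ``seed``. A result whose minimum effective sample
        size falls below ``ess_floor`` is returned flagged
        (``converged=False``) with a :class:`ConvergenceWarning`.
        """
        if burn_in >= iterations:
            raise ParameterError("burn_in must be smaller than iterations")
        counts = self.table.counts.astype(float)
        # restrict to bins strictly below the smallest credible Linf
        edges_all = self.table.edges_cm
        mu = self.priors.means
        cv = self.priors.cvs
        free = cv > 0
        if not free.any():
            theta = mu.copy()
            samples = np.tile(theta, (1, 1))
            ci = {n: (float(v), float(v)) for n, v in zip(_PARAM_NAMES, theta)}
            return LBBResults(*theta, ci=ci, acceptance_rate=1.0,
                              ess={n: math.inf for n in _PARAM_NAMES},
                              converged=True, priors=self.priors,
                              samples=samples, year=self.table.year)
        # trailing empty bins carry no likelihood but would force Linf above
        # their top edge; drop them so the prior support is not truncated
        edges = edges_all
        trailing_empty = np.cumprod(counts[::-1] == 0)[::-1].astype(bool)
        if trailing_empty.any():
            first_keep = np.nonzero(~trailing_empty)[0][-1] + 1
            edges = edges_all[: first_keep + 1]
            counts = counts[:first_keep]
        log_mu = np.log(mu)
        sigma = np.where(free, np.maximum(cv, 1e-6), 1.0)
        rng = np.random.default_rng(seed)
        n_free = int(free.sum())
        free_idx = np.nonzero(free)[0]
        kept_chains = []
        acc_total = 0
        n_total = 0
        # the recursion needs Linf above the top occupied bin edge, so start
        # the chains there even when the prior mean sits below it
        log_start = log_mu.copy()
        if free[0]:
            log_start[0] = max(log_mu[0], math.log(1.02 * edges[-1]))
        for c in range(chains):
            x = log_start + np.where(free, 0.05 * sigma * rng.standard_normal(5), 0.0)
            # make sure the start is feasible
            for _ in range(200):
                lp = self._log_posterior(x, free, log_mu, sigma, counts, edges)
                if np.isfinite(lp):
                    break
                x = log_start + np.where(free, 0.05 * sigma * rng.standard_normal(5), 0.0)
            else:
                raise DataError("could not find a feasible MCMC start point")
            scale = 1.0
            chol = np.diag(0.25 * sigma[free_idx] / math.sqrt(n_free))
            acc_win = 0
            burn_draws = np.empty((burn_in, n_free))
            draws = []
            for it in range(iterations):
                prop = x.copy()
                prop[free_idx] += scale * (chol @ rng.standard_normal(n_free))
                lp_prop = self._log_posterior(prop, free, log_mu, sigma, counts, edges)
                if np.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    acc_win += 1
                    if it >= burn_in:
                        acc_total += 1
                if it < burn_in:
                    burn_draws[it] = x[free_idx]
                    if (it + 1) % 100 == 0:  # adapt only during burn-in
                        scale *= math.exp((acc_win / 100.0 - 0.30))
                        scale = float(np.clip(scale, 1e-3, 1e3))
                        acc_win = 0
                        # switch to the empirical covariance once enough
                        # burn-in history exists to estimate the ridge
                        if it + 1 >= max(500, 50 * n_free):
                            cov = np.cov(burn_draws[it // 2: it + 1].T)
                            cov = np.atleast_2d(cov) + 1e-10 * np.eye(n_free)
                            try:
                                chol = (2.38 / math.sqrt(n_free)) * np.linalg.cholesky(cov)
                                scale = float(np.clip(scale, 0.2, 5.0))
                            except np.linalg.LinAlgError:
                                pass
                else:
                    n_total += 1
                    if (it - burn_in) % thin == 0:
                        draws.append(np.exp(x))
            kept_chains.append(np.array(draws))
        all_draws = np.stack(kept_chains)  # (chains, n_kept, 5)
        flat = all_draws.reshape(-1, 5)
        med = np.median(flat, axis=0)
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        ci = {n: (float(a), float(b)) for n, a, b in zip(_PARAM_NAMES, lo, hi)}
        ess = {}
        import arviz as az

        for j, name in enumerate(_PARAM_NAMES):
            if free[j]:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ess[name] = float(az.ess(all_draws[:, :, j]))
            else:
                ess[name] = math.inf
        converged = min(ess.values()) >= ess_floor
        if not converged:
            warnings.warn(
                f"LBB fit flagged: min ESS {min(ess.values()):.0f} < {ess_floor:.0f}",
                ConvergenceWarning, stacklevel=2)
        return LBBResults(
            linf=float(med[0]), lc=float(med[1]), alpha=float(med[2]),
            mk=float(med[3]), fk=float(med[4]),
            ci=ci,
            acceptance_rate=acc_total / max(n_total, 1),
            ess=ess,
            converged=converged,
            priors=self.priors,
            samples=flat,
            year=self.table.year,
        )


def fit_lbb(table: LengthFrequencyTable, priors: LBBPriors | None = None,
            **mcmc) -> LBBResults:
    """Functional wrapper around :class:`LBBModel`."""
    return LBBModel(table, priors).fit(**mcmc)


# ---------------------------------------------------------------------------
# per-recruit reference points
# ---------------------------------------------------------------------------


class PerRecruit(NamedTuple):
    ypr: float
    cpue_r: float
    b0_r: float
    bb0: float


def _bh_bracket(x: float, zk: float) -> float:
    return (1.0 - 3.0 * x / (1.0 + 1.0 / zk) + 3.0 * x**2 / (1.0 + 2.0 / zk)
            - x**3 / (1.0 + 3.0 / zk))


def relative_yield_per_recruit(linf: float, lc: float, mk: float, fk: float
                               ) -> PerRecruit:
    """Beverton-Holt relative per-recruit quantities (see module docstring).

    ``bb0 = 1`` exactly when ``fk = 0`` (the fished and unfished stocks
    coincide).
    """
    if not (0 < lc < linf):
        raise ParameterError("need 0 < lc < linf")
    if not (mk > 0 and fk >= 0):
        raise ParameterError("need mk > 0 and fk >= 0")
    x = 1.0 - lc / linf
    zk = mk + fk
    fm = fk / mk
    xm = x**mk
    cpue_r = xm * _bh_bracket(x, zk) / (1.0 + fm)
    ypr = fm * cpue_r
    b0_r = xm * _bh_bracket(x, mk)
    return PerRecruit(ypr=float(ypr), cpue_r=float(cpue_r), b0_r=float(b0_r),
                      bb0=float(cpue_r / b0_r))


def l_opt(linf: float, mk: float) -> float:
    """Length of maximum unexploited cohort biomass, Linf * 3/(3 + M/K)."""
    if not (linf > 0 and mk > 0):
        raise ParameterError("linf and mk must be positive")
    return float(linf * 3.0 / (3.0 + mk))


def lc_opt(linf: float, fm: float, mk: float) -> float:
    """Optimal length at first capture,
    Linf * (2 + 3 F/M) / ((1 + F/M)(3 + M/K))."""
    if not (linf > 0 and mk > 0 and fm >= 0):
        raise ParameterError("linf, mk must be positive and fm >= 0")
    return float(linf * (2.0 + 3.0 * fm) / ((1.0 + fm) * (3.0 + mk)))


def bmsy_proxy(linf: float, mk: float) -> float:
    """Bmsy/B0 proxy: B/B0 evaluated at F = M and Lc = Lc-opt(F/M = 1)."""
    lc = lc_opt(linf, 1.0, mk)
    return relative_yield_per_recruit(linf, lc, mk, mk).bb0


def b_over_bmsy(bb0: float, bmsy_b0: float) -> float:
    """B/Bmsy = (B/B0) / (Bmsy/B0)."""
    if not bmsy_b0 > 0:
        raise ParameterError("bmsy_b0 must be positive")
    return float(bb0 / bmsy_b0)


@dataclass(frozen=True)
class ReferencePoints:
    l_opt: float
    lc_opt: float
    ypr: float
    cpue_r: float
    b0_r: float
    bb0: float
    bmsy_b0: float
    bbmsy: float


def compute_reference_points(linf: float, lc: float, mk: float, fk: float
                             ) -> ReferencePoints:
    """Full Lopt / Lc-opt / per-recruit / B-ratio chain from LBB outputs."""
    pr = relative_yield_per_recruit(linf, lc, mk, fk)
    bmsy_b0 = bmsy_proxy(linf, mk)
    return ReferencePoints(
        l_opt=l_opt(linf, mk),
        lc_opt=lc_opt(linf, fk / mk, mk),
        ypr=pr.ypr,
        cpue_r=pr.cpue_r,
        b0_r=pr.b0_r,
        bb0=pr.bb0,
        bmsy_b0=bmsy_b0,
        bbmsy=b_over_bmsy(pr.bb0, bmsy_b0),
    )


# ---------------------------------------------------------------------------
# length indicators and status
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthIndicators:
    l95th: float
    l95_over_linf: float
    lmean: float
    lmean_over_lcopt: float
    lc_over_lcopt: float


def _weighted_percentile(table: LengthFrequencyTable, q: float) -> float:
    """Count-weighted percentile of length with linear interpolation within
    bins (each fish spread uniformly over its bin)."""
    edges = table.edges_cm
    cum = np.concatenate([[0.0], np.cumsum(table.counts)]).astype(float)
    if cum[-1] == 0:
        raise DataError("all counts are zero")
    target = q / 100.0 * cum[-1]
    return float(np.interp(target, cum, edges))


def length_indicators(table: LengthFrequencyTable, linf: float, lc: float,
                      lcopt: float) -> LengthIndicators:
    """L95th, Lmean (over bins with midpoint above Lc) and their ratios."""
    if table.n_fish == 0:
        raise DataError("all counts are zero")
    l95 = _weighted_percentile(table, 95.0)
    mids = table.mid_cm
    above = mids > lc
    if not above.any() or table.counts[above].sum() == 0:
        raise DataError("no fish above Lc: Lmean undefined")
    lmean = float(np.average(mids[above], weights=table.counts[above]))
    return LengthIndicators(
        l95th=l95,
        l95_over_linf=l95 / linf,
        lmean=lmean,
        lmean_over_lcopt=lmean / lcopt,
        lc_over_lcopt=lc / lcopt,
    )


def classify_status(bb0: float, bbmsy: float, fm: float,
                    healthy_bbmsy: float = 1.0,
                    fully_exploited_bbmsy: float = 0.5,
                    overfished_bbmsy: float = 0.2,
                    healthy_fm: float = 1.0) -> str:
    """Four-way stock status from B/Bmsy and F/M.

    Boundaries are inclusive upward: B/Bmsy = 1 with F/M = 1 is 'healthy'.
    A stock with B/Bmsy >= 1 but F/M > 1 is labelled 'fully exploited'
    (biomass still high, fishing pressure above the proxy MSY level).
    """
    for v in (bb0, bbmsy, fm):
        if not np.isfinite(v):
            raise ParameterError("status inputs must be finite")
    if bbmsy >= healthy_bbmsy:
        return "healthy" if fm <= healthy_fm else "fully exploited"
    if bbmsy >= fully_exploited_bbmsy:
        return "fully exploited"
    if bbmsy >= overfished_bbmsy:
        return "overfished"
    return "collapsed"
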