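"""Synthetic fishery data with the structure the assessment assumes.

The raw logs behind a high-seas purse-seine fishery are commercially
sensitive and rarely published, so every stage of the pipeline is exercised
against simulated data generated here:

* equilibrium length structure under von Bertalanffy growth, two-phase
  mortality (natural everywhere, fishing only on selected lengths) and a
  logistic selection ogive — the generative inverse of the length-based
  Bayesian biomass (LBB) model;
* an age-structured variant with annual recruitment pulses, which produces
  the modal (cohort) structure that ELEFAN growth analysis requires;
* allometric length–weight records with multiplicative lognormal noise;
* purse-seine logbooks concentrated in the 35–45° N, 145–160° E study box
  with an annually drifting catch-weighted centroid and a declining CPUE.

Observation conventions
-----------------------
The default length-frequency sampler draws a fish's length bin with
probability proportional to ``N_i * S(L_i)``, where ``N_i`` is the number of
survivors attaining the bin's lower edge under the survivorship recursion

    N_{i+1} = N_i * ((Linf - L_{i+1}) / (Linf - L_i)) ** (M/K + F/K * S(L_i))

and ``S`` is the logistic retention ogive. This is the master-equation
convention of the LBB model (no pile-up correction). With ``pile_up=True``
the weight gains a factor proportional to the time spent in the bin,
``dt_i = ln((Linf - L_i)/(Linf - L_{i+1}))``, which is the
continuous-recruitment snapshot a length-converted catch curve assumes.
The two conventions differ by a slope of exactly K on the catch curve, so
recovery tests must pair each estimator with its matching convention; see
docs/methods.md.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ParameterError
from .tables import LengthFrequencyTable, LogbookRecord

__all__ = [
    "PopulationScenario",
    "FishRecord",
    "STUDY_BOX",
    "logistic_selectivity",
    "simulate_length_frequency",
    "simulate_cohort_length_frequency",
    "simulate_length_weight",
    "simulate_logbook",
]

#: (lat_min, lat_max, lon_min, lon_max) of the high-seas study area.
STUDY_BOX = (35.0, 45.0, 145.0, 160.0)


@dataclass(frozen=True)
class PopulationScenario:
    """Generating parameters for one simulated stock.

    Lengths are in cm except the length–weight coefficient ``lw_a`` which is
    expressed for lengths in mm (the unit measured at sea). ``m_over_k`` and
    ``f_over_k`` are mortality rates standardized by the growth coefficient,
    the natural parameters of length-based models.
    """

    linf_mean: float = 40.0  # cm
    linf_cv: float = 0.05  # individual asymptotic-length variability
    k: float = 0.6  # 1/year
    t0: float = 0.0  # year
    m_over_k: float = 1.5
    f_over_k: float = 0.5
    lc: float = 20.0  # cm, length at 50% retention
    alpha: float = 2.0  # 1/cm, ogive steepness (np.inf = knife edge)
    lw_a: float = 2.67e-7  # g * mm^-b
    lw_b: float = 3.0
    n_fish: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.linf_mean > 0, "linf_mean must be > 0"),
            (self.linf_cv >= 0, "linf_cv must be >= 0"),
            (self.k > 0, "k must be > 0"),
            (self.m_over_k > 0, "m_over_k must be > 0"),
            (self.f_over_k >= 0, "f_over_k must be >= 0"),
            (0 <= self.lc < self.linf_mean, "need 0 <= lc < linf_mean"),
            (self.alpha > 0, "alpha must be > 0"),
            (self.lw_a > 0 and self.lw_b > 0, "lw_a and lw_b must be > 0"),
            (self.n_fish >= 1, "n_fish must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ParameterError(msg)

    def with_(self, **kwargs) -> "PopulationScenario":
        """Copy with fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FishRecord:
    """A simulated (or measured) individual fish."""

    fork_length_mm: float
    weight_g: float
    age: float = float("nan")
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if not self.fork_length_mm > 0:
            raise ParameterError("fork_length_mm must be > 0")
        if not self.weight_g > 0:
            raise ParameterError("weight_g must be > 0")


def logistic_selectivity(length, lc: float, alpha: float):
    """Probability of gear retention at ``length`` (cm).

    ``alpha=np.inf`` gives the knife-edge limit (retained iff L >= lc).
    """
    length = np.asarray(length, dtype=float)
    if np.isinf(alpha):
        return (length >= lc).astype(float)
    return 1.0 / (1.0 + np.exp(-alpha * (length - lc)))


def _bin_weights(linf_i: np.ndarray, edges: np.ndarray, scenario: PopulationScenario,
                 pile_up: bool) -> np.ndarray:
    """Per-fish categorical weights over length bins (rows: fish, cols: bins).

    Bins whose upper edge reaches the individual's Linf get zero weight.
    """
    lower = edges[:-1][None, :]
    upper = edges[1:][None, :]
    linf = linf_i[:, None]
    valid = upper < linf
    sel = logistic_selectivity(edges[:-1], scenario.lc, scenario.alpha)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, (linf - upper) / (linf - lower), 1.0)
        expo = scenario.m_over_k + scenario.f_over_k * sel
        # survivors attaining each bin's lower edge
        log_n = np.concatenate(
            [np.zeros((linf_i.size, 1)), np.cumsum(expo * np.log(ratio), axis=1)[:, :-1]],
            axis=1,
        )
        weights = np.exp(log_n) * sel
        if pile_up:
            weights = weights * np.where(valid, -np.log(ratio), 0.0)
    return np.where(valid, weights, 0.0)


def _sample_bins(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    totals = weights.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ParameterError("scenario leaves some fish with no selectable length bin")
    cdf = np.cumsum(weights / totals, axis=1)
    u = rng.random((weights.shape[0], 1))
    return (u > cdf[:, :-1]).sum(axis=1)


def simulate_length_frequency(
    scenario: PopulationScenario,
    bin_width_mm: float = 10.0,
    year: int = 0,
    pile_up: bool = False,
) -> LengthFrequencyTable:
    """Draw one year's catch length-frequency sample.

    Each fish receives its own asymptotic length
    ``Linf_i ~ Normal(linf_mean, linf_cv * linf_mean)`` and its length bin is
    drawn with probability proportional to survivors-times-retention (see
    module docstring for the two observation conventions). Counts sum to
    ``scenario.n_fish``; the call is deterministic given ``scenario.seed``.
    """
    if not bin_width_mm > 0:
        raise ParameterError("bin_width_mm must be > 0")
    rng = np.random.default_rng(scenario.seed)
    sd = scenario.linf_cv * scenario.linf_mean
    linf_i = rng.normal(scenario.linf_mean, sd, size=scenario.n_fish)
    linf_i = np.clip(linf_i, max(scenario.lc + 1e-6, 0.3 * scenario.linf_mean), None)
    w_cm = bin_width_mm / 10.0
    n_bins = int(np.ceil(linf_i.max() / w_cm)) + 1
    edges = w_cm * np.arange(n_bins + 1)
    weights = _bin_weights(linf_i, edges, scenario, pile_up)
    bins = _sample_bins(weights, rng)
    counts = np.bincount(bins, minlength=n_bins)
    return LengthFrequencyTable(
        year, 10.0 * w_cm * np.arange(n_bins), counts, bin_width_mm
    ).trimmed()


def simulate_cohort_length_frequency(
    scenario: PopulationScenario,
    bin_width_mm: float = 10.0,
    year: int = 0,
    sample_fraction: float = 0.5,
    max_cohorts: int = 20,
    recruit_sd: float = 0.1,
) -> LengthFrequencyTable:
    """Length frequency of a snapshot with annual recruitment pulses.

    Cohorts aged ``sample_fraction + j`` years (j = 0, 1, ...) are present at
    sampling; cohort abundance decays under age-integrated mortality
    ``M + F * S(L(t))`` and individuals spread around the cohort mean length
    through individual Linf variability plus a recruitment-timing jitter of
    sd ``recruit_sd`` years. This produces the multi-modal structure that
    modal-progression methods (ELEFAN) need, which the equilibrium generator
    cannot: its continuous recruitment smears modes out. Set
    ``recruit_sd=0`` for perfectly synchronous (noise-controlled) pulses.
    """
    if not 0 <= sample_fraction < 1:
        raise ParameterError("sample_fraction must be in [0, 1)")
    if recruit_sd < 0:
        raise ParameterError("recruit_sd must be >= 0")
    rng = np.random.default_rng(scenario.seed)
    k, t0 = scenario.k, scenario.t0
    m = scenario.m_over_k * k
    f = scenario.f_over_k * k
    ages = sample_fraction + np.arange(max_cohorts, dtype=float)
    # age-integrated survival on a fine grid (selection makes F length-varying)
    tgrid = np.linspace(0.0, ages[-1], 2048)
    lgrid = scenario.linf_mean * (1.0 - np.exp(-k * (tgrid - t0)))
    zgrid = m + f * logistic_selectivity(np.clip(lgrid, 0, None), scenario.lc, scenario.alpha)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (zgrid[1:] + zgrid[:-1]) * np.diff(tgrid))])
    surv = np.exp(-np.interp(ages, tgrid, cum))
    mean_len = scenario.linf_mean * (1.0 - np.exp(-k * (ages - t0)))
    catch_weight = surv * logistic_selectivity(mean_len, scenario.lc, scenario.alpha)
    if catch_weight.sum() <= 0:
        raise ParameterError("no cohort is selectable under this scenario")
    p = catch_weight / catch_weight.sum()
    # rejection-sample individuals so retention acts on individual length
    lengths = np.empty(0)
    sd = scenario.linf_cv * scenario.linf_mean
    while lengths.size < scenario.n_fish:
        n_draw = 2 * (scenario.n_fish - lengths.size) + 32
        a = ages[rng.choice(ages.size, size=n_draw, p=surv / surv.sum())]
        if recruit_sd > 0:
            a = np.clip(a + rng.normal(0.0, recruit_sd, size=n_draw), 0.02, None)
        linf_i = rng.normal(scenario.linf_mean, sd, size=n_draw)
        cand = np.clip(linf_i, 1e-3, None) * (1.0 - np.exp(-k * (a - t0)))
        keep = rng.random(n_draw) < logistic_selectivity(cand, scenario.lc, scenario.alpha)
        lengths = np.concatenate([lengths, cand[keep & (cand > 0)]])
    lengths = lengths[: scenario.n_fish]
    w_cm = bin_width_mm / 10.0
    n_bins = int(np.ceil(lengths.max() / w_cm)) + 1
    counts = np.bincount(np.floor(lengths / w_cm).astype(int), minlength=n_bins)
    return LengthFrequencyTable(
        year, 10.0 * w_cm * np.arange(n_bins), counts, bin_width_mm
    ).trimmed()


def simulate_length_weight(
    scenario: PopulationScenario,
    n: int,
    noise_sd: float = 0.05,
    length_range_mm: tuple[float, float] | None = None,
) -> list[FishRecord]:
    """Simulate length–weight records ``W = a * L^b * exp(eps)``.

    ``eps ~ Normal(0, noise_sd^2)`` on the natural-log scale. Lengths are
    uniform over ``length_range_mm`` (default 30–95% of the mean asymptotic
    length). Deterministic given ``scenario.seed``.
    """
    if n < 2:
        raise ParameterError("need n >= 2 length-weight records")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(scenario.seed)
    if length_range_mm is None:
        length_range_mm = (3.0 * scenario.linf_mean, 9.5 * scenario.linf_mean)
    lengths = rng.uniform(*length_range_mm, size=n)
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    weights = scenario.lw_a * lengths**scenario.lw_b * np.exp(eps)
    sexes = rng.choice(["F", "M"], size=n)
    return [
        FishRecord(float(length), float(weight), sex=str(sex))
        for length, weight, sex in zip(lengths, weights, sexes)
    ]


def simulate_logbook(
    years: list[int],
    ops_per_year: int,
    centroid_path: list[tuple[float, float]],
    spread_deg: float = 1.0,
    seed: int = 0,
    median_catch_t: float = 30.0,
    catch_decline: float = 0.85,
    catch_sigma: float = 0.5,
    mean_extra_nets: float = 2.0,
) -> list[LogbookRecord]:
    """Simulate purse-seine logbook records around drifting annual centroids.

    Per year, operation positions are bivariate normal around that year's
    centroid, truncated to the 35–45° N / 145–160° E study box. Net
    deployments are ``1 + Poisson(mean_extra_nets)``; catches are lognormal
    with median ``median_catch_t * catch_decline**year_index``, emulating the
    observed year-on-year CPUE decline. Deterministic given ``seed``.
    """
    if not years:
        raise ParameterError("years must be non-empty")
    if len(centroid_path) != len(years):
        raise ParameterError("need one (lat, lon) centroid per year")
    if spread_deg < 0:
        raise ParameterError("spread_deg must be >= 0")
    lat0, lat1, lon0, lon1 = STUDY_BOX
    for la, lo in centroid_path:
        if not (lat0 <= la <= lat1 and lon0 <= lo <= lon1):
            raise ParameterError(f"centroid ({la}, {lo}) outside the study box")
    rng = np.random.default_rng(seed)
    records: list[LogbookRecord] = []
    for j, (yr, (cla, clo)) in enumerate(zip(years, centroid_path)):
        lats = np.empty(0)
        lons = np.empty(0)
        while lats.size < ops_per_year:
            m = ops_per_year - lats.size
            la = rng.normal(cla, spread_deg, size=2 * m + 8)
            lo = rng.normal(clo, spread_deg, size=2 * m + 8)
            ok = (la >= lat0) & (la <= lat1) & (lo >= lon0) & (lo <= lon1)
            lats = np.concatenate([lats, la[ok]])
            lons = np.concatenate([lons, lo[ok]])
        lats, lons = lats[:ops_per_year], lons[:ops_per_year]
        nets = 1 + rng.poisson(mean_extra_nets, size=ops_per_year)
        med = median_catch_t * catch_decline**j
        catches = np.exp(rng.normal(np.log(med), catch_sigma, size=ops_per_year))
        months = rng.integers(5, 12, size=ops_per_year)  # May–November season
        days = rng.integers(1, 29, size=ops_per_year)
        for la, lo, ne, ca, mo, da in zip(lats, lons, nets, catches, months, days):
            records.append(
                LogbookRecord(dt.date(yr, int(mo), int(da)), float(la), float(lo),
                              int(ne), float(ca))
            )
    return records
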