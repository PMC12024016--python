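"""Shared fixtures: simulated stocks and small pipeline inputs.

The expensive artifacts (50k-fish cohort sample, ELEFAN and LBB recovery
fits) are session-scoped so unit and acceptance tests share one computation.
"""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from lbstock import (ElefanModel, LBBModel, LBBPriors, PopulationScenario,
                     simulate_cohort_length_frequency,
                     simulate_length_frequency, simulate_length_weight,
                     simulate_logbook, write_length_frequency, write_logbook)


@pytest.fixture(scope="session")
def cohort_scenario() -> PopulationScenario:
    """Noise-controlled growth-recovery stock: Linf=40, K=0.6, Z/K=2."""
    return PopulationScenario(linf_mean=40.0, linf_cv=0.02, k=0.6, t0=0.0,
                              m_over_k=1.5, f_over_k=0.5, lc=15.0, alpha=2.0,
                              n_fish=50_000, seed=5)


@pytest.fixture(scope="session")
def cohort_table(cohort_scenario):
    return simulate_cohort_length_frequency(cohort_scenario,
                                            sample_fraction=0.5, recruit_sd=0.0)


@pytest.fixture(scope="session")
def elefan_recovery_fit(cohort_table):
    return ElefanModel(cohort_table).fit((34.0, 46.0), (0.3, 1.0), grid=(49, 36))


@pytest.fixture(scope="session")
def lbb_scenario() -> PopulationScenario:
    """Biomass-recovery stock: Linf=40, Lc/Linf=0.5, M/K=1.5, F/K=0.5."""
    return PopulationScenario(linf_mean=40.0, linf_cv=0.02, lc=20.0, alpha=2.0,
                              m_over_k=1.5, f_over_k=0.5, n_fish=5_000, seed=11)


@pytest.fixture(scope="session")
def lbb_recovery(lbb_scenario):
    """(scenario, table, posterior) for the LBB parameter-recovery check."""
    table = simulate_length_frequency(lbb_scenario)
    priors = LBBPriors.from_table(table, mk_prior=1.5, fk_prior=0.5,
                                  alpha_prior=4.0, fk_cv=0.5, alpha_cv=0.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = LBBModel(table, priors).fit(seed=3)
    return lbb_scenario, table, results


@pytest.fixture()
def pipeline_inputs(tmp_path):
    """Small synthetic CSV inputs and a fast pipeline config."""
    years = [2019, 2020]
    tables = {}
    lw_rows = []
    for i, yr in enumerate(years):
        scen = PopulationScenario(seed=100 + i, n_fish=2_000, linf_cv=0.03)
        tables[yr] = simulate_cohort_length_frequency(scen, year=yr,
                                                      recruit_sd=0.15)
        for rec in simulate_length_weight(scen.with_(seed=200 + i), n=120):
            lw_rows.append((yr, rec.fork_length_mm, rec.weight_g, rec.sex))
    write_length_frequency(tables, tmp_path / "lf.csv")
    pd.DataFrame(lw_rows, columns=["year", "length_mm", "weight_g", "sex"]
                 ).to_csv(tmp_path / "lw.csv", index=False)
    records = simulate_logbook(years, 300, [(40.0, 150.0), (41.0, 151.0)],
                               spread_deg=1.0, seed=3)
    write_logbook(records, tmp_path / "logbook.csv")
    config = {
        "seed": 1,
        "inputs": {
            "length_frequency": str(tmp_path / "lf.csv"),
            "length_weight": str(tmp_path / "lw.csv"),
            "logbook": str(tmp_path / "logbook.csv"),
        },
        "mean_temp_c": 25.0,
        "elefan": {"linf_range": [34, 46], "k_range": [0.3, 1.0],
                   "grid": [20, 15]},
        "lbb": {"mcmc": {"chains": 2, "iterations": 3000, "burn_in": 1000},
                "use_elefan_linf": True},
    }
    return tmp_path, config
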