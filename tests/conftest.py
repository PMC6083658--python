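import pathlib

import pytest

import groomchoice as gc

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_log() -> gc.EventLog:
    return gc.EventLog.from_tsv(DATA / "toy_events.tsv")


@pytest.fixture(scope="session")
def toy_roster() -> gc.Roster:
    return gc.Roster.from_csv(DATA / "toy_roster.csv")


@pytest.fixture(scope="session")
def toy_table(toy_log, toy_roster):
    ratings = gc.EloRatings.from_events(toy_log, roster=toy_roster)
    dyads = gc.DyadIndex.from_events(toy_log)
    return gc.build_choice_table(toy_log, toy_roster, ratings, dyads,
                                 group="toy")


@pytest.fixture(scope="session")
def sim():
    """One moderately sized simulated community (log, roster, truth)."""
    cfg = gc.SimulationConfig(n_days=40, rng_seed=2)
    return gc.simulate_group(cfg)


@pytest.fixture(scope="session")
def sim_products(sim):
    log, roster, truth = sim
    ratings = gc.EloRatings.from_events(log, roster=roster)
    dyads = gc.DyadIndex.from_events(log)
    table, report = gc.build_choice_table(log, roster, ratings, dyads,
                                          group="south")
    return {"log": log, "roster": roster, "truth": truth,
            "ratings": ratings, "dyads": dyads, "table": table,
            "report": report}
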