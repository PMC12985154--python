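import numpy as np
import pandas as pd
import pytest

from trialcea import (SimConfig, UnitCostTable, apply_dropout, generate_cohort,
                      toy_benefit_table, toy_sf6d_coefficients, toy_value_set)
from trialcea.costing import CATEGORIES, CostLedger, PERIODS


@pytest.fixture(scope="session")
def toy_vs():
    return toy_value_set()


@pytest.fixture(scope="session")
def toy_sf():
    return toy_sf6d_coefficients()


@pytest.fixture(scope="session")
def unit_costs():
    return UnitCostTable()


@pytest.fixture(scope="session")
def benefits():
    return toy_benefit_table()


@pytest.fixture(scope="session")
def pilot_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def pilot_dataset(pilot_config):
    """A 50-patient pilot cohort with the default monotone dropout."""
    return apply_dropout(generate_cohort(pilot_config), pilot_config)


def make_ledger(rows):
    """Build a CostLedger from (patient, arm, period, category→amount) dicts."""
    recs, arms = [], {}
    for pid, arm, period, amounts in rows:
        arms[pid] = arm
        rec = {"patient_id": pid, "period": period}
        rec.update({c: 0.0 for c in CATEGORIES})
        rec.update(amounts)
        recs.append(rec)
    df = pd.DataFrame(recs).set_index(["patient_id", "period"])
    return CostLedger(amounts=df, arms=pd.Series(arms, name="arm"))


@pytest.fixture
def table3_ledger():
    """Arm-level published cost components replayed as a tiny ledger.

    Two identical patients per arm carrying the printed per-patient arm
    means. The PPT productivity entry is split across its two printed period
    components (1263 + 972); the remaining entries carry the printed
    12-week category totals, whose sums are what the assembler must
    reproduce.
    """
    ppt = {"intervention": {"intervention_medical": 301.0, "transport": 371.0,
                            "productivity": 1263.0},
           "followup": {"productivity": 972.0}}
    pt = {"intervention": {"intervention_medical": 239.0, "transport": 434.0,
                           "productivity": 3759.0},
          "followup": {}}
    rows = []
    for pid, arm, comp in (("a1", "PPT", ppt), ("a2", "PPT", ppt),
                           ("b1", "PT", pt), ("b2", "PT", pt)):
        for period in PERIODS:
            rows.append((pid, arm, period, comp[period]))
    return make_ledger(rows)
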