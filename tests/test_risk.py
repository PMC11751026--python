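"""Additive mixture risk (MRQ) and bee contact hazard (MHQ) engines."""

import numpy as np
import pandas as pd
import pytest

from cupmix.risk import (
    aggregate_risk,
    bee_hq,
    categorize,
    hazard_table,
    pnec,
    risk_table,
    sample_mhq,
    sample_mrq,
)

from conftest import make_endpoints, make_table


def test_pnec_assessment_factors():
    row = pd.Series({"noec_collembola_mg_kg": 10.0})
    assert pnec(row, "collembola") == pytest.approx(1.0)
    row = pd.Series({"noec_earthworm_mg_kg": np.nan,
                     "lc50_earthworm_mg_kg": 1000.0})
    assert pnec(row, "earthworm") == pytest.approx(1.0)


def test_pnec_prefers_noec_over_lc50():
    row = pd.Series({"noec_earthworm_mg_kg": 5.0,
                     "lc50_earthworm_mg_kg": 1000.0})
    assert pnec(row, "earthworm") == pytest.approx(0.5)


def test_pnec_absent_endpoint_is_none():
    assert pnec(pd.Series({"noec_collembola_mg_kg": np.nan}), "collembola") is None
    with pytest.raises(KeyError):
        pnec(pd.Series(dtype=float), "honeybadger")


@pytest.mark.parametrize("mrq, category", [
    (0.0, "negligible"), (0.005, "negligible"), (0.01, "low"), (0.05, "low"),
    (0.1, "medium"), (0.5, "medium"), (1.0, "high"), (1.0001, "very_high"),
    (1.5, "very_high"),
])
def test_categorize_bands(mrq, category):
    assert categorize(mrq) == category


def test_categorize_rejects_negative():
    with pytest.raises(ValueError):
        categorize(-0.1)


def two_compound_sample():
    table = make_table([
        dict(month=0, compound="F01", conc=100.0, status="quantified"),
        dict(month=0, compound="H01", conc=50.0, status="quantified"),
    ])
    # NOEC 1 mg/kg -> PNEC 0.1 mg/kg = 100 ug/kg for both compounds
    endpoints = make_endpoints([
        ("F01", 1.0, 1.0, np.nan, 1000.0),
        ("H01", 1.0, 1.0, np.nan, 1000.0),
    ])
    return table, endpoints


def test_sample_mrq_hand_arithmetic():
    table, endpoints = two_compound_sample()
    res = sample_mrq(table.records, endpoints, "collembola")
    assert res.rq == pytest.approx({"F01": 1.0, "H01": 0.5})
    assert res.mrq == pytest.approx(1.5)
    assert res.rq_max == pytest.approx(1.0)
    assert res.rq_max_compound == "F01"
    assert res.frac_rq_max == pytest.approx(2 / 3)
    assert res.category == "very_high"
    assert res.coverage == 1.0


def test_empty_sample_is_negligible():
    table = make_table([dict(month=0, compound="F01", conc=0.0,
                             status="not_detected")])
    res = sample_mrq(table.records, make_endpoints([]), "collembola")
    assert res.mrq == 0.0
    assert res.category == "negligible"
    assert res.rq_max_compound is None


def test_mrq_linearity_in_mec():
    table, endpoints = two_compound_sample()
    res1 = sample_mrq(table.records, endpoints, "collembola")
    doubled = table.records.copy()
    doubled["concentration_ug_kg"] *= 2
    res2 = sample_mrq(doubled, endpoints, "collembola")
    assert res2.mrq == pytest.approx(2 * res1.mrq)


def test_below_loq_contributes_zero_but_counts_for_coverage():
    table = make_table([
        dict(month=0, compound="F01", conc=100.0, status="quantified"),
        dict(month=0, compound="H01", conc=0.0, status="below_loq"),
        dict(month=0, compound="I01", conc=0.0, status="below_loq"),
    ])
    endpoints = make_endpoints([("F01", 1.0, 1.0, np.nan, 1000.0),
                                ("H01", 1.0, 1.0, np.nan, 1000.0)])
    res = sample_mrq(table.records, endpoints, "collembola")
    assert res.mrq == pytest.approx(1.0)     # only F01 carries concentration
    assert res.rq["H01"] == 0.0
    assert res.coverage == pytest.approx(2 / 3)  # I01 has no endpoint


def test_partition_additivity():
    """MRQ over a partition of the compounds sums to the whole-sample MRQ."""
    table, endpoints = two_compound_sample()
    rec = table.records
    whole = sample_mrq(rec, endpoints, "collembola").mrq
    parts = sum(
        sample_mrq(rec[rec.compound_id == cid], endpoints, "collembola").mrq
        for cid in ("F01", "H01"))
    assert parts == whole  # exact, not approximate


def test_removing_top_compound_reduces_mrq_by_rq_max():
    table, endpoints = two_compound_sample()
    rec = table.records
    full = sample_mrq(rec, endpoints, "collembola")
    rest = sample_mrq(rec[rec.compound_id != full.rq_max_compound],
                      endpoints, "collembola")
    assert full.mrq - rest.mrq == pytest.approx(full.rq_max, abs=1e-15)


def test_bee_hq_hand_value():
    # 2.23 g x 100 ng/g / (1000 ng/bee / 10) = 2.23
    assert bee_hq(100.0, 1000.0) == pytest.approx(2.23)
    assert bee_hq(0.0, 1000.0) == 0.0
    with pytest.raises(ValueError):
        bee_hq(10.0, 0.0)


def test_sample_mhq_threshold_is_strict():
    table = make_table([
        dict(month=0, compound="F01", conc=100.0, status="quantified"),
    ])
    # HQ = 2.23*100/(2230/10) = 1.0 exactly
    res = sample_mhq(table.records, make_endpoints([
        ("F01", np.nan, np.nan, np.nan, 2230.0)]))
    assert res.mhq == pytest.approx(1.0)
    assert not res.hazard
    table2 = make_table([
        dict(month=0, compound="F01", conc=100.0, status="quantified"),
        dict(month=0, compound="H01", conc=100.0, status="quantified"),
    ])
    res2 = sample_mhq(table2.records, make_endpoints([
        ("F01", np.nan, np.nan, np.nan, 2230.0 / 0.6),
        ("H01", np.nan, np.nan, np.nan, 2230.0 / 0.6)]))
    assert res2.mhq == pytest.approx(1.2)
    assert res2.hazard


def test_vectorised_tables_match_per_sample_engine(campaign, campaign_endpoints):
    """risk_table / hazard_table agree with the record-level engines."""
    table, _ = campaign
    sub = table.subset(matrix="soil", system="arable", distance_class="in_field")
    rt = risk_table(sub, campaign_endpoints, "earthworm")
    ht = hazard_table(sub, campaign_endpoints)
    rec = sub.records
    for _, row in rt.sample(10, random_state=0).iterrows():
        mask = ((rec.site_id == row.site_id) & (rec.matrix == row.matrix)
                & (rec.distance_class == row.distance_class)
                & (rec.month_index == row.month_index))
        ref = sample_mrq(rec[mask], campaign_endpoints, "earthworm")
        assert row.mrq == pytest.approx(ref.mrq, rel=1e-12, abs=1e-15)
        assert row.category == ref.category
    for _, row in ht.sample(5, random_state=1).iterrows():
        mask = ((rec.site_id == row.site_id)
                & (rec.distance_class == row.distance_class)
                & (rec.month_index == row.month_index))
        ref = sample_mhq(rec[mask], campaign_endpoints)
        assert row.mhq == pytest.approx(ref.mhq, rel=1e-12, abs=1e-15)


def test_aggregate_mean_and_max():
    df = pd.DataFrame({
        "system": ["arable"] * 3, "month_index": [0] * 3,
        "distance_class": ["in_field"] * 3,
        "site_id": ["a", "b", "c"], "mrq": [0.2, 0.4, 0.6]})
    agg = aggregate_risk(df, "mrq")
    assert agg.loc[0, "mean"] == pytest.approx(0.4)
    assert agg.loc[0, "max"] == pytest.approx(0.6)
    assert not agg.loc[0, "incomplete"]
    agg2 = aggregate_risk(df.iloc[:2], "mrq")
    assert agg2.loc[0, "mean"] == pytest.approx(0.3)
    assert agg2.loc[0, "incomplete"]


def test_aggregate_category_composition():
    df = pd.DataFrame({
        "system": ["arable"] * 3, "month_index": [0] * 3,
        "distance_class": ["in_field"] * 3,
        "site_id": ["a", "b", "c"], "mrq": [1.0, 1.1, 1.2]})
    agg = aggregate_risk(df, "mrq")
    assert agg.loc[0, "mean_category"] == "very_high"
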