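"""Familiarity-index computation, exclusion rules and pooling."""

import numpy as np
import pandas as pd
import pytest

from songmem import (
    CohortConfig,
    EmptyCellError,
    MissingNovelRatesError,
    SsaRate,
    compute_fi,
    fi_table,
    fit_rates_table,
    generate_cohort,
    pool_fi,
)


def rate(stimulus, stim_class, value, **over):
    kw = dict(bird="b", group="g", hemisphere="left", region="NCM", site=1, set=1,
              mean_magnitude=100.0, r_squared=0.9, fit_window=(6, 25))
    kw.update(over)
    return SsaRate(stimulus=stimulus, stim_class=stim_class, rate=value, **kw)


def test_fi_is_novel_mean_over_familiar_rate():
    records = compute_fi([
        rate("N1", "N", -1.0), rate("N2", "N", -1.5),
        rate("F1", "F", -0.5), rate("F2", "F", -1.25),
    ])
    by_stim = {r.familiar_stimulus: r for r in records}
    assert by_stim["F1"].fi == pytest.approx(2.5)
    assert by_stim["F2"].fi == pytest.approx(1.0)
    assert by_stim["F1"].novel_rate_mean == pytest.approx(-1.25)
    assert not by_stim["F1"].excluded


def test_equal_rates_give_fi_of_one():
    records = compute_fi([rate("N1", "N", -1.2), rate("F1", "F", -1.2)])
    assert records[0].fi == pytest.approx(1.0)


def test_nonnegative_familiar_rate_is_excluded_with_reason():
    (rec,) = compute_fi([rate("N1", "N", -1.0), rate("F1", "F", 0.2)])
    assert rec.excluded
    assert rec.excluded_reason == "nonnegative_rate"
    assert np.isnan(rec.fi)
    (zero,) = compute_fi([rate("N1", "N", -1.0), rate("F1", "F", 0.0)])
    assert zero.excluded_reason == "nonnegative_rate"


def test_nonnegative_novel_mean_is_excluded_with_reason():
    (rec,) = compute_fi([rate("N1", "N", 0.4), rate("N2", "N", -0.1),
                         rate("F1", "F", -1.0)])
    assert rec.excluded_reason == "nonnegative_novel_mean"


def test_missing_novel_rates_raise():
    with pytest.raises(MissingNovelRatesError):
        compute_fi([rate("F1", "F", -1.0)])


def test_table_and_object_paths_agree(noisy_cohort):
    _, table, _ = noisy_cohort
    rates = fit_rates_table(table)
    tab = fi_table(rates)
    one = rates[(rates["bird"] == "hdac3i_b01") & (rates["hemisphere"] == "left")
                & (rates["site"] == 1) & (rates["set"] == 1)]
    objs = [rate(r.stimulus, r.stim_class, r.rate, bird=r.bird, hemisphere=r.hemisphere,
                 region=r.region, site=r.site, set=r.set) for r in one.itertuples()]
    recs = {r.familiar_stimulus: r for r in compute_fi(objs)}
    sub = tab[(tab["bird"] == "hdac3i_b01") & (tab["hemisphere"] == "left")
              & (tab["site"] == 1) & (tab["set"] == 1)]
    for row in sub.itertuples():
        assert row.fi == pytest.approx(recs[row.familiar_stimulus].fi, rel=1e-12)


def test_fi_invariant_to_per_site_gain(noisy_cohort, rng):
    _, table, _ = noisy_cohort
    scaled = table.copy()
    site_cols = ["bird", "hemisphere", "region", "site"]
    gains = {tuple(k): g for k, g in zip(
        scaled[site_cols].drop_duplicates().itertuples(index=False),
        rng.uniform(0.2, 8.0, size=1000))}
    scaled["magnitude"] *= [gains[tuple(k)] for k in scaled[site_cols].itertuples(index=False)]
    fi0 = fi_table(fit_rates_table(table))
    fi1 = fi_table(fit_rates_table(scaled))
    assert np.allclose(fi0["fi"], fi1["fi"], rtol=1e-9, equal_nan=True)


def _records(fis, **labels):
    base = dict(bird="b", group="g", hemisphere="left", region="NCM", site=1, set=1)
    base.update(labels)
    return pd.DataFrame([{**base, "familiar_stimulus": f"F{i}", "fi": v,
                          "novel_rate_mean": -1.0, "familiar_rate": -1.0,
                          "excluded_reason": None} for i, v in enumerate(fis)])


def test_pool_median_odd_and_even_counts():
    pooled = pool_fi(_records([1.0, 1.2, 1.4]))
    assert pooled["median_fi"].iloc[0] == pytest.approx(1.2)
    assert pooled["n"].iloc[0] == 3
    pooled = pool_fi(_records([1.0, 2.0]))
    assert pooled["median_fi"].iloc[0] == pytest.approx(1.5)


def test_pool_skips_excluded_records_and_marks_empty_cells():
    df = _records([1.0, 1.3, 9.9])
    df.loc[2, "excluded_reason"] = "nonnegative_rate"
    pooled = pool_fi(df, cells=[("g", "left", "NCM"), ("g", "right", "NCM")])
    left = pooled[pooled["hemisphere"] == "left"].iloc[0]
    right = pooled[pooled["hemisphere"] == "right"].iloc[0]
    assert left["n"] == 2 and left["median_fi"] == pytest.approx(1.15)
    assert right["n"] == 0 and np.isnan(right["median_fi"])


def test_pool_raises_when_nothing_to_pool():
    df = _records([1.0])
    df["excluded_reason"] = "nonnegative_rate"
    with pytest.raises(EmptyCellError):
        pool_fi(df)


def test_full_pipeline_recovers_configured_fi_exactly_without_noise():
    cfg = CohortConfig(n_birds_per_group={"g": 2},
                       fi_true={("g", "left", "NCM"): 1.19},
                       electrodes_per_hemisphere_nonncm=0, noise_cv=0.0, seed=4)
    table, _ = generate_cohort(cfg)
    pooled = pool_fi(fi_table(fit_rates_table(table)))
    left = pooled[pooled["hemisphere"] == "left"]["median_fi"].iloc[0]
    right = pooled[pooled["hemisphere"] == "right"]["median_fi"].iloc[0]
    assert left == pytest.approx(1.19, abs=1e-12)
    assert right == pytest.approx(1.0, abs=1e-12)
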