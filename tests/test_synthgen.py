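"""Generator contracts: determinism, construction fidelity, validation."""

import numpy as np
import pandas as pd
import pytest

from songmem import (
    CohortConfig,
    ConfigurationError,
    ResponseSeries,
    delta_delta_ct,
    extract_magnitude,
    fi_table,
    fit_rates_table,
    generate_cohort,
    generate_epochs,
    generate_qpcr,
)


def test_identical_config_and_seed_give_bit_identical_tables():
    cfg = CohortConfig(n_birds_per_group={"g": 2}, electrodes_per_hemisphere_nonncm=0, seed=3)
    t1, g1 = generate_cohort(cfg)
    t2, g2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert g1.site_amplitudes == g2.site_amplitudes
    assert g1.slopes_mag == g2.slopes_mag


def test_different_seeds_differ():
    base = dict(n_birds_per_group={"g": 1}, electrodes_per_hemisphere_nonncm=0)
    t1, _ = generate_cohort(CohortConfig(**base, seed=1))
    t2, _ = generate_cohort(CohortConfig(**base, seed=2))
    assert not np.allclose(t1["magnitude"], t2["magnitude"])


def test_adding_birds_does_not_perturb_existing_sites():
    small = CohortConfig(n_birds_per_group={"g": 2}, electrodes_per_hemisphere_nonncm=0, seed=5)
    large = CohortConfig(n_birds_per_group={"g": 4}, electrodes_per_hemisphere_nonncm=0, seed=5)
    ts, _ = generate_cohort(small)
    tl, _ = generate_cohort(large)
    shared = tl[tl["bird"].isin(ts["bird"].unique())].reset_index(drop=True)
    pd.testing.assert_frame_equal(ts, shared)


def test_zero_noise_series_slope_matches_ground_truth_exactly(noiseless_cohort):
    _, table, truth = noiseless_cohort
    rates = fit_rates_table(table)
    for row in rates.itertuples():
        key = f"{row.bird}|{row.hemisphere}|{row.region}|{row.site}|{row.set}|{row.stimulus}"
        slope_mag = row.rate / 100.0 * row.mean_magnitude
        assert slope_mag == pytest.approx(truth.slopes_mag[key], rel=1e-9, abs=1e-12)


def test_null_effect_cohort_has_identical_familiar_and_novel_slopes():
    cfg = CohortConfig(n_birds_per_group={"g": 1}, electrodes_per_hemisphere_nonncm=0,
                       noise_cv=0.0, seed=1)
    table, _ = generate_cohort(cfg)
    rates = fit_rates_table(table)
    assert np.allclose(rates["rate"], cfg.novel_slope_pct, atol=1e-9)
    fi = fi_table(rates)
    assert np.allclose(fi["fi"], 1.0, atol=1e-9)


def test_configured_fi_halves_the_familiar_slope(noiseless_cohort):
    _, table, _ = noiseless_cohort
    rates = fit_rates_table(table)
    cell = rates[(rates["group"] == "hdac3i") & (rates["hemisphere"] == "left")
                 & (rates["region"] == "NCM")]
    fam = cell.loc[cell["stim_class"] == "F", "rate"]
    nov = cell.loc[cell["stim_class"] == "N", "rate"]
    assert np.allclose(fam, nov.mean() / 2.0, atol=1e-9)


def test_fast_phase_adds_early_decline_but_leaves_fit_window_linear():
    cfg = CohortConfig(n_birds_per_group={"g": 1}, electrodes_per_hemisphere_ncm=1,
                       electrodes_per_hemisphere_nonncm=0, n_test_sets=1,
                       noise_cv=0.0, fast_phase_drop_frac=0.5, seed=0)
    table, _ = generate_cohort(cfg)
    one = table[(table["stimulus"] == "N1") & (table["set"] == 1)
                & (table["hemisphere"] == "left")].sort_values("trial")
    m = one["magnitude"].to_numpy()
    # trial 1 is elevated above the linear extrapolation; trials 6+ are exactly linear
    lin = np.polyfit(np.arange(6, 26), m[5:], 1)
    assert m[0] > np.polyval(lin, 1) + 1e-6
    assert np.allclose(np.polyval(lin, np.arange(6, 26)), m[5:], rtol=1e-10)


@pytest.mark.parametrize("overrides, field", [
    (dict(n_birds_per_group={}), "n_birds_per_group"),
    (dict(n_birds_per_group={"g": 0}), "n_birds_per_group"),
    (dict(trials_per_song=6), "trials_per_song"),
    (dict(novel_slope_pct=0.5), "novel_slope_pct"),
    (dict(novel_slope_pct=-11.0), "novel_slope_pct"),
    (dict(noise_cv=-0.1), "noise_cv"),
    (dict(n_test_sets=0), "n_test_sets"),
    (dict(fi_true={("g", "left", "NCM"): -1.0}), "fi_true"),
    (dict(fi_true={("nope", "left", "NCM"): 1.2}), "fi_true"),
    (dict(fi_true={("g", "dorsal", "NCM"): 1.2}), "fi_true"),
    (dict(electrodes_per_hemisphere_ncm=0, electrodes_per_hemisphere_nonncm=0),
     "electrodes_per_hemisphere_ncm"),
])
def test_invalid_config_raises_error_naming_field(overrides, field):
    kwargs = dict(n_birds_per_group={"g": 1})
    kwargs.update(overrides)
    with pytest.raises(ConfigurationError, match=field):
        CohortConfig(**kwargs)


# --- epochs ---------------------------------------------------------------

def _series(mags):
    return ResponseSeries(bird="b", group="g", hemisphere="left", region="NCM",
                          site=1, set=1, stimulus="N1", stim_class="N",
                          magnitudes=np.asarray(mags, dtype=float))


def test_zero_magnitude_series_yields_near_zero_extraction():
    epochs = generate_epochs(_series(np.zeros(25)), sampling_rate=2000.0,
                             seed=1, noise_sd=0.1)
    extracted = np.array([extract_magnitude(e) for e in epochs])
    assert np.all(extracted < 0.02)


def test_epoch_round_trip_recovers_magnitudes():
    mags = np.linspace(40.0, 10.0, 25)
    series = _series(mags)
    # noiseless synthesis: recovery exact to rounding
    for e, m in zip(generate_epochs(series, sampling_rate=2000.0, seed=0, noise_sd=0.0), mags):
        assert extract_magnitude(e) == pytest.approx(m, rel=1e-9)
    # noisy synthesis: error bounded by baseline RMS sampling fluctuation
    noise_sd = 0.5
    epochs = generate_epochs(series, sampling_rate=25000.0, seed=0, noise_sd=noise_sd)
    extracted = np.array([extract_magnitude(e) for e in epochs])
    tol = 6 * noise_sd / np.sqrt(2 * 0.5 * 25000)
    assert np.all(np.abs(extracted - mags) < tol)


def test_epoch_generation_validates_inputs():
    s = _series(np.ones(25))
    with pytest.raises(ConfigurationError):
        generate_epochs(s, sampling_rate=-1.0)
    with pytest.raises(ConfigurationError):
        generate_epochs(s, stim_window=(0.2, 0.6), baseline_window=(0.0, 0.3))
    with pytest.raises(ConfigurationError):
        generate_epochs(s, stim_window=(1.0, 1.0))


# --- qPCR -----------------------------------------------------------------

def test_qpcr_unit_fold_change_and_zero_noise_gives_100_percent_everywhere():
    ct = generate_qpcr(noise_sd=0.0, seed=0)
    rel = delta_delta_ct(ct)
    assert np.allclose(rel["rel_expr_pct"], 100.0)


def test_qpcr_twofold_change_in_left_ncm_only():
    ct = generate_qpcr(fold_changes={("hdac3i", "left", "NCM", "zenk"): 2.0},
                       noise_sd=0.0, seed=0)
    rel = delta_delta_ct(ct)
    target = (rel["group"] == "hdac3i") & (rel["hemisphere"] == "left") \
        & (rel["region"] == "NCM") & (rel["gene"] == "zenk")
    assert np.allclose(rel.loc[target, "rel_expr_pct"], 200.0)
    assert np.allclose(rel.loc[~target, "rel_expr_pct"], 100.0)


def test_qpcr_table_is_reproducible_under_fixed_seed():
    a = generate_qpcr(noise_sd=0.4, seed=9)
    b = generate_qpcr(noise_sd=0.4, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert not np.allclose(a["ct"], generate_qpcr(noise_sd=0.4, seed=10)["ct"])


def test_qpcr_rejects_nonpositive_fold_change():
    with pytest.raises(ConfigurationError, match="fold_changes"):
        generate_qpcr(fold_changes={("hdac3i", "left", "NCM", "zenk"): 0.0})
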