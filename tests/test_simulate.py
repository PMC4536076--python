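import numpy as np
import pandas as pd
import pytest

from quiescreen.doseresponse import FourPLParams, four_pl
from quiescreen.exceptions import ConfigError
from quiescreen.hits import call_primary, call_secondary, reconcile
from quiescreen.kinetics import KineticsParams
from quiescreen.qc import compute_plate_stats, normalize_wells, z_prime
from quiescreen.simulate import (
    ScreenSimConfig,
    default_dose_grid,
    generate_ct_table,
    generate_dose_response,
    generate_kinetics_series,
    generate_screen_plates,
    generate_secondary_plates,
)


def test_layout_must_sum_to_96():
    with pytest.raises(ConfigError, match="96"):
        ScreenSimConfig(n_neg=12, n_pos=4, n_compound_wells=79)


def test_viability_fractions_validated():
    with pytest.raises(ConfigError, match="viability"):
        ScreenSimConfig(actives={"PW-0001": {"quiescent": (1.2, 0.5)}})


def test_zero_noise_no_actives_reads_baseline_everywhere():
    cfg = ScreenSimConfig(n_compounds=80, well_cv=0.0, seed=0)
    tables, truth = generate_screen_plates(cfg)
    for cond, table in tables.items():
        cmp_wells = table.data[table.data["role"] == "compound"]
        assert np.allclose(cmp_wells["luminescence"], cfg.baseline[cond])
        norm = normalize_wells(table, compute_plate_stats(table))
        assert np.allclose(norm.loc[norm["role"] == "compound", "relative_atp"], 100.0)
    assert not truth["active"].any()


def test_compound_count_fills_fourteen_plates_per_condition():
    cfg = ScreenSimConfig(seed=1)  # default 1120 compounds
    tables, _ = generate_screen_plates(cfg)
    assert all(len(t.plate_ids) == 14 for t in tables.values())
    assert all(len(t) == 14 * 96 for t in tables.values())


def test_same_seed_bit_identical_different_seed_differs():
    cfg1 = ScreenSimConfig(n_compounds=80, seed=7)
    cfg2 = ScreenSimConfig(n_compounds=80, seed=7)
    cfg3 = ScreenSimConfig(n_compounds=80, seed=8)
    t1, _ = generate_screen_plates(cfg1)
    t2, _ = generate_screen_plates(cfg2)
    t3, _ = generate_screen_plates(cfg3)
    for cond in t1:
        pd.testing.assert_frame_equal(t1[cond].data, t2[cond].data)
        assert not t1[cond].data["luminescence"].equals(t3[cond].data["luminescence"])


def test_simulated_z_prime_near_closed_form():
    cfg = ScreenSimConfig(n_compounds=80 * 50, well_cv=0.07, seed=3)
    tables, _ = generate_screen_plates(cfg)
    qc = compute_plate_stats(tables["proliferating"])
    base = cfg.baseline["proliferating"]
    closed = z_prime(base, 0.07 * base,
                     base * 0.1, 0.07 * base * 0.1)
    assert abs(qc["z_prime"].median() - closed) < 0.08
    assert qc["passed"].all()


def test_noise_free_pipeline_recovers_exact_truth(small_screen_cfg):
    """Zero noise: the confirmed set equals the true-active set exactly."""
    cfg = ScreenSimConfig(
        n_compounds=small_screen_cfg.n_compounds,
        actives=small_screen_cfg.actives,
        well_cv=0.0,
        seed=4,
    )
    tables, truth = generate_screen_plates(cfg)
    active_ids = set(truth.loc[truth["active"], "compound_id"])
    secondary = generate_secondary_plates(cfg, sorted(active_ids))
    for cond in tables:
        qc = compute_plate_stats(tables[cond])
        prim = call_primary(normalize_wells(tables[cond], qc), qc)
        qc2 = compute_plate_stats(secondary[cond])
        sec = call_secondary(normalize_wells(secondary[cond], qc2), qc2)
        rec = reconcile(prim, sec)
        confirmed = set(rec.loc[rec["confirmed"], "compound_id"])
        assert confirmed == active_ids


def test_dose_response_generator_zero_noise_exact_and_seeded():
    truth = FourPLParams(100, 0, 1.07, 1)
    df, _ = generate_dose_response(truth, cv=0.0, seed=0)
    grid = np.array(default_dose_grid())
    assert sorted(df["concentration_uM"].unique()) == sorted(grid)
    assert len(df) == 30  # triplicate 10-point default design
    expected = four_pl(df["concentration_uM"].to_numpy(), truth)
    assert np.allclose(df["response_pct"], expected)

    a, _ = generate_dose_response(truth, cv=0.1, seed=5)
    b, _ = generate_dose_response(truth, cv=0.1, seed=5)
    c, _ = generate_dose_response(truth, cv=0.1, seed=6)
    pd.testing.assert_frame_equal(a, b)
    assert not a["response_pct"].equals(c["response_pct"])


def test_kinetics_generator_closed_form_and_transient():
    truth = KineticsParams(100.0, np.log(2) / 4, np.log(2) / 1.5)
    series, _ = generate_kinetics_series(truth, cv=0.0, seed=0)
    # 24 h = six parent half-lives
    a = series.areas["bisacodyl"]
    assert a[-1] / truth.a0 == pytest.approx(2.0**-6, rel=1e-12)
    # monoester rises then falls across the sampled grid (transient species)
    b = series.areas["monoester"]
    assert b[1] > b[0] and b[-1] < b.max()


def test_ct_generator_round_trips_and_housekeeping_constant():
    from quiescreen.qpcr import ddct_fold

    table, _ = generate_ct_table({"IFITM1": {"quiescent": 6.32}}, replicate_sd=0.0)
    hk = table[table["gene"] == "18S"]
    assert hk["ct"].nunique() == 1  # constant across samples by construction
    out = ddct_fold(table).set_index(["gene", "sample"])
    assert out.loc[("IFITM1", "quiescent"), "fold_change"] == pytest.approx(6.32, rel=1e-12)


def test_edge_gradient_degrades_z_prime():
    """A strong row/column gradient widens the control spread and lowers Z'
    (edge effects are simulated but never corrected)."""
    flat = ScreenSimConfig(n_compounds=80 * 10, well_cv=0.05, seed=21)
    warped = ScreenSimConfig(n_compounds=80 * 10, well_cv=0.05, seed=21,
                             edge_gradient=0.4)
    z_flat = compute_plate_stats(generate_screen_plates(flat)[0]["quiescent"])
    z_warp = compute_plate_stats(generate_screen_plates(warped)[0]["quiescent"])
    assert z_warp["z_prime"].median() < z_flat["z_prime"].median() - 0.05


def test_strong_active_recovery_at_default_noise(small_screen_cfg):
    """At the default noise level (Z' ~ 0.7) strong actives (2% viability)
    are recovered as confirmed hits with sensitivity and specificity >= 95%."""
    cfg = small_screen_cfg
    tables, truth = generate_screen_plates(cfg)
    active_ids = set(truth.loc[truth["active"], "compound_id"])
    secondary = generate_secondary_plates(cfg, sorted(active_ids))
    sens, spec = [], []
    for cond in tables:
        qc = compute_plate_stats(tables[cond])
        prim = call_primary(normalize_wells(tables[cond], qc), qc)
        qc2 = compute_plate_stats(secondary[cond])
        sec = call_secondary(normalize_wells(secondary[cond], qc2), qc2)
        rec = reconcile(prim, sec)
        confirmed = set(rec.loc[rec["confirmed"], "compound_id"])
        inactive = set(truth["compound_id"]) - active_ids
        sens.append(len(confirmed & active_ids) / len(active_ids))
        spec.append(1 - len(confirmed & inactive) / len(inactive))
    assert min(sens) >= 0.95
    assert min(spec) >= 0.95
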