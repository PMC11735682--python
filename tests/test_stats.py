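"""Layer-average units and the branching statistical design."""

import numpy as np
import pandas as pd
import pytest

from hvospipe.stats import (
    bootstrap_anova,
    factorial_anova_tukey,
    layer_averages,
    normality_screen,
    run_group_stats,
    simulate_layer_units,
    variance_screen,
    welch_t,
)
from oracles import balanced_oneway_f, levene_by_hand, welch_by_hand

PARAMS = ["amplitude_pct", "half_width_ms", "rise_time_ms", "dn_latency_ms_per_um", "decay_time_ms"]


def _cell_table(groups):
    """groups: list of (slice_id, res, stim, n, value) -> uniform-parameter cells."""
    rows = []
    for slice_id, res, stim, n, val in groups:
        for _ in range(n):
            rows.append(
                dict(slice_id=slice_id, genotype="WT", sex="F", residence_layer=res,
                     stimulation_layer=stim, in_analysis=res in ("L2/3", "L4"),
                     **{p: val for p in PARAMS})
            )
    return pd.DataFrame(rows)


def test_layers_with_fewer_than_eight_cells_are_dropped():
    units = layer_averages(_cell_table([("s1", "L2/3", "L4", 7, 1.0)]))
    assert len(units) == 0
    units = layer_averages(_cell_table([("s1", "L2/3", "L4", 8, 1.0)]))
    assert len(units) == 1 and units["n_cells"].iloc[0] == 8


def test_unit_mean_of_identical_cells_is_the_common_value():
    units = layer_averages(_cell_table([("s1", "L4", "L4", 9, 2.5)]))
    assert units["amplitude_pct"].iloc[0] == pytest.approx(2.5)


def test_two_slice_fixture_matches_spreadsheet_means():
    table = _cell_table([("s1", "L2/3", "L4", 8, 1.0), ("s2", "L2/3", "L4", 10, 3.0)])
    # hand-edit half of s2's cells to 5.0 -> mean 4.0
    idx = table.index[table["slice_id"] == "s2"][:5]
    table.loc[idx, "amplitude_pct"] = 5.0
    units = layer_averages(table).set_index("slice_id")
    assert units.loc["s1", "amplitude_pct"] == pytest.approx(1.0)
    assert units.loc["s2", "amplitude_pct"] == pytest.approx(4.0)


def _units(values_by_group, parameter="amplitude_pct"):
    rows = []
    for (geno, res, stim, sex), values in values_by_group.items():
        for i, v in enumerate(values):
            rows.append(
                dict(slice_id=f"{geno}{res}{stim}{i}", genotype=geno, sex=sex,
                     residence_layer=res, stimulation_layer=stim, n_cells=8,
                     **{parameter: v})
            )
    return pd.DataFrame(rows)


def test_shapiro_prefers_log_scale_for_lognormal_data(rng):
    wins = 0
    for _ in range(20):
        sample = np.exp(rng.normal(0, 1, 60))
        units = pd.DataFrame({"dn_latency_ms_per_um": sample})
        w_log = normality_screen(units, "dn_latency_ms_per_um", "log").statistic
        w_id = normality_screen(units, "dn_latency_ms_per_um", "identity").statistic
        wins += w_log > w_id
    assert wins >= 17


def test_shapiro_type_one_error_is_nominal(rng):
    rejections = 0
    for _ in range(1000):
        units = pd.DataFrame({"amplitude_pct": rng.normal(0.5, 0.1, 50)})
        rejections += normality_screen(units, "amplitude_pct").p_value < 0.05
    assert 0.03 <= rejections / 1000 <= 0.07


def test_constant_sample_is_an_error_not_a_p_value():
    units = pd.DataFrame({"amplitude_pct": np.full(10, 1.0)})
    with pytest.raises(ValueError):
        normality_screen(units, "amplitude_pct")


def test_levene_identical_groups_gives_zero_statistic():
    u = _units({("WT", "L2/3", "L4", "F"): [1, 2, 3], ("cKO", "L2/3", "L4", "F"): [1, 2, 3]})
    res = variance_screen(u, "amplitude_pct", "genotype")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_levene_matches_hand_computed_fixture():
    a = np.array([1.0, 2.0, 4.0])
    b = np.array([10.0, 10.5, 20.0])
    u = _units({("WT", "L2/3", "L4", "F"): a, ("cKO", "L2/3", "L4", "F"): b})
    res = variance_screen(u, "amplitude_pct", "genotype")
    w, p = levene_by_hand([b, a])  # group order does not matter
    assert res.statistic == pytest.approx(w)
    assert res.p_value == pytest.approx(p)


def test_levene_detects_ninefold_variance_ratio(rng):
    a, b = rng.normal(0, 1, 50), rng.normal(0, 3, 50)
    u = _units({("WT", "L2/3", "L4", "F"): a, ("cKO", "L2/3", "L4", "F"): b})
    assert variance_screen(u, "amplitude_pct", "genotype").p_value < 0.01


def test_welch_identical_groups_gives_zero_t():
    u = _units({("WT", "L2/3", "L4", "F"): [1, 2, 3], ("WT", "L2/3", "L4", "M"): [1, 2, 3]})
    assert welch_t(u, "amplitude_pct").statistic == pytest.approx(0.0)


def test_welch_matches_hand_computed_values_and_antisymmetry():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
    u = _units({("WT", "L2/3", "L4", "F"): a, ("WT", "L2/3", "L4", "M"): b})
    res = welch_t(u, "amplitude_pct")
    t_hand, df_hand = welch_by_hand(a, b)  # F group sorts first
    assert res.statistic == pytest.approx(t_hand)
    assert res.df[0] == pytest.approx(df_hand)
    u2 = _units({("WT", "L2/3", "L4", "M"): a, ("WT", "L2/3", "L4", "F"): b})
    assert welch_t(u2, "amplitude_pct").statistic == pytest.approx(-res.statistic)


def _balanced_units(rng, effect=0.0, n=6):
    groups = {}
    for geno in ("WT", "cKO"):
        for res in ("L2/3", "L4"):
            for stim in ("L2/3", "L4"):
                mu = 1.0 + (effect if geno == "cKO" else 0.0)
                groups[(geno, res, stim, "F")] = rng.normal(mu, 0.2, n)
    return _units(groups)


def test_anova_main_effect_matches_between_within_ratio(rng):
    units = _balanced_units(rng, effect=0.5)
    out = factorial_anova_tukey(units, "amplitude_pct", factors=["genotype"],
                                include_interactions=False, transform="identity")
    res = out["anova"]["genotype"]
    a = units[units.genotype == "WT"]["amplitude_pct"].to_numpy()
    b = units[units.genotype == "cKO"]["amplitude_pct"].to_numpy()
    assert res.statistic == pytest.approx(balanced_oneway_f([a, b]), rel=1e-9)


def test_anova_null_fixture_keeps_small_f_and_tukey_covers_zero(rng):
    units = _balanced_units(rng, effect=0.0, n=8)
    out = factorial_anova_tukey(units, "amplitude_pct", transform="identity")
    assert out["anova"]["genotype"].p_value > 0.01
    tuk = out["tukey"]
    assert (tuk["lower"].astype(float) <= 0).all() or (tuk["upper"].astype(float) >= 0).all()


def test_anova_empty_cell_raises():
    units = _balanced_units(np.random.default_rng(0))
    units = units[~((units.genotype == "WT") & (units.residence_layer == "L4"))]
    with pytest.raises(ValueError, match="empty design cells"):
        factorial_anova_tukey(units, "amplitude_pct", transform="identity")


def test_bootstrap_anova_is_deterministic_given_seed(rng):
    units = _balanced_units(rng, effect=0.3)
    kw = dict(parameter="amplitude_pct", factors=["genotype"], effect="genotype",
              B=500, include_interactions=False, transform="identity")
    p1 = bootstrap_anova(units, seed=42, **kw).p_value
    p2 = bootstrap_anova(units, seed=42, **kw).p_value
    assert p1 == p2


def test_bootstrap_anova_tracks_classical_p_under_homoscedastic_null(rng):
    # under a homoscedastic null the parametric bootstrap and the classical
    # F test should agree closely, dataset by dataset
    diffs = []
    for i in range(30):
        units = _balanced_units(rng, effect=0.0, n=8)
        res = bootstrap_anova(units, "amplitude_pct", ["genotype"], "genotype",
                              B=2000, seed=100 + i, include_interactions=False,
                              transform="identity")
        a = units[units.genotype == "WT"]["amplitude_pct"].to_numpy()
        b = units[units.genotype == "cKO"]["amplitude_pct"].to_numpy()
        from scipy.stats import f_oneway

        p_classical = f_oneway(a, b).pvalue
        diffs.append(abs(res.p_value - p_classical))
    assert np.median(diffs) < 0.03
    assert max(diffs) < 0.10


def test_bootstrap_anova_warns_on_tiny_B(rng):
    units = _balanced_units(rng)
    with pytest.warns(UserWarning):
        bootstrap_anova(units, "amplitude_pct", ["genotype"], "genotype", B=50,
                        seed=0, include_interactions=False, transform="identity")


def test_run_group_stats_branches_on_levene(rng):
    units = simulate_layer_units(seed=0)
    report = run_group_stats(units, parameters=["amplitude_pct", "dn_latency_ms_per_um"],
                             B=300, seed=1)
    for param, entry in report.items():
        lev = entry["levene_design"]
        expected = "bootstrap_anova" if lev.p_value < 0.05 else "anova_tukey"
        assert entry["branch"] == expected
    assert report["dn_latency_ms_per_um"]["normality"].transform == "log"


def test_simulated_cohort_matches_printed_scales():
    units = simulate_layer_units(seed=3)
    wt = units[units.genotype == "WT"]
    ko = units[units.genotype == "cKO"]
    assert len(wt) == 55 and len(ko) == 54
    assert wt["amplitude_pct"].mean() == pytest.approx(0.499, abs=3 * 0.020 * 3)
    assert ko["dn_latency_ms_per_um"].mean() == pytest.approx(0.0125, abs=3 * 0.0005 * 3)
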