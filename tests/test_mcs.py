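import numpy as np
import pytest

from ptew.errors import ConfigError, NoDataError
from ptew.mcs import (
    DistributionSpec,
    MCSConfig,
    child_rng,
    run_cr_mcs,
    run_hi_mcs,
    run_mcs,
    sample,
    sensitivity_contribution,
)
from ptew.risk import CARCINOGENIC, NONCARCINOGENIC, cdi, cr, hi, hq


def _rng(name="x", seed=123):
    return child_rng(seed, name)


def test_fixed_spec_returns_constant_vector():
    draws = sample(DistributionSpec("a", "fixed", {"value": 5.0}), 100, _rng())
    assert np.all(draws == 5.0) and draws.shape == (100,)


def test_triangular_sample_mean_matches_analytic_value():
    spec = DistributionSpec("EF", "triangular", {"low": 180, "mode": 345, "high": 365})
    draws = sample(spec, 1_000_000, _rng("EF"))
    assert draws.mean() == pytest.approx((180 + 345 + 365) / 3, abs=0.5)
    assert draws.min() >= 180 and draws.max() <= 365


def test_lognormal_moment_matching():
    spec = DistributionSpec("C_Fe", "lognormal", {"mean": 8.72, "sd": 6.35})
    draws = sample(spec, 1_000_000, _rng("C_Fe"))
    assert draws.mean() == pytest.approx(8.72, abs=0.05)
    assert draws.std(ddof=1) == pytest.approx(6.35, abs=0.1)
    assert (draws > 0).all()


def test_truncated_normal_respects_bound():
    spec = DistributionSpec("IR", "normal", {"mean": 0.2, "sd": 0.5, "low": 0.0})
    draws = sample(spec, 50_000, _rng("IR"))
    assert (draws >= 0).all()


def test_invalid_specs_rejected():
    with pytest.raises(ConfigError):
        DistributionSpec("a", "normal", {"mean": 1.0, "sd": -0.1})
    with pytest.raises(ConfigError):
        DistributionSpec("a", "triangular", {"low": 2.0, "mode": 1.0, "high": 3.0})
    with pytest.raises(ConfigError):
        DistributionSpec("a", "nope", {})


def test_single_varying_input_gets_full_contribution():
    rng = _rng()
    x = rng.normal(size=2000)
    out = 3.0 * x + 1.0
    contrib = sensitivity_contribution({"x": x, "k": np.full(2000, 2.0)}, out)
    assert contrib["x"] == pytest.approx(100.0)
    assert contrib["k"] == 0.0


def test_inverse_input_gets_negative_full_contribution():
    rng = _rng("bw")
    bw = rng.lognormal(0.0, 0.2, size=2000)
    out = 1.0 / bw
    contrib = sensitivity_contribution({"BW": bw}, out)
    assert contrib["BW"] == pytest.approx(-100.0)


def test_two_symmetric_normals_split_contribution():
    rng = _rng("pair")
    a, b = rng.normal(size=(2, 100_000))
    contrib = sensitivity_contribution({"a": a, "b": b}, a + b)
    assert contrib["a"] == pytest.approx(50.0, abs=5.0)
    assert contrib["b"] == pytest.approx(50.0, abs=5.0)
    assert abs(contrib["a"]) + abs(contrib["b"]) == pytest.approx(100.0)


def test_constant_output_has_no_variance_to_attribute():
    with pytest.raises(NoDataError):
        sensitivity_contribution({"x": np.arange(5.0)}, np.ones(5))


def test_run_mcs_missing_spec_names_the_input():
    with pytest.raises(ConfigError, match="'b'"):
        run_mcs(
            lambda x: x["a"] + x["b"],
            [DistributionSpec("a", "fixed", {"value": 1.0})],
            MCSConfig(n_iter=10, seed=0),
        )


def test_linear_model_mean_converges_to_closed_form():
    spec = DistributionSpec("X", "normal", {"mean": 4.0, "sd": 2.0})
    res = run_mcs(
        lambda x: 3.0 * x["X"], {"X": spec}, MCSConfig(n_iter=100_000, seed=7)
    )
    se = 3.0 * 2.0 / np.sqrt(100_000)
    assert res.mean == pytest.approx(12.0, abs=3 * se)


def test_identical_seed_gives_bit_identical_results(config):
    a = run_hi_mcs("children", config, MCSConfig(n_iter=2000, seed=42))
    b = run_hi_mcs("children", config, MCSConfig(n_iter=2000, seed=42))
    assert np.array_equal(a.draws, b.draws)
    assert a.mean == b.mean and a.percentiles == b.percentiles
    assert a.sensitivity == b.sensitivity


def test_adding_an_input_does_not_perturb_other_streams():
    base = {"a": DistributionSpec("a", "normal", {"mean": 0.0, "sd": 1.0})}
    extended = dict(base)
    extended["z"] = DistributionSpec("z", "normal", {"mean": 0.0, "sd": 1.0})
    res_a = run_mcs(lambda x: x["a"], base, MCSConfig(n_iter=500, seed=3))
    res_b = run_mcs(lambda x: x["a"], extended, MCSConfig(n_iter=500, seed=3))
    assert np.array_equal(res_a.draws, res_b.draws)


def _fixed_child_winter_specs(config):
    """Every HI input pinned at its child-winter point value."""
    profile = config.profiles["children"]
    means = config.study.mean_concentrations("winter")
    specs = {
        "IR": DistributionSpec("IR", "fixed", {"value": profile.ir}),
        "EF": DistributionSpec("EF", "fixed", {"value": profile.ef_mode}),
        "ED": DistributionSpec("ED", "fixed", {"value": profile.ed}),
        "BW": DistributionSpec("BW", "fixed", {"value": profile.bw}),
    }
    for m, c in means.items():
        specs[f"C_{m}"] = DistributionSpec(f"C_{m}", "fixed", {"value": c})
        specs[f"RfD_{m}"] = DistributionSpec(
            f"RfD_{m}", "fixed", {"value": config.metals[m].reference_dose}
        )
    return specs


def test_all_fixed_specs_collapse_to_deterministic_hi(config):
    from ptew.mcs import hi_model

    profile = config.profiles["children"]
    means = config.study.mean_concentrations("winter")
    expected = hi(
        {m: hq(cdi(c, profile, NONCARCINOGENIC), config.metals[m]) for m, c in means.items()}
    )
    res = run_mcs(
        hi_model(config.metals, profile),
        _fixed_child_winter_specs(config),
        MCSConfig(n_iter=1000, seed=5),
    )
    assert res.mean == expected  # bit-exact collapse
    assert res.percentiles[5.0] == expected and res.percentiles[95.0] == expected
    assert res.sensitivity == {}


def test_cr_mcs_fixed_at_adult_winter_minimum(config):
    from ptew.mcs import cr_model

    profile = config.profiles["adults"]
    low = config.study.concentrations["Pb"]["winter"].low
    specs = {
        "C_Pb": DistributionSpec("C_Pb", "fixed", {"value": low}),
        "IR": DistributionSpec("IR", "fixed", {"value": profile.ir}),
        "EF": DistributionSpec("EF", "fixed", {"value": profile.ef_mode}),
        "ED": DistributionSpec("ED", "fixed", {"value": profile.ed}),
        "BW": DistributionSpec("BW", "fixed", {"value": profile.bw}),
        "AT": DistributionSpec("AT", "fixed", {"value": profile.lifetime_years * 365}),
        "SF": DistributionSpec("SF", "fixed", {"value": config.metals["Pb"].sf}),
    }
    res = run_mcs(cr_model("Pb", profile), specs, MCSConfig(n_iter=100, seed=1))
    assert res.mean == pytest.approx(3.99e-8, rel=0.02)
    assert res.mean == cr(cdi(low, profile, CARCINOGENIC), config.metals["Pb"].sf)


def test_percentiles_bracket_the_median(config):
    res = run_hi_mcs("adults", config, MCSConfig(n_iter=5000, seed=9))
    median = float(np.median(res.draws))
    assert res.percentiles[5.0] <= median <= res.percentiles[95.0]


def test_hi_mcs_mean_matches_brute_force_expectation(config):
    """The engine's mean agrees with an independent large-sample expectation."""
    res = run_hi_mcs("children", config, MCSConfig(n_iter=10_000, seed=11))
    # independent brute-force oracle with a flat numpy RNG, 10^6 draws
    rng = np.random.default_rng(2024)
    n = 1_000_000
    profile = config.profiles["children"]
    ir = rng.normal(profile.ir, profile.ir * config.mcs.ir_cv, n)
    while (ir < 0).any():
        ir[ir < 0] = rng.normal(profile.ir, profile.ir * config.mcs.ir_cv, int((ir < 0).sum()))
    ef = rng.triangular(profile.ef_min, profile.ef_mode, profile.ef_max, n)
    from ptew.mcs import lognormal_parameters

    mu, sig = lognormal_parameters(profile.bw, profile.bw * config.mcs.bw_cv)
    bw = rng.lognormal(mu, sig, n)
    total = np.zeros(n)
    for m, spec in config.metals.items():
        pick = rng.integers(0, 2, n).astype(bool)
        c = np.empty(n)
        for season, mask in (("winter", pick), ("summer", ~pick)):
            mom = config.study.concentrations[m][season]
            mu_c, sig_c = lognormal_parameters(mom.mean, mom.sd)
            c[mask] = rng.lognormal(mu_c, sig_c, int(mask.sum()))
        total += c / spec.reference_dose
    oracle = total * ir * ef / (profile.f * bw * 365.0)
    se = oracle.std() / np.sqrt(10_000)  # dominated by the 10^4-draw engine run
    assert res.mean == pytest.approx(oracle.mean(), abs=3 * se)


def test_cr_mcs_pb_concentration_dominates(config):
    res = run_cr_mcs("children", config, MCSConfig(n_iter=10_000, seed=13))
    top = max(res.sensitivity, key=lambda k: abs(res.sensitivity[k]))
    assert top == "C_Pb"
    assert res.sensitivity["BW"] < 0
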