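"""Per-species mixed models, RAC spatial correction, GAMM screening."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from aviantrends import specimen_data as sd
from aviantrends import synthetic_data as syn
from aviantrends import temporal_models as tm


def _null_frame(rng, n=150, subspecies=("east", "west")):
    year = rng.integers(1900, 2009, n).astype(float)
    frame = pd.DataFrame(
        {
            "year": year,
            "decade": (year // 10) * 10,
            "sex": rng.choice(["male", "female"], n),
            "altitude": rng.uniform(0, 1500, n),
            "subspecies": rng.choice(list(subspecies), n),
            "latitude": rng.uniform(-43, -11, n),
            "longitude": rng.uniform(115, 153, n),
            "month": rng.integers(1, 13, n),
        }
    )
    frame["season"] = np.ceil(frame["month"] / 2)
    return frame


# ---------------------------------------------------------------- fit_lmm

def test_noiseless_trend_recovered_exactly(rng):
    frame = _null_frame(rng)
    frame["wing_length"] = 2.0 + 0.5 * (frame["decade"] / 10.0)
    fit = tm.fit_lmm(frame, tm.ModelSpec.wing())
    assert fit.coef("decade") == pytest.approx(0.5, abs=1e-7)
    assert np.abs(fit.resid).max() < 1e-6


def test_agrees_with_statsmodels_mixedlm(specimen_frame):
    spec = tm.ModelSpec.wing()
    fit = tm.fit_lmm(specimen_frame, spec)

    f = specimen_frame.copy()
    f["sexm"] = (f["sex"] == "male").astype(float)
    f["dec"] = f["decade"] / 10.0 - (f["decade"] / 10.0).mean()
    sm_fit = smf.mixedlm(
        "wing_length ~ dec + sexm + altitude", f, groups=f["subspecies"]
    ).fit(reml=True)
    assert fit.coef("decade") == pytest.approx(sm_fit.params["dec"], rel=1e-4)
    assert fit.coef("sex") == pytest.approx(sm_fit.params["sexm"], rel=1e-4)
    assert fit.sigma_u**2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=0.01)
    assert fit.sigma_e[0] ** 2 == pytest.approx(sm_fit.scale, rel=0.01)


def test_single_subspecies_drops_random_effect(rng):
    frame = _null_frame(rng, subspecies=("only",))
    frame["wing_length"] = 60 + rng.normal(0, 1, len(frame))
    with pytest.warns(UserWarning, match="random intercept dropped"):
        fit = tm.fit_lmm(frame, tm.ModelSpec.wing())
    assert fit.sigma_u == 0.0


def test_singular_design_names_offender(rng):
    frame = _null_frame(rng)
    frame["altitude"] = 0.0  # constant column collides with the intercept
    frame["wing_length"] = 60.0 + rng.normal(0, 1, len(frame))
    with pytest.raises(ValueError, match="singular"):
        tm.fit_lmm(frame, tm.ModelSpec.wing())


def test_wald_df_convention(specimen_frame):
    fit = tm.fit_lmm(specimen_frame, tm.ModelSpec.wing())
    assert fit.df == fit.n_obs - len(fit.terms)


# ---------------------------------------------------------------- effects

def test_extract_effect_per_year_conversion(specimen_frame):
    fit = tm.fit_lmm(specimen_frame, tm.ModelSpec.wing())
    eff = tm.extract_effect(fit, "wing_length", species="spA")
    assert eff.beta * 10 == pytest.approx(fit.coef("decade"), abs=1e-15)
    assert eff.se * 10 == pytest.approx(fit.coef_se("decade"), abs=1e-15)
    assert eff.t == pytest.approx(eff.beta / eff.se, abs=1e-12)
    assert np.sign(eff.beta) == np.sign(fit.coef("decade"))
    assert 0 < eff.p <= 1


# ---------------------------------------------------------------- RAC

def test_rac_zero_when_single_cell():
    with pytest.warns(UserWarning, match="one raster cell"):
        rac = tm.compute_rac(np.array([1.0, 2.0, 3.0]),
                             np.array([-30.1, -30.2, -30.3]),
                             np.array([140.1, 140.2, 140.3]))
    np.testing.assert_array_equal(rac.values, 0.0)


def test_rac_tracks_smooth_gradient(rng):
    n = 3000
    lat = rng.uniform(-40, -10, n)
    lon = rng.uniform(115, 153, n)
    resid = 0.3 * (lat + 25) + 0.2 * (lon - 130)
    rac = tm.compute_rac(resid, lat, lon)
    assert np.corrcoef(rac.values, resid)[0, 1] > 0.9


def test_rac_uncorrelated_with_independent_residuals(rng):
    n = 10_000
    rac = tm.compute_rac(
        rng.standard_normal(n), rng.uniform(-40, -10, n), rng.uniform(115, 153, n)
    )
    assert abs(np.corrcoef(rac.values, rng.standard_normal(n))[0, 1]) < 0.05


# ---------------------------------------------------------------- Moran's I

def test_morans_i_checkerboard_is_minus_one():
    side = 8
    xx, yy = np.meshgrid(range(side), range(side))
    z = ((xx + yy) % 2 * 2 - 1).ravel().astype(float)
    # rook contiguity weights
    n = side * side
    w = np.zeros((n, n))
    for i in range(n):
        xi, yi = i % side, i // side
        for j in range(n):
            xj, yj = j % side, j // side
            if abs(xi - xj) + abs(yi - yj) == 1:
                w[i, j] = 1.0
    assert tm.morans_i(z, weights=w) == pytest.approx(-1.0)


def test_morans_i_null_expectation(rng):
    vals = []
    for _ in range(40):
        n = 200
        vals.append(
            tm.morans_i(rng.standard_normal(n), rng.uniform(-40, -10, n),
                        rng.uniform(115, 153, n))
        )
    assert np.mean(vals) == pytest.approx(-1 / 199, abs=0.01)


def test_morans_i_positive_on_gradient(rng):
    n = 400
    lat = rng.uniform(-40, -10, n)
    lon = rng.uniform(115, 153, n)
    z = 0.5 * lat + 0.3 * lon
    # a pure planar field under power-1 inverse-distance weights on a
    # roughly square domain sits near 0.42 -- far above the ~0 null
    assert tm.morans_i(z, lat, lon) > 0.3


# ---------------------------------------------------------------- residual ACF

def test_residual_acf_behaviour(rng):
    years = np.repeat(np.arange(1900, 2000), 3)
    white = rng.standard_normal(years.size)
    assert abs(tm.residual_acf(white, years)) < 0.25

    series = np.zeros(100)
    for t in range(1, 100):
        series[t] = 0.8 * series[t - 1] + rng.standard_normal()
    assert tm.residual_acf(np.repeat(series, 3), years) == pytest.approx(0.8, abs=0.2)

    with pytest.raises(ValueError, match="constant"):
        tm.residual_acf(np.ones(years.size), years)


# ------------------------------------------------- variance structure

def test_variance_structure_selection(rng):
    spec = tm.ModelSpec.wing()
    keep_homo = 0
    pick_strat = 0
    n_sim = 20
    for r in range(n_sim):
        r_rng = np.random.default_rng(600 + r)
        frame = _null_frame(r_rng)
        male = (frame["sex"] == "male").to_numpy()
        base = 60 + 2 * male
        frame["wing_length"] = base + r_rng.normal(0, 1.5, len(frame))
        chosen, _ = tm.select_variance_structure(frame, spec)
        keep_homo += not chosen.heteroscedastic
        frame["wing_length"] = base + r_rng.normal(0, np.where(male, 1.0, 3.0))
        chosen, _ = tm.select_variance_structure(frame, spec)
        pick_strat += chosen.heteroscedastic
    assert keep_homo >= 0.9 * n_sim
    assert pick_strat >= 0.9 * n_sim


def test_aic_tie_keeps_simpler_model(monkeypatch, specimen_frame):
    spec = tm.ModelSpec.wing()
    real = tm.fit_lmm

    def nearly_tied(frame, s, method="reml"):
        fit = real(frame, s, method)
        if s.heteroscedastic:
            fit.aic = fit.aic + 100  # force a within-2 or worse comparison
        return fit

    monkeypatch.setattr(tm, "fit_lmm", nearly_tied)
    chosen, _ = tm.select_variance_structure(specimen_frame, spec)
    assert not chosen.heteroscedastic


# ---------------------------------------------------------------- GAMM

def test_gamm_edf_near_one_for_linear_truth():
    edfs = []
    for r in range(11):
        rng = np.random.default_rng(700 + r)
        frame = _null_frame(rng, n=800)
        frame["wing_length"] = (
            60 - 0.02 * (frame["year"] - 1950)
            + 2 * (frame["sex"] == "male")
            + rng.normal(0, 1.5, len(frame))
        )
        edfs.append(tm.fit_gamm(frame, tm.ModelSpec.wing()).edf)
    assert np.median(edfs) == pytest.approx(1.0, abs=0.2)


def test_gamm_edf_large_for_nonlinear_truth(rng):
    frame = _null_frame(rng, n=600)
    frame["wing_length"] = (
        60 + 3 * np.sin((frame["year"] - 1900) / 108 * 3 * np.pi)
        + rng.normal(0, 1.0, len(frame))
    )
    assert tm.fit_gamm(frame, tm.ModelSpec.wing()).edf > 3


def test_gamm_infinite_penalty_matches_linear_fit(rng):
    frame = _null_frame(rng, n=400, subspecies=("only",))
    frame["wing_length"] = (
        60 - 0.02 * (frame["year"] - 1950)
        + 2 * (frame["sex"] == "male")
        + 0.0005 * frame["altitude"]
        + rng.normal(0, 1.0, len(frame))
    )
    gamm = tm.fit_gamm(frame, tm.ModelSpec.wing(), lambda_=np.inf)
    assert gamm.edf == pytest.approx(1.0, abs=1e-3)
    # independent oracle: ordinary least squares on the same design
    x = np.column_stack(
        [
            np.ones(len(frame)),
            frame["year"] - frame["year"].mean(),
            (frame["sex"] == "male").astype(float),
            frame["altitude"],
        ]
    )
    slope = np.linalg.lstsq(x, frame["wing_length"].to_numpy(), rcond=None)[0][1]
    assert gamm.year_linear_slope() == pytest.approx(slope, abs=1e-6)


def test_gamm_needs_enough_years(rng):
    frame = _null_frame(rng, n=100)
    frame["year"] = rng.choice([1950.0, 1960, 1970, 1980], len(frame))
    frame["wing_length"] = 60.0 + rng.normal(0, 1, len(frame))
    with pytest.raises(ValueError, match="15 distinct"):
        tm.fit_gamm(frame, tm.ModelSpec.wing())


# ------------------------------------------------- two-stage protocol

def test_rac_protocol_reduces_spatial_autocorrelation():
    """On spatially autocorrelated synthetic data, adding the RAC never
    leaves residual Moran's I meaningfully higher, and reduces it overall."""
    before, after = [], []
    cfg = syn.StudyConfig(master_seed=5, spatial_sill=2.0, spatial_range=8.0)
    spec = tm.ModelSpec.wing()
    for s in range(20):
        truth = syn.SpeciesTruth(name="s", wing_slope=-0.01, depth_slope=0.0)
        recs, _ = syn.simulate_specimens(truth, cfg, seed=4000 + s, n_specimens=120)
        frame = sd.records_to_frame(recs)
        fit0 = tm.fit_lmm(frame, spec)
        lat = frame["latitude"].to_numpy()
        lon = frame["longitude"].to_numpy()
        before.append(tm.morans_i(fit0.resid, lat, lon))
        rac = tm.compute_rac(fit0.resid, lat, lon)
        fit1 = tm.fit_lmm(frame.assign(rac=rac.values), spec)
        after.append(tm.morans_i(fit1.resid, lat, lon))
    before, after = np.abs(before), np.abs(after)
    assert np.mean(after) < np.mean(before)
    assert np.all(after <= before + 0.02)
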