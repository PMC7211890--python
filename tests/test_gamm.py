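import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from billclim import gamm
from billclim import synthetic_data as sd
from billclim.gamm import (
    ModelSpec,
    RankDeficientError,
    bergmann_test,
    build_design,
    fit_gamm,
    gvif,
    morans_i,
    predict_with_ci,
    r2_from_components,
    r2_nakagawa,
    refit_alternative_bodysize,
    thinplate_basis,
    wald_tests,
)

# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def test_design_has_fourteen_fixed_columns(small_designs):
    assert small_designs.X.shape[1] == 14
    assert small_designs.fixed_names[0] == "intercept"
    assert "tarsus_mm" in small_designs.fixed_names


def test_interaction_columns_are_products(small_designs):
    names = small_designs.fixed_names
    X = small_designs.X
    for a, b in [("rel_min_temp", "mean_temp"), ("rel_max_temp", "recent_precip")]:
        prod = X[:, names.index(a)] * X[:, names.index(b)]
        np.testing.assert_allclose(X[:, names.index(f"{a}:{b}")], prod, rtol=1e-12)


def test_single_sex_table_is_rank_deficient(small_sim):
    grid, spec, info = small_sim
    females = spec.copy()
    females["sex"] = "female"
    with pytest.raises(RankDeficientError, match="sex_male"):
        build_design(info["covariates"], females, ModelSpec(k=15))


# ---------------------------------------------------------------------------
# thin-plate basis
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_points():
    rng = np.random.default_rng(0)
    return rng.uniform(35, 39, 20), rng.uniform(-122, -119, 20)


def test_tps_penalty_null_space_and_psd(toy_points):
    lat, lon = toy_points
    tps = thinplate_basis(lat, lon, k=10)
    assert tps.null_dim == 3
    assert tps.basis.shape == (20, 10)
    # penalty is exactly zero on the null-space columns
    assert np.abs(tps.penalty[-3:, :]).max() == 0.0
    assert np.abs(tps.penalty[:, -3:]).max() == 0.0
    eig = np.linalg.eigvalsh((tps.penalty + tps.penalty.T) / 2)
    assert eig.min() >= -1e-8


def test_tps_interpolates_at_full_rank(toy_points):
    lat, lon = toy_points
    z = np.sin(lat) + np.cos(lon) + lat * lon / 100.0
    tps = thinplate_basis(lat, lon, k=20)
    coef, *_ = np.linalg.lstsq(tps.basis, z, rcond=None)
    assert np.abs(tps.basis @ coef - z).max() < 1e-6


def test_tps_too_few_points_raises(toy_points):
    lat, lon = toy_points
    with pytest.raises(ValueError, match="reduce k"):
        thinplate_basis(lat, lon, k=25)
    with pytest.raises(ValueError):
        thinplate_basis(lat, lon, k=3)


# ---------------------------------------------------------------------------
# REML fit
# ---------------------------------------------------------------------------


def test_ols_limit_with_pinned_variances(small_designs, small_response):
    """gamma_smooth = gamma_year = 0 reduces to OLS on [X | lat, lon]."""
    rng = np.random.default_rng(21)
    F = np.column_stack([small_designs.X, small_designs.smooth_null])
    for _ in range(5):
        y = small_response + rng.normal(0, 5, len(small_response))
        fit = fit_gamm(small_designs, y, fix_gamma_smooth=0.0, fix_gamma_year=0.0)
        b_ols, *_ = np.linalg.lstsq(F, y, rcond=None)
        assert np.abs(fit.coef[: F.shape[1]] - b_ols).max() < 1e-8
        assert fit.edf_smooth == pytest.approx(3.0, abs=1e-9)


def test_edf_limits(small_designs, small_response):
    lo = fit_gamm(small_designs, small_response, fix_gamma_smooth=0.0, fix_gamma_year=0.0)
    assert lo.edf_smooth == pytest.approx(3.0, abs=1e-9)  # infinite penalty
    hi = fit_gamm(small_designs, small_response, fix_gamma_smooth=1e10, fix_gamma_year=0.0)
    assert hi.edf_smooth == pytest.approx(small_designs.spec.k, abs=1e-3)  # no penalty


def test_edf_trace_identity(small_fit):
    """edf recomputed from an explicit influence matrix agrees with the fit."""
    d = small_fit.designs
    g = small_fit.gamma
    F = np.column_stack([d.X, d.smooth_null])
    C = np.column_stack([F, d.tps.Z_mixed, d.Z_year])
    pen = np.concatenate(
        [np.zeros(F.shape[1]), np.full(d.tps.Z_mixed.shape[1], 1.0 / g[0]), np.full(d.Z_year.shape[1], 1.0 / g[1])]
    )
    H = C.T @ C + np.diag(pen)
    Finf = np.linalg.solve(H, C.T @ C)
    np.testing.assert_allclose(np.diag(Finf), small_fit.edf_by_col, atol=1e-8)
    sm = slice(F.shape[1], F.shape[1] + d.tps.Z_mixed.shape[1])
    assert small_fit.edf_smooth == pytest.approx(3.0 + np.trace(Finf[sm, sm]), abs=1e-8)


def test_reml_optimum_is_trace_minimum(small_fit):
    """The returned criterion value is the best value ever visited."""
    assert small_fit.converged
    assert small_fit.reml_criterion <= min(small_fit.trace) + 1e-6
    assert small_fit.sigma2_resid > 0 and small_fit.sigma2_year >= 0


def test_zero_variance_response_rejected(small_designs):
    with pytest.raises(ValueError, match="zero variance"):
        fit_gamm(small_designs, np.full(len(small_designs.frame), 5.0))


def test_fit_against_mgcv_oracle(tmp_path):
    """Independent cross-check: the same model fit by R's mgcv::gam
    (tp smooth + year random effect, REML) must agree on non-intercept
    fixed coefficients and variance components."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the mgcv cross-check")
    p = sd.GenerativeParams(
        n=200, first_year=1932, last_year=1950,
        lat_min=35.5, lat_max=38.5, lon_min=-122.0, lon_max=-119.0,
        spatial_amplitude=8.0,
    )
    grid, spec, info = sd.simulate_dataset(p, seed=7)
    designs = build_design(info["covariates"], spec, ModelSpec(k=15))
    from billclim import morphometry
    y = morphometry.bill_surface_area(
        spec["bill_length_mm"].to_numpy(), spec["bill_width_mm"].to_numpy(), spec["bill_depth_mm"].to_numpy()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_gamm(designs, y)
    df = pd.DataFrame(designs.X[:, 1:], columns=[f"x{i}" for i in range(1, 14)])
    df["lat"] = designs.frame["decimal_latitude"].to_numpy()
    df["lon"] = designs.frame["decimal_longitude"].to_numpy()
    df["year"] = designs.frame["year"].to_numpy()
    df["y"] = y
    csv = tmp_path / "mgcv_in.csv"
    df.to_csv(csv, index=False)
    rcode = f"""
    d <- read.csv("{csv}"); d$yearf <- factor(d$year)
    suppressMessages(library(mgcv))
    fml <- as.formula(paste("y ~", paste(sprintf("x%d", 1:13), collapse="+"),
                            "+ s(lat,lon,k=15) + s(yearf,bs='re')"))
    m <- gam(fml, data=d, method="REML")
    co <- summary(m)$p.table[, 1]
    vc <- gam.vcomp(m)
    edf <- sum(m$edf[grep("s.lat", names(coef(m)))])
    cat(paste(co, collapse=","), "\n")
    cat(vc["s(yearf)", 1], m$sig2, edf, "\n")
    """
    res = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    lines = [ln for ln in res.stdout.strip().splitlines() if ln.strip()]
    mgcv_coef = np.array([float(v) for v in lines[-2].split(",")])
    sd_year_r, sig2_r, edf_r = (float(v) for v in lines[-1].split())
    ours = fit.coef_fixed.to_numpy()
    np.testing.assert_allclose(ours[1:], mgcv_coef[1:], rtol=2e-3, atol=2e-3)
    assert fit.sd_year == pytest.approx(sd_year_r, rel=1e-2)
    assert fit.sigma2_resid == pytest.approx(sig2_r, rel=1e-2)
    # conventions differ by exactly the shared constant in the null space
    assert fit.edf_smooth == pytest.approx(edf_r + 1.0, abs=0.05)


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------


def test_wald_table_schema_and_p_oracle(small_fit):
    tab = wald_tests(small_fit)
    assert list(tab.columns) == ["term", "estimate", "se", "statistic", "stat_type", "df", "p"]
    trows = tab[tab["stat_type"] == "t"]
    assert len(trows) == 14
    # p-values match the t survival function at the fit's residual df
    expect = 2 * stats.t.sf(np.abs(trows["statistic"]), small_fit.df_resid)
    np.testing.assert_allclose(trows["p"].to_numpy(), expect, rtol=1e-12)
    smooth = tab[tab["stat_type"] == "F"]
    assert len(smooth) == 1 and smooth["term"].iloc[0] == "s(latitude,longitude)"
    assert 0 <= smooth["p"].iloc[0] <= 1


def test_wald_t_from_printed_inputs():
    """The t ratio from a reported estimate/SE pair of -5.22/1.90 rounds to
    -2.75, consistent with a published -2.76 given printed rounding."""
    t = -5.22 / 1.90
    assert t == pytest.approx(-2.747, abs=1e-3)
    assert abs(t - (-2.76)) < 0.02


# ---------------------------------------------------------------------------
# R²
# ---------------------------------------------------------------------------


def test_r2_arithmetic():
    m, c = r2_from_components(1.0, 1.0, 2.0)
    assert (m, c) == (0.25, 0.5)


def test_r2_equal_when_no_year_variance(small_designs, small_response):
    fit = fit_gamm(small_designs, small_response, fix_gamma_year=0.0)
    m, c = r2_nakagawa(fit)
    assert m == pytest.approx(c, abs=1e-12)
    assert 0 <= m <= c <= 1


def test_r2_ordering(small_fit):
    m, c = r2_nakagawa(small_fit)
    assert 0 <= m <= c <= 1


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


def test_morans_brute_force_and_expectation():
    W = np.array(
        [[0, 1, 2, 0.5], [1, 0, 3, 1], [2, 3, 0, 0.2], [0.5, 1, 0.2, 0]], dtype=float
    )
    x = np.array([1.0, -2.0, 0.5, 3.0])
    res = morans_i(x, weights=W)
    n = 4
    xc = x - x.mean()
    brute = n / W.sum() * sum(
        W[i, j] * xc[i] * xc[j] for i in range(n) for j in range(n)
    ) / (xc @ xc)
    assert res.I == pytest.approx(brute, abs=1e-12)
    assert res.expected == pytest.approx(-1.0 / 3.0)


def test_morans_random_fixtures_match_double_sum():
    rng = np.random.default_rng(17)
    for n in (10, 30, 50):
        lat = rng.uniform(34, 40, n)
        lon = rng.uniform(-123, -118, n)
        x = rng.standard_normal(n)
        res = morans_i(x, lat, lon)
        from billclim.climate_covariates import haversine_km
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    W[i, j] = 1.0 / haversine_km(lat[i], lon[i], lat[j], lon[j])
        xc = x - x.mean()
        brute = n / W.sum() * (xc @ W @ xc) / (xc @ xc)
        assert res.I == pytest.approx(brute, abs=1e-12)
        assert res.expected == pytest.approx(-1.0 / (n - 1))


def test_morans_permutation_agrees_with_analytic():
    rng = np.random.default_rng(23)
    n = 120
    lat = rng.uniform(34, 40, n)
    lon = rng.uniform(-123, -118, n)
    x = rng.standard_normal(n) + 0.5 * lat  # mild spatial trend
    res = morans_i(x, lat, lon, permutations=999, rng=np.random.default_rng(1))
    assert abs(res.p - res.p_permutation) < 0.05


def test_morans_degenerate_inputs():
    with pytest.raises(ValueError):
        morans_i(np.ones(10), np.arange(10.0), np.arange(10.0))
    with pytest.warns(RuntimeWarning, match="coincident"):
        lat = np.array([35.0, 35.0, 36.0, 37.0])
        lon = np.array([-120.0, -120.0, -121.0, -119.0])
        morans_i(np.array([1.0, 2.0, -1.0, 0.5]), lat, lon)


# ---------------------------------------------------------------------------
# GVIF
# ---------------------------------------------------------------------------


def test_gvif_orthogonal_columns():
    n = 400
    t = np.arange(n)
    X = np.column_stack([np.ones(n), np.sin(t), np.cos(t), np.sin(2 * t)])
    out = gvif(X, ["intercept", "a", "b", "c"])
    np.testing.assert_allclose(out["gvif"], 1.0, atol=1e-3)


def _standardized(v):
    v = v - v.mean()
    return v / v.std(ddof=1)


def test_gvif_known_correlation():
    rng = np.random.default_rng(2)
    z1 = _standardized(rng.standard_normal(500))
    z2 = rng.standard_normal(500)
    z2 = _standardized(z2 - z1 * (z1 @ z2) / (z1 @ z1))  # exactly orthogonal
    x2 = 0.9 * z1 + np.sqrt(1 - 0.81) * z2
    X = np.column_stack([np.ones(500), z1, x2])
    out = gvif(X, ["intercept", "x1", "x2"])
    assert out["gvif"].to_numpy() == pytest.approx([1 / (1 - 0.81)] * 2, rel=1e-9)
    assert out["gvif"].iloc[0] == pytest.approx(5.263, abs=1e-3)


def test_gvif_single_column_term_equals_classical_vif(small_designs):
    X = small_designs.X
    names = small_designs.fixed_names
    out = gvif(X, names)
    j = names.index("tarsus_mm")
    others = [i for i, nm in enumerate(names) if nm not in ("intercept", "tarsus_mm")]
    # classical VIF via the regression R^2 of the column on the others
    A = np.column_stack([np.ones(len(X)), X[:, others]])
    yj = X[:, j]
    resid = yj - A @ np.linalg.lstsq(A, yj, rcond=None)[0]
    r2 = 1 - (resid @ resid) / np.sum((yj - yj.mean()) ** 2)
    vif = 1.0 / (1.0 - r2)
    got = out.loc[out["term"] == "tarsus_mm", "gvif"].iloc[0]
    assert got == pytest.approx(vif, rel=1e-6)


# ---------------------------------------------------------------------------
# alternative body size & Bergmann
# ---------------------------------------------------------------------------


def test_wing_refit_swaps_exactly_one_column(small_sim):
    grid, spec, info = small_sim
    d_tarsus = build_design(info["covariates"], spec, ModelSpec(k=15))
    d_wing = build_design(info["covariates"], spec, ModelSpec(bodysize="wing", k=15))
    diff_cols = [
        i for i in range(d_tarsus.X.shape[1])
        if not np.allclose(d_tarsus.X[:, i], d_wing.X[:, i])
    ]
    assert diff_cols == [d_tarsus.fixed_names.index("tarsus_mm")]
    assert d_wing.fixed_names[diff_cols[0]] == "wing_chord_mm"


def test_wing_coefficient_near_zero_when_tarsus_generates(small_sim):
    """The generative model uses tarsus only, so wing chord is a null
    covariate: its estimate should be near 0 relative to its SE."""
    grid, spec, info = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = refit_alternative_bodysize(info["covariates"], spec, ModelSpec(k=15))
    est = fit.coef_fixed["wing_chord_mm"]
    se = fit.se_fixed["wing_chord_mm"]
    assert abs(est) < 3 * se
    # deterministic refit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit2 = refit_alternative_bodysize(info["covariates"], spec, ModelSpec(k=15))
    np.testing.assert_array_equal(fit.coef, fit2.coef)


def test_bergmann_recovers_negative_slope():
    """Body size declining with mean temperature is recovered when the
    temperature field has enough non-spatial variation for the slope to
    be identifiable next to the spatial smooth (with a strong latitude
    gradient, mean temperature is nearly a pure function of latitude and
    the smooth legitimately absorbs it — a concurvity limit, not a bug)."""
    p = sd.GenerativeParams(
        n=200, first_year=1932, last_year=1950,
        lat_min=35.5, lat_max=38.5, lon_min=-122.0, lon_max=-119.0,
        lat_gradient=-0.3, anomaly_sd=1.2,
    )
    grid, spec, info = sd.simulate_dataset(p, seed=19)
    rng = np.random.default_rng(31)
    modified = spec.merge(info["covariates"], left_on="catalog_id", right_on="key")
    spec2 = spec.copy()
    spec2["tarsus_mm"] = 25.0 - 0.4 * modified["mean_temp"].to_numpy() + rng.normal(0, 0.3, len(spec))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = bergmann_test(info["covariates"], spec2, ModelSpec(k=15))
    assert list(tab.columns) == ["term", "estimate", "se", "statistic", "stat_type", "df", "p"]
    row = tab[tab["term"] == "mean_temp"].iloc[0]
    assert row["estimate"] < 0
    assert abs(row["estimate"] - (-0.4)) < 2 * row["se"]


def test_bergmann_null_slope(small_sim):
    """Tarsus independent of climate -> slope consistent with zero."""
    grid, spec, info = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = bergmann_test(info["covariates"], spec, ModelSpec(k=15))
    row = tab[tab["term"] == "mean_temp"].iloc[0]
    assert abs(row["estimate"]) < 3 * row["se"]
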