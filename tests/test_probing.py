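import math

import numpy as np
import pytest
from scipy import stats

from suscept.moderation import InteractionModel
from suscept.probing import (
    classify_pattern,
    crossover_point,
    jn_region,
    pa_index,
    plot_data,
    poi_from_geometry,
    poi_index,
    probe_interaction,
    simple_slopes,
    susceptible_group,
)


def make_model(
    b_env=2.0,
    b_mod=0.5,
    b_int=1.0,
    var_env=0.04,
    var_mod=0.04,
    var_int=0.04,
    cov_env_int=0.0,
    cov_mod_int=0.0,
    df_resid=300,
    env_sd=1.0,
    mod_sd=0.5,
):
    return InteractionModel(
        b_env=b_env,
        b_mod=b_mod,
        b_int=b_int,
        var_env=var_env,
        var_mod=var_mod,
        var_int=var_int,
        cov_env_int=cov_env_int,
        cov_mod_int=cov_mod_int,
        df_resid=df_resid,
        env_sd=env_sd,
        mod_sd=mod_sd,
    )


def random_model(rng, df_resid=300):
    b_env = rng.normal(0, 2)
    b_mod = rng.normal(0, 1)
    b_int = rng.normal(0, 1)
    # random PSD 2x2 blocks for (mod, int) and (env, int)
    A = rng.normal(size=(2, 2)) * 0.3
    V1 = A @ A.T + 0.01 * np.eye(2)
    B = rng.normal(size=(2, 2)) * 0.3
    V2 = B @ B.T + 0.01 * np.eye(2)
    return make_model(
        b_env=b_env,
        b_mod=b_mod,
        b_int=b_int if abs(b_int) > 1e-3 else 0.1,
        var_env=V2[0, 0],
        var_mod=V1[0, 0],
        var_int=V1[1, 1],
        cov_env_int=V2[0, 1],
        cov_mod_int=V1[0, 1],
        df_resid=df_resid,
        env_sd=abs(rng.normal(1.0, 0.3)) + 0.2,
        mod_sd=abs(rng.normal(0.4, 0.1)) + 0.05,
    )


def grid_scan_bounds(m, alpha=0.05, span=12.0, n_grid=100_001):
    """Independent oracle: dense scan of the group-difference t-ratio,
    with each sign flip refined by direct bisection of |t| - t_crit."""
    t_crit = stats.t.ppf(1 - alpha / 2, m.df_resid)

    def excess(x_raw):
        num = m.b_mod + m.b_int * x_raw
        var = m.var_mod + x_raw**2 * m.var_int + 2 * x_raw * m.cov_mod_int
        return np.abs(num / np.sqrt(var)) - t_crit

    xs = np.linspace(-span, span, n_grid) * m.env_sd
    e = excess(xs)
    flips = np.where((e[:-1] > 0) != (e[1:] > 0))[0]
    bounds = []
    for i in flips:
        lo, hi = xs[i], xs[i + 1]
        flo = excess(lo)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fmid = excess(mid)
            if (fmid > 0) == (flo > 0):
                lo, flo = mid, fmid
            else:
                hi = mid
        bounds.append(float(0.5 * (lo + hi) / m.env_sd))
    return bounds


class TestSimpleSlopes:
    def test_linear_evaluation(self):
        m = make_model(b_env=2.0, b_int=1.0, mod_sd=0.5)
        high, low = simple_slopes(m)
        assert high.slope == pytest.approx(2.5)
        assert low.slope == pytest.approx(1.5)

    def test_se_hand_value(self):
        m = make_model(var_env=0.04, var_int=0.01, cov_env_int=0.0, mod_sd=1.0)
        high, _ = simple_slopes(m, moderator_sd=1.0)
        assert high.se == pytest.approx(math.sqrt(0.05), abs=1e-12)
        assert high.se == pytest.approx(0.2236, abs=1e-4)

    def test_midpoint_identity(self, rng):
        for _ in range(50):
            m = random_model(rng)
            high, low = simple_slopes(m)
            assert (high.slope + low.slope) / 2 == pytest.approx(
                m.b_env, rel=1e-12, abs=1e-12
            )

    def test_p_from_t_distribution(self):
        m = make_model()
        high, _ = simple_slopes(m)
        assert high.p == pytest.approx(
            2 * stats.t.sf(abs(high.t), m.df_resid)
        )


class TestJnRegion:
    def test_hand_solved_quadratic(self):
        # t_crit = 2 exactly: pick df so that ppf gives 2? Use a direct
        # check instead: solve 0.84 x^2 + x + 0.09 = 0 by hand.
        m = make_model(
            b_mod=0.5, b_int=1.0, var_mod=0.04, var_int=0.04, cov_mod_int=0.0
        )
        # evaluate with alpha chosen so t_crit == 2
        alpha = 2 * stats.t.sf(2.0, m.df_resid)
        region = jn_region(m, alpha=alpha)
        assert region.ros_lower == pytest.approx(-1.0924, abs=1e-3)
        assert region.ros_upper == pytest.approx(-0.0981, abs=1e-3)
        # outside the band: significant; inside: not
        assert region.significant_at(-2.0)
        assert region.significant_at(1.0)
        assert not region.significant_at(-0.5)

    def test_bounds_satisfy_definition(self, rng):
        checked = 0
        for _ in range(200):
            m = random_model(rng)
            region = jn_region(m)
            for bound in (region.ros_lower, region.ros_upper):
                if bound is None:
                    continue
                x = bound * m.env_sd
                t = (m.b_mod + m.b_int * x) / math.sqrt(
                    m.var_mod + x * x * m.var_int + 2 * x * m.cov_mod_int
                )
                assert abs(abs(t) - region.t_crit) < 1e-8
                checked += 1
        assert checked > 50

    def test_large_main_effect_all_significant(self):
        m = make_model(b_mod=10.0, b_int=1e-6, var_int=0.04)
        region = jn_region(m)
        assert region.all_significant
        assert region.ros_lower is None

    def test_zero_interaction_variance(self):
        m = make_model(var_int=0.0)
        with pytest.raises(ValueError):
            jn_region(m)

    def test_matches_grid_scan(self, rng):
        for _ in range(30):
            m = random_model(rng)
            region = jn_region(m)
            scan = grid_scan_bounds(m)
            solved = sorted(
                b
                for b in (region.ros_lower, region.ros_upper)
                if b is not None and -12 < b < 12
            )
            if solved:
                for b in solved:
                    assert min(abs(b - s) for s in scan) < 1e-3


class TestCrossover:
    def test_zero_mod_coefficient(self):
        m = make_model(b_mod=0.0, b_int=2.0)
        assert crossover_point(m) == 0.0

    def test_printed_coefficient_arithmetic(self):
        # HCC B = 0.037, interaction B = 3.055, env SD = 8.38/72
        m = make_model(
            b_mod=0.037, b_int=3.055, env_sd=8.38 / 72.0
        )
        assert crossover_point(m) == pytest.approx(-0.104, abs=1e-3)

    def test_sign_flip(self):
        m1 = make_model(b_mod=0.3, b_int=1.5)
        m2 = make_model(b_mod=0.3, b_int=-1.5)
        assert crossover_point(m1) == pytest.approx(-crossover_point(m2))

    def test_parallel_lines_error(self):
        m = make_model(b_int=0.0)
        with pytest.raises(ZeroDivisionError):
            crossover_point(m)


class TestPoi:
    def test_midpoint_half(self):
        assert poi_from_geometry(0.0, (-2, 2), +1) == 0.5

    def test_adverse_edge_whole_area(self):
        assert poi_from_geometry(-2.0, (-2, 2), +1) == 1.0

    def test_interior_hand_value(self):
        # crossover +1, vantage right: 1^2/(1^2+3^2) = 0.1
        assert poi_from_geometry(1.0, (-2, 2), +1) == pytest.approx(0.1)

    def test_clamped_outside_range(self):
        assert poi_from_geometry(5.0, (-2, 2), +1) == 0.0
        assert poi_from_geometry(-5.0, (-2, 2), +1) == 1.0

    def test_agrees_with_numeric_integration(self, rng):
        for _ in range(200):
            cx = rng.uniform(-3, 3)
            L, U = -2.0, 2.0
            side = rng.choice([-1, 1])
            slope = rng.uniform(0.1, 5.0)  # |gap| grows linearly from cx
            xs = np.linspace(L, U, 20_001)
            gap = slope * np.abs(xs - cx)
            right = np.trapezoid(np.where(xs >= cx, gap, 0.0), xs)
            left = np.trapezoid(np.where(xs < cx, gap, 0.0), xs)
            want = (right if side > 0 else left) / (right + left)
            got = poi_from_geometry(cx, (L, U), side)
            assert got == pytest.approx(want, abs=1e-4)

    def test_poi_via_model(self):
        m = make_model(b_mod=0.0, b_int=1.0)
        assert poi_index(m, outcome_polarity=1) == pytest.approx(0.5)


class TestPa:
    def test_crossover_at_median(self):
        m = make_model(b_mod=0.0, b_int=1.0)  # crossover 0, vantage right
        xs = np.linspace(-1, 1, 101)  # median exactly 0
        assert pa_index(m, xs, 1) == pytest.approx(0.5, abs=0.01)

    def test_count_hand_value(self):
        m = make_model(b_mod=-0.5, b_int=1.0)  # crossover +0.5, vantage right
        assert pa_index(m, [-1.0, 0.0, 1.0, 2.0], 1) == 0.5

    def test_crossover_below_minimum(self):
        m = make_model(b_mod=5.0, b_int=1.0, env_sd=1.0)  # crossover -5
        assert pa_index(m, [0.0, 1.0, 2.0], 1) == 1.0

    def test_empty_sample(self):
        m = make_model()
        with pytest.raises(ValueError):
            pa_index(m, [], 1)


def probe_with(m, env_polarity=1, outcome_polarity=1, alpha=0.05):
    return probe_interaction(
        m,
        alpha=alpha,
        env_polarity=env_polarity,
        outcome_polarity=outcome_polarity,
        env_values_sd=np.linspace(-2, 2, 101),
    )


class TestClassify:
    def test_both_ends_significant_differential(self):
        # strong symmetric interaction, crossover near 0
        m = make_model(
            b_mod=0.01, b_int=1.0, var_mod=0.01, var_int=0.01, mod_sd=0.4
        )
        probe = probe_with(m)
        cls = classify_pattern(probe, interaction_p=0.001)
        assert cls.label == "differential_susceptibility"

    def test_supportive_end_only_vantage(self):
        # crossover at the adverse edge (-2): difference only at high env
        m = make_model(
            b_mod=2.0, b_int=1.0, var_mod=0.04, var_int=0.01, mod_sd=0.4
        )
        probe = probe_with(m)
        cls = classify_pattern(probe, interaction_p=0.001)
        assert cls.label == "vantage_sensitivity"

    def test_adverse_end_only_diathesis(self):
        # crossover at the supportive edge (+2)
        m = make_model(
            b_mod=-2.0, b_int=1.0, var_mod=0.04, var_int=0.01, mod_sd=0.4
        )
        probe = probe_with(m)
        cls = classify_pattern(probe, interaction_p=0.001)
        assert cls.label == "diathesis_stress"

    def test_adverse_coded_env_flips_ends(self):
        # for an adverse-coded env (higher = worse), the supportive end
        # is the low end; crossover at +2 now means vantage sensitivity
        m = make_model(
            b_mod=-2.0, b_int=1.0, var_mod=0.04, var_int=0.01, mod_sd=0.4
        )
        probe = probe_with(m, env_polarity=-1)
        cls = classify_pattern(probe, interaction_p=0.001, env_polarity=-1)
        assert cls.label == "vantage_sensitivity"

    def test_nonsignificant_interaction_none(self):
        m = make_model(b_mod=0.01, b_int=1.0, var_mod=0.01, var_int=0.01)
        probe = probe_with(m)
        cls = classify_pattern(probe, interaction_p=0.30)
        assert cls.label == "none"
        assert cls.susceptible_group is None

    def test_no_significant_end_none(self):
        m = make_model(
            b_mod=0.0, b_int=0.05, var_mod=0.5, var_int=0.5, mod_sd=0.4
        )
        probe = probe_with(m)
        cls = classify_pattern(probe, interaction_p=0.001)
        assert cls.label == "none"

    def test_poi_gate(self):
        # differential pattern with asymmetric crossover: PoI outside band
        m = make_model(
            b_mod=-1.0, b_int=1.0, var_mod=0.01, var_int=0.01, mod_sd=0.4
        )
        probe = probe_with(m)
        assert probe.poi is not None and not 0.40 <= probe.poi <= 0.60
        lax = classify_pattern(probe, interaction_p=0.001)
        strict = classify_pattern(probe, interaction_p=0.001, poi_gate=True)
        assert lax.label == "differential_susceptibility"
        assert strict.label == "none"

    def test_affine_invariance(self, rng):
        # rescaling env, moderator and outcome by positive factors leaves
        # the classification label unchanged
        for _ in range(30):
            m = random_model(rng)
            probe = probe_with(m)
            cls = classify_pattern(probe, interaction_p=0.01)
            a, c = rng.uniform(0.2, 5, size=2)  # env, outcome scales
            b = rng.uniform(0.2, 5)  # moderator scale
            scaled = InteractionModel(
                b_env=m.b_env * c / a,
                b_mod=m.b_mod * c / b,
                b_int=m.b_int * c / (a * b),
                var_env=m.var_env * (c / a) ** 2,
                var_mod=m.var_mod * (c / b) ** 2,
                var_int=m.var_int * (c / (a * b)) ** 2,
                cov_env_int=m.cov_env_int * (c / a) * (c / (a * b)),
                cov_mod_int=m.cov_mod_int * (c / b) * (c / (a * b)),
                df_resid=m.df_resid,
                env_sd=m.env_sd * a,
                mod_sd=m.mod_sd * b,
            )
            probe2 = probe_with(scaled)
            cls2 = classify_pattern(probe2, interaction_p=0.01)
            assert cls.label == cls2.label


class TestPlotData:
    def test_grid_shape_and_flags(self):
        m = make_model(b_mod=0.01, b_int=1.0, var_mod=0.01, var_int=0.01)
        rows = plot_data(m, n_grid=41)
        assert len(rows) == 41
        region = jn_region(m)
        for row in rows:
            assert row["significant"] == (abs(row["diff_t"]) > region.t_crit)

    def test_lines_cross_at_crossover(self):
        m = make_model(b_mod=-0.5, b_int=1.0)
        cx = crossover_point(m)
        rows = plot_data(m, n_grid=2001, eval_range=(-2, 2))
        gaps = [abs(r["pred_high_moderator"] - r["pred_low_moderator"])
                for r in rows]
        xs = [r["env_sd"] for r in rows]
        assert xs[int(np.argmin(gaps))] == pytest.approx(cx, abs=0.01)


class TestSusceptibleGroup:
    def test_high_moderator_wider_range(self):
        m = make_model(b_env=1.0, b_int=1.0, mod_sd=0.5)
        assert susceptible_group(m) == "high_moderator"

    def test_low_moderator_wider_range(self):
        m = make_model(b_env=1.0, b_int=-1.0, mod_sd=0.5)
        assert susceptible_group(m) == "low_moderator"
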