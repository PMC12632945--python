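import math

import numpy as np
import pytest

from genodegrade.missingness import (BetaMissingnessModel, DispersalPlan,
                                     MissingnessProfile, apply_plan,
                                     beta_model_from_moments,
                                     beta_model_from_template,
                                     block_bounds, extract_profile,
                                     plan_from_beta, replicate_dispersal)
from genodegrade.model import MISSING, EmptyMatrixError

from conftest import build_matrix


def oracle_block_of(i: int, n: int, m: int) -> int:
    """Independent assignment of item i to its block when [0, n) is cut
    into m proportional contiguous pieces: the unique j with
    floor(j*n/m) <= i < floor((j+1)*n/m), found by scanning."""
    for j in range(m):
        if math.floor(j * n / m) <= i < math.floor((j + 1) * n / m):
            return j
    raise AssertionError(f"index {i} not covered by any block ({n=}, {m=})")


class TestBlockBounds:
    @pytest.mark.parametrize("n", range(1, 13))
    @pytest.mark.parametrize("m", range(1, 13))
    def test_partition_is_contiguous_exhaustive_nonoverlapping(self, n, m):
        if m > n:
            # only used in the m <= n orientation by the engine, but the
            # partition itself must still cover [0, n)
            bounds = block_bounds(n, m)
            covered = [i for lo, hi in bounds for i in range(lo, hi)]
            assert covered == list(range(n))
            return
        bounds = block_bounds(n, m)
        assert len(bounds) == m
        assert bounds[0][0] == 0 and bounds[-1][1] == n
        for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
            assert hi1 == lo2
        assert all(hi > lo for lo, hi in bounds)   # non-empty
        # agrees with the independently coded per-index assignment
        for j, (lo, hi) in enumerate(bounds):
            for i in range(lo, hi):
                assert oracle_block_of(i, n, m) == j

    def test_equal_blocks_when_m_divides_n(self):
        assert block_bounds(12, 4) == [(0, 3), (3, 6), (6, 9), (9, 12)]


class TestReplicateDispersal:
    def test_m_equals_n_is_exact_identity(self):
        rng = np.random.default_rng(0)
        for k in range(200):
            n = int(rng.integers(1, 40))
            x = rng.random(n)
            plan = replicate_dispersal(MissingnessProfile(x), n,
                                       np.random.default_rng(k))
            assert np.array_equal(plan.targets, x)

    @pytest.mark.parametrize("n", range(1, 13))
    @pytest.mark.parametrize("m", range(1, 13))
    def test_constant_profile_preserved(self, n, m):
        x = np.full(n, 0.37)
        plan = replicate_dispersal(MissingnessProfile(x), m,
                                   np.random.default_rng(n * 13 + m))
        assert np.allclose(plan.targets, 0.37)

    def test_downsampling_draws_from_the_right_block(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        for seed in range(100):
            plan = replicate_dispersal(MissingnessProfile(x), 2,
                                       np.random.default_rng(seed))
            assert plan.targets[0] in (0.1, 0.2)
            assert plan.targets[1] in (0.3, 0.4)

    @pytest.mark.parametrize("n", range(1, 13))
    @pytest.mark.parametrize("m", range(1, 13))
    def test_block_oracle_small_cases(self, n, m):
        """Every target obeys the independently computed block rule, for
        all shapes up to 12 x 12 and 50 seeds each."""
        base = np.random.default_rng(n * 1000 + m)
        x = base.random(n)
        prof = MissingnessProfile(x)
        for seed in range(50):
            y = replicate_dispersal(prof, m,
                                    np.random.default_rng(seed)).targets
            if m <= n:
                for j in range(m):
                    block = [x[i] for i in range(n)
                             if oracle_block_of(i, n, m) == j]
                    assert y[j] in block
            elif n == 1:
                assert np.all(y == x[0])
            else:
                for t in range(m):
                    j = oracle_block_of(t, m, n)
                    pair = ((x[j], x[j + 1]) if j < n - 1
                            else (x[n - 2], x[n - 1]))
                    assert min(pair) <= y[t] <= max(pair)

    def test_upsampling_from_extremes_has_uniform_moments(self):
        plan = replicate_dispersal(
            MissingnessProfile(np.array([0.0, 1.0])), 1000,
            np.random.default_rng(42))
        assert np.all((plan.targets >= 0) & (plan.targets < 1))
        assert abs(plan.targets.mean() - 0.5) < 0.05

    def test_monotone_template_yields_monotone_trend(self):
        x = np.linspace(0, 0.9, 50)
        plan = replicate_dispersal(MissingnessProfile(x), 5000,
                                   np.random.default_rng(7))
        r = np.corrcoef(np.arange(5000), plan.targets)[0, 1]
        assert r > 0.9

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            replicate_dispersal(MissingnessProfile(np.array([0.5])), 0,
                                np.random.default_rng(0))


class TestExtractProfile:
    def test_counts_fully_missing_per_site(self):
        m = build_matrix([
            [(None, None), (0, 1), (1, 1), (0, 0)],
            [(0, 0), (0, 1), (1, 1), (0, 0)],
        ])
        prof = extract_profile(m)
        assert prof.N == 2
        assert list(prof.proportions) == [0.25, 0.0]

    def test_empty_matrix_rejected(self):
        import genodegrade.model as model
        import numpy as np
        empty = model.GenotypeMatrix(
            ["a"], [], [], [], [], [],
            np.empty((0, 1, 2), np.int16), np.empty((0, 1), bool))
        with pytest.raises(EmptyMatrixError):
            extract_profile(empty)


class TestBetaModel:
    def test_uniform_special_case(self):
        m = beta_model_from_moments(0.5, math.sqrt(1 / 12))
        assert m.alpha == pytest.approx(1.0)
        assert m.beta == pytest.approx(1.0)

    def test_ancient_panel_moments(self):
        """Moments typical of a large ancient-DNA panel (mean 0.56,
        sd 0.21) give alpha ~ 2.569, beta ~ 2.018."""
        m = beta_model_from_moments(0.56, 0.21)
        assert m.alpha == pytest.approx(2.5689, abs=1e-3)
        assert m.beta == pytest.approx(2.0184, abs=1e-3)

    def test_infeasible_sd_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_model_from_moments(0.5, 0.5)

    def test_mean_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            beta_model_from_moments(1.0, 0.1)

    def test_from_template_hand_computation(self):
        # profile [0.5, 0.0] -> mean .25, population sd .25
        m = build_matrix([
            [(None, None), (0, 1), (1, 1), (None, None)],  # x = 0.5
            [(0, 0), (0, 1), (1, 1), (0, 0)],               # x = 0.0
        ])
        model = beta_model_from_template(m)
        assert model.mean == pytest.approx(0.25)
        assert model.sd == pytest.approx(0.25)
        nu = 0.25 * 0.75 / 0.0625 - 1
        assert model.alpha == pytest.approx(0.25 * nu)
        assert model.beta == pytest.approx(0.75 * nu)

    def test_zero_variance_template_rejected(self):
        m = build_matrix([
            [(None, None), (0, 1)],
            [(None, None), (1, 1)],
        ])
        with pytest.raises(ValueError, match="zero variance"):
            beta_model_from_template(m)

    def test_parameter_recovery_from_beta_template(self):
        from genodegrade.fixtures import TemplateSpec, make_template
        spec = TemplateSpec(4000, 60, ("beta", 2.0, 2.0), seed=5)
        model = beta_model_from_template(make_template(spec))
        assert model.mean == pytest.approx(0.5, abs=0.03)


class TestPlanFromBeta:
    def test_uniform_model_mean(self):
        model = BetaMissingnessModel(0.5, math.sqrt(1 / 12))
        plan = plan_from_beta(model, 10000, np.random.default_rng(3))
        assert abs(plan.targets.mean() - 0.5) < 0.015

    def test_single_draw_in_unit_interval(self):
        plan = plan_from_beta(beta_model_from_moments(0.3, 0.1), 1,
                              np.random.default_rng(0))
        assert 0 < plan.targets[0] < 1

    def test_seeded_determinism(self):
        model = beta_model_from_moments(0.56, 0.21)
        a = plan_from_beta(model, 100, np.random.default_rng(9))
        b = plan_from_beta(model, 100, np.random.default_rng(9))
        assert np.array_equal(a.targets, b.targets)


class TestApplyPlan:
    def test_zero_plan_is_identity(self, random_matrix):
        plan = DispersalPlan(np.zeros(random_matrix.n_sites))
        out = apply_plan(random_matrix, plan, np.random.default_rng(0))
        assert out == random_matrix

    def test_all_ones_plan_erases_everything(self, random_matrix):
        plan = DispersalPlan(np.ones(random_matrix.n_sites))
        out = apply_plan(random_matrix, plan, np.random.default_rng(0))
        assert (out.alleles == MISSING).all()

    def test_already_missing_stays_missing(self, random_matrix):
        plan = DispersalPlan(np.full(random_matrix.n_sites, 0.5))
        out = apply_plan(random_matrix, plan, np.random.default_rng(1))
        before = random_matrix.fully_missing_mask()
        after = out.fully_missing_mask()
        assert after[before].all()

    def test_realized_fraction_concentrates(self):
        from genodegrade.fixtures import make_clean_segment
        m = make_clean_segment(500, 200, seed=2)
        plan = DispersalPlan(np.full(500, 0.3))
        out = apply_plan(m, plan, np.random.default_rng(11))
        frac = out.fully_missing_mask().mean()
        assert abs(frac - 0.3) < 0.01

    def test_exact_count_realization(self):
        from genodegrade.fixtures import make_clean_segment
        m = make_clean_segment(40, 100, seed=3)
        plan = DispersalPlan(np.full(40, 0.25))
        out = apply_plan(m, plan, np.random.default_rng(4),
                         exact_count=True)
        assert np.allclose(out.missing_proportions(), 0.25)

    def test_length_mismatch_rejected(self, random_matrix):
        plan = DispersalPlan(np.zeros(random_matrix.n_sites + 1))
        with pytest.raises(ValueError, match="site count"):
            apply_plan(random_matrix, plan, np.random.default_rng(0))

    def test_non_genotype_fields_untouched(self, random_matrix):
        plan = DispersalPlan(np.full(random_matrix.n_sites, 0.9))
        out = apply_plan(random_matrix, plan, np.random.default_rng(5))
        assert out.chrom == random_matrix.chrom
        assert np.array_equal(out.pos, random_matrix.pos)
        assert out.ref == random_matrix.ref
        assert out.alt == random_matrix.alt
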