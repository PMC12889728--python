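"""Design construction, Aspin-Welch statistic, within-block
permutations and Freedman-Lane inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from fcgraph.glm import (
    aspin_welch_v,
    build_design,
    fwe_correct,
    permute_within_blocks,
    run_permutation_glm,
)
from fcgraph.synthetic import CohortConfig, generate_cohort


def cohort_with_fd(n=80, seed=0, n_sites=4):
    cfg = CohortConfig(n_participants=n, n_sites=n_sites, n_parcels=24)
    cohort, _ = generate_cohort(cfg, seed)
    rng = np.random.default_rng(seed + 1)
    cohort["mean_fd"] = rng.uniform(0.05, 0.2, size=n)
    return cohort


class TestBuildDesign:
    def test_site_dummy_count(self):
        cohort = cohort_with_fd(n_sites=2)
        design = build_design(cohort)
        assert sum(c.startswith("site_") for c in design.columns) == 1

    def test_interaction_is_product_of_centered_mains(self):
        design = build_design(cohort_with_fd())
        X = design.X
        cols = list(design.columns)
        lone = X[:, cols.index("loneliness")]
        age = X[:, cols.index("age")]
        inter = X[:, cols.index("interaction")]
        assert abs(lone.mean()) < 1e-10
        assert abs(age.mean()) < 1e-10
        assert np.abs(inter - lone * age).max() < 1e-12

    def test_centering_decorrelates_interaction(self):
        design = build_design(cohort_with_fd(n=400))
        cols = list(design.columns)
        X = design.X
        inter = X[:, cols.index("interaction")]
        for main in ("loneliness", "age"):
            r = np.corrcoef(inter, X[:, cols.index(main)])[0, 1]
            assert abs(r) < 0.25

    def test_missing_rows_dropped_and_counted(self):
        cohort = cohort_with_fd()
        cohort.loc[3, "marital"] = np.nan
        cohort.loc[7, "marital"] = np.nan
        design = build_design(cohort, model="adjusted")
        assert design.n_dropped == 2
        assert design.n == len(cohort) - 2
        # the base model does not use marital status, so nothing drops
        assert build_design(cohort, model="base").n_dropped == 0

    def test_blocks_equal_variance_groups_equal_site(self):
        design = build_design(cohort_with_fd())
        assert np.array_equal(design.blocks, design.variance_groups)
        assert len(np.unique(design.blocks)) == 4

    def test_rank_deficiency_names_columns(self):
        cohort = cohort_with_fd()
        cohort["gmv"] = cohort["moca"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            build_design(cohort)

    def test_small_site_rejected(self):
        cohort = cohort_with_fd()
        cohort.loc[cohort["site"] == "site2", "site"] = "site1"
        cohort.loc[cohort.index[:2], "site"] = "site2"
        with pytest.raises(ValueError, match="fewer than 3"):
            build_design(cohort)


class TestAspinWelchV:
    def test_single_group_equals_classical_t(self, rng):
        n, p = 60, 5
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n)
        c = np.zeros(p)
        c[2] = 1.0
        v = aspin_welch_v(y, X, c)
        t_ref = sm.OLS(y, X).fit().tvalues[2]
        assert v == pytest.approx(t_ref, abs=1e-10)

    def test_two_equal_variance_groups_agree_with_pooled_t(self, rng):
        n = 1000
        groups = np.repeat([0, 1], n // 2)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        c = np.array([0.0, 1.0])
        rel = []
        for _ in range(20):
            y = rng.normal(size=n)
            v = aspin_welch_v(y, X, c, groups)
            t = sm.OLS(y, X).fit().tvalues[1]
            if abs(t) > 0.2:
                rel.append(abs(v - t) / abs(t))
        assert np.median(rel) < 0.02

    def test_null_statistic_centered_at_zero(self, rng):
        n = 50
        groups = np.repeat([0, 1], n // 2)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        c = np.array([0.0, 1.0])
        vs = [
            aspin_welch_v(rng.normal(size=n), X, c, groups) for _ in range(300)
        ]
        assert abs(np.mean(vs)) < 3 * np.std(vs) / np.sqrt(len(vs)) + 0.05

    def test_zero_group_rss_rejected(self):
        X = np.column_stack([np.ones(6), [0, 1, 2, 3, 4, 5.0]])
        y = X @ np.array([1.0, 2.0])  # perfect fit, zero residuals
        with pytest.raises(ValueError, match="zero residual"):
            aspin_welch_v(y, X, np.array([0.0, 1.0]), np.repeat([0, 1], 3))


class TestPermuteWithinBlocks:
    def test_singleton_blocks_force_identity(self, rng):
        perm = permute_within_blocks(5, np.arange(5), rng)
        assert np.array_equal(perm, np.arange(5))

    def test_blocks_never_mix(self, rng):
        blocks = np.array([0, 0, 1, 1, 1, 2, 2])
        for _ in range(200):
            perm = permute_within_blocks(7, blocks, rng)
            assert np.array_equal(blocks[perm], blocks)

    def test_uniform_over_single_block(self, rng):
        counts = {}
        for _ in range(10000):
            perm = tuple(permute_within_blocks(4, np.zeros(4), rng))
            counts[perm] = counts.get(perm, 0) + 1
        assert len(counts) == 24
        chi2 = sum((c - 10000 / 24) ** 2 / (10000 / 24) for c in counts.values())
        assert chi2 < stats.chi2.ppf(0.999, 23)


@pytest.fixture(scope="module")
def setup():
    cohort = cohort_with_fd(n=60, seed=5)
    design = build_design(cohort)
    rng = np.random.default_rng(7)
    table = pd.DataFrame(
        rng.normal(size=(60, 6)),
        index=cohort["participant_id"],
        columns=[f"P{i}" for i in range(6)],
    )
    return design, table


class TestRunPermutationGlm:
    def test_deterministic_given_seed(self, setup):
        design, table = setup
        a = run_permutation_glm(table, design, n_perm=200, seed=9)
        b = run_permutation_glm(table, design, n_perm=200, seed=9)
        for cname in a.tables:
            pd.testing.assert_frame_equal(a.tables[cname], b.tables[cname])

    def test_fwe_dominates_uncorrected(self, setup):
        design, table = setup
        res = run_permutation_glm(table, design, n_perm=300, seed=2)
        for t in res.tables.values():
            assert (t["p_fwe"] >= t["p_unc"] - 1e-12).all()
            assert ((t["p_unc"] > 0) & (t["p_unc"] <= 1)).all()

    def test_z_is_inverse_normal_of_p(self, setup):
        design, table = setup
        res = run_permutation_glm(table, design, n_perm=300, seed=2)
        t = res.table("age")
        z_ref = np.sign(t["v"]) * stats.norm.ppf(1 - t["p_unc"] / 2)
        assert np.abs(t["z"] - z_ref).max() < 1e-12

    def test_row_mismatch_rejected(self, setup):
        design, table = setup
        with pytest.raises(ValueError, match="rows|missing"):
            run_permutation_glm(table.iloc[:-3].to_numpy(), design, n_perm=200, seed=0)

    def test_exhaustive_enumeration_for_tiny_blocks(self):
        rng = np.random.default_rng(3)
        n = 7
        X = np.column_stack(
            [np.ones(n), rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)]
        )
        from fcgraph.glm import DesignMatrix

        blocks = np.array([0, 0, 0, 1, 1, 1, 1])
        design = DesignMatrix(
            X=X,
            columns=("intercept", "loneliness", "age", "interaction"),
            contrasts={"age": np.array([0, 0, 1.0, 0])},
            blocks=blocks,
            variance_groups=np.zeros(n, dtype=int),
            participant_ids=tuple(f"s{i}" for i in range(n)),
        )
        y = rng.normal(size=(n, 2))
        with pytest.warns(UserWarning, match="exhaustively"):
            res = run_permutation_glm(y, design, n_perm=500, seed=1, contrasts=("age",))
        assert res.exhaustive
        assert res.n_perm == 6 * 24  # 3! * 4! distinct permutations
        assert (res.table("age")["p_unc"] > 0).all()


class TestFweCorrect:
    def test_extremes(self):
        dist = np.array([1.0, 2.0, 3.0, 4.0])
        assert fwe_correct(np.array([10.0]), dist)[0] == pytest.approx(1 / 5)
        assert fwe_correct(np.array([0.5]), dist)[0] == pytest.approx(1.0)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            fwe_correct(np.array([1.0]), np.array([]))
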