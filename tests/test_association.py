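"""Association-statistics tests: exact 2x2 tests, logistic fit, KS, r2."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from censite.association import (
    SeparationError,
    external_set_enrichment,
    fisher_exact_upper,
    fit_logistic_sites,
    isomir_shared_site_test,
    ks_shift_test,
    nagelkerke_r2,
    set_overlap,
    site_type_enrichment,
)
from censite.model import Region, SiteClass
from censite.scanner import ALL_CLASSES, ALL_REGIONS, SiteCountRow, SiteCountTable
from oracles import oracle_hypergeom_upper


def table_from_counts(counts_by_tid, mirna_id="mir"):
    """Build a SiteCountTable from {tid: {(class, region): count}}."""
    rows = []
    for tid, spec in counts_by_tid.items():
        counts = {(c, r): 0 for c in ALL_CLASSES for r in ALL_REGIONS}
        counts.update(spec)
        densities = {k: float(v) for k, v in counts.items()}
        rows.append(SiteCountRow(tid, mirna_id, counts, densities))
    return SiteCountTable.from_rows(rows)


class TestFisherExactUpper:
    def test_diagonal_table(self):
        res = fisher_exact_upper([[5, 0], [0, 5]])
        assert res.p_upper == pytest.approx(1 / 252, rel=1e-12)
        assert res.corrected

    def test_balanced_table(self):
        res = fisher_exact_upper([[1, 1], [1, 1]])
        assert res.p_upper == pytest.approx(5 / 6, rel=1e-12)
        assert res.odds_ratio == pytest.approx(1.0)
        assert not res.corrected

    def test_zero_successes_gives_maximal_tail(self):
        res = fisher_exact_upper([[0, 5], [3, 2]])
        assert res.p_upper == pytest.approx(1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_upper([[1, -1], [0, 2]])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_upper([[0, 0], [0, 0]])

    def test_matches_enumeration_small_margins(self):
        for w in range(0, 7):
            for x in range(0, 7):
                for y in range(0, 7):
                    for z in range(0, 7):
                        if w + x + y + z == 0:
                            continue
                        res = fisher_exact_upper([[w, x], [y, z]])
                        assert res.p_upper == pytest.approx(
                            oracle_hypergeom_upper(w, x, y, z), abs=1e-12
                        )

    def test_matches_scipy_greater(self, rng):
        for _ in range(100):
            w, x, y, z = rng.integers(0, 40, size=4)
            if w + x + y + z == 0:
                continue
            res = fisher_exact_upper([[w, x], [y, z]])
            _, p_ref = stats.fisher_exact([[w, x], [y, z]],
                                          alternative="greater")
            assert res.p_upper == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_ci_brackets_or_when_all_cells_positive(self, rng):
        for _ in range(50):
            cells = rng.integers(1, 50, size=4)
            res = fisher_exact_upper([cells[:2], cells[2:]])
            assert res.ci_low <= res.odds_ratio <= res.ci_high


class TestSiteTypeEnrichment:
    def test_planted_direction_recovered(self):
        counts = {}
        for i in range(200):
            tid = f"t{i}"
            has = (i < 100 and i % 2 == 0) or (i >= 100 and i % 10 == 0)
            counts[tid] = (
                {(SiteClass.CEN_GU_1MM, Region.UTR3): 1} if has else {}
            )
        table = table_from_counts(counts)
        targets = {f"t{i}" for i in range(100)}
        res = site_type_enrichment(
            targets, set(counts), table, "mir", SiteClass.CEN_GU_1MM
        )
        assert res.odds_ratio > 1
        assert res.p_upper < 1e-6

    def test_exclusive_mode_drops_multi_class_transcripts(self):
        counts = {
            "t0": {(SiteClass.SEED_8MER, Region.UTR3): 1,
                   (SiteClass.CEN_WC_0MM, Region.UTR3): 1},
            "t1": {(SiteClass.CEN_WC_0MM, Region.UTR3): 1},
            "t2": {},
            "t3": {},
        }
        table = table_from_counts(counts)
        res = site_type_enrichment(
            {"t0", "t1"}, set(counts), table, "mir", SiteClass.CEN_WC_0MM,
            exclusive=True,
        )
        # t0 excluded: targets reduce to t1 (with site)
        assert (res.w, res.x, res.y, res.z) == (1, 0, 0, 2)

    def test_targets_must_be_subset(self):
        table = table_from_counts({"t0": {}})
        with pytest.raises(ValueError):
            site_type_enrichment({"zz"}, {"t0"}, table, "mir",
                                 SiteClass.SEED_8MER)

    def test_null_planting_gives_or_near_one(self, rng):
        ors = []
        for rep in range(30):
            counts = {
                f"t{i}": (
                    {(SiteClass.SEED_8MER, Region.UTR3): 1}
                    if rng.random() < 0.3 else {}
                )
                for i in range(200)
            }
            table = table_from_counts(counts)
            targets = set(rng.choice(sorted(counts), size=80, replace=False))
            res = site_type_enrichment(targets, set(counts), table, "mir",
                                       SiteClass.SEED_8MER)
            ors.append(np.log(res.odds_ratio))
        assert abs(np.mean(ors)) < 0.2


class TestLogisticFit:
    def test_intercept_only_closed_form(self, rng):
        counts = {f"t{i}": {} for i in range(40)}
        table = table_from_counts(counts)
        y = pd.Series(
            {(f"t{i}", "mir"): int(i < 13) for i in range(40)}
        )
        fit = fit_logistic_sites(y, table, mode="count")
        pbar = 13 / 40
        assert fit.params["(intercept)"] == pytest.approx(
            np.log(pbar / (1 - pbar)), abs=1e-8
        )
        assert len(fit.params) == 1  # all covariates were zero-variance
        assert fit.r2_nagelkerke == pytest.approx(0.0, abs=1e-10)

    def _simulated(self, rng, n=800, beta0=-1.0, beta=1.2):
        counts = {}
        x = rng.poisson(0.7, size=n)
        for i in range(n):
            counts[f"t{i:04d}"] = {
                (SiteClass.SEED_8MER, Region.UTR3): int(x[i])
            }
        table = table_from_counts(counts)
        eta = beta0 + beta * x
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        status = pd.Series(
            {(f"t{i:04d}", "mir"): int(y[i]) for i in range(n)}
        )
        return table, status

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        table, status = self._simulated(rng)
        fit = fit_logistic_sites(
            status, table, mode="count",
            classes=[SiteClass.SEED_8MER], regions=[Region.UTR3],
        )
        X = np.column_stack([
            np.ones(len(status)),
            table.df["count_SEED_8MER_UTR3"].to_numpy(float),
        ])
        ref = sm.GLM(status.to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params,
                                   atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, rtol=1e-4)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_gradient_at_solution_is_zero(self, rng):
        table, status = self._simulated(rng)
        fit = fit_logistic_sites(
            status, table, mode="count",
            classes=[SiteClass.SEED_8MER], regions=[Region.UTR3],
        )
        X = np.column_stack([
            np.ones(len(status)),
            table.df["count_SEED_8MER_UTR3"].to_numpy(float),
        ])
        mu = 1 / (1 + np.exp(-(X @ fit.params.to_numpy())))
        grad = X.T @ (status.to_numpy() - mu)
        assert np.max(np.abs(grad)) < 1e-6

    def test_complete_separation_names_covariate(self):
        counts = {
            f"t{i}": (
                {(SiteClass.SEED_8MER, Region.UTR3): 1} if i < 20 else {}
            )
            for i in range(40)
        }
        table = table_from_counts(counts)
        y = pd.Series({(f"t{i}", "mir"): int(i < 20) for i in range(40)})
        with pytest.raises(SeparationError, match="SEED_8MER_UTR3"):
            fit_logistic_sites(
                y, table, mode="count",
                classes=[SiteClass.SEED_8MER], regions=[Region.UTR3],
            )

    def test_parameter_recovery_within_2se(self, rng):
        hits = 0
        reps = 20
        for _ in range(reps):
            table, status = self._simulated(rng, n=600)
            fit = fit_logistic_sites(
                status, table, mode="count",
                classes=[SiteClass.SEED_8MER], regions=[Region.UTR3],
            )
            est = fit.params["count_SEED_8MER_UTR3"]
            se = fit.bse["count_SEED_8MER_UTR3"]
            hits += abs(est - 1.2) <= 2 * se
        assert hits >= int(0.9 * reps)

    def test_null_covariate_type_i_rate(self, rng):
        rejections = 0
        reps = 40
        for _ in range(reps):
            n = 300
            counts = {
                f"t{i}": {(SiteClass.CEN_GU_0MM, Region.CDS):
                          int(rng.poisson(0.5))}
                for i in range(n)
            }
            table = table_from_counts(counts)
            y = pd.Series({(f"t{i}", "mir"): int(rng.random() < 0.4)
                           for i in range(n)})
            fit = fit_logistic_sites(
                y, table, mode="count",
                classes=[SiteClass.CEN_GU_0MM], regions=[Region.CDS],
            )
            rejections += fit.pvalues["count_CEN_GU_0MM_CDS"] < 0.05
        assert rejections / reps < 0.15


class TestNagelkerke:
    def test_null_model_gives_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 50) == 0.0

    def test_saturated_model_gives_one(self):
        assert nagelkerke_r2(-30.0, 0.0, 50) == pytest.approx(1.0)

    def test_formula_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 500))
            l0 = -float(rng.uniform(1, 300))
            l1 = l0 + float(rng.uniform(0, -l0))
            r2_cs = 1 - np.exp(2 * (l0 - l1) / n)
            expected = r2_cs / (1 - np.exp(2 * l0 / n))
            assert nagelkerke_r2(l0, l1, n) == pytest.approx(
                min(1.0, expected), abs=1e-12
            )

    def test_l1_below_l0_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-10.0, -20.0, 30)


class TestKsShift:
    def test_identical_samples(self):
        x = [0.1, 0.5, 0.9, 1.4]
        d, p = ks_shift_test(x, x)
        assert d == 0.0 and p == 1.0

    def test_shifted_sample_highly_significant(self, rng):
        out = rng.normal(0, 1, 200)
        d, p = ks_shift_test(out + 1.0, out)
        assert p < 1e-6

    def test_wrong_direction_not_significant(self, rng):
        out = rng.normal(0, 1, 200)
        _, p = ks_shift_test(out - 1.0, out)
        assert p > 0.5

    def test_null_pvalues_roughly_uniform(self, rng):
        # asymptotic one-sided p; sample sizes large enough for the
        # limiting distribution to apply
        ps = [
            ks_shift_test(rng.normal(size=300), rng.normal(size=300))[1]
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_shift_test([1.0], [1.0, 2.0])


class TestSetComparisons:
    def test_external_equal_to_targets_is_extreme(self):
        universe = {f"g{i}" for i in range(50)}
        targets = {f"g{i}" for i in range(10)}
        res = external_set_enrichment(targets, targets, universe)
        # perfect concordance: p is the minimal tail for these margins
        assert res.p_upper == pytest.approx(oracle_p(universe, targets))

    def test_random_external_set_near_null(self, rng):
        universe = {f"g{i}" for i in range(300)}
        targets = {f"g{i}" for i in range(60)}
        log_ors = []
        for _ in range(30):
            ext = set(rng.choice(sorted(universe), size=60, replace=False))
            res = external_set_enrichment(targets, ext, universe)
            log_ors.append(np.log(res.odds_ratio))
        assert abs(np.mean(log_ors)) < 0.25

    def test_subset_validation(self):
        with pytest.raises(ValueError):
            external_set_enrichment({"a"}, {"zzz"}, {"a", "b"})

    def test_set_overlap_counts(self):
        res = set_overlap({"a", "b", "c"}, {"b", "c", "d", "e"})
        assert (res.a_only, res.b_only, res.shared) == (1, 2, 2)
        assert set_overlap(set(), {"x"}).shared == 0


def oracle_p(universe, targets):
    w = len(targets)
    x = 0
    y = 0
    z = len(universe) - len(targets)
    return oracle_hypergeom_upper(w, x, y, z)


class TestIsomirSharedSites:
    def _table(self, rng, shared_rate, unique_rate, n=150):
        counts = {}
        for i in range(3 * n):
            tid = f"t{i:04d}"
            rate = shared_rate if i < n else unique_rate
            counts[tid] = (
                {(SiteClass.CEN_GU_1MM, Region.UTR3): 1}
                if rng.random() < rate else {}
            )
        table = table_from_counts(counts)
        shared = {f"t{i:04d}" for i in range(n)}
        a_only = {f"t{i:04d}" for i in range(n, 2 * n)}
        b_only = {f"t{i:04d}" for i in range(2 * n, 3 * n)}
        return table, shared | a_only, shared | b_only

    def test_shared_targets_enriched_for_centered_sites(self, rng):
        table, a, b = self._table(rng, shared_rate=0.6, unique_rate=0.3)
        res_a, res_b = isomir_shared_site_test(
            a, b, table, "mir", SiteClass.CEN_GU_1MM
        )
        assert res_a.odds_ratio > 1 and res_b.odds_ratio > 1

    def test_equal_rates_near_null(self, rng):
        logs = []
        for _ in range(20):
            table, a, b = self._table(rng, 0.4, 0.4)
            res_a, res_b = isomir_shared_site_test(
                a, b, table, "mir", SiteClass.CEN_GU_1MM
            )
            logs += [np.log(res_a.odds_ratio), np.log(res_b.odds_ratio)]
        assert abs(np.mean(logs)) < 0.25

    def test_identical_sets_rejected(self):
        table = table_from_counts({"t0": {}, "t1": {}})
        with pytest.raises(ValueError):
            isomir_shared_site_test({"t0", "t1"}, {"t0", "t1"}, table,
                                    "mir", SiteClass.CEN_GU_1MM)
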