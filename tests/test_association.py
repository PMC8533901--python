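"""Rank correlation, partial correlation, BH-FDR, and the association matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vigicorr.association import (
    DIMENSIONS,
    association_matrix,
    bh_adjust,
    median_split_groups,
    partial_spearman,
    spearman,
    spearman_pvalue,
)


class TestSpearman:
    def test_perfect_agreement(self, rng):
        x = rng.normal(size=50)
        assert spearman(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_inversion(self, rng):
        x = rng.normal(size=50)
        assert spearman(x, -np.exp(x)) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0]
        y = [3.0, 3.0, 1.0, 4.0, 4.0, 2.0, 5.0, 5.0]
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)
        # independent library route agrees too
        assert spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=20), r.normal(size=20)
        base = spearman(x, y)
        assert spearman(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3) == pytest.approx(base, abs=1e-12)


class TestSpearmanPValue:
    def test_null_rho_gives_one(self):
        assert spearman_pvalue(0.0, 468) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "rho, n, expected, prec",
        [(-0.173, 468, 2e-4, 1e-4), (-0.150, 468, 0.001, 5e-4)],
    )
    def test_reference_cohort_pvalues(self, rho, n, expected, prec):
        """p recomputed from reported rho at n=468 matches the printed value."""
        assert spearman_pvalue(rho, n) == pytest.approx(expected, abs=prec)

    def test_perfect_correlation_limit(self):
        assert spearman_pvalue(1.0, 20) == 0.0

    def test_type_one_error_calibration(self):
        """Empirical size of the t approximation at n=468 stays near 5%."""
        r = np.random.default_rng(2024)
        n, reps = 468, 20_000
        x = r.standard_normal((reps, n))
        y = r.standard_normal((reps, n))
        rx = stats.rankdata(x, axis=1)
        ry = stats.rankdata(y, axis=1)
        rx = (rx - rx.mean(axis=1, keepdims=True))
        ry = (ry - ry.mean(axis=1, keepdims=True))
        rho = (rx * ry).sum(axis=1) / (
            np.linalg.norm(rx, axis=1) * np.linalg.norm(ry, axis=1)
        )
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        rate = (p < 0.05).mean()
        assert 0.045 <= rate <= 0.055


class TestPartialSpearman:
    def test_empty_covariates_reduce_to_plain(self, rng):
        x, y = rng.normal(size=60), rng.normal(size=60)
        rho, p = partial_spearman(x, y, np.empty((60, 0)))
        assert rho == pytest.approx(spearman(x, y))
        assert p == pytest.approx(spearman_pvalue(rho, 60))

    def test_covariate_equal_to_y_absorbs_everything(self, rng):
        x = rng.normal(size=80)
        y = x + 0.1 * rng.normal(size=80)
        rho, _ = partial_spearman(x, y, y)
        assert abs(rho) < 0.15

    def test_matches_residualization_oracle(self, rng):
        n = 100
        z = rng.normal(size=(n, 2))
        x = z @ [1.0, -0.5] + rng.normal(size=n)
        y = z @ [0.7, 0.3] + rng.normal(size=n)
        rho, _ = partial_spearman(x, y, z)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        zr = np.column_stack([stats.rankdata(z[:, 0]), stats.rankdata(z[:, 1])])
        design = np.column_stack([np.ones(n), zr])
        H = design @ np.linalg.pinv(design)
        ex, ey = rx - H @ rx, ry - H @ ry
        oracle = ex @ ey / np.sqrt((ex @ ex) * (ey @ ey))
        assert rho == pytest.approx(oracle, abs=1e-10)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        z = rng.normal(size=50)
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_spearman(x, y, np.column_stack([z, 2 * z]))


class TestBHAdjust:
    def test_closed_form_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_matches_step_up_oracle_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(size=rng.integers(2, 40))
            out = bh_adjust(p)
            # brute-force step-up
            m = p.size
            order = np.argsort(p)
            brute = np.empty(m)
            for i, idx in enumerate(order):
                candidates = [p[order[j]] * m / (j + 1) for j in range(i, m)]
                brute[idx] = min(1.0, min(candidates))
            assert np.allclose(out, brute, atol=1e-12)
            assert np.allclose(out, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_order_preserved(self):
        p = [0.04, 0.001, 0.9]
        out = bh_adjust(p)
        assert out[1] < out[0] < out[2]

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=15),
        st.data(),
    )
    def test_monotone_in_inputs(self, p, data):
        """Raising any single input p never lowers any adjusted p."""
        i = data.draw(st.integers(0, len(p) - 1))
        raised = list(p)
        raised[i] = min(1.0, raised[i] + data.draw(st.floats(0, 1)))
        assert (bh_adjust(raised) >= bh_adjust(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split_groups([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_all_equal_goes_low_with_warning(self):
        with pytest.warns(UserWarning):
            labels = median_split_groups([5, 5, 5, 5])
        assert set(labels) == {"low"}

    def test_odd_n_sizes_differ_by_one(self, rng):
        labels = median_split_groups(rng.normal(size=11))
        low, high = (labels == "low").sum(), (labels == "high").sum()
        assert abs(low - high) == 1


class TestAssociationMatrix:
    def _tables(self, rng, n=80, effect=0.0):
        g = rng.standard_normal(n)
        pheno = pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)]})
        for d in DIMENSIONS:
            pheno[d] = 50 + 10 * rng.standard_normal(n)
        pheno["openness"] = 50 + 10 * (effect * g + np.sqrt(1 - effect**2) * rng.standard_normal(n))
        summ = pd.DataFrame(
            {
                "subject_id": pheno["subject_id"],
                "mean_vigilance": 5 + g + 0.3 * rng.standard_normal(n),
                "stability_score": np.clip(np.round(8 + 3 * g), 1, 14),
                "slope_index": -1.5 + 0.9 * g + 0.2 * rng.standard_normal(n),
                "qc_pass": True,
            }
        )
        return pheno, summ

    def test_shape_and_fdr_family(self, rng):
        pheno, summ = self._tables(rng)
        out = association_matrix(pheno, summ, compute_bf=False)
        assert len(out) == 15
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()

    def test_injected_effect_is_strongest(self, rng):
        pheno, summ = self._tables(rng, n=400, effect=0.5)
        out = association_matrix(pheno, summ, compute_bf=False)
        top = out.loc[out["p"].idxmin()]
        assert top["trait"] == "openness"

    def test_duplicate_ids_rejected(self, rng):
        pheno, summ = self._tables(rng, n=10)
        pheno.loc[1, "subject_id"] = pheno.loc[0, "subject_id"]
        with pytest.raises(ValueError, match="duplicate"):
            association_matrix(pheno, summ, compute_bf=False)

    def test_unmatched_ids_listed(self, rng):
        pheno, summ = self._tables(rng, n=10)
        summ.loc[3, "subject_id"] = "STRANGER"
        with pytest.raises(ValueError, match="STRANGER"):
            association_matrix(pheno, summ, compute_bf=False)
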