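"""PCA and RDA against explicit linear-algebra oracles and vegan."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import phylostruct as ps
from phylostruct.ordination import cumulative_percentages, hellinger


def _frame(rng, n, m, prefix="v"):
    return pd.DataFrame(
        rng.normal(size=(n, m)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"{prefix}{j}" for j in range(m)],
    )


class TestPCA:
    def test_rank_one_matrix_loads_on_first_axis(self):
        base = np.outer(np.arange(1.0, 7.0), [1.0, 2.0, 3.0])
        data = pd.DataFrame(base, columns=list("abc"))
        res = ps.pca(data)
        assert res.proportions[0] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        res = ps.pca(_frame(rng, 8, 4))
        assert res.proportions.sum() == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        data = _frame(rng, 6, 4)
        res = ps.pca(data)
        x = data.values - data.values.mean(axis=0)
        oracle = np.sort(np.linalg.eigvalsh(np.cov(x, rowvar=False)))[::-1]
        assert np.allclose(res.eigenvalues, oracle[: len(res.eigenvalues)], atol=1e-8)

    def test_matches_sklearn(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(2)
        data = _frame(rng, 10, 5)
        res = ps.pca(data)
        ref = sklearn_pca().fit(data.values)
        assert np.allclose(res.eigenvalues, ref.explained_variance_[: len(res.eigenvalues)], atol=1e-8)

    def test_constant_matrix_errors(self):
        data = pd.DataFrame(np.ones((4, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="zero total variance"):
            ps.pca(data)

    def test_hellinger_rows_unit_norm(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 20, size=(5, 8)).astype(float))
        h = hellinger(counts)
        assert np.allclose((h**2).sum(axis=1), 1.0)


class TestRDA:
    def test_orthogonal_predictors_explain_nothing(self):
        n = 12
        t = np.arange(n, dtype=float)
        responses = pd.DataFrame(
            {"r1": np.cos(2 * np.pi * t / n), "r2": np.cos(4 * np.pi * t / n)}
        )
        predictors = pd.DataFrame(
            {"p1": np.sin(2 * np.pi * t / n), "p2": np.sin(4 * np.pi * t / n)}
        )
        res = ps.rda(responses, predictors)
        assert res.proportions.sum() < 0.05

    def test_exact_linear_map_explains_everything(self):
        rng = np.random.default_rng(4)
        predictors = _frame(rng, 10, 3, "p")
        coef = rng.normal(size=(3, 4))
        responses = pd.DataFrame(
            predictors.values @ coef,
            index=predictors.index,
            columns=[f"r{j}" for j in range(4)],
        )
        res = ps.rda(responses, predictors)
        assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_hat_matrix_oracle(self):
        rng = np.random.default_rng(5)
        responses = _frame(rng, 10, 4, "r")
        predictors = _frame(rng, 10, 3, "p")
        res = ps.rda(responses, predictors)

        def std(a):
            c = a - a.mean(axis=0)
            return c / c.std(axis=0, ddof=1)

        y, x = std(responses.values), std(predictors.values)
        hat = x @ np.linalg.pinv(x.T @ x) @ x.T
        fitted = hat @ y
        oracle = np.sort(np.linalg.eigvalsh(fitted.T @ fitted / 9))[::-1]
        assert np.allclose(res.eigenvalues, oracle[: len(res.eigenvalues)], atol=1e-8)

    def test_constrained_total_bounded_by_response_variance(self):
        rng = np.random.default_rng(6)
        responses = _frame(rng, 12, 5, "r")
        predictors = _frame(rng, 12, 3, "p")
        res = ps.rda(responses, predictors)
        pca_total = ps.pca(responses, scale=True).total_variance
        assert res.eigenvalues.sum() <= pca_total + 1e-9

    def test_full_rank_predictors_recover_plain_pca(self):
        rng = np.random.default_rng(7)
        n = 6
        responses = _frame(rng, n, 3, "r")
        # n-1 independent predictors span the centered sample space
        predictors = _frame(rng, n, n - 1, "p")
        res = ps.rda(responses, predictors, scale=False)
        ref = ps.pca(responses)
        assert np.allclose(
            res.eigenvalues[: len(ref.eigenvalues)], ref.eigenvalues, atol=1e-8
        )

    def test_more_predictors_than_samples_errors(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="reduce the predictor"):
            ps.rda(_frame(rng, 5, 2, "r"), _frame(rng, 5, 6, "p"))

    def test_factor_correlations_within_unit_interval(self, default_dataset):
        res = ps.rda(default_dataset["traits"], default_dataset["env"])
        assert (res.factor_correlations.abs() <= 1.0 + 1e-12).all().all()

    def test_agrees_with_vegan_reference(self, small_dataset, tmp_path):
        """Cross-check constrained eigenvalue proportions against R vegan."""
        small_dataset["traits"].to_csv(tmp_path / "traits.tsv", sep="\t")
        small_dataset["env"].to_csv(tmp_path / "env.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            traits <- read.table("traits.tsv", header=TRUE, row.names=1, sep="\\t")
            env <- read.table("env.tsv", header=TRUE, row.names=1, sep="\\t")
            m <- rda(traits ~ ., data=env, scale=TRUE)
            write.table(data.frame(prop=m$CCA$eig / m$tot.chi), "r_rda.tsv",
                        sep="\\t", quote=FALSE)
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "r_rda.tsv", sep="\t", index_col=0)["prop"].values
        res = ps.rda(small_dataset["traits"], small_dataset["env"])
        assert np.allclose(res.proportions[: len(ref)], ref, atol=1e-8)


class TestAxisSummary:
    def test_printed_percentages_accumulate(self):
        cum = cumulative_percentages([0.440, 0.291, 0.128, 0.064])
        # slack of one print ulp: the per-axis inputs are rounded to 3 d.p.
        assert np.allclose(np.round(cum, 1), [44.0, 73.1, 85.9, 92.2], atol=0.11)

    def test_single_axis_cumulative_is_itself(self):
        assert cumulative_percentages([0.5])[0] == pytest.approx(50.0)

    def test_cumulative_non_decreasing_and_bounded(self):
        rng = np.random.default_rng(9)
        res = ps.pca(_frame(rng, 9, 5))
        cum = res.cumulative
        assert (np.diff(cum) >= -1e-12).all()
        assert cum[-1] <= 100.0 + 1e-9

    def test_summary_layout_with_stars(self, default_dataset):
        res = ps.rda(default_dataset["traits"], default_dataset["env"])
        table = res.summary()
        assert "Eigenvalues" in table.index
        assert "Cumulative percentage variance" in table.index
        # strongly coupled soil factors earn significance stars on axis 1
        ax1 = table.loc[list(default_dataset["env"].columns), table.columns[0]]
        assert any(str(v).endswith("**") for v in ax1)
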