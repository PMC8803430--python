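import numpy as np
import pandas as pd
import pytest

from tacesig.io import ExpressionMatrix
from tacesig.microenv import compare_fractions, deconvolve, stemness_index
from tacesig.simulate import generate_cohort, generate_mixtures


@pytest.fixture()
def cell_signature(rng):
    return pd.DataFrame(
        rng.uniform(0.5, 10.0, size=(40, 4)),
        index=[f"g{i}" for i in range(40)],
        columns=["A", "B", "C", "D"],
    )


class TestDeconvolve:
    def test_pure_column_recovered(self, cell_signature):
        props = pd.DataFrame(
            [[0, 0, 1.0, 0]], index=["s"], columns=cell_signature.columns
        )
        bulk = generate_mixtures(cell_signature, props)
        fr = deconvolve(bulk, cell_signature)
        np.testing.assert_allclose(fr.loc["s"], [0, 0, 1.0, 0], atol=1e-9)

    def test_noiseless_mixture_exact(self, cell_signature):
        props = pd.DataFrame(
            [[0.2, 0.3, 0.5, 0.0]], index=["s"], columns=cell_signature.columns
        )
        bulk = generate_mixtures(cell_signature, props)
        fr = deconvolve(bulk, cell_signature)
        np.testing.assert_allclose(fr.loc["s"], props.loc["s"], atol=1e-6)

    def test_fractions_on_simplex(self, cell_signature, rng):
        raw = rng.uniform(size=(12, 4))
        props = pd.DataFrame(
            raw / raw.sum(axis=1, keepdims=True),
            index=[f"s{i}" for i in range(12)],
            columns=cell_signature.columns,
        )
        bulk = generate_mixtures(cell_signature, props, noise_sd=0.5, seed=2)
        fr = deconvolve(bulk, cell_signature)
        np.testing.assert_allclose(fr.sum(axis=1), 1.0, atol=1e-9)
        assert (fr.to_numpy() >= 0).all()

    def test_column_permutation_equivariance(self, cell_signature):
        props = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4]], index=["s"], columns=cell_signature.columns
        )
        bulk = generate_mixtures(cell_signature, props)
        perm = ["C", "A", "D", "B"]
        fr1 = deconvolve(bulk, cell_signature)
        fr2 = deconvolve(bulk, cell_signature[perm])
        np.testing.assert_allclose(fr1[perm].to_numpy(), fr2.to_numpy(), atol=1e-9)

    def test_zscored_bulk_rejected(self, cell_signature):
        df = pd.DataFrame(
            np.zeros((40, 2)), index=cell_signature.index, columns=["a", "b"]
        )
        m = ExpressionMatrix(df, scale_tag="zscore")
        with pytest.raises(ValueError, match="z-score"):
            deconvolve(m, cell_signature)

    def test_log_scale_bulk_is_delogged(self, cell_signature):
        props = pd.DataFrame(
            [[0.25, 0.25, 0.25, 0.25]], index=["s"], columns=cell_signature.columns
        )
        linear = generate_mixtures(cell_signature, props)
        logged = ExpressionMatrix(np.log2(linear.values), scale_tag="raw_log")
        fr = deconvolve(logged, cell_signature)
        np.testing.assert_allclose(fr.loc["s"], props.loc["s"], atol=1e-6)

    def test_too_few_shared_genes_errors(self, cell_signature):
        df = pd.DataFrame([[1.0], [2.0]], index=["g0", "g1"], columns=["s"])
        m = ExpressionMatrix(df, scale_tag="linear")
        with pytest.raises(ValueError, match="signature genes"):
            deconvolve(m, cell_signature)


class TestCompareFractions:
    def test_planted_shift_flagged(self, rng):
        n = 40
        fracs = rng.dirichlet(np.ones(4), size=n)
        labels = pd.Series(
            [0] * 20 + [1] * 20, index=[f"s{i}" for i in range(n)]
        )
        fracs[20:, 0] += 0.3  # shift cell type 0 in nonresponders
        fracs /= fracs.sum(axis=1, keepdims=True)
        df = pd.DataFrame(
            fracs, index=labels.index, columns=["A", "B", "C", "D"]
        )
        out = compare_fractions(df, labels).set_index("cell_type")
        assert out.loc["A", "q"] < 0.05
        assert out.loc["A", "mean_nonresp"] > out.loc["A", "mean_resp"]

    def test_identical_groups_no_signal(self):
        block = np.tile([[0.2, 0.3, 0.5]], (4, 1))
        df = pd.DataFrame(
            np.vstack([block, block]),
            index=[f"s{i}" for i in range(8)],
            columns=["A", "B", "C"],
        )
        labels = pd.Series([0] * 4 + [1] * 4, index=df.index)
        out = compare_fractions(df, labels)
        assert (out["p"] > 0.99).all()

    def test_label_swap_flips_signs(self, rng):
        df = pd.DataFrame(
            rng.dirichlet(np.ones(3), size=12),
            index=[f"s{i}" for i in range(12)],
            columns=["A", "B", "C"],
        )
        labels = pd.Series([0] * 6 + [1] * 6, index=df.index)
        a = compare_fractions(df, labels)
        b = compare_fractions(df, 1 - labels)
        np.testing.assert_allclose(
            a["mean_nonresp"] - a["mean_resp"],
            -(b["mean_nonresp"] - b["mean_resp"]),
        )


class TestStemnessIndex:
    @pytest.fixture()
    def weights(self, rng):
        return pd.Series(
            rng.uniform(0.1, 2.0, size=30),
            index=[f"g{i}" for i in range(30)],
        )

    def _matrix(self, cols: dict[str, np.ndarray], weights) -> ExpressionMatrix:
        return ExpressionMatrix(
            pd.DataFrame(cols, index=weights.index), scale_tag="raw_log"
        )

    def test_concordant_sample_scores_one(self, weights, rng):
        concordant = weights.to_numpy()  # same ranks as weights -> rho = 1
        anti = -weights.to_numpy()
        noise = rng.normal(size=len(weights))
        m = self._matrix({"hi": concordant, "lo": anti, "mid": noise}, weights)
        out = stemness_index(m, weights)
        assert out.loc["hi", "rho"] == pytest.approx(1.0)
        assert out.loc["hi", "mRNAsi"] == 1.0
        assert out.loc["lo", "rho"] == pytest.approx(-1.0)
        assert out.loc["lo", "mRNAsi"] == 0.0

    def test_rho_invariant_under_monotone_transform(self, weights, rng):
        cols = {f"s{i}": rng.normal(size=len(weights)) for i in range(4)}
        m1 = self._matrix(cols, weights)
        m2 = self._matrix(
            {k: np.exp(v) for k, v in cols.items()}, weights
        )
        a = stemness_index(m1, weights)
        b = stemness_index(m2, weights)
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)

    def test_output_invariant_to_weight_order(self, weights, rng):
        cols = {f"s{i}": rng.normal(size=len(weights)) for i in range(3)}
        m = self._matrix(cols, weights)
        shuffled = weights.sample(frac=1.0, random_state=1)
        a = stemness_index(m, weights)
        b = stemness_index(m, shuffled)
        np.testing.assert_allclose(a["mRNAsi"], b["mRNAsi"], atol=1e-12)

    def test_nonresponders_higher_with_planted_gradient(self):
        m, labels, truth = generate_cohort(
            40, 40, 300, 10, 1.0, seed=55, n_stemness_genes=60, stemness_shift=1.0
        )
        out = stemness_index(m, truth.stemness_weights)
        y = labels.to_numpy()
        assert (
            out["mRNAsi"].to_numpy()[y == 1].mean()
            > out["mRNAsi"].to_numpy()[y == 0].mean()
        )

    def test_constant_cohort_warns_and_zeroes(self, weights):
        col = weights.to_numpy()
        m = self._matrix({"a": col, "b": col * 2.0}, weights)  # both rho = 1
        with pytest.warns(UserWarning, match="constant"):
            out = stemness_index(m, weights)
        assert (out["mRNAsi"] == 0).all()

    def test_too_few_genes_errors(self, weights):
        df = pd.DataFrame(
            np.random.default_rng(1).normal(size=(5, 3)),
            index=weights.index[:5],
            columns=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="at least 10"):
            stemness_index(ExpressionMatrix(df), weights)
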