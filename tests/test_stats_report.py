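"""Statistics tests with enumeration and residual-regression oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from afpom.errors import ValidationError
from afpom.stats_report import (build_group_comparison, mann_whitney_u,
                                partial_correlation, signed_r_squared)


def exact_mw_p(x, y):
    """Oracle: two-sided p by full enumeration of rank arrangements."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_of(range(n1))
    n1n2 = n1 * len(y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = u_of(idx)
        total += 1
        # two-sided: as or more extreme in either direction
        if min(u, n1n2 - u) <= min(u_obs, n1n2 - u_obs) + 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_midrank_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)

    def test_swap_antisymmetry(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=6)
        u_xy, p_xy = mann_whitney_u(x, y)
        u_yx, p_yx = mann_whitney_u(y, x)
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))
        assert p_xy == pytest.approx(p_yx)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 6)
                                       for n2 in range(n1, 6)])
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(exact_mw_p(x, y), abs=1e-12)


def residual_pcr_oracle(X, y, j):
    """Oracle: two-stage OLS residual correlation via statsmodels."""
    import statsmodels.api as sm

    others = sm.add_constant(np.delete(X, j, axis=1))
    rx = sm.OLS(X[:, j], others).fit().resid
    ry = sm.OLS(y, others).fit().resid
    return float(np.corrcoef(rx, ry)[0, 1])


class TestPartialCorrelation:
    def test_single_predictor_equals_pearson(self, rng):
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        pcr = partial_correlation(x[:, None], y)
        assert pcr.iloc[0] == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_deterministic_relation_gives_unity(self, rng):
        x1 = rng.normal(size=60)
        x2 = rng.normal(size=60)
        pcr = partial_correlation(np.column_stack([x1, x2]), x1.copy())
        assert pcr.iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_residual_regression_oracle(self, rng):
        X = rng.normal(size=(200, 11))
        y = X @ rng.normal(size=11) + rng.normal(size=200)
        pcr = partial_correlation(X, y)
        for j in range(11):
            assert pcr.iloc[j] == pytest.approx(residual_pcr_oracle(X, y, j),
                                                abs=1e-10)

    def test_agrees_with_pingouin_on_generic_data(self, rng):
        import pingouin as pg

        X = rng.normal(size=(60, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=60)
        data = pd.DataFrame(X, columns=list("abcd"))
        data["y"] = y
        pcr = partial_correlation(X, y, names=list("abcd"))
        for name in "abcd":
            covar = [c for c in "abcd" if c != name]
            ref = float(pg.partial_corr(data=data, x=name, y="y",
                                        covar=covar)["r"].iloc[0])
            assert pcr[name] == pytest.approx(ref, abs=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        X = rng.normal(size=(80, 5))
        y = rng.normal(size=80)
        a = partial_correlation(X, y)
        X2 = X.copy()
        X2[:, 2] = 7.5 * X2[:, 2] - 3.0
        b = partial_correlation(X2, y)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_constant_predictor_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 4.2
        with pytest.raises(ValidationError):
            partial_correlation(X, rng.normal(size=30))

    def test_rank_deficiency_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(ValidationError):
            partial_correlation(X, rng.normal(size=30))

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValidationError):
            partial_correlation(rng.normal(size=(10, 11)),
                                rng.normal(size=10))


class TestSignedR2:
    def test_sign_follows_correlation(self, rng):
        x = rng.normal(size=100)
        assert signed_r_squared(x, -x) == pytest.approx(-1.0)
        assert signed_r_squared(x, 2 * x) == pytest.approx(1.0)


class TestGroupComparison:
    def make_population(self, rng, n=200):
        df = pd.DataFrame(rng.uniform(0, 3, size=(n, 3)),
                          columns=["s_gNa", "s_gK1", "s_gup"])
        df["sustained"] = df.s_gNa > 1.5
        return df

    def test_constructed_ground_truth_detected(self, rng):
        df = self.make_population(rng)
        out = build_group_comparison(df, "sustained",
                                     ["s_gNa", "s_gK1", "s_gup"])
        assert bool(out.loc["s_gNa", "significant"])
        assert not bool(out.loc["s_gK1", "significant"])
        assert not bool(out.loc["s_gup", "significant"])

    def test_single_group_rejected(self, rng):
        df = self.make_population(rng)
        df["sustained"] = True
        with pytest.raises(ValidationError):
            build_group_comparison(df, "sustained", ["s_gNa"])

    def test_row_order_invariance(self, rng):
        df = self.make_population(rng)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = build_group_comparison(df, "sustained", ["s_gNa", "s_gK1"])
        b = build_group_comparison(shuffled, "sustained", ["s_gNa", "s_gK1"])
        pd.testing.assert_frame_equal(a, b)
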