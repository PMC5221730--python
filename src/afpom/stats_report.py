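"""Statistical layer: group comparisons and partial correlations.

Two questions are asked of the population: which conductances differ
between outcome groups (sustained vs unsustained reentry; terminated vs
persisting under block), answered with two-sided Mann–Whitney U tests at
a fixed α = .01; and how each conductance relates to the reentry
biomarkers (DF, RM) when the other ten are linearly controlled for,
answered with partial correlation coefficients (PCr).

No multiple-testing correction is applied by default (the fixed
P < .01 criterion is used across all eleven comparisons); a
Benjamini–Hochberg option is available.

Note on ``signed_r_squared``: the direct DF–RM association is reported
as a signed correlation-style value (the sign of r attached to the
coefficient), matching the common loose use of "R²" for a signed
association strength; it is not the literal square.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["mann_whitney_u", "partial_correlation", "build_group_comparison",
           "partial_correlation_table", "signed_r_squared", "ALPHA"]

ALPHA = 0.01
#: exact Mann–Whitney p-values up to this product of sample sizes
EXACT_LIMIT = 400


def mann_whitney_u(x, y) -> tuple:
    """Two-sided Mann–Whitney U test; returns (U of x, p).

    U is computed from rank sums with midranks for ties.  The p-value is
    exact for n1·n2 ≤ 400 without ties, otherwise the normal
    approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= EXACT_LIMIT and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def partial_correlation(X, y, names=None) -> pd.Series:
    """PCr of every column of ``X`` with ``y``, controlling for the rest.

    Each coefficient is the Pearson correlation between the residuals of
    predictor j and of y after linear regression on the remaining
    predictors (with intercept).  The residual-regression form is used
    directly because it stays well-defined in the degenerate
    perfect-correlation case (where correlation-matrix–inversion
    implementations become singular); it agrees with
    :func:`pingouin.partial_corr` away from that edge.  Requires more
    rows than columns + 2 and full column rank.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError("X and y have different numbers of rows")
    if n < p + 2:
        raise ValidationError(f"need at least {p + 2} rows for {p} predictors")
    stds = X.std(axis=0)
    if np.any(stds == 0):
        bad = list(np.flatnonzero(stds == 0))
        raise ValidationError(f"constant predictor column(s) {bad}")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        raise ValidationError("rank-deficient predictor matrix")
    names = [str(nm) for nm in names] if names is not None \
        else [f"x{j}" for j in range(p)]
    out = {}
    for j, name in enumerate(names):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        rx = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        ry = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        denom = float(np.linalg.norm(rx) * np.linalg.norm(ry))
        out[name] = float(rx @ ry / denom) if denom > 0 else float("nan")
    return pd.Series(out, name="PCr")


def signed_r_squared(x, y) -> float:
    """Signed correlation-style association value (see module docstring)."""
    r = float(np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1])
    return math.copysign(r * r, r)


def build_group_comparison(
    table: pd.DataFrame,
    outcome: str,
    factors,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-factor Mann–Whitney comparison between the two outcome groups.

    ``outcome`` names a boolean column of ``table``; ``factors`` the
    numeric columns to compare.  Returns one row per factor with group
    medians/IQRs, U, two-sided p, and the significance flag at
    ``alpha``.  Raises when either group is empty.  With ``fdr``,
    significance is instead assessed on Benjamini–Hochberg adjusted
    p-values.
    """
    if outcome not in table.columns:
        raise ValidationError(f"outcome column {outcome!r} missing")
    mask = table[outcome].astype(bool)
    g1, g0 = table[mask], table[~mask]
    if len(g1) == 0 or len(g0) == 0:
        raise ValidationError(
            f"both outcome groups must be non-empty "
            f"({outcome}: {len(g1)} true / {len(g0)} false)")
    rows = []
    for f in factors:
        x, y = g1[f].to_numpy(float), g0[f].to_numpy(float)
        u, p = mann_whitney_u(x, y)
        rows.append({
            "factor": f,
            "median_true": float(np.median(x)),
            "iqr_true": float(np.subtract(*np.percentile(x, [75, 25]))),
            "median_false": float(np.median(y)),
            "iqr_false": float(np.subtract(*np.percentile(y, [75, 25]))),
            "U": u, "p": p,
        })
    out = pd.DataFrame(rows).set_index("factor")
    if fdr:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def partial_correlation_table(
    table: pd.DataFrame,
    factors,
    outcomes,
) -> pd.DataFrame:
    """PCr of each factor with each outcome column (factors as controls).

    Rows with NaN in any involved column are dropped per outcome.
    """
    cols = {}
    for oc in outcomes:
        sub = table[list(factors) + [oc]].dropna()
        cols[oc] = partial_correlation(sub[list(factors)].to_numpy(),
                                       sub[oc].to_numpy(), names=factors)
    return pd.DataFrame(cols)


def render_pcr_heatmap(pcr: pd.DataFrame, path) -> None:
    """Save a simple PCr heat map (factors × biomarkers) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 0.5 + 0.35 * len(pcr)))
    im = ax.imshow(pcr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r",
                   aspect="auto")
    ax.set_xticks(range(pcr.shape[1]), pcr.columns)
    ax.set_yticks(range(pcr.shape[0]), pcr.index)
    fig.colorbar(im, ax=ax, label="PCr")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
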