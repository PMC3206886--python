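"""Group-level inference for the 2x2 sex-by-disease design.

Each network metric is analyzed with a two-way ANOVA modelling sex, disease
state, and their interaction; families of tests are corrected with the
Benjamini-Hochberg false-discovery-rate procedure; significant interactions
are followed up with Tukey pairwise contrasts on the four cells; and
clinical covariates are related to network organization through
age-controlled partial correlations.

The design is mildly unbalanced (18 males vs 20 females per group), so the
default sums-of-squares type is II — invariant to factor order and the
standard choice when no higher-order terms beyond the interaction are
entertained.  Type III is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PartialCorrResult",
    "two_way_anova",
    "anova_table_many",
    "fdr_adjust",
    "posthoc_pairwise",
    "partial_correlation",
]


@dataclass
class AnovaResult:
    """Two-way ANOVA summary for one metric."""

    metric_name: str
    f_sex: float
    p_sex: float
    f_disease: float
    p_disease: float
    f_interaction: float
    p_interaction: float
    cell_means: pd.DataFrame     # index (sex, group): mean, sd, n

    def to_row(self) -> dict:
        return {
            "metric": self.metric_name,
            "F_sex": self.f_sex, "p_sex": self.p_sex,
            "F_disease": self.f_disease, "p_disease": self.p_disease,
            "F_interaction": self.f_interaction,
            "p_interaction": self.p_interaction,
        }


@dataclass
class PartialCorrResult:
    """Partial correlation of x and y given linear covariates."""

    r_partial: float
    p: float
    n: int
    n_covariates: int

    @property
    def dof(self) -> int:
        return self.n - 2 - self.n_covariates


def _design_matrices(sex: np.ndarray, disease: np.ndarray):
    """Effect-coded design columns for the 2x2 layout."""
    sex = np.asarray(sex)
    disease = np.asarray(disease)
    s_levels = sorted(set(sex.tolist()))
    d_levels = sorted(set(disease.tolist()))
    if len(s_levels) != 2 or len(d_levels) != 2:
        raise ValueError("both factors must have exactly two levels")
    s = np.where(sex == s_levels[0], 1.0, -1.0)
    d = np.where(disease == d_levels[0], 1.0, -1.0)
    return s, d


def _check_cells(sex, disease) -> None:
    df = pd.DataFrame({"sex": sex, "disease": disease})
    counts = df.value_counts()
    if len(counts) < 4:
        raise ValueError("all four sex x disease cells must be populated")
    if (counts < 2).any():
        raise ValueError("need >= 2 subjects per cell")


def anova_table_many(values: np.ndarray, sex, disease,
                     ss_type: int = 2) -> pd.DataFrame:
    """Vectorized two-way ANOVA over many response columns at once.

    ``values`` is (n_subjects, n_responses); returns one row per response
    with F and p for the sex main effect, disease main effect, and their
    interaction.  With effect coding, Type II tests each main effect
    adjusted for the other (interaction excluded) and the interaction
    against the full model; Type III adjusts every term for all others.
    Zero-variance responses get F = 0, p = 1 by convention.
    """
    y = np.atleast_2d(np.asarray(values, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    _check_cells(sex, disease)
    s, d = _design_matrices(sex, disease)
    n = y.shape[0]
    if s.shape[0] != n:
        raise ValueError("factor length does not match number of subjects")
    one = np.ones(n)

    def sse(cols: list[np.ndarray]) -> np.ndarray:
        x = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return (resid ** 2).sum(axis=0)

    sse_full = sse([one, s, d, s * d])
    dof_resid = n - 4
    if dof_resid <= 0:
        raise ValueError("not enough subjects for the full 2x2 model")
    mse = sse_full / dof_resid
    # responses fitted (numerically) perfectly by the design, or constant,
    # get the F = 0, p = 1 convention rather than a 0/0 ratio
    tss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    degenerate = mse <= np.maximum(tss, 1.0) * 1e-12

    if ss_type == 2:
        ss_sex = sse([one, d]) - sse([one, s, d])
        ss_dis = sse([one, s]) - sse([one, s, d])
    elif ss_type == 3:
        ss_sex = sse([one, d, s * d]) - sse_full
        ss_dis = sse([one, s, s * d]) - sse_full
    else:
        raise ValueError("ss_type must be 2 or 3")
    ss_int = sse([one, s, d]) - sse_full

    out = {}
    ok = ~degenerate
    for name, ss in (("sex", ss_sex), ("disease", ss_dis),
                     ("interaction", ss_int)):
        ss = np.maximum(ss, 0.0)
        f = np.where(ok, ss / np.where(ok, mse, 1.0), 0.0)
        p = np.where(ok, sps.f.sf(f, 1, dof_resid), 1.0)
        # zero residual variance but a genuine effect: the term fits
        # perfectly (F unbounded)
        perfect = degenerate & (ss > np.maximum(tss, 1.0) * 1e-10)
        f = np.where(perfect, np.inf, f)
        p = np.where(perfect, 0.0, p)
        out[f"F_{name}"] = f
        out[f"p_{name}"] = p
    return pd.DataFrame(out)


def two_way_anova(values, sex, disease, metric_name: str = "metric",
                  ss_type: int = 2) -> AnovaResult:
    """Two-way ANOVA of one metric on sex, disease, and their interaction.

    Uses a single-df F test per term (each factor has two levels).  Cell
    means, SDs and counts are reported alongside.
    """
    values = np.asarray(values, dtype=float)
    table = anova_table_many(values[:, None], sex, disease, ss_type=ss_type)
    cells = (pd.DataFrame({"value": values, "sex": sex, "group": disease})
             .groupby(["sex", "group"])["value"]
             .agg(["mean", "std", "count"]))
    row = table.iloc[0]
    return AnovaResult(
        metric_name=metric_name,
        f_sex=float(row["F_sex"]), p_sex=float(row["p_sex"]),
        f_disease=float(row["F_disease"]), p_disease=float(row["p_disease"]),
        f_interaction=float(row["F_interaction"]),
        p_interaction=float(row["p_interaction"]),
        cell_means=cells,
    )


def fdr_adjust(p_values, q: float = 0.05, method: str = "bh"):
    """False-discovery-rate adjustment (Benjamini-Hochberg by default).

    Returns ``(adjusted_p, reject_mask)``.  ``method='by'`` applies the
    Benjamini-Yekutieli variant valid under arbitrary dependence.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, p_adj, _, _ = multipletests(p, alpha=q, method=sm_method)
    return p_adj, reject


def posthoc_pairwise(values, sex, disease, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD contrasts between the four sex x disease cells.

    Returns all six pairwise contrasts with family-wise adjusted p-values
    and a flag for the disease contrasts within each sex (the comparisons
    of primary interest after a significant interaction).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    _check_cells(sex, disease)
    cell = np.array([f"{s}:{g}" for s, g in zip(sex, disease)])
    if np.ptp(values) == 0:
        pairs = sorted(set(cell))
        rows = [(a, b, 0.0, 1.0, False)
                for i, a in enumerate(pairs) for b in pairs[i + 1:]]
        out = pd.DataFrame(rows, columns=["cell_a", "cell_b", "meandiff",
                                          "p_adj", "reject"])
    else:
        from itertools import combinations

        res = pairwise_tukeyhsd(values, cell, alpha=alpha)
        pairs = list(combinations(res.groupsunique, 2))
        out = pd.DataFrame({
            "cell_a": [str(a) for a, _ in pairs],
            "cell_b": [str(b) for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject,
        })
    def same_sex_disease_contrast(a: str, b: str) -> bool:
        sa, ga = a.split(":"); sb, gb = b.split(":")
        return sa == sb and ga != gb
    out["within_sex_disease_contrast"] = [
        same_sex_disease_contrast(a, b)
        for a, b in zip(out["cell_a"], out["cell_b"])
    ]
    return out


def partial_correlation(x, y, covariates=None) -> PartialCorrResult:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualized on the covariates (with intercept) and
    the residuals correlated; the p-value uses a t reference with
    ``n - 2 - n_covariates`` degrees of freedom.  With no covariates this
    reduces exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
        if z.shape[0] != n:
            raise ValueError("covariate length does not match x/y")
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2 observations")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(r_partial=r, p=p, n=n, n_covariates=k)
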