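"""Temporal statistics: differential editing, FDR, effect sizes, meta-analysis,
cell-fraction deconvolution and gene-set overlap.

The headline contrast is prenatal versus postnatal: per site, an ordinary
least-squares model of editing level on an epoch indicator plus covariates
(sex, ancestry components, optionally ADAR expression and neuronal fraction),
a two-sided t test on the epoch coefficient, and Benjamini-Hochberg control
of the FDR across sites.  Effect sizes are pooled-SD Cohen's d; multi-dataset
pooling uses a DerSimonian-Laird random-effects model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


# ---------------------------------------------------------------------------
# vectorized OLS t-test (shared with the hyper-editing and edQTL stages)


def build_design(cohort: pd.DataFrame, covariates: list[str],
                 main: str = "epoch") -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, main effect, covariates...] for a cohort table.

    ``epoch`` becomes a postnatal indicator; ``sex`` an M indicator; other
    covariates must be numeric columns.
    """
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    if main == "epoch":
        cols.append((cohort["epoch"] == "postnatal").to_numpy(dtype=float))
        names.append("epoch[postnatal]")
    elif main == "log_age":
        cols.append(np.log(cohort["age_days"].to_numpy(dtype=float)))
        names.append("log_age")
    else:
        raise ValueError(f"unknown main effect {main!r}")
    for c in covariates:
        if c == "sex":
            cols.append((cohort["sex"] == "M").to_numpy(dtype=float))
        else:
            cols.append(pd.to_numeric(cohort[c]).to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def ols_ttest(Y: np.ndarray, X: np.ndarray, coef: int = 1,
              names: list[str] | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each row of Y on X; beta, SE, t and two-sided p for one coefficient.

    Raises on a rank-deficient design, naming the dependent columns.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        bad = names or [f"col{i}" for i in range(p)]
        raise ValueError(f"collinear design matrix (columns: {bad})")
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T                      # p x n
    B = Y @ H.T                            # m x p
    resid = Y - B @ X.T
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(sigma2 * XtX_inv[coef, coef])
    beta = B[:, coef]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * sps.t.sf(np.abs(t), dof)
    return beta, se, t, pval


# ---------------------------------------------------------------------------
# differential editing (model / results objects)


@dataclass
class DifferentialEditingResults:
    """Per-site differential-editing estimates.

    ``table`` columns: delta (postnatal mean - prenatal mean on the level
    scale), beta (epoch coefficient), se, t, p, p_adj, direction in
    {postnatal biased, prenatal biased, unbiased}.
    """

    table: pd.DataFrame
    design_names: list[str]
    fdr: float
    n_samples: int

    @property
    def n_postnatal_biased(self) -> int:
        return int((self.table["direction"] == "postnatal biased").sum())

    @property
    def n_prenatal_biased(self) -> int:
        return int((self.table["direction"] == "prenatal biased").sum())

    def summary(self) -> str:
        t = self.table
        lines = [
            "Differential RNA editing (prenatal vs postnatal)",
            "=" * 48,
            f"sites tested        {len(t)}",
            f"samples             {self.n_samples}",
            f"covariates          {', '.join(self.design_names[2:]) or 'none'}",
            f"FDR threshold       {self.fdr:g}",
            f"postnatal biased    {self.n_postnatal_biased}",
            f"prenatal biased     {self.n_prenatal_biased}",
            f"unbiased            {int((t['direction'] == 'unbiased').sum())}",
            f"median |delta|      {t['delta'].abs().median():.4f}",
        ]
        return "\n".join(lines)


class DifferentialEditingModel:
    """OLS differential-editing model over an imputed editing matrix.

    Parameters
    ----------
    levels : sites x samples DataFrame with no missing cells.
    cohort : sample metadata indexed by sample id (epoch, sex, covariates).
    covariates : cohort columns entering the design (any numeric column plus
        ``sex``); the epoch indicator is always the tested term.
    """

    def __init__(self, levels: pd.DataFrame, cohort: pd.DataFrame,
                 covariates: list[str] | None = None, main: str = "epoch"):
        if levels.isna().to_numpy().any():
            raise ValueError("levels matrix must be imputed (no missing cells)")
        missing = [s for s in levels.columns if s not in cohort.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:3]}")
        self.levels = levels
        self.cohort = cohort.loc[levels.columns]
        self.covariates = covariates or []
        self.main = main

    @classmethod
    def from_matrix(cls, matrix, cohort: pd.DataFrame,
                    covariates: list[str] | None = None) -> "DifferentialEditingModel":
        """Build from a site_calling EditingMatrix."""
        return cls(matrix.levels, cohort, covariates)

    def fit(self, fdr: float = 0.05) -> DifferentialEditingResults:
        X, names = build_design(self.cohort, self.covariates, self.main)
        Y = self.levels.to_numpy(dtype=float)
        beta, se, t, p = ols_ttest(Y, X, coef=1, names=names)
        p_adj = bh_adjust(p)
        post = (self.cohort["epoch"] == "postnatal").to_numpy()
        delta = Y[:, post].mean(axis=1) - Y[:, ~post].mean(axis=1)
        direction = np.where(p_adj > fdr, "unbiased",
                             np.where(delta > 0, "postnatal biased", "prenatal biased"))
        table = pd.DataFrame({
            "delta": delta, "beta": beta, "se": se, "t": t, "p": p,
            "p_adj": p_adj, "direction": direction,
        }, index=self.levels.index)
        return DifferentialEditingResults(table, names, fdr, len(self.cohort))


# ---------------------------------------------------------------------------
# primitives


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def cohens_d(group1: np.ndarray, group2: np.ndarray) -> float:
    """(mean2 - mean1) / pooled SD, pooled over the two sample variances."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least two observations")
    n1, n2 = g1.size, g2.size
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled standard deviation is zero")
    return float((g2.mean() - g1.mean()) / math.sqrt(sp2))


@dataclass
class MetaResult:
    """DerSimonian-Laird random-effects pooling of per-study effect sizes."""

    d: np.ndarray                # per-study effects
    v: np.ndarray                # per-study variances
    tau2: float                  # between-study variance
    pooled: float
    se: float
    ci_low: float
    ci_high: float

    def summary(self) -> str:
        lines = ["Random-effects meta-analysis (DerSimonian-Laird)",
                 "=" * 48,
                 f"studies     {self.d.size}",
                 f"tau^2       {self.tau2:.4f}",
                 f"pooled d    {self.pooled:.4f}",
                 f"95% CI      [{self.ci_low:.4f}, {self.ci_high:.4f}]"]
        return "\n".join(lines)


def random_effects_pool(d: np.ndarray, v: np.ndarray) -> MetaResult:
    """Pool per-study effects with DerSimonian-Laird between-study variance.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/v; the pooled estimate uses weights 1/(v + tau^2).
    """
    d = np.asarray(d, dtype=float)
    v = np.asarray(v, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two studies")
    if (v <= 0).any():
        raise ValueError("per-study variances must be positive")
    w = 1.0 / v
    mu_fe = np.sum(w * d) / np.sum(w)
    Q = float(np.sum(w * (d - mu_fe) ** 2))
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    tau2 = max(0.0, (Q - (d.size - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (v + tau2)
    pooled = float(np.sum(w_re * d) / np.sum(w_re))
    se = float(math.sqrt(1.0 / np.sum(w_re)))
    z = sps.norm.ppf(0.975)
    return MetaResult(d, v, tau2, pooled, se, pooled - z * se, pooled + z * se)


def estimate_cell_fractions(bulk: np.ndarray, signature: pd.DataFrame) -> pd.Series:
    """Non-negative least-squares deconvolution of a bulk expression vector.

    ``signature`` is genes x cell types; the NNLS solution is renormalized to
    sum to one.
    """
    b = np.asarray(bulk, dtype=float)
    S = signature.to_numpy(dtype=float)
    if not b.any():
        raise ValueError("bulk expression vector is all zero")
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("signature columns are linearly dependent")
    coef, _ = optimize.nnls(S, b)
    total = coef.sum()
    if total == 0:
        raise ValueError("NNLS returned the zero solution")
    return pd.Series(coef / total, index=signature.columns)


def gene_set_enrichment(hits: set, gene_set: set, background: set
                        ) -> tuple[float, float]:
    """Fisher-exact overlap of a hit list with a gene set.

    Returns (sample odds ratio, two-sided p).  The odds ratio is inf when the
    off-diagonal is empty (degenerate overlap) and 0 when there is no overlap
    against a populated table.
    """
    if not background:
        raise ValueError("background gene set is empty")
    hits = hits & background
    gene_set = gene_set & background
    a = len(hits & gene_set)
    b = len(hits - gene_set)
    c = len(gene_set - hits)
    d = len(background) - a - b - c
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray,
                 exact_product: int = 400,
                 max_enumeration: int = 200_000) -> tuple[float, float]:
    """Mann-Whitney U (for group A) with a small-sample exact p.

    Without ties and nA*nB <= ``exact_product`` the exact null distribution of
    U is used; with ties, the full set of group assignments is enumerated when
    C(n, nA) <= ``max_enumeration``; otherwise the normal approximation with
    tie correction applies.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if not has_ties and a.size * b.size <= exact_product:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if has_ties and math.comb(a.size + b.size, a.size) <= max_enumeration:
        pooled = np.concatenate([a, b])
        obs = _u_statistic(a, b)
        n = pooled.size
        mu = a.size * b.size / 2.0
        count = 0
        total = 0
        idx = np.arange(n)
        for combo in itertools.combinations(idx, a.size):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= abs(obs - mu) - 1e-12:
                count += 1
        return float(obs), count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([a, b]))
    ra = ranks[:a.size].sum()
    return ra - a.size * (a.size + 1) / 2.0
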