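"""cis-edQTL mapping across temporal sample partitions.

For every editing site, allele dosages of common variants within +/-1 Mb are
regressed on the editing level with covariates (developmental period, sex,
ADAR1/ADAR2, ancestry components).  Site-level significance uses direct
permutation of the covariate-residualized editing levels (1,000 permutations
by default): the empirical p is (1 + #{permutation min p <= observed}) /
(1 + N).  The analysis runs on three partitions — all samples, prenatal only,
postnatal only — and each significant site-variant pair is classified by
temporal predominance:

constant             FDR <= 0.05 (all), same effect sign and nominal
                     p <= 0.05 in both epochs
prenatal-predominant FDR <= 0.05 prenatally, nominal p > 0.05 postnatally
postnatal-predominant  symmetric
prenatal-trending    none of the above, FDR <= 0.05 in >= 1 partition and
                     |beta_pre| > |beta_post|
postnatal-trending   symmetric
none                 otherwise

FDR is Benjamini-Hochberg over all site-variant pairs within a partition
(a lead-variant-only mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import seqio
from .config import FilterConfig
from .stats import bh_adjust

PARTITIONS = ("all", "prenatal", "postnatal")
CATEGORIES = ("constant", "prenatal-predominant", "postnatal-predominant",
              "prenatal-trending", "postnatal-trending", "none")

DEFAULT_COVARIATES = ["period", "sex", "adar1", "adar2",
                      "ancestry1", "ancestry2", "ancestry3", "ancestry4", "ancestry5"]


def _covariate_design(cohort: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    for c in covariates:
        if c == "sex":
            cols.append((cohort["sex"] == "M").to_numpy(dtype=float))
        else:
            cols.append(pd.to_numeric(cohort[c]).to_numpy(dtype=float))
    return np.column_stack(cols)


def _residualize(M: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Rows of M residualized on the columns of X."""
    beta, *_ = np.linalg.lstsq(X, M.T, rcond=None)
    return M - (X @ beta).T


@dataclass
class PartitionResults:
    """Nominal associations and permutation p values for one sample partition."""

    partition: str
    pairs: pd.DataFrame          # index (site_id, variant_id): beta, se, t, p, distance, fdr
    site_perm_p: pd.Series       # empirical permutation p per site
    lead: pd.DataFrame           # one row per site: lead variant + stats
    n_samples: int
    n_skipped_variants: int


@dataclass
class CisEdQTLResults:
    """Combined three-partition edQTL results with temporal categories."""

    partitions: dict[str, PartitionResults]
    categories: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        lines = ["cis-edQTL mapping", "=" * 48]
        for name, part in self.partitions.items():
            n_sig = int((part.pairs["fdr"] <= 0.05).sum())
            lines.append(f"{name:<10} n={part.n_samples:<4} pairs={len(part.pairs):<6} "
                         f"FDR<=5%: {n_sig}")
        if len(self.categories):
            counts = self.categories["category"].value_counts()
            lines.append("categories: " + ", ".join(
                f"{c}={int(counts.get(c, 0))}" for c in CATEGORIES))
        return "\n".join(lines)


class CisEdQTLModel:
    """Permutation-based cis-edQTL model over an imputed editing matrix.

    Parameters
    ----------
    levels : sites x samples editing levels, no missing cells.
    dosages : variants x samples 0/1/2 alt-allele dosages (NaN allowed;
        mean-imputed per variant).
    variant_pos : per-variant (chrom, pos0) table indexed by variant id.
    cohort : sample metadata (epoch, period, sex, covariates).
    """

    def __init__(self, levels: pd.DataFrame, dosages: pd.DataFrame,
                 variant_pos: pd.DataFrame, cohort: pd.DataFrame,
                 covariates: list[str] | None = None,
                 cfg: FilterConfig | None = None):
        self.cfg = cfg or FilterConfig()
        self.levels = levels
        self.dosages = dosages.reindex(columns=levels.columns)
        self.variant_pos = variant_pos
        self.cohort = cohort.loc[levels.columns]
        self.covariates = covariates if covariates is not None else [
            c for c in DEFAULT_COVARIATES if c in cohort.columns]
        self._site_pos = pd.DataFrame(
            [seqio.parse_site_id(s)[:2] for s in levels.index],
            index=levels.index, columns=["chrom", "pos0"])

    # -- core -----------------------------------------------------------------

    def _partition_samples(self, partition: str) -> pd.Index:
        if partition == "all":
            return self.levels.columns
        if partition not in PARTITIONS:
            raise ValueError(f"partition must be one of {PARTITIONS}")
        mask = self.cohort["epoch"] == partition
        return self.levels.columns[mask.to_numpy()]

    def fit_partition(self, partition: str, seed: int = 0,
                      n_permutations: int | None = None) -> PartitionResults:
        """Nominal cis associations plus site-level permutation p values."""
        cfg = self.cfg
        n_perm = n_permutations if n_permutations is not None else cfg.n_permutations
        if n_perm < 100:
            raise ValueError("need at least 100 permutations")
        samples = self._partition_samples(partition)
        n = len(samples)
        cohort = self.cohort.loc[samples]
        X = _covariate_design(cohort, self.covariates)
        q = X.shape[1]
        dof = n - q - 1
        if dof < 3:
            raise ValueError(f"partition {partition!r} too small for the design")

        G = self.dosages[samples].to_numpy(dtype=float)
        # mean-impute missing genotypes per variant
        col_mean = np.nanmean(G, axis=1)
        nan_at = np.isnan(G)
        G[nan_at] = np.take(col_mean, np.nonzero(nan_at)[0])
        af = G.mean(axis=1) / 2.0
        maf = np.minimum(af, 1.0 - af)
        poly = G.std(axis=1) > 0
        usable = (maf >= cfg.qtl_maf_floor) & poly
        n_skipped = int((~usable).sum())

        Y = self.levels[samples].to_numpy(dtype=float)
        Yr = _residualize(Y, X)
        Gr = _residualize(G, X)
        # unit-normalize residuals so correlations come from dot products
        def _norm(M):
            s = np.linalg.norm(M, axis=1, keepdims=True)
            s[s == 0] = 1.0
            return M / s
        Yn = _norm(Yr)
        Gn = _norm(Gr)

        vpos = self.variant_pos["pos0"].to_numpy()
        vchrom = self.variant_pos["chrom"].to_numpy()
        vids = self.variant_pos.index.to_numpy()

        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

        rows = []
        perm_p = {}
        lead_rows = []
        for si, sid in enumerate(self.levels.index):
            chrom, pos0 = self._site_pos.loc[sid]
            dist = np.abs(vpos - pos0)
            cis = (vchrom == chrom) & (dist <= cfg.cis_window) & usable
            idx = np.flatnonzero(cis)
            if idx.size == 0:
                continue
            g = Gn[idx]                       # m x n, unit rows
            r = g @ Yn[si]                    # correlations
            r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
            t = r * np.sqrt(dof / (1.0 - r ** 2))
            p = 2.0 * sps.t.sf(np.abs(t), dof)
            # beta / se on the residualized scale
            gnorm = np.linalg.norm(Gr[idx], axis=1)
            ynorm = np.linalg.norm(Yr[si])
            beta = r * ynorm / gnorm
            se = np.where(np.abs(t) > 0, np.abs(beta / t), np.nan)
            for k, vi in enumerate(idx):
                rows.append((sid, vids[vi], beta[k], se[k], t[k], p[k], int(dist[vi])))
            # lead variant: min p, ties by distance then id
            order = sorted(range(idx.size),
                           key=lambda k: (p[k], dist[idx[k]], vids[idx[k]]))
            k0 = order[0]
            lead_rows.append((sid, vids[idx[k0]], beta[k0], se[k0], t[k0],
                              p[k0], int(dist[idx[k0]])))
            # permutations: compare max |correlation|
            obs = float(np.max(np.abs(r)))
            y_perm = Yn[si][perms]            # n_perm x n
            null_max = np.max(np.abs(y_perm @ g.T), axis=1)
            perm_p[sid] = (1.0 + float(np.sum(null_max >= obs - 1e-15))) / (1.0 + n_perm)

        pairs = pd.DataFrame(
            rows, columns=["site_id", "variant_id", "beta", "se", "t", "p", "distance"]
        ).set_index(["site_id", "variant_id"])
        pairs["fdr"] = bh_adjust(pairs["p"].to_numpy()) if len(pairs) else []
        lead = pd.DataFrame(
            lead_rows, columns=["site_id", "variant_id", "beta", "se", "t", "p", "distance"]
        ).set_index("site_id")
        return PartitionResults(partition, pairs, pd.Series(perm_p, name="perm_p"),
                                lead, n, n_skipped)

    def fit(self, seed: int = 0, n_permutations: int | None = None,
            lead_only_fdr: bool = False) -> CisEdQTLResults:
        """Run all three partitions and classify temporal predominance."""
        parts = {}
        for i, partition in enumerate(PARTITIONS):
            parts[partition] = self.fit_partition(partition, seed=seed + i,
                                                  n_permutations=n_permutations)
        if lead_only_fdr:
            for part in parts.values():
                lead_pairs = set(zip(part.lead.index, part.lead["variant_id"]))
                sub = part.pairs.loc[part.pairs.index.isin(lead_pairs)]
                part.pairs.loc[:, "fdr"] = np.nan
                part.pairs.loc[sub.index, "fdr"] = bh_adjust(sub["p"].to_numpy())
        categories = classify_edqtl_category(parts, self.cfg)
        return CisEdQTLResults(parts, categories)


def classify_edqtl_category(parts: dict[str, PartitionResults],
                            cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Five-category temporal-predominance classification per site-variant pair.

    Rules apply in order; trending categories additionally require FDR <= 0.05
    in at least one partition so that unclassifiable noise is never promoted.
    """
    cfg = cfg or FilterConfig()
    for name in PARTITIONS:
        if name not in parts:
            raise ValueError(f"missing partition statistics: {name}")
    thr = cfg.fdr
    merged = parts["all"].pairs[["beta", "p", "fdr"]].join(
        parts["prenatal"].pairs[["beta", "p", "fdr"]],
        how="outer", lsuffix="_all", rsuffix="_pre").join(
        parts["postnatal"].pairs[["beta", "p", "fdr"]].add_suffix("_post"),
        how="outer")
    cats = []
    for _, row in merged.iterrows():
        fdr_all, fdr_pre, fdr_post = row["fdr_all"], row["fdr_pre"], row["fdr_post"]
        p_pre, p_post = row["p_pre"], row["p_post"]
        b_pre, b_post = row["beta_pre"], row["beta_post"]
        any_sig = np.nanmin([v for v in (fdr_all, fdr_pre, fdr_post)
                             if not pd.isna(v)] or [np.nan])
        if (not pd.isna(fdr_all) and fdr_all <= thr
                and not pd.isna(b_pre) and not pd.isna(b_post)
                and np.sign(b_pre) == np.sign(b_post)
                and p_pre <= 0.05 and p_post <= 0.05):
            cats.append("constant")
        elif not pd.isna(fdr_pre) and fdr_pre <= thr and (pd.isna(p_post) or p_post > 0.05):
            cats.append("prenatal-predominant")
        elif not pd.isna(fdr_post) and fdr_post <= thr and (pd.isna(p_pre) or p_pre > 0.05):
            cats.append("postnatal-predominant")
        elif not pd.isna(any_sig) and any_sig <= thr and abs(b_pre) > abs(b_post):
            cats.append("prenatal-trending")
        elif not pd.isna(any_sig) and any_sig <= thr and abs(b_post) > abs(b_pre):
            cats.append("postnatal-trending")
        else:
            cats.append("none")
    merged["category"] = cats
    return merged
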