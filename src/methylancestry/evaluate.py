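"""Performance evaluation of ancestry PCs.

Covers clustering quality of the first three scaled PCs (silhouette scores,
3D centroid distances), PC–group association tests with an assumption-driven
ANOVA / Kruskal–Wallis switch, absolute correlations against genotype-derived
PCs, partial-R² variance decomposition, covariate–ancestry confounding checks
(linear/ANOVA or mixed-model likelihood-ratio tests for repeated samples),
and the genomic inflation factor λ of a covariate-adjusted EWAS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples

from .containers import CovariateMatrix

log = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------- clustering

def silhouette(points: np.ndarray, labels) -> tuple[np.ndarray, float, dict]:
    """Silhouette scores s(i) = (b - a) / max(a, b) with Euclidean distance.

    Returns per-sample scores, their mean, and per-label mean scores.
    Samples in singleton clusters receive s = 0.
    """
    labels = np.asarray(labels)
    points = np.asarray(points, float)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 labels")
    s = silhouette_samples(points, labels)
    per_label = {lab: float(s[labels == lab].mean()) for lab in np.unique(labels)}
    return s, float(s.mean()), per_label


def centroid_metrics(points: np.ndarray, labels) -> tuple[dict, pd.DataFrame]:
    """Within-cluster mean distance to the centroid and the matrix of
    Euclidean distances between cluster centroids."""
    labels = np.asarray(labels)
    points = np.asarray(points, float)
    uniq = list(dict.fromkeys(labels))  # stable order of first appearance
    centroids = {lab: points[labels == lab].mean(axis=0) for lab in uniq}
    within = {
        lab: float(np.linalg.norm(points[labels == lab] - centroids[lab], axis=1).mean())
        for lab in uniq
    }
    between = pd.DataFrame(0.0, index=uniq, columns=uniq)
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            d = float(np.linalg.norm(centroids[a] - centroids[b]))
            between.loc[a, b] = between.loc[b, a] = d
    return within, between


# ---------------------------------------------------------------- association

def association_test(pc: np.ndarray, groups, alpha_assumption: float = 0.05) -> dict:
    """Test a PC for differences across groups.

    Runs Shapiro–Wilk normality checks per group and a median-centered
    Levene variance-homogeneity check; if every check's p exceeds
    ``alpha_assumption``, a one-way ANOVA is used, otherwise Kruskal–Wallis.
    Groups too small for the assumption checks trigger the Kruskal–Wallis
    fallback (logged).
    """
    pc = np.asarray(pc, float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("association test requires at least 2 groups")
    chunks = [pc[groups == g] for g in uniq]
    use_anova = True
    if any(len(c) < 3 for c in chunks):
        log.info("group too small for assumption checks; using Kruskal-Wallis")
        use_anova = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro_ps = [stats.shapiro(c).pvalue for c in chunks]
            levene_p = stats.levene(*chunks, center="median").pvalue
        use_anova = all(p > alpha_assumption for p in shapiro_ps) and levene_p > alpha_assumption
    if use_anova:
        res = stats.f_oneway(*chunks)
        return {"test_name": "anova", "statistic": float(res.statistic), "p": float(res.pvalue)}
    res = stats.kruskal(*chunks)
    return {"test_name": "kruskal", "statistic": float(res.statistic), "p": float(res.pvalue)}


def pc_correlations(
    ancestry_pcs: np.ndarray, genotype_pcs: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Absolute Pearson correlations between the first three ancestry PCs and
    the first three genotype-derived PCs, plus their mean.

    Constant vectors yield undefined (NaN) entries, excluded from the mean.
    """
    a = np.asarray(ancestry_pcs, float)
    g = np.asarray(genotype_pcs, float)
    if a.shape[0] != g.shape[0]:
        raise ValueError("ancestry and genotype PCs must cover the same samples")
    ka, kg = a.shape[1], g.shape[1]
    mat = np.full((ka, kg), np.nan)
    for i in range(ka):
        for j in range(kg):
            if a[:, i].std() == 0 or g[:, j].std() == 0:
                continue
            mat[i, j] = abs(stats.pearsonr(a[:, i], g[:, j]).statistic)
    df = pd.DataFrame(
        mat,
        index=[f"PC{i + 1}" for i in range(ka)],
        columns=[f"gt_PC{j + 1}" for j in range(kg)],
    )
    return df, float(np.nanmean(mat))


# ---------------------------------------------------------------- partial R2

def _sse(y: np.ndarray, x: np.ndarray | None) -> float:
    n = y.shape[0]
    design = np.ones((n, 1)) if x is None else np.column_stack([np.ones(n), x])
    resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(resid @ resid)


def partial_r2(y: np.ndarray, x_a: np.ndarray, x_b: np.ndarray) -> dict:
    """Unique-variance decomposition of y over two predictor sets.

    ``r2_A_unique`` is the proportional reduction in error sum of squares
    when adding A to a model already containing B (and symmetrically for B);
    ``r2_joint`` is the ordinary R² of the combined model.
    """
    y = np.asarray(y, float)
    x_a = np.atleast_2d(np.asarray(x_a, float).T).T
    x_b = np.atleast_2d(np.asarray(x_b, float).T).T
    n = y.shape[0]
    if n <= x_a.shape[1] + x_b.shape[1] + 1:
        raise ValueError("not enough samples for the combined design")
    xab = np.column_stack([x_a, x_b])
    full = np.column_stack([np.ones(n), xab])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("combined design is rank-deficient")
    sse_ab = _sse(y, xab)
    sse_a = _sse(y, x_a)
    sse_b = _sse(y, x_b)
    sse_0 = _sse(y, None)
    return {
        "r2_A_unique": (sse_b - sse_ab) / sse_b if sse_b > 0 else 0.0,
        "r2_B_unique": (sse_a - sse_ab) / sse_a if sse_a > 0 else 0.0,
        "r2_joint": 1.0 - sse_ab / sse_0 if sse_0 > 0 else 1.0,
    }


# ---------------------------------------------------------------- EWAS and λ

def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor λ: the median association chi-square (1 df)
    over the null median. λ near 1 indicates no systematic confounding."""
    p = np.asarray(pvalues, float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values to estimate lambda")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def mvalues(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """M-values log2(beta/(1-beta)); betas clipped away from {0,1}."""
    b = np.clip(np.asarray(beta, float), eps, 1 - eps)
    return np.log2(b / (1 - b))


def ewas_lm(
    mvals: np.ndarray, phenotype: np.ndarray, covariates: CovariateMatrix | np.ndarray | None
) -> np.ndarray:
    """Per-probe OLS of M-values on [intercept, phenotype, covariates];
    returns two-sided t-test p-values for the phenotype coefficient.

    ``mvals`` is probes x samples; ``phenotype`` is 0/1 per sample.
    """
    m = np.asarray(mvals, float)
    pheno = np.asarray(phenotype, float)
    n = pheno.shape[0]
    cov = None
    if covariates is not None:
        cov = covariates.values.to_numpy(float) if isinstance(covariates, CovariateMatrix) else np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # an intercept column supplied among the covariates would be duplicated
        const = np.all(cov == cov[0], axis=0)
        cov = cov[:, ~const]
    x = np.column_stack([np.ones(n), pheno] + ([cov] if cov is not None and cov.shape[1] else []))
    p_cols = x.shape[1]
    if np.linalg.matrix_rank(x) < p_cols:
        raise ValueError("EWAS design is rank-deficient")
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ x.T @ m.T  # p_cols x probes
    resid = m.T - x @ coef
    dof = n - p_cols
    if dof <= 0:
        raise ValueError("no residual degrees of freedom in EWAS design")
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[1] / se
    return 2.0 * stats.t.sf(np.abs(t), dof)


# ------------------------------------------- covariate-ancestry confounding

def _mixed_lrt(y: np.ndarray, groups, individuals) -> float:
    """LRT p-value for a group effect on y with a per-individual random
    intercept; both models fitted by maximum likelihood."""
    import statsmodels.api as sm

    groups = pd.Categorical(groups)
    dummies = pd.get_dummies(groups, drop_first=True).to_numpy(float)
    n = len(y)
    exog_full = np.column_stack([np.ones(n), dummies])
    exog_null = np.ones((n, 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.MixedLM(y, exog_full, groups=np.asarray(individuals)).fit(reml=False)
            null = sm.MixedLM(y, exog_null, groups=np.asarray(individuals)).fit(reml=False)
        lr = 2.0 * (full.llf - null.llf)
    except Exception as exc:  # singular fits
        log.warning("mixed-model fit failed (%s); reporting missing", exc)
        return float("nan")
    lr = max(lr, 0.0)
    return float(stats.chi2.sf(lr, df=dummies.shape[1]))


def covariate_ancestry_assoc(
    factors: pd.DataFrame,
    groups,
    individuals=None,
    repeated: bool = False,
) -> pd.Series:
    """Per-factor p-values for association with ancestry group.

    ``factors`` holds one column per adjustment factor (sex coded 0/1, age,
    control-probe PCs, cell-type PCs). Without repeated samples, each factor
    is tested by one-way ANOVA across groups (equivalent to the linear-model
    F test for two groups). With ``repeated=True``, factors are tested by a
    likelihood-ratio test between random-intercept mixed models with and
    without the group predictor. Singular fits are reported as NaN.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least 2 ancestry groups")
    out = {}
    for name in factors.columns:
        y = factors[name].to_numpy(float)
        if repeated:
            if individuals is None:
                raise ValueError("repeated=True requires individual IDs")
            out[name] = _mixed_lrt(y, groups, individuals)
        else:
            chunks = [y[groups == g] for g in uniq]
            out[name] = float(stats.f_oneway(*chunks).pvalue)
    return pd.Series(out, name="p")


# ---------------------------------------------------------------- reporting

@dataclass
class EvaluationReport:
    """Collected evaluation metrics for one pipeline variant."""

    method: str
    mean_silhouette_by_group: float
    silhouette_by_group: dict
    mean_silhouette_by_individual: float | None
    within_cluster_mean_dist: dict
    between_centroid_dist: pd.DataFrame
    assoc_tests: dict
    abs_cor_matrix: pd.DataFrame | None = None
    mean_abs_cor: float | None = None
    lam: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mean_silhouette_by_group": self.mean_silhouette_by_group,
            "silhouette_by_group": {str(k): v for k, v in self.silhouette_by_group.items()},
            "mean_silhouette_by_individual": self.mean_silhouette_by_individual,
            "within_cluster_mean_dist": {str(k): v for k, v in self.within_cluster_mean_dist.items()},
            "between_centroid_dist": self.between_centroid_dist.to_dict(),
            "assoc_tests": self.assoc_tests,
            "abs_cor_matrix": None if self.abs_cor_matrix is None else self.abs_cor_matrix.to_dict(),
            "mean_abs_cor": self.mean_abs_cor,
            "lambda": self.lam,
        }


def evaluate_pcs(
    scores: pd.DataFrame,
    group_labels,
    individual_labels=None,
    genotype_pcs: np.ndarray | None = None,
    method: str = "raw",
) -> EvaluationReport:
    """Run the clustering / association / correlation battery on the first
    three PCs of one variant."""
    pts = scores.to_numpy(float)[:, :3]
    groups = np.asarray(group_labels)
    _, mean_s, per_label = silhouette(pts, groups)
    within, between = centroid_metrics(pts, groups)
    mean_s_ind = None
    if individual_labels is not None:
        ind = np.asarray(individual_labels)
        if len(np.unique(ind)) >= 2 and len(np.unique(ind)) < len(ind):
            _, mean_s_ind, _ = silhouette(pts, ind)
    assoc = {
        col: association_test(scores[col].to_numpy(float), groups)
        for col in scores.columns[:3]
    }
    cor_mat, mean_cor = (None, None)
    if genotype_pcs is not None:
        cor_mat, mean_cor = pc_correlations(pts, np.asarray(genotype_pcs)[:, :3])
    return EvaluationReport(
        method=method,
        mean_silhouette_by_group=mean_s,
        silhouette_by_group=per_label,
        mean_silhouette_by_individual=mean_s_ind,
        within_cluster_mean_dist=within,
        between_centroid_dist=between,
        assoc_tests=assoc,
        abs_cor_matrix=cor_mat,
        mean_abs_cor=mean_cor,
    )


def plot_pc_scatter(scores: pd.DataFrame, labels, path: str) -> None:
    """Scatterplot matrix of the first three PCs colored by label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray(labels)
    cols = list(scores.columns[:3])
    uniq = list(dict.fromkeys(labels))
    fig, axes = plt.subplots(len(cols), len(cols), figsize=(9, 9))
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            ax = axes[i][j]
            if i == j:
                ax.text(0.5, 0.5, ci, ha="center", va="center")
                ax.set_xticks([]); ax.set_yticks([])
                continue
            for lab in uniq:
                m = labels == lab
                ax.scatter(scores[cj][m], scores[ci][m], s=8, label=str(lab))
    axes[0][1].legend(loc="best", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
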