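"""Covariate design construction and per-probe residualization.

The design pools technical surrogates (control-probe PCs), biological
composition (cell-type PCs), sex and age. Residualizing each selected
probe's betas against this design removes those effects before the
ancestry PCA, so the leading PCs are free to capture genetic structure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BetaMatrix, CovariateMatrix, ResidualMatrix, SampleMetadata
from .pca import svd_scores

log = logging.getLogger(__name__)


def control_probe_pcs(control: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Sample scores of the first ``n`` PCs of the control-probe intensities.

    Control probes (staining, extension, bisulfite conversion, background)
    capture technical variation such as slide, array position and scanner
    effects. Intensities are log2(x+1)-transformed and each probe is
    standardized across samples before the PCA, so no single bright probe
    class dominates.
    """
    if control.shape[0] < 1:
        raise ValueError("need at least one control probe")
    if control.shape[1] < n + 1:
        raise ValueError(f"need at least {n + 1} samples for {n} control-probe PCs")
    x = np.log2(control.to_numpy(float) + 1.0)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("control-probe matrix is constant; PCA is degenerate")
    if not keep.all():
        log.warning("dropping %d constant control probes before PCA", int((~keep).sum()))
    x = x[keep]
    x = (x - x.mean(axis=1, keepdims=True)) / sd[keep, None]
    scores, _ = svd_scores(x.T, n)  # samples x n; columns centered by construction
    return pd.DataFrame(
        scores, index=control.columns, columns=[f"ctrlPC{i + 1}" for i in range(n)]
    )


def cell_type_pcs(props: pd.DataFrame, n: int) -> pd.DataFrame:
    """Sample scores of the first ``n`` PCs of the cell-type proportions.

    Proportions live on the simplex (rows sum to 1), so at most K-1
    informative PCs exist for K cell types.
    """
    x = props.to_numpy(float)
    if np.any(np.abs(x.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("cell proportions must sum to 1 per sample")
    k = x.shape[1]
    if n > k - 1:
        raise ValueError(f"requested {n} cell-type PCs but only {k - 1} can be informative for K={k}")
    centered = x - x.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise ValueError("all samples share one cell composition; PCA is degenerate")
    scores, _ = svd_scores(centered, n)
    return pd.DataFrame(scores, index=props.index, columns=[f"cellPC{i + 1}" for i in range(n)])


def build_design(
    meta: SampleMetadata,
    ctrl_pcs: pd.DataFrame | None,
    cell_pcs: pd.DataFrame | None,
) -> CovariateMatrix:
    """Assemble [intercept, sex, age, cell PCs, control PCs] for all samples.

    Constant columns (e.g. sex in a single-sex cohort) are dropped with a
    warning instead of producing a rank-deficient design.
    """
    samples = meta.sample_ids
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    sex = meta.table["sex"]
    missing = list(samples[sex.isna()])
    cols["sex"] = (sex == "M").astype(float).to_numpy()
    age = pd.to_numeric(meta.table["age"], errors="coerce")
    missing += list(samples[age.isna()])
    if missing:
        raise ValueError(f"missing sex/age for sample(s): {sorted(set(missing))}")
    cols["age"] = age.to_numpy(float)
    design = pd.DataFrame(cols, index=samples)
    for block in (cell_pcs, ctrl_pcs):
        if block is not None:
            design = design.join(block.loc[samples])
    for name in list(design.columns):
        if name != "intercept" and design[name].nunique() <= 1:
            log.warning("dropping constant covariate column %r", name)
            design = design.drop(columns=[name])
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a minimal set of columns whose removal restores full rank
        bad = []
        q, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        thresh = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [design.columns[j] for j in np.flatnonzero(diag < thresh)]
        raise ValueError(f"design is rank-deficient; collinear column(s): {bad}")
    return CovariateMatrix(design)


def residualize_betas(beta: BetaMatrix, design: CovariateMatrix) -> ResidualMatrix:
    """Per-probe OLS residuals of beta on the covariate design.

    Every probe's beta vector (across samples) is projected off the design's
    column space, so residuals are exactly orthogonal to every covariate.
    """
    x = design.values.to_numpy(float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design is rank-deficient")
    b = beta.values.to_numpy(float)
    if np.isnan(b).any():
        raise ValueError("betas must be imputed (no missing values) before residualization")
    q, _ = np.linalg.qr(x)
    bt = b.T  # samples x probes
    resid = bt - q @ (q.T @ bt)
    return ResidualMatrix(
        pd.DataFrame(resid.T, index=beta.probe_ids, columns=beta.sample_ids)
    )
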