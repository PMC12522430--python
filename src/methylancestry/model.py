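"""The ancestry-PC model: pipeline configuration, model and results objects.

:class:`AncestryPCA` bundles the full pipeline — probe selection, masking,
filtering, quantile normalization, beta computation, imputation, covariate
residualization, rs-genotype augmentation and the final centered PCA — for
one of three variants:

``raw``
    PCA of the normalized betas of SNP-overlapping probes (the classic
    methylation-ancestry-PC approach; no covariate adjustment).
``residualized``
    betas residualized for control-probe PCs, cell-type PCs, sex and age
    before the PCA.
``augmented``
    the residualized features concatenated with genotype calls from the
    array's rs probes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .containers import (
    AncestryPCs,
    BetaMatrix,
    CovariateMatrix,
    FilterReport,
    IntensitySet,
    ProbeAnnotation,
    SampleMetadata,
    VARIANTS,
)
from .covariates import build_design, cell_type_pcs, control_probe_pcs, residualize_betas
from .genotypes import call_rs_genotypes, combine_features
from .pca import svd_scores
from .preprocess import (
    compute_beta,
    filter_probes,
    impute_missing,
    mask_by_detection,
    quantile_normalize,
)
from .probes import select_ancestry_probes


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the pipeline with field-standard defaults."""

    detp_threshold: float = 1e-16  # detection p above this -> entry masked
    bead_min: int = 3              # bead count below this counts as a failure
    bead_frac: float = 0.05        # probe removed if failure share > this
    miss_frac: float = 0.10        # probe removed if missing share > this
    maf_min: float = 0.05          # minimum minor allele frequency
    max_distance: int = 0          # max CpG-SNP distance (0 = overlap)
    beta_offset: float = 100.0     # AU offset in beta = M/(M+U+offset)
    impute_k: int = 5              # nearest probes for imputation
    n_ctrl_pcs: int = 10           # control-probe PCs in the design
    n_cell_pcs: int | None = None  # default: min(K-1, 6)
    n_pcs: int = 10                # ancestry PCs to return
    qn_strata: str = "by-type"     # 'by-type' or 'joint'
    caller: str = "threshold"      # rs genotype caller: 'threshold'/'kmeans'
    geno_low: float = 0.25
    geno_high: float = 0.75
    min_call_rate: float = 0.9     # rs probes below this are dropped
    scale: bool = True             # min-max scale the PC scores
    seed: int = 0


def minmax_scale(pcs: AncestryPCs) -> AncestryPCs:
    """Scale each PC column to span exactly [0, 1]."""
    scores = pcs.scores.to_numpy(float).copy()
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    const = hi - lo <= 0
    if const.any():
        name = pcs.scores.columns[np.argmax(const)]
        raise ValueError(f"cannot min-max scale constant column {name!r}")
    scores = (scores - lo) / (hi - lo)
    return AncestryPCs(
        scores=pd.DataFrame(scores, index=pcs.scores.index, columns=pcs.scores.columns),
        explained_variance=pcs.explained_variance,
        method=pcs.method,
        scaled=True,
    )


def compute_ancestry_pcs(features: pd.DataFrame, n_pcs: int = 10, method: str = "raw") -> AncestryPCs:
    """Centered (unscaled-variance) PCA of the samples-x-features matrix."""
    n, p = features.shape
    if n < 3:
        raise ValueError("need at least 3 samples for ancestry PCA")
    if n_pcs > min(n - 1, p):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_samples-1, n_features)={min(n - 1, p)}")
    x = features.to_numpy(float)
    x = x - x.mean(axis=0)
    scores, ev = svd_scores(x, n_pcs)
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return AncestryPCs(
        scores=pd.DataFrame(scores, index=features.index, columns=cols),
        explained_variance=ev,
        method=method,
        scaled=False,
    )


class AncestryPCA:
    """Ancestry-PC model over a methylation intensity set.

    Parameters
    ----------
    intensities
        Aligned per-probe matrices (post background correction).
    metadata
        Per-sample covariates; must cover every sample in ``intensities``.
    annotation
        Probe annotation for the matching array generation.
    variant
        'raw', 'residualized' or 'augmented'.
    config
        Pipeline thresholds; defaults follow standard practice (detection-p
        1e-16, bead <3 in >5% of samples, >10% missing, MAF >= 0.05,
        ten control-probe PCs).

    Examples
    --------
    >>> model = AncestryPCA(iset, meta, annotation, variant="augmented")
    >>> res = model.fit()
    >>> res.pcs.scores.head()
    """

    def __init__(
        self,
        intensities: IntensitySet,
        metadata: SampleMetadata,
        annotation: ProbeAnnotation,
        variant: str = "augmented",
        config: PipelineConfig | None = None,
    ) -> None:
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        self.intensities = intensities
        self.metadata = metadata.reindex(list(intensities.sample_ids))
        self.annotation = annotation
        self.variant = variant
        self.config = config or PipelineConfig()

    def fit(self) -> "AncestryPCAResults":
        cfg = self.config
        selected = select_ancestry_probes(
            self.annotation, maf_min=cfg.maf_min, max_distance=cfg.max_distance
        )
        present = [p for p in selected if p in set(self.intensities.probe_ids)]
        if not present:
            raise ValueError("none of the selected ancestry probes are present in the data")
        iset = self.intensities.subset_probes(present)
        iset = mask_by_detection(iset, threshold=cfg.detp_threshold)
        iset, report = filter_probes(
            iset, bead_min=cfg.bead_min, bead_frac=cfg.bead_frac, miss_frac=cfg.miss_frac
        )
        iset = quantile_normalize(
            iset, probe_types=self.annotation.table["probe_type"], strata=cfg.qn_strata
        )
        beta = compute_beta(iset, offset=cfg.beta_offset)
        beta = impute_missing(beta, k=cfg.impute_k, seed=cfg.seed)

        design: CovariateMatrix | None = None
        n_rs_used = 0
        if self.variant == "raw":
            features = beta.values.T.copy()
        else:
            n_cell = cfg.n_cell_pcs
            cell_cols = self.metadata.cell_columns
            if n_cell is None:
                n_cell = min(max(len(cell_cols) - 1, 0), 6)
            cell = (
                cell_type_pcs(self.metadata.table[cell_cols], n_cell)
                if n_cell > 0
                else None
            )
            ctrl = control_probe_pcs(iset.control, n=cfg.n_ctrl_pcs)
            design = build_design(self.metadata, ctrl, cell)
            resid = residualize_betas(beta, design)
            if self.variant == "residualized":
                features = combine_features(resid, None)
            else:
                geno = call_rs_genotypes(
                    iset.rs_beta, low=cfg.geno_low, high=cfg.geno_high, caller=cfg.caller
                )
                features = combine_features(resid, geno, min_call_rate=cfg.min_call_rate)
                n_rs_used = features.shape[1] - resid.values.shape[0]

        n_pcs = min(cfg.n_pcs, features.shape[0] - 1, features.shape[1])
        pcs = compute_ancestry_pcs(features, n_pcs=n_pcs, method=self.variant)
        if cfg.scale:
            pcs = minmax_scale(pcs)
        return AncestryPCAResults(
            model=self,
            pcs=pcs,
            beta=beta,
            filter_report=report,
            design=design,
            n_probes_selected=len(present),
            n_rs_used=n_rs_used,
        )


@dataclass
class AncestryPCAResults:
    """Fitted ancestry PCs plus the diagnostics of every pipeline stage."""

    model: AncestryPCA
    pcs: AncestryPCs
    beta: BetaMatrix
    filter_report: FilterReport
    design: CovariateMatrix | None
    n_probes_selected: int
    n_rs_used: int

    @property
    def scores(self) -> pd.DataFrame:
        return self.pcs.scores

    @property
    def explained_variance(self) -> np.ndarray:
        return self.pcs.explained_variance

    def summary(self) -> str:
        rep = self.filter_report
        lines = [
            "Ancestry PCA results",
            "====================",
            f"variant:              {self.model.variant}",
            f"array:                {self.model.annotation.array}",
            f"samples:              {self.pcs.scores.shape[0]}",
            f"probes selected:      {self.n_probes_selected}",
            f"probes removed (bead/call-rate): {rep.n_removed_beadcount}/{rep.n_removed_callrate}",
            f"probes used:          {rep.n_kept}",
            f"rs probes in features: {self.n_rs_used}",
            f"design columns:       {self.design.names if self.design is not None else '-'}",
            f"PCs returned:         {self.pcs.n_pcs} (min-max scaled: {self.pcs.scaled})",
            "explained variance:   "
            + " ".join(f"{v:.4f}" for v in self.pcs.explained_variance),
        ]
        return "\n".join(lines)

    def save(self, scores_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write scores as TSV plus a JSON sidecar with diagnostics."""
        mio.write_pcs(self.pcs, scores_path)
        if sidecar_path is None:
            sidecar_path = str(scores_path) + ".json"
        payload = {
            "variant": self.model.variant,
            "array": self.model.annotation.array,
            "config": asdict(self.model.config),
            "n_probes_selected": self.n_probes_selected,
            "n_rs_used": self.n_rs_used,
            "filter_report": self.filter_report.to_dict(),
            "explained_variance": [float(v) for v in self.pcs.explained_variance],
            "design_columns": self.design.names if self.design is not None else None,
        }
        Path(sidecar_path).write_text(json.dumps(payload, indent=2))


def run_variant(
    intensities: IntensitySet,
    metadata: SampleMetadata,
    annotation: ProbeAnnotation,
    variant: str,
    config: PipelineConfig | None = None,
) -> AncestryPCs:
    """Functional one-call interface: fit one pipeline variant, return PCs."""
    return AncestryPCA(intensities, metadata, annotation, variant, config).fit().pcs
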