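"""Core data containers for the ancestry-PC pipeline.

All matrix-like containers are thin wrappers around labelled
:class:`pandas.DataFrame` objects (probe IDs as the row index, sample IDs as
columns) with validation of the invariants every downstream stage relies on:
axis alignment, value ranges, and uniqueness of identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ARRAYS = ("450K", "EPICv1", "EPICv2")
PROBE_TYPES = ("I_green", "I_red", "II")
VARIANTS = ("raw", "residualized", "augmented")


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass
class ProbeAnnotation:
    """Per-probe metadata driving ancestry-probe selection.

    Parameters
    ----------
    table
        DataFrame indexed by probe ID with columns ``probe_type``
        (I_green / I_red / II), ``snp_distance`` (bp between the interrogated
        cytosine and the nearest common SNP; 0 means direct overlap), ``maf``
        (minor allele frequency of that SNP, in [0, 1]) and ``source_flags``
        (set of strings naming the published annotation(s) listing the probe;
        may be empty for probes listed nowhere).
    array
        Array generation the annotation belongs to.
    """

    table: pd.DataFrame
    array: str

    def __post_init__(self) -> None:
        if self.array not in ARRAYS:
            raise ValidationError(f"unknown array {self.array!r}; expected one of {ARRAYS}")
        required = {"probe_type", "snp_distance", "maf", "source_flags"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing required column(s): {sorted(missing)}")
        dup = self.table.index[self.table.index.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate probe_id in annotation: {dup[0]!r}")
        bad_type = set(self.table["probe_type"]) - set(PROBE_TYPES)
        if bad_type:
            raise ValidationError(f"unknown probe_type value(s): {sorted(bad_type)}")
        maf = self.table["maf"].to_numpy(float)
        bad = np.flatnonzero((maf < 0) | (maf > 1) | ~np.isfinite(maf))
        if bad.size:
            raise ValidationError(
                f"maf out of [0,1] on row {bad[0]} (probe {self.table.index[bad[0]]!r})"
            )
        dist = self.table["snp_distance"].to_numpy()
        if (dist < 0).any():
            raise ValidationError("snp_distance must be >= 0")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


def _check_matrix(name: str, df: pd.DataFrame, nonneg: bool = False, unit: bool = False) -> None:
    vals = df.to_numpy(float)
    if nonneg and np.nanmin(vals, initial=0.0) < 0:
        raise ValidationError(f"{name} contains negative values")
    if unit:
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                bad = np.argwhere((vals < 0) | (vals > 1))[0]
                raise ValidationError(
                    f"{name} value out of [0,1] at probe {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}: {vals[bad[0], bad[1]]}"
                )


@dataclass
class IntensitySet:
    """Aligned per-probe intensity matrices plus array-level control data.

    ``meth``/``unmeth``/``detp``/``beadcount`` share both axes
    (CpG probes x samples); ``control`` (control probes x samples) and
    ``rs_beta`` (rs probes x samples) share only the sample axis.
    Missing values (NaN) are allowed in ``meth``/``unmeth`` after
    detection-p masking.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    detp: pd.DataFrame
    beadcount: pd.DataFrame
    control: pd.DataFrame
    rs_beta: pd.DataFrame

    def __post_init__(self) -> None:
        samples = list(self.meth.columns)
        for name in ("unmeth", "detp", "beadcount", "control", "rs_beta"):
            df = getattr(self, name)
            if list(df.columns) != samples:
                missing = sorted(set(samples) ^ set(df.columns))
                raise ValidationError(
                    f"sample IDs of {name!r} differ from 'meth' (symmetric difference: {missing})"
                )
        probes = list(self.meth.index)
        for name in ("unmeth", "detp", "beadcount"):
            if list(getattr(self, name).index) != probes:
                raise ValidationError(f"probe IDs of {name!r} not aligned with 'meth'")
        _check_matrix("meth", self.meth, nonneg=True)
        _check_matrix("unmeth", self.unmeth, nonneg=True)
        _check_matrix("detp", self.detp, unit=True)
        _check_matrix("control", self.control, nonneg=True)
        _check_matrix("rs_beta", self.rs_beta, unit=True)

    @property
    def probe_ids(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.meth.columns

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    def subset_probes(self, probe_ids: Sequence[str]) -> "IntensitySet":
        """Restrict the CpG-probe axis to ``probe_ids`` (order preserved)."""
        return IntensitySet(
            meth=self.meth.loc[probe_ids],
            unmeth=self.unmeth.loc[probe_ids],
            detp=self.detp.loc[probe_ids],
            beadcount=self.beadcount.loc[probe_ids],
            control=self.control,
            rs_beta=self.rs_beta,
        )


@dataclass
class SampleMetadata:
    """Per-sample covariates and (optional) evaluation labels.

    ``table`` is indexed by sample ID with columns ``individual_id``, ``sex``
    (F/M), ``age`` (years), one ``cell_<name>`` column per cell type (fractions
    summing to 1 per sample), and optionally ``ancestry_label``, ``phenotype``
    (case/control) and ``gtpc1..k`` genotype-PC columns used only by the
    evaluation layer.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        for col in ("individual_id", "sex", "age"):
            if col not in self.table.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        bad_sex = set(self.table["sex"].dropna()) - {"F", "M"}
        if bad_sex:
            raise ValidationError(f"sex must be F or M, got {sorted(bad_sex)}")
        props = self.cell_props
        if props.shape[1]:
            if np.any((props < -1e-9) | (props > 1 + 1e-9)):
                raise ValidationError("cell proportions outside [0,1]")
            sums = props.sum(axis=1)
            if np.any(np.abs(sums - 1) > 1e-6):
                bad = self.table.index[np.argmax(np.abs(sums - 1))]
                raise ValidationError(f"cell proportions of sample {bad!r} do not sum to 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def cell_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("cell_")]

    @property
    def cell_props(self) -> np.ndarray:
        return self.table[self.cell_columns].to_numpy(float)

    @property
    def genotype_pc_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("gtpc")]

    @property
    def genotype_pcs(self) -> np.ndarray | None:
        cols = self.genotype_pc_columns
        return self.table[cols].to_numpy(float) if cols else None

    def reindex(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"metadata missing sample(s): {sorted(missing)}")
        return SampleMetadata(self.table.loc[list(sample_ids)])


@dataclass
class BetaMatrix:
    """Beta values (fraction methylated) for selected probes; NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_matrix("beta", self.values, unit=True)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class FilterReport:
    """Bookkeeping for probe-level exclusions (bead count, then call rate)."""

    n_input_probes: int
    removed_beadcount: list[str] = field(default_factory=list)
    removed_callrate: list[str] = field(default_factory=list)

    @property
    def n_removed_beadcount(self) -> int:
        return len(self.removed_beadcount)

    @property
    def n_removed_callrate(self) -> int:
        return len(self.removed_callrate)

    @property
    def removed_ids(self) -> list[str]:
        return self.removed_beadcount + self.removed_callrate

    @property
    def n_kept(self) -> int:
        return self.n_input_probes - len(self.removed_ids)

    def to_dict(self) -> dict:
        return {
            "n_input_probes": self.n_input_probes,
            "n_removed_beadcount": self.n_removed_beadcount,
            "n_removed_callrate": self.n_removed_callrate,
            "n_kept": self.n_kept,
            "removed_ids": self.removed_ids,
        }


@dataclass
class CovariateMatrix:
    """Residualization design: samples x named covariate columns."""

    values: pd.DataFrame  # samples x p

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate covariate column names")

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def complete(self) -> bool:
        return not self.values.isna().any().any()


@dataclass
class ResidualMatrix:
    """Per-probe OLS residuals (probes x samples), orthogonal to the design."""

    values: pd.DataFrame

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class GenotypeMatrix:
    """Called rs-probe genotypes on the half-dosage scale {0, 0.5, 1}.

    NaN marks a no-call; ``call_rate`` is the per-probe fraction of samples
    with a call.
    """

    values: pd.DataFrame  # rs probes x samples
    call_rate: pd.Series

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 0.5, 1.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValidationError(
                f"genotype entries must be 0/0.5/1/missing, got {vals[bad[0], bad[1]]}"
            )


@dataclass
class AncestryPCs:
    """Sample scores of the ancestry PCA (samples x PCs).

    After min-max scaling every column spans exactly [0, 1];
    ``explained_variance`` holds the fraction of total feature variance per
    component and is non-increasing. ``method`` names the pipeline variant
    (raw / residualized / augmented).
    """

    scores: pd.DataFrame
    explained_variance: np.ndarray
    method: str
    scaled: bool = True

    def __post_init__(self) -> None:
        if self.method not in VARIANTS:
            raise ValidationError(f"unknown method {self.method!r}; expected one of {VARIANTS}")
        self.explained_variance = np.asarray(self.explained_variance, float)
        ev = self.explained_variance
        if np.any(ev < -1e-12) or np.any(ev > 1 + 1e-12):
            raise ValidationError("explained_variance entries must lie in [0,1]")
        if np.any(np.diff(ev) > 1e-12):
            raise ValidationError("explained_variance must be non-increasing")

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[1]
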