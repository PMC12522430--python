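"""Preprocessing of the selected probes: masking, filtering, quantile
normalization, beta computation and imputation.

The stage order is fixed: detection-p masking -> probe filtering ->
quantile normalization -> beta values -> imputation. Masking precedes
filtering so that the call-rate rule sees exactly the entries that failed
detection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BetaMatrix, FilterReport, IntensitySet

log = logging.getLogger(__name__)


def mask_by_detection(iset: IntensitySet, threshold: float = 1e-16) -> IntensitySet:
    """Set meth/unmeth entries whose detection p-value exceeds ``threshold``
    to missing (NaN). A large detection p-value means the probe's signal in
    that sample is indistinguishable from background.
    """
    bad = iset.detp.to_numpy(float) > threshold
    meth = iset.meth.copy()
    unmeth = iset.unmeth.copy()
    meth.values[bad] = np.nan
    unmeth.values[bad] = np.nan
    return IntensitySet(
        meth=meth,
        unmeth=unmeth,
        detp=iset.detp,
        beadcount=iset.beadcount,
        control=iset.control,
        rs_beta=iset.rs_beta,
    )


def filter_probes(
    iset: IntensitySet,
    bead_min: int = 3,
    bead_frac: float = 0.05,
    miss_frac: float = 0.10,
) -> tuple[IntensitySet, FilterReport]:
    """Exclude unreliable probes.

    A probe is removed when the share of samples with a bead count below
    ``bead_min`` exceeds ``bead_frac`` (strict >), or when the share of
    missing (masked) entries exceeds ``miss_frac`` (strict >). A probe failing
    both rules is counted once, under the bead-count reason.
    """
    beads = iset.beadcount.to_numpy(float)
    n = iset.n_samples
    bead_fail = (beads < bead_min).mean(axis=1) > bead_frac
    miss_share = np.isnan(iset.meth.to_numpy(float)).mean(axis=1)
    miss_fail = miss_share > miss_frac

    ids = iset.probe_ids
    removed_bead = list(ids[bead_fail])
    removed_call = list(ids[~bead_fail & miss_fail])
    keep = ids[~(bead_fail | miss_fail)]
    if len(keep) == 0:
        raise ValueError("all probes removed by bead-count/call-rate filters")
    report = FilterReport(
        n_input_probes=len(ids),
        removed_beadcount=removed_bead,
        removed_callrate=removed_call,
    )
    return iset.subset_probes(keep), report


def _qn_reference(values: np.ndarray) -> np.ndarray:
    """Mean-of-order-statistics reference for one stratum (probes x samples).

    With missing values, each sample's sorted vector is linearly interpolated
    onto a common length-n_probes quantile grid before averaging; for complete
    data this reduces to the mean of order statistics.
    """
    n_ref = values.shape[0]
    grid = np.linspace(0.0, 1.0, n_ref)
    cols = []
    for j in range(values.shape[1]):
        v = np.sort(values[~np.isnan(values[:, j]), j])
        if v.size == 0:
            continue
        if v.size == 1:
            cols.append(np.full(n_ref, v[0]))
        else:
            cols.append(np.interp(grid, np.linspace(0.0, 1.0, v.size), v))
    return np.mean(cols, axis=0)


def _qn_apply(values: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map each sample's values onto ``ref`` by rank; ties receive the mean
    of the reference values their rank span covers; missing stays missing."""
    out = np.full_like(values, np.nan, dtype=float)
    n_ref = ref.size
    for j in range(values.shape[1]):
        mask = ~np.isnan(values[:, j])
        v = values[mask, j]
        m = v.size
        if m == 0:
            continue
        if m == 1:
            out[mask, j] = ref.mean()
            continue
        pos = np.linspace(0.0, n_ref - 1.0, m)
        ref_m = np.interp(pos, np.arange(n_ref), ref)
        order = np.argsort(v, kind="stable")
        assigned = np.empty(m)
        assigned[order] = ref_m
        uniq, inv = np.unique(v, return_inverse=True)
        counts = np.bincount(inv)
        means = np.bincount(inv, weights=assigned) / counts
        out[mask, j] = means[inv]
    return out


def quantile_normalize(
    iset: IntensitySet,
    probe_types: pd.Series | None = None,
    strata: str = "by-type",
) -> IntensitySet:
    """Quantile-normalize meth and unmeth intensities across samples.

    With ``strata='by-type'`` (default), normalization runs separately per
    probe chemistry (type I green / type I red / type II) so the two assay
    designs' different intensity distributions are not forced onto one
    another; ``strata='joint'`` normalizes all selected probes together.
    Meth and unmeth channels are always normalized separately.
    """
    if iset.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    if strata == "joint" or probe_types is None:
        groups = {"all": np.ones(len(iset.probe_ids), bool)}
    elif strata == "by-type":
        pt = probe_types.loc[iset.probe_ids]
        groups = {t: (pt == t).to_numpy() for t in pd.unique(pt)}
    else:
        raise ValueError(f"unknown strata mode {strata!r}")

    meth = iset.meth.to_numpy(float).copy()
    unmeth = iset.unmeth.to_numpy(float).copy()
    for name, rows in groups.items():
        if rows.sum() < 2:
            log.warning("stratum %r has <2 probes; passed through unchanged", name)
            continue
        for mat in (meth, unmeth):
            block = mat[rows]
            ref = _qn_reference(block)
            mat[rows] = _qn_apply(block, ref)
    return IntensitySet(
        meth=pd.DataFrame(meth, index=iset.probe_ids, columns=iset.sample_ids),
        unmeth=pd.DataFrame(unmeth, index=iset.probe_ids, columns=iset.sample_ids),
        detp=iset.detp,
        beadcount=iset.beadcount,
        control=iset.control,
        rs_beta=iset.rs_beta,
    )


def compute_beta(iset: IntensitySet, offset: float = 100.0) -> BetaMatrix:
    """Beta values: beta = M / (M + U + offset), elementwise; NaN propagates.

    The offset (Illumina convention, 100 AU) stabilizes the ratio at low
    total intensity and keeps beta strictly below 1.
    """
    m = iset.meth.to_numpy(float)
    u = iset.unmeth.to_numpy(float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(m, initial=0) < 0 or np.nanmin(u, initial=0) < 0:
            raise ValueError("negative intensity encountered in beta computation")
    beta = m / (m + u + offset)
    return BetaMatrix(pd.DataFrame(beta, index=iset.probe_ids, columns=iset.sample_ids))


def impute_missing(beta: BetaMatrix, k: int = 5, seed: int = 0) -> BetaMatrix:
    """k-nearest-probe imputation of missing betas.

    For a missing entry (probe i, sample s), donor probes are those with a
    value at s; they are ranked by mean squared difference to probe i over
    the samples where both are observed, and the missing value becomes the
    mean of the ``k`` nearest donors' values at s, clipped to [0, 1]. The
    procedure is deterministic (``seed`` is accepted for interface
    uniformity but unused).

    Raises
    ------
    ValueError
        If any probe is missing in every sample (the call-rate filter should
        prevent this upstream).
    """
    vals = beta.values.to_numpy(float).copy()
    obs = ~np.isnan(vals)
    fully_missing = ~obs.any(axis=1)
    if fully_missing.any():
        pid = beta.probe_ids[np.argmax(fully_missing)]
        raise ValueError(f"probe {pid!r} is missing in all samples; cannot impute")
    if obs.all():
        return BetaMatrix(beta.values.copy())

    filled = np.where(obs, vals, 0.0)
    need = np.flatnonzero(~obs.all(axis=1))
    for i in need:
        # nan-aware mean squared difference between probe i and all probes
        both = obs & obs[i]  # (n_probes, n_samples) overlap with probe i
        overlap = both.sum(axis=1)
        diff = (filled - filled[i]) * both
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.einsum("ij,ij->i", diff, diff) / overlap
        dist[overlap == 0] = np.inf
        dist[i] = np.inf
        for s in np.flatnonzero(~obs[i]):
            cand = dist.copy()
            cand[~obs[:, s]] = np.inf
            order = np.argsort(cand, kind="stable")[: min(k, np.isfinite(cand).sum())]
            order = order[np.isfinite(cand[order])]
            if order.size == 0:
                # no donor shares samples with probe i; fall back to probe mean
                vals[i, s] = np.nanmean(vals[i])
            else:
                vals[i, s] = float(np.clip(np.mean(vals[order, s]), 0.0, 1.0))
    out = pd.DataFrame(vals, index=beta.probe_ids, columns=beta.sample_ids)
    return BetaMatrix(out)
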