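"""Genotype calling from rs probes and feature assembly.

Illumina arrays carry a small set of "rs" probes that assay SNPs directly:
their beta values are trimodal (near 0, 0.5 and 1 for the three genotypes).
Called genotypes are encoded on the half-dosage scale {0, 0.5, 1} so the
genotype block lives on the same numeric scale as beta residuals and does
not dominate the unscaled PCA.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ResidualMatrix

log = logging.getLogger(__name__)


def call_rs_genotypes(
    rs_beta: pd.DataFrame,
    low: float = 0.25,
    high: float = 0.75,
    caller: str = "threshold",
) -> GenotypeMatrix:
    """Call genotypes from rs-probe betas.

    With ``caller='threshold'`` (default): beta < ``low`` -> 0,
    ``low`` <= beta <= ``high`` -> 0.5 (inclusive heterozygote band),
    beta > ``high`` -> 1. With ``caller='kmeans'`` a one-dimensional
    3-cluster k-means over all observed betas (centers initialized at
    0.05 / 0.5 / 0.95, so the result is deterministic) defines the three
    genotype classes instead. Missing betas propagate to no-calls.
    """
    vals = rs_beta.to_numpy(float)
    out = np.full_like(vals, np.nan)
    obs = ~np.isnan(vals)
    if caller == "threshold":
        out[obs & (vals < low)] = 0.0
        out[obs & (vals >= low) & (vals <= high)] = 0.5
        out[obs & (vals > high)] = 1.0
    elif caller == "kmeans":
        from sklearn.cluster import KMeans

        v = vals[obs].reshape(-1, 1)
        km = KMeans(n_clusters=3, init=np.array([[0.05], [0.5], [0.95]]), n_init=1)
        labels = km.fit_predict(v)
        order = np.argsort(km.cluster_centers_.ravel())
        remap = np.empty(3)
        remap[order] = [0.0, 0.5, 1.0]
        out[obs] = remap[labels]
    else:
        raise ValueError(f"unknown caller {caller!r}")
    values = pd.DataFrame(out, index=rs_beta.index, columns=rs_beta.columns)
    call_rate = pd.Series(obs.mean(axis=1), index=rs_beta.index, name="call_rate")
    return GenotypeMatrix(values=values, call_rate=call_rate)


def combine_features(
    resid: ResidualMatrix,
    geno: GenotypeMatrix | None = None,
    min_call_rate: float = 0.9,
) -> pd.DataFrame:
    """Samples x features matrix: residualized betas, optionally augmented
    with called rs genotypes.

    rs probes with call rate below ``min_call_rate`` are dropped (logged);
    remaining no-calls are imputed with the probe's mean call. With
    ``geno=None`` the features are the residuals alone (the
    residualized-only pipeline variant).
    """
    features = resid.values.T.copy()  # samples x probes
    if geno is None:
        return features
    if list(geno.values.columns) != list(resid.sample_ids):
        raise ValueError("sample IDs of genotype matrix do not match residual matrix")
    keep = geno.call_rate >= min_call_rate
    n_drop = int((~keep).sum())
    if n_drop:
        log.warning(
            "dropping %d rs probe(s) with call rate < %.2f: %s",
            n_drop, min_call_rate, list(geno.values.index[~keep]),
        )
    g = geno.values.loc[keep.index[keep]].T.copy()  # samples x rs probes
    g = g.fillna(g.mean())
    return pd.concat([features, g], axis=1)
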