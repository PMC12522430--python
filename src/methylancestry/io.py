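"""Tabular I/O: annotation, intensity matrices, metadata and PC scores.

All inputs are CSV/TSV (gzip transparently supported) with probe IDs as the
first column and sample IDs as the header. Missing values may be encoded as
an empty field or any capitalisation of "NA"/"NaN".
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    AncestryPCs,
    IntensitySet,
    ProbeAnnotation,
    SampleMetadata,
    ValidationError,
)

log = logging.getLogger(__name__)

_NA_VALUES = ["", "NA", "na", "Na", "nA", "NaN", "nan", "NAN"]


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "\t" if name.endswith((".tsv", ".txt")) else ","


def read_matrix(path: str | Path, dtype: type = float) -> pd.DataFrame:
    """Read a probes-x-samples matrix with row IDs in the first column."""
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    return df.astype(dtype)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep=_sep_for(path), index_label=index_label, float_format="%.17g")


def load_annotation(path: str | Path, array: str) -> ProbeAnnotation:
    """Load a probe annotation table for one array generation.

    Expected columns: ``probe_id``, ``probe_type``, ``snp_distance``, ``maf``
    and optionally ``source_flags`` (semicolon-separated list of publications /
    annotation sources naming the probe; absent or empty means none).
    """
    df = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_VALUES, keep_default_na=False)
    for col in ("probe_id", "probe_type", "snp_distance", "maf"):
        if col not in df.columns:
            raise ValidationError(f"annotation file missing required column {col!r}")
    if "source_flags" not in df.columns:
        df["source_flags"] = ""
    df["source_flags"] = [
        frozenset(s for s in str(v).split(";") if s and s.lower() != "nan")
        for v in df["source_flags"]
    ]
    df = df.set_index("probe_id")
    df["snp_distance"] = df["snp_distance"].astype(int)
    df["maf"] = df["maf"].astype(float)
    return ProbeAnnotation(table=df, array=array)


_MATRIX_KEYS = ("meth", "unmeth", "detp", "beadcount", "control", "rs_beta")


def load_intensity_set(config: Mapping[str, str | Path]) -> IntensitySet:
    """Load the six per-probe matrices named in ``config`` and align samples.

    ``config`` maps each of meth / unmeth / detp / beadcount / control /
    rs_beta to a file path. All files must contain the same sample IDs
    (column order is harmonized to the ``meth`` file's order).
    """
    missing = set(_MATRIX_KEYS) - set(config)
    if missing:
        raise ValidationError(f"intensity config missing matrix path(s): {sorted(missing)}")
    mats = {key: read_matrix(config[key]) for key in _MATRIX_KEYS}
    samples = list(mats["meth"].columns)
    for key in _MATRIX_KEYS[1:]:
        diff = sorted(set(samples) ^ set(mats[key].columns))
        if diff:
            raise ValidationError(
                f"sample IDs of {key!r} do not match 'meth' (symmetric difference: {diff})"
            )
        mats[key] = mats[key][samples]
    mats["beadcount"] = mats["beadcount"].round().astype(float)
    return IntensitySet(**mats)


def load_metadata(path: str | Path) -> SampleMetadata:
    """Load a sample metadata table (sample_id, individual_id, sex, age, ...)."""
    df = pd.read_csv(path, sep=_sep_for(path), na_values=_NA_VALUES, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValidationError("metadata file missing required column 'sample_id'")
    return SampleMetadata(df.set_index("sample_id"))


def write_intensity_set(iset: IntensitySet, out_dir: str | Path) -> dict[str, str]:
    """Write the six matrices as TSV into ``out_dir``; returns the path map
    accepted by :func:`load_intensity_set`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for key in _MATRIX_KEYS:
        path = out_dir / f"{key}.tsv"
        write_matrix(getattr(iset, key), path)
        paths[key] = str(path)
    return paths


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep=_sep_for(path), index_label="sample_id", float_format="%.17g")


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    df = annotation.table.copy()
    df["source_flags"] = [";".join(sorted(s)) for s in df["source_flags"]]
    df.to_csv(path, sep=_sep_for(path), index_label="probe_id", float_format="%.17g")


def write_pcs(pcs: AncestryPCs, path: str | Path) -> None:
    """Write scores as TSV with metadata header lines; lossless round-trip."""
    if pcs.scores.shape[0] == 0:
        raise ValidationError("no samples: refusing to write empty PC score matrix")
    if pcs.scaled:
        vals = pcs.scores.to_numpy(float)
        if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12:
            log.warning("PC scores outside [0,1] despite scaled=True; writing anyway")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# method: {pcs.method}\n")
        fh.write(f"# scaled: {int(pcs.scaled)}\n")
        ev = " ".join(format(v, ".17g") for v in pcs.explained_variance)
        fh.write(f"# explained_variance: {ev}\n")
        pcs.scores.to_csv(fh, sep="\t", index_label="sample_id", float_format="%.17g")


def read_pcs(path: str | Path) -> AncestryPCs:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        scores = pd.read_csv(fh, sep="\t", index_col=0)
    ev = np.array([float(v) for v in meta.get("explained_variance", "").split()])
    return AncestryPCs(
        scores=scores,
        explained_variance=ev,
        method=meta.get("method", "raw"),
        scaled=bool(int(meta.get("scaled", "1"))),
    )
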