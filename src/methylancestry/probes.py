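"""Selection of ancestry-informative (SNP-overlapping) CpG probes.

A CpG probe whose interrogated site directly overlaps a common SNP
("SNP0bp" probe) carries genotype information in its methylation signal;
these probes are the raw material for methylation-derived ancestry PCs.
"""

from __future__ import annotations

from .containers import ProbeAnnotation


def select_ancestry_probes(
    annotation: ProbeAnnotation,
    maf_min: float = 0.05,
    max_distance: int = 0,
) -> list[str]:
    """Return probe IDs overlapping a common SNP, in annotation order.

    A probe is selected when its SNP distance is at most ``max_distance``
    (default 0: direct overlap) and the SNP's minor allele frequency is at
    least ``maf_min`` (inclusive). For EPIC v1, where selection is based on
    published annotation lists, the probe must additionally appear in at
    least one source (non-empty ``source_flags``).

    Raises
    ------
    ValueError
        If no probe satisfies the criteria.
    """
    tab = annotation.table
    keep = (tab["snp_distance"] <= max_distance) & (tab["maf"] >= maf_min)
    if annotation.array == "EPICv1":
        keep &= tab["source_flags"].map(len) > 0
    ids = list(tab.index[keep])
    if not ids:
        raise ValueError(
            f"no ancestry-informative probes on {annotation.array} "
            f"(maf_min={maf_min}, max_distance={max_distance})"
        )
    return ids
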