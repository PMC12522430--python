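"""Synthetic methylation-array cohorts with known ancestry ground truth.

The generator emulates the statistical structure the ancestry-PC pipeline
assumes: population structure in SNP-overlapping probes (allele frequencies
drawn from the Balding–Nichols model, genotypes shrunk into beta values with
partial attenuation), batch effects reflected coherently in control probes
and in all CpG probes, sex/age/cell-composition effects, trimodal rs-probe
betas from an independent genotype draw, detection-p dropouts, bead counts,
and repeated samples per individual that share genotypes but differ by
technical noise. Every draw flows from one seed through a fixed
seed-sequence split per stage, so outputs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import IntensitySet, ProbeAnnotation, SampleMetadata
from .pca import fix_signs

_STAGES = (
    "freqs", "genotypes", "rs", "batch", "sex_age", "cell",
    "probe_params", "beta_noise", "intensity", "control", "detp",
    "bead", "phenotype",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    ``groups`` maps ancestry-group labels to numbers of individuals; each
    individual contributes ``n_repeats`` samples. ``fst`` is the
    Balding–Nichols divergence of group allele frequencies from the
    ancestral frequency. ``batch_ancestry_cor`` controls how strongly batch
    assignment follows ancestry group (0 = randomized design, 1 = fully
    confounded). Effect sizes are on the beta scale (per-probe loading
    standard deviations).
    """

    groups: Mapping[str, int] = field(default_factory=lambda: {"EUR": 30, "AFR": 30})
    n_repeats: int = 1
    n_snp_probes: int = 800
    n_nonsnp_probes: int = 1200
    n_control_probes: int = 120
    n_rs_probes: int = 59
    n_cell_types: int = 5
    fst: float = 0.3
    batch_ancestry_cor: float = 0.0
    sex_effect: float = 0.01
    age_effect: float = 0.01
    cell_effect: float = 0.02
    batch_effect: float = 0.02
    n_tech_factors: int = 1
    control_batch_effect: float = 1.0
    nonsnp_ancestry_frac: float = 0.2
    nonsnp_ancestry_effect: float = 0.02
    rs_noise_sd: float = 0.03
    noise_sd: float = 0.02
    missing_rate: float = 0.01
    cell_ancestry_shift: float = 0.0
    phenotype_rate_by_group: Mapping[str, float] | None = None
    array: str = "EPICv2"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_repeats", "n_snp_probes", "n_nonsnp_probes",
                     "n_control_probes", "n_rs_probes", "n_cell_types",
                     "n_tech_factors"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not all(v >= 1 for v in self.groups.values()):
            raise ValueError("every group needs at least one individual")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0,1)")
        for name in ("batch_ancestry_cor", "missing_rate", "nonsnp_ancestry_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    true_genotypes: pd.DataFrame      # SNP probes x samples, dosages {0,1,2}
    rs_genotypes: pd.DataFrame        # rs probes x samples, dosages {0,1,2}
    true_ancestry_axis: pd.Series     # per-sample genotype PC1
    batch: pd.Series                  # per-sample batch label (0/1)
    tech_factors: pd.DataFrame        # technical-factor levels x samples
    individual_map: pd.Series         # sample -> individual
    group: pd.Series                  # per-sample ancestry group label


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray, fst: float) -> np.ndarray:
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return rng.beta(a, b)


def simulate_cohort(
    config: SimConfig,
) -> tuple[IntensitySet, SampleMetadata, ProbeAnnotation, GroundTruth]:
    """Generate one cohort: intensity set, metadata, annotation, truth."""
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(_STAGES, np.random.SeedSequence(config.seed).spawn(len(_STAGES)))
    }
    labels = list(config.groups)
    individuals: list[tuple[str, str]] = []  # (individual_id, group)
    for g in labels:
        for i in range(config.groups[g]):
            individuals.append((f"{g}{i:03d}", g))
    n_ind = len(individuals)
    samples: list[str] = []
    ind_of_sample: list[str] = []
    group_of_sample: list[str] = []
    for ind, g in individuals:
        for r in range(config.n_repeats):
            samples.append(f"{ind}_r{r + 1}")
            ind_of_sample.append(ind)
            group_of_sample.append(g)
    n_samp = len(samples)
    if n_samp < 3:
        raise ValueError("infeasible config: need at least 3 samples")
    group_idx = np.array([labels.index(g) for g in group_of_sample])
    ind_idx_of_sample = np.array(
        [dict((ind, j) for j, (ind, _) in enumerate(individuals))[i] for i in ind_of_sample]
    )

    # --- genotypes: Balding–Nichols group frequencies, binomial dosages ---
    rng = rngs["freqs"]
    p_anc = rng.uniform(0.1, 0.9, size=config.n_snp_probes)
    p_group = np.stack(
        [_balding_nichols(rng, p_anc, config.fst) for _ in labels]
    )  # groups x probes
    rng = rngs["genotypes"]
    geno_ind = np.empty((config.n_snp_probes, n_ind), dtype=float)
    for j, (_, g) in enumerate(individuals):
        geno_ind[:, j] = rng.binomial(2, p_group[labels.index(g)])
    geno = geno_ind[:, ind_idx_of_sample]  # probes x samples (repeats share)

    rng = rngs["rs"]
    p_anc_rs = rng.uniform(0.1, 0.9, size=config.n_rs_probes)
    p_group_rs = np.stack([_balding_nichols(rng, p_anc_rs, config.fst) for _ in labels])
    rs_ind = np.empty((config.n_rs_probes, n_ind), dtype=float)
    for j, (_, g) in enumerate(individuals):
        rs_ind[:, j] = rng.binomial(2, p_group_rs[labels.index(g)])
    rs_geno = rs_ind[:, ind_idx_of_sample]

    # genotype-derived reference PCs (the evaluation's "genotyping PCs");
    # computed per individual and broadcast so repeats share scores exactly
    gcent = geno_ind.T - geno_ind.mean(axis=1)
    u, s, _ = np.linalg.svd(gcent, full_matrices=False)
    n_gt = min(3, int(np.sum(s > s[0] * max(gcent.shape) * np.finfo(float).eps)))
    gt_pcs = fix_signs(u[:, :n_gt] * s[:n_gt])[ind_idx_of_sample]

    # --- technical factors: a binary batch (factor 0, possibly following
    # ancestry) plus optional continuous axes (slide / position / scanner) ---
    rng = rngs["batch"]
    base = group_idx % 2
    follow = rng.random(n_samp) < (1 + config.batch_ancestry_cor) / 2
    batch = np.where(follow, base, 1 - base)
    n_extra = config.n_tech_factors - 1
    tech = np.vstack([
        (batch - 0.5)[None, :],
        rng.normal(0.0, 0.5, (n_extra, n_samp)) if n_extra else np.empty((0, n_samp)),
    ])

    # --- biological covariates (per individual; repeats share sex/age) ---
    rng = rngs["sex_age"]
    sex_ind = rng.random(n_ind) < 0.5
    age_ind = rng.uniform(20.0, 70.0, n_ind)
    sex = sex_ind[ind_idx_of_sample]
    age = age_ind[ind_idx_of_sample]
    rng = rngs["cell"]
    alpha = np.full(config.n_cell_types, 5.0)
    cell = np.empty((n_samp, config.n_cell_types))
    for i in range(n_samp):
        a = alpha.copy()
        a[0] += config.cell_ancestry_shift * group_idx[i] * 5.0
        cell[i] = rng.dirichlet(a)

    # --- beta values ---
    rng = rngs["probe_params"]
    n_probes = config.n_snp_probes + config.n_nonsnp_probes
    atten = rng.uniform(0.6, 0.9, config.n_snp_probes)
    base_nonsnp = np.where(
        rng.random(config.n_nonsnp_probes) < 0.5,
        rng.beta(2, 8, config.n_nonsnp_probes),
        rng.beta(8, 2, config.n_nonsnp_probes),
    )
    batch_load = rng.normal(0.0, 1.0, (n_probes, config.n_tech_factors)) * config.batch_effect
    sex_load = rng.normal(0.0, 1.0, n_probes) * config.sex_effect
    age_load = rng.normal(0.0, 1.0, n_probes) * config.age_effect
    cell_load = rng.normal(0.0, 1.0, n_probes) * config.cell_effect
    anc_mask = rng.random(config.n_nonsnp_probes) < config.nonsnp_ancestry_frac
    anc_load = rng.normal(0.0, 1.0, config.n_nonsnp_probes) * config.nonsnp_ancestry_effect
    anc_load[~anc_mask] = 0.0

    mu = np.empty((n_probes, n_samp))
    mu[: config.n_snp_probes] = 0.5 + atten[:, None] * (geno / 2.0 - 0.5)
    gz = (group_idx - group_idx.mean())
    mu[config.n_snp_probes:] = base_nonsnp[:, None] + anc_load[:, None] * gz[None, :]
    agez = (age - age.mean()) / age.std()
    cellz = cell[:, 0] - cell[:, 0].mean()
    mu += batch_load @ tech
    mu += sex_load[:, None] * (sex - 0.5)[None, :]
    mu += age_load[:, None] * agez[None, :]
    mu += cell_load[:, None] * cellz[None, :]
    rng = rngs["beta_noise"]
    beta = mu + rng.normal(0.0, config.noise_sd, mu.shape)
    beta = np.clip(beta, 0.005, 0.98)

    # --- intensities consistent with beta = M/(M+U+100) ---
    rng = rngs["intensity"]
    total = np.exp(rng.normal(np.log(10000.0), 0.2, beta.shape))
    total = np.maximum(total, 6000.0)
    meth = beta * total
    unmeth = (1.0 - beta) * total - 100.0

    # --- control probes: coherent batch loading on the log scale ---
    rng = rngs["control"]
    ctrl_base = rng.uniform(np.log(500.0), np.log(5000.0), config.n_control_probes)
    ctrl_load = (
        rng.normal(0.0, 1.0, (config.n_control_probes, config.n_tech_factors))
        * config.control_batch_effect
    )
    ctrl = np.exp(
        ctrl_base[:, None]
        + ctrl_load @ tech
        + rng.normal(0.0, 0.1, (config.n_control_probes, n_samp))
    )

    # --- rs-probe betas: trimodal around 0.05 / 0.5 / 0.95 ---
    rng_rs = rngs["beta_noise"]  # continue the beta-noise stream
    rs_beta = 0.05 + 0.45 * rs_geno + rng_rs.normal(0.0, config.rs_noise_sd, rs_geno.shape)
    rs_beta = np.clip(rs_beta, 0.0, 1.0)

    # --- detection p-values and bead counts ---
    rng = rngs["detp"]
    detp = np.full(beta.shape, 1e-30)
    detp[rng.random(beta.shape) < config.missing_rate] = 0.5
    rng = rngs["bead"]
    beads = rng.poisson(12.0, beta.shape).astype(float)
    beads[rng.random(beta.shape) < 0.005] = 1.0

    probe_ids = [f"cg{j:07d}" for j in range(n_probes)]
    ctrl_ids = [f"ctl{j:04d}" for j in range(config.n_control_probes)]
    rs_ids = [f"rs{j:06d}" for j in range(config.n_rs_probes)]

    iset = IntensitySet(
        meth=pd.DataFrame(meth, index=probe_ids, columns=samples),
        unmeth=pd.DataFrame(unmeth, index=probe_ids, columns=samples),
        detp=pd.DataFrame(detp, index=probe_ids, columns=samples),
        beadcount=pd.DataFrame(beads, index=probe_ids, columns=samples),
        control=pd.DataFrame(ctrl, index=ctrl_ids, columns=samples),
        rs_beta=pd.DataFrame(rs_beta, index=rs_ids, columns=samples),
    )

    rng = rngs["probe_params"]  # continue stream for annotation fields
    probe_type = rng.choice(["I_green", "I_red", "II"], size=n_probes, p=[0.15, 0.15, 0.7])
    maf = np.concatenate([
        np.minimum(p_anc, 1 - p_anc),
        rng.uniform(0.0, 0.5, config.n_nonsnp_probes),
    ])
    distance = np.concatenate([
        np.zeros(config.n_snp_probes, dtype=int),
        1000 + np.arange(config.n_nonsnp_probes),
    ])
    flags = [frozenset({"simulated"})] * config.n_snp_probes + [frozenset()] * config.n_nonsnp_probes
    annotation = ProbeAnnotation(
        table=pd.DataFrame(
            {
                "probe_type": probe_type,
                "snp_distance": distance,
                "maf": maf,
                "source_flags": flags,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        array=config.array,
    )

    meta = pd.DataFrame(
        {
            "individual_id": ind_of_sample,
            "sex": np.where(sex, "M", "F"),
            "age": age,
            "ancestry_label": group_of_sample,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    for k in range(config.n_cell_types):
        meta[f"cell_t{k + 1}"] = cell[:, k]
    for k in range(n_gt):
        meta[f"gtpc{k + 1}"] = gt_pcs[:, k]
    if config.phenotype_rate_by_group is not None:
        rng = rngs["phenotype"]
        rates = np.array([config.phenotype_rate_by_group[g] for g in group_of_sample])
        meta["phenotype"] = np.where(rng.random(n_samp) < rates, "case", "control")
    metadata = SampleMetadata(meta)

    truth = GroundTruth(
        true_genotypes=pd.DataFrame(geno, index=probe_ids[: config.n_snp_probes], columns=samples),
        rs_genotypes=pd.DataFrame(rs_geno, index=rs_ids, columns=samples),
        true_ancestry_axis=pd.Series(gt_pcs[:, 0], index=samples, name="ancestry_axis"),
        batch=pd.Series(batch, index=samples, name="batch"),
        tech_factors=pd.DataFrame(
            tech, index=[f"tech{f}" for f in range(config.n_tech_factors)], columns=samples
        ),
        individual_map=pd.Series(ind_of_sample, index=samples, name="individual_id"),
        group=pd.Series(group_of_sample, index=samples, name="group"),
    )
    return iset, metadata, annotation, truth


_SCENARIOS = ("clean", "batch_confounded", "covariate_correlated", "repeats")


def scenario(name: str, seed: int = 0) -> SimConfig:
    """Preset configurations for the four qualitative study regimes.

    ``clean``: randomized design, strong population structure, weak
    technical effects. ``batch_confounded``: batch effects dominate the raw
    beta variance (the regime where unadjusted ancestry PCs track batch, not
    ancestry). ``covariate_correlated``: batch and cell composition are
    partially aligned with ancestry, so residualization removes some true
    signal. ``repeats``: three samples per individual differing only by
    technical factors.
    """
    if name == "clean":
        return SimConfig(seed=seed)
    if name == "batch_confounded":
        return SimConfig(batch_effect=0.4, n_tech_factors=4, seed=seed)
    if name == "covariate_correlated":
        return SimConfig(
            batch_ancestry_cor=0.6,
            batch_effect=0.06,
            cell_ancestry_shift=0.4,
            seed=seed,
        )
    if name == "repeats":
        return SimConfig(
            groups={"EUR": 10, "AFR": 10},
            n_repeats=3,
            batch_effect=0.3,
            noise_sd=0.03,
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}; expected one of {_SCENARIOS}")
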