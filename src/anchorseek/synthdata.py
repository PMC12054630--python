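"""Synthetic dual-species single-cell data with a planted anchor-correlated program.

The generative model is a stand-in: the real studies reanalysed public data
whose distribution is unknown, so every distributional choice here (Gamma
latent stress score, log-normal library factors, negative-binomial counts)
is an explicit invention that merely produces the *structure* the pipeline
must detect — an anchor gene plus a planted co-regulated gene set whose
expression loads on a shared latent stress axis in one cell type, a partial
cross-species homolog map, and a clinical table in which a few covariates
truly track the target gene among many nulls.

Per cell i: latent stress s_i ~ Gamma(shape 2, scale stress_scale), shifted
up by ``stress_shift`` under the stressed condition; outside the stress cell
type s_i is fixed at its condition mean. Library factor L_i ~ LogNormal(0,
libsize_sigma). Per gene g: baseline log-mean beta_g ~ Uniform over
``baseline_logmean_range``; for the anchor and planted genes in stress-type
cells the log-mean is beta_g + effect_size * s_i. Counts are negative
binomial with mean L_i * exp(mu) and variance mean + dispersion * mean^2.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .preprocess import CountMatrix

_STAGE_CLINICAL = 1_000_003
_STAGE_HOMOLOGS = 1_000_019


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_cells_per_group: int = 250
    cell_types: tuple[str, ...] = ("CM", "FB", "EC")
    conditions: tuple[str, ...] = ("control", "stressed")
    anchor_id: str = "Nppa"
    n_planted: int = 30
    effect_size: float = 1.0
    stress_shift: float = 1.0
    stress_scale: float = 0.5
    baseline_logmean_range: tuple[float, float] = (-2.0, 1.0)
    dispersion: float | tuple[float, float] = 0.3
    libsize_sigma: float = 0.3
    homolog_fraction: float = 0.9
    n_subjects: int = 95
    n_covariates: int = 42
    n_true_covariates: int = 3
    covariate_effect: float = 1.0
    covariate_noise_sd: float = 0.5
    target_name: str = "SORBS2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_group < 1:
            raise ValueError("n_genes and n_cells_per_group must be >= 1")
        if self.n_planted < 0 or self.n_planted >= self.n_genes:
            raise ValueError("require 0 <= n_planted < n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.homolog_fraction <= 1.0:
            raise ValueError("homolog_fraction must be in [0, 1]")
        disp = self.dispersion
        vals = disp if isinstance(disp, (tuple, list)) else (disp,)
        if any(v <= 0 for v in vals):
            raise ValueError("dispersion must be > 0")
        if self.n_true_covariates > self.n_covariates:
            raise ValueError("n_true_covariates must be <= n_covariates")
        lo, hi = self.baseline_logmean_range
        if hi < lo:
            raise ValueError("baseline_logmean_range must be (low, high)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("cell_types", "conditions", "baseline_logmean_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "dispersion" in d and isinstance(d["dispersion"], list):
            d["dispersion"] = tuple(d["dispersion"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class GroundTruth:
    """Planted identities and latent variables recorded for test oracles."""

    anchor: dict[str, str] = field(default_factory=dict)
    planted_genes: dict[str, list[str]] = field(default_factory=dict)
    homolog_pairs: list[list[str]] = field(default_factory=list)
    stress_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    true_covariates: list[str] = field(default_factory=list)
    true_coefficients: dict[str, float] = field(default_factory=dict)

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(
            anchor={**self.anchor, **other.anchor},
            planted_genes={**self.planted_genes, **other.planted_genes},
            homolog_pairs=list(self.homolog_pairs) + list(other.homolog_pairs),
            stress_scores={**self.stress_scores, **other.stress_scores},
            true_covariates=self.true_covariates or other.true_covariates,
            true_coefficients={**self.true_coefficients, **other.true_coefficients},
        )
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _species_seed(master_seed: int, species_tag: str) -> np.random.Generator:
    key = zlib.crc32(species_tag.encode())
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(key,)))


def _gene_labels(config: SimulationConfig, uppercase: bool) -> list[str]:
    labels = [config.anchor_id] + [f"Gene{i:05d}" for i in range(1, config.n_genes)]
    if uppercase:
        labels = [l.upper() for l in labels]
    return labels


def simulate_species(
    config: SimulationConfig,
    species_tag: str,
    uppercase_labels: bool = False,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """One species' count matrix + cell metadata + ground truth.

    Deterministic given (config.seed, species_tag). Gene identities (which
    indices are anchor/planted) are fixed by the config alone so a second
    species shares the planted program while drawing independent noise.
    """
    rng = _species_seed(config.seed, species_tag)
    genes = _gene_labels(config, uppercase_labels)
    anchor = genes[0]
    planted = genes[1 : 1 + config.n_planted]
    stress_type = config.cell_types[0]

    # cell layout
    cell_types: list[str] = []
    conditions: list[str] = []
    for ct in config.cell_types:
        for cond in config.conditions:
            cell_types.extend([ct] * config.n_cells_per_group)
            conditions.extend([cond] * config.n_cells_per_group)
    n_cells = len(cell_types)
    barcodes = [f"{species_tag}_c{i:06d}" for i in range(n_cells)]
    is_stressed = np.array([c == "stressed" for c in conditions])
    in_stress_type = np.array([ct == stress_type for ct in cell_types])

    # latent stress score: Gamma draw inside the stress cell type, condition
    # mean elsewhere (no variation => no spurious correlation outside CM)
    base_mean = 2.0 * config.stress_scale
    s = rng.gamma(shape=2.0, scale=config.stress_scale, size=n_cells)
    s = s + np.where(is_stressed, config.stress_shift, 0.0)
    cond_mean = base_mean + np.where(is_stressed, config.stress_shift, 0.0)
    s = np.where(in_stress_type, s, cond_mean)

    lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_cells))

    lo, hi = config.baseline_logmean_range
    beta = rng.uniform(lo, hi, size=config.n_genes)
    if isinstance(config.dispersion, (tuple, list)):
        phi = rng.uniform(config.dispersion[0], config.dispersion[1], size=config.n_genes)
    else:
        phi = np.full(config.n_genes, float(config.dispersion))

    mu = np.exp(beta)[:, None] * lib[None, :]
    signal_rows = np.zeros(config.n_genes, dtype=bool)
    signal_rows[: 1 + config.n_planted] = True
    boost = np.exp(config.effect_size * s[in_stress_type])
    mu[np.ix_(signal_rows, in_stress_type)] *= boost[None, :]

    # NB(mean m, var m + phi m^2) via numpy's (n, p) parameterization
    n_param = (1.0 / phi)[:, None]
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param).astype(np.int32)
    x = sp.csr_matrix(counts)

    n_samples = 2  # nominal replicate structure within each condition
    sample_ids = [
        f"{species_tag}_{cond}_r{(i % n_samples) + 1}"
        for i, cond in enumerate(conditions)
    ]
    meta = pd.DataFrame(
        {
            "barcode": barcodes,
            "species": species_tag,
            "cell_type": cell_types,
            "condition": conditions,
            "sample": sample_ids,
        }
    )
    truth = GroundTruth(
        anchor={species_tag: anchor},
        planted_genes={species_tag: list(planted)},
        stress_scores={species_tag: {b: float(v) for b, v in zip(barcodes, s)}},
    )
    return CountMatrix(genes, barcodes, x), meta, truth


def simulate_pair(
    config: SimulationConfig,
    species_a: str = "mouse",
    species_b: str = "human",
) -> tuple[
    tuple[CountMatrix, pd.DataFrame],
    tuple[CountMatrix, pd.DataFrame],
    pd.DataFrame,
    GroundTruth,
]:
    """Two species with a shared planted program and a partial homolog map.

    Species-B gene labels are the uppercase transform of species-A labels
    (mouse->human symbol convention); each shared gene identity is linked in
    the homolog table independently with probability ``homolog_fraction``.
    """
    counts_a, meta_a, truth_a = simulate_species(config, species_a, uppercase_labels=False)
    counts_b, meta_b, truth_b = simulate_species(config, species_b, uppercase_labels=True)

    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STAGE_HOMOLOGS,))
    )
    linked = rng.random(config.n_genes) < config.homolog_fraction
    pairs = [
        [a, b]
        for a, b, keep in zip(counts_a.genes, counts_b.genes, linked)
        if keep
    ]
    homologs = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])

    truth = truth_a.merged_with(truth_b)
    truth.homolog_pairs = [list(p) for p in pairs]
    return (counts_a, meta_a), (counts_b, meta_b), homologs, truth


def simulate_clinical(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Subject table: target ~ Normal; true covariates = a*target + noise.

    Null covariates are independent standard normals. Which covariate slots
    carry signal is drawn from the seeded stream, so the true set's position
    among the nulls is not fixed.
    """
    if config.n_subjects < 10:
        raise ValueError(f"n_subjects must be >= 10, got {config.n_subjects}")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STAGE_CLINICAL,))
    )
    n, m = config.n_subjects, config.n_covariates
    y = rng.normal(size=n)
    cov_names = [f"cov{j + 1:02d}" for j in range(m)]
    true_idx = sorted(
        rng.choice(m, size=config.n_true_covariates, replace=False).tolist()
    )
    true_set = set(true_idx)
    data = {"subject_id": [f"s{i + 1:03d}" for i in range(n)]}
    coefs: dict[str, float] = {}
    for j, name in enumerate(cov_names):
        if j in true_set:
            data[name] = config.covariate_effect * y + rng.normal(
                0.0, config.covariate_noise_sd, size=n
            )
            coefs[name] = config.covariate_effect
        else:
            data[name] = rng.normal(size=n)
    data[config.target_name] = y
    table = pd.DataFrame(data)
    truth = GroundTruth(
        true_covariates=[cov_names[j] for j in true_idx],
        true_coefficients=coefs,
    )
    return table, truth


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> GroundTruth:
    """Run the full simulation and write all artifacts under ``out_dir``.

    Layout: species_a/ and species_b/ count bundles, homologs.tsv,
    clinical.tsv, truth.json.
    """
    from .io_formats import DatasetBundle, write_homolog_table, write_mtx_bundle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (ds_a, meta_a), (ds_b, meta_b), homologs, truth = simulate_pair(config)
    write_mtx_bundle(DatasetBundle(ds_a, meta_a, species="mouse"), out / "species_a")
    write_mtx_bundle(DatasetBundle(ds_b, meta_b, species="human"), out / "species_b")
    write_homolog_table(homologs, out / "homologs.tsv")
    clinical, truth_clin = simulate_clinical(config)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    truth = truth.merged_with(truth_clin)
    (out / "truth.json").write_text(truth.to_json() + "\n")
    return truth
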