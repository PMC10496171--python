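"""Configuration objects for the synthetic study generator and the pipeline.

The simulation emulates a two-species embryoid-body experiment: two species
(human, chimpanzee) x individuals x replicates x cell types of UMI counts,
with planted differential-expression motifs, random individual/replicate
effects, hybrid (tetraploid) cells whose allelic ratios encode planted cis
fractions, and a transcription-factor -> target network.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


def default_motif_matrix(k: int, c: int) -> np.ndarray:
    """A well-separated default motif matrix (K x C of DE probabilities).

    Motif 0 is the non-DE background, motif 1 is DE everywhere, remaining
    motifs are contiguous blocks of cell types (lineage-restricted DE).
    """
    q = np.full((k, c), 0.02)
    if k > 1:
        q[1] = 0.95
    for j in range(2, k):
        width = max(1, c // max(1, k - 2))
        start = ((j - 2) * width) % c
        q[j, start:start + width] = 0.95
    return q


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-species study.

    Defaults mirror the experimental design the package targets: 2 species x
    3 individuals x 3 replicates, negative-binomial UMI counts, log2 effect
    sizes with sd ``effect_sd``, and Beta-distributed per-gene cis fractions.
    """

    n_genes: int = 1000
    n_celltypes: int = 5
    n_individuals_per_species: int = 3
    n_replicates: int = 3
    n_cells_per_sample: int = 50
    K_motifs: int = 4
    motif_matrix: np.ndarray | None = None  # K x C; default built lazily
    motif_weights: np.ndarray | None = None  # K simplex; default ~ (0.4, rest)
    effect_sd: float = 1.75  # tau, log2 units; mean |beta| of DE genes ~ 1.4
    baseline_logmean_range: tuple[float, float] = (-3.0, 1.5)  # log10 UMI/cell
    nb_dispersion: float = 0.2  # phi; var = mu + phi mu^2
    indiv_sd: float = 0.15  # log2 units
    rep_sd: float = 0.10  # log2 units
    cis_alpha: float = 1.5  # Beta shape; mean cis fraction 0.3
    cis_beta: float = 3.5
    n_tfs: int = 0
    n_driver_tfs: int = 0
    targets_per_tf: int = 10
    driver_slope: float = 0.8  # alpha; target beta = alpha * TF beta + noise
    driver_noise_sd: float = 0.3
    inject_qc_failures: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_celltypes", "n_individuals_per_species",
                     "n_replicates", "n_cells_per_sample", "K_motifs"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.motif_matrix is None:
            self.motif_matrix = default_motif_matrix(self.K_motifs, self.n_celltypes)
        self.motif_matrix = np.asarray(self.motif_matrix, dtype=float)
        if self.motif_matrix.shape != (self.K_motifs, self.n_celltypes):
            raise ConfigError(
                f"motif_matrix must be {self.K_motifs} x {self.n_celltypes}, "
                f"got {self.motif_matrix.shape}")
        if np.any(self.motif_matrix < 0) or np.any(self.motif_matrix > 1):
            raise ConfigError("motif_matrix entries must lie in [0, 1]")
        if self.motif_weights is None:
            w = np.full(self.K_motifs, 0.6 / max(1, self.K_motifs - 1))
            w[0] = 0.4 if self.K_motifs > 1 else 1.0
            self.motif_weights = w
        self.motif_weights = np.asarray(self.motif_weights, dtype=float)
        if self.motif_weights.shape != (self.K_motifs,):
            raise ConfigError("motif_weights must have length K_motifs")
        if np.any(self.motif_weights < 0) or not math.isclose(
                float(self.motif_weights.sum()), 1.0, abs_tol=1e-12):
            raise ConfigError("motif_weights must be a simplex summing to 1")
        for name in ("effect_sd", "nb_dispersion", "indiv_sd", "rep_sd",
                     "cis_alpha", "cis_beta"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.n_driver_tfs > self.n_tfs:
            raise ConfigError("n_driver_tfs must be <= n_tfs")
        if self.n_tfs and self.targets_per_tf * self.n_tfs > self.n_genes:
            raise ConfigError(
                "targets_per_tf * n_tfs exceeds n_genes; not enough genes")

    # -- seed streams ------------------------------------------------------
    # One master seed; each stage draws from a named substream so stages are
    # reproducible independently of each other.
    _STREAMS = {"truth": 1, "species": 2, "hybrid": 3, "tf": 4, "psl": 5,
                "embedding": 6, "meta": 7}

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), self._STREAMS[stream]]))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motif_matrix"] = self.motif_matrix.tolist()
        d["motif_weights"] = self.motif_weights.tolist()
        d["baseline_logmean_range"] = list(self.baseline_logmean_range)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "motif_matrix" in d and d["motif_matrix"] is not None:
            d["motif_matrix"] = np.asarray(d["motif_matrix"], dtype=float)
        if "motif_weights" in d and d["motif_weights"] is not None:
            d["motif_weights"] = np.asarray(d["motif_weights"], dtype=float)
        if "baseline_logmean_range" in d:
            d["baseline_logmean_range"] = tuple(d["baseline_logmean_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end pipeline run.

    Holds the simulation config, stage toggles, the thresholds of every
    downstream rule (defaults are the analysis defaults), paths and the
    master seed.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "ebcomp_run"
    stages: tuple[str, ...] = (
        "simulate", "preprocess", "de", "cormotif", "cistrans", "tfdrivers")
    # preprocess
    min_genes_detected: int = 1000
    min_genes_detected_hybrid: int = 2000
    mito_low: float = 0.001
    mito_high: float = 0.2
    species_purity: float = 0.9
    min_cells_per_sample: int = 6  # samples with <= 5 cells are dropped
    min_cells_celltype: int = 5
    min_replicates_celltype: int = 2
    min_count: int = 5
    composition_pcs: int = 0
    # cormotif
    k_range: tuple[int, int] = (1, 6)
    n_starts: int = 10
    em_tol: float = 1e-6
    em_max_iter: int = 500
    de_posterior: float = 0.95
    # cistrans
    cis_hi: float = 0.75
    cis_lo: float = 0.25
    lowest_se_n: int = 1000
    # tfdrivers
    trans_cut: float = 0.75
    enrich_fdr: float = 0.05
    driver_fdr: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if not (0 <= self.mito_low < self.mito_high <= 1):
            raise ConfigError("require 0 <= mito_low < mito_high <= 1")
        if not (0 <= self.cis_lo < self.cis_hi <= 1):
            raise ConfigError("require 0 <= cis_lo < cis_hi <= 1")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ConfigError("k_range must be an increasing range with min >= 1")
        unknown_stages = set(self.stages) - {
            "simulate", "preprocess", "de", "cormotif", "cistrans", "tfdrivers"}
        if unknown_stages:
            raise ConfigError(f"unknown stages: {sorted(unknown_stages)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["stages"] = list(self.stages)
        d["k_range"] = list(self.k_range)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
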