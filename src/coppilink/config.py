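"""Configuration objects for the synthetic generator and the full pipeline.

All thresholds default to the published analysis values: TADA p < 0.05 for
de novo mutation (DNM) genes, genome-wide significance p < 5e-8 for common
variants (CVs), a +/-35 kb variant-to-gene window, RPKM > 1 in >= 1 sample
for expression calls, candidate filters r1 >= 1.2 and r2 > 0.1, a 0.5%
relative stop ratio for greedy growth, 10,000 randomization draws and 100
random-seed baseline subnetworks.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic input generator.

    The defaults emulate the scale of the reference analysis: a 10,314-node /
    51,637-edge protein-protein interaction (PPI) network, 12 spatiotemporal
    expression sites (3 developmental stages x 4 brain regions), and planted
    DNM/CV gene sets of 254 and 410 genes sharing 15 members.

    Parameters
    ----------
    coexpr_strength : float in [0, 1]
        Loading of the shared per-site latent factor for planted seed genes.
        The log-scale correlation between two planted genes equals
        ``coexpr_strength ** 2``.
    unexpressed_fraction : float in [0, 1)
        Per-site fraction of (non-planted) genes whose RPKM is forced <= 1 in
        every sample, so they fail the expression call at that site.
    planted_seed_genes : sequence of str, optional
        Genes sharing the planted co-expression module. ``None`` means "use
        the planted DNM/CV genes", which mirrors the seed genes of the
        subnetwork analysis being co-expressed.
    """

    n_genes: int = 10314
    n_edges: int = 51637
    n_sites: int = 12
    samples_per_site: int = 40
    planted_seed_genes: Optional[Sequence[str]] = None
    coexpr_strength: float = 0.5
    background_rpkm_logmean: float = 1.0
    background_rpkm_logsd: float = 1.0
    unexpressed_fraction: float = 0.25
    n_dnm_genes: int = 254
    n_cv_genes: int = 410
    n_overlap: int = 15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coexpr_strength <= 1.0):
            raise ValueError("coexpr_strength must be in [0, 1]")
        if not (0.0 <= self.unexpressed_fraction < 1.0):
            raise ValueError("unexpressed_fraction must be in [0, 1)")
        if self.background_rpkm_logsd <= 0:
            raise ValueError("background_rpkm_logsd must be positive")
        if self.n_overlap > min(self.n_dnm_genes, self.n_cv_genes):
            raise ValueError(
                "n_overlap cannot exceed min(n_dnm_genes, n_cv_genes)"
            )
        for name in ("n_genes", "n_edges", "n_sites", "samples_per_site",
                     "n_dnm_genes", "n_cv_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_overlap < 0:
            raise ValueError("n_overlap must be a non-negative count")


@dataclass
class Thresholds:
    """Every printed analysis threshold, in one flat block."""

    p_dnm: float = 0.05
    p_gwas: float = 5e-8
    window: int = 35000
    rpkm: float = 1.0
    min_samples: int = 1
    r1: float = 1.2
    r2: float = 0.1
    stop: float = 0.005
    n_perm: int = 10000
    n_baseline: int = 100

    def __post_init__(self) -> None:
        for name in ("p_dnm", "p_gwas", "window", "rpkm", "r1", "r2", "stop"):
            if getattr(self, name) <= 0 and name != "rpkm":
                raise ValueError(f"threshold {name} must be positive")
        if self.rpkm < 0:
            raise ValueError("rpkm threshold must be non-negative")
        for name in ("min_samples", "n_perm", "n_baseline"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Either ``inputs`` points at existing TSV artifacts (edge list, expression
    directory, DNM table, GWAS table, gene annotation) or — when a path is
    absent — the corresponding artifact is synthesized from ``synthetic``.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    inputs: dict = field(default_factory=dict)
    rng_seed: int = 0
    compute_betweenness: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        synth = SyntheticConfig(**raw.get("synthetic", {}))
        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(
            synthetic=synth,
            thresholds=thr,
            inputs=dict(raw.get("inputs", {})),
            rng_seed=int(raw.get("rng_seed", 0)),
            compute_betweenness=bool(raw.get("compute_betweenness", True)),
        )

    def to_dict(self) -> dict:
        out = asdict(self)
        if out["synthetic"]["planted_seed_genes"] is not None:
            out["synthetic"]["planted_seed_genes"] = list(
                out["synthetic"]["planted_seed_genes"]
            )
        return out
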