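"""Scenario configuration and the reproducible seeding scheme.

A :class:`ScenarioConfig` bundles every knob of the generative model: how many
tissues a gene is expressed in, how its eQTLs are split between tissue-specific
and multi-tissue effects, how strongly expression is genetically determined
(``h2_snp_expr``), how similar effect sizes are across tissues (``cor_tissue``),
and how strongly expression drives the trait (``r2_expr_trait``).

Randomness is organised around one master seed: every (replication, pair,
stage) triple maps to an independent child stream via
``numpy.random.SeedSequence(master, spawn_key=(rep, pair, stage))``, so any
single gene-trait pair can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigurationError, ParameterError

# default evaluation grids used by the benchmark harness
TISSUE_GRID = (1, 2, 5, 10)
MT_EQTL_GRID = (0, 6, 12, 18, 24)
COR_TISSUE_GRID = (0.0, 0.2, 0.4, 0.6, 0.8)
R2_TRAIT_GRID = (0.0, 0.00001, 0.0005, 0.005, 0.01)

# stage codes for the per-pair seeding scheme
STAGE_GENOTYPES = 0
STAGE_EFFECTS = 1
STAGE_EXPRESSION = 2
STAGE_TRAIT = 3
STAGE_CV_FOLDS = 4
STAGE_GBJ = 5
STAGE_CAUSAL_TISSUE = 6
STAGE_MIXTURE = 7


@dataclass(frozen=True)
class ScenarioConfig:
    """All parameters of one simulated genetic scenario.

    Parameters
    ----------
    n_tissues
        Number of tissues ``P`` the gene is expressed in.
    m_eqtl
        Total eQTLs per tissue (tissue-specific + multi-tissue).
    m_mt
        Number of multi-tissue eQTLs (effective in all ``P`` tissues).
        Must be 0 when ``n_tissues == 1``.
    m_null
        Non-eQTL SNPs carried along in the genotype panel.
    h2_snp_expr
        Proportion of expression variance explained by eQTLs.
    cor_tissue
        Cross-tissue correlation of multi-tissue eQTL effect sizes and of the
        non-genetic residual.
    r2_expr_trait
        Proportion of trait variance explained by the causal tissue's genetic
        expression component. 0 gives the null (no gene-trait signal).
    n_total, n_eqtl_train, n_twas
        Cohort sizes; the first ``n_eqtl_train`` individuals form the eQTL
        training split and the remaining ``n_twas`` the TWAS split.
    maf_range
        Uniform sampling interval for per-SNP minor allele frequencies,
        within (0, 0.5].
    n_pairs
        Gene-trait pairs per replication (one point estimate).
    n_reps
        Independent replications (distribution of the point estimate).
    fixed_effect
        If True (default) the expression-to-trait effect is ``sqrt(r2)``,
        giving traits whose heritability is exactly ``r2_expr_trait``; if
        False the effect is drawn once per pair from N(0, r2).
    seed
        Master seed for the scenario.
    """

    n_tissues: int = 5
    m_eqtl: int = 30
    m_mt: int = 0
    m_null: int = 30
    h2_snp_expr: float = 0.3
    cor_tissue: float = 0.0
    r2_expr_trait: float = 0.01
    n_total: int = 1500
    n_eqtl_train: int = 500
    n_twas: int = 1000
    maf_range: tuple = (0.01, 0.5)
    n_pairs: int = 100
    n_reps: int = 20
    fixed_effect: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_tissues < 1:
            raise ParameterError("n_tissues must be >= 1")
        if not (0 <= self.m_mt <= self.m_eqtl):
            raise ConfigurationError("m_mt must lie in [0, m_eqtl]")
        if self.n_tissues == 1 and self.m_mt != 0:
            raise ConfigurationError("a single-tissue gene has no multi-tissue eQTLs")
        if not (0.0 <= self.h2_snp_expr <= 1.0):
            raise ParameterError("h2_snp_expr must lie in [0, 1]")
        if not (0.0 <= self.r2_expr_trait < 1.0):
            raise ParameterError("r2_expr_trait must lie in [0, 1)")
        if not (0.0 <= self.cor_tissue < 1.0):
            raise ParameterError("cor_tissue must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must be contained in (0, 0.5]")
        if self.n_eqtl_train + self.n_twas != self.n_total:
            raise ConfigurationError(
                "n_eqtl_train + n_twas must equal n_total "
                f"({self.n_eqtl_train} + {self.n_twas} != {self.n_total})"
            )
        if min(self.n_total, self.m_eqtl) < 1:
            raise ParameterError("n_total and m_eqtl must be >= 1")

    @property
    def m_ts(self) -> int:
        """Tissue-specific eQTLs per tissue."""
        return self.m_eqtl - self.m_mt

    @property
    def n_snps(self) -> int:
        """Total genotype columns: one block of m_ts per tissue + shared + null."""
        return self.m_ts * self.n_tissues + self.m_mt + self.m_null

    def to_dict(self) -> dict:
        return asdict(self)


def child_rng(master_seed: int, rep: int = 0, pair: int = 0, stage: int = 0) -> np.random.Generator:
    """Independent generator for one (replication, pair, stage) triple."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(int(rep), int(pair), int(stage)))
    return np.random.default_rng(ss)
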