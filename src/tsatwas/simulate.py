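"""Generative model: genotypes -> eQTL effects -> multi-tissue expression -> trait.

One simulated gene is expressed in ``P`` tissues. Its genotype panel carries a
disjoint block of ``m_ts`` tissue-specific eQTL SNPs per tissue, ``m_mt``
multi-tissue eQTL SNPs shared by all tissues, and ``m_null`` non-eQTL SNPs.
Expression in tissue ``p`` is

    E[:, p] = X_ts(p) @ beta_ts[:, p] + X_mt @ beta_mt[:, p] + eps1[:, p]

with standardized genotypes, per-entry effect variance ``h2_snp_expr / m_eqtl``
(so each tissue's genetic variance totals ``h2_snp_expr``), multi-tissue effect
rows correlated at ``cor_tissue`` across tissues, and a residual with variance
``1 - h2_snp_expr`` and the same cross-tissue correlation. Each expression
column therefore has unit variance in expectation and the expected off-diagonal
correlation of E is ``cor_tissue * (h2 * m_mt / m_eqtl + 1 - h2)``.

The trait is generated on the TWAS split from the standardized genetic
component of one causal tissue: ``Y = g_std * b1 + eps2`` with
``Var(eps2) = 1 - r2_expr_trait``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .config import (
    STAGE_CAUSAL_TISSUE,
    STAGE_EFFECTS,
    STAGE_EXPRESSION,
    STAGE_GENOTYPES,
    STAGE_TRAIT,
    ScenarioConfig,
    child_rng,
)
from .exceptions import ParameterError, StructuralError


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _exchangeable_cov(p: int, diag: float, rho: float) -> np.ndarray:
    """P x P matrix with `diag` on the diagonal and rho*diag off it."""
    cov = np.full((p, p), rho * diag)
    np.fill_diagonal(cov, diag)
    return cov


@dataclass
class GenotypePanel:
    """Dosage matrix for one gene with its column layout and split labels.

    ``ts_cols[p]`` are the tissue-specific eQTL columns acting in tissue ``p``
    (disjoint across tissues), ``mt_cols`` the multi-tissue eQTL columns and
    ``null_cols`` the non-eQTL columns.
    """

    dosages: np.ndarray  # (N, M) int8 in {0, 1, 2}
    maf: np.ndarray  # (M,)
    n_train: int
    ts_cols: np.ndarray  # (P, m_ts) int
    mt_cols: np.ndarray  # (m_mt,) int
    null_cols: np.ndarray  # (m_null,) int
    snp_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.snp_ids:
            self.snp_ids = [f"snp{i}" for i in range(self.dosages.shape[1])]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def train_rows(self) -> slice:
        return slice(0, self.n_train)

    @property
    def twas_rows(self) -> slice:
        return slice(self.n_train, self.n_individuals)

    @cached_property
    def standardized(self) -> np.ndarray:
        """Column-wise mean-0, variance-1 view on the full panel.

        Training and TWAS splits deliberately reuse the full-panel moments so
        the two splits see the same linear map from dosages to features.
        Monomorphic columns are left at zero.
        """
        x = self.dosages.astype(np.float64)
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0.0] = 1.0
        return (x - mean) / sd


@dataclass
class EffectSet:
    """Realized eQTL effect sizes and the covariance blocks that drew them."""

    beta_ts: np.ndarray  # (m_ts, P)
    beta_mt: np.ndarray  # (m_mt, P)
    sigma_ts: np.ndarray  # (P, P), diagonal
    sigma_mt: np.ndarray  # (P, P), exchangeable


@dataclass
class ExpressionPanel:
    """Expression (E), its genetic component (G) and residual (eps1)."""

    expression: np.ndarray  # (N, P)
    genetic: np.ndarray  # (N, P)
    residual: np.ndarray  # (N, P)
    sigma_e: np.ndarray  # (P, P)
    n_train: int

    @property
    def n_tissues(self) -> int:
        return self.expression.shape[1]

    @property
    def train_rows(self) -> slice:
        return slice(0, self.n_train)

    @property
    def twas_rows(self) -> slice:
        return slice(self.n_train, self.expression.shape[0])


@dataclass
class TraitVector:
    """Standardized trait on the TWAS split plus the truth used to score it."""

    y: np.ndarray
    causal_tissue: int
    b1: float
    eps2: np.ndarray


def simulate_genotypes(config: ScenarioConfig, seed=None) -> GenotypePanel:
    """Draw per-SNP MAFs from U(maf_range) and dosages as Binomial(2, maf).

    Column layout: ``P`` disjoint blocks of ``m_ts`` tissue-specific eQTLs,
    then ``m_mt`` shared multi-tissue eQTLs, then ``m_null`` non-eQTL SNPs.
    Rows 0..n_eqtl_train-1 form the training split, the rest the TWAS split.
    """
    rng = _as_rng(seed if seed is not None else child_rng(config.seed, stage=STAGE_GENOTYPES))
    m = config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, maf, size=(config.n_total, m)).astype(np.int8)

    p, m_ts = config.n_tissues, config.m_ts
    ts_cols = np.arange(p * m_ts).reshape(p, m_ts)
    mt_cols = np.arange(p * m_ts, p * m_ts + config.m_mt)
    null_cols = np.arange(p * m_ts + config.m_mt, m)
    return GenotypePanel(
        dosages=dosages,
        maf=maf,
        n_train=config.n_eqtl_train,
        ts_cols=ts_cols,
        mt_cols=mt_cols,
        null_cols=null_cols,
    )


def draw_effects(config: ScenarioConfig, seed=None) -> EffectSet:
    """Draw tissue-specific and multi-tissue eQTL effect sizes.

    Per-entry variance is ``h2_snp_expr / m_eqtl`` for both kinds, so the
    genetic variance per tissue totals ``h2_snp_expr``; multi-tissue effect
    rows are multivariate normal with pairwise correlation ``cor_tissue``.
    """
    rng = _as_rng(seed if seed is not None else child_rng(config.seed, stage=STAGE_EFFECTS))
    p = config.n_tissues
    v = config.h2_snp_expr / config.m_eqtl
    sigma_ts = np.eye(p) * v
    sigma_mt = _exchangeable_cov(p, v, config.cor_tissue)

    beta_ts = rng.normal(0.0, np.sqrt(v), size=(config.m_ts, p))
    if config.m_mt > 0 and v > 0:
        chol = np.linalg.cholesky(sigma_mt)
        beta_mt = rng.standard_normal((config.m_mt, p)) @ chol.T
    else:
        beta_mt = np.zeros((config.m_mt, p))
    return EffectSet(beta_ts=beta_ts, beta_mt=beta_mt, sigma_ts=sigma_ts, sigma_mt=sigma_mt)


def simulate_expression(
    panel: GenotypePanel, effects: EffectSet, config: ScenarioConfig, seed=None
) -> ExpressionPanel:
    """Assemble E = G + eps1 on the full cohort.

    eps1 is multivariate normal with diagonal ``1 - h2_snp_expr`` and
    off-diagonal ``cor_tissue * (1 - h2_snp_expr)``.
    """
    p = config.n_tissues
    if effects.beta_ts.shape != (config.m_ts, p) or effects.beta_mt.shape != (config.m_mt, p):
        raise StructuralError("effect set dimensions do not match the configuration")
    if panel.n_snps != config.n_snps:
        raise StructuralError(
            f"genotype panel has {panel.n_snps} SNPs, configuration implies {config.n_snps}"
        )
    rng = _as_rng(seed if seed is not None else child_rng(config.seed, stage=STAGE_EXPRESSION))

    xs = panel.standardized
    genetic = np.empty((panel.n_individuals, p))
    for t in range(p):
        g = xs[:, panel.ts_cols[t]] @ effects.beta_ts[:, t]
        if config.m_mt > 0:
            g = g + xs[:, panel.mt_cols] @ effects.beta_mt[:, t]
        genetic[:, t] = g

    resid_var = 1.0 - config.h2_snp_expr
    sigma_e = _exchangeable_cov(p, resid_var, config.cor_tissue)
    if resid_var > 0:
        chol = np.linalg.cholesky(sigma_e)
        residual = rng.standard_normal((panel.n_individuals, p)) @ chol.T
    else:
        residual = np.zeros((panel.n_individuals, p))
    return ExpressionPanel(
        expression=genetic + residual,
        genetic=genetic,
        residual=residual,
        sigma_e=sigma_e,
        n_train=panel.n_train,
    )


def simulate_trait(
    expr: ExpressionPanel, config: ScenarioConfig, causal_tissue: int, seed=None
) -> TraitVector:
    """Trait on the TWAS split driven by one causal tissue's genetic component.

    ``Y = standardize(G[twas, causal]) * b1 + eps2`` with
    ``b1 = sqrt(r2_expr_trait)`` (or N(0, r2) when ``fixed_effect=False``) and
    ``Var(eps2) = 1 - r2_expr_trait``. With ``r2_expr_trait = 0`` the trait is
    pure noise, independent of the genetic component.
    """
    if not (0 <= causal_tissue < expr.n_tissues):
        raise ParameterError(f"causal_tissue must be in [0, {expr.n_tissues})")
    r2 = config.r2_expr_trait
    rng = _as_rng(seed if seed is not None else child_rng(config.seed, stage=STAGE_TRAIT))

    g = expr.genetic[expr.twas_rows, causal_tissue]
    sd = g.std()
    g_std = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)

    if r2 == 0.0:
        b1 = 0.0
    elif config.fixed_effect:
        b1 = float(np.sqrt(r2))
    else:
        b1 = float(rng.normal(0.0, np.sqrt(r2)))
    eps2 = rng.normal(0.0, np.sqrt(1.0 - r2), size=g.shape[0])
    return TraitVector(y=g_std * b1 + eps2, causal_tissue=causal_tissue, b1=b1, eps2=eps2)


def simulate_gene_trait_pair(config: ScenarioConfig, rep: int = 0, pair: int = 0):
    """One fully seeded gene-trait system: panel, effects, expression, trait.

    The causal tissue is drawn uniformly from its own seeded stream so the
    truth is reproducible per (rep, pair).
    """
    panel = simulate_genotypes(config, child_rng(config.seed, rep, pair, STAGE_GENOTYPES))
    effects = draw_effects(config, child_rng(config.seed, rep, pair, STAGE_EFFECTS))
    expr = simulate_expression(panel, effects, config, child_rng(config.seed, rep, pair, STAGE_EXPRESSION))
    causal = int(child_rng(config.seed, rep, pair, STAGE_CAUSAL_TISSUE).integers(config.n_tissues))
    trait = simulate_trait(expr, config, causal, child_rng(config.seed, rep, pair, STAGE_TRAIT))
    return panel, effects, expr, trait
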