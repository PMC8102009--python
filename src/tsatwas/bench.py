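"""Scenario runner and evaluation metrics: power, type I error, tissue FPR,
method comparisons, the mixed-gene-set experiment, and heritability recovery.

One *replication* simulates ``n_pairs`` independent gene-trait systems, trains
eQTL weights on the training split, imputes GReX and tests on the TWAS split,
and applies a Bonferroni rule. Power is the fraction of causal genes detected
(in the causal tissue for single-tissue tests; at gene level for cross-tissue
tests); under a null scenario (``r2_expr_trait = 0``) the same fraction is the
type I error. The tissue false-positive rate is, among significant
(gene, tissue) results of the single-tissue test, the fraction pointing at a
non-causal tissue.

The Bonferroni convention treats each simulated gene-trait pair as its own
test family: single-tissue tests use alpha / (number of tested tissues) and
cross-tissue tests use alpha. Dividing additionally by the number of pairs per
replication is available via ``BonferroniPolicy(genes="panel")``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import assoc_pc_regression, assoc_slr_all, zscores_from_slr
from .config import (
    STAGE_CV_FOLDS,
    STAGE_GBJ,
    STAGE_MIXTURE,
    ScenarioConfig,
    child_rng,
)
from .exceptions import ParameterError
from .gbj import assoc_gbj
from .simulate import (
    GenotypePanel,
    draw_effects,
    simulate_expression,
    simulate_gene_trait_pair,
    simulate_genotypes,
    simulate_trait,
)
from .weights import ElasticNetWeights, GroupLassoWeights, impute_grex

EQTL_METHODS = ("elastic_net", "group_lasso")
ASSOC_METHODS = ("slr", "pc_regression", "gbj")
DEFAULT_METHODS = (
    ("elastic_net", "slr"),
    ("group_lasso", "slr"),
    ("elastic_net", "pc_regression"),
    ("group_lasso", "gbj"),
)

# Scaled-down solver profile for large benchmark grids: a shorter penalty
# path (16 values over 1.5 decades), 3-fold CV and looser tolerances. On the
# default scenarios this reproduces the full-profile prediction accuracy to
# ~0.002 in GReX-truth correlation at a fraction of the cost.
FAST_TRAINER_OPTIONS = {
    "elastic_net": dict(tol=3e-3, n_alphas=16, alpha_eps=3e-2, cv=3),
    "group_lasso": dict(tol=3e-4, n_alphas=16, alpha_eps=3e-2, cv=3,
                        compute_cv_score=False),
}


@dataclass(frozen=True)
class BonferroniPolicy:
    """Multiple-testing rule applied when scoring significance.

    ``genes="pair"`` treats every simulated gene-trait pair as one family
    (denominator 1); ``genes="panel"`` divides by the number of pairs per
    replication as well. ``adjust_tissues`` divides single-tissue tests by the
    number of tissues actually tested for the gene.
    """

    alpha: float = 0.05
    genes: str = "pair"
    adjust_tissues: bool = True

    def _gene_denom(self, n_pairs: int) -> int:
        return n_pairs if self.genes == "panel" else 1

    def alpha_single(self, n_tissues_tested: int, n_pairs: int) -> float:
        denom = self._gene_denom(n_pairs) * (n_tissues_tested if self.adjust_tissues else 1)
        return self.alpha / max(denom, 1)

    def alpha_cross(self, n_pairs: int) -> float:
        return self.alpha / max(self._gene_denom(n_pairs), 1)


def _make_trainer(name: str, random_state: int, options=None):
    opts = dict((options or {}).get(name, {}))
    if name == "elastic_net":
        return ElasticNetWeights(random_state=random_state, **opts)
    if name == "group_lasso":
        return GroupLassoWeights(random_state=random_state, **opts)
    raise ParameterError(f"unknown eQTL method: {name!r}")


def _expression_label(config: ScenarioConfig) -> str:
    if config.n_tissues == 1:
        return "tissue_specific"
    if config.cor_tissue <= 0.4:
        return "differential"
    return "ubiquitous" if config.n_tissues == 10 else "similar"


def run_pair(config: ScenarioConfig, rep: int, pair: int, methods,
             policy: BonferroniPolicy, gbj_stages=(20_000, 100_000),
             gbj_max_draws=1_000_000, trainer_options=None) -> list:
    """Simulate one gene-trait pair and run the requested method combos.

    Returns flat record dicts (one per test, per tissue for slr).
    """
    panel, effects, expr, trait = simulate_gene_trait_pair(config, rep, pair)
    xs = panel.standardized
    train, twas = panel.train_rows, panel.twas_rows
    fold_seed = int(child_rng(config.seed, rep, pair, STAGE_CV_FOLDS).integers(2**31 - 1))

    eqtl_names = sorted({e for e, _ in methods})
    records = []
    for eqtl in eqtl_names:
        assoc_wanted = sorted({a for e, a in methods if e == eqtl})
        trainer = _make_trainer(eqtl, fold_seed, trainer_options)
        trainer.fit(xs[train], expr.expression[train])
        grex = impute_grex(trainer, panel, rows=twas)
        gene = f"rep{rep}_pair{pair}"

        slr_records = None
        if "slr" in assoc_wanted or "gbj" in assoc_wanted:
            slr_records = assoc_slr_all(grex, trait.y, gene=gene)

        def emit(rec, assoc_name, note_extra=""):
            records.append({
                "rep": rep, "pair": pair, "causal_tissue": f"tissue{trait.causal_tissue}",
                "eqtl_method": eqtl, "assoc_method": assoc_name,
                "tissue": rec.tissue, "n_tissues_tested": rec.n_tissues,
                "effect": rec.effect, "statistic": rec.statistic,
                "p_value": rec.p_value,
                "note": rec.note + note_extra,
            })

        for assoc_name in assoc_wanted:
            if assoc_name == "slr":
                for rec in slr_records:
                    emit(rec, "slr")
            elif assoc_name == "pc_regression":
                emit(assoc_pc_regression(grex, trait.y, gene=gene), "pc_regression")
            elif assoc_name == "gbj":
                zvec = zscores_from_slr(slr_records, grex)
                if len(zvec.z) >= 2:
                    rng = child_rng(config.seed, rep, pair, STAGE_GBJ)
                    rec = assoc_gbj(zvec, rng=rng,
                                    alpha_ref=policy.alpha_cross(config.n_pairs),
                                    stages=gbj_stages, max_draws=gbj_max_draws,
                                    gene=gene)
                    emit(rec, "gbj")
                elif len(zvec.z) == 1:
                    # TSA routing rule: a single expressed tissue goes to slr
                    only = [r for r in slr_records if r.testable][0]
                    emit(only, "gbj", note_extra=";routed_slr")
                else:
                    records.append({
                        "rep": rep, "pair": pair,
                        "causal_tissue": f"tissue{trait.causal_tissue}",
                        "eqtl_method": eqtl, "assoc_method": "gbj",
                        "tissue": "cross", "n_tissues_tested": 0,
                        "effect": np.nan, "statistic": np.nan, "p_value": np.nan,
                        "note": "not_testable",
                    })
            else:
                raise ParameterError(f"unknown association method: {assoc_name!r}")
    return records


def _score_rep(rec: pd.DataFrame, config: ScenarioConfig, policy: BonferroniPolicy) -> dict:
    """Power (or type I error) and tissue FPRs for one (method, rep) block."""
    is_null = config.r2_expr_trait == 0.0
    assoc_name = rec["assoc_method"].iloc[0]
    out = {}
    if assoc_name == "slr":
        hits = []
        for _, grp in rec.groupby("pair", sort=False):
            tested = grp[grp["p_value"].notna()]
            if tested.empty:
                hits.append(False)
                continue
            a = policy.alpha_single(int(tested["n_tissues_tested"].iloc[0]), config.n_pairs)
            sig = tested[tested["p_value"] < a]
            if is_null:
                hits.append(len(sig) > 0)
            else:
                causal = grp["causal_tissue"].iloc[0]
                hits.append((sig["tissue"] == causal).any())
        out["value"] = float(np.mean(hits))
        out["tissue_fpr_adj"] = tissue_fpr(rec, policy.alpha, adjust_tissues=True,
                                           genes=policy.genes, n_pairs=config.n_pairs)
        out["tissue_fpr_unadj"] = tissue_fpr(rec, policy.alpha, adjust_tissues=False,
                                             genes=policy.genes, n_pairs=config.n_pairs)
    else:
        a = policy.alpha_cross(config.n_pairs)
        per_pair = rec.dropna(subset=["p_value"]).groupby("pair")["p_value"].min()
        n_sig = int((per_pair < a).sum())
        out["value"] = n_sig / max(rec["pair"].nunique(), 1)
        out["tissue_fpr_adj"] = np.nan
        out["tissue_fpr_unadj"] = np.nan
    out["metric"] = "type1" if is_null else "power"
    return out


def run_scenario(config: ScenarioConfig, methods=DEFAULT_METHODS, seed=None,
                 policy: BonferroniPolicy | None = None,
                 gbj_stages=(20_000, 100_000), gbj_max_draws=1_000_000,
                 trainer_options=None, collect_records=False):
    """Run all replications of one scenario for the requested method combos.

    Returns a performance table (one row per method combo per replication)
    and, if ``collect_records``, the flat per-test record table as well.
    Deterministic for a fixed (config, seed).
    """
    if seed is not None:
        config = ScenarioConfig(**{**config.to_dict(), "seed": int(seed)})
    policy = policy or BonferroniPolicy()
    methods = [tuple(m) for m in methods]
    for e, a in methods:
        if e not in EQTL_METHODS or a not in ASSOC_METHODS:
            raise ParameterError(f"unknown method combination: {(e, a)!r}")

    all_records = []
    for rep in range(config.n_reps):
        for pair in range(config.n_pairs):
            all_records.extend(run_pair(config, rep, pair, methods, policy,
                                        gbj_stages, gbj_max_draws, trainer_options))
    rec = pd.DataFrame(all_records)

    rows = []
    label = _expression_label(config)
    for (eqtl, assoc_name) in methods:
        sub = rec[(rec["eqtl_method"] == eqtl) & (rec["assoc_method"] == assoc_name)]
        for rep, grp in sub.groupby("rep", sort=True):
            scored = _score_rep(grp, config, policy)
            rows.append({
                "n_tissues": config.n_tissues, "m_mt": config.m_mt,
                "cor_tissue": config.cor_tissue, "r2_expr_trait": config.r2_expr_trait,
                "expression_label": label,
                "eqtl_method": eqtl, "assoc_method": assoc_name, "rep": rep,
                "metric": scored["metric"], "value": scored["value"],
                "tissue_fpr_adj": scored["tissue_fpr_adj"],
                "tissue_fpr_unadj": scored["tissue_fpr_unadj"],
                "n_pairs": config.n_pairs,
                "alpha_single": policy.alpha_single(config.n_tissues, config.n_pairs),
                "alpha_cross": policy.alpha_cross(config.n_pairs),
            })
    perf = pd.DataFrame(rows)
    return (perf, rec) if collect_records else perf


def tissue_fpr(records, alpha: float = 0.05, adjust_tissues: bool = True,
               genes: str = "pair", n_pairs: int | None = None):
    """Among significant (gene, tissue) single-tissue results, the fraction in
    non-causal tissues. Returns NaN when nothing is significant."""
    rec = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records
    rec = rec[(rec["assoc_method"] == "slr") & rec["p_value"].notna()]
    if rec.empty:
        return np.nan
    n_pairs = n_pairs if n_pairs is not None else rec["pair"].nunique()
    gene_denom = n_pairs if genes == "panel" else 1
    denom = rec["n_tissues_tested"].clip(lower=1) if adjust_tissues else 1
    thresh = alpha / (gene_denom * denom)
    sig = rec[rec["p_value"] < thresh]
    if sig.empty:
        return np.nan
    return float((sig["tissue"] != sig["causal_tissue"]).mean())


def compare_methods(perf_a, perf_b) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired per-replication rates.

    Exact distribution for n <= 25 (when ties permit), normal approximation
    with continuity correction otherwise. All-zero differences return p = 1
    with a degenerate flag.
    """
    a = np.asarray(perf_a, dtype=np.float64)
    b = np.asarray(perf_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError("paired vectors must have equal length")
    diff = a - b
    if np.all(diff == 0.0):
        return {"p_value": 1.0, "difference": 0.0, "degenerate": True}
    method = "exact" if len(diff) <= 25 else "approx"
    try:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True, method=method)
    except ValueError:
        res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True, method="approx")
    return {"p_value": float(res.pvalue), "difference": float(np.mean(diff)),
            "degenerate": False}


def run_mixture_experiment(proportions, config: ScenarioConfig, seed=None,
                           policy: BonferroniPolicy | None = None,
                           gbj_stages=(20_000, 100_000), gbj_max_draws=1_000_000,
                           trainer_options=None):
    """Power of pure single-tissue, pure cross-tissue and TSA-routed strategies
    on gene sets mixing tissue-specific (P=1) and multi-tissue genes.

    At each proportion, that fraction of the ``n_pairs`` genes per replication
    is simulated as tissue-specific; the rest follow ``config``. Strategies:

    * ``single``: elastic net + per-tissue SLR on every gene (causal-tissue
      success, tissue-adjusted Bonferroni).
    * ``cross``: group lasso + GBJ; genes whose weight model is expressed in
      fewer than two tissues cannot be tested and count as misses.
    * ``tsa``: route by expressed-tissue count — one tissue to elastic
      net + SLR, more than one to group lasso + GBJ.
    """
    if seed is not None:
        config = ScenarioConfig(**{**config.to_dict(), "seed": int(seed)})
    policy = policy or BonferroniPolicy()
    base = config.to_dict()
    single_cfg = ScenarioConfig(**{**base, "n_tissues": 1, "m_mt": 0})

    rows = []
    for prop in proportions:
        if not (0.0 <= prop <= 1.0):
            raise ParameterError("proportions must lie in [0, 1]")
        hits = {"single": [], "cross": [], "tsa": []}
        for rep in range(config.n_reps):
            n_single = int(round(prop * config.n_pairs))
            order = child_rng(config.seed, rep, 0, STAGE_MIXTURE).permutation(config.n_pairs)
            is_single = np.zeros(config.n_pairs, dtype=bool)
            is_single[order[:n_single]] = True
            for pair in range(config.n_pairs):
                cfg = single_cfg if is_single[pair] else config
                recs = pd.DataFrame(run_pair(
                    cfg, rep, pair,
                    [("elastic_net", "slr"), ("group_lasso", "gbj")],
                    policy, gbj_stages, gbj_max_draws, trainer_options))
                causal = recs["causal_tissue"].iloc[0]
                slr = recs[(recs["eqtl_method"] == "elastic_net")
                           & (recs["assoc_method"] == "slr")
                           & recs["p_value"].notna()]
                gbj_rec = recs[(recs["eqtl_method"] == "group_lasso")
                               & (recs["assoc_method"] == "gbj")]

                if slr.empty:
                    single_hit = False
                else:
                    a1 = policy.alpha_single(int(slr["n_tissues_tested"].iloc[0]),
                                             config.n_pairs)
                    single_hit = bool(((slr["p_value"] < a1)
                                       & (slr["tissue"] == causal)).any())

                routed = (gbj_rec["note"].str.contains("routed_slr")).any()
                g_p = gbj_rec["p_value"].iloc[0] if len(gbj_rec) else np.nan
                a_cross = policy.alpha_cross(config.n_pairs)
                gbj_hit = bool(np.isfinite(g_p) and g_p < a_cross)
                cross_hit = gbj_hit and not routed  # pure cross cannot test 1-tissue genes
                tsa_hit = gbj_hit if not routed else False
                if routed:
                    # TSA sends the single-expressed gene to elastic-net SLR
                    tsa_hit = single_hit if slr["n_tissues_tested"].iloc[0] == 1 else bool(
                        ((slr["p_value"] < a_cross) & (slr["tissue"] == causal)).any())
                hits["single"].append(single_hit)
                hits["cross"].append(cross_hit)
                hits["tsa"].append(tsa_hit)
        for strategy, h in hits.items():
            rows.append({"proportion_single": prop, "strategy": strategy,
                         "power": float(np.mean(h)), "n": len(h)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heritability recovery
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    h2: float
    sigma_g: float
    sigma_e: float
    converged: bool
    n_iter: int
    loglik: float


@dataclass
class HeritabilityRun:
    """Per-replicate heritability estimates and their grand summary."""

    table: pd.DataFrame  # one row per (maf_range, r2, genotype replicate)
    summary: pd.DataFrame  # mean / s.e. per (maf_range, r2)
    n_failed: int = 0


def _reml_two_component(eigvals, uty, ut1, tol=1e-8, max_iter=200, floor=1e-10):
    """REML for y ~ N(mu*1, sigma_g*K + sigma_e*I) via expected-information
    scoring in the eigenbasis of K."""
    n = eigvals.shape[0]
    yc = uty - ut1 * (ut1 @ uty) / (ut1 @ ut1)
    var_y = float(yc @ yc) / (n - 1)
    sg, se = 0.5 * var_y, 0.5 * var_y
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v = sg * eigvals + se
        a = 1.0 / v
        au1 = a * ut1
        c = float(ut1 @ au1)
        q = float(au1 @ uty) / c
        py = a * uty - q * au1
        ll = -0.5 * (np.log(v).sum() + np.log(c) + float(uty @ py))

        def tr_p(m):
            return float((a * m).sum() - (au1 * au1 * m).sum() / c)

        bb = au1 / np.sqrt(c)

        def tr_pmpm(m1, m2):
            t1 = float((a * a * m1 * m2).sum())
            t2 = float((bb * bb * a * m1 * m2).sum())
            t3 = float((bb * bb * m1).sum()) * float((bb * bb * m2).sum())
            return t1 - 2.0 * t2 + t3

        w1 = eigvals
        ones = np.ones(n)
        score = 0.5 * np.array([
            float(py @ (w1 * py)) - tr_p(w1),
            float(py @ py) - tr_p(ones),
        ])
        info = 0.5 * np.array([
            [tr_pmpm(w1, w1), tr_pmpm(w1, ones)],
            [tr_pmpm(w1, ones), tr_pmpm(ones, ones)],
        ])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = score / max(np.diag(info).max(), 1.0)
        # damped update with the variance floor
        scale = 1.0
        for _ in range(30):
            cand = np.maximum(np.array([sg, se]) + scale * step, floor)
            vv = cand[0] * eigvals + cand[1]
            if np.all(vv > 0):
                break
            scale *= 0.5
        sg, se = float(cand[0]), float(cand[1])
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    h2 = sg / (sg + se)
    return HeritabilityEstimate(h2=float(h2), sigma_g=sg, sigma_e=se,
                                converged=converged, n_iter=it, loglik=float(ll_prev))


def estimate_heritability(genotypes, trait, tol=1e-8, max_iter=200) -> HeritabilityEstimate:
    """Single-component REML heritability with GRM K = ZZ'/M from
    standardized SNPs."""
    if isinstance(genotypes, GenotypePanel):
        z = genotypes.standardized
    else:
        z = np.asarray(genotypes, dtype=np.float64)
    y = np.asarray(trait, dtype=np.float64)
    if z.shape[0] != y.shape[0]:
        raise ParameterError("genotypes and trait have different lengths")
    if y.shape[0] < 50:
        raise ParameterError("heritability estimation needs at least 50 individuals")
    k = z @ z.T / z.shape[1]
    w, u = np.linalg.eigh(k)
    w = np.clip(w, 0.0, None)
    return _reml_two_component(w, u.T @ y, u.T @ np.ones(y.shape[0]),
                               tol=tol, max_iter=max_iter)


def run_heritability_study(seed: int = 0, n_individuals: int = 5000,
                           n_traits: int = 50, n_geno_reps: int = 30,
                           m_eqtl: int = 30, m_null: int = 30,
                           h2_snp_expr: float = 0.3,
                           maf_ranges=((0.01, 0.5), (0.01, 0.2), (0.01, 0.05)),
                           r2_levels=(0.0, 0.01, 0.02, 0.05),
                           fixed_effect: bool = True) -> HeritabilityRun:
    """Monte-Carlo heritability recovery across MAF regimes and signal levels.

    Each genotype replicate simulates one single-tissue gene (``m_eqtl`` eQTL
    + ``m_null`` null SNPs, expression heritability ``h2_snp_expr``), then
    generates ``n_traits`` traits from its genetic component at each
    ``r2_expr_trait`` level and averages the per-trait REML estimates. The GRM
    uses all simulated SNPs. Non-converged REML fits are excluded and counted.
    """
    rows = []
    n_failed = 0
    for mi, maf_range in enumerate(maf_ranges):
        for ri, r2 in enumerate(r2_levels):
            base = ScenarioConfig(
                n_tissues=1, m_mt=0, m_eqtl=m_eqtl, m_null=m_null,
                h2_snp_expr=h2_snp_expr, r2_expr_trait=r2,
                n_total=n_individuals, n_eqtl_train=0, n_twas=n_individuals,
                maf_range=tuple(maf_range), fixed_effect=fixed_effect,
                seed=int(seed),
            )
            for g in range(n_geno_reps):
                pair_id = (mi * len(r2_levels) + ri) * 10_000 + g
                panel = simulate_genotypes(base, child_rng(seed, g, pair_id, 0))
                effects = draw_effects(base, child_rng(seed, g, pair_id, 1))
                expr = simulate_expression(panel, effects, base,
                                           child_rng(seed, g, pair_id, 2))
                z = panel.standardized
                k = z @ z.T / z.shape[1]
                w, u = np.linalg.eigh(k)
                w = np.clip(w, 0.0, None)
                ut1 = u.T @ np.ones(n_individuals)
                ests = []
                for t in range(n_traits):
                    trait = simulate_trait(expr, base, 0,
                                           child_rng(seed, g, pair_id, 10 + t))
                    est = _reml_two_component(w, u.T @ trait.y, ut1)
                    if est.converged:
                        ests.append(est.h2)
                    else:
                        n_failed += 1
                rows.append({"maf_lo": maf_range[0], "maf_hi": maf_range[1],
                             "r2_expr_trait": r2, "geno_rep": g,
                             "h2_mean": float(np.mean(ests)) if ests else np.nan,
                             "n_traits_used": len(ests)})
    table = pd.DataFrame(rows)
    summary = (table.groupby(["maf_lo", "maf_hi", "r2_expr_trait"])["h2_mean"]
               .agg(["mean", "sem", "count"]).reset_index()
               .rename(columns={"mean": "h2", "sem": "se"}))
    return HeritabilityRun(table=table, summary=summary, n_failed=n_failed)
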