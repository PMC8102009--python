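"""Tissue-specificity-aware TWAS (TSA-TWAS) on user-supplied inputs.

The framework routes each gene by the number of tissues in which it has a
genetically regulated expression (GReX) model: genes expressed in exactly one
tissue get the single-tissue regression, genes expressed in more than one
tissue get the cross-tissue GBJ omnibus test. Inputs are a flat weight table
(gene, snp, ref, alt, tissue, weight), a dosage matrix (TSV, or VCF with a
dosage FORMAT field), a phenotype table with one or more continuous traits,
and an optional covariate table. Every record is annotated against the
supplied Bonferroni thresholds.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AssociationRecord, assoc_slr, estimate_z_correlation, zscores_from_slr
from .exceptions import ParameterError, StructuralError
from .gbj import assoc_gbj
from .weights import GrexPanel, read_weights

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ThresholdSpec:
    """A Bonferroni threshold: alpha divided by the mode's denominators.

    ``method_wise`` divides by (genes tested by this method) x (traits);
    ``family_wise`` divides by (all genes) x (traits). ``n_tissues`` is an
    optional extra denominator for per-tissue accounting.
    """

    alpha: float = 0.05
    n_genes: int = 1
    n_traits: int = 1
    n_tissues: int = 1
    mode: str = "method_wise"
    name: str = ""

    def __post_init__(self):
        if min(self.n_genes, self.n_traits, self.n_tissues) < 1:
            raise ParameterError("threshold denominators must be >= 1")
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")


def bonferroni_threshold(spec: ThresholdSpec) -> float:
    """Exact rational division alpha / (genes * traits * tissues)."""
    return spec.alpha / (spec.n_genes * spec.n_traits * spec.n_tissues)


def classify_genes(weights: pd.DataFrame):
    """Per-gene tissue count and test route from a weight table.

    Route is ``slr`` for genes with nonzero weights in exactly one tissue and
    ``gbj`` for more; genes with no nonzero weight anywhere are excluded (with
    a reason), not an error.
    """
    w = weights[weights["weight"] != 0.0]
    counts = w.groupby("gene_id")["tissue"].nunique()
    table = pd.DataFrame({
        "gene_id": counts.index,
        "n_tissues": counts.values,
        "route": np.where(counts.values == 1, "slr", "gbj"),
    })
    excluded = sorted(set(weights["gene_id"]) - set(counts.index))
    excluded = pd.DataFrame({"gene_id": excluded, "reason": "no nonzero weights"})
    return table.reset_index(drop=True), excluded


@dataclass
class AppliedStudy:
    """User-supplied inputs for an applied TSA-TWAS run."""

    weights: pd.DataFrame  # gene_id, snp_id, ref, alt, tissue, weight
    dosages: pd.DataFrame  # index snp_id, columns: ref, alt, then samples
    phenotypes: pd.DataFrame  # index sample, one column per trait
    covariates: pd.DataFrame | None = None
    dropped_snps: dict = field(default_factory=dict)


def read_dosages_tsv(path) -> pd.DataFrame:
    """Dosage TSV: rows SNPs with columns snp_id, ref, alt, then one column
    per sample holding expected alternate-allele dosage in [0, 2]."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "ref": str, "alt": str})
    missing = {"snp_id", "ref", "alt"} - set(df.columns)
    if missing:
        raise StructuralError(f"dosage table is missing columns: {sorted(missing)}")
    return df.set_index("snp_id")


def read_dosages_vcf(path, dosage_field: str = "DS") -> pd.DataFrame:
    """Read dosages from a VCF using the given FORMAT field (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF dosages requires the optional cyvcf2 dependency") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for var in vcf:
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        ds = var.format(dosage_field)
        if ds is None:
            ds = np.asarray(var.gt_types, dtype=float)
            ds[ds == 2] = np.nan  # unknown
            ds[ds == 3] = 2.0
        rows.append([snp_id, var.REF, var.ALT[0]] + list(np.asarray(ds).ravel()[: len(samples)]))
    df = pd.DataFrame(rows, columns=["snp_id", "ref", "alt"] + samples)
    return df.set_index("snp_id")


def _align_weights(gene_w: pd.DataFrame, dosages: pd.DataFrame):
    """Match weight rows to dosage rows on (snp_id, ref, alt).

    Allele-swapped entries get negated weights; strand-complement matches are
    kept; palindromic (strand-ambiguous) SNPs that only match by complement
    are dropped, as are SNPs absent from the dosage table. Returns
    (snp_ids, signs, drop counts).
    """
    kept, signs = [], []
    dropped = {"missing": 0, "allele_mismatch": 0, "ambiguous_strand": 0}
    for _, row in gene_w.iterrows():
        sid = row["snp_id"]
        if sid not in dosages.index:
            dropped["missing"] += 1
            continue
        ref, alt = dosages.loc[sid, "ref"], dosages.loc[sid, "alt"]
        wr, wa = row["ref"], row["alt"]
        palindromic = _COMPLEMENT.get(wr) == wa
        if (wr, wa) == (ref, alt):
            sign = 1.0  # palindromic exact matches assume shared strand
        elif palindromic:
            # any reorientation of an A/T or C/G SNP is strand-ambiguous
            dropped["ambiguous_strand"] += 1
            continue
        elif (wr, wa) == (alt, ref):
            sign = -1.0
        elif (_COMPLEMENT.get(wr), _COMPLEMENT.get(wa)) == (ref, alt):
            sign = 1.0
        elif (_COMPLEMENT.get(wr), _COMPLEMENT.get(wa)) == (alt, ref):
            sign = -1.0
        else:
            dropped["allele_mismatch"] += 1
            continue
        kept.append(sid)
        signs.append(sign)
    return kept, np.asarray(signs), dropped


def impute_grex_from_weights(weights: pd.DataFrame, dosages: pd.DataFrame,
                             samples) -> tuple[dict, dict]:
    """Per-gene GReX panels from a weight table and dosage matrix.

    Missing dosage values are mean-imputed per SNP; dosage columns are used as
    given (weights from flat files are on the dosage scale).
    """
    panels = {}
    all_dropped = {}
    sample_cols = list(samples)
    for gene, gw in weights[weights["weight"] != 0.0].groupby("gene_id"):
        tissues = sorted(gw["tissue"].unique())
        grex = np.zeros((len(sample_cols), len(tissues)))
        mask = np.zeros(len(tissues), dtype=bool)
        gene_dropped = {"missing": 0, "allele_mismatch": 0, "ambiguous_strand": 0}
        for ti, tissue in enumerate(tissues):
            tw = gw[gw["tissue"] == tissue]
            kept, signs, dropped = _align_weights(tw, dosages)
            for k, v in dropped.items():
                gene_dropped[k] += v
            if not kept:
                continue
            x = dosages.loc[kept, sample_cols].to_numpy(dtype=float).T
            col_mean = np.nanmean(x, axis=0)
            inds = np.where(np.isnan(x))
            if inds[0].size:
                x[inds] = np.take(col_mean, inds[1])
            w = tw.set_index("snp_id").loc[kept, "weight"].to_numpy() * signs
            grex[:, ti] = x @ w
            mask[ti] = True
        panels[gene] = GrexPanel(grex=grex, mask=mask, method="applied",
                                 tissues=list(tissues))
        all_dropped[gene] = gene_dropped
    return panels, all_dropped


def run_tsa_twas(study: AppliedStudy, thresholds=None, seed: int = 0,
                 gbj_stages=(20_000, 100_000), gbj_max_draws=1_000_000) -> pd.DataFrame:
    """Run the TSA-TWAS framework over every trait in the study.

    Steps per trait: impute GReX per gene and tissue, classify genes by
    expressed-tissue count, run the routed test (SLR with covariates for
    single-tissue genes; per-tissue SLR feeding GBJ for multi-tissue genes),
    and annotate each record against every supplied threshold.
    """
    thresholds = list(thresholds or [ThresholdSpec(name="alpha")])
    samples = study.phenotypes.index
    missing = [s for s in samples if s not in study.dosages.columns]
    if missing:
        raise StructuralError(f"samples missing from dosage table: {missing[:5]}")
    panels, dropped = impute_grex_from_weights(study.weights, study.dosages, samples)
    study.dropped_snps = dropped

    covar = None
    if study.covariates is not None:
        covar = study.covariates.loc[samples].to_numpy(dtype=float)

    rows = []
    for trait_name in study.phenotypes.columns:
        y = study.phenotypes[trait_name].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if not ok.any():
            continue  # trait with no usable values is skipped
        cv = covar[ok] if covar is not None else None
        for gene, panel in sorted(panels.items()):
            n_expr = int(panel.mask.sum())
            if n_expr == 0:
                continue
            sub = GrexPanel(grex=panel.grex[ok], mask=panel.mask,
                            method=panel.method, tissues=panel.tissues)
            if n_expr == 1:
                t_idx = int(np.nonzero(panel.mask)[0][0])
                rec = assoc_slr(sub.grex[:, t_idx], y[ok], cv, gene=gene,
                                tissue=panel.tissues[t_idx], n_tissues=1)
            else:
                slr_recs = [
                    assoc_slr(sub.grex[:, t], y[ok], cv, gene=gene,
                              tissue=panel.tissues[t], n_tissues=n_expr)
                    for t in np.nonzero(panel.mask)[0]
                ]
                zvec = zscores_from_slr(slr_recs, sub)
                if len(zvec.z) >= 2:
                    # per-gene stream: identical traits yield identical p-values
                    gene_key = zlib.crc32(gene.encode())
                    rng = np.random.default_rng(
                        np.random.SeedSequence(int(seed), spawn_key=(gene_key,)))
                    rec = assoc_gbj(zvec, rng=rng, stages=gbj_stages,
                                    max_draws=gbj_max_draws, gene=gene)
                elif len(zvec.z) == 1:
                    rec = [r for r in slr_recs if r.testable][0]
                else:
                    rec = AssociationRecord(gene, "gbj", "cross", 0,
                                            np.nan, np.nan, np.nan, "not_testable")
            row = {"trait": trait_name, "gene_id": gene, "method": rec.method,
                   "tissue": rec.tissue, "n_tissues": rec.n_tissues,
                   "effect": rec.effect, "statistic": rec.statistic,
                   "p_value": rec.p_value, "note": rec.note}
            for spec in thresholds:
                label = spec.name or spec.mode
                row[f"sig_{label}"] = bool(np.isfinite(rec.p_value)
                                           and rec.p_value < bonferroni_threshold(spec))
            rows.append(row)
    return pd.DataFrame(rows)


def load_study(weights_path, dosages_path, pheno_path, covar_path=None,
               vcf: bool = False) -> AppliedStudy:
    """Assemble an :class:`AppliedStudy` from flat files."""
    weights = read_weights(weights_path)
    dosages = read_dosages_vcf(dosages_path) if vcf else read_dosages_tsv(dosages_path)
    pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)
    covar = pd.read_csv(covar_path, sep="\t", index_col=0) if covar_path else None
    return AppliedStudy(weights=weights, dosages=dosages, phenotypes=pheno,
                        covariates=covar)
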