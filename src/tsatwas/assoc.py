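"""Gene-trait association engines.

Three tests link imputed GReX to a trait:

* :func:`assoc_slr` — per-tissue ordinary least squares of the trait on one
  tissue's GReX (plus covariates), two-sided p from the t statistic.
* :func:`assoc_pc_regression` — joint F test on the retained principal
  components of the standardized multi-tissue GReX matrix; components are kept
  while the largest-to-current eigenvalue ratio stays below a condition
  threshold.
* the Generalized Berk-Jones omnibus test in :mod:`tsatwas.gbj`, fed by
  :func:`zscores_from_slr` which converts per-tissue regressions into signed
  z scores plus the estimated correlation among them.

Covariates are handled by residualizing trait and GReX on them once (with an
intercept), which is equivalent under OLS to including them in each
regression; degrees of freedom are adjusted accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .exceptions import StructuralError
from .weights import GrexPanel

NOT_TESTABLE = "not_testable"
_P_MIN = 1e-300  # floor before the normal-quantile transform


@dataclass
class AssociationRecord:
    """One test result: per-tissue for slr, one per gene for cross-tissue."""

    gene: str
    method: str  # slr | pc_regression | gbj
    tissue: object  # tissue label for slr, "cross" otherwise
    n_tissues: int
    effect: float
    statistic: float
    p_value: float
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.note != NOT_TESTABLE and np.isfinite(self.p_value)


@dataclass
class ZVector:
    """Per-tissue z statistics for one gene and their estimated correlation."""

    z: np.ndarray
    corr: np.ndarray
    tissues: list
    dropped: list = field(default_factory=list)
    collapsed: list = field(default_factory=list)


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, dtype=np.float64)
    if c.ndim == 1:
        c = c[:, None]
    return np.column_stack([np.ones(n), c])


def residualize(values, covariates) -> tuple[np.ndarray, int]:
    """Residuals of ``values`` on [1, covariates]; returns (residuals, rank used)."""
    v = np.asarray(values, dtype=np.float64)
    d = _design(v.shape[0], covariates)
    coef, *_ = np.linalg.lstsq(d, v, rcond=None)
    return v - d @ coef, int(np.linalg.matrix_rank(d))


def assoc_slr(grex_column, trait, covariates=None, gene: str = "gene",
              tissue="tissue0", n_tissues: int = 1) -> AssociationRecord:
    """OLS of trait on one tissue's GReX; two-sided p from the t statistic.

    A zero-variance (or masked-out) GReX column yields a not-testable record
    with a NaN p-value, never p = 0.
    """
    g = np.asarray(grex_column, dtype=np.float64)
    y = np.asarray(trait, dtype=np.float64)
    if g.shape[0] != y.shape[0]:
        raise StructuralError("GReX and trait have different lengths")
    if not np.all(np.isfinite(g)) or g.var() == 0.0:
        return AssociationRecord(gene, "slr", tissue, n_tissues,
                                 np.nan, np.nan, np.nan, NOT_TESTABLE)
    g_res, k = residualize(g, covariates)
    y_res, _ = residualize(y, covariates)
    n = y.shape[0]
    df = n - k - 1
    sxx = g_res @ g_res
    beta = (g_res @ y_res) / sxx
    resid = y_res - beta * g_res
    sigma2 = (resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    t = beta / se if se > 0 else np.inf * np.sign(beta)
    p = 2.0 * stats.t.sf(abs(t), df)
    return AssociationRecord(gene, "slr", tissue, n_tissues,
                             float(beta), float(t), float(p))


def assoc_slr_all(grex: GrexPanel, trait, covariates=None, gene: str = "gene"):
    """Per-tissue SLR records for every imputable tissue of a GReX panel."""
    records = []
    n_tissues = int(grex.mask.sum())
    for t, label in enumerate(grex.tissues):
        if not grex.mask[t]:
            records.append(AssociationRecord(gene, "slr", label, n_tissues,
                                             np.nan, np.nan, np.nan, NOT_TESTABLE))
            continue
        records.append(assoc_slr(grex.grex[:, t], trait, covariates,
                                 gene=gene, tissue=label, n_tissues=n_tissues))
    return records


def assoc_pc_regression(grex, trait, covariates=None, condition_threshold: float = 30.0,
                        gene: str = "gene") -> AssociationRecord:
    """Principal-component regression across tissues with a joint F test.

    The standardized GReX matrix is decomposed into principal components;
    components are retained while (largest eigenvalue / component eigenvalue)
    <= ``condition_threshold``. The trait (residualized on covariates) is then
    regressed on the retained components and the p-value comes from the joint
    F test of those components.
    """
    if isinstance(grex, GrexPanel):
        x = grex.grex[:, grex.mask]
    else:
        x = np.asarray(grex, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
    y = np.asarray(trait, dtype=np.float64)
    n = y.shape[0]
    if x.shape[0] != n:
        raise StructuralError("GReX and trait have different lengths")
    sd = x.std(axis=0) if x.size else np.array([])
    x = x[:, sd > 0]
    n_tissues = x.shape[1]
    if n_tissues == 0:
        return AssociationRecord(gene, "pc_regression", "cross", 0,
                                 np.nan, np.nan, np.nan, NOT_TESTABLE)
    xs = (x - x.mean(axis=0)) / x.std(axis=0)
    u, s, _ = np.linalg.svd(xs, full_matrices=False)
    eig = s**2
    keep = np.zeros(eig.shape[0], dtype=bool)
    positive = eig > eig[0] * 1e-12
    keep[positive] = (eig[0] / eig[positive]) <= condition_threshold
    q = int(keep.sum())
    if q == 0:
        return AssociationRecord(gene, "pc_regression", "cross", n_tissues,
                                 np.nan, np.nan, np.nan, NOT_TESTABLE)
    y_res, k = residualize(y, covariates)
    pcs = u[:, keep]  # orthonormal columns spanning the retained components
    pcs_res, _ = residualize(pcs, covariates) if covariates is not None else (pcs, 1)
    coef, *_ = np.linalg.lstsq(pcs_res, y_res, rcond=None)
    fitted = pcs_res @ coef
    rss1 = float((y_res - fitted) @ (y_res - fitted))
    rss0 = float(y_res @ y_res)
    df2 = n - k - q
    f = ((rss0 - rss1) / q) / (rss1 / df2)
    p = stats.f.sf(f, q, df2)
    return AssociationRecord(gene, "pc_regression", "cross", n_tissues,
                             np.nan, float(f), float(p),
                             note=f"components={q}")


def estimate_z_correlation(grex_columns: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Correlation among per-tissue statistics, from the GReX regressors.

    Sample correlation of the imputed GReX columns, symmetrized and repaired
    to be positive semi-definite (eigenvalues clipped at ``eps``) with a unit
    diagonal.
    """
    r = np.corrcoef(grex_columns, rowvar=False)
    r = np.atleast_2d(r)
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    if w.min() < eps:
        w = np.clip(w, eps, None)
        r = (v * w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
    return r


def zscores_from_slr(records, grex: GrexPanel, dedup_tol: float = 1e-10) -> ZVector:
    """Signed normal-quantile z per tissue plus the estimated correlation.

    Not-testable tissues are dropped and recorded; exactly duplicated tissues
    (|r| = 1 within tolerance) are collapsed to one representative before the
    omnibus test, and the collapse is recorded.
    """
    testable = [r for r in records if r.method == "slr" and r.testable]
    dropped = [r.tissue for r in records if r.method == "slr" and not r.testable]
    if not testable:
        return ZVector(z=np.array([]), corr=np.empty((0, 0)), tissues=[], dropped=dropped)
    labels = [r.tissue for r in testable]
    idx = [grex.tissues.index(t) for t in labels]
    cols = grex.grex[:, idx]
    p = np.clip(np.array([r.p_value for r in testable]), _P_MIN, 1.0)
    sign = np.sign([r.effect for r in testable])
    sign[sign == 0] = 1.0
    z = -ndtri(p / 2.0) * sign

    # duplicates are detected on the raw correlation, before the PSD repair
    raw = np.atleast_2d(np.corrcoef(cols, rowvar=False))
    collapsed = []
    keep = []
    for i in range(len(labels)):
        dup = next((j for j in keep if abs(raw[i, j]) >= 1.0 - dedup_tol), None)
        if dup is None:
            keep.append(i)
        else:
            collapsed.append((labels[i], labels[dup]))
    if collapsed:
        z = z[keep]
        cols = cols[:, keep]
        labels = [labels[i] for i in keep]
    corr = estimate_z_correlation(cols)
    return ZVector(z=z, corr=corr, tissues=labels, dropped=dropped, collapsed=collapsed)
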