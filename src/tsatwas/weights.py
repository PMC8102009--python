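"""eQTL weight training and GReX imputation.

Two trainers produce an M x P SNP-to-expression weight matrix from the
training split:

* :class:`ElasticNetWeights` — one independent elastic-net fit per tissue
  (the single-tissue convention), penalty chosen by K-fold cross-validation
  over a log-spaced path.
* :class:`GroupLassoWeights` — one joint fit across tissues with a group
  penalty on each SNP's cross-tissue weight row, so a SNP enters either all
  tissues or none (the integrative-tissue convention).

Both are scikit-learn estimators: ``fit(X, E)`` then ``predict(X)`` returns the
genetically regulated expression (GReX), i.e. ``X @ W_``. A tissue whose
cross-validated optimum is the empty model is flagged unexpressed in
``expressed_mask_``; that mask is what drives single- versus cross-tissue
routing downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, MultiTaskLasso, MultiTaskLassoCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConvergenceError, StructuralError
from .simulate import ExpressionPanel, GenotypePanel


def _expression_matrix(expression) -> np.ndarray:
    if isinstance(expression, ExpressionPanel):
        return expression.expression
    e = np.asarray(expression, dtype=np.float64)
    return e[:, None] if e.ndim == 1 else e


def _folds(n_splits: int, random_state) -> KFold:
    # seeded shuffled folds; passing the same random_state to both trainers
    # yields identical fold assignment for paired method comparisons
    return KFold(n_splits=n_splits, shuffle=True, random_state=random_state)


class ElasticNetWeights(BaseEstimator):
    """Per-tissue elastic-net eQTL weights with cross-validated penalty.

    Parameters
    ----------
    l1_ratio : float, default 0.5
        Mixing between lasso (1.0) and ridge (0.0) penalties.
    n_alphas : int, default 50
        Penalty path length, log-spaced from the data-derived maximum.
    alpha_eps : float, default 1e-3
        Ratio of the smallest to largest penalty on the path (3 decades).
    cv : int, default 5
        Number of cross-validation folds (seeded shuffled K-fold).
    random_state : int or None
        Seeds the fold assignment.
    """

    method = "elastic_net"

    def __init__(self, l1_ratio=0.5, n_alphas=50, alpha_eps=1e-3, cv=5,
                 tol=1e-4, max_iter=3000, random_state=None):
        self.l1_ratio = l1_ratio
        self.n_alphas = n_alphas
        self.alpha_eps = alpha_eps
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, E):
        """Fit one penalized regression per tissue on the training split.

        Tissues with constant expression, or whose CV-optimal model keeps no
        SNP, are flagged unexpressed rather than raising.
        """
        X = np.asarray(X, dtype=np.float64)
        E = _expression_matrix(E)
        n, m = X.shape
        p = E.shape[1]
        w = np.zeros((m, p))
        scores = np.full(p, np.nan)
        alphas = np.full(p, np.nan)
        folds = _folds(self.cv, self.random_state)
        for t in range(p):
            y = E[:, t]
            var_y = y.var()
            if var_y == 0.0:
                continue
            model = ElasticNetCV(
                l1_ratio=self.l1_ratio,
                alphas=self.n_alphas,
                eps=self.alpha_eps,
                cv=folds,
                tol=self.tol,
                max_iter=self.max_iter,
                n_jobs=None,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X, y)
            w[:, t] = model.coef_
            alphas[t] = model.alpha_
            idx = int(np.argmin(model.mse_path_.mean(axis=-1)))
            scores[t] = 1.0 - model.mse_path_.mean(axis=-1)[idx] / var_y
        self.W_ = w
        self.alpha_ = alphas
        self.cv_score_ = scores
        self.expressed_mask_ = np.any(w != 0.0, axis=0)
        self.n_features_in_ = m
        return self

    def predict(self, X) -> np.ndarray:
        """Impute GReX: standardized dosages times the weight matrix."""
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise StructuralError(
                f"genotypes have {X.shape[1]} SNPs, model was trained on {self.n_features_in_}"
            )
        return X @ self.W_


class GroupLassoWeights(BaseEstimator):
    """Joint cross-tissue weights with a group penalty per SNP row.

    Minimizes ``sum_p ||E_p - X w_p||^2 / (2n) + alpha * sum_j ||W[j, :]||_2``
    so each SNP's weights across tissues are jointly zero or jointly active.
    With a single tissue this reduces exactly to the lasso. The penalty is
    chosen by K-fold cross-validation over a log-spaced path.
    """

    method = "group_lasso"

    def __init__(self, n_alphas=50, alpha_eps=1e-3, cv=5,
                 tol=1e-6, max_iter=10000, random_state=None,
                 compute_cv_score=True):
        self.n_alphas = n_alphas
        self.alpha_eps = alpha_eps
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.compute_cv_score = compute_cv_score

    def fit(self, X, E):
        X = np.asarray(X, dtype=np.float64)
        E = _expression_matrix(E)
        n, m = X.shape
        p = E.shape[1]
        live = E.var(axis=0) > 0.0
        w = np.zeros((m, p))
        scores = np.full(p, np.nan)
        self.alpha_ = np.nan
        if live.any():
            e_live = E[:, live]
            folds = _folds(self.cv, self.random_state)
            model = MultiTaskLassoCV(
                alphas=self.n_alphas,
                eps=self.alpha_eps,
                cv=folds,
                tol=self.tol,
                max_iter=self.max_iter,
                n_jobs=None,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                model.fit(X, e_live)
            final = [wmsg for wmsg in caught
                     if issubclass(wmsg.category, ConvergenceWarning)]
            gap = getattr(model, "dual_gap_", None)
            if final and gap is not None and gap > 10 * self.tol * max(1, n):
                raise ConvergenceError(
                    f"group lasso did not converge within {self.max_iter} sweeps",
                    gap=float(gap),
                )
            w[:, live] = model.coef_.T
            self.alpha_ = float(model.alpha_)
            if self.compute_cv_score:
                scores[live] = self._per_tissue_cv_score(X, e_live, folds)
        self.W_ = w
        self.cv_score_ = scores
        self.expressed_mask_ = np.any(w != 0.0, axis=0)
        self.n_features_in_ = m
        return self

    def _per_tissue_cv_score(self, X, E, folds) -> np.ndarray:
        """Held-out R^2 per tissue at the selected joint penalty."""
        press = np.zeros(E.shape[1])
        for train, test in folds.split(X):
            refit = MultiTaskLasso(alpha=self.alpha_, tol=self.tol, max_iter=self.max_iter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                refit.fit(X[train], E[train])
            press += ((E[test] - refit.predict(X[test])) ** 2).sum(axis=0)
        return 1.0 - press / (E.shape[0] * E.var(axis=0))

    def predict(self, X) -> np.ndarray:
        """Impute GReX: standardized dosages times the weight matrix."""
        check_is_fitted(self, "W_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise StructuralError(
                f"genotypes have {X.shape[1]} SNPs, model was trained on {self.n_features_in_}"
            )
        return X @ self.W_


@dataclass
class GrexPanel:
    """Imputed genetically regulated expression with provenance."""

    grex: np.ndarray  # (n, P)
    mask: np.ndarray  # (P,) bool, imputable tissues
    method: str
    tissues: list = field(default_factory=list)

    def __post_init__(self):
        if not self.tissues:
            self.tissues = [f"tissue{t}" for t in range(self.grex.shape[1])]


def impute_grex(model, genotypes, rows=None) -> GrexPanel:
    """GReX = standardized dosages @ W, restricted to ``rows`` if given.

    ``genotypes`` may be a :class:`GenotypePanel` (its full-panel standardized
    view is used) or an already-standardized matrix.
    """
    if isinstance(genotypes, GenotypePanel):
        x = genotypes.standardized
    else:
        x = np.asarray(genotypes, dtype=np.float64)
    if rows is not None:
        x = x[rows]
    grex = model.predict(x)
    mask = np.asarray(model.expressed_mask_, dtype=bool)
    grex = np.where(mask[None, :], grex, np.nan)
    return GrexPanel(grex=grex, mask=mask, method=model.method)


def weights_to_table(model, gene_id: str, snp_ids, tissues=None,
                     ref=None, alt=None) -> pd.DataFrame:
    """Flatten a fitted weight model to the flat-file weight-table layout.

    One row per nonzero (snp, tissue) weight with columns
    gene_id, snp_id, ref, alt, tissue, weight.
    """
    check_is_fitted(model, "W_")
    w = model.W_
    m, p = w.shape
    if len(snp_ids) != m:
        raise StructuralError("snp_ids length does not match the weight matrix")
    tissues = list(tissues) if tissues is not None else [f"tissue{t}" for t in range(p)]
    ref = list(ref) if ref is not None else ["A"] * m
    alt = list(alt) if alt is not None else ["G"] * m
    rows = []
    for j, t in zip(*np.nonzero(w)):
        rows.append((gene_id, snp_ids[j], ref[j], alt[j], tissues[t], w[j, t]))
    return pd.DataFrame(rows, columns=["gene_id", "snp_id", "ref", "alt", "tissue", "weight"])


def write_weights(table: pd.DataFrame, path) -> None:
    """Write a weight table as TSV, losslessly for nonzero weights."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"gene_id": str, "snp_id": str,
                            "ref": str, "alt": str, "tissue": str})
    missing = {"gene_id", "snp_id", "ref", "alt", "tissue", "weight"} - set(df.columns)
    if missing:
        raise StructuralError(f"weight table is missing columns: {sorted(missing)}")
    return df
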