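"""Generalized Berk-Jones omnibus test for correlated per-tissue z statistics.

The statistic orders |z| descending and, for each rank k, contrasts the
observed count of exceedances beyond the k-th largest |z| with its null
expectation under the correlated multivariate normal. The exceedance count
S(t) = #{|Z_j| >= t} has null mean d*pi0(t) (pi0 = two-sided normal tail) and a
variance inflated by the pairwise correlations (computed from bivariate normal
orthant probabilities via Owen's T function). S(t) is moment-matched to an
extended beta-binomial, and the k-th objective is the log likelihood ratio of
the observed count under the matched alternative versus the null. The
statistic is the maximum over k, restricted to the rejection region
(ranks where the observed exceedance fraction beats its null expectation).

Two p-value evaluators are provided:

* ``mc`` (default): seeded Monte Carlo from N(0, R) with decision-directed
  escalation of the number of draws.
* ``analytic``: exact boundary-crossing computation for exchangeable
  correlation (single-factor decomposition, Gauss-Hermite integration over the
  shared factor, and an order-statistic dynamic program); a general R is
  approximated by its mean off-diagonal equicorrelation.

P-values are floored at 1e-15, the documented precision floor of the test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, ndtr, ndtri, owens_t

from .assoc import AssociationRecord, ZVector
from .exceptions import SingleTissueError, StructuralError

P_FLOOR = 1e-15
_T_MAX = 38.0  # |z| beyond this is numerically indistinguishable from infinity


def _log_pi0(t):
    """log P(|Z| >= t) for standard normal Z, stable for large t."""
    return np.log(2.0) + log_ndtr(-np.asarray(t, dtype=np.float64))


def _abs_pair_tail(t, r):
    """P(|Z_i| >= t, |Z_j| >= t) for a bivariate normal with correlation r.

    Uses the Owen's-T expression for the equal-threshold bivariate CDF:
    Phi2(t, t; rho) = Phi(t) - 2 T(t, sqrt((1 - rho) / (1 + rho))).
    """
    t = np.asarray(t, dtype=np.float64)
    r = np.clip(np.asarray(r, dtype=np.float64), -0.9999999, 0.9999999)
    t, r = np.broadcast_arrays(t, r)

    def upper(t_, rho):
        a = np.sqrt((1.0 - rho) / (1.0 + rho))
        phi2 = ndtr(t_) - 2.0 * owens_t(t_, a)
        return 1.0 - 2.0 * ndtr(t_) + phi2

    out = 2.0 * (upper(t, r) + upper(t, -r))
    return np.clip(out, 0.0, 1.0)


def _ebb_gamma(pi0, var, d):
    """Dispersion of the moment-matched extended beta-binomial.

    rho = (var / (d p (1-p)) - 1) / (d - 1); gamma = rho / (1 - rho).
    Underdispersion is clipped to the binomial (gamma = 0).
    """
    denom = d * pi0 * (1.0 - pi0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (var / np.where(denom > 0, denom, 1.0) - 1.0) / (d - 1), 0.0)
    rho = np.clip(rho, 0.0, 0.999)
    return rho / (1.0 - rho)


def _ebb_loglik(s, d, lam, gamma, log_lam=None):
    """Log of the EBB kernel (binomial coefficient omitted; it cancels in ratios).

    sum_{j<s} log(lam + gamma j) + sum_{j<d-s} log(1 - lam + gamma j)
    - sum_{j<d} log(1 + gamma j)
    """
    lam = np.asarray(lam, dtype=np.float64)
    gamma = np.asarray(gamma, dtype=np.float64)
    out = np.zeros(np.broadcast_shapes(lam.shape, gamma.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        for j in range(s):
            if j == 0 and log_lam is not None:
                out = out + log_lam
            else:
                out = out + np.log(lam + gamma * j)
        for j in range(d - s):
            # lam -> 1 makes this -inf; callers mask that region out
            out = out + np.log1p(-lam + gamma * j)
        for j in range(d):
            out = out - np.log1p(gamma * j)
    return out


def _objective_all_k(t_desc, d, log_pi0_fn, pairsum_fn):
    """GBJ objective for every rank k given the sorted |z| (descending).

    ``t_desc`` may be (d,) or (B, d). Returns the same leading shape with a
    trailing k axis.
    """
    t = np.atleast_2d(np.asarray(t_desc, dtype=np.float64))
    b = t.shape[0]
    obj = np.zeros((b, d))
    for k in range(1, d + 1):
        tk = np.clip(t[:, k - 1], 0.0, _T_MAX)
        log_p0 = log_pi0_fn(tk)
        pi0 = np.exp(log_p0)
        pairsum = pairsum_fn(tk)
        var = d * pi0 * (1.0 - pi0) + (pairsum - d * (d - 1) * pi0**2)
        var = np.maximum(var, 0.0)
        lam1 = k / d
        in_region = lam1 > pi0
        if d > 1:
            gamma = _ebb_gamma(pi0, var, d)
        else:
            gamma = np.zeros_like(pi0)
        ll_alt = _ebb_loglik(k, d, np.full_like(pi0, lam1), gamma)
        ll_null = _ebb_loglik(k, d, pi0, gamma, log_lam=log_p0)
        obj[:, k - 1] = np.where(in_region, ll_alt - ll_null, 0.0)
    return obj if np.asarray(t_desc).ndim == 2 else obj[0]


def _exact_moment_fns(corr):
    """Exact per-threshold moment callables for one correlation matrix."""
    d = corr.shape[0]
    iu = np.triu_indices(d, 1)
    roff = corr[iu]

    def pairsum(t):
        t = np.atleast_1d(t)
        if d == 1 or roff.size == 0:
            return np.zeros_like(t)
        a = _abs_pair_tail(t[:, None], roff[None, :])
        return 2.0 * a.sum(axis=1)

    return _log_pi0, pairsum


class _MomentTable:
    """Interpolated moments on a t grid, for fast vectorized Monte Carlo."""

    def __init__(self, corr, t_hi=9.0, n_grid=361):
        self.t_hi = t_hi
        self.grid = np.linspace(0.0, t_hi, n_grid)
        self.log_pi0_grid = _log_pi0(self.grid)
        _, pairsum = _exact_moment_fns(corr)
        ps = pairsum(self.grid)
        self.log_ps_grid = np.log(np.maximum(ps, 1e-320))
        self.has_pairs = corr.shape[0] > 1

    def log_pi0(self, t):
        t = np.minimum(t, self.t_hi)
        return np.interp(t, self.grid, self.log_pi0_grid)

    def pairsum(self, t):
        if not self.has_pairs:
            return np.zeros_like(np.atleast_1d(t))
        t = np.minimum(t, self.t_hi)
        return np.exp(np.interp(t, self.grid, self.log_ps_grid))


def gbj_statistic(z, corr):
    """Observed GBJ statistic (exact moments) and the per-rank objectives."""
    z = np.asarray(z, dtype=np.float64)
    d = z.shape[0]
    if d < 2:
        raise SingleTissueError(
            "the GBJ test needs at least two tissues; route single-tissue genes to slr"
        )
    corr = np.asarray(corr, dtype=np.float64)
    if corr.shape != (d, d):
        raise StructuralError("correlation matrix does not match the z vector")
    if np.linalg.eigvalsh(corr).min() < -1e-6:
        raise StructuralError("correlation matrix is not positive semi-definite after repair")
    t_desc = np.sort(np.abs(z))[::-1]
    log_pi0_fn, pairsum_fn = _exact_moment_fns(corr)
    obj = _objective_all_k(t_desc, d, log_pi0_fn, pairsum_fn)
    return float(obj.max()), obj


def _mc_pvalue(stat, corr, rng, stages, alpha_ref, chunk=50_000):
    """Monte-Carlo tail probability of the statistic under N(0, corr).

    Escalates through ``stages`` cumulative draw counts; stops early once 200
    exceedances are seen or, when ``alpha_ref`` is given, once the 99.9%
    interval for p excludes it.
    """
    d = corr.shape[0]
    w, v = np.linalg.eigh(corr)
    l = v * np.sqrt(np.clip(w, 0.0, None))
    table = _MomentTable(corr)
    exceed = 0
    done = 0
    for target in stages:
        while done < target:
            b = int(min(chunk, target - done))
            zdraw = rng.standard_normal((b, d)) @ l.T
            t_desc = -np.sort(-np.abs(zdraw), axis=1)
            obj = _objective_all_k(t_desc, d, table.log_pi0, table.pairsum)
            exceed += int((obj.max(axis=1) >= stat - 1e-12).sum())
            done += b
        p_hat = (1 + exceed) / (1 + done)
        if exceed >= 100:
            break
        if alpha_ref is not None:
            se = np.sqrt(max(p_hat * (1 - p_hat), 1e-300) / done)
            if abs(p_hat - alpha_ref) > 3.3 * se:
                break
    return max(min(p_hat, 1.0), P_FLOOR), done


def _solve_boundaries(stat, d, log_pi0_fn, pairsum_fn):
    """Per-rank thresholds b_k with objective_k(b_k) = stat (inf if unreachable)."""
    bounds = np.full(d, np.inf)
    for k in range(1, d + 1):
        t_lo = float(-ndtri(k / (2.0 * d)))  # objective_k = 0 at or below this
        t_lo = max(t_lo, 0.0)
        t_hi = _T_MAX

        def f(t, k=k):
            return _objective_all_k(np.array([[t] * d]), d, log_pi0_fn, pairsum_fn)[0, k - 1] - stat

        # objective_k only depends on the k-th entry; a constant row isolates it
        if f(t_hi) < 0:
            continue
        lo, hi = t_lo, t_hi
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        bounds[k - 1] = hi
    return bounds


def _noncrossing_prob(bounds, d, rho):
    """P(no rank k has |Z|_(k) >= b_k) under exchangeable correlation rho.

    Conditions on the shared factor (Gauss-Hermite, 80 nodes); conditionally
    the |Z_i| are iid and the crossing probability follows from a dynamic
    program over exceedance counts at the sorted boundary levels.
    """
    finite = np.isfinite(bounds)
    if not finite.any():
        return 1.0
    levels = []
    for k in np.nonzero(finite)[0]:
        levels.append((bounds[k], k))  # cap: at most k exceedances beyond b_k (k is 0-based rank)
    levels.sort(key=lambda x: -x[0])
    # merge equal thresholds, keeping the tightest cap
    merged = []
    for b, cap in levels:
        if merged and abs(merged[-1][0] - b) < 1e-13:
            merged[-1] = (merged[-1][0], min(merged[-1][1], cap))
        else:
            merged.append((b, cap))

    rho = float(np.clip(rho, 0.0, 0.999))
    a, s = np.sqrt(rho), np.sqrt(1.0 - rho)
    nodes, wts = np.polynomial.hermite_e.hermegauss(80)
    wts = wts / np.sqrt(2.0 * np.pi)

    total = 0.0
    ks = np.arange(d + 1)
    for x, wt in zip(nodes, wts):
        tails = np.array([ndtr((-b - a * x) / s) + ndtr(-(b - a * x) / s) for b, _ in merged])
        probs = np.zeros(d + 1)
        probs[0] = 1.0
        prev_tail = 0.0
        ok = True
        for (b, cap), q in zip(merged, tails):
            step = (q - prev_tail) / (1.0 - prev_tail) if prev_tail < 1.0 else 1.0
            step = min(max(step, 0.0), 1.0)
            new = np.zeros(d + 1)
            for n in np.nonzero(probs > 0)[0]:
                add = stats.binom.pmf(ks[: d - n + 1], d - n, step)
                new[n : d + 1] += probs[n] * add
            new[cap + 1 :] = 0.0  # a crossing at this level
            probs = new
            prev_tail = q
            if probs.sum() == 0.0:
                ok = False
                break
        total += wt * (probs.sum() if ok else 0.0)
    return min(max(total, 0.0), 1.0)


def gbj_pvalue(z, corr, evaluator="mc", rng=None, alpha_ref=None,
               stages=(20_000, 100_000), max_draws=1_000_000):
    """P-value of the GBJ statistic for a z vector with correlation ``corr``.

    Returns ``(stat, p, info)``. ``evaluator`` is "mc" (default) or
    "analytic". The Monte-Carlo draw schedule is ``stages`` capped by
    ``max_draws``; ``alpha_ref`` enables decision-directed early stopping.
    """
    stat, _ = gbj_statistic(z, corr)
    if stat <= 0.0:
        return stat, 1.0, {"evaluator": "none", "draws": 0}
    corr = np.asarray(corr, dtype=np.float64)
    d = corr.shape[0]
    if evaluator == "mc":
        if rng is None:
            rng = np.random.default_rng(0)
        sched = sorted({int(min(s, max_draws)) for s in (*stages, max_draws)})
        p, draws = _mc_pvalue(stat, corr, rng, sched, alpha_ref)
        return stat, p, {"evaluator": "mc", "draws": draws}
    if evaluator == "analytic":
        log_pi0_fn, pairsum_fn = _exact_moment_fns(corr)
        bounds = _solve_boundaries(stat, d, log_pi0_fn, pairsum_fn)
        iu = np.triu_indices(d, 1)
        rho_bar = float(corr[iu].mean()) if iu[0].size else 0.0
        p = 1.0 - _noncrossing_prob(bounds, d, rho_bar)
        return stat, max(min(p, 1.0), P_FLOOR), {"evaluator": "analytic", "rho_bar": rho_bar}
    raise ValueError(f"unknown evaluator: {evaluator!r}")


def assoc_gbj(zvec: ZVector, evaluator="mc", rng=None, alpha_ref=None,
              stages=(20_000, 100_000), max_draws=1_000_000,
              gene: str = "gene") -> AssociationRecord:
    """Run the GBJ omnibus test on a per-tissue z vector.

    Raises :class:`SingleTissueError` for vectors with fewer than two tissues;
    the TSA router is responsible for sending those genes to the single-tissue
    test instead.
    """
    stat, p, info = gbj_pvalue(zvec.z, zvec.corr, evaluator=evaluator, rng=rng,
                               alpha_ref=alpha_ref, stages=stages, max_draws=max_draws)
    note = info["evaluator"]
    if zvec.collapsed:
        note += f";collapsed={len(zvec.collapsed)}"
    if zvec.dropped:
        note += f";dropped={len(zvec.dropped)}"
    return AssociationRecord(gene, "gbj", "cross", len(zvec.z),
                             np.nan, float(stat), float(p), note=note)
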