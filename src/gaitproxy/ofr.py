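"""Orthogonal forward regression (FROLS), its iterative refinement, and
model-structure diagnostics.

FROLS selects model terms greedily: at each step every unselected
candidate column is orthogonalized (modified Gram-Schmidt) against the
already-selected orthogonal basis and ranked by its error reduction ratio

    ERR_i = g_i^2 <w_i, w_i> / <y, y>,

the fraction of target energy the orthogonalized term explains.  The
candidate with maximal ERR is admitted; coefficients in the original basis
are recovered by back-substitution through the unit upper-triangular
Gram-Schmidt factor, so they match a direct least-squares fit on the
selected support.

Greedy selection can be trapped by correlated candidates, so the iterative
variant (iOFR) restarts the forward search once from each term of the
current model (that term forced in first) and keeps the restart with the
smallest residual sum of squares, repeating until no restart improves.

The module also carries two auxiliary analyses used when configuring the
model class: a cross-correlation scan that estimates how many input lags
matter, and a higher-order correlation test that checks whether a linear
model is sufficient (squared-input vs. linear-residual correlation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dictionary import (DesignMatrix, Monomial, TermDictionary,
                         terms_from_json, terms_to_json)
from .errors import (DomainError, InsufficientDataError, ParameterError,
                     StructuralError)

#: squared-norm ratio below which an orthogonalized candidate is treated as
#: degenerate (numerically inside the span of the selected terms); 1e-14 on
#: the energy is the roundoff floor reachable with incremental float64
#: norm updates
DEGENERACY_TOL = 1e-14


@dataclass
class StoppingRule:
    """When to stop admitting terms.

    mode='fixed_terms'  — stop after exactly ``n_terms`` terms.
    mode='err_threshold' — stop when the unexplained energy fraction
        1 - sum(ERR) drops to ``err_tolerance`` (or no candidate helps).
    mode='information_criterion' — stop when the BIC-like criterion
        N log(RSS/N) + penalty * n * log(N) stops decreasing.
    """

    mode: str = "fixed_terms"
    n_terms: int = 64
    err_tolerance: float = 1e-4
    penalty: float = 1.0

    def __post_init__(self):
        if self.mode not in ("fixed_terms", "err_threshold", "information_criterion"):
            raise ParameterError(f"unknown stopping mode {self.mode!r}")
        if self.n_terms < 1:
            raise ParameterError("n_terms must be >= 1")


@dataclass
class OFRResult:
    """Selection trace of one forward-regression run."""

    selected: List[int]            # column indices in selection order
    g: np.ndarray                  # coefficients in the orthogonal basis
    err: np.ndarray                # ERR per selected term, in order
    theta: np.ndarray              # coefficients in the original basis
    rss: float
    sum_err: float
    truncated: bool = False        # all remaining candidates degenerate
    W: Optional[np.ndarray] = None  # orthogonalized selected columns (n x k)

    @property
    def n_terms(self) -> int:
        return len(self.selected)


class OFRRegressor(RegressorMixin, BaseEstimator):
    """Sparse linear regression by forward orthogonal least squares.

    Parameters
    ----------
    n_terms : int
        Model size for the ``fixed_terms`` stopping rule (default 64).
    stopping : str
        ``fixed_terms``, ``err_threshold`` or ``information_criterion``.
    err_tolerance, penalty : float
        Parameters of the alternative stopping rules.
    refine_iterations : int
        Number of iterative-OFR refinement sweeps; 0 gives plain greedy
        FROLS, >=1 enables forced-first-term restarts with best-RSS
        acceptance.
    forced_first : sequence of int, optional
        Column indices admitted, in order, before any free selection.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Dense coefficient vector, zero outside the selected support.
    support_ : ndarray of int
        Selected column indices in selection order.
    err_ : ndarray
        Error reduction ratio of each selected term.
    rss_ : float
        Residual sum of squares of the final model.
    result_ : OFRResult
        Full selection trace.
    """

    def __init__(self, n_terms: int = 64, stopping: str = "fixed_terms",
                 err_tolerance: float = 1e-4, penalty: float = 1.0,
                 refine_iterations: int = 0,
                 forced_first: Optional[Sequence[int]] = None):
        self.n_terms = n_terms
        self.stopping = stopping
        self.err_tolerance = err_tolerance
        self.penalty = penalty
        self.refine_iterations = refine_iterations
        self.forced_first = forced_first

    def _rule(self) -> StoppingRule:
        return StoppingRule(mode=self.stopping, n_terms=self.n_terms,
                            err_tolerance=self.err_tolerance, penalty=self.penalty)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        rule = self._rule()
        forced = list(self.forced_first) if self.forced_first else []
        if self.refine_iterations > 0:
            result = _iofr(X, y, rule, max_iterations=self.refine_iterations,
                           forced_first=forced)
        else:
            result = _frols(X, y, rule, forced_first=forced)
        self.result_ = result
        self.support_ = np.asarray(result.selected, dtype=int)
        self.coef_ = np.zeros(X.shape[1])
        self.coef_[self.support_] = result.theta
        self.err_ = result.err
        self.err_sum_ = result.sum_err
        self.rss_ = result.rss
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_


def _frols(X: np.ndarray, y: np.ndarray, stop: StoppingRule,
           forced_first: Sequence[int] = (), keep_w: bool = True) -> OFRResult:
    """Forward regression with orthogonal least squares (modified Gram-Schmidt)."""
    n, m = X.shape
    if n != len(y):
        raise StructuralError("X and y have different numbers of rows")
    y = np.asarray(y, dtype=X.dtype)
    sigma = float(y @ y)
    if sigma == 0.0:
        # zero target: nothing to explain
        return OFRResult([], np.empty(0), np.empty(0), np.empty(0), 0.0, 0.0,
                         truncated=True, W=np.empty((n, 0)))

    Q = np.array(X, dtype=float, copy=True)       # running orthogonalized candidates
    norms2 = np.einsum("ij,ij->j", Q, Q)
    orig_norms2 = norms2.copy()
    if not np.any(norms2 > 0):
        raise DomainError("all candidate columns are zero")
    cy = Q.T @ y
    available = np.ones(m, dtype=bool)

    selected: List[int] = []
    g_list: List[float] = []
    err_list: List[float] = []
    W_cols: List[np.ndarray] = []
    ww_list: List[float] = []
    truncated = False
    prev_ic = np.inf
    max_terms = stop.n_terms if stop.mode == "fixed_terms" else m

    step = 0
    while len(selected) < min(max_terms, m):
        degenerate = norms2 <= DEGENERACY_TOL * np.maximum(orig_norms2, 1e-300)
        usable = available & ~degenerate
        if not usable.any():
            truncated = True
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            err_all = np.where(usable, cy ** 2 / np.where(norms2 > 0, norms2, 1.0)
                               / sigma, -np.inf)
        if step < len(forced_first):
            s = int(forced_first[step])
            if not usable[s]:
                raise ParameterError(f"forced term {s} is degenerate or reused")
        else:
            s = int(np.argmax(err_all))  # ties break toward the lowest index
        err_s = float(err_all[s])

        if stop.mode == "err_threshold" and step >= len(forced_first):
            explained = float(np.sum(err_list))
            if 1.0 - explained <= stop.err_tolerance or err_s <= 0:
                break
        if stop.mode == "information_criterion" and step >= len(forced_first):
            rss_next = sigma * max(1.0 - float(np.sum(err_list)) - err_s, 0.0)
            ic = n * np.log(max(rss_next, 1e-300) / n) \
                + stop.penalty * (len(selected) + 1) * np.log(n)
            if ic >= prev_ic:
                break
            prev_ic = ic

        w = Q[:, s].copy()
        ww = norms2[s]
        g = cy[s] / ww
        selected.append(s)
        g_list.append(float(g))
        err_list.append(err_s)
        W_cols.append(w)
        available[s] = False

        # deflate remaining candidates by w and update running statistics
        ww_list.append(float(ww))
        proj = (w @ Q) / ww
        proj[~available] = 0.0
        Q -= np.outer(w, proj)
        norms2 = norms2 - proj ** 2 * ww
        np.maximum(norms2, 0.0, out=norms2)
        cy = cy - proj * (w @ y)
        step += 1

        if stop.mode == "err_threshold" and 1.0 - float(np.sum(err_list)) <= stop.err_tolerance:
            break

    k = len(selected)
    g_arr = np.asarray(g_list)
    err_arr = np.asarray(err_list)
    if k == 0:
        theta = np.empty(0)
        rss = sigma
    else:
        # unit upper-triangular Gram-Schmidt factor: A[i, j] = <w_i, x_sj>/<w_i, w_i>
        Wmat = np.column_stack(W_cols)
        A = (Wmat.T @ X[:, selected]) / np.asarray(ww_list)[:, None]
        A = np.triu(A)
        np.fill_diagonal(A, 1.0)
        from scipy.linalg import solve_triangular
        theta = solve_triangular(A, g_arr, lower=False, unit_diagonal=True)
        resid = y - X[:, selected] @ theta
        rss = float(resid @ resid)
    W = np.column_stack(W_cols) if (keep_w and k) else np.empty((n, 0))
    return OFRResult(selected=selected, g=g_arr, err=err_arr, theta=theta,
                     rss=rss, sum_err=float(err_arr.sum()), truncated=truncated,
                     W=W if keep_w else None)


def _iofr(X: np.ndarray, y: np.ndarray, stop: StoppingRule,
          max_iterations: int = 10,
          forced_first: Sequence[int] = ()) -> OFRResult:
    """Iterative OFR: forced-first-term restarts with best-RSS acceptance.

    Iteration 0 is plain FROLS.  Each subsequent iteration re-runs the
    forward search once per term of the current model with that term forced
    in first; the best restart replaces the model only if its RSS (at equal
    model size) is strictly smaller.  Terminates at convergence or after
    ``max_iterations`` sweeps.
    """
    best = _frols(X, y, stop, forced_first=forced_first)
    if best.n_terms == 0:
        return best
    # restarts keep the model size fixed so RSS comparisons are like-for-like
    size_rule = StoppingRule(mode="fixed_terms", n_terms=best.n_terms)
    for _ in range(max_iterations):
        improved = False
        for t in list(best.selected):
            cand = _frols(X, y, size_rule, forced_first=[t])
            if cand.n_terms == best.n_terms and cand.rss < best.rss * (1 - 1e-12):
                best = cand
                improved = True
        if not improved:
            break
    return best


def ofr_select(design: DesignMatrix, target, stop: Optional[StoppingRule] = None,
               forced_first: Optional[Sequence[int]] = None) -> OFRResult:
    """Plain FROLS on a design matrix; ``target`` covers the usable instants."""
    stop = stop or StoppingRule()
    y = np.asarray(target, dtype=float)
    if len(y) != design.n_rows:
        raise StructuralError(f"target length {len(y)} != design rows {design.n_rows}")
    return _frols(design.X, y, stop, forced_first=forced_first or ())


def iofr_select(design: DesignMatrix, target, stop: Optional[StoppingRule] = None,
                max_iterations: int = 10) -> OFRResult:
    """Iterative OFR on a design matrix (see :func:`_iofr`)."""
    stop = stop or StoppingRule()
    y = np.asarray(target, dtype=float)
    if len(y) != design.n_rows:
        raise StructuralError(f"target length {len(y)} != design rows {design.n_rows}")
    if max_iterations <= 0:
        return _frols(design.X, y, stop)
    return _iofr(design.X, y, stop, max_iterations=max_iterations)


# ---------------------------------------------------------------------------
# The identified model

@dataclass
class NMAModel:
    """A selected polynomial input-only (nonlinear moving average) model.

    Prediction uses only input channels at lags 0..max_lag — never the
    output — so prediction errors cannot accumulate through feedback.
    """

    terms: List[Monomial]
    coefficients: np.ndarray
    max_lag: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.terms) != len(self.coefficients):
            raise StructuralError("terms and coefficients differ in length")

    def predict(self, signals) -> np.ndarray:
        return predict_nma(self, signals)

    def to_json(self) -> dict:
        return {"max_lag": int(self.max_lag),
                "terms": terms_to_json(self.terms, self.coefficients),
                "metadata": self.metadata}

    @classmethod
    def from_json(cls, payload: dict) -> "NMAModel":
        terms, coefs = terms_from_json(payload["terms"])
        return cls(terms=terms, coefficients=np.asarray(coefs),
                   max_lag=int(payload["max_lag"]),
                   metadata=payload.get("metadata", {}))


def predict_nma(model: NMAModel, signals) -> np.ndarray:
    """Evaluate the polynomial model on decomposed input signals.

    Returns a full-length sequence; the first ``max_lag`` samples, whose
    lagged inputs precede the recording, are NaN.
    """
    n = signals.n_samples
    L = model.max_lag
    if n <= L:
        raise InsufficientDataError(f"need more than {L} samples, got {n}")
    out = np.full(n, np.nan)
    acc = np.zeros(n - L)
    for term, c in zip(model.terms, model.coefficients):
        acc += c * term.evaluate(signals, L)
    out[L:] = acc
    return out


# ---------------------------------------------------------------------------
# Auxiliary analyses

@dataclass
class LagAnalysis:
    """Cross-correlation between an input and the target over lags 0..L."""

    lag: int                    # smallest window holding the energy fraction
    lags: np.ndarray
    correlation: np.ndarray
    band: float                 # +/- 1.96/sqrt(N) significance band
    energy_fraction: float


def max_lag_by_crosscorrelation(u, y, max_lag: int = 40,
                                energy_fraction: float = 0.95) -> LagAnalysis:
    """Estimate how many input lags carry dependence with the target.

    Computes the normalized cross-correlation r(l) = corr(u(k-l), y(k)) for
    l = 0..max_lag, keeps only lags exceeding the 1.96/sqrt(N) significance
    band, and returns the smallest lag window containing the requested
    fraction of the significant squared-correlation mass.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if u.shape != y.shape:
        raise StructuralError("sequences differ in length")
    if len(u) <= max_lag + 2:
        raise InsufficientDataError("sequence shorter than the lag range")
    if np.ptp(u) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for constant input")
    lags = np.arange(max_lag + 1)
    r = np.empty(max_lag + 1)
    for l in lags:
        a = u[: len(u) - l] if l else u
        b = y[l:]
        ra = a - a.mean()
        rb = b - b.mean()
        denom = np.sqrt((ra @ ra) * (rb @ rb))
        r[l] = (ra @ rb) / denom if denom > 0 else 0.0
    band = 1.96 / np.sqrt(len(u))
    mass = np.where(np.abs(r) > band, r ** 2, 0.0)
    total = mass.sum()
    if total == 0:
        lag = 0
    else:
        cum = np.cumsum(mass)
        lag = int(np.argmax(cum >= energy_fraction * total))
    return LagAnalysis(lag=lag, lags=lags, correlation=r, band=band,
                       energy_fraction=energy_fraction)


@dataclass
class NonlinearityReport:
    """Higher-order correlation diagnostic for linear-model adequacy."""

    lags: np.ndarray
    statistic: np.ndarray       # corr(centred u^2 (k-l), linear residual(k))
    band: float                 # per-lag 95% band 1.96/sqrt(N)
    decision_band: float        # multiplicity-adjusted band used for verdict
    verdict: str                # 'linear' or 'nonlinear'
    n_exceedances: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"lag": self.lags, "statistic": self.statistic,
                             "band": self.band})


def nonlinearity_test(u, y, max_lag: int = 18) -> NonlinearityReport:
    """Test whether a linear-in-lags model explains the input/output pair.

    The best linear model over lags 0..max_lag is fitted by least squares;
    the test statistic is the normalized cross-correlation between the
    squared, centred input and the model residuals.  For a correct linear
    model the statistic stays inside the 95% band at every lag up to
    sampling fluctuation; systematic excursions indicate unmodelled
    (even-order) nonlinearity.  The verdict uses a Bonferroni-adjusted
    band across the max_lag+1 lags so that the family-wise false-alarm
    rate, not the per-lag rate, is 5%.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if u.shape != y.shape:
        raise StructuralError("sequences differ in length")
    n = len(u)
    if n <= 3 * (max_lag + 1):
        raise InsufficientDataError("too few samples for a stable linear fit")
    if np.ptp(u) == 0:
        raise DomainError("constant input")
    rows = n - max_lag
    Xlin = np.empty((rows, max_lag + 2))
    Xlin[:, 0] = 1.0
    for l in range(max_lag + 1):
        Xlin[:, l + 1] = u[max_lag - l: n - l]
    yy = y[max_lag:]
    coef, *_ = np.linalg.lstsq(Xlin, yy, rcond=None)
    resid = yy - Xlin @ coef

    v = u ** 2
    v = v - v.mean()
    lags = np.arange(max_lag + 1)
    r = np.empty(max_lag + 1)
    e = resid - resid.mean()
    for l in lags:
        vv = v[max_lag - l: n - l]
        vc = vv - vv.mean()
        denom = np.sqrt((vc @ vc) * (e @ e))
        r[l] = (vc @ e) / denom if denom > 0 else 0.0
    band = 1.96 / np.sqrt(rows)
    z = stats.norm.ppf(1 - 0.025 / (max_lag + 1))
    decision_band = z / np.sqrt(rows)
    n_exceed = int(np.sum(np.abs(r) > decision_band))
    verdict = "nonlinear" if n_exceed > 0 else "linear"
    return NonlinearityReport(lags=lags, statistic=r, band=band,
                              decision_band=decision_band, verdict=verdict,
                              n_exceedances=n_exceed)
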