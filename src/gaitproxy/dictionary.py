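"""Candidate-term dictionary for the polynomial NMA (Volterra) model.

The model class is a multivariate polynomial of degree at most two in the
current and lagged values of the six decomposed acceleration channels:

    y(k) = theta_0 + sum_i theta_i * u_{c_i}(k - n_i)
                   + sum_{i<=j} theta_ij * u_{c_i}(k - n_i) * u_{c_j}(k - n_j)

with all lags between 0 and a maximum lag L.  With m = n_channels*(L+1)
lagged variables the full dictionary has 1 + m + m(m+1)/2 terms (constant
included).  Only input terms appear — no output feedback and no noise
terms — so predictions never accumulate error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InsufficientDataError, ParameterError, StructuralError

Factor = Tuple[str, int, int]  # (channel, lag, power)


@dataclass(frozen=True)
class Monomial:
    """A product of lagged channel values; the empty product is the constant."""

    factors: Tuple[Factor, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "factors", _canonical(self.factors))

    @property
    def is_constant(self) -> bool:
        return len(self.factors) == 0

    @property
    def degree(self) -> int:
        return sum(p for _, _, p in self.factors)

    @property
    def max_lag(self) -> int:
        return max((lag for _, lag, _ in self.factors), default=0)

    def evaluate(self, signals, start: int) -> np.ndarray:
        """Term values for k in [start, N); requires start >= max lag."""
        n = signals.n_samples
        out = np.ones(n - start, dtype=float)
        for channel, lag, power in self.factors:
            if channel not in signals:
                raise StructuralError(f"channel {channel!r} missing from signals")
            x = signals[channel][start - lag: n - lag]
            out *= x if power == 1 else x ** power
        return out

    def __str__(self):
        if self.is_constant:
            return "1"
        parts = []
        for channel, lag, power in self.factors:
            s = f"{channel}(k)" if lag == 0 else f"{channel}(k-{lag})"
            if power > 1:
                s += f"^{power}"
            parts.append(s)
        return "*".join(parts)


def _canonical(factors: Sequence[Factor]) -> Tuple[Factor, ...]:
    """Sort factors and merge repeats so equal monomials compare equal."""
    merged: Dict[Tuple[str, int], int] = {}
    for channel, lag, power in factors:
        if lag < 0:
            raise ParameterError(f"negative lag {lag}")
        if power < 1:
            raise ParameterError(f"non-positive power {power}")
        merged[(channel, int(lag))] = merged.get((channel, int(lag)), 0) + int(power)
    return tuple((c, l, p) for (c, l), p in sorted(merged.items()))


@dataclass
class TermDictionary:
    """Ordered collection of distinct candidate monomials."""

    terms: List[Monomial]
    channels: List[str]
    max_lag: int
    max_degree: int
    include_constant: bool
    #: True when terms are the full enumeration in build_dictionary order,
    #: which enables the vectorized evaluation path
    full_enumeration: bool = False

    def __len__(self):
        return len(self.terms)

    def __getitem__(self, i) -> Monomial:
        return self.terms[i]


@dataclass
class DesignMatrix:
    """Dictionary terms evaluated at the usable sample instants k in [L, N)."""

    X: np.ndarray
    dictionary: TermDictionary
    first_k: int

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


def build_dictionary(channels: Sequence[str], max_lag: int,
                     max_degree: int = 2,
                     include_constant: bool = True) -> TermDictionary:
    """Enumerate all monomials of total degree <= max_degree over lags 0..max_lag.

    For degree 2 the quadratic block contains every unordered pair (with
    repetition) of lagged variables, so the size is 1 + m + m(m+1)/2 with
    the constant included, m = len(channels) * (max_lag + 1).
    """
    if max_degree not in (1, 2):
        raise ParameterError("max_degree must be 1 or 2 (degree-2 model class)")
    if max_lag < 0:
        raise ParameterError("max_lag must be nonnegative")
    variables = [(c, lag) for c in channels for lag in range(max_lag + 1)]
    terms: List[Monomial] = []
    if include_constant:
        terms.append(Monomial())
    terms.extend(Monomial(((c, lag, 1),)) for c, lag in variables)
    if max_degree == 2:
        m = len(variables)
        for i in range(m):
            ci, li = variables[i]
            for j in range(i, m):
                cj, lj = variables[j]
                if i == j:
                    terms.append(Monomial(((ci, li, 2),)))
                else:
                    terms.append(Monomial(((ci, li, 1), (cj, lj, 1))))
    return TermDictionary(terms=terms, channels=list(channels), max_lag=max_lag,
                          max_degree=max_degree, include_constant=include_constant,
                          full_enumeration=True)


def dictionary_size(n_channels: int, max_lag: int, max_degree: int = 2,
                    include_constant: bool = True) -> int:
    """Closed-form dictionary size; matches :func:`build_dictionary`."""
    m = n_channels * (max_lag + 1)
    size = m + (m * (m + 1)) // 2 if max_degree == 2 else m
    return size + int(include_constant)


def evaluate_dictionary(dictionary: TermDictionary, signals,
                        dtype=np.float64) -> DesignMatrix:
    """Evaluate every dictionary term at k in [max_lag, N).

    The full degree-2 evaluation avoids per-term Python loops: the lagged
    variables are assembled once into a matrix V and the quadratic block is
    filled with column-wise broadcasts.
    """
    L = dictionary.max_lag
    n = signals.n_samples
    if n <= L:
        raise InsufficientDataError(f"need more than max_lag={L} samples, got {n}")
    for c in dictionary.channels:
        if c not in signals:
            raise StructuralError(f"channel {c!r} missing from signals")
    rows = n - L
    variables = [(c, lag) for c in dictionary.channels for lag in range(L + 1)]
    var_index = {v: i for i, v in enumerate(variables)}
    m = len(variables)
    V = np.empty((rows, m), dtype=dtype)
    for i, (c, lag) in enumerate(variables):
        V[:, i] = signals[c][L - lag: n - lag]

    full = dictionary.full_enumeration and _is_full_dictionary(dictionary, m)
    X = np.empty((rows, len(dictionary)), dtype=dtype)
    if full:
        col = 0
        if dictionary.include_constant:
            X[:, 0] = 1.0
            col = 1
        X[:, col:col + m] = V
        col += m
        if dictionary.max_degree == 2:
            for i in range(m):
                width = m - i
                X[:, col:col + width] = V[:, i:] * V[:, i:i + 1]
                col += width
    else:
        for j, term in enumerate(dictionary.terms):
            X[:, j] = _eval_term(term, V, var_index)
    return DesignMatrix(X=X, dictionary=dictionary, first_k=L)


def _is_full_dictionary(dictionary: TermDictionary, m: int) -> bool:
    return len(dictionary) == dictionary_size(
        len(dictionary.channels), dictionary.max_lag, dictionary.max_degree,
        dictionary.include_constant)


def _eval_term(term: Monomial, V: np.ndarray, var_index) -> np.ndarray:
    out = np.ones(V.shape[0], dtype=V.dtype)
    for channel, lag, power in term.factors:
        x = V[:, var_index[(channel, lag)]]
        out = out * (x if power == 1 else x ** power)
    return out


# ---------------------------------------------------------------------------
# JSON serialization of term lists (shared with model files)

def terms_to_json(terms: Sequence[Monomial],
                  coefficients: Optional[Sequence[float]] = None) -> List[dict]:
    out = []
    for i, t in enumerate(terms):
        d = {"factors": [{"channel": c, "lag": int(l), "power": int(p)}
                         for c, l, p in t.factors]}
        if coefficients is not None:
            d["coefficient"] = float(coefficients[i])
        out.append(d)
    return out


def terms_from_json(items: Sequence[dict]) -> Tuple[List[Monomial], List[float]]:
    terms, coefs = [], []
    for d in items:
        terms.append(Monomial(tuple((f["channel"], int(f["lag"]), int(f["power"]))
                                    for f in d["factors"])))
        coefs.append(float(d.get("coefficient", 0.0)))
    return terms, coefs
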