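"""Statistical machinery for gradient screens.

Three pieces of statistics recur throughout the screen analysis:

* a second-order polynomial (quadratic) trend fit of a biological readout
  against a single material property, with the convention that fits with
  R^2 > 0.4 are "representative" of a real trend;
* the two-sample Kolmogorov-Smirnov test, used for every group comparison
  (decile splits, flat-vs-topography grouping, ROI significance), computed
  exactly by enumeration for small samples and by the asymptotic Kolmogorov
  distribution otherwise;
* partial least squares (PLS1, NIPALS algorithm) of a readout on the three
  material properties, with each variable scaled by its standard deviation
  (a tiny offset guards axes where a property is constant, e.g. WCA on the
  hydrophilic topography-stiffness sample), leave-one-out cross-validation
  for the number of components, and variable importance in projection (VIP).

`ColumnScaler` and `NIPALSPLS` follow the scikit-learn estimator protocol
(``fit``, ``transform``/``predict``, fitted attributes with a trailing
underscore) so they compose with sklearn pipelines; the module-level
functions :func:`scale_columns` and :func:`pls_fit` are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import special

__all__ = [
    "RegressionFit",
    "KSResult",
    "PLSResult",
    "polyfit2",
    "ks_two_sample",
    "ColumnScaler",
    "scale_columns",
    "NIPALSPLS",
    "pls_fit",
]

#: R^2 above which a quadratic trend is considered representative.
REPRESENTATIVE_R2 = 0.4

#: Offset used in place of a zero standard deviation when scaling columns.
ZERO_SD_OFFSET = 1e-8

#: Largest pooled sample size for which the exact KS null is enumerated.
EXACT_KS_MAX_N = 12


# ---------------------------------------------------------------------------
# quadratic regression


@dataclass(frozen=True)
class RegressionFit:
    """Second-order polynomial fit y = b0 + b1*x + b2*x^2."""

    b0: float
    b1: float
    b2: float
    r_squared: float
    vertex_x: float | None
    representative: bool


def polyfit2(x, y) -> RegressionFit:
    """Ordinary least squares quadratic regression of ``y`` on ``x``.

    The vertex ``-b1 / (2 b2)`` is reported whenever the quadratic term is
    nonzero; for readouts with an interior optimum (e.g. proliferation vs
    water contact angle) it estimates the optimum property value.

    Raises
    ------
    ValueError
        If fewer than 3 points or fewer than 3 distinct x values are given
        (the design matrix would be singular).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError("quadratic fit needs >= 3 distinct x values")

    design = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # guard against tiny negative round-off
    r2 = min(1.0, max(0.0, r2))
    b0, b1, b2 = (float(c) for c in coef)
    vertex = -b1 / (2.0 * b2) if b2 != 0 else None
    return RegressionFit(b0, b1, b2, r2, vertex, r2 > REPRESENTATIVE_R2)


# ---------------------------------------------------------------------------
# two-sample Kolmogorov-Smirnov


@dataclass(frozen=True)
class KSResult:
    d_stat: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" or "asymptotic"

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup |F_a - F_b| over the pooled support (tie-safe)."""
    support = np.union1d(a, b)
    fa = np.searchsorted(np.sort(a), support, side="right") / a.size
    fb = np.searchsorted(np.sort(b), support, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def _ks_exact_p(pooled: np.ndarray, n1: int, d_obs: float) -> float:
    """Exact permutation p-value: enumerate all label assignments."""
    n = pooled.size
    idx = np.arange(n)
    count = 0
    total = 0
    for comb in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        d = _ks_statistic(pooled[mask], pooled[~mask])
        # tolerance for float comparison of attained statistics
        if d >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def ks_two_sample(a, b, method: str = "auto") -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs evaluated on
    the pooled sorted support (so ties are handled naturally).  The p-value
    is exact -- full enumeration of the C(n1+n2, n1) label assignments --
    when ``n1 + n2 <= 12`` (or ``method="exact"``), and otherwise uses the
    asymptotic Kolmogorov distribution evaluated at ``sqrt(ne) * D`` with
    effective sample size ``ne = n1 n2/(n1+n2)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(a, b)
    n1, n2 = a.size, b.size

    if method == "auto":
        method = "exact" if n1 + n2 <= EXACT_KS_MAX_N else "asymptotic"
    if method == "exact":
        p = _ks_exact_p(np.concatenate([a, b]), n1, d)
    elif method == "asymptotic":
        ne = n1 * n2 / (n1 + n2)
        p = float(special.kolmogorov(math.sqrt(ne) * d))
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(d, min(1.0, max(0.0, p)), n1, n2, method)


# ---------------------------------------------------------------------------
# column scaling


class ColumnScaler:
    """Center columns and divide by their standard deviation.

    A column with zero standard deviation (a material property held fixed on
    a given sample) is divided by a small offset instead, so that scaling
    never produces NaN/inf: after centering the column is identically zero
    and stays zero.

    Parameters
    ----------
    offset : float
        Divisor substituted for a zero standard deviation.
    ddof : int
        Delta degrees of freedom for the standard deviation (1 = sample SD).
    """

    def __init__(self, offset: float = ZERO_SD_OFFSET, ddof: int = 1):
        self.offset = offset
        self.ddof = ddof

    def get_params(self, deep: bool = True) -> dict:
        return {"offset": self.offset, "ddof": self.ddof}

    def set_params(self, **params) -> "ColumnScaler":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "ColumnScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.size == 0:
            raise ValueError("X must be non-empty")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=self.ddof) if X.shape[0] > self.ddof else np.zeros(X.shape[1])
        self.divisors_ = np.where(sd > 0, sd, self.offset)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return (X - self.mean_) / self.divisors_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, X_scaled) -> np.ndarray:
        return np.asarray(X_scaled, dtype=float) * self.divisors_ + self.mean_


def scale_columns(X):
    """Scale columns by their SD (zero-SD offset); returns (X_scaled, divisors)."""
    scaler = ColumnScaler()
    return scaler.fit_transform(X), scaler.divisors_


# ---------------------------------------------------------------------------
# NIPALS partial least squares (PLS1)


@dataclass
class PLSResult:
    n_components: int
    weights: np.ndarray  # (p, A) X-weights, unit norm per component
    x_scores: np.ndarray  # (n, A)
    q2_per_component: np.ndarray  # cumulative Q^2 after 1..A components
    press_per_component: np.ndarray
    vip: np.ndarray  # (p,)
    divisors: np.ndarray = field(default_factory=lambda: np.array([]))


class NIPALSPLS:
    """PLS1 regression by the NIPALS algorithm with LOO component selection.

    Predictors and response are centered and scaled by their standard
    deviations (:class:`ColumnScaler`), matching the screen's preprocessing;
    a fixed material property yields a zero column which simply carries no
    weight.  Components are extracted by NIPALS; with a single response the
    weight vector of each component is ``X' y`` normalized, followed by
    deflation of X (and y) on the extracted score.

    The number of components is chosen by leave-one-out cross-validation:
    ``PRESS_A = sum_i (y_i - yhat_{-i,A})^2`` and ``Q^2_A = 1 - PRESS_A /
    SS_tot`` are computed for A = 1..A_max (capped at the number of
    predictors).  The default selection rule is the standard significance
    rule (Wold / SIMCA): components are added while their marginal
    ``1 - PRESS_A / PRESS_{A-1}`` exceeds 0.0975; ``selection="max_q2"``
    instead keeps the A maximizing cumulative Q^2 (which for nearly linear
    noise-free responses tends to select full rank, as the extra components
    merely polish the first weight vector).

    Variable importance in projection follows the standard definition

        VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )

    with SSY_a the response variance explained by component a; the mean of
    the squared VIPs over predictors is identically 1.

    Attributes (after ``fit``)
    --------------------------
    n_components_ : selected number of components
    weights_, x_scores_, loadings_, coef_ : NIPALS quantities on scaled data
    q2_, press_ : per-component LOO diagnostics (empty when ``loo=False``)
    vip_ : variable importance per predictor
    """

    #: marginal-Q^2 threshold for a component to count as significant
    WOLD_THRESHOLD = 0.0975

    def __init__(self, n_components: int | None = None, loo: bool = True,
                 max_components: int | None = None, selection: str = "wold"):
        self.n_components = n_components
        self.loo = loo
        self.max_components = max_components
        self.selection = selection

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components,
            "loo": self.loo,
            "max_components": self.max_components,
            "selection": self.selection,
        }

    def set_params(self, **params) -> "NIPALSPLS":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- core NIPALS on already-scaled data --------------------------------
    @staticmethod
    def _nipals(Xs: np.ndarray, ys: np.ndarray, n_comp: int):
        n, p = Xs.shape
        W = np.zeros((p, n_comp))
        T = np.zeros((n, n_comp))
        P = np.zeros((p, n_comp))
        c = np.zeros(n_comp)
        X = Xs.copy()
        y = ys.copy()
        actual = 0
        for a in range(n_comp):
            w = X.T @ y
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                break
            w /= norm
            t = X @ w
            tt = float(t @ t)
            if tt < 1e-12:
                break
            p_a = X.T @ t / tt
            c_a = float(y @ t) / tt
            X = X - np.outer(t, p_a)
            y = y - c_a * t
            W[:, a], T[:, a], P[:, a], c[a] = w, t, p_a, c_a
            actual += 1
        return W[:, :actual], T[:, :actual], P[:, :actual], c[:actual]

    @staticmethod
    def _coef(W: np.ndarray, P: np.ndarray, c: np.ndarray) -> np.ndarray:
        """Regression vector b (scaled space): y_hat = Xs b."""
        if W.shape[1] == 0:
            return np.zeros(W.shape[0])
        # b = W (P' W)^-1 c
        return W @ np.linalg.solve(P.T @ W, c)

    def fit(self, X, y) -> "NIPALSPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if n != y.size:
            raise ValueError("X and y have incompatible lengths")
        if n < 4:
            raise ValueError("PLS needs at least 4 samples")
        if np.std(y) == 0:
            raise ValueError("response has zero variance")

        self.x_scaler_ = ColumnScaler().fit(X)
        self.y_scaler_ = ColumnScaler().fit(y[:, None])
        Xs = self.x_scaler_.transform(X)
        ys = self.y_scaler_.transform(y[:, None]).ravel()

        a_max = self.max_components or p
        a_max = min(a_max, p, n - 1)

        press = np.full(a_max, np.nan)
        q2 = np.full(a_max, np.nan)
        if self.n_components is not None:
            n_comp = min(self.n_components, a_max)
        elif self.loo:
            # leave-one-out PRESS per cumulative component count
            ss_tot = float(ys @ ys)
            press_acc = np.zeros(a_max)
            for i in range(n):
                keep = np.ones(n, dtype=bool)
                keep[i] = False
                W, T, P, c = self._nipals(Xs[keep], ys[keep], a_max)
                b = np.zeros(p)
                for a in range(a_max):
                    if a < W.shape[1]:
                        b = self._coef(W[:, : a + 1], P[:, : a + 1], c[: a + 1])
                    yhat = Xs[i] @ b
                    press_acc[a] += (ys[i] - yhat) ** 2
            press = press_acc
            q2 = 1.0 - press / ss_tot
            if self.selection == "max_q2":
                n_comp = int(np.nanargmax(q2)) + 1
            elif self.selection == "wold":
                n_comp = 1
                for a in range(1, a_max):
                    marginal = 1.0 - press[a] / press[a - 1]
                    if marginal <= self.WOLD_THRESHOLD:
                        break
                    n_comp = a + 1
            else:
                raise ValueError(f"unknown selection rule {self.selection!r}")
        else:
            n_comp = a_max

        W, T, P, c = self._nipals(Xs, ys, n_comp)
        n_comp = W.shape[1]
        self.weights_ = W
        self.x_scores_ = T
        self.loadings_ = P
        self.y_loadings_ = c
        self.coef_ = self._coef(W, P, c)
        self.n_components_ = n_comp
        self.press_ = press[:n_comp] if self.loo and self.n_components is None else press
        self.q2_ = q2[:n_comp] if self.loo and self.n_components is None else q2

        # VIP from the explained response variance per component
        ssy = c**2 * np.einsum("ia,ia->a", T, T)  # SSY_a = c_a^2 t_a' t_a
        total = ssy.sum()
        if total <= 0:
            self.vip_ = np.zeros(p)
        else:
            self.vip_ = np.sqrt(p * (W**2 @ ssy) / total)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Xs = self.x_scaler_.transform(X)
        ys_hat = Xs @ self.coef_
        return self.y_scaler_.inverse_transform(ys_hat[:, None]).ravel()


def pls_fit(X, y, loo: bool = True) -> PLSResult:
    """Fit a NIPALS PLS1 model; see :class:`NIPALSPLS` for details."""
    model = NIPALSPLS(loo=loo).fit(X, y)
    return PLSResult(
        n_components=model.n_components_,
        weights=model.weights_,
        x_scores=model.x_scores_,
        q2_per_component=model.q2_,
        press_per_component=model.press_,
        vip=model.vip_,
        divisors=model.x_scaler_.divisors_,
    )
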