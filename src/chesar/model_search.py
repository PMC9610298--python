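"""Exhaustive best-subset polynomial regression with LOO cross-validation.

Candidate predictors are all monomials x1^e1 ... xd^ed of total degree 1..p
in d variables — C(d+p, p) - 1 terms.  Every subset of terms (the intercept
is always included and never counted as a variable) defines one linear model
Y = X B fitted by SVD least squares; with d = 3 and p = 4 the space holds
2^34 = 17,179,869,184 models, which is why an explicit enumeration budget and
a count-only mode exist.

Each fitted model is validated by leave-one-out cross-validation computed
through the hat matrix: the LOO residual is e_i / (1 - h_ii), PRESS is the
sum of their squares, and predicted R^2 = 1 - PRESS / SST.

Model selection balances predictive fit against the number of variables.
The default ranking applies the one-standard-error rule: among all models
whose total PRESS lies within one standard error of the minimum-PRESS
model's PRESS, the one with the fewest terms wins (ties broken by lower
PRESS, then by lower subset mask).  Maximising predicted R^2 alone
("predicted_r2" ranking) is selectable but routinely prefers supersets of
the true support whose cross-validated advantage is far inside the noise.
Both rules are deterministic total orders.  Rank-deficient fits and
saturated leverages invalidate a model rather than silently polluting the
ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "SearchBudgetError",
    "MonomialBasis",
    "OLSFit",
    "PolynomialModel",
    "SearchConfig",
    "SearchResult",
    "monomial_terms",
    "model_count",
    "design_matrix",
    "ols_fit",
    "loo_cv",
    "adjusted_r2",
    "exhaustive_search",
    "predict",
]

SVD_RCOND = 1e-10
LEVERAGE_GUARD = 1e-8


class SearchBudgetError(RuntimeError):
    """Raised when the model space exceeds the enumeration budget."""


@dataclass(frozen=True)
class MonomialBasis:
    """Ordered monomial terms of total degree 1..max_order in n_vars variables."""

    n_vars: int
    max_order: int
    terms: tuple  # tuple of exponent tuples, ordered by (degree, lexicographic)

    def __len__(self) -> int:
        return len(self.terms)

    def term_label(self, index: int) -> str:
        exps = self.terms[index]
        parts = [
            f"x{i + 1}" + (f"^{e}" if e > 1 else "")
            for i, e in enumerate(exps) if e > 0
        ]
        return "*".join(parts)


def monomial_terms(d: int, p: int) -> MonomialBasis:
    """All exponent vectors with total degree in [1, p], deterministically ordered."""
    if d < 1 or p < 1:
        raise ValueError("need d >= 1 and p >= 1")
    terms = [e for e in product(range(p + 1), repeat=d) if 1 <= sum(e) <= p]
    terms.sort(key=lambda e: (sum(e), tuple(-x for x in e)))
    basis = MonomialBasis(n_vars=d, max_order=p, terms=tuple(terms))
    assert len(basis) == math.comb(d + p, p) - 1
    return basis


def model_count(d: int, p: int) -> int:
    """Number of term subsets, 2^(C(d+p, p) - 1), in exact integer arithmetic."""
    return 2 ** (math.comb(d + p, p) - 1)


def design_matrix(X: np.ndarray, basis: MonomialBasis, subset) -> np.ndarray:
    """Intercept column followed by the selected monomials evaluated row-wise."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != basis.n_vars:
        raise ValueError(f"X has {X.shape[1]} columns, basis expects {basis.n_vars}")
    cols = [np.ones(X.shape[0])]
    for idx in subset:
        exps = basis.terms[idx]
        cols.append(np.prod(X ** np.asarray(exps, dtype=float), axis=1))
    return np.column_stack(cols)


@dataclass(frozen=True)
class OLSFit:
    """Minimum-norm SVD least-squares fit of a (multi-response) linear model."""

    coefficients: np.ndarray   # (m, r)
    fitted: np.ndarray         # (n, r)
    residuals: np.ndarray      # (n, r)
    r2: np.ndarray             # (r,), nan for zero-variance responses
    leverages: np.ndarray      # (n,) hat-matrix diagonal
    rank: int
    rank_deficient: bool
    sst: np.ndarray            # (r,) total sum of squares about the mean
    underdetermined: bool


def ols_fit(design: np.ndarray, Y: np.ndarray, rcond: float = SVD_RCOND) -> OLSFit:
    """Least squares via SVD pseudo-inverse with a relative singular-value cutoff.

    Singular values below ``rcond`` times the largest are truncated and the
    fit is flagged ``rank_deficient``.  R^2 is 1 - SSE/SST per response; a
    zero-variance response yields nan with no error.
    """
    A = np.atleast_2d(np.asarray(design, dtype=float))
    Y = np.asarray(Y, dtype=float)
    y2d = Y.reshape(-1, 1) if Y.ndim == 1 else Y
    n, m = A.shape

    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    keep = s > rcond * s[0]
    rank = int(keep.sum())
    pinv = (Vt[keep].T / s[keep]) @ U[:, keep].T
    B = pinv @ y2d
    fitted = A @ B
    residuals = y2d - fitted
    sst = np.sum((y2d - y2d.mean(axis=0)) ** 2, axis=0)
    sse = np.sum(residuals**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
    leverages = np.sum(U[:, keep] ** 2, axis=1)
    return OLSFit(
        coefficients=B if Y.ndim > 1 else B,
        fitted=fitted,
        residuals=residuals,
        r2=r2,
        leverages=leverages,
        rank=rank,
        rank_deficient=rank < min(n, m),
        sst=sst,
        underdetermined=n <= m,
    )


def loo_cv(
    fit: OLSFit, guard: float = LEVERAGE_GUARD
) -> tuple[np.ndarray, np.ndarray, bool]:
    """(loo_mse, predicted_r2, valid) from the hat-matrix LOO shortcut.

    The LOO residual for observation i is e_i / (1 - h_ii); PRESS is the sum
    of squared LOO residuals, loo_mse = PRESS/n, predicted R^2 = 1 - PRESS/SST.
    Any leverage above 1 - guard (a saturated point) makes the model invalid
    for cross-validation purposes.
    """
    h = fit.leverages
    n = h.size
    if np.any(h >= 1.0 - guard):
        nan = np.full(fit.residuals.shape[1], np.nan)
        return nan, nan.copy(), False
    loo_res = fit.residuals / (1.0 - h)[:, None]
    press = np.sum(loo_res**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pred_r2 = np.where(fit.sst > 0, 1.0 - press / fit.sst, np.nan)
    return press / n, pred_r2, True


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - k - 1); k counts non-intercept terms."""
    if n - k - 1 < 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, k={k}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass(frozen=True)
class PolynomialModel:
    """One fitted and cross-validated subset model."""

    selected: tuple            # sorted basis-term indices
    mask: int                  # bitmask over the basis
    terms: tuple               # exponent tuples of the selected terms
    coefficients: np.ndarray   # (1 + n_terms, n_responses), intercept row first
    r2: np.ndarray
    adjusted_r2: np.ndarray
    predicted_r2: np.ndarray
    loo_mse: np.ndarray
    n_terms: int
    valid: bool
    rank_deficient: bool
    press: float = float("nan")     # total PRESS over all responses
    press_se: float = float("nan")  # standard error of the total PRESS

    def summary(self, basis: MonomialBasis) -> dict:
        return {
            "terms": [basis.term_label(i) for i in self.selected],
            "exponents": [list(basis.terms[i]) for i in self.selected],
            "coefficients": self.coefficients.tolist(),
            "r2": self.r2.tolist(),
            "adjusted_r2": self.adjusted_r2.tolist(),
            "predicted_r2": self.predicted_r2.tolist(),
            "loo_mse": self.loo_mse.tolist(),
            "n_terms": self.n_terms,
            "valid": self.valid,
        }


@dataclass(frozen=True)
class SearchConfig:
    """Settings for the exhaustive enumeration."""

    max_order: int = 2
    max_terms_per_model: int | None = None
    count_only: bool = False
    budget: int = 2**20
    top_k: int = 20
    ranking: str = "one_se"    # or "predicted_r2"
    svd_rcond: float = SVD_RCOND
    leverage_guard: float = LEVERAGE_GUARD

    def __post_init__(self) -> None:
        if self.ranking not in ("one_se", "predicted_r2"):
            raise ValueError(f"unknown ranking rule {self.ranking!r}")


@dataclass(frozen=True)
class SearchResult:
    basis: MonomialBasis
    ranked: tuple              # PolynomialModel, best first
    n_enumerated: int
    n_invalid: int

    @property
    def best(self) -> PolynomialModel:
        if not self.ranked:
            raise ValueError("no valid models found")
        return self.ranked[0]


def _fit_subset(subset: tuple, mask: int, basis, X, Y, n, config) -> PolynomialModel:
    A = design_matrix(X, basis, subset)
    fit = ols_fit(A, Y, rcond=config.svd_rcond)
    k = len(subset)
    if fit.rank_deficient or fit.underdetermined or n - k - 1 < 1:
        nan = np.full(fit.r2.size, np.nan)
        return PolynomialModel(
            selected=subset, mask=mask, terms=tuple(basis.terms[i] for i in subset),
            coefficients=fit.coefficients, r2=fit.r2, adjusted_r2=nan,
            predicted_r2=nan, loo_mse=nan.copy(), n_terms=k,
            valid=False, rank_deficient=fit.rank_deficient,
        )
    loo_mse, pred_r2, cv_valid = loo_cv(fit, guard=config.leverage_guard)
    adj = np.array([adjusted_r2(r, n, k) if np.isfinite(r) else np.nan for r in fit.r2])
    valid = cv_valid and bool(np.all(np.isfinite(pred_r2)))
    if cv_valid:
        sq = (fit.residuals / (1.0 - fit.leverages)[:, None]) ** 2
        press = float(np.sum(sq))
        # SE of a sum of n per-observation contributions, per response
        press_se = float(np.sqrt(np.sum(n * np.var(sq, axis=0, ddof=1))))
    else:
        press = press_se = float("nan")
    return PolynomialModel(
        selected=subset, mask=mask, terms=tuple(basis.terms[i] for i in subset),
        coefficients=fit.coefficients, r2=fit.r2, adjusted_r2=adj,
        predicted_r2=pred_r2, loo_mse=loo_mse, n_terms=k,
        valid=valid, rank_deficient=False, press=press, press_se=press_se,
    )


def _rank_models(models: list, ranking: str, sst_total: float) -> list:
    """Deterministic total order under the configured ranking rule."""
    if not models:
        return models
    if ranking == "predicted_r2":
        # maximal mean predicted R^2; fewer terms; higher adjusted R^2; mask
        return sorted(
            models,
            key=lambda m: (
                -float(np.mean(m.predicted_r2)),
                m.n_terms,
                -float(np.mean(m.adjusted_r2)),
                m.mask,
            ),
        )
    # one-standard-error rule: parsimony among near-equivalent PRESS values;
    # the SST-relative floor keeps the band meaningful for noise-free data,
    # where all adequate models sit at floating-point-level PRESS
    best = min(models, key=lambda m: (m.press, m.mask))
    threshold = best.press + best.press_se + 1e-12 * sst_total
    within = [m for m in models if m.press <= threshold]
    outside = [m for m in models if m.press > threshold]
    within.sort(key=lambda m: (m.n_terms, m.press, m.mask))
    outside.sort(key=lambda m: (m.press, m.n_terms, m.mask))
    return within + outside


def exhaustive_search(
    X: np.ndarray,
    Y: np.ndarray,
    config: SearchConfig = SearchConfig(),
) -> SearchResult | int:
    """Fit and cross-validate every term subset; return the ranked models.

    With ``count_only`` the exact model-space size is returned without any
    fitting.  Otherwise the number of subsets (after the optional
    ``max_terms_per_model`` cap) must fit the configured budget, or a
    :class:`SearchBudgetError` naming the full count is raised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y2 = np.asarray(Y, dtype=float)
    Y2 = Y2.reshape(-1, 1) if Y2.ndim == 1 else Y2
    n, d = X.shape
    basis = monomial_terms(d, config.max_order)
    m = len(basis)
    total = model_count(d, config.max_order)
    if config.count_only:
        return total

    cap = config.max_terms_per_model
    n_subsets = (
        total if cap is None or cap >= m
        else sum(math.comb(m, j) for j in range(cap + 1))
    )
    if n_subsets > config.budget:
        raise SearchBudgetError(
            f"model space holds {n_subsets} subsets of a {m}-term basis "
            f"(full space {total}); budget is {config.budget}. "
            "Use count_only, a max_terms_per_model cap, or a larger budget."
        )
    if n < 3:
        raise ValueError("need at least 3 observations")

    models = []
    n_invalid = 0
    for mask in range(2**m):
        subset = tuple(i for i in range(m) if mask >> i & 1)
        if cap is not None and len(subset) > cap:
            continue
        model = _fit_subset(subset, mask, basis, X, Y2, n, config)
        if model.valid:
            models.append(model)
        else:
            n_invalid += 1
    sst_total = float(np.sum((Y2 - Y2.mean(axis=0)) ** 2))
    models = _rank_models(models, config.ranking, sst_total)
    return SearchResult(
        basis=basis,
        ranked=tuple(models[: config.top_k]),
        n_enumerated=n_subsets,
        n_invalid=n_invalid,
    )


def predict(model: PolynomialModel, basis: MonomialBasis, X_new: np.ndarray) -> np.ndarray:
    """Evaluate a fitted subset model on new rows."""
    if not model.valid:
        raise ValueError("cannot predict from an invalid model")
    A = design_matrix(X_new, basis, model.selected)
    return A @ model.coefficients
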