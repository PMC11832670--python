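"""Per-item fit diagnostics: Infit/Outfit mean squares and modification indices.

Both mean squares compare observed responses with the Rasch model's
expectation and have expectation ~1 under a correctly specified model.  With
``P_pi`` the model probability given person p's ability:

* Outfit_i — unweighted mean of squared standardised residuals,
  ``mean_p (y_pi - P_pi)^2 / (P_pi (1 - P_pi))``.  Sensitive to surprising
  responses from persons far from the item's difficulty.
* Infit_i — information-weighted,
  ``sum_p (y_pi - P_pi)^2 / sum_p P_pi (1 - P_pi)``.  Sensitive to misfit
  near the item's difficulty.

Because person abilities are never observed, :func:`infit_outfit` averages
the residual terms over each person's ability *posterior* (same quadrature
as the calibration) instead of plugging in a point estimate.  Plug-in
abilities shrink toward the data and deflate both statistics noticeably
below 1 under the true model; the posterior-expected forms centre at 1.
:func:`point_estimate_mean_squares` exposes the classical plug-in
computation for given probabilities.

The modification index estimates, on a 1-df chi-square scale, how much the
marginal likelihood would improve if item i's discrimination were freed from
the common Rasch value of 1 — a score (Lagrange-multiplier) test evaluated at
the Rasch estimates, with an outer-product-of-gradients information estimate
and a Schur-complement adjustment for the jointly estimated difficulties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .irt import (
    N_QUADRATURE,
    PROB_CLAMP,
    DegenerateItemError,
    FitResult,
    ResponseMatrix,
    _marginal_terms,
    gauss_hermite_normal,
)

# --- types -----------------------------------------------------------------


@dataclass
class ItemFitStats:
    """Fit diagnostics for one item."""

    item_id: str
    infit: float
    outfit: float
    mod_index: float = 0.0

    def __post_init__(self) -> None:
        if self.infit < 0 or self.outfit < 0 or self.mod_index < 0:
            raise ValueError("fit statistics must be non-negative")


@dataclass
class FitFilterConfig:
    """Mean-square acceptance band; the conventional screen is [0.7, 1.3]."""

    lower: float = 0.7
    upper: float = 1.3

    def __post_init__(self) -> None:
        if not 0 < self.lower < self.upper:
            raise ValueError("need 0 < lower < upper")


# --- operations ------------------------------------------------------------


def point_estimate_mean_squares(Y: np.ndarray, P: np.ndarray
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Classical plug-in (infit, outfit) per item for given probabilities.

    ``P[p, i]`` is the model probability at person p's (point) ability.
    """
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    if (P <= PROB_CLAMP).any() or (P >= 1 - PROB_CLAMP).any():
        warnings.warn("probabilities clamped away from 0/1 for residual "
                      "standardisation", stacklevel=2)
        P = np.clip(P, PROB_CLAMP, 1 - PROB_CLAMP)
    W = P * (1 - P)
    sq = (Y - P) ** 2
    return sq.sum(axis=0) / W.sum(axis=0), (sq / W).mean(axis=0)


def infit_outfit(fit: FitResult, data: ResponseMatrix) -> list[ItemFitStats]:
    """Infit and Outfit mean squares per item of ``fit.bank``.

    ``data`` must be the matrix the model was calibrated on (items the fit
    excluded as degenerate are ignored).  The squared standardised residuals
    are averaged over each person's ability posterior given the calibrated
    item parameters.  Modification indices are computed alongside (see
    :func:`modification_index`) so the result carries all three diagnostics.
    """
    sub = data.subset_items(fit.bank.item_ids)
    Y = sub.responses.astype(float)
    nodes, w = gauss_hermite_normal(N_QUADRATURE)
    _, r, P = _marginal_terms(Y, fit.node_difficulties,
                              fit.node_discriminations, nodes, np.log(w))
    P = np.clip(P, PROB_CLAMP, 1 - PROB_CLAMP)
    # posterior-expected standardised z^2 and residual moments, per cell
    E_inv_p = r @ ((1 - P) / P)          # E[(1-P)/P | y_p]
    E_inv_q = r @ (P / (1 - P))          # E[P/(1-P) | y_p]
    z2 = Y * E_inv_p + (1 - Y) * E_inv_q
    EP = r @ P
    EP2 = r @ P**2
    Esq = Y - 2 * Y * EP + EP2           # E[(y - P)^2]
    EW = EP - EP2                        # E[P (1 - P)]
    outfit = z2.mean(axis=0)
    infit = Esq.sum(axis=0) / EW.sum(axis=0)
    mi = _modification_indices(fit, sub)
    return [
        ItemFitStats(item_id=iid, infit=float(i), outfit=float(o),
                     mod_index=float(m))
        for iid, i, o, m in zip(fit.bank.item_ids, infit, outfit, mi)
    ]


def _modification_indices(fit: FitResult, data: ResponseMatrix) -> np.ndarray:
    """LM statistic for freeing each item's discrimination, all items at once.

    The null model is the calibrated Rasch fit (difficulties plus one common
    slope on the quadrature scale); the tested direction is the deviation of
    one item's discrimination from the common value.  Nuisance parameters
    (all difficulties and the common slope) are projected out of the score
    via a Schur complement on the OPG information.
    """
    if fit.bank.model_tag != "rasch":
        raise ValueError("modification indices are defined for a Rasch fit")
    Y = data.subset_items(fit.bank.item_ids).responses.astype(float)
    alpha = fit.node_difficulties
    a = fit.node_discriminations
    nodes, w = gauss_hermite_normal(N_QUADRATURE)
    _, r, P = _marginal_terms(Y, alpha, a, nodes, np.log(w))

    rP = r @ P
    S_alpha = (rP - Y) * a[None, :]                    # per-person dl/dalpha
    t_bar = r @ nodes
    M2 = r @ (P * nodes[:, None])
    S_a = Y * (t_bar[:, None] - alpha[None, :]) - (M2 - alpha[None, :] * rP)
    S_s = S_a.sum(axis=1, keepdims=True)               # common-slope score

    u = S_a.sum(axis=0)                                # score for each a_i
    B_aa = np.einsum("pi,pi->i", S_a, S_a)
    N = np.hstack([S_alpha, S_s])                      # nuisance scores
    C = N.T @ S_a                                      # (K+1, K): cross info
    B_nui = N.T @ N
    # denom_i = B_aa_i - c_i' B_nui^{-1} c_i  (Schur complement, per item)
    sol = np.linalg.solve(B_nui, C)
    denom = B_aa - np.einsum("ki,ki->i", C, sol)
    denom = np.clip(denom, 1e-12, None)
    return u**2 / denom


def modification_index(fit: FitResult, data: ResponseMatrix,
                       item_id: str) -> float:
    """Modification index (1-df chi-square scale) for a single item."""
    if item_id in fit.excluded_item_ids:
        raise DegenerateItemError(
            f"item {item_id!r} was excluded as degenerate; no index defined")
    if item_id not in fit.bank.item_ids:
        raise ValueError(f"item {item_id!r} is not in the calibrated bank")
    j = fit.bank.item_ids.index(item_id)
    col = data.subset_items(fit.bank.item_ids).responses[:, j]
    if col.min() == col.max():
        raise DegenerateItemError(f"item {item_id!r} has constant responses")
    return float(_modification_indices(fit, data)[j])


def filter_by_fit(stats: list[ItemFitStats],
                  config: FitFilterConfig | None = None) -> list[str]:
    """Item ids whose Infit AND Outfit lie inside the acceptance band.

    Boundary values are retained: the screen excludes values strictly below
    ``lower`` or strictly above ``upper``.
    """
    if not stats:
        raise ValueError("stats must be non-empty")
    cfg = config or FitFilterConfig()
    return [
        s.item_id for s in stats
        if cfg.lower <= s.infit <= cfg.upper
        and cfg.lower <= s.outfit <= cfg.upper
    ]
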