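"""Internal-consistency and model-based reliability for the final pool."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .irt import FitResult, ResponseMatrix


@dataclass
class ReliabilityReport:
    kr20: float
    andrich: float
    n_persons: int
    n_items: int

    def to_dict(self) -> dict:
        return {"kr20": self.kr20, "andrich": self.andrich,
                "n_persons": self.n_persons, "n_items": self.n_items}


def kr20(data: ResponseMatrix) -> float:
    """Kuder-Richardson formula 20 internal consistency.

    ``(k / (k - 1)) * (1 - sum_j p_j (1 - p_j) / s2_X)`` with ``p_j`` the
    per-item endorsement proportion and ``s2_X`` the sample (n-1) variance of
    person total scores.  Invariant to person and item order.
    """
    Y = data.responses.astype(float)
    k = Y.shape[1]
    if k < 2:
        raise ValueError("KR-20 needs at least 2 items")
    total = Y.sum(axis=1)
    s2 = float(np.var(total, ddof=1))
    if s2 == 0:
        raise ValueError("total-score variance is zero")
    p = Y.mean(axis=0)
    return float(k / (k - 1) * (1 - np.sum(p * (1 - p)) / s2))


def andrich_reliability(fit: FitResult) -> float:
    """Person-separation reliability from a calibrated fit.

    The share of observed ability variance not attributable to estimation
    error: ``(Var(theta_hat) - mean(se^2)) / Var(theta_hat)``, floored at 0.
    Persons whose ability carries a divergent (convention-valued or
    infinite-SE) estimate are excluded; their pseudo-values would corrupt the
    observed variance.
    """
    pairs = [(ab.theta, ab.se) for ab in fit.abilities
             if ab.method_tag != "convention" and np.isfinite(ab.se)]
    if len(pairs) < 2:
        raise ValueError("need at least 2 persons with finite estimates")
    theta = np.array([t for t, _ in pairs])
    se2 = np.array([s for _, s in pairs]) ** 2
    var_t = float(np.var(theta, ddof=1))
    if var_t == 0:
        raise ValueError("ability variance is zero")
    return max(0.0, (var_t - float(se2.mean())) / var_t)


def reliability_report(data: ResponseMatrix, fit: FitResult) -> ReliabilityReport:
    """Both indices for the same calibrated pool."""
    return ReliabilityReport(kr20=kr20(data), andrich=andrich_reliability(fit),
                             n_persons=data.n_persons, n_items=data.n_items)
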