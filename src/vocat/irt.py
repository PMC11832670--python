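"""Item response models: calibration and ability estimation.

Dichotomous one-parameter (Rasch) and two-parameter (2PL) logistic models.
The probability that person :math:`p` endorses item :math:`i` is

.. math::

    P(y_{pi} = 1 \\mid \\theta_p) =
        \\frac{1}{1 + e^{-a_i(\\theta_p - \\alpha_i)}}

with latent ability :math:`\\theta_p`, item difficulty :math:`\\alpha_i`
(logits) and item discrimination :math:`a_i` (fixed to 1 under Rasch).

Item parameters are estimated by marginal maximum likelihood (MML): the
latent ability is integrated out against a standard-normal distribution with
Gauss-Hermite quadrature, which fixes the identification (latent mean 0,
variance 1).  Person abilities are EAP posterior means after calibration;
:func:`estimate_ability_ml` gives the maximum-likelihood ability used during
adaptive administration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, log_expit, logsumexp

# --- module-wide numerical configuration -----------------------------------

#: Number of Gauss-Hermite quadrature nodes for the latent-ability integral.
N_QUADRATURE = 61

#: Gradient infinity-norm tolerance (per-person mean log-likelihood scale)
#: below which a calibration counts as converged.
CALIBRATION_GTOL = 1e-6

#: Bracket tolerance for the one-dimensional ability line search, in logits.
ABILITY_XTOL = 1e-9

#: Box constraints on estimated 2PL discriminations.
DISCRIMINATION_BOUNDS = (0.05, 10.0)

#: Convention ability assigned to an all-"no" / all-"yes" response pattern,
#: where the maximum-likelihood estimate diverges.
CONVENTION_THETA_NO = -10.0
CONVENTION_THETA_YES = 10.0

#: Probability clamp used wherever a residual is standardised by P(1-P).
PROB_CLAMP = 1e-10

WORD_TYPES = ("noun", "verb", "adjective")


def gauss_hermite_normal(n: int = N_QUADRATURE) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and weights for a standard-normal integral.

    Returns ``(nodes, weights)`` such that ``sum(w * f(x))`` approximates
    ``E[f(Z)]`` for ``Z ~ N(0, 1)``.
    """
    x, w = hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


# --- domain types ----------------------------------------------------------


class DegenerateItemError(ValueError):
    """Raised when an operation requires a non-constant item column."""


@dataclass
class ResponseMatrix:
    """Complete persons x items binary response data.

    ``responses[p, i] = 1`` means person ``p`` endorses item ``i`` ("says the
    word").  The data contract is complete-data: every cell must be exactly
    0 or 1; missingness has to be handled upstream, never passed in silently.
    """

    person_ids: list[str]
    item_ids: list[str]
    responses: np.ndarray
    age: np.ndarray | None = None
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D persons x items array")
        n_p, n_i = self.responses.shape
        if len(self.person_ids) != n_p or len(self.item_ids) != n_i:
            raise ValueError(
                f"id lists ({len(self.person_ids)} persons, {len(self.item_ids)} "
                f"items) do not match responses shape {self.responses.shape}"
            )
        if len(set(self.person_ids)) != n_p:
            raise ValueError("person_ids are not unique")
        if len(set(self.item_ids)) != n_i:
            raise ValueError("item_ids are not unique")
        vals = np.unique(self.responses)
        if not np.isin(vals, [0, 1]).all():
            bad = [v for v in vals if v not in (0, 1)]
            raise ValueError(f"responses must be 0/1; found {bad}")
        self.responses = self.responses.astype(np.int8)
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if self.age.shape != (n_p,):
                raise ValueError("age must have one entry per person")
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
            if self.group.shape != (n_p,):
                raise ValueError("group must have one entry per person")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def subset_items(self, item_ids: list[str]) -> "ResponseMatrix":
        """Restrict to the given items, preserving their requested order."""
        index = {iid: j for j, iid in enumerate(self.item_ids)}
        cols = [index[iid] for iid in item_ids]
        return ResponseMatrix(
            person_ids=list(self.person_ids),
            item_ids=list(item_ids),
            responses=self.responses[:, cols],
            age=None if self.age is None else self.age.copy(),
            group=None if self.group is None else self.group.copy(),
        )

    def subset_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ResponseMatrix(
            person_ids=[p for p, m in zip(self.person_ids, mask) if m],
            item_ids=list(self.item_ids),
            responses=self.responses[mask],
            age=None if self.age is None else self.age[mask],
            group=None if self.group is None else self.group[mask],
        )


@dataclass
class Item:
    """A single calibrated checklist item (a word)."""

    item_id: str
    word: str = ""
    word_type: str = "noun"
    difficulty: float = 0.0
    discrimination: float = 1.0
    difficulty_se: float | None = None

    def __post_init__(self) -> None:
        if self.word_type not in WORD_TYPES:
            raise ValueError(
                f"word_type must be one of {WORD_TYPES}, got {self.word_type!r}"
            )
        if not self.discrimination > 0:
            raise ValueError("discrimination must be positive")


@dataclass
class ItemBank:
    """Ordered collection of calibrated items."""

    items: list[Item]
    model_tag: str = "rasch"

    def __post_init__(self) -> None:
        if self.model_tag not in ("rasch", "2pl"):
            raise ValueError("model_tag must be 'rasch' or '2pl'")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids in bank are not unique")
        if self.model_tag == "rasch":
            for it in self.items:
                if it.discrimination != 1.0:
                    raise ValueError(
                        "model_tag='rasch' requires all discriminations equal 1"
                    )

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def difficulties(self) -> np.ndarray:
        return np.array([it.difficulty for it in self.items])

    @property
    def discriminations(self) -> np.ndarray:
        return np.array([it.discrimination for it in self.items])

    def subset(self, item_ids: list[str]) -> "ItemBank":
        index = {it.item_id: it for it in self.items}
        return ItemBank(items=[index[iid] for iid in item_ids],
                        model_tag=self.model_tag)


@dataclass
class AbilityEstimate:
    """A latent-ability estimate with its standard error."""

    theta: float
    se: float
    method_tag: str = "ml"

    def __post_init__(self) -> None:
        if self.method_tag not in ("ml", "eap", "wle", "convention"):
            raise ValueError(f"unknown method_tag {self.method_tag!r}")
        if self.method_tag == "convention" and self.theta not in (-10.0, 0.0, 10.0):
            raise ValueError("convention estimates must be -10, 0 or +10")
        if np.isfinite(self.se) and not self.se > 0:
            raise ValueError("finite se must be positive")


@dataclass
class FitResult:
    """Output of a marginal-maximum-likelihood calibration."""

    bank: ItemBank
    abilities: list[AbilityEstimate]
    log_likelihood: float
    converged: bool
    n_excluded_degenerate: int = 0
    excluded_item_ids: list[str] = field(default_factory=list)
    #: joint OPG sampling covariance of the internal parameter vector
    #: (difficulties on the quadrature scale, then common slope if any, then
    #: free discriminations); basis of the Wald intervals
    param_cov: np.ndarray | None = None
    #: internal item parameters on the N(0,1)-latent quadrature scale; these
    #: reproduce the marginal likelihood and ability posteriors (the public
    #: bank of a Rasch fit is an equivalent rescaling with unit slopes)
    node_difficulties: np.ndarray | None = None
    node_discriminations: np.ndarray | None = None
    #: number of freely estimated parameters (difficulties + slope dof)
    n_params: int = 0


# --- item characteristic curve ---------------------------------------------


def icc(theta, item: Item):
    """Item characteristic curve: P(endorse | theta) for one item.

    Strictly increasing in ``theta``; equals 0.5 exactly at
    ``theta = item.difficulty``.  Accepts scalar or array ``theta``.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("theta must be finite")
    out = expit(item.discrimination * (theta - item.difficulty))
    return float(out) if out.ndim == 0 else out


def _prob_matrix(theta: np.ndarray, difficulties: np.ndarray,
                 discriminations: np.ndarray) -> np.ndarray:
    """Endorsement probabilities, shape (len(theta), n_items)."""
    return expit(discriminations[None, :]
                 * (theta[:, None] - difficulties[None, :]))


# --- marginal maximum likelihood -------------------------------------------


def _degenerate_columns(Y: np.ndarray) -> np.ndarray:
    col_sums = Y.sum(axis=0)
    return (col_sums == 0) | (col_sums == Y.shape[0])


def _marginal_terms(Y, alpha, a, nodes, log_w):
    """Log person-likelihood pieces for the MML objective and gradient.

    Returns ``(lp, r, P)`` where ``lp[p]`` is the marginal log-likelihood of
    person p, ``r[p, q]`` the posterior weight of quadrature node q given
    person p's responses, and ``P[q, i]`` the node x item probabilities.
    """
    Z = a[None, :] * (nodes[:, None] - alpha[None, :])    # (Q, K)
    P = expit(Z)
    logP = log_expit(Z)
    log1mP = log_expit(-Z)
    logf = Y @ logP.T + (1 - Y) @ log1mP.T                # (N, Q)
    logf += log_w[None, :]
    lp = logsumexp(logf, axis=1)
    r = np.exp(logf - lp[:, None])
    return lp, r, P


def fit_mml(Y: np.ndarray, item_ids: list[str], *, model: str = "rasch",
            free_disc: np.ndarray | None = None,
            n_quadrature: int = N_QUADRATURE,
            gtol: float = CALIBRATION_GTOL,
            words: list[str] | None = None,
            word_types: list[str] | None = None) -> FitResult:
    """Marginal-maximum-likelihood calibration on a 0/1 matrix.

    The workhorse behind :func:`fit_rasch` and :func:`fit_2pl`.

    Internally every model is a 2PL on a standard-normal latent (quadrature
    scale).  ``model='rasch'`` constrains all discriminations to one *common*
    free slope — equivalent to a Rasch model with a freely estimated latent
    variance — and the public bank is reported in the Rasch metric (unit
    slopes, difficulties and abilities multiplied by the common slope), which
    leaves every response probability unchanged.  ``free_disc`` additionally
    frees the discrimination of selected items from the common value (used
    e.g. to form likelihood-ratio oracles for the modification index; the
    result is then reported on the quadrature scale with ``model_tag='2pl'``).
    Constant columns carry no information about a finite difficulty and are
    excluded with a report.
    """
    Y = np.asarray(Y, dtype=float)
    n_persons, n_items_in = Y.shape
    if n_persons < 2 or n_items_in < 2:
        raise ValueError("need at least 2 persons and 2 items")

    degenerate = _degenerate_columns(Y)
    excluded = [iid for iid, d in zip(item_ids, degenerate) if d]
    keep = ~degenerate
    Y = Y[:, keep]
    kept_ids = [iid for iid, k in zip(item_ids, keep) if k]
    K = Y.shape[1]
    if K < 2:
        raise ValueError("fewer than 2 non-degenerate items remain")

    common_slope = model == "rasch"
    if free_disc is None:
        free_disc = np.zeros(n_items_in, dtype=bool) if common_slope \
            else np.ones(n_items_in, dtype=bool)
    free_disc = np.asarray(free_disc, dtype=bool)[keep]
    if not common_slope and not free_disc.all():
        raise ValueError("2PL fits estimate every discrimination")
    n_free_a = int(free_disc.sum())
    common_mask = ~free_disc
    n_slopes = (1 if common_slope else 0) + n_free_a

    if model == "2pl" and n_persons < 2 * K:
        warnings.warn(
            f"2PL fit with {n_persons} persons on {K} items; fewer than "
            "2x items persons may give unstable discriminations",
            stacklevel=2,
        )

    nodes, w = gauss_hermite_normal(n_quadrature)
    log_w = np.log(w)

    # starting values: logit of proportion correct, slopes 1
    p_obs = np.clip(Y.mean(axis=0), 0.01, 0.99)
    alpha0 = -np.log(p_obs / (1 - p_obs))
    x0 = np.concatenate([alpha0, np.ones(n_slopes)])

    lo, hi = DISCRIMINATION_BOUNDS
    bounds = [(None, None)] * K + [(lo, hi)] * n_slopes

    def unpack(x):
        alpha = x[:K]
        a = np.ones(K)
        pos = K
        if common_slope:
            a[common_mask] = x[pos]
            pos += 1
        a[free_disc] = x[pos:]
        return alpha, a

    def slope_scores(Y_, alpha, rP, r, P):
        # per-person d logL / d a_i = E_post[(y - P)(z_q - alpha_i)]
        t_bar = r @ nodes                                 # (N,)
        M2 = r @ (P * nodes[:, None])                     # (N, K)
        return Y_ * (t_bar[:, None] - alpha[None, :]) \
            - (M2 - alpha[None, :] * rP)

    def objective(x):
        alpha, a = unpack(x)
        lp, r, P = _marginal_terms(Y, alpha, a, nodes, log_w)
        nll = -lp.mean()
        rP = r @ P                                        # (N, K) E_post[P]
        g_alpha = (Y - rP).mean(axis=0) * a               # d nll / d alpha
        grad = [g_alpha]
        s_a = slope_scores(Y, alpha, rP, r, P)
        if common_slope:
            grad.append([-s_a.mean(axis=0)[common_mask].sum()])
        if n_free_a:
            grad.append(-s_a.mean(axis=0)[free_disc])
        return nll, np.concatenate(grad)

    res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 2000, "gtol": gtol, "ftol": 1e-14})
    alpha_hat, a_hat = unpack(res.x)
    # projected gradient: a coordinate pinned at a bound is optimal when the
    # gradient points out of the feasible box
    pg = res.jac.copy()
    for j, (blo, bhi) in enumerate(bounds):
        if blo is not None and res.x[j] <= blo + 1e-10 and pg[j] > 0:
            pg[j] = 0.0
        if bhi is not None and res.x[j] >= bhi - 1e-10 and pg[j] < 0:
            pg[j] = 0.0
    grad_norm = float(np.max(np.abs(pg)))
    converged = grad_norm < max(gtol, 1e-5)
    if not converged:
        warnings.warn(
            f"calibration did not reach gradient tolerance "
            f"(|grad|_inf = {grad_norm:.2e})", stacklevel=2)

    if (np.any(a_hat <= lo * (1 + 1e-8))
            or np.any(a_hat >= hi * (1 - 1e-8))):
        warnings.warn("a discrimination estimate hit its bound "
                      f"[{lo}, {hi}]", stacklevel=2)

    lp, r, P = _marginal_terms(Y, alpha_hat, a_hat, nodes, log_w)

    # parameter covariance: outer-product-of-gradients information estimate
    rP = r @ P
    scores_alpha = (rP - Y) * a_hat[None, :]              # per-person scores
    s_a = slope_scores(Y, alpha_hat, rP, r, P)
    score_blocks = [scores_alpha]
    if common_slope:
        score_blocks.append(s_a[:, common_mask].sum(axis=1, keepdims=True))
    if n_free_a:
        score_blocks.append(s_a[:, free_disc])
    S = np.hstack(score_blocks)
    info = S.T @ S
    try:
        cov = np.linalg.inv(info)
        alpha_se = np.sqrt(np.clip(np.diag(cov)[:K], 0, None))
    except np.linalg.LinAlgError:                         # pragma: no cover
        cov = None
        alpha_se = np.full(K, np.nan)

    # EAP abilities and posterior SDs (quadrature scale)
    theta_eap = r @ nodes
    theta_var = r @ nodes**2 - theta_eap**2
    theta_sd = np.sqrt(np.clip(theta_var, 1e-12, None))

    pure_rasch = common_slope and n_free_a == 0
    model_tag = "rasch" if pure_rasch else "2pl"
    if pure_rasch:
        # rescale to the Rasch metric: unit slopes, latent N(0, s^2)
        s_common = float(a_hat[0])
        difficulty = s_common * alpha_hat
        disc_report = np.ones(K)
        if cov is not None:
            # delta method for d_i = s * alpha_i using cov of (alpha_i, s)
            var_d = (s_common**2 * np.diag(cov)[:K]
                     + alpha_hat**2 * cov[K, K]
                     + 2 * s_common * alpha_hat * cov[:K, K])
            difficulty_se = np.sqrt(np.clip(var_d, 0, None))
        else:                                             # pragma: no cover
            difficulty_se = np.full(K, np.nan)
        theta_eap = s_common * theta_eap
        theta_sd = s_common * theta_sd
    else:
        difficulty = alpha_hat
        disc_report = a_hat
        difficulty_se = alpha_se

    wlist = words if words is not None else kept_ids
    tlist = word_types if word_types is not None else ["noun"] * n_items_in
    kept_words = [w_ for w_, k in zip(wlist, keep) if k] \
        if len(wlist) == n_items_in else kept_ids
    kept_types = [t for t, k in zip(tlist, keep) if k] \
        if len(tlist) == n_items_in else ["noun"] * K

    items = [
        Item(item_id=iid, word=w_, word_type=t, difficulty=float(al),
             discrimination=float(av), difficulty_se=float(se))
        for iid, w_, t, al, av, se
        in zip(kept_ids, kept_words, kept_types, difficulty, disc_report,
               difficulty_se)
    ]
    bank = ItemBank(items=items, model_tag=model_tag)
    abilities = [AbilityEstimate(float(t), float(s), "eap")
                 for t, s in zip(theta_eap, theta_sd)]
    return FitResult(
        bank=bank,
        abilities=abilities,
        log_likelihood=float(lp.sum()),
        converged=converged,
        n_excluded_degenerate=len(excluded),
        excluded_item_ids=excluded,
        param_cov=cov,
        node_difficulties=alpha_hat,
        node_discriminations=a_hat,
        n_params=K + n_slopes,
    )


def fit_rasch(data: ResponseMatrix, **kwargs) -> FitResult:
    """Calibrate a Rasch model (all discriminations fixed at 1) by MML."""
    return fit_mml(data.responses, data.item_ids, model="rasch", **kwargs)


def fit_2pl(data: ResponseMatrix, **kwargs) -> FitResult:
    """Calibrate a 2PL model (item-specific discriminations) by MML."""
    return fit_mml(data.responses, data.item_ids, model="2pl", **kwargs)


# --- person-ability estimation ---------------------------------------------


def _ability_loglik(theta: float, y: np.ndarray, alpha: np.ndarray,
                    a: np.ndarray) -> float:
    z = a * (theta - alpha)
    # log P = -log(1+e^-z); log (1-P) = -log(1+e^z)
    return float(np.sum(y * z - np.logaddexp(0.0, z)))


def estimate_ability_ml(responses, items: ItemBank) -> AbilityEstimate:
    """Maximum-likelihood ability for one response vector on calibrated items.

    Maximises ``L(theta) = prod_i exp(y_i (theta - alpha_i)) /
    (1 + exp(theta - alpha_i))`` (with slopes under a 2PL bank) by a bounded
    line search.  A uniform response pattern has no finite maximiser; the
    conventional values -10 (all "no") / +10 (all "yes") are returned with
    ``method_tag='convention'``.  The standard error is
    ``1 / sqrt(sum a_i^2 P_i (1 - P_i))`` at the returned ability.
    """
    y = np.asarray(responses, dtype=float)
    if y.size == 0:
        raise ValueError("empty response vector")
    if y.shape != (len(items),):
        raise ValueError(
            f"got {y.size} responses for {len(items)} items")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("responses must be 0/1")

    alpha = items.difficulties
    a = items.discriminations

    if y.min() == y.max():
        theta = CONVENTION_THETA_YES if y[0] == 1 else CONVENTION_THETA_NO
        return AbilityEstimate(theta=theta,
                               se=ability_se(theta, items),
                               method_tag="convention")

    res = minimize_scalar(lambda t: -_ability_loglik(t, y, alpha, a),
                          bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": ABILITY_XTOL})
    theta = float(res.x)
    return AbilityEstimate(theta=theta, se=ability_se(theta, items),
                           method_tag="ml")


def ability_se(theta: float, items: ItemBank) -> float:
    """Standard error of an ability estimate from Fisher information.

    ``1 / sqrt(sum_i a_i^2 P_i (1 - P_i))`` evaluated at ``theta``; for a
    Rasch bank (all slopes 1) this is exactly ``1 / sqrt(sum P_i (1-P_i))``.
    Weakly decreasing as items are added at fixed ``theta``.
    """
    if len(items) == 0:
        raise ValueError("need at least one item")
    P = _prob_matrix(np.atleast_1d(float(theta)), items.difficulties,
                     items.discriminations)[0]
    info = float(np.sum(items.discriminations**2 * P * (1 - P)))
    if info <= 0:                                         # pragma: no cover
        return float("inf")
    return 1.0 / np.sqrt(info)
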