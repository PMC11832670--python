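"""Adaptive test administration.

The session loop alternates provisional ability estimation, nearest-difficulty
item selection and response collection:

* the ability starts at 0 before any response;
* while the response pattern is uniform (all "no" / all "yes") the
  maximum-likelihood estimate diverges and the conventional values -10 / +10
  are used instead;
* otherwise the ability is the maximum-likelihood estimate on the items
  administered so far;
* the next item is the free item whose difficulty is nearest the current
  ability — for a Rasch bank this coincides with maximum-information
  selection;
* the session stops once the ability standard error falls to the requested
  threshold (only evaluated while the ML estimate is finite), or when the
  pool (or an item budget) is exhausted.

The transcript records every administered item with its word and difficulty,
the response pattern, the ability/SE trajectory and the stop reason —
everything needed to re-estimate the final ability offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .irt import AbilityEstimate, Item, ItemBank, estimate_ability_ml


class PoolExhausted(Exception):
    """Distinct signal that no unadministered item remains (not bad input)."""


@dataclass
class CatConfig:
    """Stopping configuration; ``se_threshold`` of 0.3-0.5 is typical."""

    se_threshold: float = 0.4
    max_items: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.se_threshold > 0:
            raise ValueError("se_threshold must be positive")


@dataclass
class AdministeredItem:
    item_id: str
    word: str
    difficulty: float


@dataclass
class CatSession:
    """Complete transcript of one adaptive administration."""

    administered: list[AdministeredItem] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    trajectory: list[tuple[float, float]] = field(default_factory=list)
    final: AbilityEstimate | None = None
    stop_reason: str | None = None
    config: CatConfig | None = None

    def to_dict(self) -> dict:
        return {
            "theta": self.final.theta if self.final else None,
            "se": self.final.se if self.final else None,
            "items": [{"item_id": it.item_id, "word": it.word,
                       "difficulty": it.difficulty}
                      for it in self.administered],
            "responses": list(self.responses),
            "trajectory": [{"theta": t, "se": s} for t, s in self.trajectory],
            "stop_reason": self.stop_reason,
            "config": {"se_threshold": self.config.se_threshold,
                       "max_items": self.config.max_items,
                       "seed": self.config.seed} if self.config else None,
        }


def provisional_ability(responses: list[int],
                        items: ItemBank) -> AbilityEstimate:
    """Ability given the session history so far.

    Empty history starts at 0; a uniform history gets the -10/+10 convention;
    a mixed history delegates to the maximum-likelihood estimator.
    """
    if len(responses) == 0:
        return AbilityEstimate(theta=0.0, se=float("inf"),
                               method_tag="convention")
    return estimate_ability_ml(responses, items)


def next_item(bank: ItemBank, administered: list[str],
              theta: float) -> Item:
    """Unadministered item with difficulty nearest the current ability.

    Ties are broken by lower difficulty, then by item id, so selection is
    deterministic.  Raises :class:`PoolExhausted` when no item remains.
    """
    seen = set(administered)
    free = [it for it in bank if it.item_id not in seen]
    if not free:
        raise PoolExhausted("all items have been administered")
    return min(free, key=lambda it: (abs(it.difficulty - theta),
                                     it.difficulty, it.item_id))


def run_session(bank: ItemBank, responder: Callable[[Item], int],
                config: CatConfig | None = None) -> CatSession:
    """Administer one adaptive session against a response callback.

    ``responder`` receives each selected :class:`~vocat.irt.Item` and must
    return 0 or 1.  A non-binary return aborts the session with the partial
    transcript preserved on the raised error.
    """
    cfg = config or CatConfig()
    max_items = cfg.max_items if cfg.max_items is not None else len(bank)
    session = CatSession(config=cfg)

    while True:
        est = provisional_ability(session.responses,
                                  bank.subset([it.item_id for it
                                               in session.administered]))
        if (est.method_tag != "convention" and np.isfinite(est.se)
                and est.se <= cfg.se_threshold):
            session.stop_reason = "se_reached"
            break
        if len(session.administered) >= max_items:
            session.stop_reason = ("max_items" if max_items < len(bank)
                                   else "pool_exhausted")
            break
        try:
            item = next_item(bank,
                             [it.item_id for it in session.administered],
                             est.theta)
        except PoolExhausted:
            session.stop_reason = "pool_exhausted"
            break
        resp = responder(item)
        if resp not in (0, 1):
            err = ValueError(
                f"responder returned non-binary {resp!r} for item "
                f"{item.item_id}")
            err.partial_session = session  # type: ignore[attr-defined]
            raise err
        session.administered.append(AdministeredItem(
            item_id=item.item_id, word=item.word, difficulty=item.difficulty))
        session.responses.append(int(resp))
        est = provisional_ability(session.responses,
                                  bank.subset([it.item_id for it
                                               in session.administered]))
        session.trajectory.append((est.theta, est.se))

    session.final = provisional_ability(
        session.responses,
        bank.subset([it.item_id for it in session.administered]))
    return session


@dataclass
class CatSummary:
    """Aggregate performance of simulated adaptive sessions."""

    mean_items: float
    bias: float
    rmse: float
    exhaustion_rate: float
    n_sessions: int


def simulate_cat(bank: ItemBank, theta_true, config: CatConfig | None = None,
                 n_replicates: int = 1, seed: int = 0,
                 return_sessions: bool = False):
    """Simulate Rasch responders through the adaptive engine.

    Each replicate at each true ability answers item ``i`` positively with
    probability ``icc(theta_true, item_i)``.  Sessions that end on a
    convention-valued ability (uniform pattern) are excluded from bias/RMSE
    but counted in the item and exhaustion summaries.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    cfg = config or CatConfig()
    rng = np.random.default_rng(seed)
    theta_true = np.atleast_1d(np.asarray(theta_true, dtype=float))

    sessions, errors, n_items_used, exhausted = [], [], [], 0
    for t in theta_true:
        for _ in range(n_replicates):
            def responder(item: Item, _t=t) -> int:
                from .irt import icc
                return int(rng.random() < icc(_t, item))
            s = run_session(bank, responder, cfg)
            n_items_used.append(len(s.administered))
            exhausted += s.stop_reason == "pool_exhausted"
            if s.final.method_tag != "convention":
                errors.append(s.final.theta - t)
            if return_sessions:
                sessions.append(s)
    errors = np.asarray(errors)
    summary = CatSummary(
        mean_items=float(np.mean(n_items_used)),
        bias=float(errors.mean()) if errors.size else float("nan"),
        rmse=float(np.sqrt((errors**2).mean())) if errors.size else float("nan"),
        exhaustion_rate=exhausted / len(n_items_used),
        n_sessions=len(n_items_used),
    )
    return (summary, sessions) if return_sessions else summary
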