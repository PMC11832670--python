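"""Synthetic item banks and response matrices with the study's structure.

The generator emulates a vocabulary-checklist calibration study: a pool of
379 words (197 nouns, 92 verbs, 90 adjectives) whose difficulties increase
with a rated age-of-acquisition (AoA) grade, answered completely by 1190
caregivers of children aged 3-8 years, with abilities that increase with
age.  A configurable fraction of items violates the Rasch model (injected
discriminations far from 1) and group-specific difficulty shifts can be
injected to exercise the DIF screen.  A truth record accompanies every
artefact so recovery can be checked against the generating parameters.

All randomness flows from the single seed in :class:`GeneratorConfig`; equal
configurations reproduce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .irt import Item, ItemBank, ResponseMatrix

# discriminations given to misfit items: half theta-independent noise items
# (slope ~ 0), half over-discriminating (slope 3)
MISFIT_DISCRIMINATIONS = (0.0, 3.0)


@dataclass
class GeneratorConfig:
    """Generating parameters; the defaults mirror the calibration study.

    ``theta_intercept``/``theta_slope``/``theta_sd`` define the latent
    ability model ``theta = intercept + slope * age + Normal(0, sd)``; the
    default -5.5 + 1.0/year centres abilities near 0 at age 5.5 with roughly
    unit spread around the age trend.  Difficulties map monotonically from a
    simulated AoA grade onto ``difficulty_range`` logits.
    """

    n_items: int = 379
    n_persons: int = 1190
    word_type_counts: dict[str, int] = field(
        default_factory=lambda: {"noun": 197, "verb": 92, "adjective": 90})
    difficulty_range: tuple[float, float] = (-4.0, 4.0)
    aoa_range: tuple[float, float] = (1.0, 10.0)
    theta_intercept: float = -5.5
    theta_slope: float = 1.0
    theta_sd: float = 1.0
    age_range: tuple[float, float] = (3.0, 8.0)
    misfit_fraction: float = 0.25
    dif_items: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_persons < 1:
            raise ValueError("counts must be positive")
        if sum(self.word_type_counts.values()) != self.n_items:
            raise ValueError(
                f"word_type_counts sum to {sum(self.word_type_counts.values())}"
                f", expected n_items = {self.n_items}")
        if not 0 <= self.misfit_fraction <= 1:
            raise ValueError("misfit_fraction must be in [0, 1]")


def make_item_bank(config: GeneratorConfig | None = None
                   ) -> tuple[ItemBank, dict]:
    """Generate an item bank plus a truth record.

    Each item gets a simulated AoA rating; difficulties are an affine,
    strictly increasing map of AoA rank onto ``difficulty_range``, so the
    difficulty/AoA rank correlation is exactly 1.  ``misfit_fraction`` of the
    items receive a true discrimination drawn from
    :data:`MISFIT_DISCRIMINATIONS` (alternating) instead of the Rasch value
    1; the bank itself always records the nominal Rasch parameterisation,
    the truth record the generating one.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    aoa = np.sort(rng.uniform(*cfg.aoa_range, size=cfg.n_items))
    lo, hi = cfg.difficulty_range
    ranks = np.arange(cfg.n_items)
    difficulty = lo + (hi - lo) * ranks / max(cfg.n_items - 1, 1)

    word_types = np.array(
        [t for t, c in cfg.word_type_counts.items() for _ in range(c)],
        dtype=object)
    rng.shuffle(word_types)

    n_misfit = int(round(cfg.misfit_fraction * cfg.n_items))
    misfit_idx = rng.choice(cfg.n_items, size=n_misfit, replace=False)
    true_disc = np.ones(cfg.n_items)
    for j, idx in enumerate(np.sort(misfit_idx)):
        true_disc[idx] = MISFIT_DISCRIMINATIONS[j % len(MISFIT_DISCRIMINATIONS)]

    width = len(str(cfg.n_items))
    items = [
        Item(item_id=f"w{k:0{width}d}", word=f"word_{k:0{width}d}",
             word_type=str(wt), difficulty=float(d), discrimination=1.0)
        for k, (wt, d) in enumerate(zip(word_types, difficulty))
    ]
    bank = ItemBank(items=items, model_tag="rasch")
    truth = {
        "aoa": aoa,
        "difficulty": difficulty,
        "discrimination": true_disc,
        "misfit_item_ids": [items[i].item_id for i in np.sort(misfit_idx)],
        "seed": cfg.seed,
    }
    return bank, truth


def simulate_responses(bank: ItemBank, truth: dict,
                       config: GeneratorConfig | None = None
                       ) -> tuple[ResponseMatrix, dict]:
    """Simulate a complete response matrix from a generated bank.

    Ages are uniform on ``age_range``; abilities follow the linear age model
    plus noise; responses are Bernoulli draws from the 2PL curve with each
    item's *true* discrimination, plus any injected group difficulty shifts.
    A binary ``sex`` group label ('f'/'m') is attached for the DIF screen.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed + 1)

    n = cfg.n_persons
    age = rng.uniform(*cfg.age_range, size=n)
    theta = (cfg.theta_intercept + cfg.theta_slope * age
             + rng.normal(0.0, cfg.theta_sd, size=n))
    group = np.where(rng.random(n) < 0.5, "f", "m").astype(object)

    alpha = truth["difficulty"]
    a = truth["discrimination"]
    # person x item difficulty shifts for injected DIF
    shift = np.zeros((n, len(bank)))
    ids = bank.item_ids
    for item_id, g, delta in cfg.dif_items:
        j = ids.index(item_id)
        shift[group == g, j] += delta

    P = expit(a[None, :] * (theta[:, None] - (alpha[None, :] + shift)))
    Y = (rng.random((n, len(bank))) < P).astype(np.int8)

    width = len(str(n))
    data = ResponseMatrix(
        person_ids=[f"p{k:0{width}d}" for k in range(n)],
        item_ids=list(ids),
        responses=Y,
        age=age,
        group=group,
    )
    person_truth = {"theta": theta, "age": age, "group": group,
                    "seed": cfg.seed}
    return data, person_truth


def generate_study(config: GeneratorConfig | None = None
                   ) -> tuple[ItemBank, ResponseMatrix, dict]:
    """Bank + responses + merged truth record in one call."""
    cfg = config or GeneratorConfig()
    bank, item_truth = make_item_bank(cfg)
    data, person_truth = simulate_responses(bank, item_truth, cfg)
    truth = {"items": item_truth, "persons": person_truth}
    return bank, data, truth
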