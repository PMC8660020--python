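"""Synthetic co-labeling cohorts.

Each animal contributes a binary vector: one entry per reporter-positive
(Tdt+) cell, 1 if the cell is also positive for the second label (Ctb or
cFos).  Entries are independent Bernoulli(p) draws with p the group's true
co-labeling probability, which is the ground truth attached to each group.
"""

from __future__ import annotations

from dataclasses import dataclass

from natalmap.resampling import AnimalVector
from natalmap.seeding import child_rng

__all__ = ["CohortGroupSpec", "CohortSimParams", "simulate_colabel_cohort"]


@dataclass(frozen=True)
class CohortGroupSpec:
    """One design cell: birthdate x second factor (target region or
    behavioral condition), with true co-label probability and cohort size.

    ``cells_per_animal`` is either a fixed count or a (low, high) range
    sampled uniformly (inclusive) per animal.
    """

    birthdate: str
    factor2: str
    p: float
    n_animals: int
    cells_per_animal: int | tuple[int, int] = (40, 120)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        lo, hi = self._range()
        if lo < 1 or hi < lo:
            raise ValueError("cells per animal must be >= 1")

    def _range(self) -> tuple[int, int]:
        if isinstance(self.cells_per_animal, int):
            return self.cells_per_animal, self.cells_per_animal
        lo, hi = self.cells_per_animal
        return int(lo), int(hi)


@dataclass(frozen=True)
class CohortSimParams:
    groups: tuple[CohortGroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))


def simulate_colabel_cohort(params: CohortSimParams) -> list[AnimalVector]:
    """Draw per-animal co-labeling counts for every group.

    Reproducible under a fixed seed; each group gets its own child stream so
    adding groups does not perturb existing ones.
    """
    animals: list[AnimalVector] = []
    for spec in params.groups:
        rng = child_rng(params.seed, "cohort", spec.birthdate, spec.factor2)
        lo, hi = spec._range()
        for a in range(spec.n_animals):
            n_total = int(rng.integers(lo, hi + 1))
            n_pos = int(rng.binomial(n_total, spec.p))
            animals.append(AnimalVector(
                animal_id=f"{spec.birthdate}-{spec.factor2}-{a:02d}",
                birthdate=spec.birthdate,
                factor2=spec.factor2,
                n_total=n_total,
                n_pos=n_pos,
            ))
    return animals
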