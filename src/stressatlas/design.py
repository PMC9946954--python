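"""Experimental design of the combined abiotic-stress atlas.

Seven single stresses — (C)old, (D)arkness, (H)eat, (L)ight, (M)annitol,
(N)itrogen deficiency, (S)alt — are combined pairwise.  Three pairs are
infeasible: cold/heat and darkness/light are mutually exclusive, and
heat/light is lethal.  That leaves 18 two-stress conditions which, together
with the 7 single stresses and two untreated control batches (F and L),
give 27 conditions; at 3 replicates each, 81 RNA-seq samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

SINGLE_CODES: tuple[str, ...] = ("C", "D", "H", "L", "M", "N", "S")

#: infeasible stress pairs (unordered)
EXCLUDED_PAIRS: frozenset[frozenset[str]] = frozenset(
    {frozenset({"C", "H"}), frozenset({"D", "L"}), frozenset({"H", "L"})}
)

CONTROL_CODES: tuple[str, str] = ("ctrl_F", "ctrl_L")


def combined_code(x: str, y: str) -> str:
    """Canonical two-letter code for the combination of stresses *x* and *y*.

    Letters are ordered alphabetically so every unordered pair has exactly
    one code (e.g. the cold+darkness condition is always "CD").
    """
    if x == y:
        raise ValueError(f"combined condition needs two distinct stresses, got {x!r} twice")
    a, b = sorted((x, y))
    return a + b


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str
    replicate: int
    batch: str


@dataclass(frozen=True)
class StressDesign:
    """The 27-condition design: singles, pairwise combinations, two controls."""

    single_codes: tuple[str, ...]
    combined_codes: tuple[str, ...]
    control_codes: tuple[str, ...]
    replicates_per_condition: int
    seed: int = 0
    samples: tuple[Sample, ...] = field(default=(), repr=False)

    @property
    def conditions(self) -> tuple[str, ...]:
        return self.single_codes + self.combined_codes + self.control_codes

    @property
    def stress_conditions(self) -> tuple[str, ...]:
        """Singles plus combinations; controls excluded."""
        return self.single_codes + self.combined_codes

    def n_samples(self) -> int:
        return len(self.samples)

    def stress_group(self, letter: str) -> tuple[str, ...]:
        """All conditions (single + combined) whose code contains *letter*.

        E.g. the darkness group is (D, CD, DM, DN, DS, DH-equivalent) — six
        conditions; heat and light have five because of the excluded pairs.
        """
        if letter not in self.single_codes:
            raise ValueError(f"unknown stress code {letter!r}")
        return tuple(c for c in self.stress_conditions if letter in c)

    def partners(self, code: str) -> tuple[str, str]:
        """The two single-stress letters of a combined code."""
        if code not in self.combined_codes:
            raise ValueError(f"{code!r} is not a combined condition")
        return code[0], code[1]


def make_design(n_replicates: int = 3, seed: int = 0) -> StressDesign:
    """Build the 27-condition stress design.

    Parameters
    ----------
    n_replicates
        Biological replicates per condition (>= 2; the study used 3).
    seed
        Recorded for provenance; the design itself is fully deterministic.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    combos = tuple(
        combined_code(x, y)
        for x, y in itertools.combinations(SINGLE_CODES, 2)
        if frozenset({x, y}) not in EXCLUDED_PAIRS
    )
    samples = []
    for cond in SINGLE_CODES + combos + CONTROL_CODES:
        batch = cond[-1] if cond.startswith("ctrl_") else "F"
        for rep in range(1, n_replicates + 1):
            samples.append(Sample(f"{cond}_{rep}", cond, rep, batch))
    return StressDesign(
        single_codes=SINGLE_CODES,
        combined_codes=combos,
        control_codes=CONTROL_CODES,
        replicates_per_condition=n_replicates,
        seed=seed,
        samples=tuple(samples),
    )
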