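"""Synthetic sequence/structure pairs with implanted, known shift events.

The generator emulates incongruent evolution in its simplest testable
form: object b has (nearly) the same sequence as object a, but a
contiguous block of its structure annotation is displaced by a few
positions against its own sequence -- exactly the signal a bi-alignment
is meant to recover.  Sequences differ only by point substitutions, so
the planted 4-way alignment needs no sequence gaps and its score can be
written down in closed form via the planted column list.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import NamedTuple

from .core import (
    ALL_GAP,
    BiAlignment,
    Column4,
    DELETION,
    INSERTION,
    InputError,
    MATCH,
)

__all__ = ["FixtureSpec", "ShiftTruth", "Fixture", "generate_fixture", "planted_columns"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STRUCTURE_STATES = "HETC"  # helix, sheet, turn, coil
FILLER = "C"  # structure state written into the hole a displaced block leaves


class ShiftTruth(NamedTuple):
    """One implanted shift: structure block [start, end) of object b is
    displaced by ``magnitude`` positions in ``direction`` (+1 right, -1
    left) against b's own sequence.  ``region`` is the affected span."""

    start: int
    end: int
    magnitude: int
    direction: int

    @property
    def region(self) -> tuple[int, int]:
        lo = self.start - (self.magnitude if self.direction < 0 else 0)
        hi = self.end + (self.magnitude if self.direction > 0 else 0)
        return (lo, hi)


class Fixture(NamedTuple):
    seq_a: str
    seq_b: str
    str_a: str
    str_b: str
    truth: tuple[ShiftTruth, ...]


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic pair.

    Defaults describe a small instance in the detectable regime: length
    60 over the 20 amino acids, an {H,E,T,C} structure annotation in runs
    of 2-4 states (boundary-dense, so a displaced block mismatches at
    several positions), one implanted shift of magnitude 1 over a
    16-position block, and a 10% point-substitution rate between the two
    sequences.
    """

    length: int = 60
    seq_alphabet: str = AMINO_ACIDS
    struct_alphabet: str = STRUCTURE_STATES
    n_shifts: int = 1
    magnitudes: tuple[int, ...] = (1,)
    block_length: int = 16
    min_run: int = 2
    max_run: int = 4
    noise: float = 0.1
    lambda_max: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InputError("length must be positive")
        if len(self.magnitudes) != self.n_shifts:
            raise InputError("need one magnitude per implanted shift")
        if any(m < 1 for m in self.magnitudes):
            raise InputError("shift magnitudes must be >= 1")
        if any(m > self.lambda_max for m in self.magnitudes):
            raise InputError("implanted shift magnitudes must not exceed lambda_max")
        if not 0.0 <= self.noise <= 1.0:
            raise InputError("noise must be a rate in [0, 1]")
        if not 1 <= self.min_run <= self.max_run:
            raise InputError("need 1 <= min_run <= max_run")
        # every shift needs its block plus clearance on both sides
        need = self.n_shifts * (self.block_length + 2 * max(self.magnitudes, default=0) + 2)
        if self.n_shifts and need > self.length:
            raise InputError(
                f"cannot place {self.n_shifts} shift(s) of block length "
                f"{self.block_length} in {self.length} positions"
            )


def _random_structure(
    rng: random.Random, length: int, alphabet: str, min_run: int, max_run: int
) -> str:
    """Structure annotation laid out in runs of equal states.

    A displaced block is only detectable where it crosses run boundaries
    (within a run, shifted and unshifted annotation agree), so the run
    length range controls how visible an implanted shift is.
    """
    out: list[str] = []
    prev = None
    while len(out) < length:
        state = rng.choice([s for s in alphabet if s != prev] or list(alphabet))
        out.extend(state * rng.randint(min_run, max_run))
        prev = state
    return "".join(out[:length])


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministically generate one synthetic pair from ``spec``.

    b's sequence is a's with point substitutions at rate ``spec.noise``;
    b's structure is a's with each implanted block displaced by its
    magnitude (direction drawn per shift), the vacated hole filled with
    the coil-like filler state.
    """
    rng = random.Random(spec.seed)
    n = spec.length
    seq_a = "".join(rng.choice(spec.seq_alphabet) for _ in range(n))
    str_a = _random_structure(rng, n, spec.struct_alphabet, spec.min_run, spec.max_run)
    seq_b = "".join(
        (
            rng.choice([c for c in spec.seq_alphabet if c != ch])
            if rng.random() < spec.noise and len(spec.seq_alphabet) > 1
            else ch
        )
        for ch in seq_a
    )
    # place non-overlapping blocks with clearance >= max magnitude + 1
    truths: list[ShiftTruth] = []
    str_b = list(str_a)
    margin = max(spec.magnitudes, default=0) + 1
    occupied: list[tuple[int, int]] = []
    for mag in spec.magnitudes:
        for _ in range(1000):
            start = rng.randint(margin, n - spec.block_length - margin)
            end = start + spec.block_length
            lo, hi = start - margin, end + margin
            if all(hi <= o_lo or lo >= o_hi for o_lo, o_hi in occupied):
                occupied.append((lo, hi))
                break
        else:  # pragma: no cover - prevented by FixtureSpec validation
            raise InputError("could not place non-overlapping shift blocks")
        direction = rng.choice((-1, 1))
        k = mag * direction
        block = str_a[start:end]
        str_b[start + k : end + k] = block
        if direction > 0:
            str_b[start : start + mag] = FILLER * mag
        else:
            str_b[end - mag : end] = FILLER * mag
        truths.append(ShiftTruth(start, end, mag, direction))
    truths.sort()
    return Fixture(seq_a, seq_b, str_a, "".join(str_b), tuple(truths))


def planted_columns(fixture: Fixture) -> list[Column4]:
    """The planted bi-alignment of a fixture as a 4-way column list.

    U is the identity alignment of the two (equal-length) sequences; V
    realigns each displaced structure block, which shows up as one pair
    of shift runs of the implanted magnitude in b's self-alignment.  Used
    to compute the planted solution's score; the engine's optimum must be
    at least as good.
    """
    n = len(fixture.seq_a)
    cols: list[Column4] = []
    pos = 0
    for t in fixture.truth:
        i, j, k = t.start, t.end, t.magnitude
        cols.extend([Column4(MATCH, MATCH)] * (max(i if t.direction > 0 else i - k, pos) - pos))
        if t.direction > 0:
            # b's structure block sits k later: V inserts b_str[i..i+k),
            # then matches the block, then deletes a_str[j..j+k) while the
            # sequences keep matching.
            cols.extend([Column4(ALL_GAP, INSERTION)] * k)
            cols.extend([Column4(MATCH, MATCH)] * (j - i))
            cols.extend([Column4(MATCH, DELETION)] * k)
            pos = j + k
        else:
            # block sits k earlier: delete a_str[i-k..i) against matching
            # sequences, match the block, then insert b's filler chunk.
            cols.extend([Column4(MATCH, DELETION)] * k)
            cols.extend([Column4(MATCH, MATCH)] * (j - i))
            cols.extend([Column4(ALL_GAP, INSERTION)] * k)
            pos = j
    cols.extend([Column4(MATCH, MATCH)] * (n - pos))
    return cols
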