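"""Core data model: chords, intervals, trials, rating datasets and stimulus designs.

Chords are major triads identified by their root pitch class, coded 0..11
internally (0 = A, 1 = A#, ..., 11 = G#).  The on-disk CSV dialect uses the
1..12 coding (A major triad is 1, ..., G sharp major triad is 12); the shift
happens only at I/O time.

A rating is a Degree of Relatedness (DOR): how well the final chord of a
sequence belongs to the preceding context, on a 9-point scale
(1 = least appropriate, 5 = neutral, 9 = most appropriate).  Synthetic
datasets may carry real-valued ratings in [1, 9].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PITCH_NAMES",
    "COMMON_INTERVALS",
    "Trial",
    "RatingDataset",
    "interval",
    "transpose",
    "has_repetition",
    "generate_stimulus_set",
    "simulation_sequences",
    "read_dor_csv",
    "write_dor_csv",
]

#: Pitch-class names in internal 0..11 coding.
PITCH_NAMES = ("A", "A#", "B", "C", "C#", "D", "D#", "E", "F", "F#", "G", "G#")

#: Root intervals (semitones) shared by all three sequence-length conditions:
#: major second, perfect fourth, perfect fifth, minor seventh.
COMMON_INTERVALS = (2, 5, 7, 10)

_CSV_HEADER = ["participant", "chord1", "chord2", "chord3", "chord4", "rating"]


def _check_root(r: int) -> int:
    r = int(r)
    if not 0 <= r <= 11:
        raise ValueError(f"chord root must be in 0..11, got {r}")
    return r


def interval(a: int, b: int) -> int:
    """Directed root interval from chord ``a`` to chord ``b``, in semitones mod 12."""
    return (_check_root(b) - _check_root(a)) % 12


def transpose(seq: Sequence[int], k: int) -> tuple[int, ...]:
    """Shift every root of ``seq`` by ``k`` semitones (mod 12); intervals are preserved."""
    return tuple((_check_root(r) + k) % 12 for r in seq)


def has_repetition(seq: Sequence[int]) -> bool:
    """True if the sequence contains an immediately repeated chord."""
    return any(seq[i] == seq[i + 1] for i in range(len(seq) - 1))


@dataclass(frozen=True)
class Trial:
    """One rated chord sequence.

    Parameters
    ----------
    participant : str
        Participant identifier.
    sequence : tuple of int
        Roots of the 2--4 chords, internal 0..11 coding.
    rating : float
        DOR on the 9-point scale; integers for behavioural data, reals in
        [1, 9] for synthetic continuous-mode data.
    """

    participant: str
    sequence: tuple[int, ...]
    rating: float

    def __post_init__(self) -> None:
        seq = tuple(_check_root(r) for r in self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not 2 <= len(seq) <= 4:
            raise ValueError(f"sequence length must be 2..4, got {len(seq)}")
        if not 1.0 <= float(self.rating) <= 9.0:
            raise ValueError(f"rating must lie in [1, 9], got {self.rating}")

    @property
    def condition(self) -> int:
        """Sequence-length condition (2, 3 or 4)."""
        return len(self.sequence)


@dataclass
class RatingDataset:
    """A collection of rated trials with a free-text provenance tag."""

    trials: list[Trial]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("RatingDataset must contain at least one trial")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.participant, None)
        return list(seen)

    @property
    def conditions(self) -> set[int]:
        return {t.condition for t in self.trials}

    def by_condition(self, condition: int) -> "RatingDataset":
        sel = [t for t in self.trials if t.condition == condition]
        if not sel:
            raise ValueError(f"no trials for condition {condition}")
        return RatingDataset(sel, self.provenance)

    def by_participant(self, participant: str) -> "RatingDataset":
        sel = [t for t in self.trials if t.participant == participant]
        if not sel:
            raise ValueError(f"no trials for participant {participant!r}")
        return RatingDataset(sel, self.provenance)

    def without_repetitions(self) -> "RatingDataset":
        """Drop trials containing an immediately repeated chord.

        Ratings of repeated chords are unstable and the matching expectancy
        cells are excluded from estimation, so such trials take no part in
        fitting or evaluation.
        """
        sel = [t for t in self.trials if not has_repetition(t.sequence)]
        if not sel:
            raise ValueError("all trials contain immediate repetitions")
        return RatingDataset(sel, self.provenance)

    def subset(self, indices: Iterable[int]) -> "RatingDataset":
        return RatingDataset([self.trials[i] for i in indices], self.provenance)


def generate_stimulus_set(
    condition: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> list[tuple[int, ...]]:
    """Enumerate the stimulus design for one sequence-length condition.

    * condition 2: all 12 x 12 ordered root pairs (144 sequences, repetitions
      included in the design although later excluded from fitting);
    * condition 3: all 12 x 12 ordered pairs of successive root intervals,
      each realized from a uniformly random initial root (144 sequences);
    * condition 4: all 4 x 4 x 4 interval triples over the common intervals
      {2, 5, 7, 10}, random initial root per sequence (64 sequences).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if condition == 2:
        return [(a, b) for a in range(12) for b in range(12)]
    if condition == 3:
        out = []
        for i1 in range(12):
            for i2 in range(12):
                r = int(rng.integers(12))
                out.append((r, (r + i1) % 12, (r + i1 + i2) % 12))
        return out
    if condition == 4:
        out = []
        for i1 in COMMON_INTERVALS:
            for i2 in COMMON_INTERVALS:
                for i3 in COMMON_INTERVALS:
                    r = int(rng.integers(12))
                    out.append((r, (r + i1) % 12, (r + i1 + i2) % 12, (r + i1 + i2 + i3) % 12))
        return out
    raise ValueError(f"condition must be 2, 3 or 4, got {condition}")


def simulation_sequences() -> list[tuple[int, ...]]:
    """The 253 repetition-free 2- and 3-chord patterns used for parameter recovery.

    All 2-chord ordered pairs with distinct roots (12 x 11 = 132), plus all
    3-chord interval patterns with both successive intervals nonzero
    (11 x 11 = 121), anchored at a canonical initial root of 0 (the
    interval-indexed models are transposition-invariant).
    """
    out: list[tuple[int, ...]] = [(a, b) for a in range(12) for b in range(12) if a != b]
    for i1 in range(1, 12):
        for i2 in range(1, 12):
            out.append((0, i1 % 12, (i1 + i2) % 12))
    return out


def read_dor_csv(path) -> RatingDataset:
    """Read a ratings table in the deposited-data dialect.

    One row per trial: participant, chord1..chord4 as 1..12 codes (trailing
    chord columns empty for shorter sequences), rating 1..9.
    """
    trials: list[Trial] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 6:
                raise ValueError(f"{path}: row {lineno}: expected 6 columns, got {len(row)}")
            participant = row[0].strip()
            roots = []
            for cell in row[1:5]:
                cell = cell.strip()
                if not cell:
                    continue
                try:
                    code = int(cell)
                except ValueError as exc:
                    raise ValueError(f"{path}: row {lineno}: bad chord code {cell!r}") from exc
                if not 1 <= code <= 12:
                    raise ValueError(f"{path}: row {lineno}: chord code {code} not in 1..12")
                roots.append(code - 1)
            try:
                rating = float(row[5])
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: bad rating {row[5]!r}") from exc
            if not 1.0 <= rating <= 9.0:
                raise ValueError(f"{path}: row {lineno}: rating {rating} outside the 1..9 scale")
            try:
                trials.append(Trial(participant, tuple(roots), rating))
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    if not trials:
        raise ValueError(f"{path}: no trials found")
    return RatingDataset(trials, provenance=str(path))


def write_dor_csv(dataset: RatingDataset | None, path) -> None:
    """Write a ratings table in the deposited-data dialect (1-based chord codes).

    ``dataset=None`` writes a header-only file.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        if dataset is None:
            return
        for t in dataset.trials:
            chords = [str(r + 1) for r in t.sequence] + [""] * (4 - len(t.sequence))
            rating = t.rating
            cell = str(int(rating)) if float(rating).is_integer() else repr(float(rating))
            writer.writerow([t.participant, *chords, cell])
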