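"""Discrete character matrices over declared state spaces.

A :class:`CharacterMatrix` maps taxon labels to state labels drawn from an
ordered state space, with explicit support for missing observations.  The
ordering of the state space is significant: it fixes the row/column indexing
of every rate matrix built on top of the matrix.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

#: Sentinel for a missing observation.  Stored as ``None``; rendered as an
#: empty cell in CSV output.
MISSING = None

#: Five-state scoring of reproductive systems, in fixed rate-matrix order.
FIVE_STATES: tuple[str, ...] = (
    "distyly",
    "tristyly",
    "semihomostyly",
    "dioecy",
    "homostyly",
)

#: Binary scoring.  State 0 is trimorphism, state 1 dimorphism; this
#: orientation fixes the meaning of lambda_0/q_01 in the BiSSE module.
BINARY_STATES: tuple[str, ...] = ("trimorphism", "dimorphism")


@dataclass
class CharacterMatrix:
    """Taxon -> state mapping over an ordered state space.

    Parameters
    ----------
    states
        Ordered state labels; index in this tuple is the state's integer code.
    data
        Mapping from taxon label to state label, or ``None`` for missing.
    """

    states: tuple[str, ...]
    data: dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        bad = {s for s in self.data.values() if s is not None and s not in self.states}
        if bad:
            raise ValueError(f"states outside declared state space: {sorted(bad)}")
        if len(set(self.data)) != len(self.data):
            raise ValueError("duplicate taxa")

    # -- basic queries ----------------------------------------------------

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.data)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, taxon: str) -> Optional[str]:
        return self.data[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.data

    def state_index(self, taxon: str) -> Optional[int]:
        """Integer code of the taxon's state, or ``None`` if missing."""
        s = self.data[taxon]
        return None if s is None else self.states.index(s)

    def missing_taxa(self) -> list[str]:
        return [t for t, s in self.data.items() if s is None]

    def non_missing(self) -> int:
        """Number of taxa with an observed state (the AICc sample size)."""
        return sum(1 for s in self.data.values() if s is not None)

    def state_counts(self) -> Counter:
        return Counter(s for s in self.data.values() if s is not None)

    def is_monomorphic(self) -> bool:
        return len(self.state_counts()) <= 1

    # -- manipulation -----------------------------------------------------

    def subset(self, taxa: Iterable[str]) -> "CharacterMatrix":
        keep = set(taxa)
        return CharacterMatrix(self.states, {t: s for t, s in self.data.items() if t in keep})

    def drop(self, taxa: Iterable[str]) -> "CharacterMatrix":
        gone = set(taxa)
        return CharacterMatrix(self.states, {t: s for t, s in self.data.items() if t not in gone})

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_mapping(
        cls, states: Sequence[str], mapping: Mapping[str, Optional[str]]
    ) -> "CharacterMatrix":
        return cls(tuple(states), dict(mapping))

    def to_csv(self, path: str | Path, column: str = "state") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["taxon", column])
            for t, s in self.data.items():
                w.writerow([t, "" if s is None else s])

    @classmethod
    def from_csv(
        cls, path: str | Path, states: Sequence[str], column: str = "state"
    ) -> "CharacterMatrix":
        data: dict[str, Optional[str]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                val = (row[column] or "").strip()
                data[row["taxon"].strip()] = val if val else None
        return cls(tuple(states), data)
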