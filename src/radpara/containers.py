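"""In-memory containers for per-site read-count piles over reference RAD loci."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .likelihood import BASES


@dataclass
class SitePile:
    """Per-individual base counts at one reference site.

    ``counts`` has shape ``(n_individuals, 4)`` in A, C, G, T order.
    """

    locus_id: str
    pos: int
    ref: str
    counts: np.ndarray

    def depth(self) -> np.ndarray:
        """Total read depth per individual."""
        return self.counts.sum(axis=1)


@dataclass
class Locus:
    """All site piles of one reference locus, ``counts`` shaped (length, n_ind, 4)."""

    locus_id: str
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape[0] != len(self.ref):
            raise ValueError(
                f"locus {self.locus_id}: reference length {len(self.ref)} "
                f"does not match {self.counts.shape[0]} pile rows"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"locus {self.locus_id}: negative read count")

    @property
    def length(self) -> int:
        return self.counts.shape[0]


@dataclass
class PileSet:
    """A collection of loci sharing one individual panel."""

    individuals: list[str]
    loci: dict[str, Locus] = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci)

    @property
    def total_sites(self) -> int:
        return sum(loc.length for loc in self.loci.values())

    def add_locus(self, locus: Locus) -> None:
        if locus.counts.shape[1] != self.n_individuals:
            raise ValueError(
                f"locus {locus.locus_id} has {locus.counts.shape[1]} individuals, "
                f"pile set has {self.n_individuals}"
            )
        if locus.locus_id in self.loci:
            raise ValueError(f"duplicate locus id {locus.locus_id}")
        self.loci[locus.locus_id] = locus

    def iter_sites(self) -> Iterator[SitePile]:
        for loc in self.loci.values():
            for pos in range(loc.length):
                yield SitePile(loc.locus_id, pos, loc.ref[pos], loc.counts[pos])

    def site(self, locus_id: str, pos: int) -> SitePile:
        loc = self.loci[locus_id]
        return SitePile(locus_id, pos, loc.ref[pos], loc.counts[pos])

    def stacked_counts(self) -> np.ndarray:
        """All piles stacked to shape (total_sites, n_individuals, 4)."""
        if not self.loci:
            return np.zeros((0, self.n_individuals, 4), dtype=np.int64)
        return np.concatenate([loc.counts for loc in self.loci.values()], axis=0)

    def site_index(self) -> list[tuple[str, int]]:
        """(locus_id, pos) keys aligned with :meth:`stacked_counts` rows."""
        return [
            (lid, pos)
            for lid, loc in self.loci.items()
            for pos in range(loc.length)
        ]

    def references(self) -> dict[str, str]:
        return {lid: loc.ref for lid, loc in self.loci.items()}


def validate_bases(seq: str, context: str = "sequence") -> None:
    bad = set(seq.upper()) - set(BASES)
    if bad:
        raise ValueError(f"{context} contains non-ACGT characters: {sorted(bad)}")
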