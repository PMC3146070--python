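"""Container for mapped single-end read alignments.

Reads are plain genomic intervals with a strand — the package consumes
already-mapped alignments and never touches sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genome import GenomeModel


@dataclass
class ReadAlignmentSet:
    """Mapped read intervals for one sample/replicate.

    ``chrom``, ``start``, ``end`` and ``strand`` are parallel arrays;
    intervals are 0-based half-open.
    """

    sample_id: str
    replicate: int
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    genome: GenomeModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=object)
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.strand) == n):
            raise ValidationError("read arrays have mismatched lengths")
        if n and ((self.start < 0).any() or (self.end <= self.start).any()):
            raise ValidationError("reads must satisfy 0 <= start < end")
        if self.genome is not None:
            self.validate_against(self.genome)

    def validate_against(self, genome: GenomeModel) -> None:
        for name in np.unique(self.chrom.astype(str)) if len(self) else []:
            if name not in genome:
                raise ValidationError(f"unknown chromosome {name!r}")
            sel = self.chrom == name
            if (self.end[sel] > genome.length_of(name)).any():
                raise ValidationError(f"read extends past end of {name}")
        self.genome = genome

    def __len__(self) -> int:
        return len(self.chrom)

    def sorted(self) -> "ReadAlignmentSet":
        order = np.lexsort((self.start, self.chrom.astype(str)))
        return ReadAlignmentSet(self.sample_id, self.replicate,
                                self.chrom[order], self.start[order],
                                self.end[order], self.strand[order],
                                self.genome)

    def records(self) -> list[tuple]:
        return list(zip(self.chrom.tolist(), self.start.tolist(),
                        self.end.tolist(), self.strand.tolist()))

    def __eq__(self, other) -> bool:  # record-level equality
        if not isinstance(other, ReadAlignmentSet):
            return NotImplemented
        return self.records() == other.records()
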