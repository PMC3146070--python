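"""Per-base-pair coverage tracks: read extension, pileup, normalization.

The processing chain is fixed by a small state machine: raw pileup →
median-scaled → replicate-averaged.  Mapped single-end reads are first
extended in the 3' direction of their strand to the expected fragment
length (default 200 bp, from 36-bp reads), each base pair then counts
the number of overlapping extended fragments, each replicate track is
rescaled so all samples share a common genome-wide median, and finally
replicates are averaged base-by-base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (ConfigurationError, NormalizationError, StateError,
                     ValidationError)
from .genome import GenomeModel
from .reads import ReadAlignmentSet

RAW = "raw"
MEDIAN_SCALED = "median_scaled"
REPLICATE_AVERAGED = "replicate_averaged"


@dataclass
class CoverageTrack:
    """Per-chromosome signal vectors plus normalization bookkeeping.

    Raw pileups hold integer counts; scaling converts to float.
    ``scale_factor`` is the multiplier applied at the median-scaling
    step (1.0 before scaling).
    """

    sample_id: str
    genome: GenomeModel
    data: dict[str, np.ndarray]
    normalization_state: str = RAW
    scale_factor: float = 1.0
    median_mode: str = field(default="nonzero", repr=False)

    def __post_init__(self) -> None:
        for c in self.genome.chromosomes:
            if c.name not in self.data:
                raise ValidationError(f"track missing chromosome {c.name}")
            if len(self.data[c.name]) != c.length:
                raise ValidationError(
                    f"track length mismatch on {c.name}")

    def values(self) -> np.ndarray:
        """All per-bp values, concatenated in genome order."""
        return np.concatenate([self.data[n] for n in self.genome.names])

    def total(self) -> float:
        return float(sum(self.data[n].sum() for n in self.genome.names))

    def normalization_median(self, mode: str | None = None) -> float:
        """Median used for scaling.

        ``nonzero`` (default): median over covered bases only, falling
        back to the genome-wide median when at least half the genome is
        covered.  ``all``: genome-wide median including zeros.  The
        fallback exists because a desk-scale experiment leaves most of
        the genome uncovered, where the genome-wide median is zero and
        scaling is undefined.
        """
        mode = mode or self.median_mode
        v = self.values()
        if mode == "all":
            return float(np.median(v))
        if mode != "nonzero":
            raise ConfigurationError(f"unknown median mode {mode!r}")
        nz = v[v > 0]
        if nz.size == 0:
            raise NormalizationError("all-zero track has no median to scale")
        if nz.size >= 0.5 * v.size:
            return float(np.median(v))
        return float(np.median(nz))

    def scaled_by(self, factor: float, state: str) -> "CoverageTrack":
        data = {n: self.data[n].astype(np.float64) * factor
                for n in self.genome.names}
        return CoverageTrack(self.sample_id, self.genome, data,
                             normalization_state=state,
                             scale_factor=self.scale_factor * factor,
                             median_mode=self.median_mode)


def extend_reads(reads: ReadAlignmentSet, target_length: int = 200,
                 genome: GenomeModel | None = None) -> ReadAlignmentSet:
    """Extend each read to ``target_length`` in its strand's 3' direction.

    A ``+`` read keeps its 5' end (start) and grows rightward; a ``-``
    read keeps its 5' end (end) and grows leftward.  Extended intervals
    are clamped to chromosome bounds; the read count is preserved.
    """
    genome = genome or reads.genome
    if genome is None:
        raise ValidationError("a genome is required to clamp extended reads")
    obs = reads.end - reads.start
    if len(reads) and int(obs.max()) > target_length:
        raise ConfigurationError(
            f"target_length {target_length} < observed read length {int(obs.max())}")
    fwd = reads.strand == "+"
    new_start = np.where(fwd, reads.start, reads.end - target_length)
    new_end = np.where(fwd, reads.start + target_length, reads.end)
    lens = np.array([genome.length_of(c) for c in reads.chrom],
                    dtype=np.int64) if len(reads) else np.array([], dtype=np.int64)
    new_start = np.maximum(new_start, 0)
    new_end = np.minimum(new_end, lens)
    return ReadAlignmentSet(reads.sample_id, reads.replicate, reads.chrom,
                            new_start, new_end, reads.strand, genome)


def pileup(intervals: ReadAlignmentSet, genome: GenomeModel) -> CoverageTrack:
    """Count, at every base pair, the number of overlapping intervals.

    Integer arithmetic throughout, so the total signal equals the sum
    of interval lengths exactly.
    """
    intervals.validate_against(genome)
    data = {}
    chrom_arr = intervals.chrom.astype(str) if len(intervals) else np.array([])
    for c in genome.chromosomes:
        diff = np.zeros(c.length + 1, dtype=np.int64)
        if len(intervals):
            sel = chrom_arr == c.name
            if sel.any():
                np.add.at(diff, intervals.start[sel], 1)
                np.add.at(diff, intervals.end[sel], -1)
        data[c.name] = np.cumsum(diff[:-1])
    return CoverageTrack(intervals.sample_id, genome, data,
                         normalization_state=RAW)


def median_scale(tracks: list[CoverageTrack],
                 target_median: float | str = "common",
                 median_mode: str = "nonzero") -> list[CoverageTrack]:
    """Rescale each track so all share the same normalization median.

    With ``target_median="common"`` the target is the first track's
    median; a number fixes the target explicitly.
    """
    if not tracks:
        raise ConfigurationError("no tracks to scale")
    medians = [t.normalization_median(median_mode) for t in tracks]
    if any(m <= 0 for m in medians):
        raise NormalizationError("cannot scale a track with nonpositive median")
    if target_median == "common":
        target = medians[0]
    else:
        target = float(target_median)
        if target <= 0:
            raise ConfigurationError("target median must be positive")
    out = []
    for t, m in zip(tracks, medians):
        scaled = t.scaled_by(target / m, MEDIAN_SCALED)
        scaled.median_mode = median_mode
        out.append(scaled)
    return out


def average_replicates(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Base-by-base arithmetic mean of median-scaled replicate tracks."""
    if not tracks:
        raise ConfigurationError("no tracks to average")
    states = {t.normalization_state for t in tracks}
    if states != {MEDIAN_SCALED}:
        raise StateError(
            f"average_replicates requires median_scaled tracks, got {states}")
    genome = tracks[0].genome
    for t in tracks[1:]:
        if t.genome.names != genome.names:
            raise ValidationError("replicates use different genomes")
    k = len(tracks)
    data = {n: sum(t.data[n] for t in tracks) / k for n in genome.names}
    return CoverageTrack(tracks[0].sample_id, genome, data,
                         normalization_state=REPLICATE_AVERAGED,
                         scale_factor=float(np.mean([t.scale_factor
                                                     for t in tracks])))


def coverage_pipeline(replicates: list[ReadAlignmentSet],
                      genome: GenomeModel, extend_to: int = 200,
                      target_median: float | str = "common",
                      median_mode: str = "nonzero") -> CoverageTrack:
    """extend → pileup → median-scale → average, in one call."""
    raw = [pileup(extend_reads(r, extend_to, genome), genome)
           for r in replicates]
    scaled = median_scale(raw, target_median, median_mode)
    return average_replicates(scaled)
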