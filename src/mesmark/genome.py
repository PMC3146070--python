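"""Genome and gene-annotation containers.

Coordinates are 0-based, half-open throughout the package; any 1-based
text input is converted at the I/O boundary.  A gene stores ``(start,
end, strand)`` and derives its transcription start/end sites from the
strand: on ``+`` the TSS is ``start`` and the TES is ``end - 1``; on
``-`` the TSS is ``end - 1`` and the TES is ``start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX",
          "X", "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII",
          "XIX", "XX"]


def _roman(n: int) -> str:
    if 1 <= n <= len(_ROMAN):
        return _ROMAN[n - 1]
    raise ConfigurationError(f"autosome index {n} out of supported range")


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    is_x: bool = False


@dataclass
class GenomeModel:
    """Named chromosomes with lengths and an X/autosome flag.

    At most one chromosome may be flagged as the X; at least one
    autosome is required.
    """

    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        if any(c.length <= 0 for c in self.chromosomes):
            raise ValidationError("chromosome lengths must be positive")
        n_x = sum(c.is_x for c in self.chromosomes)
        if n_x > 1:
            raise ValidationError("at most one X chromosome is allowed")
        if len(self.chromosomes) - n_x < 1:
            raise ValidationError("at least one autosome is required")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def length_of(self, name: str) -> int:
        return self._by_name()[name].length

    def is_x(self, name: str) -> bool:
        return self._by_name()[name].is_x

    def __contains__(self, name: str) -> bool:
        return name in self._by_name()

    def _by_name(self) -> dict[str, Chromosome]:
        return {c.name: c for c in self.chromosomes}

    @property
    def x_name(self) -> str | None:
        for c in self.chromosomes:
            if c.is_x:
                return c.name
        return None


def build_toy_genome(n_autosomes: int, chrom_length: int,
                     include_x: bool = True) -> GenomeModel:
    """Construct a deterministic toy genome.

    Autosomes are named ``chrI`` ... in Roman-numeral order; the X, when
    requested, is named ``chrX`` and carries the same length.
    """
    if n_autosomes < 1:
        raise ConfigurationError("n_autosomes must be >= 1")
    chrom_length = int(chrom_length)
    if chrom_length < 10_000:
        raise ConfigurationError("chrom_length must be >= 10000")
    chroms = [Chromosome(f"chr{_roman(i + 1)}", chrom_length)
              for i in range(n_autosomes)]
    if include_x:
        chroms.append(Chromosome("chrX", chrom_length, is_x=True))
    return GenomeModel(chroms)


_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "gene_class"]


class GeneTable:
    """A set of gene annotations backed by a :class:`pandas.DataFrame`.

    Columns: ``gene_id, chrom, start, end, strand, gene_class``.
    Gene ids are unique; intervals are 0-based half-open and validated
    against a genome when one is supplied.
    """

    def __init__(self, df: pd.DataFrame, genome: GenomeModel | None = None):
        missing = [c for c in _GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"gene table missing columns: {missing}")
        df = df[_GENE_COLUMNS].reset_index(drop=True).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
            raise ValidationError("gene intervals must satisfy 0 <= start < end")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be '+' or '-'")
        if genome is not None:
            for chrom, sub in df.groupby("chrom"):
                if chrom not in genome:
                    raise ValidationError(f"unknown chromosome {chrom!r}")
                if (sub["end"] > genome.length_of(chrom)).any():
                    raise ValidationError(
                        f"gene extends past end of {chrom}")
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    @property
    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()

    def classes(self) -> pd.Series:
        return self.df.set_index("gene_id")["gene_class"]

    def tss(self) -> np.ndarray:
        """Strand-aware transcription start site per gene."""
        fwd = self.df["strand"].to_numpy() == "+"
        return np.where(fwd, self.df["start"], self.df["end"] - 1)

    def tes(self) -> np.ndarray:
        """Strand-aware transcription end site per gene."""
        fwd = self.df["strand"].to_numpy() == "+"
        return np.where(fwd, self.df["end"] - 1, self.df["start"])

    def subset(self, gene_ids) -> "GeneTable":
        ids = set(gene_ids)
        unknown = ids - set(self.df["gene_id"])
        if unknown:
            raise ValidationError(f"unknown gene ids: {sorted(unknown)[:5]}")
        sub = self.df[self.df["gene_id"].isin(ids)]
        return GeneTable(sub, self.genome)

    def genes_by_class(self, gene_class: str) -> list[str]:
        sel = self.df["gene_class"] == gene_class
        return self.df.loc[sel, "gene_id"].tolist()
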