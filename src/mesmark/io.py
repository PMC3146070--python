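"""Readers and writers for the plain-text formats the pipeline touches.

All genomic text formats are BED-flavoured (0-based, half-open).
Readers validate against a :class:`~mesmark.genome.GenomeModel` when one
is supplied and never silently clamp; writers are deterministic (the
same in-memory object always produces identical bytes).

Formats:

* reads — BED6 (chrom, start, end, name, score=0, strand)
* gene annotation — BED6 plus a sidecar TSV mapping gene id → class
* coverage — bedGraph, run-length compressed at 6-decimal precision
* tag tables / staining counts / qPCR Cp tables — TSV with a header row
* genome — TSV (chrom, length, is_x)
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coverage import RAW, CoverageTrack
from .errors import ParseError, ValidationError
from .genome import Chromosome, GeneTable, GenomeModel
from .reads import ReadAlignmentSet

log = logging.getLogger(__name__)


# -- BED reads ---------------------------------------------------------------

def read_bed_reads(path, genome: GenomeModel | None = None,
                   sample_id: str | None = None,
                   replicate: int = 0) -> ReadAlignmentSet:
    """Read mapped intervals from a BED file (>= 3 columns).

    Strand defaults to ``+`` when column 6 is absent.  Malformed lines
    raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    chroms, starts, ends, strands = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path.name}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path.name}:{lineno}: need 0 <= start < end")
            strand = fields[5] if len(fields) >= 6 else "+"
            if strand not in ("+", "-"):
                raise ParseError(f"{path.name}:{lineno}: bad strand {strand!r}")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    rs = ReadAlignmentSet(sample_id or path.stem, replicate,
                          np.array(chroms, dtype=object),
                          np.array(starts, dtype=np.int64),
                          np.array(ends, dtype=np.int64),
                          np.array(strands, dtype=object))
    if genome is not None:
        rs.validate_against(genome)
    return rs


def write_bed_reads(reads: ReadAlignmentSet, path) -> None:
    with open(path, "w") as fh:
        for i, (c, s, e, st) in enumerate(reads.records()):
            fh.write(f"{c}\t{s}\t{e}\tr{i}\t0\t{st}\n")


# -- gene annotation ---------------------------------------------------------

def read_gene_annotation(path_bed, path_class_tsv=None,
                         genome: GenomeModel | None = None) -> GeneTable:
    """Merge a BED6 gene file with a sidecar class TSV.

    Genes missing from the class file get class ``unassigned`` (logged);
    a class entry for an unknown gene is an error, as is a duplicate
    gene id in the BED.
    """
    path_bed = Path(path_bed)
    rows = []
    with open(path_bed) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path_bed.name}:{lineno}: gene BED needs 6 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path_bed.name}:{lineno}: non-integer coordinate") from exc
            rows.append((fields[3], fields[0], start, end, fields[5]))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene id {dup!r} in {path_bed.name}")

    classes = {}
    if path_class_tsv is not None:
        cdf = pd.read_csv(path_class_tsv, sep="\t", header=None,
                          names=["gene_id", "gene_class"], comment="#")
        unknown = set(cdf["gene_id"]) - set(df["gene_id"])
        if unknown:
            raise ValidationError(
                f"class file names genes absent from BED: {sorted(unknown)[:5]}")
        classes = dict(zip(cdf["gene_id"], cdf["gene_class"]))
    df["gene_class"] = df["gene_id"].map(classes).fillna("unassigned")
    n_missing = int((df["gene_class"] == "unassigned").sum())
    if n_missing and path_class_tsv is not None:
        log.warning("%d gene(s) missing from class file; class set to "
                    "'unassigned'", n_missing)
    return GeneTable(df, genome)


def write_gene_annotation(genes: GeneTable, path_bed, path_class_tsv) -> None:
    with open(path_bed, "w") as fh:
        for rec in genes.df.itertuples(index=False):
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene_id}"
                     f"\t0\t{rec.strand}\n")
    with open(path_class_tsv, "w") as fh:
        for rec in genes.df.itertuples(index=False):
            fh.write(f"{rec.gene_id}\t{rec.gene_class}\n")


# -- bedGraph ----------------------------------------------------------------

_PRECISION = 6


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length-compressed bedGraph; zero runs are omitted (gaps read
    back as 0).  Values are written with 6 decimal places."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.sample_id}"\n')
        fh.write(f"#mesmark normalization_state={track.normalization_state} "
                 f"scale_factor={track.scale_factor!r}\n")
        for name in track.genome.names:
            v = np.asarray(track.data[name], dtype=np.float64)
            if not np.isfinite(v).all():
                raise ValidationError(f"non-finite values on {name}")
            r = np.round(v, _PRECISION)
            if len(r) == 0:
                continue
            breaks = np.flatnonzero(np.diff(r)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(r)]))
            for s, e in zip(starts, ends):
                val = r[s]
                if val == 0:
                    continue
                fh.write(f"{name}\t{s}\t{e}\t{val:.6f}\n")


def read_bedgraph(path, genome: GenomeModel,
                  sample_id: str | None = None) -> CoverageTrack:
    """Reconstruct a per-bp track from bedGraph; gaps become 0.

    Overlapping intervals and out-of-bounds coordinates are errors.
    """
    path = Path(path)
    data = {c.name: np.zeros(c.length, dtype=np.float64)
            for c in genome.chromosomes}
    seen_end: dict[str, int] = {}
    state, scale = RAW, 1.0
    name = sample_id or path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#mesmark"):
                for token in line.split()[1:]:
                    k, _, val = token.partition("=")
                    if k == "normalization_state":
                        state = val
                    elif k == "scale_factor":
                        scale = float(val)
                continue
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path.name}:{lineno}: expected 4 columns")
            chrom = fields[0]
            if chrom not in genome:
                raise ValidationError(
                    f"{path.name}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: bad field") from exc
            if start < 0 or end <= start or end > genome.length_of(chrom):
                raise ParseError(
                    f"{path.name}:{lineno}: interval out of bounds")
            if start < seen_end.get(chrom, 0):
                raise ParseError(
                    f"{path.name}:{lineno}: overlapping intervals")
            seen_end[chrom] = end
            data[chrom][start:end] = value
    return CoverageTrack(name, genome, data, normalization_state=state,
                         scale_factor=scale)


# -- genome ------------------------------------------------------------------

def write_genome_tsv(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\tis_x\n")
        for c in genome.chromosomes:
            fh.write(f"{c.name}\t{c.length}\t{int(c.is_x)}\n")


def read_genome_tsv(path) -> GenomeModel:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "length", "is_x"):
        if col not in df.columns:
            raise ParseError(f"genome TSV missing column {col!r}")
    return GenomeModel([Chromosome(r.chrom, int(r.length), bool(r.is_x))
                        for r in df.itertuples(index=False)])


# -- tabular inputs ----------------------------------------------------------

def read_tag_table(path) -> pd.DataFrame:
    """TSV with header ``gene<TAB>tissue1...``; returns a DataFrame
    indexed by gene id with integer tissue columns."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ParseError("tag table must start with a 'gene' column")
    df = df.set_index("gene")
    if df.index.duplicated().any():
        raise ValidationError("duplicate gene ids in tag table")
    if (df < 0).any().any():
        raise ValidationError("negative tag counts")
    return df.astype(np.int64)


def write_tag_table(tags: pd.DataFrame, path) -> None:
    out = tags.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_stain_table(path) -> pd.DataFrame:
    """TSV with columns genotype, assay, positive, total."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["genotype", "assay", "positive", "total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"staining table missing columns: {missing}")
    if (df["total"] <= 0).any() or (df["positive"] < 0).any() \
            or (df["positive"] > df["total"]).any():
        raise ValidationError("need 0 <= positive <= total, total > 0")
    return df


def read_qpcr_table(path) -> pd.DataFrame:
    """TSV with columns sample, Cp, dilution_factor, role (chip|input)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["sample", "Cp", "dilution_factor", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"qPCR table missing columns: {missing}")
    if not df["role"].isin(["chip", "input"]).all():
        raise ValidationError("role must be 'chip' or 'input'")
    return df


def write_config_echo(config: dict, path) -> None:
    """Echo an effective configuration as flat YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, default_flow_style=False, sort_keys=True)


def read_gene_list(path) -> set[str]:
    """One gene id per line; blank lines and # comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
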