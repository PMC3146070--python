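"""Synthetic-data generator for the pipeline.

Emulates the statistical structure of an embryo ChIP-seq experiment on a
toy multi-chromosome genome: 36-bp single-end mapped reads drawn from a
mixture of uniform background and gene-body enrichment, where which
genes are enriched depends on the sample's marking mode.

Four modes mirror the biology being modelled:

``mes4_maintenance``
    Maintenance methylation of H3K36 restricted to germline-expressed
    gene bodies, with a 5' positional bias and depletion on the X
    chromosome.
``transcription_coupled``
    Co-transcriptional marking of all expressed genes, soma included,
    with the usual 3' bias.
``pan_h3``, ``input``
    Flat controls: nucleosome occupancy and sheared chromatin have no
    gene-class structure, so reads are uniform over the genome.

Reads carry no sequence; the simulator produces mapped intervals
directly (no FASTQ, no error model, no duplicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PlacementError, ValidationError
from .genome import GeneTable, GenomeModel
from .reads import ReadAlignmentSet

MODES = ("mes4_maintenance", "transcription_coupled", "pan_h3", "input")
BIASES = ("five_prime", "three_prime", "uniform")

#: Tissues recognised by the expression-tag simulator.
TISSUES = ("germline", "muscle", "nerve", "gut")
SOMATIC_TISSUES = ("muscle", "nerve", "gut")

#: Which tissues a gene class expresses in (nonzero expected tag count).
CLASS_TISSUES = {
    "germline": ("germline",),
    "germline_specific": ("germline",),
    "soma": SOMATIC_TISSUES,
    "ubiquitous": TISSUES,
}


@dataclass
class EnrichmentModel:
    """Where simulated ChIP fragments come from.

    With probability ``background_fraction`` a read is uniform over the
    genome; otherwise a source gene is drawn with probability
    proportional to ``class_weights[class] * gene_length``, multiplied
    by ``x_weight_multiplier`` for X-linked genes, and the fragment
    start is placed in the gene body with a linear positional bias of
    slope ``bias_strength`` toward the chosen end.
    """

    mode: str
    background_fraction: float = 0.2
    positional_bias: str = "uniform"
    bias_strength: float = 0.0
    class_weights: dict = field(default_factory=dict)
    x_weight_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.positional_bias not in BIASES:
            raise ConfigurationError(
                f"unknown positional bias {self.positional_bias!r}")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ConfigurationError("background_fraction must be in [0, 1]")
        if self.bias_strength < 0:
            raise ConfigurationError("bias_strength must be >= 0")
        if self.x_weight_multiplier < 0:
            raise ConfigurationError("x_weight_multiplier must be >= 0")
        if any(w < 0 or not np.isfinite(w) for w in self.class_weights.values()):
            raise ConfigurationError("class weights must be finite and >= 0")
        if self.mode not in ("pan_h3", "input"):
            if not any(w > 0 for w in self.class_weights.values()):
                raise ConfigurationError(
                    f"mode {self.mode!r} requires at least one nonzero "
                    "class weight")

    @property
    def is_flat(self) -> bool:
        """Flat controls draw every read from the uniform background."""
        return self.mode in ("pan_h3", "input")


@dataclass
class SimulationConfig:
    n_reads: int
    read_length: int = 36
    seed: int = 0
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ConfigurationError("n_reads must be > 0")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be > 0")
        if self.replicate_count < 1:
            raise ConfigurationError("replicate_count must be >= 1")


def default_mes4_model() -> EnrichmentModel:
    """Maintenance-marking sample: germline and ubiquitous gene bodies
    only, 5'-biased, strongly depleted on the X."""
    return EnrichmentModel(
        mode="mes4_maintenance",
        background_fraction=0.2,
        positional_bias="five_prime",
        bias_strength=1.0,
        class_weights={"germline": 1.0, "ubiquitous": 1.0, "soma": 0.0},
        x_weight_multiplier=0.15,
    )


def default_transcription_model() -> EnrichmentModel:
    """Co-transcriptional marking: every expressed class, 3'-biased."""
    return EnrichmentModel(
        mode="transcription_coupled",
        background_fraction=0.2,
        positional_bias="three_prime",
        bias_strength=1.0,
        class_weights={"germline": 1.0, "ubiquitous": 1.0, "soma": 1.0},
        x_weight_multiplier=0.5,
    )


def default_control_model(mode: str = "input") -> EnrichmentModel:
    return EnrichmentModel(mode=mode, background_fraction=1.0)


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # one independent stream per replicate, jointly reproducible
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def annotate_genes(genome: GenomeModel, genes_per_chrom: int,
                   gene_length_range: tuple[int, int],
                   class_proportions: dict[str, float],
                   seed: int,
                   x_class_proportions: dict[str, float] | None = None,
                   placement: str = "spaced") -> GeneTable:
    """Place genes on each chromosome and assign classes.

    ``class_proportions`` must sum to 1 (within 1e-9).  When
    ``x_class_proportions`` is given it replaces the mixture on the X
    chromosome, which is how the simulator reproduces the scarcity of
    germline-expressed genes on the X.  Strands are assigned at random.

    ``placement="spaced"`` (default) divides each chromosome into equal
    slots and drops one gene at a random offset inside each, so genes
    never overlap and the class truth labels stay unambiguous for
    recovery tests; ``placement="uniform"`` draws starts uniformly and
    permits overlap.  Downstream code must tolerate overlapping genes
    either way.
    """
    if placement not in ("spaced", "uniform"):
        raise ConfigurationError(f"unknown placement {placement!r}")
    if genes_per_chrom < 1:
        raise ConfigurationError("genes_per_chrom must be >= 1")
    lo, hi = int(gene_length_range[0]), int(gene_length_range[1])
    if not 0 < lo <= hi:
        raise ConfigurationError("invalid gene length range")

    def _check(props: dict[str, float], label: str) -> None:
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError(f"{label} class proportions must sum to 1")
        if any(p < 0 for p in props.values()):
            raise ConfigurationError(f"{label} class proportions must be >= 0")

    _check(class_proportions, "autosome")
    if x_class_proportions is not None:
        _check(x_class_proportions, "X")

    rng = np.random.default_rng(seed)
    rows = []
    gene_idx = 0
    for chrom in genome.chromosomes:
        if hi > chrom.length:
            raise PlacementError(
                f"gene length {hi} exceeds {chrom.name} length {chrom.length}")
        props = class_proportions
        if chrom.is_x and x_class_proportions is not None:
            props = x_class_proportions
        labels = list(props)
        probs = np.array([props[k] for k in labels], dtype=float)
        probs = probs / probs.sum()
        lengths = rng.integers(lo, hi + 1, size=genes_per_chrom)
        if placement == "spaced":
            slot = chrom.length // genes_per_chrom
            if hi > slot:
                raise PlacementError(
                    f"gene length {hi} exceeds slot {slot} on {chrom.name}; "
                    "use fewer genes, shorter genes or placement='uniform'")
            offsets = rng.integers(0, slot - lengths + 1)
            starts = np.arange(genes_per_chrom, dtype=np.int64) * slot + offsets
        else:
            starts = rng.integers(0, chrom.length - lengths + 1)
        strands = rng.choice(["+", "-"], size=genes_per_chrom)
        classes = rng.choice(labels, size=genes_per_chrom, p=probs)
        for L, s, st, cl in zip(lengths, starts, strands, classes):
            rows.append((f"gene{gene_idx:05d}", chrom.name, int(s),
                         int(s + L), st, cl))
            gene_idx += 1
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand", "gene_class"])
    return GeneTable(df, genome)


def _sample_relative_positions(rng: np.random.Generator, n: int,
                               bias: str, strength: float) -> np.ndarray:
    """Draw gene-body relative positions u in [0, 1) with a linear density.

    five_prime:  f(u) ∝ 1 + s(1-u)   (mass toward u=0, the TSS)
    three_prime: f(u) ∝ 1 + s·u      (mass toward u=1, the TES)
    uniform or s=0: flat.
    """
    if bias == "uniform" or strength == 0:
        return rng.random(n)
    q = rng.random(n)
    s = float(strength)
    if bias == "five_prime":
        a, b = 1.0 + s, -s
    else:
        a, b = 1.0, s
    # inverse CDF of f(u) = (a + b u) / (a + b/2)
    disc = a * a + 2.0 * b * q * (a + b / 2.0)
    u = (np.sqrt(disc) - a) / b
    return np.clip(u, 0.0, np.nextafter(1.0, 0.0))


def simulate_reads(genome: GenomeModel, annotation: GeneTable,
                   model: EnrichmentModel, config: SimulationConfig,
                   replicate: int = 0, sample_id: str = "sim",
                   ) -> ReadAlignmentSet:
    """Simulate one replicate of mapped reads under an enrichment model.

    Exactly ``config.n_reads`` reads are emitted, clamped to chromosome
    ends and sorted by (chrom, start).  Read strands are random — ChIP
    fragments are sequenced from either end — and do not affect which
    gene a read came from.
    """
    if annotation.genome is not genome:
        annotation = GeneTable(annotation.df, genome)
    rng = _replicate_rng(config.seed, replicate)
    n = config.n_reads
    rl = config.read_length

    bg_fraction = 1.0 if model.is_flat else model.background_fraction
    is_background = rng.random(n) < bg_fraction
    n_bg = int(is_background.sum())
    n_fg = n - n_bg

    chrom_names = np.array(genome.names, dtype=object)
    chrom_lengths = np.array([c.length for c in genome.chromosomes],
                             dtype=np.int64)

    chroms = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=np.int64)

    if n_bg:
        p = chrom_lengths / chrom_lengths.sum()
        ci = rng.choice(len(chrom_names), size=n_bg, p=p)
        chroms[is_background] = chrom_names[ci]
        starts[is_background] = rng.integers(0, chrom_lengths[ci])

    if n_fg:
        df = annotation.df
        weights = df["gene_class"].map(
            lambda c: model.class_weights.get(c, 0.0)).to_numpy(dtype=float)
        lengths = (df["end"] - df["start"]).to_numpy(dtype=float)
        on_x = df["chrom"].map(genome.is_x).to_numpy(dtype=bool)
        w = weights * lengths * np.where(on_x, model.x_weight_multiplier, 1.0)
        total = w.sum()
        if total <= 0:
            raise ConfigurationError(
                "enrichment model assigns zero weight to every gene")
        gi = rng.choice(len(df), size=n_fg, p=w / total)
        u = _sample_relative_positions(rng, n_fg, model.positional_bias,
                                       model.bias_strength)
        g_start = df["start"].to_numpy()[gi]
        g_end = df["end"].to_numpy()[gi]
        g_len = g_end - g_start
        fwd = df["strand"].to_numpy()[gi] == "+"
        offset = np.floor(u * g_len).astype(np.int64)
        pos = np.where(fwd, g_start + offset, g_end - 1 - offset)
        chroms[~is_background] = df["chrom"].to_numpy(dtype=object)[gi]
        starts[~is_background] = pos

    length_by_name = {c.name: c.length for c in genome.chromosomes}
    lens = np.array([length_by_name[c] for c in chroms], dtype=np.int64)
    ends = np.minimum(starts + rl, lens)
    strands = rng.choice(["+", "-"], size=n)

    out = ReadAlignmentSet(sample_id, replicate, chroms, starts, ends,
                           strands, genome)
    return out.sorted()


def simulate_replicates(genome: GenomeModel, annotation: GeneTable,
                        model: EnrichmentModel, config: SimulationConfig,
                        sample_id: str = "sim") -> list[ReadAlignmentSet]:
    """All replicates of a sample, each from its own derived stream."""
    return [simulate_reads(genome, annotation, model, config,
                           replicate=r, sample_id=sample_id)
            for r in range(config.replicate_count)]


def simulate_expression_tags(annotation: GeneTable, tissues: list[str],
                             depth: float, seed: int) -> pd.DataFrame:
    """Per-gene x per-tissue tag counts with class-determined support.

    A gene's class fixes the set of tissues in which its expected count
    is nonzero (Poisson with mean ``depth``); all other tissues are
    exactly zero.  Returns a DataFrame indexed by gene id with one
    column per tissue.
    """
    unknown = [t for t in tissues if t not in TISSUES]
    if unknown:
        raise ConfigurationError(f"unknown tissue names: {unknown}")
    missing = [t for t in TISSUES if t not in tissues]
    if missing:
        raise ConfigurationError(
            f"tissues must include all of {TISSUES}; missing {missing}")
    if depth <= 0:
        raise ConfigurationError("depth must be > 0")
    rng = np.random.default_rng(seed)
    df = annotation.df
    counts = np.zeros((len(df), len(tissues)), dtype=np.int64)
    for j, tissue in enumerate(tissues):
        expressed = df["gene_class"].map(
            lambda c: tissue in CLASS_TISSUES.get(c, ())).to_numpy(dtype=bool)
        n_expr = int(expressed.sum())
        if n_expr:
            counts[expressed, j] = rng.poisson(depth, size=n_expr)
    out = pd.DataFrame(counts, columns=list(tissues),
                       index=pd.Index(df["gene_id"], name="gene"))
    if (out < 0).any().any():
        raise ValidationError("negative tag count")  # pragma: no cover
    return out
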