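"""Per-gene gene-body scores and chromosome-level summaries.

A gene's score is the mean coverage over every base pair between its
transcription start and end sites (introns included, strand ignored);
the log10 of that mean is what scatter comparisons plot.  Zero-mean
genes have no defined log10 score and are excluded from scatter tables,
with the exclusions counted rather than imputed (an optional pseudocount
is available for users who prefer imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .coverage import MEDIAN_SCALED, REPLICATE_AVERAGED, CoverageTrack
from .errors import ConfigurationError, ValidationError
from .genome import GeneTable, GenomeModel


def gene_body_score(track: CoverageTrack, genes: GeneTable,
                    pseudocount: float = 0.0) -> pd.DataFrame:
    """Mean gene-body signal and log10 score per gene.

    Returns a DataFrame with columns ``gene_id, gene_class, chrom,
    body_length, mean_signal, log10_score``; ``log10_score`` is NaN
    where ``mean_signal + pseudocount == 0``.
    """
    if track.normalization_state not in (MEDIAN_SCALED, REPLICATE_AVERAGED):
        raise ValidationError(
            "gene scores require a median_scaled or replicate_averaged track")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be >= 0")
    df = genes.df
    if (df["end"] - df["start"] <= 0).any():
        raise ValidationError("zero-length gene")
    rows = []
    for rec in df.itertuples(index=False):
        if rec.chrom not in track.genome:
            raise ValidationError(f"unknown chromosome {rec.chrom!r}")
        if rec.end > track.genome.length_of(rec.chrom):
            raise ValidationError(f"gene {rec.gene_id} out of bounds")
        body = track.data[rec.chrom][rec.start:rec.end]
        mean = float(body.mean())
        shifted = mean + pseudocount
        log10 = float(np.log10(shifted)) if shifted > 0 else np.nan
        rows.append((rec.gene_id, rec.gene_class, rec.chrom,
                     rec.end - rec.start, mean, log10))
    return pd.DataFrame(rows, columns=["gene_id", "gene_class", "chrom",
                                       "body_length", "mean_signal",
                                       "log10_score"])


@dataclass
class ScatterResult:
    """Paired log10 scores plus an accounting of excluded genes."""
    table: pd.DataFrame           # gene_id, log10_a, log10_b, highlighted
    n_dropped_a: int              # undefined on axis a
    n_dropped_b: int              # undefined on axis b


def scatter_table(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                  highlight: set[str] | None = None) -> ScatterResult:
    """Pair two score tables gene-by-gene for a log-log scatter.

    The gene universe is the intersection of the two tables; genes with
    an undefined log10 score on either axis are dropped and counted.
    """
    highlight = set(highlight or ())
    a = scores_a.set_index("gene_id")
    b = scores_b.set_index("gene_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValidationError("score tables share no genes")
    a = a.loc[common]
    b = b.loc[common]
    bad_a = a["log10_score"].isna()
    bad_b = b["log10_score"].isna()
    keep = ~(bad_a | bad_b)
    out = pd.DataFrame({
        "gene_id": common[keep],
        "log10_a": a.loc[keep, "log10_score"].to_numpy(),
        "log10_b": b.loc[keep, "log10_score"].to_numpy(),
    })
    out["highlighted"] = out["gene_id"].isin(highlight)
    return ScatterResult(out, int(bad_a.sum()), int(bad_b.sum()))


def chromosome_summary(track: CoverageTrack,
                       genome: GenomeModel | None = None) -> pd.DataFrame:
    """Mean signal per chromosome plus the X : pooled-autosome ratio.

    The ratio row uses chromosome name ``X:A``; it is absent when the
    genome has no X chromosome.
    """
    genome = genome or track.genome
    rows = [(c.name, float(track.data[c.name].mean()), c.is_x)
            for c in genome.chromosomes]
    df = pd.DataFrame(rows, columns=["chrom", "mean_signal", "is_x"])
    x_name = genome.x_name
    if x_name is not None:
        auto = np.concatenate([track.data[c.name]
                               for c in genome.chromosomes if not c.is_x])
        ratio = float(track.data[x_name].mean() / auto.mean())
        df.attrs["x_autosome_ratio"] = ratio
    return df


def x_autosome_ratio(track: CoverageTrack) -> float:
    """mean(X) / mean(pooled autosomes); raises without an X chromosome."""
    df = chromosome_summary(track)
    if "x_autosome_ratio" not in df.attrs:
        raise ValidationError("genome has no X chromosome")
    return df.attrs["x_autosome_ratio"]


def intergenic_values(track: CoverageTrack, genes: GeneTable) -> np.ndarray:
    """Per-bp signal over bases outside every gene body."""
    chunks = []
    for c in track.genome.chromosomes:
        mask = np.ones(c.length, dtype=bool)
        sub = genes.df[genes.df["chrom"] == c.name]
        for s, e in zip(sub["start"], sub["end"]):
            mask[s:e] = False
        chunks.append(track.data[c.name][mask])
    return np.concatenate(chunks)


def classify_enriched(scores: pd.DataFrame, track: CoverageTrack,
                      genes: GeneTable,
                      background_quantile: float = 0.95) -> dict:
    """Call genes whose mean body signal clears an intergenic quantile.

    This is a reconstruction of "clear enrichment" as signal above the
    given quantile of the intergenic per-bp background; the threshold
    used is echoed in the result.
    """
    if not 0.0 < background_quantile < 1.0:
        raise ConfigurationError("background_quantile must be in (0, 1)")
    bg = intergenic_values(track, genes)
    if bg.size == 0:
        raise ValidationError("no intergenic bases to estimate background")
    threshold = float(np.quantile(bg, background_quantile))
    enriched = set(scores.loc[scores["mean_signal"] > threshold, "gene_id"])
    return {"enriched": enriched, "threshold": threshold,
            "background_quantile": background_quantile,
            "n_intergenic_bases": int(bg.size)}


def rank_auc(scores: pd.DataFrame, positive_class: str,
             negative_class: str, column: str = "mean_signal") -> float:
    """AUC of the score ranking positive-class vs negative-class genes.

    Rank-based, so any monotone transform of the score (mean signal or
    its log10) yields the same value.
    """
    sub = scores[scores["gene_class"].isin([positive_class, negative_class])]
    if sub["gene_class"].nunique() < 2:
        raise ValidationError("need genes of both classes for an AUC")
    y = (sub["gene_class"] == positive_class).to_numpy(dtype=int)
    return float(roc_auc_score(y, sub[column].to_numpy()))
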