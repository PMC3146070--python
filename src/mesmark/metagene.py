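"""Anchored metagene profiles around the TSS and TES.

Genes are aligned at a strand-aware anchor; signal is averaged in
fixed-width bins (default 50 bp) from 1 kb upstream to 1.5 kb downstream
of the TSS, and 1.5 kb upstream to 1 kb downstream of the TES.  Bin
means are first computed per gene, then averaged across genes; the
spread across genes gives a 95% confidence interval per bin
(normal approximation mean ± 1.96·SEM by default, Student-t optional).

Upstream always means 5' of the gene: on a minus-strand gene the window
is mirrored on the genome.  The window is anchored, not clipped to the
gene, so short genes still contribute every bin; only bins that would
run off a chromosome end drop that gene (and its count) from the bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageTrack
from .errors import ConfigurationError, ValidationError
from .genome import GeneTable

TSS = "tss"
TES = "tes"

#: Default windows, in bp: (upstream, downstream) per anchor.
DEFAULT_WINDOWS = {TSS: (1000, 1500), TES: (1500, 1000)}
DEFAULT_BIN = 50


@dataclass
class MetageneProfile:
    anchor: str
    upstream: int
    downstream: int
    bin_width: int
    bins: pd.DataFrame  # offset, mean, ci_halfwidth, n

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_table(self) -> pd.DataFrame:
        t = self.bins.copy()
        t["ci_lo"] = t["mean"] - t["ci_halfwidth"]
        t["ci_hi"] = t["mean"] + t["ci_halfwidth"]
        return t[["offset", "mean", "ci_lo", "ci_hi", "n"]]


def _per_gene_bin_means(track: CoverageTrack, genes: GeneTable,
                        anchor: str, upstream: int, downstream: int,
                        bin_width: int) -> np.ndarray:
    """(n_genes, n_bins) matrix of per-gene bin means; NaN where a bin
    leaves the chromosome."""
    n_bins = (upstream + downstream) // bin_width
    anchors = genes.tss() if anchor == TSS else genes.tes()
    fwd = genes.df["strand"].to_numpy() == "+"
    chroms = genes.df["chrom"].to_numpy()
    offs = np.arange(-upstream, downstream)
    out = np.full((len(genes.df), n_bins), np.nan)
    for i, (a, f, chrom) in enumerate(zip(anchors, fwd, chroms)):
        L = track.genome.length_of(chrom)
        pos = a + offs if f else a - offs
        ok = (pos >= 0) & (pos < L)
        vals = np.full(offs.shape, np.nan)
        vals[ok] = track.data[chrom][pos[ok]]
        binned = vals.reshape(n_bins, bin_width)
        complete = ~np.isnan(binned).any(axis=1)
        out[i, complete] = binned[complete].mean(axis=1)
    return out


def profile(track: CoverageTrack, genes: GeneTable, geneset,
            anchor: str = TSS, upstream: int | None = None,
            downstream: int | None = None, bin_width: int = DEFAULT_BIN,
            ci: str = "normal") -> MetageneProfile:
    """Average signal in strand-oriented bins around an anchor.

    ``geneset`` is an iterable of gene ids (must be a subset of the
    annotation).  Offsets label the 5' edge of each bin: bin ``[0, 50)``
    starts at the anchor, upstream bins carry negative offsets.
    """
    anchor = anchor.lower()
    if anchor not in (TSS, TES):
        raise ConfigurationError(f"anchor must be 'tss' or 'tes', got {anchor!r}")
    up_d, down_d = DEFAULT_WINDOWS[anchor]
    upstream = up_d if upstream is None else int(upstream)
    downstream = down_d if downstream is None else int(downstream)
    if bin_width <= 0:
        raise ConfigurationError("bin width must be positive")
    if upstream % bin_width or downstream % bin_width:
        raise ConfigurationError("bin width must divide both window spans")
    ids = list(geneset)
    if not ids:
        raise ValidationError("empty gene set")
    sub = genes.subset(ids)

    mat = _per_gene_bin_means(track, sub, anchor, upstream, downstream,
                              bin_width)
    n = (~np.isnan(mat)).sum(axis=0)
    if (n < 1).any():
        raise ValidationError("a bin has no contributing genes")
    import warnings as _warnings
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # bins with a single contributing gene have no spread estimate;
        # their CI is set to zero below
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sd = np.where(n > 1, sd, 0.0)
    sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    if ci == "normal":
        crit = np.full(mean.shape, 1.96)
    elif ci == "t":
        crit = np.where(n > 1, stats.t.ppf(0.975, np.maximum(n - 1, 1)), 0.0)
    else:
        raise ConfigurationError(f"unknown CI method {ci!r}")
    half = np.where(n > 1, crit * sem, 0.0)
    offsets = np.arange(-upstream, downstream, bin_width)
    bins = pd.DataFrame({"offset": offsets, "mean": mean,
                         "ci_halfwidth": half, "n": n})
    return MetageneProfile(anchor, upstream, downstream, bin_width, bins)


def profile_contrast(profile_a: MetageneProfile,
                     profile_b: MetageneProfile) -> pd.DataFrame:
    """Per-bin mean difference (a − b) with a pooled 95% CI."""
    same = (profile_a.anchor == profile_b.anchor
            and profile_a.upstream == profile_b.upstream
            and profile_a.downstream == profile_b.downstream
            and profile_a.bin_width == profile_b.bin_width)
    if not same:
        raise ValidationError("profiles have mismatched geometry")
    a, b = profile_a.bins, profile_b.bins
    diff = a["mean"].to_numpy() - b["mean"].to_numpy()
    pooled = np.sqrt(a["ci_halfwidth"].to_numpy() ** 2
                     + b["ci_halfwidth"].to_numpy() ** 2)
    return pd.DataFrame({"offset": a["offset"], "difference": diff,
                         "ci_halfwidth": pooled,
                         "n_a": a["n"], "n_b": b["n"]})
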