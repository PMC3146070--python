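"""Expression-class gene sets from multi-tissue tag-count tables.

Classification mirrors SAGE-style breadth-of-expression rules:

* *ubiquitous* — expressed (≥ 1 tag by default) in germline, muscle,
  nerve and gut alike;
* *somatic* — strongly expressed (≥ 8 tags by default) in at least one
  somatic tissue while carrying zero germline tags ("not expressed"
  means strictly below the 1-tag expression threshold, i.e. exactly 0
  at the default);
* *germline-enriched* — an externally supplied list minus an exclusion
  list (e.g. spermatogenesis genes);
* *larval/adult germline-specific* — the triple intersection of the
  germline-enriched list, the germline-expressed genes from tags, and a
  strictly-maternal list.

Raw tag counts are used as-is; no library-size normalization is applied
before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, ValidationError


@dataclass
class GeneSetConfig:
    somatic_tissues: tuple[str, ...] = ("muscle", "nerve", "gut")
    germline_tissue: str = "germline"
    expressed_threshold: int = 1
    somatic_threshold: int = 8

    def __post_init__(self) -> None:
        if self.expressed_threshold < 1 or self.somatic_threshold < 1:
            raise ConfigurationError("tag thresholds must be >= 1")
        if not self.somatic_tissues:
            raise ConfigurationError("somatic tissue list is empty")


def _require_tissues(tags: pd.DataFrame, tissues) -> None:
    missing = [t for t in tissues if t not in tags.columns]
    if missing:
        raise ValidationError(f"tag table missing tissue columns: {missing}")
    if (tags[list(tissues)] < 0).any().any():
        raise ValidationError("negative tag counts")


def define_ubiquitous(tags: pd.DataFrame,
                      cfg: GeneSetConfig | None = None) -> set[str]:
    """Genes expressed in the germline and every somatic tissue."""
    cfg = cfg or GeneSetConfig()
    tissues = (cfg.germline_tissue, *cfg.somatic_tissues)
    _require_tissues(tags, tissues)
    ok = (tags[list(tissues)] >= cfg.expressed_threshold).all(axis=1)
    return set(tags.index[ok])


def define_somatic(tags: pd.DataFrame,
                   cfg: GeneSetConfig | None = None) -> set[str]:
    """Genes strongly expressed somewhere in the soma with no germline tags."""
    cfg = cfg or GeneSetConfig()
    tissues = (cfg.germline_tissue, *cfg.somatic_tissues)
    _require_tissues(tags, tissues)
    somatic_hit = (tags[list(cfg.somatic_tissues)]
                   >= cfg.somatic_threshold).any(axis=1)
    germline_silent = tags[cfg.germline_tissue] < cfg.expressed_threshold
    return set(tags.index[somatic_hit & germline_silent])


def define_germline_enriched(input_genes, exclude_genes=()) -> set[str]:
    """Set difference of a published germline-enriched list and an
    exclusion list; duplicates collapse under set semantics."""
    return set(input_genes) - set(exclude_genes)


def define_larval_adult_germline_specific(germline_enriched,
                                          sage_germline_expressed,
                                          strictly_maternal) -> set[str]:
    """Triple intersection defining genes expressed only in the
    post-embryonic germline."""
    return set(germline_enriched) & set(sage_germline_expressed) \
        & set(strictly_maternal)


def germline_expressed(tags: pd.DataFrame,
                       cfg: GeneSetConfig | None = None) -> set[str]:
    """Genes with at least the expression-threshold tags in germline."""
    cfg = cfg or GeneSetConfig()
    _require_tissues(tags, (cfg.germline_tissue,))
    ok = tags[cfg.germline_tissue] >= cfg.expressed_threshold
    return set(tags.index[ok])
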