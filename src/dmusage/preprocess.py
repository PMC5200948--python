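"""Expression-based filtering of features and genes before model fitting.

Two filter flavours exist:

* :func:`filter_features` / :func:`filter_genes` — the cohort-scale rules used
  ahead of QTL scans (a feature must be decently expressed in enough samples;
  a gene must be expressed in enough samples and keep >= 2 features);
* :func:`prefilter_low_fraction` — the lighter differential-usage pre-filter
  that drops features whose usage is below a fraction threshold in *every*
  sample.

Proportions for the filter decisions are computed against the gene totals of
the *raw* (unfiltered) matrix; column totals are recomputed after subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneCounts

__all__ = ["FilterConfig", "filter_features", "filter_genes",
           "prefilter_low_fraction", "filter_dataset"]


@dataclass
class FilterConfig:
    """Thresholds for feature/gene expression filtering.

    Defaults follow a large-cohort QTL setting (the 70-sample gene rule); for a
    small differential-usage design, lower ``min_samps_gene`` (e.g. to the
    number of samples) or rely on :func:`prefilter_low_fraction` alone.
    """

    min_feature_count: int = 10
    min_feature_prop: float = 0.05
    min_samps_feature: int = 5
    min_gene_count: int = 10
    min_samps_gene: int = 70
    min_features_per_gene: int = 2

    def __post_init__(self):
        for name in ("min_feature_count", "min_feature_prop", "min_samps_feature",
                     "min_gene_count", "min_samps_gene"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_features_per_gene < 2:
            raise ValueError("min_features_per_gene must be >= 2")


def _proportions(gene: GeneCounts) -> np.ndarray:
    """Per-sample feature proportions y_ji / m_i; zero-total samples give 0."""
    totals = gene.column_totals.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, gene.counts / totals, 0.0)
    return props


def filter_features(gene: GeneCounts, config: FilterConfig) -> GeneCounts:
    """Keep features with count >= min_feature_count AND proportion >=
    min_feature_prop jointly in at least min_samps_feature samples."""
    props = _proportions(gene)
    ok_per_sample = (gene.counts >= config.min_feature_count) & \
                    (props >= config.min_feature_prop)
    keep = ok_per_sample.sum(axis=1) >= config.min_samps_feature
    return gene.subset_features(keep)


def filter_genes(dataset, config: FilterConfig):
    """Keep genes expressed (total >= min_gene_count) in >= min_samps_gene
    samples with >= min_features_per_gene surviving features."""
    kept = []
    for gene in dataset:
        enough_samples = (gene.column_totals >= config.min_gene_count).sum() \
            >= config.min_samps_gene
        if enough_samples and gene.n_features >= config.min_features_per_gene:
            kept.append(gene)
    return kept


def prefilter_low_fraction(dataset, threshold: float = 0.05,
                           min_features_per_gene: int = 2):
    """Drop features whose within-sample proportion is < threshold in EVERY sample.

    Genes left with fewer than ``min_features_per_gene`` features are removed.
    """
    out = []
    for gene in dataset:
        props = _proportions(gene)
        keep = (props >= threshold).any(axis=1)
        sub = gene.subset_features(keep)
        if sub.n_features >= min_features_per_gene:
            out.append(sub)
    return out


def filter_dataset(dataset, config: FilterConfig):
    """Feature filter then gene filter; returns (kept genes, summary table)."""
    rows, kept = [], []
    filtered = [(g, filter_features(g, config)) for g in dataset]
    survivors = filter_genes([f for _, f in filtered], config)
    surviving_ids = {g.gene_id for g in survivors}
    for orig, filt in filtered:
        rows.append({
            "gene_id": orig.gene_id,
            "n_features_before": orig.n_features,
            "n_features_after": filt.n_features,
            "kept": orig.gene_id in surviving_ids,
        })
        if orig.gene_id in surviving_ids:
            kept.append(filt)
    return kept, pd.DataFrame(rows)
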