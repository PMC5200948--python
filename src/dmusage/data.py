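"""Core data containers for multivariate (per-gene, per-feature) count data.

A *gene* is an observational unit whose outcome is a vector of counts over
``q`` features (transcripts, exonic bins, junctions ...) in each of ``n``
samples.  The per-sample total ``m_i`` is treated as ancillary: it reflects
sequencing depth and overall gene expression, not relative feature usage, so
no library-size normalisation is applied anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneCounts", "DMParameters", "MomentSummary"]


@dataclass
class GeneCounts:
    """One gene's feature-by-sample integer count matrix.

    Parameters
    ----------
    gene_id : str
        Gene identifier.
    feature_ids : list of str
        Identifiers of the ``q`` features (rows); unique within the gene.
    sample_ids : list of str
        Identifiers of the ``n`` samples (columns); unique.
    counts : ndarray of shape (q, n)
        Non-negative integer counts.
    """

    gene_id: str
    feature_ids: list
    sample_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError(f"{self.gene_id}: counts must be a 2-d (q x n) matrix")
        q, n = self.counts.shape
        if len(self.feature_ids) != q:
            raise ValueError(f"{self.gene_id}: {len(self.feature_ids)} feature ids for {q} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{self.gene_id}: {len(self.sample_ids)} sample ids for {n} columns")
        if len(set(self.feature_ids)) != q:
            raise ValueError(f"{self.gene_id}: duplicate feature ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"{self.gene_id}: duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError(f"{self.gene_id}: counts must be integers")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError(f"{self.gene_id}: negative counts")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def column_totals(self) -> np.ndarray:
        """Per-sample totals ``m_i``."""
        return self.counts.sum(axis=0)

    @property
    def mean_expression(self) -> float:
        """Arithmetic mean over samples of the per-sample gene totals."""
        return float(self.column_totals.mean())

    def subset_features(self, keep: np.ndarray) -> "GeneCounts":
        """Return a copy restricted to the features selected by boolean/index mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            fids = [f for f, k in zip(self.feature_ids, keep) if k]
            sub = self.counts[keep]
        else:
            fids = [self.feature_ids[i] for i in keep]
            sub = self.counts[keep]
        return GeneCounts(self.gene_id, fids, list(self.sample_ids), sub.copy())

    def reorder_samples(self, order) -> "GeneCounts":
        order = np.asarray(order)
        return GeneCounts(
            self.gene_id,
            list(self.feature_ids),
            [self.sample_ids[i] for i in order],
            self.counts[:, order].copy(),
        )


@dataclass
class DMParameters:
    """Dirichlet-multinomial parameters: per-group proportions and shared concentration.

    The concentration ``gamma_plus`` (Dirichlet precision) is shared across
    groups; the dispersion is ``theta = 1 / (1 + gamma_plus)``, so ``theta -> 0``
    recovers the multinomial.  The Dirichlet parameter vector of group ``k`` is
    recoverable as ``gamma_k = gamma_plus * pi_k``.
    """

    proportions_by_group: dict
    concentration: float

    _TOL = 1e-10

    def __post_init__(self):
        if not np.isfinite(self.concentration) or self.concentration <= 0:
            raise ValueError("concentration (gamma_plus) must be a positive finite scalar")
        clean = {}
        for k, pi in self.proportions_by_group.items():
            pi = np.asarray(pi, dtype=float)
            if (pi <= 0).any() or (pi >= 1).any() and pi.size > 1:
                raise ValueError(f"group {k}: proportions must lie in (0, 1)")
            if abs(pi.sum() - 1.0) > 1e-8:
                raise ValueError(f"group {k}: proportions sum to {pi.sum()}, not 1")
            clean[k] = pi / pi.sum()
        self.proportions_by_group = clean

    @property
    def dispersion(self) -> float:
        """theta = 1 / (1 + gamma_plus), in (0, 1)."""
        return 1.0 / (1.0 + self.concentration)

    def gamma(self, group) -> np.ndarray:
        """Dirichlet parameter vector gamma = gamma_plus * pi for one group."""
        return self.concentration * self.proportions_by_group[group]


@dataclass
class MomentSummary:
    """Mean, covariance and overdispersion inflation factor of a DM count vector.

    ``inflation_factor`` is ``c = (m + gamma_plus) / (1 + gamma_plus)``, the
    multiplier taking the multinomial covariance to the DM covariance; it is
    >= 1 and tends to 1 as the concentration grows.
    """

    mean: np.ndarray
    covariance: np.ndarray
    inflation_factor: float
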