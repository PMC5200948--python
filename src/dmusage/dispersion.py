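"""Concentration (dispersion) estimation by adjusted profile likelihood.

The concentration ``gamma_plus`` is the parameter of interest; the per-group
proportions are nuisance parameters that are profiled out.  The raw profile
log-likelihood PL(gamma_plus) is known to be biased with many nuisance
parameters, so a Cox-Reid adjustment subtracts half the log-determinant of the
observed information of the nuisance proportions:

    APL(gamma_plus) = PL(gamma_plus) - 1/2 log det I_obs(pi_hat)

penalising concentrations at which the data are unusually informative about
the proportions.  Estimation is by grid search over log10 gamma_plus; per-gene
APL curves are cached so that empirical-Bayes moderation (shrinking each
gene's curve toward the all-gene average, or toward the average over genes of
similar expression) is a cheap weighted sum of curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dm
from .data import GeneCounts

__all__ = [
    "DispersionConfig",
    "DispersionEstimates",
    "profile_loglik",
    "adjusted_profile_loglik",
    "apl_curve",
    "apl_matrix",
    "estimate_common",
    "estimate_genewise",
    "build_trend_sets",
]

MODES = ("common", "genewise-none", "genewise-moderate-common", "genewise-moderate-trend")


@dataclass
class DispersionConfig:
    """Settings for concentration estimation.

    Parameters
    ----------
    mode : str
        One of ``common``, ``genewise-none``, ``genewise-moderate-common``,
        ``genewise-moderate-trend``.
    grid_length : int
        Number of grid points, equally spaced in log10 gamma_plus.
    grid_log10_range : (float, float)
        Endpoints of the log10 gamma_plus grid (default [0, 6], i.e.
        gamma_plus in [1, 1e6]).
    moderation_weight : float
        W >= 0; the all-gene (or neighborhood) average APL curve enters the
        per-gene objective with this weight, i.e. the shared curve counts as
        W pseudo-genes of data.  The default 0.05 is deliberately weak: it is
        enough to pull flat, boundary-bound likelihood curves toward the
        shared optimum without displacing well-identified per-gene maxima,
        and was validated on concentration-recovery simulations.  W = 0
        disables moderation.
    trend_window_fraction : float
        Fraction of genes in each expression-ranked trend neighborhood.
    trend_min_genes : int
        Minimum neighborhood size; datasets smaller than this fall back to
        moderation toward the common curve.
    adjustment : str
        ``cox-reid`` (default) or ``none`` (raw profile likelihood).
    """

    mode: str = "genewise-moderate-common"
    grid_length: int = 21
    grid_log10_range: tuple = (0.0, 6.0)
    moderation_weight: float = 0.05
    trend_window_fraction: float = 0.1
    trend_min_genes: int = 50
    adjustment: str = "cox-reid"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown dispersion mode {self.mode!r}; choose from {MODES}")
        if self.grid_length < 3:
            raise ValueError("grid_length must be >= 3")
        lo, hi = self.grid_log10_range
        if not lo < hi:
            raise ValueError("grid_log10_range must be strictly increasing")
        if not np.isfinite(self.moderation_weight) or self.moderation_weight < 0:
            raise ValueError("moderation_weight must be finite and >= 0")
        if self.adjustment not in ("cox-reid", "none"):
            raise ValueError("adjustment must be 'cox-reid' or 'none'")

    @property
    def grid(self) -> np.ndarray:
        lo, hi = self.grid_log10_range
        return np.logspace(lo, hi, self.grid_length)


@dataclass
class DispersionEstimates:
    """Per-gene concentration estimates plus the grid diagnostics behind them."""

    table: pd.DataFrame  # gene_id, gamma_plus, at_boundary, mean_expression, mode
    grid: np.ndarray
    apl: np.ndarray  # genes x grid, the (moderated) objective actually maximised
    mode: str

    def __getitem__(self, gene_id: str) -> float:
        row = self.table.loc[self.table["gene_id"] == gene_id, "gamma_plus"]
        if row.empty:
            raise KeyError(gene_id)
        return float(row.iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        """Diagnostic log-log scatter of gamma_plus_hat vs mean gene expression."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.table["mean_expression"], self.table["gamma_plus"], s=8, alpha=0.6)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("mean gene expression")
        ax.set_ylabel(r"$\hat{\gamma}_+$")
        ax.set_title(f"dispersion estimates ({self.mode})")
        return ax


def profile_loglik(gene: GeneCounts, grouping: dict, gamma_plus: float,
                   init: dict | None = None) -> float:
    """PL(gamma_plus): log-likelihood with per-group proportions maximised out."""
    fit = dm.estimate_proportions(gene, grouping, gamma_plus, init=init)
    return fit.loglik


def _cr_logdet(gene: GeneCounts, grouping: dict, gamma_plus: float, proportions: dict):
    """log det of the block-diagonal observed information over groups.

    Returns (logdet, ok); ok is False when the information is not positive
    definite (degenerate data), in which case callers fall back to the raw PL.
    """
    logdet = 0.0
    for g, sub in dm._split_by_group(gene, grouping).items():
        info = dm.observed_information(sub, proportions[g], gamma_plus)
        sign, ld = np.linalg.slogdet(info)
        if sign <= 0 or not np.isfinite(ld):
            return 0.0, False
        logdet += ld
    return logdet, True


def adjusted_profile_loglik(gene: GeneCounts, grouping: dict, gamma_plus: float,
                            init: dict | None = None) -> float:
    """APL(gamma_plus) = PL - 1/2 log det I_obs at the profiled proportions."""
    fit = dm.estimate_proportions(gene, grouping, gamma_plus, init=init)
    logdet, ok = _cr_logdet(gene, grouping, gamma_plus, fit.proportions)
    if not ok:
        warnings.warn(f"{gene.gene_id}: observed information not positive definite "
                      f"at gamma_plus={gamma_plus:g}; using raw profile likelihood")
        return fit.loglik
    return fit.loglik - 0.5 * logdet


def apl_curve(gene: GeneCounts, grouping: dict, grid: np.ndarray,
              adjustment: str = "cox-reid") -> np.ndarray:
    """(A)PL evaluated on a concentration grid, warm-starting along the grid."""
    vals = np.empty(len(grid))
    init = None
    for k, gp in enumerate(grid):
        fit = dm.estimate_proportions(gene, grouping, float(gp), init=init)
        init = fit.proportions  # warm start the next grid point
        if adjustment == "cox-reid":
            logdet, ok = _cr_logdet(gene, grouping, float(gp), fit.proportions)
            vals[k] = fit.loglik - 0.5 * logdet if ok else fit.loglik
        else:
            vals[k] = fit.loglik
    return vals


def apl_matrix(genes, grouping: dict, config: DispersionConfig) -> np.ndarray:
    """Stack of per-gene (A)PL curves, genes x grid."""
    grid = config.grid
    return np.vstack([apl_curve(g, grouping, grid, config.adjustment) for g in genes])


def _argmax_smallest(values: np.ndarray) -> int:
    """Index of the maximum; ties broken toward the smallest gamma_plus."""
    return int(np.flatnonzero(values >= values.max() - 0.0)[0])


def estimate_common(genes, grouping: dict, config: DispersionConfig | None = None,
                    curves: np.ndarray | None = None) -> float:
    """Single concentration shared by all genes: argmax of the mean APL curve."""
    config = config or DispersionConfig(mode="common")
    genes = list(genes)
    if not genes and curves is None:
        raise ValueError("cannot estimate a common concentration from zero genes")
    if curves is None:
        curves = apl_matrix(genes, grouping, config)
    mean_curve = curves.mean(axis=0)
    return float(config.grid[_argmax_smallest(mean_curve)])


def build_trend_sets(mean_expressions, config: DispersionConfig) -> list:
    """Expression-ranked neighborhoods for moderation toward a dispersion trend.

    Genes are ranked by mean expression; each gene's set is the window of
    ``max(ceil(fraction * G), trend_min_genes)`` consecutive ranks centred on
    it, shifted (not shrunk) at the extremes so every window has full size.
    """
    mean_expressions = np.asarray(mean_expressions, dtype=float)
    G = mean_expressions.size
    w = max(int(np.ceil(config.trend_window_fraction * G)), config.trend_min_genes)
    if w > G:
        raise ValueError(f"trend neighborhoods need >= {w} genes, have {G}")
    order = np.argsort(mean_expressions, kind="stable")
    rank = np.empty(G, dtype=int)
    rank[order] = np.arange(G)
    sets = [None] * G
    for g in range(G):
        lo = rank[g] - w // 2
        lo = min(max(lo, 0), G - w)
        sets[g] = order[lo:lo + w]
    return sets


def estimate_genewise(genes, grouping: dict, config: DispersionConfig,
                      curves: np.ndarray | None = None) -> DispersionEstimates:
    """Per-gene concentration on the grid, optionally moderated.

    The maximised objective per gene is ``APL_g + W * mean(APL over C)`` where
    C is all genes (moderate-common) or the gene's expression neighborhood
    (moderate-trend); W = 0 reproduces the unmoderated genewise estimator.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene collection")
    grid = config.grid
    if curves is None:
        curves = apl_matrix(genes, grouping, config)
    W = config.moderation_weight
    if config.mode == "genewise-none" or W == 0:
        objective = curves
    elif config.mode == "genewise-moderate-common" or config.mode == "common":
        objective = curves + W * curves.mean(axis=0)
    elif config.mode == "genewise-moderate-trend":
        me = np.array([g.mean_expression for g in genes])
        try:
            sets = build_trend_sets(me, config)
        except ValueError:
            warnings.warn("too few genes for trend neighborhoods; "
                          "falling back to moderation toward the common curve")
            sets = None
        if sets is None:
            objective = curves + W * curves.mean(axis=0)
        else:
            target = np.vstack([curves[C].mean(axis=0) for C in sets])
            objective = curves + W * target
    else:  # pragma: no cover
        raise ValueError(config.mode)

    idx = np.array([_argmax_smallest(row) for row in objective])
    if config.mode == "common":
        common = estimate_common(genes, grouping, config, curves=curves)
        gp = np.full(len(genes), common)
        idx = np.full(len(genes), int(np.flatnonzero(grid == common)[0]))
    else:
        gp = grid[idx]
    table = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "gamma_plus": gp,
        "at_boundary": (idx == 0) | (idx == len(grid) - 1),
        "mean_expression": [g.mean_expression for g in genes],
        "mode": config.mode,
    })
    return DispersionEstimates(table=table, grid=grid, apl=objective, mode=config.mode)
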