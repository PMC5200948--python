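"""Differential transcript usage (DTU): per-gene likelihood-ratio tests.

For each gene the full model fits one proportion vector per condition group
and the null model fits a single pooled vector, both at the same fixed
concentration estimated in a first step.  The statistic

    D = 2 * (l_full - l_null)

is referred to a chi-squared distribution with (c - 1)(q - 1) degrees of
freedom for c groups and q features, and p-values are corrected across genes
with Benjamini-Hochberg.

The high-level interface follows the statsmodels convention: build a
:class:`DTUModel` from data, call :meth:`DTUModel.fit`, inspect the returned
:class:`DTUResults` (per-gene table, dispersion diagnostics, ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from . import dispersion as disp
from . import dm
from .data import GeneCounts
from .preprocess import FilterConfig, filter_dataset

__all__ = ["TestResult", "fit_full_and_null", "lrt", "adjust_bh", "run_dtu",
           "DTUModel", "DTUResults"]

_NEG_D_TOL = 1e-6


@dataclass
class TestResult:
    """Outcome of one gene's likelihood-ratio test."""

    gene_id: str
    lr_statistic: float
    df: int
    p_value: float  # NaN when the fit failed
    adjusted_p: float = np.nan
    full_proportions: dict | None = None
    null_proportions: np.ndarray | None = None
    gamma_plus: float = np.nan
    converged: bool = True


def fit_full_and_null(gene: GeneCounts, grouping: dict, gamma_plus: float):
    """Fit per-group proportions (full) and pooled proportions (null) at fixed gamma_plus."""
    full = dm.estimate_proportions(gene, grouping, gamma_plus)
    pooled = {s: "__pooled__" for s in gene.sample_ids}
    null = dm.estimate_proportions(gene, pooled, gamma_plus)
    return full, null


def lrt(gene: GeneCounts, full: dm.ProportionFit, null: dm.ProportionFit,
        n_groups: int, n_features: int, gamma_plus: float = np.nan) -> TestResult:
    """Likelihood-ratio test of equal proportions across groups.

    D is clipped at zero for tiny negative values from finite optimisation;
    a D below -1e-6 marks an optimiser failure and the p-value is reported
    missing rather than wrong.
    """
    D = 2.0 * (full.loglik - null.loglik)
    df = (n_groups - 1) * (n_features - 1)
    converged = full.converged and null.converged
    if D < -_NEG_D_TOL:
        return TestResult(gene.gene_id, float(D), df, np.nan,
                          full_proportions=full.proportions,
                          null_proportions=null.proportions.get("__pooled__"),
                          gamma_plus=gamma_plus, converged=False)
    D = max(D, 0.0)
    p = float(chi2.sf(D, df))
    return TestResult(gene.gene_id, float(D), df, p,
                      full_proportions=full.proportions,
                      null_proportions=null.proportions.get("__pooled__"),
                      gamma_plus=gamma_plus, converged=converged)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing values pass through as missing."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


class DTUModel:
    """Dirichlet-multinomial model for differential feature usage between groups.

    Parameters
    ----------
    dataset : sequence of GeneCounts
        Per-gene count matrices (ideally already filtered; see ``filter``).
    design : mapping or DataFrame
        ``sample_id -> group`` map, or a DataFrame with columns
        ``sample_id`` and ``group``.  At least two groups.
    dispersion : DispersionConfig, float, or mapping, optional
        How to obtain the per-gene concentration: a config selects an
        estimation mode (default: Cox-Reid APL with moderation toward the
        common curve); a scalar fixes one known concentration for every gene;
        a mapping gives per-gene values.
    filter : FilterConfig or None
        When given, expression filtering is applied before fitting.
    """

    def __init__(self, dataset, design, dispersion=None, filter: FilterConfig | None = None):
        if isinstance(design, pd.DataFrame):
            design = dict(zip(design["sample_id"], design["group"]))
        self.design = dict(design)
        groups = sorted(set(self.design.values()))
        if len(groups) < 2:
            raise ValueError("DTU needs at least two groups in the design")
        self.groups = groups
        dataset = list(dataset)
        for g in dataset:
            missing = [s for s in g.sample_ids if s not in self.design]
            if missing:
                raise ValueError(f"{g.gene_id}: samples {missing} absent from the design")
        self.filter_summary = None
        if filter is not None:
            dataset, self.filter_summary = filter_dataset(dataset, filter)
        self.dataset = dataset
        self.dispersion = dispersion

    @classmethod
    def from_dataframes(cls, counts: pd.DataFrame, design: pd.DataFrame, **kwargs) -> "DTUModel":
        """Build from a wide count table (gene_id, feature_id, one column per sample)."""
        from .io import dataset_from_frame

        return cls(dataset_from_frame(counts), design, **kwargs)

    def _resolve_gamma(self):
        spec = self.dispersion
        if spec is None:
            spec = disp.DispersionConfig()
        if isinstance(spec, disp.DispersionConfig):
            est = disp.estimate_genewise(self.dataset, self.design, spec)
            return dict(zip(est.table["gene_id"], est.table["gamma_plus"])), est
        if np.isscalar(spec):
            gp = float(spec)
            return {g.gene_id: gp for g in self.dataset}, None
        return dict(spec), None

    def fit(self) -> "DTUResults":
        """Estimate concentrations, run the per-gene LRT, adjust with BH."""
        gamma, disp_est = self._resolve_gamma()
        results, skipped = [], []
        for gene in self.dataset:
            gp = gamma.get(gene.gene_id)
            if gp is None or not np.isfinite(gp):
                skipped.append((gene.gene_id, "no concentration estimate"))
                continue
            present = {self.design[s] for s, tot in zip(gene.sample_ids, gene.column_totals)
                       if tot > 0}
            if len(present) < 2:
                skipped.append((gene.gene_id, "fewer than two groups with usable samples"))
                continue
            try:
                full, null = fit_full_and_null(gene, self.design, gp)
            except ValueError as e:
                skipped.append((gene.gene_id, str(e)))
                continue
            results.append(lrt(gene, full, null, n_groups=len(present),
                               n_features=gene.n_features, gamma_plus=gp))
        pvals = np.array([r.p_value for r in results])
        adj = adjust_bh(pvals) if len(results) else np.array([])
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
        return DTUResults(self, results, skipped, disp_est)


class DTUResults:
    """Fitted DTU results: per-gene statistics, diagnostics and export."""

    def __init__(self, model: DTUModel, results, skipped, dispersion_estimates):
        self.model = model
        self.results = results
        self.skipped = skipped
        self.dispersion_estimates = dispersion_estimates

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": [r.gene_id for r in self.results],
            "lr": [r.lr_statistic for r in self.results],
            "df": [r.df for r in self.results],
            "pvalue": [r.p_value for r in self.results],
            "adj_pvalue": [r.adjusted_p for r in self.results],
            "gamma_plus": [r.gamma_plus for r in self.results],
            "converged": [r.converged for r in self.results],
        })

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([r.p_value for r in self.results])

    def to_tsv(self, path) -> None:
        self.results_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self) -> str:
        df = self.results_frame()
        n = len(df)
        lines = [
            "Dirichlet-multinomial differential usage",
            "=" * 44,
            f"genes tested:            {n}",
            f"genes skipped:           {len(self.skipped)}",
            f"groups:                  {', '.join(map(str, self.model.groups))}",
        ]
        if n:
            lines += [
                f"median gamma_plus:       {np.nanmedian(df['gamma_plus']):.4g}",
                f"genes with adj. p<=0.05: {int((df['adj_pvalue'] <= 0.05).sum())}",
                f"non-converged fits:      {int((~df['converged']).sum())}",
            ]
        return "\n".join(lines)

    def plot_pvalues(self, ax=None):
        """Histogram of nominal p-values (flat under a well-calibrated null)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.pvalues[~np.isnan(self.pvalues)], bins=20, range=(0, 1))
        ax.set_xlabel("p-value")
        ax.set_ylabel("genes")
        return ax


def run_dtu(dataset, design, dispersion=None, filter: FilterConfig | None = None) -> DTUResults:
    """One-call pipeline: (optional filtering ->) dispersion -> LRT -> BH."""
    return DTUModel(dataset, design, dispersion=dispersion, filter=filter).fit()
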