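"""Dirichlet-multinomial data simulation and calibration evaluation.

The generator reproduces the null and differential-usage designs used to
study small-sample estimation of the DM model: every gene has a fixed total
expression ``m`` per sample, ``q`` features with uniform or geometrically
decaying base proportions, two groups of ``n_per_group`` samples each, and a
concentration that is either common to all genes or drawn per gene.  Per
gene and sample, proportions are drawn from a Dirichlet with parameter
``gamma_plus * pi`` and counts from a multinomial with total ``m``.

Differential genes swap the two most abundant features' proportions in the
second group, mimicking an isoform switch.

Randomness is a seeded :class:`numpy.random.Generator`; per-gene substreams
are spawned from the master seed so the draws for gene ``g`` do not depend on
how many genes precede it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GeneCounts

__all__ = [
    "SimulationConfig",
    "EvaluationReport",
    "uniform_proportions",
    "decaying_proportions",
    "simulate_null",
    "simulate_dtu",
    "simulate_tuqtl",
    "evaluate_calibration",
    "estimator_error",
]


def uniform_proportions(q: int) -> np.ndarray:
    """Equal usage of all q features."""
    if q < 2:
        raise ValueError("q must be >= 2")
    return np.full(q, 1.0 / q)


def decaying_proportions(q: int, rate: float = 0.5) -> np.ndarray:
    """Geometric decay pi_j proportional to rate**(j-1), normalised."""
    if q < 2:
        raise ValueError("q must be >= 2")
    if not 0 < rate < 1:
        raise ValueError("rate must lie in (0, 1)")
    w = rate ** np.arange(q)
    return w / w.sum()


@dataclass
class SimulationConfig:
    """Study design for DM simulations.

    Defaults mirror a small-sample two-group comparison: 1000 genes, total
    expression m = 1000 per gene and sample, q = 3 features, 3 samples per
    group, concentration gamma_plus = 100 shared by all genes.
    """

    n_genes: int = 1000
    m: int = 1000
    q: int = 3
    proportions: object = "uniform"  # "uniform", "decaying", or explicit vector
    gamma_plus: float = 100.0
    dispersion_architecture: str = "common"  # or "genewise"
    genewise_log10_range: tuple = (1.0, 3.0)
    n_per_group: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.m < self.q:
            raise ValueError("m must be >= q")
        if self.gamma_plus <= 0:
            raise ValueError("gamma_plus must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.dispersion_architecture not in ("common", "genewise"):
            raise ValueError("dispersion_architecture must be 'common' or 'genewise'")

    def base_proportions(self) -> np.ndarray:
        if isinstance(self.proportions, str):
            if self.proportions == "uniform":
                return uniform_proportions(self.q)
            if self.proportions == "decaying":
                return decaying_proportions(self.q)
            raise ValueError(f"unknown proportion shape {self.proportions!r}")
        pi = np.asarray(self.proportions, dtype=float)
        if pi.size != self.q or (pi <= 0).any() or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("explicit proportions must be a length-q simplex point")
        return pi


def _design(config: SimulationConfig):
    n = config.n_per_group
    samples = [f"s{i + 1}" for i in range(2 * n)]
    design = {s: ("A" if i < n else "B") for i, s in enumerate(samples)}
    return samples, design


def _draw_gene(rng, gene_id, samples, m, pis_by_sample, gamma_plus, q):
    counts = np.empty((q, len(samples)), dtype=np.int64)
    for i, pi in enumerate(pis_by_sample):
        p = rng.dirichlet(gamma_plus * pi)
        counts[:, i] = rng.multinomial(m, p)
    return GeneCounts(gene_id, [f"f{j + 1}" for j in range(q)], list(samples), counts)


def _gene_gamma(config: SimulationConfig, rng) -> float:
    if config.dispersion_architecture == "common":
        return config.gamma_plus
    lo, hi = config.genewise_log10_range
    return float(10 ** rng.uniform(lo, hi))


def simulate_null(config: SimulationConfig, seed=None):
    """Two-group dataset with identical DM parameters in both groups.

    Returns (dataset, truth, design): a list of :class:`GeneCounts`, a truth
    table (gene_id, gamma_plus, is_ds=False, base proportions) and the
    sample -> group map.
    """
    return simulate_dtu(config, switch_fraction=0.0, seed=seed)


def simulate_dtu(config: SimulationConfig, switch_fraction: float, seed=None):
    """Dataset where a fraction of genes swap their two most abundant features.

    The first ``round(switch_fraction * n_genes)`` genes are differential:
    group B uses the base proportions with the two largest entries exchanged.
    A gene whose top-two proportions are tied has a no-op swap and is
    re-labelled null in the truth table.
    """
    if not 0 <= switch_fraction <= 1:
        raise ValueError("switch_fraction must lie in [0, 1]")
    if seed is None:
        seed = config.seed
    samples, design = _design(config)
    pi0 = config.base_proportions()
    order = np.argsort(pi0)[::-1]
    pi_alt = pi0.copy()
    pi_alt[order[0]], pi_alt[order[1]] = pi0[order[1]], pi0[order[0]]
    swap_is_noop = pi0[order[0]] == pi0[order[1]]

    n_ds = int(round(switch_fraction * config.n_genes))
    master = np.random.SeedSequence(seed)
    children = master.spawn(config.n_genes)
    dataset, truth = [], []
    n = config.n_per_group
    for g, child in enumerate(children):
        rng = np.random.default_rng(child)
        gp = _gene_gamma(config, rng)
        is_ds = g < n_ds and not swap_is_noop
        pis = [pi0] * n + [pi_alt if is_ds else pi0] * n
        gene = _draw_gene(rng, f"g{g + 1}", samples, config.m, pis, gp, config.q)
        dataset.append(gene)
        truth.append({"gene_id": gene.gene_id, "gamma_plus": gp, "is_ds": is_ds,
                      "pi0": ",".join(f"{x:.10g}" for x in pi0)})
    return dataset, pd.DataFrame(truth), design


def simulate_tuqtl(config: SimulationConfig, n_samples: int = 30,
                   n_snps_per_gene: int = 5, maf_range=(0.1, 0.5),
                   qtl_fraction: float = 0.0, seed=None):
    """Counts, genotypes and gene regions for a cis-QTL scan.

    Genes are laid out every 100 kb on one chromosome with a 5 kb body; SNPs
    fall uniformly inside each gene's +/- 5 kb window with dosages drawn from
    Hardy-Weinberg at a per-SNP allele frequency.  Under the global null
    (``qtl_fraction = 0``) genotypes are independent of the counts.  For a
    QTL gene, the first SNP is causal: samples' proportions follow the base
    vector for dosage 0 and the top-two-swapped vector for carriers.

    Returns (dataset, genotypes, regions, truth).
    """
    from .qtl import GeneRegion, SnpRecord

    if seed is None:
        seed = config.seed
    samples = [f"s{i + 1}" for i in range(n_samples)]
    pi0 = config.base_proportions()
    order = np.argsort(pi0)[::-1]
    pi_alt = pi0.copy()
    pi_alt[order[0]], pi_alt[order[1]] = pi0[order[1]], pi0[order[0]]
    n_qtl = int(round(qtl_fraction * config.n_genes))
    master = np.random.SeedSequence(seed)
    children = master.spawn(config.n_genes)
    dataset, genotypes, regions, truth = [], [], [], []
    for g, child in enumerate(children):
        rng = np.random.default_rng(child)
        gid = f"g{g + 1}"
        start = g * 100_000 + 10_000
        region = GeneRegion(gid, "chr1", start, start + 5_000)
        lo, hi = region.window(5000)
        gp = _gene_gamma(config, rng)
        is_qtl = g < n_qtl
        snps, causal = [], None
        for k in range(n_snps_per_gene):
            maf = rng.uniform(*maf_range)
            dose = rng.binomial(2, maf, size=n_samples).astype(float)
            pos = int(rng.integers(lo, hi + 1))
            snp = SnpRecord(f"{gid}_snp{k + 1}", "chr1", pos, list(samples), dose)
            snps.append(snp)
            if causal is None:
                causal = snp
        if is_qtl:
            pis = [pi_alt if causal.genotypes[i] >= 1 else pi0
                   for i in range(n_samples)]
        else:
            pis = [pi0] * n_samples
        gene = _draw_gene(rng, gid, samples, config.m, pis, gp, config.q)
        dataset.append(gene)
        genotypes.extend(snps)
        regions.append(region)
        truth.append({"gene_id": gid, "gamma_plus": gp, "is_qtl": is_qtl,
                      "causal_snp": causal.snp_id if is_qtl else ""})
    return dataset, genotypes, regions, pd.DataFrame(truth)


@dataclass
class EvaluationReport:
    """Calibration and power summaries of a set of per-gene tests."""

    fp_rate: float  # fraction of true nulls with nominal p <= fp_threshold
    fp_threshold: float
    power: float  # fraction of true positives with nominal p <= fp_threshold
    by_threshold: pd.DataFrame  # threshold, tpr, achieved_fdr, n_called (on adjusted p)

    def __str__(self):
        head = (f"FP rate at p<={self.fp_threshold:g}: {self.fp_rate:.4f}; "
                f"power: {self.power:.4f}")
        return head + "\n" + self.by_threshold.to_string(index=False)


def evaluate_calibration(results: pd.DataFrame, truth: pd.DataFrame,
                         thresholds=(0.01, 0.05, 0.1),
                         fp_threshold: float = 0.05) -> EvaluationReport:
    """FP rate on nominal p-values and TPR / achieved FDR on adjusted p-values.

    ``results`` needs columns gene_id, pvalue, adj_pvalue; ``truth`` needs
    gene_id, is_ds.  Achieved FDR is FP / (FP + TP) among called genes, 0 when
    nothing is called.
    """
    merged = results.merge(truth[["gene_id", "is_ds"]], on="gene_id", how="left",
                           validate="one_to_one")
    if merged["is_ds"].isna().any():
        raise ValueError("results contain genes absent from the truth table")
    null = merged[~merged["is_ds"]]
    alt = merged[merged["is_ds"]]
    ok_null = null["pvalue"].notna()
    fp_rate = float((null.loc[ok_null, "pvalue"] <= fp_threshold).mean()) if ok_null.any() else 0.0
    power = float((alt["pvalue"] <= fp_threshold).mean()) if len(alt) else 0.0
    rows = []
    for t in thresholds:
        called = merged["adj_pvalue"] <= t
        n_called = int(called.sum())
        tp = int((called & merged["is_ds"]).sum())
        fp = n_called - tp
        rows.append({
            "threshold": t,
            "tpr": tp / len(alt) if len(alt) else 0.0,
            "achieved_fdr": fp / n_called if n_called else 0.0,
            "n_called": n_called,
        })
    return EvaluationReport(fp_rate=fp_rate, fp_threshold=fp_threshold,
                            power=power, by_threshold=pd.DataFrame(rows))


def estimator_error(estimates: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Median absolute and raw (signed) error of concentration estimates.

    ``estimates`` needs columns gene_id, gamma_plus; ``truth`` needs gene_id,
    gamma_plus.  Errors are reported on the natural and the log10 scale.
    """
    merged = estimates.merge(truth[["gene_id", "gamma_plus"]], on="gene_id",
                             suffixes=("_hat", "_true"), validate="one_to_one")
    if merged.empty:
        raise ValueError("no overlapping genes between estimates and truth")
    err = merged["gamma_plus_hat"] - merged["gamma_plus_true"]
    log_err = np.log10(merged["gamma_plus_hat"]) - np.log10(merged["gamma_plus_true"])
    return {
        "median_abs_error": float(err.abs().median()),
        "median_raw_error": float(err.median()),
        "median_abs_error_log10": float(log_err.abs().median()),
        "median_raw_error_log10": float(log_err.median()),
        "n_genes": int(len(merged)),
    }
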