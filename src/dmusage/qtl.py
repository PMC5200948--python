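"""Transcript-usage QTL scan with genotype blocking and permutation adjustment.

For each gene, nearby bi-allelic SNPs (within a +/- 5 kb window around the
gene body, minor allele carried by at least five samples) define candidate
groupings of the expression samples by minor-allele dosage (0/1/2).  SNPs
sharing an identical genotype vector define the same model, so they are
collapsed into *blocks* and each block is tested once with the per-gene
likelihood-ratio test.  Because many blocks are tested per gene, nominal
p-values are adjusted by permuting the expression sample labels (genotypes
fixed) and comparing the observed per-gene minimum p against the permutation
minima, with +1 smoothing; Benjamini-Hochberg is then applied across genes.

The per-gene concentration is estimated once from the full cohort (no
grouping) and reused for every block of that gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dispersion as disp
from . import dm
from .data import GeneCounts
from .model import TestResult, adjust_bh, fit_full_and_null, lrt

__all__ = [
    "SnpRecord", "GeneRegion", "GenotypeBlock",
    "filter_snps", "block_snps", "test_block", "permutation_adjust",
    "TuQTLModel", "TuQTLResults", "run_tuqtl",
]


@dataclass
class SnpRecord:
    """One SNP: position plus per-sample minor-allele dosage (NaN = missing)."""

    snp_id: str
    chromosome: str
    position: int  # 1-based
    sample_ids: list
    genotypes: np.ndarray  # float array, values in {0, 1, 2, nan}

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")
        if len(self.sample_ids) != self.genotypes.size:
            raise ValueError(f"{self.snp_id}: genotype/sample length mismatch")
        obs = self.genotypes[~np.isnan(self.genotypes)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError(f"{self.snp_id}: dosages must be 0, 1, 2 or missing")


@dataclass
class GeneRegion:
    """Gene genomic range, 1-based inclusive, with a cis window around it."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")

    def window(self, size: int = 5000):
        """[start - size, end + size], clipped at position 1."""
        return max(self.start - size, 1), self.end + size


@dataclass
class GenotypeBlock:
    """Maximal set of SNPs near one gene sharing an identical genotype vector."""

    block_id: str
    gene_id: str
    snp_ids: list
    sample_ids: list
    genotypes: np.ndarray  # representative dosage vector


def filter_snps(snps, region: GeneRegion, expression_samples,
                window: int = 5000, min_minor_samples: int = 5):
    """Retain SNPs informative for one gene's cis scan.

    Keeps SNPs on the gene's chromosome within the +/- window, restricted to
    the samples shared with the expression data, that show at least two
    distinct observed dosages and whose minor allele is carried (dosage 1
    or 2) by at least ``min_minor_samples`` non-missing samples.
    """
    expression_samples = list(expression_samples)
    lo, hi = region.window(window)
    out = []
    for snp in snps:
        if snp.chromosome != region.chromosome or not lo <= snp.position <= hi:
            continue
        idx = [i for i, s in enumerate(snp.sample_ids) if s in set(expression_samples)]
        if not idx:
            raise ValueError(f"{snp.snp_id}: no samples shared with the expression data")
        sample_pos = {s: i for i, s in enumerate(snp.sample_ids)}
        geno = np.array([snp.genotypes[sample_pos[s]] if s in sample_pos else np.nan
                         for s in expression_samples])
        obs = geno[~np.isnan(geno)]
        if obs.size == 0 or np.unique(obs).size < 2:
            continue  # monomorphic (or fully missing) in this cohort
        carriers = int((obs >= 1).sum())
        if carriers < min_minor_samples:
            continue
        out.append(SnpRecord(snp.snp_id, snp.chromosome, snp.position,
                             expression_samples, geno))
    return out


def block_snps(snps, gene_id: str):
    """Partition retained SNPs into blocks of identical genotype vectors.

    The missing-data pattern is part of the key, so every member of a block
    induces exactly the same model.  Blocks are ordered by the position of
    their leftmost member.
    """
    groups = {}
    for snp in snps:
        key = tuple(-1.0 if np.isnan(g) else g for g in snp.genotypes)
        groups.setdefault(key, []).append(snp)
    blocks = []
    for members in groups.values():
        members = sorted(members, key=lambda s: (s.position, s.snp_id))
        blocks.append(GenotypeBlock(
            block_id="", gene_id=gene_id,
            snp_ids=[s.snp_id for s in members],
            sample_ids=list(members[0].sample_ids),
            genotypes=members[0].genotypes.copy(),
        ))
    # deterministic ordering by the position of each block's leftmost member
    pos_of = {s.snp_id: s.position for s in snps}
    blocks.sort(key=lambda b: (min(pos_of[i] for i in b.snp_ids), b.snp_ids[0]))
    for k, b in enumerate(blocks):
        b.block_id = f"{gene_id}_block{k + 1}"
    return blocks


def test_block(gene: GeneCounts, block: GenotypeBlock, gamma_plus: float,
               counts_override: np.ndarray | None = None) -> TestResult | None:
    """LRT of equal proportions across the block's dosage groups.

    Samples with a missing dosage are excluded; returns None when fewer than
    two non-empty dosage groups remain.  ``counts_override`` substitutes a
    column-permuted count matrix during permutation runs.
    """
    counts = gene.counts if counts_override is None else counts_override
    geno = block.genotypes
    keep = ~np.isnan(geno)
    keep &= counts.sum(axis=0) > 0
    if keep.sum() < 2:
        return None
    sub = GeneCounts(gene.gene_id, list(gene.feature_ids),
                     [f"s{i}" for i in range(int(keep.sum()))],
                     counts[:, keep])
    grouping = {f"s{i}": int(d) for i, d in enumerate(geno[keep])}
    levels = set(grouping.values())
    if len(levels) < 2:
        return None
    full, null = fit_full_and_null(sub, grouping, gamma_plus)
    res = lrt(sub, full, null, n_groups=len(levels), n_features=gene.n_features,
              gamma_plus=gamma_plus)
    res.gene_id = gene.gene_id
    return res


def permutation_adjust(observed_min_p: np.ndarray, permutation_min_p: np.ndarray,
                       block_p: list | None = None):
    """Permutation adjustment of per-gene minimum p-values.

    Parameters
    ----------
    observed_min_p : array, shape (G,)
        Observed minimum nominal p per gene.
    permutation_min_p : array, shape (G, B)
        Minimum nominal p per gene and permutation.
    block_p : list of arrays, optional
        Nominal block p-values per gene; when given, per-block empirical
        p-values against the pooled permutation null are also returned.

    Returns
    -------
    adjusted : array (G,)
        (1 + #{permutation minima <= observed}) / (1 + B), per gene.
    block_empirical : list of arrays or None
        Per-block empirical p against the pooled null of all permutation
        minima.
    """
    perm = np.asarray(permutation_min_p, dtype=float)
    if perm.ndim != 2 or perm.shape[1] < 1:
        raise ValueError("need at least one permutation")
    obs = np.asarray(observed_min_p, dtype=float)
    B = perm.shape[1]
    adjusted = (1.0 + (perm <= obs[:, None]).sum(axis=1)) / (1.0 + B)
    block_emp = None
    if block_p is not None:
        pool = np.sort(perm[np.isfinite(perm)])
        N = pool.size
        block_emp = [(1.0 + np.searchsorted(pool, p, side="right")) / (1.0 + N)
                     for p in block_p]
    return adjusted, block_emp


class TuQTLModel:
    """Cis scan for genotype-associated transcript usage.

    Parameters
    ----------
    dataset : sequence of GeneCounts
        Filtered expression data.
    genotypes : sequence of SnpRecord
    regions : sequence of GeneRegion
        Genomic ranges of the genes in ``dataset``; genes without a region
        are skipped with a recorded reason.
    window : int
        Cis window in base pairs on each side of the gene body.
    min_minor_samples : int
        Minor-allele carrier threshold for SNP retention.
    dispersion : DispersionConfig, float or mapping, optional
        As in :class:`~dmusage.model.DTUModel`, but the estimation grouping
        pools all samples (one cohort-wide proportion vector per gene).
    """

    def __init__(self, dataset, genotypes, regions, window: int = 5000,
                 min_minor_samples: int = 5, dispersion=None):
        self.dataset = list(dataset)
        self.genotypes = list(genotypes)
        self.regions = {r.gene_id: r for r in regions}
        self.window = window
        self.min_minor_samples = min_minor_samples
        self.dispersion = dispersion
        geno_samples = set()
        for s in self.genotypes:
            geno_samples.update(s.sample_ids)
        for g in self.dataset:
            if geno_samples and not geno_samples.intersection(g.sample_ids):
                raise ValueError(f"{g.gene_id}: no samples shared between "
                                 "genotype and expression data")

    def _resolve_gamma(self):
        spec = self.dispersion
        if spec is None:
            spec = disp.DispersionConfig()
        if isinstance(spec, disp.DispersionConfig):
            pooled = {s: "__all__" for g in self.dataset for s in g.sample_ids}
            est = disp.estimate_genewise(self.dataset, pooled, spec)
            return dict(zip(est.table["gene_id"], est.table["gamma_plus"]))
        if np.isscalar(spec):
            return {g.gene_id: float(spec) for g in self.dataset}
        return dict(spec)

    def fit(self, n_permutations: int = 100, seed=None) -> "TuQTLResults":
        """Scan every gene's blocks, then permutation-adjust per-gene minima."""
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        gamma = self._resolve_gamma()
        rows, skipped = [], []
        obs_min, perm_min, gene_order, block_ps = [], [], [], []
        master = np.random.SeedSequence(seed)
        genes = sorted(self.dataset, key=lambda g: g.gene_id)
        children = master.spawn(len(genes))
        for gene, child in zip(genes, children):
            # canonical sample order makes results invariant to input ordering
            gene = gene.reorder_samples(np.argsort(np.asarray(gene.sample_ids, dtype=object)))
            region = self.regions.get(gene.gene_id)
            if region is None:
                skipped.append((gene.gene_id, "no genomic region"))
                continue
            retained = filter_snps(self.genotypes, region, gene.sample_ids,
                                   window=self.window,
                                   min_minor_samples=self.min_minor_samples)
            if not retained:
                skipped.append((gene.gene_id, "no SNP retained"))
                continue
            blocks = block_snps(retained, gene.gene_id)
            gp = gamma[gene.gene_id]
            gene_rows = []
            for block in blocks:
                res = test_block(gene, block, gp)
                if res is None:
                    skipped.append((block.block_id, "fewer than two dosage groups"))
                    continue
                gene_rows.append((block, res))
            if not gene_rows:
                continue
            ps = np.array([r.p_value for _, r in gene_rows])
            valid = ps[~np.isnan(ps)]
            if valid.size == 0:
                skipped.append((gene.gene_id, "no converged block test"))
                continue
            # permutation null: permute expression sample labels, genotypes fixed
            rng = np.random.default_rng(child)
            mins = np.empty(n_permutations)
            for b in range(n_permutations):
                perm = rng.permutation(gene.n_samples)
                pcounts = gene.counts[:, perm]
                pmin = np.inf
                for block, _ in gene_rows:
                    pres = test_block(gene, block, gp, counts_override=pcounts)
                    if pres is not None and not np.isnan(pres.p_value):
                        pmin = min(pmin, pres.p_value)
                mins[b] = pmin if np.isfinite(pmin) else 1.0
            obs_min.append(valid.min())
            perm_min.append(mins)
            gene_order.append(gene.gene_id)
            block_ps.append(ps)
            for block, res in gene_rows:
                rows.append({
                    "gene_id": gene.gene_id,
                    "block_id": block.block_id,
                    "snp_ids": ",".join(block.snp_ids),
                    "lr": res.lr_statistic,
                    "df": res.df,
                    "pvalue": res.p_value,
                    "gamma_plus": gp,
                })
        table = pd.DataFrame(rows, columns=["gene_id", "block_id", "snp_ids", "lr",
                                            "df", "pvalue", "gamma_plus"])
        if gene_order:
            adjusted, block_emp = permutation_adjust(
                np.array(obs_min), np.vstack(perm_min), block_ps)
            gene_adj = dict(zip(gene_order, adjusted))
            bh = adjust_bh(adjusted)
            gene_bh = dict(zip(gene_order, bh))
            table["gene_adj_pvalue"] = table["gene_id"].map(gene_adj)
            table["gene_bh_pvalue"] = table["gene_id"].map(gene_bh)
            emp = {}
            for gid, ps, es in zip(gene_order, block_ps, block_emp):
                emp[gid] = iter(es)
            table["block_empirical_pvalue"] = [next(emp[g]) for g in table["gene_id"]]
        else:
            table["gene_adj_pvalue"] = []
            table["gene_bh_pvalue"] = []
            table["block_empirical_pvalue"] = []
        return TuQTLResults(self, table, skipped, n_permutations, seed)


class TuQTLResults:
    """Per-block association results with permutation-adjusted gene-level p-values."""

    def __init__(self, model, table: pd.DataFrame, skipped, n_permutations, seed):
        self.model = model
        self.table = table
        self.skipped = skipped
        self.n_permutations = n_permutations
        self.seed = seed

    def gene_frame(self) -> pd.DataFrame:
        """One row per gene: minimum nominal p and the adjusted p-values."""
        if self.table.empty:
            return pd.DataFrame(columns=["gene_id", "min_pvalue", "gene_adj_pvalue",
                                         "gene_bh_pvalue"])
        g = self.table.groupby("gene_id", sort=True).agg(
            min_pvalue=("pvalue", "min"),
            gene_adj_pvalue=("gene_adj_pvalue", "first"),
            gene_bh_pvalue=("gene_bh_pvalue", "first"),
        ).reset_index()
        return g

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self) -> str:
        gf = self.gene_frame()
        lines = [
            "Transcript-usage QTL scan",
            "=" * 44,
            f"genes with tested blocks: {gf.shape[0]}",
            f"blocks tested:            {len(self.table)}",
            f"permutations:             {self.n_permutations}",
            f"skipped units:            {len(self.skipped)}",
        ]
        if len(gf):
            lines.append(f"genes at adj. p<=0.05:    "
                         f"{int((gf['gene_adj_pvalue'] <= 0.05).sum())}")
        return "\n".join(lines)


def run_tuqtl(dataset, genotypes, regions, window: int = 5000,
              min_minor_samples: int = 5, dispersion=None,
              n_permutations: int = 100, seed=None) -> TuQTLResults:
    """One-call cis scan: filter -> block -> test -> permutation adjust -> BH."""
    model = TuQTLModel(dataset, genotypes, regions, window=window,
                       min_minor_samples=min_minor_samples, dispersion=dispersion)
    return model.fit(n_permutations=n_permutations, seed=seed)
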