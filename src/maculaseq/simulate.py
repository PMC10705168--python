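"""Synthetic datasets with the statistical structure the analysis assumes.

The generator emulates the study's inputs so every pipeline stage is testable
against known ground truth:

* exon-level counts drawn negative-binomial around
  mean = size_factor_j * mu_g * pi_{g,e} * 2^(beta_g * x_j), with log-normal
  baseline means across genes, per-sample library scaling, designated
  differentially expressed genes (log2 fold change beta applied in the
  non-reference groups) and designated differentially spliced genes (a
  proportion mass delta moved between two exons in the non-reference groups,
  leaving the gene-level mean unchanged so splicing truth is orthogonal to
  expression truth by construction);
* per-sample per-SNP allelic read counts: heterozygotes draw a
  negative-binomial depth and binomial alt reads at the site's true alt
  fraction rho; homozygotes emit only the matching allele; LD-proxy
  genotypes match the target's heterozygosity with probability r^2 (a
  deliberate simplification of linkage disequilibrium — only the r^2 >= 0.8
  threshold behaviour matters downstream);
* marker-panel libraries: multinomial allocation of a fixed library size so
  each panel's expected read share equals its target fraction.

Negative-binomial parameterization: mean mu and dispersion alpha with
var = mu + alpha * mu^2, so alpha = 0 is the Poisson limit.

Default cohort sizes follow the study design (12 normal, 10 intermediate
AMD, 5 neovascular donors). All randomness flows from a single integer seed
through one numpy Generator, making every output reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExonCountMatrix
from .io import ProxyMap
from .qc import DEFAULT_PANELS


@dataclass
class AseSite:
    """Configuration of one simulated SNP eligible for allelic imbalance."""

    snp_id: str
    chrom: str = "chr1"
    pos: int = 1_000_000
    ref: str = "C"
    alt: str = "T"
    rho: float = 0.5  # true alt-allele fraction in heterozygotes
    depth_mean: float = 100.0
    depth_dispersion: float = 0.1
    het_fraction: float = 0.5  # probability a sample is heterozygous
    proxy_snp: str | None = None
    proxy_r2: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if not 0.0 <= self.proxy_r2 <= 1.0:
            raise ValueError(f"proxy_r2 must be in [0, 1], got {self.proxy_r2}")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_per_group: dict = field(default_factory=lambda: {"normal": 12, "iAMD": 10, "NEO": 5})
    tissue: str = "RPE_choroid"
    n_genes: int = 2000
    exons_per_gene: tuple[int, int] = (4, 12)
    baseline_log_mean: float = float(np.log(100.0))
    baseline_log_sd: float = 1.0
    dispersion: float = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    reference_group: str = "normal"
    de_genes: dict = field(default_factory=dict)  # gene -> true log2 fold change
    dsg_genes: dict = field(default_factory=dict)  # gene -> proportion shift delta
    ase_sites: list = field(default_factory=list)
    # target marker-panel read shares for the simulated tissue's libraries;
    # the defaults are realistic for clean RPE/choroid dissections (retina
    # phototransduction genes ~0.06%, RPE/choroid markers ~0.65%)
    marker_fractions: dict = field(default_factory=lambda: {"retina": 0.0006, "RPE_choroid": 0.0065})

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.reference_group not in self.n_per_group:
            raise ValueError(
                f"reference group {self.reference_group!r} not in n_per_group"
            )
        for gene, delta in self.dsg_genes.items():
            if not 0.0 <= delta < 0.4:
                raise ValueError(
                    f"dsg shift for {gene} must be in [0, 0.4) under the designed "
                    f"exon proportions, got {delta}"
                )
        self.ase_sites = [
            AseSite(**s) if isinstance(s, dict) else s for s in self.ase_sites
        ]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("exons_per_gene", "size_factor_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def gene_names(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for group, n in self.n_per_group.items():
            for i in range(1, n + 1):
                rows.append({"sample": f"{group}_{i:02d}", "group": group, "tissue": self.tissue})
        return pd.DataFrame(rows).set_index("sample")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + alpha mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def simulate_exon_counts(config: SimulationConfig) -> tuple[ExonCountMatrix, pd.DataFrame]:
    """Simulate an exon count matrix plus its gene-level truth table.

    Truth columns: gene, is_de, true_log2fc, is_dsg, delta, shift_from_exon,
    shift_to_exon. Fixed seed gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    samples = config.sample_sheet()
    n_samples = len(samples)
    is_alt = (samples["group"] != config.reference_group).to_numpy()

    lo, hi = config.exons_per_gene
    n_exons = rng.integers(lo, hi + 1, size=config.n_genes)
    mu = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)
    sf = rng.uniform(*config.size_factor_range, size=n_samples)

    unknown = (set(config.de_genes) | set(config.dsg_genes)) - set(genes)
    if unknown:
        raise ValueError(f"effect genes not in the simulated gene set: {sorted(unknown)}")

    count_blocks, key_rows, truth_rows = [], [], []
    for g, gene in enumerate(genes):
        k = int(n_exons[g])
        delta = config.dsg_genes.get(gene, 0.0)
        if gene in config.dsg_genes:
            # designed proportions guaranteeing a valid shift of up to 0.4:
            # a large donor exon 0, a small acceptor exon 1, the rest equal
            pi_ref = np.empty(k)
            pi_ref[0], pi_ref[1] = 0.45, 0.05
            pi_ref[2:] = 0.5 / (k - 2) if k > 2 else 0.0
            pi_alt = pi_ref.copy()
            pi_alt[0] -= delta
            pi_alt[1] += delta
            truth_shift = (0, 1)
        else:
            pi_ref = rng.dirichlet(np.full(k, 5.0))
            pi_alt = pi_ref
            truth_shift = (-1, -1)
        lfc = config.de_genes.get(gene, 0.0)
        fold = np.where(is_alt, 2.0**lfc, 1.0)
        pi = np.where(is_alt[None, :], pi_alt[:, None], pi_ref[:, None])
        mean = sf[None, :] * mu[g] * pi * fold[None, :]
        count_blocks.append(_nb_draw(rng, mean, config.dispersion))
        for e in range(k):
            # synthetic coordinates: 1 kb exons spaced 2 kb apart per gene
            start = 10_000 * (g + 1) + 2_000 * e
            key_rows.append({"gene": gene, "exon_index": e, "chrom": "chrS",
                             "start": start, "end": start + 1_000})
        truth_rows.append(
            {
                "gene": gene,
                "is_de": gene in config.de_genes,
                "true_log2fc": lfc,
                "is_dsg": gene in config.dsg_genes,
                "delta": delta,
                "shift_from_exon": truth_shift[0],
                "shift_to_exon": truth_shift[1],
            }
        )

    keys = pd.DataFrame(key_rows).set_index(["gene", "exon_index"])
    counts = pd.DataFrame(
        np.vstack(count_blocks), index=keys.index, columns=samples.index
    )
    matrix = ExonCountMatrix(counts, keys, samples)
    truth = pd.DataFrame(truth_rows)
    return matrix, truth


def simulate_allelic_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, ProxyMap, pd.DataFrame]:
    """Simulate allelic read counts, genotype calls, LD proxies and truth.

    Returns (allelic records, genotype records, proxy map, truth table). The
    truth table records each sample x site's genotype and true alt fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    samples = config.sample_sheet()
    allelic_rows, geno_rows, truth_rows = [], [], []
    pm = ProxyMap()
    for site in config.ase_sites:
        if site.proxy_snp is not None:
            pm.add(site.snp_id, site.proxy_snp, site.proxy_r2)
        for sample, meta in samples.iterrows():
            het = rng.random() < site.het_fraction
            if het:
                depth = int(_nb_draw(rng, np.array(site.depth_mean), site.depth_dispersion))
                alt_reads = int(rng.binomial(depth, site.rho)) if depth > 0 else 0
                ref_reads = depth - alt_reads
                alleles = (site.ref, site.alt)
                genotype = "het"
            else:
                hom_alt = bool(rng.random() < 0.5)
                depth = int(_nb_draw(rng, np.array(site.depth_mean), site.depth_dispersion))
                ref_reads, alt_reads = (0, depth) if hom_alt else (depth, 0)
                alleles = (site.alt, site.alt) if hom_alt else (site.ref, site.ref)
                genotype = "hom_alt" if hom_alt else "hom_ref"
            allelic_rows.append(
                {
                    "sample": sample,
                    "tissue": meta["tissue"],
                    "group": meta["group"],
                    "snp_id": site.snp_id,
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": site.alt,
                    "ref_reads": ref_reads,
                    "alt_reads": alt_reads,
                }
            )
            geno_rows.append(
                {
                    "sample": sample,
                    "snp_id": site.snp_id,
                    "allele1": alleles[0],
                    "allele2": alleles[1],
                    "source": "chip",
                }
            )
            if site.proxy_snp is not None:
                # proxy heterozygosity matches the target with P = r^2
                match = rng.random() < site.proxy_r2
                proxy_het = het if match else not het
                p_alleles = (site.ref, site.alt) if proxy_het else (site.ref, site.ref)
                geno_rows.append(
                    {
                        "sample": sample,
                        "snp_id": site.proxy_snp,
                        "allele1": p_alleles[0],
                        "allele2": p_alleles[1],
                        "source": "proxy",
                    }
                )
            truth_rows.append(
                {
                    "sample": sample,
                    "snp_id": site.snp_id,
                    "genotype": genotype,
                    "true_rho": site.rho if het else (1.0 if genotype == "hom_alt" else 0.0),
                }
            )
    allelic = pd.DataFrame(
        allelic_rows,
        columns=["sample", "tissue", "group", "snp_id", "chrom", "pos", "ref", "alt",
                 "ref_reads", "alt_reads"],
    )
    genotypes = pd.DataFrame(
        geno_rows, columns=["sample", "snp_id", "allele1", "allele2", "source"]
    )
    truth = pd.DataFrame(truth_rows, columns=["sample", "snp_id", "genotype", "true_rho"])
    return allelic, genotypes, pm, truth


def simulate_marker_library(
    config: SimulationConfig,
    library_size: int = 1_000_000,
    n_background: int = 200,
) -> CountMatrix:
    """Multinomial marker-gene libraries at the configured panel fractions.

    Each sample's reads are allocated multinomially so a panel's expected
    share equals its target fraction (split equally across the panel's
    genes); the remainder goes to background genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    fractions = config.marker_fractions
    total_fraction = sum(fractions.values())
    if total_fraction > 1.0:
        raise ValueError(f"panel fractions sum to {total_fraction} > 1")
    gene_names: list[str] = []
    probs: list[float] = []
    for tissue_key, fraction in fractions.items():
        panel = DEFAULT_PANELS[tissue_key]
        gene_names.extend(panel.genes)
        probs.extend([fraction / len(panel.genes)] * len(panel.genes))
    background = [f"BG{i:04d}" for i in range(1, n_background + 1)]
    gene_names.extend(background)
    probs.extend([(1.0 - total_fraction) / n_background] * n_background)

    samples = config.sample_sheet()
    draws = rng.multinomial(library_size, probs, size=len(samples)).T
    counts = pd.DataFrame(draws, index=pd.Index(gene_names, name="gene"), columns=samples.index)
    return CountMatrix(counts, samples)
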