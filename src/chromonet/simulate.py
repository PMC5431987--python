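"""Synthetic RNA-seq count generator with phenotype-specific co-expression regimes.

Emulates the statistical structure a chromosomal co-expression contrast rests
on, at gene-count level (no reads):

* a *healthy* regime in which gene log-expression is coupled through a small
  number of genome-wide latent factors, so that strongly dependent gene pairs
  sit on *different* chromosomes as often as chance dictates;
* a *cancer* regime in which co-expression collapses onto compact,
  coordinate-contiguous blocks of neighbouring genes on one chromosome, each
  block coherently shifted up or down in mean expression.

Counts are negative-binomial around depth-scaled means with multiplicative
%GC and gene-length biases, so the normalization stages have real work to do.
The latent layer is a Gaussian copula on log2 means, which gives closed-form
mutual information for oracle tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Chromosome labels accepted by the integration filter.
CONVENTIONAL_CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-regime count simulation.

    Parameters
    ----------
    n_genes, n_chromosomes
        Genome size. Genes are spread near-evenly over the first
        ``n_chromosomes`` conventional chromosome labels.
    n_healthy, n_cancer
        Samples per condition.
    block_size
        Genes per intra-chromosomal co-regulation block. Blocks tile each
        chromosome contiguously in coordinate order.
    rho_intra
        Loading of the per-block latent factor in the cancer regime, in [0, 1).
        The latent correlation between two genes of one block is rho_intra**2.
    rho_inter
        Loading of the genome-wide latent factors in the healthy regime,
        in [0, 1).
    de_shift
        log2 mean shift magnitude applied to every deregulated block in the
        cancer condition (sign drawn per block).
    nb_dispersion
        Negative-binomial dispersion (variance = m + dispersion * m**2);
        0 degenerates to Poisson.
    depth_range
        Uniform interval for per-sample library-size multipliers.
    seed
        Master seed; every stochastic step derives its stream from it.
    n_inter_factors
        Number of genome-wide factors in the healthy regime.
    de_block_fraction
        Fraction of blocks that receive the mean shift.
    defect_fraction
        Fraction of annotation records deliberately corrupted (missing symbol,
        non-conventional chromosome, unresolvable duplicate identifier) to
        exercise the integration filters. Off by default.
    base_log2_mean, base_log2_sd
        Distribution of per-gene baseline log2 expression.
    biological_sd
        Per-gene, per-sample latent standard deviation on the log2 scale.
    gc_bias, length_bias
        Strength of the multiplicative count biases: the expected count is
        multiplied by ``2**(gc_bias * (gc - 0.5))`` and by
        ``(length / 10_000) ** length_bias``.
    """

    n_genes: int = 600
    n_chromosomes: int = 6
    n_healthy: int = 100
    n_cancer: int = 100
    block_size: int = 20
    rho_intra: float = 0.9
    rho_inter: float = 0.6
    de_shift: float = 1.0
    nb_dispersion: float = 0.1
    depth_range: tuple[float, float] = (0.6, 1.6)
    seed: int = 0
    n_inter_factors: int = 5
    de_block_fraction: float = 1.0
    defect_fraction: float = 0.0
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.5
    biological_sd: float = 1.0
    gc_bias: float = 2.0
    length_bias: float = 0.3

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_chromosomes <= 0:
            raise SimulationConfigError("n_genes and n_chromosomes must be positive")
        if self.n_chromosomes > len(CONVENTIONAL_CHROMOSOMES):
            raise SimulationConfigError(
                f"n_chromosomes must be <= {len(CONVENTIONAL_CHROMOSOMES)}"
            )
        if self.n_healthy <= 0 or self.n_cancer <= 0:
            raise SimulationConfigError("sample counts must be positive")
        if self.block_size <= 0:
            raise SimulationConfigError("block_size must be positive")
        if self.block_size > self.n_genes // self.n_chromosomes:
            raise SimulationConfigError("block_size must not exceed genes per chromosome")
        for name in ("rho_intra", "rho_inter"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise SimulationConfigError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.de_block_fraction <= 1.0:
            raise SimulationConfigError("de_block_fraction must lie in [0, 1]")
        if not 0.0 <= self.defect_fraction < 1.0:
            raise SimulationConfigError("defect_fraction must lie in [0, 1)")
        if self.nb_dispersion < 0:
            raise SimulationConfigError("nb_dispersion must be >= 0")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise SimulationConfigError("depth_range must satisfy 0 < low <= high")
        if self.n_inter_factors <= 0:
            raise SimulationConfigError("n_inter_factors must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Generator-side truth for parameter-recovery tests.

    Attributes
    ----------
    gene_block
        Series mapping gene_id -> block id (every gene belongs to exactly one
        coordinate-contiguous block).
    block_sign
        Series mapping block id -> true DE sign in the cancer condition
        (+1 up, -1 down, 0 not deregulated).
    healthy_factor
        Series mapping gene_id -> genome-wide factor index used in the
        healthy regime.
    """

    gene_block: pd.Series
    block_sign: pd.Series
    healthy_factor: pd.Series

    def de_sign(self) -> pd.Series:
        """Per-gene true DE sign (cancer vs healthy)."""
        return self.gene_block.map(self.block_sign).rename("de_sign")

    def pair_regime(self, gene_a: str, gene_b: str, condition: str) -> str:
        """Correlation regime of an unordered gene pair in one condition.

        Returns ``"intra-block"``, ``"inter-factor"`` or ``"independent"``.
        """
        if condition == "cancer":
            if self.gene_block[gene_a] == self.gene_block[gene_b]:
                return "intra-block"
            return "independent"
        if condition == "healthy":
            if self.healthy_factor[gene_a] == self.healthy_factor[gene_b]:
                return "inter-factor"
            return "independent"
        raise ValueError(f"unknown condition {condition!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_block.index,
                "block": self.gene_block.values,
                "de_sign": self.de_sign().values,
                "healthy_factor": self.healthy_factor.values,
            }
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    # Distinct, reproducible stream per stage of the generator.
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def make_annotation(cfg: SimulationConfig) -> pd.DataFrame:
    """Generate a gene annotation table.

    Columns: ``gene_id, symbol, alt_symbol, chromosome, start, end, gc,
    biotype``. Genes are laid out on each chromosome as 1-based,
    non-overlapping intervals in coordinate order; %GC is uniform on
    [0.3, 0.7].

    If ``cfg.defect_fraction > 0`` a matching number of records is corrupted
    (missing symbol, non-conventional chromosome, or an appended conflicting
    duplicate of the gene's identifier); the affected gene ids are recorded in
    ``result.attrs["defect_log"]``. One additional *resolvable* duplicate
    (matching symbols, higher %GC) is appended per 200 defective records to
    exercise the minimum-%GC tie-break without losing the gene.
    """
    cfg.validate()
    rng = _rng(cfg.seed, 0)

    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    symbols = np.array([f"SYM{i}" for i in range(cfg.n_genes)], dtype=object)
    alt_symbols = np.array([f"ALT{i}" for i in range(cfg.n_genes)], dtype=object)

    chrom_labels = CONVENTIONAL_CHROMOSOMES[: cfg.n_chromosomes]
    chrom_of = np.empty(cfg.n_genes, dtype=object)
    starts = np.empty(cfg.n_genes, dtype=np.int64)
    ends = np.empty(cfg.n_genes, dtype=np.int64)
    for label, idx in zip(chrom_labels, np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)):
        chrom_of[idx] = label
        lengths = np.exp(rng.uniform(np.log(500), np.log(50_000), size=idx.size)).astype(np.int64)
        gaps = rng.integers(1_000, 50_000, size=idx.size)
        pos = 1
        for k, g in enumerate(idx):
            starts[g] = pos
            ends[g] = pos + lengths[k] - 1
            pos = ends[g] + 1 + gaps[k]

    gc = rng.uniform(0.3, 0.7, size=cfg.n_genes)
    biotype = np.where(rng.random(cfg.n_genes) < 0.9, "protein_coding", "lincRNA")

    ann = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "alt_symbol": alt_symbols,
            "chromosome": chrom_of,
            "start": starts,
            "end": ends,
            "gc": gc,
            "biotype": biotype,
        }
    )

    defect_log: list[tuple[str, str]] = []
    extra_rows: list[dict] = []
    n_defects = int(round(cfg.defect_fraction * cfg.n_genes))
    if n_defects:
        victims = rng.choice(cfg.n_genes, size=n_defects, replace=False)
        kinds = ["missing_symbol", "nonconventional_chromosome", "duplicate_id"]
        for j, v in enumerate(victims):
            kind = kinds[j % len(kinds)]
            gid = ann.at[v, "gene_id"]
            if kind == "missing_symbol":
                ann.at[v, "symbol"] = ""
            elif kind == "nonconventional_chromosome":
                ann.at[v, "chromosome"] = "MT" if j % 2 else "HSCHR6_MHC_COX"
            else:
                # Conflicting second candidate: symbols disagree, so the
                # integration merge must drop the identifier entirely.
                extra_rows.append(
                    {
                        "gene_id": gid,
                        "symbol": f"{ann.at[v, 'symbol']}_ALTREC",
                        "alt_symbol": ann.at[v, "alt_symbol"],
                        "chromosome": ann.at[v, "chromosome"],
                        "start": ann.at[v, "start"],
                        "end": ann.at[v, "end"],
                        "gc": min(0.7, ann.at[v, "gc"] + 0.05),
                        "biotype": ann.at[v, "biotype"],
                    }
                )
            defect_log.append((gid, kind))
        # A few benign duplicates whose symbols agree: min-%GC rule resolves
        # them and the gene survives integration.
        n_benign = max(1, n_defects // 200)
        clean = np.setdiff1d(np.arange(cfg.n_genes), victims)
        for v in rng.choice(clean, size=min(n_benign, clean.size), replace=False):
            extra_rows.append(
                {
                    "gene_id": ann.at[v, "gene_id"],
                    "symbol": ann.at[v, "symbol"],
                    "alt_symbol": ann.at[v, "alt_symbol"],
                    "chromosome": ann.at[v, "chromosome"],
                    "start": ann.at[v, "start"],
                    "end": ann.at[v, "end"],
                    "gc": min(0.7, ann.at[v, "gc"] + 0.1),
                    "biotype": ann.at[v, "biotype"],
                }
            )
    if extra_rows:
        ann = pd.concat([ann, pd.DataFrame(extra_rows)], ignore_index=True)

    ann.attrs["defect_log"] = pd.DataFrame(defect_log, columns=["gene_id", "defect"])
    return ann


def _assign_blocks(cfg: SimulationConfig, ann: pd.DataFrame) -> pd.Series:
    """Tile each chromosome's genes into contiguous blocks of ~block_size."""
    first = ann.drop_duplicates("gene_id", keep="first")
    block = pd.Series(index=pd.Index(first["gene_id"], name="gene_id"), dtype=np.int64)
    next_block = 0
    for _, sub in first.groupby("chromosome", sort=False):
        sub = sub.sort_values("start")
        n_blocks = max(1, int(round(len(sub) / cfg.block_size)))
        for part in np.array_split(np.arange(len(sub)), n_blocks):
            block.loc[sub["gene_id"].iloc[part]] = next_block
            next_block += 1
    return block.astype(np.int64)


def simulate_counts(
    cfg: SimulationConfig, ann: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the count matrix for both conditions.

    Returns ``(counts, samples, truth)``: a genes x samples integer DataFrame,
    a sample sheet with columns ``sample, condition``, and the
    :class:`GroundTruth`. Healthy samples share genome-wide latent factors
    (loading ``rho_inter``); cancer samples share per-block factors (loading
    ``rho_intra``) and a coherent ±``de_shift`` per deregulated block. Counts
    are negative-binomial around depth-, %GC- and length-scaled means.
    Bit-identical for a given config.
    """
    cfg.validate()
    first = ann.drop_duplicates("gene_id", keep="first").reset_index(drop=True)
    genes = pd.Index(first["gene_id"], name="gene_id")
    G = len(genes)

    rng = _rng(cfg.seed, 1)

    block = _assign_blocks(cfg, ann)
    block_ids = np.unique(block.values)
    signs = pd.Series(0, index=pd.Index(block_ids, name="block"), dtype=np.int64)
    n_de = int(round(cfg.de_block_fraction * len(block_ids)))
    de_blocks = rng.choice(block_ids, size=n_de, replace=False)
    signs.loc[de_blocks] = rng.choice([-1, 1], size=n_de)
    factor = pd.Series(
        rng.integers(0, cfg.n_inter_factors, size=G), index=genes, name="healthy_factor"
    )
    truth = GroundTruth(gene_block=block.loc[genes], block_sign=signs, healthy_factor=factor)

    mu = cfg.base_log2_mean + rng.normal(0.0, cfg.base_log2_sd, size=G)
    gc = first["gc"].to_numpy()
    length = (first["end"] - first["start"] + 1).to_numpy(dtype=float)
    log2_bias = cfg.gc_bias * (gc - 0.5) + cfg.length_bias * np.log2(length / 1e4)

    n_h, n_c = cfg.n_healthy, cfg.n_cancer
    # Healthy latent layer: genome-wide factors shared across chromosomes.
    fac_h = rng.standard_normal((cfg.n_inter_factors, n_h))
    z_h = cfg.rho_inter * fac_h[factor.to_numpy()] + np.sqrt(
        1 - cfg.rho_inter**2
    ) * rng.standard_normal((G, n_h))
    # Cancer latent layer: one factor per contiguous block, plus the shift.
    block_idx = pd.Index(block_ids).get_indexer(block.loc[genes].to_numpy())
    fac_c = rng.standard_normal((len(block_ids), n_c))
    z_c = cfg.rho_intra * fac_c[block_idx] + np.sqrt(
        1 - cfg.rho_intra**2
    ) * rng.standard_normal((G, n_c))
    shift = (signs.loc[block.loc[genes]].to_numpy() * cfg.de_shift)[:, None]

    log2_mean_h = mu[:, None] + cfg.biological_sd * z_h
    log2_mean_c = mu[:, None] + cfg.biological_sd * z_c + shift
    log2_mean = np.concatenate([log2_mean_h, log2_mean_c], axis=1)

    depth = rng.uniform(*cfg.depth_range, size=n_h + n_c)
    m = depth[None, :] * 2.0 ** (log2_mean + log2_bias[:, None])

    if cfg.nb_dispersion > 0:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, m * cfg.nb_dispersion)
    else:
        lam = m
    counts = rng.poisson(lam).astype(np.int64)

    sample_ids = [f"H{i:04d}" for i in range(n_h)] + [f"T{i:04d}" for i in range(n_c)]
    samples = pd.DataFrame(
        {
            "sample": sample_ids,
            "condition": ["healthy"] * n_h + ["cancer"] * n_c,
        }
    )
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# TSV export (tab-separated, header rows)

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
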