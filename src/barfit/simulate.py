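"""Synthetic barcoded-screen generator with ground truth.

Emulates a pooled transposon selection screen at desk scale: a library of
uniquely barcoded insertion mutants, sampled before selection (T0) and after
plating under selective and non-selective (control) conditions across several
independent experiments, with sequencing reads drawn multinomially at a fixed
per-sample depth — the compositional constraint of pooled sequencing.

The generative model inverts the per-gene analysis model: the log2 abundance
change of barcode *i* in non-T0 sample *k* of condition *j* is

    delta_{i,k} = C_j + B_i + eps_{i,k}

with C_control = 0 and C_selective the gene's true fitness, B_i ~ N(0,
varsigma2) a per-insertion effect drawn once per barcode and shared across all
of its samples, and eps ~ N(0, sigma2) per observation. Insertion positions
are uniform along each gene body so that curation has realistic work to do.

Defaults mirror a three-experiment screen (one T0, one control and one
selective sample per experiment) at a megaread-per-sample depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BarcodePool, CountMatrix, SampleSheet, write_counts

_GENE_LEN = 999  # nominal CDS length, nt
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Scenario for one synthetic screen.

    ``barcodes_per_gene`` is a fixed count, or a Poisson mean when
    ``barcode_distribution="poisson"`` (floored at 1 so every gene exists).
    ``fitness_spec`` maps locus tags to true fitness (log2 units); when None,
    a fraction ``fraction_null`` of genes is neutral and the rest draw their
    fitness uniformly from ``fitness_levels``.
    """

    n_genes: int = 500
    barcodes_per_gene: float = 10
    barcode_distribution: str = "fixed"  # or "poisson"
    depth_per_sample: int = 1_000_000
    n_experiments: int = 3
    varsigma2: float = 0.1
    sigma2: float = 0.3
    fitness_spec: dict[str, float] | None = None
    fraction_null: float = 0.9
    fitness_levels: tuple[float, ...] = (-4.0, -2.0, 2.0)
    dark_sensitive_genes: int = 0  # near-zero T0 abundance confounder
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_per_sample <= 0 or self.n_genes <= 0 or self.n_experiments <= 0:
            raise ValueError("n_genes, depth_per_sample, n_experiments must be > 0")
        if self.varsigma2 < 0 or self.sigma2 < 0:
            raise ValueError("variances must be >= 0")
        if not 0 <= self.fraction_null <= 1:
            raise ValueError("fraction_null must be in [0, 1]")
        if self.barcode_distribution not in {"fixed", "poisson"}:
            raise ValueError("barcode_distribution must be 'fixed' or 'poisson'")


@dataclass
class SimTruth:
    """Ground truth of a simulated screen, keyed for recovery tests."""

    gene_fitness: pd.Series  # locus_tag -> true fitness
    barcode_effect: pd.Series  # barcode -> B_i
    initial_abundance: pd.Series  # barcode -> relative abundance at T0
    gene_fraction: pd.Series  # barcode -> fractional insertion position
    seed: int


def _random_barcodes(n: int, rng: np.random.Generator, length: int = 20) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for _ in range(50):
        draw = rng.integers(0, 4, size=(n - len(out), length))
        for row in draw:
            bc = "".join(_BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
        if len(out) == n:
            return out
    raise RuntimeError("could not draw unique barcodes")  # pragma: no cover


def simulate_pool(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw the mutant library: a :class:`BarcodePool` plus each barcode's
    initial relative abundance (log-normal, normalized to sum 1)."""
    rng = rng or np.random.default_rng(cfg.seed)
    tags = [f"gene_{i:05d}" for i in range(cfg.n_genes)]
    if cfg.barcode_distribution == "poisson":
        per_gene = np.maximum(rng.poisson(cfg.barcodes_per_gene, cfg.n_genes), 1)
    else:
        per_gene = np.full(cfg.n_genes, int(cfg.barcodes_per_gene))
    n_bc = int(per_gene.sum())

    barcodes = _random_barcodes(n_bc, rng)
    locus = np.repeat(tags, per_gene)
    frac = rng.uniform(0.0, 1.0, n_bc)
    gene_start = 1 + 2000 * np.repeat(np.arange(cfg.n_genes), per_gene)
    pos = gene_start + np.round(frac * (_GENE_LEN - 1)).astype(np.int64)

    table = pd.DataFrame(
        {
            "locus_tag": locus,
            "insertion_pos": pos,
            "strand": "+",
            "gene_fraction": frac,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    abund = rng.lognormal(mean=0.0, sigma=1.0, size=n_bc)
    if cfg.dark_sensitive_genes:
        # confounder: some genes nearly absent from the starting pool
        dark = rng.choice(cfg.n_genes, size=cfg.dark_sensitive_genes, replace=False)
        mask = np.isin(np.repeat(np.arange(cfg.n_genes), per_gene), dark)
        abund[mask] *= 1e-6
    abund /= abund.sum()
    return BarcodePool(table), pd.Series(abund, index=table.index, name="abundance")


def _sample_sheet(cfg: SimConfig) -> SampleSheet:
    rows = []
    for e in range(1, cfg.n_experiments + 1):
        for cond in ("T0", "control", "selective"):
            rows.append((f"{cond}_{e}", f"exp{e}", cond, e))
    df = pd.DataFrame(rows, columns=["sample_id", "experiment_id", "condition", "replicate"])
    return SampleSheet(df.set_index("sample_id"))


def _true_fitness(cfg: SimConfig, tags, rng: np.random.Generator) -> pd.Series:
    if cfg.fitness_spec is not None:
        fit = pd.Series(0.0, index=tags)
        for tag, f in cfg.fitness_spec.items():
            fit[tag] = f
        return fit
    n_alt = int(round((1 - cfg.fraction_null) * len(tags)))
    alt = rng.choice(len(tags), size=n_alt, replace=False)
    vals = np.zeros(len(tags))
    vals[alt] = rng.choice(cfg.fitness_levels, size=n_alt)
    return pd.Series(vals, index=tags)


def simulate_screen(
    pool: BarcodePool,
    abundance: pd.Series,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Sequence the simulated screen: returns (CountMatrix, SimTruth).

    Every sample's counts are multinomial at ``depth_per_sample`` over the
    barcode relative abundances; non-T0 samples multiply each barcode's
    abundance by 2**(C_j + B_i + eps) before renormalizing.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    sheet = _sample_sheet(cfg)
    tags = pd.unique(pool.table["locus_tag"])
    fitness = _true_fitness(cfg, tags, rng)
    b = rng.normal(0.0, np.sqrt(cfg.varsigma2), len(pool.barcodes))
    bc_fitness = fitness.loc[pool.table["locus_tag"]].to_numpy()

    a0 = abundance.loc[pool.barcodes].to_numpy()
    counts = {}
    for sample_id, row in sheet.table.iterrows():
        if row["condition"] == "T0":
            p = a0
        else:
            c_j = bc_fitness if row["condition"] == "selective" else 0.0
            eps = rng.normal(0.0, np.sqrt(cfg.sigma2), len(a0))
            p = a0 * np.exp2(c_j + b + eps)
        p = p / p.sum()
        counts[sample_id] = rng.multinomial(cfg.depth_per_sample, p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pool.barcodes, dtype=np.int64),
        pool=pool,
        sheet=sheet,
    )
    truth = SimTruth(
        gene_fitness=fitness,
        barcode_effect=pd.Series(b, index=pool.barcodes),
        initial_abundance=abundance,
        gene_fraction=pool.table["gene_fraction"],
        seed=cfg.seed,
    )
    return cm, truth


def simulate(cfg: SimConfig):
    """Convenience wrapper: pool + screen from one config/seed."""
    rng = np.random.default_rng(cfg.seed)
    pool, abund = simulate_pool(cfg, rng)
    return simulate_screen(pool, abund, cfg, rng)


def write_simulation(cm: CountMatrix, truth: SimTruth, outdir: str | Path) -> None:
    """Write the screen in the same TSV formats the readers accept, plus the
    ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(
        cm,
        outdir / "counts.tsv",
        outdir / "pool.tsv",
        outdir / "samples.tsv",
    )
    truth.gene_fitness.rename("true_fitness").to_csv(outdir / "truth_genes.tsv", sep="\t")
    pd.DataFrame(
        {
            "barcode_effect": truth.barcode_effect,
            "initial_abundance": truth.initial_abundance,
            "gene_fraction": truth.gene_fraction,
        }
    ).to_csv(outdir / "truth_barcodes.tsv", sep="\t")
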