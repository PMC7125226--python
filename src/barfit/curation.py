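"""Barcode and gene retention filters applied before fitness modeling.

Three filters, applied in order:

1. **position** — keep only barcodes inserted within the middle fraction of the
   coding sequence (default the middle 80%, i.e. gene_fraction in [0.1, 0.9]);
   insertions near either end of a gene often leave a functional protein, so
   they dilute the fitness signal;
2. **T0 depth** — keep only barcodes with at least ``min_t0_reads`` reads summed
   over all pre-selection (T0) samples, so every retained mutant has a reliable
   baseline abundance;
3. **representation** — keep only genes covered by at least
   ``min_barcodes_per_gene`` surviving barcodes at distinct insertion
   coordinates, so a gene's fitness never rests on a single insertion event.

Barcodes that map to no gene (intergenic insertions, null locus_tag) are
dropped first; they are kept in raw files so those stay faithful to the
sequencing run.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import CountMatrix, ValidationError


@dataclass(frozen=True)
class CurationParams:
    """Retention thresholds. Defaults follow common BarSeq practice:
    middle 80% of the CDS, >=3 distinct-position barcodes per gene,
    >=15 T0 reads per barcode summed across replicates."""

    middle_fraction: float = 0.80
    min_barcodes_per_gene: int = 3
    min_t0_reads: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.middle_fraction <= 1:
            raise ValueError("middle_fraction must be in (0, 1]")
        if self.min_barcodes_per_gene < 1:
            raise ValueError("min_barcodes_per_gene must be >= 1")
        if self.min_t0_reads < 0:
            raise ValueError("min_t0_reads must be >= 0")


@dataclass
class CurationReport:
    n_input_barcodes: int
    removed_intergenic: int
    removed_position: int
    removed_t0_reads: int
    removed_gene_representation: int
    n_barcodes_retained: int
    n_genes_retained: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("intergenic", self.removed_intergenic),
            ("position", self.removed_position),
            ("t0_reads", self.removed_t0_reads),
            ("gene_representation", self.removed_gene_representation),
        ]
        return pd.DataFrame(rows, columns=["filter", "n_removed"])


class EmptyCurationError(ValidationError):
    """No genes survived curation."""


def curate(cm: CountMatrix, params: CurationParams | None = None):
    """Apply the three retention filters; returns (restricted CountMatrix,
    CurationReport).

    Raises :class:`EmptyCurationError` if nothing survives, and
    :class:`ValidationError` if the position filter is requested but the pool
    carries no gene fractions.
    """
    params = params or CurationParams()
    pool = cm.pool.table
    n_input = len(pool)

    mapped = pool.index[pool["locus_tag"].notna()]
    removed_intergenic = n_input - len(mapped)

    # position filter: gene_fraction within the middle band, inclusive bounds
    sub = pool.loc[mapped]
    if params.middle_fraction < 1 and sub["gene_fraction"].isna().any():
        raise ValidationError(
            "position filter requires gene_fraction for every mapped barcode; "
            "annotate the pool from a GFF or supply gene_fraction in the pool file"
        )
    lo = (1 - params.middle_fraction) / 2
    hi = 1 - lo
    frac = sub["gene_fraction"]
    pos_ok = sub.index[frac.isna() | ((frac >= lo) & (frac <= hi))]
    removed_position = len(sub) - len(pos_ok)

    # T0 read filter: per barcode, reads summed across all T0 samples
    t0_samples = cm.sheet.samples_where("T0")
    t0_sum = cm.counts.loc[pos_ok, list(t0_samples)].sum(axis=1)
    t0_ok = pos_ok[t0_sum >= params.min_t0_reads]
    removed_t0 = len(pos_ok) - len(t0_ok)

    # gene representation: >= min barcodes at distinct insertion positions
    surv = pool.loc[t0_ok]
    n_distinct = surv.groupby("locus_tag")["insertion_pos"].nunique()
    keep_genes = set(n_distinct.index[n_distinct >= params.min_barcodes_per_gene])
    final = surv.index[surv["locus_tag"].isin(keep_genes)]
    removed_repr = len(t0_ok) - len(final)

    if len(keep_genes) == 0:
        raise EmptyCurationError(
            "no genes retained after curation; thresholds "
            f"{params} removed every barcode"
        )

    report = CurationReport(
        n_input_barcodes=n_input,
        removed_intergenic=removed_intergenic,
        removed_position=removed_position,
        removed_t0_reads=removed_t0,
        removed_gene_representation=removed_repr,
        n_barcodes_retained=len(final),
        n_genes_retained=len(keep_genes),
    )
    return cm.restrict(final), report
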