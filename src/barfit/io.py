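"""Readers, writers and the in-memory data model for a barcoded fitness screen.

A screen is described by three tab-separated files:

* a **count table** — rows are barcodes, columns are samples, entries are
  non-negative integer read counts;
* a **pool map** — one row per barcode giving the locus tag of the gene the
  transposon landed in (empty for intergenic insertions), the 1-based genomic
  insertion coordinate, the strand of the gene, and optionally the fractional
  position within the coding sequence;
* a **sample sheet** — one row per sample giving the experiment it belongs to
  and its condition (``T0``, ``control`` or ``selective``).

Gene models may additionally be supplied as GFF3, in which case the fractional
insertion position is computed from the annotated coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CONDITIONS = ("T0", "control", "selective")

POOL_COLUMNS = ["barcode", "locus_tag", "insertion_pos", "strand"]
SHEET_COLUMNS = ["sample_id", "experiment_id", "condition", "replicate"]


class ParseError(ValueError):
    """A screen file could not be parsed."""


class ValidationError(ValueError):
    """Parsed screen data violate an invariant of the data model."""


@dataclass
class BarcodePool:
    """Barcode-to-gene assignment with fractional insertion positions.

    ``table`` is indexed by barcode with columns ``locus_tag`` (None for
    intergenic insertions), ``insertion_pos`` (1-based), ``strand`` and
    ``gene_fraction`` (position within the CDS measured from the start codon,
    in [0, 1]; NaN when no gene model has been applied).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique()
            raise ValidationError(f"duplicate barcodes in pool: {list(dups[:5])}")
        if "gene_fraction" not in self.table.columns:
            self.table = self.table.assign(gene_fraction=np.nan)
        frac = self.table["gene_fraction"]
        bad = frac.dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValidationError("gene_fraction outside [0, 1]")

    @property
    def barcodes(self) -> pd.Index:
        return self.table.index

    def locus_of(self) -> pd.Series:
        return self.table["locus_tag"]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BarcodePool) and self.table.equals(other.table)


@dataclass
class SampleSheet:
    """Sample metadata: experiment membership and condition labels.

    ``table`` is indexed by sample_id with columns ``experiment_id``,
    ``condition`` and ``replicate``. Every experiment must contain at least
    one T0 (pre-selection baseline) sample.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample_ids in sample sheet")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(
                f"unknown condition labels {sorted(bad)}; expected one of {CONDITIONS}"
            )
        for exp, grp in self.table.groupby("experiment_id"):
            if not (grp["condition"] == "T0").any():
                raise ValidationError(f"experiment {exp!r} has no T0 sample")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_where(self, condition: str) -> pd.Index:
        return self.table.index[self.table["condition"] == condition]

    def condition_of(self, sample_id: str) -> str:
        return self.table.at[sample_id, "condition"]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleSheet) and self.table.equals(other.table)


@dataclass
class CountMatrix:
    """Barcode x sample integer read counts plus pool and sample metadata."""

    counts: pd.DataFrame
    pool: BarcodePool
    sheet: SampleSheet

    def __post_init__(self) -> None:
        c = self.counts
        if not set(c.index) == set(self.pool.barcodes):
            missing = set(c.index) - set(self.pool.barcodes)
            extra = set(self.pool.barcodes) - set(c.index)
            raise ValidationError(
                "count-table barcodes and pool barcodes differ "
                f"(in counts only: {sorted(missing)[:5]}, in pool only: {sorted(extra)[:5]})"
            )
        if not set(c.columns) == set(self.sheet.sample_ids):
            raise ValidationError("count-table samples and sample-sheet samples differ")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("counts must be integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def restrict(self, barcodes: Iterable[str]) -> "CountMatrix":
        """Return a copy restricted to the given barcodes (order preserved)."""
        keep = [b for b in self.counts.index if b in set(barcodes)]
        return CountMatrix(
            counts=self.counts.loc[keep].copy(),
            pool=BarcodePool(self.pool.table.loc[keep].copy()),
            sheet=self.sheet,
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.pool == other.pool
            and self.sheet == other.sheet
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_pool(path: str | Path) -> BarcodePool:
    """Read a pool map TSV (columns: barcode, locus_tag, insertion_pos, strand
    [, gene_fraction])."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "locus_tag": str})
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ParseError(f"could not parse pool file {path}: {exc}") from exc
    missing = set(POOL_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"pool file {path} missing columns {sorted(missing)}")
    df["locus_tag"] = df["locus_tag"].where(df["locus_tag"].notna() & (df["locus_tag"] != ""), None)
    df = df.set_index("barcode")
    df["insertion_pos"] = df["insertion_pos"].astype(np.int64)
    return BarcodePool(df)


def write_pool(pool: BarcodePool, path: str | Path) -> None:
    out = pool.table.reset_index().rename(columns={"index": "barcode"})
    if out.columns[0] != "barcode":
        out = out.rename(columns={out.columns[0]: "barcode"})
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV (columns: sample_id, experiment_id, condition,
    replicate)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "experiment_id": str})
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"could not parse sample sheet {path}: {exc}") from exc
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"sample sheet {path} missing columns {sorted(missing)}")
    df = df.set_index("sample_id")
    df["replicate"] = df["replicate"].astype(np.int64)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.table.reset_index()
    if out.columns[0] != "sample_id":
        out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, sep="\t", index=False)


def _read_count_table(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"could not parse count table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    for lineno, (bc, row) in enumerate(df.iterrows(), start=2):
        for val in row:
            if not float(val).is_integer() or val < 0:
                raise ValidationError(
                    f"count table {path} line {lineno} (barcode {bc!r}): "
                    f"invalid count {val!r} (non-negative integer required)"
                )
    return df.astype(np.int64)


def read_counts(
    counts_path: str | Path,
    pool_path: str | Path,
    sheet_path: str | Path,
) -> CountMatrix:
    """Assemble and validate a :class:`CountMatrix` from its three TSV files."""
    counts = _read_count_table(counts_path)
    pool = read_pool(pool_path)
    sheet = read_sample_sheet(sheet_path)
    return CountMatrix(counts=counts, pool=pool, sheet=sheet)


def write_counts(
    cm: CountMatrix,
    counts_path: str | Path,
    pool_path: str | Path,
    sheet_path: str | Path,
) -> None:
    """Write a :class:`CountMatrix` back to the three TSV files."""
    out = cm.counts.copy()
    out.index.name = "barcode"
    out.to_csv(counts_path, sep="\t")
    write_pool(cm.pool, pool_path)
    write_sample_sheet(cm.sheet, sheet_path)


# ---------------------------------------------------------------------------
# gene models


class OutOfGeneError(ValueError):
    """Insertion coordinate falls outside the gene's annotated bounds."""


def gene_fraction_from_gff(insertion_pos: int, gene_record) -> float:
    """Fractional position of an insertion within a gene, measured from the
    start codon.

    ``gene_record`` is any object with 1-based inclusive ``start``/``end``
    coordinates and a ``strand`` attribute (e.g. a ``gffutils.Feature``). On
    the minus strand the fraction is flipped so that 0 is always the start
    codon end of the CDS.
    """
    start, end = int(gene_record.start), int(gene_record.end)
    if not start <= insertion_pos <= end:
        raise OutOfGeneError(
            f"insertion at {insertion_pos} outside gene bounds [{start}, {end}]"
        )
    if end == start:
        return 0.0
    frac = (insertion_pos - start) / (end - start)
    if getattr(gene_record, "strand", "+") == "-":
        frac = 1.0 - frac
    return frac


def annotate_gene_fractions(pool: BarcodePool, gff_path: str | Path) -> BarcodePool:
    """Fill ``gene_fraction`` for every mapped barcode from GFF3 gene models.

    Every non-null locus_tag in the pool must be present in the GFF (matched
    against the feature's ``locus_tag`` attribute, falling back to its ID).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_tag = {}
    for feat in db.all_features():
        if feat.featuretype not in {"gene", "CDS"}:
            continue
        tags = feat.attributes.get("locus_tag", [feat.id])
        for tag in tags:
            by_tag.setdefault(tag, feat)

    table = pool.table.copy()
    fracs = []
    for bc, row in table.iterrows():
        tag = row["locus_tag"]
        if tag is None:
            fracs.append(np.nan)
            continue
        if tag not in by_tag:
            raise ValidationError(f"locus_tag {tag!r} (barcode {bc!r}) absent from GFF")
        fracs.append(gene_fraction_from_gff(int(row["insertion_pos"]), by_tag[tag]))
    table["gene_fraction"] = fracs
    return BarcodePool(table)
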