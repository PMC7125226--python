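"""Depth normalization, log2 transform and T0-baseline adjustment.

Raw counts are turned into the response modelled per gene:

    value(i, s) = log2( (c(i, s) + 1) * D_ref / D_s )

where ``D_s`` is sample *s*'s library size (column sum), ``D_ref`` the median
library size across samples, and the pseudocount of one keeps zero counts
finite. The pre-selection baseline is then removed: for each barcode and each
non-T0 sample, the mean log2 value over that experiment's T0 samples is
subtracted, leaving the log2 abundance change under selection or control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleSheet, ValidationError


@dataclass
class NormalizedMatrix:
    """T0-adjusted log2 values for the non-T0 samples.

    ``y`` is barcode x sample (log2 units), finite everywhere;
    ``reference_depth`` and ``library_sizes`` record the scaling used.
    """

    y: pd.DataFrame
    reference_depth: float
    library_sizes: pd.Series
    sheet: SampleSheet

    def __post_init__(self) -> None:
        if not np.isfinite(self.y.to_numpy()).all():
            raise ValidationError("normalized matrix contains non-finite values")


def log2_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample pseudocounted, depth-scaled log2 counts (all samples,
    T0 included)."""
    depths = cm.counts.sum(axis=0).astype(float)
    zero = depths.index[depths == 0]
    if len(zero):
        raise ValidationError(f"zero-depth sample(s): {list(zero)}")
    d_ref = float(depths.median())
    scaled = (cm.counts + 1).astype(float) * (d_ref / depths)
    return np.log2(scaled)


def t0_adjust(logvals: pd.DataFrame, sheet: SampleSheet) -> NormalizedMatrix:
    """Subtract each experiment's mean T0 log2 value per barcode; drop T0
    columns."""
    y = {}
    for exp, grp in sheet.table.groupby("experiment_id"):
        t0 = grp.index[grp["condition"] == "T0"]
        if len(t0) == 0:
            raise ValidationError(f"experiment {exp!r} has no T0 sample")
        baseline = logvals[list(t0)].mean(axis=1)
        for s in grp.index[grp["condition"] != "T0"]:
            y[s] = logvals[s] - baseline
    cols = [s for s in sheet.sample_ids if s in y]  # sheet order
    ymat = pd.DataFrame(y)[cols]
    depths = logvals.attrs.get("library_sizes")
    return NormalizedMatrix(
        y=ymat,
        reference_depth=logvals.attrs.get("reference_depth", np.nan),
        library_sizes=depths if depths is not None else pd.Series(dtype=float),
        sheet=sheet,
    )


def normalize(cm: CountMatrix) -> NormalizedMatrix:
    """Full normalization: pseudocount, depth scaling, log2, T0 subtraction."""
    depths = cm.counts.sum(axis=0).astype(float)
    logvals = log2_normalize(cm)
    logvals.attrs["library_sizes"] = depths
    logvals.attrs["reference_depth"] = float(depths.median())
    return t0_adjust(logvals, cm.sheet)
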