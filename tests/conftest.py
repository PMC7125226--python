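from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from barfit.io import BarcodePool, CountMatrix, SampleSheet

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def build_cm(counts: dict, pool_rows: list, sheet_rows: list) -> CountMatrix:
    """Assemble a CountMatrix from plain literals.

    ``counts`` maps sample_id -> {barcode: reads}; ``pool_rows`` are
    (barcode, locus_tag, insertion_pos, gene_fraction) tuples; ``sheet_rows``
    are (sample_id, experiment_id, condition, replicate).
    """
    pool = pd.DataFrame(
        pool_rows, columns=["barcode", "locus_tag", "insertion_pos", "gene_fraction"]
    ).set_index("barcode")
    pool["strand"] = "+"
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "experiment_id", "condition", "replicate"]
    ).set_index("sample_id")
    cdf = pd.DataFrame(counts)
    if set(cdf.index) == set(pool.index):
        cdf = cdf.reindex(pool.index).astype(np.int64)
    return CountMatrix(counts=cdf, pool=BarcodePool(pool), sheet=SampleSheet(sheet))


@pytest.fixture
def simple_sheet_rows():
    return [
        ("t0_1", "exp1", "T0", 1),
        ("ctl_1", "exp1", "control", 1),
        ("sel_1", "exp1", "selective", 1),
    ]


@pytest.fixture
def toy_cm(simple_sheet_rows):
    """3 barcodes x 3 samples, two genes, one intergenic barcode."""
    pool_rows = [
        ("AAAA", "geneA", 1100, 0.2),
        ("CCCC", "geneA", 1500, 0.5),
        ("GGGG", None, 9000, np.nan),
    ]
    counts = {
        "t0_1": {"AAAA": 100, "CCCC": 50, "GGGG": 25},
        "ctl_1": {"AAAA": 90, "CCCC": 60, "GGGG": 30},
        "sel_1": {"AAAA": 10, "CCCC": 5, "GGGG": 40},
    }
    return build_cm(counts, pool_rows, simple_sheet_rows)


def three_experiment_sheet_rows(n_experiments: int = 3):
    rows = []
    for e in range(1, n_experiments + 1):
        for cond in ("T0", "control", "selective"):
            rows.append((f"{cond}_{e}", f"exp{e}", cond, e))
    return rows


def random_gene_block(rng: np.random.Generator):
    """Random small per-gene dataset in model long form: (y, x, groups).

    2-4 barcodes, 2-3 samples per condition, parameters drawn broadly.
    """
    n_bc = rng.integers(2, 5)
    n_per = rng.integers(2, 4)
    mu = rng.normal(0, 2)
    cond = rng.normal(0, 2)
    vs2 = rng.uniform(0, 0.5)
    s2 = rng.uniform(0.05, 0.6)
    b = rng.normal(0, np.sqrt(vs2), n_bc)
    x = np.tile(np.r_[np.full(n_per, 0.5), np.full(n_per, -0.5)], n_bc)
    groups = np.repeat(np.arange(n_bc), 2 * n_per)
    y = mu + cond * x + b[groups] + rng.normal(0, np.sqrt(s2), len(x))
    return y, x, groups


def block_to_frame(y, x, groups):
    """Reshape long-form (y, x, groups) into the barcode x sample frame plus
    sample sheet that fit_gene accepts."""
    n_bc = len(np.unique(groups))
    n_s = len(y) // n_bc
    cols = [f"s{j}" for j in range(n_s)]
    ymat = pd.DataFrame(y.reshape(n_bc, n_s), index=[f"bc{i}" for i in range(n_bc)], columns=cols)
    conds = np.where(x[:n_s] > 0, "selective", "control")
    sheet = pd.DataFrame(
        {
            "sample_id": cols + ["t0"],
            "experiment_id": "exp1",
            "condition": list(conds) + ["T0"],
            "replicate": 1,
        }
    ).set_index("sample_id")
    return ymat, SampleSheet(sheet)
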