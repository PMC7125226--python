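"""Small assay calculators: circadian cosinor phase, transformation
efficiency, and relative qPCR fold change."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class CosineFit:
    """Single-harmonic cosinor fit Y(t) = mesor + A*cos(2*pi*(t - phi)/P).

    ``phi`` (hours, in [0, P)) is the time of peak expression; ``A`` >= 0 is
    the amplitude in expression units. ``degenerate`` is set when the series
    carries no rhythmic component (A = 0), in which case phi is reported as 0.
    """

    amplitude: float
    phase: float
    period: float
    mesor: float
    rss: float
    degenerate: bool = False


def fit_cosine(times, values, period: float = 24.0) -> CosineFit:
    """Least-squares cosinor fit at a fixed period (default 24 h).

    Linear in (mesor, a, b) through Y = mesor + a*cos(wt) + b*sin(wt) with
    w = 2*pi/period; then A = hypot(a, b) and phi = atan2(b, a)/w mod period.
    Exact on noiseless data of the model family. Requires >=3 distinct time
    points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and the same length")
    if len(np.unique(t)) < 3:
        raise ValueError("need >=3 distinct time points")
    w = 2.0 * math.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, a, b = coef
    amp = math.hypot(a, b)
    rss = float(np.sum((y - X @ coef) ** 2))
    if amp < 1e-12:
        return CosineFit(0.0, 0.0, period, float(mesor), rss, degenerate=True)
    phi = (math.atan2(b, a) / w) % period
    if period - phi < 1e-9:  # round-off just below one full period wraps to 0
        phi = 0.0
    return CosineFit(float(amp), float(phi), period, float(mesor), rss)


@dataclass
class EfficiencyResult:
    """Transformation efficiency: antibiotic-resistant colonies per CFU
    plated without selection, both back-corrected for their dilutions."""

    efficiency: float
    resistant_count: float
    cfu_count: float
    resistant_dilution: float
    cfu_dilution: float


def transformation_efficiency(
    resistant: float,
    resistant_dilution: float,
    cfu: float,
    cfu_dilution: float,
    plated_volume_ml: float = 1.0,
) -> EfficiencyResult:
    """efficiency = (resistant * resistant_dilution) / (cfu * cfu_dilution);
    the common plated volume cancels. ``cfu`` must be > 0 and dilution
    factors >= 1 (a 10x dilution is 10)."""
    if cfu <= 0:
        raise ValueError("CFU count must be > 0 to define an efficiency")
    if min(resistant_dilution, cfu_dilution) < 1:
        raise ValueError("dilution factors must be >= 1")
    if resistant < 0:
        raise ValueError("colony counts must be >= 0")
    if plated_volume_ml <= 0:
        raise ValueError("plated volume must be > 0")
    eff = (resistant * resistant_dilution) / (cfu * cfu_dilution)
    return EfficiencyResult(eff, resistant, cfu, resistant_dilution, cfu_dilution)


@dataclass
class FoldChange:
    """Relative expression by the 2^-ddCt method."""

    ddct: float
    fold: float


def fold_change_ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_base: float,
    ct_ref_base: float,
) -> FoldChange:
    """ddCt = (Ct_target - Ct_ref)_treatment - (Ct_target - Ct_ref)_baseline;
    fold = 2**(-ddCt). One cycle earlier for the target under treatment means
    a two-fold induction."""
    cts = (ct_target_treat, ct_ref_treat, ct_target_base, ct_ref_base)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("Ct values must be finite")
    ddct = (ct_target_treat - ct_ref_treat) - (ct_target_base - ct_ref_base)
    return FoldChange(ddct=ddct, fold=2.0 ** (-ddct))
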