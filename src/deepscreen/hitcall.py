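"""Threshold-based hit identification and class labelling.

Hits are clones whose mean cluster intensity at a named condition exceeds the
library mean FI by a fold factor (2.0 for stringent calls, 1.5 once the assay
noise floor is known).  For classifier training, intensities at the 5-minute
wash condition are binned into non-hit / low-hit / high-hit classes around a
reference clone's intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

# Class bins chosen so the reference parent clone (FI 190.05) sits roughly
# centred in the low-hit band.
DEFAULT_NON_HIT_MAX = 150.0
DEFAULT_HIGH_HIT_MIN = 250.0
REFERENCE_FI_G98A = 190.05

NON_HIT, LOW_HIT, HIGH_HIT = "non_hit", "low_hit", "high_hit"
CLASS_ORDER = (NON_HIT, LOW_HIT, HIGH_HIT)


@dataclass(frozen=True)
class HitThresholds:
    library_fi_mean: float
    fold: float = 2.0
    condition_id: str = ""

    def __post_init__(self):
        if self.fold <= 1:
            raise ValueError("fold must be > 1")

    @property
    def threshold(self) -> float:
        return self.fold * self.library_fi_mean


@dataclass(frozen=True)
class ClassBins:
    non_hit_max: float = DEFAULT_NON_HIT_MAX
    high_hit_min: float = DEFAULT_HIGH_HIT_MIN
    reference_fi: float = REFERENCE_FI_G98A

    def __post_init__(self):
        if not self.non_hit_max < self.high_hit_min:
            raise ValueError("non_hit_max must be < high_hit_min")


def _fi_column(table: pd.DataFrame, condition: str, channel: str = "T",
               stat: str = "mean") -> pd.Series:
    col = f"{condition}__{channel}__{stat}"
    if col in table.columns:
        return table[col]
    if condition in table.columns:
        return table[condition]
    raise KeyError(f"no FI column for condition {condition!r}")


def library_mean(table: pd.DataFrame, condition: str, channel: str = "T",
                 stat: str = "mean") -> float:
    """Arithmetic mean of per-UMI FI_mean values at one condition (all rows)."""
    fis = _fi_column(table, condition, channel, stat).dropna()
    if fis.empty:
        raise ValueError(f"no rows with condition {condition!r}")
    return float(fis.mean())


def call_hits_fold(table: pd.DataFrame, fi_mean: float, fold: float = 2.0,
                   condition: str | None = None, channel: str = "T",
                   stat: str = "mean") -> pd.DataFrame:
    """Rows whose FI at the condition is >= fold x library mean (inclusive)."""
    thr = HitThresholds(library_fi_mean=fi_mean, fold=fold,
                        condition_id=condition or "").threshold
    fis = _fi_column(table, condition, channel, stat)
    return table[fis >= thr]


def bin_three_class(fi: float, bins: ClassBins = ClassBins()) -> str:
    """Partition one FI value: <=non_hit_max | (.,.) | >=high_hit_min."""
    if fi <= bins.non_hit_max:
        return NON_HIT
    if fi >= bins.high_hit_min:
        return HIGH_HIT
    return LOW_HIT


def binary_vs_reference(fi: float, reference_fi: float = REFERENCE_FI_G98A,
                        fold: float = 1.5) -> str:
    """Binary call against a reference clone: hit iff fi >= fold x reference."""
    if reference_fi <= 0:
        raise ValueError("reference_fi must be positive")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    return "hit" if fi >= fold * reference_fi else NON_HIT


def _censor(values):
    """Map censored strings like '>1e-5' to their bound before ranking."""
    out = []
    for v in values:
        if isinstance(v, str):
            v = float(v.lstrip("<>").strip())
        out.append(float(v))
    return np.asarray(out)


def rank_correlation(x, y):
    """Spearman rho with average-rank ties; censored entries placed at bound.

    Values given as strings (e.g. ``">1e-5"`` for affinities beyond the
    measurable range) contribute at the stated bound.  Constant input is
    undefined and returns NaN.
    """
    xv, yv = _censor(x), _censor(y)
    if len(xv) != len(yv) or len(xv) < 3:
        raise ValueError("need equal-length inputs of at least 3 values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    return float(sstats.spearmanr(xv, yv).statistic)


def annotate_hits(table: pd.DataFrame, condition: str, fold: float = 2.0,
                  bins: ClassBins = ClassBins(), channel: str = "T",
                  stat: str = "mean") -> pd.DataFrame:
    """Add ``hit`` (fold over library mean) and ``class`` (three-way bin) columns."""
    fi_mean = library_mean(table, condition, channel, stat)
    fis = _fi_column(table, condition, channel, stat)
    out = table.copy()
    out["hit"] = fis >= HitThresholds(fi_mean, fold).threshold
    out["class"] = [bin_three_class(v, bins) if np.isfinite(v) else NON_HIT
                    for v in fis]
    return out
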