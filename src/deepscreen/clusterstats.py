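"""Per-UMI replicate statistics and genotype-phenotype linkage.

Every clone appears on the flow cell as >= 12 replicate clusters sharing one
28-mer UMI.  This module groups the per-cluster intensities by UMI, rejects
outlier replicates by median absolute deviation, summarizes the survivors
(mean/median/sd/sem per condition x channel), error-corrects the CDR reads
for each UMI into a consensus genotype, and inner-joins genotype to phenotype
on the UMI.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import Counter

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_REPLICATES = 12
DEFAULT_MIN_READS = 3
DEFAULT_MAD_K = 3.0


def reject_outliers_mad(values, k: float = DEFAULT_MAD_K) -> np.ndarray:
    """Keep values with |v - median| <= k * MAD (raw, unscaled MAD).

    MAD = median(|v - median(v)|).  When the MAD is zero (at least half the
    replicates identical) only values equal to the median survive, so the
    median itself is never rejected.  Fewer than 3 values pass through
    unchanged with a warning, since a robust scale cannot be estimated.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        warnings.warn("fewer than 3 values: MAD rejection skipped", stacklevel=2)
        return values
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return values[values == med]
    return values[np.abs(values - med) <= k * mad]


def group_by_umi(intensities: pd.DataFrame,
                 min_replicates: int = DEFAULT_MIN_REPLICATES) -> pd.DataFrame:
    """Retain UMIs backed by >= ``min_replicates`` non-rejected clusters.

    A cluster rejected in any condition (it fell outside the imaging area)
    is treated as rejected outright.  Returns the intensity rows of the
    surviving UMIs, restricted to non-rejected clusters; the number of
    dropped UMIs is logged.
    """
    if intensities.empty:
        return intensities.copy()
    df = intensities.copy()
    # cluster identity = (umi, tile, x, y); rejected anywhere -> rejected
    key = ["umi", "tile", "x", "y"]
    cluster_rej = df.groupby(key)["rejected"].transform("max").astype(bool)
    df = df[~cluster_rej]
    n_clusters = df.groupby("umi")[["tile", "x", "y"]].apply(
        lambda g: len(g[["tile", "x", "y"]].drop_duplicates()))
    keep = set(n_clusters[n_clusters >= min_replicates].index)
    dropped = df["umi"].nunique() - len(keep) + intensities["umi"].nunique() - df["umi"].nunique()
    if dropped:
        logger.info("group_by_umi: dropped %d UMIs below %d replicates",
                    dropped, min_replicates)
    return df[df["umi"].isin(keep)].copy()


def summarize(intensities: pd.DataFrame, mad_k: float = DEFAULT_MAD_K) -> pd.DataFrame:
    """Per UMI x condition x channel: MAD-filter then mean/median/sd/sem.

    sd is the sample standard deviation (n-1); sem = sd / sqrt(n_kept).
    Groups with a single kept value have undefined sd/sem (NaN) and are
    flagged via n_kept.
    """
    rows = []
    for (umi, cond, channel), g in intensities.groupby(["umi", "condition", "channel"]):
        vals = g["fi"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n_total = len(g)
        if len(vals) >= 3:
            kept = reject_outliers_mad(vals, k=mad_k)
        else:
            kept = vals
        n_kept = len(kept)
        if n_kept == 0:
            rows.append((umi, cond, channel, n_total, 0,
                         np.nan, np.nan, np.nan, np.nan))
            continue
        mean = float(np.mean(kept))
        median = float(np.median(kept))
        sd = float(np.std(kept, ddof=1)) if n_kept >= 2 else np.nan
        sem = sd / math.sqrt(n_kept) if n_kept >= 2 else np.nan
        rows.append((umi, cond, channel, n_total, n_kept, mean, median, sd, sem))
    return pd.DataFrame(rows, columns=["umi", "condition", "channel",
                                       "n_total", "n_kept",
                                       "mean", "median", "sd", "sem"])


def consensus_cdr(reads, min_reads: int = DEFAULT_MIN_READS,
                  per_position: bool = False):
    """Consensus CDR for one UMI's reads, or ``None`` when there is none.

    Default mode is whole-read plurality: the most frequent full-length read
    wins if it is the unique winner; ties or fewer than ``min_reads`` reads
    drop the UMI.  ``per_position`` voting (majority at each column over
    reads of the modal length) is available but can assemble chimeric
    sequences, so it is off by default.
    """
    reads = list(reads)
    if len(reads) < min_reads:
        return None
    if per_position:
        lengths = Counter(len(r) for r in reads)
        modal_len = lengths.most_common(1)[0][0]
        cohort = [r for r in reads if len(r) == modal_len]
        out = []
        for i in range(modal_len):
            counts = Counter(r[i] for r in cohort).most_common(2)
            if len(counts) > 1 and counts[0][1] == counts[1][1]:
                return None
            out.append(counts[0][0])
        return "".join(out)
    counts = Counter(reads).most_common(2)
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def consensus_table(reads: pd.DataFrame, min_reads: int = DEFAULT_MIN_READS,
                    per_position: bool = False) -> pd.DataFrame:
    """Apply :func:`consensus_cdr` per UMI; UMIs without consensus are absent."""
    rows = []
    for umi, g in reads.groupby("umi"):
        cons = consensus_cdr(g["read_seq"].tolist(), min_reads=min_reads,
                             per_position=per_position)
        if cons is not None:
            rows.append((umi, cons, len(g)))
    return pd.DataFrame(rows, columns=["umi", "consensus_cdr", "n_reads"])


def _widen(stats: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long statistics table to one row per UMI."""
    wide = stats.pivot_table(index="umi",
                             columns=["condition", "channel"],
                             values=["mean", "median", "sd", "sem", "n_kept"],
                             aggfunc="first")
    wide.columns = [f"{cond}__{chan}__{stat}" for stat, cond, chan in wide.columns]
    return wide.reset_index()


def join_genotype_phenotype(stats: pd.DataFrame, consensi: pd.DataFrame,
                            collapse: bool = False) -> pd.DataFrame:
    """Inner-join per-UMI statistics with consensus CDRs on the UMI.

    UMIs present in only one table are logged and excluded.  In collapse
    mode, UMIs sharing one consensus CDR are merged to a single row carrying
    the per-CDR UMI count (abundance) and the mean of each statistic.
    """
    if stats.empty or consensi.empty:
        return pd.DataFrame(columns=["umi", "consensus_cdr"])
    for name, df in (("statistics", stats), ("consensus", consensi)):
        if df["umi"].duplicated().any() and name == "consensus":
            raise ValueError("duplicate UMI rows in consensus input")
    wide = _widen(stats) if "condition" in stats.columns else stats
    if wide["umi"].duplicated().any():
        raise ValueError("duplicate UMI rows in statistics input")
    only_pheno = set(wide["umi"]) - set(consensi["umi"])
    only_geno = set(consensi["umi"]) - set(wide["umi"])
    if only_pheno or only_geno:
        logger.info("join: %d binding-only and %d sequence-only UMIs excluded",
                    len(only_pheno), len(only_geno))
    joined = wide.merge(consensi, on="umi", how="inner")
    if not collapse:
        return joined
    stat_cols = [c for c in joined.columns if c not in ("umi", "consensus_cdr", "n_reads")]
    agg = {c: "mean" for c in stat_cols}
    agg["umi"] = "count"
    out = joined.groupby("consensus_cdr").agg(agg).rename(columns={"umi": "abundance"})
    return out.reset_index()


def aggregate(intensities: pd.DataFrame, reads: pd.DataFrame,
              min_replicates: int = DEFAULT_MIN_REPLICATES,
              min_reads: int = DEFAULT_MIN_READS,
              mad_k: float = DEFAULT_MAD_K,
              collapse: bool = False) -> pd.DataFrame:
    """Full aggregation chain: replicate filter -> MAD -> stats -> consensus -> join."""
    grouped = group_by_umi(intensities, min_replicates=min_replicates)
    if grouped.empty:
        return pd.DataFrame(columns=["umi", "consensus_cdr"])
    stats = summarize(grouped, mad_k=mad_k)
    consensi = consensus_table(reads, min_reads=min_reads)
    return join_genotype_phenotype(stats, consensi, collapse=collapse)
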