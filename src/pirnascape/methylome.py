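"""Windowed CpG methylation quantification from Bismark-format calls.

Methylation is summarized in running windows of 50 consecutive CpG
positions (tiled by default, i.e. step = 50 CpGs), keeping only windows
with at least 10 total read observations; a window's level is the
pooled-count mean 100 * sum(meth) / sum(meth + unmeth), not the mean of
per-CpG percentages. Feature-level values are unweighted means of the
windows intersecting the feature. Conversion efficiency comes from an
unmethylated lambda spike-in; overconversion from a fully methylated pUC19
spike-in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .te_annotation import RepeatRecord

log = logging.getLogger(__name__)

COV_COLUMNS = ["chrom", "pos", "count_meth", "count_unmeth"]
WINDOW_COLUMNS = ["chrom", "start", "end", "n_cpgs", "total_obs", "mean_meth"]


def parse_bismark_cov(path) -> pd.DataFrame:
    """Read a Bismark coverage file (chrom, 1-based pos, pos, percent,
    count_meth, count_unmeth) into COV_COLUMNS with 0-based positions.

    The percent column is ignored and recomputed from the counts; a
    discrepancy > 0.5 triggers a warning, a malformed line an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "percent",
                                "count_meth", "count_unmeth"],
                         dtype={"chrom": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed Bismark coverage file {path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=COV_COLUMNS)
    try:
        for col in ("start", "count_meth", "count_unmeth", "percent"):
            df[col] = pd.to_numeric(df[col], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed Bismark coverage file {path}: {exc}") from exc
    if df[["start", "count_meth", "count_unmeth"]].isna().any().any():
        raise ValueError(f"malformed Bismark coverage file {path}")
    total = df["count_meth"] + df["count_unmeth"]
    with np.errstate(invalid="ignore"):
        recomputed = 100.0 * df["count_meth"] / total.replace(0, np.nan)
    bad = (recomputed - df["percent"]).abs() > 0.5
    if bad.any():
        warnings.warn(f"{int(bad.sum())} coverage rows have percent inconsistent "
                      "with counts; counts take precedence")
    out = df.rename(columns={"start": "pos"})[
        ["chrom", "pos", "count_meth", "count_unmeth"]].copy()
    out["pos"] = out["pos"].astype(int) - 1
    return out


def write_cov(calls: pd.DataFrame, path) -> None:
    from .simulate import write_bismark_cov
    write_bismark_cov(calls, path)


def running_windows(calls: pd.DataFrame, n_cpg: int = 50, min_obs: int = 10,
                    step: int | None = None) -> pd.DataFrame:
    """Windows of n_cpg consecutive CpG positions per chromosome.

    step is in CpG units (default n_cpg: non-overlapping tiles). Windows
    with fewer than min_obs total read observations are dropped; trailing
    partial windows (< n_cpg positions) are not emitted.
    """
    step = step or n_cpg
    rows = []
    for chrom, sub in calls.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        meth = sub["count_meth"].to_numpy()
        unmeth = sub["count_unmeth"].to_numpy()
        for i in range(0, len(pos) - n_cpg + 1, step):
            m = int(meth[i:i + n_cpg].sum())
            u = int(unmeth[i:i + n_cpg].sum())
            if m + u < min_obs:
                continue
            rows.append({"chrom": chrom, "start": int(pos[i]),
                         "end": int(pos[i + n_cpg - 1]) + 1, "n_cpgs": n_cpg,
                         "total_obs": m + u,
                         "mean_meth": 100.0 * m / (m + u)})
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def global_methylation(calls: pd.DataFrame) -> float:
    tot = (calls["count_meth"] + calls["count_unmeth"]).sum()
    return 100.0 * calls["count_meth"].sum() / tot if tot else float("nan")


def feature_methylation(windows: pd.DataFrame,
                        features: pd.DataFrame) -> pd.DataFrame:
    """Per-feature unweighted mean of window levels over intersecting windows.

    `features` needs chrom/start/end plus any id columns; features with no
    qualifying window get NaN (their count is logged).
    """
    trees: dict[str, IntervalTree] = {}
    for i, w in enumerate(windows.itertuples()):
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w.mean_meth)
    values, n_windows = [], []
    for f in features.itertuples():
        t = trees.get(f.chrom)
        hits = [h.data for h in t.overlap(f.start, f.end)] if t else []
        values.append(float(np.mean(hits)) if hits else np.nan)
        n_windows.append(len(hits))
    out = features.copy()
    out["mean_meth"] = values
    out["n_windows"] = n_windows
    missing = int(np.isnan(values).sum())
    if missing:
        log.info("feature_methylation: %d features without qualifying windows",
                 missing)
    return out


def metaplot(calls: pd.DataFrame, features: pd.DataFrame, flank: int = 2000,
             body_bins: int = 100, flank_bins: int = 40) -> pd.DataFrame:
    """Pooled-count methylation profile over scaled feature bodies +-flank.

    Bin indices -flank_bins..-1 are the upstream flank (fixed-width bins),
    0..body_bins-1 the length-scaled body, body_bins..body_bins+flank_bins-1
    the downstream flank. Minus-strand features are reversed so bin 0 is
    always the TSS side. Returns per-bin pooled counts and mean percent.
    """
    n_bins = body_bins + 2 * flank_bins
    meth = np.zeros(n_bins)
    total = np.zeros(n_bins)
    flank_w = flank / flank_bins
    by_chrom = {c: sub.sort_values("pos") for c, sub in calls.groupby("chrom")}
    short = 0
    for f in features.itertuples():
        sub = by_chrom.get(f.chrom)
        if sub is None:
            continue
        length = f.end - f.start
        if length < body_bins:
            short += 1
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [f.start - flank, f.end + flank])
        if hi <= lo:
            continue
        p = pos[lo:hi]
        m = sub["count_meth"].to_numpy()[lo:hi]
        u = sub["count_unmeth"].to_numpy()[lo:hi]
        rel = np.empty(p.size)
        up = p < f.start
        down = p >= f.end
        body = ~(up | down)
        rel[up] = (p[up] - (f.start - flank)) / flank_w - flank_bins
        rel[body] = (p[body] - f.start) / length * body_bins
        rel[down] = body_bins + (p[down] - f.end) / flank_w
        bins = np.floor(rel).astype(int) + flank_bins
        bins = np.clip(bins, 0, n_bins - 1)
        strand = getattr(f, "strand", "+")
        if strand == "-":
            bins = n_bins - 1 - bins
        np.add.at(meth, bins, m)
        np.add.at(total, bins, m + u)
    if short:
        log.info("metaplot: %d features shorter than body_bins bp", short)
    with np.errstate(invalid="ignore"):
        pct = np.where(total > 0, 100.0 * meth / np.maximum(total, 1), np.nan)
    return pd.DataFrame({
        "bin": np.arange(-flank_bins, body_bins + flank_bins),
        "count_meth": meth, "total_obs": total, "mean_meth": pct})


@dataclass
class ConversionStats:
    conversion_pct: float        # lambda: unmethylated calls correctly converted
    puc19_retention_pct: float   # pUC19: methylated calls retained
    overconversion_pct: float


def conversion_rate(lambda_calls: pd.DataFrame,
                    puc19_calls: pd.DataFrame) -> ConversionStats:
    lm = lambda_calls["count_meth"].sum()
    lu = lambda_calls["count_unmeth"].sum()
    pm = puc19_calls["count_meth"].sum()
    pu = puc19_calls["count_unmeth"].sum()
    conv = 100.0 * lu / (lm + lu) if lm + lu else float("nan")
    ret = 100.0 * pm / (pm + pu) if pm + pu else float("nan")
    return ConversionStats(conversion_pct=conv, puc19_retention_pct=ret,
                           overconversion_pct=100.0 - ret)


def exclude_exonic_repeats(te_records: Sequence[RepeatRecord],
                           exons: pd.DataFrame) -> list[RepeatRecord]:
    """Drop transposon copies overlapping any exon by >= 1 bp."""
    trees: dict[str, IntervalTree] = {}
    for e in exons.itertuples():
        trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end)
    return [r for r in te_records
            if not (trees.get(r.chrom) and trees[r.chrom].overlap(r.start, r.end))]


@dataclass
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def compare_groups(a, b) -> TTestResult:
    """Unpaired two-sided Welch t-test. Two groups with zero variance and
    different means are degenerate (flagged, NaN statistics); identical
    groups give t=0, p=1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("compare_groups needs >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0)
        return TTestResult(t=float("nan"), p=float("nan"), degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(t), p=float(p))


def high_methylation_chi_square(values_genome, values_cgi,
                                threshold: float = 80.0) -> tuple[float, float]:
    """Chi-square comparing the fraction of highly methylated windows
    (>= threshold percent) between the genome and CGI regions."""
    from .cgi import chi_square
    g = np.asarray(values_genome, dtype=float)
    c = np.asarray(values_cgi, dtype=float)
    table = np.array([[(g >= threshold).sum(), (g < threshold).sum()],
                      [(c >= threshold).sum(), (c < threshold).sum()]])
    return chi_square(table)
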