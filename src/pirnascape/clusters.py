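"""piRNA cluster detection by sliding-window density significance.

A window of `window` bp (default 5000) slides in steps of window/10; the
weighted alignment mass in each window is tested against a one-sided
Poisson tail under the uniform genome-wide rate, and windows with
p <= pdens (default 0.01) are merged and trimmed to the outermost read
boundaries. Alignment lengths are restricted to 23-33 nt, clusters below
`min_reads` weighted mass are dropped, and strandedness is called
uni+/uni-/dual from the dominant-strand mass fraction (threshold 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

CLUSTER_COLUMNS = ["chrom", "start", "end", "strandedness", "weighted_mass",
                   "rpkm"]


@dataclass
class ClusterParams:
    window: int = 5000
    pdens: float = 0.01
    pimin: int = 23
    pimax: int = 33
    uni_threshold: float = 0.75
    min_reads: float = 10.0

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.pdens < 1:
            raise ValueError("pdens must be in (0,1)")
        if self.pimin > self.pimax:
            raise ValueError("pimin > pimax")


def _five_prime(df: pd.DataFrame) -> np.ndarray:
    return np.where(df["strand"].to_numpy() == "+",
                    df["start"].to_numpy(), df["end"].to_numpy() - 1)


def significant_windows(alignments: pd.DataFrame, chrom_sizes: Mapping[str, int],
                        params: ClusterParams) -> pd.DataFrame:
    """All sliding windows whose Poisson tail probability is <= pdens.

    Returns columns chrom, start, end, mass, p. The background rate is the
    total (length-filtered) weighted mass divided by total genome length.
    """
    step = max(1, params.window // 10)
    lengths = alignments["end"] - alignments["start"]
    aln = alignments[(lengths >= params.pimin) & (lengths <= params.pimax)]
    total_len = sum(chrom_sizes.values())
    total_mass = aln["weight"].sum()
    lam = total_mass / total_len * params.window
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = aln[aln["chrom"] == chrom]
        if sub.empty:
            continue
        n_bins = size // step + 1
        bin_mass = np.zeros(n_bins + 10)
        np.add.at(bin_mass, np.minimum(_five_prime(sub) // step, n_bins - 1),
                  sub["weight"].to_numpy())
        k = max(1, params.window // step)
        window_mass = np.convolve(bin_mass, np.ones(k), mode="valid")
        pvals = stats.poisson.sf(np.ceil(window_mass) - 1, lam)
        sig = np.where((window_mass > 0) & (pvals <= params.pdens))[0]
        for i in sig:
            rows.append({"chrom": chrom, "start": int(i * step),
                         "end": int(min(i * step + params.window, size)),
                         "mass": float(window_mass[i]), "p": float(pvals[i])})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mass", "p"])


def call_clusters(alignments: pd.DataFrame, chrom_sizes: Mapping[str, int],
                  params: ClusterParams | None = None) -> pd.DataFrame:
    """Merge significant windows into clusters, trim to read extents, call
    strandedness, and rank by weighted mass. Returns CLUSTER_COLUMNS + rank."""
    params = params or ClusterParams()
    if alignments.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS + ["rank"])
    lengths = alignments["end"] - alignments["start"]
    aln = alignments[(lengths >= params.pimin) & (lengths <= params.pimax)].copy()
    if aln.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS + ["rank"])
    aln["p5"] = _five_prime(aln)
    windows = significant_windows(alignments, chrom_sizes, params)
    total_mass_m = aln["weight"].sum() / 1e6

    rows = []
    for chrom in chrom_sizes:
        w = windows[windows["chrom"] == chrom].sort_values("start")
        if w.empty:
            continue
        sub = aln[aln["chrom"] == chrom]
        p5 = sub["p5"].to_numpy()
        # merge overlapping / touching significant windows
        merged: list[list[int]] = []
        for win in w.itertuples():
            if merged and win.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], win.end)
            else:
                merged.append([win.start, win.end])
        for ms, me in merged:
            ms, me = _refine_edges(p5, sub["weight"].to_numpy(), ms, me, params,
                                   lam_per_bp=aln["weight"].sum() / sum(chrom_sizes.values()))
            inside = (p5 >= ms) & (p5 < me)
            if not inside.any():
                continue
            hit = sub[inside]
            start = int(hit["start"].min())
            end = int(hit["end"].max())
            mass = float(hit["weight"].sum())
            if mass < params.min_reads:
                continue
            plus = float(hit.loc[hit["strand"] == "+", "weight"].sum())
            frac_plus = plus / mass
            if frac_plus >= params.uni_threshold:
                strandedness = "uni+"
            elif 1 - frac_plus >= params.uni_threshold:
                strandedness = "uni-"
            else:
                strandedness = "dual"
            rpkm = mass / ((end - start) / 1e3) / total_mass_m if total_mass_m else 0.0
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "strandedness": strandedness, "weighted_mass": mass,
                         "rpkm": rpkm})
    df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    # trimming can in principle stretch neighbours into contact; merge any overlap
    df = _merge_overlapping(df, aln, params)
    return rank_and_cumulate(df)[0]


def _refine_edges(p5: np.ndarray, weights: np.ndarray, ms: int, me: int,
                  params: ClusterParams, lam_per_bp: float) -> tuple[int, int]:
    """Shrink a merged significant region to its outermost significant step
    bins.

    Window-level significance leaves up to window-step of low-density slop
    at each edge (any window overlapping a dense locus is significant); a
    stray background read there would otherwise stretch the trimmed
    cluster. Bins of width window/10 are re-tested with the same Poisson
    tail at bin scale and the region is cut back to the outermost bin that
    passes.
    """
    step = max(1, params.window // 10)
    inside = (p5 >= ms) & (p5 < me)
    if not inside.any():
        return ms, me
    pos = p5[inside]
    w = weights[inside]
    bins = (pos - ms) // step
    n_bins = (me - ms + step - 1) // step
    mass = np.zeros(n_bins)
    np.add.at(mass, bins, w)
    lam_bin = lam_per_bp * step
    pv = stats.poisson.sf(np.ceil(mass) - 1, lam_bin)
    sig = np.where((mass > 0) & (pv <= params.pdens))[0]
    if sig.size == 0:
        return ms, me
    return ms + int(sig[0]) * step, min(me, ms + (int(sig[-1]) + 1) * step)


def _merge_overlapping(df: pd.DataFrame, aln: pd.DataFrame,
                       params: ClusterParams) -> pd.DataFrame:
    if df.empty:
        return df
    out = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for r in sub.itertuples():
            if cur is not None and r.start < cur["end"]:
                cur["end"] = max(cur["end"], r.end)
                cur["weighted_mass"] += r.weighted_mass
                cur["strandedness"] = "dual"  # recomputed below
                cur["_dirty"] = True
            else:
                if cur is not None:
                    out.append(cur)
                cur = r._asdict()
                cur.pop("Index", None)
                cur["_dirty"] = False
        if cur is not None:
            out.append(cur)
    res = pd.DataFrame(out)
    for i in res.index[res["_dirty"]]:
        hit = aln[(aln["chrom"] == res.at[i, "chrom"])
                  & (aln["p5"] >= res.at[i, "start"])
                  & (aln["p5"] < res.at[i, "end"])]
        mass = float(hit["weight"].sum())
        plus = float(hit.loc[hit["strand"] == "+", "weight"].sum())
        frac = plus / mass if mass else 0.0
        res.at[i, "weighted_mass"] = mass
        res.at[i, "strandedness"] = ("uni+" if frac >= params.uni_threshold else
                                     "uni-" if 1 - frac >= params.uni_threshold
                                     else "dual")
    return res.drop(columns="_dirty")


def call_strandedness(plus_mass: float, minus_mass: float,
                      uni_threshold: float = 0.75) -> str:
    total = plus_mass + minus_mass
    if total == 0:
        return "dual"
    frac = plus_mass / total
    if frac >= uni_threshold:
        return "uni+"
    if 1 - frac >= uni_threshold:
        return "uni-"
    return "dual"


def rank_and_cumulate(clusters: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Rank clusters by weighted mass (descending, genomic-order tie-break),
    add cumulative piRNA fraction, and return (table, N90) where N90 is the
    smallest number of top clusters holding >= 90% of cluster-derived mass."""
    if clusters.empty:
        df = clusters.copy()
        df["rank"] = pd.Series(dtype=int)
        df["cum_fraction"] = pd.Series(dtype=float)
        return df, 0
    df = clusters.sort_values(
        ["weighted_mass", "chrom", "start"], ascending=[False, True, True],
        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    total = df["weighted_mass"].sum()
    df["cum_fraction"] = df["weighted_mass"].cumsum() / total
    n90 = int(np.searchsorted(df["cum_fraction"].to_numpy(), 0.9 - 1e-12) + 1)
    return df, n90


def coverage_stats(clusters: pd.DataFrame, genome_length: int,
                   total_mass: float) -> tuple[float, float]:
    """(fraction of genome covered by clusters, fraction of piRNA mass inside
    clusters). Clusters are non-overlapping by construction."""
    if clusters.empty:
        return 0.0, 0.0
    covered = float((clusters["end"] - clusters["start"]).sum())
    assigned = float(clusters["weighted_mass"].sum())
    return covered / genome_length, (assigned / total_mass if total_mass else 0.0)


def overlap_between_samples(a: pd.DataFrame, b: pd.DataFrame,
                            min_fraction: float = 0.0) -> dict[str, int]:
    """Cluster overlap between two samples.

    A cluster is `shared` when it overlaps a cluster of the other sample by
    >= 1 bp and, when min_fraction > 0, reciprocally by that fraction of
    each cluster's length.
    """
    def overlaps(x, other):
        n = 0
        for r in x.itertuples():
            sub = other[other["chrom"] == r.chrom]
            ov = np.minimum(sub["end"], r.end) - np.maximum(sub["start"], r.start)
            lens_other = (sub["end"] - sub["start"]).to_numpy()
            ok = (ov.to_numpy() > 0)
            if min_fraction > 0:
                ok &= (ov.to_numpy() >= min_fraction * (r.end - r.start))
                ok &= (ov.to_numpy() >= min_fraction * lens_other)
            n += bool(ok.any())
        return n
    a_shared = overlaps(a, b)
    b_shared = overlaps(b, a)
    return {"a_only": len(a) - a_shared, "b_only": len(b) - b_shared,
            "a_shared": a_shared, "b_shared": b_shared}


def write_bed(clusters: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in clusters.itertuples():
            strand = {"uni+": "+", "uni-": "-"}.get(r.strandedness, ".")
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strandedness}\t"
                     f"{round(r.weighted_mass)}\t{strand}\n")
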