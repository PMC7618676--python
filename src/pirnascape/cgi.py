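"""CpG island detection (Gardiner-Garden & Frommer criteria) and annotation.

A CpG island is a region with G+C content >= 50%, length >= 200 bp,
observed/expected CpG ratio >= 0.6 and a CpG-count significance
P <= 1e-5. The scan slides a min_len window at step 1, merges qualifying
windows, trims each merged region to its outermost CpG dinucleotides and
re-tests the trimmed region against every threshold. The P value is the
one-sided binomial tail P(X >= N_CpG) with X ~ Binomial(L-1, f_C * f_G)
under independence of C and G at the region's own base frequencies.

N positions are excluded from all counts and from the effective length;
no island may span a run of >= max_n_run Ns (default 10).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .smallrna import _build_trees
from .te_annotation import RepeatRecord

log = logging.getLogger(__name__)

CGI_COLUMNS = ["chrom", "start", "end", "length", "gc_fraction", "obs_exp",
               "p_value"]


def obs_exp_cpg(sequence: str) -> float:
    """Observed/expected CpG ratio: (N_CpG * L) / (N_C * N_G).

    Defined as 0 when the sequence contains no C or no G. N positions are
    excluded from the counts and from L; a CpG interrupted by an N is not
    counted.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode(), dtype="S1")
    n_n = int((arr == b"N").sum())
    L = arr.size - n_n
    n_c = int((arr == b"C").sum())
    n_g = int((arr == b"G").sum())
    if n_c == 0 or n_g == 0 or L == 0:
        return 0.0
    n_cpg = int(((arr[:-1] == b"C") & (arr[1:] == b"G")).sum())
    return n_cpg * L / (n_c * n_g)


def _region_stats(arr: np.ndarray) -> tuple[int, int, int, int, int]:
    n_n = int((arr == b"N").sum())
    leff = arr.size - n_n
    n_c = int((arr == b"C").sum())
    n_g = int((arr == b"G").sum())
    n_cpg = int(((arr[:-1] == b"C") & (arr[1:] == b"G")).sum())
    return leff, n_c, n_g, n_cpg, n_n


def cgi_pvalue(leff: int, n_c: int, n_g: int, n_cpg: int) -> float:
    if leff < 2 or n_c == 0 or n_g == 0:
        return 1.0
    p = (n_c / leff) * (n_g / leff)
    return float(stats.binom.sf(n_cpg - 1, leff - 1, p))


def _qualifying_region(arr: np.ndarray, min_gc: float, min_len: int,
                       min_oe: float, max_p: float) -> dict | None:
    leff, n_c, n_g, n_cpg, _ = _region_stats(arr)
    if arr.size < min_len or leff == 0 or n_c == 0 or n_g == 0:
        return None
    gc = (n_c + n_g) / leff
    oe = n_cpg * leff / (n_c * n_g)
    p = cgi_pvalue(leff, n_c, n_g, n_cpg)
    if gc >= min_gc and oe >= min_oe and p <= max_p:
        return {"gc_fraction": gc, "obs_exp": oe, "p_value": p}
    return None


def find_cgis(genome: Mapping[str, str], min_gc: float = 0.5, min_len: int = 200,
              min_oe: float = 0.6, max_p: float = 1e-5,
              max_n_run: int = 10) -> pd.DataFrame:
    """Scan the genome for CpG islands (see module docstring for algorithm)."""
    rows = []
    for chrom in genome:
        seq = genome[chrom].upper()
        if len(seq) < min_len:
            log.info("find_cgis: contig %s shorter than %d bp, skipped",
                     chrom, min_len)
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1")
        # split at long N runs so no island spans them
        is_n = (arr == b"N").astype(np.int8)
        segments = _segments_without_long_n(is_n, max_n_run, arr.size)
        for seg_s, seg_e in segments:
            rows.extend(_scan_segment(chrom, arr, seg_s, seg_e, min_gc,
                                      min_len, min_oe, max_p))
    return pd.DataFrame(rows, columns=CGI_COLUMNS)


def _segments_without_long_n(is_n: np.ndarray, max_n_run: int, size: int):
    if not is_n.any():
        return [(0, size)]
    # run-length positions of N runs >= max_n_run
    diff = np.diff(np.concatenate([[0], is_n, [0]]))
    run_starts = np.where(diff == 1)[0]
    run_ends = np.where(diff == -1)[0]
    segments, prev = [], 0
    for s, e in zip(run_starts, run_ends):
        if e - s >= max_n_run:
            if s > prev:
                segments.append((prev, s))
            prev = e
    if prev < size:
        segments.append((prev, size))
    return segments


def _scan_segment(chrom: str, arr: np.ndarray, seg_s: int, seg_e: int,
                  min_gc: float, min_len: int, min_oe: float,
                  max_p: float) -> list[dict]:
    seg = arr[seg_s:seg_e]
    L = seg.size
    if L < min_len:
        return []
    is_c = (seg == b"C").astype(np.int64)
    is_g = (seg == b"G").astype(np.int64)
    is_n = (seg == b"N").astype(np.int64)
    cpg = np.zeros(L, dtype=np.int64)
    cpg[:-1] = (seg[:-1] == b"C") & (seg[1:] == b"G")

    def wsum(x):
        c = np.concatenate([[0], np.cumsum(x)])
        return c[min_len:] - c[:-min_len]

    nc, ng, nn, ncpg = wsum(is_c), wsum(is_g), wsum(is_n), wsum(cpg)
    # CpGs straddling the window end belong to the window only if the G fits
    tail = np.zeros(nc.size, dtype=np.int64)
    tail = cpg[min_len - 1:min_len - 1 + nc.size]
    ncpg = ncpg - tail
    leff = min_len - nn
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(leff > 0, (nc + ng) / np.maximum(leff, 1), 0.0)
        oe = np.where((nc > 0) & (ng > 0),
                      ncpg * leff / np.maximum(nc * ng, 1), 0.0)
    passing = np.where((gc >= min_gc) & (oe >= min_oe))[0]
    if passing.size == 0:
        return []
    # merge windows that overlap (next start strictly inside previous window)
    regions = []
    rs = passing[0]
    prev = passing[0]
    for p in passing[1:]:
        if p < prev + min_len:
            prev = p
        else:
            regions.append((rs, prev + min_len))
            rs = prev = p
    regions.append((rs, prev + min_len))

    cpg_pos = np.where(cpg == 1)[0]
    out = []
    for rs, re in regions:
        # trim to outermost CpG dinucleotides
        inside = cpg_pos[(cpg_pos >= rs) & (cpg_pos + 2 <= re)]
        if inside.size == 0:
            continue
        ts, te = int(inside[0]), int(inside[-1] + 2)
        q = _qualifying_region(seg[ts:te], min_gc, min_len, min_oe, max_p)
        if q is None:
            continue
        out.append({"chrom": chrom, "start": seg_s + ts, "end": seg_s + te,
                    "length": te - ts, **q})
    return out


def annotate_cgis(cgis: pd.DataFrame, te_records: Sequence[RepeatRecord],
                  genes: pd.DataFrame, active: np.ndarray | None = None,
                  tss_flank: int = 100,
                  precedence: tuple[str, ...] = ("te", "tss", "genic"),
                  ) -> tuple[pd.DataFrame, pd.Series, dict[str, float]]:
    """Categorize each CGI as TE / TSS / genic / intergenic (by precedence,
    >=1 bp overlap) and report what fraction of transposon copies (all and
    potentially-active only) are overlapped by a CGI.

    Returns (annotated CGIs, category counts, te-side overlap fractions).
    """
    te_trees = _build_trees((r.chrom, r.start, r.end, i)
                            for i, r in enumerate(te_records)
                            if r.te_class != "Simple")
    tss_iv = []
    for g in genes.itertuples():
        tss = g.start if g.strand == "+" else g.end - 1
        tss_iv.append((g.chrom, max(0, tss - tss_flank), tss + tss_flank + 1, "tss"))
    tss_trees = _build_trees(tss_iv)
    gene_trees = _build_trees((g.chrom, g.start, g.end, "gene")
                              for g in genes.itertuples())

    cats = []
    for r in cgis.itertuples():
        cat = "intergenic"
        for kind in precedence:
            trees = {"te": te_trees, "tss": tss_trees, "genic": gene_trees}[kind]
            t = trees.get(r.chrom)
            if t and t.overlap(r.start, r.end):
                cat = {"genic": "genic"}.get(kind, kind)
                break
        cats.append(cat)
    annotated = cgis.copy()
    annotated["category"] = cats
    counts = annotated["category"].value_counts().reindex(
        ["te", "tss", "genic", "intergenic"], fill_value=0)

    cgi_trees = _build_trees((r.chrom, r.start, r.end, i)
                             for i, r in enumerate(cgis.itertuples()))
    te_list = [r for r in te_records if r.te_class != "Simple"]
    hit = np.array([bool(cgi_trees.get(r.chrom)
                         and cgi_trees[r.chrom].overlap(r.start, r.end))
                    for r in te_list]) if te_list else np.array([], dtype=bool)
    fractions = {"all": float(hit.mean()) if hit.size else 0.0}
    if active is not None and te_list:
        act = np.asarray([a for a, r in zip(active, te_records)
                          if r.te_class != "Simple"], dtype=bool)
        fractions["active"] = float(hit[act].mean()) if act.any() else 0.0
    return annotated, counts, fractions


def shuffle_regions(cgis: pd.DataFrame, chrom_sizes: Mapping[str, int],
                    rng: np.random.Generator, max_tries: int = 200) -> pd.DataFrame:
    """Length- and chromosome-preserving uniform placement, non-overlapping
    within the shuffle."""
    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for r in cgis.itertuples():
        length = r.end - r.start
        hi = chrom_sizes[r.chrom] - length
        if hi <= 0:
            raise ValueError("genome too small to place shuffled region")
        for attempt in range(max_tries):
            s = int(rng.integers(0, hi))
            if all(e <= s or b >= s + length for b, e in occupied[r.chrom]):
                occupied[r.chrom].append((s, s + length))
                rows.append({"chrom": r.chrom, "start": s, "end": s + length})
                break
        else:
            raise ValueError("genome too small to place shuffles without overlap")
    return pd.DataFrame(rows)


def shuffle_enrichment(cgis: pd.DataFrame, te_records: Sequence[RepeatRecord],
                       genes: pd.DataFrame, chrom_sizes: Mapping[str, int],
                       n_shuffles: int = 20, seed: int = 0,
                       ) -> tuple[float, float, pd.DataFrame]:
    """Chi-square enrichment of CGI genomic categories against shuffled
    regions: a 2 x k contingency of category counts (observed vs pooled
    shuffles), Pearson statistic without continuity correction."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    _, obs, _ = annotate_cgis(cgis, te_records, genes)
    pooled = obs * 0
    for _ in range(n_shuffles):
        shuf = shuffle_regions(cgis, chrom_sizes, rng)
        _, counts, _ = annotate_cgis(shuf, te_records, genes)
        pooled = pooled + counts
    table = pd.DataFrame({"observed": obs, "shuffled": pooled}).T
    table = table.loc[:, (table.sum(axis=0) > 0)]
    stat, p = chi_square(table.to_numpy())
    return stat, p, table


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction.
    A table that matches its expected counts exactly gives (0, 1)."""
    table = np.asarray(table, dtype=float)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def write_cgi_bed(cgis: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(cgis.itertuples()):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tCGI{i}\t0\t+\n")
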