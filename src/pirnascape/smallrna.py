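"""piRNA selection, collapsing, mapping and genomic classification.

piRNAs are small RNAs of at least 23 nt (shorter reads are miRNA/siRNA
sized and dropped). Multimapping reads contribute fractionally: a read with
n reported alignment sites adds 1/n of its collapsed count at each site, so
total weighted mass is conserved.

The built-in toy mapper reports every genomic site with at most
``max_mismatch`` mismatches that contains an exact matched stretch of at
least ``min_match`` bases (seed-and-verify over an exact k-mer index); reads
with more than ``max_sites`` sites are discarded. Production alignments come
in as SAM/BAM via :func:`ingest_sam`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._seq import KmerIndex, encode, kmer_codes, revcomp
from .te_annotation import RepeatRecord

log = logging.getLogger(__name__)

ALN_COLUMNS = ["read_id", "seq", "chrom", "start", "end", "strand",
               "n_hits", "count", "weight"]


@dataclass(frozen=True)
class CollapsedRead:
    sequence: str
    count: int

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")


def read_fastq(path) -> list[str]:
    from Bio import SeqIO
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def select_pirnas(reads: Iterable, min_len: int = 23,
                  max_len: int | None = None) -> list:
    """Keep piRNA-sized reads: length >= min_len (and <= max_len when set)."""
    def _len(r):
        return len(r.sequence) if isinstance(r, CollapsedRead) else len(r)
    return [r for r in reads
            if _len(r) >= min_len and (max_len is None or _len(r) <= max_len)]


def collapse(reads: Iterable[str]) -> list[CollapsedRead]:
    """Exact-sequence deduplication; counts conserve the input total."""
    counts = Counter(reads)
    return [CollapsedRead(seq, n) for seq, n in counts.items()]


def _max_run_fraction(seq: str) -> float:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best / len(seq)


def _max_dinuc_fraction(seq: str) -> float:
    if len(seq) < 4:
        return 0.0
    best = run = 2
    for i in range(2, len(seq)):
        run = run + 1 if seq[i] == seq[i - 2] else 2
        best = max(best, run)
    return best / len(seq)


def dust_filter(reads: Sequence[CollapsedRead],
                threshold: float = 0.75) -> list[CollapsedRead]:
    """Drop low-complexity reads: those whose longest mononucleotide run or
    longest period-2 (dinucleotide) repeat exceeds `threshold` of the read."""
    return [r for r in reads
            if _max_run_fraction(r.sequence) <= threshold
            and _max_dinuc_fraction(r.sequence) <= threshold]


def _longest_exact_run(read_codes: np.ndarray, ref_codes: np.ndarray) -> int:
    mism = np.where(read_codes != ref_codes)[0]
    edges = np.concatenate([[-1], mism, [read_codes.size]])
    return int(np.diff(edges).max() - 1)


def toy_map(reads: Sequence[CollapsedRead], genome: Mapping[str, str],
            max_mismatch: int = 3, min_match: int = 15,
            max_sites: int = 1000) -> pd.DataFrame:
    """Map collapsed reads to all qualifying genomic sites with 1/n weights.

    A site qualifies when the full-length alignment has <= max_mismatch
    mismatches and contains an exact matched stretch >= min_match. Reads
    shorter than min_match can never qualify. Returns an alignment table
    (ALN_COLUMNS); weight = count / n_hits per site.
    """
    index = KmerIndex(genome, min_match)
    chrom_names = index.chroms
    chrom_codes = {c: encode(genome[c]) for c in chrom_names}
    rows = []
    for ri, read in enumerate(reads):
        seq = read.sequence.upper().replace("U", "T")
        L = len(seq)
        if L < min_match:
            continue
        sites: set[tuple[str, int, str]] = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            codes = encode(s)
            kmers = kmer_codes(codes, min_match)
            valid = np.where(kmers >= 0)[0]
            if valid.size == 0:
                continue
            qidx, gpos = index.lookup_many(kmers[valid])
            if gpos.size == 0:
                continue
            starts = gpos - valid[qidx]
            for gs in np.unique(starts):
                ci, local = index.to_chrom(np.array([gs]))
                chrom = chrom_names[int(ci[0])]
                st = int(local[0])
                if st < 0 or st + L > len(genome[chrom]):
                    continue
                ref = chrom_codes[chrom][st:st + L]
                mism = int((ref != codes).sum())
                if mism > max_mismatch:
                    continue
                if mism > 0 and _longest_exact_run(codes, ref) < min_match:
                    continue
                sites.add((chrom, st, strand))
        n = len(sites)
        if n == 0 or n > max_sites:
            continue
        w = read.count / n
        for chrom, st, strand in sorted(sites):
            rows.append((f"r{ri}", read.sequence, chrom, st, st + L, strand,
                         n, read.count, w))
    return pd.DataFrame(rows, columns=ALN_COLUMNS)


def ingest_sam(path, counts: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Load pre-mapped alignments from SAM/BAM; n from the NH tag when
    present, otherwise the number of records sharing the read id."""
    import pysam
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            seq = aln.get_forward_sequence() or aln.query_sequence or ""
            rows.append((aln.query_name, seq, aln.reference_name,
                         aln.reference_start, aln.reference_end,
                         "-" if aln.is_reverse else "+",
                         aln.get_tag("NH") if aln.has_tag("NH") else None))
    df = pd.DataFrame(rows, columns=["read_id", "seq", "chrom", "start", "end",
                                     "strand", "n_hits"])
    per_read = df.groupby("read_id")["read_id"].transform("size")
    df["n_hits"] = df["n_hits"].fillna(per_read).astype(int)
    df["count"] = df["read_id"].map(counts).fillna(1).astype(int) if counts \
        else 1
    df["weight"] = df["count"] / df["n_hits"]
    return df[ALN_COLUMNS]


@dataclass
class OriginBreakdown:
    """Weighted mass and normalized proportions per genomic origin category."""
    masses: dict[str, float]

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.masses.values())
        if total == 0:
            return {k: 0.0 for k in self.masses}
        return {k: v / total for k, v in self.masses.items()}

    @property
    def te_proportion(self) -> float:
        return sum(p for k, p in self.proportions.items()
                   if k not in ("exon", "intron", "non-coding"))


def _build_trees(intervals: Iterable[tuple[str, int, int, str]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e, label in intervals:
        if e > s:
            trees.setdefault(chrom, IntervalTree()).addi(s, e, label)
    return trees


def classify_origin(alignments: pd.DataFrame,
                    te_records: Sequence[RepeatRecord],
                    genes: pd.DataFrame,
                    exons: pd.DataFrame,
                    precedence: tuple[str, ...] = ("te", "exon", "intron")) -> OriginBreakdown:
    """Assign each alignment's weight to TE class / exon / intron / non-coding.

    Default precedence is TE first (a TE inside an intron counts as TE),
    then exon, then intron (inside a gene but no exon overlap); anything
    overlapping no feature is non-coding.
    """
    te_trees = _build_trees((r.chrom, r.start, r.end, r.te_class)
                            for r in te_records if r.te_class != "Simple")
    exon_trees = _build_trees((e.chrom, e.start, e.end, "exon")
                              for e in exons.itertuples())
    gene_trees = _build_trees((g.chrom, g.start, g.end, "gene")
                              for g in genes.itertuples())
    masses: dict[str, float] = {"exon": 0.0, "intron": 0.0, "non-coding": 0.0}

    def lookup(trees, chrom, s, e):
        t = trees.get(chrom)
        return t.overlap(s, e) if t else ()

    for a in alignments.itertuples():
        category = None
        for kind in precedence:
            if kind == "te":
                hits = lookup(te_trees, a.chrom, a.start, a.end)
                if hits:
                    category = sorted(h.data for h in hits)[0]
                    break
            elif kind == "exon":
                if lookup(exon_trees, a.chrom, a.start, a.end):
                    category = "exon"
                    break
            elif kind == "intron":
                if lookup(gene_trees, a.chrom, a.start, a.end):
                    category = "intron"
                    break
        masses[category or "non-coding"] = masses.get(category or "non-coding", 0.0) \
            + a.weight
    return OriginBreakdown(masses=masses)


def length_histogram(reads: Sequence[CollapsedRead]) -> tuple[pd.Series, float]:
    """Count-weighted relative length frequencies and the weighted median."""
    if not reads:
        raise ValueError("length_histogram: empty read set")
    counts: Counter[int] = Counter()
    for r in reads:
        counts[len(r.sequence)] += r.count
    freq = pd.Series(counts, dtype=float).sort_index()
    freq /= freq.sum()
    cum = freq.cumsum()
    median = float(cum.index[np.searchsorted(cum.values, 0.5)])
    return freq, median


def bin_signal(alignments: pd.DataFrame, chrom_sizes: Mapping[str, int],
               bin_size: int = 1_000_000) -> pd.DataFrame:
    """Per-bin weighted mass normalized to RPM and log2(RPM+1).

    Alignments are assigned to bins by their start coordinate; RPM uses the
    total weighted mapped mass so unlogged RPM sums to 1e6.
    """
    total = alignments["weight"].sum()
    rows = []
    for chrom, size in chrom_sizes.items():
        sub = alignments[alignments["chrom"] == chrom]
        n_bins = max(1, -(-size // bin_size))
        mass = np.zeros(n_bins)
        if not sub.empty:
            np.add.at(mass, np.minimum(sub["start"].to_numpy() // bin_size,
                                       n_bins - 1), sub["weight"].to_numpy())
        for b in range(n_bins):
            rpm = mass[b] * 1e6 / total if total > 0 else 0.0
            rows.append({"chrom": chrom, "start": b * bin_size,
                         "end": min((b + 1) * bin_size, size),
                         "mass": mass[b], "rpm": rpm,
                         "log2_rpm": float(np.log2(rpm + 1))})
    return pd.DataFrame(rows)
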