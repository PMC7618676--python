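"""Transposon annotation: RepeatMasker ``.out`` parsing, potentially-active
copy calling, and family/class composition statistics.

A transposon copy is called *potentially active* when it is both young
(percent divergence from the family consensus strictly below ``max_div``,
default 5%) and close to full length (copy length at least
``min_length_fraction`` of the consensus length, default 0.90, with optional
per-family absolute overrides). Simple/low-complexity repeats are never
activity-called and are excluded from transposon composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TE_CLASSES = ("LTR", "LINE", "SINE", "DNA", "RC", "DIRS", "PLE", "Unknown", "Simple")

_CLASS_ALIASES = {
    "Simple_repeat": "Simple",
    "Low_complexity": "Simple",
    "Satellite": "Simple",
    "Helitron": "RC",
}


def normalize_class(raw: str) -> str:
    head = raw.split("/")[0].split("-")[0]
    head = _CLASS_ALIASES.get(raw, _CLASS_ALIASES.get(head, head))
    return head if head in TE_CLASSES else "Unknown"


@dataclass(frozen=True)
class RepeatRecord:
    """One transposon copy interval (0-based half-open genome coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    te_class: str
    perc_div: float
    consensus_begin: int  # 1-based on consensus
    consensus_end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if not 0.0 <= self.perc_div <= 100.0:
            raise ValueError(f"perc_div {self.perc_div} outside [0,100]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConsensusEntry:
    family: str
    te_class: str
    full_length: int

    def __post_init__(self):
        if self.full_length <= 0:
            raise ValueError("consensus full_length must be positive")


@dataclass
class ActiveCallConfig:
    max_div: float = 5.0
    min_length_fraction: float = 0.90
    length_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.max_div <= 0:
            raise ValueError("max_div must be > 0")
        if not 0 < self.min_length_fraction <= 1:
            raise ValueError("min_length_fraction must be in (0,1]")


class RepeatMaskerParseError(ValueError):
    pass


def parse_repeatmasker_out(path) -> list[RepeatRecord]:
    """Parse a RepeatMasker ``.out`` file into RepeatRecords.

    Coordinates are converted from the format's 1-based inclusive convention
    to 0-based half-open; 'C' (complement) strands map to '−'... returned as
    '-'. Header lines (anything not starting with a numeric SW score) are
    skipped.
    """
    records: list[RepeatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or not fields[0].replace(".", "").isdigit():
                continue  # header / blank
            if len(fields) < 14:
                raise RepeatMaskerParseError(
                    f"line {lineno}: expected >=14 columns, got {len(fields)}"
                )
            try:
                perc_div = float(fields[1])
                q_begin = int(fields[5])
                q_end = int(fields[6])
            except ValueError as exc:
                raise RepeatMaskerParseError(f"line {lineno}: {exc}") from exc
            strand = "-" if fields[8] in ("C", "-") else "+"
            name, classfam = fields[9], fields[10]
            te_class = normalize_class(classfam)
            family = classfam.split("/", 1)[1] if "/" in classfam else name
            if strand == "+":
                c_begin, c_end = int(fields[11]), int(fields[12])
            else:  # complement rows store (left) end begin
                c_begin, c_end = int(fields[13]), int(fields[12])
            records.append(
                RepeatRecord(
                    chrom=fields[4],
                    start=q_begin - 1,
                    end=q_end,
                    strand=strand,
                    family=family,
                    te_class=te_class,
                    perc_div=perc_div,
                    consensus_begin=c_begin,
                    consensus_end=c_end,
                )
            )
    return records


def write_repeatmasker_out(records: Iterable[RepeatRecord], chrom_sizes: Mapping[str, int],
                           consensus_lengths: Mapping[str, int], path) -> None:
    """Write records in the 15-column space-aligned ``.out`` dialect."""
    header = (
        "   SW  perc perc perc  query     position in query          matching"
        "    repeat           position in repeat\n"
        "score  div. del. ins.  sequence  begin  end        (left)   repeat"
        "    class/family     begin  end  (left)   ID\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, r in enumerate(records, start=1):
            left = chrom_sizes[r.chrom] - r.end
            clen = consensus_lengths.get(r.family, r.consensus_end)
            cleft = clen - r.consensus_end
            if r.strand == "+":
                rep = f"{r.consensus_begin} {r.consensus_end} ({cleft})"
                strand = "+"
            else:
                rep = f"({cleft}) {r.consensus_end} {r.consensus_begin}"
                strand = "C"
            fh.write(
                f"{1000} {r.perc_div:.1f} 0.0 0.0 {r.chrom} {r.start + 1} {r.end} "
                f"({left}) {strand} {r.family} {r.te_class}/{r.family} {rep} {i}\n"
            )


def read_consensus_meta(path) -> dict[str, ConsensusEntry]:
    """Read family<TAB>class<TAB>full_length metadata."""
    df = pd.read_csv(path, sep="\t")
    return {
        row.family: ConsensusEntry(row.family, row.te_class, int(row.full_length))
        for row in df.itertuples()
    }


def call_active(records: Sequence[RepeatRecord],
                consensus: Mapping[str, ConsensusEntry],
                cfg: ActiveCallConfig | None = None) -> np.ndarray:
    """Per-record boolean potentially-active flags.

    Divergence boundary is strict (< max_div); length boundary inclusive.
    Records whose family has no consensus entry are flagged False and logged.
    """
    cfg = cfg or ActiveCallConfig()
    flags = np.zeros(len(records), dtype=bool)
    missing: set[str] = set()
    for i, r in enumerate(records):
        if r.te_class == "Simple":
            continue
        entry = consensus.get(r.family)
        if entry is None:
            missing.add(r.family)
            continue
        min_len = cfg.length_overrides.get(
            r.family, cfg.min_length_fraction * entry.full_length
        )
        flags[i] = r.length >= min_len and r.perc_div < cfg.max_div
    if missing:
        log.warning("no consensus entry for %d families: %s",
                    len(missing), sorted(missing)[:5])
    return flags


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def family_stats(records: Sequence[RepeatRecord], active: np.ndarray,
                 genome_length: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family copy/activity table and per-class genomic composition.

    Genome fractions use the union of copy intervals so overlapping records
    are counted once. Simple repeats are dropped from both tables.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    fam_rows: dict[str, dict] = {}
    fam_iv: dict[str, dict[str, list]] = {}
    cls_iv: dict[str, dict[str, list]] = {}
    for r, a in zip(records, active):
        if r.te_class == "Simple":
            continue
        row = fam_rows.setdefault(
            r.family, {"family": r.family, "te_class": r.te_class,
                       "total_copies": 0, "active_copies": 0}
        )
        row["total_copies"] += 1
        row["active_copies"] += bool(a)
        fam_iv.setdefault(r.family, {}).setdefault(r.chrom, []).append((r.start, r.end))
        cls_iv.setdefault(r.te_class, {}).setdefault(r.chrom, []).append((r.start, r.end))
    for fam, row in fam_rows.items():
        bp = sum(_union_length(iv) for iv in fam_iv[fam].values())
        row["genome_fraction"] = bp / genome_length
        row["active_pct"] = 100.0 * row["active_copies"] / row["total_copies"]
    fam_df = pd.DataFrame(fam_rows.values()).sort_values("family").reset_index(drop=True) \
        if fam_rows else pd.DataFrame(
            columns=["family", "te_class", "total_copies", "active_copies",
                     "genome_fraction", "active_pct"])
    cls_rows = [
        {"te_class": c,
         "genome_fraction": sum(_union_length(iv) for iv in ivs.values()) / genome_length}
        for c, ivs in sorted(cls_iv.items())
    ]
    cls_df = pd.DataFrame(cls_rows) if cls_rows else pd.DataFrame(
        columns=["te_class", "genome_fraction"])
    return fam_df, cls_df


def divergence_length_scatter(records: Sequence[RepeatRecord],
                              consensus: Mapping[str, ConsensusEntry]) -> pd.DataFrame:
    """(perc_div, length_fraction) per copy, for divergence-vs-length plots."""
    rows = []
    for r in records:
        entry = consensus.get(r.family)
        if entry is None:
            continue
        rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                     "family": r.family, "te_class": r.te_class,
                     "perc_div": r.perc_div,
                     "length_fraction": r.length / entry.full_length})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family", "te_class",
                                       "perc_div", "length_fraction"])


def write_active_bed(records: Sequence[RepeatRecord], active: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for r, a in zip(records, active):
            if a:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t"
                         f"{round(r.perc_div * 10)}\t{r.strand}\n")
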