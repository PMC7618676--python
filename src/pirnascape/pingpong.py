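"""Ping-pong amplification signatures.

The ping-pong cycle leaves two sequence fingerprints: complementary piRNA
pairs whose 5' ends overlap by exactly 10 nt, and a 1U/10A nucleotide bias
(uridine at position 1 of primary piRNAs, adenine at position 10 of
secondary piRNAs). This module computes the 5'-overlap distance histogram
between opposite-strand alignment pairs and the weighted base composition
at read positions 1 and 10, globally and per transposon family/class.

Distance convention: for a plus-strand alignment with 5' end at s and a
minus-strand alignment with 5' end at genomic position e-1 (half-open
coordinates), d = (e-1) - s + 1, i.e. the number of overlapping 5' bases;
d = 10 is the ping-pong signal. Pair contributions are products of the two
alignment weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .smallrna import _build_trees
from .te_annotation import RepeatRecord

log = logging.getLogger(__name__)

BASES = ("A", "U", "C", "G")


@dataclass
class PingPongProfile:
    overlap_freq: pd.Series             # index d=1..d_max, sums to 1 when pairs exist
    pair_mass: float
    pos_composition: pd.DataFrame | None = None  # rows A/U/C/G, cols pos1/pos10
    low_confidence: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return self.pair_mass == 0


def overlap_distances(alignments: pd.DataFrame, d_max: int = 30) -> PingPongProfile:
    """5'-overlap distance histogram between + and - alignments.

    Only pair distances 1..d_max are counted; frequencies are normalized to
    sum to 1. An input with no opposite-strand pairs yields an all-zero,
    `empty` profile rather than an error.
    """
    freq = np.zeros(d_max)
    for _, sub in alignments.groupby("chrom", sort=False):
        plus = sub[sub["strand"] == "+"]
        minus = sub[sub["strand"] == "-"]
        if plus.empty or minus.empty:
            continue
        w_plus = plus.groupby("start")["weight"].sum()
        w_minus = minus.groupby(minus["end"] - 1)["weight"].sum()
        for d in range(1, d_max + 1):
            # minus 5' sits at plus 5' + d - 1
            shifted = w_minus.reindex(w_plus.index + d - 1).to_numpy()
            freq[d - 1] += np.nansum(w_plus.to_numpy() * shifted)
    total = freq.sum()
    series = pd.Series(freq / total if total > 0 else freq,
                       index=pd.RangeIndex(1, d_max + 1, name="distance"))
    if total == 0:
        log.info("overlap_distances: no opposite-strand pairs")
    return PingPongProfile(overlap_freq=series, pair_mass=float(total))


def positional_composition(alignments: pd.DataFrame) -> pd.DataFrame:
    """Weighted A/U/C/G proportions at read positions 1 and 10 (5'->3',
    read orientation). Reads shorter than 10 nt are excluded (logged)."""
    seqs = alignments["seq"].str.upper().str.replace("T", "U")
    ok = seqs.str.len() >= 10
    n_short = int((~ok).sum())
    if n_short:
        log.info("positional_composition: excluded %d reads shorter than 10 nt",
                 n_short)
    seqs, w = seqs[ok], alignments.loc[ok, "weight"]
    out = pd.DataFrame(0.0, index=list(BASES), columns=["pos1", "pos10"])
    for col, pos in (("pos1", 0), ("pos10", 9)):
        mass = w.groupby(seqs.str[pos]).sum()
        for b in BASES:
            out.loc[b, col] = mass.get(b, 0.0)
        tot = out[col].sum()
        if tot > 0:
            out[col] /= tot
    return out


def restrict_to_te(alignments: pd.DataFrame,
                   te_records: Sequence[RepeatRecord]) -> pd.DataFrame:
    """Alignments overlapping >=1 bp of a transposon copy, annotated with the
    family and class of the (first) overlapped copy."""
    trees = _build_trees((r.chrom, r.start, r.end, (r.family, r.te_class))
                         for r in te_records if r.te_class != "Simple")
    fams, classes, keep = [], [], []
    for a in alignments.itertuples():
        t = trees.get(a.chrom)
        hits = sorted(h.data for h in t.overlap(a.start, a.end)) if t else []
        keep.append(bool(hits))
        if hits:
            fams.append(hits[0][0])
            classes.append(hits[0][1])
    out = alignments[np.array(keep, dtype=bool)].copy() if len(keep) else alignments.copy()
    out["family"] = fams
    out["te_class"] = classes
    return out


def pingpong_profile(alignments: pd.DataFrame, d_max: int = 30,
                     min_pairs: float = 50.0) -> PingPongProfile:
    prof = overlap_distances(alignments, d_max=d_max)
    prof.pos_composition = positional_composition(alignments)
    prof.low_confidence = prof.pair_mass < min_pairs
    return prof


def per_family_profiles(te_alignments: pd.DataFrame, d_max: int = 30,
                        min_pairs: float = 50.0,
                        by: str = "family") -> dict[str, PingPongProfile]:
    """Profiles grouped by TE family (or class); groups with pair mass below
    `min_pairs` are flagged low-confidence."""
    return {key: pingpong_profile(sub, d_max=d_max, min_pairs=min_pairs)
            for key, sub in te_alignments.groupby(by, sort=True)}
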