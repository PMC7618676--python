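"""Seeded synthetic data generator with ground truth.

Emulates the inputs of a germline small-RNA + sperm-methylome study: a toy
genome carrying planted transposon copies of controlled divergence and 5'
truncation, planted CpG islands and gene models, small-RNA reads with a
piRNA-like length law (median 29 nt), ping-pong partner pairs (5' ends
overlapping by exactly 10 nt) with 1U/10A biases, uni-/dual-strand piRNA
cluster loci, and binomially sampled per-CpG methylation calls with
unmethylated-lambda / methylated-pUC19 spike-ins.

Every emitted read and CpG has exactly one truth row; identical configs give
byte-identical outputs. Coordinates are 0-based half-open internally; file
writers use each format's native convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp
from .te_annotation import (ActiveCallConfig, ConsensusEntry, RepeatRecord,
                            write_repeatmasker_out)


class SimulationError(RuntimeError):
    pass


def triangular_length_law(lo: int = 23, hi: int = 33, peak: int = 29,
                          width: int = 7) -> dict[int, float]:
    """Truncated triangular distribution over read lengths.

    Weight = width - |l - peak|, clipped at the range ends; the default has
    both its mode and its median at 29 nt.
    """
    lengths = np.arange(lo, hi + 1)
    w = np.maximum(0, width - np.abs(lengths - peak)).astype(float)
    w /= w.sum()
    return {int(l): p for l, p in zip(lengths, w) if p > 0}


@dataclass
class TEPlan:
    family: str
    te_class: str
    consensus_length: int
    n_copies: int
    divergence: float | Sequence[float] = 0.0   # per-base substitution rate
    truncation: float | Sequence[float] = 0.0   # fraction of 5' consensus removed
    strand: str | None = None                   # None = random

    def per_copy(self, attr) -> list[float]:
        v = getattr(self, attr)
        if np.isscalar(v):
            return [float(v)] * self.n_copies
        v = list(v)
        if len(v) != self.n_copies:
            raise ValueError(f"{attr} list length != n_copies for {self.family}")
        return [float(x) for x in v]


@dataclass
class ClusterPlan:
    chrom: str
    start: int
    end: int
    strandedness: str           # uni+ / uni- / dual
    read_mass: int
    plus_fraction: float | None = None  # dual clusters default to 0.5


@dataclass
class GenePlan:
    n_genes: int = 20
    length_range: tuple[int, int] = (3000, 8000)
    exons_per_gene: tuple[int, int] = (2, 3)


@dataclass
class CGIPlan:
    n: int = 8
    length_range: tuple[int, int] = (250, 600)
    cg_density: float = 0.7


@dataclass
class SimConfig:
    seed: int
    genome_length: int = 1_000_000
    n_chroms: int = 1
    gc_fraction: float = 0.40
    te_plan: list[TEPlan] = field(default_factory=list)
    cluster_plan: list[ClusterPlan] = field(default_factory=list)
    gene_plan: GenePlan = field(default_factory=GenePlan)
    cgi_plan: CGIPlan = field(default_factory=lambda: CGIPlan(n=0))
    te_read_mass: int = 0
    background_read_mass: int = 0
    pingpong_fraction: float = 0.3
    u1_bias: float = 0.8
    a10_bias: float = 0.9
    length_law: dict[int, float] = field(default_factory=triangular_length_law)
    meth_plan: dict[str, float] = field(default_factory=lambda: {
        "tss": 0.60, "te_active": 0.96, "te": 0.93, "gene": 0.80, "background": 0.90})
    tss_halfwidth: int = 300
    coverage_mean: float = 10.0
    n_spike_cpgs: int = 2000
    conversion_failure: float = 0.005
    puc19_meth: float = 1.0

    def validate(self) -> None:
        for name in ("gc_fraction", "pingpong_fraction", "u1_bias", "a10_bias",
                     "conversion_failure", "puc19_meth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        for p in self.meth_plan.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("meth_plan values must be in [0,1]")
        if abs(sum(self.length_law.values()) - 1.0) > 1e-9:
            raise ValueError("length_law must sum to 1")
        sizes = self.chrom_sizes()
        for c in self.cluster_plan:
            if c.end <= c.start or c.start < 0 or c.end > sizes.get(c.chrom, -1):
                raise ValueError(f"cluster interval invalid: {c}")
            if c.strandedness not in ("uni+", "uni-", "dual"):
                raise ValueError(f"bad strandedness {c.strandedness}")

    def chrom_sizes(self) -> dict[str, int]:
        base = self.genome_length // self.n_chroms
        sizes = {f"chr{i + 1}": base for i in range(self.n_chroms)}
        sizes[f"chr{self.n_chroms}"] += self.genome_length - base * self.n_chroms
        return sizes


class _Allocator:
    """Non-overlapping interval placement by rejection sampling."""

    def __init__(self, chrom_sizes: Mapping[str, int], rng: np.random.Generator):
        self.sizes = dict(chrom_sizes)
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
        self.rng = rng

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.occupied[chrom].append((start, end))

    def _free(self, chrom: str, start: int, end: int) -> bool:
        return all(e <= start or s >= end for s, e in self.occupied[chrom])

    def place(self, length: int, what: str, pad: int = 20,
              max_tries: int = 2000) -> tuple[str, int]:
        chroms = list(self.sizes)
        weights = np.array([self.sizes[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(max_tries):
            chrom = chroms[self.rng.choice(len(chroms), p=weights)]
            hi = self.sizes[chrom] - length
            if hi <= 0:
                continue
            start = int(self.rng.integers(0, hi))
            if self._free(chrom, start - pad, start + length + pad):
                self.reserve(chrom, start, start + length)
                return chrom, start
        raise SimulationError(f"cannot place {what}: genome capacity exceeded")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random sequence as a byte array (dtype S1)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.frombuffer(b"ACGT", dtype="S1")[rng.choice(4, size=n, p=p)]


def _cpg_rich_seq(rng: np.random.Generator, n: int, cg_density: float) -> np.ndarray:
    parts = []
    total = 0
    bases = np.frombuffer(b"ACGT", dtype="S1")
    while total < n:
        if rng.random() < cg_density:
            parts.append(b"CG")
        else:
            parts.append(bases[rng.integers(0, 4)] + bases[rng.integers(0, 4)])
        total += 2
    return np.frombuffer(b"".join(parts)[:n], dtype="S1").copy()


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """Independent per-base substitution (no indels); returns (seq, n_substituted)."""
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    idx = np.where(mask)[0]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for i in idx:
        choices = bases[bases != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out, int(idx.size)


@dataclass
class Simulation:
    config: SimConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    consensus: dict[str, str]
    consensus_meta: dict[str, ConsensusEntry]
    te_records: list[RepeatRecord]
    te_truth: pd.DataFrame       # planted copies with realized divergence + active flag
    genes: pd.DataFrame          # chrom,start,end,strand,gene_id
    exons: pd.DataFrame          # chrom,start,end,gene_id
    cgis: pd.DataFrame           # planted CpG-rich inserts
    clusters: pd.DataFrame       # planted cluster loci

    def write(self, outdir) -> None:
        import os
        os.makedirs(outdir, exist_ok=True)
        j = lambda name: os.path.join(outdir, name)
        write_fasta(self.genome, j("genome.fa"))
        write_fasta(self.consensus, j("consensus.fa"))
        pd.DataFrame(
            [{"family": e.family, "te_class": e.te_class, "full_length": e.full_length}
             for e in self.consensus_meta.values()]
        ).to_csv(j("consensus.tsv"), sep="\t", index=False)
        write_repeatmasker_out(
            self.te_records, self.chrom_sizes,
            {f: e.full_length for f, e in self.consensus_meta.items()}, j("repeats.out"))
        with open(j("genes.bed"), "w") as fh:
            for g in self.genes.itertuples():
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        write_gff(self.genes, self.exons, j("genes.gff3"))
        for name, df in (("te_truth", self.te_truth), ("clusters_truth", self.clusters),
                         ("cgis_truth", self.cgis)):
            df.to_csv(j(name + ".tsv"), sep="\t", index=False)


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples():
            fh.write(f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            for e in exons[exons.gene_id == g.gene_id].itertuples():
                fh.write(f"{e.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                         f"Parent={g.gene_id}\n")


def simulate_genome(config: SimConfig) -> Simulation:
    """Build the toy genome with planted TEs, genes and CpG islands.

    A planted TE copy is the family consensus, 5'-truncated to
    (1-truncation) of its length, then substituted base-by-base at the
    divergence rate; the emitted percent divergence is the realized
    substitution fraction (1 decimal, RepeatMasker style) and the truth
    `active` flag applies the default activity rule (< 5% divergence,
    length >= 90% of consensus) to those same realized values.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    sizes = config.chrom_sizes()
    genome = {c: _random_seq(rng, n, config.gc_fraction) for c, n in sizes.items()}
    alloc = _Allocator(sizes, rng)
    for cl in config.cluster_plan:
        alloc.reserve(cl.chrom, cl.start, cl.end)

    # planted CpG islands (sequence inserts)
    cgi_rows = []
    for i in range(config.cgi_plan.n):
        lo, hi = config.cgi_plan.length_range
        length = int(rng.integers(lo, hi + 1))
        chrom, start = alloc.place(length, f"CGI {i}")
        seq = _cpg_rich_seq(rng, length, config.cgi_plan.cg_density)
        genome[chrom][start:start + length] = seq
        cgi_rows.append({"chrom": chrom, "start": start, "end": start + length,
                         "cgi_id": f"cgi{i}"})

    # gene models (annotation only; background sequence)
    gene_rows, exon_rows = [], []
    gp = config.gene_plan
    for i in range(gp.n_genes):
        length = int(rng.integers(gp.length_range[0], gp.length_range[1] + 1))
        chrom, start = alloc.place(length, f"gene {i}")
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i}"
        gene_rows.append({"chrom": chrom, "start": start, "end": start + length,
                          "strand": strand, "gene_id": gid})
        n_ex = int(rng.integers(gp.exons_per_gene[0], gp.exons_per_gene[1] + 1))
        cuts = np.sort(rng.choice(np.arange(1, 2 * n_ex), size=2 * n_ex - 1,
                                  replace=False)) * length // (2 * n_ex)
        bounds = np.concatenate([[0], cuts, [length]])
        for k in range(n_ex):
            s, e = int(bounds[2 * k]), int(bounds[2 * k + 1])
            if e > s:
                exon_rows.append({"chrom": chrom, "start": start + s,
                                  "end": start + e, "gene_id": gid})

    # transposon copies
    consensus: dict[str, str] = {}
    meta: dict[str, ConsensusEntry] = {}
    te_records: list[RepeatRecord] = []
    te_rows = []
    act_cfg = ActiveCallConfig()
    for plan in config.te_plan:
        cons = _random_seq(rng, plan.consensus_length, 0.5)
        consensus[plan.family] = cons.tobytes().decode()
        meta[plan.family] = ConsensusEntry(plan.family, plan.te_class,
                                           plan.consensus_length)
        divs = plan.per_copy("divergence")
        truncs = plan.per_copy("truncation")
        for ci in range(plan.n_copies):
            trunc_len = int(round(truncs[ci] * plan.consensus_length))
            body = cons[trunc_len:]
            if body.size == 0:
                raise SimulationError(f"truncation removes whole copy of {plan.family}")
            mutated, n_sub = _mutate(rng, body, divs[ci])
            perc_div = round(100.0 * n_sub / mutated.size, 1)
            strand = plan.strand or ("+" if rng.random() < 0.5 else "-")
            chrom, start = alloc.place(mutated.size, f"TE copy of {plan.family}")
            insert = mutated if strand == "+" else np.frombuffer(
                revcomp(mutated.tobytes().decode()).encode(), dtype="S1").copy()
            genome[chrom][start:start + mutated.size] = insert
            end = start + mutated.size
            active = (perc_div < act_cfg.max_div
                      and mutated.size >= act_cfg.min_length_fraction * plan.consensus_length)
            te_records.append(RepeatRecord(
                chrom=chrom, start=start, end=end, strand=strand,
                family=plan.family, te_class=plan.te_class, perc_div=perc_div,
                consensus_begin=trunc_len + 1, consensus_end=plan.consensus_length))
            te_rows.append({"chrom": chrom, "start": start, "end": end,
                            "strand": strand, "family": plan.family,
                            "te_class": plan.te_class, "perc_div": perc_div,
                            "truncation": truncs[ci], "active": active})

    te_cols = ["chrom", "start", "end", "strand", "family", "te_class",
               "perc_div", "truncation", "active"]
    cluster_rows = [{"chrom": c.chrom, "start": c.start, "end": c.end,
                     "strandedness": c.strandedness, "read_mass": c.read_mass,
                     "cluster_id": f"cluster{i}"}
                    for i, c in enumerate(config.cluster_plan)]
    return Simulation(
        config=config,
        genome={c: a.tobytes().decode() for c, a in genome.items()},
        chrom_sizes=sizes,
        consensus=consensus,
        consensus_meta=meta,
        te_records=te_records,
        te_truth=pd.DataFrame(te_rows, columns=te_cols),
        genes=pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "gene_id"]),
        exons=pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene_id"]),
        cgis=pd.DataFrame(cgi_rows, columns=["chrom", "start", "end", "cgi_id"]),
        clusters=pd.DataFrame(cluster_rows, columns=["chrom", "start", "end",
                                                     "strandedness", "read_mass",
                                                     "cluster_id"]),
    )


class _Locus:
    """Pre-indexed 5'-position candidates for U-biased read sampling."""

    def __init__(self, genome: Mapping[str, str], chrom: str, start: int, end: int):
        self.chrom = chrom
        self.start, self.end = start, end
        seq = np.frombuffer(genome[chrom][start:end].encode(), dtype="S1")
        pos = np.arange(start, end)
        self.u5 = {"+": pos[seq == b"T"], "-": pos[seq == b"A"]}
        self.n5 = {"+": pos[seq != b"T"], "-": pos[seq != b"A"]}

    def sample_5p(self, rng: np.random.Generator, strand: str, want_u: bool) -> int:
        pool = self.u5[strand] if want_u else self.n5[strand]
        if pool.size == 0:
            pool = np.concatenate([self.u5[strand], self.n5[strand]])
        return int(pool[rng.integers(0, pool.size)])


def simulate_small_rna(config: SimConfig, sim: Simulation) -> pd.DataFrame:
    """Emit reads from cluster/TE loci plus background, with ping-pong partners.

    A partner read sits on the opposite strand with its 5' end exactly 10 nt
    inside the primary's 5' end, so the partner's position-10 base is the
    complement of the primary's position-1 base (the 10A signature follows
    from the 1U bias). Partner emission probabilities are conditioned on the
    primary's first base so that the overall partner fraction equals
    `pingpong_fraction` while the fraction of partners whose primary starts
    with U equals `a10_bias`.

    Returns a truth DataFrame (one row per emitted read) including the read
    sequence (DNA alphabet, as sequenced).
    """
    rng = np.random.default_rng([config.seed, 1])
    q, f, a = config.u1_bias, config.pingpong_fraction, config.a10_bias
    p_u = 0.0 if q == 0 else f * a / q
    p_n = 0.0 if q == 1 else f * (1 - a) / (1 - q)
    if p_u > 1 or p_n > 1:
        warnings.warn("pingpong_fraction/a10_bias infeasible for u1_bias; clamping")
        p_u, p_n = min(p_u, 1.0), min(p_n, 1.0)

    lengths = np.array(sorted(config.length_law), dtype=int)
    lprobs = np.array([config.length_law[int(l)] for l in lengths])
    draw_len = lambda: int(lengths[rng.choice(lengths.size, p=lprobs)])

    rows = []

    def emit(chrom, strand, p5, length, role, source):
        size = sim.chrom_sizes[chrom]
        if strand == "+":
            s, e = p5, p5 + length
        else:
            s, e = p5 - length + 1, p5 + 1
        if s < 0 or e > size:
            return False
        seq = sim.genome[chrom][s:e] if strand == "+" else revcomp(sim.genome[chrom][s:e])
        rows.append({"read_id": f"r{len(rows):07d}", "chrom": chrom, "start": s,
                     "end": e, "strand": strand, "length": length, "role": role,
                     "source": source, "seq": seq,
                     "first_base": seq[0].replace("T", "U"),
                     "base10": seq[9].replace("T", "U") if length >= 10 else ""})
        return True

    def emit_primary_and_partner(locus: _Locus, strand: str, source: str):
        want_u = rng.random() < q
        p5 = locus.sample_5p(rng, strand, want_u)
        if not emit(locus.chrom, strand, p5, draw_len(), "primary", source):
            return
        base = sim.genome[locus.chrom][p5]
        is_u = (base == "T") if strand == "+" else (base == "A")
        if rng.random() < (p_u if is_u else p_n):
            pstrand = "-" if strand == "+" else "+"
            pp5 = p5 + 9 if strand == "+" else p5 - 9
            emit(locus.chrom, pstrand, pp5, draw_len(), "secondary", source)

    for ci, cl in enumerate(config.cluster_plan):
        if cl.read_mass <= 0:
            warnings.warn(f"cluster{ci} has zero read mass; skipped")
            continue
        locus = _Locus(sim.genome, cl.chrom, cl.start, cl.end)
        plus_frac = {"uni+": 1.0, "uni-": 0.0}.get(
            cl.strandedness, cl.plus_fraction if cl.plus_fraction is not None else 0.5)
        for _ in range(cl.read_mass):
            strand = "+" if rng.random() < plus_frac else "-"
            emit_primary_and_partner(locus, strand, f"cluster{ci}")

    if config.te_read_mass > 0:
        if sim.te_truth.empty:
            raise SimulationError("te_read_mass > 0 but no TE copies planted")
        loci = [_Locus(sim.genome, r.chrom, r.start, r.end)
                for r in sim.te_truth.itertuples()]
        fams = sim.te_truth["family"].tolist()
        for _ in range(config.te_read_mass):
            k = int(rng.integers(0, len(loci)))
            strand = "+" if rng.random() < 0.5 else "-"
            emit_primary_and_partner(loci[k], strand, fams[k])

    if config.background_read_mass > 0:
        chroms = list(sim.chrom_sizes)
        w = np.array([sim.chrom_sizes[c] for c in chroms], dtype=float)
        w /= w.sum()
        emitted = 0
        while emitted < config.background_read_mass:
            chrom = chroms[rng.choice(len(chroms), p=w)]
            length = draw_len()
            p5 = int(rng.integers(0, sim.chrom_sizes[chrom]))
            strand = "+" if rng.random() < 0.5 else "-"
            if emit(chrom, strand, p5, length, "background", "background"):
                emitted += 1

    cols = ["read_id", "chrom", "start", "end", "strand", "length", "role",
            "source", "seq", "first_base", "base10"]
    return pd.DataFrame(rows, columns=cols)


def write_fastq(reads: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for r in reads.itertuples():
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def _interval_lookup(intervals: list[tuple[int, int]], pos: np.ndarray) -> np.ndarray:
    """Boolean membership of positions in a set of (possibly overlapping) intervals."""
    if not intervals:
        return np.zeros(pos.size, dtype=bool)
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.size, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


@dataclass
class MethylomeSim:
    coverage: pd.DataFrame      # chrom,pos,count_meth,count_unmeth
    lambda_cov: pd.DataFrame
    puc19_cov: pd.DataFrame
    cpg_truth: pd.DataFrame     # chrom,pos,p,category


def simulate_methylome(config: SimConfig, sim: Simulation) -> MethylomeSim:
    """Binomially sampled per-CpG methylation calls over the toy genome.

    Each CpG gets a true methylation probability from `meth_plan` by the
    highest-precedence feature covering it (TSS window > active TE > TE >
    gene > background), depth ~ Poisson(coverage_mean) (zero-depth CpGs are
    absent from the coverage output, as in real coverage files), and
    methylated count ~ Binomial(depth, p). Spike-ins: lambda CpGs methylate
    at the conversion-failure rate; pUC19 CpGs at `puc19_meth`.
    """
    rng = np.random.default_rng([config.seed, 2])
    hw = config.tss_halfwidth
    cat_intervals: dict[str, dict[str, list[tuple[int, int]]]] = {}

    def add(cat, chrom, s, e):
        cat_intervals.setdefault(cat, {}).setdefault(chrom, []).append((s, e))

    if "tss" in config.meth_plan:
        for g in sim.genes.itertuples():
            tss = g.start if g.strand == "+" else g.end - 1
            add("tss", g.chrom, max(0, tss - hw), tss + hw)
    for r in sim.te_truth.itertuples():
        if "te_active" in config.meth_plan and r.active:
            add("te_active", r.chrom, r.start, r.end)
        else:
            add("te", r.chrom, r.start, r.end)
    for g in sim.genes.itertuples():
        add("gene", g.chrom, g.start, g.end)
    if "cgi" in config.meth_plan:
        for c in sim.cgis.itertuples():
            add("cgi", c.chrom, c.start, c.end)

    precedence = [c for c in ("tss", "cgi", "te_active", "te", "gene")
                  if c in config.meth_plan]
    truth_rows, cov_rows = [], []
    for chrom, seq in sim.genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        cpg = np.where((arr[:-1] == b"C") & (arr[1:] == b"G"))[0]
        if cpg.size == 0:
            continue
        category = np.full(cpg.size, "background", dtype=object)
        unassigned = np.ones(cpg.size, dtype=bool)
        for cat in precedence:
            hit = _interval_lookup(cat_intervals.get(cat, {}).get(chrom, []), cpg)
            take = hit & unassigned
            category[take] = cat
            unassigned &= ~hit
        p = np.array([config.meth_plan[c] for c in category])
        depth = rng.poisson(config.coverage_mean, size=cpg.size)
        meth = rng.binomial(depth, p)
        truth_rows.append(pd.DataFrame({"chrom": chrom, "pos": cpg, "p": p,
                                        "category": category}))
        keep = depth > 0
        cov_rows.append(pd.DataFrame({"chrom": chrom, "pos": cpg[keep],
                                      "count_meth": meth[keep],
                                      "count_unmeth": (depth - meth)[keep]}))

    def spike(name, p_meth):
        pos = np.arange(config.n_spike_cpgs) * 10
        depth = rng.poisson(config.coverage_mean, size=pos.size)
        meth = rng.binomial(depth, p_meth)
        keep = depth > 0
        return pd.DataFrame({"chrom": name, "pos": pos[keep],
                             "count_meth": meth[keep],
                             "count_unmeth": (depth - meth)[keep]})

    empty = pd.DataFrame(columns=["chrom", "pos", "count_meth", "count_unmeth"])
    coverage = pd.concat(cov_rows, ignore_index=True) if cov_rows else empty
    truth = (pd.concat(truth_rows, ignore_index=True) if truth_rows
             else pd.DataFrame(columns=["chrom", "pos", "p", "category"]))
    return MethylomeSim(coverage=coverage,
                        lambda_cov=spike("lambda", config.conversion_failure),
                        puc19_cov=spike("pUC19", config.puc19_meth),
                        cpg_truth=truth)


def write_bismark_cov(df: pd.DataFrame, path) -> None:
    """Write Bismark coverage lines: chrom, 1-based pos, pos, percent, meth, unmeth."""
    with open(path, "w") as fh:
        for r in df.itertuples():
            tot = r.count_meth + r.count_unmeth
            pct = 100.0 * r.count_meth / tot if tot else 0.0
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.pos + 1}\t{pct:.6f}\t"
                     f"{r.count_meth}\t{r.count_unmeth}\n")
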