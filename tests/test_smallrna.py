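"""Read selection, collapsing, dust filtering, toy mapping, 1/n weighting
and genomic origin classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnascape import smallrna as sr
from pirnascape._seq import revcomp
from pirnascape.te_annotation import RepeatRecord

EMPTY_GENES = pd.DataFrame(columns=["chrom", "start", "end", "strand", "gene_id"])
EMPTY_EXONS = pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])


def test_select_pirnas_length_boundaries():
    reads = ["A" * 22, "C" * 23, "G" * 33, "T" * 34]
    kept = sr.select_pirnas(reads, min_len=23)
    assert kept == ["C" * 23, "G" * 33, "T" * 34]
    assert sr.select_pirnas(reads, min_len=23, max_len=33) == ["C" * 23, "G" * 33]


def test_collapse_conserves_total_count():
    reads = ["ACGT"] * 2 + ["GGCC", "TTAA"]
    collapsed = sr.collapse(reads)
    by_seq = {r.sequence: r.count for r in collapsed}
    assert by_seq == {"ACGT": 2, "GGCC": 1, "TTAA": 1}
    assert sum(r.count for r in collapsed) == len(reads)


def test_dust_filter_behaviour():
    polya = sr.CollapsedRead("A" * 30, 1)
    dinuc = sr.CollapsedRead("ACACACACACACACACACACACACACAC", 1)
    rng = np.random.default_rng(0)
    random_read = sr.CollapsedRead(
        "".join(rng.choice(list("ACGT"), size=29)), 1)
    kept = sr.dust_filter([polya, dinuc, random_read])
    assert kept == [random_read]
    # threshold 1.0 removes nothing: run fractions cannot exceed 1
    assert sr.dust_filter([polya, dinuc, random_read], threshold=1.0) == \
        [polya, dinuc, random_read]


def test_dust_keeps_random_reads_overwhelmingly():
    rng = np.random.default_rng(1)
    reads = [sr.CollapsedRead("".join(rng.choice(list("ACGT"), size=29)), 1)
             for _ in range(500)]
    assert len(sr.dust_filter(reads)) >= 499


def _genome_with(insert, n_copies, length=5000, seed=0):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), size=length))
    positions = [500 + i * 1500 for i in range(n_copies)]
    seq = list(base)
    for p in positions:
        seq[p:p + len(insert)] = insert
    return {"chr1": "".join(seq)}, positions


def test_toy_map_unique_locus():
    rng = np.random.default_rng(2)
    read = "".join(rng.choice(list("ACGT"), size=29))
    genome, pos = _genome_with(read, 1)
    aln = sr.toy_map([sr.CollapsedRead(read, 3)], genome)
    assert len(aln) == 1
    row = aln.iloc[0]
    assert (row.start, row.end, row.strand, row.n_hits) == (pos[0], pos[0] + 29, "+", 1)
    assert row.weight == 3.0


def test_toy_map_duplicated_locus_splits_weight():
    rng = np.random.default_rng(3)
    read = "".join(rng.choice(list("ACGT"), size=29))
    genome, _ = _genome_with(read, 2)
    aln = sr.toy_map([sr.CollapsedRead(read, 4)], genome)
    assert len(aln) == 2 and (aln["n_hits"] == 2).all()
    assert aln["weight"].tolist() == [2.0, 2.0]


def test_toy_map_reverse_strand_and_mismatches():
    rng = np.random.default_rng(4)
    target = "".join(rng.choice(list("ACGT"), size=29))
    genome, pos = _genome_with(target, 1)
    read = revcomp(target)
    mutated = read[:20] + ("A" if read[20] != "A" else "C") + read[21:]
    aln = sr.toy_map([sr.CollapsedRead(mutated, 1)], genome)
    assert len(aln) == 1 and aln.iloc[0].strand == "-"
    too_many = read[:3] + "".join(
        "A" if b != "A" else "C" for b in read[3:7]) + read[7:]
    assert sr.toy_map([sr.CollapsedRead(too_many, 1)], genome).empty


def test_toy_map_unmappable_read():
    genome = {"chr1": "AT" * 2000}
    read = "GC" * 15
    assert sr.toy_map([sr.CollapsedRead(read, 1)], genome).empty


def _brute_force_map(read, genome, max_mismatch=3, min_match=15):
    sites = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for chrom, ref in genome.items():
            for s in range(len(ref) - len(seq) + 1):
                window = ref[s:s + len(seq)]
                mism = [i for i, (a, b) in enumerate(zip(seq, window)) if a != b]
                if len(mism) > max_mismatch:
                    continue
                edges = [-1] + mism + [len(seq)]
                longest = max(b - a - 1 for a, b in zip(edges, edges[1:]))
                if longest >= min_match:
                    sites.append((chrom, s, strand))
    return sorted(set(sites))


def test_toy_map_agrees_with_brute_force():
    """Seed-and-verify mapping equals an exhaustive all-positions scan,
    including multimapping and mismatched reads."""
    rng = np.random.default_rng(7)
    genome = {"chrA": "".join(rng.choice(list("ACGT"), size=6000)),
              "chrB": "".join(rng.choice(list("ACGT"), size=4000))}
    # plant a duplicated segment across chromosomes
    seg = genome["chrA"][1000:1030]
    genome["chrB"] = genome["chrB"][:2000] + seg + genome["chrB"][2030:]
    reads = []
    for i in range(30):
        chrom = "chrA" if i % 2 else "chrB"
        s = int(rng.integers(0, len(genome[chrom]) - 29))
        seq = genome[chrom][s:s + 29]
        seq = list(seq)
        for _ in range(int(rng.integers(0, 3))):   # up to 2 mutations
            j = int(rng.integers(0, 29))
            seq[j] = "ACGT"[int(rng.integers(0, 4))]
        reads.append("".join(seq))
    reads.append(seg)  # multimapper
    aln = sr.toy_map([sr.CollapsedRead(r, 1) for r in reads], genome)
    got = {rid: sorted(zip(sub.chrom, sub.start, sub.strand))
           for rid, sub in aln.groupby("read_id")}
    for i, read in enumerate(reads):
        expected = _brute_force_map(read, genome)
        assert got.get(f"r{i}", []) == expected, f"read {i} disagrees"


def test_weight_conservation(demo_alignments, demo_reads):
    total = demo_alignments.groupby("read_id")["weight"].sum()
    counts = demo_alignments.groupby("read_id")["count"].first()
    assert np.allclose(total, counts, atol=1e-9)


def _te_rec(chrom, s, e, te_class="LTR"):
    return RepeatRecord(chrom, s, e, "+", "Fam", te_class, 1.0, 1, e - s)


def _aln_row(chrom, s, e, weight=1.0):
    return {"read_id": f"x{s}", "seq": "A" * (e - s), "chrom": chrom,
            "start": s, "end": e, "strand": "+", "n_hits": 1, "count": 1,
            "weight": weight}


def test_classify_origin_precedence_and_desert():
    aln = pd.DataFrame([_aln_row("chr1", 100, 129),    # in TE inside gene
                        _aln_row("chr1", 5000, 5029)])  # desert
    genes = pd.DataFrame([{"chrom": "chr1", "start": 50, "end": 500,
                           "strand": "+", "gene_id": "g"}])
    exons = pd.DataFrame([{"chrom": "chr1", "start": 50, "end": 500,
                           "gene_id": "g"}])
    out = sr.classify_origin(aln, [_te_rec("chr1", 90, 200)], genes, exons)
    assert out.masses["LTR"] == 1.0 and out.masses["non-coding"] == 1.0
    assert sum(out.proportions.values()) == pytest.approx(1.0, abs=1e-9)


def test_classify_origin_exon_intron_split():
    aln = pd.DataFrame([_aln_row("chr1", 100, 129),   # exon
                        _aln_row("chr1", 300, 329)])  # intron
    genes = pd.DataFrame([{"chrom": "chr1", "start": 50, "end": 500,
                           "strand": "+", "gene_id": "g"}])
    exons = pd.DataFrame([{"chrom": "chr1", "start": 80, "end": 200,
                           "gene_id": "g"}])
    out = sr.classify_origin(aln, [], genes, exons)
    assert out.masses["exon"] == 1.0 and out.masses["intron"] == 1.0


def test_classify_origin_order_invariant(demo_alignments, demo_sim):
    a = sr.classify_origin(demo_alignments, demo_sim.te_records,
                           demo_sim.genes, demo_sim.exons)
    shuffled = demo_alignments.sample(frac=1.0, random_state=0)
    b = sr.classify_origin(shuffled, demo_sim.te_records,
                           demo_sim.genes, demo_sim.exons)
    for k in a.masses:
        assert a.masses[k] == pytest.approx(b.masses[k], abs=1e-9)


def test_length_histogram():
    reads = [sr.CollapsedRead("A" * 29, 5)]
    freq, median = sr.length_histogram(reads)
    assert freq.to_dict() == {29: 1.0} and median == 29
    with pytest.raises(ValueError):
        sr.length_histogram([])


def test_length_histogram_recovers_planted_median(demo_reads):
    collapsed = sr.collapse(demo_reads["seq"].tolist())
    freq, median = sr.length_histogram(collapsed)
    assert median == 29
    assert freq.sum() == pytest.approx(1.0)


def test_bin_signal_conservation_and_split():
    aln = pd.DataFrame([_aln_row("chr1", 100, 129, weight=2.0),
                        _aln_row("chr1", 1_000_100, 1_000_129, weight=2.0)])
    df = sr.bin_signal(aln, {"chr1": 2_000_000})
    assert df["rpm"].tolist() == [5e5, 5e5]
    assert df["rpm"].sum() == pytest.approx(1e6)
    one = sr.bin_signal(aln.iloc[:1], {"chr1": 500_000})
    assert one["rpm"].iloc[0] == pytest.approx(1e6)


def test_ingest_sam_uses_nh_tag(tmp_path):
    sam = tmp_path / "toy.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t101\t255\t29M\t*\t0\t0\t" + "A" * 29 + "\t*\tNH:i:2\n"
        "r1\t16\tchr1\t301\t255\t29M\t*\t0\t0\t" + "T" * 29 + "\t*\tNH:i:2\n"
        "r2\t0\tchr1\t501\t255\t29M\t*\t0\t0\t" + "C" * 29 + "\t*\n")
    df = sr.ingest_sam(sam, counts={"r1": 4})
    r1 = df[df.read_id == "r1"]
    assert (r1["weight"] == 2.0).all() and (r1["n_hits"] == 2).all()
    assert r1["start"].tolist() == [100, 300]
    assert df[df.read_id == "r2"]["weight"].iloc[0] == 1.0
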