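"""CpG island scanning (GGF criteria), annotation and shuffle enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pirnascape import cgi
from pirnascape.te_annotation import RepeatRecord


def test_obs_exp_examples():
    assert cgi.obs_exp_cpg("CGCGCG") == pytest.approx(2.0)
    assert cgi.obs_exp_cpg("AAAA") == 0.0
    assert cgi.obs_exp_cpg("") == 0.0
    # N positions drop out of counts and length
    assert cgi.obs_exp_cpg("CGNCG") == cgi.obs_exp_cpg("CGCG") == pytest.approx(2.0)


def test_obs_exp_converges_to_one_for_iid_sequence():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=200_000))
    assert cgi.obs_exp_cpg(seq) == pytest.approx(1.0, abs=0.05)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
def test_obs_exp_matches_direct_count(seq):
    n_c, n_g = seq.count("C"), seq.count("G")
    L = len(seq) - seq.count("N")
    n_cpg = sum(seq[i:i + 2] == "CG" for i in range(len(seq) - 1))
    expected = 0.0 if (n_c == 0 or n_g == 0 or L == 0) else n_cpg * L / (n_c * n_g)
    assert cgi.obs_exp_cpg(seq) == pytest.approx(expected)


def test_planted_cg_repeat_recovered_exactly():
    """A 250-bp CG repeat inside an AT-only genome is returned as exactly one
    island spanning the insert (no flanking CpGs to extend into)."""
    rng = np.random.default_rng(3)
    at = "".join(rng.choice(list("AT"), size=5000))
    insert = "CG" * 125
    genome = {"chr1": at[:2000] + insert + at[2000:]}
    out = cgi.find_cgis(genome)
    assert len(out) == 1
    row = out.iloc[0]
    assert (row.start, row.end) == (2000, 2250)
    assert row.gc_fraction == 1.0 and row.obs_exp == pytest.approx(2.0)
    assert row.p_value <= 1e-5


def test_all_at_genome_has_no_islands():
    rng = np.random.default_rng(4)
    genome = {"chr1": "".join(rng.choice(list("AT"), size=3000))}
    assert cgi.find_cgis(genome).empty


def test_short_contig_skipped():
    assert cgi.find_cgis({"tiny": "CG" * 50}).empty


def test_emitted_islands_satisfy_all_thresholds(demo_sim):
    out = cgi.find_cgis(demo_sim.genome)
    assert len(out) >= 1
    for r in out.itertuples():
        seq = demo_sim.genome[r.chrom][r.start:r.end]
        assert r.end - r.start >= 200
        assert cgi.obs_exp_cpg(seq) >= 0.6
        gc = (seq.count("C") + seq.count("G")) / len(seq)
        assert gc >= 0.5
        assert r.p_value <= 1e-5
        assert seq.startswith("CG") and seq.endswith("CG")  # trimmed to CpGs


def test_position_shift_equivariance():
    rng = np.random.default_rng(5)
    core = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=3000))
    core = core[:1000] + "CG" * 120 + core[1240:]
    a = cgi.find_cgis({"chr1": core})
    b = cgi.find_cgis({"chr1": "A" * 137 + core})
    assert len(a) == len(b) >= 1
    assert (b["start"].to_numpy() - a["start"].to_numpy() == 137).all()


def test_long_n_run_breaks_islands():
    insert = "CG" * 150
    genome = {"chr1": insert + "N" * 50 + insert}
    out = cgi.find_cgis(genome)
    assert len(out) == 2
    assert out["end"].max() <= 650 and (out["end"] - out["start"] == 300).all()


def brute_force_cgis(seq, min_gc=0.5, min_len=200, min_oe=0.6, max_p=1e-5):
    """Independent enumerator: score every min_len window with plain string
    ops, chain-merge overlapping passers, trim to outermost CpG, re-test."""
    passing = []
    for i in range(len(seq) - min_len + 1):
        w = seq[i:i + min_len]
        n_c, n_g = w.count("C"), w.count("G")
        n_cpg = sum(w[j:j + 2] == "CG" for j in range(min_len - 1))
        if n_c and n_g and (n_c + n_g) / min_len >= min_gc \
                and n_cpg * min_len / (n_c * n_g) >= min_oe:
            passing.append(i)
    regions, out = [], []
    for i in passing:
        if regions and i < regions[-1][2] + min_len:   # overlaps previous passer
            regions[-1] = (regions[-1][0], i + min_len, i)
        else:
            regions.append((i, i + min_len, i))
    for rs, re, _ in regions:
        cpgs = [j for j in range(rs, re - 1) if seq[j:j + 2] == "CG"]
        if not cpgs:
            continue
        ts, te = cpgs[0], cpgs[-1] + 2
        w = seq[ts:te]
        L = len(w)
        n_c, n_g = w.count("C"), w.count("G")
        n_cpg = sum(w[j:j + 2] == "CG" for j in range(L - 1))
        if L < min_len or not n_c or not n_g:
            continue
        gc = (n_c + n_g) / L
        oe = n_cpg * L / (n_c * n_g)
        p = stats.binom.sf(n_cpg - 1, L - 1, (n_c / L) * (n_g / L))
        if gc >= min_gc and oe >= min_oe and p <= max_p:
            out.append((ts, te))
    return out


def test_scan_matches_brute_force_enumerator():
    rng = np.random.default_rng(6)
    n_with_hits = 0
    for rep in range(25):
        gc = rng.uniform(0.45, 0.6)
        seq = "".join(rng.choice(list("ACGT"),
                                 p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2],
                                 size=2000))
        if rep % 3 == 0:  # plant a CpG-rich patch in some sequences
            patch = "".join("CG" if rng.random() < 0.5 else
                            "".join(rng.choice(list("ACGT"), size=2))
                            for _ in range(150))
            k = int(rng.integers(0, 1700))
            seq = seq[:k] + patch[:300] + seq[k + 300:]
        got = cgi.find_cgis({"s": seq})
        expected = brute_force_cgis(seq)
        assert [(r.start, r.end) for r in got.itertuples()] == expected
        n_with_hits += bool(expected)
    assert n_with_hits >= 3  # the comparison exercised non-trivial cases


TE = [RepeatRecord("chr1", 1000, 2000, "+", "Gypsy", "LTR", 1.0, 1, 1000)]
GENES = pd.DataFrame([{"chrom": "chr1", "start": 5000, "end": 8000,
                       "strand": "+", "gene_id": "g1"}])


def _cgi_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_annotate_precedence():
    cgis = _cgi_df([("chr1", 1500, 1700),    # inside TE
                    ("chr1", 4950, 5150),    # over TSS
                    ("chr1", 6000, 6300),    # genic
                    ("chr1", 20_000, 20_300)])  # desert
    annotated, counts, fractions = cgi.annotate_cgis(cgis, TE, GENES)
    assert annotated["category"].tolist() == ["te", "tss", "genic", "intergenic"]
    assert counts.to_dict() == {"te": 1, "tss": 1, "genic": 1, "intergenic": 1}
    assert fractions["all"] == 1.0  # the single TE copy is overlapped


def test_annotate_active_fraction():
    te2 = TE + [RepeatRecord("chr1", 30_000, 31_000, "+", "Gypsy", "LTR",
                             9.0, 1, 1000)]
    cgis = _cgi_df([("chr1", 1500, 1700)])
    _, _, fractions = cgi.annotate_cgis(cgis, te2, GENES,
                                        active=np.array([True, False]))
    assert fractions["all"] == 0.5 and fractions["active"] == 1.0


def test_chi_square_reference_value():
    """Pearson chi-square without continuity correction on [[90,10],[50,50]]
    is 800/21 = 38.095..., cross-checked by direct sum of (O-E)^2/E."""
    table = np.array([[90, 10], [50, 50]])
    stat, p = cgi.chi_square(table)
    expected = ((90 - 70) ** 2 / 70 + (10 - 30) ** 2 / 30
                + (50 - 70) ** 2 / 70 + (50 - 30) ** 2 / 30)
    assert stat == pytest.approx(expected)
    assert stat == pytest.approx(800 / 21)
    assert p < 1e-8


def test_chi_square_null_table():
    stat, p = cgi.chi_square(np.array([[50, 50], [50, 50]]))
    assert stat == 0.0 and p == 1.0


def test_shuffle_regions_preserve_length_and_chrom():
    cgis = _cgi_df([("chr1", 100, 400), ("chr1", 900, 1100)])
    shuf = cgi.shuffle_regions(cgis, {"chr1": 50_000}, np.random.default_rng(0))
    assert (shuf["end"] - shuf["start"]).tolist() == [300, 200]
    assert (shuf["chrom"] == "chr1").all()
    with pytest.raises(ValueError):
        cgi.shuffle_regions(_cgi_df([("chr1", 0, 400)]), {"chr1": 300},
                            np.random.default_rng(0))


def test_shuffle_enrichment_detects_planted_bias():
    # all regions on the TE -> strongly non-random vs uniform shuffles
    cgis = _cgi_df([("chr1", 1000 + 10 * i, 1060 + 10 * i) for i in range(40)])
    stat, p, table = cgi.shuffle_enrichment(cgis, TE, GENES, {"chr1": 200_000},
                                            n_shuffles=10, seed=1)
    assert p < 1e-6
    assert table.loc["observed", "te"] == 40
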