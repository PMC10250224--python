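"""CLIP alignment, peak calling, CIMS FDR, significance and annotation."""

import numpy as np
import pytest

from circdimorph import parclip, study
from circdimorph.core_io import GeneModel, GenomeRef, Transcript, reverse_complement
from circdimorph.parclip import ClipAlignment, CimsSite, Peak


@pytest.fixture(scope="module")
def flat_genome():
    rng = np.random.default_rng(77)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    return GenomeRef({"chrC": seq})


# ---------------------------------------------------------------------------
# alignment


def test_align_exact_read(flat_genome):
    read = flat_genome.fetch("chrC", 500, 550)
    (a,) = parclip.align_clip_reads([("r", read)], flat_genome)
    assert (a.contig, a.start, a.end, a.strand) == ("chrC", 500, 550, "+")
    assert a.conversions == ()


def test_align_records_tc_conversion(flat_genome):
    seq = flat_genome.fetch("chrC", 500, 550)
    tpos = 500 + seq.index("T")
    read = seq.replace("T", "C", 1)
    (a,) = parclip.align_clip_reads([("r", read)], flat_genome)
    assert a.conversions == (tpos,)
    assert a.start == 500


def test_align_minus_strand_conversion(flat_genome):
    plus = flat_genome.fetch("chrC", 700, 750)
    sense = reverse_complement(plus)  # a minus-strand read
    t_idx = sense.index("T")
    read = sense[:t_idx] + "C" + sense[t_idx + 1 :]
    (a,) = parclip.align_clip_reads([("r", read)], flat_genome)
    assert a.strand == "-"
    # conversion position maps back to the plus-strand 'A'
    (conv,) = a.conversions
    assert flat_genome.fetch("chrC", conv, conv + 1) == "A"
    assert 700 <= conv < 750


def test_align_discards_over_budget_mismatches(flat_genome):
    seq = flat_genome.fetch("chrC", 100, 150)
    # three non-T>C substitutions exceed max_mm=2
    b = bytearray(seq, "ascii")
    n = 0
    for i in range(50):
        if chr(b[i]) in "AG" and n < 3:
            b[i] = ord("C") if chr(b[i]) == "A" else ord("T")
            if chr(b[i]) != seq[i]:
                n += 1
    read = b.decode()
    assert parclip.align_clip_reads([("r", read)], flat_genome) == []


def test_align_discards_multimapper():
    core = "ACGTTGCAAGGTTCCAGTAC" * 3
    genome = GenomeRef({"c": core + "A" * 50 + core})
    read = core[:50]
    assert parclip.align_clip_reads([("r", read)], genome) == []


# ---------------------------------------------------------------------------
# peak calling


def _mk(reads, contig="chrC", strand="+"):
    return [
        ClipAlignment(f"r{i}", contig, s, e, strand, conv)
        for i, (s, e, conv) in enumerate(reads)
    ]


def test_call_peaks_requires_min_cov(flat_genome):
    sxl = _mk([(100, 150, ())] * 4)  # coverage 4 < 5
    assert parclip.call_peaks(sxl, [], flat_genome) == []


def test_call_peaks_merges_close_runs(flat_genome):
    left = [(100, 150, ())] * 6
    right = [(155, 205, ())] * 6  # gap of 5 < merge_gap 10
    peaks = parclip.call_peaks(_mk(left + right), [], flat_genome)
    assert len(peaks) == 1
    assert peaks[0].start == 100 and peaks[0].end == 205
    far = [(300, 350, ())] * 6
    peaks = parclip.call_peaks(_mk(left + far), [], flat_genome)
    assert len(peaks) == 2


def test_call_peaks_poisson_oracle(flat_genome):
    """P-value equals direct summation of the Poisson mass function."""
    sxl = _mk([(100, 150, ())] * 15)
    igg = _mk([(2000, 2050, ())] * 15)  # same library size, no local igg
    (peak,) = parclip.call_peaks(sxl, igg, flat_genome)
    assert peak.sxl_count == 15 and peak.igg_count == 0
    # mean = (0+1) * 15/15 = 1; upper tail at 15
    import math

    oracle = 1.0 - sum(math.exp(-1) / math.factorial(k) for k in range(15))
    assert peak.p_value == pytest.approx(oracle, rel=1e-9)
    assert peak.ratio == pytest.approx((15 / 15) / (1 / 15))


def test_call_peaks_empty_pulldown(flat_genome):
    assert parclip.call_peaks([], _mk([(0, 50, ())]), flat_genome) == []


# ---------------------------------------------------------------------------
# CIMS


def test_cims_no_conversions_no_sites(flat_genome):
    peak = Peak("p", "chrC", 100, 160, "+")
    aligns = _mk([(100, 150, ())] * 8)
    assert parclip.find_cims(peak, aligns, flat_genome) == []


def test_cims_planted_and_sprayed_calibration():
    res = study.cims_calibration_study(1, n_perm=1000)
    assert res["cims_planted_fdr"] < 0.05
    assert res["cims_sprayed_median_fdr"] > 0.3


def test_cims_reproducible_and_converged():
    res1 = study.cims_calibration_study(1, n_perm=1000)
    res2 = study.cims_calibration_study(1, n_perm=1000)
    assert res1["cims_planted_fdr"] == res2["cims_planted_fdr"]
    res4 = study.cims_calibration_study(1, n_perm=4000)
    assert abs(res1["cims_planted_fdr"] - res4["cims_planted_fdr"]) <= 0.05


# ---------------------------------------------------------------------------
# significance


def _peak(ratio, p, fdr=None):
    pk = Peak("p", "c", 0, 50, "+", ratio=ratio, p_value=p)
    if fdr is not None:
        pk.cims_sites = [CimsSite(10, 3, 8, fdr)]
    return pk


def test_significance_branch_rules():
    assert parclip.significant_peaks([_peak(12, 1e-6, fdr=0.1)]) != []
    assert parclip.significant_peaks([_peak(12, 1e-6)]) == []
    assert parclip.significant_peaks([_peak(150, 1e-6)]) != []
    assert parclip.significant_peaks([_peak(150, 1e-3)]) == []
    assert parclip.significant_peaks([_peak(12, 1e-6, fdr=0.5)]) == []


def test_significance_monotone_in_ratio_and_p():
    base = _peak(15, 1e-5, fdr=0.1)
    parclip.significant_peaks([base])
    assert base.significant
    for ratio, p in ((20, 1e-5), (15, 1e-9), (200, 1e-5)):
        pk = _peak(ratio, p, fdr=0.1)
        parclip.significant_peaks([pk])
        assert pk.significant


# ---------------------------------------------------------------------------
# region annotation


@pytest.fixture(scope="module")
def annotated_world(flat_genome):
    # plus-strand coding gene: exons [200,500) and [700,1000); CDS [300,800)
    tx = Transcript("ga.t", ((200, 500), (700, 1000)), (300, 800))
    ga = GeneModel("ga", "chrC", "+", "coding", [tx])
    return flat_genome, [ga]


def test_assign_genomic_region_midpoint_rule(annotated_world):
    genome, models = annotated_world
    peaks = [
        Peak("p5", "chrC", 210, 260, "+"),   # midpoint 235 -> 5'UTR
        Peak("pc", "chrC", 400, 450, "+"),   # CDS
        Peak("p3", "chrC", 850, 900, "+"),   # 3'UTR
        Peak("pi", "chrC", 550, 600, "+"),   # intron
        Peak("px", "chrC", 1500, 1550, "+"),  # intergenic
    ]
    table = parclip.assign_genomic_region(peaks, models, genome)
    assert [p.region for p in peaks] == ["5UTR", "CDS", "3UTR", "intron",
                                         "intergenic"]
    assert table.at["intron", "peaks"] == 1
    # density arithmetic: peaks per kb of annotated category length
    assert table.at["intron", "kb"] == pytest.approx(0.2)
    assert table.at["intron", "density_per_kb"] == pytest.approx(5.0)


def test_assign_circ_region_categories(annotated_world, toy_gene):
    genome, gene = toy_gene
    from conftest import make_exonic_call

    call = make_exonic_call(gene, 1, 1)  # circle = exon 2 [300,400)
    peaks = [
        Peak("in", "chrT", 320, 360, "+"),    # inside the circle exon
        Peak("up", "chrT", 220, 260, "+"),    # intron upstream of acceptor
        Peak("ex", "chrT", 120, 160, "+"),    # nearest exon outside (exon 1)
        Peak("far", "chrT", 800, 850, "+"),   # beyond the gene
    ]
    table = parclip.assign_circ_region(peaks, [call], [gene])
    cats = {p.peak_id: {c for _, c in p.circ_assignments} for p in peaks}
    assert cats["in"] == {"bs_exon"}
    assert cats["up"] == {"flank_intron"}
    assert cats["ex"] == {"flank_exon"}
    assert cats["far"] == set()
    assert set(table["category"]) == {"bs_exon", "flank_intron", "flank_exon"}


def test_assign_circ_region_terminal_circle_missing_flank(toy_gene):
    genome, gene = toy_gene
    from conftest import make_exonic_call

    call = make_exonic_call(gene, 0, 0)  # first exon: no upstream features
    peak = Peak("dn", "chrT", 210, 250, "+")  # downstream intron
    parclip.assign_circ_region([peak], [call], [gene])
    assert {c for _, c in peak.circ_assignments} == {"flank_intron"}


# ---------------------------------------------------------------------------
# k-mer enrichment


def test_kmer_pure_repeat_tops_ranking():
    seqs = ["A" * 40] * 5
    df = parclip.kmer_enrichment(seqs, k=5, n_shuffle=20, seed=0)
    assert df.iloc[0]["kmer"] == "AAAAA"


def test_kmer_null_calibration():
    rng = np.random.default_rng(8)
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            for _ in range(30)]
    df = parclip.kmer_enrichment(seqs, k=5, n_shuffle=60, seed=1)
    assert float(df["z"].abs().median()) < 2.0


def test_kmer_planted_motif_ranks_first():
    rng = np.random.default_rng(9)
    seqs = []
    for i in range(50):
        s = list("".join("ACGT"[j] for j in rng.integers(0, 4, 40)))
        if i < 30:  # 60% of peaks carry a U-rich (TTTTT in DNA space) core
            pos = int(rng.integers(0, 35))
            s[pos : pos + 5] = "TTTTT"
        seqs.append("".join(s))
    df = parclip.kmer_enrichment(seqs, k=5, n_shuffle=50, seed=2)
    assert df.iloc[0]["kmer"] == "TTTTT"


def test_kmer_requires_long_enough_sequence():
    with pytest.raises(ValueError):
        parclip.kmer_enrichment(["ACG"], k=5)


def test_dinucleotide_shuffle_preserves_composition():
    rng = np.random.default_rng(4)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))

    def dinucs(s):
        from collections import Counter

        return Counter(zip(s, s[1:]))

    for _ in range(5):
        shuf = parclip._dinucleotide_shuffle(seq, rng)
        assert dinucs(shuf) == dinucs(seq)
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]
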