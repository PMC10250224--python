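"""Junction library construction, read scanning and call aggregation."""

import numpy as np
import pytest

from circdimorph import bsjcall, synthio
from circdimorph.core_io import (
    BackSpliceJunction,
    GeneModel,
    GenomeRef,
    SampleSpec,
    Transcript,
    reverse_complement,
)


@pytest.fixture(scope="module")
def three_exon_world():
    rng = np.random.default_rng(17)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    genome = GenomeRef({"chrT": seq})
    tx = Transcript("g.t1", ((100, 300), (500, 700), (900, 1100)), (150, 1050))
    gene = GeneModel("g", "chrT", "+", "coding", [tx])
    return genome, [gene]


def test_three_exon_gene_yields_six_exonic_entries(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome, read_length=100,
                                    min_anchor=10)
    exonic = [e for e in lib.entries.values() if e.kind == "exonic-BSJ"]
    assert len(exonic) == 6
    pairs = {(e.junction.acceptor, e.junction.donor) for e in exonic}
    assert pairs == {(100, 300), (100, 700), (100, 1100), (500, 700),
                     (500, 1100), (900, 1100)}
    lariat = [e for e in lib.entries.values() if e.kind == "lariat"]
    # 2 introns x branch-point window 15..50 step 5 (8 positions)
    assert len(lariat) == 16


def test_single_exon_probe_is_end_plus_start(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome, read_length=100,
                                    min_anchor=10)
    e = lib.entries[BackSpliceJunction("chrT", "+", 100, 300).junction_id]
    L = 90
    exon = genome.fetch("chrT", 100, 300)
    assert e.probe == exon[-L:] + exon[:L]
    assert e.jpos == L


def test_minus_strand_probe_in_transcript_orientation(three_exon_world):
    genome, _ = three_exon_world
    tx = Transcript("m.t1", ((100, 300), (500, 700)), None)
    gene = GeneModel("m", "chrT", "-", "noncoding", [tx])
    lib = bsjcall.build_bsj_library([gene], genome, read_length=100,
                                    min_anchor=10)
    e = lib.entries[BackSpliceJunction("chrT", "-", 100, 700).junction_id]
    mature = reverse_complement(
        genome.fetch("chrT", 100, 300) + genome.fetch("chrT", 500, 700)
    )
    assert e.probe == mature[-90:] + mature[:90]


def test_library_contains_probe_for_every_planted_circle(tiny_world, tiny_truth):
    genome, models = tiny_world
    lib = bsjcall.build_bsj_library(models, genome, read_length=100)
    for c in tiny_truth.circles:
        assert c.junction.junction_id in lib.entries


def test_library_bounds_validation(three_exon_world):
    genome, models = three_exon_world
    with pytest.raises(ValueError):
        bsjcall.build_bsj_library(models, genome, read_length=20, min_anchor=10)
    with pytest.raises(ValueError):
        bsjcall.build_bsj_library(models, genome, min_anchor=0)


# ---------------------------------------------------------------------------
# scanning


def _junction_read(entry, left_anchor, read_length=100):
    start = entry.jpos - left_anchor
    return entry.probe[start : start + read_length]


def test_scan_assigns_exact_junction_read(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome)
    jid = BackSpliceJunction("chrT", "+", 100, 700).junction_id
    read = _junction_read(lib.entries[jid], 60)
    (a,) = bsjcall.scan_reads([("r1", read)], lib, max_mm=0)
    assert a.junction_id == jid and a.offset == 60 and a.mismatches == 0
    assert a.unique_best


def test_scan_rejects_subminimal_anchor(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome)
    jid = BackSpliceJunction("chrT", "+", 100, 700).junction_id
    read = _junction_read(lib.entries[jid], 91)  # 9 nt on the acceptor side
    assert bsjcall.scan_reads([("r1", read)], lib, max_mm=0) == []
    assert bsjcall.scan_reads([("r1", read)], lib, max_mm=1) == []


def test_scan_skips_short_and_wrong_length_reads(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome)
    assert bsjcall.scan_reads([("r1", "ACGT"), ("r2", "A" * 50)], lib) == []


def test_scan_mismatch_policy(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome)
    jid = BackSpliceJunction("chrT", "+", 500, 1100).junction_id
    read = _junction_read(lib.entries[jid], 40)
    mutated = read[:20] + ("A" if read[20] != "A" else "C") + read[21:]
    assert bsjcall.scan_reads([("r", mutated)], lib, max_mm=0) == []
    (a,) = bsjcall.scan_reads([("r", mutated)], lib, max_mm=1)
    assert a.junction_id == jid and a.mismatches == 1


def test_scan_unstranded_accepts_reverse_complement(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome)
    jid = BackSpliceJunction("chrT", "+", 500, 700).junction_id
    read = reverse_complement(_junction_read(lib.entries[jid], 30))
    assert bsjcall.scan_reads([("r", read)], lib, max_mm=0, stranded=True) == []
    (a,) = bsjcall.scan_reads([("r", read)], lib, max_mm=0, stranded=False)
    assert a.junction_id == jid


def test_scan_linear_locus_tie_is_not_unique(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome)
    # forge a genome that also contains a junction probe window linearly
    jid = BackSpliceJunction("chrT", "+", 100, 300).junction_id
    read = _junction_read(lib.entries[jid], 50)
    genome2 = GenomeRef({"chrT": genome.contigs["chrT"] + read})
    (a,) = bsjcall.scan_reads([("r", read)], lib, max_mm=0, genome=genome2)
    assert not a.unique_best
    (b,) = bsjcall.scan_reads([("r", read)], lib, max_mm=0, genome=genome)
    assert b.unique_best


def test_scan_matches_truth_labels_exactly(tiny_world, tiny_config):
    genome, models = tiny_world
    sample = SampleSpec("F_head_Rplus", "F", "head", "Rplus")
    truth = synthio.plant_truth(genome, models, [sample], 8, tiny_config)
    sim = synthio.simulate_rnaseq(truth, sample, 20000, 11)
    lib = bsjcall.build_bsj_library(models, genome)
    asn = bsjcall.scan_reads(sim, lib, max_mm=0, genome=genome)
    t = sim.truth
    detectable = set(
        t.loc[t["source"].isin(["BSJ", "ciRNA-junction"])
              & (t["offset"] >= 10) & (t["offset"] <= 90), "read_id"]
    )
    assigned = {a.read_id for a in asn if a.unique_best}
    assert assigned == detectable


def test_anchor_monotonicity(tiny_world, tiny_config):
    """Raising min_anchor never increases the assignment count."""
    genome, models = tiny_world
    sample = SampleSpec("F_head_Rplus", "F", "head", "Rplus")
    truth = synthio.plant_truth(genome, models, [sample], 8, tiny_config)
    sim = synthio.simulate_rnaseq(truth, sample, 8000, 12)
    counts = []
    for anchor in (5, 10, 20, 35):
        lib = bsjcall.build_bsj_library(models, genome, min_anchor=anchor)
        counts.append(len(bsjcall.scan_reads(sim, lib, max_mm=0)))
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# aggregation and typing


def test_aggregate_counts_and_conservation(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome)
    jid = BackSpliceJunction("chrT", "+", 100, 700).junction_id
    reads_a = [(f"a{i}", _junction_read(lib.entries[jid], 30 + i))
               for i in range(12)]
    asn = {
        "A": bsjcall.scan_reads(reads_a, lib, max_mm=0),
        "B": [],
    }
    calls = bsjcall.aggregate_calls(asn, lib, models)
    (call,) = [c for c in calls if c.call_id == jid]
    assert call.counts == {"A": 12, "B": 0}
    assert call.circ_type == "exonic"
    assert call.exon_chain == ((100, 300), (500, 700))
    matrix = bsjcall.counts_matrix(calls)
    n_unique = {s: sum(a.unique_best for a in asn[s]) for s in asn}
    assert matrix.sum(axis=0).to_dict() == n_unique


def test_aggregate_empty_assignments(three_exon_world):
    genome, models = three_exon_world
    lib = bsjcall.build_bsj_library(models, genome)
    assert bsjcall.aggregate_calls({"A": []}, lib, models) == []


def test_classify_call_rules(three_exon_world):
    genome, models = three_exon_world
    exonic = BackSpliceJunction("chrT", "+", 500, 1100)
    assert bsjcall.classify_call(exonic, models) == "exonic"
    cirna = BackSpliceJunction("chrT", "+", 300, 500 - 25)
    assert bsjcall.classify_call(cirna, models) == "ciRNA"
    off = BackSpliceJunction("chrT", "+", 503, 1103)
    assert bsjcall.classify_call(off, models) == "unassigned"
    # branch point outside the window is not a ciRNA
    far = BackSpliceJunction("chrT", "+", 300, 500 - 60)
    assert bsjcall.classify_call(far, models) == "unassigned"


def test_summarize_structure(three_exon_world):
    genome, models = three_exon_world
    from conftest import make_exonic_call

    g = models[0]
    calls = [
        make_exonic_call(g, 0, 0),
        make_exonic_call(g, 0, 2),
        make_exonic_call(g, 1, 1),
    ]
    summary = bsjcall.summarize_structure(calls, models)
    per = summary["per_call"].set_index("junction_id")
    assert per.loc[calls[0].call_id, "n_exons"] == 1
    assert per.loc[calls[1].call_id, "mature_length"] == 600
    assert summary["circles_per_gene_hist"].to_dict() == {3: 1}
    lengths = sorted(per["mature_length"])
    assert summary["median_length"] == float(np.median(lengths))
    assert per.loc[calls[2].call_id, "origin"] == "middle"
    assert per.loc[calls[1].call_id, "origin"] == "full_span"
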