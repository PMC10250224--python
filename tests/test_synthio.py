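"""Synthetic genome/read generators: determinism, construction invariants,
rate contracts."""

import numpy as np
import pytest
from scipy import stats as sps

from circdimorph import synthio
from circdimorph.core_io import SampleSpec, reverse_complement
from circdimorph.synthio import ConfigError, SimConfig


def _fasta_bytes(genome):
    return "".join(f">{n}\n{genome.contigs[n]}\n" for n in sorted(genome.contigs))


def test_generate_genome_deterministic(tmp_path):
    cfg = SimConfig()
    g1, m1 = synthio.generate_genome(40, 7, cfg)
    g2, m2 = synthio.generate_genome(40, 7, cfg)
    assert _fasta_bytes(g1) == _fasta_bytes(g2)
    from circdimorph.core_io import write_annotation

    p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
    write_annotation(m1, p1)
    write_annotation(m2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_every_intron_starts_gt_ends_ag(tiny_world):
    genome, models = tiny_world
    for g in models:
        for t in g.transcripts:
            for s, e in t.introns:
                intron = genome.fetch(g.contig, s, e, g.strand)
                assert intron[:2] == "GT" and intron[-2:] == "AG"


def test_exon_count_distribution_uniform():
    cfg = SimConfig()
    _, models = synthio.generate_genome(200, 5, cfg)
    counts = np.bincount(
        [len(g.canonical.exons) for g in models], minlength=9
    )[3:9]
    assert counts.sum() == 200
    p = sps.chisquare(counts).pvalue
    assert p > 0.01


def test_genome_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(exon_len=(300, 80)).validate()
    with pytest.raises(ConfigError):
        SimConfig(n_rrna=0).validate()
    with pytest.raises(ConfigError):
        synthio.generate_genome(0, 1)


def test_config_file_roundtrip(tmp_path):
    cfg = SimConfig(class_counts={"null": 5, "female_biased": 2}, fold=6.0,
                    bias_tissues=("head",), host_tpm=30.0)
    path = tmp_path / "c.txt"
    cfg.to_file(path)
    assert SimConfig.from_file(path) == cfg
    path.write_text("nonsense_key=1\n")
    with pytest.raises(ConfigError):
        SimConfig.from_file(path)


# ---------------------------------------------------------------------------
# truth planting


def test_planted_classes_have_exact_rate_structure(tiny_truth):
    cfg = tiny_truth.config
    by_cls = {}
    for c in tiny_truth.circles:
        by_cls.setdefault(c.cls, []).append(c)
    assert len(by_cls["female_biased"]) == cfg.class_counts["female_biased"]
    for tissue in ("head", "body", "gonad"):
        f = tiny_truth.base_rates("F", tissue)
        m = tiny_truth.base_rates("M", tissue)
        for c in by_cls["female_biased"]:
            assert f[c.circle_id] / m[c.circle_id] == pytest.approx(cfg.fold)
        for c in by_cls["female_specific"]:
            assert m[c.circle_id] == 0.0 and f[c.circle_id] > 0
        for c in by_cls["null"]:
            assert f[c.circle_id] == pytest.approx(m[c.circle_id])
    # null rates identical across all six conditions
    base = tiny_truth.base_rates("F", "head")
    for sex in ("F", "M"):
        for tissue in ("head", "body", "gonad"):
            r = tiny_truth.base_rates(sex, tissue)
            for c in by_cls["null"]:
                assert r[c.circle_id] == pytest.approx(base[c.circle_id])


def test_planted_junctions_sit_on_annotation(tiny_truth):
    genes = tiny_truth.genes_by_id
    for c in tiny_truth.circles:
        g = genes[c.gene_id]
        if c.circ_type == "exonic":
            assert c.junction.acceptor in g.exon_starts()
            assert c.junction.donor in g.exon_ends()
        else:
            offs = tiny_truth.config.branch_offset
            hit = False
            for s, e in g.canonical.introns:
                if g.strand == "+":
                    hit |= (c.junction.acceptor == s
                            and c.junction.donor == e - offs)
                else:
                    hit |= (c.junction.donor == e
                            and c.junction.acceptor == s + offs)
            assert hit


def test_too_many_circles_requested_is_config_error(tiny_world):
    genome, models = tiny_world
    cfg = SimConfig(class_counts={"null": 100000})
    with pytest.raises(ConfigError, match="candidate"):
        synthio.plant_truth(genome, models, synthio.default_design(), 1, cfg)


# ---------------------------------------------------------------------------
# RNA-seq simulation


def test_depth_zero_gives_empty_library(tiny_truth):
    sample = SampleSpec("F_head_Rminus", "F", "head", "Rminus")
    sim = synthio.simulate_rnaseq(tiny_truth, sample, 0, 1)
    assert len(sim) == 0 and len(sim.truth) == 0


def test_truth_label_counts_sum_to_depth(tiny_truth):
    sample = SampleSpec("M_body_Rminus", "M", "body", "Rminus")
    sim = synthio.simulate_rnaseq(tiny_truth, sample, 5000, 3)
    assert len(sim) == 5000
    assert sim.truth["source"].isin(["linear", "BSJ", "ciRNA-junction"]).all()
    assert len(sim.truth) == 5000


def test_zero_survival_rplus_reads_all_circle_derived(tiny_world, tiny_config):
    import dataclasses

    genome, models = tiny_world
    cfg = dataclasses.replace(tiny_config, rnaser_linear_survival=0.0)
    sample = SampleSpec("F_head_Rplus", "F", "head", "Rplus")
    truth = synthio.plant_truth(genome, models, [sample], 8, cfg)
    sim = synthio.simulate_rnaseq(truth, sample, 3000, 5)
    doubled = {
        c.circle_id: truth.circ_mature(c.circle_id) * 2 for c in truth.circles
    }
    for (_, seq), unit in zip(sim.reads, sim.truth["unit"]):
        assert seq in doubled[unit]


def test_rnaser_contract_on_mixture(tiny_truth):
    """Expected linear:circular ratio in R+ = survival x that of R-."""
    rm = SampleSpec("F_gonad_Rminus", "F", "gonad", "Rminus")
    rp = SampleSpec("F_gonad_Rplus", "F", "gonad", "Rplus")

    def lin_circ(sample):
        sources, probs = tiny_truth.mixture(sample)
        lin = sum(p for (k, _), p in zip(sources, probs) if k in ("linear", "rrna"))
        circ = sum(p for (k, _), p in zip(sources, probs) if k.startswith("circ"))
        return lin / circ

    survival = tiny_truth.config.rnaser_linear_survival
    assert lin_circ(rp) == pytest.approx(survival * lin_circ(rm), rel=1e-9)


def test_bsj_counts_match_binomial_oracle(tiny_truth):
    """Aggregate BSJ read counts over 20 seeds stay within binomial error."""
    sample = SampleSpec("F_head_Rminus", "F", "head", "Rminus")
    rates = tiny_truth.bsj_rates(sample)
    depth, n_seeds = 5000, 20
    totals = {cid: 0 for cid in rates}
    for s in range(n_seeds):
        sim = synthio.simulate_rnaseq(tiny_truth, sample, depth, 100 + s)
        t = sim.truth
        junc = t[t["source"].isin(["BSJ", "ciRNA-junction"])]
        for cid, n in junc["unit"].value_counts().items():
            totals[cid] += int(n)
    big = sorted(rates, key=rates.get, reverse=True)[:5]
    n_total = depth * n_seeds
    for cid in big:
        expect = rates[cid] * n_total
        sd = np.sqrt(n_total * rates[cid] * (1 - rates[cid]))
        assert abs(totals[cid] - expect) < 4 * sd


def test_simulated_reads_deterministic(tiny_truth):
    sample = SampleSpec("F_head_Rplus", "F", "head", "Rplus")
    a = synthio.simulate_rnaseq(tiny_truth, sample, 2000, 42)
    b = synthio.simulate_rnaseq(tiny_truth, sample, 2000, 42)
    assert a.reads == b.reads


# ---------------------------------------------------------------------------
# PAR-CLIP simulation


@pytest.fixture(scope="module")
def clip_truth():
    cfg = SimConfig(
        class_counts={"null": 8}, max_circles_per_gene=1,
        site_counts={"bs_exon": 4, "flank_intron": 3, "utr3": 2, "other": 1},
        clip_error_rate=0.0, coding_hosts_only=True,
    )
    genome, models = synthio.generate_genome(20, 21, cfg)
    sample = SampleSpec("F_head_Rminus", "F", "head", "Rminus")
    return synthio.plant_truth(genome, models, [sample], 22, cfg)


def test_igg_without_errors_has_no_conversions(clip_truth):
    sim = synthio.simulate_parclip(clip_truth, "IgG", 4000, 3)
    genome = clip_truth.genome
    plus = genome.contigs[clip_truth.models[0].contig]
    minus = reverse_complement(plus)
    for _, seq in sim.reads:
        assert seq in plus or seq in minus


def test_zero_affinity_site_draws_no_signal_reads(clip_truth):
    import dataclasses

    truth = synthio.TruthSet(
        genome=clip_truth.genome, models=clip_truth.models,
        config=clip_truth.config, circles=clip_truth.circles,
        sites=[dataclasses.replace(s, affinity=0.0) if i == 0 else s
               for i, s in enumerate(clip_truth.sites)],
        expression=clip_truth.expression,
    )
    dead = truth.sites[0].site_id
    sim = synthio.simulate_parclip(truth, "SXL", 20000, 4)
    assert not (sim.truth["unit"] == dead).any()


def test_conversion_rate_matches_closed_form():
    """P(read carries >= 1 conversion) = 1 - (1-q)^t for t covered site Ts."""
    import dataclasses

    cfg = SimConfig(
        class_counts={"null": 4}, max_circles_per_gene=1,
        site_counts={"bs_exon": 2}, clip_error_rate=0.0, clip_jitter_sd=0.0,
        coding_hosts_only=True,
    )
    genome, models = synthio.generate_genome(12, 31, cfg)
    sample = SampleSpec("F_head_Rminus", "F", "head", "Rminus")
    truth = synthio.plant_truth(genome, models, [sample], 32, cfg)
    site = truth.sites[0]
    base = "T" if site.strand == "+" else "A"
    t_count = truth.genome.fetch(site.contig, site.start, site.end, "+").count(base)
    q = cfg.conversion_rate
    expect = 1 - (1 - q) ** t_count

    # jitter 0: every signal read covers the whole site; a conversion shows
    # as C where the reference slice has T
    mid = (site.start + site.end) // 2
    start = mid - cfg.clip_read_length // 2
    ref = truth.genome.fetch(site.contig, start,
                             start + cfg.clip_read_length, site.strand)
    n_conv = n_reads = 0
    for s in range(10):
        sim = synthio.simulate_parclip(truth, "SXL", 4000, 200 + s)
        for (_, seq), unit in zip(sim.reads, sim.truth["unit"]):
            if unit != site.site_id:
                continue
            n_reads += 1
            diffs = sum(1 for a, b in zip(ref, seq) if a == "T" and b == "C")
            n_conv += int(diffs >= 1)
    frac = n_conv / n_reads
    sd = np.sqrt(expect * (1 - expect) / n_reads)
    assert abs(frac - expect) < 4 * sd


def test_parclip_deterministic(clip_truth):
    a = synthio.simulate_parclip(clip_truth, "SXL", 3000, 9)
    b = synthio.simulate_parclip(clip_truth, "SXL", 3000, 9)
    assert a.reads == b.reads
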