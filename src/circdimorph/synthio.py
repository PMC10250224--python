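"""Seeded generators for a toy genome, fractionated RNA-seq and PAR-CLIP reads.

The generators emulate the structure of a sex-dimorphic circRNA study:
six sex x tissue samples, each sequenced as three RNA fractions —

``polyA``
    poly(A)-selected mRNA; coding-gene fragments only, unstranded.
``Rminus``
    rRNA/mRNA-depleted RNA; linear fragments from all genes, a small
    residual of rRNA reads, and circle-derived fragments (both
    junction-spanning and internal); strand-specific.
``Rplus``
    the R- material after RNase R digestion: linear fragments survive
    with a small probability (default 2%), circle-derived fragments
    survive with probability 1; strand-specific.

plus two PAR-CLIP libraries (an RBP pulldown carrying T>C conversions at
planted binding sites, and an IgG background control).

Everything is deterministic under (config, seed): identical inputs give
byte-identical FASTA/GTF/FASTQ/TSV outputs.

Rate convention: each planted circle c has a canonical back-splice
junction (BSJ) read *rate* in the R- fraction of a (sex, tissue)
condition,

    rate_c = circ_frac * (read_len - 1) * a_c * eff_c(sex, tissue) / S

with abundance ``a_c``, class fold-effect ``eff_c`` and
``S = sum_c a_c * mature_len_c`` evaluated at eff = 1.  A read drawn for
a circle is junction-spanning with probability (read_len - 1) /
mature_len, which makes the BSJ rate independent of circle length.  The
R+ fraction thins linear sources by the RNase-R survival probability and
renormalizes to the requested depth; :meth:`TruthSet.bsj_rates` exposes
the exact per-fraction probabilities so tests can use binomial oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    BackSpliceJunction,
    CircCall,
    GeneModel,
    GenomeRef,
    SampleSpec,
    Transcript,
    mature_sequence,
    reverse_complement,
)

CIRCLE_CLASSES = (
    "null",
    "female_biased",
    "male_biased",
    "female_specific",
    "male_specific",
)
SITE_ROLES = ("bs_exon", "flank_intron", "flank_exon", "utr3", "other")
CONDITIONS = tuple(
    (sex, tissue) for sex in ("F", "M") for tissue in ("head", "body", "gonad")
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised when generator configuration is infeasible."""


@dataclass
class SimConfig:
    """All tunable generator parameters (defaults are the study conditions)."""

    # genome layout
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (60, 2000)
    intergenic: tuple[int, int] = (500, 1500)
    utr_len: tuple[int, int] = (20, 150)
    n_rrna: int = 1
    n_noncoding: int = 2
    p_minus: float = 0.5
    # reads
    read_length: int = 100
    error_rate: float = 0.001
    # fraction composition
    circ_frac_rminus: float = 0.02
    rrna_frac_rminus: float = 0.02
    rnaser_linear_survival: float = 0.02
    # circle planting
    class_counts: dict = field(default_factory=lambda: {"null": 30})
    n_cirna: int = 0
    fold: float = 8.0
    bias_tissues: Optional[tuple[str, ...]] = None
    abundance_sigma: float = 0.8
    abundance_clip: tuple[float, float] = (0.25, 8.0)
    class_abundance: dict = field(default_factory=dict)
    max_circles_per_gene: Optional[int] = None
    max_span: int = 100_000
    branch_offset: int = 25
    coding_hosts_only: bool = False  # restrict circles to coding genes
    # expression
    expr_sigma: float = 1.0
    expr_condition_sigma: float = 0.0
    host_tpm: Optional[float] = None
    # PAR-CLIP
    site_counts: dict = field(default_factory=dict)
    site_len: int = 30
    site_margin: int = 30
    site_margin_loose: int = 5
    site_min_ts: int = 4
    clip_read_length: int = 50
    clip_jitter_sd: float = 5.0
    clip_enrichment: float = 20.0
    conversion_rate: float = 0.25
    clip_error_rate: float = 0.001

    def validate(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic", "utr_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"{name} bounds ({lo}, {hi}) infeasible")
        if self.n_rrna < 1:
            raise ConfigError("at least one rRNA gene is required")
        if self.intron_len[0] < 4:
            raise ConfigError("introns must hold GT/AG dinucleotides")
        if not 0 <= self.rnaser_linear_survival <= 1:
            raise ConfigError("rnaser_linear_survival must be in [0, 1]")
        if not 0 <= self.conversion_rate <= 1:
            raise ConfigError("conversion_rate must be in [0, 1]")
        for cls in self.class_counts:
            if cls not in CIRCLE_CLASSES:
                raise ConfigError(f"unknown circle class {cls!r}")
        for role in self.site_counts:
            if role not in SITE_ROLES:
                raise ConfigError(f"unknown binding-site role {role!r}")
        if self.circ_frac_rminus + self.rrna_frac_rminus >= 1:
            raise ConfigError("fraction composition exceeds 1")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}={json.dumps(getattr(self, f.name))}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in valid:
                    raise ConfigError(f"unknown config key {key!r}")
                kwargs[key] = json.loads(value)
        for key in ("exons_per_gene", "exon_len", "intron_len", "intergenic",
                    "utr_len", "abundance_clip", "bias_tissues"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# genome generation


def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def _mature_to_genomic(exons: Sequence[tuple[int, int]], strand: str, m: int) -> int:
    """Genomic position of mature (spliced, transcript-orientation) coordinate m."""
    if strand == "-":
        total = sum(e - s for s, e in exons)
        m = total - 1 - m
    for s, e in exons:
        if m < e - s:
            return s + m
        m -= e - s
    raise ValueError("mature coordinate beyond transcript")


def generate_genome(
    n_genes: int,
    seed: int,
    config: Optional[SimConfig] = None,
    contig: str = "chrS",
) -> tuple[GenomeRef, list[GeneModel]]:
    """Random genome and annotation with planted GT/AG splice dinucleotides.

    Genes are laid out left to right on a single contig separated by
    intergenic gaps; each gene has one (canonical) transcript.  Coding
    genes carry a CDS leaving 5'/3' UTRs; at least one gene is rRNA and a
    few are noncoding.  Deterministic under (n_genes, seed, config).
    """
    config = config or SimConfig()
    config.validate()
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if n_genes < config.n_rrna + config.n_noncoding:
        raise ConfigError("n_genes smaller than required rRNA + noncoding genes")
    rng = np.random.default_rng(seed)

    biotypes = (
        ["rRNA"] * config.n_rrna
        + ["noncoding"] * config.n_noncoding
        + ["coding"] * (n_genes - config.n_rrna - config.n_noncoding)
    )
    biotypes = [biotypes[i] for i in rng.permutation(n_genes)]

    models: list[GeneModel] = []
    layout = []  # (gene_idx, exons, introns, strand)
    cursor = 0
    for gi in range(n_genes):
        cursor += int(rng.integers(config.intergenic[0], config.intergenic[1] + 1))
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_exons)
        intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1,
                                   max(0, n_exons - 1))
        strand = "-" if rng.random() < config.p_minus else "+"
        exons = []
        pos = cursor
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        cursor = pos
        layout.append((gi, exons, strand))
    total_len = cursor + int(rng.integers(config.intergenic[0], config.intergenic[1] + 1))

    seq = _random_bases(rng, total_len)
    for gi, exons, strand in layout:
        for i in range(len(exons) - 1):
            s, e = exons[i][1], exons[i + 1][0]  # intron
            if strand == "+":
                seq[s : s + 2] = b"GT"
                seq[e - 2 : e] = b"AG"
            else:
                # transcript-orientation GT/AG read off the minus strand
                seq[e - 2 : e] = b"AC"
                seq[s : s + 2] = b"CT"

    for gi, exons, strand in layout:
        mature_len = sum(e - s for s, e in exons)
        cds = None
        if biotypes[gi] == "coding":
            max_utr = max(config.utr_len[0], min(config.utr_len[1], mature_len // 4))
            u5 = int(rng.integers(config.utr_len[0], max_utr + 1))
            u3 = int(rng.integers(config.utr_len[0], max_utr + 1))
            a = _mature_to_genomic(exons, strand, u5)
            b = _mature_to_genomic(exons, strand, mature_len - u3 - 1)
            cds = (min(a, b), max(a, b) + 1)
        gene_id = f"g{gi:04d}"
        tx = Transcript(f"{gene_id}.t1", tuple(exons), cds)
        models.append(GeneModel(gene_id, contig, strand, biotypes[gi], [tx]))

    genome = GenomeRef({contig: seq.decode()})
    return genome, models


# ---------------------------------------------------------------------------
# truth planting


@dataclass(frozen=True)
class PlantedCircle:
    circle_id: str
    junction: BackSpliceJunction
    circ_type: str  # exonic | ciRNA
    gene_id: str
    exon_chain: tuple[tuple[int, int], ...]
    mature_length: int
    cls: str
    abundance: float

    def effect(self, sex: str, tissue: str, fold: float,
               bias_tissues: Optional[tuple[str, ...]]) -> float:
        in_scope = bias_tissues is None or tissue in bias_tissues
        if self.cls == "female_biased":
            return fold if (sex == "F" and in_scope) else 1.0
        if self.cls == "male_biased":
            return fold if (sex == "M" and in_scope) else 1.0
        if self.cls == "female_specific":
            return 0.0 if sex == "M" else 1.0
        if self.cls == "male_specific":
            return 0.0 if sex == "F" else 1.0
        return 1.0

    def to_call(self) -> CircCall:
        return CircCall(
            junction=self.junction,
            circ_type=self.circ_type,
            gene_id=self.gene_id,
            exon_chain=self.exon_chain if self.circ_type == "exonic" else (),
        )


@dataclass(frozen=True)
class BindingSite:
    site_id: str
    contig: str
    start: int
    end: int
    strand: str
    affinity: float
    role: str
    circle_id: Optional[str]  # set for circRNA-relative roles
    gene_id: Optional[str]


@dataclass
class TruthSet:
    """Planted ground truth consumed by tests and study protocols."""

    genome: GenomeRef
    models: list[GeneModel]
    config: SimConfig
    circles: list[PlantedCircle]
    sites: list[BindingSite]
    expression: pd.DataFrame  # gene x condition ("F:head", ...), molar units

    def __post_init__(self) -> None:
        self._gene_by_id = {g.gene_id: g for g in self.models}
        self._circ_by_id = {c.circle_id: c for c in self.circles}
        self._gene_mature: dict[str, str] = {}
        self._circ_mature: dict[str, str] = {}
        # S = sum a_c * M_c at eff = 1 anchors the absolute rate scale
        self._rate_unit = 0.0
        s_base = sum(c.abundance * c.mature_length for c in self.circles)
        if s_base > 0:
            self._rate_unit = self.config.circ_frac_rminus / s_base

    # -- sequence caches ----------------------------------------------------

    def gene_mature(self, gene_id: str) -> str:
        if gene_id not in self._gene_mature:
            g = self._gene_by_id[gene_id]
            t = g.canonical
            plus = "".join(self.genome.fetch(g.contig, s, e, "+") for s, e in t.exons)
            self._gene_mature[gene_id] = (
                reverse_complement(plus) if g.strand == "-" else plus
            )
        return self._gene_mature[gene_id]

    def circ_mature(self, circle_id: str) -> str:
        if circle_id not in self._circ_mature:
            c = self._circ_by_id[circle_id]
            self._circ_mature[circle_id] = mature_sequence(c.to_call(), self.genome)
        return self._circ_mature[circle_id]

    @property
    def circles_by_id(self) -> dict[str, PlantedCircle]:
        return self._circ_by_id

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return self._gene_by_id

    @property
    def junctions(self) -> set[BackSpliceJunction]:
        return {c.junction for c in self.circles}

    def true_tpm(self) -> pd.DataFrame:
        """True TPM of coding genes per condition (molar shares x 1e6)."""
        coding = [g.gene_id for g in self.models if g.biotype == "coding"]
        expr = self.expression.loc[coding]
        return expr / expr.sum(axis=0) * 1e6

    # -- per-sample read mixtures -------------------------------------------

    def base_rates(self, sex: str, tissue: str) -> dict[str, float]:
        """Canonical (R- fraction) per-circle BSJ read rates for a condition."""
        k = self._rate_unit * (self.config.read_length - 1)
        return {
            c.circle_id: k
            * c.abundance
            * c.effect(sex, tissue, self.config.fold, self.config.bias_tissues)
            for c in self.circles
        }

    def mixture(self, sample: SampleSpec) -> tuple[list[tuple[str, str]], np.ndarray]:
        """Read-source distribution for a sample: (kind, unit) labels + probs.

        Kinds: ``linear`` (gene fragment), ``rrna`` (residual rRNA),
        ``circ_junc`` (junction-spanning circle fragment), ``circ_int``
        (internal circle fragment).
        """
        cfg = self.config
        cond = f"{sample.sex}:{sample.tissue}"
        expr = self.expression[cond]
        sources: list[tuple[str, str]] = []
        weights: list[float] = []

        def gene_weight(g: GeneModel) -> float:
            return float(expr[g.gene_id]) * len(self.gene_mature(g.gene_id))

        if sample.fraction == "polyA":
            for g in self.models:
                if g.biotype == "coding":
                    sources.append(("linear", g.gene_id))
                    weights.append(gene_weight(g))
            probs = np.array(weights)
            if probs.sum() <= 0:
                raise ConfigError("no coding-gene expression for polyA fraction")
            return sources, probs / probs.sum()

        # R- composition in absolute probabilities
        # absolute read probability of each circle (junction + internal):
        # circ_frac * a_c * eff_c * M_c / S, with S = sum(a*M) at eff = 1
        circ_tot = {}
        for c in self.circles:
            eff = c.effect(sample.sex, sample.tissue, cfg.fold, cfg.bias_tissues)
            circ_tot[c.circle_id] = (
                c.abundance * eff * c.mature_length * self._rate_unit
            )
        circ_sum = sum(circ_tot.values())
        if circ_sum + cfg.rrna_frac_rminus >= 0.9:
            raise ConfigError(
                "circle + rRNA mass exceeds 90% of the R- library; lower "
                "circ_frac_rminus, abundances or fold effects"
            )
        rrna_genes = [g for g in self.models if g.biotype == "rRNA"]
        linear_genes = [g for g in self.models if g.biotype != "rRNA"]
        rw = np.array([gene_weight(g) for g in rrna_genes])
        lw = np.array([gene_weight(g) for g in linear_genes])
        rw = rw / rw.sum() * cfg.rrna_frac_rminus
        lw = lw / lw.sum() * (1.0 - circ_sum - cfg.rrna_frac_rminus)

        survival = cfg.rnaser_linear_survival if sample.fraction == "Rplus" else 1.0
        p_junc = {}
        for c in self.circles:
            p_junc[c.circle_id] = min(1.0, (cfg.read_length - 1) / c.mature_length)
        for g, w in zip(linear_genes, lw):
            sources.append(("linear", g.gene_id))
            weights.append(w * survival)
        for g, w in zip(rrna_genes, rw):
            sources.append(("rrna", g.gene_id))
            weights.append(w * survival)
        for c in self.circles:
            pj = p_junc[c.circle_id]
            sources.append(("circ_junc", c.circle_id))
            weights.append(circ_tot[c.circle_id] * pj)
            sources.append(("circ_int", c.circle_id))
            weights.append(circ_tot[c.circle_id] * (1 - pj))
        probs = np.array(weights)
        total = probs.sum()
        if total <= 0:
            raise ConfigError("empty read mixture")
        return sources, probs / total

    def bsj_rates(self, sample: SampleSpec) -> dict[str, float]:
        """Exact per-circle probability that a read of *sample* is a BSJ read."""
        sources, probs = self.mixture(sample)
        return {
            unit: float(p)
            for (kind, unit), p in zip(sources, probs)
            if kind == "circ_junc"
        }


def plant_truth(
    genome: GenomeRef,
    models: Sequence[GeneModel],
    design: Sequence[SampleSpec],
    seed: int,
    config: Optional[SimConfig] = None,
) -> TruthSet:
    """Plant circles, expression levels and CLIP binding sites.

    Circle classes: ``null`` (identical rates in all conditions),
    ``female_biased``/``male_biased`` (rate fold ``config.fold`` in the
    biased sex, optionally restricted to ``config.bias_tissues``) and
    ``female_specific``/``male_specific`` (rate 0 in the opposite sex).
    Exonic circles sit exactly on annotated exon boundaries; ciRNAs run
    from an intron 5' end to a branch point ``config.branch_offset`` nt
    upstream of the intron 3' end (transcript orientation).
    """
    config = config or SimConfig()
    config.validate()
    for s in design:
        _ = s.stranded  # SampleSpec validates itself on construction
    rng = np.random.default_rng(seed)
    models = list(models)
    gene_by_id = {g.gene_id: g for g in models}

    # -- exonic circle candidates
    exonic_cands = []
    for g in models:
        if g.biotype == "rRNA":
            continue
        if config.coding_hosts_only and g.biotype != "coding":
            continue
        exons = g.canonical.exons
        for i in range(len(exons)):
            for j in range(i, len(exons)):
                acceptor, donor = exons[i][0], exons[j][1]
                mature = sum(e - s for s, e in exons[i : j + 1])
                if mature < config.read_length or donor - acceptor > config.max_span:
                    continue
                exonic_cands.append((g, exons[i : j + 1], acceptor, donor))
    cirna_cands = []
    for g in models:
        if g.biotype == "rRNA":
            continue
        for (s, e) in g.canonical.introns:
            if (e - s) - config.branch_offset < config.read_length:
                continue
            if g.strand == "+":
                acceptor, donor = s, e - config.branch_offset
            else:
                acceptor, donor = s + config.branch_offset, e
            cirna_cands.append((g, acceptor, donor))

    n_exonic = sum(config.class_counts.values())
    order = list(rng.permutation(len(exonic_cands)))
    picked = []
    per_gene: dict[str, int] = {}
    for idx in order:
        g = exonic_cands[idx][0]
        if (
            config.max_circles_per_gene is not None
            and per_gene.get(g.gene_id, 0) >= config.max_circles_per_gene
        ):
            continue
        picked.append(exonic_cands[idx])
        per_gene[g.gene_id] = per_gene.get(g.gene_id, 0) + 1
        if len(picked) == n_exonic:
            break
    if len(picked) < n_exonic:
        raise ConfigError(
            f"requested {n_exonic} exonic circles but only {len(picked)} "
            "candidate exon-boundary pairs are available"
        )
    corder = list(rng.permutation(len(cirna_cands)))[: config.n_cirna]
    if len(corder) < config.n_cirna:
        raise ConfigError(
            f"requested {config.n_cirna} ciRNAs but only {len(corder)} introns qualify"
        )

    class_sequence = [
        cls for cls in CIRCLE_CLASSES for _ in range(config.class_counts.get(cls, 0))
    ]
    circles: list[PlantedCircle] = []
    lo, hi = config.abundance_clip
    for n, (cand, cls) in enumerate(zip(picked, class_sequence)):
        g, chain, acceptor, donor = cand
        a = float(np.clip(np.exp(rng.normal(0.0, config.abundance_sigma)), lo, hi))
        a *= config.class_abundance.get(cls, 1.0)
        circles.append(
            PlantedCircle(
                circle_id=f"pc{n:04d}",
                junction=BackSpliceJunction(g.contig, g.strand, acceptor, donor),
                circ_type="exonic",
                gene_id=g.gene_id,
                exon_chain=tuple(chain),
                mature_length=sum(e - s for s, e in chain),
                cls=cls,
                abundance=a,
            )
        )
    for n, idx in enumerate(corder):
        g, acceptor, donor = cirna_cands[idx]
        a = float(np.clip(np.exp(rng.normal(0.0, config.abundance_sigma)), lo, hi))
        circles.append(
            PlantedCircle(
                circle_id=f"ci{n:04d}",
                junction=BackSpliceJunction(g.contig, g.strand, acceptor, donor),
                circ_type="ciRNA",
                gene_id=g.gene_id,
                exon_chain=(),
                mature_length=donor - acceptor,
                cls="null",
                abundance=a,
            )
        )

    # -- expression
    host_genes = {c.gene_id for c in circles}
    rows = {}
    for g in models:
        base = (
            config.host_tpm
            if (config.host_tpm is not None and g.gene_id in host_genes)
            else float(np.exp(rng.normal(0.0, config.expr_sigma)))
        )
        if config.host_tpm is not None and g.gene_id not in host_genes:
            # put the remaining transcriptome mass on non-host genes so that
            # host TPMs land near the requested value
            n_other = max(1, len(models) - len(host_genes))
            base *= (1e6 - config.host_tpm * len(host_genes)) / n_other
        row = {}
        for sex, tissue in CONDITIONS:
            jitter = (
                float(np.exp(rng.normal(0.0, config.expr_condition_sigma)))
                if config.expr_condition_sigma > 0
                else 1.0
            )
            row[f"{sex}:{tissue}"] = base * jitter
        rows[g.gene_id] = row
    expression = pd.DataFrame.from_dict(rows, orient="index")
    expression = expression[[f"{s}:{t}" for s, t in CONDITIONS]]

    truth = TruthSet(
        genome=GenomeRef(dict(genome.contigs)),
        models=models,
        config=config,
        circles=circles,
        sites=[],
        expression=expression,
    )
    truth.sites = _plant_sites(truth, rng)
    return truth


def _transcript_ts(truth: TruthSet, contig: str, start: int, end: int, strand: str) -> int:
    seq = truth.genome.fetch(contig, start, end, strand)
    return seq.count("T")


def _plant_sites(truth: TruthSet, rng: np.random.Generator) -> list[BindingSite]:
    cfg = truth.config
    if not cfg.site_counts:
        return []
    sites: list[BindingSite] = []
    used: list[tuple[int, int]] = []

    def free(s: int, e: int) -> bool:
        return all(e <= us or s >= ue for us, ue in used)

    def place(fs: int, fe: int, margin: int, contig: str, strand: str) -> Optional[tuple[int, int]]:
        lo = fs + margin
        hi = fe - margin - cfg.site_len
        if hi < lo:
            return None
        for _ in range(20):
            s = int(rng.integers(lo, hi + 1))
            e = s + cfg.site_len
            if free(s, e) and _transcript_ts(truth, contig, s, e, strand) >= cfg.site_min_ts:
                return s, e
        return None

    min_feature = cfg.site_len + 2 * cfg.site_margin
    exonic = [c for c in truth.circles if c.circ_type == "exonic"]
    order = list(rng.permutation(len(exonic)))
    counter = 0

    def feature_choices(circle: PlantedCircle, role: str) -> list[tuple[int, int]]:
        g = truth.genes_by_id[circle.gene_id]
        exons = list(g.canonical.exons)
        introns = list(g.canonical.introns)
        a, d = circle.junction.acceptor, circle.junction.donor
        if role == "bs_exon":
            return [iv for iv in circle.exon_chain if iv[1] - iv[0] >= min_feature]
        if role == "flank_intron":
            out = []
            for s, e in introns:
                if (e == a or s == d) and e - s >= min_feature:
                    out.append((s, e))
            return out
        if role == "flank_exon":
            out = []
            idx_first = next(i for i, iv in enumerate(exons) if iv[0] == a)
            idx_last = next(i for i, iv in enumerate(exons) if iv[1] == d)
            if idx_first > 0:
                out.append(exons[idx_first - 1])
            if idx_last < len(exons) - 1:
                out.append(exons[idx_last + 1])
            return [iv for iv in out if iv[1] - iv[0] >= min_feature]
        raise ValueError(role)

    for role in ("bs_exon", "flank_intron", "flank_exon"):
        need = cfg.site_counts.get(role, 0)
        placed = 0
        for oi in order:
            if placed >= need:
                break
            circle = exonic[oi]
            g = truth.genes_by_id[circle.gene_id]
            for fs, fe in feature_choices(circle, role):
                got = place(fs, fe, cfg.site_margin, g.contig, g.strand)
                if got is None:
                    continue
                s, e = got
                sites.append(
                    BindingSite(f"site{counter:04d}", g.contig, s, e, g.strand,
                                1.0, role, circle.circle_id, g.gene_id)
                )
                used.append((s, e))
                counter += 1
                placed += 1
                break
        if placed < need:
            raise ConfigError(
                f"could only place {placed}/{need} {role!r} binding sites; "
                "plant more/larger circles or relax margins"
            )

    need = cfg.site_counts.get("utr3", 0)
    placed = 0
    coding = [g for g in truth.models if g.biotype == "coding"]
    for gi in rng.permutation(len(coding)):
        if placed >= need:
            break
        g = coding[gi]
        _, utr3 = g.utrs()
        for fs, fe in utr3:
            got = place(fs, fe, cfg.site_margin_loose, g.contig, g.strand)
            if got is None:
                continue
            s, e = got
            sites.append(
                BindingSite(f"site{counter:04d}", g.contig, s, e, g.strand,
                            1.0, "utr3", None, g.gene_id)
            )
            used.append((s, e))
            counter += 1
            placed += 1
            break
    if placed < need:
        raise ConfigError(f"could only place {placed}/{need} 3'UTR binding sites")

    need = cfg.site_counts.get("other", 0)
    placed = 0
    contig = truth.models[0].contig
    spans = sorted(g.span for g in truth.models)
    gaps = []
    prev = 0
    for s, e in spans:
        if s - prev >= min_feature:
            gaps.append((prev, s))
        prev = max(prev, e)
    attempts = 0
    while placed < need and attempts < 200:
        attempts += 1
        fs, fe = gaps[int(rng.integers(0, len(gaps)))]
        strand = "+" if rng.random() < 0.5 else "-"
        got = place(fs, fe, cfg.site_margin_loose, contig, strand)
        if got is None:
            continue
        s, e = got
        sites.append(
            BindingSite(f"site{counter:04d}", contig, s, e, strand,
                        1.0, "other", None, None)
        )
        used.append((s, e))
        counter += 1
        placed += 1
    if placed < need:
        raise ConfigError(f"could only place {placed}/{need} intergenic binding sites")
    return sites


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimReads:
    """A simulated library: (read_id, sequence) pairs plus truth labels."""

    library_id: str
    reads: list[tuple[str, str]]
    truth: pd.DataFrame  # read_id, source, unit

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.reads)


def _apply_errors(
    reads: list[str], rng: np.random.Generator, error_rate: float
) -> list[str]:
    if error_rate <= 0 or not reads:
        return reads
    read_len = len(reads[0])
    ks = rng.binomial(read_len, error_rate, size=len(reads))
    out = reads
    for i in np.nonzero(ks)[0]:
        seq = bytearray(out[i], "ascii")
        for pos in rng.integers(0, len(seq), ks[i]):
            old = seq[pos]
            choices = [b for b in b"ACGT" if b != old]
            seq[pos] = choices[int(rng.integers(0, 3))]
        out[i] = seq.decode()
    return out


def simulate_rnaseq(
    truth: TruthSet, sample: SampleSpec, depth: int, seed: int
) -> SimReads:
    """Simulate one fractionated RNA-seq library of *depth* merged reads.

    Read sources follow :meth:`TruthSet.mixture`; back-splice junction
    reads place the junction uniformly within the read with at least one
    nucleotide on each side.  PolyA reads are emitted in random
    orientation; R-/R+ reads are strand-specific (transcript sense).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    read_len = cfg.read_length
    rows_id: list[str] = []
    rows_src: list[str] = []
    rows_unit: list[str] = []
    rows_off: list[int] = []  # junction offset within the read (-1 otherwise)
    seqs: list[str] = []
    if depth > 0:
        sources, probs = truth.mixture(sample)
        counts = rng.multinomial(depth, probs)
        for (kind, unit), n in zip(sources, counts):
            if n == 0:
                continue
            if kind in ("linear", "rrna"):
                mat = truth.gene_mature(unit)
                if len(mat) < read_len:
                    raise ConfigError(
                        f"transcript of {unit} shorter than read length"
                    )
                starts = rng.integers(0, len(mat) - read_len + 1, n)
                batch = [mat[s : s + read_len] for s in starts]
                label = "linear"
                offsets = [-1] * n
            elif kind == "circ_int":
                mat = truth.circ_mature(unit)
                starts = rng.integers(0, len(mat) - read_len + 1, n)
                batch = [mat[s : s + read_len] for s in starts]
                label = "linear"
                offsets = [-1] * n
            else:  # circ_junc
                mat = truth.circ_mature(unit)
                anchors = rng.integers(1, read_len, n)  # nt left of the junction
                batch = [mat[len(mat) - a :] + mat[: read_len - a] for a in anchors]
                circ = truth.circles_by_id[unit]
                label = "ciRNA-junction" if circ.circ_type == "ciRNA" else "BSJ"
                offsets = [int(a) for a in anchors]
            if not sample.stranded:
                flips = rng.random(n) < 0.5
                batch = [
                    reverse_complement(s) if f else s for s, f in zip(batch, flips)
                ]
            seqs.extend(batch)
            rows_src.extend([label] * n)
            rows_unit.extend([unit] * n)
            rows_off.extend(offsets)
        seqs = _apply_errors(seqs, rng, cfg.error_rate)
        rows_id = [f"{sample.sample_id}.{i:08d}" for i in range(len(seqs))]
    truth_df = pd.DataFrame(
        {"read_id": rows_id, "source": rows_src, "unit": rows_unit,
         "offset": rows_off}
    )
    return SimReads(sample.sample_id, list(zip(rows_id, seqs)), truth_df)


def simulate_parclip(
    truth: TruthSet, library: str, depth: int, seed: int
) -> SimReads:
    """Simulate a PAR-CLIP library ('SXL' pulldown or 'IgG' control).

    The pulldown draws reads centered on planted binding sites with
    Gaussian jitter plus uniform background; every pulldown read
    overlapping a site converts each covered site T (transcript
    orientation) to C with probability ``config.conversion_rate``.  The
    IgG control is uniform background only, with conversions arising only
    from the sequencing error rate.  ``clip_enrichment`` is the planted
    expected pulldown:control enrichment ratio of a site's peak under
    library-size scaling (the same statistic the significance rule
    thresholds); the control library should be deep enough that its +1
    pseudocount is negligible.
    """
    if library not in ("SXL", "IgG"):
        raise ValueError("library must be 'SXL' or 'IgG'")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    R = cfg.clip_read_length
    contigs = sorted(truth.genome.contigs)
    clens = np.array([truth.genome.length(c) for c in contigs], dtype=float)
    g_tot = clens.sum()

    sites = truth.sites if library == "SXL" else []
    if library == "SXL" and sites:
        # Signal budget targeting an expected pulldown:control ratio of
        # ``clip_enrichment`` at each site's peak (the statistic the
        # significance rule thresholds).  With library-size scaling the
        # expected ratio is (s_i + B*f) / (D*f) where f is the expected
        # peak footprint as a fraction of the (two-stranded) genome, B the
        # background read count and D the library depth; solving
        # s_i = f*(enr*aff_i*D - B) summed over sites gives a closed form.
        footprint = cfg.site_len + R // 2 + int(2 * cfg.clip_jitter_sd) + R - 1
        f = footprint / (2.0 * g_tot)
        n_sites = len(sites)
        aff_sum = sum(s.affinity for s in sites)
        signal = f * depth * (cfg.clip_enrichment * aff_sum - n_sites)
        signal /= max(1e-12, 1.0 - f * n_sites)
        signal = float(np.clip(signal, 0.0, 0.9 * depth))
        probs = [(depth - signal) / max(depth, 1)]
        units: list[Optional[BindingSite]] = [None]
        for s in sites:
            share = s.affinity / aff_sum if aff_sum > 0 else 0.0
            probs.append(signal * share / max(depth, 1))
            units.append(s)
        probs = np.array(probs)
        probs = probs / probs.sum()
    else:
        probs = np.array([1.0])
        units = [None]

    # per-contig, per-strand site lookup for conversion marking
    site_ts: dict[str, list[tuple[int, int, list[int]]]] = {}
    for s in truth.sites:
        seq = truth.genome.fetch(s.contig, s.start, s.end, "+")
        if s.strand == "+":
            t_pos = [s.start + i for i, b in enumerate(seq) if b == "T"]
        else:
            t_pos = [s.start + i for i, b in enumerate(seq) if b == "A"]
        site_ts.setdefault(f"{s.contig}:{s.strand}", []).append(
            (s.start, s.end, t_pos)
        )

    counts = rng.multinomial(depth, probs) if depth > 0 else np.zeros(len(probs), int)
    out_seqs: list[str] = []
    rows_src: list[str] = []
    rows_unit: list[str] = []
    placements: list[tuple[str, str, int]] = []
    for unit, n in zip(units, counts):
        if n == 0:
            continue
        if unit is None:
            cidx = rng.choice(len(contigs), size=n, p=clens / g_tot)
            strands = np.where(rng.random(n) < 0.5, "+", "-")
            for ci, st in zip(cidx, strands):
                contig = contigs[ci]
                start = int(rng.integers(0, truth.genome.length(contig) - R + 1))
                placements.append((contig, st, start))
                rows_src.append("CLIP-background")
                rows_unit.append(".")
        else:
            mid = (unit.start + unit.end) // 2
            jitters = np.rint(rng.normal(0.0, cfg.clip_jitter_sd, n)).astype(int)
            cl = truth.genome.length(unit.contig)
            for j in jitters:
                start = int(np.clip(mid + j - R // 2, 0, cl - R))
                placements.append((unit.contig, unit.strand, start))
                rows_src.append("CLIP-signal")
                rows_unit.append(unit.site_id)

    for contig, strand, start in placements:
        seq = truth.genome.fetch(contig, start, start + R, strand)
        if library == "SXL" and cfg.conversion_rate > 0:
            for ss, se, t_pos in site_ts.get(f"{contig}:{strand}", ()):
                if se <= start or ss >= start + R:
                    continue
                b = bytearray(seq, "ascii")
                for gp in t_pos:
                    if start <= gp < start + R and rng.random() < cfg.conversion_rate:
                        idx = gp - start if strand == "+" else (start + R - 1) - gp
                        b[idx] = ord("C")
                seq = b.decode()
        out_seqs.append(seq)
    out_seqs = _apply_errors(out_seqs, rng, cfg.clip_error_rate)
    lib_id = f"clip_{library}"
    rids = [f"{lib_id}.{i:08d}" for i in range(len(out_seqs))]
    truth_df = pd.DataFrame({"read_id": rids, "source": rows_src, "unit": rows_unit})
    return SimReads(lib_id, list(zip(rids, out_seqs)), truth_df)


# ---------------------------------------------------------------------------
# canonical experiment design


def default_design() -> list[SampleSpec]:
    """The full six-condition, three-fraction sample sheet."""
    out = []
    for sex, tissue in CONDITIONS:
        for fraction in ("polyA", "Rminus", "Rplus"):
            out.append(SampleSpec(f"{sex}_{tissue}_{fraction}", sex, tissue, fraction))
    return out
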