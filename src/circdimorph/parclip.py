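"""PAR-CLIP peak calling, T>C crosslink-site analysis and peak annotation.

The pulldown (e.g. SXL) and IgG control libraries are aligned by exact
contiguous scan; T-on-reference read as C is recorded as a
crosslink-induced conversion rather than a mismatch.  Candidate peaks
are maximal coverage runs on one strand; enrichment over IgG is scored
with a one-sided Poisson tail on library-size-scaled counts (a +1
pseudocount on the IgG side keeps the statistic total).  Crosslink-
induced mutation sites (CIMS) inside a peak get an empirical FDR from
read-level permutations that redistribute each read's conversions
uniformly over the reference-T positions it covers.  Final significance
uses a two-branch rule: moderate enrichment (>= 10x, P < 1e-4) requires
a CIMS site at FDR <= 0.3; extreme enrichment (>= 100x, P < 1e-4)
stands on its own.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._align import SubstringIndex
from .core_io import CircCall, GeneModel, GenomeRef

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alignment


@dataclass(frozen=True)
class ClipAlignment:
    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    conversions: tuple[int, ...] = ()  # genomic positions of T>C columns


def clip_genome_index(genome: GenomeRef, read_length: int, max_mm: int = 2) -> SubstringIndex:
    seed = max(12, read_length // (max_mm + 1))
    return SubstringIndex(dict(genome.contigs), seed_len=seed,
                          both_strands=True, tc_aware=True)


def align_clip_reads(
    reads,
    genome: GenomeRef,
    max_mm: int = 2,
    genome_index: Optional[SubstringIndex] = None,
) -> list[ClipAlignment]:
    """Unique-best contiguous alignment of CLIP reads.

    T->C columns (transcript orientation) are conversions and do not
    count toward *max_mm*; any other substitution does.  Reads with
    several equal-quality loci (multi-mappers) are discarded.
    """
    from .bsjcall import iter_reads

    out = []
    idx = genome_index
    stats = {"aligned": 0, "unaligned": 0, "multi": 0}
    for read_id, seq in iter_reads(reads):
        if idx is None:
            idx = clip_genome_index(genome, len(seq), max_mm)
        hits = idx.best_hits(seq, max_mm)
        if not hits:
            stats["unaligned"] += 1
            continue
        if len(hits) > 1:
            stats["multi"] += 1
            continue
        h = hits[0]
        out.append(
            ClipAlignment(read_id, h.name, h.start, h.start + len(seq),
                          h.strand, h.conversions)
        )
        stats["aligned"] += 1
    logger.info("align_clip_reads: %s", stats)
    return out


# ---------------------------------------------------------------------------
# peaks


@dataclass
class CimsSite:
    position: int  # genomic position of the reference T
    k: int  # conversions observed
    m: int  # read coverage
    fdr: float


@dataclass
class Peak:
    peak_id: str
    contig: str
    start: int
    end: int
    strand: str
    sxl_count: int = 0
    igg_count: int = 0
    ratio: float = 0.0
    p_value: float = 1.0
    cims_sites: list[CimsSite] = field(default_factory=list)
    significant: bool = False
    region: str = ""
    circ_assignments: list[tuple[str, str]] = field(default_factory=list)

    @property
    def best_cims_fdr(self) -> float:
        return min((s.fdr for s in self.cims_sites), default=float("nan"))

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _by_strand(alignments: Sequence[ClipAlignment]) -> dict[tuple[str, str], list[ClipAlignment]]:
    groups: dict[tuple[str, str], list[ClipAlignment]] = {}
    for a in alignments:
        groups.setdefault((a.contig, a.strand), []).append(a)
    return groups


def _overlap_count(starts: list[int], ends: list[int], s: int, e: int) -> int:
    # reads sorted by start and (separately) by end; count start < e and end > s
    return len(starts) - (len(starts) - bisect_left(starts, e)) - bisect_right(ends, s)


def call_peaks(
    sxl_alignments: Sequence[ClipAlignment],
    igg_alignments: Sequence[ClipAlignment],
    genome: GenomeRef,
    min_cov: int = 5,
    merge_gap: int = 10,
) -> list[Peak]:
    """Coverage-run candidate peaks with Poisson enrichment P-values.

    A candidate is a maximal run of positions with pulldown coverage >=
    *min_cov* on one strand; runs closer than *merge_gap* are merged.
    ``ratio = (sxl/N_sxl) / ((igg+1)/N_igg)`` with library sizes N;
    ``p_value`` is the upper Poisson tail of observing >= sxl_count reads
    at mean ``(igg_count+1) * N_sxl / N_igg``.
    """
    n_sxl, n_igg = len(sxl_alignments), len(igg_alignments)
    if n_sxl == 0:
        logger.warning("call_peaks: empty pulldown library; no peaks")
        return []
    sxl_groups = _by_strand(sxl_alignments)
    igg_groups = _by_strand(igg_alignments)
    peaks: list[Peak] = []
    counter = 0
    for (contig, strand) in sorted(sxl_groups):
        aligns = sxl_groups[(contig, strand)]
        length = genome.length(contig)
        cov = np.zeros(length + 1, dtype=np.int32)
        for a in aligns:
            cov[a.start] += 1
            cov[a.end] -= 1
        cov = np.cumsum(cov)[:-1]
        above = cov >= min_cov
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        runs = list(zip(edges[::2], edges[1::2]))
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        s_starts = sorted(a.start for a in aligns)
        s_ends = sorted(a.end for a in aligns)
        igg = igg_groups.get((contig, strand), [])
        i_starts = sorted(a.start for a in igg)
        i_ends = sorted(a.end for a in igg)
        for s, e in merged:
            sxl_count = _overlap_count(s_starts, s_ends, s, e)
            igg_count = _overlap_count(i_starts, i_ends, s, e) if igg else 0
            n_igg_eff = max(n_igg, 1)
            ratio = (sxl_count / n_sxl) / ((igg_count + 1) / n_igg_eff)
            mu = (igg_count + 1) * n_sxl / n_igg_eff
            p = float(sps.poisson.sf(sxl_count - 1, mu))
            peaks.append(
                Peak(f"peak{counter:05d}", contig, int(s), int(e), strand,
                     sxl_count, igg_count, ratio, p)
            )
            counter += 1
    return peaks


# ---------------------------------------------------------------------------
# CIMS


def find_cims(
    peak: Peak,
    sxl_alignments: Sequence[ClipAlignment],
    genome: GenomeRef,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CimsSite]:
    """Crosslink-induced mutation sites within a peak, with permutation FDR.

    Candidate sites are reference-T positions (transcript orientation)
    with >= 2 observed conversions.  In each permutation round every read
    redistributes its conversions uniformly over the reference-T
    positions it covers inside the peak; FDR(site with k conversions) =
    (mean permuted count of positions with k' >= k) / (observed count of
    positions with >= k conversions), clamped to [0, 1].
    """
    base = "T" if peak.strand == "+" else "A"
    seq = genome.fetch(peak.contig, peak.start, peak.end, "+")
    t_pos = [peak.start + i for i, b in enumerate(seq) if b == base]
    if not t_pos:
        return []
    t_index = {p: i for i, p in enumerate(t_pos)}
    n_t = len(t_pos)

    obs = np.zeros(n_t, dtype=int)
    cover = np.zeros(n_t, dtype=int)
    read_specs = []  # (covered T indices, number of conversions)
    for a in sxl_alignments:
        if a.contig != peak.contig or a.strand != peak.strand:
            continue
        if a.end <= peak.start or a.start >= peak.end:
            continue
        lo = bisect_left(t_pos, a.start)
        hi = bisect_left(t_pos, a.end)
        if lo == hi:
            continue
        covered = np.arange(lo, hi)
        cover[covered] += 1
        c = 0
        for conv in a.conversions:
            if conv in t_index and a.start <= conv < a.end:
                obs[t_index[conv]] += 1
                c += 1
        if c > 0:
            read_specs.append((covered, min(c, len(covered))))

    sites = [i for i in range(n_t) if obs[i] >= 2]
    if not sites:
        return []
    rng = np.random.default_rng(seed)
    perm = np.zeros((n_perm, n_t), dtype=np.int32)
    for covered, c in read_specs:
        t = len(covered)
        if c >= t:
            perm[:, covered] += 1
            continue
        rand = rng.random((n_perm, t))
        chosen = np.argpartition(rand, c - 1, axis=1)[:, :c]
        rows = np.repeat(np.arange(n_perm), c)
        np.add.at(perm, (rows, covered[chosen].ravel()), 1)

    out = []
    for i in sites:
        k = int(obs[i])
        numer = float((perm >= k).sum(axis=1).mean())
        denom = int((obs >= k).sum())
        fdr = min(1.0, max(0.0, numer / denom)) if denom else 1.0
        out.append(CimsSite(t_pos[i], k, int(cover[i]), fdr))
    return out


# ---------------------------------------------------------------------------
# significance


def significant_peaks(
    peaks: Sequence[Peak],
    ratio_low: float = 10.0,
    ratio_high: float = 100.0,
    p_max: float = 1e-4,
    cims_fdr_max: float = 0.3,
) -> list[Peak]:
    """Two-branch significance rule; flags peaks in place, returns the kept.

    Branch (i): ratio >= ratio_low, P < p_max, and some CIMS site with
    FDR <= cims_fdr_max.  Branch (ii): ratio >= ratio_high and P < p_max
    regardless of CIMS.
    """
    kept = []
    for p in peaks:
        has_cims = any(s.fdr <= cims_fdr_max for s in p.cims_sites)
        p.significant = bool(
            p.p_value < p_max
            and (p.ratio >= ratio_high or (p.ratio >= ratio_low and has_cims))
        )
        if p.significant:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# annotation


REGION_CATEGORIES = ("5UTR", "CDS", "3UTR", "exon_noncoding", "intron", "intergenic")


def _region_lengths(models: Sequence[GeneModel], genome: GenomeRef) -> dict[str, int]:
    lengths = dict.fromkeys(REGION_CATEGORIES, 0)
    covered = 0
    for g in models:
        t = g.canonical
        covered += t.span[1] - t.span[0]
        lengths["intron"] += sum(e - s for s, e in t.introns)
        if g.biotype == "coding" and t.cds is not None:
            u5, u3 = g.utrs(t)
            lengths["5UTR"] += sum(e - s for s, e in u5)
            lengths["3UTR"] += sum(e - s for s, e in u3)
            lengths["CDS"] += t.cds_exonic_length
        else:
            lengths["exon_noncoding"] += t.exonic_length
    total = sum(genome.length(c) for c in genome.contigs)
    lengths["intergenic"] = max(0, total - covered)
    return lengths


def assign_genomic_region(
    peaks: Sequence[Peak],
    models: Sequence[GeneModel],
    genome: GenomeRef,
) -> pd.DataFrame:
    """Label peaks by the genomic category of their midpoint.

    Precedence exon > intron > intergenic over same-strand genes; exonic
    midpoints in coding genes are sub-labelled 5'UTR / CDS / 3'UTR by the
    canonical transcript.  Returns the per-category peak count and
    density (peaks per kb of annotated category length); each peak's
    ``region`` is set in place.
    """
    for p in peaks:
        mid = p.midpoint()
        label = "intergenic"
        for g in models:
            if g.contig != p.contig or g.strand != p.strand:
                continue
            t = g.canonical
            if not (t.span[0] <= mid < t.span[1]):
                continue
            in_exon = any(s <= mid < e for s, e in t.exons)
            if in_exon:
                if g.biotype == "coding" and t.cds is not None:
                    u5, u3 = g.utrs(t)
                    if any(s <= mid < e for s, e in u5):
                        label = "5UTR"
                    elif any(s <= mid < e for s, e in u3):
                        label = "3UTR"
                    else:
                        label = "CDS"
                else:
                    label = "exon_noncoding"
                break
            if label == "intergenic":
                label = "intron"
        p.region = label
    counts = pd.Series([p.region for p in peaks]).value_counts()
    lengths = _region_lengths(models, genome)
    rows = []
    for cat in REGION_CATEGORIES:
        n = int(counts.get(cat, 0))
        kb = lengths[cat] / 1000.0
        rows.append({"region": cat, "peaks": n, "kb": kb,
                     "density_per_kb": (n / kb) if kb else float("nan")})
    return pd.DataFrame(rows).set_index("region")


CIRC_CATEGORIES = ("bs_exon", "flank_intron", "flank_exon")


def assign_circ_region(
    peaks: Sequence[Peak],
    calls: Sequence[CircCall],
    models: Sequence[GeneModel],
) -> pd.DataFrame:
    """Assign peaks to circRNA-relative categories.

    For each (peak, exonic call) on the same gene and strand: *bs_exon*
    iff the peak overlaps an exon of the circle's chain; *flank_intron*
    iff it overlaps the intron immediately outside either circle
    boundary; *flank_exon* iff it overlaps the nearest annotated exon
    outside the circle on either side.  One peak may collect several
    categories across calls (category percentages can sum above 100%).
    Calls at a transcript terminus simply lack the missing flank.
    Returns the long-form (peak_id, junction_id, category) table and
    records assignments on each peak.
    """
    gene_by_id = {g.gene_id: g for g in models}
    rows = []
    for call in calls:
        if call.circ_type != "exonic" or not call.gene_id:
            continue
        g = gene_by_id[call.gene_id]
        t = g.canonical
        exons = list(t.exons)
        introns = list(t.introns)
        a, d = call.junction.acceptor, call.junction.donor
        up_intron = next(((s, e) for s, e in introns if e == a), None)
        down_intron = next(((s, e) for s, e in introns if s == d), None)
        idx_first = next((i for i, iv in enumerate(exons) if iv[0] == a), None)
        idx_last = next((i for i, iv in enumerate(exons) if iv[1] == d), None)
        up_exon = exons[idx_first - 1] if idx_first else None
        down_exon = (
            exons[idx_last + 1]
            if idx_last is not None and idx_last < len(exons) - 1
            else None
        )
        features: list[tuple[str, tuple[int, int]]] = [
            ("bs_exon", iv) for iv in call.exon_chain
        ]
        for cat, iv in (("flank_intron", up_intron), ("flank_intron", down_intron),
                        ("flank_exon", up_exon), ("flank_exon", down_exon)):
            if iv is not None:
                features.append((cat, iv))
        for p in peaks:
            if p.contig != g.contig or p.strand != g.strand:
                continue
            cats = set()
            for cat, (s, e) in features:
                if p.start < e and p.end > s:
                    cats.add(cat)
            for cat in sorted(cats):
                p.circ_assignments.append((call.call_id, cat))
                rows.append({"peak_id": p.peak_id, "junction_id": call.call_id,
                             "category": cat})
    return pd.DataFrame(rows, columns=["peak_id", "junction_id", "category"])


# ---------------------------------------------------------------------------
# k-mer enrichment


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving dinucleotide composition."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    for _ in range(100):
        # pick a random terminal edge for every non-final vertex
        terminal = {}
        for v in vertices:
            if v == last:
                continue
            terminal[v] = edges[v][int(rng.integers(0, len(edges[v])))]
        # the terminal edges must lead every vertex to `last`
        ok = True
        for v in terminal:
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in terminal:
                    ok = False
                    break
                seen.add(u)
                u = terminal[u]
            if not ok:
                break
        if ok:
            break
    else:
        return seq
    shuffled = {}
    for v in vertices:
        rest = list(edges[v])
        if v in terminal:
            rest.remove(terminal[v])
        rng.shuffle(rest)
        if v in terminal:
            rest.append(terminal[v])
        shuffled[v] = rest
    out = [seq[0]]
    pos = {v: 0 for v in vertices}
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[u][pos[u]]
        pos[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def kmer_enrichment(
    sequences: Sequence[str],
    k: int = 5,
    n_shuffle: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """k-mer z-scores against dinucleotide-preserving shuffled backgrounds.

    ``z = (observed - mean_shuffled) / sd_shuffled`` per k-mer, ranked
    descending.  Sequences shorter than k are skipped.
    """
    seqs = [s.upper() for s in sequences if len(s) >= k]
    if not seqs:
        raise ValueError("no sequence of length >= k")
    rng = np.random.default_rng(seed)

    def count(seq_list: Sequence[str]) -> dict[str, int]:
        c: dict[str, int] = {}
        for s in seq_list:
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                c[w] = c.get(w, 0) + 1
        return c

    observed = count(seqs)
    bg = {w: np.zeros(n_shuffle) for w in observed}
    for r in range(n_shuffle):
        shuffled = [_dinucleotide_shuffle(s, rng) for s in seqs]
        for w, n in count(shuffled).items():
            if w in bg:
                bg[w][r] = n
    rows = []
    for w, obs in observed.items():
        mean = float(bg[w].mean())
        sd = float(bg[w].std(ddof=1)) if n_shuffle > 1 else 0.0
        z = (obs - mean) / sd if sd > 0 else 0.0
        rows.append({"kmer": w, "observed": obs, "mean_shuffled": mean,
                     "sd_shuffled": sd, "z": z})
    df = pd.DataFrame(rows).sort_values("z", ascending=False, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# output


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """BED6+4: name, score=ratio, strand, then p_value, best CIMS FDR,
    significant, region."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [p.contig, str(p.start), str(p.end), p.peak_id,
                     f"{p.ratio:.3f}", p.strand, f"{p.p_value:.3e}",
                     f"{p.best_cims_fdr:.3f}", str(int(p.significant)),
                     p.region or "."]
                ) + "\n"
            )
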