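"""Back-splice junction (BSJ) read detection against a junction library.

Instead of chimeric alignment, candidate junctions are enumerated from
the annotation: for every gene, every ordered pair of exon boundaries of
the canonical transcript defines an exonic back-splice junction, and
every intron defines a family of lariat junctions (intron 5' end joined
to branch-point positions near the intron 3' end).  Each junction gets a
*probe*: the last L nt of the circle's mature sequence followed by its
first L nt (transcript orientation), with ``L = read_length -
min_anchor``.  A read is assigned to a junction when it matches the
probe with the junction placed at least ``min_anchor`` nt from both read
ends and at most ``max_mm`` substitutions; the minimum-anchor rule
mirrors the chimeric-segment minimum used by splice-aware aligners.

Matching is exact-first (hash lookup of the whole read against all
valid probe windows), with a seed-and-verify fallback for ``max_mm >=
1``: the read is cut into ``max_mm + 1`` segments, any error-free
segment locates the candidate probe window, and the full overlap is
verified by Hamming comparison.  Reads that also match a linear
(non-junction) locus of the genome at equal or better quality are
flagged non-unique and excluded from counting.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from ._align import SubstringIndex
from .core_io import (
    BackSpliceJunction,
    CircCall,
    GeneModel,
    GenomeRef,
    reverse_complement,
)

logger = logging.getLogger(__name__)

ReadSource = Union[str, Path, Iterable[tuple[str, str]]]


def iter_reads(source: ReadSource) -> Iterable[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ path, SimReads or pairs."""
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.FastxFile(str(source)) as fh:
            for rec in fh:
                yield rec.name, rec.sequence.upper()
        return
    if hasattr(source, "reads"):  # synthio.SimReads
        yield from source.reads
        return
    yield from source


# ---------------------------------------------------------------------------
# junction library


@dataclass(frozen=True)
class JunctionEntry:
    junction: BackSpliceJunction
    kind: str  # 'exonic-BSJ' | 'lariat'
    gene_id: Optional[str]
    probe: str
    jpos: int  # offset of the junction within the probe
    exon_chain: tuple[tuple[int, int], ...] = ()

    @property
    def junction_id(self) -> str:
        return self.junction.junction_id


class JunctionLibrary:
    """Probe collection indexed for exact and seeded approximate lookup."""

    def __init__(self, entries: dict[str, JunctionEntry], read_length: int,
                 min_anchor: int) -> None:
        self.entries = entries
        self.read_length = read_length
        self.min_anchor = min_anchor
        self._window_index: Optional[dict[str, list[tuple[str, int]]]] = None
        self._segment_index: Optional[dict[str, list[tuple[str, int]]]] = None
        self._segment_len: Optional[int] = None

    def __len__(self) -> int:
        return len(self.entries)

    def _valid_anchor_range(self, entry: JunctionEntry) -> range:
        # junction offset a within a read: probe window [jpos-a, jpos-a+R)
        R = self.read_length
        lo = max(self.min_anchor, self.min_anchor, R - (len(entry.probe) - entry.jpos))
        hi = min(R - self.min_anchor, entry.jpos)
        return range(lo, hi + 1)

    def window_index(self) -> dict[str, list[tuple[str, int]]]:
        """read-length probe windows -> [(junction_id, junction offset)]."""
        if self._window_index is None:
            idx: dict[str, list[tuple[str, int]]] = {}
            R = self.read_length
            for jid, entry in self.entries.items():
                for a in self._valid_anchor_range(entry):
                    w = entry.probe[entry.jpos - a : entry.jpos - a + R]
                    idx.setdefault(w, []).append((jid, a))
            self._window_index = idx
        return self._window_index

    def segment_index(self, n_segments: int) -> tuple[dict[str, list[tuple[str, int]]], int]:
        seg_len = self.read_length // n_segments
        if self._segment_index is None or self._segment_len != seg_len:
            idx: dict[str, list[tuple[str, int]]] = {}
            for jid, entry in self.entries.items():
                p = entry.probe
                for off in range(0, len(p) - seg_len + 1):
                    idx.setdefault(p[off : off + seg_len], []).append((jid, off))
            self._segment_index = idx
            self._segment_len = seg_len
        return self._segment_index, seg_len


def build_bsj_library(
    models: Sequence[GeneModel],
    genome: GenomeRef,
    read_length: int = 100,
    min_anchor: int = 10,
    max_span: int = 100_000,
    branch_window: tuple[int, int] = (15, 50),
    branch_step: int = 5,
) -> JunctionLibrary:
    """Enumerate candidate back-splice junctions and build their probes.

    Exonic junctions: all ordered exon-boundary pairs (i <= j) of each
    gene's canonical transcript, restricted to one gene and a genomic
    span of at most *max_span*.  Lariat junctions: each intron's 5' end
    joined to branch-point positions ``branch_window[0]..branch_window[1]``
    nt upstream of the intron 3' end (transcript orientation), stepped by
    *branch_step*.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    if read_length <= 2 * min_anchor:
        raise ValueError("read_length must exceed 2 * min_anchor")
    L = read_length - min_anchor
    entries: dict[str, JunctionEntry] = {}
    ambiguous_genes: set[str] = set()
    n_truncated = 0

    def add(junction: BackSpliceJunction, kind: str, gene_id: str,
            mature: str, chain: tuple[tuple[int, int], ...]) -> None:
        nonlocal n_truncated
        side = min(L, len(mature))
        if side < L:
            n_truncated += 1
        probe = mature[-side:] + mature[:side]
        jid = junction.junction_id
        if jid in entries:
            if entries[jid].gene_id != gene_id:
                ambiguous_genes.add(jid)
            return
        entries[jid] = JunctionEntry(junction, kind, gene_id, probe, side, chain)

    for g in models:
        t = g.canonical
        exons = t.exons
        plus_seqs = [genome.fetch(g.contig, s, e, "+") for s, e in exons]
        for i in range(len(exons)):
            for j in range(i, len(exons)):
                acceptor, donor = exons[i][0], exons[j][1]
                if donor - acceptor > max_span:
                    continue
                mature = "".join(plus_seqs[i : j + 1])
                if g.strand == "-":
                    mature = reverse_complement(mature)
                add(
                    BackSpliceJunction(g.contig, g.strand, acceptor, donor),
                    "exonic-BSJ",
                    g.gene_id,
                    mature,
                    tuple(exons[i : j + 1]),
                )
        for (s, e) in t.introns:
            for b in range(branch_window[0], branch_window[1] + 1, branch_step):
                if (e - s) - b < 2 * min_anchor:
                    continue
                if g.strand == "+":
                    acceptor, donor = s, e - b
                else:
                    acceptor, donor = s + b, e
                mature = genome.fetch(g.contig, acceptor, donor, g.strand)
                add(
                    BackSpliceJunction(g.contig, g.strand, acceptor, donor),
                    "lariat",
                    g.gene_id,
                    mature,
                    (),
                )
    if n_truncated:
        logger.warning(
            "%d probes truncated (circle mature sequence shorter than %d nt)",
            n_truncated, L,
        )
    for jid in ambiguous_genes:
        e = entries[jid]
        entries[jid] = JunctionEntry(e.junction, e.kind, None, e.probe, e.jpos,
                                     e.exon_chain)
        logger.warning("junction %s maps to multiple genes; gene unset", jid)
    return JunctionLibrary(entries, read_length, min_anchor)


# ---------------------------------------------------------------------------
# read scanning


def linear_genome_index(
    genome: GenomeRef, read_length: int, max_mm: int
) -> SubstringIndex:
    """Both-strand genome index used for the linear-locus uniqueness check.

    Build once and pass to :func:`scan_reads` when scanning many samples
    against the same genome.
    """
    return SubstringIndex(
        dict(genome.contigs),
        seed_len=min(50, max(20, read_length // (max_mm + 1))),
        both_strands=True,
    )


@dataclass(frozen=True)
class BsjAssignment:
    read_id: str
    junction_id: str
    offset: int  # junction position within the read (= left anchor length)
    mismatches: int
    unique_best: bool


def _hamming_window(read: str, probe: str, start: int, max_mm: int) -> Optional[int]:
    if start < 0 or start + len(read) > len(probe):
        return None
    window = probe[start : start + len(read)]
    if window == read:
        return 0
    mm = 0
    for a, b in zip(read, window):
        if a != b:
            mm += 1
            if mm > max_mm:
                return None
    return mm


def scan_reads(
    reads: ReadSource,
    library: JunctionLibrary,
    max_mm: int = 1,
    stranded: bool = True,
    genome: Optional[GenomeRef] = None,
    genome_index: Optional[SubstringIndex] = None,
) -> list[BsjAssignment]:
    """Assign reads to back-splice junctions.

    A read is assigned iff some probe alignment places the junction with
    >= min_anchor nt on each side and <= max_mm mismatches.  Among
    candidates the fewest mismatches wins; ties between distinct
    junctions, or an equal-quality contiguous match to the genome
    (*genome* given), mark the assignment ``unique_best=False`` — such
    assignments are excluded from counting downstream.  Unstranded reads
    are scanned in both orientations.
    """
    R = library.read_length
    min_anchor = library.min_anchor
    window_idx = library.window_index()
    seg_idx = seg_len = None
    if max_mm > 0:
        seg_idx, seg_len = library.segment_index(max_mm + 1)
    genome_idx = genome_index
    if genome_idx is None and genome is not None:
        genome_idx = linear_genome_index(genome, R, max_mm)

    stats = Counter()
    out: list[BsjAssignment] = []
    entries = library.entries

    def candidates(seq: str) -> list[tuple[str, int, int]]:
        found = window_idx.get(seq)
        cands: dict[tuple[str, int], int] = {}
        if found:
            for jid, a in found:
                cands[(jid, a)] = 0
        if max_mm > 0:
            seen_aln: set[tuple[str, int]] = set()
            for si in range(max_mm + 1):
                off = si * seg_len
                for jid, poff in seg_idx.get(seq[off : off + seg_len], ()):
                    start = poff - off
                    key = (jid, start)
                    if key in seen_aln:
                        continue
                    seen_aln.add(key)
                    entry = entries[jid]
                    a = entry.jpos - start
                    if a < min_anchor or R - a < min_anchor:
                        continue
                    if (jid, a) in cands:
                        continue
                    mm = _hamming_window(seq, entry.probe, start, max_mm)
                    if mm is not None:
                        cands[(jid, a)] = mm
        return [(jid, a, mm) for (jid, a), mm in cands.items()]

    for read_id, seq in iter_reads(reads):
        if len(seq) < 2 * min_anchor:
            stats["too_short"] += 1
            continue
        if len(seq) != R:
            stats["wrong_length"] += 1
            continue
        cands = candidates(seq)
        if not stranded:
            rc = reverse_complement(seq)
            cands += candidates(rc)
        if not cands:
            stats["unassigned"] += 1
            continue
        best_mm = min(mm for _, _, mm in cands)
        best = [(jid, a) for jid, a, mm in cands if mm == best_mm]
        jids = {jid for jid, _ in best}
        unique = len(jids) == 1
        if unique and genome_idx is not None:
            if genome_idx.query(seq, best_mm):
                unique = False
                stats["linear_tie"] += 1
        jid, a = min(best)
        stats["assigned" if unique else "ambiguous"] += 1
        out.append(BsjAssignment(read_id, jid, a, best_mm, unique))
    logger.info("scan_reads: %s", dict(stats))
    return out


# ---------------------------------------------------------------------------
# aggregation and typing


def aggregate_calls(
    assignments: dict[str, Sequence[BsjAssignment]],
    library: JunctionLibrary,
    models: Sequence[GeneModel],
    branch_window: tuple[int, int] = (15, 50),
) -> list[CircCall]:
    """Aggregate unique-best assignments into per-junction CircCalls.

    One call per junction with at least one unique-best assignment in any
    sample; counts are per-sample assignment totals; the exon chain and
    cognate gene come from the junction library; the circle type is
    re-derived from the annotation via :func:`classify_call`.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for sample_id, asns in assignments.items():
        for a in asns:
            if a.unique_best:
                counts[a.junction_id][sample_id] += 1
    sample_ids = list(assignments)
    calls = []
    for jid in sorted(counts):
        entry = library.entries[jid]
        circ_type = classify_call(entry.junction, models, branch_window)
        calls.append(
            CircCall(
                junction=entry.junction,
                circ_type=circ_type,
                gene_id=entry.gene_id,
                exon_chain=entry.exon_chain if circ_type == "exonic" else (),
                counts={s: counts[jid].get(s, 0) for s in sample_ids},
            )
        )
    return calls


def classify_call(
    junction: BackSpliceJunction,
    models: Sequence[GeneModel],
    branch_window: tuple[int, int] = (15, 50),
) -> str:
    """Type a junction: exonic circRNA, intronic ciRNA, or unassigned.

    ``exonic``: both boundaries coincide exactly with annotated exon
    boundaries of one gene on the junction strand.  ``ciRNA``: the
    interval lies within one intron, starts at the intron 5' end
    (strand-aware) and ends within the branch-point window upstream of
    the intron 3' end.  Everything else is ``unassigned`` and excluded
    from cohort statistics downstream.
    """
    lo, hi = branch_window
    for g in models:
        if g.contig != junction.contig or g.strand != junction.strand:
            continue
        if junction.acceptor in g.exon_starts() and junction.donor in g.exon_ends():
            return "exonic"
    for g in models:
        if g.contig != junction.contig or g.strand != junction.strand:
            continue
        for t in g.transcripts:
            for (s, e) in t.introns:
                if not (s <= junction.acceptor and junction.donor <= e):
                    continue
                if g.strand == "+":
                    if junction.acceptor == s and e - hi <= junction.donor <= e - lo:
                        return "ciRNA"
                else:
                    if junction.donor == e and s + lo <= junction.acceptor <= s + hi:
                        return "ciRNA"
    return "unassigned"


def summarize_structure(
    calls: Sequence[CircCall], models: Sequence[GeneModel]
) -> dict:
    """Cohort structure summaries over typed calls.

    Returns per-call metrics plus: gene-region origin fractions, the
    circles-per-gene histogram, the exon-count histogram (exonic calls)
    and the median mature length.  Unassigned calls are excluded.
    """
    gene_by_id = {g.gene_id: g for g in models}
    rows = []
    for c in calls:
        if c.circ_type == "unassigned":
            continue
        origin = "intronic" if c.circ_type == "ciRNA" else "middle"
        if c.circ_type == "exonic" and c.gene_id in gene_by_id:
            g = gene_by_id[c.gene_id]
            if g.biotype != "coding":
                origin = "noncoding"
            else:
                exons = g.canonical.exons
                has_first = c.exon_chain[0] == exons[0]
                has_last = c.exon_chain[-1] == exons[-1]
                if g.strand == "-":
                    has_first, has_last = has_last, has_first
                if has_first and has_last:
                    origin = "full_span"
                elif has_first:
                    origin = "5_terminal"
                elif has_last:
                    origin = "3_terminal"
        rows.append(
            {
                "junction_id": c.call_id,
                "circ_type": c.circ_type,
                "gene_id": c.gene_id,
                "n_exons": c.n_exons,
                "mature_length": c.mature_length,
                "origin": origin,
            }
        )
    per_call = pd.DataFrame(
        rows,
        columns=["junction_id", "circ_type", "gene_id", "n_exons",
                 "mature_length", "origin"],
    )
    if len(per_call):
        origin_fractions = per_call["origin"].value_counts(normalize=True)
        circs_per_gene = per_call.groupby("gene_id").size().value_counts().sort_index()
        exonic = per_call[per_call["circ_type"] == "exonic"]
        exon_count_hist = exonic["n_exons"].value_counts().sort_index()
        median_length = float(per_call["mature_length"].median())
    else:
        origin_fractions = pd.Series(dtype=float)
        circs_per_gene = pd.Series(dtype=int)
        exon_count_hist = pd.Series(dtype=int)
        median_length = float("nan")
    return {
        "per_call": per_call,
        "origin_fractions": origin_fractions,
        "circles_per_gene_hist": circs_per_gene,
        "exon_count_hist": exon_count_hist,
        "median_length": median_length,
    }


# ---------------------------------------------------------------------------
# tabular outputs


def assignments_table(assignments: Sequence[BsjAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "junction_id": a.junction_id,
                "offset": a.offset,
                "mismatches": a.mismatches,
                "unique_best": a.unique_best,
            }
            for a in assignments
        ],
        columns=["read_id", "junction_id", "offset", "mismatches", "unique_best"],
    )


def counts_matrix(calls: Sequence[CircCall]) -> pd.DataFrame:
    """Junction x sample BSJ count matrix from aggregated calls."""
    data = {c.call_id: c.counts for c in calls}
    df = pd.DataFrame.from_dict(data, orient="index").fillna(0).astype(int)
    return df.sort_index()
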