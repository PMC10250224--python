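"""Shared data model, coordinate conventions and on-disk formats.

All coordinates are 0-based, half-open (BED convention) throughout the
package.  GTF input/output converts to and from the 1-based inclusive
convention at the boundary, and nowhere else.

A back-splice junction joins an upstream 3' splice site (the *acceptor*,
the genomic start of the upstream-most circularized exon) to a downstream
5' splice site (the *donor*, the genomic end of the downstream-most
circularized exon).  Junction identity is purely genomic:
``(contig, strand, acceptor, donor)`` with ``acceptor < donor``; the
upstream/downstream roles are resolved strand-aware only when splice-site
roles matter.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

BIOTYPES = ("coding", "noncoding", "rRNA")
FRACTIONS = ("polyA", "Rminus", "Rplus")
SEXES = ("F", "M")
TISSUES = ("head", "body", "gonad")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or internally inconsistent annotation."""


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeRef:
    """In-memory reference genome: contig name -> uppercase sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
        self.contigs = {n: s.upper() for n, s in self.contigs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on *contig*; reverse complement on '-'."""
        if contig not in self.contigs:
            raise LookupError(f"contig {contig!r} not in genome")
        seq = self.contigs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"[{start}, {end}) outside contig {contig!r} of length {len(seq)}"
            )
        sub = seq[start:end]
        return reverse_complement(sub) if strand == "-" else sub

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeRef":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]).upper() for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.contigs):
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene model

Interval = tuple[int, int]


@dataclass(frozen=True)
class Transcript:
    """One exon chain.  ``exons`` are genomic, sorted, non-overlapping;
    ``cds`` is the genomic span of the coding region (may bridge introns)."""

    transcript_id: str
    exons: tuple[Interval, ...]
    cds: Optional[Interval] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(
                f"transcript {self.transcript_id!r} has no exons"
            )
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: empty exon [{s},{e})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: exons unsorted/overlap"
                )
            if prev_end is not None and s == prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: zero-length intron"
                )
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.exons[0][0] <= cs < ce <= self.exons[-1][1]):
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: CDS outside exon span"
                )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def cds_exonic_length(self) -> int:
        if self.cds is None:
            return 0
        cs, ce = self.cds
        return sum(max(0, min(e, ce) - max(s, cs)) for s, e in self.exons)


@dataclass
class GeneModel:
    """A gene with one or more transcripts on one strand of one contig."""

    gene_id: str
    contig: str
    strand: str
    biotype: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id!r}: bad strand")
        if self.biotype not in BIOTYPES:
            raise AnnotationError(
                f"gene {self.gene_id!r}: biotype {self.biotype!r} not in {BIOTYPES}"
            )
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id!r} has no transcripts")

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def canonical(self) -> Transcript:
        """Canonical transcript: longest CDS, then longest exonic length,
        then lexicographic id (deterministic tie-break)."""
        return max(
            self.transcripts,
            key=lambda t: (t.cds_exonic_length, t.exonic_length, t.transcript_id),
        )

    def exon_starts(self) -> set[int]:
        return {s for t in self.transcripts for s, _ in t.exons}

    def exon_ends(self) -> set[int]:
        return {e for t in self.transcripts for _, e in t.exons}

    def utrs(self, transcript: Optional[Transcript] = None) -> tuple[list[Interval], list[Interval]]:
        """(5'UTR, 3'UTR) exonic intervals for *transcript* (default canonical).

        Strand-aware: on '-', the 5'UTR is the exonic region with genomic
        coordinates above the CDS end.  Empty lists when there is no CDS.
        """
        t = transcript or self.canonical
        if t.cds is None:
            return [], []
        cs, ce = t.cds
        low, high = [], []
        for s, e in t.exons:
            if s < cs:
                low.append((s, min(e, cs)))
            if e > ce:
                high.append((max(s, ce), e))
        if self.strand == "+":
            return low, high
        return high, low


# ---------------------------------------------------------------------------
# sample sheet


@dataclass(frozen=True)
class SampleSpec:
    """One sequencing library: sex x tissue x RNA fraction."""

    sample_id: str
    sex: str
    tissue: str
    fraction: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sample {self.sample_id!r}: sex must be F or M")
        if self.tissue not in TISSUES:
            raise ValueError(f"sample {self.sample_id!r}: tissue {self.tissue!r}")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"sample {self.sample_id!r}: fraction {self.fraction!r}")

    @property
    def stranded(self) -> bool:
        # R-/R+ libraries are strand-specific; polyA is not.
        return self.fraction != "polyA"

    @property
    def condition(self) -> tuple[str, str]:
        return (self.sex, self.tissue)


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    samples = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["sample_id", "sex", "tissue", "fraction"]
        if header[: len(required)] != required:
            raise ValueError(
                f"sample sheet must start with columns {required}, got {header}"
            )
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            spec = SampleSpec(*fields[:4])
            key = (spec.sex, spec.tissue, spec.fraction)
            if key in seen:
                raise ValueError(f"duplicate (sex, tissue, fraction) {key}")
            seen.add(key)
            samples.append(spec)
    return samples


def write_sample_sheet(samples: Sequence[SampleSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\ttissue\tfraction\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.tissue}\t{s.fraction}\n")


# ---------------------------------------------------------------------------
# junctions and calls


@dataclass(frozen=True, order=True)
class BackSpliceJunction:
    """Genomic identity of a circle-closing junction (acceptor < donor)."""

    contig: str
    strand: str
    acceptor: int  # genomic start of the circle (0-based)
    donor: int  # genomic end of the circle (half-open)

    def __post_init__(self) -> None:
        if not self.acceptor < self.donor:
            raise ValueError(
                f"junction requires acceptor < donor, got {self.acceptor}, {self.donor}"
            )

    @property
    def junction_id(self) -> str:
        return f"{self.contig}:{self.acceptor}-{self.donor}({self.strand})"

    @classmethod
    def from_id(cls, jid: str) -> "BackSpliceJunction":
        loc, strand = jid[:-1].rsplit("(", 1)
        contig, rng = loc.rsplit(":", 1)
        a, d = rng.split("-")
        return cls(contig, strand, int(a), int(d))


CIRC_TYPES = ("exonic", "ciRNA", "unassigned")


@dataclass
class CircCall:
    """One circular RNA call with per-sample BSJ read counts."""

    junction: BackSpliceJunction
    circ_type: str = "unassigned"
    gene_id: Optional[str] = None
    exon_chain: tuple[Interval, ...] = ()
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.circ_type not in CIRC_TYPES:
            raise ValueError(f"unknown circ_type {self.circ_type!r}")
        if (self.circ_type == "exonic") != bool(self.exon_chain):
            raise ValueError("exon_chain present iff circ_type == 'exonic'")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative BSJ count")

    @property
    def call_id(self) -> str:
        return self.junction.junction_id

    @property
    def mature_length(self) -> int:
        if self.circ_type == "exonic":
            return sum(e - s for s, e in self.exon_chain)
        return self.junction.donor - self.junction.acceptor

    @property
    def n_exons(self) -> int:
        return len(self.exon_chain) if self.circ_type == "exonic" else 0


def mature_sequence(call: CircCall, genome: GenomeRef) -> str:
    """Mature (spliced, transcript-orientation) sequence of a circle.

    Exonic circles concatenate exon sequences; the concatenation is
    reverse-complemented for minus-strand circles.  ciRNAs (and unassigned
    calls) are contiguous genomic slices in transcript orientation.
    """
    j = call.junction
    if call.circ_type == "exonic":
        plus = "".join(
            genome.fetch(j.contig, s, e, "+") for s, e in call.exon_chain
        )
        return reverse_complement(plus) if j.strand == "-" else plus
    return genome.fetch(j.contig, j.acceptor, j.donor, j.strand)


# ---------------------------------------------------------------------------
# GTF I/O

_BIOTYPE_TO_GTF = {"coding": "protein_coding", "noncoding": "ncRNA", "rRNA": "rRNA"}
_GTF_TO_BIOTYPE = {v: k for k, v in _BIOTYPE_TO_GTF.items()}
_GTF_TO_BIOTYPE.update({b: b for b in BIOTYPES})


def read_annotation(path: str | Path, genome: Optional[GenomeRef] = None) -> list[GeneModel]:
    """Parse a GTF file into GeneModels.

    Requires gene/transcript/exon features (CDS optional) with gene_id and
    transcript_id attributes.  When *genome* is given, features falling
    outside their contig raise :class:`AnnotationError`.
    """
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise AnnotationError(
                    f"{path}: malformed GTF record at line {lineno}"
                )
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for gene in db.features_of_type("gene"):
        biotype_raw = gene.attributes.get("gene_biotype", ["protein_coding"])[0]
        biotype = _GTF_TO_BIOTYPE.get(biotype_raw, "noncoding")
        transcripts = []
        for tx in db.children(gene, featuretype="transcript", order_by="start"):
            exons = tuple(
                sorted(
                    (f.start - 1, f.end)
                    for f in db.children(tx, featuretype="exon")
                )
            )
            if not exons:
                raise AnnotationError(
                    f"transcript {tx.id!r} of gene {gene.id!r} has no exons"
                )
            cds_feats = list(db.children(tx, featuretype="CDS"))
            cds = None
            if cds_feats:
                cds = (min(f.start - 1 for f in cds_feats), max(f.end for f in cds_feats))
            transcripts.append(Transcript(tx.id, exons, cds))
        model = GeneModel(gene.id, gene.seqid, gene.strand, biotype, transcripts)
        if genome is not None:
            if model.contig not in genome:
                raise AnnotationError(
                    f"gene {model.gene_id!r}: contig {model.contig!r} not in genome"
                )
            if model.span[1] > genome.length(model.contig):
                raise AnnotationError(
                    f"gene {model.gene_id!r} extends past end of {model.contig!r}"
                )
        models.append(model)
    return models


def write_annotation(models: Iterable[GeneModel], path: str | Path) -> None:
    """Emit GeneModels as GTF (1-based inclusive on disk)."""

    def attrs(**kv: str) -> str:
        return " ".join(f'{k} "{v}";' for k, v in kv.items())

    with open(path, "w") as fh:
        for g in models:
            biotype = _BIOTYPE_TO_GTF[g.biotype]
            gs, ge = g.span
            fh.write(
                "\t".join(
                    [g.contig, "circdimorph", "gene", str(gs + 1), str(ge),
                     ".", g.strand, ".", attrs(gene_id=g.gene_id, gene_biotype=biotype)]
                ) + "\n"
            )
            for t in g.transcripts:
                ts, te = t.span
                common = dict(gene_id=g.gene_id, transcript_id=t.transcript_id,
                              gene_biotype=biotype)
                fh.write(
                    "\t".join(
                        [g.contig, "circdimorph", "transcript", str(ts + 1), str(te),
                         ".", g.strand, ".", attrs(**common)]
                    ) + "\n"
                )
                for s, e in t.exons:
                    fh.write(
                        "\t".join(
                            [g.contig, "circdimorph", "exon", str(s + 1), str(e),
                             ".", g.strand, ".", attrs(**common)]
                        ) + "\n"
                    )
                if t.cds is not None:
                    cs, ce = t.cds
                    for s, e in t.exons:
                        os_, oe = max(s, cs), min(e, ce)
                        if os_ < oe:
                            fh.write(
                                "\t".join(
                                    [g.contig, "circdimorph", "CDS", str(os_ + 1),
                                     str(oe), ".", g.strand, "0", attrs(**common)]
                                ) + "\n"
                            )


# ---------------------------------------------------------------------------
# BED12 I/O for circ calls


def write_circ_bed(calls: Iterable[CircCall], path: str | Path) -> None:
    """BED12: one row per call; exonic calls carry their exon chain as
    blocks, ciRNAs are single-block rows.  The name field encodes
    ``junction_id|circ_type|gene_id`` so the paired reader round-trips."""
    with open(path, "w") as fh:
        for call in calls:
            j = call.junction
            start, end = j.acceptor, j.donor
            if call.circ_type == "exonic":
                blocks = call.exon_chain
            else:
                blocks = ((start, end),)
            for bs, be in blocks:
                if not (start <= bs < be <= end):
                    raise ValueError(
                        f"call {call.call_id}: block [{bs},{be}) outside "
                        f"[{start},{end}); write refused"
                    )
            if blocks[0][0] != start or blocks[-1][1] != end:
                raise ValueError(
                    f"call {call.call_id}: blocks do not cover both junction "
                    "boundaries; write refused"
                )
            sizes = ",".join(str(be - bs) for bs, be in blocks)
            offsets = ",".join(str(bs - start) for bs, _ in blocks)
            name = f"{call.call_id}|{call.circ_type}|{call.gene_id or '.'}"
            fh.write(
                "\t".join(
                    [j.contig, str(start), str(end), name, "0", j.strand,
                     str(start), str(end), "0", str(len(blocks)), sizes, offsets]
                ) + "\n"
            )


def read_circ_bed(path: str | Path) -> list[CircCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            contig, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            _, circ_type, gene_id = name.split("|")
            chain = tuple(
                (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
            )
            calls.append(
                CircCall(
                    junction=BackSpliceJunction(contig, strand, start, end),
                    circ_type=circ_type,
                    gene_id=None if gene_id == "." else gene_id,
                    exon_chain=chain if circ_type == "exonic" else (),
                )
            )
    return calls
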