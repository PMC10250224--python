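"""Count matrices, size factors, TPM, and TPM-normalized back-splicing levels.

Normalization follows the two-track scheme used for RNase-R fractionated
designs: BSJ counts from the untreated (R-) libraries are scaled by
DESeq2-style median-of-ratios size factors (falling back to adjusted
library size — total minus mRNA minus rRNA reads — when too few
junctions are observed in every sample), while BSJ counts from the
RNase-R treated (R+) libraries are divided by the cognate gene's TPM
estimated from the polyA libraries, isolating back-splicing activity
from host-gene transcription.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._align import SubstringIndex
from .core_io import CircCall, GeneModel, GenomeRef, reverse_complement

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene-level read counting


class TranscriptIndex:
    """Exact scanner of reads against canonical spliced transcripts."""

    def __init__(
        self,
        models: Sequence[GeneModel],
        genome: GenomeRef,
        read_length: int = 100,
        max_mm: int = 1,
    ) -> None:
        self.models = list(models)
        self.max_mm = max_mm
        self.biotype = {g.gene_id: g.biotype for g in models}
        seqs = {}
        for g in models:
            t = g.canonical
            plus = "".join(genome.fetch(g.contig, s, e, "+") for s, e in t.exons)
            seqs[g.gene_id] = (
                reverse_complement(plus) if g.strand == "-" else plus
            )
        seed = min(50, max(20, read_length // (max_mm + 1)))
        self._index = SubstringIndex(seqs, seed_len=seed)

    def genes_matching(self, seq: str, stranded: bool) -> set[str]:
        hits = {h.name for h in self._index.query(seq, self.max_mm)}
        if not stranded:
            hits |= {
                h.name
                for h in self._index.query(reverse_complement(seq), self.max_mm)
            }
        return hits


def gene_counts(
    reads,
    index: TranscriptIndex,
    stranded: bool = False,
) -> tuple[pd.Series, dict]:
    """Per-gene read counts by exact transcript scan.

    A read counts toward a gene iff it matches the gene's canonical
    spliced transcript contiguously with at most ``index.max_mm``
    mismatches; reads matching two or more genes are discarded.  Returns
    the counts (all genes, zeros included) and a stats dict separating
    mRNA and rRNA reads for the library-size reduction step.
    """
    from .bsjcall import iter_reads

    counts = {g.gene_id: 0 for g in index.models}
    stats = {"total": 0, "ambiguous": 0, "unassigned": 0, "rrna": 0, "mrna": 0}
    for _, seq in iter_reads(reads):
        stats["total"] += 1
        genes = index.genes_matching(seq, stranded)
        if not genes:
            stats["unassigned"] += 1
            continue
        if len(genes) > 1:
            stats["ambiguous"] += 1
            continue
        (gene,) = genes
        counts[gene] += 1
        if index.biotype[gene] == "rRNA":
            stats["rrna"] += 1
        else:
            stats["mrna"] += 1
    return pd.Series(counts, name="count"), stats


def effective_lengths(models: Sequence[GeneModel]) -> pd.Series:
    """Canonical-transcript exonic length per gene (TPM effective length)."""
    return pd.Series({g.gene_id: g.canonical.exonic_length for g in models})


# ---------------------------------------------------------------------------
# TPM


def tpm(gene_count: pd.Series, lengths: pd.Series) -> pd.Series:
    """Transcripts per million from counts and effective lengths.

    ``rate_g = count_g / length_g``; ``TPM_g = rate_g / sum(rate) * 1e6``.
    An all-zero column yields all-zero TPM (flagged via log).
    """
    lengths = lengths.reindex(gene_count.index)
    if (lengths[gene_count > 0] <= 0).any():
        raise ValueError("counted gene with non-positive effective length")
    rate = gene_count / lengths.where(lengths > 0, np.nan)
    total = rate.sum()
    if total == 0 or np.isnan(total):
        logger.warning("tpm: zero total count; returning all-zero column")
        return pd.Series(0.0, index=gene_count.index)
    return (rate / total * 1e6).fillna(0.0)


def tpm_table(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    return pd.DataFrame({c: tpm(counts[c], lengths) for c in counts.columns})


# ---------------------------------------------------------------------------
# size factors


@dataclass
class NormFactors:
    factors: pd.Series  # sample -> positive scale factor, geometric mean 1
    method: str  # 'median-of-ratios' | 'library-size'

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


def size_factors(
    matrix: pd.DataFrame,
    min_nonzero_rows: int = 10,
    adjusted_lib_sizes: Optional[pd.Series] = None,
) -> NormFactors:
    """DESeq2-style median-of-ratios size factors for a count matrix.

    The reference for each all-nonzero row is its geometric mean across
    samples; a sample's factor is the median of its ratios to the
    reference.  When fewer than *min_nonzero_rows* rows are nonzero in
    every sample the estimator is unstable, and the fallback is adjusted
    library size (*adjusted_lib_sizes*, e.g. total minus mRNA minus rRNA
    reads; column sums when not given).  Factors are rescaled to
    geometric mean 1 so normalized counts stay on the counts scale.
    """
    if matrix.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    values = matrix.to_numpy(dtype=float)
    nonzero = (values > 0).all(axis=1)
    if nonzero.sum() >= min_nonzero_rows:
        sub = values[nonzero]
        log_ref = np.log(sub).mean(axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_ref, axis=0))
        method = "median-of-ratios"
    else:
        logger.warning(
            "size_factors: only %d all-nonzero rows (<%d); falling back to "
            "library-size factors", int(nonzero.sum()), min_nonzero_rows,
        )
        if adjusted_lib_sizes is not None:
            sizes = adjusted_lib_sizes.reindex(matrix.columns).to_numpy(float)
        else:
            sizes = values.sum(axis=0)
        if (sizes <= 0).any():
            raise ValueError("non-positive library size in fallback")
        factors = sizes
        method = "library-size"
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=matrix.columns), method)


def normalize(matrix: pd.DataFrame, factors: NormFactors | pd.Series) -> pd.DataFrame:
    """Divide each column by its sample's size factor."""
    f = factors.factors if isinstance(factors, NormFactors) else factors
    missing = [c for c in matrix.columns if c not in f.index]
    if missing:
        raise KeyError(f"no size factor for samples {missing}")
    return matrix / f.reindex(matrix.columns)


# ---------------------------------------------------------------------------
# back-splicing level


@dataclass
class LevelTable:
    """TPM-normalized back-splicing levels (junction x R+ sample)."""

    levels: pd.DataFrame
    low_expression: set[str]  # junctions with cognate TPM < eps everywhere
    eps: float


def backsplice_level(
    rplus_counts: pd.DataFrame,
    tpm_values: pd.DataFrame,
    calls: Sequence[CircCall],
    sample_map: dict[str, str],
    eps: float = 1.0,
) -> LevelTable:
    """BSJ_R+ / max(cognate TPM, eps) per junction and sample.

    *sample_map* pairs each R+ column with the polyA column of the same
    (sex, tissue).  Junctions without a cognate gene are dropped (logged);
    junctions whose cognate TPM is below *eps* in every sample are
    retained but flagged low-expression and should be excluded from
    differential back-splicing.
    """
    gene_of = {c.call_id: c.gene_id for c in calls}
    missing = [c for c in rplus_counts.columns if c not in sample_map]
    if missing:
        raise KeyError(f"no polyA pairing for R+ samples {missing}")
    keep = [j for j in rplus_counts.index if gene_of.get(j)]
    dropped = len(rplus_counts.index) - len(keep)
    if dropped:
        logger.info("backsplice_level: %d junctions without cognate gene dropped",
                    dropped)
    levels = {}
    low = set(keep)
    for rp_col in rplus_counts.columns:
        pa_col = sample_map[rp_col]
        col = []
        for j in keep:
            g = gene_of[j]
            # genes absent from the TPM table (e.g. noncoding hosts) count
            # as unexpressed: clamped by eps and flagged low-expression
            t = float(tpm_values.at[g, pa_col]) if g in tpm_values.index else 0.0
            if t >= eps:
                low.discard(j)
            col.append(rplus_counts.at[j, rp_col] / max(t, eps))
        levels[rp_col] = col
    table = pd.DataFrame(levels, index=keep)
    if low:
        logger.info("backsplice_level: %d junctions flagged low-expression",
                    len(low))
    return LevelTable(table, low, eps)
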