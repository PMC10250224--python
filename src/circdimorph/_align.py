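"""Seed-and-verify contiguous matching against small reference sets.

This is a desk-scale exact scanner, not a general aligner: references are
held in memory, candidate loci come from exact seed lookups, and matches
are verified by Hamming comparison.  With ``n_seeds = max_mm + 1`` evenly
spaced seeds, the pigeonhole principle guarantees that any alignment with
at most ``max_mm`` substitutions is found (one seed must be error-free).

``tc_aware=True`` additionally tolerates T-on-reference read as C
(PAR-CLIP crosslink-induced conversions): both read and reference are
collapsed C->T for seeding so conversions cannot break seeds, and during
verification a reference-T/read-C column is recorded as a conversion
instead of counting toward the mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core_io import reverse_complement


def _collapse(seq: str) -> str:
    return seq.replace("C", "T")


@dataclass(frozen=True)
class Hit:
    """One contiguous match of a read against a named reference."""

    name: str
    strand: str  # orientation of the read relative to the stored sequence
    start: int  # coordinate in the reference's own (plus) coordinates
    mismatches: int
    conversions: tuple[int, ...] = ()  # reference coordinates of T->C columns


class SubstringIndex:
    """Exact-seed index over named sequences.

    Parameters
    ----------
    seqs:
        name -> sequence.  Sequences are indexed on the plus strand; with
        ``both_strands=True`` the reverse complement is indexed too and
        hits are reported in plus coordinates with ``strand='-'``.
    seed_len:
        exact seed length; shorter seeds are more sensitive but yield more
        candidate verifications.
    """

    def __init__(
        self,
        seqs: dict[str, str],
        seed_len: int = 20,
        both_strands: bool = False,
        tc_aware: bool = False,
    ) -> None:
        self.seqs = seqs
        self.seed_len = seed_len
        self.both_strands = both_strands
        self.tc_aware = tc_aware
        self._stored: dict[tuple[str, str], str] = {}
        self._index: dict[str, list[tuple[str, str, int]]] = {}
        for name, seq in seqs.items():
            variants = [("+", seq)]
            if both_strands:
                variants.append(("-", reverse_complement(seq)))
            for strand, s in variants:
                self._stored[(name, strand)] = s
                key_space = _collapse(s) if tc_aware else s
                for i in range(len(s) - seed_len + 1):
                    self._index.setdefault(key_space[i : i + seed_len], []).append(
                        (name, strand, i)
                    )

    def _verify(
        self, read: str, stored: str, start: int, max_mm: int
    ) -> Optional[tuple[int, tuple[int, ...]]]:
        if start < 0 or start + len(read) > len(stored):
            return None
        window = stored[start : start + len(read)]
        if window == read:
            return 0, ()
        mm = 0
        conversions = []
        for i, (r, w) in enumerate(zip(read, window)):
            if r == w:
                continue
            if self.tc_aware and w == "T" and r == "C":
                conversions.append(start + i)
                continue
            mm += 1
            if mm > max_mm:
                return None
        return mm, tuple(conversions)

    def query(self, read: str, max_mm: int = 0) -> list[Hit]:
        """All distinct loci matching *read* with <= max_mm substitutions.

        Hit coordinates for '-' hits are converted back to plus-strand
        coordinates of the named sequence (the read then matches the
        reverse complement of ``seq[start:start+len(read)]``).
        """
        k = self.seed_len
        if len(read) < k:
            return []
        read_space = _collapse(read) if self.tc_aware else read
        n_seeds = max_mm + 1
        if n_seeds == 1:
            offsets = [0]
        else:
            span = len(read) - k
            offsets = sorted({round(i * span / (n_seeds - 1)) for i in range(n_seeds)})
        seen: set[tuple[str, str, int]] = set()
        hits: list[Hit] = []
        for off in offsets:
            for name, strand, pos in self._index.get(
                read_space[off : off + k], ()
            ):
                start = pos - off
                key = (name, strand, start)
                if key in seen:
                    continue
                seen.add(key)
                res = self._verify(read, self._stored[(name, strand)], start, max_mm)
                if res is None:
                    continue
                mm, conv = res
                if strand == "+":
                    hits.append(Hit(name, "+", start, mm, conv))
                else:
                    L = len(self.seqs[name])
                    g_start = L - (start + len(read))
                    g_conv = tuple(sorted(L - 1 - c for c in conv))
                    hits.append(Hit(name, "-", g_start, mm, g_conv))
        return hits

    def best_hits(self, read: str, max_mm: int = 0) -> list[Hit]:
        """Hits achieving the minimum mismatch count (may be empty)."""
        hits = self.query(read, max_mm)
        if not hits:
            return []
        best = min(h.mismatches for h in hits)
        return [h for h in hits if h.mismatches == best]
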