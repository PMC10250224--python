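"""Threshold-rule classification of circular RNA calls.

All criteria are fold-change threshold rules applied to BSJ read counts
(one library per sex x tissue x fraction; no replicate variance model):

* reliable: R+ count at least twice the matched R- count (and at least 2)
  in some sample — the RNase-R enrichment filter;
* differentially expressed: >= ``min_fold`` between R+ samples, with the
  normalized R- counts changing in the same direction;
* sex-specific: >= ``min_reads`` in one sex's R+ sample and zero reads in
  every opposite-sex sample;
* differentially back-spliced: the same fold rule applied to the
  TPM-normalized level (BSJ_R+ / cognate TPM), with the level required to
  reach ``min_level`` in at least one side; qualifying junctions get a
  group label G1-G6 on a fixed tissue x direction grid.

Matrices are junction x condition, with condition columns labelled
``"F:head"``, ``"M:gonad"`` etc.  A pseudocount of 0.5 keeps fold changes
total when a side has zero counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core_io import CircCall

Condition = tuple[str, str]  # (sex, tissue)


def cond_label(sex: str, tissue: str) -> str:
    return f"{sex}:{tissue}"


@dataclass(frozen=True)
class ComparisonSpec:
    name: str
    side_a: Condition
    side_b: Condition
    kind: str  # 'between-tissue' | 'between-sex'

    def __post_init__(self) -> None:
        if self.side_a == self.side_b:
            raise ValueError("comparison sides must differ")
        if self.kind == "between-sex" and self.side_a[1] != self.side_b[1]:
            raise ValueError("between-sex comparisons pair identical tissues")

    @property
    def col_a(self) -> str:
        return cond_label(*self.side_a)

    @property
    def col_b(self) -> str:
        return cond_label(*self.side_b)


def sex_comparisons() -> list[ComparisonSpec]:
    """Female-vs-male comparisons of counterpart tissues (side a = female)."""
    return [
        ComparisonSpec(f"{t}_FvM", ("F", t), ("M", t), "between-sex")
        for t in ("head", "body", "gonad")
    ]


def tissue_comparisons(sex: str) -> list[ComparisonSpec]:
    out = []
    tissues = ("head", "body", "gonad")
    for i, a in enumerate(tissues):
        for b in tissues[i + 1 :]:
            out.append(
                ComparisonSpec(f"{sex}_{a}_v_{b}", (sex, a), (sex, b),
                               "between-tissue")
            )
    return out


# Group grid: tissue x direction of the female-vs-male level change.
# G1/G2 head female/male-higher, G3/G4 body, G6/G5 gonad (ovary/testis).
GROUP_GRID = {
    ("head", "a"): "G1",
    ("head", "b"): "G2",
    ("body", "a"): "G3",
    ("body", "b"): "G4",
    ("gonad", "b"): "G5",
    ("gonad", "a"): "G6",
}


# ---------------------------------------------------------------------------
# reliability


@dataclass
class ReliabilityResult:
    flags: pd.DataFrame  # junction x condition, boolean
    reliable: set[str]  # reliable in >= 1 sample


def reliable_filter(
    rplus: pd.DataFrame, rminus: pd.DataFrame, min_count: int = 2
) -> ReliabilityResult:
    """RNase-R enrichment filter: reliable iff R+ >= 2 x R- and R+ >= min_count.

    ``rplus`` and ``rminus`` must share condition columns (same sex and
    tissue); a missing pairing raises with the offending sample named.
    The ``min_count`` floor decides the zero-denominator case (R- = 0).
    """
    for col in rplus.columns:
        if col not in rminus.columns:
            raise KeyError(f"R+ sample {col!r} has no matched R- sample")
    rminus = rminus.reindex(index=rplus.index, columns=rplus.columns).fillna(0)
    flags = (rplus >= 2 * rminus) & (rplus >= min_count)
    return ReliabilityResult(flags, set(flags.index[flags.any(axis=1)]))


# ---------------------------------------------------------------------------
# differential expression


def _directional_fold(
    values: pd.DataFrame,
    direction_ref: pd.DataFrame,
    comp: ComparisonSpec,
    min_fold: float,
    pseudocount: float,
) -> pd.Series:
    """Per-junction direction ('a', 'b' or '') for one comparison.

    Toward a iff (v_a + p)/(v_b + p) >= min_fold and ref_a > ref_b
    (strictly, same direction); symmetric for b.  No junction can be
    flagged toward both sides.
    """
    va, vb = values[comp.col_a], values[comp.col_b]
    ra, rb = direction_ref[comp.col_a], direction_ref[comp.col_b]
    fold_a = (va + pseudocount) / (vb + pseudocount)
    toward_a = (fold_a >= min_fold) & (ra > rb)
    toward_b = ((1.0 / fold_a) >= min_fold) & (rb > ra)
    out = pd.Series("", index=values.index)
    out[toward_a] = "a"
    out[toward_b] = "b"
    return out


def diff_expression(
    rplus: pd.DataFrame,
    rminus_normalized: pd.DataFrame,
    comparisons: Sequence[ComparisonSpec],
    reliable: Optional[Iterable[str]] = None,
    min_fold: float = 4.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential expression by raw R+ fold change with R- direction check.

    Returns junction x comparison with values 'a', 'b' or '' (the flagged
    side); rows restricted to the reliable set when given.
    """
    if reliable is not None:
        idx = [j for j in rplus.index if j in set(reliable)]
        rplus = rplus.loc[idx]
    rminus_normalized = rminus_normalized.reindex(rplus.index).fillna(0)
    return pd.DataFrame(
        {
            c.name: _directional_fold(rplus, rminus_normalized, c, min_fold,
                                      pseudocount)
            for c in comparisons
        }
    )


# ---------------------------------------------------------------------------
# sex specificity


def sex_specific(
    rplus: pd.DataFrame,
    rminus: pd.DataFrame,
    reliable: Optional[Iterable[str]] = None,
    min_reads: int = 15,
    opposite_rminus_counts: bool = True,
) -> pd.DataFrame:
    """Sex-specific circles: strong in one sex, undetected in the other.

    Flagged for sex S iff the maximum R+ count over S's samples is
    >= *min_reads* and every opposite-sex sample has zero reads — in both
    R+ and R- fractions by default (``opposite_rminus_counts=False``
    relaxes the rule to R+ libraries only).  Returns junction x ['F','M']
    booleans, restricted to the reliable set when given.
    """
    if reliable is not None:
        idx = [j for j in rplus.index if j in set(reliable)]
        rplus = rplus.loc[idx]
    rminus = rminus.reindex(rplus.index).fillna(0)
    out = {}
    for sex, other in (("F", "M"), ("M", "F")):
        own = [c for c in rplus.columns if c.startswith(f"{sex}:")]
        opp = [c for c in rplus.columns if c.startswith(f"{other}:")]
        strong = rplus[own].max(axis=1) >= min_reads
        silent = (rplus[opp] == 0).all(axis=1)
        if opposite_rminus_counts:
            opp_m = [c for c in rminus.columns if c.startswith(f"{other}:")]
            silent &= (rminus[opp_m] == 0).all(axis=1)
        out[sex] = strong & silent
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# differential back-splicing and groups


@dataclass
class BackspliceDiff:
    flags: pd.DataFrame  # junction x comparison: 'a' / 'b' / ''
    groups: pd.DataFrame  # junction x ['group', 'groups']


def diff_backsplicing(
    levels: pd.DataFrame,
    rminus_normalized: pd.DataFrame,
    comparisons: Sequence[ComparisonSpec],
    reliable: Optional[Iterable[str]] = None,
    low_expression: Optional[Iterable[str]] = None,
    min_fold: float = 4.0,
    min_level: float = 15.0,
    pseudocount: float = 0.5,
) -> BackspliceDiff:
    """Differential back-splicing on TPM-normalized levels, with G1-G6 groups.

    Toward side a iff (level_a + p)/(level_b + p) >= min_fold, the larger
    of the two levels reaches *min_level*, and the normalized R- counts
    change in the same direction.  Between-sex comparisons map onto the
    fixed group grid (G1 = head female-higher ... G6 = ovary-higher).
    Junctions flagged low-expression (cognate TPM below the floor in all
    samples) are excluded.
    """
    idx = list(levels.index)
    if reliable is not None:
        rel = set(reliable)
        idx = [j for j in idx if j in rel]
    if low_expression is not None:
        low = set(low_expression)
        idx = [j for j in idx if j not in low]
    levels = levels.loc[idx]
    rminus_normalized = rminus_normalized.reindex(idx).fillna(0)
    flags = {}
    for comp in comparisons:
        d = _directional_fold(levels, rminus_normalized, comp, min_fold,
                              pseudocount)
        big_enough = levels[[comp.col_a, comp.col_b]].max(axis=1) >= min_level
        d[~big_enough] = ""
        flags[comp.name] = d
    flags = pd.DataFrame(flags, index=idx)
    group_sets: dict[str, list[str]] = {j: [] for j in idx}
    for comp in comparisons:
        if comp.kind != "between-sex":
            continue
        tissue = comp.side_a[1]
        for j, side in flags[comp.name].items():
            if side and (tissue, side) in GROUP_GRID:
                group_sets[j].append(GROUP_GRID[(tissue, side)])
    groups = pd.DataFrame(
        {
            "group": [sorted(v)[0] if v else "" for v in group_sets.values()],
            "groups": [",".join(sorted(v)) for v in group_sets.values()],
        },
        index=idx,
    )
    return BackspliceDiff(flags, groups)


# ---------------------------------------------------------------------------
# alternative back-splicing


@dataclass(frozen=True)
class AltBSEvent:
    gene_id: str
    kind: str  # 'alt5' (shared acceptor, donors differ) | 'alt3'
    boundary: int  # the shared genomic boundary position
    members: tuple[str, ...]  # junction ids (>= 2)
    samples: tuple[str, ...]  # columns where >= 2 members have R+ >= 1

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an AltBS event needs >= 2 member junctions")


def alt_backsplicing(
    calls: Sequence[CircCall], rplus: Optional[pd.DataFrame] = None
) -> list[AltBSEvent]:
    """Enumerate alternative back-splicing events among exonic calls.

    Per gene, each acceptor shared by >= 2 distinct donors yields one
    alt5 event (the 5'SS side varies) and each donor shared by >= 2
    distinct acceptors yields one alt3 event.  An event is observed in a
    sample iff at least two of its members have an R+ count >= 1 there.
    Callers should pass reliable exonic calls only.
    """
    by_acc: dict[tuple[str, int], list[CircCall]] = defaultdict(list)
    by_don: dict[tuple[str, int], list[CircCall]] = defaultdict(list)
    for c in calls:
        if c.circ_type != "exonic" or not c.gene_id:
            continue
        by_acc[(c.gene_id, c.junction.acceptor)].append(c)
        by_don[(c.gene_id, c.junction.donor)].append(c)

    def observed(members: list[CircCall]) -> tuple[str, ...]:
        if rplus is None:
            return ()
        cols = []
        for col in rplus.columns:
            n = sum(
                1
                for m in members
                if m.call_id in rplus.index and rplus.at[m.call_id, col] >= 1
            )
            if n >= 2:
                cols.append(col)
        return tuple(cols)

    events = []
    for (gene, boundary), members in sorted(by_acc.items()):
        if len({m.junction.donor for m in members}) >= 2:
            events.append(
                AltBSEvent(gene, "alt5", boundary,
                           tuple(sorted(m.call_id for m in members)),
                           observed(members))
            )
    for (gene, boundary), members in sorted(by_don.items()):
        if len({m.junction.acceptor for m in members}) >= 2:
            events.append(
                AltBSEvent(gene, "alt3", boundary,
                           tuple(sorted(m.call_id for m in members)),
                           observed(members))
            )
    return events
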