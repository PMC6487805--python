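"""Per-column classification of a grouped alignment.

A column is *conserved-common* when every record shows the same single
unambiguous base — the Clustal ``*`` convention (no gaps, no ambiguity
codes). A column is *taxon-specific* for group G when all members of G
share one character c (an unambiguous base, or the gap as a conserved
deletion) and c is absent from every record outside G; within-group
polymorphism (strain-specific variation) always disqualifies the column
for that group. Specificity is strict exclusion: the signature character
must be missing from every off-target record, not merely from each
outgroup consensus, because only strict exclusion guarantees a primer
3'-end mismatch against every off-target strain.

Ambiguity codes are handled conservatively: inside the focal group they
disqualify outright; in an outgroup record, a code whose IUPAC expansion
could equal the signature base also disqualifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignment import DNA_BASES, GAP, IUPAC_AMBIGUITY, GroupedAlignment
from .errors import AlignmentShapeError, UnknownGroupError


@dataclass(frozen=True)
class ColumnVerdict:
    """Classification of one alignment column."""

    column_index: int
    conserved_common: bool
    specific_for: frozenset[str]

    def __post_init__(self) -> None:
        if self.conserved_common and self.specific_for:
            raise ValueError("a conserved-common column cannot be specific")


def _could_match(ch: str, base: str) -> bool:
    """True if outgroup character `ch` could stand for `base`."""
    if ch == base:
        return True
    expansion = IUPAC_AMBIGUITY.get(ch)
    return expansion is not None and base in expansion


def classify_column(
    column: Sequence[str],
    groups: Mapping[str, Sequence[int]],
    column_index: int = 0,
) -> ColumnVerdict:
    """Classify one column given the group partition of record indices."""
    n = sum(len(idx) for idx in groups.values())
    if len(column) != n:
        raise AlignmentShapeError(
            f"column has {len(column)} characters for {n} records"
        )
    chars = [c.upper() for c in column]

    distinct = set(chars)
    conserved = len(distinct) == 1 and distinct <= DNA_BASES

    specific: set[str] = set()
    if not conserved:
        for g, members in groups.items():
            inside = {chars[i] for i in members}
            if len(inside) != 1:
                continue  # strain-specific polymorphism
            c = inside.pop()
            if c not in DNA_BASES and c != GAP:
                continue  # ambiguity code inside the group
            member_set = set(members)
            outside = [chars[i] for i in range(n) if i not in member_set]
            if c == GAP:
                # conserved deletion: only a signature if every other
                # record shows a plain base there
                if all(ch in DNA_BASES for ch in outside):
                    specific.add(g)
            else:
                if not any(_could_match(ch, c) for ch in outside):
                    specific.add(g)

    return ColumnVerdict(
        column_index=column_index,
        conserved_common=conserved,
        specific_for=frozenset(specific),
    )


def classify_alignment(aln: GroupedAlignment) -> list[ColumnVerdict]:
    """Classify every column of the alignment, in order."""
    return [
        classify_column(aln.column(i), aln.groups, column_index=i)
        for i in range(aln.n_columns)
    ]


def count_fragment_mutations(
    verdicts: Sequence[ColumnVerdict],
    group: str,
    fragment_len: int = 20,
    known_groups: Sequence[str] | None = None,
) -> list[int]:
    """Tile columns into consecutive `fragment_len` fragments and count,
    per fragment, the columns that are taxon-specific for `group`.

    A trailing partial fragment is counted too (use
    :func:`has_partial_fragment` to detect it). `known_groups`, when
    given, validates the group label.
    """
    if fragment_len < 1:
        raise ValueError("fragment_len must be >= 1")
    if known_groups is not None and group not in known_groups:
        raise UnknownGroupError(f"no such taxon group: {group!r}")
    n = len(verdicts)
    n_fragments = (n + fragment_len - 1) // fragment_len
    counts = [0] * n_fragments
    for i, v in enumerate(verdicts):
        if group in v.specific_for:
            counts[i // fragment_len] += 1
    return counts


def fragment_spans(n_columns: int, fragment_len: int) -> list[tuple[int, int]]:
    """1-based inclusive column spans of each fragment tile."""
    return [
        (start + 1, min(start + fragment_len, n_columns))
        for start in range(0, n_columns, fragment_len)
    ]


def has_partial_fragment(n_columns: int, fragment_len: int) -> bool:
    return n_columns % fragment_len != 0
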