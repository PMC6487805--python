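"""Average mutation index: a simple moving average over fragment counts.

The alignment is tiled into non-overlapping fragments of 20 columns
(one primer annealing site). With per-fragment taxon-specific mutation
counts M_f, the average mutation index over a window of w fragments is
the simple moving average

    S̄_f = (1/w) * (M_f + M_{f-1} + ... + M_{f-w+1})

anchored to the *central* fragment of the window, which is why w must
be odd. The same values follow from the O(1)-per-step recurrence

    S̄_f = S̄_{f-1} - M_{f-w}/w + M_f/w

after a direct sum for the first window. The window slides by one whole
fragment, so the profile's resolution is per-fragment. No edge padding
is applied: S̄ is undefined for the first and last (w-1)/2 fragments. A
trailing partial fragment keeps its count but is excluded from the SMA,
since it breaks the per-20-nt normalisation.

Defaults follow the LAMP use case: 20-nt fragments and a 300-bp window
(15 fragments — amplicons beyond ~300 bp amplify poorly), with regions
recommended at an index of 2 or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .classify import ColumnVerdict, count_fragment_mutations, fragment_spans
from .errors import ParameterError, TooShortAlignmentError


def _check_window(m_len: int, w: int) -> None:
    if w < 1 or w % 2 == 0:
        raise ParameterError(f"window must be a positive odd number, got {w}")
    if w > m_len:
        raise ParameterError(
            f"window of {w} fragments exceeds the {m_len} fragments available"
        )


def sma_direct(M: Sequence[float], w: int) -> list[float]:
    """Simple moving average by explicit summation of each window."""
    _check_window(len(M), w)
    return [sum(M[j : j + w]) / w for j in range(len(M) - w + 1)]


def sma_recurrent(M: Sequence[float], w: int) -> list[float]:
    """Simple moving average via the sliding recurrence.

    The first window is summed directly; each later value updates the
    previous one by removing the fragment that left the window and
    adding the one that entered. Agrees with :func:`sma_direct` to
    floating-point accuracy.
    """
    _check_window(len(M), w)
    out = [sum(M[:w]) / w]
    for f in range(w, len(M)):
        out.append(out[-1] - M[f - w] / w + M[f] / w)
    return out


@dataclass
class MutationProfile:
    """Per-group fragment counts and smoothed average mutation index."""

    group: str
    fragment_len: int
    window_fragments: int
    n_columns: int
    M: list[int]
    last_partial: bool
    S: list[float]

    @property
    def n_full_fragments(self) -> int:
        return self.n_columns // self.fragment_len

    @property
    def spans(self) -> list[tuple[int, int]]:
        """1-based inclusive column span of each fragment (incl. partial)."""
        return fragment_spans(self.n_columns, self.fragment_len)

    @property
    def central_fragments(self) -> list[int]:
        """0-based fragment index anchoring each S value."""
        half = (self.window_fragments - 1) // 2
        return [j + half for j in range(len(self.S))]

    @property
    def anchors(self) -> list[tuple[int, int]]:
        """1-based inclusive column span of each S value's central fragment."""
        spans = self.spans
        return [spans[f] for f in self.central_fragments]

    @property
    def anchor_midpoints(self) -> list[int]:
        """1-based column midpoint of each central fragment (plot x-axis)."""
        return [(a + b) // 2 for a, b in self.anchors]

    def sma_at_fragment(self, f: int) -> float | None:
        """S̄ anchored at fragment `f`, or None where undefined."""
        half = (self.window_fragments - 1) // 2
        j = f - half
        if 0 <= j < len(self.S):
            return self.S[j]
        return None

    def to_table(self) -> pd.DataFrame:
        """Tab-friendly table: one row per fragment (S̄ empty if undefined)."""
        rows = []
        spans = self.spans
        for f, (count, (a, b)) in enumerate(zip(self.M, spans)):
            s = self.sma_at_fragment(f)
            rows.append(
                {
                    "group": self.group,
                    "fragment": f + 1,
                    "col_start": a,
                    "col_end": b,
                    "mutations": count,
                    "sma": "" if s is None else round(s, 6),
                    "partial": self.last_partial and f == len(self.M) - 1,
                }
            )
        return pd.DataFrame(rows)

    def write_table(self, path, line_endings: str = "unix") -> None:
        terminator = "\r\n" if line_endings == "windows" else "\n"
        self.to_table().to_csv(path, sep="\t", index=False, lineterminator=terminator)


def build_profile(
    verdicts: Sequence[ColumnVerdict],
    group: str,
    fragment_len: int = 20,
    window_bp: int = 300,
    known_groups: Sequence[str] | None = None,
) -> MutationProfile:
    """Count per-fragment mutations for `group` and smooth them.

    `window_bp` must be a multiple of `fragment_len` and correspond to an
    odd number of fragments (defaults: 300 bp = 15 fragments of 20 nt).
    """
    if fragment_len < 1:
        raise ParameterError("fragment_len must be >= 1")
    if window_bp % fragment_len != 0:
        raise ParameterError(
            f"window of {window_bp} bp is not a whole number of "
            f"{fragment_len}-nt fragments"
        )
    w = window_bp // fragment_len
    if w % 2 == 0:
        raise ParameterError(
            f"window of {w} fragments is even; an odd count is required to "
            "anchor the average to a central fragment"
        )
    n_columns = len(verdicts)
    full = n_columns // fragment_len
    if full < w:
        raise TooShortAlignmentError(
            f"alignment has {full} full fragments, fewer than the window of "
            f"{w}; at least {w * fragment_len} columns are required"
        )
    M = count_fragment_mutations(verdicts, group, fragment_len, known_groups)
    last_partial = n_columns % fragment_len != 0
    M_full = M[:full]
    S = sma_recurrent(M_full, w)
    return MutationProfile(
        group=group,
        fragment_len=fragment_len,
        window_fragments=w,
        n_columns=n_columns,
        M=M,
        last_partial=last_partial,
        S=S,
    )


@dataclass(frozen=True)
class TargetRegion:
    """A candidate target: 1-based inclusive column range plus its peak."""

    start: int
    end: int
    peak_value: float
    peak_fragment: int  # 0-based index of the peak's central fragment
    peak_anchor: tuple[int, int]  # 1-based span of that fragment

    def __len__(self) -> int:
        return self.end - self.start + 1


def select_target_region(
    profile: MutationProfile,
    threshold: float = 2.0,
    max_len: int = 2000,
) -> TargetRegion | None:
    """Pick the region of at most `max_len` columns around the SMA peak.

    Returns None when no S̄ value reaches `threshold`. Ties resolve to
    the leftmost peak; the region is centred on the peak's central
    fragment and clamped to the alignment bounds.
    """
    span = profile.window_fragments * profile.fragment_len
    if max_len < span:
        raise ParameterError(
            f"max_len {max_len} is smaller than one window span ({span})"
        )
    if not profile.S:
        return None
    peak_idx = max(range(len(profile.S)), key=lambda j: (profile.S[j], -j))
    peak = profile.S[peak_idx]
    if peak < threshold:
        return None
    frag = profile.central_fragments[peak_idx]
    a, b = profile.anchors[peak_idx]
    mid = (a + b) // 2
    length = min(max_len, profile.n_columns)
    start = mid - (length - 1) // 2
    start = max(1, min(start, profile.n_columns - length + 1))
    end = start + length - 1
    return TargetRegion(
        start=start, end=end, peak_value=peak, peak_fragment=frag, peak_anchor=(a, b)
    )
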