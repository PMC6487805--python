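"""Masked target export for downstream LAMP primer design.

The exported file carries the focal group's ungapped consensus over the
selected region, wrapped at 60 characters, with a parallel annotation
line under each sequence line: ``*`` marks conserved-common positions
(identical across the whole alignment) and ``-`` marks the focal
group's taxon-specific mutations — the region-of-interest mark-up that
primer-design services accept for steering primer ends onto specific
sites. Conserved deletions (gap signatures) exist only in the alignment
coordinate system: they vanish on degapping and are therefore reported
in the profile table but never marked in the file.
"""

from __future__ import annotations

import logging
import shutil
import zipfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .alignment import (
    DNA_BASES,
    GAP,
    LINE_TERMINATORS,
    GroupedAlignment,
)
from .classify import ColumnVerdict
from .errors import (
    OutputCollisionError,
    RegionSizeError,
    UnknownGroupError,
    WriteError,
)

logger = logging.getLogger(__name__)

WRAP = 60
MAX_TARGET_LEN = 2000


@dataclass(frozen=True)
class MaskedTarget:
    """Ungapped focal target with its parallel annotation string.

    `column_map[i]` is the 1-based alignment column behind target
    position i; `region` is the exported alignment-column range
    (1-based inclusive).
    """

    group: str
    target_sequence: str
    annotation: str
    column_map: tuple[int, ...]
    region: tuple[int, int]

    def __post_init__(self) -> None:
        if not (
            len(self.target_sequence) == len(self.annotation) == len(self.column_map)
        ):
            raise ValueError("sequence, annotation and column map must align")

    @property
    def specific_positions(self) -> list[int]:
        """0-based target positions carrying a '-' mark."""
        return [i for i, c in enumerate(self.annotation) if c == "-"]

    @property
    def conserved_positions(self) -> list[int]:
        return [i for i, c in enumerate(self.annotation) if c == "*"]


def build_focal_consensus(
    aln: GroupedAlignment,
    group: str,
    region: tuple[int, int],
) -> tuple[str, list[int]]:
    """Majority consensus of the focal group over `region`, degapped.

    Per column the majority unambiguous base wins (ties alphabetical,
    logged); columns whose focal majority is the gap are dropped, as are
    columns with no unambiguous focal base at all (warned). Returns the
    consensus string and the 1-based alignment column of each kept
    position.
    """
    if group not in aln.groups:
        raise UnknownGroupError(f"no such taxon group: {group!r}")
    start, end = region
    if not (1 <= start <= end <= aln.n_columns):
        raise ValueError(
            f"region {region} outside alignment columns 1-{aln.n_columns}"
        )
    members = aln.members(group)
    seq: list[str] = []
    column_map: list[int] = []
    for col in range(start - 1, end):
        tally = Counter(m.sequence[col] for m in members)
        base_counts = {b: tally[b] for b in DNA_BASES if tally[b] > 0}
        best_count = max(base_counts.values(), default=0)
        if tally[GAP] > best_count:
            continue  # focal majority is a deletion: absent from the target
        if not base_counts:
            logger.warning(
                "group %s column %d has no unambiguous base; dropped",
                group,
                col + 1,
            )
            continue
        winners = sorted(b for b, c in base_counts.items() if c == best_count)
        if len(winners) > 1:
            logger.info(
                "group %s column %d: tie %s, keeping %s",
                group,
                col + 1,
                "/".join(winners),
                winners[0],
            )
        seq.append(winners[0])
        column_map.append(col + 1)
    return "".join(seq), column_map


def make_masked_target(
    aln: GroupedAlignment,
    verdicts: Sequence[ColumnVerdict],
    group: str,
    region: tuple[int, int],
    max_len: int = MAX_TARGET_LEN,
) -> MaskedTarget:
    """Build the masked target for `group` over `region` (in memory)."""
    sequence, column_map = build_focal_consensus(aln, group, region)
    if len(sequence) > max_len:
        raise RegionSizeError(
            f"degapped target for {group} spans {len(sequence)} bases, above "
            f"the {max_len}-base limit; narrow the region"
        )
    marks = []
    for col in column_map:
        v = verdicts[col - 1]
        if group in v.specific_for:
            marks.append("-")
        elif v.conserved_common:
            marks.append("*")
        else:
            marks.append(" ")
    return MaskedTarget(
        group=group,
        target_sequence=sequence,
        annotation="".join(marks),
        column_map=tuple(column_map),
        region=region,
    )


def write_masked_target(
    target: MaskedTarget,
    path: str | Path,
    line_endings: str = "unix",
) -> Path:
    """Write the masked target file: header line, then 60-character
    sequence lines each followed by its aligned annotation line."""
    eol = LINE_TERMINATORS[line_endings]
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(
                f";{target.group} target, alignment columns "
                f"{target.region[0]}-{target.region[1]} (1-based inclusive), "
                "* conserved-common, - taxon-specific" + eol
            )
            for i in range(0, len(target.target_sequence), WRAP):
                fh.write(target.target_sequence[i : i + WRAP] + eol)
                fh.write(target.annotation[i : i + WRAP] + eol)
    except OSError as exc:
        raise WriteError(f"could not write {path}: {exc}") from exc
    return path


def make_primerexplorer_input(
    aln: GroupedAlignment,
    verdicts: Sequence[ColumnVerdict],
    group: str,
    region: tuple[int, int],
    path: str | Path,
    line_endings: str = "unix",
    max_len: int = MAX_TARGET_LEN,
) -> MaskedTarget:
    """Build and write the ready-to-use primer-design input file."""
    target = make_masked_target(aln, verdicts, group, region, max_len=max_len)
    write_masked_target(target, path, line_endings=line_endings)
    return target


def read_masked_target(path: str | Path) -> tuple[str, str]:
    """Parse a masked target file back into (sequence, annotation)."""
    seq_parts: list[str] = []
    ann_parts: list[str] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    body = [ln for ln in lines if not ln.startswith(";")]
    for i in range(0, len(body), 2):
        seq = body[i]
        ann = body[i + 1] if i + 1 < len(body) else ""
        # trailing spaces on annotation lines are significant padding
        ann = ann.ljust(len(seq))
        seq_parts.append(seq)
        ann_parts.append(ann)
    return "".join(seq_parts), "".join(ann_parts)


def bundle_outputs(
    outputs: Iterable[str | Path],
    out_dir: str | Path,
    project_id: str,
    zip: bool = False,
    overwrite: bool = False,
) -> Path:
    """Collect output files into a project directory or ZIP archive."""
    out_dir = Path(out_dir)
    dest = out_dir / project_id
    archive = out_dir / f"{project_id}.zip"
    target = archive if zip else dest
    if target.exists():
        if not overwrite:
            raise OutputCollisionError(
                f"output {target} already exists; pass overwrite to replace it"
            )
        if target.is_dir():
            shutil.rmtree(target)
        else:
            target.unlink()
    files = [Path(p) for p in outputs]
    if zip:
        out_dir.mkdir(parents=True, exist_ok=True)
        with zipfile.ZipFile(archive, "w", zipfile.ZIP_DEFLATED) as zf:
            for f in files:
                zf.write(f, arcname=f"{project_id}/{f.name}")
        return archive
    dest.mkdir(parents=True, exist_ok=True)
    for f in files:
        if f.parent.resolve() != dest.resolve():
            shutil.copy2(f, dest / f.name)
    return dest
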