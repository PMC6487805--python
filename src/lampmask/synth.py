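"""Synthetic grouped alignments with planted, known ground truth.

The generator builds a random backbone sequence shared by every strain
and then plants, per group, signature columns where all group members
carry a base (or a deletion block) that no outside record shows. Strain
noise adds private mutations at other columns; by construction those
columns are group-polymorphic, so the classifier must never call them.
Ground truth is exact, not statistical: the returned per-group column
sets are precisely what a correct classifier reports.

In a two-group alignment a column planted for one group is unavoidably
also specific for the other (the backbone base is then absent outside
it); the returned truth accounts for this complement effect.

An adversarial mode plants *spoiled* columns: the signature base is
leaked into one outside record, so a correct classifier rejects them.

No evolutionary realism is attempted — no substitution model, no indel
process beyond the planted deletion blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import GroupedAlignment, StrainRecord, EM_DASH
from .errors import PlanError

BASES = "ACGT"


@dataclass
class PlantPlan:
    """Recipe for one synthetic alignment.

    planted_specific / spoiled_specific map group labels ("G1", "G2",
    ...) to 1-based column sets; gap_blocks maps group labels to lists
    of 1-based inclusive (start, end) deletion ranges. All planted
    structure must be mutually disjoint. `strain_noise` is the per-
    strain private mutation probability at eligible columns (only
    groups with at least 2 strains receive noise, so noise can never
    make a group uniform).
    """

    n_groups: int = 3
    strains_per_group: int | Sequence[int] = 3
    n_columns: int = 600
    planted_specific: Mapping[str, Sequence[int]] = field(default_factory=dict)
    strain_noise: float = 0.0
    gap_blocks: Mapping[str, Sequence[tuple[int, int]]] = field(default_factory=dict)
    spoiled_specific: Mapping[str, Sequence[int]] = field(default_factory=dict)
    seed: int = 0
    gene_id: str | None = "gene1"

    @property
    def group_labels(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_groups)]

    @property
    def group_sizes(self) -> list[int]:
        if isinstance(self.strains_per_group, int):
            return [self.strains_per_group] * self.n_groups
        sizes = list(self.strains_per_group)
        if len(sizes) != self.n_groups:
            raise PlanError(
                f"{len(sizes)} group sizes given for {self.n_groups} groups"
            )
        return sizes

    def validate(self) -> None:
        if self.n_groups < 2:
            raise PlanError("at least 2 groups are required")
        if any(s < 1 for s in self.group_sizes):
            raise PlanError("every group needs at least 1 strain")
        if self.n_columns < 1:
            raise PlanError("n_columns must be positive")
        if not 0.0 <= self.strain_noise < 1.0:
            raise PlanError("strain_noise must be in [0, 1)")
        labels = set(self.group_labels)
        claimed: set[int] = set()
        for mapping, kind in (
            (self.planted_specific, "planted"),
            (self.spoiled_specific, "spoiled"),
        ):
            for g, cols in mapping.items():
                if g not in labels:
                    raise PlanError(f"{kind} columns for unknown group {g!r}")
                for c in cols:
                    if not 1 <= c <= self.n_columns:
                        raise PlanError(f"{kind} column {c} outside 1-{self.n_columns}")
                    if c in claimed:
                        raise PlanError(f"column {c} claimed more than once")
                    claimed.add(c)
        for g, blocks in self.gap_blocks.items():
            if g not in labels:
                raise PlanError(f"gap block for unknown group {g!r}")
            for a, b in blocks:
                if not 1 <= a <= b <= self.n_columns:
                    raise PlanError(f"gap block ({a}, {b}) out of bounds")
                for c in range(a, b + 1):
                    if c in claimed:
                        raise PlanError(f"column {c} claimed more than once")
                    claimed.add(c)


def _gap_columns(plan: PlantPlan, group: str) -> set[int]:
    cols: set[int] = set()
    for a, b in plan.gap_blocks.get(group, ()):
        cols.update(range(a, b + 1))
    return cols


def generate_alignment(
    plan: PlantPlan,
) -> tuple[GroupedAlignment, dict[str, set[int]]]:
    """Build the alignment a plan describes, plus its exact truth.

    Returns the GroupedAlignment and a mapping group -> set of 1-based
    columns that are taxon-specific for that group (planted signature
    bases and conserved deletion blocks, with the two-group complement
    effect applied). Spoiled columns are excluded from the truth.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    labels = plan.group_labels
    sizes = plan.group_sizes
    n = plan.n_columns

    backbone = rng.choice(list(BASES), size=n)
    # matrix of per-strain sequences, row order = input order
    rows: list[np.ndarray] = []
    row_group: list[str] = []
    for g, size in zip(labels, sizes):
        for _ in range(size):
            rows.append(backbone.copy())
            row_group.append(g)
    mat = np.array(rows)

    group_rows = {
        g: [i for i, rg in enumerate(row_group) if rg == g] for g in labels
    }

    def alt_base(b: str) -> str:
        choices = [x for x in BASES if x != b]
        return choices[rng.integers(len(choices))]

    # planted signature bases: all focal rows flip to a non-backbone base
    for g, cols in plan.planted_specific.items():
        for c in cols:
            sig = alt_base(backbone[c - 1])
            mat[group_rows[g], c - 1] = sig

    # spoiled columns: like planted, but the signature leaks into one
    # outside record, so the column must NOT be called specific
    for g, cols in plan.spoiled_specific.items():
        outside = [i for i in range(len(rows)) if row_group[i] != g]
        for c in cols:
            sig = alt_base(backbone[c - 1])
            mat[group_rows[g], c - 1] = sig
            leak = outside[rng.integers(len(outside))]
            mat[leak, c - 1] = sig

    # conserved deletion blocks
    for g, blocks in plan.gap_blocks.items():
        for a, b in blocks:
            mat[group_rows[g], a - 1 : b] = "-"

    # strain noise: private mutations at otherwise untouched columns,
    # one strain per column, only in groups of >= 2 strains
    noise_cols: set[int] = set()
    if plan.strain_noise > 0:
        claimed = {
            c
            for mapping in (plan.planted_specific, plan.spoiled_specific)
            for cols in mapping.values()
            for c in cols
        }
        for g in labels:
            claimed |= _gap_columns(plan, g)
        eligible = [c for c in range(1, n + 1) if c not in claimed]
        noisy_rows = [
            i for i in range(len(rows)) if len(group_rows[row_group[i]]) >= 2
        ]
        for i in noisy_rows:
            hits = rng.random(len(eligible)) < plan.strain_noise
            for c, hit in zip(eligible, hits):
                if hit and c not in noise_cols:
                    mat[i, c - 1] = alt_base(mat[i, c - 1])
                    noise_cols.add(c)

    records = []
    for i, g in enumerate(row_group):
        k = group_rows[g].index(i) + 1
        records.append(
            StrainRecord(
                taxon_id=g,
                gene_id=plan.gene_id,
                strain_id=f"s{k}",
                sequence="".join(mat[i]),
                raw_header=EM_DASH.join(
                    [g] + ([plan.gene_id] if plan.gene_id else []) + [f"s{k}"]
                ),
            )
        )
    aln = GroupedAlignment.from_records(records)

    truth: dict[str, set[int]] = {g: set() for g in labels}
    for g, cols in plan.planted_specific.items():
        truth[g].update(cols)
    for g in plan.gap_blocks:
        truth[g].update(_gap_columns(plan, g))
    if plan.n_groups == 2:
        # the other group's unchanged backbone base is absent outside it
        other = {labels[0]: labels[1], labels[1]: labels[0]}
        for g in labels:
            planted = set(plan.planted_specific.get(g, ())) | _gap_columns(plan, g)
            truth[other[g]].update(planted - noise_cols)
    return aln, truth


def random_plan(
    seed: int,
    n_groups: int | None = None,
    strains_per_group: Sequence[int] | None = None,
    n_columns: int | None = None,
    planted_per_group: int | None = None,
    strain_noise: float = 0.02,
    with_gap_blocks: bool = False,
) -> PlantPlan:
    """Draw a random feasible plan (used for stress/property testing).

    Unset dimensions are sampled: 2-5 groups, 1-6 strains per group,
    400-5,000 columns, up to 25 planted columns per group.
    """
    rng = np.random.default_rng(seed)
    if n_groups is None:
        n_groups = int(rng.integers(2, 6))
    labels = [f"G{i + 1}" for i in range(n_groups)]
    if strains_per_group is None:
        strains_per_group = [int(rng.integers(1, 7)) for _ in range(n_groups)]
    if n_columns is None:
        n_columns = int(rng.integers(400, 5001))
    if planted_per_group is None:
        planted_per_group = int(rng.integers(3, 26))

    free = list(rng.permutation(np.arange(1, n_columns + 1)))
    planted: dict[str, list[int]] = {}
    for g in labels:
        planted[g] = sorted(int(free.pop()) for _ in range(planted_per_group))
    gap_blocks: dict[str, list[tuple[int, int]]] = {}
    if with_gap_blocks:
        # carve one short deletion block per group from untouched columns
        used = {c for cols in planted.values() for c in cols}
        cursor = 1
        for g in labels:
            length = int(rng.integers(3, 9))
            while cursor + length <= n_columns:
                block = set(range(cursor, cursor + length))
                if not block & used:
                    gap_blocks[g] = [(cursor, cursor + length - 1)]
                    used |= block
                    cursor += length + 5
                    break
                cursor += 1
    return PlantPlan(
        n_groups=n_groups,
        strains_per_group=strains_per_group,
        n_columns=n_columns,
        planted_specific=planted,
        strain_noise=strain_noise,
        gap_blocks=gap_blocks,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
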