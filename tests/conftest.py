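import pytest

from lampmask.classify import ColumnVerdict, classify_alignment
from lampmask.synth import PlantPlan, generate_alignment


def make_verdicts(n_columns, specific=None):
    """Hand-built verdict list: `specific` maps 1-based column -> set of
    group labels; everything else is uninformative (not conserved)."""
    specific = specific or {}
    return [
        ColumnVerdict(
            column_index=i,
            conserved_common=False,
            specific_for=frozenset(specific.get(i + 1, ())),
        )
        for i in range(n_columns)
    ]


@pytest.fixture
def small_plan():
    """3 groups x 2 strains, 60 columns, G1 signatures at 5, 18, 25."""
    return PlantPlan(
        n_groups=3,
        strains_per_group=2,
        n_columns=60,
        planted_specific={"G1": [5, 18, 25]},
        seed=1,
    )


@pytest.fixture
def small_alignment(small_plan):
    return generate_alignment(small_plan)


@pytest.fixture
def rich_plan():
    """3 groups x 3 strains, 900 columns, hotspot for G1, noise, one
    conserved deletion block for G3."""
    return PlantPlan(
        n_groups=3,
        strains_per_group=3,
        n_columns=900,
        planted_specific={
            "G1": list(range(400, 460, 2)),
            "G2": [100, 105, 110, 115],
        },
        strain_noise=0.01,
        gap_blocks={"G3": [(700, 706)]},
        seed=11,
    )


@pytest.fixture
def rich_alignment(rich_plan):
    return generate_alignment(rich_plan)


@pytest.fixture
def rich_verdicts(rich_alignment):
    aln, _ = rich_alignment
    return classify_alignment(aln)
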