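# Methods

## Column classification

Let the alignment have records r_1…r_n partitioned into taxon groups by
their header labels. For one column with characters c_1…c_n:

- **conserved-common** iff all characters are equal and are a plain
  base (A/C/G/T). Gaps and IUPAC ambiguity codes break the call — this
  mirrors the Clustal `*` convention, and a position that is ambiguous
  in any strain is not a safe primer site.
- **taxon-specific for group G** iff (a) every member of G carries the
  same character c, (b) c is a plain base or the gap character, (c) c
  occurs in no record outside G, and (d) when c is the gap, every
  outside record carries a plain base (the deletion itself is then the
  group's signature). Within-group variation at the column
  (strain-specific polymorphism) always disqualifies it for that group.

Specificity is *strict exclusion* rather than consensus difference: the
signature character must be absent from every off-target record, since
a primer 3′-end mismatch is only guaranteed against every off-target
strain under that condition. Ambiguity codes are treated
conservatively: inside the focal group they disqualify outright; in an
outside record, a code whose IUPAC expansion could equal the signature
base (e.g. `N`, or `R` versus a signature `A`) also disqualifies the
column. The alternative — treating outside ambiguity as a mismatch —
would call columns specific on evidence that may not support them.

A consequence worth knowing: in a two-group alignment a column that is
specific for one group is usually specific for the other as well
(whatever base the second group shares then occurs nowhere outside it).
This is forced by the definition, not an artefact.

## Average mutation index

Columns are tiled into consecutive non-overlapping fragments of 20
(one primer annealing site); M_f is the number of columns in fragment
f that are taxon-specific for the group under analysis. The index is
the simple moving average over w fragments,

    S̄_f = (M_f + M_{f−1} + … + M_{f−w+1}) / w,

computed by the sliding recurrence S̄_f = S̄_{f−1} − M_{f−w}/w + M_f/w
after a direct sum for the first window (the direct form is kept as an
independent oracle; the two agree to < 1e-9 by test). Each value is
anchored to the central fragment of its window, which requires w odd.

Parameter defaults, with units:

| parameter | default | why |
|---|---|---|
| fragment length | 20 nt | one primer annealing site |
| window | 300 bp = 15 fragments | effective LAMP amplicons stay under ~300 bp |
| selection threshold | S̄ ≥ 2 | recommended minimum density for specific design |
| region size cap | 2,000 columns | downstream primer-design input limit |

Numerical and edge choices:

- The window slides by one whole **fragment**, not one column — the
  recurrence removes and adds whole-fragment counts, so the profile's
  resolution is per-fragment.
- No edge padding: S̄ is undefined for the first and last (w−1)/2
  fragments. Padding would bias the edges toward zero.
- A trailing partial fragment keeps its count in tables and the
  processed alignment but is excluded from the SMA, because it breaks
  the per-20-nt normalisation.
- Region selection centres a window of at most 2,000 columns on the
  peak's central fragment, clamped to the alignment bounds. Ties in
  the peak resolve to the **leftmost** window; a plateau of tied
  windows therefore anchors at its left end. This is deterministic and
  documented, not meaningful.
- When no window reaches the threshold the CLI exports the whole
  alignment if it fits the size cap, otherwise the best (sub-threshold)
  window, with a log note either way.

## Masked target export

The exported target is the focal group's **majority consensus** over
the selected region, degapped. Majority is per column over plain bases
only; ties resolve alphabetically (A<C<G<T) and are logged; a column
whose focal majority is the gap is dropped (it does not exist in the
target); a column with no plain focal base at all is dropped with a
warning, never silently substituted. A consensus represents the taxon
and is deterministic; `--focal-strain` exports one named strain's
sequence instead.

The annotation line under each 60-character sequence line marks the
mapped conserved-common columns with `*` and the focal group's
taxon-specific columns with `-`; the two sets are disjoint by
construction. Conserved-deletion signatures cannot carry a mark on a
degapped sequence: they are counted in profiles and the processed
alignment but omitted from the mask (logged). The wrap width of 60 with
interleaved annotation lines keeps marks aligned both visually and for
parsers; LF or CRLF terminators are selectable for downstream tools on
either platform.

Header parsing defaults to the em-dash delimiter as printed in the
header grammar; no silent fallback to the hyphen is attempted, because
mis-splitting accession-style names quietly is worse than an explicit
error (`--delimiter` overrides). Sequences are uppercased on ingest and
RNA `U` is transliterated to `T` (logged once).

## Synthetic alignments and what tests show

The generator (`lampmask.synth`) plants exact, known structure on a
random backbone: per-group signature columns (a base absent outside the
group), optional conserved deletion blocks, and per-strain private
mutations ("strain noise") at columns disjoint from all planted
structure, one strain per column, only in groups of two or more strains
— so noise columns are group-polymorphic by construction and the
ground truth stays exact rather than statistical. An adversarial mode
leaks a signature base into one outside record to verify that spoiled
columns are rejected. The two-group complement effect described above
is folded into the returned truth.

Default stress conditions: 2–5 groups, 1–6 strains per group,
400–5,000 columns, noise rate 0.02 per strain and eligible column —
alignment sizes typical of single-gene ortholog panels. What passing
tests demonstrate: the classifier implements its definition exactly and
the pipeline's bookkeeping (tiling, anchoring, masking, coordinates) is
correct. What they do not demonstrate: performance on real data, where
sequencing error, misalignment, recombination and sampling bias violate
the generator's clean assumptions; no substitution model or indel
process is simulated.

## Known limitations

- Nucleotide alignments only; no codon-aware or protein logic, and no
  phylogenetic weighting of strains — every strain counts equally.
- Primer design itself (Tm, GC, loop structure) is out of scope; the
  masked file is the hand-off to a dedicated design tool.
- The classifier is exact set logic per column; it has no notion of
  statistical support, so a single mislabelled strain in the input
  removes every signature it conflicts with.
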