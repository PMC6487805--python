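# lampmask

Taxon-specific mutation discovery in multi-species, multi-strain
nucleotide alignments, with masked-target export for LAMP
(loop-mediated isothermal amplification) primer design.

## The problem

Designing a *species-specific* LAMP assay means placing primer ends on
positions that are conserved in every strain of the target taxon but
absent from every close relative. Given a multiple sequence alignment
of orthologues that spans several taxa and several strains per taxon,
`lampmask`:

1. classifies every alignment column, per taxon group, as
   **conserved-common** (identical unambiguous base across all
   records), **taxon-specific** (one group shares a signature
   character that no outside record carries — strain-level
   polymorphism within the group disqualifies the column), or
   uninformative;
2. profiles the density of taxon-specific mutations with an
   **average mutation index**: the alignment is tiled into 20-nt
   fragments (one primer annealing site), per-fragment counts
   M_f are smoothed by a simple moving average over a window of
   w fragments,

   ```
   S̄_f = (1/w) Σ_{i=0}^{w-1} M_{f-i}
       = S̄_{f-1} − M_{f-w}/w + M_f/w      (sliding recurrence)
   ```

   anchored to the *central* fragment of the window (w odd; default
   w = 15 fragments = 300 bp, matching effective LAMP amplicon sizes);
3. auto-selects, per taxon, a target region of at most 2,000 columns
   centred on the index peak (regions with S̄ ≥ 2 are recommended); and
4. exports, per taxon, a **masked target file** ready for primer-design
   services: the ungapped focal consensus with a parallel annotation
   line marking conserved-common positions with `*` and taxon-specific
   mutations with `-`, so the designer can steer primer 3′ ends onto
   the specific sites.

Group membership is read from the record headers, which use a
delimiter-separated grammar (em-dash by default, configurable):

```
>TaxonID—GeneID—StrainID      or      >TaxonID—StrainID
```

Strains with identical taxon labels form one group; record and group
order follow the input. Clustal files (with or without per-line
cumulative residue counts) and aligned FASTA are accepted.

## Worked example

```python
from lampmask import (PlantPlan, generate_alignment, classify_alignment,
                      count_fragment_mutations, build_profile)

plan = PlantPlan(n_groups=3, strains_per_group=2, n_columns=60,
                 planted_specific={"G1": [5, 18, 25]}, seed=1)
aln, truth = generate_alignment(plan)
verdicts = classify_alignment(aln)
M = count_fragment_mutations(verdicts, "G1", 20)
print(M)                                     # [2, 1, 0]
prof = build_profile(verdicts, "G1", fragment_len=20, window_bp=60)
print(prof.S, prof.anchors)                  # [1.0] [(21, 40)]
```

The three planted G1 signature columns (5, 18, 25) tile into the three
20-nt fragments as counts 2, 1 and 0; a 3-fragment window has a single
average mutation index value, (2+1+0)/3 = 1.0, anchored to the middle
fragment (columns 21–40, 1-based).

The full workflow runs from the shell:

```
catch input.aln --out results --project-id demo
```

which writes, per taxon group, a profile table, density plots (eps,
pdf, png, svg, tiff), and a masked primer-design input, plus one
processed alignment with per-fragment mutation counts and a JSON
manifest — 22 output files for a 3-group alignment. Add `--zip` for a
single archive, `--line-endings windows` for CRLF output, and
`--delimiter` if your headers do not use the em-dash. See
`catch --help` for every option; `docs/methods.md` documents the model
and the numerical choices.

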