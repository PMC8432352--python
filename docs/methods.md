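# Methods

## The problem and the model

*Ackermannviridae* phages present up to four tail spike proteins (TSP1–TSP4)
on a branched receptor-binding complex. Two architectural facts drive
everything in this package:

* the **N-terminus of each TSP is type-specific and conserved** family-wide
  (it docks the protein into the complex), so a protein can be typed by
  N-terminal similarity alone;
* the **C-terminal receptor-binding module is free to diverge** and is
  occasionally exchanged between TSP scaffolds, so module similarity — not
  type — predicts receptor specificity.

The pipeline turns these facts into operations: anchored cluster
extraction, N-terminal typing, identity-threshold subtyping, C-terminally
anchored module-share detection, junction-motif discovery, whole-genome
ANI, and host-label transfer over subtypes and module-equivalence links.

## Pairwise identity (the single primitive)

All protein comparisons use one scoring scheme: BLOSUM62, affine gaps
costing 10 + 1·L for a gap of length L, end gaps charged like internal gaps
(`Bio.Align.PairwiseAligner`, open −11 / extend −1 in its convention).
Identity is identical columns divided by **total alignment columns, end
gaps included** — the conservative denominator: it can only lower identity,
so every ≥ 75 % decision would also hold under the lenient "aligned columns
only" convention (available via `AlignmentParams.denominator` for
sensitivity analysis). The identity separation this package relies on is
wide (within-subtype ≳ 0.9 vs cross-subtype ≲ 0.35 around a 0.75 cut), so
the substitution-matrix choice is immaterial; BLOSUM62 is the default
because it is the field's default.

Two consequences of the cheap gap extension are worth knowing. First,
optimal *local* alignments of unrelated ~200-residue sequences can chain
chance positive patches into blocks longer than 100 columns — at ~20–25 %
identity. Length filters alone therefore mean little for local alignments;
every local decision here pairs a length floor with an identity floor.
Second, the left edge of a local block is unstable: the aligner may drag a
few weak columns ahead of a genuinely shared region. Module-share start
positions are therefore **refined to the first run of five consecutive
identical columns** — a run with chance probability ~20⁻⁵ per position,
whereas a real module junction opens with the conserved 7-mer motif. When
the scaffold residues immediately flanking the junction happen to be equal
in both proteins, the shared region genuinely begins one residue earlier
and is reported as such; the packaged reference scaffolds have distinct
flank residues, as the real types do.

## Stage parameters (defaults, units, rationale)

| parameter | default | rationale |
|---|---|---|
| anchor/wedge identity floor | 0.5 | *vriC* and the wedge are well conserved; 0.5 separates them from background (~0.25) with a wide margin |
| min full-length TSP | 500 aa | shortest real TSP ≈ 698 aa; 500 keeps margin while excluding small ORFs |
| cluster walk cap | 6 features | 4 TSPs + one interleaved small ORF + the wedge |
| typing windows | 150/250/150/450 aa (types 1/3, 2, 4) | cover the conserved N-terminal (TD/XD) region of each type without reaching far into the module |
| typing floor | 0.30 | background identity between unrelated windows ≈ 0.25; within-type windows score ≳ 0.5 even at 15 % scaffold divergence |
| subtype threshold | 0.75 (inclusive) | the published cut; single-linkage components, since within-subtype members are typically > 95 % identical the linkage choice is immaterial |
| module share | identity ≥ 0.75 over ≥ 300 aa, ends within 10 aa of both C-termini | formalises "similar except for the N-terminal domains"; reported real module identities are 91–100 % |
| motif discovery | k ∈ [5,10], exact match, support ≥ 0.8 | the motif is reported as verbatim-conserved; a mismatch budget is exposed but off by default |
| ANI | 500-nt fragments, 15-mer seeds, blocks ≥ 100 nt; match +1, mismatch −2, gap 4 + 2·L | standard fragment-ANI practice with the published seed/block floors; identity per block over all block columns |

Subtype labels (`TSP{t}-{k}`) are ordered by descending component size with
lexicographic tie-break, so they are input-order invariant — but they are a
property of the analysed cohort, not of any published labelling;
correspondence to published subtype names goes through membership lists.

## The knowledge base

`src/ackertsp/data/` packages a transcription of the published
subtype → receptor/host table: 13 entries, per-subtype phage membership
lists, and three shared-module equivalence links (TSP1-1~TSP4-7,
TSP3-3~TSP4-2, TSP3-1~TSP4-8). Predictions inherit the `experimental` tier
only over a direct subtype match; any equivalence hop downgrades to
`inferred`. One published row prints a total (32) that disagrees with its
own name list (30); the loader records the mismatch in
`KnowledgeBase.count_mismatches` rather than silently picking a side.
Receptors are encoded at serogroup level (e.g. the broad-range TSP3 entry
covers O:4 and O:9 jointly); strain-level exceptions such as O-antigen
acetylation are not modelled.

## The synthetic cohort generator

`ackertsp.simulate` emulates exactly the statistics the analysis assumes:

* **Genomes**: per-genus random backbone (default 20 kb desk scale; real
  genomes are ~157 kb, a config switch restores realistic lengths) with one
  co-oriented cluster spliced in: *vriC*, 3–4 TSP genes (optionally a small
  decoy ORF between them), wedge. Within a genus each phage's backbone
  diverges from a common ancestor at the configured rate (defaults 1.5–5 %
  bracketing the published within-genus ANI ranges).
* **Proteins**: TSP = family-conserved type scaffold (64/260/64/390 aa,
  mutated per phage at 5 %) + module drawn from the genus/type subtype pool
  (mutated at 2 %). Modules of types 1/3/4 open with GTTAVSL, which is
  exempt from mutation (conserved in the real family), putting the motif at
  residues 65/65/391. With probability `p_swap` (default 0.05) a phage's
  TSP4 carries the module of its own TSP1 or TSP3 subtype — a planted swap
  with recorded junctions. 20 % of phages lack TSP3, the one type absent in
  a fifth of real genomes. Genus sizes (6/3/4/2) mirror the family's skew
  toward *Kuttervirus* at desk scale.
* **Nucleotides**: each ancestral gene is back-translated once with uniform
  random synonymous codons; per-phage protein substitutions are mirrored by
  a random codon of the new residue. Synonymous choices are thereby
  inherited along lineages, as in real genomes — nucleotide similarity
  tracks protein relatedness, and ANI reflects backbone plus conserved-gene
  divergence. Every gene starts with Met/ATG so the ORF fallback can
  rediscover it on unannotated input.
* **References**: the packaged reference proteins (vriC, wedge, four
  full-length type-defining TSPs) are *synthetic stand-ins*, generated once
  from a fixed RNG and frozen, with lengths matching the reported real TSP
  gene lengths. Real analyses must supply real reference FASTA; the
  synthetic ones exist so that the generator, the typing references and the
  tests form one closed, download-free world.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: codon usage and GC skew, insertions/deletions
(all divergence is substitutional), rearrangements, partial or frameshifted
TSP genes, annotation errors beyond missing `/translation` qualifiers, and
real O-antigen chemistry. `mutate()` substitutes exactly round(rate·len)
distinct positions, so divergence levels are exact rather than binomially
noisy.

## Numerical and degenerate-input choices

* Typing ties within 10⁻⁹ → unassigned with an `ambiguous` flag; within a
  phage, a contested type goes to the higher N-terminal identity (ties: the
  earlier cluster position).
* Candidate translations with internal stops are rejected downstream, not
  at parse time; codons containing N translate to X; ambiguity codes other
  than N are rejected at parse time.
* ANI of a pair with no qualifying block is reported as absent (NaN in the
  matrix), never as 0 — absence of alignment is not zero identity. The
  symmetrized value is the mean of the two directions.
* Motif hits suppress any shorter motif contained in a reported longer one
  at equal support; positions are 1-based first occurrences.
* All pipeline outputs are sorted and fixed-format; two runs on the same
  inputs are byte-identical (the manifest records the run directory, which
  may differ).

## Scale choices

Test and acceptance cohorts use 5–15 phages with 5–20 kb backbones, sizes
at which the full pipeline (hundreds of ~700–1200-residue global alignments
plus a full ANI matrix) completes in seconds per cohort while leaving every
statistical separation (identity blocks, ANI cohesion, motif support) far
from its thresholds. The acceptance script averages subtype recovery over
five cohorts and 20-seed sweeps run in the test suite.

## Known limitations

* Subtyping is single-linkage: one aberrant intermediate protein could
  bridge two otherwise-distinct subtypes. Real cohorts show a wide identity
  gap (≳ 95 % within vs ≲ 30 % between), so this is theoretical; raising
  the threshold only ever splits (refinement monotonicity is tested).
* The ANI block model is a reconstruction of fragment-based ANI practice,
  not of any proprietary aligner; absolute values on real data may shift by
  a point or two, though genus-cohesion *ordering* is robust.
* Module-share detection requires the shared block to reach both
  C-termini; a swap followed by substantial C-terminal divergence of one
  partner would be missed by design.
* Host predictions are label transfers: they inherit every limitation of
  the underlying experimental table, including serogroup granularity and
  its one internally inconsistent row.
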