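# Methods

This note documents the models and procedures `orscan` implements, the
defaults that matter, and what the synthetic-data validation does and
does not demonstrate.

## Translated homology search

The search emulates a TBLASTN-style protein-vs-translated-genome scan.
All six reading frames of each genome record are translated (codons
containing N translate to `X`, which never matches a stop — ambiguous
sequence therefore cannot create spurious defects). Candidate regions
are found by exact 4-mer amino-acid seeding on the translated frames,
extended without gaps under an X-drop of 20, and every surviving
candidate (ungapped score ≥ 40) is rescored by exact Smith–Waterman
affine-gap alignment of the full query against a padded subject window.
Scoring is BLOSUM62 with gap open 11 and extend 1; a gap of length *g*
costs `open + (g−1)·extend`. Reported scores are therefore exact local
alignment scores of the query against the spanned subject; the seeding
only decides *where* to align. An exhaustive dynamic-programming oracle
is kept in the test suite and the scan is required to agree with it.

Hit significance uses the Karlin–Altschul expectation
`E = K·m·n·e^(−λS)` with the standard gapped BLOSUM62/11/1 constants
λ = 0.267, K = 0.041 (configurable). The search space *n* is the total
translated genome length in amino acids over both strands
(2·length/3 summed over records), *m* the query length. Hits are kept
at E ≤ 1e−10.

HSPs on one chromosome and strand whose genomic gap is below
`max_chain_gap` (default 5 kb) chain into candidate loci; since OR genes
are single-exon, chains only need to bridge HSPs split by frameshifts
or in-frame stops, so the default is deliberately far below the 1 Mb
cluster scale. Chaining is single-linkage over the interval envelope,
which equals the transitive closure of the gap relation (property-tested
against an O(n²) union-find oracle). Each locus records its best query
by lowest E-value, then longest aligned span, then lexicographic id.

## Gene models and status

The locus envelope is extended by 1,500 bp of flank on both sides —
enough to recover a full ~310-codon OR ORF beyond any HSP. The reading
frame is anchored on the best HSP, and the gene is the stop-free
in-frame interval that overlaps the aligned envelope the most, from the
first ATG *preceding the aligned region* (15 codons of alignment-start
jitter tolerated) to the first downstream stop. Requiring the ATG to
precede the alignment matters: a methionine deep inside the aligned
region is an internal residue, not a start, and accepting it would
silently "repair" 5′-truncated genes.

Defects:

* **premature_stop** — an in-frame stop strictly interior to the aligned
  envelope, *and* the best query aligns with score ≥ 60 to the
  translated envelope on each side of it. The two-sided support
  requirement rejects stops that sit in noisy alignment overhangs
  (local alignments occasionally extend a few codons into flanking
  sequence), which otherwise misclassify truncated genes as
  pseudogenes.
* **frameshift** — colinear HSPs of the same query on one strand that
  advance along the query while switching reading frame.
* **missing_start / missing_stop** — no qualifying ATG, or the ORF runs
  off the extended region without a stop codon.
* **too_short** — an otherwise intact ORF of ≤ 250 aa.

Status is a total, deterministic function of the defect set: any
ORF-disrupting defect (premature stop, frameshift) ⇒ pseudogene;
otherwise any boundary defect or short ORF ⇒ partial; otherwise
functional, which therefore requires a defect-free ORF of ≥ 251 aa
("more than 250 amino acids" read strictly). Disruptive defects take
precedence when defects co-occur, on the view that a broken reading
frame is stronger evidence of pseudogenization than a missing boundary.

Candidates are verified by comparing the model peptide's best local
alignment score against the OR query set with its best score against a
decoy (non-OR) set — a self-contained stand-in for re-checking
candidates against an external protein database; candidates scoring no
better against ORs than decoys are dropped with a logged reason.
Overlapping same-strand models are deduplicated keeping the higher
verification score, then the longer peptide.

## Topology and glycosylation sites

Transmembrane prediction is Kyte–Doolittle window-averaged hydropathy:
each residue's score is the mean over a centred window of 19 (truncated
at the termini), runs above 1.6 become segments, segments closer than 3
residues merge, and segments shorter than 15 aa are dropped. Models
with 6–8 segments are flagged `topology_ok`. The prediction annotates
models without changing their status — a strict mode (`require_7tm`)
that drops models outside 6–8 helices exists but is off by default,
since topology checking is a recheck, not a filter. This is a
deliberately simple hydropathy method, not an HMM: it does not predict
inside/outside orientation and will undercount helices interrupted by
polar residues. N-glycosylation sites are canonical N-X-S/T sequons
with X ≠ P; overlapping sequons are all reported.

## Clusters and repertoire tables

A cluster is a maximal single-linkage chain of genes on one chromosome
in which consecutive genes are separated by strictly less than 1 Mb,
measured between nearest gene edges (the conservative reading; a gap of
exactly 1,000,000 bp does not join). Whether the rule chains
transitively is genuinely open; single-linkage chaining is adopted and
exposed via `max_gap`. A cluster is flagged as a candidate tandem array
when all of its ≥ 2 members share one transcriptional orientation.
Summary tables report counts and percentages (two decimals, half-up
rounding to match conventional report precision) at species and
per-chromosome granularity; chromosome size is carried as a reporting
field only — no relation between chromosome size and OR count is
assumed.

## Motif discovery

The motif model is ZOOPS (zero or one occurrence per sequence): with
probability γ a sequence contains one motif occurrence uniform over
valid offsets, otherwise it is pure background; the motif is a PWM over
the 20 amino acids and the background is the 0-order empirical residue
distribution of the input. EM alternates site posteriors with
pseudocount-regularized (α = 0.01) PWM and γ updates until the
penalized log-likelihood improves by less than 1e−6 or 100 iterations.
Because EM converges readily to off-by-one optima, each run finishes
with column-shift refinement: the converged PWM is slid left/right by
up to two columns (vacated columns filled with background) and EM rerun,
keeping any improvement.

Top-k discovery (default k = 5) runs EM over a width grid
{8, 10, 12, 15, 20, 30, 50} — a full 5–50 scan is available by flag —
with 5 seeded restarts per width; each restart screens 10 candidate
starting windows drawn from the data with a 2-iteration burn-in and
refines the best. Widths compete on a BIC-style length-penalized
log-likelihood ratio (19 free parameters per column, scaled by log of
the realized site count), which stops pure-background columns from
inflating the width. The winner's sites are masked before the next
rank; windows overlapping masked positions are excluded as candidate
sites, so successive motifs never overlap. Everything is driven by
seeded generators and reruns are bitwise identical.

On sets of full-length homologous OR peptides the top motifs are wide,
because flanking columns are themselves conserved within the family;
the canonical DRY-region block then appears inside a longer consensus.
The planted-motif validation therefore embeds the block in random
flanks, where exact recovery is the correct expectation.

## Distances, trees and group assignment

Pairwise distances are 1 − identities / aligned columns from global
affine-gap alignments (BLOSUM62, 11/1). Trees are classic neighbor
joining — Q-matrix pair selection, Saitou–Nei branch lengths, negative
branches clamped to zero, deterministic tie-breaking by the
lexicographically smallest subtree labels, three-point termination —
exported as newick. NJ is exact on additive matrices and is
property-tested as such, with `skbio.tree.nj` as an independent
cross-check. Approximate-ML tree inference on a multiple alignment is
intentionally not re-implemented: distance-based NJ is the one
methodological substitution in the package, and the newick export lets
users substitute an externally built tree.

Group assignment defaults to nearest-reference (robust, no MSA
required): each gene takes the group of its closest labelled reference,
with exact ties resolved to the alphabetically first group; support is
the nearest-reference distance. Tree mode assigns the group of the
smallest NJ clade containing the gene and at least one reference,
falling back to nearest-reference when that clade mixes groups. Groups
β, γ, δ, ε, ζ map to type I and η, κ to type II; θ and λ are accepted
as reference labels but typed as non-OR. Bootstrap support is out of
scope in the distance-only path. Expansion detection reports
`fold = focal count / mean per-species reference count` with the
denominator floored at one gene, flagging `fold ≥ 2` (configurable).

## Synthetic genomes

The generator emulates the repertoire structure the pipeline targets.
Defaults define the reference study condition: 2 chromosomes × 1 Mb of
iid background at GC 0.41 (fish-like), 3 clusters of 10 template copies
(30 genes), intergene gaps uniform in 6–25 kb (realistic OR cluster
spacing, and above the 5 kb HSP chain gap so neighbouring genes cannot
fuse into one locus), same-strand orientation within a cluster, 5%
per-copy amino-acid divergence, 6% pseudogenization and 3% truncation —
the category mix of a low-pseudogene teleost repertoire.

Templates follow OR architecture: ~307 aa with seven 21-aa hydrophobic
helices (I/L/V/F) separated by hydrophilic loops, the conserved
`MAYDRYVAIC` block at the helix-3 junction, an N-terminal N-G-T sequon,
and group-specific randomized loop/helix composition (pairwise template
divergence well above 25%, so group assignment is well-posed).
Back-translation draws synonymous codons uniformly — codon bias is
irrelevant to every downstream test. Pseudogenizing lesions (one
premature stop or a 1-nt frameshift, chosen uniformly) land in the
middle 60% of the CDS so they fall inside alignable sequence;
truncations remove one third of the CDS from the start (ATG lost) or
stop end — large enough that a truncated gene cannot masquerade as an
intact ORF of > 250 aa after running into flanking sequence. The
initial methionine is excluded from divergence substitutions so
mutation load never silently deletes the start codon. A truth table
records every planted gene's coordinates, strand, status, template,
group and cluster.

What the simulation does **not** emulate: repeats and isochore
structure, multi-exon decoy genes, codon bias, assembly gaps, and
cross-species query divergence beyond simple iid substitution. Passing
the planted-truth tests therefore demonstrates correctness of the
pipeline's logic under clean single-exon conditions, not performance on
repeat-rich real assemblies.

## Problem sizes and numerical choices

The validation suite runs the full pipeline on the reference simulation
(2 × 1 Mb, 30 genes) and on a compact variant (2 × 300 kb, 15 genes,
elevated lesion rates); oracle batteries use 200 random alignment
pairs, 100 random cluster layouts, 300 random peptides and 50 random
additive matrices of up to 8 taxa. These sizes keep the whole suite in
the minutes range on one CPU while exercising every code path.
Degenerate inputs are defined throughout: empty gene lists summarize to
zero with a warning, sequences shorter than the motif width are skipped
with a warning, singleton clusters have orientation fraction 1 and no
tandem flag, and peptides shorter than the hydropathy window are
annotated with zero helices rather than an error at the pipeline level.
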