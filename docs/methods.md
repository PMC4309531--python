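# Methods

`phamclade` reimplements, as a reusable library, the comparative-genomics
workflow used to delineate clades ("genera") among closely related virulent
phage genomes: pairwise similarity-based homology calls, transitive protein
families, core-gene identification, profile-based screening for remote
relatives, a concatenated-core phylogeny, and discovery of repeated
intergenic promoter elements. This note records the models, the parameters
that matter, and the design decisions taken where the procedure left room.

## Pairwise homology

Two proteins are homologous when

* their end-gap-free (semi-global) Needleman–Wunsch alignment under BLOSUM60
  shows **> 40 % similarity**, and
* their lengths differ by **< 50 %** of the longer length.

*Alignment objective.* Affine gaps with `gap_open = −11`, `gap_extend = −1`
(configurable; these are common defaults for BLOSUM-family matrices — the
original procedure does not state its penalties). Terminal gap runs in
either sequence cost nothing. The dynamic program allows an alignment to
leave *both* sequences' terminal segments unaligned at zero cost; this is
the exact optimum of the "terminal gaps are free" objective, and the unit
tests pin it to a brute-force enumeration over all alignments
(monotone aligned-pair subsets with closed-form interior gap costs).

*Similarity and identity.* Similarity = aligned residue pairs with a
positive matrix score, divided by the **longer** protein's length.
The procedure's own denominator is unstated; we use the longer length
because the shorter-length convention lets a short protein reach 40 % by
matching a cherry-picked fragment of a longer one — on synthetic data this
produced rare spurious cross-family edges that transitivity then amplified
into family mergers. With the length gate in place the two conventions
differ by at most a factor of two, and equal-length homolog pairs are
unaffected. Identity is exact matches over the aligned span (terminal
overhangs excluded).

*Matrix.* The canonical NCBI BLOSUM60 (loaded from biotite's matrix
collection), with X rescored to 0 against everything so unknown residues are
neutral.

*Complexity.* All-vs-all alignment is exact by default (~400 k pairs for the
default 11-genome set, about two minutes on one core via the shared numba
kernel). A shared-5-mer prefilter is available as an opt-in speed knob, but
it is off by default: at the divergence where homologs sit near the 40 %
threshold (~30 % raw identity), about a third of genuine homolog pairs share
no exact 5-mer, and transitive clustering cannot afford to lose those edges.

## Families, cores, clade statistics

Families are connected components of the homology graph (a protein joins a
family if homologous to any member). Within-genome pairs are evaluated so
paralogs merge (flag to disable). Family identifiers are deterministic,
ordered by the smallest member under (genome input order, coordinate).
Core families have ≥ 1 member in every genome of the roster.

The clade homology matrix reports, for each ordered genome pair (A, B), the
percentage of A's proteins with at least one homolog in B (diagonal fixed at
100). Within-clade means average ordered pairs inside a clade; the between
mean averages ordered pairs across clades. A single-genome clade has no
within mean.

The relaxed 35 % similarity mode (used before tree building) is the same
code path with one parameter changed; the pipeline aligns every pair once at
35 % and derives the 40 % graph by filtering.

Marker selection consumes an externally produced hit report
(family → best e-value) and keeps core families with no significant hit
(e > 0.001); no network search is performed. Degenerate primers come from an
exhaustive scan of codon-aware family alignments for windows (20–25 nt, no
gaps) whose per-position IUPAC degeneracy product stays ≤ 8, paired under
amplicon-length bounds.

## Profiles and remote-homolog screening

Each multi-member family is aligned progressively (UPGMA guide tree on
pairwise similarity; profile-to-profile extension of the same end-gap-free
DP) and condensed to per-column log-odds (half-bit units) over Henikoff
position-weighted counts with substitution-matrix pseudocounts
(mass 5 per column; the larger-than-minimal mass softens the penalty for
residues unseen among a column's few, correlated members). Significance is
empirical: ≥ 200 shuffled member sequences are scored and a Gumbel
(extreme-value) location/scale is fitted; a hit's e-value is
`db_size × P_null(score ≥ s)` with `db_size` the number of proteins scanned
in the current screen.

Profile–target scoring is overhang-free on **both** sides (local-style, as
in the standard profile-search tools): a remote homolog scores on the
conserved stretch it still shares with the family instead of paying for
every diverged column. This matters: with the profile forced to match end
to end, the negative contribution of diverged columns always exceeds the
conserved-motif signal, and remote homologs below the pairwise gate become
undetectable.

A genome is retained by the screen when ≥ 20 distinct family profiles
(not hits) find at least one match at e < 0.001.

## Phylogeny

Universal single-copy families (exactly one member per genome, at the
relaxed threshold) are aligned, trimmed, and concatenated. Trimming removes
columns with gap fraction > 0.2 or smoothed normalised entropy
(window 3) > 0.5 — a deliberately simple stand-in for matrix-aware trimmers,
with both cutoffs exposed. Distances are Poisson-corrected p-distances
(−ln(1 − p), p capped at 0.95) over shared non-gap columns; trees are
neighbor-joining (scikit-bio, negative branches clamped to zero), with
supports from 100 seeded column-resampling bootstrap replicates, and
midpoint rooting. A maximum-likelihood engine can be plugged behind the same
tree contract; the distance default keeps the computation fully internal
and is sufficient for topology-level questions at this scale.

## Promoter repeats and σ70 scan

Repeats are sought only between annotated genes (the elements of interest
are intergenic; a flag widens the search). Exact 15-mers occurring at ≥ 2
positions seed candidate instances; instances sharing seeds cluster
transitively; every instance is anchored to a representative frame and the
element boundary is found by X-drop extension of column conservation
(threshold 0.8, drop 1.5; for two-copy clusters 0.7/0.35, because a flank
column matches by chance 1 in 4 and the walk needs a lower bar but a much
shorter leash). Cross-genome merging compares representatives at the best
ungapped offset (identity over the shorter element, ≥ 0.8) and harmonises
instance lengths to the modal element length. Consensus profiles count
bases per position (ungapped, best-offset stacking; length differences
beyond 2 nt are irreconcilable); the strictly conserved count is the number
of positions where all instances agree.

Two-copy clusters sit at an information floor: with n = 2 every flank
position has a 25 % chance of agreeing by accident, so boundary calls can
overshoot by a few bases and occasionally a doubly mutated edge truncates an
element below the length cutoff. On the default synthetic set this costs
~2 of the 10 second-clade instances; the six-copy clade is recovered
exactly.

The σ70 scan slides both strands for TTGACA (−35) and TATAAT (−10) with ≤ 1
mismatch per box and a 15–19 nt spacer (bracketing the canonical 17), and is
tested against a naive full scan.

## Synthetic data

The generator emulates the study design so every stage has planted truth:

* **Structure** — two clades of 6 + 5 genomes; 26 core families (one copy in
  every genome), 45 clade-specific families per clade, 10 orphans per
  genome; mean protein length 150 aa (uniform ± 40).
* **Evolution** — two-level star-within-clades genealogy: root → clade
  ancestors (half the between-clade divergence each) → genome copies
  (within-clade divergence 0.05). Substitutions draw the replacement from a
  tempered substitution-matrix-conditional distribution (∝ bg·2^(s/4));
  the tempering lets repeated substitution converge to background instead of
  saturating at ~45 % similarity.
* **Site rates** — each family carries per-site rate multipliers: two
  conserved motif blocks of 12 residues (rate 0.02) in an otherwise
  Gamma(shape 4) background. Conserved motifs are what make profile
  searches more sensitive than pairwise comparison, and without them no
  divergence window exists in which a homolog evades the 40 % pairwise gate
  yet remains profile-detectable.
* **Calibration** — between-clade divergence 0.85 puts cross-clade ortholog
  similarity at ~50 % (mean 50.2, 0/25 replicate families failing to merge).
  Pushing the mean to ~45 % makes about 1 in 20 families fail to merge
  across clades, which breaks exact family recovery, so ~50 % is as close
  as the design reliably allows. The remote-homolog outgroup evolves
  straight from the root at divergence 0.99: pairwise similarity ~24 %
  (all sampled pairs below the 40 % gate) yet all 25 shared families are
  detected by their profiles at e < 0.001.
* **Genomes** — genes are reverse-translated with synonymous codon usage
  exponentially tilted to hit each clade's GC target (49.3 % / 54.8 %,
  solved by 1-D root finding with the fixed TAA stops accounted for);
  intergenic spacers are drawn at the target GC; tRNA blocks (12 vs 3) sit
  upstream of the anchor ("large terminase") ORF; ~20 % of genes are placed
  on the reverse strand.
* **Repeats** — a 41-nt master element per clade embeds exact
  TTGACA-N17-TATAAT boxes; copies (5,6,5,6,5,5 in clade A = 32; 2 per
  genome in clade B) are planted in designated spacers with per-position
  mutation probability 0.012 outside the protected boxes, which puts the
  expected strictly conserved count near 32 of 41 for the 32-copy clade.
  The realised count is recorded in the truth object and is what tests
  compare against.
* **Coverage** — per-base Poisson(50) depth with one 500-bp, 3× terminus
  block at the genome start.

What the generator does *not* emulate: insertions/deletions within coding
sequences (family members are length-identical, so multiple alignment is
easy by construction), genome rearrangement and mosaicism, sequencing error,
and real intergenic sequence structure. Passing the planted-truth tests
therefore shows the pipeline's logic is correct under the stated model; it
does not bound performance on real genomes with indels or mosaic ancestry.

## Numerical choices and degenerate inputs

* Deterministic tie-breaks throughout: diagonal > vertical > horizontal in
  DP traceback; full-corner end cell preferred; family ids by smallest
  member; NJ ties by taxon order (via the distance-matrix id order).
* All randomness (decoy calibration, bootstrap, generator) flows from
  explicit integer seeds; the same seed reproduces byte-identical outputs.
* Empty intergenic sets, single-member families, all-gap columns,
  single-genome clades, zero-length trees and all-zero coverage tracks are
  handled (empty result, trivial profile, dropped column with warning,
  absent mean, warned arbitrary root, warned empty list respectively).
* Problem sizes for the default verification run: 11 genomes × 81 proteins,
  ~400 k pairwise alignments, 134 profiled families, 100 bootstrap
  replicates — about five minutes end to end on one core.

## Known limitations

* The pairwise stage is quadratic in total protein count; beyond a few
  thousand proteins the opt-in k-mer prefilter or an external search tool
  becomes necessary.
* Progressive alignment has no iterative refinement; with real indels the
  profile columns blur and profile sensitivity drops.
* E-value calibration assumes the shuffled-decoy null transfers to real
  proteome composition.
* Two-copy repeat clusters have intrinsically fuzzy boundaries (above).
* The genus-assignment thresholds (40 % shared proteins; 20 % subfamily
  band) are conventions exposed as configuration, not estimated quantities.
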