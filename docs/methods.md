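# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the simulation-based tests do and do not
demonstrate about real repertoire data.

## The analysis model

The pipeline treats a repertoire sample as the set of *unique VH nucleotide
sequences* observed in one (subject, timepoint, B-cell subset) cell
population. Sequences are validated molecule-wise: a UMI group supports a
consensus only with at least 5 reads and a mean within-group mismatch
fraction of at most 0.1, computed against the Phred-weighted majority call
(positions with tied base weights are called N and excluded from the error
computation — a deterministic, conservative convention). Identical consensus
sequences under different UMIs are PCR-independent captures of the same
transcript sequence and merge into one unique sequence whose
`duplicate_count` is the copy number. The read quality filter uses
mean-read Phred ≥ 20; a per-base trimming reading of the same threshold would
also be defensible, and the mean-read choice follows the common
FilterSeq-quality semantics of UMI amplicon pipelines.

Clones are inferred per stratum by three criteria: identical junction length,
identical V and J gene (alleles stripped), and single-linkage clustering of
the nucleotide junction at a length-normalized Hamming threshold of 0.1.
Single linkage at a fixed cut equals connected components of the thresholded
distance graph, which is how it is implemented (scipy sparse connected
components); the dendrogram above the cut is never needed. Clone labels are
deterministic: clusters are ranked by size, ties broken by the smallest
member sequence id.

Two clustering strata exist. Within-sample metrics cluster per (subject,
timepoint, subset). Longitudinal overlap requires clone identity to be
comparable across timepoints, so overlap analyses cluster the pooled BL+FUP6
sequences per (subject, subset); pooling is the construction under which
"shared clone" is well defined, and the package always records which mode
produced a clone id.

### Diversity and overlap

Hill numbers are computed from clone-abundance proportions; q = 0 is clone
richness and q = 1 the exponential of Shannon entropy. Because samples differ
in depth, all diversity and overlap estimates use a fixed-depth bootstrap:
n = 126 unique sequences drawn *with replacement*, 200 repetitions, and an
admission floor of 100 unique sequences per sample. With replacement is
forced: admissible samples may hold only 100–125 unique sequences, fewer than
the draw depth. Overlap per repetition is |clones in both draws| over the
union of clones seen (Jaccard); "bl" (baseline-referenced) and "mean"
(mean of the two directional overlaps) denominators are selectable and the
choice is recorded in a `definition_tag` column, since "proportion of shared
clones" admits all three readings.

The closed form E[distinct] = n·(1 − (1 − 1/n)^n) for a bootstrap of n
singletons (n = 126 gives ≈ 79.7) calibrates the q = 0 estimator in the
tests.

### SHM and annotation

V/J assignment maximizes ungapped identity of the germline V prefix (through
its conserved Cys codon) and J suffix (from its conserved Trp/Phe codon) over
all offsets, with deterministic tie-breaks (identity, then name). The aligner
assumes substitution-only divergence — the regime the simulator produces —
and an assignment is rejected below 60 % V identity. Real data contain
indels; for real inputs the annotation stage is designed to be bypassed by
ingesting an externally annotated AIRR table. SHM frequency is the mismatch
fraction over the aligned V region 5′ of the junction; the junction is
excluded because it has no unique germline. The junction is delimited by one
conserved anchor residue per side (the IMGT junction convention); the
alternative reading of "two flanking amino acids" as two residues per side
was considered and not adopted.

### Proteome matching

The patient database is built from translated productive VH sequences of both
timepoints combined, deduplicated at the protein level with provenance kept.
Tryptic digestion cleaves after K/R except before P (cleavage sites via
pyteomics), zero missed cleavages and a 6–40 AA length filter by default.
Observed peptides pass a mode-specific FDR filter (DDA q ≤ 0.1, DIA
q ≤ 0.01) and are exact-substring matched. The "≥ 30 % identity to the
somatically mutated CDR3" rule is operationalized as ≥ 30 % positional
coverage of the CDR3 AA span (junction minus anchors) by uniquely mapping
peptides: peptides are matched exactly against the subject's own proteins, so
identity within a mapped peptide is always 100 % and coverage is the only
free quantity. Peptide uniqueness is judged at the CDR3-group level (entries
with identical CDR3 strings pool into one group) because clonally related
entries share frameworks and sequence-level uniqueness would void nearly
every peptide. I/L are distinguished by default; an `equate_il` flag folds
them for mass-spectrometry-faithful matching.

### Statistics

Longitudinal comparisons use the Wilcoxon signed-rank test (the paired
reading of the ambiguous phrase "rank-sum paired test"), exact for ≤ 25
tie-free pairs and tie-corrected normal approximation beyond; Mann–Whitney U
is exact up to a pooled n of 12 without ties. Dunn's post hoc z-tests use the
tie-corrected pooled rank variance with Bonferroni multiplication by the
number of comparisons. Benjamini–Hochberg is the statsmodels step-up
implementation. The plan runner reports the figure-style significance tiers
(# p<0.1, * p<0.05, ** p<0.01, *** p<0.001) and can apply a global BH across
a plan item's cells, defaulting to per-test behavior.

## The synthetic repertoire generator

The generator produces what the analysis assumes and nothing more:

- **V(D)J recombination** on a packaged toy germline set — 10 V segments
  (two per family IGHV1–IGHV5, 291 nt, conserved Cys anchor) and 4 J segments
  (conserved Trp, one Phe, 48 nt from the anchor), random stop-free codons
  frozen into FASTA. Junctions are built in frame: V anchor codon + random
  insert (length uniform on multiples of 3, default 0–30 nt) + J anchor
  codon; stop-containing inserts are resampled. No exonuclease chew-back, no
  D segment, no indels.
- **Clone structure**: per subset, `n_clones` founders with member counts
  from a truncated zeta (power) law, producing both singletons and > 50-member
  clones. Members are independent SHM draws from the founder — single linkage
  at 0.1 tolerates the star topology; explicit lineage trees are not modelled.
  Draws are kept sequence-distinct where the rate allows, draws gaining a stop
  codon are resampled (the analysis operates on the productive repertoire),
  and distinct founders always receive distinct (V, J, junction) triples so
  the true partition is recoverable in principle.
- **SHM** mutates each non-junction site independently at the subset's rate;
  the junction is spared by default so that true lineages always satisfy the
  clustering threshold and recovery tests stay interpretable. Real SHM does
  hit CDR3; a `mutate_junction` flag enables that for stress tests. No
  hotspot motifs.
- **Subset phenotypes** (defaults): naive — 300 clones, near-singleton sizes,
  SHM 0, IgD/IgM; double-negative — 150 clones, heavy-tailed sizes
  (zeta a = 1.8, max 200), SHM 0.04, class-switched; memory — 200 clones,
  a = 2.2, SHM 0.06, switched; plasmablasts — 80 clones, a = 1.6 (most
  expanded), SHM 0.07, IgG/IgA. These realize the qualitative contrasts the
  analysis must resolve (diverse-unmutated vs. expanded-mutated).
- **Longitudinal design**: each BL clone lineage re-seeds FUP6 independently
  with probability `retention_fraction` (default 0.02, the low-overlap
  regime), with fresh size and SHM draws, topped up with new clones to
  `fup6_diversity_scale` × n_clones.
- **Reads**: one unique UMI per molecule (8 or 12 nt), reads per molecule
  Poisson (mean 12) by default, i.i.d. per-base substitution errors (default
  10⁻³), constant Q30 qualities with a configurable fraction of flat-Q15
  reads so the Q20 filter is exercisable.
- **Peptides**: translated molecules are tryptically digested; a configurable
  fraction of peptides is emitted with q-values below the mode's FDR cutoff,
  plus shuffled decoys with q-values spanning [0, 1].

All randomness flows from the single config seed through one generator
stream; identical configs give byte-identical outputs.

**What passing tests show — and don't.** Exact recovery on error-free,
junction-sparing, indel-free simulations validates the pipeline's logic and
bookkeeping, not its robustness to indels, junction mutation, UMI collisions
or chimeras, none of which the generator produces. Calibration results
(bootstrap means, overlap monotonicity, test sizes) hold under the
generator's independence assumptions; real repertoires violate several
(lineage structure within clones, non-uniform sequencing error).

## Problem sizes

The default simulated subject carries ~730 clones per timepoint across four
subsets (a few thousand molecules); tests use reduced two-subset
configurations (40–60 clones per subset) chosen so the full suite and the
acceptance script each finish in well under a minute of compute per stage
while keeping every admission floor (n ≥ 100 unique sequences) reachable.

## Known limitations

- The aligner is ungapped and single-frame; real IgBLAST/IMGT annotation is
  out of scope and externally annotated tables are the intended real-data
  entry point.
- Isotype is metadata (the wet protocol derives it from isotype-specific
  primers), not inferred from sequence; the simulated pipeline carries it as
  a sequence→isotype map.
- Paired-end assembly, UMI error-correction networks, chimera detection,
  light chains, lineage trees, Chao-type extrapolation and spectrum-level
  proteomics are deliberately not modelled.
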