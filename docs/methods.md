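# Methods

This note documents the models, parameter defaults and design choices behind
`nifbkit`, and what the synthetic ground truth does and does not establish
about real data.

## Fingerprint model

A motif pattern is an ordered list of literal residues and fixed-width
wildcards (`Cx3Cx2C` spans eight residues). The default fingerprint is the
six SAM-radical motifs `HPC`, `Cx3Cx2C`, `ExRP`, `AGPG`, `TxTxN`,
`Cx2CRxDAxG`, required in N-to-C order. Scanning is exhaustive: every
offset is tested and overlapping occurrences are all reported. A literal
never matches the unknown residue `X` — an unknown residue cannot confirm a
strictly conserved position — while wildcards match anything.

**Ordered matching.** Each motif must start strictly after the end of the
previous motif's chosen hit. Placement is greedy leftmost. Because every
occurrence of a given pattern has the same span, the leftmost feasible hit
also ends earliest, and an exchange argument shows greedy leftmost succeeds
whenever any ordered placement exists; the backtracking fallback is retained
as a safety net but provably never changes the verdict (a property the test
suite asserts). Order enforcement can be relaxed to simple presence
(`ordered=False`, CLI `--unordered`) since conservation of motif order,
while visually evident in known NifB proteins, is an assumption.

**Span localization.** For domain annotation the passing placement is
re-packed rightward (`compact=True`): the last hit keeps its earliest
position and every earlier hit moves to its rightmost feasible occurrence.
This matters because an N-terminal homology segment occasionally contains a
spurious copy of a short motif (an accidental `HPC` arises roughly once per
~8,000 random residues); under plain leftmost placement such a hit inflates
the inferred SAM-radical span and can swallow the flanking domain. The
filter verdict is computed before compaction and is unaffected.

**Discovery.** Given an alignment of trusted proteins, a column is
conserved when it is gap-free and one residue reaches `min_conservation`
(default 1.0). Maximal runs of conserved columns, allowing at most
`max_wildcard_run` consecutive non-conserved gap-free columns as wildcards,
are emitted as patterns that must start and end on a literal and contain at
least `min_motif_len` literals. The wildcard-run cap defaults to 3 — the
smallest value able to represent the AdoMet triad `Cx3Cx2C`, whose three
consecutive arbitrary positions are the longest wildcard stretch in the
fingerprint. On noise-free generator output with fixed spacer lengths the
procedure recovers the six default motifs exactly.

## Homology domains and architecture

NifX-like and NifN-like domains are located by Smith-Waterman local
alignment (BLOSUM62, gap open 11, extend 1 — conventional protein defaults)
of the search region against each reference in a panel. A domain is called
when the best alignment covers at least `min_aligned_length = 50`
residue pairs at identity ≥ `identity_threshold = 0.45`, identity being
counted over residue-paired columns only.

The identity default was calibrated against an explicit null: the best
local alignment of a random 150-mer against the shipped panel reaches
≥ 50 residue pairs at up to ~0.42 identity (measured over several seeds of
1,000 trials), which is the familiar twilight-zone behaviour of short
pairwise alignments; planted template copies at 50% identity or better
always score ≥ 0.50. The 0.45 default sits between the two with margin on
both sides, giving an empirically clean null at the cost of missing true
homologs in the 35–45% band — a regime where profile methods, not pairwise
alignment, are the right tool. Both thresholds are parameters of the
reference panel.

Classification order mirrors curation: the fingerprint decides NifB-ness
first (`NOT_NIFB` if it fails, regardless of homology domains); the
NifX-like domain is then searched C-terminal to the SAM span and the
NifN-like domain in both flanks (its position is recorded, not enforced).
A SAM + NifN call without NifX matches no described architecture; the label
falls back to `SINGLE` with the NifN annotation retained in the domain list.
The reference panel shipped in `data/` consists of synthetic templates
(used by the generator and tests, with no biological claim); real analyses
should supply curated NifX/NifN FASTA panels.

## Curation report and frequencies

The curation report records input/retained/removed counts and the reduction
fraction to three decimals, always as computed from the data. Removed
records are re-scanned full-length for a NifX-like domain
(`reclassify_rejected`), quantifying how many rejections are explained by
NifX mis-annotation. Frequency tables count non-`NOT_NIFB` calls per
(superkingdom, group); records without a taxonomy row fall into an
`unassigned` row rather than being dropped. Percentages are within-row and
rounded half-up to integers, matching how such tables are conventionally
displayed.

## Alignment, blocks, distances, trees

**Progressive aligner.** Pairwise global-alignment identities (BLOSUM62,
11/1) define guide distances; average-linkage clustering fixes a
deterministic merge order; profiles are merged by Needleman-Wunsch with
average-of-pairs column scores, a linear per-column gap cost of −4, and a
fixed diagonal-up-left tie-break. It is a minimal, reproducible aligner for
desk-scale sets — externally computed MSAs can be supplied instead and are
the better choice for publication-grade trees.

**Block selection.** Columns are classified by modal-residue frequency:
conserved at ≥ 0.5, highly conserved at ≥ 0.85; gap-containing columns are
excluded outright (`allow_gaps=False`). Candidate blocks are maximal runs
split wherever ≥ 8 consecutive non-conserved columns occur, trimmed so both
flanks are highly conserved, and discarded below 10 columns. These are the
canonical defaults of conserved-block trimming; published block lengths from
other alignments are aligner- and version-dependent, so the package logs its
own block lengths rather than targeting any particular figure.

**Distances.** p-distances use pairwise deletion (gap-free shared columns
only); the Poisson correction d = −ln(1−p) is the default. A pair with no
comparable columns, or p = 1 under the correction, is an error naming the
offending sequences.

**Neighbor joining.** Standard agglomerative NJ with the rate-corrected
criterion. Determinism: ties in Q are broken toward the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest leaf
label, tie tolerance 1e-12), and negative branch-length estimates are
clamped to zero. The 3-taxon closed form v_a = (d_ab + d_ac − d_bc)/2 ends
the agglomeration; a 2-taxon input becomes a single edge split evenly across
the degenerate root. Correctness is established by the additive-recovery
property (100 random trees of 4–10 leaves, RF = 0) and by cross-checking
topologies against an independent NJ implementation.

**Rooting and comparison.** Outgroup rooting places the root at the
midpoint of the outgroup leaf's branch; a rooted input is unrooted first, so
re-rooting on the same leaf is idempotent. Robinson-Foulds distances count
non-trivial unrooted bipartitions present in exactly one tree. Newick is
the exchange format; round-trips preserve topology and branch lengths to
1e-9.

## In-silico computations

Masses are average (not monoisotopic) residue masses plus one water,
matching the convention used when comparing with size-exclusion estimates.
In-silico PCR requires the 3'-terminal `anneal_len` (default 15) bases of
each primer to occur exactly once on the template; annealing then extends as
far as the primer continues to match, and the remaining 5' extension is a
tail. The amplicon's `sequence`/`start`/`end` are template-anchored (so
length = end − start + 1), while `full_product` additionally carries the
tails, as a real PCR product would.

`truncation_surrogate` builds a synthetic stand-in for a C-terminal
truncation construct: a 1404-nt CDS (468 codons) whose ends are dictated by
a published primer pair — the forward primer's annealing region opens the
CDS, the reverse primer anneals up to codon 327 and appends nine histidine
codons plus a stop — with seeded random non-stop codons between. Amplifying
it reproduces the construct arithmetic from first principles: a 981-nt
native span completed by the primer-encoded His9 tract into a 1008-nt coding
region, i.e. 336 residues, against 468 for the full-length protein. The
surrogate is synthetic; users with the real coding sequence obtain the same
numbers by supplying it as the template.

The growth-rate constant is ln 2 / t_d (per hour for t_d in hours).

## Synthetic data

Each NifB-class record is: optional NifN-like segment, a leading spacer, the
six motif instances separated by uniform random spacers (default 8–16
residues, wildcards filled uniformly over the 20 canonical residues), a
trailing spacer, and an optional NifX-like segment. Homology segments are
template copies substituted down to `domain_identity` (default 0.7).
Contaminants are NifX-template copies with flanking spacers, rejection-
sampled to fail the fingerprint (they essentially always do). Optional
global substitution noise (default 0) never hits motif literal positions,
keeping truth labels exact; a motif-ablation option builds NifB-like decoys
that fail the filter.

Group proportions are converted to integer counts by largest-remainder
rounding. The default four-group mix (50 records each, 20% contaminants)
emulates the observed architecture distribution across diazotroph lineages:
Euryarchaeota 100% single-domain; two bacterial groups dominated by the
two-domain fusion (70–80%); and a Firmicutes-like group carrying all three
forms at 55/32.5/12.5% — values chosen to be exactly representable at the
default group size so noise-free closure can be asserted as equality.

What passing tests show: the pipeline's stages are internally consistent
and recover planted structure perfectly in the noise-free regime, and
detection degrades monotonically with substitution noise. What they do not
show: performance on real sequences, where domains diverge by indels and
deep homology rather than point substitution, motif spacing varies more
widely, and taxonomy is messier; the generator makes no attempt to simulate
evolution along a tree.

## Known limitations

- Pairwise alignment against a small panel is a deliberate simplification
  of profile-based domain assignment; it cannot reach twilight-zone
  homologs.
- The NJ path is the implemented estimator; maximum-likelihood tree search
  is out of scope.
- The progressive aligner is for self-contained testing and small sets; its
  guide tree and gap model are minimal.
- Headline counts from any particular curated database can only be
  reproduced with that database; the acceptance machinery therefore
  measures property-level correctness on generated data with known truth.
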