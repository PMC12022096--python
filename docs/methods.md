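# Methods

## Guide placement and residue assignment

A protospacer is placed by exact search on the spliced CDS: a match of the
20-mer itself is a '+'-strand guide, a match of its reverse complement a
'−'-strand guide.  The blunt SpCas9 cut is placed between protospacer
positions 17 and 18 (3 bp 5′ of the NGG PAM) — the canonical SpCas9
geometry; in coding-strand coordinates the cut position is
`match_start + 17` ('+') or `match_start + 3` ('−').  The guide's target
residues are the codons of the two nucleotides flanking the cut,
`{⌊(cut−1)/3⌋+1, ⌊cut/3⌋+1}` clipped to the protein: two consecutive
residues when the cut sits at or near a codon boundary, one residue when
both flanking bases share a codon.  This two-codon rule (rather than a ±k
window) matches the field's guide naming convention, in which a guide is
labelled by the one or two residues at its cut (e.g. `sgQ58/K59`).
Protospacers matching the CDS at more than one site — including the
degenerate palindromic case, where strand and hence cut position are
undefined — are rejected rather than placed arbitrarily.

CDS coordinates are 0-based half-open internally; every user-facing
residue position is 1-based.  Multi-exon genes are out of scope: callers
supply the spliced CDS.

## Counting

A read increments exactly one guide when exactly one library protospacer
(in either orientation) occurs as an exact substring; reads matching zero
or several distinct guides are tallied per-sample as unassigned, and a
read matching one guide several times counts once.  Exact matching keeps
the behaviour assertable against a brute-force scan oracle and is the
package's reference behaviour; there is deliberately no mismatch
tolerance.  Counting is invariant to read order and quality strings.

## Normalization and contrasts

RPM = counts / column total × 1e6, so every sample column sums to 1e6.
Per replicate pair r, `lfc_r = log2(rpm_num,r + 1) − log2(rpm_den,r + 1)`;
the pseudocount is applied to RPM, not to raw counts.  Replicates are
paired by replicate index and the per-replicate LFCs averaged.  The
paired drop-out contrast (Cas9⁺ day 14 over Cas9⁻ parental day 0) retains
the full depletion signal while cancelling library-composition features
shared by both arms at infection.

Low-count filtering flags guides with fewer than 300 reads in a chosen
reference sample (the parental day-0 sample in the drop-out design);
flagged guides stay in the table but are excluded from binning and
residue mapping, since a handful of reads cannot support a stable LFC.

### Activity correction

Guides differ in on-target editing efficiency, which biases region
calling: a functionally critical window tiled only by weak guides looks
mild.  Given per-guide activity scores in (0, 1] (scores on (0, 100] are
rescaled), the corrected value is `lfc_mean / max(activity, 0.2)`.
Division is the minimal monotone correction that rescales a depletion
produced by a partially active guide up to its full-activity equivalent;
the 0.2 floor prevents blow-up for near-dead guides.  The correction
never flips sign.  One caveat is intrinsic to the form: any additive
composition offset in the LFC is divided too, so corrected values of
weak guides inherit an amplified offset — region gates should therefore
be set on the corrected scale.  The exact functional form used by
published pipelines is not standardized; this one is documented here as
the package's interpretation, and a second optional divisor (e.g. a
frameshift-rate column) can be applied through the same function.

## Control calibration and QC

The depletion threshold is the 5th percentile (linear interpolation) of
the negative-control mean LFCs; a guide counts as depleted when strictly
below it.  Calibrating on negative controls rather than on zero matters:
under total-count normalization, a broadly essential target shifts every
neutral guide upward (survivors gain share as the depleted mass leaves
the pool), so the neutral reference point is empirical, not 0.  Screen
performance is the ROC AUC separating positive from negative controls,
computed as the Mann–Whitney U statistic of depletion scores normalized
by |POS|·|NEG| with ties counted ½ — identical to the trapezoid integral
of the empirical ROC but simpler to verify against an exhaustive
pairwise oracle.  Group comparisons use the unpaired two-tailed Wilcoxon
rank-sum test, exact for small tie-free samples and tie-corrected normal
otherwise.

## Binning and region calling

Scored (unfiltered, CDS-targeting by default) guides are sorted by mean
LFC descending, ties broken by guide id for determinism, and split into
17 contiguous rank groups as equal as possible (the first N mod 17 bins
take one extra guide): bin 1 holds the most enriched guides, bin 17 the
most depleted.  Rank bins always contain ~N/17 guides whether or not
anything is truly depleted, so region calls accept an optional absolute
LFC gate alongside the bin criterion.

Each residue's track value is the mean of its assigned guides' (raw or
corrected) LFCs; its bin is the extreme bin among them (max for
depletion tracks, min for enrichment), because a residue hit by one
extreme guide and one weak guide is still evidence of function.
Residues whose bin qualifies (and which pass the gate) seed regions;
seeds separated by at most `max_gap` (default 1) non-qualifying residues
merge.  No long-range smoothing is applied — named functional regions in
this kind of screen span only a few residues, so a LOESS-style smoother
would only blur them.  Labels follow the field's convention: a
two-residue region as `F223/V224`, a longer span as `R234_G237`.

Structure export writes a chosen track field into the B-factor column
(text columns 61–66) of ATOM/HETATM records of the selected chain,
preserving every other byte of the file; residues without a value get
B = 0.00.  Any structure viewer's B-factor coloring then renders the
screen as a heat map.

## Single-locus allele analysis

Reads are globally aligned to the amplicon with match +2, mismatch −4,
gap open −12, gap extend −1; alignments scoring below 0.4 × 2 × read
length are discarded as unalignable.  Published amplicon tools do not
state their tie-breaking; this package defines its own reference
behaviour by left-normalizing every indel (shifting each gap to its
leftmost equivalent placement), which makes descriptors canonical
regardless of the aligner's internal tie-breaks.  Edit events are only
trusted within ±20 nt of the cut — Cas9 repair outcomes concentrate at
the cut, so isolated distant mismatches are treated as sequencing noise.
Events inside the window merge into one replacement descriptor
(multiple disjoint events are flagged compound).

Protein consequences are obtained by re-translating the edited CDS and
trimming the longest common prefix then suffix against the reference
protein; trimming the prefix first pushes ambiguous deletions in repeat
runs to their 3′-most protein position, as HGVS prescribes.  Frame class
follows net indel length mod 3.  Alleles are keyed by consequence string
(not nucleotide sequence), per-timepoint abundance is RPM over aligned
reads, and per-allele LFC is computed against the reference (day 1)
timepoint with the same RPM + 1 pseudocount as the screen.  The
frameshift-versus-in-frame comparison applies the rank-sum test to
per-allele LFCs at a chosen day; at a locus whose in-frame disruptions
destroy function, the two classes deplete alike and the test should not
reject.

## Synthetic screens

The generator emulates the statistical structure of the screens, not
their biochemistry.  Genes are random codon sequences (ATG start, single
terminal stop) with codon usage weighted 1.8-fold per G/C — human coding
sequence is GC3-rich, and without this bias a random CDS lacks the NGG
density needed to reach the ~47.5 % residue coverage an NGG-restricted
tiling design attains on a real kinase CDS.  Libraries take every
NGG-adjacent 20-mer on either strand, drop duplicates and multi-mappers,
and by default subsample to 47.5 % coverage; controls (24 negative, 18
positive, 10 non-targeting — six guides for each of four non-essential
and three essential control genes, rounding the library to roughly 300)
are random 20-mers absent from the CDS.

Guide abundances start lognormal (σ = 0.5) from one pool shared by all
arms and replicates.  Depletion is exponential in population doublings
(the screens run ~14 doublings at about one per day): after D doublings
a Cas9-arm guide's expected abundance is multiplied by
2^(−D·activity·effect), with per-guide activity ~ Beta(5, 2) (mean 0.71,
the right shape for a designed library's predicted efficiencies) and
`effect` the per-doubling log2 cost of the targeted residues.  Drug arms
multiply resistance-region guides by 2^(+D·enrich·in_frame_prob·activity),
modelling at guide level that only the in-frame fraction of edits yields
a functional resistant protein.  Parental (Cas9⁻) arms are untouched.
Counts are negative binomial (gamma–Poisson) around depth × relative
abundance at 1e6 reads per sample.  The dispersion default of 0.008 was
set so that the negative-control LFC spread matches the control
calibration regime these screens report (5th percentile near −0.3 at
this depth); it is the one noise parameter downstream tolerances are
sensitive to.  Truth tables carry every expected RPM so planted expected
LFCs are available in closed form.

The amplicon generator evolves a stated allele mixture (day-1 fractions
× per-day multipliers, renormalized), emits reads with optional uniform
base error, and records left-normalized descriptors, consequences and
expected fractions.

### What the simulations do and do not show

Passing tests on these simulations demonstrate that the pipeline's
arithmetic, calling rules and statistics recover planted truth under
realistic count noise.  They do not capture guide-sequence-dependent
repair-outcome spectra, off-target cutting, double-strand-break toxicity
of control guides, cell-cycle or fitness interactions, or PCR/sequencing
artefacts beyond uniform base error — so real-data performance,
especially of region boundaries, should be judged with those limitations
in mind.  Coverage is itself a sensitivity limit: at 47.5 % coverage a
several-residue window is occasionally untiled and cannot be recovered
by any method.

## Problem sizes

Default test and acceptance runs use a 393-residue gene, ~200–230 CDS
guides plus 52 controls, two replicates at 1e6 reads per sample, 10–20
simulated screens for recovery statistics, and a few hundred amplicon
reads per timepoint — sizes at which every stage, including the
alignment-based allele stage, completes in seconds while keeping
recovery statistics well away from their tolerance edges.
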