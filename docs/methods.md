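# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each stage of the pipeline.

## Homology scan and numt assembly

The discovery scan is a classical seed-and-extend local search. Exact
`word_size = 20` seeds from the mitochondrial query are indexed and located on
both strands of every nuclear scaffold; seed matches sharing a diagonal are
extended without gaps under blastn-like scores (match +2, mismatch −3) with an
X-dropoff of 100 raw score units, and each hit is trimmed to its maximal-score
extent. Significance uses the Karlin–Altschul formula E = m·n·2^(−bit) with
λ solved from (1/4)e^(2λ) + (3/4)e^(−3λ) = 1 (uniform base composition) and
K = 0.3; the default e-value cutoff is 0.01 for both the discovery scan and
cross-genome conservation profiling. The circular mitogenome is handled by
appending its first word_size − 1 bases to the query; hits running across the
origin are split at position 1 and reported as two mitochondrial intervals.

Ungapped extension is exact when post-insertion divergence is
substitution-only. Copies that also carry indels surface as several collinear
fragments, which the downstream 10 kb clustering reunites into one numt —
fragment counts then reflect alignment breaks, not insertion events. Hit
boundaries are maximal-scoring positions, so a hit can legitimately extend a
few bases into flanking sequence when the flank happens to match
(P(> 5 bp overshoot) ≈ 1% per end); any local aligner behaves this way.

Filtering keeps hits strictly longer than 200 bp. Clustering is
single-linkage per scaffold on the gap between nearest fragment ends
(merge iff gap ≤ 10,000 bp), blind to strand and mitochondrial origin; numts
are numbered in genome order and the result is invariant to input order.

## Genetic codes and reading-frame intactness

Code tables come from the NCBI translation tables (1: standard; 2: vertebrate
mitochondrial). A fragment is tested against a gene by local alignment
(match +1, mismatch −1, gap open −5, gap extend −2 — Biopython's C aligner),
which makes the classification invariant to flanking non-homologous sequence.
The aligned block is read in the gene's codon frame; internal stop codons are
counted under both codes, excluding the gene's own terminal stop ("premature"
excludes the natural stop). `intact_mito_frame` requires a gap-free block
with zero internal mitochondrial stops. By default only the overlapping
segment is assessed (`require_full_gene` switches to whole-gene mode).
Incomplete stop codons completed by polyadenylation (T/TA) are *not* treated
as stops; only the 3-nt stop sets count. The pipeline applies stricter
homology gates than the unit-level classifier (identity ≥ 0.8 over ≥ 150
aligned columns) because chance local alignments between a fragment and an
unrelated gene rarely exceed a few dozen columns, while genuine numt gene
copies align over hundreds.

## Pairwise dN/dS (NG86)

Site counts are fractional per codon position: each position contributes one
site split by the fraction of its non-stop single-nucleotide mutants that are
synonymous; mutants that would create a stop are excluded from the
denominator. Sites are averaged over the two sequences. Codon pairs differing
at 2–3 positions are resolved by averaging over all orderings of single steps
whose intermediates are sense codons; pairs whose every pathway crosses a
stop are excluded and logged. Alongside the fractional counts, integer
"minimal-path" counts are reported (ties broken by maximising synonymous
steps) because survey tables conventionally print integers. Proportions are
corrected with Jukes–Cantor; p ≥ 3/4 is reported as a `saturated` flag, never
a silent NaN. ω is defined only when dS > 0; gene copies with zero observed
substitutions produce an empty row rather than 0/0. Significance is a
two-sided Fisher exact test on [[Sd, S−Sd], [Nd, N−Nd]] (counts rounded to
integers). The counting method is a pluggable strategy; NG86 is the default
because it is exactly checkable against exhaustive enumeration.

## Distances and trees

The Tajima–Nei (1984) distance d = −b·ln(1 − p/b) uses
b = (1 − Σg_i² + p²/h)/2 and h = Σ_{i<j} x_ij²/(2 g_i g_j), with base
frequencies pooled over both sequences; it reduces to Jukes–Cantor under
equal frequencies and uniform mismatch classes. Columns containing gaps or N
are skipped pairwise (pairwise deletion). Saturation (p ≥ b) raises an error
naming the pair rather than returning infinity.

Neighbour joining follows Saitou–Nei with deterministic tie-breaking (lowest
index pair) and a fixed negative-branch policy: negative estimates are
clamped to zero with the deficit moved to the sister branch, preserving path
lengths. NJ recovers any additive matrix exactly (property-tested against
random trees). The numt/background branch partition requires the numt taxa
to be monophyletic in the unrooted sense: the clade's internal branches plus
its stem are labelled `numt` (encoded in Newick as a `#numt` label suffix);
in the rooting where the clade wraps around the root, the background
subtree's branch — the background side of the separating edge — stays
background, matching the convention that a cherry {a,b} on ((a,b),(c,d))
yields exactly three numt branches.

Homologous gene copies entering the tree stage are projected onto shared
gene coordinates (positions outside a copy's aligned block become N, i.e.
missing data); an external multiple aligner is unnecessary for these
near-identical, gap-free projections.

## Codon selection models

The engine is the GY94 reversible Markov chain over the sense codons of the
chosen code (60 for vertebrate-mito). For single-nucleotide changes,
q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous]; multi-nucleotide changes are
forbidden. Codon frequencies are empirical functions of the alignment
(`equal`, `F1x4`, or the default `F3x4`), never optimised. **Scaling
convention:** every site-class generator is normalised to one expected
substitution per codon per unit branch length under its own stationary
distribution, so branch lengths read identically in every class. (codeml
instead shares a single scale across classes, so absolute log-likelihoods
are not comparable between the two programs; likelihood *differences* of
nested fits, which are all the pipeline interprets, are.) Mitochondrial and
nuclear rate differences are absorbed by free per-branch lengths; no clock
is imposed.

Likelihoods use Felsenstein pruning over site patterns with per-node
rescaling; transition matrices come from the eigendecomposition of the
symmetrised generator (Π^{1/2} Q Π^{−1/2}), giving exp(Qt) for all branches
from one decomposition per (κ, ω). Untranslatable codons (N, stops in the
data) are missing data (all-ones partials), logged. Two- and three-leaf
likelihoods are verified against matrix-exponential closed forms and full
brute-force state summation.

The suite: one_ratio (1 free ω), two_ratio (ω_background, ω_numt),
two_ratio_fixed (ω_numt ≡ 1), M1a (p₀ with 0 < ω₀ < 1, rest neutral), M2a
(M1a + a class with ω₂ ≥ 1), cladeC (three classes: shared purifying ω₀,
neutral, and a divergent class with independent ω per branch partition), and
cladeC_fixed (divergent class's numt ω ≡ 1). The purifying class's ω₀ is
estimated freely (bounded below 1) rather than fixed at 0 even when reported
estimates sit at that boundary. Free-parameter counts beyond κ and branch
lengths are 1, 2, 1, 2, 4, 5, 4 respectively, which yields the default LRT
degrees of freedom (e.g. cladeC vs two_ratio: 3; cladeC vs cladeC_fixed: 1);
df is overridable. ω fixed at 1 is an interior point, so the standard
chi-square applies; proportions hitting 0 are logged as boundary warnings.

Fitting is bounded L-BFGS-B on transformed parameters (log for κ ∈ [0.05,
100], ω ∈ [10⁻⁶, 50] and branch lengths ∈ [10⁻⁸, 20]; softmax logits for
class proportions), with 3 seeded starts by default (deterministic given the
seed) and optional extra starts; feeding a nested null's solution as a start
for the alternative guarantees the nesting inequality up to optimizer
tolerance, and `lrt` raises if it is violated beyond 0.05 log units.
Convergence tolerance is 1e-10 on the objective.

## Synthetic data

`simulate_mitogenome` lays out 13 protein-coding genes with realistic
vertebrate lengths (ND1…CYTB, 11.4 kb total) between a leading 1.6 kb
rRNA-like block, 70 bp tRNA-sized spacers and a trailing D-loop pad to
16.5 kb; every gene is constructively stop-free under the mitochondrial code.
All genes are simulated on the forward strand (real ND6 is not — irrelevant
to the analyses exercised here).

`simulate_numt_landscape` plants insertion events with full ground truth.
Donor lineages: *canonical* (the reference itself), or *heteroplasmic*/
*hybrid* donors first evolved to a target divergence under purifying-selection
emulation — substitutions creating in-frame stops are rejected and other
nonsynonymous changes accepted with probability 0.15 — because the donor
molecule was a functioning mitochondrial genome until insertion.
Post-insertion decay is neutral and uniform (per-site substitution
probability = `age`), with optional indels (rate 5% of substitutions,
geometric mean length 2, off by default so frame analyses stay exact). The
nuclear:mitochondrial rate asymmetry of real genomes appears here only as the
freedom to give donors high divergence while keeping post-insertion age low;
an explicit 1:10 default rate ratio applies when both are derived from a
common time scale. Backgrounds are uniform random DNA: no repeats,
retrotransposons, GC structure or pre-existing old numts, so a perfect
discovery round-trip on synthetic data bounds algorithmic correctness, not
performance on real genomes. Every generator is a pure function of
(config, seed); the mitogenome and landscape draw from decorrelated streams.

The default landscape plants 12 events spanning lengths 250–14,000 bp,
post-insertion divergences 0–0.12, one to four fragments (spacers 400–9,900
bp), both strands and all three donor types, on three 200 kb scaffolds with
≥ 25 kb separation between events.

`simulate_codon_alignment` draws site classes from the model's proportions
and evolves each site along the tree using the same generators the fitter
uses (validated against the transition matrices on large samples).

## Study conditions used by tests and the acceptance script

Codon-model calibration and recovery run on an 8-taxon tree — a clade of
five numt copies (one per lineage carrying an old insertion) against three
mitochondrial references — with a numt-clade length of ≈ 0.9
substitutions/codon, the scale of an insertion tens of Myr old; a shallower
clade leaves ω_numt underdetermined at 500 codons. Alignments are 500 codons
under the vertebrate-mito code with equal codon frequencies and κ = 2; the
near-neutral regime (ω_background, ω_numt) = (0.011, 0.994) matches a
strongly purifying mitochondrial background against an effectively neutral
numt clade. Recovery is assessed over 20 replicates; LRT calibration over a
40-replicate Monte-Carlo sample in the test suite (measured type-I rate
≈ 3–9% at nominal 5%) and 20 replicates in the acceptance script. Brute-force
likelihood oracles use ≤ 4 leaves and ≤ 25 codons; NJ recovery uses 50 random
trees of ≤ 8 taxa.

## Known limitations

* Ungapped-only extension; heavily indel-eroded copies fragment (recovered
  by clustering but with inflated fragment counts).
* K = 0.3 is a documented constant, not a computed Karlin–Altschul K; e-values
  are therefore approximate (they gate obvious noise, not borderline calls).
* NG86 only for pairwise dN/dS (by design; ML pairwise rates belong to the
  codon-model suite).
* No bootstrap supports, Bayes empirical Bayes site identification,
  branch-site model A, or gamma rate variation.
* The age classifier (recent / intermediate / ancient) is a transparent rule
  on dS thresholds (defaults 0.1 and 1.0) and cross-genome presence, with dS
  taking precedence; it codifies a qualitative argument, not a calibrated
  estimator.
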