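# Methods

## Problem setting

Given a collection of MS/MS spectra from one or more related organisms and
a (possibly small) table of seed peptide-spectrum matches, the package
finds pairs of spectra generated by *related* peptides — identical,
singly substituted, singly modified, or terminally truncated forms —
assembles the pairs into subnetworks that ideally each cover one peptide
family, and transfers peptide annotations from seeded to unseeded spectra
while tracking the accumulated error. No protein database is needed beyond
the seeds, which is what makes the approach applicable to organisms
without a sequenced genome.

## PRM transform

Alignment operates on prefix-residue-mass (PRM) spectra: each spectrum is
re-expressed as a list of candidate peptide-bond prefix masses with
positive scores. Candidates are the b- and y-type interpretations of every
observed peak (for a y-type peak at fragment mass f in a precursor of
neutral mass M, the implied prefix is M − f + proton). Each candidate is
scored over ten ion channels — b, y, their H₂O/NH₃ losses, doubly charged
forms, and +1 isotopes — where a channel supported by a peak of intensity
rank r among R peaks contributes

    weight · max(0, log(((R − r + 1)/R) / 0.05)),

and an unsupported primary channel (b or y) subtracts a miss penalty of
3.1 weighted score units. Candidates with non-positive totals are dropped
and the top 100 by score are kept.

Because a complete b/y ladder is symmetric under p ↔ M − p, every peak
also generates a "mirror" candidate. Mirrors are resolved by score
competition: the channel weights are asymmetric (y 1.2, b 0.8, reflecting
the y-ion dominance of tryptic CID spectra), so the true interpretation
outscores its mirror whenever y ions are more intense than b ions, and the
strictly weaker of each complementary pair is removed. Two *true* bonds
whose prefix masses sum to ≈ M produce coincident fragment peaks; such
candidates carry two peaks in each primary-channel window and are exempt
from the competition, so real bonds are never lost to it.

This scorer is deliberately transparent and untrained; it is a pluggable
interface, and the alignment statistics downstream require nothing of it
beyond positive peak scores. Trained fragmentation models would transfer
directly.

## One-offset alignment

Two PRM spectra with precursor difference Δ are aligned under a
single-breakpoint model: s1 peaks at prefix mass ≤ b match s2 peaks at the
same mass; peaks above b match after shifting by Δ. This is exactly the
fragment-space effect of one modification, one substitution, or one
terminal truncation. All breakpoints b ∈ {0} ∪ {prefix masses of s1} ∪
{M₁} are scanned; within a breakpoint, peak pairs within the fragment
tolerance (0.4 Da) are matched greedily one-to-one by smallest mass error
(ties to lower index), and the breakpoint maximizing T₁ + T₂ wins (ties to
the smallest breakpoint, for determinism). When |Δ| is inside the
precursor grouping window (0.1 Da) only the unshifted matching is used.
Pairs with more than one independent offset are out of scope by design;
multiply modified peptides are reached through chains of one-offset edges.

## Exact alignment significance

A "random alignment" against a spectrum S with N peaks is a subset of its
peaks, each included independently with probability θ. The score
distribution over all 2^N subsets is computed exactly by dynamic
programming on a discretized score grid (0.1 score units; peak scores
round to the nearest positive grid step):

    D[i, t] = θ·D[i−1, t − score(i)] + (1 − θ)·D[i−1, t],  D[0, 0] = 1.

The p-value of an observed matched total T is the tail Σ_{t≥T} D[N, t],
with T rounded *down* to its grid bin so discretization can only make the
p-value conservative. A pair is accepted when max(p₁, p₂) < 5·10⁻⁹ — both
spectra must be well explained. Histograms are memoized per spectrum, so
the all-vs-all pass costs one DP per spectrum, not per pair. θ defaults to
0.05 and can be re-estimated per dataset by matching random theoretical
peptide ladders against the observed PRM spectra (`estimate_theta`).

The all-vs-all pass is banded by the modification cap (±375 Da, enough for
deletion/extension of up to two Trp residues) and uses an exact rejection
shortcut: the matched total on either side can never exceed the summed
score of peaks that have *any* counterpart within tolerance (unshifted or
shifted), so a pair whose upper bound already misses the cutoff is
discarded without the breakpoint scan. This prunes the overwhelming
majority of cross-family pairs at a few searchsorted calls each.

A Gaussian approximation of the null (moment-matched normal) is included
only as the comparison baseline the exact method is tested against; it is
not a supported scoring path.

## Network assembly and splitting

Accepted pairs are inserted in order of increasing pair p-value into a
union-find structure that tracks, per component, the set of distinct
precursor-mass bins (bin width = the 0.1 Da precursor window). An edge
that would merge two components is skipped permanently if the merged
inventory would exceed 100 bins; edges internal to a component are always
kept, and each edge is considered exactly once. The rationale: merging two
large subnetworks should require highly significant evidence, and the
pairs that create mixed subnetworks — false matches and multiplexed
(co-fragmented) spectra — have comparatively weak p-values because part of
the multiplexed spectrum remains unexplained by either constituent
peptide. When seed annotations are available the package can also estimate
the edge FDR on seed-labeled edges and re-filter the network to a target
edge FDR by p cutoff.

## Propagation and localization

Seeds annotate their nodes at depth 0. The annotated set then grows one
node at a time, always crossing the lowest-p annotated→unannotated edge
(Prim-style). This ordering, rather than synchronous breadth-first waves,
is deliberate: it guarantees every node is reached through its best
available chain of evidence, so a doubly modified peptide is annotated via
its singly modified intermediate instead of through a single ambiguous
two-event jump from the seed.

When a node is annotated, the incoming edge's Δ is localized on the
propagated peptide. Every residue position is tried as the modification
site; negative Δ additionally generates truncation candidates wherever
−Δ matches a prefix or suffix mass (including variants where the retained
boundary residue sheds its own modification). Each candidate's theoretical
prefix ladder is scored against the receiving node's PRM spectrum — the
summed score of matched peaks minus 0.5 score units per unexplained ladder
mass, so a candidate whose ladder merely contains the true ladder cannot
tie with the truth — and the best-scoring candidate wins (truncations beat
equal-scoring modifications; remaining ties go to the N-terminal-most
site). Candidates that would drive a residue's mass non-positive are
rejected as chemically impossible. Because p-values of near-perfect edges
are nearly tied and cannot distinguish a one-event edge from a composite
substitution-plus-modification edge, the annotation for a node is taken
from whichever annotated neighbor's edge yields the best localization
score, with the p-value as tie-break; with no spectra supplied this
reduces exactly to the lowest-p rule.

An annotation propagated n steps from a seed is correct only if the seed
and all n edges are correct, giving FDR_n = 1 − (1−a)(1−r)ⁿ with a the
seed FDR (0.0003) and r the edge FDR (0.005, or estimated from
seed-labeled edges). The run-level aggregate is the ID_k-weighted mean of
FDR_k over propagation steps k ≥ 1, and propagation stops at the first
annotation that would push the aggregate over the 1% budget. Stopping is
conservative: a deep annotation encountered early ends the run even if
later shallow annotations would have lowered the mean again.

## Evaluation

Gold-standard pair labels follow a three-way rule: *true* if the two
peptides are identical, one is a prefix/suffix of the other, or one is a
singly modified or singly mutated (one substitution) form of the other;
*ambiguous* if they share ≥ 12 consecutive residues or their singly
charged b/y ion sets overlap by more than 60% of the smaller set;
*false* otherwise. Ambiguous pairs are excluded from every precision and
FDR denominator. The edge FDR estimate is #false/(#false+#true) over
labeled edges. Propagated annotations are compared with planted truth at
the fragment-mass level (equal precursor mass and matching prefix
ladders), so a substitution reported as a located mass offset at the
correct position counts as correct — the sequence-level interpretation of
an offset is downstream of this package.

## Synthetic data

The generator emulates a multi-species tryptic dataset: peptide families
of length 8–25 ending in K/R; per-species orthologs differing by one
substitution drawn (default rate 0.6) from the +14 Da residue-pair set
(Asp/Glu, Gly/Ala, Ser/Thr, Asn/Gln, Asn/Lys, Thr/Asp, Val/Leu, Val/Ile);
additional modified (rate 0.15, masses +15.995/+42.011/+79.966) and
truncated (rate 0.08, one or two terminal residues) variant spectra;
complete b/y ladders with y intensities strictly above b (exponential rank
decay within each series, 3% jitter); uniform noise peaks at half the
signal-peak count with intensities below the signal's 20th percentile; and
7% multiplexed spectra formed as the peak union of two co-eluting
precursors within a 3 Da isolation window. Charges are 2+ (70%) or 3+.
Everything is reproducible from a single integer seed, and `truth_labels`
emits seed tables at a configurable identified fraction per species (zero
for the genome-free scenario).

A second fixture, `generate_bridged_families`, builds the worst case for
network purity: two families of co-eluting *isobaric* peptides (sequence
anagrams) with disjoint modification sets, joined by multiplexed bridge
spectra — the scenario the precursor-mass constraint exists to break.

What the generator does not emulate: isotope envelopes, real
fragmentation-efficiency patterns (the b/y intensity separation is
idealized), retention time, charge-dependent fragmentation, and spectra
where one primary ion series is absent. Passing tests therefore
demonstrate the correctness of the algorithms and their statistics under a
clean fragmentation model, not instrument-level robustness; on real data
the PRM scorer is the component one would replace with a trained model.

## Problem sizes and tolerances

Unit and acceptance tests run on synthetic datasets of 3 species × 100
families (≈ 370 spectra), 100-spectrum histogram-oracle batches (N ≤ 15,
compared bin-by-bin at 10⁻¹²), 10⁵ null draws for calibration (checked
within 3 binomial standard errors at α = 10⁻², 10⁻³), 60 random + 25
planted alignment-oracle pairs (N ≤ 30, exact agreement), and 50 simulated
40-node networks for FDR conservatism. The full suite runs in a few
seconds; `scripts/acceptance.py` in well under a minute. Histogram
conservation is asserted at 10⁻⁹; mass arithmetic at 10⁻⁶ Da.

## Known limitations

- The one-offset alignment cannot represent two independent events on a
  single edge; such pairs can still be accepted when long, and are handled
  by routing annotations through intermediate variants. When no
  intermediate spectrum exists, the localized annotation degrades to the
  best single-offset approximation.
- Mirror resolution assumes y-over-b intensity dominance; spectra with
  inverted or absent series will keep mirror peaks (costing sensitivity,
  not correctness of accepted pairs).
- The edge FDR r is treated as constant across edges and depths; the
  aggregate FDR is exact only under edge-independence, and path-sharing
  makes realized errors correlated (the conservatism test bounds this
  empirically).
- Consensus clustering of redundant spectra is assumed done upstream;
  whether it changes p-value calibration is untested here.
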