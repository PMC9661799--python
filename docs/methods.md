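# Methods

## The event model

Copy-number profiles are vectors of integers `0..cap` (default cap 8) per
haplotype over a shared segmentation. For the distance machinery a genome
is one symbol string: haplotype A's chromosomes in layout order, then
haplotype B's, all separated by the chromosome separator `X`. Working on
the concatenated string is what lets a WGD be a *single* event touching
both haplotypes, while segmental events are confined to one
(haplotype, chromosome) unit because their runs terminate at `X`.

Four one-step weighted finite-state transducers over the tropical
semiring (min, +) define the elementary events:

* **LOH-phase loss**: a contiguous run of −1 decrements that may drive
  segments to 0; cost 1 per run.
* **Segmental loss**: a −1 run whose results stay ≥ 1.
* **Segmental gain**: a +1 run over non-zero segments, results ≤ cap.
* **WGD**: +1 on every non-zero symbol of the whole string, `X` and 0
  unchanged, cost 1 (`wgd_mode="double"` doubles each non-zero symbol
  instead; both step semantics are supported because both readings of a
  "genome doubling" appear in practice, and the increment form is the
  package default).

All runs skip zero-copy segments at no cost — deleted DNA is simply not
there to interrupt an event — and cannot start on them. Each one-step
machine is self-composed `|Σ|−1` times (LOH) or `|Σ|−2` times (the
others) so that any reachable copy number can be produced, and the
asymmetric machine is the phase chain `T_LOH ∘ T_WGD ∘ T_L ∘ T_G`. The
phase order is definitional: LOH first because zeroed segments constrain
everything downstream, WGD before segmental losses/gains so that copies
created by a doubling can subsequently be lost. MED(x → y) is the
tropical shortest distance of `x ∘ T ∘ y`; it is +∞ exactly when y is
positive somewhere x is zero. The symmetric distance is the ancestor
kernel `S[x,y] = SD(x ∘ T⁻¹ ∘ T ∘ y) = min_z MED(z→x) + MED(z→y)`; it is
always finite (take z = y with the x-branch deleting what only y has) and
is the distance used for tree building.

## Lazy evaluation of the composition

`fst_core` implements the machinery literally: eager composition,
inversion, projection, n-fold self-composition, Dijkstra shortest
distance, and a lazy best-first shortest path that expands the product of
a machine chain only along visited states. That route is exact but
exponential in machine count, so it serves as the reference on small
inputs.

The production path (`_dpcore`) exploits the structure of the n-fold
self-compositions: the product of n one-step run machines is equivalent,
after canonicalizing runs to "prefix" form, to a machine whose state is a
single integer — the number of currently open runs (*pending depth*).
Opening a run costs 1, closing is free, so the transition cost between
depth states is `max(0, d_new − d_old)` per phase, and the lazy
composition of the whole chain restricted to one X-free unit becomes a
forward dynamic program over tuples (LOH depth, loss depth, gain depth)
— squared, plus a per-position ancestor value, for the symmetric kernel.
Two details make this exact:

* a state is feasible at a position only if consistent intermediate
  symbols exist (post-LOH value u, post-WGD value `u+j` on non-zero u,
  post-loss value m ≥ 1 matching the target), which is checked in O(cap);
* runs cannot open on zero-copy positions, but letting the relaxation pay
  for a depth increase there is harmless: deferring the same payment to
  the next non-skipped position costs exactly the same.

The WGD count j is a global variable shared by all units; callers
minimize over j (bounded: an optimal increment-mode explanation never
uses j ≥ max(target), since dropping one WGD then saves one event
without raising any staircase). Per-unit results are memoized by content,
which makes cohort-scale matrices fast (most chromosomes repeat). The
kernels are numba-compiled and release the GIL, so the `p²+p` pair groups
(the affine-plane construction over the smallest prime p with p² ≥ N,
every unordered pair in exactly one group) can run on threads; results
are independent of worker count by construction. Equivalence of the
production path with the explicit engine and with a brute-force
phase-ordered search is asserted in the test suite; this equivalence, not
a particular traversal order, is the module contract.

Optimal paths are recovered by backtracing the DP tables (ties broken
toward the smallest state, making extraction deterministic), giving
per-branch `EventRecord`s whose replay in phase order reproduces the
child profile exactly, and, for the symmetric kernel, a witnessing
ancestor profile.

## Evolutionary phasing

Allele-specific callers report unordered (major, minor) pairs. The
phasing FST is a linear chain with two mirrored transitions per segment
(major→minor and minor→major), so its 2ⁿ accepting paths are the possible
haplotype assignments. Composing it on both sides with the
reference-side machine `u = (d ∘ T)↓` (d the all-ones haploid reference)
and taking the shortest path yields the assignment minimizing
MED(1s → hapA) + MED(1s → hapB), each haplotype treated as its own
genome (its own WGD count). The implementation evaluates this with the
same depth DP (source fixed at 1, a per-position orientation choice) and
is tested against exhaustive 2ⁿ enumeration. Ties are resolved by placing
the major copy number on haplotype A at the first unbalanced segment (the
mirror image always scores identically). Swaps are allowed at every
segment boundary; phasing runs genome-wide in one pass, which is
equivalent to per-chromosome phasing because no segmental event crosses
`X` (only the per-haplotype WGD count couples chromosomes).

## Trees, ancestors, events

The tree topology comes from neighbor joining on the symmetric MED matrix
(deterministic smallest-index tie-break; negative length estimates are
clamped to 0 with a warning). The tree is rooted by placing the root on
the diploid's pendant branch. Ancestral profiles minimize the total
asymmetric MED along the tree, directed away from the diploid root. That
Steiner problem is NP-complete, so we use a monotone local search:
internal nodes are initialized bottom-up with the pairwise witness
ancestor of their children, then re-optimized coordinate-wise (every
segment/haplotype, all values `0..cap`, accepting only improvements)
until a sweep changes nothing (default cap of 10 sweeps; the objective
provably never increases and each evaluation touches only the three
adjacent branches and one chromosome, served from the per-unit cache).
Final branch lengths are the asymmetric MEDs, so the branch event lists
sum exactly to the tree length. Events are counted once, at the branch
where the change occurs, which is what lets parallel (homoplastic)
changes on sibling branches stay separate.

`tree_stats` reports tree length, trunk length (root to the MRCA of the
non-diploid samples), maximal root-to-leaf length and their ratio.
Robinson-Foulds distances are computed as bipartition symmetric
differences (cross-checked against dendropy).

## WGD detection and resampling

The evidence score of sample t is `s = MED_noWGD(d,t) − MED_WGD(d,t) ≥ 0`;
s ≥ 1 means the cheapest explanation includes a doubling. Replacing the
WGD phase with n-step variants gives MED_nWGD, non-increasing in n; the
inferred WGD count is the smallest n reaching the unbounded value. Two
resampling schemes quantify robustness: chromosome bootstrap (draw
chromosomes with replacement — valid because segmental events respect
chromosome boundaries and WGD is indifferent to chromosome identity) and
the natural segment jackknife (draw N segments with replacement, drop
duplicates, keep order; retains 1 − 1/e of segments in expectation). A
sample is called WGD-positive when ≥ 5% (configurable) of replicates
show ≥ 1 WGD; branch support is the percentage of replicate trees
containing each bipartition. Region scores count, per BED region, events
covering at least 90% of the region (the event-covers-region direction:
regions of interest such as genes are small relative to events, so the
inverse reading would almost never fire), with a WGD counted as a gain
for every region.

## Simulators

The **MED-model simulator** draws Poisson(μ = 10) events per genome on a
length-50 haploid sequence (5 chromosomes × 10 segments): 5% WGD, 47.5%
gain, 47.5% loss, geometric(p = 0.2) lengths, starts uniform over
non-zero positions, constraints enforced. Because the generative process
matches the distance model, the true event count is a certified upper
bound on the MED, which the suite checks on 1000 draws, and the Euclidean
contrast (r² ≈ 0.17 between Euclidean distance to the diploid and true
count) is computed from it by `scripts/acceptance.py`.

The **genome-level simulator** deliberately does *not* speak the distance
model's language: it evolves token genomes (chromosome copies holding
reference-segment identities with orientation) along a random joined
topology rooted at the diploid, with Poisson(Δt·S·μ) events per branch
(S = 440 segments by default: 2 × 22 chromosomes × 10 segments). Events:
whole-chromosome gain/loss, focal loss, insertion (implemented as
duplication of a contiguous run inserted at a uniform position — the
mechanism is otherwise unconstrained), BFB (terminal loss followed by
inverted duplication of the remaining terminal run — the canonical BFB
outcome; profiles only see counts), WGD (true duplication of every
chromosome copy), and copy-neutral inversions and balanced/unbalanced
translocations. A translocated segment thereafter travels with its host
chromosome (gaining chr2 also gains the chr1 segment moved onto it). All
types are equally weighted except BFB at 0.1 relative weight and WGD at
its configured probability (default 0.000125, the large-tree setting;
0.0125/0.065 reproduce the low/high-WGD regimes). Deletions never touch
haplotype-B material (including copies that acquired B tokens by
translocation), which precludes homozygous deletions. Profiles are
derived by counting token occurrences, clipped at the cap (rare at
default rates and logged). Per-branch random substreams are spawned from
(seed, preorder branch index), so runs are byte-reproducible.

What the simulations do **not** model: read-level noise (logR/BAF),
subclonal mixtures within one sample, chromothripsis as a single event,
and calling errors in the upstream segmentation. Passing the recovery
tests therefore demonstrates correctness of the inference given exact
integer profiles, not robustness to measurement noise; the resampling
machinery exists precisely to probe the latter on real data.

## Problem sizes and numerical choices

The validation suite uses the study conditions above at these sizes:
oracle equivalence on 520 random pairs (cap 3, 4–8 segments, 1–2
chromosomes, with and without WGD); 1000 profiles for the lower bound;
500 for the Euclidean contrast; 50 × 2¹² assignments for phasing; 200+200
genomes for WGD recovery; 25 trees per N ∈ {5, 10, 15, 20} at μ = 0.025
for the tree-recovery ordering (topology RF only — ancestral
reconstruction cannot change the NJ topology). Distances are exact
integers throughout; +∞ is a first-class value (a sentinel in the
kernels, `math.inf` at the API); no floating point enters the distance
core. Degenerate inputs: empty event lists for identical profiles, an
explicit error naming the offending zero segments when an infinite branch
is requested, a warning (not an error) for jackknifing a single-segment
genome.

## Known limitations

* Ancestral reconstruction is a local search; it guarantees monotone
  improvement and determinism, not global Steiner optimality (verified
  optimal on small brute-forceable instances).
* The MED undercounts histories whose true event order violates the
  canonical phase order, and a tetraploidization followed by many
  chromosome losses is counted as 1 + (number of losses) events — the
  distance is a lower bound by design.
* Horizontal segment dependencies are assumed contiguous with the
  reference genome; heavy rearrangement (many translocations/inversions)
  degrades accuracy gracefully but is not modeled.
* Input profiles must be integer copy numbers on a shared segmentation;
  calling copy number from reads is upstream of this package
  (`harmonize_segmentation` only unifies breakpoints).
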