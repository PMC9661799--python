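# medphylo

Whole-genome-doubling-aware phylogenies from allele-specific copy-number
profiles.

Somatic copy-number alterations (SCNAs) are a rich record of a tumor's
evolutionary history, but they break the assumptions most phylogenetic
methods rely on: one gain or loss can span many segments at once, events
overlap and overwrite each other, fully deleted material can never be
regained, and whole-genome doublings (WGD) change every segment in a
single step. `medphylo` reconstructs trees, ancestral genomes, and
individual events from segmented haplotype-specific integer copy-number
profiles (bulk samples, subclones, or single cells) under an explicit
evolutionary model that respects all of these constraints.

## The model

A genome is a pair of integer copy-number vectors (haplotypes A and B,
values `0..8`) over a shared segmentation, encoded as a symbol string over
`{0..8, X}` with `X` marking chromosome boundaries. Four event classes
act on it, in a fixed phase order:

1. **LOH losses** — contiguous −1 runs that may reach zero. They come
   first because a segment at zero is gone for good: later events skip it
   and gains can never restore it.
2. **WGD** — one event adds a copy to every non-zero segment of both
   haplotypes, crossing chromosome boundaries (a `--wgd-x2` variant
   doubles instead).
3. **Segmental losses** — contiguous −1 runs that keep segments ≥ 1.
4. **Segmental gains** — contiguous +1 runs on non-zero segments; runs
   pass over zero-copy segments at no cost and stop at `X`.

The **minimum-event distance** MED(x → y) is the least number of such
events transforming x into y, computed as the tropical-semiring shortest
path through the chain of weighted finite-state transducers
`T_LOH ∘ T_WGD ∘ T_L ∘ T_G` (each one-step machine self-composed enough
times to span the copy-number range). The distance is asymmetric —
MED(x → y) is infinite if y needs a segment x has already lost — so the
pairwise distance used for tree building is the symmetric kernel

    S[x, y] = min over ancestors z of  MED(z → x) + MED(z → y),

i.e. the shortest path through `x ∘ T⁻¹ ∘ T ∘ y`. The composition is
evaluated lazily (a best-first dynamic program over phase-machine states,
per chromosome), so distances on 440-segment genomes take milliseconds.

On top of the distance the package provides evolutionary phasing of
major/minor copy numbers (exact minimum-evolution assignment via a
phasing FST), neighbor-joining tree inference rooted at a diploid,
minimum-event ancestral reconstruction with per-branch event extraction,
WGD detection via the evidence score
`s = MED_noWGD(diploid, t) − MED_WGD(diploid, t)` with multi-WGD counting
and bootstrap calling, chromosome-bootstrap/segment-jackknife branch
support, and two simulators for validation.

## Worked example

Simulate genome-level evolution (chromosomal and focal gains/losses,
BFBs, translocations, inversions, WGDs) along a random 5-leaf tree, then
infer everything back:

```
$ medphylo simulate -o demo_sim -n 5 --mu 0.03 --chromosomes 8 --segments 6 --seed 17
$ medphylo infer demo_sim/cohort.tsv -o demo_out --bootstrap 50 --seed 17
INFO cohort: 5 samples, 48 segments
INFO pairwise distances written (max 7)
INFO tree length 14, trunk 3
```

`demo_out/tree.nwk` holds the rooted tree with integer branch lengths
(numbers of events) and bootstrap support on internal branches:

```
(diploid:0,(S4:0,(S1:0,(S2:0,(S3:2,S5:1)88:3)50:3)52:2):3);
```

Fourteen events explain all five genomes; the trunk (diploid → MRCA)
carries 3 of the 13 events on the longest root-to-leaf path (trunk
fraction 0.23), so most SCNAs here arose after the samples started
diverging. `events.tsv` lists each event at the branch where it
happened, e.g. two independent LOH losses on the terminal branch of S3:

```
branch  kind      haplotype  chrom  start    end
S3      loh_loss  A          chr4   1        6000000
S3      loh_loss  A          chr8   1        6000000
S5      gain      A          chr5   1000001  4000000
```

and `wgd.tsv` reports the WGD evidence score, inferred WGD count, and
the bootstrap fraction per sample (all zero here — no doubling was
simulated). Input is a plain TSV (`sample_id chrom start end cn_a cn_b`,
1-based inclusive); unphased major/minor calls are accepted with
`--input-mode major-minor` (evolutionary phasing), total copy numbers
with `--input-mode total`.

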