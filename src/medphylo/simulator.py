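"""Two validation simulators.

1. The MED-model profile simulator draws a Poisson number of events
   (WGD / gain / loss with fixed probabilities, geometric lengths,
   uniform starts over non-zero positions) and applies them directly to a
   copy-number sequence, so the true event count is known.  It emulates
   exactly the process the distance model assumes.

2. The genome-level simulator evolves actual genomes (sequences of
   reference-segment tokens per chromosome copy) along a random tree:
   whole-chromosome gains/losses, focal losses, insertions
   (duplications), breakage-fusion-bridge cycles, WGD, and copy-neutral
   inversions and balanced/unbalanced translocations.  Copy-number
   profiles are derived afterwards by counting tokens, so the data
   generation is deliberately *not* expressed in the distance model's
   event vocabulary.  Deletions never target haplotype-B-derived
   chromosome copies, which prevents homozygous deletions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_model import Cohort, CopyNumberProfile, GenomeLayout
from .phylogeny import TreeNode

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MED-model simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MedSimConfig:
    """Study conditions of the model-level simulation.

    Defaults follow the accuracy-evaluation setting: event count
    Poisson(mu=10); 5% WGD, 47.5% gain, 47.5% loss; geometric(p=0.2) run
    lengths; 5 chromosomes of 10 segments (a length-50 sequence).
    """

    mu: float = 10.0
    p_wgd: float = 0.05
    p_gain: float = 0.475
    p_loss: float = 0.475
    p_geom: float = 0.2
    n_chromosomes: int = 5
    segs_per_chrom: int = 10
    cap: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(self.p_wgd + self.p_gain + self.p_loss, 1.0):
            raise ValueError("event-type probabilities must sum to 1")
        if not (0 < self.p_geom <= 1):
            raise ValueError("p_geom must be in (0, 1]")

    def layout(self) -> GenomeLayout:
        return GenomeLayout.uniform(self.n_chromosomes, self.segs_per_chrom)


def simulate_profile_with_known_count(
    config: MedSimConfig, rng: np.random.Generator | None = None
) -> tuple[CopyNumberProfile, int]:
    """One haploid profile evolved from all-ones, plus its true event count.

    Events obey the biological constraints: no gains of zero-copy
    segments, zero-copy segments are skipped inside runs, gains and
    losses end at chromosome boundaries, WGD affects every non-zero
    position.  An event that can find no non-zero position is skipped and
    not counted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout = config.layout()
    n = layout.n_segments
    seq = np.ones(n, dtype=np.int64)
    bounds = [(sl.start, sl.stop) for sl in layout.chrom_slices().values()]

    def chrom_end(pos: int) -> int:
        for lo, hi in bounds:
            if lo <= pos < hi:
                return hi
        raise AssertionError

    n_events = int(rng.poisson(config.mu))
    applied = 0
    for _ in range(n_events):
        kind = rng.choice(
            ["wgd", "gain", "loss"], p=[config.p_wgd, config.p_gain, config.p_loss]
        )
        nonzero = np.flatnonzero(seq > 0)
        if nonzero.size == 0:
            continue
        if kind == "wgd":
            seq[seq > 0] = np.minimum(seq[seq > 0] + 1, config.cap)
            applied += 1
            continue
        start = int(rng.choice(nonzero))
        length = int(rng.geometric(config.p_geom))
        stop = min(start + length, chrom_end(start))
        span = seq[start:stop]
        nz = span > 0
        if kind == "gain":
            span[nz] = np.minimum(span[nz] + 1, config.cap)
        else:
            span[nz] -= 1
        seq[start:stop] = span
        applied += 1
    return CopyNumberProfile("sim", seq), applied


# ---------------------------------------------------------------------------
# genome-level simulator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimConfig:
    """Study conditions of the genome-level simulation.

    The genome is 2 x ``n_chromosomes`` chromosomes (two haplotype sets)
    of ``segs_per_chrom`` uniform segments; with the defaults S = 440
    segments.  Each branch of length dt carries Poisson(dt * S * mu)
    events.  All event types are equally likely except BFBs (relative
    weight ``bfb_relative``) and WGDs (absolute probability ``wgd_prob``).
    Focal event lengths are geometric(``p_geom``).
    """

    n_leaves: int = 10
    mu: float = 0.025
    delta_t: float = 1.0
    n_chromosomes: int = 22
    segs_per_chrom: int = 10
    wgd_prob: float = 0.000125
    bfb_relative: float = 0.1
    p_geom: float = 0.2
    cap: int = 8
    seed: int = 0

    def layout(self) -> GenomeLayout:
        return GenomeLayout.uniform(self.n_chromosomes, self.segs_per_chrom)

    @property
    def S(self) -> int:
        return 2 * self.n_chromosomes * self.segs_per_chrom

    @property
    def lam(self) -> float:
        return self.delta_t * self.S * self.mu


#: copy-neutral or copy-changing event names, in dispatch order
_EVENT_TYPES = [
    "chrom_gain",
    "chrom_loss",
    "focal_loss",
    "insertion",
    "bal_translocation",
    "unbal_translocation",
    "inversion",
    "bfb",
    "wgd",
]


@dataclass
class ChromosomeCopy:
    origin_hap: str  # haplotype of the founding copy ("A"/"B")
    tokens: list  # (hap, chrom_index, segment_index, orientation)


class SimulatedGenome:
    """A genome as a set of chromosome copies holding segment tokens."""

    def __init__(self, layout: GenomeLayout):
        self.layout = layout
        self.copies: list[ChromosomeCopy] = []
        for hap in ("A", "B"):
            for ci in range(len(layout.chromosomes)):
                n = len(layout.segments[layout.chromosomes[ci]])
                self.copies.append(
                    ChromosomeCopy(hap, [(hap, ci, si, 1) for si in range(n)])
                )

    def clone(self) -> "SimulatedGenome":
        g = SimulatedGenome.__new__(SimulatedGenome)
        g.layout = self.layout
        g.copies = [ChromosomeCopy(c.origin_hap, list(c.tokens)) for c in self.copies]
        return g

    # -- events ------------------------------------------------------------

    def _deletable(self) -> list[int]:
        """Copies eligible for deletions.

        Haplotype-B material is protected (no deletions of haplotype 2),
        which prevents homozygous deletions; a copy that acquired B tokens
        through a translocation is protected as a whole.
        """
        return [
            i
            for i, c in enumerate(self.copies)
            if c.tokens and all(h == "A" for (h, _c, _s, _o) in c.tokens)
        ]

    def _nonempty(self) -> list[int]:
        return [i for i, c in enumerate(self.copies) if c.tokens]

    def gain_chromosome(self, idx: int) -> None:
        c = self.copies[idx]
        self.copies.append(ChromosomeCopy(c.origin_hap, list(c.tokens)))

    def lose_chromosome(self, idx: int) -> None:
        self.copies.pop(idx)

    def focal_loss(self, idx: int, start: int, length: int) -> None:
        toks = self.copies[idx].tokens
        del toks[start : start + length]

    def insertion(self, idx: int, start: int, length: int, at: int) -> None:
        toks = self.copies[idx].tokens
        dup = list(toks[start : start + length])
        toks[at:at] = dup

    def inversion(self, idx: int, start: int, length: int) -> None:
        toks = self.copies[idx].tokens
        seg = [(h, c, s, -o) for (h, c, s, o) in reversed(toks[start : start + length])]
        toks[start : start + length] = seg

    def bfb(self, idx: int, lost: int, duplicated: int) -> None:
        """Breakage-fusion-bridge: terminal loss then inverted duplication."""
        toks = self.copies[idx].tokens
        if lost >= len(toks):
            lost = len(toks) - 1
        if lost > 0:
            del toks[len(toks) - lost :]
        duplicated = min(duplicated, len(toks))
        tail = toks[len(toks) - duplicated :]
        toks.extend((h, c, s, -o) for (h, c, s, o) in reversed(tail))

    def balanced_translocation(self, i1: int, k1: int, i2: int, k2: int) -> None:
        """Swap the terminal runs of two chromosome copies (copy-neutral)."""
        t1, t2 = self.copies[i1].tokens, self.copies[i2].tokens
        tail1, tail2 = t1[len(t1) - k1 :], t2[len(t2) - k2 :]
        self.copies[i1].tokens = t1[: len(t1) - k1] + tail2
        self.copies[i2].tokens = t2[: len(t2) - k2] + tail1

    def unbalanced_translocation(self, src: int, k: int, dst: int) -> None:
        """Move the terminal run of one copy onto the end of another."""
        t = self.copies[src].tokens
        tail = t[len(t) - k :]
        self.copies[src].tokens = t[: len(t) - k]
        self.copies[dst].tokens = self.copies[dst].tokens + tail

    def wgd(self) -> None:
        self.copies.extend(
            ChromosomeCopy(c.origin_hap, list(c.tokens)) for c in list(self.copies)
        )


def genome_to_profile(
    genome: SimulatedGenome, layout: GenomeLayout, cap: int = 8, sample_id: str = "sim"
) -> CopyNumberProfile:
    """Copy numbers by counting token occurrences, clipped at the cap."""
    n = layout.n_segments
    offsets = {ci: sl.start for ci, sl in enumerate(layout.chrom_slices().values())}
    counts = {"A": np.zeros(n, dtype=np.int64), "B": np.zeros(n, dtype=np.int64)}
    for c in genome.copies:
        for hap, ci, si, _o in c.tokens:
            counts[hap][offsets[ci] + si] += 1
    clipped = int((counts["A"] > cap).sum() + (counts["B"] > cap).sum())
    if clipped:
        logger.warning("%d segment counts exceed cap=%d; clipping", clipped, cap)
    return CopyNumberProfile(
        sample_id, np.minimum(counts["A"], cap), np.minimum(counts["B"], cap)
    )


def _event_weights(config: GenomeSimConfig) -> tuple[list[str], np.ndarray]:
    others = [t for t in _EVENT_TYPES if t not in ("bfb", "wgd")]
    w = np.array([1.0] * len(others) + [config.bfb_relative])
    w = w / w.sum() * (1.0 - config.wgd_prob)
    return others + ["bfb"] + ["wgd"], np.append(w, config.wgd_prob)


def _random_event(genome: SimulatedGenome, rng: np.random.Generator, config: GenomeSimConfig):
    """Apply one random event; returns its log record or None if skipped."""
    types, probs = _event_weights(config)
    kind = str(rng.choice(types, p=probs))

    def geom() -> int:
        return int(rng.geometric(config.p_geom))

    if kind == "wgd":
        genome.wgd()
        return {"kind": kind}
    if kind == "chrom_gain":
        pool = genome._nonempty()
        if not pool:
            return None
        idx = int(rng.choice(pool))
        genome.gain_chromosome(idx)
        return {"kind": kind, "copy": idx}
    if kind in ("chrom_loss", "focal_loss", "bfb"):
        pool = genome._deletable()
        if not pool:
            return None
        idx = int(rng.choice(pool))
        toks = genome.copies[idx].tokens
        if kind == "chrom_loss":
            genome.lose_chromosome(idx)
            return {"kind": kind, "copy": idx}
        if kind == "focal_loss":
            start = int(rng.integers(0, len(toks)))
            length = min(geom(), len(toks) - start)
            genome.focal_loss(idx, start, length)
            return {"kind": kind, "copy": idx, "start": start, "length": length}
        genome.bfb(idx, geom(), geom())
        return {"kind": kind, "copy": idx}
    pool = genome._nonempty()
    if not pool:
        return None
    idx = int(rng.choice(pool))
    toks = genome.copies[idx].tokens
    if kind == "insertion":
        start = int(rng.integers(0, len(toks)))
        length = min(geom(), len(toks) - start)
        at = int(rng.integers(0, len(toks) + 1))
        genome.insertion(idx, start, length, at)
        return {"kind": kind, "copy": idx, "start": start, "length": length, "at": at}
    if kind == "inversion":
        start = int(rng.integers(0, len(toks)))
        length = min(geom(), len(toks) - start)
        genome.inversion(idx, start, length)
        return {"kind": kind, "copy": idx, "start": start, "length": length}
    if kind == "bal_translocation":
        if len(pool) < 2:
            return None
        i1, i2 = (int(v) for v in rng.choice(pool, size=2, replace=False))
        k1 = min(geom(), len(genome.copies[i1].tokens))
        k2 = min(geom(), len(genome.copies[i2].tokens))
        genome.balanced_translocation(i1, k1, i2, k2)
        return {"kind": kind, "copies": (i1, i2)}
    if kind == "unbal_translocation":
        if len(pool) < 2:
            return None
        src, dst = (int(v) for v in rng.choice(pool, size=2, replace=False))
        k = min(geom(), len(genome.copies[src].tokens))
        genome.unbalanced_translocation(src, k, dst)
        return {"kind": kind, "src": src, "dst": dst, "k": k}
    raise AssertionError(kind)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_topology(n_leaves: int, seed: int = 0) -> TreeNode:
    """Random rooted binary topology by random joining, diploid at the root."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"S{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(int(v) for v in rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.add(TreeNode(name="diploid"))
    root.add(nodes[0])
    return root


def evolve_genomes(
    tree: TreeNode, config: GenomeSimConfig
) -> tuple[dict[str, SimulatedGenome], Cohort, dict[str, list[dict]]]:
    """Mutate genomes along the tree; derive leaf profiles by counting.

    Returns (leaf genomes by name, cohort of leaf profiles + diploid,
    per-branch event logs).  Branch event counts are Poisson(dt * S * mu);
    per-branch random substreams are derived deterministically from the
    seed and the branch's preorder index.
    """
    layout = config.layout()
    root_genome = SimulatedGenome(layout)
    leaf_genomes: dict[str, SimulatedGenome] = {}
    logs: dict[str, list[dict]] = {}
    counter = 0
    for node in tree.postorder():
        if node.name is None:
            counter += 1
            node.name = f"anc{counter}"

    branch_index = {}
    for i, node in enumerate(tree.preorder()):
        branch_index[node.name] = i

    def walk(node: TreeNode, genome: SimulatedGenome) -> None:
        for child in node.children:
            g = genome.clone()
            if child.name == "diploid" and child.is_leaf:
                leaf_genomes[child.name] = g
                logs[child.name] = []
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(branch_index[child.name],))
            )
            n_events = int(rng.poisson(config.lam))
            child.length = n_events
            log = []
            for _ in range(n_events):
                rec = _random_event(g, rng, config)
                if rec is not None:
                    log.append(rec)
            logs[child.name] = log
            if child.is_leaf:
                leaf_genomes[child.name] = g
            else:
                walk(child, g)

    walk(tree, root_genome)
    profiles = [
        genome_to_profile(g, layout, config.cap, name)
        for name, g in sorted(leaf_genomes.items())
        if name != "diploid"
    ]
    cohort = Cohort(layout, profiles)
    return leaf_genomes, cohort, logs


def simulate_cohort(config: GenomeSimConfig) -> tuple[Cohort, TreeNode, dict[str, list[dict]]]:
    """Random topology + genome evolution + derived cohort, in one call."""
    tree = simulate_topology(config.n_leaves, seed=config.seed)
    _genomes, cohort, logs = evolve_genomes(tree, config)
    return cohort, tree, logs
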