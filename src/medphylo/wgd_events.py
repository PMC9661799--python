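"""WGD evidence scoring and counting, resampling-based robustness, and
per-branch event detection with region scoring.

The WGD evidence score of a sample t against the diploid d is

    s = MED_noWGD(d, t) - MED_WGD(d, t)  >=  0,

and s >= 1 means the minimum-event explanation prefers at least one WGD.
The number of WGDs is counted by capping the WGD phase at n events: the
smallest n whose distance equals the unbounded MED-WGD is the inferred
count.  Robustness against noisy profiles comes from resampling whole
chromosomes with replacement (bootstrap) or segments via a natural
jackknife (draw N with replacement, discard duplicates, keep order); a
sample is called WGD-positive when at least ``threshold`` (default 5%) of
replicates show at least one WGD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import (
    Cohort,
    CopyNumberProfile,
    GenomeLayout,
    diploid_profile,
)
from .med_model import EventModel, EventRecord, extract_events, med_wgd_curve
from .phylogeny import TreeNode, _bipartitions

logger = logging.getLogger(__name__)


@dataclass
class WgdResult:
    sample_id: str
    s: int  # evidence score MED_noWGD - MED_WGD
    wgd_count: int
    bootstrap_fraction: float | None = None  # replicates with >= 1 WGD
    multi_bootstrap_fraction: float | None = None  # replicates with >= 2 WGDs
    call: bool | None = None


@dataclass
class RegionScore:
    name: str
    chrom: str
    start: int
    end: int
    gains: int
    losses: int

    @property
    def net(self) -> int:
        return self.gains - self.losses


def wgd_evidence(
    profile: CopyNumberProfile, model: EventModel, layout: GenomeLayout
) -> WgdResult:
    """Evidence score and WGD count of one profile against the diploid."""
    d = diploid_profile(layout, haploid=profile.haploid)
    curve = med_wgd_curve(d, profile, model, layout)
    if any(math.isinf(c) for c in curve):  # pragma: no cover - d has no zeros
        raise ValueError("infinite distance from the diploid")
    best = curve[-1]
    s = int(curve[0] - best)
    wgd_count = next(n for n, c in enumerate(curve) if c == best)
    return WgdResult(profile.sample_id, s, wgd_count)


def resample_cohort(
    cohort: Cohort,
    strategy: str = "chromosome_bootstrap",
    B: int = 100,
    seed: int = 0,
) -> list[Cohort]:
    """B resampled cohorts; identical seeds give identical replicates."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    layout = cohort.layout
    out = []
    for _ in range(B):
        if strategy == "chromosome_bootstrap":
            out.append(_chromosome_bootstrap(cohort, rng))
        elif strategy == "segment_jackknife":
            out.append(_segment_jackknife(cohort, rng))
        else:
            raise ValueError(f"unknown resampling strategy {strategy!r}")
    return out


def _chromosome_bootstrap(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    layout = cohort.layout
    k = len(layout.chromosomes)
    draws = rng.integers(0, k, size=k)
    chroms = tuple(f"{layout.chromosomes[d]}.b{i}" for i, d in enumerate(draws))
    segments = {c: list(layout.segments[layout.chromosomes[d]]) for c, d in zip(chroms, draws)}
    new_layout = GenomeLayout(chroms, segments)
    slices = layout.chrom_slices()
    take = np.concatenate(
        [np.arange(s.start, s.stop) for s in (slices[layout.chromosomes[d]] for d in draws)]
    )
    return _subset_cohort(cohort, new_layout, take)


def _segment_jackknife(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    layout = cohort.layout
    n = layout.n_segments
    if n == 1:
        logger.warning("jackknife on a single-segment genome is degenerate")
    kept = np.unique(rng.integers(0, n, size=n))  # order preserved (sorted indices)
    chrom_slices = layout.chrom_slices()
    chroms, segments, take = [], {}, []
    for c in layout.chromosomes:
        sl = chrom_slices[c]
        local = [i for i in kept if sl.start <= i < sl.stop]
        if not local:
            continue
        chroms.append(c)
        segments[c] = [layout.segments[c][i - sl.start] for i in local]
        take.extend(local)
    new_layout = GenomeLayout(tuple(chroms), segments)
    return _subset_cohort(cohort, new_layout, np.array(take))


def _subset_cohort(cohort: Cohort, new_layout: GenomeLayout, take: np.ndarray) -> Cohort:
    profiles = [
        CopyNumberProfile(
            p.sample_id,
            p.hapA[take],
            None if p.haploid else p.hapB[take],
        )
        for p in cohort.profiles
    ]
    return Cohort(new_layout, profiles)


def jackknife_retained_fraction(cohort: Cohort, replicates: list[Cohort]) -> float:
    """Mean fraction of segments kept by the jackknife (expected 1 - 1/e)."""
    n = cohort.layout.n_segments
    return float(np.mean([r.layout.n_segments / n for r in replicates]))


def call_wgd_with_bootstrap(
    profile: CopyNumberProfile,
    model: EventModel,
    layout: GenomeLayout,
    B: int = 100,
    threshold: float = 0.05,
    seed: int = 0,
    strategy: str = "chromosome_bootstrap",
) -> WgdResult:
    """WGD call from the evidence score over B resampled replicates.

    The status is positive when at least ``threshold`` of replicates show
    >= 1 WGD; the multi-WGD fraction counts replicates with >= 2.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    base = wgd_evidence(profile, model, layout)
    # the resampling cohort needs a non-reserved id even when scoring the
    # reference itself
    safe = CopyNumberProfile("__sample__", profile.hapA, profile.hapB)
    cohort = Cohort(layout, [safe])
    reps = resample_cohort(cohort, strategy, B, seed)
    counts = []
    for rep in reps:
        res = wgd_evidence(rep.profiles[0], model, rep.layout)
        counts.append(res.wgd_count)
    frac = float(np.mean([c >= 1 for c in counts]))
    multi = float(np.mean([c >= 2 for c in counts]))
    return WgdResult(
        profile.sample_id,
        base.s,
        base.wgd_count,
        bootstrap_fraction=frac,
        multi_bootstrap_fraction=multi,
        call=frac >= threshold,
    )


# ---------------------------------------------------------------------------
# branch support
# ---------------------------------------------------------------------------


def branch_support(tree: TreeNode, replicate_trees: list[TreeNode]) -> TreeNode:
    """Annotate internal branches with the percent of replicates containing
    the same leaf bipartition."""
    leaf_set = tree.leaf_names()
    for rep in replicate_trees:
        if rep.leaf_names() != leaf_set:
            raise ValueError("replicate tree has a different leaf set")
    rep_splits = [_bipartitions(t) for t in replicate_trees]
    all_leaves = leaf_set
    for node in tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = node.leaf_names()
        split = frozenset((side, frozenset(all_leaves - side)))
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        hits = sum(split in s for s in rep_splits)
        node.support = int(round(100 * hits / max(1, len(replicate_trees))))
    return tree


# ---------------------------------------------------------------------------
# per-branch events and region scoring
# ---------------------------------------------------------------------------


def detect_tree_events(
    tree: TreeNode, model: EventModel, layout: GenomeLayout
) -> dict[str, list[EventRecord]]:
    """Events per branch of a reconstructed tree (postorder traversal).

    Each event appears exactly once, at the branch where the copy-number
    change occurs; parallel changes on separate branches stay separate.
    Branches are keyed by the name of their child node (internal nodes get
    stable generated names).
    """
    # give internal nodes stable names
    counter = 0
    for node in tree.postorder():
        if node.name is None:
            counter += 1
            node.name = f"clone{counter}"
    events = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        events[node.name] = extract_events(node.parent.profile, node.profile, model, layout)
    return events


def _event_span_bp(ev: EventRecord, layout: GenomeLayout) -> list[tuple[str, int, int]]:
    """Genomic intervals covered by an event (whole genome for a WGD)."""
    if ev.kind == "wgd":
        return [
            (c, layout.segments[c][0][0], layout.segments[c][-1][1])
            for c in layout.chromosomes
        ]
    segs = layout.segments[ev.chromosome]
    return [(ev.chromosome, segs[ev.start_segment][0], segs[ev.end_segment][1])]


def score_regions(
    events_by_branch: dict[str, list[EventRecord]],
    regions: pd.DataFrame,
    layout: GenomeLayout,
    min_overlap: float = 0.9,
) -> list[RegionScore]:
    """#gains and #losses per region of interest across all branches.

    An event hits a region when it covers at least ``min_overlap`` of the
    region's length; a WGD counts as a gain for every region (every
    non-zero segment is gained).  Regions on unknown chromosomes are
    skipped with a warning.
    """
    scores = []
    for row in regions.itertuples(index=False):
        chrom, start, end, name = str(row.chrom), int(row.start), int(row.end), str(row.name)
        if chrom not in layout.chromosomes:
            logger.warning("region %s on unknown chromosome %s skipped", name, chrom)
            continue
        gains = losses = 0
        rlen = end - start
        for evs in events_by_branch.values():
            for ev in evs:
                cover = 0
                for c, s, e in _event_span_bp(ev, layout):
                    if c == chrom:
                        cover += max(0, min(e, end) - max(s, start))
                if rlen > 0 and cover / rlen >= min_overlap:
                    if ev.delta > 0:
                        gains += 1
                    else:
                        losses += 1
        scores.append(RegionScore(name, chrom, start, end, gains, losses))
    return scores


def wgd_results_table(results: list[WgdResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "evidence_score": [r.s for r in results],
            "wgd_count": [r.wgd_count for r in results],
            "bootstrap_fraction": [r.bootstrap_fraction for r in results],
            "call": [r.call if r.call is not None else (r.wgd_count >= 1) for r in results],
        }
    )
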