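"""Segmented haplotype-specific copy-number profiles and their symbol encoding.

A cohort of tumor samples (or single cells) is described on one shared
``GenomeLayout``: an ordered list of chromosomes, each carrying ordered,
non-overlapping segments.  Every sample contributes one integer copy number
per segment and haplotype.  Profiles are turned into symbol strings over the
alphabet ``{0..cap, X}`` for the transducer machinery: haplotype A's
chromosomes in layout order, separated by the chromosome separator ``X``,
then another ``X``, then haplotype B's chromosomes likewise.

Coordinates in input/output TSV files are 1-based inclusive (the common
segment-table convention); internally everything is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: chromosome separator symbol in encoded sequences
SEP = "X"

#: default maximum representable copy number
DEFAULT_CAP = 8

#: reserved sample id of the diploid reference appended to every cohort
DIPLOID_ID = "diploid"


class SegmentationError(ValueError):
    """Raised when samples do not share a common segmentation."""


@dataclass(frozen=True)
class GenomeLayout:
    """Shared segmented genome: chromosome names and per-chromosome segments.

    ``segments[chrom]`` is a list of ``(start, end)`` pairs, 0-based
    half-open, sorted and non-overlapping.
    """

    chromosomes: tuple[str, ...]
    segments: dict[str, list[tuple[int, int]]] = field(compare=False)

    def __post_init__(self) -> None:
        for chrom in self.chromosomes:
            segs = self.segments[chrom]
            for start, end in segs:
                if start >= end:
                    raise ValueError(f"empty segment {chrom}:{start}-{end}")
            for (s0, e0), (s1, e1) in zip(segs, segs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping segments on {chrom}")

    @classmethod
    def uniform(
        cls, n_chromosomes: int, segs_per_chrom: int, seg_length: int = 1_000_000
    ) -> "GenomeLayout":
        """Uniform layout with ``n_chromosomes`` x ``segs_per_chrom`` equal segments."""
        chroms = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
        segments = {
            c: [(i * seg_length, (i + 1) * seg_length) for i in range(segs_per_chrom)]
            for c in chroms
        }
        return cls(chroms, segments)

    @property
    def n_segments(self) -> int:
        return sum(len(self.segments[c]) for c in self.chromosomes)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(self.segments[c]) for c in self.chromosomes}

    def segment_lengths(self) -> np.ndarray:
        """Genomic length (bp) of every segment, in layout order."""
        return np.array(
            [e - s for c in self.chromosomes for (s, e) in self.segments[c]],
            dtype=np.int64,
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Slice of the flat per-segment vectors covered by each chromosome."""
        out, off = {}, 0
        for c in self.chromosomes:
            n = len(self.segments[c])
            out[c] = slice(off, off + n)
            off += n
        return out

    def total_length(self) -> int:
        return int(self.segment_lengths().sum())


@dataclass
class CopyNumberProfile:
    """Integer copy numbers for one sample on a shared layout.

    ``hapB is None`` marks a haploid profile (total copy numbers measured
    against a haploid all-ones reference), as used by the MED-model
    simulator and the total-copy-number input mode.
    """

    sample_id: str
    hapA: np.ndarray
    hapB: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hapA = np.asarray(self.hapA, dtype=np.int64)
        if self.hapB is not None:
            self.hapB = np.asarray(self.hapB, dtype=np.int64)
            if self.hapA.shape != self.hapB.shape:
                raise ValueError("haplotype vectors differ in length")
        if (self.hapA < 0).any() or (self.hapB is not None and (self.hapB < 0).any()):
            raise ValueError(f"negative copy number in sample {self.sample_id!r}")

    @property
    def haploid(self) -> bool:
        return self.hapB is None

    def haplotypes(self) -> list[np.ndarray]:
        return [self.hapA] if self.haploid else [self.hapA, self.hapB]

    def max_value(self) -> int:
        return int(max(h.max(initial=0) for h in self.haplotypes()))

    def copy(self) -> "CopyNumberProfile":
        return CopyNumberProfile(
            self.sample_id,
            self.hapA.copy(),
            None if self.hapB is None else self.hapB.copy(),
        )

    def equals(self, other: "CopyNumberProfile") -> bool:
        if self.haploid != other.haploid:
            return False
        if not np.array_equal(self.hapA, other.hapA):
            return False
        return self.haploid or np.array_equal(self.hapB, other.hapB)


def diploid_profile(layout: GenomeLayout, haploid: bool = False) -> CopyNumberProfile:
    """The normal reference: copy number 1 on every segment of each haplotype."""
    ones = np.ones(layout.n_segments, dtype=np.int64)
    if haploid:
        return CopyNumberProfile(DIPLOID_ID, ones)
    return CopyNumberProfile(DIPLOID_ID, ones, ones.copy())


@dataclass
class Cohort:
    layout: GenomeLayout
    profiles: list[CopyNumberProfile]
    diploid: CopyNumberProfile = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.diploid is None:
            haploid = bool(self.profiles) and self.profiles[0].haploid
            self.diploid = diploid_profile(self.layout, haploid=haploid)
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in cohort")
        if DIPLOID_ID in ids:
            raise ValueError(f"sample id {DIPLOID_ID!r} is reserved")
        n = self.layout.n_segments
        for p in self.all_profiles():
            if p.hapA.shape[0] != n:
                raise ValueError(
                    f"sample {p.sample_id!r} has {p.hapA.shape[0]} segments, layout has {n}"
                )

    def all_profiles(self) -> list[CopyNumberProfile]:
        """Tumor profiles plus the diploid reference (reconstruction root)."""
        return [*self.profiles, self.diploid]

    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.all_profiles()]

    def __getitem__(self, sample_id: str) -> CopyNumberProfile:
        for p in self.all_profiles():
            if p.sample_id == sample_id:
                return p
        raise KeyError(sample_id)


@dataclass(frozen=True)
class EncodedSequence:
    """Symbol string over ``{0..cap, X}``; see :func:`encode`."""

    symbols: tuple

    def __len__(self) -> int:
        return len(self.symbols)


def profile_units(profile: CopyNumberProfile, layout: GenomeLayout) -> list[np.ndarray]:
    """Split a profile into per-(haplotype, chromosome) vectors.

    Units are the maximal X-free stretches of the encoding: segmental events
    are confined to one unit, WGD spans all of them.
    """
    slices = layout.chrom_slices()
    return [
        np.asarray(hap[slices[c]]) for hap in profile.haplotypes() for c in layout.chromosomes
    ]


def unit_labels(layout: GenomeLayout, haploid: bool) -> list[tuple[str, str]]:
    """(haplotype, chromosome) label for each unit, matching profile_units order."""
    haps = ["A"] if haploid else ["A", "B"]
    return [(h, c) for h in haps for c in layout.chromosomes]


def encode(profile: CopyNumberProfile, layout: GenomeLayout) -> EncodedSequence:
    """Concatenate both haplotypes chromosome-wise with ``X`` separators."""
    units = profile_units(profile, layout)
    symbols: list = []
    for i, unit in enumerate(units):
        if i:
            symbols.append(SEP)
        symbols.extend(int(v) for v in unit)
    return EncodedSequence(tuple(symbols))


def decode(
    seq: EncodedSequence, layout: GenomeLayout, sample_id: str = "decoded", haploid: bool = False
) -> CopyNumberProfile:
    """Inverse of :func:`encode` (bit-exact round trip)."""
    units: list[list[int]] = [[]]
    for sym in seq.symbols:
        if sym == SEP:
            units.append([])
        else:
            units[-1].append(int(sym))
    sizes = [len(layout.segments[c]) for c in layout.chromosomes]
    n_haps = 1 if haploid else 2
    if len(units) != n_haps * len(sizes):
        raise ValueError("encoded sequence does not match layout")
    for unit, expected in zip(units, sizes * n_haps):
        if len(unit) != expected:
            raise ValueError("encoded sequence does not match layout")
    k = len(sizes)
    hapA = np.concatenate([np.array(u, dtype=np.int64) for u in units[:k]])
    if haploid:
        return CopyNumberProfile(sample_id, hapA)
    hapB = np.concatenate([np.array(u, dtype=np.int64) for u in units[k:]])
    return CopyNumberProfile(sample_id, hapA, hapB)


def profile_summaries(
    profile: CopyNumberProfile, layout: GenomeLayout
) -> tuple[float, float]:
    """Length-weighted average ploidy and fraction of the genome with LOH."""
    w = layout.segment_lengths().astype(float)
    w = w / w.sum()
    if profile.haploid:
        total = profile.hapA.astype(float)
        loh = profile.hapA == 0
    else:
        total = (profile.hapA + profile.hapB).astype(float)
        loh = np.minimum(profile.hapA, profile.hapB) == 0
    return float(np.dot(w, total)), float(np.dot(w, loh))


# ---------------------------------------------------------------------------
# TSV input / output
# ---------------------------------------------------------------------------

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}
_SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def _clip_column(values: pd.Series, cap: int, name: str) -> pd.Series:
    if (values < 0).any():
        raise ValueError(f"negative copy number in column {name!r}")
    over = values > cap
    if over.any():
        logger.warning(
            "%d copy numbers in column %r exceed cap=%d; clipping", int(over.sum()), name, cap
        )
    return values.clip(upper=cap)


def read_cohort_tsv(
    path,
    allele_columns: tuple[str, str] | tuple[str] = ("cn_a", "cn_b"),
    cap: int = DEFAULT_CAP,
    include_sex_chromosomes: bool = False,
) -> Cohort:
    """Read a cohort table: one row per sample x segment.

    Expected header: ``sample_id  chrom  start  end`` plus the allele
    columns (two for phased/major-minor input, one for total copy numbers).
    Coordinates are 1-based inclusive.  All samples must share one
    segmentation; use :func:`harmonize_segmentation` first otherwise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"sample_id", "chrom", "start", "end", *allele_columns}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    if not include_sex_chromosomes:
        dropped = df["chrom"].isin(_SEX_CHROMS)
        if dropped.any():
            logger.info("excluding %d sex-chromosome rows", int(dropped.sum()))
            df = df[~dropped]
    for col in allele_columns:
        df[col] = _clip_column(df[col].astype(np.int64), cap, col)

    # 1-based inclusive -> 0-based half-open
    df = df.assign(start=df["start"] - 1)

    by_sample = {sid: g for sid, g in df.groupby("sample_id", sort=False)}
    layouts = {
        sid: tuple(sorted(map(tuple, g[["chrom", "start", "end"]].itertuples(index=False))))
        for sid, g in by_sample.items()
    }
    if len(set(layouts.values())) > 1:
        raise SegmentationError(
            "samples have differing segmentations; run harmonize_segmentation first"
        )

    first = next(iter(by_sample.values()))
    chrom_order = list(dict.fromkeys(df["chrom"]))
    segments = {
        c: sorted(
            (int(s), int(e))
            for s, e in first.loc[first["chrom"] == c, ["start", "end"]].itertuples(index=False)
        )
        for c in chrom_order
    }
    layout = GenomeLayout(tuple(chrom_order), segments)

    order = {
        (c, s): i
        for i, (c, s) in enumerate(
            (c, s) for c in chrom_order for (s, _e) in segments[c]
        )
    }
    profiles = []
    for sid, g in by_sample.items():
        idx = np.array([order[(c, int(s))] for c, s in zip(g["chrom"], g["start"])])
        vecs = []
        for col in allele_columns:
            v = np.zeros(layout.n_segments, dtype=np.int64)
            v[idx] = g[col].to_numpy()
            vecs.append(v)
        if len(allele_columns) == 1:
            profiles.append(CopyNumberProfile(str(sid), vecs[0]))
        else:
            profiles.append(CopyNumberProfile(str(sid), vecs[0], vecs[1]))
    return Cohort(layout, profiles)


def write_cohort_tsv(cohort: Cohort, path, allele_columns=("cn_a", "cn_b")) -> None:
    """Re-export a cohort in the input TSV dialect (1-based inclusive)."""
    rows = []
    for p in cohort.profiles:
        i = 0
        for c in cohort.layout.chromosomes:
            for start, end in cohort.layout.segments[c]:
                row = {
                    "sample_id": p.sample_id,
                    "chrom": c,
                    "start": start + 1,
                    "end": end,
                    allele_columns[0]: int(p.hapA[i]),
                }
                if not p.haploid:
                    row[allele_columns[1]] = int(p.hapB[i])
                rows.append(row)
                i += 1
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def harmonize_segmentation(
    tables: dict[str, pd.DataFrame],
    allele_columns: tuple[str, str] = ("cn_a", "cn_b"),
    cap: int = DEFAULT_CAP,
) -> Cohort:
    """Build a cohort on the union of all samples' breakpoints.

    ``tables`` maps sample id to a per-sample segment table with columns
    ``chrom, start, end`` (1-based inclusive) plus the allele columns.  Each
    sample's copy numbers are carried onto every sub-segment they span;
    regions not covered by a sample are an error.
    """
    prepared = {}
    chrom_order: list[str] = []
    for sid, t in tables.items():
        t = t.copy()
        t["start"] = t["start"] - 1
        for col in allele_columns:
            t[col] = _clip_column(t[col].astype(np.int64), cap, col)
        prepared[sid] = t
        for c in dict.fromkeys(t["chrom"].astype(str)):
            if c not in chrom_order:
                chrom_order.append(c)

    breakpoints: dict[str, set[int]] = {c: set() for c in chrom_order}
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_order}
    for t in prepared.values():
        for c, s, e in t[["chrom", "start", "end"]].itertuples(index=False):
            c = str(c)
            breakpoints[c].update((int(s), int(e)))
            spans[c].append((int(s), int(e)))

    segments = {}
    for c in chrom_order:
        bps = sorted(breakpoints[c])
        covered = []
        for s, e in zip(bps, bps[1:]):
            if any(a <= s and e <= b for a, b in spans[c]):
                covered.append((s, e))
        segments[c] = covered
    layout = GenomeLayout(tuple(chrom_order), segments)

    flat = [(c, s, e) for c in chrom_order for (s, e) in segments[c]]
    profiles = []
    for sid, t in prepared.items():
        vecs = [np.full(len(flat), -1, dtype=np.int64) for _ in allele_columns]
        for row in t.itertuples(index=False):
            c = str(row.chrom)
            for i, (fc, fs, fe) in enumerate(flat):
                if fc == c and row.start <= fs and fe <= row.end:
                    for v, col in zip(vecs, allele_columns):
                        v[i] = getattr(row, col)
        for v in vecs:
            if (v < 0).any():
                missing = [flat[i] for i in np.flatnonzero(v < 0)][:3]
                raise SegmentationError(
                    f"sample {sid!r} does not cover segments {missing} of the "
                    "harmonized layout"
                )
        profiles.append(CopyNumberProfile(str(sid), *vecs))
    return Cohort(layout, profiles)


def read_bed(path) -> pd.DataFrame:
    """Regions of interest from a BED file (0-based half-open, as standard)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"][: 4],
        dtype={0: str},
    )
    if "name" not in df.columns or df["name"].isna().all():
        df["name"] = [f"region{i + 1}" for i in range(len(df))]
    df["name"] = df["name"].fillna("")
    return df[["chrom", "start", "end", "name"]]
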