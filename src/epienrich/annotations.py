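"""Binary genomic annotations from chromatin-state segmentations.

A chromatin-state segmentation (e.g. IDEAS) labels genome segments with
states such as ``10_TssA`` (active TSS) or ``4_Enh`` (enhancer).  Merging the
segments belonging to a chosen group of states yields a binary annotation of
"active" regulatory elements for a tissue; per-variant membership in that
annotation is the indicator a_jC entering the heritability-partitioning
model.  Coordinates follow the BED convention (0-based, half-open)
internally; variant positions are 1-based at I/O boundaries and converted
once at ingestion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Active promoter/enhancer state labels merged into the "active" annotation.
ACTIVE_STATES = frozenset(
    {"10_TssA", "8_TssAFlnk", "14_TssWk", "4_Enh", "6_EnhG", "17_EnhGA"}
)

#: Regulatory-element classes partitioning the active states.
CLASS_STATE_GROUPS: dict[str, frozenset[str]] = {
    "promoter": frozenset({"10_TssA", "8_TssAFlnk", "14_TssWk"}),
    "enhancer": frozenset({"4_Enh"}),
    "genic_enhancer": frozenset({"6_EnhG", "17_EnhGA"}),
}

#: Extended MHC region excluded from LD-score regression (GRCh37).
MHC_GRCH37 = ("6", 25_000_000, 34_000_000)
#: MHC region excluded before distance-based clumping (GRCh38).
MHC_GRCH38 = ("6", 28_510_120, 33_480_577)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end), optionally state-labelled."""

    chrom: str
    start: int
    end: int
    state: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """A named binary annotation: merged, disjoint intervals per chromosome.

    ``intervals`` maps chromosome label to an ``(k, 2)`` integer array of
    sorted, non-overlapping, non-adjacent ``[start, end)`` rows (maximally
    merged).  ``provenance`` records which state labels were merged.
    """

    name: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size:
                order = np.argsort(arr[:, 0], kind="stable")
                arr = arr[order]
                if np.any(arr[:, 0] >= arr[:, 1]) or np.any(arr[:, 0] < 0):
                    raise ValueError(f"invalid intervals on {chrom}")
                if np.any(arr[1:, 0] <= arr[:-1, 1]):
                    raise ValueError(
                        f"intervals on {chrom} overlap or touch; merge first"
                    )
            clean[chrom] = arr
        self.intervals = clean

    @property
    def total_length(self) -> int:
        """Total bases covered."""
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self.intervals.values())
        )

    @property
    def n_intervals(self) -> int:
        return int(sum(len(a) for a in self.intervals.values()))

    def to_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Maximally merge sorted intervals; adjacency counts as overlap."""
    if starts.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    out_s = [int(starts[0])]
    out_e = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.column_stack([out_s, out_e]).astype(np.int64)


def merge_intervals(
    intervals: Iterable[GenomicInterval], name: str = "merged",
    provenance: Sequence[str] = (),
) -> AnnotationSet:
    """Union a collection of intervals into a merged AnnotationSet."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        arr = np.asarray(sorted(ivs), dtype=np.int64)
        merged[chrom] = _merge_sorted(arr[:, 0], arr[:, 1])
    return AnnotationSet(name=name, intervals=merged,
                         provenance=tuple(provenance))


def merge_active_states(
    segmentation: Iterable[GenomicInterval],
    state_group: Iterable[str] = ACTIVE_STATES,
    name: str = "active",
) -> AnnotationSet:
    """Merge all segments whose state label is in ``state_group``.

    Returns the maximally merged set-theoretic union; unknown labels in
    ``state_group`` (absent from the segmentation) produce a warning only,
    since state vocabularies are dataset-dependent.
    """
    state_group = set(state_group)
    segmentation = list(segmentation)
    seen = {iv.state for iv in segmentation if iv.state is not None}
    unknown = state_group - seen
    if unknown and seen:
        warnings.warn(
            f"state labels not present in segmentation: {sorted(unknown)}",
            stacklevel=2,
        )
    picked = [iv for iv in segmentation if iv.state in state_group]
    return merge_intervals(picked, name=name,
                           provenance=tuple(sorted(state_group)))


def class_annotations(
    segmentation: Iterable[GenomicInterval],
    groups: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, AnnotationSet]:
    """Build the promoter / enhancer / genic-enhancer class annotations.

    The union of the three classes covers exactly the bases of the global
    active annotation (the class state groups partition the active states).
    """
    if groups is None:
        groups = CLASS_STATE_GROUPS
    segmentation = list(segmentation)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            cls: merge_active_states(segmentation, states, name=cls)
            for cls, states in groups.items()
        }


def annotate_variants(
    chroms: Sequence[str] | np.ndarray,
    positions_1based: Sequence[int] | np.ndarray,
    annotation: AnnotationSet,
) -> np.ndarray:
    """Binary membership of variants (1-based positions) in an annotation.

    A variant at 1-based position p is a member iff base p-1 (0-based) lies
    inside one of the annotation's half-open intervals.  Variants on
    chromosomes absent from the annotation get membership 0 (logged once).
    """
    chroms = np.asarray(chroms, dtype=object)
    pos0 = np.asarray(positions_1based, dtype=np.int64) - 1
    member = np.zeros(len(pos0), dtype=bool)
    missing: set[str] = set()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        arr = annotation.intervals.get(str(chrom))
        if arr is None or arr.size == 0:
            if arr is None:
                missing.add(str(chrom))
            continue
        # interval index whose start <= pos: searchsorted on starts
        idx = np.searchsorted(arr[:, 0], pos0[mask], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(mask.sum(), dtype=bool)
        inside[ok] = pos0[mask][ok] < arr[idx[ok], 1]
        member[mask] = inside
    if missing:
        logger.info(
            "%d chromosome(s) absent from annotation %r: %s",
            len(missing), annotation.name, sorted(missing),
        )
    return member


def exclude_region(
    chroms: Sequence[str] | np.ndarray,
    positions_1based: Sequence[int] | np.ndarray,
    region: tuple[str, int, int],
) -> np.ndarray:
    """Keep-mask for variants, dropping any inside ``region`` (half-open).

    ``region`` is (chrom, start, end) in 0-based half-open coordinates, e.g.
    the extended MHC locus.  Returns a boolean array, True = retained.
    """
    chrom, start, end = region
    chroms = np.asarray(chroms, dtype=object)
    pos0 = np.asarray(positions_1based, dtype=np.int64) - 1
    inside = (chroms == chrom) & (pos0 >= start) & (pos0 < end)
    n_removed = int(inside.sum())
    if n_removed:
        logger.info("excluded %d variant(s) in %s:%d-%d",
                    n_removed, chrom, start, end)
    return ~inside


def exclude_region_intervals(
    annotation: AnnotationSet, region: tuple[str, int, int]
) -> AnnotationSet:
    """Remove every interval intersecting ``region`` from an annotation."""
    chrom, start, end = region
    out: dict[str, np.ndarray] = {}
    for c, arr in annotation.intervals.items():
        if c != chrom or arr.size == 0:
            out[c] = arr
            continue
        keep = (arr[:, 1] <= start) | (arr[:, 0] >= end)
        out[c] = arr[keep]
    return AnnotationSet(name=annotation.name, intervals=out,
                         provenance=annotation.provenance)


# ---------------------------------------------------------------------------
# BED I/O

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED4 (column 4, if present, is the state label)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            state = parts[3] if len(parts) > 3 else None
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), state)
            )
    return out


def write_bed(path, intervals: Iterable[GenomicInterval] | AnnotationSet) -> None:
    """Write intervals as BED3 (or BED4 when state labels are present)."""
    if isinstance(intervals, AnnotationSet):
        intervals = intervals.to_intervals()
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.state is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.state}\n")
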