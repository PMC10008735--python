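"""Hierarchical annotation of collapsed 15-45 nt reads.

Reads are matched ungapped, full-length, forward-strand against the
reference via a 15-mer seed index with verification; tRNAs are matched
against their CCA-appended mature sequences.  Each read is assigned to the
first category in the priority order that contains a hit (miRNA first, so
mature miRNAs embedded in longer transcripts are never absorbed by broader
classes).  Ties across parents within the winning category split the read's
count equally; nested rRNA hits are collapsed to the most specific mature
subunit before tie-splitting, so nothing is ever counted under both 45S and
a subunit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import features as feat
from .fragments import REPORTED_GROUP, assign_rsrna_parent, classify_tsrna_subtype
from .reference import DEFAULT_PRIORITY, KMER, ReferenceSet

log = logging.getLogger(__name__)

MIN_LEN, MAX_LEN = 15, 45

#: Parent category -> fragment-class name used for composition reporting.
READ_CATEGORY = {
    "miRNA": "miRNA",
    "rRNA": "rsRNA",
    "YRNA": "ysRNA",
    "tRNA": "tsRNA",
    "mt_tRNA": "tsRNA",
    "piRNA": "piRNA",
    "other_ncRNA": "other_ncRNA",
    "spike_in": "spike_in",
}


@dataclass(frozen=True)
class ReadRecord:
    """A collapsed read: one distinct sequence with its multiplicity."""

    id: str
    sequence: str
    count: int = 1


@dataclass
class AnnotationRecord:
    """Assignment of one collapsed read to a category and its parents.

    ``hits`` are (parent_id, start, end) with 1-based inclusive coordinates
    (on the CCA-appended sequence for tRNAs); ``weight`` is the equal split
    across tied parents and ``hit_weights`` the per-parent share in count
    units (``count * weight``).
    """

    read_id: str
    count: int
    category: str
    hits: Tuple[Tuple[str, int, int], ...]
    mismatches: int
    weight: float

    @property
    def hit_weights(self) -> Tuple[float, ...]:
        return tuple(self.count * self.weight for _ in self.hits)

    @property
    def length(self) -> int:
        _, s, e = self.hits[0]
        return e - s + 1


def collapse_reads(sequences: Iterable[str]) -> List[ReadRecord]:
    """Length-filter to [15, 45] nt and collapse identical sequences.

    Reads containing non-ACGT characters are dropped with a logged warning.
    The sum of collapsed counts equals the number of reads passing filters.
    """
    counts: Dict[str, int] = {}
    dropped = 0
    acgt = set("ACGT")
    for seq in sequences:
        seq = seq.upper()
        if not MIN_LEN <= len(seq) <= MAX_LEN:
            continue
        if set(seq) - acgt:
            dropped += 1
            continue
        counts[seq] = counts.get(seq, 0) + 1
    if dropped:
        log.warning("dropped %d reads with non-ACGT characters", dropped)
    return [ReadRecord(f"u{i:06d}", seq, c)
            for i, (seq, c) in enumerate(counts.items(), start=1)]


class KmerIndex:
    """15-mer seed index over the reference (tRNAs CCA-appended)."""

    def __init__(self, ref: ReferenceSet, k: int = KMER):
        self.ref = ref
        self.k = k
        self.seqs: Dict[str, str] = {}
        self.index: Dict[str, List[Tuple[str, int]]] = {}
        for parent in sorted(ref, key=lambda p: p.id):
            seq = parent.sequence
            if parent.category in ("tRNA", "mt_tRNA"):
                seq = seq + "CCA"
            self.seqs[parent.id] = seq
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((parent.id, i))

    def hits(self, read: str, max_mismatch: int = 0
             ) -> Dict[str, Tuple[int, int, int]]:
        """Best ungapped full-length hit per parent: parent -> (start, end, mm).

        Coordinates are 1-based inclusive.  Seeds are taken from every exact
        15-mer window of the read, so with ``max_mismatch=1`` a hit is found
        whenever at least one window of the read is mismatch-free.
        """
        n = len(read)
        offsets = (0,) if max_mismatch == 0 else tuple(range(n - self.k + 1))
        best: Dict[str, Tuple[int, int, int]] = {}
        seen: set[Tuple[str, int]] = set()
        for off in offsets:
            for parent_id, pos in self.index.get(read[off : off + self.k], ()):
                start0 = pos - off
                if start0 < 0 or (parent_id, start0) in seen:
                    continue
                seen.add((parent_id, start0))
                ref_seq = self.seqs[parent_id]
                if start0 + n > len(ref_seq):
                    continue
                window = ref_seq[start0 : start0 + n]
                mm = sum(a != b for a, b in zip(read, window)) \
                    if window != read else 0
                if mm > max_mismatch:
                    continue
                prev = best.get(parent_id)
                if prev is None or (mm, start0) < (prev[2], prev[0] - 1):
                    best[parent_id] = (start0 + 1, start0 + n, mm)
        return best


def assign_category(
    read: ReadRecord,
    index: KmerIndex,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    max_mismatch: int = 0,
) -> Optional[AnnotationRecord]:
    """Assign a collapsed read to the first priority category with a hit."""
    hits = index.hits(read.sequence, max_mismatch=max_mismatch)
    if not hits:
        return None
    ref = index.ref
    by_cat: Dict[str, List[str]] = {}
    for pid in hits:
        by_cat.setdefault(ref[pid].category, []).append(pid)
    for category in priority:
        if category not in by_cat:
            continue
        parents = sorted(by_cat[category])
        if category == "rRNA" and len(parents) > 1:
            # Nesting consistency: collapse 45S + subunit to the subunit.
            parents = [assign_rsrna_parent(parents, ref)]
        chosen = tuple((pid, hits[pid][0], hits[pid][1]) for pid in parents)
        mm = max(hits[pid][2] for pid in parents)
        return AnnotationRecord(
            read_id=read.id, count=read.count,
            category=READ_CATEGORY[category],
            hits=chosen, mismatches=mm, weight=1.0 / len(parents),
        )
    return None  # pragma: no cover - priority covers all categories


def _feature_keys(rec: AnnotationRecord, ref: ReferenceSet,
                  rsrna_bins: Mapping[str, Sequence[Tuple[int, int]]]
                  ) -> List[Tuple[str, float]]:
    """Category-specific feature identities with per-feature count shares."""
    out: List[Tuple[str, float]] = []
    for (pid, start, end), w in zip(rec.hits, rec.hit_weights):
        parent = ref[pid]
        if rec.category == "rsRNA":
            label = feat.rsrna_bin_label(start, end, rsrna_bins.get(pid))
            key = feat.rsrna_feature(pid, label)
        elif rec.category == "tsRNA":
            group = REPORTED_GROUP[
                classify_tsrna_subtype(start, end, parent.body_length)]
            key = feat.tsrna_feature(parent.category, parent.subcategory, group)
        elif rec.category == "ysRNA":
            key = feat.ysrna_feature(pid, feat.ysrna_is_five_prime(start))
        else:
            key = pid
        out.append((key, w))
    return out


@dataclass
class LibraryAnnotation:
    """One sample's annotation result."""

    records: List[AnnotationRecord]
    unannotated: int
    feature_counts: pd.Series  # float counts (tie splits are fractional)
    feature_categories: pd.Series

    @property
    def mapped_total(self) -> float:
        return float(self.feature_counts.sum())

    def category_counts(self) -> pd.Series:
        return self.feature_counts.groupby(self.feature_categories).sum()


def annotate_library(
    reads: Sequence[ReadRecord],
    ref: ReferenceSet,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    max_mismatch: int = 0,
    rsrna_bins: Mapping[str, Sequence[Tuple[int, int]]] | None = None,
    index: KmerIndex | None = None,
) -> LibraryAnnotation:
    """Annotate a collapsed library into fragment-level feature counts.

    Conservation holds exactly: annotated + unannotated counts equal the
    total collapsed counts.  ``rsrna_bins`` maps rRNA parents to peak
    intervals used as counting bins (defaults to the bundled peak loci).
    """
    if rsrna_bins is None:
        rsrna_bins = feat.DEFAULT_RSRNA_PEAKS
    if index is None:
        index = KmerIndex(ref)
    if not reads:
        log.warning("empty library")
    missing = [c for c in (p.category for p in ref) if c not in priority]
    if missing:
        raise ValueError(f"priority does not cover categories: {sorted(set(missing))}")

    records: List[AnnotationRecord] = []
    unannotated = 0
    counts: Dict[str, float] = {}
    categories: Dict[str, str] = {}
    for read in reads:
        rec = assign_category(read, index, priority, max_mismatch)
        if rec is None:
            unannotated += read.count
            continue
        records.append(rec)
        for key, w in _feature_keys(rec, ref, rsrna_bins):
            counts[key] = counts.get(key, 0.0) + w
            categories[key] = rec.category
    keys = sorted(counts)
    return LibraryAnnotation(
        records=records,
        unannotated=unannotated,
        feature_counts=pd.Series([counts[k] for k in keys], index=keys,
                                 dtype=float),
        feature_categories=pd.Series([categories[k] for k in keys], index=keys),
    )


def compute_class_proportions(lib: LibraryAnnotation) -> Dict[str, float]:
    """Category fractions over annotated reads (sums to 1)."""
    cat = lib.category_counts()
    total = cat.sum()
    if total <= 0:
        raise ValueError("no annotated reads")
    return (cat / total).to_dict()


def rpm_normalize(counts, mapped_total: float):
    """Reads-per-million over mapped (annotated) reads."""
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / mapped_total


def length_distribution(records: Iterable[AnnotationRecord], category: str,
                        mapped_total: float) -> np.ndarray:
    """RPM-weighted read-length histogram over 15-45 nt (31 bins)."""
    if category not in set(READ_CATEGORY.values()):
        raise ValueError(f"unknown category {category!r}")
    hist = np.zeros(MAX_LEN - MIN_LEN + 1)
    for rec in records:
        if rec.category != category:
            continue
        hist[rec.length - MIN_LEN] += rec.count
    return rpm_normalize(hist, mapped_total)


# ---------------------------------------------------------------------------
# Count matrices


@dataclass
class CountMatrix:
    """Feature x sample counts with feature and sample metadata.

    ``counts`` holds float counts (tie splits are fractional); use
    :meth:`export_counts` for the rounded integer view (round-half-even,
    applied only at export) and :meth:`rpm` for the per-million view.
    """

    counts: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    @classmethod
    def from_libraries(cls, libraries: Mapping[str, LibraryAnnotation],
                       sample_meta: pd.DataFrame) -> "CountMatrix":
        counts = pd.DataFrame({s: lib.feature_counts
                               for s, lib in libraries.items()}).fillna(0.0)
        cats = {}
        for lib in libraries.values():
            cats.update(lib.feature_categories.to_dict())
        meta = pd.DataFrame({"category": pd.Series(cats)}).loc[counts.index]
        return cls(counts=counts.sort_index(), feature_meta=meta.sort_index(),
                   sample_meta=sample_meta)

    @property
    def mapped_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def export_counts(self) -> pd.DataFrame:
        return pd.DataFrame(np.rint(self.counts.to_numpy()).astype(np.int64),
                            index=self.counts.index, columns=self.counts.columns)

    def rpm(self) -> pd.DataFrame:
        return self.counts * 1e6 / self.mapped_totals


def write_annotation_bed(records: Iterable[AnnotationRecord], path) -> None:
    """Export annotation records as BED-like TSV.

    Coordinates are 0-based half-open in this export only (flagged in the
    header); everywhere else in the package they are 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED convention)\n")
        fh.write("parent\tstart\tend\tread_id\tcount\tcategory\n")
        for rec in records:
            for pid, s, e in rec.hits:
                fh.write(f"{pid}\t{s - 1}\t{e}\t{rec.read_id}\t{rec.count}\t"
                         f"{rec.category}\n")
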