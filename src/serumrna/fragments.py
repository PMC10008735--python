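"""Fragment-level characterization: tsRNA cleavage subtypes, nested rsRNA
parent assignment, positional coverage profiles, peak calling, and ysRNA /
tsRNA composition summaries.

tsRNA subtype calls use mature-tRNA coordinates with the CCA tail appended:
a fragment beginning within the first ``delta`` nt is a 5' fragment, one
reaching past the body into the tail is 3'CCA, one ending within ``delta``
of the 3' body end is 3', and everything else is an inner fragment.  The
boundary tolerance delta (default 3 nt) absorbs ragged cleavage ends while
keeping the inner class meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import features as feat
from .reference import ReferenceSet
from .simulate import SUBTYPE_3CCA, SUBTYPE_3P, SUBTYPE_5P, SUBTYPE_INNER

REPORTED_GROUP = {
    SUBTYPE_5P: feat.GROUP_5P,
    SUBTYPE_INNER: feat.GROUP_INNER,
    SUBTYPE_3P: feat.GROUP_3P,
    SUBTYPE_3CCA: feat.GROUP_3P,
}

MATURE_RRNAS = ("5S", "5.8S", "18S", "28S", "mt-12S", "mt-16S")


def classify_tsrna_subtype(start: int, end: int, body_length: int,
                           delta: int = 3) -> str:
    """Cleavage subtype of a tRNA fragment aligned at [start, end].

    Coordinates are 1-based inclusive on the CCA-appended mature tRNA of
    body length ``body_length`` (tail occupies positions body_length+1..+3).
    The rule partitions every valid span into exactly one of four subtypes.
    """
    L = body_length
    if not (1 <= start <= end <= L + 3):
        raise ValueError(f"span [{start},{end}] outside [1,{L + 3}]")
    if start <= delta:
        return SUBTYPE_5P
    if end >= L + 1:
        return SUBTYPE_3CCA
    if end >= L - delta + 1:
        return SUBTYPE_3P
    return SUBTYPE_INNER


def assign_rsrna_parent(parent_ids: Sequence[str], ref: ReferenceSet) -> str:
    """Most specific parent among nested rRNA hits.

    A read matching a mature subunit (which also matches the 45S precursor)
    is counted under the subunit; a read matching only precursor spacer
    sequence is counted under 45S.
    """
    if not parent_ids:
        raise ValueError("no rRNA hits to assign")
    for pid in parent_ids:
        if ref[pid].category != "rRNA":
            raise ValueError(f"{pid} is not an rRNA parent")
    mature = sorted(p for p in parent_ids if p in MATURE_RRNAS)
    if mature:
        return mature[0]
    return sorted(parent_ids)[0]


@dataclass
class CoverageProfile:
    """Per-position fragment depth along one parental RNA (1-based)."""

    parent_id: str
    depth: np.ndarray  # depth[i] = coverage at position i+1
    total_fragments: float

    @property
    def length(self) -> int:
        return len(self.depth)


@dataclass
class Peak:
    parent_id: str
    start: int
    end: int
    summit: int
    mean_height: float
    share: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def coverage_profile(annotations: Iterable, parent_id: str,
                     ref: ReferenceSet) -> CoverageProfile:
    """Accumulate weighted fragment depth on ``parent_id``.

    ``annotations`` yields records with ``hits`` (parent, start, end) and a
    per-hit ``weight`` in count units; only hits on the requested parent
    contribute.  Sum(depth) equals sum(fragment length x weight).
    """
    parent = ref[parent_id]
    length = parent.length + (3 if parent.category in ("tRNA", "mt_tRNA") else 0)
    diff = np.zeros(length + 1)
    total = 0.0
    for rec in annotations:
        for (pid, start, end), w in zip(rec.hits, rec.hit_weights):
            if pid != parent_id:
                continue
            diff[start - 1] += w
            diff[end] -= w
            total += w
    return CoverageProfile(parent_id, np.cumsum(diff[:-1]), total)


def detect_peaks(profile: CoverageProfile, threshold_frac: float = 0.25,
                 merge_gap: int = 10, min_width: int = 10) -> List[Peak]:
    """Call positional expression peaks on a coverage profile.

    Maximal runs of positions with depth >= threshold_frac x max depth;
    runs separated by fewer than ``merge_gap`` positions are merged and
    peaks narrower than ``min_width`` discarded.  Scaling the profile by any
    positive constant leaves the calls unchanged.
    """
    depth = profile.depth
    if depth.size == 0 or depth.max() <= 0:
        return []
    mask = depth >= threshold_frac * depth.max()
    runs: List[List[int]] = []
    for pos in np.flatnonzero(mask):
        if runs and pos - runs[-1][1] <= 1:
            runs[-1][1] = pos
        else:
            runs.append([pos, pos])
    merged: List[List[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    total = depth.sum()
    peaks = []
    for s0, e0 in merged:
        if e0 - s0 + 1 < min_width:
            continue
        segment = depth[s0 : e0 + 1]
        summit = s0 + int(np.argmax(segment))
        peaks.append(Peak(
            parent_id=profile.parent_id,
            start=s0 + 1, end=e0 + 1, summit=summit + 1,
            mean_height=float(segment.mean()),
            share=float(segment.sum() / total),
        ))
    return sorted(peaks, key=lambda p: p.start)


def _records_of_category(annotations: Iterable, category: str):
    return [rec for rec in annotations if rec.category == category]


def ysrna_composition(annotations: Iterable, ref: ReferenceSet) -> pd.DataFrame:
    """Per-YRNA-gene read fractions and the overall 5' fraction.

    Returns a frame indexed by gene with columns ``fraction`` and
    ``five_prime_fraction`` (per gene); the overall 5' share is stored in
    ``df.attrs['five_prime_fraction']``.  A fragment is 5' when it starts
    within the first 3 nt of the YRNA.
    """
    genes = sorted(p.id for p in ref.by_category("YRNA"))
    counts = {g: 0.0 for g in genes}
    five = {g: 0.0 for g in genes}
    for rec in _records_of_category(annotations, "ysRNA"):
        for (pid, start, _end), w in zip(rec.hits, rec.hit_weights):
            counts[pid] += w
            if feat.ysrna_is_five_prime(start):
                five[pid] += w
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no ysRNA reads")
    df = pd.DataFrame({
        "fraction": [counts[g] / total for g in genes],
        "five_prime_fraction": [five[g] / counts[g] if counts[g] else np.nan
                                for g in genes],
    }, index=pd.Index(genes, name="gene"))
    df.attrs["five_prime_fraction"] = sum(five.values()) / total
    return df


def tsrna_composition(annotations: Iterable, ref: ReferenceSet,
                      mapped_total: float) -> pd.DataFrame:
    """Anticodon x cleavage-group RPM table, split cytoplasmic vs mitochondrial.

    Rows are (kind, anticodon) with kind in {cyto, mt}; columns are the three
    reported groups.  Row sums equal the per-tRNA tsRNA RPM.
    """
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    rows: Dict[Tuple[str, str], Dict[str, float]] = {}
    for rec in annotations:
        if rec.category != "tsRNA":
            continue
        for (pid, start, end), w in zip(rec.hits, rec.hit_weights):
            parent = ref[pid]
            kind = "mt" if parent.category == "mt_tRNA" else "cyto"
            group = REPORTED_GROUP[
                classify_tsrna_subtype(start, end, parent.body_length)
            ]
            cell = rows.setdefault((kind, parent.subcategory),
                                   {g: 0.0 for g in feat.TSRNA_GROUPS})
            cell[group] += w * 1e6 / mapped_total
    if not rows:
        return pd.DataFrame(columns=list(feat.TSRNA_GROUPS))
    df = pd.DataFrame.from_dict(rows, orient="index")[list(feat.TSRNA_GROUPS)]
    df.index = pd.MultiIndex.from_tuples(df.index, names=["kind", "anticodon"])
    return df.sort_index()


def group_shares(composition: pd.DataFrame, kind: str) -> pd.Series:
    """Aggregate cleavage-group shares (fractions) for cyto or mt tsRNAs."""
    sub = composition.loc[kind]
    totals = sub.sum(axis=0)
    return totals / totals.sum()
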