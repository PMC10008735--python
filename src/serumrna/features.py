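"""Canonical fragment-level feature identities.

Counting happens at the level the field reports: mature miRNA ids, tsRNAs as
parent tRNA x cleavage group (5', inner', 3'+3'CCA combined), rsRNAs as
parent rRNA x positional peak bin (e.g. ``rsRNA-18S#3``) or background, and
ysRNAs as YRNA gene x 5'/3' end.  The simulator and the annotation engine
share these constructors so ground truth and recovered counts are directly
comparable.
"""

from __future__ import annotations

from typing import Sequence, Tuple

GROUP_5P = "5p"
GROUP_INNER = "inner"
GROUP_3P = "3p"  # 3' and 3'CCA combined, as reported
TSRNA_GROUPS = (GROUP_5P, GROUP_INNER, GROUP_3P)

#: Printed rsRNA expression-peak intervals (1-based inclusive) used both as
#: the simulator's planted loci and as the default counting bins.
DEFAULT_RSRNA_PEAKS = {
    "18S": [(674, 692), (897, 919), (1194, 1223), (1838, 1862)],
    "28S": [(1336, 1355), (1963, 1982), (2895, 2920)],
}


def mirna_feature(parent_id: str) -> str:
    return parent_id


def tsrna_feature(parent_category: str, anticodon: str, group: str) -> str:
    prefix = "mt-tsRNA" if parent_category == "mt_tRNA" else "tsRNA"
    return f"{prefix}-{anticodon}-{group}"


def ysrna_feature(gene: str, five_prime: bool) -> str:
    return f"ysRNA-{gene}-{GROUP_5P if five_prime else GROUP_3P}"


def rsrna_feature(parent_id: str, bin_label: str | None) -> str:
    if bin_label is None:
        return f"rsRNA-{parent_id}"
    return f"rsRNA-{parent_id}{bin_label}"


def rsrna_bin_label(
    start: int, end: int, peaks: Sequence[Tuple[int, int]] | None
) -> str | None:
    """Peak bin for a fragment: ``#i`` when >= half the read overlaps peak i.

    Parents without a peak model get a single parent-level feature (None).
    """
    if peaks is None:
        return None
    read_len = end - start + 1
    for i, (ps, pe) in enumerate(peaks, start=1):
        overlap = min(end, pe) - max(start, ps) + 1
        if overlap * 2 >= read_len:
            return f"#{i}"
    return "-bg"


def ysrna_is_five_prime(start: int) -> bool:
    """A YRNA fragment is 5' when it starts within the first 3 nt."""
    return start <= 3
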