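"""Synthetic parental-RNA reference set for circulating small-RNA analysis.

The reference mimics the databases a serum small-RNA annotation pipeline
aligns against -- mature miRNAs, nuclear and mitochondrial rRNAs (with the
45S precursor nesting 18S/5.8S/28S), the four YRNA genes, cytoplasmic and
mitochondrial tRNAs, piRNAs, a handful of other ncRNAs and the exogenous
cel-miR-39 spike-in.  Sequences are random under a uniform base model with
15-mer-uniqueness rejection sampling, so every read of >= 15 nt maps to
exactly one category (the deliberate 45S superset being the only exception).
That property is what turns annotation into an exact parameter-recovery
exercise against the simulator's ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Tuple

import numpy as np

log = logging.getLogger(__name__)

KMER = 15

CATEGORIES = (
    "miRNA",
    "rRNA",
    "YRNA",
    "tRNA",
    "mt_tRNA",
    "piRNA",
    "other_ncRNA",
    "spike_in",
)

#: Hierarchical matching order: mature miRNAs claim reads first so that a
#: miRNA embedded in a longer transcript is never absorbed by a broader class.
DEFAULT_PRIORITY = (
    "miRNA",
    "rRNA",
    "YRNA",
    "tRNA",
    "mt_tRNA",
    "piRNA",
    "other_ncRNA",
    "spike_in",
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Cytoplasmic tRNA isodecoders carried by the default reference.  The list
# deliberately covers the anticodons that recur in serum tsRNA work
# (Gly-GCC, Ala-TGC, the Leu/Lys isoacceptors, ...).
CYTO_TRNAS = (
    "Ala-TGC", "Gly-CCC", "Gly-GCC", "Leu-CAG", "Leu-CAA",
    "Lys-TTT", "Lys-CTT", "Glu-CTC", "Glu-TTC", "Ser-AGA",
    "Ser-GCT", "Arg-CCT", "Arg-TCT", "Val-CAC", "Val-AAC",
    "Cys-GCA", "Thr-AGT", "Asp-GTC", "His-GTG", "Gln-CTG",
)
MT_TRNAS = ("Leu-TAA", "Ser-TGA", "Lys-TTT", "Met-CAT", "His-GTG")

SPIKE_IN_ID = "cel-miR-39"

# YRNA gene lengths (nt), all inside the canonical 83-113 nt range.
YRNA_LENGTHS = {"RNY1": 112, "RNY3": 102, "RNY4": 96, "RNY5": 83}

RRNA_LENGTHS = {
    "18S": 1880,
    "28S": 2930,
    "5S": 121,
    "5.8S": 157,
    "mt-12S": 954,
    "mt-16S": 1559,
}
# 45S external/internal transcribed spacer lengths: 5'ETS, ITS1, ITS2, 3'ETS.
SPACERS = (100, 80, 80, 60)


@dataclass(frozen=True)
class ParentRNA:
    """A parental RNA a circulating fragment can derive from."""

    id: str
    category: str
    subcategory: str
    sequence: str
    cca_appended: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.id}: sequence alphabet must be ACGT")
        if len(self.sequence) < KMER:
            raise ValueError(f"{self.id}: parent shorter than {KMER} nt")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def body_length(self) -> int:
        """Length excluding a post-transcriptionally appended CCA tail."""
        return self.length - 3 if self.cca_appended else self.length


def append_cca(trna: ParentRNA) -> ParentRNA:
    """Return a copy of a tRNA with the mature CCA tail appended.

    The rule is unconditional: a genomically CCA-ending tRNA still receives
    the tail, because mature coordinates count the appended copy.  Appending
    twice is an error.
    """
    if trna.category not in ("tRNA", "mt_tRNA"):
        raise ValueError("CCA appending applies to tRNA/mt_tRNA only")
    if trna.cca_appended:
        raise ValueError(f"{trna.id}: CCA tail already appended")
    return replace(trna, sequence=trna.sequence + "CCA", cca_appended=True)


@dataclass
class ReferenceSet:
    """Container of parental RNAs plus the 45S nesting map.

    ``nested`` maps a precursor id to ``[(child_id, start, end)]`` with
    1-based inclusive coordinates of the mature subunit inside the precursor.
    """

    parents: Dict[str, ParentRNA]
    nested: Dict[str, List[Tuple[str, int, int]]] = field(default_factory=dict)
    seed: int | None = None

    def __getitem__(self, parent_id: str) -> ParentRNA:
        return self.parents[parent_id]

    def __contains__(self, parent_id: str) -> bool:
        return parent_id in self.parents

    def __iter__(self):
        return iter(self.parents.values())

    def by_category(self, category: str) -> List[ParentRNA]:
        return [p for p in self.parents.values() if p.category == category]

    def spacer_regions(self, precursor_id: str) -> List[Tuple[int, int]]:
        """1-based inclusive intervals of a precursor not covered by subunits."""
        prec = self.parents[precursor_id]
        covered = sorted((s, e) for _, s, e in self.nested.get(precursor_id, []))
        regions, cursor = [], 1
        for s, e in covered:
            if s > cursor:
                regions.append((cursor, s - 1))
            cursor = e + 1
        if cursor <= prec.length:
            regions.append((cursor, prec.length))
        return regions


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _kmers(seq: str) -> Iterable[str]:
    for i in range(len(seq) - KMER + 1):
        yield seq[i : i + KMER]


class _UniqueSeqFactory:
    """Rejection-samples random sequences whose 15-mers are globally fresh."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.seen: set[str] = set()

    def register(self, seq: str) -> None:
        self.seen.update(_kmers(seq))

    def fresh(self, length: int, max_tries: int = 200) -> str:
        for _ in range(max_tries):
            seq = _random_seq(self.rng, length)
            kmers = set(_kmers(seq))
            # Reject internal repeats too: keeps every 15-mer single-copy.
            if len(kmers) == length - KMER + 1 and not (kmers & self.seen):
                self.seen |= kmers
                return seq
        raise RuntimeError("could not generate a k-mer-unique sequence")


def build_default_reference(seed: int) -> ReferenceSet:
    """Generate the bundled mini reference set (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    factory = _UniqueSeqFactory(rng)
    parents: Dict[str, ParentRNA] = {}

    def add(pid: str, category: str, subcategory: str, seq: str) -> None:
        if pid in parents:
            raise ValueError(f"duplicate parent id {pid}")
        parents[pid] = ParentRNA(pid, category, subcategory, seq)

    # Nuclear + mitochondrial rRNAs.
    rrna_seqs = {name: factory.fresh(n) for name, n in RRNA_LENGTHS.items()}
    for name, seq in rrna_seqs.items():
        add(name, "rRNA", name, seq)

    # 45S precursor: 5'ETS + 18S + ITS1 + 5.8S + ITS2 + 28S + 3'ETS.  Spacer
    # k-mers (including the junction windows) must be fresh; subunit-internal
    # windows are the sanctioned nesting exception.
    order = ("18S", "5.8S", "28S")
    for _ in range(200):
        spacers = [_random_seq(rng, n) for n in SPACERS]
        seq45 = (
            spacers[0] + rrna_seqs["18S"] + spacers[1]
            + rrna_seqs["5.8S"] + spacers[2] + rrna_seqs["28S"] + spacers[3]
        )
        offsets, cursor = [], 0
        for sp, sub in zip(spacers[:3], order):
            cursor += len(sp)
            offsets.append((sub, cursor + 1, cursor + len(rrna_seqs[sub])))
            cursor += len(rrna_seqs[sub])
        inside = np.zeros(len(seq45), dtype=bool)
        for _, s, e in offsets:
            inside[s - 1 : e] = True
        new_kmers = set()
        ok = True
        for i in range(len(seq45) - KMER + 1):
            if inside[i : i + KMER].all():
                continue  # window fully inside a mature subunit
            km = seq45[i : i + KMER]
            if km in factory.seen or km in new_kmers:
                ok = False
                break
            new_kmers.add(km)
        if ok:
            factory.seen |= new_kmers
            add("45S", "rRNA", "45S", seq45)
            nested = {"45S": offsets}
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not assemble a k-mer-clean 45S precursor")

    # YRNA genes.
    for gene, n in YRNA_LENGTHS.items():
        add(gene, "YRNA", gene, factory.fresh(n))

    # tRNAs, labelled amino-acid/anticodon; bodies 70-77 nt.
    for anticodon in CYTO_TRNAS:
        add(f"tRNA-{anticodon}", "tRNA", anticodon,
            factory.fresh(int(rng.integers(70, 78))))
    for anticodon in MT_TRNAS:
        add(f"mt-tRNA-{anticodon}", "mt_tRNA", anticodon,
            factory.fresh(int(rng.integers(66, 74))))

    # Mature miRNAs (19-25 nt); three serum classics plus synthetic fill.
    mirna_ids = ["mir-451a", "mir-320a", "mir-146a"] + [
        f"mir-s{i:03d}" for i in range(1, 48)
    ]
    for mid in mirna_ids:
        add(mid, "miRNA", mid, factory.fresh(int(rng.integers(19, 26))))

    # piRNAs (26-32 nt).
    for i in range(1, 21):
        add(f"piR-s{i:03d}", "piRNA", f"piR-s{i:03d}",
            factory.fresh(int(rng.integers(26, 33))))

    # A few other ncRNAs (sn/sno/linc/antisense stand-ins).
    for oid, n in (("snRNA-U1", 164), ("snRNA-U2", 188), ("snoRNA-s1", 134),
                   ("snoRNA-s2", 121), ("lincRNA-s1", 240), ("antisense-s1", 180)):
        add(oid, "other_ncRNA", oid, factory.fresh(n))

    # Exogenous spike-in (cel-miR-39-like, 22 nt).
    add(SPIKE_IN_ID, "spike_in", SPIKE_IN_ID, factory.fresh(22))

    return ReferenceSet(parents=parents, nested=nested, seed=seed)


# ---------------------------------------------------------------------------
# I/O


def write_reference_fasta(ref: ReferenceSet, fasta_path, table_path=None) -> None:
    """Write the reference as FASTA plus a TSV annotation table."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=f"{p.category} {p.subcategory}")
        for p in ref
    ]
    with open(fasta_path, "w") as fh:
        seqio_write(records, fh, "fasta")
    if table_path is not None:
        with open(table_path, "w") as fh:
            fh.write("id\tcategory\tsubcategory\tlength\n")
            for p in ref:
                fh.write(f"{p.id}\t{p.category}\t{p.subcategory}\t{p.length}\n")


def read_reference_fasta(fasta_path, table_path) -> ReferenceSet:
    """Load a reference from FASTA + annotation table (no nesting map)."""
    from Bio.SeqIO import parse as seqio_parse

    meta: Dict[str, Tuple[str, str]] = {}
    with open(table_path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError("annotation table must start with an 'id' header")
        for line in fh:
            pid, category, subcategory, _ = line.rstrip("\n").split("\t")
            meta[pid] = (category, subcategory)
    parents = {}
    for rec in seqio_parse(str(fasta_path), "fasta"):
        category, subcategory = meta[rec.id]
        parents[rec.id] = ParentRNA(rec.id, category, subcategory, str(rec.seq).upper())
    return ReferenceSet(parents=parents)
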