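"""Readers and writers for reads, truth tables and stage outputs."""

from __future__ import annotations

import gzip
import hashlib
import json
from typing import Iterator, Mapping, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path) -> Iterator[Tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, optionally gzipped."""
    path = str(path)
    fmt = "fastq" if path.rstrip(".gz").endswith(("fastq", "fq")) else "fasta"
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


def write_reads(truth: pd.DataFrame, path, fmt: str = "fasta") -> None:
    """Write simulated reads (truth table rows) as FASTA or gzipped FASTQ.

    FASTQ qualities are a constant 'I' per base; simulated reads carry no
    error model beyond the optional substitution noise.
    """
    records = [
        SeqRecord(Seq(row.sequence), id=row.read_id, description="")
        for row in truth.itertuples()
    ]
    if fmt == "fasta":
        with _open_text(path, "wt") as fh:
            SeqIO.write(records, fh, "fasta")
    elif fmt == "fastq":
        for rec in records:
            rec.letter_annotations["phred_quality"] = [40] * len(rec.seq)
        with _open_text(path, "wt") as fh:
            SeqIO.write(records, fh, "fastq")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def provenance_header(seed, config_hash: str) -> str:
    return f"# serumrna {__version__} | seed={seed} | config={config_hash}\n"


def write_tsv(df: pd.DataFrame, path, seed=None, config_hash: str = "-",
              index: bool = True) -> None:
    """Write a stage table as TSV with a provenance comment line."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config_hash))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def write_json(obj, path, seed=None, config_hash: str = "-") -> None:
    payload = {"_provenance": {"tool": f"serumrna {__version__}",
                               "seed": seed, "config": config_hash}}
    payload.update(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
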