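"""Format readers/writers shared across the package.

FASTA/FASTQ go through Biopython; the minimal VCF (CHROM POS ID REF ALT)
and the TSV tables are deliberately header-light plain text.  All readers
are transparent to gzip (by file extension) and tolerant of Windows line
endings.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("hairpincode")

PHRED_OFFSET = 33


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class FastqRecord(NamedTuple):
    """One FASTQ record; ``desc`` is the title text after the first token."""

    id: str
    seq: str
    quals: Tuple[int, ...]
    desc: str = ""

    @property
    def qual_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.quals)


def read_fasta(path) -> Dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(references: Dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in references.items()]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path) -> Iterator[FastqRecord]:
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            name, _, desc = title.partition(" ")
            quals = tuple(ord(c) - PHRED_OFFSET for c in qual)
            yield FastqRecord(name, seq.upper(), quals, desc)


def read_fastq_paired(r1_path, r2_path) -> Iterator[Tuple[FastqRecord, FastqRecord]]:
    """Iterate matched read pairs; raises naming the first offending record."""
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    idx = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = r1_path if r1 is None else r2_path
            raise ValueError(f"truncated FASTQ pairing: {short} ends at record {idx}")
        if _strip_mate(r1.id) != _strip_mate(r2.id):
            raise ValueError(
                f"read id mismatch at record {idx}: {r1.id!r} vs {r2.id!r}")
        yield r1, r2
        idx += 1


def _strip_mate(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def write_fastq(records: Iterable[FastqRecord], path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            title = f"{rec.id} {rec.desc}".rstrip()
            fh.write(f"@{title}\n{rec.seq}\n+\n{rec.qual_string}\n")
            n += 1
    return n


# -- minimal VCF (CHROM POS ID REF ALT) --------------------------------------

VCF_HEADER = ("##fileformat=VCFv4.2\n"
              "#CHROM\tPOS\tID\tREF\tALT\n")


def write_vcf_minimal(variants: pd.DataFrame, path) -> None:
    """Write a minimal VCF; POS is emitted 1-based from 0-based ``pos``."""
    with _open_text(path, "wt") as fh:
        fh.write(VCF_HEADER)
        for row in variants.itertuples(index=False):
            vid = getattr(row, "id", ".") or "."
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{vid}\t{row.ref}\t{row.alt}\n")


def read_vcf_minimal(path) -> pd.DataFrame:
    """Read CHROM/POS/ID/REF/ALT; multi-allelic or non-SNP rows are skipped.

    Returns 0-based ``pos``.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: malformed VCF row")
            chrom, pos, vid, ref, alt = parts[:5]
            if "," in alt:
                warnings.warn(f"{path}:{lineno}: multi-allelic site skipped")
                continue
            if len(ref) != 1 or len(alt) != 1:
                warnings.warn(f"{path}:{lineno}: non-SNP row skipped")
                continue
            rows.append((chrom, int(pos) - 1, vid, ref.upper(), alt.upper()))
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])


# -- TSV tables ---------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


# -- run configuration --------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration for a simulate/resolve run."""

    model: str = "five_letter"
    seed: int = 1
    hairpin: str = ""
    failure_threshold: float = 0.05
    n_fragments: int = 1000
    read_length: int = 100
    fragment_length: int = 100
    fragment_length_dist: str = "fixed"   # fixed | normal | cfdna_bimodal
    min_coverage: int = 3
    min_reads_per_allele: int = 6
    min_nominal_q: int = 25
    scoring: Dict[str, float] = field(default_factory=dict)
    conversion: Dict[str, float] = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with _open_text(path, "wt") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with _open_text(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
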