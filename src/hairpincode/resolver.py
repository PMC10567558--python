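"""End-to-end read-pair resolution.

Pipeline per pair: trim hairpin read-through on both arms, complement read 2
into copy-strand space, align the arms, decode the aligned columns, then
apply the unexpected-pairing filter: pairs with more than
``failure_threshold`` (default 5%) unexpected base pairings did not derive
from a hairpin-connected original/copy construct and are discarded.

Resolved per-position quality is the minimum of the two arm qualities
(capped at 60); masked columns (gaps, nonpermissible pairs, instrument N)
get quality 2.  The modification track travels in the FASTQ description as
an ``XM:Z:`` tag with one character per position (``.`` none, ``m`` 5mC,
``h`` 5hmC, ``M`` modC of unresolved subtype), convertible to a SAM
``MM``-style summary downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from . import io as hio
from .align import (AlignScoring, align_arms, find_hairpin_offset,
                    reverse_complement, transform_read2,
                    trim_hairpin_readthrough)
from .codec import GAP, DecodingModel, resolve_columns

MASKED_QUAL = 2
MAX_QUAL = 60


def deaminate(seq: str) -> str:
    """C->T conversion of an unprotected sequence (as the hairpin is read)."""
    return seq.upper().replace("C", "T")


@dataclass(frozen=True)
class ResolverParams:
    """Parameters of the resolution pipeline."""

    scoring: AlignScoring = field(default_factory=AlignScoring)
    hairpin: str = ""
    failure_threshold: float = 0.05
    trim_max_mismatches: int = 1
    trim_min_overlap: int = 4


@dataclass
class ResolvedRead:
    """A decoded single-end read over {A,C,G,T,N} with modification track."""

    read_id: str
    sequence: str
    mod_track: str           # one tag char per position: . m h M
    quals: List[int]
    unexpected_fraction: float
    passed: bool
    n_columns: int = 0
    fail_reason: str = ""

    def to_fastq_record(self) -> hio.FastqRecord:
        return hio.FastqRecord(self.read_id, self.sequence, tuple(self.quals),
                               desc=f"XM:Z:{self.mod_track}")

    @classmethod
    def from_fastq_record(cls, rec: hio.FastqRecord) -> "ResolvedRead":
        track = "." * len(rec.seq)
        for token in rec.desc.split():
            if token.startswith("XM:Z:"):
                track = token[5:]
        return cls(rec.id, rec.seq, track, list(rec.quals), 0.0, True,
                   n_columns=len(rec.seq))


@dataclass
class ResolutionStats:
    """Run-level tallies of the resolution pipeline."""

    n_pairs_in: int = 0
    n_resolved: int = 0
    n_filtered: int = 0
    n_columns: int = 0
    n_unexpected_columns: int = 0
    n_masked_positions: int = 0
    fail_reasons: Dict[str, int] = field(default_factory=dict)

    @property
    def resolution_rate(self) -> float:
        return self.n_resolved / self.n_pairs_in if self.n_pairs_in else 0.0

    def to_dataframe(self):
        import pandas as pd
        rows = [("n_pairs_in", self.n_pairs_in),
                ("n_resolved", self.n_resolved),
                ("n_filtered", self.n_filtered),
                ("resolution_rate", self.resolution_rate),
                ("n_columns", self.n_columns),
                ("n_unexpected_columns", self.n_unexpected_columns),
                ("n_masked_positions", self.n_masked_positions)]
        rows += [(f"filtered_{k}", v) for k, v in sorted(self.fail_reasons.items())]
        return pd.DataFrame(rows, columns=["metric", "value"])


def resolve_read_pair(r1: hio.FastqRecord, r2: hio.FastqRecord,
                      model: DecodingModel,
                      params: Optional[ResolverParams] = None) -> ResolvedRead:
    """Resolve one read pair into a single-end decoded read."""
    params = params or ResolverParams()
    if hio._strip_mate(r1.id) != hio._strip_mate(r2.id):
        raise ValueError(f"read id mismatch: {r1.id!r} vs {r2.id!r}")

    # Pair-aware hairpin trimming: both arms read through at the same
    # offset (the fragment length), so a full-window hit in either read is
    # trusted for both, while a short suffix hit (which can arise by
    # chance) is honored only when the mate shows it at the same offset.
    hp = deaminate(params.hairpin)
    hit1 = find_hairpin_offset(r1.seq, hp, params.trim_max_mismatches,
                               params.trim_min_overlap)
    hit2 = find_hairpin_offset(r2.seq, reverse_complement(hp),
                               params.trim_max_mismatches,
                               params.trim_min_overlap)
    cut = None
    if hit1 is not None and hit1[1]:
        cut = hit1[0]
    elif hit2 is not None and hit2[1]:
        cut = hit2[0]
    elif hit1 is not None and hit2 is not None and hit1[0] == hit2[0]:
        cut = hit1[0]
    s1, q1 = r1.seq.upper(), list(r1.quals)
    s2, q2 = r2.seq.upper(), list(r2.quals)
    if cut is not None:
        s1, q1 = s1[:cut], q1[:cut]
        s2, q2 = s2[:cut], q2[:cut]
    if not s1 or not s2:
        return ResolvedRead(r1.id, "", "", [], 1.0, False,
                            fail_reason="empty_after_trimming")

    aln = align_arms(s1, q1, transform_read2(s2), q2, model, params.scoring)
    res = resolve_columns(aln.columns, model)

    quals: List[int] = []
    for col, base in zip(aln.columns, res.bases):
        if base == "N" or col.orig_base == GAP or col.copy_base == GAP:
            quals.append(MASKED_QUAL)
        else:
            quals.append(min(col.orig_qual, col.copy_qual, MAX_QUAL))

    frac = res.unexpected_fraction
    passed = frac <= params.failure_threshold
    return ResolvedRead(r1.id, res.bases, res.mod_track, quals, frac, passed,
                        n_columns=res.n_columns,
                        fail_reason="" if passed else "unexpected_pairing")


def resolve_pairs(pairs: Iterable[Tuple[hio.FastqRecord, hio.FastqRecord]],
                  model: DecodingModel,
                  params: Optional[ResolverParams] = None,
                  stats: Optional[ResolutionStats] = None
                  ) -> Iterator[ResolvedRead]:
    """Resolve an in-memory stream of pairs, yielding every ResolvedRead
    (passing and failing) while accumulating ``stats``."""
    params = params or ResolverParams()
    for r1, r2 in pairs:
        rr = resolve_read_pair(r1, r2, model, params)
        if stats is not None:
            stats.n_pairs_in += 1
            stats.n_columns += rr.n_columns
            stats.n_unexpected_columns += round(rr.unexpected_fraction * rr.n_columns)
            stats.n_masked_positions += rr.sequence.count("N")
            if rr.passed:
                stats.n_resolved += 1
            else:
                stats.n_filtered += 1
                stats.fail_reasons[rr.fail_reason] = \
                    stats.fail_reasons.get(rr.fail_reason, 0) + 1
        yield rr


def resolve_fastq(r1_path, r2_path, model: DecodingModel,
                  params: Optional[ResolverParams] = None,
                  out_fastq=None, stats_tsv=None
                  ) -> Tuple[List[ResolvedRead], ResolutionStats]:
    """Resolve a paired FASTQ file set.

    Writes one single-end record per passing pair to ``out_fastq`` (if
    given) with the modification track in the description, and the stats
    table to ``stats_tsv``.  Returns the passing reads and the stats.
    """
    stats = ResolutionStats()
    passing: List[ResolvedRead] = []
    for rr in resolve_pairs(hio.read_fastq_paired(r1_path, r2_path),
                            model, params, stats):
        if rr.passed:
            passing.append(rr)
    if out_fastq is not None:
        hio.write_fastq((rr.to_fastq_record() for rr in passing), out_fastq)
    if stats_tsv is not None:
        hio.write_tsv(stats.to_dataframe(), stats_tsv)
    hio.logger.info("resolved %d/%d pairs (%.2f%%)", stats.n_resolved,
                    stats.n_pairs_in, 100.0 * stats.resolution_rate)
    return passing, stats
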