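"""Site-level methylation quantification and accuracy statistics.

Aggregates placed resolved reads into per-site counts of modification
calls (CpG/CHG/CHH contexts), and computes the accuracy statistics used to
benchmark the decoding: sensitivity and specificity on the methylated /
unmethylated controls, the 3x3 call-rate matrix for six-letter data, the
empirical Phred table (stratified by called base and nominal quality) and
genetic accuracy, plus between-table comparison summaries (Pearson r,
Bland-Altman median difference and 2.5/97.5 percentiles).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as hio
from .align import complement, reverse_complement
from .resolver import ResolvedRead
from .simulate import Methylome, SimTruth, cytosine_context
from .simulate import STATE_5HMC, STATE_5MC, STATE_UNMOD

MAX_EMPIRICAL_Q = 60

#: Row/column order of the call-rate matrix.
CALL_STATES = (STATE_UNMOD, STATE_5MC, STATE_5HMC)

_TAG_TO_STATE = {".": STATE_UNMOD, "m": STATE_5MC, "h": STATE_5HMC}


@dataclass
class PlacedRead:
    """A resolved read with its placement on a reference.

    ``sequence``/``mod_track`` stay in fragment (read) orientation; for a
    minus-strand placement read position ``j`` maps to reference position
    ``end - 1 - j`` and the read base is the complement of the
    reference-strand base.
    """

    read: ResolvedRead
    chrom: str
    start: int
    end: int
    strand: str

    def ref_pos(self, j: int) -> int:
        return self.start + j if self.strand == "+" else self.end - 1 - j


def placements_from_truth(reads: Iterable[ResolvedRead],
                          truth: SimTruth) -> List[PlacedRead]:
    """Place resolved reads using the simulator's ground-truth table."""
    frag_ix = truth.fragments.set_index("frag_id")
    read_ix = truth.reads.set_index("read_id")
    placed = []
    for rr in reads:
        frag_id = read_ix.at[rr.read_id, "frag_id"]
        row = frag_ix.loc[frag_id]
        placed.append(PlacedRead(rr, row["chrom"], int(row["start"]),
                                 int(row["end"]), row["strand"]))
    return placed


def read_sam_minimal(path, tag: str = "XM") -> List[PlacedRead]:
    """Read placements of externally aligned resolved reads from SAM.

    Only QNAME/FLAG/RNAME/POS/CIGAR/SEQ and the per-position modification
    track tag are used; soft clips are honored; reads with indels or
    without the tag are skipped with a warning.
    """
    import pysam

    placed: List[PlacedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            ops = {op for op, _ in (rec.cigartuples or [])}
            if ops - {0, 4, 7, 8}:  # only M/S/=/X supported
                warnings.warn(f"{rec.query_name}: indel CIGAR skipped")
                continue
            try:
                track = rec.get_tag(tag)
            except KeyError:
                warnings.warn(f"{rec.query_name}: no {tag} tag, skipped")
                continue
            seq = rec.query_sequence
            left = rec.cigartuples[0][1] if rec.cigartuples[0][0] == 4 else 0
            right = rec.cigartuples[-1][1] if rec.cigartuples[-1][0] == 4 else 0
            core = seq[left:len(seq) - right or None]
            track_core = track[left:len(track) - right or None]
            quals = list(rec.query_qualities[left:len(seq) - right or None]
                         if rec.query_qualities is not None
                         else [30] * len(core))
            start, end = rec.reference_start, rec.reference_start + len(core)
            if rec.is_reverse:
                core = reverse_complement(core)
                track_core = track_core[::-1]
                quals = quals[::-1]
            rr = ResolvedRead(rec.query_name, core, track_core, quals,
                              0.0, True, n_columns=len(core))
            placed.append(PlacedRead(rr, rec.reference_name, start, end,
                                     "-" if rec.is_reverse else "+"))
    return placed


def pileup_methylation(placed: Sequence[PlacedRead],
                       references: Dict[str, str],
                       min_coverage: int = 3,
                       pool_cpg: bool = False) -> pd.DataFrame:
    """Per-site methylation counts over all positions called as C.

    Returns one row per (chrom, pos, strand) with context, per-state
    counts, coverage, the modified fraction, and a ``pass_coverage`` flag
    (default threshold 3 reads).  With ``pool_cpg`` the two strands of
    each CpG unit are pooled onto the plus-strand C coordinate.
    """
    counts: Dict[Tuple[str, int, str], List[int]] = {}
    tag_index = {".": 0, "m": 1, "h": 2, "M": 3}  # unmod, 5mC, 5hmC, unknown
    for pr in placed:
        seq = pr.read.sequence
        track = pr.read.mod_track
        for j, base in enumerate(seq):
            if base != "C":
                continue
            key = (pr.chrom, pr.ref_pos(j), pr.strand)
            c = counts.setdefault(key, [0, 0, 0, 0])
            c[tag_index[track[j]]] += 1

    rows = []
    for (chrom, pos, strand), (n_unmod, n_5mc, n_5hmc, n_unknown) in counts.items():
        ref = references.get(chrom)
        if ref is None:
            raise ValueError(f"read placed on unknown reference {chrom!r}")
        if not 0 <= pos < len(ref):
            raise ValueError(f"placement outside {chrom!r}: position {pos}")
        refbase = ref[pos] if strand == "+" else complement(ref[pos])
        if refbase == "N":
            continue
        ctx = cytosine_context(ref, pos, strand) if refbase == "C" else "nonC"
        rows.append((chrom, pos, strand, ctx, n_unmod, n_5mc, n_5hmc, n_unknown))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "n_unmod", "n_5mC", "n_5hmC",
                                     "n_modC_unknown"])
    if pool_cpg and not df.empty:
        df = _pool_cpg_strands(df)
    df["n_mod"] = df["n_5mC"] + df["n_5hmC"] + df["n_modC_unknown"]
    df["coverage"] = df["n_mod"] + df["n_unmod"]
    df["fraction_mod"] = df["n_mod"] / df["coverage"]
    df["pass_coverage"] = df["coverage"] >= min_coverage
    return df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def _pool_cpg_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Pool CpG counts across strands onto the plus-strand C coordinate."""
    df = df.copy()
    unit_pos = df["pos"].where(~((df["context"] == "CpG") &
                                 (df["strand"] == "-")), df["pos"] - 1)
    df["pos"] = unit_pos
    df["strand"] = np.where(df["context"] == "CpG", ".", df["strand"])
    agg = df.groupby(["chrom", "pos", "strand", "context"], as_index=False)[
        ["n_unmod", "n_5mC", "n_5hmC", "n_modC_unknown"]].sum()
    return agg


def control_accuracy(table: pd.DataFrame, control: str, kind: str) -> float:
    """Sensitivity or specificity (percent) on a ground-truth control.

    ``kind`` is "methylated" (sensitivity: modC / all observed C) or
    "unmethylated" (specificity: unmodC / all observed C), over CpG-context
    sites of the named control.
    """
    sub = table[(table["chrom"] == control) & (table["context"] == "CpG")]
    n_mod = int(sub["n_mod"].sum())
    n_unmod = int(sub["n_unmod"].sum())
    total = n_mod + n_unmod
    if total == 0:
        raise ValueError(f"no cytosine observations on control {control!r}")
    if kind == "methylated":
        return 100.0 * n_mod / total
    if kind == "unmethylated":
        return 100.0 * n_unmod / total
    raise ValueError(f"kind must be methylated/unmethylated, got {kind!r}")


def call_rate_matrix(placed: Sequence[PlacedRead], methylome: Methylome,
                     references: Dict[str, str],
                     controls: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """3x3 called-vs-true rate matrix estimated on the three controls.

    Each column comes from the control whose CpGs have the corresponding
    true state; rates are proportions among C-called bases aligned to
    those CpGs (calls with unresolved modC subtype are excluded).  Columns
    sum to 1.
    """
    controls = controls or {"puc19_like": STATE_UNMOD,
                            "lambda_like": STATE_5MC,
                            "hmc_oligo": STATE_5HMC}
    mat = pd.DataFrame(0.0, index=list(CALL_STATES), columns=list(CALL_STATES))
    tallies = {s: {c: 0 for c in CALL_STATES} for s in CALL_STATES}
    for pr in placed:
        if pr.chrom not in controls:
            continue
        true_for_column = controls[pr.chrom]
        ref = references[pr.chrom]
        seq, track = pr.read.sequence, pr.read.mod_track
        for j, base in enumerate(seq):
            if base != "C":
                continue
            pos = pr.ref_pos(j)
            refbase = ref[pos] if pr.strand == "+" else complement(ref[pos])
            if refbase != "C" or cytosine_context(ref, pos, pr.strand) != "CpG":
                continue
            true_state, level = methylome.state_at(pr.chrom, pos, pr.strand)
            if true_state != true_for_column or \
                    (true_for_column != STATE_UNMOD and level < 1.0):
                continue
            called = _TAG_TO_STATE.get(track[j])
            if called is None:      # unresolved modC subtype
                continue
            tallies[true_for_column][called] += 1
    for true_state in CALL_STATES:
        total = sum(tallies[true_state].values())
        if total == 0:
            raise ValueError(
                f"no coverage for call-rate column {true_state!r}")
        for called in CALL_STATES:
            mat.at[called, true_state] = tallies[true_state][called] / total
    return mat


def empirical_phred(n_correct: int, n_incorrect: int) -> int:
    """Empirical Q = floor(-10*log10(1 - correct/(correct+incorrect))),
    capped at 60; 60 whenever there are no incorrect observations."""
    if n_correct < 0 or n_incorrect < 0 or n_correct + n_incorrect == 0:
        raise ValueError("need nonnegative counts with at least one observation")
    if n_incorrect == 0:
        return MAX_EMPIRICAL_Q
    err = n_incorrect / (n_correct + n_incorrect)
    return min(MAX_EMPIRICAL_Q, math.floor(-10.0 * math.log10(err)))


def build_empirical_phred_table(placed: Sequence[PlacedRead],
                                references: Dict[str, str],
                                masked: Optional[Set[Tuple[str, int]]] = None
                                ) -> pd.DataFrame:
    """Tally correct/incorrect base calls stratified by base and nominal Q.

    ``masked`` positions (e.g. known variant sites) and N bases in either
    the reference or the read are ignored.
    """
    masked = masked or set()
    counts: Dict[Tuple[str, int], List[int]] = {}
    for pr in placed:
        ref = references[pr.chrom]
        for j, base in enumerate(pr.read.sequence):
            if base == "N":
                continue
            pos = pr.ref_pos(j)
            if (pr.chrom, pos) in masked:
                continue
            truth = ref[pos] if pr.strand == "+" else complement(ref[pos])
            if truth == "N":
                continue
            key = (base, pr.read.quals[j])
            c = counts.setdefault(key, [0, 0])
            c[0 if base == truth else 1] += 1
    rows = [(b, q, c[0], c[1], empirical_phred(c[0], c[1]))
            for (b, q), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["base", "nominal_q", "n_correct",
                                       "n_incorrect", "empirical_q"])


def genetic_accuracy(table: pd.DataFrame,
                     min_nominal_q: int = 25) -> Dict[str, float]:
    """Per-base and overall genetic accuracy (percent) from the Phred table,
    restricted to nominal quality >= ``min_nominal_q``."""
    sub = table[table["nominal_q"] >= min_nominal_q]
    if sub.empty or (sub["n_correct"].sum() + sub["n_incorrect"].sum()) == 0:
        raise ValueError("no observations at or above the nominal-Q cutoff")
    out: Dict[str, float] = {}
    for base, grp in sub.groupby("base"):
        nc, ni = int(grp["n_correct"].sum()), int(grp["n_incorrect"].sum())
        out[base] = 100.0 * nc / (nc + ni)
    nc, ni = int(sub["n_correct"].sum()), int(sub["n_incorrect"].sum())
    out["overall"] = 100.0 * nc / (nc + ni)
    return out


def compare_tables(table_a: pd.DataFrame, table_b: pd.DataFrame,
                   min_coverage: int = 3) -> Dict[str, float]:
    """Compare two methylation tables at shared sites.

    Restricted to sites covered >= ``min_coverage`` in both; returns
    Pearson r of modified fractions plus Bland-Altman summaries of the
    percent difference (median, empirical 2.5 and 97.5 percentiles).
    """
    keys = ["chrom", "pos", "strand"]
    a = table_a[table_a["coverage"] >= min_coverage]
    b = table_b[table_b["coverage"] >= min_coverage]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    if len(merged) < 2:
        raise ValueError("fewer than 2 shared sites after coverage filtering")
    fa = merged["fraction_mod_a"].to_numpy() * 100.0
    fb = merged["fraction_mod_b"].to_numpy() * 100.0
    if np.std(fa) == 0 or np.std(fb) == 0:
        r = 1.0 if np.allclose(fa, fb) else float("nan")
    else:
        r = float(np.corrcoef(fa, fb)[0, 1])
    diff = fa - fb
    return {"pearson_r": r,
            "median_diff": float(np.median(diff)),
            "limit_2.5": float(np.percentile(diff, 2.5)),
            "limit_97.5": float(np.percentile(diff, 97.5)),
            "n_sites": int(len(merged))}
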