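"""Arm transformation and pairwise alignment of original vs copy strand.

Read 2 as sequenced is the PCR complement of the copy strand read from the
open adapter end, so cognate positions in read 1 and read 2 share an index
and the copy-strand base is recovered by an element-wise complement (no
reversal).  The two arms are then globally aligned with a Needleman-Wunsch
variant whose column score is driven by decoding-model permissibility (a
permissible (orig, copy) pair scores as a match, anything else as a
mismatch), affine gap costs, and free end gaps on the hairpin-proximal
(right-hand) side so that arms of unequal length after trimming align on
their shared adapter-proximal prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .codec import GAP, BasePairColumn, DecodingModel

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = set("ACGTN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# Internal fixed-point scale for alignment scores: parameters are exact to
# 1e-3, DP runs in int64 so traceback comparisons are exact.
_SCALE = 1000
_NEG = np.int64(-(10 ** 15))


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def transform_read2(seq: str) -> str:
    """Map read 2 (as sequenced) into copy-strand space.

    Element-wise complement, order preserved; N maps to N.
    """
    bad = set(seq.upper()) - _VALID
    if bad:
        raise ValueError(f"non-IUPAC characters in read 2: {sorted(bad)}")
    return complement(seq.upper())


@dataclass(frozen=True)
class AlignScoring:
    """Alignment scoring parameters (arbitrary units).

    Defaults are chosen so that a single substitution never beats opening a
    gap on typical reads: match +1, mismatch -2, gap open -4, gap extend -1
    (the first base of a gap costs open + extend).
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    free_end_gaps: bool = True


@dataclass
class ArmAlignment:
    """Aligned column sequence for one read pair."""

    columns: List[BasePairColumn]
    score: float
    n_aligned_columns: int   # columns with two non-gap bases
    n_unexpected: int        # nonpermissible non-N pairs plus gap columns


def find_hairpin_offset(seq: str, hairpin_seq: str, max_mismatches: int = 1,
                        min_overlap: int = 4) -> Optional[Tuple[int, bool]]:
    """Locate hairpin read-through in a read.

    Returns ``(offset, is_full_window)`` for the earliest hit, or None.
    Full-length hairpin windows may carry up to ``max_mismatches``
    mismatches; a partial hairpin prefix overhanging the read end must
    match exactly and span at least ``min_overlap`` bases.  A full-window
    hit is strong evidence on its own; a short suffix hit can occur by
    chance and callers should corroborate it (e.g. against the mate, which
    reads through at the same offset).
    """
    if not hairpin_seq:
        return None
    h = hairpin_seq.upper()
    s = seq.upper()
    lh, ls = len(h), len(s)
    for i in range(ls):
        w = ls - i
        if w >= lh:
            mm = sum(1 for a, b in zip(s[i:i + lh], h) if a != b)
            if mm <= max_mismatches:
                return i, True
        elif w >= min_overlap:
            if s[i:] == h[:w]:
                return i, False
    return None


def trim_hairpin_readthrough(seq: str, quals: Optional[Sequence[int]],
                             hairpin_seq: str, max_mismatches: int = 1,
                             min_overlap: int = 4
                             ) -> Tuple[str, Optional[List[int]]]:
    """Truncate a read at the first occurrence of the hairpin sequence.

    See ``find_hairpin_offset`` for the matching rules.  Empty
    ``hairpin_seq`` is a no-op.
    """
    hit = find_hairpin_offset(seq, hairpin_seq, max_mismatches, min_overlap)
    s = seq.upper()
    if hit is None:
        return s, list(quals) if quals is not None else None
    i, _ = hit
    return s[:i], list(quals[:i]) if quals is not None else None


def _pair_score_matrix(model: DecodingModel, scoring: AlignScoring) -> np.ndarray:
    w = np.full((5, 5), int(round(scoring.mismatch * _SCALE)), dtype=np.int64)
    m = int(round(scoring.match * _SCALE))
    for (o, c) in model.permissible_pairs:
        w[_BASE_INDEX[o], _BASE_INDEX[c]] = m
    return w


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))


def align_arms(read1: str, quals1: Sequence[int],
               read2_transformed: str, quals2: Sequence[int],
               model: DecodingModel,
               scoring: Optional[AlignScoring] = None) -> ArmAlignment:
    """Globally align the original arm against the copy arm.

    Column score is ``match`` when the (orig, copy) pair is permissible
    under ``model`` and ``mismatch`` otherwise; gaps are affine; trailing
    gaps on the hairpin-proximal (right) end are free.  Traceback prefers
    diagonal over up (gap in copy) over left (gap in original).
    Columns are returned left-to-right from the adapter end.
    """
    scoring = scoring or AlignScoring()
    s1, s2 = read1.upper(), read2_transformed.upper()
    if not s1 or not s2:
        raise ValueError("align_arms requires two nonempty sequences")
    for name, s in (("read1", s1), ("read2", s2)):
        bad = set(s) - _VALID
        if bad:
            raise ValueError(f"non-IUPAC characters in {name}: {sorted(bad)}")
    if len(quals1) != len(s1) or len(quals2) != len(s2):
        raise ValueError("quality length does not match sequence length")

    n, m = len(s1), len(s2)
    w = _pair_score_matrix(model, scoring)
    e1, e2 = _encode(s1), _encode(s2)

    # Fast path: equal lengths with every identity column permissible.
    # Any gapped alternative scores strictly lower (match > 0, gaps < 0).
    if n == m and scoring.match > 0:
        col_scores = w[e1, e2]
        match_i = int(round(scoring.match * _SCALE))
        if np.all(col_scores == match_i):
            cols = [BasePairColumn(a, b, q1, q2)
                    for a, b, q1, q2 in zip(s1, s2, quals1, quals2)]
            return ArmAlignment(cols, float(n * scoring.match), n, 0)

    go = int(round(scoring.gap_open * _SCALE))
    ge = int(round(scoring.gap_extend * _SCALE))
    goe = go + ge

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in s2 (consumes s1)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)  # gap in s1 (consumes s2)
    M[0, 0] = 0
    ii = np.arange(1, n + 1, dtype=np.int64)
    jj = np.arange(1, m + 1, dtype=np.int64)
    X[1:, 0] = go + ge * ii
    Y[0, 1:] = go + ge * jj
    j_idx = np.arange(m, dtype=np.int64)  # 0..m-1, for the Y-row scan

    for i in range(1, n + 1):
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        Xc = np.maximum(np.maximum(Mp + goe, Xp + ge), Yp + goe)
        Xc[0] = X[i, 0]
        diag = np.maximum(np.maximum(Mp[:-1], Xp[:-1]), Yp[:-1])
        Mc = M[i]
        Mc[1:] = w[e1[i - 1], e2] + diag
        Mc[0] = _NEG
        # Y within-row scan: Y[j] = max_{k<j} (base[k] + go + (j-k)*ge)
        base = np.maximum(Mc, Xc)
        run = np.maximum.accumulate(base[:-1] - ge * j_idx)
        Yc = Y[i]
        Yc[1:] = run + goe + ge * j_idx
        Yc[0] = _NEG
        X[i] = Xc

    # End cell: corner, or (free end gaps) best over last row / last column,
    # preferring fewer trailing free gaps, then M > X > Y.
    def cell_best(i: int, j: int) -> Tuple[int, int]:
        vals = (M[i, j], X[i, j], Y[i, j])
        k = int(np.argmax(vals))
        return int(vals[k]), k

    if scoring.free_end_gaps:
        best = None
        cands = [(n, j) for j in range(m + 1)] + [(i, m) for i in range(n + 1)]
        for (i, j) in cands:
            v, k = cell_best(i, j)
            key = (v, i + j, -k)
            if best is None or key > best[0]:
                best = (key, i, j, k)
        _, ei, ej, state = best
        score_i = best[0][0]
    else:
        score_i, state = cell_best(n, m)
        ei, ej = n, m

    cols_rev: List[BasePairColumn] = []
    # Trailing free-gap columns (unpenalized overhang past the end cell).
    for j in range(m - 1, ej - 1, -1):
        cols_rev.append(BasePairColumn(GAP, s2[j], None, quals2[j]))
    for i in range(n - 1, ei - 1, -1):
        cols_rev.append(BasePairColumn(s1[i], GAP, quals1[i], None))

    i, j = ei, ej
    while i > 0 or j > 0:
        if state == 0:  # M
            cols_rev.append(BasePairColumn(s1[i - 1], s2[j - 1],
                                           quals1[i - 1], quals2[j - 1]))
            tgt = M[i, j] - w[e1[i - 1], e2[j - 1]]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if M[i, j] == tgt:
                state = 0
            elif X[i, j] == tgt:
                state = 1
            else:
                state = 2
        elif state == 1:  # X: gap in copy strand
            cols_rev.append(BasePairColumn(s1[i - 1], GAP, quals1[i - 1], None))
            v = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + goe == v:
                state = 0
            elif X[i, j] + ge == v:
                state = 1
            else:
                state = 2
        else:  # Y: gap in original strand
            cols_rev.append(BasePairColumn(GAP, s2[j - 1], None, quals2[j - 1]))
            v = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + goe == v:
                state = 0
            elif X[i, j] + goe == v:
                state = 1
            else:
                state = 2

    cols = cols_rev[::-1]
    n_aligned = 0
    n_unexpected = 0
    for c in cols:
        if c.orig_base == GAP or c.copy_base == GAP:
            n_unexpected += 1
        else:
            n_aligned += 1
            if c.orig_base != "N" and c.copy_base != "N" and \
                    (c.orig_base, c.copy_base) not in model.permissible_pairs:
                n_unexpected += 1
    return ArmAlignment(cols, score_i / _SCALE, n_aligned, n_unexpected)
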