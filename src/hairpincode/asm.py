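"""Allele-specific methylation (ASM) calling from phased resolved reads.

Each resolved read that overlaps a heterozygous SNP is assigned to the
allele it carries at the variant position; its modC/unmodC calls at
CpG-context cytosines then count toward that allele's side of a 2x2
contingency table (allele x modification status, one count per (read, CpG)
observation).  SNPs with at least ``min_reads_per_allele`` reads on each
allele (default 6) are tested with a two-sided Fisher exact test and the
p-values are Benjamini-Hochberg adjusted across all tested SNPs.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .align import complement
from .quantify import PlacedRead
from .simulate import cytosine_context

MOD_TAGS = frozenset("mhM")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _read_allele(pr: PlacedRead, pos: int) -> Optional[str]:
    """Reference-strand base the read reports at reference position ``pos``,
    or None if the read has no aligned base there."""
    if not (pr.start <= pos < pr.end):
        return None
    j = pos - pr.start if pr.strand == "+" else pr.end - 1 - pos
    if j < 0 or j >= len(pr.read.sequence):
        return None
    base = pr.read.sequence[j]
    if base == "N":
        return None
    return base if pr.strand == "+" else complement(base)


def _read_cpg_calls(pr: PlacedRead, ref: str) -> Tuple[int, int]:
    """(modC, unmodC) call counts at CpG-context cytosines in one read."""
    n_mod = n_unmod = 0
    for j, base in enumerate(pr.read.sequence):
        if base != "C":
            continue
        pos = pr.ref_pos(j)
        refbase = ref[pos] if pr.strand == "+" else complement(ref[pos])
        if refbase != "C" or cytosine_context(ref, pos, pr.strand) != "CpG":
            continue
        if pr.read.mod_track[j] in MOD_TAGS:
            n_mod += 1
        else:
            n_unmod += 1
    return n_mod, n_unmod


def call_asm(placed: Sequence[PlacedRead], variants: pd.DataFrame,
             references: Dict[str, str],
             min_reads_per_allele: int = 6) -> pd.DataFrame:
    """Test each heterozygous SNP for allele-methylation association.

    ``variants`` needs columns chrom/pos/ref/alt (0-based pos).  Reads
    whose base at the variant site is absent, N, or matches neither allele
    are excluded.  Returns one row per tested SNP sorted by p-value, with
    the contingency counts, Fisher two-sided p, BH q and -log10(p).
    """
    by_chrom: Dict[str, List[PlacedRead]] = {}
    for pr in placed:
        by_chrom.setdefault(pr.chrom, []).append(pr)

    rows = []
    for var in variants.itertuples(index=False):
        ref_allele = var.ref.upper()
        alt_allele = var.alt.upper()
        if len(ref_allele) != 1 or len(alt_allele) != 1 \
                or ref_allele == alt_allele:
            warnings.warn(f"{var.chrom}:{var.pos + 1}: not a het SNP, skipped")
            continue
        ref_seq = references.get(var.chrom)
        if ref_seq is None:
            warnings.warn(f"{var.chrom}: unknown reference, variant skipped")
            continue
        counts = {ref_allele: [0, 0], alt_allele: [0, 0]}  # [modC, unmodC]
        n_reads = {ref_allele: 0, alt_allele: 0}
        for pr in by_chrom.get(var.chrom, ()):
            allele = _read_allele(pr, int(var.pos))
            if allele not in counts:
                continue
            n_reads[allele] += 1
            n_mod, n_unmod = _read_cpg_calls(pr, ref_seq)
            counts[allele][0] += n_mod
            counts[allele][1] += n_unmod
        if n_reads[ref_allele] < min_reads_per_allele \
                or n_reads[alt_allele] < min_reads_per_allele:
            continue
        table = [counts[ref_allele], counts[alt_allele]]
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append((var.chrom, int(var.pos), ref_allele, alt_allele,
                     counts[ref_allele][0], counts[ref_allele][1],
                     counts[alt_allele][0], counts[alt_allele][1],
                     n_reads[ref_allele], n_reads[alt_allele], float(p)))

    df = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "ref_modC", "ref_unmodC",
        "alt_modC", "alt_unmodC", "n_reads_ref", "n_reads_alt", "p_value"])
    if not df.empty:
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        with np.errstate(divide="ignore"):
            df["neg_log10_p"] = -np.log10(df["p_value"].to_numpy())
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["neg_log10_p"] = pd.Series(dtype=float)
    return df
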