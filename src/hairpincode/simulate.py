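"""Chemistry-faithful simulation of hairpin original/copy strand libraries.

The simulator builds the hairpin-linked molecule for each sampled fragment
and pushes it through the enzymatic steps with parameterized failure
rates:

* five-letter: protect every modC on the original strand (TET oxidation +
  glycosylation; fails with ``p_protect_fail``), then deaminate every
  unprotected C on both strands (deamination fails with ``p_deam_fail``).
* six-letter: glycosylate 5hmC (fails with ``p_glyc_fail``, after which the
  base behaves as 5mC), DNMT5-copy 5mC across the CpG unit onto the copy
  strand (fails with ``p_copy_fail``), protect original-strand 5mC
  (``p_protect_fail``), then deaminate unprotected Cs on both strands.

Read 1 reports the converted original arm from the open adapter end; read 2
reports the PCR complement of the converted copy arm at the same indices.
Fragments shorter than the read length read through the hairpin into the
other arm.  Sequencing substitution errors, constant base quality and PCR
duplicates are applied last.  The simulator and the decoding tables are
independent renderings of the same chemistry; their agreement is the
package's core oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as hio
from .align import complement, reverse_complement
from .codec import DecodingModel
from .resolver import deaminate

#: Synthetic hairpin adapter used by default (unmethylated, so it is read
#: fully C->T converted).
DEFAULT_HAIRPIN = "TCAGCAGTTGGTCGAT"

#: Molar proportions of the spike-in control pool used when simulating the
#: three ground-truth controls together (the 80-bp oligo would otherwise be
#: essentially unsampled next to the 20-kb methylated control).
CONTROL_POOL_WEIGHTS = {"lambda_like": 0.6, "puc19_like": 0.3,
                        "hmc_oligo": 0.1}

STATE_UNMOD = "unmodC"
STATE_5MC = "5mC"
STATE_5HMC = "5hmC"
_STATE_CHAR = {STATE_UNMOD: ".", STATE_5MC: "m", STATE_5HMC: "h"}

_RC = {"+": "-", "-": "+"}


def cytosine_context(seq: str, pos: int, strand: str) -> str:
    """CpG/CHG/CHH context of the cytosine at ``pos`` on ``strand``.

    Neighbours running off the sequence end are treated as H.
    """
    n = len(seq)
    if strand == "+":
        n1 = seq[pos + 1] if pos + 1 < n else "H"
        n2 = seq[pos + 2] if pos + 2 < n else "H"
        if n1 == "G":
            return "CpG"
        return "CHG" if n2 == "G" else "CHH"
    n1 = seq[pos - 1] if pos - 1 >= 0 else "H"
    n2 = seq[pos - 2] if pos - 2 >= 0 else "H"
    if n1 == "C":
        return "CpG"
    return "CHG" if n2 == "C" else "CHH"


@dataclass(frozen=True)
class ConversionModel:
    """All chemistry and sequencing error rates the simulator applies."""

    p_protect_fail: float = 0.0   # original-strand modC escapes protection
    p_deam_fail: float = 0.0      # unprotected C escapes deamination
    p_copy_fail: float = 0.0      # six-letter: DNMT5 fails to copy a 5mC
    p_glyc_fail: float = 0.0      # six-letter: 5hmC escapes glycosylation
    seq_error_rate: float = 0.0   # substitution rate per base per read arm
    pcr_duplicate_rate: float = 0.0
    base_quality: int = 30

    def __post_init__(self):
        for name in ("p_protect_fail", "p_deam_fail", "p_copy_fail",
                     "p_glyc_fail", "seq_error_rate", "pcr_duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


class Methylome:
    """Per-cytosine modification states and levels.

    One row per (chrom, pos, strand) with ``context`` in {CpG, CHG, CHH},
    ``state`` in {unmodC, 5mC, 5hmC} and ``level``: the probability that a
    given molecule carries the modification at that site (1.0 for a fully
    modified site, 0.0 for unmodified).  Sites absent from the table are
    unmodified.
    """

    COLUMNS = ["chrom", "pos", "strand", "context", "state", "level"]

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        self._lookup: Dict[Tuple[str, int, str], Tuple[str, float]] = {
            (r.chrom, r.pos, r.strand): (r.state, r.level)
            for r in self.df.itertuples(index=False)}

    def state_at(self, chrom: str, pos: int, strand: str) -> Tuple[str, float]:
        return self._lookup.get((chrom, pos, strand), (STATE_UNMOD, 0.0))

    def to_tsv(self, path) -> None:
        hio.write_tsv(self.df, path)

    @classmethod
    def from_tsv(cls, path) -> "Methylome":
        return cls(hio.read_tsv(path))

    @classmethod
    def from_rows(cls, rows: Iterable[Tuple]) -> "Methylome":
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


def _all_cytosine_rows(name: str, seq: str,
                       state_for) -> List[Tuple]:
    """One row per cytosine on either strand; ``state_for(pos, strand,
    context)`` returns (state, level)."""
    rows = []
    for i, b in enumerate(seq):
        if b == "C":
            ctx = cytosine_context(seq, i, "+")
            st, lv = state_for(i, "+", ctx)
            rows.append((name, i, "+", ctx, st, lv))
        if b == "G":
            ctx = cytosine_context(seq, i, "-")
            st, lv = state_for(i, "-", ctx)
            rows.append((name, i, "-", ctx, st, lv))
    return rows


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def make_controls(seed: int, lambda_length: int = 20_000,
                  puc19_length: int = 2_700, oligo_length: int = 80
                  ) -> Tuple[Dict[str, str], Methylome]:
    """Build the three spike-in ground-truth controls.

    * ``lambda_like``: random sequence, every CpG 5mC on both strands.
    * ``puc19_like``: random sequence, every cytosine unmodified.
    * ``hmc_oligo``: short GC-balanced oligo with symmetrical 5hmC at one
      CpG and asymmetrical (one strand only) 5hmC at another - three
      hmC-bearing strand positions in total.
    """
    rng = np.random.default_rng(seed)
    refs: Dict[str, str] = {}
    rows: List[Tuple] = []

    lam = _random_seq(rng, lambda_length)
    refs["lambda_like"] = lam
    rows += _all_cytosine_rows(
        "lambda_like", lam,
        lambda p, s, c: (STATE_5MC, 1.0) if c == "CpG" else (STATE_UNMOD, 0.0))

    puc = _random_seq(rng, puc19_length)
    refs["puc19_like"] = puc
    rows += _all_cytosine_rows("puc19_like", puc,
                               lambda p, s, c: (STATE_UNMOD, 0.0))

    # GC-balanced oligo with CpGs planted at fixed offsets.
    sym_cpg, asym_cpg = oligo_length // 4, (3 * oligo_length) // 4
    while True:
        oligo = list(_random_seq(rng, oligo_length))
        oligo[sym_cpg:sym_cpg + 2] = "CG"
        oligo[asym_cpg:asym_cpg + 2] = "CG"
        oligo = "".join(oligo)
        gc = (oligo.count("G") + oligo.count("C")) / oligo_length
        if 0.45 <= gc <= 0.55:
            break
    refs["hmc_oligo"] = oligo
    hmc_sites = {(sym_cpg, "+"), (sym_cpg + 1, "-"), (asym_cpg, "+")}
    rows += _all_cytosine_rows(
        "hmc_oligo", oligo,
        lambda p, s, c: (STATE_5HMC, 1.0) if (p, s) in hmc_sites
        else (STATE_UNMOD, 0.0))

    return refs, Methylome.from_rows(rows)


@dataclass
class SimTruth:
    """Ground truth of one simulated library.

    ``fragments`` has one row per distinct molecule (0-based half-open
    coordinates, fragment-oriented sequence, per-position modification
    state string and the error-free converted arms); ``reads`` links each
    emitted read pair to its fragment and flags PCR duplicates.
    """

    fragments: pd.DataFrame
    reads: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        hio.write_tsv(self.fragments, outdir / "truth_fragments.tsv")
        hio.write_tsv(self.reads, outdir / "truth_reads.tsv")

    @classmethod
    def read(cls, outdir) -> "SimTruth":
        outdir = Path(outdir)
        frags = hio.read_tsv(outdir / "truth_fragments.tsv",
                             keep_default_na=False)
        reads = hio.read_tsv(outdir / "truth_reads.tsv", keep_default_na=False)
        return cls(frags, reads)


def _sample_fragment_length(rng: np.random.Generator, dist: str,
                            mean_length: int, ref_len: int) -> int:
    if dist == "fixed":
        length = mean_length
    elif dist == "normal":
        length = int(round(rng.normal(mean_length, mean_length * 0.1)))
    elif dist == "cfdna_bimodal":
        # mono/di-nucleosomal mixture typical of plasma cfDNA
        if rng.random() < 0.8:
            length = int(round(rng.normal(167, 10)))
        else:
            length = int(round(rng.normal(330, 20)))
    else:
        raise ValueError(f"unknown fragment length distribution {dist!r}")
    return max(1, min(length, ref_len))


def _convert_fragment(fragment: str, states: str, six_letter: bool,
                      conv: ConversionModel, rng: np.random.Generator
                      ) -> Tuple[str, str]:
    """Apply the enzymatic steps to one molecule.

    Returns (converted original arm, converted copy arm); both indexed so
    that position k of the copy arm is cognate to position k of the
    original arm.
    """
    L = len(fragment)
    orig = list(fragment)
    copy = list(complement(fragment))
    protected_orig = [False] * L
    protected_copy = [False] * L

    for k, st in enumerate(states):
        if st == ".":
            continue
        eff = st
        if six_letter:
            if eff == "h" and rng.random() < conv.p_glyc_fail:
                eff = "m"           # unglycosylated 5hmC behaves as 5mC
            if eff == "h":
                protected_orig[k] = True   # glycosylation protects
            else:  # 5mC
                # DNMT5 copies the methyl group across the CpG unit; the
                # copied 5mC on the copy strand is protected.
                if k + 1 < L and fragment[k + 1] == "G" and \
                        rng.random() >= conv.p_copy_fail:
                    protected_copy[k + 1] = True
                if rng.random() >= conv.p_protect_fail:
                    protected_orig[k] = True
        else:
            if rng.random() >= conv.p_protect_fail:
                protected_orig[k] = True

    for arm, protected in ((orig, protected_orig), (copy, protected_copy)):
        for k in range(L):
            if arm[k] == "C" and not protected[k]:
                if rng.random() >= conv.p_deam_fail:
                    arm[k] = "T"
    return "".join(orig), "".join(copy)


def _apply_seq_errors(seq: str, rate: float,
                      rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    out = list(seq)
    for k in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != out[k]]
        out[k] = choices[rng.integers(0, 3)]
    return "".join(out)


def simulate_library(references: Dict[str, str], methylome: Methylome,
                     conversion: ConversionModel, model: DecodingModel,
                     n_fragments: int, read_length: int = 100,
                     fragment_length: int = 100,
                     fragment_length_dist: str = "fixed",
                     hairpin: str = DEFAULT_HAIRPIN, seed: int = 1,
                     reference_weights: Optional[Dict[str, float]] = None
                     ) -> Tuple[List[Tuple[hio.FastqRecord, hio.FastqRecord]],
                                SimTruth]:
    """Simulate a paired-end library from ``references`` + ``methylome``.

    Fragments are sampled uniformly within each reference, on either
    strand; references are drawn length-proportionally unless
    ``reference_weights`` gives explicit molar proportions (as for a
    spike-in control pool, whose short members would otherwise be barely
    sampled).  Identical inputs and seed produce byte-identical output.
    """
    if not references:
        raise ValueError("empty reference set")
    rng = np.random.default_rng(seed)
    six = model.is_six_letter
    hp_conv = deaminate(hairpin)

    names = sorted(references)
    if reference_weights is None:
        raw = np.array([len(references[n]) for n in names], dtype=float)
    else:
        raw = np.array([reference_weights.get(n, 0.0) for n in names],
                       dtype=float)
        if raw.sum() <= 0:
            raise ValueError("reference_weights sum to zero")
    weights = raw / raw.sum()

    frag_rows: List[Tuple] = []
    read_rows: List[Tuple] = []
    pairs: List[Tuple[hio.FastqRecord, hio.FastqRecord]] = []
    qual = (min(conversion.base_quality, 60),)
    read_no = 0

    for fi in range(n_fragments):
        name = names[rng.choice(len(names), p=weights)]
        ref = references[name]
        L = _sample_fragment_length(rng, fragment_length_dist,
                                    fragment_length, len(ref))
        start = int(rng.integers(0, len(ref) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        window = ref[start:start + L]
        fragment = window if strand == "+" else reverse_complement(window)

        state_chars = []
        for k, b in enumerate(fragment):
            if b != "C":
                state_chars.append(".")
                continue
            refpos = start + k if strand == "+" else start + L - 1 - k
            st, lv = methylome.state_at(name, refpos, strand)
            if st != STATE_UNMOD and rng.random() < lv:
                state_chars.append(_STATE_CHAR[st])
            else:
                state_chars.append(".")
        states = "".join(state_chars)

        conv_orig, conv_copy = _convert_fragment(fragment, states, six,
                                                 conversion, rng)
        frag_id = f"f{fi:06d}"
        frag_rows.append((frag_id, name, start, start + L, strand,
                          fragment, states, conv_orig, conv_copy))

        molecule = conv_orig + hp_conv + conv_copy[::-1]
        molecule_rc = reverse_complement(molecule)
        n_copies = 1 + int(rng.random() < conversion.pcr_duplicate_rate)
        for dup in range(n_copies):
            r1_seq = _apply_seq_errors(molecule[:read_length],
                                       conversion.seq_error_rate, rng)
            r2_seq = _apply_seq_errors(molecule_rc[:read_length],
                                       conversion.seq_error_rate, rng)
            rid = f"r{read_no:07d}"
            read_no += 1
            read_rows.append((rid, frag_id, int(dup > 0)))
            pairs.append((hio.FastqRecord(rid, r1_seq, qual * len(r1_seq)),
                          hio.FastqRecord(rid, r2_seq, qual * len(r2_seq))))

    truth = SimTruth(
        fragments=pd.DataFrame(frag_rows, columns=[
            "frag_id", "chrom", "start", "end", "strand",
            "sequence", "states", "conv_orig", "conv_copy"]),
        reads=pd.DataFrame(read_rows,
                           columns=["read_id", "frag_id", "duplicate"]))
    return pairs, truth


def write_library(pairs, truth: SimTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_fastq((r1 for r1, _ in pairs), outdir / "reads_R1.fastq")
    hio.write_fastq((r2 for _, r2 in pairs), outdir / "reads_R2.fastq")
    truth.write(outdir)


# -- diploid sample with heterozygous SNPs and allele-specific methylation ----

@dataclass
class SampleGenome:
    """A diploid genome-like sample for allele-specific methylation tests.

    ``reference`` is haplotype 1; haplotype 2 differs at the heterozygous
    SNPs.  At ASM loci, CpGs within ``asm_window`` of the SNP are fully
    methylated in cis with the reference allele and fully unmethylated with
    the alternate allele; all other CpGs share a Beta-mixture methylation
    level between the haplotypes.
    """

    name: str
    reference: str
    hap_seqs: Tuple[str, str]
    methylomes: Tuple[Methylome, Methylome]
    variants: pd.DataFrame         # chrom, pos (0-based), id, ref, alt
    asm_truth: pd.DataFrame        # chrom, pos, is_asm

    @property
    def references(self) -> Dict[str, str]:
        return {self.name: self.reference}


def _beta_mixture_level(rng: np.random.Generator) -> float:
    # Bimodal CpG methylation typical of a somatic genome: mostly high,
    # a minority low.
    if rng.random() < 0.7:
        return float(rng.beta(8.0, 1.5))
    return float(rng.beta(1.5, 8.0))


def make_sample_genome(length: int = 60_000, n_het_snps: int = 20,
                       asm_fraction: float = 0.5, seed: int = 1,
                       asm_window: int = 60, name: str = "sample",
                       min_snp_spacing: int = 300) -> SampleGenome:
    """Generate a diploid sample with het SNPs and optional ASM loci."""
    if not 0.0 <= asm_fraction <= 1.0:
        raise ValueError("asm_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    ref = _random_seq(rng, length)

    # evenly spaced-ish SNP positions with a minimum gap
    positions: List[int] = []
    margin = asm_window + 10
    tries = 0
    while len(positions) < n_het_snps and tries < 100 * max(1, n_het_snps):
        tries += 1
        p = int(rng.integers(margin, length - margin))
        if all(abs(p - q) >= min_snp_spacing for q in positions):
            positions.append(p)
    positions.sort()

    var_rows = []
    hap2 = list(ref)
    n_asm = int(round(asm_fraction * len(positions)))
    asm_flags = [i < n_asm for i in range(len(positions))]
    rng.shuffle(asm_flags)
    for i, p in enumerate(positions):
        rb = ref[p]
        alt = "ACGT".replace(rb, "")[rng.integers(0, 3)]
        hap2[p] = alt
        var_rows.append((name, p, f"snp{i}", rb, alt))
    hap2 = "".join(hap2)
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "id",
                                               "ref", "alt"])

    asm_positions = {p for p, f in zip(positions, asm_flags) if f}
    shared_levels: Dict[Tuple[int, str], float] = {}

    def level_for(pos: int, strand: str) -> float:
        key = (pos, strand)
        if key not in shared_levels:
            shared_levels[key] = _beta_mixture_level(rng)
        return shared_levels[key]

    def build_methylome(seq: str, hap: int) -> Methylome:
        def state_for(pos, strand, ctx):
            if ctx != "CpG":
                return (STATE_UNMOD, 0.0)
            near_asm = any(abs(pos - ap) <= asm_window for ap in asm_positions)
            if near_asm:
                return (STATE_5MC, 1.0) if hap == 1 else (STATE_UNMOD, 0.0)
            return (STATE_5MC, level_for(pos, strand))
        return Methylome.from_rows(_all_cytosine_rows(name, seq, state_for))

    meth1 = build_methylome(ref, 1)
    meth2 = build_methylome(hap2, 2)
    asm_truth = pd.DataFrame(
        [(name, p, int(p in asm_positions)) for p in positions],
        columns=["chrom", "pos", "is_asm"])
    return SampleGenome(name, ref, (ref, hap2), (meth1, meth2),
                        variants, asm_truth)


def simulate_diploid_library(sample: SampleGenome, conversion: ConversionModel,
                             model: DecodingModel, n_fragments: int,
                             read_length: int = 100, fragment_length: int = 100,
                             hairpin: str = DEFAULT_HAIRPIN, seed: int = 1
                             ) -> Tuple[List[Tuple[hio.FastqRecord,
                                                   hio.FastqRecord]], SimTruth]:
    """Simulate equal numbers of fragments from each haplotype.

    Truth coordinates are in reference space (SNPs are substitutions, so
    the haplotypes are co-linear).
    """
    half = n_fragments // 2
    out_pairs = []
    frag_tables = []
    read_tables = []
    for hap_i, (seq, meth) in enumerate(zip(sample.hap_seqs,
                                            sample.methylomes)):
        pairs, truth = simulate_library(
            {sample.name: seq}, meth, conversion, model,
            half if hap_i == 0 else n_fragments - half,
            read_length=read_length, fragment_length=fragment_length,
            hairpin=hairpin, seed=seed + hap_i)
        tag = f"h{hap_i + 1}"
        frags = truth.fragments.copy()
        frags["frag_id"] = tag + frags["frag_id"]
        frags["haplotype"] = hap_i + 1
        reads = truth.reads.copy()
        reads["read_id"] = tag + reads["read_id"]
        reads["frag_id"] = tag + reads["frag_id"]
        renamed = [( hio.FastqRecord(tag + r1.id, r1.seq, r1.quals, r1.desc),
                     hio.FastqRecord(tag + r2.id, r2.seq, r2.quals, r2.desc))
                   for r1, r2 in pairs]
        out_pairs.extend(renamed)
        frag_tables.append(frags)
        read_tables.append(reads)
    truth = SimTruth(pd.concat(frag_tables, ignore_index=True),
                     pd.concat(read_tables, ignore_index=True))
    return out_pairs, truth
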