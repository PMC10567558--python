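"""Two-base decoding of hairpin-linked original/copy strand read pairs.

Each sequenced position is observed twice: once on the original sample
strand (which retains cytosine modifications through enzymatic protection)
and once on the enzymatically synthesized copy strand.  After deamination
of unprotected cytosines, every single-base state maps to an ordered pair
(original-arm base, copy-strand base).  Only a handful of the 16 ordered
pairs can be produced by error-free chemistry ("permissible pairs"); all
other pairs flag an error and are masked as N in the resolved read.

Five-letter model: A, C, G, T plus modC (5mC or 5hmC, undifferentiated).
Six-letter model: additionally separates 5mC from 5hmC at CpG units, where
DNMT5 copies 5mC (but not glycosylated 5hmC) onto the copy strand, making
the three CpG states distinguishable by the pair pattern at the C and the
following G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

BASES = ("A", "C", "G", "T")
GAP = "-"

# Modification-status vocabulary.
MOD_NONE = "none"
MOD_C = "modC"                      # five-letter: 5mC or 5hmC, undifferentiated
MOD_5MC = "5mC"
MOD_5HMC = "5hmC"
MOD_UNKNOWN = "modC_subtype_unknown"  # six-letter modC outside a resolvable CpG unit

#: One-character tag encoding of a modification status (FASTQ/SAM carrier).
MOD_TAG = {MOD_NONE: ".", MOD_5MC: "m", MOD_5HMC: "h",
           MOD_C: "M", MOD_UNKNOWN: "M"}

ORIGINAL = "original"
COPY = "copy"

ALWAYS_NONPERMISSIBLE = "always_nonpermissible"
GENETIC_MISCALL = "genetic_miscall"
EPIGENETIC_MISCALL = "epigenetic_miscall"


class State(NamedTuple):
    """Decoded state of one position: genetic base plus modification status.

    ``copy_methyl`` marks a G whose copy-strand C carries a DNMT5-copied
    methyl group (six-letter mode only); it distinguishes (G,C) from (G,T)
    so that the CpG-unit context rules and the substitution-channel
    combinatorics see them as different states.
    """

    genetic_base: str
    mod_status: str
    copy_methyl: bool = False


STATE_N = State("N", MOD_NONE)


class BasePairColumn(NamedTuple):
    """One aligned column: cognate bases from the two arms with qualities.

    ``copy_base`` is the base physically present on the copy strand (read 2
    as sequenced reports its complement; see ``strand_align.transform_read2``).
    Qualities are ``None`` exactly when the corresponding base is a gap.
    """

    orig_base: str
    copy_base: str
    orig_qual: Optional[int] = None
    copy_qual: Optional[int] = None


@dataclass(frozen=True)
class DecodingModel:
    """Permissible-pair table and state semantics for one decoding mode."""

    name: str
    permissible_pairs: Dict[Tuple[str, str], State]

    @classmethod
    def five_letter(cls) -> "DecodingModel":
        pairs = {
            ("A", "T"): State("A", MOD_NONE),
            ("T", "A"): State("T", MOD_NONE),
            ("G", "T"): State("G", MOD_NONE),
            ("T", "G"): State("C", MOD_NONE),
            ("C", "G"): State("C", MOD_C),
        }
        return cls("five_letter", pairs)

    @classmethod
    def six_letter(cls) -> "DecodingModel":
        pairs = {
            ("A", "T"): State("A", MOD_NONE),
            ("T", "A"): State("T", MOD_NONE),
            ("G", "T"): State("G", MOD_NONE),
            ("T", "G"): State("C", MOD_NONE),
            ("C", "G"): State("C", MOD_C),
            # G whose copy-strand C carries a DNMT5-copied methyl group.
            # Only meaningful immediately after a (C,G) column; an isolated
            # (G,C) is chemically impossible and masked in resolve_columns.
            ("G", "C"): State("G", MOD_NONE, copy_methyl=True),
        }
        return cls("six_letter", pairs)

    @classmethod
    def from_name(cls, name: str) -> "DecodingModel":
        key = name.lower().replace("-", "_")
        if key in ("five", "five_letter", "5"):
            return cls.five_letter()
        if key in ("six", "six_letter", "6"):
            return cls.six_letter()
        raise ValueError(f"unknown decoding model {name!r}")

    @property
    def is_six_letter(self) -> bool:
        return self.name == "six_letter"

    def permissible_table_tsv(self) -> str:
        """Permissible-pair table as TSV (orig_base, copy_base, genetic_base, mod_status)."""
        lines = ["orig_base\tcopy_base\tgenetic_base\tmod_status"]
        for (o, c), st in sorted(self.permissible_pairs.items()):
            lines.append(f"{o}\t{c}\t{st.genetic_base}\t{st.mod_status}")
        return "\n".join(lines) + "\n"


def resolve_pair(column: BasePairColumn, model: DecodingModel) -> State:
    """Resolve one aligned column to a State.

    Total over all inputs: permissible pairs map to their state, instrument
    N on either arm and any nonpermissible (or gap) pair map to (N, none).
    """
    o, c = column.orig_base, column.copy_base
    if o in ("N", GAP) or c in ("N", GAP):
        return STATE_N
    return model.permissible_pairs.get((o, c), STATE_N)


@dataclass
class ColumnResolution:
    """Outcome of decoding a column sequence."""

    bases: str
    mods: List[str]
    n_columns: int = 0
    n_aligned: int = 0        # columns with two non-gap bases
    n_unexpected: int = 0     # nonpermissible pairs + gaps (+ isolated (G,C) in six-letter)
    n_ncall: int = 0          # columns containing an instrument N (uninformative)
    n_isolated_gc: int = 0    # six-letter (G,C) columns without a preceding (C,G)

    @property
    def mod_track(self) -> str:
        return "".join(MOD_TAG[m] for m in self.mods)

    @property
    def unexpected_fraction(self) -> float:
        return self.n_unexpected / self.n_columns if self.n_columns else 0.0


def resolve_columns(columns: Sequence[BasePairColumn],
                    model: DecodingModel) -> ColumnResolution:
    """Decode a sequence of aligned columns into bases + modification track.

    In six-letter mode the CpG unit rules apply: a (C,G) column followed
    immediately by (G,C) is 5mC at the C, by (G,T) is 5hmC, by anything
    else (including the read end) modC of unknown subtype.  A (G,C) column
    not preceded by (C,G) is masked N and counted as unexpected.
    """
    n = len(columns)
    bases: List[str] = []
    mods: List[str] = []
    res = ColumnResolution(bases="", mods=mods, n_columns=n)
    six = model.is_six_letter

    for i, col in enumerate(columns):
        o, c = col.orig_base, col.copy_base
        if o == GAP or c == GAP:
            res.n_unexpected += 1
            bases.append("N")
            mods.append(MOD_NONE)
            continue
        if o == "N" or c == "N":
            res.n_ncall += 1
            res.n_aligned += 1
            bases.append("N")
            mods.append(MOD_NONE)
            continue
        res.n_aligned += 1
        state = model.permissible_pairs.get((o, c))
        if state is None:
            res.n_unexpected += 1
            bases.append("N")
            mods.append(MOD_NONE)
            continue
        if six and (o, c) == ("G", "C"):
            prev = columns[i - 1] if i > 0 else None
            if prev is None or (prev.orig_base, prev.copy_base) != ("C", "G"):
                res.n_unexpected += 1
                res.n_isolated_gc += 1
                bases.append("N")
                mods.append(MOD_NONE)
                continue
        mod = state.mod_status
        if six and (o, c) == ("C", "G"):
            nxt = columns[i + 1] if i + 1 < n else None
            nxt_pair = (nxt.orig_base, nxt.copy_base) if nxt is not None else None
            if nxt_pair == ("G", "C"):
                mod = MOD_5MC
            elif nxt_pair == ("G", "T"):
                mod = MOD_5HMC
            else:
                mod = MOD_UNKNOWN
        bases.append(state.genetic_base)
        mods.append(mod)

    res.bases = "".join(bases)
    return res


@dataclass
class SubstitutionChannelReport:
    """Classification of all 24 single-base substitution types.

    A substitution type is (read arm, from-base, to-base).  Applying it to
    every permissible pair carrying the from-base on that arm either never
    yields a permissible pair (the error is always masked as N), or can
    silently change the genetic base (genetic miscall) or only the
    modification status (epigenetic miscall).
    """

    model_name: str
    classification: Dict[Tuple[str, str, str], str] = field(default_factory=dict)

    def count(self, kind: str) -> int:
        return sum(1 for v in self.classification.values() if v == kind)

    @property
    def n_always_nonpermissible(self) -> int:
        return self.count(ALWAYS_NONPERMISSIBLE)

    @property
    def n_genetic_miscall(self) -> int:
        return self.count(GENETIC_MISCALL)

    @property
    def n_epigenetic_miscall(self) -> int:
        return self.count(EPIGENETIC_MISCALL)

    def to_tsv(self) -> str:
        lines = ["arm\tfrom_base\tto_base\tclassification"]
        for (arm, fb, tb), cls in sorted(self.classification.items()):
            lines.append(f"{arm}\t{fb}\t{tb}\t{cls}")
        return "\n".join(lines) + "\n"


def enumerate_substitution_channels(model: DecodingModel) -> SubstitutionChannelReport:
    """Exhaustively classify the 24 substitution types against ``model``.

    For each (arm, from, to): apply the substitution to every permissible
    pair containing ``from`` on ``arm``; if no application lands on a
    permissible pair the type is always nonpermissible, otherwise it is a
    genetic miscall if any landing changes the genetic base, else an
    epigenetic miscall.
    """
    report = SubstitutionChannelReport(model_name=model.name)
    for arm_idx, arm in ((0, ORIGINAL), (1, COPY)):
        for fb in BASES:
            for tb in BASES:
                if tb == fb:
                    continue
                changes_genetic = False
                changes_epi = False
                for pair, old_state in model.permissible_pairs.items():
                    if pair[arm_idx] != fb:
                        continue
                    new_pair = list(pair)
                    new_pair[arm_idx] = tb
                    new_state = model.permissible_pairs.get(tuple(new_pair))
                    if new_state is None:
                        continue
                    if new_state.genetic_base != old_state.genetic_base:
                        changes_genetic = True
                    elif (new_state.mod_status != old_state.mod_status
                          or new_state.copy_methyl != old_state.copy_methyl):
                        changes_epi = True
                if changes_genetic:
                    cls = GENETIC_MISCALL
                elif changes_epi:
                    cls = EPIGENETIC_MISCALL
                else:
                    cls = ALWAYS_NONPERMISSIBLE
                report.classification[(arm, fb, tb)] = cls
    return report
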