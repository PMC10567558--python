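# Methods

## The two-base code

Hairpin-linked library preparation joins each original sample DNA strand to
an enzymatically synthesized, modification-free copy strand. After
protection of modified cytosines and deamination of unprotected ones, a
paired-end run observes every position twice: read 1 reports the converted
original arm, read 2 the PCR complement of the converted copy arm at the
same indices. The ordered pair (original-arm base, copy-strand base) then
encodes up to 16 states, of which error-free chemistry can produce only a
few ("permissible pairs"):

| original | copy | state (five-letter) |
|----------|------|---------------------|
| A | T | A |
| T | A | T |
| G | T | G |
| T | G | C (unmodified; deaminated on the original arm) |
| C | G | modC (5mC or 5hmC, protected) |

The six-letter model adds (G, C): a G whose copy-strand C carries a
DNMT5-copied methyl group. Because DNMT5 copies methylation only across a
CpG unit, this pair is meaningful only immediately after a (C, G) column;
the CpG unit patterns distinguish the three cytosine states:

* unmodified CpG: (T,G) (G,T)
* 5mC: (C,G) (G,C) — methyl copied, both positions protected
* 5hmC: (C,G) (G,T) — glycosylation blocks the copy

An isolated (G, C) column is chemically impossible and is masked N and
counted as an unexpected pairing. A (C, G) column whose successor is
neither (G, C) nor (G, T) — including a non-CpG context or the read end —
is reported as modC of unknown subtype (`M` in the tag dialect), since
5mC and 5hmC cannot be separated outside a resolvable CpG unit.

### Error suppression

Any non-permissible pair is masked as N rather than guessed. Exhaustive
enumeration over the 24 single-base substitution types (2 arms x 4
from-bases x 3 to-bases) shows that, in the five-letter model, 18 types can
never convert a permissible pair into another permissible pair; 4 types can
silently change the genetic base (A<->G on either arm, in copy-strand-base
convention: orig A<->G and copy A<->G) and 2 can change only the
modification status (orig C<->T). The six-letter model has 16/4/4: the
added (G, C) pair makes copy-arm T<->C an epigenetic channel in both
directions. The per-column miscall probability under a uniform
substitution rate e per arm is composition-weighted: each permissible pair
contributes e/3 per landing channel, which for typical genomic composition
comes to roughly 0.4e against a raw error rate of e, with the remaining
errors masked as N.

## Arm alignment

Cognate positions in read 1 and the complemented read 2 share an index, so
the aligner's job is only to absorb rare synthesis/sequencing indels. We
use a Needleman–Wunsch variant whose column score is driven by
permissibility under the decoding model (match +1 if the (orig, copy) pair
is permissible, else mismatch -2), affine gap costs (open -4, extend -1;
the first gap base costs open+extend), and free end gaps on the
hairpin-proximal (right) side only, so arms of unequal length align on
their shared adapter-proximal prefix. Defaults were chosen so a single
substitution never beats opening a gap; all are exposed in configuration.
Traceback prefers diagonal over up (gap in copy) over left (gap in
original); among equal-scoring end cells the one with fewest trailing free
gaps wins. Scores are held internally as integers at 1/1000 resolution so
DP and traceback arithmetic are exact. When both arms have equal length
and every identity column is permissible, the identity alignment is
provably optimal (match > 0, gaps < 0) and the quadratic DP is skipped.

Gap columns are counted as unexpected base pairing for the failure filter:
they indicate an indel somewhere in synthesis, amplification or
sequencing, and conservative rejection is preferred. Columns containing an
instrument N resolve to N but count toward neither correct nor unexpected
pairings — they are information-free.

## Resolution pipeline

Per read pair: hairpin read-through trimming, read-2 complementation, arm
alignment, column decoding, then the failure filter: pairs with more than
5% unexpected base pairing (configurable) did not derive from a
hairpin-connected original/copy construct and are discarded; the rest are
emitted as single-end reads over {A,C,G,T,N} with a per-position
modification track (`.`/`m`/`h`/`M`) carried in the FASTQ description as an
`XM:Z:` tag (convertible to a SAM `MM`-style tag downstream).

Trimming searches for the deaminated (C->T) hairpin in read 1 and its
reverse complement in read 2, allowing one mismatch in a full-length
window. A partial hairpin prefix at the read end must match exactly over
at least 4 bases and — because a short suffix match arises by chance in a
few percent of reads — is honored only when both mates show it at the same
offset (both arms read through at the fragment length). Resolved
per-position quality is the minimum of the two arm qualities capped at 60
(the production method uses proprietary instrument-specific calibration
tables; the minimum is conservative, monotone and reproducible, and
`build_empirical_phred_table` can recalibrate against a truth set).
Masked columns get quality 2. Input quality trimming is deliberately not
performed; reads are consumed as given.

## Simulator

The simulator is an independent rendering of the same chemistry and serves
as the codec's oracle: with all-zero failure rates, every simulated column
must land exactly on the permissible-pair table, and resolution must
recover each fragment's sequence and modification track exactly.

Per molecule, the six-letter step order is: glycosylate 5hmC (fails with
`p_glyc_fail`, after which the base behaves as 5mC), DNMT5-copy 5mC across
the CpG unit (fails with `p_copy_fail`), protect original-strand 5mC
(fails with `p_protect_fail`), deaminate every unprotected C on both arms
(fails with `p_deam_fail`). Five-letter mode protects all modC on the
original arm and synthesizes an unmodified copy arm. Protection failure is
modeled on the original arm only; a successfully copied 5mC on the copy
strand is protected deterministically, so the 5mC->5hmC confusion rate of
the six-letter code recovers `p_copy_fail` directly. Each enzymatic event
is drawn independently per molecule per site. A 5mC that escapes
protection deaminates and reads as unmodified C — not N — which is how
conversion loss manifests as a sensitivity shortfall in practice.

Parameter map (all configurable; defaults 0 so the zero-error round trip
is the baseline):

* sensitivity ~ 1 - `p_protect_fail` (methylated control)
* specificity ~ 1 - `p_deam_fail` (unmethylated control)
* call-rate M[5hmC][5mC] ~ `p_copy_fail`; M[5mC][5hmC] ~ `p_glyc_fail`
* `seq_error_rate`: uniform substitution rate per base per read arm
* `pcr_duplicate_rate`: probability a pair is emitted twice (flagged in
  truth); `base_quality`: constant nominal Phred (default 30)

Fragments are sampled uniformly within references on either strand;
references are drawn length-proportionally, or by explicit molar weights
for the spike-in pool (0.6 / 0.3 / 0.1 for the methylated, unmethylated
and oligo controls — without weighting the 80-bp oligo would be
essentially unsampled next to the 20-kb control). Fragment length
distributions: fixed (default), normal, and a bimodal cfDNA-like mixture
(modes ~167/~330 bp). Fragments shorter than the read length read through
the hairpin into the opposite arm, exactly as the trimmer expects.
Coordinates are 0-based half-open; strand is explicit everywhere.

### Ground-truth controls

* `lambda_like`: random 20-kb sequence, every CpG 5mC on both strands
  (emulating an M.SssI-treated phage spike-in).
* `puc19_like`: random 2.7-kb sequence, all cytosines unmodified.
* `hmc_oligo`: 80-bp GC-balanced oligo with symmetrical 5hmC at one CpG
  (both strands) and asymmetrical 5hmC at another (one strand) — three
  hmC-bearing strand positions.

### Diploid sample

`make_sample_genome` builds a genome-like reference with heterozygous SNPs
(minimum spacing keeps cis windows disjoint). A fraction of SNPs are
allele-specific-methylation loci: CpGs within +-60 bp are fully methylated
in cis with the reference allele and fully unmethylated with the
alternate, emulating the imprinted-locus pattern where reads carrying one
allele are entirely methylated and the other entirely unmethylated. All
other CpGs draw a per-site methylation level from a bimodal Beta mixture
(70% Beta(8, 1.5), 30% Beta(1.5, 8)) shared between haplotypes, so
site-level quantification spans [0, 1]; per-molecule states are Bernoulli
draws from the site level.

### What the simulator does not emulate

No indel or chimera error modes, no instrument-specific quality profiles
(constant nominal quality), no coverage biases, no bisulfite/EM-seq-style
three-state comparison reads, and no genome mapping ambiguity (placements
come from the ground truth or from externally aligned SAM). Passing tests
therefore demonstrate the correctness of the decoding stack and its
statistics under the modeled error processes, not performance on real
instrument data.

## Quantification and statistics

Methylation is tallied at every position whose resolved genetic call is C,
keyed by (chrom, pos, strand) with CpG/CHG/CHH context derived from the
reference (neighbors running off the end count as H); N calls are
ignored. CpG strand pooling onto the plus-strand coordinate is optional.
Sites below the coverage threshold (default 3 reads) are flagged.

* Sensitivity = modC / (modC + unmodC) over CpG sites of the methylated
  control; specificity analogously with unmodC on the unmethylated
  control; both reported as percent.
* The 3x3 call-rate matrix estimates each column from the control whose
  CpGs have that true state, as proportions among C-called bases aligned
  to those CpGs; calls with unresolved modC subtype (read-end boundary)
  are excluded, so columns sum to 1.
* Empirical Phred: counts of correct/incorrect calls against a truth
  reference (variant-masked positions and N bases skipped), stratified by
  called base and nominal quality; Q = floor(-10 log10(incorrect/total)),
  capped at 60, with 60 assigned when no incorrect observation exists.
* Genetic accuracy = correct/(correct+incorrect) per base and overall,
  restricted to nominal quality >= 25.
* Table comparison: Pearson r of site-level modified fractions plus
  Bland–Altman median difference and empirical 2.5/97.5 percentiles,
  restricted to sites covered >= 3x in both tables.

Allele-specific methylation: reads overlapping a heterozygous SNP are
assigned to the allele they carry (reads with no base, N, or a third base
at the site are excluded); each (read, CpG) C-call contributes one count
to the allele's side of the 2x2 table. SNPs with >= 6 reads per allele
are tested by two-sided Fisher exact test and Benjamini–Hochberg adjusted
across all tested SNPs.

## Numerical and design choices

* The unexpected-pairing fraction counts gap columns and (six-letter)
  isolated (G,C) columns; instrument-N columns count toward neither side.
* Duplicate pairs are left in quantification unless removed upstream;
  the truth table flags them for callers who want exact-duplicate
  collapse.
* Percent values are reported at full precision and formatted to two
  decimals at the CLI; internal fractions are never rounded.
* Determinism: a single numpy Generator seeded per run; identical config
  and seed give byte-identical outputs.

## Problem sizes in the test suite

The suite exercises the stack at desk scale: round trips use 1,000
fragments of 100 bp; parameter-recovery runs use 10,000 fragments
(>= 50,000 CpG observations on the methylated control), which bounds the
binomial standard error well below the effects being recovered; error
suppression uses ~10^5 aligned columns; ASM power/null runs use 3,000 -
6,000 diploid fragments over 12 - 40 kb with 4 - 12 SNPs. All stochastic
assertions use fixed seeds and 3-standard-deviation bands around analytic
(binomial or channel-accounting) expectations.

## Known limitations

* The aligner is quadratic per read pair; it is intended for short reads.
* The resolved-quality model (min of arms) understates quality where arms
  are independent and overstates it under correlated errors; empirical
  recalibration is provided for truth-available data.
* Six-letter subtype calls at a CpG whose partner G falls outside the read
  are reported as subtype-unknown rather than imputed.
* The minimal SAM reader supports match/soft-clip CIGARs only; indel
  alignments are skipped with a warning.
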