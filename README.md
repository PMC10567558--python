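# hairpincode

Decoding stack for hairpin-linked **original/copy strand sequencing**: a
method that reads genetics and cytosine modifications (5mC, 5hmC) from the
same DNA fragment in one run. Each sample strand is joined via a synthetic
hairpin to an enzymatically synthesized, modification-free copy strand;
modified cytosines are protected and unprotected cytosines deaminated, so
after paired-end sequencing every position is observed twice and the
ordered base pair (original arm, copy strand) encodes both the genetic
base and its modification state — a **two-base code** with up to 16
states.

The package is aimed at method developers and pipeline engineers who need
the complete decoding stack to be testable without any real sequencing
data. It provides:

* **codec** — the five-letter (A, C, G, T, modC) and six-letter
  (…, 5mC, 5hmC) permissible-pair tables, column decoding with the
  CpG-unit rules, and exhaustive substitution-channel combinatorics
  (of the 24 single-base substitution types, 18 can never produce another
  permissible five-letter pair and are masked as N — the code's built-in
  error suppression).
* **strand_align / resolver** — pair-aware hairpin-read-through trimming,
  read-2 complementation into copy-strand space, a permissibility-scored
  Needleman–Wunsch alignment of the two arms (affine gaps, free end gaps
  on the hairpin-proximal side), column decoding, and the 5%
  unexpected-pairing failure filter. Output is a single-end FASTQ over
  {A,C,G,T,N} with a per-position modification track (`XM:Z:` tag;
  `.`=none, `m`=5mC, `h`=5hmC, `M`=modC of unresolved subtype).
* **simulator** — a chemistry-faithful read simulator with parameterized
  failure rates (protection, deamination, DNMT5 copy, glycosylation,
  sequencing substitutions, PCR duplicates), the three ground-truth
  spike-in controls (fully CpG-methylated 20-kb control, fully
  unmethylated 2.7-kb control, an 80-bp oligo with symmetric and
  asymmetric 5hmC), and a diploid genome generator with heterozygous SNPs
  and allele-specific methylation.
* **quantify** — per-site CpG/CHG/CHH methylation tables, control
  sensitivity/specificity, the 3×3 call-rate matrix, empirical Phred
  tables `Q = ⌊−10·log₁₀(n_incorrect/(n_correct+n_incorrect))⌋` capped at
  60, genetic accuracy at nominal Q ≥ 25, and Pearson/Bland–Altman table
  comparison.
* **asm** — allele-specific methylation: two-sided Fisher exact tests of
  allele × modC contingency (≥ 6 reads per allele) with
  Benjamini–Hochberg correction.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Simulate a six-letter spike-in control library with realistic enzymatic
failure rates, resolve it, and measure accuracy:

```sh
hairpincode simulate --out sim --model six --n-fragments 4000 --seed 7 \
    --p-protect-fail 0.02 --p-deam-fail 0.001 --p-copy-fail 0.05
hairpincode resolve --r1 sim/reads_R1.fastq --r2 sim/reads_R2.fastq \
    --model six --out resolved
hairpincode accuracy --resolved resolved.fastq --truth-dir sim \
    --ref sim/reference.fasta --model six \
    --methylome sim/methylome.tsv --out-prefix acc
```

which prints

```
resolved 4000/4000 pairs (100.00%)
sensitivity_percent     97.9953
specificity_percent     99.9476
genetic_accuracy_overall_percent        100.0000
```

and writes the call-rate matrix (`acc.call_rate_matrix.tsv`, abridged):

```
        unmodC    5mC      5hmC
unmodC  0.9996    0.0203   0.0000
5mC     0.0000    0.9295   0.0019
5hmC    0.0004    0.0502   0.9981
```

The numbers recover the simulation parameters: sensitivity ≈
1 − p_protect_fail (98%), specificity ≈ 1 − p_deam_fail (99.9%), and the
rate at which a true 5mC is miscalled 5hmC ≈ p_copy_fail (5%) — a 5mC
whose DNMT5 copy step failed produces exactly the 5hmC read-out pattern.
Genetic accuracy stays at 100% here because no sequencing substitutions
were injected; with `--seq-error-rate` set, most substitutions land on
nonpermissible pairs and are masked as N rather than miscalled.

`hairpincode codec-report --model five` prints the permissible-pair table
and the 18/4/2 substitution-channel split; `hairpincode asm` tests
allele-specific methylation from a resolved library and a variant list.

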