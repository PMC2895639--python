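# altej

Decomposition, classification, and simulation of **alternative end-joining
(alt-EJ)** repair junctions at double-strand breaks.

When a double-strand break is repaired by end joining, the junction
sequence records the repair mechanism: annealing at **microhomologies**
(sequence attributable to either side of the break), **blunt** rejoining,
or **insertions** — often templated ("T-nucleotides") from DNA flanking
the break, copied imperfectly and in either orientation.  Junctions with
long (≥ 5 nt) microhomologies or > 3 bp insertions are signatures of
polymerase-θ–dependent alt-EJ; blunt joins, 1–4 nt microhomologies, and
1–3 bp insertions are typical of classical non-homologous end joining.
`altej` is written for researchers who sequence repair products across a
defined break substrate — such as the *Drosophila* P-element excision gap
with its 17-nt non-complementary 3′ tails and 8-bp target-site
duplication — and need reproducible junction calls and cohort statistics.

## The model

Against a break construct (left arm ending at the break, right arm
beginning at it, both 5′→3′ top strand), a junction read is decomposed by
maximal retention:

    p  = longest read prefix matching a left-arm prefix
    s  = longest read suffix matching a right-arm suffix
    mh = max(0, p + s − |read|)          # microhomology length
    insertion = read[p : |read| − s]     # when p + s < |read|

Deletions on each side are `[min, min + mh]` ranges (the microhomology is
attributable to either arm).  Microhomology calls are refined
mismatch-tolerantly (one internal mismatch, minimum upgraded length 6 by
default), insertions are scanned for maximal ungapped templates in the
flanking arms (both orientations, ≤ 1 mismatch) and tiled greedily into
templated runs, and cohorts are compared with the two-sided Fisher's
exact test (point-probability rule, exact integer arithmetic).

A mechanistic simulator generates junction cohorts under genotype presets
(resection → microhomology annealing, blunt joining, or iterative 3–8 nt
templated synthesis), with per-read ground truth and replayable traces,
so the whole pipeline is testable without external data.

## Worked example

```python
>>> from altej import pwa_construct, JunctionRead, decompose, refine_microhomology
>>> c = pwa_construct()
>>> read = JunctionRead("j1", "acccagacCATGATGAcccagac")
>>> d = decompose(c, read)
>>> (d.p, d.s, d.mh_len, d.mh_seq)
(16, 11, 4, 'ATGA')
>>> call = refine_microhomology(c, read)
>>> (call.length, call.mismatch_count, call.mismatch_offsets, call.exact_side)
(8, 1, (3,), 'left')
```

The exact decomposition finds a 4-nt microhomology, but allowing one
internal mismatch reveals an 8-nt imperfect microhomology (`CATGATGA`,
mismatching the right arm at offset 3) — the read matches the left arm
exactly over the call and the right arm at 7 of 8 positions, evidence
that annealing used the longer, imperfect repeat.

The command line ties the pipeline together.  `altej repro` reruns the
packaged cohort tables end to end:

```text
$ altej repro
genotype        n   n_long_mh  ...  mean_insertion_len  mean_mh_len  frac_ins_gt3
spnA            66  21         ...  5.7                 4.6          0.1364
mus308_D5_2003  23  0          ...  13.3                2.3          0.4348
mus308_D2_2003  25  1          ...  3.8                 2.3          0.1200

long-microhomology depletion, table1 vs table2 (Fisher exact):
table   21      45      0       23
p_value 0.00112345
```

Reading the output: the Rad51-deficient baseline cohort (n = 66 printed
isolates) uses long microhomologies in 21 junctions, while the
helicase-domain mutant cohort (n = 23) uses none (p ≈ 0.0011 < 0.01) yet
makes long, complex insertions (mean insertion 13.3 nt, 43 % over 3 bp);
the polymerase-deficient cohort (n = 25) loses both signatures (mean
insertion 3.8 nt, 12 % over 3 bp).

Other subcommands: `decompose`, `classify`, `templates`, `summarize`,
`compare`, and `simulate` (e.g.
`altej simulate --preset wildtype --n 500 --seed 7 --out-fasta sim.fasta
--out-truth truth.tsv`).

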