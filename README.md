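# cmca — conservation–mutation correlation analysis of protein families

`cmca` detects co-evolving position pairs and mutually mutative position
networks in a multiple alignment of a protein family. It is aimed at
protein engineers and molecular evolution researchers who want to know
which alignment columns mutate *together* — the kind of long-range coupling
that underlies allosteric communication, for example between the ligand
groove and distant surface sites of PDZ domains.

Conservation-based couplings (SCA-style) are dominated in highly conserved
families by the conservation signal itself. `cmca` complements that view
with a **mutation-centred** statistic: positions are compared not by how
conserved they are, but by how their *mutation spectra* co-vary.

## Model

An alignment of `N` sequences over `M = 21` symbols (the 20 amino acids plus
the gap, treated as a 21st residue type) and `L` columns is one-hot encoded
and tallied into the integer position frequency matrix `F (M × L)`, where
`F[k, l]` counts symbol `k` at column `l` and every column sums to `N`.

**Gap reduction.** Columns where the natural-residue fraction
`q_l = (Σ_{k≥1} F[k, l]) / N` is below 20% (i.e. more than 80% gaps) are
deleted; a column at exactly 20% is kept. A position map records the
surviving columns and, optionally, the residue numbering of a named
reference sequence.

**Mutative factor.** With `n_l` the number of distinct symbols (gap
included) at column `l`, each symbol's mutation score is

```
t(f; N, n) = (n − 1) / (|f − N/n| + 1)
```

`N/n` is the column's average symbol frequency. The factor peaks (value
`n − 1`) when a symbol's count sits exactly at that average — the signature
of an actively diversifying position — and is identically zero at invariant
columns (`n = 1`). At `N = 100` and `n = 20` the maximum over integer
frequencies is 19, reached at `f = 5`.

**Correlation matrices.** Pearson correlation over the 21-dimensional
column profiles yields two symmetric `L × L` matrices: `R_con` from the
count profiles `F[:, l]` (conservation flavour) and `R_mut` from the
mutative-factor profiles `T[:, l]` (mutation flavour). Zero-variance
profiles (e.g. invariant columns under the mutation flavour) are flagged as
undefined and their correlations set to 0.

**Coupling extraction.** Lower-triangle entries of `R_mut` strictly above
0.80 become coupled pairs; pairs that fall close together in the matrix
plane are clustered into labelled regions (R1, R2, …); connected components
of the pair graph form the mutative groups — the inferred co-evolving
networks. For display, entries below 0.5 and the diagonal are masked.

## Worked example

Simulate a desk-scale family with known structure — 240 sequences × 129
columns, 27 gap-dominated columns, and three planted coupled sets — then
run the full pipeline:

```bash
cmca simulate --preset pdz-like -o family.fasta --truth truth.json
cmca -v run -i family.fasta -o out --reference seq001
```

which logs

```
INFO cmca: alignment: 240 sequences x 129 columns (0 residue codes mapped to gap)
INFO cmca: gap reduction: 27 of 129 columns deleted, 102 kept
INFO cmca: coupling: 16 pairs in 15 regions forming 3 groups
```

The 27 gap-dominated columns (85% gaps, so `q = 0.15 < 0.20`) are deleted,
leaving 102 columns. The 16 extracted pairs are exactly the within-set
pairs of the three planted coupled sets (sizes 5, 3 and 3 give
10 + 3 + 3 = 16 pairs), and the three recovered groups are exactly the
planted sets. `out/pairs.tsv` reports each pair in both numbering systems
(reduced-alignment index and reference-sequence residue number, `–` where
the reference has a gap):

```
region	i	j	r	ref_i	ref_j
R1	41	6	1.000000	44	8
R2	77	6	1.000000	81	8
...
```

The planted pairs reach `r = 1.000000` because the generator plants perfect
co-variation. `out/` also holds the frequency matrix, the mutative-factor
matrix, both correlation matrices as TSV, and `report.json` with pairs,
regions, groups, undefined positions, parameters and provenance.
`cmca pairs` re-thresholds an existing `r_mut.tsv` without recomputation,
and `cmca plot` renders banded heatmap/contour figures (red > 0.90,
pink > 0.80, orange > 0.70).

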