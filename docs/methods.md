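# Methods

## Data model

A protein family is a gapped multiple alignment: `N ≥ 2` equal-length rows
over a fixed 21-symbol alphabet — the gap at index 0, the 20 standard amino
acids at indices 1–20. The gap is a first-class residue type: indels carry
evolutionary information (a structural element present in some members and
absent in others), so gap counts participate in the statistics rather than
being discarded.

Input normalisation maps the `.` and space gap dialects to `-`, uppercases
residues, and replaces non-standard codes (X, B, Z, U, O, J, `*`) by the
gap with a logged warning and a reported replacement count. The model has
exactly 21 residue classes; mapping ambiguity codes to a 22nd class would
change every downstream profile dimension for a handful of characters,
while mapping them to the most common amino acid would invent data. Mapping
to gap is the least-information choice and is always counted and surfaced.

## Position statistics

One-hot encoding gives a binary tensor `X (N × 21 × L)` with exactly one 1
per sequence–column cell; summing over sequences gives the integer position
frequency matrix `F (21 × L)`, each column summing to `N`.

**Gap-column reduction.** The natural-residue fraction of column `l` is
`q_l = Σ_{k=1..20} F[k, l] / N` (the gap row excluded from the numerator).
Columns with `q_l` strictly below the threshold (default 0.20) are deleted.
The comparison is deliberately strict — "fewer than 20% natural residues" —
so a column at exactly 20% survives; the boundary is pinned by a dedicated
test. Reduction is idempotent, and the gap row is retained afterwards:
residual gaps in surviving columns still inform the correlations. Every
run emits a position map (kept original columns, all `q` values, optional
reference numbering) so reduced indices are always traceable; reports carry
both the reduced index and the reference residue number to prevent
off-by-one confusion between coordinate systems.

## The mutative factor

The per-symbol mutation score at a column with `n` observed symbol types
(gap included) is

    t(f; N, n) = (n − 1) / (|f − N/n| + 1)

with `f` the symbol's integer count and `N/n` the column's average symbol
frequency, kept as an exact real (no rounding). The functional form encodes
four requirements: it is zero for every symbol at invariant columns
(`n = 1`, no mutation to correlate); it is finite at `f = N/n` (the `+1` in
the denominator); it peaks exactly at the average frequency with maximum
`n − 1`; and it decays monotonically as a count moves away from the
average. A symbol sitting at the column average is the signature of active
diversification — neither fixed (high `f`) nor effectively absent (low
`f`). The test suite checks all four properties exhaustively over integer
`f` for `N ∈ {10, 100, 240}` and `n ∈ 1..21`.

## Correlation matrices

Both matrices are plain Pearson correlations between 21-dimensional column
profiles, with the per-column mean over symbols subtracted:

* conservation flavour — profiles are the count columns `F[:, l]`;
* mutation flavour — profiles are the mutative-factor columns `T[:, l]`,
  where `T[k, l] = t(F[k, l]; N, n_l)` for all 21 symbols, including
  symbols absent from the column.

Numerical choices:

* **Covariance divisor.** Population form (divide by `M`) internally; the
  divisor cancels in the correlation, and a `ddof` switch plus an
  invariance test document that fact.
* **Gap row.** Included in the correlation sums by default (`n_l` always
  counts the gap regardless). The choice is exposed as
  `include_gap_row` because it matters: in a family with shared indel
  structure the gap row is genuine co-variation, but in a gapless family it
  is an all-zero row common to every column — structure, not signal. The
  i.i.d.-noise test uses the excluded-gap view for exactly this reason.
* **Zero-variance profiles.** An invariant column has an all-zero mutation
  profile and no defined correlation. Such positions are listed in
  `undefined_positions`, their off-diagonal entries set to 0 and diagonal
  to 1, instead of letting NaN propagate. "No mutation" cannot couple, so
  0 is the faithful value.
* Correlations are not clipped; symmetry, unit diagonal and `|r| ≤ 1` are
  asserted to 1e−9 against a brute-force per-pair Pearson oracle.

## Coupling extraction

* **Pairs**: lower-triangle entries with `r` strictly greater than the
  threshold (default 0.80 — "higher than" is read as strict, and the
  boundary is tested). Coefficients are reported at 6 decimals.
* **Display floor**: entries below 0.5 and the diagonal are masked in
  figures; an entry at exactly 0.5 is shown.
* **Regions**: single-linkage clustering of pair cells in the `(i, j)`
  plane under Chebyshev distance with radius 5 (configurable). There is no
  canonical definition of a "region" of a correlation map; this rule is the
  package's own, chosen because single linkage merges the staircase-shaped
  pair runs that visual inspection groups together, and Chebyshev distance
  treats the two matrix axes symmetrically. Region labels (R1, R2, … by
  smallest member cell) are therefore parameter-dependent descriptors, not
  a stable output surface.
* **Groups**: connected components (via networkx) of the undirected graph
  on positions with pairs as edges, validated against a brute-force
  transitive-closure oracle. The default minimum reported size is 2; a
  `--min-group-size 3` view restricts to the larger networks that are
  usually the biologically interesting ones.

## Synthetic families

The generator plants three kinds of structure, each mirroring a feature the
analysis must handle:

* **Background columns** draw a dominant residue with probability
  `background` (default 0.90), else a uniform alternative — the conserved
  bulk of a real family.
* **Gap columns** place `round(fraction · N)` gaps by exact count, not by
  per-sequence sampling, so threshold boundary behaviour is deterministic.
* **Coupled sets** share a latent state per sequence, drawn uniformly from
  `states_per_set` states and mapped to residues through **one shared
  state-to-residue map for all member columns of a set**. Member columns
  are then identical across sequences, so their mutation correlation is
  exactly 1. (Giving each member column its *own* residue map — even with
  identical count multisets — does not produce `r = 1`: the profiles
  become vectors with disjoint supports, whose Pearson correlation is
  negative, not unity. The shared map is what makes perfect co-variation
  exact.) Different sets use disjoint residue pools so they cannot collide
  in profile space.

The desk-scale integration fixture (`pdz_like_fixture`) has 240 sequences ×
129 columns with 27 columns at 85% gaps (`q = 0.15`, below the 20% rule,
leaving 102) and three planted sets of sizes 5, 3 and 3. Its background
columns are fully conserved (`background = 1.0`). That choice reflects how
strongly conserved a structure-aligned domain family is, and it isolates
the mutation signal cleanly: invariant columns are undefined under the
mutation flavour and contribute correlation 0, so the only couplings above
threshold are the planted ones. A noisy conserved background
(`background < 1`) would instead produce near-duplicate "dip-shaped"
mutative profiles at columns sharing a dominant residue — one tiny value at
the dominant symbol, near-constant values elsewhere — which correlate
highly with each other regardless of any true coupling. That is a real
property of the statistic worth knowing when interpreting results on real
families: mutation correlations between two *barely* variable columns with
the same consensus residue can be large without co-evolution. The fixture
deliberately avoids that regime; the planted-recovery tests on noisy
backgrounds only assert rank order (planted above background), which holds
robustly.

What the generator does **not** emulate: phylogenetic relatedness among
sequences (rows are i.i.d.), biased residue usage, sequence redundancy, or
correlated indel patterns. Passing recovery tests therefore show the
statistics behave as designed on independent sequences; they do not show
robustness to shared-ancestry correlation, which the mutation-centred view
mitigates but the generator cannot probe.

## Problem sizes

Default test and verification runs use families up to 240 × 129 (the
fixture), 100-replicate recovery sweeps at 100 × 15, and exhaustive factor
evaluation up to N = 240; the full pipeline is O(N·L + M·L²) and completes
in seconds at these sizes.

## Known limitations

* No correction for phylogenetic structure or sequence weighting; families
  of closely related sequences will share background correlation.
* No statistical significance for correlation values; thresholds are
  descriptive cutoffs, not hypothesis tests.
* The dip-profile effect described above: mutation correlations between
  near-invariant columns sharing a consensus residue can be inflated.
* Region labels depend on the clustering radius and are not comparable
  across parameter settings.
* Only aligned FASTA is read; other alignment formats must be converted
  upstream, and structural alignment itself is out of scope.
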