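# Methods

This note documents the models, conventions and defaults behind `mihakit`,
and what the synthetic-data generators do and do not emulate.

## Epitope windowing

A variant record is a protein sequence with one nonsynonymous substitution
(1-based position, reference and alternate residue) and the population
frequency of the MiHA-positive allele. For each requested length *L*
(default {9, 10}, the lengths HLA-A2 predominantly presents),
`enumerate_windows` emits every substring of length *L* that lies within
the protein and covers the variant position — for an interior variant with
at least *L* − 1 flanking residues on each side, exactly *L* windows per
length. Coordinates are 1-based inclusive throughout ("position 6 of the
nonamer" means offset 6). Windows containing residues outside the standard
20-letter alphabet are skipped with a logged warning, because coefficient
matrices are defined over that alphabet only.

Which allele is "MiHA-positive" is a convention, not a biological fact: by
default the alternate allele is the candidate, and `swap_miha_allele` (or
`--miha-positive ref`) exchanges the roles and complements the allele
frequency. Both allelic peptides are always emitted so downstream policy
can decide which must bind.

## Binding score

The predicted dissociation half-time is multiplicative:
T½ = c · ∏ᵢ m(i, pᵢ), with an allele constant c (seconds) and one
coefficient per position/residue. Useful identities that the tests
exercise: the score is monotone in any coefficient on the peptide's path,
scales linearly in c, and log T½ is the sum of the logs (checked to 1e−9
relative for strictly positive coefficients). A zero coefficient
annihilates the score, which is how published matrices encode forbidden
anchor residues.

`filter_binders` applies an **inclusive** threshold (default 30 s: a
moderate HLA-A2 binder scores above this level, and a value exactly at the
minimum is kept). The binding policy is configurable because it is
genuinely open which allelic peptide had to pass in the original screens:

* `alt_only` (default) — the MiHA-positive peptide must bind; the
  counterpart allelic epitope of a known antigen can fail binding and be
  dropped independently, which is the behavior this default reproduces;
* `either` / `both` — for sensitivity analyses.

Coefficient files are TSV matrices (rows = positions, columns = the 20
amino acids alphabetically) with a `#allele=<name> length=<L>
constant=<c>` header. Floats are written with `repr`, so a write/read
round-trip is bit-exact. Published matrices are not shipped;
`simulate.random_coefficient_table` provides seeded synthetic tables
(log-normal coefficients around 1, mimicking the shape of real matrices:
most positions near-neutral, anchors far from 1).

## Clinical applicability

Under Hardy–Weinberg proportions at MiHA-positive allele frequency *p*
(*q* = 1 − *p*), and donor/recipient independence,

A(p) = P(recipient ≥ 1 positive allele) · P(donor 0 positive alleles)
     = (1 − q²) · q².

A is maximal at q² = ½ (p ≈ 0.293) where A = 0.25, so a threshold *t* <
0.25 defines a band of usable frequencies, solved in closed form from
x² − x + t ≤ 0 with x = q². For t = 0.20 the exact band is
(0.14935, 0.47427); the default operational band is the rounded, inclusive
[0.15, 0.46], with the exact solution available via `frequency_band`.
Both assumptions (HWE, independence) are carried as metadata on results;
sibling-donor transplants violate independence, and the formula is used
there only as the conventional shortlisting criterion.

A donor/recipient pair is **disparate** in the graft-versus-tumor direction
iff the recipient carries ≥ 1 positive allele and the donor carries none —
exactly the event whose probability A(p) computes, and the rule used to
verify detected responses against genotypes.

## ELISA classification

ODs (414 nm, mean of triplicates) are classified low (< 0.4), intermediate
(0.4 ≤ OD < 1.25) or high (≥ 1.25); triage retains intermediate ∪ high.
The 0.4 boundary is assigned to *intermediate*: descriptions of the
low/intermediate cut vary between "≤ 0.39" and "≤ 0.4" in the literature
this convention comes from, and the majority reading (low binders fall
strictly below 0.4) is fixed here and in the file-format docs. Whether a
borderline OD = 0.4 peptide proceeds is therefore a documented convention,
not a measurement claim.

## Panel design

With *k* fluorochromes, C(*k*, 2) unordered two-color codes exist — 15 for
the six-channel default set (PE, APC, Qdot605, Qdot655, Qdot705, Qdot800),
10 for the five-channel monitoring kit shipped as a fixture.
`assign_codes` hands codes to peptides deterministically (lexicographic in
channel-index order, peptides in input order); the original kit's exact
code-to-peptide map is one valid instance, included as
`data/miha_kit_panel.tsv` and validated clean by `validate_panel`.

`pack_pools` computes ceil((candidates + controls)/capacity) pools, seeds
one control into each leading pool, and fills candidates in input order; a
75-candidate, 4-control screen at capacity 15 gives five pools of 15 plus a
remainder pool of 4, controls in pools A–D. Codes need only be unique
within a pool, so every pool can reuse the same channel set. Spectral
considerations (the low intensity of Qdot565/585/800, compensation) are
out of scope; pairing is purely combinatorial.

## Flow gating and decoding

Event tables are delimited text with one intensity column per multimer
channel plus `cd8_intensity`, `dump_intensity` (pooled CD4/CD14/CD16/CD19
lineage markers) and `viability_intensity` (dead-cell dye). Events are
assumed pre-gated as singlet lymphocytes; scatter gating is not modeled.

Positivity is thresholded on transformed intensities — identity, log10, or
arcsinh(x/cofactor) (cofactor default 150, the conventional
variance-stabilizer for cytometry) — with fixed per-channel thresholds by
default; `GatingConfig.from_negative_control` derives thresholds as a
quantile (default 99.9 %) of an unstained control, since real analyses gate
manually and any automatic rule must be explicit and overridable.

`gate_cd8` applies viability → dump → CD8 gates (a conjunction; the order
only structures the logged per-gate counts). `decode_events` assigns an
event to a specificity iff its positive-channel set equals that
specificity's code exactly; events positive in one channel, in three or
more, or in a two-channel combination no code claims, are counted
`unassigned` and excluded — the correction for single/triple/quadruple
multimer-positive artifacts. Counts always partition the gated events
(assigned + unassigned + negative = gated). `dual_color_frequency` gives
the conventional two-color readout (other channels ignored), which is by
construction ≥ the decoded frequency for the same code. Frequencies are
percentages of gated CD8+ events, formatted to two decimals with values in
(0, 0.01) rendered `<0.01%`; machine output keeps exact values.

## Synthetic data

All generators derive independent streams from one seed
(`numpy.random.default_rng([seed, stream])`) and are byte-deterministic.
Defaults (fixture seed 20110624):

* **Variants** — 50 random proteins of 30–80 residues, one substitution
  each, allele frequency ~ U(0.01, 0.6), so an expected
  0.31/0.59 ≈ 52.5 % of candidates fall in the [0.15, 0.46] band (a
  testable calibration).
* **ODs** — class weights default to the 32/33/42 split of a 107-peptide
  screen; per-class draws are uniform on [0, 0.39], [0.4, 1.24],
  [1.25, 2.5], so re-classification recovers the truth class exactly. An
  `exact_counts` option realizes a stated split exactly for bookkeeping
  tests.
* **Events** — hierarchy: 95 % live, 90 % of live dump-negative, 70 % of
  those CD8+. Among gated events, specificity labels are drawn at the spike
  frequencies, plus 1 % single-positive and 0.2 % triple-positive noise.
  Intensities are two log-normal components per channel (negative
  median 50, σ_log 0.4; positive median 10⁴, σ_log 0.5); the default linear
  threshold of 1000 sits > 7 negative-component log-SDs above the negative
  median, so threshold gating is effectively exact (mislabel probability
  ~10⁻⁶ per channel) and any decoding discrepancy is attributable to the
  decoder.
* **Genotypes** — donor and recipient drawn independently as Binomial(2, p)
  per SNP; the truth disparity flag equals the analytic rule row-wise.

What the generators deliberately do **not** emulate: spectral spillover and
compensation (noise is injected as discrete single/triple-positive events
instead, which is what exercises the correction-by-exclusion rule),
doublets, acquisition drift, plate effects in the ELISA, enrichment/
expansion kinetics (represented only as elevated spike frequencies), and
linkage between SNPs. Passing tests therefore demonstrate correctness of
the decision rules and decoding logic, not robustness to instrument
artifacts real data would add.

## Test and simulation sizes

The decoder-recovery check runs 20 seeded acquisitions of 100 000 events
(≈ 60 000 gated) with ten specificities spiked at 0.05–1 % of CD8+ events;
recovered frequencies are compared with each acquisition's emitted truth
table at 3 binomial SEs, and with the nominal spike levels as a mean
absolute error below 2 SEs across all 200 spike checks — comparing each of
200 individual checks with a 3-SE band against the *nominal* rate would
fail ~40 % of the time from generator sampling noise alone, which is why
the per-check comparison targets the realized truth. Monte-Carlo checks of
the applicability formula use 10⁶ genotype pairs per frequency (binomial
SE ≈ 4×10⁻⁴). The whole suite runs in well under a minute on one core.

## Known limitations

* Only single-residue substitutions are modeled; splice variants, cryptic
  translation products and proteasome-spliced peptides — documented
  confounders of reverse immunology — are out of scope.
* Binding tables are length- and allele-specific; peptides of a length
  with no supplied table are an error, not silently skipped.
* The applicability formula ignores population stratification and related
  donors.
* Three-color codes and spectral-aware pairing optimization are not
  implemented.
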