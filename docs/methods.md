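# Methods

This note documents the models, parameter choices and numerical decisions
behind the two pipelines, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Disproportionality screening

Spontaneous-report databases over-represent drug–event pairs that
clinicians suspect are related; disproportionality analysis quantifies the
excess over an independence baseline. The counting unit is the report: in
record mode, several mentions of the same (drug, term) pair within one
report are collapsed before tabulation, because one report constitutes one
observation regardless of how many lines repeat the pair. Margins of every
2×2 table are taken over the **full** report table, not the term group:
restricting margins to the group would delete the comparator reports the
statistics are defined against.

The information component is the shrinkage observed-to-expected estimator
`IC = log2((a + ½)/(E + ½))` with `E = (a+b)(a+c)/N`, and its 95%
credibility lower bound uses the standard closed-form approximation
`IC025 = IC − 3.3 (a + ½)^(−1/2) − 2 (a + ½)^(−3/2)`. This estimator is
the de-facto standard in modern disproportionality work; a full-Bayes
BCPNN bound would differ slightly in the third decimal for small `a`, a
spread that does not move any retention decision at the default
thresholds. The penalty term is strictly positive for every finite count,
so IC025 < IC always; IC is exactly 0 when `a = E`.

Retention semantics: PRR ≥ 2 (inclusive — a pair sitting exactly at 2
counts), IC025 > 0 (strict — a bound of exactly zero is not positive),
a ≥ 5 (inclusive), all adjustable on `fit()`. PRR is undefined when the
drug has no reports or when no other drug reports the term (`c = 0`); such
pairs carry NaN and are never retained, rather than being assigned an
infinite ratio. Retention is monotone in `a` at fixed margins, which the
property tests assert.

Burden summaries use retained reports only: the group total is the sum of
retained pair counts, recomputed on every call rather than stored. The
within-drug percentage divides by the drug's total reports over the whole
table (all AEs), so a drug whose reports are mostly seizure-related ranks
high on burden even if it contributes little to the pool, and vice versa —
the two top-10 rankings are deliberately different views whose
intersection is the interesting set. Ties everywhere break by descending
value then lexicographic name, so outputs are deterministic. The coverage
set is the shortest prefix of terms, sorted by descending retained count,
whose cumulative pool share reaches the coverage level (default 98%); the
comparison is made with a 1e−9 slack so exact-boundary sums are included.

## Conservation profiling

The scoring scheme rescales the 20×20 core of BLOSUM90 linearly onto
[0, 1]; ambiguity rows (B, Z, X, `*`) of published files are dropped
**before** the minimum and maximum are computed, so the normalization is
reproducible regardless of which file dialect supplied the table (the
bundled copy is the NCBI BLAST half-bit table; its core minimum is −6 and
its maximum 11, attained at W–W). Gap scores sit outside the normalized
range by design: −0.5 for a residue against a gap (either direction,
terminal gaps included — the data give no reason to distinguish them) and
0 for gap–gap columns, so indels read as worse than any substitution while
gap–gap columns are neutral.

Alignments are consumed, never produced: inputs are aligned FASTA with
`>SUBUNIT|SPECIES|ACCESSION` headers and exactly one human row per file.
Every comparison is within-subunit, against that alignment's human
reference.

The ECD/non-ECD split is annotation-driven (the ECD ends at the residue
before TM1); it is defined on the human sequence, and alignment columns
where the human row is gapped inherit the label of the nearest preceding
human residue (leading gaps count as ECD). Insertion columns relative to
the human sequence therefore keep alignment-column numbering rather than
being dropped from the plots.

Coordinates: the reference subunit — by default the one with the longest
human sequence, GABRR1 in the full receptor family; if a requested
reference is absent the longest is substituted with a prominent log
message — keeps identity ECD numbering, and every other subunit's ECD
coordinates are shifted by the integer that moves its cys-loop
second-cysteine column onto the reference's anchor coordinate. The anchor
residue must be a cysteine in the human row, which is validated, and an
anchor falling in a human-gap column is a hard error. Non-ECD numbering
restarts at 1 per subunit. Segment summaries average scores over the
alignment columns spanned by each segment's human coordinates, excluding
gap–gap columns (no observation in either sequence), and report segments
in the fixed order A–G, TM1–TM4.

## Synthetic data

The ortholog generator copies a human reference and, per position, applies
a substitution with its segment's probability `p_sub` and an indel with
`p_indel` (deletion or insertion after the position, equal odds). The
substituted residue is drawn from a softmax over the raw BLOSUM90 row of
the original residue with identity excluded — a cheap stand-in for a
time-reversible substitution model that preserves biochemical similarity,
sufficient for the monotonicity and rate-recovery properties the tests
check. Because the simulation knows the homology, it emits the true
alignment directly; no aligner runs, so aligner error is *not* part of
what passing tests demonstrate. Real ortholog sets also differ in ways the
generator ignores: phylogenetic correlation between species, lineage- and
domain-specific indel length distributions, and non-uniform composition.

The report generator draws one multinomial of `N` reports over the drug ×
term grid with cell probabilities `p_i q_j λ_ij / Z`; spiked pairs carry
λ > 1 and are the planted signals. Marginals default to uniform. Real
FAERS extracts have heavy-tailed margins, duplicated cases and stimulated
reporting waves; none of these are emulated, so the recovery results
characterize the statistics, not FAERS itself. Record-mode inputs are
exercised by expanding counts into single-drug single-term reports, which
keeps the multinomial truth exact.

Study-condition defaults, fixed once: recovery tests use N = 100,000
reports over 50 drugs × 40 terms with 10 pairs spiked at λ = 8 (expected
null cell ≈ 50 reports, spiked ≈ 390 — comfortably past all three
retention thresholds); rate recovery uses 12 segments of 100 residues with
`p_sub` spaced linearly on [0.01, 0.6]; the fixture bundle uses 20,000
reports over 10 drugs × 8 terms with two pairs at λ = 12, strong enough
that retention held in 50/50 calibration seeds. Single-seed assertions
were frozen only after multi-seed Monte-Carlo checks of the kind recorded
in the test docstrings.

## Numerical and design notes

- Human segment coordinates are 1-based inclusive; alignment columns
  1-based. All I/O is plain text (TSV, FASTA, YAML, JSON).
- The normalization rejects constant raw matrices (undefined rescale) and
  asymmetric tables (hard error naming the offending pair).
- Scoring rejects characters outside alphabet ∪ {`-`} with the column
  index in the message.
- `run_all` writes a manifest with a SHA-256 hash per output; figures are
  PNG, whose encoder embeds no timestamps, so reruns are hash-identical.
  The manifest's own timestamp is the only varying field.
- The red-flag join matches drug names exactly after case-folding and
  trimming; fuzzy matching is deliberately absent because silent joins
  corrupt pharmacovigilance outputs. In-silico hit tables are consumed as
  opaque data (drug, model, ordinal fit score); the profiler that produces
  them is outside the package's scope.
- The command-line layer is a thin wrapper: every command is a few lines
  over the library objects (`DisproportionalityModel` / `ConservationModel`
  and their results).

## Limitations

- No MedDRA hierarchy traversal: the term group is a flat list standing in
  for a class subtree.
- No case deduplication or drug-name normalization (RxNorm); inputs are
  assumed curated.
- PRR has no variance-based confidence bound here; retention relies on the
  IC credibility bound, matching the screening rule implemented.
- Conservation scores are per-column and unweighted; no attempt is made to
  model structural context beyond the segment annotations.
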