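# Methods

## Scope and model

The package treats peptide aggregation propensity as a purely
sequence-intrinsic, per-residue quantity: each of the 20 standard residues
carries a fixed propensity value (`a3v`, the AGGRESCAN experimental scale,
transcribed verbatim in `scales.py`), and all sequence-level behaviour is
derived from sliding-window averages of those values. No structural,
kinetic, or lipid-environment modelling is attempted; the engine ranks
sequences, it does not predict rates. Substitutions are the only edit
operation — no indels — so every scan preserves length and alignment.

## Windowed score

For a sequence of length *n* ≤ 75 the window size is *w* = 5 (the
length-tiering to 7/9/11 for longer inputs is implemented and tested
structurally, but all peptides in this domain are ≤ 37 residues). The
profile value `a4v(i)` is the mean of `a3v` over the *w* positions
centered at *i*. Two conventions required a decision because the
reference webserver's edge handling is not published:

- **Terminal windows** are completed with a fixed boundary propensity
  (`terminal_pad = −0.3094`) for positions beyond the termini, and always
  divided by *w*. This down-weights terminal residues (position 1
  contributes to 3 windows instead of 5), which is the weighting that
  reproduces published score *differences* for terminal substitutions
  exactly.
- **Normalization** subtracts a fixed per-residue baseline:
  `Na4vSS = 100 · (mean(a4v) − baseline)` with `baseline = 0.02695`.

The two constants were fixed once, by a minimax fit against 36 published
webserver scores for IAPP-derived peptides of two lengths (37 and 15
residues); the maximum residual is 0.048, i.e. every anchor reproduces its
printed one-decimal value. They are properties of the scale object (and
injectable), not per-analysis tunables. Consequences worth noting:

- The homopolymer closed form is
  `Na4vSS(poly-X, n) = 100·(((5n−6)·a3v(X) + 6·pad)/(5n) − baseline)`,
  which tends to `100·(a3v(X) − baseline)` for long chains; the naive
  `100·a3v(X)` holds only under a truncated-mean edge convention, which
  the calibration rejected.
- Substituting position *p* perturbs `a4v` only within the half-window
  (|i−p| ≤ 2), so substitutions more than one window apart contribute
  exactly additively to Na4vSS (tested for V17D+F23R).

**Hot spots** are maximal runs of ≥ 5 consecutive positions with
`a4v > −0.02`, prolines excluded (a proline terminates a run and never
belongs to one). The threshold, minimum run length, and proline rule are
the standard AGGRESCAN defaults. The baseline constant is deliberately
*not* applied to the profile used for hot-spot detection — it belongs to
the normalization, and applying it to `a4v` would shift the detection
threshold with no published evidence either way. Under this choice the
engine reproduces the published qualitative behaviour: human IAPP shows
hot spots at 13–18 and 24–28; V17D, F23R, F23G and I26A each delete one;
N22I, N31V and R11W broaden them.

## Physicochemical descriptors

- **GRAVY** is the plain Kyte–Doolittle mean. Report cells use a
  two-stage display rounding (half-away-from-zero to 3 decimals, then to
  2), which is how the reference tabulations were evidently produced: it
  reproduces all 30 published values, including −0.2946 → −0.30, which a
  single 2-decimal rounding cannot.
- **Net charge** is the Henderson–Hasselbalch sum over the N-terminal
  amine, C-terminal carboxyl, and K/R/H (basic) and D/E/C/Y (acidic) side
  chains, with the EMBOSS pKa set by default and a fully injectable
  `ChargeModel`. Cysteines are treated as free thiols (no disulfide
  correction); the scored C-terminal fragments contain none, so the
  simplification is inert for the headline results. Z(pH) is strictly
  decreasing, so the **isoelectric point** is the unique root on [0, 14],
  found by bisection to 1e−4 (cross-checked against `scipy.optimize.brentq`
  in tests). Published integer-level charge statements reproduce (the
  native C-terminal fragment rounds to 0 at pH 7, its F23R variant to +1);
  note that near the C-terminal pKa (3.6) the fragment's charge
  transiently rises toward +1, so "neutral over pH 3–8.5" holds only in
  the integer-rounded sense above ~pH 4.
- **Hydrophobic moment** is Eisenberg's μH per residue
  (|Σ h·e^{inδ}|/n) with the consensus scale, default δ = 100°; no
  published values exist for these peptides, so it is oracle- and
  property-tested only.
- The "theoretical average rate of aggregation" named alongside these
  descriptors in the source analysis specifies no algorithm and is not
  implemented.

## Variant catalog and its fixture

The catalog maps each position to observed substitute residues with
occurrence counts. The packaged 240-species IAPP table transcribes the
published per-position substitution lists and per-position occurrence
totals. Per-substitute counts within a position were not published, so the
loader apportions each position's total uniformly across its listed
substitutes (earliest listed receive the remainder). Every position-level
quantity — the 113 distinct variants, 1,640 total occurrences, 1,187
within residues 17–31, the conserved set {2, 12, 16}, the per-position
totals (S29: 211, H18: 209, F23: 206, A8: 168) — is exact; only the
within-position split is a modelling choice, and nothing downstream
depends on it except the synthetic generator's within-position mix. The
single nonstandard record (L27X) is carried in a separate bucket: it
counts toward occurrence totals (reaching 1,640 requires it) but is never
scored or scanned.

## Design scans

Scans enumerate exhaustively — all scorable catalog variants for k = 1,
all k-combinations at pairwise-distinct positions for k ≥ 2 — with a
configurable combination budget that errors out rather than truncating
silently. Classification against a threshold is strict (<) on
full-precision scores; rounding is display-only, because the published
counts imply a binary classification that rounding could corrupt. Sorting
is total (score, then first variant position, then substitute letter,
then label), making reports byte-reproducible. Pearson correlation is
delegated to `scipy.stats.pearsonr` with explicit rejection of constant
vectors (tests carry an independent textbook-formula oracle).

## Synthetic panels

The generator draws each panel member independently, sampling every
position from its substitution distribution (residual mass = reference
residue); positions are independent by design, since every statistic the
package computes is per-position. Defaults mirror the packaged table:
panel size 240 and probability = count/240, which reproduces the
published occurrence structure in expectation (1,640 total) and keeps
{2, 12, 16} invariant. The L27X mass is sampled as a literal X so
occurrence totals can be recovered. Determinism is contracted as
(seed, config, generator version), with the RNG algorithm
(`numpy-default-rng(PCG64)`) pinned in the config metadata. What the
generator does **not** emulate: phylogenetic correlation between
sequences, linkage between sites, indels, and variable panel coverage per
position — so recovery tests validate the counting machinery, not any
evolutionary realism.

## Known discrepancies

Documented here because tests assert them honestly:

- Two published single-variant scores are internally inconsistent with
  the rest of their own table and irreproducible under any
  positive-weight window convention: T4I (printed 0.9, computed −0.26;
  the identical T→I substitutions at positions 6 and 9 print −0.2) and
  T36S (printed −9.1, identical to the adjacent Y37H row; the
  substitution's propensity delta implies −5.9). Both were excluded from
  the calibration fit.
- The published "43% of variants score below the reference" figure does
  not follow from the published table: 54 of the 112 scorable variants
  carry a strictly negative propensity delta (48%), a count that depends
  only on the sign of the substitution's scale difference and therefore
  cannot be altered by any window convention. The corresponding
  acceptance test asserts 43% and fails by design.
- Likewise "30 variants below −6.6": the pipeline counts 31 (the extra
  one, I26L at −6.75, is robustly below; borderline F23L sits at −6.57,
  above). The acceptance test asserts 30 and fails by design.
- The score/hydropathy Pearson correlation computes to 0.8788 against a
  published 0.87 — agreement to one unit in the last printed digit.
- Published counts with ambiguous referents (the ~95 favourable doubles
  and 644 favourable triples, whose comparison threshold and candidate
  pool are unstated) are computable via `multi_scan` +
  `classify_vs_reference` for any threshold choice but are not asserted.

## Problem sizes

Everything is desk-scale: 37-residue reference, 112-variant single scan,
≤ C(112, 3) ≈ 2.3×10⁵ triple combinations (capped by the budget), panels
of 240 (matching the study design) and 10,000 (frequency-convergence
tests). The full test suite runs in a few seconds on one CPU.
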