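# iappdesign

Aggregation-propensity profiling and biomimetic variant design for islet
amyloid polypeptide (IAPP/amylin) and related short peptides.

Human IAPP is a 37-residue hormone co-secreted with insulin; its amyloid
fibrils are a hallmark of type-2 diabetes, while homologues from many
species (rat IAPP, for instance) barely aggregate. This package implements
the computational side of a biomimetic design strategy: catalog the
residue substitutions that evolution has already explored across a panel
of species, substitute them — singly or in combination — into the human
sequence, and rank the resulting de-novo candidates by predicted
aggregation propensity.

It is aimed at protein-aggregation and peptide-design researchers who want
a scriptable, tested version of this pipeline rather than a chain of web
servers.

## What it computes

**Aggregation propensity (Na4vSS).** Each residue carries an intrinsic
aggregation propensity `a3v` (the AGGRESCAN experimental scale). A sliding
window of length-dependent size `w` (5 for peptides ≤ 75 residues)
averages these into the per-residue profile `a4v`; windows overhanging the
termini are completed with a fixed boundary value. The sequence score is
the windowed sum normalized to 100 residues,

    Na4vSS = 100 · (mean(a4v) − baseline),

with more negative values meaning less aggregation-prone. *Hot spots* —
candidate aggregation nuclei — are maximal runs of ≥ 5 consecutive
residues with `a4v` above the hot-spot threshold (−0.02), prolines
excluded. The two terminal constants are calibration constants fixed
against published webserver output for IAPP peptides (see
`docs/methods.md`).

**Physicochemical descriptors.** GRAVY (mean Kyte–Doolittle hydropathy),
Henderson–Hasselbalch net charge Z(pH) with the EMBOSS pKa set
(injectable), isoelectric point by bisection, and the Eisenberg
hydrophobic moment μH at a configurable periodicity angle (100° helix /
180° strand).

**Variant catalogs.** Per-position substitution tables with occurrence
counts, built from aligned equal-length panels or loaded from the packaged
240-species IAPP table (113 distinct substitutions, 1,640 occurrences,
hypervariable 17–31 segment, invariant C2/L12/L16).

**Design scans.** Exhaustive single/double/triple substitution of catalog
variants into a reference, ranked by Na4vSS, classified against a
threshold, flagged for hot-spot deletion, and correlated against GRAVY.

**Synthetic panels.** A seeded generator draws cross-species-like panels
with position-specific substitution probabilities, so every stage is
testable without downloads.

## Worked example

```python
import iappdesign as iap

peptides = iap.builtin_sequences()
hiapp = peptides["hIAPP"]                 # KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY

profile = iap.score_sequence(hiapp)
print(iap.display_na4vss(profile.na4vss)) # -5.6
print(profile.hot_spots)                  # ((13, 18), (24, 28))

catalog = iap.load_species_table()        # 240-species substitution table
table = iap.single_scan(hiapp, catalog)   # 112 scorable single variants
best = table.records[0]
print(best.label, iap.display_na4vss(best.na4vss))   # V17D -14.8
print(round(iap.scan_correlation(table), 2))         # 0.88
```

The same pipeline from the shell:

```
$ iappdesign score peptides.fasta
id      length  na4vss  n_hot_spots  hot_spots
hIAPP   37      -5.6    2            13-18;24-28
rIAPP   37      -8.8    1            13-18
C_native        15      6.6     1    1-6
F23R_fragment   15      -5.3    0    .
```

Reading: human IAPP scores −5.6 with two hot spots (the LANFLV 13–18 and
GAIL-centered 24–28 segments); rat IAPP is markedly less
aggregation-prone (−8.8, one hot spot); the native C-terminal 23–37
fragment is strongly aggregating (+6.6) while its F23R variant (−5.3)
loses its hot spot entirely — the design rationale for that variant.
`iappdesign scan --k 2` ranks double substitutions (V17D+F23R reaches
−22.9); `iappdesign catalog` and `iappdesign simulate` handle panel
statistics and synthetic panel generation.

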