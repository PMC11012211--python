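# Methods

## Scope and model

`dcmvus` operationalises a reanalysis procedure for rare variants
(gnomAD MAF < 1%) in dilated cardiomyopathy genes that were previously
classified as VUS under the ACMG framework. It deliberately models only
the frequency-driven subset of that framework — PM2 rarity, a BS1-style
benign-frequency demotion, and a three-way stratification of residual
ambiguity — because those are the criteria a periodic population-frequency
update can move. The other ACMG criteria (PVS1 splice logic, PS3
functional-assay grading, PP1 segregation counting, in-silico predictor
aggregation) are out of scope; their net effect enters only through two
curated inputs: the four-level evidence status and the
corroborated-pathogenic flag.

All frequencies are in percent, matching how clinical reanalysis tables
print gnomAD MAF. Absence from gnomAD is a distinct state, not 0.0: an
absent variant satisfies PM2 and falls in the very-low frequency bin.

## The decision procedure

Rules fire in order; exactly one branch fires per record, and the branch
name is emitted as a rule trace.

1. **LB demotion** (`maf_demotion`): MAF present and ≥ `lb_promotion_cutoff`.
2. **LP promotion** (`lp_promotion`): ClinVar LP/P **and** PM2
   (MAF absent or ≤ `pm2_cutoff`) **and** `corroborated_pathogenic`.
3. **Subclassification tree**: off-panel genes → VUS (`off_panel`);
   otherwise by (MAF bin, evidence status):

   | bin \ status | none | supportive | equivocal | conflicting |
   |---|---|---|---|---|
   | very low (<0.005 or no MAF) | VUS-LP | VUS-LP | VUS | VUS |
   | low (0.005–0.04) | VUS-LP | VUS-LP | VUS | VUS-LB |
   | medium (>0.04) | VUS-LB | VUS-LB | VUS-LB | VUS-LB |

The engine requires `prior_class` in the VUS family and never emits B or
P: definitive calls at the extremes need evidence types it does not model.

### Thresholds (percent MAF)

| parameter | default | meaning |
|---|---|---|
| `very_low_cutoff` | 0.005 | ceiling observed for definitively pathogenic variants in inherited arrhythmia syndromes; lower edge of the low bin |
| `pm2_cutoff` | 0.01 | PM2 rarity criterion |
| `medium_cutoff` | 0.04 | familial-DCM prevalence ≈ 1/2500; upper edge of the low bin |
| `lb_promotion_cutoff` | 0.1 | outright demotion to LB; BS1-style benign frequency |
| `rare_cutoff` | 1.0 | cohort inclusion filter (validation only) |

`lb_promotion_cutoff` is a package choice rather than a published
constant: in the reference cohort the five demoted variants span MAF
0.185–0.827% while the highest non-demoted MAF is 0.075%, so any cutoff
in (0.075, 0.185] reproduces the demotions; 0.1% is the conventional BS1
operating point for dominant cardiomyopathies and sits in that interval.
It is configurable, as are all thresholds and both gene lists
(YAML/JSON via `EngineConfig`).

**Boundary ties.** The bin definitions are strict on both sides
(< 0.005, > 0.04), leaving the exact boundary values formally unassigned;
the engine assigns both to the LOW bin. PM2 is inclusive (≤ 0.01) and the
demotion cutoff is inclusive (≥ 0.1). These tie rules are unit-tested and
configurable only through the cutoffs themselves.

### Evidence model

The tree's evidence axis needs four levels — none / supportive /
equivocal / conflicting — not three: the reference cohort contains pairs
of variants identical in ClinVar code and MAF bin that received different
subclassifications, which forces an explicit "data exist but are
uninformative" middle state. When no curated review is supplied, the
status defaults from the ClinVar code: no record → none; VUSc
(conflicting submissions) → conflicting; B/LB → conflicting (a benign
assertion contradicts a pathogenic hypothesis); VUS/LP/P → supportive.
This default mapping was selected by exhaustive search as the one
maximising row-level agreement with the reference cohort's published
labels; explicit per-row curation always takes precedence.

In the shipped cohort, 7 of 125 rows carry a curated override (five TTN
missense and one TTN/one DSP row where the reviewed literature was
equivocal rather than the code-implied default, and one TTN missense with
supportive data despite a ClinVar-LB code), and 10 ClinVar-LP rows carry
the corroborated flag that licenses promotion. The overrides were fitted
by the same exhaustive search and are committed in the fixture's
`data_status`/`corroborated` columns; the engine reads them like any
other input and never sees the `expected_2023` column.

### Off-panel genes

The tree's first node is definite gene–disease association, but the
procedure's source material never states the outcome for an off-panel
gene. The engine keeps such records at plain VUS — the conservative
reading — and flags them (`off_panel` trace, validation warning).

## Consequence taxonomy

Variants are bucketed by molecular footprint from the HGVS strings alone:
frameshifts are indels (the driving lesion is the inserted/deleted bases),
stop-loss extensions are grouped with nonsense (both alter the stop
codon), UTR changes with intronic (non-coding), and the exon-level
gross-deletion token `del ex. N_M` is an indel. This grouping is the only
one consistent with the reference cohort's published per-type totals. The
classifier validates shape, not biology: residue letters are matched as
three-letter tokens without checking them against the amino-acid alphabet
(clinical tables contain transcription slips such as `IIe` for `Ile`),
and positions are not checked against any transcript. Full HGVS
validation and normalisation are non-goals.

## Cohort analytics

Aggregation works on exact integer counts; percentages are display-only
(two decimals, half-up) because published roundings are not always
self-consistent. Patient categories partition LP carriers into LP-only
and LP-plus-VUS-LP, and count VUS-LP carriers *without* any LP variant
separately — the literal "patients with a VUS-LP" reading would
double-count the overlap; both counters are exposed.

One documented inconsistency in the source material: a prose paragraph
describes 63 deleterious-leaning variants (44/11/7/1 by type) where the
printed table gives 67 (48/10/7/2). The table is treated as authoritative;
the 63-variant figure is not re-derivable from the per-variant data and is
excluded from reports.

## Synthetic cohorts

The generator emulates the *structure* of a DCM reanalysis table: a
zero-truncated Poisson number of variants per patient (mean 2, matching
125 variants across 65 patients), MAF drawn log-uniform over
10⁻⁴–0.9% with a 25% absent-from-gnomAD fraction (cohort MAFs span four
orders of magnitude, so uniform sampling would starve the very-low bin),
a ClinVar mix dominated by VUS/VUSc/no-record, HGVS strings synthesised
per consequence class at arbitrary positions, and a 3% off-panel decoy
(MYBPC3). It does **not** emulate a realistic mutational spectrum, gene
length effects, linkage between variants, or trio structure — so passing
tests on synthetic cohorts demonstrate the engine's logical invariants
(conservation, MAF monotonicity, oracle equivalence, I/O round-trips) at
scale, not calibration against real-world class frequencies.

## Verification strategy

The engine is checked two independent ways: cell-by-cell against an
exhaustively enumerated decision table, and row-by-row on the reference
cohort against its published 2023 labels (all 125 reproduce; rows that
resisted reproduction under any evidence assignment would be surfaced,
and there are none). The enumeration keys on five frequency strata rather
than the three public bins, because two threshold rules cut across the
bins (PM2 splits the low bin at 0.01; demotion splits medium at 0.1);
five strata make every rule a pure function of the stratum, keeping the
lookup exact for any record. Property tests (hypothesis, derandomised)
cover MAF monotonicity — holding evidence fixed, a higher MAF never moves
a call toward pathogenic — plus idempotence of the engine on its own
VUS-family output and permutation invariance of the aggregates. The
acceptance script re-runs the full pipeline on the embedded cohort and a
>10,000-row synthetic cohort in well under a minute on one CPU.

## Known limitations

* Evidence enters as curated table columns; there are no live gnomAD or
  ClinVar queries, so reanalysis is only as current as the input table.
* Gene symbols are compared case-insensitively but not alias-resolved.
* The subclassification is DCM-specific (the 0.04% prevalence threshold,
  the 19-gene panel); porting to another disease means re-deriving both.
* VUS-LP/VUS-LB express tendency only and are deliberately excluded from
  any actionable category.
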