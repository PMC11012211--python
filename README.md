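# dcmvus

Reinterpretation of ambiguous genetic variants in dilated cardiomyopathy
(DCM).

Roughly half of DCM is inherited, yet most rare variants found in
diagnostic panels end up classified as *variants of uncertain significance*
(VUS) under the ACMG framework — not actionable for the patient or their
relatives. Much of that ambiguity is an artefact of stale population
frequencies: gnomAD grows every year, and a variant that looked rare at
first report may now be demonstrably too common to cause a dominant
cardiomyopathy (or rarer than ever thought, strengthening a pathogenic
case). `dcmvus` implements a periodic-reanalysis engine for clinical
genetics groups working on DCM cohorts: it re-evaluates every prior VUS
call against updated allele frequencies and a curated evidence review, and
stratifies whatever ambiguity remains.

## The decision procedure

All frequencies are gnomAD minor allele frequencies (MAF) **in percent**;
"no MAF" (absent from gnomAD) is treated as maximally rare. For each rare
variant (MAF < 1%) previously classified as a VUS, three rules fire in
order:

1. **Demotion to likely benign (LB)** — MAF ≥ 0.1%: too common for a
   dominant cardiomyopathy allele.
2. **Promotion to likely pathogenic (LP)** — ClinVar asserts LP/P, the
   PM2 rarity criterion is met (no MAF or MAF ≤ 0.01%), and corroborating
   functional/ancillary evidence is on file.
3. **VUS subclassification** — the rest stay formally VUS but are
   stratified by a decision tree on three axes:
   * *definite gene–disease association*: variants in genes outside the
     19-gene definite-DCM panel (ACTC1, ACTN2, BAG3, DES, DSP, FLNC, JPH2,
     LMNA, MYH7, NEXN, PLN, RBM20, SCN5A, TNNC1, TNNI3, TNNT2, TPM1, TTN,
     VCL) remain plain VUS;
   * *evidence status* from the literature review: none / supportive /
     equivocal / conflicting;
   * *MAF bin*: very low (< 0.005% or no MAF), low (0.005–0.04%), medium
     (> 0.04%, the familial-DCM prevalence of ~1/2500).

   Medium-frequency variants lean benign (VUS-LB); very rare variants with
   no or supportive data lean deleterious (VUS-LP); conflicting data pushes
   toward VUS-LB at low frequency and to unresolved VUS when very rare.

VUS-LP and VUS-LB are *tendencies*, not clinical calls: the engine never
emits B or P, and no management decision should rest on a subclassified
VUS. Every output row carries a rule trace naming the branch that fired,
so each call is auditable from the row's own fields.

The package also ships a consequence classifier (missense / nonsense /
indel / intronic from HGVS c./p. strings; frameshifts count as indels,
stop-loss with nonsense, UTR with intronic), cohort analytics (class ×
type cross-tabs, per-gene and per-year breakdowns, per-patient carrier
counts), a seeded synthetic-cohort generator, and an exhaustively
enumerated decision-table oracle used to cross-check the engine.

## Worked example

The package embeds a reference cohort: 125 rare variants (all prior VUS,
2016–2019) in 65 unrelated DCM patients across 16 definite genes, with
curated evidence columns.

```sh
python examples/reclassify_cohort.py
```

```
cohort: 125 rare variants, 65 patients
left the VUS category: 15 (5 demoted to LB by updated gnomAD frequency, 10 promoted to LP)
still ambiguous: 110 -> VUS-LP 67, VUS 16, VUS-LB 27
patients with an LP variant: 10 (LP only: 6, LP plus a VUS-LP: 4)
patients whose most suspicious finding is a VUS-LP: 44
```

12% of the cohort's ambiguity resolves by the frequency update alone; of
what remains, 67/110 variants lean deleterious and 27/110 lean benign.
The ten LP carriers gain a genetic diagnosis; the 44 VUS-LP-only carriers
are flagged for close follow-up. `examples/titin_subanalysis.py` restricts
the report to TTN (81 variants), and `examples/synthetic_stress_test.py`
audits every engine call on a 2,000-patient synthetic cohort against the
enumerated decision table.

The same pipeline is available from a shell:

```sh
dcmvus fixture --output cohort.tsv
dcmvus classify --input cohort.tsv --output classified.tsv
dcmvus report classified.tsv
dcmvus simulate --patients 100 --seed 1 --output synthetic.tsv
```

Input is a TSV (one row per variant per patient; `NA` for missing; MAF in
percent); thresholds and the gene panel are overridable via
`--config thresholds.yaml`.

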