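# ckdcohort

Rule-based EHR phenotyping of chronic kidney disease (CKD) and the
conditions that put patients at risk for it — hypertension (HTN),
diabetes mellitus (DM) and prediabetes — from flat-file extracts of
longitudinal electronic health records. It is written for registry
builders and health-services researchers who need a reproducible,
auditable implementation of a two-tier cohort definition:

* **Repository** (permissive tier): a patient enters on *any single*
  qualifying measure — one eGFR < 60 mL/min/1.73 m², UACR ≥ 30 mg/g,
  UPCR ≥ 150 mg/g, HbA1c ≥ 5.7 %, random glucose ≥ 140 mg/dL, fasting
  glucose ≥ 100 mg/dL, one blood pressure ≥ 140 systolic or ≥ 90
  diastolic, any diagnosis code for one of the four conditions, or any
  anti-hyperglycemic prescription.
* **Registry** (strict, guideline-based tier), evaluated only for
  repository members; flags are *not* mutually exclusive:
  * **CKD** — two eGFR < 60 at least 90 days apart, **or** two
    albuminuria-range labs (UACR ≥ 30 or UPCR ≥ 150) at least 90 days
    apart, **or** one CKD diagnosis code in any setting.
  * **HTN** — two readings with SBP ≥ 140 or DBP ≥ 90 at least 14 days
    apart (configurable to a strict > 14), **or** one HTN diagnosis code.
  * **DM** — one HbA1c ≥ 6.5 %; or two random glucoses ≥ 200 mg/dL, or
    two fasting glucoses ≥ 126 mg/dL, each pair at least 1 day but no
    more than 2 years apart; or one anti-hyperglycemic prescription
    (insulin, sulfonylurea, thiazolidinedione, DPP-4 inhibitor, GLP-1
    agonist, SGLT2 inhibitor, metformin); or two outpatient DM codes on
    distinct dates; or one inpatient DM code. Patients whose only DM
    evidence is metformin prescribed alongside a polycystic ovarian
    syndrome (PCOS) diagnosis are excluded from the DM flag.
  * **Prediabetes** — one HbA1c in 5.7–6.4 %; or two random glucoses in
    140–199 mg/dL or two fasting glucoses in 100–125 mg/dL within the
    same 1-day-to-2-year window; or any prediabetes diagnosis code.

eGFR is materialized from serum creatinine with the 2009 CKD-EPI
creatinine equation for adults,

```
eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age
         · 1.018 [female] · (1.159 [Black], optional, off by default)
```

(κ = 0.7/0.9 and α = −0.329/−0.411 for females/males), and with the
bedside Schwartz equation `eGFR = 0.413 · height(cm) / Scr(mg/dL)` for
children (< 18 completed years at the draw, nearest height within a
365-day window). Patient zip codes map through a zip → RUCA (Rural-Urban
Commuting Area) crosswalk to a binary urban/rural classification, with a
separate `unclassified` bucket so the three categories always partition
the cohort. A STROBE-style attrition report counts candidates →
repository → registry with per-condition subtotals.

A seeded synthetic cohort generator (`ckdcohort.synthetic`) plants
qualifying patterns, one-clause-off near-misses, PCOS-exclusion and
pediatric scenarios with ground-truth labels defined by construction; it
is the package's built-in test bed and demo input.

## Worked example

Generate a 300-patient synthetic cohort and phenotype it in one run:

```
ckdcohort phenotype --synthetic --n 300 --seed 42 --out demo/
cat demo/attrition.txt
```

```
Participant flow
  candidate records ............ 300
  repository (any single measure) 208
  registry (guideline criteria) . 168
  condition subtotals (not mutually exclusive):
    CKD ........................ 30
    hypertension ............... 91
    diabetes ................... 38
    prediabetes ................ 50
  DM cleared by PCOS-metformin exclusion: 3
  residence:
    urban ...................... 94
    rural ...................... 200
    unclassified ............... 6
  config hash: 5fdcc05265be
```

208 of 300 patients have at least one qualifying measure (the rest are
background-only records); 168 of those meet at least one strict
condition rule, and the condition subtotals (30 + 91 + 38 + 50 > 168)
overlap because one patient can carry several conditions. Three
patients' only diabetes evidence was metformin with a PCOS code, so
their DM flag was cleared. Per-patient flags with the pathway that fired
each rule are in `demo/registry.csv`, e.g.

```
patient_id,in_repository,in_registry,ckd,htn,dm,prediabetes,...,ckd_pathway,...
P000000,True,True,True,False,False,False,...,lab_pair_egfr,...
P000001,True,True,True,False,False,False,...,lab_pair_albuminuria,...
```

and the full evidence trail (every event that fired a pathway) is in
`demo/evidence.csv`. `ckdcohort synth` writes a cohort plus ground-truth
labels without phenotyping it; `ckdcohort phenotype --in dir/` runs on
existing tables; `ckdcohort report --out demo/` re-prints the flow.
Thresholds, temporal windows, ICD prefix lists, the medication lexicon,
eGFR constants and geography files are all overridable from a YAML file
passed via `--config`; the resolved configuration and its hash are
recorded in `manifest.json`.

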