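# mrdflow

Standardized, one-tube, fixed-gate measurable residual disease (MRD)
detection for acute myeloid leukemia (AML) flow cytometry, following a
LAIP-based different-from-normal (DfN) strategy.

After induction chemotherapy, leukemic cells persisting below the 5%
cytomorphologic blast threshold ("measurable residual disease") predict
relapse, but conventional flow-cytometric MRD analysis relies on
investigator-individualized gates and suffers poor inter-rater
reliability.  `mrdflow` implements a reproducible alternative for
laboratories and method developers: a hierarchical gating cascade over a
single eight-antibody tube (CD7, CD13, CD33, CD34, CD45, CD56, CD117,
HLA-DR plus scatter) in which only the pre-gates are adjustable and every
disease-defining gate is fixed.

## The method

1. **Gating.** Doublets (FSC-A/FSC-H) and debris are excluded; CD45⁺
   leukocytes form the denominator *N*<sub>CD45</sub>; progenitors +
   monocytes (P/M) and lymphocytes are gated on CD45/SSC; P/M events
   expressing CD13 and/or CD33 ("myP/M") are split by the backbone markers
   CD34, CD117 and HLA-DR into 8 main populations, each crossed with 4
   aberrant categories — deficiency of CD13 or CD33 (true absence), strong
   cross-lineage CD7 or CD56 — giving **32 monitored subpopulations**
   (24 of them with a marker of immaturity, CD34⁺ and/or CD117⁺).
2. **Reference values.** For each subpopulation, the upper limit of the
   one-sided 97.5% reference range of its %CD45⁺ frequency across
   leukemia-free controls (bone-marrow donors, ALL in molecular CR,
   hip-surgery patients, untreated PCNSL), with attribution of each value
   to the subcohort that drives it.
3. **MRD calling.** At diagnosis a category affecting ≥10% of myP/M is a
   LAIP (aLAIP).  At follow-up only subpopulations with ≥20 events are
   analyzed; the sample is MRD⁺ when any subpopulation exceeds its
   reference.  Excesses (percentage points of CD45⁺) are summed per
   category and the largest sum is the MRD load.  Positivity by a
   diagnostic aLAIP category is a reoccurrence; a de-novo category is
   post-treatment DfN (ptDfN).  Alternative schemes: ELN-style flat 0.1%
   cutoff on the immature compartment, an immature-only reference scheme,
   and a Lo/Hi split at an excess of 0.1.
4. **Reliability.** Krippendorff's α (nominal, interval or ratio metric)
   for multi-rater agreement on MRD status or subpopulation percentages.
5. **Simulation.** A synthetic bone-marrow generator (normal constituents,
   cohort-dependent background aberrancies, leukemic clones at arbitrary
   residual fractions) with *exact* ground truth, so every stage is
   testable without patient data.

## Worked example

```sh
python examples/03_mrd_call.py
```

builds a reference panel from 20 simulated controls, plants a
CD34⁺CD117⁺HLA-DR⁻ clone with strong CD7 at 40% of CD45⁺ at diagnosis and
0.5% at follow-up, and prints:

```
MRD report (mrdflow-report/1)
sample: patient_fu
gating: 200000 events, 196000 singlets, 180000 CD45+, 23287 P/M, 23287 myP/M
MRD status: POS  (load 0.4981% via CD7pos, Hi, origin aLAIP_only)
ELN scheme: pos; ImmOnly scheme: pos
positive subpopulations (pct > reference):
  CD34+CD117+HLA-DR-CD7+: 0.5000% (ref 0.0019%, burden 0.4981)
```

The clone is recovered at its planted frequency (0.5% of CD45⁺), the
burden is its excess over the control-derived reference, and the origin is
classified as a reoccurring diagnostic aLAIP rather than a de-novo
aberrancy.  The other examples cover gating (`01`), reference estimation
with cohort attribution (`02`), inter-rater reliability (`04`) and
rare-event detectability (`05` — a reference of 0.001% of CD45⁺ requires
2,000,000 CD45⁺ events to yield the 20-event minimum).

A thin CLI wraps the same functions:

```sh
mrdflow simulate --kind lfc --n-samples 20 --out lfc/
mrdflow reference --manifest manifest.csv --out panel.json
mrdflow call --events followup.csv --diagnosis dx.csv --reference panel.json
mrdflow irr --ratings ratings.csv --metric nominal
```

## Layout

- `src/mrdflow/` — library (`panel_io`, `fcs`, `gating`, `populations`,
  `reference`, `mrd`, `irr`, `synthetic`, `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — model, parameters, design choices, limitations
- `tests/` — pytest suite (unit, property and acceptance tests)
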