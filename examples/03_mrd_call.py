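"""Full MRD call on a simulated diagnosis / follow-up pair.

A CD34+CD117+HLA-DR- clone with strong cross-lineage CD7 is planted at 40%
of CD45+ at diagnosis and 0.5% at follow-up; the diagnostic aLAIP profile
then classifies the follow-up positivity as reoccurrence (aLAIP) rather
than de-novo appearance (ptDfN).
"""

from mrdflow import CloneSpec, GateConfig, estimate_reference, generate_lfc_cohort, generate_patient_pair, label_events, run_pipeline, tabulate

config = GateConfig()

cohort = generate_lfc_cohort(n_samples=20, seed=7, config=config, n_events=60_000)
panel = estimate_reference([
    tabulate(label_events(ev, config), cohort_label=ev.cohort_label)
    for ev, _ in cohort
])

clone = CloneSpec(backbone=(True, True, False),
                  categories=frozenset({"CD7pos"}), fraction=0.40)
(dx, _), (fu, _) = generate_patient_pair(
    clone, residual_fraction=5e-3, seed=11, config=config, n_events=200_000
)

report = run_pipeline(fu, config, panel, diagnosis_events=dx)
print(report.to_text())
print("\nThe MRD load is the excess over the reference summed within the "
      "leading aberrant category, in percentage points of CD45+ events.")
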