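"""Outlier recovery: clustered assays hidden among null assays.

Injects two assays whose actives are jittered copies of template
conformers into a background of eight null assays, then flags assays
whose NN-NI ComboT separation exceeds mu + sigma across assays.
"""

from combotan import AssayPlan, GeneratorConfig, evaluate_study, find_outliers, synthesize_study

plan = tuple(AssayPlan() for _ in range(8)) + tuple(
    AssayPlan(category="confirmatory", mode="clustered", sigma=0.25) for _ in range(2)
)
study = synthesize_study(GeneratorConfig(seed=6, n_compounds=60, assay_plan=plan))
result = evaluate_study(study.conformers, study.assays)

report = find_outliers(result.per_aid)
clustered = sorted(aid for aid, t in study.truth.items() if t["mode"] == "clustered")
lo, hi = report.bounds["combo_stopt"]
print(f"ComboT(shape-opt) NN-NI bounds across assays: [{lo:.3f}, {hi:.3f}]")
print("true clustered assays:", clustered)
print("flagged upper-bound outliers:", sorted(report.upper["combo_stopt"]))

# Upper-bound outliers are assays whose active/active pairs are markedly
# more 3-D similar than their active/inactive pairs - exactly the
# compound-series structure the clustered generator injects.
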