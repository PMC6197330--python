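"""Metabolite panel models: interaction terms, PCA, and the patient LMM.

First fits per-metabolite ~ genotype * treatment linear models on a log2
panel where 8 of 40 metabolites carry a genotype x treatment interaction
(the treatment rescues the mutant difference).  Then fits the paired patient
mixed model y ~ age + treatment + (1|patient) on 5 patients sampled on and
off treatment and tests the treatment effect with a chi-square(1) LRT.
"""

import eisakit as ek
from eisakit.metabolites import (
    fit_interaction_lm,
    patient_panel_lmm,
    pca_scores,
    transform_panel,
)

design = ek.make_metabolite_design(n_per_group=5)
truth = ek.make_metabolite_truth(
    [f"met_{i:02d}" for i in range(40)], seed=41, n_interaction=8,
    interaction_size=1.0, sigma=0.2,
)
panel = ek.simulate_metabolites(design, truth, seed=41)

log_panel = transform_panel(panel, "log2")
fits = fit_interaction_lm(log_panel, design.genotype, design.treatment)
hits = fits.index[fits.interaction_padj <= 0.05]
planted = set(truth.loc[truth.beta_interaction != 0, "feature"])
print(f"interaction hits at FDR 0.05: {len(hits)} "
      f"({len(planted & set(hits))} of {len(planted)} planted)")

pca = pca_scores(log_panel)
print("variance explained by PC1/PC2:",
      pca["variance_explained"].iloc[:2].round(3).to_list())

p_truth = ek.make_patient_truth(
    [f"aa_{i}" for i in range(6)], seed=43, beta_treatment=0.8,
    sigma_b=0.5, sigma_e=0.25,
)
patients = ek.simulate_patients(5, p_truth, seed=43)
lmm = patient_panel_lmm(patients)
print("\npatient panel LMM (treatment effect per metabolite):")
print(lmm[["beta_treatment", "lrt_stat", "pvalue", "padj"]].round(4))
# beta_treatment estimates the within-patient off-minus-on shift; the
# random intercept absorbs each patient's baseline
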