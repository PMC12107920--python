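# Shipped model catalogue and default-mode correspondence table.
#
# 16 models: 8 built-in patch-level classifiers, 2 custom patch-level
# classifiers, 3 built-in MIL slide-level models, 2 attention-MIL biomarker
# models, 1 custom MIL tissue classifier. Biomarker and survival models are
# on-demand only (default_eligible: false); the flag is per model so sites
# can change the policy. The correspondence table is illustrative and
# site-configurable. Patching geometry for the attention-MIL path is
# 224 px at 1.14 microns per pixel; patch-level entries carry the
# per-model geometry their deployment config would supply.

models:
  # ---- patch-level, built-in ----
  - name: pancancer-lymphocytes-inceptionv4.tcga
    task_kind: patch_binary
    classes: [lymphocyte-negative, lymphocyte-positive]
    target_class: lymphocyte-positive
    visualization: measurement
    toolbox: wsinfer
    builtin: true
    purpose: tissue
    patching: {patch_size_px: 100, spacing_mpp: 0.5}
  - name: breast-tumor-resnet34.tcga-brca
    task_kind: patch_binary
    classes: [no-tumor, tumor]
    target_class: tumor
    visualization: measurement
    toolbox: wsinfer
    builtin: true
    purpose: tissue
    patching: {patch_size_px: 350, spacing_mpp: 0.25}
  - name: lung-tumor-resnet34.tcga-luad
    task_kind: patch_multiclass
    classes: [lepidic, benign, acinar, micropapillary, mucinous, solid]
    visualization: color
    toolbox: wsinfer
    builtin: true
    purpose: tissue
    patching: {patch_size_px: 350, spacing_mpp: 0.5}
  - name: pancreas-tumor-preactresnet34.tcga-paad
    task_kind: patch_binary
    classes: [tumor-positive]
    target_class: tumor-positive
    visualization: measurement
    toolbox: wsinfer
    builtin: true
    purpose: tissue
    patching: {patch_size_px: 350, spacing_mpp: 1.0}
  - name: prostate-tumor-resnet34.tcga-prad
    task_kind: patch_multiclass
    classes: [grade3, grade4or5, benign]
    visualization: color
    toolbox: wsinfer
    builtin: true
    purpose: tissue
    patching: {patch_size_px: 175, spacing_mpp: 0.5}
  - name: lymphnodes-tiatoolbox-resnet50.patchcamelyon
    task_kind: patch_binary
    classes: [nomets, mets]
    target_class: mets
    visualization: measurement
    toolbox: wsinfer
    builtin: true
    purpose: tissue
    patching: {patch_size_px: 96, spacing_mpp: 1.0}
  - name: colorectal-tiatoolbox-resnet50.kather100k
    task_kind: patch_multiclass
    classes: [background, normal_colon_mucosa, debris,
              colorectal_adenocarcinoma_epithelium, adipose, mucus,
              smooth_muscle, cancer_associated_stroma, lymphocytes]
    visualization: color
    toolbox: wsinfer
    builtin: true
    purpose: tissue
    patching: {patch_size_px: 224, spacing_mpp: 0.5}
  - name: colorectal-resnet34.penn
    task_kind: patch_multiclass
    classes: [epithelium, stroma, tumor, necrosis, dysplasia]
    visualization: color
    toolbox: wsinfer
    builtin: true
    purpose: tissue
    patching: {patch_size_px: 224, spacing_mpp: 0.5}

  # ---- patch-level, custom ----
  - name: prostate-resnet18-caputo
    task_kind: patch_binary
    classes: [negative, positive]
    target_class: positive
    visualization: measurement
    toolbox: wsinfer
    builtin: false
    purpose: tissue
    patching: {patch_size_px: 224, spacing_mpp: 0.5}
  - name: hpv-resnet50-merolla
    task_kind: patch_binary
    classes: [HPV negative, HPV positive]
    target_class: HPV positive
    visualization: measurement
    toolbox: wsinfer
    builtin: false
    purpose: tissue
    patching: {patch_size_px: 224, spacing_mpp: 0.5}

  # ---- slide-level, built-in MIL ----
  - name: pancancer-tp53-mut.tcga
    task_kind: slide_mil_class
    classes: [wildtype, mutant]
    visualization: density
    toolbox: wsinfer-mil
    builtin: true
    purpose: biomarker
    default_eligible: false
    patching: {patch_size_px: 224, spacing_mpp: 1.14}
  - name: gbmlgg-survival-porpoise.tcga
    task_kind: slide_mil_survival
    classes: [logits-time0, logits-time1, logits-time2, logits-time3]
    visualization: density
    toolbox: wsinfer-mil
    builtin: true
    purpose: survival
    default_eligible: false
    patching: {patch_size_px: 224, spacing_mpp: 1.14}
    risk: {formula_id: logit_sum, median_threshold: 0.0}
  - name: kirp-survival-porpoise.tcga
    task_kind: slide_mil_survival
    classes: [logits-time0, logits-time1, logits-time2, logits-time3]
    visualization: density
    toolbox: wsinfer-mil
    builtin: true
    purpose: survival
    default_eligible: false
    patching: {patch_size_px: 224, spacing_mpp: 1.14}
    risk: {formula_id: logit_sum, median_threshold: 0.0}

  # ---- slide-level, attention-MIL biomarker models ----
  - name: braf-attMIL-marugoto
    task_kind: slide_mil_class
    classes: [MUT, WT]
    visualization: density
    toolbox: marugoto
    builtin: false
    purpose: biomarker
    default_eligible: false
    patching: {patch_size_px: 224, spacing_mpp: 1.14}
  - name: msi-attMIL-marugoto
    task_kind: slide_mil_class
    classes: [MSIH, nonMSIH]
    visualization: density
    toolbox: marugoto
    builtin: false
    purpose: biomarker
    default_eligible: false
    patching: {patch_size_px: 224, spacing_mpp: 1.14}

  # ---- slide-level, custom ----
  - name: colorectal-mil-angeloni
    task_kind: slide_mil_class
    classes: [low-grade dysplasia, high-grade dysplasia, adenocarcinoma, other]
    visualization: density
    toolbox: wsinfer-mil
    builtin: false
    purpose: tissue
    patching: {patch_size_px: 224, spacing_mpp: 1.14}

correspondence:
  - {tissue: breast, stain: H&E, model: breast-tumor-resnet34.tcga-brca}
  - {tissue: breast, stain: H&E, model: pancancer-lymphocytes-inceptionv4.tcga}
  - {tissue: lung, stain: H&E, model: lung-tumor-resnet34.tcga-luad}
  - {tissue: pancreas, stain: H&E, model: pancreas-tumor-preactresnet34.tcga-paad}
  - {tissue: prostate, stain: H&E, model: prostate-tumor-resnet34.tcga-prad}
  - {tissue: prostate, stain: H&E, model: prostate-resnet18-caputo}
  - {tissue: lymph node, stain: H&E, model: lymphnodes-tiatoolbox-resnet50.patchcamelyon}
  - {tissue: colorectal, stain: H&E, model: colorectal-tiatoolbox-resnet50.kather100k}
  - {tissue: colorectal, stain: H&E, model: colorectal-resnet34.penn}
  - {tissue: colorectal, stain: H&E, model: colorectal-mil-angeloni}
  # biomarker models are listed so sites flipping default_eligible get them
  # in default mode too; with the shipped flags they are filtered out.
  - {tissue: colorectal, stain: H&E, model: braf-attMIL-marugoto}
  - {tissue: colorectal, stain: H&E, model: msi-attMIL-marugoto}
  - {tissue: oropharynx, stain: H&E, model: hpv-resnet50-merolla}
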