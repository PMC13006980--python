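# gatedsurv

Cancer-type-aware multimodal survival modelling under missing modalities.

`gatedsurv` implements a discrete-time hazard model that fuses three
patient-level data modalities — histopathology whole-slide-image patch
embeddings (2048-d, the always-available anchor), bulk-RNA embeddings
(256-d, optional) and clinical-text embeddings (768-d, optional) — through
an availability-masked gated fusion layer, a shared transformer encoder and
cancer-type-specific hazard heads. It is aimed at methods researchers in
computational oncology and biostatistics who want a compact, fully
inspectable reference implementation of this class of model, together with
the evaluation protocols that matter in practice: missing-modality stress
tests, train/validation/test split sensitivity, institution-grouped
(tissue-source-site) validation, and a multi-seed statistical comparison
harness. All experiments run on synthetic cohorts with plantable prognostic
signal; no external data are required.

## Model

Each modality is projected into a shared d = 32 embedding space,

    Z_m = Dropout(ReLU(x_m W_mᵀ + b_m)),   m ∈ {img, rna, txt},

with zero-tensor substitution for unavailable modalities. A bias-free gate
maps the concatenated embeddings to three logits L; availability is imposed
by an additive penalty with the binary mask M (image column always 1),

    L_masked = L + (1 − M) ⊙ (−10⁹),     G = softmax(L_masked),

so absent modalities receive vanishing weight and the remaining weights
renormalise. The fused embedding Σ_m G_m ⊙ Z_m passes through a shared
pre-norm transformer encoder; a per-cancer head then emits T = 4 per-bin
hazards ĥ = σ(W_c h + b_c), from which the survival curve is
Ŝ(t) = Π_{k≤t}(1 − ĥ_k). Training minimises the censored discrete-time
negative log-likelihood (events contribute −[log Ŝ(τ−1) + log ĥ_τ],
censored patients −log Ŝ(τ)) with structured modality dropout, and
performance is measured by the concordance index over comparable pairs
(ties in risk credited ½). The network runs on a small NumPy reverse-mode
autodiff core in float64, so every number is bit-reproducible per seed.

## Worked example

```python
import gatedsurv as gs

cohort, truth = gs.generate_cohort(
    gs.SimConfig(n_patients=300, cancer_types=("BRCA", "LUAD")), seed=42
)
fit = gs.MultimodalSurvivalModel(cohort).fit(
    train_config=gs.TrainConfig(epochs=30, seed=42), seed=42
)
print(fit.summary())
```

```
Multimodal discrete-time survival fit
=============================================
cancer types: 2  time bins: 4  fusion: gated
split: patient 4:2:4  seed: 42
epochs run: 30  best val C-index: 0.861 (epoch 23)

test C-index by cancer type
---------------------------------------------
  BRCA         n=60    C-index 0.836
  LUAD         n=60    C-index 0.824
---------------------------------------------
  mean (unweighted)      C-index 0.830
```

The cohort has a planted log-linear risk signal; scoring the *true* latent
risks on the same test split gives the oracle ceiling (here 0.845), so the
fitted model recovers almost all of the available prognostic information.
Per-patient output includes the hazard/survival curves, the scalar risk
(−Σ_t Ŝ(t), higher = worse prognosis) and the learned fusion weights:

```
patient_id cancer_type  hazard_1   surv_4      risk    w_img    w_rna    w_txt
    P00002        BRCA  0.399816 0.065138 -1.416199 0.261435 0.466345 0.272220
    P00009        LUAD  0.027316 0.555372 -3.160732 0.232865 0.493984 0.273152
```

`w_img/w_rna/w_txt` are the per-patient gate weights; when a modality is
masked at evaluation time its weight collapses to ~0 and the rest
renormalise. The command-line interface mirrors the library
(`gatedsurv simulate | preprocess | train | evaluate | sweep-missing |
stats | run-all`), writing a JSON run manifest next to every artifact.

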