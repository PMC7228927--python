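# stxseg

Automated segmentation of intratumoural regions from saturation-transfer
MRI, with quantitative magnetization-transfer (MT) modelling and
CEST/relayed-NOE isolation.

Tumour xenografts are heterogeneous: active tumour, necrotic/apoptotic
tissue, and blood/edema coexist within one lesion, and bulk-averaging a
whole tumour blurs exactly the physiology (metabolism, cellularity,
macromolecular content) that saturation-transfer MRI is sensitive to.
`stxseg` segments these regions automatically from a single-slice
saturation-transfer study — T1/T2 maps plus Z-spectrum images over a
range of saturation amplitudes B1 and frequency offsets Δω — and then
quantifies each region's two-pool MT parameters and aggregate
chemical-exchange (CEST/NOE) contribution.  It is written for
preclinical imaging groups who want a tested, scriptable reference
implementation of this pipeline, including a synthetic phantom cohort
generator so every stage can be validated without animal data.

## Method

1. **Preprocessing** — linear signal-drift correction from interleaved
   667-ppm reference scans; per-voxel B0 mapping from a Lorentzian fit to
   the WASSR spectrum, Z(Δω) = 1 − AΓ²/(Γ² + (Δω − δ0)²); recentring of
   the low-B1 spectra on the direct-effect peak of a two-Lorentzian fit;
   T1 from inversion recovery, S(TI) = a + b·e^(−TI/T1); T2 from the
   WASSR dip via the steady-state direct-saturation signal
   S = S0·R1(R2² + Δω²)/(R1(R2² + Δω²) + ω1²R2); normalization of all
   images to a common 0–1 scale (T1/4000 ms, T2/300 ms, Z = S/S0); mask
   erosion.
2. **Segmentation** — pooled-cohort observation matrix (m voxels × n
   image types) → FastICA unmixing → components ordered by normalized
   mutual information against the mean protocol image → five-cluster
   full-covariance Gaussian mixture (cluster count validated by the BIC
   gradient) → rule-based assignment of clusters to tissues (blood/edema
   anchored on its extreme component mean; the rest ranked along the
   tissue-graded component: muscle, muscle/connective,
   necrosis/apoptosis, active tumour).  Robustness by leave-one-out
   retraining; protocol choice by correlating segmentation-derived
   necrosis fractions with a histology-style reference; exhaustive
   image-subset search for reduced protocols.
3. **Quantification** — per-cluster two-pool MT fit (free T2A, R, M0B,
   T2B; super-Lorentzian semisolid lineshape, Lorentzian for
   blood/edema; MT effect reported as the product R·M0B), extrapolated
   inter-cluster contrast spectra, and exchange isolation via the
   extrapolated MT reference: MTR_AREX = 1/Z_lab − 1/Z_EMR and
   AREX = MTR_AREX/T1_obs.

The model details, generator design, and numerical choices are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a four-subject synthetic cohort, preprocess it, segment it, and
compare with the known truth:

```python
import numpy as np
from stxseg import make_cohort, simulate_study, preprocess_study, segment_cohort
from stxseg.validation import necrosis_fraction

truths = make_cohort(4, seed=11)
studies = [preprocess_study(simulate_study(t)) for t in truths]
seg = segment_cohort(studies, "t1t2_high_b1", k_ics=3, k_clusters=5, seed=0)

for t in truths:
    labels = seg.label_maps[t.subject_id]
    mask = labels > 0
    acc = np.mean(labels[mask] == t.label_map[mask])
    ml = necrosis_fraction(labels)
    print(f"{t.subject_id}: accuracy {acc:.3f}  "
          f"necrosis fraction {ml:.3f} (truth {t.true_necrosis_fraction:.3f})")
```

prints

```
phantom000: accuracy 1.000  necrosis fraction 0.472 (truth 0.472)
phantom001: accuracy 1.000  necrosis fraction 0.207 (truth 0.207)
phantom002: accuracy 1.000  necrosis fraction 0.115 (truth 0.115)
phantom003: accuracy 1.000  necrosis fraction 0.216 (truth 0.214)
```

i.e. every in-mask voxel of each subject received the correct tissue
label, and the segmentation-derived necrotic fraction of each tumour
(necrotic voxels over tumour + necrotic voxels) matches the generator's
ground truth.  At default noise (SNR ≈ 100) the phantom classes are
well separated; accuracy degrades gracefully as noise rises.

The same pipeline is available from the shell:

```
stxseg simulate --subjects 10 --seed 0 --out cohort/
stxseg preprocess cohort/phantom000 --out prep/phantom000   # per subject
stxseg segment prep/ --protocol t1t2_high_b1 --ics 3 --out seg/
stxseg loo prep/ --out loo.csv
stxseg qmt cohort/phantom000 seg/phantom000_labels.nii.gz --out qmt.csv
stxseg arex cohort/phantom000 seg/phantom000_labels.nii.gz --out arex.csv
```

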