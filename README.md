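# cranioface

Region-fusion craniofacial reconstruction: estimating a person's face
surface from their skull surface using learned, region-specific skull–face
shape relations.

Craniofacial reconstruction supports forensic identification and
archaeology: given an unknown skull, predict the soft-tissue face that
covered it. Because the relation between bone and soft tissue differs
between craniofacial regions (orbits, nose, mouth, the facial frame), a
single global statistical model smears these differences. `cranioface`
instead:

1. **segments** corresponded skull/face training meshes into five regions
   (left eye, right eye, nose, mouth, frame) with fuzzy c-means clustering
   on robust-PCA vertex features;
2. **embeds** each region of each modality in a low-dimensional latent
   space with a Gaussian process latent variable model (GP-LVM) under an
   ARD squared-exponential kernel,
   `k(x,x') = σ_f² exp(−½ Σ_d (x_d−x'_d)²/M_d)`;
3. **regresses** skull latent coordinates to face latent coordinates per
   region with least-squares support vector regression (LSSVR), whose
   training reduces to one dense KKT solve
   `[[0, 1ᵀ],[1, Ω + I/C]]·[b; α] = [0; y]` with RBF Gram matrix
   `Ω_ij = exp(−‖x_i−x_j‖²/2σ²)`, optionally conditioning on z-scored age
   and BMI;
4. **fuses** the five regional face predictions into one smooth mesh:
   orthogonal-Procrustes rigid positioning, graph-distance boundary bands,
   and a pair of 3-D thin-plate splines per seam that meet exactly at the
   midpoint targets `P₂ = (P₀+P₁)/2`.

Reconstruction quality is measured by `averageError`, the mean Euclidean
distance (mm) between corresponding vertices of the reconstructed and true
face.

Paired skull/face CT datasets are not publicly distributable, so the
package ships a first-class synthetic generator (`cranioface.synthetic`)
producing corresponded head-mesh populations with known region-wise latent
structure, planted age/BMI soft-tissue effects and controllable noise; all
end-to-end claims are tested against it.

## Worked example

```bash
python examples/03_train_and_reconstruct.py
```

trains on 60 synthetic pairs (~1,600 vertices per mesh) and evaluates on 12
held-out skulls:

```
Reconstruction errors (averageError, mm)
    region   min_mm   max_mm  mean_mm    sd_mm
     frame 0.353424 2.611060 0.957864 0.746740
  left_eye 0.438497 2.209565 1.019525 0.585112
     mouth 0.363724 1.997483 0.925302 0.541749
      nose 0.461778 3.055732 1.197228 0.779776
 right_eye 0.528454 2.848872 1.155053 0.755040
fused_face 0.473870 2.359546 1.033089 0.606974

mean test averageError: regional 1.033 mm,  global 1.486 mm,  mean-face predictor 2.546 mm
```

The fused regional reconstruction (1.03 mm mean error) beats both the
global single-region pipeline (1.49 mm) — the same machinery without the
regional decomposition — and the skull-blind population-mean-face
predictor (2.55 mm). `examples/04_attribute_effects.py` shows the
attribute response: reconstructing one skull at BMI 30 instead of BMI 20
moves the face outward by ≈2 mm on average.

The other examples cover population generation (`01`) and segmentation
(`02`). A thin CLI wraps the same pipeline for shell use:

```bash
cranioface simulate --seed 7 --out data/
cranioface train --data data/ --out model/
cranioface reconstruct --model model/ --skull data/s000_skull.obj --out face.obj
cranioface evaluate --model model/ --test data/ --out report/
```

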