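# gyroshape

Elastic shape analysis of wearable gyroscope trajectories for motor-function
assessment in pediatric neuromuscular disease.

Clinical monitoring of Duchenne muscular dystrophy (DMD) and spinal muscular
atrophy (SMA) still leans on subjective ordinal scales.  Wrist-worn IMUs
record angular-velocity curves for simple activities of daily living (arm
curls, knocking), but raw curves confound *what* a movement looks like with
*how fast and when* it is performed — children repeat the same motion at
different rates, and growing limbs change signal scale.  `gyroshape`
implements the shape-based pipeline that untangles this:

1. **Elastic registration** in the square-root velocity function (SRVF)
   representation q = sign(β̇)·√|β̇|.  Time warps γ act as (q∘γ)√γ̇ — an
   L2 isometry — so the optimal alignment of β₂ to β₁ solves

       γ* = argmin_γ ‖q₁ − (q₂∘γ)√γ̇‖,

   by dynamic programming over monotone lattice paths plus a smooth local
   refinement.  The attained minimum is the amplitude distance d_a(β₁, β₂),
   invariant to how fast either movement was performed.
2. **Phase–amplitude separation** about the Karcher mean
   μ̂ = argmin_q Σᵢ min_γ ‖q − (qᵢ∘γᵢ)√γ̇ᵢ‖², decomposing every repetition
   into a phase γᵢ* and an amplitude β̃ᵢ with βᵢ = β̃ᵢ∘γᵢ*.
3. **Shape (vertical) PCA** on the aligned SRVFs: SVD of their covariance
   yields orthonormal directions U_k and subject scores c_ik = ⟨qᵢ, U_k⟩
   (vertical principal components, VPCs).  On activity data VPC1 reads out
   movement speed and VPC2 motion asymmetry.
4. **A bootstrapped PLS motor-function index**: canonical-mode partial least
   squares links the four wearable features (VPC1/VPC2 × curl/knock) to
   clinical measures (age, muscle echogenicity, normalized elbow torque,
   Brooke score); 70/30 subject-level bootstrap replicates give the held-out
   canonical-correlation distribution; the first X-side weight vector is the
   index.  A random-intercept mixed model tests age × cohort interactions
   (two-sided Wald, Benjamini–Hochberg, α = 0.01), and the same bootstrap
   harness benchmarks the aligned features against unaligned functional PCA
   and NMF.

Because no wearable dataset of this kind is publicly deposited, the package
ships a first-class synthetic cohort generator (`gyroshape.simulate`) with
cohort-dependent speed/asymmetry latents, random time warps, multi-visit
structure, and clinical covariates tied to the latents — every stage of the
pipeline is testable against known ground truth.

## Worked example

```python
from gyroshape import (CohortConfig, generate_cohort, separate_phase_amplitude,
                       bootstrap_pls, repeated_shape_pca)
from gyroshape.pca import fit_shape_pca
from gyroshape.index import DEFAULT_Y_VARS

cfg = CohortConfig(seed=5)                  # 15 DMD, 7 SMA, 9 healthy
trajs, clinical, truth = generate_cohort(cfg)

curls = [t for t in trajs if t.activity == "curl"]
sep = separate_phase_amplitude(curls)
model = fit_shape_pca(sep.aligned_srvfs, n_retained=3, activity="curl")
print((100 * model.variance_fractions).round(1))   # [97.4  1.3  0.8]

embedding = repeated_shape_pca(trajs, n_runs=10, n_retained=2, seed=6)
feats = [c for c in embedding.columns if c.startswith("VPC")]
patients = embedding.merge(clinical[clinical.cohort.isin(("DMD", "SMA"))],
                           on="subject_id").dropna(subset=list(DEFAULT_Y_VARS))
index = bootstrap_pls(patients[feats], patients[list(DEFAULT_Y_VARS)],
                      n_boot=2000, seed=7)
lo, hi = index.intervals["5-95"][:, 0]
print(round(index.medians[0], 2), (round(float(lo), 2), round(float(hi), 2)))
# 0.91 (0.67, 0.96)
```

The variance line says VPC1 (speed) dominates amplitude variability in this
cohort; the last line is the bootstrapped median held-out canonical
correlation of the motor-function index with the clinical block and its
5–95% percentile interval — high here because the synthetic clinical
covariates are built from the same latents the wearable features recover.
Run the scripts in `examples/` for narrated, single-capability versions of
each stage (alignment, separation, PCA modes, the index, the full
pipeline).

A thin CLI mirrors the pipeline for shell use:

```bash
gyroshape simulate --seed 3 --out study/
gyroshape report --trajectories study/trajectories.csv \
                 --clinical study/clinical.csv --seed 3 --out study/results
```

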