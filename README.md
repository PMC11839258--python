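# pmgait

Principal-movement decomposition and local dynamic stability analysis of
treadmill walking kinematics.

## The problem

How stable is human walking, and which parts of the gait cycle does speed
affect?  A common experimental design records 3-D marker trajectories while
participants walk on a treadmill at several fractions of their preferred
walking speed (PWS), e.g. 40%–145% in eight steps, with both young and
older adults.  `pmgait` implements the full analysis chain for such data,
for movement scientists and biomechanists who want a tested, scriptable
alternative to ad-hoc MATLAB pipelines:

1. **Posture vectors.** Each frame's 13 lower-body markers (39
   coordinates) form a posture vector p(t).  Per trial, vectors are
   centered on the mean posture and scaled by the mean Euclidean distance
   ‖p(t) − p̄‖, removing marker-placement and anthropometric differences.
2. **Principal movements (PMs).** All trials are pooled into one matrix
   and the covariance is eigendecomposed.  Eigenvector PC_k is a
   whole-body movement pattern ("principal movement" PM_k, resembling a
   gait-cycle phase); the score series PP_k(t) = PC_kᵀ p(t) is its
   position in posture space, and the relative explained variance
   rVAR_k = 100·var(PP_k)/Σ_j var(PP_j) its share of the coordination
   structure.  Principal accelerations PA_k(t) are the second derivative
   of PP_k after a third-order zero-phase 7-Hz low-pass Butterworth
   filter.  Leave-one-subject-out refits verify that the retained PMs
   (default: first five) are robust.
3. **Local dynamic stability.** Each PP_k(t) is delay-embedded
   (τ = 10 samples, m = 4 by default; average mutual information and
   false-nearest-neighbor diagnostics are built in) and the largest
   Lyapunov exponent λ₁ is estimated with Wolf's fiducial-trajectory
   algorithm.  Lower λ₁ = better attenuation of the small perturbations
   of steady walking = higher local dynamic stability.
4. **Statistics.** Mixed (split-plot) repeated-measures ANOVA — speed
   (8 within levels) × age group (2 between levels) — with
   Greenhouse–Geisser correction, partial η², observed power, Bonferroni
   post hoc paired t-tests (α = 0.006), Shapiro–Wilk normality screening,
   Pearson speed–stability correlations, and the matching a-priori
   noncentral-F power analysis.

A synthetic-cohort generator produces marker data with the same
statistical structure (shared stride harmonics, per-subject variation,
measurement noise) plus an optional chaotic component of *known* largest
Lyapunov exponent (a time-scaled Lorenz signal, ground-truthed by an
independent Benettin variational integrator), so every stage of the
pipeline is testable without any motion-capture data.

## Worked example

```python
import numpy as np
import pmgait

# a-priori power analysis for the 2x8 mixed design
n = pmgait.required_sample_size(effect_f=0.25, alpha=0.05, power=0.95,
                                n_groups=2, n_measures=8, corr=0.5, epsilon=1.0)
print(f"required participants: {n}")

# synthetic cohort -> principal movements -> stability
spec = pmgait.SyntheticCohortSpec(n_subjects=6, duration_s=20.0, seed=1)
trials = pmgait.generate_cohort(spec)
pooled = pmgait.pool([pmgait.preprocess_trial(t) for t in trials])
basis = pmgait.fit_basis(pooled, k_retained=5)
print("explained variance (%):",
      np.round(100 * basis.explained_variance_ratio[:5], 2))

scores = [pmgait.principal_accelerations(s)
          for s in pmgait.project_pooled(basis, pooled)]
rvar = pmgait.participant_rvar(scores, k_retained=5)
print(rvar.head(3).to_string(index=False))

lye = pmgait.stability_table(scores[:2], k_retained=3)
print(lye[["subject", "condition", "pm", "lye"]].round(3).to_string(index=False))
```

prints

```
required participants: 24
explained variance (%): [42.06 30.32 10.18  6.64  4.73]
subject age_group condition  pm metric     value
    S01     young       100   1   rvar 42.308690
    S01     young       100   2   rvar 29.651049
    S01     young       100   3   rvar 11.550687
subject condition  pm    lye
    S01        40   1 -0.237
    S01        40   2 -0.257
    S01        40   3  0.117
    ...
```

Reading: 24 participants suffice for the design's target power; the first
five pooled PMs carry ~94% of the postural variance (PM₁ alone 42%);
subject S01's trial at 100% PWS distributes its own variance similarly;
and the per-trial Wolf exponents (nats/s) are near zero for this mostly
periodic synthetic gait — slightly negative values mean the estimator
found net convergence at the sampled scales, positive values net
divergence (less stable).

The same pipeline runs from the shell:

```bash
pmgait run-all --config run.yaml --out results/
```

with a YAML config selecting the input (synthetic spec or cohort CSV +
participant metadata), marker layout, retained PMs, filter, embedding and
statistics settings.  Outputs are `rvar_table.csv`, `lye_table.csv`,
`anova_table.csv`, `posthoc_table.csv`, `correlation_table.csv`,
`robustness_table.csv` and a `manifest.json` with content hashes; reruns
with the same seed are byte-identical.

## Layout

| module | contents |
| --- | --- |
| `pmgait.synthetic` | cohort generator, Lorenz trajectory, Benettin oracle |
| `pmgait.io` | cohort CSV / C3D readers, result-table schemas |
| `pmgait.posture` | posture vectors, centering/normalization, pooling |
| `pmgait.decomposition` | PM basis, scores, rVAR, accelerations, spectra, LOO robustness |
| `pmgait.stability` | AMI, FNN, delay embedding, Wolf λ₁ |
| `pmgait.stats` | mixed RM-ANOVA, post hoc, correlations, power analysis |
| `pmgait.pipeline` / `pmgait.cli` | orchestration, `pmgait` command |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
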