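# stnprofiler

Parametric profiling of cellular state transitions from one-dimensional
flow-cytometry measurements.

Flow cytometry time courses — DNA-content histograms across a synchronized
cell cycle, or a marker's expression while sorted subpopulations relax back
toward their parent distribution — show subpopulations that are asymmetric,
heavy-tailed, and transient: they appear, swell, and vanish between time
points. `stnprofiler` models each sample as a finite mixture of **skew
t-Normal (STN)** components,

```
psi(y | xi, sigma^2, lambda, nu) = 2 t(y | xi, sigma^2, nu) Phi(lambda (y - xi) / sigma)
```

a Student-t kernel (location `xi`, scale `sigma^2`, df `nu`) skewed by a
standard-normal cdf factor (skewness `lambda`). One STN component can absorb
an asymmetric, outlier-prone population that would otherwise cost several
Gaussian components, so the fitted mixture's parameters track biologically
meaningful features over time instead of bookkeeping artifacts.

The package provides, as a library plus a thin `stnprofiler` command:

- **ECM/ECME fitting** of g-component STN mixtures (`fit_ecme`), with
  closed-form conditional M-steps, an optional shared degrees-of-freedom
  update that maximizes the observed likelihood directly (CML), and Aitken
  acceleration stopping (`|l - l_inf| < 1e-6` by default).
- **Greedy model-order selection** (`greedy_fit`): insert one component at a
  time — a 19-quantile global search scored by a second-order Taylor
  approximation of the inserted log-likelihood, partial-EM refinement of the
  new component only, acceptance while the exact gain beats a penalty
  (default `m = 2.5 log n`). Work per insertion scales as O(n g r) for r
  grid candidates.
- **Entropy merging** (`merge_path`, `select_num_clusters`): post-fit,
  iteratively merge the pair of clusters maximizing the assignment-entropy
  reduction, and read the cluster count off the entropy-versus-k elbow. The
  mixture density is invariant; only the grouping of components changes.
- **Profile comparison** (`ks_distance`, `kl_distance`, `gap_statistic`,
  `compare_profiles`): goodness of fit D_n against the fitted cdf, BIC,
  Kullback-Leibler divergence between fitted profiles, and the Gap statistic
  of the hard clustering.
- **I/O and simulation**: single-channel FCS 2.0/3.0/3.1 reading (and a
  minimal writer), one-value-per-line text, JSON model documents, and a
  seeded generator of cell-cycle-like and clonal-relaxation time courses
  with known ground truth.

## Worked example

Fitting a synthetic two-population sample (`python examples/01_fit_single_sample.py`):

```
converged=True after 3237 iterations, loglik=-3661.44, BIC=7391.29
component 1: w 0.40->0.392  xi 0.0->-0.008  sigma2 1.0->0.935  lam +4.0->+3.42  nu 5->5.1
component 2: w 0.60->0.608  xi 6.0->6.002  sigma2 1.5->1.626  lam -3.0->-3.31  nu 5->3.9
```

Both locations are recovered to about 0.01, the weights to under 0.01, and
the skewness estimates keep their generating signs — the right-skewed and
left-skewed populations are identified, not just their means.

Profiling a five-point synthetic DNA-content course
(`python examples/04_temporal_profile.py`):

```
t    true_g  fit_g      D_n       BIC   KL_vs_t0
  0    2       2     0.0112    20268.1   0.0000
  1    3       3     0.0062    21417.2   0.4971
  2    3       3     0.0083    21320.5   0.7172
  3    3       3     0.0098    21353.4   0.4542
  4    2       2     0.0150    20164.8   0.0044
```

The greedy fit discovers the transient S-phase-like subpopulation exactly
when it exists (g rises from 2 to 3 and back), D_n stays near the sampling
noise floor (~1.36/sqrt(n) = 0.03), and the KL divergence from the first
time point rises and falls with the transient's weight.

The other examples cover greedy selection on three separated populations
(`02`), entropy merging of an overfitted two-cluster sample (`03`), and FCS
round-tripping (`05`). The same steps are scriptable from a shell:

```
stnprofiler simulate --scenario cell-cycle -o course/
stnprofiler greedy course/t4.txt -o model.json
stnprofiler merge course/t4.txt model.json -o merged.json
```

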