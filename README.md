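# sporemorph

Landmark-based geometric morphometrics for crescent-shaped myxospores.

Myxozoans (microscopic parasitic cnidarians) are described and compared
almost entirely through the size and shape of their myxospores, yet the
standard practice reduces a spore to a handful of linear measurements —
length, thickness, posterior angle.  `sporemorph` implements the full
geometric-morphometrics treatment of ceratomyxid-type spores in sutural
view for researchers studying intraspecific shape variation in these
parasites: an eight-landmark scheme constructed from the spore outline,
generalized Procrustes analysis (GPA), decomposition of shape variation
into symmetric (among-spore) and asymmetric (between-valve) components,
digitization quality control, morphospace PCA with thin-plate-spline
deformation grids, and Procrustes ANOVA/ANCOVA with residual-randomization
permutation (RRPP) inference.

Because micrograph-derived landmark data for such studies are rarely
deposited, the package ships a first-class synthetic spore-population
generator: a parametric crescent family (circular-arc centerline, tapered
width profile) with valve-bending and width modes, lognormal size with
host effects, allometry, bilateral-asymmetry noise and per-replicate
digitization noise.  Its default calibration emulates a study of 107
spores from five fish hosts (20/16/19/17/35) digitized twice.

## The model in brief

For landmarks **x**₁…**x**₈ per spore, centroid size is
CS = √Σᵢ|**x**ᵢ − x̄|².  GPA removes location, size and orientation,
leaving Procrustes shape coordinates near the consensus; statistics run in
the tangent space.  Object symmetry splits the tangent space into exact
orthogonal complements: the symmetric subspace (variation among spores)
and the asymmetric subspace (variation between the two shell valves of a
spore).  Hypotheses are tested with sequential (type I) sums of squares
based on Procrustes distance,

    shape_sym ~ size * host        (Procrustes ANCOVA)
    size      ~ host               (Procrustes ANOVA)

with p-values from RRPP (reduced-model residuals permuted, 10,000
iterations) and effect sizes Z on the log-F scale, plus a permutational
test of multivariate dispersion as the homogeneity check.

## Worked example

The `analysis/` scripts run the whole study on the default synthetic
cohort, writing tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_superimposition.py
python analysis/04_symmetry_decomposition.py
python analysis/05_morphospace.py
python analysis/06_shape_models.py
```

Output of the run at the frozen default seed (cohort-level numbers vary a
little from seed to seed):

```
repeatability (mean ICC over 16 coordinates): 0.9949
% measurement error (replicate variance share): 0.173%
...
tangent-space adequacy: slope 0.99262, uncentered correlation 0.999978
centroid size: mean 27.1 µm, CV 15.2%, range [16.8, 40.3]
...
symmetric (among-spore) component: 79.5% of total shape variance
asymmetric (between-valve) component: 20.5%
...
PC variance (%): [66.58 17.49  9.01  5.44  0.67  0.34]
PC1 dominated by ['L7', 'L3', 'L1'] ([34.8 31.6 14.8]%) - the posterior-angle landmarks
PC2 dominated by ['L5', 'L4', 'L6'] ([31.1 24.5 15.5]%) - the spore-length landmarks
...
Procrustes ANCOVA: symmetric shape ~ size * host (10000 permutations)
            df      SS      MS     Rsq     F       Z      p
size         1  0.4463  0.4463  0.1922 26.73   3.084 0.0001
host         4   0.213 0.05326 0.09173  3.19   1.931 0.0127
size:host    4 0.04335 0.01084 0.01867 0.649 -0.2931 0.6514
```

Reading the numbers: landmark placement is highly repeatable (ICC ≈ 0.995)
and contributes < 1 % of the phenotypic variance, so the configurations
are fit for analysis.  Most shape variation (~80 %) is shared by both
shell valves; the rest is left/right asymmetry.  PC1 (posterior-angle
landmarks) and PC2 (length landmarks) carry ~84 % of the variance.  Spore
size affects shape (allometry, p = 1e−4), host identity affects shape
after controlling for size, and the allometric slope is shared across
hosts (non-significant interaction) — with no evidence of dispersion
heterogeneity among hosts.

The same machinery is scriptable, e.g.:

```python
from sporemorph import (default_calibration, sample_population,
                        digitize_replicates, gpa, tangent_projection, pca)

spec = default_calibration()
cohort = sample_population(spec)
dataset = digitize_replicates(cohort, 2, spec)
result = gpa(dataset.replicate_mean())
morphospace = pca(tangent_projection(result))
print(morphospace.variance_pct[:3])
```

and a CLI mirrors the stages
(`sporemorph simulate | digitize | qc | gpa | symmetry | pca | ancova |
dispersion | run`, sharing `--seed`, `--config`, `--out`).

## Layout

```
src/sporemorph/      the library: simulate, landmarks, procrustes,
                     symmetry, qc, morphospace, rrpp, io, pipeline, cli
analysis/            numbered study scripts (worked example)
tests/               pytest suite (unit, property and round-trip checks)
scripts/acceptance.py  headline-statistics reproduction
docs/methods.md      models, numerical choices, limitations
```
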