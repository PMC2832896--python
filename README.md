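# nlhvdm — nonlinear hidden-variable dynamic modelling of transcription

A toolkit for inferring a transcription factor's *hidden* activity time
course from expression time series of its target genes, and for screening
putative targets by per-gene kinetic fits.  Microarray (or RNA-seq) time
courses measure mRNA, not protein activity; `nlhvdm` treats the TF activity
p(t) as an unobserved variable and estimates it jointly with gene kinetics —
the hidden-variable dynamic modelling (HVDM) idea, here with a nonlinear
cooperative-binding regulation function and per-gene time delays.  The
canonical application is the p53 network: p53 binds DNA as a tetramer
(Hill coefficient 4) and its consensus site RRRCWWGYYY can be counted on
upstream sequence to corroborate predicted targets.

It is written for computational biologists who have a stimulus–response
expression time course (e.g. 7 time points over 12 h, 3 replicates), a
handful of known targets to train on, and want (i) the TF's activity
profile, (ii) a ranked list of putative targets with activation/inhibition
calls and delays, and (iii) sequence-level corroboration.

## Model

Each target gene i follows the delay ODE

    dx_i/dt = c_i + k_i · f_i( p(t − τ_i) ) − d_i · x_i(t)

    f_i = δ_i·g + (1 − δ_i)(1 − g),    g = [ p^n / (K_i^n + p^n) ]^m

with basal rate c_i, maximal TF-driven rate k_i, half-saturation K_i,
degradation d_i, delay τ_i ≤ 2.5 h and direction δ_i (1 induced,
0 inhibited).  p(t) is a natural cubic spline through activity values at the
measurement times, confined to [0, 1], with p(t − τ) = 0 for t ≤ τ.  For
N = 5 training genes and 7 time points the joint fit has 26 free parameters
(5×4 rates + 6 post-stimulus activity knots), optimised by a real-coded
genetic algorithm with a bounded least-squares polish, best of 10 restarts.
Screening then fixes p(t) and fits (c, k, K, d, η, τ) per gene — η ∈ [−1, 1]
selects δ by sign — twice per restart (with and without delay), ranking
genes by relative model error ε = Σ(u−x)²/Σx².  See `docs/methods.md` for
the full treatment.

## Worked example

Generate a 5-gene synthetic panel with known ground truth (pulse-shaped
activity, measurement noise σ = 0.1), infer the activity, then screen:

```
$ nlhvdm synth --genes 5 --noise 0.1 --frac-inhibited 0 --delays 0 \
      --well-conditioned --seed 3 --out expr.tsv --truth truth.json
wrote 5 genes x 7 time points to expr.tsv

$ nlhvdm infer-activity --expr expr.tsv --seed 1 --out activity.tsv --fit-json fit.json
objective 0.0002501 over 10 runs; 26 free parameters

$ cat activity.tsv
# config_hash=51cc018d57cf
# seed=1
# objective=0.000250085
time    activity      ci_low        ci_high
0       0             0             0
2       0.13462282    0.14966419    0.20480243
4       0.58681111    0.66503259    0.94424906
6       1             1             1
8       0.28950926    0.39651591    0.77728923
10      0.11935098    0.11953151    0.12278616
12      5.4095716e-35 0.0001843949  0.00086334808
```

The `activity` column is the best-of-10-restarts estimate in the unit-peak
gauge (activity and K are only jointly identified up to a common scale, so
every run is normalised to peak 1); `ci_low`/`ci_high` is the 2.5/97.5
percentile band across restarts.  The generating profile for this seed had
knot values (0, 0.22, 0.78, 1.00, 0.71, 0.24, 0): the estimate tracks the
rise, peak position and return to baseline — Pearson r = 0.93 against truth
at the knots under this noise level — while the wide band at t = 8 flags the
knot the data constrain least.  The objective 0.00025 is the summed per-gene
relative squared fit error.

```
$ nlhvdm screen --expr expr.tsv --activity activity.tsv --seed 1 --out screen.tsv
screened 5 probes; consensus {'agree': 5, 'disagree': 0, 'undetermined': 0}
```

`screen.tsv` holds one row per probe — error, (c, k, K, d, τ, δ), whether
the delayed fit won, the model's regulation call (+1/−1), the
correlation-method call and the two-way consensus — sorted by error, i.e.
by the strength of evidence that the TF drives the gene.  Motif support
comes from `nlhvdm motif-scan --fasta upstream.fa --windows 5000,10000`,
which counts perfect RRRCWWGYYY matches per upstream window and bins genes
by count (0/1/2/>2).

All commands accept `--config config.yaml` (GA settings, solver step, search
boxes, thresholds) and `--seed`; outputs carry the config hash and seed, and
identical inputs reproduce byte-identical outputs.

## Library use

The estimators follow scikit-learn conventions:

```python
from nlhvdm import TFActivityEstimator, TargetGeneScreen, make_activity, simulate_panel

truth = simulate_panel(make_activity("pulse"), 5, noise_sd=0.1,
                       delay_choices=(0,), well_conditioned=True, seed=3)
est = TFActivityEstimator(restarts=10, random_state=1).fit(truth.dataset)
est.profile_.knot_values       # inferred activity at the knots
est.kinetics_                  # per-gene GeneKinetics
screen = TargetGeneScreen(random_state=1).fit(truth.dataset, profile=est.profile_)
screen.results_                # error-ranked FitResults
```

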