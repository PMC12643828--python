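# habclust

Unsupervised classification of lateral habenula (LHb) neurons from in
vivo spike trains, with stimulus- and state-modulation analyses.

The LHb encodes aversive signals, and its neurons fire in strikingly
diverse spontaneous patterns — from slow irregular bursting to fast
tonic spiking.  `habclust` implements an end-to-end pipeline that turns
per-neuron spike times into firing phenotypes and asks how those
phenotypes respond to aversive stimuli (foot shocks) and to spontaneous
behavioral-state fluctuations indexed by facial motion energy.  It is
aimed at electrophysiologists with well-isolated single-unit spike
times (e.g., juxtacellular recordings) and at methodologists who want a
fully synthetic, ground-truthed testbed for spike-train clustering.

## The method

1. **Features.**  Per neuron: mean firing rate, ISI coefficient of
   variation CV = SD(ISI)/mean(ISI), burst index (fraction of ISIs
   < 25 ms), the ISI distribution over 0–0.5 s and the spike
   autocorrelogram over ±0.1 s (zero-lag excluded).
2. **Embedding.**  The two histogram banks are z-scored per bin and
   reduced with sparse PCA; the first 8 components of each, plus the
   3 scalars, form a 19-dimensional feature vector per neuron.
3. **Clustering.**  Gaussian mixtures are fitted for k = 1..8 with 100
   restarts each; the Bayesian information criterion
   `BIC = −2 log L + M log N` is averaged over restarts and k is chosen
   at the smallest mean BIC or the saturation point of its gradient.
   Clusters are labelled Type-1..k in order of ascending firing rate.
4. **Matching.**  Clusters from two datasets (e.g. anesthetized vs
   awake) are compared by cosine similarity of centroids in a shared
   feature space and matched one-to-one with the Hungarian algorithm
   (minimising Σ(1−SC)); pairs with SC < 0.6 are rejected.
5. **Modulation.**  Foot-shock responses are quantified by PSTHs
   (−0.2..+1.3 s, 20 ms bins), the foot-shock modulation index
   `FSMI = (FR_stim − FR_base)/(FR_stim + FR_base)`, and the area under
   the z-scored response over the first 300 ms.  Behavioral state is
   partitioned at the 80th/20th percentiles of facial motion energy and
   summarised by `BSMI = (FR_active − FR_quiet)/(FR_active + FR_quiet)`
   with a per-neuron rank-sum significance call at α = 0.05.

A synthetic-data module generates populations of the four published
LHb firing phenotypes (calibrated refractory-gamma renewal processes
with burst insertion), foot-shock sessions with short- and long-latency
response components, and state-coupled sessions — so every stage of the
pipeline is testable against known ground truth without any recordings.
See `docs/methods.md` for the full model description and design
rationale.

## Worked example

Simulate a 280-neuron anesthetized-preset population and cluster it:

```bash
habclust simulate --preset anesthetized --n-per-type 70 --duration 120 \
    --seed 3 --out demo/data
habclust cluster demo/data --seed 3 --out demo/clust
habclust report demo/data demo/clust/labels.csv --out demo/report
```

The cluster step prints `selected k = 4` and writes the BIC curve:

```
 k  bic_mean  bic_ci_low  bic_ci_high
 1    7244.5      7244.5       7244.5
 2    2455.6      2176.0       2735.2
 3     207.0        30.4        383.6
 4   -1181.4     -1302.7      -1060.0
 5    -610.5      -659.8       -561.2
 6      33.7       -31.5         98.8
```

The mean BIC falls steeply up to four components, is minimal there, and
rises again — four firing phenotypes, each recovered with its 70
neurons.  The per-type summary shows the four phenotypes in rate order
(slow-bursty, slow-regular, fast-regular, fast-bursty):

```
 type  n  rate_mean  rate_sd  cv_mean  cv_sd  burst_index_mean  burst_index_sd
    1 70      2.094    0.198    1.517  0.115             0.224           0.022
    2 70      3.433    0.121    0.704  0.031             0.003           0.003
    3 70     10.641    0.213    0.742  0.019             0.030           0.004
    4 70     19.555    0.369    0.948  0.030             0.240           0.008
```

From Python, the modulation indices converge to their analytic values —
a stimulus that triples the firing rate during its window gives
FSMI → (3−1)/(3+1) = 0.5:

```python
from habclust import ResponseSpec, generate_fs_session, compute_fsmi

resp = ResponseSpec.from_window_gain(3.0, n_trials=150)
train, trials = generate_fs_session(10.0, resp, seed=3)
rec = compute_fsmi(train, trials)
print(f"FSMI = {rec.fsmi:.3f} (baseline {rec.fr_baseline:.1f} Hz, "
      f"stimulus {rec.fr_stimulus:.1f} Hz)")
```

```
FSMI = 0.496 (baseline 10.1 Hz, stimulus 29.9 Hz)
```

The library surface is sklearn-style: `HistogramSparsePCA` and
`BICGaussianMixture` are estimators with `fit`/`transform`/`predict`
and trailing-underscore fitted attributes, and compose with sklearn
pipelines; module-level functions (`compute_fsmi`, `match_clusters`,
`partition_states`, ...) wrap them for one-shot use.

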