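# Methods

`habclust` classifies in vivo single-neuron spike trains from the
lateral habenula (LHb) into firing phenotypes and quantifies how those
phenotypes are modulated by aversive stimuli and by spontaneous
behavioral state.  This note documents the models, the tunable
parameters, the synthetic data the tests rest on, and the numerical
choices made where the procedure was genuinely open.

## Spontaneous-activity features

For each neuron with spike times $t_1 < t_2 < \dots < t_n$ over a
recording of duration $T$ we compute:

- **Mean firing rate** $n/T$ (Hz).
- **ISI distribution** over 0–0.5 s.  Bin width 5 ms (100 bins).  The
  histogram mass is normalised by the *total* ISI count, so intervals
  longer than 0.5 s leave mass outside the binned range; this keeps
  slow cells distinguishable by the mass remaining in range.
- **Coefficient of variation (CV)** = SD(ISI)/mean(ISI), with the
  population (n-denominator) standard deviation.  CV is 0 for
  clock-like firing and ≈1 for Poisson firing.
- **Burst index** = fraction of ISIs strictly shorter than 25 ms.
- **Autocorrelogram (ACG)** over ±0.1 s, bin width 2 ms (100 bins).
  Every ordered spike pair with $0<|\Delta t|\le 0.1$ s increments the
  bin of its lag; zero-lag self-pairs are excluded; counts are divided
  by the number of spikes.  The per-spike normalisation is a
  convention only: the z-scoring applied before embedding removes any
  per-neuron uniform scaling.

Neurons with fewer than 10 spikes are reported but excluded from
clustering (rate is defined, CV/burst are not stable).  Bin widths are
configuration parameters; the defaults resolve the sub-25 ms burst
structure while keeping each histogram bank ~100-dimensional.

## Embedding and clustering

The 19 clustering features per neuron are: rate, CV, burst index, the
first 8 sparse principal components of the ISI histogram bank and the
first 8 of the ACG bank.

**Sparse PCA.**  Each histogram bin column is z-scored across neurons
(constant columns dropped with a warning), then decomposed with
L1-penalised dictionary learning (scikit-learn's mini-batch solver).
The penalty default (1.0) zeroes roughly half of the loading entries
on the synthetic presets; with penalty 0 the transform is exact dense
PCA.  When two datasets are to be compared, the sparse components and
the feature standardization are fitted on the pooled neurons so both
datasets share axes — a prerequisite for centroid matching to be
meaningful.

**Mixture fitting and model selection.**  All 19 features are z-scored
(rate in Hz and unit-free indices are incommensurate) and fitted with
Gaussian mixtures with full covariances (regularisation 1e-6; diagonal
covariance available in config).  For each candidate cluster number
$k$ in 1..8 the EM fit is repeated from 100 randomly seeded k-means
initializations, and

$$\mathrm{BIC} = -2\log L + M\ln N$$

is recorded per restart, where $M$ counts the free parameters of the
chosen covariance structure ($k-1$ weights, $kd$ means,
$kd(d+1)/2$ full covariances).  Restarts are k-means-initialized
because the restart mean of the BIC is otherwise dominated by poor
local optima from random assignments, which destroys the structure of
the BIC-vs-k curve.

The selected $k$ is the smallest whose mean BIC is at the grid minimum
or whose gradient has saturated, operationalised locally: the
improvement gained by stepping into $k$ falls below 10% of the
improvement of the preceding step, with the scan stopping at the grid
argmin so a rising BIC cannot trigger it.  A saturation threshold
relative to the first (1→2) improvement was rejected: that drop is one
to two orders of magnitude larger than every later one, making the
rule fire one step early on sizeable fractions of simulated
populations.  Final labels come from the best-BIC restart at the
selected $k$, then renamed so mean firing rate ascends with the label
index (ties broken by ascending burst index).

Per-feature importance is $|\text{cluster mean} - \text{global mean}|$
in standardized units.  t-SNE is provided for visualisation only and
never feeds the statistics.

## Cluster matching

Clusters fitted separately on two datasets are compared by the cosine
similarity of their centroids in the shared standardized feature space
(raw feature units available as an option).  The Hungarian algorithm
minimises the total dissimilarity $\sum (1-\mathrm{SC})$; unequal
cluster counts are handled by rectangular assignment, leaving extra
clusters unmatched.  Assigned pairs with similarity below 0.6 are
dropped from the accepted set; the comparison is inclusive, so a pair
at exactly 0.60 is retained.

## Foot-shock modulation

PSTHs span −0.2 to +1.3 s around stimulus onset in 20 ms bins (75
bins), pooling counts over trials and dividing by trials × bin width.
The modulation index

$$\mathrm{FSMI} = \frac{FR_{stim} - FR_{base}}{FR_{stim} + FR_{base}} \in [-1, 1]$$

uses the mean rate in the 0.5 s stimulus window versus the 1 s
preceding onset (two different baselines deliberately coexist: the
PSTH window starts at −0.2 s, the FSMI baseline covers −1..0 s).
Rates pool spikes across trials; for equal-length windows this equals
averaging within-trial rates.  Neurons with whole-recording rate below
1 Hz are excluded (they may fire less than one spike per stimulus).
Trials whose windows are truncated by the recording edges are dropped
with a warning, not padded.

The sustained response is the area under the z-scored PSTH over the
first 300 ms (sum of per-bin z times bin width, units z·s).  The
z-score baseline is the PSTH's own pre-stimulus bins (−0.2..0 s, 10
bins); the 1 s FSMI baseline is available as a config alternative.
A flat baseline with zero variance makes the z-score undefined and is
flagged rather than silently zeroed.

## Behavioral-state modulation

Facial motion energy is smoothed with a 0.5 s moving average (to
suppress single-sample flicker epochs) and thresholded at the
session's own 80th/20th percentiles: samples at or above the 80th
percentile form "active" epochs, at or below the 20th "quiet" epochs;
intermediate samples belong to neither.  Comparisons are inclusive so
that discrete traces whose high level coincides with the percentile
still partition; for continuous traces this is a measure-zero detail.
Epochs shorter than 0.5 s are dropped; sessions need ≥10 s in each
state.  Because thresholds are per-session empirical percentiles, the
partition is invariant to monotone rescaling of the motion signal.

$$\mathrm{BSMI} = \frac{FR_{active} - FR_{quiet}}{FR_{active} + FR_{quiet}} \in [-1, 1]$$

with rates pooled over all epochs of a state.  Each neuron is
classified as `increase` / `decrease` / `no_change` by a two-sample
Mann–Whitney rank-sum test on the per-epoch rate vectors at
α = 0.05 (the protocol's "unpaired Wilcoxon signed-rank" is
self-contradictory — the signed-rank test is paired — so the unpaired
reading is implemented for the per-neuron test, matching "active
*versus* quiet"; the population-level contrast across neurons is the
paired signed-rank test).  Fewer than 3 epochs per state yields
`no_change` with an insufficient-data flag.

## Group statistics

Cross-type comparisons: one-way ANOVA with Tukey's HSD post hoc
intervals at α = 0.05, family per feature.  Pairwise relationships:
Pearson correlation with two-sided p.  Tables report mean ± SD.

## Synthetic data

The generator provides ground truth for every stage; its defaults are
the study conditions the analysis targets.

**Spontaneous phenotypes.**  Each type is a renewal process whose ISIs
are `refractory + Gamma(shape, scale)`, optionally interleaved with
bursts: with probability `burst_prob` a base event appends a geometric
run (mean 2) of intra-burst ISIs drawn uniformly from a sub-25 ms
range.  Calibration to a (rate, CV, burst index) target is analytic
and open loop:

1. rate and CV fix the gamma mean and variance in closed form;
2. if the plain gamma base already produces *more* short ISIs than the
   target burst index (the usual case at the published rates), an
   absolute refractory period is solved by a 1-D root find on the
   gamma CDF — refractoriness is also the physiologically natural
   mechanism suppressing short intervals;
3. otherwise bursts are inserted, with the base shape re-solved
   jointly so the *marginal* ISI distribution keeps the target rate
   and CV exactly while the short-ISI fraction meets the target.

The published per-type (rate, CV, burst index) values for both
conditions are built in as presets; all eight calibrate to within a
few percent of their targets at 120 s recordings (the fast, regular,
bursty awake Type-4 corner requires the longer 15–24 ms intra-burst
range).  The Type-2 CV values, not printed directly in the source
tables, are reconstructed from the printed pairwise mean differences.

Within a type, every neuron shares the same parameters: the synthetic
types are *homogeneous*, so within-type feature spread reflects
sampling noise only.  Real LHb types have large between-neuron spread
(published SDs are comparable to the means) and overlap in any single
feature; recovery results on the synthetic presets therefore
demonstrate the machinery (feature extraction, selection rule,
matching) under clean separation, not the difficulty of the biological
classification problem.  The presets also inherit none of the
anesthetic pharmacology; the two conditions are simply alternative
parameter sets.

**Foot-shock sessions** draw spikes from an inhomogeneous renewal
process by time rescaling: a unit-rate gamma renewal process (Poisson
by default) is generated in operational time and mapped through the
inverse cumulative intensity.  Excited responses add two alpha-shaped
kernels $(t/\tau)e^{1-t/\tau}$ peaking at 40 ms and 210 ms after
onset; inhibited responses multiply the intensity by a factor < 1
during the 0.5 s stimulus.  `ResponseSpec.from_window_gain(g)` scales
the kernels so the stimulus-window mean intensity is $g\times$
baseline, which makes the expected FSMI exactly $(g-1)/(g+1)$ — the
identity the tests verify.  Stimuli repeat every 5 s; the default
trial count is 69.

**State sessions** build motion energy as a rectified
Ornstein–Uhlenbeck process (correlation time 2 s, 20 Hz sampling)
smoothed 0.5 s, and multiply the spike intensity by `active_gain`
wherever motion is at or above its session 80th percentile — the same
rule the analysis applies, so the planted BSMI limit is
$(g-1)/(g+1)$.  Between the 20th and 80th percentiles the intensity
stays at baseline, which keeps the quiet-state rate equal to the base
rate.

## Problem sizes and tolerances

End-to-end checks use populations of 280 neurons (70 per type) at
120 s per recording with the full 100-restart budget — the scale at
which a full-covariance 19-dimensional mixture is well determined.
Unit-level pipeline tests use the same population sizes with reduced
restart budgets (10–40) and 90 s recordings.  Feature extraction is
validated bin-for-bin (tolerance 1e-12) against brute-force pair
enumeration on trains of ≤200 spikes; index identities are checked to
±0.05 at ≥100 trials / ≥300 s sessions; the per-neuron state test's
type-I error is required to lie in [0.03, 0.07] over 1000 null
sessions.

## Known limitations

- The synthetic types are homogeneous (see above); ARI near 1 on them
  says nothing about real between-neuron heterogeneity.
- On the awake preset the two slow types (7.15 vs 7.37 Hz, differing
  mainly in burst index and CV) sit at the edge of what full-covariance
  BIC can resolve at 70 neurons per type: the mean-BIC improvement from
  three to four components is within restart noise, so the selected k
  alternates between 3 and 4 across seeds.  The anesthetized preset is
  stable at k = 4.  When four clusters are imposed, both presets
  recover the planted labels essentially perfectly.
- The exact sparse-PCA variant and penalty of the original analysis
  are not reproducible from the available description; component
  shapes are therefore not expected to match figure-for-figure, only
  the subspace behaviour (penalty → 0 equals PCA) is pinned.
- Whether features were standardized before mixture fitting, and
  which baseline feeds the z-scored PSTH, are undocumented upstream;
  both are explicit config switches here.
- BIC with full covariances in 19 dimensions is conservative at small
  n; populations much below ~15 neurons per covariance parameter row
  will under-split regardless of true structure.
- Epoch-rate rank tests treat epochs as exchangeable units; epochs of
  very different lengths make rates heteroskedastic, which the test
  ignores (a 1 s-binned variant is the config alternative).
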