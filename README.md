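# tcdflow

Unsupervised flow-typing of transcranial Doppler (TCD) cerebral blood flow
velocity waveforms.

TCD records the pulsatile blood flow velocity in the large cerebral arteries.
The shape of each beat — an initial systolic upstroke followed by up to three
peaks (P1, P2, P3) and a diastolic runoff — carries diagnostic information:
large-vessel occlusion (LVO) blunts or suppresses this structure.  Clinical
grading of beat morphology (e.g. TIBI flow grades) is subjective; `tcdflow`
implements a fully objective alternative: per-depth recordings are reduced to
normalized average beats, each beat is summarized by three morphological
features, and the feature space is partitioned by spectral clustering with
the gap statistic choosing the number of clusters.  Per-cluster exemplars and
archetypes, and the composition of each cluster by subject group (LVO /
in-hospital control / out-of-hospital control), make the discovered flow
types interpretable.

Since clinical recordings cannot be redistributed, the package includes a
synthetic beat-train generator with four planted morphological flow types
(normal, late-onset, narrow-spike, blunted), heart-rate variability, noise
and artifact beats, used throughout the test-suite as ground truth.

## The method

For each per-depth 30 s recording, beats are segmented at the foot of the
systolic upstroke, artifact beats are removed by iterated interquartile-range
fences on beat length and cross-correlation with the ensemble mean, and the
accepted beats (at least 15, else the recording is excluded) are aligned at
onset, end-padded, and averaged.  The average beat is resampled to 125 Hz,
smoothed with a 90 ms Hanning window, rescaled to [0, 1] in velocity, and
cubic-spline resampled to exactly 100 samples.  From each normalized beat
`x(t_0 .. t_99)` three features are extracted:

* `onset = n : x(t_n) = max_i x(t_i)` — time of maximal velocity;
* `canopy = card{ i : x(t_i) > x(t_0) + 0.25 (x(t_sys) − x(t_dias)) }` — the
  systolic canopy length in samples;
* `peaks = card(TP) + Σ_{k ∈ PP} (1 − |x(t_k) − x(t_k−1)| / 0.01)` — a
  weighted count of true peaks/troughs (sign changes of the successive
  difference within the canopy) and pseudo-peaks (sub-threshold difference
  runs), weighting near-flat structures toward the total.

The z-scored N×3 feature matrix is clustered by normalized spectral
clustering (RBF affinity) for k = 2..7.  The cluster count is selected by the
gap statistic `G_k = E*[log W_k] − log W_k`, where `W_k` is the pooled
intra-cluster dispersion `Σ_r D_r / (2 n_r)` and the reference expectation is
bootstrapped from uniform samples drawn over the data's range in its
right-singular basis; the selected k is the smallest with
`G_k > G_{k+1} − S_{k+1}`.  Within each cluster, members are ranked by mean
squared distance to the other members: the closest is the cluster exemplar,
and the mean of the five closest is the cluster archetype.

## Worked example

Generate a noise-free validation cohort (25 recordings per flow type; the
occlusion-like types III/IV assigned to the LVO group), run the full
preprocessing and clustering path, and compare against the planted types:

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from tcdflow import (FLOW_TYPES, SimConfig, FlowTypeModel,
                     generate_recording, process_recording)

cfg = SimConfig(noise_sd=0.0, artifact_beat_rate=0.0, heart_rate_sd=4.0)
rng = np.random.default_rng(7)
beats, truth = [], []
for ft, spec in FLOW_TYPES.items():
    group = "LVO" if ft in ("III", "IV") else "OHC"
    for i in range(25):
        rec = generate_recording(cfg, spec, rng,
                                 subject_id=f"{ft}{i:02d}", group=group)
        nb, _ = process_recording(rec)
        beats.append(nb); truth.append(ft)

model = FlowTypeModel.from_beats(beats)
res = model.fit(seed=7, k=4)
print(res.summary())
print("agreement with planted flow types:",
      round(adjusted_rand_score(truth, res.labels), 3))
```

Output:

```
Flow-type clustering results
============================================================
observations:       100
selected clusters:  4
cluster sizes:      [25, 25, 25, 25]

cluster composition (% of member waveforms):
  cluster 0: n=25   LVO 100%, IHC 0%, OHC 0%  exemplar=IV10|left|46.6021|85
  cluster 1: n=25   LVO 0%, IHC 0%, OHC 100%  exemplar=I01|left|51.1643|1
  cluster 2: n=25   LVO 100%, IHC 0%, OHC 0%  exemplar=III22|left|46.8736|72
  cluster 3: n=25   LVO 0%, IHC 0%, OHC 100%  exemplar=II14|left|49.8471|39

agreement with planted flow types: 1.0
```

Each planted flow type is recovered as its own cluster; the two
occlusion-like morphologies form 100%-LVO clusters, mirroring the kind of
group-enriched flow types the method is designed to expose.  (Exemplar ids
encode subject, hemisphere, insonation depth and row index.)

Cluster-count selection via the gap statistic, on a planted 3-D feature
cloud:

```python
from tcdflow import generate_feature_cloud, gap_profile, select_k

rng = np.random.default_rng(3)
X, labels = generate_feature_cloud(k=4, n_per_cluster=60, separation=6.0, rng=rng)
profile = gap_profile(X, k_range=range(2, 8), n_boot=100, seed=3)
sel = select_k(profile)
print("gap:", np.round(profile.gap, 2))   # [0.49 0.73 1.43 1.26 1.12 1.02]
print(sel.k, sel.elbow_found)             # 4 True
```

The gap statistic peaks at the planted cluster count and the smallest-k
selection rule returns 4.

## Command line

Every stage is also a `tcdflow` subcommand operating on plain-text files:

```bash
tcdflow simulate --out recs/ --seed 17          # cohort of recording CSVs
tcdflow preprocess --in recs/ --out beats.csv   # normalized average beats
tcdflow features --in beats.csv --out features.csv
tcdflow cluster --in features.csv --out clusters.json --bootstrap 1000 --seed 17
tcdflow report --beats beats.csv --clusters clusters.json --out report/
tcdflow run --config run.yaml --out runs/demo   # all stages + manifest
```

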