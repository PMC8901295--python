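# dtfnet

Brain-network feature extraction and classification for two-class
motor-imagery EEG, built around the **Directed Transfer Function (DTF)**.

Imagining a left- versus right-hand movement changes not only the spectra
of single EEG channels but the *directed information flow* between
channels. `dtfnet` turns multichannel EEG trials into network-flow
features and classifies them:

1. fit a multivariate autoregressive (MVAR) model to each trial,
2. evaluate its DTF connectivity at chosen frequencies,
3. use the directed channel-pair flows as features — optionally fused
   with classical univariate AR coefficients,
4. classify trials with a linear-kernel SVM under stratified tenfold
   cross-validation (or repeated 50/50 splits).

A synthetic MVAR trial generator with *exact* analytic ground-truth
connectivity makes every stage testable without any EEG recordings.

## The model

An `N`-channel trial `S(t)` is modelled as an MVAR(p) process

    S(t) = Σ_{k=1..p}  Λ_k S(t−k) + E(t),

with `Λ_k` the `N×N` lag-`k` coefficient matrices and `E(t)` white noise.
In the frequency domain the characteristic matrix

    A(f) = I − Σ_{k=1..p} Λ_k e^{−j2πfkΔt},   Δt = 1/fs,

has inverse `H(f) = A(f)^{−1}`, the transfer matrix from innovations to
observations. The DTF row-normalises its squared magnitudes:

    γ²_ij(f) = |H_ij(f)|² / Σ_{m=1..N} |H_im(f)|²,

the fraction of total inflow into channel `i` contributed by channel `j`
at frequency `f`. Rows sum to one, every entry lies in `[0, 1]`, and —
because `H` captures cascaded paths — γ² reflects *indirect* as well as
direct coupling. The model order `p` can be fixed or selected by the
multichannel Akaike information criterion. Univariate AR features are the
Burg-estimated coefficients `a_1..a_p` of each channel.

## Worked example

Simulate an 80-trial, 10-channel session in which the two classes differ
only in the *direction* of a three-channel coupling ring (C3→C4→Cz→C3
versus its reverse), then compare feature pipelines:

```sh
cat > two_class.yaml <<EOF
seed: 21
n_channels: 10
n_trials_per_class: 40
trial_seconds: 6.0
EOF
dtfnet simulate --spec two_class.yaml --out trials.npz

cat > run.yaml <<EOF
input: trials.npz
feature: all
freqs: [10, 15, 20, 25, 30]
mvar_order: 2
ar_order: 6
scheme: tenfold-cv
n_repeats: 10
svm_c: 1.0
seed: 1
out_dir: out
EOF
dtfnet run --config run.yaml
```

which prints

```
     config  kind  frequency_hz  n_features  mean_accuracy_pct  sd_accuracy_pct
         ar    ar           NaN          60              55.25        16.300911
   dtf@10Hz   dtf          10.0          90             100.00         0.000000
   dtf@15Hz   dtf          15.0          90             100.00         0.000000
   dtf@20Hz   dtf          20.0          90             100.00         0.000000
   dtf@25Hz   dtf          25.0          90             100.00         0.000000
   dtf@30Hz   dtf          30.0          90             100.00         0.000000
ar+dtf@30Hz fused          30.0         150             100.00         0.000000
```

By construction the ring reversal leaves every channel's *univariate*
spectrum unchanged, so the 60 AR features hover at chance (55%), while
the 90 directed-flow DTF features separate the classes perfectly at every
read-out frequency; fusing the two families keeps the DTF performance.
Each run also writes `out/accuracy_report.tsv` and a `manifest.json`
recording seeds, orders and package versions; the same config and seed
reproduce both byte for byte.

The same comparison is available from Python:

```python
from dtfnet import (SimSpec, make_two_class_trialset, dtf_features,
                    ar_features, train_eval, EvalScheme)

ts, ground_truth = make_two_class_trialset(SimSpec(seed=21))
ft = dtf_features(ts, freqs=(30.0,), mvar_order=2)
res = train_eval(ft, EvalScheme(n_repeats=10, seed=1))
print(res.mean_accuracy)            # 100.0
print(ground_truth[+1].at(30.0))    # analytic class-+1 gamma^2 matrix
```

`ARFeatureExtractor` and `DTFFeatureExtractor` are scikit-learn
transformers operating on `(trials, channels, samples)` arrays, so they
also compose directly with sklearn pipelines and model selection.

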