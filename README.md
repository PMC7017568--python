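# spikegc

Directed-network structure identification for spiking neural data with
linear and nonlinear **conditional Granger causality**, plus the leaky
integrate-and-fire (LIF) network simulator used to benchmark it against
ground truth.

## The problem

Multi-electrode recordings give simultaneous spike trains from many neurons,
but not the wiring between them.  A channel *y* "Granger-causes" a channel
*x* when including y's past improves the prediction of x's future beyond
x's own past.  For a network, each ordered pair is tested *conditionally*
— with the pasts of all remaining channels included in both models — so
direct influences are separated from mediated ones.

Spiking dynamics are strongly nonlinear, so a linear vector-autoregressive
(VAR) predictor underfits.  The nonlinear identification method (NGCIM)
replaces each channel's lag block with radial-basis-function (RBF)
evaluations

  y = w₀ + Σᵢ wᵢ Φ(‖X − cᵢ‖),

with kernels Gaussian `exp(−r²/2σ²)`, reflected sigmoidal
`1/(1+exp(r²/σ²))` or inverse multiquadric `1/√(r²+σ²)`; centers cᵢ come
from k-means, the shared width σ from a k-nearest-neighbour rule over the
centers, and the output weights from least squares.  The causality index for
source *y*, target *x*, conditioning set *Z* is

  F_{y→x|Z} = ln(Σ_reduced / Σ_full),

the log-ratio of residual variances without/with y's block; the reduced
model reuses the identical bases of the retained blocks, so the models are
exactly nested and F ≥ 0.  Presence of each directed edge is decided by a
one-sided F-test at α = 0.01.  The linear baseline (LGCIM) is the same
machinery with raw lag blocks.

The bundled simulator provides ground truth: random sparse directed networks
(each ordered pair connected with probability 0.2), LIF membrane dynamics
τ_m dV/dt = E_m − V + R_m I(t) with exponentially decaying synaptic currents,
threshold/reset/refractory spiking, and 10-ms binning of the resulting spike
trains.

## Worked example

```python
from spikegc.io import make_fixture
from spikegc.pipeline import identify_network, accuracy
from spikegc import conditional_gc

# 3-neuron chain 0 -> 1 -> 2, 120 s of simulated spiking, 10-ms bins
conn, series = make_fixture("chain3", seed=0, duration=120_000.0)
dec = identify_network(series, "ngcim-gf", random_state=0)
print(dec)                 # [[0 0 0]
                           #  [1 0 0]
                           #  [0 1 0]]   (column acts row; matches truth)
print(accuracy(dec, conn)) # 100.0

r = conditional_gc(series.data.astype(float), source=0, target=2, seed=0)
print(r.f, r.p_value, r.decision)
# 0.0013 0.390 False  -> the mediated 0->2 influence is correctly rejected
r = conditional_gc(series.data.astype(float), source=0, target=1, seed=0)
print(r.f, r.p_value, r.decision)
# 0.0057 1.2e-08 True -> the direct 0->1 edge is detected
```

The decision matrix uses the column-acts-row convention: entry `[i, j] = 1`
means channel *j* drives channel *i*.  Accuracy is the percentage of the
n² ordered-pair decisions (diagonal included, fixed to "absent") matching
ground truth — one wrong decision on a 6-node network scores 35/36 = 97.22%.

The same operations are available from a shell:

```sh
spikegc simulate --nodes 6 --ratio 0.2 --duration-s 300 --seed 1 --out-prefix net
spikegc identify --input net_series.csv --method ngcim --kernel gf --out dec.txt
spikegc accuracy --est dec.txt --truth net_B.txt
spikegc experiment --config exp.yaml --out report/
```

## Estimator API

`GrangerNetworkIdentifier` is a scikit-learn-style estimator:

```python
from spikegc import GrangerNetworkIdentifier
est = GrangerNetworkIdentifier(method="rbf", kernel="gf", order=5,
                               alpha=0.01, random_state=0).fit(series.data)
est.decisions_   # binary adjacency, column acts row
est.f_matrix_    # causality indices
est.p_values_    # per-pair significance
```

`RBFRegressor` / `RBFFeatures` expose the RBF fitting pipeline on its own.

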