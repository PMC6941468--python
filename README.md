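# ictolat

Epilepsy lateralization from scalp EEG via source-space functional networks
and node ictogenicity.

Before epilepsy surgery, clinicians must decide which hemisphere — and often
whether one or both — to probe with intracranial electrodes. Scalp ictal EEG
frequently fails to lateralize the epileptogenic zone on visual review.
`ictolat` implements a model-based pipeline that turns 19-channel ictal scalp
EEG into a left/right/inconclusive lateralization hypothesis:

1. **Preprocess** — down-sample to 256 Hz, zero-phase 4th-order Butterworth
   band-pass 1–25 Hz, split into non-overlapping 16-s segments (4096 samples).
2. **Inverse** — eLORETA (exact low-resolution electromagnetic tomography),
   a weighted minimum-norm solution with zero localization error for point
   sources, maps channels to cortical source time series.
3. **Parcellate** — 15 regions of interest covering the default-mode,
   salience and frontoparietal control networks; each ROI is summarized by
   the first principal component of its sources.
4. **Network** — per segment, a 15×15 functional network of phase-locking
   values, `PLV_ij = |1/Ns Σ_k exp(iΔφ_ij(t_k))|`, screened against 99 IAAFT
   surrogates at the 95% level.
5. **Ictogenicity** — each node becomes a theta neuron
   `θ̇_i = 1 − cos θ_i + (1 + cos θ_i) I_i(t)` with
   `I_i = I0 + ξ_i + (K/N) Σ_j a_ji [1 − cos(θ_j − θ_s)]`
   (I0 = −1.2, σ = 0.6). Brain network ictogenicity (BNI) is the fraction of
   time the network spends seizing; the coupling K is calibrated so the
   intact network sits at BNI = 0.5, and node ictogenicity
   `NI_i = (BNI_pre − BNI_post_i)/BNI_pre` scores each ROI by virtual removal.
6. **Lateralize** — segment → seizure → patient consensus over top-NI ROIs,
   concordance bookkeeping (C/D/I) against surgical metadata, and a one-sided
   exact binomial test of whether the useful-prediction rate beats chance.

The clinical recordings behind the original study are not public, so the
package ships a first-class synthetic generator (`ictolat.synth`): a spherical
source space with an analytic dipole forward model, ictal phase-oscillator
sources with a *planted* epileptogenic ROI, and planted 15-node networks —
every stage is testable against known ground truth.

## Worked example

Calibrate and score a planted 15-node network (focus at node 3, couplings
scaled ×10):

```python
from ictolat import (ThetaParams, generate_planted_network,
                     node_ictogenicity, tune_k)

net = generate_planted_network(n_nodes=15, focus=3, strength=10.0, seed=1)
p = ThetaParams(t_steps=200_000, seed=42)
k = tune_k(net, p, n_real=4)          # -> 48.0
res = node_ictogenicity(net, p, k, n_real=4)
print(res.bni_pre)                    # 0.523  (calibrated to 0.5 +- 0.05)
print(res.ni.round(3))
# [-0.008  0.057  0.024  0.798 -0.027  0.030  0.055  0.043  0.020  0.055
#   0.063  0.038  0.054 -0.011  0.051]
print(res.top_roi())                  # (3, 'Precuneus')
```

Node 3's NI of 0.80 means its virtual removal cuts the network's seizure
time by 80% — the planted focus is recovered; every other node sits near 0.

The concordance summary of the study cohort (15 operated patients with known
Engel outcome) is recomputed from the packaged metadata table:

```console
$ ictolat reproduce-table3
good outcome: {"C": 6, "D": 2, "I": 2}
bad outcome:  {"C": 1, "D": 2, "I": 2}
useful predictions: 12 of 15
binomial p-value: 0.0176
```

Among good-outcome patients 6/10 predictions agree with the performed
surgery; among bad-outcome patients only 1/5 does — and a prediction is
potentially useful in every case except agreeing with a failed surgery or
disagreeing with a successful one. 12 useful calls out of 15 beats a
coin-flip predictor (p ≈ 0.02).

A full synthetic pipeline run is available from the shell:

```bash
ictolat synth --focus "Superior temporal right" --gain 5 --duration 64 \
    --seed 1 --out demo/
ictolat pipeline demo/eeg.csv --leadfield demo/leadfield.npz --out demo/ni.json
```

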