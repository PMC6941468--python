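# Methods

This note records the models implemented in `ictolat`, the parameters that
matter, the choices made where the design was genuinely open, and what the
synthetic tests do and do not demonstrate.

## Signal conditioning

Recordings at 256/512/1024 Hz are down-sampled to 256 Hz by polyphase
decimation (anti-alias filtering is internal to `scipy.signal.resample_poly`);
other rates are accepted with a warning via a rational approximation, and
upsampling is refused. Band-passing is a 4th-order Butterworth with corners
at 1 and 25 Hz applied forward and backward (`sosfiltfilt`), so the effective
magnitude response is the squared 4th-order response and the phase response
is exactly zero — phases feed the connectivity stage, so zero phase
distortion is load-bearing, not cosmetic. Edge handling uses odd reflection
padding of 3× the filter's state length. Segmentation takes consecutive
non-overlapping windows of exactly 4096 samples (16 s) and discards the
remainder; epochs under 16 s are rejected.

The reference montage before source mapping is the average reference: the
eLORETA operator is built against an average-referenced gain and
`apply_inverse` centers the data the same way. This is a package convention
(configurable only by pre-referencing the data yourself), chosen because the
centering matrix H is part of the eLORETA formulation anyway.

## eLORETA

Scalar (fixed-orientation) eLORETA with diagonal weights, fixed point

    w_i <- sqrt( k_i^T (K W^{-1} K^T + alpha H)^+ k_i ),

initialized at W = I, iterated until the max relative weight change is below
`tol` (default 1e-6, cap 100 iterations), and inverse operator
M = W^{-1} K^T (K W^{-1} K^T + alpha H)^+. The 3×3 block-weight (free
orientation) variant is out of scope because the intended source models are
dipoles normal to the cortical sheet. Regularization defaults to
alpha = 0.05·trace(Kc Kc^T)/n_channels; the original analysis does not report
its value, so it is an exposed parameter and results can be sensitive to it.
Zero-norm gain columns are rejected at load time. The defining property —
zero localization error on noise-free point sources — is asserted
exhaustively on small leadfields in the test suite.

## Parcellation

Per ROI, member source series are mean-centered and projected on the leading
eigenvector of their covariance (first principal component). The PC sign is
arbitrary; it is fixed by non-negative correlation with the ROI-mean series
because a sign flip shifts the instantaneous phase by π and would corrupt
cross-ROI phase differences. Parcellation is computed per seizure before
segmentation (the component basis is then common to all of a seizure's
segments); computing it per segment would also be defensible but makes
segment networks less comparable.

## PLV networks and surrogate screening

PLV is the modulus of the time-averaged unit phasor of the Hilbert phase
difference over the 4096-sample segment. Finite samples bias PLV upward
(independent phases give E[PLV] ≈ √π/2/√Ns ≈ 0.014 at Ns = 4096), and shared
narrowband spectra inflate it further, so each edge is screened against 99
IAAFT surrogates (10 iterations, initialized from a random permutation, no
convergence stopping; the final amplitude-adjustment step makes the
surrogate's sorted values exactly equal the original's). Surrogates are
generated independently per ROI, preserving each ROI's spectrum and
amplitude distribution while destroying cross-ROI phase relations. The
rank rule: an edge survives iff its original PLV strictly exceeds at least
95 of its 99 surrogate values (top 5 of the 100 pooled) — the standard
surrogate rank test at the 95% level, applied per pair with no
multiple-testing correction across the 105 pairs (a faithful-reproduction
choice). A network with no surviving edges is flagged degenerate and the
ictogenicity stage refuses it.

One caveat the test suite encodes: for a *pure* sinusoid the IAAFT surrogate
is the same sinusoid with shifted phase, and two equal-frequency pure tones
are trivially phase-locked — so the surrogate test correctly *rejects* such
an edge. Genuine coupling is detectable only when the shared rhythm diffuses
in phase (as ictal rhythms do), which is how both the synthetic generator
and the network tests construct their signals.

## Theta-model ictogenicity

Each node follows the SNIC normal form
dθ_i = [1 − cos θ_i + (1 + cos θ_i) I_i] dt with
I_i = I0 + ξ_i + (K/N) Σ_{j≠i} a_ji [1 − cos(θ_j − θ_s)], I0 = −1.2,
noise s.d. σ = 0.6, N = 15. The stable/unstable fixed phases are
θ_s,u = ∓arccos((1 + I0)/(1 − I0)) (θ_s on the stable branch). Integration
is Euler–Maruyama at dt = 0.01 with the noise kick (1 + cos θ)·σ·√dt·𝒩(0,1);
all phases start at θ_s and the first 10% of steps are discarded as
transient. A node is counted ictal from the step its phase (measured from
θ_s in the rotation direction) passes the unstable fixed point until it
returns to within 0.1 rad of θ_s. For I0 ≥ 0 no fixed points exist — the
node rotates perpetually and is ictal throughout, by the model's own state
definition. The hot loop is numba-compiled; a plain-numpy twin of the
integrator is kept and asserted bitwise-equal in the tests.

At these parameters an *uncoupled* node essentially never escapes: the
Kramers factor for the θ_s → θ_u passage is ~e^(−30), so single-node BNI is
0 to numerical resolution. Network seizures are cooperative — resting-state
phase fluctuations make the non-negative coupling term strictly positive on
average, lifting the effective input toward the bifurcation — which is
exactly the regime the K calibration exploits, and why BNI(K) rises from ~0
to a plateau near 0.9 on planted networks.

BNI is the node-averaged ictal fraction. `tune_k` brackets K by doubling
and bisects until |BNI(K) − 0.5| ≤ 0.05, estimating BNI as the mean over
`n_real` noise realizations (default 4). `node_ictogenicity` deletes row
and column i, re-simulates the remaining 14 nodes at the same K — the 1/N
prefactor keeps the intact N so K retains its meaning — and uses common
random numbers for BNI_pre and every BNI_post_i, which both reduces variance
and makes the NI identity hold exactly against the stored values. NI ties
below 1e-12 resolve to the lower canonical ROI index with a warning.

Problem sizes: the package's defaults are desk-scale — T = 2×10^5 steps and
4 noise realizations for calibration and NI (the original analysis used
T = 4×10^6; larger T is a parameter, not a code change), and the Monte-Carlo
recovery tests run 20 seeds at T = 4×10^4 with 2 realizations. At these
sizes the planted focus (strength 10) is recovered in 20/20 seeds and
calibration verifies within ±0.05 of BNI = 0.5 under fresh seeds.

## Consensus and concordance

"Consistently highest NI within a seizure" is operationalized as the mode of
per-segment argmax-NI ROIs, ties broken by the higher mean NI across the
seizure's segments, then by canonical order with a warning. At the patient
level the most frequent seizure-level ROI wins; midline (fused) ROIs carry
no hemisphere, so they are excluded from hemisphere determination, and
winners spanning both hemispheres — or only midline winners — yield an
inconclusive prediction. Concordance against surgery is C (same
hemisphere), D (opposite), I (inconclusive prediction, or no surgical
localization available). A prediction is potentially useful in every cell
except D-with-good-outcome and C-with-bad-outcome. The usefulness test is
the one-sided exact binomial tail P(X ≥ k | n, p0 = 0.5); a coin-flip null
is the natural formalization of "random predictor" for a binary
useful/not-useful call.

The packaged `data/table3.csv` transcribes the study cohort's metadata
(implantation, surgery localization, Engel class, per-patient prediction and
printed C/D/I label); `reproduce_table3` recomputes the C/D/I column from
prediction vs surgery hemisphere and the suite asserts row-by-row agreement
with the printed labels. One cohort ambiguity is worth noting: the patient
whose five seizures each nominated a different ROI is recorded with
prediction "right" in the metadata (the most-frequent rule with its
tie-breaks), while a split-vote reading would call it inconclusive; the
table stores the printed value verbatim and the consensus operation's rule
is documented here as an interpretation.

## Synthetic generator: what it emulates, and what it does not

The generator exists so every stage can be tested against planted ground
truth. Geometry: sources on the upper cap of the unit sphere (default 300;
the original source space had 8004), nearest-centroid ROI assignment with
one source pinned per ROI, 19 electrodes at schematic 10-20 positions on a
radius-1.2 sphere, and a homogeneous-medium radial-dipole potential as the
forward model — enough to exercise the inverse's localization property
while staying analytic and deterministic. Dynamics: ROI-level Kuramoto
oscillators at 6 ± 1 Hz with phase diffusion (1.5 rad/√s), all-to-all
baseline coupling (total pull 6 rad/s split over 15 ROIs), the focus ROI's
couplings scaled by `coupling_gain`; sources follow their ROI phase plus a
small OU jitter (0.2 rad, τ = 0.1 s) under a slow positive amplitude
envelope. These values were chosen once so that baseline inter-ROI locking
is partial and a gain-5 focus tops the ROI-level PLV row-sum in ≥90% of
seeds, which the suite verifies; a focus-free network shows no systematic
winner.

Not emulated: realistic head-model conductivity layers, electrode
digitization, ocular/muscle artifacts, inter-seizure variability of the
focus, and volume-conduction leakage structure beyond what the spherical
model produces. Passing the synthetic suite therefore shows the *pipeline*
is correct and sensitive under its own assumptions; it does not certify
clinical performance on real recordings, which is what the cohort
concordance bookkeeping (real study metadata) speaks to.

## Known limitations

- The eLORETA regularization of the original analysis is unknown; the
  default here is a scale heuristic.
- The ictal-state detection rule (entry at the unstable point, exit within
  0.1 rad of rest) reproduces the SNIC-rotation criterion qualitatively but
  its constants are package choices.
- Whether BNI_post should share noise with BNI_pre is unspecified in the
  source material; common random numbers were chosen for variance reduction.
- EDF export is not provided (no writer in the dependency set); the CSV+JSON
  matrix dialect is the package's interchange format. EDF reading requires
  the `edf` extra.
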