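"""Synthetic ground-truth generator for the full analysis chain.

The recordings the study analysed come from a clinical archive that is not
publicly deposited, so this module generates inputs with the statistical
structure the analysis assumes, at desk scale:

* a spherical source space (default 300 radially-oriented cortical dipoles
  on the upper cap of the unit sphere) partitioned into the 15 canonical
  ROIs, with an analytic dipole forward model to 19 scalp channels placed
  at schematic 10-20 positions;
* ictal source dynamics as noisy coupled phase oscillators in the 3-12 Hz
  band, organized at the ROI level, with one *planted* epileptogenic ROI
  whose couplings to the rest of the network are scaled up so that, at the
  ROI level, it shows the strongest aggregate phase locking;
* linear projection to the scalp with additive Gaussian sensor noise;
* directly planted 15-node functional networks for exercising the
  ictogenicity stage in isolation.

Everything is bit-reproducible given the spec/seed arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inverse import Leadfield
from .montage import CHANNELS_1020, electrode_positions
from .preprocess import EEGRecording
from .rois import HEMISPHERE_OF_ROI, N_ROIS, ROI_LABELS

VALID_FS = (256.0, 512.0, 1024.0)
MIN_DURATION = 16.0

# Schematic ROI centroid directions on the source sphere:
# (inclination from vertex [deg], azimuth from anterior midline [deg],
#  positive toward the left). Paired ROIs are mirror-symmetric; fused
# midline ROIs sit on the sagittal plane.
_ROI_CENTROID_ANGLES: dict[str, tuple[float, float]] = {
    "Medial orbitofrontal": (75.0, 0.0),
    "Rostral anterior cingulate": (55.0, 0.0),
    "Rostral middle frontal": (30.0, 0.0),
    "Precuneus": (35.0, 180.0),
    "Caudal anterior cingulate": (15.0, 180.0),
    "Parahippocampal left": (85.0, 115.0),
    "Parahippocampal right": (85.0, -115.0),
    "Supramarginal left": (65.0, 115.0),
    "Supramarginal right": (65.0, -115.0),
    "Superior temporal left": (85.0, 80.0),
    "Superior temporal right": (85.0, -80.0),
    "Insula left": (70.0, 90.0),
    "Insula right": (70.0, -90.0),
    "Superior parietal left": (50.0, 150.0),
    "Superior parietal right": (50.0, -150.0),
}

_CAP_MAX_INCLINATION = 95.0  # degrees; sources cover the upper cap


def _unit(incl_deg: float, azim_deg: float) -> np.ndarray:
    incl = np.deg2rad(incl_deg)
    azim = np.deg2rad(azim_deg)
    return np.array(
        [-np.sin(incl) * np.sin(azim), np.sin(incl) * np.cos(azim), np.cos(incl)]
    )


def roi_centroids() -> np.ndarray:
    """Unit direction of each ROI centroid, canonical order, shape (15, 3)."""
    return np.array([_unit(*_ROI_CENTROID_ANGLES[r]) for r in ROI_LABELS])


@dataclass
class SourceSpaceSpec:
    """Geometry of the synthetic cortical source space.

    Sources live on the upper cap of the unit sphere; each belongs to
    exactly one of the 15 canonical ROIs (nearest-centroid assignment, with
    the first 15 sources pinned to the centroids so no ROI is empty).
    """

    n_sources: int = 300
    seed: int = 0
    positions: np.ndarray = field(init=False)
    roi_of_source: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.n_sources < N_ROIS:
            raise ValueError("too few sources to cover ROIs")
        rng = np.random.default_rng(self.seed)
        centroids = roi_centroids()
        pinned = centroids.copy()
        n_free = self.n_sources - N_ROIS
        z = rng.uniform(np.cos(np.deg2rad(_CAP_MAX_INCLINATION)), 1.0, n_free)
        phi = rng.uniform(0.0, 2 * np.pi, n_free)
        r_xy = np.sqrt(1.0 - z**2)
        free = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
        pos = np.vstack([pinned, free])
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        nearest = np.argmax(pos @ centroids.T, axis=1)
        nearest[:N_ROIS] = np.arange(N_ROIS)  # pinned sources keep their ROI
        self.positions = pos
        self.roi_of_source = np.array([ROI_LABELS[i] for i in nearest])


@dataclass
class GroundTruth:
    """The planted epileptogenic focus and generation noise level."""

    focus_roi: str
    coupling_gain: float = 5.0
    noise_sd_sensor: float = 0.0

    def __post_init__(self) -> None:
        if self.focus_roi not in ROI_LABELS:
            raise ValueError(f"unknown ROI label: {self.focus_roi!r}")
        if HEMISPHERE_OF_ROI[self.focus_roi] == "midline":
            raise ValueError(
                "focus must be a lateralized ROI; fused midline ROIs carry "
                "no lateralization information"
            )
        if self.coupling_gain <= 1:
            raise ValueError("coupling_gain must exceed 1")

    @property
    def focus_hemisphere(self) -> str:
        return HEMISPHERE_OF_ROI[self.focus_roi]

    @property
    def focus_index(self) -> int:
        return ROI_LABELS.index(self.focus_roi)


def generate_leadfield(spec: SourceSpaceSpec, n_channels: int = 19) -> Leadfield:
    """Analytic single-sphere dipole leadfield for the 19-channel montage.

    Each source is a radially oriented current dipole; the potential at an
    electrode is the homogeneous-medium dipole potential

        v(r_e) = (r_e - r_s) . n_s / (4 pi |r_e - r_s|^3)

    sampled at the schematic 10-20 electrode positions (sphere radius 1.2,
    outside the unit source sphere). Deterministic given the spec.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if n_channels != len(CHANNELS_1020):
        raise ValueError("only the standard 19-channel montage is supported")
    elec = electrode_positions()
    src = spec.positions
    orient = src  # radial orientation on the unit sphere
    diff = elec[:, None, :] - src[None, :, :]  # (n_ch, n_src, 3)
    dist = np.linalg.norm(diff, axis=2)
    gain = np.einsum("csk,sk->cs", diff, orient) / (4 * np.pi * dist**3)
    return Leadfield(
        gain=gain,
        positions=src,
        roi_of_source=spec.roi_of_source,
        channel_labels=CHANNELS_1020,
    )


# --- ictal source dynamics ---------------------------------------------------

# ROI-level oscillator parameters (dimensionless unless noted). The band and
# coupling scale are chosen so baseline inter-ROI locking is partial and the
# planted focus's boosted couplings dominate the ROI-level PLV row sums.
_F_CENTER = 6.0       # Hz, center of the 3-12 Hz ictal rhythm
_F_SPREAD = 1.0       # Hz, s.d. of per-ROI natural frequency jitter
_BASE_COUPLING = 6.0  # rad/s, total baseline pull on a ROI from the network
_PHASE_NOISE = 1.5    # rad/sqrt(s), ROI-level phase diffusion
_SOURCE_JITTER_SD = 0.2   # rad, within-ROI source phase jitter (OU, stationary)
_SOURCE_JITTER_TAU = 0.1  # s, OU correlation time
_ENV_DEPTH = 0.5      # amplitude envelope modulation depth
_ENV_FREQ = 0.25      # Hz, envelope frequency


def roi_coupling_matrix(truth: GroundTruth | None, rng: np.random.Generator) -> np.ndarray:
    """Symmetric ROI-to-ROI coupling, focus row/column scaled by the gain."""
    c = np.full((N_ROIS, N_ROIS), _BASE_COUPLING / N_ROIS)
    c *= rng.uniform(0.5, 1.5, size=c.shape)
    c = (c + c.T) / 2
    np.fill_diagonal(c, 0.0)
    if truth is not None:
        f = truth.focus_index
        c[f, :] *= truth.coupling_gain
        c[:, f] *= truth.coupling_gain
    return c


def generate_ictal_sources(
    spec: SourceSpaceSpec,
    truth: GroundTruth | None,
    fs: float,
    duration: float,
    seed: int,
) -> np.ndarray:
    """Simulate ictal source signals, shape (n_sources, fs*duration).

    ROI phases evolve as Kuramoto oscillators with heterogeneous natural
    frequencies around 6 Hz, phase diffusion, and all-to-all coupling; the
    planted focus ROI's couplings are scaled by ``coupling_gain`` so it
    phase-locks the rest of the network hardest. Each source follows its
    ROI phase plus a small Ornstein-Uhlenbeck jitter and carries a slow
    positive amplitude envelope: x(t) = A(t) cos(phase).

    ``truth=None`` generates a focus-free network (all couplings baseline).
    """
    if float(fs) not in VALID_FS:
        raise ValueError(f"sampling rate must be one of {VALID_FS}")
    if duration < MIN_DURATION:
        raise ValueError("seizure too short: need at least 16 s")
    rng = np.random.default_rng(seed)
    n_samples = int(round(fs * duration))
    dt = 1.0 / fs
    n_src = spec.n_sources

    coupling = roi_coupling_matrix(truth, rng)
    omega = 2 * np.pi * (_F_CENTER + _F_SPREAD * rng.standard_normal(N_ROIS))
    roi_phase = rng.uniform(0, 2 * np.pi, N_ROIS)
    roi_idx = np.array([ROI_LABELS.index(r) for r in spec.roi_of_source])

    jitter = np.zeros(n_src)
    ou_decay = dt / _SOURCE_JITTER_TAU
    ou_kick = _SOURCE_JITTER_SD * np.sqrt(2 * ou_decay)
    env_phase = rng.uniform(0, 2 * np.pi, n_src)

    out = np.empty((n_src, n_samples))
    t = 0.0
    for k in range(n_samples):
        env = 1.0 + _ENV_DEPTH * np.sin(2 * np.pi * _ENV_FREQ * t + env_phase)
        out[:, k] = env * np.cos(roi_phase[roi_idx] + jitter)
        # ROI-level Kuramoto step
        dphi = roi_phase[None, :] - roi_phase[:, None]
        pull = np.sum(coupling * np.sin(dphi), axis=1)
        roi_phase = roi_phase + (omega + pull) * dt
        roi_phase += _PHASE_NOISE * np.sqrt(dt) * rng.standard_normal(N_ROIS)
        # within-ROI source jitter (OU)
        jitter += -ou_decay * jitter + ou_kick * rng.standard_normal(n_src)
        t += dt
    return out


def project_to_scalp(
    sources: np.ndarray,
    lf: Leadfield,
    noise_sd: float,
    seed: int,
    fs: float = 256.0,
) -> EEGRecording:
    """Forward-project source signals to the scalp with sensor noise.

    channels = gain @ sources + N(0, noise_sd) i.i.d. per channel/sample.
    """
    sources = np.asarray(sources, dtype=float)
    if sources.ndim != 2 or sources.shape[0] != lf.n_sources:
        raise ValueError(
            f"source matrix has {sources.shape} but leadfield expects "
            f"{lf.n_sources} sources"
        )
    rng = np.random.default_rng(seed)
    data = lf.gain @ sources
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return EEGRecording(data=data, fs=fs, channel_labels=lf.channel_labels)


def generate_synthetic_seizure(
    spec: SourceSpaceSpec,
    truth: GroundTruth,
    fs: float = 256.0,
    duration: float = 64.0,
    seed: int = 0,
) -> tuple[EEGRecording, Leadfield, np.ndarray]:
    """Convenience wrapper: leadfield + sources + scalp recording in one call."""
    lf = generate_leadfield(spec)
    src = generate_ictal_sources(spec, truth, fs, duration, seed)
    rec = project_to_scalp(src, lf, truth.noise_sd_sensor, seed + 1, fs=fs)
    return rec, lf, src


def generate_planted_network(
    n_nodes: int = 15,
    focus: int = 3,
    strength: float = 10.0,
    seed: int = 0,
):
    """Plant a focus node in an otherwise unstructured functional network.

    Baseline weights are i.i.d. uniform on [0, 0.2] (symmetrized by
    construction, zero diagonal); the focus node's row and column are
    multiplied by ``strength`` and all entries capped at 1 — a direct
    fixture for node-ictogenicity recovery tests.
    """
    from .network import FunctionalNetwork

    if strength < 1:
        raise ValueError("strength must be >= 1")
    if not 0 <= focus < n_nodes:
        raise ValueError("focus index out of range")
    rng = np.random.default_rng(seed)
    a = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    a[iu] = rng.uniform(0.0, 0.2, size=iu[0].size)
    a = a + a.T
    a[focus, :] *= strength
    a[:, focus] *= strength
    np.fill_diagonal(a, 0.0)
    a = np.minimum(a, 1.0)
    return FunctionalNetwork(
        adjacency=a, raw_plv=a.copy(), n_surrogates=0, segment_index=0
    )
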