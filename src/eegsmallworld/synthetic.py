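"""Synthetic two-group EEG cohort with known band-specific coupling.

The generator emulates the statistical structure that the connectivity
pipeline assumes, at a scale where ground truth is known:

* channels are partitioned into *source clusters* (scalp regions);
  each cluster has one band-limited Gaussian source per band, and a
  cluster-level coupling graph says which clusters share sources: a
  channel mixes the unit-variance sum of its cluster's own and coupled
  clusters' sources at coupling strength ``c`` with a private source
  (``sqrt(c)*shared + sqrt(1-c)*private``), so within-cluster pairs
  have correlation ~c, pairs in coupled clusters correlate through the
  shared sources, and pairs in unconnected clusters are independent;
* every channel additionally receives independent 1/f^alpha background
  noise;
* the "patient" group differs only in the theta band: the
  inter-region coupling edges are removed (fragmented topology, fewer
  coupled channel pairs) and the coupling strength is reduced by >= 30%
  relative to controls — a known, recoverable group effect;
* each subject's executive task time is a linear function of their
  realized theta coupling deficit plus Gaussian noise, and the error
  count is Poisson with a rate increasing in the same deficit, so
  behavior correlates with connectivity by construction.

Sources are band-limited Gaussian noise, not phase-coupled oscillators:
mutual information detects any dependence, so linear mixing is the
simplest model with controllable MI. Per-channel signals are
standardized to unit variance before scaling to microvolts, since
histogram MI is only approximately invariant to channel-wise scaling
under binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import DEFAULT_BANDS, BandDefinition, bandpass_zero_phase

#: 10-20 system montage used in the emulated recordings (24 channels).
MONTAGE_24 = [
    "FP1", "FPz", "FP2", "AF3", "AF4", "F7", "F5", "F3", "F1", "Fz", "F2",
    "F4", "F6", "F8", "T7", "C3", "C4", "T8", "P7", "P3", "P4", "P8", "O1", "O2",
]


class ConfigurationError(ValueError):
    pass


def default_regions(n_channels: int = 24) -> list[list[int]]:
    """Partition of the montage into 4 contiguous scalp regions
    (frontal-polar/frontal, fronto-central, centro-temporal,
    parieto-occipital for the 24-channel montage)."""
    if n_channels == 24:
        return [[0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11],
                [12, 13, 14, 15, 16, 17], [18, 19, 20, 21, 22, 23]]
    edges = np.linspace(0, n_channels, 5).astype(int)
    return [list(range(edges[k], edges[k + 1])) for k in range(4)]


def star_coupling(n_clusters: int, hub: int = 0) -> np.ndarray:
    """Cluster-level adjacency with one hub region coupled to all
    others — the integrated configuration."""
    a = np.zeros((n_clusters, n_clusters), dtype=int)
    for k in range(n_clusters):
        if k != hub:
            a[hub, k] = a[k, hub] = 1
    return a


def no_coupling(n_clusters: int) -> np.ndarray:
    """Cluster-level adjacency with no inter-region edges — the
    fragmented configuration."""
    return np.zeros((n_clusters, n_clusters), dtype=int)


def channel_coupling_adjacency(clusters: list[list[int]],
                               cluster_adjacency: np.ndarray,
                               n_channels: int) -> np.ndarray:
    """Channel-level 0/1 adjacency implied by the source-cluster model:
    two channels are coupled iff their clusters' closed neighborhoods
    share at least one source."""
    k = len(clusters)
    adj = np.asarray(cluster_adjacency)
    neigh = [set([a]) | {b for b in range(k) if adj[a, b]} for a in range(k)]
    member = {}
    for a, cl in enumerate(clusters):
        for ch in cl:
            member[ch] = a
    out = np.zeros((n_channels, n_channels), dtype=int)
    for i in range(n_channels):
        for j in range(i + 1, n_channels):
            if i in member and j in member and neigh[member[i]] & neigh[member[j]]:
                out[i, j] = out[j, i] = 1
    return out


@dataclass
class BehaviorModel:
    """executive_time = intercept + slope * theta_deficit + N(0, sd);
    error_count ~ Poisson(error_base + error_slope * theta_deficit).

    Defaults are calibrated so a deficit of 0 (control) gives a mean
    time near 76 s and the default patient deficit (0.45) near 124 s.
    """

    intercept_s: float = 75.93
    slope_s_per_deficit: float = 106.0
    noise_sd_s: float = 15.0
    error_base: float = 0.31
    error_slope: float = 2.6

    def validate(self) -> None:
        if self.noise_sd_s < 0 or self.error_base < 0:
            raise ConfigurationError("behavior model noise/base must be nonnegative")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults: 14 subjects per group, 24 channels, 250 Hz, 60 s per
    subject, conventional delta/theta/alpha/beta bands. Channels are
    partitioned into 4 scalp regions (source clusters); the control
    theta configuration couples the regions through a frontal hub
    (star adjacency) at strength 0.95, while the patient theta
    configuration has no inter-region coupling and strength 0.50 (a 47%
    reduction) — fewer coupled channel pairs and weaker coupling.
    Strengths and the background-noise scale are set so that coupled
    channel pairs land in the normalized-MI range where absolute
    thresholding between 0.15 and 0.45 is informative.
    """

    n_per_group: int = 14
    n_channels: int = 24
    fs: float = 250.0
    duration_s: float = 60.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    source_clusters: list[list[int]] = field(default_factory=list)
    coupling_graph_control: dict[str, np.ndarray] = field(default_factory=dict)
    coupling_graph_patient: dict[str, np.ndarray] = field(default_factory=dict)
    coupling_strength_control: dict[str, float] = field(default_factory=dict)
    coupling_strength_patient: dict[str, float] = field(default_factory=dict)
    noise_exponent: float = 1.0
    noise_scale: float = 0.3
    strength_jitter_sd: float = 0.04
    amplitude_uv: float = 20.0
    behavior_model: BehaviorModel = field(default_factory=BehaviorModel)
    seed: int | None = None

    def __post_init__(self):
        if not self.source_clusters:
            self.source_clusters = default_regions(self.n_channels)
        k = len(self.source_clusters)
        if not self.coupling_graph_control:
            self.coupling_graph_control = {b.name: star_coupling(k) for b in self.bands}
        if not self.coupling_graph_patient:
            self.coupling_graph_patient = {
                b.name: (no_coupling(k) if b.name == "theta" else star_coupling(k))
                for b in self.bands
            }
        if not self.coupling_strength_control:
            self.coupling_strength_control = {
                b.name: (0.95 if b.name == "theta" else 0.85) for b in self.bands
            }
        if not self.coupling_strength_patient:
            self.coupling_strength_patient = {
                b.name: (0.50 if b.name == "theta" else 0.85) for b in self.bands
            }

    def validate(self) -> None:
        if self.n_per_group < 1 or self.n_channels < 2:
            raise ConfigurationError("need n_per_group >= 1 and n_channels >= 2")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fs and duration must be positive")
        for b in self.bands:
            try:
                b.validate(self.fs)
            except ValueError as exc:
                raise ConfigurationError(str(exc)) from exc
        seen: set[int] = set()
        for cluster in self.source_clusters:
            for ch in cluster:
                if not (0 <= ch < self.n_channels):
                    raise ConfigurationError(f"cluster channel {ch} out of range")
                if ch in seen:
                    raise ConfigurationError(f"channel {ch} in more than one cluster")
                seen.add(ch)
        k = len(self.source_clusters)
        for graphs in (self.coupling_graph_control, self.coupling_graph_patient):
            for name, a in graphs.items():
                a = np.asarray(a)
                if a.shape != (k, k):
                    raise ConfigurationError(f"cluster adjacency for {name!r} must be {k}x{k}")
                if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
                    raise ConfigurationError(
                        f"cluster adjacency for {name!r} must be symmetric, zero diagonal")
        for strengths in (self.coupling_strength_control, self.coupling_strength_patient):
            for name, c in strengths.items():
                if not (0.0 <= c <= 1.0):
                    raise ConfigurationError(f"coupling strength for {name!r} outside [0, 1]")
        self.behavior_model.validate()

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        """Build from a flat dict of scalar overrides (JSON config)."""
        known = {"n_per_group", "n_channels", "fs", "duration_s", "noise_exponent",
                 "noise_scale", "strength_jitter_sd", "amplitude_uv", "seed"}
        scalars = {k: v for k, v in d.items() if k in known}
        cfg = cls(**scalars)
        if "coupling_strength_control" in d:
            cfg.coupling_strength_control.update(d["coupling_strength_control"])
        if "coupling_strength_patient" in d:
            cfg.coupling_strength_patient.update(d["coupling_strength_patient"])
        return cfg


@dataclass
class SubjectRecording:
    """One subject's cleaned multichannel EEG plus behavioral scores.

    ``theta_coupling_deficit`` stores the generative ground truth
    (control-mean theta strength minus this subject's realized
    strength); it is not available for real recordings.
    """

    subject_id: str
    group: str  # control | patient
    data: np.ndarray  # (n_channels, n_samples), microvolts
    fs: float
    channel_labels: list[str]
    executive_time_s: float
    error_count: int
    theta_coupling_deficit: float | None = None

    def validate(self) -> None:
        if self.group not in ("control", "patient"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ConfigurationError("data rows must match channel labels")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("missing/non-finite samples")
        if self.fs <= 0 or self.executive_time_s <= 0 or self.error_count < 0:
            raise ConfigurationError("invalid fs or behavioral scores")


def powerlaw_noise(n_samples: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit variance."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    amp = np.zeros(n_freq)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = amp * (rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq))
    x = np.fft.irfft(spectrum, n=n_samples)
    return _standardize(x)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _band_limited_source(n_samples: int, fs: float, band: BandDefinition,
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian process band-limited to ``band``; extra
    samples at both ends absorb filter transients."""
    pad = int(2 * fs)
    white = rng.standard_normal(n_samples + 2 * pad)
    filtered = bandpass_zero_phase(white, fs, band.low, band.high)
    return _standardize(filtered[pad : pad + n_samples])


def generate_cohort(config: SimulationConfig) -> list[SubjectRecording]:
    """Generate 2 * n_per_group recordings (controls first), deterministic
    given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration_s * config.fs))
    if config.n_channels == 24:
        labels = list(MONTAGE_24)
    else:
        labels = [f"ch{c + 1:02d}" for c in range(config.n_channels)]
    bm = config.behavior_model
    theta_ref = config.coupling_strength_control.get("theta", 0.0)
    cohort: list[SubjectRecording] = []
    for group in ("control", "patient"):
        graphs = (config.coupling_graph_control if group == "control"
                  else config.coupling_graph_patient)
        strengths = (config.coupling_strength_control if group == "control"
                     else config.coupling_strength_patient)
        for s in range(config.n_per_group):
            subject_id = f"{'ctl' if group == 'control' else 'pat'}{s + 1:02d}"
            # per-subject realized coupling strength (jittered per band)
            realized = {
                name: float(np.clip(c + rng.normal(0.0, config.strength_jitter_sd), 0.0, 1.0))
                for name, c in strengths.items()
            }
            x = np.zeros((config.n_channels, n_samples))
            clustered = {ch for cl in config.source_clusters for ch in cl}
            for band in config.bands:
                c = realized.get(band.name, 0.0)
                adj = np.asarray(graphs[band.name])
                k = len(config.source_clusters)
                sources = [_band_limited_source(n_samples, config.fs, band, rng)
                           for _ in range(k)]
                for alpha, cluster in enumerate(config.source_clusters):
                    # closed neighborhood: own source plus sources of
                    # coupled clusters, renormalized to unit variance
                    neigh = [alpha] + [b for b in range(k) if adj[alpha, b]]
                    shared = sum(sources[b] for b in neigh) / np.sqrt(len(neigh))
                    for ch in cluster:
                        private = _band_limited_source(n_samples, config.fs, band, rng)
                        x[ch] += np.sqrt(c) * shared + np.sqrt(1.0 - c) * private
                for ch in range(config.n_channels):
                    if ch not in clustered:
                        x[ch] += _band_limited_source(n_samples, config.fs, band, rng)
            if config.noise_scale > 0:
                for ch in range(config.n_channels):
                    x[ch] += config.noise_scale * powerlaw_noise(
                        n_samples, config.noise_exponent, rng)
            for ch in range(config.n_channels):
                x[ch] = _standardize(x[ch]) * config.amplitude_uv
            deficit = theta_ref - realized.get("theta", theta_ref)
            time_s = bm.intercept_s + bm.slope_s_per_deficit * deficit + rng.normal(0.0, bm.noise_sd_s)
            time_s = float(max(time_s, 20.0))
            err_rate = max(bm.error_base + bm.error_slope * deficit, 0.0)
            rec = SubjectRecording(
                subject_id=subject_id, group=group, data=x, fs=config.fs,
                channel_labels=labels, executive_time_s=time_s,
                error_count=int(rng.poisson(err_rate)),
                theta_coupling_deficit=float(deficit),
            )
            rec.validate()
            cohort.append(rec)
    return cohort


def patient_like_config(theta_strength_reduction: float = 0.474,
                        **overrides) -> SimulationConfig:
    """Convenience constructor: default config with the patient theta
    strength set to control * (1 - reduction)."""
    cfg = SimulationConfig(**overrides)
    cfg.coupling_strength_patient = dict(cfg.coupling_strength_patient)
    cfg.coupling_strength_patient["theta"] = (
        cfg.coupling_strength_control["theta"] * (1.0 - theta_strength_reduction)
    )
    return cfg
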