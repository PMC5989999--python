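"""Synthetic multichannel EEG with controllable network dynamics.

The generator produces labeled recordings that reproduce, qualitatively, the
electroclinical archetypes relevant to dynamic network analysis in infancy:

``normal``
    quasi-stationary pink-noise background with weak, slowly drifting
    inter-channel correlation and a heterogeneous power profile across the
    scalp (some channels intrinsically louder than others);
``burst_suppression``
    widespread intermittent high-amplitude bursts on a strongly suppressed
    background; each burst is a near-synchronous generalized discharge
    expressing one of a small library of recurring scalp polarity patterns;
``hypsarrhythmia``
    persistent chaotic high-amplitude activity with high inter-channel
    correlation and fast switching between correlation states;
``stationary_control``
    a strictly stationary process with one fixed cross-covariance pattern,
    used to calibrate surrogate-based z-scores.

Construction: a latent discrete state sequence selects one of a small
library of cross-covariance patterns.  For the state-mixture phenotypes
(normal, hypsarrhythmia, stationary control) dwell times are exponentially
distributed and each channel mixes private pink noise with shared pink-noise
sources, the mixing weights crossfading at state changes over
``(1 - transition_sharpness) * state_dwell_mean`` seconds.  For burst
suppression the latent states ride on the bursts themselves: bursts cycle
through the pattern library in shuffled balanced order, so each pattern
recurs and the time-averaged cross-correlation stays weak relative to the
within-burst correlation.  Everything is deterministic given the seed.

These are fixtures for exercising the analysis method, not biophysical models
of neonatal EEG.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import EEGRecording, STANDARD_1020_LABELS, write_edf

__all__ = [
    "PhenotypeParams",
    "CohortManifest",
    "PHENOTYPES",
    "default_params",
    "generate_recording",
    "generate_cohort",
    "cohort_params",
]

PHENOTYPES = ("normal", "burst_suppression", "hypsarrhythmia",
              "stationary_control")

#: Number of cross-covariance patterns in the latent-state library.
STATE_LIBRARY_SIZE = 4
#: Shared pink-noise sources mixed into every channel (rank of each pattern).
N_SHARED_SOURCES = 3
#: Shortest latent dwell allowed, seconds (guards against zero-length states).
MIN_DWELL_S = 0.3
#: Mean burst duration for burst suppression, seconds.
BURST_DURATION_MEAN_S = 1.0
#: Cosine ramp length for burst envelope edges, seconds.
BURST_RAMP_S = 0.05


@dataclass(frozen=True)
class PhenotypeParams:
    """Parameters of one synthetic recording.

    ``structure_seed`` controls subject-level structure (pattern library,
    channel gains) separately from the per-recording noise seed, so several
    segments from one simulated subject share the same latent architecture.
    It defaults to ``seed``.
    """

    phenotype: str
    n_channels: int = 19
    fs: float = 512.0
    duration: float = 10.0
    burst_rate: float = 0.0           # bursts per second (burst_suppression)
    burst_amplitude_gain: float = 1.0
    suppression_level: float = 1.0
    state_dwell_mean: float = 2.0     # mean latent-state dwell, seconds
    transition_sharpness: float = 1.0  # 1 = instantaneous switch
    spectral_slope: float = 1.0       # 1/f^a background
    cross_cov_strength: float = 0.3   # shared-source variance fraction
    seed: int = 0
    structure_seed: int | None = None
    base_amplitude_uv: float = 20.0   # background RMS scale, microvolts
    gain_spread: float = 0.0          # lognormal sigma of per-channel gains
    pattern_drift: float = 0.0        # 0 = independent states, >0 = states
                                      # drawn as perturbations of one base
    power_mod: float = 0.0            # slow independent per-channel amplitude
                                      # modulation (lognormal sigma); leaves
                                      # within-window correlations intact but
                                      # decorrelates band-power vectors
    power_mod_cutoff_hz: float = 0.35  # bandwidth of the slow modulation
    burst_weight_jitter: float = 0.4  # per-burst spread of channel weights
    burst_private_level: float = 0.3  # desynchronized fraction within bursts

    def validate(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype: {self.phenotype!r}")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not (0 < self.transition_sharpness <= 1):
            raise ValueError("transition_sharpness must be in (0, 1]")
        if not (0 <= self.cross_cov_strength <= 1):
            raise ValueError("cross_cov_strength must be in [0, 1]")


#: Phenotype presets.  Normal background has a heterogeneous power profile
#: and weak drifting correlation; the pathological archetypes have strong,
#: distinct correlation states and spatially flat (generalized) power.
_PRESETS: dict[str, dict] = {
    "normal": dict(
        cross_cov_strength=0.30, state_dwell_mean=2.5,
        transition_sharpness=0.3, gain_spread=0.5, pattern_drift=0.35,
        base_amplitude_uv=20.0,
    ),
    "burst_suppression": dict(
        cross_cov_strength=0.85, state_dwell_mean=1.25,
        transition_sharpness=0.9, burst_rate=0.8, burst_amplitude_gain=4.0,
        suppression_level=0.2, base_amplitude_uv=30.0,
        power_mod=0.35, power_mod_cutoff_hz=0.5,
    ),
    "hypsarrhythmia": dict(
        cross_cov_strength=0.90, state_dwell_mean=2.0,
        transition_sharpness=0.8, gain_spread=0.02, base_amplitude_uv=60.0,
        power_mod=0.5,
    ),
    "stationary_control": dict(
        cross_cov_strength=0.08, gain_spread=0.25, base_amplitude_uv=20.0,
    ),
}


def default_params(phenotype: str, **overrides) -> PhenotypeParams:
    """Build :class:`PhenotypeParams` from the phenotype preset."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype: {phenotype!r}")
    kwargs = dict(_PRESETS[phenotype])
    kwargs.update(overrides)
    return PhenotypeParams(phenotype=phenotype, **kwargs)


# ---------------------------------------------------------------------------
# Signal construction
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                fs: float, slope: float) -> np.ndarray:
    """1/f^slope noise, unit variance per series, zero mean."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.empty_like(freqs)
    shape[0] = 0.0  # no DC
    f = np.maximum(freqs[1:], 0.5)  # flatten below 0.5 Hz to bound drift
    shape[1:] = f ** (-slope / 2.0)
    spec = (rng.standard_normal((n_series, freqs.size))
            + 1j * rng.standard_normal((n_series, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pattern_library(rng: np.random.Generator, n_channels: int,
                     drift: float) -> np.ndarray:
    """Library of unit-row mixing matrices, shape (L, n, r).

    ``drift > 0`` draws every state as a perturbation of one base pattern
    (slowly drifting rhythms); ``drift == 0`` draws independent states.
    """
    shape = (STATE_LIBRARY_SIZE, n_channels, N_SHARED_SOURCES)
    if drift > 0:
        base = rng.standard_normal((n_channels, N_SHARED_SOURCES))
        lib = base[None] + drift * rng.standard_normal(shape)
    else:
        lib = rng.standard_normal(shape)
    norms = np.linalg.norm(lib, axis=2, keepdims=True)
    norms[norms == 0] = 1.0
    return lib / norms


def _state_sequence(rng: np.random.Generator, n_states: int, duration: float,
                    dwell_mean: float) -> list[tuple[float, int]]:
    """(start_time, state_index) pairs covering [0, duration)."""
    out = []
    t, prev = 0.0, -1
    while t < duration:
        choices = [s for s in range(n_states) if s != prev]
        state = int(rng.choice(choices)) if len(choices) else 0
        out.append((t, state))
        dwell = max(MIN_DWELL_S, rng.exponential(dwell_mean))
        t += dwell
        prev = state
    return out


def _mixing_weights(events: list[tuple[float, int]], library: np.ndarray,
                    n_samples: int, fs: float, fade_s: float) -> np.ndarray:
    """Time-resolved mixing weights (n, r, T), crossfaded at state changes."""
    L, n, r = library.shape
    lam = np.zeros((len(events), n_samples))  # per-event activation
    times = np.arange(n_samples) / fs
    fade = max(fade_s, 1.0 / fs)
    for i, (t0, _state) in enumerate(events):
        t1 = events[i + 1][0] if i + 1 < len(events) else np.inf
        # crossfades are centered on the state boundary so that adjacent
        # states overlap linearly over the fade interval
        if i > 0:
            up = np.clip((times - (t0 - fade / 2.0)) / fade, 0.0, 1.0)
        else:
            up = np.ones_like(times)
        if np.isfinite(t1):
            down = np.clip(((t1 + fade / 2.0) - times) / fade, 0.0, 1.0)
        else:
            down = np.ones_like(times)
        lam[i] = np.minimum(up, down)
    total = lam.sum(axis=0)
    total[total == 0] = 1.0
    lam /= total
    W = np.einsum("et,enr->nrt", lam,
                  np.stack([library[s] for _, s in events]))
    # keep per-channel shared-source variance constant through crossfades
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return W / norms


def _burst_suppression_signal(params: PhenotypeParams,
                              rng_struct: np.random.Generator,
                              rng_noise: np.random.Generator,
                              n: int, T: int) -> np.ndarray:
    """Burst-suppression core signal (unit background scale).

    Bursts are near-synchronous generalized discharges: within a burst every
    channel carries a common pink-noise transient with a signed weight taken
    from one of ``STATE_LIBRARY_SIZE`` scalp polarity patterns.  Bursts cycle
    through the pattern library in shuffled balanced order, so each pattern
    recurs across the record while the time-averaged cross-correlation stays
    far weaker than the within-burst correlation.  The suppressed background
    is weak desynchronized pink noise.
    """
    fs, duration = params.fs, params.duration
    L = STATE_LIBRARY_SIZE
    # subject-level polarity patterns (+1/-1 per channel)
    signs = np.where(rng_struct.random((L, n)) < 0.5, -1.0, 1.0)
    n_bursts = max(1, int(round(params.burst_rate * duration)))
    private = _pink_noise(rng_noise, n, T, fs, params.spectral_slope)
    sources = _pink_noise(rng_noise, n_bursts, T, fs, params.spectral_slope)
    order = np.concatenate([rng_noise.permutation(L)
                            for _ in range(n_bursts // L + 1)])[:n_bursts]
    spacing = duration / n_bursts
    centers = ((np.arange(n_bursts) + 0.5) * spacing
               + rng_noise.uniform(-0.1 * spacing, 0.1 * spacing, n_bursts))
    dur_hi = min(BURST_DURATION_MEAN_S, 0.8 * spacing)
    env = np.full(T, params.suppression_level)
    x = private.copy()
    p = params.burst_private_level
    for i, tc in enumerate(centers):
        d = rng_noise.uniform(0.85, 1.0) * dur_hi
        a = max(int((tc - d / 2) * fs), 0)
        b = min(int((tc + d / 2) * fs), T)
        env[a:b] = params.burst_amplitude_gain
        w = signs[order[i]] * (1.0 + params.burst_weight_jitter
                               * np.abs(rng_noise.standard_normal(n)))
        x[:, a:b] = (np.sqrt(1.0 - p ** 2) * np.outer(w, sources[i, a:b])
                     + p * private[:, a:b])
    fade_s = max((1.0 - params.transition_sharpness)
                 * params.state_dwell_mean, BURST_RAMP_S)
    ramp = max(2, int(fade_s * fs / 2))
    kernel = np.hanning(2 * ramp + 1)
    kernel /= kernel.sum()
    env = np.convolve(env, kernel, mode="same")
    return x * env[None, :]


def _slow_channel_modulation(rng: np.random.Generator, n: int, T: int,
                             fs: float, sigma: float,
                             cutoff_hz: float = 0.35) -> np.ndarray:
    """Independent slow lognormal amplitude envelopes per channel.

    Nearly constant within a 2-s window (for sub-Hz cutoffs), so windowed
    channel correlations are unchanged while windowed band-power vectors
    decorrelate across windows.
    """
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    shape = np.exp(-(freqs / cutoff_hz) ** 2)
    shape[0] = 0.0
    spec = (rng.standard_normal((n, freqs.size))
            + 1j * rng.standard_normal((n, freqs.size))) * shape
    m = np.fft.irfft(spec, n=T, axis=1)
    sd = m.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    m /= sd
    return np.exp(sigma * m - 0.5 * sigma ** 2)


def generate_recording(params: PhenotypeParams) -> EEGRecording:
    """Generate one multichannel recording (microvolts, as-recorded montage).

    Deterministic given ``params.seed`` / ``params.structure_seed``.
    """
    params.validate()
    n = params.n_channels
    T = int(round(params.duration * params.fs))
    structure_seed = (params.seed if params.structure_seed is None
                      else params.structure_seed)
    rng_struct = np.random.default_rng([int(structure_seed), 17])
    rng_noise = np.random.default_rng([int(params.seed), 43])

    gains = np.exp(params.gain_spread * rng_struct.standard_normal(n)) \
        if params.gain_spread > 0 else np.ones(n)

    if params.phenotype == "burst_suppression":
        x = _burst_suppression_signal(params, rng_struct, rng_noise, n, T)
    else:
        library = _pattern_library(rng_struct, n, params.pattern_drift)
        if params.phenotype == "stationary_control":
            events = [(0.0, 0)]
        else:
            events = _state_sequence(rng_noise, STATE_LIBRARY_SIZE,
                                     params.duration, params.state_dwell_mean)
        fade_s = (1.0 - params.transition_sharpness) * params.state_dwell_mean
        W = _mixing_weights(events, library, T, params.fs, fade_s)
        shared = _pink_noise(rng_noise, N_SHARED_SOURCES, T, params.fs,
                             params.spectral_slope)
        private = _pink_noise(rng_noise, n, T, params.fs,
                              params.spectral_slope)
        c = params.cross_cov_strength
        x = (np.sqrt(1.0 - c) * private
             + np.sqrt(c) * np.einsum("nrt,rt->nt", W, shared))

    if params.power_mod > 0:
        x = x * _slow_channel_modulation(rng_noise, n, T, params.fs,
                                         params.power_mod,
                                         params.power_mod_cutoff_hz)

    x = x * (params.base_amplitude_uv * gains[:, None])
    x = x - x.mean(axis=1, keepdims=True)  # zero mean per channel

    labels = (STANDARD_1020_LABELS[:n] if n <= len(STANDARD_1020_LABELS)
              else STANDARD_1020_LABELS
              + [f"X{i}" for i in range(n - len(STANDARD_1020_LABELS))])
    return EEGRecording(x, params.fs, labels, reference="as_recorded")


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Index of a generated cohort: one entry per written EDF record."""

    records: list[dict]                 # {record_id, phenotype, path, seed}
    groups: dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"records": self.records, "groups": self.groups}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        d = json.loads(Path(path).read_text())
        return cls(records=d["records"], groups=d.get("groups", {}))


def generate_cohort(configs: list[PhenotypeParams], out_dir: str | Path,
                    record_ids: list[str] | None = None) -> CohortManifest:
    """Generate and write one EDF per config; return the manifest.

    Record ids default to ``{phenotype}_{index:03d}``; explicit ids must be
    unique.  Deterministic given the per-record seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if record_ids is None:
        record_ids = [f"{p.phenotype}_{i:03d}" for i, p in enumerate(configs)]
    if len(record_ids) != len(configs):
        raise ValueError("record_ids length must match configs")
    if len(set(record_ids)) != len(record_ids):
        dupes = sorted({r for r in record_ids if record_ids.count(r) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    records = []
    groups = {}
    for rid, p in zip(record_ids, configs):
        rec = generate_recording(p)
        rec.record_id = rid
        path = out_dir / f"{rid}.edf"
        write_edf(rec, path)
        records.append({"record_id": rid, "phenotype": p.phenotype,
                        "path": str(path), "seed": int(p.seed)})
        groups[p.phenotype] = p.phenotype
    manifest = CohortManifest(records=records, groups=groups)
    manifest.save(out_dir / "manifest.json")
    return manifest


def cohort_params(phenotypes: list[str], subjects_per_group: int,
                  segments_per_subject: int, base_seed: int,
                  fs: float = 256.0, duration: float = 10.0,
                  n_channels: int = 19) -> tuple[list[str], list[PhenotypeParams],
                                                 list[str], list[str]]:
    """Study-style cohort layout: several 10-s records per simulated subject.

    Returns ``(record_ids, params, subject_ids, labels)`` with one entry per
    record.  Records of one subject share a structure seed (same latent
    pattern library and channel gains) and differ in their noise seeds.
    """
    record_ids, params, subject_ids, labels = [], [], [], []
    for g, phen in enumerate(phenotypes):
        for s in range(subjects_per_group):
            subj = f"{phen}_s{s:02d}"
            subj_seed = int(base_seed * 100003 + g * 1009 + s * 101) % (2**31)
            for k in range(segments_per_subject):
                rec_seed = (subj_seed + 7919 * (k + 1)) % (2**31)
                record_ids.append(f"{subj}_seg{k:02d}")
                params.append(default_params(
                    phen, fs=fs, duration=duration, n_channels=n_channels,
                    seed=rec_seed, structure_seed=subj_seed))
                subject_ids.append(subj)
                labels.append(phen)
    return record_ids, params, subject_ids, labels
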