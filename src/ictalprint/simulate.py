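"""Synthetic multimodal cohorts with planted, per-person ictal signatures.

The restricted clinical recordings are emulated at desk scale: instead
of 1,000+ hours per person, each synthetic recording is just long
enough to host the requested number of seizures with inter-seizure
gaps that leave room for the pre-ictal and baseline windows (minutes
to a few hours). The physiology kept is exactly what the downstream
analysis consumes:

* **EEG background** — 1/f^alpha colored Gaussian noise (alpha = 1 by
  default, spectrum clamped flat below 0.5 Hz), with a slowly varying
  multiplicative amplitude drift (log-normal, ~2-min correlation)
  shared by both channels, standing in for vigilance/impedance drift.
* **Ictal EEG signature** — during each seizure, band-pass-filtered
  noise per EEG band is added so the band's power becomes
  ``eeg_band_gain[band]`` times the local background power in that
  band (gains are multiplicative power gains; 1 = no change).
* **EMG signature** — the proximal channel additionally receives a
  20–100 Hz broadband burst train whose mean power is
  ``emg_burst_gain`` times the local background >20 Hz power,
  emulating temporalis muscle activity bleeding into the electrode.
* **Ictal artifact** — every seizure (any person) also adds a
  person-independent >20 Hz artifact of random per-seizure power
  (muscle/movement artifact is near-universal in ictal EEG); its
  power factor range is configurable and set to 1 (off) in null
  cohorts.
* **Accelerometry** — gravity projection plus white noise, with
  piecewise-constant "posture epochs" that rotate gravity about the
  device x-axis (rolling/turning leaves the x projection untouched);
  motor-involved seizures add a smoothed step of ``acc_shift_g`` on
  the x-axis (trunk pitch change) and optionally a tremor oscillation
  of amplitude ``acc_tremor_amp`` at a person-specific 2–3.5 Hz rate.

All randomness for one person flows from a single seeded generator,
so identical profiles and seeds give bit-identical recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    ChannelSignal, Recording, SeizureAnnotation,
    write_recording, write_annotations,
)
from .features import BANDS

__all__ = [
    "PersonProfile", "CohortSpec", "ConfigurationError",
    "simulate_recording", "simulate_cohort",
    "archetype_cohort", "null_cohort", "ARCHETYPE_SIGNATURES",
]

EEG_FS = 207.0
ACC_FS = 10.0

_FBTCS_SIGNATURE = {
    "eeg_band_gain": {b: 3.0 for b in BANDS if b != "hf"},
    "emg_burst_gain": 6.0,
    "acc_shift_g": 0.5,
    "acc_tremor_amp": 0.12,
}


class ConfigurationError(ValueError):
    """The cohort specification cannot be realized."""


@dataclass
class PersonProfile:
    """Planted ictal signature and seizure statistics for one person."""

    person_id: str
    seed: int
    eeg_band_gain: dict[str, float] = field(default_factory=dict)
    emg_burst_gain: float = 1.0
    acc_shift_g: float = 0.0
    acc_tremor_amp: float = 0.0
    n_seizures: int = 10
    seizure_duration_s: tuple[float, float] = (20.0, 90.0)

    def __post_init__(self) -> None:
        known = set(BANDS) - {"hf"}
        unknown = set(self.eeg_band_gain) - known
        if unknown:
            raise ConfigurationError(f"unknown EEG bands {sorted(unknown)}; valid: {sorted(known)}")
        gains = list(self.eeg_band_gain.values()) + [self.emg_burst_gain]
        if any(g < 0 for g in gains):
            raise ConfigurationError("gains must be >= 0")
        if any(0 <= g < 1.0 for g in gains):
            # power gains below 1 would require notching the background
            raise ConfigurationError(
                "band/EMG power gains below 1 (ictal suppression) are not supported"
            )
        if self.n_seizures < 10:
            raise ConfigurationError(
                f"n_seizures must be >= 10 (cohort inclusion rule), got {self.n_seizures}"
            )
        lo, hi = self.seizure_duration_s
        if not (6.0 < lo <= hi):
            raise ConfigurationError(
                f"seizure durations must satisfy 6 < min <= max, got {self.seizure_duration_s}"
            )


@dataclass
class CohortSpec:
    """Cohort-level generation parameters shared by all persons."""

    profiles: list[PersonProfile]
    interictal_gap_s: tuple[float, float] = (420.0, 620.0)
    background_eeg: dict = field(default_factory=lambda: {
        "alpha": 1.0,           # 1/f exponent
        "sd_uv": 20.0,          # background standard deviation, µV
        "amp_mod_sd": 0.3,      # log-amplitude drift sd
        "amp_mod_period_s": 120.0,
        # per-seizure ictal >20 Hz artifact power factor, drawn uniform;
        # (1, 1) disables it (null cohorts)
        "ictal_artifact_gain": (1.2, 3.5),
        # amplitude factor of the ictal EEG component on the distal channel
        # (the seizure focus projects more strongly to the proximal contact)
        "dist_projection": 0.35,
        # state-dependent background rhythms: waxing/waning alpha (and,
        # weaker, beta) activity whose squared envelope adds up to
        # `burst_scale` x the band's baseline power over ~minutes
        # "infraslow" is the 0.05-0.45 Hz range: electrode/sweat slow
        # potentials, below every analysis band but part of the raw
        # signal variance
        "rhythm_bursts": {"alpha": 2.0, "beta": 1.0, "infraslow": 4.0},
        "rhythm_period_s": 180.0,
    })
    background_acc: dict = field(default_factory=lambda: {
        "gravity_g": (0.05, 0.0, 0.995),
        "noise_sd_g": 0.02,
        # posture epochs: every few minutes gravity re-orients (pitch
        # then roll); ranges of 0 disable
        "roll_epoch_s": (300.0, 900.0),
        "roll_range_rad": 0.7,
        "pitch_range_rad": 0.12,
        # everyday movement: random activity bouts of band-limited
        # dynamic acceleration on all axes (walking, fidgeting)
        "activity_rate": 0.35,
        "activity_bout_s": (30.0, 300.0),
        "activity_amp_g": (0.05, 0.25),
        "activity_band_hz": (1.0, 4.0),
    })
    fbtcs_extra: dict[str, int] = field(default_factory=dict)
    #: per-seizure log-normal sd of the signature intensity: every
    #: seizure's planted excesses (band power, EMG power, posture
    #: shift, tremor) are scaled by one LogNormal(0, sd) draw, since
    #: real seizures of one person vary in intensity
    intensity_jitter_sd: float = 0.35
    max_duration_s: float | None = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ConfigurationError("a cohort needs at least 1 profile")
        ids = [p.person_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate person ids: {ids}")
        lo, hi = self.interictal_gap_s
        if not (0 < lo <= hi):
            raise ConfigurationError(f"bad interictal gap bounds {self.interictal_gap_s}")


# ---------------------------------------------------------------------------
# Noise primitives
# ---------------------------------------------------------------------------

_F_CLAMP = 0.5  # Hz; spectrum flat below this to keep variance finite


def _colored_noise(n: int, fs: float, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^alpha Gaussian noise (clamped flat below 0.5 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.maximum(freqs, _F_CLAMP) ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _band_fraction(lo: float, hi: float, fs: float, alpha: float) -> float:
    """Fraction of the clamped 1/f^alpha variance inside [lo, hi] Hz."""
    nyq = fs / 2.0
    f = np.linspace(1e-4, nyq, 40001)
    s = np.maximum(f, _F_CLAMP) ** (-alpha)
    total = np.trapezoid(s, f)
    mask = (f >= lo) & (f <= hi)
    return float(np.trapezoid(s[mask], f[mask]) / total)


def _bandlimited_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise confined to [lo, hi] Hz (FFT brick-wall with
    1-bin cosine shoulders), edge-tapered with 1-s cosine ramps."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = ((freqs >= lo) & (freqs <= hi)).astype(float)
    x = np.fft.irfft(spec * mask, n=n)
    sd = np.std(x)
    if sd > 0:
        x /= sd
    ramp = min(int(round(fs)), n // 4)
    if ramp > 1:
        w = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        x[:ramp] *= w
        x[-ramp:] *= w[::-1]
    return x


def _burst_envelope(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """On/off burst train, smoothed, normalized to unit mean square."""
    env = np.zeros(n)
    i = 0
    on = bool(rng.integers(0, 2))
    while i < n:
        seg = int(round((rng.exponential(1.0) + 0.4) * fs))
        if on:
            env[i : i + seg] = 1.0
        i += seg
        on = not on
    if env.max() == 0.0:
        env[:] = 1.0
    win = max(1, int(round(0.3 * fs)))
    kernel = np.hanning(win + 2)[1:-1]
    kernel /= kernel.sum()
    env = np.convolve(env, kernel, mode="same")
    ms = np.mean(env * env)
    return env / np.sqrt(ms) if ms > 0 else np.ones(n)


def _step_envelope(n: int, fs: float, ramp_s: float = 2.0) -> np.ndarray:
    """Smoothed step: cosine ramp up, hold, cosine ramp down."""
    env = np.ones(n)
    ramp = min(int(round(ramp_s * fs)), max(n // 4, 1))
    if ramp > 1:
        w = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = w
        env[-ramp:] = w[::-1]
    return env


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------

def _plan_seizures(profile: PersonProfile, cohort: CohortSpec, rng: np.random.Generator):
    n_fbtcs = cohort.fbtcs_extra.get(profile.person_id, 0)
    n_total = profile.n_seizures + n_fbtcs
    lo, hi = profile.seizure_duration_s
    durations = rng.uniform(lo, hi, size=n_total)
    fbtcs_idx = set(rng.choice(n_total, size=n_fbtcs, replace=False).tolist()) if n_fbtcs else set()
    for i in fbtcs_idx:
        durations[i] = rng.uniform(60.0, 120.0)
    onsets = np.empty(n_total)
    t = 0.0
    for i in range(n_total):
        t += rng.uniform(*cohort.interictal_gap_s)
        onsets[i] = t
        t += durations[i]
    total_s = int(np.ceil(t + 60.0))
    if cohort.max_duration_s is not None and total_s > cohort.max_duration_s:
        raise ConfigurationError(
            f"person {profile.person_id}: {n_total} seizures with gaps "
            f"{cohort.interictal_gap_s} need {total_s} s > "
            f"max_duration_s={cohort.max_duration_s:g}"
        )
    labels = ["FBTCS" if i in fbtcs_idx else "electrographic" for i in range(n_total)]
    return onsets, durations, labels, total_s


def simulate_recording(
    profile: PersonProfile, cohort: CohortSpec
) -> tuple[Recording, list[SeizureAnnotation]]:
    """Generate one person's multimodal recording plus its annotations.

    Deterministic given ``profile.seed``; all planted seizures are
    annotated with their exact onset and duration.
    """
    if profile not in cohort.profiles:
        raise ConfigurationError(f"profile {profile.person_id!r} not in cohort")
    rng = np.random.default_rng(profile.seed)
    onsets, durations, labels, total_s = _plan_seizures(profile, cohort, rng)

    bg = cohort.background_eeg
    alpha, sd_uv = bg["alpha"], bg["sd_uv"]
    n_eeg = int(total_s * EEG_FS)
    eeg = {
        "EEG_prox": _colored_noise(n_eeg, EEG_FS, alpha, rng) * sd_uv,
        "EEG_dist": _colored_noise(n_eeg, EEG_FS, alpha, rng) * sd_uv,
    }

    # slow shared amplitude drift (log-normal), control point every amp_mod_period_s
    period = bg.get("amp_mod_period_s", 120.0)
    mod_sd = bg.get("amp_mod_sd", 0.15)
    knots_t = np.arange(0.0, total_s + period, period)
    knots = rng.normal(0.0, mod_sd, size=len(knots_t))
    t_eeg = np.arange(n_eeg) / EEG_FS
    scale = np.exp(np.interp(t_eeg, knots_t, knots))
    for ch in eeg.values():
        ch *= scale

    # waxing/waning background rhythms (vigilance-state alpha/beta),
    # independent envelopes per channel, mean added power = burst_scale
    # x the band's baseline power
    rhythm_period = bg.get("rhythm_period_s", 180.0)
    rhythm_knots_t = np.arange(0.0, total_s + rhythm_period, rhythm_period)
    for band, burst_scale in sorted(bg.get("rhythm_bursts", {}).items()):
        if burst_scale <= 0:
            continue
        lo, hi = BANDS[band] if band in BANDS else (0.05, 0.45)
        base_var = (sd_uv ** 2) * _band_fraction(lo, hi, EEG_FS, alpha)
        for ch in ("EEG_prox", "EEG_dist"):
            knots = rng.normal(0.0, 0.5, size=len(rhythm_knots_t))
            env = np.exp(np.interp(t_eeg, rhythm_knots_t, knots))
            env /= np.sqrt(np.mean(env * env))
            comp = _bandlimited_noise(n_eeg, EEG_FS, lo, hi, rng)
            eeg[ch] += np.sqrt(burst_scale * base_var) * env * comp * scale

    acc_cfg = cohort.background_acc
    gx, gy, gz = acc_cfg["gravity_g"]
    n_acc = int(total_s * ACC_FS)
    noise_sd = acc_cfg["noise_sd_g"]
    # posture epochs: piecewise-constant re-orientation (pitch about y,
    # then roll about x) of the gravity projection
    roll_lo, roll_hi = acc_cfg.get("roll_epoch_s", (300.0, 900.0))
    roll_range = acc_cfg.get("roll_range_rad", 0.7)
    pitch_range = acc_cfg.get("pitch_range_rad", 0.12)
    roll = np.zeros(n_acc)
    pitch = np.zeros(n_acc)
    if roll_range > 0 or pitch_range > 0:
        i = 0
        while i < n_acc:
            seg = int(round(rng.uniform(roll_lo, roll_hi) * ACC_FS))
            roll[i : i + seg] = rng.uniform(-roll_range, roll_range)
            pitch[i : i + seg] = rng.uniform(-pitch_range, pitch_range)
            i += seg
    g_x = gx * np.cos(pitch) + gz * np.sin(pitch)
    g_z0 = -gx * np.sin(pitch) + gz * np.cos(pitch)
    g_y = gy * np.cos(roll) - g_z0 * np.sin(roll)
    g_z = gy * np.sin(roll) + g_z0 * np.cos(roll)
    acc = {
        "ACC_x": g_x + rng.normal(0.0, noise_sd, n_acc),
        "ACC_y": g_y + rng.normal(0.0, noise_sd, n_acc),
        "ACC_z": g_z + rng.normal(0.0, noise_sd, n_acc),
    }
    # everyday-activity bouts: dynamic acceleration on all axes
    act_rate = acc_cfg.get("activity_rate", 0.0)
    if act_rate > 0:
        bout_lo, bout_hi = acc_cfg.get("activity_bout_s", (30.0, 300.0))
        amp_lo, amp_hi = acc_cfg.get("activity_amp_g", (0.05, 0.25))
        act_lo_hz, act_hi_hz = acc_cfg.get("activity_band_hz", (1.0, 4.0))
        i = 0
        while i < n_acc:
            seg = int(round(rng.uniform(bout_lo, bout_hi) * ACC_FS))
            seg = min(seg, n_acc - i)
            if rng.uniform() < act_rate and seg > ACC_FS:
                amp = rng.uniform(amp_lo, amp_hi)
                for ch in acc.values():
                    ch[i : i + seg] += amp * _bandlimited_noise(
                        seg, ACC_FS, act_lo_hz, act_hi_hz, rng)
            i += seg
    t_acc = np.arange(n_acc) / ACC_FS
    tremor_hz = rng.uniform(2.0, 3.5)
    art_lo, art_hi = bg.get("ictal_artifact_gain", (1.0, 1.0))
    dist_proj = bg.get("dist_projection", 0.7)

    annotations: list[SeizureAnnotation] = []
    for i, (onset, dur, lab) in enumerate(zip(onsets, durations, labels)):
        sid = f"{profile.person_id}-{i:03d}"
        annotations.append(SeizureAnnotation(profile.person_id, sid, float(onset),
                                             float(dur), lab))
        if lab == "FBTCS":
            band_gain = _FBTCS_SIGNATURE["eeg_band_gain"]
            emg_gain = _FBTCS_SIGNATURE["emg_burst_gain"]
            shift = _FBTCS_SIGNATURE["acc_shift_g"]
            tremor = _FBTCS_SIGNATURE["acc_tremor_amp"]
        else:
            band_gain = profile.eeg_band_gain
            emg_gain = profile.emg_burst_gain
            shift = profile.acc_shift_g
            tremor = profile.acc_tremor_amp

        i0 = int(np.floor(onset * EEG_FS))
        i1 = int(np.floor((onset + dur) * EEG_FS))
        nseg = i1 - i0
        local = float(np.mean(scale[i0:i1]))
        jitter = float(np.exp(rng.normal(0.0, cohort.intensity_jitter_sd)))
        for band, gain in sorted(band_gain.items()):
            if gain == 1.0:
                continue
            lo, hi = BANDS[band]
            target_var = jitter * (gain - 1.0) * (sd_uv ** 2) * _band_fraction(lo, hi, EEG_FS, alpha)
            amp = np.sqrt(target_var) * local
            comp = _bandlimited_noise(nseg, EEG_FS, lo, hi, rng)
            eeg["EEG_prox"][i0:i1] += amp * comp
            eeg["EEG_dist"][i0:i1] += dist_proj * amp * comp
        hi_emg = min(100.0, EEG_FS / 2.0 - 3.0)
        hf_var = (sd_uv ** 2) * _band_fraction(20.0, hi_emg, EEG_FS, alpha)
        if emg_gain != 1.0:
            comp = _bandlimited_noise(nseg, EEG_FS, 20.0, hi_emg, rng)
            env = _burst_envelope(nseg, EEG_FS, rng)
            eeg["EEG_prox"][i0:i1] += np.sqrt(jitter * (emg_gain - 1.0) * hf_var) * local * comp * env
        art_gain = rng.uniform(art_lo, art_hi)
        if art_gain != 1.0:
            comp = _bandlimited_noise(nseg, EEG_FS, 20.0, hi_emg, rng)
            amp = np.sqrt((art_gain - 1.0) * hf_var) * local
            eeg["EEG_prox"][i0:i1] += amp * comp
            eeg["EEG_dist"][i0:i1] += 0.9 * amp * comp

        if shift != 0.0 or tremor != 0.0:
            a0 = int(np.floor(onset * ACC_FS))
            a1 = int(np.floor((onset + dur) * ACC_FS))
            env = _step_envelope(a1 - a0, ACC_FS)
            # posture change = rotation of gravity about the device
            # y-axis (magnitude-preserving), by the angle that moves
            # the x projection by `shift` g from upright
            theta = np.arcsin(np.clip(jitter * shift, -0.95, 0.95)) * env
            sl = slice(a0, a1)
            cos_t, sin_t = np.cos(theta), np.sin(theta)
            acc["ACC_x"][sl] += g_x[sl] * (cos_t - 1.0) + g_z[sl] * sin_t
            acc["ACC_z"][sl] += -g_x[sl] * sin_t + g_z[sl] * (cos_t - 1.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            osc = np.sin(2.0 * np.pi * tremor_hz * t_acc[sl] + phase)
            acc["ACC_x"][sl] += jitter * tremor * env * osc

    channels = [
        ChannelSignal("EEG_prox", "eeg", EEG_FS, eeg["EEG_prox"]),
        ChannelSignal("EEG_dist", "eeg", EEG_FS, eeg["EEG_dist"]),
        ChannelSignal("ACC_x", "acc", ACC_FS, acc["ACC_x"]),
        ChannelSignal("ACC_y", "acc", ACC_FS, acc["ACC_y"]),
        ChannelSignal("ACC_z", "acc", ACC_FS, acc["ACC_z"]),
    ]
    rec = Recording(person_id=profile.person_id, channels=channels)
    return rec, annotations


def simulate_cohort(cohort: CohortSpec, out_dir: str | Path) -> dict:
    """Simulate every profile, write EDFs + one annotation CSV + manifest.

    Returns the manifest (also written as ``manifest.json``): relative
    paths of all artifacts plus the seeds and parameters that produced
    them, so a run is fully reproducible from the manifest alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recordings: dict[str, str] = {}
    seeds: dict[str, int] = {}
    all_annos: list[SeizureAnnotation] = []
    for profile in cohort.profiles:
        rec, annos = simulate_recording(profile, cohort)
        fname = f"{profile.person_id}.edf"
        write_recording(rec, out_dir / fname)
        recordings[profile.person_id] = fname
        seeds[profile.person_id] = profile.seed
        all_annos.extend(annos)
    write_annotations(all_annos, out_dir / "annotations.csv")
    manifest = {
        "annotations": "annotations.csv",
        "recordings": recordings,
        "seeds": seeds,
        "parameters": {
            "interictal_gap_s": list(cohort.interictal_gap_s),
            "background_eeg": cohort.background_eeg,
            "background_acc": {
                "gravity_g": list(cohort.background_acc["gravity_g"]),
                "noise_sd_g": cohort.background_acc["noise_sd_g"],
            },
            "fbtcs_extra": cohort.fbtcs_extra,
            "intensity_jitter_sd": cohort.intensity_jitter_sd,
            "profiles": [
                {
                    "person_id": p.person_id, "seed": p.seed,
                    "eeg_band_gain": p.eeg_band_gain,
                    "emg_burst_gain": p.emg_burst_gain,
                    "acc_shift_g": p.acc_shift_g,
                    "acc_tremor_amp": p.acc_tremor_amp,
                    "n_seizures": p.n_seizures,
                    "seizure_duration_s": list(p.seizure_duration_s),
                }
                for p in cohort.profiles
            ],
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Stock cohorts
# ---------------------------------------------------------------------------

#: Four archetype ictal signatures: theta-dominant (B), mixed
#: theta+movement (E), EMG-dominant (G), movement-dominant (I).
#: Dominant power gains are >= 3x background.
ARCHETYPE_SIGNATURES: dict[str, dict] = {
    "B": {"eeg_band_gain": {"delta": 1.5, "low_theta": 5.0, "high_theta": 3.5},
          "emg_burst_gain": 1.0, "acc_shift_g": 0.0, "acc_tremor_amp": 0.0},
    "E": {"eeg_band_gain": {"low_theta": 3.0, "high_theta": 2.0},
          "emg_burst_gain": 1.0, "acc_shift_g": 0.25, "acc_tremor_amp": 0.0},
    "G": {"eeg_band_gain": {}, "emg_burst_gain": 7.0,
          "acc_shift_g": 0.0, "acc_tremor_amp": 0.0},
    "I": {"eeg_band_gain": {"delta": 3.0}, "emg_burst_gain": 1.0,
          "acc_shift_g": 0.45, "acc_tremor_amp": 0.0},
}

_DEFAULT_COUNTS = {"B": 25, "E": 15, "G": 12, "I": 22}
_DEFAULT_FBTCS = {"B": 2, "E": 2}


def _person_seeds(seed: int, ids: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(ids))
    return {pid: int(c.generate_state(1)[0] % (2 ** 31)) for pid, c in zip(ids, children)}


def archetype_cohort(
    seed: int = 1,
    n_seizures: dict[str, int] | None = None,
    fbtcs_extra: dict[str, int] | None = None,
) -> CohortSpec:
    """The stock 4-person cohort with pairwise-distinct ictal archetypes.

    Default electrographic seizure counts are 25/15/12/22 for persons
    B/E/G/I with two additional FBTCS each for B and E (78 planted
    seizures, 74 electrographic non-FBTCS).
    """
    counts = dict(_DEFAULT_COUNTS if n_seizures is None else n_seizures)
    fbtcs = dict(_DEFAULT_FBTCS if fbtcs_extra is None else fbtcs_extra)
    seeds = _person_seeds(seed, sorted(counts))
    profiles = [
        PersonProfile(person_id=pid, seed=seeds[pid], n_seizures=counts[pid],
                      **ARCHETYPE_SIGNATURES[pid])
        for pid in sorted(counts)
    ]
    return CohortSpec(profiles=profiles, fbtcs_extra=fbtcs)


def null_cohort(seed: int = 1, n_seizures: int = 12, n_persons: int = 4) -> CohortSpec:
    """A negative-control cohort: all ictal signatures zeroed (gains 1,
    no movement, no ictal artifact) and homogeneous backgrounds (no
    amplitude drift, posture epochs, rhythm bursts or activity bouts),
    so every analysis period of every person is exchangeable. Seizures
    are annotated but leave no trace in the signals."""
    ids = [chr(ord("A") + i) for i in range(n_persons)]
    seeds = _person_seeds(seed, ids)
    profiles = [
        PersonProfile(person_id=pid, seed=seeds[pid], n_seizures=n_seizures)
        for pid in ids
    ]
    spec = CohortSpec(profiles=profiles)
    spec.background_eeg.update({
        "ictal_artifact_gain": (1.0, 1.0),
        "amp_mod_sd": 0.0,
        "rhythm_bursts": {},
    })
    spec.background_acc.update({
        "roll_range_rad": 0.0,
        "pitch_range_rad": 0.0,
        "activity_rate": 0.0,
    })
    return spec
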