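"""The multimodal feature catalog: EEG spectral, EMG-estimate and accelerometry.

Spectral features come from a Welch periodogram (2-s Hamming windows,
50% overlap, per-window mean detrend, one-sided density scaling) so
that the integral of the density over frequency equals the signal
variance. Band powers are trapezoidal integrals of that density; the
relative-power denominator is the 0.5–48 Hz total band (below mains
frequency, within Nyquist at 207 Hz).

The EMG estimate exploits the fact that the subcutaneous electrode
lead spans the temporalis muscle: EEG frequency content above 20 Hz is
dominated by temporalis EMG, so the >20 Hz band power of the bipolar
EEG channels serves as a surface-EMG surrogate. The proximal channel
(``emg_power_prox``) is the canonical one.

The accelerometer features describe trunk orientation (per-axis means,
pitch/roll), movement intensity (per-axis variability, signal-magnitude
area, first differences) and rhythmicity (dominant frequency), all at
the native 10 or 20 Hz rate.

The default catalog has 68 named features; it is data (a
:class:`FeatureCatalog`), enumerable and serializable alongside any
result that depends on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Recording
from .segmentation import AnalysisPeriod, Exclusion

__all__ = [
    "BANDS", "TOTAL_BAND", "EMG_LOW_HZ", "EMG_GUARD_HZ",
    "FeatureDef", "FeatureCatalog", "default_catalog", "paper_feature_names",
    "estimate_psd", "band_power", "relative_band_power", "emg_power",
    "spectral_edge", "peak_frequency", "line_length", "hjorth_parameters",
    "acc_features", "compute_feature_table", "METADATA_COLUMNS",
]

#: EEG band partition (Hz). "hf" is the 20–48 Hz remainder of the total band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "low_theta": (4.0, 6.0),
    "high_theta": (6.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 20.0),
    "hf": (20.0, 48.0),
}
TOTAL_BAND = (0.5, 48.0)

EMG_LOW_HZ = 20.0
EMG_GUARD_HZ = 3.0      # anti-alias margin below Nyquist
EMG_HIGH_HZ = 100.0     # min(100, fs/2 - guard) in practice

METADATA_COLUMNS = ["person_id", "seizure_id", "kind"]

_EEG_CHANNEL_SUFFIX = {"EEG_prox": "", "EEG_dist": "_dist"}
_EMG_CHANNEL_SUFFIX = {"EEG_prox": "_prox", "EEG_dist": "_dist"}


class SignalLengthError(ValueError):
    """Input shorter than the spectral estimator's minimum window."""


@dataclass(frozen=True)
class FeatureDef:
    """One catalog entry: a named feature and how it is computed."""

    name: str
    modality: str                 # "eeg" | "emg" | "acc"
    channel: str                  # channel label, or "all" for acc combos
    definition: str               # human-readable computing rule
    params: tuple = ()


@dataclass
class FeatureCatalog:
    """Ordered, uniquely named feature definitions."""

    entries: list[FeatureDef]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in catalog: {dupes}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subset(self, names: Sequence[str]) -> "FeatureCatalog":
        by_name = {e.name: e for e in self.entries}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise KeyError(f"features not in catalog: {missing}")
        return FeatureCatalog([by_name[n] for n in names])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = [
            {"name": e.name, "modality": e.modality, "channel": e.channel,
             "definition": e.definition, "params": list(e.params)}
            for e in self.entries
        ]
        text = json.dumps(payload, indent=2, sort_keys=False) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Spectral primitives
# ---------------------------------------------------------------------------

def estimate_psd(
    x: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density (units²/Hz).

    Hamming windows of ``window_s`` seconds with fractional ``overlap``
    and per-window mean detrend; the integral of the density over
    [0, fs/2] approximates the signal variance.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if len(x) < nperseg:
        raise SignalLengthError(
            f"need at least {nperseg} samples ({window_s:g} s at fs={fs:g}), got {len(x)}"
        )
    freqs, pxx = sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), detrend="constant",
        scaling="density",
    )
    return freqs, pxx


def band_power(
    freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float
) -> float:
    """Trapezoidal integral of the density over [lo, hi] Hz.

    Band edges off the frequency grid are handled by linear
    interpolation of the density at the edge.
    """
    if not (0.0 <= lo < hi):
        raise ValueError(f"band must satisfy 0 <= lo < hi, got [{lo}, {hi}]")
    if hi > freqs[-1] + 1e-9:
        raise ValueError(f"band upper edge {hi} Hz beyond Nyquist {freqs[-1]:g} Hz")
    inside = (freqs > lo) & (freqs < hi)
    grid = np.concatenate(([lo], freqs[inside], [hi]))
    dens = np.concatenate((
        [np.interp(lo, freqs, psd)], psd[inside], [np.interp(hi, freqs, psd)]
    ))
    return float(np.trapezoid(dens, grid))


def relative_band_power(
    freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float,
    total_band: tuple[float, float] = TOTAL_BAND,
) -> float:
    """Band power as a fraction of the total-band power; 0 if the total is 0."""
    t_lo, t_hi = total_band
    if lo < t_lo - 1e-9 or hi > t_hi + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] outside total band {total_band}")
    denom = band_power(freqs, psd, t_lo, t_hi)
    if denom <= 0.0:
        return 0.0
    return band_power(freqs, psd, lo, hi) / denom


def emg_power(x: np.ndarray, fs: float) -> float:
    """Surface-EMG surrogate: EEG band power above 20 Hz (units²).

    Integrates [20, min(100, fs/2 − 3)] Hz; at fs = 207 the band is
    [20, 100] Hz.
    """
    freqs, psd = estimate_psd(x, fs)
    hi = min(EMG_HIGH_HZ, fs / 2.0 - EMG_GUARD_HZ)
    return band_power(freqs, psd, EMG_LOW_HZ, hi)


def spectral_edge(
    freqs: np.ndarray, psd: np.ndarray, fraction: float = 0.95,
    band: tuple[float, float] = TOTAL_BAND,
) -> float:
    """Frequency below which ``fraction`` of the band power lies (Hz)."""
    lo, hi = band
    inside = (freqs > lo) & (freqs < hi)
    grid = np.concatenate(([lo], freqs[inside], [hi]))
    dens = np.concatenate((
        [np.interp(lo, freqs, psd)], psd[inside], [np.interp(hi, freqs, psd)]
    ))
    cum = np.concatenate(([0.0], np.cumsum(np.diff(grid) * (dens[:-1] + dens[1:]) / 2.0)))
    total = cum[-1]
    if total <= 0.0:
        return lo
    return float(np.interp(fraction * total, cum, grid))


def peak_frequency(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float] = TOTAL_BAND
) -> float:
    """Frequency of maximum density within the band (Hz)."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        return lo
    sub = np.where(mask)[0]
    return float(freqs[sub[np.argmax(psd[sub])]])


def line_length(x: np.ndarray, fs: float) -> float:
    """Mean absolute first difference per second (units/s)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(np.mean(np.abs(np.diff(x))) * fs)


def hjorth_parameters(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    """Hjorth activity (units²), mobility (Hz-like) and complexity.

    mobility = sqrt(var(dx/dt) / var(x)); complexity is the mobility of
    the derivative over the mobility of the signal. Both are 0 for a
    constant input.
    """
    x = np.asarray(x, dtype=float)
    dx = np.diff(x) * fs
    ddx = np.diff(dx) * fs
    var_x = float(np.var(x))
    var_dx = float(np.var(dx))
    var_ddx = float(np.var(ddx))
    activity = var_x
    mobility = np.sqrt(var_dx / var_x) if var_x > 0 else 0.0
    mob_dx = np.sqrt(var_ddx / var_dx) if var_dx > 0 else 0.0
    complexity = mob_dx / mobility if mobility > 0 else 0.0
    return activity, float(mobility), float(complexity)


# ---------------------------------------------------------------------------
# Per-modality feature blocks
# ---------------------------------------------------------------------------

def _eeg_channel_features(x: np.ndarray, fs: float, suffix: str) -> dict[str, float]:
    freqs, psd = estimate_psd(x, fs)
    out: dict[str, float] = {}
    for band, (lo, hi) in BANDS.items():
        out[f"eeg_abspow_{band}{suffix}"] = band_power(freqs, psd, lo, hi)
        out[f"eeg_relpow_{band}{suffix}"] = relative_band_power(freqs, psd, lo, hi)
    out[f"eeg_totpow{suffix}"] = band_power(freqs, psd, *TOTAL_BAND)
    out[f"eeg_sef95{suffix}"] = spectral_edge(freqs, psd, 0.95)
    out[f"eeg_peakfreq{suffix}"] = peak_frequency(freqs, psd)
    out[f"eeg_linelength{suffix}"] = line_length(x, fs)
    act, mob, comp = hjorth_parameters(x, fs)
    out[f"eeg_hjorth_activity{suffix}"] = act
    out[f"eeg_hjorth_mobility{suffix}"] = mob
    out[f"eeg_hjorth_complexity{suffix}"] = comp
    return out


def _highpass(x: np.ndarray, fs: float, cutoff: float = EMG_LOW_HZ) -> np.ndarray:
    sos = sps.butter(4, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _emg_channel_features(x: np.ndarray, fs: float, suffix: str) -> dict[str, float]:
    freqs, psd = estimate_psd(x, fs)
    hi = min(EMG_HIGH_HZ, fs / 2.0 - EMG_GUARD_HZ)
    power = band_power(freqs, psd, EMG_LOW_HZ, hi)
    denom = band_power(freqs, psd, TOTAL_BAND[0], hi)
    hp = _highpass(x, fs)
    win = max(1, int(round(0.25 * fs)))
    kernel = np.ones(win) / win
    rms = np.sqrt(np.maximum(np.convolve(hp * hp, kernel, mode="valid"), 0.0))
    zc = np.count_nonzero(np.diff(np.signbit(hp))) * fs / max(len(hp) - 1, 1)
    return {
        f"emg_power{suffix}": power,
        f"emg_relpow{suffix}": power / denom if denom > 0 else 0.0,
        f"emg_rms_mean{suffix}": float(np.mean(rms)),
        f"emg_rms_max{suffix}": float(np.max(rms)),
        f"emg_zcr{suffix}": float(zc),
    }


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    xd = np.asarray(x, dtype=float)
    xd = xd - np.mean(xd)
    freqs, psd = estimate_psd(xd, fs)
    mask = freqs > 0.25
    if not mask.any() or np.max(psd[mask]) <= 0:
        return 0.0
    sub = np.where(mask)[0]
    return float(freqs[sub[np.argmax(psd[sub])]])


def acc_features(
    ax: np.ndarray, ay: np.ndarray, az: np.ndarray, fs: float,
    movement_threshold_g: float = 0.05,
) -> dict[str, float]:
    """Trunk posture and movement descriptors from the 3-axis accelerometer.

    Orientation: per-axis means, pitch/roll (degrees) from the mean
    gravity projection. Movement: per-axis and magnitude variability,
    signal-magnitude area, mean absolute first differences (g/s),
    dominant frequencies, and the fraction of samples whose magnitude
    deviates from its mean by more than ``movement_threshold_g``.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError(f"axis length mismatch: {len(ax)}, {len(ay)}, {len(az)}")
    if len(ax) < 2 * fs:
        raise SignalLengthError(f"need at least 2 s of accelerometry at fs={fs:g}")
    m = np.sqrt(ax * ax + ay * ay + az * az)
    mean = {"x": float(np.mean(ax)), "y": float(np.mean(ay)), "z": float(np.mean(az))}
    out: dict[str, float] = {}
    for axis, v in (("x", ax), ("y", ay), ("z", az)):
        out[f"acc_{axis}_mean"] = mean[axis]
        out[f"acc_{axis}_sd"] = float(np.std(v))
        out[f"acc_{axis}_madiff"] = float(np.mean(np.abs(np.diff(v))) * fs)
        out[f"acc_{axis}_domfreq"] = _dominant_frequency(v, fs)
    out["acc_m_mean"] = float(np.mean(m))
    out["acc_m_sd"] = float(np.std(m))
    out["acc_m_madiff"] = float(np.mean(np.abs(np.diff(m))) * fs)
    out["acc_m_domfreq"] = _dominant_frequency(m, fs)
    out["acc_pitch_deg"] = float(np.degrees(
        np.arctan2(mean["x"], np.hypot(mean["y"], mean["z"]))))
    out["acc_roll_deg"] = float(np.degrees(
        np.arctan2(mean["y"], np.hypot(mean["x"], mean["z"]))))
    out["acc_sma"] = float(np.mean(np.abs(ax) + np.abs(ay) + np.abs(az)))
    out["acc_move_frac"] = float(np.mean(np.abs(m - np.mean(m)) > movement_threshold_g))
    return out


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

def paper_feature_names() -> list[str]:
    """The five canonical fingerprint features, in radar order F1–F5."""
    return [
        "acc_x_mean",            # F1: x-axis acceleration component
        "emg_power_prox",        # F2: EMG power, proximal contact
        "eeg_relpow_delta",      # F3: relative delta power
        "eeg_relpow_low_theta",  # F4: relative low-theta power
        "eeg_relpow_high_theta", # F5: relative high-theta power
    ]


def fingerprint_families() -> dict[str, str]:
    """Map catalog features to the fingerprint family they respond to.

    Tree-based importance is invariant to monotone transforms, so
    several catalog features carry the same discriminative signal as a
    canonical fingerprint feature (e.g. trunk pitch is a monotone
    function of the mean x acceleration; the >20 Hz proximal band
    power has RMS and sub-band twins). The families group such
    equivalents: ``acc_x`` (F1), ``emg_prox`` (F2), ``delta`` (F3),
    ``low_theta`` (F4), ``high_theta`` (F5). Features outside any
    family are omitted.
    """
    fam: dict[str, str] = {}
    fam.update({n: "acc_x" for n in
                ("acc_x_mean", "acc_pitch_deg", "acc_m_mean", "acc_sma")})
    fam.update({n: "emg_prox" for n in
                ("emg_power_prox", "emg_relpow_prox", "emg_rms_mean_prox",
                 "emg_rms_max_prox", "emg_zcr_prox", "eeg_abspow_hf",
                 "eeg_relpow_hf",
                 # whole-spectrum shape summaries of the proximal
                 # channel: their between-person variation is the >20 Hz
                 # power share (RMS frequency, 95% edge, and its inverse)
                 "eeg_hjorth_mobility", "eeg_hjorth_complexity",
                 "eeg_sef95")})
    for band, key in (("delta", "delta"), ("low_theta", "low_theta"),
                      ("high_theta", "high_theta")):
        for suffix in ("", "_dist"):
            fam[f"eeg_relpow_{band}{suffix}"] = key
            fam[f"eeg_abspow_{band}{suffix}"] = key
    return fam


def default_catalog() -> FeatureCatalog:
    """The 68-entry default feature catalog (38 EEG + 10 EMG + 20 acc).

    The proximal EEG channel carries the unsuffixed names (so the five
    canonical fingerprint features appear verbatim); the distal channel
    is suffixed ``_dist``.
    """
    entries: list[FeatureDef] = []
    for ch, suffix in _EEG_CHANNEL_SUFFIX.items():
        for band, (lo, hi) in BANDS.items():
            entries.append(FeatureDef(
                f"eeg_abspow_{band}{suffix}", "eeg", ch,
                f"absolute band power {lo}-{hi} Hz (uV^2)", (lo, hi)))
            entries.append(FeatureDef(
                f"eeg_relpow_{band}{suffix}", "eeg", ch,
                f"relative band power {lo}-{hi} Hz over {TOTAL_BAND[0]}-{TOTAL_BAND[1]} Hz",
                (lo, hi)))
        entries.append(FeatureDef(f"eeg_totpow{suffix}", "eeg", ch,
                                  f"total power {TOTAL_BAND[0]}-{TOTAL_BAND[1]} Hz (uV^2)"))
        entries.append(FeatureDef(f"eeg_sef95{suffix}", "eeg", ch,
                                  "95% spectral edge frequency (Hz)"))
        entries.append(FeatureDef(f"eeg_peakfreq{suffix}", "eeg", ch,
                                  "peak frequency of the density (Hz)"))
        entries.append(FeatureDef(f"eeg_linelength{suffix}", "eeg", ch,
                                  "mean |first difference| per second (uV/s)"))
        entries.append(FeatureDef(f"eeg_hjorth_activity{suffix}", "eeg", ch,
                                  "Hjorth activity = variance (uV^2)"))
        entries.append(FeatureDef(f"eeg_hjorth_mobility{suffix}", "eeg", ch,
                                  "Hjorth mobility"))
        entries.append(FeatureDef(f"eeg_hjorth_complexity{suffix}", "eeg", ch,
                                  "Hjorth complexity"))
    for ch, suffix in _EMG_CHANNEL_SUFFIX.items():
        entries.append(FeatureDef(f"emg_power{suffix}", "emg", ch,
                                  ">20 Hz band power, EMG estimate (uV^2)"))
        entries.append(FeatureDef(f"emg_relpow{suffix}", "emg", ch,
                                  ">20 Hz power relative to 0.5 Hz..upper EMG edge"))
        entries.append(FeatureDef(f"emg_rms_mean{suffix}", "emg", ch,
                                  "mean of 0.25-s RMS of >20 Hz high-passed signal (uV)"))
        entries.append(FeatureDef(f"emg_rms_max{suffix}", "emg", ch,
                                  "max of 0.25-s RMS of >20 Hz high-passed signal (uV)"))
        entries.append(FeatureDef(f"emg_zcr{suffix}", "emg", ch,
                                  "zero-crossing rate of >20 Hz high-passed signal (1/s)"))
    for axis in ("x", "y", "z"):
        ch = f"ACC_{axis}"
        entries.append(FeatureDef(f"acc_{axis}_mean", "acc", ch, f"mean {axis}-axis acceleration (g)"))
        entries.append(FeatureDef(f"acc_{axis}_sd", "acc", ch, f"{axis}-axis standard deviation (g)"))
        entries.append(FeatureDef(f"acc_{axis}_madiff", "acc", ch,
                                  f"mean |first difference| per second, {axis}-axis (g/s)"))
        entries.append(FeatureDef(f"acc_{axis}_domfreq", "acc", ch,
                                  f"dominant frequency of the {axis}-axis (Hz)"))
    entries.append(FeatureDef("acc_m_mean", "acc", "all", "mean acceleration magnitude (g)"))
    entries.append(FeatureDef("acc_m_sd", "acc", "all", "magnitude standard deviation (g)"))
    entries.append(FeatureDef("acc_m_madiff", "acc", "all",
                              "mean |first difference| per second of magnitude (g/s)"))
    entries.append(FeatureDef("acc_m_domfreq", "acc", "all", "dominant frequency of magnitude (Hz)"))
    entries.append(FeatureDef("acc_pitch_deg", "acc", "all", "trunk pitch from mean gravity (deg)"))
    entries.append(FeatureDef("acc_roll_deg", "acc", "all", "trunk roll from mean gravity (deg)"))
    entries.append(FeatureDef("acc_sma", "acc", "all", "signal-magnitude area (g)"))
    entries.append(FeatureDef("acc_move_frac", "acc", "all",
                              "fraction of samples with |m - mean(m)| > threshold"))
    return FeatureCatalog(entries)


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def _slice(samples: np.ndarray, fs: float, start_s: float, end_s: float) -> np.ndarray:
    # half-open [start, end) in sample indices, index = floor(t * fs)
    i0 = int(np.floor(start_s * fs))
    i1 = int(np.floor(end_s * fs))
    if i0 < 0 or i1 > len(samples):
        raise IndexError(
            f"period [{start_s:g}, {end_s:g}] s outside signal of "
            f"{len(samples) / fs:g} s"
        )
    return samples[i0:i1]


def _period_features(rec: Recording, period: AnalysisPeriod) -> dict[str, float]:
    values: dict[str, float] = {}
    for label, suffix in _EEG_CHANNEL_SUFFIX.items():
        ch = rec.channel(label)
        x = _slice(ch.samples, ch.fs, period.start_s, period.end_s)
        values.update(_eeg_channel_features(x, ch.fs, suffix))
        values.update(_emg_channel_features(x, ch.fs, _EMG_CHANNEL_SUFFIX[label]))
    acc = {axis: rec.channel(f"ACC_{axis}") for axis in ("x", "y", "z")}
    fs_acc = acc["x"].fs
    sliced = {axis: _slice(c.samples, c.fs, period.start_s, period.end_s)
              for axis, c in acc.items()}
    values.update(acc_features(sliced["x"], sliced["y"], sliced["z"], fs_acc))
    return values


def compute_feature_table(
    rec: Recording,
    periods: Sequence[AnalysisPeriod],
    catalog: FeatureCatalog | None = None,
) -> tuple[pd.DataFrame, list[Exclusion]]:
    """Evaluate the catalog on every period of one recording.

    Returns ``(table, log)``: a DataFrame with metadata columns
    (person_id, seizure_id, kind) followed by the catalog features in
    catalog order, and an exclusion log of periods whose feature
    computation failed (those rows are dropped, never NaN-filled).
    """
    catalog = catalog if catalog is not None else default_catalog()
    rows: list[dict] = []
    log: list[Exclusion] = []
    for p in periods:
        if p.person_id != rec.person_id:
            raise ValueError(
                f"period {p.seizure_id!r} belongs to {p.person_id!r}, "
                f"recording is {rec.person_id!r}"
            )
        try:
            vals = _period_features(rec, p)
        except IndexError:
            raise
        except (SignalLengthError, ValueError) as exc:
            log.append(Exclusion(p.person_id, p.seizure_id, "feature",
                                 f"{p.kind}: {exc}"))
            continue
        row = {"person_id": p.person_id, "seizure_id": p.seizure_id, "kind": p.kind}
        missing = [n for n in catalog.names if n not in vals]
        if missing:
            raise KeyError(f"catalog names not computed: {missing}")
        for name in catalog.names:
            row[name] = vals[name]
        rows.append(row)
    table = pd.DataFrame(rows, columns=METADATA_COLUMNS + catalog.names)
    return table, log
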