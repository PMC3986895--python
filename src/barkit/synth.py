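"""Synthetic bark data, at two levels.

1. **Parametric feature tables** — calls drawn from per-population Gaussian
   distributions of the five discriminating acoustic features, with calls
   nested within males: a male-level random offset carries a fraction
   ``rho_male`` of the total variance and call-level noise carries the rest,
   so the pooled per-population moments match the profile exactly in
   expectation.

2. **Audio bouts** — source-filter style waveforms (harmonic pulse train with
   a linear F0 sweep, mixed with band-limited noise) assembled into calls and
   bouts with known gap structure, returned together with ground-truth
   element labels. These exist to exercise segmentation and feature
   extraction, not to imitate real bark timbre.

The three built-in population profiles carry the published per-population
mean ± SD of Ex1 duration (ms), F0 start (Hz), F0 linear trend
(dimensionless), frequency range (Hz) and peak-frequency deviation (Hz) for
West African green monkeys and South/East African vervets, and the study's
sampling design (12/12/13 males contributing 120/120/112 calls).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import ElementLabel, Waveform

__all__ = [
    "FEATURE_NAMES",
    "POPULATIONS",
    "DEFAULT_DESIGN",
    "PopulationProfile",
    "BoutSpec",
    "SynthDataset",
    "builtin_profiles",
    "sample_feature_table",
    "synthesize_element",
    "synthesize_bout",
]

#: The five features with published per-population distributions.
FEATURE_NAMES = (
    "ex1_duration",
    "f0_start",
    "f0_linear_trend",
    "frequency_range",
    "pf_deviation",
)

POPULATIONS = ("green_monkey", "south_vervet", "east_vervet")

#: (n_males, n_calls) per population; 10 calls/male with the deficit of the
#: third population spread over its last males.
DEFAULT_DESIGN: dict[str, tuple[int, int]] = {
    "green_monkey": (12, 120),
    "south_vervet": (12, 120),
    "east_vervet": (13, 112),
}

# Published per-population mean/SD (units: ms, Hz, -, Hz, Hz).
_PROFILE_TABLE = {
    "green_monkey": {
        "mean": (262.0, 254.0, -0.14, 197.0, 128.0),
        "sd": (110.0, 40.0, 0.12, 708.0, 68.0),
    },
    "south_vervet": {
        "mean": (99.0, 282.0, -0.11, 116.0, 101.0),
        "sd": (16.0, 57.0, 0.23, 831.0, 53.0),
    },
    "east_vervet": {
        "mean": (113.0, 320.0, -0.10, 565.0, 156.0),
        "sd": (19.0, 61.0, 0.23, 645.0, 115.0),
    },
}


@dataclass(frozen=True)
class PopulationProfile:
    """Per-population feature distribution plus male/call variance split.

    ``rho_male`` is the fraction of each feature's total variance assigned
    to between-male differences (the published tables give only pooled SDs,
    so the split is a model choice; see the methods note).
    """

    name: str
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    rho_male: float = 0.25

    def __post_init__(self) -> None:
        if set(self.feature_means) != set(self.feature_sds):
            raise ValueError("means and SDs must cover the same features")
        if any(sd < 0 for sd in self.feature_sds.values()):
            raise ValueError("feature SDs must be non-negative")
        if not 0.0 <= self.rho_male < 1.0:
            raise ValueError(f"rho_male must be in [0, 1), got {self.rho_male}")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.feature_means)


def builtin_profiles(rho_male: float = 0.25) -> dict[str, PopulationProfile]:
    """The three built-in population profiles (published mean ± SD)."""
    return {
        name: PopulationProfile(
            name=name,
            feature_means=dict(zip(FEATURE_NAMES, row["mean"])),
            feature_sds=dict(zip(FEATURE_NAMES, row["sd"])),
            rho_male=rho_male,
        )
        for name, row in _PROFILE_TABLE.items()
    }


@dataclass
class SynthDataset:
    """A sampled feature table plus the design and seed that produced it."""

    features: pd.DataFrame
    seed: int
    design: dict[str, tuple[int, int]]

    @property
    def n_calls(self) -> int:
        return len(self.features)


def _calls_per_male(n_males: int, n_calls: int, calls_per_male: int) -> list[int]:
    """Allocate calls to males: full quota first, deficit off the last males.

    Which males contributed fewer calls is not published; the deficit is
    spread arbitrarily over the last males (each keeps at least one call).
    """
    if n_calls > n_males * calls_per_male:
        raise ValueError(
            f"cannot place {n_calls} calls on {n_males} males at "
            f"{calls_per_male} calls/male"
        )
    if n_calls < n_males:
        raise ValueError("need at least one call per male")
    per = [calls_per_male] * n_males
    deficit = n_males * calls_per_male - n_calls
    i = n_males - 1
    while deficit > 0:
        take = min(calls_per_male - 1, deficit)
        per[i] -= take
        deficit -= take
        i -= 1
    return per


def sample_feature_table(
    profiles: dict[str, PopulationProfile] | None = None,
    design: dict[str, tuple[int, int]] | None = None,
    calls_per_male: int = 10,
    rho_male: float | None = None,
    seed: int = 0,
) -> SynthDataset:
    """Draw a call-level feature table from per-population profiles.

    For each male a feature offset is drawn from N(0, rho_male * SD^2); his
    calls are drawn around (mean + offset) with variance (1 - rho_male) * SD^2.
    Marginally each call is N(mean, SD^2), so pooled per-population moments
    converge to the profile values. Features are sampled independently —
    published tables give no between-feature correlations — and are not
    truncated, so the printed moments are preserved even where SD > mean.

    Parameters
    ----------
    profiles : mapping, optional
        Population name -> :class:`PopulationProfile`; defaults to the three
        built-in profiles.
    design : mapping, optional
        Population name -> (n_males, n_calls); defaults to the study design
        (12/12/13 males, 120/120/112 calls).
    rho_male : float, optional
        Override the profiles' between-male variance fraction.
    """
    if profiles is None:
        profiles = builtin_profiles()
    if design is None:
        design = {
            name: DEFAULT_DESIGN.get(name, (12, 120)) for name in profiles
        }
    if rho_male is not None:
        if not 0.0 <= rho_male < 1.0:
            raise ValueError(f"rho_male must be in [0, 1), got {rho_male}")
        profiles = {k: replace(p, rho_male=rho_male) for k, p in profiles.items()}

    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for name, profile in profiles.items():
        n_males, n_calls = design[name]
        if n_males < 1 or n_calls < 1:
            raise ValueError(f"{name}: need at least one male and one call")
        feats = profile.features
        means = np.array([profile.feature_means[f] for f in feats])
        sds = np.array([profile.feature_sds[f] for f in feats])
        rho = profile.rho_male
        for male_idx, k in enumerate(_calls_per_male(n_males, n_calls, calls_per_male)):
            male_id = f"{name}_m{male_idx + 1:02d}"
            offset = rng.normal(0.0, sds * np.sqrt(rho))
            values = means + offset + rng.normal(
                0.0, sds * np.sqrt(1.0 - rho), size=(k, len(feats))
            )
            for call_idx in range(k):
                row = {
                    "population": name,
                    "male_id": male_id,
                    "bout_id": f"{male_id}_b1",
                    "call_id": f"{male_id}_c{call_idx + 1:03d}",
                }
                row.update(dict(zip(feats, values[call_idx])))
                rows.append(row)
    table = pd.DataFrame(rows)
    return SynthDataset(features=table, seed=seed, design=dict(design))


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoutSpec:
    """Recipe for a synthetic calling bout.

    A bout is ``n_calls`` calls; call *i* contains ``elements_per_call[i]``
    elements. Within a call consecutive elements are separated by
    ``intra_call_gap_ms``; calls are separated by ``inter_call_gap_ms``
    (which must exceed the intra-call gap so the bout is segmentable).
    Inhalation elements are rendered at lower amplitude and lower tonality
    than exhalations, as in real bark series.
    """

    n_calls: int = 3
    elements_per_call: tuple[int, ...] | int = 1
    f0_start: float = 300.0
    f0_end: float = 260.0
    ex1_duration_ms: float = 150.0
    intra_call_gap_ms: float = 50.0
    inter_call_gap_ms: float = 300.0
    tonal_fraction: float = 0.8
    amplitude: float = 1.0
    sampling_rate: int = 44100
    noise_floor: float = 0.0
    lead_silence_ms: float = 100.0

    def element_counts(self) -> tuple[int, ...]:
        counts = self.elements_per_call
        if isinstance(counts, int):
            counts = (counts,) * self.n_calls
        if len(counts) != self.n_calls:
            raise ValueError(
                f"elements_per_call has {len(counts)} entries for "
                f"{self.n_calls} calls"
            )
        return tuple(counts)

    def __post_init__(self) -> None:
        if self.n_calls < 1:
            raise ValueError("a bout needs at least one call")
        if not self.intra_call_gap_ms < self.inter_call_gap_ms:
            raise ValueError(
                "intra_call_gap_ms must be below inter_call_gap_ms "
                "(otherwise the bout is not segmentable)"
            )
        if min(self.ex1_duration_ms, self.intra_call_gap_ms, self.inter_call_gap_ms) <= 0:
            raise ValueError("durations and gaps must be positive")
        nyquist = self.sampling_rate / 2
        if not (0 < self.f0_start < nyquist and 0 < self.f0_end < nyquist):
            raise ValueError("f0 values must lie in (0, sampling_rate/2)")
        if not 0.0 <= self.tonal_fraction <= 1.0:
            raise ValueError("tonal_fraction must be in [0, 1]")
        self.element_counts()


def synthesize_element(
    f0_start: float,
    f0_end: float,
    duration_ms: float,
    tonal_fraction: float = 1.0,
    sampling_rate: int = 44100,
    seed: int | np.random.Generator = 0,
    n_harmonics: int | None = None,
) -> Waveform:
    """Synthesize one exhalation-like element.

    The voiced component is a harmonic series (1/k amplitude roll-off) whose
    fundamental sweeps linearly from ``f0_start`` to ``f0_end``; it is mixed
    with band-limited Gaussian noise in amplitude proportion
    ``tonal_fraction : (1 - tonal_fraction)`` and RMS-normalized. A 5 ms
    raised-cosine ramp removes edge clicks. The sample count is
    ``floor(duration_ms / 1000 * sampling_rate)``.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    nyquist = sampling_rate / 2
    if max(f0_start, f0_end) >= nyquist:
        raise ValueError(
            f"f0 ({max(f0_start, f0_end)} Hz) must be below Nyquist ({nyquist} Hz)"
        )
    if min(f0_start, f0_end) <= 0:
        raise ValueError("f0 must be positive")
    if not 0.0 <= tonal_fraction <= 1.0:
        raise ValueError("tonal_fraction must be in [0, 1]")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(duration_ms / 1000.0 * sampling_rate)
    if n < 2:
        raise ValueError("duration too short for the sampling rate")

    t = np.arange(n) / sampling_rate
    f0 = np.linspace(f0_start, f0_end, n)
    phase = 2.0 * np.pi * np.cumsum(f0) / sampling_rate

    voiced = np.zeros(n)
    if tonal_fraction > 0:
        f0_max = max(f0_start, f0_end)
        if n_harmonics is None:
            # keep all harmonics below 90 % of Nyquist, at most 30
            n_harmonics = min(30, max(1, int(0.9 * nyquist / f0_max)))
        for k in range(1, n_harmonics + 1):
            voiced += np.sin(k * phase) / k
        voiced /= _rms(voiced)

    noise = np.zeros(n)
    if tonal_fraction < 1:
        noise = rng.standard_normal(n)
        # band-limit: keep energy in the call band (80 Hz .. 0.45 * rate)
        sos = sps.butter(4, [80.0, 0.45 * sampling_rate], btype="bandpass",
                         fs=sampling_rate, output="sos")
        noise = sps.sosfiltfilt(sos, noise)
        noise /= _rms(noise)

    x = tonal_fraction * voiced + (1.0 - tonal_fraction) * noise

    ramp_n = min(n // 4, int(0.005 * sampling_rate))
    if ramp_n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        x[:ramp_n] *= ramp
        x[-ramp_n:] *= ramp[::-1]

    x /= _rms(x)
    del t
    return Waveform(0.1 * x, sampling_rate)


def _rms(x: np.ndarray) -> float:
    r = float(np.sqrt(np.mean(np.square(x))))
    return r if r > 0 else 1.0


def _element_sequence(n_elements: int) -> list[str]:
    """Element types within one call: Ex1, then Ex2s; calls of three or more
    elements end with an inhalation (as in typical multi-unit bark series)."""
    if n_elements == 1:
        return ["Ex1"]
    if n_elements == 2:
        return ["Ex1", "Ex2"]
    return ["Ex1"] + ["Ex2"] * (n_elements - 2) + ["Inhal"]


def synthesize_bout(
    spec: BoutSpec, seed: int = 0
) -> tuple[Waveform, list[ElementLabel]]:
    """Render a bout waveform plus exact ground-truth element labels.

    Exhalations carry the spec's F0 sweep and tonal fraction; within-call
    exhalations (Ex2) are rendered at 70 % of the Ex1 duration, inhalations
    at 60 % duration, 30 % amplitude and tonal fraction 0.05. With
    ``noise_floor = 0`` every sample outside a labelled element is exactly
    zero.
    """
    rng = np.random.default_rng(seed)
    rate = spec.sampling_rate
    pieces: list[np.ndarray] = []
    labels: list[ElementLabel] = []
    cursor = int(spec.lead_silence_ms / 1000.0 * rate)
    pieces.append(np.zeros(cursor))

    counts = spec.element_counts()
    for call_idx, n_el in enumerate(counts):
        for el_idx, el_type in enumerate(_element_sequence(n_el)):
            if el_type == "Ex1":
                dur, amp, tonal = spec.ex1_duration_ms, 1.0, spec.tonal_fraction
            elif el_type == "Ex2":
                dur, amp, tonal = 0.7 * spec.ex1_duration_ms, 0.9, spec.tonal_fraction
            else:  # Inhal: weaker and noisier
                dur, amp, tonal = 0.6 * spec.ex1_duration_ms, 0.3, 0.05
            wav = synthesize_element(
                spec.f0_start, spec.f0_end, dur,
                tonal_fraction=tonal, sampling_rate=rate, seed=rng,
            )
            x = spec.amplitude * amp * wav.samples
            onset = cursor / rate
            cursor += len(x)
            labels.append(ElementLabel(onset, cursor / rate, el_type))
            pieces.append(x)
            last_in_call = el_idx == n_el - 1
            gap_ms = spec.inter_call_gap_ms if last_in_call else spec.intra_call_gap_ms
            if not (last_in_call and call_idx == len(counts) - 1):
                gap_n = int(gap_ms / 1000.0 * rate)
                pieces.append(np.zeros(gap_n))
                cursor += gap_n

    pieces.append(np.zeros(int(spec.lead_silence_ms / 1000.0 * rate)))
    samples = np.concatenate(pieces)
    if spec.noise_floor > 0:
        samples = samples + rng.normal(0.0, spec.noise_floor, size=len(samples))
    return Waveform(samples, rate), labels
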