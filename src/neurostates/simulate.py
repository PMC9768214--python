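"""Synthetic evoked-state EEG with controllable band-specific phase coupling.

Generative model
----------------
Each frequency band carries a small set of *shared drivers* — unit-power
narrowband Gaussian processes — one per channel-pair class:

* ``within_left``   — shared by the left fronto-central-temporal ROI
  (F3, F7, FC1, FC5, C3, T7);
* ``within_right``  — the mirror ROI (F4, F8, FC2, FC6, C4, T8);
* ``fronto_occipital`` — shared by the frontal and occipital channels
  outside those ROIs (Fp1, Fp2, Fz and the occipital row);
* ``global``        — shared by every channel.

The four classes partition all channel pairs. A member channel receives
each driver rotated by a fixed per-channel analytic phase offset
(golden-angle sequences assigned by rank within each class group, so
the left and right ROIs see identical lag multisets). Two channels
sharing a driver therefore exhibit a *constant, nonzero* phase lag —
exactly the asymmetric phase-difference signature the phase lag index
detects, while remaining invisible to zero-lag (volume-conduction-like)
leakage. The remaining channel variance is filled with independent
narrowband noise, and broadband white noise is added on top, so the
per-pair PLI grows monotonically with the class coupling value.

The six shipped state profiles encode the qualitative contrasts of the
evoked-state study: fatigue sharply raises global low-band coupling
density; attentiveness strengthens fronto-occipital coupling; positive
and negative affect tilt coupling toward the right and left hemisphere
ROIs respectively; resting keeps a moderately clustered, weakly
integrated topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import LEFT_ROI, RIGHT_ROI, MontageSpec, standard_30_channel_montage
from .recording import EEGRecording
from .signal import DEFAULT_BANDS, BandDefinition

__all__ = [
    "StateProfile",
    "PAIR_CLASSES",
    "shipped_profiles",
    "get_profile",
    "pair_class",
    "generate_state_recording",
    "generate_cohort",
]

PAIR_CLASSES = ("within_left", "within_right", "fronto_occipital", "global")

_GOLDEN_ANGLE = 2.399963229728653  # radians; quasi-uniform phase offsets

#: Relative amplitude of each band's oscillatory component (EEG power
#: falls with frequency).
_BAND_AMPLITUDE = {"low": 1.0, "high": 0.6}

#: Overall oscillation scale in microvolts RMS.
_SCALE_UV = 20.0


@dataclass(frozen=True)
class StateProfile:
    """Coupling parameters defining one synthetic mental state.

    ``coupling`` maps ``(band_name, pair_class)`` to the *effective*
    phase-locking strength in [0, 1] that channel pairs of the class
    exhibit; the ``global`` entry is the background every pair shares,
    so specific classes should state values >= it. ``noise_sd`` is the
    broadband white-noise amplitude relative to the oscillatory scale.
    """

    name: str
    coupling: dict[tuple[str, str], float] = field(hash=False)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for key, w in self.coupling.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"coupling {key} = {w} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def asymmetry(self) -> float:
        """Signed right-minus-left low-band coupling offset, in [-1, 1]."""
        return self.coupling.get(("low", "within_right"), 0.0) - self.coupling.get(
            ("low", "within_left"), 0.0
        )

    def weight(self, band: str, cls: str) -> float:
        return self.coupling.get((band, cls), 0.0)


def _profile(name, low, high, noise_sd=1.0):
    coupling = {}
    for band_name, weights in (("low", low), ("high", high)):
        for cls, w in zip(PAIR_CLASSES, weights):
            coupling[(band_name, cls)] = w
    return StateProfile(name=name, coupling=coupling, noise_sd=noise_sd)


# Coupling per band: (within_left, within_right, fronto_occipital, global).
# Values are *effective pair locking*: the phase-locking strength a channel
# pair of that class exhibits, with the global entry acting as the
# background every pair shares (so specific classes state >= global).
# Resting is moderately clustered (hemispheric ROIs) with weak global
# integration; fatigue floods the low band with near-uniform strong
# coupling (density rises abruptly, the clustering advantage over a random
# graph erodes -> gamma and sigma fall) and raises high-band density
# mildly; attentive strengthens fronto-occipital low-band coupling;
# inattentive dilutes structure with global coupling; positive/negative
# tilt the dense ROI to the right/left hemisphere, the negative state
# carrying more unstructured global coupling.
_SHIPPED = (
    _profile("resting",     low=(0.62, 0.55, 0.30, 0.14), high=(0.55, 0.46, 0.28, 0.12)),
    _profile("fatigue",     low=(0.90, 0.85, 0.80, 0.75), high=(0.68, 0.57, 0.46, 0.36),
             noise_sd=1.5),
    _profile("attentive",   low=(0.52, 0.44, 0.66, 0.15), high=(0.52, 0.43, 0.28, 0.12)),
    _profile("inattentive", low=(0.50, 0.42, 0.33, 0.24), high=(0.50, 0.41, 0.30, 0.12),
             noise_sd=1.1),
    _profile("positive",    low=(0.32, 0.68, 0.48, 0.15), high=(0.44, 0.54, 0.30, 0.12)),
    _profile("negative",    low=(0.66, 0.32, 0.42, 0.20), high=(0.54, 0.44, 0.28, 0.13),
             noise_sd=1.2),
)


def shipped_profiles() -> dict[str, StateProfile]:
    """The six built-in mental-state profiles, keyed by name."""
    return {p.name: p for p in _SHIPPED}


def get_profile(name: str) -> StateProfile:
    profiles = shipped_profiles()
    if name not in profiles:
        raise KeyError(
            f"unknown state profile {name!r}; available: {sorted(profiles)}"
        )
    return profiles[name]


def _class_members(montage: MontageSpec) -> dict[str, np.ndarray]:
    """Channel-index membership of each driver class."""
    names = montage.channel_names
    idx = {name: i for i, name in enumerate(names)}
    left = np.array([idx[c] for c in LEFT_ROI if c in idx], dtype=np.intp)
    right = np.array([idx[c] for c in RIGHT_ROI if c in idx], dtype=np.intp)
    fo = np.array(
        [i for i, c in enumerate(names) if _in_fo_group(montage, c)],
        dtype=np.intp,
    )
    everyone = np.arange(len(names), dtype=np.intp)
    return {
        "within_left": left,
        "within_right": right,
        "fronto_occipital": fo,
        "global": everyone,
    }


def _channel_offsets(montage: MontageSpec) -> np.ndarray:
    """Fixed per-channel analytic phase offsets for the shared drivers.

    Offsets are golden-angle sequences assigned by rank *within* each pair
    class's channel group (left ROI, right ROI, fronto-occipital group,
    remainder), with a distinct shift per group. The left and right ROIs
    thus see identical within-class lag multisets, so their class-mean PLI
    responds identically to equal coupling — hemispheric contrasts in the
    shipped profiles reflect coupling strength, never offset luck.
    """
    groups: list[list[int]] = [[], [], [], []]
    for i, ch in enumerate(montage.channel_names):
        if ch in LEFT_ROI:
            groups[0].append(i)
        elif ch in RIGHT_ROI:
            groups[1].append(i)
        elif _in_fo_group(montage, ch):
            groups[2].append(i)
        else:
            groups[3].append(i)
    beta = np.zeros(montage.n_channels)
    for g, idx in enumerate(groups):
        shift = 0.5 * _GOLDEN_ANGLE * g
        for rank, i in enumerate(idx):
            beta[i] = np.mod(_GOLDEN_ANGLE * rank + shift, 2.0 * np.pi)
    return beta


def _in_fo_group(montage: MontageSpec, ch: str) -> bool:
    # frontal/occipital channels outside the hemispheric ROIs, so the four
    # pair classes partition cleanly and each class's effective coupling is
    # exactly its stated value
    return (
        montage.lobe_of[ch] in ("frontal", "occipital")
        and ch not in LEFT_ROI
        and ch not in RIGHT_ROI
    )


def pair_class(montage: MontageSpec, ch_a: str, ch_b: str) -> str:
    """Coupling class of a channel pair (first matching class wins).

    Order: within_left, within_right, fronto_occipital, global — mirroring
    driver specificity. The classes partition all channel pairs.
    """
    if ch_a in LEFT_ROI and ch_b in LEFT_ROI:
        return "within_left"
    if ch_a in RIGHT_ROI and ch_b in RIGHT_ROI:
        return "within_right"
    if _in_fo_group(montage, ch_a) and _in_fo_group(montage, ch_b):
        return "fronto_occipital"
    return "global"


def _narrowband(
    rng: np.random.Generator,
    n_rows: int,
    n: int,
    fs: float,
    band: BandDefinition,
    analytic: bool = False,
) -> np.ndarray:
    """Rows of unit-RMS narrowband Gaussian noise (optionally analytic)."""
    pad = int(fs)  # one second of padding absorbs filter transients
    white = rng.standard_normal((n_rows, n + 2 * pad))
    sos = sps.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    narrow = sps.sosfiltfilt(sos, white, axis=-1)[:, pad:-pad]
    rms = np.sqrt(np.mean(narrow**2, axis=-1, keepdims=True))
    narrow /= rms
    if analytic:
        return sps.hilbert(narrow, axis=-1)
    return narrow


def generate_state_recording(
    profile: StateProfile | str,
    montage: MontageSpec | None = None,
    duration: float = 60.0,
    fs: float = 250.0,
    seed: int = 0,
    condition: str | None = None,
    subject_id: str | None = None,
) -> EEGRecording:
    """Simulate one multichannel recording of the given mental state.

    Deterministic: the same (profile, montage, duration, fs, seed) always
    yields a bit-identical recording.
    """
    if isinstance(profile, str):
        profile = get_profile(profile)
    if montage is None:
        montage = standard_30_channel_montage()
    if duration < 4.0:
        raise ValueError(
            f"duration {duration} s too short; need >= 4 s for stable "
            "phase statistics"
        )
    if fs < 60.0:
        raise ValueError(f"sampling rate {fs} Hz below the 60 Hz minimum")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    n_ch = montage.n_channels
    members = _class_members(montage)
    beta = _channel_offsets(montage)
    rotors = np.exp(1j * beta)

    data = np.zeros((n_ch, n))
    for band in DEFAULT_BANDS:
        amp = _BAND_AMPLITUDE[band.name]
        band_sig = np.zeros((n_ch, n))
        total_w2 = np.zeros(n_ch)
        drivers = _narrowband(rng, len(PAIR_CLASSES), n, fs, band, analytic=True)
        w_global = profile.weight(band.name, "global")
        for cls, driver in zip(PAIR_CLASSES, drivers):
            w = profile.weight(band.name, cls)
            if cls == "global":
                u = w
            else:
                # stated coupling is the *effective* pair locking; members
                # already share the global driver, so the class driver
                # supplies only the excess (clipped: a class cannot be less
                # locked than the global background)
                u = float(np.sqrt(max(w * w - w_global * w_global, 0.0)))
            if u == 0.0:
                continue
            ix = members[cls]
            band_sig[ix] += u * np.real(rotors[ix, None] * driver[None, :])
            total_w2[ix] += u * u
        w_ind = np.sqrt(np.clip(1.0 - total_w2, 0.0, None))
        indep = _narrowband(rng, n_ch, n, fs, band)
        band_sig += w_ind[:, None] * indep
        data += amp * band_sig
    data *= _SCALE_UV
    data += profile.noise_sd * _SCALE_UV * rng.standard_normal((n_ch, n))
    return EEGRecording(
        data=data,
        fs=fs,
        montage=montage,
        condition=condition or profile.name,
        subject_id=subject_id,
    )


def generate_cohort(
    profile_a: StateProfile | str,
    profile_b: StateProfile | str,
    n_per_group: int = 13,
    duration: float = 60.0,
    fs: float = 250.0,
    seed: int = 0,
    montage: MontageSpec | None = None,
) -> list[EEGRecording]:
    """Two labeled groups of independent single-subject recordings.

    Per-subject seeds are drawn deterministically from the master seed, so
    a fixed seed reproduces the whole cohort while subjects within a group
    differ from one another.
    """
    if n_per_group < 2:
        raise ValueError(
            f"n_per_group must be >= 2 (group statistics undefined), got "
            f"{n_per_group}"
        )
    if isinstance(profile_a, str):
        profile_a = get_profile(profile_a)
    if isinstance(profile_b, str):
        profile_b = get_profile(profile_b)
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_group)
    cohort = []
    for g, profile in enumerate((profile_a, profile_b)):
        for k in range(n_per_group):
            cohort.append(
                generate_state_recording(
                    profile,
                    montage=montage,
                    duration=duration,
                    fs=fs,
                    seed=int(subject_seeds[g * n_per_group + k]),
                    subject_id=f"{profile.name}-{k + 1:02d}",
                )
            )
    return cohort
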