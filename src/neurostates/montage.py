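"""30-channel 10-20 scalp montage with lobe and hemisphere groupings.

Channel labels follow the international 10-20 convention: odd digits mark
left-hemisphere electrodes, even digits right-hemisphere, a trailing ``z``
the midline. The default layout is a standard 30-electrode cap ordered
front to back, which contains every channel used in the hemispheric and
lobar region-of-interest analyses (F3, F7, FC1, FC5, C3, T7 on the left;
F4, F8, FC2, FC6, C4, T8 on the right; P7 and the occipital row).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MontageSpec",
    "standard_30_channel_montage",
    "LEFT_ROI",
    "RIGHT_ROI",
    "LOBES",
    "HEMISPHERES",
]

LOBES = ("frontal", "central", "parietal", "temporal", "occipital")
HEMISPHERES = ("left", "right", "midline")

#: Fronto-central-temporal ROI of the left hemisphere used in the
#: positive/negative-state asymmetry comparison.
LEFT_ROI = ("F3", "F7", "FC1", "FC5", "C3", "T7")
#: Mirror ROI of the right hemisphere.
RIGHT_ROI = ("F4", "F8", "FC2", "FC6", "C4", "T8")

# Front-to-back ordering of a standard 30-channel 10-20 cap.
_STANDARD_CHANNELS: tuple[tuple[str, str], ...] = (
    ("Fp1", "frontal"), ("Fp2", "frontal"),
    ("F7", "frontal"), ("F3", "frontal"), ("Fz", "frontal"),
    ("F4", "frontal"), ("F8", "frontal"),
    ("FC5", "frontal"), ("FC1", "frontal"), ("FC2", "frontal"), ("FC6", "frontal"),
    ("T7", "temporal"), ("C3", "central"), ("Cz", "central"),
    ("C4", "central"), ("T8", "temporal"),
    ("CP5", "parietal"), ("CP1", "parietal"), ("CP2", "parietal"), ("CP6", "parietal"),
    ("P7", "parietal"), ("P3", "parietal"), ("Pz", "parietal"),
    ("P4", "parietal"), ("P8", "parietal"),
    ("PO3", "occipital"), ("PO4", "occipital"),
    ("O1", "occipital"), ("Oz", "occipital"), ("O2", "occipital"),
)


def _hemisphere_of_label(label: str) -> str:
    tail = label[-1]
    if tail == "z":
        return "midline"
    return "left" if int(tail) % 2 == 1 else "right"


@dataclass(frozen=True)
class MontageSpec:
    """Electrode layout: ordered channel names plus lobe/hemisphere maps."""

    channel_names: tuple[str, ...]
    lobe_of: dict[str, str] = field(hash=False)
    hemisphere_of: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        for ch in self.channel_names:
            if ch not in self.lobe_of:
                raise ValueError(f"channel {ch!r} has no lobe assignment")
            if ch not in self.hemisphere_of:
                raise ValueError(f"channel {ch!r} has no hemisphere assignment")
            if self.lobe_of[ch] not in LOBES:
                raise ValueError(f"unknown lobe {self.lobe_of[ch]!r} for {ch!r}")
            if self.hemisphere_of[ch] not in HEMISPHERES:
                raise ValueError(
                    f"unknown hemisphere {self.hemisphere_of[ch]!r} for {ch!r}"
                )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names in montage")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index_of(self, label: str) -> int:
        try:
            return self.channel_names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def channels_in_lobe(self, lobe: str) -> tuple[str, ...]:
        if lobe not in LOBES:
            raise ValueError(f"unknown lobe {lobe!r}")
        return tuple(c for c in self.channel_names if self.lobe_of[c] == lobe)

    def channels_in_hemisphere(self, hemisphere: str) -> tuple[str, ...]:
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        return tuple(
            c for c in self.channel_names if self.hemisphere_of[c] == hemisphere
        )


def standard_30_channel_montage() -> MontageSpec:
    """The default 30-channel 10-20 montage, ordered front to back."""
    names = tuple(name for name, _ in _STANDARD_CHANNELS)
    lobes = {name: lobe for name, lobe in _STANDARD_CHANNELS}
    hemis = {name: _hemisphere_of_label(name) for name, _ in _STANDARD_CHANNELS}
    return MontageSpec(channel_names=names, lobe_of=lobes, hemisphere_of=hemis)
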