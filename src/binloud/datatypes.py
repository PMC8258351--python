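"""Domain types: scaling data records, stimulus specifications, profiles.

Categorical loudness scaling (CLS) records a listener's loudness judgment on
an 11-category scale (0, 5, ..., 50 CU) for a stimulus presented at a known
level.  A :class:`ScalingDataset` is the measurement record for one listener,
one presentation side and one stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

#: The 11 admissible response categories in categorical units (CU).
CU_CATEGORIES = tuple(float(c) for c in range(0, 55, 5))

LNN_CENTER_FREQS_HZ = (250.0, 500.0, 1000.0, 2000.0, 4000.0, 6000.0)
UEN_CENTER_FREQ_HZ = 1370.0
UEN_BANDWIDTH_HZ = 210.0


class StimulusKind(str, Enum):
    LNN = "LNN"   # narrowband low-noise noise, third-octave bandwidth
    UEN = "UEN"   # narrowband uniform exciting noise, 1.37 kHz / 210 Hz
    IFN = "IFN"   # broadband speech-shaped noise (female LTASS)


class Presentation(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    DIOTIC = "diotic"


@dataclass(frozen=True)
class ScalingDatum:
    """One loudness judgment: presentation level and categorical response."""

    level_db: float
    response_cu: float

    def __post_init__(self):
        if not math.isfinite(self.level_db):
            raise ValueError(f"level must be finite, got {self.level_db}")
        if self.response_cu not in CU_CATEGORIES:
            raise ValueError(
                f"response {self.response_cu} is not one of the 11 categories "
                f"0, 5, ..., 50 CU")


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulus description used throughout the package.

    ``azimuth_deg`` shifts the simulated sound incidence in the horizontal
    plane and is only admissible for the broadband IFN stimulus; narrowband
    stimuli are presented with frontal incidence.
    """

    kind: StimulusKind
    center_freq_hz: float | None = None
    presentation: Presentation = Presentation.DIOTIC
    azimuth_deg: float = 0.0
    aided: bool = False

    def __post_init__(self):
        kind = StimulusKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "presentation", Presentation(self.presentation))
        if kind is StimulusKind.LNN:
            if self.center_freq_hz not in LNN_CENTER_FREQS_HZ:
                raise ValueError(
                    f"LNN center frequency must be one of "
                    f"{LNN_CENTER_FREQS_HZ}, got {self.center_freq_hz}")
        elif kind is StimulusKind.UEN:
            if self.center_freq_hz is None:
                object.__setattr__(self, "center_freq_hz", UEN_CENTER_FREQ_HZ)
            elif self.center_freq_hz != UEN_CENTER_FREQ_HZ:
                raise ValueError("UEN center frequency is fixed at 1370 Hz")
        elif kind is StimulusKind.IFN:
            if self.center_freq_hz is not None:
                raise ValueError("IFN is broadband; center_freq_hz must be None")
        if self.azimuth_deg not in (-60.0, 0.0, 60.0):
            raise ValueError("azimuth must be -60, 0 or +60 degrees")
        if self.azimuth_deg != 0.0 and kind is not StimulusKind.IFN:
            raise ValueError("non-frontal incidence is only used for IFN")

    @property
    def label(self) -> str:
        if self.kind is StimulusKind.IFN:
            base = "IFN"
        else:
            base = f"{self.kind.value}{self.center_freq_hz:g}Hz"
        if self.azimuth_deg:
            base += f"{self.azimuth_deg:+g}deg"
        if self.aided:
            base += "-aided"
        return base


@dataclass
class ScalingDataset:
    """All loudness judgments of one listener for one stimulus/presentation."""

    listener_id: str
    stimulus: StimulusSpec
    data: list[ScalingDatum] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def levels(self):
        import numpy as np

        return np.array([d.level_db for d in self.data])

    @property
    def responses(self):
        import numpy as np

        return np.array([d.response_cu for d in self.data])

    def fittable(self) -> bool:
        """At least two distinct levels with supra-threshold responses."""
        lv = {d.level_db for d in self.data if d.response_cu > 0}
        return len(lv) >= 2


def group_datasets(records: Iterable[tuple[str, StimulusSpec, ScalingDatum]]
                   ) -> list[ScalingDataset]:
    """Group (listener, stimulus, datum) records into datasets, preserving
    first-appearance order of the (listener, stimulus) keys."""
    out: dict[tuple, ScalingDataset] = {}
    for listener, stim, datum in records:
        key = (listener, stim)
        if key not in out:
            out[key] = ScalingDataset(listener_id=listener, stimulus=stim)
        out[key].data.append(datum)
    return list(out.values())
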