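"""Electrode montage and scalp-region parcellation.

The recording montage is a 32-electrode extended international 10-20 cap.
Thirty electrodes enter the analyses; the left/right mastoids (A1/A2) serve
as reference and are excluded from all regional statistics.  The scalp is
parcellated into five lobar regions (frontal, central, parietal, occipital,
temporal) used for region-level aggregation of band power and entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

#: Region -> electrode labels (analysis electrodes only).
REGION_ELECTRODES: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
                "FT7", "FC3", "FCz", "FC4", "FT8"),
    "central": ("C3", "Cz", "C4", "CP3", "CPz", "CP4"),
    "parietal": ("P3", "Pz", "P4"),
    "occipital": ("O1", "Oz", "O2"),
    "temporal": ("T3", "TP7", "T5", "T4", "TP8", "T6"),
}

#: Full cap order as recorded (32 channels including mastoid references).
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT7", "FC3", "FCz",
    "FC4", "FT8", "T3", "C3", "Cz", "C4", "T4", "TP7", "CP3", "CPz",
    "CP4", "TP8", "T5", "P3", "P4", "Pz", "T6", "A1", "A2", "O1",
    "O2", "Oz",
)

#: The six midline electrodes used for the focused P300 analysis.
MIDLINE_6: tuple[str, ...] = ("Fz", "FCz", "Cz", "CPz", "Pz", "Oz")

REGIONS: tuple[str, ...] = tuple(REGION_ELECTRODES)


@dataclass(frozen=True)
class Montage:
    """Ordered channel set with an electrode -> region map."""

    channels: tuple[str, ...]
    region_of: Mapping[str, str] = field(repr=False)

    def region(self, label: str) -> str:
        try:
            return self.region_of[label]
        except KeyError:
            raise KeyError(f"unknown electrode label: {label!r}") from None

    @property
    def analysis_channels(self) -> tuple[str, ...]:
        """Channels that enter statistics (reference electrodes excluded)."""
        return tuple(c for c in self.channels if self.region_of[c] != "reference")

    def electrodes_in(self, region: str, subset: Sequence[str] | None = None) -> tuple[str, ...]:
        """Analysis electrodes of ``region``, optionally restricted to ``subset``."""
        pool = self.channels if subset is None else tuple(subset)
        return tuple(c for c in pool if self.region_of.get(c) == region)


def make_montage() -> Montage:
    """Build the 32-electrode cap with its five-region parcellation.

    Returns a :class:`Montage` whose ``region_of`` maps each of the 30
    analysis electrodes to one of frontal / central / parietal / occipital /
    temporal, and the mastoids A1/A2 to ``"reference"``.
    """
    region_of: dict[str, str] = {}
    for region, labels in REGION_ELECTRODES.items():
        for label in labels:
            region_of[label] = region
    region_of["A1"] = "reference"
    region_of["A2"] = "reference"
    missing = set(CHANNELS_32) - set(region_of)
    if missing:  # pragma: no cover - would indicate an internal table error
        raise RuntimeError(f"unmapped electrodes: {sorted(missing)}")
    return Montage(channels=CHANNELS_32, region_of=region_of)
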