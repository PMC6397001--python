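"""Small deterministic quantifications: arterial tone, densitometry, PLA.

Myogenic tone is the percent decrease of arterial diameter relative to the
maximum passive diameter; immunoblot densitometry is a background-subtracted
band ratio normalized to a control lane; proximity-ligation puncta are
reported per µm² of cell area.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ToneRecord",
    "DensitometryRecord",
    "percent_tone",
    "densitometry_ratio",
    "pla_puncta_density",
]


@dataclass(frozen=True)
class ToneRecord:
    active_diameter_um: float
    passive_diameter_um: float
    condition: str = ""

    def __post_init__(self):
        if not 0 < self.active_diameter_um <= self.passive_diameter_um:
            raise ValueError("require 0 < active diameter <= passive diameter")


@dataclass(frozen=True)
class DensitometryRecord:
    """One band with local background, plus its loading-control reference.

    ``local_background`` is the mean of equal-area regions measured above
    and below the band; ``control_ratio`` is the (band − bg)/(ref − refbg)
    ratio of the control lane that the result is normalized to.
    """

    band: float
    local_background: float
    reference_band: float
    reference_background: float
    control_ratio: float

    def __post_init__(self):
        if self.band <= self.local_background:
            raise ValueError("band intensity must exceed its background")
        if self.reference_band <= self.reference_background:
            raise ValueError("reference band intensity must exceed its background")
        if self.control_ratio <= 0:
            raise ValueError("control_ratio must be > 0")


def percent_tone(rec: ToneRecord) -> float:
    """Myogenic tone: 100 × (passive − active) / passive, in percent."""
    return 100.0 * (rec.passive_diameter_um - rec.active_diameter_um) / rec.passive_diameter_um


def densitometry_ratio(rec: DensitometryRecord) -> float:
    """Relative density: background-subtracted band over background-subtracted
    reference, normalized to the control lane's ratio."""
    ratio = (rec.band - rec.local_background) / (rec.reference_band - rec.reference_background)
    return ratio / rec.control_ratio


def pla_puncta_density(puncta_count: int, cell_area_um2: float) -> float:
    """Proximity-ligation puncta per µm² of cell area."""
    if puncta_count < 0:
        raise ValueError("puncta_count must be >= 0")
    if cell_area_um2 <= 0:
        raise ValueError("cell_area_um2 must be > 0")
    return puncta_count / cell_area_um2
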