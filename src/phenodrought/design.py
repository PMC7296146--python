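"""Experimental design description for platform phenotyping trials.

The layout modelled here is the conveyor-greenhouse design common in
high-throughput phenomics: each genotype is grown under two watering
regimes (well-watered control and drought), each regime replicated in a
number of carriers (trays of pots — the biological replicate unit), each
carrier holding several plants, imaged daily over a fixed observation
window.  Day indices are 1-based and contiguous; any skipped calendar day
is absorbed so the series is analysed as consecutive time points.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExperimentDesign:
    """Design constants of a two-condition phenotyping experiment.

    Defaults describe a barley RIL trial: 97 genotypes x 2 conditions x
    2 carriers x 4 plants, imaged on 32 consecutive days with the drought
    window spanning days 5-18.
    """

    n_genotypes: int = 97
    n_carriers_per_condition: int = 2
    n_plants_per_carrier: int = 4
    n_days: int = 32
    drought_start_day: int = 5
    drought_end_day: int = 18
    treatments: tuple[str, str] = ("control", "drought")

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_carriers_per_condition",
                     "n_plants_per_carrier", "n_days"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not (1 <= self.drought_start_day <= self.drought_end_day <= self.n_days):
            raise ValueError(
                "require 1 <= drought_start_day <= drought_end_day <= n_days, "
                f"got {self.drought_start_day}..{self.drought_end_day} of {self.n_days}"
            )
        if len(self.treatments) != 2 or len(set(self.treatments)) != 2:
            raise ValueError("treatments must be an ordered pair of distinct labels")

    @property
    def control(self) -> str:
        return self.treatments[0]

    @property
    def drought(self) -> str:
        return self.treatments[1]

    @property
    def days(self) -> range:
        """1-based, contiguous imaging-day indices."""
        return range(1, self.n_days + 1)

    @property
    def drought_days(self) -> range:
        return range(self.drought_start_day, self.drought_end_day + 1)

    def genotype_labels(self) -> list[str]:
        return [f"G{i:03d}" for i in range(1, self.n_genotypes + 1)]
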