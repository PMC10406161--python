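"""Species metadata: gestation lengths and the organoid age offset.

All downstream analysis works in days post conception, so every species
in a dataset needs a gestation length to place postnatal ages on that
axis.  Defaults for the nine study species ship with the package and can
be overridden from a user YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

#: The nine primate species of the core dataset.
STUDY_SPECIES: tuple[str, ...] = (
    "human",
    "chimpanzee",
    "bonobo",
    "gorilla",
    "orangutan",
    "rhesus_macaque",
    "gibbon",
    "siamang",
    "marmoset",
)


@dataclass
class SpeciesConfig:
    """Gestation lengths (days) plus the organoid incubation-day offset.

    Parameters
    ----------
    gestation_days
        Mapping from species label to gestation length in days.  Every
        species appearing in a dataset must have an entry.
    organoid_offset_days
        Constant added to organoid incubation days to place them on the
        days-post-conception axis (default 0: incubation day d maps to
        d days post conception).
    """

    gestation_days: dict[str, float] = field(default_factory=dict)
    organoid_offset_days: float = 0.0

    def __post_init__(self) -> None:
        for sp, g in self.gestation_days.items():
            if not g > 0:
                raise ValueError(f"gestation must be positive for {sp!r}, got {g}")

    def gestation(self, species: str) -> float:
        try:
            return self.gestation_days[species]
        except KeyError:
            raise KeyError(
                f"no gestation length configured for species {species!r}; "
                f"known species: {sorted(self.gestation_days)}"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            gestation_days={str(k): float(v) for k, v in raw["gestation_days"].items()},
            organoid_offset_days=float(raw.get("organoid_offset_days", 0.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "gestation_days": dict(self.gestation_days),
                    "organoid_offset_days": self.organoid_offset_days,
                },
                fh,
                sort_keys=True,
            )


def default_species_config() -> SpeciesConfig:
    """Shipped defaults for the nine study species."""
    ref = resources.files("agealign").joinpath("data/gestation.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return SpeciesConfig(
        gestation_days={str(k): float(v) for k, v in raw["gestation_days"].items()},
        organoid_offset_days=float(raw.get("organoid_offset_days", 0.0)),
    )
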