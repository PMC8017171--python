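"""Electrode montage: channel labels, scalp regions, and interpolation neighbours.

The default montage is a 32-channel 10-10 subset that keeps everything the
analyses need: the fronto-central MMN cluster (Fz, FCz, Cz), both mastoids
(M1, M2) for the linked-mastoid reference, and enough frontal/temporal/parietal
coverage for the region-pair coherence indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS = ("frontal", "central", "temporal", "parietal", "occipital", "mastoid")

_DEFAULT_REGIONS: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal",
    "F7": "frontal", "F3": "frontal", "Fz": "frontal", "F4": "frontal", "F8": "frontal",
    "FC5": "frontal", "FC1": "frontal", "FCz": "frontal", "FC2": "frontal", "FC6": "frontal",
    "T7": "temporal", "T8": "temporal",
    "C3": "central", "Cz": "central", "C4": "central",
    "CP5": "central", "CP1": "central", "CP2": "central", "CP6": "central",
    "M1": "mastoid", "M2": "mastoid",
    "P7": "parietal", "P3": "parietal", "Pz": "parietal", "P4": "parietal", "P8": "parietal",
    "POz": "parietal",
    "O1": "occipital", "Oz": "occipital", "O2": "occipital",
}

# Left-right / front-back adjacency on the reduced grid; used by the average
# interpolation method.  Symmetry is enforced at module import.
_DEFAULT_NEIGHBORS: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F3", "F7"),
    "Fp2": ("Fp1", "F4", "F8"),
    "F7": ("Fp1", "F3", "FC5", "T7"),
    "F3": ("Fp1", "F7", "Fz", "FC1", "FC5"),
    "Fz": ("F3", "F4", "FCz", "FC1", "FC2"),
    "F4": ("Fp2", "F8", "Fz", "FC2", "FC6"),
    "F8": ("Fp2", "F4", "FC6", "T8"),
    "FC5": ("F7", "F3", "C3", "T7"),
    "FC1": ("F3", "Fz", "FCz", "C3", "Cz"),
    "FCz": ("Fz", "FC1", "FC2", "Cz"),
    "FC2": ("Fz", "F4", "FCz", "C4", "Cz"),
    "FC6": ("F8", "F4", "C4", "T8"),
    "T7": ("F7", "FC5", "C3", "CP5", "M1"),
    "C3": ("FC5", "FC1", "T7", "Cz", "CP1", "CP5"),
    "Cz": ("FCz", "FC1", "FC2", "C3", "C4", "CP1", "CP2"),
    "C4": ("FC2", "FC6", "T8", "Cz", "CP2", "CP6"),
    "T8": ("F8", "FC6", "C4", "CP6", "M2"),
    "CP5": ("T7", "C3", "CP1", "P7", "P3"),
    "CP1": ("C3", "Cz", "CP5", "CP2", "P3", "Pz"),
    "CP2": ("Cz", "C4", "CP1", "CP6", "Pz", "P4"),
    "CP6": ("C4", "T8", "CP2", "P4", "P8"),
    "M1": ("T7", "P7"),
    "M2": ("T8", "P8"),
    "P7": ("CP5", "P3", "O1", "M1"),
    "P3": ("CP5", "CP1", "P7", "Pz", "O1"),
    "Pz": ("CP1", "CP2", "P3", "P4", "POz"),
    "P4": ("CP2", "CP6", "Pz", "P8", "O2"),
    "P8": ("CP6", "P4", "O2", "M2"),
    "POz": ("Pz", "O1", "Oz", "O2"),
    "O1": ("P7", "P3", "POz", "Oz"),
    "Oz": ("O1", "O2", "POz"),
    "O2": ("P8", "P4", "POz", "Oz"),
}


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus a label -> scalp-region map.

    Parameters
    ----------
    labels
        Unique channel labels, 10-20/10-10 style.
    regions
        Region for every label; regions are drawn from :data:`REGIONS`.
    neighbors
        Optional spatial adjacency used by average interpolation.  Channels
        without an entry fall back to the global good-channel mean.
    """

    labels: tuple[str, ...]
    regions: dict[str, str] = field(default_factory=dict)
    neighbors: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        missing = [lab for lab in self.labels if lab not in self.regions]
        if missing:
            raise ValueError(f"labels without a region: {missing}")
        bad_regions = {r for r in self.regions.values() if r not in REGIONS}
        if bad_regions:
            raise ValueError(f"unknown regions: {sorted(bad_regions)}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def channels_in_region(self, region: str) -> tuple[str, ...]:
        return tuple(lab for lab in self.labels if self.regions[lab] == region)

    def subset(self, labels) -> "Montage":
        labels = tuple(labels)
        return Montage(
            labels=labels,
            regions={lab: self.regions[lab] for lab in labels},
            neighbors={
                lab: tuple(n for n in self.neighbors.get(lab, ()) if n in labels)
                for lab in labels
            },
        )


def default_montage() -> Montage:
    """The 32-channel default montage (incl. Fz, FCz, Cz, M1, M2)."""
    labels = tuple(_DEFAULT_REGIONS)
    neighbors = {
        lab: tuple(sorted(set(_DEFAULT_NEIGHBORS.get(lab, ()))
                          | {o for o, ns in _DEFAULT_NEIGHBORS.items() if lab in ns}))
        for lab in labels
    }
    return Montage(labels=labels, regions=dict(_DEFAULT_REGIONS), neighbors=neighbors)
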