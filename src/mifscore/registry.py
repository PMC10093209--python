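"""Ordered schema of the 68 per-cell features.

The feature table is built around six fluorescence channels — the DAPI nuclear
counterstain plus five immune markers (CD3, CD4, CD8, PD-L1, FoxP3).  For each
segmented nucleus the pipeline records intensity statistics, morphology,
and neighbourhood (300 px radius, ~100 µm) context, giving 68 features:

==========================  =====
group                       count
==========================  =====
intensity (mean/mean25/SD)   18
AF-corrected marker means     5
morphology                    7
local cell density            1
neighbourhood positive n     10
environment SDs              27
==========================  =====

The registry is data-driven: a different feature list can be supplied without
touching extraction code, as long as every entry resolves to a known base
quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CHANNELS: tuple[str, ...] = ("DAPI", "CD3", "CD4", "CD8", "PDL1", "FoxP3")
MARKERS: tuple[str, ...] = CHANNELS[1:]

#: features that are already bounded in [0, 1] and skip percentile normalisation
BOUNDED_FEATURES: frozenset[str] = frozenset({"eccentricity", "circularity"})

MORPHOLOGY_FEATURES: tuple[str, ...] = (
    "area",
    "centroid_y",
    "centroid_x",
    "minor_axis",
    "major_axis",
    "eccentricity",
    "circularity",
)

#: base quantities whose local (300 px) standard deviation is an environment feature
ENV_SD_BASES: tuple[str, ...] = tuple(
    [f"{stat}_{ch}" for ch in CHANNELS for stat in ("mean", "mean25", "sd")]
    + [f"af_mean_{m}" for m in MARKERS]
    + ["area", "minor_axis", "major_axis", "density"]
)


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    group: str


@dataclass
class FeatureRegistry:
    """Ordered, named schema of per-cell features."""

    entries: list[FeatureEntry] = field(default_factory=list)

    @classmethod
    def default(cls) -> "FeatureRegistry":
        entries: list[FeatureEntry] = []
        for ch in CHANNELS:
            for stat in ("mean", "mean25", "sd"):
                entries.append(FeatureEntry(f"{stat}_{ch}", "intensity"))
        for m in MARKERS:
            entries.append(FeatureEntry(f"af_mean_{m}", "af_corrected"))
        for name in MORPHOLOGY_FEATURES:
            entries.append(FeatureEntry(name, "morphology"))
        entries.append(FeatureEntry("density", "density"))
        for m in MARKERS:
            entries.append(FeatureEntry(f"pos_count_{m}", "pos_count"))
        for m in MARKERS:
            entries.append(FeatureEntry(f"pos_count_af_{m}", "pos_count_af"))
        for base in ENV_SD_BASES:
            entries.append(FeatureEntry(f"env_sd_{base}", "env_sd"))
        reg = cls(entries)
        reg.validate()
        return reg

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def index(self, name: str) -> int:
        for i, e in enumerate(self.entries):
            if e.name == name:
                return i
        raise KeyError(f"unknown feature {name!r}")

    def validate(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")

    def manifest(self) -> dict:
        """JSON-serialisable description (names, groups, order)."""
        return {
            "n_features": len(self),
            "features": [{"name": e.name, "group": e.group} for e in self.entries],
            "channels": list(CHANNELS),
            "bounded": sorted(BOUNDED_FEATURES & set(self.names)),
        }
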