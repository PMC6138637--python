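"""AAL-90 parcellation bookkeeping.

The 90-region Automated Anatomical Labeling (AAL) atlas covers the cerebral
structures, 45 per hemisphere, each label suffixed ``_L`` or ``_R``. Every
downstream matrix in this package is indexed by the canonical AAL label
order (left/right interleaved), so region identity, hemisphere, lobe
category and homologue pairing are all resolved here.

Lobe categories follow the grouping used throughout the package's reports:
FRONTAL, TEMPORAL, PARIETAL, OCCIPITAL, SUBCORTICAL (thalamus, pallidum,
caudate, putamen, amygdala), HIPPOCAMPUS, and OTHER (central, cingulate,
insular and related midline structures). The assignment ships as a plain
TSV data file and can be overridden by passing a path to
:func:`load_atlas`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Hemisphere",
    "Lobe",
    "Region",
    "RegionAtlas",
    "AtlasError",
    "load_atlas",
]

N_REGIONS = 90


class AtlasError(RuntimeError):
    """Raised when the atlas table is missing, corrupt, or inconsistent."""


class Hemisphere(str, enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Lobe(str, enum.Enum):
    FRONTAL = "FRONTAL"
    TEMPORAL = "TEMPORAL"
    PARIETAL = "PARIETAL"
    OCCIPITAL = "OCCIPITAL"
    SUBCORTICAL = "SUBCORTICAL"
    HIPPOCAMPUS = "HIPPOCAMPUS"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Region:
    """One AAL volume of interest.

    ``index`` is the 1-based position in the canonical AAL-90 ordering.
    ``centroid`` holds approximate MNI display coordinates (mm) used only
    for visualization export; no statistic depends on them.
    """

    index: int
    name: str
    hemisphere: Hemisphere
    lobe: Lobe
    centroid: tuple[float, float, float]


class RegionAtlas:
    """A bilateral parcellation with homologue pairing (AAL-90 in production).

    ``homologue_pairs`` lists ``(left_pos, right_pos)`` 0-based positions
    into ``regions``; paired names differ only in their hemisphere suffix.
    Any even-sized, perfectly left/right-matched region set is accepted so
    small toy parcellations can exercise the same code paths; the packaged
    AAL table is checked for exactly 90 regions at load time.
    """

    def __init__(self, regions: list[Region]):
        if not regions or len(regions) % 2:
            raise AtlasError(f"need an even, nonzero region count, got {len(regions)}")
        self.regions = list(regions)
        self._by_name = {r.name: r for r in self.regions}
        if len(self._by_name) != len(self.regions):
            raise AtlasError("duplicate region names in atlas table")
        n_left = sum(r.hemisphere is Hemisphere.LEFT for r in self.regions)
        if n_left != len(self.regions) // 2:
            raise AtlasError(
                f"expected {len(self.regions) // 2} left regions, got {n_left}"
            )
        for r in self.regions:
            suffix = "_L" if r.hemisphere is Hemisphere.LEFT else "_R"
            if not r.name.endswith(suffix):
                raise AtlasError(
                    f"region {r.name!r} hemisphere {r.hemisphere.value} "
                    f"inconsistent with its suffix"
                )
        self.homologue_pairs = self._pair_homologues()

    def _pair_homologues(self) -> list[tuple[int, int]]:
        pos = {r.name: i for i, r in enumerate(self.regions)}
        pairs = []
        for i, r in enumerate(self.regions):
            if r.hemisphere is not Hemisphere.LEFT:
                continue
            mate = r.name[:-2] + "_R"
            if mate not in pos:
                raise AtlasError(f"no right homologue for {r.name!r}")
            j = pos[mate]
            if self.regions[j].lobe is not r.lobe:
                raise AtlasError(
                    f"homologues {r.name!r}/{mate!r} have different lobes"
                )
            pairs.append((i, j))
        return pairs

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, name: str) -> Region:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown atlas region: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def lobe_of(self, region_name: str) -> Lobe:
        """Lobe category of a region, by exact AAL label."""
        return self[region_name].lobe

    def hemisphere_split(self) -> tuple[list[int], list[int]]:
        """Homologue-aligned 0-based positions of left and right regions.

        Position ``k`` of both lists refers to the same anatomical
        structure, so a 45x45 left-vs-right matrix indexed this way has
        homologue pairs on its diagonal.
        """
        left = [i for i, _ in self.homologue_pairs]
        right = [j for _, j in self.homologue_pairs]
        return left, right


def _default_atlas_path() -> Path:
    return Path(str(resources.files("metaconn").joinpath("data/aal90_atlas.tsv")))


def load_atlas(path: str | Path | None = None) -> RegionAtlas:
    """Load the AAL-90 atlas from the packaged table or an override file.

    The table is tab- or comma-delimited with a header row and columns
    ``index, name, hemisphere, lobe, x, y, z``.
    """
    p = Path(path) if path is not None else _default_atlas_path()
    if not p.is_file():
        raise AtlasError(f"atlas table not found: {p}")
    try:
        df = pd.read_csv(p, sep=None, engine="python")
    except Exception as exc:  # malformed delimiter/encoding
        raise AtlasError(f"cannot parse atlas table {p}: {exc}") from exc
    required = {"index", "name", "hemisphere", "lobe", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasError(f"atlas table {p} missing columns: {sorted(missing)}")
    df = df.sort_values("index")
    regions = []
    for row in df.to_dict("records"):
        try:
            hemi = Hemisphere(row["hemisphere"])
            lobe = Lobe(row["lobe"])
        except ValueError as exc:
            raise AtlasError(f"bad atlas row for {row['name']!r}: {exc}") from exc
        regions.append(
            Region(
                index=int(row["index"]),
                name=str(row["name"]),
                hemisphere=hemi,
                lobe=lobe,
                centroid=(float(row["x"]), float(row["y"]), float(row["z"])),
            )
        )
    if len(regions) != N_REGIONS:
        raise AtlasError(f"atlas table {p} has {len(regions)} regions, expected {N_REGIONS}")
    return RegionAtlas(regions)
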