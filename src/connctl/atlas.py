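"""Region atlas: ordered, named parcellation regions.

The default atlas bundles 120 regions following the AAL2 naming convention
(``_L``/``_R`` suffixes mark hemispheres; vermis regions carry none).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["RegionAtlas", "load_atlas", "default_atlas"]


def _hemisphere(name: str) -> str:
    if name.endswith("_L"):
        return "left"
    if name.endswith("_R"):
        return "right"
    return "none"


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered collection of named regions.

    Region ids are the contiguous 0-based positions of ``names``; names must
    be unique.
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("atlas region names must be unique")
        if not self.names:
            raise ValueError("atlas must contain at least one region")
        if not self.hemispheres:
            object.__setattr__(
                self, "hemispheres", tuple(_hemisphere(n) for n in self.names)
            )
        elif len(self.hemispheres) != len(self.names):
            raise ValueError("hemispheres length must match names")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": range(len(self.names)),
                "region_name": self.names,
                "hemisphere": self.hemispheres,
            }
        )

    @classmethod
    def synthetic(cls, n_regions: int) -> "RegionAtlas":
        """Placeholder atlas with alternating L/R names, for simulations."""
        if n_regions <= 0:
            raise ValueError("n_regions must be positive")
        names = tuple(
            f"Region_{i // 2:03d}_{'L' if i % 2 == 0 else 'R'}"
            for i in range(n_regions)
        )
        return cls(names=names)


def load_atlas(path: str | Path) -> RegionAtlas:
    """Read a two-column (region_id, region_name) delimited atlas table."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"atlas file {path} must have two columns")
    ids = df.iloc[:, 0].to_numpy()
    names = tuple(str(n) for n in df.iloc[:, 1])
    if list(ids) != list(range(len(names))):
        raise ValueError("atlas region_ids must be contiguous 0..n-1")
    return RegionAtlas(names=names)


def default_atlas() -> RegionAtlas:
    """The bundled 120-region atlas."""
    ref = importlib.resources.files("connctl.data") / "atlas120.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_atlas(path)
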