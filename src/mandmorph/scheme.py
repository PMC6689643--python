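"""Landmark schemes: named landmarks with bilateral (object) symmetry pairing.

A scheme declares, for a bilaterally symmetric structure, which landmarks lie
on the sagittal (midline) plane and which form left/right pairs.  Every
landmark must be accounted for exactly once, so that the reflect-and-relabel
operation used in the object-symmetry decomposition is a well-defined
permutation of the landmark set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = ["LandmarkScheme", "mandible_scheme"]


@dataclass(frozen=True)
class LandmarkScheme:
    """Ordered landmark labels plus the symmetry structure over them.

    Parameters
    ----------
    names
        Ordered landmark labels; their order defines coordinate-row order.
    midline
        Indices (into ``names``) of landmarks on the sagittal plane.
    pairs
        ``(left, right)`` index pairs of bilateral landmarks.
    dimension
        Coordinate dimension, 2 or 3.
    """

    names: tuple[str, ...]
    midline: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]
    dimension: int = 3

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        seen: list[int] = list(self.midline)
        for left, right in self.pairs:
            if left == right:
                raise ValueError(f"pair ({left}, {right}) has identical members")
            seen.extend((left, right))
        if sorted(seen) != list(range(len(self.names))):
            raise ValueError(
                "every landmark index must appear exactly once across "
                "midline and pairs"
            )
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "midline", tuple(self.midline))
        object.__setattr__(
            self, "pairs", tuple((int(a), int(b)) for a, b in self.pairs)
        )

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_landmarks(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def relabel_permutation(self) -> np.ndarray:
        """Permutation ``p`` such that row i of a reflected configuration
        should be read from row ``p[i]``: midline landmarks map to
        themselves, paired landmarks swap sides."""
        perm = np.arange(len(self.names))
        for left, right in self.pairs:
            perm[left], perm[right] = right, left
        return perm

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandmarkScheme":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            names=tuple(raw["names"]),
            midline=tuple(raw["midline"]),
            pairs=tuple(tuple(p) for p in raw["pairs"]),
            dimension=int(raw.get("dimension", 3)),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "dimension": self.dimension,
            "names": list(self.names),
            "midline": list(self.midline),
            "pairs": [list(p) for p in self.pairs],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def mandible_scheme() -> LandmarkScheme:
    """The packaged 28-landmark macaque mandible scheme.

    Four landmarks on the sagittal plane (infradentale, mandibular orale,
    superior transverse torus, gnathion) and twelve left/right pairs along
    the tooth row, corpus and ramus.
    """
    ref = resources.files("mandmorph.data").joinpath("mandible_scheme.yaml")
    with resources.as_file(ref) as path:
        return LandmarkScheme.from_yaml(path)
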