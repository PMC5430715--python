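"""Stimulus layouts: image bounds and circular object regions.

A free-viewing stimulus is an image of 34.8 x 26.1 deg^2 of visual angle
containing a handful of object images of roughly 1 deg radius, with any two
object centers separated by at least 4 deg.  Coordinates are in degrees of
visual angle with the origin at the image center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["StimulusObject", "StimulusLayout", "PlacementError", "generate_layout"]

DEFAULT_BOUNDS = (34.8, 26.1)
DEFAULT_MIN_SEPARATION = 4.0
DEFAULT_OBJECT_RADIUS = 1.0


class PlacementError(RuntimeError):
    """Object placement is infeasible within the given bounds."""


@dataclass(frozen=True)
class StimulusObject:
    id: int
    x: float
    y: float
    radius: float = DEFAULT_OBJECT_RADIUS


@dataclass(frozen=True)
class StimulusLayout:
    """Image bounds plus object centers and radii.

    ``width`` and ``height`` are the full extents in degrees; objects are
    indexed by 1-based ids.
    """

    width: float = DEFAULT_BOUNDS[0]
    height: float = DEFAULT_BOUNDS[1]
    objects: tuple[StimulusObject, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for obj in self.objects:
            if abs(obj.x) > self.width / 2 or abs(obj.y) > self.height / 2:
                raise ValueError(
                    f"object {obj.id} center ({obj.x}, {obj.y}) lies outside the "
                    f"{self.width} x {self.height} image bounds"
                )

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def centers(self) -> np.ndarray:
        """Object centers as an (n_objects, 2) array."""
        return np.array([(o.x, o.y) for o in self.objects], dtype=float).reshape(-1, 2)

    def min_pairwise_separation(self) -> float:
        c = self.centers
        if len(c) < 2:
            return float("inf")
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        return float(d[np.triu_indices(len(c), k=1)].min())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "width": self.width,
            "height": self.height,
            "objects": [
                {"id": o.id, "x": o.x, "y": o.y, "radius": o.radius}
                for o in self.objects
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulusLayout":
        payload = json.loads(Path(path).read_text())
        try:
            objects = tuple(
                StimulusObject(int(o["id"]), float(o["x"]), float(o["y"]), float(o["radius"]))
                for o in payload["objects"]
            )
            return cls(float(payload["width"]), float(payload["height"]), objects)
        except KeyError as exc:
            raise ValueError(f"layout file {path} is missing key {exc}") from exc


def generate_layout(
    n_objects: int = 5,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    seed: int | np.random.Generator = 0,
    radius: float = DEFAULT_OBJECT_RADIUS,
    center_object: bool = False,
    max_attempts: int = 10_000,
) -> StimulusLayout:
    """Place ``n_objects`` circular objects at random, rejecting overlaps.

    Objects are placed one by one uniformly over the image, re-drawing any
    candidate closer than ``min_separation`` to an already placed center
    (and keeping every object fully inside the bounds).  With
    ``center_object`` the first object is pinned to the image center,
    matching stimuli whose first object coincides with the pre-stimulus
    fixation spot.

    Raises
    ------
    PlacementError
        If a center satisfying the separation constraint cannot be found
        within ``max_attempts`` draws (too many objects for the bounds).
    """
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width, height = bounds
    half_w, half_h = width / 2 - radius, height / 2 - radius
    if half_w <= 0 or half_h <= 0:
        raise PlacementError("bounds too small to contain a single object")

    centers: list[tuple[float, float]] = []
    if center_object:
        centers.append((0.0, 0.0))
    while len(centers) < n_objects:
        for _ in range(max_attempts):
            x = rng.uniform(-half_w, half_w)
            y = rng.uniform(-half_h, half_h)
            if all(np.hypot(x - cx, y - cy) >= min_separation for cx, cy in centers):
                centers.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place object {len(centers) + 1} of {n_objects} with "
                f"min separation {min_separation} deg in {width} x {height} deg "
                f"after {max_attempts} attempts"
            )
    objects = tuple(
        StimulusObject(i + 1, x, y, radius) for i, (x, y) in enumerate(centers)
    )
    return StimulusLayout(width, height, objects)
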