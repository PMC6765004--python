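"""Seeded point-scatterer phantoms: single wire, resolution target, cyst.

All generators are pure functions of their arguments (plus a seed for the
stochastic speckle phantom).  Wires much smaller than the wavelength are
modeled as unit-reflectivity point targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScattererPhantom",
    "single_wire",
    "resolution_phantom",
    "cyst_phantom",
    "load_phantom",
]

# successive wire gaps (mm) of the resolution target, used both axially
# and laterally from a shared corner wire
RESOLUTION_GAPS = (4.0, 3.0, 2.0, 1.0, 0.5)


@dataclass(frozen=True, eq=False)
class ScattererPhantom:
    """Point scatterers at (x, z) positions (mm) with linear reflectivities."""

    positions: np.ndarray     # (n, 2)
    reflectivities: np.ndarray
    seed: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        refl = np.asarray(self.reflectivities, dtype=float)
        if pos.shape[0] != refl.size or (pos.size and pos.shape[1] != 2):
            raise ValueError("positions must be (n, 2) matching reflectivities")
        if pos.size and np.any(pos[:, 1] <= 0):
            raise ValueError("all scatterers must lie at z > 0")
        if not np.all(np.isfinite(refl)):
            raise ValueError("reflectivities must be finite")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "reflectivities", refl)

    @property
    def n_scatterers(self) -> int:
        return self.reflectivities.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "x_mm": self.positions[:, 0],
                "z_mm": self.positions[:, 1],
                "reflectivity": self.reflectivities,
            }
        ).to_csv(path, index=False)


def load_phantom(path: str | Path, label: str = "") -> ScattererPhantom:
    df = pd.read_csv(path)
    return ScattererPhantom(
        positions=df[["x_mm", "z_mm"]].to_numpy(),
        reflectivities=df["reflectivity"].to_numpy(),
        label=label or str(path),
    )


def single_wire(depth: float = 60.0) -> ScattererPhantom:
    """One sub-wavelength wire on axis at `depth` (mm), reflectivity 1."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    return ScattererPhantom(
        positions=np.array([[0.0, depth]]),
        reflectivities=np.array([1.0]),
        label=f"wire@{depth:g}mm",
    )


def resolution_phantom(center_depth: float = 60.0) -> ScattererPhantom:
    """Eleven wires in an L: axial and lateral chains sharing a corner wire.

    Both chains start at (0, center_depth) with successive gaps of
    4, 3, 2, 1 and 0.5 mm; the lateral chain extends toward +x and the
    axial chain toward larger depth, 6 + 6 - 1 = 11 unique wires.
    """
    if center_depth <= 0:
        raise ValueError("center_depth must be positive")
    offsets = np.concatenate([[0.0], np.cumsum(RESOLUTION_GAPS)])
    lateral = np.column_stack([offsets, np.full(offsets.size, center_depth)])
    axial = np.column_stack([np.zeros(offsets.size - 1),
                             center_depth + offsets[1:]])
    pos = np.vstack([lateral, axial])
    return ScattererPhantom(
        positions=pos,
        reflectivities=np.ones(pos.shape[0]),
        label=f"resolution-target@{center_depth:g}mm",
    )


def cyst_phantom(
    cyst_depth: float = 70.0,
    cyst_radius: float = 4.0,
    region: tuple[float, float, float, float] | None = None,
    density: float = 15.0,
    seed: int = 0,
) -> ScattererPhantom:
    """Anechoic disc in fully developed speckle.

    Scatterer positions are uniform over `region` = (x0, x1, z0, z1) with
    `density` scatterers per mm^2 and zero-mean Gaussian reflectivities;
    every scatterer inside the cyst disc centered at (0, cyst_depth) is
    removed.  Deterministic given `seed`.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if cyst_depth <= 0 or cyst_radius <= 0:
        raise ValueError("cyst geometry must be positive")
    if region is None:
        region = (-11.0, 11.0, cyst_depth - 7.0, cyst_depth + 7.0)
    x0, x1, z0, z1 = region
    if not (x1 > x0 and z1 > z0 > 0):
        raise ValueError("region must be (x0, x1, z0, z1) with z1 > z0 > 0")
    area = (x1 - x0) * (z1 - z0)
    n = int(round(density * area))
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(z0, z1, n)])
    refl = rng.standard_normal(n)
    inside = (pos[:, 0] ** 2 + (pos[:, 1] - cyst_depth) ** 2) < cyst_radius**2
    return ScattererPhantom(
        positions=pos[~inside],
        reflectivities=refl[~inside],
        seed=seed,
        label=f"cyst@{cyst_depth:g}mm(r={cyst_radius:g}mm)",
    )
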