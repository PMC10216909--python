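"""Isolated Type II SLAP lesion construction.

A Type II SLAP lesion is a detachment of the superior labrum/biceps anchor
from the glenoid rim.  Its three subtypes are modelled purely through the
boundary conditions: the glenoid-rim attachment nodes inside a clock sector
are released (no longer pinned to the scapula), everything else — loads,
rotation schedule, contacts — stays identical to the healthy scenario.

Subtype sectors on the glenoid clock face (12 superior, 3 anterior):
anterior 12-1, posterior 11-12, combined (anterior-to-posterior) 11-1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import CapsuleMesh, ClockSector, sector_nodes
from .solver import LoadCase

__all__ = ["LesionSpec", "SUBTYPE_SECTORS", "apply_lesion"]

SUBTYPE_SECTORS: dict[str, tuple[float, float] | None] = {
    "anterior": (12.0, 1.0),
    "posterior": (11.0, 12.0),
    "combined": (11.0, 1.0),
    "none": None,
}


@dataclass(frozen=True)
class LesionSpec:
    """A lesion subtype, optionally with an overriding clock sector."""

    subtype: str = "none"
    sector: ClockSector | None = None

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPE_SECTORS:
            raise ValueError(
                f"unknown subtype {self.subtype!r}; expected one of "
                f"{sorted(SUBTYPE_SECTORS)}"
            )
        if self.sector is None and SUBTYPE_SECTORS[self.subtype] is not None:
            start, end = SUBTYPE_SECTORS[self.subtype]
            object.__setattr__(self, "sector", ClockSector(start, end))


def apply_lesion(
    load_case: LoadCase,
    mesh: CapsuleMesh,
    lesion: LesionSpec,
    handedness: str = "right",
) -> LoadCase:
    """Return a copy of ``load_case`` with the lesion sector detached.

    The released set is the glenoid-ring nodes (the labrum attachment line)
    whose clock position lies in the lesion sector; a sector that selects no
    nodes means the mesh is too coarse and is an error.  ``subtype='none'``
    returns an identical load case.
    """
    if lesion.sector is None:
        return replace(load_case, released_nodes=np.empty(0, dtype=np.int64))
    if "glenoid_ring" not in mesh.node_sets:
        raise ValueError("mesh has no glenoid_ring node set")
    released = sector_nodes(mesh, lesion.sector, ring="glenoid_ring", handedness=handedness)
    return replace(load_case, released_nodes=np.sort(released))
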