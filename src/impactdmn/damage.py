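"""Mechanical damage rules applied to per-element peak fields.

Three rules turn the raw peak fields of an impact simulation into a damage
summary: (1) a skull-fracture exclusion — the case is discarded when more
than a set fraction of skull elements exceeds the ultimate strength of
bone; (2) a geometric mapping from a binary DMN voxel mask to the set of
gray-matter elements belonging to the network; (3) a shear-energy-rate
threshold that marks an element damaged, yielding the percentage of
damaged elements within the DMN set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SKULL_ULTIMATE_STRENGTH_MPA",
    "SKULL_FRACTURE_FRACTION",
    "DAMAGE_THRESHOLD_PRESETS",
    "PeakFieldSet",
    "DamageResult",
    "skull_fractured",
    "map_dmn_elements",
    "dmn_damage_percent",
]

#: Ultimate strength of cranial bone (MPa).
SKULL_ULTIMATE_STRENGTH_MPA = 92.72
#: Fraction of skull elements that must exceed the strength for fracture
#: (the fraction spanning the maximum skull thickness).
SKULL_FRACTURE_FRACTION = 0.04
#: Named shear-energy-rate thresholds (MJ/m^3/s): "impact" is the value
#: calibrated against the functional criterion for blunt impact; "blast" is
#: the much larger value reported for blast loading and kept for reference.
DAMAGE_THRESHOLD_PRESETS = {"impact": 1.0, "blast": 100.0}


@dataclass(frozen=True)
class PeakFieldSet:
    """Per-element peak fields of one simulated impact.

    ``gray_ids``/``gray_peak`` hold the maximum shear energy rate
    (MJ/m^3/s) of every gray-matter element; ``skull_ids``/``skull_peak``
    the maximum von Mises stress (MPa) of every skull element.  Ids index
    into the owning mesh's element arrays.
    """

    gray_ids: np.ndarray
    gray_peak: np.ndarray
    skull_ids: np.ndarray
    skull_peak: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gray_ids) != len(self.gray_peak):
            raise ValueError("gray ids/peaks length mismatch")
        if len(self.skull_ids) != len(self.skull_peak):
            raise ValueError("skull ids/peaks length mismatch")
        if np.any(self.gray_peak < 0) or np.any(self.skull_peak < 0):
            raise ValueError("peak fields must be non-negative")


@dataclass(frozen=True)
class DamageResult:
    fractured: bool
    dmn_element_ids: frozenset = field(default_factory=frozenset)
    damaged_element_ids: frozenset = field(default_factory=frozenset)
    damage_percent: float = 0.0


def skull_fractured(peak_vm, strength: float = SKULL_ULTIMATE_STRENGTH_MPA,
                    fraction: float = SKULL_FRACTURE_FRACTION) -> bool:
    """Whether the skull is considered fractured.

    True iff strictly more than *fraction* of skull elements has a peak von
    Mises stress strictly above *strength* (MPa).  Both comparisons are
    strict: exactly 4 of 100 elements above strength is not a fracture
    under the default 4% rule.
    """
    peak_vm = np.asarray(peak_vm, dtype=float)
    if peak_vm.size == 0:
        raise ValueError("skull element set is empty")
    exceed = np.count_nonzero(peak_vm > strength)
    return exceed / peak_vm.size > fraction


def map_dmn_elements(mesh, dmn_mask, affine) -> frozenset:
    """Map a binary DMN voxel mask to a set of gray-matter element ids.

    Step 1 selects every mesh node whose world coordinates fall inside a
    true voxel; step 2 returns every gray-matter element sharing at least
    one selected node.  Voxel containment uses the voxel-center convention:
    a point x belongs to voxel ``floor(affine^-1 x + 0.5)`` (0-based), the
    usual NIfTI semantics where the affine maps voxel centers to world
    coordinates.  The mesh must be expressed in the mask's world frame.
    """
    mask = np.asarray(dmn_mask).astype(bool)
    affine = np.asarray(affine, dtype=float)
    if mask.ndim != 3:
        raise ValueError("dmn_mask must be a 3-D voxel grid")
    gray = np.flatnonzero(mesh.region_label == "gray")
    if gray.size == 0:
        raise ValueError("mesh has no gray-matter elements")

    inv = np.linalg.inv(affine)
    xyz1 = np.c_[mesh.nodes, np.ones(len(mesh.nodes))]
    vox = np.floor((xyz1 @ inv.T)[:, :3] + 0.5).astype(int)
    inside = np.all((vox >= 0) & (vox < mask.shape), axis=1)
    sel = np.zeros(len(mesh.nodes), dtype=bool)
    idx = vox[inside]
    sel[inside] = mask[idx[:, 0], idx[:, 1], idx[:, 2]]

    node_hit = sel[mesh.tets[gray]].any(axis=1)
    return frozenset(int(e) for e in gray[node_hit])


def dmn_damage_percent(peaks: PeakFieldSet, dmn_ids,
                       threshold: float = DAMAGE_THRESHOLD_PRESETS["impact"],
                       fractured: bool | None = None) -> DamageResult:
    """Percentage of DMN elements whose peak shear energy rate exceeds
    *threshold* (MJ/m^3/s, strict inequality).

    When *fractured* is not supplied it is derived from the skull peaks.
    Raises ``ValueError`` for an empty DMN set (percentage undefined).
    """
    dmn_ids = frozenset(int(i) for i in dmn_ids)
    if not dmn_ids:
        raise ValueError("DMN element set is empty: damage percentage undefined")
    if fractured is None:
        fractured = skull_fractured(peaks.skull_peak)
    lut = dict(zip((int(i) for i in peaks.gray_ids), peaks.gray_peak))
    missing = dmn_ids - lut.keys()
    if missing:
        raise ValueError(f"{len(missing)} DMN element(s) lack a peak value")
    damaged = frozenset(j for j in dmn_ids if lut[j] > threshold)
    percent = 100.0 * len(damaged) / len(dmn_ids)
    return DamageResult(fractured=bool(fractured), dmn_element_ids=dmn_ids,
                        damaged_element_ids=damaged, damage_percent=percent)
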