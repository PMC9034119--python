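"""Assign template components to named networks by atlas overlap.

A component map is binarized at Z > 1 and its voxels are attributed to the
networks of an integer-labelled atlas partition; the component is assigned to
the network holding the largest *normalized* overlap (component-mask size is
the denominator).  Best overlap below 50% flags the assignment as low
confidence -- in practice such components are resolved by manual/literature
lookup, which is outside this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import AnalysisGrid, GridMismatchError
from .template_ica import TemplateComponent

logger = logging.getLogger("rsnmap")


@dataclass(frozen=True)
class AtlasPartition:
    """Non-overlapping integer label volume with network names.

    ``labels`` maps label value (> 0) to network name; 0 is background.
    """

    volume: np.ndarray
    labels: dict[int, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        vol = np.asarray(self.volume)
        present = set(np.unique(vol)) - {0}
        unknown = present - set(self.labels)
        if unknown:
            raise ValueError(f"atlas labels without names: {sorted(unknown)}")


@dataclass(frozen=True)
class NetworkAssignment:
    component_id: int
    network: str
    overlap: float  # normalized overlap in [0, 1]
    low_confidence: bool


def binarize_component(
    template: TemplateComponent, grid: AnalysisGrid, z_thresh: float = 1.0
) -> np.ndarray:
    """Binary volume of voxels with Z strictly above ``z_thresh``."""
    mask = grid.devectorize(template.map) > z_thresh
    mask &= grid.mask
    if not mask.any():
        logger.warning("component %d: empty mask at Z > %g", template.id, z_thresh)
    return mask


def normalized_overlap(
    component_mask: np.ndarray, atlas: AtlasPartition
) -> dict[str, float]:
    """Fraction of component-mask voxels inside each atlas network.

    Fractions over all networks plus the implicit outside-atlas remainder
    sum to 1.  An empty component mask is an error.
    """
    if component_mask.shape != atlas.volume.shape:
        raise GridMismatchError(
            f"component mask {component_mask.shape} vs atlas {atlas.volume.shape}"
        )
    n = int(component_mask.sum())
    if n == 0:
        raise ValueError("normalized overlap undefined for an empty component mask")
    inside = atlas.volume[component_mask]
    return {
        name: float((inside == lab).sum() / n) for lab, name in atlas.labels.items()
    }


def assign_network(
    overlaps: dict[str, float], component_id: int = -1, threshold: float = 0.5
) -> NetworkAssignment:
    """Argmax network, low-confidence when the best overlap is < threshold.

    Ties at the argmax are broken lexicographically by network name (logged).
    """
    if not overlaps:
        raise ValueError("empty overlap table")
    best = max(overlaps.values())
    tied = sorted(name for name, v in overlaps.items() if v == best)
    if len(tied) > 1:
        logger.info(
            "component %d: overlap tie between %s, keeping %s",
            component_id, tied, tied[0],
        )
    return NetworkAssignment(
        component_id=component_id,
        network=tied[0],
        overlap=best,
        low_confidence=best < threshold,
    )


def assign_all(
    templates: list[TemplateComponent],
    atlases: list[AtlasPartition],
    grid: AnalysisGrid,
    z_thresh: float = 1.0,
    threshold: float = 0.5,
) -> list[NetworkAssignment]:
    """Assign every template using the maximum overlap across atlases."""
    out = []
    for tpl in templates:
        cmask = binarize_component(tpl, grid, z_thresh)
        merged: dict[str, float] = {}
        for atlas in atlases:
            for name, frac in normalized_overlap(cmask, atlas).items():
                merged[name] = max(merged.get(name, 0.0), frac)
        out.append(assign_network(merged, component_id=tpl.id, threshold=threshold))
    return out
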