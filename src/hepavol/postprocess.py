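"""Mask cleanup between and after the two segmentation stages.

The initial liver prediction is reduced to its largest 3D connected
component; trauma predictions falling outside the predicted liver are
discarded, since blunt-trauma lesions are intraparenchymal by definition.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import BinaryMask, require_same_geometry

__all__ = ["largest_connected_component", "restrict_to_liver"]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_connected_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest 3D connected component.

    ``connectivity`` is 6 (face neighbours) or 26 (face+edge+corner,
    default).  An empty mask maps to an empty mask.  A tie between
    equal-size components is broken in favour of the component containing
    the lowest voxel index in scan order, which is deterministic.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    if mask.is_empty():
        return mask.with_values(np.zeros(mask.shape, dtype=bool))
    labels, n = ndimage.label(mask.values, structure=_STRUCTS[connectivity])
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    # scipy assigns labels in scan order, so among equal-size components the
    # smallest label is the one whose first voxel comes first.
    best = int(np.argmax(sizes))
    return mask.with_values(labels == best)


def restrict_to_liver(trauma_mask: BinaryMask, liver_mask: BinaryMask) -> BinaryMask:
    """Voxel-wise intersection: drop trauma voxels outside the liver."""
    require_same_geometry(trauma_mask, liver_mask, "trauma and liver masks")
    return trauma_mask.with_values(trauma_mask.values & liver_mask.values)
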