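"""Land-use / land-cover class dictionary (7 classes, fixed codes)."""

from __future__ import annotations

from enum import IntEnum

__all__ = ["LULCClass", "CLASS_NAMES", "CLASS_CODES"]


class LULCClass(IntEnum):
    CROPLAND = 1
    FOREST = 2
    SHRUBLAND = 3
    GRASSLAND = 4
    WATER = 5
    BARREN = 6
    IMPERVIOUS = 7


CLASS_NAMES: dict[int, str] = {c.value: c.name.lower() for c in LULCClass}
CLASS_CODES: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}
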