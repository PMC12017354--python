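"""Static channel -> cortical region map for the 48-channel montage.

A configuration table, not a registration: channel 27 sits over the left
anterior medial prefrontal cortex in this probe layout; neighbouring
prefrontal channels are named coarsely and temporal channels generically.
"""

from __future__ import annotations

DEFAULT_MONTAGE: dict[int, str] = {
    25: "R-amPFC",
    26: "mPFC",
    27: "L-amPFC",
    28: "L-dlPFC",
    29: "R-dlPFC",
}


def channel_region(channel: int, montage: dict[int, str] | None = None) -> str:
    table = DEFAULT_MONTAGE if montage is None else montage
    return table.get(channel, f"CH{channel}")
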