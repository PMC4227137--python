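"""Small shared helpers."""

from __future__ import annotations

import numpy as np

from .io import PARITY_LEVELS


def parous_mask(labels) -> np.ndarray:
    """Coerce parity labels to a boolean mask (True = parous).

    Accepts the strings 'parous'/'nulliparous', booleans, or 0/1 with 1
    meaning parous.
    """
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        bad = sorted(set(arr.tolist()) - set(PARITY_LEVELS))
        if bad:
            raise ValueError(f"invalid parity labels {bad}; expected {PARITY_LEVELS}")
        return arr == "parous"
    if arr.dtype.kind == "b":
        return arr.copy()
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"numeric parity labels must be 0/1, got {sorted(uniq)}")
    return arr.astype(bool)
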