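"""Brute-force reference for gamma-patch detection.

Independent of the package implementation: binarizes the snippet at every
distinct amplitude value in decreasing order, labels 4-connected components
with scipy.ndimage, freezes pre-merge extents on fusion, and stops once the
requested number of components is identified.
"""

import numpy as np
from scipy import ndimage

STRUCT = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def oracle_patches(amp: np.ndarray, max_count: int = 4) -> list[frozenset]:
    amp = np.asarray(amp, dtype=float)
    values = np.unique(amp[amp > 0])[::-1]
    active: list[tuple[set, float, bool]] = []  # (cells, birth, fusion)
    frozen: list[tuple[set, float]] = []
    for v in values:
        labels, n_lab = ndimage.label(amp >= v, structure=STRUCT)
        new_active = []
        for lab in range(1, n_lab + 1):
            cells = {c for c in zip(*np.nonzero(labels == lab)) if amp[c] > 0}
            if not cells:
                continue
            parents = [a for a in active if a[0] & cells]
            if len(parents) == 0:
                new_active.append((cells, float(v), False))
            elif len(parents) == 1:
                new_active.append((cells, parents[0][1], parents[0][2]))
            else:
                for p in parents:
                    if not p[2]:
                        frozen.append((p[0], p[1]))
                new_active.append((cells, float(v), True))
        active = new_active
        identified = len(frozen) + sum(1 for a in active if not a[2])
        if identified >= max_count:
            break
    records = frozen + [(a[0], a[1]) for a in active if not a[2]]
    return [frozenset(cells) for cells, _ in records]
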