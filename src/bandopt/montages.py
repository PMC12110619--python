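"""Builtin electrode montages.

The 64-channel layout follows the midline/lateral-ring naming used with
BioSemi headcaps: midline electrodes ``1Z``–``8Z`` front to back, and four
concentric rings per hemisphere (``L``, ``LA``, ``LB``, ``LC`` on the left,
``R``, ``RA``, ``RB``, ``RC`` on the right), each ring holding seven
electrodes numbered front to back.  Coordinates are a top-view projection
with the nose toward +y and unit head radius; the vendor does not publish a
canonical 2D projection, so the geometry here is a regular construction that
preserves which electrodes are spatial neighbors.
"""

from __future__ import annotations

import numpy as np

from .recording import Montage

_RING_SUFFIXES = ("", "A", "B", "C")  # innermost to outermost lateral ring


def _region(x: float, y: float) -> str:
    if y > 0.35:
        return "frontal"
    if y < -0.55:
        return "occipital"
    if x < -0.55:
        return "left-temporal"
    if x > 0.55:
        return "right-temporal"
    return "parietal"


def _biosemi64() -> Montage:
    labels: list[str] = []
    pos: list[tuple[float, float]] = []

    # midline: 8 electrodes from front (nose, +y) to back
    for i, y in enumerate(np.linspace(0.92, -0.92, 8), start=1):
        labels.append(f"{i}Z")
        pos.append((0.0, float(y)))

    # four rings per side at increasing lateral radius, 7 electrodes each,
    # placed on arcs from the front of the head to the back
    for side, sign in (("L", -1.0), ("R", +1.0)):
        for ring_idx, suffix in enumerate(_RING_SUFFIXES, start=1):
            rho = 0.92 * ring_idx / len(_RING_SUFFIXES)
            for j, theta in enumerate(np.linspace(0.18 * np.pi, 0.88 * np.pi, 7),
                                      start=1):
                labels.append(f"{j}{side}{suffix}")
                pos.append((sign * rho * np.sin(theta), rho * np.cos(theta)))

    positions = np.array(pos)
    regions = [_region(x, y) for x, y in positions]
    return Montage(labels=labels, positions=positions, regions=regions)


_BUILTIN = {"biosemi64": _biosemi64}


def builtin_montage(name: str) -> Montage:
    """Return a builtin montage by name (currently only ``biosemi64``)."""
    try:
        factory = _BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown montage {name!r}; available: {sorted(_BUILTIN)}"
        ) from None
    return factory()
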