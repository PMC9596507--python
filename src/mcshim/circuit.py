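"""Circuit-parameter estimators for multi-turn loop elements.

The self-inductance of an N-turn winding is computed as the sum of the N
thin-wire per-turn self-inductances plus all pairwise mutual inductances
between turns, with each turn treated as a coaxial circular filament at its
position in the winding cross-section.

The winding cross-section is modeled as a hexagonal lattice of wire positions
whose pitch is set by a winding *fill factor* (copper area / bundle area).
Ideal orthocyclic close packing corresponds to fill 0.9069; hand-wound
("random" or "wild") windings of enameled wire achieve far less — winding
practice puts them at roughly 0.5-0.65 — so the default fill is 0.60.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ellipe, ellipk

from .constants import COPPER_RESISTIVITY, MU0
from .errors import GeometryError

#: Copper fill of an ideal hexagonally close-packed bundle, pi/(2*sqrt(3)).
CLOSE_PACK_FILL = np.pi / (2.0 * np.sqrt(3.0))

#: Default copper fill factor for a hand-wound (random-wound) bundle.
DEFAULT_FILL = 0.60


@dataclass(frozen=True)
class WireSpec:
    """Round wire described by its conductor cross-section."""

    cross_section_mm2: float = 0.5
    resistivity_ohm_m: float = COPPER_RESISTIVITY

    def __post_init__(self) -> None:
        if self.cross_section_mm2 <= 0:
            raise GeometryError("wire cross-section must be positive")
        if self.resistivity_ohm_m <= 0:
            raise GeometryError("wire resistivity must be positive")

    @property
    def radius_m(self) -> float:
        return float(np.sqrt(self.cross_section_mm2 * 1e-6 / np.pi))


def mutual_inductance(r_a_m: float, r_b_m: float, axial_sep_m: float) -> float:
    """Mutual inductance (H) of two coaxial circular filaments.

    Maxwell's elliptic-integral formula with modulus
    ``k^2 = 4 Ra Rb / ((Ra+Rb)^2 + d^2)``.
    """
    if r_a_m <= 0 or r_b_m <= 0:
        raise GeometryError("filament radii must be positive")
    k2 = 4.0 * r_a_m * r_b_m / ((r_a_m + r_b_m) ** 2 + axial_sep_m**2)
    k = np.sqrt(k2)
    return float(
        MU0 * np.sqrt(r_a_m * r_b_m) * ((2.0 / k - k) * ellipk(k2) - (2.0 / k) * ellipe(k2))
    )


def thin_wire_self_inductance(radius_m: float, wire_radius_m: float) -> float:
    """Self-inductance (H) of one circular turn of round wire.

    ``L = mu0 a (ln(8a/r_w) - 7/4)`` — thin-wire formula with uniform
    current distribution (internal inductance term mu0*a/4 included).
    """
    if radius_m <= 0 or wire_radius_m <= 0 or wire_radius_m >= radius_m:
        raise GeometryError("need 0 < wire radius < loop radius")
    return float(MU0 * radius_m * (np.log(8.0 * radius_m / wire_radius_m) - 1.75))


def bundle_positions(n_turns: int, pitch_m: float) -> np.ndarray:
    """(n, 2) turn positions in the winding cross-section plane.

    Sites of a hexagonal lattice of the given pitch, taken nearest-first from
    the bundle center, deterministically tie-broken.  Columns are (radial
    offset, axial offset) in meters.
    """
    span = int(np.ceil(np.sqrt(n_turns))) + 2
    pts = []
    for i in range(-span, span + 1):
        for j in range(-span, span + 1):
            x = (i + 0.5 * j) * pitch_m
            y = j * pitch_m * np.sqrt(3.0) / 2.0
            pts.append((x, y))
    pts.sort(key=lambda p: (p[0] ** 2 + p[1] ** 2, p[1], p[0]))
    if len(pts) < n_turns:
        raise GeometryError("internal lattice too small for requested turn count")
    return np.array(pts[:n_turns])


def estimate_self_inductance(
    radius_mm: float,
    turns: int,
    wire: WireSpec = WireSpec(),
    fill_factor: float = DEFAULT_FILL,
) -> float:
    """Self-inductance of an N-turn circular winding, in microhenry.

    Sums per-turn thin-wire self-inductances and all pairwise coaxial mutual
    inductances over the bundle cross-section.  ``fill_factor`` sets the
    lattice pitch via ``pitch = r_w * sqrt(2 pi / (sqrt(3) * fill))``; pass
    :data:`CLOSE_PACK_FILL` for an ideal orthocyclic winding.
    """
    if turns < 1:
        raise GeometryError("turns must be >= 1")
    if radius_mm <= 0:
        raise GeometryError("loop radius must be positive")
    if not (0 < fill_factor <= CLOSE_PACK_FILL + 1e-12):
        raise GeometryError(
            f"fill factor must be in (0, {CLOSE_PACK_FILL:.4f}], got {fill_factor}"
        )
    a = radius_mm * 1e-3
    rw = wire.radius_m
    pitch = rw * np.sqrt(2.0 * np.pi / (np.sqrt(3.0) * fill_factor))
    pos = bundle_positions(turns, pitch)
    radii = a + pos[:, 0]
    if np.any(radii <= rw):
        raise GeometryError("bundle does not fit: turn radius collapses below wire radius")
    z = pos[:, 1]
    total = sum(thin_wire_self_inductance(r, rw) for r in radii)
    for i in range(turns):
        for j in range(i + 1, turns):
            total += 2.0 * mutual_inductance(radii[i], radii[j], abs(z[i] - z[j]))
    return total * 1e6


def estimate_resistance(radius_mm: float, turns: int, wire: WireSpec = WireSpec()) -> float:
    """DC resistance ``rho * L / A`` of an N-turn winding, in ohm."""
    if turns < 1:
        raise GeometryError("turns must be >= 1")
    if radius_mm <= 0:
        raise GeometryError("loop radius must be positive")
    length_m = turns * 2.0 * np.pi * radius_mm * 1e-3
    return float(wire.resistivity_ohm_m * length_m / (wire.cross_section_mm2 * 1e-6))
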