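"""Solvent-accessible surface areas, contact areas, and tilt angles.

The contact area between two residue regions A and B is

    CA(A↔B) = ½·(SASA_A + SASA_B − SASA_{A+B}),

half the surface buried when the two regions are together: SASA_A and
SASA_B are evaluated with each region alone in solvent, SASA_{A+B} with
both present.  CA is symmetric, non-negative up to quadrature error, and
drops to zero once the regions separate beyond one probe diameter.

SASA uses the Shrake–Rupley rolling-probe construction with a
deterministic golden-angle spiral point set, so results are exactly
reproducible for a fixed point count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import StructureModel

__all__ = [
    "ELEMENT_RADII",
    "DEFAULT_PROBE",
    "DEFAULT_N_POINTS",
    "RegionSelection",
    "ContactAreaSeries",
    "TiltSeries",
    "ANCHOR_PRESETS",
    "sphere_points",
    "sasa",
    "contact_area",
    "contact_area_series",
    "tilt_angles",
    "max_tilt",
]

#: Bondi-style van der Waals radii in nm; hydrogens included when present.
ELEMENT_RADII: dict[str, float] = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "H": 0.120,
}

DEFAULT_PROBE = 0.14  # nm, water-sized probe
DEFAULT_N_POINTS = 960


@dataclass
class RegionSelection:
    """A labelled set of residue ranges, optionally trimmed at the termini.

    ``trim`` drops that many residues from each end of every range before
    atoms are resolved — used for inter-domain interfaces so the contact
    area of directly consecutive sequences can reach zero.
    """

    label: str
    ranges: list[tuple[str, int, int]]
    trim: int = 0

    def trimmed_ranges(self) -> list[tuple[str, int, int]]:
        out = []
        for chain, first, last in self.ranges:
            lo, hi = first + self.trim, last - self.trim
            if lo > hi:
                raise ValueError(
                    f"selection {self.label!r}: range {chain}:{first}-{last} "
                    f"empty after trim={self.trim}"
                )
            out.append((chain, lo, hi))
        return out

    def resolve(self, model: StructureModel) -> np.ndarray:
        """Atom indices of this selection in ``model`` (after trimming)."""
        mask = np.zeros(model.n_atoms, dtype=bool)
        for chain, lo, hi in self.trimmed_ranges():
            mask |= model.residue_mask(chain, lo, hi)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"selection {self.label!r} matches no atoms")
        return idx

    @classmethod
    def from_string(cls, spec: str, label: str = "", trim: int = 0) -> "RegionSelection":
        """Parse ``"A:10-50,B:3-40"`` into a selection."""
        ranges = []
        for part in spec.split(","):
            chain, _, span = part.strip().partition(":")
            first, _, last = span.partition("-")
            ranges.append((chain.strip(), int(first), int(last)))
        return cls(label=label or spec, ranges=ranges, trim=trim)


@dataclass
class ContactAreaSeries:
    """Per-frame contact area between two regions along the pull."""

    pair_label: str
    frame_ids: np.ndarray
    elongation: np.ndarray  # nm, inter-spring distance
    ca: np.ndarray  # nm²

    def __post_init__(self) -> None:
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        self.elongation = np.asarray(self.elongation, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if not (len(self.frame_ids) == len(self.elongation) == len(self.ca)):
            raise ValueError("frame_ids/elongation/ca must have equal length")
        if self.ca.size and self.ca.min() < -1e-6:
            raise ValueError(f"contact area below tolerance: {self.ca.min()} nm²")

    def __len__(self) -> int:
        return len(self.ca)


@dataclass
class TiltSeries:
    """Per-frame tilt angles α1, α2 (degrees) of a partially unfolded repeat.

    α1 and α2 are the angles between the pulling axis and the vectors from a
    shared mid anchor Cα to an N-side and a C-side anchor Cα respectively.
    """

    traj_id: str
    alpha1: np.ndarray
    alpha2: np.ndarray
    anchors: tuple = ()

    def __post_init__(self) -> None:
        self.alpha1 = np.asarray(self.alpha1, dtype=float)
        self.alpha2 = np.asarray(self.alpha2, dtype=float)
        for arr in (self.alpha1, self.alpha2):
            if arr.size and (arr.min() < 0 or arr.max() > 180):
                raise ValueError("tilt angles must lie in [0, 180] degrees")


#: Cα anchor presets (mid, N-side, C-side) for the two studied plakins.
ANCHOR_PRESETS: dict[str, dict[str, tuple[str, int]]] = {
    "desmoplakin": {"mid": ("A", 375), "n": ("A", 342), "c": ("A", 403)},
    "plectin": {"mid": ("A", 858), "n": ("A", 825), "c": ("A", 886)},
}


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-angle spiral)."""
    if n < 1:
        raise ValueError("need at least one point")
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _radii_for(model: StructureModel, indices: np.ndarray,
               overrides: Mapping[str, float] | None = None) -> np.ndarray:
    table = dict(ELEMENT_RADII)
    if overrides:
        table.update(overrides)
    radii = np.empty(len(indices))
    missing = []
    for out_i, i in enumerate(indices):
        el = model.elements[i]
        r = table.get(el, table.get(el.capitalize()))
        if r is None:
            missing.append(f"atom {i} ({model.names[i]}, element {el!r})")
        else:
            radii[out_i] = r
    if missing:
        raise ValueError("no van der Waals radius for: " + "; ".join(missing))
    return radii


def sasa(
    model: StructureModel,
    atoms: np.ndarray | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Mapping[str, float] | None = None,
) -> float:
    """Shrake–Rupley solvent-accessible surface area in nm².

    For each atom, ``n_points`` quasi-uniform test points are placed on the
    sphere of radius r_i + probe; the accessible fraction times
    4π(r_i+probe)² is summed over atoms.  Only the atoms passed in are
    present — occlusion by anything else is deliberately excluded, which is
    what the contact-area formula requires.
    """
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 32:
        raise ValueError("n_points must be at least 32")
    idx = np.arange(model.n_atoms) if atoms is None else np.asarray(atoms, dtype=int)
    if idx.size == 0:
        raise ValueError("empty atom selection")
    coords = model.coords[idx]
    ext_r = _radii_for(model, idx, radii) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    r_max = ext_r.max()
    total = 0.0
    for i in range(len(idx)):
        candidates = tree.query_ball_point(coords[i], ext_r[i] + r_max)
        candidates = [j for j in candidates if j != i]
        surface = coords[i] + ext_r[i] * unit
        if candidates:
            nb = np.asarray(candidates)
            d2 = ((surface[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= (ext_r[nb] ** 2)[None, :]).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * np.pi * ext_r[i] ** 2
    return float(total)


def contact_area(
    model: StructureModel,
    a: RegionSelection,
    b: RegionSelection,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Mapping[str, float] | None = None,
) -> float:
    """Contact area ½(SASA_A + SASA_B − SASA_{A+B}) in nm².

    SASA_A and SASA_B see each region alone in solvent; SASA_{A+B} sees the
    union.  Selections must be disjoint after trimming.
    """
    ia, ib = a.resolve(model), b.resolve(model)
    if np.intersect1d(ia, ib).size:
        raise ValueError(f"selections {a.label!r} and {b.label!r} overlap")
    sub_a, sub_b = model.subset(ia), model.subset(ib)
    sub_ab = model.subset(np.concatenate([ia, ib]))
    s_a = sasa(sub_a, probe=probe, n_points=n_points, radii=radii)
    s_b = sasa(sub_b, probe=probe, n_points=n_points, radii=radii)
    s_ab = sasa(sub_ab, probe=probe, n_points=n_points, radii=radii)
    return 0.5 * (s_a + s_b - s_ab)


def contact_area_series(
    frames: Sequence[StructureModel],
    a: RegionSelection,
    b: RegionSelection,
    elongation: Sequence[float] | Callable[[int], float],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> ContactAreaSeries:
    """Per-frame contact area with an elongation coordinate attached."""
    if len(frames) == 0:
        raise ValueError("empty frame list")
    if callable(elongation):
        elong = np.array([elongation(f.frame_id) for f in frames], dtype=float)
    else:
        elong = np.asarray(elongation, dtype=float)
        if len(elong) != len(frames):
            raise ValueError("elongation length must match frames")
    ca = np.array([contact_area(f, a, b, probe=probe, n_points=n_points)
                   for f in frames])
    # clip quadrature jitter on separated regions so the series invariant holds
    ca = np.where((ca < 0) & (ca > -1e-6), 0.0, ca)
    return ContactAreaSeries(
        pair_label=f"{a.label}|{b.label}",
        frame_ids=np.array([f.frame_id for f in frames]),
        elongation=elong,
        ca=ca,
    )


def _angle_deg(vec: np.ndarray, axis: np.ndarray) -> float:
    nv = np.linalg.norm(vec)
    na = np.linalg.norm(axis)
    if nv == 0 or na == 0:
        raise ValueError("zero-length vector in tilt computation")
    cosang = np.clip(np.dot(vec, axis) / (nv * na), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def tilt_angles(
    frames: Sequence[StructureModel],
    anchor_mid: tuple[str, int],
    anchor_n: tuple[str, int],
    anchor_c: tuple[str, int],
    axis: Sequence[float] = (1.0, 0.0, 0.0),
    traj_id: str = "",
) -> TiltSeries:
    """Tilt angles of the anchor vectors against the pulling axis, per frame.

    α1 uses the Cα vector mid→N-side anchor, α2 mid→C-side anchor; both are
    arccos of the normalized dot product, in degrees.
    """
    axis = np.asarray(axis, dtype=float)
    a1, a2 = [], []
    for frame in frames:
        mid = frame.ca_coord(*anchor_mid)
        a1.append(_angle_deg(frame.ca_coord(*anchor_n) - mid, axis))
        a2.append(_angle_deg(frame.ca_coord(*anchor_c) - mid, axis))
    return TiltSeries(traj_id=traj_id, alpha1=np.array(a1), alpha2=np.array(a2),
                      anchors=(anchor_mid, anchor_n, anchor_c, tuple(axis)))


def max_tilt(series: TiltSeries) -> float:
    """Highest of the two maximum tilting angles over the trajectory."""
    if series.alpha1.size == 0:
        raise ValueError("empty tilt series")
    return float(max(series.alpha1.max(), series.alpha2.max()))
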