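"""Cell geometries for compartmental simulation.

A morphology is a tree of cylindrical compartments hanging off an
isopotential spherical soma.  All "distance from soma" logic uses path
distance along the cable (the coordinate that electrotonic propagation
follows), never the Euclidean distance between 3-D points.

Compartment sizes obey an electrotonic accuracy rule: each compartment's
length is at most a configured fraction of the local space constant

    lambda = sqrt(d * Rm / (4 * Ri))

computed with the local diameter and the passive membrane parameters.
Dendrites are labelled ``proximal`` / ``dendrite`` / ``distal`` by the
path distance of their midpoint relative to two region boundaries
(defaults: proximal < 50 um, distal > 100 um), mirroring the binning used
for proximal-vs-distal comparisons in ganglion-cell recordings.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "Region",
    "Compartment",
    "Morphology",
    "SynapseSite",
    "space_constant",
    "build_unbranched_cable",
    "build_soma_only",
    "load_swc",
    "write_swc",
    "place_synapses",
    "sites_at",
]

#: default passive parameters used for the electrotonic step rule (can be
#: overridden per call); Rm in Ohm*cm^2, Ri in Ohm*cm.
DEFAULT_RM = 28000.0
DEFAULT_RI = 200.0

DEFAULT_SOMA_DIAMETER = 20.0  # um
DEFAULT_REGION_BOUNDARIES = (50.0, 100.0)  # um: proximal max, distal min


class Region(str, Enum):
    SOMA = "soma"
    PROXIMAL = "proximal"
    DENDRITE = "dendrite"
    DISTAL = "distal"


def space_constant(diameter_um: float, rm: float = DEFAULT_RM, ri: float = DEFAULT_RI) -> float:
    """Passive space constant lambda = sqrt(d*Rm/(4*Ri)), in um.

    ``diameter_um`` in um; Rm in Ohm*cm^2; Ri in Ohm*cm.
    """
    if diameter_um <= 0:
        raise ValueError(f"diameter must be positive, got {diameter_um}")
    d_cm = diameter_um * 1e-4
    lam_cm = math.sqrt(d_cm * rm / (4.0 * ri))
    return lam_cm * 1e4


def region_for_distance(path_distance_um: float, boundaries=DEFAULT_REGION_BOUNDARIES) -> Region:
    """Region label for a dendritic location at the given path distance."""
    proximal_max, distal_min = boundaries
    if proximal_max > distal_min:
        raise ValueError("proximal boundary must not exceed distal boundary")
    if path_distance_um < proximal_max:
        return Region.PROXIMAL
    if path_distance_um > distal_min:
        return Region.DISTAL
    return Region.DENDRITE


@dataclass(frozen=True)
class Compartment:
    """One cylindrical cable element (or the spherical soma root)."""

    id: int
    parent_id: int | None
    path_distance: float  # um, distance of the DISTAL end from the soma centre
    length: float  # um; 0 for the spherical soma
    diameter: float  # um
    region: Region

    @property
    def midpoint_distance(self) -> float:
        return self.path_distance - 0.5 * self.length

    @property
    def area_cm2(self) -> float:
        """Membrane area in cm^2 (sphere for the soma, open cylinder else)."""
        d_cm = self.diameter * 1e-4
        if self.length == 0.0:
            return math.pi * d_cm**2
        return math.pi * d_cm * self.length * 1e-4


@dataclass
class Morphology:
    """Tree of compartments; index 0 is always the soma root."""

    compartments: list[Compartment]
    region_boundaries: tuple[float, float] = DEFAULT_REGION_BOUNDARIES

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        comps = self.compartments
        if not comps:
            raise ValueError("morphology needs at least a soma")
        roots = [c for c in comps if c.parent_id is None]
        if len(roots) != 1 or comps[0].parent_id is not None:
            raise ValueError("morphology must have exactly one root, at index 0")
        ids = [c.id for c in comps]
        if ids != list(range(len(comps))):
            raise ValueError("compartment ids must be 0..n-1 in order")
        for c in comps[1:]:
            if c.parent_id is None or not (0 <= c.parent_id < c.id):
                raise ValueError(f"compartment {c.id}: parent must precede child")
            if c.length <= 0:
                raise ValueError(f"compartment {c.id}: non-positive length")
            if c.diameter <= 0:
                raise ValueError(f"compartment {c.id}: non-positive diameter")
            parent = comps[c.parent_id]
            if c.path_distance <= parent.path_distance:
                raise ValueError(
                    f"compartment {c.id}: path distance must increase from parent"
                )

    # -- basic topology -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.compartments)

    @property
    def parent_index(self) -> np.ndarray:
        """Parent index per compartment; -1 for the root."""
        return np.array(
            [-1 if c.parent_id is None else c.parent_id for c in self.compartments],
            dtype=np.int64,
        )

    @property
    def path_distances(self) -> np.ndarray:
        return np.array([c.path_distance for c in self.compartments])

    @property
    def regions(self) -> list[Region]:
        return [c.region for c in self.compartments]

    def is_unbranched(self) -> bool:
        parents = self.parent_index[1:]
        return len(set(parents.tolist())) == len(parents)

    def terminal_distance(self) -> float:
        """Path distance of the farthest compartment end (um)."""
        return float(self.path_distances.max())

    # -- electrical helper arrays --------------------------------------
    def areas_cm2(self) -> np.ndarray:
        return np.array([c.area_cm2 for c in self.compartments])

    def axial_conductances_mS(self, ri: float = DEFAULT_RI) -> np.ndarray:
        """Coupling conductance (mS) between each compartment and its parent.

        Series sum of the two half-cylinder axial resistances; the
        spherical soma contributes no axial resistance of its own.
        """
        g = np.zeros(self.n)
        for c in self.compartments[1:]:
            parent = self.compartments[c.parent_id]
            r = _half_axial_resistance(c, ri) + _half_axial_resistance(parent, ri)
            g[c.id] = 1000.0 / r  # Ohm -> mS
        return g

    def compartment_at(self, path_distance_um: float) -> int:
        """Index of the compartment whose span contains the given distance.

        For branched trees the first (lowest-id) matching compartment wins.
        """
        if path_distance_um <= 0:
            return 0
        for c in self.compartments[1:]:
            if c.path_distance - c.length <= path_distance_um <= c.path_distance:
                return c.id
        raise ValueError(
            f"no compartment spans path distance {path_distance_um:.1f} um "
            f"(max {self.terminal_distance():.1f} um)"
        )

    def to_table(self) -> "pandas.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        return pd.DataFrame(
            {
                "id": [c.id for c in self.compartments],
                "parent_id": [-1 if c.parent_id is None else c.parent_id
                              for c in self.compartments],
                "path_distance_um": [c.path_distance for c in self.compartments],
                "length_um": [c.length for c in self.compartments],
                "diameter_um": [c.diameter for c in self.compartments],
                "region": [c.region.value for c in self.compartments],
            }
        )


def _half_axial_resistance(c: Compartment, ri: float) -> float:
    """Axial resistance (Ohm) of half a compartment; 0 for the soma sphere."""
    if c.length == 0.0:
        return 0.0
    radius_cm = 0.5 * c.diameter * 1e-4
    half_len_cm = 0.5 * c.length * 1e-4
    return ri * half_len_cm / (math.pi * radius_cm**2)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_soma_only(soma_diameter: float = DEFAULT_SOMA_DIAMETER) -> Morphology:
    soma = Compartment(0, None, 0.0, 0.0, soma_diameter, Region.SOMA)
    return Morphology([soma])


def build_unbranched_cable(
    dendrite_length: float,
    diameter: float = 0.6,
    *,
    taper_to: float | None = None,
    region_boundaries: tuple[float, float] = DEFAULT_REGION_BOUNDARIES,
    max_electrotonic_step: float = 0.1,
    soma_diameter: float = DEFAULT_SOMA_DIAMETER,
    rm: float = DEFAULT_RM,
    ri: float = DEFAULT_RI,
) -> Morphology:
    """Soma plus a single unbranched dendrite.

    Parameters
    ----------
    dendrite_length : total cable length in um (0 gives a soma-only cell).
    diameter : dendritic diameter in um at the soma end.
    taper_to : optional diameter at the distal tip; linear taper in between.
    max_electrotonic_step : maximum compartment length as a fraction of the
        local space constant.
    """
    if dendrite_length < 0:
        raise ValueError("dendrite_length must be >= 0")
    if diameter <= 0:
        raise ValueError(f"non-positive diameter {diameter} for dendrite segment")
    if taper_to is not None and taper_to <= 0:
        raise ValueError(f"non-positive diameter {taper_to} for distal segment")
    if not (0 < max_electrotonic_step <= 1):
        raise ValueError("max_electrotonic_step must be in (0, 1]")

    comps = [Compartment(0, None, 0.0, 0.0, soma_diameter, Region.SOMA)]
    if dendrite_length == 0:
        return Morphology(comps, region_boundaries)

    d_tip = diameter if taper_to is None else taper_to
    # worst-case (smallest) diameter sets a uniform compartment length
    lam = space_constant(min(diameter, d_tip), rm, ri)
    n_comp = max(1, math.ceil(dendrite_length / (max_electrotonic_step * lam)))
    dx = dendrite_length / n_comp
    for i in range(n_comp):
        far = (i + 1) * dx
        mid = far - 0.5 * dx
        frac = mid / dendrite_length
        d_here = diameter + (d_tip - diameter) * frac
        comps.append(
            Compartment(
                i + 1,
                i,
                far,
                dx,
                d_here,
                region_for_distance(mid, region_boundaries),
            )
        )
    return Morphology(comps, region_boundaries)


# ---------------------------------------------------------------------------
# SWC input/output
# ---------------------------------------------------------------------------

def load_swc(
    swc_text: str,
    *,
    region_boundaries: tuple[float, float] = DEFAULT_REGION_BOUNDARIES,
    max_electrotonic_step: float = 0.1,
    rm: float = DEFAULT_RM,
    ri: float = DEFAULT_RI,
) -> Morphology:
    """Build a morphology from standard 7-column SWC text.

    Path distances are computed by summing 3-D inter-node distances along
    the tree; each inter-node segment becomes one or more cylindrical
    compartments so that the electrotonic-step rule is satisfied.  The
    first node (parent -1) becomes the spherical soma.
    """
    nodes: dict[int, tuple[float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(swc_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"SWC line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            x, y, z, radius = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise ValueError(f"SWC line {lineno}: {exc}") from None
        if radius <= 0:
            raise ValueError(f"SWC line {lineno}: non-positive radius {radius}")
        if nid in nodes:
            raise ValueError(f"SWC line {lineno}: duplicate node id {nid}")
        if parent != -1 and parent not in nodes:
            raise ValueError(
                f"SWC line {lineno}: parent {parent} does not precede node {nid}"
            )
        nodes[nid] = (x, y, z, radius, parent)
        order.append(nid)

    roots = [nid for nid in order if nodes[nid][4] == -1]
    if len(roots) != 1:
        raise ValueError(f"SWC must have exactly one root node, found {len(roots)}")
    root = roots[0]

    x0, y0, z0, r0, _ = nodes[root]
    comps = [Compartment(0, None, 0.0, 0.0, 2.0 * r0, Region.SOMA)]
    # node id -> (compartment index of the distal end, cumulative path distance)
    attach: dict[int, tuple[int, float]] = {root: (0, 0.0)}

    for nid in order:
        if nid == root:
            continue
        x, y, z, radius, parent = nodes[nid]
        px, py, pz = nodes[parent][:3]
        seg_len = math.dist((x, y, z), (px, py, pz))
        if seg_len <= 0:
            raise ValueError(f"SWC node {nid}: zero-length segment from parent {parent}")
        parent_idx, parent_dist = attach[parent]
        d_here = 2.0 * radius
        lam = space_constant(d_here, rm, ri)
        n_sub = max(1, math.ceil(seg_len / (max_electrotonic_step * lam)))
        dx = seg_len / n_sub
        idx = parent_idx
        dist = parent_dist
        for _ in range(n_sub):
            dist += dx
            comps.append(
                Compartment(
                    len(comps),
                    idx,
                    dist,
                    dx,
                    d_here,
                    region_for_distance(dist - 0.5 * dx, region_boundaries),
                )
            )
            idx = len(comps) - 1
        attach[nid] = (idx, dist)

    return Morphology(comps, region_boundaries)


def write_swc(morphology: Morphology) -> str:
    """Serialize a morphology to 7-column SWC text.

    Branch geometry is laid out along +x per branch with y used to separate
    siblings; 3-D coordinates are synthetic but inter-node path distances
    are exact, so load_swc(write_swc(m)) preserves path distances.
    """
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    soma = morphology.compartments[0]
    buf.write(f"1 1 0.0 0.0 0.0 {soma.diameter / 2:.6f} -1\n")
    # give each compartment a distinct y-lane per parent to avoid overlap
    child_rank: dict[int, int] = {}
    coords: dict[int, tuple[float, float]] = {0: (0.0, 0.0)}
    for c in morphology.compartments[1:]:
        rank = child_rank.get(c.parent_id, 0)
        child_rank[c.parent_id] = rank + 1
        px, py = coords[c.parent_id]
        y = py + rank * 1e-3  # tiny lateral offset keeps siblings distinct
        x = px + math.sqrt(max(c.length**2 - (y - py) ** 2, 1e-12))
        coords[c.id] = (x, y)
        buf.write(
            f"{c.id + 1} 3 {x:.6f} {y:.6f} 0.0 {c.diameter / 2:.6f} {c.parent_id + 1}\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# synapse placement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseSite:
    compartment_id: int
    offset: float  # fraction 0-1 along the compartment
    path_distance: float  # um

    def __post_init__(self) -> None:
        if not (0.0 <= self.offset <= 1.0):
            raise ValueError("offset must lie in [0, 1]")


def place_synapses(
    morphology: Morphology,
    mean_spacing: float = 10.0,
    regularity: float = 8.0,
    seed: int | np.random.Generator = 0,
) -> list[SynapseSite]:
    """Scatter synapse sites over the dendritic tree at regular intervals.

    Successive inter-synapse path intervals are gamma distributed with
    shape k = regularity**2 and scale mean_spacing/k, so the interval mean
    is ``mean_spacing`` and mean/SD equals ``regularity`` exactly.  At a
    branch point placement continues independently into each child.
    Deterministic for a given seed; a dendrite shorter than the first draw
    simply yields no sites.
    """
    if mean_spacing <= 0:
        raise ValueError("mean_spacing must be positive")
    if regularity <= 0:
        raise ValueError("regularity must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = regularity**2
    scale = mean_spacing / shape

    children: dict[int, list[Compartment]] = {}
    for c in morphology.compartments[1:]:
        children.setdefault(c.parent_id, []).append(c)

    sites: list[SynapseSite] = []

    def descend(comp_idx: int, next_at: float) -> None:
        """Walk distally from compartment ``comp_idx``, dropping sites."""
        for child in children.get(comp_idx, []):
            start = child.path_distance - child.length
            target = next_at
            while target <= child.path_distance:
                offset = (target - start) / child.length
                sites.append(SynapseSite(child.id, min(max(offset, 0.0), 1.0), target))
                target += shape * scale if regularity > 1e6 else rng.gamma(shape, scale)
            descend(child.id, target)

    first = mean_spacing if regularity > 1e6 else rng.gamma(shape, scale)
    descend(0, first)
    sites.sort(key=lambda s: s.path_distance)
    return sites


def sites_at(morphology: Morphology, path_distances_um) -> list[SynapseSite]:
    """Synapse sites at explicit path distances (sorted by distance)."""
    sites = []
    for d in sorted(path_distances_um):
        idx = morphology.compartment_at(d)
        c = morphology.compartments[idx]
        offset = 0.5 if c.length == 0 else (d - (c.path_distance - c.length)) / c.length
        sites.append(SynapseSite(idx, min(max(offset, 0.0), 1.0), float(d)))
    return sites
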