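"""Coarse-grained POPC bilayer vesicle construction.

One POPC lipid is represented by 13 beads — choline (NC3), phosphate (PO4),
two glycerol beads (GL1, GL2) and nine fatty-acid tail beads split 4+5
between the palmitoyl (C1A–C4A) and oleoyl (C1B–C5B) chains — following the
residue-based coarse-graining convention of ~10 heavy atoms per bead.  Head
beads (NC3, PO4, GL1, GL2) are classed hydrophilic, tail beads hydrophobic.

A vesicle is built as two concentric leaflets: outer-leaflet head beads are
tiled on a sphere of radius ``R_out`` at the prescribed area per lipid
(default 65 Å²) using a Fibonacci lattice, inner-leaflet head beads on
``R_out − thickness`` (default thickness 36.8 Å).  Each lipid spans one
leaflet (18.4 Å), tails pointing at the bilayer midplane.  An optional open
pore removes all lipids inside a spherical cap covering a given fraction of
the surface (default preset 13%), allowing lipid exchange between leaflets
during relaxation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dfield

import numpy as np

__all__ = [
    "BeadSpec",
    "LipidTemplate",
    "CGVesicle",
    "POPC_TEMPLATE",
    "popc_template",
    "leaflet_lipid_count",
    "pore_cap_angle",
    "build_vesicle",
    "write_pdb",
    "read_pdb",
    "PRESET_DIAMETERS_NM",
]

#: Initial-model diameter series (nm) for the curvature-hydrophobicity study.
PRESET_DIAMETERS_NM = (12.2, 19.6, 26.0, 34.4, 42.0)

HYDROPHILIC = "hydrophilic"
HYDROPHOBIC = "hydrophobic"


@dataclass(frozen=True)
class BeadSpec:
    """A coarse-grained bead: name, hydrophobicity class and radius (Å)."""

    name: str
    hclass: str
    radius: float = 2.35  # half the 4.7 Å CG bead diameter

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("bead radius must be positive")
        if self.hclass not in (HYDROPHILIC, HYDROPHOBIC):
            raise ValueError(f"unknown hydrophobicity class {self.hclass!r}")


@dataclass(frozen=True)
class LipidTemplate:
    """13-bead lipid: bead specs, bond topology and local geometry.

    Local coordinates are in a frame whose +z axis points from the tail end
    toward the head; the head (NC3) bead sits at z = 0 and the deepest tail
    bead at z = −span.  ``local_coords`` has shape (13, 3) with x the
    lateral (in-leaflet) offset.
    """

    beads: tuple[BeadSpec, ...]
    bonds: tuple[tuple[int, int], ...]
    local_coords: np.ndarray

    def __post_init__(self) -> None:
        if len(self.beads) != 13:
            raise ValueError("template must have exactly 13 beads")
        n_phil = sum(1 for b in self.beads if b.hclass == HYDROPHILIC)
        if n_phil != 4 or len(self.beads) - n_phil != 9:
            raise ValueError("need exactly 4 hydrophilic + 9 hydrophobic beads")
        object.__setattr__(
            self, "local_coords", np.asarray(self.local_coords, dtype=float).reshape(13, 3)
        )
        if not _connected(13, self.bonds):
            raise ValueError("bond graph must be connected")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.beads)

    @property
    def hydrophobic_mask(self) -> np.ndarray:
        return np.array([b.hclass == HYDROPHOBIC for b in self.beads])

    @property
    def span(self) -> float:
        return float(-self.local_coords[:, 2].min())

    def bond_rest_lengths(self) -> np.ndarray:
        i, j = np.array(self.bonds).T
        return np.linalg.norm(self.local_coords[i] - self.local_coords[j], axis=1)


def _connected(n: int, bonds) -> bool:
    adj = {k: set() for k in range(n)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    seen, stack = {0}, [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n


def popc_template(bead_radius: float = 2.35) -> LipidTemplate:
    """Build the 13-bead POPC template.

    The lipid spans 18.4 Å (one leaflet of the 36.8 Å bilayer); beads are
    placed on 8 depth levels (radial step 18.4/7 ≈ 2.63 Å, i.e. chain bead
    spacing compressed from the ~3.3 Å free-chain value so the lipid fits
    the leaflet).  The two glycerol beads sit side by side; the palmitoyl
    chain (4 beads) hangs under GL1 and the oleoyl chain (5 beads) under
    GL2, laterally offset so the two chains do not overlap.

    Glycerol beads are classed hydrophilic here; surface analysis exposes a
    reclassification option (see ``lipocurv.sasa.SASAConfig``).
    """
    step = 18.4 / 7.0
    names_classes_xz = [
        ("NC3", HYDROPHILIC, 0.0, 0.0),
        ("PO4", HYDROPHILIC, 0.0, 1.0),
        ("GL1", HYDROPHILIC, -1.6, 2.0),
        ("GL2", HYDROPHILIC, 1.6, 2.0),
        ("C1A", HYDROPHOBIC, -2.0, 3.0),
        ("C2A", HYDROPHOBIC, -2.0, 4.0),
        ("C3A", HYDROPHOBIC, -2.0, 5.0),
        ("C4A", HYDROPHOBIC, -2.0, 6.0),
        ("C1B", HYDROPHOBIC, 2.0, 3.0),
        ("C2B", HYDROPHOBIC, 2.0, 4.0),
        ("C3B", HYDROPHOBIC, 2.0, 5.0),
        ("C4B", HYDROPHOBIC, 2.0, 6.0),
        ("C5B", HYDROPHOBIC, 2.0, 7.0),
    ]
    beads = tuple(BeadSpec(n, c, bead_radius) for n, c, _, _ in names_classes_xz)
    coords = np.array([[x, 0.0, -lvl * step] for _, _, x, lvl in names_classes_xz])
    bonds = (
        (0, 1),  # NC3-PO4
        (1, 2),  # PO4-GL1
        (2, 3),  # GL1-GL2
        (2, 4), (4, 5), (5, 6), (6, 7),          # palmitoyl chain
        (3, 8), (8, 9), (9, 10), (10, 11), (11, 12),  # oleoyl chain
    )
    return LipidTemplate(beads=beads, bonds=bonds, local_coords=coords)


POPC_TEMPLATE = popc_template()

#: Chain angle triples (indices into the 13-bead template) used for chain
#: stiffness: head stack and both tails.
ANGLE_TRIPLES = (
    (0, 1, 2),
    (1, 2, 4), (2, 4, 5), (4, 5, 6), (5, 6, 7),
    (2, 3, 8), (3, 8, 9), (8, 9, 10), (9, 10, 11), (10, 11, 12),
)


@dataclass
class CGVesicle:
    """Bead-resolved coarse-grained vesicle.

    Attributes
    ----------
    coords : (n_beads, 3) float array, Å.
    bead_names : (n_beads,) array of template bead names.
    lipid_index : (n_beads,) int array mapping each bead to its lipid.
    leaflet : (n_lipids,) array of ``"outer"``/``"inner"`` labels.
    template : the LipidTemplate shared by all lipids.
    meta : provenance (nominal diameter nm, area per lipid Å², thickness Å,
        pore fraction, seed).
    """

    coords: np.ndarray
    bead_names: np.ndarray
    lipid_index: np.ndarray
    leaflet: np.ndarray
    template: LipidTemplate
    meta: dict = _dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.bead_names = np.asarray(self.bead_names)
        self.lipid_index = np.asarray(self.lipid_index, dtype=int)
        self.leaflet = np.asarray(self.leaflet)
        n = len(self.coords)
        if n == 0:
            raise ValueError("vesicle has no beads")
        if n % 13 != 0:
            raise ValueError("bead count must be a multiple of 13")
        if len(self.bead_names) != n or len(self.lipid_index) != n:
            raise ValueError("per-bead arrays must match coordinate count")
        if len(self.leaflet) != n // 13:
            raise ValueError("leaflet labels must be per-lipid")
        if not set(np.unique(self.leaflet)) <= {"outer", "inner"}:
            raise ValueError("leaflet labels must be 'outer' or 'inner'")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_lipids(self) -> int:
        return len(self.leaflet)

    @property
    def hydrophobic_mask(self) -> np.ndarray:
        """Per-bead hydrophobicity from the template's bead classes."""
        class_of = {b.name: b.hclass == HYDROPHOBIC for b in self.template.beads}
        return np.array([class_of[n] for n in self.bead_names])

    @property
    def bead_radii(self) -> np.ndarray:
        r_of = {b.name: b.radius for b in self.template.beads}
        return np.array([r_of[n] for n in self.bead_names])

    @property
    def head_mask(self) -> np.ndarray:
        """Mask of the outermost head bead (choline) of every lipid."""
        return self.bead_names == "NC3"

    def leaflet_of_beads(self) -> np.ndarray:
        return self.leaflet[self.lipid_index]

    def outer_head_radii(self) -> np.ndarray:
        """Radial distances (Å) of outer-leaflet choline beads from the
        bead center of mass."""
        com = self.coords.mean(axis=0)
        m = self.head_mask & (self.leaflet_of_beads() == "outer")
        if not m.any():
            raise ValueError("vesicle has no outer-leaflet head beads")
        return np.linalg.norm(self.coords[m] - com, axis=1)

    def copy_with_coords(self, coords: np.ndarray) -> "CGVesicle":
        return CGVesicle(
            coords=np.array(coords, dtype=float),
            bead_names=self.bead_names,
            lipid_index=self.lipid_index,
            leaflet=self.leaflet,
            template=self.template,
            meta=dict(self.meta),
        )


def leaflet_lipid_count(R_ref: float, area_per_lipid: float) -> int:
    """Number of lipids tiling a sphere of radius ``R_ref`` (Å) at
    ``area_per_lipid`` (Å²): round(4·pi·R_ref² / area)."""
    if R_ref <= 0 or area_per_lipid <= 0:
        raise ValueError("radius and area per lipid must be positive")
    return int(round(4.0 * np.pi * R_ref**2 / area_per_lipid))


def pore_cap_angle(f: float) -> float:
    """Half-angle (degrees) of a spherical cap covering area fraction ``f``:
    arccos(1 − 2 f), valid for 0 ≤ f < 0.5."""
    if not 0.0 <= f < 0.5:
        raise ValueError("pore area fraction must be in [0, 0.5)")
    return float(np.degrees(np.arccos(1.0 - 2.0 * f)))


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (Fibonacci lattice)."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent vectors for each unit vector u (rows)."""
    ref = np.where(np.abs(u[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(ref, u)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    return e1, e2


def build_vesicle(
    outer_diameter: float,
    area_per_lipid: float = 65.0,
    thickness: float = 36.8,
    pore_fraction: float = 0.0,
    seed: int | None = None,
    template: LipidTemplate | None = None,
    pore_axis=(0.0, 0.0, 1.0),
) -> CGVesicle:
    """Construct an initial CG bilayer vesicle.

    Parameters
    ----------
    outer_diameter : float
        Nominal outer diameter in nm (head-bead shell diameter).
    area_per_lipid : float
        Tiling area per lipid (Å²) at the head-bead radius of each leaflet.
    thickness : float
        Bilayer thickness (Å): distance between outer and inner head shells.
    pore_fraction : float
        Surface-area fraction of the open pore cap (0 disables).
    seed : int
        Controls the global lattice orientation and per-lipid azimuths.

    The outer leaflet head beads lie on ``R_out = 5·outer_diameter`` Å, the
    inner on ``R_out − thickness``; each leaflet is a Fibonacci lattice with
    ``round(4·pi·R²/area)`` lipids.  Lipid tails point toward the bilayer
    midplane.  With a pore, lipids whose lattice direction falls inside the
    cap around ``pore_axis`` are removed from both leaflets.
    """
    template = template or POPC_TEMPLATE
    R_out = outer_diameter * 10.0 / 2.0
    if R_out <= thickness:
        raise ValueError(
            f"outer radius {R_out:.1f} Å must exceed bilayer thickness {thickness} Å"
        )
    R_in = R_out - thickness
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    global_rot = Rotation.random(rng=rng).as_matrix()

    pore_axis = np.asarray(pore_axis, dtype=float)
    pore_axis = pore_axis / np.linalg.norm(pore_axis)
    cos_cap = np.cos(np.radians(pore_cap_angle(pore_fraction))) if pore_fraction > 0 else None

    coords, names, lipids, leaflets = [], [], [], []
    lipid_id = 0
    for leaflet_label, R_head, sign in (("outer", R_out, -1.0), ("inner", R_in, +1.0)):
        n_lip = leaflet_lipid_count(R_head, area_per_lipid)
        u = fibonacci_sphere(n_lip) @ global_rot.T
        if cos_cap is not None:
            u = u[u @ pore_axis < cos_cap]
        e1, e2 = _tangent_basis(u)
        az = rng.uniform(0.0, 2.0 * np.pi, size=len(u))
        ca, sa = np.cos(az)[:, None], np.sin(az)[:, None]
        t1 = ca * e1 + sa * e2  # per-lipid lateral x direction
        t2 = -sa * e1 + ca * e2
        local = template.local_coords  # (13, 3): x lateral, z depth (<= 0)
        for k in range(len(u)):
            # radial coordinate: head at R_head, deeper beads toward midplane
            radial = R_head + sign * (-local[:, 2])
            pos = radial[:, None] * u[k] + local[:, 0:1] * t1[k] + local[:, 1:2] * t2[k]
            coords.append(pos)
            names.extend(template.names)
            lipids.extend([lipid_id] * 13)
            leaflets.append(leaflet_label)
            lipid_id += 1

    meta = {
        "outer_diameter_nm": float(outer_diameter),
        "area_per_lipid_A2": float(area_per_lipid),
        "thickness_A": float(thickness),
        "pore_fraction": float(pore_fraction),
        "seed": seed,
    }
    return CGVesicle(
        coords=np.vstack(coords),
        bead_names=np.array(names),
        lipid_index=np.array(lipids),
        leaflet=np.array(leaflets),
        template=template,
        meta=meta,
    )


_META_KEYS = ("outer_diameter_nm", "area_per_lipid_A2", "thickness_A", "pore_fraction", "seed")


def write_pdb(v: CGVesicle, path) -> None:
    """Write the vesicle as a PDB bead model.

    One ATOM record per bead: bead name in the atom-name field, residue name
    POP, lipid id in the residue number (wrapped modulo 9999 past the PDB
    field width — lipid identity is recovered on read from the fixed
    13-bead-per-lipid record order), leaflet in the chain identifier
    (O = outer, I = inner).  Builder metadata is stored in REMARK 250 lines.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = v.n_beads
    arr = struc.AtomArray(n)
    arr.coord = v.coords.astype(np.float32)
    arr.atom_name = v.bead_names
    arr.res_name = np.full(n, "POP")
    arr.res_id = (v.lipid_index % 9999) + 1
    arr.chain_id = np.where(v.leaflet_of_beads() == "outer", "O", "I")
    arr.element = np.full(n, "C")
    f = PDBFile()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # atom-id wrap past 99999
        f.set_structure(arr)
    remarks = [
        f"REMARK 250 LIPOCURV {key}={v.meta.get(key)}" for key in _META_KEYS if key in v.meta
    ]
    f.lines = remarks + f.lines
    f.write(str(path))


def read_pdb(path, template: LipidTemplate | None = None) -> CGVesicle:
    """Read a vesicle PDB written by :func:`write_pdb`.

    Lipid indices are reconstructed from the canonical 13-beads-per-lipid
    record order (residue numbers wrap past 9999 and serve only as a
    consistency check).  Raises ``ValueError`` naming the offending record
    on malformed input.
    """
    from biotite.structure.io.pdb import PDBFile

    template = template or POPC_TEMPLATE
    try:
        f = PDBFile.read(str(path))
        arr = f.get_structure(model=1)
    except Exception as e:
        raise ValueError(f"malformed PDB file {path}: {e}") from e

    meta: dict = {}
    for line in f.lines:
        if line.startswith("REMARK 250 LIPOCURV "):
            key, _, val = line[len("REMARK 250 LIPOCURV "):].partition("=")
            if key in _META_KEYS:
                meta[key] = None if val in ("None", "") else float(val)
    if "seed" in meta and meta["seed"] is not None:
        meta["seed"] = int(meta["seed"])

    n = arr.array_length()
    if n == 0:
        raise ValueError(f"{path}: no ATOM records")
    if n % 13 != 0:
        raise ValueError(f"{path}: bead count {n} is not a multiple of 13 (record {n})")
    names = arr.atom_name
    expected = np.tile(np.array(template.names), n // 13)
    mismatch = np.nonzero(names != expected)[0]
    if mismatch.size:
        k = int(mismatch[0])
        raise ValueError(
            f"{path}: record {k + 1}: bead name {names[k]!r} breaks the "
            f"13-bead lipid order (expected {expected[k]!r})"
        )
    lipid_index = np.arange(n) // 13
    chain_per_lipid = arr.chain_id[::13]
    bad_chain = np.nonzero(~np.isin(chain_per_lipid, ("O", "I")))[0]
    if bad_chain.size:
        raise ValueError(
            f"{path}: record {int(bad_chain[0]) * 13 + 1}: chain id must be O or I"
        )
    leaflet = np.where(chain_per_lipid == "O", "outer", "inner")
    return CGVesicle(
        coords=arr.coord.astype(float),
        bead_names=names,
        lipid_index=lipid_index,
        leaflet=leaflet,
        template=template,
        meta=meta,
    )
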