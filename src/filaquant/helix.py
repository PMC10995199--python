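"""Helical filament geometry and buried-interface area.

A helical assembly is described by a screw operator: a signed twist (degrees,
negative = left-handed when the translation is taken positive) and a rise
(Å) along the helix axis, optionally with D1 point symmetry (a two-fold axis
perpendicular to the helix axis).  This module builds filaments from a
protomer and a :class:`HelicalParams`, recovers the parameters back from
coordinates by least-squares screw-axis decomposition, converts twist to
subunits-per-turn, and measures buried solvent-accessible surface area
(Shrake–Rupley) across an interface.

Structures are carried as lightweight :class:`StructureModel` arrays and can
be read from / written to PDB or mmCIF via :mod:`gemmi`.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "HelicalParams",
    "StructureModel",
    "ScrewTransform",
    "apply_helical_symmetry",
    "screw_decompose",
    "recover_helical_params",
    "dimers_per_turn",
    "shrake_rupley_sasa",
    "buried_interface_area",
    "read_structure",
    "units_from_chain_groups",
    "infer_units_by_axis",
]

#: van der Waals radii (Å) used for SASA; fixed for reproducibility.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.80
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


@dataclass
class HelicalParams:
    """Signed twist (deg), rise (Å) and point group of a helical assembly."""

    twist: float
    rise: float
    point_group: str = "C1"  # "C1" or "D1" (C2 axis perpendicular to helix)

    def __post_init__(self) -> None:
        if not (-180.0 < self.twist <= 180.0):
            raise ValueError("twist must lie in (-180, 180]")
        if self.rise < 0:
            raise ValueError("rise must be non-negative")
        if self.point_group not in ("C1", "D1"):
            raise ValueError("point_group must be 'C1' or 'D1'")


@dataclass
class StructureModel:
    """Atom coordinates with element, chain and filament-unit bookkeeping."""

    coords: np.ndarray                      # (N, 3) Å
    elements: np.ndarray | None = None      # (N,) str
    chains: np.ndarray | None = None        # (N,) str
    unit_index: np.ndarray | None = None    # (N,) int, position along filament
    resids: np.ndarray | None = None        # (N,) int residue numbers

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        if self.elements is None:
            self.elements = np.full(n, "C")
        else:
            self.elements = np.asarray(self.elements)
        if self.chains is None:
            self.chains = np.full(n, "A")
        else:
            self.chains = np.asarray(self.chains)
        if self.unit_index is not None:
            self.unit_index = np.asarray(self.unit_index, dtype=int)
        if self.resids is not None:
            self.resids = np.asarray(self.resids, dtype=int)

    def __len__(self) -> int:
        return len(self.coords)

    def select_residues(self, lo: int, hi: int) -> "StructureModel":
        """Atoms whose residue number lies in [lo, hi] (inclusive)."""
        if self.resids is None:
            raise ValueError("model carries no residue numbers")
        m = (self.resids >= lo) & (self.resids <= hi)
        ui = None if self.unit_index is None else self.unit_index[m]
        return StructureModel(
            self.coords[m], self.elements[m], self.chains[m], ui, self.resids[m]
        )

    def select_unit(self, k: int) -> "StructureModel":
        if self.unit_index is None:
            raise ValueError("model carries no unit indices")
        m = self.unit_index == k
        ri = None if self.resids is None else self.resids[m]
        return StructureModel(
            self.coords[m], self.elements[m], self.chains[m], self.unit_index[m], ri
        )

    def select_chains(self, names) -> "StructureModel":
        names = set(np.atleast_1d(names).tolist())
        m = np.isin(self.chains, list(names))
        ui = None if self.unit_index is None else self.unit_index[m]
        ri = None if self.resids is None else self.resids[m]
        return StructureModel(self.coords[m], self.elements[m], self.chains[m], ui, ri)

    @property
    def n_units(self) -> int:
        if self.unit_index is None:
            return 1
        return int(self.unit_index.max()) + 1

    def radii(self) -> np.ndarray:
        return np.array([VDW_RADII.get(str(e), DEFAULT_RADIUS) for e in self.elements])


@dataclass
class ScrewTransform:
    """A rigid transform decomposed about its screw axis.

    The axis is oriented so the translation along it is non-negative; the
    rotation angle is then signed by the right-hand rule about that axis
    (negative angle + positive translation = left-handed screw).
    """

    angle_deg: float
    axis: np.ndarray
    axis_point: np.ndarray
    translation: float
    rmsd: float = 0.0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError("axis must be a unit vector")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


# ---------------------------------------------------------------------------
# filament construction
# ---------------------------------------------------------------------------


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_C2X = np.diag([1.0, -1.0, -1.0])  # two-fold about the x-axis


def apply_helical_symmetry(
    protomer: StructureModel, params: HelicalParams, n_units: int
) -> StructureModel:
    """Propagate a protomer along the helix axis (z).

    Unit ``k`` is the protomer rotated by ``k * twist`` about z and
    translated ``k * rise`` along z.  Under D1 symmetry each unit also
    carries its C2 mate, generated by a two-fold axis perpendicular to z
    through the unit origin; mates share the unit index and get a primed
    chain name.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    coords, elements, chains, units = [], [], [], []
    for k in range(n_units):
        rz = _rot_z(k * params.twist)
        shift = np.array([0.0, 0.0, k * params.rise])
        xyz = protomer.coords @ rz.T + shift
        coords.append(xyz)
        elements.append(protomer.elements)
        chains.append(np.char.add(protomer.chains.astype(str), f"{k}"))
        units.append(np.full(len(protomer), k))
        if params.point_group == "D1":
            mate = protomer.coords @ _C2X.T @ rz.T + shift
            coords.append(mate)
            elements.append(protomer.elements)
            chains.append(np.char.add(protomer.chains.astype(str), f"{k}'"))
            units.append(np.full(len(protomer), k))
    return StructureModel(
        np.vstack(coords),
        np.concatenate(elements),
        np.concatenate(chains),
        np.concatenate(units),
    )


# ---------------------------------------------------------------------------
# screw decomposition
# ---------------------------------------------------------------------------


def _kabsch(a: np.ndarray, b: np.ndarray):
    """Least-squares rotation R and translation t with b ~ a @ R.T + t."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    return r, t


def screw_decompose(coords_a: np.ndarray, coords_b: np.ndarray) -> ScrewTransform:
    """Decompose the rigid map A -> B into rotation about and translation
    along its screw axis.

    The superposition is least-squares (Kabsch); the residual RMSD after
    applying the fitted transform is reported.  For a (near-)pure
    translation the axis is taken along the translation.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 3:
        raise ValueError("need >= 3 matched points of identical shape")
    centred = a - a.mean(axis=0)
    # collinearity check via second singular value
    if np.linalg.svd(centred, compute_uv=False)[1] < 1e-9 * max(
        1.0, np.abs(a).max()
    ):
        raise ValueError("points are collinear; screw axis is degenerate")

    r, t = _kabsch(a, b)
    rmsd = float(np.sqrt(np.mean(np.sum((a @ r.T + t - b) ** 2, axis=1))))

    cos_theta = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)

    if theta < 1e-5:
        # pure translation (or identity); the threshold sits well above the
        # ~1e-7 rad numerical noise of the superposition

        trans = float(np.linalg.norm(t))
        axis = t / trans if trans > 1e-12 else np.array([0.0, 0.0, 1.0])
        return ScrewTransform(0.0, axis, np.zeros(3), trans, rmsd)

    if np.pi - theta < 1e-9:
        # 180°: axis from the symmetric part, sign fixed by translation below
        w, v = np.linalg.eigh((r + np.eye(3)) / 2.0)
        axis = v[:, np.argmax(w)]
    else:
        axis = np.array(
            [r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]]
        ) / (2.0 * np.sin(theta))
    axis = axis / np.linalg.norm(axis)

    trans = float(t @ axis)
    angle = np.rad2deg(theta)
    if trans < 0:
        axis, trans, angle = -axis, -trans, -angle
    elif trans == 0 and axis[2] < 0:
        # no translation to orient by: use +z hemisphere convention
        axis, angle = -axis, -angle
    # re-sign angle by right-hand rule about the (possibly flipped) axis
    # (arccos lost the sign; recover it from the antisymmetric part)
    sin_part = np.array(
        [r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]]
    ) / 2.0
    s = float(sin_part @ axis)
    if abs(s) > 1e-12:
        angle = np.copysign(abs(angle), s)

    # axis point: solve (I - R) p = t_perp in the plane normal to the axis
    t_perp = t - trans * axis
    p = np.linalg.lstsq(np.eye(3) - r, t_perp, rcond=None)[0]
    p = p - (p @ axis) * axis
    return ScrewTransform(float(angle), axis, p, trans, rmsd)


def recover_helical_params(
    filament: StructureModel, pairs=None
) -> tuple[HelicalParams, list[ScrewTransform]]:
    """Recover (twist, rise) from a filament by per-pair screw decomposition.

    ``pairs`` selects which unit pairs to decompose (default: all successive
    pairs).  The twist is the circular mean of per-pair angles and the rise
    the mean translation; per-pair transforms are returned for spread
    inspection.  Units must hold equally many atoms in consistent order.
    """
    n = filament.n_units
    if n < 2:
        raise ValueError("need >= 2 units to recover helical parameters")
    if pairs is None:
        pairs = [(k, k + 1) for k in range(n - 1)]
    transforms = []
    for i, j in pairs:
        a = filament.select_unit(i).coords
        b = filament.select_unit(j).coords
        if a.shape != b.shape:
            raise ValueError(
                f"units {i} and {j} have different atom counts; match atoms "
                "by name before recovering parameters"
            )
        transforms.append(screw_decompose(a, b))
    angles = np.deg2rad([t.angle_deg for t in transforms])
    twist = float(np.rad2deg(np.angle(np.mean(np.exp(1j * angles)))))
    if twist <= -180.0:
        twist += 360.0
    rise = float(np.mean([t.translation for t in transforms]))
    return HelicalParams(twist=twist, rise=rise), transforms


def dimers_per_turn(twist: float) -> tuple[float, int]:
    """Subunits (dimers) per helical turn: ``360 / |twist|``.

    Returns the exact value and its round-half-up integer.
    """
    if twist == 0:
        raise ValueError("twist of 0 makes no turn")
    exact = 360.0 / abs(twist)
    return exact, int(np.floor(exact + 0.5))


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral points on the unit sphere."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


_UNIT_SPHERE = _sphere_points(N_SPHERE_POINTS)


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> float:
    """Total solvent-accessible surface area (Å²), Shrake–Rupley.

    Test points are placed on each atom's solvent-expanded sphere
    (radius + probe) along a fixed golden-section spiral; a point is
    accessible if it lies outside every neighbour's expanded sphere.
    """
    if len(model) == 0:
        raise ValueError("empty structure")
    coords = model.coords
    radii = model.radii() + probe
    pts = _UNIT_SPHERE if n_points == N_SPHERE_POINTS else _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    total = 0.0
    for i in range(len(coords)):
        neigh = tree.query_ball_point(coords[i], radii[i] + rmax)
        neigh = [j for j in neigh if j != i]
        surface = coords[i] + radii[i] * pts
        if neigh:
            d2 = np.sum(
                (surface[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2
            )
            buried = np.any(d2 < (radii[neigh] ** 2)[None, :], axis=1)
            n_acc = int(np.sum(~buried))
        else:
            n_acc = len(pts)
        total += 4.0 * np.pi * radii[i] ** 2 * n_acc / len(pts)
    return float(total)


def buried_interface_area(
    part_a: StructureModel,
    part_b: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> float:
    """Buried surface area of the A:B interface (Å²), total over both sides.

    ``BSA = SASA(A) + SASA(B) - SASA(A u B)``.
    """
    if len(part_a) == 0 or len(part_b) == 0:
        raise ValueError("both parts must contain atoms")
    union = StructureModel(
        np.vstack([part_a.coords, part_b.coords]),
        np.concatenate([part_a.elements, part_b.elements]),
        np.concatenate([part_a.chains, part_b.chains]),
    )
    bsa = (
        shrake_rupley_sasa(part_a, probe, n_points)
        + shrake_rupley_sasa(part_b, probe, n_points)
        - shrake_rupley_sasa(union, probe, n_points)
    )
    return float(bsa)


def units_from_chain_groups(model: StructureModel, groups) -> StructureModel:
    """Assign filament unit indices from ordered chain-name groups.

    ``groups`` lists, per unit along the filament, the chain names that make
    it up (e.g. one dimer per unit in a deposited filament model).  Atoms in
    chains not mentioned are dropped.  This is the bridge from a deposited
    coordinate file to :func:`recover_helical_params`.
    """
    coords, elements, chains, units = [], [], [], []
    for k, names in enumerate(groups):
        part = model.select_chains(list(names))
        if len(part) == 0:
            raise ValueError(f"unit {k}: no atoms in chains {names}")
        coords.append(part.coords)
        elements.append(part.elements)
        chains.append(part.chains)
        units.append(np.full(len(part), k))
    return StructureModel(
        np.vstack(coords),
        np.concatenate(elements),
        np.concatenate(chains),
        np.concatenate(units),
    )


# ---------------------------------------------------------------------------
# file I/O (gemmi)
# ---------------------------------------------------------------------------


def read_structure(path) -> StructureModel:
    """Read atoms from a PDB or mmCIF file into a :class:`StructureModel`."""
    import gemmi

    st = gemmi.read_structure(str(path))
    coords, elements, chains, resids = [], [], [], []
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    elements.append(atom.element.name)
                    chains.append(chain.name)
                    resids.append(residue.seqid.num)
        break  # first model only
    if not coords:
        raise ValueError(f"no atoms found in {path}")
    return StructureModel(
        np.array(coords), np.array(elements), np.array(chains),
        resids=np.array(resids),
    )


def infer_units_by_axis(
    model: StructureModel, chains_per_unit: int = 2
) -> StructureModel:
    """Group chains into filament units ordered along the principal axis.

    Chain centroids are projected onto the first principal axis of their
    spread (the helix axis for an elongated filament), sorted, and taken
    ``chains_per_unit`` at a time (e.g. 2 for a filament of dimers).  Chains
    whose atom counts differ from the modal count are dropped so successive
    units stay comparable atom-by-atom.
    """
    names, counts = np.unique(model.chains, return_counts=True)
    modal = np.bincount(counts).argmax()
    keep = [str(n) for n, c in zip(names, counts) if c == modal]
    if len(keep) < 2 * chains_per_unit:
        raise ValueError("fewer than two complete units with matching chains")
    cents = np.array(
        [model.select_chains(n).coords.mean(axis=0) for n in keep]
    )
    spread = cents - cents.mean(axis=0)
    axis = np.linalg.svd(spread, compute_uv=True)[2][0]
    order = np.argsort(spread @ axis)
    ordered = [keep[i] for i in order]
    groups = [
        ordered[i: i + chains_per_unit]
        for i in range(0, len(ordered) - chains_per_unit + 1, chains_per_unit)
        if len(ordered[i: i + chains_per_unit]) == chains_per_unit
    ]
    return units_from_chain_groups(model, groups)


def write_pdb(model: StructureModel, path) -> None:
    """Write a model as PDB; filament unit index is encoded in chain names."""
    import gemmi

    st = gemmi.Structure()
    st.name = "filaquant"
    md = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    for i in range(len(model)):
        cname = str(model.chains[i])[:2]
        if cname not in chain_map:
            chain_map[cname] = gemmi.Chain(cname)
        chain = chain_map[cname]
        res = gemmi.Residue()
        res.name = "PSA"
        res.seqid = gemmi.SeqId(len(chain) + 1, " ")
        atom = gemmi.Atom()
        atom.name = "C"
        atom.element = gemmi.Element(str(model.elements[i]))
        atom.pos = gemmi.Position(*model.coords[i])
        res.add_atom(atom)
        chain.add_residue(res)
    for chain in chain_map.values():
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))
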