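"""Binding-site geometry on protein--ligand coordinate models.

This module measures how well a guanylyltransferase binding pocket holds
its phospho-acid ligand: which protein atoms hydrogen-bond to the ligand,
how far each H-bond partner sits from the plane of the sp2 group it bonds
to (the out-of-pi-plane distortion), which residues contact the ligand
directly or through bridging waters / Mg2+ ions, and how two ligand poses
in a common frame differ (carboxylate rotation about the O--O axis, net
displacement of a chemical group).

Coordinates are in Angstrom throughout.  PDB reading/writing is backed by
:mod:`gemmi`; only the first MODEL of a multi-model file is retained and
alternate locations are resolved to the highest-occupancy conformer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptyStructureError,
    InsufficientPointsError,
    PDBParseError,
    SelectorError,
    SerializationError,
)

__all__ = [
    "Atom",
    "StructureModel",
    "PlanarGroup",
    "HBondGeometry",
    "ContactRecord",
    "Superposition",
    "RotationResult",
    "MetalSite",
    "read_pdb",
    "write_pdb",
    "fit_plane",
    "out_of_plane_distance",
    "detect_hbonds",
    "average_pi_distortion",
    "contact_table",
    "superpose_kabsch",
    "carboxylate_rotation",
    "group_displacement",
    "metal_coordination",
]

#: residue names treated as water when looking for bridging molecules
WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD"})

#: heavy-atom elements that can donate or accept an H-bond
HBOND_ELEMENTS = frozenset({"N", "O"})

#: default heavy-atom donor--acceptor distance window (Angstrom)
DEFAULT_HBOND_WINDOW = (2.4, 3.5)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom of a coordinate model (PDB conventions, Angstrom)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    chain: str
    res_name: str
    res_num: int
    insertion_code: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    is_hetero: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    def key(self) -> tuple:
        return (self.chain, self.res_num, self.insertion_code, self.name)


@dataclass
class StructureModel:
    """An ordered atom collection (first MODEL only, alt-locs resolved)."""

    atoms: list[Atom]
    title: str = ""
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def select(self, chain=None, res_name=None, res_num=None) -> list[Atom]:
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if res_name is not None and a.res_name != res_name:
                continue
            if res_num is not None and a.res_num != res_num:
                continue
            out.append(a)
        return out

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)


@dataclass
class PlanarGroup:
    """A least-squares plane through an sp2 group (unit normal, centroid)."""

    group_kind: str           # carboxylate | peptide_amide | guanine_ring | custom
    normal: np.ndarray        # unit 3-vector
    centroid: np.ndarray      # Angstrom
    rms_residual: float       # RMS point-to-plane distance, Angstrom
    member_atoms: list[Atom] = field(default_factory=list)


@dataclass
class HBondGeometry:
    """A donor--acceptor pair, optionally with its pi-plane distortion."""

    donor: Atom
    acceptor: Atom
    heavy_distance: float
    pi_group: PlanarGroup | None = None
    pi_distance: float | None = None
    partner_role: str | None = None   # donor_is_partner | acceptor_is_partner


@dataclass
class ContactRecord:
    """A protein-atom-to-ligand-atom interaction averaged over chains."""

    protein_residue: tuple[str, str, int]   # (chain label, res_name, res_num)
    protein_atom: str
    ligand_atom: str
    per_chain_distances: dict[str, float]
    mean_distance: float
    bridged_via: str                        # direct | water | magnesium


@dataclass
class Superposition:
    """An optimal rigid motion ``x -> R x + t`` with its residual RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int
    stable: bool = True

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RotationResult:
    """Unsigned rotation of a reference atom about the carboxylate O--O axis."""

    axis: np.ndarray
    angle_deg: float
    reference_atom: str


@dataclass
class MetalSite:
    """One metal ion and the N/O atoms coordinating it."""

    metal: Atom
    coordinating: list[tuple[Atom, float, str]]   # (atom, distance, source)


# ---------------------------------------------------------------------------
# PDB input / output (gemmi-backed)
# ---------------------------------------------------------------------------

def _validate_pdb_text(text: str) -> int:
    """Check fixed-column coordinate records; return their count.

    Raises :class:`PDBParseError` naming the offending 1-based line.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: coordinate record shorter than 54 columns")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed coordinate field ({exc})") from exc
        n += 1
    return n


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy alternate; ties go to the earliest letter."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        k = a.key()
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, b.alt_loc or "~") > (b.occupancy, a.alt_loc or "~"):
                # higher occupancy wins; on an exact occupancy tie the
                # lexicographically earlier alt-loc ('' < 'A' < 'B') wins
                best[k] = a
    return [best[k] for k in order]


def read_pdb(text: str) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is kept; alternate locations are resolved to the
    highest-occupancy conformer (ties: earliest alt-loc letter).
    """
    if _validate_pdb_text(text) == 0:
        raise EmptyStructureError("no ATOM or HETATM records found")
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise EmptyStructureError("no coordinate model could be built")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                alt = at.altloc if at.altloc not in ("", "\x00") else ""
                icode = res.seqid.icode.strip()
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name,
                    alt_loc=alt,
                    chain=chain.name,
                    res_name=res.name,
                    res_num=res.seqid.num,
                    insertion_code=icode,
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    occupancy=at.occ,
                    is_hetero=(res.het_flag == "H"),
                ))
    atoms = _resolve_altlocs(atoms)
    if not atoms:
        raise EmptyStructureError("structure contains zero atoms")
    return StructureModel(atoms=atoms, title=st.name or "", source_id=st.name or "")


def write_pdb(model: StructureModel) -> str:
    """Serialize a model to fixed-column PDB text (3-decimal coordinates)."""
    if not model.atoms:
        raise EmptyStructureError("cannot write an empty structure")
    for a in model.atoms:
        if len(a.name) > 4:
            raise SerializationError(f"atom name {a.name!r} exceeds 4 characters")
    st = gemmi.Structure()
    st.name = model.title or model.source_id or "cofkit"
    gmodel = gemmi.Model("1")
    cur_chain = None
    cur_res = None
    cur_res_key = None
    for a in model.atoms:
        if cur_chain is None or cur_chain.name != a.chain:
            cur_chain = gemmi.Chain(a.chain)
            gmodel.add_chain(cur_chain)
            cur_chain = gmodel[-1]
            cur_res_key = None
        res_key = (a.res_name, a.res_num, a.insertion_code)
        if res_key != cur_res_key:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_num, a.insertion_code or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            cur_chain.add_residue(res)
            cur_res = cur_chain[-1]
            cur_res_key = res_key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.altloc = a.alt_loc or "\x00"
        at.pos = gemmi.Position(*a.coords)
        at.occ = a.occupancy
        at.b_iso = 0.0
        at.serial = a.serial
        cur_res.add_atom(at)
    st.add_model(gmodel)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# planes and out-of-plane distances
# ---------------------------------------------------------------------------

def fit_plane(points: Sequence, group_kind: str = "custom",
              member_atoms: list[Atom] | None = None) -> PlanarGroup:
    """Total-least-squares plane through >= 3 non-collinear points.

    The normal is the singular direction of smallest variance of the
    centered points; ``rms_residual`` is the RMS point-to-plane distance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise InsufficientPointsError("plane fit requires >= 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(float(s[0]), 1.0)
    if s[1] < 1e-9 * scale:
        raise DegenerateGeometryError("points are collinear or coincident")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    residual = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    if residual < 1e-9:
        residual = 0.0
    return PlanarGroup(group_kind=group_kind, normal=normal, centroid=centroid,
                       rms_residual=residual, member_atoms=member_atoms or [])


def out_of_plane_distance(plane: PlanarGroup, point: Sequence[float]) -> float:
    """Unsigned distance from ``point`` to the plane (Angstrom)."""
    p = np.asarray(point, dtype=float)
    return float(abs((p - plane.centroid) @ plane.normal))


# ---------------------------------------------------------------------------
# sp2 group discovery
# ---------------------------------------------------------------------------

def _find_carboxylates(atoms: Sequence[Atom]) -> list[list[Atom]]:
    """Geometric carboxylate detection within one residue's atoms.

    A carboxylate is a carbon with exactly two oxygens within 1.4 A plus at
    least one carbon neighbour within 1.75 A; the group used for the plane
    is {C, O, O, attached C}.
    """
    groups = []
    carbons = [a for a in atoms if a.element.upper() == "C"]
    for c in carbons:
        oxy = [a for a in atoms if a.element.upper() == "O"
               and 0.0 < np.linalg.norm(a.xyz - c.xyz) <= 1.40]
        if len(oxy) != 2:
            continue
        attached = [a for a in carbons if a is not c
                    and np.linalg.norm(a.xyz - c.xyz) <= 1.75]
        if not attached:
            continue
        groups.append([c, *oxy, attached[0]])
    return groups


def _peptide_amide_group(model: StructureModel, atom: Atom) -> list[Atom] | None:
    """Backbone amide plane atoms for a backbone N or O H-bond partner.

    For a carbonyl O of residue i the plane is {CA_i, C_i, O_i, N_{i+1}};
    for an amide N of residue i it is {CA_{i-1}, C_{i-1}, O_{i-1}, N_i}.
    Returns ``None`` when flanking atoms are absent (chain terminus).
    """
    def get(res_num: int, name: str) -> Atom | None:
        for a in model.atoms:
            if (a.chain == atom.chain and a.res_num == res_num
                    and a.name == name and not a.is_hetero):
                return a
        return None

    if atom.name == "O":
        members = [get(atom.res_num, "CA"), get(atom.res_num, "C"),
                   atom, get(atom.res_num + 1, "N")]
    elif atom.name == "N":
        members = [get(atom.res_num - 1, "CA"), get(atom.res_num - 1, "C"),
                   get(atom.res_num - 1, "O"), atom]
    else:
        return None
    if any(m is None for m in members):
        return None
    return members  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# H-bond detection and the distortion statistic
# ---------------------------------------------------------------------------

def _assign_donor_acceptor(lig: Atom, partner: Atom) -> tuple[Atom, Atom]:
    """Heuristic donor/acceptor assignment on heavy atoms (no hydrogens).

    A lone nitrogen is taken as the donor; for O...O pairs the
    protein/water side is treated as the donor.  The assignment is a
    labelling convention only -- detection and the pi-plane statistic are
    symmetric in it.
    """
    le, pe = lig.element.upper(), partner.element.upper()
    if le == "N" and pe != "N":
        return lig, partner
    if pe == "N" and le != "N":
        return partner, lig
    return partner, lig


def detect_hbonds(model: StructureModel,
                  ligand_selector: tuple[str, str, int],
                  max_heavy_distance: float = DEFAULT_HBOND_WINDOW[1],
                  min_heavy_distance: float = DEFAULT_HBOND_WINDOW[0]) -> list[HBondGeometry]:
    """Enumerate ligand--protein/water H-bonds on heavy atoms.

    A pair qualifies when one N/O atom belongs to the selected ligand, the
    other to the protein or a water, and the heavy-atom distance lies in
    ``[min_heavy_distance, max_heavy_distance]``.  When the ligand side
    belongs to a carboxylate, or the protein side is a backbone amide N/O,
    the sp2 plane is fitted and ``pi_distance`` records how far the
    *partner* atom (the atom H-bonding to that plane) sits out of it.
    """
    chain, res_name, res_num = ligand_selector
    lig_atoms = model.select(chain=chain, res_name=res_name, res_num=res_num)
    if not lig_atoms:
        raise SelectorError(f"ligand {ligand_selector} not found in model")
    lig_ids = {id(a) for a in lig_atoms}
    carboxylates = _find_carboxylates(lig_atoms)

    partners = [a for a in model.atoms
                if id(a) not in lig_ids
                and a.element.upper() in HBOND_ELEMENTS
                and (not a.is_hetero or a.is_water)]
    out: list[HBondGeometry] = []
    for la in lig_atoms:
        if la.element.upper() not in HBOND_ELEMENTS:
            continue
        for pa in partners:
            d = float(np.linalg.norm(la.xyz - pa.xyz))
            if not (min_heavy_distance <= d <= max_heavy_distance):
                continue
            donor, acceptor = _assign_donor_acceptor(la, pa)
            pi_group = None
            pi_distance = None
            partner_role = None
            group = next((g for g in carboxylates if any(m is la for m in g)), None)
            if group is not None:
                pi_group = fit_plane([m.xyz for m in group], "carboxylate", group)
                pi_distance = out_of_plane_distance(pi_group, pa.xyz)
                partner_atom = pa
            else:
                members = None
                if not pa.is_hetero:
                    members = _peptide_amide_group(model, pa)
                if members is not None:
                    pi_group = fit_plane([m.xyz for m in members], "peptide_amide", members)
                    pi_distance = out_of_plane_distance(pi_group, la.xyz)
                    partner_atom = la
            if pi_group is not None:
                partner_role = ("donor_is_partner" if partner_atom is donor
                                else "acceptor_is_partner")
            out.append(HBondGeometry(donor=donor, acceptor=acceptor,
                                     heavy_distance=d, pi_group=pi_group,
                                     pi_distance=pi_distance,
                                     partner_role=partner_role))
    out.sort(key=lambda h: (h.acceptor.chain, h.acceptor.res_num, h.acceptor.name,
                            h.donor.chain, h.donor.res_num, h.donor.name))
    return out


def average_pi_distortion(hbonds: Iterable[HBondGeometry]) -> float:
    """Arithmetic mean of the out-of-pi-plane distances (Angstrom).

    H-bonds without a fitted sp2 plane are excluded; an empty qualifying
    set is an error rather than a silent 0.
    """
    vals = [h.pi_distance for h in hbonds if h.pi_distance is not None]
    if not vals:
        raise SelectorError("no H-bond in the set carries a pi-plane distance")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# contact table
# ---------------------------------------------------------------------------

def contact_table(model: StructureModel, ligand_res_name: str,
                  cutoff: float = 4.0, bridge_cutoff: float = 3.5) -> list[ContactRecord]:
    """Protein--ligand contacts averaged over every chain holding the ligand.

    Direct contacts are protein-atom/ligand-atom pairs within ``cutoff``.
    Bridged contacts run through a water oxygen or Mg2+ ion that is within
    ``bridge_cutoff`` of both sides; their recorded distance is the
    protein-atom-to-bridge distance.  Records are keyed by
    (residue, protein atom, ligand atom) and averaged across chains where
    the contact exists; output order is (res_num, protein_atom, ligand_atom).
    """
    lig_chains = sorted({a.chain for a in model.atoms
                         if a.res_name == ligand_res_name})
    if not lig_chains:
        raise SelectorError(f"ligand residue {ligand_res_name!r} absent from model")

    # key -> {chain: (distance, kind)}
    table: dict[tuple, dict[str, tuple[float, str]]] = {}
    resnames: dict[tuple, str] = {}

    def put(key, chain, dist, kind):
        entry = table.setdefault(key, {})
        old = entry.get(chain)
        # direct beats bridged; otherwise keep the shortest distance
        rank = {"direct": 0, "magnesium": 1, "water": 2}
        if old is None or (rank[kind], dist) < (rank[old[1]], old[0]):
            entry[chain] = (dist, kind)

    for ch in lig_chains:
        lig_atoms = [a for a in model.atoms
                     if a.chain == ch and a.res_name == ligand_res_name]
        prot_atoms = [a for a in model.atoms if a.chain == ch and not a.is_hetero]
        bridges = [a for a in model.atoms if a.chain == ch and a.is_hetero
                   and (a.is_water or a.element.upper() == "MG")
                   and a.res_name != ligand_res_name]
        for pa in prot_atoms:
            for la in lig_atoms:
                d = float(np.linalg.norm(pa.xyz - la.xyz))
                if d <= cutoff:
                    key = (pa.res_num, pa.name, la.name)
                    resnames[key] = pa.res_name
                    put(key, ch, d, "direct")
        for br in bridges:
            kind = "magnesium" if br.element.upper() == "MG" else "water"
            near_lig = [la for la in lig_atoms
                        if np.linalg.norm(br.xyz - la.xyz) <= bridge_cutoff]
            if not near_lig:
                continue
            for pa in prot_atoms:
                d = float(np.linalg.norm(pa.xyz - br.xyz))
                if d > bridge_cutoff:
                    continue
                for la in near_lig:
                    key = (pa.res_num, pa.name, la.name)
                    resnames.setdefault(key, pa.res_name)
                    put(key, ch, d, kind)

    records: list[ContactRecord] = []
    for key in sorted(table):
        res_num, patom, latom = key
        per_chain = {ch: d for ch, (d, _) in sorted(table[key].items())}
        kinds = {k for _, k in table[key].values()}
        kind = "direct" if "direct" in kinds else (
            "magnesium" if "magnesium" in kinds else "water")
        chain_label = ",".join(sorted(table[key]))
        records.append(ContactRecord(
            protein_residue=(chain_label, resnames[key], res_num),
            protein_atom=patom, ligand_atom=latom,
            per_chain_distances=per_chain,
            mean_distance=float(np.mean(list(per_chain.values()))),
            bridged_via=kind))
    return records


# ---------------------------------------------------------------------------
# superposition and pose comparison
# ---------------------------------------------------------------------------

def superpose_kabsch(ref: np.ndarray, mov: np.ndarray) -> Superposition:
    """Optimal proper-rotation least-squares superposition (Kabsch).

    Finds ``R, t`` minimising ``sum ||R m_i + t - r_i||^2`` with
    ``det(R) = +1`` (reflections excluded).  Near-collinear point sets are
    solved but flagged ``stable=False`` with a warning.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise InsufficientPointsError("ref and mov must be matching n x 3 arrays")
    n = ref.shape[0]
    if n < 3:
        raise InsufficientPointsError("superposition requires >= 3 paired atoms")
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    p = mov - cm
    q = ref - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    stable = True
    sq = np.linalg.svd(q, compute_uv=False)
    if sq[1] < 1e-8 * max(sq[0], 1.0):
        stable = False
        warnings.warn("collinear point set: superposition is not unique",
                      RuntimeWarning, stacklevel=2)
    t = cr - rot @ cm
    moved = mov @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=t, rmsd=rmsd,
                         n_atoms=n, stable=stable)


def _coords_by_name(atoms: Sequence[Atom] | Mapping[str, Sequence[float]],
                    name: str) -> np.ndarray:
    if isinstance(atoms, Mapping):
        if name not in atoms:
            raise SelectorError(f"atom {name!r} absent from ligand")
        return np.asarray(atoms[name], dtype=float)
    for a in atoms:
        if a.name == name:
            return a.xyz
    raise SelectorError(f"atom {name!r} absent from ligand")


def carboxylate_rotation(lig_a, lig_b,
                         oxygen_names: tuple[str, str] = ("O1", "O2"),
                         reference_atom: str = "C2") -> RotationResult:
    """Unsigned rotation of ``reference_atom`` about the carboxylate O--O axis.

    Both ligand poses must already sit in a common frame (protein
    superposed).  The axis is the O->O direction averaged over the two
    poses after sign alignment; the angle is measured between the
    projections, onto the plane normal to that axis, of the vectors from
    the O--O midpoint to the reference atom.  Result in [0, 180] degrees.
    """
    o1a = _coords_by_name(lig_a, oxygen_names[0])
    o2a = _coords_by_name(lig_a, oxygen_names[1])
    o1b = _coords_by_name(lig_b, oxygen_names[0])
    o2b = _coords_by_name(lig_b, oxygen_names[1])
    ra = _coords_by_name(lig_a, reference_atom)
    rb = _coords_by_name(lig_b, reference_atom)

    axis_a = o2a - o1a
    axis_b = o2b - o1b
    na, nb = np.linalg.norm(axis_a), np.linalg.norm(axis_b)
    if na < 1e-6 or nb < 1e-6:
        raise DegenerateGeometryError("carboxylate oxygens coincide")
    axis_a /= na
    axis_b /= nb
    if axis_a @ axis_b < 0:
        axis_b = -axis_b
    axis = axis_a + axis_b
    axis /= np.linalg.norm(axis)

    def projected(ref, o1, o2):
        v = ref - (o1 + o2) / 2.0
        p = v - (v @ axis) * axis
        if np.linalg.norm(p) < 1e-6:
            raise DegenerateGeometryError("reference atom lies on the O--O axis")
        return p / np.linalg.norm(p)

    pa = projected(ra, o1a, o2a)
    pb = projected(rb, o1b, o2b)
    angle = math.degrees(math.acos(float(np.clip(pa @ pb, -1.0, 1.0))))
    return RotationResult(axis=axis, angle_deg=angle, reference_atom=reference_atom)


def group_displacement(lig_a, lig_b, atom_selector: str) -> float:
    """Euclidean displacement of one named atom between two poses (Angstrom)."""
    a = _coords_by_name(lig_a, atom_selector)
    b = _coords_by_name(lig_b, atom_selector)
    return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# metal coordination
# ---------------------------------------------------------------------------

def metal_coordination(model: StructureModel, metal_element: str = "MG",
                       coordination_cutoff: float = 2.8) -> list[MetalSite]:
    """List N/O atoms coordinating each ion of ``metal_element``.

    Coordinating atoms are annotated with their distance and source
    category (``protein``, ``ligand`` or ``water``) and sorted by distance.
    An absent metal yields an empty list, not an error.
    """
    target = metal_element.upper()
    sites: list[MetalSite] = []
    for m in model.atoms:
        if m.element.upper() != target:
            continue
        coord = []
        for a in model.atoms:
            if a is m or a.element.upper() not in HBOND_ELEMENTS:
                continue
            d = float(np.linalg.norm(a.xyz - m.xyz))
            if d > coordination_cutoff:
                continue
            source = ("water" if a.is_water
                      else ("ligand" if a.is_hetero else "protein"))
            coord.append((a, d, source))
        coord.sort(key=lambda t: (t[1], t[0].serial))
        sites.append(MetalSite(metal=m, coordinating=coord))
    sites.sort(key=lambda s: (s.metal.chain, s.metal.res_num, s.metal.serial))
    return sites
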