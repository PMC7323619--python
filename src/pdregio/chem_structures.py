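"""Substrates, aromatic C-H sites, conformers, and seed geometries of the
Pd(OAc)2 intermediates.

Two intermediate templates are built per aromatic C-H site, one for each
candidate mechanism:

* SEAr (electrophilic aromatic substitution): a Wheland-type ipso complex.
  Pd sits above the site carbon along the local ring normal at 2.1 A, the
  carbon is pyramidalised, and its hydrogen is retained, pushed to the face
  opposite Pd.
* PA (proton abstraction / concerted metalation-deprotonation): Pd
  approaches the same carbon at 2.1 A while one acetate oxygen is oriented
  toward the site hydrogen at <= 2.0 A, poised to accept the proton.

These are seed geometries only; they exist to give a quantum-chemistry
optimiser a sensible starting point, not to be minima themselves.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import DomainError, InputError

GeometryAtom = tuple[str, float, float, float]
Geometry = list[GeometryAtom]

#: atoms added by the Pd(OAc)2 fragment: Pd + 2 x CH3COO (7 atoms each)
PD_FRAGMENT_ATOMS = 15

#: initial Pd-C seed distance (A); near typical optimised Pd(II)-aryl bonds
PD_C_SEED = 2.1

#: any non-bonded pair closer than this (A) marks a steric clash
CLASH_DISTANCE = 0.7


class Mechanism(str, enum.Enum):
    """Candidate C-H activation mechanisms."""

    PA = "PA"
    SEAR = "SEAR"


class Status(str, enum.Enum):
    RAW = "RAW"
    PRESCREENED = "PRESCREENED"
    OPTIMIZED = "OPTIMIZED"
    DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class AromaticSite:
    """One symmetry-unique aromatic C-H position.

    ``atom_index`` refers to the substrate's hydrogen-explicit molecule;
    ``h_label`` ("H1", "H2", ...) is assigned in canonical atom order and is
    therefore invariant to the input atom numbering.
    """

    atom_index: int
    h_label: str
    ring_id: int


@dataclass
class Conformer:
    """A 3D embedding of the substrate, ranked by force-field energy.

    ``ff_energy`` (kcal/mol) is heuristic and used only to order conformers.
    """

    coordinates: Geometry
    ff_energy: float
    substrate: "Substrate"
    index: int = 0


@dataclass
class Substrate:
    """A parsed input molecule with perceived aromaticity and explicit H."""

    id: str
    name: str
    mol: Chem.Mol
    source_text: str

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()


@dataclass
class Intermediate:
    """One Pd(OAc)2-substrate complex (mechanism x site x conformer)."""

    substrate_id: str
    site: AromaticSite
    mechanism: Mechanism
    conformer_index: int
    geometry: Optional[Geometry]
    status: Status = Status.RAW
    electronic_energy: Optional[float] = None  # Hartree
    gibbs_energy: Optional[float] = None  # Hartree
    pd_c_distance: Optional[float] = None  # A
    imaginary_freqs: list[float] = field(default_factory=list)  # cm^-1 magnitudes
    discard_reason: Optional[str] = None

    def discard(self, reason: str) -> None:
        self.status = Status.DISCARDED
        self.discard_reason = reason

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.substrate_id, self.mechanism.value, self.site.h_label)


def _looks_like_molblock(text: str) -> bool:
    return "V2000" in text or "V3000" in text or text.count("\n") >= 3


def parse_substrate(text: str, id: str, name: str = "") -> Substrate:
    """Parse a SMILES string or MOL block into a :class:`Substrate`.

    Aromaticity is perceived and hydrogens are made explicit. A molecule
    without an aromatic ring is rejected: the pipeline only enumerates
    aromatic C-H sites.
    """
    text = text.rstrip("\n") if _looks_like_molblock(text) else text.strip()
    if not text:
        raise InputError(f"substrate {id!r}: empty structure input")
    if _looks_like_molblock(text):
        mol = Chem.MolFromMolBlock(text, sanitize=True)
        if mol is None:
            raise InputError(f"substrate {id!r}: unparseable MOL block")
    else:
        mol = Chem.MolFromSmiles(text, sanitize=True)
        if mol is None:
            raise InputError(f"substrate {id!r}: unparseable SMILES {text!r}")
    mol = Chem.AddHs(mol)
    Chem.SetAromaticity(mol)
    if not any(a.GetIsAromatic() for a in mol.GetAtoms()):
        raise DomainError(f"substrate {id!r}: no aromatic C-H sites (no aromatic ring)")
    return Substrate(id=id, name=name or id, mol=mol, source_text=text)


def enumerate_ch_sites(s: Substrate) -> list[AromaticSite]:
    """Enumerate symmetry-unique aromatic C-H positions.

    One site per aromatic carbon carrying exactly one hydrogen; carbons with
    identical canonical symmetry ranks are collapsed to a single
    representative (benzene yields one site). Labels H1..Hn follow canonical
    rank order, so they are stable under permutations of the input atoms.
    """
    mol = s.mol
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    ring_info = mol.GetRingInfo()

    def ring_id_of(idx: int) -> int:
        for rid, ring in enumerate(ring_info.AtomRings()):
            if idx in ring:
                return rid
        return -1

    by_rank: dict[int, int] = {}
    for atom in mol.GetAtoms():
        if not (atom.GetIsAromatic() and atom.GetSymbol() == "C"):
            continue
        h_neighbors = [n for n in atom.GetNeighbors() if n.GetSymbol() == "H"]
        if len(h_neighbors) != 1:
            continue
        rank = ranks[atom.GetIdx()]
        # keep the lowest atom index as the class representative
        if rank not in by_rank or atom.GetIdx() < by_rank[rank]:
            by_rank[rank] = atom.GetIdx()

    sites = []
    for n, rank in enumerate(sorted(by_rank), start=1):
        idx = by_rank[rank]
        sites.append(AromaticSite(atom_index=idx, h_label=f"H{n}", ring_id=ring_id_of(idx)))
    return sites


def generate_conformers(s: Substrate, max_n: int, seed: int) -> list[Conformer]:
    """Embed up to ``max_n`` distinct 3D conformers, lowest energy first.

    Distance-geometry embedding (ETKDG) with RMSD pruning, ranked by MMFF94
    (UFF fallback) energy. Deterministic for a given seed.
    """
    if max_n < 1:
        raise InputError(f"max_n must be >= 1, got {max_n}")
    mol = Chem.Mol(s.mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = 0.5
    params.useRandomCoords = False
    conf_ids = AllChem.EmbedMultipleConfs(mol, numConfs=max_n, params=params)
    if len(conf_ids) == 0:
        raise DomainError(f"substrate {s.id!r}: 3D embedding failed")

    energies: list[tuple[float, int]] = []
    mmff_props = AllChem.MMFFGetMoleculeProperties(mol)
    for cid in conf_ids:
        energy = 0.0
        ff = None
        if mmff_props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(mol, mmff_props, confId=cid)
        if ff is None:
            ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
        if ff is not None:
            ff.Minimize(maxIts=200)
            energy = float(ff.CalcEnergy())
        energies.append((energy, cid))
    energies.sort(key=lambda t: (t[0], t[1]))

    conformers = []
    for i, (energy, cid) in enumerate(energies):
        conf = mol.GetConformer(cid)
        coords: Geometry = []
        for atom in mol.GetAtoms():
            p = conf.GetAtomPosition(atom.GetIdx())
            coords.append((atom.GetSymbol(), round(p.x, 4), round(p.y, 4), round(p.z, 4)))
        conformers.append(Conformer(coordinates=coords, ff_energy=energy, substrate=s, index=i))
    return conformers


# ---------------------------------------------------------------------------
# Pd(OAc)2 template construction


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _any_perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(_unit(v), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def _acetate(o1: np.ndarray, out_dir: np.ndarray, perp_hint: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Idealised acetate (CH3COO) anchored at its coordinating oxygen ``o1``,
    extending along ``out_dir``. 7 atoms: O, C, O, C, H, H, H."""
    out = _unit(out_dir)
    p = perp_hint - np.dot(perp_hint, out) * out
    p = _any_perp(out) if np.linalg.norm(p) < 1e-6 else _unit(p)

    c1 = o1 + 1.27 * out
    ang_o = math.radians(124.0)
    o2 = c1 + 1.25 * (math.cos(ang_o) * (-out) + math.sin(ang_o) * p)
    ang_c = math.radians(118.0)
    c2 = c1 + 1.50 * (math.cos(ang_c) * (-out) - math.sin(ang_c) * p)

    axis = _unit(c2 - c1)
    w1 = p - np.dot(p, axis) * axis
    w1 = _any_perp(axis) if np.linalg.norm(w1) < 1e-6 else _unit(w1)
    w2 = np.cross(axis, w1)
    tet = math.radians(109.47)
    hs = []
    for phi in (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0):
        d = math.cos(tet) * (-axis) + math.sin(tet) * (math.cos(phi) * w1 + math.sin(phi) * w2)
        hs.append(c2 + 1.09 * d)
    return [("O", o1), ("C", c1), ("O", o2), ("C", c2), ("H", hs[0]), ("H", hs[1]), ("H", hs[2])]


def _site_frame(c: Conformer, site: AromaticSite) -> tuple[np.ndarray, int, np.ndarray, np.ndarray]:
    """Return (coords array, H index, ring normal, in-plane C->H direction)
    for the site carbon. The normal sign points to the less crowded face."""
    s = c.substrate
    atom = s.mol.GetAtomWithIdx(site.atom_index)
    if not (atom.GetIsAromatic() and atom.GetSymbol() == "C"):
        raise InputError(
            f"site atom {site.atom_index} of {s.id!r} is not an aromatic carbon"
        )
    h_neighbors = [n.GetIdx() for n in atom.GetNeighbors() if n.GetSymbol() == "H"]
    if len(h_neighbors) != 1:
        raise InputError(f"site atom {site.atom_index} of {s.id!r} does not bear exactly one H")
    ring_neighbors = [n.GetIdx() for n in atom.GetNeighbors() if n.GetIsAromatic()]
    if len(ring_neighbors) < 2:
        raise InputError(f"site atom {site.atom_index} of {s.id!r} has no two aromatic neighbours")

    xyz = np.array([[x, y, z] for _, x, y, z in c.coordinates], dtype=float)
    cpos = xyz[site.atom_index]
    r1, r2 = xyz[ring_neighbors[0]] - cpos, xyz[ring_neighbors[1]] - cpos
    normal = _unit(np.cross(r1, r2))
    # choose the face with more clearance for the metal fragment
    others = np.delete(xyz, site.atom_index, axis=0)
    def clearance(n):
        probe = cpos + PD_C_SEED * n
        return float(np.min(np.linalg.norm(others - probe, axis=1)))
    if clearance(-normal) > clearance(normal):
        normal = -normal
    h_dir = _unit(xyz[h_neighbors[0]] - cpos)
    return xyz, h_neighbors[0], normal, h_dir


def _has_clash(xyz: np.ndarray) -> bool:
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    iu = np.triu_indices(len(xyz), k=1)
    return bool(np.any(d[iu] < CLASH_DISTANCE))


def build_intermediate(c: Conformer, site: AromaticSite, mech: Mechanism) -> Intermediate:
    """Attach the Pd(OAc)2 fragment to one aromatic C-H site.

    Returns a RAW intermediate, or a DISCARDED one (reason "clash") if the
    placement leaves any two atoms closer than 0.7 A.
    """
    s = c.substrate
    xyz, h_idx, normal, h_dir = _site_frame(c, site)
    cpos = xyz[site.atom_index].copy()
    coords = [list(t) for t in c.coordinates]

    if mech is Mechanism.SEAR:
        pd = cpos + PD_C_SEED * normal
        # pyramidalise: push the retained H to the face opposite Pd
        new_h = cpos + 1.09 * _unit(h_dir - 0.45 * normal)
        coords[h_idx][1:] = [float(v) for v in new_h]
        axis = _unit(pd - cpos)
        u = h_dir - np.dot(h_dir, axis) * axis
        u = _any_perp(axis) if np.linalg.norm(u) < 1e-6 else _unit(u)
        o_a = pd + 2.0 * _unit(0.6 * axis + u)
        o_b = pd + 2.0 * _unit(0.6 * axis - u)
        frag = [("Pd", pd)]
        frag += _acetate(o_a, _unit(o_a - pd), np.cross(axis, u))
        frag += _acetate(o_b, _unit(o_b - pd), np.cross(axis, u))
    else:  # PA: acetate oxygen poised to abstract the site hydrogen
        pd = cpos + PD_C_SEED * _unit(normal + 0.45 * h_dir)
        hpos = np.array(coords[h_idx][1:], dtype=float)
        # abstracting O on the intersection of spheres around Pd (2.05 A)
        # and the site H (1.85 A)
        r_po, r_ho = 2.05, 1.85
        dvec = hpos - pd
        d = float(np.linalg.norm(dvec))
        ex = _unit(dvec)
        a_len = (r_po**2 - r_ho**2 + d**2) / (2.0 * d)
        rad = r_po**2 - a_len**2
        perp = normal - np.dot(normal, ex) * ex
        perp = _any_perp(ex) if np.linalg.norm(perp) < 1e-6 else _unit(perp)
        if rad > 0:
            o_a = pd + a_len * ex + math.sqrt(rad) * perp
        else:  # spheres disjoint: fall back to the Pd->H line
            o_a = pd + r_po * ex
        axis = _unit(pd - cpos)
        o_b = pd + 2.0 * axis  # second acetate trans to the aryl carbon
        frag = [("Pd", pd)]
        frag += _acetate(o_a, _unit(o_a - 0.5 * (pd + hpos)), perp)
        frag += _acetate(o_b, axis, perp)

    geometry: Geometry = [
        (el, round(float(x), 4), round(float(y), 4), round(float(z), 4))
        for el, x, y, z in coords
    ] + [
        (el, round(float(p[0]), 4), round(float(p[1]), 4), round(float(p[2]), 4))
        for el, p in frag
    ]
    inter = Intermediate(
        substrate_id=s.id,
        site=site,
        mechanism=mech,
        conformer_index=c.index,
        geometry=geometry,
    )
    full = np.array([[x, y, z] for _, x, y, z in geometry], dtype=float)
    if _has_clash(full):
        inter.discard("clash")
    return inter


def build_all_intermediates(conformers: Sequence[Conformer], sites: Sequence[AromaticSite]) -> list[Intermediate]:
    """Both mechanisms for every (conformer, site) pair."""
    out = []
    for conf in conformers:
        for site in sites:
            for mech in (Mechanism.PA, Mechanism.SEAR):
                out.append(build_intermediate(conf, site, mech))
    return out


def write_xyz(intermediates: Sequence[Intermediate], path: str) -> None:
    """Multi-record XYZ; the comment line encodes substrate/site/mechanism."""
    with open(path, "w") as fh:
        for i in intermediates:
            if i.geometry is None:
                continue
            fh.write(f"{len(i.geometry)}\n")
            fh.write(f"{i.substrate_id} {i.site.h_label} {i.mechanism.value} conf{i.conformer_index}\n")
            for el, x, y, z in i.geometry:
                fh.write(f"{el:<3s} {x:12.4f} {y:12.4f} {z:12.4f}\n")
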