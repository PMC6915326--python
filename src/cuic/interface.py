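"""Protein-rRNA interface-index from a ribosome (or toy) complex structure.

For each ribosomal protein chain the interface-index is the fraction of its
resolved residues that interface the partner rRNA chains.  Two interface
criteria are provided:

``dsasa``
    A residue is interfacial when its solvent-accessible surface area drops
    by more than ``dsasa_cut`` (default 1.0 A^2) between the isolated chain
    and the chain in complex with the rRNA partners.  SASA uses the
    Shrake-Rupley method (probe 1.4 A, 960 sphere points per atom, element
    radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / P 1.80 A).

``contact``
    A residue is interfacial when any of its heavy atoms lies within
    ``contact_cut`` (default 5.0 A) of any partner heavy atom.

Proteins with index > 0.6 (strict) are classed "penetrated" (core), the
rest "surface".  Small-subunit proteins are scored against 18S rRNA, large-
subunit proteins against the 5S, 5.8S and 28S rRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InputError

#: Van der Waals radii (A) by element; hydrogens are ignored entirely.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960
PENETRATED_CUT = 0.6


@dataclass
class Residue:
    residue_id: str
    residue_name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) float64


@dataclass
class ChainStructure:
    """One chain with heavy atoms only; molecule_class is 'protein' or 'rna'."""

    chain_id: str
    molecule_class: str
    residues: list[Residue]
    rp_name: str = ""
    subunit: str = ""

    def atom_coords(self) -> np.ndarray:
        if not self.residues:
            return np.empty((0, 3))
        return np.vstack([r.coords for r in self.residues])

    def atom_radii(self) -> np.ndarray:
        radii, bad = [], []
        for r in self.residues:
            for name, el in zip(r.atom_names, r.elements):
                if el not in VDW_RADII:
                    bad.append(f"{self.chain_id}/{r.residue_id}/{name} ({el})")
                else:
                    radii.append(VDW_RADII[el])
        if bad:
            raise InputError("unknown element for atoms: " + ", ".join(bad))
        return np.asarray(radii)

    def residue_atom_slices(self) -> list[slice]:
        slices, i = [], 0
        for r in self.residues:
            n = len(r.coords)
            slices.append(slice(i, i + n))
            i += n
        return slices


@dataclass
class InterfaceIndexResult:
    chain_id: str
    rp_name: str
    n_residues: int
    n_interface: int
    interface_residue_ids: frozenset[str] = field(repr=False, default=frozenset())

    @property
    def index(self) -> float:
        return self.n_interface / self.n_residues

    @property
    def structural_class(self) -> str:
        return "penetrated" if self.index > PENETRATED_CUT else "surface"


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


_UNIT_SPHERE = _sphere_points(N_SPHERE_POINTS)


def sasa_per_atom(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise InputError("need at least one atom")
    if not np.all(np.isfinite(coords)):
        raise InputError("non-finite atom coordinates")
    sphere = _UNIT_SPHERE if n_points == N_SPHERE_POINTS else _sphere_points(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + ext[i] * sphere
        neigh = tree.query_ball_point(coords[i], ext[i] + max_ext)
        neigh = [j for j in neigh if j != i]
        if neigh:
            d2 = np.sum(
                (pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2
            )
            buried = np.any(d2 < (ext[neigh] ** 2)[None, :], axis=1)
            n_acc = int(np.sum(~buried))
        else:
            n_acc = len(pts)
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * n_acc / len(pts)
    return areas


def sasa_per_residue(chain_atoms: ChainStructure, extra_coords=None,
                     extra_radii=None) -> np.ndarray:
    """Residue SASA of one chain, optionally in the context of extra atoms
    (whose own areas are discarded)."""
    coords = chain_atoms.atom_coords()
    radii = chain_atoms.atom_radii()
    n_own = len(coords)
    if extra_coords is not None and len(extra_coords):
        coords = np.vstack([coords, extra_coords])
        radii = np.concatenate([radii, extra_radii])
    per_atom = sasa_per_atom(coords, radii)[:n_own]
    return np.array([per_atom[s].sum() for s in chain_atoms.residue_atom_slices()])


# ---------------------------------------------------------------------------
# Interface residues and the interface-index
# ---------------------------------------------------------------------------

def interface_residues(
    chain: ChainStructure,
    partners: Sequence[ChainStructure],
    mode: str = "dsasa",
    dsasa_cut: float = 1.0,
    contact_cut: float = 5.0,
) -> set[str]:
    """Residue ids of ``chain`` that interface the partner chains."""
    if chain.molecule_class != "protein":
        raise InputError(f"chain {chain.chain_id} is not a protein chain")
    if not partners:
        raise InputError("empty partner set")
    for p in partners:
        if p.molecule_class != "rna":
            raise InputError(f"partner chain {p.chain_id} is not RNA")
    partner_coords = np.vstack([p.atom_coords() for p in partners])
    if mode == "contact":
        tree = cKDTree(partner_coords)
        out = set()
        for res in chain.residues:
            d, _ = tree.query(res.coords, k=1)
            if np.min(d) <= contact_cut:
                out.add(res.residue_id)
        return out
    if mode == "dsasa":
        partner_radii = np.concatenate([p.atom_radii() for p in partners])
        alone = sasa_per_residue(chain)
        in_complex = sasa_per_residue(chain, partner_coords, partner_radii)
        delta = alone - in_complex
        return {
            res.residue_id
            for res, d in zip(chain.residues, delta)
            if d > dsasa_cut
        }
    raise InputError(f"unknown interface mode {mode!r}")


def interface_index(
    chain: ChainStructure,
    partners: Sequence[ChainStructure],
    mode: str = "dsasa",
    dsasa_cut: float = 1.0,
    contact_cut: float = 5.0,
) -> InterfaceIndexResult:
    """Fraction of the chain's resolved residues that interface the rRNA."""
    resolved = [r for r in chain.residues if len(r.coords) > 0]
    if not resolved:
        raise InputError(f"chain {chain.chain_id} has no resolved residues")
    iface = interface_residues(chain, partners, mode, dsasa_cut, contact_cut)
    return InterfaceIndexResult(
        chain_id=chain.chain_id,
        rp_name=chain.rp_name or chain.chain_id,
        n_residues=len(resolved),
        n_interface=len(iface),
        interface_residue_ids=frozenset(iface),
    )


def ribosome_interface_table(
    chains: Sequence[ChainStructure],
    mode: str = "dsasa",
    dsasa_cut: float = 1.0,
    contact_cut: float = 5.0,
) -> pd.DataFrame:
    """Interface-index for every protein chain against the rRNA chains of its
    own subunit (SSU proteins vs 18S; LSU proteins vs 5S/5.8S/28S)."""
    rna_by_subunit: dict[str, list[ChainStructure]] = {}
    for c in chains:
        if c.molecule_class == "rna":
            rna_by_subunit.setdefault(c.subunit, []).append(c)
    rows = []
    for c in chains:
        if c.molecule_class != "protein":
            continue
        partners = rna_by_subunit.get(c.subunit, [])
        if not partners:
            raise InputError(
                f"no rRNA partner chains annotated for subunit {c.subunit!r}"
            )
        r = interface_index(c, partners, mode, dsasa_cut, contact_cut)
        rows.append(
            {
                "chain_id": r.chain_id,
                "rp_name": r.rp_name,
                "n_residues": r.n_residues,
                "n_interface": r.n_interface,
                "index": r.index,
                "class": r.structural_class,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Structure loading (PDB / mmCIF via gemmi) and the chain-role map
# ---------------------------------------------------------------------------

def _best_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: the highest-occupancy altloc."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def load_chain_structures(path, roles: Mapping[str, Mapping]) -> list[ChainStructure]:
    """Read a PDB/mmCIF file and build ChainStructure objects for the chains
    listed in ``roles`` (mapping chain_id -> dict with molecule_class and
    optionally rp_name, subunit).  Hydrogens and waters are dropped;
    alternate conformations resolve to the highest-occupancy atom."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    out = []
    for chain in model:
        role = roles.get(chain.name)
        if role is None:
            continue
        residues = []
        for res in chain:
            if res.is_water():
                continue
            names, elements, xyz = [], [], []
            for atom in _best_altloc(res):
                el = atom.element.name.upper()
                if el in ("H", "D"):
                    continue
                names.append(atom.name)
                elements.append(el)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if xyz:
                residues.append(
                    Residue(
                        residue_id=f"{res.seqid.num}{res.seqid.icode}".strip(),
                        residue_name=res.name,
                        atom_names=names,
                        elements=elements,
                        coords=np.asarray(xyz, dtype=float),
                    )
                )
        out.append(
            ChainStructure(
                chain_id=chain.name,
                molecule_class=str(role["molecule_class"]),
                residues=residues,
                rp_name=str(role.get("rp_name", "")),
                subunit=str(role.get("subunit", "")),
            )
        )
    return out


def read_roles(path) -> dict[str, dict]:
    """Chain-role TSV: chain_id, rp_name, molecule_class, subunit."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return df.set_index("chain_id").to_dict("index")


def transform_chains(
    chains: Iterable[ChainStructure],
    rotation: Optional[np.ndarray] = None,
    translation: Optional[np.ndarray] = None,
) -> list[ChainStructure]:
    """Rigid-body transform of a whole complex (used to check invariance)."""
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    out = []
    for c in chains:
        res = [
            Residue(r.residue_id, r.residue_name, list(r.atom_names),
                    list(r.elements), r.coords @ R.T + t)
            for r in c.residues
        ]
        out.append(
            ChainStructure(c.chain_id, c.molecule_class, res, c.rp_name, c.subunit)
        )
    return out
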