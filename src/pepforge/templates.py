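"""Residue topology and ideal-geometry templates.

Heavy-atom internal-coordinate (z-matrix) templates for the 20 standard
amino acids are derived automatically from the ideal coordinates of the
chemical component dictionary shipped with biotite.  Each side-chain atom
is placed from three previously placed reference atoms by bond length,
bond angle and torsion; torsions across freely rotatable, acyclic single
bonds are exposed as chi degrees of freedom.

Non-natural residues used by the stapled-peptide chemistry are defined by
hand: CBA (cyclobutylalanine, planar-ring approximation) and the two
hydrocarbon-staple residues S5A / R8A (alpha-methyl, alkenyl side chains,
modelled as saturated carbon chains closed by an explicit inter-residue
bond).

D-amino acids reuse the L template with every torsion negated, which
produces the exact mirror image under fixed bond lengths and angles.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np

from .geometry import bond_angle, bond_length, dihedral

# backbone ideal internal coordinates (Engh-Huber-like values)
BB_N_CA = 1.458
BB_CA_C = 1.525
BB_C_N = 1.329
BB_C_O = 1.231
BB_ANG_N_CA_C = 111.2
BB_ANG_CA_C_N = 116.2
BB_ANG_C_N_CA = 121.7
BB_ANG_CA_C_O = 120.8

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# PDB v3 residue names for D-amino acids (Gly is achiral)
L_TO_D = {
    "ALA": "DAL", "ARG": "DAR", "ASN": "DSG", "ASP": "DAS", "CYS": "DCY",
    "GLN": "DGN", "GLU": "DGL", "HIS": "DHI", "ILE": "DIL", "LEU": "DLE",
    "LYS": "DLY", "MET": "MED", "PHE": "DPN", "PRO": "DPR", "SER": "DSN",
    "THR": "DTH", "TRP": "DTR", "TYR": "DTY", "VAL": "DVA",
}
D_TO_L = {v: k for k, v in L_TO_D.items()}

# package-convention names for non-natural residues
NONNATURAL = {"CBA", "S5A", "R8A"}
# CBA has a D form in principle; staple residues come in fixed chirality
L_TO_D["CBA"] = "DCB"
D_TO_L["DCB"] = "CBA"


@dataclass(frozen=True)
class AtomEntry:
    """One side-chain atom of a z-matrix template.

    ``torsion_dof`` is ``None`` for a rigid placement, ``("chi", k)`` when
    the torsion is the k-th chi angle (1-based), or ``("chi", k, offset)``
    for a branch atom placed at a fixed offset from chi_k.
    """
    name: str
    element: str
    refs: tuple[str, str, str]
    bond: float
    angle: float
    torsion: float
    torsion_dof: tuple | None = None


@dataclass(frozen=True)
class ResidueTemplate:
    code: str
    one_letter: str | None
    side_chain: tuple[AtomEntry, ...]      # includes CB when present
    bonds: tuple[tuple[str, str], ...]     # heavy-atom intra-residue bonds
    n_chi: int
    alpha_methyl: bool = False             # alpha,alpha-disubstituted


_BACKBONE = ("N", "CA", "C", "O", "OXT")


def _ccd_sidechain_entries(code: str) -> tuple[list[AtomEntry], list, int]:
    import biotite.structure.info as info

    arr = info.residue(code)
    heavy = [i for i in range(arr.array_length())
             if arr.element[i] != "H" and arr.atom_name[i] != "OXT"]
    names = {i: arr.atom_name[i] for i in heavy}
    coords = {arr.atom_name[i]: arr.coord[i].astype(float) for i in heavy}
    elements = {arr.atom_name[i]: str(arr.element[i]).capitalize()
                for i in heavy}
    g = nx.Graph()
    g.add_nodes_from(names.values())
    order = {}
    for i, j, o in arr.bonds.as_array():
        if i in names and j in names:
            g.add_edge(names[i], names[j])
            order[frozenset((names[i], names[j]))] = int(o)
    rings = set()
    for cyc in nx.cycle_basis(g):
        for k in range(len(cyc)):
            rings.add(frozenset((cyc[k], cyc[(k + 1) % len(cyc)])))

    # BFS placement order through the side chain starting at CA
    parent = {"CB": "CA"}
    placed = ["N", "CA", "C", "O"]
    queue = ["CB"] if "CB" in g else []
    entries: list[AtomEntry] = []
    chi_axes: dict[frozenset, tuple[int, str]] = {}
    n_chi = 0
    while queue:
        atom = queue.pop(0)
        par = parent[atom]
        if atom == "CB":
            refs = ("N", "C", "CA")
        else:
            gp = parent.get(par, "CA" if par == "CB" else None)
            if gp is None:
                gp = "CA"
            ggp = parent.get(gp)
            if ggp is None:
                ggp = {"CA": "N", "CB": "CA"}.get(gp, "N")
            refs = (ggp, gp, par)
        tor = dihedral(coords[refs[0]], coords[refs[1]], coords[refs[2]],
                       coords[atom])
        axis = frozenset((refs[1], refs[2]))
        dof = None
        if atom != "CB":
            rotatable = (axis not in rings
                         and order.get(axis, 1) == 1
                         and refs[2] not in ("C",))
            if rotatable:
                if axis in chi_axes:
                    k, first = chi_axes[axis]
                    first_tor = next(e.torsion for e in entries
                                     if e.name == first)
                    dof = ("chi", k, tor - first_tor)
                else:
                    n_chi += 1
                    chi_axes[axis] = (n_chi, atom)
                    dof = ("chi", n_chi)
        entries.append(AtomEntry(
            name=atom, element=elements[atom], refs=refs,
            bond=bond_length(coords[refs[2]], coords[atom]),
            angle=bond_angle(coords[refs[1]], coords[refs[2]], coords[atom]),
            torsion=tor, torsion_dof=dof))
        placed.append(atom)
        for nb in sorted(g.neighbors(atom)):
            if nb not in placed and nb not in parent and nb not in _BACKBONE:
                parent[nb] = atom
                queue.append(nb)
    bonds = [tuple(sorted(e)) for e in g.edges]
    return entries, bonds, n_chi


def _handmade(code: str) -> ResidueTemplate:
    ch = lambda k: ("chi", k)  # noqa: E731
    if code == "CBA":
        # cyclobutylalanine: CB-CG(ring: CG-CD1-CE-CD2) planar-square ring
        sc = [
            AtomEntry("CB", "C", ("N", "C", "CA"), 1.530, 110.5, 122.6),
            AtomEntry("CG", "C", ("N", "CA", "CB"), 1.530, 114.0, -65.0, ch(1)),
            AtomEntry("CD1", "C", ("CA", "CB", "CG"), 1.551, 135.0, 120.0, ch(2)),
            AtomEntry("CD2", "C", ("CA", "CB", "CG"), 1.551, 135.0, -60.0,
                      ("chi", 2, 180.0)),
            AtomEntry("CE", "C", ("CB", "CG", "CD1"), 1.551, 90.0, 180.0),
        ]
        bonds = [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
                 ("CD1", "CE"), ("CD2", "CE")]
        return ResidueTemplate(code, None, tuple(sc), tuple(bonds), 2)
    if code in ("S5A", "R8A"):
        # alpha-methyl, linear saturated carbon chain standing in for the
        # pentenyl / octenyl staple arms; the macrocycle is closed by an
        # explicit inter-residue bond between the terminal chain carbons
        n_carbon = 5 if code == "S5A" else 8
        chain = ["CB", "CG", "CD", "CE", "CF", "CH", "CI", "CJ"][:n_carbon]
        sc = [AtomEntry("CM", "C", ("N", "C", "CA"), 1.530, 110.5, -119.0),
              AtomEntry("CB", "C", ("N", "C", "CA"), 1.530, 110.5, 122.6)]
        bonds = [("CA", "CM"), ("CA", "CB")]
        window = ["N", "CA", "CB"]
        for k, atom in enumerate(chain[1:], start=1):
            sc.append(AtomEntry(atom, "C", tuple(window[-3:]), 1.530, 111.0,
                                -65.0 if k == 1 else 180.0, ch(k)))
            bonds.append((window[-1], atom))
            window.append(atom)
        return ResidueTemplate(code, None, tuple(sc), tuple(bonds),
                               n_carbon - 1, alpha_methyl=True)
    raise KeyError(f"unknown residue: {code}")


@lru_cache(maxsize=None)
def get_template(code: str) -> ResidueTemplate:
    """Template for a residue code (L 3-letter, D 3-letter, or non-natural).

    D templates are the mirrored L templates (all torsions negated).
    """
    code = code.upper()
    if code in D_TO_L:
        base = get_template(D_TO_L[code])
        sc = tuple(AtomEntry(e.name, e.element, e.refs, e.bond, e.angle,
                             -e.torsion,
                             e.torsion_dof if e.torsion_dof is None or
                             len(e.torsion_dof) == 2
                             else (e.torsion_dof[0], e.torsion_dof[1],
                                   -e.torsion_dof[2]))
                   for e in base.side_chain)
        return ResidueTemplate(code, None, sc, base.bonds, base.n_chi,
                               base.alpha_methyl)
    if code in NONNATURAL:
        return _handmade(code)
    if code not in THREE_TO_ONE:
        raise KeyError(f"unknown residue: {code}")
    if code == "GLY":
        return ResidueTemplate("GLY", "G", (), (), 0)
    entries, bonds, n_chi = _ccd_sidechain_entries(code)
    return ResidueTemplate(code, THREE_TO_ONE[code], tuple(entries),
                           tuple(bonds), n_chi)


def default_chis(code: str) -> list[float]:
    """Ideal-geometry chi angles of the template rotamer."""
    tpl = get_template(code)
    chis = [0.0] * tpl.n_chi
    for e in tpl.side_chain:
        if e.torsion_dof is not None and len(e.torsion_dof) == 2:
            chis[e.torsion_dof[1] - 1] = e.torsion
    return chis


# side-chain charged groups: residue -> (sign, atom names forming the group)
CHARGED_GROUPS = {
    "ASP": (-1, ("OD1", "OD2")),
    "GLU": (-1, ("OE1", "OE2")),
    "LYS": (+1, ("NZ",)),
    "ARG": (+1, ("NE", "NH1", "NH2")),
}
for _l, _d in L_TO_D.items():
    if _l in CHARGED_GROUPS:
        CHARGED_GROUPS[_d] = CHARGED_GROUPS[_l]

# hydrogen-bond donor heavy atoms (with implicit H) per residue side chain
SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "TRP": ("NE1",), "HIS": ("NE2",),
}
# acceptor heavy atoms per residue side chain (His neutral: ND1 acceptor)
SIDECHAIN_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",), "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"), "HIS": ("ND1",), "MET": (),
}
for _l, _d in L_TO_D.items():
    if _l in SIDECHAIN_DONORS:
        SIDECHAIN_DONORS[_d] = SIDECHAIN_DONORS[_l]
    if _l in SIDECHAIN_ACCEPTORS:
        SIDECHAIN_ACCEPTORS[_d] = SIDECHAIN_ACCEPTORS[_l]
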