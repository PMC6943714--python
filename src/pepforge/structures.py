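"""Structure data model, peptide construction and PDB input/output.

Coordinates are in Angstroms, residue numbering is 1-based within each
chain, and atom naming follows PDB v3 conventions.  Peptides are built in
dihedral space from ideal-geometry templates (fixed bond lengths and
angles), so a conformation is fully specified by its backbone and
side-chain torsions.

Extended sequence notation
--------------------------
* uppercase one-letter codes are L-amino acids, lowercase are D,
* bracketed tokens name non-natural residues: ``[Cba]`` cyclobutylalanine,
  ``[S5]`` / ``[R8]`` the two hydrocarbon-staple residues (their macrocycle
  is closed automatically when both are present),
* a trailing ``--`` marks head-to-tail (N-C) cyclization.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import templates as T
from .geometry import place_atom

CHARGE_HYDROPHOBIC = "hydrophobic"
CHARGE_POLAR = "polar"
CHARGE_CHARGED = "charged-group"
CHARGE_OTHER = "other"


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    residue_index: int
    chain_id: str
    charge_class: str = CHARGE_OTHER


@dataclass
class Residue:
    code: str
    is_d: bool
    atoms: list[Atom] = field(default_factory=list)
    backbone_refs: dict[str, int] = field(default_factory=dict)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name} not in residue {self.code}")

    def has(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def chain_id(self) -> str:
        return self.atoms[0].chain_id

    @property
    def index(self) -> int:
        return self.atoms[0].residue_index


# an inter-residue covalent link: ((chain, res_index, atom), (chain, res_index, atom))
Bond = tuple[tuple[str, int, str], tuple[str, int, str]]


@dataclass
class ComplexStructure:
    receptor: list[Residue]
    peptide: list[Residue]
    inter_residue_bonds: list[Bond] = field(default_factory=list)
    peptide_capped: bool = False

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("empty peptide")
        seen = set()
        for r in self.receptor + self.peptide:
            for a in r.atoms:
                key = (a.chain_id, a.residue_index, a.name)
                if key in seen:
                    raise ValueError(f"duplicated atom identifier {key}")
                seen.add(key)
        for b in self.inter_residue_bonds:
            for ref in b:
                if ref not in seen:
                    raise ValueError(f"inter_residue_bond references missing atom {ref}")

    def all_atoms(self) -> list[Atom]:
        return [a for r in self.receptor + self.peptide for a in r.atoms]

    def find_residue(self, chain_id: str, index: int) -> Residue:
        for r in self.receptor + self.peptide:
            if r.chain_id == chain_id and r.index == index:
                return r
        raise KeyError(f"no residue {chain_id}:{index}")


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a synthetic complex with known interface-descriptor counts."""
    n_buried_hydrophobic: int = 0
    n_hbonds: int = 0
    n_salt_bridges: int = 0
    n_like_charge_contacts: int = 0
    geometry_seed: int = 0

    def __post_init__(self):
        if min(self.n_buried_hydrophobic, self.n_hbonds,
               self.n_salt_bridges, self.n_like_charge_contacts) < 0:
            raise ValueError("counts must be >= 0")


# ---------------------------------------------------------------------------
# sequence notation
# ---------------------------------------------------------------------------

_BRACKET = {"CBA": "CBA", "S5": "S5A", "R8": "R8A", "DCBA": "DCB"}
_TOKEN = re.compile(r"\[([A-Za-z0-9]+)\]|([A-Za-z])")


def parse_sequence(text: str) -> tuple[list[str], bool]:
    """Parse extended notation into residue codes and a cyclization flag."""
    text = text.strip()
    cyclic = text.endswith("--")
    if cyclic:
        text = text[:-2]
    if not text:
        raise ValueError("empty sequence")
    codes: list[str] = []
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"unknown residue at {text[pos:]!r}")
        pos = m.end()
        if m.group(1) is not None:
            tok = m.group(1).upper()
            if tok not in _BRACKET:
                raise ValueError(f"unknown residue [{m.group(1)}]")
            codes.append(_BRACKET[tok])
        else:
            ch = m.group(2)
            three = T.ONE_TO_THREE.get(ch.upper())
            if three is None:
                raise ValueError(f"unknown residue {ch!r}")
            if ch.islower():
                if three == "GLY":
                    codes.append("GLY")  # glycine is achiral
                else:
                    codes.append(T.L_TO_D[three])
            else:
                codes.append(three)
    if pos != len(text):
        raise ValueError(f"unknown residue at {text[pos:]!r}")
    return codes, cyclic


def is_d_code(code: str) -> bool:
    return code.upper() in T.D_TO_L


def parse_residue_token(tok: str) -> str:
    """One residue in extended notation ('F', 'f', 'dF', 'Cba', 'DPN')
    to an internal residue code."""
    tok = tok.strip()
    if len(tok) == 1:
        codes, _ = parse_sequence(tok)
        return codes[0]
    if len(tok) == 2 and tok[0] == "d":
        codes, _ = parse_sequence(tok[1].lower())
        return codes[0]
    up = tok.upper()
    if up in _BRACKET:
        return _BRACKET[up]
    if up in T.THREE_TO_ONE or up in T.D_TO_L or up in T.NONNATURAL:
        return up
    raise ValueError(f"unknown residue {tok!r}")


def charge_class_of(code: str, atom_name: str, element: str,
                    terminal: str | None = None) -> str:
    """Atom category used by the interface descriptors.

    ``terminal`` is ``"N"`` / ``"C"`` for the free, ionized termini of an
    uncapped chain, else None.
    """
    if element == "H":
        return CHARGE_OTHER
    if element in ("C", "S"):
        return CHARGE_HYDROPHOBIC
    if element in ("N", "O"):
        grp = T.CHARGED_GROUPS.get(code.upper())
        if grp is not None and atom_name in grp[1]:
            return CHARGE_CHARGED
        if terminal == "N" and atom_name == "N":
            return CHARGE_CHARGED
        if terminal == "C" and atom_name in ("O", "OXT"):
            return CHARGE_CHARGED
        return CHARGE_POLAR
    return CHARGE_OTHER


# ---------------------------------------------------------------------------
# peptide construction in dihedral space
# ---------------------------------------------------------------------------

class PeptideBuilder:
    """Rebuilds peptide Cartesian coordinates from torsions.

    The atom table, template references and bond list are fixed at
    construction; :meth:`build` maps a torsion set to an ``(n_atoms, 3)``
    coordinate array.  Torsion angles are degrees.
    """

    def __init__(self, codes: list[str], chain_id: str = "B",
                 capped: bool = False, cyclic: bool = False):
        self.codes = [c.upper() for c in codes]
        self.chain_id = chain_id
        self.capped = capped
        self.cyclic = cyclic
        self.tpls = [T.get_template(c) for c in self.codes]
        self.atom_meta: list[tuple[int, str, str]] = []  # (res_i, name, element)
        self.index: dict[tuple[int, str], int] = {}
        for i, tpl in enumerate(self.tpls):
            for name, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                self._add(i, name, el)
            for e in tpl.side_chain:
                self._add(i, e.name, e.element)
        self.n_atoms = len(self.atom_meta)
        self.n_res = len(self.codes)
        self.bonds = self._bond_list()

    def _add(self, res_i: int, name: str, element: str) -> None:
        self.index[(res_i, name)] = len(self.atom_meta)
        self.atom_meta.append((res_i, name, element))

    def _bond_list(self) -> list[tuple[int, int]]:
        bonds = []
        for i, tpl in enumerate(self.tpls):
            bonds += [(self.index[(i, "N")], self.index[(i, "CA")]),
                      (self.index[(i, "CA")], self.index[(i, "C")]),
                      (self.index[(i, "C")], self.index[(i, "O")])]
            for a, b in tpl.bonds:
                bonds.append((self.index[(i, a)], self.index[(i, b)]))
            if tpl.code in ("PRO", "DPR"):
                bonds.append((self.index[(i, "N")], self.index[(i, "CD")]))
            if i + 1 < self.n_res:
                bonds.append((self.index[(i, "C")], self.index[(i + 1, "N")]))
        if self.cyclic:
            bonds.append((self.index[(self.n_res - 1, "C")],
                          self.index[(0, "N")]))
        return sorted(set(tuple(sorted(b)) for b in bonds))

    def default_torsions(self, phi: float = -57.0, psi: float = -47.0
                         ) -> dict[str, np.ndarray | list]:
        return {
            "phi": np.full(self.n_res, phi),
            "psi": np.full(self.n_res, psi),
            "omega": np.full(self.n_res, 180.0),
            "chi": [np.array(T.default_chis(c)) for c in self.codes],
        }

    def build(self, torsions: dict) -> np.ndarray:
        phi = np.asarray(torsions["phi"], dtype=float)
        psi = np.asarray(torsions["psi"], dtype=float)
        omega = np.asarray(torsions["omega"], dtype=float)
        chi = torsions["chi"]
        xyz = np.empty((self.n_atoms, 3))
        ix = self.index
        for i, tpl in enumerate(self.tpls):
            if i == 0:
                n = np.array([0.0, 0.0, 0.0])
                ca = np.array([T.BB_N_CA, 0.0, 0.0])
                ang = np.deg2rad(180.0 - T.BB_ANG_N_CA_C)
                c = ca + T.BB_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
            else:
                pn = xyz[ix[(i - 1, "N")]]
                pca = xyz[ix[(i - 1, "CA")]]
                pc = xyz[ix[(i - 1, "C")]]
                n = place_atom(pn, pca, pc, T.BB_C_N, T.BB_ANG_CA_C_N,
                               psi[i - 1])
                ca = place_atom(pca, pc, n, T.BB_N_CA, T.BB_ANG_C_N_CA,
                                omega[i])
                c = place_atom(pc, n, ca, T.BB_CA_C, T.BB_ANG_N_CA_C, phi[i])
            xyz[ix[(i, "N")]] = n
            xyz[ix[(i, "CA")]] = ca
            xyz[ix[(i, "C")]] = c
            xyz[ix[(i, "O")]] = place_atom(n, ca, c, T.BB_C_O,
                                           T.BB_ANG_CA_C_O, psi[i] + 180.0)
            chis = chi[i]
            for e in tpl.side_chain:
                tor = e.torsion
                if e.torsion_dof is not None:
                    k = e.torsion_dof[1]
                    off = e.torsion_dof[2] if len(e.torsion_dof) == 3 else 0.0
                    tor = float(chis[k - 1]) + off
                a, b, cref = (xyz[ix[(i, r)]] for r in e.refs)
                xyz[ix[(i, e.name)]] = place_atom(a, b, cref, e.bond, e.angle,
                                                  tor)
        return xyz

    def to_residues(self, xyz: np.ndarray, start_index: int = 1
                    ) -> list[Residue]:
        residues = []
        for i, tpl in enumerate(self.tpls):
            res = Residue(code=self.codes[i], is_d=is_d_code(self.codes[i]))
            terminal = None
            if not self.capped and not self.cyclic:
                if i == 0:
                    terminal = "N"
                elif i == self.n_res - 1:
                    terminal = "C"
            for j, (res_i, name, el) in enumerate(self.atom_meta):
                if res_i != i:
                    continue
                res.atoms.append(Atom(
                    name=name, element=el, coords=xyz[j].copy(),
                    residue_index=start_index + i, chain_id=self.chain_id,
                    charge_class=charge_class_of(self.codes[i], name, el,
                                                 terminal)))
            for k, a in enumerate(res.atoms):
                if a.name in ("N", "CA", "C", "O", "CB"):
                    res.backbone_refs[a.name] = k
            residues.append(res)
        return residues

    def staple_bond(self) -> Bond | None:
        """The macrocycle-closing bond when both staple residues occur."""
        locs = [(i, c) for i, c in enumerate(self.codes) if c in ("S5A", "R8A")]
        if len(locs) != 2:
            return None
        (i, ci), (j, cj) = locs
        tip = {"S5A": "CF", "R8A": "CJ"}
        return ((self.chain_id, i + 1, tip[ci]), (self.chain_id, j + 1, tip[cj]))


def build_ideal_helix(sequence: str | list[str], phi: float = -57.0,
                      psi: float = -47.0, chain_id: str = "B",
                      capped: bool = False) -> list[Residue]:
    """Build an ideal alpha-helical peptide from extended sequence notation."""
    if isinstance(sequence, str):
        codes, cyclic = parse_sequence(sequence)
    else:
        codes, cyclic = list(sequence), False
    builder = PeptideBuilder(codes, chain_id=chain_id, capped=capped,
                             cyclic=cyclic)
    xyz = builder.build(builder.default_torsions(phi=phi, psi=psi))
    return builder.to_residues(xyz)


def mutate_residue(cs: ComplexStructure, position: int, new_code: str
                   ) -> ComplexStructure:
    """Replace peptide residue ``position`` (1-based) by ``new_code``.

    Backbone atoms keep their coordinates; the new side chain is placed
    from the ideal template at its default rotamer.
    """
    import copy

    cs = copy.deepcopy(cs)
    if not 1 <= position <= len(cs.peptide):
        raise ValueError(f"no peptide residue {position}")
    old = cs.peptide[position - 1]
    code = new_code.upper()
    tpl = T.get_template(code)  # raises for unknown residues
    chain, index = old.chain_id, old.index
    keep = [a for a in old.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    new = Residue(code=code, is_d=is_d_code(code), atoms=list(keep))
    coords = {a.name: a.coords for a in keep}
    for e in tpl.side_chain:
        a, b, c = (coords[r] for r in e.refs)
        tor = e.torsion
        pos_xyz = place_atom(a, b, c, e.bond, e.angle, tor)
        coords[e.name] = pos_xyz
        new.atoms.append(Atom(name=e.name, element=e.element,
                              coords=pos_xyz, residue_index=index,
                              chain_id=chain,
                              charge_class=charge_class_of(code, e.name,
                                                           e.element)))
    for a in new.atoms:
        a.charge_class = charge_class_of(code, a.name, a.element)
    for k, a in enumerate(new.atoms):
        if a.name in ("N", "CA", "C", "O", "CB"):
            new.backbone_refs[a.name] = k
    cs.peptide[position - 1] = new
    return cs


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _to_gemmi(cs: ComplexStructure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "pepforge"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    serial = 1
    for res in cs.receptor + cs.peptide:
        cid = res.chain_id
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        g_res = gemmi.Residue()
        g_res.name = res.code[:3]
        g_res.seqid = gemmi.SeqId(res.index, " ")
        for a in res.atoms:
            g_at = gemmi.Atom()
            g_at.name = a.name
            g_at.element = gemmi.Element(a.element)
            g_at.pos = gemmi.Position(*a.coords)
            g_at.serial = serial
            serial += 1
            g_res.add_atom(g_at)
        chains[cid].add_residue(g_res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_complex(cs: ComplexStructure, path: str) -> None:
    _to_gemmi(cs).write_pdb(str(path))


def read_complex(path: str, receptor_chains: list[str] | str = "A",
                 peptide_chain: str = "B",
                 peptide_capped: bool = False) -> ComplexStructure:
    """Read a protein-peptide complex from a PDB file.

    Waters and other hetero solvent are skipped; for alternate locations
    only the first conformer is kept.
    """
    if isinstance(receptor_chains, str):
        receptor_chains = [receptor_chains]
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()
    st.remove_waters()
    model = st[0]
    names = [ch.name for ch in model]
    for cid in list(receptor_chains) + [peptide_chain]:
        if cid not in names:
            raise ValueError(f"chain not found: {cid}")

    def convert(chain: gemmi.Chain, is_peptide: bool) -> list[Residue]:
        residues = []
        g_residues = [r for r in chain if r.name != "HOH"]
        for gi, g_res in enumerate(g_residues):
            code = g_res.name.strip().upper()
            res = Residue(code=code, is_d=is_d_code(code))
            terminal = None
            if is_peptide and not peptide_capped:
                if gi == 0:
                    terminal = "N"
                elif gi == len(g_residues) - 1:
                    terminal = "C"
            for k, g_at in enumerate(g_res):
                el = g_at.element.name
                res.atoms.append(Atom(
                    name=g_at.name, element=el,
                    coords=np.array([g_at.pos.x, g_at.pos.y, g_at.pos.z]),
                    residue_index=g_res.seqid.num, chain_id=chain.name,
                    charge_class=charge_class_of(code, g_at.name, el,
                                                 terminal)))
            for k, a in enumerate(res.atoms):
                if a.name in ("N", "CA", "C", "O", "CB"):
                    res.backbone_refs[a.name] = k
            residues.append(res)
        return residues

    receptor = []
    for cid in receptor_chains:
        for ch in model:
            if ch.name == cid:
                receptor += convert(ch, False)
    peptide = []
    for ch in model:
        if ch.name == peptide_chain:
            peptide = convert(ch, True)
    if not peptide:
        raise ValueError("empty peptide")
    bonds = _detect_disulfides(receptor + peptide)
    return ComplexStructure(receptor=receptor, peptide=peptide,
                            inter_residue_bonds=bonds,
                            peptide_capped=peptide_capped)


def _detect_disulfides(residues: list[Residue]) -> list[Bond]:
    cys = [(r, a) for r in residues for a in r.atoms
           if r.code in ("CYS", "DCY") and a.name == "SG"]
    bonds: list[Bond] = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            (ri, ai), (rj, aj) = cys[i], cys[j]
            if np.linalg.norm(ai.coords - aj.coords) < 2.5:
                bonds.append(((ri.chain_id, ri.index, "SG"),
                              (rj.chain_id, rj.index, "SG")))
    return bonds
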