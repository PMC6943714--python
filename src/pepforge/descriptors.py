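"""Interface descriptors of a protein-peptide complex.

The four descriptors feeding the empirical binding-affinity score are

* ``dXH`` - buried solvent-accessible surface area of hydrophobic atoms
  (carbon and sulfur), converted to kcal/mol,
* ``dXC`` - buried SASA of nitrogen/oxygen atoms of charged Asp/Glu/Lys/Arg
  side chains (and free ionized termini), converted to kcal/mol,
* ``XHB`` - number of conventional hydrogen bonds across the interface,
* ``XSB`` - net salt bridges across the interface: favorable
  (opposite-charge) group pairs minus repulsive (like-charge) pairs.

SASA uses a deterministic sphere-point (Shrake-Rupley style) algorithm
with a Fibonacci-spiral point set.  Structures are assumed hydrogen-free;
donor hydrogens are inferred from heavy-atom connectivity and placed at
ideal positions on demand.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import templates as T
from .geometry import fibonacci_sphere
from .structures import CHARGE_CHARGED, ComplexStructure, Residue

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

N_H = 1.01   # donor N-H bond length, A
O_H = 0.96


@dataclass
class SASAResult:
    per_atom_area: np.ndarray
    total: float
    probe_radius: float
    n_points: int


@dataclass
class BurialResult:
    receptor_delta: np.ndarray
    peptide_delta: np.ndarray
    hydrophobic_area: float       # buried C/S area, both sides, A^2
    charged_area: float           # buried charged-group N/O area, A^2
    buried_sa: float              # total interface buried area, A^2


@dataclass
class InterfaceDescriptors:
    dXH: float
    dXC: float
    XHB: int
    XSB: int
    buried_SA: float
    hydrophobic_area: float = 0.0
    charged_area: float = 0.0
    conversion: float = 0.025


@dataclass
class PackingMetrics:
    dihedral_normality: float
    packing1d_normality: float
    packing3d_normality: float


def _radii(elements: list[str]) -> np.ndarray:
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        try:
            out[i] = VDW_RADII[el]
        except KeyError:
            raise ValueError(f"no radius for element {el!r}") from None
    return out


def compute_sasa(coords: np.ndarray, elements: list[str],
                 probe: float = 1.4, n_points: int = 960) -> SASAResult:
    """Solvent-accessible surface area by deterministic sphere sampling."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise ValueError("need at least one atom")
    radii = _radii(list(elements)) + probe
    sphere = fibonacci_sphere(n_points)
    n = len(coords)
    areas = np.empty(n)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        nb = np.where((d2[i] < (radii[i] + radii) ** 2)
                      & (np.arange(n) != i))[0]
        if len(nb):
            pd2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            buried = (pd2 < radii[nb] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return SASAResult(per_atom_area=areas, total=float(areas.sum()),
                      probe_radius=probe, n_points=n_points)


def sasa_of_atoms(atoms, probe: float = 1.4, n_points: int = 960) -> SASAResult:
    coords = np.array([a.coords for a in atoms])
    return compute_sasa(coords, [a.element for a in atoms], probe, n_points)


def compute_burial(cs: ComplexStructure, probe: float = 1.4,
                   n_points: int = 960) -> BurialResult:
    """Per-atom SASA loss upon complex formation and class-summed burial."""
    rec = [a for r in cs.receptor for a in r.atoms]
    pep = [a for r in cs.peptide for a in r.atoms]
    sasa_rec = sasa_of_atoms(rec, probe, n_points).per_atom_area
    sasa_pep = sasa_of_atoms(pep, probe, n_points).per_atom_area
    both = sasa_of_atoms(rec + pep, probe, n_points).per_atom_area
    d_rec = np.maximum(sasa_rec - both[:len(rec)], 0.0)
    d_pep = np.maximum(sasa_pep - both[len(rec):], 0.0)
    hydro = chg = 0.0
    for atoms, deltas in ((rec, d_rec), (pep, d_pep)):
        for a, d in zip(atoms, deltas):
            if a.element in ("C", "S"):
                hydro += d
            elif a.charge_class == CHARGE_CHARGED:
                chg += d
    return BurialResult(receptor_delta=d_rec, peptide_delta=d_pep,
                        hydrophobic_area=float(hydro),
                        charged_area=float(chg),
                        buried_sa=float(d_rec.sum() + d_pep.sum()))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _amide_h(res: Residue, prev_c: np.ndarray | None) -> np.ndarray | None:
    """Ideal backbone amide H; None for proline."""
    if res.code in ("PRO", "DPR") or not res.has("N"):
        return None
    n = res.atom("N").coords
    ca = res.atom("CA").coords
    if prev_c is not None:
        direction = -_unit(_unit(ca - n) + _unit(prev_c - n))
    else:
        direction = _unit(n - ca)
    return n + N_H * direction


def _sp2_nh2(n: np.ndarray, parent: np.ndarray, plane_ref: np.ndarray
             ) -> list[np.ndarray]:
    """Two in-plane H on an sp2 -NH2 (amide / guanidinium)."""
    x = _unit(n - parent)
    normal = np.cross(parent - plane_ref, n - parent)
    normal = _unit(normal)
    y = np.cross(normal, x)
    out = []
    for sign in (1.0, -1.0):
        d = np.cos(np.deg2rad(60.0)) * x + sign * np.sin(np.deg2rad(60.0)) * y
        out.append(n + N_H * d)
    return out


def _sp3_nh3(n: np.ndarray, parent: np.ndarray) -> list[np.ndarray]:
    """Three tetrahedral H on an ammonium nitrogen (fixed phase)."""
    axis = _unit(n - parent)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    y = _unit(np.cross(axis, ref))
    z = np.cross(axis, y)
    out = []
    for k in range(3):
        az = 2.0 * np.pi * k / 3.0
        d = (np.cos(np.deg2rad(70.5)) * axis
             + np.sin(np.deg2rad(70.5)) * (np.cos(az) * y + np.sin(az) * z))
        out.append(n + N_H * d)
    return out


@dataclass
class _Donor:
    d: np.ndarray                  # heavy donor atom
    hs: list                       # explicit H positions (may be empty)
    rotatable: bool = False        # hydroxyl/thiol: H orients freely on a cone
    parent: np.ndarray | None = None


def _bonded_heavy(res: Residue, name: str) -> list[np.ndarray]:
    tpl_bonds = T.get_template(res.code).bonds if _has_template(res.code) else ()
    out = []
    for a, b in tpl_bonds:
        other = b if a == name else (a if b == name else None)
        if other and res.has(other):
            out.append(res.atom(other).coords)
    return out


def _has_template(code: str) -> bool:
    try:
        T.get_template(code)
        return True
    except KeyError:
        return False


def collect_donors(residues: list[Residue], capped: bool) -> list[_Donor]:
    donors: list[_Donor] = []
    by_key = {(r.chain_id, r.index): r for r in residues}
    for pos, res in enumerate(residues):
        prev = by_key.get((res.chain_id, res.index - 1))
        prev_c = None
        if prev is not None and prev.has("C") and res.has("N"):
            c = prev.atom("C").coords
            if np.linalg.norm(c - res.atom("N").coords) < 1.8:
                prev_c = c
        if res.has("N") and res.has("CA"):
            h = _amide_h(res, prev_c)
            if h is not None:
                donors.append(_Donor(d=res.atom("N").coords, hs=[h]))
        code = res.code.upper()
        for name in T.SIDECHAIN_DONORS.get(code, ()):
            if not res.has(name):
                continue
            atom = res.atom(name)
            nbrs = _bonded_heavy(res, name)
            if not nbrs:
                continue
            if name in ("OG", "OG1", "OH", "SG"):
                donors.append(_Donor(d=atom.coords, hs=[], rotatable=True,
                                     parent=nbrs[0]))
            elif name == "NZ":
                donors.append(_Donor(d=atom.coords,
                                     hs=_sp3_nh3(atom.coords, nbrs[0])))
            elif name in ("ND2", "NE2", "NH1", "NH2") and len(nbrs) == 1:
                parent = nbrs[0]
                ref = None
                for cand in ("CB", "CG", "CD", "NE", "CZ", "CA"):
                    if res.has(cand) and not np.allclose(
                            res.atom(cand).coords, parent):
                        ref = res.atom(cand).coords
                        break
                if ref is None:
                    continue
                donors.append(_Donor(d=atom.coords,
                                     hs=_sp2_nh2(atom.coords, parent, ref)))
            else:  # single in-plane H (Trp NE1, His NE2, Arg NE)
                if len(nbrs) >= 2:
                    direction = -_unit(sum(_unit(nb - atom.coords)
                                           for nb in nbrs))
                    donors.append(_Donor(d=atom.coords,
                                         hs=[atom.coords + N_H * direction]))
    return donors


def collect_acceptors(residues: list[Residue]) -> list[np.ndarray]:
    acc = []
    for res in residues:
        for a in res.atoms:
            if a.name in ("O", "OXT"):
                acc.append(a.coords)
        for name in T.SIDECHAIN_ACCEPTORS.get(res.code.upper(), ()):
            if res.has(name):
                acc.append(res.atom(name).coords)
    return acc


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    u = _unit(d - h)
    v = _unit(a - h)
    return float(np.rad2deg(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def _best_angle(donor: _Donor, a: np.ndarray) -> float:
    """Best achievable donor-H-acceptor angle for this donor."""
    if donor.rotatable:
        # H constrained to a tetrahedral cone about parent->D; choose the
        # azimuth that points it most directly at the acceptor
        axis = _unit(donor.d - donor.parent)
        da = _unit(a - donor.d)
        perp = da - np.dot(da, axis) * axis
        if np.linalg.norm(perp) < 1e-9:
            hdir = axis  # acceptor on-axis: degenerate, point along axis
        else:
            perp = _unit(perp)
            hdir = (np.cos(np.deg2rad(70.5)) * axis
                    + np.sin(np.deg2rad(70.5)) * perp)
        h = donor.d + O_H * hdir
        return _dha_angle(donor.d, h, a)
    return max((_dha_angle(donor.d, h, a) for h in donor.hs), default=0.0)


def count_hbonds(cs: ComplexStructure, d_max: float = 3.5,
                 angle_min: float = 120.0) -> int:
    """Conventional hydrogen bonds across the receptor-peptide interface.

    Each donor(-H) is paired with at most one acceptor; among
    geometrically valid candidates the shortest donor-acceptor distance
    wins.
    """
    total = 0
    pairs = ((collect_donors(cs.receptor, True), collect_acceptors(cs.peptide)),
             (collect_donors(cs.peptide, cs.peptide_capped),
              collect_acceptors(cs.receptor)))
    for donors, acceptors in pairs:
        if not acceptors:
            continue
        acc = np.array(acceptors)
        for donor in donors:
            dist = np.linalg.norm(acc - donor.d, axis=1)
            cand = np.where(dist <= d_max)[0]
            valid = [(dist[i], i) for i in cand
                     if _best_angle(donor, acc[i]) >= angle_min]
            if valid:
                total += 1
    return total


# ---------------------------------------------------------------------------
# salt bridges
# ---------------------------------------------------------------------------

def _charged_groups(residues: list[Residue], capped: bool
                    ) -> list[tuple[int, np.ndarray]]:
    """(sign, coords-array) per charged group."""
    groups = []
    for pos, res in enumerate(residues):
        grp = T.CHARGED_GROUPS.get(res.code.upper())
        if grp is not None:
            sign, names = grp
            coords = [res.atom(n).coords for n in names if res.has(n)]
            if coords:
                groups.append((sign, np.array(coords)))
        if not capped:
            if pos == 0 and res.has("N") \
                    and res.atom("N").charge_class == CHARGE_CHARGED:
                groups.append((+1, np.array([res.atom("N").coords])))
            if pos == len(residues) - 1:
                coords = [res.atom(n).coords for n in ("O", "OXT")
                          if res.has(n)
                          and res.atom(n).charge_class == CHARGE_CHARGED]
                if coords:
                    groups.append((-1, np.array(coords)))
    return groups


def count_salt_bridges(cs: ComplexStructure, d_max: float = 4.0) -> int:
    """Net salt bridges: favorable minus repulsive charged-group contacts."""
    rec = _charged_groups(cs.receptor, True)
    pep = _charged_groups(cs.peptide, cs.peptide_capped)
    net = 0
    for s1, c1 in rec:
        for s2, c2 in pep:
            dmin = np.sqrt(((c1[:, None, :] - c2[None, :, :]) ** 2)
                           .sum(-1)).min()
            if dmin <= d_max:
                net += 1 if s1 * s2 < 0 else -1
    return net


# ---------------------------------------------------------------------------
# combined descriptors
# ---------------------------------------------------------------------------

def compute_descriptors(cs: ComplexStructure, conversion: float = 0.025,
                        probe: float = 1.4, n_points: int = 960,
                        hb_d_max: float = 3.5, hb_angle_min: float = 120.0,
                        sb_d_max: float = 4.0) -> InterfaceDescriptors:
    burial = compute_burial(cs, probe, n_points)
    xhb = count_hbonds(cs, hb_d_max, hb_angle_min)
    xsb = count_salt_bridges(cs, sb_d_max)
    return InterfaceDescriptors(
        dXH=conversion * burial.hydrophobic_area,
        dXC=conversion * burial.charged_area,
        XHB=xhb, XSB=xsb, buried_SA=burial.buried_sa,
        hydrophobic_area=burial.hydrophobic_area,
        charged_area=burial.charged_area, conversion=conversion)


# ---------------------------------------------------------------------------
# packing-normality surrogates
# ---------------------------------------------------------------------------

# reference constants for the surrogate Z-scores (fixed, documented)
_RAMA_CENTERS = np.array([[-63.0, -43.0], [-120.0, 130.0], [60.0, 45.0]])
_RAMA_WEIGHTS = np.array([0.45, 0.45, 0.10])
_RAMA_SIGMA = 30.0
_DIH_REF_MEAN, _DIH_REF_SD = -2.5, 1.0
_CONTACT_REF_MEAN, _CONTACT_REF_SD = 12.0, 4.0


def _rama_logp(phi: float, psi: float) -> float:
    d = _RAMA_CENTERS - np.array([phi, psi])
    d = (d + 180.0) % 360.0 - 180.0
    p = (_RAMA_WEIGHTS
         * np.exp(-(d ** 2).sum(1) / (2.0 * _RAMA_SIGMA ** 2))).sum()
    return float(np.log(p + 1e-12))


def packing_metrics(cs: ComplexStructure) -> PackingMetrics:
    """Simple bundled surrogate for knowledge-based packing normality.

    Dihedral normality scores peptide (phi, psi) pairs against a coarse
    smooth Ramachandran frequency model (mirrored for D residues);
    1D/3D packing normality are interface atom-contact-count Z-scores
    against fixed reference constants.  These are stand-ins with the same
    interface as an external knowledge-based provider.
    """
    from .geometry import dihedral as dih

    logps = []
    pep = cs.peptide
    for i in range(1, len(pep) - 1):
        try:
            prev_c = pep[i - 1].atom("C").coords
            n = pep[i].atom("N").coords
            ca = pep[i].atom("CA").coords
            c = pep[i].atom("C").coords
            nxt_n = pep[i + 1].atom("N").coords
        except KeyError:
            continue
        phi = dih(prev_c, n, ca, c)
        psi = dih(n, ca, c, nxt_n)
        if pep[i].is_d:
            phi, psi = -phi, -psi
        logps.append(_rama_logp(phi, psi))
    dihedral_z = 0.0
    if logps:
        dihedral_z = (float(np.mean(logps)) - _DIH_REF_MEAN) / _DIH_REF_SD

    rec = np.array([a.coords for r in cs.receptor for a in r.atoms])
    counts = []
    dirs = []
    for r in cs.peptide:
        for a in r.atoms:
            if len(rec) == 0:
                break
            d = np.linalg.norm(rec - a.coords, axis=1)
            near = d < 4.5
            counts.append(int(near.sum()))
            if near.any():
                vecs = rec[near] - a.coords
                vecs /= np.linalg.norm(vecs, axis=1)[:, None]
                dirs.append(np.linalg.norm(vecs.mean(0)))
    c_mean = float(np.mean(counts)) if counts else 0.0
    z1 = (c_mean - _CONTACT_REF_MEAN) / _CONTACT_REF_SD
    # directional anisotropy of contacts: well-packed atoms see neighbors
    # spread over directions (low mean resultant length)
    aniso = float(np.mean(dirs)) if dirs else 1.0
    z3 = (0.5 - aniso) / 0.25
    return PackingMetrics(dihedral_normality=float(dihedral_z),
                          packing1d_normality=float(z1),
                          packing3d_normality=float(z3))
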