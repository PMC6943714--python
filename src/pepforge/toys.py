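"""Synthetic toy complexes with known interface-descriptor counts.

Each requested interaction is realized at an isolated "site" along the
x-axis, with the receptor-side residue approaching from -y and the
peptide-side residue from +y.  Sites are spaced far enough apart
(15 A) that they cannot interact, so the descriptor counts of the whole
complex are exactly the sum over sites:

* hydrogen bond:  Gly amide N-H (receptor) donating head-on to a Gly
  carbonyl O (peptide) at 2.9 A,
* salt bridge:    Glu carboxylate OE1 (receptor) facing a Lys ammonium
  NZ (peptide) at 3.2 A, with the N-H hydrogens angled away so the
  contact is ionic, not a counted hydrogen bond,
* like-charge:    two Lys NZ groups head-to-head at 3.8 A,
* buried hydrophobic: two Ala CB methyls facing at 4.2 A.

Orientation spin about the approach axis is drawn from a seeded
generator, so complexes are deterministic per ``geometry_seed``; the
construction is verified against the descriptor module and retried with
fresh spins on the (rare) failure.
"""
from __future__ import annotations

import numpy as np

from .descriptors import compute_burial, compute_descriptors
from .geometry import rotation_about_axis
from .structures import ComplexStructure, PeptideBuilder, Residue, ToySpec

_SITE_SPACING = 15.0
_Y = np.array([0.0, 1.0, 0.0])


def _single_residue(code: str, chain_id: str) -> Residue:
    b = PeptideBuilder([code], chain_id=chain_id, capped=True)
    xyz = b.build(b.default_torsions())
    return b.to_residues(xyz)[0]


def _orient(res: Residue, p_name: str, q_name: str, q_target: np.ndarray,
            direction: np.ndarray, spin: float) -> None:
    """Rigidly move ``res`` so that atom Q sits at ``q_target`` with the
    P->Q bond along ``direction``, then spin about that axis."""
    p = res.atom(p_name).coords
    q = res.atom(q_name).coords
    v = (q - p) / np.linalg.norm(q - p)
    d = direction / np.linalg.norm(direction)
    axis = np.cross(v, d)
    if np.linalg.norm(axis) < 1e-9:
        rot = np.eye(3) if np.dot(v, d) > 0 else rotation_about_axis(
            np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9
            else np.array([0.0, 0.0, 1.0]), 180.0)
    else:
        ang = np.rad2deg(np.arccos(np.clip(np.dot(v, d), -1.0, 1.0)))
        rot = rotation_about_axis(axis, ang)
    rot = rotation_about_axis(d, spin) @ rot
    for a in res.atoms:
        a.coords = rot @ (a.coords - q) + q_target


def _site(kind: str, center: np.ndarray, spin_r: float, spin_p: float
          ) -> tuple[Residue, Residue]:
    if kind == "hbond":
        rec = _single_residue("GLY", "A")
        pep = _single_residue("GLY", "B")
        _orient(rec, "CA", "N", center - 1.45 * _Y, _Y, spin_r)
        _orient(pep, "C", "O", center + 1.45 * _Y, -_Y, spin_p)
    elif kind == "salt":
        rec = _single_residue("GLU", "A")
        pep = _single_residue("LYS", "B")
        _orient(rec, "CD", "OE1", center - 1.6 * _Y, _Y, spin_r)
        _orient(pep, "CE", "NZ", center + 1.6 * _Y, -_Y, spin_p)
    elif kind == "like":
        rec = _single_residue("LYS", "A")
        pep = _single_residue("LYS", "B")
        _orient(rec, "CE", "NZ", center - 1.9 * _Y, _Y, spin_r)
        _orient(pep, "CE", "NZ", center + 1.9 * _Y, -_Y, spin_p)
    elif kind == "hydro":
        rec = _single_residue("ALA", "A")
        pep = _single_residue("ALA", "B")
        _orient(rec, "CA", "CB", center - 2.1 * _Y, _Y, spin_r)
        _orient(pep, "CA", "CB", center + 2.1 * _Y, -_Y, spin_p)
    else:
        raise ValueError(kind)
    return rec, pep


def _assemble(spec: ToySpec, rng: np.random.Generator) -> ComplexStructure:
    kinds = (["hbond"] * spec.n_hbonds + ["salt"] * spec.n_salt_bridges
             + ["like"] * spec.n_like_charge_contacts
             + ["hydro"] * spec.n_buried_hydrophobic)
    receptor: list[Residue] = []
    peptide: list[Residue] = []
    for k, kind in enumerate(kinds):
        center = np.array([_SITE_SPACING * k, 0.0, 0.0])
        rec, pep = _site(kind, center, rng.uniform(0, 360),
                         rng.uniform(0, 360))
        receptor.append(rec)
        peptide.append(pep)
    # isolated anchors so both components are always non-empty
    anchor_r = _single_residue("ALA", "A")
    for a in anchor_r.atoms:
        a.coords = a.coords + np.array([-50.0, -150.0, 0.0])
    anchor_p = _single_residue("ALA", "B")
    for a in anchor_p.atoms:
        a.coords = a.coords + np.array([-50.0, 150.0, 0.0])
    receptor.append(anchor_r)
    peptide.append(anchor_p)
    for i, r in enumerate(receptor, start=1):
        for a in r.atoms:
            a.residue_index = i
    for i, r in enumerate(peptide, start=1):
        for a in r.atoms:
            a.residue_index = i
    return ComplexStructure(receptor=receptor, peptide=peptide,
                            peptide_capped=True)


def make_toy_complex(spec: ToySpec, max_retries: int = 8) -> ComplexStructure:
    """Build a complex whose descriptors match ``spec`` exactly.

    The hydrogen-bond and net salt-bridge counts are verified against the
    descriptor module with default criteria; buried hydrophobic atoms are
    guaranteed to number at least ``n_buried_hydrophobic``.
    """
    target_xsb = spec.n_salt_bridges - spec.n_like_charge_contacts
    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.geometry_seed, attempt])
        cs = _assemble(spec, rng)
        desc = compute_descriptors(cs)
        if desc.XHB != spec.n_hbonds or desc.XSB != target_xsb:
            continue
        if spec.n_buried_hydrophobic:
            burial = compute_burial(cs)
            atoms = ([a for r in cs.receptor for a in r.atoms],
                     [a for r in cs.peptide for a in r.atoms])
            n_buried = sum(
                1 for side, deltas in zip(atoms,
                                          (burial.receptor_delta,
                                           burial.peptide_delta))
                for a, d in zip(side, deltas)
                if a.element in ("C", "S") and d > 1.0)
            if n_buried < spec.n_buried_hydrophobic:
                continue
        return cs
    raise RuntimeError("placement failed")
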