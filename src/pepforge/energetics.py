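"""Simplified force-field energetics and rigid-body binding-energy flavors.

The nonbonded model is a 12-6 Lennard-Jones term, a screened Coulomb term
with the distance-dependent dielectric eps(d) = 4d (so the pair energy is
k*qi*qj / (4*d^2)), and a Gaussian-exclusion continuum solvation term in
which a fully exposed atom contributes its reference solvation free
energy and loses it progressively as neighbors occlude its first
solvation shell.  An optional nonpolar term converts buried solvent-
accessible surface area to energy with a 0.65 kcal/(mol*A^2) scale.

Parameters (Lennard-Jones, lumped heavy-atom partial charges, solvation
reference energies/volumes) ship as versioned CSVs in ``pepforge/data``;
they are a compact representative set covering every atom the structure
builder emits, with D-amino acids sharing their L parameters.

Four rigid-body binding-energy flavors are provided:

* ``simple``       E(complex) - E(protein) - E(peptide), components taken
                   in their in-complex conformations,
* ``strain``       as simple but with the free peptide minimized first,
                   which adds a non-negative strain penalty,
* ``neutralized``  as simple with charged side chains and free termini
                   given neutral charge templates,
* ``solvated``     as simple plus the continuum solvation term and the
                   0.65-scaled buried-surface nonpolar term.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from . import templates as T
from .structures import CHARGE_CHARGED, ComplexStructure, Residue

COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)
SASA_SCALE = 0.65            # kcal/(mol*A^2)
_R_FLOOR = 0.4               # pair-distance clamp, A

FLAVORS = ("simple", "strain", "neutralized", "solvated")


@dataclass(frozen=True)
class AtomType:
    name: str
    rmin_half: float
    epsilon: float
    dg_ref: float
    volume: float
    lam: float


@dataclass
class ForceFieldParams:
    types: dict[str, AtomType]
    charges: dict[tuple[str, str], tuple[str, float]]  # (res, atom) -> (type, q)
    coulomb_constant: float = COULOMB_CONSTANT
    sasa_scale: float = SASA_SCALE

    def assign(self, res_code: str, atom_name: str, element: str = "",
               neutralized: bool = False, terminal: str | None = None
               ) -> tuple[str, float]:
        code = res_code.upper()
        if code in T.D_TO_L:
            code = T.D_TO_L[code]
        key = (code, atom_name)
        if key not in self.charges:
            raise KeyError(f"unparameterized atom type: {code}:{atom_name}")
        tname, q = self.charges[key]
        if neutralized:
            grp = T.CHARGED_GROUPS.get(code)
            if grp is not None and atom_name in grp[1]:
                q = 0.0
            if grp is not None and code in ("ASP", "GLU") \
                    and atom_name in ("CG", "CD"):
                q = 0.0
            if grp is not None and code == "LYS" and atom_name == "CE":
                q = 0.0
            if grp is not None and code == "ARG" and atom_name in ("CD", "CZ"):
                q = 0.0
        if terminal == "N" and atom_name == "N" and not neutralized:
            q += 1.0  # free ammonium terminus
        if terminal == "C" and atom_name in ("O", "OXT") and not neutralized:
            q -= 0.5  # shared carboxylate charge
        return tname, q


@lru_cache(maxsize=1)
def default_params() -> ForceFieldParams:
    types = {}
    data = resources.files("pepforge") / "data"
    with (data / "atom_types.csv").open() as f:
        for row in csv.DictReader(f):
            types[row["type"]] = AtomType(
                row["type"], float(row["rmin_half"]), float(row["epsilon"]),
                float(row["dg_ref"]), float(row["volume"]),
                float(row["lambda"]))
    charges = {}
    with (data / "charges.csv").open() as f:
        for row in csv.DictReader(f):
            charges[(row["residue"], row["atom"])] = (
                row["type"], float(row["charge"]))
    return ForceFieldParams(types=types, charges=charges)


@dataclass
class EnergyBreakdown:
    vdw: float
    coulomb: float
    solvation: float = 0.0
    nonpolar_sasa: float = 0.0

    @property
    def total(self) -> float:
        return self.vdw + self.coulomb + self.solvation + self.nonpolar_sasa


@dataclass
class TypedAtom:
    """An atom with assigned force-field parameters."""
    type_name: str
    charge: float
    coords: np.ndarray


def type_residues(residues: list[Residue], params: ForceFieldParams,
                  neutralized: bool = False, capped: bool = True
                  ) -> list[TypedAtom]:
    out = []
    for pos, res in enumerate(residues):
        for a in res.atoms:
            terminal = None
            if not capped:
                if pos == 0 and a.name == "N":
                    terminal = "N"
                if pos == len(residues) - 1 and a.name in ("O", "OXT") \
                        and a.charge_class == CHARGE_CHARGED:
                    terminal = "C"
            tname, q = params.assign(res.code, a.name, a.element,
                                     neutralized=neutralized,
                                     terminal=terminal)
            out.append(TypedAtom(tname, q, a.coords))
    return out


def _param_arrays(atoms: list[TypedAtom], params: ForceFieldParams):
    rmin = np.array([params.types[a.type_name].rmin_half for a in atoms])
    eps = np.array([params.types[a.type_name].epsilon for a in atoms])
    q = np.array([a.charge for a in atoms])
    xyz = np.array([a.coords for a in atoms], dtype=float)
    return xyz, rmin, eps, q


def nonbonded_energy(group_a: list[TypedAtom], group_b: list[TypedAtom],
                     params: ForceFieldParams | None = None
                     ) -> EnergyBreakdown:
    """Pairwise vdW + screened-Coulomb energy between two atom groups.

    Only cross-group pairs contribute (rigid-group interaction energy).
    """
    params = params or default_params()
    xa, ra, ea, qa = _param_arrays(group_a, params)
    xb, rb, eb, qb = _param_arrays(group_b, params)
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    d = np.maximum(d, _R_FLOOR)
    rm = ra[:, None] + rb[None, :]
    eps = np.sqrt(ea[:, None] * eb[None, :])
    s6 = (rm / d) ** 6
    vdw = float((eps * (s6 ** 2 - 2.0 * s6)).sum())
    coul = float((params.coulomb_constant * qa[:, None] * qb[None, :]
                  / (4.0 * d ** 2)).sum())
    return EnergyBreakdown(vdw=vdw, coulomb=coul)


def solvation_energy(atoms: list[TypedAtom],
                     params: ForceFieldParams | None = None) -> float:
    """Gaussian-exclusion continuum solvation free energy.

    An isolated atom contributes exactly its reference free energy; each
    neighbor subtracts a Gaussian-weighted shell-exclusion term.
    """
    params = params or default_params()
    xyz, rmin, _, _ = _param_arrays(atoms, params)
    dg = np.array([params.types[a.type_name].dg_ref for a in atoms])
    vol = np.array([params.types[a.type_name].volume for a in atoms])
    lam = np.array([params.types[a.type_name].lam for a in atoms])
    n = len(atoms)
    if n == 1:
        return float(dg[0])
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    d = np.maximum(d, _R_FLOOR)
    np.fill_diagonal(d, np.inf)
    x = (d - rmin[:, None]) / lam[:, None]
    f = (dg[:, None] / (2 * np.sqrt(np.pi) * lam[:, None] * d ** 2)
         * np.exp(-x ** 2)) * vol[None, :]
    return float((dg - f.sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# bonded topology (restraint form) for internal energies and minimization
# ---------------------------------------------------------------------------

K_BOND = 300.0   # kcal/(mol*A^2)
K_13 = 80.0      # Urey-Bradley-style 1-3 distance restraint


def build_exclusions(n: int, bonds: list[tuple[int, int]]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pair arrays with 1-2/1-3 exclusion and 0.5-scaled 1-4.

    Returns (pair_i, pair_j, scale, pairs13).
    """
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    excl: dict[tuple[int, int], float] = {}
    pairs13 = set()
    for i in range(n):
        for j in adj[i]:
            excl[tuple(sorted((i, j)))] = 0.0
            for k in adj[j]:
                if k != i:
                    p = tuple(sorted((i, k)))
                    excl.setdefault(p, 0.0)
                    if p[0] != p[1]:
                        pairs13.add(p)
                    for m in adj[k]:
                        if m not in (i, j):
                            excl.setdefault(tuple(sorted((i, m))), 0.5)
    iu, ju = np.triu_indices(n, k=1)
    scale = np.ones(len(iu))
    for t, (i, j) in enumerate(zip(iu, ju)):
        s = excl.get((int(i), int(j)))
        if s is not None:
            scale[t] = s
    p13 = np.array(sorted(pairs13), dtype=int).reshape(-1, 2)
    return iu, ju, scale, p13


@lru_cache(maxsize=None)
def _intra_ideal_table(code: str) -> dict[frozenset, float]:
    from .structures import PeptideBuilder

    try:
        b = PeptideBuilder([code], capped=True)
    except KeyError:
        return {}
    xyz = b.build(b.default_torsions())
    names = [m[1] for m in b.atom_meta]
    table = {}
    _, _, scale, p13 = build_exclusions(b.n_atoms, b.bonds)
    for i, j in b.bonds:
        table[frozenset((names[i], names[j]))] = float(
            np.linalg.norm(xyz[i] - xyz[j]))
    for i, j in p13:
        table.setdefault(frozenset((names[i], names[j])), float(
            np.linalg.norm(xyz[i] - xyz[j])))
    return table


def _intra_ideal(code: str, a: str, b: str) -> float | None:
    return _intra_ideal_table(code.upper()).get(frozenset((a, b)))


def _link_ideal_table() -> dict[tuple[str, str], float]:
    from .structures import PeptideBuilder

    b = PeptideBuilder(["GLY", "GLY"], capped=True)
    xyz = b.build(b.default_torsions())
    names = {(m[0], m[1]): k for k, m in enumerate(b.atom_meta)}
    pairs = [("C", "N"), ("CA", "N"), ("O", "N"), ("C", "CA")]
    return {(a, bb): float(np.linalg.norm(xyz[names[(0, a)]]
                                          - xyz[names[(1, bb)]]))
            for a, bb in pairs}


_LINK_IDEAL = _link_ideal_table()


class System:
    """Typed atoms + topology of a complex, with vectorized energetics.

    Covalent geometry is maintained by harmonic restraints on bonded
    (1-2) and geminal (1-3) distances taken from the input coordinates;
    nonbonded pairs exclude 1-2/1-3 and scale 1-4 interactions by 0.5.
    """

    def __init__(self, cs: ComplexStructure,
                 params: ForceFieldParams | None = None,
                 neutralized: bool = False):
        self.params = params or default_params()
        self.cs = cs
        residues = cs.receptor + cs.peptide
        typed = (type_residues(cs.receptor, self.params, neutralized)
                 + type_residues(cs.peptide, self.params, neutralized,
                                 capped=cs.peptide_capped))
        self.atoms = typed
        self.coords0 = np.array([a.coords for a in typed])
        self.xyz, self.rmin, self.eps, self.q = _param_arrays(
            typed, self.params)
        self.dg = np.array([self.params.types[a.type_name].dg_ref
                            for a in typed])
        self.vol = np.array([self.params.types[a.type_name].volume
                             for a in typed])
        self.lam = np.array([self.params.types[a.type_name].lam
                             for a in typed])
        self.group = np.array(
            [0] * sum(len(r.atoms) for r in cs.receptor)
            + [1] * sum(len(r.atoms) for r in cs.peptide))
        self.key_to_idx = {}
        k = 0
        for r in residues:
            for a in r.atoms:
                self.key_to_idx[(a.chain_id, a.residue_index, a.name)] = k
                k += 1
        self.bonds = self._bonds(residues)
        self._build_pairs()

    def _bonds(self, residues: list[Residue]) -> list[tuple[int, int]]:
        bonds = []
        idx = self.key_to_idx
        for pos, r in enumerate(residues):
            try:
                tpl_bonds = T.get_template(r.code).bonds
            except KeyError:
                tpl_bonds = ()
            key = lambda n: (r.chain_id, r.index, n)  # noqa: E731
            for n1, n2 in [("N", "CA"), ("CA", "C"), ("C", "O")] \
                    + list(tpl_bonds):
                if key(n1) in idx and key(n2) in idx:
                    bonds.append((idx[key(n1)], idx[key(n2)]))
            if r.code.upper() in ("PRO", "DPR") and key("CD") in idx:
                bonds.append((idx[key("N")], idx[key("CD")]))
            nxt = (r.chain_id, r.index + 1, "N")
            if key("C") in idx and nxt in idx:
                c = self.coords0[idx[key("C")]]
                n = self.coords0[idx[nxt]]
                if np.linalg.norm(c - n) < 1.8:
                    bonds.append((idx[key("C")], idx[nxt]))
        for b1, b2 in self.cs.inter_residue_bonds:
            if b1 in idx and b2 in idx:
                bonds.append((idx[b1], idx[b2]))
        return sorted(set(tuple(sorted(b)) for b in bonds))

    def _build_pairs(self) -> None:
        n = len(self.atoms)
        self.pair_i, self.pair_j, self.pair_scale, self.p13 = \
            build_exclusions(n, self.bonds)
        self.bond_idx = np.array(self.bonds, dtype=int).reshape(-1, 2)
        self.bond_r0 = self._ideal_distances(self.bond_idx)
        self.r13_0 = self._ideal_distances(self.p13)

    def _ideal_distances(self, idx: np.ndarray) -> np.ndarray:
        """Restraint targets from ideal template geometry; pairs without
        a template value keep their input distance."""
        residues = self.cs.receptor + self.cs.peptide
        res_of, name_of = [], []
        for r in residues:
            for a in r.atoms:
                res_of.append(r)
                name_of.append(a.name)
        out = np.empty(len(idx))
        for k, (i, j) in enumerate(idx):
            ri, rj = res_of[i], res_of[j]
            ni, nj = name_of[i], name_of[j]
            d_in = float(np.linalg.norm(self.coords0[i] - self.coords0[j]))
            if ri is rj:
                d = _intra_ideal(ri.code, ni, nj)
            elif ri.chain_id == rj.chain_id \
                    and abs(ri.index - rj.index) == 1:
                a, b = (ni, nj) if ri.index < rj.index else (nj, ni)
                d = _LINK_IDEAL.get((a, b))
            elif {ni, nj} == {"SG"}:
                d = 2.05
            else:
                d = None  # staple closures, other links: keep as-built
            out[k] = d if d is not None else d_in
        return out

    # -- energy -------------------------------------------------------------

    def energy_grad(self, xyz: np.ndarray, include_solvation: bool = True,
                    pair_mask: np.ndarray | None = None
                    ) -> tuple[float, np.ndarray]:
        i, j, sc = self.pair_i, self.pair_j, self.pair_scale
        if pair_mask is not None:
            i, j, sc = i[pair_mask], j[pair_mask], sc[pair_mask]
        dvec = xyz[i] - xyz[j]
        r = np.linalg.norm(dvec, axis=1)
        r = np.maximum(r, _R_FLOOR)
        rm = self.rmin[i] + self.rmin[j]
        eps = np.sqrt(self.eps[i] * self.eps[j])
        s6 = (rm / r) ** 6
        e_vdw = sc * eps * (s6 ** 2 - 2.0 * s6)
        de_vdw = sc * (-12.0 * eps / r) * (s6 ** 2 - s6)
        kqq = self.params.coulomb_constant * self.q[i] * self.q[j] / 4.0
        e_coul = sc * kqq / r ** 2
        de_coul = sc * (-2.0 * kqq / r ** 3)
        energy = float(e_vdw.sum() + e_coul.sum())
        dedr = de_vdw + de_coul
        if include_solvation:
            xi = (r - self.rmin[i]) / self.lam[i]
            xj = (r - self.rmin[j]) / self.lam[j]
            gi = self.dg[i] / (2 * np.sqrt(np.pi) * self.lam[i] * r ** 2) \
                * np.exp(-xi ** 2) * self.vol[j]
            gj = self.dg[j] / (2 * np.sqrt(np.pi) * self.lam[j] * r ** 2) \
                * np.exp(-xj ** 2) * self.vol[i]
            energy += float(self.dg.sum() - (gi + gj).sum())
            dgi = gi * (-2.0 / r - 2.0 * xi / self.lam[i])
            dgj = gj * (-2.0 / r - 2.0 * xj / self.lam[j])
            dedr = dedr - dgi - dgj
        grad = np.zeros_like(xyz)
        f = (dedr / r)[:, None] * dvec
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)
        # geometry restraints
        for idx_arr, r0, k in ((self.bond_idx, self.bond_r0, K_BOND),
                               (self.p13, self.r13_0, K_13)):
            if len(idx_arr) == 0:
                continue
            dv = xyz[idx_arr[:, 0]] - xyz[idx_arr[:, 1]]
            rr = np.maximum(np.linalg.norm(dv, axis=1), 1e-9)
            energy += float((k * (rr - r0) ** 2).sum())
            fb = (2.0 * k * (rr - r0) / rr)[:, None] * dv
            np.add.at(grad, idx_arr[:, 0], fb)
            np.add.at(grad, idx_arr[:, 1], -fb)
        return energy, grad

    def energy(self, xyz: np.ndarray, include_solvation: bool = True) -> float:
        return self.energy_grad(xyz, include_solvation)[0]

    def interaction_pairs(self) -> np.ndarray:
        """Mask of receptor-peptide cross pairs."""
        return self.group[self.pair_i] != self.group[self.pair_j]

    def interaction_energy(self, xyz: np.ndarray) -> float:
        """Protein-peptide vdW + Coulomb interaction energy (no solvation,
        no restraints)."""
        mask = self.interaction_pairs()
        i, j = self.pair_i[mask], self.pair_j[mask]
        sc = self.pair_scale[mask]
        r = np.maximum(np.linalg.norm(xyz[i] - xyz[j], axis=1), _R_FLOOR)
        rm = self.rmin[i] + self.rmin[j]
        eps = np.sqrt(self.eps[i] * self.eps[j])
        s6 = (rm / r) ** 6
        e = sc * eps * (s6 ** 2 - 2.0 * s6) \
            + sc * self.params.coulomb_constant * self.q[i] * self.q[j] \
            / (4.0 * r ** 2)
        return float(e.sum())


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def _gradient_descent(system: System, xyz: np.ndarray, movable: np.ndarray,
                      gtol: float = 0.05, max_iter: int = 2000
                      ) -> tuple[np.ndarray, bool]:
    """Quasi-Newton (L-BFGS) minimization restricted to movable atoms.

    Fixed atoms are excluded from the optimization vector so they cannot
    move; the result is accepted only if it lowers the energy, which
    keeps the per-round non-increasing contract exact."""
    from scipy.optimize import minimize as _scipy_minimize

    if not movable.any():
        return xyz.copy(), True
    mov = np.where(movable)[0]
    x_full = xyz.copy()

    def fun(v):
        x_full[mov] = v.reshape(-1, 3)
        e, g = system.energy_grad(x_full)
        return e, g[mov].ravel()

    x = xyz[mov].ravel().copy()
    e, g = fun(x)
    if np.abs(g).max() < gtol:
        return xyz.copy(), True  # already a stationary point
    budget = max_iter
    converged = False
    # restart after premature line-search terminations (stiff LJ walls)
    while budget > 0:
        res = _scipy_minimize(fun, x, jac=True, method="L-BFGS-B",
                              options={"maxiter": budget, "gtol": gtol,
                                       "ftol": 1e-14})
        budget -= max(res.nit, 1)
        e_new, g_new = fun(res.x)
        improved = e_new < e - 1e-10
        if improved:
            x, e, g = res.x, e_new, g_new
        if np.abs(g).max() < gtol:
            converged = True
            break
        if not improved:
            break
    out = xyz.copy()
    out[mov] = x.reshape(-1, 3)
    return out, converged


def movable_mask(system: System, protocol: str) -> np.ndarray:
    """Movable-atom mask for the two-round minimization protocol.

    Round 1: all backbone fixed; peptide side chains move, as do receptor
    side chains within 4 A of the peptide.  Round 2: receptor fixed,
    whole peptide free.
    """
    cs = system.cs
    n = len(system.atoms)
    movable = np.zeros(n, dtype=bool)
    pep_xyz = np.array([a.coords for r in cs.peptide for a in r.atoms])
    if protocol == "round1":
        bb = ("N", "CA", "C", "O", "OXT")
        for r in cs.peptide:
            for a in r.atoms:
                if a.name not in bb:
                    movable[system.key_to_idx[(a.chain_id, a.residue_index,
                                               a.name)]] = True
        for r in cs.receptor:
            side = [a for a in r.atoms if a.name not in bb]
            if not side:
                continue
            dmin = min(np.linalg.norm(pep_xyz - a.coords, axis=1).min()
                       for a in side)
            if dmin < 4.0:
                for a in side:
                    movable[system.key_to_idx[(a.chain_id, a.residue_index,
                                               a.name)]] = True
    elif protocol == "round2":
        for r in cs.peptide:
            for a in r.atoms:
                movable[system.key_to_idx[(a.chain_id, a.residue_index,
                                           a.name)]] = True
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return movable


def minimize_complex(cs: ComplexStructure,
                     protocol: tuple[str, ...] = ("round1", "round2"),
                     params: ForceFieldParams | None = None,
                     gtol: float = 0.05, max_iter: int = 2000
                     ) -> ComplexStructure:
    """Two-round constrained minimization; returns an updated copy."""
    import copy

    cs = copy.deepcopy(cs)
    for stage in protocol:
        system = System(cs, params)
        xyz = system.xyz.copy()
        mask = movable_mask(system, stage)
        e0 = system.energy(xyz)
        x_new, converged = _gradient_descent(system, xyz, mask, gtol,
                                             max_iter)
        if not converged:
            warnings.warn(f"minimization did not converge in {stage}; "
                          "returning best-so-far", RuntimeWarning)
        if system.energy(x_new) > e0 + 1e-9:
            x_new = xyz
        k = 0
        for r in cs.receptor + cs.peptide:
            for a in r.atoms:
                a.coords = x_new[k]
                k += 1
    return cs


# ---------------------------------------------------------------------------
# binding-energy flavors
# ---------------------------------------------------------------------------

def _internal_energy(residues: list[Residue], capped: bool,
                     params: ForceFieldParams) -> tuple["System", float]:
    from .structures import ComplexStructure as CS

    # a single-component pseudo-complex reusing System topology machinery
    dummy = CS(receptor=[], peptide=list(residues), peptide_capped=capped)
    system = System(dummy, params)
    return system, system.energy(system.xyz, include_solvation=False)


def binding_energy(cs: ComplexStructure, flavor: str = "simple",
                   params: ForceFieldParams | None = None,
                   minimize_kwargs: dict | None = None) -> float:
    """Rigid-body binding energy of the peptide to the receptor, kcal/mol."""
    params = params or default_params()
    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}")
    neutral = flavor == "neutralized"
    rec = type_residues(cs.receptor, params, neutral)
    pep = type_residues(cs.peptide, params, neutral,
                        capped=cs.peptide_capped)
    cross = nonbonded_energy(rec, pep, params)
    be = cross.total
    if flavor == "strain":
        system, e_in_complex = _internal_energy(cs.peptide,
                                                cs.peptide_capped, params)
        movable = np.ones(len(system.atoms), dtype=bool)
        kw = dict(gtol=0.05, max_iter=500)
        kw.update(minimize_kwargs or {})
        x_min, _ = _gradient_descent(system, system.xyz.copy(), movable, **kw)
        e_min = system.energy(x_min, include_solvation=False)
        be += e_in_complex - min(e_min, e_in_complex)
    elif flavor == "solvated":
        from .descriptors import compute_burial

        solv_c = solvation_energy(rec + pep, params)
        solv_r = solvation_energy(rec, params)
        solv_p = solvation_energy(pep, params)
        be += solv_c - solv_r - solv_p
        burial = compute_burial(cs)
        be -= params.sasa_scale * burial.buried_sa
    return float(be)


def energy_breakdown(cs: ComplexStructure, flavor: str = "simple",
                     params: ForceFieldParams | None = None
                     ) -> EnergyBreakdown:
    """Component-wise binding energy for reporting."""
    params = params or default_params()
    neutral = flavor == "neutralized"
    rec = type_residues(cs.receptor, params, neutral)
    pep = type_residues(cs.peptide, params, neutral,
                        capped=cs.peptide_capped)
    cross = nonbonded_energy(rec, pep, params)
    solvation = nonpolar = 0.0
    if flavor == "solvated":
        from .descriptors import compute_burial

        solvation = (solvation_energy(rec + pep, params)
                     - solvation_energy(rec, params)
                     - solvation_energy(pep, params))
        nonpolar = -params.sasa_scale * compute_burial(cs).buried_sa
    return EnergyBreakdown(vdw=cross.vdw, coulomb=cross.coulomb,
                           solvation=solvation, nonpolar_sasa=nonpolar)
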