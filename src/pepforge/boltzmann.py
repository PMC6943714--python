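"""Boltzmann-weighted binding-affinity estimation from constrained local
sampling of a peptide around a known bound backbone.

The peptide is sampled in torsion space plus rigid-body coordinates while
the protein stays rigid.  Non-terminal backbone heavy atoms are tied to
the reference (bound) backbone by a flat-bottom harmonic well: motion
within the tolerance (1.0 A) is free, beyond it a harmonic penalty
applies.  The first and last peptide residues are unconstrained.

Each independent run returns its minimum-total-energy pose; the final
affinity score is the Boltzmann-weighted (by total energy) average of the
protein-peptide interaction energy over those per-run minima.  The
interaction energy deliberately excludes intra-peptide terms, so no
strain contribution enters the score.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energetics import ForceFieldParams, default_params, type_residues, \
    _param_arrays
from .geometry import dihedral, kabsch_rmsd, rotation_about_axis
from .mcsam import KB, SamplerEnergy, TorsionSpace
from .structures import ComplexStructure, PeptideBuilder

_BB_HEAVY = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class BackboneConstraint:
    tolerance: float = 1.0            # A of free motion
    force_constant: float = 10.0      # kcal/(mol*A^2)
    excluded_per_end: int = 1         # terminal residues left free

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")


@dataclass
class BindingRun:
    x: np.ndarray                     # torsions + rigid-body vector
    xyz: np.ndarray                   # peptide coordinates of the pose
    e_total: float                    # internal + interaction + constraint
    e_inter: float                    # protein-peptide interaction only


@dataclass
class BoltzmannEstimate:
    runs: list[BindingRun]
    temperature: float
    weights: np.ndarray
    affinity: float


@dataclass
class BoltzmannConfig:
    runs: int = 100
    steps_per_run: int = 2000
    t_start: float = 600.0
    t_end: float = 300.0
    sigma_torsion: float = 20.0
    sigma_trans: float = 0.3
    sigma_rot: float = 5.0            # degrees
    p_rigid: float = 0.3
    minimize_maxfun: int = 30


def constrained_indices(builder: PeptideBuilder,
                        constraint: BackboneConstraint) -> np.ndarray:
    k = constraint.excluded_per_end
    lo, hi = k, builder.n_res - 1 - k
    return np.array([i for i, (res_i, name, _) in
                     enumerate(builder.atom_meta)
                     if name in _BB_HEAVY and lo <= res_i <= hi], dtype=int)


def constraint_energy(xyz: np.ndarray, reference: np.ndarray,
                      indices: np.ndarray,
                      constraint: BackboneConstraint) -> float:
    """Flat-bottom harmonic well on constrained backbone atoms."""
    if len(indices) == 0:
        return 0.0
    d = np.linalg.norm(xyz[indices] - reference[indices], axis=1)
    over = np.maximum(0.0, d - constraint.tolerance)
    return float(constraint.force_constant * (over ** 2).sum())


def _measure_torsions(cs: ComplexStructure, builder: PeptideBuilder) -> dict:
    """Read phi/psi/omega/chi of the complexed peptide from coordinates."""
    from .mcsam import residues_to_xyz

    xyz = residues_to_xyz(cs.peptide, builder)
    ix = builder.index
    n = builder.n_res
    tor = builder.default_torsions()
    for i in range(n):
        N, CA, C = (xyz[ix[(i, a)]] for a in ("N", "CA", "C"))
        if i > 0:
            pC = xyz[ix[(i - 1, "C")]]
            pCA = xyz[ix[(i - 1, "CA")]]
            tor["phi"][i] = dihedral(pC, N, CA, C)
            tor["omega"][i] = dihedral(pCA, pC, N, CA)
        if i < n - 1:
            tor["psi"][i] = dihedral(N, CA, C, xyz[ix[(i + 1, "N")]])
        else:
            tor["psi"][i] = dihedral(N, CA, C, xyz[ix[(i, "O")]]) - 180.0
        tpl_chis = tor["chi"][i]
        for e in builder.tpls[i].side_chain:
            if e.torsion_dof is not None and len(e.torsion_dof) == 2:
                a, b, c = (xyz[ix[(i, r)]] for r in e.refs)
                tpl_chis[e.torsion_dof[1] - 1] = dihedral(
                    a, b, c, xyz[ix[(i, e.name)]])
    return tor


def _fit_transform(mobile: np.ndarray, target: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


class BindingSystem:
    """Energy terms for constrained in-site sampling of one complex."""

    def __init__(self, cs: ComplexStructure,
                 constraint: BackboneConstraint | None = None,
                 params: ForceFieldParams | None = None):
        self.params = params or default_params()
        self.constraint = constraint or BackboneConstraint()
        self.cs = cs
        codes = [r.code for r in cs.peptide]
        self.builder = PeptideBuilder(codes, chain_id=cs.peptide[0].chain_id,
                                      capped=cs.peptide_capped)
        self.space = TorsionSpace(self.builder)
        self.internal = SamplerEnergy(self.builder, self.params)
        rec_typed = type_residues(cs.receptor, self.params)
        self.rec_xyz, self.rec_rmin, self.rec_eps, self.rec_q = \
            _param_arrays(rec_typed, self.params)
        # reference pose: measured torsions, rebuilt and fitted onto the
        # bound peptide coordinates
        from .mcsam import residues_to_xyz

        self.ref_xyz = residues_to_xyz(cs.peptide, self.builder)
        tor0 = _measure_torsions(cs, self.builder)
        vec0 = np.array([
            tor0[e[0]][e[1]] if e[0] != "chi" else tor0["chi"][e[1]][e[2]]
            for e in self.space.entries])
        local0 = self.builder.build(self.space.to_torsions(vec0))
        self.rot0, self.tr0 = _fit_transform(local0, self.ref_xyz)
        self.x0 = np.concatenate([vec0, np.zeros(6)])
        self.cons_idx = constrained_indices(self.builder, self.constraint)
        self.pivot = self.ref_xyz.mean(axis=0)

    # -- pose geometry -------------------------------------------------------

    def pose_xyz(self, x: np.ndarray) -> np.ndarray:
        vec, rb = x[:self.space.n], x[self.space.n:]
        local = self.builder.build(self.space.to_torsions(vec))
        xyz = (self.rot0 @ local.T).T + self.tr0
        ang = np.linalg.norm(rb[3:])
        if ang > 1e-12:
            r = rotation_about_axis(rb[3:] / ang, np.rad2deg(ang))
            xyz = (r @ (xyz - self.pivot).T).T + self.pivot
        return xyz + rb[:3]

    # -- energies ------------------------------------------------------------

    def interaction(self, pep_xyz: np.ndarray) -> float:
        d = np.linalg.norm(pep_xyz[:, None, :] - self.rec_xyz[None, :, :],
                           axis=-1)
        d = np.maximum(d, 0.4)
        rm = self.internal.rmin[:, None] + self.rec_rmin[None, :]
        eps = np.sqrt(self.internal.eps[:, None] * self.rec_eps[None, :])
        s6 = (rm / d) ** 6
        e = float((eps * (s6 ** 2 - 2 * s6)).sum())
        e += float((self.params.coulomb_constant
                    * self.internal.q[:, None] * self.rec_q[None, :]
                    / (4 * d ** 2)).sum())
        return e

    def e_total(self, x: np.ndarray) -> float:
        xyz = self.pose_xyz(x)
        return (self.internal(xyz) + self.interaction(xyz)
                + constraint_energy(xyz, self.ref_xyz, self.cons_idx,
                                    self.constraint))

    def evaluate(self, x: np.ndarray) -> BindingRun:
        xyz = self.pose_xyz(x)
        e_int = self.internal(xyz)
        e_inter = self.interaction(xyz)
        e_cons = constraint_energy(xyz, self.ref_xyz, self.cons_idx,
                                   self.constraint)
        return BindingRun(x=x, xyz=xyz, e_total=e_int + e_inter + e_cons,
                          e_inter=e_inter)


def run_binding_sampling(cs: ComplexStructure, runs: int = 100,
                         steps_per_run: int = 2000,
                         constraint: BackboneConstraint | None = None,
                         seed: int = 0,
                         config: BoltzmannConfig | None = None,
                         params: ForceFieldParams | None = None
                         ) -> list[BindingRun]:
    """Constrained MCSAM around the bound pose; one minimum per run."""
    cfg = config or BoltzmannConfig()
    if runs is not None:
        cfg = BoltzmannConfig(**{**cfg.__dict__, "runs": runs})
    if steps_per_run is not None:
        cfg = BoltzmannConfig(**{**cfg.__dict__,
                                 "steps_per_run": steps_per_run})
    system = BindingSystem(cs, constraint, params)
    nt = system.space.n
    out: list[BindingRun] = []
    for run in range(cfg.runs):
        rng = np.random.default_rng([seed, run])

        def minimized(x):
            res = _scipy_minimize(system.e_total, x, method="L-BFGS-B",
                                  options={"maxfun": cfg.minimize_maxfun,
                                           "maxiter": cfg.minimize_maxfun})
            x_best = res.x if res.fun <= system.e_total(x) else x
            return system.evaluate(x_best)

        current = minimized(system.x0.copy())
        best = current
        for step in range(cfg.steps_per_run):
            frac = step / max(cfg.steps_per_run - 1, 1)
            temp = cfg.t_start * (cfg.t_end / cfg.t_start) ** frac
            x = current.x.copy()
            if rng.random() < cfg.p_rigid:
                x[nt:nt + 3] += rng.normal(0.0, cfg.sigma_trans, 3)
                x[nt + 3:] += rng.normal(
                    0.0, np.deg2rad(cfg.sigma_rot), 3)
            else:
                k = rng.integers(nt)
                x[k] = ((x[k] + rng.normal(0.0, cfg.sigma_torsion)
                         + 180.0) % 360.0) - 180.0
            cand = minimized(x)
            de = cand.e_total - current.e_total
            if de <= 0 or rng.random() < np.exp(-de / (KB * temp)):
                current = cand
                if cand.e_total < best.e_total:
                    best = cand
        out.append(best)
    return out


def boltzmann_estimate(runs: list[BindingRun], temperature: float = 300.0
                       ) -> BoltzmannEstimate:
    """Boltzmann-weighted (by total energy) mean interaction energy."""
    if not runs:
        raise ValueError("empty run list")
    e_tot = np.array([r.e_total for r in runs])
    e_int = np.array([r.e_inter for r in runs])
    if temperature <= 0:
        w = np.zeros(len(runs))
        w[np.argmin(e_tot)] = 1.0
    else:
        z = -(e_tot - e_tot.min()) / (KB * temperature)
        w = np.exp(z)
        w /= w.sum()
    return BoltzmannEstimate(runs=runs, temperature=temperature, weights=w,
                             affinity=float((w * e_int).sum()))


def selectivity(complex_a: ComplexStructure, complex_b: ComplexStructure,
                runs: int = 20, steps_per_run: int = 100, seed: int = 0,
                temperature: float = 300.0,
                constraint: BackboneConstraint | None = None,
                config: BoltzmannConfig | None = None,
                params: ForceFieldParams | None = None) -> float:
    """Affinity(a) - affinity(b) for the same peptide under shared
    settings and seeds; negative favors receptor a."""
    est_a = boltzmann_estimate(
        run_binding_sampling(complex_a, runs, steps_per_run, constraint,
                             seed, config, params), temperature)
    est_b = boltzmann_estimate(
        run_binding_sampling(complex_b, runs, steps_per_run, constraint,
                             seed, config, params), temperature)
    return est_a.affinity - est_b.affinity
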