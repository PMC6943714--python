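"""Dihedral-space peptide conformational sampling (multiple-copy simulated
annealing with minimization, MCSAM).

A peptide conformation is a vector of free torsions (phi/psi per residue
plus side-chain chi angles; omega is held trans and bond lengths/angles
are fixed at template values).  Each independent run initializes a stack
of random, minimized conformations and performs Monte-Carlo-with-
minimization steps: a torsion perturbation (Ramachandran-biased for
phi/psi) followed by a short torsion-space minimization and Metropolis
acceptance on minimized energies along a geometric annealing ladder.
The stack keeps a bounded, diverse set of low-energy local minima;
ensembles are merged across runs, energy-window filtered, and clustered
by backbone+C-beta RMSD with a leader algorithm.

Ramachandran bias maps are precomputed per position by scanning the
(phi, psi) grid of the central residue of the flanking tripeptide and
Boltzmann-weighting the energies at a bias temperature; maps for
D residues are, by mirror symmetry, the point reflection of the map of
the fully mirrored tripeptide.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import templates as T
from .energetics import ForceFieldParams, build_exclusions, default_params
from .geometry import kabsch_rmsd
from .structures import PeptideBuilder, Residue, parse_sequence

KB = 0.0019872041  # kcal/(mol*K)
K_CLOSURE = 100.0  # macrocycle-closure restraint, kcal/(mol*A^2)
CLOSURE_R0 = 1.53

BB_CB_NAMES = ("N", "CA", "C", "O", "CB")


@dataclass
class SamplerConfig:
    runs: int = 20
    steps_per_run: int = 500
    init_size: int = 100
    capacity: int = 200
    diversity_radius: float = 0.5
    t_start: float = 1000.0
    t_end: float = 300.0
    t_bias: float = 600.0
    rama_prob: float = 0.8
    sigma_local: float = 30.0
    minimize_maxfun: int = 40
    rama_bins: int = 36


PAPER_PROFILE = SamplerConfig(runs=500, steps_per_run=10000)


@dataclass
class DihedralConformation:
    torsion_vec: np.ndarray
    energy: float
    _builder: PeptideBuilder = field(repr=False, default=None)
    _space: "TorsionSpace" = field(repr=False, default=None)
    _cartesian: np.ndarray | None = field(repr=False, default=None)

    @property
    def cartesian(self) -> np.ndarray:
        if self._cartesian is None:
            self._cartesian = self._builder.build(
                self._space.to_torsions(self.torsion_vec))
        return self._cartesian

    @property
    def torsions(self) -> dict:
        return self._space.to_torsions(self.torsion_vec)


class TorsionSpace:
    """Mapping between a flat torsion vector and per-residue torsions."""

    def __init__(self, builder: PeptideBuilder):
        self.builder = builder
        self.entries: list[tuple] = []
        for i, code in enumerate(builder.codes):
            self.entries.append(("phi", i))
            self.entries.append(("psi", i))
            for k in range(T.get_template(code).n_chi):
                self.entries.append(("chi", i, k))
        self.n = len(self.entries)
        self._chi_defaults = [np.array(T.default_chis(c))
                              for c in builder.codes]

    def to_torsions(self, vec: np.ndarray) -> dict:
        nres = self.builder.n_res
        tor = {"phi": np.zeros(nres), "psi": np.zeros(nres),
               "omega": np.full(nres, 180.0),
               "chi": [d.copy() for d in self._chi_defaults]}
        for v, e in zip(vec, self.entries):
            if e[0] == "chi":
                tor["chi"][e[1]][e[2]] = v
            else:
                tor[e[0]][e[1]] = v
        return tor

    def random(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(-180.0, 180.0, self.n)


class RamachandranMap:
    """Per-position (phi, psi) probability grid, 10-degree bins."""

    def __init__(self, grid: np.ndarray, bins: int):
        total = grid.sum()
        if total <= 0:
            raise ValueError("empty probability grid")
        self.grid = grid / total
        self.bins = bins
        self.width = 360.0 / bins
        self._flat = self.grid.ravel()
        self._cum = np.cumsum(self._flat)

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        k = int(np.searchsorted(self._cum, rng.random()))
        i, j = divmod(min(k, self.bins ** 2 - 1), self.bins)
        phi = -180.0 + (i + rng.random()) * self.width
        psi = -180.0 + (j + rng.random()) * self.width
        return phi, psi

    def reflected(self) -> "RamachandranMap":
        """Point reflection (phi, psi) -> (-phi, -psi); bin centers map
        exactly onto bin centers, so this is a pure re-indexing."""
        return RamachandranMap(self.grid[::-1, ::-1].copy(), self.bins)


_GRID_CACHE: dict[tuple, np.ndarray] = {}


def _mirror_code(code: str) -> str:
    code = code.upper()
    if code in T.D_TO_L:
        return T.D_TO_L[code]
    if code in T.L_TO_D:
        return T.L_TO_D[code]
    return code  # achiral (GLY) or no mirror parameterized


def _tripeptide_grid(codes3: tuple[str, str, str],
                     params: ForceFieldParams, t_bias: float,
                     bins: int) -> np.ndarray:
    builder = PeptideBuilder(list(codes3), capped=True)
    energy = SamplerEnergy(builder, params)
    # flanking residues fully extended: (180, 180) is its own mirror
    # image, so achiral tripeptides give exactly point-symmetric maps
    tor = builder.default_torsions(phi=180.0, psi=180.0)
    centers = -180.0 + (np.arange(bins) + 0.5) * (360.0 / bins)
    e = np.empty((bins, bins))
    for i, phi in enumerate(centers):
        for j, psi in enumerate(centers):
            tor["phi"][1] = phi
            tor["psi"][1] = psi
            e[i, j] = energy(builder.build(tor))
    e -= e.min()
    return np.exp(-e / (KB * t_bias))


def precompute_rama(sequence: str | list[str],
                    params: ForceFieldParams | None = None,
                    t_bias: float = 600.0, bins: int = 36
                    ) -> list[RamachandranMap]:
    """Ramachandran bias maps, one per sequence position.

    Position n is scored on the tripeptide of residues (n-1, n, n+1),
    with alanine standing in for a missing neighbor at chain termini.
    """
    params = params or default_params()
    codes = parse_sequence(sequence)[0] if isinstance(sequence, str) \
        else [c.upper() for c in sequence]
    # tripeptide grids are expensive; share them process-wide for the
    # default parameter set
    if params is default_params() and (t_bias, bins) == (600.0, 36):
        cache = _GRID_CACHE
    else:
        cache = {}
    maps = []
    for n, code in enumerate(codes):
        is_d = code in T.D_TO_L
        pad = "DAL" if is_d else "ALA"  # missing neighbors match chirality
        prev = codes[n - 1] if n > 0 else pad
        nxt = codes[n + 1] if n + 1 < len(codes) else pad
        triple = (prev, code, nxt)
        if is_d:
            # mirror symmetry: compute the all-mirrored tripeptide's map
            # and reflect it through the origin
            triple = tuple(_mirror_code(c) for c in triple)
        if triple not in cache:
            cache[triple] = _tripeptide_grid(triple, params, t_bias, bins)
        m = RamachandranMap(cache[triple].copy(), bins)
        maps.append(m.reflected() if is_d else m)
    return maps


class SamplerEnergy:
    """Nonbonded + solvation energy of a builder-defined peptide topology,
    with harmonic restraints maintaining macrocycle-closure bonds."""

    def __init__(self, builder: PeptideBuilder,
                 params: ForceFieldParams | None = None):
        params = params or default_params()
        self.params = params
        typed = []
        for res_i, name, el in builder.atom_meta:
            tname, q = params.assign(builder.codes[res_i], name, el)
            typed.append((tname, q))
        self.rmin = np.array([params.types[t].rmin_half for t, _ in typed])
        self.eps = np.array([params.types[t].epsilon for t, _ in typed])
        self.q = np.array([q for _, q in typed])
        self.dg = np.array([params.types[t].dg_ref for t, _ in typed])
        self.vol = np.array([params.types[t].volume for t, _ in typed])
        self.lam = np.array([params.types[t].lam for t, _ in typed])
        self.pair_i, self.pair_j, self.scale, _ = build_exclusions(
            builder.n_atoms, builder.bonds)
        self.closures = []
        if builder.cyclic:
            self.closures.append((builder.index[(builder.n_res - 1, "C")],
                                  builder.index[(0, "N")]))
        sb = builder.staple_bond()
        if sb is not None:
            (c1, i1, a1), (c2, i2, a2) = sb
            self.closures.append((builder.index[(i1 - 1, a1)],
                                  builder.index[(i2 - 1, a2)]))
        # closure bonds are restrained, not excluded pairs; drop their
        # nonbonded term so the restraint dominates
        for (i, j) in self.closures:
            mask = (self.pair_i == min(i, j)) & (self.pair_j == max(i, j))
            self.scale[mask] = 0.0

    def __call__(self, xyz: np.ndarray) -> float:
        i, j, sc = self.pair_i, self.pair_j, self.scale
        r = np.maximum(np.linalg.norm(xyz[i] - xyz[j], axis=1), 0.4)
        rm = self.rmin[i] + self.rmin[j]
        eps = np.sqrt(self.eps[i] * self.eps[j])
        s6 = (rm / r) ** 6
        e = float((sc * eps * (s6 ** 2 - 2 * s6)).sum())
        e += float((sc * self.params.coulomb_constant * self.q[i] * self.q[j]
                    / (4 * r ** 2)).sum())
        xi = (r - self.rmin[i]) / self.lam[i]
        xj = (r - self.rmin[j]) / self.lam[j]
        gi = self.dg[i] / (2 * np.sqrt(np.pi) * self.lam[i] * r ** 2) \
            * np.exp(-xi ** 2) * self.vol[j]
        gj = self.dg[j] / (2 * np.sqrt(np.pi) * self.lam[j] * r ** 2) \
            * np.exp(-xj ** 2) * self.vol[i]
        e += float(self.dg.sum() - (gi + gj).sum())
        for (a, b) in self.closures:
            d = np.linalg.norm(xyz[a] - xyz[b])
            e += K_CLOSURE * (d - CLOSURE_R0) ** 2
        return e


# ---------------------------------------------------------------------------
# RMSD and clustering
# ---------------------------------------------------------------------------

def bb_cb_indices(builder: PeptideBuilder) -> np.ndarray:
    return np.array([k for k, (_, name, _) in enumerate(builder.atom_meta)
                     if name in BB_CB_NAMES])


def rmsd_bb_cb(xyz_a: np.ndarray, xyz_b: np.ndarray,
               indices: np.ndarray) -> float:
    """Optimal-superposition RMSD over backbone + C-beta atoms."""
    if xyz_a.shape != xyz_b.shape:
        raise ValueError("topology mismatch")
    return kabsch_rmsd(xyz_a[indices], xyz_b[indices])


def residues_to_xyz(residues: list[Residue], builder: PeptideBuilder
                    ) -> np.ndarray:
    """Coordinates of ``residues`` in the builder's atom order."""
    out = np.empty((builder.n_atoms, 3))
    for k, (res_i, name, _) in enumerate(builder.atom_meta):
        out[k] = residues[res_i].atom(name).coords
    return out


@dataclass
class ConformationStack:
    capacity: int = 200
    diversity_radius: float = 0.5
    members: list[DihedralConformation] = field(default_factory=list)
    _indices: np.ndarray | None = None

    def push(self, conf: DihedralConformation) -> None:
        idx = self._indices
        if idx is not None and self.diversity_radius > 0:
            for k, m in enumerate(self.members):
                if rmsd_bb_cb(conf.cartesian, m.cartesian, idx) \
                        < self.diversity_radius:
                    if conf.energy < m.energy:
                        self.members[k] = conf
                        self.members.sort(key=lambda c: c.energy)
                    return
        if len(self.members) < self.capacity:
            self.members.append(conf)
            self.members.sort(key=lambda c: c.energy)
        elif conf.energy < self.members[-1].energy:
            self.members[-1] = conf
            self.members.sort(key=lambda c: c.energy)


@dataclass
class ConformerEnsemble:
    sequence: list[str]
    members: list[DihedralConformation]
    builder: PeptideBuilder

    def energies(self) -> np.ndarray:
        return np.array([m.energy for m in self.members])


@dataclass
class ClusterSet:
    representatives: list[DihedralConformation]
    members: list[list[int]]
    radius: float


def filter_window(ensemble: ConformerEnsemble, window: float = 15.0
                  ) -> ConformerEnsemble:
    """Keep conformations within ``window`` kcal/mol of the minimum."""
    if not ensemble.members:
        raise ValueError("empty ensemble")
    e0 = min(m.energy for m in ensemble.members)
    kept = [m for m in ensemble.members if m.energy <= e0 + window]
    return ConformerEnsemble(ensemble.sequence, kept, ensemble.builder)


def cluster_ensemble(ensemble: ConformerEnsemble, radius: float = 1.0
                     ) -> ClusterSet:
    """Leader clustering in energy order over backbone+CB RMSD."""
    idx = bb_cb_indices(ensemble.builder)
    members = sorted(ensemble.members, key=lambda c: c.energy)
    reps: list[DihedralConformation] = []
    assign: list[list[int]] = []
    for k, conf in enumerate(members):
        placed = False
        for r, rep in enumerate(reps):
            if rmsd_bb_cb(conf.cartesian, rep.cartesian, idx) <= radius:
                assign[r].append(k)
                placed = True
                break
        if not placed:
            reps.append(conf)
            assign.append([k])
    return ClusterSet(representatives=reps, members=assign, radius=radius)


def min_rmsd_vs_reference(clusters: ClusterSet, reference: np.ndarray,
                          builder: PeptideBuilder, top_k: int = 25) -> float:
    """Lowest RMSD to reference among the top_k cluster representatives
    (energy-ranked); if fewer clusters exist, all are used."""
    idx = bb_cb_indices(builder)
    reps = clusters.representatives[:top_k]
    if not reps:
        raise ValueError("no clusters")
    return min(rmsd_bb_cb(r.cartesian, reference, idx) for r in reps)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _minimize_torsions(fun, vec: np.ndarray, maxfun: int) -> tuple[np.ndarray, float]:
    res = _scipy_minimize(fun, vec, method="L-BFGS-B",
                          options={"maxfun": maxfun, "maxiter": maxfun})
    if res.fun <= fun(vec):
        return res.x, float(res.fun)
    return vec, float(fun(vec))


def run_sampling(sequence: str | list[str], runs: int | None = None,
                 steps_per_run: int | None = None, seed: int = 0,
                 config: SamplerConfig | None = None,
                 params: ForceFieldParams | None = None,
                 energy_fn=None, rama_maps=None) -> ConformerEnsemble:
    """Full MCSAM sampling of a peptide sequence.

    ``energy_fn(torsion_vec)`` may override the physical energy (used for
    rigged-potential validation); by default the nonbonded + solvation
    model evaluates rebuilt Cartesian coordinates.  Deterministic for a
    fixed ``seed``.
    """
    cfg = config or SamplerConfig()
    if runs is not None:
        cfg = SamplerConfig(**{**cfg.__dict__, "runs": runs})
    if steps_per_run is not None:
        cfg = SamplerConfig(**{**cfg.__dict__, "steps_per_run": steps_per_run})
    codes, cyclic = (parse_sequence(sequence) if isinstance(sequence, str)
                     else ([c.upper() for c in sequence], False))
    builder = PeptideBuilder(codes, cyclic=cyclic)
    space = TorsionSpace(builder)
    params = params or default_params()
    if energy_fn is None:
        engine = SamplerEnergy(builder, params)

        def energy_fn(vec):
            return engine(builder.build(space.to_torsions(vec)))
    if rama_maps is None:
        rama_maps = precompute_rama(codes, params, cfg.t_bias, cfg.rama_bins)
    phi_psi_pairs = [(i, space.entries.index(("phi", i)),
                      space.entries.index(("psi", i)))
                     for i in range(builder.n_res)]
    idx = bb_cb_indices(builder)

    all_members: list[DihedralConformation] = []
    for run in range(cfg.runs):
        rng = np.random.default_rng([seed, run])
        stack = ConformationStack(capacity=cfg.capacity,
                                  diversity_radius=cfg.diversity_radius,
                                  _indices=idx)

        def make_conf(vec):
            v, e = _minimize_torsions(energy_fn, vec, cfg.minimize_maxfun)
            return DihedralConformation(torsion_vec=v, energy=e,
                                        _builder=builder, _space=space)

        for _ in range(cfg.init_size):
            stack.push(make_conf(space.random(rng)))
        current = stack.members[0]
        n_steps = cfg.steps_per_run
        for step in range(n_steps):
            frac = step / max(n_steps - 1, 1)
            temp = cfg.t_start * (cfg.t_end / cfg.t_start) ** frac
            vec = current.torsion_vec.copy()
            if rng.random() < cfg.rama_prob:
                i, pk, sk = phi_psi_pairs[rng.integers(builder.n_res)]
                vec[pk], vec[sk] = rama_maps[i].sample(rng)
            else:
                k = rng.integers(space.n)
                vec[k] = ((vec[k] + rng.normal(0.0, cfg.sigma_local)
                           + 180.0) % 360.0) - 180.0
            cand = make_conf(vec)
            de = cand.energy - current.energy
            if de <= 0 or rng.random() < np.exp(-de / (KB * temp)):
                current = cand
                stack.push(cand)
        all_members.extend(stack.members)
    all_members.sort(key=lambda c: c.energy)
    return ConformerEnsemble(sequence=codes, members=all_members,
                             builder=builder)
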