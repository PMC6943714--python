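"""Fluorescence-anisotropy binding models and Kd fitting.

Direct titration: protein P titrated against a fluorophore-labeled
peptide L; the measured anisotropy interpolates between the free-peptide
value r0 and the complex value rb with the exactly solved 1:1 bound
fraction (quadratic mass balance):

    fb = [(Kd + Lt + Pt) - sqrt((Kd + Lt + Pt)^2 - 4 Lt Pt)] / (2 Lt)

Competitive titration: an unlabeled competitor displaces the labeled
peptide from a preformed complex (protein held at fixed Pt, labeled
peptide at fixed Lst).  The three-species equilibrium is solved exactly
through the cubic closed form (Wang-style):

    d = Kd1 + Kd2 + Lst + Lt - Pt
    e = (Lt - Pt) Kd1 + (Lst - Pt) Kd2 + Kd1 Kd2
    f = -Kd1 Kd2 Pt
    theta = arccos[(-2 d^3 + 9 d e - 27 f) / (2 sqrt((d^2 - 3 e)^3))]
    fb = (2 sqrt(d^2-3e) cos(theta/3) - d)
         / (3 Kd1 + 2 sqrt(d^2-3e) cos(theta/3) - d)

All concentrations are molar internally.  The assay assumption Pt > Lst
is flagged (not fatal) when violated, and competitive fits check that
the fitted baseline does not fall below the free-peptide anisotropy,
which would indicate an unintended competitor-peptide interaction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass
class DirectModel:
    r0: float
    rb: float
    kd: float       # M
    lt: float       # total labeled peptide, M
    pt: float = 0.0  # total protein, M

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.lt < 0 or self.pt < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass
class CompetitiveModel:
    kd1: float      # labeled peptide - protein, M
    kd2: float      # competitor - protein, M
    pt: float       # total protein, M
    lst: float      # total labeled peptide, M
    lt: float       # total unlabeled competitor, M
    r0: float
    rb: float

    def __post_init__(self):
        if self.kd1 <= 0 or self.kd2 <= 0:
            raise ValueError("dissociation constants must be positive")
        if min(self.pt, self.lst, self.lt) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.pt <= self.lst:
            warnings.warn("assay assumption violated: Pt <= Lst",
                          RuntimeWarning)


@dataclass
class TitrationCurve:
    conc: np.ndarray          # titrant concentration, M
    anisotropy: np.ndarray
    replicate: np.ndarray
    noise_sigma: float = 0.0


def bound_fraction_direct(kd: float, lt: float, pt: float) -> float:
    """Exact 1:1 bound fraction of the labeled peptide."""
    if lt <= 0:
        raise ValueError("lt must be positive")
    s = kd + lt + pt
    disc = max(s * s - 4.0 * lt * pt, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * lt)


def direct_anisotropy(model: DirectModel) -> float:
    fb = bound_fraction_direct(model.kd, model.lt, model.pt)
    return model.r0 + (model.rb - model.r0) * fb


def bound_fraction_competitive(kd1: float, kd2: float, pt: float,
                               lst: float, lt: float) -> float:
    """Exact bound fraction of the labeled species under competition."""
    if lst <= 0:
        raise ValueError("lst must be positive")
    if lt == 0:
        return bound_fraction_direct(kd1, lst, pt)
    d = kd1 + kd2 + lst + lt - pt
    e = (lt - pt) * kd1 + (lst - pt) * kd2 + kd1 * kd2
    f = -kd1 * kd2 * pt
    q = d * d - 3.0 * e
    if q <= 0:
        raise ValueError("cubic discriminant non-positive")
    arg = (-2.0 * d ** 3 + 9.0 * d * e - 27.0 * f) / (2.0 * np.sqrt(q ** 3))
    if arg > 1.0 + 1e-9 or arg < -1.0 - 1e-9:
        raise ValueError("arccos argument out of range")
    theta = np.arccos(np.clip(arg, -1.0, 1.0))
    root = 2.0 * np.sqrt(q) * np.cos(theta / 3.0) - d
    # The trigonometric form suffers catastrophic cancellation when one
    # constant dominates (theta near 0 or pi).  The free-protein root
    # P = root/3 of P^3 + d P^2 + e P + f = 0 is physically confined to
    # [0, Pt]; polish it there with safeguarded Newton/bisection in
    # extended precision.
    dl, el, fl = np.longdouble(d), np.longdouble(e), np.longdouble(f)

    def poly(p):
        return ((p + dl) * p + el) * p + fl

    lo, hi = np.longdouble(0.0), np.longdouble(pt)
    p = min(max(np.longdouble(root) / 3.0, lo), hi)
    flo = poly(lo)
    if poly(hi) * flo > 0:  # degenerate bracket; trust the trig root
        return float(max(root / 3.0, 0.0) / (kd1 + max(root / 3.0, 0.0)))
    for _ in range(200):
        fp = poly(p)
        if fp * flo <= 0:
            hi = p
        else:
            lo, flo = p, fp
        dpoly = (3.0 * p + 2.0 * dl) * p + el
        p_new = p - fp / dpoly if dpoly != 0 else p
        if not (lo < p_new < hi):
            p_new = (lo + hi) / 2.0
        if abs(p_new - p) <= 1e-18 * max(abs(p_new), np.longdouble(1e-30)):
            p = p_new
            break
        p = p_new
    p = float(max(p, 0.0))
    return p / (kd1 + p)


def competitive_anisotropy(model: CompetitiveModel) -> float:
    fb = bound_fraction_competitive(model.kd1, model.kd2, model.pt,
                                    model.lst, model.lt)
    return model.r0 + (model.rb - model.r0) * fb


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: dict[str, float]
    stderr: dict[str, float]
    converged: bool
    residuals: np.ndarray
    flags: list[str] = field(default_factory=list)


def _weights(curve: TitrationCurve) -> np.ndarray | None:
    """Per-point weights from replicate variance (>= 2 replicates)."""
    if len(np.unique(curve.replicate)) < 2:
        return None
    w = np.ones_like(curve.anisotropy)
    for c in np.unique(curve.conc):
        m = curve.conc == c
        if m.sum() >= 2:
            sd = curve.anisotropy[m].std(ddof=1)
            w[m] = 1.0 / max(sd, 1e-6)
    return w


def fit_direct(curve: TitrationCurve, lt: float,
               p0: dict | None = None) -> FitResult:
    """Fit (r0, rb, kd) of the 1:1 model; protein concentration is the
    titrated variable."""
    conc = np.asarray(curve.conc, dtype=float)
    y = np.asarray(curve.anisotropy, dtype=float)
    if len(np.unique(conc)) < 5:
        raise ValueError("degenerate design: need >= 5 distinct "
                         "concentrations")
    w = _weights(curve)
    p0 = p0 or {}
    guess = np.array([
        p0.get("r0", y.min()), p0.get("rb", y.max()),
        np.log(p0.get("kd", np.median(conc[conc > 0]) or 1e-8)),
    ])

    def resid(p):
        r0, rb, logkd = p
        fb = np.array([bound_fraction_direct(np.exp(logkd), lt, pt)
                       for pt in conc])
        r = r0 + (rb - r0) * fb - y
        return r * w if w is not None else r

    sol = least_squares(resid, guess, method="lm", max_nfev=5000)
    return _finish(sol, ("r0", "rb", "kd"), log_params=("kd",))


def fit_competitive(curve: TitrationCurve, kd1: float, pt: float = 250e-9,
                    lst: float = 50e-9, p0: dict | None = None) -> FitResult:
    """Fit (r0, rb, kd2) of the competitive model; the competitor
    concentration is the titrated variable."""
    conc = np.asarray(curve.conc, dtype=float)
    y = np.asarray(curve.anisotropy, dtype=float)
    if len(np.unique(conc)) < 6:
        raise ValueError("degenerate design: need >= 6 distinct "
                         "concentrations")
    w = _weights(curve)
    p0 = p0 or {}
    guess = np.array([
        p0.get("r0", y.min()), p0.get("rb", y.max()),
        np.log(p0.get("kd2", kd1)),
    ])

    def model_y(p, c):
        r0, rb, logkd2 = p
        fb = np.array([bound_fraction_competitive(kd1, np.exp(logkd2),
                                                  pt, lst, ci)
                       for ci in c])
        return r0 + (rb - r0) * fb

    def resid(p):
        r = model_y(p, conc) - y
        return r * w if w is not None else r

    sol = least_squares(resid, guess, method="lm", max_nfev=5000)
    out = _finish(sol, ("r0", "rb", "kd2"), log_params=("kd2",))
    # control criterion: the observed final baseline (highest competitor
    # concentration) must not fall below the free-peptide anisotropy,
    # which would indicate an unintended competitor-tracer interaction
    tail = conc == conc.max()
    floor_obs = float(y[tail].mean())
    tail_sem = float(y[tail].std(ddof=1) / np.sqrt(tail.sum())) \
        if tail.sum() > 1 else 0.0
    margin = max(0.005, 3.0 * tail_sem)
    if floor_obs < out.params["r0"] - margin:
        out.flags.append("baseline below free-peptide anisotropy")
        warnings.warn("final baseline falls below the free-peptide "
                      "anisotropy", RuntimeWarning)
    floor_fit = model_y(sol.x, np.array([conc.max()]))[0]
    span = abs(model_y(sol.x, np.array([conc.min()]))[0] - floor_fit)
    if span < 0.02 * abs(out.params["rb"] - out.params["r0"]) + 1e-12:
        out.flags.append("kd2 unidentifiable: no displacement")
    return out


def _finish(sol, names, log_params=()) -> FitResult:
    J = sol.jac
    dof = max(len(sol.fun) - len(sol.x), 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        perr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        perr = np.full(len(sol.x), np.nan)
    params, stderr = {}, {}
    for k, (name, val, err) in enumerate(zip(names, sol.x, perr)):
        if name in log_params:
            params[name] = float(np.exp(val))
            stderr[name] = float(params[name] * err)  # delta method
        else:
            params[name] = float(val)
            stderr[name] = float(err)
    return FitResult(params=params, stderr=stderr,
                     converged=bool(sol.success), residuals=sol.fun)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_titration(model: DirectModel | CompetitiveModel,
                       design: np.ndarray, sigma: float = 0.0,
                       replicates: int = 3, seed: int = 0
                       ) -> TitrationCurve:
    """Noisy synthetic titration over a concentration series.

    For a direct model the design varies total protein; for a
    competitive model it varies the unlabeled competitor.
    """
    design = np.asarray(design, dtype=float)
    if design.size == 0:
        raise ValueError("empty design")
    rng = np.random.default_rng(seed)
    conc, ys, rep = [], [], []
    for r in range(replicates):
        for c in design:
            if isinstance(model, DirectModel):
                y = direct_anisotropy(DirectModel(
                    r0=model.r0, rb=model.rb, kd=model.kd, lt=model.lt,
                    pt=float(c)))
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    y = competitive_anisotropy(CompetitiveModel(
                        kd1=model.kd1, kd2=model.kd2, pt=model.pt,
                        lst=model.lst, lt=float(c), r0=model.r0,
                        rb=model.rb))
            conc.append(float(c))
            ys.append(y + (rng.normal(0.0, sigma) if sigma > 0 else 0.0))
            rep.append(r)
    return TitrationCurve(conc=np.array(conc), anisotropy=np.array(ys),
                          replicate=np.array(rep), noise_sigma=sigma)


def default_competition_design(n: int = 12, top: float = 1e-4,
                               dilution: float = 3.0) -> np.ndarray:
    """Serial-dilution competitor series (highest first), M."""
    return top / dilution ** np.arange(n)
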