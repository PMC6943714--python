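"""Structure-activity arithmetic and statistics.

Conversions between dissociation constants, pKd and relative binding
free energies (ddG = RT * ln(Kd/Kd_ref)); handling of qualitatively
inactive peptides by assigning a floor binding energy; Pearson
correlation and small OLS models; and the bundled fixture tables of the
conformational-sampling benchmark (per-peptide RMSD statistics) and the
prospective Ala-/D-scan of the stapled peptide ATSP-7041 (A8Q, Q9L)
against MDM2/MDMX.

Two thermal-energy constants ship with the prospective fixture: the
standard RT at 298 K (0.593 kcal/mol), which reproduces the printed
MDMX ddG column, and an effective RT of 0.815 kcal/mol which is the only
value consistent with the printed MDM2 ddG column.  The discrepancy is
in the source data; both are exposed and neither is silently corrected.
Correlations are unaffected because Pearson r is invariant under affine
rescaling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

RT_298 = 0.593                    # kcal/mol at 298 K
TABLE4_MDM2_EFFECTIVE_RT = 0.815  # reproduces the printed MDM2 ddG column
INACTIVE_FLOOR = -2.0             # kcal/mol assigned to inactive peptides

SCAN_METHODS = ("escore", "yscore", "boltzmann")


@dataclass
class AffinityRecord:
    peptide_id: str
    kd: float | None = None          # nM
    active: bool = True
    ddg_exp: float | None = None     # kcal/mol
    binding_energy: float | None = None
    calc_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kd is not None and self.kd <= 0:
            raise ValueError("kd must be positive")
        if not self.active and self.kd is not None:
            raise ValueError("inactive records have no kd")

    @property
    def pkd(self) -> float | None:
        if self.kd is None:
            return None
        return -math.log10(self.kd * 1e-9)


@dataclass
class CorrelationResult:
    n: int
    r: float

    @property
    def r2(self) -> float:
        return self.r ** 2


def kd_to_ddg(kd: float, kd_ref: float, rt: float = RT_298) -> float:
    """Relative binding free energy RT*ln(Kd/Kd_ref), kcal/mol."""
    if kd <= 0 or kd_ref <= 0:
        raise ValueError("dissociation constants must be positive")
    return rt * math.log(kd / kd_ref)


def pkd_to_ddg(pkd: float, pkd_ref: float, rt: float = RT_298) -> float:
    return rt * math.log(10.0) * (pkd_ref - pkd)


def assign_inactive_floor(records: list[AffinityRecord],
                          floor: float = INACTIVE_FLOOR
                          ) -> tuple[list[AffinityRecord], int]:
    """Give inactive peptides a floor binding energy; returns the records
    and the number modified.  Active records are untouched; idempotent."""
    n_mod = 0
    for rec in records:
        if not rec.active and rec.binding_energy != floor:
            rec.binding_energy = floor
            n_mod += 1
    return records, n_mod


def pearson(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r = stats.pearsonr(x, y)[0]
    return CorrelationResult(n=len(x), r=float(r))


def ols_two_term(x1, x2, y) -> float:
    """R^2 of an OLS fit y ~ 1 + x1 + x2; rank deficiency is an error."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x1) == len(x2) == len(y)) or len(y) < 4:
        raise ValueError("need at least 4 complete rows")
    X = np.column_stack([np.ones_like(x1), x1, x2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("pepforge") / "data" / name


def load_table2() -> pd.DataFrame:
    """Per-peptide conformational-sampling results (16 benchmark PDBs)."""
    with _fixture_path("table2.csv").open() as f:
        df = pd.read_csv(f)
    df["stapled"] = df["description"].str.contains("Stapled").astype(int)
    return df


def load_table4() -> pd.DataFrame:
    """Prospective Ala-/D-scan of ATSP-7041 (A8Q, Q9L) with measured Kd
    and calculated ddG columns."""
    with _fixture_path("table4.csv").open() as f:
        return pd.read_csv(f)


def table2_stats(df: pd.DataFrame | None = None) -> dict:
    """Summary statistics of the sampling benchmark fixture."""
    if df is None:
        df = load_table2()
    if len(df) != 16 or df[["min_rmsd", "best25", "best100",
                            "best500"]].isna().any().any():
        raise ValueError("fixture incomplete: expected 16 complete rows")
    out = {
        "mean_min_rmsd": float(df["min_rmsd"].mean()),
        "mean_best25": float(df["best25"].mean()),
        "mean_best100": float(df["best100"].mean()),
        "mean_best500": float(df["best500"].mean()),
        "mean_cluster_size": float(df["cluster_size"].mean()),
        "pearson_r_length_min_rmsd": pearson(df["n_aa"], df["min_rmsd"]).r,
        "ols_length_staple_r2": ols_two_term(df["n_aa"], df["stapled"],
                                             df["min_rmsd"]),
    }
    return out


def table4_correlations(df: pd.DataFrame | None = None,
                        include_wt: bool = False
                        ) -> dict[tuple[str, str], CorrelationResult]:
    """r^2 of each calculated-ddG column against experimental MDM2 ddG,
    per scan (mutant rows only unless ``include_wt``)."""
    if df is None:
        df = load_table4()
    cols = {m: f"{m}_ddg" for m in SCAN_METHODS}
    for c in cols.values():
        if c not in df.columns:
            raise ValueError(f"missing column {c}")
    out = {}
    for scan in ("ala", "d"):
        sub = df[df["scan"] == scan]
        for method, col in cols.items():
            x = list(sub["ddg_mdm2"].astype(float))
            y = list(sub[col].astype(float))
            if include_wt:
                x.append(0.0)
                y.append(0.0)
            out[(scan, method)] = pearson(x, y)
    return out
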