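"""Empirical scoring: the four-term interface score, the packing-score
combiner, buried-surface-area scoring, and min-max consensus.

The empirical binding-affinity score is a fixed linear regression over
the four interface descriptors,

    BA = -1.94 + 0.16*dXH - 0.68*dXC - 0.52*XHB - 0.41*XSB   [kcal/mol]

with more negative values meaning stronger predicted binding.  The
coefficients are applied as published, without refitting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .descriptors import InterfaceDescriptors, PackingMetrics

PACKING_WEIGHTS = (0.145, 0.390, 0.465)


@dataclass(frozen=True)
class EscoreCoefficients:
    intercept: float = -1.94
    w_h: float = 0.16
    w_c: float = -0.68
    w_hb: float = -0.52
    w_sb: float = -0.41


@dataclass
class ScoreVector:
    method: str
    values: dict[str, float]
    orientation: str  # "lower_better" | "higher_better"

    def __post_init__(self):
        if not self.values:
            raise ValueError("score vector needs at least one entry")
        if self.orientation not in ("lower_better", "higher_better"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def escore(desc: InterfaceDescriptors,
           coeffs: EscoreCoefficients = EscoreCoefficients()) -> float:
    """Empirical binding affinity (kcal/mol, lower = stronger)."""
    terms = (desc.dXH, desc.dXC, desc.XHB, desc.XSB)
    if not all(math.isfinite(t) for t in terms):
        raise ValueError("invalid descriptors")
    return (coeffs.intercept + coeffs.w_h * desc.dXH + coeffs.w_c * desc.dXC
            + coeffs.w_hb * desc.XHB + coeffs.w_sb * desc.XSB)


def buried_sa_score(desc: InterfaceDescriptors) -> float:
    """Buried-surface-area score (higher area = stronger; sign-flipped so
    lower is better, matching the other scores' orientation)."""
    return -desc.buried_SA


def packing_score(metrics: PackingMetrics,
                  weights: tuple[float, float, float] = PACKING_WEIGHTS
                  ) -> float:
    """Weighted average of the three packing-normality Z-scores."""
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    m = (metrics.dihedral_normality, metrics.packing1d_normality,
         metrics.packing3d_normality)
    return sum(w * x for w, x in zip(weights, m))


def consensus(score_vectors: list[ScoreVector]) -> dict[str, float]:
    """Mean of min-max normalized scores, best -> 1, worst -> 0.

    All vectors must cover the same peptides; a constant vector has no
    defined normalization and is rejected.
    """
    if not score_vectors:
        raise ValueError("no score vectors")
    ids = set(score_vectors[0].values)
    if len(ids) < 2:
        raise ValueError("need at least two peptides for min-max scaling")
    for sv in score_vectors[1:]:
        if set(sv.values) != ids:
            raise ValueError("score vectors cover different peptide ids")
    normalized: list[dict[str, float]] = []
    for sv in score_vectors:
        vals = sv.values
        lo, hi = min(vals.values()), max(vals.values())
        if hi - lo < 1e-12:
            raise ValueError(f"degenerate score range in {sv.method!r}")
        if sv.orientation == "lower_better":
            norm = {k: (hi - v) / (hi - lo) for k, v in vals.items()}
        else:
            norm = {k: (v - lo) / (hi - lo) for k, v in vals.items()}
        normalized.append(norm)
    return {k: sum(n[k] for n in normalized) / len(normalized)
            for k in sorted(ids)}
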