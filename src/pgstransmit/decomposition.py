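"""Standardized PGS effects and the variance decomposition.

The fitted regression paths (g_tw, g_m, g_f) are standardized against
the model-implied phenotype variance, and the explained phenotype
variance is split into a direct-genetic-transmission share (the child's
own PGS path) and a genetic-nurture share (everything routed through the
parental PGS paths, including the child-parent cross-covariance terms).

Because the child's PGS is correlated with the parents' PGS (passive
gene-environment correlation), the cross terms can be negative; the
nurture share ``r2_gn = r2_total - r2_gt`` may then be negative and the
transmission share may exceed the total.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ModelParameters

__all__ = ["DecompositionResult", "implied_phenotype_variance",
           "standardize_effects", "variance_decomposition"]


@dataclass(frozen=True)
class DecompositionResult:
    """Standardized effects and phenotype-variance shares (proportions)."""

    g_tw_std: float
    g_m_std: float
    g_f_std: float
    r2_total: float
    r2_gt: float
    r2_gn: float
    v_phen: float

    def as_percent(self) -> dict:
        """R-squared shares on the percent scale, one-decimal rounding."""
        return {
            "r2_total_pct": round(100.0 * self.r2_total, 1),
            "r2_gt_pct": round(100.0 * self.r2_gt, 1),
            "r2_gn_pct": round(100.0 * self.r2_gn, 1),
        }


def implied_phenotype_variance(params: ModelParameters) -> float:
    """Model-implied variance of a twin's phenotype.

    ``V_phen = (g_tw^2 + g_m^2 + g_f^2) V_PGS
               + 2 g_tw (g_m + g_f) c + 2 g_m g_f r_a V_PGS + V_ADHD``
    with ``c = 0.5 V_PGS (1 + r_a)`` the parent-child PGS covariance.
    """
    params.validate()
    v, ra = params.v_pgs, params.r_a
    gt, gm, gf = params.g_tw, params.g_m, params.g_f
    c = 0.5 * v * (1.0 + ra)
    return ((gt ** 2 + gm ** 2 + gf ** 2) * v
            + 2.0 * gt * (gm + gf) * c
            + 2.0 * gm * gf * ra * v
            + params.v_adhd)


def standardize_effects(params: ModelParameters) -> tuple[float, float, float]:
    """Standardized paths ``g' = g * sqrt(V_PGS / V_phen)``."""
    v_phen = implied_phenotype_variance(params)
    if v_phen <= 0:
        raise ValueError(f"implied phenotype variance must be > 0, got {v_phen}")
    scale = (params.v_pgs / v_phen) ** 0.5
    return (params.g_tw * scale, params.g_m * scale, params.g_f * scale)


def variance_decomposition(params: ModelParameters) -> DecompositionResult:
    """Split the explained phenotype variance into transmission and nurture.

    ``r2_total`` is the share of phenotype variance explained by all
    three PGS jointly; ``r2_gt`` is the share explained with the
    parental direct paths removed (the child path alone,
    ``g_tw^2 V_PGS / V_phen``); ``r2_gn = r2_total - r2_gt`` is the
    remainder attributable to any mechanism involving parental PGS and
    may be negative when child and parent paths have opposite signs.
    """
    v_phen = implied_phenotype_variance(params)
    if v_phen <= 0:
        raise ValueError(f"implied phenotype variance must be > 0, got {v_phen}")
    r2_total = (v_phen - params.v_adhd) / v_phen
    r2_gt = params.g_tw ** 2 * params.v_pgs / v_phen
    g_std = standardize_effects(params)
    return DecompositionResult(
        g_tw_std=g_std[0], g_m_std=g_std[1], g_f_std=g_std[2],
        r2_total=r2_total, r2_gt=r2_gt, r2_gn=r2_total - r2_gt,
        v_phen=v_phen,
    )
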