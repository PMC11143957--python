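"""Model-implied means and covariances for a twin-family group.

The observed vector for one family is ordered

    (PGS_mother, PGS_father, PGS_twin1, PGS_twin2, pheno_twin1, pheno_twin2)

and the model implies, per zygosity group, a 6-vector of means and a 6x6
covariance matrix.  Two independent constructions are provided:

* :func:`build_implied_moments` — general path-model (RAM) algebra,
  ``cov = (I - A)^-1 S (I - A)^-T`` with the fixed 0.5 transmission paths
  parent -> child PGS and free phenotype regressions in ``A``;
* :func:`closed_form_moments` — hand-derived scalar formulas for every
  entry, used as an independent oracle (no matrix inversion).

MZ co-twins share one segregation deviation (implied twin-PGS correlation
exactly 1); DZ co-twins draw independent deviations, giving twin-PGS
covariance ``0.5 * v_pgs * (1 + r_a)`` — the same as the parent-child
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "ImpliedMoments",
    "VARIABLE_NAMES",
    "ZYGOSITIES",
    "build_implied_moments",
    "closed_form_moments",
    "moment_derivatives",
]

VARIABLE_NAMES = (
    "pgs_mother", "pgs_father", "pgs_twin1", "pgs_twin2",
    "pheno_twin1", "pheno_twin2",
)

ZYGOSITIES = ("MZ", "DZ")

# indices into the 6-vector
_M, _F, _T1, _T2, _A1, _A2 = range(6)


@dataclass(frozen=True)
class ImpliedMoments:
    """Implied mean vector and covariance matrix for one zygosity group."""

    mean: np.ndarray          # shape (6,)
    cov: np.ndarray           # shape (6, 6), symmetric PSD
    zygosity: str             # "MZ" or "DZ"

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    def correlation(self, i: int, j: int) -> float:
        """Implied correlation between variables ``i`` and ``j``."""
        c = self.cov
        return float(c[i, j] / np.sqrt(c[i, i] * c[j, j]))


def _check(params: ModelParameters, zygosity: str) -> None:
    params.validate()
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"zygosity must be one of {ZYGOSITIES}, got {zygosity!r}")


def _mean_vector(params: ModelParameters) -> np.ndarray:
    return np.array([params.mu_pgs] * 4 + [params.mu_adhd] * 2, dtype=float)


def build_implied_moments(params: ModelParameters, zygosity: str) -> ImpliedMoments:
    """Implied moments via general path-model (RAM) algebra.

    The asymmetric-path matrix ``A`` carries the fixed 0.5 entries from
    each parent's PGS to each twin's PGS and the free ``g`` paths from
    PGS to phenotype; the symmetric matrix ``S`` carries exogenous
    (co)variances: parental PGS variances and their ``r_a`` covariance,
    segregation-deviation variances (shared between MZ co-twins), and the
    residual phenotype block.  ``cov = (I - A)^-1 S (I - A)^-T``.
    """
    _check(params, zygosity)
    v, ra = params.v_pgs, params.r_a
    va = params.v_adhd
    rz = params.r_mz if zygosity == "MZ" else params.r_dz
    vs = params.segregation_variance

    A = np.zeros((6, 6))
    A[_T1, _M] = A[_T1, _F] = 0.5
    A[_T2, _M] = A[_T2, _F] = 0.5
    for tw, ph in ((_T1, _A1), (_T2, _A2)):
        A[ph, tw] = params.g_tw
        A[ph, _M] = params.g_m
        A[ph, _F] = params.g_f

    S = np.zeros((6, 6))
    S[_M, _M] = S[_F, _F] = v
    S[_M, _F] = S[_F, _M] = ra * v
    S[_T1, _T1] = S[_T2, _T2] = vs
    if zygosity == "MZ":
        # one shared segregation deviation
        S[_T1, _T2] = S[_T2, _T1] = vs
    S[_A1, _A1] = S[_A2, _A2] = va
    S[_A1, _A2] = S[_A2, _A1] = rz * va

    inv = np.linalg.inv(np.eye(6) - A)
    cov = inv @ S @ inv.T
    cov = 0.5 * (cov + cov.T)   # enforce exact symmetry against round-off
    return ImpliedMoments(mean=_mean_vector(params), cov=cov, zygosity=zygosity)


def closed_form_moments(params: ModelParameters, zygosity: str) -> ImpliedMoments:
    """Implied moments from hand-derived scalar formulas (oracle).

    With ``c = 0.5 * v_pgs * (1 + r_a)`` the parent-child PGS covariance:

    * every PGS variance is ``v_pgs``;
    * cov(mother, father) = ``r_a * v_pgs``;
    * cov(parent, twin) = ``c``;
    * cov(twin1, twin2 PGS) = ``v_pgs`` (MZ) or ``c`` (DZ);
    * phenotype rows follow from substituting
      ``pheno_i = g_tw * PGS_twi + g_m * PGS_m + g_f * PGS_f + e_i``.
    """
    _check(params, zygosity)
    v, ra, va = params.v_pgs, params.r_a, params.v_adhd
    rz = params.r_mz if zygosity == "MZ" else params.r_dz
    c = 0.5 * v * (1.0 + ra)
    ctt = v if zygosity == "MZ" else c

    # PGS block (mother, father, twin1, twin2)
    P = np.array([
        [v,      ra * v, c,   c],
        [ra * v, v,      c,   c],
        [c,      c,      v,   ctt],
        [c,      c,      ctt, v],
    ])

    # phenotype weights over (m, f, t1, t2)
    w1 = np.array([params.g_m, params.g_f, params.g_tw, 0.0])
    w2 = np.array([params.g_m, params.g_f, 0.0, params.g_tw])
    W = np.column_stack([w1, w2])

    E = va * np.array([[1.0, rz], [rz, 1.0]])

    cov = np.empty((6, 6))
    cov[:4, :4] = P
    cov[:4, 4:] = P @ W
    cov[4:, :4] = cov[:4, 4:].T
    cov[4:, 4:] = W.T @ P @ W + E
    return ImpliedMoments(mean=_mean_vector(params), cov=cov, zygosity=zygosity)


def moment_derivatives(params: ModelParameters, zygosity: str):
    """Derivatives of the implied moments w.r.t. the natural parameters.

    Returns ``(dcov, dmean)`` where ``dcov`` is an array of shape
    ``(10, 6, 6)`` and ``dmean`` of shape ``(10, 6)``, ordered as
    :meth:`ModelParameters.names`.  Used by the analytic FIML gradient.
    """
    _check(params, zygosity)
    v, ra, va = params.v_pgs, params.r_a, params.v_adhd
    is_mz = zygosity == "MZ"
    c = 0.5 * v * (1.0 + ra)
    ctt = v if is_mz else c

    P = np.array([
        [v,      ra * v, c,   c],
        [ra * v, v,      c,   c],
        [c,      c,      v,   ctt],
        [c,      c,      ctt, v],
    ])
    w1 = np.array([params.g_m, params.g_f, params.g_tw, 0.0])
    w2 = np.array([params.g_m, params.g_f, 0.0, params.g_tw])
    W = np.column_stack([w1, w2])

    rz = params.r_mz if is_mz else params.r_dz

    # batched derivative blocks: dP (10,4,4), dW (10,4,2), dE (10,2,2)
    dP = np.zeros((10, 4, 4))
    dW = np.zeros((10, 4, 2))
    dE = np.zeros((10, 2, 2))

    dP[0] = P / v                         # v_pgs (P homogeneous of degree 1)
    dc = 0.5 * v
    dctt = 0.0 if is_mz else dc
    dP[1] = [[0.0, v, dc, dc],            # r_a
             [v, 0.0, dc, dc],
             [dc, dc, 0.0, dctt],
             [dc, dc, dctt, 0.0]]
    dE[2] = [[1.0, rz], [rz, 1.0]]        # v_adhd
    # r_mz / r_dz: only the active group's residual correlation matters
    dE[3 if is_mz else 4] = [[0.0, va], [va, 0.0]]
    dW[5] = [[0, 0], [0, 0], [1, 0], [0, 1]]   # g_tw
    dW[6] = [[1, 1], [0, 0], [0, 0], [0, 0]]   # g_m
    dW[7] = [[0, 0], [1, 1], [0, 0], [0, 0]]   # g_f

    PW = P @ W
    top = dP @ W + P @ dW                              # (10, 4, 2)
    WtdPW = np.einsum("ja,kjb->kab", W, dP @ W)        # W' dP W
    WtPdW = np.einsum("ja,kjb->kab", PW, dW)           # (PW)' dW = W'P dW
    bottom = WtPdW.swapaxes(1, 2) + WtdPW + WtPdW + dE

    dcov = np.zeros((10, 6, 6))
    dcov[:, :4, :4] = dP
    dcov[:, :4, 4:] = top
    dcov[:, 4:, :4] = top.swapaxes(1, 2)
    dcov[:, 4:, 4:] = bottom
    dmean = np.zeros((10, 6))
    dmean[8, :4] = 1.0
    dmean[9, 4:] = 1.0
    return dcov, dmean
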