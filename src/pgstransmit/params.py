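"""Free parameters of the intergenerational transmission model.

The model has ten free parameters shared between the MZ and DZ groups
except for the residual twin correlations:

* ``v_pgs`` — variance of the polygenic score (PGS), one value for every
  family member (mother, father, both twins);
* ``r_a`` — correlation between the parents' PGS, absorbing assortative
  mating and residual population stratification;
* ``v_adhd`` — residual variance of the phenotype (symptom score);
* ``r_mz``, ``r_dz`` — residual phenotype correlation within MZ / DZ pairs;
* ``g_tw``, ``g_m``, ``g_f`` — regression of a twin's phenotype on the
  twin's own, the mother's, and the father's PGS;
* ``mu_pgs``, ``mu_adhd`` — common PGS and phenotype means.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = ["ModelParameters", "N_FREE_FULL", "N_FREE_NO_NURTURE"]

#: Number of free parameters in the full transmission model.
N_FREE_FULL = 10
#: Number of free parameters with the genetic-nurture paths fixed at zero.
N_FREE_NO_NURTURE = 8

# order used for flat-vector round-trips
_FIELD_ORDER = (
    "v_pgs", "r_a", "v_adhd", "r_mz", "r_dz",
    "g_tw", "g_m", "g_f", "mu_pgs", "mu_adhd",
)


@dataclass(frozen=True)
class ModelParameters:
    """Parameter point of the transmission model.

    All parameters except ``r_mz`` and ``r_dz`` are constrained to equality
    across the MZ and DZ groups.
    """

    v_pgs: float = 1.0
    r_a: float = 0.0
    v_adhd: float = 1.0
    r_mz: float = 0.0
    r_dz: float = 0.0
    g_tw: float = 0.0
    g_m: float = 0.0
    g_f: float = 0.0
    mu_pgs: float = 0.0
    mu_adhd: float = 0.0

    def validate(self) -> "ModelParameters":
        """Check admissibility; return self so calls can be chained.

        Raises
        ------
        ValueError
            If a variance is not strictly positive or a correlation lies
            outside the open interval (-1, 1), or any value is non-finite.

        The check is cached: repeated calls on the same (frozen) instance
        are free.
        """
        if getattr(self, "_validated", False):
            return self
        for f in fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val):
                raise ValueError(f"parameter {f.name!r} is not finite: {val!r}")
        if self.v_pgs <= 0:
            raise ValueError(f"v_pgs must be > 0, got {self.v_pgs}")
        if self.v_adhd <= 0:
            raise ValueError(f"v_adhd must be > 0, got {self.v_adhd}")
        for name in ("r_a", "r_mz", "r_dz"):
            r = getattr(self, name)
            if not -1.0 < r < 1.0:
                raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
        object.__setattr__(self, "_validated", True)
        return self

    # -- flat-vector round trips (natural scale) ------------------------------

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _FIELD_ORDER], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(_FIELD_ORDER),):
            raise ValueError(f"expected {len(_FIELD_ORDER)} parameters, got shape {arr.shape}")
        return cls(**dict(zip(_FIELD_ORDER, arr.tolist())))

    @staticmethod
    def names() -> tuple:
        return _FIELD_ORDER

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def segregation_variance(self) -> float:
        """Variance of the Mendelian segregation deviation.

        The child PGS variance is constrained to equal the parental
        ``v_pgs``, so the deviation of a child's PGS from the mid-parent
        mean has variance ``v_pgs * (1 - r_a) / 2`` (derived, not free).
        """
        return self.v_pgs * (1.0 - self.r_a) / 2.0
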