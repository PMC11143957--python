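"""Transmission model fitting: Model and Results objects, nested fits.

The central object is :class:`PGSTransmissionModel`, built from a
:class:`~pgstransmit.data.FamilyData` (or equivalent DataFrame).  Its
:meth:`~PGSTransmissionModel.fit` maximizes the two-group FIML
log-likelihood over the ten model parameters (eight when the
genetic-nurture paths are fixed at zero) and returns a
:class:`TransmissionResults` carrying estimates, diagnostics, the
variance decomposition, and model-comparison helpers.  Saturated
(unstructured per-group moments, via EM) and baseline (independence)
reference models are fitted by the same FIML objective so that
likelihood-ratio tests and CFI/TLI/RMSEA are comparable under
missingness.

MZ families imply twin-PGS correlation exactly 1; a row with both twin
PGS observed and equal therefore carries a redundant coordinate, which
is dropped before fitting (for every model, so comparisons stay
aligned).  Observed-but-unequal MZ twin PGS are inconsistent with the
model and produce a ``-inf`` likelihood with a diagnostic.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .data import FamilyData
from .likelihood import PatternGroups, fiml_loglik, per_family_loglik
from .moments import VARIABLE_NAMES, build_implied_moments
from .params import ModelParameters, N_FREE_FULL, N_FREE_NO_NURTURE

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult", "LRTResult", "FitIndices",
    "PGSTransmissionModel", "TransmissionResults",
    "fit_transmission", "fit_no_nurture", "fit_saturated", "fit_baseline",
    "lr_test", "fit_indices",
]

_LOG2PI = np.log(2.0 * np.pi)

# indices into the natural 10-vector (ModelParameters.names order)
_IDX_LOGVAR = (0, 2)          # v_pgs, v_adhd
_IDX_ATANH = (1, 3, 4)        # r_a, r_mz, r_dz
_IDX_NURTURE = (6, 7)         # g_m, g_f
_T1, _T2 = 2, 3               # twin PGS positions in the 6-vector


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of one model fit (any of the four model kinds)."""

    model: str                      # "full" | "no_nurture" | "saturated" | "baseline"
    loglik: float
    n_free: int
    n_families: int
    converged: bool
    gradient_norm: float = np.nan
    params: object = None           # ModelParameters or per-group moment dict
    per_family_loglik: np.ndarray | None = None
    data_hash: str = ""
    n_restarts_used: int = 0
    boundary_flags: list = field(default_factory=list)
    message: str = ""


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test between nested fits."""

    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class FitIndices:
    """Approximate-fit indices of a target model vs saturated/baseline."""

    cfi: float
    tli: float
    rmsea: float
    chisq: float
    df: int
    defined: bool = True


# ---------------------------------------------------------------------------
# parameter transforms (unconstrained optimization scale)
# ---------------------------------------------------------------------------

def _to_unconstrained(theta: np.ndarray) -> np.ndarray:
    x = np.array(theta, dtype=float)
    for i in _IDX_LOGVAR:
        x[i] = np.log(theta[i])
    for i in _IDX_ATANH:
        x[i] = np.arctanh(theta[i])
    return x


def _to_natural(x: np.ndarray) -> np.ndarray:
    theta = np.array(x, dtype=float)
    for i in _IDX_LOGVAR:
        theta[i] = np.exp(np.clip(x[i], -40.0, 40.0))
    for i in _IDX_ATANH:
        theta[i] = np.tanh(x[i])
    return theta


def _chain_factors(theta: np.ndarray) -> np.ndarray:
    """d(natural)/d(unconstrained), elementwise."""
    J = np.ones_like(theta)
    for i in _IDX_LOGVAR:
        J[i] = theta[i]
    for i in _IDX_ATANH:
        J[i] = 1.0 - theta[i] ** 2
    return J


# ---------------------------------------------------------------------------
# the Model object
# ---------------------------------------------------------------------------

class PGSTransmissionModel:
    """Twin-family polygenic-score transmission model.

    Parameters
    ----------
    data : FamilyData, DataFrame, or (values, is_mz) pair
        Family-wide data in canonical layout.
    model : {"full", "no_nurture"}
        Whether the parental (genetic-nurture) paths ``g_m``, ``g_f``
        are free or fixed at zero.
    require_both_groups : bool
        Demand at least one usable family per zygosity group.
    """

    def __init__(self, data, model: str = "full", require_both_groups: bool = True):
        if model not in ("full", "no_nurture"):
            raise ValueError(f"model must be 'full' or 'no_nurture', got {model!r}")
        self.model_name = model
        values, is_mz = _as_arrays(data)
        self.raw_values = values
        values = _collapse_mz_duplicates(values, is_mz)
        self.values = values
        self.is_mz = is_mz
        self.patterns = PatternGroups(values, is_mz)
        self.data_hash = _data_hash(values, is_mz)
        counts = self.patterns.n_by_zygosity()
        if require_both_groups and ("MZ" not in counts or "DZ" not in counts):
            raise ValueError(
                f"need usable families in both zygosity groups, have {counts}"
            )
        self._free_idx = np.array(
            [i for i in range(10) if model == "full" or i not in _IDX_NURTURE]
        )
        self.n_free = N_FREE_FULL if model == "full" else N_FREE_NO_NURTURE

    @classmethod
    def from_csv(cls, path, schema=None, **kwargs) -> "PGSTransmissionModel":
        from .data import read_family_table
        return cls(read_family_table(path, schema=schema), **kwargs)

    # -- likelihood -----------------------------------------------------------

    def loglike(self, params: ModelParameters) -> float:
        """FIML log-likelihood of the data at ``params``."""
        return fiml_loglik(params, self.patterns)

    def score(self, params: ModelParameters) -> np.ndarray:
        """Analytic gradient of the log-likelihood (natural scale)."""
        _, g = fiml_loglik(params, self.patterns, grad=True)
        return g

    def _objective(self, x_free: np.ndarray):
        x = self._x_template.copy()
        x[self._free_idx] = x_free
        theta = _to_natural(x)
        params = ModelParameters.from_array(theta)
        ll, g = fiml_loglik(params, self.patterns, grad=True)
        if not np.isfinite(ll):
            return 1e12, np.zeros(len(self._free_idx))
        g = g * _chain_factors(theta)
        return -ll, -g[self._free_idx]

    # -- starting values ------------------------------------------------------

    def start_params(self) -> ModelParameters:
        """Method-of-moments starting values from pairwise-complete data."""
        v = self.values
        pgs = v[:, :4]
        ph = v[:, 4:]
        with np.errstate(all="ignore"):
            v_pgs = float(np.nanvar(pgs))
            mu_pgs = float(np.nanmean(pgs))
            v_ph = float(np.nanvar(ph))
            mu_ph = float(np.nanmean(ph))
        if not np.isfinite(v_pgs) or v_pgs <= 0:
            v_pgs, mu_pgs = 1.0, 0.0
        if not np.isfinite(v_ph) or v_ph <= 0:
            v_ph, mu_ph = 1.0, 0.0

        r_a = _pair_corr(v[:, 0], v[:, 1])
        # pooled own-PGS -> own-phenotype covariance
        covs = [_pair_cov(v[:, t], v[:, a]) for t, a in ((_T1, 4), (_T2, 5))]
        covs = [c for c in covs if np.isfinite(c)]
        g_tw = float(np.mean(covs)) / v_pgs if covs else 0.0

        r_mz = _pair_corr(v[self.is_mz, 4], v[self.is_mz, 5], default=0.3)
        r_dz = _pair_corr(v[~self.is_mz, 4], v[~self.is_mz, 5], default=0.15)
        v_adhd = max(v_ph - g_tw ** 2 * v_pgs, 0.25 * v_ph)
        return ModelParameters(
            v_pgs=v_pgs, r_a=float(np.clip(r_a, -0.9, 0.9)), v_adhd=v_adhd,
            r_mz=float(np.clip(r_mz, -0.9, 0.9)), r_dz=float(np.clip(r_dz, -0.9, 0.9)),
            g_tw=g_tw, g_m=0.0, g_f=0.0, mu_pgs=mu_pgs, mu_adhd=mu_ph,
        )

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        start: ModelParameters | None = None,
        restarts: int = 5,
        jitter: float = 0.25,
        gtol: float = 1e-6,
        ftol: float = 1e-13,
        maxiter: int = 1000,
        compute_per_family: bool = False,
        seed: int = 0,
    ) -> "TransmissionResults":
        """Maximize the FIML log-likelihood (multi-start quasi-Newton).

        Optimization runs on an unconstrained scale (log variances,
        atanh correlations) with the analytic gradient.  On
        non-convergence, up to ``restarts`` jittered restarts are tried
        (deterministic given ``seed``); the best point found is returned
        with ``converged`` reporting the optimizer's verdict.
        """
        start = (start or self.start_params()).validate()
        theta0 = start.to_array()
        if self.model_name == "no_nurture":
            theta0[list(_IDX_NURTURE)] = 0.0
        self._x_template = _to_unconstrained(theta0)

        rng = np.random.default_rng(seed)
        best = None
        n_used = 0
        x0 = self._x_template[self._free_idx].copy()
        for attempt in range(restarts + 1):
            if attempt > 0:
                x_try = x0 + rng.normal(scale=jitter, size=x0.shape)
            else:
                x_try = x0
            res = optimize.minimize(
                self._objective, x_try, jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
            )
            n_used = attempt
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if best.success and np.isfinite(best.fun):
                break
            logger.info("fit attempt %d did not converge (%s); restarting",
                        attempt, res.message)

        x = self._x_template.copy()
        x[self._free_idx] = best.x
        params = ModelParameters.from_array(_to_natural(x))
        ll = -best.fun if np.isfinite(best.fun) and best.fun < 1e11 else -np.inf

        flags = _boundary_flags(params)
        result = FitResult(
            model=self.model_name,
            loglik=float(ll),
            n_free=self.n_free,
            n_families=self.patterns.n_families,
            converged=bool(best.success and np.isfinite(ll)),
            gradient_norm=float(np.max(np.abs(best.jac))),
            params=params,
            per_family_loglik=(per_family_loglik(params, self.patterns)
                               if compute_per_family else None),
            data_hash=self.data_hash,
            n_restarts_used=n_used,
            boundary_flags=flags,
            message=str(best.message),
        )
        if flags:
            logger.warning("fit ended on parameter boundary: %s", flags)
        return TransmissionResults(self, result)

    # -- reference models -----------------------------------------------------

    def fit_saturated(self, tol: float = 1e-10, maxiter: int = 5000) -> FitResult:
        """Unstructured per-group means/covariances by FIML (EM)."""
        return _fit_saturated(self.values, self.is_mz, self.data_hash,
                              tol=tol, maxiter=maxiter)

    def fit_baseline(self) -> FitResult:
        """Independence model: free means/variances, zero covariances."""
        return _fit_baseline(self.values, self.is_mz, self.data_hash)


class TransmissionResults:
    """Results of a transmission-model fit (statsmodels-results flavoured)."""

    def __init__(self, model: PGSTransmissionModel, result: FitResult):
        self.model = model
        self.result = result

    # -- basic accessors ------------------------------------------------------

    @property
    def params(self) -> ModelParameters:
        return self.result.params

    @property
    def llf(self) -> float:
        return self.result.loglik

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def n_free(self) -> int:
        return self.result.n_free

    # -- derived quantities ---------------------------------------------------

    def standardized_effects(self):
        from .decomposition import standardize_effects
        return standardize_effects(self.params)

    def decomposition(self):
        from .decomposition import variance_decomposition
        return variance_decomposition(self.params)

    def implied_moments(self, zygosity: str):
        return build_implied_moments(self.params, zygosity)

    # -- model comparison -----------------------------------------------------

    def lr_test_saturated(self, saturated: FitResult | None = None) -> LRTResult:
        saturated = saturated or self.model.fit_saturated()
        return lr_test(saturated, self.result)

    def lr_test_nurture(self, **fit_kwargs) -> LRTResult:
        """Test g_m = g_f = 0 against the full model (df = 2)."""
        if self.model.model_name != "full":
            raise ValueError("nurture test requires a full-model fit")
        reduced = PGSTransmissionModel(
            (self.model.raw_values, self.model.is_mz), model="no_nurture",
        ).fit(**fit_kwargs)
        return lr_test(self.result, reduced.result)

    def fit_indices(self, saturated: FitResult | None = None,
                    baseline: FitResult | None = None) -> FitIndices:
        saturated = saturated or self.model.fit_saturated()
        baseline = baseline or self.model.fit_baseline()
        return fit_indices(self.result, saturated, baseline)

    def bootstrap(self, n_reps: int = 10_000, levels=(0.95, 0.992),
                  seed: int | None = None, n_jobs: int = 1):
        from .bootstrap import bootstrap
        return bootstrap(self.model, base_fit=self, n_reps=n_reps,
                         levels=levels, seed=seed, n_jobs=n_jobs)

    # -- presentation ---------------------------------------------------------

    def plot_moments(self, ax=None):
        """Diagnostic scatter of observed vs model-implied second moments.

        Pairwise-complete empirical covariances per zygosity group are
        plotted against the implied entries; points should hug the
        identity line when the model fits.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        markers = {"MZ": "o", "DZ": "s"}
        vals = self.model.values
        for zyg, flag in (("MZ", True), ("DZ", False)):
            sub = vals[self.model.is_mz == flag]
            if not len(sub):
                continue
            implied = self.implied_moments(zyg).cov
            xs, ys = [], []
            for i in range(6):
                for j in range(i, 6):
                    both = np.isfinite(sub[:, i]) & np.isfinite(sub[:, j])
                    if both.sum() < 3:
                        continue
                    xs.append(implied[i, j])
                    ys.append(np.cov(sub[both, i], sub[both, j], ddof=0)[0, 1])
            ax.scatter(xs, ys, marker=markers[zyg], alpha=0.7, label=zyg)
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("model-implied covariance")
        ax.set_ylabel("observed (pairwise-complete) covariance")
        ax.legend()
        return ax

    def summary(self) -> str:
        p = self.params
        dec = self.decomposition()
        eff = self.standardized_effects()
        lines = [
            "PGS transmission model" + (" (no genetic nurture)"
                                        if self.model.model_name == "no_nurture" else ""),
            "=" * 58,
            f"families: {self.result.n_families}   "
            f"free parameters: {self.n_free}   converged: {self.converged}",
            f"log-likelihood: {self.llf:.4f}   "
            f"|grad|: {self.result.gradient_norm:.2e}",
            "-" * 58,
            f"{'V_PGS':>8} {p.v_pgs:10.4f}    {'r_a':>8} {p.r_a:10.4f}",
            f"{'V_ADHD':>8} {p.v_adhd:10.4f}    {'r_MZ':>8} {p.r_mz:10.4f}",
            f"{'g_tw':>8} {p.g_tw:10.4f}    {'r_DZ':>8} {p.r_dz:10.4f}",
            f"{'g_m':>8} {p.g_m:10.4f}    {'mu_PGS':>8} {p.mu_pgs:10.4f}",
            f"{'g_f':>8} {p.g_f:10.4f}    {'mu_ADHD':>8} {p.mu_adhd:10.4f}",
            "-" * 58,
            f"standardized effects: g'_tw={eff[0]:.3f}  g'_m={eff[1]:.3f}  "
            f"g'_f={eff[2]:.3f}",
            f"explained variance: total={100 * dec.r2_total:.1f}%  "
            f"transmission={100 * dec.r2_gt:.1f}%  nurture={100 * dec.r2_gn:.1f}%",
        ]
        if self.result.boundary_flags:
            lines.append(f"WARNING boundary: {self.result.boundary_flags}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<TransmissionResults {self.model.model_name} "
                f"llf={self.llf:.2f} converged={self.converged}>")


# ---------------------------------------------------------------------------
# module-level operation wrappers
# ---------------------------------------------------------------------------

def fit_transmission(data, **kwargs) -> TransmissionResults:
    """Fit the ten-parameter transmission model to family data."""
    return PGSTransmissionModel(data, model="full").fit(**kwargs)


def fit_no_nurture(data, **kwargs) -> TransmissionResults:
    """Fit the eight-parameter model with g_m = g_f = 0."""
    return PGSTransmissionModel(data, model="no_nurture").fit(**kwargs)


def fit_saturated(data) -> FitResult:
    values, is_mz = _as_arrays(data)
    values = _collapse_mz_duplicates(values, is_mz)
    return _fit_saturated(values, is_mz, _data_hash(values, is_mz))


def fit_baseline(data) -> FitResult:
    values, is_mz = _as_arrays(data)
    values = _collapse_mz_duplicates(values, is_mz)
    return _fit_baseline(values, is_mz, _data_hash(values, is_mz))


def lr_test(full: FitResult | TransmissionResults,
            reduced: FitResult | TransmissionResults,
            clamp_tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test of ``reduced`` nested in ``full``.

    ``statistic = 2 * (loglik_full - loglik_reduced)``, clamped at zero;
    the p-value is the upper chi-square tail with ``df`` equal to the
    difference in free-parameter counts.
    """
    full = getattr(full, "result", full)
    reduced = getattr(reduced, "result", reduced)
    if reduced.n_free >= full.n_free:
        raise ValueError(
            f"reduced model must have fewer free parameters "
            f"({reduced.n_free} >= {full.n_free})"
        )
    if full.data_hash and reduced.data_hash and full.data_hash != reduced.data_hash:
        raise ValueError("models were fitted to different data")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -clamp_tol * max(1.0, abs(full.loglik)):
        logger.warning("LRT statistic markedly negative (%.3g): "
                       "reduced model out-fitted the full model", stat)
    stat = max(stat, 0.0)
    df = full.n_free - reduced.n_free
    if df == 0:
        p = 1.0 if stat <= clamp_tol else 0.0
    else:
        p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=float(stat), df=int(df), p_value=p)


def fit_indices(target: FitResult, saturated: FitResult,
                baseline: FitResult) -> FitIndices:
    """CFI, TLI and RMSEA of ``target`` against saturated and baseline fits.

    RMSEA uses the number of families (the independent sampling units of
    the likelihood) as its n.
    """
    target = getattr(target, "result", target)
    chisq_t = max(2.0 * (saturated.loglik - target.loglik), 0.0)
    df_t = saturated.n_free - target.n_free
    chisq_b = max(2.0 * (saturated.loglik - baseline.loglik), 0.0)
    df_b = saturated.n_free - baseline.n_free
    if df_t <= 0:
        return FitIndices(cfi=np.nan, tli=np.nan, rmsea=np.nan,
                          chisq=chisq_t, df=df_t, defined=False)
    dev_t = max(chisq_t - df_t, 0.0)
    dev_b = max(chisq_b - df_b, 0.0)
    denom = max(dev_b, dev_t)
    cfi = 1.0 if denom == 0 else 1.0 - dev_t / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df_b > 0 and chisq_b / df_b != 1.0:
        tli = ((chisq_b / df_b) - (chisq_t / df_t)) / ((chisq_b / df_b) - 1.0)
    else:
        tli = np.nan
    rmsea = float(np.sqrt(dev_t / (df_t * target.n_families)))
    return FitIndices(cfi=cfi, tli=float(tli), rmsea=rmsea,
                      chisq=float(chisq_t), df=int(df_t))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, FamilyData):
        return data.arrays()
    if isinstance(data, pd.DataFrame):
        return FamilyData(data).arrays()
    if isinstance(data, tuple) and len(data) == 2:
        values, is_mz = data
        return np.array(values, dtype=float), np.asarray(is_mz, dtype=bool)
    if isinstance(data, (list,)):  # list of FamilyRecord
        return FamilyData.from_records(data).arrays()
    raise TypeError(f"cannot interpret data of type {type(data)!r}")


def _collapse_mz_duplicates(values: np.ndarray, is_mz: np.ndarray,
                            tol: float = 1e-9) -> np.ndarray:
    """Drop the redundant MZ twin-PGS coordinate (equal duplicates only)."""
    values = np.array(values, dtype=float)
    both = is_mz & np.isfinite(values[:, _T1]) & np.isfinite(values[:, _T2])
    equal = both & (np.abs(values[:, _T1] - values[:, _T2]) <= tol)
    values[equal, _T2] = np.nan
    n_bad = int(both.sum() - equal.sum())
    if n_bad:
        logger.warning(
            "%d MZ families have unequal observed twin PGS; these rows are "
            "inconsistent with the shared-genotype assumption and will "
            "contribute -inf to the transmission likelihood", n_bad)
    return values


def _data_hash(values: np.ndarray, is_mz: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(values, dtype=float).tobytes())
    h.update(np.ascontiguousarray(is_mz, dtype=bool).tobytes())
    return h.hexdigest()


def _pair_corr(a, b, default: float = 0.0) -> float:
    both = np.isfinite(a) & np.isfinite(b)
    if both.sum() < 3:
        return default
    r = np.corrcoef(a[both], b[both])[0, 1]
    return float(r) if np.isfinite(r) else default


def _pair_cov(a, b) -> float:
    both = np.isfinite(a) & np.isfinite(b)
    if both.sum() < 3:
        return np.nan
    return float(np.cov(a[both], b[both], ddof=0)[0, 1])


def _boundary_flags(params: ModelParameters) -> list[str]:
    flags = []
    for name in ("r_a", "r_mz", "r_dz"):
        if abs(getattr(params, name)) > 0.99:
            flags.append(name)
    for name in ("v_pgs", "v_adhd"):
        if getattr(params, name) < 1e-8:
            flags.append(name)
    return flags


def _mvn_loglik_stats(n, k, mean_diff, scatter, cov) -> float:
    """Gaussian loglik from sufficient statistics, ML convention."""
    chol = linalg.cholesky(cov, lower=True)
    z = linalg.solve_triangular(chol, mean_diff, lower=True)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return float(-0.5 * (n * (k * _LOG2PI + logdet)
                         + np.trace(linalg.cho_solve((chol, True), scatter))
                         + n * (z @ z)))


def _fit_saturated(values, is_mz, data_hash, tol=1e-10, maxiter=5000) -> FitResult:
    """Per-group unstructured MVN MLE under missingness via EM."""
    total_ll = 0.0
    n_free = 0
    params = {}
    converged = True
    n_total = values.shape[0]
    for flag, zyg in ((True, "MZ"), (False, "DZ")):
        X = values[is_mz == flag]
        if X.shape[0] == 0:
            continue
        observed_any = np.isfinite(X).any(axis=0)
        cols = np.flatnonzero(observed_any)
        if cols.size == 0:
            continue
        Xg = X[:, cols]
        mu, cov, ll, ok = _em_mvnormal(Xg, tol=tol, maxiter=maxiter)
        converged &= ok
        total_ll += ll
        k = cols.size
        n_free += k + k * (k + 1) // 2
        params[zyg] = {
            "variables": [VARIABLE_NAMES[c] for c in cols],
            "mean": mu, "cov": cov,
        }
    return FitResult(model="saturated", loglik=total_ll, n_free=n_free,
                     n_families=n_total, converged=converged, params=params,
                     data_hash=data_hash)


def _em_mvnormal(X: np.ndarray, tol: float, maxiter: int):
    """EM for the MVN MLE with values missing at random.

    Returns (mean, cov, observed-data loglik, converged).  Complete rows
    make this a single-step closed form; with missingness the observed
    log-likelihood increases monotonically to the FIML optimum.
    """
    n, k = X.shape
    obs = np.isfinite(X)
    # drop rows with nothing observed (contribute 0 to the likelihood)
    keep = obs.any(axis=1)
    X, obs = X[keep], obs[keep]
    n_eff = X.shape[0]
    if n_eff == 0:
        return np.zeros(k), np.eye(k), 0.0, True

    col_mean = np.array([X[obs[:, j], j].mean() if obs[:, j].any() else 0.0
                         for j in range(k)])
    col_var = np.array([X[obs[:, j], j].var() if obs[:, j].sum() > 1 else 1.0
                        for j in range(k)])
    col_var = np.where(col_var > 1e-12, col_var, 1.0)
    mu = col_mean.copy()
    cov = np.diag(col_var)

    pattern_key = obs @ (1 << np.arange(k))
    patterns = [(np.flatnonzero(pattern_key == key), obs[pattern_key == key][0])
                for key in np.unique(pattern_key)]

    last_ll = -np.inf
    ok = False
    for _ in range(maxiter):
        S1 = np.zeros(k)
        S2 = np.zeros((k, k))
        ll = 0.0
        for rows, mask in patterns:
            o = np.flatnonzero(mask)
            m = np.flatnonzero(~mask)
            Xo = X[np.ix_(rows, o)]
            n_p = len(rows)
            So = cov[np.ix_(o, o)]
            chol = linalg.cholesky(So + 1e-12 * np.eye(o.size), lower=True)
            Do = Xo - mu[o]
            Z = linalg.solve_triangular(chol, Do.T, lower=True)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            ll += -0.5 * (n_p * (o.size * _LOG2PI + logdet) + (Z * Z).sum())

            E = np.empty((n_p, k))
            E[:, o] = Xo
            if m.size:
                B = linalg.cho_solve((chol, True), cov[np.ix_(o, m)])  # So^-1 Som
                E[:, m] = mu[m] + Do @ B
                C_m = cov[np.ix_(m, m)] - cov[np.ix_(m, o)] @ B
            S1 += E.sum(axis=0)
            S2 += E.T @ E
            if m.size:
                S2[np.ix_(m, m)] += n_p * C_m
        mu = S1 / n_eff
        cov = S2 / n_eff - np.outer(mu, mu)
        cov = 0.5 * (cov + cov.T)
        if abs(ll - last_ll) <= tol * max(1.0, abs(ll)):
            ok = True
            last_ll = ll
            break
        last_ll = ll
    # one final evaluation at the last M-step update
    final_ll = _fiml_ll_unstructured(X, obs, mu, cov)
    return mu, cov, final_ll, ok


def _fiml_ll_unstructured(X, obs, mu, cov) -> float:
    ll = 0.0
    pattern_key = obs @ (1 << np.arange(X.shape[1]))
    for key in np.unique(pattern_key):
        rows = np.flatnonzero(pattern_key == key)
        o = np.flatnonzero(obs[rows[0]])
        Xo = X[np.ix_(rows, o)]
        So = cov[np.ix_(o, o)]
        try:
            chol = linalg.cholesky(So + 1e-12 * np.eye(o.size), lower=True)
        except linalg.LinAlgError:
            return -np.inf
        Z = linalg.solve_triangular(chol, (Xo - mu[o]).T, lower=True)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        ll += -0.5 * (len(rows) * (o.size * _LOG2PI + logdet) + (Z * Z).sum())
    return float(ll)


def _fit_baseline(values, is_mz, data_hash) -> FitResult:
    """Independence model: per-variable Gaussian MLE within each group."""
    total_ll = 0.0
    n_free = 0
    params = {}
    for flag, zyg in ((True, "MZ"), (False, "DZ")):
        X = values[is_mz == flag]
        if X.shape[0] == 0:
            continue
        means, variances, names = [], [], []
        for j in range(X.shape[1]):
            col = X[np.isfinite(X[:, j]), j]
            if col.size == 0:
                continue
            m, v = col.mean(), col.var()
            v = max(v, 1e-300)
            total_ll += -0.5 * col.size * (_LOG2PI + np.log(v) + 1.0)
            means.append(m)
            variances.append(v)
            names.append(VARIABLE_NAMES[j])
            n_free += 2
        params[zyg] = {"variables": names, "mean": np.array(means),
                       "var": np.array(variances)}
    return FitResult(model="baseline", loglik=total_ll, n_free=n_free,
                     n_families=values.shape[0], converged=True, params=params,
                     data_hash=data_hash)
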