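"""Family-level nonparametric bootstrap for the transmission model.

Families are resampled with replacement, stratified by zygosity so the
MZ and DZ counts of the original design are preserved, and the model is
refitted on each replicate starting from the base-fit estimates.
Percentile confidence intervals are formed from the replicate
distributions of the standardized effects and variance shares; a
quantity is flagged significant at a level when its interval excludes
zero.  The default levels are 0.95 and the multiplicity-adjusted
0.992 = 1 - 0.05/6 (three PGS effects tested for two PGS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .params import ModelParameters

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "percentile_interval", "multiplicity_level",
           "bootstrap", "DEFAULT_QUANTITIES"]

DEFAULT_QUANTITIES = ("g_tw_std", "g_m_std", "g_f_std",
                      "r2_total", "r2_gt", "r2_gn")


@dataclass
class BootstrapResult:
    """Replicate distributions, percentile intervals and significance flags."""

    n_reps: int
    levels: tuple
    seed: int | None
    samples: dict                 # quantity -> np.ndarray of replicate values
    intervals: dict = field(default_factory=dict)   # quantity -> {level: (lo, hi)}
    significant: dict = field(default_factory=dict)  # quantity -> {level: bool}
    n_failed: int = 0

    @property
    def unreliable(self) -> bool:
        """True when more than 20% of replicates failed to converge."""
        return self.n_failed > 0.2 * self.n_reps

    def plot(self, quantity: str = "g_tw_std", level: float = 0.95, ax=None):
        """Histogram of the replicate distribution with its interval."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.2))
        samples = self.samples[quantity]
        ax.hist(samples[np.isfinite(samples)], bins=40, color="steelblue",
                alpha=0.8)
        lo, hi = self.intervals.get(quantity, {}).get(
            level, percentile_interval(samples, level))
        for x in (lo, hi):
            ax.axvline(x, color="darkred", ls="--", lw=1)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel(quantity)
        ax.set_ylabel("replicates")
        return ax

    def summary(self) -> str:
        lines = [f"bootstrap: {self.n_reps} replicates "
                 f"({self.n_failed} failed), seed={self.seed}"]
        if self.unreliable:
            lines.append("WARNING: >20% failed replicates; intervals unreliable")
        for q, per_level in self.intervals.items():
            parts = [f"{lvl:.3f}: [{lo:+.4f}, {hi:+.4f}]"
                     f"{'*' if self.significant[q][lvl] else ''}"
                     for lvl, (lo, hi) in per_level.items()]
            lines.append(f"  {q:10s} " + "   ".join(parts))
        return "\n".join(lines)


def percentile_interval(samples, level: float) -> tuple[float, float]:
    """Equal-tailed percentile interval from replicate samples.

    Uses empirical quantiles at ``(1 - level) / 2`` and
    ``1 - (1 - level) / 2`` with linear interpolation between order
    statistics; non-finite samples are dropped (and counted in the log).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    samples = np.asarray(samples, dtype=float)
    finite = np.isfinite(samples)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("percentile_interval: dropped %d non-finite samples", n_dropped)
    samples = samples[finite]
    if samples.size < 2:
        raise ValueError("need at least two finite samples for an interval")
    alpha = 1.0 - level
    lo, hi = np.quantile(samples, [alpha / 2.0, 1.0 - alpha / 2.0],
                         method="linear")
    return float(lo), float(hi)


def multiplicity_level(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted confidence level ``1 - alpha / n_tests``.

    Rounded to 3 decimals for reporting (0.05 over 6 tests -> 0.992).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return round(1.0 - alpha / n_tests, 3)


def bootstrap(
    model_or_data,
    base_fit=None,
    n_reps: int = 10_000,
    levels=(0.95, 0.992),
    seed: int | None = None,
    n_jobs: int = 1,
    quantities=DEFAULT_QUANTITIES,
) -> BootstrapResult:
    """Stratified family bootstrap of the transmission-model quantities.

    Parameters
    ----------
    model_or_data : PGSTransmissionModel or data acceptable to it
        The base model / data.
    base_fit : TransmissionResults, optional
        A converged base fit; computed here when absent.  Replicates
        start from its estimates, with one jittered fallback restart.
    n_reps, levels, seed, n_jobs
        Replicate count, confidence levels, RNG seed, parallel workers.
        Resample indices are pre-drawn from the single seed, so results
        do not depend on ``n_jobs``.
    """
    from .model import PGSTransmissionModel

    if isinstance(model_or_data, PGSTransmissionModel):
        model = model_or_data
    else:
        model = PGSTransmissionModel(model_or_data)
    if base_fit is None:
        base_fit = model.fit()
    if not base_fit.converged:
        raise ValueError("bootstrap requires a converged base fit")
    base_params = base_fit.params

    values = model.raw_values
    is_mz = model.is_mz
    mz_rows = np.flatnonzero(is_mz)
    dz_rows = np.flatnonzero(~is_mz)

    rng = np.random.default_rng(seed)
    # pre-draw all resample indices so results are independent of n_jobs
    draws = []
    for _ in range(n_reps):
        rows = np.concatenate([
            rng.choice(mz_rows, size=mz_rows.size, replace=True),
            rng.choice(dz_rows, size=dz_rows.size, replace=True),
        ])
        draws.append(rows)

    # zygosity of a stratified resample is the original counts, in order
    rep_is_mz = np.concatenate([np.ones(mz_rows.size, bool),
                                np.zeros(dz_rows.size, bool)])
    if n_jobs != 1:
        task = delayed(_one_replicate)
        results = Parallel(n_jobs=n_jobs)(
            task(values[rows], rep_is_mz, base_params, quantities)
            for rows in draws)
    else:
        results = [_one_replicate(values[rows], rep_is_mz, base_params, quantities)
                   for rows in draws]

    samples = {q: np.array([r[q] for r in results if r is not None])
               for q in quantities}
    n_failed = sum(r is None for r in results)
    out = BootstrapResult(n_reps=n_reps, levels=tuple(levels), seed=seed,
                          samples=samples, n_failed=n_failed)
    for q in quantities:
        out.intervals[q] = {}
        out.significant[q] = {}
        for level in levels:
            lo, hi = percentile_interval(samples[q], level)
            out.intervals[q][level] = (lo, hi)
            out.significant[q][level] = bool(lo > 0.0 or hi < 0.0)
    if out.unreliable:
        logger.warning("bootstrap unreliable: %d/%d replicates failed",
                       n_failed, n_reps)
    return out


def _one_replicate(rep_values, rep_is_mz, base_params: ModelParameters,
                   quantities):
    from .decomposition import variance_decomposition
    from .model import PGSTransmissionModel

    try:
        model = PGSTransmissionModel((rep_values, rep_is_mz),
                                     require_both_groups=False)
        res = model.fit(start=base_params, restarts=1, jitter=0.1)
    except Exception as exc:   # resample may be degenerate
        logger.debug("bootstrap replicate failed: %s", exc)
        return None
    if not res.converged or not np.isfinite(res.llf):
        return None
    dec = variance_decomposition(res.params)
    return {q: getattr(dec, q) for q in quantities}
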