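"""Maximum-likelihood inference and model comparison.

Insertion rates have the closed-form Poisson MLE ``Phi_i = N_i / T_i``.
Deletion parameters are estimated by box-constrained maximisation of the
pattern log likelihood in log10 parameter space, using a deterministic
grid of starting points plus seeded random multi-starts followed by
L-BFGS-B.  The exponential and Weibull models are nested (omega = 1), so
they are compared with a likelihood-ratio test on one degree of freedom.
Uncertainty is quantified by case-resampling bootstrap over patterns with
percentile intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .deletion import PARAM_BOUNDS, DeletionParams
from .likelihood import DeletionLikelihood, InsertionRates, insertion_log_likelihood
from .patterns import PatternCounts, SitePattern, count_insertions
from .tree import BRANCHES, HostTree

#: chi-square(1) cutoff at p = 0.001 for the nested model comparison.
LRT_CUTOFF = float(stats.chi2.isf(0.001, df=1))

#: log10 distance from a box bound below which an estimate is flagged.
_BOUND_TOL = 1e-3


@dataclass(frozen=True)
class FitResult:
    """MLE of the deletion process for one pattern set."""

    params: DeletionParams
    log_likelihood: float  # deletion component at the MLE
    rates: InsertionRates
    insertion_log_likelihood: float
    n_patterns: int
    converged: bool
    at_bound: dict[str, str] = field(default_factory=dict)  # param -> "lower"/"upper"
    n_starts: int = 0
    seed: int | None = None

    @property
    def total_log_likelihood(self) -> float:
        return self.log_likelihood + self.insertion_log_likelihood

    def summary(self) -> dict:
        out = {
            "model": self.params.model,
            "log_likelihood": self.log_likelihood,
            "n_patterns": self.n_patterns,
            "converged": self.converged,
            "at_bound": dict(self.at_bound),
        }
        if self.params.model == "exponential":
            out["psi_e"] = self.params.psi
        else:
            out["psi_w"] = self.params.psi
            out["inv_psi_w"] = self.params.inv_scale
            out["omega"] = self.params.omega
        return out


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio comparison of exponential (null) vs Weibull."""

    statistic: float
    dof: int
    cutoff: float
    p_value: float
    favors_weibull: bool


def fit_insertion_rates(counts: PatternCounts, tree: HostTree) -> InsertionRates:
    """Closed-form Poisson MLE Phi_i = N_i / T_i."""
    return InsertionRates({b: counts[b] / tree.branch_length[b] for b in BRANCHES})


def _params_from_log10(model: str, x: np.ndarray) -> DeletionParams:
    if model == "exponential":
        return DeletionParams.exponential(10.0 ** x[0])
    return DeletionParams.weibull(scale=10.0 ** x[0], shape=10.0 ** x[1])


def _start_points(model: str, n_starts: int, rng: np.random.Generator) -> list[np.ndarray]:
    lo, hi = math.log10(PARAM_BOUNDS[0]), math.log10(PARAM_BOUNDS[1])
    if model == "exponential":
        fixed = [np.array([v]) for v in (-2.0, -1.0, -0.5, 0.0, 0.7)]
        dim = 1
    else:
        fixed = [
            np.array([p, w])
            for p in (-1.5, -0.5, 0.5, 1.5)
            for w in (-0.8, -0.3, 0.0)
        ]
        dim = 2
    starts = fixed[:n_starts]
    while len(starts) < n_starts:
        starts.append(rng.uniform(lo, hi, size=dim))
    return starts


def fit_deletion(
    patterns: Sequence[SitePattern],
    tree: HostTree,
    model: str = "weibull",
    n_starts: int = 16,
    seed: int = 0,
    bounds: tuple[float, float] = PARAM_BOUNDS,
) -> FitResult:
    """Box-constrained MLE of the deletion parameters.

    Non-convergence of every local search is flagged on the result rather
    than raised; boundary estimates are flagged per parameter so they can
    be reported as inequalities.
    """
    patterns = list(patterns)
    if not patterns:
        raise ValueError("fit_deletion requires at least one pattern")
    loglik = DeletionLikelihood(patterns, tree)
    box = (math.log10(bounds[0]), math.log10(bounds[1]))

    # a large finite penalty keeps L-BFGS-B's finite differences well
    # defined where the likelihood underflows to zero
    _PENALTY = 1e12

    def nll(x: np.ndarray) -> float:
        if not np.all(np.isfinite(x)):
            return _PENALTY
        val = loglik(_params_from_log10(model, x))
        return _PENALTY if not np.isfinite(val) else -val

    rng = np.random.default_rng(seed)
    best_x, best_val, converged = None, float("inf"), False
    dim = 1 if model == "exponential" else 2
    for x0 in _start_points(model, n_starts, rng):
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=[box] * dim)
        if res.fun < best_val - 1e-12 or best_x is None:
            best_x, best_val = np.asarray(res.x), float(res.fun)
            converged = bool(res.success)
        elif abs(res.fun - best_val) <= 1e-12:
            converged = converged or bool(res.success)
    params = _params_from_log10(model, best_x)

    at_bound: dict[str, str] = {}
    names = ["psi"] if model == "exponential" else ["psi", "omega"]
    for name, xi in zip(names, best_x):
        if xi - box[0] < _BOUND_TOL:
            at_bound[name] = "lower"
        elif box[1] - xi < _BOUND_TOL:
            at_bound[name] = "upper"

    counts = count_insertions(patterns, tree)
    rates = fit_insertion_rates(counts, tree)
    ins_ll = insertion_log_likelihood(counts, rates, tree)
    return FitResult(
        params=params,
        log_likelihood=-best_val,
        rates=rates,
        insertion_log_likelihood=ins_ll,
        n_patterns=len(patterns),
        converged=converged,
        at_bound=at_bound,
        n_starts=n_starts,
        seed=seed,
    )


def likelihood_ratio_test(fit_e: FitResult, fit_w: FitResult, tol: float = 1e-6) -> ModelComparison:
    """2 * (l_w - l_e) against the chi-square(1) 0.001 cutoff.

    Uses the deletion components only; the Poisson insertion term is common
    to both models and cancels.  A statistic below -tol signals optimiser
    failure (the models are nested, so l_w >= l_e at the optimum).
    """
    if fit_e.params.model != "exponential" or fit_w.params.model != "weibull":
        raise ValueError("pass the exponential fit first and the weibull fit second")
    if fit_e.n_patterns != fit_w.n_patterns:
        raise ValueError("fits must be on the same data")
    stat = 2.0 * (fit_w.log_likelihood - fit_e.log_likelihood)
    if stat < -tol:
        raise RuntimeError(
            f"negative LRT statistic {stat:.6g}: Weibull optimisation failed "
            "to reach the nested exponential optimum"
        )
    stat = max(stat, 0.0)
    return ModelComparison(
        statistic=stat,
        dof=1,
        cutoff=LRT_CUTOFF,
        p_value=float(stats.chi2.sf(stat, df=1)),
        favors_weibull=stat > LRT_CUTOFF,
    )


@dataclass(frozen=True)
class BootstrapResult:
    """Case-resampling bootstrap of the deletion fit."""

    fits: tuple[FitResult, ...]
    ci: dict[str, tuple[float, float]]
    n_failed: int
    seed: int

    def fraction(self, predicate) -> float:
        """Fraction of replicates whose fitted params satisfy a predicate."""
        return float(np.mean([predicate(f.params) for f in self.fits]))


def bootstrap(
    patterns: Sequence[SitePattern],
    tree: HostTree,
    model: str = "weibull",
    n_reps: int = 1000,
    seed: int = 0,
    n_starts: int = 8,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Resample patterns with replacement and refit each replicate.

    Percentile confidence intervals are reported for psi (and omega and the
    inverse scale under the Weibull model).  Replicates whose optimiser
    never converged are counted in ``n_failed`` but still contribute their
    best point (they are typically boundary solutions, not failures of the
    likelihood itself).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    patterns = list(patterns)
    rng = np.random.default_rng(seed)
    fits: list[FitResult] = []
    n_failed = 0
    for _ in range(n_reps):
        idx = rng.integers(0, len(patterns), size=len(patterns))
        rep = [patterns[i] for i in idx]
        rep_seed = int(rng.integers(0, 2**31 - 1))
        fit = fit_deletion(rep, tree, model=model, n_starts=n_starts, seed=rep_seed)
        if not fit.converged:
            n_failed += 1
        fits.append(fit)
    alpha = (1.0 - ci_level) / 2.0
    qs = (100 * alpha, 100 * (1 - alpha))
    ci: dict[str, tuple[float, float]] = {}
    psis = np.array([f.params.psi for f in fits])
    ci["psi"] = tuple(np.percentile(psis, qs))
    if model == "weibull":
        omegas = np.array([f.params.omega for f in fits])
        ci["omega"] = tuple(np.percentile(omegas, qs))
        ci["inv_psi_w"] = tuple(np.percentile(1.0 / psis, qs))
    return BootstrapResult(tuple(fits), ci, n_failed, seed)
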