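"""Forward simulation of ERV histories and goodness-of-fit testing.

Two simulation modes are provided:

* ``factorized`` (default) draws each branch transition from the same
  per-branch probabilities the likelihood integrates over (insertion time
  averaged independently per branch).  Simulated pattern frequencies then
  converge exactly to ``exp(pattern_log_likelihood)``, which makes this
  mode the right null for goodness-of-fit tests against the fitted model.
* ``mechanistic`` draws one uniform insertion time per locus and applies
  age-consistent survival ratios along every lineage, i.e. the underlying
  biological process without the factorisation; daughters of a branching
  remain conditionally independent given the shared insertion time.

Under the exponential model the two modes coincide (memorylessness).

The goodness-of-fit test compares observed and simulated pattern counts in
an r x 2 contingency table with a seeded Monte-Carlo exact test
(conditional on margins, tables sampled by multivariate hypergeometric
draws; the p-value is the fraction of tables at most as probable as the
observed one).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special

from . import families
from .deletion import DeletionParams, survival
from .likelihood import InsertionRates, branch_transition_probs, post_branch_times
from .patterns import SitePattern, count_insertions, insertion_branch
from .tree import BRANCH_POSITION, BRANCHES, TIP_BRANCHES, HostTree, default_tree


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: either a fixed insertion branch with a count, or
    per-branch Poisson rates."""

    params: DeletionParams
    tree: HostTree = field(default_factory=default_tree)
    insertion_branch: str | None = None
    n_insertions: int | None = None
    rates: InsertionRates | None = None
    mode: str = "factorized"
    family: str = "simulated"

    def __post_init__(self) -> None:
        if self.mode not in ("factorized", "mechanistic"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")
        fixed = self.insertion_branch is not None
        if fixed:
            if self.insertion_branch not in BRANCHES:
                raise ValueError(f"unknown branch {self.insertion_branch!r}")
            if self.n_insertions is None or self.n_insertions < 1:
                raise ValueError("n_insertions must be >= 1 for a fixed insertion branch")
        elif self.rates is None:
            raise ValueError("give either insertion_branch + n_insertions or rates")


@dataclass(frozen=True)
class SimulatedPatterns:
    """Simulation output: pattern counts plus a per-locus truth log."""

    counts: dict[tuple[str, ...], int]
    insertion_branches: tuple[str, ...]
    insertion_times: tuple[float, ...] | None  # mechanistic mode only
    deletion_branches: tuple[str | None, ...]  # branch on which 1 -> x happened

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def to_patterns(self, family: str = "simulated") -> list[SitePattern]:
        out: list[SitePattern] = []
        for states, k in sorted(self.counts.items()):
            out.extend(SitePattern(states, family=family) for _ in range(k))
        return out


def _simulate_branch(
    tree: HostTree,
    params: DeletionParams,
    b0: str,
    n: int,
    rng: np.random.Generator,
    mode: str,
) -> tuple[np.ndarray, np.ndarray | None, list[str | None]]:
    """Simulate n insertions on branch b0.

    Returns (tip state matrix over the supported tips as '1'/'x' codes,
    insertion times or None, deletion branch per locus).
    """
    t0 = tree.branch_length[b0]
    desc = tree.descendants(b0)
    times = post_branch_times(tree, b0)

    # full[branch] : bool array, lineage still full-length at branch end
    full: dict[str, np.ndarray] = {}
    del_branch: list[str | None] = [None] * n

    if mode == "factorized":
        q1, p_ret = branch_transition_probs(tree, b0, params)
        full[b0] = rng.random(n) < q1
        for b in desc:
            keep = rng.random(n) < p_ret[b]
            full[b] = full[tree.parent(b)] & keep
        ti = None
    else:
        ti = rng.uniform(0.0, t0, size=n)
        surv_end = np.asarray(survival(params, t0 - ti))
        full[b0] = rng.random(n) < surv_end
        for b in desc:
            t1, t2 = times[b]
            ratio = np.asarray(survival(params, t2 - ti)) / np.asarray(survival(params, t1 - ti))
            full[b] = full[tree.parent(b)] & (rng.random(n) < ratio)

    for b in (b0, *desc):
        parent_full = np.ones(n, dtype=bool) if b == b0 else full[tree.parent(b)]
        newly = parent_full & ~full[b]
        for i in np.nonzero(newly)[0]:
            if del_branch[i] is None:
                del_branch[i] = b

    tips = sorted(tree.tip_set(b0), key=BRANCH_POSITION.get)
    mat = np.empty((n, len(tips)), dtype="<U1")
    for j, tb in enumerate(tips):
        mat[:, j] = np.where(full[tb] if tb != b0 else full[b0], "1", "x")
    return mat, ti, del_branch


def simulate_patterns(spec: SimulationSpec, seed: int = 0) -> SimulatedPatterns:
    """Simulate site patterns under the given deletion process."""
    rng = np.random.default_rng(seed)
    tree, params = spec.tree, spec.params

    jobs: list[tuple[str, int]] = []
    if spec.insertion_branch is not None:
        jobs.append((spec.insertion_branch, int(spec.n_insertions)))
    else:
        phi = spec.rates.means(tree)
        for b in BRANCHES:
            k = int(rng.poisson(phi[b])) if phi[b] > 0 else 0
            if k:
                jobs.append((b, k))

    counts: dict[tuple[str, ...], int] = {}
    ins_branches: list[str] = []
    ins_times: list[float] = []
    del_branches: list[str | None] = []
    for b0, n in jobs:
        mat, ti, dels = _simulate_branch(tree, params, b0, n, rng, spec.mode)
        tips = sorted(tree.tip_set(b0), key=BRANCH_POSITION.get)
        for i in range(n):
            states = ["0"] * 6
            for j, tb in enumerate(tips):
                states[BRANCH_POSITION[tb]] = mat[i, j]
            key = tuple(states)
            counts[key] = counts.get(key, 0) + 1
        ins_branches.extend([b0] * n)
        if ti is not None:
            ins_times.extend(ti.tolist())
        del_branches.extend(dels)

    return SimulatedPatterns(
        counts=counts,
        insertion_branches=tuple(ins_branches),
        insertion_times=tuple(ins_times) if ins_times else None,
        deletion_branches=tuple(del_branches),
    )


# ---------------------------------------------------------------------------
# goodness of fit


@dataclass(frozen=True)
class GofResult:
    """Monte-Carlo exact test of observed vs simulated pattern frequencies."""

    table: dict[tuple[str, ...], tuple[int, int]]  # pattern -> (observed, simulated)
    statistic: float  # log probability of the observed table under the null
    p_value: float
    n_observed: int
    n_simulated: int
    n_resamples: int


def _log_table_prob(obs_col: np.ndarray, row_totals: np.ndarray, n1: int) -> float:
    # multivariate hypergeometric log pmf (constant terms dropped)
    return float(np.sum(special.gammaln(row_totals + 1) - special.gammaln(obs_col + 1) - special.gammaln(row_totals - obs_col + 1)))


def gof_test(
    observed: Sequence[SitePattern] | Mapping[tuple[str, ...], int],
    spec: SimulationSpec,
    seed: int = 0,
    n_resamples: int = 100_000,
) -> GofResult:
    """Compare observed site patterns with model-simulated frequencies.

    The observed patterns must share one insertion branch (matching
    ``spec.insertion_branch``).  The simulated reference sample is drawn
    from ``spec``; the exact test conditions on both margins.
    """
    if spec.insertion_branch is None:
        raise ValueError("gof_test requires a fixed insertion branch in the spec")
    if isinstance(observed, Mapping):
        obs_counts = {tuple(k): int(v) for k, v in observed.items()}
    else:
        obs_counts = {}
        for p in observed:
            if insertion_branch(p) != spec.insertion_branch:
                raise ValueError(
                    f"observed pattern {''.join(p.states)} is not an insertion on "
                    f"branch {spec.insertion_branch!r}"
                )
            obs_counts[p.states] = obs_counts.get(p.states, 0) + 1
    if not obs_counts:
        raise ValueError("empty observed pattern set")

    rng = np.random.default_rng(seed)
    sim = simulate_patterns(spec, seed=int(rng.integers(0, 2**31 - 1)))
    keys = sorted(set(obs_counts) | set(sim.counts))
    obs = np.array([obs_counts.get(k, 0) for k in keys], dtype=np.int64)
    simc = np.array([sim.counts.get(k, 0) for k in keys], dtype=np.int64)
    row_totals = obs + simc
    n1 = int(obs.sum())

    stat = _log_table_prob(obs, row_totals, n1)
    draws = rng.multivariate_hypergeometric(row_totals, n1, size=n_resamples)
    gl = special.gammaln
    logp = np.sum(gl(row_totals + 1) - gl(draws + 1) - gl(row_totals - draws + 1), axis=1)
    p = float(np.mean(logp <= stat + 1e-9))

    return GofResult(
        table={k: (int(o), int(s)) for k, o, s in zip(keys, obs, simc)},
        statistic=stat,
        p_value=p,
        n_observed=n1,
        n_simulated=int(simc.sum()),
        n_resamples=n_resamples,
    )


# ---------------------------------------------------------------------------
# synthetic study generator


def default_study_config() -> dict[str, dict]:
    """Per-family generating conditions: the reference branch-specific
    insertion rates and the reference Weibull deletion parameters."""
    cfg: dict[str, dict] = {}
    for fam in families.FAMILIES:
        inv_scale, shape = families.WEIBULL_PARAMS[fam]
        cfg[fam] = {
            "rates": dict(families.INSERTION_RATES[fam]),
            "params": DeletionParams.weibull_inv_scale(inv_scale, shape),
        }
    return cfg


def generate_synthetic_study(
    config: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    tree: HostTree | None = None,
    mode: str = "factorized",
) -> dict[str, list[SitePattern]]:
    """Drop-in synthetic replacement for a genome-scale pattern survey.

    For each family, branch insertion counts are Poisson with mean
    ``rate * T_i`` and each insertion's deletion history follows the
    family's deletion parameters.  Ground truth (generating parameters) is
    the config itself.
    """
    tree = tree if tree is not None else default_tree()
    config = default_study_config() if config is None else config
    rng = np.random.default_rng(seed)
    out: dict[str, list[SitePattern]] = {}
    for fam in config:
        entry = config[fam]
        rates = entry["rates"]
        rates = rates if isinstance(rates, InsertionRates) else InsertionRates(rates)
        params = entry["params"]
        if not isinstance(params, DeletionParams):
            params = DeletionParams(**params)
        spec = SimulationSpec(params=params, tree=tree, rates=rates, mode=mode, family=fam)
        sim = simulate_patterns(spec, seed=int(rng.integers(0, 2**31 - 1)))
        out[fam] = sim.to_patterns(family=fam)
    return out
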