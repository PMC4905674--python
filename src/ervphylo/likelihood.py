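"""Joint likelihood of site patterns on the host chronogram.

The likelihood factorises into (i) a per-branch Poisson factor for the
number of insertions ``N_i`` on each branch, with mean ``phi_i = Phi_i T_i``,
and (ii) a per-pattern deletion factor conditional on the insertion branch.
The deletion factor sums over every assignment of states to internal nodes
that is consistent with the permitted history ``0 -> 1 -> x``, using a
pruning-style recursion over the post-insertion subtree.  Because the
Weibull deletion process is age dependent, the recursion tracks cumulative
time since the origin of the insertion branch; under the exponential model
only branch durations matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import special

from .deletion import DeletionParams, pr_delete_insertion_branch, pr_retain_post_branch
from .patterns import (
    PatternCounts,
    SitePattern,
    count_insertions,
    enumerate_coherent_patterns,
    insertion_branch,
)
from .tree import BRANCHES, BRANCH_POSITION, TIP_BRANCHES, HostTree


@dataclass(frozen=True)
class InsertionRates:
    """Per-branch Poisson insertion rates Phi_i (relative insertions/Myr)."""

    rates: Mapping[str, float]

    def __post_init__(self) -> None:
        full = {b: float(self.rates.get(b, 0.0)) for b in BRANCHES}
        if any(v < 0 for v in full.values()):
            raise ValueError("insertion rates must be non-negative")
        object.__setattr__(self, "rates", full)

    def means(self, tree: HostTree) -> dict[str, float]:
        """Expected insertion counts phi_i = Phi_i * T_i."""
        return {b: self.rates[b] * tree.branch_length[b] for b in BRANCHES}

    def __getitem__(self, branch: str) -> float:
        return self.rates[branch]


@dataclass(frozen=True)
class LikelihoodResult:
    """Joint log likelihood split into its independent components."""

    insertion_term: float
    pattern_terms: tuple[float, ...]

    @property
    def deletion_term(self) -> float:
        return float(sum(self.pattern_terms))

    @property
    def total(self) -> float:
        return self.insertion_term + self.deletion_term


def insertion_log_likelihood(counts: PatternCounts, rates: InsertionRates, tree: HostTree) -> float:
    """Log of the product of per-branch Poisson pmfs at the observed N_i."""
    phi = rates.means(tree)
    total = 0.0
    for b in BRANCHES:
        n, mean = counts[b], phi[b]
        if mean == 0.0:
            if n > 0:
                return float("-inf")
            continue  # pmf at 0 with mean 0 is 1
        total += -mean + n * math.log(mean) - float(special.gammaln(n + 1))
    return total


def post_branch_times(tree: HostTree, b0: str) -> dict[str, tuple[float, float]]:
    """(t1, t2) for every post-insertion branch: start/end times measured
    from the origin of the insertion branch b0."""
    t_end = {b0: tree.branch_length[b0]}
    out: dict[str, tuple[float, float]] = {}
    for b in tree.descendants(b0):
        t1 = t_end[tree.parent(b)]
        t2 = t1 + tree.branch_length[b]
        t_end[b] = t2
        out[b] = (t1, t2)
    return out


def branch_transition_probs(tree: HostTree, b0: str, params: DeletionParams) -> tuple[float, dict[str, float]]:
    """(q1, p_retain): probability the provirus survives its insertion
    branch, and per post-insertion branch the probability a full-length
    lineage stays full-length across it."""
    t0 = tree.branch_length[b0]
    q1 = 1.0 - pr_delete_insertion_branch(params, t0)
    p_ret: dict[str, float] = {}
    for b, (t1, t2) in post_branch_times(tree, b0).items():
        p_ret[b] = pr_retain_post_branch(params, t1, t2, t=t0)
    return q1, p_ret


def _subtree_lik(
    tree: HostTree,
    branch: str,
    parent_state: str,
    states: Sequence[str],
    p_ret: Mapping[str, float],
) -> float:
    """Probability of the observed tip states at/below ``branch`` given the
    state at the branch's origin.  Only 1 and x occur below an insertion."""
    if parent_state == "x":
        options = (("x", 1.0),)
    else:
        p = p_ret[branch]
        options = (("1", p), ("x", 1.0 - p))
    total = 0.0
    for end_state, pr in options:
        if pr == 0.0:
            continue
        if branch in TIP_BRANCHES:
            if states[BRANCH_POSITION[branch]] == end_state:
                total += pr
        else:
            sub = pr
            for child in tree.children(branch):
                sub *= _subtree_lik(tree, child, end_state, states, p_ret)
                if sub == 0.0:
                    break
            total += sub
    return total


def pattern_likelihood_given_probs(
    tree: HostTree,
    b0: str,
    states: Sequence[str],
    q1: float,
    p_ret: Mapping[str, float],
) -> float:
    """Deletion-model probability of a pattern given its insertion branch
    and precomputed branch transition probabilities."""
    if b0 in TIP_BRANCHES:
        obs = states[BRANCH_POSITION[b0]]
        return q1 if obs == "1" else (1.0 - q1)
    total = 0.0
    for s0, pr in (("1", q1), ("x", 1.0 - q1)):
        if pr == 0.0:
            continue
        sub = pr
        for child in tree.children(b0):
            sub *= _subtree_lik(tree, child, s0, states, p_ret)
            if sub == 0.0:
                break
        total += sub
    return total


def pattern_log_likelihood(pattern: SitePattern | Sequence[str], tree: HostTree, params: DeletionParams) -> float:
    """Log probability of one site pattern under the deletion model,
    conditional on its (uniquely determined) insertion branch."""
    if not isinstance(pattern, SitePattern):
        pattern = SitePattern(tuple(pattern))
    b0 = insertion_branch(pattern, tree)
    q1, p_ret = branch_transition_probs(tree, b0, params)
    lik = pattern_likelihood_given_probs(tree, b0, pattern.states, q1, p_ret)
    return math.log(lik) if lik > 0 else float("-inf")


def pattern_distribution(tree: HostTree, params: DeletionParams, b0: str) -> dict[tuple[str, ...], float]:
    """Probability of every coherent outcome pattern for insertions on
    branch ``b0``; the values sum to 1."""
    q1, p_ret = branch_transition_probs(tree, b0, params)
    return {
        states: pattern_likelihood_given_probs(tree, b0, states, q1, p_ret)
        for states in enumerate_coherent_patterns(b0)
    }


class DeletionLikelihood:
    """Cached evaluator of the deletion log likelihood of a pattern set.

    Collapses duplicate patterns and computes branch transition
    probabilities once per parameter value and insertion branch; repeated
    evaluation during optimisation is then cheap.
    """

    def __init__(self, patterns: Iterable[SitePattern], tree: HostTree):
        self.tree = tree
        self._mult: dict[tuple[str, tuple[str, ...]], int] = {}
        self.n = 0
        for p in patterns:
            key = (insertion_branch(p, tree), p.states)
            self._mult[key] = self._mult.get(key, 0) + 1
            self.n += 1
        self._branches = sorted({b for b, _ in self._mult})

    def __call__(self, params: DeletionParams) -> float:
        total = 0.0
        for b0 in self._branches:
            q1, p_ret = branch_transition_probs(self.tree, b0, params)
            for (b, states), mult in self._mult.items():
                if b != b0:
                    continue
                lik = pattern_likelihood_given_probs(self.tree, b0, states, q1, p_ret)
                if lik <= 0.0:
                    return float("-inf")
                total += mult * math.log(lik)
        return total


def joint_log_likelihood(
    patterns: Sequence[SitePattern],
    tree: HostTree,
    rates: InsertionRates,
    params: DeletionParams,
) -> LikelihoodResult:
    """Insertion (Poisson) term plus per-pattern deletion terms.

    The insertion term depends only on the rates and the branch-assignment
    counts; the pattern terms depend only on the deletion parameters.
    """
    counts = count_insertions(patterns, tree)
    ins = insertion_log_likelihood(counts, rates, tree)
    cache: dict[str, tuple[float, dict[str, float]]] = {}
    terms: list[float] = []
    for p in patterns:
        b0 = insertion_branch(p, tree)
        if b0 not in cache:
            cache[b0] = branch_transition_probs(tree, b0, params)
        q1, p_ret = cache[b0]
        lik = pattern_likelihood_given_probs(tree, b0, p.states, q1, p_ret)
        terms.append(math.log(lik) if lik > 0 else float("-inf"))
    return LikelihoodResult(ins, tuple(terms))
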