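"""The fixed six-taxon primate host chronogram.

The model operates on a rooted tree of human (h), chimpanzee (c), gorilla
(g), orangutan (o) and macaque (m), with marmoset as an unmodelled
outgroup used only to polarise presence/absence.  The nine branches are the
five external ones plus the internal branches hc, hcg, hcgo and the root
branch hcgom (macaque/ape stem).  Branch lengths are durations in Myr.

The topology is fixed: the likelihood recursion and the site-pattern
semantics are hard-wired to this shape, and general trees are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

from . import families

#: All nine model branches, tips first.
BRANCHES: tuple[str, ...] = ("h", "c", "g", "o", "m", "hc", "hcg", "hcgo", "hcgom")
TIP_BRANCHES: tuple[str, ...] = ("h", "c", "g", "o", "m")
INTERNAL_BRANCHES: tuple[str, ...] = ("hc", "hcg", "hcgo", "hcgom")

#: Child -> parent branch; the root branch hcgom has no parent.
PARENT: dict[str, str | None] = {
    "h": "hc",
    "c": "hc",
    "g": "hcg",
    "o": "hcgo",
    "m": "hcgom",
    "hc": "hcg",
    "hcg": "hcgo",
    "hcgo": "hcgom",
    "hcgom": None,
}

#: Observation order of site-pattern positions.
TIP_ORDER: tuple[str, ...] = ("human", "chimp", "gorilla", "orangutan", "macaque", "marmoset")

#: Pattern position (0-based) -> tip branch.  Marmoset (position 5) carries
#: no branch: insertions are never observed there.
POSITION_BRANCH: dict[int, str] = {0: "h", 1: "c", 2: "g", 3: "o", 4: "m"}
BRANCH_POSITION: dict[str, int] = {b: i for i, b in POSITION_BRANCH.items()}

_CHILDREN: dict[str, tuple[str, ...]] = {b: tuple(sorted(c for c, p in PARENT.items() if p == b)) for b in BRANCHES}


class TreeError(ValueError):
    """Invalid chronogram configuration."""


@dataclass(frozen=True)
class HostTree:
    """The six-primate chronogram with branch durations in Myr."""

    branch_length: Mapping[str, float]

    def __post_init__(self) -> None:
        got = set(self.branch_length)
        if got != set(BRANCHES):
            missing = set(BRANCHES) - got
            extra = got - set(BRANCHES)
            raise TreeError(
                f"tree must name exactly the nine branches {BRANCHES}; "
                f"missing={sorted(missing)} unknown={sorted(extra)}"
            )
        for b, t in self.branch_length.items():
            if not (t > 0):
                raise TreeError(f"branch {b!r} has non-positive length {t!r}")
        object.__setattr__(self, "branch_length", dict(self.branch_length))

    # -- topology ---------------------------------------------------------
    @staticmethod
    def parent(branch: str) -> str | None:
        _check_branch(branch)
        return PARENT[branch]

    @staticmethod
    def children(branch: str) -> tuple[str, ...]:
        _check_branch(branch)
        return _CHILDREN[branch]

    @staticmethod
    def ancestors(branch: str) -> tuple[str, ...]:
        """Strict ancestors, nearest first."""
        _check_branch(branch)
        out = []
        b = PARENT[branch]
        while b is not None:
            out.append(b)
            b = PARENT[b]
        return tuple(out)

    @staticmethod
    def descendants(branch: str) -> tuple[str, ...]:
        """Strict descendants in pre-order (parents before children)."""
        _check_branch(branch)
        out: list[str] = []
        stack = list(_CHILDREN[branch])
        while stack:
            b = stack.pop(0)
            out.append(b)
            stack = list(_CHILDREN[b]) + stack
        return tuple(out)

    @staticmethod
    def tip_set(branch: str) -> frozenset[str]:
        """Tip branches at or below ``branch``."""
        _check_branch(branch)
        if branch in TIP_BRANCHES:
            return frozenset({branch})
        return frozenset(b for b in HostTree.descendants(branch) if b in TIP_BRANCHES)

    # -- metrics ----------------------------------------------------------
    def tip_depth(self, tip: str) -> float:
        """Time from the ape/macaque stem split down to a tip (excludes the
        root branch hcgom, which is shared by all tips)."""
        if tip not in TIP_BRANCHES:
            raise TreeError(f"{tip!r} is not a tip branch")
        total = self.branch_length[tip]
        for a in self.ancestors(tip):
            if a != "hcgom":
                total += self.branch_length[a]
        return total

    def ultrametric_deviation(self) -> float:
        depths = [self.tip_depth(t) for t in TIP_BRANCHES]
        return max(depths) - min(depths)


def _check_branch(branch: str) -> None:
    if branch not in PARENT:
        raise TreeError(f"unknown branch label {branch!r}")


def post_insertion_branches(tree: HostTree, insertion_branch: str) -> tuple[str, ...]:
    """All strict descendants of the insertion branch, pre-order."""
    _check_branch(insertion_branch)
    return tree.descendants(insertion_branch)


@lru_cache(maxsize=1)
def default_tree() -> HostTree:
    """Chronogram with branch durations recovered from the reference
    insertion-count/rate tables (see :func:`families.derive_branch_lengths`)."""
    return HostTree(families.derive_branch_lengths())


def load_tree(source: str | Path | Mapping[str, float]) -> HostTree:
    """Build a :class:`HostTree` from a mapping or a YAML/JSON config file.

    The config must list all nine branches with positive lengths, either at
    the top level or under a ``branch_length`` key.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        import yaml

        text = Path(source).read_text()
        doc = yaml.safe_load(text)
        if not isinstance(doc, Mapping):
            raise TreeError(f"tree config {source!s} is not a key-value document")
        doc = dict(doc)
    if "branch_length" in doc:
        doc = dict(doc["branch_length"])
    try:
        lengths = {str(k): float(v) for k, v in doc.items()}
    except (TypeError, ValueError) as exc:
        raise TreeError(f"non-numeric branch length in config: {exc}") from exc
    return HostTree(lengths)


_SPECIES_ALIASES = {
    "human": "h", "homo": "h", "h": "h",
    "chimp": "c", "chimpanzee": "c", "pan": "c", "c": "c",
    "gorilla": "g", "g": "g",
    "orangutan": "o", "orang": "o", "pongo": "o", "o": "o",
    "macaque": "m", "macaca": "m", "rhesus": "m", "m": "m",
    "marmoset": "marmoset", "callithrix": "marmoset",
}


def from_newick(newick: str) -> HostTree:
    """Read the chronogram from a Newick string.

    Accepts only trees that map onto the fixed 9-branch shape: six leaves
    recognisable as the study species (marmoset optional), with the nested
    ingroup topology (((((human,chimp),gorilla),orangutan),macaque),marmoset).
    """
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick")
    leaf_branch: dict = {}
    for leaf in t.leaf_node_iter():
        label = (leaf.taxon.label if leaf.taxon else leaf.label) or ""
        key = label.strip().lower().replace("_", " ").split()[0] if label.strip() else ""
        if key not in _SPECIES_ALIASES:
            raise TreeError(f"unrecognised leaf label {label!r}")
        leaf_branch[leaf] = _SPECIES_ALIASES[key]

    lengths: dict[str, float] = {}

    def clade_name(node) -> str | None:
        tips = frozenset(leaf_branch[l] for l in node.leaf_iter())
        wanted = {
            frozenset("h"): "h", frozenset("c"): "c", frozenset("g"): "g",
            frozenset("o"): "o", frozenset("m"): "m",
            frozenset({"h", "c"}): "hc",
            frozenset({"h", "c", "g"}): "hcg",
            frozenset({"h", "c", "g", "o"}): "hcgo",
            frozenset({"h", "c", "g", "o", "m"}): "hcgom",
        }
        return wanted.get(tips)

    for node in t.preorder_node_iter():
        name = clade_name(node)
        if name is None:
            tips = frozenset(leaf_branch[l] for l in node.leaf_iter())
            if tips == frozenset({"marmoset"}) or "marmoset" in tips and len(tips) == 6:
                continue  # marmoset leaf or the overall root
            raise TreeError("newick tree does not match the fixed 9-branch topology")
        if node.edge.length is None or node.edge.length <= 0:
            raise TreeError(f"branch {name!r} lacks a positive length")
        if name in lengths:
            raise TreeError(f"duplicate clade {name!r} in newick tree")
        lengths[name] = float(node.edge.length)
    return HostTree(lengths)
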