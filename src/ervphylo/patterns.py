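"""Site patterns: the unit observation of the framework.

A site pattern is a length-6 vector over the states

* ``0`` — locus absent (pre-integration site),
* ``1`` — ERV present in full-length or partial proviral form,
* ``x`` — solo-LTR (internal region and one LTR deleted by recombination),

in the fixed observation order human, chimp, gorilla, orangutan, macaque,
marmoset.  Marmoset is the outgroup and is always ``0``.  Because the only
permitted state history at a locus is ``0 -> 1 -> x``, the set of non-0
positions of a coherent pattern is exactly the tip set descending from one
branch of the chronogram, which identifies the insertion branch uniquely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .tree import BRANCHES, BRANCH_POSITION, POSITION_BRANCH, TIP_ORDER, HostTree, default_tree

STATES = ("0", "1", "x")

#: TSV column names of the native pattern format.
TSV_COLUMNS = (
    "family",
    "u_human",
    "u_chimp",
    "u_gorilla",
    "u_orangutan",
    "u_macaque",
    "u_marmoset",
    "location",
)


class InvalidPatternError(ValueError):
    """A state vector violating the site-pattern invariants."""


class IncoherentPatternError(InvalidPatternError):
    """A pattern whose non-0 support matches no clade of the host tree.

    Such patterns have no permitted ``0 -> 1 -> x`` history on the species
    tree; empirically they can arise from incomplete lineage sorting, which
    this framework excludes.
    """


def _normalise_states(states: Sequence) -> tuple[str, ...]:
    out = []
    for s in states:
        s = str(s).strip().lower()
        if s in {"0", "absent", "-"}:
            out.append("0")
        elif s in {"1", "full", "full-length", "provirus", "partial"}:
            out.append("1")
        elif s in {"x", "solo", "solo-ltr", "s"}:
            out.append("x")
        else:
            raise InvalidPatternError(f"unknown state symbol {s!r}")
    return tuple(out)


@dataclass(frozen=True)
class SitePattern:
    """One ERV locus observed across the six primates."""

    states: tuple[str, ...]
    family: str = "other"
    location: str | None = None

    def __post_init__(self) -> None:
        states = _normalise_states(self.states)
        if len(states) != 6:
            raise InvalidPatternError(f"pattern must have 6 positions, got {len(states)}")
        if states[5] != "0":
            raise InvalidPatternError(f"marmoset state must be 0, got {states[5]!r}")
        if all(s == "0" for s in states[:5]):
            raise InvalidPatternError("pattern has no evidence of insertion (all-0)")
        object.__setattr__(self, "states", states)

    @property
    def support(self) -> frozenset[str]:
        """Tip branches at which the locus is present (state 1 or x)."""
        return frozenset(POSITION_BRANCH[i] for i, s in enumerate(self.states[:5]) if s != "0")

    @property
    def is_mixed(self) -> bool:
        """True when both full-length and solo-LTR states are present."""
        return "1" in self.states and "x" in self.states


# tip-set -> branch lookup; fixed topology so module-level.
_SUPPORT_TO_BRANCH: dict[frozenset[str], str] = {HostTree.tip_set(b): b for b in BRANCHES}


def insertion_branch(pattern: SitePattern, tree: HostTree | None = None) -> str:
    """The unique branch on which the pattern's ERV first appeared.

    Raises :class:`IncoherentPatternError` when the non-0 support is not a
    clade of the tree.
    """
    support = pattern.support
    branch = _SUPPORT_TO_BRANCH.get(support)
    if branch is None:
        raise IncoherentPatternError(
            f"pattern {''.join(pattern.states)} has support {sorted(support)}, "
            "which is not the tip set of any branch (possible incomplete "
            "lineage sorting)"
        )
    return branch


def is_coherent(states: Sequence) -> bool:
    """Whether a raw state vector forms a valid, phylogenetically coherent
    site pattern."""
    try:
        insertion_branch(SitePattern(tuple(states)))
    except InvalidPatternError:
        return False
    return True


def enumerate_coherent_patterns(branch: str | None = None) -> list[tuple[str, ...]]:
    """All coherent state vectors, optionally restricted to one insertion
    branch.  Each tip below the insertion branch is independently 1 or x."""
    branches = [branch] if branch is not None else list(BRANCHES)
    out: list[tuple[str, ...]] = []
    for b in branches:
        tips = sorted(HostTree.tip_set(b), key=BRANCH_POSITION.get)
        for combo in itertools.product("1x", repeat=len(tips)):
            states = ["0"] * 6
            for tip, s in zip(tips, combo):
                states[BRANCH_POSITION[tip]] = s
            out.append(tuple(states))
    return out


@dataclass(frozen=True)
class PatternCounts:
    """Per-branch insertion counts N_i for one pattern set."""

    counts: dict[str, int]
    by_family: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {b: int(self.counts.get(b, 0)) for b in BRANCHES}
        if any(v < 0 for v in full.values()):
            raise ValueError("insertion counts must be non-negative")
        object.__setattr__(self, "counts", full)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, branch: str) -> int:
        return self.counts[branch]


def count_insertions(patterns: Iterable[SitePattern], tree: HostTree | None = None) -> PatternCounts:
    """Tally insertion branches over a pattern set."""
    counts = {b: 0 for b in BRANCHES}
    fam: dict[str, int] = {}
    for p in patterns:
        counts[insertion_branch(p, tree)] += 1
        fam[p.family] = fam.get(p.family, 0) + 1
    return PatternCounts(counts, fam)


# ---------------------------------------------------------------------------
# readers / writers


def write_patterns_tsv(patterns: Iterable[SitePattern], path: str | Path) -> None:
    rows = [
        {
            "family": p.family,
            **{f"u_{sp}": s for sp, s in zip(TIP_ORDER, p.states)},
            "location": p.location if p.location is not None else "",
        }
        for p in patterns
    ]
    pd.DataFrame(rows, columns=list(TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_patterns_tsv(path: str | Path, strict: bool = True) -> list[SitePattern] | tuple[list[SitePattern], list[tuple[int, str]]]:
    """Read the native TSV format.

    With ``strict=True`` (default) any invalid row aborts the read with a
    diagnostic listing every offending row.  With ``strict=False`` returns
    ``(patterns, errors)`` where errors is a list of (row index, reason).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise InvalidPatternError(f"pattern TSV {path!s} lacks columns {missing}")
    patterns: list[SitePattern] = []
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            states = tuple(row[f"u_{sp}"] for sp in TIP_ORDER)
            loc = row.get("location", "") or None
            p = SitePattern(states, family=row["family"], location=loc)
            insertion_branch(p)  # coherence check
            patterns.append(p)
        except InvalidPatternError as exc:
            errors.append((int(idx), str(exc)))
    if errors and strict:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in errors[:10])
        raise InvalidPatternError(f"{len(errors)} invalid rows in {path!s}: {detail}")
    if strict:
        return patterns
    return patterns, errors


def read_patterns_excel(path: str | Path, sheet: int | str = 0, family_column: str | None = None, strict: bool = True):
    """Tolerant reader for spreadsheet-dialect pattern tables.

    Looks for one column per species (matched by name prefix against the
    observation order) plus a family column; otherwise behaves like
    :func:`read_patterns_tsv`.
    """
    df = pd.read_excel(path, sheet_name=sheet, dtype=str)
    cols: dict[str, str] = {}
    lowered = {c.lower().strip(): c for c in df.columns}
    for sp in TIP_ORDER:
        match = next((orig for low, orig in lowered.items() if low.startswith(sp[:5]) or low == f"u_{sp}"), None)
        if match is None:
            raise InvalidPatternError(f"no column for species {sp!r} in {path!s}")
        cols[sp] = match
    if family_column is None:
        family_column = next((orig for low, orig in lowered.items() if "family" in low or "group" in low), None)
    patterns: list[SitePattern] = []
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            states = tuple(row[cols[sp]] for sp in TIP_ORDER)
            fam = str(row[family_column]) if family_column else "other"
            p = SitePattern(states, family=fam)
            insertion_branch(p)
            patterns.append(p)
        except InvalidPatternError as exc:
            errors.append((int(idx), str(exc)))
    if errors and strict:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in errors[:10])
        raise InvalidPatternError(f"{len(errors)} invalid rows in {path!s}: {detail}")
    return patterns if strict else (patterns, errors)
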