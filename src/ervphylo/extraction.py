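"""Site-pattern extraction from annotated multiple alignments.

Input is a six-row alignment (observation order human, chimp, gorilla,
orangutan, macaque, marmoset) plus per-species repeat-annotation intervals
in ungapped sequence coordinates (RepeatMasker/REannotate style, already
merged into per-insertion entities).  The pipeline is:

1. ``classify_alignment`` — code every alignment cell as ``d`` (unannotated
   nucleotide), ``g`` (gap), ``s-<family>-<k>`` (solo-LTR instance) or
   ``c-<family>-<k>`` (partial/full-length ERV instance).
2. ``partition_prepatterns`` — collapse maximal runs of identical columns
   into pre-patterns, discarding runs narrower than 50 columns.
3. ``scan_candidates`` — find windows of >= 3 pre-patterns anchored on both
   sides by all-``d`` pre-patterns whose interior carries one common s/c
   instance in some row and a gap throughout some row (the outgroup row
   must be gapped: insertions postdate the marmoset split).
4. ``code_pattern`` — convert each candidate to a site pattern: interior s
   -> x, interior c -> 1, all-d interior -> inherit 1 if the pattern already
   has one else x, all-g interior -> 0; marmoset is always 0.
5. ``postfilter`` — drop candidates with < 100 nt of flanking host sequence
   on either side or < 250 nt backing the inter-flank region, and relabel
   x -> 1 where the solo-LTR call is contradicted by near-complete homology
   with an aligned full-length row (85% rule).

Coordinates are 0-based half-open; annotation strand is ignored (pattern
state does not depend on it).  Nested insertions are not modelled: the
outer annotation wins.  Candidates whose coded pattern is phylogenetically
incoherent (possible incomplete lineage sorting) are dropped and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .patterns import IncoherentPatternError, SitePattern, insertion_branch
from .tree import TIP_ORDER

GAP = "-"
MIN_PREPATTERN = 50
MIN_FLANK = 100
MIN_INTERFLANK = 250
RELABEL_IDENTITY = 0.85


class ExtractionError(ValueError):
    pass


class Annotation(NamedTuple):
    """One repeat annotation in ungapped per-species coordinates."""

    species: str  # one of TIP_ORDER
    start: int  # 0-based, half-open
    end: int
    kind: str  # "s" (solo-LTR) or "c" (partial/full-length ERV)
    family: str
    instance: int | None = None  # per (species, family) numbering; auto if None


@dataclass(frozen=True)
class ClassificationMatrix:
    """6 x m grid of cell codes plus the underlying aligned rows."""

    codes: np.ndarray  # dtype=object, shape (6, m)
    rows: tuple[str, ...]  # aligned sequences, len 6

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(self.codes[:, j])


class PrePattern(NamedTuple):
    """A collapsed run of identical classification columns."""

    column: tuple[str, ...]
    width: int
    start: int  # alignment columns [start, end)
    end: int

    @property
    def all_d(self) -> bool:
        return all(c == "d" for c in self.column)


@dataclass(frozen=True)
class CandidateSubsequence:
    """A window of pre-patterns interpretable as one ERV locus."""

    prepatterns: tuple[PrePattern, ...]
    witness_row: int  # row carrying the common s/c instance
    witness_code: str

    @property
    def interior(self) -> tuple[PrePattern, ...]:
        return self.prepatterns[1:-1]

    @property
    def flank5(self) -> PrePattern:
        return self.prepatterns[0]

    @property
    def flank3(self) -> PrePattern:
        return self.prepatterns[-1]

    @property
    def family(self) -> str:
        # codes are kind-family-instance and the family itself may contain
        # dashes (e.g. s-HERV-H-4)
        return self.witness_code.split("-", 1)[1].rsplit("-", 1)[0]


# ---------------------------------------------------------------------------
# 1. classification


def classify_alignment(
    alignment: Sequence[str] | Mapping[str, str],
    annotations: Iterable[Annotation],
) -> ClassificationMatrix:
    """Combine aligned sequences with per-species repeat annotations.

    Overlapping annotations of the same species are rejected (nested
    insertions must be resolved to the outer element upstream).
    """
    if isinstance(alignment, Mapping):
        try:
            rows = tuple(alignment[sp] for sp in TIP_ORDER)
        except KeyError as exc:
            raise ExtractionError(f"alignment lacks species {exc}") from exc
    else:
        rows = tuple(alignment)
    if len(rows) != 6:
        raise ExtractionError(f"alignment must have 6 rows, got {len(rows)}")
    m = len(rows[0])
    if any(len(r) != m for r in rows):
        raise ExtractionError("alignment rows differ in length")

    codes = np.empty((6, m), dtype=object)
    # ungapped position -> column, per row
    col_of: list[np.ndarray] = []
    for i, row in enumerate(rows):
        cols = np.array([j for j, ch in enumerate(row) if ch != GAP], dtype=np.int64)
        col_of.append(cols)
        codes[i, :] = "g"
        codes[i, cols] = "d"

    sp_index = {sp: i for i, sp in enumerate(TIP_ORDER)}
    counters: dict[tuple[str, str], int] = {}
    seen: dict[int, list[tuple[int, int]]] = {i: [] for i in range(6)}
    for ann in annotations:
        if ann.species not in sp_index:
            raise ExtractionError(f"unknown species {ann.species!r}")
        if ann.kind not in ("s", "c"):
            raise ExtractionError(f"annotation kind must be 's' or 'c', got {ann.kind!r}")
        i = sp_index[ann.species]
        seq_len = len(col_of[i])
        if not (0 <= ann.start < ann.end <= seq_len):
            raise ExtractionError(
                f"annotation {ann} exceeds ungapped length {seq_len} of {ann.species}"
            )
        for s0, e0 in seen[i]:
            if ann.start < e0 and s0 < ann.end:
                raise ExtractionError(f"conflicting overlapping annotations on {ann.species}")
        seen[i].append((ann.start, ann.end))
        if ann.instance is None:
            key = (ann.species, ann.family)
            counters[key] = counters.get(key, 0) + 1
            inst = counters[key]
        else:
            inst = ann.instance
        code = f"{ann.kind}-{ann.family}-{inst}"
        codes[i, col_of[i][ann.start : ann.end]] = code
    return ClassificationMatrix(codes, rows)


# ---------------------------------------------------------------------------
# 2. pre-patterns


def partition_prepatterns(
    matrix: ClassificationMatrix, min_width: int = MIN_PREPATTERN
) -> list[PrePattern]:
    """Maximal runs of identical columns; runs narrower than ``min_width``
    are dropped.  Consecutive retained pre-patterns may be equal after the
    filter; they are deliberately not re-merged."""
    preps: list[PrePattern] = []
    j = 0
    m = matrix.m
    while j < m:
        col = matrix.column(j)
        k = j + 1
        while k < m and matrix.column(k) == col:
            k += 1
        if k - j >= min_width:
            preps.append(PrePattern(col, k - j, j, k))
        j = k
    return preps


# ---------------------------------------------------------------------------
# 3. candidate windows


def _common_instance_rows(interior: Sequence[PrePattern]) -> list[tuple[int, str]]:
    """Rows that carry one identical s/c instance code across every interior
    pre-pattern."""
    out = []
    for q in range(6):
        code = interior[0].column[q]
        if code[0] in ("s", "c") and all(p.column[q] == code for p in interior):
            out.append((q, code))
    return out


def _gapped_rows(interior: Sequence[PrePattern]) -> list[int]:
    return [q for q in range(6) if all(p.column[q] == "g" for p in interior)]


def window_is_candidate(window: Sequence[PrePattern], require_outgroup_gap: bool = True) -> bool:
    """Brute-force check of the three window conditions (plus the outgroup
    restriction): d-anchors, a common s/c instance row, a gapped row."""
    if len(window) < 3:
        return False
    if not (window[0].all_d and window[-1].all_d):
        return False
    interior = window[1:-1]
    if not _common_instance_rows(interior):
        return False
    gapped = _gapped_rows(interior)
    if not gapped:
        return False
    if require_outgroup_gap and 5 not in gapped:
        return False
    return True


def scan_candidates(
    prepatterns: Sequence[PrePattern], require_outgroup_gap: bool = True
) -> list[CandidateSubsequence]:
    """All windows of pre-patterns satisfying the candidate conditions.

    A valid interior cannot contain an all-d pre-pattern (it would break the
    common-instance condition), so the anchors of any candidate are
    consecutive all-d pre-patterns; the scan is linear.
    """
    anchors = [i for i, p in enumerate(prepatterns) if p.all_d]
    out: list[CandidateSubsequence] = []
    for a, b in zip(anchors, anchors[1:]):
        if b - a < 2:
            continue
        window = tuple(prepatterns[a : b + 1])
        if not window_is_candidate(window, require_outgroup_gap):
            continue
        q, code = _common_instance_rows(window[1:-1])[0]
        out.append(CandidateSubsequence(window, q, code))
    return out


# ---------------------------------------------------------------------------
# 4. coding


def code_pattern(candidate: CandidateSubsequence) -> SitePattern:
    """Apply the four coding rules to a candidate window.

    Per row, over the interior pre-patterns: any solo-LTR cell gives x; any
    provirus cell gives 1 (overriding x when a row shows both); an all-
    unannotated interior inherits 1 if the pattern already carries a 1,
    otherwise x; an all-gap interior gives 0.  Marmoset is coded 0 by
    construction (its interior is gapped).
    """
    interior = candidate.interior
    states: list[str | None] = [None] * 6
    for q in range(6):
        kinds = {p.column[q][0] for p in interior}
        if "s" in kinds:
            states[q] = "x"
        if "c" in kinds:
            states[q] = "1"
    has_one = "1" in states
    for q in range(6):
        if states[q] is not None:
            continue
        kinds = {p.column[q][0] for p in interior}
        if kinds == {"d"}:
            states[q] = "1" if has_one else "x"
        elif kinds == {"g"}:
            states[q] = "0"
        else:
            # mixed d/g interior without any annotation: alignment is broken
            # across the element; treat as absence of a confident call.
            states[q] = "0"
    states[5] = "0"
    return SitePattern(tuple(states), family=candidate.family)


# ---------------------------------------------------------------------------
# 5. post-filtering


def _backing(matrix: ClassificationMatrix, row: int, start: int, end: int) -> int:
    """Called (non-gap) nucleotides of one row across alignment columns
    [start, end)."""
    return sum(1 for j in range(start, end) if matrix.rows[row][j] != GAP)


def _identity_fraction(matrix: ClassificationMatrix, row_x: int, row_1: int, start: int, end: int) -> float:
    """Fraction of the full-length row's called inter-flank sequence that is
    matched identically by the solo-LTR row."""
    called_1 = 0
    ident = 0
    for j in range(start, end):
        c1 = matrix.rows[row_1][j]
        cx = matrix.rows[row_x][j]
        if c1 != GAP:
            called_1 += 1
            if cx != GAP and cx.upper() == c1.upper():
                ident += 1
    return ident / called_1 if called_1 else 0.0


@dataclass
class ExtractionResult:
    patterns: list[SitePattern]
    n_candidates: int = 0
    n_dropped_flank: int = 0
    n_dropped_interflank: int = 0
    n_incoherent: int = 0
    n_relabelled: int = 0
    mixed: list[SitePattern] = field(default_factory=list)


def postfilter(
    candidates: Sequence[CandidateSubsequence],
    matrix: ClassificationMatrix,
    min_flank: int = MIN_FLANK,
    min_interflank: int = MIN_INTERFLANK,
    relabel_identity: float = RELABEL_IDENTITY,
    relabel_mode: str = "identity",
) -> ExtractionResult:
    """Length/backing filters and the 85% solo-LTR relabelling rule.

    ``relabel_mode="identity"`` (default) converts an x to a 1 when at least
    ``relabel_identity`` of the called sequence backing an aligned
    full-length row's inter-flank region is matched identically by the
    solo-annotated row.  ``relabel_mode="length"`` is the simpler variant
    that compares called lengths only.
    """
    if relabel_mode not in ("identity", "length"):
        raise ExtractionError(f"unknown relabel mode {relabel_mode!r}")
    result = ExtractionResult(patterns=[], n_candidates=len(candidates))
    for cand in candidates:
        i_start = cand.interior[0].start
        i_end = cand.interior[-1].end
        if cand.flank5.width < min_flank or cand.flank3.width < min_flank:
            result.n_dropped_flank += 1
            continue
        backing = [_backing(matrix, q, i_start, i_end) for q in range(6)]
        if max(backing) < min_interflank:
            result.n_dropped_interflank += 1
            continue
        pattern = code_pattern(cand)
        states = list(pattern.states)
        one_rows = [q for q, s in enumerate(states) if s == "1"]
        if one_rows:
            for q, s in enumerate(states):
                if s != "x":
                    continue
                if relabel_mode == "identity":
                    score = max(_identity_fraction(matrix, q, q1, i_start, i_end) for q1 in one_rows)
                else:
                    score = max(
                        (backing[q] / backing[q1]) if backing[q1] else 0.0 for q1 in one_rows
                    )
                if score >= relabel_identity:
                    states[q] = "1"
                    result.n_relabelled += 1
        pattern = SitePattern(tuple(states), family=pattern.family)
        try:
            insertion_branch(pattern)
        except IncoherentPatternError:
            result.n_incoherent += 1
            continue
        if pattern.is_mixed:
            result.mixed.append(pattern)
        result.patterns.append(pattern)
    return result


def extract_patterns(
    alignment: Sequence[str] | Mapping[str, str],
    annotations: Iterable[Annotation],
    min_prepattern: int = MIN_PREPATTERN,
    min_flank: int = MIN_FLANK,
    min_interflank: int = MIN_INTERFLANK,
    relabel_identity: float = RELABEL_IDENTITY,
    relabel_mode: str = "identity",
) -> ExtractionResult:
    """Full pipeline: classify, collapse, scan, code, filter."""
    matrix = classify_alignment(alignment, annotations)
    preps = partition_prepatterns(matrix, min_width=min_prepattern)
    cands = scan_candidates(preps)
    return postfilter(
        cands,
        matrix,
        min_flank=min_flank,
        min_interflank=min_interflank,
        relabel_identity=relabel_identity,
        relabel_mode=relabel_mode,
    )


# ---------------------------------------------------------------------------
# fixture generator


@dataclass(frozen=True)
class PlantSpec:
    """One planted ERV locus for fixture construction."""

    states: tuple[str, ...]  # length 6, marmoset must be "0"
    family: str = "HERV-H"
    ltr_len: int = 120
    internal_len: int = 300


def make_fixture_alignment(
    plants: Sequence[PlantSpec],
    flank_len: int = 150,
    seed: int = 0,
) -> tuple[dict[str, str], list[Annotation], list[SitePattern]]:
    """Generate a toy annotated alignment with known extraction truth.

    Flanking host sequence is identical across species (noise-free
    orthology).  A state-1 species carries LTR + internal + LTR; a state-x
    species carries a single LTR aligned over the 5' LTR columns; a state-0
    species is gapped across the element.  Returns (alignment rows by
    species, annotations, truth patterns for phylogenetically coherent
    plants).
    """
    rng = np.random.default_rng(seed)
    if flank_len < 1:
        raise ExtractionError("flank_len must be positive")
    alph = np.array(list("ACGT"))

    def rand_seq(n: int) -> str:
        return "".join(rng.choice(alph, size=n))

    rows: dict[str, list[str]] = {sp: [] for sp in TIP_ORDER}
    annotations: list[Annotation] = []
    truth: list[SitePattern] = []
    cursor = {sp: 0 for sp in TIP_ORDER}  # ungapped position per species

    def emit_shared(seq: str) -> None:
        for sp in TIP_ORDER:
            rows[sp].append(seq)
            cursor[sp] += len(seq)

    emit_shared(rand_seq(flank_len))
    for plant in plants:
        states = tuple(plant.states)
        if len(states) != 6 or states[5] != "0":
            raise ExtractionError(f"plant states must be length 6 with marmoset 0: {states}")
        if any(s not in "01x" for s in states):
            raise ExtractionError(f"bad plant states {states}")
        ltr = rand_seq(plant.ltr_len)
        internal = rand_seq(plant.internal_len)
        full = ltr + internal + ltr
        # blocks with no full-length species are only one LTR wide,
        # otherwise spurious all-gap columns would appear
        width = len(full) if "1" in states else len(ltr)
        for q, sp in enumerate(TIP_ORDER):
            s = states[q]
            if s == "1":
                rows[sp].append(full)
                annotations.append(
                    Annotation(sp, cursor[sp], cursor[sp] + width, "c", plant.family)
                )
                cursor[sp] += width
            elif s == "x":
                rows[sp].append(ltr + GAP * (width - plant.ltr_len))
                annotations.append(
                    Annotation(sp, cursor[sp], cursor[sp] + plant.ltr_len, "s", plant.family)
                )
                cursor[sp] += plant.ltr_len
            else:
                rows[sp].append(GAP * width)
        emit_shared(rand_seq(flank_len))
        try:
            p = SitePattern(states, family=plant.family)
            insertion_branch(p)
        except (IncoherentPatternError, ValueError):
            continue
        truth.append(p)
    aligned = {sp: "".join(parts) for sp, parts in rows.items()}
    return aligned, annotations, truth
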