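"""Alignment classification, pre-patterns, window scanning, coding, filters."""

import itertools

import numpy as np
import pytest

from ervphylo.extraction import (
    Annotation,
    CandidateSubsequence,
    ClassificationMatrix,
    ExtractionError,
    PlantSpec,
    PrePattern,
    classify_alignment,
    code_pattern,
    extract_patterns,
    make_fixture_alignment,
    partition_prepatterns,
    postfilter,
    scan_candidates,
    window_is_candidate,
)
from ervphylo.patterns import SitePattern
from ervphylo.tree import TIP_ORDER


def D():
    return ("d",) * 6


class TestClassify:
    def test_unannotated_gapless_alignment_all_d(self):
        rows = {sp: "ACGT" * 10 for sp in TIP_ORDER}
        m = classify_alignment(rows, [])
        assert all(m.codes[i, j] == "d" for i in range(6) for j in range(40))

    def test_single_interval_codes_exact_columns(self):
        rows = {sp: "A" * 30 for sp in TIP_ORDER}
        m = classify_alignment(rows, [Annotation("human", 5, 12, "c", "HERV-H")])
        assert list(m.codes[0, 5:12]) == ["c-HERV-H-1"] * 7
        assert all(m.codes[0, j] == "d" for j in list(range(5)) + list(range(12, 30)))
        assert all(m.codes[1, j] == "d" for j in range(30))

    def test_gap_cells_and_coordinate_mapping(self):
        rows = {sp: "AAAAAAAAAA" for sp in TIP_ORDER}
        rows["chimp"] = "AAA----AAA"  # ungapped length 6
        m = classify_alignment(rows, [Annotation("chimp", 2, 5, "s", "ERV9")])
        assert list(m.codes[1, :]) == ["d", "d", "s-ERV9-1", "-g-g-g".split("-")[1], "g", "g", "g", "s-ERV9-1", "s-ERV9-1", "d"]

    def test_interval_exceeding_sequence_rejected(self):
        rows = {sp: "AAAA" for sp in TIP_ORDER}
        with pytest.raises(ExtractionError, match="exceeds"):
            classify_alignment(rows, [Annotation("human", 0, 10, "c", "X")])

    def test_overlapping_annotations_rejected(self):
        rows = {sp: "A" * 30 for sp in TIP_ORDER}
        anns = [Annotation("human", 0, 10, "c", "X"), Annotation("human", 5, 15, "s", "X")]
        with pytest.raises(ExtractionError, match="overlapping"):
            classify_alignment(rows, anns)


class TestPartition:
    def test_constant_matrix_single_prepattern(self):
        rows = {sp: "A" * 200 for sp in TIP_ORDER}
        preps = partition_prepatterns(classify_alignment(rows, []))
        assert len(preps) == 1 and preps[0].width == 200 and preps[0].all_d

    def test_sub_50_runs_dropped(self):
        # widths 60 / 49 / 70 with distinct columns -> the 49 run vanishes
        rows = {sp: "A" * 179 for sp in TIP_ORDER}
        anns = [Annotation("human", 60, 109, "s", "X"), Annotation("chimp", 109, 179, "c", "Y")]
        preps = partition_prepatterns(classify_alignment(rows, anns))
        assert [p.width for p in preps] == [60, 70]

    def test_random_matrices_match_run_length_oracle(self, rng):
        """Unfiltered partition widths must reproduce a brute-force
        run-length encoding of the column sequence."""
        for _ in range(30):
            m = int(rng.integers(1, 120))
            cols = rng.integers(0, 3, size=m)  # 3 distinct column types
            codes = np.empty((6, m), dtype=object)
            for j, c in enumerate(cols):
                codes[:, j] = ["d", "g", "s-X-1"][c]
            matrix = ClassificationMatrix(codes, tuple("A" * m for _ in range(6)))
            preps = partition_prepatterns(matrix, min_width=1)
            # oracle: itertools.groupby run lengths
            runs = [len(list(g)) for _, g in itertools.groupby(cols)]
            assert [p.width for p in preps] == runs
            assert sum(p.width for p in preps) == m


def random_prepatterns(rng, n):
    """Random symbolic pre-pattern sequence for scan testing."""
    pool = ["d", "g", "s-A-1", "s-A-2", "c-B-1"]
    preps = []
    pos = 0
    for _ in range(n):
        if rng.random() < 0.35:
            col = D()
        else:
            col = tuple(pool[i] for i in rng.integers(0, len(pool), size=6))
        w = int(rng.integers(50, 120))
        preps.append(PrePattern(col, w, pos, pos + w))
        pos += w
    return preps


def brute_force_windows(preps, require_outgroup_gap=True):
    """Quadratic oracle: re-check the candidate conditions from scratch for
    every O(n^2) window."""
    hits = []
    n = len(preps)
    for i in range(n):
        for j in range(i + 2, n):
            window = preps[i : j + 1]
            if window[0].column != D() or window[-1].column != D():
                continue
            interior = window[1:-1]
            common = False
            for q in range(6):
                first = interior[0].column[q]
                if first[0] in "sc" and all(p.column[q] == first for p in interior):
                    common = True
            gap_rows = [q for q in range(6) if all(p.column[q] == "g" for p in interior)]
            if not common or not gap_rows:
                continue
            if require_outgroup_gap and 5 not in gap_rows:
                continue
            hits.append((i, j))
    return hits


class TestScan:
    def test_worked_example_single_candidate(self):
        preps = [
            PrePattern(D(), 100, 0, 100),
            PrePattern(("s-A-1", "s-A-1", "s-A-1", "c-B-1", "g", "g"), 300, 100, 400),
            PrePattern(D(), 100, 400, 500),
        ]
        cands = scan_candidates(preps)
        assert len(cands) == 1
        assert cands[0].witness_row in (0, 1, 2, 3)

    def test_no_gap_row_no_candidate(self):
        preps = [
            PrePattern(D(), 100, 0, 100),
            PrePattern(("s-A-1",) * 6, 300, 100, 400),
            PrePattern(D(), 100, 400, 500),
        ]
        assert scan_candidates(preps) == []

    def test_outgroup_must_be_gapped(self):
        preps = [
            PrePattern(D(), 100, 0, 100),
            PrePattern(("s-A-1", "g", "d", "d", "d", "d"), 300, 100, 400),
            PrePattern(D(), 100, 400, 500),
        ]
        assert scan_candidates(preps) == []
        assert len(scan_candidates(preps, require_outgroup_gap=False)) == 1

    def test_matches_quadratic_oracle_on_random_sequences(self, rng):
        for trial in range(40):
            preps = random_prepatterns(rng, int(rng.integers(3, 60)))
            got = {(p.prepatterns[0].start, p.prepatterns[-1].end) for p in scan_candidates(preps)}
            expected = {
                (preps[i].start, preps[j].end) for i, j in brute_force_windows(preps)
            }
            assert got == expected


def literal_rule_interpreter(candidate):
    """Second, independent implementation of the four coding rules, applied
    row by row in their published order."""
    interior = candidate.interior
    u = [None] * 6
    for q in range(6):
        if any(p.column[q][0] == "s" for p in interior):
            u[q] = "x"
        if any(p.column[q][0] == "c" for p in interior):
            u[q] = "1"
    for q in range(6):
        if u[q] is None and all(p.column[q] == "d" for p in interior):
            u[q] = "1" if "1" in u else "x"
    for q in range(6):
        if u[q] is None and all(p.column[q] == "g" for p in interior):
            u[q] = "0"
    u = ["0" if v is None else v for v in u]  # mixed unannotated/gap: no call
    u[5] = "0"
    return tuple(u)


class TestCoding:
    def test_worked_example(self):
        cand = CandidateSubsequence(
            (
                PrePattern(D(), 100, 0, 100),
                PrePattern(("s-A-1", "s-A-1", "s-A-1", "c-B-1", "g", "g"), 300, 100, 400),
                PrePattern(D(), 100, 400, 500),
            ),
            witness_row=0,
            witness_code="s-A-1",
        )
        assert code_pattern(cand).states == ("x", "x", "x", "1", "0", "0")

    def test_terminal_presence_only(self):
        cand = CandidateSubsequence(
            (
                PrePattern(D(), 100, 0, 100),
                PrePattern(("c-B-1", "g", "g", "g", "g", "g"), 300, 100, 400),
                PrePattern(D(), 100, 400, 500),
            ),
            witness_row=0,
            witness_code="c-B-1",
        )
        assert code_pattern(cand).states == ("1", "0", "0", "0", "0", "0")

    def test_unannotated_row_inherits_presence(self):
        # all-d interior row: 1 if the pattern already carries a 1, else x
        base = [
            PrePattern(D(), 100, 0, 100),
            PrePattern(("c-B-1", "d", "g", "g", "g", "g"), 300, 100, 400),
            PrePattern(D(), 100, 400, 500),
        ]
        cand = CandidateSubsequence(tuple(base), 0, "c-B-1")
        assert code_pattern(cand).states == ("1", "1", "0", "0", "0", "0")
        solo = [
            PrePattern(D(), 100, 0, 100),
            PrePattern(("s-B-1", "d", "g", "g", "g", "g"), 300, 100, 400),
            PrePattern(D(), 100, 400, 500),
        ]
        cand = CandidateSubsequence(tuple(solo), 0, "s-B-1")
        assert code_pattern(cand).states == ("x", "x", "0", "0", "0", "0")

    def test_rule_order_matches_literal_interpreter(self, rng):
        """Randomised candidates (including rows mixing s and c of the same
        instance) decoded identically by the independent interpreter."""
        cells = ["s-A-1", "c-A-1", "d", "g"]
        for _ in range(200):
            k = int(rng.integers(1, 4))
            interior = []
            pos = 100
            for _ in range(k):
                col = [cells[i] for i in rng.integers(0, 4, size=5)]
                col.append("g")
                interior.append(PrePattern(tuple(col), 60, pos, pos + 60))
                pos += 60
            window = (
                PrePattern(D(), 100, 0, 100),
                *interior,
                PrePattern(D(), 100, pos, pos + 100),
            )
            if not window_is_candidate(window):
                continue
            q, code = next(
                (q, interior[0].column[q])
                for q in range(6)
                if interior[0].column[q][0] in "sc"
                and all(p.column[q] == interior[0].column[q] for p in interior)
            )
            cand = CandidateSubsequence(window, q, code)
            assert code_pattern(cand).states == literal_rule_interpreter(cand)


class TestPostfilter:
    def test_short_flank_dropped(self):
        rows, anns, truth = make_fixture_alignment(
            [PlantSpec(("1", "0", "0", "0", "0", "0"))], flank_len=99, seed=0
        )
        res = extract_patterns(rows, anns)
        assert res.patterns == [] and res.n_dropped_flank == 1

    def test_interflank_boundary_kept_at_250(self):
        keep = [PlantSpec(("1", "0", "0", "0", "0", "0"), ltr_len=50, internal_len=150)]  # 250 nt
        rows, anns, _ = make_fixture_alignment(keep, seed=1)
        assert len(extract_patterns(rows, anns).patterns) == 1
        drop = [PlantSpec(("1", "0", "0", "0", "0", "0"), ltr_len=50, internal_len=149)]  # 249 nt
        rows, anns, _ = make_fixture_alignment(drop, seed=1)
        res = extract_patterns(rows, anns)
        assert res.patterns == [] and res.n_dropped_interflank == 1

    def test_true_solo_ltr_not_relabelled(self):
        rows, anns, truth = make_fixture_alignment(
            [PlantSpec(("x", "x", "x", "1", "0", "0"))], seed=3
        )
        res = extract_patterns(rows, anns)
        assert [p.states for p in res.patterns] == [("x", "x", "x", "1", "0", "0")]
        assert res.n_relabelled == 0
        assert len(res.mixed) == 1  # mixed patterns are flagged for review

    def test_nearly_full_solo_annotation_relabelled(self):
        """A solo-annotated sequence homologous to ~96% of an aligned
        full-length element is corrected from x to 1 by the 85% rule."""
        rng = np.random.default_rng(5)
        element = "".join(rng.choice(list("ACGT"), size=500))
        flank = "".join(rng.choice(list("ACGT"), size=150))
        rows = {sp: flank + "-" * 500 + flank for sp in TIP_ORDER}
        rows["human"] = flank + element + flank
        rows["chimp"] = flank + element[:480] + "-" * 20 + flank
        anns = [
            Annotation("human", 150, 650, "c", "HERV-H"),
            Annotation("chimp", 150, 630, "s", "HERV-H"),
        ]
        res = extract_patterns(rows, anns)
        assert res.n_relabelled == 1
        assert [p.states for p in res.patterns] == [("1", "1", "0", "0", "0", "0")]
        # the length-ratio variant agrees in this clear-cut case
        res_len = extract_patterns(rows, anns, relabel_mode="length")
        assert [p.states for p in res_len.patterns] == [("1", "1", "0", "0", "0", "0")]


class TestFixtureRoundTrip:
    def test_single_plant_recovered_exactly(self):
        rows, anns, truth = make_fixture_alignment(
            [PlantSpec(("x", "x", "x", "1", "0", "0"), family="HERV-H")], seed=0
        )
        res = extract_patterns(rows, anns)
        assert [p.states for p in res.patterns] == [t.states for t in truth]
        assert res.patterns[0].family == "HERV-H"

    def test_sub_50_ltr_remnant_invisible(self):
        rows, anns, _ = make_fixture_alignment(
            [PlantSpec(("x", "0", "0", "0", "0", "0"), ltr_len=40, internal_len=0)], seed=0
        )
        res = extract_patterns(rows, anns)
        assert res.patterns == [] and res.n_candidates == 0

    def test_hundred_random_plants_recall_and_precision_one(self, rng):
        """Noise-free fixtures: extraction recovers exactly the planted
        coherent patterns (recall = precision = 1)."""
        from ervphylo.patterns import enumerate_coherent_patterns

        coherent = enumerate_coherent_patterns()
        plants = []
        for _ in range(100):
            states = coherent[int(rng.integers(0, len(coherent)))]
            plants.append(
                PlantSpec(
                    states,
                    family=str(rng.choice(["HERV-H", "ERV9", "HERV-K"])),
                    # LTRs long enough that even solo-only loci clear the
                    # 250 nt inter-flank backing filter
                    ltr_len=int(rng.integers(260, 400)),
                    internal_len=int(rng.integers(200, 400)),
                )
            )
        rows, anns, truth = make_fixture_alignment(plants, seed=17)
        res = extract_patterns(rows, anns)
        got = sorted((p.states, p.family) for p in res.patterns)
        expected = sorted((t.states, t.family) for t in truth)
        assert got == expected
        assert len(truth) == 100
        assert res.n_incoherent == 0

    def test_incoherent_plants_dropped_and_counted(self):
        plants = [
            PlantSpec(("1", "0", "1", "0", "0", "0")),  # not a clade
            PlantSpec(("1", "1", "0", "0", "0", "0")),
        ]
        rows, anns, truth = make_fixture_alignment(plants, seed=2)
        assert len(truth) == 1
        res = extract_patterns(rows, anns)
        assert res.n_incoherent == 1
        assert [p.states for p in res.patterns] == [("1", "1", "0", "0", "0", "0")]
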