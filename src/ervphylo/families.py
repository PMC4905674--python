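"""Reference data for six primate ERV families.

Published branch-specific insertion counts, relative insertion rates
(insertions per Myr), and deletion-model maximum-likelihood estimates for
the six ERV groups analysed over the human/chimp/gorilla/orangutan/macaque
phylogeny (marmoset outgroup).  These tables drive the defaults of the
synthetic-data generator and supply the chronogram branch lengths, which
are recovered from the (count, rate) pairs by least squares.
"""

from __future__ import annotations

FAMILIES = ("ERV9", "HERV-K11", "HERV-H", "HERV-K", "group-I", "group-II")

BRANCHES = ("h", "c", "g", "o", "m", "hc", "hcg", "hcgo", "hcgom")

#: Branch-specific insertion counts per family.
INSERTION_COUNTS: dict[str, dict[str, int]] = {
    "ERV9":     {"h": 0, "c": 0, "g": 1, "o": 37, "m": 78, "hc": 0, "hcg": 17, "hcgo": 81, "hcgom": 31},
    "HERV-K11": {"h": 0, "c": 0, "g": 0, "o": 7,  "m": 90, "hc": 0, "hcg": 4,  "hcgo": 69, "hcgom": 27},
    "HERV-H":   {"h": 0, "c": 0, "g": 0, "o": 16, "m": 54, "hc": 1, "hcg": 9,  "hcgo": 23, "hcgom": 13},
    "HERV-K":   {"h": 9, "c": 4, "g": 2, "o": 6,  "m": 17, "hc": 0, "hcg": 5,  "hcgo": 8,  "hcgom": 8},
    "group-I":  {"h": 0, "c": 1, "g": 9, "o": 1,  "m": 66, "hc": 0, "hcg": 2,  "hcgo": 14, "hcgom": 38},
    "group-II": {"h": 0, "c": 0, "g": 0, "o": 3,  "m": 41, "hc": 0, "hcg": 4,  "hcgo": 26, "hcgom": 38},
}

#: Published relative insertion rates (insertions per Myr), rounded to 2 dp.
INSERTION_RATES: dict[str, dict[str, float]] = {
    "ERV9":     {"h": 0.00, "c": 0.00, "g": 0.12, "o": 2.02, "m": 2.56, "hc": 0.00, "hcg": 1.75, "hcgo": 6.64, "hcgom": 2.50},
    "HERV-K11": {"h": 0.00, "c": 0.00, "g": 0.00, "o": 0.38, "m": 2.95, "hc": 0.00, "hcg": 0.41, "hcgo": 5.66, "hcgom": 2.18},
    "HERV-H":   {"h": 0.00, "c": 0.00, "g": 0.00, "o": 0.87, "m": 1.77, "hc": 0.50, "hcg": 0.93, "hcgo": 1.89, "hcgom": 1.05},
    "HERV-K":   {"h": 1.36, "c": 0.61, "g": 0.23, "o": 0.33, "m": 0.56, "hc": 0.00, "hcg": 0.52, "hcgo": 0.66, "hcgom": 0.65},
    "group-I":  {"h": 0.00, "c": 0.15, "g": 1.05, "o": 0.05, "m": 2.16, "hc": 0.00, "hcg": 0.21, "hcgo": 1.15, "hcgom": 3.06},
    "group-II": {"h": 0.00, "c": 0.00, "g": 0.00, "o": 0.16, "m": 1.34, "hc": 0.00, "hcg": 0.41, "hcgo": 2.13, "hcgom": 3.06},
}

#: Exponential deletion-rate MLEs (per Myr) per family.
EXPONENTIAL_RATE: dict[str, float] = {
    "ERV9": 0.14,
    "HERV-K11": 0.11,
    "HERV-H": 0.05,
    "HERV-K": 0.16,
    "group-I": 0.10,
    "group-II": 0.10,
}

#: Weibull MLEs per family as (inverse scale 1/psi_w in 1/Myr, shape omega).
#: For all families except HERV-H the estimates sit on the box boundary of
#: the constrained fit (inverse scale > 100, shape below the quoted value);
#: the boundary values are used as point values here.
WEIBULL_PARAMS: dict[str, tuple[float, float]] = {
    "ERV9": (100.0, 0.14),
    "HERV-K11": (100.0, 0.12),
    "HERV-H": (0.09, 0.18),
    "HERV-K": (100.0, 0.13),
    "group-I": (100.0, 0.13),
    "group-II": (100.0, 0.12),
}

#: Families whose Weibull MLEs hit the parameter box boundary.
WEIBULL_AT_BOUND = frozenset(f for f in FAMILIES if f != "HERV-H")

#: Published per-family log likelihoods (exponential, Weibull) of the
#: deletion component.  Used for likelihood-ratio arithmetic checks.
REFERENCE_LOG_LIKELIHOODS: dict[str, tuple[float, float]] = {
    "ERV9": (-158.54, -107.55),
    "HERV-K11": (-144.83, -74.68),
    "HERV-H": (-140.88, -121.79),
    "HERV-K": (-58.46, -32.33),
    "group-I": (-109.17, -47.54),
    "group-II": (-89.25, -50.62),
}


def derive_branch_lengths(
    counts: dict[str, dict[str, int]] | None = None,
    rates: dict[str, dict[str, float]] | None = None,
) -> dict[str, float]:
    """Branch durations (Myr) recovered from (count, rate) pairs.

    Each family supplies an observation ``N = rate * T`` per branch; the
    least-squares estimate pooling families is
    ``T = sum(N * rate) / sum(rate**2)`` over families with non-zero rate.
    Rounding noise in the published rates is averaged out across families.
    """
    counts = INSERTION_COUNTS if counts is None else counts
    rates = INSERTION_RATES if rates is None else rates
    lengths: dict[str, float] = {}
    for b in BRANCHES:
        num = 0.0
        den = 0.0
        for fam in counts:
            r = rates[fam][b]
            if r > 0:
                num += counts[fam][b] * r
                den += r * r
        if den == 0:
            raise ValueError(f"no family with positive rate on branch {b!r}")
        lengths[b] = num / den
    return lengths
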