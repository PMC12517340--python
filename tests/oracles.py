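"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — exhaustive enumeration and literal
set scans — and shares no code with the package's own computational paths.
"""

from __future__ import annotations

import math


def exhaustive_fisher_p(a: int, b: int, c: int, d: int, tie_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Sums P(table) over every table with the observed margins whose point
    probability is <= the observed table's (within a relative tie
    tolerance).
    """
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def log_prob(x: int) -> float:
        # P(a=x) = C(row1, x) C(row2, col1-x) / C(n, col1)
        return (math.lgamma(row1 + 1) - math.lgamma(x + 1) - math.lgamma(row1 - x + 1)
                + math.lgamma(row2 + 1) - math.lgamma(col1 - x + 1)
                - math.lgamma(row2 - col1 + x + 1)
                - (math.lgamma(n + 1) - math.lgamma(col1 + 1) - math.lgamma(n - col1 + 1)))

    lo, hi = max(0, col1 - row2), min(row1, col1)
    p_obs = math.exp(log_prob(a))
    total = 0.0
    for x in range(lo, hi + 1):
        p = math.exp(log_prob(x))
        if p <= p_obs * (1 + tie_tol):
            total += p
    return min(total, 1.0)


def brute_force_cells(db, drug_name: str, pt_term: str) -> tuple[int, int, int, int]:
    """2x2 cells by literal membership scan over the normalized frames."""
    key = drug_name.strip().casefold()
    drug_cases = {cid for cid, name in zip(db.drugs["case_id"], db.drugs["drug_name"])
                  if name.strip().casefold() == key}
    event_cases = {cid for cid, pt in zip(db.events["case_id"], db.events["pt_term"])
                   if pt == pt_term}
    all_cases = set(db.cases["case_id"])
    a = len(drug_cases & event_cases)
    b = len(drug_cases - event_cases)
    c = len(event_cases - drug_cases)
    d = len(all_cases - drug_cases - event_cases)
    return a, b, c, d


def direct_ror(a: float, b: float, c: float, d: float) -> float:
    return (a * d) / (b * c)


def direct_wald_ci(a: float, b: float, c: float, d: float, z: float = 1.959964):
    log_ror = math.log(direct_ror(a, b, c, d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def event_frequency_rank(db, drug_name: str) -> list[tuple[str, int]]:
    """(pt, count) pairs among a drug's cases, count desc then PT asc."""
    key = drug_name.strip().casefold()
    drug_cases = {cid for cid, name in zip(db.drugs["case_id"], db.drugs["drug_name"])
                  if name.strip().casefold() == key}
    counts: dict[str, set] = {}
    for cid, pt in zip(db.events["case_id"], db.events["pt_term"]):
        if cid in drug_cases:
            counts.setdefault(pt, set()).add(cid)
    return sorted(((pt, len(s)) for pt, s in counts.items()), key=lambda t: (-t[1], t[0]))
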