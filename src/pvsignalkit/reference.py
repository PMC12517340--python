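"""Published vedotin-ADC signal tables bundled as worked-example inputs.

Two transcribed disproportionality tables ship with the package: the JADER
screen (per-drug report counts, RORs and 95% CIs for polatuzumab,
brentuximab and enfortumab vedotin) and the corresponding FAERS top-50
screen.  They serve as fixture inputs for re-applying the signal criterion
and for margin-consistency checks; they are published summary rows, not a
raw report database.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .disproportionality import ContingencyTable, compute_ror

__all__ = [
    "load_reference_signals",
    "signal_counts",
    "reconstruct_table_from_margins",
    "JADER_TOTAL_REPORTS",
    "JADER_DRUG_REPORTS",
]

#: cumulative JADER report count over the study window (Apr 2004 – Jun 2023)
JADER_TOTAL_REPORTS = 2_200_140

#: suspect-drug report counts in the JADER screen
JADER_DRUG_REPORTS = {
    "polatuzumab vedotin": 2_168,
    "brentuximab vedotin": 2_673,
    "enfortumab vedotin": 1_688,
}


def load_reference_signals(dialect: str) -> pd.DataFrame:
    """The transcribed signal table for ``"jader"`` or ``"faers"``."""
    if dialect not in ("jader", "faers"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = resources.files("pvsignalkit.data").joinpath(f"{dialect}_reference_signals.csv")
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def signal_counts(table: pd.DataFrame) -> dict[str, int]:
    """Per-drug count of rows meeting the strict signal criterion ci_low > 1."""
    flagged = table[table["ci_low"] > 1.0]
    return flagged.groupby("drug").size().to_dict()


def reconstruct_table_from_margins(a: int, drug_total: int, grand_total: int,
                                   printed_ror: float) -> ContingencyTable:
    """Recover the full 2x2 table from its printed margins and ROR.

    Given the pair count ``a``, the drug's total report count, the database
    total and the published ROR, the unknown event-background cell ``c``
    solves the ROR identity

        ror = a * (N - drug_total - c) / (b * c),   b = drug_total - a,

    giving c = a * (N - drug_total) / (ror * b + a), rounded to the nearest
    integer report count.  ``compute_ror`` on the result should return the
    printed value up to rounding of the printed figure.
    """
    b = drug_total - a
    rest = grand_total - drug_total
    c = round(a * rest / (printed_ror * b + a))
    d = rest - c
    return ContingencyTable(a=a, b=b, c=int(c), d=int(d))


def reconstructed_cmv_reactivation_ror() -> float:
    """ROR recomputed from the polatuzumab / CMV-reactivation margins."""
    table = reconstruct_table_from_margins(
        a=29, drug_total=JADER_DRUG_REPORTS["polatuzumab vedotin"],
        grand_total=JADER_TOTAL_REPORTS, printed_ror=30.15)
    return compute_ror(table)
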