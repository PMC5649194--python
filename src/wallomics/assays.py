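"""Scalar cell-surface assays and the per-strain phenotype table.

The phenotype table collects, per strain, the cell-wall composition
(chitin, β-1,3-glucans, β-1,6-glucans, mannans as % of wall mass), the
octane-partitioning hydrophobicity index, the AFM-derived stiffness,
adhesion-event frequency and contour length, and the cell size — the block
the multi-block integration stage correlates against gene expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PHENOTYPE_COLUMNS",
    "PhenotypeTable",
    "hydrophobicity_index",
    "glucan_ratio",
    "validate_phenotype_table",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
]

PHENOTYPE_COLUMNS = [
    "chitin_pct", "b13_pct", "b16_pct", "mannan_pct",
    "hydrophobicity_pct", "stiffness_kPa", "adhesion_pct",
    "contour_nm", "size_um",
]

_PCT_FIELDS = ["chitin_pct", "b13_pct", "b16_pct", "mannan_pct",
               "hydrophobicity_pct", "adhesion_pct"]
_COMPOSITION_FIELDS = ["chitin_pct", "b13_pct", "b16_pct", "mannan_pct"]


@dataclass
class PhenotypeTable:
    """Strains × phenotype variables, with optional per-field SDs.

    ``data`` is a DataFrame indexed by strain with the columns of
    ``PHENOTYPE_COLUMNS`` and, optionally, matching ``<field>_sd`` columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")

    @property
    def strains(self) -> list:
        return list(self.data.index)

    def values_block(self) -> pd.DataFrame:
        """The strains × variables value block (no SD columns)."""
        return self.data[PHENOTYPE_COLUMNS]


def hydrophobicity_index(A0: float, AF: float, convention: str = "bounded") -> float:
    """Octane-adhesion (MATH-style) hydrophobicity index in percent.

    ``A0`` and ``AF`` are the OD600 of the aqueous cell suspension before and
    after octane partitioning.  The default ``"bounded"`` convention returns
    100·(A0−AF)/A0 ∈ [0, 100] — the fraction of cells that moved into the
    organic phase.  ``"literal"`` returns 100·(A0−AF)/AF (unbounded; kept
    for comparison with the alternative reading of the index).
    """
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    if AF < 0 or AF > A0:
        raise ValueError("AF must satisfy 0 <= AF <= A0")
    if convention == "bounded":
        return 100.0 * (A0 - AF) / A0
    if convention == "literal":
        if AF == 0:
            raise ValueError("literal convention undefined at AF=0")
        return 100.0 * (A0 - AF) / AF
    raise ValueError(f"unknown convention {convention!r}")


def glucan_ratio(b16_pct: float, b13_pct: float) -> float:
    """β-1,6-glucan share of total β-glucans: b16/(b16+b13)."""
    if b16_pct < 0 or b13_pct < 0:
        raise ValueError("glucan percentages must be non-negative")
    total = b16_pct + b13_pct
    if total == 0:
        raise ValueError("total beta-glucan content is zero")
    return b16_pct / total


def validate_phenotype_table(table: PhenotypeTable,
                             composition_range: tuple = (90.0, 110.0),
                             ) -> list[str]:
    """Check phenotype-table invariants; return one message per violation.

    Checks: all percentage fields in [0, 100]; the four-component wall
    composition sums within ``composition_range`` (measured wall recoveries
    cluster near 100 but rarely hit it exactly); all SD columns ≥ 0.
    An empty list means the table is valid.
    """
    violations: list[str] = []
    df = table.data
    for strain, row in df.iterrows():
        for fld in _PCT_FIELDS:
            v = row[fld]
            if not (0.0 <= v <= 100.0):
                violations.append(f"{strain}.{fld}: {v} outside [0, 100]")
        total = sum(row[f] for f in _COMPOSITION_FIELDS)
        lo, hi = composition_range
        if not (lo <= total <= hi):
            violations.append(f"{strain}.composition_sum: {total:.1f} outside [{lo}, {hi}]")
        for col in df.columns:
            if col.endswith("_sd") and row[col] < 0:
                violations.append(f"{strain}.{col}: negative SD {row[col]}")
    return violations


def read_phenotype_tsv(path) -> PhenotypeTable:
    """Read a phenotype table TSV (strain column + PHENOTYPE_COLUMNS [+ SDs])."""
    df = pd.read_csv(path, sep="\t", comment="#").set_index("strain")
    return PhenotypeTable(df)


def write_phenotype_tsv(table: PhenotypeTable, path) -> None:
    """Write a phenotype table; percentages in %, stiffness kPa, lengths nm/µm."""
    from .io_cli import atomic_write_text
    df = table.data.reset_index()
    df = df.rename(columns={df.columns[0]: "strain"})
    header = "# units: *_pct %, stiffness_kPa kPa, contour_nm nm, size_um um\n"
    atomic_write_text(path, header + df.to_csv(sep="\t", index=False))
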