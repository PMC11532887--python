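"""Binary symptom data model, delimited-text I/O, screening, and occurrence summaries.

The central container is :class:`BinarySymptomMatrix`: a case x symptom 0/1
table plus a per-case group label.  All downstream stages (network
estimation, centrality, communities, resampling, comparison) consume it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

__all__ = [
    "SymptomCatalog",
    "BinarySymptomMatrix",
    "load_matrix",
    "write_matrix",
    "filter_symptoms",
    "occurrence_table",
    "round_percent",
]


@dataclass(frozen=True)
class SymptomCatalog:
    """Ordered catalog of symptom codes with display names.

    Parameters
    ----------
    codes
        Short unique identifiers (e.g. ``"S1"``).
    names
        Display labels, parallel to ``codes``.  Defaults to the codes.
    """

    codes: tuple[str, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        codes = tuple(str(c) for c in self.codes)
        names = tuple(str(n) for n in self.names) if self.names else codes
        if len(codes) == 0:
            raise ValueError("catalog must contain at least one symptom")
        if any(c == "" for c in codes):
            raise ValueError("symptom codes must be non-empty")
        if len(set(codes)) != len(codes):
            raise ValueError("symptom codes must be unique")
        if len(names) != len(codes):
            raise ValueError("names must be parallel to codes")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.codes)

    def index_of(self, code: str) -> int:
        return self.codes.index(code)

    def subset(self, keep: Sequence[int]) -> "SymptomCatalog":
        return SymptomCatalog(
            tuple(self.codes[i] for i in keep), tuple(self.names[i] for i in keep)
        )


@dataclass
class BinarySymptomMatrix:
    """Case x symptom presence/absence table with per-case group labels.

    ``values`` is an ``(n_cases, p_symptoms)`` integer array of 0/1 entries;
    ``group`` holds one non-empty label per case.
    """

    values: np.ndarray
    catalog: SymptomCatalog
    group: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.group = np.asarray(self.group, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 1:
            raise ValueError("matrix must contain at least one case")
        if p != len(self.catalog):
            raise ValueError(
                f"matrix has {p} columns but catalog has {len(self.catalog)} symptoms"
            )
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry at case {bad[0]}, symptom "
                f"{self.catalog.codes[bad[1]]}"
            )
        if self.group.shape != (n,):
            raise ValueError("group labels must be one per case")
        if any(str(g) == "" for g in self.group):
            raise ValueError("group labels must be non-empty")

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def p_symptoms(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(str(g), None)
        return list(seen)

    def occurrence_rates(self) -> np.ndarray:
        """Per-symptom occurrence proportion (column mean)."""
        return self.values.mean(axis=0)

    def select_group(self, label: str) -> "BinarySymptomMatrix":
        mask = np.array([str(g) == label for g in self.group])
        if not mask.any():
            raise ValueError(f"no cases with group label {label!r}")
        return BinarySymptomMatrix(self.values[mask], self.catalog, self.group[mask])

    def subset_symptoms(self, keep: Sequence[int]) -> "BinarySymptomMatrix":
        keep = list(keep)
        return BinarySymptomMatrix(
            self.values[:, keep], self.catalog.subset(keep), self.group
        )

    def to_frame(self, group_column: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.catalog.codes))
        df[group_column] = [str(g) for g in self.group]
        return df


def round_percent(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage ``100 * count / total`` rounded half-up to ``ndigits``."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, ROUND_HALF_UP))


def _sniff_sep(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_matrix(path: str | Path, group_column: str = "group") -> BinarySymptomMatrix:
    """Read a delimited 0/1 table with a group column.

    The header row holds symptom codes plus ``group_column``; cells are 0, 1
    or empty.  Empty cells are filled with the per-symptom mode (ties go to
    0) and the number of fills is logged — full imputation is deliberately
    out of scope.

    Raises
    ------
    ValueError
        If a cell is neither 0, 1 nor empty (the offending row/column is
        named), or if ``group_column`` is missing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    if group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found in {path.name}")
    groups = df[group_column].to_numpy(dtype=object)
    data = df.drop(columns=[group_column])
    codes = [str(c) for c in data.columns]

    values = np.empty(data.shape, dtype=np.int8)
    missing = np.zeros(data.shape, dtype=bool)
    for j, code in enumerate(codes):
        col = data.iloc[:, j].str.strip()
        for i, cell in enumerate(col):
            if cell == "":
                missing[i, j] = True
                values[i, j] = 0
            elif cell in ("0", "1"):
                values[i, j] = int(cell)
            else:
                raise ValueError(
                    f"non-binary value {cell!r} at row {i + 2}, column {code!r}"
                )
    n_fill = int(missing.sum())
    if n_fill:
        for j in range(len(codes)):
            m = missing[:, j]
            if m.any():
                observed = values[~m, j]
                mode = 1 if observed.size and observed.mean() > 0.5 else 0
                values[m, j] = mode
        logger.info("filled %d empty cell(s) with per-symptom mode", n_fill)
    return BinarySymptomMatrix(values, SymptomCatalog(tuple(codes)), groups)


def write_matrix(
    m: BinarySymptomMatrix,
    path: str | Path,
    group_column: str = "group",
    sep: str = "\t",
) -> None:
    """Write the matrix in the same dialect :func:`load_matrix` reads."""
    m.to_frame(group_column).to_csv(path, sep=sep, index=False)


def filter_symptoms(
    m: BinarySymptomMatrix, lo: float = 0.01, hi: float = 0.99
) -> tuple[BinarySymptomMatrix, list[str]]:
    """Screen out symptoms with extreme occurrence rates.

    Retains symptoms whose occurrence rate satisfies ``lo <= rate <= hi``
    (boundaries inclusive: only rates strictly below ``lo`` or strictly
    above ``hi`` are excluded).  Returns the screened matrix and the list of
    excluded codes in catalog order.
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    rates = m.occurrence_rates()
    keep = [j for j in range(m.p_symptoms) if lo <= rates[j] <= hi]
    excluded = [m.catalog.codes[j] for j in range(m.p_symptoms) if j not in keep]
    if not keep:
        raise ValueError("no symptoms survive screening")
    if excluded:
        logger.info("screening excluded %d symptom(s): %s", len(excluded), excluded)
    return m.subset_symptoms(keep), excluded


def _two_group_p(a_pos: int, a_n: int, b_pos: int, b_n: int) -> float:
    """Yates continuity-corrected chi-square p for a 2x2 occurrence table."""
    table = np.array([[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0  # degenerate margin: no association testable
    return float(chi2_contingency(table, correction=True)[1])


def occurrence_table(m: BinarySymptomMatrix, group_column: str = "group") -> pd.DataFrame:
    """Per-symptom occurrence counts/percents, per group, with a 2x2 test.

    Percentages are rounded half-up to 2 decimals.  The comparison p-value
    (Yates continuity-corrected chi-square) is only filled when exactly two
    groups are present; otherwise the column is NaN.
    """
    labels = m.group_labels()
    counts_by_group = {}
    n_by_group = {}
    for g in labels:
        sub = m.select_group(g)
        if sub.n_cases == 0:
            raise ValueError(f"group {g!r} has zero cases")
        counts_by_group[g] = sub.values.sum(axis=0)
        n_by_group[g] = sub.n_cases

    n_total = m.n_cases
    total_counts = m.values.sum(axis=0)
    rows = []
    for j, code in enumerate(m.catalog.codes):
        row: dict[str, object] = {
            "symptom": m.catalog.names[j],
            "code": code,
            "n_total": int(total_counts[j]),
            "pct_total": round_percent(int(total_counts[j]), n_total),
        }
        for g in labels:
            row[f"n_{g}"] = int(counts_by_group[g][j])
            row[f"pct_{g}"] = round_percent(int(counts_by_group[g][j]), n_by_group[g])
        if len(labels) == 2:
            a, b = labels
            row["p"] = _two_group_p(
                int(counts_by_group[a][j]), n_by_group[a],
                int(counts_by_group[b][j]), n_by_group[b],
            )
        else:
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
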