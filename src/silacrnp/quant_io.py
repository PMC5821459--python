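"""Reading, filtering, and transforming quantified protein-group tables.

The universal input is the tab-delimited protein-group table emitted by the
MaxQuant-style search software ("proteinGroups" dialect): one protein group
per row with an unnormalized heavy/light SILAC ratio, a razor+unique peptide
count, and "+"-convention contaminant / reverse-decoy flags.  This module
turns pairs of label-swapped tables into the 2-D condition-fraction
coordinates every downstream statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError, FormatError

__all__ = [
    "DEFAULT_DIALECT",
    "LabelDesign",
    "ProteinGroupTable",
    "SwapPairCoordinates",
    "read_protein_groups",
    "write_protein_groups",
    "filter_groups",
    "heavy_fraction",
    "ratio_from_fraction",
    "condition_fraction",
    "merge_swap_pair",
]

#: logical field -> default column header in the proteinGroups dialect
DEFAULT_DIALECT: dict[str, str] = {
    "gene": "Gene names",
    "ratio": "Ratio H/L",
    "peptides": "Razor + unique peptides",
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
}

#: canonical internal column order
_COLUMNS = [
    "gene_symbol",
    "ratio_hl",
    "razor_unique_peptides",
    "is_contaminant",
    "is_reverse",
    "group_members",
]


@dataclass(frozen=True)
class LabelDesign:
    """Which experimental condition each isotope label carries in one mixture."""

    heavy: str
    light: str

    def __post_init__(self) -> None:
        if self.heavy == self.light:
            raise DesignError("heavy and light must carry different conditions")

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.heavy, self.light)

    def is_swap_of(self, other: "LabelDesign") -> bool:
        return self.heavy == other.light and self.light == other.heavy


@dataclass
class ProteinGroupTable:
    """Quantified protein groups from one SILAC mixture.

    ``df`` columns: gene_symbol, ratio_hl (NaN = missing), razor_unique_peptides,
    is_contaminant, is_reverse, group_members (the uncollapsed ";"-joined group).
    """

    df: pd.DataFrame
    sample_id: str
    design: LabelDesign

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"table missing internal columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_symbols(self) -> pd.Index:
        return pd.Index(self.df["gene_symbol"])


@dataclass
class SwapPairCoordinates:
    """Per-protein 2-D point: condition fraction in each of two swapped mixtures."""

    df: pd.DataFrame  # columns: protein, x, y
    condition: str
    dropped: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def points(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _parse_flag(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip().eq("+")


def _collapse_duplicates(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Keep one record per gene symbol: most razor+unique peptides, ties -> first."""
    dup_symbols = df.loc[df["gene_symbol"].duplicated(), "gene_symbol"].unique().tolist()
    if not dup_symbols:
        return df, []
    df = df.sort_values(
        ["gene_symbol", "razor_unique_peptides"],
        ascending=[True, False],
        kind="stable",
    )
    df = df.drop_duplicates("gene_symbol", keep="first")
    return df.sort_index(), dup_symbols


def read_protein_groups(
    path,
    design: LabelDesign,
    sample_id: str | None = None,
    dialect: dict[str, str] | None = None,
) -> ProteinGroupTable:
    """Parse one proteinGroups-dialect TSV into a :class:`ProteinGroupTable`.

    Ratios that are blank, NaN, zero, or infinite are preserved as missing
    (a zero or infinite unnormalized ratio means the protein was detected
    with one label only, so no meaningful fraction can be formed).
    Ambiguous groups ("A;B;C") are collapsed to the first symbol, with the
    full membership kept in ``group_members``.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - delegated to pandas
        raise FormatError(f"cannot read {path}: {exc}") from exc
    for logical, column in colmap.items():
        if column not in raw.columns:
            raise FormatError(
                f"required column {column!r} (field {logical!r}) absent from {path}"
            )

    genes = raw[colmap["gene"]].astype(str).str.strip()
    group_members = genes.copy()
    genes = genes.str.split(";").str[0]

    def _num(column: str, caster, what: str) -> pd.Series:
        out = []
        for i, cell in enumerate(raw[column]):
            cell = cell.strip()
            if cell in ("", "NaN", "nan", "NA"):
                out.append(np.nan)
                continue
            try:
                out.append(caster(cell))
            except ValueError as exc:
                raise FormatError(
                    f"unparsable {what} {cell!r} at row {i} of {path}"
                ) from exc
        return pd.Series(out, index=raw.index, dtype=float)

    ratio = _num(colmap["ratio"], float, "ratio")
    ratio[(ratio <= 0) | ~np.isfinite(ratio)] = np.nan
    peptides = _num(colmap["peptides"], float, "peptide count").fillna(0)
    if np.any(peptides < 0) or np.any(peptides != np.floor(peptides)):
        raise FormatError("peptide counts must be non-negative integers")

    df = pd.DataFrame(
        {
            "gene_symbol": genes,
            "ratio_hl": ratio,
            "razor_unique_peptides": peptides.astype(int),
            "is_contaminant": _parse_flag(raw[colmap["contaminant"]]),
            "is_reverse": _parse_flag(raw[colmap["reverse"]]),
            "group_members": group_members,
        }
    )
    df, _ = _collapse_duplicates(df)
    return ProteinGroupTable(
        df.reset_index(drop=True),
        sample_id=sample_id or str(path),
        design=design,
    )


def write_protein_groups(table: ProteinGroupTable, path, dialect: dict[str, str] | None = None) -> None:
    """Write a table back out in the proteinGroups dialect (round-trippable)."""
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    out = pd.DataFrame(
        {
            colmap["gene"]: table.df["group_members"],
            colmap["ratio"]: table.df["ratio_hl"],
            colmap["peptides"]: table.df["razor_unique_peptides"],
            colmap["contaminant"]: np.where(table.df["is_contaminant"], "+", ""),
            colmap["reverse"]: np.where(table.df["is_reverse"], "+", ""),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def filter_groups(
    table: ProteinGroupTable, min_peptides: int = 2
) -> tuple[ProteinGroupTable, dict[str, list[str]]]:
    """QC filtering: drop contaminants, reverse decoys, low-evidence and unquantified rows.

    Each removed record is logged under exactly one reason (checked in the
    order contaminant, reverse, low_peptides, missing_ratio), so the reasons
    partition the removed set.
    """
    df = table.df
    removal_log: dict[str, list[str]] = {
        "contaminant": [],
        "reverse": [],
        "low_peptides": [],
        "missing_ratio": [],
    }
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.is_contaminant:
            reason = "contaminant"
        elif row.is_reverse:
            reason = "reverse"
        elif row.razor_unique_peptides < min_peptides:
            reason = "low_peptides"
        elif not np.isfinite(row.ratio_hl):
            reason = "missing_ratio"
        else:
            continue
        keep[i] = False
        removal_log[reason].append(row.gene_symbol)
    filtered = replace(table, df=df.loc[keep].reset_index(drop=True))
    return filtered, removal_log


def heavy_fraction(r):
    """Heavy-channel fraction h = r / (1 + r) for heavy/light ratio r.

    Accepts scalars or arrays; missing (NaN) ratios propagate.  A bijection
    (0, inf) -> (0, 1) with inverse r = h / (1 - h).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise DomainError("heavy/light ratio must be strictly positive")
    h = arr / (1.0 + arr)
    return float(h) if np.isscalar(r) else h


def ratio_from_fraction(h):
    """Inverse of :func:`heavy_fraction`: r = h / (1 - h) for h in (0, 1)."""
    arr = np.asarray(h, dtype=float)
    if np.any((arr[np.isfinite(arr)] <= 0) | (arr[np.isfinite(arr)] >= 1)):
        raise DomainError("fraction must lie strictly inside (0, 1)")
    r = arr / (1.0 - arr)
    return float(r) if np.isscalar(h) else r


def condition_fraction(ratio_hl, design: LabelDesign, condition: str):
    """Fraction of signal attributable to ``condition`` given the label design.

    Returns h = r/(1+r) when the condition was heavy-labelled in this
    mixture, and 1 − h when it was light-labelled, so the two conditions'
    fractions always sum to exactly 1.
    """
    h = heavy_fraction(ratio_hl)
    if condition == design.heavy:
        return h
    if condition == design.light:
        return 1.0 - h
    raise DesignError(
        f"condition {condition!r} not in design {design.conditions}"
    )


def merge_swap_pair(
    table1: ProteinGroupTable, table2: ProteinGroupTable, condition: str
) -> SwapPairCoordinates:
    """Join two label-swapped mixtures into per-protein (x, y) coordinates.

    x is the ``condition`` fraction in ``table1``, y in ``table2``.  Only
    proteins quantified in both mixtures appear; the one-sided proteins are
    recorded in the drop log (the coordinates of a protein seen in a single
    mixture are undefined in this design).
    """
    if not table1.design.is_swap_of(table2.design):
        raise DesignError(
            "merge_swap_pair requires opposite label designs, got "
            f"{table1.design.conditions} and {table2.design.conditions}"
        )
    d1 = table1.df.dropna(subset=["ratio_hl"]).set_index("gene_symbol")
    d2 = table2.df.dropna(subset=["ratio_hl"]).set_index("gene_symbol")
    shared = d1.index.intersection(d2.index)
    dropped = {
        "only_in_mixture1": sorted(d1.index.difference(d2.index)),
        "only_in_mixture2": sorted(d2.index.difference(d1.index)),
    }
    x = condition_fraction(d1.loc[shared, "ratio_hl"].to_numpy(), table1.design, condition)
    y = condition_fraction(d2.loc[shared, "ratio_hl"].to_numpy(), table2.design, condition)
    df = pd.DataFrame({"protein": shared, "x": x, "y": y}).reset_index(drop=True)
    return SwapPairCoordinates(df, condition=condition, dropped=dropped)
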