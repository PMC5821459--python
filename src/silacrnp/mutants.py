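"""Catalytic-mutant (EN-, RT-) vs wild-type comparisons.

Each replicate mixes a light-labelled mutant capture with a heavy-labelled
wild-type capture, so a protein's heavy fraction h = r/(1+r) reads as its
relative retention by wild type: h = 0.5 means no change, h > 0.5 depletion
in the mutant.  Replicates are made comparable by translating all fractions
so the bait (ORF2p) sits exactly at 0.5; significance against 0.5 uses a
one-sample t-test per protein with Benjamini-Hochberg correction, and the
EN-vs-RT contrast uses a two-sample test.  For display, per-replicate
recovery folds normalized to the bait feed a pair of aligned histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .quant_io import ProteinGroupTable, heavy_fraction
from .stats import bh_adjust, one_sample_t, welch_t

__all__ = [
    "MutantExperiment",
    "shift_normalize",
    "relative_recovery",
    "require_replicates",
    "shifted_fraction_matrix",
    "recovery_matrix",
    "test_vs_wt",
    "test_en_vs_rt",
    "double_histogram",
    "significance_stars",
]


@dataclass
class MutantExperiment:
    """Replicated capture of one mutant (light) against wild type (heavy)."""

    mutant_label: str                    # "EN" or "RT"
    replicates: list[ProteinGroupTable]
    bait: str = "ORF2"

    def __post_init__(self) -> None:
        if not self.replicates:
            raise DomainError("experiment needs at least one replicate")
        for i, rep in enumerate(self.replicates):
            genes = set(rep.df.loc[rep.df["ratio_hl"].notna(), "gene_symbol"])
            if self.bait not in genes:
                raise DomainError(
                    f"bait {self.bait!r} not quantified in replicate {i} "
                    f"of experiment {self.mutant_label!r}"
                )


def shift_normalize(fractions: pd.Series, bait: str) -> tuple[pd.Series, list[str]]:
    """Translate heavy fractions so the bait sits exactly at 0.5.

    Returns the shifted series (unclipped: the translation preserves all
    pairwise differences, and clipping would bias the per-protein means)
    together with the labels that fall outside [0, 1] after the shift.
    """
    if bait not in fractions.index:
        raise DomainError(f"bait {bait!r} missing from replicate")
    shift = fractions.loc[bait] - 0.5
    shifted = fractions - shift
    out_of_range = shifted.index[(shifted < 0) | (shifted > 1)].tolist()
    return shifted, out_of_range


def relative_recovery(ratios: pd.Series, bait: str) -> pd.Series:
    """Mutant/WT recovery fold per protein, normalized so the bait reads 1.

    On the heavy/light scale v_i = (L/H)_i / (L/H)_bait = r_bait / r_i;
    invariant to any common rescaling of the replicate's ratios.
    """
    if bait not in ratios.index:
        raise DomainError(f"bait {bait!r} missing from replicate")
    if ratios.loc[bait] <= 0 or not np.isfinite(ratios.loc[bait]):
        raise DomainError("bait ratio must be positive and finite")
    return ratios.loc[bait] / ratios


def require_replicates(tables: list[ProteinGroupTable], min_n: int = 2) -> list[str]:
    """Proteins quantified in at least ``min_n`` of the given replicates."""
    counts: dict[str, int] = {}
    for t in tables:
        for g in t.df.loc[t.df["ratio_hl"].notna(), "gene_symbol"]:
            counts[g] = counts.get(g, 0) + 1
    return sorted(g for g, c in counts.items() if c >= min_n)


def _replicate_series(table: ProteinGroupTable) -> pd.Series:
    df = table.df.dropna(subset=["ratio_hl"])
    return pd.Series(df["ratio_hl"].to_numpy(), index=df["gene_symbol"].to_numpy())


def shifted_fraction_matrix(exp: MutantExperiment, min_n: int = 2) -> pd.DataFrame:
    """Proteins x replicates matrix of bait-shifted heavy fractions.

    Only proteins quantified in >= ``min_n`` replicates are retained; cells
    for replicates lacking the protein stay NaN.
    """
    keep = require_replicates(exp.replicates, min_n=min_n)
    cols = {}
    for i, rep in enumerate(exp.replicates):
        ratios = _replicate_series(rep)
        shifted, _ = shift_normalize(heavy_fraction_series(ratios), exp.bait)
        cols[f"rep{i + 1}"] = shifted
    mat = pd.DataFrame(cols).reindex(keep)
    mat.index.name = "protein"
    return mat


def heavy_fraction_series(ratios: pd.Series) -> pd.Series:
    return pd.Series(heavy_fraction(ratios.to_numpy()), index=ratios.index)


def recovery_matrix(exp: MutantExperiment, min_n: int = 2) -> pd.DataFrame:
    """Proteins x replicates matrix of bait-normalized recovery folds."""
    keep = require_replicates(exp.replicates, min_n=min_n)
    cols = {}
    for i, rep in enumerate(exp.replicates):
        cols[f"rep{i + 1}"] = relative_recovery(_replicate_series(rep), exp.bait)
    mat = pd.DataFrame(cols).reindex(keep)
    mat.index.name = "protein"
    return mat


def test_vs_wt(shifted: pd.DataFrame, mu0: float = 0.5) -> pd.DataFrame:
    """Per-protein one-sample t-test of the shifted fractions against 0.5.

    Zero-variance proteins are flagged degenerate and excluded from the BH
    family (their q is NaN).  Returns protein, n, mean, sd, t, df, p, q,
    degenerate.
    """
    rows = []
    for protein, row in shifted.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if vals.size < 2:
            continue
        res = one_sample_t(vals, mu0)
        rows.append(
            {
                "protein": protein,
                "n": vals.size,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=pd.Series(dtype=float))
    out["q"] = np.nan
    ok = ~out["degenerate"]
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def test_en_vs_rt(
    en: pd.DataFrame, rt: pd.DataFrame, equal_var: bool = False
) -> pd.DataFrame:
    """Per-protein two-sample test of EN vs RT shifted fractions (Welch default)."""
    shared = en.index.intersection(rt.index)
    rows = []
    for protein in shared:
        a = en.loc[protein].dropna().to_numpy(dtype=float)
        b = rt.loc[protein].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            continue
        res = welch_t(a, b, equal_var=equal_var)
        rows.append(
            {
                "protein": protein,
                "n_en": a.size,
                "n_rt": b.size,
                "mean_en": a.mean(),
                "mean_rt": b.mean(),
                "t": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=pd.Series(dtype=float))
    out["q"] = np.nan
    ok = ~out["degenerate"]
    if ok.any():
        out.loc[ok, "q"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def double_histogram(
    en_recovery: pd.Series,
    rt_recovery: pd.Series,
    bin_width: float = 2.0,
    bait_value: float = 1.0,
) -> dict:
    """Aligned EN/RT histograms of recovery folds with a crossing summary.

    Bin edges are anchored at 0 with the given width; the "crisscross"
    count is the number of proteins whose EN and RT positions fall on
    opposite sides of the bait position (a sign flip between mutants).
    """
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    shared = en_recovery.index.intersection(rt_recovery.index)
    en = en_recovery.loc[shared].astype(float)
    rt = rt_recovery.loc[shared].astype(float)
    hi = float(max(en.max(), rt.max(), bait_value))
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    counts_en, _ = np.histogram(en.to_numpy(), bins=edges)
    counts_rt, _ = np.histogram(rt.to_numpy(), bins=edges)
    positions = pd.DataFrame({"en": en, "rt": rt})
    crossing = (en - bait_value) * (rt - bait_value) < 0
    return {
        "edges": edges,
        "counts_en": counts_en,
        "counts_rt": counts_rt,
        "positions": positions,
        "crisscross": int(crossing.sum()),
        "crossing_proteins": sorted(positions.index[crossing]),
    }


def significance_stars(q: float) -> str:
    """Display convention: '*' for 0.01 < q <= 0.05, '**' for q <= 0.01."""
    if not np.isfinite(q):
        return ""
    if q <= 0.01:
        return "**"
    if q <= 0.05:
        return "*"
    return ""
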