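"""Concordance reporting between call sets.

Everything here is exact integer arithmetic on cross-tabulations: two
call matrices (or a printed contingency table read from TSV) become a
:class:`CallCrossTab`, from which agreement rates, VINO-call
breakdowns, parent-to-F1 genotype predictions and call-vs-sequence
statistics are derived as plain ratios of table cells.

Percentages are reported to two decimals with round-half-even.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CallCrossTab",
    "cross_tabulate",
    "pairwise_agreement",
    "vino_breakdown",
    "predict_f1",
    "f1_concordance_summary",
    "truth_concordance",
    "truth_concordance_stats",
    "as_percent",
]

_CANON = {"A": "AA", "H": "AB", "B": "BB", "AA": "AA", "AB": "AB", "BB": "BB", "N": "N", "V": "V"}


def as_percent(fraction: float) -> float:
    """Fraction -> percentage, two decimals, round-half-even."""
    return float(np.round(fraction * 100.0, 2))


@dataclass
class CallCrossTab:
    """A contingency table of calls from two sources."""

    counts: pd.DataFrame  # rows = source A classes, cols = source B classes

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_tsv(self, path):
        self.counts.rename_axis("call").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CallCrossTab":
        return cls(pd.read_csv(path, sep="\t", comment="#", index_col=0).astype(np.int64))


def cross_tabulate(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> CallCrossTab:
    """Count call pairs cell-by-cell over two aligned call matrices.

    Single-character calls are widened to the conventional AA/AB/BB
    labels; N and V pass through.
    """
    if calls_a.shape != calls_b.shape:
        raise ValueError("call matrices must share dimensions")
    if list(calls_a.columns) != list(calls_b.columns) or list(calls_a.index) != list(calls_b.index):
        raise ValueError("call matrices must share probe and sample order")
    a = pd.Series(calls_a.to_numpy(dtype=object).ravel()).map(_CANON)
    b = pd.Series(calls_b.to_numpy(dtype=object).ravel()).map(_CANON)
    tab = pd.crosstab(a, b)
    order = [c for c in ("AA", "AB", "BB", "V", "N") if c in tab.index]
    corder = [c for c in ("AA", "AB", "BB", "V", "N") if c in tab.columns]
    return CallCrossTab(tab.loc[order, corder].astype(np.int64))


def pairwise_agreement(tab: CallCrossTab, classes=("AA", "AB", "BB")) -> float:
    """Diagonal fraction of the classes x classes submatrix."""
    rows = [c for c in classes if c in tab.counts.index]
    cols = [c for c in classes if c in tab.counts.columns]
    common = [c for c in rows if c in cols]
    sub = tab.counts.loc[rows, cols]
    denom = int(sub.to_numpy().sum())
    if denom == 0:
        raise ValueError("empty submatrix: agreement undefined")
    num = sum(int(tab.counts.loc[c, c]) for c in common)
    return num / denom


def vino_breakdown(tab: CallCrossTab) -> tuple[pd.Series, int]:
    """The V row as per-column fractions plus its margin."""
    if "V" not in tab.counts.index:
        raise ValueError("cross-tab has no V row")
    row = tab.counts.loc["V"]
    margin = int(row.sum())
    if margin == 0:
        return row.astype(float) * np.nan, 0
    return row / margin, margin


# ---------------------------------------------------------------------------
# Parent -> F1 prediction


def predict_f1(parent1, parent2):
    """Predicted F1 categories from two parental vinotype vectors.

    Two homozygous parents yield a genotype prediction (AA+AA -> AA,
    BB+BB -> BB, opposite homozygotes -> AB).  Any parent that is AB, V
    or N yields only the compound category label ("AA,V", "V,N", ...)
    with no prediction.  Returns a DataFrame with columns ``category``
    and ``predicted`` (None where no prediction exists).
    """
    p1 = pd.Series(parent1).map(_CANON)
    p2 = pd.Series(parent2).map(_CANON)
    if p1.isna().any() or p2.isna().any():
        raise ValueError("unrecognized call symbol in parental vectors")
    cats = p1.str.cat(p2, sep=",")
    predicted = pd.Series([None] * len(p1), index=p1.index, dtype=object)
    both_hom = p1.isin(["AA", "BB"]) & p2.isin(["AA", "BB"])
    predicted[both_hom & (p1 == p2)] = p1[both_hom & (p1 == p2)]
    predicted[both_hom & (p1 != p2)] = "AB"
    return pd.DataFrame({"category": cats, "predicted": predicted})


def f1_concordance_summary(tab: CallCrossTab) -> dict:
    """Statistics of a (parental category) x (observed F1 call) table.

    * shared-homozygous concordance: fraction of AA,AA / BB,BB loci
      where the F1 call matches the shared parental allele;
    * the discordant remainder split into N-or-V, wrong-het (AB) and
      wrong-homozygote counts;
    * predicted-het concordance over the AA,BB / BB,AA rows.

    A statistic whose rows are absent from the table is reported as
    None rather than zero.
    """
    c = tab.counts
    out = {
        "shared_hom_concordance": None,
        "shared_hom_discordant": None,
        "discordant_n_or_v": None,
        "discordant_wrong_het": None,
        "discordant_wrong_hom": None,
        "predicted_het_concordance": None,
    }
    hom_rows = [r for r in ("AA,AA", "BB,BB") if r in c.index]
    if hom_rows:
        num = 0
        denom = 0
        n_or_v = wrong_het = wrong_hom = 0
        for r in hom_rows:
            allele = r.split(",")[0]
            denom += int(c.loc[r].sum())
            num += int(c.loc[r, allele]) if allele in c.columns else 0
            n_or_v += sum(int(c.loc[r, x]) for x in ("N", "V") if x in c.columns)
            wrong_het += int(c.loc[r, "AB"]) if "AB" in c.columns else 0
            other = "BB" if allele == "AA" else "AA"
            wrong_hom += int(c.loc[r, other]) if other in c.columns else 0
        out["shared_hom_concordance"] = num / denom
        out["shared_hom_discordant"] = denom - num
        out["discordant_n_or_v"] = n_or_v
        out["discordant_wrong_het"] = wrong_het
        out["discordant_wrong_hom"] = wrong_hom
    het_rows = [r for r in ("AA,BB", "BB,AA") if r in c.index]
    if het_rows:
        denom = sum(int(c.loc[r].sum()) for r in het_rows)
        num = sum(int(c.loc[r, "AB"]) for r in het_rows if "AB" in c.columns)
        out["predicted_het_concordance"] = num / denom if denom else None
    return out


# ---------------------------------------------------------------------------
# Calls vs sequence-derived truth classes


def truth_concordance(calls: pd.DataFrame, truth: pd.DataFrame):
    """Cross-tabulate a vinotype matrix against per-cell truth classes.

    Truth classes are {AA, BB, AB, Deleted, Inaccessible, Excluded}.
    Returns ``(CallCrossTab, stats dict)``; see
    :func:`truth_concordance_stats` for the statistics.
    """
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must share dimensions")
    a = pd.Series(calls.to_numpy(dtype=object).ravel()).map(_CANON)
    b = pd.Series(truth.to_numpy(dtype=object).ravel()).map(lambda x: _CANON.get(x, x))
    tab = pd.crosstab(a, b)
    order = [c for c in ("AA", "AB", "BB", "V", "N") if c in tab.index]
    corder = [c for c in ("AA", "BB", "AB", "Deleted", "Inaccessible", "Excluded") if c in tab.columns]
    xtab = CallCrossTab(tab.loc[order, corder].astype(np.int64))
    return xtab, truth_concordance_stats(xtab)


def truth_concordance_stats(tab: CallCrossTab) -> dict:
    """Derived statistics of a calls x truth-class cross-tab.

    * het_call_rate: AB-row margin over the grand total;
    * hom_concordance: diagonal fraction of the {AA,BB} x {AA,BB} block;
    * v_total / v_rate: V-row margin and its fraction of all calls;
    * v_hom_fraction: fraction of V calls whose truth is AA or BB.
    """
    c = tab.counts
    total = tab.total
    stats = {}
    stats["het_call_rate"] = int(c.loc["AB"].sum()) / total if "AB" in c.index else 0.0
    hom_rows = [r for r in ("AA", "BB") if r in c.index]
    hom_cols = [r for r in ("AA", "BB") if r in c.columns]
    block = c.loc[hom_rows, hom_cols]
    denom = int(block.to_numpy().sum())
    diag = sum(int(c.loc[r, r]) for r in hom_rows if r in hom_cols)
    stats["hom_concordance"] = diag / denom if denom else None
    if "V" in c.index:
        v_margin = int(c.loc["V"].sum())
        stats["v_total"] = v_margin
        stats["v_rate"] = v_margin / total
        v_hom = sum(int(c.loc["V", col]) for col in hom_cols)
        stats["v_hom_fraction"] = v_hom / v_margin if v_margin else None
    else:
        stats["v_total"] = 0
        stats["v_rate"] = 0.0
        stats["v_hom_fraction"] = None
    return stats
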