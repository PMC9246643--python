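"""Diagnostic-concordance statistics for 2x2 reading-vs-reference tables.

An MRI reading scored against an arthroscopic reference standard yields a
2x2 contingency table (TP, FP, FN, TN).  From it:

    sensitivity = TP / (TP + FN)        (per cent)
    specificity = TN / (FP + TN)        (per cent)
    accuracy    = (TP + TN) / n         (per cent)
    kappa       = (p0 - pe) / (1 - pe)  (Cohen's chance-corrected agreement)

with observed agreement p0 = (TP + TN)/n and chance agreement
pe = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n^2.  Kappa is banded as
poor-or-general (< 0.45), strong (0.45–0.75) and very-strong (> 0.75).
Two readings are compared by a chi-square test (no continuity correction)
on their correct/incorrect counts.

Five packaged tables ship with the module: four single-sequence knee-MRI
readings (T1WI, T2WI, SE-T2WI, FS-T2WI) and one multimodal reading, each
scoring 198 cartilages against arthroscopy (123 with lesions, 75 without).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticSummary",
    "ChiSquareResult",
    "summarize",
    "kappa_band",
    "chi_square_compare",
    "load_fixture_tables",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), the display convention."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """TP/FP/FN/TN counts of a reading against the reference standard.

    Marginals are always derived from the cells (the packaged multimodal
    table's printed row total is internally inconsistent; cells govern).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    label: str = ""

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError("cell counts must be nonnegative")
        if sum(cells) < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def correct(self) -> int:
        return self.tp + self.tn

    @property
    def incorrect(self) -> int:
        return self.fp + self.fn


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity/accuracy (per cent), kappa and its band.

    Sensitivity or specificity is None when the reference margin it
    conditions on is empty.  Values are unrounded; use
    :func:`round_half_up` for display.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float
    kappa: float
    kappa_band: str
    n: int
    label: str = ""


def summarize(table: ContingencyTable2x2) -> DiagnosticSummary:
    """All four concordance statistics of one 2x2 table."""
    n = table.n
    ref_pos = table.tp + table.fn
    ref_neg = table.fp + table.tn
    sens = 100.0 * table.tp / ref_pos if ref_pos >= 1 else None
    spec = 100.0 * table.tn / ref_neg if ref_neg >= 1 else None
    acc = 100.0 * table.correct / n

    p0 = table.correct / n
    pe = ((table.tp + table.fp) * ref_pos + (table.fn + table.tn) * ref_neg) / n**2
    kappa = 1.0 if pe == 1.0 and p0 == 1.0 else (p0 - pe) / (1.0 - pe)
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        kappa=kappa,
        kappa_band=kappa_band(kappa),
        n=n,
        label=table.label,
    )


def kappa_band(kappa: float) -> str:
    """Agreement band: < 0.45 poor-or-general, 0.45–0.75 strong, else very-strong."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0.45:
        return "poor-or-general"
    if kappa <= 0.75:
        return "strong"
    return "very-strong"


class ChiSquareResult(NamedTuple):
    chi2: float
    p: float
    expected_ok: bool


def chi_square_compare(
    a: ContingencyTable2x2, b: ContingencyTable2x2
) -> ChiSquareResult:
    """Chi-square comparison of two readings' accuracies.

    Builds the 2x2 table of correct/incorrect counts by reading method and
    applies the chi-square test of independence without continuity
    correction.  ``expected_ok`` is False (with a warning) when any expected
    cell falls below 1.
    """
    obs = np.array([[a.correct, a.incorrect], [b.correct, b.incorrect]], float)
    if obs.sum(axis=1).min() < 1:
        raise ValueError("degenerate table: no observations in one reading")
    expected = stats.contingency.expected_freq(obs)
    ok = bool(expected.min() >= 1.0)
    if not ok:
        warnings.warn("chi-square expected count below 1", stacklevel=2)
    if np.allclose(obs[0], obs[1]):
        return ChiSquareResult(0.0, 1.0, ok)
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(chi2), float(p), ok)


def load_fixture_tables() -> list[ContingencyTable2x2]:
    """The five packaged knee-MRI reading tables (n = 198 each)."""
    path = resources.files("ilrdd.data").joinpath("koa_reading_tables.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return [
        ContingencyTable2x2(
            tp=int(r["tp"]), fp=int(r["fp"]), fn=int(r["fn"]), tn=int(r["tn"]),
            label=r["label"],
        )
        for r in rows
    ]


def read_tables_csv(path) -> list[ContingencyTable2x2]:
    """Read tables from a CSV with header tp,fp,fn,tn,label."""
    with open(path, "r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return [
        ContingencyTable2x2(
            tp=int(r["tp"]), fp=int(r["fp"]), fn=int(r["fn"]), tn=int(r["tn"]),
            label=r.get("label", ""),
        )
        for r in rows
    ]
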