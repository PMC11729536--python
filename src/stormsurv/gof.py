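"""U-CARE-style goodness-of-fit tests for the time-dependent CJS model.

Three contingency-table tests are implemented:

* **Test 2.CT** (trap-dependence): among individuals detected at or before
  occasion *i* and detected again afterwards, is detection at *i* associated
  with the next detection falling at *i+1* rather than later?  A positive
  pooled (Mantel-Haenszel-style) z means "trap-happiness".
* **Test 3.SR** (transience): among individuals detected at occasion *i*, are
  newly marked individuals as likely as previously marked ones to ever be
  detected again?
* **Test 3.SM**: among individuals detected at *i* and detected again later,
  does the timing of the next detection (at *i+1* vs later) depend on whether
  the mark is new?

Each per-occasion 2x2 table contributes a raw Pearson chi-square with 1 df;
no continuity correction is applied.  A table is informative only if every
margin is positive and all expected counts are at least 2 (a documented
surrogate for U-CARE's pooling rules); non-informative tables carry df 0.
The variance inflation factor is the ratio of summed chi-square to summed df
over a chosen set of tests (by default excluding 2.CT, whose signal is
instead modelled structurally via trap-dependent resighting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .encounters import EncounterHistory, histories_to_matrix

__all__ = [
    "ContingencyComponent",
    "TestResult",
    "GofResult",
    "pearson_chi2",
    "test_2ct",
    "test_3sr",
    "test_3sm",
    "estimate_chat",
    "run_gof",
]

MIN_EXPECTED = 2.0


@dataclass
class ContingencyComponent:
    occasion: int
    table: np.ndarray          # 2x2 counts
    chi2: float
    df: int
    informative: bool
    # contributions to the pooled directional statistic
    mh_num: float = 0.0        # O11 - E11
    mh_var: float = 0.0


@dataclass
class TestResult:
    name: str
    components: list[ContingencyComponent]
    chi2: float
    df: int
    p: float | None            # None when df == 0 (all tables non-informative)
    signed_z: float | None = None

    @property
    def informative(self) -> bool:
        return self.df > 0


@dataclass
class GofResult:
    tests: dict[str, TestResult]
    chat: float
    chat_components: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tests.values():
            for c in t.components:
                rows.append(
                    {
                        "test": t.name,
                        "occasion": c.occasion,
                        "chi2": c.chi2,
                        "df": c.df,
                        "informative": c.informative,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "tests": {
                t.name: {"chi2": t.chi2, "df": t.df, "p": t.p, "signed_z": t.signed_z}
                for t in self.tests.values()
            },
            "chat": self.chat,
            "chat_components": list(self.chat_components),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def pearson_chi2(table: np.ndarray) -> tuple[float, int, float, float]:
    """Raw Pearson chi-square for a 2x2 table plus MH directional pieces.

    Returns (chi2, df, O11-E11, hypergeometric variance of O11).  df is 0
    (table non-informative) when any margin is zero or any expected count
    falls below ``MIN_EXPECTED``.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0, 0, 0.0, 0.0
    expected = np.outer(rows, cols) / n
    if (expected < MIN_EXPECTED).any():
        return 0.0, 0, 0.0, 0.0
    chi2 = float(((table - expected) ** 2 / expected).sum())
    num = float(table[0, 0] - expected[0, 0])
    var = float(rows[0] * rows[1] * cols[0] * cols[1] / (n**2 * (n - 1))) if n > 1 else 0.0
    return chi2, 1, num, var


def _assemble(name: str, comps: list[ContingencyComponent], signed: bool) -> TestResult:
    chi2 = float(sum(c.chi2 for c in comps))
    df = int(sum(c.df for c in comps))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else None
    z = None
    if signed:
        var = sum(c.mh_var for c in comps if c.informative)
        if var > 0:
            z = float(sum(c.mh_num for c in comps if c.informative) / np.sqrt(var))
    return TestResult(name, comps, chi2, df, p, z)


def _as_matrix(histories) -> np.ndarray:
    if isinstance(histories, np.ndarray):
        return np.asarray(histories, dtype=int)
    return histories_to_matrix(histories)


def test_2ct(histories) -> TestResult:
    """Trap-dependence test; positive signed z = trap-happiness."""
    X = _as_matrix(histories)
    n_occ = X.shape[1]
    if n_occ < 3:
        raise ValueError("Test 2.CT needs at least 3 occasions")
    first = np.argmax(X, axis=1) + 1  # 1-based first detection
    comps: list[ContingencyComponent] = []
    for i in range(2, n_occ - 1):  # 1-based interior occasions 2..n_occ-2
        seen_by_i = first <= i
        after = X[:, i:]  # occasions i+1..n_occ (0-based cols i..)
        has_after = after.any(axis=1)
        sel = seen_by_i & has_after
        if not sel.any():
            comps.append(ContingencyComponent(i, np.zeros((2, 2)), 0.0, 0, False))
            continue
        seen_at_i = X[sel, i - 1] == 1
        next_at_ip1 = X[sel, i] == 1
        # rows: seen at i yes/no; cols: next detection at i+1 / later
        table = np.array(
            [
                [(seen_at_i & next_at_ip1).sum(), (seen_at_i & ~next_at_ip1).sum()],
                [(~seen_at_i & next_at_ip1).sum(), (~seen_at_i & ~next_at_ip1).sum()],
            ],
            dtype=float,
        )
        chi2, df, num, var = pearson_chi2(table)
        comps.append(ContingencyComponent(i, table, chi2, df, df > 0, num, var))
    return _assemble("2.CT", comps, signed=True)


def test_3sr(histories) -> TestResult:
    """Transience test; positive signed z = newly marked return less often."""
    X = _as_matrix(histories)
    n_occ = X.shape[1]
    if n_occ < 3:
        raise ValueError("Test 3.SR needs at least 3 occasions")
    first = np.argmax(X, axis=1) + 1
    comps: list[ContingencyComponent] = []
    for i in range(2, n_occ):  # 1-based occasions 2..n_occ-1
        at_i = X[:, i - 1] == 1
        if not at_i.any():
            comps.append(ContingencyComponent(i, np.zeros((2, 2)), 0.0, 0, False))
            continue
        new = first[at_i] == i
        seen_after = X[at_i, i:].any(axis=1)
        # rows: new / old mark; cols: never detected after / detected after
        table = np.array(
            [
                [(new & ~seen_after).sum(), (new & seen_after).sum()],
                [(~new & ~seen_after).sum(), (~new & seen_after).sum()],
            ],
            dtype=float,
        )
        chi2, df, num, var = pearson_chi2(table)
        comps.append(ContingencyComponent(i, table, chi2, df, df > 0, num, var))
    return _assemble("3.SR", comps, signed=True)


def test_3sm(histories) -> TestResult:
    """Next-detection-timing test for new vs old marks (detected-again subset)."""
    X = _as_matrix(histories)
    n_occ = X.shape[1]
    if n_occ < 4:
        raise ValueError("Test 3.SM needs at least 4 occasions")
    first = np.argmax(X, axis=1) + 1
    comps: list[ContingencyComponent] = []
    for i in range(2, n_occ - 1):
        sel = (X[:, i - 1] == 1) & X[:, i:].any(axis=1)
        if not sel.any():
            comps.append(ContingencyComponent(i, np.zeros((2, 2)), 0.0, 0, False))
            continue
        new = first[sel] == i
        next_at_ip1 = X[sel, i] == 1
        # rows: new / old; cols: next at i+1 / later
        table = np.array(
            [
                [(new & next_at_ip1).sum(), (new & ~next_at_ip1).sum()],
                [(~new & next_at_ip1).sum(), (~new & ~next_at_ip1).sum()],
            ],
            dtype=float,
        )
        chi2, df, num, var = pearson_chi2(table)
        comps.append(ContingencyComponent(i, table, chi2, df, df > 0, num, var))
    return _assemble("3.SM", comps, signed=True)


def estimate_chat(
    tests: Iterable[TestResult], exclude: set[str] | frozenset[str] = frozenset({"2.CT"})
) -> float:
    """Variance inflation factor: summed chi-square / summed df.

    Reported raw (no floor at 1); by default Test 2.CT is excluded because
    trap-dependence is handled structurally in the resighting model.
    """
    included = [t for t in tests if t.name not in exclude]
    total_df = sum(t.df for t in included)
    if total_df <= 0:
        raise ValueError("zero total df across included tests")
    return float(sum(t.chi2 for t in included) / total_df)


def run_gof(
    histories, exclude_from_chat: set[str] | frozenset[str] = frozenset({"2.CT"})
) -> GofResult:
    """Run all three tests and estimate the variance inflation factor."""
    X = _as_matrix(histories)
    tests = {
        "2.CT": test_2ct(X),
        "3.SR": test_3sr(X),
        "3.SM": test_3sm(X),
    }
    chat = estimate_chat(tests.values(), exclude=exclude_from_chat)
    included = tuple(n for n in tests if n not in exclude_from_chat)
    return GofResult(tests, chat, included)
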