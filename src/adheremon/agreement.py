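"""Chance-corrected agreement between dichotomized adherence measures.

Two binary measures (e.g. electronic monitoring vs. viral suppression) are
cross-classified into a 2x2 table; from it we compute

* observed agreement          Pa    = (n11 + n00) / n
* Cohen chance agreement      Pe    = pA1*pB1 + pA0*pB0
* Cohen's kappa               kappa = (Pa - Pe) / (1 - Pe)
* Gwet chance agreement       Pe_g  = 2*pi*(1 - pi),  pi = (pA1 + pB1)/2
* Gwet's AC1                  AC1   = (Pa - Pe_g) / (1 - Pe_g)

Cohen's kappa is vulnerable to the "kappa paradox": with strongly skewed
marginals (nearly everyone adherent), kappa can be near zero despite high
observed agreement.  Gwet's AC1 replaces the marginal-product chance term
with one based on the average marginal, which stays well below 1 under
skew, so AC1 tracks the observed agreement more faithfully.  For K
categories the Gwet chance term is (1/(K-1)) * sum_k pi_k (1 - pi_k); the
2*pi*(1-pi) form here is its K=2 case.

Category coding convention: 1 = "positive" (poor adherence / unsuppressed),
0 = "negative" (good adherence / suppressed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_POSITIVE_LABELS = {1, True, "poor", "unsuppressed", "1"}
_NEGATIVE_LABELS = {0, False, "good", "suppressed", "0"}


class DegenerateMarginalsError(ValueError):
    """Chance agreement equals 1, so the chance-corrected coefficient is undefined."""


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 cross-classification; first index = measure A, second = measure B.

    ``n11`` counts pairs positive on both measures, ``n10`` positive on A
    only, ``n01`` positive on B only, ``n00`` negative on both.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self):
        for f in ("n11", "n10", "n01", "n00"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.n == 0:
            raise ValueError("2x2 table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def p_a1(self) -> float:
        """Marginal positive proportion of measure A."""
        return (self.n11 + self.n10) / self.n

    @property
    def p_b1(self) -> float:
        """Marginal positive proportion of measure B."""
        return (self.n11 + self.n01) / self.n

    def swapped(self) -> "TwoByTwo":
        """The same table with measures A and B interchanged."""
        return TwoByTwo(self.n11, self.n01, self.n10, self.n00)


@dataclass(frozen=True)
class AgreementResult:
    """Agreement summary for one measure pair."""

    pa: float
    pe: float
    pe_gamma: float
    kappa: float
    ac1: float
    n: int


def _code(values) -> np.ndarray:
    """Map labels to 1/0/NaN (positive/negative/missing)."""
    out = np.full(len(values), np.nan)
    for i, v in enumerate(values):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
            continue
        if v in _POSITIVE_LABELS:
            out[i] = 1.0
        elif v in _NEGATIVE_LABELS:
            out[i] = 0.0
        elif isinstance(v, str) and v.lower() in ("missing", "unobserved", "na", ""):
            continue
        else:
            raise ValueError(f"unrecognized category label: {v!r}")
    return out


def cross_classify(a, b) -> tuple[TwoByTwo, int]:
    """Cross-classify two equal-length category sequences into a 2x2 table.

    Pairs with a missing value in either measure are dropped listwise; the
    dropped count is returned alongside the table.  Accepts 0/1, booleans,
    or the labels good/poor and suppressed/unsuppressed (positive = poor /
    unsuppressed); missing = None, NaN, "missing" or "unobserved".
    """
    a = _code(list(a))
    b = _code(list(b))
    if len(a) != len(b):
        raise ValueError("measure sequences must have equal length")
    keep = ~np.isnan(a) & ~np.isnan(b)
    n_dropped = int(len(a) - keep.sum())
    if keep.sum() == 0:
        raise ValueError("no complete pairs to cross-classify")
    a, b = a[keep], b[keep]
    t = TwoByTwo(
        n11=int(np.sum((a == 1) & (b == 1))),
        n10=int(np.sum((a == 1) & (b == 0))),
        n01=int(np.sum((a == 0) & (b == 1))),
        n00=int(np.sum((a == 0) & (b == 0))),
    )
    return t, n_dropped


def observed_agreement(t: TwoByTwo) -> float:
    """Proportion of pairs on which the two measures agree."""
    return (t.n11 + t.n00) / t.n


def cohen_kappa(t: TwoByTwo) -> tuple[float, float]:
    """(Pe, kappa): marginal-product chance agreement and Cohen's kappa.

    Raises :class:`DegenerateMarginalsError` when both marginals are
    concentrated on one category (Pe = 1), where kappa is undefined.
    """
    pe = t.p_a1 * t.p_b1 + (1 - t.p_a1) * (1 - t.p_b1)
    if pe >= 1.0:
        raise DegenerateMarginalsError("Pe = 1: kappa undefined for degenerate marginals")
    pa = observed_agreement(t)
    return pe, (pa - pe) / (1 - pe)


def gwet_ac1(t: TwoByTwo) -> tuple[float, float]:
    """(Pe_gamma, AC1): Gwet-adjusted chance agreement and the AC1 coefficient."""
    pi = (t.p_a1 + t.p_b1) / 2
    pe_gamma = 2 * pi * (1 - pi)
    if pe_gamma >= 1.0:
        raise DegenerateMarginalsError("Pe_gamma = 1: AC1 undefined")
    pa = observed_agreement(t)
    return pe_gamma, (pa - pe_gamma) / (1 - pe_gamma)


def agreement_result(t: TwoByTwo) -> AgreementResult:
    """All agreement statistics for one table."""
    pa = observed_agreement(t)
    pe, kappa = cohen_kappa(t)
    pe_gamma, ac1 = gwet_ac1(t)
    return AgreementResult(pa=pa, pe=pe, pe_gamma=pe_gamma, kappa=kappa, ac1=ac1, n=t.n)


def agreement_report(
    measures: pd.DataFrame,
    pairs: list[tuple[str, str]],
    strata: str | None = None,
) -> pd.DataFrame:
    """Agreement table for several measure pairs, overall and by stratum.

    Parameters
    ----------
    measures
        One row per participant with one column per dichotomized measure
        (labels as accepted by :func:`cross_classify`) and optionally a
        stratification column.
    pairs
        Column-name pairs to compare, e.g. ``[("vl", "em"), ("vl", "sr")]``.
    strata
        Optional column name; one block of rows per stratum is added after
        the overall block.  Strata with no complete pairs for a given
        comparison are skipped with a warning.
    """
    blocks = [("overall", measures)]
    if strata is not None:
        for level, grp in measures.groupby(strata, sort=True):
            blocks.append((str(level), grp))
    rows = []
    for label, grp in blocks:
        for a_col, b_col in pairs:
            try:
                t, n_dropped = cross_classify(grp[a_col], grp[b_col])
                res = agreement_result(t)
            except (ValueError, DegenerateMarginalsError) as exc:
                warnings.warn(
                    f"skipping stratum {label!r}, pair {a_col} vs {b_col}: {exc}",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "stratum": label,
                    "measure_a": a_col,
                    "measure_b": b_col,
                    "n": res.n,
                    "n_dropped": n_dropped,
                    "observed_agreement": res.pa,
                    "expected_agreement": res.pe,
                    "adjusted_expected_agreement": res.pe_gamma,
                    "kappa": res.kappa,
                    "ac1": res.ac1,
                }
            )
    return pd.DataFrame(rows)
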