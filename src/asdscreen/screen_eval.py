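"""Confusion matrices, predictive values, and reconstruction of printed tables.

Everything here reduces to integer 2x2 tables.  ``confusion`` tallies a
screener against an outcome, ``metrics`` turns a table into sensitivity,
specificity, PPV and NPV with Wilson score intervals, and
``stratified_metrics`` evaluates the screener within intensity strata.

``reconstruct_counts`` / ``reconstruct_stratified`` invert rounding: given
group sizes and predictive values printed at a known precision, they search
exhaustively for every integer table consistent with the printed numbers.
This turns published rounded percentages into exact integer confusion
tables (with an explicit uniqueness verdict), which is what makes
cell-exact regression tests against a published table possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "Estimate",
    "InconsistencyError",
    "MetricSet",
    "Reconstruction",
    "StratifiedReconstruction",
    "StratifiedTable",
    "confusion",
    "metrics",
    "reconstruct_counts",
    "reconstruct_stratified",
    "round_half_up",
    "stratified_metrics",
]


class InconsistencyError(ValueError):
    """No integer table is consistent with the printed values."""


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (the convention used when matching printed values)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer 2x2 table: screener (test) versus later outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_test_positive(self) -> int:
        return self.tp + self.fp

    @property
    def n_test_negative(self) -> int:
        return self.fn + self.tn

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_noncases(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion(
    test_flags: Sequence[bool], outcome_flags: Sequence[bool]
) -> ConfusionMatrix:
    """Tally aligned screener and outcome flags into a confusion matrix."""
    test = np.asarray(test_flags, dtype=bool)
    outcome = np.asarray(outcome_flags, dtype=bool)
    if test.shape != outcome.shape or test.ndim != 1:
        raise ValueError(
            f"test and outcome must be equal-length 1-d sequences "
            f"(got {test.shape} vs {outcome.shape})"
        )
    return ConfusionMatrix(
        tp=int(np.sum(test & outcome)),
        fp=int(np.sum(test & ~outcome)),
        fn=int(np.sum(~test & outcome)),
        tn=int(np.sum(~test & ~outcome)),
    )


@dataclass(frozen=True)
class Estimate:
    """A proportion with its Wilson interval; ``defined`` is False when the
    denominator was zero (value and interval are then None, never 0/NaN)."""

    value: float | None
    ci_low: float | None
    ci_high: float | None
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.value is not None

    @property
    def percent(self) -> float | None:
        return None if self.value is None else 100.0 * self.value


def _estimate(numerator: int, denominator: int, alpha: float) -> Estimate:
    if denominator == 0:
        return Estimate(None, None, None, numerator, denominator)
    lo, hi = proportion_confint(numerator, denominator, alpha=alpha, method="wilson")
    p = numerator / denominator
    # guard against float fuzz at boundary proportions: the interval must
    # contain the point estimate and stay inside [0, 1]
    lo = min(max(float(lo), 0.0), p)
    hi = max(min(float(hi), 1.0), p)
    return Estimate(p, lo, hi, numerator, denominator)


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, PPV and NPV for one confusion matrix."""

    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    cm: ConfusionMatrix

    def rounded_percent(self, decimals: int = 2) -> dict[str, float | None]:
        """Percent-scale values rounded half-up, as a printed table shows them."""
        return {
            name: None if est.value is None else round_half_up(100 * est.value, decimals)
            for name, est in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


def metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> MetricSet:
    """Compute the four screening metrics with 95% Wilson score intervals.

    A metric whose denominator is zero is returned as an undefined
    :class:`Estimate` rather than 0 or NaN; the other metrics are unaffected.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return MetricSet(
        sensitivity=_estimate(cm.tp, cm.n_cases, alpha),
        specificity=_estimate(cm.tn, cm.n_noncases, alpha),
        ppv=_estimate(cm.tp, cm.n_test_positive, alpha),
        npv=_estimate(cm.tn, cm.n_test_negative, alpha),
        cm=cm,
    )


@dataclass(frozen=True)
class StratifiedTable:
    """Per-stratum confusion matrices whose componentwise sum is the marginal."""

    strata: Mapping[str, ConfusionMatrix]

    @property
    def marginal(self) -> ConfusionMatrix:
        out = ConfusionMatrix(0, 0, 0, 0)
        for cm in self.strata.values():
            out = out + cm
        return out

    def metric_sets(self, alpha: float = 0.05) -> dict[str, MetricSet]:
        out = {}
        for label, cm in self.strata.items():
            out[label] = metrics(cm, alpha) if cm.total > 0 else None
        return out


def stratified_metrics(
    test_flags: Sequence[bool],
    outcome_flags: Sequence[bool],
    stratum_labels: Sequence[str],
    alpha: float = 0.05,
) -> tuple[StratifiedTable, dict[str, MetricSet | None]]:
    """Evaluate the screener within each stratum (e.g. low/high intensity).

    Returns the stratified table (strata sum to the marginal by construction)
    and per-stratum metric sets; an empty stratum maps to ``None``.
    """
    labels = np.asarray(stratum_labels)
    test = np.asarray(test_flags, dtype=bool)
    outcome = np.asarray(outcome_flags, dtype=bool)
    if not (len(labels) == len(test) == len(outcome)):
        raise ValueError("test, outcome and stratum labels must be aligned")
    strata = {}
    for label in sorted(set(labels.tolist())):
        mask = labels == label
        strata[label] = confusion(test[mask], outcome[mask])
    table = StratifiedTable(strata=strata)
    return table, table.metric_sets(alpha)


# ---------------------------------------------------------------------------
# Reconstruction of integer tables from printed rounded percentages
# ---------------------------------------------------------------------------


def _matches(numerator: int, denominator: int, printed: float, decimals: int) -> bool:
    """Does numerator/denominator, as a half-up percentage, print as `printed`?"""
    pct = Decimal(numerator * 100) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return pct.quantize(q, rounding=ROUND_HALF_UP) == Decimal(repr(float(printed))).quantize(q)


@dataclass(frozen=True)
class Reconstruction:
    """All integer tables consistent with printed PPV/NPV at given precision."""

    candidates: tuple[ConfusionMatrix, ...]

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def table(self) -> ConfusionMatrix:
        if not self.unique:
            raise InconsistencyError(
                f"reconstruction is ambiguous ({len(self.candidates)} candidates)"
            )
        return self.candidates[0]


def reconstruct_counts(
    n_pos: int,
    n_neg: int,
    ppv_printed: float,
    npv_printed: float,
    decimals: int = 2,
) -> Reconstruction:
    """Invert printed PPV/NPV into integer confusion tables.

    Searches every tp in 0..n_pos and tn in 0..n_neg for which
    ``100*tp/n_pos`` and ``100*tn/n_neg``, rounded half-up at ``decimals``,
    equal the printed percentages.  Raises :class:`InconsistencyError` when
    no integer table matches (e.g. a typo in the printed value).
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("group sizes must be positive")
    for name, v in (("ppv", ppv_printed), ("npv", npv_printed)):
        if not 0 <= v <= 100:
            raise ValueError(f"printed {name} must lie in [0, 100], got {v}")
    tps = [tp for tp in range(n_pos + 1) if _matches(tp, n_pos, ppv_printed, decimals)]
    tns = [tn for tn in range(n_neg + 1) if _matches(tn, n_neg, npv_printed, decimals)]
    cands = tuple(
        ConfusionMatrix(tp=tp, fp=n_pos - tp, fn=n_neg - tn, tn=tn)
        for tp, tn in product(tps, tns)
    )
    if not cands:
        raise InconsistencyError(
            f"no integer table with n_pos={n_pos}, n_neg={n_neg} reproduces "
            f"PPV={ppv_printed} and NPV={npv_printed} at {decimals} decimals"
        )
    return Reconstruction(candidates=cands)


def _two_way_splits(
    n_total: int,
    num_total: int,
    printed_low: float,
    printed_high: float,
    decimals: int,
) -> list[tuple[int, int]]:
    """(group_low, numerator_low) splits consistent with both printed values.

    The group of size ``n_total`` (with total numerator ``num_total``) is
    split into low/high subgroups; both subgroup proportions must round to
    their printed percentages. Degenerate single-stratum splits are allowed
    when one printed value is None.
    """
    out = []
    for n_low in range(n_total + 1):
        n_high = n_total - n_low
        for num_low in range(min(n_low, num_total) + 1):
            num_high = num_total - num_low
            if num_high > n_high:
                continue
            if n_low == 0:
                ok_low = printed_low is None and num_low == 0
            else:
                ok_low = printed_low is not None and _matches(
                    num_low, n_low, printed_low, decimals
                )
            if n_high == 0:
                ok_high = printed_high is None and num_high == 0
            else:
                ok_high = printed_high is not None and _matches(
                    num_high, n_high, printed_high, decimals
                )
            if ok_low and ok_high:
                out.append((n_low, num_low))
    return out


@dataclass(frozen=True)
class StratifiedReconstruction:
    """Candidate stratified tables plus an induced-metric consistency verdict."""

    candidates: tuple[StratifiedTable, ...]

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def table(self) -> StratifiedTable:
        if not self.unique:
            raise InconsistencyError(
                f"stratified reconstruction is ambiguous "
                f"({len(self.candidates)} candidates)"
            )
        return self.candidates[0]

    def induced_metrics_invariant(self, decimals: int = 1) -> bool:
        """True when per-stratum sensitivity/specificity agree across all
        candidates at the given printed precision."""
        seen = set()
        for table in self.candidates:
            key = []
            for label in sorted(table.strata):
                ms = metrics(table.strata[label])
                key.append(
                    tuple(
                        None if est.value is None else round_half_up(100 * est.value, decimals)
                        for est in (ms.sensitivity, ms.specificity)
                    )
                )
            seen.add(tuple(key))
        return len(seen) == 1


def reconstruct_stratified(
    n_pos: int,
    n_neg: int,
    stratified_ppvs: Mapping[str, float],
    stratified_npvs: Mapping[str, float],
    marginal_ppv: float,
    marginal_npv: float,
    decimals: int = 2,
) -> StratifiedReconstruction:
    """Invert printed stratified + marginal PPV/NPV into integer tables.

    The screener-positive group (size ``n_pos``) and screener-negative group
    (size ``n_neg``) are each split into the strata named in the printed
    maps (keys must agree, e.g. ``{"low": ..., "high": ...}``).  The search
    enumerates every marginal table consistent with the marginal PPV/NPV,
    every split of n_pos with per-stratum tp matching the stratified PPVs,
    and every split of n_neg with per-stratum tn matching the stratified
    NPVs.  All consistent stratified tables are returned; use
    :meth:`StratifiedReconstruction.induced_metrics_invariant` to check
    whether the sensitivities/specificities they induce are unambiguous.

    With a single stratum this reduces exactly to :func:`reconstruct_counts`.
    """
    if set(stratified_ppvs) != set(stratified_npvs):
        raise ValueError("stratified PPV and NPV maps must share stratum labels")
    labels = sorted(stratified_ppvs)
    marginal = reconstruct_counts(n_pos, n_neg, marginal_ppv, marginal_npv, decimals)
    if len(labels) == 1:
        only = labels[0]
        return StratifiedReconstruction(
            candidates=tuple(StratifiedTable(strata={only: cm}) for cm in marginal.candidates)
        )
    if len(labels) != 2:
        raise ValueError("stratified reconstruction supports 1 or 2 strata")
    lo, hi = labels if labels != ["high", "low"] else ("low", "high")

    tables: list[StratifiedTable] = []
    for marg in marginal.candidates:
        pos_splits = _two_way_splits(
            n_pos, marg.tp, stratified_ppvs[lo], stratified_ppvs[hi], decimals
        )
        neg_splits = _two_way_splits(
            n_neg, marg.tn, stratified_npvs[lo], stratified_npvs[hi], decimals
        )
        for (p_lo, tp_lo), (m_lo, tn_lo) in product(pos_splits, neg_splits):
            cm_lo = ConfusionMatrix(
                tp=tp_lo, fp=p_lo - tp_lo, fn=(m_lo - tn_lo), tn=tn_lo
            )
            cm_hi = ConfusionMatrix(
                tp=marg.tp - tp_lo,
                fp=(n_pos - p_lo) - (marg.tp - tp_lo),
                fn=(n_neg - m_lo) - (marg.tn - tn_lo),
                tn=marg.tn - tn_lo,
            )
            tables.append(StratifiedTable(strata={lo: cm_lo, hi: cm_hi}))
    if not tables:
        raise InconsistencyError(
            "no integer split of the screener-positive/negative groups reproduces "
            "all printed stratified and marginal predictive values"
        )
    return StratifiedReconstruction(candidates=tuple(tables))


def bayes_ppv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """PPV from sensitivity, specificity and prevalence via Bayes' rule."""
    num = sensitivity * prevalence
    return num / (num + (1 - specificity) * (1 - prevalence))


def bayes_npv(sensitivity: float, specificity: float, prevalence: float) -> float:
    """NPV from sensitivity, specificity and prevalence via Bayes' rule."""
    num = specificity * (1 - prevalence)
    return num / (num + (1 - sensitivity) * prevalence)
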