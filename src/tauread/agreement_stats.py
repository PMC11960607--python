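"""Reader-study agreement endpoints and chance-corrected reliability.

Implements the statistics used to validate the visual stratification method
against a quantitation reference standard:

* positive/negative percent agreement (PPA/NPA) and overall agreement with
  Wilson score confidence intervals,
* Fleiss kappa (multi-rater, two categories) with the Fleiss-Nee-Landis
  large-sample standard error, computable either from a full read matrix or
  from the published summary (per-scan agreement splits plus per-reader
  positive-call totals),
* Cohen kappa for two rating vectors (test-retest reliability) with the
  Fleiss-Cohen-Everitt asymptotic standard error,
* majority reads, protocol success criteria, and a seeded reader-panel
  simulator for Monte-Carlo calibration checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .imaging_io import CALL_NEGATIVE, CALL_POSITIVE


# --- proportions ---------------------------------------------------------------

def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    low, high = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    # exact boundary semantics: the score interval is [0, .] at 0 successes
    # and [., 1] at n successes; clear float residue from the closed form
    if successes == 0:
        low = 0.0
    if successes == n:
        high = 1.0
    return float(low), float(high)


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its Wilson CI, reported on the percent scale."""

    numerator: int
    denominator: int
    point_pct: float
    ci_low_pct: float
    ci_high_pct: float
    level: float = 0.95

    @staticmethod
    def from_counts(numerator: int, denominator: int, level: float = 0.95) -> "ProportionEstimate":
        low, high = wilson_interval(numerator, denominator, level)
        return ProportionEstimate(
            numerator=numerator,
            denominator=denominator,
            point_pct=100.0 * numerator / denominator,
            ci_low_pct=100.0 * low,
            ci_high_pct=100.0 * high,
            level=level,
        )

    def to_dict(self) -> dict:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "point_pct": self.point_pct,
            "ci_low_pct": self.ci_low_pct,
            "ci_high_pct": self.ci_high_pct,
            "level": self.level,
        }


# --- read matrices -------------------------------------------------------------

@dataclass
class ReadMatrix:
    """Scans x readers binary calls (True = high-tau) with optional truth.

    ``truth`` entries may be ``None`` for scans without a reference standard
    (e.g. failed quantitation); such scans are excluded from PPA/NPA
    denominators but still contribute to kappa.
    """

    scan_ids: list[str]
    reader_ids: list[str]
    calls: np.ndarray
    truth: Optional[list[Optional[bool]]] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.shape != (len(self.scan_ids), len(self.reader_ids)):
            raise ValueError("calls must be scans x readers")
        if self.truth is not None and len(self.truth) != len(self.scan_ids):
            raise ValueError("truth must have one entry per scan")

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)

    @property
    def n_readers(self) -> int:
        return len(self.reader_ids)

    def reader_index(self, reader_id: str) -> int:
        try:
            return self.reader_ids.index(reader_id)
        except ValueError:
            raise KeyError(f"unknown reader: {reader_id}") from None

    @staticmethod
    def from_long(df: pd.DataFrame) -> "ReadMatrix":
        """Build from a long table with scan_id / reader_id / call (+truth)."""
        scan_ids = list(dict.fromkeys(df["scan_id"]))
        reader_ids = list(dict.fromkeys(df["reader_id"]))
        calls = np.zeros((len(scan_ids), len(reader_ids)), dtype=bool)
        seen = np.zeros_like(calls)
        s_idx = {s: i for i, s in enumerate(scan_ids)}
        r_idx = {r: j for j, r in enumerate(reader_ids)}
        truth: list[Optional[bool]] = [None] * len(scan_ids)
        has_truth = "truth" in df.columns
        for row in df.itertuples(index=False):
            i, j = s_idx[row.scan_id], r_idx[row.reader_id]
            calls[i, j] = row.call == CALL_POSITIVE
            seen[i, j] = True
            if has_truth and isinstance(row.truth, str) and row.truth:
                truth[i] = row.truth == CALL_POSITIVE
        if not seen.all():
            i, j = np.argwhere(~seen)[0]
            raise ValueError(f"missing call for scan {scan_ids[i]}, reader {reader_ids[j]}")
        return ReadMatrix(scan_ids, reader_ids, calls, truth if has_truth else None)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, scan in enumerate(self.scan_ids):
            t = self.truth[i] if self.truth is not None else None
            t_str = "" if t is None else (CALL_POSITIVE if t else CALL_NEGATIVE)
            for j, reader in enumerate(self.reader_ids):
                rows.append(
                    {
                        "scan_id": scan,
                        "reader_id": reader,
                        "call": CALL_POSITIVE if self.calls[i, j] else CALL_NEGATIVE,
                        "truth": t_str,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 counts of one reader's calls against the reference standard."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn, self.n_excluded) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "ContingencyCounts") -> "ContingencyCounts":
        return ContingencyCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.n_excluded + other.n_excluded,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def contingency_from_reads(matrix: ReadMatrix, reader_id: str) -> ContingencyCounts:
    """Tally one reader's calls against the truth; truthless scans excluded."""
    if matrix.truth is None:
        raise ValueError("read matrix carries no truth labels")
    j = matrix.reader_index(reader_id)
    tp = fp = tn = fn = excluded = 0
    for i in range(matrix.n_scans):
        t = matrix.truth[i]
        if t is None:
            excluded += 1
            continue
        call = bool(matrix.calls[i, j])
        if call and t:
            tp += 1
        elif call and not t:
            fp += 1
        elif not call and t:
            fn += 1
        else:
            tn += 1
    return ContingencyCounts(tp, fp, tn, fn, n_excluded=excluded)


@dataclass(frozen=True)
class EndpointEstimates:
    ppa: ProportionEstimate
    npa: ProportionEstimate
    overall: ProportionEstimate


def ppa_npa(counts: ContingencyCounts, level: float = 0.95) -> EndpointEstimates:
    """PPA = 100*TP/(TP+FN), NPA = 100*TN/(TN+FP), overall agreement, each with Wilson CI."""
    if counts.tp + counts.fn < 1:
        raise ValueError("no truth-positive scans: PPA undefined")
    if counts.tn + counts.fp < 1:
        raise ValueError("no truth-negative scans: NPA undefined")
    level = float(level)
    return EndpointEstimates(
        ppa=ProportionEstimate.from_counts(counts.tp, counts.tp + counts.fn, level),
        npa=ProportionEstimate.from_counts(counts.tn, counts.tn + counts.fp, level),
        overall=ProportionEstimate.from_counts(counts.tp + counts.tn, counts.total, level),
    )


# --- kappa statistics ----------------------------------------------------------

@dataclass(frozen=True)
class KappaEstimate:
    """Chance-corrected agreement with large-sample CI.

    ``ci_high`` is capped at 1.0 (and ``ci_low`` floored at -1.0) for
    reporting; ``statistic`` and ``se`` are unadjusted.
    """

    statistic: float
    se: float
    ci_low: float
    ci_high: float
    method: str
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "level": self.level,
        }


def _kappa_ci(statistic: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    return max(statistic - z * se, -1.0), min(statistic + z * se, 1.0)


def fleiss_kappa(matrix: ReadMatrix, level: float = 0.95) -> KappaEstimate:
    """Fleiss kappa over all scans and readers of a read matrix.

    Reduces the matrix to its agreement-split summary, so it is exactly equal
    (bit for bit) to :func:`fleiss_kappa_from_summary` on that summary.
    """
    if matrix.n_readers < 2 or matrix.n_scans < 2:
        raise ValueError("Fleiss kappa needs >= 2 readers and >= 2 scans")
    n = matrix.n_readers
    splits: dict[tuple[int, int], int] = {}
    for k in matrix.calls.sum(axis=1):
        key = (max(int(k), n - int(k)), min(int(k), n - int(k)))
        splits[key] = splits.get(key, 0) + 1
    totals = [int(t) for t in matrix.calls.sum(axis=0)]
    return fleiss_kappa_from_summary(splits, totals, matrix.n_scans, level)


def fleiss_kappa_from_summary(
    split_counts: Mapping[tuple[int, int], int],
    positive_totals: Sequence[int],
    n_scans: int,
    level: float = 0.95,
) -> KappaEstimate:
    """Fleiss kappa from published summary data.

    ``split_counts`` maps per-scan agreement splits, e.g. ``(5, 0)`` for
    unanimous and ``(4, 1)`` for one dissenter, to the number of scans with
    that split; ``positive_totals`` gives each reader's total positive calls.
    Identical to :func:`fleiss_kappa` on any matrix realising the summary.
    """
    n_readers = len(positive_totals)
    if n_readers < 2:
        raise ValueError("need >= 2 readers")
    if sum(split_counts.values()) != n_scans:
        raise ValueError("split counts must sum to n_scans")
    total_pos = int(sum(positive_totals))
    if not 0 <= total_pos <= n_scans * n_readers:
        raise ValueError("positive totals inconsistent with matrix size")
    n = n_readers
    p_pos = total_pos / (n_scans * n)
    marginals = np.array([p_pos, 1.0 - p_pos])
    p_e = float((marginals**2).sum())
    if p_e >= 1.0:
        raise ValueError("all calls in a single category: Fleiss kappa undefined")
    p_o = 0.0
    for (a, b), count in split_counts.items():
        if a + b != n or min(a, b) < 0:
            raise ValueError(f"split {(a, b)} inconsistent with {n} readers")
        p_o += count * (a * (a - 1) + b * (b - 1)) / (n * (n - 1))
    p_o /= n_scans
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss-Nee-Landis large-sample variance of the overall kappa
    var = (
        2.0
        / (n_scans * n * (n - 1))
        * (p_e - (2 * n - 3) * p_e**2 + 2 * (n - 2) * float((marginals**3).sum()))
        / (1.0 - p_e) ** 2
    )
    se = float(np.sqrt(var))
    low, high = _kappa_ci(kappa, se, level)
    return KappaEstimate(kappa, se, low, high, method="fleiss", level=level)


def cohen_kappa(
    calls_a: Sequence[bool], calls_b: Sequence[bool], level: float = 0.95
) -> KappaEstimate:
    """Two-rating Cohen kappa with the Fleiss-Cohen-Everitt asymptotic SE."""
    a = np.asarray(calls_a, dtype=bool)
    b = np.asarray(calls_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length rating vectors of length >= 2")
    n = a.size
    # observed cell proportions p[i][j]: i = rating A category, j = rating B
    p = np.zeros((2, 2))
    for i, av in enumerate((True, False)):
        for j, bv in enumerate((True, False)):
            p[i, j] = np.sum((a == av) & (b == bv)) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float((row * col).sum())
    if p_e >= 1.0:
        if np.array_equal(a, b):
            return KappaEstimate(1.0, 0.0, 1.0, 1.0, method="cohen", level=level)
        raise ValueError("degenerate marginals: Cohen kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss, Cohen & Everitt (1969) large-sample variance
    term_a = sum(
        p[i, i] * ((1 - p_e) - (row[i] + col[i]) * (1 - p_o)) ** 2 for i in range(2)
    )
    term_b = (1 - p_o) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term_c = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (term_a + term_b - term_c) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    low, high = _kappa_ci(kappa, se, level)
    return KappaEstimate(float(kappa), se, low, high, method="cohen", level=level)


# --- majority reads and report -------------------------------------------------

def majority_read(matrix: ReadMatrix, tie_rule: str = "error") -> np.ndarray:
    """Per-scan consensus call: the category with strictly more votes.

    Even panels can tie; ``tie_rule`` is one of {"error", "positive",
    "negative"}.
    """
    if tie_rule not in {"error", "positive", "negative"}:
        raise ValueError("tie_rule must be 'error', 'positive' or 'negative'")
    pos = matrix.calls.sum(axis=1)
    neg = matrix.n_readers - pos
    if np.any(pos == neg):
        if tie_rule == "error":
            tied = [matrix.scan_ids[i] for i in np.flatnonzero(pos == neg)[:5]]
            raise ValueError(f"tied majority vote on scan(s): {tied}")
        return pos >= neg if tie_rule == "positive" else pos > neg
    return pos > neg


def majority_contingency(matrix: ReadMatrix, tie_rule: str = "error") -> ContingencyCounts:
    """Contingency of the majority read against truth."""
    calls = majority_read(matrix, tie_rule)
    consensus = ReadMatrix(
        matrix.scan_ids, ["majority"], calls.reshape(-1, 1), matrix.truth
    )
    return contingency_from_reads(consensus, "majority")


@dataclass
class AgreementReport:
    """Per-reader and pooled endpoints plus reliability and success verdicts.

    The pooled row sums per-reader contingencies (this reproduces published
    "overall" rows whose CIs are Wilson intervals on pooled counts); per-reader
    medians are also reported, clearly separated.
    """

    reader_counts: dict[str, ContingencyCounts]
    per_reader: dict[str, EndpointEstimates]
    pooled_counts: ContingencyCounts
    pooled: EndpointEstimates
    median_ppa_pct: float
    median_npa_pct: float
    median_overall_pct: float
    fleiss: Optional[KappaEstimate]
    success_ppa_npa: bool = False
    success_fleiss: bool = False
    level: float = 0.95

    def to_dict(self) -> dict:
        def endpoints(e: EndpointEstimates) -> dict:
            return {
                "ppa": e.ppa.to_dict(),
                "npa": e.npa.to_dict(),
                "overall": e.overall.to_dict(),
            }

        return {
            "per_reader": {r: endpoints(e) for r, e in self.per_reader.items()},
            "pooled": endpoints(self.pooled),
            "median_ppa_pct": self.median_ppa_pct,
            "median_npa_pct": self.median_npa_pct,
            "median_overall_pct": self.median_overall_pct,
            "fleiss": self.fleiss.to_dict() if self.fleiss else None,
            "success_ppa_npa": self.success_ppa_npa,
            "success_fleiss": self.success_fleiss,
            "level": self.level,
        }


def evaluate_success_criteria(
    report: AgreementReport,
    n_required_readers: int = 3,
    bound_pct: float = 50.0,
    fleiss_min: float = 0.64,
    fleiss_ci_min: float = 0.55,
) -> tuple[bool, bool]:
    """Protocol success rules (all comparisons inclusive, ">= bound").

    Primary: at least ``n_required_readers`` readers have both PPA and NPA
    CI lower bounds at or above ``bound_pct``. Secondary: Fleiss kappa at
    least ``fleiss_min`` with CI lower bound at least ``fleiss_ci_min``.
    """
    qualifying = sum(
        1
        for e in report.per_reader.values()
        if e.ppa.ci_low_pct >= bound_pct and e.npa.ci_low_pct >= bound_pct
    )
    success_ppa_npa = qualifying >= n_required_readers
    success_fleiss = bool(
        report.fleiss is not None
        and report.fleiss.statistic >= fleiss_min
        and report.fleiss.ci_low >= fleiss_ci_min
    )
    return success_ppa_npa, success_fleiss


def build_agreement_report(matrix: ReadMatrix, level: float = 0.95) -> AgreementReport:
    """Full study-style agreement report from a read matrix with truth."""
    reader_counts = {r: contingency_from_reads(matrix, r) for r in matrix.reader_ids}
    per_reader = {r: ppa_npa(c, level) for r, c in reader_counts.items()}
    pooled_counts = ContingencyCounts(0, 0, 0, 0)
    for c in reader_counts.values():
        pooled_counts = pooled_counts + c
    pooled = ppa_npa(pooled_counts, level)
    fleiss: Optional[KappaEstimate] = None
    if matrix.n_readers >= 2:
        try:
            fleiss = fleiss_kappa(matrix, level)
        except ValueError:
            fleiss = None
    report = AgreementReport(
        reader_counts=reader_counts,
        per_reader=per_reader,
        pooled_counts=pooled_counts,
        pooled=pooled,
        median_ppa_pct=float(np.median([e.ppa.point_pct for e in per_reader.values()])),
        median_npa_pct=float(np.median([e.npa.point_pct for e in per_reader.values()])),
        median_overall_pct=float(
            np.median([e.overall.point_pct for e in per_reader.values()])
        ),
        fleiss=fleiss,
        level=level,
    )
    report.success_ppa_npa, report.success_fleiss = evaluate_success_criteria(report)
    return report


# --- simulation ----------------------------------------------------------------

def simulate_reader_panel(
    truth: Sequence[bool],
    sensitivity: float,
    specificity: float,
    n_readers: int,
    seed: int,
) -> ReadMatrix:
    """Independent readers with fixed per-scan sensitivity/specificity."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    truth_arr = np.asarray(truth, dtype=bool)
    rng = np.random.default_rng(seed)
    p_positive = np.where(truth_arr, sensitivity, 1.0 - specificity)
    calls = rng.random((truth_arr.size, n_readers)) < p_positive[:, None]
    return ReadMatrix(
        scan_ids=[f"scan_{i + 1:04d}" for i in range(truth_arr.size)],
        reader_ids=[f"reader_{j + 1}" for j in range(n_readers)],
        calls=calls,
        truth=[bool(t) for t in truth_arr],
    )


def analytic_fleiss_kappa(
    prevalence: float, sensitivity: float, specificity: float
) -> float:
    """Large-sample Fleiss kappa for independent readers with common operating point."""
    pi, s, c = prevalence, sensitivity, specificity
    p_o = pi * (s**2 + (1 - s) ** 2) + (1 - pi) * (c**2 + (1 - c) ** 2)
    p = pi * s + (1 - pi) * (1 - c)
    p_e = p**2 + (1 - p) ** 2
    return (p_o - p_e) / (1.0 - p_e)
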