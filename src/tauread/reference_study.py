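"""Reference reader-study summary counts and a consistent read matrix.

The published validation of the visual high-tau stratification reports only
summary counts for its 140-scan, five-reader panel: per-reader true-positive
and true-negative counts against quantitation (70 high-tau and 70 non-high-tau
scans), per-scan agreement splits (124 unanimous, 9 with one dissenter, 7 with
a 3-2 split), per-reader positive-call totals, and the majority-read
contingency (TP/FN/TN/FP = 60/10/62/8).

:func:`reader_study_read_matrix` reconstructs one explicit binary read matrix
that satisfies *all* of those counts simultaneously, so every downstream
statistic (per-reader and pooled PPA/NPA, Fleiss kappa, majority reads,
success criteria) can be recomputed through the ordinary code paths rather
than asserted from the summary. The reconstruction is synthetic at the level
of which particular scan got which calls — any matrix matching the summary
gives identical agreement statistics, since all of them are functions of the
counts above.
"""

from __future__ import annotations

import numpy as np

from .agreement_stats import ReadMatrix

#: Per-reader true positives among the 70 quantitation-high-tau scans.
READER_TRUE_POSITIVES = (58, 59, 63, 60, 52)
#: Per-reader true negatives among the 70 quantitation-non-high-tau scans.
READER_TRUE_NEGATIVES = (63, 62, 61, 61, 64)
N_HIGH_TAU = 70
N_NON_HIGH = 70

#: Per-scan agreement splits across the 5 readers.
AGREEMENT_SPLITS = {(5, 0): 124, (4, 1): 9, (3, 2): 7}
#: Per-reader total positive calls over all 140 scans.
READER_POSITIVE_TOTALS = (65, 67, 72, 69, 58)
#: Majority-read contingency (tp, fn, tn, fp).
MAJORITY_COUNTS = {"tp": 60, "fn": 10, "tn": 62, "fp": 8}


def reader_study_read_matrix() -> ReadMatrix:
    """A 140-scan x 5-reader matrix consistent with the published counts.

    Layout (truth-positive scans first):

    * 52 high-tau scans called positive unanimously, 6 called negative
      unanimously;
    * 12 high-tau disagreement scans: 4 with a 4-1 positive majority (reader 5
      dissenting), 4 with a 3-2 positive majority, 4 with a 4-1 negative
      majority (one reader calling positive);
    * 6 non-high scans called positive unanimously, 60 called negative
      unanimously;
    * 4 non-high disagreement scans: one 4-1 negative majority, two 3-2
      positive majorities, one 3-2 negative majority.

    Reader assignments on the disagreement scans are fixed so the per-reader
    TP/TN totals come out exactly as published.
    """
    rows: list[tuple[tuple[int, ...], bool]] = []

    def add(pattern: tuple[int, ...], truth: bool, times: int = 1) -> None:
        rows.extend([(pattern, truth)] * times)

    # truth-positive scans ------------------------------------------------
    add((1, 1, 1, 1, 1), True, 52)   # unanimous TP
    add((0, 0, 0, 0, 0), True, 6)    # unanimous FN
    add((1, 1, 1, 1, 0), True, 4)    # 4-1 positive majority, reader 5 dissents
    add((0, 1, 1, 1, 0), True, 2)    # 3-2 positive majorities
    add((1, 1, 1, 0, 0), True)
    add((1, 0, 1, 1, 0), True)
    add((0, 0, 1, 0, 0), True, 3)    # 4-1 negative majorities, lone positive r3
    add((0, 0, 0, 1, 0), True)       # lone positive r4

    # truth-negative scans -------------------------------------------------
    add((1, 1, 1, 1, 1), False, 6)   # unanimous FP
    add((0, 0, 0, 0, 0), False, 60)  # unanimous TN
    add((0, 0, 0, 1, 0), False)      # 4-1 negative majority, FP by r4
    add((0, 1, 1, 1, 0), False)      # 3-2 positive majorities
    add((1, 0, 1, 1, 0), False)
    add((0, 1, 1, 0, 0), False)      # 3-2 negative majority

    calls = np.array([pattern for pattern, _ in rows], dtype=bool)
    truth = [truth for _, truth in rows]
    matrix = ReadMatrix(
        scan_ids=[f"scan_{i + 1:04d}" for i in range(len(rows))],
        reader_ids=[f"reader_{j + 1}" for j in range(5)],
        calls=calls,
        truth=truth,
    )
    _check_against_summary(matrix)
    return matrix


def _check_against_summary(matrix: ReadMatrix) -> None:
    """Construction-time consistency check against the published counts."""
    truth = np.array([bool(t) for t in matrix.truth])
    tp = matrix.calls[truth].sum(axis=0)
    tn = (~matrix.calls[~truth]).sum(axis=0)
    assert tuple(int(x) for x in tp) == READER_TRUE_POSITIVES, tp
    assert tuple(int(x) for x in tn) == READER_TRUE_NEGATIVES, tn
    assert tuple(int(x) for x in matrix.calls.sum(axis=0)) == READER_POSITIVE_TOTALS
    pos = matrix.calls.sum(axis=1)
    splits: dict[tuple[int, int], int] = {}
    for k in pos:
        key = (max(int(k), 5 - int(k)), min(int(k), 5 - int(k)))
        splits[key] = splits.get(key, 0) + 1
    assert splits == AGREEMENT_SPLITS, splits
    maj = pos > 2
    assert int((maj & truth).sum()) == MAJORITY_COUNTS["tp"]
    assert int((~maj & truth).sum()) == MAJORITY_COUNTS["fn"]
    assert int((~maj & ~truth).sum()) == MAJORITY_COUNTS["tn"]
    assert int((maj & ~truth).sum()) == MAJORITY_COUNTS["fp"]
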