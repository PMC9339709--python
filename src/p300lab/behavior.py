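"""Behavioral scoring: oddball task metrics and the d2 paper-pencil test.

Oddball metrics follow signal-detection conventions: the omission error
rate counts target trials without a correct target-key response (both no
press and wrong key, configurable), the commission rate counts target-key
responses to standards, and d' = z(hit rate) - z(false-alarm rate) with
extreme rates clipped to [1/(2N), 1 - 1/(2N)] so the z-transform stays
finite.  RT statistics are computed over correct target responses only;
RT variability (RTV) is their standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scheduler import StimulusSequence

D2_N_LINES = 14
D2_LINE_LENGTH = 47
D2_TARGET = ("d", 2)  # the letter d with two strokes
D2_LINE_TIME_LIMIT = 20.0  # s, metadata


@dataclass
class VotMetrics:
    omission_rate: float  # %
    commission_rate: float  # %
    d_prime: float
    rt_mean: float  # s
    rt_variability: float  # s (SD of correct-target RTs)
    n_targets: int
    n_standards: int


def _clip_rate(rate: float, n: int) -> float:
    lo = 1.0 / (2 * n)
    return float(np.clip(rate, lo, 1.0 - lo))


def score_vot(
    behavior: pd.DataFrame,
    sequence: StimulusSequence,
    count_no_press_as_omission: bool = True,
) -> VotMetrics:
    """Score an oddball block from the trial-aligned response table.

    ``behavior`` needs one row per trial (aligned with ``sequence``) with
    ``response`` (left/right/none) and ``response_time`` columns.
    """
    if len(behavior) != sequence.n_trials:
        raise ValueError("behavior table not aligned with the sequence")
    is_target = sequence.is_target
    n_targets = int(is_target.sum())
    n_standards = int((~is_target).sum())
    if n_targets == 0:
        raise ValueError("no target trials: metrics undefined")
    target_side = "right" if sequence.standard_side == "left" else "left"
    resp = behavior["response"].to_numpy()
    rts = behavior["response_time"].to_numpy(dtype=float)

    correct_target = is_target & (resp == target_side)
    if count_no_press_as_omission:
        omitted = is_target & ~correct_target
    else:
        omitted = is_target & (resp != target_side) & (resp != "none")
    commissions = ~is_target & (resp == target_side)

    omission_rate = 100.0 * omitted.sum() / n_targets
    commission_rate = 100.0 * commissions.sum() / n_standards if n_standards else 0.0
    hit_rate = _clip_rate(correct_target.sum() / n_targets, n_targets)
    fa_rate = _clip_rate(commissions.sum() / n_standards, n_standards) if n_standards else 0.5
    d_prime = float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))

    rt = rts[correct_target]
    rt = rt[np.isfinite(rt)]
    rt_mean = float(rt.mean()) if rt.size else float("nan")
    rt_var = float(rt.std(ddof=1)) if rt.size > 1 else 0.0
    return VotMetrics(
        omission_rate=float(omission_rate),
        commission_rate=float(commission_rate),
        d_prime=d_prime,
        rt_mean=rt_mean,
        rt_variability=rt_var,
        n_targets=n_targets,
        n_standards=n_standards,
    )


def d_prime(hit_rate: float, fa_rate: float, n_targets: int | None = None, n_standards: int | None = None) -> float:
    """z(HR) - z(FA); rates clipped to [1/(2N), 1-1/(2N)] when N is given."""
    if n_targets:
        hit_rate = _clip_rate(hit_rate, n_targets)
    if n_standards:
        fa_rate = _clip_rate(fa_rate, n_standards)
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


# ---------------------------------------------------------------------------
# d2 test
# ---------------------------------------------------------------------------


@dataclass
class D2Metrics:
    processing_speed: int  # total characters processed
    concentration_performance: int  # correct hits minus all errors
    omissions: int  # missed targets within the processed span
    commissions: int  # crossed non-targets
    hits: int


def generate_d2_sheet(seed: int = 0, p_target: float = 0.4583) -> list[list[tuple[str, int]]]:
    """Random 14 x 47 sheet of (letter, strokes) symbols.

    Targets are 'd' with two strokes; distractors are 'd' with 1/3/4
    strokes and 'p' with 1-4 strokes.  The default target fraction mirrors
    the printed test (about 21.6 targets per 47-character line).
    """
    rng = np.random.default_rng(seed)
    distractors = [("d", s) for s in (1, 3, 4)] + [("p", s) for s in (1, 2, 3, 4)]
    sheet = []
    for _ in range(D2_N_LINES):
        line = []
        for _ in range(D2_LINE_LENGTH):
            if rng.random() < p_target:
                line.append(D2_TARGET)
            else:
                line.append(distractors[rng.integers(len(distractors))])
        sheet.append(line)
    return sheet


def score_d2(sheet: list[list[tuple[str, int]]], marks: list[list[int]]) -> D2Metrics:
    """Score crossed positions against the sheet.

    The processed span of a line runs up to (and including) the last mark;
    a line without marks contributes nothing.  Hits are crossed targets;
    commissions crossed non-targets; omissions uncrossed targets within
    the processed span.  Concentration performance = hits minus all
    errors (commissions and omissions).
    """
    if len(sheet) != len(marks):
        raise ValueError("marks must have one list per sheet line")
    processed = hits = comm = omit = 0
    for line, line_marks in zip(sheet, marks):
        for m in line_marks:
            if not 0 <= m < len(line):
                raise ValueError(f"mark {m} beyond line length {len(line)}")
        if not line_marks:
            continue
        span = max(line_marks) + 1
        processed += span
        marked = set(line_marks)
        for pos in range(span):
            is_target = tuple(line[pos]) == D2_TARGET
            if pos in marked:
                if is_target:
                    hits += 1
                else:
                    comm += 1
            elif is_target:
                omit += 1
    return D2Metrics(
        processing_speed=processed,
        concentration_performance=hits - comm - omit,
        omissions=omit,
        commissions=comm,
        hits=hits,
    )


def simulate_d2_marks(
    sheet: list[list[tuple[str, int]]],
    speed: int,
    p_omission: float,
    p_commission: float,
    seed: int = 0,
) -> list[list[int]]:
    """Plausible mark pattern: process ``speed`` characters per line, miss
    targets with ``p_omission``, cross distractors with ``p_commission``."""
    rng = np.random.default_rng(seed)
    marks = []
    for line in sheet:
        span = min(speed, len(line))
        line_marks = []
        for pos in range(span):
            if tuple(line[pos]) == D2_TARGET:
                if rng.random() >= p_omission:
                    line_marks.append(pos)
            elif rng.random() < p_commission:
                line_marks.append(pos)
        marks.append(line_marks)
    return marks


def exclude_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Single-pass mask: True where |value - mean| <= k * SD.

    Mean and SD are computed over all values of the measure; values at
    exactly k SD are retained (strict inequality).  No re-iteration.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(values.shape, dtype=bool)
    return np.abs(values - values.mean()) <= k * sd
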