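"""Adaptive staircase psychophysics: simulation and threshold analysis.

Two forced-choice tasks probe cone contrast sensitivity with the
silent-substitution stimuli: a 4AFC square-localization task (guess rate
0.25) and a 2-alternative ridge motion-discrimination task using the
ring-and-wedge stimulus (guess rate 0.5).  Both use a 1-up/1-down staircase
over 21 ordered contrast steps (level 1 = highest contrast, 21 = lowest): a
correct response steps toward lower contrast, an incorrect response (or a
"nothing visible" report, treated as incorrect) steps toward higher
contrast, converging on the 50%-correct point.  The square staircase stops
after at least 14 reversals, the ridge staircase after 8; either stops early
once more than 8 correct responses have accumulated at the lowest contrast
(ceiling performance).

The threshold estimate is the mean of the last six reversal levels (the
lowest level for ceiling runs), convertible to mean L+M Michelson contrast
through the per-level contrast table.  Group comparison uses the 95%
t-distribution prediction interval of the untreated thresholds: a
post-treatment threshold below it is evidence for a robust change in cone
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeibullObserver",
    "StaircaseConfig",
    "StaircaseResult",
    "default_level_contrasts",
    "run_staircase",
    "threshold_in_contrast",
    "contrast_to_level",
    "prediction_interval",
    "exceeds_untreated_range",
    "SQUARE_TASK",
    "RIDGE_TASK",
]


@dataclass(frozen=True)
class WeibullObserver:
    """Stochastic observer with a Weibull psychometric function over contrast.

    P(correct | c) = guess + (1 - guess)(1 - lapse)(1 - exp(-(c/alpha)^beta)),
    which rises monotonically from the guess rate to 1 - lapse(1 - guess).
    """

    alpha: float  # contrast at ~63% of the rise
    beta: float = 3.0  # psychometric slope
    guess_rate: float = 0.25
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if not 0 < self.guess_rate < 1:
            raise ValueError("guess_rate must lie in (0, 1)")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    def p_correct(self, contrast: float) -> float:
        f = 1.0 - np.exp(-((contrast / self.alpha) ** self.beta))
        return self.guess_rate + (1.0 - self.guess_rate) * (1.0 - self.lapse_rate) * f

    def contrast_at(self, p: float) -> float:
        """Contrast at which P(correct) = p (e.g. the 50%-correct point)."""
        f = (p - self.guess_rate) / ((1.0 - self.guess_rate) * (1.0 - self.lapse_rate))
        if not 0 < f < 1:
            raise ValueError(f"performance level {p} is unreachable for this observer")
        return self.alpha * (-np.log(1.0 - f)) ** (1.0 / self.beta)


@dataclass(frozen=True)
class StaircaseConfig:
    n_levels: int = 21
    min_reversals: int = 14
    ceiling_correct: int = 8  # stop once MORE than this many correct at the floor
    start_level: int = 1
    max_trials: int = 1000

    def __post_init__(self) -> None:
        if self.min_reversals <= 0 or self.ceiling_correct <= 0:
            raise ValueError("stop criteria must be positive")
        if not 1 <= self.start_level <= self.n_levels:
            raise ValueError("start level outside the level range")


#: 4AFC square-localization task: >= 14 reversals.
SQUARE_TASK = StaircaseConfig(min_reversals=14)
#: 2-alternative ridge motion task: >= 8 reversals.
RIDGE_TASK = StaircaseConfig(min_reversals=8)


def default_level_contrasts(
    n_levels: int = 21, highest: float = 0.52, lowest: float = 0.16
) -> np.ndarray:
    """Geometric level-to-contrast table (level 1 = highest contrast).

    Anchored at the extreme mean L+M Michelson contrasts observed across
    staircase thresholds (0.16-0.52); a physical calibration would replace
    this table with measured per-level contrasts.
    """
    return np.geomspace(highest, lowest, n_levels)


@dataclass(frozen=True)
class StaircaseResult:
    trials: pd.DataFrame  # columns: trial, level, contrast, correct
    reversal_levels: np.ndarray
    threshold_steps: float
    ceiling: bool
    config: StaircaseConfig = field(repr=False, default=StaircaseConfig())


def run_staircase(
    observer,
    config: StaircaseConfig = SQUARE_TASK,
    level_contrasts: np.ndarray | None = None,
    seed: int | None = None,
) -> StaircaseResult:
    """Simulate one 1-up/1-down staircase with a stochastic observer.

    ``observer`` needs a ``p_correct(contrast)`` method.  Level moves are
    clamped to [1, n_levels]; a reversal is logged whenever the intended move
    direction flips.  The threshold is the mean of the last six reversal
    levels, or the lowest-contrast level for ceiling runs.
    """
    if level_contrasts is None:
        level_contrasts = default_level_contrasts(config.n_levels)
    level_contrasts = np.asarray(level_contrasts, dtype=float)
    if level_contrasts.size != config.n_levels:
        raise ValueError("level_contrasts must cover every level")
    rng = np.random.default_rng(seed)

    level = config.start_level
    last_direction = 0
    reversals: list = []
    correct_at_floor = 0
    log = []
    ceiling = False
    for trial in range(config.max_trials):
        contrast = level_contrasts[level - 1]
        correct = bool(rng.random() < observer.p_correct(contrast))
        log.append((trial, level, contrast, correct))
        if correct and level == config.n_levels:
            correct_at_floor += 1
            if correct_at_floor > config.ceiling_correct:
                ceiling = True
                break
        direction = 1 if correct else -1  # +1 toward lower contrast
        if last_direction != 0 and direction != last_direction:
            reversals.append(level)
        last_direction = direction
        level = int(np.clip(level + direction, 1, config.n_levels))
        if len(reversals) >= config.min_reversals:
            break

    reversals = np.asarray(reversals, dtype=float)
    if ceiling:
        threshold = float(config.n_levels)
    elif reversals.size:
        threshold = float(reversals[-6:].mean())
    else:
        threshold = float(level)
    trials = pd.DataFrame(log, columns=["trial", "level", "contrast", "correct"])
    return StaircaseResult(trials, reversals, threshold, ceiling, config)


def threshold_in_contrast(
    threshold_steps: float, level_contrasts: np.ndarray
) -> float:
    """Convert a step-unit threshold to Michelson contrast by interpolation."""
    lc = np.asarray(level_contrasts, dtype=float)
    if np.any(~np.isfinite(lc)):
        raise ValueError("level-contrast table contains missing levels")
    levels = np.arange(1, lc.size + 1, dtype=float)
    if not levels[0] <= threshold_steps <= levels[-1]:
        raise ValueError("threshold outside the level range")
    return float(np.interp(threshold_steps, levels, lc))


def contrast_to_level(contrast: float, level_contrasts: np.ndarray) -> float:
    """Inverse of the level table: continuous level at a given contrast."""
    lc = np.asarray(level_contrasts, dtype=float)
    levels = np.arange(1, lc.size + 1, dtype=float)
    order = np.argsort(lc)
    return float(np.interp(contrast, lc[order], levels[order]))


def prediction_interval(values: np.ndarray, level: float = 0.95) -> tuple:
    """t-distribution prediction interval: mean +/- t * s * sqrt(1 + 1/n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    m = v.mean()
    s = v.std(ddof=1)
    if s == 0:
        return (float(m), float(m))
    t = stats.t.ppf((1 + level) / 2, v.size - 1)
    half = t * s * np.sqrt(1.0 + 1.0 / v.size)
    return (float(m - half), float(m + half))


def exceeds_untreated_range(threshold: float, interval: tuple) -> str:
    """Classify a threshold against the untreated prediction interval.

    Lower thresholds are better; only a threshold strictly below the lower
    bound counts as "improved beyond range".  Values at the boundary are
    "within" (the interval is closed).
    """
    lo, _ = interval
    return "improved beyond range" if threshold < lo else "within untreated range"
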