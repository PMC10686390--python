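"""Threshold microperimetry simulated with a 4-2-1 staircase.

Sensitivity is expressed as decibels of attenuation of the device's
maximum stimulus luminance: higher dB means a dimmer stimulus, so a seen
response moves the staircase *up* in dB (dimmer) and a not-seen response
moves it down (brighter).  The instrument's dynamic range is 0-34 dB and
all presented levels and reported thresholds are clipped to it.

The observer answers through a cumulative-Gaussian psychometric function
with optional lapse (false-negative) and guess (false-positive) rates:

    P(seen | level L) = (1 - fn) * Phi((T - L) / sigma) + fp * (1 - Phi(...))

where T is the true threshold and sigma the psychometric spread.  With
sigma = 0 the observer is deterministic: seen iff L <= T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DB_MIN = 0.0
DB_MAX = 34.0
DEFAULT_START_DB = 17.0
MAX_PRESENTATIONS = 30

_STEPS_DB = (4.0, 2.0, 1.0)


@dataclass(frozen=True)
class ObserverModel:
    """Psychometric observer answering stimulus presentations."""

    true_threshold_db: float
    slope_sd_db: float = 0.5
    false_pos_rate: float = 0.03
    false_neg_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.slope_sd_db < 0:
            raise ValueError("slope_sd_db must be >= 0")
        for r in (self.false_pos_rate, self.false_neg_rate):
            if not (0 <= r < 1):
                raise ValueError("response-error rates must lie in [0, 1)")

    def p_seen(self, level_db: float) -> float:
        """Probability of a 'seen' response at the given attenuation."""
        if self.slope_sd_db == 0:
            phi = 1.0 if level_db <= self.true_threshold_db else 0.0
        else:
            z = (self.true_threshold_db - level_db) / self.slope_sd_db
            phi = 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
        return (1.0 - self.false_neg_rate) * phi + self.false_pos_rate * (1.0 - phi)


def respond(observer: ObserverModel, level_db: float, rng: np.random.Generator) -> bool:
    """Draw one seen/not-seen response to a presentation."""
    return bool(rng.random() < observer.p_seen(level_db))


@dataclass
class StaircaseResult:
    """Outcome of one threshold staircase."""

    estimate_db: float
    presentation_log: list[tuple[float, bool]] = field(default_factory=list)
    n_reversals: int = 0


def staircase_421(
    observer: ObserverModel,
    rng: np.random.Generator,
    start_level_db: float = DEFAULT_START_DB,
) -> StaircaseResult:
    """Run a 4-2-1 dB staircase and return the threshold estimate.

    Step size shrinks 4 -> 2 -> 1 dB at each response reversal and the
    staircase terminates at the first reversal while on the 1 dB step.
    The estimate is the highest (dimmest) attenuation answered "seen",
    or 0 dB if nothing was ever seen.  A response at a range boundary
    that cannot be stepped past (seen at 34 dB, not seen at 0 dB)
    terminates immediately, as does a hard presentation cap.
    """
    if not (DB_MIN <= start_level_db <= DB_MAX):
        raise ValueError("start level outside the 0-34 dB dynamic range")
    level = float(start_level_db)
    step_idx = 0
    log: list[tuple[float, bool]] = []
    prev_seen: bool | None = None
    n_reversals = 0
    highest_seen: float | None = None

    while len(log) < MAX_PRESENTATIONS:
        seen = respond(observer, level, rng)
        log.append((level, seen))
        if seen:
            highest_seen = level if highest_seen is None else max(highest_seen, level)
        if prev_seen is not None and seen != prev_seen:
            n_reversals += 1
            if step_idx == len(_STEPS_DB) - 1:
                break
            step_idx += 1
        prev_seen = seen
        if seen and level >= DB_MAX:
            break
        if not seen and level <= DB_MIN:
            break
        delta = _STEPS_DB[step_idx] if seen else -_STEPS_DB[step_idx]
        level = min(DB_MAX, max(DB_MIN, level + delta))

    estimate = DB_MIN if highest_seen is None else highest_seen
    return StaircaseResult(estimate_db=estimate, presentation_log=log,
                           n_reversals=n_reversals)


def simulate_exam(
    true_thresholds_db,
    rng_seed,
    slope_sd_db: float = 0.5,
    false_pos_rate: float = 0.03,
    false_neg_rate: float = 0.03,
    start_level_db: float = DEFAULT_START_DB,
) -> np.ndarray:
    """Measure a full examination: one independent staircase per stimulus.

    Parameters
    ----------
    true_thresholds_db : array-like
        Underlying threshold per stimulus (any real; the staircase output
        is confined to 0-34 dB).
    rng_seed : int or numpy SeedSequence/Generator
        Seed controlling every response draw; identical seeds give
        identical examinations.

    Returns
    -------
    ndarray of measured sensitivities, same length as the input.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    thresholds = np.asarray(true_thresholds_db, dtype=float)
    out = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        obs = ObserverModel(
            true_threshold_db=float(t),
            slope_sd_db=slope_sd_db,
            false_pos_rate=false_pos_rate,
            false_neg_rate=false_neg_rate,
        )
        out[i] = staircase_421(obs, rng, start_level_db).estimate_db
    return out
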