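"""Behavioral readouts: up-down 50% withdrawal threshold and Gait General Score.

The mechanical threshold follows the up-down (Dixon) staircase on a
logarithmically spaced von Frey filament set: a withdrawal (X) steps the next
stimulus down one filament, no response (O) steps it up, and testing stops a
fixed number of responses after the first direction change, or at the range
limits.  The 50% threshold is ``10**(x_f + k * delta)`` grams, where ``x_f``
is the log10 force of the last filament presented, ``delta`` the mean log10
filament spacing, and ``k`` the Dixon correction factor for the observed
response pattern.  Here ``k`` is obtained from the maximum-likelihood fit of
a normal psychometric function with scale ``delta`` to the staircase — the
construction underlying the published correction tables — so arbitrary
filament sets are supported.

The Gait General Score for a paw is the percentage of gait parameters that
are *not* significantly different (unpaired two-sample t-test, p < 0.05)
between baseline and day 7: ``(1 - n_significant / F) * 100`` with F = 42
parameters by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Default 8-filament von Frey set (gram force), 0.007-6.0 g.
DEFAULT_FILAMENTS: tuple[float, ...] = (0.007, 0.02, 0.07, 0.16, 0.4, 1.0, 2.0, 6.0)

#: Default number of responses collected after the first staircase reversal.
N_POST_REVERSAL = 4

RESPONSE = "X"  # withdrawal
NO_RESPONSE = "O"


class UpDownSequenceError(ValueError):
    """Raised when a response sequence violates the up-down staircase rules."""


@dataclass(frozen=True)
class VonFreyTrial:
    """One up-down staircase: filament set, starting filament, responses."""

    responses: str
    filaments: tuple[float, ...] = DEFAULT_FILAMENTS
    start_index: int = 4  # 0.4 g on the default set

    def __post_init__(self) -> None:
        object.__setattr__(self, "filaments", tuple(self.filaments))
        f = np.asarray(self.filaments)
        if len(f) < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("filaments must be strictly increasing, length >= 2")
        if not 0 <= self.start_index < len(f):
            raise ValueError("start_index outside the filament set")


def filament_log_step(filaments) -> float:
    """Mean log10 spacing (delta) of the filament set."""
    logs = np.log10(np.asarray(filaments, dtype=float))
    return float(np.mean(np.diff(logs)))


def updown_walk(trial: VonFreyTrial) -> tuple[list[int], str]:
    """Reconstruct the filament indices presented and the terminal status.

    Returns (indices, status) with status one of ``"ok"`` (terminated by the
    post-reversal count), ``"ceiling"`` (no response at the strongest
    filament), ``"floor"`` (withdrawal at the weakest filament) or
    ``"short"`` (staircase ended early).  Raises :class:`UpDownSequenceError`
    for malformed sequences.
    """
    seq = trial.responses
    if not seq:
        raise UpDownSequenceError("empty response sequence")
    bad = set(seq) - {RESPONSE, NO_RESPONSE}
    if bad:
        raise UpDownSequenceError(f"invalid response characters: {sorted(bad)}")

    top = len(trial.filaments) - 1
    idx = trial.start_index
    indices = []
    first_reversal: int | None = None
    stop_at: int | None = None
    for i, r in enumerate(seq):
        if stop_at is not None and i >= stop_at:
            raise UpDownSequenceError("responses continue past the terminal pattern")
        indices.append(idx)
        if first_reversal is None and i > 0 and r != seq[i - 1]:
            first_reversal = i
            stop_at = i + N_POST_REVERSAL + 1
        if r == RESPONSE:
            if idx == 0:
                if i != len(seq) - 1:
                    raise UpDownSequenceError(
                        "responses continue after withdrawal at the weakest filament"
                    )
                return indices, "floor"
            idx -= 1
        else:
            if idx == top:
                if i != len(seq) - 1:
                    raise UpDownSequenceError(
                        "responses continue after no-response at the strongest filament"
                    )
                return indices, "ceiling"
            idx += 1
    if stop_at is not None and len(seq) == stop_at:
        return indices, "ok"
    return indices, "short"


def _ml_log_threshold(log_forces: np.ndarray, responses: str, sigma: float) -> float:
    """MLE of the 50% point of a normal psychometric function, scale sigma."""
    x = np.asarray(log_forces, dtype=float)
    is_x = np.array([r == RESPONSE for r in responses])

    def nll(mu: float) -> float:
        z = (x - mu) / sigma
        logp = stats.norm.logcdf(z)
        log1mp = stats.norm.logcdf(-z)
        return -float(np.sum(np.where(is_x, logp, log1mp)))

    lo, hi = x.min() - 3 * sigma, x.max() + 3 * sigma
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def dixon_k(trial: VonFreyTrial) -> float:
    """Dixon correction factor k for the trial's terminal response pattern."""
    indices, status = updown_walk(trial)
    if status in ("ceiling", "floor"):
        raise ValueError("k is undefined for range-limited staircases")
    logs = np.log10(np.asarray(trial.filaments, dtype=float))
    delta = filament_log_step(trial.filaments)
    mu = _ml_log_threshold(logs[indices], trial.responses, sigma=delta)
    x_f = logs[indices[-1]]
    return (mu - x_f) / delta


def updown_threshold(trial: VonFreyTrial) -> float:
    """50% withdrawal threshold (grams) from an up-down staircase.

    All-O staircases reaching the strongest filament report the ceiling
    (strongest filament force); all-X staircases reaching the weakest report
    the floor.  Otherwise the threshold is ``10**(x_f + k*delta)``, clamped
    to the filament range.
    """
    indices, status = updown_walk(trial)
    fmin, fmax = trial.filaments[0], trial.filaments[-1]
    if status == "ceiling":
        return fmax
    if status == "floor":
        return fmin
    if RESPONSE not in trial.responses:
        return fmax
    if NO_RESPONSE not in trial.responses:
        return fmin
    logs = np.log10(np.asarray(trial.filaments, dtype=float))
    delta = filament_log_step(trial.filaments)
    mu = _ml_log_threshold(logs[indices], trial.responses, sigma=delta)
    x_f = logs[indices[-1]]
    thr = 10.0 ** (x_f + ((mu - x_f) / delta) * delta)
    return float(np.clip(thr, fmin, fmax))


# ---------------------------------------------------------------------------
# Gait General Score
# ---------------------------------------------------------------------------

BASELINE = "baseline"
DAY7 = "day7"


def gait_general_score(
    gait,
    paw: str | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> float:
    """Gait General Score (%) for one paw.

    Parameters
    ----------
    gait
        Long-format table with columns ``timepoint`` (``baseline``/``day7``),
        optionally ``paw``, plus one column per gait parameter.  Non-parameter
        bookkeeping columns (``mouse``) are ignored.
    paw
        Paw to score when the table holds several.
    alpha
        Per-parameter significance cut (raw p, no multiplicity correction).
    equal_var
        Classic equal-variance t-test by default; ``False`` gives Welch.

    A parameter with zero variance in both groups has an undefined t-test and
    is counted as not significant.  Missing cells are dropped per parameter.
    """
    df = gait
    if paw is not None:
        if "paw" not in df.columns:
            raise ValueError("gait table has no 'paw' column")
        df = df[df["paw"] == paw]
    if "timepoint" not in df.columns:
        raise ValueError("gait table needs a 'timepoint' column")
    params = [c for c in df.columns if c not in ("mouse", "timepoint", "paw")]
    if not params:
        raise ValueError("gait table has no parameter columns")

    base = df[df["timepoint"] == BASELINE]
    day7 = df[df["timepoint"] == DAY7]
    if len(base) < 2 or len(day7) < 2:
        raise ValueError("need >= 2 mice per timepoint")

    n_sig = 0
    for p in params:
        a = base[p].dropna().to_numpy(dtype=float)
        b = day7[p].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("parameter %s: fewer than 2 observations, skipped", p)
            continue
        if np.var(a) == 0 and np.var(b) == 0:
            logger.info("parameter %s: zero variance in both groups, not significant", p)
            continue
        pval = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
        if np.isfinite(pval) and pval < alpha:
            n_sig += 1
    return (1.0 - n_sig / len(params)) * 100.0
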