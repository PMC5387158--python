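"""Simulated observers performing the dual-staircase global-motion confidence task.

The task is a forced-choice judgement of the global (mean) direction of a
random-dot motion stimulus — left or right of vertical — followed by a
confidence rating on a 0-100 scale.  Two interleaved conditions hold
performance near 71% correct with 2-up-1-down adaptive staircases:

* ``MU`` (mean staircase): the mean motion angle adapts, the direction SD is
  fixed at 30 degrees.
* ``SIGMA`` (variance staircase): the direction SD adapts, the mean angle is
  fixed at 15 degrees.

Per trial the dot direction sample is ``sign(side) * mean_angle +
Normal(0, sd_angle)`` (angles from vertical, LEFT negative).

The simulated observer integrates a small random subsample of the dots
(``n_effective_dots``) — a limited-capacity global-motion observer — and adds
internal Gaussian noise; this makes accuracy strictly monotone in either
adapted quantity, so both staircases converge.  Confidence is the
uncertainty-normalized decision evidence corrupted by metacognitive noise,
shifted additively by the trial's direction SD (a variance-induced confidence
bias), and mapped affinely onto 0-100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MU = "MU"
SIGMA = "SIGMA"
CONDITIONS = (MU, SIGMA)
LEFT, RIGHT, NONE = "LEFT", "RIGHT", "NONE"

#: column order of the trial-table CSV contract
TRIAL_COLUMNS = [
    "trial_index", "block", "condition", "true_side", "mean_angle",
    "sd_angle", "response", "correct", "rt_ms", "confidence_raw",
    "confidence_bin",
]


@dataclass
class SessionConfig:
    """Layout and stimulus parameters of one session."""

    n_main_trials: int = 320
    n_blocks: int = 8
    n_practice_trials: int = 56
    fixed_mean_angle: float = 15.0   # deg, SIGMA condition
    fixed_sd: float = 30.0           # deg, MU condition
    n_dots: int = 1100
    aperture_radius: float = 9.5     # degrees visual angle (metadata only)
    stimulus_duration_ms: float = 250.0
    response_window_ms: float = 800.0
    max_dot_lifetime_fraction: float = 0.93  # metadata only; no rendering
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_main_trials % 2:
            raise ValueError("n_main_trials must be even (equal condition split)")
        if self.n_main_trials % self.n_blocks:
            raise ValueError("n_main_trials must be divisible by n_blocks")
        if (self.n_main_trials // self.n_blocks) % 2:
            raise ValueError("per-block trial count must be even for balanced blocks")
        for name in ("stimulus_duration_ms", "response_window_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_dots < 1:
            raise ValueError("n_dots must be >= 1")


@dataclass
class ObserverParams:
    """Generative parameters of one simulated observer.

    sensory_noise
        SD (deg) of internal Gaussian noise added to the integrated motion
        estimate; sets type-I sensitivity.
    n_effective_dots
        number of dots the observer integrates per trial; controls how much
        the stimulus direction SD leaks into the decision variable, hence how
        effective the variance staircase is.
    metacognitive_noise
        unitless SD of Gaussian noise added to the normalized confidence
        evidence |estimate| / sigma_eff (whose own spread is of order 1);
        0 gives confidence that is a deterministic monotone function of the
        decision evidence, large values drive type-II AROC to 0.5.
    variance_bias_weight
        additive confidence shift per degree of stimulus direction SD — the
        generative variance-induced confidence bias (negative: noisier
        stimuli feel less certain).  The confidence evidence itself is
        normalized by the observer's internal uncertainty, so this weight is
        the sole direct path from stimulus SD to confidence.
    """

    sensory_noise: float = 15.0
    n_effective_dots: int = 8
    metacognitive_noise: float = 0.5
    confidence_gain: float = 25.0
    confidence_offset: float = 25.0
    variance_bias_weight: float = -0.25
    rt_base_ms: float = 300.0
    rt_noise_ms: float = 55.0

    def __post_init__(self) -> None:
        if self.sensory_noise <= 0:
            raise ValueError("sensory_noise must be > 0")
        if self.confidence_gain <= 0:
            raise ValueError("confidence_gain must be > 0")
        if self.metacognitive_noise < 0:
            raise ValueError("metacognitive_noise must be >= 0")
        if self.n_effective_dots < 1:
            raise ValueError("n_effective_dots must be >= 1")


@dataclass
class Staircase:
    """One 2-up-1-down adaptive track.

    Two consecutive correct responses make the task harder by one step, a
    single error makes it easier; the rule's accuracy fixed point is
    sqrt(1/2) ~ 0.707.  "Harder" is a smaller mean angle for MU and a larger
    direction SD for SIGMA.
    """

    condition: str
    level: float
    step_size: float
    level_bounds: tuple[float, float]
    consecutive_correct: int = 0
    n_reversals: int = 0
    _last_direction: int = 0  # +1 easier, -1 harder

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        lo, hi = self.level_bounds
        if not lo <= self.level <= hi:
            raise ValueError("level outside level_bounds")

    @classmethod
    def default(cls, condition: str) -> "Staircase":
        if condition == MU:
            return cls(MU, level=15.0, step_size=1.0, level_bounds=(0.5, 45.0))
        return cls(SIGMA, level=30.0, step_size=2.0, level_bounds=(5.0, 90.0))

    def update(self, correct: bool) -> "Staircase":
        """Apply one trial outcome in place (also returns self)."""
        direction = 0
        if not correct:
            self.consecutive_correct = 0
            direction = +1  # easier
        else:
            self.consecutive_correct += 1
            if self.consecutive_correct >= 2:
                self.consecutive_correct = 0
                direction = -1  # harder
        if direction:
            easier_sign = +1 if self.condition == MU else -1
            self.level += direction * easier_sign * self.step_size
            lo, hi = self.level_bounds
            self.level = min(max(self.level, lo), hi)
            if self._last_direction and direction != self._last_direction:
                self.n_reversals += 1
            self._last_direction = direction
        return self


def staircase_update(state: Staircase, correct: bool) -> Staircase:
    """Functional form of :meth:`Staircase.update` (state is mutated)."""
    return state.update(correct)


def make_stimulus(condition, level, true_side, config, rng):
    """Draw the per-trial dot direction sample.

    Returns ``(dots, mean_angle, sd_angle)`` where ``dots`` are ``n_dots``
    directions drawn from ``Normal(sign * mean_angle, sd_angle)``; sign is -1
    for LEFT and +1 for RIGHT.  ``(mean_angle, sd_angle)`` is
    ``(level, fixed_sd)`` for MU and ``(fixed_mean_angle, level)`` for SIGMA.
    """
    if level <= 0:
        raise ValueError(f"invalid staircase level {level!r}: must be > 0")
    if condition == MU:
        mean_angle, sd_angle = float(level), float(config.fixed_sd)
    elif condition == SIGMA:
        mean_angle, sd_angle = float(config.fixed_mean_angle), float(level)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if sd_angle <= 0:
        raise ValueError(f"invalid direction SD {sd_angle!r}: must be > 0")
    sign = -1.0 if true_side == LEFT else +1.0
    dots = sign * mean_angle + rng.normal(0.0, sd_angle, size=config.n_dots)
    return dots, mean_angle, sd_angle


def observer_respond(dots, sd_angle, params, rng):
    """Simulate one choice, RT and raw confidence from a dot sample.

    The internal estimate is the mean of an ``n_effective_dots`` subsample
    plus ``Normal(0, sensory_noise)``; response is RIGHT iff the estimate is
    positive.  Confidence evidence is the uncertainty-normalized magnitude
    ``|estimate| / sigma_eff`` (the observer knows its own noise level, so
    confidence approximates the probability of being correct) plus
    metacognitive noise, shifted by ``variance_bias_weight * sd_angle`` and
    mapped affinely onto [0, 100].
    """
    dots = np.asarray(dots, dtype=float)
    if dots.size == 0:
        raise ValueError("empty dot sample")
    n_eff = min(params.n_effective_dots, dots.size)
    if n_eff < dots.size:
        sub = dots[rng.choice(dots.size, size=n_eff, replace=False)]
    else:
        sub = dots
    estimate = sub.mean() + rng.normal(0.0, params.sensory_noise)
    response = RIGHT if estimate > 0 else LEFT
    sigma_eff = np.sqrt(params.sensory_noise ** 2 + sd_angle ** 2 / n_eff)
    evidence = abs(estimate) / sigma_eff
    if params.metacognitive_noise > 0:
        evidence += rng.normal(0.0, params.metacognitive_noise)
    confidence = (params.confidence_offset
                  + params.confidence_gain * evidence
                  + params.variance_bias_weight * sd_angle)
    confidence = float(np.clip(confidence, 0.0, 100.0))
    rt_ms = params.rt_base_ms + rng.gamma(2.0, params.rt_noise_ms / 2.0)
    return response, float(rt_ms), confidence


def _run_trial(condition, staircase, params, config, rng):
    true_side = LEFT if rng.random() < 0.5 else RIGHT
    dots, mean_angle, sd_angle = make_stimulus(
        condition, staircase.level, true_side, config, rng)
    response, rt_ms, confidence = observer_respond(dots, sd_angle, params, rng)
    correct = response == true_side
    staircase.update(correct)
    return dict(condition=condition, true_side=true_side, mean_angle=mean_angle,
                sd_angle=sd_angle, response=response, correct=bool(correct),
                rt_ms=rt_ms, confidence_raw=confidence)


def run_staircase_trials(condition, n_trials, params, config=None, rng=None,
                         staircase=None):
    """Run one staircase track alone for ``n_trials``; returns a trial table.

    Used for convergence checks: post-burn-in accuracy should sit near the
    2-up-1-down fixed point of sqrt(1/2) ~ 70.7% correct.
    """
    config = config or SessionConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    staircase = staircase or Staircase.default(condition)
    rows = []
    for i in range(n_trials):
        rec = _run_trial(condition, staircase, params, config, rng)
        rec.update(trial_index=i, block=0, confidence_bin=np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)[TRIAL_COLUMNS]


@dataclass
class Session:
    """One simulated session: the main trial table plus practice outcome."""

    trials: pd.DataFrame
    practice_accuracy: float
    practice_passed: bool      # practice accuracy > 0.70 entry criterion
    config: SessionConfig
    params: ObserverParams
    practice_trials: pd.DataFrame | None = None


def run_session(params, config=None, rng=None, keep_practice=False) -> Session:
    """Simulate practice then the interleaved dual-staircase main session.

    Practice (no confidence ratings, accuracy feedback implied) precedes the
    main session; both adaptive tracks run continuously from the first
    practice trial onward, so the main session starts near convergence and
    discarding its first block suffices to remove residual drift.  Conditions
    interleave randomly within blocks with equal per-block counts.
    """
    config = config or SessionConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)

    # practice: alternating conditions, no confidence ratings
    stairs = {c: Staircase.default(c) for c in CONDITIONS}
    practice_rows = []
    for i in range(config.n_practice_trials):
        cond = CONDITIONS[i % 2]
        rec = _run_trial(cond, stairs[cond], params, config, rng)
        rec.update(trial_index=i, block=-1,
                   confidence_raw=np.nan, confidence_bin=np.nan)
        practice_rows.append(rec)
    practice = pd.DataFrame(practice_rows)[TRIAL_COLUMNS]
    practice_accuracy = float(practice["correct"].mean())
    per_block = config.n_main_trials // config.n_blocks
    rows = []
    idx = 0
    for block in range(1, config.n_blocks + 1):
        order = np.array([MU] * (per_block // 2) + [SIGMA] * (per_block // 2))
        rng.shuffle(order)
        for cond in order:
            rec = _run_trial(cond, stairs[cond], params, config, rng)
            rec.update(trial_index=idx, block=block, confidence_bin=np.nan)
            rows.append(rec)
            idx += 1
    trials = pd.DataFrame(rows)[TRIAL_COLUMNS]
    return Session(trials=trials,
                   practice_accuracy=practice_accuracy,
                   practice_passed=practice_accuracy > 0.70,
                   config=config, params=params,
                   practice_trials=practice if keep_practice else None)


# per-subject covariate generation: cohort of healthy adults aged 20-40
# (mean 24, SD 5), 29/48 female; TIV in ml, males ~100 ml larger on average.
def _draw_covariates(n_subjects, rng):
    age = np.clip(rng.normal(24.0, 5.0, n_subjects), 20.0, 40.0)
    gender = (rng.random(n_subjects) < 29 / 48).astype(int)  # 1 = female
    tiv = rng.normal(1400.0, 100.0, n_subjects) + 100.0 * (gender == 0)
    return age, gender, tiv


def default_param_sampler(rng) -> ObserverParams:
    """Draw heterogeneous observer parameters for one cohort member."""
    return ObserverParams(
        sensory_noise=float(np.clip(rng.normal(15.0, 3.0), 5.0, 40.0)),
        n_effective_dots=8,
        metacognitive_noise=float(np.clip(rng.normal(0.7, 0.45), 0.02, 4.0)),
        confidence_gain=float(np.clip(rng.normal(25.0, 4.0), 5.0, 60.0)),
        confidence_offset=float(rng.normal(25.0, 5.0)),
        variance_bias_weight=float(rng.normal(-0.25, 0.15)),
        rt_base_ms=float(np.clip(rng.normal(300.0, 40.0), 150.0, 600.0)),
        rt_noise_ms=float(np.clip(rng.normal(55.0, 10.0), 10.0, 200.0)),
    )


def simulate_cohort(n_subjects, config=None, rng=None, param_sampler=None):
    """Simulate a cohort of sessions with heterogeneous observers.

    Returns ``(sessions, truth)`` where ``truth`` is a DataFrame (one row per
    subject) of the generating observer parameters and the demographic
    covariates (age, gender coded 1=female, total intracranial volume in ml)
    used downstream as nuisance regressors.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    config = config or SessionConfig()
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    param_sampler = param_sampler or default_param_sampler

    params_list = [param_sampler(rng) for _ in range(n_subjects)]
    meta = np.array([p.metacognitive_noise for p in params_list])
    if np.var(meta) == 0:
        warnings.warn("zero variance in metacognitive_noise across the cohort: "
                      "AROC recovery tests will be vacuous", stacklevel=2)
    age, gender, tiv = _draw_covariates(n_subjects, rng)

    sessions, truth_rows = [], []
    for i, p in enumerate(params_list):
        sessions.append(run_session(p, config, rng))
        row = {"subject": i, **vars(p),
               "age": age[i], "gender": int(gender[i]), "tiv": tiv[i]}
        truth_rows.append(row)
    return sessions, pd.DataFrame(truth_rows)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    return df[TRIAL_COLUMNS]
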