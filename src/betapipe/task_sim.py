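"""Two-alternative probabilistic reward task simulator.

Simulates the 6-block task (40 trials per block, 70/30 gain probabilities in
blocks 1-5 and 60/40 in block 6, six point schemes) together with an agent
that first learns, then exploits the advantageous option with rare isolated
explorative choices.  Outcome sequences are pre-built per option with exact
gain counts and a cap on runs of identical outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigError

ADV = "advantageous"
DIS = "disadvantageous"
GAIN = "gain"
LOSS = "loss"

#: canonical choice-type labels used throughout the pipeline
CHOICE_TYPES = ("HP", "pre-LP", "LP", "post-LP")


@dataclass(frozen=True)
class ReinforcementScheme:
    """Point magnitudes and gain probabilities for one block.

    ``loss_points`` is the worse of the two outcomes, ``gain_points`` the
    better one; both options share the magnitudes and differ only in the
    probability of drawing the better outcome.
    """

    name: str
    loss_points: int
    gain_points: int
    p_gain_advantageous: float
    p_gain_disadvantageous: float

    def __post_init__(self) -> None:
        for p in (self.p_gain_advantageous, self.p_gain_disadvantageous):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"scheme {self.name}: probability {p} outside [0, 1]")
        if not self.p_gain_advantageous > self.p_gain_disadvantageous:
            raise ConfigError(
                f"scheme {self.name}: p_gain_advantageous must exceed p_gain_disadvantageous"
            )
        if self.gain_points < self.loss_points:
            raise ConfigError(f"scheme {self.name}: gain_points below loss_points")

    def p_gain(self, option: str) -> float:
        if option == ADV:
            return self.p_gain_advantageous
        if option == DIS:
            return self.p_gain_disadvantageous
        raise ValueError(f"unknown option {option!r}")

    def points(self, outcome: str) -> int:
        return self.gain_points if outcome == GAIN else self.loss_points

    def expected_payoff(self, option: str) -> float:
        p = self.p_gain(option)
        return p * self.gain_points + (1.0 - p) * self.loss_points


#: the six standard schemes; I-V run at 70/30, VI at 60/40
STANDARD_SCHEMES: dict[str, ReinforcementScheme] = {
    "I": ReinforcementScheme("I", -20, 20, 0.7, 0.3),
    "II": ReinforcementScheme("II", 0, 20, 0.7, 0.3),
    "III": ReinforcementScheme("III", -20, 0, 0.7, 0.3),
    "IV": ReinforcementScheme("IV", 20, 50, 0.7, 0.3),
    "V": ReinforcementScheme("V", -50, -20, 0.7, 0.3),
    "VI": ReinforcementScheme("VI", -20, 20, 0.6, 0.4),
}

#: the three permitted scheme orders
SCHEME_ORDERS = (
    "I-II-III-IV-V-VI",
    "I-IV-III-V-II-VI",
    "I-IV-III-II-V-VI",
)


@dataclass
class TaskConfig:
    """Block structure of the task."""

    n_blocks: int = 6
    trials_per_block: int = 40
    scheme_order: str = SCHEME_ORDERS[0]
    schemes: tuple[ReinforcementScheme, ...] | None = None
    max_outcome_run: int = 3

    def resolve_schemes(self) -> tuple[ReinforcementScheme, ...]:
        if self.schemes is not None:
            return tuple(self.schemes)
        names = self.scheme_order.split("-")
        return tuple(STANDARD_SCHEMES[n] for n in names)

    def validate(self) -> list[str]:
        """Return a list of human-readable violations (empty if valid)."""
        errors: list[str] = []
        if self.n_blocks < 1:
            errors.append("task.n_blocks: must be >= 1")
        if self.trials_per_block < 1:
            errors.append("task.trials_per_block: must be >= 1")
        if self.max_outcome_run < 1:
            errors.append("task.max_outcome_run: must be >= 1")
        if self.schemes is None:
            if self.scheme_order not in SCHEME_ORDERS:
                errors.append(
                    f"task.scheme_order: {self.scheme_order!r} is not one of the "
                    f"three permitted sequences {SCHEME_ORDERS}"
                )
            elif self.n_blocks != len(self.scheme_order.split("-")):
                errors.append("task.n_blocks: must match the scheme_order length")
        elif len(self.schemes) != self.n_blocks:
            errors.append("task.schemes: length must equal n_blocks")
        if not errors:
            for s in self.resolve_schemes():
                g = int(round(s.p_gain_advantageous * self.trials_per_block))
                if not _arrangeable(g, self.trials_per_block - g, self.max_outcome_run):
                    errors.append(
                        f"task: scheme {s.name} gain count infeasible under "
                        f"max_outcome_run={self.max_outcome_run}"
                    )
        return errors


@dataclass
class AgentParams:
    """Behavioral stand-in for a participant.

    Two-phase choice model: a learning phase of roughly
    ``n_learning_trials`` mixed choices followed by a stationary preference
    for the advantageous option (``p_advantageous_stable``).  Disadvantageous
    choices in the stable phase are kept isolated (flanked by advantageous
    ones) with probability ``p_lp_isolated``.  RTs are log-normal with a
    choice-type-dependent location; the default ordering is
    LP > pre-LP = post-LP > HP.
    """

    n_learning_trials: float = 6.0
    p_advantageous_stable: float = 0.90
    p_lp_isolated: float = 1.0
    rt_log_mean_by_type: dict[str, float] = field(
        default_factory=lambda: {
            "HP": 6.55,
            "pre-LP": 6.65,
            "LP": 6.80,
            "post-LP": 6.65,
            "other": 6.60,
        }
    )
    rt_log_sd: float = 0.25

    def validate(self) -> list[str]:
        errors: list[str] = []
        if not 0.0 <= self.p_advantageous_stable <= 1.0:
            errors.append("agent.p_advantageous_stable: outside [0, 1]")
        if not 0.0 <= self.p_lp_isolated <= 1.0:
            errors.append("agent.p_lp_isolated: outside [0, 1]")
        if self.rt_log_sd <= 0:
            errors.append("agent.rt_log_sd: must be > 0")
        missing = [t for t in CHOICE_TYPES if t not in self.rt_log_mean_by_type]
        if missing:
            errors.append(f"agent.rt_log_mean_by_type: missing entries for {missing}")
        return errors


def _arrangeable(a: int, b: int, cap: int) -> bool:
    """Can ``a`` of one symbol and ``b`` of the other be arranged with no run > cap?"""
    return a <= cap * (b + 1) and b <= cap * (a + 1)


def build_outcome_sequence(
    p_gain: float, n: int, max_run: int, rng: np.random.Generator
) -> list[str]:
    """Quasirandom gain/loss sequence with exact counts and a run cap.

    The number of gains equals ``round(p_gain * n)`` exactly; no run of
    identical outcomes exceeds ``max_run``.  Sampling is sequential: at each
    position a feasible symbol is drawn with probability proportional to its
    remaining count, so the order depends only on ``rng``.
    """
    if n < 1:
        raise ConfigError("build_outcome_sequence: n must be >= 1")
    if max_run < 1:
        raise ConfigError("build_outcome_sequence: max_run must be >= 1")
    n_gain = int(round(p_gain * n))
    n_loss = n - n_gain
    if not _arrangeable(n_gain, n_loss, max_run):
        raise ConfigError(
            f"build_outcome_sequence: {n_gain} gains / {n_loss} losses cannot be "
            f"arranged with max_run={max_run}"
        )
    remaining = {GAIN: n_gain, LOSS: n_loss}
    seq: list[str] = []
    run_sym: str | None = None
    run_len = 0
    for _ in range(n):
        candidates: list[tuple[str, int]] = []
        for sym in (GAIN, LOSS):
            if remaining[sym] == 0:
                continue
            new_run = run_len + 1 if sym == run_sym else 1
            if new_run > max_run:
                continue
            other = GAIN if sym == LOSS else LOSS
            a, b = remaining[sym] - 1, remaining[other]
            # feasibility of the remainder: the next run of `sym` may hold at
            # most max_run - new_run items before an `other` must intervene
            if a <= max_run * b + (max_run - new_run) and b <= max_run * (a + 1):
                candidates.append((sym, remaining[sym]))
        if not candidates:  # pragma: no cover - excluded by the upfront check
            raise ConfigError("build_outcome_sequence: dead end (internal error)")
        total = sum(w for _, w in candidates)
        draw = rng.random() * total
        acc = 0.0
        chosen = candidates[-1][0]
        for sym, w in candidates:
            acc += w
            if draw < acc:
                chosen = sym
                break
        seq.append(chosen)
        remaining[chosen] -= 1
        run_len = run_len + 1 if chosen == run_sym else 1
        run_sym = chosen
    return seq


def provisional_choice_types(choices: list[str]) -> list[str]:
    """Context type of each choice from its within-block neighbors.

    Used by the agent to condition RT on the eventual choice-type context;
    trials matching none of the four definitions are labeled ``"other"``.
    """
    n = len(choices)
    types = []
    for t in range(n):
        prev = choices[t - 1] if t > 0 else None
        nxt = choices[t + 1] if t < n - 1 else None
        c = choices[t]
        if c == ADV and prev == ADV and nxt == ADV:
            types.append("HP")
        elif c == ADV and prev == ADV and nxt == DIS:
            types.append("pre-LP")
        elif c == DIS and prev == ADV and nxt == ADV:
            types.append("LP")
        elif c == ADV and prev == DIS and nxt == ADV:
            types.append("post-LP")
        else:
            types.append("other")
    return types


def simulate_subject(
    config: TaskConfig,
    agent: AgentParams,
    rng: np.random.Generator,
    subject_id: str = "s00",
) -> pd.DataFrame:
    """Simulate one subject; returns a tidy per-trial table."""
    errs = config.validate() + agent.validate()
    if errs:
        raise ConfigError("; ".join(errs))
    schemes = config.resolve_schemes()
    rows: list[dict] = []
    n = config.trials_per_block
    for b, scheme in enumerate(schemes):
        outcome_seq = {
            ADV: build_outcome_sequence(scheme.p_gain_advantageous, n, config.max_outcome_run, rng),
            DIS: build_outcome_sequence(scheme.p_gain_disadvantageous, n, config.max_outcome_run, rng),
        }
        used = {ADV: 0, DIS: 0}
        n_learn = int(rng.poisson(agent.n_learning_trials))
        n_learn = min(n_learn, max(0, n - 8))
        choices: list[str] = []
        for t in range(n):
            if t < n_learn:
                c = ADV if rng.random() < 0.5 else DIS
            elif t < n_learn + 4:
                c = ADV  # seed the four-in-a-row criterion run
            else:
                prev = choices[-1]
                if prev == DIS and rng.random() < agent.p_lp_isolated:
                    c = ADV
                else:
                    c = ADV if rng.random() < agent.p_advantageous_stable else DIS
            choices.append(c)
        types = provisional_choice_types(choices)
        for t, c in enumerate(choices):
            outcome = outcome_seq[c][used[c]]
            used[c] += 1
            mu = agent.rt_log_mean_by_type.get(
                types[t], agent.rt_log_mean_by_type.get("other", 6.6)
            )
            rt_ms = float(np.exp(rng.normal(mu, agent.rt_log_sd)))
            rows.append(
                {
                    "subject_id": subject_id,
                    "block": b,
                    "trial": t,
                    "scheme": scheme.name,
                    "choice": c,
                    "outcome": outcome,
                    "points": scheme.points(outcome),
                    "rt_ms": rt_ms,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: TaskConfig,
    agent: AgentParams,
    n_subjects: int,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Simulate ``n_subjects`` independent subjects from one master seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    width = max(2, len(str(n_subjects)))
    tables = [
        simulate_subject(config, agent, np.random.default_rng(child), f"s{i:0{width}d}")
        for i, child in enumerate(children)
    ]
    return pd.concat(tables, ignore_index=True)
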