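"""Synthetic trial-level data for the two-session crossover AB design.

The generator emulates the study conditions: each participant performs the
RSVP task in three blocks (baseline, during-tDCS, post) of two sessions, one
session per stimulation polarity, with ~130 short-lag and ~65 long-lag trials
per block and T1 accuracy around 82%.

Latent model (logit scale, per participant):

* baseline short-lag and long-lag T2|T1 logits and the T1 logit are drawn
  around the configured population means with a common between-subject SD;
* a bivariate-normal pair of stimulation effects (delta_anodal,
  delta_cathodal) with SD ``effect_sd`` and correlation ``rho_true`` is added
  to the short-lag logit during the tDCS block of the matching polarity's
  session (and, scaled by ``post_decay``, in the post block);
* a practice/learning shift is added to the short-lag logit in session 2;
* trial outcomes are independent Bernoulli draws given the cell
  probabilities (T2 correctness drawn independently of T1; only the
  conditional T2|T1 probability is identifiable from the scored task).

The anodal-vs-cathodal correlation of true change scores is ``rho_true``;
binomial trial noise attenuates what the pipeline can recover, which
:func:`attenuation_curve` quantifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .pipeline import LAG_DIALECTS

__all__ = ["SimConfig", "GroundTruth", "simulate_study", "attenuation_curve"]

log = logging.getLogger(__name__)

_PROB_CLIP = (0.01, 0.99)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the replication study's design.

    Counts and accuracy levels come from the published task description
    (130/65 short/long trials per 20-minute block, T1 accuracy ~.82, T2|T1
    ~.44 at the short and ~.83 at the long lag, 18 of 40 participants
    anodal-first); ``rho_true`` defaults to the original study's estimate of
    the anodal/cathodal effect correlation (-.45). Dispersion parameters are
    on the logit scale; see the package methods note for their calibration.
    """

    n_participants: int = 40
    trials_short: int = 130
    trials_long: int = 65
    t1_acc_mean: float = 0.82
    t2g1_short_mean: float = 0.44
    t2g1_long_mean: float = 0.83
    between_subject_sd: float = 0.7
    effect_sd: float = 0.4
    rho_true: float = -0.45
    learning_effect: float = 0.2
    post_decay: float = 1.0
    order_balance: float = 18.0 / 40.0
    dialect: str = "study2"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("t1_acc_mean", "t2g1_short_mean", "t2g1_long_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.trials_short <= 0 or self.trials_long <= 0:
            raise ValueError("trial counts must be positive")
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not -1.0 <= self.rho_true <= 1.0:
            raise ValueError(f"|rho_true| must be <= 1, got {self.rho_true}")
        if not 0.0 <= self.order_balance <= 1.0:
            raise ValueError("order_balance must be in [0, 1]")
        if self.between_subject_sd < 0 or self.effect_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.dialect not in LAG_DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Latent state behind one simulated dataset.

    ``participants`` has one row per participant (session order, baseline
    logits, the anodal/cathodal effect pair); ``cells`` has the latent
    probability of every participant x session x polarity x block x lag
    cell. ``n_clipped`` counts probabilities clipped into [0.01, 0.99].
    """

    participants: pd.DataFrame
    cells: pd.DataFrame
    n_clipped: int = 0
    config: SimConfig | None = None


def _participant_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"p{idx + 1:0{width}d}" for idx in range(n)]


def _bivariate_effects(
    sd: float, rho: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n draws of (delta_anodal, delta_cathodal): SD ``sd``, correlation
    ``rho``. Explicit Cholesky factor so the degenerate cases (sd = 0,
    rho = +/-1) work."""
    z = rng.standard_normal((n, 2))
    a = z[:, 0]
    c = rho * z[:, 0] + np.sqrt(max(1.0 - rho**2, 0.0)) * z[:, 1]
    return sd * np.column_stack([a, c])


def _lag_plan(config: SimConfig) -> list[tuple[int, bool, int]]:
    """(lag, is_short, n_trials) per lag of the dialect."""
    if config.dialect == "study2":
        return [(3, True, config.trials_short), (8, False, config.trials_long)]
    # three-lag design: the short-lag budget is split over lags 2 and 4
    half = config.trials_short // 2
    return [(2, True, half), (4, True, config.trials_short - half), (10, False, config.trials_long)]


def simulate_study(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one crossover dataset; deterministic under a fixed config.

    Returns the trial table (columns ``participant, session, polarity,
    block, lag, t1_correct, t2_correct``; one row per trial) and the
    :class:`GroundTruth` behind it.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    labels = _participant_labels(n)

    n_first = int(round(config.order_balance * n))
    anodal_first = np.zeros(n, dtype=bool)
    anodal_first[rng.permutation(n)[:n_first]] = True

    base_short = rng.normal(_logit(config.t2g1_short_mean), config.between_subject_sd, n)
    base_long = rng.normal(_logit(config.t2g1_long_mean), config.between_subject_sd, n)
    base_t1 = rng.normal(_logit(config.t1_acc_mean), config.between_subject_sd, n)

    effects = _bivariate_effects(
        config.effect_sd, config.rho_true, n, rng
    )
    delta = {"anodal": effects[:, 0], "cathodal": effects[:, 1]}

    participants = pd.DataFrame(
        {
            "participant": labels,
            "session_order": np.where(anodal_first, "anodal_first", "cathodal_first"),
            "base_logit_short": base_short,
            "base_logit_long": base_long,
            "base_logit_t1": base_t1,
            "delta_anodal": delta["anodal"],
            "delta_cathodal": delta["cathodal"],
        }
    )

    block_gain = {"baseline": 0.0, "tdcs": 1.0, "post": config.post_decay}
    lag_plan = _lag_plan(config)

    cell_rows = []
    for i, lab in enumerate(labels):
        for session in (1, 2):
            if anodal_first[i]:
                polarity = "anodal" if session == 1 else "cathodal"
            else:
                polarity = "cathodal" if session == 1 else "anodal"
            learn = config.learning_effect if session == 2 else 0.0
            for block in ("baseline", "tdcs", "post"):
                shift = block_gain[block] * delta[polarity][i]
                for lag, is_short, n_trials in lag_plan:
                    logit_t2 = (
                        base_short[i] + shift + learn if is_short else base_long[i]
                    )
                    cell_rows.append(
                        (
                            lab, session, polarity, block, lag, n_trials,
                            _expit(base_t1[i]), _expit(logit_t2),
                        )
                    )
    cells = pd.DataFrame(
        cell_rows,
        columns=[
            "participant", "session", "polarity", "block", "lag",
            "n_trials", "p_t1", "p_t2_given_t1",
        ],
    )
    clip_mask = (cells[["p_t1", "p_t2_given_t1"]] < _PROB_CLIP[0]) | (
        cells[["p_t1", "p_t2_given_t1"]] > _PROB_CLIP[1]
    )
    n_clipped = int(clip_mask.to_numpy().sum())
    if n_clipped:
        log.info("clipped %d latent cell probabilities into [%.2f, %.2f]",
                 n_clipped, *_PROB_CLIP)
    cells[["p_t1", "p_t2_given_t1"]] = cells[["p_t1", "p_t2_given_t1"]].clip(*_PROB_CLIP)

    counts = cells["n_trials"].to_numpy()
    total = int(counts.sum())
    rep = np.repeat(np.arange(len(cells)), counts)
    p_t1 = cells["p_t1"].to_numpy()[rep]
    p_t2 = cells["p_t2_given_t1"].to_numpy()[rep]
    t1 = (rng.random(total) < p_t1).astype(int)
    t2 = (rng.random(total) < p_t2).astype(int)

    trials = pd.DataFrame(
        {
            "participant": cells["participant"].to_numpy()[rep],
            "session": cells["session"].to_numpy()[rep],
            "polarity": cells["polarity"].to_numpy()[rep],
            "block": cells["block"].to_numpy()[rep],
            "lag": cells["lag"].to_numpy()[rep],
            "t1_correct": t1,
            "t2_correct": t2,
        }
    )
    truth = GroundTruth(
        participants=participants, cells=cells, n_clipped=n_clipped, config=config
    )
    return trials, truth


# --------------------------------------------------------------------------
# measurement-noise attenuation


def _recover_r_cell_level(
    config: SimConfig, trials_short: int, trials_long: int, rng: np.random.Generator
) -> float:
    """Partial correlation recovered from one cell-count-level replicate.

    Draws the latent model exactly as :func:`simulate_study` but samples
    binomial cell counts directly (no per-trial rows), computes AB-magnitude
    change scores, and returns the anodal-vs-cathodal partial correlation
    (session order partialled out). Used for Monte-Carlo attenuation curves
    where per-trial tables would be needlessly slow.
    """
    from .correlation import partial_correlation

    n = config.n_participants
    n_first = int(round(config.order_balance * n))
    anodal_first = np.zeros(n, dtype=bool)
    anodal_first[rng.permutation(n)[:n_first]] = True
    base_short = rng.normal(_logit(config.t2g1_short_mean), config.between_subject_sd, n)
    base_long = rng.normal(_logit(config.t2g1_long_mean), config.between_subject_sd, n)
    base_t1 = rng.normal(_logit(config.t1_acc_mean), config.between_subject_sd, n)
    eff = _bivariate_effects(config.effect_sd, config.rho_true, n, rng)

    p_t1 = np.clip(_expit(base_t1), *_PROB_CLIP)
    deltas = {}
    for j, pol in enumerate(("anodal", "cathodal")):
        session2 = anodal_first if pol == "cathodal" else ~anodal_first
        learn = config.learning_effect * session2
        ab = {}
        for block, gain in (("baseline", 0.0), ("tdcs", 1.0)):
            p_short = np.clip(_expit(base_short + gain * eff[:, j] + learn), *_PROB_CLIP)
            p_long = np.clip(_expit(base_long), *_PROB_CLIP)
            acc = {}
            for name, p2, t in (("short", p_short, trials_short), ("long", p_long, trials_long)):
                n_t1c = rng.binomial(t, p_t1)
                n_t1c = np.maximum(n_t1c, 1)  # p_t1 >= .5 here; guard only
                acc[name] = rng.binomial(n_t1c, p2) / n_t1c
            ab[block] = acc["long"] - acc["short"]
        deltas[pol] = ab["tdcs"] - ab["baseline"]
    est = partial_correlation(
        deltas["anodal"], deltas["cathodal"], anodal_first.astype(float)
    )
    return est.r


def attenuation_curve(
    config: SimConfig,
    trial_grid: list[int],
    n_reps: int = 300,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expected recovered correlation vs trials per cell.

    Binomial trial noise attenuates the observable anodal/cathodal
    correlation below ``rho_true``; this Monte-Carlo curve shows the
    recovery improving with trial count. Long-lag trial counts are scaled
    proportionally to the short-lag grid. Returns a table with columns
    ``trials_short, trials_long, mean_r, sd_r, n_reps``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ratio = config.trials_long / config.trials_short
    rows = []
    for t_short in trial_grid:
        t_long = max(1, int(round(t_short * ratio)))
        rs = np.array(
            [_recover_r_cell_level(config, t_short, t_long, rng) for _ in range(n_reps)]
        )
        rows.append(
            dict(trials_short=t_short, trials_long=t_long,
                 mean_r=float(rs.mean()), sd_r=float(rs.std(ddof=1)), n_reps=n_reps)
        )
    return pd.DataFrame(rows)
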