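"""Trial-level attentional-blink pipeline.

Turns raw RSVP trial tables into per-participant AB-magnitude change scores:

1. :func:`read_trials` — load and validate a delimited trial table;
2. :func:`cell_accuracy` — T1 accuracy and T2|T1 accuracy per
   participant x session x polarity x block x lag cell;
3. :func:`exclude_low_t1` — drop participants whose first-session mean T1
   accuracy falls below a cutoff (default 63%, the study's engagement
   criterion);
4. :func:`harmonize_lags` — map the older three-lag design (lags 2/4/10)
   onto the two-lag design (3/8) by averaging the two short lags;
5. :func:`ab_magnitude` / :func:`ab_change_scores` — AB magnitude
   (long-lag minus short-lag T2|T1 accuracy) per block, then change scores
   versus the no-stimulation baseline block.

T2|T1 accuracy is the proportion of trials with T2 reported correctly among
the trials where T1 was reported correctly; cells with no T1-correct trials
carry an explicit NaN (never an imputed zero) and downstream steps refuse to
consume them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "LAG_DIALECTS",
    "TRIAL_COLUMNS",
    "read_trials",
    "validate_trials",
    "cell_accuracy",
    "exclude_low_t1",
    "harmonize_lags",
    "ab_magnitude",
    "ab_change_scores",
]

#: admissible T1->T2 lags per study generation
LAG_DIALECTS: dict[str, frozenset[int]] = {
    "study1": frozenset({2, 4, 10}),
    "study2": frozenset({3, 8}),
}

TRIAL_COLUMNS = [
    "participant",
    "session",
    "polarity",
    "block",
    "lag",
    "t1_correct",
    "t2_correct",
]

_POLARITIES = ("anodal", "cathodal")
_BLOCKS = ("baseline", "tdcs", "post")

CELL_KEYS = ["participant", "session", "polarity", "block", "lag"]


class TrialFormatError(ValueError):
    """Structural problem with a trial table (missing columns etc.)."""


class TrialValidationError(ValueError):
    """Row-level problem with a trial table (bad labels, bad lags ...)."""


def _bad_rows(mask: pd.Series, what: str, values: pd.Series) -> str:
    rows = mask[mask].index.tolist()
    shown = ", ".join(str(r) for r in rows[:10])
    offending = sorted(set(values[mask].tolist()))
    return (
        f"{mask.sum()} row(s) with {what} {offending} "
        f"(row index {shown}{'...' if len(rows) > 10 else ''})"
    )


def validate_trials(trials: pd.DataFrame, dialect: str = "study2") -> pd.DataFrame:
    """Validate a trial table in place and return it with canonical dtypes.

    Checks column presence, label domains, the lag dialect, and that every
    (participant, polarity) pair maps to exactly one session (the crossover
    structure). Raises :class:`TrialFormatError` or
    :class:`TrialValidationError` with offending values and row indices.
    """
    if dialect not in LAG_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(LAG_DIALECTS)}")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialFormatError(f"missing column(s): {missing}")
    t = trials.loc[:, TRIAL_COLUMNS].copy()

    problems = []
    sess = pd.to_numeric(t["session"], errors="coerce")
    bad = ~sess.isin([1, 2])
    if bad.any():
        problems.append(_bad_rows(bad, "session outside {1, 2}:", t["session"]))
    bad = ~t["polarity"].isin(_POLARITIES)
    if bad.any():
        problems.append(_bad_rows(bad, "unknown polarity", t["polarity"]))
    bad = ~t["block"].isin(_BLOCKS)
    if bad.any():
        problems.append(_bad_rows(bad, "unknown block", t["block"]))
    lag = pd.to_numeric(t["lag"], errors="coerce")
    bad = ~lag.isin(sorted(LAG_DIALECTS[dialect]))
    if bad.any():
        problems.append(
            _bad_rows(bad, f"lag outside the {dialect} set {sorted(LAG_DIALECTS[dialect])}:", t["lag"])
        )
    for col in ("t1_correct", "t2_correct"):
        v = pd.to_numeric(t[col], errors="coerce")
        bad = ~v.isin([0, 1])
        if bad.any():
            problems.append(_bad_rows(bad, f"non-boolean {col}", t[col]))
    if problems:
        raise TrialValidationError("; ".join(problems))

    t["session"] = sess.astype(int)
    t["lag"] = lag.astype(int)
    t["t1_correct"] = pd.to_numeric(t["t1_correct"]).astype(int)
    t["t2_correct"] = pd.to_numeric(t["t2_correct"]).astype(int)

    # crossover: one session per (participant, polarity)
    nsess = t.groupby(["participant", "polarity"], sort=False)["session"].nunique()
    multi = nsess[nsess > 1]
    if not multi.empty:
        pairs = ", ".join(f"{p}/{pol}" for p, pol in multi.index[:10])
        raise TrialValidationError(
            f"(participant, polarity) pairs observed in more than one session: {pairs}"
        )
    return t


def read_trials(path, dialect: str = "study2") -> pd.DataFrame:
    """Read a comma-delimited trial table (header row, booleans as 0/1)."""
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrialFormatError(f"cannot read trial table {path}: {exc}") from exc
    return validate_trials(raw, dialect)


def cell_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-cell trial counts and accuracies.

    Returns one row per observed participant x session x polarity x block x
    lag cell with ``n_trials``, ``n_t1_correct``, ``t1_acc``,
    ``n_t2_correct_given_t1`` and ``t2_given_t1_acc``. T2 is only ever
    counted on T1-correct trials; a cell with no T1-correct trials gets
    ``t2_given_t1_acc = NaN``.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    g = trials.assign(
        t2_and_t1=trials["t1_correct"] * trials["t2_correct"]
    ).groupby(CELL_KEYS, sort=True, as_index=False)
    acc = g.agg(
        n_trials=("t1_correct", "size"),
        n_t1_correct=("t1_correct", "sum"),
        n_t2_correct_given_t1=("t2_and_t1", "sum"),
    )
    acc["t1_acc"] = acc["n_t1_correct"] / acc["n_trials"]
    with np.errstate(invalid="ignore", divide="ignore"):
        acc["t2_given_t1_acc"] = np.where(
            acc["n_t1_correct"] > 0,
            acc["n_t2_correct_given_t1"] / acc["n_t1_correct"].replace(0, np.nan),
            np.nan,
        )
    return acc


def exclude_low_t1(
    acc: pd.DataFrame, cutoff: float = 0.63
) -> tuple[list, list]:
    """Split participants on first-session mean T1 accuracy.

    The mean is trial-weighted over all session-1 blocks and lags
    (total T1-correct / total trials). A participant is excluded iff the
    mean is strictly below ``cutoff``; exactly at the cutoff is retained.

    Returns ``(retained, excluded)`` as sorted lists of participant labels.
    """
    participants = acc["participant"].unique()
    s1 = acc[acc["session"] == 1]
    have_s1 = set(s1["participant"])
    orphans = sorted(set(participants) - have_s1)
    if orphans:
        raise ValueError(
            f"participant(s) with no session-1 trials: {orphans}"
        )
    means = (
        s1.groupby("participant")[["n_t1_correct", "n_trials"]].sum()
    )
    mean_t1 = means["n_t1_correct"] / means["n_trials"]
    excluded = sorted(mean_t1.index[mean_t1 < cutoff])
    retained = sorted(mean_t1.index[mean_t1 >= cutoff])
    return retained, excluded


def harmonize_lags(acc: pd.DataFrame, dialect: str) -> pd.DataFrame:
    """Map a study-1 accuracy table (lags 2/4/10) onto the lag-3/8 scheme.

    The two short lags are averaged without trial weighting — the synthetic
    "lag 3" T2|T1 accuracy is the plain mean of the lag-2 and lag-4
    accuracies — and lag 10 is relabelled lag 8. A study-2 table is returned
    unchanged (as a copy). Any cell missing lag 2 or lag 4 raises.

    The synthetic lag-3 rows carry summed trial counts for bookkeeping, but
    their ``t2_given_t1_acc`` is the unweighted mean, so the count-ratio
    identity deliberately does not hold for those rows.
    """
    if dialect == "study2":
        return acc.copy()
    if dialect != "study1":
        raise ValueError(f"unknown dialect {dialect!r}")

    group_keys = ["participant", "session", "polarity", "block"]
    out_rows = []
    for keys, cell in acc.groupby(group_keys, sort=True):
        lags = set(cell["lag"])
        if not {2, 4} <= lags:
            missing = sorted({2, 4} - lags)
            raise ValueError(
                f"cell {dict(zip(group_keys, keys))} missing lag(s) {missing}; "
                "cannot form the lag-3 proxy"
            )
        short = cell.set_index("lag")
        proxy = {
            **dict(zip(group_keys, keys)),
            "lag": 3,
            "n_trials": int(short.loc[2, "n_trials"] + short.loc[4, "n_trials"]),
            "n_t1_correct": int(
                short.loc[2, "n_t1_correct"] + short.loc[4, "n_t1_correct"]
            ),
            "n_t2_correct_given_t1": int(
                short.loc[2, "n_t2_correct_given_t1"]
                + short.loc[4, "n_t2_correct_given_t1"]
            ),
        }
        proxy["t1_acc"] = proxy["n_t1_correct"] / proxy["n_trials"]
        proxy["t2_given_t1_acc"] = float(
            (short.loc[2, "t2_given_t1_acc"] + short.loc[4, "t2_given_t1_acc"]) / 2.0
        )
        out_rows.append(proxy)
        if 10 in lags:
            long_row = short.loc[10].to_dict()
            long_row.update(dict(zip(group_keys, keys)), lag=8)
            out_rows.append(long_row)
    out = pd.DataFrame(out_rows, columns=list(acc.columns))
    return out.sort_values(CELL_KEYS).reset_index(drop=True)


def _short_long(acc: pd.DataFrame) -> tuple[int, int]:
    lags = sorted(set(acc["lag"]))
    if len(lags) != 2:
        raise ValueError(
            f"AB magnitude needs exactly one short and one long lag; got lags {lags} "
            "(harmonize study-1 tables first)"
        )
    return lags[0], lags[1]


def ab_magnitude(acc: pd.DataFrame) -> pd.DataFrame:
    """AB magnitude per participant x session x polarity x block.

    AB magnitude is T2|T1 accuracy at the long lag minus T2|T1 accuracy at
    the short lag. NaN accuracies (cells without T1-correct trials) raise
    rather than propagate silently.
    """
    short, long_ = _short_long(acc)
    bad = acc["t2_given_t1_acc"].isna()
    if bad.any():
        cells = acc.loc[bad, CELL_KEYS].to_dict("records")[:5]
        raise ValueError(
            f"undefined T2|T1 accuracy (no T1-correct trials) in cell(s): {cells}"
        )
    wide = acc.pivot_table(
        index=["participant", "session", "polarity", "block"],
        columns="lag",
        values="t2_given_t1_acc",
        aggfunc="first",
    )
    for lag in (short, long_):
        if lag not in wide.columns:
            raise ValueError(f"lag {lag} absent from accuracy table")
    missing = wide.index[wide[[short, long_]].isna().any(axis=1)]
    if len(missing):
        raise ValueError(
            f"cells missing a lag for AB magnitude: {missing.tolist()[:5]}"
        )
    out = wide.reset_index()
    out["ab_magnitude"] = out[long_] - out[short]
    return out[["participant", "session", "polarity", "block", "ab_magnitude"]]


def ab_change_scores(acc: pd.DataFrame) -> pd.DataFrame:
    """Per participant x polarity AB-magnitude change scores.

    ``delta_tdcs = AB(tdcs) - AB(baseline)`` and
    ``delta_post = AB(post) - AB(baseline)``; ``session_order`` is
    ``anodal_first`` when the participant's anodal session was session 1.
    Every retained participant must contribute all three blocks for both
    polarities.
    """
    ab = ab_magnitude(acc)
    wide = ab.pivot_table(
        index=["participant", "polarity"],
        columns="block",
        values="ab_magnitude",
        aggfunc="first",
    )
    for blk in _BLOCKS:
        if blk not in wide.columns:
            wide[blk] = np.nan
    incomplete = wide.index[wide[list(_BLOCKS)].isna().any(axis=1)]
    if len(incomplete):
        detail = [
            {
                "participant": p,
                "polarity": pol,
                "missing": [b for b in _BLOCKS if pd.isna(wide.loc[(p, pol), b])],
            }
            for p, pol in incomplete[:5]
        ]
        raise ValueError(f"missing block(s) for change scores: {detail}")

    # session order from the anodal session index
    sess = (
        ab[ab["polarity"] == "anodal"]
        .groupby("participant")["session"]
        .first()
    )
    both = wide.reset_index().groupby("participant")["polarity"].nunique()
    lacking = sorted(both.index[both < 2].tolist() + sorted(set(wide.reset_index()["participant"]) - set(sess.index)))
    if lacking:
        raise ValueError(f"participant(s) missing a polarity: {sorted(set(lacking))}")

    out = wide.reset_index()
    out["delta_tdcs"] = out["tdcs"] - out["baseline"]
    out["delta_post"] = out["post"] - out["baseline"]
    out["session_order"] = out["participant"].map(
        lambda p: "anodal_first" if sess[p] == 1 else "cathodal_first"
    )
    return out[
        ["participant", "polarity", "delta_tdcs", "delta_post", "session_order"]
    ].sort_values(["participant", "polarity"]).reset_index(drop=True)
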