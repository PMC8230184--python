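"""Empirical-level analysis: RT filtering, cell summaries and the six
canonical reference-back cost measures.

Cost conventions
----------------
Each measure contrasts the cells that demand a working-memory control
operation against matched baseline cells:

* updating:      no-switch/reference  -  no-switch/comparison
* comparison:    no-switch/different  -  no-switch/same
* switching:     switch               -  no-switch
* gate-opening:  reference/switch     -  reference/no-switch
* gate-closing:  comparison/switch    -  comparison/no-switch
* substitution:  (reference/different - reference/same)
                 - (comparison/different - comparison/same)

RT costs are slow-minus-fast differences of mean correct RT (seconds);
accuracy costs are reported on the easy-minus-hard orientation so a
positive value always means poorer performance in the costly condition.
Costs are computed per subject and then averaged (subject as the unit
of analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CELLS

RT_FAST = 0.150  #: lower RT bound, seconds; strictly faster is excluded
RT_SLOW = 3.0    #: upper RT bound, seconds; strictly slower is excluded

COST_NAMES = (
    "updating", "comparison", "switching", "gate-opening", "gate-closing", "substitution",
)


def contrast_weights(name: str) -> dict:
    """Per-cell weights (cell index -> weight) defining a cost contrast.

    Weights are normalized so that each side of a simple contrast
    averages its constituent cells.  Applied to mean RT they give the
    RT cost; applied with a sign flip to accuracy they give the
    accuracy cost; applied to cell-varying model parameters they give
    the parameter effect.
    """
    if name == "updating":
        plus = [c for c in CELLS if c.switching == "no-switch" and c.updating == "reference"]
        minus = [c for c in CELLS if c.switching == "no-switch" and c.updating == "comparison"]
    elif name == "comparison":
        plus = [c for c in CELLS if c.switching == "no-switch" and c.match == "different"]
        minus = [c for c in CELLS if c.switching == "no-switch" and c.match == "same"]
    elif name == "switching":
        plus = [c for c in CELLS if c.switching == "switch"]
        minus = [c for c in CELLS if c.switching == "no-switch"]
    elif name == "gate-opening":
        plus = [c for c in CELLS if c.updating == "reference" and c.switching == "switch"]
        minus = [c for c in CELLS if c.updating == "reference" and c.switching == "no-switch"]
    elif name == "gate-closing":
        plus = [c for c in CELLS if c.updating == "comparison" and c.switching == "switch"]
        minus = [c for c in CELLS if c.updating == "comparison" and c.switching == "no-switch"]
    elif name == "substitution":
        w: dict = {}
        for c in CELLS:
            sign = (1 if c.match == "different" else -1) * (1 if c.updating == "reference" else -1)
            w[c.index] = sign / 2.0
        return w
    else:
        raise KeyError(f"unknown cost measure {name!r}")
    w = {}
    for c in plus:
        w[c.index] = 1.0 / len(plus)
    for c in minus:
        w[c.index] = -1.0 / len(minus)
    return w


class EmptyDataError(ValueError):
    pass


def clean(trials: pd.DataFrame):
    """Drop block-initial trials and outlier RTs; report removals by reason.

    Keeps responded trials with RT in [0.150 s, 3 s] (bounds inclusive:
    only strictly faster/slower RTs are outliers).
    """
    first = trials["cell"] == 0
    responded = trials[~first]
    fast = responded["rt"] < RT_FAST
    slow = responded["rt"] > RT_SLOW
    kept = responded[~fast & ~slow]
    if len(kept) == 0:
        raise EmptyDataError("no responded trials remain after filtering")
    report = {
        "n_input": int(len(trials)),
        "n_first_trial": int(first.sum()),
        "n_fast": int(fast.sum()),
        "n_slow": int(slow.sum()),
        "n_kept": int(len(kept)),
    }
    return kept.reset_index(drop=True), report


def _quantiles(rts: np.ndarray, qs=(0.1, 0.5, 0.9)):
    if rts.size == 0:
        return [np.nan] * len(qs)
    return list(np.quantile(rts, qs))


def cell_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-cell accuracy, mean correct RT and RT quantiles.

    Returns one row per subject x cell with columns ``n``, ``accuracy``,
    ``mean_rt`` (correct trials), and 0.1/0.5/0.9 RT quantiles for
    correct and error responses.  Cells with no trials are absent.
    """
    rows = []
    for (subject, cell), sub in trials.groupby(["subject", "cell"]):
        if cell == 0:
            continue
        correct = sub["correct"].to_numpy(dtype=bool)
        rt = sub["rt"].to_numpy(dtype=float)
        qc = _quantiles(rt[correct])
        qe = _quantiles(rt[~correct])
        rows.append(
            {
                "subject": subject,
                "cell": cell,
                "n": len(sub),
                "accuracy": float(correct.mean()),
                "mean_rt": float(rt[correct].mean()) if correct.any() else np.nan,
                "rt_q10_correct": qc[0], "rt_q50_correct": qc[1], "rt_q90_correct": qc[2],
                "rt_q10_error": qe[0], "rt_q50_error": qe[1], "rt_q90_error": qe[2],
            }
        )
    return pd.DataFrame(rows)


def group_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Unweighted subject average of per-cell summaries."""
    return (
        summaries.drop(columns=["subject"]).groupby("cell").mean(numeric_only=True).reset_index()
    )


def canonical_costs(summaries: pd.DataFrame) -> pd.DataFrame:
    """The six canonical cost measures from per-subject cell summaries.

    Computes each cost per subject then averages; returns one row per
    measure with ``rt_cost`` (s), ``acc_cost`` (proportion) and the cell
    weights used.  A positive value means poorer performance in the
    costly condition.
    """
    per_subject = per_subject_costs(summaries)
    group = (
        per_subject.groupby("measure", sort=False)[["rt_cost", "acc_cost"]].mean().reset_index()
    )
    return group


def per_subject_costs(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-subject cost measures (long format: subject, measure, costs)."""
    rows = []
    for subject, sub in summaries.groupby("subject"):
        rt = dict(zip(sub["cell"], sub["mean_rt"]))
        acc = dict(zip(sub["cell"], sub["accuracy"]))
        for name in COST_NAMES:
            w = contrast_weights(name)
            missing = [c for c in w if c not in rt]
            if missing:
                raise KeyError(
                    f"subject {subject}: cells {missing} required by {name!r} are missing"
                )
            rt_cost = sum(wi * rt[c] for c, wi in w.items())
            acc_cost = -sum(wi * acc[c] for c, wi in w.items())
            rows.append(
                {"subject": subject, "measure": name, "rt_cost": rt_cost, "acc_cost": acc_cost}
            )
    return pd.DataFrame(rows)
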