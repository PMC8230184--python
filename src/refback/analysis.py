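"""Posterior inference on cost effects, predictive checks, parameter
recovery, and individual-difference correlations.

Effect posteriors apply the same cell algebra as the behavioral cost
measures to the group-level (hyper-mean) draws of a cell-varying
parameter: for every retained draw, the contrast (e.g. reference minus
comparison for the updating effect) is computed, giving the posterior
distribution of the effect.  Each effect is summarized by its posterior
mean M, SD, standardized magnitude Z = M/SD, an equal-tailed 95%
credible interval, and a one-tailed Bayesian p — the posterior
probability that the effect does not run in its most-sampled direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import wfpt
from .costs import (
    COST_NAMES, canonical_costs, cell_summary, clean, contrast_weights, group_summary,
)
from .design import CELLS
from .model import HierarchicalDDMResults, ReferenceBackDDM
from .sampler import SamplerConfig
from .simulate import GroupModel, simulate_dataset

#: parameters whose effects are contrasted across design cells
EFFECT_PARAMETERS = ("v", "t0")


@dataclass
class EffectSummary:
    """Posterior summary of one cost contrast on one parameter."""

    name: str
    parameter: str
    draws: np.ndarray = field(repr=False)
    mean: float = 0.0
    sd: float = 0.0
    z: float = 0.0
    p: float = 0.5
    ci: tuple = (0.0, 0.0)

    @classmethod
    def from_draws(cls, name: str, parameter: str, draws: np.ndarray) -> "EffectSummary":
        draws = np.asarray(draws, dtype=float).ravel()
        m = float(draws.mean())
        s = float(draws.std())
        n = draws.size
        n_pos = float(np.sum(draws > 0))
        n_neg = float(np.sum(draws < 0))
        n_zero = n - n_pos - n_neg
        p = min(n_pos + 0.5 * n_zero, n_neg + 0.5 * n_zero) / n
        p = min(max(p, 0.5 / n), 0.5)   # keep p in (0, 0.5]
        z = m / s if s > 0 else 0.0
        ci = tuple(np.percentile(draws, [2.5, 97.5]))
        return cls(name=name, parameter=parameter, draws=draws,
                   mean=m, sd=s, z=z, p=p, ci=ci)


def _hyper_mean_draws(results: HierarchicalDDMResults) -> dict:
    flat = results.mu_draws.reshape(-1, results.spec.n_params)
    return {name: flat[:, i] for i, name in enumerate(results.param_names)}


def effect_posterior(
    results: HierarchicalDDMResults,
    contrast_name: str,
    parameter: str,
    rhat_tol: float | None = 1.1,
) -> EffectSummary:
    """Posterior distribution of a cost contrast on a model parameter.

    ``parameter`` is ``'v'`` (drift magnitude), ``'t0'`` (non-decision
    time) or ``'a'`` (threshold; only the reference-vs-comparison
    contrast exists, requested as ``contrast_name='updating'``).
    Refuses unconverged chains unless ``rhat_tol`` is None.
    """
    results.check_converged(rhat_tol)
    draws = _hyper_mean_draws(results)
    spec = results.spec
    if parameter == "a":
        if contrast_name != "updating":
            raise KeyError("threshold effects are defined only for the updating contrast")
        if spec.variant == "threshold-fixed":
            raise KeyError("threshold is constant in the threshold-fixed variant")
        eff = draws["a_ref"] - draws["a_comp"]
        return EffectSummary.from_draws("updating", "a", eff)
    if parameter not in EFFECT_PARAMETERS:
        raise KeyError(f"unknown effect parameter {parameter!r}")
    w = contrast_weights(contrast_name)
    labels = {c.index: c.label for c in CELLS}
    single = f"{parameter}" in draws  # constrained variant: contrast is exactly zero
    eff = None
    for cell_idx, wi in w.items():
        name = parameter if single else f"{parameter}_{labels[cell_idx]}"
        term = wi * draws[name]
        eff = term if eff is None else eff + term
    return EffectSummary.from_draws(contrast_name, parameter, eff)


def all_effects(results: HierarchicalDDMResults, rhat_tol: float | None = 1.1) -> pd.DataFrame:
    """Summary table of the six contrasts for drift and non-decision time,
    plus the reference-vs-comparison threshold effect."""
    rows = []
    for parameter in EFFECT_PARAMETERS:
        for name in COST_NAMES:
            e = effect_posterior(results, name, parameter, rhat_tol)
            rows.append({"parameter": parameter, "measure": name, "mean": e.mean,
                         "sd": e.sd, "z": e.z, "p": e.p,
                         "ci_2.5%": e.ci[0], "ci_97.5%": e.ci[1]})
    try:
        e = effect_posterior(results, "updating", "a", rhat_tol)
        rows.append({"parameter": "a", "measure": "updating", "mean": e.mean,
                     "sd": e.sd, "z": e.z, "p": e.p,
                     "ci_2.5%": e.ci[0], "ci_97.5%": e.ci[1]})
    except KeyError:
        pass
    return pd.DataFrame(rows)


def _simulate_from_params(trials: pd.DataFrame, spec, theta: np.ndarray,
                          rng: np.random.Generator, dt: float) -> pd.DataFrame:
    """Re-simulate choices/RTs for an observed trial design at ``theta``."""
    sim = trials.copy()
    v_signed, a_c, t0_c, z, sz, sv = spec.expand(theta)
    cells = sim["cell"].to_numpy()
    rt = np.array(sim["rt"], dtype=float)
    resp = np.array(sim["response"], dtype=object)
    for c in range(1, 9):
        m = cells == c
        n_c = int(m.sum())
        if n_c == 0:
            continue
        up, rts = wfpt._sim_kernel(
            n_c, v_signed[c - 1], a_c[c - 1], z, sz, sv, t0_c[c - 1],
            dt, int(rng.integers(0, 2**31)),
        )
        rt[m] = rts
        resp[m] = np.where(up, "same", "different")
    sim["rt"] = rt
    sim["response"] = resp
    sim["correct"] = (sim["response"] == sim["match"]) & (sim["cell"] > 0)
    return sim


STAT_COLUMNS = ["accuracy", "mean_rt", "rt_q10_correct", "rt_q50_correct", "rt_q90_correct",
                "rt_q10_error", "rt_q50_error", "rt_q90_error"]


@dataclass
class PredictiveSummary:
    """Posterior-predictive cell summaries and cost effects."""

    cells: pd.DataFrame      # per cell x statistic: observed, predicted mean + 95% CI
    costs: pd.DataFrame      # per measure x (rt_cost, acc_cost): observed, predicted + CI
    n_reps: int

    def coverage(self, stats=("accuracy", "rt_q10_correct", "rt_q50_correct",
                              "rt_q90_correct")) -> float:
        """Fraction of observed cell statistics inside the 95% predictive CI."""
        sub = self.cells[self.cells["statistic"].isin(stats)].dropna(subset=["observed"])
        inside = (sub["observed"] >= sub["ci_2.5%"]) & (sub["observed"] <= sub["ci_97.5%"])
        return float(inside.mean())


def posterior_predictive(
    results: HierarchicalDDMResults,
    n_reps: int = 100,
    seed: int = 0,
    dt: float = 5e-4,
    rhat_tol: float | None = 1.1,
) -> PredictiveSummary:
    """Posterior-predictive check against the fitted dataset.

    For each of ``n_reps`` replicates, one retained posterior draw is
    selected per subject, that subject's observed trial sequence is
    re-simulated, and group-level cell summaries and the six cost
    effects are computed through the same code path as the observed
    statistics.
    """
    results.check_converged(rhat_tol)
    rng = np.random.default_rng(seed)
    model = results.model
    trials = model.trials
    obs_sum = cell_summary(trials)
    obs_group = group_summary(obs_sum)
    obs_costs = canonical_costs(obs_sum)

    rep_cells = []
    rep_costs = []
    for rep in range(n_reps):
        thetas = results.draw_subject_sample(rng)
        sims = []
        for si, s in enumerate(results.subjects):
            sub = trials[trials["subject"] == s]
            sims.append(_simulate_from_params(sub, results.spec, thetas[si], rng, dt))
        sim_all = pd.concat(sims, ignore_index=True)
        sim_sum = cell_summary(sim_all)
        g = group_summary(sim_sum)
        g["rep"] = rep
        rep_cells.append(g)
        c = canonical_costs(sim_sum)
        c["rep"] = rep
        rep_costs.append(c)
    rep_cells = pd.concat(rep_cells, ignore_index=True)
    rep_costs = pd.concat(rep_costs, ignore_index=True)

    cell_rows = []
    for cell in range(1, 9):
        obs_row = obs_group[obs_group["cell"] == cell]
        pred = rep_cells[rep_cells["cell"] == cell]
        for stat in STAT_COLUMNS:
            vals = pred[stat].dropna().to_numpy()
            if vals.size == 0:
                continue
            lo, hi = np.percentile(vals, [2.5, 97.5])
            cell_rows.append(
                {
                    "cell": cell, "statistic": stat,
                    "observed": float(obs_row[stat].iloc[0]) if len(obs_row) else np.nan,
                    "predicted": float(vals.mean()),
                    "ci_2.5%": float(lo), "ci_97.5%": float(hi),
                }
            )
    cost_rows = []
    for name in COST_NAMES:
        for col in ("rt_cost", "acc_cost"):
            vals = rep_costs.loc[rep_costs["measure"] == name, col].to_numpy()
            lo, hi = np.percentile(vals, [2.5, 97.5])
            cost_rows.append(
                {
                    "measure": name, "kind": col,
                    "observed": float(obs_costs.loc[obs_costs["measure"] == name, col].iloc[0]),
                    "predicted": float(vals.mean()),
                    "ci_2.5%": float(lo), "ci_97.5%": float(hi),
                }
            )
    return PredictiveSummary(
        cells=pd.DataFrame(cell_rows), costs=pd.DataFrame(cost_rows), n_reps=n_reps
    )


def recovery_study(
    group: GroupModel,
    n_subjects: int = 20,
    n_trials: int = 512,
    n_blocks: int = 4,
    seed: int = 0,
    config: SamplerConfig | None = None,
    rhat_tol: float | None = None,
):
    """Simulate from known parameters, refit hierarchically, and score recovery.

    Returns ``(report, results, dataset)`` where ``report`` is a dict
    holding the per-parameter true-vs-recovered table (``table``) and,
    per parameter family, the pooled Pearson r and mean signed error.
    """
    from .model import HierarchicalReferenceBackDDM

    dataset = simulate_dataset(group, n_subjects, n_trials, n_blocks, seed=seed)
    trials, _ = clean(dataset.trials)
    model = HierarchicalReferenceBackDDM(trials, variant=group.spec.variant)
    results = model.fit(config=config, seed=seed + 1)
    if rhat_tol is not None:
        results.check_converged(rhat_tol)

    means = results.subject_means()
    sds = results.subject_sds()
    rows = []
    for s in results.subjects:
        truth = dataset.params_of(s)
        for i, name in enumerate(group.spec.param_names):
            rows.append(
                {
                    "subject": s, "parameter": name, "family": group.spec.family[i],
                    "true": truth[i], "recovered": means.loc[s, name],
                    "posterior_sd": sds.loc[s, name],
                }
            )
    table = pd.DataFrame(rows)
    by_family = {}
    for fam, sub in table.groupby("family"):
        r = pearsonr(sub["true"], sub["recovered"])[0] if len(sub) > 2 else np.nan
        by_family[fam] = {
            "pearson_r": float(r),
            "mean_signed_error": float((sub["recovered"] - sub["true"]).mean()),
            "rmse": float(np.sqrt(((sub["recovered"] - sub["true"]) ** 2).mean())),
        }
    report = {"table": table, "by_family": by_family}
    return report, results, dataset


def map_effect_table(trials: pd.DataFrame, variant: str = "top",
                     config: SamplerConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-subject MAP parameter effects from non-hierarchical fits.

    Fits each subject separately (no shrinkage) and evaluates the six
    contrasts on drift and non-decision time plus the threshold shift at
    the MAP draw.  Returns subjects x effect columns
    (``<param>_<measure>``).
    """
    subjects = sorted(trials["subject"].unique())
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(len(subjects))
    labels = {c.index: c.label for c in CELLS}
    rows = []
    for si, s in enumerate(subjects):
        sub = trials[trials["subject"] == s]
        res = ReferenceBackDDM(sub, variant=variant).fit(
            config=config, seed=int(seeds[si].generate_state(1)[0] % 2**31)
        )
        mp = res.map_estimate()
        row = {"subject": s}
        for parameter in EFFECT_PARAMETERS:
            for name in COST_NAMES:
                w = contrast_weights(name)
                row[f"{parameter}_{name}"] = sum(
                    wi * mp[f"{parameter}_{labels[c]}"] for c, wi in w.items()
                )
        if variant != "threshold-fixed":
            row["a_updating"] = mp["a_ref"] - mp["a_comp"]
        rows.append(row)
    return pd.DataFrame(rows)


def individual_difference_correlations(
    map_effects: pd.DataFrame,
    empirical_costs: pd.DataFrame,
    outlier_z: float | None = 3.0,
):
    """Pearson correlations between MAP parameter effects and behavioral costs.

    ``map_effects`` is subjects x effect columns (from
    :func:`map_effect_table`); ``empirical_costs`` the per-subject cost
    table (long format with ``measure``, ``rt_cost``, ``acc_cost``).
    Cost values more than ``outlier_z`` SDs from the mean are excluded
    pairwise (set to None to disable).  Returns ``(corr, excluded)``:
    the full augmented correlation matrix and a log of exclusions.
    """
    wide = empirical_costs.pivot(index="subject", columns="measure")
    wide.columns = [f"{kind}_{measure}" for kind, measure in wide.columns]
    joined = map_effects.set_index("subject").join(wide, how="inner")
    if len(joined) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    excluded = []
    cols = list(joined.columns)
    mask = pd.DataFrame(True, index=joined.index, columns=cols)
    if outlier_z is not None:
        for col in cols:
            if not (col.startswith("rt_cost") or col.startswith("acc_cost")):
                continue
            x = joined[col]
            zs = (x - x.mean()) / x.std()
            bad = zs.abs() > outlier_z
            for s in joined.index[bad]:
                excluded.append({"subject": s, "variable": col, "z": float(zs[s])})
            mask.loc[bad, col] = False
    corr = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            m = mask[ci] & mask[cj]
            if m.sum() >= 3:
                r = pearsonr(joined.loc[m, ci], joined.loc[m, cj])[0]
            else:
                r = np.nan
            corr.loc[ci, cj] = corr.loc[cj, ci] = r
    return corr, pd.DataFrame(excluded)
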