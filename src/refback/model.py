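"""Bayesian diffusion models of reference-back performance.

The public surface follows the model/results idiom: build a model
object from a trial table, call :meth:`fit` to run DE-MCMC, and work
with the returned results object (posterior draws, summaries, DIC,
MAP estimates, posterior predictions).

``ReferenceBackDDM`` fits one subject non-hierarchically.
``HierarchicalReferenceBackDDM`` fits a multi-subject dataset with
truncated-normal population distributions over every free parameter,
shrinking subject estimates toward the group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from . import wfpt
from .costs import clean
from .design import CELLS, ModelSpec, VARIANTS, annotate_trials, build_model_spec
from .priors import Priors
from .sampler import SamplerConfig, de_mcmc, hierarchical_de_mcmc


class ConvergenceError(RuntimeError):
    """Raised when downstream analysis is attempted on unconverged chains."""


def _pack(trials: pd.DataFrame):
    rt = np.ascontiguousarray(trials["rt"], dtype=float)
    upper = np.ascontiguousarray(trials["response"] == "same")
    cell = np.ascontiguousarray(trials["cell"].to_numpy() - 1, dtype=np.int64)
    if np.any(cell < 0) or np.any(cell > 7):
        raise ValueError("trials must be annotated and exclude block-initial trials")
    return rt, upper, cell


def _loglike_packed(theta, spec: ModelSpec, rt, upper, cell) -> float:
    v_signed, a_c, t0_c, z, sz, sv = spec.expand(theta)
    return wfpt._loglik_cells(
        rt, upper, cell, v_signed, a_c, t0_c, z, sz, sv,
        wfpt.SERIES_EPS, wfpt.DENSITY_FLOOR,
    )


def ez_start(trials: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Moment-based start values (EZ-diffusion style) for the sampler.

    Per design cell, accuracy, mean and variance of correct RT give
    closed-form drift, boundary and non-decision time on the s = 1
    scale; these seed the chains and are never used as estimates.
    """
    v_cell = np.full(8, 1.5)
    a_cell = np.full(8, 1.2)
    t0_cell = np.full(8, 0.3)
    min_rt = float(trials["rt"].min())
    for c in range(1, 9):
        sub = trials[trials["cell"] == c]
        if len(sub) < 5:
            continue
        n = len(sub)
        pc = float(sub["correct"].mean())
        pc = min(max(pc, 0.5 + 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))
        rts = sub.loc[sub["correct"], "rt"].to_numpy(dtype=float)
        if rts.size < 3:
            continue
        mrt, vrt = float(rts.mean()), float(rts.var())
        if vrt <= 1e-6:
            continue
        L = np.log(pc / (1 - pc))
        x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
        if x <= 0:
            continue
        v = x**0.25
        a = L / v
        y = -v * a
        mdt = (a / (2 * v)) * (1 - np.exp(y)) / (1 + np.exp(y))
        v_cell[c - 1] = np.clip(v, 0.2, 8.0)
        a_cell[c - 1] = np.clip(a, 0.3, 4.0)
        t0_cell[c - 1] = np.clip(mrt - mdt, 0.06, 0.95)
    t0_cell = np.minimum(t0_cell, max(min_rt * 0.9, 0.06))
    theta = np.empty(spec.n_params)
    for i, name in enumerate(spec.param_names):
        fam = spec.family[i]
        if fam == "v":
            cells = [c for c in range(8) if spec.v_idx[c] == i]
            theta[i] = float(np.mean(v_cell[cells]))
        elif fam == "a":
            cells = [c for c in range(8) if spec.a_idx[c] == i]
            theta[i] = float(np.mean(a_cell[cells]))
        elif fam == "t0":
            cells = [c for c in range(8) if spec.t0_idx[c] == i]
            theta[i] = float(np.mean(t0_cell[cells]))
        elif fam == "z":
            theta[i] = 0.5
        elif fam == "sz":
            theta[i] = 0.1
        elif fam == "sv":
            theta[i] = 0.5
    return np.clip(theta, spec.lower + 1e-3, spec.upper - 1e-3)


def _rhat_table(draws: np.ndarray, names) -> pd.Series:
    """Split R-hat per parameter from (chain, draw, param) draws."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({n: draws[:, :, i] for i, n in enumerate(names)})
        r = az.rhat(ds)
    return pd.Series({n: float(r[n].values) for n in names})


class ReferenceBackDDM:
    """Non-hierarchical diffusion model for one subject's trials.

    Parameters
    ----------
    trials : DataFrame
        Cleaned, annotated trials of a single subject (columns ``rt``,
        ``response``, ``cell``; cell indices 1..8).
    variant : str
        One of ``top``, ``threshold-fixed``, ``drift-fixed``,
        ``ndt-fixed``.
    priors : Priors, optional
        Truncated-normal priors; defaults to the package priors.
    """

    def __init__(self, trials: pd.DataFrame, variant: str = "top", priors: Priors | None = None):
        self.spec = build_model_spec(variant)
        self.priors = priors or Priors.default(self.spec)
        self.trials = trials.reset_index(drop=True)
        self._rt, self._upper, self._cell = _pack(self.trials)
        cells_needed = set(np.unique(self._cell) + 1)
        if len(cells_needed) < 8:
            warnings.warn(f"cells {sorted(set(range(1, 9)) - cells_needed)} have no trials")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, subject=None, variant: str = "top",
        priors: Priors | None = None,
    ) -> "ReferenceBackDDM":
        """Build from a raw trial table: annotate, filter, select subject."""
        if subject is not None:
            df = df[df["subject"] == subject]
        if "cell" not in df.columns:
            df = annotate_trials(df)
        df, _ = clean(df)
        return cls(df, variant=variant, priors=priors)

    def loglike(self, theta) -> float:
        """Data log-likelihood at ``theta`` (density floored at 1e-10)."""
        return _loglike_packed(np.asarray(theta, float), self.spec, self._rt, self._upper, self._cell)

    def logposterior(self, theta) -> float:
        theta = np.asarray(theta, dtype=float)
        if not self.spec.in_support(theta):
            return -np.inf
        lp = self.priors.logpdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.loglike(theta)

    def start_params(self) -> np.ndarray:
        return ez_start(self.trials, self.spec)

    def fit(self, config: SamplerConfig | None = None, seed: int = 0) -> "DDMResults":
        """Run DE-MCMC and return posterior results."""
        config = config or SamplerConfig()
        rng = np.random.default_rng(seed)
        d = self.spec.n_params
        K = config.chains_for(d)
        theta0 = self.start_params()
        x0 = np.empty((K, d))
        for k in range(K):
            for attempt in range(200):
                cand = theta0 * (1 + 0.05 * rng.standard_normal(d)) + 0.01 * rng.standard_normal(d)
                cand = np.clip(cand, self.spec.lower + 1e-4, self.spec.upper - 1e-4)
                if np.isfinite(self.logposterior(cand)):
                    x0[k] = cand
                    break
            else:
                raise RuntimeError("could not find finite start points")
        draws, logp = de_mcmc(self.logposterior, x0, config, rng)
        return DDMResults(self, draws, logp, config, seed)


class DDMResults:
    """Posterior draws and diagnostics from a non-hierarchical fit."""

    def __init__(self, model, draws, logpost, config, seed):
        self.model = model
        self.spec = model.spec
        self.draws = draws            # (chain, draw, param)
        self.logpost = logpost        # (chain, draw)
        self.config = config
        self.seed = seed
        flat = draws.reshape(-1, draws.shape[-1])
        self.params = pd.Series(flat.mean(axis=0), index=self.spec.param_names)
        self.bse = pd.Series(flat.std(axis=0), index=self.spec.param_names)

    @property
    def param_names(self):
        return self.spec.param_names

    def rhat(self) -> pd.Series:
        return _rhat_table(self.draws, self.param_names)

    @property
    def converged(self) -> bool:
        return bool(self.rhat().max() <= 1.1)

    def map_estimate(self) -> pd.Series:
        """Retained draw with the highest log posterior."""
        k, j = np.unravel_index(np.argmax(self.logpost), self.logpost.shape)
        return pd.Series(self.draws[k, j], index=self.param_names)

    def _deviance(self, theta) -> float:
        return -2.0 * self.model.loglike(theta)

    def dic(self, max_draws: int = 2000):
        """(DIC, mean deviance, pD) with pD = Dbar - D(posterior mean)."""
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        if flat.shape[0] > max_draws:
            idx = np.linspace(0, flat.shape[0] - 1, max_draws).astype(int)
            flat = flat[idx]
        dbar = float(np.mean([self._deviance(th) for th in flat]))
        theta_bar = flat.mean(axis=0)
        if not self.spec.in_support(theta_bar):
            warnings.warn("posterior mean outside support; using highest-posterior draw")
            theta_bar = self.map_estimate().to_numpy()
        d_hat = self._deviance(theta_bar)
        pd_eff = dbar - d_hat
        return dbar + pd_eff, dbar, pd_eff

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, 95% CI, R-hat."""
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "mean": self.params,
                "sd": self.bse,
                "ci_2.5%": lo,
                "ci_97.5%": hi,
                "rhat": self.rhat(),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value, log_post."""
        K, n, d = self.draws.shape
        rows = []
        for k in range(K):
            for i, name in enumerate(self.param_names):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": k,
                            "iteration": np.arange(n),
                            "parameter": name,
                            "value": self.draws[k, :, i],
                            "log_posterior": self.logpost[k],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


class HierarchicalReferenceBackDDM:
    """Hierarchical diffusion model for a multi-subject trial table."""

    def __init__(self, trials: pd.DataFrame, variant: str = "top", priors: Priors | None = None):
        self.spec = build_model_spec(variant)
        self.priors = priors or Priors.default(self.spec)
        self.trials = trials.reset_index(drop=True)
        self.subjects = sorted(self.trials["subject"].unique())
        if len(self.subjects) < 2:
            raise ValueError("hierarchical fitting requires >= 2 subjects")
        self._packed = []
        self._sub_trials = []
        for s in self.subjects:
            sub = self.trials[self.trials["subject"] == s]
            self._sub_trials.append(sub)
            self._packed.append(_pack(sub))

    @classmethod
    def from_dataframe(cls, df, variant="top", priors=None):
        if "cell" not in df.columns:
            df = annotate_trials(df)
        df, _ = clean(df)
        return cls(df, variant=variant, priors=priors)

    def loglike_subject(self, s: int, theta) -> float:
        rt, upper, cell = self._packed[s]
        return _loglike_packed(np.asarray(theta, float), self.spec, rt, upper, cell)

    def fit(self, config: SamplerConfig | None = None, seed: int = 0) -> "HierarchicalDDMResults":
        config = config or SamplerConfig()
        rng = np.random.default_rng(seed)
        theta0 = np.vstack(
            [ez_start(sub, self.spec) for sub in self._sub_trials]
        )
        out = hierarchical_de_mcmc(
            self.loglike_subject,
            theta0,
            self.priors,
            config,
            rng,
            support_ok=self.spec.in_support,
        )
        return HierarchicalDDMResults(self, out, config, seed)


class HierarchicalDDMResults:
    """Group- and subject-level posterior draws from a hierarchical fit."""

    def __init__(self, model, out, config, seed):
        self.model = model
        self.spec = model.spec
        self.subjects = model.subjects
        self.mu_draws = out["mu"]          # (chain, draw, param)
        self.sd_draws = out["sd"]          # (chain, draw, param)
        self.subject_draws = out["theta"]  # (chain, draw, subject, param)
        self.loglik_draws = out["loglik"]  # (chain, draw, subject)
        self.config = config
        self.seed = seed
        flat_mu = self.mu_draws.reshape(-1, self.spec.n_params)
        self.params = pd.Series(flat_mu.mean(axis=0), index=self.spec.param_names)
        self.bse = pd.Series(flat_mu.std(axis=0), index=self.spec.param_names)

    @property
    def param_names(self):
        return self.spec.param_names

    def rhat(self) -> pd.Series:
        return _rhat_table(self.mu_draws, self.param_names)

    @property
    def converged(self) -> bool:
        return bool(self.rhat().max() <= 1.1)

    def check_converged(self, rhat_tol: float | None = 1.1) -> None:
        if rhat_tol is None:
            return
        r = self.rhat()
        if r.max() > rhat_tol:
            raise ConvergenceError(
                f"max R-hat {r.max():.3f} exceeds {rhat_tol}; pass rhat_tol=None to override"
            )

    def subject_means(self) -> pd.DataFrame:
        """Posterior-mean subject-level parameters (subjects x params)."""
        m = self.subject_draws.reshape(-1, len(self.subjects), self.spec.n_params).mean(axis=0)
        return pd.DataFrame(m, index=self.subjects, columns=self.param_names)

    def subject_sds(self) -> pd.DataFrame:
        s = self.subject_draws.reshape(-1, len(self.subjects), self.spec.n_params).std(axis=0)
        return pd.DataFrame(s, index=self.subjects, columns=self.param_names)

    def summary(self) -> pd.DataFrame:
        """Group-level posterior summary (hyper-means and hyper-SDs)."""
        flat_mu = self.mu_draws.reshape(-1, self.spec.n_params)
        flat_sd = self.sd_draws.reshape(-1, self.spec.n_params)
        lo, hi = np.percentile(flat_mu, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "hyper_mean": self.params,
                "hyper_mean_sd": self.bse,
                "ci_2.5%": lo,
                "ci_97.5%": hi,
                "hyper_sd": flat_sd.mean(axis=0),
                "rhat": self.rhat(),
            }
        )

    def dic(self):
        """DIC on subject-summed deviance, pD = Dbar - D(posterior means)."""
        total_ll = self.loglik_draws.sum(axis=2)   # (chain, draw)
        dbar = float(np.mean(-2.0 * total_ll))
        means = self.subject_means().to_numpy()
        d_hat = 0.0
        for s in range(len(self.subjects)):
            th = means[s]
            if not self.spec.in_support(th):
                k, j = np.unravel_index(
                    np.argmax(self.loglik_draws[:, :, s]), self.loglik_draws[:, :, s].shape
                )
                th = self.subject_draws[k, j, s]
            d_hat += -2.0 * self.model.loglike_subject(s, th)
        pd_eff = dbar - d_hat
        return dbar + pd_eff, dbar, pd_eff

    def draw_subject_sample(self, rng: np.random.Generator) -> np.ndarray:
        """One retained joint draw index per subject -> (S, d) array."""
        K, n, S, d = self.subject_draws.shape
        out = np.empty((S, d))
        for s in range(S):
            k = rng.integers(K)
            j = rng.integers(n)
            out[s] = self.subject_draws[k, j, s]
        return out


def select_per_subject(
    trials: pd.DataFrame,
    variants=VARIANTS,
    priors_by_variant: dict | None = None,
    config: SamplerConfig | None = None,
    seed: int = 0,
):
    """Fit every variant per subject non-hierarchically and rank by DIC.

    Returns ``(table, per_subject)``: a model-selection table with one
    row per variant (free-parameter count, summed DIC difference from
    the top model, number and percentage of subjects preferring it) and
    the per-subject DIC long table.
    """
    subjects = sorted(trials["subject"].unique())
    if len(variants) < 2:
        raise ValueError("need at least two variants to compare")
    ss = np.random.SeedSequence(seed)
    fit_seeds = ss.spawn(len(subjects) * len(variants))
    rows = []
    i = 0
    for s in subjects:
        sub = trials[trials["subject"] == s]
        for variant in variants:
            model = ReferenceBackDDM(sub, variant=variant,
                                     priors=(priors_by_variant or {}).get(variant))
            res = model.fit(config=config, seed=int(fit_seeds[i].generate_state(1)[0] % 2**31))
            dic, dbar, pd_eff = res.dic()
            rows.append(
                {
                    "subject": s, "variant": variant, "dic": dic,
                    "mean_deviance": dbar, "pd": pd_eff,
                    "n_params": model.spec.n_params,
                }
            )
            i += 1
    per_subject = pd.DataFrame(rows)
    pref = per_subject.loc[per_subject.groupby("subject")["dic"].idxmin()]
    counts = pref["variant"].value_counts()
    summed = per_subject.groupby("variant")["dic"].sum()
    top_ref = summed.get("top", summed.min())
    table = pd.DataFrame(
        {
            "variant": list(variants),
            "n_params": [build_model_spec(v).n_params for v in variants],
            "dic_diff_from_top": [summed[v] - top_ref for v in variants],
            "n_preferring": [int(counts.get(v, 0)) for v in variants],
        }
    )
    table["pct_preferring"] = 100.0 * table["n_preferring"] / len(subjects)
    return table, per_subject
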