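"""Synthetic reference-back data from known diffusion parameters.

Sessions follow the task design: stimuli (X/O) and frame colors
(red/blue) drawn independently and equiprobably, except the first trial
of each block which is always red-framed, provides the initial referent
and receives no response.  The default session is 512 trials in 4
blocks.  Subject-level parameters are drawn from truncated-normal
population distributions; choices and RTs come from the diffusion
simulator, so the generative process matches the model being fitted.

The default group configuration plants the qualitative parameter
pattern this task is known for — lower drift magnitudes and longer
non-decision times in cells requiring working-memory control, and a
higher threshold in updating (reference) mode — at plausible mid-range
values.  These are fixture-generating defaults, not empirical estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import wfpt
from .design import CELLS, ModelSpec, annotate_trials, build_model_spec

#: default hyper-means: baseline value and per-factor shifts, by family
DEFAULT_EFFECTS = {
    "v": {"base": 3.0, "reference": -0.5, "different": -0.9, "switch": -0.3},
    "t0": {"base": 0.30, "reference": 0.05, "different": 0.02, "switch": 0.02},
    "a": {"base": 1.15, "reference": 0.15},
    "z": {"base": 0.5},
    "sz": {"base": 0.12},
    "sv": {"base": 0.8},
}

#: default hyper-SDs of the population distributions, by family
DEFAULT_HYPER_SD = {"v": 0.4, "a": 0.12, "z": 0.04, "t0": 0.04, "sv": 0.25, "sz": 0.04}


@dataclass
class GroupModel:
    """Truncated-normal population distributions for every free parameter."""

    spec: ModelSpec
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if np.any(self.sd < 0):
            raise ValueError("hyper-SD must be >= 0")
        if len(self.mean) != self.spec.n_params or len(self.sd) != self.spec.n_params:
            raise ValueError("group model must cover every free parameter")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.spec.param_names, "hyper_mean": self.mean, "hyper_sd": self.sd}
        )


def default_group(
    spec: ModelSpec | None = None,
    effects: dict | None = None,
    hyper_sd: dict | None = None,
    null: bool = False,
) -> GroupModel:
    """Build a GroupModel from baseline values and per-factor shifts.

    ``effects[family]`` holds a ``base`` value plus optional additive
    shifts keyed ``reference``/``different``/``switch`` applied to cells
    at those factor levels.  ``null=True`` drops all shifts (no
    condition effects), which is the calibration configuration.
    """
    spec = spec or build_model_spec("top")
    eff = {k: dict(v) for k, v in DEFAULT_EFFECTS.items()}
    for k, v in (effects or {}).items():
        eff.setdefault(k, {}).update(v)
    sds = dict(DEFAULT_HYPER_SD)
    sds.update(hyper_sd or {})
    if null:
        for fam in eff:
            eff[fam] = {"base": eff[fam]["base"]}

    mean = np.empty(spec.n_params)
    sd = np.empty(spec.n_params)
    cell_by_name = {}
    for c in CELLS:
        cell_by_name[f"v_{c.label}"] = c
        cell_by_name[f"t0_{c.label}"] = c
    for i, (name, fam) in enumerate(zip(spec.param_names, spec.family)):
        e = eff[fam]
        val = e["base"]
        c = cell_by_name.get(name)
        if c is not None:
            if c.updating == "reference":
                val += e.get("reference", 0.0)
            if c.match == "different":
                val += e.get("different", 0.0)
            if c.switching == "switch":
                val += e.get("switch", 0.0)
        elif name == "a_ref":
            val += e.get("reference", 0.0)
        mean[i] = val
        sd[i] = sds[fam]
    # keep the population comfortably inside support
    mean = np.clip(mean, spec.lower + 1e-3, spec.upper - 1e-3)
    return GroupModel(spec=spec, mean=mean, sd=sd)


def draw_subject_params(group: GroupModel, rng: np.random.Generator) -> np.ndarray:
    """One subject's parameter vector from the population distributions."""
    spec = group.spec
    out = np.empty(spec.n_params)
    for i in range(spec.n_params):
        m, s = group.mean[i], group.sd[i]
        lo, hi = spec.lower[i], spec.upper[i]
        if s == 0:
            out[i] = m
        else:
            a, b = (lo - m) / s, (hi - m) / s
            out[i] = truncnorm.ppf(rng.uniform(), a, b, loc=m, scale=s)
    # enforce the joint start-point constraint by shrinking sz if needed
    z, sz = out[spec.z_idx], out[spec.sz_idx]
    limit = 2 * min(z, 1 - z) - 1e-3
    if sz >= limit:
        out[spec.sz_idx] = max(limit, 0.0)
    return out


def generate_sequence(n_trials: int, n_blocks: int, rng: np.random.Generator):
    """Frames and stimuli for one session; first trial per block is red."""
    if n_blocks < 1 or n_trials < n_blocks or n_trials % n_blocks != 0:
        raise ValueError("n_trials must divide evenly into n_blocks blocks")
    per_block = n_trials // n_blocks
    frames = np.where(rng.uniform(size=n_trials) < 0.5, "red", "blue").astype(object)
    stimuli = np.where(rng.uniform(size=n_trials) < 0.5, "X", "O").astype(object)
    blocks = np.repeat(np.arange(1, n_blocks + 1), per_block)
    trial = np.tile(np.arange(1, per_block + 1), n_blocks)
    frames[trial == 1] = "red"
    return pd.DataFrame({"block": blocks, "trial": trial, "frame": frames, "stimulus": stimuli})


@dataclass
class SimulatedDataset:
    """Synthetic trials plus the generating truth."""

    trials: pd.DataFrame
    subject_params: pd.DataFrame  # long: subject, parameter, value
    group: GroupModel
    seed: int

    def params_of(self, subject) -> np.ndarray:
        sub = self.subject_params[self.subject_params["subject"] == subject]
        order = {n: i for i, n in enumerate(self.group.spec.param_names)}
        sub = sub.sort_values("parameter", key=lambda s: s.map(order))
        return sub["value"].to_numpy()


def simulate_dataset(
    group: GroupModel,
    n_subjects: int,
    n_trials: int = 512,
    n_blocks: int = 4,
    seed: int = 0,
    outlier_rate: float = 0.0,
    dt: float = 1e-4,
) -> SimulatedDataset:
    """Simulate a full multi-subject reference-back study.

    Optionally contaminates responded trials at ``outlier_rate`` with
    uniform fast guesses (0–150 ms) and slow stragglers (3–6 s), half
    each, to exercise the RT filter.
    """
    spec = group.spec
    ss = np.random.SeedSequence(seed)
    sub_seeds = ss.spawn(n_subjects)
    frames_all = []
    params_rows = []
    for s in range(1, n_subjects + 1):
        rng = np.random.default_rng(sub_seeds[s - 1])
        theta = draw_subject_params(group, rng)
        for name, val in zip(spec.param_names, theta):
            params_rows.append({"subject": s, "parameter": name, "value": val})
        sess = generate_sequence(n_trials, n_blocks, rng)
        sess.insert(0, "subject", s)
        sess = annotate_trials(sess)
        v_signed, a_c, t0_c, z, sz, sv = spec.expand(theta)
        rt = np.full(len(sess), np.nan)
        resp = np.full(len(sess), "none", dtype=object)
        cells = sess["cell"].to_numpy()
        for c in range(1, 9):
            m = cells == c
            n_c = int(m.sum())
            if n_c == 0:
                continue
            kern_seed = int(rng.integers(0, 2**31))
            up, rts = wfpt._sim_kernel(
                n_c, v_signed[c - 1], a_c[c - 1], z, sz, sv, t0_c[c - 1], dt, kern_seed
            )
            rt[m] = rts
            resp[m] = np.where(up, "same", "different")
        if outlier_rate > 0:
            responded = np.flatnonzero(cells > 0)
            n_out = rng.binomial(responded.size, outlier_rate)
            pick = rng.choice(responded, size=n_out, replace=False)
            fast = rng.uniform(size=n_out) < 0.5
            rt[pick[fast]] = rng.uniform(0.0, 0.149, size=int(fast.sum()))
            rt[pick[~fast]] = rng.uniform(3.001, 6.0, size=int((~fast).sum()))
        sess["response"] = resp
        sess["rt"] = rt
        sess["correct"] = (sess["response"] == sess["match"]) & (sess["cell"] > 0)
        frames_all.append(sess)
    trials = pd.concat(frames_all, ignore_index=True)
    return SimulatedDataset(
        trials=trials,
        subject_params=pd.DataFrame(params_rows),
        group=group,
        seed=seed,
    )
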