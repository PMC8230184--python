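"""Reference-back task structure: trial annotation and model variants.

The reference-back task crosses three binary factors: updating (red
"reference" frames cue a working-memory update, blue "comparison" frames
cue maintenance), switching (whether the frame color changed from the
previous trial), and match (whether the probe equals the current WM
referent).  The first trial of each block establishes the initial
referent with a red frame and requires no response; the probe on every
other trial is compared against the referent *before* any update takes
place, and the referent is then replaced on red-frame trials only.

Four nested model variants are defined over the resulting 8 design
cells: the "top" model lets drift rate and non-decision time vary over
every cell and boundary separation over updating mode; the constrained
variants remove the threshold, drift, or non-decision-time effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UPDATING = ("reference", "comparison")
SWITCHING = ("no-switch", "switch")
MATCH = ("same", "different")

VARIANTS = ("top", "threshold-fixed", "drift-fixed", "ndt-fixed")

#: support bounds for each parameter family (diffusion coefficient s = 1)
SUPPORT = {
    "v": (0.0, 10.0),
    "a": (0.1, 5.0),
    "z": (0.05, 0.95),
    "t0": (0.05, 1.0),
    "sv": (0.0, 5.0),
    "sz": (0.0, 0.9),
}


class SequenceError(ValueError):
    """Raised when a trial sequence violates the task structure."""


@dataclass(frozen=True)
class DesignCell:
    """One cell of the 2 (updating) x 2 (switching) x 2 (match) design."""

    updating: str
    switching: str
    match: str
    index: int

    @property
    def label(self) -> str:
        u = "ref" if self.updating == "reference" else "comp"
        s = "ns" if self.switching == "no-switch" else "sw"
        m = "same" if self.match == "same" else "diff"
        return f"{u}_{s}_{m}"


def cell_of(updating: str, switching: str, match: str) -> DesignCell:
    """Deterministic bijection from factor levels to cell index 1..8."""
    if updating not in UPDATING:
        raise ValueError(f"unknown updating level {updating!r}")
    if switching not in SWITCHING:
        raise ValueError(f"unknown switching level {switching!r}")
    if match not in MATCH:
        raise ValueError(f"unknown match level {match!r}")
    index = (
        1
        + 4 * UPDATING.index(updating)
        + 2 * SWITCHING.index(switching)
        + MATCH.index(match)
    )
    return DesignCell(updating, switching, match, index)


#: all 8 cells in index order
CELLS = tuple(
    cell_of(u, s, m) for u in UPDATING for s in SWITCHING for m in MATCH
)


def cell_from_index(index: int) -> DesignCell:
    if not 1 <= index <= 8:
        raise ValueError(f"cell index must be 1..8, got {index}")
    return CELLS[index - 1]


def annotate_sequence(frames, stimuli):
    """Annotate one block of (frame color, stimulus) pairs.

    Returns a list of dicts with keys ``referent`` (referent before the
    trial), ``updating``, ``switching``, ``match`` (the correct answer)
    and ``cell`` (a :class:`DesignCell`, or None for the excluded first
    trial).  The referent comparison precedes the update.
    """
    frames = list(frames)
    stimuli = list(stimuli)
    if len(frames) == 0:
        raise SequenceError("empty block")
    if len(frames) != len(stimuli):
        raise SequenceError("frames and stimuli must have equal length")
    if frames[0] != "red":
        raise SequenceError("first trial of a block must be red-framed")
    out = [
        {"referent": None, "updating": "reference", "switching": None,
         "match": None, "cell": None}
    ]
    referent = stimuli[0]
    for k in range(1, len(frames)):
        updating = "reference" if frames[k] == "red" else "comparison"
        switching = "no-switch" if frames[k] == frames[k - 1] else "switch"
        match = "same" if stimuli[k] == referent else "different"
        out.append(
            {
                "referent": referent,
                "updating": updating,
                "switching": switching,
                "match": match,
                "cell": cell_of(updating, switching, match),
            }
        )
        if frames[k] == "red":
            referent = stimuli[k]
    return out


def annotate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Annotate a trial table (columns subject, block, trial, stimulus, frame).

    Adds ``referent``, ``updating``, ``switching``, ``match`` and ``cell``
    (index 1..8; 0 marks the excluded block-initial trial).  Rows must be
    ordered by trial within block.
    """
    df = df.copy()
    referent = np.empty(len(df), dtype=object)
    updating = np.empty(len(df), dtype=object)
    switching = np.empty(len(df), dtype=object)
    match = np.empty(len(df), dtype=object)
    cell = np.zeros(len(df), dtype=int)
    for (_, _), idx in df.groupby(["subject", "block"], sort=False).groups.items():
        sub = df.loc[idx]
        ann = annotate_sequence(sub["frame"].tolist(), sub["stimulus"].tolist())
        for pos, (i, a) in enumerate(zip(idx, ann)):
            referent[df.index.get_loc(i)] = a["referent"]
            updating[df.index.get_loc(i)] = a["updating"]
            switching[df.index.get_loc(i)] = a["switching"]
            match[df.index.get_loc(i)] = a["match"]
            cell[df.index.get_loc(i)] = a["cell"].index if a["cell"] else 0
    df["referent"] = referent
    df["updating"] = updating
    df["switching"] = switching
    df["match"] = match
    df["cell"] = cell
    if "response" in df.columns:
        df["correct"] = (df["response"] == df["match"]) & (df["cell"] > 0)
    return df


@dataclass
class ModelSpec:
    """Map from (parameter family x design cell) to free-parameter indices.

    ``theta`` vectors are ordered as ``param_names``; ``v_idx``/``a_idx``/
    ``t0_idx`` give, for each 0-based cell, the index into theta of the
    parameter used by that cell.  Drift parameters are magnitudes toward
    the correct response: the signed drift passed to the likelihood is
    positive in "same" cells (upper boundary = "same") and negative in
    "different" cells.
    """

    variant: str
    param_names: list
    lower: np.ndarray
    upper: np.ndarray
    v_idx: np.ndarray
    a_idx: np.ndarray
    t0_idx: np.ndarray
    z_idx: int
    sz_idx: int
    sv_idx: int
    family: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def expand(self, theta: np.ndarray):
        """Per-cell arrays (v_signed, a, t0) plus scalars (z, sz, sv)."""
        theta = np.asarray(theta, dtype=float)
        sign = np.array([1.0 if c.match == "same" else -1.0 for c in CELLS])
        v_signed = sign * theta[self.v_idx]
        return (
            v_signed,
            theta[self.a_idx],
            theta[self.t0_idx],
            theta[self.z_idx],
            theta[self.sz_idx],
            theta[self.sv_idx],
        )

    def in_support(self, theta: np.ndarray) -> bool:
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= self.lower) or np.any(theta >= self.upper):
            return False
        z, sz = theta[self.z_idx], theta[self.sz_idx]
        return z - sz / 2 > 0 and z + sz / 2 < 1


def build_model_spec(variant: str) -> ModelSpec:
    """Construct one of the four factorial model variants.

    Free-parameter counts are 21 (top), 20 (threshold-fixed), and 14
    (drift-fixed and ndt-fixed).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    names: list = []
    family: list = []
    lower: list = []
    upper: list = []

    def add(name, fam):
        names.append(name)
        family.append(fam)
        lo, hi = SUPPORT[fam]
        lower.append(lo)
        upper.append(hi)
        return len(names) - 1

    if variant == "drift-fixed":
        i = add("v", "v")
        v_idx = np.full(8, i)
    else:
        v_idx = np.array([add(f"v_{c.label}", "v") for c in CELLS])

    if variant == "threshold-fixed":
        i = add("a", "a")
        a_idx = np.full(8, i)
    else:
        a_ref = add("a_ref", "a")
        a_comp = add("a_comp", "a")
        a_idx = np.array([a_ref if c.updating == "reference" else a_comp for c in CELLS])

    if variant == "ndt-fixed":
        i = add("t0", "t0")
        t0_idx = np.full(8, i)
    else:
        t0_idx = np.array([add(f"t0_{c.label}", "t0") for c in CELLS])

    z_idx = add("z", "z")
    sz_idx = add("sz", "sz")
    sv_idx = add("sv", "sv")

    return ModelSpec(
        variant=variant,
        param_names=names,
        lower=np.array(lower),
        upper=np.array(upper),
        v_idx=v_idx,
        a_idx=a_idx,
        t0_idx=t0_idx,
        z_idx=z_idx,
        sz_idx=sz_idx,
        sv_idx=sv_idx,
        family=family,
    )


TRIAL_COLUMNS = [
    "subject", "block", "trial", "stimulus", "frame", "response", "rt",
]


def read_trials(path) -> pd.DataFrame:
    """Read a trial table from delimited text (CSV with header)."""
    return pd.read_csv(path)


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
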