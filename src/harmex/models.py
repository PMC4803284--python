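"""The six expectancy models mapping a chord sequence to an internal fitness E.

Every model outputs E(c_tau) in [0, 1], the internal fitness ("harmonic
expectancy") of the final chord of a sequence given its context; ratings are
assumed to relate to it linearly, A = 10 * E.

Models
------
1P  pitch profile          E depends only on the final chord's root.
2P  pitch Markov           E depends on the final pitch pair (prev, cur).
1M  interval model         E depends only on the final root interval.
2M  second-order Markov    E depends on the intervals from the two preceding
                           chords to the final chord (reference fixed to c_t).
BU  Bayesian updating      A hidden tonal reference X (one of the 12 triads)
                           carries a belief distribution, updated by Bayes'
                           rule after each observed transition; E marginalizes
                           a reference-relative transition matrix T over the
                           belief.
BS  updating + switching   As BU, but the reference prior is reset (anchored
                           on the previous chord, weight kappa) whenever the
                           posterior confidence falls below a threshold theta.
                           With theta = 0 the BS model reduces to BU.

The expectancy matrix T is a 12 x 12 grid of free fitness values in [0, 1],
indexed by reference-relative chord labels: label(c | X) = interval(X, c),
0-based here (the 1-based label used in prose is this + 1).  Cells that would
describe an immediately repeated chord are excluded (stored as NaN) because
ratings of repeated chords are unstable: the diagonal for BU/BS/2P, the unison
column (and the diagonal, which implies c_{t-2} = c_{t-1}) for 2M, and the
unison entry of the 1M interval vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .chords import has_repetition, interval

__all__ = [
    "Model",
    "ModelParams",
    "BSState",
    "ExcludedTrialError",
    "excluded_mask",
    "initial_belief",
    "bu_step",
    "bs_step",
    "expectancy",
    "key_profile",
    "params_to_json",
    "params_from_json",
]

#: Likelihood floor used during belief updates; prevents all-zero posteriors
#: when the grid admits T entries of exactly 0.
LIK_EPS = 1e-12


class Model(str, Enum):
    """Closed enumeration of the six expectancy models."""

    P1 = "1P"
    P2 = "2P"
    M1 = "1M"
    M2 = "2M"
    BU = "BU"
    BS = "BS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ExcludedTrialError(ValueError):
    """Raised when a sequence touches an excluded (repeated-chord) cell."""


def excluded_mask(model: Model) -> np.ndarray:
    """Boolean mask of excluded cells for the model's parameter grid.

    Shape (12, 12) for matrix-parameterized models, (12,) for 1P/1M.
    """
    model = Model(model)
    if model is Model.P1:
        return np.zeros(12, dtype=bool)
    if model is Model.M1:
        m = np.zeros(12, dtype=bool)
        m[0] = True  # unison interval = repetition
        return m
    m = np.zeros((12, 12), dtype=bool)
    if model in (Model.P2, Model.BU, Model.BS):
        np.fill_diagonal(m, True)
    elif model is Model.M2:
        m[:, 0] = True       # j = 0 implies c_{t-1} = c_t
        np.fill_diagonal(m, True)  # i = j implies c_{t-2} = c_{t-1}
    return m


@dataclass
class ModelParams:
    """Parameter bundle for one model.

    ``T`` is a 12-vector for 1P/1M and a 12 x 12 matrix otherwise, with NaN at
    excluded cells.  ``kappa`` (initial reference weight on the first chord,
    grid 1/12) and ``theta`` (BS reset threshold, grid 0.05) apply only to the
    reference-updating models; theta is fixed to 0 for BU.
    """

    model: Model
    T: np.ndarray
    kappa: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        self.model = Model(self.model)
        self.T = np.asarray(self.T, dtype=float)
        expected = (12,) if self.model in (Model.P1, Model.M1) else (12, 12)
        if self.T.shape != expected:
            raise ValueError(f"{self.model.value}: T must have shape {expected}, got {self.T.shape}")
        mask = excluded_mask(self.model)
        vals = self.T[~mask]
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("T entries must lie in [0, 1]")
        if self.model in (Model.BU, Model.BS):
            if self.kappa is None or not 0 < self.kappa <= 1:
                raise ValueError("kappa must lie in (0, 1] for BU/BS")
            if self.model is Model.BU:
                self.theta = 0.0
            elif self.theta is None or not 0 <= self.theta <= 1:
                raise ValueError("theta must lie in [0, 1] for BS")
        else:
            self.kappa = None
            self.theta = None

    def copy(self) -> "ModelParams":
        return ModelParams(self.model, self.T.copy(), self.kappa, self.theta)


@dataclass
class BSState:
    """Belief state of the BS model: reference distribution plus the time step
    ``w`` of the most recent prior switch (w = 1 when none occurred)."""

    belief: np.ndarray
    w: int = 1


def initial_belief(c1: int, kappa: float) -> np.ndarray:
    """Initial reference distribution after hearing the first chord.

    Probability ``kappa`` that the reference equals the first chord, the
    remaining mass spread evenly over the other 11 candidates.  ``kappa`` =
    1/12 gives the uniform distribution; kappa = 1 a point mass.
    """
    if not 0 < kappa <= 1:
        raise ValueError(f"kappa must lie in (0, 1], got {kappa}")
    b = np.full(12, (1.0 - kappa) / 11.0)
    b[c1 % 12] = kappa
    return b


def _pair_likelihood(T: np.ndarray, c_prev: int, c_cur: int) -> np.ndarray:
    """Likelihood vector over the 12 references X for observing c_prev -> c_cur."""
    if c_prev == c_cur:
        raise ExcludedTrialError("immediate chord repetition touches excluded cells")
    X = np.arange(12)
    lik = T[(c_prev - X) % 12, (c_cur - X) % 12]
    return np.clip(lik, LIK_EPS, None)


def bu_step(belief: np.ndarray, c_prev: int, c_cur: int, T: np.ndarray) -> np.ndarray:
    """One Bayesian update of the reference belief: posterior ~ likelihood * prior."""
    post = _pair_likelihood(T, c_prev, c_cur) * belief
    z = post.sum()
    if z <= 0:
        raise ValueError("degenerate evidence: all-zero unnormalized posterior")
    return post / z


def bs_step(state: BSState, t: int, c_prev: int, c_cur: int, params: ModelParams) -> BSState:
    """One update of the BS model at time step ``t`` (the index of ``c_cur``).

    The provisional posterior is computed from the cumulative belief; if its
    maximum falls below ``theta`` (or at t = 2, where the cumulative prior is
    already the initial distribution anchored on c_prev), the prior is replaced
    by the initial-state form anchored on ``c_prev`` before updating, and the
    switch time ``w`` is set to ``t``.
    """
    if params.model is not Model.BS:
        raise ValueError("bs_step requires BS parameters")
    lik = _pair_likelihood(params.T, c_prev, c_cur)
    post = lik * state.belief
    post = post / post.sum()
    if t > 2 and post.max() >= params.theta:
        return BSState(post, state.w)
    reset_prior = initial_belief(c_prev, params.kappa)
    post = lik * reset_prior
    return BSState(post / post.sum(), t if t > 2 else state.w)


def _final_expectancy(T: np.ndarray, belief: np.ndarray, c_prev: int, c_cur: int) -> float:
    if c_prev == c_cur:
        raise ExcludedTrialError("immediate chord repetition touches excluded cells")
    X = np.arange(12)
    fit = T[(c_prev - X) % 12, (c_cur - X) % 12]
    return float(fit @ belief)


def expectancy(params: ModelParams, sequence) -> float:
    """Internal fitness E in [0, 1] of the final chord of ``sequence``.

    For BU/BS the belief is propagated over chords 1..tau-1 and E marginalizes
    the transition fitness of the final pair over the belief; for 2M at tau = 2
    a flat prior over the unobserved c_{t-2} averages the matrix column.
    """
    seq = tuple(int(r) % 12 for r in sequence)
    model = params.model
    if model is Model.P1:
        if len(seq) < 1:
            raise ValueError("1P needs at least one chord")
        return float(params.T[seq[-1]])
    if len(seq) < 2:
        raise ValueError(f"{model.value} needs at least two chords")
    if model is not Model.P1 and has_repetition(seq):
        raise ExcludedTrialError("sequence contains an immediate repetition")
    if model is Model.P2:
        return float(params.T[seq[-2], seq[-1]])
    if model is Model.M1:
        return float(params.T[interval(seq[-2], seq[-1])])
    if model is Model.M2:
        j = interval(seq[-2], seq[-1])
        if len(seq) == 2:
            col = params.T[:, j]
            return float(np.nanmean(col))
        i = interval(seq[-3], seq[-1])
        return float(params.T[i, j])
    # BU / BS
    T = params.T
    if model is Model.BU:
        belief = initial_belief(seq[0], params.kappa)
        for t in range(2, len(seq)):  # update on pairs (c_{t-1}, c_t), t < tau
            belief = bu_step(belief, seq[t - 2], seq[t - 1], T)
    else:
        state = BSState(initial_belief(seq[0], params.kappa), w=1)
        for t in range(2, len(seq)):
            state = bs_step(state, t, seq[t - 2], seq[t - 1], params)
        belief = state.belief
    return _final_expectancy(T, belief, seq[-2], seq[-1])


def key_profile(T: np.ndarray, reduce: str = "mean", dor_scale: bool = False) -> np.ndarray:
    """Key-profile of a BU/BS expectancy matrix.

    Marginalizes the preceding chord: for each reference-relative label j, the
    mean (default) or sum of T(i, j) over the 11 defined preceding labels i.
    The mean keeps the profile on the [0, 1] fitness scale, so ``dor_scale``
    can map it to an ideal DOR via x 10; the literal sum is exposed as well.
    """
    T = np.asarray(T, dtype=float)
    if reduce == "mean":
        prof = np.nanmean(T, axis=0)
    elif reduce == "sum":
        prof = np.nansum(T, axis=0)
    else:
        raise ValueError("reduce must be 'mean' or 'sum'")
    return prof * 10.0 if dor_scale else prof


def params_to_json(params: ModelParams) -> str:
    """Serialize parameters to JSON (NaN cells as nulls); round-trips bit-exactly."""
    T = params.T
    if T.ndim == 1:
        grid = [None if np.isnan(v) else float(v) for v in T]
    else:
        grid = [[None if np.isnan(v) else float(v) for v in row] for row in T]
    doc = {
        "model": params.model.value,
        "T": grid,
        "kappa": params.kappa,
        "theta": params.theta,
    }
    return json.dumps(doc, indent=1)


def params_from_json(text: str) -> ModelParams:
    doc = json.loads(text)
    grid = doc["T"]
    if grid and isinstance(grid[0], list):
        T = np.array([[np.nan if v is None else v for v in row] for row in grid], dtype=float)
    else:
        T = np.array([np.nan if v is None else v for v in grid], dtype=float)
    return ModelParams(Model(doc["model"]), T, doc.get("kappa"), doc.get("theta"))
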