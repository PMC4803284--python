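"""Rating->probability map, cross-entropy cost, and discrete coordinate descent.

The cost treats each trial's normalized rating A' = A/10 as a target
probability for the final chord and the model output E as the matching
Bernoulli parameter:

    h(A', E) = -[A' ln E + (1 - A') ln(1 - E)]

summed over trials.  Each term is minimized at E = A', so noiseless data
generated through A = 10 * E is fitted exactly when the generating parameters
lie on the search grid; the cost is non-negative and additive over trials.

All parameters live on discrete grids (T entries step 0.1 on [0, 1], kappa
step 1/12 on (0, 1], theta step 0.05 on [0, 1]) and are estimated by
coordinate descent: parameters are visited in random order, each compared
against its +/- one-step grid neighbours, and moved only on strict
improvement; sweeps repeat until none moves.  Random restarts guard against
local minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chords import RatingDataset, has_repetition
from .models import LIK_EPS, Model, ModelParams, excluded_mask

__all__ = [
    "T_GRID",
    "KAPPA_GRID",
    "THETA_GRID",
    "FitResult",
    "rating_to_prob",
    "cross_entropy",
    "make_evaluator",
    "coordinate_descent_fit",
]

T_GRID = np.round(np.arange(11) * 0.1, 10)          # 0.0, 0.1, ..., 1.0
KAPPA_GRID = np.arange(1, 13) / 12.0                # 1/12, ..., 1
THETA_GRID = np.round(np.arange(21) * 0.05, 10)     # 0.0, 0.05, ..., 1.0

_CE_EPS = 1e-12


def rating_to_prob(A) -> np.ndarray | float:
    """Map a DOR rating A in [1, 9] to a target probability A' = A/10."""
    arr = np.asarray(A, dtype=float)
    if np.any((arr < 1.0) | (arr > 9.0)):
        raise ValueError("ratings must lie in [1, 9]")
    out = arr / 10.0
    return float(out) if out.ndim == 0 else out


def _ce_terms(a: np.ndarray, e: np.ndarray) -> np.ndarray:
    e = np.clip(e, _CE_EPS, 1.0 - _CE_EPS)
    return -(a * np.log(e) + (1.0 - a) * np.log1p(-e))


class _Evaluator:
    """Vectorized per-model cost machinery over a fixed trial set.

    Subclasses precompute integer index structures from the sequences so that
    ``expectancies(theta)`` is a handful of numpy gathers; ``theta`` is the
    flat vector of free parameters with per-entry grids in ``grids``.
    """

    model: Model

    def __init__(self, sequences, ratings):
        self.sequences = [tuple(s) for s in sequences]
        self.targets = rating_to_prob(np.asarray(ratings, dtype=float))
        if np.asarray(self.targets).ndim == 0:
            self.targets = np.array([self.targets])

    # -- interface -------------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.grids)

    def expectancies(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cost(self, theta: np.ndarray) -> float:
        return float(_ce_terms(self.targets, self.expectancies(theta)).sum())

    def unpack(self, theta: np.ndarray) -> ModelParams:
        raise NotImplementedError

    def pack(self, params: ModelParams) -> np.ndarray:
        raise NotImplementedError


class _CellEvaluator(_Evaluator):
    """Models whose E is a single gather from the parameter vector/matrix
    (1P, 2P, 1M) or a gather plus column means (2M)."""

    def __init__(self, model: Model, sequences, ratings):
        super().__init__(sequences, ratings)
        self.model = Model(model)
        mask = excluded_mask(self.model)
        self.mask = mask
        free = np.flatnonzero(~mask.ravel())
        self.free_flat = free                      # flat indices into T
        lookup = -np.ones(mask.size, dtype=int)
        lookup[free] = np.arange(free.size)
        self.grids = [T_GRID] * free.size

        idx = []
        self._col_trials: list[int] = []           # 2M two-chord trials
        self._col_j: list[int] = []
        for n, seq in enumerate(self.sequences):
            if self.model is Model.P1:
                flat = seq[-1]
            elif self.model is Model.P2:
                flat = seq[-2] * 12 + seq[-1]
            elif self.model is Model.M1:
                flat = (seq[-1] - seq[-2]) % 12
            else:  # 2M
                j = (seq[-1] - seq[-2]) % 12
                if len(seq) == 2:
                    self._col_trials.append(n)
                    self._col_j.append(j)
                    idx.append(0)  # placeholder, overwritten below
                    continue
                i = (seq[-1] - seq[-3]) % 12
                flat = i * 12 + j
            k = lookup[flat]
            if k < 0:
                raise ValueError("sequence touches an excluded cell; filter repetitions first")
            idx.append(k)
        self.idx = np.asarray(idx, dtype=int)
        self._col_trials = np.asarray(self._col_trials, dtype=int)
        self._col_j = np.asarray(self._col_j, dtype=int)
        self._direct = np.setdiff1d(np.arange(len(self.sequences)), self._col_trials)

    def expectancies(self, theta: np.ndarray) -> np.ndarray:
        E = theta[self.idx]
        if self.model is Model.M2 and self._col_trials.size:
            Tm = np.zeros(144)
            Tm[self.free_flat] = theta
            Tm = Tm.reshape(12, 12)
            counts = (~self.mask).sum(axis=0)
            with np.errstate(invalid="ignore"):
                col_means = np.where(counts > 0, Tm.sum(axis=0) / np.maximum(counts, 1), np.nan)
            E = E.copy()
            E[self._col_trials] = col_means[self._col_j]
        return E

    def unpack(self, theta: np.ndarray) -> ModelParams:
        T = np.full(self.mask.shape, np.nan).ravel()
        T[self.free_flat] = theta
        return ModelParams(self.model, T.reshape(self.mask.shape))

    def pack(self, params: ModelParams) -> np.ndarray:
        return params.T.ravel()[self.free_flat].astype(float)


class _ReferenceEvaluator(_Evaluator):
    """BU and BS: belief propagation over the hidden reference, vectorized per
    sequence-length group across all 12 candidate references."""

    def __init__(self, model: Model, sequences, ratings):
        super().__init__(sequences, ratings)
        self.model = Model(model)
        if self.model not in (Model.BU, Model.BS):
            raise ValueError("reference evaluator requires BU or BS")
        self.mask = excluded_mask(self.model)
        free = np.flatnonzero(~self.mask.ravel())
        self.free_flat = free
        self.grids = [T_GRID] * free.size + [KAPPA_GRID]
        if self.model is Model.BS:
            self.grids = self.grids + [THETA_GRID]

        X = np.arange(12)
        self._groups = []
        for L in (2, 3, 4):
            rows = [n for n, s in enumerate(self.sequences) if len(s) == L]
            if not rows:
                continue
            seqs = np.array([self.sequences[n] for n in rows], dtype=int)
            if np.any(np.diff(seqs, axis=1) % 12 == 0):
                raise ValueError("sequence contains an immediate repetition; filter first")
            # F[n, s, X]: flat index into T for pair (c_s, c_{s+1}) under reference X
            prev = seqs[:, :-1, None]
            cur = seqs[:, 1:, None]
            F = ((prev - X) % 12) * 12 + (cur - X) % 12
            anchors = seqs[:, :-1, None] == X      # (n, L-1, 12): X == c_s
            self._groups.append((np.asarray(rows), F, anchors))

    def expectancies(self, theta: np.ndarray) -> np.ndarray:
        n_free = self.free_flat.size
        Tflat = np.full(144, np.nan)
        Tflat[self.free_flat] = theta[:n_free]
        kappa = theta[n_free]
        theta_sw = theta[n_free + 1] if self.model is Model.BS else 0.0
        off = (1.0 - kappa) / 11.0

        E = np.empty(len(self.sequences))
        for rows, F, anchors in self._groups:
            n_pairs = F.shape[1]
            B = np.where(anchors[:, 0, :], kappa, off)
            if self.model is Model.BU:
                for s in range(n_pairs - 1):
                    B = B * np.clip(Tflat[F[:, s, :]], LIK_EPS, None)
                Tfin = Tflat[F[:, -1, :]]
                E[rows] = (Tfin * B).sum(axis=1) / B.sum(axis=1)
            else:
                for s in range(n_pairs - 1):
                    lik = np.clip(Tflat[F[:, s, :]], LIK_EPS, None)
                    post = B * lik
                    post = post / post.sum(axis=1, keepdims=True)
                    if s == 0:
                        # t = 2: the prior anchored on c_1 IS the initial state
                        B = post
                        continue
                    reset = post.max(axis=1) < theta_sw
                    if np.any(reset):
                        prior_r = np.where(anchors[:, s, :], kappa, off)
                        post_r = prior_r * lik
                        post_r = post_r / post_r.sum(axis=1, keepdims=True)
                        post = np.where(reset[:, None], post_r, post)
                    B = post
                Tfin = Tflat[F[:, -1, :]]
                E[rows] = (Tfin * B).sum(axis=1)
        return E

    def unpack(self, theta: np.ndarray) -> ModelParams:
        n_free = self.free_flat.size
        T = np.full(144, np.nan)
        T[self.free_flat] = theta[:n_free]
        kappa = float(theta[n_free])
        theta_sw = float(theta[n_free + 1]) if self.model is Model.BS else 0.0
        return ModelParams(self.model, T.reshape(12, 12), kappa, theta_sw)

    def pack(self, params: ModelParams) -> np.ndarray:
        vec = list(params.T.ravel()[self.free_flat].astype(float))
        vec.append(float(params.kappa))
        if self.model is Model.BS:
            vec.append(float(params.theta))
        return np.asarray(vec)


def make_evaluator(model: Model, sequences, ratings) -> _Evaluator:
    """Build the vectorized cost evaluator for ``model`` over fixed trials."""
    model = Model(model)
    if model in (Model.BU, Model.BS):
        return _ReferenceEvaluator(model, sequences, ratings)
    return _CellEvaluator(model, sequences, ratings)


def _filtered(dataset: RatingDataset) -> RatingDataset:
    if any(has_repetition(t.sequence) for t in dataset.trials):
        return dataset.without_repetitions()
    return dataset


def cross_entropy(dataset: RatingDataset, params: ModelParams) -> float:
    """Total Bernoulli cross-entropy of the model on a dataset.

    Trials with immediate chord repetitions are excluded (their expectancy
    cells are undefined).
    """
    data = _filtered(dataset)
    ev = make_evaluator(params.model, [t.sequence for t in data], [t.rating for t in data])
    return ev.cost(ev.pack(params))


@dataclass
class FitResult:
    """Outcome of a coordinate-descent fit."""

    params: ModelParams
    cost: float
    restarts: int
    best_restart_index: int
    seed: int
    n_trials: int
    restart_costs: list[float] = field(default_factory=list)
    traces: list[list[float]] | None = None


def _descend(ev: _Evaluator, rng, reshuffle_each_sweep: bool, idx: np.ndarray):
    """Neighbour-move sweeps from grid-index state ``idx`` until a sweep is quiet."""
    grids = ev.grids
    theta = np.array([g[i] for g, i in zip(grids, idx)])
    cost = ev.cost(theta)
    trace = [cost]
    order = rng.permutation(len(grids))
    while True:
        if reshuffle_each_sweep:
            order = rng.permutation(len(grids))
        moved = False
        for p in order:
            g = grids[p]
            for step in (1, -1):
                j = idx[p] + step
                if not 0 <= j < len(g):
                    continue
                old = theta[p]
                theta[p] = g[j]
                c = ev.cost(theta)
                if c < cost:
                    cost = c
                    idx[p] = j
                    moved = True
                else:
                    theta[p] = old
        trace.append(cost)
        if not moved:
            break
    return theta, cost, trace


def coordinate_descent_fit(
    dataset: RatingDataset,
    model: Model,
    restarts: int = 100,
    seed: int = 0,
    reshuffle_each_sweep: bool = True,
    keep_traces: bool = False,
    init_params: ModelParams | None = None,
) -> FitResult:
    """Fit a model by grid coordinate descent with random restarts.

    Each restart initializes every free parameter uniformly at random on its
    grid (``init_params``, if given, seeds restart 0 instead — useful for
    nested-model comparisons), then performs neighbour-move sweeps in a
    freshly shuffled order until no parameter moves; the best terminal cost
    over all restarts wins.  Fully deterministic given ``seed``.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    data = _filtered(dataset)
    ev = make_evaluator(model, [t.sequence for t in data], [t.rating for t in data])
    if ev.n_params == 0:
        raise ValueError("model has no free parameters on this dataset")

    children = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    restart_costs: list[float] = []
    traces: list[list[float]] = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        if r == 0 and init_params is not None:
            theta0 = ev.pack(init_params)
            idx = np.array([int(np.argmin(np.abs(g - v))) for g, v in zip(ev.grids, theta0)])
        else:
            idx = np.array([rng.integers(len(g)) for g in ev.grids])
        theta, cost, trace = _descend(ev, rng, reshuffle_each_sweep, idx)
        restart_costs.append(cost)
        if keep_traces:
            traces.append(trace)
        if best is None or cost < best[1]:
            best = (theta.copy(), cost, r)

    theta, cost, r = best
    return FitResult(
        params=ev.unpack(theta),
        cost=cost,
        restarts=restarts,
        best_restart_index=r,
        seed=seed,
        n_trials=len(data),
        restart_costs=restart_costs,
        traces=traces if keep_traces else None,
    )
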