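"""Synthetic rating datasets from planted model parameters, and the
parameter-recovery study.

Ratings are generated through the linear map A = 10 * E.  Planted expectancy
values are drawn from {0.1, ..., 0.9}: an expectancy outside [0.1, 0.9] is not
expressible by any rating on the 1-9 scale, while the fitting grid itself
keeps the full 0-1 range.  The default (continuous) rating channel is
lossless, so for models without reference updating (1P, 2P, 1M, 2M) recovery
of on-grid planted parameters is exact; discretization to the 9-point scale
plus Gaussian noise is opt-in for realism studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chords import (
    RatingDataset,
    Trial,
    generate_stimulus_set,
    has_repetition,
    simulation_sequences,
)
from .fitting import KAPPA_GRID, THETA_GRID, coordinate_descent_fit, make_evaluator
from .models import Model, ModelParams, excluded_mask

__all__ = [
    "RecoveryReport",
    "sample_params",
    "simulate_ratings",
    "simulate_experiment",
    "recovery_study",
]

#: Planted expectancy values: grid values whose 10x image stays on the rating scale.
SIM_T_GRID = np.round(np.arange(1, 10) * 0.1, 10)


def sample_params(model: Model, seed=None, rng: np.random.Generator | None = None) -> ModelParams:
    """Draw every free parameter uniformly from its grid; excluded cells stay NaN.

    BU parameters always carry theta = 0 (no switching).
    """
    model = Model(model)
    if rng is None:
        rng = np.random.default_rng(seed)
    mask = excluded_mask(model)
    T = np.full(mask.shape, np.nan)
    n_free = int((~mask).sum())
    T[~mask] = rng.choice(SIM_T_GRID, size=n_free)
    kappa = theta = None
    if model in (Model.BU, Model.BS):
        kappa = float(rng.choice(KAPPA_GRID))
        theta = 0.0 if model is Model.BU else float(rng.choice(THETA_GRID))
    return ModelParams(model, T, kappa, theta)


def simulate_ratings(
    params: ModelParams,
    sequences,
    mode: str = "continuous",
    participants: int = 1,
    noise_sd: float = 0.0,
    seed=None,
    repetition_rating: float | None = None,
) -> RatingDataset:
    """Generate a rating dataset from planted parameters.

    Continuous mode emits A = 10 * E exactly (clipped to the 1-9 scale, which
    is inert for expectancies in [0.1, 0.9]); discrete mode adds Gaussian
    noise of ``noise_sd`` rating points, rounds to the 9-point scale and
    clips.  One replicate of every sequence per simulated participant.

    Models other than 1P define no expectancy for immediately repeated
    chords; such sequences are refused unless ``repetition_rating`` supplies
    a base rating for them (useful for emulating the complete behavioural
    design, where repeated-chord trials exist but are excluded from fitting).
    """
    if mode not in ("continuous", "discrete"):
        raise ValueError(f"mode must be 'continuous' or 'discrete', got {mode!r}")
    sequences = [tuple(s) for s in sequences]
    rep_mask = np.array([has_repetition(s) for s in sequences])
    if params.model is not Model.P1 and rep_mask.any() and repetition_rating is None:
        raise ValueError(
            "sequences contain immediate repetitions; pass repetition_rating or filter them"
        )
    rng = np.random.default_rng(seed)
    base = np.empty(len(sequences))
    if params.model is Model.P1:
        rep_mask[:] = False
    clean = [s for s, r in zip(sequences, rep_mask) if not r]
    if clean:
        ev = make_evaluator(params.model, clean, np.full(len(clean), 5.0))
        base[~rep_mask] = 10.0 * ev.expectancies(ev.pack(params))
    if rep_mask.any():
        base[rep_mask] = float(repetition_rating)
    trials = []
    for p in range(participants):
        pid = f"sim{p + 1:02d}"
        if mode == "continuous":
            ratings = np.clip(base, 1.0, 9.0)
        else:
            noisy = base + rng.normal(0.0, noise_sd, size=base.size)
            ratings = np.clip(np.rint(noisy), 1.0, 9.0)
        for seq, a in zip(sequences, ratings):
            trials.append(Trial(pid, seq, float(a)))
    return RatingDataset(trials, provenance=f"synthetic:{params.model.value}")


def simulate_experiment(
    params: ModelParams,
    participants: int = 15,
    mode: str = "discrete",
    noise_sd: float = 1.0,
    seed=None,
) -> RatingDataset:
    """Emulate the full behavioural design from planted parameters.

    All three conditions are enumerated (144 + 144 + 64 sequences, the random
    initial roots of the 3- and 4-chord conditions drawn from ``seed``) and
    rated by ``participants`` simulated listeners.  Repeated-chord trials of
    the 2-chord design, for which the models define no expectancy, receive a
    neutral base rating of 5.
    """
    rng = np.random.default_rng(seed)
    sequences = []
    for cond in (2, 3, 4):
        sequences.extend(generate_stimulus_set(cond, rng=rng))
    sim_seed = int(rng.integers(2**31 - 1))
    return simulate_ratings(
        params,
        sequences,
        mode=mode,
        participants=participants,
        noise_sd=noise_sd,
        seed=sim_seed,
        repetition_rating=5.0,
    )


@dataclass
class RecoveryReport:
    """Per-parameter estimation error summary over repetitions.

    ``bias`` and ``sd`` hold the mean and standard deviation of
    (estimate - truth) for each free parameter, in evaluator packing order
    (T cells first, then kappa and theta where applicable); ``errors`` keeps
    the raw repetition x parameter error matrix.
    """

    model: Model
    repetitions: int
    param_names: list[str]
    bias: np.ndarray
    sd: np.ndarray
    errors: np.ndarray

    @property
    def max_abs_bias(self) -> float:
        return float(np.max(np.abs(self.bias)))

    @property
    def max_sd(self) -> float:
        return float(np.max(self.sd))


def _param_names(model: Model) -> list[str]:
    mask = excluded_mask(model)
    if mask.ndim == 1:
        names = [f"T[{i}]" for i in np.flatnonzero(~mask)]
    else:
        names = [f"T[{k // 12},{k % 12}]" for k in np.flatnonzero(~mask.ravel())]
    if model in (Model.BU, Model.BS):
        names.append("kappa")
    if model is Model.BS:
        names.append("theta")
    return names


def recovery_study(
    model: Model,
    repetitions: int = 100,
    restarts: int = 100,
    seed: int = 0,
    sequences=None,
    mode: str = "continuous",
    noise_sd: float = 0.0,
    randomize_roots: bool | None = None,
) -> RecoveryReport:
    """Plant random parameters, simulate ratings, re-estimate, and report the
    per-parameter mean bias and standard deviation of the estimates.

    The default stimulus set is the 253 repetition-free 2- and 3-chord
    patterns.  Interval-indexed models are transposition-invariant, so those
    use the canonical root-0 anchoring; the pitch-indexed models (1P, 2P)
    randomize the 3-chord initial roots per repetition instead.
    """
    model = Model(model)
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if randomize_roots is None:
        randomize_roots = model in (Model.P1, Model.P2)
    base = [tuple(s) for s in (sequences if sequences is not None else simulation_sequences())]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(repetitions)
    packer = make_evaluator(model, base[:1], [5.0])  # fixes the packing order only
    errors = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        truth = sample_params(model, rng=rng)
        seqs = base
        if randomize_roots:
            seqs = []
            for s in base:
                k = int(rng.integers(12)) if len(s) > 2 else 0
                seqs.append(tuple((r + k) % 12 for r in s))
        fit_seed = int(rng.integers(2**31 - 1))
        sim_seed = int(rng.integers(2**31 - 1))
        data = simulate_ratings(truth, seqs, mode=mode, noise_sd=noise_sd, seed=sim_seed)
        fit = coordinate_descent_fit(data, model, restarts=restarts, seed=fit_seed)
        errors.append(packer.pack(fit.params) - packer.pack(truth))
    err = np.asarray(errors)
    return RecoveryReport(
        model=model,
        repetitions=repetitions,
        param_names=_param_names(model),
        bias=err.mean(axis=0),
        sd=err.std(axis=0, ddof=0),
        errors=err,
    )
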