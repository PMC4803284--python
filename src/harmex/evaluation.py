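"""Held-out evaluation schemes and statistical comparison of the models.

Two schemes mirror the behavioural analysis: the *individual* split trains
each model per participant on the 2- and 3-chord conditions and tests on the
4-chord condition; the *kfold* scheme pools all participants and conditions
and runs a 10-fold cross-validation.  Paired per-unit test cross-entropies
(units = participants or folds) are compared with an exact two-sided binomial
sign test (ties excluded) and, for the k-fold scheme, a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .chords import RatingDataset
from .fitting import FitResult, coordinate_descent_fit, cross_entropy
from .models import Model, ModelParams

__all__ = [
    "SplitScheme",
    "SignTestResult",
    "ComparisonResult",
    "split_individual",
    "kfold_split",
    "evaluate",
    "sign_test",
    "paired_t_test",
    "model_comparison",
]


@dataclass(frozen=True)
class SplitScheme:
    """Evaluation scheme: ``kind`` is 'individual' (train = 2+3-chord,
    test = 4-chord, per participant) or 'kfold' (pooled random folds)."""

    kind: str = "individual"
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("individual", "kfold"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")


def split_individual(dataset: RatingDataset) -> tuple[RatingDataset, RatingDataset]:
    """Deterministic condition split: train on 2- and 3-chord trials, test on 4-chord."""
    train = [t for t in dataset if t.condition in (2, 3)]
    test = [t for t in dataset if t.condition == 4]
    if not train or not test:
        missing = "2/3-chord" if not train else "4-chord"
        raise ValueError(f"dataset has no {missing} trials")
    return RatingDataset(train, dataset.provenance), RatingDataset(test, dataset.provenance)


def kfold_split(dataset: RatingDataset, k: int = 10, seed: int = 0):
    """Random partition into ``k`` near-equal folds; each fold serves once as test."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(dataset)
    if n < k:
        raise ValueError(f"need at least {k} trials for {k} folds, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    pairs = []
    for i in range(k):
        test_idx = folds[i]
        train_idx = np.concatenate([folds[j] for j in range(k) if j != i])
        pairs.append((dataset.subset(train_idx), dataset.subset(test_idx)))
    return pairs


def evaluate(params: ModelParams, dataset: RatingDataset) -> float:
    """Cross-entropy of fixed parameters on a dataset (no updates)."""
    return cross_entropy(dataset, params)


@dataclass(frozen=True)
class SignTestResult:
    n_pos: int
    n_neg: int
    N: int
    p: float


def sign_test(differences) -> SignTestResult:
    """Exact two-sided binomial sign test; zero differences (ties) are excluded.

    p = min(1, 2 * P(X <= min(n_pos, n_neg))) with X ~ Binomial(N, 1/2).
    """
    d = np.asarray(differences, dtype=float)
    n_pos = int((d > 0).sum())
    n_neg = int((d < 0).sum())
    N = n_pos + n_neg
    if N == 0:
        raise ValueError("all differences are ties; sign test undefined")
    k = min(n_pos, n_neg)
    p = min(1.0, 2.0 * float(stats.binom.cdf(k, N, 0.5)))
    return SignTestResult(n_pos, n_neg, N, p)


def paired_t_test(x, y) -> tuple[float, int, float]:
    """Classical paired t-test; returns (T, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with >= 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), x.size - 1, float(res.pvalue)


@dataclass
class ComparisonResult:
    """Pairwise model comparison over paired evaluation units."""

    table: pd.DataFrame
    train_entropies: dict[str, np.ndarray]
    test_entropies: dict[str, np.ndarray]
    units: list[str]
    scheme: SplitScheme

    def mean_test_entropy(self) -> dict[str, float]:
        return {m: float(np.mean(v)) for m, v in self.test_entropies.items()}


def model_comparison(
    dataset: RatingDataset,
    models,
    scheme: SplitScheme,
    restarts: int = 100,
    seed: int = 0,
) -> ComparisonResult:
    """Fit every model on each training unit, evaluate held-out cross-entropy,
    and tabulate all pairwise sign tests (plus paired t-tests for k-fold).

    Units are participants for the individual scheme and folds for the k-fold
    scheme; the per-unit test cross-entropies are the paired observations.
    """
    models = [Model(m) for m in models]
    if len(models) < 2:
        raise ValueError("need at least two models to compare")

    units: list[str] = []
    splits: list[tuple[RatingDataset, RatingDataset]] = []
    if scheme.kind == "individual":
        for pid in dataset.participants:
            sub = dataset.by_participant(pid)
            splits.append(split_individual(sub))
            units.append(pid)
    else:
        for i, pair in enumerate(kfold_split(dataset, scheme.k, scheme.seed)):
            splits.append(pair)
            units.append(f"fold{i}")

    ss = np.random.SeedSequence(seed)
    fit_seeds = ss.generate_state(len(models) * len(units)) % (2**31 - 1)
    train_H = {m.value: np.empty(len(units)) for m in models}
    test_H = {m.value: np.empty(len(units)) for m in models}
    for mi, model in enumerate(models):
        for ui, (train, test) in enumerate(splits):
            fit = coordinate_descent_fit(
                train, model, restarts=restarts, seed=int(fit_seeds[mi * len(units) + ui])
            )
            train_H[model.value][ui] = fit.cost
            test_H[model.value][ui] = evaluate(fit.params, test)

    rows = []
    for m1, m2 in combinations(models, 2):
        d = test_H[m1.value] - test_H[m2.value]
        row = {"model1": m1.value, "model2": m2.value}
        try:
            st = sign_test(d)
            row.update(n_pos=st.n_pos, n_neg=st.n_neg, N=st.N, p_sign=st.p)
        except ValueError:
            row.update(n_pos=0, n_neg=0, N=0, p_sign=np.nan)
        if scheme.kind == "kfold":
            try:
                T, df, p = paired_t_test(test_H[m1.value], test_H[m2.value])
                row.update(t_stat=T, t_df=df, p_t=p)
            except ValueError:
                row.update(t_stat=np.nan, t_df=len(units) - 1, p_t=np.nan)
        rows.append(row)

    return ComparisonResult(
        table=pd.DataFrame(rows),
        train_entropies=train_H,
        test_entropies=test_H,
        units=units,
        scheme=scheme,
    )
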