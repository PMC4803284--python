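"""Pre-modeling behavioural statistics on participant-averaged DORs.

All analyses operate on DORs averaged across participants for each distinct
chord context: factor tests on the 2-chord design (Kruskal-Wallis), interval
effects on the 3-chord design (Friedman over the complete 12 x 12 interval
grid), grouping of the six preceding-chord-position interval profiles
(non-metric MDS and complete-link clustering), and the context-gain analysis
subtracting matched 2-chord DORs from 3-chord DORs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.manifold import MDS

from .chords import COMMON_INTERVALS, RatingDataset, interval

__all__ = [
    "TestResult",
    "ProfileVector",
    "Dendrogram",
    "PROFILE_LABELS",
    "average_dors",
    "kruskal_wallis_by_factor",
    "friedman_by_interval",
    "interval_profile_vectors",
    "profile_distance_matrix",
    "nonmetric_mds",
    "complete_link_clustering",
    "context_gain_analysis",
]

#: The six preceding-chord positions, labelled Cm-Cn for the interval between
#: the m-th chord and the final (n-th) chord of each condition.
PROFILE_LABELS = ("C1-C2", "C1-C3", "C2-C3", "C1-C4", "C2-C4", "C3-C4")


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class ProfileVector:
    """Mean DORs at the four shared intervals {2, 5, 7, 10} semitones for one
    preceding-chord position."""

    label: str
    values: tuple[float, float, float, float]
    intervals: tuple[int, ...] = COMMON_INTERVALS


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge history (scipy linkage matrix) over labelled leaves."""

    merges: np.ndarray
    labels: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def average_dors(dataset: RatingDataset, condition: int) -> pd.Series:
    """Participant-averaged mean DOR per distinct stimulus pattern.

    Keys: (root1, root2) for the 2-chord condition; successive-interval tuples
    for the 3- and 4-chord conditions.
    """
    sub = dataset.by_condition(condition)
    keys, vals = [], []
    for t in sub:
        s = t.sequence
        if condition == 2:
            keys.append((s[0], s[1]))
        else:
            keys.append(tuple(interval(s[i], s[i + 1]) for i in range(len(s) - 1)))
        vals.append(float(t.rating))
    frame = pd.DataFrame({"key": keys, "dor": vals})
    table = frame.groupby("key")["dor"].mean()
    table.index = pd.MultiIndex.from_tuples(table.index)
    table.name = "mean_dor"
    return table


def _require_complete_pairs(table: pd.Series) -> None:
    expected = {(a, b) for a in range(12) for b in range(12)}
    got = set(table.index)
    missing = sorted(expected - got)
    if missing:
        raise ValueError(f"incomplete design; missing cells: {missing[:6]}{'...' if len(missing) > 6 else ''}")


def kruskal_wallis_by_factor(table: pd.Series, factor: str) -> TestResult:
    """Tie-corrected Kruskal-Wallis test of one factor on the 2-chord table.

    ``factor`` groups the 144 pattern means by the root interval, the first
    chord's pitch, or the second chord's pitch (12 groups of 12).
    """
    _require_complete_pairs(table)
    if factor == "interval":
        key = lambda ab: (ab[1] - ab[0]) % 12
    elif factor == "first_pitch":
        key = lambda ab: ab[0]
    elif factor == "second_pitch":
        key = lambda ab: ab[1]
    else:
        raise ValueError(f"unknown factor {factor!r}")
    groups = [[] for _ in range(12)]
    for ab, v in table.items():
        groups[key(ab)].append(v)
    H, p = stats.kruskal(*groups)
    return TestResult(f"kruskal_wallis[{factor}]", float(H), 11, float(p))


def _friedman_grid(table: pd.Series, treatment: str) -> np.ndarray:
    """Arrange the 3-chord (interval1, interval2) table as blocks x treatments."""
    _require_complete_pairs(table)
    grid = np.empty((12, 12))
    for (i1, i2), v in table.items():
        if treatment == "interval_from_second":
            grid[i1, i2] = v                      # blocks = interval1, treatments = interval2
        elif treatment == "interval_from_first":
            grid[i2, (i1 + i2) % 12] = v          # blocks = interval2, treatments = c1->c3 interval
        else:
            raise ValueError(f"unknown treatment {treatment!r}")
    return grid


def _friedman(grid: np.ndarray, name: str) -> TestResult:
    if np.all(grid.max(axis=1) - grid.min(axis=1) == 0):
        raise ValueError("all treatments tie within every block; Friedman test degenerate")
    chi2, p = stats.friedmanchisquare(*[grid[:, j] for j in range(grid.shape[1])])
    return TestResult(name, float(chi2), grid.shape[1] - 1, float(p))


def friedman_by_interval(table: pd.Series, treatment: str) -> TestResult:
    """Friedman test of one interval factor on the complete 3-chord grid.

    ``interval_from_second`` tests the penultimate-to-final interval (blocks =
    first-interval levels); ``interval_from_first`` tests the first-to-final
    interval (blocks = penultimate-interval levels).
    """
    grid = _friedman_grid(table, treatment)
    return _friedman(grid, f"friedman[{treatment}]")


def interval_profile_vectors(dataset: RatingDataset) -> list[ProfileVector]:
    """Mean DOR at the shared intervals {2, 5, 7, 10} for each of the six
    preceding-chord positions across the 2-, 3- and 4-chord conditions."""
    positions = {
        "C1-C2": (2, 0),
        "C1-C3": (3, 0),
        "C2-C3": (3, 1),
        "C1-C4": (4, 0),
        "C2-C4": (4, 1),
        "C3-C4": (4, 2),
    }
    out = []
    for label in PROFILE_LABELS:
        cond, pos = positions[label]
        sub = dataset.by_condition(cond)
        sums = {iv: [] for iv in COMMON_INTERVALS}
        for t in sub:
            iv = interval(t.sequence[pos], t.sequence[-1])
            if iv in sums:
                sums[iv].append(float(t.rating))
        vals = []
        for iv in COMMON_INTERVALS:
            if not sums[iv]:
                raise ValueError(f"no trials for position {label} at interval {iv}")
            vals.append(float(np.mean(sums[iv])))
        out.append(ProfileVector(label, tuple(vals)))
    return out


def profile_distance_matrix(vectors: list[ProfileVector]) -> np.ndarray:
    """Euclidean distance matrix between the profile vectors."""
    V = np.array([v.values for v in vectors])
    diff = V[:, None, :] - V[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    return D


def nonmetric_mds(
    D: np.ndarray,
    dims: int = 2,
    n_init: int = 50,
    seed: int = 0,
    max_iter: int = 5000,
    eps: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Non-metric multidimensional scaling of a distance matrix.

    SMACOF with monotone (isotonic) regression of disparities; the best of
    ``n_init`` random initializations is kept.  Returns the embedding and the
    Kruskal stress-1 value.
    """
    D = _check_distance_matrix(D)
    common = dict(
        n_components=dims,
        n_init=n_init,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    try:
        mds = MDS(metric="precomputed", metric_mds=False, init="random", **common)
    except TypeError:  # older scikit-learn API
        mds = MDS(metric=False, dissimilarity="precomputed", **common)
    coords = mds.fit_transform(D)
    return coords, float(mds.stress_)


def complete_link_clustering(D: np.ndarray, labels=PROFILE_LABELS) -> Dendrogram:
    """Complete-linkage agglomerative clustering of a distance matrix.

    Merge heights equal the maximum inter-cluster distance, hence are
    monotone non-decreasing.
    """
    D = _check_distance_matrix(D)
    if D.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    Z = linkage(squareform(D, checks=False), method="complete")
    return Dendrogram(Z, tuple(labels[: D.shape[0]]))


def _mean_rank_posthoc(grid: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Nemenyi-style pairwise mean-rank comparisons after a Friedman test.

    ``grid`` is blocks x treatments; z = (Ra - Rb) / sqrt(k(k+1)/(6n)),
    Bonferroni-corrected over the k(k-1)/2 pairs.
    """
    n, k = grid.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, grid)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    threshold = alpha / n_pairs
    rows = []
    for a, b in combinations(range(k), 2):
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append(
            {
                "treatment_a": a,
                "treatment_b": b,
                "mean_rank_a": mean_ranks[a],
                "mean_rank_b": mean_ranks[b],
                "z": z,
                "p": p,
                "significant": p < threshold,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_pairs"] = n_pairs
    return out


def context_gain_analysis(
    dataset: RatingDataset, alpha: float = 0.05
) -> tuple[pd.DataFrame, TestResult, pd.DataFrame]:
    """Context gain: 3-chord DORs minus matched 2-chord DORs.

    Each 3-chord pattern is matched to the 2-chord pattern with the same
    final (penultimate-to-last) interval; the interval dominance of the
    2-chord results motivates matching on interval rather than pitch.  The
    gain grid is arranged with blocks = final interval and treatments = the
    first-to-last-chord interval, Friedman-tested with pairwise mean-rank
    post-hoc comparisons (Bonferroni over 66 pairs).
    """
    mean2 = average_dors(dataset, 2)
    _require_complete_pairs(mean2)
    mean2_by_interval = np.zeros(12)
    counts = np.zeros(12)
    for (a, b), v in mean2.items():
        iv = (b - a) % 12
        mean2_by_interval[iv] += v
        counts[iv] += 1
    mean2_by_interval /= counts

    mean3 = average_dors(dataset, 3)
    _require_complete_pairs(mean3)
    gain = np.empty((12, 12))  # rows: final interval i2; cols: c1->c3 interval
    for (i1, i2), v in mean3.items():
        gain[i2, (i1 + i2) % 12] = v - mean2_by_interval[i2]
    gain_df = pd.DataFrame(
        gain,
        index=pd.Index(range(12), name="final_interval"),
        columns=pd.Index(range(12), name="c1_to_c3_interval"),
    )
    try:
        test = _friedman(gain, "friedman[context_gain:c1_to_c3_interval]")
    except ValueError:
        # fully tied grid (e.g. 3-chord data copied from matched 2-chord means)
        test = TestResult("friedman[context_gain:c1_to_c3_interval]:all-ties", 0.0, 11, 1.0)
    posthoc = _mean_rank_posthoc(gain, alpha=alpha)
    return gain_df, test, posthoc
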