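"""Short time-series expression profile clustering.

Partitions a gene x timepoint table of log-ratios (relative to time 0)
into induced / unaffected / repressed gene sets, following the
model-profile approach used for short expression time courses: a
library of integer-valued candidate profiles (unit steps bounded by c
per transition, first level 0) is reduced to m representative profiles
by greedy max-min correlation-distance selection; genes are assigned
to the best-correlated profile; profile enrichment is judged against a
permutation null (shuffling each gene's timepoint order) with a
binomial tail and Bonferroni correction; significant profiles are
classed by the sign of their mean level. Genes whose maximal absolute
log-ratio stays below a minimum change (0.5 by default) are filtered
out before assignment and reported with the unaffected set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import binomial_upper_tail

__all__ = [
    "TimeCourse",
    "ModelProfile",
    "TemporalParams",
    "GeneSets",
    "ShortTimeSeriesModel",
    "TemporalPartitionResults",
    "filter_min_change",
    "enumerate_candidate_profiles",
    "select_representative_profiles",
    "assign_genes_to_profiles",
    "profile_significance",
    "partition_gene_sets",
]


@dataclass
class TimeCourse:
    """Gene x timepoint log-ratios relative to the first timepoint."""

    genes: list[str]
    timepoints: list[float]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timepoints) < 3:
            raise ValueError("need at least three timepoints")
        if self.values.shape != (len(self.genes), len(self.timepoints)):
            raise ValueError("values shape must be (genes, timepoints)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not np.allclose(self.values[:, 0], 0.0):
            raise ValueError("first-timepoint values must be 0 (log-ratios)")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values, index=pd.Index(self.genes, name="gene"),
            columns=[f"{t:g}" for t in self.timepoints],
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TimeCourse":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), [float(c) for c in df.columns], df.to_numpy())


@dataclass(frozen=True)
class ModelProfile:
    """Integer level per timepoint, first level 0."""

    profile_id: int
    levels: tuple[int, ...]

    def __post_init__(self):
        if self.levels[0] != 0:
            raise ValueError("profiles start at level 0")

    @property
    def mean_level(self) -> float:
        return float(np.mean(self.levels))


@dataclass
class TemporalParams:
    c: int = 2  # max unit change per step
    m: int = 50  # representative profiles
    min_change: float = 0.5  # on |log-ratio| relative to time 0
    n_permutations: int = 1000  # used only when T! > 5040
    alpha: float = 0.05  # Bonferroni-corrected significance level

    def __post_init__(self):
        if self.c < 1 or self.m < 2 or self.min_change < 0:
            raise ValueError("require c >= 1, m >= 2, min_change >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------


def filter_min_change(
    timecourse: TimeCourse, params: TemporalParams
) -> tuple[list[str], list[str]]:
    """Split genes into retained/removed by max |log-ratio| >= min_change."""
    maxabs = np.abs(timecourse.values).max(axis=1)
    keep = maxabs >= params.min_change
    genes = np.asarray(timecourse.genes)
    return list(genes[keep]), list(genes[~keep])


def enumerate_candidate_profiles(T: int, c: int) -> list[ModelProfile]:
    """All (2c+1)^(T-1) integer profiles with per-step change in [-c, c].

    Deterministic order: steps enumerated lexicographically from -c to
    +c, profile ids assigned in that order.
    """
    n = (2 * c + 1) ** (T - 1)
    if n > 10**6:
        raise ValueError(
            f"(2c+1)^(T-1) = {n} candidate profiles exceed 1e6; reduce c"
        )
    steps = range(-c, c + 1)
    profiles = []
    for pid, deltas in enumerate(itertools.product(steps, repeat=T - 1)):
        levels = (0, *itertools.accumulate(deltas))
        profiles.append(ModelProfile(pid, tuple(levels)))
    return profiles


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Rows to zero mean, unit norm; zero-variance rows become zero."""
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, x / norm, 0.0)
    return out


def select_representative_profiles(
    candidates: Sequence[ModelProfile], m: int
) -> list[ModelProfile]:
    """Greedy max-min selection of m profiles (1 - Pearson distance).

    Selection starts from the flat (all-zero) profile, which is always
    included; each step adds the candidate maximizing its minimum
    distance to the already-selected set together with that candidate's
    mirror (negated) profile, so the library is closed under negation
    and induced/repressed patterns are treated symmetrically. Ties
    break by enumeration order; deterministic. Returned sorted by
    profile id (m may be exceeded by one when the last pair completes).
    """
    lv = np.array([p.levels for p in candidates], dtype=float)
    std = _standardize_rows(lv)
    nonzero = np.linalg.norm(std, axis=1) > 0
    flat_idx = [i for i, p in enumerate(candidates) if np.ptp(p.levels) == 0]
    if not flat_idx:
        raise ValueError("candidate set must contain the flat profile")
    flat = flat_idx[0]
    n_eligible = int(nonzero.sum()) + 1
    if m > n_eligible:
        raise ValueError(
            f"m={m} exceeds the {n_eligible} selectable profiles "
            "(nonzero-variance candidates plus the flat profile)"
        )
    by_levels = {p.levels: i for i, p in enumerate(candidates)}
    selected = [flat]
    # distance to the flat profile: correlation with a constant vector is
    # defined as 0, so every candidate starts at distance 1
    min_dist = np.ones(len(candidates))
    min_dist[~nonzero] = 0.0  # other degenerate profiles never selected
    min_dist[flat] = -np.inf

    def take(idx):
        selected.append(idx)
        min_dist[idx] = -np.inf
        d = 1.0 - std @ std[idx]
        d[~nonzero] = 0.0
        np.minimum(min_dist, d, out=min_dist)

    while len(selected) < m:
        nxt = int(np.argmax(min_dist))  # first max = enumeration order
        take(nxt)
        mirror = by_levels.get(tuple(-l for l in candidates[nxt].levels))
        if mirror is not None and np.isfinite(min_dist[mirror]):
            take(mirror)
    return sorted((candidates[i] for i in selected), key=lambda p: p.profile_id)


def assign_genes_to_profiles(
    timecourse: TimeCourse, profiles: Sequence[ModelProfile]
) -> pd.Series:
    """Assign each gene to the profile with maximal Pearson correlation.

    Correlation with the zero-variance flat profile is defined as 0;
    zero-variance genes go to the flat profile; ties break toward the
    lowest profile id.
    """
    ids, corr = _assignment_matrix(timecourse.values, profiles)
    return pd.Series(ids, index=timecourse.genes, name="profile_id")


def _assignment_matrix(
    values: np.ndarray, profiles: Sequence[ModelProfile]
) -> tuple[np.ndarray, np.ndarray]:
    profiles = sorted(profiles, key=lambda p: p.profile_id)
    lv = np.array([p.levels for p in profiles], dtype=float)
    pstd = _standardize_rows(lv)
    gstd = _standardize_rows(values)
    corr = gstd @ pstd.T
    best = corr.argmax(axis=1)  # first max -> lowest profile id
    flat_positions = [
        k for k, p in enumerate(profiles) if np.ptp(p.levels) == 0
    ]
    if flat_positions:
        zero_var = np.linalg.norm(gstd, axis=1) == 0
        best = np.where(zero_var, flat_positions[0], best)
    ids = np.array([profiles[k].profile_id for k in best])
    return ids, corr


def profile_significance(
    assignments: pd.Series,
    timecourse: TimeCourse,
    profiles: Sequence[ModelProfile],
    params: TemporalParams,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Permutation-null enrichment p-value per profile.

    The null shuffles each gene's timepoint order independently
    (exhaustive over all T! orders when T! <= 5040, otherwise
    ``n_permutations`` seeded draws); the expected assigned count per
    profile is the mean over the null, and the p-value is the
    Binomial(n_genes, expected/n_genes) upper tail at the observed
    count, Bonferroni-corrected over the m profiles.
    """
    profiles = sorted(profiles, key=lambda p: p.profile_id)
    T = timecourse.n_timepoints
    n_genes = len(timecourse.genes)
    values = timecourse.values
    if math.factorial(T) <= 5040:
        perms = np.array(list(itertools.permutations(range(T))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(T) for _ in range(params.n_permutations)])
    pid_index = {p.profile_id: k for k, p in enumerate(profiles)}
    null_counts = np.zeros(len(profiles))
    chunk = max(1, 200_000 // max(n_genes, 1))
    for lo in range(0, len(perms), chunk):
        sub = perms[lo : lo + chunk]
        permuted = values[:, sub]  # (genes, n_perm_chunk, T)
        flat = permuted.transpose(1, 0, 2).reshape(-1, T)
        ids, _ = _assignment_matrix(flat, profiles)
        pos = np.array([pid_index[i] for i in ids])
        null_counts += np.bincount(pos, minlength=len(profiles))
    expected = null_counts / len(perms)
    observed = np.array(
        [(assignments.to_numpy() == p.profile_id).sum() for p in profiles]
    )
    m = len(profiles)
    p_raw = np.empty(m)
    eps = 1.0 / (len(perms) * max(n_genes, 1) + 1)
    for k in range(m):
        p0 = min(max(expected[k] / n_genes, eps), 1.0 - eps)
        p_raw[k] = binomial_upper_tail(int(observed[k]), n_genes, p0)
    p_bonf = np.minimum(1.0, p_raw * m)
    return pd.DataFrame(
        {
            "observed": observed,
            "expected": expected,
            "p_value": p_raw,
            "p_bonferroni": p_bonf,
            "significant": p_bonf <= params.alpha,
            "mean_level": [p.mean_level for p in profiles],
        },
        index=pd.Index([p.profile_id for p in profiles], name="profile_id"),
    )


@dataclass
class GeneSets:
    """Disjoint induced / unaffected / repressed gene sets."""

    up: list[str]
    flat: list[str]
    down: list[str]

    def sizes(self) -> tuple[int, int, int]:
        return len(self.up), len(self.flat), len(self.down)


def partition_gene_sets(
    assignments: pd.Series,
    significance: pd.DataFrame,
    filtered_out_genes: Sequence[str],
) -> GeneSets:
    """Class genes by the sign of their significant profile's mean level.

    Genes assigned to significant profiles inherit the profile class
    (positive mean level -> up, zero -> flat, negative -> down); genes
    that failed the minimum-change filter join the flat/unaffected
    set; genes on non-significant profiles are left out.
    """
    sig = significance[significance["significant"]]
    up, flat, down = [], sorted(filtered_out_genes), []
    for pid, row in sig.iterrows():
        members = sorted(assignments.index[assignments == pid])
        if row["mean_level"] > 0:
            up.extend(members)
        elif row["mean_level"] < 0:
            down.extend(members)
        else:
            flat.extend(members)
    return GeneSets(sorted(up), sorted(flat), sorted(down))


# ---------------------------------------------------------------------------
# Model / results objects


@dataclass
class TemporalPartitionResults:
    assignments: pd.Series
    significance: pd.DataFrame
    gene_sets: GeneSets
    profiles: list[ModelProfile]
    retained_genes: list[str]
    filtered_genes: list[str]
    params: TemporalParams

    def plot_profiles(self, ax=None):
        """Mean level trajectory of each significant profile, scaled by
        its assigned gene count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sig = self.significance[self.significance["significant"]]
        for pid, row in sig.iterrows():
            profile = next(p for p in self.profiles if p.profile_id == pid)
            ax.plot(profile.levels, lw=1 + 2 * row["observed"] / max(
                1, len(self.assignments)), label=f"profile {pid} "
                f"(n={int(row['observed'])})")
        ax.set_xlabel("timepoint")
        ax.set_ylabel("model level")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        u, f, d = self.gene_sets.sizes()
        n_sig = int(self.significance["significant"].sum())
        return "\n".join(
            [
                "Short time-series profile partition",
                f"  genes in              {len(self.retained_genes) + len(self.filtered_genes)}",
                f"  below min change      {len(self.filtered_genes)} "
                f"(|log-ratio| < {self.params.min_change})",
                f"  profiles (m)          {len(self.profiles)}",
                f"  significant profiles  {n_sig} (Bonferroni {self.params.alpha})",
                f"  gene sets             up {u} / unaffected {f} / down {d}",
            ]
        )


class ShortTimeSeriesModel:
    """Profile-clustering model for a short expression time course.

    ``fit`` runs filtering, candidate enumeration, greedy profile
    selection, correlation assignment, permutation significance and the
    three-way partition, returning :class:`TemporalPartitionResults`.
    """

    def __init__(self, timecourse: TimeCourse, params: TemporalParams | None = None):
        self.timecourse = timecourse
        self.params = params or TemporalParams()

    def fit(self, seed: int | None = 0) -> TemporalPartitionResults:
        tc, params = self.timecourse, self.params
        retained, removed = filter_min_change(tc, params)
        keep = np.isin(np.asarray(tc.genes), retained)
        sub = TimeCourse(
            list(np.asarray(tc.genes)[keep]), tc.timepoints, tc.values[keep]
        )
        candidates = enumerate_candidate_profiles(tc.n_timepoints, params.c)
        m = min(params.m, sum(1 for p in candidates if np.ptp(p.levels) > 0) + 1)
        profiles = select_representative_profiles(candidates, m)
        if len(sub.genes) == 0:
            assignments = pd.Series([], dtype=int, name="profile_id")
            significance = pd.DataFrame(
                {
                    "observed": 0,
                    "expected": 0.0,
                    "p_value": 1.0,
                    "p_bonferroni": 1.0,
                    "significant": False,
                    "mean_level": [p.mean_level for p in profiles],
                },
                index=pd.Index([p.profile_id for p in profiles], name="profile_id"),
            )
        else:
            assignments = assign_genes_to_profiles(sub, profiles)
            significance = profile_significance(
                assignments, sub, profiles, params, seed=seed
            )
        gene_sets = partition_gene_sets(assignments, significance, removed)
        return TemporalPartitionResults(
            assignments, significance, gene_sets, profiles, retained, removed, params
        )
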