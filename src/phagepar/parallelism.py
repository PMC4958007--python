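"""Pairwise parallelism between replicate wells and occurrence-spectrum
statistics.

Parallelism between wells *i* and *j* is

    P_ij = 1/2 ( |S_i ∩ S_j| / |S_i|  +  |S_i ∩ S_j| / |S_j| )

where S_i is well i's union of de novo mutations, optionally coarsened to
the regulatory-element/codon ("cluster") identity level and optionally
excluding named features (e.g. the D-promoter) or reversions.  The
background-effect test partitions the sum of squares of within-background
P_ij values and compares the between-background share (R) against a null
generated by permuting well-to-background labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, well_mutation_set

LEVELS = ("nucleotide", "cluster")


def well_identity_sets(dataset: Dataset, level: str = "nucleotide",
                       include_reversions: bool = True,
                       exclude_features: frozenset[str] = frozenset()
                       ) -> dict[str, frozenset[str]]:
    """Per-well mutation identity sets at the requested level."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    exclude_features = frozenset(exclude_features)
    rev = dataset.all_reversion_keys
    out = {}
    for w in dataset.wells:
        keys = well_mutation_set(w, include_reversions, rev)
        if exclude_features:
            keys = {k for k in keys
                    if not exclude_features
                    & set(dataset.mutation_catalog[k].features)}
        if level == "cluster":
            keys = {dataset.mutation_catalog[k].cluster_id for k in keys}
        out[w.well_id] = frozenset(keys)
    return out


@dataclass
class PairwiseParallelism:
    level: str
    values: pd.DataFrame           # symmetric; NaN where a set is empty
    include_reversions: bool
    excluded_features: frozenset[str] = frozenset()

    @property
    def well_ids(self) -> list[str]:
        return list(self.values.index)

    def pair_values(self) -> pd.Series:
        """Upper-triangle P_ij values indexed by (well_i, well_j)."""
        vals = {}
        ids = self.well_ids
        arr = self.values.to_numpy()
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                vals[(ids[a], ids[b])] = arr[a, b]
        return pd.Series(vals, dtype=float)


def pairwise_parallelism(dataset: Dataset, level: str = "nucleotide",
                         include_reversions: bool = True,
                         exclude_features=()) -> PairwiseParallelism:
    """Symmetric matrix of P_ij over all retained well pairs.

    A well whose identity set is empty after exclusions contributes NaN
    (missing) rather than zero: "no mutations to compare" is not the same
    observation as "no sharing".
    """
    sets = well_identity_sets(dataset, level, include_reversions,
                              frozenset(exclude_features))
    if len(sets) < 2:
        raise ValueError("need at least two wells")
    if all(len(s) == 0 for s in sets.values()):
        raise ValueError("all well mutation sets are empty")
    ids = list(sets)
    n = len(ids)
    arr = np.full((n, n), np.nan)
    for a in range(n):
        sa = sets[ids[a]]
        if sa:
            arr[a, a] = 1.0
        for b in range(a + 1, n):
            sb = sets[ids[b]]
            if not sa or not sb:
                continue
            inter = len(sa & sb)
            arr[a, b] = arr[b, a] = 0.5 * (inter / len(sa) + inter / len(sb))
    values = pd.DataFrame(arr, index=ids, columns=ids)
    return PairwiseParallelism(level, values, include_reversions,
                               frozenset(exclude_features))


def within_background_summary(parallelism: PairwiseParallelism,
                              dataset: Dataset) -> pd.DataFrame:
    """Per-background mean P_ij over within-background pairs.

    Returns a frame indexed by background with columns ``mean``, ``se`` and
    ``n_pairs``, plus a ``grand`` row holding the unweighted mean of the
    background means and its SE over backgrounds.  The grand mean is
    deliberately unweighted: backgrounds lose unequal numbers of wells to
    QC, and the experiment's summary statistic averages backgrounds, not
    pairs.
    """
    pairs = parallelism.pair_values()
    bg_of = {w.well_id: w.background_id for w in dataset.wells}
    rows = {}
    for bg in dict.fromkeys(bg_of.values()):
        vals = np.array([v for (i, j), v in pairs.items()
                         if bg_of.get(i) == bg and bg_of.get(j) == bg
                         and np.isfinite(v)])
        if len(vals) == 0:
            warnings.warn(f"background {bg}: fewer than 2 comparable wells")
            continue
        se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows[bg] = (vals.mean(), se, len(vals))
    df = pd.DataFrame(rows, index=["mean", "se", "n_pairs"]).T
    means = df["mean"].to_numpy()
    grand_se = (means.std(ddof=1) / np.sqrt(len(means))
                if len(means) > 1 else np.nan)
    df.loc["grand"] = (means.mean(), grand_se, df["n_pairs"].sum())
    return df


# ---------------------------------------------------------------------------
# Occurrence spectrum
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceSpectrum:
    """Per-mutation well counts and squared-frequency co-occurrence
    probabilities.

    ``squared_frequency[k] = (count_k / n_wells)**2`` is the probability
    that mutation k is found in each of two wells drawn at random.
    """

    per_mutation_well_count: dict[str, int]
    n_wells: int

    @property
    def squared_frequency(self) -> dict[str, float]:
        return {k: (c / self.n_wells) ** 2
                for k, c in self.per_mutation_well_count.items()}

    @property
    def mean_squared_frequency(self) -> float:
        sq = self.squared_frequency
        return float(np.mean(list(sq.values()))) if sq else np.nan

    def to_series(self) -> pd.Series:
        return pd.Series(self.per_mutation_well_count).sort_values(
            ascending=False)


def occurrence_spectrum(dataset: Dataset, include_reversions: bool = False,
                        group_features=()) -> OccurrenceSpectrum:
    """Well-occurrence counts per mutation, optionally pooling all
    mutations of a named feature (e.g. the D-promoter) into one entry."""
    group_features = frozenset(group_features)
    rev = dataset.all_reversion_keys
    counts: dict[str, int] = {}
    for w in dataset.wells:
        keys = well_mutation_set(w, include_reversions, rev)
        ids = set()
        for k in keys:
            feats = group_features & set(dataset.mutation_catalog[k].features)
            ids.add(sorted(feats)[0] if feats else k)
        for i in ids:
            counts[i] = counts.get(i, 0) + 1
    return OccurrenceSpectrum(counts, n_wells=len(dataset.wells))


# ---------------------------------------------------------------------------
# Background effect on parallelism (sum-of-squares partition)
# ---------------------------------------------------------------------------

def _r_statistic(P: np.ndarray, labels: np.ndarray) -> float:
    """Share of the sum of squares of within-group P_ij values that lies
    between groups.  Returns 0 when all values are equal."""
    iu, ju = np.triu_indices(len(labels), k=1)
    same = labels[iu] == labels[ju]
    vals = P[iu[same], ju[same]]
    grp = labels[iu[same]]
    ok = np.isfinite(vals)
    vals, grp = vals[ok], grp[ok]
    if len(vals) == 0:
        return 0.0
    grand = vals.mean()
    ss_total = ((vals - grand) ** 2).sum()
    if ss_total == 0:
        return 0.0
    ss_between = 0.0
    for g in np.unique(grp):
        gv = vals[grp == g]
        ss_between += len(gv) * (gv.mean() - grand) ** 2
    return float(ss_between / ss_total)


@dataclass
class BackgroundPartitionResult:
    r_real: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    level: str
    include_reversions: bool
    excluded_features: frozenset[str] = frozenset()

    def summary(self) -> str:
        lines = [
            "Background effect on parallelism (sum-of-squares partition)",
            f"  level: {self.level}   reversions included: {self.include_reversions}",
            f"  excluded features: {sorted(self.excluded_features) or 'none'}",
            f"  R_real = {self.r_real:.4f}",
            f"  permutations = {self.n_perm}",
            f"  null mean R = {self.null_distribution.mean():.4f}",
            f"  p = {self.p_value:.4g}",
        ]
        return "\n".join(lines)


class BackgroundEffectTest:
    """Does parallelism differ among ancestral backgrounds?

    Fits the sum-of-squares partition R = SS_between / SS_total over
    within-background P_ij values and calibrates it by permuting the
    well-to-background labels (group sizes preserved), which accounts for
    the non-independence of pairwise comparisons sharing a well.
    """

    def __init__(self, dataset: Dataset, level: str = "nucleotide",
                 include_reversions: bool = True, exclude_features=()):
        self.dataset = dataset
        self.level = level
        self.include_reversions = include_reversions
        self.exclude_features = frozenset(exclude_features)
        self.parallelism = pairwise_parallelism(
            dataset, level, include_reversions, self.exclude_features)
        self._labels = pd.Categorical(
            [dataset.background_of(w) for w in self.parallelism.well_ids]
        ).codes.astype(np.int64)
        if len(np.unique(self._labels)) < 2:
            raise ValueError("need wells from at least two backgrounds")

    def fit(self, n_perm: int = 9999, seed: int | None = None
            ) -> BackgroundPartitionResult:
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
        rng = np.random.default_rng(seed)
        P = self.parallelism.values.to_numpy()
        r_real = _r_statistic(P, self._labels)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = _r_statistic(P, rng.permutation(self._labels))
        p = (1 + np.sum(null >= r_real)) / (n_perm + 1)
        return BackgroundPartitionResult(
            r_real=r_real, null_distribution=null, p_value=float(p),
            n_perm=n_perm, level=self.level,
            include_reversions=self.include_reversions,
            excluded_features=self.exclude_features)


def background_effect_test(dataset: Dataset, level: str = "nucleotide",
                           n_perm: int = 9999, seed: int | None = None,
                           include_reversions: bool = True,
                           exclude_features=()) -> BackgroundPartitionResult:
    return BackgroundEffectTest(dataset, level, include_reversions,
                                exclude_features).fit(n_perm, seed)
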