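"""Epistasis analyses: within/between parallelism ratio, the
mutation-by-background likelihood-ratio framework with stepwise removal of
influential mutations, the reversion LRT, and pairwise co-occurrence
randomization.

All presence/absence likelihoods are at the *well* level: a mutation is
"present" in a well when at least one of its sequenced isolates carries it.
The co-occurrence test is the exception — its unit is the isolate (two
mutations co-occur when some isolate carries both), counted per well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, false_discovery_control

from .data import Dataset, classify_reversions, isolate_presence_matrix, presence_matrix
from .parallelism import pairwise_parallelism


# ---------------------------------------------------------------------------
# Method 1: within- vs between-background parallelism ratio
# ---------------------------------------------------------------------------

@dataclass
class WithinBetweenResult:
    mean_within: float
    mean_between: float
    ratio: float                    # NaN when mean_between == 0
    null_ratios: np.ndarray
    p_value: float
    n_perm: int
    level: str

    def summary(self) -> str:
        return "\n".join([
            "Within- vs between-background parallelism",
            f"  level: {self.level}",
            f"  mean within  = {self.mean_within:.4f}",
            f"  mean between = {self.mean_between:.4f}",
            f"  ratio        = {self.ratio:.4f}",
            f"  permutations = {self.n_perm}   p (ratio >= observed) = {self.p_value:.4g}",
        ])


def _within_between_means(P: np.ndarray, labels: np.ndarray
                          ) -> tuple[float, float]:
    iu, ju = np.triu_indices(len(labels), k=1)
    vals = P[iu, ju]
    ok = np.isfinite(vals)
    same = labels[iu] == labels[ju]
    w = vals[ok & same]
    b = vals[ok & ~same]
    return (w.mean() if len(w) else np.nan, b.mean() if len(b) else np.nan)


class WithinBetweenTest:
    """Is parallelism higher within backgrounds than between them?

    The statistic is the ratio of the mean P_ij over within-background
    pairs to the mean over between-background pairs; the null distribution
    comes from permuting well-to-background labels, preserving group sizes.
    """

    def __init__(self, dataset: Dataset, level: str = "nucleotide",
                 include_reversions: bool = False, exclude_features=()):
        self.dataset = dataset
        self.level = level
        self.parallelism = pairwise_parallelism(
            dataset, level, include_reversions, frozenset(exclude_features))
        self._labels = pd.Categorical(
            [dataset.background_of(w) for w in self.parallelism.well_ids]
        ).codes.astype(np.int64)
        if len(np.unique(self._labels)) < 2:
            raise ValueError("need at least two backgrounds")

    def fit(self, n_perm: int = 9999, seed: int | None = None
            ) -> WithinBetweenResult:
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
        rng = np.random.default_rng(seed)
        P = self.parallelism.values.to_numpy()
        mw, mb = _within_between_means(P, self._labels)
        ratio = mw / mb if mb else np.nan
        null = np.empty(n_perm)
        for i in range(n_perm):
            w, b = _within_between_means(P, rng.permutation(self._labels))
            null[i] = w / b if b else np.nan
        if np.isnan(ratio):
            p = np.nan
        else:
            p = (1 + np.nansum(null >= ratio)) / (n_perm + 1)
        return WithinBetweenResult(
            mean_within=float(mw), mean_between=float(mb), ratio=float(ratio),
            null_ratios=null, p_value=float(p), n_perm=n_perm, level=self.level)


def within_between_test(dataset: Dataset, level: str = "nucleotide",
                        include_reversions: bool = False,
                        n_boot: int = 9999, seed: int | None = None
                        ) -> WithinBetweenResult:
    return WithinBetweenTest(dataset, level, include_reversions).fit(n_boot, seed)


# ---------------------------------------------------------------------------
# Method 2: mutation x background LRT
# ---------------------------------------------------------------------------

@dataclass
class LRTResult:
    lnl_null: float
    lnl_alt: float
    lam: float                      # lnL_alt - lnL_null >= 0
    per_mutation_delta: pd.Series   # sorted descending; empty for reversion LRT
    p_value: float
    method: str                     # "randomization" | "chi-squared"
    n_perm: int = 0
    df: int | None = None
    saturated: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            "Likelihood-ratio test",
            f"  lnL(null) = {self.lnl_null:.4f}",
            f"  lnL(alt)  = {self.lnl_alt:.4f}",
            f"  Lambda    = {self.lam:.4f}",
            f"  p = {self.p_value:.4g} ({self.method}"
            + (f", {self.n_perm} permutations)" if self.method == "randomization"
               else f", df={self.df})"),
        ]
        if len(self.per_mutation_delta):
            top = self.per_mutation_delta.head(5)
            lines.append("  largest per-mutation contributions:")
            lines += [f"    {k}: {v:.4f}" for k, v in top.items()]
        return "\n".join(lines)


def _binomial_lnl(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Maximised Bernoulli log-likelihood for success counts out of totals,
    elementwise, with the 0*log(0) = 0 convention."""
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        t1 = np.where(counts > 0, counts * np.log(p), 0.0)
        t2 = np.where(totals - counts > 0,
                      (totals - counts) * np.log1p(-p), 0.0)
    return t1 + t2


class MutationBackgroundLRT:
    """Does the probability of a mutation arising depend on background?

    Null: every mutation k arises in any well with one probability p_k.
    Alternative: p_{k,b} varies by background.  Both are Bernoulli models
    over wells with MLE plug-in probabilities; Λ = lnL_alt − lnL_null sums
    exactly over mutations, and each mutation's ΔlnL measures how much that
    mutation alone is associated with background.  Significance comes from
    permuting well-to-background labels.  Reversions are excluded by
    default since their opportunity is background-specific by construction.
    """

    def __init__(self, dataset: Dataset, include_reversions: bool = False):
        self.dataset = dataset
        M = presence_matrix(dataset, include_reversions=include_reversions)
        # drop unobserved columns (cannot arise after QC subsetting)
        M = M.loc[:, M.any(axis=0)]
        self.matrix = M
        self._labels = pd.Categorical(
            [dataset.background_of(w) for w in M.index]).codes.astype(np.int64)
        # a single background is allowed: the models coincide and Lambda = 0
        self.n_backgrounds = len(np.unique(self._labels))

    def _lnl_parts(self, labels: np.ndarray, M: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
        n_wells = M.shape[0]
        counts = M.sum(axis=0)
        lnl0 = _binomial_lnl(counts, np.full_like(counts, n_wells, dtype=float))
        onehot = np.eye(self.n_backgrounds, dtype=float)[labels]
        group_counts = onehot.T @ M          # B x K
        group_sizes = onehot.sum(axis=0)     # B
        lnl1 = _binomial_lnl(group_counts, group_sizes[:, None]).sum(axis=0)
        return lnl0, lnl1

    def fit(self, n_perm: int = 999, seed: int | None = None,
            subset: list[str] | None = None) -> LRTResult:
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
        M_df = self.matrix if subset is None else self.matrix[list(subset)]
        M = M_df.to_numpy(dtype=float)
        labels = self._labels
        lnl0, lnl1 = self._lnl_parts(labels, M)
        delta = np.clip(lnl1 - lnl0, 0.0, None)
        lam = float(delta.sum())
        counts = M.sum(axis=0)
        saturated = tuple(M_df.columns[(counts == 0) | (counts == M.shape[0])])

        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            l0, l1 = self._lnl_parts(rng.permutation(labels), M)
            null[i] = np.clip(l1 - l0, 0.0, None).sum()
        p = (1 + np.sum(null >= lam)) / (n_perm + 1)

        per = pd.Series(delta, index=M_df.columns).sort_values(ascending=False)
        return LRTResult(
            lnl_null=float(lnl0.sum()), lnl_alt=float(lnl1.sum()), lam=lam,
            per_mutation_delta=per, p_value=float(p), method="randomization",
            n_perm=n_perm, saturated=saturated)

    def stepwise(self, alpha: float = 0.05, n_perm: int = 999,
                 seed: int | None = None) -> list[tuple[str, float]]:
        """Iteratively remove the most background-associated mutation.

        At each step the mutation with the largest ΔlnL (ties broken by
        lexicographic key) is removed and the global test re-run; stops
        once p >= alpha.  Returns [(removed_key, p_after_removal), ...].
        """
        remaining = list(self.matrix.columns)
        rng = np.random.default_rng(seed)
        removed: list[tuple[str, float]] = []
        result = self.fit(n_perm, int(rng.integers(2**31)), subset=remaining)
        while result.p_value < alpha and remaining:
            per = result.per_mutation_delta
            top = min(per[per == per.max()].index)  # lexicographic tie-break
            remaining.remove(top)
            if not remaining:
                removed.append((top, np.nan))
                break
            result = self.fit(n_perm, int(rng.integers(2**31)), subset=remaining)
            removed.append((top, result.p_value))
        return removed


def mutation_background_lrt(dataset: Dataset, exclude_reversions: bool = True,
                            n_perm: int = 999, seed: int | None = None
                            ) -> LRTResult:
    model = MutationBackgroundLRT(dataset,
                                  include_reversions=not exclude_reversions)
    return model.fit(n_perm, seed)


def stepwise_influential(dataset: Dataset, alpha: float = 0.05,
                         n_perm: int = 999, seed: int | None = None
                         ) -> list[tuple[str, float]]:
    return MutationBackgroundLRT(dataset).stepwise(alpha, n_perm, seed)


# ---------------------------------------------------------------------------
# Reversion LRT
# ---------------------------------------------------------------------------

class ReversionLRT:
    """Is the probability of background reversion equal across backgrounds?

    Per-background binomial counts of reverted wells out of available
    wells; the null pools one probability, the alternative fits one per
    background.  2Λ is referred to a chi-squared distribution with
    B − 1 degrees of freedom.
    """

    def __init__(self, reverted: dict[str, int], totals: dict[str, int]):
        if set(reverted) != set(totals):
            raise ValueError("reverted and totals must cover the same backgrounds")
        if len(totals) < 2:
            raise ValueError("need at least two backgrounds")
        for b in totals:
            if not 0 <= reverted[b] <= totals[b]:
                raise ValueError(f"background {b}: invalid counts")
        self.backgrounds = sorted(totals)
        self.reverted = np.array([reverted[b] for b in self.backgrounds], float)
        self.totals = np.array([totals[b] for b in self.backgrounds], float)

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "ReversionLRT":
        flags = classify_reversions(dataset)
        reverted: dict[str, int] = {}
        totals: dict[str, int] = {}
        for w in dataset.wells:
            totals[w.background_id] = totals.get(w.background_id, 0) + 1
            reverted[w.background_id] = (reverted.get(w.background_id, 0)
                                         + int(flags[w.well_id]))
        return cls(reverted, totals)

    def fit(self) -> LRTResult:
        pooled = _binomial_lnl(self.reverted.sum(), self.totals.sum())
        lnl0 = float(pooled)
        lnl1 = float(_binomial_lnl(self.reverted, self.totals).sum())
        lam = max(lnl1 - lnl0, 0.0)
        df = len(self.backgrounds) - 1
        p = float(chi2.sf(2 * lam, df))
        return LRTResult(lnl_null=lnl0, lnl_alt=lnl1, lam=lam,
                         per_mutation_delta=pd.Series(dtype=float),
                         p_value=p, method="chi-squared", df=df)


def reversion_lrt(dataset: Dataset) -> LRTResult:
    return ReversionLRT.from_dataset(dataset).fit()


# ---------------------------------------------------------------------------
# Method 3: pairwise co-occurrence randomization
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceResult:
    table: pd.DataFrame             # filtered table (false-positive guard applied)
    full_table: pd.DataFrame        # all tested pairs, with `dropped` column
    n_rand: int
    blocks: dict[str, frozenset[str]]

    def summary(self) -> str:
        sig = self.table[self.table["p"] < 0.05]
        lines = [
            "Pairwise co-occurrence randomization "
            f"({self.n_rand} replicates, {len(self.full_table)} comparisons)",
            f"  significant at p<0.05 (uncorrected): {len(sig)}",
        ]
        for _, row in sig.sort_values("p").head(10).iterrows():
            lines.append(
                f"    {row['a']} x {row['b']}: observed {row['observed']:g}, "
                f"expected {row['expected']:.1f}, p = {row['p']:.4g}")
        return "\n".join(lines)


class CooccurrenceTest:
    """Do pairs of de novo mutations attract or repel each other?

    Co-occurrence of a pair is counted at the isolate level (both present
    in at least one isolate) and tallied over wells.  Singleton mutations
    (one well) and reversions are removed first.  The null preserves each
    mutation's well count *and* its per-well isolate counts: a replicate
    re-places each mutation independently onto a random set of wells of the
    same size and then onto random isolates within those wells.  Two-tailed
    empirical p-values detect both repulsion and attraction.  Pairs with
    p < 0.05 but a single observed co-occurrence are dropped from the main
    table as the most obvious false positives.  No multiple-testing
    correction is applied to ``p``; a Benjamini-Hochberg column ``p_bh``
    is included as a labelled extension.
    """

    def __init__(self, dataset: Dataset, blocks: dict[str, set[str]] | None = None,
                 min_wells: int = 2, isolate_level_null: bool = False):
        self.dataset = dataset
        self.isolate_level_null = isolate_level_null
        X, iso_well = isolate_presence_matrix(dataset, include_reversions=False)
        well_counts = X.groupby(iso_well.to_numpy()).any().sum(axis=0)
        keep = well_counts[well_counts >= min_wells].index.tolist()
        if len(keep) < 2:
            raise ValueError("fewer than two non-singleton, non-reversion mutations")
        self.X = X[keep]
        self.iso_well = iso_well
        self.wells = list(dict.fromkeys(iso_well))
        self._well_rows = {w: np.flatnonzero(iso_well.to_numpy() == w)
                           for w in self.wells}
        if blocks is None:
            blocks = {"D-promoter": self._feature_block("D-promoter")}
        self.blocks = {name: frozenset(m) & set(keep)
                       for name, m in blocks.items()}
        self.blocks = {n: m for n, m in self.blocks.items() if len(m) >= 2}

    def _feature_block(self, feature_id: str) -> set[str]:
        return {k for k, rec in self.dataset.mutation_catalog.items()
                if feature_id in rec.features}

    # -- counting -----------------------------------------------------------

    def _augment(self, X: np.ndarray) -> np.ndarray:
        cols = [X]
        for members in self.blocks.values():
            idx = [self.X.columns.get_loc(m) for m in sorted(members)]
            cols.append(X[:, idx].any(axis=1, keepdims=True))
        return np.concatenate(cols, axis=1)

    def _count(self, X: np.ndarray) -> np.ndarray:
        """Well-level co-occurrence counts for the augmented column set.

        Entry [i, j] is the number of wells where identities i and j are
        carried together by >= 1 isolate; a block's diagonal entry counts
        wells where two *distinct* members share an isolate.
        """
        A = self._augment(X)
        k = A.shape[1]
        C = np.zeros((k, k), dtype=np.int64)
        for rows in self._well_rows.values():
            sub = A[rows].astype(np.int64)
            C += (sub.T @ sub) > 0
        # diagonals carry no pair information for plain mutations; a block's
        # diagonal is redefined as the count of wells where two *distinct*
        # members share an isolate
        for i in range(self.X.shape[1]):
            C[i, i] = 0
        for offset, members in enumerate(self.blocks.values()):
            bi = self.X.shape[1] + offset
            idx = [self.X.columns.get_loc(m) for m in sorted(members)]
            C[bi, bi] = sum(
                int((X[rows][:, idx].sum(axis=1) >= 2).any())
                for rows in self._well_rows.values())
        return C

    def _randomized(self, rng: np.random.Generator) -> np.ndarray:
        """One null replicate of the isolate x mutation matrix."""
        X0 = self.X.to_numpy()
        out = np.zeros_like(X0)
        n_wells = len(self.wells)
        iso_well = self.iso_well.to_numpy()
        for k in range(X0.shape[1]):
            col = X0[:, k]
            if self.isolate_level_null:
                out[rng.permutation(len(col))[:col.sum()], k] = True
                continue
            per_well = [int(col[rows].sum()) for rows in self._well_rows.values()]
            occupied = [c for c in per_well if c > 0]
            chosen = rng.choice(n_wells, size=len(occupied), replace=False)
            counts = rng.permutation(occupied)
            for w_i, c in zip(chosen, counts):
                rows = self._well_rows[self.wells[w_i]]
                pick = rng.choice(rows, size=min(int(c), len(rows)), replace=False)
                out[pick, k] = True
        return out

    def fit(self, n_rand: int = 1000, seed: int | None = None
            ) -> CooccurrenceResult:
        if n_rand < 100:
            warnings.warn(f"n_rand={n_rand} is small; p-values will be coarse")
        rng = np.random.default_rng(seed)
        X0 = self.X.to_numpy()
        obs = self._count(X0)

        ge = np.zeros_like(obs)
        le = np.zeros_like(obs)
        total = np.zeros(obs.shape, dtype=float)
        for _ in range(n_rand):
            C = self._count(self._randomized(rng))
            ge += C >= obs
            le += C <= obs
            total += C

        names = list(self.X.columns) + list(self.blocks)
        block_names = set(self.blocks)
        rows = []
        for i, j in combinations(range(len(names)), 2):
            a, b = names[i], names[j]
            if a in block_names or b in block_names:
                block, other = (a, b) if a in block_names else (b, a)
                if other in self.blocks[block]:
                    continue  # member-vs-own-block is not a meaningful pair
                a, b = block, other
            rows.append((a, b, obs[i, j], total[i, j] / n_rand,
                         ge[i, j], le[i, j]))
        for name in self.blocks:
            i = names.index(name)
            rows.append((name, name, obs[i, i], total[i, i] / n_rand,
                         ge[i, i], le[i, i]))

        df = pd.DataFrame(rows, columns=["a", "b", "observed", "expected",
                                         "n_ge", "n_le"])
        p_ge = (1 + df["n_ge"]) / (n_rand + 1)
        p_le = (1 + df["n_le"]) / (n_rand + 1)
        df["p"] = np.minimum(1.0, 2 * np.minimum(p_ge, p_le))
        df["dropped"] = (df["p"] < 0.05) & (df["observed"] == 1)
        df = df.drop(columns=["n_ge", "n_le"])
        kept = df[~df["dropped"]].drop(columns="dropped").reset_index(drop=True)
        # extension beyond the core test: BH-adjusted p-values
        kept["p_bh"] = false_discovery_control(kept["p"], method="bh")
        return CooccurrenceResult(table=kept, full_table=df, n_rand=n_rand,
                                  blocks=dict(self.blocks))


def cooccurrence_test(dataset: Dataset, n_rand: int = 1000,
                      seed: int | None = None,
                      blocks: dict[str, set[str]] | None = None
                      ) -> CooccurrenceResult:
    return CooccurrenceTest(dataset, blocks=blocks).fit(n_rand, seed)
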