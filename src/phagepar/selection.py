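"""Selection-coefficient estimation from competition trajectories and
time-to-lysis curve summaries.

The selection coefficient s of a mutant competed against a reference is the
per-generation slope of ln(mutant frequency) against generation number.
Each replicate trajectory is fitted separately by ordinary least squares
and the replicate slopes are averaged; the SE is taken across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FrequencyTrajectory:
    """Mutant-frequency observations for one competition replicate.

    ``observations`` is a list of (passage, mutant_frequency) pairs with
    strictly increasing passages; frequencies must lie strictly inside
    (0, 1) for the log transform.
    """

    replicate_id: str
    observations: list[tuple[float, float]]
    initial_ratio: str = ""

    def __post_init__(self):
        passages = [p for p, _ in self.observations]
        if any(b <= a for a, b in zip(passages, passages[1:])):
            raise ValueError(
                f"replicate {self.replicate_id}: passages must be increasing")


@dataclass
class SelectionEstimate:
    s: float                        # mean of per-replicate slopes
    se: float
    per_replicate: pd.Series
    generations_per_passage: float
    excluded: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            "Selection coefficient (log-linear regression per replicate)",
            f"  generations per passage: {self.generations_per_passage:g}",
            f"  replicates used: {len(self.per_replicate)}"
            + (f" (excluded: {', '.join(self.excluded)})" if self.excluded else ""),
            f"  s = {self.s:.4f} +/- {self.se:.4f} per generation",
        ]
        return "\n".join(lines)


def estimate_selection(trajectories: list[FrequencyTrajectory],
                       generations_per_passage: float = 2.0
                       ) -> SelectionEstimate:
    """Average per-replicate OLS slope of ln frequency on generation."""
    slopes = {}
    excluded = []
    for tr in trajectories:
        passages = np.array([p for p, _ in tr.observations], dtype=float)
        freqs = np.array([f for _, f in tr.observations], dtype=float)
        if np.any((freqs <= 0) | (freqs >= 1)):
            warnings.warn(
                f"replicate {tr.replicate_id}: boundary frequency, excluded")
            excluded.append(tr.replicate_id)
            continue
        if len(passages) < 2:
            warnings.warn(
                f"replicate {tr.replicate_id}: fewer than two points, excluded")
            excluded.append(tr.replicate_id)
            continue
        gens = passages * generations_per_passage
        slope = np.polyfit(gens, np.log(freqs), 1)[0]
        slopes[tr.replicate_id] = slope
    if not slopes:
        raise ValueError("no usable replicates")
    per = pd.Series(slopes)
    se = per.std(ddof=1) / np.sqrt(len(per)) if len(per) > 1 else np.nan
    return SelectionEstimate(s=float(per.mean()), se=float(se),
                             per_replicate=per,
                             generations_per_passage=generations_per_passage,
                             excluded=tuple(excluded))


def read_trajectories(path) -> list[FrequencyTrajectory]:
    """Read a TSV with columns replicate_id, passage, mutant_frequency."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for rid, g in df.groupby("replicate_id", sort=True):
        g = g.sort_values("passage")
        out.append(FrequencyTrajectory(
            str(rid), list(zip(g["passage"], g["mutant_frequency"]))))
    return out


# ---------------------------------------------------------------------------
# Time-to-lysis curves
# ---------------------------------------------------------------------------

@dataclass
class LysisCurve:
    genotype: str
    times: np.ndarray
    mean_burst: np.ndarray
    se_burst: np.ndarray            # NaN where < 2 replicates
    lysis_time: float               # NaN when no rise detected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times,
                             "mean_burst": self.mean_burst,
                             "se_burst": self.se_burst})


@dataclass
class LysisSummary:
    curves: dict[str, LysisCurve]
    delays: pd.DataFrame            # pairwise lysis-time differences (row - col)
    rise_multiple: float
    baseline_points: int

    @property
    def lysis_times(self) -> pd.Series:
        return pd.Series({g: c.lysis_time for g, c in self.curves.items()})

    def summary(self) -> str:
        lines = [f"Time-to-lysis summary (rise threshold = "
                 f"{self.rise_multiple:g} x baseline of first "
                 f"{self.baseline_points} points)"]
        for g, t in self.lysis_times.items():
            lines.append(f"  {g}: lysis at "
                         + (f"{t:g} min" if np.isfinite(t) else "not detected"))
        return "\n".join(lines)


def summarize_lysis(burst_counts: pd.DataFrame, rise_multiple: float = 2.0,
                    baseline_points: int = 5) -> LysisSummary:
    """Per-genotype mean/SE burst curves and lysis-time delays.

    ``burst_counts`` has columns genotype, time_min, replicate, burst.
    The lysis time is the first time point whose mean burst exceeds
    ``rise_multiple`` times the baseline (the mean over the first
    ``baseline_points`` time points) — "when titer begins to rise" made
    operational; the threshold is reported alongside the estimates.
    Delays are differences of lysis times between genotypes sharing the
    assay's time grid.
    """
    required = {"genotype", "time_min", "replicate", "burst"}
    if not required <= set(burst_counts.columns):
        raise ValueError(f"burst table must have columns {sorted(required)}")
    curves = {}
    for g, sub in burst_counts.groupby("genotype", sort=True):
        agg = sub.groupby("time_min")["burst"].agg(["mean", "std", "count"])
        agg = agg.sort_index()
        se = np.where(agg["count"] >= 2,
                      agg["std"] / np.sqrt(agg["count"]), np.nan)
        baseline = agg["mean"].iloc[:baseline_points].mean()
        above = agg.index[agg["mean"] > rise_multiple * baseline]
        lysis_time = float(above[0]) if len(above) else float("nan")
        curves[g] = LysisCurve(g, agg.index.to_numpy(dtype=float),
                               agg["mean"].to_numpy(), se, lysis_time)
    genotypes = list(curves)
    times = pd.Series({g: curves[g].lysis_time for g in genotypes})
    delays = pd.DataFrame(
        times.to_numpy()[:, None] - times.to_numpy()[None, :],
        index=genotypes, columns=genotypes)
    return LysisSummary(curves, delays, rise_multiple, baseline_points)
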