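"""Post-run docking analytics.

Covers the standard evaluation battery for repeated docking runs: RMSD-based
success counting against a reference pose (2.0 Å threshold by convention),
energy-ordered leader clustering of docked conformations with rank-1
reporting, Tukey five-number summaries with IQR outliers, convergence tables,
and a pairwise one-sided Mann–Whitney comparison matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genome import rmsd

__all__ = [
    "Cluster",
    "ClusterReport",
    "SuccessSummary",
    "FiveNumberSummary",
    "cluster_conformations",
    "success_summary",
    "distribution_summary",
    "convergence_table",
    "mann_whitney_matrix",
    "plot_convergence",
    "plot_energy_boxes",
]


@dataclass
class Cluster:
    """One conformational cluster: member pose indices and its lowest energy."""

    members: list[int]
    lowest_energy: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterReport:
    """Clusters sorted by lowest member energy; rank 1 is the first cluster."""

    clusters: list[Cluster]
    rmsd_tolerance: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def rank1(self) -> Cluster | None:
        return self.clusters[0] if self.clusters else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.clusters) + 1),
                "size": [c.size for c in self.clusters],
                "lowest_energy": [c.lowest_energy for c in self.clusters],
                "members": [",".join(map(str, c.members)) for c in self.clusters],
            }
        )


def cluster_conformations(poses: list[np.ndarray], energies: list[float],
                          rmsd_tol: float = 2.0) -> ClusterReport:
    """Energy-ordered leader clustering of docked conformations.

    Poses are processed by ascending energy (ties broken by input index); a
    pose joins the first existing cluster whose *seed* (lowest-energy member)
    lies within ``rmsd_tol``, otherwise it seeds a new cluster.  Clusters come
    out sorted by their lowest member energy, so the first cluster (rank 1)
    always contains the global minimum-energy pose.
    """
    if rmsd_tol <= 0:
        raise ValueError("rmsd_tol must be positive")
    if len(poses) != len(energies):
        raise ValueError("poses and energies must have equal length")
    if not poses:
        return ClusterReport([], rmsd_tol)
    order = sorted(range(len(poses)), key=lambda i: (energies[i], i))
    seeds: list[np.ndarray] = []
    clusters: list[Cluster] = []
    for i in order:
        for seed_pose, cluster in zip(seeds, clusters):
            if rmsd(poses[i], seed_pose) < rmsd_tol:
                cluster.members.append(i)
                break
        else:
            seeds.append(np.asarray(poses[i]))
            clusters.append(Cluster([i], float(energies[i])))
    return ClusterReport(clusters, rmsd_tol)


@dataclass
class SuccessSummary:
    """Docking success statistics over repeated runs.

    ``mean_rmsd_success`` is ``None`` (not 0) when no run succeeded.
    """

    n_runs: int
    n_success: int
    mean_rmsd_all: float
    mean_rmsd_success: float | None
    rmsds: list[float] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_runs if self.n_runs else 0.0


def success_summary(poses: list[np.ndarray], reference: np.ndarray,
                    rmsd_tol: float = 2.0) -> SuccessSummary:
    """Count successful redockings: RMSD to the reference strictly below
    ``rmsd_tol`` (2.0 Å docking convention).  Averages are reported over all
    runs and over the successful subset."""
    if not poses:
        raise ValueError("no poses to summarize")
    ref = np.asarray(reference, dtype=float)
    rmsds = [rmsd(p, ref) for p in poses]
    hits = [r for r in rmsds if r < rmsd_tol]
    return SuccessSummary(
        n_runs=len(poses),
        n_success=len(hits),
        mean_rmsd_all=float(np.mean(rmsds)),
        mean_rmsd_success=float(np.mean(hits)) if hits else None,
        rmsds=rmsds,
    )


@dataclass
class FiveNumberSummary:
    """Tukey box-plot statistics of an energy sample."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def distribution_summary(energies: list[float]) -> FiveNumberSummary:
    """Five-number summary plus 1.5-IQR outliers.

    Quartiles use linear interpolation between order statistics; whiskers end
    at the most extreme data points within ``Q1 - 1.5 IQR`` / ``Q3 + 1.5 IQR``
    and everything beyond them is flagged as an outlier.
    """
    x = np.asarray(energies, dtype=float)
    if x.size == 0:
        raise ValueError("empty energy list")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return FiveNumberSummary(
        minimum=float(x.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=float(x.max()),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def convergence_table(traces: dict[str, list[list[float]]],
                      checkpoints: list[int]) -> pd.DataFrame:
    """Mean best-so-far energy per algorithm at chosen generation checkpoints.

    ``traces`` maps an algorithm label to its per-run traces; traces shorter
    than a checkpoint contribute their final (converged) value.
    """
    rows = []
    for label, runs in traces.items():
        for g in checkpoints:
            vals = [t[min(g, len(t) - 1)] for t in runs if t]
            rows.append({"algorithm": label, "generation": g,
                         "mean_best_energy": float(np.mean(vals))})
    return pd.DataFrame(rows)


def mann_whitney_matrix(samples: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise one-sided Mann–Whitney p-values.

    Entry (A, B) tests the alternative that A's energies are stochastically
    *lower* (better) than B's.  This is offered as a generic nonparametric
    comparison utility; it is one reasonable choice of test, not the only one.
    """
    names = list(samples)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for a in names:
        for b in names:
            if a == b:
                continue
            stat = mannwhitneyu(samples[a], samples[b], alternative="less")
            mat.loc[a, b] = stat.pvalue
    return mat


def plot_convergence(table: pd.DataFrame, path: str) -> None:
    """Render a convergence diagram (mean best energy vs generation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in table.groupby("algorithm"):
        ax.plot(grp["generation"], grp["mean_best_energy"], marker="o",
                label=str(label))
    ax.set_xlabel("generation")
    ax.set_ylabel("mean best energy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_energy_boxes(samples: dict[str, list[float]], path: str) -> None:
    """Render per-algorithm energy box plots (Tukey whiskers)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(list(samples.values()), tick_labels=list(samples.keys()))
    ax.set_ylabel("energy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
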