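"""Cohort-level statistics on per-person Gamma-plane signatures.

Given each person's (shape, scale) point from their speed-peak
distribution, this module fits the shape-scale power relation y = a x^b
(by nonlinear least squares in original coordinates, log-log initialized),
blindly partitions the cohort with k = 2 city-block k-means (component-wise
median centroids, i.e. L1 k-medians), regresses each patient's Fano factor
on their L1 distance to the normal-control cluster centroid, regresses age
on shape within groups, and compares groups with Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CohortScatter",
    "PowerFit",
    "LinearFit",
    "ClusterResult",
    "fit_power_law",
    "kmeans_cityblock",
    "centroid_distances",
    "linear_fit",
    "ranksum_test",
    "cohort_report",
]

_NC, _PD = "NC", "PD"


@dataclass
class CohortScatter:
    """Per-person signature points with veridical labels and covariates."""

    participant_ids: list[str]
    points: np.ndarray  # (n, 2): (shape, scale) of each person's peak fit
    labels: list[str]  # "NC" | "PD"
    ages: np.ndarray
    max_shifts: np.ndarray
    years_since_diagnosis: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.max_shifts = np.asarray(self.max_shifts, dtype=float)
        n = len(self.participant_ids)
        if self.points.shape != (n, 2):
            raise ValueError("points must be (n, 2)")
        if np.any(self.points <= 0):
            raise ValueError("signature points must be strictly positive")
        bad = set(self.labels) - {_NC, _PD}
        if bad:
            raise ValueError(f"labels must be NC or PD, got {bad}")
        if len(self.labels) != n or len(self.ages) != n or len(self.max_shifts) != n:
            raise ValueError("all per-person columns must have equal length")

    @property
    def fano(self) -> np.ndarray:
        """Fano factor of each person's peak distribution = its Gamma scale."""
        return self.points[:, 1]

    def subset(self, label: str) -> np.ndarray:
        return np.asarray([lab == label for lab in self.labels])


@dataclass(frozen=True)
class PowerFit:
    """y = coefficient * x**exponent, least squares on the original scale."""

    coefficient: float
    exponent: float
    ci_coefficient: tuple[float, float]
    ci_exponent: tuple[float, float]
    sse: float
    r_squared: float
    adj_r_squared: float
    rmse: float
    n: int


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least squares y = slope * x + intercept."""

    slope: float
    intercept: float
    ci_slope: tuple[float, float]
    ci_intercept: tuple[float, float]
    sse: float
    r_squared: float
    adj_r_squared: float
    rmse: float
    n: int


@dataclass
class ClusterResult:
    """k-medians outcome: assignments, centroids, cost, label disagreement."""

    assignments: np.ndarray
    centroids: np.ndarray
    cost: float
    cost_history: list[float] = field(default_factory=list)
    misclassified_ids: list[str] = field(default_factory=list)
    nc_cluster: int = -1


def _gof(y: np.ndarray, resid: np.ndarray, n_params: int) -> tuple[float, float, float, float]:
    """SSE, R^2, adjusted R^2 (n-1 over n-p), RMSE with n-p denominator."""
    n = y.size
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)
    rmse = math.sqrt(sse / (n - n_params))
    return sse, r2, adj, rmse


def fit_power_law(points) -> PowerFit:
    """Fit y = a x^b by nonlinear least squares in original coordinates.

    The log-log OLS line provides the initial guess; confidence intervals
    are Jacobian-based asymptotics with a t(n-2) quantile, matching the
    conventions of standard curve-fitting tools.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) pairs")
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 points")
    if np.any(pts <= 0):
        raise ValueError("power-law fit needs strictly positive data")
    x, y = pts[:, 0], pts[:, 1]

    b0, log_a0 = np.polyfit(np.log(x), np.log(y), 1)
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, a, b: a * np.power(x, b),
            x,
            y,
            p0=[math.exp(log_a0), b0],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"power-law fit did not converge: {exc}") from exc
    a, b = popt
    resid = y - a * x**b
    sse, r2, adj, rmse = _gof(y, resid, 2)
    tq = stats.t.ppf(0.975, len(x) - 2)
    se = np.sqrt(np.diag(pcov))
    return PowerFit(
        coefficient=float(a),
        exponent=float(b),
        ci_coefficient=(float(a - tq * se[0]), float(a + tq * se[0])),
        ci_exponent=(float(b - tq * se[1]), float(b + tq * se[1])),
        sse=sse,
        r_squared=r2,
        adj_r_squared=adj,
        rmse=rmse,
        n=len(x),
    )


def _l1(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    return np.abs(points[:, None, :] - centroids[None, :, :]).sum(axis=2)


def kmeans_cityblock(
    points, k: int = 2, restarts: int = 50, seed: int = 0, max_iter: int = 200
) -> ClusterResult:
    """Lloyd iterations with L1 assignment and component-wise-median update.

    The median minimizes within-cluster L1 cost, so the total cost is
    non-increasing across iterations (recorded in ``cost_history`` of the
    winning run).  Best of ``restarts`` random initializations, each
    seeded from ``seed``; ties in assignment go to the lower cluster index.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2:
        raise ValueError("points must be 2-D (n, d)")
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need >= {k} points, got {n}")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"fewer than {k} distinct points; clusters degenerate")
    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(restarts):
        # sample distinct rows as initial centroids
        cen = X[rng.choice(n, size=k, replace=False)].astype(float)
        assign = np.full(n, -1)
        history: list[float] = []
        for _it in range(max_iter):
            d = _l1(X, cen)
            new_assign = d.argmin(axis=1)
            # keep every cluster non-empty: give an empty cluster the point
            # farthest from its nearest centroid
            for j in range(k):
                if not np.any(new_assign == j):
                    new_assign[d.min(axis=1).argmax()] = j
            history.append(float(np.abs(X - cen[new_assign]).sum()))
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for j in range(k):
                cen[j] = np.median(X[assign == j], axis=0)
        cost = float(np.abs(X - cen[assign]).sum())
        if best is None or cost < best.cost:
            best = ClusterResult(
                assignments=assign.copy(),
                centroids=cen.copy(),
                cost=cost,
                cost_history=history,
            )
    assert best is not None
    return best


def centroid_distances(points, centroid) -> np.ndarray:
    """City-block (L1) distance from each point to one centroid."""
    X = np.asarray(points, dtype=float)
    c = np.asarray(centroid, dtype=float)
    if X.shape[-1] != c.shape[-1]:
        raise ValueError("centroid dimension mismatch")
    return np.abs(X - c).sum(axis=-1)


def linear_fit(x, y) -> LinearFit:
    """OLS line with t(n-2) confidence intervals and 2-parameter GOF stats."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (x, y) pairs of equal length")
    if np.ptp(x) == 0:
        raise ValueError("singular design: x is constant")
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = beta
    resid = y - X @ beta
    sse, r2, adj, rmse = _gof(y, resid, 2)
    n = x.size
    sigma2 = sse / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    tq = stats.t.ppf(0.975, n - 2)
    se_s, se_i = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        ci_slope=(float(slope - tq * se_s), float(slope + tq * se_s)),
        ci_intercept=(float(intercept - tq * se_i), float(intercept + tq * se_i)),
        sse=sse,
        r_squared=r2,
        adj_r_squared=adj,
        rmse=rmse,
        n=int(n),
    )


def ranksum_test(sample_x, sample_y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact by full enumeration over rank assignments when both samples have
    <= 10 observations (mid-ranks for ties, so identical samples give
    p = 1); otherwise the normal approximation with tie correction.
    Returns (rank-sum statistic of sample_x, p-value).
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # mid-ranks for ties
    w_obs = float(ranks[:nx].sum())
    if nx <= 10 and ny <= 10:
        mu = ranks.sum() * nx / (nx + ny)
        d_obs = abs(w_obs - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(nx + ny), nx):
            w = ranks[list(combo)].sum()
            if abs(w - mu) >= d_obs - 1e-12:
                count += 1
            total += 1
        return w_obs, count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w_obs, float(res.pvalue)


def _fit_dict(fit) -> dict:
    return asdict(fit)


def cohort_report(
    scatter: CohortScatter,
    k: int = 2,
    restarts: int = 50,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Full cohort analysis: the validation battery over one scatter.

    Produces group medians/ranges of Fano factor and max shift, power fits
    (full cohort and per group), the k = 2 L1 clustering with its
    misclassification against veridical labels, the patient
    Fano-vs-distance-to-NC-centroid regression, age-on-shape regressions
    per group, and rank-sum group comparisons.  Analyses whose group has
    fewer than 3 members are skipped with a warning.
    """
    nc_mask = scatter.subset(_NC)
    pd_mask = scatter.subset(_PD)
    report: dict = {"n": len(scatter.participant_ids)}

    def _summary(v: np.ndarray) -> dict:
        return {
            "median": float(np.median(v)),
            "min": float(v.min()),
            "max": float(v.max()),
        }

    report["fano"] = {
        "NC": _summary(scatter.fano[nc_mask]) if nc_mask.any() else None,
        "PD": _summary(scatter.fano[pd_mask]) if pd_mask.any() else None,
        "all": _summary(scatter.fano),
    }
    report["max_shift"] = {
        "NC": _summary(scatter.max_shifts[nc_mask]) if nc_mask.any() else None,
        "PD": _summary(scatter.max_shifts[pd_mask]) if pd_mask.any() else None,
        "all": _summary(scatter.max_shifts),
    }

    report["power_fit"] = {}
    for name, mask in (("cohort", np.ones(len(scatter.points), bool)), ("NC", nc_mask), ("PD", pd_mask)):
        if mask.sum() >= 3:
            report["power_fit"][name] = _fit_dict(fit_power_law(scatter.points[mask]))
        else:
            warnings.warn(f"power fit for {name} skipped: < 3 members", stacklevel=2)
            report["power_fit"][name] = None

    cluster = kmeans_cityblock(scatter.points, k=k, restarts=restarts, seed=seed)
    # the NC cluster is the one holding the majority of veridical NC people
    nc_counts = np.bincount(cluster.assignments[nc_mask], minlength=k)
    nc_cluster = int(nc_counts.argmax())
    predicted_nc = cluster.assignments == nc_cluster
    mis = [
        pid
        for pid, pred, is_nc in zip(
            scatter.participant_ids, predicted_nc, nc_mask, strict=True
        )
        if pred != is_nc
    ]
    cluster.misclassified_ids = mis
    cluster.nc_cluster = nc_cluster
    report["clustering"] = {
        "assignments": cluster.assignments.tolist(),
        "centroids": cluster.centroids.tolist(),
        "nc_cluster": nc_cluster,
        "cost": cluster.cost,
        "misclassified_ids": mis,
        "n_misclassified": len(mis),
    }

    nc_centroid = cluster.centroids[nc_cluster]
    pd_dist = centroid_distances(scatter.points[pd_mask], nc_centroid)
    report["pd_distance_to_nc_centroid"] = {
        "participant_ids": [
            pid for pid, m in zip(scatter.participant_ids, pd_mask) if m
        ],
        "distances": pd_dist.tolist(),
    }
    if pd_mask.sum() >= 3:
        report["fano_vs_distance_PD"] = _fit_dict(
            linear_fit(pd_dist, scatter.fano[pd_mask])
        )
    else:
        report["fano_vs_distance_PD"] = None

    report["age_vs_shape"] = {}
    for name, mask in (("NC", nc_mask), ("PD", pd_mask)):
        if mask.sum() >= 3:
            report["age_vs_shape"][name] = _fit_dict(
                linear_fit(scatter.points[mask, 0], scatter.ages[mask])
            )
        else:
            report["age_vs_shape"][name] = None

    if nc_mask.any() and pd_mask.any():
        stat_f, p_f = ranksum_test(scatter.fano[nc_mask], scatter.fano[pd_mask])
        stat_m, p_m = ranksum_test(
            scatter.max_shifts[nc_mask], scatter.max_shifts[pd_mask]
        )
        report["ranksum"] = {
            "fano_NC_vs_PD": {"statistic": stat_f, "p": p_f},
            "max_shift_NC_vs_PD": {"statistic": stat_m, "p": p_m},
        }
    else:
        report["ranksum"] = None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "cohort_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        pd.DataFrame(
            {
                "participant": scatter.participant_ids,
                "shape": scatter.points[:, 0],
                "scale": scatter.points[:, 1],
                "label": scatter.labels,
                "age": scatter.ages,
                "fano": scatter.fano,
                "max_shift": scatter.max_shifts,
                "cluster": cluster.assignments,
            }
        ).to_csv(out / "cohort_scatter.csv", index=False)
    return report
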