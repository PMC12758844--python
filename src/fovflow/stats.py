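"""Group-level significance machinery.

Three tools used throughout the pipeline: one-sample t-tests against a
null level (chance accuracy, GC baseline, zero correlation),
Benjamini-Hochberg FDR with an explicit family size (the laminar
analysis corrects each task's layer x ROI x feature grid as one family
of 24 tests), and the nonparametric cluster-based sign-flip permutation
test for time-resolved effects, where contiguous suprathreshold time
points form clusters whose summed t-statistic is compared with the
max-cluster null distribution obtained by randomly flipping each
subject's effect sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    t: float
    df: int
    p: float
    tail: str
    q: float | None = None


@dataclass
class Cluster:
    t_start: float
    t_end: float
    mass: float
    p_corrected: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    cluster_forming_p: float
    corrected_p: float
    n_permutations: int
    tail: str
    seed: int | None
    t_values: np.ndarray
    times: np.ndarray

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < self.corrected_p]


def one_sample_t(values: np.ndarray, mu: float = 0.0,
                 tail: str = "two") -> TestResult:
    """One-sample t-test of ``values`` against ``mu``.

    tail="one" tests mean > mu; tail="two" is the ordinary two-sided
    test. Zero-variance samples are an error (t undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 values")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance sample")
    n = x.size
    t = (x.mean() - mu) / (x.std(ddof=1) / np.sqrt(n))
    df = n - 1
    p = sps.t.sf(t, df) if tail == "one" else 2 * sps.t.sf(abs(t), df)
    return TestResult(t=float(t), df=df, p=float(p), tail=tail)


def fdr_bh(pvals: np.ndarray, m: int | None = None,
           alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values with explicit family size.

    ``m`` defaults to ``len(pvals)`` but may be larger, allowing a subset
    of a declared test family to be corrected against the full family
    size. Returns (q values, rejection mask at q < ``alpha``).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("family size m must be >= len(pvals)")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw_q = ranked * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(raw_q[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q, q < alpha


def _t_rows(data: np.ndarray) -> np.ndarray:
    """Per-column one-sample t across rows (subjects)."""
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return m / (sd / np.sqrt(n))


def _clusters_from_t(t: np.ndarray, t_crit: float,
                     tail: str) -> list[tuple[int, int, float]]:
    """Maximal runs of suprathreshold time points: (start, stop, mass).

    For the two-tailed test positive and negative excursions form
    separate clusters; mass is the sum of t over the run.
    """
    out = []
    if tail == "one":
        masks = [t > t_crit]
    else:
        masks = [t > t_crit, t < -t_crit]
    for mask in masks:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.r_[idx[0], idx[breaks + 1]]
        stops = np.r_[idx[breaks], idx[-1]]
        for a, b in zip(starts, stops):
            out.append((int(a), int(b), float(t[a:b + 1].sum())))
    out.sort(key=lambda c: c[0])
    return out


def cluster_permutation(subject_courses: np.ndarray, *,
                        times: np.ndarray | None = None,
                        null_value: float = 0.0, n_perm: int = 50000,
                        cluster_forming_p: float = 0.01,
                        corrected_p: float = 0.01, tail: str = "one",
                        seed=0) -> ClusterResult:
    """Cluster-based sign-flip permutation test over time.

    ``subject_courses`` is a subject x time effect matrix; effects are
    tested against ``null_value``. Clusters are maximal runs of time
    points whose per-time one-sample t passes ``cluster_forming_p`` at
    the stated tail; the cluster statistic is the summed t. The null
    distribution is the maximum cluster statistic under random whole-
    time-course sign flips per subject; cluster p-values use the +1
    correction so they are never exactly zero.
    """
    data = np.asarray(subject_courses, dtype=float) - null_value
    n_sub, n_time = data.shape
    if n_sub < 5:
        raise ValueError("need >= 5 subjects")
    if n_perm < 100:
        raise ValueError("insufficient permutations (need >= 100)")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if times is None:
        times = np.arange(n_time, dtype=float)
    rng = np.random.default_rng(seed)
    df = n_sub - 1
    t_crit = (sps.t.isf(cluster_forming_p, df) if tail == "one"
              else sps.t.isf(cluster_forming_p / 2, df))

    t_obs = _t_rows(data)
    obs_clusters = _clusters_from_t(t_obs, t_crit, tail)

    # vectorized sign-flip t statistics, chunked to bound memory
    ss = (data ** 2).sum(axis=0)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        r = min(5000, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(r, n_sub))
        m = signs @ data / n_sub
        var = (ss[None, :] - n_sub * m ** 2) / df
        var = np.maximum(var, 1e-300)
        t_perm = m / np.sqrt(var / n_sub)
        for i in range(r):
            cl = _clusters_from_t(t_perm[i], t_crit, tail)
            stat = max((abs(c[2]) for c in cl), default=0.0)
            null_max[done + i] = stat
        done += r

    clusters = []
    for a, b, mass in obs_clusters:
        p = (1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)
        clusters.append(Cluster(t_start=float(times[a]),
                                t_end=float(times[b]), mass=mass,
                                p_corrected=float(p)))
    return ClusterResult(clusters=clusters,
                         cluster_forming_p=cluster_forming_p,
                         corrected_p=corrected_p, n_permutations=n_perm,
                         tail=tail, seed=seed, t_values=t_obs,
                         times=np.asarray(times, dtype=float))
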