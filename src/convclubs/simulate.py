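"""Synthetic panels from the time-varying factor model, with planted clubs.

Panels are generated directly on the analysis (log) scale from

    X_it = delta_it * mu_t,
    delta_it = delta_i + sigma_i * xi_it / (L(t) * t^alpha),

with a common trend mu_t, standard-normal noise xi_it, and the slowly varying
function L(t) = log t (L(1) is replaced by L(2), since log 1 = 0 makes the
loading noise scale undefined at the first period).  Units in the same club
share the limit delta_i, so with alpha > 0 their loadings — and hence their
relative transition paths — converge.  Divergent units receive unit-specific
limits plus small per-period drift offsets, the minimal structure under the
alternative hypothesis that no common limit exists.

Because the club structure is known exactly, the generator turns the test and
the clustering algorithm into checkable procedures: size and power of the
one-sided test, and partition recovery of the classifier, can be measured by
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clubs import ClubConvergence, ClubPartition
from .logt import DEFAULT_CRITICAL, fit_logt
from .panel import PanelData, PanelError

__all__ = [
    "ClubSpec",
    "DivergentSpec",
    "FactorModelSpec",
    "generate_panel",
    "recovery_score",
    "run_power_study",
    "study_scale_spec",
]


@dataclass(frozen=True)
class ClubSpec:
    """One planted club: ``size`` units sharing limit ``delta`` with noise
    scale ``sigma`` (>= 0; zero gives the noise-free factor structure)."""

    size: int
    delta: float
    sigma: float = 0.05


@dataclass(frozen=True)
class DivergentSpec:
    """One planted divergent unit: its own limit ``delta`` plus a per-period
    ``drift`` added to the loading, so it shares a limit with nobody."""

    delta: float
    drift: float
    sigma: float = 0.05


@dataclass(frozen=True)
class FactorModelSpec:
    """Parameters of the synthetic factor-model panel.

    Parameters
    ----------
    n_periods : int
        Panel length T (>= 5).
    clubs : tuple of ClubSpec
        Planted convergence clubs; all members of a club share delta.
    divergent : tuple of DivergentSpec
        Planted divergent units (may be empty).
    alpha : float, default 0.5
        Decay exponent of the loading noise; alpha > 0 yields within-club
        convergence at rate t^-alpha / log t.
    trend : {"linear_drift", "random_walk_drift"}
        Common trend mu_t: deterministic drift from level 1, or a random walk
        with the same drift plus small Gaussian innovations.
    drift : float, default 0.02
        Trend increment per period (log-income-like growth).
    seed : int, default 0
        Seeds every random stream; streams are split per unit so the draw for
        a unit does not depend on how many units precede it.
    """

    n_periods: int
    clubs: tuple[ClubSpec, ...]
    divergent: tuple[DivergentSpec, ...] = ()
    alpha: float = 0.5
    trend: str = "linear_drift"
    drift: float = 0.02
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "clubs", tuple(self.clubs))
        object.__setattr__(self, "divergent", tuple(self.divergent))
        if self.n_periods < 5:
            raise PanelError("n_periods must be >= 5")
        if not self.clubs and not self.divergent:
            raise PanelError("spec must plant at least one club or divergent unit")
        if any(c.size < 1 for c in self.clubs):
            raise PanelError("club sizes must be >= 1")
        if any(c.sigma < 0 for c in self.clubs) or \
                any(d.sigma < 0 for d in self.divergent):
            raise PanelError("noise scales sigma must be >= 0")
        if self.trend not in ("linear_drift", "random_walk_drift"):
            raise PanelError(f"unknown trend {self.trend!r}")

    @property
    def n_units(self) -> int:
        return sum(c.size for c in self.clubs) + len(self.divergent)


def _loading_noise_scale(T: int, alpha: float) -> np.ndarray:
    """sigma_it / sigma_i = 1 / (L(t) t^alpha) with L(t) = log t, L(1) := L(2)."""
    t = np.arange(1, T + 1, dtype=float)
    L = np.log(t)
    L[0] = np.log(2.0)
    return 1.0 / (L * t ** alpha)


def _common_trend(spec: FactorModelSpec, rng: np.random.Generator) -> np.ndarray:
    T = spec.n_periods
    if spec.trend == "linear_drift":
        return 1.0 + spec.drift * np.arange(T, dtype=float)
    steps = spec.drift + 0.25 * spec.drift * rng.standard_normal(T - 1)
    return np.concatenate([[1.0], 1.0 + np.cumsum(steps)])


def generate_panel(spec: FactorModelSpec,
                   start_year: int = 2000) -> tuple[PanelData, dict[str, int]]:
    """Simulate one panel and return it with its planted labels.

    Returns
    -------
    panel : PanelData
        Log-scale panel of shape (N, T); ids are ``U01``, ``U02``, ...
        numbered club by club, divergent units last.
    truth : dict
        Map from unit id to its planted label: 1, 2, ... for clubs (in spec
        order), 0 for divergent units.

    Notes
    -----
    Identical spec (including seed) gives a bit-identical panel.
    """
    T = spec.n_periods
    N = spec.n_units
    children = np.random.SeedSequence(spec.seed).spawn(N + 1)
    mu = _common_trend(spec, np.random.default_rng(children[0]))
    scale = _loading_noise_scale(T, spec.alpha)

    values = np.empty((N, T))
    ids: list[str] = []
    truth: dict[str, int] = {}
    width = max(2, len(str(N)))
    unit = 0
    for label, club in enumerate(spec.clubs, start=1):
        for _ in range(club.size):
            rng = np.random.default_rng(children[unit + 1])
            xi = rng.standard_normal(T)
            delta_it = club.delta + club.sigma * xi * scale
            uid = f"U{unit + 1:0{width}d}"
            values[unit] = delta_it * mu
            ids.append(uid)
            truth[uid] = label
            unit += 1
    for div in spec.divergent:
        rng = np.random.default_rng(children[unit + 1])
        xi = rng.standard_normal(T)
        delta_it = (div.delta + div.drift * np.arange(T, dtype=float)
                    + div.sigma * xi * scale)
        uid = f"U{unit + 1:0{width}d}"
        values[unit] = delta_it * mu
        ids.append(uid)
        truth[uid] = 0
        unit += 1

    panel = PanelData(values=values, ids=ids,
                      years=list(range(start_year, start_year + T)), scale="log")
    return panel, truth


def study_scale_spec(seed: int = 0) -> FactorModelSpec:
    """A 44 x 17 panel shaped like the Sub-Saharan study: three well-separated
    clubs of 12, 14 and 14 units plus 4 divergent units.

    Club limits are separated by several within-club noise standard
    deviations, the regime in which the classifier should recover the
    planted structure; the divergent units sit away from every club limit
    and drift further away over the sample.
    """
    return FactorModelSpec(
        n_periods=17,
        clubs=(ClubSpec(12, 1.60, 0.05),
               ClubSpec(14, 1.00, 0.05),
               ClubSpec(14, 0.60, 0.05)),
        divergent=(DivergentSpec(2.80, 0.040),
                   DivergentSpec(0.12, -0.004),
                   DivergentSpec(2.10, 0.020),
                   DivergentSpec(0.35, -0.010)),
        alpha=0.5,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# recovery metric

def _labels_from_partition(partition, ids: list[str]) -> np.ndarray:
    if isinstance(partition, ClubPartition):
        mapping = {u: partition.club_of(u) for u in partition.all_ids()}
    elif isinstance(partition, dict):
        mapping = partition
    else:
        raise TypeError("partition must be a ClubPartition or an id -> label dict")
    try:
        return np.array([mapping[u] for u in ids])
    except KeyError as exc:
        raise PanelError(f"partition is missing unit {exc.args[0]!r}") from None


def recovery_score(true_partition, estimated) -> float:
    """Adjusted agreement (adjusted Rand index) between two partitions.

    Both arguments may be :class:`ClubPartition` objects or ``id -> label``
    dicts.  The divergent group counts as one extra block.  The score is 1
    exactly when the partitions coincide up to club relabelling, is ~0 for
    independent random partitions, and can be negative for systematic
    disagreement.
    """
    from sklearn.metrics import adjusted_rand_score

    a = true_partition if isinstance(true_partition, dict) else None
    ids_true = set(a) if a is not None else set(true_partition.all_ids())
    ids_est = (set(estimated) if isinstance(estimated, dict)
               else set(estimated.all_ids()))
    if ids_true != ids_est:
        raise PanelError("partitions cover different unit ids")
    ids = sorted(ids_true)
    return float(adjusted_rand_score(_labels_from_partition(true_partition, ids),
                                     _labels_from_partition(estimated, ids)))


# ---------------------------------------------------------------------------
# monte carlo

def run_power_study(specs: dict[str, FactorModelSpec], reps: int = 200,
                    seed: int = 0, critical: float = DEFAULT_CRITICAL,
                    cluster: bool = False, r: float = 0.3) -> pd.DataFrame:
    """Monte-Carlo size/power (and optionally recovery) over a grid of specs.

    For each named spec, simulates ``reps`` independent panels (seeds derived
    from ``seed``), runs the full-panel log t test, and reports the rejection
    (divergence) rate with its binomial Monte-Carlo standard error.  With
    ``cluster=True`` the club classifier is also run on each panel and the
    mean recovery score against the planted truth is reported.

    Returns a DataFrame with one row per cell:
    ``cell, reps, diverge_rate, diverge_se[, mean_recovery, recovery_se]``.
    """
    if reps < 1:
        raise PanelError("reps must be >= 1")
    master = np.random.default_rng(seed)
    rows = []
    for name, spec in specs.items():
        cell_seeds = master.integers(0, 2**31 - 1, size=reps)
        rejections = np.empty(reps, dtype=bool)
        scores = np.empty(reps) if cluster else None
        for k, s in enumerate(cell_seeds):
            panel, truth = generate_panel(replace(spec, seed=int(s)))
            res = fit_logt(panel, r=r)
            rejections[k] = (not res.degenerate) and res.t_b < critical
            if cluster:
                est = ClubConvergence(panel, r=r, critical=critical).fit()
                scores[k] = recovery_score(truth, est.merged)
        rate = rejections.mean()
        row = {"cell": name, "reps": reps, "diverge_rate": rate,
               "diverge_se": float(np.sqrt(rate * (1 - rate) / reps))}
        if cluster:
            row["mean_recovery"] = float(scores.mean())
            row["recovery_se"] = float(scores.std(ddof=1) / np.sqrt(reps))
        rows.append(row)
    return pd.DataFrame(rows)
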