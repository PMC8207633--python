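"""Convergence-club clustering and club merging.

When a full panel rejects convergence, subsets of units may still converge to
distinct steady-state paths.  The classification proceeds in five steps:

1. sort units decreasingly by their final-period observation;
2. find the first adjacent pair passing the log t test, then extend it to the
   core group maximizing the test statistic;
3. sieve the remaining units one at a time against the core at critical value
   c* (0 for samples under 50), with a conservative fallback that regrows the
   club from the best-ranked candidates when the joint test fails;
4. recurse on the remainder until it forms a final club, shrinks to a
   singleton, or no passing pair is left (divergent group);
5. merge adjacent clubs whose union passes the joint log t test, iterating
   until the classification is stable; finally test the divergent group
   against each club.

Every subgroup test reuses one regression specification (trimming fraction,
HAC lags, critical value).  The procedure is fully deterministic: ties in the
sorting and candidate ranking break lexicographically by unit id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logt import (DEFAULT_CRITICAL, LogTResult, _fit_logt_from_H,
                   decide_convergence)
from .panel import PanelData, PanelError

__all__ = [
    "ClubPartition",
    "ClubConvergence",
    "ClubConvergenceResults",
    "sort_cross_section",
    "form_core_group",
    "sieve_candidates",
    "find_initial_clubs",
    "merge_clubs",
    "classify_panel",
]


@dataclass
class ClubPartition:
    """An ordered classification of panel units into clubs plus a divergent group.

    Clubs are ordered from the highest-ranked (largest final-period values)
    downward, mirroring the order in which the algorithm found them.  Every
    unit id appears in exactly one club or in ``divergent``.
    """

    clubs: list[list[str]]
    divergent: list[str]
    fits: list[LogTResult] = field(default_factory=list)
    divergent_fit: LogTResult | None = None
    c_star: float = 0.0
    stage: str = "initial"

    @property
    def n_clubs(self) -> int:
        return len(self.clubs)

    def all_ids(self) -> list[str]:
        out = [u for club in self.clubs for u in club]
        return out + list(self.divergent)

    def club_of(self, unit_id: str) -> int:
        """1-based club label; 0 for divergent units."""
        for k, club in enumerate(self.clubs, start=1):
            if unit_id in club:
                return k
        if unit_id in self.divergent:
            return 0
        raise KeyError(unit_id)

    def membership(self) -> pd.DataFrame:
        """Long table (country_id, club); divergent coded 0."""
        rows = [(u, k) for k, club in enumerate(self.clubs, start=1) for u in club]
        rows += [(u, 0) for u in self.divergent]
        return pd.DataFrame(rows, columns=["country_id", "club"])

    def fit_table(self) -> pd.DataFrame:
        """Per-club fit table (club, size, a, b, s_b, t_b, decision)."""
        rows = []
        for k, (club, fit) in enumerate(zip(self.clubs, self.fits), start=1):
            rows.append({"club": k, "size": len(club), **fit.to_dict()})
        if self.divergent:
            row = {"club": 0, "size": len(self.divergent)}
            if self.divergent_fit is not None:
                row.update(self.divergent_fit.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# internal engine

class _ClubEngine:
    """Shared state for the clustering steps: the value matrix, id -> row map,
    and one regression specification applied to every subgroup test."""

    def __init__(self, panel: PanelData, r: float, hac_lags: int | None,
                 critical: float):
        if panel.scale != "log":
            raise PanelError("club clustering expects a log-scale panel")
        self.panel = panel
        self.values = panel.values
        self.index = {u: i for i, u in enumerate(panel.ids)}
        self.r = r
        self.hac_lags = hac_lags
        self.critical = critical

    def fit_ids(self, ids: list[str]) -> LogTResult:
        rows = [self.index[u] for u in ids]
        x = self.values[rows]
        mean = x.mean(axis=0)
        if np.any(np.abs(mean) < 1e-12):
            raise PanelError("degenerate subgroup: zero cross-sectional mean")
        h = x / mean
        H = ((h - 1.0) ** 2).mean(axis=0)
        return _fit_logt_from_H(H, self.r, self.hac_lags, len(rows))

    def stat(self, ids: list[str]) -> float:
        """Test statistic for a subgroup; +inf for exact (degenerate) convergence."""
        res = self.fit_ids(ids)
        return math.inf if res.degenerate else res.t_b

    def passes(self, ids: list[str]) -> bool:
        return not self.stat(ids) < self.critical

    # -- step 1 ---------------------------------------------------------
    def sort_ids(self, ids: list[str], ordering: str = "final") -> list[str]:
        if ordering == "final":
            key = {u: self.values[self.index[u], -1] for u in ids}
        elif ordering == "last_half_mean":
            half = self.values.shape[1] // 2
            key = {u: self.values[self.index[u], half:].mean() for u in ids}
        else:
            raise PanelError(f"unknown ordering {ordering!r}")
        return sorted(ids, key=lambda u: (-key[u], u))

    # -- step 2 ---------------------------------------------------------
    def core_group(self, ordering: list[str]) -> list[str] | None:
        n = len(ordering)
        for k in range(n - 1):
            if not self.stat(ordering[k:k + 2]) > self.critical:
                continue
            # extend {k, k+1, ..., k+j}; keep the j maximizing the statistic
            best_j, best_stat = 1, -math.inf
            for j in range(1, n - k):
                s = self.stat(ordering[k:k + j + 1])
                if s > best_stat:
                    best_j, best_stat = j, s
            return ordering[k:k + best_j + 1]
        return None

    # -- step 3 ---------------------------------------------------------
    def sieve(self, core: list[str], complement: list[str],
              c_star: float) -> list[str]:
        if not complement:
            return list(core)
        one_at_a_time = {u: self.stat(core + [u]) for u in complement}
        candidates = [u for u in complement if one_at_a_time[u] > c_star]
        if not candidates:
            return list(core)
        club = core + candidates
        if self.passes(club):
            return club
        # conservative fallback: regrow from the core, adding candidates in
        # decreasing order of their one-at-a-time statistic while the joint
        # test keeps passing; stop at the first failure
        ranked = sorted(candidates, key=lambda u: (-one_at_a_time[u], u))
        extended = list(core)
        for u in ranked:
            if self.passes(extended + [u]):
                extended.append(u)
            else:
                break
        return extended

    # -- step 4 ---------------------------------------------------------
    def initial_clubs(self, c_star: float, ordering: str) -> ClubPartition:
        remaining = list(self.panel.ids)
        clubs: list[list[str]] = []
        divergent: list[str] = []
        first = True
        while remaining:
            if len(remaining) == 1:
                divergent.extend(remaining)
                break
            if not first and self.passes(remaining):
                clubs.append(self.sort_ids(remaining, ordering))
                break
            order = self.sort_ids(remaining, ordering)
            core = self.core_group(order)
            if core is None:
                divergent.extend(order)
                break
            complement = [u for u in order if u not in core]
            club = self.sieve(core, complement, c_star)
            clubs.append(sorted(club, key=lambda u: order.index(u)))
            remaining = [u for u in order if u not in club]
            first = False
        return ClubPartition(
            clubs=clubs, divergent=divergent,
            fits=[self.fit_ids(c) for c in clubs],
            divergent_fit=(self.fit_ids(divergent) if len(divergent) >= 2 else None),
            c_star=c_star, stage="initial")

    # -- step 5 ---------------------------------------------------------
    def merge(self, partition: ClubPartition,
              merge_divergent: bool = True) -> ClubPartition:
        clubs = [list(c) for c in partition.clubs]
        changed = True
        while changed and len(clubs) > 1:
            changed = False
            merged: list[list[str]] = []
            current = clubs[0]
            for nxt in clubs[1:]:
                if self.passes(current + nxt):
                    current = current + nxt
                    changed = True
                else:
                    merged.append(current)
                    current = nxt
            merged.append(current)
            clubs = merged
        divergent = list(partition.divergent)
        if merge_divergent and divergent:
            for k, club in enumerate(clubs):
                if self.passes(club + divergent):
                    clubs[k] = club + divergent
                    divergent = []
                    break
        return ClubPartition(
            clubs=clubs, divergent=divergent,
            fits=[self.fit_ids(c) for c in clubs],
            divergent_fit=(self.fit_ids(divergent) if len(divergent) >= 2 else None),
            c_star=partition.c_star, stage="merged")


# ---------------------------------------------------------------------------
# model / results surface

class ClubConvergence:
    """Full convergence-club analysis of a balanced log-scale panel.

    Runs the full-panel log t test; if convergence is rejected, applies the
    five-step clustering and merging algorithm.

    Parameters
    ----------
    panel : PanelData
        Log-scale balanced panel.
    r, hac_lags :
        Regression specification shared by every subgroup test (see
        :class:`~convclubs.logt.LogTModel`).
    critical : float, default -1.65
        One-sided rejection threshold; subgroups pass when t_b >= critical.
    c_star : float, default 0.0
        Sieving threshold of step 3; zero keeps membership conservative for
        samples under 50 units.
    ordering : {"final", "last_half_mean"}, default "final"
        Step 1 ranking: final-period observation, or the mean over the last
        half of the sample.
    merge_divergent : bool, default True
        Whether step 5 finally tests the divergent group against each club.
    """

    def __init__(self, panel: PanelData, r: float = 0.3,
                 hac_lags: int | None = None,
                 critical: float = DEFAULT_CRITICAL, c_star: float = 0.0,
                 ordering: str = "final", merge_divergent: bool = True):
        self._engine = _ClubEngine(panel, r, hac_lags, critical)
        self.panel = panel
        self.c_star = c_star
        self.ordering = ordering
        self.merge_divergent = merge_divergent

    def fit(self) -> "ClubConvergenceResults":
        eng = self._engine
        full = eng.fit_ids(list(self.panel.ids))
        decision = decide_convergence(full, eng.critical)
        if decision in ("converge", "exact"):
            ids = eng.sort_ids(list(self.panel.ids), self.ordering)
            one = ClubPartition(clubs=[ids], divergent=[], fits=[full],
                                c_star=self.c_star, stage="initial")
            merged = ClubPartition(clubs=[list(ids)], divergent=[], fits=[full],
                                   c_star=self.c_star, stage="merged")
            return ClubConvergenceResults(self, full, decision, one, merged)
        initial = eng.initial_clubs(self.c_star, self.ordering)
        merged = eng.merge(initial, self.merge_divergent)
        return ClubConvergenceResults(self, full, decision, initial, merged)


class ClubConvergenceResults:
    """Results of :meth:`ClubConvergence.fit`.

    Attributes
    ----------
    full_result : LogTResult
        The full-panel log t test.
    full_decision : str
        "converge", "diverge" or "exact" for the whole panel.
    initial, merged : ClubPartition
        The classification before and after club merging (identical single
        clubs when the full panel already converges).
    """

    def __init__(self, model: ClubConvergence, full_result: LogTResult,
                 full_decision: str, initial: ClubPartition,
                 merged: ClubPartition):
        self.model = model
        self.full_result = full_result
        self.full_decision = full_decision
        self.initial = initial
        self.merged = merged

    @property
    def n_clubs(self) -> int:
        return self.merged.n_clubs

    def summary(self) -> str:
        parts = [self.full_result.summary(), ""]
        for stage, part in (("initial", self.initial), ("final", self.merged)):
            parts.append(f"{stage} classification: {part.n_clubs} club(s), "
                         f"{len(part.divergent)} divergent")
            if part.clubs:
                parts.append(part.fit_table().to_string(index=False))
            parts.append("")
        return "\n".join(parts).rstrip() + "\n"


# ---------------------------------------------------------------------------
# functional surface

def _engine(panel: PanelData, r: float = 0.3, hac_lags: int | None = None,
            critical: float = DEFAULT_CRITICAL) -> _ClubEngine:
    return _ClubEngine(panel, r, hac_lags, critical)


def sort_cross_section(panel: PanelData, ordering: str = "final") -> list[str]:
    """Step 1: ids sorted decreasingly by final-period value (ties: id order)."""
    eng = _engine(panel)
    return eng.sort_ids(list(panel.ids), ordering)


def form_core_group(panel: PanelData, ordering: list[str], r: float = 0.3,
                    hac_lags: int | None = None,
                    critical: float = DEFAULT_CRITICAL) -> list[str] | None:
    """Step 2: the highest-ranked passing pair, extended to maximize t_b.

    Returns None when no adjacent pair passes ("no convergence subgroups").
    """
    return _engine(panel, r, hac_lags, critical).core_group(list(ordering))


def sieve_candidates(panel: PanelData, core: list[str], complement: list[str],
                     c_star: float = 0.0, r: float = 0.3,
                     hac_lags: int | None = None,
                     critical: float = DEFAULT_CRITICAL) -> list[str]:
    """Step 3: admit complement members whose one-at-a-time statistic exceeds c*."""
    return _engine(panel, r, hac_lags, critical).sieve(
        list(core), list(complement), c_star)


def find_initial_clubs(panel: PanelData, c_star: float = 0.0, r: float = 0.3,
                       hac_lags: int | None = None,
                       critical: float = DEFAULT_CRITICAL,
                       ordering: str = "final") -> ClubPartition:
    """Steps 1-4: the initial classification into clubs plus a divergent group."""
    return _engine(panel, r, hac_lags, critical).initial_clubs(c_star, ordering)


def merge_clubs(panel: PanelData, partition: ClubPartition, r: float = 0.3,
                hac_lags: int | None = None,
                critical: float = DEFAULT_CRITICAL,
                merge_divergent: bool = True) -> ClubPartition:
    """Step 5: iteratively merge adjacent clubs whose union passes the joint test."""
    return _engine(panel, r, hac_lags, critical).merge(partition, merge_divergent)


def classify_panel(panel: PanelData, **config) -> ClubConvergenceResults:
    """Full-panel test followed, on rejection, by clustering and merging.

    Keyword arguments are forwarded to :class:`ClubConvergence`.
    """
    return ClubConvergence(panel, **config).fit()
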