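"""Balanced country × year expenditure panels: reading, validation, transforms.

The analysis downstream (relative transition paths, the log t regression,
club clustering) operates on the natural logarithm of a strictly positive,
balanced N × T panel — typically per-capita government health expenditure at
purchasing power parity.  This module owns the panel container and the
plumbing that gets raw tables into that shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PanelData",
    "PanelError",
    "PanelValidationError",
    "Violation",
    "read_panel_table",
    "write_panel_table",
    "validate_panel",
    "log_transform",
    "smooth_series",
]


class PanelError(ValueError):
    """Malformed panel input (parse failures, bad coordinates, domain errors)."""


class PanelValidationError(PanelError):
    """A panel violates the balanced-panel contract; carries the violations."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__(
            "panel validation failed: " + "; ".join(str(v) for v in violations)
        )


@dataclass(frozen=True)
class Violation:
    """One broken panel invariant, with the rule name and offending coordinates."""

    rule: str
    message: str
    coordinates: tuple = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.coordinates:
            return f"{self.rule}: {self.message} at {self.coordinates}"
        return f"{self.rule}: {self.message}"


@dataclass
class PanelData:
    """A balanced N × T panel of unit × year observations.

    Parameters
    ----------
    values : ndarray of shape (N, T)
        Observations; strictly positive on the raw scale, unrestricted on the
        log scale.
    ids : list of str
        Unit (country) identifiers, one per row, unique.
    years : list of int
        Calendar years, one per column, strictly increasing and consecutive.
        The method's internal time index t = 1..T maps onto these.
    scale : {"raw", "log"}
        Whether ``values`` holds raw expenditure or its natural log.
    """

    values: np.ndarray
    ids: list[str] = field(default_factory=list)
    years: list[int] = field(default_factory=list)
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PanelError("values must be a 2-D (units × years) array")
        self.ids = [str(i) for i in self.ids]
        self.years = [int(y) for y in self.years]
        n, t = self.values.shape
        if len(self.ids) != n:
            raise PanelError(f"{len(self.ids)} ids for {n} rows")
        if len(self.years) != t:
            raise PanelError(f"{len(self.years)} years for {t} columns")
        if self.scale not in ("raw", "log"):
            raise PanelError(f"unknown scale {self.scale!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_periods(self) -> int:
        return self.values.shape[1]

    def row(self, unit_id: str) -> np.ndarray:
        return self.values[self.ids.index(unit_id)]

    def subset(self, unit_ids: list[str]) -> "PanelData":
        """Panel restricted to ``unit_ids``, in the order given."""
        idx = [self.ids.index(u) for u in unit_ids]
        return replace(self, values=self.values[idx], ids=list(unit_ids))

    def copy(self) -> "PanelData":
        return replace(self, values=self.values.copy(), ids=list(self.ids),
                       years=list(self.years))

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame, index = unit ids, columns = years."""
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="country_id"),
                            columns=self.years)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str = "raw") -> "PanelData":
        return cls(values=frame.to_numpy(dtype=float),
                   ids=[str(i) for i in frame.index],
                   years=[int(c) for c in frame.columns], scale=scale)


# ---------------------------------------------------------------------------
# validation

def validate_panel(panel: PanelData) -> list[Violation]:
    """Check the balanced-panel contract; return all violations (empty = valid).

    Rules checked: minimum size (N >= 2, T >= 5), no missing cells, strict
    positivity on the raw scale, unique ids, strictly increasing consecutive
    years.
    """
    out: list[Violation] = []
    n, t = panel.values.shape
    if n < 2:
        out.append(Violation("min_units", f"need at least 2 units, got {n}"))
    if t < 5:
        out.append(Violation("min_periods", f"need at least 5 periods, got {t}"))
    bad = np.argwhere(~np.isfinite(panel.values))
    for i, j in bad:
        out.append(Violation("missing_value", "non-finite cell",
                             (panel.ids[i], panel.years[j])))
    if panel.scale == "raw":
        nonpos = np.argwhere(np.isfinite(panel.values) & (panel.values <= 0))
        for i, j in nonpos:
            out.append(Violation("nonpositive_value",
                                 f"value {panel.values[i, j]} not > 0",
                                 (panel.ids[i], panel.years[j])))
    seen: set[str] = set()
    for uid in panel.ids:
        if uid in seen:
            out.append(Violation("duplicate_id", f"id {uid!r} repeated", (uid,)))
        seen.add(uid)
    years = panel.years
    for a, b in zip(years, years[1:]):
        if b != a + 1:
            out.append(Violation("non_consecutive_years",
                                 f"year {b} follows {a}", (a, b)))
    return out


def _require_valid(panel: PanelData) -> PanelData:
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(violations)
    return panel


# ---------------------------------------------------------------------------
# i/o

def _read_delimited(path) -> pd.DataFrame:
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        # round_trip parsing so write -> read is bit-exact
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise PanelError(f"cannot open {path}: {exc}") from exc
    except Exception as exc:  # pandas raises several parser error types
        raise PanelError(f"cannot parse {path}: {exc}") from exc


def read_panel_table(path, layout: str = "wide") -> PanelData:
    """Read a delimited country × year table into a validated raw-scale panel.

    Parameters
    ----------
    path : str or path-like
        CSV/TSV file. ``wide``: one id column (first column) and one column
        per year, named either ``2000`` or ``y2000``.  ``long``: columns
        ``country_id, year, value`` (by name, or the first three columns).
    layout : {"wide", "long"}

    Returns
    -------
    PanelData on the raw scale, years ascending, unit order as first seen.

    Raises
    ------
    PanelError
        On parse failures, non-numeric cells (with coordinates), or an
        unbalanced long table (listing the missing (id, year) pairs).
    PanelValidationError
        If the resulting panel violates the balanced-panel contract.
    """
    if layout not in ("wide", "long"):
        raise PanelError(f"unknown layout {layout!r}")
    frame = _read_delimited(path)
    if layout == "wide":
        panel = _panel_from_wide(frame)
    else:
        panel = _panel_from_long(frame)
    return _require_valid(panel)


def _year_from_label(label) -> int:
    s = str(label).strip()
    if s.lower().startswith("y"):
        s = s[1:]
    try:
        return int(s)
    except ValueError:
        raise PanelError(f"column {label!r} is not a year") from None


def _panel_from_wide(frame: pd.DataFrame) -> PanelData:
    if frame.shape[1] < 2:
        raise PanelError("wide table needs an id column and at least one year column")
    id_col = frame.columns[0]
    ids = [str(v) for v in frame[id_col]]
    years = [_year_from_label(c) for c in frame.columns[1:]]
    order = np.argsort(years)
    values = np.empty((len(ids), len(years)))
    cols = list(frame.columns[1:])
    for jj, j in enumerate(order):
        col = pd.to_numeric(frame[cols[j]], errors="coerce")
        bad = np.flatnonzero(col.isna() & frame[cols[j]].notna())
        if bad.size:
            i = int(bad[0])
            raise PanelError(
                f"non-numeric cell at ({ids[i]}, {years[j]}): {frame[cols[j]].iloc[i]!r}")
        values[:, jj] = col.to_numpy()
    return PanelData(values=values, ids=ids, years=sorted(years), scale="raw")


def _panel_from_long(frame: pd.DataFrame) -> PanelData:
    cols = {c.lower(): c for c in frame.columns}
    try:
        id_c = cols.get("country_id", frame.columns[0])
        yr_c = cols.get("year", frame.columns[1])
        val_c = cols.get("value", frame.columns[2])
    except IndexError:
        raise PanelError("long table needs columns country_id, year, value") from None
    sub = frame[[id_c, yr_c, val_c]].copy()
    sub.columns = ["country_id", "year", "value"]
    sub["country_id"] = sub["country_id"].astype(str)
    sub["year"] = pd.to_numeric(sub["year"], errors="coerce")
    if sub["year"].isna().any():
        row = int(np.flatnonzero(sub["year"].isna())[0])
        raise PanelError(f"non-numeric year in row {row + 2}")
    val = pd.to_numeric(sub["value"], errors="coerce")
    bad = np.flatnonzero(val.isna() & sub["value"].notna())
    if bad.size:
        i = int(bad[0])
        raise PanelError(
            f"non-numeric cell at ({sub['country_id'].iloc[i]}, "
            f"{int(sub['year'].iloc[i])}): {sub['value'].iloc[i]!r}")
    sub["value"] = val
    dup = sub.duplicated(["country_id", "year"])
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise PanelError(
            f"duplicate record for ({sub['country_id'].iloc[i]}, "
            f"{int(sub['year'].iloc[i])})")
    ids = list(dict.fromkeys(sub["country_id"]))
    years = sorted(int(y) for y in sub["year"].unique())
    wide = sub.pivot(index="country_id", columns="year", values="value")
    wide = wide.reindex(index=ids, columns=years)
    if wide.isna().any().any():
        ii, jj = np.where(wide.isna().to_numpy())
        missing = [(str(wide.index[i]), int(wide.columns[j]))
                   for i, j in zip(ii, jj)]
        raise PanelError(f"unbalanced panel; missing (id, year) pairs: {missing}")
    return PanelData.from_frame(wide, scale="raw")


def write_panel_table(panel: PanelData, path) -> None:
    """Write the panel as a normalized wide CSV (columns country_id, y<year>...)."""
    frame = panel.to_frame()
    frame.columns = [f"y{y}" for y in panel.years]
    # repr gives the shortest exact decimal, so write -> read round-trips
    # bit-identically
    frame.to_csv(path, index=True, float_format=lambda x: repr(float(x)))


# ---------------------------------------------------------------------------
# transforms

def log_transform(panel: PanelData) -> PanelData:
    """Elementwise natural log of a strictly positive raw panel.

    The convergence machinery works throughout on X_it = log(expenditure),
    so this is the single entry point from raw data to the analysis scale.
    """
    if panel.scale != "raw":
        raise PanelError("log_transform expects a raw-scale panel")
    nonpos = np.argwhere(panel.values <= 0)
    if nonpos.size:
        i, j = nonpos[0]
        raise PanelError(
            f"log undefined: value {panel.values[i, j]} at "
            f"({panel.ids[i]}, {panel.years[j]})")
    return replace(panel, values=np.log(panel.values), scale="log")


def smooth_series(panel: PanelData, method: str = "none",
                  strength: float = 6.25) -> PanelData:
    """Optionally smooth each country's log series before testing.

    ``method="none"`` is the identity and the default. ``"trend_filter"``
    replaces each series by its Hodrick–Prescott trend with penalty
    ``strength`` (6.25 is the conventional value for annual data); the filter
    leaves constant and linear-trend series unchanged.
    """
    if panel.scale != "log":
        raise PanelError("smooth_series expects a log-scale panel")
    if method == "none":
        return panel.copy()
    if method != "trend_filter":
        raise PanelError(f"unknown smoothing method {method!r}")
    if not (strength > 0):
        raise PanelError("trend_filter strength must be positive")
    from statsmodels.tsa.filters.hp_filter import hpfilter

    smoothed = np.empty_like(panel.values)
    for i in range(panel.n_units):
        _, trend = hpfilter(panel.values[i], lamb=strength)
        smoothed[i] = np.asarray(trend)
    return replace(panel, values=smoothed)
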