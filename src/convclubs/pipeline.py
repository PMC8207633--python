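"""Config-driven end-to-end analysis runs and report exports.

`run_analysis` reproduces the full analysis surface on one input panel: the
full-panel log t test, the initial club classification, club merging, the
relative transition paths per club, and a membership table — all written as
plain CSV/JSON plus a run log recording every resolved setting, so a run is
auditable and byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clubs import ClubConvergence, ClubConvergenceResults, ClubPartition
from .logt import DEFAULT_CRITICAL, compute_transition
from .panel import (PanelData, PanelError, log_transform, read_panel_table,
                    smooth_series, validate_panel)

__all__ = [
    "AnalysisConfig",
    "ConfigError",
    "AnalysisReport",
    "run_analysis",
    "export_transition_paths",
    "summarize_club_outcomes",
]


class ConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass
class AnalysisConfig:
    """Settings of one end-to-end run.

    ``start_year``/``end_year`` restrict the panel window (inclusive); None
    keeps the data's full range.  The remaining fields mirror the model
    options (see :class:`~convclubs.clubs.ClubConvergence`).
    """

    input_path: str
    layout: str = "wide"
    start_year: int | None = None
    end_year: int | None = None
    r: float = 0.3
    hac_lags: int | None = None
    critical: float = DEFAULT_CRITICAL
    c_star: float = 0.0
    smoothing: str = "none"
    smoothing_strength: float = 6.25
    ordering: str = "final"
    merge_divergent: bool = True
    output_dir: str = "convclubs_report"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0.2 <= self.r <= 0.3):
            raise ConfigError(f"r={self.r} outside [0.2, 0.3]")
        if self.layout not in ("wide", "long"):
            raise ConfigError(f"unknown layout {self.layout!r}")
        if self.smoothing not in ("none", "trend_filter"):
            raise ConfigError(f"unknown smoothing {self.smoothing!r}")
        if (self.start_year is not None and self.end_year is not None
                and self.end_year < self.start_year):
            raise ConfigError("end_year before start_year")


@dataclass
class AnalysisReport:
    """Return value of :func:`run_analysis`: the fitted results plus the
    paths of every file written."""

    results: ClubConvergenceResults
    outputs: dict[str, Path] = field(default_factory=dict)


def _window(panel: PanelData, start: int | None, end: int | None) -> PanelData:
    if start is None and end is None:
        return panel
    lo = start if start is not None else panel.years[0]
    hi = end if end is not None else panel.years[-1]
    keep = [j for j, y in enumerate(panel.years) if lo <= y <= hi]
    if not keep:
        raise ConfigError(f"window {lo}-{hi} outside available years "
                          f"{panel.years[0]}-{panel.years[-1]}")
    from dataclasses import replace
    return replace(panel, values=panel.values[:, keep],
                   years=[panel.years[j] for j in keep])


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(type(obj))


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the complete convergence analysis described by ``config``.

    Reads and validates the input panel, applies the year window, takes
    natural logs (and optional trend-filter smoothing), runs the full-panel
    test and — on rejection — the club clustering and merging algorithm, and
    writes the report bundle into ``config.output_dir``:

    ``full_test.json``, ``clubs_initial.csv``, ``clubs_final.csv``,
    ``membership.csv``, ``transition_paths.csv``, ``summary.json`` and
    ``run_log.txt``.  Outputs carry no timestamps: identical input and config
    give byte-identical files.
    """
    config.validate()
    try:
        raw = read_panel_table(config.input_path, layout=config.layout)
    except PanelError as exc:
        raise PanelError(f"[read] {exc}") from exc
    panel = _window(raw, config.start_year, config.end_year)
    violations = validate_panel(panel)
    if violations:
        raise PanelError("[validate] " + "; ".join(str(v) for v in violations))
    logp = log_transform(panel)
    if config.smoothing != "none":
        logp = smooth_series(logp, method=config.smoothing,
                             strength=config.smoothing_strength)
    model = ClubConvergence(
        logp, r=config.r, hac_lags=config.hac_lags, critical=config.critical,
        c_star=config.c_star, ordering=config.ordering,
        merge_divergent=config.merge_divergent)
    results = model.fit()

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    full = dict(results.full_result.to_dict())
    full["decision"] = results.full_decision
    outputs["full_test"] = outdir / "full_test.json"
    _write_json(full, outputs["full_test"])

    for stage, part in (("initial", results.initial), ("final", results.merged)):
        path = outdir / f"clubs_{stage}.csv"
        part.fit_table().to_csv(path, index=False)
        outputs[f"clubs_{stage}"] = path

    membership = results.initial.membership().rename(columns={"club": "initial_club"})
    final = results.merged.membership().rename(columns={"club": "final_club"})
    membership = membership.merge(final, on="country_id")
    outputs["membership"] = outdir / "membership.csv"
    membership.to_csv(outputs["membership"], index=False)

    paths = export_transition_paths(logp, results.merged)
    outputs["transition_paths"] = outdir / "transition_paths.csv"
    paths.to_csv(outputs["transition_paths"], index=False)

    summary = {
        "n_units": logp.n_units,
        "n_periods": logp.n_periods,
        "years": [logp.years[0], logp.years[-1]],
        "full_decision": results.full_decision,
        "n_initial_clubs": results.initial.n_clubs,
        "n_final_clubs": results.merged.n_clubs,
        "n_divergent": len(results.merged.divergent),
        "final_club_sizes": [len(c) for c in results.merged.clubs],
        "divergent_ids": list(results.merged.divergent),
    }
    outputs["summary"] = outdir / "summary.json"
    _write_json(summary, outputs["summary"])

    resolved = asdict(config)
    resolved["hac_lags_resolved"] = results.full_result.hac_lags
    resolved["start_index_resolved"] = results.full_result.start_index
    log_lines = ["convclubs run log", "=" * 18]
    log_lines += [f"{k} = {resolved[k]}" for k in sorted(resolved)]
    log_lines += ["", "pipeline: read -> window -> validate -> log"
                  + (" -> smooth" if config.smoothing != "none" else "")
                  + " -> full test"
                  + ("" if results.full_decision != "diverge"
                     else " -> clustering -> merging")]
    outputs["run_log"] = outdir / "run_log.txt"
    outputs["run_log"].write_text("\n".join(log_lines) + "\n")

    return AnalysisReport(results=results, outputs=outputs)


def export_transition_paths(panel: PanelData,
                            partition: ClubPartition) -> pd.DataFrame:
    """Tidy long table of relative transition paths, panel-wide and per club.

    Columns: ``country_id, year, club, h, h_club`` where ``h`` is relative to
    the whole panel and ``h_club`` is recomputed within the unit's club (the
    within-club mean of ``h_club`` is 1 at every year; for divergent units it
    is computed within the divergent group, or NaN for a singleton).
    """
    trans = compute_transition(panel)
    frame = trans.to_frame()
    frame["club"] = [partition.club_of(u) for u in frame["country_id"]]

    h_club = pd.Series(np.nan, index=frame.index)
    groups = [list(c) for c in partition.clubs]
    if len(partition.divergent) >= 2:
        groups.append(list(partition.divergent))
    for members in groups:
        sub = compute_transition(panel.subset(members)).to_frame()
        sub = sub.set_index(["country_id", "year"])["h"]
        mask = frame["country_id"].isin(members)
        keys = list(zip(frame.loc[mask, "country_id"], frame.loc[mask, "year"]))
        h_club.loc[mask] = sub.loc[keys].to_numpy()
    frame["h_club"] = h_club
    return frame[["country_id", "year", "club", "h", "h_club"]]


def summarize_club_outcomes(partition: ClubPartition,
                            outcomes: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-club summary of an external outcome (e.g. infant
    mortality), with no inferential statistics.

    ``outcomes`` needs columns ``country_id`` and ``outcome`` (or any second
    column, taken as the outcome).  Units without an outcome value are
    counted as missing, never imputed.

    Returns one row per club (divergent group as club 0): ``club, label,
    size, n, n_missing, mean, min, max``.
    """
    if outcomes.empty:
        lookup = {}
    else:
        cols = list(outcomes.columns)
        id_col = "country_id" if "country_id" in cols else cols[0]
        val_col = ("outcome" if "outcome" in cols
                   else [c for c in cols if c != id_col][0])
        vals = pd.to_numeric(outcomes[val_col], errors="coerce")
        lookup = dict(zip(outcomes[id_col].astype(str), vals))

    extra = set(lookup) - set(partition.all_ids())
    if extra:
        raise PanelError(f"outcome table has unknown ids: {sorted(extra)}")

    rows = []
    blocks = [(k, f"Club {k}", club)
              for k, club in enumerate(partition.clubs, start=1)]
    if partition.divergent:
        blocks.append((0, "Divergent", list(partition.divergent)))
    for club_no, label, members in blocks:
        vals = np.array([lookup.get(u, np.nan) for u in members], dtype=float)
        present = vals[np.isfinite(vals)]
        rows.append({
            "club": club_no, "label": label, "size": len(members),
            "n": int(present.size), "n_missing": int(len(members) - present.size),
            "mean": float(present.mean()) if present.size else np.nan,
            "min": float(present.min()) if present.size else np.nan,
            "max": float(present.max()) if present.size else np.nan,
        })
    return pd.DataFrame(rows)
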