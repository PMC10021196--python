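"""Formatted delta tables mirroring the published scenario-table layout."""

from __future__ import annotations

import hashlib
import json
import time

import pandas as pd

from .scenarios import DeltaTable, REPORT_YEARS

__all__ = ["render_tables", "write_manifest"]


def _cell(delta_pp: float, rel_pct: float) -> str:
    return f"{delta_pp:+.2f} ({rel_pct:+.1f}%)"


def render_tables(deltas, metric: str = "dm_prev", years=REPORT_YEARS) -> pd.DataFrame:
    """One row per scenario, one column per reporting year.

    Cells are formatted "p.p. (relative %)"; a ``baseline`` row gives the
    baseline prevalence in percent.  Raises if a requested year is missing
    from any delta table.
    """
    deltas = list(deltas)
    rows = []
    baseline_row = None
    for dt in deltas:
        if not isinstance(dt, DeltaTable):
            raise TypeError("render_tables expects DeltaTable objects")
        row = {"scenario": dt.scenario}
        for year in years:
            sel = dt.frame[(dt.frame.metric == metric) & (dt.frame.year == year)]
            if sel.empty:
                raise KeyError(f"scenario {dt.scenario!r}: missing year {year}")
            row[f"{year:.0f}"] = _cell(float(sel["delta_pp"].iloc[0]),
                                       float(sel["delta_rel_pct"].iloc[0]))
            if baseline_row is None or f"{year:.0f}" not in baseline_row:
                baseline_row = baseline_row or {"scenario": "baseline"}
                baseline_row[f"{year:.0f}"] = f"{100 * float(sel['baseline'].iloc[0]):.1f}"
        rows.append(row)
    cols = ["scenario"] + [f"{y:.0f}" for y in years]
    out = [baseline_row] + rows if baseline_row else rows
    return pd.DataFrame(out, columns=cols)


def write_manifest(path, outputs, seeds=None, configs=None) -> dict:
    """Write a JSON run manifest (configs, seeds, version, output hashes)."""
    from . import __version__

    def sha256(p):
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()

    manifest = {
        "package": "diabesim",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": seeds or {},
        "configs": [str(c) for c in (configs or [])],
        "outputs": {str(p): sha256(p) for p in outputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
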