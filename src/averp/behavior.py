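"""Behavioral summaries: hit rate, false alarm, trimmed response times.

Hit rate is the responded fraction of target trials; false alarm the
responded fraction of standard trials.  Response times come from target
trials only and are trimmed in a single pass to the cell mean +- 3 SD
(inclusive bounds), which retains essentially all of a well-behaved
(approximately Gaussian) RT distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_formats import Event, INTENSITIES, MODALITIES


def _cell_events(events: list[Event], intensity: str, modality: str) -> list[Event]:
    return [e for e in events if e.intensity == intensity and e.modality == modality]


def hit_rate(events: list[Event]) -> float:
    """Responded targets / total targets; NaN when the cell has no targets."""
    targets = [e for e in events if e.role == "target"]
    if not targets:
        return float("nan")
    return sum(e.responded for e in targets) / len(targets)


def false_alarm(events: list[Event]) -> float:
    """Responded standards / total standards; NaN when no standards."""
    standards = [e for e in events if e.role == "standard"]
    if not standards:
        return float("nan")
    return sum(e.responded for e in standards) / len(standards)


def trim_rts(rts, k: float = 3.0) -> tuple[np.ndarray, float]:
    """Single-pass mean +- k*SD trim with inclusive bounds.

    Returns ``(retained, retention_fraction)``.  Mean and SD come from the
    untrimmed input (no iteration).  Fewer than 2 values are returned
    untrimmed with a warning, since an SD cannot be formed.
    """
    rts = np.asarray(list(rts), dtype=float)
    if rts.size < 2:
        warnings.warn("fewer than 2 RTs: returning untrimmed", stacklevel=2)
        return rts, 1.0
    mean = rts.mean()
    sd = rts.std(ddof=1)
    keep = (rts >= mean - k * sd) & (rts <= mean + k * sd)
    return rts[keep], float(keep.mean())


def cell_summary(events: list[Event], k: float = 3.0) -> dict:
    """HT, FA and trimmed RT statistics for one design cell's events."""
    rts = [e.response_time_ms for e in events if e.role == "target" and e.responded]
    out = {"ht": hit_rate(events), "fa": false_alarm(events),
           "n_rt_total": len(rts)}
    if len(rts) >= 2:
        kept, retention = trim_rts(rts, k)
        out.update(rt_mean_ms=float(kept.mean()), rt_sd_ms=float(kept.std(ddof=1)),
                   n_rt_used=int(kept.size), rt_retention=retention)
    elif rts:
        out.update(rt_mean_ms=float(rts[0]), rt_sd_ms=float("nan"),
                   n_rt_used=1, rt_retention=1.0)
    else:
        out.update(rt_mean_ms=float("nan"), rt_sd_ms=float("nan"),
                   n_rt_used=0, rt_retention=float("nan"))
    return out


def behavior_tables(logs: dict[str, list[Event]], groups: dict[str, str],
                    k: float = 3.0) -> dict[str, pd.DataFrame]:
    """ANOVA-ready long tables for HT, FA and RT.

    ``logs`` maps subject id to its responded events; ``groups`` maps subject
    id to its age group.  Each measure gets one row per subject x intensity x
    modality; trimming is applied within each such cell.  A missing cell
    (no trials) raises, since the mixed ANOVA needs a complete design.
    """
    records = []
    for sid, events in logs.items():
        for intensity in INTENSITIES:
            for modality in MODALITIES:
                cell = _cell_events(events, intensity, modality)
                if not cell:
                    raise ValueError(f"subject {sid}: no trials in cell "
                                     f"({intensity}, {modality})")
                s = cell_summary(cell, k)
                records.append({"subject": sid, "group": groups[sid],
                                "intensity": intensity, "modality": modality, **s})
    df = pd.DataFrame(records)
    base = ["subject", "group", "intensity", "modality"]
    return {
        "ht": df[base + ["ht"]].rename(columns={"ht": "value"}),
        "fa": df[base + ["fa"]].rename(columns={"fa": "value"}),
        "rt": df[base + ["rt_mean_ms"]].rename(columns={"rt_mean_ms": "value"}),
        "cells": df,
    }


def summary_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Group-level summary in the usual report layout: per group x intensity
    x modality, HT% and FA% as mean (SD) over subjects, RT mean (SD) in ms."""
    rows = []
    for (group, intensity, modality), sub in cells.groupby(["group", "intensity", "modality"]):
        rows.append({
            "group": group, "intensity": intensity, "modality": modality,
            "ht_pct_mean": 100 * sub["ht"].mean(), "ht_pct_sd": 100 * sub["ht"].std(ddof=1),
            "fa_pct_mean": 100 * sub["fa"].mean(), "fa_pct_sd": 100 * sub["fa"].std(ddof=1),
            "rt_ms_mean": sub["rt_mean_ms"].mean(), "rt_ms_sd": sub["rt_mean_ms"].std(ddof=1),
        })
    return pd.DataFrame(rows)
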