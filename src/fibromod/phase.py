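"""Phase-wise eigengene activity and differential-activity module selection.

Treated samples are grouped into the inflammatory (days 1-2), acute fibrotic
(days 7-14) and late fibrotic (day >= 21) phases; all control samples form a
single pooled control class.  A module's activity in a phase is the mean of
the absolute eigengene entries over that phase's samples (absolute values,
because module members may be regulated in either direction).  Control
samples also achieve non-zero activity, so selection uses the ratio of phase
to control activity, the differential activity (DA).  Modules reaching
DA >= 2.5 in any phase are selected and assigned to every phase where they
reach the threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .network import ModuleSet

FIBROSIS_PHASES = ("inflammatory", "acute", "late")
DA_THRESHOLD = 2.5
_EPS = 1e-8


def build_phase_map(design: pd.DataFrame) -> pd.Series:
    """sample_id -> phase from a design table (columns sample_id, day, group).

    Treated samples map to their fibrosis phase by day; every control sample
    maps to the pooled ``control`` class.
    """
    from .simulate import phase_for_day

    required = {"sample_id", "day", "group"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    phase = [
        "control" if row.group == "control" else phase_for_day(row.day)
        for row in design.itertuples()
    ]
    out = pd.Series(phase, index=design["sample_id"].to_numpy(), name="phase")
    if not (out == "control").any():
        raise ValueError("phase map has no control samples")
    return out


def phase_scores(eigengenes: pd.DataFrame, phase_map: pd.Series) -> pd.DataFrame:
    """Mean absolute eigengene entry per module and phase.

    ``eigengenes`` is samples x modules, aligned with ``phase_map``'s index.
    """
    if not eigengenes.index.equals(phase_map.index):
        if set(eigengenes.index) != set(phase_map.index):
            raise ValueError("eigengene samples do not match the phase map")
        phase_map = phase_map.reindex(eigengenes.index)
    rows = {}
    for phase in (*FIBROSIS_PHASES, "control"):
        samples = phase_map.index[phase_map == phase]
        if len(samples) == 0:
            raise ValueError(f"phase {phase!r} has no samples")
        rows[phase] = eigengenes.loc[samples].abs().mean(axis=0)
    return pd.DataFrame(rows)


def differential_activity(scores: pd.DataFrame) -> pd.DataFrame:
    """DA per module and fibrosis phase: phase score / control score.

    Control scores below a small epsilon are clamped (with a warning and an
    ``unstable`` flag) so the ratio stays finite.
    """
    if "control" not in scores.columns:
        raise ValueError("scores must include a 'control' column")
    control = scores["control"].to_numpy(float)
    unstable = control < _EPS
    if unstable.any():
        warnings.warn(
            f"{int(unstable.sum())} module(s) have near-zero control activity; "
            "their DA values are unstable")
    denom = np.maximum(control, _EPS)
    da = scores.loc[:, list(FIBROSIS_PHASES)].div(denom, axis=0)
    da.columns = [f"DA_{p}" for p in FIBROSIS_PHASES]
    da["unstable"] = unstable
    return da


def select_modules(da: pd.DataFrame,
                   threshold: float = DA_THRESHOLD) -> pd.DataFrame:
    """Selection and phase assignment from a DA table.

    A module is selected when its DA reaches the threshold (inclusive) in at
    least one phase, and is assigned to every phase at or above it.
    """
    cols = [f"DA_{p}" for p in FIBROSIS_PHASES]
    missing = set(cols) - set(da.columns)
    if missing:
        raise ValueError(f"DA table missing columns: {sorted(missing)}")
    out = da.copy()
    hits = da.loc[:, cols].ge(threshold)
    out["selected"] = hits.any(axis=1)
    out["assigned_phases"] = [
        ",".join(p for p, h in zip(FIBROSIS_PHASES, row) if h)
        for row in hits.to_numpy()
    ]
    return out


def phase_activity_report(module_set: ModuleSet, phase_map: pd.Series,
                          threshold: float = DA_THRESHOLD) -> pd.DataFrame:
    """Per-module phase activity table (the selection summary).

    One row per module (unassigned label 0 excluded), ordered by module id:
    phase eigengene scores, DA values, selection flag, assigned phases and
    hub gene.
    """
    eg = module_set.eigengenes
    if set(eg.index) != set(phase_map.index):
        raise ValueError("eigengene samples do not match the phase map")
    scores = phase_scores(eg, phase_map)
    da = differential_activity(scores)
    sel = select_modules(da, threshold)
    report = pd.concat(
        [scores.rename(columns={p: f"EG_{p}" for p in scores.columns}), sel],
        axis=1,
    )
    report.insert(0, "module_id", [int(m) for m in report.index])
    report["hub_gene"] = [module_set.hub_gene[int(m)] for m in report.index]
    return report.sort_values("module_id").reset_index(drop=True)
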