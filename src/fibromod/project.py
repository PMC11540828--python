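"""Projection of frozen biomarker modules onto targeted-panel DEG tables.

A reduced-representation assay measures only part of each module, so each
module is first restricted to the panel.  Per compound and concentration the
module is scored two ways:

* **DEG fraction** - the share of measured module genes called DEG; the
  module counts as *activated* when strictly more than 20% of its measured
  genes are differentially expressed;
* **module score** - the mean absolute log2 fold change over all measured
  module genes (DEG or not), an overall activation measure.

Concentration-responsiveness of the module score is assessed per compound by
ordinary least squares on log10 concentration; a module/compound pair is
called dose-responsive when the slope is positive with p below 0.05.  Genes
differentially expressed at two or more concentrations of a compound are
reported as recurrent, with a flag for genes recurrent under more than one
compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProjectionParams:
    activation_fraction_threshold: float = 0.20
    min_measured_genes: int = 3
    trend_alpha: float = 0.05
    score_weighting: str = "plain"  # or "kme"

    def __post_init__(self) -> None:
        if not 0 < self.activation_fraction_threshold < 1:
            raise ValueError("activation threshold must be in (0, 1)")
        if self.min_measured_genes < 1:
            raise ValueError("min_measured_genes must be >= 1")
        if self.score_weighting not in ("plain", "kme"):
            raise ValueError(f"unknown weighting {self.score_weighting!r}")


@dataclass
class ConditionDEG:
    """One tested condition: a compound at one concentration with its DEG
    table restricted to the measured panel."""

    compound: str
    concentration: float
    table: pd.DataFrame  # columns gene_id, log2fc, padj, is_deg

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be strictly positive")


@dataclass
class ProjectionResult:
    activation: pd.DataFrame   # module x condition DEG fractions / flags
    trends: pd.DataFrame       # module x compound OLS trend statistics
    recurrent: pd.DataFrame    # recurrent DEGs per module x compound
    measured: pd.DataFrame     # per-module panel coverage
    not_evaluable: list[int] = field(default_factory=list)


def restrict_to_panel(
    module_genes: Mapping[int, Sequence[str]],
    panel: Sequence[str],
    min_measured_genes: int = 3,
) -> pd.DataFrame:
    """Intersect each module with the measured panel.

    Returns one row per module: total size, measured gene count and an
    evaluable flag (at least ``min_measured_genes`` measured).
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    pset = set(panel)
    rows = []
    for module, genes in sorted(module_genes.items()):
        measured = sorted(set(genes) & pset)
        rows.append({
            "module_id": module, "n_total": len(genes),
            "n_measured": len(measured),
            "evaluable": len(measured) >= min_measured_genes,
            "measured_genes": measured,
        })
    return pd.DataFrame(rows)


def deg_fraction(measured_genes: Sequence[str], condition: ConditionDEG,
                 threshold: float = 0.20) -> tuple[float, bool]:
    """Fraction of measured module genes flagged DEG in the condition, and
    the activation call (strict > threshold)."""
    table = condition.table.set_index("gene_id")
    present = [g for g in measured_genes if g in table.index]
    if not present:
        raise ValueError("no measured module genes found in the DEG table")
    frac = float(table.loc[present, "is_deg"].mean())
    return frac, frac > threshold


def module_score(measured_genes: Sequence[str], condition: ConditionDEG,
                 weighting: str = "plain",
                 kme: Mapping[str, float] | None = None) -> float:
    """Mean |log2FC| over measured module genes (all genes, DEG or not).

    With ``kme`` weighting the mean is weighted by |kME| (normalized to sum
    to one), emphasising genes central to the module.
    """
    table = condition.table.set_index("gene_id")
    present = [g for g in measured_genes if g in table.index]
    if not present:
        raise ValueError("no usable genes for the module score")
    values = table.loc[present, "log2fc"].abs().to_numpy(float)
    if weighting == "plain":
        return float(values.mean())
    if weighting != "kme":
        raise ValueError(f"unknown weighting {weighting!r}")
    if kme is None:
        raise ValueError("kme weights required for kme weighting")
    w = np.abs(np.array([kme.get(g, 0.0) for g in present], float))
    if w.sum() == 0:
        return float(values.mean())
    return float(np.average(values, weights=w / w.sum()))


def concentration_trend(scores: Sequence[float],
                        concentrations: Sequence[float],
                        alpha: float = 0.05) -> dict:
    """OLS of module score on log10 concentration.

    Returns slope, standard error, two-sided p, 95% CI and the
    dose-responsive call (positive slope with p < alpha).  With exactly two
    concentrations the slope is reported but inference is flagged NA.
    """
    conc = np.asarray(concentrations, float)
    y = np.asarray(scores, float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if conc.size != y.size or conc.size < 2:
        raise ValueError("need matching scores for >= 2 concentrations")
    x = np.log10(conc)
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    res = stats.linregress(x, y)
    out = {"slope": float(res.slope), "intercept": float(res.intercept)}
    if np.unique(x).size < 3:
        out.update(stderr=np.nan, pvalue=np.nan, ci_low=np.nan, ci_high=np.nan,
                   dose_responsive=False)
        return out
    df = x.size - 2
    tcrit = stats.t.ppf(0.975, df)
    out.update(
        stderr=float(res.stderr),
        pvalue=float(res.pvalue),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        dose_responsive=bool(res.slope > 0 and res.pvalue < alpha),
    )
    return out


def recurrent_degs(measured_genes: Sequence[str],
                   conditions: Sequence[ConditionDEG],
                   min_hits: int = 2) -> list[str]:
    """Measured module genes called DEG at >= ``min_hits`` concentrations of
    one compound (conditions must all belong to that compound)."""
    compounds = {c.compound for c in conditions}
    if len(compounds) > 1:
        raise ValueError(f"conditions span multiple compounds: {sorted(compounds)}")
    hits: dict[str, int] = {}
    for cond in conditions:
        table = cond.table.set_index("gene_id")
        for g in measured_genes:
            if g in table.index and bool(table.loc[g, "is_deg"]):
                hits[g] = hits.get(g, 0) + 1
    return sorted(g for g, n in hits.items() if n >= min_hits)


def project_modules(
    module_genes: Mapping[int, Sequence[str]],
    panel: Sequence[str],
    conditions: Sequence[ConditionDEG],
    params: ProjectionParams | None = None,
    kme: Mapping[str, float] | None = None,
) -> ProjectionResult:
    """Run the full projection over all modules and conditions."""
    params = params or ProjectionParams()
    measured = restrict_to_panel(module_genes, panel, params.min_measured_genes)
    measured_map = dict(zip(measured["module_id"], measured["measured_genes"]))
    evaluable = dict(zip(measured["module_id"], measured["evaluable"]))

    act_rows = []
    for module in sorted(module_genes):
        for cond in conditions:
            row = {"module_id": module, "compound": cond.compound,
                   "concentration": cond.concentration}
            if not evaluable[module]:
                row.update(n_measured=len(measured_map[module]), n_deg=np.nan,
                           deg_fraction=np.nan, activated=False,
                           module_score=np.nan, evaluable=False)
            else:
                genes = measured_map[module]
                frac, active = deg_fraction(
                    genes, cond, params.activation_fraction_threshold)
                row.update(
                    n_measured=len(genes),
                    n_deg=int(round(frac * len(genes))),
                    deg_fraction=frac, activated=active,
                    module_score=module_score(
                        genes, cond, params.score_weighting, kme),
                    evaluable=True,
                )
            act_rows.append(row)
    activation = pd.DataFrame(act_rows)

    trend_rows, rec_rows = [], []
    compounds = sorted({c.compound for c in conditions})
    for compound in compounds:
        conds = sorted((c for c in conditions if c.compound == compound),
                       key=lambda c: c.concentration)
        for module in sorted(module_genes):
            if not evaluable[module]:
                continue
            sub = activation[(activation["module_id"] == module)
                             & (activation["compound"] == compound)]
            sub = sub.sort_values("concentration")
            trend = concentration_trend(
                sub["module_score"], sub["concentration"], params.trend_alpha)
            trend_rows.append({"module_id": module, "compound": compound, **trend})
            if len(conds) >= 2:
                for gene in recurrent_degs(measured_map[module], conds):
                    rec_rows.append({"module_id": module, "compound": compound,
                                     "gene_id": gene})
    trends = pd.DataFrame(trend_rows)
    recurrent = pd.DataFrame(rec_rows, columns=["module_id", "compound", "gene_id"])
    if len(recurrent):
        multi = recurrent.groupby("gene_id")["compound"].nunique()
        recurrent["multi_compound"] = recurrent["gene_id"].map(multi).ge(2)
    else:
        recurrent["multi_compound"] = pd.Series(dtype=bool)
    not_eval = [int(m) for m, ok in evaluable.items() if not ok]
    return ProjectionResult(activation=activation, trends=trends,
                            recurrent=recurrent,
                            measured=measured.drop(columns="measured_genes"),
                            not_evaluable=not_eval)
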