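# fibromod

Phase-specific co-expression biomarker modules for chemically induced lung
fibrosis — module discovery from in vivo time-course transcriptomics,
differential-activity phase selection, annotation, and projection onto
targeted-panel concentration-response data.

## The problem

Lung fibrosis induced by chemicals (bleomycin being the classic model
compound) develops in histopathologically distinct phases: an inflammatory
phase (days 1–2 after exposure), an acute fibrotic phase (days 7–14) and a
late fibrotic phase (day 21 onwards). Groups of co-expressed genes whose
activity peaks in a particular phase are candidate *composite biomarkers*:
applied to short-term in vitro assays they can flag compounds likely to
drive fibrosis, long before any tissue-level outcome is observable. This
package implements that workflow for toxicologists and computational
biologists building such screens, together with a synthetic-data generator
so every stage is testable against known ground truth.

## The method

**Module discovery** follows the weighted co-expression recipe. For genes
*i, j* with Pearson correlation *cor(i, j)* the unsigned soft-threshold
adjacency is

    a_ij = |cor(i, j)|^β          (β = 4)

and pairwise similarity is the topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    k_i = Σ_j a_ij.

Genes are clustered by average linkage on `1 − TOM`; branches holding at
least 30 genes become modules (a recursive branch decomposition with a
variance-explained cohesion filter by default; a classic static height cut
is available), and modules whose **eigengenes** — the first principal
component of the standardized module submatrix — correlate with |r| > 0.75
are merged. Each module is summarized by its eigengene, its variance
explained, and its **hub gene** (the member with maximal kME, the
correlation with the eigengene).

**Phase selection** scores each module in each phase as the mean absolute
eigengene entry over that phase's samples (EG score). Control samples also
achieve non-zero activity, so selection uses the **differential activity**

    DA(m, P) = EG(m, P) / EG(m, control),

and a module is selected — and assigned to a phase — when DA ≥ 2.5.

**Projection** applies frozen modules to external per-condition DEG tables
from a reduced gene panel (DEG: BH-adjusted p < 0.05 and |log2FC| ≥ 1). A
module is *activated* in a condition when strictly more than 20% of its
measured genes are DEGs; the *module score* is the mean |log2FC| over all
measured module genes. Concentration-responsiveness is assessed by OLS of
the module score on log10 concentration (dose-responsive: slope > 0,
p < 0.05), and genes differentially expressed at ≥ 2 concentrations of a
compound are reported as recurrent.

## Worked example

```python
import fibromod as fm

config = fm.SimulationConfig(seed=1)          # 2000 genes, 8 planted modules
expr, design, truth = fm.simulate_invivo(config)
modules = fm.detect_modules(expr)
report = fm.phase_activity_report(modules, fm.build_phase_map(design))
cols = ["module_id", "DA_inflammatory", "DA_acute", "DA_late",
        "selected", "assigned_phases", "hub_gene"]
print(report[cols].round(2).to_string(index=False))
```

prints

```
 module_id  DA_inflammatory  DA_acute  DA_late  selected   assigned_phases hub_gene
         1             0.99      1.21     8.20      True              late   G00840
         2             2.77      2.08    21.50      True inflammatory,late   G00592
         3             1.88     12.31     1.85      True             acute   G00421
         4             1.02     12.57     2.13      True             acute   G00247
         5             1.05     15.47     1.35      True             acute   G00207
         6             8.23      1.32     1.05      True      inflammatory   G00092
         7            11.05      1.60     1.18      True      inflammatory   G00055
         8            18.07      1.21     1.48      True      inflammatory   G00004
```

All eight planted modules are recovered at their planted sizes (30–250
genes), each peaks (largest DA, shown per row) in its planted phase, and all
are selected at the DA ≥ 2.5 threshold; the hub gene is the member most
strongly correlated with the module eigengene. Off-peak DA values sit near
1, i.e. near control-level activity.

The same workflow is available from the shell:

```bash
fibromod all --seed 1 --out run_out     # simulate → deg → network → phase-da → project
fibromod report --out run_out           # text summary of the artifacts
```

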