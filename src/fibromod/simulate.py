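"""Synthetic time-course and concentration-response expression data.

Emulates two study designs with known planted structure so that every
downstream stage (normalization, differential expression, network module
detection, phase scoring, panel projection) can be validated against ground
truth:

* an in vivo mouse time course: treated vs control animals sampled at eight
  timepoints spanning the inflammatory (days 1-2), acute fibrotic (days 7-14)
  and late fibrotic (day >= 21) phases of developing lung fibrosis, with
  co-expression modules whose activity peaks in a chosen phase;
* an in vitro targeted-panel concentration series (airway epithelial cells
  exposed to compounds at 4-7 sub-cytotoxic levels, sequenced counts with a
  handful of replicates per condition).

Planted module model
--------------------
Each module m has a latent per-sample activity score

    z_s = A * f(day_s) * (1 + cv * eps_s) + A * sigma_lat * eps'_s

where ``A`` is the module amplitude (log2 units), ``f`` the phase trajectory
(1 during the module's phase, a small baseline elsewhere, 0 in controls),
``cv`` the between-animal response heterogeneity and ``sigma_lat`` a small
residual latent wobble.  Both noise terms scale with ``A`` so an amplitude-0
(null) module carries no shared signal at all.  Gene g of the module observes
``loading_g * z_s`` plus independent Gaussian noise; loadings carry random
sign, so module members may be strongly positively or negatively correlated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

PHASE_PROFILES = ("inflammatory", "acute", "late", "general", "null")

#: phases of bleomycin-induced fibrosis by day of sampling
INFLAMMATORY_DAYS = (1, 2)
ACUTE_DAYS = (7, 14)
LATE_FROM_DAY = 21

DEFAULT_TIMEPOINTS = (1, 2, 7, 14, 21, 28, 35)


def phase_for_day(day: float) -> str:
    """Histopathology-derived phase label for a treated sample at ``day``."""
    if day in INFLAMMATORY_DAYS:
        return "inflammatory"
    if day in ACUTE_DAYS:
        return "acute"
    if day >= LATE_FROM_DAY:
        return "late"
    # days between the named ranges (e.g. 3-6) fall to the nearer early phase
    return "inflammatory" if day < ACUTE_DAYS[0] else "acute"


def phase_trajectory(profile: str, day: float, baseline: float = 0.1) -> float:
    """Latent module activity in [0, 1] for a treated sample at ``day``.

    ``inflammatory`` peaks on days 1-2, ``acute`` on days 7-14, ``late`` from
    day 21 onwards; off-phase days sit at ``baseline`` (default 0.1, so phase
    specificity rather than mere on/off behaviour is exercised).  ``general``
    is active on every treated day and ``null`` is identically zero.
    """
    if profile == "null":
        return 0.0
    if profile == "general":
        return 1.0
    if profile == "inflammatory":
        return 1.0 if day in INFLAMMATORY_DAYS else baseline
    if profile == "acute":
        return 1.0 if day in ACUTE_DAYS else baseline
    if profile == "late":
        return 1.0 if day >= LATE_FROM_DAY else baseline
    raise ValueError(f"unknown phase profile: {profile!r}")


@dataclass(frozen=True)
class ModulePlan:
    """Blueprint for one planted co-expression module."""

    module_id: str
    size: int
    phase_profile: str
    amplitude: float = 1.5
    loading_range: tuple[float, float] = (0.4, 0.9)

    def __post_init__(self) -> None:
        if self.size < 30:
            raise ValueError(f"module size must be >= 30, got {self.size}")
        if self.phase_profile not in PHASE_PROFILES:
            raise ValueError(f"unknown phase profile: {self.phase_profile!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.phase_profile == "null" and self.amplitude != 0:
            raise ValueError("null profile requires amplitude 0")
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid loading range {self.loading_range}")


def default_module_plans(amplitude: float = 1.5) -> list[ModulePlan]:
    """Eight planted modules mirroring the in vivo study: phase-peaked
    modules of 30-250 genes covering all three fibrosis phases."""
    sizes = (30, 40, 60, 80, 100, 150, 200, 250)
    profiles = ("inflammatory", "inflammatory", "inflammatory",
                "acute", "acute", "acute", "late", "late")
    return [
        ModulePlan(f"M{i}", size, prof, amplitude=amplitude)
        for i, (size, prof) in enumerate(zip(sizes, profiles), start=1)
    ]


@dataclass
class SimulationConfig:
    """Parameters of the in vivo time-course generator.

    Defaults mirror the emulated study design: 7 post-exposure timepoints,
    8 treated and 8 control animals per timepoint, unit-variance residual
    noise per gene.  ``activity_cv`` is the coefficient of variation of the
    module response between treated animals (bleomycin responses are highly
    heterogeneous); both latent noise terms scale with the module amplitude.
    """

    n_genes: int = 2000
    module_plans: list[ModulePlan] = field(default_factory=default_module_plans)
    timepoints: tuple[int, ...] = DEFAULT_TIMEPOINTS
    n_per_group: int = 8
    noise_sd: float = 1.0
    activity_cv: float = 3.0
    latent_sd: float = 0.05
    count_mode: bool = False
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p.size for p in self.module_plans)
        if total > self.n_genes:
            raise ValueError(
                f"planted module sizes sum to {total} > n_genes={self.n_genes}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class TruthLabels:
    """Ground-truth gene->module assignment of a simulated dataset."""

    labels: pd.Series  # gene_id -> module_id ("" for background)
    profiles: dict[str, str]  # module_id -> phase profile

    def module_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, mod in self.labels.items():
            if mod:
                out.setdefault(mod, []).append(gene)
        return out


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_invivo(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Simulate the treated-vs-control mouse time course.

    Returns ``(expression, design, truth)`` where ``expression`` is a
    genes x samples DataFrame (log-intensity scale, or negative-binomial
    counts if ``count_mode``), ``design`` has one row per sample with columns
    ``sample_id, day, group, phase``, and ``truth`` records the planted
    assignment.  Identical configs (including seed) give identical output.
    """
    rng_noise, rng_mod, rng_base = _spawn_rngs(config.seed, 3)

    days = np.repeat(config.timepoints, config.n_per_group)
    n_t = days.size
    all_days = np.concatenate([days, days])
    treated = np.concatenate([np.ones(n_t, bool), np.zeros(n_t, bool)])
    n_samples = 2 * n_t

    sample_ids = [
        f"{'T' if tr else 'C'}_d{d}_r{i % config.n_per_group + 1}"
        for i, (d, tr) in enumerate(zip(all_days, treated))
    ]
    design = pd.DataFrame({
        "sample_id": sample_ids,
        "day": all_days,
        "group": np.where(treated, "treated", "control"),
        "phase": [phase_for_day(d) if tr else "control"
                  for d, tr in zip(all_days, treated)],
    })

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    X = rng_noise.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

    labels = pd.Series([""] * config.n_genes, index=gene_ids, name="module_id")
    profiles: dict[str, str] = {}
    g0 = 0
    for plan in config.module_plans:
        traj = np.array([phase_trajectory(plan.phase_profile, d) for d in all_days])
        traj[~treated] = 0.0
        hetero = 1.0 + config.activity_cv * rng_mod.normal(0.0, 1.0, n_samples)
        z = plan.amplitude * traj * hetero
        z += plan.amplitude * config.latent_sd * rng_mod.normal(0.0, 1.0, n_samples)
        loadings = rng_mod.uniform(*plan.loading_range, plan.size)
        loadings *= rng_mod.choice([-1.0, 1.0], plan.size)
        X[g0:g0 + plan.size] += loadings[:, None] * z[None, :]
        labels.iloc[g0:g0 + plan.size] = plan.module_id
        profiles[plan.module_id] = plan.phase_profile
        g0 += plan.size

    if config.count_mode:
        base = rng_base.uniform(3.0, 9.0, config.n_genes)
        mu = 2.0 ** (base[:, None] + X)
        X = _nb_sample(rng_base, mu, config.dispersion).astype(float)

    expr = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    return expr, design, TruthLabels(labels=labels, profiles=profiles)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with mean ``mu`` and var ``mu + d*mu^2``
    via the gamma-Poisson mixture (Poisson when dispersion is 0)."""
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# in vitro concentration series


COMPOUND_CLASSES = ("fibrosis", "inflammation", "inert")


def dose_factor(
    concentration: float,
    concentrations: Sequence[float],
    floor: float = 0.25,
) -> float:
    """Planted dose-effect multiplier in [floor, 1].

    Linear in log10 concentration between the lowest (``floor``) and highest
    (1.0) tested level, so module scores regressed on log10 concentration
    have an exactly linear planted trend.
    """
    conc = np.asarray(concentrations, float)
    if np.any(conc <= 0) or concentration <= 0:
        raise ValueError("concentrations must be strictly positive")
    lo, hi = np.log10(conc.min()), np.log10(conc.max())
    if hi == lo:
        return 1.0
    t = (np.log10(concentration) - lo) / (hi - lo)
    return floor + (1.0 - floor) * float(t)


@dataclass
class InvitroDataset:
    """One simulated panel experiment: per-condition count matrices plus the
    planted per-gene log2 fold changes."""

    counts: dict[tuple[str, float], pd.DataFrame]  # (compound, conc) -> genes x samples
    designs: dict[tuple[str, float], pd.DataFrame]
    planted_lfc: dict[tuple[str, float], pd.Series]
    panel: list[str]
    compound_classes: dict[str, str]
    concentrations: list[float]


def default_panel(truth: TruthLabels, rng: np.random.Generator,
                  n_background: int = 200,
                  all_genes: Sequence[str] | None = None) -> list[str]:
    """Targeted panel covering roughly 20% of each planted module (clipped to
    4-42 genes, the coverage range of the emulated reduced panel) plus
    background genes."""
    panel: list[str] = []
    for mod, genes in sorted(truth.module_genes().items()):
        n = int(np.clip(round(0.2 * len(genes)), 4, 42))
        take = rng.choice(len(genes), size=n, replace=False)
        panel += [genes[i] for i in sorted(take)]
    if all_genes is not None:
        background = [g for g in all_genes if not truth.labels.get(g, "")]
        n_bg = min(n_background, len(background))
        take = rng.choice(len(background), size=n_bg, replace=False)
        panel += [background[i] for i in sorted(take)]
    return panel


def simulate_invitro(
    config: SimulationConfig,
    truth: TruthLabels,
    panel: Sequence[str],
    compound_classes: Mapping[str, str],
    concentrations: Sequence[float],
    n_replicates: int = 3,
    lfc_range: tuple[float, float] = (2.0, 4.0),
    background_hit_fraction: float = 0.3,
    dose_floor: float = 0.25,
) -> InvitroDataset:
    """Simulate the targeted-panel concentration series.

    ``compound_classes`` maps compound name -> class: ``fibrosis`` compounds
    shift panel genes of every planted (non-null) module, ``inflammation``
    compounds only genes of inflammatory-profile modules, ``inert`` compounds
    shift nothing.  Active (non-inert) compounds additionally shift a random
    ``background_hit_fraction`` of off-module panel genes, emulating the
    broad stress response real exposures provoke beyond the fibrosis
    modules.  Planted |log2FC| grows with concentration via
    :func:`dose_factor`; counts are negative-binomial with the configured
    dispersion, ``n_replicates`` treated vs control samples per condition.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    known = set(truth.labels.index)
    missing = [g for g in panel if g not in known]
    if missing:
        raise ValueError(f"panel genes outside the simulated universe: {missing[:5]}")
    for name, cls in compound_classes.items():
        if cls not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {cls!r} for {name!r}")
    conc = sorted(float(c) for c in concentrations)
    if len(conc) < 2:
        raise ValueError("need at least 2 concentration levels")

    rng_gene, rng_counts = _spawn_rngs(config.seed + 1_000_003, 2)

    # per-gene baseline expression and per-(compound, gene) latent effect
    baseline = pd.Series(rng_gene.lognormal(np.log(200.0), 1.0, len(panel)), index=panel)
    gene_module = truth.labels.reindex(panel).fillna("")
    profiles = truth.profiles

    counts: dict[tuple[str, float], pd.DataFrame] = {}
    designs: dict[tuple[str, float], pd.DataFrame] = {}
    planted: dict[tuple[str, float], pd.Series] = {}
    for compound in sorted(compound_classes):
        cls = compound_classes[compound]
        base_lfc = pd.Series(
            rng_gene.uniform(*lfc_range, len(panel))
            * rng_gene.choice([-1.0, 1.0], len(panel)),
            index=panel,
        )
        background_hit = pd.Series(
            rng_gene.random(len(panel)) < background_hit_fraction, index=panel)
        affected = pd.Series(False, index=panel)
        if cls == "fibrosis":
            affected[:] = [
                bool(m) and profiles.get(m) != "null" for m in gene_module
            ]
        elif cls == "inflammation":
            affected[:] = [profiles.get(m) == "inflammatory" for m in gene_module]
        if cls != "inert":
            affected |= (gene_module == "") & background_hit
        for c in conc:
            lfc = base_lfc.where(affected, 0.0) * dose_factor(c, conc, dose_floor)
            mu_ctrl = np.tile(baseline.values[:, None], (1, n_replicates))
            mu_trt = baseline.values[:, None] * 2.0 ** lfc.values[:, None]
            mu_trt = np.tile(mu_trt, (1, n_replicates))
            mu = np.hstack([mu_trt, mu_ctrl])
            mat = _nb_sample(rng_counts, mu, config.dispersion).astype(float)
            cols = [f"{compound}_{c:g}_T{i+1}" for i in range(n_replicates)] + \
                   [f"{compound}_{c:g}_C{i+1}" for i in range(n_replicates)]
            counts[(compound, c)] = pd.DataFrame(mat, index=panel, columns=cols)
            designs[(compound, c)] = pd.DataFrame({
                "sample_id": cols,
                "group": ["treated"] * n_replicates + ["control"] * n_replicates,
            })
            planted[(compound, c)] = lfc
    return InvitroDataset(
        counts=counts, designs=designs, planted_lfc=planted, panel=panel,
        compound_classes=dict(compound_classes), concentrations=conc,
    )


# ---------------------------------------------------------------------------
# I/O


def write_invivo(outdir: str | Path, expr: pd.DataFrame, design: pd.DataFrame,
                 truth: TruthLabels, config: SimulationConfig) -> dict[str, Path]:
    """Write expression / design / truth TSVs and the config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "simulation.yaml",
    }
    expr.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    design.to_csv(paths["design"], sep="\t", index=False)
    truth_df = truth.labels.rename("module_id").to_frame()
    truth_df["phase_profile"] = [
        truth.profiles.get(m, "") for m in truth.labels
    ]
    truth_df.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    cfg = dataclasses.asdict(config)
    cfg["module_plans"] = [dataclasses.asdict(p) for p in config.module_plans]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths
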