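"""Weighted co-expression network construction and module detection.

The pipeline follows the standard weighted co-expression recipe: Pearson
correlation -> unsigned soft-threshold adjacency ``|cor|^beta`` (default
beta = 4) -> topological overlap matrix (TOM) -> average-linkage clustering
of ``1 - TOM`` -> branch decomposition into modules of at least 30 genes ->
merging of modules whose eigengenes correlate above 0.75.

The network is unsigned so that strongly anti-correlated genes land in the
same module.  Each module is summarized by its eigengene (first principal
component of the standardized member submatrix, one entry per sample) and
its hub gene (the member correlating most strongly with the eigengene).

Two branch-cutting strategies are provided.  ``static`` cuts the dendrogram
at a fixed fraction of the maximum merge height and keeps branches of at
least the minimum module size.  The default ``recursive`` strategy walks the
dendrogram top-down, splitting any node whose children could still hold a
module and collecting terminal branches as module candidates; candidates
must beat a size-dependent variance-explained floor (what the first
principal component of pure noise would explain) to survive, weak members
are stripped by module membership (kME), and unassigned genes with strong
membership are rescued back.  The recursive strategy is far more robust when
a diffuse background blob dominates the upper dendrogram, where any single
cut height either fragments the background into spurious modules or swallows
real ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkParams", "ModuleSet", "drop_zero_variance", "correlation_matrix",
    "soft_adjacency", "scale_free_fit", "scan_soft_threshold",
    "topological_overlap", "cluster_genes", "cut_static", "cut_recursive",
    "compute_eigengenes", "merge_modules", "hub_genes", "detect_modules",
]


@dataclass
class NetworkParams:
    """Tuning parameters of the network stage."""

    power: int = 4
    min_module_size: int = 30
    merge_cor_threshold: float = 0.75
    cut_height_quantile: float = 0.99
    use_tom: bool = True
    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 8, 10, 12)
    cut_method: str = "recursive"  # or "static"
    core_min: int = 10
    kme_min: float = 0.3
    kme_rescue: float = 0.4
    ve_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 < self.merge_cor_threshold < 1:
            raise ValueError("merge_cor_threshold must be in (0, 1)")
        if not 0 < self.cut_height_quantile < 1:
            raise ValueError("cut_height_quantile must be in (0, 1)")
        if self.cut_method not in ("recursive", "static"):
            raise ValueError(f"unknown cut_method {self.cut_method!r}")


@dataclass
class ModuleSet:
    """Detected modules: labels, eigengenes and summaries.

    ``labels`` maps every clustered gene to an integer module id, with 0
    reserved for unassigned genes.  Eigengene columns are unit-norm sample
    vectors, sign-oriented so the mean member correlation is non-negative.
    """

    labels: pd.Series                 # gene_id -> int (0 = unassigned)
    eigengenes: pd.DataFrame          # samples x modules
    hub_gene: dict[int, str]
    variance_explained: dict[int, float]
    kme: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(c) for c in self.eigengenes.columns)

    @property
    def sizes(self) -> dict[int, int]:
        counts = self.labels[self.labels > 0].value_counts()
        return {int(m): int(counts.get(m, 0)) for m in self.module_ids}

    def module_genes(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def to_frame(self) -> pd.DataFrame:
        """gene_id, module_id, kME table (assigned genes only)."""
        assigned = self.labels[self.labels > 0]
        return pd.DataFrame({
            "gene_id": assigned.index,
            "module_id": assigned.to_numpy(int),
            "kME": self.kme.reindex(assigned.index).to_numpy(float),
        })


def drop_zero_variance(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove genes with zero variance; returns (filtered, dropped ids)."""
    sd = matrix.std(axis=1, ddof=0)
    dropped = list(matrix.index[sd == 0])
    return matrix.loc[sd > 0], dropped


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation (genes in rows)."""
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    sd = matrix.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = list(matrix.index[sd == 0])[:5]
        raise ValueError(f"zero-variance genes present (drop first): {bad}")
    cor = np.corrcoef(matrix.to_numpy(float))
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=matrix.index, columns=matrix.index)


def soft_adjacency(cor: pd.DataFrame | np.ndarray, power: int = 4) -> np.ndarray:
    """Unsigned soft-threshold adjacency ``|cor|^power`` with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    a = np.abs(np.asarray(cor, float)) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of the weighted degree distribution.

    Bins the connectivities ``k_i = sum_j a_ij``, regresses log10(frequency)
    on log10(mean k per bin) and returns the signed R^2 (negated when the
    slope is positive, the convention used for soft-threshold selection)
    together with the mean connectivity.
    """
    k = np.asarray(adjacency, float).sum(axis=1)
    mean_k = float(k.mean())
    if np.allclose(k, k[0]):
        warnings.warn("degenerate connectivity (all equal); R^2 reported as 0")
        return 0.0, mean_k
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    keep = np.flatnonzero(counts > 0)
    bin_k = np.array([k[which == b].mean() for b in keep])
    freq = counts[keep] / k.size
    usable = bin_k > 0
    if usable.sum() < 3:
        warnings.warn("too few usable connectivity bins; R^2 reported as 0")
        return 0.0, mean_k
    x, y = np.log10(bin_k[usable]), np.log10(freq[usable])
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(-np.sign(slope) * r ** 2), mean_k


def scan_soft_threshold(cor: pd.DataFrame | np.ndarray,
                        candidate_powers=(1, 2, 3, 4, 5, 6, 8, 10, 12)) -> pd.DataFrame:
    """Scale-free fit for each candidate power (one row per power)."""
    rows = []
    for p in candidate_powers:
        r2, mk = scale_free_fit(soft_adjacency(cor, p))
        rows.append({"power": int(p), "r_squared": r2, "mean_connectivity": mk})
    return pd.DataFrame(rows)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for
    i != j and 1 on the diagonal; shared neighbours raise the similarity of
    a gene pair beyond its direct adjacency.
    """
    a = np.asarray(adjacency, float)
    if (a < 0).any():
        raise ValueError("adjacency entries must be non-negative")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    numerator = a @ a + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cluster_genes(dissimilarity: np.ndarray) -> np.ndarray:
    """Average-linkage hierarchical clustering; returns the scipy linkage
    matrix.  Deterministic for a fixed input (scipy's tie-breaking)."""
    d = np.asarray(dissimilarity, float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity contains NaN")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    return linkage(squareform(d, checks=False), method="average")


def _standardize(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    if (sd == 0).any():
        raise ValueError("constant gene rows cannot be standardized")
    return x / sd[:, None]


def _eigengene(xs: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """(unit-norm eigengene, variance explained, member kMEs) of a z-scored
    submatrix.  Sign: mean member correlation >= 0; exact ties fall back to
    making the first member's correlation positive."""
    _, s, vt = np.linalg.svd(xs, full_matrices=False)
    e = vt[0]
    kme = _corr_with(xs, e)
    mean_kme = kme.mean()
    if mean_kme < 0 or (np.isclose(mean_kme, 0.0) and kme[0] < 0):
        e, kme = -e, -kme
    ve = float(s[0] ** 2 / (s ** 2).sum())
    return e, ve, kme


def _corr_with(xs: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Pearson correlation of each z-scored row of ``xs`` with vector ``e``."""
    ec = e - e.mean()
    norm = np.linalg.norm(ec)
    if norm == 0:
        return np.zeros(xs.shape[0])
    return xs @ (ec / norm) / np.sqrt(xs.shape[1])


def compute_eigengenes(matrix: pd.DataFrame, labels: pd.Series) -> ModuleSet:
    """Eigengene, variance explained, kME and hub gene for every module.

    Genes are z-scored before the decomposition; the eigengene is the first
    right-singular vector (length = number of samples, unit Euclidean norm).
    """
    labels = labels.reindex(matrix.index).fillna(0).astype(int)
    eig: dict[int, np.ndarray] = {}
    ve: dict[int, float] = {}
    hubs: dict[int, str] = {}
    kme_all = pd.Series(np.nan, index=matrix.index, dtype=float)
    for m in sorted(set(labels) - {0}):
        genes = labels.index[labels == m]
        if len(genes) < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        xs = _standardize(matrix.loc[genes])
        e, v, kme = _eigengene(xs)
        eig[m], ve[m] = e, v
        kme_all.loc[genes] = kme
        order = np.lexsort((np.asarray(genes, str), -kme))
        hubs[m] = str(genes[order[0]])
    eg = pd.DataFrame(eig, index=matrix.columns)
    return ModuleSet(labels=labels, eigengenes=eg, hub_gene=hubs,
                     variance_explained=ve, kme=kme_all)


def hub_genes(module_set: ModuleSet) -> pd.DataFrame:
    """Per-module hub gene table (module_id, hub_gene, kME)."""
    rows = [
        {"module_id": m, "hub_gene": module_set.hub_gene[m],
         "kME": float(module_set.kme.loc[module_set.hub_gene[m]])}
        for m in module_set.module_ids
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# branch cutting


def _node_members(z: np.ndarray, n: int) -> list[list[int]]:
    members: list[list[int] | None] = [[i] for i in range(n)] + [None] * (n - 1)
    for j in range(n - 1):
        a, b = int(z[j, 0]), int(z[j, 1])
        members[n + j] = members[a] + members[b]  # type: ignore[operator]
    return members  # type: ignore[return-value]


def cut_static(z: np.ndarray, n_genes: int, min_module_size: int = 30,
               height_fraction: float = 0.99) -> np.ndarray:
    """Static cut at ``height_fraction`` of the maximum merge height;
    branches of at least ``min_module_size`` become modules (labelled by
    decreasing size), everything else is 0."""
    from scipy.cluster.hierarchy import fcluster

    height = height_fraction * z[:, 2].max()
    flat = fcluster(z, t=height, criterion="distance")
    out = np.zeros(n_genes, int)
    sizes = pd.Series(flat).value_counts()
    next_id = 1
    for cluster_id in sizes.index:
        if sizes[cluster_id] < min_module_size:
            continue
        out[flat == cluster_id] = next_id
        next_id += 1
    if next_id == 1:
        warnings.warn("no branch reached the minimum module size; all genes unassigned")
    return out


def _branch_candidates(z: np.ndarray, n: int, min_module_size: int,
                       core_min: int) -> list[np.ndarray]:
    """Top-down two-branch decomposition of the dendrogram.

    Descends while a child could still contain a module (size >= the minimum
    module size); terminal nodes and sub-minimum side branches of at least
    ``core_min`` genes are returned as module candidates.
    """
    members = _node_members(z, n)
    sizes = [len(m) for m in members]
    candidates: list[np.ndarray] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        a, b = int(z[node - n, 0]), int(z[node - n, 1])
        big = [c for c in (a, b) if sizes[c] >= min_module_size]
        if len(big) == 2:
            stack += big
        elif len(big) == 1:
            stack.append(big[0])
            other = b if big[0] == a else a
            if sizes[other] >= core_min:
                candidates.append(np.asarray(members[other]))
        else:
            if sizes[node] >= core_min:
                candidates.append(np.asarray(members[node]))
    return candidates


def _noise_ve(n_genes: int, n_samples: int) -> float:
    """Variance explained by the first PC of pure noise (random-matrix
    largest-eigenvalue approximation)."""
    return (1.0 + np.sqrt(n_genes / n_samples)) ** 2 / n_genes


def cut_recursive(matrix: pd.DataFrame, z: np.ndarray,
                  params: NetworkParams) -> tuple[np.ndarray, dict[int, int]]:
    """Recursive branch decomposition with cohesion filtering.

    Returns integer labels (0 = unassigned) plus the originating branch size
    per label.  Candidates whose first principal component explains less
    than ``ve_factor`` times the noise floor are discarded; members with
    ``|kME| < kme_min`` are stripped.
    """
    n, n_samples = matrix.shape
    x_all = matrix.to_numpy(float)
    candidates = _branch_candidates(z, n, params.min_module_size, params.core_min)
    labels = np.zeros(n, int)
    branch_size: dict[int, int] = {}
    next_id = 1
    for idx in candidates:
        sub = x_all[idx]
        sd = sub.std(axis=1)
        if (sd == 0).any():
            continue
        xs = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, ve, kme = _eigengene(xs)
        if ve < params.ve_factor * _noise_ve(len(idx), n_samples):
            continue
        keep = idx[np.abs(kme) >= params.kme_min]
        if len(keep) < 3:
            continue
        labels[keep] = next_id
        branch_size[next_id] = len(idx)
        next_id += 1
    return labels, branch_size


def merge_modules(matrix: pd.DataFrame, labels: pd.Series,
                  r_merge: float = 0.75) -> ModuleSet:
    """Iteratively merge the module pair with the highest absolute eigengene
    correlation until no pair exceeds ``r_merge`` (ties broken towards the
    lowest module indices), then recompute all summaries."""
    labels = labels.reindex(matrix.index).fillna(0).astype(int).copy()
    while True:
        module_set = compute_eigengenes(matrix, labels)
        mods = module_set.module_ids
        if len(mods) < 2:
            break
        eg = module_set.eigengenes.loc[:, mods].to_numpy(float)
        r = np.abs(np.corrcoef(eg.T))
        np.fill_diagonal(r, -1.0)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if r[i, j] <= r_merge:
            break
        lo, hi = sorted((mods[i], mods[j]))
        labels[labels == hi] = lo
    return module_set


def _renumber_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels > 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    remap = {old: new for new, old in enumerate(order, start=1)}
    return labels.map(lambda m: remap.get(m, 0)).astype(int)


def detect_modules(matrix: pd.DataFrame,
                   params: NetworkParams | None = None) -> ModuleSet:
    """Full module-detection pass on a (log-scale) expression matrix.

    correlation -> soft adjacency -> (optionally TOM) dissimilarity ->
    average-linkage dendrogram -> branch cutting -> eigengene merging ->
    kME rescue of unassigned genes -> minimum-size filter.  The final labels
    are renumbered by decreasing module size, 0 meaning unassigned.
    """
    params = params or NetworkParams()
    cor = correlation_matrix(matrix).to_numpy(float)
    adjacency = soft_adjacency(cor, params.power)
    if params.use_tom:
        similarity = topological_overlap(adjacency)
    else:
        similarity = adjacency.copy()
        np.fill_diagonal(similarity, 1.0)
    dissimilarity = 1.0 - similarity
    np.fill_diagonal(dissimilarity, 0.0)
    z = cluster_genes(dissimilarity)

    if params.cut_method == "static":
        raw = cut_static(z, len(matrix), params.min_module_size,
                         params.cut_height_quantile)
        branch_size = {int(m): int((raw == m).sum()) for m in set(raw) - {0}}
    else:
        raw, branch_size = cut_recursive(matrix, z, params)

    labels = pd.Series(raw, index=matrix.index)
    if (labels > 0).sum() == 0:
        warnings.warn("no modules detected")
        return compute_eigengenes(matrix, labels)

    # eigengene merging (branch sizes accumulate through merges)
    merged = merge_modules(matrix, labels, params.merge_cor_threshold)
    merged_sizes: dict[int, int] = {}
    for m in merged.module_ids:
        parts = set(labels[merged.labels == m]) - {0}
        merged_sizes[m] = sum(branch_size.get(int(p), 0) for p in parts)
    labels = merged.labels.copy()

    # rescue unassigned genes with strong module membership
    unassigned = labels.index[labels == 0]
    if len(unassigned) and merged.module_ids:
        xs = _standardize(matrix.loc[unassigned])
        mods = merged.module_ids
        corr = np.column_stack([
            _corr_with(xs, merged.eigengenes[m].to_numpy(float)) for m in mods
        ])
        best = np.abs(corr).argmax(axis=1)
        strong = np.abs(corr).max(axis=1) >= params.kme_rescue
        labels.loc[unassigned[strong]] = [mods[b] for b in best[strong]]

    # final minimum-size filter against the originating branch size
    for m in list(set(labels) - {0}):
        size = int((labels == m).sum())
        if max(size, merged_sizes.get(int(m), 0)) < params.min_module_size:
            labels[labels == m] = 0

    return compute_eigengenes(matrix, _renumber_by_size(labels))


# ---------------------------------------------------------------------------
# I/O


def write_modules(module_set: ModuleSet, assignment_path, eigengene_path) -> None:
    """Module assignment TSV (gene_id, module_id, kME) and eigengene matrix
    TSV (modules in rows, samples in columns)."""
    module_set.to_frame().to_csv(assignment_path, sep="\t", index=False)
    module_set.eigengenes.T.to_csv(eigengene_path, sep="\t", index_label="module_id")


def read_modules(assignment_path) -> pd.DataFrame:
    table = pd.read_csv(assignment_path, sep="\t")
    missing = {"gene_id", "module_id"} - set(table.columns)
    if missing:
        raise ValueError(f"module table missing columns: {sorted(missing)}")
    return table
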