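"""Unsigned weighted co-expression network construction and module detection.

The network is built on the experiments x genes fold-change matrix:
adjacency a_ij = |cor(g_i, g_j)|^beta (unsigned — co-induced and co-repressed
genes group together), converted to topological overlap (TOM) similarity and
clustered by average linkage on 1 - TOM.  Modules are the branches of a
static cut; clusters below ``min_module_size`` become unassigned.

The soft power beta is selected among candidate values by an expression-based
heuristic rather than a scale-free-topology fit index: non-expressed genes
are noise and should fall outside every module, so the power maximising the
Welch t-statistic of vehicle (DMSO) intensity, module members vs.
non-members, is chosen.  Modules whose eigengenes correlate at or above
``merge_eigengene_correlation`` are merged iteratively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import FoldChangeMatrix


@dataclass
class NetworkConfig:
    candidate_powers: tuple[int, ...] = (4, 6, 8, 10)
    min_module_size: int = 5
    merge_eigengene_correlation: float = 0.8
    cut_height: float = 0.99

    def validate(self) -> None:
        if not self.candidate_powers:
            raise ValueError("candidate_powers must be nonempty")
        if any(p < 1 for p in self.candidate_powers):
            raise ValueError("soft powers must be >= 1")
        if not (0 < self.merge_eigengene_correlation <= 1):
            raise ValueError("merge_eigengene_correlation must lie in (0, 1]")
        if not (0 < self.cut_height <= 1):
            raise ValueError("cut_height must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class GeneModule:
    module_id: str
    genes: list[str]
    weight_vector: np.ndarray | None = None  # unit-norm, orientation-fixed
    hub_gene: str | None = None


@dataclass
class ModuleSet:
    modules: list[GeneModule]
    unassigned: list[str]
    soft_power_used: int | None = None
    power_selection_tstats: dict[int, float] = field(default_factory=dict)

    def assignment(self) -> pd.Series:
        """gene -> module id ("" = unassigned), covering the full universe."""
        pairs = {g: m.module_id for m in self.modules for g in m.genes}
        pairs.update({g: "" for g in self.unassigned})
        return pd.Series(pairs, dtype=object)

    def module(self, module_id: str) -> GeneModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


def adjacency(fcm: FoldChangeMatrix, power: int) -> pd.DataFrame:
    """Soft-thresholded unsigned adjacency |pearson|^power with unit diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    X = fcm.values
    if X.shape[0] < 3:
        raise ValueError("need at least 3 experiments for correlations")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [g for g, s in zip(fcm.genes, sd) if s == 0]
        raise ValueError(f"zero-variance gene columns: {bad[:5]}")
    corr = np.corrcoef(X, rowvar=False)
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 1.0)
    a = np.clip(a, 0.0, 1.0)
    return pd.DataFrame(a, index=fcm.genes, columns=fcm.genes)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological-overlap similarity of an unsigned adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    A = adj.to_numpy()
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    k = A.sum(axis=0) - np.diag(A)
    # shared-neighbour sums excluding i and j themselves (diagonal is 1)
    L = A @ A - A * np.diag(A)[:, None] - A * np.diag(A)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom = np.where(denom > 0, tom, 1.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _cluster_genes(tom: pd.DataFrame, config: NetworkConfig) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    Returns gene -> module id ("" for genes in clusters below the size
    floor).  Module ids are assigned by decreasing module size.
    """
    genes = list(tom.index)
    diss = 1.0 - tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    cut = config.cut_height * Z[:, 2].max()
    labels = hierarchy.fcluster(Z, t=cut, criterion="distance")

    counts = pd.Series(labels).value_counts()
    keep = counts[counts >= config.min_module_size].index
    # stable ordering: by size desc, then smallest original label
    keep = sorted(keep, key=lambda lab: (-counts[lab], lab))
    relabel = {lab: f"M{i + 1:03d}" for i, lab in enumerate(keep)}
    return pd.Series(
        [relabel.get(lab, "") for lab in labels], index=pd.Index(genes, name="gene"), dtype=object
    )


def _modules_from_assignment(assignment: pd.Series) -> ModuleSet:
    modules = []
    for mid in sorted(assignment[assignment != ""].unique()):
        modules.append(GeneModule(module_id=mid, genes=list(assignment.index[assignment == mid])))
    unassigned = list(assignment.index[assignment == ""])
    return ModuleSet(modules=modules, unassigned=unassigned)


def membership_tstat(assignment: pd.Series, vehicle_intensity: pd.Series) -> float:
    """Welch t of vehicle log2 intensity, module members vs. non-members."""
    members = assignment != ""
    x = vehicle_intensity[assignment.index[members]]
    y = vehicle_intensity[assignment.index[~members]]
    if len(x) < 2 or len(y) < 2:
        return np.nan
    t, _ = stats.ttest_ind(x, y, equal_var=False)
    return float(t)


def detect_modules(
    fcm: FoldChangeMatrix,
    config: NetworkConfig,
    vehicle_intensity: pd.Series,
    merge: bool = True,
) -> ModuleSet:
    """Detect modules at the soft power maximising the expression t-statistic.

    For each candidate power: adjacency -> TOM -> average-linkage clustering
    -> static cut -> size floor; the Welch t-statistic (members vs.
    non-members on mean vehicle log2 intensity) scores the power.  The
    ModuleSet of the t-maximising power is returned (smallest power wins
    ties); similar modules are then merged unless ``merge`` is False.
    """
    config.validate()
    missing = set(fcm.genes) - set(vehicle_intensity.index)
    if missing:
        raise ValueError(f"vehicle intensities missing for genes {sorted(missing)[:5]}")

    tstats: dict[int, float] = {}
    assignments: dict[int, pd.Series] = {}
    for power in sorted(config.candidate_powers):
        adj = adjacency(fcm, power)
        tom = tom_similarity(adj)
        assignment = _cluster_genes(tom, config)
        if (assignment != "").sum() == 0:
            warnings.warn(f"power {power}: all genes unassigned; excluded from selection")
            tstats[power] = np.nan
            continue
        assignments[power] = assignment
        tstats[power] = membership_tstat(assignment, vehicle_intensity)

    valid = {p: t for p, t in tstats.items() if np.isfinite(t)}
    if not valid:
        raise ValueError("module detection failed at every candidate power")
    best_t = max(valid.values())
    best_power = min(p for p, t in valid.items() if t == best_t)

    mset = _modules_from_assignment(assignments[best_power])
    mset.soft_power_used = best_power
    mset.power_selection_tstats = tstats
    if merge:
        mset = merge_modules(mset, fcm, config.merge_eigengene_correlation)
        mset.soft_power_used = best_power
        mset.power_selection_tstats = tstats
    return mset


def merge_modules(mset: ModuleSet, fcm: FoldChangeMatrix, threshold: float) -> ModuleSet:
    """Iteratively merge module pairs whose eigengenes correlate >= threshold.

    Correlation is signed Pearson on raw (pre-Z) module scores across
    experiments; after each merge eigengenes are recomputed, so the loop
    terminates only when no pair of surviving modules qualifies.
    """
    from .scoring import raw_module_scores

    groups = {m.module_id: list(m.genes) for m in mset.modules}
    while len(groups) > 1:
        ids = sorted(groups)
        raw = raw_module_scores(fcm, groups)[ids]
        corr = np.corrcoef(raw.to_numpy(), rowvar=False)
        n = len(ids)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                c = corr[i, j]
                if c >= threshold and (best is None or c > best[0]):
                    best = (c, ids[i], ids[j])
        if best is None:
            break
        _, a, b = best
        groups[a] = groups[a] + groups[b]
        del groups[b]

    # relabel merged modules by decreasing size
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    modules = [
        GeneModule(module_id=f"M{i + 1:03d}", genes=sorted(genes))
        for i, (_, genes) in enumerate(ordered)
    ]
    return ModuleSet(
        modules=modules,
        unassigned=list(mset.unassigned),
        soft_power_used=mset.soft_power_used,
        power_selection_tstats=dict(mset.power_selection_tstats),
    )
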