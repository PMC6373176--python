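"""Module eigengene (module score) computation on fold-change data.

The eigengene summarises the induction or repression of a module's genes in
each experiment.  It deviates from the conventional WGCNA eigengene in two
ways, both aimed at making "no perturbation" map to a score of exactly zero:

(a) member fold-change columns are *scaled only* (divided by their standard
    deviation, not mean-centred) before the singular value decomposition —
    centring would manufacture non-zero scores for experiments in which all
    member genes are unperturbed;
(b) the raw score is normalised to unit variance (divided by its standard
    deviation across experiments, again without mean subtraction) so that
    scores are comparable across modules and a score of +/-2 marks a large
    perturbation in the context of the whole compound panel.

The raw score of experiment e is the e-th entry of the first left singular
vector scaled by the first singular value; the sign is oriented so that the
mean correlation with member gene columns is non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FoldChangeMatrix
from .network import ModuleSet


@dataclass
class ModuleScoreTable:
    """Experiments x modules raw and Z-scaled module scores."""

    raw_scores: pd.DataFrame
    z_scores: pd.DataFrame

    @property
    def experiments(self):
        return self.raw_scores.index

    @property
    def modules(self) -> list[str]:
        return list(self.raw_scores.columns)


def _module_eigenvector(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First singular triplet of the scale-only member submatrix.

    Returns (raw score vector = u1 * s1, unit-norm gene weight vector v1),
    sign-oriented so the mean Pearson correlation of the score with member
    columns is >= 0.
    """
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("member gene with zero variance across experiments")
    Xs = X / sd
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    raw = U[:, 0] * S[0]
    weights = Vt[0]
    # orientation: mean correlation with member columns >= 0
    rc = raw - raw.mean()
    Xc = Xs - Xs.mean(axis=0)
    denom = np.linalg.norm(rc) * np.linalg.norm(Xc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrs = (Xc.T @ rc) / denom
    corrs = corrs[np.isfinite(corrs)]
    if corrs.size and corrs.mean() < 0:
        raw = -raw
        weights = -weights
    return raw, weights


def raw_module_scores(fcm: FoldChangeMatrix, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Raw (pre-Z) module scores for arbitrary gene groupings."""
    cols = {}
    for mid, genes in groups.items():
        if len(genes) < 2:
            raise ValueError(f"module {mid} has fewer than 2 genes")
        missing = set(genes) - set(fcm.genes)
        if missing:
            raise ValueError(f"module {mid}: genes absent from matrix: {sorted(missing)[:5]}")
        raw, _ = _module_eigenvector(fcm.data[genes].to_numpy())
        cols[mid] = raw
    return pd.DataFrame(cols, index=fcm.experiments)


def compute_module_scores(fcm: FoldChangeMatrix, modules: ModuleSet) -> ModuleScoreTable:
    """Raw and unit-variance (Z) module scores; zero rows stay exactly zero.

    Z-scaling divides each raw score column by its standard deviation across
    experiments without subtracting the mean, preserving raw zeros.  As a
    side effect, each module's unit-norm weight vector and (later) hub gene
    are attached to the ModuleSet entries.
    """
    raw_cols = {}
    for module in modules.modules:
        if len(module.genes) < 2:
            raise ValueError(f"module {module.module_id} has fewer than 2 genes")
        X = fcm.data[module.genes].to_numpy()
        raw, weights = _module_eigenvector(X)
        raw_cols[module.module_id] = raw
        module.weight_vector = weights

    raw_df = pd.DataFrame(raw_cols, index=fcm.experiments)
    sds = raw_df.std(axis=0, ddof=1)
    if (sds == 0).any():
        flat = list(sds.index[sds == 0])
        raise ValueError(f"module score constant across experiments: {flat}")
    z_df = raw_df / sds
    return ModuleScoreTable(raw_scores=raw_df, z_scores=z_df)


def eigengene_gene_correlation(
    fcm: FoldChangeMatrix, modules: ModuleSet, scores: ModuleScoreTable
) -> dict[str, pd.Series]:
    """Pearson correlation of each member gene with its module eigengene.

    Also assigns each module's hub gene (the most correlated member; ties
    broken lexicographically by gene id).
    """
    out: dict[str, pd.Series] = {}
    for module in modules.modules:
        score = scores.z_scores[module.module_id].to_numpy()
        corrs = {}
        for gene in module.genes:
            x = fcm.data[gene].to_numpy()
            corrs[gene] = float(np.corrcoef(score, x)[0, 1])
        series = pd.Series(corrs).sort_index()
        out[module.module_id] = series
        best = series.max()
        module.hub_gene = min(series.index[series == best])
    return out
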