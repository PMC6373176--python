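"""Hypergeometric enrichment of co-expression modules for screen genes.

Each module containing at least one screen gene is tested for
over-representation of the screen set with the upper-tail hypergeometric
probability P(X >= overlap); modules with no overlap are excluded from both
the tests and the Bonferroni multiplier.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .network import ModuleSet


def hypergeometric_enrichment(
    modules: ModuleSet,
    screen_genes: set[str],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of screen-gene overlap per module.

    Population = ``universe``; successes = screen genes in the universe;
    draws = module size (restricted to the universe).  Bonferroni multiplier
    is the number of modules actually tested (overlap >= 1).  Returns a
    DataFrame sorted by p with columns module_id, module_size, overlap,
    screen_in_universe, universe_size, p, p_bonferroni, enriched.
    """
    if not universe:
        raise ValueError("empty universe")
    screen_in_universe = screen_genes & universe
    if not screen_in_universe:
        raise ValueError("no screen genes in universe")
    if not screen_genes <= universe:
        missing = sorted(screen_genes - universe)
        raise ValueError(f"screen genes outside universe: {missing[:5]}")

    M = len(universe)
    n_success = len(screen_in_universe)

    rows = []
    for module in modules.modules:
        member = set(module.genes) & universe
        overlap = len(member & screen_in_universe)
        if overlap == 0:
            continue
        N = len(member)
        p = float(stats.hypergeom.sf(overlap - 1, M, n_success, N))
        rows.append((module.module_id, N, overlap, n_success, M, p))

    result = pd.DataFrame(
        rows, columns=["module_id", "module_size", "overlap", "screen_in_universe", "universe_size", "p"]
    )
    n_tested = len(result)
    result["p_bonferroni"] = (result["p"] * n_tested).clip(upper=1.0)
    result["enriched"] = result["p_bonferroni"] < alpha
    return result.sort_values("p", kind="stable").reset_index(drop=True)
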