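"""Synthetic perturbation and knockdown data with known ground truth.

Two generators:

* :func:`generate_perturbation_dataset` — a compound-perturbation expression
  panel mimicking a toxicogenomics repository: hepatocyte-like cultures
  exposed to compounds at up to three concentrations and three time points,
  with vehicle (DMSO) arrays for every time point.  Co-expressed gene modules
  are planted through a single latent factor per module.  The first
  ``n_signal_modules`` modules form an oxidative-stress-like ("signal")
  programme: each intrinsically reactive compound drives each signal module
  with some probability and a compound-specific random magnitude (so the
  signal factors correlate, as related stress modules do, but below the merge
  threshold); bioactivated compounds drive signal modules more rarely and at
  half strength.  Remaining ("background") modules represent unrelated
  biology and are each driven by a few dedicated non-reactive compounds.
  Signal-module member genes double as the planted NRF2-dependent gene set.

* :func:`generate_sirna_dataset` — a paired-donor knockdown screen with
  conditions siCON / siNRF2 / siKEAP1, planting genes positively (and a
  smaller set negatively) controlled by NRF2.

Both are deterministic given their seed and return a :class:`GroundTruth`
so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EXPERIMENT_COLUMNS, FoldChangeMatrix

CONC_LEVELS = ["low", "middle", "high"]
TIME_LEVELS = [8, 24, 48]  # hours


@dataclass
class SyntheticDesign:
    """Parameters of the planted-structure perturbation panel.

    Defaults give a desk-scale panel (2,000 genes, 60 compounds x 3
    concentrations x 3 times = 540 experiments) preserving the structure of
    the full repository at reduced size.  Module genes are "expressed"
    (higher vehicle intensity) while unassigned genes sit at background
    intensity — the gap the soft-power selection heuristic keys on.
    """

    n_genes: int = 2000
    n_compounds: int = 60
    concentrations_per_compound: int = 3
    times_per_compound: int = 3
    module_sizes: list[int] = field(
        default_factory=lambda: [30, 25, 20, 15, 12, 10, 8, 8, 6, 6]
    )
    expressed_intensity_mean: float = 8.0
    noise_intensity_mean: float = 4.0
    intensity_sd: float = 1.0
    factor_sd_background: float = 0.4
    factor_magnitude_perturbers: float = 4.0
    loading_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 0.3
    fraction_reactive: float = 0.15
    fraction_bioactivated: float = 0.25
    n_signal_modules: int = 4
    p_reactive_module: float = 0.6
    p_bioactivated_module: float = 0.3
    bioactivated_attenuation: float = 0.5
    perturbers_per_background_module: int = 3
    magnitude_multiplier_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes: total planted genes exceed n_genes")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module_sizes: every module must have >= 2 genes")
        if not (1 <= self.concentrations_per_compound <= 3):
            raise ValueError("concentrations_per_compound must be in 1..3")
        if not (1 <= self.times_per_compound <= 3):
            raise ValueError("times_per_compound must be in 1..3")
        for name in ("factor_sd_background", "noise_sd", "intensity_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.factor_magnitude_perturbers < 0:
            raise ValueError("factor_magnitude_perturbers must be >= 0")
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("loading_range must lie within (0, 1]")
        if not (0 <= self.fraction_reactive + self.fraction_bioactivated <= 1):
            raise ValueError("reactive + bioactivated fractions must lie in [0, 1]")
        if not (0 <= self.n_signal_modules <= len(self.module_sizes)):
            raise ValueError("n_signal_modules must not exceed the number of modules")


@dataclass
class GroundTruth:
    """Oracle for parameter-recovery tests."""

    gene_module_assignment: pd.Series  # gene -> module id ("" = unassigned)
    latent_factors: pd.DataFrame | None  # experiments x modules
    loadings: pd.Series | None  # gene -> loading (module genes only)
    nrf2_dependent_genes: pd.Series | None  # gene -> signed log2 effect
    compound_labels: pd.DataFrame | None  # compound, reactivity, dili_concern, is_drug
    signal_modules: list[str] = field(default_factory=list)  # NRF2-like module ids


def _experiment_index(design: SyntheticDesign) -> pd.MultiIndex:
    keys = []
    for c in range(design.n_compounds):
        for ci in range(design.concentrations_per_compound):
            for ti in range(design.times_per_compound):
                keys.append((f"CPD{c:03d}", CONC_LEVELS[ci], TIME_LEVELS[ti]))
    return pd.MultiIndex.from_tuples(keys, names=EXPERIMENT_COLUMNS)


def _level_scale(ci: int, n_conc: int, ti: int, n_time: int) -> float:
    # linear in level index along each axis, averaged; equals 1 at the
    # highest concentration and latest time
    return 0.5 * ((ci + 1) / n_conc + (ti + 1) / n_time)


def generate_perturbation_dataset(design: SyntheticDesign):
    """Simulate a compound-perturbation panel with planted modules.

    Returns
    -------
    intensities : pd.DataFrame
        Genes x samples log2 intensities (treated and vehicle arrays).
    sample_sheet : pd.DataFrame
        One row per sample with experiment keys and vehicle flags.
    truth : GroundTruth
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    genes = [f"G{i:04d}" for i in range(design.n_genes)]
    n_modules = len(design.module_sizes)
    module_ids = [f"M{m + 1:02d}" for m in range(n_modules)]

    assignment = pd.Series("", index=pd.Index(genes, name="gene"), dtype=object)
    loadings = pd.Series(0.0, index=assignment.index)
    pos = 0
    lo, hi = design.loading_range
    for mid, size in zip(module_ids, design.module_sizes):
        members = genes[pos : pos + size]
        assignment.loc[members] = mid
        loadings.loc[members] = rng.uniform(lo, hi, size=size)
        pos += size
    is_module_gene = (assignment != "").to_numpy()

    compounds = [f"CPD{c:03d}" for c in range(design.n_compounds)]
    n_reactive = int(round(design.fraction_reactive * design.n_compounds))
    n_bioact = int(round(design.fraction_bioactivated * design.n_compounds))
    perm = rng.permutation(design.n_compounds)
    reactive = {compounds[i] for i in perm[:n_reactive]}
    bioactivated = {compounds[i] for i in perm[n_reactive : n_reactive + n_bioact]}

    signal_ids = module_ids[: design.n_signal_modules]
    background_ids = module_ids[design.n_signal_modules :]
    mlo, mhi = design.magnitude_multiplier_range

    # perturber map: compound -> module -> relative magnitude.  Reactive
    # compounds hit signal modules often and hard; bioactivated ones rarely
    # and at half strength; background modules have dedicated drivers drawn
    # from the remaining compounds.
    perturbers: dict[str, dict[str, float]] = {cpd: {} for cpd in compounds}
    for cpd in compounds:
        if cpd in reactive:
            for mid in signal_ids:
                if rng.random() < design.p_reactive_module:
                    perturbers[cpd][mid] = rng.uniform(mlo, mhi)
        elif cpd in bioactivated:
            for mid in signal_ids:
                if rng.random() < design.p_bioactivated_module:
                    perturbers[cpd][mid] = design.bioactivated_attenuation * rng.uniform(mlo, mhi)
    plain = [c for c in compounds if c not in reactive and c not in bioactivated]
    for mid in background_ids:
        n_dedicated = min(design.perturbers_per_background_module, len(plain))
        if n_dedicated == 0:
            continue
        for i in rng.choice(len(plain), size=n_dedicated, replace=False):
            perturbers[plain[i]][mid] = rng.uniform(mlo, mhi)

    index = _experiment_index(design)
    n_exp = len(index)

    factors = rng.normal(0.0, design.factor_sd_background, size=(n_exp, n_modules))
    for e, (cpd, conc, time_h) in enumerate(index):
        pert = perturbers[cpd]
        if not pert:
            continue
        ci = CONC_LEVELS.index(conc)
        ti = TIME_LEVELS.index(time_h)
        scale = _level_scale(ci, design.concentrations_per_compound, ti, design.times_per_compound)
        for m, mid in enumerate(module_ids):
            if mid in pert:
                factors[e, m] += design.factor_magnitude_perturbers * pert[mid] * scale

    # planted fold changes: loading * factor for module genes, plus noise
    fc = rng.normal(0.0, design.noise_sd, size=(n_exp, design.n_genes))
    for m, mid in enumerate(module_ids):
        member_mask = (assignment == mid).to_numpy()
        fc[:, member_mask] += np.outer(factors[:, m], loadings.to_numpy()[member_mask])

    # vehicle baselines: expressed module genes vs. background noise genes
    base = np.where(
        is_module_gene,
        rng.normal(design.expressed_intensity_mean, design.intensity_sd, design.n_genes),
        rng.normal(design.noise_intensity_mean, design.intensity_sd, design.n_genes),
    )

    times = TIME_LEVELS[: design.times_per_compound]
    columns: dict[str, np.ndarray] = {}
    sheet_rows: list[tuple] = []
    vehicle_mean: dict[int, np.ndarray] = {}
    for ti, time_h in enumerate(times):
        reps = []
        for r in range(2):
            sid = f"VEH_t{time_h}_r{r}"
            arr = base + rng.normal(0.0, 0.05, design.n_genes)
            columns[sid] = arr
            reps.append(arr)
            sheet_rows.append((sid, "DMSO", "vehicle", time_h, 1))
        vehicle_mean[time_h] = np.mean(reps, axis=0)

    # treated arrays reproduce the planted fold change exactly against the
    # time-matched vehicle mean; array-level noise is folded into noise_sd
    for e, (cpd, conc, time_h) in enumerate(index):
        sid = f"{cpd}_{conc}_t{time_h}"
        columns[sid] = vehicle_mean[time_h] + fc[e]
        sheet_rows.append((sid, cpd, conc, time_h, 0))

    intensities = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    sample_sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "compound", "concentration", "time_h", "is_vehicle"]
    )

    labels = pd.DataFrame(
        {
            "compound": compounds,
            "is_drug": 1,
            "reactivity": [
                "reactive"
                if c in reactive
                else ("bioactivated" if c in bioactivated else "not_bioactivated_or_reactive")
                for c in compounds
            ],
            "dili_concern": [
                "most" if (c in reactive or c in bioactivated) else "less_none" for c in compounds
            ],
        }
    )

    signal_members = assignment.index[assignment.isin(signal_ids)]
    truth = GroundTruth(
        gene_module_assignment=assignment,
        latent_factors=pd.DataFrame(factors, index=index, columns=module_ids),
        loadings=loadings[is_module_gene],
        nrf2_dependent_genes=loadings[signal_members],
        compound_labels=labels,
        signal_modules=list(signal_ids),
    )
    return intensities, sample_sheet, truth


def planted_fold_change_matrix(design: SyntheticDesign):
    """Convenience: generate a panel and reduce it to its FoldChangeMatrix."""
    from .io import compute_fold_changes

    intensities, sheet, truth = generate_perturbation_dataset(design)
    fcm = compute_fold_changes(intensities, sheet)
    # fold-change rows come back sorted by experiment key; align the truth
    truth.latent_factors = truth.latent_factors.loc[fcm.experiments]
    vehicle_cols = sheet.loc[sheet["is_vehicle"] == 1, "sample_id"]
    vehicle_intensity = intensities[vehicle_cols].mean(axis=1)
    return fcm, vehicle_intensity, truth


def generate_sirna_dataset(
    n_donors: int = 4,
    effect_size: float = 1.0,
    n_true_targets: int = 100,
    n_genes: int = 2000,
    donor_sd: float = 0.5,
    noise_sd: float = 0.25,
    seed: int = 0,
    n_repressed: int = 15,
    keap1_ratio: float = 0.8,
    baseline_mean: float = 8.0,
    gene_universe: list[str] | None = None,
    target_genes: list[str] | None = None,
    repressed_genes: list[str] | None = None,
):
    """Simulate a paired-donor siCON/siNRF2/siKEAP1 knockdown screen.

    Genes positively controlled by NRF2 drop by ``effect_size`` log2 units
    under siNRF2 and rise by ``effect_size * keap1_ratio`` under siKEAP1;
    a smaller repressed set moves oppositely.  Donor random intercepts
    (``donor_sd``) are shared across the three conditions of a donor and so
    cancel in paired contrasts.

    Returns genes x samples log2 intensities, a condition sheet with columns
    ``sample_id, donor, condition``, and a :class:`GroundTruth` whose
    ``nrf2_dependent_genes`` maps each planted gene to its signed effect
    (positive = positively controlled by NRF2).
    """
    if n_donors < 2:
        raise ValueError("paired contrasts need at least 2 donors")

    rng = np.random.default_rng(seed)
    if gene_universe is not None:
        genes = list(gene_universe)
        n_genes = len(genes)
    else:
        genes = [f"G{i:04d}" for i in range(n_genes)]
    effects = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    if target_genes is not None:
        missing = set(target_genes) - set(genes)
        if missing:
            raise ValueError(f"target genes outside universe: {sorted(missing)[:5]}")
        n_true_targets = len(target_genes)
        effects.loc[list(target_genes)] = effect_size
        if repressed_genes is None:
            repressed_genes = [g for g in genes if g not in set(target_genes)][:n_repressed]
        if set(repressed_genes) & set(target_genes):
            raise ValueError("repressed and target gene sets overlap")
        n_repressed = len(repressed_genes)
        effects.loc[list(repressed_genes)] = -effect_size
    else:
        effects.iloc[:n_true_targets] = effect_size
        effects.iloc[n_true_targets : n_true_targets + n_repressed] = -effect_size
    if n_true_targets + n_repressed >= n_genes:
        raise ValueError("planted genes must be fewer than n_genes")

    base = rng.normal(baseline_mean, 1.0, n_genes)
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    eff = effects.to_numpy()
    for d in range(n_donors):
        donor_shift = rng.normal(0.0, donor_sd, n_genes)
        for cond, sign in (("siCON", 0.0), ("siNRF2", -1.0), ("siKEAP1", keap1_ratio)):
            sid = f"D{d + 1}_{cond}"
            noise = rng.normal(0.0, noise_sd, n_genes)
            columns[sid] = base + donor_shift + sign * eff + noise
            sheet_rows.append((sid, f"D{d + 1}", cond))

    intensities = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "donor", "condition"])
    truth = GroundTruth(
        gene_module_assignment=pd.Series("", index=intensities.index, dtype=object),
        latent_factors=None,
        loadings=None,
        nrf2_dependent_genes=effects[effects != 0],
        compound_labels=None,
    )
    return intensities, sheet, truth
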