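"""Tabular input/output and experiment-level fold-change construction.

An *experiment* is one (compound, concentration, time) condition measured
against time-matched vehicle (DMSO) controls.  The central container is
:class:`FoldChangeMatrix`: experiments x genes log2 fold changes, the object
all network and scoring stages consume.

Expression matrices are plain TSV with genes as rows and samples as columns
(first column the gene identifier).  The sample sheet is a TSV with columns
``sample_id, compound, concentration, time_h, is_vehicle``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ["sample_id", "compound", "concentration", "time_h", "is_vehicle"]

DILI_CONCERN_VALUES = frozenset({"most", "less_none", "ambiguous", "absent"})
REACTIVITY_VALUES = frozenset(
    {"reactive", "bioactivated", "not_bioactivated_or_reactive", "unknown"}
)

EXPERIMENT_COLUMNS = ["compound", "concentration", "time_h"]


@dataclass
class FoldChangeMatrix:
    """Experiments x genes log2 fold changes.

    ``data`` is indexed by a (compound, concentration, time_h) MultiIndex and
    has one column per gene.  No missing values are tolerated and gene
    identifiers must be unique: each gene is represented by a single column.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.MultiIndex) or list(self.data.index.names) != EXPERIMENT_COLUMNS:
            raise ValueError(f"fold-change index must be a {EXPERIMENT_COLUMNS} MultiIndex")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in fold-change matrix for genes {bad[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate experiment keys in fold-change matrix")

    @property
    def experiments(self) -> pd.MultiIndex:
        return self.data.index

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def write_tsv(self, path) -> None:
        self.data.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "FoldChangeMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(EXPERIMENT_COLUMNS)
        df.columns.name = None
        return cls(df)


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TSV; first column is the gene identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene identifiers in expression matrix")
    return df


def write_expression_matrix(df: pd.DataFrame, path, gene_column: str = "gene") -> None:
    out = df.copy()
    out.index.name = gene_column
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns {missing}")
    return sheet


def compute_fold_changes(intensities: pd.DataFrame, sample_sheet: pd.DataFrame) -> FoldChangeMatrix:
    """Per-experiment log2 fold changes against time-matched vehicle.

    For every (compound, concentration, time_h) treated condition the value
    for gene g is mean(log2 treated) - mean(log2 vehicle at the same time).

    Parameters
    ----------
    intensities
        Genes x samples log2 intensities covering treated and vehicle arrays.
    sample_sheet
        One row per sample; ``is_vehicle`` (0/1) marks the DMSO controls.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sample_sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns {missing}")
    unknown = set(sample_sheet["sample_id"]) - set(intensities.columns)
    if unknown:
        raise ValueError(f"samples in sheet absent from matrix: {sorted(unknown)[:5]}")
    if intensities.isna().any().any():
        raise ValueError("missing values in intensity matrix")

    vehicle = sample_sheet[sample_sheet["is_vehicle"].astype(int) == 1]
    treated = sample_sheet[sample_sheet["is_vehicle"].astype(int) == 0]
    if treated.empty:
        raise ValueError("no treated samples in sample sheet")

    # per-time vehicle means, genes x times
    vehicle_means: dict = {}
    for time_h, grp in vehicle.groupby("time_h"):
        vehicle_means[time_h] = intensities[grp["sample_id"]].mean(axis=1)

    rows = []
    keys = []
    for (compound, conc, time_h), grp in treated.groupby(EXPERIMENT_COLUMNS, sort=True):
        if time_h not in vehicle_means:
            raise ValueError(
                f"experiment ({compound}, {conc}, {time_h}) has no time-matched vehicle samples"
            )
        fc = intensities[grp["sample_id"]].mean(axis=1) - vehicle_means[time_h]
        rows.append(fc)
        keys.append((compound, conc, time_h))

    data = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(keys, names=EXPERIMENT_COLUMNS))
    data.columns.name = None
    return FoldChangeMatrix(data)


def read_compound_annotations(path) -> pd.DataFrame:
    """Read compound annotations (is_drug flag, reactivity class, DILI concern)."""
    ann = pd.read_csv(path, sep="\t")
    return validate_annotations(ann)


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    required = ["compound", "is_drug", "reactivity", "dili_concern"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    bad_r = set(ann["reactivity"]) - REACTIVITY_VALUES
    if bad_r:
        raise ValueError(f"unknown reactivity values {sorted(bad_r)}")
    bad_d = set(ann["dili_concern"]) - DILI_CONCERN_VALUES
    if bad_d:
        raise ValueError(f"unknown dili_concern values {sorted(bad_d)}")
    if ann["compound"].duplicated().any():
        raise ValueError("duplicate compounds in annotation table")
    return ann


TABLE2_MODULES = ["144", "192", "224", "325"]


@dataclass
class Table2Fixture:
    """Published 47-compound table of NRF2-module eigengene values.

    Displayed eigengene values are rounded to one decimal; significance of a
    cell (eigengene >= 2.0 at full precision) is therefore carried as an
    explicit flag rather than re-derived by thresholding the rounded value —
    a displayed "2.0" occurs both marked and unmarked.
    """

    table: pd.DataFrame
    modules: list[str] = field(default_factory=lambda: list(TABLE2_MODULES))

    @property
    def compounds(self) -> list[str]:
        return list(self.table["compound"])

    def eigengenes(self) -> pd.DataFrame:
        """Compounds x modules displayed (rounded) eigengene values."""
        cols = {m: self.table[f"eig_{m}"].to_numpy() for m in self.modules}
        return pd.DataFrame(cols, index=self.table["compound"])

    def significance(self) -> pd.DataFrame:
        """Compounds x modules boolean significance marks."""
        cols = {m: self.table[f"sig_{m}"].astype(bool).to_numpy() for m in self.modules}
        return pd.DataFrame(cols, index=self.table["compound"])

    def annotations(self) -> pd.DataFrame:
        ann = self.table[["compound", "drug", "dili_concern", "reactivity"]].copy()
        ann = ann.rename(columns={"drug": "is_drug"})
        ann["is_drug"] = ann["is_drug"].astype(int)
        return validate_annotations(ann)


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged transcription of the published compound table."""
    with resources.files("nrf2modnet.data").joinpath("table2_fixture.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    expected = (
        ["compound"]
        + [c for m in TABLE2_MODULES for c in (f"eig_{m}", f"sig_{m}")]
        + ["drug", "dili_concern", "reactivity"]
    )
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"fixture malformed; missing columns {missing}")
    for m in TABLE2_MODULES:
        marked = table[table[f"sig_{m}"].astype(bool)]
        if (marked[f"eig_{m}"] < 2.0).any():
            raise ValueError(f"fixture inconsistency: marked cell below 2.0 in module {m}")
    return Table2Fixture(table)
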