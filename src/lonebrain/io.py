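"""Tabular I/O for cohort phenotypes and imaging-derived phenotype blocks.

All artifacts are delimited text (TSV) with a header row and a shared
``participant_id`` column.  Column headers carry 1-based feature labels for
human readability (``vol_001``..., ``fc_2_1``..., ``fa_001``...); internally
everything is 0-based.  Functional coupling is stored as the 4950-entry
row-major lower triangle (i > j) per participant; full 100x100 matrices are
accepted behind a flag and vectorized on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas, TractCatalog

log = logging.getLogger("lonebrain")

__all__ = [
    "CohortTable",
    "SchemaError",
    "read_cohort",
    "write_cohort_tables",
    "volume_columns",
    "edge_columns",
    "fa_columns",
]

#: Continuous confounds recorded for every participant, in file order.
CONFOUND_COLUMNS = (
    "bmi",
    "head_size",
    "motion_task",
    "motion_rest",
    "head_pos_x",
    "head_pos_y",
    "head_pos_z",
    "table_pos",
)

PHENOTYPE_COLUMNS = ("participant_id", "loneliness", "sex", "age") + CONFOUND_COLUMNS + ("site",)

FLOAT_FORMAT = "%.10g"  # text round-trip precision for all numeric tables


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


@dataclass
class CohortTable:
    """Per-participant phenotypes: outcome, demographics, and confounds.

    ``loneliness`` is the binary outcome y (1 = often feels lonely),
    ``sex`` is binary (1 = man, 0 = woman), ``age`` is in years, ``site``
    is a categorical acquisition-site label.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PHENOTYPE_COLUMNS) - set(self.table.columns)
        if missing:
            raise SchemaError(f"phenotype table missing columns: {sorted(missing)}")
        y = self.table["loneliness"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise SchemaError("loneliness must be binary 0/1")
        if self.table.isna().any().any():
            raise SchemaError("phenotype table contains missing values after loading")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def loneliness(self) -> np.ndarray:
        return self.table["loneliness"].to_numpy(dtype=int)

    @property
    def sex(self) -> np.ndarray:
        return self.table["sex"].to_numpy(dtype=int)

    @property
    def age(self) -> np.ndarray:
        return self.table["age"].to_numpy(dtype=float)

    @property
    def site(self) -> np.ndarray:
        return self.table["site"].to_numpy()


def volume_columns(n_regions: int) -> list[str]:
    return [f"vol_{r + 1:03d}" for r in range(n_regions)]


def edge_columns(n_regions: int) -> list[str]:
    """Row-major lower-triangle edge labels fc_<i>_<j>, 1-based, i > j."""
    return [
        f"fc_{i + 1}_{j + 1}"
        for i in range(n_regions)
        for j in range(i)
    ]


def fa_columns(n_tracts: int) -> list[str]:
    return [f"fa_{t + 1:03d}" for t in range(n_tracts)]


def _read_block(
    path: str | Path, prefix: str, expected: list[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if "participant_id" not in df.columns:
        raise SchemaError(f"{path}: missing participant_id column")
    cols = [c for c in df.columns if c.startswith(prefix)]
    if cols != expected:
        raise SchemaError(
            f"{path}: expected {len(expected)} {prefix}* columns in canonical "
            f"order, found {len(cols)}"
        )
    return df, df[cols].to_numpy(dtype=float)


def read_cohort(
    volumes_path: str | Path,
    fc_path: str | Path,
    fa_path: str | Path,
    phenotype_path: str | Path,
    *,
    atlas: Atlas,
    catalog: TractCatalog,
    fc_full_matrix: bool = False,
) -> tuple[CohortTable, np.ndarray, np.ndarray, np.ndarray]:
    """Load and align the four cohort tables on ``participant_id``.

    Returns ``(cohort, volumes[n, R], fc_edges[n, E], fa[n, T])`` with rows in
    phenotype-file order.  Rows with missing phenotype values are dropped (and
    counted in the log); an identifier mismatch across files is an error.
    """
    pheno = pd.read_csv(phenotype_path, sep="\t")
    missing = set(PHENOTYPE_COLUMNS) - set(pheno.columns)
    if missing:
        raise SchemaError(f"{phenotype_path}: missing columns {sorted(missing)}")
    n_raw = len(pheno)
    pheno = pheno.dropna()
    if len(pheno) < n_raw:
        log.info(
            "dropped %d of %d participants with missing phenotype values",
            n_raw - len(pheno), n_raw,
        )

    R = atlas.n_regions
    vol_df, volumes = _read_block(volumes_path, "vol_", volume_columns(R))
    if fc_full_matrix:
        expected_fc = [f"fc_{i + 1}_{j + 1}" for i in range(R) for j in range(R)]
        fc_df, fc_flat = _read_block(fc_path, "fc_", expected_fc)
        full = fc_flat.reshape(len(fc_flat), R, R)
        ii, jj = np.tril_indices(R, k=-1)
        fc = full[:, ii, jj]
    else:
        fc_df, fc = _read_block(fc_path, "fc_", edge_columns(R))
    fa_df, fa = _read_block(fa_path, "fa_", fa_columns(catalog.n_tracts))

    ids = pheno["participant_id"].to_numpy()
    for name, df in (("volumes", vol_df), ("fc", fc_df), ("fa", fa_df)):
        other = df["participant_id"].to_numpy()
        if set(ids) - set(other):
            offenders = sorted(set(ids) - set(other))[:10]
            raise SchemaError(
                f"{name} table missing participant ids present in phenotypes: "
                f"{offenders}"
            )

    def align(df: pd.DataFrame, arr: np.ndarray) -> np.ndarray:
        pos = pd.Series(np.arange(len(df)), index=df["participant_id"])
        return arr[pos.loc[ids].to_numpy()]

    cohort = CohortTable(pheno.reset_index(drop=True))
    log.info("cohort loaded: n=%d participants", cohort.n)
    return cohort, align(vol_df, volumes), align(fc_df, fc), align(fa_df, fa)


def write_cohort_tables(
    out_dir: str | Path,
    cohort: CohortTable,
    volumes: np.ndarray,
    fc_edges: np.ndarray,
    fa: np.ndarray,
) -> dict[str, Path]:
    """Write the four cohort tables as TSV; returns paths keyed by artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = cohort.table["participant_id"]
    paths = {}

    def dump(name: str, cols: list[str], arr: np.ndarray) -> None:
        df = pd.DataFrame(arr, columns=cols)
        df.insert(0, "participant_id", ids.to_numpy())
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        paths[name] = p

    paths["phenotypes"] = out / "phenotypes.tsv"
    cohort.table.to_csv(
        paths["phenotypes"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    dump("volumes", volume_columns(volumes.shape[1]), volumes)
    dump("fc", edge_columns(int((1 + np.sqrt(1 + 8 * fc_edges.shape[1])) / 2)), fc_edges)
    dump("fa", fa_columns(fa.shape[1]), fa)
    return paths
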