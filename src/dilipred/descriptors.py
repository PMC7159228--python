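"""Compound descriptor tables: input, optional computation, preprocessing.

The modeling pipeline is descriptor-agnostic: it consumes a compounds x
named-numeric-descriptors table from CSV.  A pluggable backend can compute an
open-source descriptor panel directly from SMILES (the ``rdkit`` backend
yields the 2D physicochemical/topological panel of RDKit); this panel is a
documented stand-in, not a reproduction of any proprietary descriptor set.

Preprocessing drops degenerate descriptors (zero variance, exact
duplicates), imputes missing values by the fitting-set median, and
standardizes each retained descriptor to mean 0 / sd 1 — margin-based
classifiers are scale-sensitive, so standardization is on by default.  The
fitted :class:`ScalingParams` are reusable at prediction time and JSON
round-trippable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PreprocessingError(ValueError):
    pass


class BackendUnavailableError(RuntimeError):
    pass


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors table; NaN marks a masked/missing value."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate compound ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        # infinities are invalid, not missing: surface them
        arr = self.values.to_numpy(dtype=float, copy=False)
        if np.isinf(arr).any():
            raise ValueError("descriptor values must be finite or missing (NaN)")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the value is missing."""
        return self.values.isna()

    def subset_descriptors(self, names: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(self.values.loc[:, list(names)].copy())


def read_descriptor_table(path: str | Path) -> DescriptorMatrix:
    """Read a CSV with a leading compound-id column and numeric descriptors.

    Non-numeric cells become masked missing values; their count is logged.
    Duplicate compound ids are a format error.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    n_masked = int((numeric.isna() & df.notna()).to_numpy().sum())
    if n_masked:
        logger.info("%s: %d non-numeric cell(s) masked as missing", path, n_masked)
    return DescriptorMatrix(numeric.astype(float))


# ---------------------------------------------------------------------------
# Descriptor backends


def _rdkit_backend(smiles: str) -> dict[str, float] | None:
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise BackendUnavailableError(
            "descriptor backend 'rdkit' requires the rdkit package; "
            "install with `pip install dilipred[chem]` or supply a "
            "precomputed descriptor table instead"
        ) from exc
    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return {k: float(v) for k, v in Descriptors.CalcMolDescriptors(mol).items()}


DESCRIPTOR_BACKENDS: dict[str, Callable[[str], dict[str, float] | None]] = {
    "rdkit": _rdkit_backend,
}


def compute_descriptors(
    smiles: Sequence[str],
    compound_ids: Sequence[str] | None = None,
    backend: str = "rdkit",
) -> DescriptorMatrix:
    """Compute a descriptor panel from SMILES with the named backend.

    Values are deterministic for a fixed backend version.  Unparseable
    SMILES yield fully-masked rows and their ids are logged.
    """
    if backend not in DESCRIPTOR_BACKENDS:
        raise BackendUnavailableError(
            f"unknown descriptor backend {backend!r}; "
            f"available: {sorted(DESCRIPTOR_BACKENDS)}"
        )
    fn = DESCRIPTOR_BACKENDS[backend]
    if compound_ids is None:
        compound_ids = [f"CMPD{i:04d}" for i in range(len(smiles))]
    rows: list[dict[str, float] | None] = []
    bad: list[str] = []
    for cid, smi in zip(compound_ids, smiles):
        row = fn(smi)
        if row is None:
            bad.append(cid)
        rows.append(row)
    columns = next((list(r) for r in rows if r is not None), [])
    data = [
        [np.nan] * len(columns) if r is None else [r[c] for c in columns] for r in rows
    ]
    if bad:
        logger.warning("unparseable SMILES masked for compound(s): %s", bad)
    df = pd.DataFrame(data, index=list(compound_ids), columns=columns, dtype=float)
    # a backend may emit non-finite values for exotic inputs; mask them
    df = df.where(np.isfinite(df))
    return DescriptorMatrix(df)


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class ScalingParams:
    """Frozen per-descriptor imputation and standardization parameters."""

    kept: list[str]
    median: pd.Series  # imputation value per kept descriptor
    center: pd.Series
    scale: pd.Series
    fitted_on: str = ""

    def __post_init__(self) -> None:
        if (self.scale <= 0).any():
            bad = list(self.scale.index[self.scale <= 0])
            raise ValueError(f"non-positive scale for descriptors {bad}")

    def transform(self, matrix: DescriptorMatrix) -> DescriptorMatrix:
        """Impute then standardize, using the stored fitting-set statistics."""
        df = matrix.values.loc[:, self.kept]
        df = df.fillna(self.median)
        out = (df - self.center) / self.scale
        return DescriptorMatrix(out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kept": self.kept,
            "median": self.median.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "fitted_on": self.fitted_on,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalingParams":
        payload = json.loads(Path(path).read_text())
        kept = payload["kept"]
        return cls(
            kept=kept,
            median=pd.Series(payload["median"], index=kept),
            center=pd.Series(payload["center"], index=kept),
            scale=pd.Series(payload["scale"], index=kept),
            fitted_on=payload.get("fitted_on", ""),
        )


def preprocess(
    matrix: DescriptorMatrix,
    fit_ids: Sequence[str] | None = None,
    standardize: bool = True,
    fitted_on: str = "",
) -> tuple[DescriptorMatrix, ScalingParams]:
    """Reduce and standardize a descriptor matrix.

    Drops descriptors that are entirely missing or have zero variance on the
    fitting rows, keeps one copy of exact-duplicate columns (first by column
    order), imputes remaining missing values by the fitting-set median, and
    centers/scales each retained descriptor.  ``fit_ids`` restricts the rows
    the statistics are fitted on (e.g. the labeled training pool); the
    transform is applied to all rows.

    Standard deviations use ddof=0 so scaled columns have exactly unit
    variance on the fitting set.
    """
    fit = matrix.values if fit_ids is None else matrix.values.loc[list(fit_ids)]

    observed = fit.notna().sum(axis=0)
    std = fit.std(axis=0, ddof=0)
    degenerate = (observed == 0) | (std == 0) | std.isna()
    kept = [c for c in fit.columns if not degenerate[c]]
    n_dropped = len(fit.columns) - len(kept)
    if n_dropped:
        logger.info("preprocess: dropped %d degenerate descriptor(s)", n_dropped)
    if not kept:
        raise PreprocessingError("all descriptors are degenerate")

    median = fit[kept].median(axis=0)
    imputed = fit[kept].fillna(median)
    dup = imputed.T.duplicated(keep="first")
    if dup.any():
        logger.info("preprocess: dropped %d duplicate descriptor column(s)", int(dup.sum()))
        kept = [c for c in kept if not dup[c]]
        median = median.loc[kept]
        imputed = imputed[kept]

    center = imputed.mean(axis=0)
    scale = imputed.std(axis=0, ddof=0)
    if not standardize:
        center = pd.Series(0.0, index=center.index)
        scale = pd.Series(1.0, index=scale.index)
    params = ScalingParams(
        kept=kept, median=median, center=center, scale=scale, fitted_on=fitted_on
    )
    return params.transform(matrix), params
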