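"""Shared data model and tabular I/O for the reference-gene stability pipeline.

Tables are oriented genes-as-rows, samples-as-columns. Delimiter is
auto-detected between comma and tab (overridable); decimal separator is
".". Missing Ct values are encoded as empty cells or "NA" and are carried
as NaN — they never silently become 0.
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "ExpressionTable",
    "SampleMetadata",
    "StabilityResult",
    "read_ct_table",
    "read_expression_table",
    "read_sample_metadata",
    "write_report",
    "DataValidationError",
]

#: Allowed range for amplification efficiency on the fold-per-cycle scale.
EFFICIENCY_FOLD_RANGE = (1.0, 2.2)


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _as_fold_efficiency(value: float, context: str = "") -> float:
    """Normalise an efficiency given as percent (91.3) or fold (1.913).

    Values above the fold-scale upper bound 2.2 are interpreted as percent
    and converted via E_fold = 1 + E_percent / 100.
    """
    e = float(value)
    if e > EFFICIENCY_FOLD_RANGE[1]:
        e = 1.0 + e / 100.0
    lo, hi = EFFICIENCY_FOLD_RANGE
    if not (lo < e <= hi):
        raise DataValidationError(
            f"amplification efficiency {value!r} outside ({lo}, {hi}] "
            f"on the fold scale{(' for ' + context) if context else ''}"
        )
    return e


@dataclass
class CtMatrix:
    """Quantification-cycle values, genes x samples.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    ``efficiencies`` maps gene id -> amplification efficiency E on the
    fold-per-cycle scale (E = 2.0 is 100% efficiency). ``replicates`` is an
    optional genes x samples x replicates array of technical-replicate Ct
    values; ``values`` is then their per-well mean.
    """

    values: pd.DataFrame
    efficiencies: pd.Series | None = None
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene id(s): {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample id(s): {dups}")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if (finite <= 0).any():
            raise DataValidationError("Ct values must be > 0 (or missing)")
        if self.efficiencies is not None:
            self.efficiencies = pd.Series(
                {g: _as_fold_efficiency(e, context=str(g)) for g, e in self.efficiencies.items()},
                name="efficiency",
            ).reindex(self.values.index)
            if self.efficiencies.isna().any():
                missing = self.efficiencies.index[self.efficiencies.isna()].tolist()
                raise DataValidationError(f"efficiency missing for gene(s): {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def efficiency_vector(self, default: float = 2.0) -> pd.Series:
        """Per-gene efficiencies, filling with ``default`` when unattached."""
        if self.efficiencies is None:
            return pd.Series(default, index=self.values.index, name="efficiency")
        return self.efficiencies

    def subset_samples(self, sample_ids: Sequence[str]) -> "CtMatrix":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        reps = None
        if self.replicates is not None:
            idx = [self.sample_ids.index(s) for s in keep]
            reps = self.replicates[:, idx, :]
        return CtMatrix(self.values[keep].copy(), self.efficiencies, reps)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CtMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        eff = self.efficiencies.loc[keep] if self.efficiencies is not None else None
        reps = None
        if self.replicates is not None:
            idx = [self.gene_ids.index(g) for g in keep]
            reps = self.replicates[idx, :, :]
        return CtMatrix(self.values.loc[keep].copy(), eff, reps)


@dataclass
class ExpressionTable:
    """RNA-Seq abundance values, transcripts x samples (fragments or FPKM)."""

    values: pd.DataFrame
    unit_tag: str = "fragments"

    def __post_init__(self) -> None:
        if self.unit_tag not in ("fragments", "fpkm"):
            raise DataValidationError(f"unknown unit_tag {self.unit_tag!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate transcript id(s): {dups}")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise DataValidationError("abundance values must be nonnegative")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleMetadata:
    """Sample -> group labels (organ, stage, treatment, free-form extras)."""

    table: pd.DataFrame  # indexed by sample_id

    REQUIRED = ("organ", "stage", "treatment")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample id(s) in metadata: {dups}")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise DataValidationError(f"metadata missing required column {col!r}")
            bad = self.table.index[
                self.table[col].isna() | (self.table[col].astype(str).str.strip() == "")
            ].tolist()
            if bad:
                raise DataValidationError(f"empty {col!r} label for sample(s): {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def groups(self, by: str) -> pd.Series:
        if by not in self.table.columns:
            raise DataValidationError(f"no grouping column {by!r} in metadata")
        return self.table[by].astype(str)

    def select(self, **criteria: str) -> list[str]:
        """Sample ids matching all equality criteria, e.g. ``organ='leaf'``."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in criteria.items():
            mask &= self.groups(col) == str(value)
        return list(self.table.index[mask])

    def validate_against(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise DataValidationError(f"sample(s) absent from metadata: {missing}")


@dataclass
class StabilityResult:
    """Per-gene score and rank from one stability algorithm.

    ``direction`` is lower-is-stabler for every algorithm implemented here;
    ranks are average ranks (ties share the mean of their positions).
    """

    algorithm: str
    scores: pd.Series
    ranks: pd.Series
    lower_is_stabler: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise DataValidationError(f"{self.algorithm}: non-finite stability score")
        g = len(self.ranks)
        if not math.isclose(float(self.ranks.sum()), g * (g + 1) / 2, rel_tol=1e-9):
            raise DataValidationError(f"{self.algorithm}: ranks are not a valid tie-averaged permutation")

    def ordering(self) -> list[str]:
        """Gene ids from most to least stable (rank ascending, id tie-break)."""
        df = pd.DataFrame({"rank": self.ranks})
        df.index.name = None
        df["gene"] = df.index.astype(str)
        return list(df.sort_values(["rank", "gene"]).index)


# ---------------------------------------------------------------------------
# readers


def _sniff_sep(text: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    header = text.splitlines()[0] if text else ""
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_text(source: str | os.PathLike | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text()


def _parse_matrix(
    text: str, sep: str | None, what: str, transpose: bool = False
) -> pd.DataFrame:
    sep = _sniff_sep(text, sep)
    df = pd.read_csv(io.StringIO(text), sep=sep, index_col=0, na_values=["NA", ""], dtype=str)
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate {what} id(s): {dups}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise DataValidationError(
                f"non-numeric value {df.loc[bad[0], col]!r} at row {bad[0]!r}, column {col!r}"
            )
        out[col] = converted
    return out


def read_ct_table(
    source: str | os.PathLike | IO[str],
    *,
    sep: str | None = None,
    transpose: bool = False,
    efficiency_column: str = "efficiency",
    efficiencies: Mapping[str, float] | None = None,
) -> CtMatrix:
    """Read a Ct matrix (first column gene id, header row sample ids).

    An optional per-gene efficiency column (percent or fold scale) is split
    off by name; a sidecar mapping can be supplied instead via
    ``efficiencies``. Missing cells ("" or "NA") become NaN.
    """
    df = _parse_matrix(_read_text(source), sep, "gene", transpose)
    eff = None
    if efficiency_column in df.columns:
        eff = df[efficiency_column]
        df = df.drop(columns=[efficiency_column])
    if efficiencies is not None:
        eff = pd.Series(dict(efficiencies))
    return CtMatrix(df, efficiencies=eff)


def read_expression_table(
    source: str | os.PathLike | IO[str],
    *,
    sep: str | None = None,
    transpose: bool = False,
    unit_tag: str = "fragments",
) -> ExpressionTable:
    df = _parse_matrix(_read_text(source), sep, "transcript", transpose)
    if df.isna().any().any():
        where = df.stack(future_stack=True)
        where = where[where.isna()]
        raise DataValidationError(f"missing abundance value at {where.index[0]}")
    return ExpressionTable(df, unit_tag=unit_tag)


def read_sample_metadata(
    source: str | os.PathLike | IO[str],
    *,
    sep: str | None = None,
    matrix_samples: Iterable[str] | None = None,
) -> SampleMetadata:
    text = _read_text(source)
    sep = _sniff_sep(text, sep)
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "sample_id"})
    meta = SampleMetadata(df.set_index("sample_id"))
    if matrix_samples is not None:
        meta.validate_against(matrix_samples)
    return meta


# ---------------------------------------------------------------------------
# report writing


def write_report(
    results: Sequence[StabilityResult],
    destination: str | os.PathLike,
    consensus: "object | None" = None,
    extras: Mapping[str, object] | None = None,
) -> dict:
    """Write a TSV rank table and a JSON summary under ``destination``.

    Output is bit-stable for identical inputs: JSON keys are sorted and
    floats are serialised with repr-round-tripping precision.
    """
    if not results:
        raise DataValidationError("no stability results to report")
    dest = Path(destination)
    try:
        dest.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataValidationError(f"cannot create report directory {dest}: {exc}") from exc

    genes = list(results[0].scores.index)
    table = pd.DataFrame(index=pd.Index(genes, name="gene"))
    summary: dict = {"algorithms": {}}
    for res in results:
        table[f"{res.algorithm}_score"] = res.scores.reindex(genes)
        table[f"{res.algorithm}_rank"] = res.ranks.reindex(genes)
        summary["algorithms"][res.algorithm] = {
            "scores": {str(g): float(v) for g, v in res.scores.items()},
            "ranks": {str(g): float(v) for g, v in res.ranks.items()},
            "metadata": _jsonable(res.metadata),
        }
    if consensus is not None:
        table["geomean_rank"] = consensus.comprehensive_value.reindex(genes)
        table["final_rank"] = consensus.final_rank.reindex(genes)
        summary["consensus"] = consensus.to_dict()
    if extras:
        summary.update({k: _jsonable(v) for k, v in extras.items()})

    table.to_csv(dest / "stability.tsv", sep="\t", float_format="%.10g")
    (dest / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2, allow_nan=False) + "\n"
    )
    return summary


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj
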