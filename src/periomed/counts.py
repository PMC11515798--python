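"""Loading, validation, filtering and aggregation of taxa count tables.

The unit of analysis throughout the package is a samples x taxa table of
non-negative integer read counts with a per-sample study label, so that
tables pooled from heterogeneous 16S studies can be filtered study-wise
before topic modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TaxaCountTable",
    "load_count_table",
    "min_abundance_filter",
    "aggregate_taxa",
]


@dataclass
class TaxaCountTable:
    """Samples x taxa integer count matrix with per-sample study labels.

    Parameters
    ----------
    counts
        DataFrame with unique sample ids as index and unique taxon ids
        (genus, "genus species" or "genus species subsp. name" labels) as
        columns; entries are non-negative integers.
    study
        Per-sample study identifier, aligned to ``counts.index``. Defaults
        to a single study ``"study0"``.
    """

    counts: pd.DataFrame
    study: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dup}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            cell = (self.counts.index[rows[0]], self.counts.columns[cols[0]])
            raise ValueError(f"negative count at sample={cell[0]!r}, taxon={cell[1]!r}")
        totals = self.counts.sum(axis=1)
        empty = totals.index[totals == 0].tolist()
        if empty:
            raise ValueError(f"samples with zero total count: {empty}")
        if self.study is None:
            self.study = pd.Series("study0", index=self.counts.index, name="study")
        else:
            self.study = pd.Series(self.study)
            if not self.study.index.equals(self.counts.index):
                self.study = self.study.reindex(self.counts.index)
                if self.study.isna().any():
                    raise ValueError("study labels missing for some samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def totals(self) -> pd.Series:
        """Per-sample total read count (library size)."""
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "TaxaCountTable":
        return TaxaCountTable(self.counts.loc[list(sample_ids)].copy(),
                              self.study.loc[list(sample_ids)].copy())


def load_count_table(
    path: str | Path,
    dialect: str = "tsv_taxa_by_samples",
    study: pd.Series | None = None,
) -> TaxaCountTable:
    """Read a TSV count table and normalise its orientation.

    Parameters
    ----------
    path
        TSV file with a header row and an id column.
    dialect
        ``"tsv_taxa_by_samples"`` (rows are taxa, columns samples — the common
        deposition layout) or ``"tsv_samples_by_taxa"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("tsv_taxa_by_samples", "tsv_samples_by_taxa"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if dialect == "tsv_taxa_by_samples":
        raw = raw.T
    # integer-parse with a cell-level error message
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-integer or negative count at sample={row!r}, taxon={col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        parsed[col] = numeric.astype(np.int64)
    parsed.index = parsed.index.astype(str).rename("sample_id")
    parsed.columns = parsed.columns.astype(str).rename(None)
    return TaxaCountTable(parsed, study)


def min_abundance_filter(table: TaxaCountTable, threshold: int = 100) -> TaxaCountTable:
    """Remove rare taxa per study: keep a taxon for a study's samples only if
    its total count within that study is >= ``threshold``.

    Taxa dropped in one study but retained in another remain as all-zero
    columns for the first study's samples; taxa below threshold in every
    study are removed from the table. Samples are always retained.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    counts = table.counts.copy()
    removed: dict[str, list[tuple[str, int]]] = {}
    for study_id, sample_idx in table.study.groupby(table.study).groups.items():
        block = counts.loc[sample_idx]
        study_totals = block.sum(axis=0)
        drop = study_totals.index[study_totals < threshold]
        if len(drop):
            removed[str(study_id)] = [(t, int(study_totals[t])) for t in drop]
            counts.loc[sample_idx, drop] = 0
    keep = counts.columns[counts.sum(axis=0) > 0]
    if len(keep) == 0:
        totals = table.counts.sum(axis=0)
        raise ValueError(
            "min_abundance_filter would remove all taxa; per-taxon totals: "
            + ", ".join(f"{t}={int(v)}" for t, v in totals.items())
        )
    for study_id, entries in removed.items():
        logger.info(
            "min_abundance_filter(threshold=%d): study %s removed %d taxa: %s",
            threshold, study_id, len(entries),
            ", ".join(f"{t} (total {c})" for t, c in entries),
        )
    return TaxaCountTable(counts[keep], table.study.copy())


def _taxon_label(taxon: str, level: str) -> str:
    parts = taxon.split()
    if level == "genus":
        return parts[0]
    if level == "species":
        return " ".join(parts[:2]) if len(parts) >= 2 else parts[0]
    raise ValueError(f"unknown aggregation level: {level!r}")


def aggregate_taxa(table: TaxaCountTable, level: str = "genus") -> TaxaCountTable:
    """Sum counts over taxa sharing the same genus or species label.

    Taxon ids are assumed to be whitespace-separated Linnaean labels
    ("Genus species subsp. name"); the genus is the first token and the
    species the first two. Column sums (per-sample totals) are conserved.
    """
    labels = [_taxon_label(t, level) for t in table.taxon_ids]
    agg = table.counts.T.groupby(pd.Index(labels, name="taxon")).sum().T
    # preserve first-appearance order of labels
    order = list(dict.fromkeys(labels))
    return TaxaCountTable(agg[order], table.study.copy())


def write_count_table(table: TaxaCountTable, path: str | Path,
                      dialect: str = "tsv_taxa_by_samples") -> None:
    """Write a count table as TSV in either orientation."""
    out = table.counts.T if dialect == "tsv_taxa_by_samples" else table.counts
    out.to_csv(path, sep="\t")
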