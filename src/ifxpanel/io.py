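"""Domain types and tabular I/O for the pipeline.

All tables travel as a simple TSV dialect: UTF-8, tab-separated, first
header cell the literal ``id``, no quoting of identifiers. Count tables may
alternatively be read from BIOM-style JSON (dense or sparse).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

DISEASES = ("HC", "CD", "UC")
TIMEPOINTS = ("pre", "post")
RESPONSES = ("R", "NONR", "NA")

#: Reference genes used for Ct normalisation. HGDC (the genomic-DNA
#: contamination control printed on the same array) is accepted but opt-in.
DEFAULT_HOUSEKEEPING = ("ACTB", "B2M", "GAPDH", "HPRT1", "RPLP0")

#: Ranks of a SILVA-style lineage, shallowest first.
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Cell values in a Ct TSV meaning "no amplification detected".
CT_SENTINELS = frozenset({"NA", "Undetermined", "undetermined", ""})

DEFAULT_CT_CEILING = 35.0


class DataError(ValueError):
    """Raised when an input file or table violates its contract."""


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """One biopsy sample: who it came from and how it is grouped.

    ``response`` is the patient's eventual infliximab outcome; healthy
    controls carry the literal ``"NA"``.
    """

    sample_id: str
    subject_id: str
    disease: str
    timepoint: str
    response: str

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise DataError(
                f"sample {self.sample_id!r}: unknown disease {self.disease!r}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise DataError(
                f"sample {self.sample_id!r}: unknown timepoint {self.timepoint!r}"
            )
        if self.response not in RESPONSES:
            raise DataError(
                f"sample {self.sample_id!r}: unknown response {self.response!r}"
            )
        if self.disease == "HC" and self.response != "NA":
            raise DataError(
                f"sample {self.sample_id!r}: healthy controls must have response NA"
            )

    @property
    def group_label(self) -> str:
        """Canonical analysis-group label, e.g. ``CD_PRE_R`` or ``HC``."""
        if self.disease == "HC":
            return "HC"
        return f"{self.disease}_{self.timepoint.upper()}_{self.response}"


class Metadata:
    """An ordered, id-unique collection of :class:`SampleMeta`."""

    def __init__(self, samples: Iterable[SampleMeta]):
        self.samples: tuple[SampleMeta, ...] = tuple(samples)
        self._by_id: dict[str, SampleMeta] = {}
        for s in self.samples:
            if s.sample_id in self._by_id:
                raise DataError(f"duplicate sample_id {s.sample_id!r}")
            self._by_id[s.sample_id] = s

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleMeta]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> SampleMeta:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_of(self, sample_id: str) -> str:
        return self._by_id[sample_id].group_label

    def samples_in_group(self, label: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group_label == label]

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.group_label not in seen:
                seen.append(s.group_label)
        return seen

    def pre_post_pairs(self) -> list[tuple[str, str]]:
        """(pre, post) sample-id pairs sharing a subject; validates pairing."""
        by_subject: dict[str, dict[str, str]] = {}
        for s in self.samples:
            slot = by_subject.setdefault(s.subject_id, {})
            if s.timepoint in slot:
                raise DataError(
                    f"subject {s.subject_id!r} has multiple {s.timepoint!r} samples"
                )
            slot[s.timepoint] = s.sample_id
        return [
            (d["pre"], d["post"]) for d in by_subject.values() if len(d) == 2
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "subject_id": [s.subject_id for s in self.samples],
                "disease": [s.disease for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
                "response": [s.response for s in self.samples],
            }
        )


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Taxa x samples read counts (non-negative integers).

    ``data`` is indexed by taxon id with sample ids as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicated taxon ids: {dupes}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicated sample ids: {dupes}")
        if not np.issubdtype(df.to_numpy().dtype, np.integer):
            raise DataError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise DataError("counts must be non-negative")
        totals = df.sum(axis=0)
        empty = totals.index[totals == 0].tolist()
        if empty:
            raise DataError(f"samples with zero total counts: {empty}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

_UNASSIGNED = frozenset({"", "unassigned", "na", "none"})


@dataclass
class TaxonomyMap:
    """taxon id -> ranked SILVA-style lineage (domain..genus)."""

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for tid, lin in self.lineages.items():
            if len(lin) != len(LINEAGE_RANKS):
                raise DataError(
                    f"taxon {tid!r}: lineage must have {len(LINEAGE_RANKS)} ranks"
                )

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        return self.lineages[taxon_id]

    def genus_label(self, taxon_id: str) -> str:
        """Genus for a feature; unassigned genera pool under their family."""
        lin = self.lineages[taxon_id]
        genus = lin[-1]
        if genus.lower() in _UNASSIGNED:
            family = lin[LINEAGE_RANKS.index("family")]
            if family.lower() in _UNASSIGNED:
                family = "unclassified"
            return f"unassigned_{family}"
        return genus

    def matches_blocklist(self, taxon_id: str, blocklist: Sequence[str]) -> bool:
        terms = {b.lower() for b in blocklist}
        lin = self.lineages[taxon_id]
        return any(rank.lower() in terms for rank in lin)

    def require_complete(self, taxon_ids: Iterable[str]) -> None:
        missing = [t for t in taxon_ids if t not in self.lineages]
        if missing:
            raise DataError(f"taxa without taxonomy entries: {missing[:10]}")


# ---------------------------------------------------------------------------
# Ct matrix
# ---------------------------------------------------------------------------


@dataclass
class CtMatrix:
    """Genes x samples qPCR cycle-threshold values.

    Undetermined wells are stored at ``ct_ceiling`` with ``imputed`` True so
    downstream stages can flag low-confidence genes.
    """

    data: pd.DataFrame
    housekeeping_ids: tuple[str, ...]
    ct_ceiling: float = DEFAULT_CT_CEILING
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise DataError("duplicated gene ids")
        if df.columns.duplicated().any():
            raise DataError("duplicated sample ids")
        self.housekeeping_ids = tuple(self.housekeeping_ids)
        if not self.housekeeping_ids:
            raise DataError("housekeeping_ids must be non-empty")
        missing = [g for g in self.housekeeping_ids if g not in df.index]
        if missing:
            raise DataError(f"housekeeping genes absent from matrix: {missing}")
        vals = df.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise DataError("Ct matrix contains non-finite entries")
        if (vals <= 0).any() or (vals > self.ct_ceiling + 1e-9).any():
            raise DataError(f"Ct values must lie in (0, {self.ct_ceiling}]")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=df.index, columns=df.columns
            )
        elif self.imputed.shape != df.shape:
            raise DataError("imputed mask shape mismatch")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def assay_gene_ids(self) -> list[str]:
        """Gene ids excluding the housekeeping set."""
        hk = set(self.housekeeping_ids)
        return [g for g in self.data.index if g not in hk]


# ---------------------------------------------------------------------------
# TSV dialect helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "id":
        raise DataError(
            f"{path}: first header cell must be 'id', got {df.columns[0]!r}"
        )
    df = df.set_index("id")
    df.index.name = None
    return df


def read_count_table(path: str, format: str = "tsv") -> CountTable:
    """Read a taxa x samples count table from TSV or BIOM-style JSON."""
    if format == "tsv":
        raw = _read_tsv(path)
        counts = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
        for col in raw.columns:
            num = pd.to_numeric(raw[col], errors="coerce")
            bad = num.isna() | (num != num.round())
            if bad.any():
                row = raw.index[bad.to_numpy().nonzero()[0][0]]
                raise DataError(
                    f"{path}: non-integer count at ({row}, {col}): "
                    f"{raw.at[row, col]!r}"
                )
            counts[col] = num.astype(np.int64)
        return CountTable(counts)
    if format == "biom_json":
        return _read_biom_json(path)
    raise DataError(f"unknown count-table format {format!r}")


def _read_biom_json(path: str) -> CountTable:
    """Minimal reader for BIOM-style JSON feature tables (dense or sparse)."""
    with open(path) as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(rows), len(cols)), dtype=np.int64)
    if doc.get("matrix_type", "dense") == "dense":
        arr = np.asarray(doc["data"])
        if arr.shape != mat.shape:
            raise DataError(f"{path}: dense data shape mismatch")
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            raise DataError(f"{path}: counts must be non-negative integers")
        mat = arr.astype(np.int64)
    else:
        for r, c, v in doc["data"]:
            if v < 0 or v != int(v):
                raise DataError(f"{path}: bad sparse count at ({r}, {c}): {v}")
            mat[int(r), int(c)] = int(v)
    return CountTable(pd.DataFrame(mat, index=rows, columns=cols))


def write_count_table(table: CountTable, path: str) -> None:
    table.data.to_csv(path, sep="\t", index_label="id")


def read_taxonomy(path: str) -> TaxonomyMap:
    raw = _read_tsv(path)
    missing = [r for r in LINEAGE_RANKS if r not in raw.columns]
    if missing:
        raise DataError(f"{path}: taxonomy missing rank columns {missing}")
    lineages = {
        tid: tuple(raw.loc[tid, list(LINEAGE_RANKS)]) for tid in raw.index
    }
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str) -> None:
    df = pd.DataFrame.from_dict(
        {tid: list(lin) for tid, lin in tax.lineages.items()},
        orient="index",
        columns=list(LINEAGE_RANKS),
    )
    df.to_csv(path, sep="\t", index_label="id")


def read_ct_matrix(
    path: str,
    housekeeping_ids: Sequence[str] = DEFAULT_HOUSEKEEPING,
    ct_ceiling: float = DEFAULT_CT_CEILING,
) -> CtMatrix:
    """Read a genes x samples Ct TSV.

    Sentinel entries (``NA`` / ``Undetermined`` / empty) denote wells where
    no amplification was detected; they are set to ``ct_ceiling`` and
    flagged in the ``imputed`` mask.
    """
    raw = _read_tsv(path)
    ct = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    imputed = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        cell = raw[col]
        sentinel = cell.isin(CT_SENTINELS)
        num = pd.to_numeric(cell.where(~sentinel), errors="coerce")
        bad = num.isna() & ~sentinel
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise DataError(
                f"{path}: unparseable Ct at ({row}, {col}): {raw.at[row, col]!r}"
            )
        ct[col] = num.fillna(ct_ceiling)
        imputed[col] = sentinel.to_numpy()
    return CtMatrix(ct, tuple(housekeeping_ids), ct_ceiling, imputed)


def write_ct_matrix(ct: CtMatrix, path: str) -> None:
    """Write a Ct TSV; imputed wells round-trip as ``Undetermined``."""
    out = ct.data.astype(object).copy()
    mask = ct.imputed.to_numpy()
    out = out.where(~ct.imputed, "Undetermined")
    del mask
    out.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def read_metadata(path: str) -> Metadata:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "subject_id", "disease", "timepoint", "response"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise DataError(f"{path}: metadata missing columns {missing}")
    samples = []
    for i, row in raw.iterrows():
        try:
            samples.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    subject_id=row["subject_id"],
                    disease=row["disease"],
                    timepoint=row["timepoint"],
                    response=row["response"],
                )
            )
        except DataError as exc:
            raise DataError(f"{path}: row {i + 1}: {exc}") from exc
    return Metadata(samples)


def write_metadata(meta: Metadata, path: str) -> None:
    meta.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross-table consistency
# ---------------------------------------------------------------------------


def check_sample_consistency(
    meta: Metadata,
    counts: CountTable | None = None,
    ct: CtMatrix | None = None,
) -> None:
    """Enforce exact (case-sensitive) sample-id agreement across inputs."""
    ref = set(meta.sample_ids)
    for name, ids in (
        ("count table", counts.sample_ids if counts is not None else None),
        ("Ct matrix", ct.sample_ids if ct is not None else None),
    ):
        if ids is None:
            continue
        got = set(ids)
        if got != ref:
            extra = sorted(got - ref)
            missing = sorted(ref - got)
            raise DataError(
                f"{name} sample ids disagree with metadata "
                f"(extra={extra[:5]}, missing={missing[:5]})"
            )
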