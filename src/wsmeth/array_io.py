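"""Readers and writers for the file formats the pipeline touches.

Manifest (probe annotation), beta matrix + sample sheet, GMT gene-set
libraries, expression matrices and result tables (TSV, BED).  Manifest
positions are 1-based (Illumina convention); BED exports convert to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Relation",
    "Group",
    "ProbeAnnotation",
    "BetaMatrix",
    "GeneSetLibrary",
    "FormatError",
    "read_manifest",
    "write_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_probe_list",
    "read_series_matrix",
    "write_dmr_bed",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class Relation(str, Enum):
    """Position of a probe relative to its CpG island."""

    ISLAND = "Island"
    N_SHORE = "N_Shore"
    S_SHORE = "S_Shore"
    N_SHELF = "N_Shelf"
    S_SHELF = "S_Shelf"
    OPEN_SEA = "OpenSea"


#: relations counting as "CpG-rich" for region-level testing
CPG_RICH = frozenset(
    {Relation.ISLAND, Relation.N_SHORE, Relation.S_SHORE, Relation.N_SHELF, Relation.S_SHELF}
)


class Group(str, Enum):
    CASE = "CASE"
    CTRL = "CTRL"


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic, island and gene metadata for one array probe."""

    probe_id: str
    chrom: str
    position: int  # 1-based bp
    genes: frozenset = frozenset()
    island_name: str = ""
    relation: Relation = Relation.OPEN_SEA

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"{self.probe_id}: position must be >= 1, got {self.position}")
        if (self.relation is Relation.OPEN_SEA) != (self.island_name == ""):
            raise ValueError(
                f"{self.probe_id}: relation {self.relation.value!r} inconsistent with "
                f"island_name {self.island_name!r}"
            )

    @property
    def cpg_rich(self) -> bool:
        return self.relation in CPG_RICH


def _chrom_key(chrom: str):
    """Sort key putting chr1..chr22 numerically before chrX/chrY."""
    c = chrom.lower().removeprefix("chr")
    try:
        return (0, int(c), chrom)
    except ValueError:
        return (1, 0, chrom)


def sort_annotations(annotations: Iterable[ProbeAnnotation]) -> list[ProbeAnnotation]:
    """Sort by (chromosome, position, probe_id); probe_id breaks position ties."""
    return sorted(annotations, key=lambda a: (_chrom_key(a.chrom), a.position, a.probe_id))


# manifest column dialects: ours -> file column name
_DIALECTS = {
    "generic": {
        "probe_id": "probe_id",
        "chrom": "chrom",
        "position": "position",
        "genes": "genes",
        "island_name": "island_name",
        "relation": "relation",
    },
    "EPIC": {
        "probe_id": "IlmnID",
        "chrom": "CHR",
        "position": "MAPINFO",
        "genes": "UCSC_RefGene_Name",
        "island_name": "UCSC_CpG_Islands_Name",
        "relation": "Relation_to_UCSC_CpG_Island",
    },
}
_DIALECTS["HM450"] = dict(_DIALECTS["EPIC"])

_RELATION_ALIASES = {
    "": Relation.OPEN_SEA,
    "opensea": Relation.OPEN_SEA,
    "open sea": Relation.OPEN_SEA,
    "open_sea": Relation.OPEN_SEA,
    "island": Relation.ISLAND,
    "n_shore": Relation.N_SHORE,
    "s_shore": Relation.S_SHORE,
    "n_shelf": Relation.N_SHELF,
    "s_shelf": Relation.S_SHELF,
}


def _parse_relation(raw: str) -> Relation:
    key = raw.strip().lower()
    # manifests may list one relation per transcript; take the first
    key = key.split(";")[0].strip()
    if key in _RELATION_ALIASES:
        return _RELATION_ALIASES[key]
    raise FormatError(f"unrecognised island relation {raw!r}")


def parse_genes(raw: str) -> frozenset:
    """Split a ';'-separated gene field into an uppercased symbol set."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    symbols = {g.strip().upper() for g in str(raw).replace(",", ";").split(";")}
    symbols.discard("")
    symbols.discard("-")
    symbols.discard("—")
    return frozenset(symbols)


def read_manifest(path, dialect: str = "generic") -> list[ProbeAnnotation]:
    """Read a probe-annotation manifest (TSV); positions are 1-based.

    Rows whose position cannot be parsed as a positive integer are dropped
    and counted in the log.  A missing required column is a fatal
    :class:`FormatError` naming the column.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown manifest dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    cols = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for ours, theirs in cols.items():
        if theirs not in df.columns and ours in ("probe_id", "chrom", "position"):
            raise FormatError(f"manifest {path}: required column {theirs!r} missing")
    out: list[ProbeAnnotation] = []
    n_dropped = 0
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        try:
            position = int(str(rec[cols["position"]]).replace(",", ""))
            if position < 1:
                raise ValueError
        except (ValueError, TypeError):
            n_dropped += 1
            continue
        probe_id = rec[cols["probe_id"]].strip()
        if probe_id in seen:
            raise FormatError(f"manifest {path}: duplicate probe_id {probe_id!r}")
        seen.add(probe_id)
        island = rec.get(cols["island_name"], "").strip()
        if island in ("-", "—"):
            island = ""
        island = island.split(";")[0].strip()
        relation = _parse_relation(rec.get(cols["relation"], "")) if island else Relation.OPEN_SEA
        if island and relation is Relation.OPEN_SEA:
            # relation column empty but an island is named: treat as open sea
            island = ""
        chrom = rec[cols["chrom"]].strip()
        if not chrom.lower().startswith("chr"):
            chrom = f"chr{chrom}"
        out.append(
            ProbeAnnotation(
                probe_id=probe_id,
                chrom=chrom,
                position=position,
                genes=parse_genes(rec.get(cols["genes"], "")),
                island_name=island,
                relation=relation,
            )
        )
    if n_dropped:
        logger.warning("read_manifest: dropped %d rows with unparseable positions", n_dropped)
    return out


def write_manifest(annotations: Iterable[ProbeAnnotation], path) -> None:
    rows = [
        {
            "probe_id": a.probe_id,
            "chrom": a.chrom,
            "position": a.position,
            "genes": ";".join(sorted(a.genes)),
            "island_name": a.island_name,
            "relation": a.relation.value,
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with two-group labels."""

    probe_ids: list
    sample_ids: list
    values: np.ndarray  # shape (n_probes, n_samples), NaN = missing
    groups: dict = field(default_factory=dict)  # sample_id -> Group

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-6 or finite.max() > 1 + 1e-6):
            i, j = np.argwhere(~np.isnan(self.values) & ((self.values < -1e-6) | (self.values > 1 + 1e-6)))[0]
            raise ValueError(
                f"beta value {self.values[i, j]!r} out of [0,1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def case_columns(self) -> np.ndarray:
        return np.array([self.groups[s] is Group.CASE for s in self.sample_ids])

    def group_split(self) -> tuple[np.ndarray, np.ndarray]:
        """(case values, control values) column blocks."""
        mask = self.case_columns
        return self.values[:, mask], self.values[:, ~mask]

    def drop_incomplete(self) -> "BetaMatrix":
        """Remove probes with any missing value (counted in the log)."""
        keep = ~np.isnan(self.values).any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("excluding %d probes with missing betas", n_drop)
        return BetaMatrix(
            probe_ids=[p for p, k in zip(self.probe_ids, keep) if k],
            sample_ids=list(self.sample_ids),
            values=self.values[keep],
            groups=dict(self.groups),
        )

    def subset(self, probe_ids: Iterable) -> "BetaMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        wanted = [p for p in probe_ids if p in index]
        return BetaMatrix(
            probe_ids=wanted,
            sample_ids=list(self.sample_ids),
            values=self.values[[index[p] for p in wanted]],
            groups=dict(self.groups),
        )


def read_sample_sheet(path) -> dict:
    """TSV with columns sample_id, group (CASE/CTRL) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"sample sheet {path}: required column {col!r} missing")
    groups = {}
    for rec in df.itertuples(index=False):
        try:
            groups[rec.sample_id] = Group(rec.group.strip().upper())
        except ValueError:
            raise FormatError(
                f"sample sheet {path}: group {rec.group!r} for {rec.sample_id!r} "
                f"is not CASE/CTRL"
            ) from None
    return groups


def write_sample_sheet(groups: Mapping, path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [Group(g).value for g in groups.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_beta_matrix(path, sample_sheet) -> BetaMatrix:
    """Read a TSV beta matrix (probes as rows, first column probe_id).

    ``sample_sheet`` is a path or an already-parsed mapping.  Any sample in
    the matrix header absent from the sheet is fatal; non-numeric cells are
    fatal with coordinates; values outside [0,1] beyond 1e-6 are fatal.
    """
    groups = sample_sheet if isinstance(sample_sheet, Mapping) else read_sample_sheet(sample_sheet)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    unknown = [s for s in df.columns if s not in groups]
    if unknown:
        raise FormatError(f"beta matrix {path}: samples absent from sample sheet: {unknown}")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j, sample in enumerate(df.columns):
        col = pd.to_numeric(pd.Series(raw[:, j]).replace("", np.nan), errors="coerce")
        bad = col.isna() & ~pd.Series(raw[:, j]).str.strip().str.lower().isin(["", "na", "nan"])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"beta matrix {path}: non-numeric value {raw[i, j]!r} at probe "
                f"{df.index[i]!r}, sample {sample!r}"
            )
        values[:, j] = col.to_numpy()
    return BetaMatrix(
        probe_ids=list(df.index),
        sample_ids=list(df.columns),
        values=values,
        groups={s: groups[s] for s in df.columns},
    )


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    pd.DataFrame(
        matrix.values, index=pd.Index(matrix.probe_ids, name="probe_id"), columns=matrix.sample_ids
    ).to_csv(path, sep="\t", float_format="%.17g")


@dataclass
class GeneSetLibrary:
    """term_id -> (term_name, gene symbol set); symbols are uppercased."""

    terms: dict = field(default_factory=dict)

    @property
    def all_genes(self) -> frozenset:
        out: set = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path) -> GeneSetLibrary:
    """Read a GMT library: ``term<TAB>description<TAB>gene1<TAB>gene2...``.

    Lines with fewer than three fields are skipped with a warning.
    """
    terms: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("read_gmt: %s line %d has <3 fields, skipped", path, lineno)
                continue
            term_id, name = fields[0].strip(), fields[1].strip()
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                logger.warning("read_gmt: %s line %d has no genes, skipped", path, lineno)
                continue
            terms[term_id] = (name, genes)
    return GeneSetLibrary(terms=terms)


def write_gmt(library: GeneSetLibrary, path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, genes) in library.terms.items():
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def read_gene_list(path) -> list:
    """One gene symbol per line, uppercased, de-duplicated, order kept."""
    seen, out = set(), []
    with open(path) as fh:
        for line in fh:
            g = line.strip().upper()
            if g and g not in seen:
                seen.add(g)
                out.append(g)
    return out


def read_probe_list(path) -> list:
    """One probe id per line (a probe universe), order kept."""
    seen, out = set(), []
    with open(path) as fh:
        for line in fh:
            p = line.strip()
            if p and p not in seen:
                seen.add(p)
                out.append(p)
    return out


def read_series_matrix(path, groups: Mapping | None = None):
    """Parse a plain-text GEO series-matrix table (offline convenience).

    Reads the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` into a DataFrame indexed by the ID column.
    """
    rows, header, inside = [], None, False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.lower().startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if line.lower().startswith("!series_matrix_table_end"):
                break
            if not inside or not line:
                continue
            fields = [f.strip().strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
            else:
                rows.append(fields)
    if header is None:
        raise FormatError(f"{path}: no series-matrix table block found")
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    return df.apply(pd.to_numeric, errors="coerce")


def write_dmr_bed(dmrs, path) -> None:
    """Write DMRs as BED (0-based half-open): chrom, start-1, end, name, score.

    name is ``gene1,gene2;island_name``; score is -log10 of the DMR p-value.
    """
    with open(path, "w") as fh:
        for d in dmrs:
            start0 = d.start - 1
            if start0 < 0 or start0 >= d.end:
                raise ValueError(f"DMR {d.island_name}: invalid BED interval {start0}-{d.end}")
            name = f"{','.join(sorted(d.genes))};{d.island_name}"
            score = -np.log10(max(d.p_value, 1e-300))
            fh.write(f"{d.chrom}\t{start0}\t{d.end}\t{name}\t{score:.4f}\n")


def write_table(records, path) -> None:
    """Write a DataFrame or list of dicts/dataclasses as a TSV table."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
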