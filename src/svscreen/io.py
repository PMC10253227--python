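"""Readers, writers and in-memory containers for screen artifacts.

The module owns every external format the pipeline touches:

* sgRNA count tables — TSV with a two-column ``sgRNA<TAB>gene`` prefix
  followed by one integer column per sample (the de-facto dialect of pooled
  screen count files), paired with a sample-metadata TSV;
* sgRNA library maps — TSV ``guide_id<TAB>gene[<TAB>spacer]``;
* gene sets — GMT (``name<TAB>description<TAB>gene...``);
* results tables — gene statistics and cross-screen comparisons, TSV;
* raw reads — FASTQ (optionally gzipped) quantified by exact spacer match.

All readers validate and reject rather than coerce; every writer/reader
pair is a round-trip identity on the data it owns.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import LibraryError, ParseError, SchemaError

_DNA = frozenset("ACGT")

VALID_CONDITIONS = ("control", "treated", "nt")

#: columns required in a sample-metadata table
SAMPLE_FIELDS = ("condition", "dose", "timepoint", "replicate")


@dataclass(frozen=True)
class SgRNALibrary:
    """Mapping from guide identifier to gene symbol and optional spacer.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by unique ``guide_id``; column ``gene`` (opaque
        case-sensitive symbol) and optionally ``spacer`` (uniform-length
        DNA over {A,C,G,T}).  Any further columns (e.g. simulated baseline
        abundances) are carried along untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "gene" not in self.table.columns:
            raise SchemaError("library table must have a 'gene' column")
        if not self.table.index.is_unique:
            dupes = self.table.index[self.table.index.duplicated()][:3]
            raise LibraryError(f"duplicate guide ids in library: {list(dupes)}")
        if "spacer" in self.table.columns:
            spacers = self.table["spacer"].astype(str)
            lengths = spacers.str.len().unique()
            if len(lengths) > 1:
                raise LibraryError(
                    f"spacers must have uniform length, found lengths {sorted(lengths)}"
                )
            bad = spacers[~spacers.map(lambda s: set(s) <= _DNA)]
            if len(bad):
                raise LibraryError(
                    f"non-ACGT spacer for guide {bad.index[0]!r}: {bad.iloc[0]!r}"
                )

    @property
    def guides(self) -> pd.Index:
        return self.table.index

    @property
    def genes(self) -> pd.Series:
        """guide_id -> gene symbol."""
        return self.table["gene"]

    @property
    def spacers(self) -> pd.Series | None:
        return self.table["spacer"] if "spacer" in self.table.columns else None

    def gene_sizes(self) -> pd.Series:
        """Number of guides per gene."""
        return self.table.groupby("gene").size()

    def subset(self, guides: Iterable[str]) -> "SgRNALibrary":
        return SgRNALibrary(self.table.loc[list(guides)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SgRNALibrary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        first = df.columns[0]
        df = df.rename(columns={first: "guide_id"}).set_index("guide_id")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "guide_id"
        out.to_csv(path, sep="\t")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CountMatrix:
    """Guide-by-sample integer read counts plus per-sample metadata.

    ``counts`` is indexed by guide id with one column per sample;
    ``samples`` is indexed by sample id with columns ``condition``
    (one of ``control``/``treated``/``nt``), ``dose``, ``timepoint``
    and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.is_unique:
            raise SchemaError("duplicate sample ids in count table")
        if not self.samples.index.is_unique:
            raise SchemaError("duplicate sample ids in metadata")
        missing = [c for c in self.counts.columns if c not in self.samples.index]
        if missing:
            raise SchemaError(f"samples without metadata: {missing}")
        for f in SAMPLE_FIELDS:
            if f not in self.samples.columns:
                raise SchemaError(f"sample metadata missing column {f!r}")
        bad_cond = set(self.samples["condition"]) - set(VALID_CONDITIONS)
        if bad_cond:
            raise SchemaError(
                f"unknown condition labels {sorted(bad_cond)}; "
                f"expected one of {VALID_CONDITIONS}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise SchemaError("counts must be integers")
        if (vals < 0).any():
            raise SchemaError("counts must be non-negative")
        # keep metadata aligned to count columns
        self.samples = self.samples.loc[self.counts.columns]

    @property
    def guides(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_where(self, condition: str) -> pd.Index:
        return self.samples.index[self.samples["condition"] == condition]

    def check_library(self, library: SgRNALibrary) -> None:
        unknown = self.counts.index.difference(library.guides)
        if len(unknown):
            raise SchemaError(
                f"{len(unknown)} guides absent from library, e.g. {unknown[0]!r}"
            )

    def subset_guides(self, guides: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(guides)], self.samples.copy())


@dataclass
class NormalizedMatrix:
    """Reads-per-million table; same layout and metadata as CountMatrix."""

    values: pd.DataFrame
    samples: pd.DataFrame

    @property
    def guides(self) -> pd.Index:
        return self.values.index

    def samples_where(self, condition: str) -> pd.Index:
        return self.samples.index[self.samples["condition"] == condition]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


class GeneSetCollection:
    """Ordered collection of named, non-empty gene sets."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self._sets:
            raise SchemaError(f"duplicate gene-set name {gs.name!r}")
        if not gs.genes:
            raise SchemaError(f"gene set {gs.name!r} is empty")
        self._sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are deduplicated; duplicate set names or
    lines with no member genes raise :class:`SchemaError`.  An empty file
    yields an empty collection.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            name, description = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise SchemaError(f"{path}:{lineno}: gene set {name!r} has no genes")
            coll.add(GeneSet(name, description, genes))
    return coll


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def read_count_table(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a count TSV (``sgRNA<TAB>gene<TAB><sample...>``) plus metadata.

    Every count must be a non-negative integer and every sample column must
    have a metadata row; violations raise :class:`ParseError` /
    :class:`SchemaError` naming the offending cell or sample.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if len(df.columns) < 3 or df.columns[0] != "sgRNA" or df.columns[1] != "gene":
        raise SchemaError(
            f"{path}: expected header 'sgRNA<TAB>gene<TAB><sample...>', "
            f"got {list(df.columns[:3])}"
        )
    sample_cols = list(df.columns[2:])
    counts = {}
    for col in sample_cols:
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() | (num % 1 != 0) | (num < 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-integer count {df[col].iloc[i]!r} for guide "
                f"{df['sgRNA'].iloc[i]!r}, sample {col!r}"
            )
        counts[col] = num.astype(np.int64)
    count_df = pd.DataFrame(counts)
    count_df.index = pd.Index(df["sgRNA"], name="sgRNA")
    if not count_df.index.is_unique:
        raise SchemaError(f"{path}: duplicate guide ids")
    meta = read_sample_metadata(metadata_path)
    missing = [c for c in sample_cols if c not in meta.index]
    if missing:
        raise SchemaError(f"{metadata_path}: no metadata for samples {missing}")
    return CountMatrix(count_df, meta.loc[sample_cols])


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if meta.columns[0] != "sample_id":
        raise SchemaError(f"{path}: first metadata column must be 'sample_id'")
    meta = meta.set_index("sample_id")
    for f in SAMPLE_FIELDS:
        if f not in meta.columns:
            raise SchemaError(f"{path}: metadata missing column {f!r}")
    meta["timepoint"] = meta["timepoint"].astype(float)
    meta["dose"] = meta["dose"].fillna("")
    return meta


def write_count_table(
    cm: CountMatrix,
    library: SgRNALibrary,
    path: str | Path,
    metadata_path: str | Path,
) -> None:
    genes = library.genes.reindex(cm.guides)
    out = cm.counts.copy()
    out.insert(0, "gene", genes.to_numpy())
    out.index.name = "sgRNA"
    out.to_csv(path, sep="\t")
    meta = cm.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t", float_format="%g")


def _fmt(x: object) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


GENE_RESULT_COLUMNS = ("gene", "n_sgrnas", "logFC", "ks_stat", "p_value", "fdr", "hit")
COMPARISON_COLUMNS = ("gene", "rank_control", "rank_treated", "relative_score")


def _write_table(df: pd.DataFrame, columns: tuple[str, ...], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in df[list(columns)].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_gene_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a gene-level result table.

    Columns ``gene, n_sgrnas, logFC, ks_stat, p_value, fdr, hit``; floats
    serialized with 6 significant digits; rows ordered by descending logFC
    with ties broken by gene name, so two runs on identical input produce
    byte-identical files.
    """
    df = results.sort_values(
        ["logFC", "gene"], ascending=[False, True], kind="mergesort"
    )
    _write_table(df, GENE_RESULT_COLUMNS, path)


def read_gene_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: result table missing columns {sorted(missing)}")
    df["hit"] = df["hit"].map({"True": True, "False": False, True: True, False: False})
    if df["hit"].isna().any():
        raise ParseError(f"{path}: 'hit' column must be True/False")
    return df


def write_comparison(comparison: pd.DataFrame, path: str | Path) -> None:
    """Write a cross-screen comparison table (expressed genes only).

    Rows ordered by descending relative score, ties by gene name.
    """
    df = comparison[comparison["expressed"]].sort_values(
        ["relative_score", "gene"], ascending=[False, True], kind="mergesort"
    )
    _write_table(df, COMPARISON_COLUMNS, path)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table: gene, log_fc, significant, direction.

    ``direction`` must be one of up/down/ns, and ``up`` rows must be
    significant with positive log_fc.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log_fc", "significant", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: DE table missing columns {sorted(missing)}")
    if df["significant"].dtype == object:
        df["significant"] = df["significant"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    bad_dir = set(df["direction"]) - {"up", "down", "ns"}
    if bad_dir:
        raise SchemaError(f"{path}: unknown direction labels {sorted(bad_dir)}")
    up = df["direction"] == "up"
    if ((up & ~df["significant"]) | (up & (df["log_fc"] <= 0))).any():
        raise SchemaError(f"{path}: 'up' rows must be significant with log_fc > 0")
    return df


def _open_maybe_gz(path: str | Path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def count_guides_from_fastq(
    fastq_path: str | Path,
    library: SgRNALibrary,
    offset: int | str = "scan",
) -> tuple[pd.Series, int]:
    """Quantify guides in a FASTQ file by exact spacer matching.

    Each read increments exactly one guide: with an integer ``offset`` the
    window ``read[offset:offset+L]`` must equal a spacer exactly; with
    ``offset="scan"`` the first matching window (left to right) wins.  No
    mismatches are tolerated.  Libraries with duplicate spacers are
    ambiguous and rejected.

    Returns
    -------
    (counts, unmatched) :
        per-guide counts (indexed like the library) and the number of
        reads matching no spacer.
    """
    spacers = library.spacers
    if spacers is None:
        raise LibraryError("library has no spacer sequences")
    if spacers.duplicated().any():
        dup = spacers[spacers.duplicated()].iloc[0]
        raise LibraryError(f"duplicate spacer sequence in library: {dup!r}")
    spacer_len = len(spacers.iloc[0])
    lookup: Mapping[str, str] = {s: g for g, s in spacers.items()}
    counts = pd.Series(0, index=library.guides, dtype=np.int64)
    unmatched = 0

    from Bio import SeqIO

    with _open_maybe_gz(fastq_path) as fh:
        for record in SeqIO.parse(fh, "fastq"):
            seq = str(record.seq).upper()
            hit = None
            if offset == "scan":
                for i in range(len(seq) - spacer_len + 1):
                    g = lookup.get(seq[i : i + spacer_len])
                    if g is not None:
                        hit = g
                        break
            else:
                g = lookup.get(seq[int(offset) : int(offset) + spacer_len])
                hit = g
            if hit is None:
                unmatched += 1
            else:
                counts[hit] += 1
    return counts, unmatched
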