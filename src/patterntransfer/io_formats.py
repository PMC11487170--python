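"""Readers and writers for the tabular dialects the pipeline touches.

Everything here is plain UTF-8, tab-separated text with Unix newlines:
gene x sample TPM matrices, sample annotation tables, OMA standalone
ortholog outputs (``OrthologousMatrix.txt`` / ``Map-SeqNum-ID.txt``),
Trinity ``gene_trans_map`` files, OMA splice files and GMT gene-set
collections.  Parsing is strict: duplicate identifiers, negative values
and malformed rows raise :class:`FormatError` naming the offender, so
that bad inputs never propagate silently into a factorization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleAnnotation",
    "OrthologMap",
    "GeneSetCollection",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_sample_annotations",
    "write_sample_annotations",
    "read_oma_orthologs",
    "write_oma_orthologs",
    "read_gene_trans_map",
    "gene_trans_map_to_splice",
    "read_gmt",
    "write_gmt",
]

#: float format used for every numeric TSV written by the package; fixed so
#: that identical runs produce byte-identical files.
FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A non-negative gene x sample expression matrix in TPM units."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class SampleAnnotation:
    """Metadata for one sample: which dataset, tissue and physiological state.

    ``state`` is a label such as ``euthermia``, ``torpor`` or ``IBA``
    (interbout arousal); ``library_size`` is total mapped reads or the
    expression column sum, used to flag sequencing-depth artifacts.
    """

    sample_id: str
    dataset: str
    tissue: str
    state: str
    replicate: str | None = None
    library_size: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FormatError("empty sample_id")
        if not self.tissue:
            raise FormatError(f"sample {self.sample_id!r}: empty tissue label")
        if not self.state:
            raise FormatError(f"sample {self.sample_id!r}: empty state label")
        if self.library_size is not None:
            self.library_size = float(self.library_size)
            if not np.isfinite(self.library_size) or self.library_size <= 0:
                raise FormatError(
                    f"sample {self.sample_id!r}: library_size must be a "
                    f"positive real, got {self.library_size}"
                )


@dataclass
class OrthologMap:
    """Validated one-to-one gene pairs between two species."""

    species_a: str
    species_b: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        for a, b in self.pairs:
            if not a or not b:
                raise FormatError(f"ortholog pair with empty identifier: {(a, b)!r}")
            if a in seen_a:
                raise FormatError(
                    f"one-to-one violation: {self.species_a} gene {a!r} "
                    "appears in more than one ortholog pair"
                )
            if b in seen_b:
                raise FormatError(
                    f"one-to-one violation: {self.species_b} gene {b!r} "
                    "appears in more than one ortholog pair"
                )
            seen_a.add(a)
            seen_b.add(b)

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def reversed(self) -> "OrthologMap":
        return OrthologMap(
            species_a=self.species_b,
            species_b=self.species_a,
            pairs=[(b, a) for a, b in self.pairs],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO biological process terms from a GMT file)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in frame.index]
    sample_ids = [str(s) for s in frame.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(sample_ids, "sample")
    values = np.empty(frame.shape, dtype=float)
    raw = frame.to_numpy()
    for j, sample in enumerate(sample_ids):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = np.nonzero(pd.isna(col))[0]
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"{path.name}: non-numeric value {raw[i, j]!r} at gene "
                f"{gene_ids[i]!r}, sample {sample!r}"
            )
        values[:, j] = col
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise FormatError(
            f"{path.name}: negative value at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# sample annotations

_REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "dataset", "tissue", "state")


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_ANNOTATION_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    _check_unique(list(frame["sample_id"]), "sample")
    annotations = []
    for _, row in frame.iterrows():
        lib = row.get("library_size")
        if lib is not None and (pd.isna(lib) or lib == ""):
            lib = None
        if lib is not None:
            try:
                lib = float(lib)
            except ValueError as exc:
                raise FormatError(
                    f"{path.name}: non-numeric library_size {lib!r} for "
                    f"sample {row['sample_id']!r}"
                ) from exc
        rep = row.get("replicate")
        if rep is not None and pd.isna(rep):
            rep = None
        annotations.append(
            SampleAnnotation(
                sample_id=str(row["sample_id"]),
                dataset=str(row["dataset"]),
                tissue=str(row["tissue"]),
                state=str(row["state"]),
                replicate=None if rep is None else str(rep),
                library_size=lib,
            )
        )
    return annotations


def write_sample_annotations(
    annotations: Iterable[SampleAnnotation], path: str | Path
) -> None:
    rows = []
    for a in annotations:
        rows.append(
            {
                "sample_id": a.sample_id,
                "dataset": a.dataset,
                "tissue": a.tissue,
                "state": a.state,
                "replicate": "" if a.replicate is None else a.replicate,
                "library_size": "" if a.library_size is None else FLOAT_FORMAT % a.library_size,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def annotations_by_sample(
    annotations: Iterable[SampleAnnotation],
) -> dict[str, SampleAnnotation]:
    out: dict[str, SampleAnnotation] = {}
    for a in annotations:
        if a.sample_id in out:
            raise FormatError(f"duplicate annotation for sample {a.sample_id!r}")
        out[a.sample_id] = a
    return out


# ---------------------------------------------------------------------------
# OMA standalone ortholog outputs


def read_oma_orthologs(
    matrix_path: str | Path,
    map_path: str | Path,
    species_a: str,
    species_b: str,
) -> OrthologMap:
    """Parse OMA standalone's OrthologousMatrix.txt / Map-SeqNum-ID.txt pair.

    The matrix file holds one row per ortholog group with an integer entry
    number per species column (0 = no ortholog in that species); the map
    file translates (species, entry number) to a sequence identifier.  The
    returned map contains exactly the rows where both requested species are
    present, and satisfies the one-to-one invariant.
    """
    matrix_path, map_path = Path(matrix_path), Path(map_path)

    id_of: dict[tuple[str, int], str] = {}
    with open(map_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(
                    f"{map_path.name}:{lineno}: expected 3 tab-separated "
                    f"fields (species, entry, id), got {len(fields)}"
                )
            species, entry_str, seq_id = fields
            try:
                entry = int(entry_str)
            except ValueError as exc:
                raise FormatError(
                    f"{map_path.name}:{lineno}: non-integer entry number "
                    f"{entry_str!r}"
                ) from exc
            key = (species, entry)
            if key in id_of:
                raise FormatError(
                    f"{map_path.name}:{lineno}: duplicate map record for "
                    f"species {species!r} entry {entry}"
                )
            id_of[key] = seq_id

    header: list[str] | None = None
    pairs: list[tuple[str, str]] = []
    with open(matrix_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for sp in (species_a, species_b):
                    if sp not in header:
                        raise FormatError(
                            f"{matrix_path.name}: species {sp!r} not in "
                            f"header {header}"
                        )
                col_a = header.index(species_a)
                col_b = header.index(species_b)
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"{matrix_path.name}:{lineno}: row has {len(fields)} "
                    f"fields, header has {len(header)}"
                )
            try:
                ea, eb = int(fields[col_a]), int(fields[col_b])
            except ValueError as exc:
                raise FormatError(
                    f"{matrix_path.name}:{lineno}: non-integer entry number"
                ) from exc
            if ea == 0 or eb == 0:
                continue  # 0 means "no ortholog in this species"
            try:
                ga = id_of[(species_a, ea)]
            except KeyError:
                raise FormatError(
                    f"{matrix_path.name}:{lineno}: entry {ea} of species "
                    f"{species_a!r} has no record in {map_path.name}"
                ) from None
            try:
                gb = id_of[(species_b, eb)]
            except KeyError:
                raise FormatError(
                    f"{matrix_path.name}:{lineno}: entry {eb} of species "
                    f"{species_b!r} has no record in {map_path.name}"
                ) from None
            pairs.append((ga, gb))
    if header is None:
        raise FormatError(f"{matrix_path.name}: no header line found")
    return OrthologMap(species_a=species_a, species_b=species_b, pairs=pairs)


def write_oma_orthologs(
    omap: OrthologMap, matrix_path: str | Path, map_path: str | Path
) -> None:
    """Write an :class:`OrthologMap` back out in the OMA standalone dialect."""
    with open(matrix_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# orthologous matrix\n")
        fh.write(f"{omap.species_a}\t{omap.species_b}\n")
        for i in range(len(omap.pairs)):
            fh.write(f"{i + 1}\t{i + 1}\n")
    with open(map_path, "w", encoding="utf-8", newline="\n") as fh:
        for i, (a, b) in enumerate(omap.pairs, 1):
            fh.write(f"{omap.species_a}\t{i}\t{a}\n")
        for i, (a, b) in enumerate(omap.pairs, 1):
            fh.write(f"{omap.species_b}\t{i}\t{b}\n")


# ---------------------------------------------------------------------------
# Trinity gene_trans_map -> OMA splice file


def read_gene_trans_map(path: str | Path) -> dict[str, list[str]]:
    """Read a Trinity gene_trans_map: gene id TAB transcript id per row."""
    path = Path(path)
    transcripts: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 2 tab-separated "
                    f"columns (gene, transcript), got {len(fields)}"
                )
            gene, transcript = fields
            bucket = transcripts.setdefault(gene, [])
            if transcript in bucket:
                raise FormatError(
                    f"{path.name}:{lineno}: duplicate transcript "
                    f"{transcript!r} for gene {gene!r}"
                )
            bucket.append(transcript)
    return transcripts


def gene_trans_map_to_splice(path: str | Path) -> list[str]:
    """Convert a gene_trans_map into OMA splice-file lines.

    One line per gene with two or more isoforms, transcript ids joined by
    ``"; "`` in first-seen order.  Single-isoform genes are omitted: OMA
    treats genes absent from the splice file as single-variant.
    """
    transcripts = read_gene_trans_map(path)
    return ["; ".join(ts) for ts in transcripts.values() if len(ts) >= 2]


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs at least "
                    "(name, description, one member)"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if m and m not in seen:
                    members.append(m)
                    seen.add(m)
            if not members:
                raise FormatError(f"{path.name}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *members]) + "\n")
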