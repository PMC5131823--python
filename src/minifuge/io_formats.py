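"""Readers and writers for the formats the toolkit speaks.

FASTA/FASTQ go through Biopython (gzip-transparently); taxonomy dumps use the
pipe-delimited NCBI ``nodes.dmp``/``names.dmp`` dialect (only the first three
columns of ``nodes.dmp`` are read); sequence-to-taxon maps are two-column TSV;
classification and abundance reports are TSV tables handled as pandas frames.

Sequences are normalized on input: uppercased, with any character outside
``{A, C, G, T, N}`` mapped to ``N``.  ``N`` bases are indexed but never match
a query, so this normalization is lossless for exact-match search.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import NO_RANK, TaxNode, TaxonomyTree

_NORMALIZE = {c: c for c in "ACGTN"}
_NORMALIZE_TABLE = str.maketrans(
    {chr(i): _NORMALIZE.get(chr(i).upper(), "N") for i in range(256)}
)

#: Column order of the per-read classification report.
REPORT_COLUMNS = (
    "readID",
    "seqID",
    "taxID",
    "score",
    "2ndBestScore",
    "hitLength",
    "queryLength",
    "numMatches",
)


@dataclass(frozen=True)
class GenomeRecord:
    """One named DNA sequence tied to a taxon id — the unit of indexing."""

    seq_id: str
    taxon_id: int
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Read:
    """A sequencing read.  Qualities are carried but never interpreted."""

    read_id: str
    sequence: str
    quality: str | None = None


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
    elif path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map non-ACGTN characters to N."""
    return seq.upper().translate(_NORMALIZE_TABLE)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def parse_fasta(
    path: str | Path, taxmap: Mapping[str, int] | None = None
) -> list[GenomeRecord]:
    """Read a (possibly gzipped) FASTA file into normalized genome records.

    ``taxmap`` optionally assigns taxon ids by sequence id; unmapped records
    get taxon 0.  Empty files and headers without sequence are errors.
    """
    with _open_maybe_gzip(path) as fh:
        raw = list(SeqIO.parse(fh, "fasta"))
    if not raw:
        raise ValueError(f"no FASTA records in {path}")
    records = []
    for rec in raw:
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has no sequence")
        taxon = int(taxmap.get(rec.id, 0)) if taxmap else 0
        records.append(GenomeRecord(seq_id=rec.id, taxon_id=taxon, sequence=seq))
    seen: set[str] = set()
    for rec in records:
        if rec.seq_id in seen:
            raise ValueError(f"duplicate sequence id {rec.seq_id!r}")
        seen.add(rec.seq_id)
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 80) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def parse_fastq(path: str | Path) -> list[Read]:
    """Read FASTQ into :class:`Read` objects (qualities kept, not used)."""
    with _open_maybe_gzip(path) as fh:
        raw = list(SeqIO.parse(fh, "fastq"))
    return [
        Read(
            read_id=rec.id,
            sequence=normalize_sequence(str(rec.seq)),
            quality="".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            ),
        )
        for rec in raw
    ]


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        recs = []
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            qual = r.quality or "I" * len(r.sequence)
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            recs.append(rec)
        SeqIO.write(recs, fh, "fastq")


# ---------------------------------------------------------------------------
# Taxonomy dumps and seqid2taxid maps
# ---------------------------------------------------------------------------

def _parse_dump_line(line: str) -> list[str]:
    return [field.strip() for field in line.rstrip("\n").rstrip("|").split("|")]


def parse_taxonomy(nodes_path: str | Path, names_path: str | Path | None = None) -> TaxonomyTree:
    """Parse pipe-delimited ``nodes.dmp`` (+ optional ``names.dmp``) dumps.

    Only the first three columns of ``nodes.dmp`` are used (taxid, parent,
    rank); extra NCBI columns are ignored.  Node order in the file does not
    matter.  Orphan parents and cycles raise ``ValueError``.
    """
    names: dict[int, str] = {}
    if names_path is not None:
        with _open_maybe_gzip(names_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _parse_dump_line(line)
                taxid = int(fields[0])
                # prefer the scientific name when a name class column exists
                if len(fields) >= 4 and fields[3] and fields[3] != "scientific name":
                    continue
                names.setdefault(taxid, fields[1])

    nodes = []
    with _open_maybe_gzip(nodes_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _parse_dump_line(line)
            if len(fields) < 3:
                raise ValueError(f"malformed nodes.dmp line: {line!r}")
            taxid, parent = int(fields[0]), int(fields[1])
            rank = fields[2].replace(" ", "_") or NO_RANK
            nodes.append(
                TaxNode(taxon_id=taxid, parent_id=parent, rank=rank, name=names.get(taxid, ""))
            )
    if not nodes:
        raise ValueError(f"no taxonomy nodes in {nodes_path}")
    return TaxonomyTree(nodes)


def write_taxonomy(
    tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path | None = None
) -> None:
    """Write a tree back out in the pipe-delimited dump dialect."""
    with open(nodes_path, "w") as fh:
        for node in tree.nodes():
            rank = node.rank.replace("_", " ")
            fh.write(f"{node.taxon_id}\t|\t{node.parent_id}\t|\t{rank}\t|\n")
    if names_path is not None:
        with open(names_path, "w") as fh:
            for node in tree.nodes():
                name = node.name or f"taxon {node.taxon_id}"
                fh.write(f"{node.taxon_id}\t|\t{name}\t|\t\t|\tscientific name\t|\n")


def parse_seqid2taxid(path: str | Path) -> dict[str, int]:
    """Two-column TSV: sequence id, taxon id."""
    out: dict[str, int] = {}
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            seq_id, taxid = line.split("\t")[:2]
            out[seq_id.strip()] = int(taxid)
    return out


def write_seqid2taxid(taxmap: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, taxid in taxmap.items():
            fh.write(f"{seq_id}\t{taxid}\n")


# ---------------------------------------------------------------------------
# Classification and abundance reports
# ---------------------------------------------------------------------------

def classification_report_frame(results: Sequence, tree: TaxonomyTree | None = None) -> pd.DataFrame:
    """One row per (read, label) pair; unclassified reads get a taxID-0 row."""
    rows = []
    for res in results:
        if res.labels:
            for label in res.labels:
                name = tree.name(label) if tree is not None and label in tree else ""
                rows.append(
                    (
                        res.read_id,
                        name or str(label),
                        int(label),
                        float(res.score),
                        float(res.second_best_score),
                        int(res.best_hit_length),
                        int(res.query_length),
                        len(res.labels),
                    )
                )
        else:
            rows.append((res.read_id, "unclassified", 0, 0.0, 0.0, 0, int(res.query_length), 0))
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def write_classification_report(
    results: Sequence, path: str | Path, tree: TaxonomyTree | None = None
) -> None:
    classification_report_frame(results, tree).to_csv(path, sep="\t", index=False)


def read_classification_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def filter_report(rows, min_score: float = 0, min_hit_length: int = 0):
    """Keep rows passing both thresholds: score >= min_score and
    hitLength >= min_hit_length.  Thresholds of 0 are the identity filter.
    Order-preserving and idempotent."""
    if min_score < 0 or min_hit_length < 0:
        raise ValueError("filter thresholds must be nonnegative")
    if isinstance(rows, pd.DataFrame):
        mask = (rows["score"] >= min_score) & (rows["hitLength"] >= min_hit_length)
        return rows[mask]
    return [
        r
        for r in rows
        if r["score"] >= min_score and r["hitLength"] >= min_hit_length
    ]


def write_abundance_report(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_abundance_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
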