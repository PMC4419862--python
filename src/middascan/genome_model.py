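"""Gene annotations, deterministic gene order, and virtual clusters.

Every window statistic in middascan is defined on the *ordinal* gene
order along a contig, not on base-pair coordinates: a virtual cluster
(VC) of size ``ncl`` is simply ``ncl`` consecutive genes.  This module
establishes that order from a GFF3 file or a plain gene table and
enumerates all VCs of a given size.

Ordering convention: genes are sorted by start coordinate ascending,
ties broken by gene id (lexicographic).  Strand is recorded but never
used for ordering.  Windows never cross contig boundaries, because a
gene cluster is physically contiguous on one sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from middascan.errors import InputError

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene.

    Coordinates are 1-based and inclusive at both ends (GFF3
    convention).  ``strand`` is one of ``+``, ``-`` or ``.`` (unknown).
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise InputError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise InputError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in _STRANDS:
            raise InputError(
                f"gene {self.gene_id}: strand {self.strand!r} not in {{+,-,.}}"
            )


@dataclass(frozen=True)
class VirtualCluster:
    """A window of ``size`` consecutive genes on one contig.

    ``start_index`` is the 1-based ordinal of the first gene within its
    contig.
    """

    contig: str
    start_index: int
    size: int
    gene_ids: tuple[str, ...]


class GeneOrder:
    """Per-contig ordered gene records; the coordinate system for windows.

    Contigs are kept in lexicographic order; within each contig genes
    are sorted by start coordinate, ties broken by gene id.  Ordinal
    indices are 1-based and contiguous within each contig.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        by_contig: dict[str, list[GeneRecord]] = {}
        seen: set[str] = set()
        for rec in records:
            if rec.gene_id in seen:
                raise InputError(f"duplicate gene id: {rec.gene_id}")
            seen.add(rec.gene_id)
            by_contig.setdefault(rec.contig, []).append(rec)
        if not seen:
            raise InputError("annotation contains zero genes")
        self._contigs: dict[str, list[GeneRecord]] = {}
        for contig in sorted(by_contig):
            recs = sorted(by_contig[contig], key=lambda r: (r.start, r.gene_id))
            self._contigs[contig] = recs
        self._index: dict[str, tuple[str, int]] = {}
        for contig, recs in self._contigs.items():
            for i, rec in enumerate(recs, start=1):
                self._index[rec.gene_id] = (contig, i)

    @property
    def contigs(self) -> list[str]:
        return list(self._contigs)

    def genes_on(self, contig: str) -> list[GeneRecord]:
        try:
            return list(self._contigs[contig])
        except KeyError:
            raise InputError(f"unknown contig: {contig}") from None

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __iter__(self) -> Iterator[GeneRecord]:
        for recs in self._contigs.values():
            yield from recs

    def gene_ids(self) -> list[str]:
        """All gene ids in genome order (contigs lexicographic)."""
        return [rec.gene_id for rec in self]

    def record(self, gene_id: str) -> GeneRecord:
        contig, i = self.locate(gene_id)
        return self._contigs[contig][i - 1]

    def locate(self, gene_id: str) -> tuple[str, int]:
        """Return (contig, 1-based ordinal index) of a gene."""
        try:
            return self._index[gene_id]
        except KeyError:
            raise InputError(f"unknown gene id: {gene_id}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self._contigs == other._contigs


def enumerate_virtual_clusters(order: GeneOrder, ncl: int) -> list[VirtualCluster]:
    """All windows of ``ncl`` consecutive genes, per contig.

    A contig with G genes yields max(0, G - ncl + 1) windows starting at
    ordinals 1..G-ncl+1.  Windows never span contigs.
    """
    if ncl < 1:
        raise InputError(f"ncl must be >= 1, got {ncl}")
    out: list[VirtualCluster] = []
    for contig in order.contigs:
        recs = order.genes_on(contig)
        ids = [r.gene_id for r in recs]
        for i in range(len(ids) - ncl + 1):
            out.append(
                VirtualCluster(contig, i + 1, ncl, tuple(ids[i : i + ncl]))
            )
    return out


def read_annotation(path: str | os.PathLike, format: str | None = None) -> GeneOrder:
    """Read a gene annotation into a :class:`GeneOrder`.

    ``format`` is ``gff3`` or ``gene_tsv``; when omitted it is inferred
    from the file extension (``.gff``/``.gff3`` vs anything else).
    GFF3 reading takes features of type ``gene`` and the ``ID``
    attribute as gene id.  The gene TSV dialect is five tab-separated
    columns with a header: gene_id, contig, start, end, strand.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"annotation file not found: {path}")
    if format is None:
        format = "gff3" if path.lower().endswith((".gff", ".gff3")) else "gene_tsv"
    if format == "gff3":
        return _read_gff3(path)
    if format == "gene_tsv":
        return _read_gene_tsv(path)
    raise InputError(f"unknown annotation format: {format!r}")


def _read_gff3(path: str) -> GeneOrder:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    records = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        gene_id = ids[0] if ids else feat.id
        if gene_id is None:
            raise InputError(f"gene feature without ID at {feat.seqid}:{feat.start}")
        strand = feat.strand if feat.strand in _STRANDS else "."
        records.append(GeneRecord(gene_id, feat.seqid, feat.start, feat.end, strand))
    return GeneOrder(records)


_TSV_HEADER = ["gene_id", "contig", "start", "end", "strand"]


def _read_gene_tsv(path: str) -> GeneOrder:
    records = []
    with open(path, newline="") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_HEADER:
            raise InputError(
                f"gene TSV header must be {_TSV_HEADER}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise InputError(f"{path}:{lineno}: expected 5 columns")
            gene_id, contig, start, end, strand = cols
            try:
                records.append(
                    GeneRecord(gene_id, contig, int(start), int(end), strand)
                )
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from None
    return GeneOrder(records)


def write_annotation(order: GeneOrder, path: str | os.PathLike) -> None:
    """Write the gene TSV dialect (tab-separated, LF line endings)."""
    with open(os.fspath(path), "w", newline="") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for rec in order:
            fh.write(
                f"{rec.gene_id}\t{rec.contig}\t{rec.start}\t{rec.end}\t{rec.strand}\n"
            )
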