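"""Readers and writers for the pipeline's text formats.

All tabular formats are TSV; band profiles use the FPC "sizes" dialect
(clone name line, band-count line, one band per line, ``-1`` terminator).
Internal coordinates are 0-based half-open; BLAST-tabular and GFF3 inputs are
1-based and converted on read.  Writers emit deterministic, sorted output.
"""

from __future__ import annotations

import csv
from typing import Iterable, Mapping

from .anchoring import GeneticMap, MapLocus
from .assembly import Assembly, EvidenceMarker, MarkerKind
from .fingerprint import BandProfile, Method
from .synteny import Hit, HitTable, QueryKind

__all__ = [
    "FormatError",
    "read_sizes", "write_sizes",
    "read_markers", "write_markers",
    "read_genetic_map", "write_genetic_map",
    "read_hit_table", "write_hit_table",
    "read_probe_hits", "write_probe_hits",
    "write_bed", "read_gff3_genes", "write_gff3_genes",
    "write_assembly_tables", "write_fpc_export",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FPC sizes dialect


def write_sizes(path, profiles: Iterable) -> None:
    profs = sorted(profiles, key=lambda p: p.clone_id)
    with open(path, "w") as fh:
        for p in profs:
            fh.write(f"{p.clone_id}\n{p.n}\n")
            for b in p.bands:
                fh.write(f"{b}\n")
            fh.write("-1\n")


def read_sizes(path, method: Method = Method.AGAROSE) -> dict:
    """Parse a sizes file into ``clone_id -> BandProfile``.

    Malformed records raise :class:`FormatError` with the offending line
    number; ``write_sizes`` then ``read_sizes`` is the identity on bands.
    """
    profiles = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        clone_id = lines[i].strip()
        if i + 1 >= len(lines):
            raise FormatError(f"{path}:{i + 1}: record truncated after clone name")
        try:
            n = int(lines[i + 1])
        except ValueError:
            raise FormatError(f"{path}:{i + 2}: expected band count, got "
                              f"{lines[i + 1]!r}") from None
        bands = []
        j = i + 2
        for k in range(n):
            if j + k >= len(lines):
                raise FormatError(f"{path}:{len(lines)}: record for "
                                  f"{clone_id!r} truncated")
            try:
                bands.append(int(lines[j + k]))
            except ValueError:
                raise FormatError(f"{path}:{j + k + 1}: expected band value, "
                                  f"got {lines[j + k]!r}") from None
        term = j + n
        if term >= len(lines) or lines[term].strip() != "-1":
            raise FormatError(f"{path}:{term + 1}: missing '-1' terminator "
                              f"for {clone_id!r}")
        profiles[clone_id] = BandProfile(clone_id, method, tuple(sorted(bands)))
        i = term + 1
    return profiles


# ---------------------------------------------------------------------------
# marker / probe-hit tables


def write_markers(path, markers: Iterable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["marker_id", "kind", "clone_id"])
        for m in sorted(markers, key=lambda m: m.marker_id):
            for clone in sorted(m.clones):
                w.writerow([m.marker_id, m.kind.value, clone])


def read_markers(path) -> list:
    grouped: dict = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["marker_id", "kind", "clone_id"]:
            raise FormatError(f"{path}: bad marker header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            mid, kind, clone = row
            try:
                k = MarkerKind(kind)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unknown kind {kind!r}") from None
            grouped.setdefault((mid, k), set()).add(clone)
    return [EvidenceMarker(mid, k, frozenset(clones))
            for (mid, k), clones in sorted(grouped.items())]


def write_probe_hits(path, matrix: Mapping) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["probe_id", "bac_id"])
        for probe in sorted(matrix):
            for bac in sorted(matrix[probe]):
                w.writerow([probe, bac])


def read_probe_hits(path) -> dict:
    matrix: dict = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["probe_id", "bac_id"]:
            raise FormatError(f"{path}: bad probe-hit header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            matrix.setdefault(row[0], set()).add(row[1])
    return matrix


# ---------------------------------------------------------------------------
# genetic map


def write_genetic_map(path, gmap: GeneticMap) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["marker_id", "group", "cm"])
        for locus in sorted(gmap.loci, key=lambda l: (l.group, l.cm, l.marker_id)):
            w.writerow([locus.marker_id, locus.group, f"{locus.cm:.6g}"])


def read_genetic_map(path, n_groups: int = 13) -> GeneticMap:
    loci = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["marker_id", "group", "cm"]:
            raise FormatError(f"{path}: bad genetic-map header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                loci.append(MapLocus(row[0], int(row[1]), float(row[2])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed locus row "
                                  f"{row!r}") from None
    return GeneticMap(loci, n_groups)


# ---------------------------------------------------------------------------
# BLAST tabular subset


def _query_kind(qid: str) -> QueryKind:
    return QueryKind.BES if qid.endswith(("_L", "_R")) else QueryKind.PROBE_SOURCE


def write_hit_table(path, table: HitTable) -> None:
    """Emit a BLAST outfmt-6-like table (sstart written 1-based)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in sorted(table.hits,
                        key=lambda h: (h.query_id, h.target_chrom, h.target_pos)):
            w.writerow([h.query_id, h.target_chrom, "100.00", "40", "0", "0",
                        "1", "40", h.target_pos + 1, h.target_pos + 40,
                        "1e-10", "80.0"])


def read_hit_table(path, chrom_lengths: Mapping | None = None) -> HitTable:
    """Parse qseqid/sseqid/sstart from BLAST tabular (12 columns) or a bare
    3-column (query, chrom, sstart) TSV; sstart is 1-based on disk."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            row = line.split("\t")
            if len(row) >= 12:
                qid, chrom, sstart = row[0], row[1], row[8]
            elif len(row) == 3:
                qid, chrom, sstart = row
            else:
                raise FormatError(f"{path}:{lineno}: expected 3 or >=12 columns,"
                                  f" got {len(row)}")
            try:
                pos = int(sstart) - 1
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed position "
                                  f"{sstart!r}") from None
            if pos < 0:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            hits.append(Hit(qid, _query_kind(qid), chrom, pos))
    return HitTable(hits, {}, dict(chrom_lengths or {}))


# ---------------------------------------------------------------------------
# BED / GFF3


def write_bed(path, intervals: Iterable) -> None:
    """``(chrom, start, end, name)`` rows, 0-based half-open."""
    with open(path, "w", newline="") as fh:
        for chrom, start, end, name in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_gff3_genes(path, genes: Iterable) -> None:
    """``(chrom, start, end)`` 0-based half-open -> GFF3 gene features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (chrom, start, end) in enumerate(sorted(genes), start=1):
            fh.write(f"{chrom}\tbacmap\tgene\t{start + 1}\t{end}\t.\t+\t.\t"
                     f"ID=gene{i}\n")


def read_gff3_genes(path) -> list:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            row = line.split("\t")
            if len(row) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            if row[2] != "gene":
                continue
            try:
                genes.append((row[0], int(row[3]) - 1, int(row[4])))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from None
    return genes


# ---------------------------------------------------------------------------
# assembly exports


def write_assembly_tables(prefix, assembly: Assembly) -> None:
    """TSV contig and singleton tables under ``<prefix>.contigs.tsv`` and
    ``<prefix>.singletons.tsv``."""
    with open(f"{prefix}.contigs.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig_id", "clone_id", "cb_offset", "cb_length",
                    "q_clone", "buried_into"])
        for ctg in assembly.contigs:
            for cid, off in ctg.members:
                w.writerow([ctg.contig_id, cid, off, ctg.cb_length,
                            int(cid in ctg.q_clones),
                            ctg.buried.get(cid, "")])
    with open(f"{prefix}.singletons.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["clone_id"])
        for cid in sorted(assembly.singletons):
            w.writerow([cid])


def write_fpc_export(path, assembly: Assembly, markers: Iterable = ()) -> None:
    """Simplified FPC-style text export: one contig record per block with
    member clones, CB extents and attached markers."""
    by_clone: dict = {}
    for m in markers:
        for clone in m.clones:
            by_clone.setdefault(clone, []).append(m.marker_id)
    with open(path, "w") as fh:
        for ctg in assembly.contigs:
            fh.write(f"Ctg{ctg.contig_id}  cb_length={ctg.cb_length}\n")
            for cid, off in ctg.members:
                marks = ",".join(sorted(by_clone.get(cid, [])))
                fh.write(f"  {cid} {off} {marks}\n")
        fh.write("Singletons\n")
        for cid in sorted(assembly.singletons):
            fh.write(f"  {cid}\n")
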