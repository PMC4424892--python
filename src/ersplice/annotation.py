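"""Annotation and peak-file IO plus promoter (TSS) grouping.

GTF input follows the Ensembl attribute dialect (``gene_id "...";
transcript_id "...";``). GTF coordinates are 1-based closed and are converted
to the package-internal 0-based half-open convention on load; BED is already
0-based half-open and is taken as-is.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional

from gffutils.feature import feature_from_line

from .models import BindingSiteSet, GeneModel, TranscriptAnnotation, TranscriptModel


class AnnotationParseError(ValueError):
    pass


def load_annotation(gtf_path) -> TranscriptAnnotation:
    """Parse an Ensembl-dialect GTF into a :class:`TranscriptAnnotation`.

    Only ``exon`` features are required: gene and transcript structures are
    assembled from the exons' ``gene_id`` / ``transcript_id`` attributes.
    A missing attribute raises :class:`AnnotationParseError` naming the line.
    """
    genes: Dict[str, GeneModel] = {}
    tx_exons: Dict[str, List] = {}
    tx_meta: Dict[str, tuple] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = feature_from_line(line, dialect=None)
            if feat.featuretype != "exon":
                continue
            try:
                gid = feat.attributes["gene_id"][0]
                tid = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise AnnotationParseError(
                    f"{gtf_path}:{lineno}: exon line missing {exc} attribute"
                ) from None
            # GTF 1-based closed -> 0-based half-open
            iv = (feat.start - 1, feat.end)
            tx_exons.setdefault(tid, []).append(iv)
            tx_meta[tid] = (gid, feat.seqid, feat.strand)
    for tid, exons in tx_exons.items():
        gid, chrom, strand = tx_meta[tid]
        gene = genes.get(gid)
        if gene is None:
            gene = genes[gid] = GeneModel(gid, chrom, strand)
        gene.add_transcript(
            TranscriptModel(tid, gid, chrom, strand, exons)
        )
    if not genes:
        raise AnnotationParseError(f"{gtf_path}: no exon records found")
    return TranscriptAnnotation(genes=genes)


def write_annotation(annotation: TranscriptAnnotation, gtf_path) -> None:
    """Write the model back to Ensembl-dialect GTF (deterministic order)."""
    with open(gtf_path, "w") as fh:
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            s, e = gene.span
            fh.write(_gtf_line(gene.chrom, "gene", s, e, gene.strand,
                               f'gene_id "{gid}";'))
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                fh.write(_gtf_line(gene.chrom, "transcript", tx.start, tx.end,
                                   gene.strand, attrs))
                for (xs, xe) in tx.exons:
                    fh.write(_gtf_line(gene.chrom, "exon", xs, xe,
                                       gene.strand, attrs))


def _gtf_line(chrom: str, ftype: str, start0: int, end0: int, strand: str,
              attrs: str) -> str:
    # internal 0-based half-open -> GTF 1-based closed
    return (f"{chrom}\tersplice\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}"
            f"\t.\t{attrs}\n")


def group_by_tss(
    annotation: TranscriptAnnotation,
    tolerance_bp: int = 50,
    expression: Optional[Mapping[str, float]] = None,
) -> TranscriptAnnotation:
    """Partition each gene's transcripts into promoter (TSS) groups.

    Transcripts are sorted by strand-aware TSS (5'->3') and greedily seeded:
    a transcript joins the current group when its TSS lies within
    ``tolerance_bp`` of the group seed, else it opens a new group. Sorting
    first makes the partition independent of transcript input order.

    Group labels are ``TSS01``, ``TSS02``, ... ordered by decreasing total
    expression when ``expression`` (transcript id -> abundance) is given,
    else in transcription order (5'->3').
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be non-negative")
    for gene in annotation.genes.values():
        txs = sorted(
            gene.transcripts.values(),
            key=lambda t: (t.tss if gene.strand == "+" else -t.tss,
                           t.transcript_id),
        )
        groups: List[List[TranscriptModel]] = []
        seed_tss: Optional[int] = None
        for tx in txs:
            if seed_tss is not None and abs(tx.tss - seed_tss) <= tolerance_bp:
                groups[-1].append(tx)
            else:
                groups.append([tx])
                seed_tss = tx.tss
        if expression is not None:
            groups.sort(
                key=lambda grp: -sum(
                    expression.get(t.transcript_id, 0.0) for t in grp
                )
            )
        for i, grp in enumerate(groups, start=1):
            label = f"TSS{i:02d}"
            for tx in grp:
                tx.tss_group = label
    return annotation


class PeakFileError(ValueError):
    pass


def load_peaks(bed_path, receptor: str) -> BindingSiteSet:
    """Read a BED3+ file of binding sites; validates and sorts per chrom."""
    intervals: Dict[str, List] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise PeakFileError(
                    f"{bed_path}:{lineno}: expected >=3 BED columns"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise PeakFileError(
                    f"{bed_path}:{lineno}: start >= end ({start} >= {end})"
                )
            intervals.setdefault(chrom, []).append((start, end))
    return BindingSiteSet(receptor=receptor, intervals=intervals)


def write_peaks(peaks: BindingSiteSet, bed_path) -> None:
    with open(bed_path, "w") as fh:
        for chrom in sorted(peaks.intervals):
            for i, (s, e) in enumerate(peaks.intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{peaks.receptor}_{chrom}_{i}\n")
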