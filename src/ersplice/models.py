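"""Core in-memory containers shared by all pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based closed GTF happens only at file boundaries (see
:mod:`ersplice.annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

Interval = Tuple[int, int]


@dataclass
class TranscriptModel:
    """A transcript: ordered, non-overlapping exons on one strand.

    The transcription start site (TSS) is strand-aware: the minimum
    coordinate on '+' transcripts and the maximum coordinate on '-'
    transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Interval]
    tss_group: Optional[str] = None

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}: "
                    f"({s0},{e0}) and ({s1},{e1})"
                )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (on '-' this is the maximum coordinate)."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        """Mature transcript length: summed exon lengths in bp."""
        return sum(e - s for s, e in self.exons)

    def introns(self) -> List[Interval]:
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)

    @property
    def span(self) -> Interval:
        starts = [t.start for t in self.transcripts.values()]
        ends = [t.end for t in self.transcripts.values()]
        return (min(starts), max(ends))

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @property
    def length(self) -> int:
        """Union-of-exons length in bp (used as the gene's effective length)."""
        ivs = sorted(
            e for t in self.transcripts.values() for e in t.exons
        )
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
        return total

    def add_transcript(self, tx: TranscriptModel) -> None:
        if tx.chrom != self.chrom or tx.strand != self.strand:
            raise ValueError(
                f"transcript {tx.transcript_id} disagrees with gene "
                f"{self.gene_id} on chrom/strand"
            )
        self.transcripts[tx.transcript_id] = tx

    def tss_groups(self) -> Dict[str, List[TranscriptModel]]:
        """Transcripts keyed by their promoter (TSS) group label."""
        groups: Dict[str, List[TranscriptModel]] = {}
        for tx in self.transcripts.values():
            if tx.tss_group is None:
                raise ValueError(
                    f"transcript {tx.transcript_id} has no TSS group; run "
                    "group_by_tss first"
                )
            groups.setdefault(tx.tss_group, []).append(tx)
        return groups


@dataclass
class TranscriptAnnotation:
    """The full gene -> transcript -> exon model for one annotation."""

    genes: Dict[str, GeneModel] = field(default_factory=dict)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def transcript_index(self) -> Dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts()}

    def chroms(self) -> List[str]:
        return sorted({g.chrom for g in self.genes.values()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptAnnotation):
            return NotImplemented
        if set(self.genes) != set(other.genes):
            return False
        for gid, g in self.genes.items():
            h = other.genes[gid]
            if (g.chrom, g.strand) != (h.chrom, h.strand):
                return False
            if set(g.transcripts) != set(h.transcripts):
                return False
            for tid, t in g.transcripts.items():
                if t.exons != h.transcripts[tid].exons:
                    return False
        return True


@dataclass
class BindingSiteSet:
    """ChIP-seq peak intervals for one receptor (ERalpha or ERbeta)."""

    receptor: str
    intervals: Dict[str, List[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            for s, e in ivs:
                if s >= e:
                    raise ValueError(
                        f"empty/inverted interval ({s},{e}) on {chrom}"
                    )
            self.intervals[chrom] = sorted(ivs)

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def chroms(self) -> List[str]:
        return sorted(self.intervals)
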