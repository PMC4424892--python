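"""ER binding-site integration: peak-to-gene windows and density matrices.

Differentially spliced genes (DSGs) are annotated with ERalpha/ERbeta
ChIP-seq peaks falling within +/-10 kb of the gene body and classified into
Group 1 (both receptors), Group 2 (ERalpha only) and Group 3 (ERbeta only).
A binned tag-density matrix around binding-site centers supports
density-heat-map style downstream summaries.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import BindingSiteSet, GeneModel

FLANK_BP = 10_000


def gene_window(gene: GeneModel, flank_bp: int = FLANK_BP) -> Tuple[str, int, int]:
    """Strand-independent +/-flank window around the gene span, clipped at 0."""
    s, e = gene.span
    return (gene.chrom, max(0, s - flank_bp), e + flank_bp)


class ChromosomeMismatchError(ValueError):
    pass


def _peak_trees(peaks: BindingSiteSet) -> Dict[str, IntervalTree]:
    return {
        chrom: IntervalTree.from_tuples(ivs)
        for chrom, ivs in peaks.intervals.items()
    }


def _check_chroms(gene_chroms: set, peaks: BindingSiteSet) -> None:
    peak_chroms = set(peaks.intervals)
    if peak_chroms and gene_chroms and not (peak_chroms & gene_chroms):
        raise ChromosomeMismatchError(
            f"no shared chromosome names between annotation "
            f"({sorted(gene_chroms)}) and {peaks.receptor} peaks "
            f"({sorted(peak_chroms)})"
        )


def annotate_dsg_binding(
    genes: Iterable[GeneModel],
    era_peaks: BindingSiteSet,
    erb_peaks: BindingSiteSet,
    *,
    flank_bp: int = FLANK_BP,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Per-gene receptor-binding flags and Figure-5-style group labels.

    A receptor is associated with a gene when at least one of its peaks
    overlaps the gene's +/-flank window by >= ``min_overlap_bp``. Groups:
    1 = both receptors, 2 = ERalpha only, 3 = ERbeta only, 'none' otherwise.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    genes = list(genes)
    gene_chroms = {g.chrom for g in genes}
    _check_chroms(gene_chroms, era_peaks)
    _check_chroms(gene_chroms, erb_peaks)
    trees = {"era": _peak_trees(era_peaks), "erb": _peak_trees(erb_peaks)}

    def hit(receptor: str, chrom: str, lo: int, hi: int) -> bool:
        tree = trees[receptor].get(chrom)
        if tree is None:
            return False
        return any(
            min(iv.end, hi) - max(iv.begin, lo) >= min_overlap_bp
            for iv in tree.overlap(lo, hi)
        )

    rows = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        chrom, lo, hi = gene_window(gene, flank_bp)
        has_era = hit("era", chrom, lo, hi)
        has_erb = hit("erb", chrom, lo, hi)
        if has_era and has_erb:
            group = "1"
        elif has_era:
            group = "2"
        elif has_erb:
            group = "3"
        else:
            group = "none"
        rows.append(dict(gene_id=gene.gene_id, has_era=has_era,
                         has_erb=has_erb, group=group))
    return pd.DataFrame(rows, columns=["gene_id", "has_era", "has_erb", "group"])


def group_counts(annotation_table: pd.DataFrame) -> Dict[str, int]:
    counts = annotation_table["group"].value_counts().to_dict()
    return {g: int(counts.get(g, 0)) for g in ("1", "2", "3", "none")}


def density_matrix(
    reference_sites: Sequence[Tuple[str, int]],
    tag_positions: Mapping[str, Sequence[int]],
    *,
    half_window: int = 1500,
    bin_width: int = 50,
) -> np.ndarray:
    """Binned tag counts around each reference site center.

    ``reference_sites`` is a sequence of (chrom, center); ``tag_positions``
    maps chrom -> genomic read-start positions. Returns an array of shape
    (n_sites, 2*half_window/bin_width); bins extending past the chromosome
    start simply collect no tags.
    """
    if (2 * half_window) % bin_width != 0:
        raise ValueError("bin_width must divide the 2*half_window span")
    n_bins = (2 * half_window) // bin_width
    edges = np.arange(-half_window, half_window + bin_width, bin_width)
    mat = np.zeros((len(reference_sites), n_bins), dtype=np.int64)
    tags_sorted = {
        chrom: np.sort(np.asarray(pos, dtype=np.int64))
        for chrom, pos in tag_positions.items()
    }
    for i, (chrom, center) in enumerate(reference_sites):
        tags = tags_sorted.get(chrom)
        if tags is None or tags.size == 0:
            continue
        lo = np.searchsorted(tags, center - half_window, side="left")
        hi = np.searchsorted(tags, center + half_window, side="left")
        offsets = tags[lo:hi] - center
        mat[i], _ = np.histogram(offsets, bins=edges)
    return mat
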