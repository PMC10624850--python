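"""Transcription-start-nucleotide and pause-nucleotide calling.

Annotated TSSs typically report the longest mRNA isoform, not the
nucleotide where transcription actually initiates. The TSN (+1 nt) is
therefore called empirically, as the mode of nascent-RNA 5'-ends within
−100..+400 nt of the annotated TSS. The pause nucleotide is the mode of
3'-ends (active sites) in the same window; its distance from the TSN is
reported in the 1-based convention (+1 = TSN, −1 = first upstream nt,
no position 0) and classified into the early (+1..+30) or late
(+31..+60) pause window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genes import GeneModel
from .tracks import EndTrack

TSN_WINDOW = (-100, 400)  # offsets from annotated TSS queried for calling
EARLY_WINDOW = (1, 30)  # 1-based nt from TSN
LATE_WINDOW = (31, 60)


@dataclass(frozen=True)
class TSNCall:
    gene_id: str
    chrom: str
    strand: str
    called: bool
    tsn: int | None = None  # absolute 0-based coordinate
    offset: int | None = None  # strand-aware nt downstream of annotated TSS
    count: float = 0.0


@dataclass(frozen=True)
class PauseCall:
    gene_id: str
    called: bool
    pause: int | None = None  # absolute 0-based coordinate
    distance: int | None = None  # 1-based nt from TSN (+1 = TSN)
    pause_class: str = "none"  # early | late | outside | none
    count: float = 0.0
    fraction_early: float = 0.0
    fraction_late: float = 0.0


def offset_profile(
    track: EndTrack, gene: GeneModel, anchor: int, off_lo: int, off_hi: int
) -> np.ndarray:
    """Counts on the gene strand indexed by strand-aware offset from ``anchor``.

    Index 0 of the result corresponds to offset ``off_lo`` (upstream end
    of the window); offsets run upstream → downstream regardless of
    strand. Positions falling outside the chromosome contribute zero.
    """
    n = off_hi - off_lo + 1
    if gene.strand == "+":
        start, end = anchor + off_lo, anchor + off_hi + 1
        return _clipped_window(track, gene.chrom, "+", start, end, n)
    start, end = anchor - off_hi, anchor - off_lo + 1
    return _clipped_window(track, gene.chrom, "-", start, end, n)[::-1]


def _clipped_window(track, chrom, strand, start, end, n) -> np.ndarray:
    out = np.zeros(n)
    lo = max(start, 0)
    size = (track.chrom_sizes or {}).get(chrom)
    hi = min(end, size) if size is not None else end
    if hi <= lo:
        return out
    vals = track.window_counts(chrom, strand, lo, hi)
    offset = lo - start
    out[offset : offset + len(vals)] = vals
    return out


def call_tsn(
    five_prime: EndTrack, gene: GeneModel, window: tuple[int, int] = TSN_WINDOW
) -> TSNCall:
    """Call the TSN as the 5'-end mode in the annotated-TSS window.

    Ties break to the most upstream position; zero signal in the window
    leaves the gene uncalled.
    """
    off_lo, off_hi = window
    profile = offset_profile(five_prime, gene, gene.tss, off_lo, off_hi)
    if profile.sum() <= 0:
        return TSNCall(gene.gene_id, gene.chrom, gene.strand, called=False)
    idx = int(np.argmax(profile))  # first max == most upstream
    offset = off_lo + idx
    tsn = gene.offset_to_pos(gene.tss, offset)
    return TSNCall(
        gene.gene_id, gene.chrom, gene.strand, called=True,
        tsn=tsn, offset=offset, count=float(profile[idx]),
    )


def _to_one_based(d0: int) -> int:
    """0-based signed distance -> 1-based convention with no position 0."""
    return d0 + 1 if d0 >= 0 else d0


def call_pause(
    three_prime: EndTrack,
    tsn: TSNCall,
    gene: GeneModel,
    window: tuple[int, int] = TSN_WINDOW,
) -> PauseCall:
    """Call the pause nucleotide as the 3'-end mode in the TSS window.

    The distance from the TSN uses the 1-based convention; the call is
    classified early (+1..+30), late (+31..+60) or outside. Zero signal
    gives class ``none``. Pause fractions over the two windows are
    attached (see :func:`pause_fraction`).
    """
    if not tsn.called:
        raise ValueError(f"gene {gene.gene_id}: TSN must be called before the pause")
    off_lo, off_hi = window
    profile = offset_profile(three_prime, gene, gene.tss, off_lo, off_hi)
    if profile.sum() <= 0:
        return PauseCall(gene.gene_id, called=False)
    idx = int(np.argmax(profile))
    pause = gene.offset_to_pos(gene.tss, off_lo + idx)
    d0 = gene.pos_to_offset(tsn.tsn, pause)
    distance = _to_one_based(d0)
    if EARLY_WINDOW[0] <= distance <= EARLY_WINDOW[1]:
        pause_class = "early"
    elif LATE_WINDOW[0] <= distance <= LATE_WINDOW[1]:
        pause_class = "late"
    else:
        pause_class = "outside"
    f_early, f_late = pause_fraction(three_prime, tsn, gene)
    return PauseCall(
        gene.gene_id, called=True, pause=pause, distance=distance,
        pause_class=pause_class, count=float(profile[idx]),
        fraction_early=f_early, fraction_late=f_late,
    )


def pause_fraction(
    three_prime: EndTrack, tsn: TSNCall, gene: GeneModel
) -> tuple[float, float]:
    """Share of pause-region polymerase in the early vs late window.

    Areas under the 3'-end curve over +1..+30 and +31..+60 from the TSN,
    each divided by the +1..+60 sum; (0, 0) when the region is empty.
    """
    if not tsn.called:
        raise ValueError("TSN must be called to compute pause fractions")
    profile = offset_profile(three_prime, gene, tsn.tsn, 0, 59)  # 0-based +1..+60
    early = float(profile[:30].sum())
    late = float(profile[30:].sum())
    total = early + late
    if total <= 0:
        return 0.0, 0.0
    return early / total, late / total


def detect_clear_pause(
    three_prime: EndTrack,
    tsn: TSNCall,
    gene: GeneModel,
    min_count: float = 5.0,
    enrichment: float = 3.0,
) -> bool:
    """Heuristic flag for a well-defined promoter-proximal pause.

    True when the maximal 3'-end count in +1..+60 reaches ``min_count``
    and exceeds ``enrichment`` times the median per-nt 3'-end count of
    the +201..+400 background window.
    """
    if not tsn.called:
        raise ValueError("TSN must be called to assess the pause")
    pause_region = offset_profile(three_prime, gene, tsn.tsn, 0, 59)
    background = offset_profile(three_prime, gene, tsn.tsn, 200, 399)
    peak = float(pause_region.max()) if len(pause_region) else 0.0
    bg = float(np.median(background)) if len(background) else 0.0
    return peak >= min_count and peak >= enrichment * bg


def tss_offset_stats(
    calls: list[TSNCall], window: tuple[int, int] = TSN_WINDOW
) -> tuple[float, float, pd.Series]:
    """Mean/median TSN–TSS offset and a 1-nt histogram over the window."""
    offsets = np.array([c.offset for c in calls if c.called], dtype=float)
    if len(offsets) == 0:
        raise ValueError("no called TSNs")
    edges = np.arange(window[0], window[1] + 2)
    hist, _ = np.histogram(offsets, bins=edges)
    series = pd.Series(hist, index=pd.Index(edges[:-1], name="offset"), name="n_genes")
    return float(offsets.mean()), float(np.median(offsets)), series


def call_sites_for_genes(
    five_prime: EndTrack,
    three_prime: EndTrack,
    genes: list[GeneModel],
    window: tuple[int, int] = TSN_WINDOW,
    representative_tsn: dict[str, TSNCall] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TSN and pause tables for a gene set.

    When ``representative_tsn`` is given (typically calls from the
    unphosphorylated-CTD, unstressed sample), those TSNs anchor the
    pause calls instead of per-sample TSNs — one +1 nt per gene across
    all antibodies and conditions.
    """
    tsn_rows, pause_rows = [], []
    for gene in genes:
        tsn = (
            representative_tsn.get(gene.gene_id)
            if representative_tsn is not None
            else None
        ) or call_tsn(five_prime, gene, window)
        tsn_rows.append(
            dict(
                gene=gene.gene_id, chrom=gene.chrom, strand=gene.strand,
                tss=gene.tss, called=tsn.called,
                tsn=tsn.tsn if tsn.called else -1,
                offset=tsn.offset if tsn.called else 0,
                count=tsn.count,
            )
        )
        if tsn.called:
            p = call_pause(three_prime, tsn, gene, window)
            pause_rows.append(
                dict(
                    gene=gene.gene_id, called=p.called,
                    pause=p.pause if p.called else -1,
                    distance=p.distance if p.called else 0,
                    pause_class=p.pause_class, count=p.count,
                    fraction_early=p.fraction_early, fraction_late=p.fraction_late,
                )
            )
        else:
            pause_rows.append(
                dict(
                    gene=gene.gene_id, called=False, pause=-1, distance=0,
                    pause_class="none", count=0.0,
                    fraction_early=0.0, fraction_late=0.0,
                )
            )
    return pd.DataFrame(tsn_rows), pd.DataFrame(pause_rows)


def pause_distance_histogram(
    pause_table: pd.DataFrame, lo: int = -100, hi: int = 400
) -> pd.Series:
    """Histogram of pause distances from the TSN (1-based, no zero)."""
    dist = pause_table.loc[pause_table["called"], "distance"].to_numpy()
    index = [d for d in range(lo, hi + 1) if d != 0]
    counts = pd.Series(0, index=pd.Index(index, name="distance"), name="n_genes")
    values, n = np.unique(dist, return_counts=True)
    for v, c in zip(values.tolist(), n.tolist()):
        if v in counts.index:
            counts.loc[v] = c
    return counts
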