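"""Phospho/unphospho ratio tracks, metagene composites, and gene activity.

Ratio tracks compare the density of engaged polymerase carrying a given
CTD phosphorylation against the unphosphorylated form at every
nucleotide, on log2 scale so equality centers at 0. Composite
(metagene) profiles aggregate anchored per-gene signal — promoter
windows linear around the TSN, gene bodies scaled to 50 bins, and
termination windows linear around the CPS — reporting the per-bin mean
with a 12.5–87.5% interval across genes. Transcriptional activity is
measured as gbRPK: normalized 3'-end counts in the gene body per kb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel
from .tracks import EndTrack
from .tsn_pause import _clipped_window

ANTIBODY_SET = ("unPh", "Ser2Ph", "Ser5Ph", "Ser7Ph")


@dataclass
class RatioTrack:
    """Per-nucleotide log2 ratio of two normalized tracks.

    Same sparse layout as :class:`EndTrack` but values may be negative;
    positions covered by neither input are implicitly 0 (equal
    pseudocounts on both sides).
    """

    data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    pseudocount: float
    numerator: str = ""
    denominator: str = ""
    chrom_sizes: dict[str, int] | None = None

    def arrays(self, chrom: str, strand: str):
        return self.data.get((chrom, strand), (np.empty(0, dtype=np.int64), np.empty(0)))

    def window_counts(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        if end <= start:
            return np.zeros(0)
        pos, val = self.arrays(chrom, strand)
        out = np.zeros(end - start)
        lo, hi = np.searchsorted(pos, [start, end])
        out[pos[lo:hi] - start] = val[lo:hi]
        return out


def log2_ratio_track(
    numerator: EndTrack,
    denominator: EndTrack,
    pseudocount: float = 0.5,
) -> RatioTrack:
    """log2((num + p) / (den + p)) at every position covered by either track.

    A symmetric pseudocount ``p`` keeps the ratio defined at positions
    where one side is empty and preserves the centering property: equal
    inputs give exactly 0 everywhere, including (0, 0).
    """
    if numerator.genome != denominator.genome:
        raise ValueError("ratio tracks require matching genomes")
    if numerator.end_kind != denominator.end_kind:
        raise ValueError("ratio tracks require matching end kinds")
    data = {}
    for key in sorted(set(numerator.data) | set(denominator.data)):
        npos, nval = numerator.arrays(*key)
        dpos, dval = denominator.arrays(*key)
        pos = np.union1d(npos, dpos)
        num = np.zeros(len(pos))
        num[np.searchsorted(pos, npos)] = nval
        den = np.zeros(len(pos))
        den[np.searchsorted(pos, dpos)] = dval
        data[key] = (pos, np.log2((num + pseudocount) / (den + pseudocount)))
    return RatioTrack(
        data=data, pseudocount=pseudocount,
        numerator=str(numerator.metadata.get("sample", "")),
        denominator=str(denominator.metadata.get("sample", "")),
        chrom_sizes=numerator.chrom_sizes,
    )


@dataclass
class CompositeProfile:
    """Anchored per-gene signal matrix with per-bin mean and spread band."""

    anchor: str  # "tsn" | "body" | "cps"
    bin_width: int | str  # nt, or "scaled50" for gene-body mode
    offsets: np.ndarray  # bin start offsets (anchor-relative) or bin index
    matrix: np.ndarray  # n_genes x n_bins
    gene_ids: list[str]
    bin_widths: np.ndarray | None = None  # per-gene widths, gene-body mode only
    q_band: tuple[float, float] = (0.125, 0.875)
    _stats: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def q_lo(self) -> np.ndarray:
        return np.quantile(self.matrix, self.q_band[0], axis=0)

    @property
    def q_hi(self) -> np.ndarray:
        return np.quantile(self.matrix, self.q_band[1], axis=0)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean": self.mean,
                "q12.5": self.q_lo,
                "q87.5": self.q_hi,
            }
        )

    def gene_mass(self, i: int) -> float:
        """Total signal of gene ``i`` reconstructed from its bins."""
        widths = self.bin_widths[i] if self.bin_widths is not None else np.full(
            self.matrix.shape[1], self.bin_width
        )
        return float((self.matrix[i] * widths).sum())


def _gene_anchor(gene: GeneModel, anchor: str) -> int:
    if anchor == "tsn":
        if gene.tsn is None:
            raise ValueError(f"gene {gene.gene_id}: TSN required for TSN-anchored profile")
        return gene.tsn
    if anchor == "cps":
        return gene.cps
    raise ValueError(f"unknown anchor {anchor!r}")


def _extract(source, gene: GeneModel, read_strand: str, anchor: int, lo: int, hi: int) -> np.ndarray:
    """Anchored window oriented downstream-rightward regardless of gene strand."""
    n = hi - lo + 1
    if gene.strand == "+":
        return _clipped_window(source, gene.chrom, read_strand, anchor + lo, anchor + hi + 1, n)
    return _clipped_window(source, gene.chrom, read_strand, anchor - hi, anchor - lo + 1, n)[::-1]


def _read_strand(gene: GeneModel, signal: str) -> str:
    if signal == "sense":
        return gene.strand
    if signal == "antisense":
        return "-" if gene.strand == "+" else "+"
    raise ValueError(f"signal must be 'sense' or 'antisense', got {signal!r}")


def composite_profile(
    source,
    genes: list[GeneModel],
    anchor: str = "tsn",
    window: tuple[int, int] = (-1000, 1000),
    bin_width: int = 1,
    signal: str = "sense",
) -> CompositeProfile:
    """Build a composite (metagene) profile from a count or ratio track.

    ``anchor`` selects the mode: ``"tsn"`` and ``"cps"`` extract a
    linear window (offsets ``window[0]`` inclusive to ``window[1]``
    exclusive, averaged into ``bin_width``-nt bins); ``"body"`` scales
    each gene's TSN→CPS span into 50 equal bins (per-nt mean per bin),
    excluding genes shorter than 50 nt with a warning. Minus-strand
    genes are coordinate-reversed so downstream is rightward; sense and
    antisense signal are profiled separately via ``signal``.
    """
    if anchor == "body":
        return _body_profile(source, genes, signal)
    lo, hi = window
    length = hi - lo
    if length <= 0 or length % bin_width != 0:
        raise ValueError(f"window span {length} must be a positive multiple of bin_width={bin_width}")
    rows, ids = [], []
    for gene in genes:
        a = _gene_anchor(gene, anchor)
        vals = _extract(source, gene, _read_strand(gene, signal), a, lo, hi - 1)
        rows.append(vals.reshape(-1, bin_width).mean(axis=1))
        ids.append(gene.gene_id)
    matrix = np.vstack(rows) if rows else np.zeros((0, length // bin_width))
    return CompositeProfile(
        anchor=anchor, bin_width=bin_width,
        offsets=np.arange(lo, hi, bin_width), matrix=matrix, gene_ids=ids,
    )


N_BODY_BINS = 50


def _body_profile(source, genes: list[GeneModel], signal: str) -> CompositeProfile:
    rows, ids, widths = [], [], []
    for gene in genes:
        if gene.tsn is None:
            raise ValueError(f"gene {gene.gene_id}: TSN required for gene-body profile")
        body_len = gene.pos_to_offset(gene.tsn, gene.cps) + 1
        if body_len < N_BODY_BINS:
            warnings.warn(f"gene {gene.gene_id}: body shorter than {N_BODY_BINS} nt, excluded")
            continue
        vals = _extract(source, gene, _read_strand(gene, signal), gene.tsn, 0, body_len - 1)
        edges = np.round(np.linspace(0, body_len, N_BODY_BINS + 1)).astype(int)
        w = np.diff(edges)
        sums = np.add.reduceat(vals, edges[:-1])
        rows.append(sums / w)
        widths.append(w)
        ids.append(gene.gene_id)
    matrix = np.vstack(rows) if rows else np.zeros((0, N_BODY_BINS))
    return CompositeProfile(
        anchor="body", bin_width="scaled50",
        offsets=np.arange(N_BODY_BINS), matrix=matrix, gene_ids=ids,
        bin_widths=np.vstack(widths) if widths else None,
    )


def crossing_point(
    ratio_a: np.ndarray,
    ratio_b: np.ndarray,
    search_range: tuple[int, int] | None = None,
    k: int = 5,
) -> int | None:
    """First sustained crossing of per-bin profile A above profile B.

    Returns the first bin index in ``search_range`` (half-open, default
    the whole profile) where A−B turns from ≤0 to >0 and stays positive
    for at least ``k`` consecutive bins (or through the end of the
    range); ``None`` if A never sustainably exceeds B. This locates,
    e.g., where one CTD phosphorylation overtakes another along a
    metagene profile.
    """
    a = np.asarray(ratio_a, dtype=float)
    b = np.asarray(ratio_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share binning")
    lo, hi = search_range if search_range is not None else (0, len(a))
    d = a - b
    for i in range(lo, hi):
        if d[i] <= 0:
            continue
        if i > lo and d[i - 1] > 0:
            continue  # not the start of a positive run
        run_end = min(i + k, hi)
        if np.all(d[i:run_end] > 0):
            return i
    return None


def gbRPK(
    three_prime,
    gene: GeneModel,
    body_start_offset: int = 500,
    body: tuple[int, int] | None = None,
) -> float:
    """Gene-body polymerase density: body counts per kb of body length.

    The gene body runs from ``body_start_offset`` nt downstream of the
    TSN (excluding the promoter-proximal region, where paused
    polymerase would mask elongation) to the CPS; ``body`` overrides it
    with explicit strand-aware offsets from the TSN. The returned value
    is (Σ 3'-end counts in body) / body_length × 1000.
    """
    anchor = gene.tsn if gene.tsn is not None else gene.tss
    if body is None:
        end_off = gene.pos_to_offset(anchor, gene.cps)
        body = (body_start_offset, end_off)
    start_off, end_off = body
    length = end_off - start_off + 1
    if length <= 0:
        raise ValueError(
            f"gene {gene.gene_id}: empty gene body (offsets {start_off}..{end_off})"
        )
    vals = _extract(three_prime, gene, gene.strand, anchor, start_off, end_off)
    return float(vals.sum()) / length * 1000.0


def sum_antibody_activity(gbrpk_by_antibody: dict[str, float]) -> float:
    """Summed-antibody activity: unPh + Ser2Ph + Ser5Ph + Ser7Ph gbRPK."""
    missing = [ab for ab in ANTIBODY_SET if ab not in gbrpk_by_antibody]
    if missing:
        raise ValueError(f"missing antibodies for summed activity: {missing}")
    return float(sum(gbrpk_by_antibody[ab] for ab in ANTIBODY_SET))


def group_by_activity(
    records: pd.DataFrame,
    n_groups: int = 4,
    value_col: str = "sum_gbRPK",
    id_col: str = "gene",
) -> pd.DataFrame:
    """Quantile-partition genes into activity groups (1 = least active).

    Ties are broken deterministically by gene id, so equal-activity
    genes always land in the same groups across runs.
    """
    if len(records) < n_groups:
        raise ValueError(f"need at least {n_groups} genes to form {n_groups} groups")
    out = records.sort_values([value_col, id_col], kind="stable").reset_index(drop=True)
    labels = np.empty(len(out), dtype=int)
    for g, chunk in enumerate(np.array_split(np.arange(len(out)), n_groups), start=1):
        labels[chunk] = g
    out["activity_group"] = labels
    return out.sort_values(id_col, kind="stable").reset_index(drop=True)


def classify_hs_response(
    gbrpk_reference: float,
    gbrpk_treated: float,
    up_fc: float = 2.0,
    down_fc: float = 0.5,
    min_activity: float = 1.0,
) -> str:
    """Classify a gene's heat-shock response from gene-body densities.

    ``activated`` when treated/reference ≥ ``up_fc`` and the treated
    density clears ``min_activity``; ``repressed`` when the ratio drops
    to ``down_fc`` or below with an active reference; otherwise
    ``unchanged``. A silent reference with an active treated sample
    counts as activated.
    """
    if not up_fc > 1 or not 0 < down_fc < 1:
        raise ValueError("thresholds must satisfy up_fc > 1 and 0 < down_fc < 1")
    if gbrpk_reference <= 0:
        return "activated" if gbrpk_treated >= min_activity else "unchanged"
    ratio = gbrpk_treated / gbrpk_reference
    if ratio >= up_fc and gbrpk_treated >= min_activity:
        return "activated"
    if ratio <= down_fc and gbrpk_reference >= min_activity:
        return "repressed"
    return "unchanged"
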