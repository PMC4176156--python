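"""Start-codon-aligned metagene occupancy profiles.

The profile follows the classic recipe for visualizing the 5' ribosome
accumulation: take well-expressed single-exon genes longer than 1000 nt
(rpkm > 30), align them at the first nucleotide of the start codon, average
nucleotide-level coverage over genes across a window of 50 nt upstream plus
1000 nt of reading frame, and divide by the mean over the window's last
300 positions so that an unperturbed profile plateaus at 1.0.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import FootprintAlignment, Transcript, TranscriptSet

logger = logging.getLogger(__name__)

WINDOW_UP = 50
WINDOW_DOWN = 1000
TAIL = 300


@dataclass(frozen=True)
class CoverageVector:
    """Per-nucleotide read coverage of one transcript."""

    transcript_id: str
    counts: np.ndarray


@dataclass(frozen=True)
class GeneExpression:
    transcript_id: str
    read_count: int
    rpkm: float


@dataclass(frozen=True)
class MetageneProfile:
    """Mean and tail-normalized coverage over start-relative positions."""

    positions: np.ndarray  # −window_up .. window_down−1
    mean_coverage: np.ndarray  # reads/nt, averaged over genes
    normalized: np.ndarray  # mean_coverage / tail_mean
    n_genes: int
    tail_mean: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean_coverage": self.mean_coverage,
                "normalized": self.normalized,
                "n_genes": self.n_genes,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def coverage(
    tx: Transcript,
    alignments: Iterable[FootprintAlignment],
    mode: str = "full",
) -> CoverageVector:
    """Nucleotide coverage of one transcript.

    ``full`` increments every covered nucleotide (smooth profiles); ``end5``
    and ``end3`` increment only the footprint's 5'-most or 3'-most
    nucleotide.
    """
    if mode not in ("full", "end5", "end3"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    counts = np.zeros(tx.length + 1, dtype=np.int64)  # +1 slot for the diff trick
    for aln in alignments:
        if aln.transcript_id != tx.id:
            raise ValueError(f"alignment on {aln.transcript_id} passed with {tx.id}")
        if aln.start < 0 or aln.end > tx.length:
            raise ValueError(
                f"{tx.id}: alignment [{aln.start},{aln.end}) out of bounds"
            )
        if mode == "full":
            counts[aln.start] += 1
            counts[aln.end] -= 1
        elif mode == "end5":
            counts[aln.start] += 1
        else:
            counts[aln.end - 1] += 1
    if mode == "full":
        counts = np.cumsum(counts)
    return CoverageVector(tx.id, counts[: tx.length])


def coverage_map(
    txs: TranscriptSet,
    alignments: Iterable[FootprintAlignment],
    mode: str = "full",
    read_class: str | None = "footprint",
) -> dict[str, CoverageVector]:
    """Coverage for every annotated transcript (reads grouped by reference)."""
    grouped: dict[str, list[FootprintAlignment]] = {tid: [] for tid in txs}
    for aln in alignments:
        if read_class is not None and aln.read_class != read_class:
            continue
        if aln.transcript_id in grouped:
            grouped[aln.transcript_id].append(aln)
    return {tid: coverage(txs[tid], alns, mode) for tid, alns in grouped.items()}


def expression_table(
    txs: TranscriptSet, alignments: Sequence[FootprintAlignment]
) -> list[GeneExpression]:
    """Per-gene read counts and rpkm.

    A read belongs to a gene when its 5' end lies within the transcript; the
    per-million denominator counts footprint-class reads only, and the
    kilobase denominator is the transcript length.
    """
    footprints = [a for a in alignments if a.read_class == "footprint"]
    total = len(footprints)
    if total == 0:
        raise ValueError("no footprint-class alignments; cannot compute expression")
    counts = {tid: 0 for tid in txs}
    for aln in footprints:
        tx = txs.get(aln.transcript_id)
        if tx is not None and 0 <= aln.start < tx.length:
            counts[aln.transcript_id] += 1
    millions = total / 1e6
    return [
        GeneExpression(
            transcript_id=tid,
            read_count=counts[tid],
            rpkm=counts[tid] / (txs[tid].length / 1000.0) / millions,
        )
        for tid in txs.sorted_ids()
    ]


def select_genes(
    txs: TranscriptSet,
    expr: Iterable[GeneExpression],
    min_len: int = 1000,
    min_rpkm: float = 30.0,
    require_single_exon: bool = True,
) -> list[str]:
    """Gene filter for the metagene: single-exon, length and rpkm strictly
    above their thresholds.  Returns ids in lexicographic order."""
    rpkm = {e.transcript_id: e.rpkm for e in expr}
    kept = []
    for tid in txs.sorted_ids():
        tx = txs[tid]
        if require_single_exon and tx.exon_count != 1:
            continue
        if tx.length <= min_len:
            continue
        if rpkm.get(tid, 0.0) <= min_rpkm:
            continue
        kept.append(tid)
    return kept


def metagene_profile(
    txs: TranscriptSet,
    selected_ids: Sequence[str],
    coverages: Mapping[str, CoverageVector],
    window_up: int = WINDOW_UP,
    window_down: int = WINDOW_DOWN,
    tail: int = TAIL,
) -> MetageneProfile:
    """Average coverage over genes aligned at the start codon and normalize.

    Position ``p`` in [-window_up, window_down) maps to nucleotide
    ``cds_start + p`` of each gene.  Genes whose 5'UTR is shorter than the
    upstream window or whose CDS is shorter than the downstream window are
    dropped (counted in the log), not padded.  The tail mean is taken over
    the last ``tail`` positions *of the window*.
    """
    if not selected_ids:
        raise ValueError("no genes selected for the metagene profile")
    rows = []
    dropped = 0
    for tid in selected_ids:
        tx = txs[tid]
        if tx.cds_start < window_up or tx.cds_length < window_down:
            dropped += 1
            continue
        cov = coverages[tid].counts
        rows.append(cov[tx.cds_start - window_up : tx.cds_start + window_down])
    if dropped:
        logger.warning(
            "metagene: dropped %d/%d genes incompatible with the -%d..+%d window",
            dropped,
            len(selected_ids),
            window_up,
            window_down,
        )
    if not rows:
        raise ValueError("no selected gene is compatible with the metagene window")
    mean_cov = np.vstack(rows).mean(axis=0)
    tail_mean = float(mean_cov[window_up + window_down - tail :].mean())
    if tail_mean == 0.0:
        raise ValueError("tail coverage is zero; profile cannot be normalized")
    return MetageneProfile(
        positions=np.arange(-window_up, window_down),
        mean_coverage=mean_cov,
        normalized=mean_cov / tail_mean,
        n_genes=len(rows),
        tail_mean=tail_mean,
    )


def peak_area(
    profile: MetageneProfile, region: tuple[int, int] = (0, 300)
) -> float:
    """Area of the normalized profile above the 1.0 plateau within ``region``
    (start-relative positions, half-open).  Zero for a flat profile."""
    lo, hi = region
    mask = (profile.positions >= lo) & (profile.positions < hi)
    excess = np.clip(profile.normalized[mask] - 1.0, 0.0, None)
    return float(excess.sum())
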