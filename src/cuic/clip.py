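"""CLIP-cluster specificity scoring for the CUIC region.

Given CLIP-seq binding clusters (transcript-space intervals, one RNA-binding
protein per record) and the CUIC hit of each RP-coding transcript, the
specificity score of an RBP is the number of its clusters on RP transcripts
that overlap the CUIC region, divided by its total number of clusters on
those transcripts.  RBPs are then ranked by score; in the original analysis
eIF3 components and TIA1/TIAL1 rank at the top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import InputError, UndefinedResultError
from .motif import MotifHit

logger = logging.getLogger(__name__)

Interval = tuple[int, int]  # 0-based half-open [a, b)


@dataclass(frozen=True)
class ClipCluster:
    """One CLIP interval on a transcript for one RBP."""

    rbp: str
    transcript_id: str
    start: int
    end: int
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(
                f"cluster start must be < end, got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class SpecificityScore:
    rbp: str
    n_overlap_cuic: int
    n_total: int

    @property
    def score(self) -> float:
        return self.n_overlap_cuic / self.n_total


def overlaps(c: ClipCluster, region: Interval) -> bool:
    """Half-open interval overlap on the same transcript."""
    a, b = region
    return c.start < b and a < c.end


def cuic_region(
    hit: MotifHit, flank: int = 10, seq_length: Optional[int] = None
) -> Interval:
    """Motif footprint extended by ``flank`` nt each side, clipped to the UTR.

    The UTR length defaults to ``hit.end + hit.dist_to_start_codon`` (the
    distance convention makes it recoverable from the hit itself).
    """
    L = seq_length if seq_length is not None else hit.end + hit.dist_to_start_codon
    return max(0, hit.start - flank), min(L, hit.end + flank)


def specificity_score(
    clusters: Iterable[ClipCluster],
    regions: Mapping[str, Interval],
    rp_transcripts: set[str],
) -> SpecificityScore:
    """Score one RBP's CUIC-region specificity.

    ``clusters`` must all belong to a single RBP.  Duplicate records
    (same rbp/transcript/interval/dataset) are counted once.  The
    denominator is every cluster on an RP transcript; the numerator is
    those that additionally overlap that transcript's CUIC region.
    """
    uniq = set(clusters)
    rbps = {c.rbp for c in uniq}
    if len(rbps) > 1:
        raise InputError(f"clusters span multiple RBPs: {sorted(rbps)}")
    on_rp = [c for c in uniq if c.transcript_id in rp_transcripts]
    if not on_rp:
        raise UndefinedResultError(
            f"RBP {next(iter(rbps), '?')}: no clusters on RP transcripts"
        )
    n_hit = sum(
        1
        for c in on_rp
        if c.transcript_id in regions and overlaps(c, regions[c.transcript_id])
    )
    return SpecificityScore(
        rbp=next(iter(rbps)), n_overlap_cuic=n_hit, n_total=len(on_rp)
    )


def score_all_rbps(
    clusters: Iterable[ClipCluster],
    regions: Mapping[str, Interval],
    rp_transcripts: set[str],
    min_total: int = 5,
) -> list[SpecificityScore]:
    """Group clusters by RBP and score each; RBPs with fewer than
    ``min_total`` clusters on RP transcripts are excluded with a warning."""
    by_rbp: dict[str, list[ClipCluster]] = {}
    for c in clusters:
        by_rbp.setdefault(c.rbp, []).append(c)
    scores = []
    for rbp in sorted(by_rbp):
        try:
            s = specificity_score(by_rbp[rbp], regions, rp_transcripts)
        except UndefinedResultError:
            logger.warning("RBP %s has no clusters on RP transcripts; excluded", rbp)
            continue
        if s.n_total < min_total:
            logger.warning(
                "RBP %s has only %d clusters on RP transcripts (< %d); excluded",
                rbp, s.n_total, min_total,
            )
            continue
        scores.append(s)
    return scores


def rank_rbps(scores: Sequence[SpecificityScore]) -> pd.DataFrame:
    """Rank RBPs by descending score; ties by larger n_total, then name."""
    if not scores:
        raise UndefinedResultError("no specificity scores to rank")
    df = pd.DataFrame(
        {
            "rbp": [s.rbp for s in scores],
            "n_overlap_cuic": [s.n_overlap_cuic for s in scores],
            "n_total": [s.n_total for s in scores],
            "score": [s.score for s in scores],
        }
    )
    df = df.sort_values(
        ["score", "n_total", "rbp"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    return df


# ---------------------------------------------------------------------------
# BED6 I/O (transcript coordinates: chrom = transcript_id, name = RBP)
# ---------------------------------------------------------------------------

_BED_COLS = ["transcript_id", "start", "end", "rbp", "score", "strand"]


def read_clip_bed(path) -> list[ClipCluster]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 6:
        raise InputError(f"{path}: expected BED6(+1), found {df.shape[1]} columns")
    df = df.iloc[:, :7] if df.shape[1] >= 7 else df.assign(dataset_id="")
    df.columns = _BED_COLS + ["dataset_id"]
    df["dataset_id"] = df["dataset_id"].fillna("").astype(str)
    return [
        ClipCluster(
            rbp=str(r.rbp),
            transcript_id=str(r.transcript_id),
            start=int(r.start),
            end=int(r.end),
            dataset_id=str(r.dataset_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_clip_bed(clusters: Iterable[ClipCluster], path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(
                f"{c.transcript_id}\t{c.start}\t{c.end}\t{c.rbp}\t0\t+\t{c.dataset_id}\n"
            )
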