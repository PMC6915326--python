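"""Scanning 5' UTRs for the CUIC consensus and positional classification.

The CUIC element ("cis-element upstream of the initiation codon") is a
degenerate pyrimidine 8-mer, consensus YYYYTTYC, found in the 5' UTR of most
ribosomal-protein (RP) coding mRNAs within 100 nt of the start codon.  This
module scans transcript 5' UTR sequences for the consensus, classifies
transcripts as CUIC-positive, summarises motif-to-start-codon distances,
relates observed transcript 5' ends to the motif position (alternative
5'-end / truncated-isoform analysis) and applies a 5' TOP-like sequence rule.

Coordinates are 0-based half-open on the UTR; position ``L`` (the UTR
length) is the A of the AUG, so a motif with ``end == L`` has
``dist_to_start_codon == 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import prod
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

from .errors import ConfigError, InputError, UndefinedResultError

logger = logging.getLogger(__name__)

#: Default CUIC consensus: (T/C)(T/C)(T/C)(T/C)TT(T/C)C.
CUIC_CONSENSUS = "YYYYTTYC"

#: Xenopus laevis Rps4x.S 5' UTR (72 nt) as transcribed in embryos
#: (RefSeq NM_001097003.1 locus; 5' end from embryo RNA-seq).  Carries two
#: CUIC instances, TCTCTTCC and TCTTTTCC, the second abutting the AUG.
RPS4X_S_UTR5 = (
    "CGCGCTCTCTTCCTGCCAGAGTTCAGCGCGCACTCTTTATCCCGGCGGGACCGGAAGGAGGAGGTCTTTTCC"
)

_VALID_NUCLEOTIDES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    """One consensus match on a transcript 5' UTR.

    ``dist_to_start_codon`` is measured from the motif's 3' end to the first
    nucleotide of the initiation codon (0 = motif abuts the AUG).
    """

    transcript_id: str
    start: int
    end: int
    matched_seq: str
    dist_to_start_codon: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(f"invalid hit interval [{self.start}, {self.end})")
        if self.dist_to_start_codon < 0:
            raise InputError("dist_to_start_codon must be non-negative")


@dataclass
class TranscriptRecord:
    """A transcript's 5' UTR with its annotation and per-sample abundance."""

    transcript_id: str
    gene_symbol: str = ""
    is_rp: bool = False
    utr5_seq: str = ""
    species: str = ""
    abundance: dict[str, float] = field(default_factory=dict)

    @property
    def utr_length(self) -> int:
        return len(self.utr5_seq)


@dataclass(frozen=True)
class FivePrimeEndObservation:
    """An observed transcript 5' terminal on the reference UTR coordinate."""

    transcript_id: str
    sample_label: str
    end_pos: int


# ---------------------------------------------------------------------------
# IUPAC consensus handling
# ---------------------------------------------------------------------------

def _iupac_sets(consensus: str) -> list[frozenset[str]]:
    """Expand an IUPAC consensus into one allowed-base set per position."""
    if not consensus:
        raise ConfigError("consensus must be a non-empty IUPAC string")
    sets = []
    for i, code in enumerate(consensus.upper().replace("U", "T")):
        if code not in "ACGTRYSWKMBDHVN":
            raise ConfigError(
                f"invalid IUPAC code {code!r} at consensus position {i}"
            )
        sets.append(frozenset(ambiguous_dna_values[code]))
    return sets


def normalize_sequence(seq: str, *, what: str = "sequence") -> str:
    """Uppercase, strip whitespace and map U->T; reject non-nucleotide chars."""
    clean = "".join(seq.split()).upper().replace("U", "T")
    for i, ch in enumerate(clean):
        if ch not in _VALID_NUCLEOTIDES:
            raise InputError(f"invalid nucleotide {ch!r} at {what} position {i}")
    return clean


def count_consensus_words(consensus: str) -> int:
    """Number of distinct DNA words matching an IUPAC consensus.

    The count is the product of per-position degeneracies; e.g. YYYYTTYC has
    2**5 = 32 matching 8-mers and "NN" has 16 matching dimers.
    """
    return prod(len(s) for s in _iupac_sets(consensus))


# ---------------------------------------------------------------------------
# Scanning and classification
# ---------------------------------------------------------------------------

def scan_cuic(
    utr5_seq: str,
    consensus: str = CUIC_CONSENSUS,
    *,
    transcript_id: str = "",
) -> list[MotifHit]:
    """Find every (possibly overlapping) consensus match in a 5' UTR.

    Matching is case-insensitive and U/T-insensitive.  Hits are returned in
    5'->3' order with ``dist_to_start_codon`` filled from the UTR length.
    """
    pos_sets = _iupac_sets(consensus)
    seq = normalize_sequence(utr5_seq)
    k, L = len(pos_sets), len(seq)
    hits: list[MotifHit] = []
    for start in range(L - k + 1):
        window = seq[start : start + k]
        if all(ch in s for ch, s in zip(window, pos_sets)):
            hits.append(
                MotifHit(
                    transcript_id=transcript_id,
                    start=start,
                    end=start + k,
                    matched_seq=window,
                    dist_to_start_codon=L - (start + k),
                )
            )
    return hits


def best_hit(hits: Sequence[MotifHit]) -> Optional[MotifHit]:
    """Hit closest to the AUG; ties broken toward the 3'-most start."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.dist_to_start_codon, -h.start))


def classify_cuic_gene(
    t: TranscriptRecord,
    max_dist: int = 100,
    consensus: str = CUIC_CONSENSUS,
) -> tuple[bool, Optional[MotifHit]]:
    """Is the transcript CUIC-positive (a hit strictly < ``max_dist`` nt
    upstream of the AUG)?  Returns the flag and the best hit (or None)."""
    hits = scan_cuic(t.utr5_seq, consensus, transcript_id=t.transcript_id)
    near = [h for h in hits if h.dist_to_start_codon < max_dist]
    if not near:
        return False, None
    return True, best_hit(near)


def distance_band_fraction(
    hits: Iterable[MotifHit], lo: int = 20, hi: int = 80
) -> float:
    """Fraction of best hits whose distance to the AUG lies in [lo, hi]."""
    dists = [h.dist_to_start_codon for h in hits]
    if not dists:
        raise UndefinedResultError("no hits: band fraction undefined")
    return sum(lo <= d <= hi for d in dists) / len(dists)


def relative_end_offsets(
    obs: Iterable[FivePrimeEndObservation],
    hits_by_transcript: Mapping[str, MotifHit],
) -> tuple[list[int], int]:
    """Signed offset of each observed 5' end relative to the motif start.

    Negative offsets place the 5' terminal upstream of the motif; 0 means
    the transcript starts exactly at the motif.  Observations on transcripts
    without a CUIC hit are skipped; the skip count is returned and logged.
    """
    offsets: list[int] = []
    n_skipped = 0
    for o in obs:
        hit = hits_by_transcript.get(o.transcript_id)
        if hit is None:
            n_skipped += 1
            continue
        offsets.append(o.end_pos - hit.start)
    if n_skipped:
        logger.warning(
            "skipped %d 5'-end observations on transcripts without a CUIC hit",
            n_skipped,
        )
    return offsets, n_skipped


def classify_truncated_isoform(offset: int, tol: int = 10) -> bool:
    """True if a 5' end lies within ``tol`` nt of the motif start
    (the truncated, TOP-like-generating isoform)."""
    return abs(offset) <= tol


def is_top_like(seq_from_5prime: str, min_py_run: int = 5) -> bool:
    """5' TOP-like rule: a cap-adjacent C followed by pyrimidines.

    True iff the first base is C and the first ``min_py_run`` bases are all
    pyrimidines (C/T/U).
    """
    seq = normalize_sequence(seq_from_5prime)
    if len(seq) < min_py_run:
        raise InputError(
            f"sequence length {len(seq)} shorter than min_py_run={min_py_run}"
        )
    head = seq[:min_py_run]
    return head[0] == "C" and all(ch in "CT" for ch in head)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_transcripts(fasta_path, annot_path=None) -> list[TranscriptRecord]:
    """Load UTR sequences from FASTA, optionally joined with an annotation TSV
    (columns: transcript_id, gene_symbol, is_rp; extra columns ignored)."""
    annot: dict[str, dict] = {}
    if annot_path is not None:
        df = pd.read_csv(annot_path, sep="\t", dtype={"transcript_id": str})
        annot = df.set_index("transcript_id").to_dict("index")
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = annot.get(rec.id, {})
        records.append(
            TranscriptRecord(
                transcript_id=rec.id,
                gene_symbol=str(row.get("gene_symbol", "")),
                is_rp=bool(int(row.get("is_rp", 0))),
                utr5_seq=normalize_sequence(str(rec.seq), what=f"{rec.id} sequence"),
                species=str(row.get("species", "")),
            )
        )
    return records


def read_five_prime_ends(path) -> list[FivePrimeEndObservation]:
    """TSV with columns transcript_id, sample_label, end_pos."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    return [
        FivePrimeEndObservation(r.transcript_id, r.sample_label, int(r.end_pos))
        for r in df.itertuples(index=False)
    ]


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": h.transcript_id,
                "start": h.start,
                "end": h.end,
                "matched_seq": h.matched_seq,
                "dist_to_start_codon": h.dist_to_start_codon,
            }
            for h in hits
        ],
        columns=["transcript_id", "start", "end", "matched_seq", "dist_to_start_codon"],
    )


def hits_from_frame(df: pd.DataFrame) -> list[MotifHit]:
    return [
        MotifHit(
            transcript_id=str(r.transcript_id),
            start=int(r.start),
            end=int(r.end),
            matched_seq=str(r.matched_seq),
            dist_to_start_codon=int(r.dist_to_start_codon),
        )
        for r in df.itertuples(index=False)
    ]
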