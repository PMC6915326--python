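"""RNA secondary-structure parsing and the motif-anchored pairing profile.

Secondary structures arrive as Vienna-style dot-bracket strings (normally
produced by an external thermodynamic folder such as RNAfold).  The profile
operation aligns every structure on its CUIC motif anchor and reports, per
offset, the mean fraction of double-stranded (paired) nucleotides, smoothed
with a centred moving average — the motif of RP mRNAs characteristically
sits in a single-stranded loop, which appears as a dip at offset 0.

``fold_maxpair`` is a deterministic maximum-base-pairing (Nussinov) folder
provided as a self-contained stand-in so the pipeline can run without an
external folder; it maximises pair count, not free energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, FormatError, InputError, UndefinedResultError
from .motif import normalize_sequence

#: Watson-Crick plus wobble pairs (on T-normalised sequences).
_CAN_PAIR = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)


@dataclass
class SecondaryStructure:
    """A dot-bracket structure with its per-nucleotide paired indicator."""

    transcript_id: str
    sequence: str
    dotbracket: str
    paired: np.ndarray  # 0/1 per nucleotide

    def __len__(self) -> int:
        return len(self.dotbracket)


@dataclass
class PairedFractionProfile:
    """Mean double-stranded fraction per offset around the motif anchor."""

    offsets: np.ndarray        # -H..+H
    mean_paired: np.ndarray    # moving-average smoothed; NaN where uncovered
    raw_mean: np.ndarray       # unsmoothed per-offset mean
    n_per_offset: np.ndarray   # transcripts covering each offset
    window: int


def parse_dotbracket(db: str, seq: str, transcript_id: str = "") -> SecondaryStructure:
    """Validate a plain ()./dot-bracket string against its sequence.

    Pseudoknot alphabets ([], {}, letters) are rejected; brackets must be
    balanced and properly nested.
    """
    if len(db) != len(seq):
        raise InputError(
            f"structure length {len(db)} != sequence length {len(seq)}"
        )
    stack: list[int] = []
    paired = np.zeros(len(db), dtype=np.int8)
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
            paired[i] = 1
        elif ch == ")":
            if not stack:
                raise FormatError(f"unbalanced ')' at position {i}")
            stack.pop()
            paired[i] = 1
        elif ch != ".":
            raise FormatError(f"invalid dot-bracket character {ch!r} at position {i}")
    if stack:
        raise FormatError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(
        transcript_id=transcript_id,
        sequence=normalize_sequence(seq),
        dotbracket=db,
        paired=paired,
    )


def fold_maxpair(seq: str, min_loop: int = 3) -> str:
    """Maximum-base-pairing fold (Nussinov recursion), deterministic.

    Allowed pairs are AU/UA, GC/CG and GU/UG with at least ``min_loop``
    unpaired nucleotides inside every hairpin.  Traceback prefers pairing
    the leftmost base with the largest admissible partner.
    """
    s = normalize_sequence(seq)
    n = len(s)
    if n == 0:
        raise InputError("empty sequence")

    def can_pair(i: int, j: int) -> bool:
        return j - i > min_loop and (s[i], s[j]) in _CAN_PAIR

    m = np.zeros((n + 1, n + 1), dtype=np.int32)  # m[i][j] over s[i..j]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    cand = 1 + m[i + 1][k - 1] + (m[k + 1][j] if k < j else 0)
                    if cand > best:
                        best = cand
            m[i][j] = best

    db = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or m[i][j] == 0:
            continue
        paired_k = None
        for k in range(j, i + min_loop, -1):  # largest admissible partner first
            if can_pair(i, k):
                cand = 1 + m[i + 1][k - 1] + (m[k + 1][j] if k < j else 0)
                if cand == m[i][j]:
                    paired_k = k
                    break
        if paired_k is None:
            stack.append((i + 1, j))
        else:
            db[i], db[paired_k] = "(", ")"
            stack.append((i + 1, paired_k - 1))
            if paired_k < j:
                stack.append((paired_k + 1, j))
    return "".join(db)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; edges average over the available neighbours
    and NaN entries are ignored (all-NaN windows stay NaN)."""
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be a positive odd integer, got {window}")
    half = window // 2
    n = len(values)
    out = np.full(n, np.nan)
    for i in range(n):
        seg = values[max(0, i - half) : min(n, i + half + 1)]
        if np.any(~np.isnan(seg)):
            out[i] = np.nanmean(seg)
    return out


def paired_fraction_profile(
    structures: Sequence[SecondaryStructure],
    anchors: Mapping[str, int],
    half_width: int = 50,
    window: int = 7,
) -> PairedFractionProfile:
    """Motif-anchored mean pairing profile.

    For each offset o in -half_width..+half_width, the paired indicator is
    averaged across the transcripts whose UTR covers position anchor+o; the
    per-offset means are then smoothed with a centred ``window``-nt moving
    average.  Transcripts missing from ``anchors`` are ignored.
    """
    if window % 2 == 0 or window < 1:
        raise ConfigError(f"window must be a positive odd integer, got {window}")
    offsets = np.arange(-half_width, half_width + 1)
    total = np.zeros(offsets.size)
    count = np.zeros(offsets.size, dtype=np.int64)
    n_used = 0
    for st in structures:
        anchor = anchors.get(st.transcript_id)
        if anchor is None:
            continue
        n_used += 1
        pos = anchor + offsets
        ok = (pos >= 0) & (pos < len(st))
        total[ok] += st.paired[pos[ok]]
        count[ok] += 1
    if n_used == 0:
        raise UndefinedResultError("no structures with a motif anchor")
    raw = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return PairedFractionProfile(
        offsets=offsets,
        mean_paired=moving_average(raw, window),
        raw_mean=raw,
        n_per_offset=count,
        window=window,
    )


# ---------------------------------------------------------------------------
# Vienna-style multi-record file I/O  (">id" / sequence / dot-bracket)
# ---------------------------------------------------------------------------

def read_vienna(path) -> list[SecondaryStructure]:
    structures = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"expected '>' header at line {i + 1} of {path}")
        if i + 2 >= len(lines):
            raise FormatError(f"truncated record at end of {path}")
        tid = lines[i][1:].split()[0]
        # RNAfold appends the energy after the structure; strip it.
        db = lines[i + 2].split()[0]
        structures.append(parse_dotbracket(db, lines[i + 1], transcript_id=tid))
        i += 3
    return structures


def write_vienna(structures: Sequence[SecondaryStructure], path) -> None:
    with open(path, "w") as fh:
        for st in structures:
            fh.write(f">{st.transcript_id}\n{st.sequence}\n{st.dotbracket}\n")
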