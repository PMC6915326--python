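"""Seeded synthetic data with known ground truth for every pipeline stage.

Each generator emulates the statistical structure of one analysis:

* ``gen_transcripts`` — 5' UTRs (100-300 nt) with a CUIC word planted in a
  configurable fraction of RP transcripts at a controlled distance from the
  AUG.  Backgrounds are purine-only by default so the pyrimidine consensus
  has zero background hit rate ("hard" mode uses uniform backgrounds).
  Planted motifs are embedded in a G/C stem so a hairpin can close over
  them.  Per-transcript FPKM is drawn for two developmental stages with an
  RP-specific stage fold-change.
* ``gen_structures`` — dot-bracket structures with the planted motif forced
  single-stranded inside a closing stem (the loop signature).
* ``gen_clip`` — CLIP clusters that overlap their transcript's CUIC region
  with a controlled per-RBP probability rho, otherwise placed entirely
  outside it.
* ``gen_toy_complex`` — a toy peptide + RNA complex with an exactly planted
  interface-residue fraction.
* ``gen_biased_abundance`` — an abundance table whose abundant/non-abundant
  membership follows a logistic function of the interface-index with effect
  size beta (beta = 0 is the null).

One global seed fans out to fixed per-generator substreams, so outputs are
fully deterministic and adding a generator does not shift existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .clip import ClipCluster, Interval
from .errors import ConfigError
from .interface import ChainStructure, Residue
from .motif import CUIC_CONSENSUS, TranscriptRecord, _iupac_sets
from .structure import SecondaryStructure, parse_dotbracket

#: Fixed substream ids: new generators append, never renumber.
_STREAMS = {
    "transcripts": 11,
    "structures": 12,
    "clip": 13,
    "complex": 14,
    "abundance": 15,
    "five_prime": 16,
    "indices": 17,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], seed])


@dataclass
class SimulationConfig:
    """Study conditions for the transcript-level generators."""

    seed: int = 0
    n_rp: int = 80
    n_nonrp: int = 400
    motif_prevalence: float = 0.7          # fraction of RP transcripts with CUIC
    dist_distribution: tuple = ("uniform", 20, 80)  # motif end -> AUG distance
    utr_len_range: tuple[int, int] = (100, 300)
    stem_len: int = 10                     # G/C stem closing over the motif
    background: str = "purine"             # or "uniform" (hard mode)
    consensus: str = CUIC_CONSENSUS
    # two-stage abundance (branching -> refinement)
    rp_stage_fold: float = 0.5
    nonrp_stage_fold: float = 1.0
    stage_noise_sd: float = 0.25
    # CLIP
    n_rbps: int = 200
    clusters_per_rbp: int = 100
    cluster_width: int = 20
    clip_rho: float = 0.3
    region_flank: int = 10

    def validate(self) -> None:
        if not 0.0 <= self.motif_prevalence <= 1.0:
            raise ConfigError("motif_prevalence must be in [0, 1]")
        if not 0.0 <= self.clip_rho <= 1.0:
            raise ConfigError("clip_rho must be in [0, 1]")
        if self.background not in ("purine", "uniform"):
            raise ConfigError("background must be 'purine' or 'uniform'")
        lo, hi = self.utr_len_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid utr_len_range")
        kind = self.dist_distribution[0]
        if kind not in ("uniform", "point"):
            raise ConfigError("dist_distribution must be ('uniform', lo, hi) or ('point', d)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "dist_distribution" in raw:
            raw["dist_distribution"] = tuple(raw["dist_distribution"])
        if "utr_len_range" in raw:
            raw["utr_len_range"] = tuple(raw["utr_len_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _consensus_words(consensus: str) -> list[str]:
    return ["".join(w) for w in product(*(sorted(s) for s in _iupac_sets(consensus)))]


def _sample_dist(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    kind = cfg.dist_distribution[0]
    if kind == "point":
        return int(cfg.dist_distribution[1])
    lo, hi = cfg.dist_distribution[1], cfg.dist_distribution[2]
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# Transcripts with planted motifs
# ---------------------------------------------------------------------------

def gen_transcripts(
    cfg: SimulationConfig,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Generate RP and non-RP transcripts plus a planted-truth table.

    Truth columns: transcript_id, is_rp, has_motif, start, end, dist, word,
    stem (stem arm length actually planted); start/end are -1 for
    motif-free transcripts.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "transcripts")
    words = _consensus_words(cfg.consensus)
    k = len(cfg.consensus)
    alphabet = "AG" if cfg.background == "purine" else "ACGT"
    records, truth = [], []
    lo_len, hi_len = cfg.utr_len_range
    for i in range(cfg.n_rp + cfg.n_nonrp):
        is_rp = i < cfg.n_rp
        tid = f"{'RP' if is_rp else 'NRP'}{i:05d}"
        L = int(rng.integers(lo_len, hi_len + 1))
        seq = list(rng.choice(list(alphabet), size=L))
        plant = is_rp and rng.random() < cfg.motif_prevalence
        start = end = -1
        word = ""
        stem = 0
        if plant:
            dist = _sample_dist(cfg, rng)
            dist = min(dist, L - k)  # keep the motif inside the UTR
            end = L - dist
            start = end - k
            word = words[int(rng.integers(len(words)))]
            seq[start:end] = list(word)
            stem = min(cfg.stem_len, start, L - end)
            seq[start - stem : start] = ["G"] * stem
            seq[end : end + stem] = ["C"] * stem
        base = float(np.exp(rng.normal(np.log(80.0), 1.0)))
        fold = cfg.rp_stage_fold if is_rp else cfg.nonrp_stage_fold
        later = base * fold * float(np.exp(rng.normal(0.0, cfg.stage_noise_sd)))
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_symbol=tid.lower(),
                is_rp=is_rp,
                utr5_seq="".join(seq),
                species="synthetic",
                abundance={"branching": base, "refinement": later},
            )
        )
        truth.append(
            {
                "transcript_id": tid,
                "is_rp": is_rp,
                "has_motif": plant,
                "start": start,
                "end": end,
                "dist": (L - end) if plant else -1,
                "word": word,
                "stem": stem,
                "utr_length": L,
            }
        )
    return records, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Structures with a single-stranded loop over the motif
# ---------------------------------------------------------------------------

def gen_structures(
    transcripts: Sequence[TranscriptRecord], truth: pd.DataFrame
) -> list[SecondaryStructure]:
    """Dot-bracket structures: the planted G/C stem pairs and closes a loop
    containing the motif footprint; everything else is unpaired.
    Motif-free transcripts are fully single-stranded."""
    info = truth.set_index("transcript_id")
    out = []
    for t in transcripts:
        row = info.loc[t.transcript_id]
        db = ["."] * t.utr_length
        if bool(row["has_motif"]) and int(row["stem"]) > 0:
            start, end, stem = int(row["start"]), int(row["end"]), int(row["stem"])
            for off in range(stem):
                i, j = start - 1 - off, end + off
                # planted as G..C; pair only where complementarity holds
                if (t.utr5_seq[i], t.utr5_seq[j]) in {("G", "C"), ("C", "G")}:
                    db[i], db[j] = "(", ")"
        out.append(
            parse_dotbracket("".join(db), t.utr5_seq, transcript_id=t.transcript_id)
        )
    return out


# ---------------------------------------------------------------------------
# CLIP clusters with controlled region-overlap probability
# ---------------------------------------------------------------------------

def gen_clip(
    cfg: SimulationConfig,
    regions: Mapping[str, Interval],
    utr_lengths: Mapping[str, int],
    rho_by_rbp: Optional[Mapping[str, float]] = None,
) -> tuple[list[ClipCluster], pd.DataFrame]:
    """Per RBP, each cluster overlaps its transcript's CUIC region with
    probability rho (placed to overlap), otherwise entirely outside it."""
    cfg.validate()
    rng = _rng(cfg.seed, "clip")
    if rho_by_rbp is None:
        rho_by_rbp = {f"RBP{j:04d}": cfg.clip_rho for j in range(cfg.n_rbps)}
    tids = sorted(regions)
    if not tids:
        raise ConfigError("no CUIC regions available to place clusters on")
    w = cfg.cluster_width
    clusters, truth = [], []
    for rbp in sorted(rho_by_rbp):
        rho = rho_by_rbp[rbp]
        n_in = 0
        for ci in range(cfg.clusters_per_rbp):
            tid = tids[int(rng.integers(len(tids)))]
            a, b = regions[tid]
            L = utr_lengths[tid]
            if rng.random() < rho:
                s_lo, s_hi = max(0, a - w + 1), min(b - 1, L - w)
                s = int(rng.integers(s_lo, s_hi + 1))
                n_in += 1
            else:
                starts = [s for s in range(0, L - w + 1) if s + w <= a or s >= b]
                if not starts:
                    raise ConfigError(
                        f"no room to place a non-overlapping cluster on {tid}"
                    )
                s = int(starts[int(rng.integers(len(starts)))])
            clusters.append(
                ClipCluster(rbp=rbp, transcript_id=tid, start=s, end=s + w,
                            dataset_id=f"sim{ci}")
            )
        truth.append({"rbp": rbp, "rho": rho, "n_overlapping": n_in,
                      "n_total": cfg.clusters_per_rbp})
    return clusters, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Toy peptide + RNA complexes with planted interface fractions
# ---------------------------------------------------------------------------

def gen_toy_complex(
    n_residues: int,
    planted_fraction: float,
    seed: int = 0,
    interface_dist: float = 3.5,
    far_dist: float = 20.0,
) -> tuple[list[ChainStructure], pd.DataFrame]:
    """A straight single-phosphate-per-residue RNA backbone plus a peptide
    whose residues sit either ``interface_dist`` (< 5 A) or ``far_dist``
    (> 12 A) from the RNA axis.  Contact-mode interface fraction equals
    ``planted_fraction`` exactly.  Returns ([peptide, rna], truth labels)."""
    if not 0.0 <= planted_fraction <= 1.0:
        raise ConfigError("planted_fraction must be in [0, 1]")
    n_iface = planted_fraction * n_residues
    if abs(n_iface - round(n_iface)) > 1e-9:
        raise ConfigError(
            f"n_residues * planted_fraction = {n_iface} is not an integer"
        )
    n_iface = int(round(n_iface))
    rng = _rng(seed, "complex")
    spacing = 5.9  # approx. P-P distance along an extended backbone
    rna_res = [
        Residue(
            residue_id=str(i + 1),
            residue_name="U",
            atom_names=["P"],
            elements=["P"],
            coords=np.array([[i * spacing, 0.0, 0.0]]),
        )
        for i in range(n_residues)
    ]
    labels = np.zeros(n_residues, dtype=bool)
    labels[rng.choice(n_residues, size=n_iface, replace=False)] = True
    pep_res = []
    for i in range(n_residues):
        y = interface_dist if labels[i] else far_dist
        pep_res.append(
            Residue(
                residue_id=str(i + 1),
                residue_name="ALA",
                atom_names=["CA"],
                elements=["C"],
                coords=np.array([[i * spacing, y, 0.0]]),
            )
        )
    chains = [
        ChainStructure("A", "protein", pep_res, rp_name="toyRP", subunit="SSU"),
        ChainStructure("B", "rna", rna_res, rp_name="", subunit="SSU"),
    ]
    truth = pd.DataFrame(
        {
            "chain_id": "A",
            "residue_id": [r.residue_id for r in pep_res],
            "is_interface": labels,
        }
    )
    return chains, truth


def write_toy_complex_pdb(chains: Sequence[ChainStructure], path) -> None:
    """Minimal single-model PDB writer for the toy complexes."""
    lines = []
    serial = 1
    for ch in chains:
        for res in ch.residues:
            for name, el, (x, y, z) in zip(res.atom_names, res.elements, res.coords):
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{res.residue_name:>4s} "
                    f"{ch.chain_id}{int(res.residue_id):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {el:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Interface-index-biased abundance tables
# ---------------------------------------------------------------------------

def gen_indices(
    n_rp: int, high_frac: float = 0.25, index_cut: float = 0.6, seed: int = 0
) -> dict[str, float]:
    """Interface indices: ``high_frac`` of RPs uniform above the cut
    (core-penetrating), the rest uniform below it (surface)."""
    rng = _rng(seed, "indices")
    high = rng.random(n_rp) < high_frac
    vals = np.where(
        high,
        rng.uniform(index_cut, 1.0, n_rp),
        rng.uniform(0.0, index_cut, n_rp),
    )
    return {f"RP{i:03d}": float(v) for i, v in enumerate(vals)}


def calibrate_logistic_bias(
    indices: Sequence[float],
    n_abundant_target: float,
    fold_target: float,
    index_cut: float = 0.6,
) -> tuple[float, float]:
    """Solve (baseline, beta) of P(abundant) = expit(baseline - beta*index)
    so the expected abundant-group size and the expected fold-depletion of
    high-index RPs hit the targets.  beta = 0 is returned for fold 1."""
    idx = np.asarray(indices, dtype=float)
    hi = idx > index_cut
    if not hi.any() or hi.all():
        raise ConfigError("indices must straddle the index cut")

    def solve_baseline(beta: float) -> float:
        def size_gap(c: float) -> float:
            return expit(c - beta * idx).sum() - n_abundant_target
        return brentq(size_gap, -60.0, 60.0, xtol=1e-12)

    def expected_fold(beta: float) -> float:
        p = expit(solve_baseline(beta) - beta * idx)
        frac_ab = p[hi].sum() / p.sum()
        frac_non = (1 - p)[hi].sum() / (1 - p).sum()
        return frac_non / frac_ab

    if abs(fold_target - 1.0) < 1e-12:
        return solve_baseline(0.0), 0.0
    beta = brentq(lambda b: expected_fold(b) - fold_target, 1e-9, 80.0, xtol=1e-10)
    return solve_baseline(beta), beta


def gen_biased_abundance(
    index_by_rp: Mapping[str, float],
    beta: float,
    seed: int = 0,
    baseline: Optional[float] = None,
    n_abundant_target: Optional[float] = None,
    fpkm_cut: float = 100.0,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Draw an FPKM table whose abundant-class membership follows
    P(abundant) = expit(baseline - beta * index).

    If ``baseline`` is omitted it is solved so the expected abundant count
    equals ``n_abundant_target`` (default: 3/8 of the RPs).  FPKM values are
    log10-normal within class, truncated to the correct side of
    ``fpkm_cut``.  Returns (fpkm table, truth with membership and params).
    """
    rng = _rng(seed, "abundance")
    names = sorted(index_by_rp)
    idx = np.array([index_by_rp[k] for k in names])
    if baseline is None:
        target = n_abundant_target if n_abundant_target is not None else 0.375 * len(names)

        def size_gap(c: float) -> float:
            return expit(c - beta * idx).sum() - target

        baseline = brentq(size_gap, -60.0, 60.0, xtol=1e-12)
    p_ab = expit(baseline - beta * idx)
    abundant = rng.random(len(names)) < p_ab
    log_cut = np.log10(fpkm_cut)
    fpkm = np.empty(len(names))
    for i, ab in enumerate(abundant):
        while True:  # truncated draw: class side of the cut
            v = rng.normal(log_cut + (0.5 if ab else -0.8), 0.45)
            if (v > log_cut) == ab and v != log_cut:
                fpkm[i] = 10.0 ** v
                break
    truth = pd.DataFrame(
        {
            "rp_name": names,
            "index": idx,
            "p_abundant": p_ab,
            "abundant": abundant,
            "fpkm": fpkm,
        }
    )
    truth.attrs["beta"] = beta
    truth.attrs["baseline"] = float(baseline)
    return dict(zip(names, fpkm)), truth


# ---------------------------------------------------------------------------
# Observed 5' ends (axon-like vs embryo-like samples)
# ---------------------------------------------------------------------------

def gen_five_prime_ends(
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    n_per_transcript: int = 5,
    axon_noise_sd: float = 3.0,
) -> pd.DataFrame:
    """5'-end observations: the axon-like sample starts at the motif start
    +/- Gaussian noise (truncated isoforms); the embryo-like sample starts
    uniformly upstream of the motif."""
    rng = _rng(cfg.seed, "five_prime")
    rows = []
    for r in truth.itertuples(index=False):
        if not r.has_motif:
            continue
        for _ in range(n_per_transcript):
            axon = int(np.clip(round(r.start + rng.normal(0, axon_noise_sd)),
                               0, r.utr_length))
            embryo = int(rng.integers(0, max(1, r.start - 10)))
            rows.append({"transcript_id": r.transcript_id,
                         "sample_label": "axon", "end_pos": axon})
            rows.append({"transcript_id": r.transcript_id,
                         "sample_label": "embryo", "end_pos": embryo})
    return pd.DataFrame(rows)
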