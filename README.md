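# cuic

Analyses around a 5′ UTR *cis*-element of ribosomal-protein (RP) mRNAs.

Most RP-coding mRNAs carry a degenerate pyrimidine 8-mer — consensus
**YYYYTTYC**, named CUIC (*cis*-element upstream of the initiation codon) —
within 100 nt of the start codon, typically 20–80 nt upstream. The element
sits in a single-stranded loop of the predicted secondary structure, is
bound preferentially by translation-initiation-associated RNA-binding
proteins in CLIP-seq data, and marks transcripts whose truncated 5′-end
isoforms resemble 5′ TOP mRNAs. On the protein side, the RPs whose mRNAs
are abundant in axons occupy surface positions of the ribosome, quantified
by the **interface-index**

```
interface-index = (# residues interfacing rRNA) / (# resolved residues)
```

with proteins above 0.6 classed as core/penetrated. `cuic` implements the
full desk-scale analysis chain:

- **`cuic.motif`** — IUPAC consensus scanning of 5′ UTRs (0-based, half-open;
  distance measured from the motif 3′ end to the AUG), CUIC-gene
  classification (< 100 nt), distance-band statistics (20–80 nt inclusive),
  5′-end offsets relative to the motif, truncated-isoform and 5′ TOP-like
  calls.
- **`cuic.structure`** — dot-bracket parsing, a deterministic
  maximum-base-pairing (Nussinov) fallback folder, and the motif-anchored
  mean double-stranded-fraction profile (7-nt moving average).
- **`cuic.clip`** — per-RBP specificity score: clusters overlapping the CUIC
  region (motif ± 10 nt) divided by all clusters on RP transcripts.
- **`cuic.interface`** — Shrake–Rupley SASA (probe 1.4 Å, 960 points/atom)
  and ΔSASA- or contact-based interface residues from PDB/mmCIF complexes;
  SSU proteins are scored against 18S rRNA, LSU proteins against
  5S/5.8S/28S.
- **`cuic.stats`** — two-sample KS and Mann-Whitney tests (asymptotic and
  exact small-sample modes), Fisher's exact test, fold-depletion of
  high-index RPs from the abundant (FPKM > 100) group, stage-ratio
  distributions, and FRAP relative recovery
  `Rx = (Ix − Ipost) / (Ipre − Ipost)`.
- **`cuic.simulate`** — seeded generators with machine-readable ground truth
  for every stage (planted motifs, loop structures, CLIP overlap rates, toy
  peptide–RNA complexes, index-biased abundance tables).

## Worked example

Scanning the 72-nt *Xenopus laevis* Rps4x.S 5′ UTR shipped with the package:

```python
>>> import cuic
>>> for h in cuic.scan_cuic(cuic.RPS4X_S_UTR5):
...     print(h.start, h.matched_seq, h.dist_to_start_codon)
5 TCTCTTCC 59
64 TCTTTTCC 0
```

Two CUIC instances: one 59 nt upstream of the AUG and one abutting it
(distance 0) — the motif pair known to drive this UTR's regulated
translation. The same chain runs end-to-end on simulated data from a shell:

```bash
$ cuic simulate --seed 1 --out-dir demo
fixtures written to demo
$ cuic scan --fasta demo/utrs.fa --annot demo/annot.tsv --out demo/hits.tsv
57 / 480 transcripts CUIC-positive
$ cuic profile --structs demo/utrs.db --hits demo/hits.tsv --out demo/profile.tsv
profile over 101 offsets written to demo/profile.tsv
$ cuic clip-score --bed demo/clip.bed --hits demo/hits.tsv --out demo/scores.tsv
200 RBPs scored (flank 10 nt)
$ cuic bias --index demo/index.tsv --abund demo/fpkm.tsv --out demo/bias.json
abundant mean 0.263 vs non-abundant 0.482; KS p=0.000509; Fisher p=0.0049; fold depletion 5.54
```

The 57/480 positives are the planted 70%-prevalence RP motifs (57 of 80 RP
transcripts; non-RP backgrounds are purine-only and never match); the
profile dips to 0 over the motif; the mean specificity score recovers the
planted overlap probability ρ = 0.3; and the bias report recovers the
planted surface-bias of abundant RPs (abundant group mean index well below
the non-abundant group, with a significant Fisher depletion of high-index
proteins).

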