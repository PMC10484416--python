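"""Simplified lncRNA:DNA triplex prediction by local alignment.

A triplex-forming lncRNA lays its single strand in the major groove of a
DNA duplex, contacting the purine strand base by base (Hoogsteen / reverse
Hoogsteen pairing). The canonical triplex code used here is:

* parallel (pyrimidine) motif: U.(A:T) and C.(G:C) — the RNA runs parallel
  to the purine strand;
* antiparallel (purine) motif: A.(A:T), G.(G:C) and U.(A:T) — the RNA runs
  antiparallel to the purine strand.

Triplex targeting sites (TTS) are local alignments between the RNA and the
DNA under these pairing rules, scored with match/mismatch/affine-gap
penalties so the affinity of a perfect contact equals its length in bp.
Both strands of the duplex are examined. All non-overlapping sites above a
threshold are recovered by iterated masking of the best alignment.
Overlapping TTSs on the DNA are merged into DNA binding sites (DBS); the
matching lncRNA intervals are the DNA binding domains (DBD).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from numba import njit

DEFAULT_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0, "gap_extend": -1.0}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

NEG = -1e9


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"sequence contains invalid base {exc.args[0]!r}") from None


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _pairing_matrix(motif: str, match: float, mismatch: float) -> np.ndarray:
    sub = np.full((5, 5), mismatch)
    if motif == "parallel":
        pairs = [(3, 0), (1, 2)]            # U.(A:T), C.(G:C)
    elif motif == "antiparallel":
        pairs = [(0, 0), (2, 2), (3, 0)]    # A.(A:T), G.(G:C), U.(A:T)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    for r, d in pairs:
        sub[r, d] = match
    sub[4, :] = mismatch  # N never matches
    sub[:, 4] = mismatch
    return sub


@njit(cache=False)
def _sw_best(rna, dna, sub, gap_open, gap_extend, dna_mask):  # pragma: no cover
    n, m = rna.shape[0], dna.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    pH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 from F, 3 from E
    pE = np.zeros((n + 1, m + 1), np.uint8)  # 1 opened from H, 0 extended
    pF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                pE[i, j] = 1
            else:
                E[i, j] = e_ext
                pE[i, j] = 0
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                pF[i, j] = 1
            else:
                F[i, j] = f_ext
                pF[i, j] = 0
            if dna_mask[j - 1]:
                s = NEG
            else:
                s = sub[rna[i - 1], dna[j - 1]]
            diag = H[i - 1, j - 1] + s
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from the best cell
    i, j = bi, bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            opened = pE[i, j] == 1
            j -= 1
            if opened:
                state = 0
        else:
            opened = pF[i, j] == 1
            i -= 1
            if opened:
                state = 0
    return best, i, bi, j, bj


@dataclasses.dataclass
class TTS:
    """Triplex targeting site: one local RNA:DNA alignment."""

    lnc_start: int
    lnc_end: int
    dna_start: int
    dna_end: int
    affinity: float
    motif: str
    strand: str

    def __post_init__(self) -> None:
        if self.affinity <= 0:
            raise ValueError("TTS affinity must be positive")


@dataclasses.dataclass
class DBS:
    """DNA binding site: union of overlapping TTS intervals on the DNA."""

    dna_start: int
    dna_end: int
    affinity: float          # max member affinity
    n_tts: int
    lnc_start: int           # envelope of member lncRNA intervals (the DBD)
    lnc_end: int
    lncRNA: str = ""
    gene: str = ""

    @property
    def length(self) -> int:
        return self.dna_end - self.dna_start


def find_tts(
    lnc_seq: str,
    dna_seq: str,
    scoring: dict | None = None,
    min_affinity: float = 30.0,
    motifs: tuple = ("parallel", "antiparallel"),
    both_strands: bool = True,
    max_sites: int = 25,
) -> list[TTS]:
    """All non-overlapping local triplex alignments with affinity >= threshold.

    For each pairing motif the RNA is aligned against the purine strand in
    its required orientation; both strands of the duplex are considered by
    also aligning against the reverse complement. Sites are recovered best
    first; after each hit the covered DNA positions are masked and the
    alignment repeated until the best score drops below ``min_affinity``.
    """
    if not lnc_seq or not dna_seq:
        return []
    params = dict(DEFAULT_SCORING)
    if scoring:
        params.update(scoring)
    rna_fwd = _encode(lnc_seq)
    configs = []
    for motif in motifs:
        sub = _pairing_matrix(motif, params["match"], params["mismatch"])
        rna = rna_fwd if motif == "parallel" else rna_fwd[::-1]
        configs.append((motif, "+", rna, _encode(dna_seq), sub))
        if both_strands:
            configs.append((motif, "-", rna, _encode(revcomp(dna_seq)), sub))

    n_r, n_d = len(lnc_seq), len(dna_seq)
    sites: list[TTS] = []
    for motif, strand, rna, dna, sub in configs:
        mask = np.zeros(len(dna), dtype=np.bool_)
        for _ in range(max_sites):
            score, ri0, ri1, dj0, dj1 = _sw_best(
                rna, dna, sub, params["gap_open"], params["gap_extend"], mask
            )
            if score < min_affinity or dj1 <= dj0:
                break
            mask[dj0:dj1] = True
            if motif == "antiparallel":  # RNA was reversed
                ri0, ri1 = n_r - ri1, n_r - ri0
            if strand == "-":  # DNA was reverse-complemented
                dj0, dj1 = n_d - dj1, n_d - dj0
            sites.append(
                TTS(int(ri0), int(ri1), int(dj0), int(dj1), float(score), motif, strand)
            )
    sites.sort(key=lambda t: (t.dna_start, t.dna_end, -t.affinity))
    return sites


def merge_tts_to_dbs(
    tts_list: list[TTS],
    min_len: int = 50,
    lncRNA: str = "",
    gene: str = "",
) -> list[DBS]:
    """Merge overlapping TTS DNA intervals; keep merged sites > ``min_len`` bp."""
    if not tts_list:
        return []
    ordered = sorted(tts_list, key=lambda t: (t.dna_start, t.dna_end))
    groups: list[list[TTS]] = [[ordered[0]]]
    cur_end = ordered[0].dna_end
    for tts in ordered[1:]:
        if tts.dna_start < cur_end:
            groups[-1].append(tts)
            cur_end = max(cur_end, tts.dna_end)
        else:
            groups.append([tts])
            cur_end = tts.dna_end
    out = []
    for group in groups:
        start = min(t.dna_start for t in group)
        end = max(t.dna_end for t in group)
        if end - start <= min_len:
            continue
        out.append(
            DBS(
                dna_start=start,
                dna_end=end,
                affinity=max(t.affinity for t in group),
                n_tts=len(group),
                lnc_start=min(t.lnc_start for t in group),
                lnc_end=max(t.lnc_end for t in group),
                lncRNA=lncRNA,
                gene=gene,
            )
        )
    return out


def dbs_binding_call(dbs_list: list[DBS], affinity_cut: float = 100.0) -> bool:
    """True iff any DBS has affinity strictly above the cutoff."""
    return any(d.affinity > affinity_cut for d in dbs_list)


# -- promoters -----------------------------------------------------------

@dataclasses.dataclass
class PromoterWindow:
    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str


def extract_promoters(
    gene_annotation: pd.DataFrame,
    genome: dict[str, str],
    upstream: int = 3500,
    downstream: int = 1500,
) -> list[PromoterWindow]:
    """Strand-oriented promoter windows around each gene's TSS.

    The TSS is ``start`` for plus-strand genes and ``end`` for minus-strand
    genes; the window spans ``upstream`` bp before to ``downstream`` bp
    after the TSS in gene orientation (minus-strand sequences are
    reverse-complemented). Windows are clipped at contig ends with a
    warning; genes on contigs absent from the genome are skipped.
    """
    out = []
    skipped = 0
    for row in gene_annotation.itertuples():
        if row.chrom not in genome:
            skipped += 1
            continue
        contig = genome[row.chrom]
        if row.strand == "-":
            tss = int(row.end)
            lo, hi = tss - downstream, tss + upstream
        else:
            tss = int(row.start)
            lo, hi = tss - upstream, tss + downstream
        clipped_lo, clipped_hi = max(0, lo), min(len(contig), hi)
        if (clipped_lo, clipped_hi) != (lo, hi):
            warnings.warn(f"promoter window of {row.gene} clipped at contig ends")
        seq = contig[clipped_lo:clipped_hi]
        if row.strand == "-":
            seq = revcomp(seq)
        out.append(
            PromoterWindow(row.gene, row.chrom, clipped_lo, clipped_hi, row.strand, seq)
        )
    if skipped:
        warnings.warn(f"{skipped} genes on contigs absent from the genome; skipped")
    return out


# -- output formats -------------------------------------------------------

def tts_to_bed(tts_list: list[TTS], chrom: str, name: str) -> pd.DataFrame:
    """BED6 rows for TTS intervals (score capped at 1000)."""
    rows = [
        (chrom, t.dna_start, t.dna_end, f"{name}_tts{i}", min(int(t.affinity), 1000),
         t.strand)
        for i, t in enumerate(tts_list)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def tts_coverage_bedgraph(tts_list: list[TTS], chrom: str, length: int) -> pd.DataFrame:
    """bedGraph intervals of TTS coverage depth along the DNA."""
    depth = np.zeros(length + 1, dtype=int)
    for t in tts_list:
        depth[t.dna_start] += 1
        depth[t.dna_end] -= 1
    depth = np.cumsum(depth[:-1])
    rows = []
    start = 0
    for pos in range(1, length + 1):
        if pos == length or depth[pos] != depth[start]:
            if depth[start] > 0:
                rows.append((chrom, start, pos, int(depth[start])))
            start = pos
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])
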