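"""miRanda-style miRNA:3'UTR duplex alignment.

A miRNA is aligned antiparallel against a UTR by affine-gap local dynamic
programming (Gotoh) over base-pair scores: Watson-Crick pairs score
``match_wc``, G:U wobbles ``match_wobble``, mismatches ``mismatch``; pair
scores at miRNA positions 2-8 (the seed, counted from the 5' end) are
multiplied by ``seed_weight``.  Each reported hit carries the alignment score
S and a duplex free-energy estimate dG obtained by summing per-pair stacking
energies over the paired positions (G:C -2.2, A:U -1.1, G:U -0.5 kcal/mol) —
a deterministic, monotone proxy for a folding-based energy.  A hit passes
when S >= min_score and dG <= max_energy (140 and -10 in this work).
Non-overlapping hits are extracted greedily by descending score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .config import AlignerParams

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

#: (miRNA base, target base) classes: 2 = Watson-Crick, 1 = G:U wobble, 0 = none
_PAIR_CLASS = np.zeros((4, 4), dtype=np.int64)
for _a, _b in ((0, 3), (3, 0)):
    _PAIR_CLASS[_a, _b] = 2  # A:U
for _a, _b in ((1, 2), (2, 1)):
    _PAIR_CLASS[_a, _b] = 3  # G:C (kept distinct for the energy table)
for _a, _b in ((2, 3), (3, 2)):
    _PAIR_CLASS[_a, _b] = 1  # G:U


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA sequence (T and U equivalent, case-insensitive)."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def _matrices(params: AlignerParams) -> tuple[np.ndarray, np.ndarray]:
    sub = np.empty((4, 4))
    energy = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            cls = _PAIR_CLASS[a, b]
            if cls == 3:
                sub[a, b] = params.match_wc
                energy[a, b] = params.energy_gc
            elif cls == 2:
                sub[a, b] = params.match_wc
                energy[a, b] = params.energy_au
            elif cls == 1:
                sub[a, b] = params.match_wobble
                energy[a, b] = params.energy_gu
            else:
                sub[a, b] = params.mismatch
    return sub, energy


@njit(cache=False)
def _gotoh(q, u, w, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    m, n = q.shape[0], u.shape[0]
    neg = -1e18
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), neg)
    F = np.full((m + 1, n + 1), neg)
    for i in range(1, m + 1):
        qi = q[i - 1]
        wi = w[i - 1]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] + gap_open + gap_extend, E[i, j - 1] + gap_extend)
            f = max(H[i - 1, j] + gap_open + gap_extend, F[i - 1, j] + gap_extend)
            h = H[i - 1, j - 1] + wi * sub[qi, u[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


@dataclass(frozen=True)
class DuplexHit:
    """One miRNA:UTR alignment: location on the UTR, score and energy."""

    mirna_id: str
    gene_id: str
    start: int  # 0-based, half-open on the UTR
    end: int
    score: float
    energy: float  # kcal/mol, <= 0 for any paired duplex
    passes: bool
    n_paired: int


def _traceback(H, E, F, q, u, w, sub, gap_open, gap_extend, i, j):
    """Recover aligned pairs of the local alignment ending at H[i, j]."""
    eps = 1e-9
    pairs = []  # (query index, target index), 0-based
    consumed_u = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] <= eps:
                break
            diag = H[i - 1, j - 1] + w[i - 1] * sub[q[i - 1], u[j - 1]]
            if abs(H[i, j] - diag) < eps:
                pairs.append((i - 1, j - 1))
                consumed_u.append(j - 1)
                i, j = i - 1, j - 1
            elif abs(H[i, j] - E[i, j]) < eps:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in the miRNA: UTR base consumed
            consumed_u.append(j - 1)
            if abs(E[i, j] - (H[i, j - 1] + gap_open + gap_extend)) < eps:
                state = "H"
            j -= 1
        else:  # gap in the UTR: miRNA base consumed
            if abs(F[i, j] - (H[i - 1, j] + gap_open + gap_extend)) < eps:
                state = "H"
            i -= 1
    return pairs, consumed_u


def align_duplex(
    mirna_seq: str,
    utr_seq: str,
    params: AlignerParams | None = None,
    mirna_id: str = "",
    gene_id: str = "",
) -> list[DuplexHit]:
    """Non-overlapping local duplex alignments of a miRNA against a UTR.

    The miRNA (given 5'->3') is reversed so that left-to-right alignment
    against the UTR realizes the antiparallel duplex geometry; seed weighting
    is mapped onto the reversed coordinates accordingly.  Hits are extracted
    greedily by descending score (ties to the leftmost start), masking the
    spanned UTR window after each extraction, until no remaining window
    reaches ``params.report_floor``.
    """
    if params is None:
        params = AlignerParams()
    q = encode(mirna_seq)[::-1].copy()
    u = encode(utr_seq)
    m = len(q)
    w = np.ones(m)
    for p in range(params.seed_start, params.seed_end + 1):  # 1-based, 5' end
        idx = m - p
        if 0 <= idx < m:
            w[idx] = params.seed_weight
    sub, energy = _matrices(params)

    segments: dict[tuple[int, int], tuple | None] = {}

    def best_in(seg):
        a, b = seg
        if b - a < 1:
            return None
        H, E, F = _gotoh(q, u[a:b], w, sub, params.gap_open, params.gap_extend)
        flat = int(np.argmax(H))
        i, j = divmod(flat, H.shape[1])
        score = float(H[i, j])
        if score < params.report_floor:
            return None
        pairs, consumed = _traceback(H, E, F, q, u[a:b], w, sub,
                                     params.gap_open, params.gap_extend, i, j)
        if not consumed:
            return None
        start, end = a + min(consumed), a + max(consumed) + 1
        dg = float(sum(energy[q[pi], u[a + tj]] for pi, tj in pairs))
        return (score, start, end, dg, len(pairs))

    segments[(0, len(u))] = best_in((0, len(u)))
    hits: list[DuplexHit] = []
    while True:
        live = [(seg, h) for seg, h in segments.items() if h is not None]
        if not live:
            break
        seg, h = min(live, key=lambda x: (-x[1][0], x[1][1]))
        score, start, end, dg, n_paired = h
        hits.append(DuplexHit(
            mirna_id=mirna_id, gene_id=gene_id, start=start, end=end,
            score=score, energy=dg,
            passes=(score >= params.min_score and dg <= params.max_energy),
            n_paired=n_paired,
        ))
        a, b = seg
        del segments[seg]
        for sub_seg in ((a, start), (end, b)):
            if sub_seg[1] - sub_seg[0] >= 1:
                segments[sub_seg] = best_in(sub_seg)
    hits.sort(key=lambda h: (h.start, -h.score))
    return hits


def scan_targets(
    mirna_seqs: dict[str, str],
    utrs: dict[str, str],
    params: AlignerParams | None = None,
) -> list[DuplexHit]:
    """Align every miRNA against every UTR; returns all reported hits."""
    if params is None:
        params = AlignerParams()
    hits: list[DuplexHit] = []
    for gid, utr in utrs.items():
        for mid, mseq in mirna_seqs.items():
            hits.extend(align_duplex(mseq, utr, params, mirna_id=mid, gene_id=gid))
    return hits
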