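"""Naive reference implementations used to validate the fast paths.

Everything here is deliberately written as direct brute force over the
definitions — exhaustive window enumeration for the triplex scan and the
CpG detector, explicit structure enumeration for the Boltzmann ensemble,
per-base counting for interval coverage — sharing no code with the
optimized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np

from .model import GenomicInterval, ScreenParams
from .triads import TriadTable, triad_weight
from .triplex import TranscriptInterval, TriplexHit

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def _diagonal_hits(
    rna: str,
    dna: str,
    orientation: str,
    table: TriadTable,
    params: ScreenParams,
) -> list[tuple[int, int, int, int, int]]:
    """All reduced qualifying windows as (i, j, length, matches, wsum)."""
    lg = params.min_triplex_len
    n, m = len(rna), len(dna)
    out = []
    for d in range(-(n - 1), m):
        i0 = max(0, -d)
        j0 = i0 + d
        length = min(n - i0, m - j0)
        if length < lg:
            continue
        weights = []
        for k in range(length):
            r, t = rna[i0 + k], dna[j0 + k]
            try:
                w = triad_weight(r, t, orientation, table)
            except ValueError:  # ambiguous symbol scores 0
                w = 0
            weights.append(w)
        w_arr = np.asarray(weights, dtype=np.int64)
        sw = np.concatenate([[0], np.cumsum(w_arr)])
        sm = np.concatenate([[0], np.cumsum(w_arr > 0)])
        # every (a, b) window, checked directly against the three thresholds
        a_idx = np.arange(length + 1)
        span = a_idx[None, :] - a_idx[:, None]  # span[a, b] = b - a
        wsum = sw[None, :] - sw[:, None]
        msum = sm[None, :] - sm[:, None]
        ok = (
            (span >= lg)
            & (wsum >= params.min_stability * span)
            & (100.0 * msum >= params.min_identity * span)
        )
        if not ok.any():
            continue
        windows = sorted(
            (int(a), int(b)) for a, b in np.argwhere(ok)
        )
        # overlap components, reduced to the best window per component
        comps: list[list[tuple[int, int]]] = []
        comp_end = None
        for a, b in windows:
            if comp_end is None or a >= comp_end:
                comps.append([])
                comp_end = b
            comps[-1].append((a, b))
            comp_end = max(comp_end, b)
        for comp in comps:
            best = max(
                comp,
                key=lambda ab: (
                    (sw[ab[1]] - sw[ab[0]]) / (ab[1] - ab[0]),  # mean stability
                    ab[1] - ab[0],
                    -ab[0],
                ),
            )
            a, b = best
            out.append(
                (i0 + a, j0 + a, b - a, int(sm[b] - sm[a]), int(sw[b] - sw[a]))
            )
    return out


def brute_force_scan(
    rna_seq: str,
    dna_seq: str,
    params: ScreenParams,
    table: TriadTable | None = None,
    *,
    chrom: str = "seq",
    origin: int = 1,
) -> list[TriplexHit]:
    """Exhaustive enumeration equivalent of :func:`triplexscreen.triplex.scan_triplexes`."""
    table = table or TriadTable.default()
    rna = rna_seq.upper().replace("T", "U")
    dna_fwd = dna_seq.upper().replace("U", "T")
    n, m = len(rna), len(dna_fwd)
    dna_rev = _revcomp_dna(dna_fwd)
    hits = []
    for dna_strand, dna in (("+", dna_fwd), ("-", dna_rev)):
        for orientation in ("parallel", "antiparallel"):
            rna_used = rna if orientation == "parallel" else rna[::-1]
            for i, j, length, matches, wsum in _diagonal_hits(
                rna_used, dna, orientation, table, params
            ):
                if orientation == "parallel":
                    tfo = TranscriptInterval(i + 1, i + length)
                else:
                    tfo = TranscriptInterval(n - length - i + 1, n - i)
                if dna_strand == "+":
                    gstart = origin + j
                else:
                    gstart = origin + m - length - j
                hits.append(
                    TriplexHit(
                        tfo=tfo,
                        tts=GenomicInterval(chrom, gstart, gstart + length - 1, dna_strand),
                        orientation=orientation,
                        dna_strand=dna_strand,
                        length=length,
                        identity=100.0 * matches / length,
                        stability=wsum / length,
                    )
                )
    hits.sort(key=TriplexHit.sort_key)
    return hits


def max_interval_coverage(intervals: list[tuple[int, int]]) -> int:
    """Maximum per-base coverage depth, by literal per-base counting."""
    if not intervals:
        return 0
    lo = min(s for s, _ in intervals)
    hi = max(e for _, e in intervals)
    counts = np.zeros(hi - lo + 1, dtype=np.int64)
    for s, e in intervals:
        counts[s - lo : e - lo + 1] += 1
    return int(counts.max())


def brute_force_cpg_islands(
    seq: str,
    *,
    window: int = 200,
    min_gc: float = 50.0,
    min_oe: float = 0.6,
) -> list[tuple[int, int]]:
    """Merged qualifying-window boundaries (0-based inclusive) by direct counting."""
    seq = seq.upper()
    n = len(seq)
    if n < window:
        return []
    qualifying = []
    for s in range(n - window + 1):
        sub = seq[s : s + window]
        n_c = sub.count("C")
        n_g = sub.count("G")
        n_cg = sub.count("CG")
        gc = 100.0 * (n_c + n_g) / window
        oe = (n_cg * window) / (n_c * n_g) if n_c and n_g else 0.0
        if gc >= min_gc and oe >= min_oe:
            qualifying.append(s)
    merged = []
    for s in qualifying:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], s + window - 1))
        else:
            merged.append((s, s + window - 1))
    return merged


def enumerate_punp(
    seq: str,
    pair_boltzmann: np.ndarray,
) -> np.ndarray:
    """Per-base unpaired probability by explicit structure enumeration.

    ``pair_boltzmann[i, j]`` must be the Boltzmann factor of pairing bases
    i and j (0 where the pair is disallowed by alphabet, hairpin or span
    constraints).  Every pseudoknot-free structure is generated exactly once
    by the classic first-base decomposition, and its weight is the product
    of the factors of its pairs.
    """
    n = len(seq)
    bp = pair_boltzmann
    z_total = 0.0
    unp_weight = np.zeros(n, dtype=np.float64)

    def structures(i: int, j: int):
        """Yield (weight, pairs) for region [i, j] inclusive."""
        if i > j:
            yield 1.0, []
            return
        # base i unpaired
        for w, pairs in structures(i + 1, j):
            yield w, pairs
        # base i paired with k
        for k in range(i + 1, j + 1):
            if bp[i, k] == 0.0:
                continue
            for w_in, p_in in structures(i + 1, k - 1):
                for w_out, p_out in structures(k + 1, j):
                    yield bp[i, k] * w_in * w_out, [(i, k)] + p_in + p_out

    for w, pairs in structures(0, n - 1):
        z_total += w
        paired = np.zeros(n, dtype=bool)
        for a, b in pairs:
            paired[a] = paired[b] = True
        unp_weight[~paired] += w
    return unp_weight / z_total


def count_structures(pair_boltzmann: np.ndarray) -> int:
    """Number of admissible structures (used to keep oracle inputs tractable)."""
    n = pair_boltzmann.shape[0]
    memo: dict[tuple[int, int], int] = {}

    def cnt(i: int, j: int) -> int:
        if i >= j:
            return 1
        key = (i, j)
        if key in memo:
            return memo[key]
        total = cnt(i + 1, j)
        for k in range(i + 1, j + 1):
            if pair_boltzmann[i, k] != 0.0:
                total += cnt(i + 1, k - 1) * cnt(k + 1, j)
        memo[key] = total
        return total

    return cnt(0, n - 1)
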