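"""Triplex scan: find TFO/TTS matches between a transcript and a promoter duplex.

The scan is an ungapped diagonal search.  For each duplex strand (either may
serve as the purine-rich strand) and each third-strand orientation
(parallel / antiparallel), every RNA-vs-DNA alignment diagonal is scored
position-wise with the triad table.  A window qualifies as a triplex hit if

* its length is at least ``min_triplex_len`` (LongTarget-style ``-lg``),
* its identity — the percentage of positions whose triad weight is
  positive — is at least ``min_identity`` (``-i``), and
* its mean triad weight is at least ``min_stability`` (``-S``).

Overlapping qualifying windows on one diagonal describe the same physical
contact and are reduced to a single hit: the window with the highest mean
stability (ties: longer, then leftmost).  This keeps hit counts
non-redundant, which matters because the density of overlapping hits across
diagonals is the screen's interaction-strength statistic (TFO1).

TFO1 selection is a sweep-line maximum-overlap count over the hits' TTS
intervals on the target DNA: the peak is the region of maximal coverage
depth and the cluster is every hit covering it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numba import njit

from .model import GenomicInterval, ScreenParams
from .triads import TriadTable, encode_sequence

logger = logging.getLogger(__name__)

_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T/U, C<->G, N->N


class TranscriptInterval(NamedTuple):
    """1-based inclusive interval on a transcript (nt offsets)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TriplexHit:
    """One predicted TFO/TTS duplex-triplex match."""

    tfo: TranscriptInterval
    tts: GenomicInterval
    orientation: str  # parallel | antiparallel
    dna_strand: str   # which duplex strand the RNA was scanned against
    length: int
    identity: float   # percent of positions with a positive triad weight
    stability: float  # mean triad weight

    def __post_init__(self) -> None:
        if self.length != self.tfo.length or self.length != self.tts.length:
            raise ValueError("TFO, TTS and hit length disagree")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity out of range: {self.identity}")

    def sort_key(self) -> tuple:
        return (
            self.tts.start,
            self.tts.end,
            self.tfo.start,
            self.orientation,
            self.dna_strand,
        )


@dataclass(frozen=True)
class Tfo1Cluster:
    """The densest cluster of overlapping hits on the target DNA."""

    peak_interval: GenomicInterval | None
    hit_count: int
    member_hits: tuple[TriplexHit, ...]

    def __post_init__(self) -> None:
        if self.hit_count != len(self.member_hits):
            raise ValueError("hit_count must equal the number of member hits")


@njit(cache=True)
def _scan_diagonals(rna, dna, wmat, lg, min_ident, min_stab):  # pragma: no cover
    """Return per-diagonal reduced hits as rows [i, j, length, matches, wsum].

    i/j are 0-based offsets into the working RNA/DNA sequences.  Qualifying
    windows are located with an exact prefix-margin pruning step (a window
    [a, b) qualifies iff both running margins at b are no smaller than at a),
    then enumerated and reduced per overlap-component.
    """
    n = rna.shape[0]
    m = dna.shape[0]
    out = np.empty((16, 5), dtype=np.int64)
    n_out = 0

    max_l = min(n, m)
    sw = np.empty(max_l + 1, dtype=np.int64)
    sm = np.empty(max_l + 1, dtype=np.int64)
    gw = np.empty(max_l + 1, dtype=np.float64)
    gm = np.empty(max_l + 1, dtype=np.float64)
    pmw = np.empty(max_l + 1, dtype=np.float64)
    pmm = np.empty(max_l + 1, dtype=np.float64)
    win_a = np.empty(256, dtype=np.int64)
    win_b = np.empty(256, dtype=np.int64)

    for d in range(-(n - 1), m):
        i0 = -d if d < 0 else 0
        j0 = i0 + d
        L = min(n - i0, m - j0)
        if L < lg:
            continue
        sw[0] = 0
        sm[0] = 0
        gw[0] = 0.0
        gm[0] = 0.0
        pmw[0] = 0.0
        pmm[0] = 0.0
        for k in range(L):
            w = wmat[rna[i0 + k], dna[j0 + k]]
            sw[k + 1] = sw[k] + w
            sm[k + 1] = sm[k] + (1 if w > 0 else 0)
            gw[k + 1] = sw[k + 1] - min_stab * (k + 1)
            gm[k + 1] = 100.0 * sm[k + 1] - min_ident * (k + 1)
            pmw[k + 1] = min(pmw[k], gw[k + 1])
            pmm[k + 1] = min(pmm[k], gm[k + 1])

        # enumerate qualifying windows (ends pre-filtered by the margins)
        n_win = 0
        for b in range(lg, L + 1):
            if gw[b] < pmw[b - lg] - 1e-9 or gm[b] < pmm[b - lg] - 1e-9:
                continue
            for a in range(0, b - lg + 1):
                length = b - a
                if (sw[b] - sw[a]) >= min_stab * length and 100.0 * (
                    sm[b] - sm[a]
                ) >= min_ident * length:
                    if n_win >= win_a.shape[0]:
                        new_a = np.empty(win_a.shape[0] * 2, dtype=np.int64)
                        new_b = np.empty(win_a.shape[0] * 2, dtype=np.int64)
                        new_a[:n_win] = win_a[:n_win]
                        new_b[:n_win] = win_b[:n_win]
                        win_a = new_a
                        win_b = new_b
                    win_a[n_win] = a
                    win_b[n_win] = b
                    n_win += 1
        if n_win == 0:
            continue

        order = np.argsort(win_a[:n_win], kind="mergesort")
        comp_end = -1
        best_a = -1
        best_b = -1
        best_ws = -1
        for idx in range(n_win + 1):
            if idx < n_win:
                a = win_a[order[idx]]
                b = win_b[order[idx]]
            else:
                a = comp_end + 10  # sentinel: force the last component to close
                b = a + 1
            if best_a >= 0 and a >= comp_end:
                # close the current component and emit its best window
                if n_out >= out.shape[0]:
                    new = np.empty((out.shape[0] * 2, 5), dtype=np.int64)
                    new[:n_out] = out[:n_out]
                    out = new
                blen = best_b - best_a
                out[n_out, 0] = i0 + best_a
                out[n_out, 1] = j0 + best_a
                out[n_out, 2] = blen
                out[n_out, 3] = sm[best_b] - sm[best_a]
                out[n_out, 4] = sw[best_b] - sw[best_a]
                n_out += 1
                best_a = -1
            if idx == n_win:
                break
            if best_a < 0:
                best_a = a
                best_b = b
                best_ws = sw[b] - sw[a]
                comp_end = b
            else:
                comp_end = max(comp_end, b)
                ws = sw[b] - sw[a]
                blen = b - a
                cur_len = best_b - best_a
                # higher mean stability, then longer, then leftmost
                better = False
                if ws * cur_len > best_ws * blen:
                    better = True
                elif ws * cur_len == best_ws * blen:
                    if blen > cur_len:
                        better = True
                    elif blen == cur_len and a < best_a:
                        better = True
                if better:
                    best_a = a
                    best_b = b
                    best_ws = ws
    return out[:n_out]


def _fraction_ambiguous(codes: np.ndarray) -> float:
    return float(np.mean(codes == 4)) if codes.size else 0.0


def scan_triplexes(
    rna_seq: str,
    dna_seq: str,
    params: ScreenParams,
    table: TriadTable | None = None,
    *,
    chrom: str = "seq",
    origin: int = 1,
) -> list[TriplexHit]:
    """Scan a transcript against a promoter duplex for triplex hits.

    Parameters
    ----------
    rna_seq : str
        Transcript sequence (T is read as U).
    dna_seq : str
        Forward-strand duplex sequence; both strands are tried as the
        scanned (purine) strand.
    chrom, origin : str, int
        Genomic location of ``dna_seq[0]`` (1-based), used to report TTS
        coordinates on the forward strand of the genome.

    Returns
    -------
    list of TriplexHit, ordered by (TTS position, TFO position, orientation).
    """
    table = table or TriadTable.default()
    lg = params.min_triplex_len
    if len(rna_seq) < lg or len(dna_seq) < lg:
        raise ValueError(
            f"sequences must be at least min_triplex_len={lg} nt "
            f"(got RNA {len(rna_seq)}, DNA {len(dna_seq)})"
        )
    rna = encode_sequence(rna_seq)
    dna_fwd = encode_sequence(dna_seq)
    for name, codes in (("RNA", rna), ("DNA", dna_fwd)):
        frac = _fraction_ambiguous(codes)
        if frac > 0.10:
            logger.warning(
                "%s sequence has %.1f%% ambiguous bases; they score weight 0",
                name,
                100 * frac,
            )
    n, m = len(rna), len(dna_fwd)
    dna_rev = _COMPLEMENT_CODE[dna_fwd][::-1].copy()

    hits: list[TriplexHit] = []
    for dna_strand, dna_codes in (("+", dna_fwd), ("-", dna_rev)):
        for orientation in ("parallel", "antiparallel"):
            rna_codes = rna if orientation == "parallel" else rna[::-1].copy()
            wmat = table.weight_matrix(orientation)
            rows = _scan_diagonals(
                rna_codes,
                dna_codes,
                wmat,
                lg,
                float(params.min_identity),
                float(params.min_stability),
            )
            for i, j, length, matches, wsum in rows:
                if orientation == "parallel":
                    tfo = TranscriptInterval(int(i) + 1, int(i + length))
                else:
                    tfo = TranscriptInterval(int(n - length - i) + 1, int(n - i))
                if dna_strand == "+":
                    gstart = origin + int(j)
                else:
                    gstart = origin + int(m - length - j)
                tts = GenomicInterval(chrom, gstart, gstart + int(length) - 1, dna_strand)
                hits.append(
                    TriplexHit(
                        tfo=tfo,
                        tts=tts,
                        orientation=orientation,
                        dna_strand=dna_strand,
                        length=int(length),
                        identity=100.0 * int(matches) / int(length),
                        stability=int(wsum) / int(length),
                    )
                )
    hits.sort(key=TriplexHit.sort_key)
    return hits


def select_tfo1(hits: list[TriplexHit]) -> Tfo1Cluster:
    """Pick the maximum-coverage cluster of TTS intervals (the TFO1).

    Sweep-line over interval endpoints; among runs of maximal depth, ties go
    to the run whose covering hits have the higher mean stability, then to
    the leftmost run.
    """
    if not hits:
        return Tfo1Cluster(peak_interval=None, hit_count=0, member_hits=())
    events: dict[int, int] = {}
    for h in hits:
        events[h.tts.start] = events.get(h.tts.start, 0) + 1
        events[h.tts.end + 1] = events.get(h.tts.end + 1, 0) - 1
    positions = sorted(events)
    depth = 0
    runs: list[tuple[int, int, int]] = []  # (depth, run_start, run_end)
    for pos, nxt in zip(positions, positions[1:] + [None]):
        depth += events[pos]
        if nxt is not None and depth > 0:
            runs.append((depth, pos, nxt - 1))
    max_depth = max(r[0] for r in runs)
    best = None
    for depth, start, end in runs:
        if depth != max_depth:
            continue
        members = tuple(h for h in hits if h.tts.start <= start and h.tts.end >= end)
        mean_stab = sum(h.stability for h in members) / len(members)
        key = (-mean_stab, start)
        if best is None or key < best[0]:
            best = (key, start, end, members)
    _, start, end, members = best
    chrom = members[0].tts.chrom
    return Tfo1Cluster(
        peak_interval=GenomicInterval(chrom, start, end, "."),
        hit_count=len(members),
        member_hits=members,
    )
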