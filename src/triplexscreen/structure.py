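"""Windowed RNA accessibility: per-base unpaired probabilities (P_unp).

The partition function is computed per sliding window (length ``W``, step 1)
with a McCaskill-style inside/outside dynamic programme over pseudoknot-free
structures.  The energy model is a simple additive base-pair model (defaults
GC -3, AU -2, GU -1, kT 0.616, hairpin loops of at least 3 nt): the screen
consumes only the binary P_unp >= threshold cut, so internal consistency —
exact agreement with brute-force Boltzmann enumeration — is the design goal
rather than parity with a full nearest-neighbour energy engine.  Profile
values are the arithmetic mean of the per-window P_unp over every window
covering a base; accessible regions are maximal runs above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import ScreenParams
from .triads import encode_sequence
from .triplex import TranscriptInterval, TriplexHit

DEFAULT_PAIR_ENERGIES: dict[frozenset[str], float] = {
    frozenset({"G", "C"}): -3.0,
    frozenset({"A", "U"}): -2.0,
    frozenset({"G", "U"}): -1.0,
}


@dataclass(frozen=True)
class EnergyModel:
    """Additive base-pair energy model (kcal/mol-like units, negative = stabilizing)."""

    pair_energies: dict[frozenset[str], float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES)
    )
    min_hairpin: int = 3
    kT: float = 0.616

    def __post_init__(self) -> None:
        allowed = {frozenset(p) for p in ({"G", "C"}, {"A", "U"}, {"G", "U"})}
        for pair in self.pair_energies:
            if frozenset(pair) not in allowed:
                raise ValueError(f"disallowed base pair {set(pair)}")
        if self.min_hairpin < 0:
            raise ValueError("min_hairpin must be >= 0")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    def boltzmann_matrix(self, seq: str, max_span: int | None = None) -> np.ndarray:
        """Pairwise Boltzmann factors for a sequence, honouring hairpin and span rules.

        ``bp[i, j]`` is ``exp(-E(i,j)/kT)`` when bases i and j may pair
        (allowed alphabet pair, ``j - i - 1 >= min_hairpin`` and
        ``j - i + 1 <= max_span``), else 0.  Upper triangle only.
        """
        codes = encode_sequence(seq)  # A=0 C=1 G=2 U=3, ambiguous=4
        letters = "ACGU" + "N"
        n = len(seq)
        bp = np.zeros((n, n), dtype=np.float64)
        for i in range(n):
            for j in range(i + self.min_hairpin + 1, n):
                if max_span is not None and (j - i + 1) > max_span:
                    continue
                key = frozenset({letters[codes[i]], letters[codes[j]]})
                e = self.pair_energies.get(key)
                if e is not None:
                    bp[i, j] = np.exp(-e / self.kT)
        return bp


@dataclass(frozen=True)
class AccessibilityProfile:
    """Per-base unpaired probability over a transcript."""

    punp: np.ndarray
    window: int
    span: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.punp, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError("punp must be a 1-D array")
        if arr.size and (arr.min() < -1e-12 or arr.max() > 1 + 1e-12):
            raise ValueError("P_unp values must lie in [0, 1]")
        object.__setattr__(self, "punp", np.clip(arr, 0.0, 1.0))

    def __len__(self) -> int:
        return self.punp.size


@dataclass(frozen=True)
class AccessibleRegion:
    """Maximal run of consecutive bases with P_unp at or above the threshold."""

    interval: TranscriptInterval
    mean_punp: float


@njit(cache=True)
def _pair_prob_kernel(bp):  # pragma: no cover
    """Pair probability matrix from pairwise Boltzmann factors.

    Inside part: Qh[i, j] = partition function of the half-open region
    [i, j).  Outside part: component-sum over innermost enclosing pairs,
    organised through H[p, l] so the whole computation is O(n^3).
    """
    n = bp.shape[0]
    qh = np.ones((n + 1, n + 2), dtype=np.float64)  # qh[i, j], 0<=i<=j<=n
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            acc = qh[i, j - 1]
            for k in range(i, j - 1):
                if bp[k, j - 1] > 0.0:
                    acc += qh[i, k] * bp[k, j - 1] * qh[k + 1, j - 1]
            qh[i, j] = acc

    pout = np.zeros((n, n), dtype=np.float64)
    h = np.zeros((n, n), dtype=np.float64)  # h[p, l]
    prob = np.zeros((n, n), dtype=np.float64)
    z = qh[0, n]
    for span in range(n - 1, 0, -1):
        # outside values for pairs (k, l) with l - k == span
        for k in range(0, n - span):
            l = k + span
            if bp[k, l] == 0.0:
                continue
            acc = qh[0, k] * qh[l + 1, n]
            for p in range(0, k):
                if h[p, l] > 0.0:
                    acc += h[p, l] * qh[p + 1, k]
            pout[k, l] = acc
            prob[k, l] = bp[k, l] * qh[k + 1, l] * acc / z
            prob[l, k] = prob[k, l]
        # fold this span level into H for the smaller spans
        for p in range(0, n - span):
            q = p + span
            if bp[p, q] > 0.0 and pout[p, q] > 0.0:
                contrib = bp[p, q] * pout[p, q]
                for l in range(p + 1, q):
                    h[p, l] += contrib * qh[l + 1, q]
    return prob


def pair_probabilities(
    seq: str, model: EnergyModel | None = None, max_span: int | None = None
) -> np.ndarray:
    """Symmetric base-pairing probability matrix for one sequence window."""
    model = model or EnergyModel()
    seq = seq.upper().replace("T", "U")
    if len(seq) == 0:
        return np.zeros((0, 0))
    bp = model.boltzmann_matrix(seq, max_span=max_span)
    return _pair_prob_kernel(bp)


def unpaired_profile(
    seq: str, params: ScreenParams, model: EnergyModel | None = None
) -> AccessibilityProfile:
    """Sliding-window P_unp profile (RNAplfold-style, mean over covering windows)."""
    model = model or EnergyModel()
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    w = min(params.fold_window, n)
    if n == 0:
        return AccessibilityProfile(np.zeros(0), params.fold_window, params.fold_span)
    acc = np.zeros(n, dtype=np.float64)
    cov = np.zeros(n, dtype=np.float64)
    for s in range(0, n - w + 1):
        pm = pair_probabilities(seq[s : s + w], model, max_span=params.fold_span)
        punp_w = 1.0 - pm.sum(axis=1)
        acc[s : s + w] += punp_w
        cov[s : s + w] += 1.0
    return AccessibilityProfile(acc / cov, params.fold_window, params.fold_span)


def accessible_regions(
    profile: AccessibilityProfile, threshold: float
) -> list[AccessibleRegion]:
    """Maximal runs of consecutive positions with P_unp >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    punp = profile.punp
    regions: list[AccessibleRegion] = []
    start = None
    for i in range(len(punp) + 1):
        above = i < len(punp) and punp[i] >= threshold
        if above and start is None:
            start = i
        elif not above and start is not None:
            regions.append(
                AccessibleRegion(
                    interval=TranscriptInterval(start + 1, i),
                    mean_punp=float(punp[start:i].mean()),
                )
            )
            start = None
    return regions


def overlap_hits_accessible(
    hits: list[TriplexHit], regions: list[AccessibleRegion]
) -> tuple[int, list[list[int]]]:
    """Count hits whose TFO overlaps at least one accessible region.

    Returns the count and, per hit, the indices of overlapping regions.
    """
    annotations: list[list[int]] = []
    count = 0
    for h in hits:
        idx = [
            i
            for i, r in enumerate(regions)
            if max(h.tfo.start, r.interval.start) <= min(h.tfo.end, r.interval.end)
        ]
        annotations.append(idx)
        if idx:
            count += 1
    return count, annotations
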