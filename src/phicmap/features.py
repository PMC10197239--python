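"""Sequence- and read-derived genome tracks.

parS motif scanning against the degenerate 16-mer consensus
``TGTTTCACGTGAAACA`` (which is its own reverse complement), windowed GC
content / GC skew and the cumulative skew track, ori/ter calling from the
skew inversion with a parS-cluster tie-break, sliding-window read-coverage
profiles, and the secondary-diagonal (replichore arm alignment) signal
profile of a balanced contact map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact import ContactMatrix, circular_distance, expected_by_separation
from .io import GenomeRecord

PARS_CONSENSUS = "TGTTTCACGTGAAACA"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ParSHit:
    """One parS motif match (0-based start of the 16-mer window)."""

    position: int
    strand: str
    mismatches: int


@dataclass
class SkewProfile:
    """Windowed GC skew / GC fraction tracks plus the cumulative skew."""

    window: int
    step: int
    starts: np.ndarray  # window start positions (bp)
    skew: np.ndarray  # (G-C)/(G+C) per window, 0 where G+C == 0
    gc: np.ndarray  # (G+C)/window per window
    zero_gc: np.ndarray  # bool flag where G+C == 0
    cumulative: np.ndarray  # per-base running sum of (G:+1, C:-1), length L
    genome_length: int


@dataclass
class OriTerCall:
    ori: int
    ter: int
    inversion_points: list[int]
    parS_cluster_center: int | None
    low_confidence: bool = False


@dataclass
class CoverageProfile:
    """Tiled-window mean read depth (reads per bp per window)."""

    window: int
    starts: np.ndarray
    depth: np.ndarray
    median: float
    genome_length: int


@dataclass
class DiagonalSignalProfile:
    """Strength of the secondary (anti-)diagonal along the genome.

    ``offsets`` are bin offsets from the ori (profile centered on ori);
    ``values`` are the normalized mean balanced contact on the anti-diagonal
    through each position, smoothed with a circular moving average.
    """

    offsets: np.ndarray
    values: np.ndarray
    min_separation: int
    smooth_bins: int
    ori_bin: int


# ---------------------------------------------------------------------------
# parS scanning


def _seq_to_ints(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[arr]


def _hamming_scan(seq_ints: np.ndarray, motif_ints: np.ndarray, length: int) -> np.ndarray:
    """Mismatch count of the motif at every (circular) offset of the genome."""
    k = motif_ints.size
    ext = np.concatenate([seq_ints, seq_ints[: k - 1]])
    mism = np.zeros(length, dtype=np.int32)
    for j in range(k):
        mism += ext[j : j + length] != motif_ints[j]
    return mism


def scan_parS(
    genome: GenomeRecord,
    consensus: str = PARS_CONSENSUS,
    max_mismatch: int = 2,
) -> list[ParSHit]:
    """All (circular) windows on either strand within ``max_mismatch`` of the
    consensus. A locus matching on both strands is reported once, keeping the
    lower mismatch count ('+' preferred on ties)."""
    consensus = consensus.upper()
    if set(consensus) - set("ACGT"):
        raise ValueError("consensus contains ambiguous bases")
    if max_mismatch > 8:
        raise ValueError("max_mismatch must be <= 8")
    seq = genome.sequence.upper()
    seq_ints = _seq_to_ints(seq)
    length = len(seq)
    fwd = _hamming_scan(seq_ints, _seq_to_ints(consensus), length)
    rev = _hamming_scan(seq_ints, _seq_to_ints(reverse_complement(consensus)), length)
    if not genome.circular:
        k = len(consensus)
        fwd[length - k + 1 :] = k
        rev[length - k + 1 :] = k
    hits = []
    positions = np.flatnonzero((fwd <= max_mismatch) | (rev <= max_mismatch))
    for pos in positions:
        if fwd[pos] <= rev[pos]:
            hits.append(ParSHit(int(pos), "+", int(fwd[pos])))
        else:
            hits.append(ParSHit(int(pos), "-", int(rev[pos])))
    return hits


# ---------------------------------------------------------------------------
# GC tracks


def gc_tracks(genome: GenomeRecord, window: int = 10_000, step: int = 1_000) -> SkewProfile:
    """Windowed (G-C)/(G+C), GC fraction, and per-base cumulative skew.

    Windows are circular, anchored every ``step`` bp.
    """
    if window == 0:
        raise ValueError("window must be positive")
    seq = genome.sequence.upper()
    length = len(seq)
    if window > length:
        raise ValueError("window exceeds genome length")
    if step > window:
        raise ValueError("step must be <= window")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    starts = np.arange(0, length, step, dtype=np.int64)

    def window_sums(track):
        cum = np.concatenate([[0], np.cumsum(np.concatenate([track, track]))])
        return cum[starts + window] - cum[starts]

    g = window_sums(is_g)
    c = window_sums(is_c)
    denom = g + c
    zero = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(zero, 0.0, (g - c) / np.where(zero, 1, denom))
    gc = denom / window
    cumulative = np.cumsum(is_g - is_c).astype(float)
    return SkewProfile(
        window=window,
        step=step,
        starts=starts,
        skew=skew,
        gc=gc,
        zero_gc=zero,
        cumulative=cumulative,
        genome_length=length,
    )


# ---------------------------------------------------------------------------
# ori/ter calling


def _largest_circular_cluster(positions: np.ndarray, radius: int, length: int):
    """Largest single-linkage cluster (gap <= radius) on a circle; returns
    (members, center=circular median)."""
    pos = np.sort(positions)
    n = pos.size
    if n == 1:
        return pos, int(pos[0])
    gaps = np.diff(np.concatenate([pos, [pos[0] + length]]))
    # cut the circle at the largest gap, then cluster linearly
    cut = int(np.argmax(gaps))
    order = np.roll(pos, -cut - 1)
    unrolled = order.copy()
    for i in range(1, n):
        if unrolled[i] < unrolled[i - 1]:
            unrolled[i:] += length
    clusters, current = [], [unrolled[0]]
    for v in unrolled[1:]:
        if v - current[-1] <= radius:
            current.append(v)
        else:
            clusters.append(current)
            current = [v]
    clusters.append(current)
    best = max(clusters, key=len)
    center = int(np.median(best)) % length
    return np.asarray(best) % length, center


def call_ori_ter(
    skew: SkewProfile,
    parS_hits: list[ParSHit] | None = None,
    cluster_radius: int = 100_000,
    smooth_windows: int = 5,
) -> OriTerCall:
    """Call ori and ter from the GC-skew inversion.

    Inversion points are the extremes of the smoothed cumulative skew (the
    loci where the windowed skew changes sign). The inversion closest to the
    parS cluster center is the ori; the one closest to the ori antipode is
    the ter. Without parS hits the cumulative-skew global minimum is taken as
    ori and the call is flagged low-confidence.
    """
    length = skew.genome_length
    # cumulative skew at window-start resolution, circularly smoothed
    cum = skew.cumulative[np.minimum(skew.starts + skew.window // 2, length - 1)]
    # remove the linear trend of a circular walk so extremes are well defined
    drift = skew.cumulative[-1] / length
    centers = (skew.starts + skew.window // 2) % length
    cum = cum - drift * (skew.starts + skew.window // 2)
    if smooth_windows > 1:
        kernel = np.ones(smooth_windows) / smooth_windows
        n = cum.size
        cum = np.convolve(np.concatenate([cum[-smooth_windows:], cum, cum[:smooth_windows]]),
                          kernel, mode="same")[smooth_windows : smooth_windows + n]
    sm_skew = np.gradient(cum)
    signs = np.sign(sm_skew)
    signs = signs[signs != 0]
    if cum.max() - cum.min() == 0 or signs.size == 0 or (signs == signs[0]).all():
        raise ValueError("no skew inversion")
    lo = int(centers[int(np.argmin(cum))])
    hi = int(centers[int(np.argmax(cum))])
    if lo == hi:
        raise ValueError("no skew inversion")
    inversions = sorted({lo, hi})
    if parS_hits:
        positions = np.asarray([h.position for h in parS_hits])
        _, center = _largest_circular_cluster(positions, cluster_radius, length)
        d = [circular_distance(p, center, length) for p in (lo, hi)]
        ori = [lo, hi][int(np.argmin(d))]
        low_confidence = False
        cluster_center = center
    else:
        ori = lo
        low_confidence = True
        cluster_center = None
    antipode = (ori + length // 2) % length
    others = [p for p in (lo, hi) if p != ori]
    ter = min(others, key=lambda p: circular_distance(p, antipode, length))
    return OriTerCall(
        ori=ori,
        ter=ter,
        inversion_points=inversions,
        parS_cluster_center=cluster_center,
        low_confidence=low_confidence,
    )


# ---------------------------------------------------------------------------
# Coverage


def coverage_profile(
    positions: np.ndarray | list[int], genome_length: int, window: int = 10_000
) -> CoverageProfile:
    """Tiled-window read counts normalized to per-bp depth; an empty position
    list yields an all-zero profile."""
    if window < 1:
        raise ValueError("window must be >= 1")
    positions = np.asarray(positions, dtype=np.int64)
    n_win = -(-genome_length // window)
    counts = np.bincount(positions // window, minlength=n_win).astype(float)
    starts = np.arange(n_win, dtype=np.int64) * window
    widths = np.minimum(starts + window, genome_length) - starts
    depth = counts / widths
    return CoverageProfile(
        window=window,
        starts=starts,
        depth=depth,
        median=float(np.median(depth)),
        genome_length=genome_length,
    )


# ---------------------------------------------------------------------------
# Secondary diagonal (arm alignment) signal


def secondary_diagonal_signal(
    m: ContactMatrix,
    ori_bin: int,
    min_separation: int = 10,
    smooth_bins: int | None = None,
) -> DiagonalSignalProfile:
    """Strength of each anti-diagonal of a balanced map, centered on ori.

    For each anti-diagonal class ``k`` (bin pairs with ``i + j = k mod N``),
    the signal is the mean of ``M[i,j] / E[sep(i,j)]`` over unmasked pairs
    with circular separation greater than ``min_separation``, where ``E`` is
    the genome-wide mean contact at the same separation. The profile is
    indexed by the genome position the anti-diagonal reflects through
    (``k/2``), smoothed with a circular moving average, and rotated so the
    ori sits at the center.
    """
    if not m.balanced:
        raise ValueError("secondary_diagonal_signal requires a balanced matrix")
    n = m.n_bins
    if not 1 <= min_separation < n / 4:
        raise ValueError("min_separation must be in [1, N/4)")
    if smooth_bins is None:
        smooth_bins = max(5, n // 20)
    if smooth_bins % 2 == 0:
        smooth_bins += 1
    exp = expected_by_separation(m)
    idx = np.arange(n)
    i_grid, j_grid = np.meshgrid(idx, idx, indexing="ij")
    sep = np.abs(i_grid - j_grid)
    sep = np.minimum(sep, n - sep)
    ok = (sep > min_separation) & ~(m.masked[:, None] | m.masked[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = m.matrix / exp[sep]
    ok &= np.isfinite(ratio)
    k = (i_grid + j_grid) % n
    sums = np.bincount(k[ok], weights=ratio[ok], minlength=n)
    cnts = np.bincount(k[ok], minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        signal_k = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    # anti-diagonal through genome position b has k = 2b (mod N)
    profile = signal_k[(2 * idx) % n]
    # circular moving average
    kernel = np.ones(smooth_bins) / smooth_bins
    padded = np.concatenate([profile[-smooth_bins:], profile, profile[:smooth_bins]])
    nan = np.isnan(padded)
    filled = np.where(nan, np.nanmean(profile), padded)
    smoothed = np.convolve(filled, kernel, mode="same")[smooth_bins : smooth_bins + n]
    # rotate so ori maps to the center bin
    center = n // 2
    rotated = np.roll(smoothed, center - (ori_bin % n))
    offsets = idx - center
    return DiagonalSignalProfile(
        offsets=offsets,
        values=rotated,
        min_separation=min_separation,
        smooth_bins=smooth_bins,
        ori_bin=ori_bin,
    )
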