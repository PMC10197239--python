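"""Virome quantification of prophage induction.

RPKM per prophage region (reads per kb of region per million mapped reads),
spike-in calibration to absolute VLP/g, excision/circularization junction
detection from discordant read pairs at the prophage edges, and a
fold-over-background induction call.

A read counts toward a region iff its mapped start lies within the region
(start-based counting, depth-invariant). The alignment table has one row per
read pair with 0-based positions in memory (see :mod:`phicmap.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CoverageProfile


@dataclass
class RegionQuant:
    region: tuple[int, int]
    name: str
    mapped_reads: int
    rpkm: float
    induced: bool | None = None


@dataclass
class SpikeCalibration:
    spike_id: str
    pfu_added: float
    spike_rpkm: float
    sample_weight: float

    def __post_init__(self):
        if self.pfu_added <= 0:
            raise ValueError("pfu_added must be positive")
        if self.sample_weight <= 0:
            raise ValueError("sample_weight must be positive")


@dataclass
class JunctionCall:
    left: int
    right: int
    supporting_pairs: int
    refined_phage_interval: tuple[int, int]
    discordant_orientation_pairs: int = 0


def _read_starts(alignments: pd.DataFrame, ref: str) -> np.ndarray:
    """Mapped starts of both mates on the given reference."""
    a = alignments.loc[alignments["ref"] == ref, "pos"].to_numpy(np.int64)
    b = alignments.loc[alignments["mate_ref"] == ref, "mate_pos"].to_numpy(np.int64)
    return np.concatenate([a, b])


def region_rpkm(
    alignments: pd.DataFrame,
    regions: list[tuple[int, int]],
    total_mapped: int,
    ref: str,
    replicon_length: int | None = None,
    names: list[str] | None = None,
) -> list[RegionQuant]:
    """RPKM per region: ``reads / (total_mapped / 1e6) / (length / 1e3)``.

    ``total_mapped`` counts individual reads (two per pair) mapped anywhere
    in the reference set.
    """
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    starts = _read_starts(alignments, ref)
    quants = []
    for i, (start, end) in enumerate(regions):
        if end <= start:
            raise ValueError(f"degenerate region {(start, end)}")
        if replicon_length is not None and (start < 0 or end > replicon_length):
            raise ValueError(f"region {(start, end)} outside replicon of length {replicon_length}")
        n = int(((starts >= start) & (starts < end)).sum())
        rpkm = n / (total_mapped / 1e6) / ((end - start) / 1e3)
        name = names[i] if names else f"region_{i}"
        quants.append(RegionQuant(region=(start, end), name=name, mapped_reads=n, rpkm=rpkm))
    return quants


def spike_rpkm(
    alignments: pd.DataFrame, spike_id: str, spike_length: int, total_mapped: int
) -> float:
    """RPKM of a spiked phage genome (whole reference as the region)."""
    n = int((alignments["ref"] == spike_id).sum() + (alignments["mate_ref"] == spike_id).sum())
    return n / (total_mapped / 1e6) / (spike_length / 1e3)


def estimate_vlp_per_gram(
    quants: list[RegionQuant], spike: SpikeCalibration
) -> tuple[float, dict[str, float]]:
    """Absolute quantification against the spike.

    Each region's VLP count is ``rpkm * pfu_added / spike_rpkm``; the sample
    VLP/g sums the per-region estimates (induced prophage regions are what
    callers should pass) and divides by the fecal sample weight.
    """
    if spike.spike_rpkm <= 0:
        raise ValueError("spike not detected (spike RPKM is zero)")
    per_region = {q.name: q.rpkm * spike.pfu_added / spike.spike_rpkm for q in quants}
    total = sum(per_region.values())
    return total / spike.sample_weight, per_region


def detect_circularization(
    alignments: pd.DataFrame,
    predicted: tuple[int, int],
    ref: str,
    edge_window: int = 500,
    min_support: int = 5,
    read_length: int = 35,
) -> JunctionCall | None:
    """Call the excision/circularization junction of an induced prophage.

    Candidate pairs have one mate starting within ``edge_window`` of the
    predicted left border and the other mate ending within ``edge_window`` of
    the right border, with orientations consistent with reads crossing the
    junction of an excised circle: the left-edge mate on the reverse strand
    (pointing off the left edge) and the right-edge mate on the forward
    strand (pointing off the right edge). Pairs at the edges with any other
    orientation are tallied separately as a diagnostic.

    With at least ``min_support`` consistent pairs, the junction is the
    5'-most left-edge mate start and the 3'-most right-edge mate end, and the
    refined phage interval is ``[left, right)``. Returns ``None`` otherwise.
    """
    left_b, right_b = predicted
    if edge_window >= (right_b - left_b) / 2:
        raise ValueError("edge_window must be smaller than half the interval")
    both = alignments[(alignments["ref"] == ref) & (alignments["mate_ref"] == ref)]
    p1 = both["pos"].to_numpy(np.int64)
    p2 = both["mate_pos"].to_numpy(np.int64)
    s1 = both["strand"].to_numpy()
    s2 = both["mate_strand"].to_numpy()

    def classify(pos, strand):
        near_left = np.abs(pos - left_b) <= edge_window
        near_right = np.abs(pos + read_length - right_b) <= edge_window
        return near_left, near_right, strand

    l1, r1, _ = classify(p1, s1)
    l2, r2, _ = classify(p2, s2)
    # mate A at the left edge, mate B at the right edge (either order)
    cand_ab = l1 & r2
    cand_ba = l2 & r1
    ori_ab = cand_ab & (s1 == "-") & (s2 == "+")
    ori_ba = cand_ba & (s2 == "-") & (s1 == "+")
    consistent = ori_ab | ori_ba
    discordant = int(((cand_ab | cand_ba) & ~consistent).sum())
    n_support = int(consistent.sum())
    if n_support < min_support:
        return None
    left_starts = np.concatenate([p1[ori_ab], p2[ori_ba]])
    right_ends = np.concatenate([p2[ori_ab], p1[ori_ba]]) + read_length
    left = int(left_starts.min())
    right = int(right_ends.max())
    return JunctionCall(
        left=left,
        right=right,
        supporting_pairs=n_support,
        refined_phage_interval=(left, right),
        discordant_orientation_pairs=discordant,
    )


def host_background_rpkm(
    alignments: pd.DataFrame,
    ref: str,
    replicon_length: int,
    prophage_regions: list[tuple[int, int]],
    window: int,
    total_mapped: int,
) -> float:
    """Median RPKM of prophage-free control windows of the given size tiled
    along the host chromosome."""
    starts = _read_starts(alignments, ref)
    controls = []
    for w0 in range(0, replicon_length - window + 1, window):
        w1 = w0 + window
        if any(w0 < e and s < w1 for s, e in prophage_regions):
            continue
        n = int(((starts >= w0) & (starts < w1)).sum())
        controls.append(n / (total_mapped / 1e6) / (window / 1e3))
    if not controls:
        raise ValueError("no prophage-free control windows available")
    return float(np.median(controls))


def induction_call(
    quants: list[RegionQuant],
    host_background: float,
    fold_threshold: float = 10.0,
) -> list[RegionQuant]:
    """Flag regions whose RPKM reaches ``fold_threshold`` times the host
    background RPKM (median of equally sized prophage-free windows)."""
    if host_background < 0:
        raise ValueError("host background RPKM must be nonnegative")
    for q in quants:
        q.induced = bool(q.rpkm >= fold_threshold * host_background and q.rpkm > 0)
    return quants
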