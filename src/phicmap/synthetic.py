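"""Synthetic data with known ground truth.

Generates circular bacterial genomes with a GC-skew inversion at ori/ter and
implanted parS motifs, Hi-C contact pairs with power-law distance decay, CID
blocks, a parS/ori-anchored secondary diagonal and prophage signals
(elevated coverage, corner loop), and virome read-pair alignment tables with
spike-ins and circle-consistent excision-junction pairs.

Every generator takes an explicit integer seed and is byte-deterministic for
identical (parameters, seed). Circular distance everywhere is
``min(|p1-p2|, L-|p1-p2|)``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .contact import ContactPairs
from .features import PARS_CONSENSUS
from .io import GenomeRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ProphageSpec:
    """One implanted prophage interval and its activity implants."""

    start: int
    end: int
    induced: bool = False
    coverage_fold: float = 1.0
    loop_strength: float = 1.0
    junction_pair_count: int = 0
    name: str = "prophage"


@dataclass
class SpikeSpec:
    spike_id: str
    length: int
    pfu_added: float
    sample_weight: float


@dataclass
class SyntheticTruth:
    """All implanted parameters of a synthetic study system."""

    genome_length: int
    ori_pos: int
    ter_pos: int
    parS_sites: list = field(default_factory=list)  # (position, mismatches)
    domain_boundaries: list = field(default_factory=list)  # bp, sorted unique
    arm_alignment_strength: float = 1.0
    prophage_specs: list = field(default_factory=list)
    spike_specs: list = field(default_factory=list)
    seed: int = 0
    skew_positive_ori_to_ter: bool = True

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        L = self.genome_length
        if self.ori_pos == self.ter_pos:
            raise ValueError("ori and ter must differ")
        for pos in (self.ori_pos, self.ter_pos):
            if not 0 <= pos < L:
                raise ValueError(f"position {pos} outside [0, {L})")
        for pos, mm in self.parS_sites:
            if not 0 <= pos < L:
                raise ValueError(f"parS position {pos} outside [0, {L})")
            if not 0 <= mm <= 2:
                raise ValueError("parS mismatch count must be in 0..2")
        b = list(self.domain_boundaries)
        if b != sorted(set(b)):
            raise ValueError("domain boundaries must be sorted and unique")
        if any(not 0 <= x < L for x in b):
            raise ValueError("domain boundary outside genome")
        if self.arm_alignment_strength < 1:
            raise ValueError("arm_alignment_strength must be >= 1")
        for p in self.prophage_specs:
            if not (0 <= p.start < p.end <= L):
                raise ValueError(f"prophage interval {(p.start, p.end)} outside [0, {L}]")
            if not p.induced and p.coverage_fold != 1.0:
                raise ValueError("coverage_fold must be 1 for non-induced prophages")
            if p.coverage_fold < 1 or p.loop_strength < 1 or p.junction_pair_count < 0:
                raise ValueError("prophage implant strengths must be >= 1 (counts >= 0)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        d["parS_sites"] = [tuple(x) for x in d.get("parS_sites", [])]
        d["prophage_specs"] = [ProphageSpec(**p) for p in d.get("prophage_specs", [])]
        d["spike_specs"] = [SpikeSpec(**s) for s in d.get("spike_specs", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# Genome simulation


def _mutate_motif(motif: str, n_sub: int, rng: np.random.Generator) -> str:
    """The consensus with exactly ``n_sub`` substitutions."""
    arr = np.frombuffer(motif.encode("ascii"), dtype=np.uint8).copy()
    sites = rng.choice(len(motif), size=n_sub, replace=False)
    for s in sites:
        choices = BASES[BASES != arr[s]]
        arr[s] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_genome(
    length: int,
    ori_pos: int,
    ter_pos: int,
    parS_sites: list[tuple[int, int]] = (),
    skew_amplitude: float = 0.2,
    seed: int = 0,
    gc_content: float = 0.5,
    name: str = "synthetic_chr",
) -> tuple[GenomeRecord, SyntheticTruth]:
    """A circular genome whose GC skew is ``+amplitude`` on the ori->ter
    replichore and ``-amplitude`` on the other, with exact-mismatch parS
    motifs implanted at the requested positions."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if not 0 < skew_amplitude <= 0.5:
        raise ValueError("skew_amplitude must be in (0, 0.5]")
    if ori_pos == ter_pos:
        raise ValueError("ori and ter must differ")
    parS_sites = list(parS_sites)
    # reject overlapping 16-mer implants (circularly)
    k = len(PARS_CONSENSUS)
    sorted_sites = sorted(p for p, _ in parS_sites)
    for a, b in zip(sorted_sites, sorted_sites[1:] + [s + length for s in sorted_sites[:1]]):
        if b - a < k:
            raise ValueError("overlapping parS implants")

    rng = np.random.default_rng(seed)
    pos = np.arange(length, dtype=np.int64)
    on_first = ((pos - ori_pos) % length) < ((ter_pos - ori_pos) % length)
    sign = np.where(on_first, 1.0, -1.0)
    p_a = (1 - gc_content) / 2
    p_g = gc_content * (1 + sign * skew_amplitude) / 2
    u = rng.random(length)
    # cumulative thresholds: A | T | G | C
    seq = np.empty(length, dtype=np.uint8)
    seq[:] = ord("C")
    seq[u < p_a + p_a + p_g] = ord("G")
    seq[u < 2 * p_a] = ord("T")
    seq[u < p_a] = ord("A")
    for site_pos, mm in parS_sites:
        if not 0 <= mm <= 2:
            raise ValueError("parS mismatch count must be in 0..2")
        motif = np.frombuffer(_mutate_motif(PARS_CONSENSUS, mm, rng).encode(), dtype=np.uint8)
        idx = (site_pos + np.arange(k)) % length
        seq[idx] = motif
    genome = GenomeRecord(name=name, sequence=seq.tobytes().decode("ascii"), circular=True)
    truth = SyntheticTruth(
        genome_length=length,
        ori_pos=ori_pos,
        ter_pos=ter_pos,
        parS_sites=parS_sites,
        seed=seed,
        skew_positive_ori_to_ter=True,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Hi-C contact pairs


def contact_weight_matrix(
    truth: SyntheticTruth,
    bin_size: int,
    decay_exponent: float,
    domain_factor: float | list[float] = 2.0,
    arm_kernel_bins: float = 2.0,
) -> np.ndarray:
    """Bin-level sampling weights implementing power-law decay, CID blocks,
    the ori-anchored anti-diagonal, and prophage coverage/loop implants.

    ``domain_factor`` enriches same-segment pairs between consecutive domain
    boundaries; a scalar applies uniformly, a list gives one factor per
    segment (segment k spans boundary k-1 to boundary k, segment 0 wrapping
    past the last boundary). Induced-prophage copy number scales the weight
    by ``coverage_fold`` per prophage endpoint (so within-prophage pairs get
    the square), the way contact counts scale with DNA copy number.
    """
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be > 0")
    L = truth.genome_length
    n = -(-L // bin_size)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    sep = np.minimum(sep, n - sep)
    w = (1.0 + sep) ** (-decay_exponent)

    boundaries = sorted({b // bin_size for b in truth.domain_boundaries})
    if len(boundaries) >= 2:
        seg = np.searchsorted(boundaries, idx, side="right") % len(boundaries)
        factors = (
            np.full(len(boundaries), float(domain_factor))
            if np.isscalar(domain_factor)
            else np.asarray(domain_factor, dtype=float)
        )
        if factors.size != len(boundaries):
            raise ValueError("need one domain factor per segment")
        same = seg[:, None] == seg[None, :]
        w[same] *= factors[seg[:, None].repeat(n, axis=1)][same]

    if truth.arm_alignment_strength > 1:
        ori_bin = truth.ori_pos // bin_size
        k = (idx[:, None] + idx[None, :]) % n
        target = (2 * ori_bin) % n
        dk = np.abs(k - target)
        dk = np.minimum(dk, n - dk) / 2.0  # anti-diagonal index -> bin units
        w *= 1.0 + (truth.arm_alignment_strength - 1.0) * np.exp(-dk / arm_kernel_bins)

    copy_number = np.ones(n)
    for p in truth.prophage_specs:
        b0, b1 = p.start // bin_size, -(-p.end // bin_size)
        pbins = np.arange(b0, b1) % n
        if p.induced and p.coverage_fold > 1:
            copy_number[pbins] *= p.coverage_fold
        if p.loop_strength > 1:
            lo, hi = b0 % n, (b1 - 1) % n
            w[lo, hi] *= p.loop_strength
            w[hi, lo] *= p.loop_strength
    w *= np.outer(copy_number, copy_number)
    return w


def simulate_contact_pairs(
    truth: SyntheticTruth,
    n_pairs: int,
    decay_exponent: float = 1.0,
    bin_size: int = 10_000,
    seed: int = 0,
    domain_factor: float | list[float] = 2.0,
    arm_kernel_bins: float = 2.0,
    replicon: str = "synthetic_chr",
) -> ContactPairs:
    """Sample exactly ``n_pairs`` contact pairs from the bin-level weights,
    with uniform placement within bins."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    L = truth.genome_length
    n = -(-L // bin_size)
    if n < 50:
        raise ValueError("bin_size must divide the genome into >= 50 bins")
    w = contact_weight_matrix(truth, bin_size, decay_exponent, domain_factor, arm_kernel_bins)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n)
    probs = w[iu]
    probs = probs / probs.sum()
    counts = rng.multinomial(n_pairs, probs)
    nonzero = counts > 0
    b1 = np.repeat(iu[0][nonzero], counts[nonzero])
    b2 = np.repeat(iu[1][nonzero], counts[nonzero])
    widths = np.minimum((np.arange(n) + 1) * bin_size, L) - np.arange(n) * bin_size
    p1 = b1 * bin_size + rng.integers(0, widths[b1])
    p2 = b2 * bin_size + rng.integers(0, widths[b2])
    positions = np.column_stack([p1, p2])
    return ContactPairs(replicon=replicon, positions=positions, length=L)


def pairs_to_frame(pairs: ContactPairs) -> pd.DataFrame:
    """4DN-style pairs table (strands not modeled; reported as '+')."""
    n = pairs.n_pairs
    return pd.DataFrame(
        {
            "readID": [f"pair_{i}" for i in range(n)],
            "chrom1": pairs.replicon,
            "pos1": pairs.positions[:, 0],
            "chrom2": pairs.replicon,
            "pos2": pairs.positions[:, 1],
            "strand1": "+",
            "strand2": "+",
        }
    )


# ---------------------------------------------------------------------------
# Virome read-pair alignments


def _sample_outside(
    rng: np.random.Generator, n: int, length: int, forbidden: list[tuple[int, int]], span: int
) -> np.ndarray:
    """Uniform fragment starts whose [p, p+span) avoids all forbidden intervals."""
    out = np.empty(n, dtype=np.int64)
    got = 0
    while got < n:
        cand = rng.integers(0, length - span, size=max(2 * (n - got), 16))
        ok = np.ones(cand.size, dtype=bool)
        for s, e in forbidden:
            ok &= (cand + span <= s) | (cand >= e)
        cand = cand[ok][: n - got]
        out[got : got + cand.size] = cand
        got += cand.size
    return out


def simulate_virome_alignments(
    truth: SyntheticTruth,
    n_read_pairs: int,
    read_length: int = 35,
    background_fraction: float = 0.1,
    seed: int = 0,
    host_name: str = "synthetic_chr",
) -> pd.DataFrame:
    """A virome alignment table (one row per read pair, 0-based positions).

    Reads are drawn from induced prophages in proportion to
    ``coverage_fold x length`` and from spikes in proportion to
    ``pfu_added x length``; ``background_fraction`` of pairs fall uniformly
    on the host chromosome outside prophages; exactly
    ``junction_pair_count`` circle-consistent junction pairs are placed at
    the edges of each induced prophage (left-edge mate on '-', right-edge
    mate on '+'). The emitted pair count equals ``n_read_pairs`` exactly.
    """
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0, 1)")
    for p in truth.prophage_specs:
        if p.junction_pair_count > 0 and not p.induced:
            raise ValueError(f"junction pairs requested for non-induced prophage {p.name}")
        if read_length >= p.end - p.start:
            raise ValueError("read_length must be smaller than the shortest prophage")
    L = truth.genome_length
    rng = np.random.default_rng(seed)
    induced = [p for p in truth.prophage_specs if p.induced]
    n_junction = sum(p.junction_pair_count for p in induced)
    n_background = int(round(background_fraction * n_read_pairs))
    n_source = n_read_pairs - n_junction - n_background
    if n_source < 0:
        raise ValueError("n_read_pairs too small for requested junction/background pairs")

    sources: list[tuple[str, str, int, int, float]] = []  # (kind, ref, start, end, weight)
    for p in induced:
        sources.append(("prophage", host_name, p.start, p.end, p.coverage_fold * (p.end - p.start)))
    for s in truth.spike_specs:
        sources.append(("spike", s.spike_id, 0, s.length, s.pfu_added * s.length))

    weights = np.asarray([s[4] for s in sources], dtype=float)
    if weights.sum() > 0:
        counts = rng.multinomial(n_source, weights / weights.sum())
    else:
        counts = np.zeros(len(sources), dtype=int)
        n_background += n_source

    rows = []
    insert = 3 * read_length
    for (kind, ref, start, end, _w), c in zip(sources, counts):
        if c == 0:
            continue
        span = min(insert, end - start)
        p0 = start + rng.integers(0, max(end - start - span, 1), size=c)
        for p in p0:
            rows.append((ref, int(p), "+", ref, int(p + span - read_length), "-"))
    if n_background:
        forbidden = [(p.start, p.end) for p in truth.prophage_specs]
        p0 = _sample_outside(rng, n_background, L, forbidden, insert)
        for p in p0:
            rows.append((host_name, int(p), "+", host_name, int(p + insert - read_length), "-"))
    for p in induced:
        if p.junction_pair_count == 0:
            continue
        lpos = p.start + rng.integers(0, read_length, size=p.junction_pair_count)
        rpos = p.end - 2 * read_length + rng.integers(0, read_length, size=p.junction_pair_count)
        for lp, rp in zip(lpos, rpos):
            rows.append((host_name, int(lp), "-", host_name, int(rp), "+"))

    df = pd.DataFrame(rows, columns=["ref", "pos", "strand", "mate_ref", "mate_pos", "mate_strand"])
    df.insert(0, "read_id", [f"vread_{i}" for i in range(len(df))])
    assert len(df) == n_read_pairs
    return df


# ---------------------------------------------------------------------------
# The packaged study system: a 5-prophage consortium genome


def consortium_truth(seed: int = 0) -> SyntheticTruth:
    """The canonical 5-prophage synthetic study system.

    A 2 Mb circular genome with an ori/ter skew inversion, a parS cluster by
    the ori, an arm-alignment anti-diagonal, three functional prophages
    (CID block + corner loop + elevated coverage + junction pairs; all
    induced) and two cryptic prophages carrying no 3D or activity implants.
    """
    prophages = [
        ProphageSpec(400_000, 450_000, induced=True, coverage_fold=10.0, loop_strength=5.0,
                     junction_pair_count=200, name="P1_functional"),
        ProphageSpec(700_000, 740_000, induced=True, coverage_fold=5.0, loop_strength=4.0,
                     junction_pair_count=120, name="P2_functional"),
        ProphageSpec(1_500_000, 1_540_000, induced=True, coverage_fold=4.0, loop_strength=5.0,
                     junction_pair_count=80, name="P3_functional"),
        ProphageSpec(900_000, 940_000, name="C1_cryptic"),
        ProphageSpec(1_700_000, 1_745_000, name="C2_cryptic"),
    ]
    boundaries = sorted(
        b for p in prophages[:3] for b in (p.start, p.end)
    )
    ori = 200_000
    return SyntheticTruth(
        genome_length=2_000_000,
        ori_pos=ori,
        ter_pos=1_200_000,
        parS_sites=[(ori - 30_000, 0), (ori + 10_000, 1), (ori + 25_000, 2)],
        domain_boundaries=boundaries,
        arm_alignment_strength=3.0,
        prophage_specs=prophages,
        spike_specs=[SpikeSpec("spike_phage", 6_000, pfu_added=30.0, sample_weight=0.25)],
        seed=seed,
    )


def simulate_consortium(
    seed: int = 0,
    n_pairs: int = 1_000_000,
    n_read_pairs: int = 100_000,
    bin_size: int = 5_000,
    skew_amplitude: float = 0.2,
) -> dict:
    """Generate the full consortium bundle: genome, truth, contact pairs and
    virome alignments, all from one seed."""
    truth = consortium_truth(seed)
    genome, gtruth = simulate_genome(
        truth.genome_length,
        truth.ori_pos,
        truth.ter_pos,
        parS_sites=truth.parS_sites,
        skew_amplitude=skew_amplitude,
        seed=seed,
        name="consortium_chr",
    )
    # segments alternate gap / prophage starting at the first boundary (P1);
    # prophage segments are enriched over the gaps so their CID square scores
    # above the flanking windows
    segment_factors = [1.25, 4.0, 1.25, 4.0, 1.25, 4.0]
    pairs = simulate_contact_pairs(
        truth, n_pairs=n_pairs, decay_exponent=1.0, bin_size=bin_size, seed=seed + 1,
        domain_factor=segment_factors, replicon=genome.name,
    )
    alignments = simulate_virome_alignments(
        truth, n_read_pairs=n_read_pairs, read_length=35, background_fraction=0.1,
        seed=seed + 2, host_name=genome.name,
    )
    return {
        "truth": truth,
        "genome": genome,
        "pairs": pairs,
        "alignments": alignments,
        "bin_size": bin_size,
        "read_length": 35,
    }
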