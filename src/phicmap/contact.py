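"""Binned Hi-C contact matrices: construction, ICE balancing, downsampling,
log2-ratio comparison, the genomic distance law, and HiCrep-style SCC.

All replicons are treated as circular; the circular genomic distance between
two positions is ``s = min(|p1-p2|, L - |p1-p2|)``. Bins are 0-based half-open
``[k*bin_size, (k+1)*bin_size)``; the last bin may be short.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


def circular_distance(p1, p2, length):
    """Circular distance ``min(|p1-p2|, L-|p1-p2|)`` (vectorized)."""
    d = np.abs(np.asarray(p1) - np.asarray(p2))
    return np.minimum(d, length - d)


@dataclass
class ContactPairs:
    """Unbinned Hi-C contact pairs on one (circular) replicon."""

    replicon: str
    positions: np.ndarray  # (n, 2) int array of 0-based bp
    length: int
    circular: bool = True

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64).reshape(-1, 2)
        bad = (self.positions < 0) | (self.positions >= self.length)
        if bad.any():
            idx = int(np.flatnonzero(bad.any(axis=1))[0])
            raise ValueError(
                f"pair record {idx} has position outside [0, {self.length}): "
                f"{tuple(self.positions[idx])}"
            )

    @property
    def n_pairs(self) -> int:
        return self.positions.shape[0]


@dataclass
class ContactMatrix:
    """Symmetric binned contact map with optional balancing state."""

    replicon: str
    bin_size: int
    matrix: np.ndarray
    total_contacts: float
    balanced: bool = False
    bias: np.ndarray | None = None
    masked: np.ndarray | None = None  # bool, True = excluded bin
    replicon_length: int | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if self.masked is None:
            self.masked = np.zeros(n, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def copy(self) -> "ContactMatrix":
        return replace(
            self,
            matrix=self.matrix.copy(),
            bias=None if self.bias is None else self.bias.copy(),
            masked=self.masked.copy(),
        )


@dataclass
class DistanceLaw:
    """Mean contact per bin-pair in log-spaced circular-distance strata."""

    strata_bp: np.ndarray  # stratum lower edges in bp, ascending
    values: np.ndarray  # mean contact per bin-pair per stratum
    bin_size: int


# ---------------------------------------------------------------------------


def bin_pairs(pairs: ContactPairs, bin_size: int) -> ContactMatrix:
    """Accumulate contact pairs into a symmetric binned matrix.

    Each pair increments ``M[b1, b2]`` and its mirror by 1; intra-bin pairs
    increment the diagonal entry once.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = -(-pairs.length // bin_size)  # ceil
    if n < 2:
        raise ValueError("need at least 2 bins")
    b1 = pairs.positions[:, 0] // bin_size
    b2 = pairs.positions[:, 1] // bin_size
    m = np.zeros((n, n))
    np.add.at(m, (b1, b2), 1.0)
    np.add.at(m, (b2, b1), 1.0)
    # intra-bin pairs were added twice on the diagonal; count them once
    diag_counts = np.bincount(b1[b1 == b2], minlength=n).astype(float)
    m[np.diag_indices(n)] -= diag_counts
    return ContactMatrix(
        replicon=pairs.replicon,
        bin_size=bin_size,
        matrix=m,
        total_contacts=float(pairs.n_pairs),
        replicon_length=pairs.length,
    )


def ice_balance(
    m: ContactMatrix,
    max_iter: int = 300,
    tol: float = 1e-6,
    min_coverage_fraction: float = 0.1,
) -> ContactMatrix:
    """Iterative correction (ICE): equalize bin visibility by iterative
    proportional fitting of per-bin biases until row sums converge.

    Bins whose raw marginal falls below ``min_coverage_fraction`` times the
    mean marginal are masked and excluded. The accumulated bias vector is
    stored so that ``raw[i,j] = balanced[i,j] * bias[i] * bias[j]``.
    """
    if m.balanced:
        raise ValueError("matrix is already balanced")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    w = m.matrix.astype(float).copy()
    n = w.shape[0]
    marg = w.sum(axis=1)
    masked = m.masked | (marg < min_coverage_fraction * marg.mean())
    if masked.all():
        raise ValueError("all bins masked: no bin passes the coverage filter")
    w[masked, :] = 0.0
    w[:, masked] = 0.0
    bias = np.ones(n)
    active = ~masked
    for _ in range(max_iter):
        s = w.sum(axis=1)
        s_mean = s[active].mean()
        if s_mean == 0:
            raise ValueError("all unmasked bins have zero marginal")
        db = np.where(active & (s > 0), s / s_mean, 1.0)
        w /= np.outer(db, db)
        bias *= db
        if np.abs(db - 1.0).max() < tol:
            break
    bias_out = np.where(active, bias, np.nan)
    return ContactMatrix(
        replicon=m.replicon,
        bin_size=m.bin_size,
        matrix=w,
        total_contacts=m.total_contacts,
        balanced=True,
        bias=bias_out,
        masked=masked,
        replicon_length=m.replicon_length,
    )


def downsample(m: ContactMatrix, target: int, seed: int) -> ContactMatrix:
    """Subsample contacts without replacement (multivariate hypergeometric on
    the upper-triangle pixel counts) down to exactly ``target`` contacts."""
    if m.balanced:
        raise ValueError("downsample operates on raw (unbalanced) matrices")
    counts = m.matrix
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("downsample requires integer contact counts")
    n = m.n_bins
    iu = np.triu_indices(n)
    colors = np.round(counts[iu]).astype(np.int64)
    total = int(colors.sum())
    if not 1 <= target <= total:
        raise ValueError(f"target {target} outside [1, {total}]")
    if target == total:
        out = counts.copy()
    else:
        rng = np.random.default_rng(seed)
        sub = rng.multivariate_hypergeometric(colors, target, method="marginals")
        out = np.zeros_like(counts)
        out[iu] = sub
        out = out + out.T - np.diag(np.diag(out))
    return ContactMatrix(
        replicon=m.replicon,
        bin_size=m.bin_size,
        matrix=out,
        total_contacts=float(target),
        masked=m.masked.copy(),
        replicon_length=m.replicon_length,
    )


def log2_ratio(m1: ContactMatrix, m2: ContactMatrix, pseudocount: float = 1.0) -> np.ndarray:
    """Signed log2 comparison map after scaling to equal totals.

    Bins masked in either input are NaN in the output.
    """
    if m1.matrix.shape != m2.matrix.shape or m1.bin_size != m2.bin_size:
        raise ValueError("matrices must share shape and bin size")
    if m1.balanced != m2.balanced:
        raise ValueError("compare two balanced or two raw matrices, not a mix")
    a = m1.matrix.astype(float)
    b = m2.matrix.astype(float)
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise ValueError("empty matrix in ratio")
    scale = sa / sb
    out = np.log2((a + pseudocount) / (b * scale + pseudocount))
    masked = m1.masked | m2.masked
    out[masked, :] = np.nan
    out[:, masked] = np.nan
    return out


def _circular_sep_matrix(n: int) -> np.ndarray:
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n - d)


def expected_by_separation(m: ContactMatrix) -> np.ndarray:
    """Genome-wide mean contact at each circular bin separation 0..N//2,
    computed over unmasked bin pairs. NaN where no pairs contribute."""
    n = m.n_bins
    sep = _circular_sep_matrix(n)
    ok = ~(m.masked[:, None] | m.masked[None, :])
    nmax = n // 2
    sums = np.bincount(sep[ok], weights=m.matrix[ok], minlength=nmax + 1)
    cnts = np.bincount(sep[ok], minlength=nmax + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnts > 0, sums / cnts, np.nan)


def distance_law(m: ContactMatrix, n_strata: int = 30) -> DistanceLaw:
    """Mean contact per bin-pair in log-spaced circular-distance strata."""
    n = m.n_bins
    if n < 4:
        raise ValueError("need at least 4 bins for a distance law")
    exp = expected_by_separation(m)  # per bin separation
    max_sep = n // 2
    edges_bins = np.unique(
        np.round(np.logspace(0, np.log10(max_sep), n_strata)).astype(int)
    )
    edges_bins = edges_bins[edges_bins >= 1]
    sep_counts = _pair_counts_by_separation(m)
    lows, vals = [], []
    for k, lo in enumerate(edges_bins):
        hi = edges_bins[k + 1] if k + 1 < len(edges_bins) else max_sep + 1
        sl = slice(lo, hi)
        weights = sep_counts[sl]
        v = exp[sl]
        good = ~np.isnan(v) & (weights > 0)
        if good.any():
            lows.append(lo * m.bin_size)
            vals.append(np.average(v[good], weights=weights[good]))
    return DistanceLaw(
        strata_bp=np.asarray(lows, dtype=float),
        values=np.asarray(vals, dtype=float),
        bin_size=m.bin_size,
    )


def _pair_counts_by_separation(m: ContactMatrix) -> np.ndarray:
    n = m.n_bins
    sep = _circular_sep_matrix(n)
    ok = ~(m.masked[:, None] | m.masked[None, :])
    return np.bincount(sep[ok], minlength=n // 2 + 1).astype(float)


def scc(
    m1: ContactMatrix,
    m2: ContactMatrix,
    max_dist: int,
    smooth_h: int = 1,
) -> float:
    """Stratum-adjusted correlation coefficient (HiCrep-style).

    Both matrices are smoothed with a (2h+1)-wide mean filter, then per-diagonal
    Pearson correlations up to ``max_dist`` (bp) are combined with
    variance-based stratum weights. Zero-variance strata are skipped.
    """
    if m1.matrix.shape != m2.matrix.shape or m1.bin_size != m2.bin_size:
        raise ValueError("matrices must share shape and bin size")
    n = m1.n_bins
    d_max = min(max_dist // m1.bin_size, n - 2)
    if d_max < 2:
        raise ValueError("max_dist must cover at least 2 bins")
    size = 2 * smooth_h + 1
    a = ndimage.uniform_filter(m1.matrix.astype(float), size=size, mode="wrap")
    b = ndimage.uniform_filter(m2.matrix.astype(float), size=size, mode="wrap")
    num = 0.0
    den = 0.0
    any_stratum = False
    for d in range(1, d_max + 1):
        x = np.diagonal(a, offset=d)
        y = np.diagonal(b, offset=d)
        if x.size < 2:
            continue
        vx, vy = x.std(), y.std()
        if vx == 0 or vy == 0:
            continue
        # identical strata correlate exactly; avoids float dust from corrcoef
        r = 1.0 if np.array_equal(x, y) else float(np.corrcoef(x, y)[0, 1])
        w = x.size * vx * vy
        num += w * r
        den += w
        any_stratum = True
    if not any_stratum:
        raise ValueError("all strata degenerate (zero variance)")
    return num / den
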