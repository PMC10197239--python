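"""File formats and shared record types.

Text formats only: FASTA genomes (via Biopython), 4DN-style ``.pairs`` tables,
dense contact-matrix TSV with a small metadata header (plus a cooler-dump-style
bin/pixel table pair), virome alignment TSV, spike-in TSV, BED/bedGraph tracks
and JSON truth sidecars.

Coordinate conventions: all in-memory coordinates are 0-based bp; ``.pairs``
and the alignment TSV store 1-based positions (converted on read/write); BED
and bedGraph are 0-based half-open per their specs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PAIRS_COLUMNS = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
ALIGNMENT_COLUMNS = ["read_id", "ref", "pos", "strand", "mate_ref", "mate_pos", "mate_strand"]


@dataclass
class GenomeRecord:
    """A (circular) replicon sequence with an identifier."""

    name: str
    sequence: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, circular: bool = True) -> list[GenomeRecord]:
    return [
        GenomeRecord(rec.id, str(rec.seq).upper(), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# .pairs (4DN-style text)


def write_pairs(df: pd.DataFrame, path: str | Path, *, zero_based: bool = True) -> None:
    """Write a pairs table.

    ``df`` must carry columns readID chrom1 pos1 chrom2 pos2 strand1 strand2;
    positions are converted to 1-based on output when ``zero_based``.
    """
    out = df.loc[:, PAIRS_COLUMNS].copy()
    if zero_based:
        out["pos1"] = out["pos1"].astype(np.int64) + 1
        out["pos2"] = out["pos2"].astype(np.int64) + 1
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path: str | Path, *, zero_based: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=PAIRS_COLUMNS)
    if zero_based:
        df["pos1"] = df["pos1"].astype(np.int64) - 1
        df["pos2"] = df["pos2"].astype(np.int64) - 1
    return df


# ---------------------------------------------------------------------------
# Virome alignment TSV (one row per read pair)


def write_alignments(df: pd.DataFrame, path: str | Path, *, zero_based: bool = True) -> None:
    out = df.loc[:, ALIGNMENT_COLUMNS].copy()
    if zero_based:
        out["pos"] = out["pos"].astype(np.int64) + 1
        out["mate_pos"] = out["mate_pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path, *, zero_based: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    if zero_based:
        df["pos"] = df["pos"].astype(np.int64) - 1
        df["mate_pos"] = df["mate_pos"].astype(np.int64) - 1
    return df


def read_alignments_sam(path: str | Path) -> pd.DataFrame:
    """Adapter: read paired alignments from a (text) SAM file via pysam.

    Produces the same 0-based table as :func:`read_alignments`; only primary,
    mapped, paired records are kept and each pair is reported once (from its
    first-in-pair mate).
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.mate_is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_read1:
                continue
            rows.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    rec.next_reference_name or rec.reference_name,
                    rec.next_reference_start,
                    "-" if rec.mate_is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Spike-in specification TSV


def read_spike_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"spike_id", "length", "pfu_added", "sample_weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    return df


def write_spike_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dense matrix TSV

_MATRIX_HEADER = "# phicmap matrix"


def write_matrix_tsv(m, path: str | Path) -> None:
    """Dense TSV with a 3-line metadata header (replicon, bin size, masked bins)."""
    masked = ",".join(str(i) for i in np.flatnonzero(m.masked)) if m.masked is not None else ""
    with open(path, "w") as fh:
        fh.write(f"{_MATRIX_HEADER} replicon={m.replicon} total_contacts={m.total_contacts}\n")
        fh.write(f"# bin_size={m.bin_size} balanced={int(m.balanced)}\n")
        fh.write(f"# masked_bins={masked}\n")
        np.savetxt(fh, m.matrix, delimiter="\t", fmt="%.10g")


def read_matrix_tsv(path: str | Path):
    from .contact import ContactMatrix

    with open(path) as fh:
        line1 = fh.readline().strip()
        line2 = fh.readline().strip()
        line3 = fh.readline().strip()
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    meta1 = dict(tok.split("=", 1) for tok in line1.replace(_MATRIX_HEADER, "").split())
    meta2 = dict(tok.split("=", 1) for tok in line2.lstrip("# ").split())
    masked_field = line3.split("=", 1)[1] if "=" in line3 else ""
    masked = np.zeros(data.shape[0], dtype=bool)
    if masked_field:
        masked[[int(i) for i in masked_field.split(",")]] = True
    return ContactMatrix(
        replicon=meta1["replicon"],
        bin_size=int(meta2["bin_size"]),
        matrix=data,
        total_contacts=float(meta1["total_contacts"]),
        balanced=bool(int(meta2["balanced"])),
        masked=masked,
    )


def write_cool_text(m, prefix: str | Path) -> None:
    """Bin-table + pixel-table pair following the cooler text-dump convention.

    Writes ``<prefix>.bins.tsv`` (chrom, start, end) and ``<prefix>.pixels.tsv``
    (bin1_id, bin2_id, count) with upper-triangle pixels only.
    """
    prefix = str(prefix)
    n = m.matrix.shape[0]
    starts = np.arange(n, dtype=np.int64) * m.bin_size
    ends = np.minimum(starts + m.bin_size, m.replicon_length or (n * m.bin_size))
    bins = pd.DataFrame({"chrom": m.replicon, "start": starts, "end": ends})
    bins.to_csv(prefix + ".bins.tsv", sep="\t", index=False)
    iu = np.triu_indices(n)
    vals = m.matrix[iu]
    keep = vals != 0
    pixels = pd.DataFrame(
        {"bin1_id": iu[0][keep], "bin2_id": iu[1][keep], "count": vals[keep]}
    )
    pixels.to_csv(prefix + ".pixels.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / bedGraph


def write_bed(intervals: Sequence[tuple], path: str | Path, replicon: str) -> None:
    """BED6 from (start, end, name, score, strand) tuples, 0-based half-open."""
    with open(path, "w") as fh:
        for iv in intervals:
            start, end, name, score, strand = iv
            fh.write(f"{replicon}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED4+ prophage predictions: chrom, start, end, name[, score, strand]."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]),
                    "end": int(parts[2]),
                    "name": parts[3] if len(parts) > 3 else ".",
                }
            )
    return pd.DataFrame(rows)


def write_bedgraph(
    starts: np.ndarray, ends: np.ndarray, values: np.ndarray, path: str | Path, replicon: str
) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{replicon}\t{int(s)}\t{int(e)}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# JSON sidecars


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
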