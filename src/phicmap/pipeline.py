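"""End-to-end orchestration: configuration, staged pipeline, reports.

The pipeline runs bin -> balance -> insulation/borders -> refinement ->
3D signatures -> coverage -> virome quantification -> junctions -> report.
Every run serializes its configuration (and its hash) next to the outputs,
and reports regenerate byte-identically from the same inputs and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contact, features, io, prophage as prophage_mod, synthetic, virome

log = logging.getLogger("phicmap")


@dataclass
class RunConfig:
    """All pipeline inputs, resolutions and thresholds, with defaults.

    Either ``synthetic_seed`` is set (the packaged synthetic consortium is
    generated on the fly) or file inputs are given. A run may enter with
    contact pairs or with a pre-binned matrix TSV.
    """

    outdir: str = "phicmap_out"
    # inputs
    synthetic_seed: int | None = None
    synthetic_n_pairs: int = 1_000_000
    synthetic_n_read_pairs: int = 100_000
    fasta: str | None = None
    prophage_bed: str | None = None
    pairs: str | None = None
    matrix_tsv: str | None = None
    alignments: str | None = None
    spike_tsv: str | None = None
    # resolutions
    bin_size: int = 5_000
    comparison_bin_size: int = 10_000
    coverage_window: int = 10_000
    gc_window: int = 10_000
    gc_step: int = 1_000
    # balancing
    ice_max_iter: int = 300
    ice_tol: float = 1e-6
    ice_min_coverage_fraction: float = 0.1
    # architecture
    insulation_window: int = 5
    border_min_prominence: float = 0.2
    max_shift: int = 20_000
    cluster_radius: int = 100_000
    diag_min_separation: int = 10
    # classification thresholds
    t_domain: float = 1.5
    t_loop: float = 2.0
    t_depletion: float = 0.67
    min_contacts_for_3d: float = 5e4
    # virome
    read_length: int = 35
    edge_window: int = 500
    junction_min_support: int = 5
    induction_fold_threshold: float = 10.0
    # seeds
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        # hash of the analysis parameters; the output location is not part
        # of the analysis, so identical runs into different directories
        # produce identical reports
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def thresholds(self) -> prophage_mod.SignatureThresholds:
        return prophage_mod.SignatureThresholds(self.t_domain, self.t_loop, self.t_depletion)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    prophages: list
    matrix: contact.ContactMatrix
    balanced: contact.ContactMatrix
    ori_call: features.OriTerCall | None
    summary: dict
    outdir: Path


def _stage(name: str, detail: str = "") -> None:
    log.info("stage %-14s %s", name, detail)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage and write tracks, matrices, the per-prophage report
    and a JSON summary into ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump({"config_hash": chash, **config.to_dict()}, fh, sort_keys=True)

    # ------------------------------------------------------------------ inputs
    truth = None
    genome = None
    spikes = None
    alignments = None
    prophage_intervals: list[tuple[int, int]] = []
    prophage_names: list[str] = []

    if config.synthetic_seed is not None:
        _stage("simulate", f"consortium seed={config.synthetic_seed}")
        bundle = synthetic.simulate_consortium(
            seed=config.synthetic_seed,
            n_pairs=config.synthetic_n_pairs,
            n_read_pairs=config.synthetic_n_read_pairs,
            bin_size=config.bin_size,
        )
        truth = bundle["truth"]
        genome = bundle["genome"]
        pairs = bundle["pairs"]
        alignments = bundle["alignments"]
        spikes = truth.spike_specs
        prophage_intervals = [(p.start, p.end) for p in truth.prophage_specs]
        prophage_names = [p.name for p in truth.prophage_specs]
        io.write_json(truth.to_dict(), outdir / "truth.json")
        io.write_fasta([genome], outdir / "genome.fasta")
        matrix = contact.bin_pairs(pairs, config.bin_size)
    else:
        if config.fasta:
            genome = io.read_fasta(config.fasta)[0]
        if config.prophage_bed:
            bed = io.read_bed(config.prophage_bed)
            prophage_intervals = list(zip(bed["start"], bed["end"]))
            prophage_names = list(bed["name"])
        if config.pairs:
            _stage("binmap", f"pairs={config.pairs} bin={config.bin_size}")
            df = io.read_pairs(config.pairs)
            length = len(genome) if genome else int(max(df["pos1"].max(), df["pos2"].max())) + 1
            pairs = contact.ContactPairs(
                replicon=str(df["chrom1"].iloc[0]),
                positions=df[["pos1", "pos2"]].to_numpy(),
                length=length,
            )
            matrix = contact.bin_pairs(pairs, config.bin_size)
        elif config.matrix_tsv:
            _stage("binmap", f"prebuilt matrix={config.matrix_tsv}")
            pairs = None
            matrix = io.read_matrix_tsv(config.matrix_tsv)
        else:
            raise ValueError("stage binmap: need synthetic_seed, pairs, or matrix_tsv")
        if config.alignments:
            alignments = io.read_alignments(config.alignments)
        if config.spike_tsv:
            spikes = [
                synthetic.SpikeSpec(r.spike_id, int(r.length), float(r.pfu_added),
                                    float(r.sample_weight))
                for r in io.read_spike_table(config.spike_tsv).itertuples()
            ]

    _stage("binmap", f"{matrix.n_bins} bins, {matrix.total_contacts:.0f} contacts")
    io.write_matrix_tsv(matrix, outdir / "matrix_raw.tsv")

    # ------------------------------------------------------------------ balance
    _stage("balance", "ICE")
    balanced = contact.ice_balance(
        matrix,
        max_iter=config.ice_max_iter,
        tol=config.ice_tol,
        min_coverage_fraction=config.ice_min_coverage_fraction,
    )
    io.write_matrix_tsv(balanced, outdir / "matrix_balanced.tsv")

    # ------------------------------------------------------------------ genome tracks
    ori_call = None
    ori_bin = 0
    if genome is not None:
        _stage("architecture", "parS / GC skew / ori-ter / secondary diagonal")
        hits = features.scan_parS(genome)
        skew = features.gc_tracks(genome, window=config.gc_window, step=config.gc_step)
        ori_call = features.call_ori_ter(skew, hits, cluster_radius=config.cluster_radius)
        ori_bin = ori_call.ori // config.bin_size
        io.write_bed(
            [(h.position, h.position + 16, f"parS_mm{h.mismatches}", h.mismatches, h.strand)
             for h in hits],
            outdir / "parS.bed",
            genome.name,
        )
        starts = skew.starts
        ends = np.minimum(starts + config.gc_step, skew.genome_length)
        io.write_bedgraph(starts, ends, skew.skew, outdir / "gc_skew.bedgraph", genome.name)
        diag = features.secondary_diagonal_signal(
            balanced, ori_bin, min_separation=config.diag_min_separation
        )
        pd.DataFrame({"bin_offset_from_ori": diag.offsets, "signal": diag.values}).to_csv(
            outdir / "secondary_diagonal.tsv", sep="\t", index=False, float_format="%.6g"
        )

    # ------------------------------------------------------------------ insulation & borders
    _stage("insulation", f"window={config.insulation_window} bins")
    profile = prophage_mod.insulation_profile(balanced, window=config.insulation_window)
    borders = prophage_mod.detect_borders(profile, min_prominence=config.border_min_prominence)
    _stage("borders", f"{len(borders)} detected")
    bstarts = np.arange(balanced.n_bins) * config.bin_size
    io.write_bedgraph(
        bstarts,
        np.minimum(bstarts + config.bin_size, balanced.replicon_length or bstarts[-1] + config.bin_size),
        np.nan_to_num(profile.scores),
        outdir / "insulation.bedgraph",
        matrix.replicon,
    )

    # ------------------------------------------------------------------ prophage records
    genome_length = balanced.replicon_length or balanced.n_bins * config.bin_size
    too_few_contacts = matrix.total_contacts < config.min_contacts_for_3d
    cov_positions = (
        pairs.positions.ravel() if pairs is not None else None
    )
    cov = (
        features.coverage_profile(cov_positions, genome_length, window=config.coverage_window)
        if cov_positions is not None
        else None
    )

    records = []
    for (start, end), name in zip(prophage_intervals, prophage_names):
        rec = prophage_mod.ProphageRecord(
            replicon=matrix.replicon, name=name, predicted=(start, end)
        )
        if too_few_contacts:
            rec.refine_status = "NA: coverage too low"
        else:
            interval, status, l_ok, r_ok = prophage_mod.refine_prophage(
                (start, end), borders, config.bin_size, genome_length, max_shift=config.max_shift
            )
            rec.refined, rec.refine_status = interval, status
            rec.left_refined, rec.right_refined = l_ok, r_ok
            rec.domain_score, rec.loop_score, rec.depletion_score = (
                prophage_mod.signature_scores(balanced, rec.interval)
            )
            if cov is not None and cov.median > 0:
                rec.coverage_ratio = prophage_mod.coverage_ratio(cov, rec.interval)
            prophage_mod.classify_prophage(rec, config.thresholds())
        records.append(rec)
    _stage("signatures", f"{sum(r.functional_call for r in records)} functional calls")

    # ------------------------------------------------------------------ virome
    quants = []
    junctions: dict[str, virome.JunctionCall | None] = {}
    vlp_per_gram = None
    vlp_per_region: dict[str, float] = {}
    if alignments is not None and prophage_intervals:
        _stage("virome", f"{len(alignments)} read pairs")
        host = matrix.replicon
        total_mapped = 2 * len(alignments)
        quants = virome.region_rpkm(
            alignments, prophage_intervals, total_mapped, host,
            replicon_length=genome_length, names=prophage_names,
        )
        background = virome.host_background_rpkm(
            alignments, host, genome_length, prophage_intervals,
            window=config.coverage_window, total_mapped=total_mapped,
        )
        virome.induction_call(quants, background, fold_threshold=config.induction_fold_threshold)
        for (start, end), name in zip(prophage_intervals, prophage_names):
            junctions[name] = virome.detect_circularization(
                alignments, (start, end), host,
                edge_window=config.edge_window,
                min_support=config.junction_min_support,
                read_length=config.read_length,
            )
        if spikes:
            sp = spikes[0]
            s_rpkm = virome.spike_rpkm(alignments, sp.spike_id, sp.length, total_mapped)
            if s_rpkm > 0:
                cal = virome.SpikeCalibration(sp.spike_id, sp.pfu_added, s_rpkm, sp.sample_weight)
                induced_quants = [q for q in quants if q.induced]
                vlp_per_gram, vlp_per_region = virome.estimate_vlp_per_gram(induced_quants, cal)
        junction_rows = [
            (host, j.left, host, j.right, name, j.supporting_pairs)
            for name, j in junctions.items() if j is not None
        ]
        pd.DataFrame(
            junction_rows,
            columns=["chrom1", "start1", "chrom2", "start2", "name", "supporting_pairs"],
        ).to_csv(outdir / "junctions.bedpe.tsv", sep="\t", index=False)

    # ------------------------------------------------------------------ report
    qmap = {q.name: q for q in quants}
    rows = []
    for rec in records:
        q = qmap.get(rec.name)
        j = junctions.get(rec.name)
        rows.append(
            {
                "prophage": rec.name,
                "replicon": rec.replicon,
                "predicted_start": rec.predicted[0],
                "predicted_end": rec.predicted[1],
                "refined_start": rec.refined[0] if rec.refined else "NA",
                "refined_end": rec.refined[1] if rec.refined else "NA",
                "refine_status": rec.refine_status,
                "domain_score": _fmt(rec.domain_score),
                "loop_score": _fmt(rec.loop_score),
                "depletion_score": _fmt(rec.depletion_score),
                "coverage_ratio": _fmt(rec.coverage_ratio),
                "labels": "+".join(sorted(rec.signature_labels)) or "none",
                "functional_call": rec.functional_call,
                "mapped_reads": q.mapped_reads if q else "NA",
                "rpkm": _fmt(q.rpkm) if q else "NA",
                "induced": q.induced if q else "NA",
                "junction_left": j.left if j else "NA",
                "junction_right": j.right if j else "NA",
                "junction_support": j.supporting_pairs if j else 0,
                "vlp_estimate": _fmt(vlp_per_region.get(rec.name, float("nan"))),
            }
        )
    report = pd.DataFrame(rows)
    report_path = outdir / "prophage_report.tsv"
    with open(report_path, "w") as fh:
        fh.write(f"# phicmap prophage report\n# config_hash={chash}\n")
        fh.write(f"# thresholds={json.dumps(config.thresholds().as_dict(), sort_keys=True)}\n")
        report.to_csv(fh, sep="\t", index=False)

    summary = {
        "config_hash": chash,
        "n_bins": int(matrix.n_bins),
        "total_contacts": float(matrix.total_contacts),
        "n_prophages": len(records),
        "n_functional": int(sum(r.functional_call for r in records)),
        "n_induced": int(sum(1 for q in quants if q.induced)),
        "n_junctions": int(sum(1 for j in junctions.values() if j is not None)),
        "ori": None if ori_call is None else int(ori_call.ori),
        "ter": None if ori_call is None else int(ori_call.ter),
        "vlp_per_gram": vlp_per_gram,
    }
    io.write_json(summary, outdir / "summary.json")
    _stage("report", str(report_path))
    return PipelineResult(
        report=report,
        prophages=records,
        matrix=matrix,
        balanced=balanced,
        ori_call=ori_call,
        summary=summary,
        outdir=outdir,
    )


def _fmt(x: float) -> str:
    return "NA" if x is None or not np.isfinite(x) else f"{x:.6g}"


# ---------------------------------------------------------------------------


def compare_conditions(
    m_a: contact.ContactMatrix,
    m_b: contact.ContactMatrix,
    prophages: list,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-prophage 3D-signature deltas (condition b minus a) after
    downsampling both raw maps to the common minimum total and balancing,
    plus the log2-ratio map. Antisymmetric by construction: swapping the
    conditions negates every delta."""
    if m_a.bin_size != m_b.bin_size or m_a.matrix.shape != m_b.matrix.shape:
        raise ValueError("bin-size or shape mismatch between conditions")
    target = int(min(m_a.total_contacts, m_b.total_contacts))
    da = contact.downsample(m_a, target, seed=seed) if m_a.total_contacts > target else m_a
    db = contact.downsample(m_b, target, seed=seed) if m_b.total_contacts > target else m_b
    ratio = contact.log2_ratio(db, da, pseudocount=pseudocount)
    ba = contact.ice_balance(da)
    bb = contact.ice_balance(db)
    rows = []
    for rec in prophages:
        interval = rec.interval if hasattr(rec, "interval") else tuple(rec)
        name = getattr(rec, "name", str(interval))
        sa = prophage_mod.signature_scores(ba, interval)
        sb = prophage_mod.signature_scores(bb, interval)
        rows.append(
            {
                "prophage": name,
                "domain_delta": sb[0] - sa[0],
                "loop_delta": sb[1] - sa[1],
                "depletion_delta": sb[2] - sa[2],
            }
        )
    return pd.DataFrame(rows), ratio
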