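"""Config-driven orchestration of the analysis stages.

Stages (``centromeres`` -> ``diffmod``; ``nonb``; ``hic``; ``report``) run
in dependency order on the files named in a :class:`PipelineConfig`;
completed stages write their tables/BEDs under the output directory and a
manifest records the seed, parameters, input hashes and outputs, making a
fixed-seed rerun byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, parse_region
from .diffmod import call_dmws, pericentromere_profile, region_fold_change_test, region_intensity
from .domains import (
    EnrichmentDomain,
    call_enrichment_domains,
    compare_domains,
    compute_bin_enrichment,
    partition_variable_stable,
)
from .hic import (
    balance_matrix,
    compare_boundaries,
    compartment_pc1,
    difference_map,
    find_tads,
    read_contact_matrix,
    region_pc1_stats,
)
from .intervals import ChromSizes, GenomicInterval
from .io import read_bedgraph, read_fasta, write_bed, write_table
from .nonb import (
    MOTIF_CLASSES,
    motif_density,
    permutation_enrichment,
    scan_motifs,
    window_free_energy,
)
from .windows import CoverageTrack, WindowGrid, make_windows

logger = logging.getLogger(__name__)

STAGES = ("centromeres", "diffmod", "nonb", "hic", "report")
_DEPS = {"diffmod": ("centromeres",), "report": ()}


class StageError(RuntimeError):
    pass


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_track(
    path: str, grid: WindowGrid, sample: str, mark: str, rep: int,
    library: Optional[float] = None,
) -> CoverageTrack:
    """Read a bedGraph aligned to the grid.

    ``library`` is the genome-wide mapped-read total for the sample; when
    the bedGraph covers only a chromosome segment the segment sum would
    misstate the library, so an explicit value from the config is preferred.
    """
    df = read_bedgraph(path)
    expect = [(w.chrom, w.start, w.end) for w in grid.windows]
    got = list(zip(df["chrom"], df["start"], df["end"]))
    if got != expect:
        raise StageError(f"bedGraph {path} windows do not match the {grid.width}-bp grid")
    counts = df["value"].to_numpy()
    return CoverageTrack(grid, counts, library_size=library or max(counts.sum(), 1.0),
                         sample=sample, mark=mark, replicate=rep)


def _grid_from_tracks(config: PipelineConfig) -> WindowGrid:
    """Chrom sizes from the genome FASTA when present, else from track extents."""
    width = config.params["dmw_window"]
    if config.genome:
        sizes = {r.id: len(r) for r in read_fasta(config.genome)}
    else:
        sizes: Dict[str, int] = {}
        for t in config.tracks:
            df = read_bedgraph(t["chip"])
            for chrom, end in df.groupby("chrom")["end"].max().items():
                sizes[chrom] = max(sizes.get(chrom, 0), int(end))
    if not sizes:
        raise StageError("no genome and no tracks: cannot build a window grid")
    return make_windows(ChromSizes(sizes), width)


def _grouped_tracks(config: PipelineConfig, grid: WindowGrid, mark: str) -> Dict[str, List[CoverageTrack]]:
    """sample -> ChIP replicate tracks for one mark (Input handled separately)."""
    out: Dict[str, List[CoverageTrack]] = {}
    for t in config.tracks:
        if t["mark"] != mark:
            continue
        out.setdefault(t["sample"], []).append(
            _load_track(t["chip"], grid, t["sample"], mark, t["replicate"],
                        library=t.get("chip_library"))
        )
    return out


def _input_tracks(config: PipelineConfig, grid: WindowGrid, mark: str) -> Dict[str, List[CoverageTrack]]:
    out: Dict[str, List[CoverageTrack]] = {}
    for t in config.tracks:
        if t["mark"] != mark:
            continue
        out.setdefault(t["sample"], []).append(
            _load_track(t["input"], grid, t["sample"], mark, t["replicate"],
                        library=t.get("input_library"))
        )
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_centromeres(config: PipelineConfig, ctx: Dict[str, Any], outdir: Path) -> List[str]:
    p = config.params
    grid = ctx.setdefault("grid", _grid_from_tracks(config))
    chip = _grouped_tracks(config, grid, "CENH3")
    inputs = _input_tracks(config, grid, "CENH3")
    if "parent" not in chip:
        raise StageError("centromeres stage needs CENH3 tracks for sample 'parent'")
    domains: Dict[str, EnrichmentDomain] = {}
    rows = []
    for sample in sorted(chip):
        ch, inp = chip[sample][0], inputs[sample][0]
        if len(chip[sample]) > 1:  # pool replicates for domain calling
            ch = CoverageTrack(grid, np.sum([t.counts for t in chip[sample]], axis=0),
                               sum(t.library_size for t in chip[sample]), sample, "CENH3")
            inp = CoverageTrack(grid, np.sum([t.counts for t in inputs[sample]], axis=0),
                                sum(t.library_size for t in inputs[sample]), sample, "CENH3")
        fc = compute_bin_enrichment(ch, inp, pseudocount=p["pseudocount"])
        called = call_enrichment_domains(
            fc, ch, threshold=p["fc_threshold"], min_width=p["min_width"],
            merge_gap=p["merge_gap"], sample=sample,
        )
        if not called:
            raise StageError(f"no CENH3 domain called for sample {sample!r}")
        dom = max(called, key=lambda d: d.width)
        domains[sample] = dom
        rows.append({"sample": sample, "chrom": dom.interval.chrom,
                     "start": dom.interval.start, "end": dom.interval.end,
                     "size_bp": dom.width, "mean_fc": dom.mean_fc, "peak_fc": dom.peak_fc})
    derived = [domains[s] for s in sorted(domains) if s != "parent"]
    comp_rows = []
    for d in derived:
        c = compare_domains(domains["parent"], d, left_is_short_arm=p["left_is_short_arm"])
        comp_rows.append({
            "derived_sample": d.sample, "size_delta_bp": c.size_delta,
            "retained_fraction": c.retained_fraction,
            "lost_short_arm_bp": c.lost_short_arm_bp,
            "lost_long_arm_bp": c.lost_long_arm_bp, "direction": c.direction,
        })
    partition = partition_variable_stable(domains["parent"], derived) if derived else None
    ctx["domains"], ctx["partition"] = domains, partition
    outputs = []
    write_table(pd.DataFrame(rows), outdir / "centromere_domains.tsv")
    outputs.append("centromere_domains.tsv")
    write_bed([d.interval for d in domains.values()], outdir / "centromere_domains.bed")
    outputs.append("centromere_domains.bed")
    if comp_rows:
        write_table(pd.DataFrame(comp_rows), outdir / "domain_comparisons.tsv")
        outputs.append("domain_comparisons.tsv")
    if partition:
        r1 = [GenomicInterval(iv.chrom, iv.start, iv.end, name="R1") for iv in partition.r1]
        r2 = [GenomicInterval(iv.chrom, iv.start, iv.end, name="R2") for iv in partition.r2]
        write_bed(r1 + r2, outdir / "partition.bed")
        outputs.append("partition.bed")
    return outputs


def _stage_diffmod(config: PipelineConfig, ctx: Dict[str, Any], outdir: Path) -> List[str]:
    p = config.params
    grid = ctx.setdefault("grid", _grid_from_tracks(config))
    partition = ctx.get("partition")
    marks = sorted({t["mark"] for t in config.tracks if t["mark"] != "CENH3"})
    if not marks:
        raise StageError("diffmod stage needs at least one non-CENH3 mark")
    dmw_rows, intensity_rows, profile_rows = [], [], []
    all_dmws = []
    for mark in marks:
        chip = _grouped_tracks(config, grid, mark)
        if "parent" not in chip:
            raise StageError(f"mark {mark}: no parent tracks")
        for sample in sorted(chip):
            if sample == "parent":
                continue
            dmws = call_dmws(chip["parent"], chip[sample], grid,
                             fc_threshold=p["dmw_fc"], alpha=p["dmw_alpha"],
                             mark=mark, contrast=f"{sample}_vs_parent")
            all_dmws.extend(dmws)
            for d in dmws:
                dmw_rows.append({
                    "chrom": d.window.chrom, "start": d.window.start, "end": d.window.end,
                    "mark": mark, "contrast": d.contrast, "log2_fc": d.log2_fc,
                    "p_value": d.p_value, "adj_p": d.adj_p, "direction": d.direction,
                })
            # region fold changes over R1/R2
            if partition and partition.r1 and partition.r2:
                for rname, ivs in (("R1", partition.r1), ("R2", partition.r2)):
                    a = _sum_region(chip[sample], ivs)
                    b = _sum_region(chip["parent"], ivs)
                    fc_val, p_val = region_fold_change_test(a, b)
                    intensity_rows.append({
                        "mark": mark, "contrast": f"{sample}_vs_parent", "region": rname,
                        "fold_change": fc_val, "p_value": p_val,
                    })
        # pericentromere profiles for the parent domain
        dom = ctx.get("domains", {}).get("parent")
        cen = dom.interval if dom else (parse_region(config.centromere) if config.centromere else None)
        if cen is not None:
            for sample in sorted(chip):
                prof = pericentromere_profile(chip[sample][0], cen,
                                              flank=p["flank"], box=p["profile_box"])
                for k, iv, val in zip(prof.box_indices, prof.boxes, prof.intensities):
                    profile_rows.append({"mark": mark, "sample": sample, "box": k,
                                         "start": iv.start, "end": iv.end, "intensity": val})
    ctx["dmws"] = all_dmws
    outputs = []
    write_table(pd.DataFrame(dmw_rows), outdir / "dmws.tsv")
    outputs.append("dmws.tsv")
    if dmw_rows:
        write_bed([GenomicInterval(r["chrom"], r["start"], r["end"],
                                   name=f"{r['mark']}:{r['direction']}") for r in dmw_rows],
                  outdir / "dmws.bed")
        outputs.append("dmws.bed")
    if intensity_rows:
        write_table(pd.DataFrame(intensity_rows), outdir / "region_fold_changes.tsv")
        outputs.append("region_fold_changes.tsv")
    if profile_rows:
        write_table(pd.DataFrame(profile_rows), outdir / "pericentromere_profiles.tsv")
        outputs.append("pericentromere_profiles.tsv")
    return outputs


def _sum_region(tracks: Sequence[CoverageTrack], ivs: Sequence[GenomicInterval]):
    """Pooled-replicate intensity record over a multi-interval region."""
    from .diffmod import IntensityRecord

    raw = sum(region_intensity(t, iv).raw_count for t in tracks for iv in ivs)
    lib = sum(t.library_size for t in tracks)
    span = GenomicInterval(ivs[0].chrom, min(i.start for i in ivs), max(i.end for i in ivs))
    return IntensityRecord(region=span, sample=tracks[0].sample, mark=tracks[0].mark,
                           raw_count=raw, library_size=lib)


def _stage_nonb(config: PipelineConfig, ctx: Dict[str, Any], outdir: Path) -> List[str]:
    p = config.params
    if not config.genome:
        raise StageError("nonb stage needs a genome FASTA")
    records = read_fasta(config.genome)
    sizes = ChromSizes({r.id: len(r) for r in records})
    grid = make_windows(sizes, p["density_window"])
    dom = ctx.get("domains", {}).get("parent")
    cen = dom.interval if dom else (parse_region(config.centromere) if config.centromere else None)
    density_rows, perm_rows, hit_rows = [], [], []
    for rec in records:
        for cls in MOTIF_CLASSES:
            hits = scan_motifs(rec, cls)
            for h in hits:
                hit_rows.append({"chrom": h.interval.chrom, "start": h.interval.start,
                                 "end": h.interval.end, "class": cls, "strand": h.strand})
            dens = motif_density(hits, grid)
            dens.insert(3, "class", cls)
            density_rows.append(dens)
            if cen is not None and cen.chrom == rec.id:
                cen_idx = [i for i, w in enumerate(grid.windows)
                           if w.chrom == cen.chrom and cen.start < w.end and w.start < cen.end]
                if 0 < len(cen_idx) < grid.n_windows - len(cen_idx):
                    obs, pval = permutation_enrichment(
                        dens["count"].to_numpy(), cen_idx,
                        n_perm=p["n_perm"], seed=config.seed,
                    )
                    perm_rows.append({"chrom": rec.id, "class": cls,
                                      "observed_mean": obs, "perm_p": pval})
        energies = window_free_energy(rec, width=p["energy_window"], step=p["energy_step"])
        write_table(pd.DataFrame(
            [{"chrom": e.interval.chrom, "start": e.interval.start,
              "end": e.interval.end, "kcal_mol": e.score} for e in energies]),
            outdir / f"energy_{rec.id}.tsv")
    outputs = []
    write_table(pd.DataFrame(hit_rows), outdir / "motif_hits.tsv")
    outputs.append("motif_hits.tsv")
    write_table(pd.concat(density_rows, ignore_index=True), outdir / "motif_density.tsv")
    outputs.append("motif_density.tsv")
    if perm_rows:
        write_table(pd.DataFrame(perm_rows), outdir / "motif_enrichment.tsv")
        outputs.append("motif_enrichment.tsv")
    outputs.extend(f"energy_{r.id}.tsv" for r in records)
    return outputs


def _stage_hic(config: PipelineConfig, ctx: Dict[str, Any], outdir: Path) -> List[str]:
    p = config.params
    if len(config.contacts) < 2:
        raise StageError("hic stage needs contact matrices for two samples")
    samples = sorted(config.contacts)
    mats = {}
    for s in samples:
        m = read_contact_matrix(config.contacts[s]["path"], resolution=p["tad_resolution"])
        mats[s] = balance_matrix(balance_matrix(m, "depth"), "KR")
    a, b = samples[0], samples[1]
    diff = difference_map(mats[b], mats[a])
    np.savetxt(outdir / "difference_map.tsv", diff, delimiter="\t", fmt="%.6g")
    tracks = {s: compartment_pc1(mats[s]) for s in samples}
    pc1_rows = []
    for s in samples:
        for i, v in enumerate(tracks[s].pc1):
            pc1_rows.append({"sample": s, "bin": i, "pc1": v,
                             "label": tracks[s].labels[i]})
    write_table(pd.DataFrame(pc1_rows), outdir / "compartments.tsv")
    partition = ctx.get("partition")
    outputs = ["difference_map.tsv", "compartments.tsv"]
    if partition and partition.r1 and partition.r2:
        regions = {
            "R1": GenomicInterval(partition.r1[0].chrom,
                                  min(i.start for i in partition.r1),
                                  max(i.end for i in partition.r1)),
            "R2": GenomicInterval(partition.r2[0].chrom,
                                  min(i.start for i in partition.r2),
                                  max(i.end for i in partition.r2)),
        }
        stats_df = region_pc1_stats(tracks[a], regions, tracks[b])
        write_table(stats_df, outdir / "pc1_region_stats.tsv")
        outputs.append("pc1_region_stats.tsv")
    tads = {s: find_tads(mats[s], insulation_window=p["insulation_window"],
                         delta=p["tad_delta"], significance=p["tad_significance"])
            for s in samples}
    dmws = ctx.get("dmws", [])
    cmp_df = compare_boundaries(tads[a], tads[b],
                                features=[d.window for d in dmws],
                                slack=p["boundary_slack"])
    write_table(cmp_df, outdir / "tad_boundary_comparison.tsv")
    outputs.append("tad_boundary_comparison.tsv")
    for s in samples:
        write_bed([tads[s].matrix.bin_interval(bi) for bi in tads[s].boundaries]
                  or [], outdir / f"tad_boundaries_{s}.bed")
        outputs.append(f"tad_boundaries_{s}.bed")
    return outputs


def _stage_report(config: PipelineConfig, ctx: Dict[str, Any], outdir: Path) -> List[str]:
    """Assemble the headline tables produced by completed stages."""
    pieces = []
    for name in ("centromere_domains.tsv", "domain_comparisons.tsv",
                 "region_fold_changes.tsv", "motif_enrichment.tsv",
                 "pc1_region_stats.tsv", "tad_boundary_comparison.tsv"):
        f = outdir / name
        if f.exists():
            pieces.append(f"## {name}\n{f.read_text()}")
    (outdir / "report.txt").write_text("\n".join(pieces) if pieces else "no stage outputs\n")
    return ["report.txt"]


_STAGE_FN = {
    "centromeres": _stage_centromeres,
    "diffmod": _stage_diffmod,
    "nonb": _stage_nonb,
    "hic": _stage_hic,
    "report": _stage_report,
}


def run_pipeline(
    config: PipelineConfig, stages: Optional[Sequence[str]] = None
) -> Dict[str, Any]:
    """Run the requested stages in dependency order.

    Returns a manifest dict (also written to ``manifest.json``): seed,
    parameters, input hashes, per-stage status and outputs.  A failing stage
    aborts its dependents but not independent stages.
    """
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx: Dict[str, Any] = {}
    inputs = {}
    for f in [config.genome, config.annotations] + [
        t[k] for t in config.tracks for k in ("chip", "input")
    ] + [c["path"] for c in config.contacts.values()]:
        if f:
            inputs[f] = _sha256(f)
    manifest: Dict[str, Any] = {
        "version": __version__, "seed": config.seed, "params": dict(config.params),
        "inputs": inputs, "stages": {},
    }
    failed: set = set()
    for stage in STAGES:
        if stage not in stages:
            continue
        deps = _DEPS.get(stage, ())
        blocked = [d for d in deps if d in failed]
        if blocked:
            manifest["stages"][stage] = {"status": "skipped", "blocked_by": blocked}
            continue
        t0 = time.monotonic()
        try:
            outputs = _STAGE_FN[stage](config, ctx, outdir)
            manifest["stages"][stage] = {
                "status": "ok", "outputs": outputs,
                "seconds": round(time.monotonic() - t0, 3),
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            logger.error("stage %s failed: %s", stage, exc)
            failed.add(stage)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
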