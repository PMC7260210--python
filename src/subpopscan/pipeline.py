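"""End-to-end orchestration: QC -> relatedness -> ROH -> LD -> varLD -> F_ST
-> consensus signatures, with a flat key=value configuration and a JSON run
manifest (parameters, library versions, seed, output hashes) so a rerun with
the same configuration is bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import fst as fst_mod
from . import io as io_mod
from . import ld as ld_mod
from . import qc as qc_mod
from . import relatedness, roh, signatures, synthetic, varld
from .model import GenotypePanel, HaplotypePanel

logger = logging.getLogger("subpopscan.pipeline")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study settings (30/15-SNP
    windows, 99.9th percentiles, 20 heterozygosity bins, 0.90 call rates,
    HWE p < 1e-5)."""

    outdir: str = "subpopscan_out"
    seed: int = 0
    # inputs: either two panel files, or a simulated dataset
    input_a: Optional[str] = None
    input_b: Optional[str] = None
    input_format: str = "vcf"
    simulate: bool = False
    subset: Optional[str] = None          # e.g. "coat_color=black"
    # qc
    sample_call_rate: float = 0.90
    snp_call_rate: float = 0.90
    hwe_p: float = 1e-5
    # roh
    roh_window_snps: int = 30
    roh_het_allowed: int = 1
    roh_min_len_bp: int = 1_000_000
    roh_min_density_bp_per_snp: int = 120_000
    roh_max_gap_bp: int = 1_000_000
    # windowed scans
    window_snps: int = 15
    percentile: float = 99.9
    n_het_bins: int = 20
    min_consecutive: int = 2

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat key = value configuration file ('#' comments)."""
        values: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                values[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                values[key] = int(val)
            elif isinstance(default, float):
                values[key] = float(val)
            else:
                values[key] = val
        return cls(**values)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _align_haplotypes(hap: HaplotypePanel, panel: GenotypePanel) -> HaplotypePanel:
    """Subset a haplotype panel to the QC'd panel's (chrom, pos) markers."""
    keys = {(c, int(p)) for c, p in zip(panel.markers.chrom, panel.markers.pos_bp)}
    keep = [j for j in range(hap.n_snps)
            if (hap.markers.chrom[j], int(hap.markers.pos_bp[j])) in keys]
    return hap.take_snps(keep)


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim = synthetic.SimConfig(seed=config.seed)
        panel, hap, _ = synthetic.simulate_two_pops(sim)
        return panel, hap, {"simulated": dataclasses.asdict(sim)}
    if not config.input_a or not config.input_b:
        raise FileNotFoundError("config must name input_a and input_b (or simulate)")
    for p in (config.input_a, config.input_b):
        probe = Path(p)
        candidates = [probe] + [probe.with_suffix(s)
                                for s in (".vcf", ".ped", ".bed")]
        if not any(c.exists() for c in candidates):
            raise FileNotFoundError(f"input not found: {p}")
    panelA, hapA = io_mod.read_panel(config.input_a, config.input_format)
    panelB, hapB = io_mod.read_panel(config.input_b, config.input_format)
    panelA, repA = qc_mod.filter_call_rate(panelA, config.sample_call_rate,
                                           config.snp_call_rate)
    panelB, repB = qc_mod.filter_call_rate(panelB, config.sample_call_rate,
                                           config.snp_call_rate)
    panelA, hweA = qc_mod.hwe_filter(panelA, config.hwe_p, scope="pooled")
    panelB, hweB = qc_mod.hwe_filter(panelB, config.hwe_p, scope="pooled")
    merged, shared = qc_mod.keep_shared_polymorphic(panelA, panelB)
    hap = None
    if hapA is not None and hapB is not None:
        hA = _align_haplotypes(hapA, merged)
        hB = _align_haplotypes(hapB, merged)
        if hA.n_snps == merged.n_snps and hB.n_snps == merged.n_snps:
            subA = hA.subpop if hA.subpop is not None \
                else np.asarray(["A"] * hA.n_samples, object)
            subB = hB.subpop if hB.subpop is not None \
                else np.asarray(["B"] * hB.n_samples, object)
            hap = HaplotypePanel(
                markers=merged.markers,
                samples=np.concatenate([hA.samples, hB.samples]),
                haplotypes=np.vstack([hA.haplotypes, hB.haplotypes]),
                subpop=np.concatenate([subA, subB]),
            )
    qc_report = {
        "call_rate_a": repA.removed, "call_rate_b": repB.removed,
        "hwe_a": hweA.removed, "hwe_b": hweB.removed,
        "shared_polymorphic": shared.removed,
    }
    return merged, hap, {"qc": qc_report}


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to outdir)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "versions": _versions(),
        "stages": {},
        "outputs": {},
    }
    t0 = time.time()
    panel, hap, meta = _load_inputs(config)
    manifest["stages"]["load"] = {"seconds": round(time.time() - t0, 3), **meta}

    if config.subset:
        key, _, value = config.subset.partition("=")
        attr = getattr(panel, key.strip(), None)
        if attr is None:
            raise ValueError(f"subset field {key!r} absent from panel metadata")
        keep = np.flatnonzero(attr == value.strip())
        panel = panel.take_samples(keep)
        if hap is not None:
            hap = hap.take_samples(keep)

    pops = panel.subpop_labels()
    if len(pops) != 2:
        raise ValueError(f"pipeline needs exactly two subpopulations, got {pops}")
    popA, popB = pops

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(path)

    def save_regions(regions, name: str) -> None:
        bed, tsv = io_mod.write_regions(regions, out / name)
        manifest["outputs"][bed.name] = _sha256(bed)
        manifest["outputs"][tsv.name] = _sha256(tsv)

    # panel summary
    t = time.time()
    save_df(qc_mod.summarize_panel(panel), "panel_summary.tsv")
    manifest["stages"]["summary"] = {"seconds": round(time.time() - t, 3)}

    # relatedness
    t = time.time()
    grm = relatedness.compute_grm(panel)
    fgrm = relatedness.f_grm(grm)
    pca = relatedness.pca_grm(grm, n_components=10)
    save_df(pd.DataFrame(grm.matrix, index=grm.samples, columns=grm.samples)
            .reset_index().rename(columns={"index": "sample"}), "grm.tsv")
    save_df(pd.DataFrame({"sample": panel.samples, "subpop": panel.subpop,
                          "f_grm": fgrm}), "f_grm.tsv")
    pca_df = pd.DataFrame(pca.coordinates,
                          columns=[f"PC{i + 1}" for i in range(pca.coordinates.shape[1])])
    pca_df.insert(0, "sample", panel.samples)
    pca_df.insert(1, "subpop", panel.subpop)
    save_df(pca_df, "pca.tsv")
    save_df(pd.DataFrame({
        "component": np.arange(1, len(pca.variance_proportions) + 1),
        "variance_proportion": pca.variance_proportions,
    }), "pca_variance.tsv")
    manifest["stages"]["relatedness"] = {"seconds": round(time.time() - t, 3)}

    # ROH
    t = time.time()
    params = roh.RohParams(
        window_snps=config.roh_window_snps,
        het_allowed_per_window=config.roh_het_allowed,
        min_len_bp=config.roh_min_len_bp,
        min_density_bp_per_snp=config.roh_min_density_bp_per_snp,
        max_gap_bp=config.roh_max_gap_bp,
    )
    seg_sliding = roh.detect_roh_sliding(panel, params)
    seg_consec = roh.detect_roh_consecutive(panel, params)
    save_df(roh.segments_to_dataframe(seg_sliding), "roh_segments_sliding.tsv")
    save_df(roh.segments_to_dataframe(seg_consec), "roh_segments_consecutive.tsv")
    froh_s = roh.f_roh(seg_sliding, panel.markers, panel.samples)
    froh_c = roh.f_roh(seg_consec, panel.markers, panel.samples)
    save_df(pd.DataFrame({"sample": panel.samples, "subpop": panel.subpop,
                          "f_roh_sliding": froh_s.to_numpy(),
                          "f_roh_consecutive": froh_c.to_numpy()}), "f_roh.tsv")
    save_df(roh.roh_length_summary(seg_sliding, panel), "roh_length_summary.tsv")
    roh_regions = {}
    track_df = panel.markers.to_dataframe()[["chrom", "pos_bp"]].copy()
    for pop in (popA, popB):
        members = panel.samples[panel.sample_indices(pop)]
        scores = roh.autozygosity_track(seg_sliding, panel.markers, members)
        track_df[f"autozygosity_{pop}"] = scores
        roh_regions[f"ROH_{pop}"] = roh.roh_islands(
            scores, panel.markers, percentile=config.percentile,
            min_adjacent=config.min_consecutive, source=f"ROH_{pop}")
        save_regions(roh_regions[f"ROH_{pop}"], f"roh_islands_{pop}.bed")
    save_df(track_df, "autozygosity_track.tsv")
    manifest["stages"]["roh"] = {"seconds": round(time.time() - t, 3),
                                 "n_segments_sliding": len(seg_sliding),
                                 "n_segments_consecutive": len(seg_consec)}

    # haplotype-based stages
    varld_regions = []
    if hap is not None:
        t = time.time()
        hA, hB = hap.subset(popA), hap.subset(popB)
        mafA, mafB = hA.to_genotype_panel().maf(), hB.to_genotype_panel().maf()
        joint_maf = np.minimum(mafA, mafB)
        for pop, h in ((popA, hA), (popB, hB)):
            save_df(ld_mod.ld_decay(h), f"ld_decay_{pop}.tsv")
            save_df(ld_mod.adjacent_r2_summary(h, maf=joint_maf),
                    f"adjacent_r2_{pop}.tsv")
        save_df(ld_mod.phase_persistence(hA, hB), "phase_persistence.tsv")
        manifest["stages"]["ld"] = {"seconds": round(time.time() - t, 3)}

        t = time.time()
        vtrack, varld_regions = varld.varld_scan(
            hA, hB, window_snps=config.window_snps,
            percentile=config.percentile, min_consecutive=config.min_consecutive)
        manifest["outputs"]["varld_track.tsv"] = _sha256(
            io_mod.write_track(vtrack, out / "varld_track.tsv"))
        save_regions(varld_regions, "varld_regions.bed")
        manifest["stages"]["varld"] = {"seconds": round(time.time() - t, 3),
                                       "n_regions": len(varld_regions)}
    else:
        logger.warning("no phased haplotypes: LD and varLD stages skipped")

    # F_ST
    t = time.time()
    ftrack = fst_mod.fst_window_track(panel, window_snps=config.window_snps)
    fst_regions = fst_mod.fst_outlier_regions(
        ftrack, n_bins=config.n_het_bins, percentile=config.percentile,
        min_consecutive=config.min_consecutive)
    mean_fst, sd_fst = fst_mod.global_fst(panel)
    manifest["outputs"]["fst_track.tsv"] = _sha256(
        io_mod.write_track(ftrack, out / "fst_track.tsv"))
    save_regions(fst_regions, "fst_regions.bed")
    manifest["stages"]["fst"] = {"seconds": round(time.time() - t, 3),
                                 "global_mean": mean_fst, "global_sd": sd_fst,
                                 "n_regions": len(fst_regions)}

    # consensus
    t = time.time()
    sources = dict(roh_regions)
    sources["FST"] = fst_regions
    if varld_regions:
        sources["VARLD"] = varld_regions
    sigs = signatures.consensus(sources)
    save_df(signatures.report(sigs), "signatures.tsv")
    save_regions(signatures.signatures_to_regions(sigs), "signatures.bed")
    manifest["stages"]["signatures"] = {"seconds": round(time.time() - t, 3),
                                        "n_signatures": len(sigs)}

    manifest["total_seconds"] = round(time.time() - t0, 3)
    manifest_path = out / "manifest.json"
    stable = {k: v for k, v in manifest.items() if k != "total_seconds"}
    manifest_path.write_text(json.dumps(_without_timings(stable), indent=2,
                                        sort_keys=True) + "\n")
    manifest["outputs"]["manifest.json"] = _sha256(manifest_path)
    return manifest


def _without_timings(manifest: dict) -> dict:
    """Manifest copy with wall-clock timings removed, so identical reruns
    produce byte-identical manifests."""
    out = json.loads(json.dumps(manifest))
    for stage in out.get("stages", {}).values():
        stage.pop("seconds", None)
    return out


def _versions() -> dict:
    from importlib.metadata import version

    import scipy

    from . import __version__

    return {
        "subpopscan": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "click": version("click"),
    }
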