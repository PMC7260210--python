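"""Readers and writers for PLINK text, PLINK binary and VCF panels, plus
track/region output.

Alleles are recoded to alt-allele dosage at load; the original letters are
retained in the :class:`~subpopscan.model.MarkerMap` so panels from different
arrays can be aligned on (chrom, pos, alleles). For PLINK binary, allele A1 of
the .bim is taken as the alt (counted) allele. Plain 4-column .map files carry
no allele roles, so the .ped reader falls back to coding the minor allele as
alt; our own .map writer emits an extended 6-column map (chrom, id, cM, bp,
ref, alt) which round-trips the coding exactly.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    MISSING,
    CandidateRegion,
    GenotypePanel,
    HaplotypePanel,
    MarkerMap,
    WindowTrack,
    regions_to_dataframe,
)

logger = logging.getLogger("subpopscan.io")

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK .bed


# ---------------------------------------------------------------------------
# reading


def read_panel(path, fmt: str) -> tuple[GenotypePanel, Optional[HaplotypePanel]]:
    """Read a genotype panel; returns (panel, haplotypes-or-None).

    Haplotypes are only returned for VCF input in which every genotype record
    is phased ("|" separator) and complete.
    """
    if fmt == "plink_text":
        return _read_plink_text(path), None
    if fmt == "plink_bed":
        return _read_plink_bed(path), None
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {fmt!r}")


def _strip_ext(path, exts: Sequence[str]) -> Path:
    p = Path(path)
    for e in exts:
        if p.suffix == e:
            return p.with_suffix("")
    return p


def _read_map(path: Path) -> tuple[MarkerMap, bool]:
    """Read .map; returns (map, has_alleles). Alleles default to placeholders."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(line.split())
    ncols = len(rows[0]) if rows else 4
    has_alleles = ncols >= 6
    chrom = [r[0] for r in rows]
    snp_id = [r[1] for r in rows]
    pos = [int(r[3]) for r in rows]
    if has_alleles:
        ref = [r[4] for r in rows]
        alt = [r[5] for r in rows]
    else:
        ref = ["0"] * len(rows)
        alt = ["1"] * len(rows)
    return (
        MarkerMap(chrom=chrom, pos_bp=pos, snp_id=snp_id,
                  allele_ref=ref, allele_alt=alt),
        has_alleles,
    )


def _read_plink_text(path) -> GenotypePanel:
    prefix = _strip_ext(path, [".ped", ".map"])
    mmap, has_alleles = _read_map(prefix.with_suffix(".map"))
    m = mmap.n_snps
    samples, subpop, geno_rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"ped line for {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields) - 6} allele fields, expected {2 * m}"
                )
            subpop.append(fields[0])
            samples.append(fields[1])
            geno_rows.append(fields[6:])
    alleles = np.asarray(geno_rows, dtype=object).reshape(len(samples), m, 2)

    if not has_alleles:
        ref_l, alt_l = _infer_alleles(alleles, mmap)
        mmap = MarkerMap(chrom=mmap.chrom, pos_bp=mmap.pos_bp, snp_id=mmap.snp_id,
                         allele_ref=ref_l, allele_alt=alt_l)

    dosage = np.full((len(samples), m), MISSING, dtype=np.int8)
    for j in range(m):
        a = alleles[:, j, :]
        valid = (a != "0").all(axis=1)
        known = np.isin(a, [mmap.allele_ref[j], mmap.allele_alt[j]]).all(axis=1)
        bad = valid & ~known
        if bad.any():
            raise ValueError(
                f"SNP {mmap.snp_id[j]}: unexpected allele(s) "
                f"{sorted(set(a[bad].ravel()) - {mmap.allele_ref[j], mmap.allele_alt[j]})}"
            )
        dosage[valid, j] = (a[valid] == mmap.allele_alt[j]).sum(axis=1)
    return GenotypePanel(markers=mmap, samples=samples, dosage=dosage,
                         subpop=np.asarray(subpop, dtype=object))


def _infer_alleles(alleles: np.ndarray, mmap: MarkerMap):
    """Minor allele becomes alt (lexicographic tie-break); used for plain maps."""
    ref_l, alt_l = [], []
    for j in range(alleles.shape[1]):
        col = alleles[:, j, :].ravel()
        col = col[col != "0"]
        uniq, counts = np.unique(col, return_counts=True)
        if len(uniq) > 2:
            raise ValueError(f"SNP {mmap.snp_id[j]}: more than two alleles {list(uniq)}")
        if len(uniq) == 0:
            ref_l.append("0")
            alt_l.append("0")
        elif len(uniq) == 1:
            ref_l.append(uniq[0])
            alt_l.append("0")
        else:
            order = np.lexsort((uniq, counts))  # ascending count, lexicographic ties
            alt_l.append(uniq[order[0]])
            ref_l.append(uniq[order[1]])
    return ref_l, alt_l


def _read_plink_bed(path) -> GenotypePanel:
    prefix = _strip_ext(path, [".bed", ".bim", ".fam"])
    bim_rows = []
    with open(prefix.with_suffix(".bim")) as fh:
        for line in fh:
            if line.strip():
                bim_rows.append(line.split())
    mmap = MarkerMap(
        chrom=[r[0] for r in bim_rows],
        pos_bp=[int(r[3]) for r in bim_rows],
        snp_id=[r[1] for r in bim_rows],
        allele_alt=[r[4] for r in bim_rows],  # A1 = counted allele
        allele_ref=[r[5] for r in bim_rows],
    )
    samples, subpop = [], []
    with open(prefix.with_suffix(".fam")) as fh:
        for line in fh:
            f = line.split()
            if f:
                subpop.append(f[0])
                samples.append(f[1])
    n, m = len(samples), mmap.n_snps
    with open(prefix.with_suffix(".bed"), "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bps = (n + 3) // 4  # bytes per SNP
    if len(raw) != m * bps:
        raise ValueError(f"{prefix}.bed has {len(raw)} data bytes, expected {m * bps}")
    raw = raw.reshape(m, bps)
    codes = (raw[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    codes = codes.reshape(m, bps * 4)[:, :n]  # SNP x sample 2-bit codes
    # 00 -> hom A1 (dosage 2), 01 -> missing, 10 -> het, 11 -> hom A2
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    dosage = lut[codes].T
    return GenotypePanel(markers=mmap, samples=samples, dosage=dosage,
                         subpop=np.asarray(subpop, dtype=object))


def _read_vcf(path) -> tuple[GenotypePanel, Optional[HaplotypePanel]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    subpop = _subpop_from_vcf_header(vcf.raw_header, samples)
    chrom, pos, snp_id, ref, alt = [], [], [], [], []
    dos_cols, hap_cols = [], []
    any_unphased = False
    any_missing = False
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"site {v.ID or f'{v.CHROM}:{v.POS}'} is not biallelic")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        snp_id.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0])
        g = np.asarray(v.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        a = g[:, :2]
        miss = (a < 0).any(axis=1)
        any_missing |= bool(miss.any())
        col = np.where(miss, MISSING, a.clip(min=0).sum(axis=1)).astype(np.int8)
        dos_cols.append(col)
        if not g[:, 2].all():
            any_unphased = True
        hap_cols.append(a)
    vcf.close()
    mmap = MarkerMap(chrom=chrom, pos_bp=pos, snp_id=snp_id,
                     allele_ref=ref, allele_alt=alt)
    dosage = np.stack(dos_cols, axis=1) if dos_cols else np.zeros((len(samples), 0), np.int8)
    panel = GenotypePanel(markers=mmap, samples=samples, dosage=dosage, subpop=subpop)
    hap_panel: Optional[HaplotypePanel] = None
    if dos_cols and not any_unphased and not any_missing:
        # hap_cols entries are (n_samples, 2); interleave into (2n, m)
        hap = np.stack(hap_cols, axis=2).reshape(2 * len(samples), mmap.n_snps)
        hap_panel = HaplotypePanel(markers=mmap, samples=samples,
                                   haplotypes=hap.astype(np.uint8), subpop=subpop)
    elif any_unphased:
        logger.warning("VCF %s contains unphased records; haplotypes withheld", path)
    return panel, hap_panel


def _subpop_from_vcf_header(raw_header: str, samples: list[str]):
    pops = {}
    for line in raw_header.splitlines():
        if line.startswith("##SAMPLE=<"):
            body = line[len("##SAMPLE=<"):].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(",") if "=" in kv)
            if "ID" in fields and "Population" in fields:
                pops[fields["ID"]] = fields["Population"]
    if pops and all(s in pops for s in samples):
        return np.asarray([pops[s] for s in samples], dtype=object)
    return None


# ---------------------------------------------------------------------------
# writing


def write_panel(panel: GenotypePanel, prefix, fmt: str,
                haplotypes: Optional[HaplotypePanel] = None) -> list[Path]:
    """Write a panel (and optionally phased haplotypes, VCF only)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "plink_text":
        return _write_plink_text(panel, prefix)
    if fmt == "plink_bed":
        return _write_plink_bed(panel, prefix)
    if fmt == "vcf":
        return [_write_vcf(panel, prefix, haplotypes)]
    raise ValueError(f"unknown format {fmt!r}")


def _write_map(panel: GenotypePanel, path: Path) -> None:
    mm = panel.markers
    with open(path, "w") as fh:
        for j in range(mm.n_snps):
            fh.write(f"{mm.chrom[j]}\t{mm.snp_id[j]}\t0\t{mm.pos_bp[j]}"
                     f"\t{mm.allele_ref[j]}\t{mm.allele_alt[j]}\n")


def _write_plink_text(panel: GenotypePanel, prefix: Path) -> list[Path]:
    mm = panel.markers
    _write_map(panel, prefix.with_suffix(".map"))
    geno_strings = {
        MISSING: lambda j: "0 0",
        0: lambda j: f"{mm.allele_ref[j]} {mm.allele_ref[j]}",
        1: lambda j: f"{mm.allele_ref[j]} {mm.allele_alt[j]}",
        2: lambda j: f"{mm.allele_alt[j]} {mm.allele_alt[j]}",
    }
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(panel.samples):
            fid = panel.subpop[i] if panel.subpop is not None else "0"
            fields = [fid, s, "0", "0", "0", "-9"]
            fields += [geno_strings[int(d)](j) for j, d in enumerate(panel.dosage[i])]
            fh.write(" ".join(fields) + "\n")
    return [prefix.with_suffix(".ped"), prefix.with_suffix(".map")]


def _write_plink_bed(panel: GenotypePanel, prefix: Path) -> list[Path]:
    mm = panel.markers
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(mm.n_snps):
            fh.write(f"{mm.chrom[j]}\t{mm.snp_id[j]}\t0\t{mm.pos_bp[j]}"
                     f"\t{mm.allele_alt[j]}\t{mm.allele_ref[j]}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, s in enumerate(panel.samples):
            fid = panel.subpop[i] if panel.subpop is not None else "0"
            fh.write(f"{fid}\t{s}\t0\t0\t0\t-9\n")
    n, m = panel.n_samples, panel.n_snps
    # dosage -> 2-bit codes: 2 -> 00 (hom A1), missing -> 01, 1 -> 10, 0 -> 11
    code_of = np.zeros(4, dtype=np.uint8)
    code_of[[2, 1, 0]] = [0b00, 0b10, 0b11]
    codes = np.where(panel.dosage == MISSING, 0b01,
                     code_of[panel.dosage.clip(min=0)]).astype(np.uint8)
    bps = (n + 3) // 4
    padded = np.zeros((m, bps * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4] | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    return [prefix.with_suffix(s) for s in (".bed", ".bim", ".fam")]


def _write_vcf(panel: GenotypePanel, prefix: Path,
               haplotypes: Optional[HaplotypePanel] = None) -> Path:
    path = prefix if str(prefix).endswith(".vcf") else prefix.with_suffix(".vcf")
    mm = panel.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for _, start, stop in mm.chrom_blocks():
            fh.write(f"##contig=<ID={mm.chrom[start]}>\n")
        if panel.subpop is not None:
            for s, p in zip(panel.samples, panel.subpop):
                fh.write(f"##SAMPLE=<ID={s},Population={p}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j in range(mm.n_snps):
            if haplotypes is not None:
                h = haplotypes.haplotypes[:, j]
                gts = [f"{h[2 * i]}|{h[2 * i + 1]}" for i in range(panel.n_samples)]
            else:
                gt_of = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
                gts = [gt_of[int(d)] for d in panel.dosage[:, j]]
            fh.write(f"{mm.chrom[j]}\t{mm.pos_bp[j]}\t{mm.snp_id[j]}"
                     f"\t{mm.allele_ref[j]}\t{mm.allele_alt[j]}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


def write_regions(regions: Sequence[CandidateRegion], bed_path) -> tuple[Path, Path]:
    """Write regions as BED (0-based half-open) plus a companion TSV that keeps
    the library's 1-based inclusive coordinates."""
    bed_path = Path(bed_path)
    bed_path.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = bed_path.with_suffix(".tsv")
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start_bp, r.end_bp, r.source))
    with open(bed_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsource\tn_units\n")
        for r in ordered:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.source}\t{r.n_units}\n")
    df = regions_to_dataframe(ordered)
    df.to_csv(tsv_path, sep="\t", index=False)
    return bed_path, tsv_path


def write_track(track: WindowTrack, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    track.to_dataframe().to_csv(path, sep="\t", index=False)
    return path
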