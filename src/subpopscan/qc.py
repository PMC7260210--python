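"""Marker and sample quality control shared by both subpopulations.

Filter order is fixed: sample call rate -> SNP call rate -> Hardy-Weinberg ->
shared-polymorphic intersection. Each step returns the filtered panel plus a
:class:`QcReport` whose removal counts reconcile exactly with the in/out
totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import MISSING, GenotypePanel, MarkerMap

logger = logging.getLogger("subpopscan.qc")


@dataclass
class QcReport:
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    removed: dict = field(default_factory=dict)

    def check(self) -> None:
        sample_removed = sum(v for k, v in self.removed.items() if k.startswith("sample_"))
        snp_removed = sum(v for k, v in self.removed.items() if k.startswith("snp_"))
        assert self.n_samples_in - sample_removed == self.n_samples_out
        assert self.n_snps_in - snp_removed == self.n_snps_out


def filter_call_rate(panel: GenotypePanel, sample_min: float = 0.90,
                     snp_min: float = 0.90) -> tuple[GenotypePanel, QcReport]:
    """Drop samples, then SNPs, with call rate below threshold."""
    if not (0 < sample_min <= 1 and 0 < snp_min <= 1):
        raise ValueError("call-rate thresholds must lie in (0, 1]")
    n0, m0 = panel.n_samples, panel.n_snps
    keep_s = np.flatnonzero(panel.call_rate_samples() >= sample_min)
    if len(keep_s) == 0:
        report = QcReport(n0, 0, m0, m0, {"sample_call_rate": n0})
        raise RuntimeError(f"all {n0} samples removed by call-rate filter: {report}")
    p1 = panel.take_samples(keep_s)
    keep_m = np.flatnonzero(p1.call_rate_snps() >= snp_min)
    out = p1.take_snps(keep_m)
    report = QcReport(
        n0, out.n_samples, m0, out.n_snps,
        {"sample_call_rate": n0 - len(keep_s), "snp_call_rate": m0 - len(keep_m)},
    )
    report.check()
    return out, report


def hwe_chi2_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg proportions.

    Returns 1.0 for monomorphic counts (the test carries no information there).
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_alt + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(panel: GenotypePanel, idx: np.ndarray) -> np.ndarray:
    d = panel.dosage[idx]
    n_ref = (d == 0).sum(axis=0)
    n_het = (d == 1).sum(axis=0)
    n_alt = (d == 2).sum(axis=0)
    return np.array([
        hwe_chi2_pvalue(int(a), int(b), int(c))
        for a, b, c in zip(n_ref, n_het, n_alt)
    ])


def hwe_filter(panel: GenotypePanel, p_max: float = 1e-5,
               scope: str = "per_subpopulation") -> tuple[GenotypePanel, QcReport]:
    """Remove SNPs deviating from Hardy-Weinberg equilibrium.

    With ``scope='per_subpopulation'`` (default) the chi-square test runs
    within each subpopulation and a SNP failing in either one is dropped;
    ``scope='pooled'`` runs a single pooled test.
    """
    n0, m0 = panel.n_samples, panel.n_snps
    if scope == "per_subpopulation":
        pops = panel.subpop_labels()
        if len(pops) < 1:
            raise ValueError("per-subpopulation HWE requires subpopulation labels")
        groups = [panel.sample_indices(p) for p in pops]
    elif scope == "pooled":
        groups = [np.arange(panel.n_samples)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    fail = np.zeros(m0, dtype=bool)
    for idx in groups:
        fail |= _hwe_pvalues(panel, idx) < p_max
    out = panel.take_snps(np.flatnonzero(~fail))
    report = QcReport(n0, n0, m0, out.n_snps, {"snp_hwe": int(fail.sum())})
    report.check()
    return out, report


def keep_shared_polymorphic(panelA: GenotypePanel,
                            panelB: GenotypePanel) -> tuple[GenotypePanel, QcReport]:
    """Merge two panels on the (chrom, pos, allele-compatible) SNP intersection,
    keeping only SNPs polymorphic in the pooled sample.

    Allele roles swapped between the panels are reconciled by flipping panel
    B's dosage to panel A's coding; allele-set mismatches at a shared position
    are dropped with a warning.
    """
    a_keys = {(panelA.markers.chrom[j], int(panelA.markers.pos_bp[j])): j
              for j in range(panelA.n_snps)}
    idxA, idxB, flipB = [], [], []
    n_mismatch = 0
    mA, mB = panelA.markers, panelB.markers
    for j in range(panelB.n_snps):
        key = (mB.chrom[j], int(mB.pos_bp[j]))
        if key not in a_keys:
            continue
        i = a_keys[key]
        pairA = (mA.allele_ref[i], mA.allele_alt[i])
        pairB = (mB.allele_ref[j], mB.allele_alt[j])
        if pairA == pairB:
            idxA.append(i); idxB.append(j); flipB.append(False)
        elif pairA == pairB[::-1]:
            idxA.append(i); idxB.append(j); flipB.append(True)
        else:
            n_mismatch += 1
            logger.warning("allele mismatch at %s:%s (%s vs %s); SNP dropped",
                           key[0], key[1], pairA, pairB)
    if not idxA:
        raise RuntimeError("no shared SNPs between panels")
    order = np.argsort(idxA, kind="stable")  # keep panel A's map order
    idxA = np.asarray(idxA)[order]
    idxB = np.asarray(idxB)[order]
    flipB = np.asarray(flipB)[order]

    subA = panelA.take_snps(idxA)
    subB = panelB.take_snps(idxB)
    dB = subB.dosage.copy()
    if flipB.any():
        cols = np.flatnonzero(flipB)
        obs = dB[:, cols] != MISSING
        dB[:, cols] = np.where(obs, 2 - dB[:, cols], MISSING)

    dosage = np.vstack([subA.dosage, dB])
    subpopA = subA.subpop if subA.subpop is not None else np.asarray(["A"] * subA.n_samples, object)
    subpopB = subB.subpop if subB.subpop is not None else np.asarray(["B"] * subB.n_samples, object)
    coat = None
    if subA.coat_color is not None and subB.coat_color is not None:
        coat = np.concatenate([subA.coat_color, subB.coat_color])
    merged = GenotypePanel(
        markers=subA.markers,
        samples=np.concatenate([subA.samples, subB.samples]),
        dosage=dosage,
        subpop=np.concatenate([subpopA, subpopB]),
        coat_color=coat,
    )
    p = merged.alt_freq()
    poly = np.flatnonzero((p > 0) & (p < 1))
    out = merged.take_snps(poly)
    report = QcReport(
        panelA.n_samples + panelB.n_samples, out.n_samples,
        panelA.n_snps + panelB.n_snps, out.n_snps,
        {
            "snp_not_shared": (panelA.n_snps - len(idxA)) + (panelB.n_snps - len(idxB)),
            "snp_monomorphic": len(idxA) - len(poly),
            "snp_duplicate_of_shared": len(idxA),  # B copies of shared SNPs collapse into A rows
        },
    )
    report.check()
    return out, report


def summarize_panel(panel: GenotypePanel, by: str = "subpop") -> pd.DataFrame:
    """Mean +/- sd of per-SNP MAF and per-sample observed heterozygosity,
    pooled and per subpopulation."""
    rows = []
    groups: list[tuple[str, object]] = [("pooled", None)]
    if by == "subpop" and panel.subpop is not None:
        groups += [(p, p) for p in panel.subpop_labels()]
    for label, pop in groups:
        idx = panel.sample_indices(pop)
        sub = panel.take_samples(idx)
        maf = sub.maf()
        maf = maf[np.isfinite(maf)]
        het = sub.het_per_sample()
        het = het[np.isfinite(het)]
        rows.append({
            "group": label,
            "n_samples": sub.n_samples,
            "maf_mean": float(np.mean(maf)) if len(maf) else np.nan,
            "maf_sd": float(np.std(maf, ddof=1)) if len(maf) > 1 else 0.0,
            "het_mean": float(np.mean(het)) if len(het) else np.nan,
            "het_sd": float(np.std(het, ddof=1)) if len(het) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
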