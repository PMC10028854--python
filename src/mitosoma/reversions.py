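"""Haplotype-site reversion analysis with NUMT contamination correction.

Haplotype sites are the positions where a conplastic mitochondrial genome
differs from the B6 (C57BL/6J) genome; a somatic reversion reintroduces the
B6 allele.  Because a nuclear-embedded copy of the mitochondrial sequence
(NUMT) on chr1 carries the B6 alleles, a small fraction of nuclear reads
contaminates the mitochondrial pileup inside the NUMT-homologous interval
and inflates apparent reversion frequencies there.  The contamination
fraction is estimated from reads unique to the chr1 junctions (conservative:
the maximum junction estimate) and subtracted from both the reversion allele
depth and the duplex depth at affected sites.

Site significance is empirical: a site's (corrected) frequency is compared
one-sidedly with the per-position frequency distribution of all
non-haplotype background positions of the same condition table, taken
unfiltered (high-frequency positions included).  Age deltas compare
depth-normalised young and aged tables and use the magnitude of the
background per-position deltas as the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import HaplotypeSite
from .spectra import classify_mutation
from .stats import bh_adjust, empirical_p_one_sided, fisher_exact
from .variants import ConditionTable

logger = logging.getLogger(__name__)


@dataclass
class NumtEstimate:
    """Estimated fraction of chr1 (NUMT) reads in the mitochondrial pileup."""

    contamination_fraction: float
    junction_estimates: list[float]
    est_chr1_depth: float
    method: str = "junction"
    cluster_estimates: list[float] | None = None
    cluster_median: float = np.nan

    @classmethod
    def zero(cls) -> "NumtEstimate":
        return cls(0.0, [], 0.0)


def estimate_numt_contamination(
    junction_depths,
    mt_mean_depth: float,
    cluster_depths=None,
) -> NumtEstimate:
    """Contamination fraction from chr1-junction read counts.

    Each junction fraction is its chr1-supporting read count divided by the
    mean mitochondrial duplex depth; the headline fraction is the maximum
    across junctions (conservative).  Optional SNV-cluster counts give a
    median cross-validation estimate.
    """
    if mt_mean_depth <= 0:
        raise ValueError("mean mitochondrial depth must be positive")
    junctions = [float(j) / mt_mean_depth for j in junction_depths]
    fraction = max(junctions) if junctions else 0.0
    if not 0 <= fraction < 1:
        raise ValueError(f"implausible contamination fraction {fraction}")
    est = NumtEstimate(
        contamination_fraction=fraction,
        junction_estimates=junctions,
        est_chr1_depth=fraction * mt_mean_depth,
        method="junction",
    )
    if cluster_depths is not None:
        est.cluster_estimates = [float(c) / mt_mean_depth for c in cluster_depths]
        est.cluster_median = float(np.median(est.cluster_estimates))
        est.method = "junction+snv_cluster"
    return est


def read_junction_counts(path) -> list[float]:
    """Junction-count TSV: ``junction_id  chr1_read_count``."""
    df = pd.read_csv(path, sep="\t")
    if "chr1_read_count" not in df.columns:
        raise ValueError(f"{path}: need a chr1_read_count column")
    return df["chr1_read_count"].astype(float).tolist()


def correct_reversion_counts(
    site_alt_depth: float, site_depth: float, est: NumtEstimate
) -> tuple[float, float, float]:
    """NUMT-corrected (count, depth, frequency) at a haplotype site.

    All chr1 reads are assumed to carry the B6 allele: the estimated chr1
    depth is subtracted from both the reversion allele depth (floored at
    zero) and the duplex depth.
    """
    corrected_depth = site_depth - est.est_chr1_depth
    if corrected_depth <= 0:
        raise ValueError("corrected duplex depth would be non-positive")
    corrected_count = site_alt_depth - est.est_chr1_depth
    if corrected_count < 0:
        logger.warning(
            "corrected reversion count floored at 0 (raw %.1f, est chr1 depth %.1f)",
            site_alt_depth,
            est.est_chr1_depth,
        )
        corrected_count = 0.0
    return corrected_count, corrected_depth, corrected_count / corrected_depth


def _site_frequencies(
    table: ConditionTable,
    sites: list[HaplotypeSite],
    est: NumtEstimate,
    numt_interval: tuple[int, int] | None,
) -> pd.DataFrame:
    """Raw and corrected B6-allele frequency per haplotype site."""
    rows = []
    for s in sites:
        depth = table.depth[s.position - 1]
        if depth <= 0:
            rows.append(
                {"position": s.position, "covered": False, "raw_freq": np.nan,
                 "corrected_freq": np.nan, "b6_depth": np.nan, "alt_depth_total": np.nan}
            )
            continue
        at_site = table.variants[table.variants["position"] == s.position]
        snvs = at_site[at_site["kind"] == "SNV"]
        b6_depth = float(snvs.loc[snvs["alt"] == s.b6_allele, "alt_depth"].sum())
        total_alt = float(at_site["alt_depth"].sum())
        raw = b6_depth / depth
        in_numt = (
            numt_interval is not None
            and numt_interval[0] <= s.position <= numt_interval[1]
        )
        if in_numt and est.est_chr1_depth > 0:
            _, _, corrected = correct_reversion_counts(b6_depth, depth, est)
        else:
            corrected = raw
        rows.append(
            {
                "position": s.position,
                "covered": True,
                "raw_freq": raw,
                "corrected_freq": corrected,
                "b6_depth": b6_depth,
                "alt_depth_total": total_alt,
                "numt_corrected": bool(in_numt and est.est_chr1_depth > 0),
            }
        )
    return pd.DataFrame(rows)


def _background_positions(table: ConditionTable, sites: list[HaplotypeSite]) -> np.ndarray:
    mask = np.ones(table.L, dtype=bool)
    mask[[s.position - 1 for s in sites]] = False
    mask &= table.depth > 0
    return np.flatnonzero(mask)


def haplotype_site_test(
    table: ConditionTable,
    sites: list[HaplotypeSite],
    est: NumtEstimate | None = None,
    numt_interval: tuple[int, int] | None = None,
    rank_test_min_sites: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Per-site one-sided empirical p against the background frequency distribution.

    ``table`` must be the unfiltered condition table (the background keeps
    positions above the usual 1e-3 cap).  Returns the per-site frame (with
    BH-adjusted p-values and the reversion share of alternate reads) and,
    for strains with at least ``rank_test_min_sites`` covered sites, a
    Wilcoxon rank-sum p of sites versus background (NaN otherwise).
    """
    est = est or NumtEstimate.zero()
    df = _site_frequencies(table, sites, est, numt_interval)
    bg_idx = _background_positions(table, sites)
    bg_freq = table.position_frequency()[bg_idx]
    pvals = []
    for row in df.itertuples(index=False):
        if not row.covered:
            pvals.append(np.nan)
            continue
        pvals.append(empirical_p_one_sided(row.corrected_freq, bg_freq, side="greater"))
    df["empirical_p"] = pvals
    df["n_background"] = bg_idx.size
    df["adjusted_p"] = bh_adjust(df["empirical_p"])
    with np.errstate(invalid="ignore", divide="ignore"):
        df["reversion_share"] = np.where(
            df["alt_depth_total"] > 0, df["b6_depth"] / df["alt_depth_total"], np.nan
        )
    covered = df[df["covered"]]
    rank_p = np.nan
    if len(covered) >= rank_test_min_sites:
        rank_p = float(
            sps.ranksums(covered["corrected_freq"], bg_freq, alternative="greater").pvalue
        )
    return df, rank_p


def age_delta_test(
    young: ConditionTable,
    aged: ConditionTable,
    sites: list[HaplotypeSite],
    est_young: NumtEstimate | None = None,
    est_aged: NumtEstimate | None = None,
    numt_interval: tuple[int, int] | None = None,
    delta_side: str = "magnitude",
) -> pd.DataFrame:
    """Change in corrected reversion frequency with age, per haplotype site.

    Young and aged tables should be depth-normalised to each other.  The
    null for a site's delta is the distribution of per-position background
    deltas; by default "more extreme" means larger in magnitude
    (``delta_side="signed"`` compares signed deltas one-sidedly in the
    direction of the observation).  BH adjusts across sites; sites without
    coverage in either age group are reported as no-calls.
    """
    est_young = est_young or NumtEstimate.zero()
    est_aged = est_aged or NumtEstimate.zero()
    fy = _site_frequencies(young, sites, est_young, numt_interval)
    fa = _site_frequencies(aged, sites, est_aged, numt_interval)
    bg_idx = _background_positions(young, sites)
    bg_idx = bg_idx[aged.depth[bg_idx] > 0]
    bg_delta = aged.position_frequency()[bg_idx] - young.position_frequency()[bg_idx]

    rows = []
    for s, ry, ra in zip(sites, fy.itertuples(index=False), fa.itertuples(index=False)):
        if not (ry.covered and ra.covered):
            rows.append(
                {"position": s.position, "strain": s.strain, "covered": False,
                 "young_freq": np.nan, "aged_freq": np.nan, "delta": np.nan,
                 "empirical_p": np.nan}
            )
            continue
        delta = ra.corrected_freq - ry.corrected_freq
        if delta_side == "magnitude":
            p = empirical_p_one_sided(delta, bg_delta, side="magnitude")
        else:
            p = empirical_p_one_sided(delta, bg_delta, side="greater" if delta >= 0 else "less")
        rows.append(
            {
                "position": s.position,
                "strain": s.strain,
                "covered": True,
                "young_freq": ry.corrected_freq,
                "aged_freq": ra.corrected_freq,
                "delta": delta,
                "empirical_p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_adjust(df["empirical_p"])
    df["sign"] = np.sign(df["delta"])
    return df


def reversion_allele_test(
    table: ConditionTable,
    sites: list[HaplotypeSite],
) -> pd.DataFrame:
    """Fisher test of B6-allele share at each site versus its genome-wide expectation.

    For every covered site with alternate reads, a 2x2 table contrasts the
    B6-allele versus other-allele alt depths at the site with the summed alt
    depths of the matching strand-collapsed substitution class versus all
    other SNVs genome-wide (haplotype sites excluded from the background).
    Sites with zero alternate depth are no-calls.
    """
    site_pos = {s.position for s in sites}
    snv = table.variants[
        (table.variants["kind"] == "SNV") & ~table.variants["position"].isin(site_pos)
    ]
    class_totals: dict[str, float] = {}
    for row in snv.itertuples(index=False):
        cls, _ = classify_mutation(row.ref, row.alt)
        class_totals[cls] = class_totals.get(cls, 0.0) + float(row.alt_depth)
    grand_total = sum(class_totals.values())

    rows = []
    for s in sites:
        at_site = table.variants[
            (table.variants["position"] == s.position) & (table.variants["kind"] == "SNV")
        ]
        b6 = float(at_site.loc[at_site["alt"] == s.b6_allele, "alt_depth"].sum())
        other = float(at_site["alt_depth"].sum()) - b6
        if b6 + other == 0:
            rows.append(
                {"position": s.position, "strain": s.strain, "reversion_share": np.nan,
                 "odds_ratio": np.nan, "p": np.nan, "note": "no alternate reads"}
            )
            continue
        cls, _ = classify_mutation(s.conplastic_allele, s.b6_allele)
        bg_cls = class_totals.get(cls, 0.0)
        bg_other = grand_total - bg_cls
        odds, p = fisher_exact(
            [[round(b6), round(other)], [round(bg_cls), round(bg_other)]]
        )
        rows.append(
            {
                "position": s.position,
                "strain": s.strain,
                "reversion_share": b6 / (b6 + other),
                "odds_ratio": odds,
                "p": p,
                "note": "",
            }
        )
    df = pd.DataFrame(rows)
    df["adjusted_p"] = bh_adjust(df["p"])
    return df
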