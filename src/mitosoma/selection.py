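"""hN/hS selection testing against a simulated uniform-placement null.

The statistic for a gene is ``hN/hS``: nonsynonymous variant counts per
nonsynonymous site over synonymous variant counts per synonymous site, with
counts weighted by duplex alternate-allele depth and sites counted by
equal-weight enumeration (stop gains are nonsynonymous).  Its null
distribution is obtained by simulation: the observed mutation total and
strand-collapsed type proportions are redrawn and every simulated mutation
is placed uniformly at random (with replacement) among the positions whose
reference nucleotide admits its type, then re-scored per gene.

Two placement units are supported.  ``event`` (default) relocates each
observed heteroplasmic event carrying its alt-depth weight, which preserves
the clustering of duplex reads into events and keeps the null calibrated
under alt-depth weighting.  ``read`` redraws per-type totals from a
multinomial over the summed alt depths and places every read independently;
it is narrower because it ignores read clustering.

Empirical p-values are two-tailed (the more extreme tail fraction doubled,
ties counted as extreme, clipped at 1); simulations where a gene's hN or hS
is zero are excluded for that gene, and genes whose observed statistic is
undefined are reported with an ``undefined`` verdict, never dropped
silently.  BH adjustment runs across genes (and conditions, when several
are analysed together) within a mode, or within each frequency bin for the
binned scan.
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, complement, count_syn_nonsyn_sites
from .spectra import SNV_CLASSES
from .stats import bh_adjust, empirical_p_two_tailed
from .variants import ConditionTable, apply_site_filters

_ALT_IDX = {b: i for i, b in enumerate("ACGT")}

#: default frequency-bin edges for the binned selection scan
DEFAULT_BIN_EDGES = (4e-6, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 1.0)


@dataclass
class SimulationConfig:
    n_sims: int = 10_000
    seed: int = 0
    placement_domain: str = "whole_genome"  # or "noDloop"
    placement_unit: str = "event"  # or "read"
    type_proportions: pd.Series | None = None
    total_count: int | None = None

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.placement_domain not in ("whole_genome", "noDloop"):
            raise ValueError(f"unknown placement_domain {self.placement_domain!r}")
        if self.placement_unit not in ("event", "read"):
            raise ValueError(f"unknown placement_unit {self.placement_unit!r}")


@dataclass
class HnhsResult:
    gene: str
    hN: float
    hS: float
    ratio: float
    n_sims: int
    empirical_p: float
    adjusted_p: float = np.nan
    mode: str = "aggregated"
    bin_label: str | None = None
    verdict: str = "none"
    condition: tuple | None = None


# ---------------------------------------------------------------------------
# Placement model: admissible positions and per-gene consequence categories
# ---------------------------------------------------------------------------

_pm_cache: "weakref.WeakKeyDictionary[ReferenceGenome, dict]" = weakref.WeakKeyDictionary()


class PlacementModel:
    """Precomputed consequence categories for uniform mutation placement.

    Category codes: 0 = outside genes (or trimmed/unscored coding bases);
    gene ``g`` owns codes ``1 + 2 g`` (nonsynonymous, including stop gains)
    and ``2 + 2 g`` (synonymous).  Overlapping genes follow first-annotation
    attribution, matching consequence annotation.
    """

    def __init__(self, genome: ReferenceGenome, exclude_dloop: bool = False):
        self.genome = genome
        self.exclude_dloop = exclude_dloop
        L = genome.L
        genes = genome.regions_of_class("protein_coding")
        self.gene_names = [g.name for g in genes]
        self.sites = np.array([count_syn_nonsyn_sites(genome, g) for g in genes])  # (G, 2)
        self.K = 2 * len(genes) + 1

        # consequence code for every (position, alt) substitution
        code_tab = genome.code.table
        self.cat = np.zeros((L, 4), dtype=np.int16)
        assigned = np.zeros(L, dtype=bool)
        for g_idx, gene in enumerate(genes):
            pos = genome.coding_positions(gene)
            cds = genome.coding_sequence(gene)
            for i, p in enumerate(pos):
                p0 = int(p) - 1
                if assigned[p0]:
                    continue
                assigned[p0] = True
                cstart = i - i % 3
                codon = cds[cstart : cstart + 3]
                aa = code_tab[codon]
                for alt in "ACGT":
                    if alt == genome.sequence[p0]:
                        continue
                    alt_coding = alt if gene.strand == "+" else complement(alt)
                    mutated = codon[: i % 3] + alt_coding + codon[i % 3 + 1 :]
                    syn = code_tab[mutated] == aa
                    self.cat[p0, _ALT_IDX[alt]] = 2 + 2 * g_idx if syn else 1 + 2 * g_idx

        domain = np.ones(L, dtype=bool)
        if exclude_dloop:
            for r in genome.regions_of_class("D-loop"):
                domain[genome.region_positions(r) - 1] = False
        refs = np.frombuffer(genome.sequence.encode(), dtype="S1").astype("U1")

        # per SNV class: admissible 0-based positions and their category codes
        self.class_positions: list[np.ndarray] = []
        self.class_codes: list[np.ndarray] = []
        self.class_pcat: list[np.ndarray] = []
        for cls in SNV_CLASSES:
            pur = cls.split("/")[0]  # e.g. "G>A"
            r1, a1 = pur[0], pur[2]
            r2, a2 = complement(r1), complement(a1)
            pos1 = np.flatnonzero((refs == r1) & domain)
            pos2 = np.flatnonzero((refs == r2) & domain)
            codes = np.concatenate(
                [self.cat[pos1, _ALT_IDX[a1]], self.cat[pos2, _ALT_IDX[a2]]]
            )
            self.class_positions.append(np.concatenate([pos1, pos2]))
            self.class_codes.append(codes)
            n = codes.size
            self.class_pcat.append(
                np.bincount(codes, minlength=self.K) / n if n else np.zeros(self.K)
            )

    @classmethod
    def for_genome(cls, genome: ReferenceGenome, exclude_dloop: bool = False) -> "PlacementModel":
        per_genome = _pm_cache.setdefault(genome, {})
        if exclude_dloop not in per_genome:
            per_genome[exclude_dloop] = cls(genome, exclude_dloop)
        return per_genome[exclude_dloop]

    def substitution_code(self, position: int, alt: str) -> int:
        return int(self.cat[(position - 1) % self.genome.L, _ALT_IDX[alt]])


# ---------------------------------------------------------------------------
# Observed statistics
# ---------------------------------------------------------------------------


def _observed_events(
    table: ConditionTable, pm: PlacementModel, unit: str = "per_sample"
) -> pd.DataFrame:
    """SNV events with class index, consequence code and alt-depth weight.

    With ``unit="per_sample"`` (and a table carrying the per-replicate
    breakdown) events private to different replicates are separate units --
    they are independent heteroplasmies, which is what a relocation null
    should resample.  With ``unit="record"`` the aggregated (position, ref,
    alt) records are the units; analyses that stratify records by their
    aggregated frequency (the binned scan) must relocate the records they
    selected, not their constituents, or the conditioning on stacked records
    breaks the exchangeability of the null.
    """
    from .spectra import classify_mutation

    use_ps = unit == "per_sample" and table.per_sample is not None
    v = table.per_sample if use_ps else table.variants
    snv = v[v["kind"] == "SNV"]
    if pm.exclude_dloop:
        domain_pos = set()
        for r in pm.genome.regions_of_class("D-loop"):
            domain_pos.update((pm.genome.region_positions(r)).tolist())
        snv = snv[~snv["position"].isin(domain_pos)]
    rows = []
    for row in snv.itertuples(index=False):
        cls, _ = classify_mutation(row.ref, row.alt)
        rows.append(
            (
                int(row.position),
                SNV_CLASSES.index(cls),
                pm.substitution_code(int(row.position), row.alt.upper()),
                float(row.alt_depth),
            )
        )
    return pd.DataFrame(rows, columns=["position", "class_idx", "code", "weight"])


def _gene_counts(events: pd.DataFrame, K: int) -> np.ndarray:
    """Weighted counts per consequence category code."""
    out = np.zeros(K)
    if len(events):
        np.add.at(out, events["code"].to_numpy(), events["weight"].to_numpy())
    return out


def compute_hnhs(
    table: ConditionTable,
    genome: ReferenceGenome,
    gene,
    exclude_dloop: bool = False,
) -> HnhsResult:
    """Observed hN, hS and their ratio for one gene (statistic only).

    Counts are the summed alternate-allele depths of the gene's
    nonsynonymous and synonymous SNVs; any frequency filtering is expected
    to have been applied to ``table`` already.
    """
    pm = PlacementModel.for_genome(genome, exclude_dloop)
    g_idx = pm.gene_names.index(gene if isinstance(gene, str) else gene.name)
    counts = _gene_counts(_observed_events(table, pm), pm.K)
    nonsyn, syn = counts[1 + 2 * g_idx], counts[2 + 2 * g_idx]
    n_sites, s_sites = pm.sites[g_idx]
    hN = nonsyn / n_sites
    hS = syn / s_sites
    ratio = hN / hS if hN > 0 and hS > 0 else np.nan
    verdict = "undefined" if np.isnan(ratio) else "none"
    return HnhsResult(
        gene=pm.gene_names[g_idx], hN=hN, hS=hS, ratio=ratio,
        n_sims=0, empirical_p=np.nan, verdict=verdict, condition=table.condition,
    )


# ---------------------------------------------------------------------------
# Simulated null
# ---------------------------------------------------------------------------


def _null_code_sums_read(
    pm: PlacementModel, total: int, proportions: np.ndarray, n_sims: int, rng
) -> np.ndarray:
    """Read-unit null: every mutation placed independently (multinomial collapse)."""
    q = np.concatenate([p * pcat for p, pcat in zip(proportions, pm.class_pcat)])
    q = q / q.sum()
    draws = rng.multinomial(int(round(total)), q, size=n_sims)
    return draws.reshape(n_sims, len(SNV_CLASSES), pm.K).sum(axis=1).astype(float)


def _null_code_sums_event(
    pm: PlacementModel, events: pd.DataFrame, n_sims: int, rng
) -> np.ndarray:
    """Event-unit null: relocate each observed event with its alt-depth weight."""
    sums = np.zeros((n_sims, pm.K))
    for c in range(len(SNV_CLASSES)):
        sub = events[events["class_idx"] == c]
        m = len(sub)
        if m == 0:
            continue
        codes_pool = pm.class_codes[c]
        if codes_pool.size == 0:
            raise ValueError(f"mutation type {SNV_CLASSES[c]} has no admissible positions")
        w = sub["weight"].to_numpy()
        chunk = max(1, min(n_sims, int(4e6 // m)))
        for lo in range(0, n_sims, chunk):
            hi = min(lo + chunk, n_sims)
            idx = rng.integers(0, codes_pool.size, size=(hi - lo, m))
            codes = codes_pool[idx]
            flat = codes + pm.K * np.arange(hi - lo)[:, None]
            sums[lo:hi] += np.bincount(
                flat.ravel(),
                weights=np.broadcast_to(w, (hi - lo, m)).ravel(),
                minlength=(hi - lo) * pm.K,
            ).reshape(hi - lo, pm.K)
    return sums


def simulate_null(
    genome: ReferenceGenome,
    config: SimulationConfig,
    events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene null distributions of the hN/hS statistic.

    Returns a DataFrame with one column per gene and ``n_sims`` rows; entries
    are NaN where a simulation left the gene's hN or hS at zero (those
    simulations are excluded from that gene's empirical p).  With
    ``placement_unit="event"`` the observed events (from the table being
    tested) must be supplied; with ``"read"`` the config's ``total_count``
    and ``type_proportions`` suffice.
    """
    pm = PlacementModel.for_genome(genome, config.placement_domain == "noDloop")
    rng = np.random.default_rng(config.seed)
    if config.placement_unit == "event":
        if events is None:
            raise ValueError("event placement requires the observed events")
        sums = _null_code_sums_event(pm, events, config.n_sims, rng)
    else:
        if config.type_proportions is not None:
            props = config.type_proportions.reindex(list(SNV_CLASSES), fill_value=0.0).to_numpy()
            total = config.total_count
        elif events is not None:
            props = np.zeros(len(SNV_CLASSES))
            np.add.at(props, events["class_idx"].to_numpy(), events["weight"].to_numpy())
            total = props.sum()
        else:
            raise ValueError("read placement requires type_proportions or events")
        for c in np.flatnonzero(props):
            if pm.class_codes[c].size == 0:
                raise ValueError(f"mutation type {SNV_CLASSES[c]} has no admissible positions")
        if total is None or total <= 0 or props.sum() <= 0:
            sums = np.zeros((config.n_sims, pm.K))
        else:
            sums = _null_code_sums_read(pm, total, props / props.sum(), config.n_sims, rng)
    out = {}
    for g, name in enumerate(pm.gene_names):
        hN = sums[:, 1 + 2 * g] / pm.sites[g, 0]
        hS = sums[:, 2 + 2 * g] / pm.sites[g, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where((hN > 0) & (hS > 0), hN / hS, np.nan)
        out[name] = ratio
    return pd.DataFrame(out)


def empirical_pvalue(observed: HnhsResult, null_ratios: np.ndarray) -> HnhsResult:
    """Attach the two-tailed empirical p to an observed statistic."""
    if np.isnan(observed.ratio):
        observed.empirical_p = np.nan
        observed.verdict = "undefined"
        return observed
    observed.empirical_p = empirical_p_two_tailed(observed.ratio, null_ratios)
    return observed


def _verdicts(df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    df = df.copy()
    for (_, _), idx in df.groupby(["mode", "bin_label"], dropna=False).groups.items():
        df.loc[idx, "adjusted_p"] = bh_adjust(df.loc[idx, "empirical_p"])
    sig = df["adjusted_p"] < threshold
    df.loc[:, "verdict"] = np.where(
        df["ratio"].isna(),
        "undefined",
        np.where(sig & (df["ratio"] > 1), "positive", np.where(sig & (df["ratio"] < 1), "negative", "none")),
    )
    return df


# ---------------------------------------------------------------------------
# Scans
# ---------------------------------------------------------------------------


def _scan_one(
    table: ConditionTable,
    genome: ReferenceGenome,
    mode: str,
    bin_label: str | None,
    config: SimulationConfig,
) -> list[dict]:
    exclude_dloop = mode in ("aggregated_noDloop", "binned")
    pm = PlacementModel.for_genome(genome, exclude_dloop)
    events = _observed_events(table, pm, unit="record" if mode == "binned" else "per_sample")
    null = simulate_null(
        genome,
        SimulationConfig(
            n_sims=config.n_sims,
            seed=config.seed,
            placement_domain="noDloop" if exclude_dloop else config.placement_domain,
            placement_unit=config.placement_unit,
        ),
        events=events,
    )
    counts = _gene_counts(events, pm.K)
    rows = []
    for g, name in enumerate(pm.gene_names):
        hN = counts[1 + 2 * g] / pm.sites[g, 0]
        hS = counts[2 + 2 * g] / pm.sites[g, 1]
        ratio = hN / hS if hN > 0 and hS > 0 else np.nan
        nr = null[name].to_numpy()
        p = empirical_p_two_tailed(ratio, nr) if not np.isnan(ratio) else np.nan
        rows.append(
            {
                "condition": "/".join(table.condition),
                "gene": name,
                "mode": mode,
                "bin_label": bin_label,
                "hN": hN,
                "hS": hS,
                "ratio": ratio,
                "n_sims": int(np.count_nonzero(~np.isnan(nr))),
                "empirical_p": p,
            }
        )
    return rows


def selection_scan(
    tables: list[ConditionTable] | ConditionTable,
    genome: ReferenceGenome,
    mode: str = "aggregated",
    config: SimulationConfig | None = None,
    max_freq: float = 1e-3,
    bin_edges=DEFAULT_BIN_EDGES,
    bh_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene selection test in aggregated or frequency-binned mode.

    Aggregated modes (``aggregated``, ``aggregated_noDloop``) first drop
    positions above the ``max_freq`` cap; the binned mode keeps all
    frequencies, bins each allele by its own frequency, excludes the D-loop
    from observed counts and null placement, and recomputes the type
    proportions within every bin.  BH runs across genes and conditions
    within the mode (per bin for the binned mode); verdicts use the
    ``bh_threshold`` and the side of 1 of the ratio.
    """
    if isinstance(tables, ConditionTable):
        tables = [tables]
    config = config or SimulationConfig()
    if mode not in ("aggregated", "aggregated_noDloop", "binned"):
        raise ValueError(f"unknown mode {mode!r}")
    rows: list[dict] = []
    for t_idx, table in enumerate(tables):
        cfg = SimulationConfig(
            n_sims=config.n_sims,
            seed=config.seed + 7919 * t_idx,
            placement_domain=config.placement_domain,
            placement_unit=config.placement_unit,
        )
        if mode in ("aggregated", "aggregated_noDloop"):
            filtered = apply_site_filters(table, max_freq=max_freq)
            rows.extend(_scan_one(filtered, genome, mode, None, cfg))
        else:
            freq = table.allele_frequencies().to_numpy()
            edges = np.asarray(bin_edges, dtype=float)
            if not np.all(np.diff(edges) > 0):
                raise ValueError("bin edges must be strictly increasing")
            for b in range(len(edges) - 1):
                lo, hi = edges[b], edges[b + 1]
                sub = table.copy()
                inbin = (freq >= lo) & (freq < hi)
                sub.variants = table.variants[inbin].reset_index(drop=True)
                if sub.variants.empty:
                    continue
                if sub.per_sample is not None:
                    keys = set(
                        map(tuple, sub.variants[["position", "ref", "alt"]].itertuples(index=False))
                    )
                    ps_keys = list(
                        map(tuple, sub.per_sample[["position", "ref", "alt"]].itertuples(index=False))
                    )
                    sub.per_sample = sub.per_sample[
                        [k in keys for k in ps_keys]
                    ].reset_index(drop=True)
                label = f"[{lo:g},{hi:g})"
                bcfg = SimulationConfig(
                    n_sims=cfg.n_sims,
                    seed=cfg.seed + 104729 * (b + 1),
                    placement_domain="noDloop",
                    placement_unit=cfg.placement_unit,
                )
                rows.extend(_scan_one(sub, genome, mode, label, bcfg))
    df = pd.DataFrame(
        rows,
        columns=[
            "condition", "gene", "mode", "bin_label", "hN", "hS", "ratio",
            "n_sims", "empirical_p",
        ],
    )
    df["adjusted_p"] = np.nan
    df["verdict"] = "undefined"
    if len(df):
        df = _verdicts(df, bh_threshold)
    return df


def consequence_sfs(
    table: ConditionTable,
    genome: ReferenceGenome,
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Frequency spectra of missense vs synonymous mutations.

    Per frequency bin, the alt-depth-weighted count of missense (synonymous)
    coding SNVs relative to the total missense (synonymous) count; each of
    the two columns sums to 1 when any such mutation exists.
    """
    pm = PlacementModel.for_genome(genome, False)
    events = _observed_events(table, pm)
    freq = pd.Series(
        table.allele_frequencies().to_numpy(), index=table.variants.index
    )
    snv_mask = table.variants["kind"] == "SNV"
    events = events.assign(freq=freq[snv_mask].to_numpy())
    is_nonsyn = (events["code"] > 0) & (events["code"] % 2 == 1)
    is_syn = (events["code"] > 0) & (events["code"] % 2 == 0)
    edges = np.asarray(bin_edges, dtype=float)
    labels = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    out = pd.DataFrame(0.0, index=labels, columns=["missense", "synonymous"])
    which = np.clip(np.searchsorted(edges, events["freq"].to_numpy(), side="right") - 1, -1, len(labels))
    for name, mask in (("missense", is_nonsyn), ("synonymous", is_syn)):
        sel = mask.to_numpy() & (which >= 0) & (which < len(labels))
        w = events["weight"].to_numpy()[sel]
        b = which[sel]
        sums = np.zeros(len(labels))
        np.add.at(sums, b, w)
        total = sums.sum()
        out[name] = sums / total if total > 0 else np.nan
    out.index.name = "bin"
    return out
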