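"""Ground-truth recovery benchmarks on the canonical synthetic scenarios.

Each routine regenerates data from a scenario of :mod:`mitosoma.simulate`,
runs the corresponding analysis end to end, and measures how well the known
truth is recovered (or, for the exact primitives, how closely an independent
computation is matched).  They are used both by the test suite and by the
reproduction script, and are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaincinv, gammaln

from .genome import (
    GeneticCode,
    ReferenceGenome,
    RegionAnnotation,
    count_syn_nonsyn_sites,
    translate_with_frameshift,
)
from .hotspots import sliding_window_scan
from .reversions import estimate_numt_contamination, haplotype_site_test
from .selection import SimulationConfig, selection_scan
from .simulate import (
    GenomeSpec,
    dloop_artifact_truth,
    generate_genome,
    missense_thinning_truth,
    neutral_truth,
    reversion_truth,
    condition_table,
)
from .stats import fisher_exact, poisson_ci
from .variants import ConditionTable, VARIANT_COLUMNS


def _default_genome(seed: int = 1) -> ReferenceGenome:
    genome, _ = generate_genome(GenomeSpec(), seed=seed)
    return genome


# ---------------------------------------------------------------------------
# Exact primitives against independent computations
# ---------------------------------------------------------------------------


def site_counting_agreement(n_genes: int = 100, max_codons: int = 30, seed: int = 0) -> dict:
    """Equal-weight site counts vs brute-force enumeration on random genes."""
    rng = np.random.default_rng(seed)
    code = GeneticCode()
    non_stop = [c for c, aa in code.table.items() if aa != "*"]
    agree = 0
    max_err = 0.0
    for _ in range(n_genes):
        k = int(rng.integers(1, max_codons + 1))
        cds = "".join(rng.choice(non_stop, size=k))
        genome = ReferenceGenome(cds, [RegionAnnotation("g", "protein_coding", 1, len(cds), "+")])
        nonsyn, syn = count_syn_nonsyn_sites(genome, genome.regions[0])
        bn = bs = 0.0
        for i in range(len(cds)):
            cstart = i - i % 3
            codon = cds[cstart : cstart + 3]
            for b in "ACGT":
                if b == cds[i]:
                    continue
                mutated = codon[: i % 3] + b + codon[i % 3 + 1 :]
                if code.table[mutated] == code.table[codon]:
                    bs += 1 / 3
                else:
                    bn += 1 / 3
        err = max(abs(nonsyn - bn), abs(syn - bs))
        max_err = max(max_err, err)
        agree += err < 1e-9 and abs(nonsyn + syn - len(cds)) < 1e-9
    return {"n_genes": n_genes, "n_agree": agree, "max_abs_error": max_err}


def poisson_ci_max_error(k_max: int = 50) -> float:
    """Largest deviation of the CI bounds from the inverse-gamma closed form."""
    err = 0.0
    for k in range(k_max + 1):
        lo, hi = poisson_ci(k)
        lo_ref = 0.0 if k == 0 else float(gammaincinv(k, 0.025))
        hi_ref = float(gammaincinv(k + 1, 0.975))
        err = max(err, abs(lo - lo_ref), abs(hi - hi_ref))
    return err


def fisher_max_error(n_tables: int = 200, max_margin: int = 10_000, seed: int = 0) -> float:
    """Two-sided Fisher p vs direct log-gamma hypergeometric summation."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(0, max_margin // 2, size=4))
        _, p = fisher_exact([[a, b], [c, d]])
        N, K, n = a + b + c + d, a + b, a + c
        ks = np.arange(max(0, K + n - N), min(K, n) + 1)
        lp = (
            gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
            + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
        )
        p_ref = float(np.exp(lp[lp <= lp[ks == a][0] + 1e-12]).sum())
        worst = max(worst, abs(p - min(p_ref, 1.0)))
    return worst


def frameshift_oracle_agreement(n_genes: int = 50, seed: int = 0) -> dict:
    """Premature-stop indices after A indels vs string-surgery re-translation."""
    rng = np.random.default_rng(seed)
    code = GeneticCode()
    non_stop = [c for c, aa in code.table.items() if aa != "*"]
    agree = total = 0
    for _ in range(n_genes):
        cds = "ATG" + "".join(rng.choice(non_stop, size=20)) + "TAA"
        genome = ReferenceGenome(cds, [RegionAnnotation("g", "protein_coding", 1, len(cds), "+")])
        pos = int(rng.integers(1, len(cds) - 1))
        for op in ("insert_A", "delete_A"):
            mutated = cds[:pos] + "A" + cds[pos:] if op == "insert_A" else cds[:pos] + cds[pos + 1 :]
            aa = code.translate(mutated)
            expected = aa.index("*") + 1 if "*" in aa else None
            got = translate_with_frameshift(genome, genome.regions[0], pos, op)
            agree += got == expected
            total += 1
    return {"n_cases": total, "n_agree": agree}


def hotspot_geometry(window: int = 150, L: int = 1_000, position: int = 400) -> dict:
    """Window count over a single mutated position, and rotation equivariance."""
    variants = pd.DataFrame(
        [(position, "C", "T", "SNV", 10)], columns=VARIANT_COLUMNS
    )
    depth = np.full(L, 1_000.0)
    t = ConditionTable(("B6", "liver", "young"), variants, depth)
    track = sliding_window_scan(t, window=window)
    n_elevated = int((track.frequency > 0).sum())
    r = 217
    rotated = ConditionTable(
        ("B6", "liver", "young"),
        pd.DataFrame([((position - 1 + r) % L + 1, "C", "T", "SNV", 10)], columns=VARIANT_COLUMNS),
        depth,
    )
    track_rot = sliding_window_scan(rotated, window=window)
    exact = bool(np.array_equal(np.roll(track.frequency, r), track_rot.frequency))
    return {"n_elevated_windows": n_elevated, "rotation_bit_exact": exact}


# ---------------------------------------------------------------------------
# Scenario recovery suites
# ---------------------------------------------------------------------------


def null_calibration(n_seeds: int = 50, n_sims: int = 2_000, seed: int = 0) -> dict:
    """False-call fraction of the selection test on neutral data.

    Each seed simulates one neutral condition (no thinning, no region
    multipliers) over the default 8-gene genome and runs the aggregated
    selection scan; significance is BH-adjusted p < 0.01 within the
    condition.
    """
    genome = _default_genome()
    sig = tot = 0
    for i in range(n_seeds):
        truth = neutral_truth(seed=seed + i)
        t, _ = condition_table(truth, genome, [], ("B6", "liver", "young"))
        df = selection_scan(
            t, genome, "aggregated", SimulationConfig(n_sims=n_sims, seed=seed + i)
        )
        sig += int(df.verdict.isin(["positive", "negative"]).sum())
        tot += int((df.verdict != "undefined").sum())
    return {"n_tests": tot, "n_significant": sig, "fraction_significant": sig / tot}


def artifact_reproduction(n_seeds: int = 50, n_sims: int = 2_000, seed: int = 0) -> dict:
    """Frequency-pooled vs binned selection on the D-loop hotspot scenario.

    Three conditions per seed; the aggregated scan should call positive
    selection (the spectrum-pooling artifact) while the binned, D-loop-
    excluded scan should stay quiet.
    """
    genome = _default_genome()
    conds = [("B6", "brain", "young"), ("B6", "heart", "young"), ("B6", "liver", "young")]
    agg_hit = clean = joint = 0
    for i in range(n_seeds):
        truth = dloop_artifact_truth(seed=seed + i)
        tables = [condition_table(truth, genome, [], c)[0] for c in conds]
        cfg = SimulationConfig(n_sims=n_sims, seed=seed + i)
        da = selection_scan(tables, genome, "aggregated", cfg)
        db = selection_scan(tables, genome, "binned", cfg)
        a = int((da.verdict == "positive").sum()) >= 1
        b = int(db.verdict.isin(["positive", "negative"]).sum()) == 0
        agg_hit += a
        clean += b
        joint += a and b
    return {
        "n_seeds": n_seeds,
        "fraction_aggregated_positive": agg_hit / n_seeds,
        "fraction_binned_clean": clean / n_seeds,
        "fraction_artifact_reproduced": joint / n_seeds,
    }


def thinning_recovery(n_seeds: int = 50, n_sims: int = 2_000, seed: int = 0, edge: float = 5e-5) -> dict:
    """Binned selection on data whose amino-acid-changing mutations are
    thinned 2-fold above the frequency edge; counts where the significant
    verdicts land relative to that edge."""
    genome = _default_genome()
    hi = lo = 0
    for i in range(n_seeds):
        truth = missense_thinning_truth(seed=seed + i, edge=edge)
        t, _ = condition_table(truth, genome, [], ("B6", "liver", "young"))
        df = selection_scan(
            t, genome, "binned", SimulationConfig(n_sims=n_sims, seed=seed + i)
        )
        for _, row in df[df.verdict.isin(["positive", "negative"])].iterrows():
            bin_lo = float(row.bin_label.strip("[)").split(",")[0])
            if bin_lo >= edge:
                hi += 1
            else:
                lo += 1
    total = hi + lo
    return {
        "n_significant": total,
        "n_in_bins_above_edge": hi,
        "concentration_above_edge": hi / total if total else np.nan,
    }


def reversion_recovery(n_seeds: int = 100, fold: float = 7.0, seed: int = 0) -> dict:
    """NUMT-corrected reversion enrichment on the contaminated scenario.

    Per seed: estimate the contamination fraction from junction counts,
    correct the four haplotype sites, compare each to the background
    per-position frequency distribution (BH at 0.01), and estimate the fold
    as mean corrected site frequency over mean background frequency.
    """
    genome, sites = generate_genome(
        GenomeSpec(n_haplotype_sites=4, haplotype_interval=(1000, 3000)), seed=1
    )
    site_pos = {s.position for s in sites}
    bg_idx = np.array([p for p in range(genome.L) if p + 1 not in site_pos])
    folds = []
    all_sig = 0
    joint = 0
    for i in range(n_seeds):
        truth = reversion_truth(seed=seed + i, fold=fold)
        t, extras = condition_table(truth, genome, sites, ("CONP", "liver", "young"))
        lo, hi = truth.numt_interval
        outside = np.ones(genome.L, bool)
        outside[lo - 1 : hi] = False
        est = estimate_numt_contamination(
            extras["junction_counts"], t.depth[outside].mean()
        )
        df, _ = haplotype_site_test(t, sites, est, numt_interval=truth.numt_interval)
        fold_est = float(df.corrected_freq.mean() / t.position_frequency()[bg_idx].mean())
        folds.append(fold_est)
        sig = bool((df.adjusted_p < 0.01).all())
        within = abs(fold_est / fold - 1) < 0.25
        all_sig += sig
        joint += sig and within
    return {
        "n_seeds": n_seeds,
        "median_fold_estimate": float(np.median(folds)),
        "true_fold": fold,
        "fraction_all_sites_significant": all_sig / n_seeds,
        "fraction_recovered": joint / n_seeds,
    }
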