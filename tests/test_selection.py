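import numpy as np
import pandas as pd
import pytest

from mitosoma.genome import annotate_substitution, count_syn_nonsyn_sites
from mitosoma.selection import (
    PlacementModel,
    SimulationConfig,
    compute_hnhs,
    consequence_sfs,
    empirical_pvalue,
    selection_scan,
    simulate_null,
    _observed_events,
)
from mitosoma.simulate import GenomeSpec, generate_genome, neutral_truth, condition_table
from mitosoma.spectra import SNV_CLASSES
from mitosoma.stats import empirical_p_two_tailed
from mitosoma.variants import apply_site_filters


def find_substitution(genome, gene, want):
    """First substitution in a gene with the requested consequence."""
    for p in genome.coding_positions(gene):
        p = int(p)
        ref = genome.base(p)
        for alt in "ACGT":
            if alt != ref and annotate_substitution(genome, p, ref, alt) == want:
                return p, ref, alt
    raise AssertionError(f"no {want} substitution found")


class TestComputeHnhs:
    def test_ratio_arithmetic(self, default_genome, table_factory):
        gene = default_genome.regions_of_class("protein_coding")[0]
        p_n, r_n, a_n = find_substitution(default_genome, gene, "missense")
        p_s, r_s, a_s = find_substitution(default_genome, gene, "synonymous")
        t = table_factory(
            default_genome.L,
            [(p_n, r_n, a_n, "SNV", 5), (p_s, r_s, a_s, "SNV", 2)],
            depth=10_000,
        )
        res = compute_hnhs(t, default_genome, gene)
        n_sites, s_sites = count_syn_nonsyn_sites(default_genome, gene)
        assert res.hN == pytest.approx(5 / n_sites)
        assert res.hS == pytest.approx(2 / s_sites)
        assert res.ratio == pytest.approx((5 / n_sites) / (2 / s_sites))

    def test_zero_synonymous_is_undefined(self, default_genome, table_factory):
        gene = default_genome.regions_of_class("protein_coding")[0]
        p_n, r_n, a_n = find_substitution(default_genome, gene, "missense")
        t = table_factory(default_genome.L, [(p_n, r_n, a_n, "SNV", 5)], depth=10_000)
        res = compute_hnhs(t, default_genome, gene)
        assert np.isnan(res.ratio)
        assert res.verdict == "undefined"


class TestSimulateNull:
    def test_zero_total_count_all_undefined(self, default_genome):
        cfg = SimulationConfig(
            n_sims=5, seed=0, placement_unit="read",
            type_proportions=pd.Series({c: 1 / 6 for c in SNV_CLASSES}),
            total_count=0,
        )
        null = simulate_null(default_genome, cfg)
        assert null.isna().all().all()

    def test_fixed_seed_bit_identical(self, default_genome, table_factory):
        gene = default_genome.regions_of_class("protein_coding")[0]
        p_n, r_n, a_n = find_substitution(default_genome, gene, "missense")
        t = table_factory(default_genome.L, [(p_n, r_n, a_n, "SNV", 5)], depth=10_000)
        pm = PlacementModel.for_genome(default_genome)
        ev = _observed_events(t, pm)
        cfg = SimulationConfig(n_sims=50, seed=42)
        n1 = simulate_null(default_genome, cfg, events=ev)
        n2 = simulate_null(default_genome, cfg, events=ev)
        pd.testing.assert_frame_equal(n1, n2)

    def test_event_null_matches_brute_force_resampler(self, toy_genome, table_factory):
        """Independent oracle: relocate events with a plain python loop over
        admissible positions and annotate_substitution, compare null means."""
        rows = [(19, "C", "T", "SNV", 4), (16, "A", "C", "SNV", 2), (24, "T", "G", "SNV", 3)]
        t = table_factory(toy_genome.L, rows, depth=10_000)
        pm = PlacementModel.for_genome(toy_genome)
        ev = _observed_events(t, pm)
        null = simulate_null(toy_genome, SimulationConfig(n_sims=400, seed=1), events=ev)

        rng = np.random.default_rng(7)
        refs = np.array(list(toy_genome.sequence))
        gene = toy_genome.regions_of_class("protein_coding")[0]
        n_sites, s_sites = count_syn_nonsyn_sites(toy_genome, gene)
        ratios = []
        for _ in range(400):
            hn = hs = 0.0
            for _, e in ev.iterrows():
                cls = SNV_CLASSES[int(e.class_idx)]
                pur = cls.split("/")[0]
                comp = dict(zip("ACGT", "TGCA"))
                cands = [
                    (i + 1, refs[i], pur[2] if refs[i] == pur[0] else comp[pur[2]])
                    for i in range(toy_genome.L)
                    if refs[i] in (pur[0], comp[pur[0]])
                ]
                pos, ref, alt = cands[int(rng.integers(len(cands)))]
                csq = annotate_substitution(toy_genome, pos, ref, alt)
                if csq in ("missense", "nonsense"):
                    hn += e.weight
                elif csq == "synonymous":
                    hs += e.weight
            ratios.append((hn / n_sites) / (hs / s_sites) if hn > 0 and hs > 0 else np.nan)
        brute = np.array(ratios)
        a, b = null[gene.name].to_numpy(), brute
        mu_a, mu_b = np.nanmean(a), np.nanmean(b)
        se = np.sqrt(np.nanvar(a) / np.sum(~np.isnan(a)) + np.nanvar(b) / np.sum(~np.isnan(b)))
        assert abs(mu_a - mu_b) < 3 * se


class TestEmpiricalP:
    def test_tail_count_arithmetic(self, default_genome, table_factory):
        gene = default_genome.regions_of_class("protein_coding")[0]
        res = compute_hnhs(
            table_factory(default_genome.L, [], depth=10_000), default_genome, gene
        )
        res.ratio, res.verdict = 2.0, "none"
        null = np.concatenate([np.full(50, 3.0), np.full(9_950, 1.0)])
        res = empirical_pvalue(res, null)
        assert res.empirical_p == pytest.approx(2 * 50 / 10_000)

    def test_observation_at_null_median_clipped_to_one(self):
        null = np.linspace(0.5, 1.5, 1001)
        assert empirical_p_two_tailed(1.0, null) == 1.0


class TestScans:
    def test_single_bin_matches_aggregated_statistics(self, mito_code):
        """On a D-loop-free genome a one-bin scan reproduces the aggregated
        statistics (records are the counting unit in both when no replicate
        breakdown is attached)."""
        genome, _ = generate_genome(GenomeSpec(), seed=3)
        # D-loop-free variant of the default layout: strip the D-loop annotation
        from mitosoma.genome import ReferenceGenome

        regions = [r for r in genome.regions if r.region_class != "D-loop"]
        nodloop = ReferenceGenome(genome.sequence, regions)
        truth = neutral_truth(seed=3)
        t, _ = condition_table(truth, nodloop, [], ("B6", "liver", "young"))
        t.per_sample = None
        t = apply_site_filters(t, max_freq=1.0)
        cfg = SimulationConfig(n_sims=50, seed=0)
        agg = selection_scan(t, nodloop, "aggregated", cfg, max_freq=1.0)
        binned = selection_scan(t, nodloop, "binned", cfg, bin_edges=(0.0, 1.0))
        a = agg.set_index("gene")[["hN", "hS", "ratio"]]
        b = binned.set_index("gene")[["hN", "hS", "ratio"]]
        pd.testing.assert_frame_equal(a, b.loc[a.index])

    def test_increasing_bin_edges_required(self, default_genome, table_factory):
        t = table_factory(default_genome.L, [], depth=10_000)
        with pytest.raises(ValueError, match="strictly increasing"):
            selection_scan(t, default_genome, "binned", SimulationConfig(n_sims=2, seed=0),
                           bin_edges=(1e-3, 1e-4))

    def test_exclusions_reported_not_dropped(self, default_genome, table_factory):
        t = table_factory(default_genome.L, [], depth=10_000)
        out = selection_scan(t, default_genome, "aggregated", SimulationConfig(n_sims=2, seed=0))
        assert len(out) == len(default_genome.regions_of_class("protein_coding"))
        assert (out.verdict == "undefined").all()


class TestNullCalibration:
    def test_pvalues_uniform_under_own_null(self, default_genome, table_factory):
        """Statistics drawn from the null itself get uniform empirical
        p-values (KS distance below 3/sqrt(n))."""
        gene = default_genome.regions_of_class("protein_coding")[0]
        rng = np.random.default_rng(0)
        rows = []
        for p in rng.choice(default_genome.L, size=60, replace=False) + 1:
            ref = default_genome.base(int(p))
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append((int(p), ref, alt, "SNV", int(rng.integers(1, 6))))
        t = table_factory(default_genome.L, rows, depth=100_000)
        pm = PlacementModel.for_genome(default_genome)
        ev = _observed_events(t, pm)
        n = 500
        null = simulate_null(
            default_genome, SimulationConfig(n_sims=n, seed=5), events=ev
        )[gene.name].to_numpy()
        valid = null[~np.isnan(null)]
        pvals = np.array([empirical_p_two_tailed(x, valid) for x in valid])
        grid = np.sort(pvals)
        ks = np.max(np.abs(grid - np.arange(1, grid.size + 1) / grid.size))
        assert ks <= 3 / np.sqrt(n)


class TestConsequenceSfs:
    def test_proportions_sum_to_one_and_localise(self, default_genome, table_factory):
        gene = default_genome.regions_of_class("protein_coding")[0]
        p_n, r_n, a_n = find_substitution(default_genome, gene, "missense")
        p_s, r_s, a_s = find_substitution(default_genome, gene, "synonymous")
        t = table_factory(
            default_genome.L,
            [(p_n, r_n, a_n, "SNV", 2), (p_s, r_s, a_s, "SNV", 3)],
            depth=100_000,  # both frequencies fall in [1e-5, 5e-5)
        )
        sfs = consequence_sfs(t, default_genome)
        assert sfs["missense"].sum() == pytest.approx(1.0)
        assert sfs["synonymous"].sum() == pytest.approx(1.0)
        assert sfs.loc["[1e-05,5e-05)", "missense"] == pytest.approx(1.0)
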