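"""Synthetic duplex-sequencing datasets with known ground truth.

The generator emulates the statistical structure of an aggregated duplex
experiment on a small circular mt-genome: per-position duplex depths around
2x10^4 per sample (so ~8x10^4 per four-replicate condition, the scale of a
well-covered condition), low-frequency heteroplasmic events whose
condition-scale frequencies are log-uniform between 1e-6 and 1e-3, an
8-class mutation spectrum dominated by G>A/C>T with a strong G>T/C>A
component, region rate multipliers (D-loop, OriL), optional
frequency-dependent spectrum shifts, frequency-banded thinning of
amino-acid-changing mutations (selection), B6-reversion enrichment at
haplotype sites, and a small NUMT read contamination restricted to the
chr1-homologous interval, with matching junction read counts.

Event frequencies are parameterised on the aggregated *condition* scale
(the scale every analysis consumes): an event drawn at frequency f in one
of n replicate samples receives a per-sample binomial frequency of n*f, so
the aggregated table shows it near f.  Fixed seeds give byte-identical
outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneticCode, HaplotypeSite, ReferenceGenome, RegionAnnotation, revcomp
from .selection import PlacementModel
from .spectra import ALL_CLASSES
from .variants import SampleMeta, aggregate_condition

_ALT_IDX = {b: i for i, b in enumerate("ACGT")}

#: default 8-class spectrum, shaped like an aged-rodent mitochondrial profile
DEFAULT_SPECTRUM = {
    "G>A/C>T": 0.35,
    "G>T/C>A": 0.22,
    "G>C/C>G": 0.06,
    "T>C/A>G": 0.12,
    "T>A/A>T": 0.05,
    "T>G/A>C": 0.05,
    "INS": 0.05,
    "DEL": 0.10,
}


def _stable_seed(*parts) -> list[int]:
    out = []
    for p in parts:
        if isinstance(p, int):
            out.append(p % (2**31))
        else:
            out.append(zlib.crc32(str(p).encode()) % (2**31))
    return out


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Layout of the synthetic circular mt-genome."""

    n_genes: int = 8
    gene_length: int = 450  # nt, divisible by 3, includes start and stop codons
    dloop_length: int = 900
    trna_length: int = 70
    oril_length: int = 32
    rrna_lengths: tuple[int, int] = (400, 300)
    spacer_length: int = 28
    minus_strand_genes: tuple[int, ...] = (5,)  # 0-based gene indices on the minus strand
    n_haplotype_sites: int = 0
    haplotype_interval: tuple[int, int] | None = None  # restrict site placement
    haplotype_strain: str = "CONP"

    def __post_init__(self):
        if self.gene_length % 3:
            raise ValueError("gene_length must be divisible by 3")
        if self.n_genes < 1 or self.dloop_length < 100:
            raise ValueError("degenerate genome layout")


def _random_orf(rng, length: int, code: GeneticCode) -> str:
    """Random ORF: ATG start, TAA stop, no internal stop under the mito code."""
    non_stop = [c for c, aa in code.table.items() if aa != "*" and c != "ATG"]
    n_mid = length // 3 - 2
    mid = rng.choice(non_stop, size=n_mid)
    return "ATG" + "".join(mid) + "TAA"


def generate_genome(
    spec: GenomeSpec, seed: int = 0
) -> tuple[ReferenceGenome, list[HaplotypeSite]]:
    """Build a random genome realising the layout, with valid ORFs.

    Genes are synthesised as stop-free ORFs (on their coding strand);
    haplotype sites, when requested, are placed at distinct positions inside
    coding genes (restricted to ``haplotype_interval`` when set) with the
    reference carrying the conplastic allele.
    """
    rng = np.random.default_rng(_stable_seed(seed, "genome"))
    code = GeneticCode()
    chunks: list[str] = []
    regions: list[RegionAnnotation] = []
    cursor = 1

    def add(name, region_class, seq, strand="+"):
        nonlocal cursor
        chunks.append(seq)
        regions.append(
            RegionAnnotation(name, region_class, cursor, cursor + len(seq) - 1, strand)
        )
        cursor += len(seq)

    def random_seq(n):
        return "".join(rng.choice(list("ACGT"), size=n))

    add("D-loop", "D-loop", random_seq(spec.dloop_length))
    add("tRNA-1", "tRNA", random_seq(spec.trna_length))
    half = spec.n_genes // 2
    for i in range(half):
        orf = _random_orf(rng, spec.gene_length, code)
        strand = "-" if i in spec.minus_strand_genes else "+"
        add(f"gene{i + 1}", "protein_coding", revcomp(orf) if strand == "-" else orf, strand)
    add("OriL", "OriL", random_seq(spec.oril_length))
    for i in range(half, spec.n_genes):
        orf = _random_orf(rng, spec.gene_length, code)
        strand = "-" if i in spec.minus_strand_genes else "+"
        add(f"gene{i + 1}", "protein_coding", revcomp(orf) if strand == "-" else orf, strand)
    add("tRNA-2", "tRNA", random_seq(spec.trna_length))
    add("rRNA-1", "rRNA", random_seq(spec.rrna_lengths[0]))
    add("rRNA-2", "rRNA", random_seq(spec.rrna_lengths[1]))
    if spec.spacer_length:
        add("spacer", "other", random_seq(spec.spacer_length))

    genome = ReferenceGenome("".join(chunks), regions)

    sites: list[HaplotypeSite] = []
    if spec.n_haplotype_sites:
        from .genome import annotate_substitution

        coding = np.concatenate(
            [genome.coding_positions(g) for g in genome.regions_of_class("protein_coding")]
        )
        if spec.haplotype_interval:
            lo, hi = spec.haplotype_interval
            coding = coding[(coding >= lo) & (coding <= hi)]
        if coding.size < spec.n_haplotype_sites:
            raise ValueError("more haplotype sites requested than available positions")
        chosen = np.sort(rng.choice(coding, size=spec.n_haplotype_sites, replace=False))
        for p in chosen:
            p = int(p)
            ref = genome.base(p)
            b6 = rng.choice([b for b in "ACGT" if b != ref])
            csq = annotate_substitution(genome, p, ref, b6)
            sites.append(
                HaplotypeSite(
                    position=p,
                    b6_allele=str(b6),
                    conplastic_allele=ref,
                    strain=spec.haplotype_strain,
                    consequence="missense" if csq == "nonsense" else csq,
                )
            )
    return genome, sites


def write_genome_files(
    genome: ReferenceGenome, sites: list[HaplotypeSite], out_dir: str | Path
) -> dict:
    """Write FASTA, BED6+2 and haplotype TSV in the formats the loaders read."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.L, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
    bed = out / "regions.bed"
    with open(bed, "w") as fh:
        for r in genome.regions:
            fh.write(
                f"{genome.name}\t{r.start - 1}\t{r.end}\t{r.name}\t0\t{r.strand}\t"
                f"{r.region_class}\t{r.frame_offset}\n"
            )
    hap = out / "haplotype_sites.tsv"
    pd.DataFrame(
        [
            {
                "position": s.position,
                "b6_allele": s.b6_allele,
                "conplastic_allele": s.conplastic_allele,
                "strain": s.strain,
            }
            for s in sites
        ],
        columns=["position", "b6_allele", "conplastic_allele", "strain"],
    ).to_csv(hap, sep="\t", index=False)
    return {"fasta": fasta, "bed": bed, "haplotype_tsv": hap}


# ---------------------------------------------------------------------------
# Condition simulation
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated experiment."""

    base_rate: float = 0.05  # expected mutation events per position per sample
    spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    spectrum_high: dict | None = None  # class mix above high_freq_threshold
    high_freq_threshold: float | None = None
    freq_range: tuple[float, float] = (1e-6, 1e-3)  # condition-scale, log-uniform
    region_freq_ranges: dict = field(default_factory=dict)  # region_class -> (lo, hi)
    region_multipliers: dict = field(default_factory=dict)  # region_class -> rate fold
    segment_multipliers: list = field(default_factory=list)  # (start, end, fold)
    missense_thinning: float = 1.0  # divide amino-acid-changing event rate by this ...
    thinning_freq_band: tuple[float, float] = (5e-5, np.inf)  # ... in this band
    age_rate_factor: dict = field(default_factory=lambda: {"young": 1.0, "aged": 2.0})
    reversion_fold: float = 0.0  # haplotype-site B6 frequency as fold over background mean
    reversion_age_factor: dict = field(default_factory=lambda: {"young": 1.0, "aged": 1.0})
    contamination: float = 0.0  # NUMT read fraction
    numt_interval: tuple[int, int] | None = (1000, 3000)
    depth_mean: float = 20_000.0
    depth_dispersion: float = 2000.0  # NB size; ~2% positional spread, duplex coverage is smooth
    n_replicates: int = 4
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["thinning_freq_band"] = [self.thinning_freq_band[0], min(self.thinning_freq_band[1], 1e30)]
        return json.dumps(d, indent=2, default=float)


def _position_params(truth: SimTruth, genome: ReferenceGenome):
    """Per-position rate multiplier and frequency range from the region layout."""
    mult = np.ones(genome.L)
    lo = np.full(genome.L, truth.freq_range[0])
    hi = np.full(genome.L, truth.freq_range[1])
    for r in genome.regions:
        pos0 = genome.region_positions(r) - 1
        if r.region_class in truth.region_multipliers:
            mult[pos0] *= truth.region_multipliers[r.region_class]
        if r.region_class in truth.region_freq_ranges:
            flo, fhi = truth.region_freq_ranges[r.region_class]
            lo[pos0], hi[pos0] = flo, fhi
    for start, end, fold in truth.segment_multipliers:
        mult[start - 1 : end] *= fold
    return mult, lo, hi


def expected_background_frequency(truth: SimTruth, genome: ReferenceGenome) -> float:
    """Expected per-position aggregated mutation frequency away from haplotype sites."""
    mult, lo, hi = _position_params(truth, genome)
    mean_f = (hi - lo) / np.log(hi / lo)
    return float(truth.n_replicates * truth.base_rate * np.mean(mult * mean_f))


def _class_probs(spectrum: dict, group: str) -> np.ndarray:
    """Spectrum restricted to the classes admissible on a reference group."""
    probs = np.array([spectrum.get(c, 0.0) for c in ALL_CLASSES])
    mask = np.zeros(len(ALL_CLASSES), dtype=bool)
    for i, c in enumerate(ALL_CLASSES):
        if c in ("INS", "DEL"):
            mask[i] = True
        elif (c[0] == "G") == (group == "GC"):
            mask[i] = True
    probs = probs * mask
    if probs.sum() <= 0:
        raise ValueError(f"spectrum has no admissible classes for group {group}")
    return probs / probs.sum()


def _alleles_for_class(cls: str, ref: str, genome: ReferenceGenome, position: int):
    if cls == "INS":
        return ref, ref + "A", "INS"
    if cls == "DEL":
        return ref + genome.base(position + 1), ref, "DEL"
    part1, part2 = cls.split("/")
    if ref == part1[0]:
        return ref, part1[2], "SNV"
    if ref == part2[0]:
        return ref, part2[2], "SNV"
    raise ValueError(f"class {cls} not admissible at ref {ref}")


def simulate_sample(
    truth: SimTruth,
    genome: ReferenceGenome,
    sites: list[HaplotypeSite],
    meta: SampleMeta,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """One sample's variant table and duplex depth vector.

    Events arise Poisson per position at ``base_rate`` times the region
    multiplier; each draws a condition-scale frequency (log-uniform over the
    region's range), a class from the (possibly frequency-shifted) spectrum
    restricted to its reference base, and an alternate-read depth
    ``Binomial(depth, n_replicates * f)``.  Amino-acid-changing SNVs inside
    the thinning band are kept with probability ``1 / missense_thinning``.
    Haplotype sites add B6-allele reads at ``reversion_fold`` times the
    expected background frequency; NUMT contamination adds depth (and B6
    alternate reads at haplotype sites) inside the contaminated interval,
    plus matching junction counts (returned separately by
    :func:`simulate_condition`).
    """
    L = genome.L
    p_nb = truth.depth_dispersion / (truth.depth_dispersion + truth.depth_mean)
    depth = rng.negative_binomial(truth.depth_dispersion, p_nb, size=L).astype(float)

    mult, flo, fhi = _position_params(truth, genome)
    rate = truth.base_rate * truth.age_rate_factor.get(meta.age, 1.0)
    n_events = rng.poisson(rate * mult.sum())
    pos0 = rng.choice(L, size=n_events, p=mult / mult.sum())
    u = rng.random(n_events)
    freq = flo[pos0] * (fhi[pos0] / flo[pos0]) ** u

    refs = np.frombuffer(genome.sequence.encode(), dtype="S1").astype("U1")[pos0]
    is_gc = np.isin(refs, ["G", "C"])
    use_high = (
        np.zeros(n_events, dtype=bool)
        if truth.high_freq_threshold is None or truth.spectrum_high is None
        else freq > truth.high_freq_threshold
    )
    cls_idx = np.zeros(n_events, dtype=int)
    for gc in (True, False):
        for high in (True, False):
            m = (is_gc == gc) & (use_high == high)
            if not m.any():
                continue
            spec = truth.spectrum_high if high else truth.spectrum
            probs = _class_probs(spec, "GC" if gc else "TA")
            cls_idx[m] = rng.choice(len(ALL_CLASSES), size=int(m.sum()), p=probs)

    # selection: thin amino-acid-changing SNVs inside the frequency band
    if truth.missense_thinning != 1.0:
        pm = PlacementModel.for_genome(genome)
        keep = np.ones(n_events, dtype=bool)
        for i in range(n_events):
            cls = ALL_CLASSES[cls_idx[i]]
            if cls in ("INS", "DEL"):
                continue
            ref, alt, _ = _alleles_for_class(cls, refs[i], genome, int(pos0[i]) + 1)
            code = pm.cat[pos0[i], _ALT_IDX[alt]]
            nonsyn = code > 0 and code % 2 == 1
            lo_b, hi_b = truth.thinning_freq_band
            if nonsyn and lo_b <= freq[i] < hi_b:
                keep[i] = rng.random() < 1.0 / truth.missense_thinning
        pos0, freq, refs, cls_idx = pos0[keep], freq[keep], refs[keep], cls_idx[keep]
        n_events = int(keep.sum())

    sample_freq = np.minimum(truth.n_replicates * freq, 1.0)
    alt_depth = rng.binomial(depth[pos0].astype(int), sample_freq)
    rows = []
    for i in np.flatnonzero(alt_depth > 0):
        p1 = int(pos0[i]) + 1
        ref, alt, kind = _alleles_for_class(ALL_CLASSES[cls_idx[i]], refs[i], genome, p1)
        rows.append((p1, ref, alt, kind, int(alt_depth[i])))

    # haplotype-site reversions
    if truth.reversion_fold > 0 and sites:
        bg = expected_background_frequency(truth, genome)
        # reversions are present in every replicate, so the per-sample
        # frequency is already the condition-scale frequency
        f_site = min(
            1.0,
            truth.reversion_fold * bg * truth.reversion_age_factor.get(meta.age, 1.0),
        )
        for s in sites:
            k = rng.binomial(int(depth[s.position - 1]), f_site)
            if k > 0:
                rows.append((s.position, s.conplastic_allele, s.b6_allele, "SNV", int(k)))

    # NUMT contamination: chr1 reads add depth, and B6 alt reads at haplotype sites
    if truth.contamination > 0 and truth.numt_interval is not None:
        lo_n, hi_n = truth.numt_interval
        idx = np.arange(lo_n - 1, hi_n)
        contam = rng.poisson(truth.contamination * depth[idx])
        depth[idx] += contam
        for s in sites:
            if lo_n <= s.position <= hi_n:
                k = int(contam[s.position - lo_n])
                if k > 0:
                    rows.append((s.position, s.conplastic_allele, s.b6_allele, "SNV", k))

    variants = (
        pd.DataFrame(rows, columns=["position", "ref", "alt", "kind", "alt_depth"])
        .groupby(["position", "ref", "alt", "kind"], as_index=False)["alt_depth"]
        .sum()
        .sort_values(["position", "ref", "alt"], kind="mergesort")
        .reset_index(drop=True)
    )
    return variants[["position", "ref", "alt", "kind", "alt_depth"]], depth


def simulate_condition(
    truth: SimTruth,
    genome: ReferenceGenome,
    sites: list[HaplotypeSite],
    condition: tuple[str, str, str],
    out_dir: str | Path | None = None,
) -> tuple[list, dict]:
    """All replicate samples of one condition, plus junction counts.

    Returns ``(samples, extras)`` where ``samples`` is a list of
    ``(variants, depth, meta)`` ready for :func:`aggregate_condition` and
    ``extras['junction_counts']`` holds the per-junction mean chr1 depth
    summed across samples (two junctions flanking the NUMT interval).  With
    ``out_dir`` set, the per-sample TSVs, junction TSV and truth JSON are
    written in the formats the readers consume.
    """
    strain, tissue, age = condition
    samples = []
    junctions = np.zeros(2)
    for r in range(truth.n_replicates):
        rng = np.random.default_rng(_stable_seed(truth.seed, "/".join(condition), r))
        meta = SampleMeta(f"{strain}_{tissue}_{age}_{r + 1}", strain, tissue, age, r + 1)
        variants, depth = simulate_sample(truth, genome, sites, meta, rng)
        samples.append((variants, depth, meta))
        if truth.contamination > 0:
            window = 20  # bp of junction sequence unique to chr1
            lam = window * truth.contamination * depth.mean()
            junctions += rng.poisson(lam, size=2) / window
    extras = {"junction_counts": junctions.tolist()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for variants, depth, meta in samples:
            variants.drop(columns=["kind"]).to_csv(
                out / f"{meta.sample_id}.variants.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                {"position": np.arange(1, genome.L + 1), "duplex_depth": depth.astype(int)}
            ).to_csv(out / f"{meta.sample_id}.depth.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"junction_id": ["upstream", "downstream"], "chr1_read_count": junctions}
        ).to_csv(out / "junctions.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(truth.to_json())
    return samples, extras


def condition_table(truth, genome, sites, condition):
    """Convenience: simulate one condition and aggregate it."""
    samples, extras = simulate_condition(truth, genome, sites, condition)
    return aggregate_condition(samples), extras


# ---------------------------------------------------------------------------
# Canonical scenarios
# ---------------------------------------------------------------------------


def neutral_truth(seed: int = 0, **kw) -> SimTruth:
    """No selection, no hotspots, no reversions: the type-I-error configuration."""
    kw.setdefault("age_rate_factor", {"young": 1.0, "aged": 1.0})
    return SimTruth(seed=seed, **kw)


def hotspot_truth(seed: int = 0, segment: tuple[int, int] = (4400, 4599), fold: float = 5.0) -> SimTruth:
    """A focal rate multiplier over a segment, for window-scan recovery."""
    return SimTruth(
        seed=seed,
        segment_multipliers=[(segment[0], segment[1], fold)],
        age_rate_factor={"young": 1.0, "aged": 1.0},
    )


def dloop_artifact_truth(seed: int = 0) -> SimTruth:
    """The spurious-positive-selection regime: a D-loop hotspot of
    high-frequency mutations whose spectrum (replication-like, transition
    heavy) differs from the low-frequency genome-wide spectrum (ROS heavy).
    Pooling frequencies then biases the aggregated null toward synonymous-
    prone types while gene bodies carry the transversion-leaning spectrum."""
    low = {
        "G>A/C>T": 0.04, "G>T/C>A": 0.40, "G>C/C>G": 0.12,
        "T>C/A>G": 0.02, "T>A/A>T": 0.18, "T>G/A>C": 0.18,
        "INS": 0.02, "DEL": 0.04,
    }
    high = {
        "G>A/C>T": 0.55, "G>T/C>A": 0.005, "G>C/C>G": 0.005,
        "T>C/A>G": 0.41, "T>A/A>T": 0.005, "T>G/A>C": 0.005,
        "INS": 0.01, "DEL": 0.01,
    }
    return SimTruth(
        seed=seed,
        base_rate=0.5,
        spectrum=low,
        spectrum_high=high,
        high_freq_threshold=5e-5,
        freq_range=(1e-6, 5e-5),
        region_freq_ranges={"D-loop": (5e-5, 8e-5)},
        region_multipliers={"D-loop": 6.0, "protein_coding": 4.0},
        age_rate_factor={"young": 1.0, "aged": 1.0},
    )


def missense_thinning_truth(seed: int = 0, thinning: float = 2.0, edge: float = 5e-5) -> SimTruth:
    """Negative selection above a frequency edge: amino-acid-changing
    mutations thinned ``thinning``-fold for frequencies above ``edge``."""
    return SimTruth(
        seed=seed,
        base_rate=0.2,
        missense_thinning=thinning,
        thinning_freq_band=(edge, np.inf),
        age_rate_factor={"young": 1.0, "aged": 1.0},
    )


def reversion_truth(
    seed: int = 0,
    fold: float = 7.0,
    contamination: float = 0.005,
    aged_factor: float = 1.0,
) -> SimTruth:
    """Reversion enrichment with NUMT contamination, at an NZB-like elevated
    heteroplasmy scale where the contamination correction is material."""
    return SimTruth(
        seed=seed,
        base_rate=1.9,
        freq_range=(1e-6, 2e-4),
        reversion_fold=fold,
        reversion_age_factor={"young": 1.0, "aged": aged_factor},
        contamination=contamination,
        age_rate_factor={"young": 1.0, "aged": 1.0},
    )


SCENARIOS = {
    "neutral": neutral_truth,
    "hotspot": hotspot_truth,
    "dloop_artifact": dloop_artifact_truth,
    "missense_thinning": missense_thinning_truth,
    "reversion": reversion_truth,
}


def write_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict:
    """Emit the canonical fixture scenarios (genome + one condition each).

    Every scenario directory holds the genome files, per-sample variant and
    depth TSVs, junction counts and a ``truth.json``; regeneration with the
    same seed is byte-identical.
    """
    out = Path(out_dir)
    written = {}
    for name, make in SCENARIOS.items():
        truth = make(seed=seed)
        n_sites = 4 if name == "reversion" else 0
        spec = GenomeSpec(
            n_haplotype_sites=n_sites,
            haplotype_interval=truth.numt_interval if n_sites else None,
        )
        genome, sites = generate_genome(spec, seed=seed)
        scen_dir = out / name
        paths = write_genome_files(genome, sites, scen_dir)
        simulate_condition(truth, genome, sites, ("B6", "liver", "young"), out_dir=scen_dir)
        written[name] = paths
    return written
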