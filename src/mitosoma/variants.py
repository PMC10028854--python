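"""Reading, validation, aggregation and filtering of duplex variant tables.

A *sample* is a pair of files: a variant table (TSV dialect
``position  ref  alt  alt_depth`` or a VCF 4.2 with per-sample AD/DP) and a
per-position duplex depth table (``position  duplex_depth`` covering the whole
genome).  Samples sharing a condition key (strain, tissue, age) are summed
position-wise into a :class:`ConditionTable`; frequencies are always
recomputed from summed counts, never averaged across samples.

Multi-allelic sites are tracked per (ref, alt); the "mutation frequency at a
position" used by the frequency cap is the sum of all alternate-allele depths
divided by the duplex depth.  Indels are normalised to their left-aligned
minimal (anchor-base) representation at the reader boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import ReferenceGenome

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["position", "ref", "alt", "kind", "alt_depth"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    strain: str
    tissue: str
    age: str
    replicate: int = 1

    def __post_init__(self):
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def condition_key(self) -> tuple[str, str, str]:
        return (self.strain, self.tissue, self.age)


def classify_kind(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "INS"
    if len(ref) > len(alt):
        return "DEL"
    return "MNV"


def left_align(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal left-aligned representation, keeping at least one base each."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


class ConditionTable:
    """Per-position aggregated alternate-allele and duplex depths for one condition."""

    def __init__(
        self,
        condition: tuple[str, str, str],
        variants: pd.DataFrame,
        depth: np.ndarray,
        n_samples: int = 1,
        provenance: dict | None = None,
        per_sample: pd.DataFrame | None = None,
    ):
        missing = set(VARIANT_COLUMNS) - set(variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        self.condition = tuple(condition)
        self.variants = variants.reset_index(drop=True)
        self.depth = np.asarray(depth, dtype=float)
        self.n_samples = n_samples
        self.provenance = dict(provenance or {})
        #: optional per-replicate breakdown of the same alleles (column ``sample``);
        #: kept because replicate-private events are independent heteroplasmies,
        #: which downstream resampling nulls can then treat as separate units
        self.per_sample = per_sample.reset_index(drop=True) if per_sample is not None else None

    @property
    def L(self) -> int:
        return self.depth.size

    def copy(self) -> "ConditionTable":
        return ConditionTable(
            self.condition,
            self.variants.copy(),
            self.depth.copy(),
            self.n_samples,
            dict(self.provenance),
            self.per_sample.copy() if self.per_sample is not None else None,
        )

    def allele_frequencies(self) -> pd.Series:
        """Per-record frequency: alt_depth / duplex depth at the position."""
        d = self.depth[self.variants["position"].to_numpy(dtype=int) - 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            return pd.Series(
                np.where(d > 0, self.variants["alt_depth"].to_numpy() / d, np.nan),
                index=self.variants.index,
            )

    def position_alt_depth(self) -> np.ndarray:
        """Summed alternate-allele depth per position (length-L array)."""
        out = np.zeros(self.L)
        if len(self.variants):
            np.add.at(
                out,
                self.variants["position"].to_numpy(dtype=int) - 1,
                self.variants["alt_depth"].to_numpy(dtype=float),
            )
        return out

    def position_frequency(self) -> np.ndarray:
        """Per-position mutation frequency (sum of alt depths / duplex depth)."""
        counts = self.position_alt_depth()
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(self.depth > 0, counts / self.depth, 0.0)
        return freq


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_depth(depth_path: str | Path, L: int | None) -> np.ndarray:
    df = pd.read_csv(depth_path, sep="\t")
    if not {"position", "duplex_depth"}.issubset(df.columns):
        raise ValueError(f"{depth_path}: need columns position, duplex_depth")
    positions = df["position"].to_numpy(dtype=int)
    n = L if L is not None else int(positions.max())
    missing = sorted(set(range(1, n + 1)) - set(positions.tolist()))
    if missing:
        raise ValueError(f"{depth_path}: missing depth rows for positions {missing[:10]}")
    depth = np.zeros(n)
    depth[positions - 1] = df["duplex_depth"].to_numpy(dtype=float)
    if (depth < 0).any():
        raise ValueError(f"{depth_path}: negative depths")
    return depth


def _read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    if not {"position", "ref", "alt", "alt_depth"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns position, ref, alt, alt_depth")
    return df[["position", "ref", "alt", "alt_depth"]]


def _read_variants_vcf(path: str | Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            sample = rec.samples[0] if rec.samples else None
            ad = sample.get("AD") if sample is not None else None
            for i, alt in enumerate(rec.alts):
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    alt_depth = int(ad[i + 1])
                elif "AD" in rec.info:
                    info_ad = rec.info["AD"]
                    alt_depth = int(info_ad[i] if isinstance(info_ad, tuple) else info_ad)
                else:
                    raise ValueError(f"{path}: record at {rec.pos} lacks an AD field")
                rows.append({"position": rec.pos, "ref": rec.ref, "alt": alt, "alt_depth": alt_depth})
    return pd.DataFrame(rows, columns=["position", "ref", "alt", "alt_depth"])


def read_sample(
    variant_path: str | Path,
    depth_path: str | Path,
    meta: SampleMeta,
    genome: ReferenceGenome | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Read and validate one sample's variant and depth tables.

    Returns ``(variants, depth)`` where ``variants`` has columns
    ``position, ref, alt, kind, alt_depth`` and ``depth`` is a length-L
    float array.  Validation failures (positions beyond the genome,
    alt depth exceeding duplex depth, reference mismatches) raise with the
    offending positions listed.
    """
    depth = _read_depth(depth_path, genome.L if genome is not None else None)
    path = str(variant_path)
    df = _read_variants_vcf(path) if path.endswith(".vcf") else _read_variants_tsv(path)

    records = []
    for row in df.itertuples(index=False):
        position, ref, alt = left_align(int(row.position), str(row.ref).upper(), str(row.alt).upper())
        alt_depth = int(row.alt_depth)
        if alt_depth < 1:
            raise ValueError(f"{variant_path}: alt_depth < 1 at position {position}")
        if position < 1 or position > depth.size:
            raise ValueError(f"{variant_path}: position {position} outside 1..{depth.size}")
        if alt_depth > depth[position - 1]:
            raise ValueError(
                f"{variant_path}: alt_depth {alt_depth} exceeds duplex depth "
                f"{depth[position - 1]:.0f} at position {position}"
            )
        if genome is not None:
            expected = "".join(genome.base(position + k) for k in range(len(ref)))
            if expected != ref:
                raise ValueError(
                    f"{variant_path}: ref {ref!r} does not match genome "
                    f"{expected!r} at position {position}"
                )
        records.append((position, ref, alt, classify_kind(ref, alt), alt_depth))
    variants = pd.DataFrame(records, columns=VARIANT_COLUMNS)
    return variants, depth


# ---------------------------------------------------------------------------
# Aggregation and filters
# ---------------------------------------------------------------------------


def aggregate_condition(
    samples: list[tuple[pd.DataFrame, np.ndarray, SampleMeta]],
) -> ConditionTable:
    """Sum variant and duplex depths across the samples of one condition."""
    if not samples:
        raise ValueError("no samples to aggregate")
    keys = {meta.condition_key for _, _, meta in samples}
    if len(keys) != 1:
        raise ValueError(f"mixed condition keys: {sorted(keys)}")
    L = {depth.size for _, depth, _ in samples}
    if len(L) != 1:
        raise ValueError("samples cover genomes of different lengths")
    depth = np.sum([d for _, d, _ in samples], axis=0)
    tagged = [v.assign(sample=meta.sample_id) for v, _, meta in samples]
    allv = pd.concat([v.drop(columns=["sample"]) for v in tagged], ignore_index=True)
    per_sample = pd.concat(tagged, ignore_index=True)
    if len(allv):
        agg = (
            allv.groupby(["position", "ref", "alt", "kind"], as_index=False)["alt_depth"]
            .sum()
            .sort_values(["position", "ref", "alt"], kind="mergesort")
            .reset_index(drop=True)
        )
    else:
        agg = pd.DataFrame(columns=VARIANT_COLUMNS)
    return ConditionTable(
        keys.pop(), agg[VARIANT_COLUMNS], depth, n_samples=len(samples),
        provenance={"filters": []}, per_sample=per_sample,
    )


def apply_site_filters(
    table: ConditionTable,
    haplotype_sites=None,
    max_freq: float = 1e-3,
    drop_haplotype: bool = False,
) -> ConditionTable:
    """Frequency cap and haplotype-site filter.

    Positions whose total mutation frequency (summed alt depths over duplex
    depth) exceeds ``max_freq`` lose all their alleles; with
    ``drop_haplotype`` every allele at a haplotype-site position is removed
    regardless of frequency.  Filter provenance is recorded so downstream
    analyses (the reversion module needs the unfiltered table) can tell what
    was applied.
    """
    out = table.copy()
    freq = out.position_frequency()
    keep = np.ones(len(out.variants), dtype=bool)
    pos0 = out.variants["position"].to_numpy(dtype=int) - 1
    keep &= freq[pos0] <= max_freq
    if drop_haplotype and haplotype_sites:
        hpos = {s.position for s in haplotype_sites}
        keep &= ~out.variants["position"].isin(hpos).to_numpy()
    removed_pos = set(out.variants.loc[~keep, "position"].tolist())
    out.variants = out.variants[keep].reset_index(drop=True)
    if out.per_sample is not None:
        out.per_sample = out.per_sample[
            ~out.per_sample["position"].isin(removed_pos)
        ].reset_index(drop=True)
    out.provenance.setdefault("filters", []).append(
        {"max_freq": max_freq, "drop_haplotype": bool(drop_haplotype)}
    )
    return out


def de_novo_filter(
    table: ConditionTable, max_alt_depth: int = 100, max_freq: float = 0.01
) -> pd.DataFrame:
    """Unique de-novo mutation events.

    Keeps alleles with alternate depth below ``max_alt_depth`` and allele
    frequency below ``max_freq``; each surviving (position, ref, alt) is
    scored exactly once (weight 1) regardless of its depth.
    """
    freq = table.allele_frequencies().to_numpy()
    keep = (table.variants["alt_depth"].to_numpy() < max_alt_depth) & (freq < max_freq)
    events = (
        table.variants[keep][["position", "ref", "alt", "kind"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return events


def normalize_depth(tables: list[ConditionTable]) -> list[ConditionTable]:
    """Deterministic depth normalisation across conditions.

    At every position the alternate-allele counts of each table are rescaled
    by the binomial-downsampling expectation to the minimum depth across
    tables (count * min_depth / depth) and the duplex depth is set to that
    minimum; frequencies are unchanged in expectation.  Positions with zero
    depth in any table are excluded from all tables and logged.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to normalise")
    if len({t.L for t in tables}) != 1:
        raise ValueError("tables cover genomes of different lengths")
    depths = np.stack([t.depth for t in tables])
    min_depth = depths.min(axis=0)
    excluded = np.flatnonzero(min_depth == 0)
    if excluded.size:
        logger.warning("depth normalisation: %d zero-depth positions excluded", excluded.size)
    out = []
    for t in tables:
        nt = t.copy()
        pos0 = nt.variants["position"].to_numpy() - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(t.depth > 0, min_depth / t.depth, 0.0)
        nt.variants["alt_depth"] = nt.variants["alt_depth"].to_numpy(dtype=float) * scale[pos0]
        nt.variants = nt.variants[nt.variants["alt_depth"] > 0].reset_index(drop=True)
        if nt.per_sample is not None:
            ps0 = nt.per_sample["position"].to_numpy() - 1
            nt.per_sample["alt_depth"] = (
                nt.per_sample["alt_depth"].to_numpy(dtype=float) * scale[ps0]
            )
            nt.per_sample = nt.per_sample[nt.per_sample["alt_depth"] > 0].reset_index(drop=True)
        nt.depth = min_depth.copy()
        nt.provenance["depth_normalized"] = True
        out.append(nt)
    return out


# ---------------------------------------------------------------------------
# Round-trip serialisation
# ---------------------------------------------------------------------------


def write_condition_table(table: ConditionTable, prefix: str | Path) -> None:
    """Write ``<prefix>.variants.tsv``, ``<prefix>.depth.tsv`` and a JSON sidecar."""
    prefix = Path(prefix)
    table.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"position": np.arange(1, table.L + 1), "duplex_depth": table.depth}
    ).to_csv(f"{prefix}.depth.tsv", sep="\t", index=False)
    sidecar = {
        "condition": list(table.condition),
        "n_samples": table.n_samples,
        "provenance": table.provenance,
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def read_condition_table(prefix: str | Path) -> ConditionTable:
    prefix = Path(prefix)
    variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t", dtype={"ref": str, "alt": str})
    if variants.empty:
        variants = pd.DataFrame(columns=VARIANT_COLUMNS)
    depth_df = pd.read_csv(f"{prefix}.depth.tsv", sep="\t")
    depth = np.zeros(int(depth_df["position"].max()))
    depth[depth_df["position"].to_numpy() - 1] = depth_df["duplex_depth"].to_numpy(dtype=float)
    sidecar = json.loads(Path(f"{prefix}.json").read_text())
    return ConditionTable(
        tuple(sidecar["condition"]),
        variants[VARIANT_COLUMNS],
        depth,
        n_samples=sidecar["n_samples"],
        provenance=sidecar["provenance"],
    )
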