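"""Circular mitochondrial genome model: annotations, genetic code, consequences.

The mitochondrial genome is represented as a circular sequence with 1-based
inclusive coordinates (position ``L + 1`` wraps to ``1``).  Region annotations
carry a functional class (D-loop, OriL, protein coding, tRNA, rRNA, other),
strand and reading-frame offset.  All consequence calls (synonymous /
missense / nonsense) and synonymous/nonsynonymous site counting use the
vertebrate mitochondrial genetic code (AGA/AGG stop, ATA Met, TGA Trp).

Site counting follows equal-weight Nei-Gojobori accounting: each of the three
possible substitutions at a codon position contributes 1/3 of a site to the
class of its consequence, with stop gains counted as nonsynonymous.  For a
gene of complete codons the two site totals sum exactly to the gene length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

REGION_CLASSES = ("D-loop", "OriL", "protein_coding", "tRNA", "rRNA", "other")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GeneticCode:
    """Codon -> amino-acid map (``*`` marks stop codons).

    Defaults to the vertebrate mitochondrial code (NCBI translation table 2).
    """

    def __init__(self, table_id: int = 2):
        ct = CodonTable.unambiguous_dna_by_id[table_id]
        self.table: dict[str, str] = dict(ct.forward_table)
        for codon in ct.stop_codons:
            self.table[codon] = "*"
        if len(self.table) != 64:
            raise ValueError(f"genetic code table {table_id} has {len(self.table)} codons")
        self.table_id = table_id

    def translate_codon(self, codon: str) -> str:
        return self.table[codon.upper()]

    def translate(self, seq: str) -> str:
        return "".join(self.table[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


@dataclass(frozen=True)
class RegionAnnotation:
    """A named annotated interval, 1-based inclusive; may wrap the origin."""

    name: str
    region_class: str
    start: int
    end: int
    strand: str = "+"
    frame_offset: int = 0
    wraps: bool = False

    def __post_init__(self):
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"region {self.name!r}: unknown class {self.region_class!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"region {self.name!r}: strand must be + or -")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError(f"region {self.name!r}: frame_offset must be 0-2")
        if self.start > self.end and not self.wraps:
            raise ValueError(f"region {self.name!r}: start > end but not flagged as wrapping")


@dataclass(frozen=True)
class HaplotypeSite:
    """A fixed difference between a conplastic mt-genome and the B6 genome."""

    position: int
    b6_allele: str
    conplastic_allele: str
    strain: str = ""
    consequence: str | None = None

    def __post_init__(self):
        if self.b6_allele == self.conplastic_allele:
            raise ValueError(f"haplotype site {self.position}: alleles identical")


class ReferenceGenome:
    """Circular mt-genome sequence plus typed annotations and a genetic code."""

    def __init__(
        self,
        sequence: str,
        regions: list[RegionAnnotation],
        code: GeneticCode | None = None,
        name: str = "chrM",
    ):
        sequence = sequence.upper()
        bad = [i + 1 for i, b in enumerate(sequence) if b not in "ACGT"]
        if bad:
            raise ValueError(f"non-ACGT characters at positions {bad[:10]}")
        self.sequence = sequence
        self.name = name
        self.code = code or GeneticCode()
        for r in regions:
            if not (1 <= r.start <= self.L and 1 <= r.end <= self.L):
                raise ValueError(
                    f"region {r.name!r} ({r.start}-{r.end}) outside genome of length {self.L}"
                )
        self.regions = list(regions)

    @property
    def L(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based circular position."""
        return self.sequence[(position - 1) % self.L]

    def context(self, position: int) -> str:
        """Trinucleotide context centred on ``position`` (wraps the origin)."""
        return self.base(position - 1) + self.base(position) + self.base(position + 1)

    # ---- region queries -------------------------------------------------

    def _contains(self, region: RegionAnnotation, position: int) -> bool:
        p = (position - 1) % self.L + 1
        if region.wraps:
            return p >= region.start or p <= region.end
        return region.start <= p <= region.end

    def regions_at(self, position: int) -> list[RegionAnnotation]:
        return [r for r in self.regions if self._contains(r, position)]

    def coding_region_at(self, position: int) -> RegionAnnotation | None:
        """First protein-coding region containing the position, in annotation order."""
        for r in self.regions:
            if r.region_class == "protein_coding" and self._contains(r, position):
                return r
        return None

    def regions_of_class(self, region_class: str) -> list[RegionAnnotation]:
        return [r for r in self.regions if r.region_class == region_class]

    def region_positions(self, region: RegionAnnotation) -> np.ndarray:
        """Plus-strand 1-based positions of a region in genomic order (wrapping)."""
        if region.wraps:
            return np.concatenate(
                [np.arange(region.start, self.L + 1), np.arange(1, region.end + 1)]
            )
        return np.arange(region.start, region.end + 1)

    def region_length(self, region: RegionAnnotation) -> int:
        if region.wraps:
            return self.L - region.start + 1 + region.end
        return region.end - region.start + 1

    # ---- coding geometry ------------------------------------------------

    def coding_positions(self, gene: RegionAnnotation, trim_partial: bool = True) -> np.ndarray:
        """Plus-strand positions of a gene in coding-strand order.

        Applies the frame offset and, when ``trim_partial`` is set, drops the
        trailing partial codon of genes with incomplete stop codons.
        """
        if gene.region_class != "protein_coding":
            raise ValueError(f"{gene.name!r} is not protein_coding")
        pos = self.region_positions(gene)
        if gene.strand == "-":
            pos = pos[::-1]
        if gene.frame_offset:
            pos = pos[gene.frame_offset :]
        if trim_partial and len(pos) % 3:
            logger.warning(
                "gene %s: length %d not divisible by 3; trailing partial codon excluded",
                gene.name,
                len(pos),
            )
            pos = pos[: len(pos) - len(pos) % 3]
        return pos

    def coding_base(self, position: int, strand: str) -> str:
        b = self.base(position)
        return b if strand == "+" else complement(b)

    def coding_sequence(self, gene: RegionAnnotation, trim_partial: bool = True) -> str:
        pos = self.coding_positions(gene, trim_partial=trim_partial)
        return "".join(self.coding_base(int(p), gene.strand) for p in pos)


# ---------------------------------------------------------------------------
# Consequence annotation and site counting
# ---------------------------------------------------------------------------


def annotate_substitution(genome: ReferenceGenome, position: int, ref: str, alt: str) -> str:
    """Consequence of a single-nucleotide substitution.

    Returns one of ``synonymous``, ``missense``, ``nonsense``, ``noncoding``.
    The substitution is given on the plus strand; minus-strand genes are
    handled by complementing into the coding frame.  A mismatch between
    ``ref`` and the genome sequence raises (this guards coordinate bugs).
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"need single ACGT alleles, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if genome.base(position) != ref:
        raise ValueError(
            f"ref allele {ref!r} does not match genome base "
            f"{genome.base(position)!r} at position {position}"
        )
    gene = genome.coding_region_at(position)
    if gene is None:
        return "noncoding"
    pos = genome.coding_positions(gene)
    idx = np.flatnonzero(pos == (position - 1) % genome.L + 1)
    if idx.size == 0:  # frame-offset head or trimmed partial codon
        return "noncoding"
    i = int(idx[0])
    codon_start = i - i % 3
    codon = "".join(genome.coding_base(int(p), gene.strand) for p in pos[codon_start : codon_start + 3])
    alt_coding = alt if gene.strand == "+" else complement(alt)
    mutated = codon[: i % 3] + alt_coding + codon[i % 3 + 1 :]
    aa_ref = genome.code.translate_codon(codon)
    aa_alt = genome.code.translate_codon(mutated)
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def count_syn_nonsyn_sites(genome: ReferenceGenome, gene: RegionAnnotation) -> tuple[float, float]:
    """Equal-weight synonymous/nonsynonymous site counts for a coding gene.

    Each of the 9 possible substitutions per codon contributes 1/3 site to
    the class of its consequence (stop gains count as nonsynonymous), so
    ``nonsyn + syn`` equals the counted coding length exactly.
    Returns ``(nonsyn_sites, syn_sites)``.
    """
    cds = genome.coding_sequence(gene)
    code = genome.code.table
    nonsyn = 0.0
    syn = 0.0
    for cstart in range(0, len(cds), 3):
        codon = cds[cstart : cstart + 3]
        aa = code[codon]
        for j in range(3):
            for b in "ACGT":
                if b == codon[j]:
                    continue
                mutated = codon[:j] + b + codon[j + 1 :]
                if code[mutated] == aa:
                    syn += 1.0 / 3.0
                else:
                    nonsyn += 1.0 / 3.0
    return nonsyn, syn


def translate_with_frameshift(
    genome: ReferenceGenome, gene: RegionAnnotation, position: int, op: str
) -> int | None:
    """Codon index of the first premature stop after a single-A indel.

    ``op`` is ``insert_A`` (an A inserted on the plus strand immediately
    after ``position``, the anchor-base convention of ``C>CA``) or
    ``delete_A`` (the base immediately after ``position`` removed, as in
    ``CA>C``).  The gene is re-translated from its start; returns the
    1-based codon index of the first stop codon, or ``None`` if translation
    runs to the end of the annotated gene without one.
    """
    if op not in ("insert_A", "delete_A"):
        raise ValueError(f"unknown op {op!r}")
    pos = genome.region_positions(gene)
    idx = np.flatnonzero(pos == (position - 1) % genome.L + 1)
    if idx.size == 0:
        raise ValueError(f"position {position} not in gene {gene.name!r}")
    i = int(idx[0])
    plus = "".join(genome.base(int(p)) for p in pos)
    if op == "insert_A":
        mutated = plus[: i + 1] + "A" + plus[i + 1 :]
    else:
        if i + 1 >= len(plus):
            raise ValueError("no base after the anchor within the gene")
        mutated = plus[: i + 1] + plus[i + 2 :]
    coding = mutated if gene.strand == "+" else revcomp(mutated)
    coding = coding[gene.frame_offset :]
    for c, cstart in enumerate(range(0, len(coding) - 2, 3), start=1):
        if genome.code.translate_codon(coding[cstart : cstart + 3]) == "*":
            return c
    return None


# ---------------------------------------------------------------------------
# Loading from disk
# ---------------------------------------------------------------------------


def load_reference(
    fasta_path: str | Path,
    bed_path: str | Path,
    haplotype_tsv: str | Path | None = None,
) -> tuple[ReferenceGenome, list[HaplotypeSite]]:
    """Load a single-record FASTA, a BED6+2 annotation, and optional haplotype sites.

    The BED is 0-based half-open with columns
    ``chrom start end name score strand region_class frame``; coordinates are
    converted to the 1-based inclusive convention used throughout.  Haplotype
    sites come from a TSV with header
    ``position  b6_allele  conplastic_allele  strain`` and are annotated with
    the consequence of the reversion substitution (conplastic -> B6 allele);
    stop gains are folded into ``missense`` for site classification.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one FASTA record, found {len(records)}")
    sequence = str(records[0].seq).upper()

    regions = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{bed_path}: expected BED6+2 (8 columns), got {len(f)}")
            start0, end0 = int(f[1]), int(f[2])
            if end0 > len(sequence):
                raise ValueError(
                    f"region {f[3]!r} end {end0} exceeds genome length {len(sequence)}"
                )
            regions.append(
                RegionAnnotation(
                    name=f[3],
                    region_class=f[6],
                    start=start0 + 1,
                    end=end0,
                    strand=f[5],
                    frame_offset=int(f[7]),
                )
            )
    genome = ReferenceGenome(sequence, regions, name=records[0].id)

    sites: list[HaplotypeSite] = []
    if haplotype_tsv is not None:
        import pandas as pd

        df = pd.read_csv(haplotype_tsv, sep="\t")
        required = {"position", "b6_allele", "conplastic_allele", "strain"}
        if not required.issubset(df.columns):
            raise ValueError(f"{haplotype_tsv}: missing columns {required - set(df.columns)}")
        for row in df.itertuples(index=False):
            p = int(row.position)
            if not 1 <= p <= genome.L:
                raise ValueError(f"haplotype site position {p} outside 1..{genome.L}")
            csq = annotate_substitution(genome, p, str(row.conplastic_allele), str(row.b6_allele))
            if csq == "nonsense":
                csq = "missense"
            sites.append(
                HaplotypeSite(
                    position=p,
                    b6_allele=str(row.b6_allele),
                    conplastic_allele=str(row.conplastic_allele),
                    strain=str(row.strain),
                    consequence=csq,
                )
            )
    return genome, sites
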