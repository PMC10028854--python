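import numpy as np
import pytest

from mitosoma.genome import (
    GeneticCode,
    ReferenceGenome,
    RegionAnnotation,
    annotate_substitution,
    count_syn_nonsyn_sites,
    load_reference,
    revcomp,
    translate_with_frameshift,
)
from mitosoma.simulate import write_genome_files


def brute_force_sites(cds: str, code: GeneticCode):
    """Independent oracle: enumerate all single-nucleotide changes of a CDS."""
    nonsyn = syn = 0.0
    for i in range(len(cds)):
        codon_start = i - i % 3
        codon = cds[codon_start : codon_start + 3]
        for b in "ACGT":
            if b == cds[i]:
                continue
            mutated = codon[: i % 3] + b + codon[i % 3 + 1 :]
            if code.translate_codon(mutated) == code.translate_codon(codon):
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return nonsyn, syn


class TestGeneticCode:
    def test_vertebrate_mitochondrial_reassignments(self, mito_code):
        assert mito_code.translate_codon("AGA") == "*"
        assert mito_code.translate_codon("AGG") == "*"
        assert mito_code.translate_codon("ATA") == "M"
        assert mito_code.translate_codon("TGA") == "W"
        assert len(mito_code.table) == 64


class TestAnnotateSubstitution:
    def test_third_position_transition_is_synonymous(self, toy_genome):
        # codon 1 is ATG at 13-15; G>A gives ATA = Met under the mito code
        assert annotate_substitution(toy_genome, 15, "G", "A") == "synonymous"

    def test_stop_gain_is_nonsense(self, toy_genome):
        # codon 3 is CGA at 19-21; C>A gives AGA = STOP in the mito code
        assert annotate_substitution(toy_genome, 19, "C", "A") == "nonsense"

    def test_amino_acid_change_is_missense(self, toy_genome):
        # codon 2 AAA (Lys), first position A>C gives CAA (Gln)
        assert annotate_substitution(toy_genome, 16, "A", "C") == "missense"

    def test_dloop_position_is_noncoding(self, toy_genome):
        assert annotate_substitution(toy_genome, 5, toy_genome.base(5), "G") in ("noncoding",)

    def test_reference_mismatch_raises(self, toy_genome):
        with pytest.raises(ValueError, match="does not match"):
            annotate_substitution(toy_genome, 15, "C", "A")

    def test_agrees_with_brute_force_translation(self, mito_code):
        """Random toy genes: consequence equals full-translation comparison."""
        rng = np.random.default_rng(7)
        non_stop = [c for c, aa in mito_code.table.items() if aa != "*"]
        for _ in range(10):
            k = rng.integers(2, 12)
            cds = "ATG" + "".join(rng.choice(non_stop, size=k)) + "TAA"
            genome = ReferenceGenome(
                cds, [RegionAnnotation("g", "protein_coding", 1, len(cds), "+")]
            )
            for i in range(len(cds)):
                for alt in "ACGT":
                    if alt == cds[i]:
                        continue
                    mutated = cds[:i] + alt + cds[i + 1 :]
                    aa0 = mito_code.translate(cds)
                    aa1 = mito_code.translate(mutated)
                    got = annotate_substitution(genome, i + 1, cds[i], alt)
                    j = i // 3
                    if aa1[j] == aa0[j]:
                        assert got == "synonymous"
                    elif aa1[j] == "*":
                        assert got == "nonsense"
                    else:
                        assert got == "missense"

    def test_minus_strand_matches_revcomp_gene(self, mito_code):
        """A substitution on a minus-strand gene equals the consequence of its
        complement in the equivalent plus-strand gene."""
        rng = np.random.default_rng(11)
        non_stop = [c for c, aa in mito_code.table.items() if aa != "*"]
        cds = "ATG" + "".join(rng.choice(non_stop, size=8)) + "TAA"
        plus = ReferenceGenome(cds, [RegionAnnotation("g", "protein_coding", 1, len(cds), "+")])
        minus = ReferenceGenome(
            revcomp(cds), [RegionAnnotation("g", "protein_coding", 1, len(cds), "-")]
        )
        comp = dict(zip("ACGT", "TGCA"))
        L = len(cds)
        for i in range(L):
            for alt in "ACGT":
                if alt == cds[i]:
                    continue
                fwd = annotate_substitution(plus, i + 1, cds[i], alt)
                rev = annotate_substitution(minus, L - i, comp[cds[i]], comp[alt])
                assert fwd == rev


class TestSiteCounting:
    def test_single_codon_TTT(self, mito_code):
        """TTT (Phe): only TTC is synonymous among the 9 single changes."""
        genome = ReferenceGenome(
            "TTT", [RegionAnnotation("g", "protein_coding", 1, 3, "+")]
        )
        nonsyn, syn = count_syn_nonsyn_sites(genome, genome.regions[0])
        assert nonsyn == pytest.approx(8 / 3)
        assert syn == pytest.approx(1 / 3)

    def test_identical_codons_are_additive(self):
        g1 = ReferenceGenome("TTT", [RegionAnnotation("g", "protein_coding", 1, 3, "+")])
        g5 = ReferenceGenome("TTT" * 5, [RegionAnnotation("g", "protein_coding", 1, 15, "+")])
        n1, s1 = count_syn_nonsyn_sites(g1, g1.regions[0])
        n5, s5 = count_syn_nonsyn_sites(g5, g5.regions[0])
        assert n5 == pytest.approx(5 * n1)
        assert s5 == pytest.approx(5 * s1)

    def test_conservation_and_brute_force_agreement(self, mito_code):
        rng = np.random.default_rng(3)
        non_stop = [c for c, aa in mito_code.table.items() if aa != "*"]
        for _ in range(20):
            k = int(rng.integers(1, 29))
            cds = "ATG" + "".join(rng.choice(non_stop, size=k))
            genome = ReferenceGenome(
                cds, [RegionAnnotation("g", "protein_coding", 1, len(cds), "+")]
            )
            nonsyn, syn = count_syn_nonsyn_sites(genome, genome.regions[0])
            bn, bs = brute_force_sites(cds, mito_code)
            assert nonsyn == pytest.approx(bn)
            assert syn == pytest.approx(bs)
            assert nonsyn + syn == pytest.approx(len(cds))


class TestFrameshift:
    def test_insertion_creates_inframe_stop(self):
        # ATG AAA TAA: inserting A after position 4 gives ATG AAA A|TA A..,
        # i.e. codon 2 becomes AAA -> AAT and codon 3 TAA; first stop moves.
        genome = ReferenceGenome(
            "ATGAAATAA", [RegionAnnotation("g", "protein_coding", 1, 9, "+")]
        )
        # hand translation: insert A after pos 3 -> ATG AAA ATA A ; no stop before end
        assert translate_with_frameshift(genome, genome.regions[0], 3, "insert_A") is None
        # delete the A at position 6 -> ATG AAT AA: no stop either
        assert translate_with_frameshift(genome, genome.regions[0], 5, "delete_A") is None

    def test_hand_translated_examples(self, mito_code):
        # gene ATG AAT AAA TAA; inserting an A after position 4 shifts to
        # ATG AAA TAA ATA A -> stop at codon 3
        genome = ReferenceGenome(
            "ATGAATAAATAA", [RegionAnnotation("g", "protein_coding", 1, 12, "+")]
        )
        assert translate_with_frameshift(genome, genome.regions[0], 4, "insert_A") == 3
        # deleting the A after position 3: ATG ATA AAT AA -> no stop codon
        assert translate_with_frameshift(genome, genome.regions[0], 3, "delete_A") is None

    def test_indel_oracle_on_random_genes(self, mito_code):
        """Insertion/deletion re-translation agrees with an independent
        string-surgery + translation oracle."""
        rng = np.random.default_rng(5)
        non_stop = [c for c, aa in mito_code.table.items() if aa != "*"]
        for _ in range(20):
            cds = "ATG" + "".join(rng.choice(non_stop, size=15)) + "TAA"
            genome = ReferenceGenome(
                cds, [RegionAnnotation("g", "protein_coding", 1, len(cds), "+")]
            )
            pos = int(rng.integers(1, len(cds) - 1))
            for op in ("insert_A", "delete_A"):
                mutated = (
                    cds[:pos] + "A" + cds[pos:] if op == "insert_A" else cds[:pos] + cds[pos + 1 :]
                )
                aa = mito_code.translate(mutated)
                expected = aa.index("*") + 1 if "*" in aa else None
                assert translate_with_frameshift(genome, genome.regions[0], pos, op) == expected


class TestLoadReference:
    def test_round_trip_through_files(self, tmp_path, reversion_genome):
        genome, sites = reversion_genome
        paths = write_genome_files(genome, sites, tmp_path)
        loaded, loaded_sites = load_reference(
            paths["fasta"], paths["bed"], paths["haplotype_tsv"]
        )
        assert loaded.sequence == genome.sequence
        assert [(r.name, r.start, r.end, r.strand) for r in loaded.regions] == [
            (r.name, r.start, r.end, r.strand) for r in genome.regions
        ]
        assert [(s.position, s.b6_allele) for s in loaded_sites] == [
            (s.position, s.b6_allele) for s in sites
        ]
        assert all(s.consequence in ("missense", "synonymous", "noncoding") for s in loaded_sites)

    def test_multi_record_fasta_rejected(self, tmp_path):
        fasta = tmp_path / "two.fa"
        fasta.write_text(">a\nACGT\n>b\nACGT\n")
        bed = tmp_path / "r.bed"
        bed.write_text("a\t0\t4\tx\t0\t+\tother\t0\n")
        with pytest.raises(ValueError, match="exactly one"):
            load_reference(fasta, bed)

    def test_region_beyond_genome_names_offender(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">g\n" + "ACGTACGTAC" * 3 + "\n")
        bed = tmp_path / "r.bed"
        bed.write_text("g\t0\t31\tbadregion\t0\t+\tother\t0\n")
        with pytest.raises(ValueError, match="badregion"):
            load_reference(fasta, bed)

    def test_non_acgt_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            ReferenceGenome("ACGTN", [])


class TestCircularity:
    def test_position_L_plus_1_wraps(self, toy_genome):
        assert toy_genome.base(toy_genome.L + 1) == toy_genome.base(1)

    def test_context_wraps_origin(self, toy_genome):
        ctx = toy_genome.context(1)
        assert ctx == toy_genome.base(toy_genome.L) + toy_genome.base(1) + toy_genome.base(2)
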