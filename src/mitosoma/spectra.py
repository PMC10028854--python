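"""Mutation-class and trinucleotide spectra.

Single-nucleotide variants are collapsed across strands into six classes
named by their purine-reference representative (``G>A/C>T`` covers both a
G>A and a C>T change); insertions and deletions complete the 8-class
spectrum.  Trinucleotide contexts are collapsed to the pyrimidine-centred
representative, so ``ACG`` stands for both ACG with a C>T and CGT with a
G>A on the other strand.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, complement, revcomp
from .stats import bh_adjust, fisher_exact
from .variants import ConditionTable

logger = logging.getLogger(__name__)

SNV_CLASSES = ("G>A/C>T", "G>T/C>A", "G>C/C>G", "T>C/A>G", "T>A/A>T", "T>G/A>C")
ALL_CLASSES = SNV_CLASSES + ("INS", "DEL")

#: reference-nucleotide pair whose summed depth is the denominator of each SNV class
CLASS_REF_PAIR = {c: ("G:C" if c.startswith("G") else "T:A") for c in SNV_CLASSES}


def classify_mutation(ref: str, alt: str, context: str | None = None):
    """Strand-collapsed class of a mutation, plus the collapsed context.

    Returns ``(class, collapsed_context)``; the context is ``None`` for
    indels and when no context is supplied.  Ambiguous (non-ACGT) alleles
    raise.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != len(alt):
        kind = "INS" if len(alt) > len(ref) else "DEL"
        return kind, None
    if len(ref) != 1:
        raise ValueError(f"unsupported multi-nucleotide substitution {ref}>{alt}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"ambiguous alleles {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "GT":
        cls = f"{ref}>{alt}/{complement(ref)}>{complement(alt)}"
    else:
        cls = f"{complement(ref)}>{complement(alt)}/{ref}>{alt}"
    ctx = None
    if context is not None:
        context = context.upper()
        if len(context) != 3 or any(b not in "ACGT" for b in context):
            raise ValueError(f"bad trinucleotide context {context!r}")
        if context[1] != ref:
            raise ValueError(f"context {context!r} is not centred on ref {ref!r}")
        ctx = context if context[1] in "CT" else revcomp(context)
    return cls, ctx


class MutationSpectrum:
    """Counts over the 8 mutation classes with their depth denominators."""

    def __init__(
        self,
        counts: pd.Series | dict,
        denominators: dict | None = None,
        trinucleotide: pd.Series | None = None,
    ):
        self.counts = pd.Series(counts, dtype=float).reindex(ALL_CLASSES, fill_value=0.0)
        self.denominators = dict(denominators or {})
        self.trinucleotide = trinucleotide

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def proportions(self) -> pd.Series:
        t = self.total
        return self.counts / t if t > 0 else self.counts * np.nan

    def frequencies(self) -> pd.Series:
        """Per-class frequency with reference-nucleotide-restricted denominators.

        SNV classes divide by the summed duplex depth over positions whose
        reference base belongs to the class's strand pair; insertions and
        deletions divide by the total duplex depth.
        """
        out = {}
        for cls in ALL_CLASSES:
            denom = self.denominators.get(CLASS_REF_PAIR.get(cls, "total"), np.nan)
            if not denom or np.isnan(denom):
                logger.warning("spectrum class %s: zero/missing denominator", cls)
                out[cls] = np.nan
            else:
                out[cls] = self.counts[cls] / denom
        return pd.Series(out)


def depth_denominators(table: ConditionTable, genome: ReferenceGenome) -> dict:
    refs = np.frombuffer(genome.sequence.encode(), dtype="S1").astype("U1")
    gc = np.isin(refs, ["G", "C"])
    return {
        "G:C": float(table.depth[gc].sum()),
        "T:A": float(table.depth[~gc].sum()),
        "total": float(table.depth.sum()),
    }


def class_frequency_spectrum(table: ConditionTable, genome: ReferenceGenome) -> MutationSpectrum:
    """Alt-depth-weighted 8-class spectrum of a (filtered) condition table."""
    counts = dict.fromkeys(ALL_CLASSES, 0.0)
    for row in table.variants.itertuples(index=False):
        cls, _ = classify_mutation(row.ref, row.alt)
        counts[cls] += float(row.alt_depth)
    return MutationSpectrum(counts, depth_denominators(table, genome))


def trinucleotide_spectrum(events: pd.DataFrame, genome: ReferenceGenome) -> pd.Series:
    """Mutation fractions per (class, collapsed trinucleotide context).

    ``events`` is the unique-event table from ``de_novo_filter``; each event
    counts once and fractions are relative to the total number of events, so
    they sum to 1 (indels occupy a context-less cell per class).  Contexts
    wrap the circular origin.
    """
    cells: dict[tuple[str, str], float] = {}
    n = len(events)
    for row in events.itertuples(index=False):
        if row.kind == "SNV":
            cls, ctx = classify_mutation(row.ref, row.alt, genome.context(int(row.position)))
        else:
            cls, ctx = classify_mutation(row.ref, row.alt)
            ctx = "."
        cells[(cls, ctx)] = cells.get((cls, ctx), 0.0) + 1.0
    s = pd.Series(cells, dtype=float).sort_index()
    s.index.names = ["mutation_class", "context"]
    return s / n if n else s


def age_class_test(young: MutationSpectrum, aged: MutationSpectrum) -> pd.DataFrame:
    """Per-class Fisher's exact test of count enrichment with age.

    For every class a 2x2 table ``[count, denominator - count]`` x
    ``[young, aged]`` is tested two-sided; the odds ratio is oriented so
    values above 1 mean enrichment in aged.  BH adjustment runs across the
    8 classes; classes with a missing denominator are skipped with a log
    entry.
    """
    rows = []
    for cls in ALL_CLASSES:
        pair = CLASS_REF_PAIR.get(cls, "total")
        dy, da = young.denominators.get(pair, 0), aged.denominators.get(pair, 0)
        ky, ka = round(young.counts[cls]), round(aged.counts[cls])
        if not dy or not da:
            logger.warning("age_class_test: class %s skipped (zero denominator)", cls)
            rows.append({"mutation_class": cls, "odds_ratio": np.nan, "p": np.nan})
            continue
        odds, p = fisher_exact([[ka, round(da) - ka], [ky, round(dy) - ky]])
        rows.append({"mutation_class": cls, "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(df["p"])
    return df


def null_consequence_spectrum(genome: ReferenceGenome) -> tuple[pd.Series, pd.Series]:
    """Class composition of all possible missense and synonymous changes.

    Enumerates the three possible substitutions at every coding position
    once (overlapping genes attributed to the first annotated region),
    classifies each by strand-collapsed class and consequence, and returns
    the two spectra normalised to sum to 1: ``(missense, synonymous)``.
    """
    from .genome import annotate_substitution

    missense = dict.fromkeys(SNV_CLASSES, 0.0)
    synonymous = dict.fromkeys(SNV_CLASSES, 0.0)
    seen: set[int] = set()
    for gene in genome.regions_of_class("protein_coding"):
        for p in genome.coding_positions(gene):
            p = int(p)
            if p in seen or genome.coding_region_at(p) is not gene:
                continue
            seen.add(p)
            ref = genome.base(p)
            for alt in "ACGT":
                if alt == ref:
                    continue
                cls, _ = classify_mutation(ref, alt)
                csq = annotate_substitution(genome, p, ref, alt)
                if csq == "missense":
                    missense[cls] += 1.0
                elif csq == "synonymous":
                    synonymous[cls] += 1.0
    mis = pd.Series(missense)
    syn = pd.Series(synonymous)
    return mis / mis.sum() if mis.sum() else mis, syn / syn.sum() if syn.sum() else syn


def spectrum_table(spectrum: MutationSpectrum) -> pd.DataFrame:
    """Flat TSV-ready layout: class, count, denominator, fraction, frequency."""
    freq = spectrum.frequencies()
    prop = spectrum.proportions()
    return pd.DataFrame(
        {
            "mutation_class": list(ALL_CLASSES),
            "count": spectrum.counts.to_numpy(),
            "denominator": [
                spectrum.denominators.get(CLASS_REF_PAIR.get(c, "total"), np.nan)
                for c in ALL_CLASSES
            ],
            "fraction": prop.to_numpy(),
            "frequency": freq.to_numpy(),
        }
    )
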