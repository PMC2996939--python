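"""Map genomic SNPs through gene models onto codons and proteins.

Each SNP allele is evaluated independently against the reference CDS of every
gene model it falls in (multiple SNPs in one codon are never combined).  The
classification follows the codon translations: synonymous, nonsynonymous,
stop_gained or stop_lost.  Positions are 1-based; minus-strand genes count
CDS coordinates from the rightmost exon base and alt alleles are
reverse-complemented before codon substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_effects import codon_change_effect, translate_codon
from .core_io import GeneModel, SnpRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

EFFECT_CLASSES = ("synonymous", "nonsynonymous", "stop_gained", "stop_lost")


class RefMismatchError(ValueError):
    """SNP ref allele disagrees with the reference genome."""


class ModelError(ValueError):
    """Gene model inconsistent with the genome (e.g. CDS length)."""


@dataclass(frozen=True)
class ProteinEffect:
    """The protein-level consequence of one SNP allele in one gene model."""

    protein_id: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    effect_class: str
    accessions: frozenset[str]
    snp: SnpRecord

    def __post_init__(self) -> None:
        object.__setattr__(self, "accessions", frozenset(self.accessions))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def genomic_to_cds(model: GeneModel, gpos: int) -> int | None:
    """Strand-aware spliced CDS coordinate of a genomic position.

    Returns ``None`` when the position falls in an intron or outside the
    gene (a "non-coding" signal, not an exception; callers filter).
    """
    offset = 0
    for start, end in model.exons:
        if start <= gpos <= end:
            plus_pos = offset + (gpos - start) + 1
            if model.strand == "+":
                return plus_pos
            return model.cds_length - plus_pos + 1
        offset += end - start + 1
    return None


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds` (1-based CDS position -> genomic)."""
    if not (1 <= cds_pos <= model.cds_length):
        raise ValueError(f"CDS position {cds_pos} outside gene {model.gene_id}")
    plus_pos = cds_pos if model.strand == "+" else model.cds_length - cds_pos + 1
    offset = 0
    for start, end in model.exons:
        length = end - start + 1
        if plus_pos <= offset + length:
            return start + (plus_pos - offset) - 1
        offset += length
    raise AssertionError("unreachable")


def spliced_cds(model: GeneModel, genome: dict[str, str]) -> str:
    """Spliced, strand-oriented CDS sequence of a gene model."""
    chrom_seq = genome[model.chrom]
    if model.exons[-1][1] > len(chrom_seq):
        raise ModelError(f"gene {model.gene_id}: exon beyond chromosome end")
    seq = "".join(chrom_seq[start - 1 : end] for start, end in model.exons)
    return revcomp(seq) if model.strand == "-" else seq


def snp_protein_effect(
    model: GeneModel, cds_sequence: str, snp: SnpRecord
) -> ProteinEffect | None:
    """Protein-level effect of one SNP in one gene model, or None if non-coding."""
    if len(cds_sequence) != model.cds_length or model.cds_length % 3 != 0:
        raise ModelError(
            f"gene {model.gene_id}: CDS sequence length {len(cds_sequence)} "
            f"inconsistent with model"
        )
    if snp.chrom != model.chrom:
        return None
    cds_pos = genomic_to_cds(model, snp.pos)
    if cds_pos is None:
        return None
    ref_base = snp.ref if model.strand == "+" else snp.ref.translate(_COMPLEMENT)
    alt_base = snp.alt if model.strand == "+" else snp.alt.translate(_COMPLEMENT)
    if cds_sequence[cds_pos - 1] != ref_base:
        raise RefMismatchError(
            f"SNP {snp.chrom}:{snp.pos} {snp.ref}>{snp.alt}: reference allele "
            f"does not match CDS of {model.gene_id} at CDS position {cds_pos}"
        )
    codon_index = (cds_pos - 1) // 3  # 0-based
    within = (cds_pos - 1) % 3
    ref_codon = cds_sequence[codon_index * 3 : codon_index * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    return ProteinEffect(
        protein_id=model.gene_id,
        protein_pos=codon_index + 1,
        ref_aa=translate_codon(ref_codon),
        alt_aa=translate_codon(alt_codon),
        effect_class=codon_change_effect(ref_codon, alt_codon),
        accessions=snp.accessions,
        snp=snp,
    )


def map_snps(
    genome: dict[str, str],
    models: dict[str, GeneModel],
    snps: list[SnpRecord],
) -> list[ProteinEffect]:
    """Map every SNP onto every overlapping gene model.

    A SNP falling in two models (e.g. genes overlapping on both strands) is
    evaluated separately in each.
    """
    by_chrom: dict[str, list[tuple[int, int, GeneModel, str]]] = {}
    for model in models.values():
        cds = spliced_cds(model, genome)
        span = (model.exons[0][0], model.exons[-1][1])
        by_chrom.setdefault(model.chrom, []).append((span[0], span[1], model, cds))
    effects = []
    for snp in snps:
        for start, end, model, cds in by_chrom.get(snp.chrom, []):
            if start <= snp.pos <= end:
                eff = snp_protein_effect(model, cds, snp)
                if eff is not None:
                    effects.append(eff)
    return effects


# ---------------------------------------------------------------------------
# Proteome-wide summaries
# ---------------------------------------------------------------------------


@dataclass
class EffectSummary:
    """Proteome-wide counts of SNP consequences with printed percentages.

    ``affected_aa`` counts distinct amino-acid positions (stop codons
    excluded) hit by at least one SNP allele; ``syn_count``/``nonsyn_count``
    count distinct positions with at least one effect of that class, so a
    position hit both ways contributes to both.  Percentages use the
    amino-acid-only denominator and round half-to-even to two decimals.
    """

    total_aa: int
    affected_aa: int
    affected_stop: int
    syn_count: int
    nonsyn_count: int
    per_aa_nonsyn: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_aa <= 0:
            raise ValueError("empty proteome")

    def _pct(self, count: int) -> float:
        return round(100.0 * count / self.total_aa, 2)

    @property
    def pct_affected(self) -> float:
        return self._pct(self.affected_aa)

    @property
    def pct_affected_incl_stop(self) -> float:
        return self._pct(self.affected_aa + self.affected_stop)

    @property
    def pct_synonymous(self) -> float:
        return self._pct(self.syn_count)

    @property
    def pct_nonsynonymous(self) -> float:
        return self._pct(self.nonsyn_count)


def summarize_effects(
    effects: list[ProteinEffect], proteome: dict[str, str]
) -> EffectSummary:
    """Aggregate per-position effect counts over a proteome."""
    if not proteome:
        raise ValueError("empty proteome")
    total_aa = sum(len(seq.rstrip("*")) for seq in proteome.values())
    aa_positions: set[tuple[str, int]] = set()
    stop_positions: set[tuple[str, int]] = set()
    syn_positions: set[tuple[str, int]] = set()
    nonsyn_positions: set[tuple[str, int]] = set()
    per_aa_nonsyn_pairs: set[tuple[str, int, str]] = set()
    for eff in effects:
        key = (eff.protein_id, eff.protein_pos)
        if eff.ref_aa == "*":
            stop_positions.add(key)
        else:
            aa_positions.add(key)
            if eff.effect_class == "synonymous":
                syn_positions.add(key)
            elif eff.effect_class in ("nonsynonymous", "stop_gained"):
                nonsyn_positions.add(key)
                per_aa_nonsyn_pairs.add((eff.protein_id, eff.protein_pos, eff.alt_aa))
    per_aa: dict[str, int] = {}
    for protein_id, pos, _alt in per_aa_nonsyn_pairs:
        ref_aa = proteome[protein_id][pos - 1]
        per_aa[ref_aa] = per_aa.get(ref_aa, 0) + 1
    return EffectSummary(
        total_aa=total_aa,
        affected_aa=len(aa_positions),
        affected_stop=len(stop_positions),
        syn_count=len(syn_positions),
        nonsyn_count=len(nonsyn_positions),
        per_aa_nonsyn=per_aa,
    )


def aa_abundance_odds(
    effects: list[ProteinEffect], proteome: dict[str, str], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-amino-acid log2 odds of being nonsynonymously substituted.

    For each amino acid ``a`` the 2x2 table contrasts the number of
    nonsynonymous substitutions originating from ``a`` against the abundance
    of ``a`` in the proteome.  Positive log2 odds ratios mean the residue is
    substituted more often than its abundance predicts.  A Haldane-Anscombe
    0.5 correction is applied (and flagged) when any cell is zero.  P-values
    come from Fisher's exact test, BH-adjusted across the 20 residues.
    """
    from .site_statistics import bh_adjust, fisher_exact

    nonsyn = [
        e
        for e in effects
        if e.effect_class in ("nonsynonymous", "stop_gained") and e.ref_aa != "*"
    ]
    if not nonsyn:
        raise ValueError("no nonsynonymous effects")
    pairs = {(e.protein_id, e.protein_pos, e.alt_aa) for e in nonsyn}
    subs_from: dict[str, int] = {}
    for protein_id, pos, _alt in pairs:
        aa = proteome[protein_id][pos - 1]
        subs_from[aa] = subs_from.get(aa, 0) + 1
    counts: dict[str, int] = {}
    for seq in proteome.values():
        for aa in seq.rstrip("*"):
            counts[aa] = counts.get(aa, 0) + 1
    total_aa = sum(counts.values())
    total_subs = sum(subs_from.values())
    rows = []
    for aa in sorted(counts):
        k = subs_from.get(aa, 0)
        table = [[k, total_subs - k], [counts[aa], total_aa - counts[aa]]]
        p, _ = fisher_exact(table)
        a, b = float(table[0][0]), float(table[0][1])
        c, d = float(table[1][0]), float(table[1][1])
        corrected = 0 in (a, b, c, d)
        if corrected:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log2_or = float(np.log2((a * d) / (b * c)))
        rows.append(
            {
                "aa": aa,
                "n_nonsyn": k,
                "n_in_proteome": counts[aa],
                "log2_odds_ratio": log2_or,
                "p_value": p,
                "zero_cell_corrected": corrected,
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = bh_adjust(df["p_value"].to_list())
    df["significant"] = df["q_value"] <= alpha
    return df


def snp_summary(
    snps: list[SnpRecord], effects: list[ProteinEffect]
) -> dict[str, int]:
    """Non-redundant SNP bookkeeping in the style of per-dataset overviews.

    Identity of a non-redundant SNP is (chrom, pos, alt).  A SNP "causes at
    least one non-synonymous substitution" if any overlapping gene model
    classifies it as nonsynonymous / stop_gained / stop_lost.
    """
    all_keys = {s.key for s in snps}
    coding: dict[tuple, set[str]] = {}
    for eff in effects:
        coding.setdefault(eff.snp.key, set()).add(eff.effect_class)
    nonsyn_keys = {
        k
        for k, classes in coding.items()
        if classes & {"nonsynonymous", "stop_gained", "stop_lost"}
    }
    return {
        "n_nonredundant": len(all_keys),
        "n_coding": len(coding),
        "n_nonsyn_any": len(nonsyn_keys),
        "n_always_synonymous": len(coding) - len(nonsyn_keys),
    }


def effects_to_frame(effects: list[ProteinEffect]) -> pd.DataFrame:
    """Effects as a TSV-ready table mirroring the record fields."""
    rows = [
        {
            "protein_id": e.protein_id,
            "protein_pos": e.protein_pos,
            "ref_aa": e.ref_aa,
            "alt_aa": e.alt_aa,
            "effect_class": e.effect_class,
            "chrom": e.snp.chrom,
            "genomic_pos": e.snp.pos,
            "ref_base": e.snp.ref,
            "alt_base": e.snp.alt,
            "accessions": ",".join(sorted(e.accessions)),
        }
        for e in effects
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "protein_pos",
            "ref_aa",
            "alt_aa",
            "effect_class",
            "chrom",
            "genomic_pos",
            "ref_base",
            "alt_base",
            "accessions",
        ],
    )


def frame_to_effects(df: pd.DataFrame) -> list[ProteinEffect]:
    """Rebuild ProteinEffect records from :func:`effects_to_frame` output."""
    out = []
    for _, row in df.iterrows():
        accs = frozenset(str(row["accessions"]).split(","))
        snp = SnpRecord(
            str(row["chrom"]),
            int(row["genomic_pos"]),
            row["ref_base"],
            row["alt_base"],
            accs,
        )
        out.append(
            ProteinEffect(
                protein_id=row["protein_id"],
                protein_pos=int(row["protein_pos"]),
                ref_aa=row["ref_aa"],
                alt_aa=row["alt_aa"],
                effect_class=row["effect_class"],
                accessions=accs,
                snp=snp,
            )
        )
    return out
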