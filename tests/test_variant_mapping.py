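"""SNP-to-protein mapping: coordinate arithmetic, strand handling, effect
classification, and proteome-wide summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosnp.core_io import GeneModel, SnpRecord
from phosnp.variant_mapping import (
    EffectSummary,
    RefMismatchError,
    aa_abundance_odds,
    cds_to_genomic,
    genomic_to_cds,
    map_snps,
    snp_protein_effect,
    snp_summary,
    spliced_cds,
    summarize_effects,
)


def _snp(chrom, pos, ref, alt, accs=("a1",)):
    return SnpRecord(chrom, pos, ref, alt, frozenset(accs))


class TestCoordinates:
    def test_plus_strand_two_exons(self):
        model = GeneModel("g", "c", "+", ((101, 150), (201, 249)))
        assert genomic_to_cds(model, 220) == 70
        assert genomic_to_cds(model, 101) == 1
        assert genomic_to_cds(model, 150) == 50

    def test_minus_strand_counts_from_rightmost_base(self):
        model = GeneModel("g", "c", "-", ((101, 148),))
        assert genomic_to_cds(model, 148) == 1
        assert genomic_to_cds(model, 101) == 48

    def test_intron_and_flanks_are_non_coding(self):
        model = GeneModel("g", "c", "+", ((101, 150), (201, 249)))
        assert genomic_to_cds(model, 151) is None
        assert genomic_to_cds(model, 100) is None
        assert genomic_to_cds(model, 250) is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_bijection_roundtrip(self, data):
        strand = data.draw(st.sampled_from("+-"))
        e1 = data.draw(st.integers(1, 50))
        l1 = data.draw(st.integers(1, 30))
        gap = data.draw(st.integers(1, 20))
        l2 = data.draw(st.integers(1, 30))
        total = l1 + l2 + data.draw(st.integers(0, 2)) * 0
        # pad exon 2 so total CDS length is divisible by 3
        pad = (3 - (l1 + l2) % 3) % 3
        exons = ((e1, e1 + l1 - 1), (e1 + l1 + gap, e1 + l1 + gap + l2 + pad - 1))
        model = GeneModel("g", "c", strand, exons)
        seen = set()
        for cds_pos in range(1, model.cds_length + 1):
            gpos = cds_to_genomic(model, cds_pos)
            assert genomic_to_cds(model, gpos) == cds_pos
            seen.add(gpos)
        assert len(seen) == model.cds_length


class TestSnpEffect:
    def test_nonsynonymous_s_to_t(self):
        # CDS ATG TCT GGA on '+' strand at 1..9
        genome = {"c": "ATGTCTGGA"}
        model = GeneModel("g", "c", "+", ((1, 9),))
        cds = spliced_cds(model, genome)
        eff = snp_protein_effect(model, cds, _snp("c", 4, "T", "A"))
        assert (eff.protein_pos, eff.ref_aa, eff.alt_aa) == (2, "S", "T")
        assert eff.effect_class == "nonsynonymous"

    def test_synonymous_third_position(self):
        genome = {"c": "ATGTCTGGA"}
        model = GeneModel("g", "c", "+", ((1, 9),))
        cds = spliced_cds(model, genome)
        eff = snp_protein_effect(model, cds, _snp("c", 6, "T", "C"))
        assert eff.effect_class == "synonymous"
        assert eff.ref_aa == eff.alt_aa == "S"

    def test_minus_strand_alt_is_reverse_complemented(self, toy_minus_gene):
        genome, model, protein = toy_minus_gene
        cds = spliced_cds(model, genome)
        assert cds == "ATGTCTAGAGGATAA"
        # genomic alt A at the genomic base complementing CDS position 4
        gpos = cds_to_genomic(model, 4)
        ref_g = genome["chrB"][gpos - 1]
        eff = snp_protein_effect(model, cds, _snp("chrB", gpos, ref_g, "T"))
        # CDS base 4 is T (codon TCT, S); genomic T -> CDS A gives ACT (T)
        assert (eff.ref_aa, eff.alt_aa) == ("S", "T")
        assert eff.effect_class == "nonsynonymous"

    def test_stop_codon_effects(self):
        genome = {"c": "ATGTACTAA"}  # M Y *
        model = GeneModel("g", "c", "+", ((1, 9),))
        cds = spliced_cds(model, genome)
        gained = snp_protein_effect(model, cds, _snp("c", 6, "C", "A"))
        assert gained.effect_class == "stop_gained"
        lost = snp_protein_effect(model, cds, _snp("c", 7, "T", "C"))
        assert lost.effect_class == "stop_lost"
        assert lost.ref_aa == "*"

    def test_ref_mismatch_raises_with_record_context(self):
        genome = {"c": "ATGTCTGGA"}
        model = GeneModel("g", "c", "+", ((1, 9),))
        cds = spliced_cds(model, genome)
        with pytest.raises(RefMismatchError, match="c:4"):
            snp_protein_effect(model, cds, _snp("c", 4, "G", "A"))

    def test_intronic_snp_returns_none(self, toy_plus_gene):
        genome, model, _ = toy_plus_gene
        cds = spliced_cds(model, genome)
        assert snp_protein_effect(model, cds, _snp("chrA", 50, "G", "A")) is None


class TestSummaries:
    def test_printed_count_percentages(self):
        summary = EffectSummary(
            total_aa=12_285_899,
            affected_aa=314_705,
            affected_stop=594,
            syn_count=160_634,
            nonsyn_count=155_311,
        )
        assert summary.pct_affected == 2.56
        assert summary.pct_synonymous == 1.31
        assert summary.pct_nonsynonymous == 1.26

    def test_no_snps_gives_zero_percentages(self):
        summary = summarize_effects([], {"p": "MSTY"})
        assert summary.pct_affected == 0.0
        assert summary.pct_synonymous == 0.0

    def test_positions_counted_once_across_accessions(self, toy_plus_gene):
        genome, model, protein = toy_plus_gene
        cds = spliced_cds(model, genome)
        snps = [
            _snp("chrA", 4, "T", "A", ("a1", "a2")),
            _snp("chrA", 4, "T", "G", ("a3",)),  # same position, other allele
        ]
        effects = map_snps(genome, {"g_plus": model}, snps)
        summary = summarize_effects(effects, {"g_plus": protein})
        assert summary.affected_aa == 1
        assert summary.nonsyn_count == 1

    def test_snp_summary_classification(self, toy_plus_gene):
        genome, model, _ = toy_plus_gene
        snps = [
            _snp("chrA", 4, "T", "A"),  # nonsynonymous
            _snp("chrA", 6, "T", "C"),  # synonymous
            _snp("chrA", 50, "G", "A"),  # intronic
        ]
        effects = map_snps(genome, {"g_plus": model}, snps)
        counts = snp_summary(snps, effects)
        assert counts == {
            "n_nonredundant": 3,
            "n_coding": 2,
            "n_nonsyn_any": 1,
            "n_always_synonymous": 1,
        }


class TestAbundanceOdds:
    def _uniform_effects(self, proteome, n=400, seed=5):
        """Substitutions drawn uniformly over residues (abundance-matched)."""
        rng = np.random.default_rng(seed)
        from phosnp.variant_mapping import ProteinEffect

        positions = [
            (pid, pos + 1)
            for pid, seq in proteome.items()
            for pos in range(len(seq))
        ]
        effects = []
        for idx in rng.choice(len(positions), size=n, replace=False):
            pid, pos = positions[int(idx)]
            ref = proteome[pid][pos - 1]
            alt = "W" if ref != "W" else "L"
            effects.append(
                ProteinEffect(pid, pos, ref, alt, "nonsynonymous",
                              frozenset({"a1"}),
                              SnpRecord("c", pos, "A", "G", frozenset({"a1"})))
            )
        return effects

    def test_uniform_substitutions_show_no_enrichment(self, sim_small):
        proteome = sim_small.proteome
        effects = self._uniform_effects(proteome)
        df = aa_abundance_odds(effects, proteome)
        assert not df["significant"].any()
        assert df["log2_odds_ratio"].abs().mean() < 0.8

    def test_serine_only_substitutions_positive_log_odds(self):
        from phosnp.variant_mapping import ProteinEffect

        proteome = {"p": "MSMSMSMSASDFKLHH" * 4}
        effects = []
        for pos, aa in enumerate(proteome["p"], start=1):
            if aa == "S":
                effects.append(
                    ProteinEffect("p", pos, "S", "N", "nonsynonymous",
                                  frozenset({"a1"}),
                                  SnpRecord("c", pos, "A", "G",
                                            frozenset({"a1"})))
                )
        df = aa_abundance_odds(effects, proteome).set_index("aa")
        assert df.loc["S", "log2_odds_ratio"] > 0
        assert (df.drop(index="S")["log2_odds_ratio"] < 0).all()

    def test_zero_cell_is_corrected_and_flagged(self):
        from phosnp.variant_mapping import ProteinEffect

        proteome = {"p": "MMMMSSSS"}
        effects = [
            ProteinEffect("p", 5, "S", "N", "nonsynonymous", frozenset({"a"}),
                          SnpRecord("c", 5, "A", "G", frozenset({"a"})))
        ]
        df = aa_abundance_odds(effects, proteome).set_index("aa")
        assert df["zero_cell_corrected"].any()
        assert np.isfinite(df["log2_odds_ratio"]).all()
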