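"""Gene-effect annotation: coding effects, splice sites, SV truncation, tallies."""

import pytest

from radmut.filtering import CandidateVariant
from radmut.impact import (
    EffectCall,
    GeneModel,
    annotate_sv_call,
    annotate_variant,
    genes_affected_per_line,
)
from radmut.spectra import SVCall, SVEvent

# hand-built gene on "c": 4 bp 5'UTR, CDS ATGTGGAAA | intron GTCCCCAG |
# CDS GAATAA, 4 bp 3'UTR  ->  protein M W K E *
SEQ = "AAAA" + "ATGTGGAAA" + "GTCCCCAG" + "GAATAA" + "TTTT" + "G" * 69
GENE = GeneModel(
    gene_id="g1", chromosome="c", strand="+", tx_start=1, tx_end=31,
    exons=((1, 13), (22, 31)), cds=((5, 13), (22, 27)),
)
REF = {"c": SEQ}


def var(pos, ref, alt, line="L1"):
    return CandidateVariant(line, "c", pos, ref, alt, 30, 30)


def effects(v):
    return [(c.effect, c.impact_level) for c in annotate_variant(v, [GENE], REF)]


class TestSmallVariantAnnotation:
    def test_stop_gained_is_nonsense_high(self):
        # TGG codon at 8-10; G>A at 10 makes TGA
        assert effects(var(10, "G", "A")) == [("nonsense", "high")]

    def test_missense_moderate(self):
        # TGG -> CGG (W -> R)
        assert effects(var(8, "T", "C")) == [("missense", "moderate")]

    def test_synonymous_low(self):
        # AAA -> AAG, both lysine
        assert effects(var(13, "A", "G")) == [("synonymous", "low_or_other")]

    def test_splice_donor_loss_high(self):
        assert effects(var(14, "G", "A")) == [("splice_site_loss", "high")]
        assert effects(var(21, "G", "C")) == [("splice_site_loss", "high")]

    def test_frameshift_vs_inframe(self):
        # 1 bp deletion in CDS
        assert effects(var(7, "GT", "G")) == [("frameshift", "high")]
        # 3 bp deletion in CDS: moderate inframe
        assert effects(var(5, "ATGT", "A")) == [("inframe_indel", "moderate")]

    def test_utr_intron_intergenic(self):
        assert effects(var(2, "A", "C")) == [("utr", "low_or_other")]
        assert effects(var(18, "C", "T")) == [("intron", "low_or_other")]
        assert effects(var(60, "G", "T")) == [("intergenic", "none")]

    def test_off_chromosome_is_an_error(self):
        with pytest.raises(ValueError):
            annotate_variant(
                CandidateVariant("L1", "nope", 5, "A", "G", 30, 30), [GENE], REF
            )

    def test_minus_strand_symmetry(self, toy_reference):
        """Effect classes are unchanged under reverse-complementing everything."""
        from Bio.Seq import Seq

        minus = [g for g in toy_reference.genes if g.strand == "-"][0]
        seq = toy_reference.sequences[minus.chromosome]
        L = len(seq)
        # mirror genome and gene model
        flip_seq = str(Seq(seq).reverse_complement())
        flip = GeneModel(
            gene_id=minus.gene_id, chromosome=minus.chromosome, strand="+",
            tx_start=L + 1 - minus.tx_end, tx_end=L + 1 - minus.tx_start,
            exons=tuple(sorted((L + 1 - e, L + 1 - s) for s, e in minus.exons)),
            cds=tuple(sorted((L + 1 - e, L + 1 - s) for s, e in minus.cds)),
        )
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}

        def sv(pos, ref, alt):
            return CandidateVariant("L1", minus.chromosome, pos, ref, alt, 30, 30)

        for pos in range(minus.cds[0][0], minus.cds[0][0] + 30):
            ref_base = seq[pos - 1]
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                e1 = annotate_variant(
                    sv(pos, ref_base, alt), [minus],
                    {minus.chromosome: seq},
                )[0].effect
                e2 = annotate_variant(
                    sv(L + 1 - pos, comp[ref_base], comp[alt]), [flip],
                    {minus.chromosome: flip_seq},
                )[0].effect
                assert e1 == e2


class TestSvAnnotation:
    def _genes(self, n, start=1000, spacing=500, length=300):
        return [
            GeneModel(
                gene_id=f"g{i}", chromosome="c", strand="+",
                tx_start=start + i * (length + spacing),
                tx_end=start + i * (length + spacing) + length - 1,
                exons=((start + i * (length + spacing),
                        start + i * (length + spacing) + length - 1),),
                cds=((start + i * (length + spacing) + 10,
                      start + i * (length + spacing) + 10 + 89),),
            )
            for i in range(n)
        ]

    def test_large_deletion_truncates_every_overlapped_gene(self):
        genes = self._genes(21)
        span = (genes[0].tx_start - 50, genes[-1].tx_end + 50)
        call = SVCall("L1", (SVEvent("large_deletion", (("c", span[0]), ("c", span[1]))),),
                      "large_deletion")
        calls = annotate_sv_call(call, genes)
        assert len(calls) == 21
        assert all(c.effect == "gene_truncation" and c.impact_level == "high"
                   for c in calls)

    def test_internal_duplication_affects_but_does_not_truncate(self):
        genes = self._genes(3)
        span = (genes[0].tx_start - 50, genes[-1].tx_end + 50)
        call = SVCall("L1", (SVEvent("duplication", (("c", span[0]), ("c", span[1]))),),
                      "duplication")
        calls = annotate_sv_call(call, genes)
        assert {c.effect for c in calls} == {"whole_gene_duplication"}
        assert {c.impact_level for c in calls} == {"low_or_other"}

    def test_duplication_breakpoint_inside_gene_truncates(self):
        genes = self._genes(1)
        inside = genes[0].tx_start + 10
        call = SVCall("L1", (SVEvent("duplication", (("c", inside), ("c", inside + 5000))),),
                      "duplication")
        [c] = annotate_sv_call(call, genes)
        assert c.effect == "gene_truncation"

    def test_intergenic_sv(self):
        call = SVCall("L1", (SVEvent("inversion", (("c", 10), ("c", 50))),), "inversion")
        [c] = annotate_sv_call(call, self._genes(1))
        assert c.effect == "intergenic" and c.impact_level == "none"


class TestGenesAffectedPerLine:
    def mk(self, gene, effect, line="L1", origin="small"):
        from radmut.impact import IMPACT_BY_EFFECT

        return EffectCall(gene, effect, IMPACT_BY_EFFECT[effect], line, origin)

    def test_empty_input_gives_empty_table(self):
        assert genes_affected_per_line([]).empty

    def test_dedup_within_gene(self):
        calls = [self.mk("g1", "missense"), self.mk("g1", "synonymous")]
        table = genes_affected_per_line(calls)
        assert table.loc["L1", "affected_total"] == 1
        assert table.loc["L1", "moderate_total"] == 1  # most severe wins

    def test_mixed_line_tally(self):
        calls = [
            self.mk("g1", "nonsense"),
            self.mk("g2", "missense"),
            self.mk(None, "intergenic"),
            self.mk("g3", "gene_truncation", origin="sv"),
        ]
        table = genes_affected_per_line(calls)
        row = table.loc["L1"]
        assert row["affected_total"] == 3
        assert row["high_total"] == 2 and row["moderate_total"] == 1
        assert row["affected_small"] == 2 and row["affected_sv"] == 1
        assert row["high_small"] == 1 and row["high_sv"] == 1

    def test_high_plus_moderate_bounded_by_total(self, toy_reference):
        import numpy as np

        from radmut.filtering import apply_candidate_filters
        from radmut.synthetic import gamma_spectrum, simulate_group

        sim = simulate_group(gamma_spectrum(), toy_reference, n_lines=3,
                             seed=np.random.default_rng(30))
        calls = []
        for fv in apply_candidate_filters(sim.records):
            if fv.disposition == "pass":
                calls.extend(
                    annotate_variant(fv.variant, toy_reference.genes,
                                     toy_reference.sequences)
                )
        table = genes_affected_per_line(calls)
        assert ((table["high_total"] + table["moderate_total"])
                <= table["affected_total"]).all()
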