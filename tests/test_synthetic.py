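"""Synthetic-study generator: determinism, Mendelian transmission, read evidence."""

import math

import numpy as np
import pytest

from radmut.rates import SelfingModel, genotype_distribution
from radmut.synthetic import (
    BulkSamplingSpec,
    RadiationSpectrum,
    SyntheticGenomeSpec,
    TruthMutation,
    carbon_ion_spectrum,
    gamma_spectrum,
    generate_reference,
    induce_mutations,
    simulate_bulk_reads,
    transmit_selfing,
)


def small_spec(**kw):
    defaults = dict(n_chromosomes=2, chromosome_length=60_000, n_genes=6,
                    gene_length=1_500, seed=1)
    defaults.update(kw)
    return SyntheticGenomeSpec(**defaults)


class TestGenerateReference:
    def test_deterministic_for_fixed_seed(self):
        a, b = generate_reference(small_spec()), generate_reference(small_spec())
        assert a.sequences == b.sequences
        assert a.genes == b.genes

    def test_zero_genes_gives_empty_gene_set(self):
        ref = generate_reference(small_spec(n_genes=0))
        assert ref.genes == ()
        assert len(ref.sequences) == 2

    def test_sizing_error_when_genes_do_not_fit(self):
        with pytest.raises(ValueError, match="cannot pack"):
            generate_reference(
                SyntheticGenomeSpec(n_chromosomes=1, chromosome_length=10_000,
                                    n_genes=50, gene_length=1_000, seed=0)
            )

    def test_gene_models_are_wellformed(self, toy_reference):
        from Bio.Seq import Seq

        strands = set()
        prev_end = {}
        for g in toy_reference.genes:
            strands.add(g.strand)
            assert len(g.cds) >= 2  # at least two CDS exons
            # non-overlapping along each chromosome
            assert g.tx_start > prev_end.get(g.chromosome, 0)
            prev_end[g.chromosome] = g.tx_end
            # canonical GT..AG splice dinucleotides
            seq = toy_reference.sequences[g.chromosome]
            for s, e in g.introns:
                donor, acceptor = seq[s - 1 : s + 1], seq[e - 2 : e]
                if g.strand == "-":
                    donor, acceptor = (
                        str(Seq(acceptor).reverse_complement()),
                        str(Seq(donor).reverse_complement()),
                    )
                assert donor == "GT" and acceptor == "AG"
            # ORF: starts ATG, single stop at the end
            aa = str(Seq(g.cds_sequence(toy_reference.sequences)).translate())
            assert g.cds_sequence(toy_reference.sequences).startswith("ATG")
            assert aa.endswith("*") and "*" not in aa[:-1]
        assert strands == {"+", "-"}  # both strands represented

    def test_gc_fraction_honoured(self):
        ref = generate_reference(small_spec(n_genes=0, gc_fraction=0.44, seed=3))
        seq = "".join(ref.sequences.values())
        gc = sum(b in "GC" for b in seq) / len(seq)
        assert gc == pytest.approx(0.44, abs=0.01)


class TestInduceMutations:
    def test_poisson_mean_recovery(self, toy_reference):
        lines = induce_mutations(toy_reference, gamma_spectrum(), 200, seed=2)
        counts = [sum(m.mutation_class == "SBS" for m in muts) for muts in lines]
        se = math.sqrt(57.0 / 200)
        assert abs(np.mean(counts) - 57.0) < 3 * se

    def test_all_zero_means_give_no_mutations(self, toy_reference):
        spectrum = RadiationSpectrum(
            label="null", dose=1.0, mean_sbs=0, mean_del=0, mean_ins=0, mean_sv=0,
            sbs_category_probs=gamma_spectrum().sbs_category_probs,
            indel_size_probs={1: 1.0}, sv_type_probs={"inversion": 1.0},
        )
        lines = induce_mutations(toy_reference, spectrum, 20, seed=3)
        assert all(not muts for muts in lines)

    def test_complex_only_spectrum_forces_multi_event_svs(self, toy_reference):
        spectrum = RadiationSpectrum(
            label="cx", dose=1.0, mean_sbs=0, mean_del=0, mean_ins=0, mean_sv=3.0,
            sbs_category_probs=gamma_spectrum().sbs_category_probs,
            indel_size_probs={1: 1.0}, sv_type_probs={"complex": 1.0},
            complex_event_range=(2, 3),
        )
        lines = induce_mutations(toy_reference, spectrum, 10, seed=4)
        svs = [m for muts in lines for m in muts]
        assert svs
        assert all(len(m.sv_events) >= 2 for m in svs)

    def test_sbs_alleles_respect_reference_base(self, toy_reference):
        lines = induce_mutations(toy_reference, carbon_ion_spectrum(), 5, seed=6)
        for muts in lines:
            for m in muts:
                if m.mutation_class == "SBS":
                    seq = toy_reference.sequences[m.chromosome]
                    assert seq[m.position - 1] == m.ref_allele != m.alt_allele

    def test_all_heterozygous_at_induction(self, toy_reference):
        lines = induce_mutations(toy_reference, gamma_spectrum(), 3, seed=7)
        for muts in lines:
            for m in muts:
                assert m.genotype_by_generation == {1: "heterozygous"}


class TestTransmitSelfing:
    def _many_het(self, n=10_000):
        return [[TruthMutation("L", "chr1", i + 1, "SBS", "A", "G")
                 for i in range(n)]]

    def test_marginals_match_closed_form_at_m5(self):
        lines = transmit_selfing(self._many_het(), 5, seed=8)
        states = [m.genotype_by_generation[5] for m in lines[0]]
        n = len(states)
        for state, p in zip(("lost", "heterozygous", "homozygous"),
                            genotype_distribution(SelfingModel(), 5)):
            freq = sum(s == state for s in states) / n
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * se

    def test_no_selfing_keeps_everything_heterozygous(self):
        lines = transmit_selfing(self._many_het(100), 1, seed=9)
        assert all(m.genotype_by_generation[1] == "heterozygous" for m in lines[0])

    def test_absorbing_states(self):
        lines = transmit_selfing(self._many_het(2_000), 6, seed=10)
        for m in lines[0]:
            traj = [m.genotype_by_generation[k] for k in range(1, 7)]
            for a, b in zip(traj, traj[1:]):
                if a == "lost":
                    assert b == "lost"
                if a == "homozygous":
                    assert b == "homozygous"


class TestSimulateBulkReads:
    def _bulk(self, **kw):
        defaults = dict(n_seedlings=24, mean_depth=30, error_rate=0.0,
                        n_background_variants=0, n_false_positives=0)
        defaults.update(kw)
        return BulkSamplingSpec(**defaults)

    def _lines_with_state(self, state, n):
        return [[
            TruthMutation("L", "chr1", i + 1, "SBS", "A", "G",
                          genotype_by_generation={5: state})
            for i in range(n)
        ]]

    def test_homozygous_sites_have_vaf_one_without_error(self, toy_reference):
        records, truth = simulate_bulk_reads(
            self._lines_with_state("homozygous", 200), 5, self._bulk(),
            toy_reference, seed=11,
        )
        assert len(records) == 200
        assert all(r.alt_count == r.depth for r in records)

    def test_heterozygous_bulk_vaf_centers_on_half(self, toy_reference):
        records, _ = simulate_bulk_reads(
            self._lines_with_state("heterozygous", 10_000), 5, self._bulk(),
            toy_reference, seed=12,
        )
        vafs = np.array([r.alt_count / r.depth for r in records])
        se = vafs.std(ddof=1) / math.sqrt(len(vafs))
        assert abs(vafs.mean() - 0.5) < 3 * se

    def test_lost_mutations_are_not_emitted(self, toy_reference):
        records, truth = simulate_bulk_reads(
            self._lines_with_state("lost", 50), 5, self._bulk(),
            toy_reference, seed=13,
        )
        assert records == [] and truth.empty

    def test_false_positive_bookkeeping(self, toy_reference):
        records, truth = simulate_bulk_reads(
            self._lines_with_state("homozygous", 10), 5,
            self._bulk(n_false_positives=5), toy_reference, seed=14,
        )
        artifacts = truth[truth.origin == "artifact"]
        assert len(artifacts) == 5
        assert all(r.alt_count / r.depth < 0.40
                   for r in records[-5:])  # artifacts emitted last for the line

    def test_background_shared_across_lines(self, toy_reference):
        lines = [
            [TruthMutation(f"L{j}", "chr1", 1 + j, "SBS", "A", "G",
                           genotype_by_generation={5: "homozygous"})]
            for j in range(3)
        ]
        _, truth = simulate_bulk_reads(
            lines, 5, self._bulk(n_background_variants=4), toy_reference, seed=15,
        )
        bg = truth[truth.origin == "background"]
        sites = bg.groupby(["chromosome", "position"]).line_id.nunique()
        assert len(sites) == 4 and (sites == 3).all()

    def test_every_record_traceable_to_one_truth_row(self, toy_reference):
        lines = transmit_selfing(
            induce_mutations(toy_reference, gamma_spectrum(), 3, seed=16), 5, seed=17
        )
        records, truth = simulate_bulk_reads(
            lines, 5, self._bulk(n_background_variants=5, n_false_positives=2),
            toy_reference, seed=18,
        )
        keys = [(r.line_id, r.chromosome, r.position, r.ref_allele, r.alt_allele)
                for r in records]
        truth_keys = list(
            truth[["line_id", "chromosome", "position", "ref_allele", "alt_allele"]]
            .itertuples(index=False, name=None)
        )
        assert sorted(keys) == sorted(truth_keys)
        assert len(set(keys)) == len(keys)

    def test_unresolved_genotype_is_an_error(self, toy_reference):
        lines = [[TruthMutation("L", "chr1", 1, "SBS", "A", "G")]]
        with pytest.raises(ValueError, match="transmit_selfing"):
            simulate_bulk_reads(lines, 5, self._bulk(), toy_reference, seed=19)


class TestDeterminism:
    def test_identical_seeds_identical_outputs(self, toy_reference):
        def run():
            lines = induce_mutations(toy_reference, carbon_ion_spectrum(), 3, seed=20)
            lines = transmit_selfing(lines, 5, seed=21)
            return simulate_bulk_reads(lines, 5, BulkSamplingSpec(), toy_reference,
                                       seed=22)

        (rec_a, truth_a), (rec_b, truth_b) = run(), run()
        assert rec_a == rec_b
        assert truth_a.equals(truth_b)
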