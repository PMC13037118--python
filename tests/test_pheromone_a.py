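"""a-pheromone gene calling: protein validation, genome scanning, peptides."""

import numpy as np
import pytest

from pheroscan.config import PipelineConfig
from pheroscan.motifs import find_caax_motifs
from pheroscan.pheromone_a import (MaturePeptide, extract_a_mature_peptides,
                                   repeat_support, scan_genome_for_a_pheromones,
                                   validate_a_protein)
from pheroscan.seqio import Frame, SequenceRecord, reverse_complement, translate
from pheroscan.simulate import (make_a_gene, make_a_genome, make_decoy_contig,
                                random_a_mature)


class TestValidateProtein:
    def test_textbook_a_pheromone_accepted(self):
        call = validate_a_protein("MFLILVAKDWSCVIA")
        assert call.functional
        assert call.evidence == {"terminal_motif": True,
                                 "hydrophobic_nterm": True,
                                 "no_signal_peptide": True}
        assert [p.sequence for p in call.mature_peptides] == ["MFLILVAKDWSC"]

    def test_hydrophilic_nterm_rejected(self):
        call = validate_a_protein("MDDDDDDDDDDCVIA")
        assert call.verdict == "rejected:hydrophilic_nterm"

    def test_missing_terminal_motif_rejected(self):
        call = validate_a_protein("MFLILVAKDWSAVIA")
        assert call.verdict == "rejected:no_terminal_motif"

    def test_internal_stop_is_early_stop(self):
        call = validate_a_protein("MFLILVA*KDWSCVIA")
        assert call.verdict == "rejected:early_stop"

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            validate_a_protein("")


class TestGenomeScan:
    def test_minus_strand_planted_gene_recovered(self):
        record, truth = make_a_gene("WDSKGHC", 1, Frame("-", 1), "CaaX", seed=7)
        calls = scan_genome_for_a_pheromones([record])
        assert len(calls) == 1
        call = calls[0]
        assert call.strand == "-" and call.functional
        assert call.protein.endswith(truth.data["protein"][-4:])
        assert [p.sequence for p in call.mature_peptides] == ["WDSKGHC"]

    def test_destroyed_motif_is_not_called(self):
        record, truth = make_a_gene("WDSKGHC", 1, Frame("+", 0), "CaaX", seed=7)
        protein = truth.data["protein"]
        # recode the Cys of the terminal motif as Gly: no motif before the stop
        broken = protein[:-4] + "G" + protein[-3:]
        rng = np.random.default_rng(0)
        from pheroscan.simulate import _encode
        dna = _encode(broken, rng) + "TAA"
        calls = scan_genome_for_a_pheromones(
            [SequenceRecord(id="broken", seq=dna, alphabet="dna")])
        assert [c for c in calls if c.functional] == []

    def test_decoy_contigs_produce_no_calls(self):
        decoys = [make_decoy_contig(seed, length=800) for seed in range(1, 11)]
        assert scan_genome_for_a_pheromones(decoys) == []

    def test_cds_retranslates_to_reported_protein(self):
        contigs, _ = make_a_genome(seed=17, n_genes=2)
        calls = scan_genome_for_a_pheromones(contigs)
        assert calls
        by_id = {r.id: r.seq for r in contigs}
        for call in calls:
            cds = by_id[call.contig][call.cds_start:call.cds_end]
            if call.strand == "-":
                cds = reverse_complement(cds)
            assert translate(cds, Frame("+", 0)) == call.protein + "*"
            assert (call.cds_end - call.cds_start) % 3 == 0

    def test_multi_repeat_gene_reports_one_peptide_per_motif(self):
        record, truth = make_a_gene(random_a_mature(np.random.default_rng(4)),
                                    5, Frame("+", 2), "CpaX", seed=44)
        calls = scan_genome_for_a_pheromones([record])
        assert len(calls) == 1
        peptides = calls[0].mature_peptides
        assert len(peptides) == 5
        assert [p.sequence for p in peptides] == [truth.data["mature"]] * 5
        assert all(p.support == pytest.approx(1.0) for p in peptides)


class TestMaturePeptides:
    def test_single_terminal_hit_reports_longest_window(self):
        protein = "MFLILVAWDEKGHSDWGHC" + "VIA"  # lone terminal CaaX
        hits = find_caax_motifs(protein)
        peptides = extract_a_mature_peptides(protein, hits)
        assert len(peptides) == 1
        assert peptides[0].length == 12  # tie-break: longest candidate
        assert peptides[0].sequence == protein[-15:-3]

    def test_too_few_preceding_residues_rejected(self):
        protein = "MFLC" + "VIA"
        hits = find_caax_motifs(protein)
        assert extract_a_mature_peptides(protein, hits) == []

    def test_identical_repeats_have_full_support(self):
        call = validate_a_protein("MFLILVAKILVX" + "WDSKGHC" + "VIA"
                                  + "WDSKGHC" + "VIA")
        seqs = [p.sequence for p in call.mature_peptides]
        assert seqs == ["WDSKGHC", "WDSKGHC"]
        assert all(p.support == pytest.approx(1.0) for p in call.mature_peptides)

    def test_peptide_lengths_always_in_window(self, cfg):
        rng = np.random.default_rng(11)
        for seed in range(20):
            contigs, _ = make_a_genome(seed=seed + 300, n_genes=1)
            for call in scan_genome_for_a_pheromones(contigs):
                for pep in call.mature_peptides:
                    assert 7 <= pep.length <= 12
                    assert pep.sequence.endswith("C")


class TestRepeatSupport:
    def _pep(self, seq):
        return MaturePeptide(sequence=seq, start=0, end=len(seq), motif_kind="CaaX")

    def test_identical_member_scores_one(self):
        assert repeat_support(self._pep("WDSKGHSC"),
                              [self._pep("WDSKGHSC")]) == pytest.approx(1.0)

    def test_empty_library_scores_zero(self):
        assert repeat_support(self._pep("WDSKGHSC"), []) == 0.0

    def test_single_substitution_at_length_eight(self):
        support = repeat_support(self._pep("WDSKGHSC"), [self._pep("WDSKGHTC")])
        assert support == pytest.approx(7 / 8)
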