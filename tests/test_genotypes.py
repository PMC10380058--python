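import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tgskit.errors import ConfigurationError, GenotypeParseError
from tgskit.genotypes import (
    GenotypeCall,
    GenotypeMatrix,
    encode,
    read_genotype_tsv,
    read_vcf,
    write_genotype_tsv,
    write_vcf,
)
from tgskit.panel import Panel, SNPPanelEntry


def test_half_calls_are_rejected():
    with pytest.raises(ValueError, match="half-call"):
        GenotypeCall("A", None)
    assert GenotypeCall.missing().is_missing


class TestGenotypeTsv:
    def test_cells_parse_to_allele_pairs(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\trs1\trs2\ns1\tAG\t--\n")
        gm = read_genotype_tsv(p)
        assert gm.call("s1", "rs1") == GenotypeCall("A", "G")
        assert gm.call("s1", "rs2").is_missing

    def test_malformed_cell_names_coordinates(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\trs1\ns1\tAGT\n")
        with pytest.raises(GenotypeParseError) as err:
            read_genotype_tsv(p)
        assert "s1" in str(err.value) and "rs1" in str(err.value)

    def test_roundtrip_exact(self, tiny_matrix, tmp_path):
        p = tmp_path / "g.tsv"
        write_genotype_tsv(tiny_matrix, p)
        back = read_genotype_tsv(p)
        assert back.sample_ids == tiny_matrix.sample_ids
        assert back.locus_ids == tiny_matrix.locus_ids
        assert (back.calls == tiny_matrix.calls).all()


class TestVcf:
    def _write_vcf(self, path, body, samples=("s1", "s2", "s3")):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        path.write_text(header + body)

    def test_calls_matched_by_rsid_in_panel_order(self, tiny_panel, tmp_path):
        p = tmp_path / "g.vcf"
        # file order deliberately differs from panel order
        self._write_vcf(p,
            "1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t1|1\t0/0\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t./.\t1/1\n"
            "1\t300\trs3\tT\tA\t.\t.\t.\tGT\t0/1\t0/1\t0/1\n"
            "1\t400\trs4\tG\tC\t.\t.\t.\tGT\t1/1\t0/0\t0/1\n")
        gm = read_vcf(p, tiny_panel)
        assert gm.locus_ids == ["rs1", "rs2", "rs3", "rs4"]
        assert gm.call("s1", "rs1") == GenotypeCall("A", "A")
        assert gm.call("s2", "rs1").is_missing        # ./. convention
        assert gm.call("s2", "rs2") == GenotypeCall("T", "T")  # phased |
        assert gm.call("s1", "rs4") == GenotypeCall("C", "C")

    def test_absent_panel_locus_is_all_missing(self, tiny_panel, tmp_path, caplog):
        p = tmp_path / "g.vcf"
        self._write_vcf(p, "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        with caplog.at_level("WARNING"):
            gm = read_vcf(p, tiny_panel)
        assert gm.n_loci == 4
        assert all(gm.call(s, "rs2").is_missing for s in gm.sample_ids)
        assert any("rs2" in rec.message for rec in caplog.records)

    def test_multiallelic_record_set_missing(self, tiny_panel, tmp_path, caplog):
        p = tmp_path / "g.vcf"
        self._write_vcf(p, "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/2\t1/1\n")
        with caplog.at_level("WARNING"):
            gm = read_vcf(p, tiny_panel)
        assert all(gm.call(s, "rs1").is_missing for s in gm.sample_ids)
        assert any("multi-allelic" in rec.message for rec in caplog.records)

    def test_unreadable_vcf_raises_parse_error(self, tiny_panel, tmp_path):
        p = tmp_path / "g.vcf"
        p.write_text("this is not a vcf\n")
        with pytest.raises(GenotypeParseError):
            read_vcf(p, tiny_panel)

    def test_write_read_roundtrip(self, tiny_panel, tiny_matrix, tmp_path):
        p = tmp_path / "out.vcf"
        write_vcf(tiny_matrix, tiny_panel, p)
        back = read_vcf(p, tiny_panel)
        em_a = encode(tiny_matrix, tiny_panel)
        em_b = encode(back, tiny_panel)
        assert np.array_equal(em_a.scores, em_b.scores, equal_nan=True)


class TestEncode:
    def test_all_16_allele_pairs_enumerated(self):
        """Exhaustive contract: earlier=A, later=G over every ordered pair."""
        panel = Panel(entries=(
            SNPPanelEntry(rsid="rs1", beta=0.1, earlier_allele="A", later_allele="G"),
        ))
        expected = {  # None = mismatch -> missing
            ("A", "A"): 2.0, ("A", "G"): 1.0, ("G", "A"): 1.0, ("G", "G"): 0.0,
        }
        for a1, a2 in itertools.product("ACGT", repeat=2):
            gm = GenotypeMatrix(["s"], ["rs1"], np.array([[a1 + a2]], dtype="U2"))
            em = encode(gm, panel)
            want = expected.get((a1, a2))
            if want is None:
                assert np.isnan(em.scores[0, 0])
                assert em.mismatch_count == 1
            else:
                assert em.scores[0, 0] == want
                assert em.mismatch_count == 0

    def test_missing_propagates_without_mismatch(self, tiny_panel, tiny_matrix):
        em = encode(tiny_matrix, tiny_panel)
        assert np.isnan(em.scores[2, 2])
        assert em.mismatch_count == 0

    def test_encoding_values(self, tiny_panel, tiny_matrix):
        em = encode(tiny_matrix, tiny_panel)
        # panel orientation: rs1 A/G, rs2 C/T, rs3 T/A, rs4 G/C (earlier/later)
        assert em.scores[0].tolist() == [2.0, 1.0, 2.0, 2.0]
        assert em.scores[1].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_locus_not_in_panel_is_config_error(self, tiny_panel):
        gm = GenotypeMatrix(["s"], ["rs999"], np.array([["AA"]], dtype="U2"))
        with pytest.raises(ConfigurationError, match="rs999"):
            encode(gm, tiny_panel)

    def test_strand_flip_rescues_complemented_calls(self):
        panel = Panel(entries=(
            SNPPanelEntry(rsid="rs1", beta=0.1, earlier_allele="A", later_allele="G"),
        ))
        gm = GenotypeMatrix(["s"], ["rs1"], np.array([["TC"]], dtype="U2"))
        em_off = encode(gm, panel, strand_flip=False)
        assert np.isnan(em_off.scores[0, 0]) and em_off.mismatch_count == 1
        em_on = encode(gm, panel, strand_flip=True)  # TC complements to AG
        assert em_on.scores[0, 0] == 1.0 and em_on.mismatch_count == 0


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.sampled_from([0, 1, 2, -1]), min_size=1, max_size=12),
       st.integers(min_value=0, max_value=3))
def test_complement_property_swapping_alleles_maps_s_to_2_minus_s(codes, seed):
    """Swapping earlier/later panel alleles maps every score s to 2 - s."""
    rng = np.random.default_rng(seed)
    allele_pairs = [tuple(rng.permutation(list("ACGT"))[:2]) for _ in codes]
    fwd = Panel(entries=tuple(
        SNPPanelEntry(rsid=f"rs{j}", beta=0.02, earlier_allele=e, later_allele=l)
        for j, (e, l) in enumerate(allele_pairs)))
    rev = Panel(entries=tuple(
        SNPPanelEntry(rsid=f"rs{j}", beta=0.02, earlier_allele=l, later_allele=e)
        for j, (e, l) in enumerate(allele_pairs)))
    cells = []
    for code, (e, l) in zip(codes, allele_pairs):
        cells.append({2: e + e, 1: e + l, 0: l + l, -1: ""}[code])
    gm = GenotypeMatrix(["s"], [f"rs{j}" for j in range(len(codes))],
                        np.array([cells], dtype="U2"))
    s_fwd = encode(gm, fwd).scores[0]
    s_rev = encode(gm, rev).scores[0]
    mask = ~np.isnan(s_fwd)
    assert np.array_equal(np.isnan(s_fwd), np.isnan(s_rev))
    assert np.array_equal(s_rev[mask], 2.0 - s_fwd[mask])
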