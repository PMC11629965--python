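"""Quantification-file parsers: column mapping, replicates, error handling."""

import gzip
import json

import h5py
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txsum import (
    ColumnMap,
    DataError,
    FormatError,
    derive_tpm,
    read_generic_tsv,
    read_kallisto,
    read_rsem,
    read_salmon,
)
from txsum.quant_io import DIALECTS

SALMON_HEADER = "Name\tLength\tEffectiveLength\tTPM\tNumReads\n"


def write_quant_sf(path, rows, header=SALMON_HEADER):
    path.write_text(header + "".join(rows))
    return path


SALMON_ROWS = [
    "tx1\t1000\t850.5\t600000\t30\n",
    "tx2\t500\t350.25\t250000\t10\n",
    "tx3\t2000\t1850\t150000\t9\n",
]


class TestSalmon:
    def test_columns_map_in_file_order(self, tmp_path):
        q = read_salmon(write_quant_sf(tmp_path / "quant.sf", SALMON_ROWS))
        assert q.transcript_ids == ["tx1", "tx2", "tx3"]
        assert q.effective_length.tolist() == [850.5, 350.25, 1850.0]
        assert q.counts.tolist() == [30.0, 10.0, 9.0]
        assert q.abundance.tolist() == [600000.0, 250000.0, 150000.0]

    def test_directory_dispatch(self, tmp_path):
        write_quant_sf(tmp_path / "quant.sf", SALMON_ROWS)
        q = read_salmon(tmp_path)
        assert q.n_transcripts == 3
        assert q.sample_id == tmp_path.name

    def test_missing_column_named_in_error(self, tmp_path):
        header = "Name\tLength\tTPM\tNumReads\n"
        rows = ["tx1\t100\t1e6\t5\n"]
        path = write_quant_sf(tmp_path / "quant.sf", rows, header)
        with pytest.raises(FormatError, match="EffectiveLength"):
            read_salmon(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        rows = [SALMON_ROWS[0], "tx2\t500\toops\t1\t1\n"]
        path = write_quant_sf(tmp_path / "quant.sf", rows)
        with pytest.raises(FormatError, match="line 3"):
            read_salmon(path)

    def test_bootstrap_block_round_trips(self, canonical_gt, canonical_dir):
        q = read_salmon(canonical_dir / "salmon" / "sample_1", with_inferential=True)
        assert q.replicates.shape == (6, 4)
        np.testing.assert_array_equal(q.replicates, canonical_gt.replicate_tensor[:, 0, :])
        assert q.replicate_kind == "bootstrap"

    def test_missing_replicates_is_explicit_error(self, tmp_path):
        write_quant_sf(tmp_path / "quant.sf", SALMON_ROWS)
        with pytest.raises(DataError, match="no inferential replicates"):
            read_salmon(tmp_path, with_inferential=True)

    def test_gibbs_kind_from_meta_info(self, tmp_path):
        write_quant_sf(tmp_path / "quant.sf", SALMON_ROWS)
        aux = tmp_path / "aux_info"
        (aux / "bootstrap").mkdir(parents=True)
        (aux / "meta_info.json").write_text(
            json.dumps({"num_bootstraps": 2, "samp_type": "gibbs"})
        )
        payload = np.arange(6, dtype="<f8").tobytes()
        with gzip.open(aux / "bootstrap" / "bootstraps.gz", "wb") as fh:
            fh.write(payload)
        q = read_salmon(tmp_path, with_inferential=True)
        assert q.replicate_kind == "gibbs"
        # replicate-major layout: first replicate is values 0..2
        np.testing.assert_array_equal(q.replicates[:, 0], [0, 1, 2])

    @pytest.mark.parametrize("ending", ["\r\n", "\n"])
    def test_line_ending_and_trailing_blank_invariance(self, tmp_path, ending):
        text = SALMON_HEADER + "".join(SALMON_ROWS)
        path = tmp_path / "quant.sf"
        path.write_bytes(text.replace("\n", ending).encode() + ending.encode() * 2)
        q = read_salmon(path)
        assert q.n_transcripts == 3
        assert q.counts.tolist() == [30.0, 10.0, 9.0]


class TestKallisto:
    def test_tsv_abundance_from_tpm_column(self, tmp_path):
        (tmp_path / "abundance.tsv").write_text(
            "target_id\tlength\teff_length\test_counts\ttpm\n"
            "tx1\t800\t651\t20\t700000\n"
            "tx2\t400\t251\t12\t300000\n"
        )
        q = read_kallisto(tmp_path)
        assert q.abundance.tolist() == [700000.0, 300000.0]
        assert q.effective_length.tolist() == [651.0, 251.0]

    def test_h5_bootstraps_match_serialized_values(self, tmp_path):
        from txsum import synthetic

        gt = synthetic.generate(
            synthetic.SyntheticSpec(n_genes=2, isoforms_per_gene=2, n_samples=1,
                                    n_bootstrap=3, seed=5),
            tmp_path,
        )
        q = read_kallisto(tmp_path / "kallisto" / "sample_1", prefer_h5=True,
                          with_inferential=True)
        assert q.replicates.shape == (4, 3)
        np.testing.assert_array_equal(q.replicates, gt.replicate_tensor[:, 0, :])
        np.testing.assert_allclose(q.abundance, gt.tpm[:, 0], rtol=1e-12)

    def test_tsv_wins_unless_prefer_h5(self, tmp_path):
        (tmp_path / "abundance.tsv").write_text(
            "target_id\tlength\teff_length\test_counts\ttpm\n"
            "tx1\t800\t650\t99\t1000000\n"
        )
        with h5py.File(tmp_path / "abundance.h5", "w") as h5:
            h5.create_dataset("aux/ids", data=[b"tx1"])
            h5.create_dataset("aux/eff_lengths", data=[650.0])
            h5.create_dataset("est_counts", data=[11.0])
        assert read_kallisto(tmp_path).counts.tolist() == [99.0]
        assert read_kallisto(tmp_path, prefer_h5=True).counts.tolist() == [11.0]

    def test_h5_missing_dataset_named_in_error(self, tmp_path):
        with h5py.File(tmp_path / "abundance.h5", "w") as h5:
            h5.create_dataset("aux/ids", data=[b"tx1"])
            h5.create_dataset("est_counts", data=[1.0])
        with pytest.raises(FormatError, match="aux/eff_lengths"):
            read_kallisto(tmp_path, prefer_h5=True)

    def test_replicates_require_h5(self, tmp_path):
        (tmp_path / "abundance.tsv").write_text(
            "target_id\tlength\teff_length\test_counts\ttpm\ntx1\t800\t650\t9\t1e6\n"
        )
        with pytest.raises(DataError, match="replicates"):
            read_kallisto(tmp_path, with_inferential=True)


RSEM_ISO = (
    "transcript_id\tgene_id\tlength\teffective_length\texpected_count\tTPM\tFPKM\tIsoPct\n"
    "t1\tgA\t1000\t801\t30\t600000\t1\t60\n"
    "t2\tgA\t600\t401\t20\t400000\t1\t40\n"
)
RSEM_GENE = (
    "gene_id\ttranscript_id(s)\tlength\teffective_length\texpected_count\tTPM\tFPKM\n"
    "gA\tt1,t2\t840\t641\t50\t1000000\t1\n"
)


class TestRsem:
    def test_isoform_level_keeps_embedded_mapping(self, tmp_path):
        path = tmp_path / "s.isoforms.results"
        path.write_text(RSEM_ISO)
        q = read_rsem(path, level="isoform")
        assert q.transcript_ids == ["t1", "t2"]
        assert q.gene_ids == ["gA", "gA"]
        assert not q.already_summarized

    def test_gene_level_flagged_already_summarized(self, tmp_path):
        path = tmp_path / "s.genes.results"
        path.write_text(RSEM_GENE)
        q = read_rsem(path, level="gene")
        assert q.transcript_ids == ["gA"]
        assert q.already_summarized

    def test_level_file_mismatch(self, tmp_path):
        iso = tmp_path / "s.isoforms.results"
        iso.write_text(RSEM_ISO)
        with pytest.raises(DataError, match="isoform-level file"):
            read_rsem(iso, level="gene")
        gene = tmp_path / "s.genes.results"
        gene.write_text(RSEM_GENE)
        with pytest.raises(DataError, match="gene-level file"):
            read_rsem(gene, level="isoform")


class TestGenericTsv:
    def test_derives_tpm_when_no_abundance_column(self, tmp_path):
        path = tmp_path / "quants.tsv"
        path.write_text("tx\tn_reads\teff_len\na\t10\t100\nb\t10\t200\n")
        q = read_generic_tsv(path, ColumnMap("tx", "n_reads", "eff_len"))
        np.testing.assert_allclose(q.abundance, [2e6 / 3, 1e6 / 3])

    def test_unknown_column_echoed(self, tmp_path):
        path = tmp_path / "quants.tsv"
        path.write_text("tx\tn_reads\teff_len\na\t10\t100\n")
        with pytest.raises(FormatError, match="my_len"):
            read_generic_tsv(path, ColumnMap("tx", "n_reads", "my_len"))

    def test_abundance_column_read_not_derived(self, tmp_path):
        path = tmp_path / "quants.tsv"
        path.write_text("tx\tn_reads\teff_len\ttpm\na\t10\t100\t123\nb\t10\t200\t456\n")
        q = read_generic_tsv(path, ColumnMap("tx", "n_reads", "eff_len", "tpm"))
        assert q.abundance.tolist() == [123.0, 456.0]

    def test_duplicate_transcript_id_rejected(self, tmp_path):
        path = tmp_path / "quants.tsv"
        path.write_text("tx\tn_reads\teff_len\na\t10\t100\na\t5\t100\n")
        with pytest.raises(DataError, match="duplicate"):
            read_generic_tsv(path, ColumnMap("tx", "n_reads", "eff_len"))

    @pytest.mark.parametrize("dialect,header,row", [
        ("oarfish", "tname\tlen\tnum_reads", "a\t500\t12.5"),
        ("piscem", "target_name\teeln\tecount", "a\t500\t12.5"),
    ])
    def test_preset_dialects(self, tmp_path, dialect, header, row):
        path = tmp_path / "q.tsv"
        path.write_text(header + "\n" + row + "\n")
        q = read_generic_tsv(path, DIALECTS[dialect], source_format=dialect)
        assert q.counts.tolist() == [12.5]
        assert q.effective_length.tolist() == [500.0]
        assert q.abundance.tolist() == [1e6]


class TestDeriveTpm:
    def test_hand_example(self):
        np.testing.assert_allclose(
            derive_tpm(np.array([10.0, 10.0]), np.array([100.0, 200.0])),
            [666666.6666666667, 333333.3333333333],
        )

    def test_all_zero_counts(self):
        assert derive_tpm(np.zeros(2), np.array([100.0, 200.0])).tolist() == [0.0, 0.0]

    def test_single_transcript_gets_full_mass(self):
        assert derive_tpm(np.array([3.0]), np.array([512.0])).tolist() == [1e6]

    def test_negative_input_rejected(self):
        with pytest.raises(DataError):
            derive_tpm(np.array([-1.0]), np.array([100.0]))

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=30),
        st.data(),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_sums_to_one_million(self, counts, data):
        lengths = data.draw(
            st.lists(
                st.floats(min_value=1, max_value=1e5),
                min_size=len(counts), max_size=len(counts),
            )
        )
        tpm = derive_tpm(np.array(counts), np.array(lengths))
        if any(c > 0 for c in counts):
            assert tpm.sum() == pytest.approx(1e6, rel=1e-6)
        else:
            assert tpm.sum() == 0
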