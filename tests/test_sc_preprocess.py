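"""Reader contracts, QC arithmetic (with scanpy as independent oracle),
boundary-exact cell filtering, and lineage pooling."""

import numpy as np
import pandas as pd
import pytest

from nnice import sc_preprocess as scp
from nnice.types import CountMatrix


def _cm(values, genes=None, cols=None, labels=None):
    values = np.asarray(values)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cols = cols or [f"C{i}" for i in range(values.shape[1])]
    return CountMatrix(values=values, gene_ids=genes, column_ids=cols,
                       labels=labels)


class TestReadCounts:
    def test_dense_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame([[1, 2], [0, 5], [3, 0]],
                          index=["G1", "G2", "MT-G3"], columns=["S1", "S2"])
        p = tmp_path / "m.tsv"
        df.to_csv(p, sep="\t")
        m = scp.read_counts(p, format="dense_tsv")
        assert m.gene_ids == ["G1", "G2", "MT-G3"]
        assert m.column_ids == ["S1", "S2"]
        assert np.array_equal(m.values, df.to_numpy())

    def test_barcode_mismatch_raises(self, small_reference, tmp_path):
        from nnice.synthetic import write_reference

        paths = write_reference(small_reference, tmp_path)
        text = paths["barcodes"].read_text().splitlines()
        paths["barcodes"].write_text("\n".join(text[:-1]) + "\n")
        with pytest.raises(ValueError, match="barcodes"):
            scp.read_counts(tmp_path, format="tenx_triplet")

    def test_labels_attached_from_triplet(self, small_reference, tmp_path):
        from nnice.synthetic import write_reference

        write_reference(small_reference, tmp_path)
        m = scp.read_counts(tmp_path, format="tenx_triplet")
        assert m.labels == small_reference.labels

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _cm(np.zeros((2, 1), dtype=int), genes=["G1", "G1"])


class TestComputeQC:
    def test_hand_computed_fixture(self):
        # single column [5, 0, 3] with gene 0 mitochondrial
        m = _cm(np.array([[5], [0], [3]]), genes=["MT-G0", "G1", "G2"])
        qc = scp.compute_qc(m)
        assert qc.n_genes_by_counts[0] == 2
        assert qc.total_counts[0] == 8
        assert qc.pct_counts_mito[0] == pytest.approx(62.5)

    def test_all_zero_column_flagged(self):
        m = _cm(np.array([[0, 1], [0, 2]]), genes=["MT-G0", "G1"])
        qc = scp.compute_qc(m)
        assert (qc.n_genes_by_counts[0], qc.total_counts[0],
                qc.pct_counts_mito[0]) == (0, 0, 0)
        assert qc.zero_total_columns == ["C0"]

    def test_no_mito_genes_means_zero_pct(self, rng):
        m = _cm(rng.integers(0, 10, size=(5, 4)))
        qc = scp.compute_qc(m)
        assert np.all(qc.pct_counts_mito == 0)

    def test_explicit_mito_set_overrides_prefix(self):
        m = _cm(np.array([[4], [4]]), genes=["G0", "G1"])
        qc = scp.compute_qc(m, mito_genes={"G1"})
        assert qc.pct_counts_mito[0] == pytest.approx(50.0)

    def test_matches_scanpy_oracle(self, small_reference):
        """Independent cross-check of all three metrics against scanpy."""
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        m = small_reference
        adata = ad.AnnData(m.values.T.astype(np.float32))
        adata.var_names = m.gene_ids
        adata.var["mito"] = [g.startswith("MT-") for g in m.gene_ids]
        sc.pp.calculate_qc_metrics(adata, qc_vars=["mito"], inplace=True,
                                   percent_top=None, log1p=False)
        qc = scp.compute_qc(m)
        np.testing.assert_array_equal(
            qc.n_genes_by_counts, adata.obs["n_genes_by_counts"].to_numpy()
        )
        np.testing.assert_allclose(
            qc.total_counts, adata.obs["total_counts"].to_numpy()
        )
        np.testing.assert_allclose(
            qc.pct_counts_mito, adata.obs["pct_counts_mito"].to_numpy(),
            rtol=1e-6,
        )


def _boundary_fixture():
    """12 cells engineered so 4 fail each rule disjointly (bounds 200-300,
    mito < 5%): cells 0-3 detect too few genes, cells 4-7 too many, cells
    8-11 are in-bounds but at/above 5% mitochondrial counts."""
    n_genes = 600
    genes = ["MT-G0"] + [f"G{i}" for i in range(1, n_genes)]
    cols = []
    for n_nonmito, mito_count in [
        (199, 0), (150, 0), (100, 0), (10, 0),       # fail min_genes
        (301, 0), (350, 0), (400, 0), (599, 0),      # fail max_genes
        (250, 14), (250, 20), (250, 250), (250, 1000),  # fail mito >= 5%
    ]:
        col = np.zeros(n_genes, dtype=int)
        col[1:n_nonmito + 1] = 1
        col[0] = mito_count
        cols.append(col)
    return _cm(np.stack(cols, axis=1), genes=genes)


class TestFilterCells:
    MIN_G, MAX_G, MAX_MITO = 200, 300, 5.0

    def test_brute_force_oracle_on_boundary_fixture(self):
        m = _boundary_fixture()
        qc = scp.compute_qc(m)
        with pytest.warns(UserWarning):
            kept = scp.filter_cells(m, qc, self.MIN_G, self.MAX_G,
                                    self.MAX_MITO)
        # independent exhaustive per-cell re-check
        expected = []
        for j, cid in enumerate(m.column_ids):
            col = m.values[:, j]
            n = int((col > 0).sum())
            tot = int(col.sum())
            mito = 100 * col[0] / tot if tot else 0.0
            if self.MIN_G <= n <= self.MAX_G and mito < self.MAX_MITO:
                expected.append(cid)
        assert kept.column_ids == expected
        assert expected == []  # every cell fails exactly one rule

    def test_boundary_semantics(self):
        """n=200 & mito 4.9% kept; n=199 removed; mito exactly 5% removed."""
        genes = ["MT-G0"] + [f"G{i}" for i in range(1, 600)]
        keep_col = np.zeros(600, dtype=int)
        keep_col[1:200] = 2  # 199 non-mito genes detected
        keep_col[0] = 20     # with mito: 200 genes; 20/418 = 4.78% < 5
        low_col = np.zeros(600, dtype=int)
        low_col[1:200] = 1   # 199 genes, no mito
        mito5_col = np.zeros(600, dtype=int)
        mito5_col[1:229] = 1
        mito5_col[0] = 12    # 229 genes; 12/240 = 5.0% exactly
        m = _cm(np.stack([keep_col, low_col, mito5_col], axis=1), genes=genes)
        qc = scp.compute_qc(m)
        kept = scp.filter_cells(m, qc, 200, 3000, 5.0)
        assert kept.column_ids == ["C0"]

    def test_wide_open_thresholds_are_identity(self, small_reference):
        qc = scp.compute_qc(small_reference)
        kept = scp.filter_cells(small_reference, qc, 0, 10**9, 100.0)
        assert kept.equals(small_reference)

    def test_idempotent_and_pure_selection(self, small_reference):
        qc = scp.compute_qc(small_reference)
        once = scp.filter_cells(small_reference, qc, min_genes=150,
                                max_genes=3000)
        twice = scp.filter_cells(once, scp.compute_qc(once), min_genes=150,
                                 max_genes=3000)
        assert once.equals(twice)
        for cid in once.column_ids:
            i, j = once.column_ids.index(cid), small_reference.column_ids.index(cid)
            assert np.array_equal(once.values[:, i],
                                  small_reference.values[:, j])


class TestPooling:
    def test_reference_map_assignments(self):
        assert scp.TENX_POOLING_MAP["CD4+/CD45RO+ memory T cells"] == "CD4 T cell"
        assert scp.TENX_POOLING_MAP["CD56+ NK cells"] == "NK cell"
        assert scp.TENX_POOLING_MAP["CD19+ B cells"] == "B cell"
        assert scp.TENX_POOLING_MAP["CD14+ monocytes"] == "Myeloid"
        assert scp.TENX_POOLING_MAP["CD34+ cells"] == "Other"
        assert scp.pool_cell_types(
            ["CD8+ cytotoxic T cells", "CD8+/CD45RA+ naive cytotoxic T cells"],
            scp.TENX_POOLING_MAP,
        ) == ["CD8 T cell", "CD8 T cell"]

    def test_identity_on_already_pooled(self):
        from nnice.types import POOLED_TYPES

        idmap = {t: t for t in POOLED_TYPES}
        labels = list(POOLED_TYPES)
        assert scp.pool_cell_types(labels, idmap) == labels

    def test_unmapped_label_is_explicit_error(self):
        with pytest.raises(KeyError, match="platelets"):
            scp.pool_cell_types(["CD19+ B cells", "platelets"],
                                scp.TENX_POOLING_MAP)

    def test_pooling_preserves_column_count_and_order(self, small_reference):
        pooled = scp.pool_matrix(small_reference, scp.TENX_POOLING_MAP)
        assert pooled.column_ids == small_reference.column_ids
        assert len(pooled.labels) == small_reference.n_columns

    def test_pooling_map_tsv_round_trip(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("".join(f"{k}\t{v}\n"
                             for k, v in scp.FLOW_POOLING_MAP.items()))
        assert scp.read_pooling_map(p) == scp.FLOW_POOLING_MAP
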