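import numpy as np
import pandas as pd
import pytest

from sctab.corpus import (
    CellByGeneMatrix,
    FilterParams,
    donor_split,
    filter_corpus,
    normalize,
    stream_batches,
    subsample,
    write_chunk_store,
    align_genes,
)
from sctab.synthetic import generate_preset


def make_matrix(values, layer="raw"):
    values = np.asarray(values)
    genes = np.array([f"G{i}" for i in range(values.shape[1])])
    return CellByGeneMatrix(values, genes, layer)


def make_records(cell_types, donors, **overrides):
    n = len(cell_types)
    base = {
        "cell_id": [f"c{i}" for i in range(n)],
        "cell_type": cell_types,
        "donor_id": donors,
        "assay": ["10x 3' v3"] * n,
        "dataset_id": ["d0"] * n,
        "is_primary": [True] * n,
        "tissue": ["t"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestNormalize:
    def test_equal_counts_split_size_factor(self):
        out = normalize(make_matrix([[5, 5]]))
        assert np.allclose(out.values, np.log1p(5000.0))

    def test_zero_row_stays_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero total"):
            out = normalize(make_matrix([[0, 0, 0], [1, 1, 2]]))
        assert np.all(out.values[0] == 0)

    def test_expm1_row_sum_recovers_size_factor(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(3.0, size=(10, 20))
        x[:, 0] += 1  # avoid zero rows
        out = normalize(make_matrix(x))
        sums = np.expm1(out.values.astype(np.float64)).sum(axis=1)
        assert np.allclose(sums, 10_000.0, atol=1e-2)

    def test_double_normalization_rejected(self):
        out = normalize(make_matrix([[1, 2]]))
        with pytest.raises(ValueError, match="already normalized"):
            normalize(out)

    def test_negative_entries_fatal(self):
        with pytest.raises(ValueError, match="negative"):
            normalize(make_matrix([[1, -1]]))


@pytest.fixture(scope="module")
def edge_corpus():
    return generate_preset("filter-edge")


class TestFilterCorpus:
    def test_boundary_types(self, edge_corpus):
        c = edge_corpus
        _, records, report = filter_corpus(c.matrix, c.records, c.graph, FilterParams())
        surviving = set(records["cell_type"])
        counts = c.records.groupby("cell_type").size()
        # 4,999-cell type removed, 5,000-cell type kept
        below = c.records.loc[
            c.records.cell_id.str.startswith("below_cells"), "cell_type"
        ].iloc[0]
        at = c.records.loc[
            c.records.cell_id.str.startswith("at_cells"), "cell_type"
        ].iloc[0]
        assert below not in surviving and at in surviving
        assert counts[below] == 4999 and counts[at] == 5000

    def test_29_donor_type_removed_30_kept(self, edge_corpus):
        c = edge_corpus
        _, records, _ = filter_corpus(c.matrix, c.records, c.graph, FilterParams())
        surviving = set(records["cell_type"])
        below = c.records.loc[
            c.records.cell_id.str.startswith("below_donors"), "cell_type"
        ].iloc[0]
        at = c.records.loc[
            c.records.cell_id.str.startswith("at_donors"), "cell_type"
        ].iloc[0]
        assert below not in surviving and at in surviving

    def test_report_accounting_balances(self, edge_corpus):
        c = edge_corpus
        _, _, report = filter_corpus(c.matrix, c.records, c.graph, FilterParams())
        assert sum(report.removed.values()) + report.surviving_cells == report.input_cells

    def test_row_order_invariance(self, edge_corpus):
        c = edge_corpus
        _, rec1, _ = filter_corpus(c.matrix, c.records, c.graph, FilterParams())
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(c.records))
        _, rec2, _ = filter_corpus(
            c.matrix.subset(perm),
            c.records.iloc[perm].reset_index(drop=True),
            c.graph,
            FilterParams(),
        )
        assert set(rec1["cell_id"]) == set(rec2["cell_id"])

    def test_survivor_set_matches_bruteforce_refilter(self, edge_corpus):
        """Independent filter: straight pandas re-implementation."""
        c = edge_corpus
        _, records, _ = filter_corpus(c.matrix, c.records, c.graph, FilterParams())
        df = c.records.copy()
        df = df[df.is_primary]
        df = df[df.assay.str.startswith("10x")]
        ok_types = []
        for t, grp in df.groupby("cell_type"):
            if (
                len(grp) >= 5000
                and grp.donor_id.nunique() >= 30
                and c.graph.ancestor_count(t) >= 7
            ):
                ok_types.append(t)
        expected = set(df[df.cell_type.isin(ok_types)].cell_id)
        assert set(records["cell_id"]) == expected

    def test_unresolvable_terms_reported_not_silently_dropped(self, edge_corpus):
        c = edge_corpus
        records = c.records.copy()
        records.loc[:10, "cell_type"] = "CL:does-not-exist"
        _, _, report = filter_corpus(c.matrix, records, c.graph, FilterParams())
        assert "CL:does-not-exist" in report.unresolvable_terms

    def test_empty_result_raises_with_report(self, edge_corpus):
        c = edge_corpus
        with pytest.raises(ValueError, match="no cells survive"):
            filter_corpus(
                c.matrix, c.records, c.graph, FilterParams(min_cells=10**9)
            )


class TestDonorSplit:
    def test_exact_multiples(self):
        donors = [f"d{i}" for i in range(20)]
        split = donor_split(donors, seed=0)
        sizes = {s: len(split.donors(s)) for s in ("train", "val", "test")}
        assert sizes == {"train": 14, "val": 3, "test": 3}

    def test_documented_rounding_small_n(self):
        # floor for val and test, remainder to train: 10 donors -> (8, 1, 1)
        split = donor_split([f"d{i}" for i in range(10)], seed=0)
        sizes = {s: len(split.donors(s)) for s in ("train", "val", "test")}
        assert sizes == {"train": 8, "val": 1, "test": 1}

    def test_deterministic_given_seed(self):
        donors = [f"d{i}" for i in range(37)]
        assert donor_split(donors, seed=5).assignment == donor_split(donors, seed=5).assignment

    def test_partition_is_exhaustive_and_disjoint(self):
        donors = [f"d{i}" for i in range(23)]
        split = donor_split(donors, seed=1)
        all_assigned = (
            split.donors("train") + split.donors("val") + split.donors("test")
        )
        assert sorted(all_assigned) == sorted(donors)

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError, match="sum to 1"):
            donor_split(list("abcdef"), fractions=(0.5, 0.2, 0.2), seed=0)

    def test_too_few_donors_raise(self):
        with pytest.raises(ValueError, match="at least 3"):
            donor_split(["a", "b"], seed=0)

    def test_proportions_converge(self):
        donors = [f"d{i}" for i in range(10_000)]
        fracs = []
        for seed in range(20):
            split = donor_split(donors, seed=seed)
            fracs.append(len(split.donors("train")) / 10_000)
        assert abs(np.mean(fracs) - 0.70) < 0.01


class TestSubsample:
    @pytest.fixture(scope="class")
    def records(self):
        rng = np.random.default_rng(0)
        return make_records(
            ["T"] * 400,
            [f"d{i}" for i in rng.integers(0, 20, size=400)],
        )

    def test_nested_cell_mode(self, records):
        out = subsample(records, "cell", [0.15, 0.30], seed=0)
        assert set(out[0.15]).issubset(set(out[0.30]))
        assert len(out[0.15]) == round(0.15 * 400)

    def test_fraction_one_is_identity(self, records):
        out = subsample(records, "cell", [1.0], seed=0)
        assert len(out[1.0]) == len(records)

    def test_donor_mode_keeps_whole_donors(self, records):
        out = subsample(records, "donor", [0.3, 0.6], seed=0)
        for f in (0.3, 0.6):
            chosen = set(records["donor_id"].to_numpy()[out[f]])
            for d in chosen:
                donor_rows = np.flatnonzero((records["donor_id"] == d).to_numpy())
                assert set(donor_rows).issubset(set(out[f]))
        assert set(out[0.3]).issubset(set(out[0.6]))

    def test_non_ascending_fractions_raise(self, records):
        with pytest.raises(ValueError, match="ascending"):
            subsample(records, "cell", [0.3, 0.15], seed=0)


class TestChunkStore:
    @pytest.fixture(scope="class")
    def store(self, tmp_path_factory):
        rng = np.random.default_rng(0)
        n = 1000
        matrix = make_matrix(rng.poisson(2, size=(n, 8)))
        records = make_records(["T"] * n, ["d0"] * n)
        path = tmp_path_factory.mktemp("store") / "chunks"
        write_chunk_store(matrix, records, path, chunk_size=256)
        return path

    def test_batch_arithmetic(self, store):
        batches = list(stream_batches(store, batch_size=128, seed=0))
        assert len(batches) == 8
        assert sorted(len(b.cell_ids) for b in batches)[0] == 104
        assert sum(len(b.cell_ids) for b in batches) == 1000

    def test_epoch_covers_every_row_exactly_once(self, store):
        batches = list(stream_batches(store, batch_size=128, shuffle_buffer=300, seed=3))
        ids = np.concatenate([b.cell_ids for b in batches])
        assert sorted(ids) == sorted(f"c{i}" for i in range(1000))

    def test_same_seed_same_sequence(self, store):
        a = [tuple(b.cell_ids) for b in stream_batches(store, 128, 300, seed=7)]
        b = [tuple(b.cell_ids) for b in stream_batches(store, 128, 300, seed=7)]
        assert a == b

    def test_corrupted_chunk_named_in_error(self, store, tmp_path):
        import shutil

        bad = tmp_path / "bad"
        shutil.copytree(store, bad)
        victim = sorted(bad.glob("chunk-*.parquet"))[1]
        victim.write_bytes(b"not parquet")
        with pytest.raises(IOError, match=victim.name):
            list(stream_batches(bad, batch_size=128, seed=0))

    def test_chunk_smaller_than_batch_rejected(self, store):
        with pytest.raises(ValueError, match="chunk_size"):
            list(stream_batches(store, batch_size=512, seed=0))


class TestAlignGenes:
    def test_reorders_and_zero_fills(self):
        m = make_matrix([[1, 2, 3]])
        with pytest.warns(UserWarning):
            out = align_genes(m, ["G2", "G0", "GX"])
        assert out.values.tolist() == [[3, 1, 0]]

    def test_low_coverage_warns(self):
        m = make_matrix([[1, 2]])
        with pytest.warns(UserWarning, match="vocabulary"):
            align_genes(m, ["G0", "X1", "X2", "X3", "X4"])
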