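"""Address building, UMI collapse, cell calling, and the count matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wellcount.alignkit import AlignedFragment
from wellcount.molcount import (
    AddressTable,
    CountMatrix,
    call_cells,
    collapse_group,
    collapse_umis,
    to_matrix,
    umi_distance,
)


def _frag(read_id, bc="AAACCCGGGTTT", umi="ACGTACGT", gene="geneX", kept=True):
    return AlignedFragment(
        read_id=read_id,
        cell_barcode=bc,
        umi=umi,
        gene_id=gene,
        species="human",
        strand="sense",
        alignment_score=40,
        fragment_length=40,
        status="kept" if kept else "discarded",
        reason=None if kept else "low_score",
    )


def brute_force_collapse(counts):
    """Literal pairwise implementation of the ascending-order merge rule.

    Visits addresses in ascending (initial read_count, UMI) order; each
    merges into the neighbor (Hamming distance 1) with the highest current
    count, provided that count strictly exceeds its own, ties on the target
    breaking to the lexicographically smallest UMI.  Uses explicit pairwise
    distance computations throughout.
    """
    current = dict(counts)
    for umi in sorted(current, key=lambda u: (counts[u], u)):
        if umi not in current:
            continue
        neighbors = [v for v in current if v != umi and umi_distance(umi, v) == 1]
        strictly_higher = [v for v in neighbors if current[v] > current[umi]]
        if not strictly_higher:
            continue
        top = max(current[v] for v in strictly_higher)
        target = min(v for v in strictly_higher if current[v] == top)
        current[target] += current.pop(umi)
    return current


class TestBuildAddresses:
    def test_identical_addresses_collapse_with_multiplicity(self):
        table = AddressTable.from_fragments([_frag(f"r{i}") for i in range(3)])
        assert table.n_addresses == 1
        assert table.total_reads == 3

    def test_gene_distinguishes_addresses(self):
        table = AddressTable.from_fragments(
            [_frag("r0", gene="geneX"), _frag("r1", gene="geneY")]
        )
        assert table.n_addresses == 2

    def test_discarded_fragments_ignored(self):
        table = AddressTable.from_fragments([_frag("r0", kept=False)])
        assert table.n_addresses == 0

    def test_empty_input(self):
        assert AddressTable.from_fragments([]).n_addresses == 0


class TestUmiDistance:
    @pytest.mark.parametrize(
        "u1, u2, d",
        [
            ("ACGTACGT", "ACGTACGT", 0),
            ("ACGTACGT", "ACGTACGA", 1),
            ("AAAAAAAA", "TTAAAAAA", 2),
        ],
    )
    def test_examples(self, u1, u2, d):
        assert umi_distance(u1, u2) == d

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            umi_distance("ACGT", "ACGTA")


class TestCollapseGroup:
    def test_low_count_neighbor_absorbed(self):
        assert collapse_group({"AAAAAAAA": 10, "AAAAAAAT": 2}) == {"AAAAAAAA": 12}

    def test_distant_umis_untouched(self):
        group = {"AAAAAAAA": 5, "CCCCCCCC": 5}
        assert collapse_group(group) == group

    def test_equal_coverage_tie_not_merged(self):
        group = {"AAAAAAAA": 4, "AAAAAAAT": 4}
        assert collapse_group(group) == group

    def test_chain_absorption_through_growth(self):
        # 1-read error merges into the 4-read address, which then outgrows
        # and absorbs the 5-read neighbor it previously tied... only if
        # strictly greater at visit time
        group = {"AAAAAAAA": 4, "AAAAAAAT": 1, "AAAAAACA": 5}
        # visit order: T(1) -> merges into CA? distance(T-variant, CA)?
        assert collapse_group(group) == brute_force_collapse(group)

    def test_read_conservation_and_no_growth(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 8))
            umis = {
                "".join("ACGT"[b] for b in rng.integers(0, 4, 8)): int(rng.integers(1, 20))
                for _ in range(n)
            }
            out = collapse_group(umis)
            assert sum(out.values()) == sum(umis.values())
            assert len(out) <= len(umis)

    @settings(max_examples=300, derandomize=True)
    @given(
        st.dictionaries(
            st.text(alphabet="ACGT", min_size=3, max_size=3),
            st.integers(min_value=1, max_value=15),
            min_size=1,
            max_size=6,
        )
    )
    def test_matches_brute_force_oracle(self, group):
        assert collapse_group(group) == brute_force_collapse(group)

    def test_collapse_umis_preserves_reads_per_group(self):
        table = AddressTable()
        table.add("BC", "geneX", "AAAAAAAA", 9)
        table.add("BC", "geneX", "AAAAAAAT", 1)
        table.add("BC", "geneY", "AAAAAAAT", 4)
        out = collapse_umis(table)
        assert out.total_reads == table.total_reads
        assert out.groups[("BC", "geneX")] == {"AAAAAAAA": 10}
        assert out.groups[("BC", "geneY")] == {"AAAAAAAT": 4}


class TestCallCells:
    def _bimodal_totals(self, n_cells=60, n_ambient=600, seed=2):
        rng = np.random.default_rng(seed)
        totals = {}
        for i in range(n_cells):
            totals[f"CELL{i:04d}"] = int(rng.poisson(800)) + 1
        for i in range(n_ambient):
            totals[f"AMBI{i:04d}"] = int(rng.poisson(2)) + 1
        return totals

    def test_knee_separates_planted_population(self):
        totals = self._bimodal_totals()
        res = call_cells(totals)
        assert set(res.selected) == {f"CELL{i:04d}" for i in range(60)}

    def test_expected_cells_override_takes_top_n(self):
        totals = self._bimodal_totals()
        res = call_cells(totals, expected_cells=10)
        assert len(res.selected) == 10
        top = sorted(totals.items(), key=lambda t: (-t[1], t[0]))[:10]
        assert res.selected == [bc for bc, _ in top]

    def test_selected_set_downward_closed_in_rank(self):
        totals = self._bimodal_totals(seed=5)
        res = call_cells(totals)
        floor = min(totals[bc] for bc in res.selected)
        unselected = set(totals) - set(res.selected)
        assert all(totals[bc] <= floor for bc in unselected)

    def test_too_few_barcodes_rejected(self):
        with pytest.raises(ValueError):
            call_cells({f"B{i}": 10 + i for i in range(5)})

    def test_degenerate_distribution_needs_override(self):
        with pytest.raises(ValueError, match="override"):
            call_cells({f"B{i:03d}": 7 for i in range(50)})

    def test_n_containing_barcodes_excluded(self):
        totals = self._bimodal_totals()
        totals["NNNNAAAACCCC"] = 10_000
        res = call_cells(totals)
        assert "NNNNAAAACCCC" not in res.selected


class TestCountMatrix:
    def test_to_matrix_counts_addresses(self):
        table = AddressTable()
        table.add("BC1", "geneX", "AAAAAAAA")
        table.add("BC1", "geneX", "CCCCCCCC")
        table.add("BC1", "geneY", "AAAAAAAA")
        table.add("BC2", "geneY", "GGGGGGGG")
        table.add("IGNORED", "geneX", "AAAAAAAA")
        m = to_matrix(table, ["BC1", "BC2"], {"geneX": "human", "geneY": "mouse"})
        assert m.X.toarray().tolist() == [[2, 1], [0, 1]]
        assert m.n_molecules.tolist() == [3, 1]
        assert m.n_genes_detected.tolist() == [2, 1]

    def test_unknown_gene_is_error(self):
        table = AddressTable()
        table.add("BC1", "mystery", "AAAAAAAA")
        with pytest.raises(KeyError):
            to_matrix(table, ["BC1"], {"geneX": "human"})

    def test_mtx_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        counts = rng.poisson(1.0, size=(5, 7))
        m = CountMatrix.from_dense(
            counts,
            barcodes=[f"B{i}" for i in range(5)],
            genes=[f"g{j}" for j in range(7)],
            species=["human"] * 4 + ["mouse"] * 3,
        )
        m.write(tmp_path / "mat")
        back = CountMatrix.read(tmp_path / "mat")
        assert back.barcodes == m.barcodes
        assert back.genes == m.genes
        assert back.species == m.species
        assert (back.X.toarray() == counts).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix.from_dense(np.array([[1, -1]]))


class TestPipelineOracle:
    def test_error_free_addresses_equal_truth(self, small_run):
        """With no sequencing errors the observed address table (including
        read counts) is byte-for-byte the simulated truth."""
        truth_table = small_run["truth"].address_table()
        assert small_run["result"].raw_table.groups == truth_table.groups

    def test_error_free_matrix_equals_collapsed_truth(self, small_run):
        """The matrix equals the truth table passed through the same
        UMI-collapse rule (which has its own brute-force oracle)."""
        truth = small_run["truth"]
        result = small_run["result"]
        cells = set(truth.cell_barcodes())
        assert set(result.matrix.barcodes) == cells
        expected = {
            key: len(group)
            for key, group in collapse_umis(truth.address_table()).groups.items()
            if key[0] in cells
        }
        observed = {}
        X = result.matrix.X
        for i, bc in enumerate(result.matrix.barcodes):
            row = X[i].toarray().ravel()
            for g in np.nonzero(row)[0]:
                observed[(bc, result.matrix.genes[g])] = int(row[g])
        assert observed == expected
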