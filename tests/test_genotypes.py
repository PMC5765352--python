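"""Genotype calling and filtering against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossqtl import (
    AlleleCounts,
    GenotypeMatrix,
    build_parental_snp_table,
    call_progeny_genotypes,
    filter_markers,
    filter_strains,
    simulate_allele_counts,
)
from crossqtl.genotypes import ParentalSNPTable

from conftest import noiseless_params
from crossqtl.simulate import simulate_genotypes

BASES = ["A", "C", "G", "T"]


def _counts_frame(rows):
    """rows: list of (chrom, pos, {base: count})"""
    recs = []
    for chrom, pos, d in rows:
        recs.append({"chrom": chrom, "pos": pos, **{b: d.get(b, 0) for b in BASES}})
    return pd.DataFrame(recs)


def _oracle_confident(d: dict) -> str | None:
    """Independent restatement of the five-fold parental confidence rule."""
    items = sorted(((d.get(b, 0), b) for b in BASES), reverse=True)
    top, second = items[0], items[1]
    if top[0] == 0:
        return None
    if second[0] == 0 or top[0] >= 5 * second[0]:
        return top[1]
    return None


class TestParentalSNPTable:
    def test_clean_disagreeing_bases_make_a_snp(self):
        p1 = _counts_frame([("chr1", 100, {"A": 10})])
        p2 = _counts_frame([("chr1", 100, {"C": 10})])
        snps = build_parental_snp_table(p1, p2)
        assert len(snps) == 1
        rec = snps.records.iloc[0]
        assert (rec["base_p1"], rec["base_p2"]) == ("A", "C")

    def test_ambiguous_parent_excluded_by_five_fold_rule(self):
        # 10 < 5 x 3: parent 1 has no confident base
        p1 = _counts_frame([("chr1", 100, {"A": 10, "C": 3})])
        p2 = _counts_frame([("chr1", 100, {"C": 10})])
        assert len(build_parental_snp_table(p1, p2)) == 0

    def test_same_confident_base_is_not_a_marker(self):
        p1 = _counts_frame([("chr1", 100, {"G": 20})])
        p2 = _counts_frame([("chr1", 100, {"G": 15})])
        assert len(build_parental_snp_table(p1, p2)) == 0

    def test_agrees_with_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            n = rng.integers(1, 21)
            pos = rng.choice(10_000, size=n, replace=False) + 1
            rows1, rows2, expected = [], [], []
            for p in sorted(pos):
                d1 = {b: int(rng.integers(0, 15)) for b in BASES}
                d2 = {b: int(rng.integers(0, 15)) for b in BASES}
                rows1.append(("chr1", int(p), d1))
                rows2.append(("chr1", int(p), d2))
                b1, b2 = _oracle_confident(d1), _oracle_confident(d2)
                if b1 is not None and b2 is not None and b1 != b2:
                    expected.append((int(p), b1, b2))
            snps = build_parental_snp_table(_counts_frame(rows1), _counts_frame(rows2))
            got = list(
                zip(snps.records["pos"], snps.records["base_p1"], snps.records["base_p2"])
            )
            assert got == expected

    def test_malformed_records_rejected_with_position(self):
        p1 = _counts_frame([("chr1", 100, {"A": 10}), ("chr1", 100, {"A": 9})])
        p2 = _counts_frame([("chr1", 100, {"C": 10})])
        with pytest.raises(ValueError, match="chr1:100"):
            build_parental_snp_table(p1, p2)
        p1 = _counts_frame([("chr1", 100, {"A": -1})])
        with pytest.raises(ValueError, match="negative"):
            build_parental_snp_table(p1, _counts_frame([("chr1", 100, {"C": 10})]))


def _snps_for(markers: list[str]) -> ParentalSNPTable:
    recs = pd.DataFrame(
        [(m, m.rsplit("_", 1)[0], int(m.rsplit("_", 1)[1]), "A", "C") for m in markers],
        columns=["marker", "chrom", "pos", "base_p1", "base_p2"],
    ).set_index("marker")
    return ParentalSNPTable(recs)


def _counts(pairs: dict[str, tuple[int, int]]) -> AlleleCounts:
    markers = list(pairs)
    p1 = pd.DataFrame([[v[0] for v in pairs.values()]], index=["s1"], columns=markers)
    p2 = pd.DataFrame([[v[1] for v in pairs.values()]], index=["s1"], columns=markers)
    return AlleleCounts(p1, p2)


class TestProgenyCalling:
    @pytest.mark.parametrize(
        "n1,n2,expected",
        [
            (10, 1, "P1"),   # 10 >= 5x1
            (5, 1, "P1"),    # boundary: exactly five-fold
            (4, 1, None),    # below five-fold
            (0, 0, None),    # no reads
            (1, 0, "P1"),    # any positive count beats zero
            (0, 7, "P2"),
            (2, 10, "P2"),
            (9, 2, None),    # 9 < 10
        ],
    )
    def test_five_fold_call_rule(self, n1, n2, expected):
        G = call_progeny_genotypes(_counts({"chr1_10": (n1, n2)}), _snps_for(["chr1_10"]))
        got = G.calls.iloc[0, 0]
        assert (got if pd.notna(got) else None) == expected

    def test_exhaustive_agreement_with_enumerated_oracle(self):
        """Every (n1, n2) pair with total reads <= 12 matches the written-out rule."""
        pairs = {}
        expected = {}
        for n1 in range(13):
            for n2 in range(13 - n1):
                m = f"chr1_{1000 + 100 * n1 + n2}"
                pairs[m] = (n1, n2)
                if n1 > 0 and n1 >= 5 * n2:
                    expected[m] = "P1"
                elif n2 > 0 and n2 >= 5 * n1:
                    expected[m] = "P2"
                else:
                    expected[m] = None
        G = call_progeny_genotypes(_counts(pairs), _snps_for(list(pairs)))
        for m, want in expected.items():
            got = G.calls.loc["s1", m]
            assert (got if pd.notna(got) else None) == want, (m, pairs[m])

    @given(n1=st.integers(0, 500), n2=st.integers(0, 500))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_property_call_symmetry_and_confidence(self, n1, n2):
        """For any count pair: swapping the parents swaps the call, and a call
        is only made when the winner has at least five-fold support."""
        G = call_progeny_genotypes(_counts({"chr1_10": (n1, n2)}), _snps_for(["chr1_10"]))
        G_swap = call_progeny_genotypes(_counts({"chr1_10": (n2, n1)}), _snps_for(["chr1_10"]))
        call, swapped = G.calls.iloc[0, 0], G_swap.calls.iloc[0, 0]
        assert (call == "P1") == (swapped == "P2")
        assert (pd.isna(call)) == (pd.isna(swapped))
        if call == "P1":
            assert n1 >= 5 * n2 and n1 > 0
        elif call == "P2":
            assert n2 >= 5 * n1 and n2 > 0

    def test_unknown_marker_rejected(self):
        with pytest.raises(ValueError, match="absent from the SNP table"):
            call_progeny_genotypes(_counts({"chr1_99": (3, 0)}), _snps_for(["chr1_10"]))

    def test_calling_is_symmetric_under_parent_swap(self):
        params = noiseless_params(error_rate=0.05, mean_depth=8.0, seed=43)
        truth = simulate_genotypes(params)
        counts = simulate_allele_counts(truth, params)
        snps = ParentalSNPTable(
            truth.markers.assign(base_p1="A", base_p2="C")[
                ["chrom", "pos", "base_p1", "base_p2"]
            ]
        )
        G = call_progeny_genotypes(counts, snps)
        G_swapped = call_progeny_genotypes(AlleleCounts(counts.p2, counts.p1), snps)
        swap = {"P1": "P2", "P2": "P1"}
        pd.testing.assert_frame_equal(
            G.calls.map(lambda v: swap.get(v, v)), G_swapped.calls
        )

    def test_noiseless_calls_equal_truth_at_covered_markers(self):
        params = noiseless_params(mean_depth=30.0)
        truth = simulate_genotypes(params)
        counts = simulate_allele_counts(truth, params)
        snps = ParentalSNPTable(
            truth.markers.assign(base_p1="A", base_p2="C")[
                ["chrom", "pos", "base_p1", "base_p2"]
            ]
        )
        G = call_progeny_genotypes(counts, snps)
        covered = G.calls.notna()
        assert covered.to_numpy().mean() > 0.99
        assert (G.calls[covered] == truth.genotypes[covered]).all().all() or (
            G.calls.to_numpy()[covered.to_numpy()]
            == truth.genotypes.to_numpy()[covered.to_numpy()]
        ).all()


def _matrix(calls: np.ndarray, read_strains=None) -> GenotypeMatrix:
    n, m = calls.shape
    markers = [f"chr1_{100 * (j + 1)}" for j in range(m)]
    df = pd.DataFrame(
        calls, index=[f"s{i:03d}" for i in range(n)], columns=markers
    ).replace({"": None})
    meta = pd.DataFrame(
        {"chrom": "chr1", "pos": [100 * (j + 1) for j in range(m)]}, index=pd.Index(markers, name="marker")
    )
    mrs = None if read_strains is None else pd.Series(read_strains, index=markers)
    return GenotypeMatrix(df, meta, marker_read_strains=mrs)


class TestMarkerFilter:
    def test_low_read_fraction_marker_dropped(self):
        calls = np.full((100, 2), "", dtype=object)
        calls[:50, 0] = "P1"
        calls[50:, 0] = "P2"
        calls[:2, 1] = "P1"
        calls[2:4, 1] = "P2"
        G = _matrix(calls, read_strains=[100, 4])  # reads in 4 < 5% of 100
        out = filter_markers(G)
        assert list(out.marker_ids) == ["chr1_100"]
        assert out.marker_meta.loc["chr1_200", "reason"] == "low_read_fraction"

    def test_twofold_ratio_boundary_is_inclusive(self):
        calls = np.full((100, 2), "", dtype=object)
        calls[:30, 0] = "P1"
        calls[30:45, 0] = "P2"   # 30:15 = exactly 2.0 -> retained
        calls[:31, 1] = "P1"
        calls[31:46, 1] = "P2"   # 31:15 > 2.0 -> dropped
        out = filter_markers(_matrix(calls))
        assert list(out.marker_ids) == ["chr1_100"]

    def test_marker_with_one_sided_calls_fails_ratio(self):
        calls = np.full((100, 1), "", dtype=object)
        calls[:60, 0] = "P1"
        out = filter_markers(_matrix(calls))
        assert len(out.marker_ids) == 0

    def test_agrees_with_independent_oracle_on_random_matrices(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            n, m = int(rng.integers(20, 80)), int(rng.integers(3, 15))
            calls = rng.choice(["P1", "P2", ""], size=(n, m), p=[0.4, 0.4, 0.2])
            reads = rng.integers(0, n + 1, size=m)
            G = _matrix(calls.astype(object), read_strains=reads)
            out = filter_markers(G)
            expected = []
            for j, marker in enumerate(G.marker_ids):
                p1 = (calls[:, j] == "P1").sum()
                p2 = (calls[:, j] == "P2").sum()
                ok_reads = reads[j] >= 0.05 * n
                ok_ratio = p1 > 0 and p2 > 0 and 0.5 <= p1 / p2 <= 2.0
                if ok_reads and ok_ratio:
                    expected.append(marker)
            assert list(out.marker_ids) == expected

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(53)
        calls = rng.choice(["P1", "P2", ""], size=(60, 12), p=[0.45, 0.45, 0.1])
        once = filter_markers(_matrix(calls.astype(object)))
        twice = filter_markers(once)
        pd.testing.assert_frame_equal(once.calls, twice.calls)


def _pheno_for(strains, kan=None, nat=None, ypd=None) -> pd.DataFrame:
    rows = []
    for s in strains:
        rows.append((s, "YPD+Kan", 2, 1, (kan or {}).get(s, 1.0)))
        rows.append((s, "YPD+Nat", 2, 1, (nat or {}).get(s, 1.0)))
        rows.append((s, "YPD", 4, 1, (ypd or {}).get(s, 20.0)))
    return pd.DataFrame(rows, columns=["strain", "condition", "day", "replicate", "area"])


class TestStrainFilter:
    def test_coverage_threshold_is_strict(self):
        calls = np.full((3, 2), "P1", dtype=object)
        calls[0, 1] = "P2"
        calls[1, 1] = "P2"
        G = _matrix(calls)
        G.strain_covered = pd.Series([749, 750, 800], index=G.strains)
        out = filter_strains(G, _pheno_for(G.strains), min_markers=750)
        assert list(out.dropped("low_coverage")) == ["s000"]

    def test_double_drug_resistance_dropped(self):
        calls = np.full((3, 2), "P1", dtype=object)
        calls[:, 1] = "P2"
        G = _matrix(calls)
        G.strain_covered = pd.Series(1000, index=G.strains)
        pheno = _pheno_for(G.strains, kan={"s001": 8.0}, nat={"s001": 7.0, "s002": 9.0})
        out = filter_strains(G, pheno, checks=("drug_double_resistant",))
        assert list(out.dropped("drug_double_resistant")) == ["s001"]
        assert "s002" in out.strains  # resistant on one plate only

    def test_no_growth_on_rich_medium_dropped(self):
        calls = np.full((3, 2), "P1", dtype=object)
        calls[:, 1] = "P2"
        G = _matrix(calls)
        G.strain_covered = pd.Series(1000, index=G.strains)
        out = filter_strains(G, _pheno_for(G.strains, ypd={"s002": 0.0}),
                             checks=("no_growth",))
        assert list(out.dropped("no_growth")) == ["s002"]

    def test_identical_strains_keep_first_by_name(self):
        rng = np.random.default_rng(59)
        base = rng.choice(["P1", "P2"], size=30)
        calls = np.vstack([base, base, rng.choice(["P1", "P2"], size=30)]).astype(object)
        G = _matrix(calls)
        G.strain_covered = pd.Series(1000, index=G.strains)
        out = filter_strains(G, _pheno_for(G.strains))
        assert list(out.dropped("near_duplicate")) == ["s001"]

    def test_planted_drop_set_recovered_exactly(self):
        rng = np.random.default_rng(61)
        n, m = 40, 60
        calls = rng.choice(["P1", "P2"], size=(n, m)).astype(object)
        calls[7] = calls[3]          # duplicate of s003
        calls[25] = calls[12]        # duplicate of s012
        G = _matrix(calls)
        covered = pd.Series(1000, index=G.strains)
        covered.iloc[5] = 10         # low coverage
        G.strain_covered = covered
        pheno = _pheno_for(
            G.strains,
            kan={"s009": 8.0}, nat={"s009": 8.0},   # double resistant
            ypd={"s011": 0.0},                        # no growth
        )
        out = filter_strains(G, pheno)
        assert set(out.dropped()) == {"s005", "s009", "s011", "s007", "s025"}
        assert list(out.dropped("near_duplicate")) == ["s007", "s025"]

    def test_missing_phenotype_condition_rejected_by_name(self):
        calls = np.full((2, 2), "P1", dtype=object)
        G = _matrix(calls)
        G.strain_covered = pd.Series(1000, index=G.strains)
        pheno = _pheno_for(G.strains)
        pheno = pheno[pheno["condition"] != "YPD+Nat"]
        with pytest.raises(ValueError, match="YPD\\+Nat"):
            filter_strains(G, pheno)

    def test_filter_is_idempotent(self):
        rng = np.random.default_rng(67)
        calls = rng.choice(["P1", "P2"], size=(20, 30)).astype(object)
        calls[4] = calls[2]
        G = _matrix(calls)
        G.strain_covered = pd.Series(1000, index=G.strains)
        pheno = _pheno_for(G.strains)
        once = filter_strains(G, pheno)
        twice = filter_strains(once, pheno, checks=("drug_double_resistant", "no_growth", "near_duplicate"))
        pd.testing.assert_frame_equal(once.calls, twice.calls)
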