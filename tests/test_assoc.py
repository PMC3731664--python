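import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from conftest import make_panel
from domestiscan.assoc import (
    association_scan,
    fisher_exact_two_sided,
    ld_matrix,
    ld_pair,
)
from domestiscan.errors import DomestiscanError
from domestiscan.panel_io import AccessionMeta, Panel
from domestiscan.variants import segregating_sites


def enumeration_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by full enumeration (independent oracle)."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    denom = math.comb(n, c1)
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        if w <= obs:
            total += w
    return Fraction(total, denom)


class TestFisherExact:
    def test_complete_separation_headline_bound(self):
        """(21,0;0,158): p equals 1/C(179,21), below the printed 1.2e-26."""
        p = fisher_exact_two_sided(21, 0, 0, 158)
        assert p == pytest.approx(1 / math.comb(179, 21), rel=1e-9)
        assert p <= 1.2e-26

    def test_zero_column_margin_gives_one(self):
        assert fisher_exact_two_sided(0, 5, 0, 7) == 1.0

    def test_small_table_enumeration(self):
        assert fisher_exact_two_sided(3, 1, 1, 3) == pytest.approx(34 / 70, rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(DomestiscanError):
            fisher_exact_two_sided(-1, 0, 0, 1)

    def test_exact_rational_oracle_small_n(self):
        """Agreement with exact integer-arithmetic enumeration for n <= 15."""
        for n in range(1, 16):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        got = fisher_exact_two_sided(a, b, c, d)
                        want = float(enumeration_oracle(a, b, c, d))
                        assert got == pytest.approx(want, rel=1e-9), (a, b, c, d)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    )
    def test_swap_invariance(self, a, b, c, d):
        """p unchanged under simultaneous row swap and under column swap."""
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(a, b, c, d)
        assert p == pytest.approx(fisher_exact_two_sided(c, d, a, b), rel=1e-9)
        assert p == pytest.approx(fisher_exact_two_sided(b, a, d, c), rel=1e-9)
        assert 0 < p <= 1


class TestAssociationScan:
    def test_perfect_separator_is_top_hit(self):
        # variant at col 1 separates phenotype perfectly; col 3 does not
        panel = make_panel(
            {"wild": ["AAAA", "ATAA"], "cultivated": ["ACAT", "ACAA"]}
        )
        result = association_scan(segregating_sites(panel), panel)
        # col 1 maps to anchor - 1
        assert result.top_hit == panel.anchor_upstream_bp - 1

    def test_planted_causal_site_recovered(self, paper_panel):
        panel, truth = paper_panel
        vt = segregating_sites(panel)
        result = association_scan(vt, panel)
        assert result.top_hit == truth["causal_upstream_bp"]
        best = result.table["p_two_sided"].min()
        assert best == pytest.approx(1 / math.comb(179, 21), rel=1e-9)

    def test_monomorphic_variant_p_one_not_error(self):
        from domestiscan.variants import Variant, VariantTable

        panel = make_panel({"wild": ["AT"], "cultivated": ["AT"]})
        v = Variant(
            position_upstream_bp=panel.anchor_upstream_bp,
            columns=(0, 1),
            vtype="SNP",
            ref_allele="A",
            alt_alleles=["G"],
            calls={"W1": "A", "C1": None},  # alt carrier lost to missing data
            multiallelic=False,
        )
        result = association_scan(VariantTable([v], ["W1", "C1"]), panel)
        assert result.table["p_two_sided"].iloc[0] == 1.0

    def test_all_null_ties_break_to_most_distal(self):
        # allele splits identical in both phenotype classes: every p = 1
        panel = make_panel({"wild": ["AT", "GC"], "cultivated": ["AT", "GC"]})
        result = association_scan(segregating_sites(panel), panel)
        assert (result.table["p_two_sided"] == 1.0).all()
        assert result.top_hit == result.table["position_upstream_bp"].max()

    def test_permutation_destroys_planted_signal(self, paper_panel):
        """Shuffling phenotypes wipes out the causal signal (>=95% of 100 shuffles)."""
        panel, _ = paper_panel
        vt = segregating_sites(panel)
        rng = np.random.default_rng(2024)
        phenos = [panel.phenotype_of(i) for i in panel.ids]
        null_hits = 0
        for _ in range(100):
            shuffled = list(phenos)
            rng.shuffle(shuffled)
            meta = [
                AccessionMeta(i, panel.meta_of(i).group, ph)
                for i, ph in zip(panel.ids, shuffled)
            ]
            perm = Panel(dict(panel.sequences), meta, panel.anchor_upstream_bp)
            res = association_scan(vt, perm)
            if res.table["p_two_sided"].min() > 0.01:
                null_hits += 1
        assert null_hits >= 95


class TestLD:
    def test_perfect_coupling(self):
        ci = {"a": "A", "b": "A", "c": "G", "d": "G"}
        cj = {"a": "T", "b": "T", "c": "C", "d": "C"}
        r2, dprime = ld_pair(ci, cj)
        assert r2 == pytest.approx(1.0) and dprime == pytest.approx(1.0)

    def test_independence(self):
        ci = {"a": "A", "b": "A", "c": "G", "d": "G"}
        cj = {"a": "T", "b": "C", "c": "T", "d": "C"}
        r2, dprime = ld_pair(ci, cj)
        assert r2 == pytest.approx(0.0) and dprime == pytest.approx(0.0)

    def test_worked_frequency_example(self):
        """3x AB, 1x Ab, 1x aB, 1x ab: D = 1/18, r^2 = 1/16, D' = 1/4."""
        ci = dict(zip("pqrstu", "AAAAGG"))
        cj = dict(zip("pqrstu", "TTTCTC"))
        r2, dprime = ld_pair(ci, cj)
        assert r2 == pytest.approx(1 / 16, rel=1e-12)
        assert dprime == pytest.approx(0.25, rel=1e-12)

    def test_multiallelic_rejected(self):
        ci = {"a": "A", "b": "C", "c": "G"}
        cj = {"a": "T", "b": "T", "c": "C"}
        with pytest.raises(DomestiscanError):
            ld_pair(ci, cj)

    def test_monomorphic_reported_missing(self):
        ci = {"a": "A", "b": "A"}
        cj = {"a": "T", "b": "C"}
        r2, dprime = ld_pair(ci, cj)
        assert math.isnan(r2) and math.isnan(dprime)

    @settings(derandomize=True, deadline=None, max_examples=300)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=30))
    def test_bounds_and_relabeling_invariance(self, pairs):
        ids = [f"s{k}" for k in range(len(pairs))]
        ci = {i: ("A" if x else "G") for i, (x, _) in zip(ids, pairs)}
        cj = {i: ("T" if y else "C") for i, (_, y) in zip(ids, pairs)}
        r2, dprime = ld_pair(ci, cj)
        if math.isnan(r2):
            return
        assert 0 <= r2 <= 1 and 0 <= dprime <= 1
        # relabel alleles at site i: swap A <-> G
        ci_sw = {i: ("G" if a == "A" else "A") for i, a in ci.items()}
        r2_sw, dprime_sw = ld_pair(ci_sw, cj)
        assert r2_sw == pytest.approx(r2, abs=1e-12)
        assert dprime_sw == pytest.approx(dprime, abs=1e-12)

    def test_matrix_symmetric_with_unit_diagonal(self, paper_panel):
        panel, truth = paper_panel
        vt = segregating_sites(panel)
        ld = ld_matrix(vt, panel)
        assert np.allclose(ld.r2, ld.r2.T, equal_nan=True)
        assert np.allclose(np.diag(ld.r2), 1.0)
        # linked sites sit in high LD with the causal site, as in a sweep
        pos = ld.positions
        ci = pos.index(truth["causal_upstream_bp"])
        for col in truth["linked_cols"]:
            cj = pos.index(panel.anchor_upstream_bp - col)
            assert ld.r2[ci, cj] > 0.6

    def test_fully_linked_pair_has_r2_one(self):
        panel = make_panel({"wild": ["ATAT", "ATAT"], "cultivated": ["GTGT", "GTGT"]})
        vt = segregating_sites(panel)
        ld = ld_matrix(vt, panel)
        assert ld.r2[0, 1] == pytest.approx(1.0)
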