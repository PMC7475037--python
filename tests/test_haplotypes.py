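import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introscan.haplotypes import (
    ArchaicGenotypes,
    HaplotypePanel,
    MonomorphicSiteError,
    allele_frequency,
    archaic_match_matrix,
    introgression_segment,
    ld_r2,
    private_archaic_sites,
)


def tiny_panel(columns, pops=None, positions=None):
    """Panel from a list of per-site haplotype columns (site-major)."""
    alleles = np.asarray(columns, dtype=np.int8).T
    n_hap, n_sites = alleles.shape
    ids = [f"h{i}" for i in range(n_hap)]
    pops = pops or {h: "POP" for h in ids}
    positions = positions if positions is not None else np.arange(n_sites) * 100
    return HaplotypePanel(
        positions=np.asarray(positions),
        ref_alleles=["A"] * n_sites,
        alt_alleles=["G"] * n_sites,
        alleles=alleles,
        haplotype_ids=ids,
        pop_of_haplotype=pops,
    )


def brute_force_r2(a, b):
    """Independent oracle: explicit 2x2 gamete counting, cross-product algebra."""
    n11 = n10 = n01 = n00 = 0
    for x, y in zip(a, b):
        if x and y:
            n11 += 1
        elif x and not y:
            n10 += 1
        elif not x and y:
            n01 += 1
        else:
            n00 += 1
    num = (n11 * n00 - n10 * n01) ** 2
    den = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    return num / den


class TestAlleleFrequency:
    def test_all_zero_column(self):
        panel = tiny_panel([[0] * 6], pops={f"h{i}": "P1" if i < 3 else "P2" for i in range(6)})
        freqs = allele_frequency(panel, 0)
        assert freqs == {"P1": 0.0, "P2": 0.0, "ALL": 0.0}

    def test_direct_count(self):
        panel = tiny_panel([[1, 1, 1, 1, 0, 0, 0, 0]])
        assert allele_frequency(panel, 0)["POP"] == 0.5

    def test_matches_ground_truth_carriers(self, panel_sim, panel_config):
        panel, _, truth = panel_sim
        site = sorted(truth.private_site_indices)[0]
        freqs = allele_frequency(panel, site)
        for pop in panel_config.pop_labels:
            carriers = sum(
                1 for h in truth.introgressed_haplotype_ids
                if panel.pop_of_haplotype[h] == pop
            )
            assert freqs[pop] == pytest.approx(carriers / panel_config.n_haplotypes_per_pop)


class TestLdR2:
    def test_perfect_coupling(self):
        panel = tiny_panel([[1, 1, 1, 0, 0, 0], [1, 1, 1, 0, 0, 0]])
        assert ld_r2(panel, 0, 1).r2 == pytest.approx(1.0)

    def test_independence(self):
        panel = tiny_panel([[1, 1, 0, 0], [1, 0, 1, 0]])
        assert ld_r2(panel, 0, 1).r2 == pytest.approx(0.0)

    def test_one_ninth_case(self):
        # AB, AB, Ab, aB, ab, ab
        panel = tiny_panel([[1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 0, 0]])
        assert ld_r2(panel, 0, 1).r2 == pytest.approx(1 / 9)

    def test_monomorphic_raises(self):
        panel = tiny_panel([[1, 1, 1, 1], [1, 0, 1, 0]])
        with pytest.raises(MonomorphicSiteError):
            ld_r2(panel, 0, 1)

    def test_symmetry_and_label_swap(self):
        panel = tiny_panel([[1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 0, 0]])
        r_ab = ld_r2(panel, 0, 1).r2
        r_ba = ld_r2(panel, 1, 0).r2
        swapped = tiny_panel([[0, 0, 0, 1, 1, 1], [1, 1, 0, 1, 0, 0]])
        r_swap = ld_r2(swapped, 0, 1).r2
        assert r_ab == pytest.approx(r_ba)
        assert r_ab == pytest.approx(r_swap)

    def test_counts_sum_to_haplotypes(self):
        panel = tiny_panel([[1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 0, 0]])
        assert ld_r2(panel, 0, 1).haplotype_counts.sum() == 6

    def test_pseudo_snp_column(self):
        panel = tiny_panel([[1, 1, 0, 0]])
        column = np.array([1, 1, 0, 0])
        assert ld_r2(panel, 0, column).r2 == pytest.approx(1.0)

    def test_haplotype_subset(self):
        panel = tiny_panel([[1, 1, 0, 0, 1, 0], [1, 1, 0, 0, 0, 1]])
        assert ld_r2(panel, 0, 1, haplotype_subset=[0, 1, 2, 3]).r2 == pytest.approx(1.0)

    @given(st.data())
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        n = 20
        a = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < n
            )
        )
        b = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda v: 0 < sum(v) < n
            )
        )
        panel = tiny_panel([a, b])
        result = ld_r2(panel, 0, 1)
        assert 0.0 <= result.r2 <= 1.0 + 1e-12
        assert result.r2 == pytest.approx(brute_force_r2(a, b))


class TestPrivateArchaicSites:
    def test_recovers_ground_truth(self, panel_sim, panel_config):
        panel, archaic, truth = panel_sim
        found = private_archaic_sites(panel, panel_config.outgroup_pop, archaic)
        assert set(found.tolist()) == truth.private_site_indices

    def test_single_outgroup_copy_excluded(self):
        pops = {f"h{i}": "OUT" if i < 4 else "POP" for i in range(8)}
        # outgroup haplotype h0 carries one copy of the archaic allele
        panel = tiny_panel([[1, 0, 0, 0, 1, 1, 0, 0]], pops=pops)
        archaic = ArchaicGenotypes(["n1"], np.array([[2.0]]))
        assert private_archaic_sites(panel, "OUT", archaic).size == 0

    def test_all_missing_archaic_excluded(self):
        pops = {f"h{i}": "OUT" if i < 4 else "POP" for i in range(8)}
        panel = tiny_panel([[0, 0, 0, 0, 1, 1, 0, 0]], pops=pops)
        archaic = ArchaicGenotypes(["n1"], np.array([[np.nan]]))
        assert private_archaic_sites(panel, "OUT", archaic).size == 0

    def test_no_overlap_with_outgroup_polymorphic(self, panel_sim, panel_config):
        panel, archaic, _ = panel_sim
        found = private_archaic_sites(panel, panel_config.outgroup_pop, archaic)
        out_idx = panel.haplotype_indices(panel_config.outgroup_pop)
        out_freq = panel.alleles[out_idx].mean(axis=0)
        polymorphic = np.flatnonzero((out_freq > 0) & (out_freq < 1))
        assert len(np.intersect1d(found, polymorphic)) == 0


class TestIntrogressionSegment:
    def test_perfect_ld_spans_all_sites(self):
        column = [1, 1, 0, 0, 1, 0]
        panel = tiny_panel([column] * 5, positions=[10, 20, 30, 40, 50])
        segment = introgression_segment(panel, 2)
        assert segment.start_bp == 10 and segment.end_bp == 50
        assert segment.member_sites.tolist() == [0, 1, 2, 3, 4]

    def test_impossible_threshold_gives_focal_alone(self):
        column = [1, 1, 0, 0, 1, 0]
        panel = tiny_panel([column] * 5)
        segment = introgression_segment(panel, 2, r2_threshold=1.01)
        assert segment.member_sites.tolist() == [2]
        assert segment.length_bp == 0

    def test_monomorphic_focal_rejected(self):
        panel = tiny_panel([[0, 0, 0, 0], [1, 0, 1, 0]])
        with pytest.raises(MonomorphicSiteError):
            introgression_segment(panel, 0)

    def test_recovers_planted_segment(self, panel_sim, panel_config):
        panel, archaic, truth = panel_sim
        private = sorted(truth.private_site_indices)
        focal = private[len(private) // 2]
        segment = introgression_segment(panel, focal, private_sites=private)
        lo, hi = truth.segment_bounds_bp
        members = segment.member_sites
        assert set(private) <= set(members.tolist())
        assert np.all(panel.positions[members] >= lo)
        assert np.all(panel.positions[members] < hi)
        assert segment.n_private == len(private)

    def test_threshold_monotonicity(self, panel_sim):
        panel, _, truth = panel_sim
        focal = sorted(truth.private_site_indices)[14]
        lengths = [
            len(introgression_segment(panel, focal, r2_threshold=t).member_sites)
            for t in (0.2, 0.5, 0.8, 0.95)
        ]
        assert lengths == sorted(lengths, reverse=True)


class TestArchaicMatchMatrix:
    def _simple_inputs(self):
        pops = {f"h{i}": "OUT" if i < 4 else "POP" for i in range(8)}
        # site 0: archaic allele absent in outgroup, carriers fixed for it
        # site 1: archaic dosage below threshold
        panel = tiny_panel(
            [[0, 0, 0, 0, 1, 1, 0, 0], [0, 0, 0, 0, 1, 0, 0, 0]], pops=pops
        )
        archaic = ArchaicGenotypes(["n1", "n2"], np.array([[2.0, 1.0], [2.0, 1.0]]))
        return panel, archaic

    def test_fixed_carrier_subset_matches(self):
        panel, archaic = self._simple_inputs()
        table = archaic_match_matrix(panel, [4, 5], [6, 7], "OUT", archaic)
        site0 = table[(table.site == 0) & (table.subset == "carrier")]
        assert site0.status.tolist() == ["match"]

    def test_low_dosage_site_not_selected(self):
        panel, archaic = self._simple_inputs()
        table = archaic_match_matrix(panel, [4, 5], [6, 7], "OUT", archaic, min_archaic_count=3)
        assert 1 not in set(table.site)

    def test_exact_tie_reported(self):
        pops = {f"h{i}": "OUT" if i < 4 else "POP" for i in range(8)}
        panel = tiny_panel([[0, 0, 0, 0, 1, 1, 0, 0]], pops=pops)
        archaic = ArchaicGenotypes(["n1", "n2"], np.array([[2.0], [2.0]]))
        table = archaic_match_matrix(panel, [4, 5, 6, 7], [6, 7], "OUT", archaic)
        carrier = table[table.subset == "carrier"]
        assert carrier.status.tolist() == ["tie"]

    def test_empty_subsets_rejected(self):
        panel, archaic = self._simple_inputs()
        with pytest.raises(ValueError):
            archaic_match_matrix(panel, [], [6, 7], "OUT", archaic)

    def test_recovers_planted_private_sites(self, panel_sim, panel_config):
        panel, archaic, truth = panel_sim
        carriers = sorted(truth.alu_carrier_haplotype_ids)
        noncarriers = sorted(
            truth.introgressed_haplotype_ids - truth.alu_carrier_haplotype_ids
        )
        table = archaic_match_matrix(
            panel, carriers, noncarriers, panel_config.outgroup_pop, archaic
        )
        selected = set(table.site)
        assert truth.private_site_indices <= selected
        private_rows = table[table.site.isin(truth.private_site_indices)]
        assert (private_rows.status == "match").all()
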