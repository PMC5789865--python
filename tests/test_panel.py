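"""Panel curation: inclusion criteria, population transfer, LD pruning, TSV round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poprisk import (DiseasePanel, InclusionThresholds, SnpMarker,
                     filter_by_discovery_criteria, ld_prune, load_panels_tsv,
                     transform_panel, write_panels_tsv)
from tests.conftest import make_marker


class TestMarkerValidation:
    def test_rejects_nonpositive_or(self):
        with pytest.raises(ValueError, match="positive"):
            make_marker(orx=0.0)

    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError, match="identical"):
            make_marker(risk_allele="A", other_allele="A")

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError):
            make_marker(p=0.0)

    def test_panel_rejects_duplicate_rsids(self):
        with pytest.raises(ValueError, match="duplicate"):
            DiseasePanel("d", [make_marker("rs1"), make_marker("rs1")])


class TestInclusionCriteria:
    def test_genome_wide_significant_discovery_retained(self):
        m = make_marker(p=5e-8, study_type="gwas_discovery")
        assert filter_by_discovery_criteria([m]) == [m]

    def test_empty_input(self):
        assert filter_by_discovery_criteria([]) == []

    @pytest.mark.parametrize(
        "marker_kw, expected",
        [
            # discovery-only GWAS at 1e-6 misses the 1e-7 gate
            (dict(p=1e-6, study_type="gwas_discovery"), False),
            # the same P with a significant replication passes the replication route
            (dict(p=1e-6, study_type="gwas_with_replication", p_replication=0.01), False),
            (dict(p=9e-7, study_type="gwas_with_replication", p_replication=0.01), True),
            (dict(p=1e-6, study_type="gwas_with_replication", p_replication=0.06), False),
            (dict(p=0.04, study_type="candidate_snp"), True),
            (dict(p=0.05, study_type="candidate_snp"), False),
            (dict(p=1e-8, study_type="gwas_discovery"), True),
            (dict(p=1e-7, study_type="gwas_discovery"), False),  # strict threshold
        ],
    )
    def test_three_routes(self, marker_kw, expected):
        m = make_marker(**marker_kw)
        assert (filter_by_discovery_criteria([m]) == [m]) is expected

    def test_relaxed_gate_for_endometrial_panels(self):
        m = make_marker(p=5e-6, study_type="gwas_discovery")
        assert filter_by_discovery_criteria([m]) == []
        assert filter_by_discovery_criteria([m], endometrial_exception=True) == [m]

    def test_missing_replication_p_rejected_not_crashed(self, caplog):
        m = make_marker(p=1e-8, study_type="gwas_with_replication", p_replication=None)
        with caplog.at_level("WARNING"):
            assert filter_by_discovery_criteria([m]) == []
        assert "p_replication" in caplog.text

    def test_mixed_example_first_dropped_second_retained(self):
        weak = make_marker("rsA", p=1e-6, study_type="gwas_discovery")
        replicated = make_marker("rsB", p=9.9e-7, study_type="gwas_with_replication",
                                 p_replication=0.01)
        kept = filter_by_discovery_criteria([weak, replicated])
        assert [m.rsid for m in kept] == ["rsB"]

    def test_order_preserved(self):
        ms = [make_marker(f"rs{i}", p=1e-9) for i in range(5)]
        assert filter_by_discovery_criteria(ms) == ms

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["gwas_discovery", "gwas_with_replication", "candidate_snp"]),
                st.floats(1e-12, 1.0),
                st.one_of(st.none(), st.floats(1e-6, 1.0)),
            ),
            max_size=20,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_idempotent(self, specs):
        markers = [
            make_marker(f"rs{i}", p=p, study_type=t, p_replication=pr)
            for i, (t, p, pr) in enumerate(specs)
        ]
        once = filter_by_discovery_criteria(markers)
        assert filter_by_discovery_criteria(once) == once


class TestPanelTransfer:
    def test_rule_by_rule(self):
        panel = DiseasePanel("d", [
            make_marker("rs1", orx=1.5, east_asian_status="validated"),
            make_marker("rs2", orx=1.4, east_asian_status="tested_null"),
            make_marker("rs3", orx=1.3, east_asian_status="untested"),
        ])
        ea = [
            make_marker("rs1", orx=1.8, discovery_population="han_chinese",
                        east_asian_status="validated"),
            make_marker("rs9", orx=2.0, discovery_population="han_chinese",
                        east_asian_status="east_asian_discovered"),
        ]
        out = transform_panel(panel, ea)
        assert out.rsids == ["rs1", "rs3", "rs9"]
        by = {m.rsid: m for m in out.markers}
        assert by["rs1"].or_per_allele == 1.8   # East-Asian OR adopted
        assert by["rs3"].or_per_allele == 1.3   # original OR carried over
        assert by["rs9"].or_per_allele == 2.0   # appended discovery

    def test_all_untested_is_identity(self):
        panel = DiseasePanel("d", [make_marker("rs1"), make_marker("rs2")])
        assert transform_panel(panel, []).rsids == panel.rsids

    def test_validated_without_ea_entry_errors(self):
        panel = DiseasePanel("d", [make_marker("rs1", east_asian_status="validated")])
        with pytest.raises(ValueError, match="rs1"):
            transform_panel(panel, [])

    def test_appended_rsid_collision_errors(self):
        panel = DiseasePanel("d", [make_marker("rs1")])
        ea = [make_marker("rs1", east_asian_status="east_asian_discovered")]
        with pytest.raises(ValueError, match="collides"):
            transform_panel(panel, ea)

    def test_count_never_drops_by_more_than_tested_null(self):
        panel = DiseasePanel("d", [
            make_marker("rs1", east_asian_status="tested_null"),
            make_marker("rs2", east_asian_status="tested_null"),
            make_marker("rs3", east_asian_status="untested"),
        ])
        out = transform_panel(panel, [])
        assert len(panel) - len(out) <= 2


class TestLdPrune:
    def test_pair_keeps_smaller_p(self):
        panel = DiseasePanel("d", [
            make_marker("rsA", p=1e-7), make_marker("rsB", p=1e-9),
        ])
        r2 = np.array([[1.0, 0.9], [0.9, 1.0]])
        assert ld_prune(panel, r2).rsids == ["rsB"]

    def test_uncorrelated_panel_unchanged(self):
        panel = DiseasePanel("d", [make_marker(f"rs{i}", p=1e-9) for i in range(4)])
        assert ld_prune(panel, np.eye(4)).rsids == panel.rsids

    def test_mutually_correlated_triple_keeps_best(self):
        panel = DiseasePanel("d", [
            make_marker("rsA", p=1e-8), make_marker("rsB", p=1e-10),
            make_marker("rsC", p=1e-9),
        ])
        r2 = np.ones((3, 3))
        assert ld_prune(panel, r2).rsids == ["rsB"]

    def test_dimension_mismatch_errors(self):
        panel = DiseasePanel("d", [make_marker("rsA")])
        with pytest.raises(ValueError, match="shape"):
            ld_prune(panel, np.eye(2))

    def test_out_of_range_r2_errors(self):
        panel = DiseasePanel("d", [make_marker("rsA"), make_marker("rsB")])
        r2 = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ld_prune(panel, r2)

    @given(st.integers(2, 8), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50)
    def test_no_surviving_pair_at_or_above_threshold(self, m, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 1, size=(m, m))
        r2 = (base + base.T) / 2
        np.fill_diagonal(r2, 1.0)
        panel = DiseasePanel("d", [
            make_marker(f"rs{i}", p=float(rng.uniform(1e-10, 1e-8))) for i in range(m)
        ])
        pruned = ld_prune(panel, r2, threshold=0.8)
        idx = [panel.rsids.index(r) for r in pruned.rsids]
        for a in idx:
            for b in idx:
                if a != b:
                    assert r2[a, b] < 0.8


class TestPanelTsv:
    def test_round_trip_and_duplicate_resolution(self, tmp_path, small_panel):
        path = tmp_path / "panels.tsv"
        write_panels_tsv({"trait": small_panel}, path)
        loaded = load_panels_tsv(path)
        assert loaded["trait"].rsids == small_panel.rsids
        orig = {m.rsid: m.or_per_allele for m in small_panel.markers}
        assert {m.rsid: m.or_per_allele for m in loaded["trait"].markers} == orig
        # duplicate rsid: the larger study wins
        lines = path.read_text().rstrip().splitlines()
        dup = lines[1].split("\t")
        dup[6] = "9.9"       # odds ratio of the duplicate row
        dup[11] = "99000"    # n_cases much larger
        path.write_text("\n".join(lines + ["\t".join(dup)]) + "\n")
        reloaded = load_panels_tsv(path)
        assert reloaded["trait"].markers[0].or_per_allele == 9.9
        assert len(reloaded["trait"]) == len(small_panel)
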