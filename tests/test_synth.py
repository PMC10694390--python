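"""Generator contracts: determinism, planted structure, conservation."""

import numpy as np
import pandas as pd
import pytest

from sevscape import pairdiff
from sevscape.containers import CellTypeReference, GroundTruth
from sevscape.synth import (
    ConfigurationError,
    SimulationConfig,
    expected_sev_shares,
    simulate_diagnostic_cohort,
    simulate_paired_cohort,
    simulate_reference,
    simulate_tissue_bulk,
    subset_by_source,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,fragment",
        [
            ({"n_genes": 0}, "n_genes"),
            ({"n_lost": 400, "n_tumor_up": 300}, "n_lost"),
            ({"frac_caf_expressed": 1.5}, "frac_caf_expressed"),
            ({"n_clusters": 10, "markers_per_cluster": 300}, "markers_per_cluster"),
            ({"release_rates": [1.0, 2.0]}, "release_rates"),
            ({"n_cases": 1}, "n_cases"),
        ],
    )
    def test_invalid_configs_name_the_violated_invariant(self, kwargs, fragment):
        with pytest.raises(ConfigurationError, match=fragment):
            SimulationConfig(**kwargs).validate()


class TestSimulateReference:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=7, n_genes=200, cells_per_cluster=20)
        a = simulate_reference(cfg)
        b = simulate_reference(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[2].profiles, b[2].profiles)

    def test_single_cluster_gets_full_cell_share(self):
        cfg = SimulationConfig(
            n_clusters=1, markers_per_cluster=10, n_genes=100,
            cells_per_cluster=10, seed=1, n_immune_clusters=0,
        )
        _, _, ref, truth = simulate_reference(cfg)
        shares = expected_sev_shares(ref, truth)
        assert shares[ref.clusters[0]] == pytest.approx(1.0)

    def test_markers_stand_out_eightfold_in_their_cluster(self):
        cfg = SimulationConfig(seed=3, n_clusters=4, markers_per_cluster=50)
        sc, labels, ref, _ = simulate_reference(cfg)
        cpm = sc.div(sc.sum(axis=1), axis=0) * 1e6
        ok = 0
        total = 0
        for c in ref.clusters:
            spec = ref.profiles[c] / ref.profiles.drop(columns=c).mean(axis=1)
            markers = spec.sort_values(ascending=False).index[:50]
            own = cpm[labels == c].mean(axis=0)
            other = cpm[labels != c].mean(axis=0)
            ratio = own[markers] / other[markers]
            ok += (ratio >= 8).sum()
            total += len(markers)
        assert ok / total >= 0.95

    def test_immune_flags_cover_configured_clusters(self):
        cfg = SimulationConfig(seed=0, n_immune_clusters=2)
        _, _, ref, _ = simulate_reference(cfg)
        assert sum(ref.immune.values()) == 2


class TestSimulateTissueBulk:
    def _uniform_reference(self, k=3, genes=50):
        idx = [f"g{i}" for i in range(genes)]
        prof = pd.DataFrame(
            np.full((genes, k), 1e6 / genes), index=idx,
            columns=[f"c{j}" for j in range(k)],
        )
        return CellTypeReference(
            profiles=prof,
            cell_counts={f"c{j}": 100 for j in range(k)},
            immune={f"c{j}": False for j in range(k)},
        )

    def test_symmetric_configuration_gives_uniform_shares(self):
        ref = self._uniform_reference()
        truth = GroundTruth(
            cluster_release_rates={c: 2.0 for c in ref.clusters},
            cluster_cell_counts=dict(ref.cell_counts),
        )
        _, truth2 = simulate_tissue_bulk(ref, truth, depth=100_000, seed=1)
        for v in truth2.expected_sev_shares.values():
            assert v == pytest.approx(1 / 3)

    def test_zero_release_rate_zeroes_that_share(self):
        ref = self._uniform_reference()
        truth = GroundTruth(
            cluster_release_rates={"c0": 0.0, "c1": 1.0, "c2": 1.0},
            cluster_cell_counts=dict(ref.cell_counts),
        )
        _, truth2 = simulate_tissue_bulk(ref, truth, depth=100_000, seed=1)
        assert truth2.expected_sev_shares["c0"] == pytest.approx(0.0)

    def test_cluster_mismatch_raises_key_error(self):
        ref = self._uniform_reference()
        truth = GroundTruth(
            cluster_release_rates={"x": 1.0},
            cluster_cell_counts={"x": 5},
        )
        with pytest.raises(KeyError):
            simulate_tissue_bulk(ref, truth, depth=1000, seed=0)

    def test_monte_carlo_attribution_matches_closed_form(self):
        """Disjoint-support reference: n=(100,200,700), r=(5,1,1).

        With each gene expressed in exactly one cluster, the specificity
        attribution is exact, so the Monte-Carlo average of attributed
        shares over replicates must match n_k·r_k/Σ within ±0.02.
        """
        from sevscape.sourcetrace import attribute_abundance, signature_from_reference

        genes = [f"g{i}" for i in range(90)]
        prof = np.zeros((90, 3))
        for j in range(3):
            prof[j * 30 : (j + 1) * 30, j] = 1e6 / 30
        ref = CellTypeReference(
            profiles=pd.DataFrame(prof, index=genes, columns=["c0", "c1", "c2"]),
            cell_counts={"c0": 100, "c1": 200, "c2": 700},
            immune={c: False for c in ("c0", "c1", "c2")},
        )
        truth = GroundTruth(
            cluster_release_rates={"c0": 5.0, "c1": 1.0, "c2": 1.0},
            cluster_cell_counts=dict(ref.cell_counts),
        )
        sig = signature_from_reference(ref, m=10)
        w = np.array([100 * 5, 200 * 1, 700 * 1], dtype=float)
        expected = w / w.sum()
        shares = []
        for rep in range(200):
            bulk_m, _ = simulate_tissue_bulk(ref, truth, depth=50_000, seed=1000 + rep)
            att = attribute_abundance(
                bulk_m.values["bulk"], sig, ref.cell_counts
            )
            shares.append(att.per_cluster["sev_pct"].to_numpy())
        mc = np.mean(shares, axis=0)
        assert np.abs(mc - expected).max() < 0.02


class TestSimulatePairedCohort:
    def test_counts_are_nonnegative_integers(self, cohort_bundle):
        cohort, _ = cohort_bundle
        arr = cohort.values.to_numpy()
        assert (arr >= 0).all()
        assert np.issubdtype(arr.dtype, np.integer)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(
            seed=9, n_genes=200, n_patients=2, library_size=50_000,
            markers_per_cluster=10, n_tumor_up=30, n_lost=5,
        )
        a, _ = simulate_paired_cohort(cfg)
        b, _ = simulate_paired_cohort(cfg)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_all_sources_present_per_patient(self, cohort_bundle):
        cohort, _ = cohort_bundle
        for i in range(7):
            for src in ("T", "N", "O", "B"):
                assert len(cohort.samples_for(f"P{i+1}", src)) == 1
        assert len(subset_by_source(cohort, "CAF").sample_ids) == 4

    def test_null_simulation_yields_empty_signature(self):
        """No planted effect: the majority-vote signature is noise only."""
        cfg = SimulationConfig(
            seed=13, tumor_effect_log2fc=0.0, n_tumor_up=0, n_lost=0,
        )
        cohort, truth = simulate_paired_cohort(cfg)
        assert truth.tumor_up_genes == set()
        results = [
            pairdiff.per_patient_contrast(cohort, f"P{i+1}", "T", "N")
            for i in range(7)
        ]
        sig = pairdiff.majority_vote(results, 4)
        assert len(sig.members) < 0.01 * cfg.n_genes

    def test_no_lost_genes_when_n_lost_zero(self):
        cfg = SimulationConfig(seed=4, n_lost=0, n_genes=500, library_size=200_000)
        _, truth = simulate_paired_cohort(cfg)
        assert truth.lost_genes == set()


class TestSimulateDiagnosticCohort:
    def test_cohort_shape_matches_defaults(self):
        cfg = SimulationConfig(seed=2, n_genes=100, markers_per_cluster=10)
        m, truth = simulate_diagnostic_cohort(cfg)
        groups = [md.group for md in m.metadata.values()]
        assert groups.count("case") == 140 and groups.count("control") == 118
        assert len(truth.diagnostic_markers) == cfg.n_diagnostic_markers

    def test_null_effect_aucs_center_at_half(self):
        from scipy.stats import rankdata

        cfg = SimulationConfig(
            seed=21, marker_effect_log2fc=0.0, n_cases=100, n_controls=100,
            n_genes=500,
        )
        m, _ = simulate_diagnostic_cohort(cfg)
        y = np.array([1 if md.group == "case" else 0 for md in m.metadata.values()])
        cpm = m.cpm().to_numpy()
        n1, n0 = y.sum(), len(y) - y.sum()
        aucs = []
        for g in range(cpm.shape[0]):
            r = rankdata(cpm[g])
            aucs.append((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_huge_single_marker_effect_gives_perfect_auc(self):
        from sevscape.diagpanel import roc_auc

        cfg = SimulationConfig(
            seed=5, marker_effect_log2fc=10.0, n_diagnostic_markers=1,
            n_cases=30, n_controls=30, n_genes=200, diag_biological_sigma=0.1,
            nb_dispersion=500.0,
        )
        m, truth = simulate_diagnostic_cohort(cfg)
        g = next(iter(truth.diagnostic_markers))
        y = [1 if m.metadata[s].group == "case" else 0 for s in m.sample_ids]
        auc, _, _ = roc_auc(m.cpm().loc[g].to_numpy(), y)
        assert auc == 1.0
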