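"""Ion-count phenotyping: transform, clustering, gating, matching, enrichment."""

import numpy as np
import pandas as pd
import pytest

from picscan.errors import ConfigurationError, ValidationError
from picscan.phenotype import (GATE_MARKERS, GateConfig, PhenoSimConfig,
                               contact_cluster_table, derive_gate_thresholds,
                               differential_marker, gate_immune_subtype,
                               generate_phenotype_matrix, hierarchical_cluster,
                               log_transform, match_coordinates)


class TestLogTransform:
    def test_anchor_values(self):
        assert log_transform(np.array([0.0]))[0] == 0.0
        assert log_transform(np.array([np.e - 1]))[0] == pytest.approx(1.0)

    def test_round_trip(self, rng):
        raw = rng.integers(0, 500, size=(20, 4)).astype(float)
        back = np.expm1(log_transform(raw))
        np.testing.assert_allclose(back, raw, rtol=1e-12, atol=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            log_transform(np.array([-1.0]))

    def test_variance_stabilization_on_nb_counts(self, rng):
        mean, size = 50.0, 2.0  # overdispersed
        draws = rng.negative_binomial(size, size / (size + mean), 10_000).astype(float)
        raw_cv = draws.std() / draws.mean()
        logged = log_transform(draws)
        log_cv = logged.std() / logged.mean()
        assert log_cv < raw_cv


class TestHierarchicalCluster:
    def _blobs(self, rng, n1=30, n2=30, sep=10.0):
        x1 = rng.normal(0.0, 1.0, size=(n1, 4))
        x2 = rng.normal(sep, 1.0, size=(n2, 4))
        df = pd.DataFrame(np.vstack([x1, x2]),
                          columns=["CD3", "CD4", "CD45", "CK"])
        truth = np.array([1] * n1 + [2] * n2)
        return df, truth

    def test_separated_blobs_ari_one(self, rng):
        from sklearn.metrics import adjusted_rand_score
        df, truth = self._blobs(rng)
        labels = hierarchical_cluster(df, k=2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_one_single_cluster(self, rng):
        df, _ = self._blobs(rng)
        assert set(hierarchical_cluster(df, k=1)) == {1}

    def test_k_exceeding_rows_rejected(self, rng):
        df, _ = self._blobs(rng, n1=2, n2=2)
        with pytest.raises(ValidationError):
            hierarchical_cluster(df, k=5)

    def test_cluster_one_is_cd4_t_like(self, rng):
        df, truth = self._blobs(rng)
        # the high-CD3/CD4 blob is the second one here
        labels = hierarchical_cluster(df, k=2)
        high = labels[truth == 2]
        assert (high == 1).all()

    def test_duplicating_rows_preserves_assignment(self, rng):
        df, _ = self._blobs(rng, n1=10, n2=10)
        base = hierarchical_cluster(df, k=2)
        doubled = pd.concat([df, df], ignore_index=True)
        again = hierarchical_cluster(doubled, k=2)[: len(df)]
        np.testing.assert_array_equal(base, again)


class TestGating:
    def _row(self, **counts):
        base = {m: 0.0 for m in GATE_MARKERS}
        base.update(counts)
        return pd.Series({m: np.log1p(v) for m, v in base.items()})

    def test_cd4_t_cell_pattern(self):
        row = self._row(CD45=60, CD3=45, CD4=30, CD8a=2)
        assert gate_immune_subtype(row) == "cd4_t"

    def test_all_zero_is_non_immune(self):
        assert gate_immune_subtype(self._row()) == "non_immune"

    def test_double_positive_goes_cd8(self):
        row = self._row(CD45=60, CD3=45, CD4=30, CD8a=30)
        assert gate_immune_subtype(row) == "cd8_t"

    @pytest.mark.parametrize("counts,expect", [
        (dict(CD45=60, CD3=40, CD8a=30), "cd8_t"),
        (dict(CD45=60, CD20=30), "b_cell"),
        (dict(CD45=60, CD56=30), "nk"),
        (dict(CD45=60, CD14=30), "monocyte_macrophage"),
        (dict(CD45=60, CD68=30), "monocyte_macrophage"),
        (dict(CD45=60), "unclassified"),
    ])
    def test_branches(self, counts, expect):
        assert gate_immune_subtype(self._row(**counts)) == expect

    def test_missing_marker_errors(self):
        row = self._row().drop("CD56")
        with pytest.raises(ConfigurationError):
            gate_immune_subtype(row)

    def test_invariance_under_monotone_rescaling(self):
        rows = [self._row(CD45=60, CD3=45, CD4=30),
                self._row(CD45=60, CD20=30),
                self._row()]
        gate = GateConfig()
        scaled_gate = GateConfig(
            thresholds={m: 3.0 * t + 1.0 for m, t in gate.thresholds.items()})
        for row in rows:
            scaled_row = 3.0 * row + 1.0
            assert (gate_immune_subtype(row, gate)
                    == gate_immune_subtype(scaled_row, scaled_gate))

    def test_derived_midpoint_thresholds(self, rng):
        cfg = PhenoSimConfig()
        df = generate_phenotype_matrix(cfg, seed=3)
        markers = list(cfg.cd4_means)
        logm = log_transform(df[markers])
        labels = hierarchical_cluster(logm, k=2)
        gate = derive_gate_thresholds(logm, labels)
        assert set(gate.thresholds) == set(markers)
        # CD45 separates the clusters; its midpoint sits between class means
        lo = logm["CD45"][labels == 2].mean()
        hi = logm["CD45"][labels == 1].mean()
        assert lo < gate.thresholds["CD45"] < hi


class TestMatchCoordinates:
    def _frames(self, rng, n=40, jitter=1.0):
        ev = pd.DataFrame({
            "id": np.arange(n),
            "x_um": rng.uniform(0, 1000, n),
            "y_um": rng.uniform(0, 1000, n),
        })
        roi = ev.copy()
        roi["x_um"] += rng.normal(0, jitter, n)
        roi["y_um"] += rng.normal(0, jitter, n)
        return ev, roi

    def test_full_match_under_small_jitter(self, rng):
        ev, roi = self._frames(rng)
        matched = match_coordinates(ev, roi, tolerance_um=5.0)
        assert len(matched) == len(ev)
        assert (matched["event_id"].to_numpy()
                == matched["roi_id"].to_numpy()).mean() > 0.95

    def test_empty_roi_set(self):
        ev = pd.DataFrame({"id": [1], "x_um": [0.0], "y_um": [0.0]})
        roi = pd.DataFrame(columns=["id", "x_um", "y_um"])
        assert len(match_coordinates(ev, roi, tolerance_um=5.0)) == 0

    def test_equidistant_tie_goes_to_lowest_id(self):
        ev = pd.DataFrame({"id": [7, 3], "x_um": [0.0, 2.0], "y_um": [0.0, 0.0]})
        roi = pd.DataFrame({"id": [1], "x_um": [1.0], "y_um": [0.0]})
        matched = match_coordinates(ev, roi, tolerance_um=5.0)
        assert len(matched) == 1
        assert matched.iloc[0]["event_id"] == 3

    def test_each_roi_matched_once(self, rng):
        ev = pd.DataFrame({"id": [0, 1], "x_um": [0.0, 0.5], "y_um": [0.0, 0.0]})
        roi = pd.DataFrame({"id": [0], "x_um": [0.1], "y_um": [0.0]})
        matched = match_coordinates(ev, roi, tolerance_um=5.0)
        assert len(matched) == 1

    def test_affine_transform_applied(self):
        ev = pd.DataFrame({"id": [0], "x_um": [10.0], "y_um": [20.0]})
        roi = pd.DataFrame({"id": [0], "x_um": [110.0], "y_um": [120.0]})
        shift = lambda x, y: (x + 100.0, y + 100.0)  # noqa: E731
        assert len(match_coordinates(ev, roi, 1.0, transform=shift)) == 1


class TestDifferentialMarker:
    def test_identical_groups_p_one(self):
        g = pd.DataFrame({"HLA-DR": [1.0, 1.0, 1.0]})
        comp, dmed = differential_marker(g, g.copy(), "HLA-DR")
        assert comp.p == 1.0
        assert dmed == 0.0

    def test_power_for_twofold_shift(self, rng):
        """A planted 2x shift at n=30/30 reaches p<0.01 in >=90% of runs."""
        hits = 0
        shifts = []
        for _ in range(100):
            a = np.log1p(rng.negative_binomial(5, 5 / (5 + 40.0), 30).astype(float))
            b = np.log1p(rng.negative_binomial(5, 5 / (5 + 20.0), 30).astype(float))
            ga = pd.DataFrame({"HLA-DR": a})
            gb = pd.DataFrame({"HLA-DR": b})
            comp, dmed = differential_marker(ga, gb, "HLA-DR")
            hits += comp.p < 0.01
            shifts.append(dmed)
        assert hits >= 90
        # median log shift recovered within 20 % of log(2) expectation
        assert np.mean(shifts) == pytest.approx(np.log(2.0), rel=0.2)


class TestGeneratorAndEnrichment:
    def test_generator_is_seed_deterministic(self):
        a = generate_phenotype_matrix(seed=9)
        b = generate_phenotype_matrix(seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_group_sizes_default(self):
        df = generate_phenotype_matrix(seed=0)
        assert int(df["contact"].sum()) == 42
        assert int((~df["contact"]).sum()) == 143

    def test_contingency_margins(self):
        df = generate_phenotype_matrix(seed=1)
        markers = list(PhenoSimConfig().cd4_means)
        labels = hierarchical_cluster(log_transform(df[markers]), k=2)
        table = contact_cluster_table(df["contact"], labels)
        assert table.sum() == len(df)
        assert table[0].sum() == 42
        assert table[1].sum() == 143
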