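import numpy as np
import pytest

from synkit import (
    ColorPoint,
    ValidationSpec,
    dbscan_labels,
    preset,
    twcv,
    validate_group,
    validate_participant,
)
from synkit.errors import ConfigError
from synkit.model_io import Grapheme, Participant, ParticipantGroup
from synkit.synthdata import ArchetypeParams, gen_group, gen_participant

from .oracles import brute_dbscan, brute_twcv


def _labels_to_partition(labels):
    """(core+border cluster partition ignored) -> per-cluster index sets."""
    clusters = {}
    for i, lab in enumerate(labels):
        if lab >= 0:
            clusters.setdefault(lab, set()).add(i)
    return clusters


class TestDbscanLabels:
    def test_identical_points_one_cluster(self):
        pts = np.zeros((5, 3))
        labeling = dbscan_labels(pts, eps=1.0, min_pts=3)
        assert labeling.num_clusters == 1
        assert labeling.noise_count == 0

    def test_isolated_points_all_noise(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float)
        labeling = dbscan_labels(pts, eps=1.0, min_pts=2)
        assert labeling.num_clusters == 0
        assert labeling.noise_count == 3

    def test_empty_input(self):
        labeling = dbscan_labels(np.empty((0, 3)), eps=1.0, min_pts=3)
        assert labeling.labels.size == 0
        assert labeling.num_clusters == 0

    def test_inclusive_eps_radius(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        labeling = dbscan_labels(pts, eps=1.0, min_pts=2)
        assert labeling.num_clusters == 1

    def test_accepts_color_points(self):
        pts = [ColorPoint((0, 0, 0), "Luv")] * 4
        assert dbscan_labels(pts, eps=1.0, min_pts=3).num_clusters == 1

    def test_matches_bruteforce_oracle_randomized(self, rng):
        """Core-point partition and noise set match exhaustive DBSCAN."""
        for _ in range(60):
            n = int(rng.integers(5, 50))
            pts = rng.random((n, 3)) * 10
            eps = float(rng.uniform(0.5, 4.0))
            min_pts = int(rng.integers(2, 6))
            labeling = dbscan_labels(pts, eps, min_pts)

            oracle_cores, oracle_noise = brute_dbscan(pts, eps, min_pts)
            assert labeling.num_clusters == len(oracle_cores)
            noise = frozenset(np.flatnonzero(labeling.labels == -1).tolist())
            assert noise == oracle_noise
            # every oracle core-component maps into exactly one cluster
            clusters = _labels_to_partition(labeling.labels)
            for component in oracle_cores:
                owning = {labeling.labels[i] for i in component}
                assert len(owning) == 1
                assert owning.pop() in clusters

    def test_enlarging_eps_never_adds_noise(self, rng):
        pts = rng.random((40, 3)) * 10
        noise_counts = [
            dbscan_labels(pts, eps, 4).noise_count for eps in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert noise_counts == sorted(noise_counts, reverse=True)


class TestTwcv:
    def test_identical_cluster_zero(self):
        pts = np.ones((4, 3))
        assert twcv(pts, np.zeros(4, dtype=int)) == pytest.approx(0.0)

    def test_two_point_cluster(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert twcv(pts, np.array([0, 0])) == pytest.approx(1.0)

    def test_noise_excluded(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0], [100.0, 0, 0]])
        assert twcv(pts, np.array([0, 0, -1])) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 50))
            pts = rng.random((n, 3)) * 100
            labeling = dbscan_labels(pts, float(rng.uniform(5, 30)), 3)
            assert twcv(pts, labeling) == pytest.approx(
                brute_twcv(pts, labeling.labels), abs=1e-9
            )

    def test_translation_invariance_and_quadratic_scaling(self, rng):
        pts = rng.random((30, 3)) * 50
        labels = rng.integers(-1, 3, size=30)
        base = twcv(pts, labels)
        assert twcv(pts + 1234.5, labels) == pytest.approx(base, rel=1e-9)
        assert twcv(pts * 3.0, labels) == pytest.approx(9.0 * base, rel=1e-9)


def _uniform_participant(hex_free_color, n_graphemes=6):
    graphemes = tuple(
        Grapheme(f"S{i}", (ColorPoint(hex_free_color, "sRGB"),) * 3)
        for i in range(n_graphemes)
    )
    return Participant("mono", graphemes)


class TestValidateParticipant:
    SPEC = ValidationSpec(min_complete_graphemes=4, min_pts=4)

    def test_single_color_dominant_cluster(self):
        res = validate_participant(_uniform_participant((0.8, 0.1, 0.1)), self.SPEC)
        assert not res.valid
        assert res.reason == "dominant_color_cluster"
        assert res.prop_largest_cluster == pytest.approx(1.0)
        assert res.num_clusters == 1

    def test_too_few_complete_graphemes(self):
        graphemes = tuple(
            Grapheme(f"S{i}", (ColorPoint((0.5, 0.2, 0.9), "sRGB"),) * 2 + (None,))
            for i in range(6)
        ) + (Grapheme("C", (ColorPoint((0.5, 0.2, 0.9), "sRGB"),) * 3),)
        res = validate_participant(Participant("p", graphemes), self.SPEC)
        assert not res.valid
        assert res.reason == "too_few_complete_graphemes"
        assert res.num_complete_graphemes == 1
        assert res.twcv is None and res.prop_largest_cluster is None

    def test_well_separated_synesthete_valid(self):
        p = gen_participant(
            ArchetypeParams("synesthete", jitter_sd=0.01, seed=7)
        )
        res = validate_participant(p, ValidationSpec())
        assert res.valid and res.reason == "ok"
        assert res.num_clusters >= 3

    def test_empty_participant_edge(self):
        spec = ValidationSpec(min_complete_graphemes=0)
        res = validate_participant(Participant("empty", ()), spec)
        assert res.num_clusters == 0
        assert res.twcv == pytest.approx(0.0)
        assert not res.valid
        assert res.reason == "too_few_distinct_colors"

    def test_min_pts_above_point_count_all_noise(self):
        p = gen_participant(ArchetypeParams("random", n_symbols=2, seed=1))
        spec = ValidationSpec(min_complete_graphemes=1, min_pts=10)
        res = validate_participant(p, spec)
        assert res.num_clusters == 0


class TestValidateGroup:
    def test_row_per_participant_in_order(self):
        group, _ = gen_group(
            [(ArchetypeParams("synesthete"), 1), (ArchetypeParams("random"), 1)],
            seed=3,
        )
        table = validate_group(group, ValidationSpec())
        assert list(table["participant_id"]) == [p.id for p in group.participants]

    def test_empty_group(self):
        assert len(validate_group(ParticipantGroup((), "Luv"))) == 0

    def test_archetype_recovery_rates(self):
        group, truth = gen_group(
            [
                (ArchetypeParams("synesthete"), 40),
                (ArchetypeParams("single_color"), 40),
            ],
            seed=11,
        )
        table = validate_group(group, ValidationSpec())
        merged = table.merge(truth, on="participant_id")
        syn = merged[merged.archetype == "synesthete"]["valid"]
        mono = merged[merged.archetype == "single_color"]["valid"]
        assert syn.mean() >= 0.95
        assert (~mono).mean() >= 0.95


def test_presets():
    assert preset("default").max_prop_single_cluster == pytest.approx(0.8)
    assert preset("rater_strict").max_prop_single_cluster == pytest.approx(0.6)
    with pytest.raises(ConfigError):
        preset("nope")


def test_spec_field_validation():
    with pytest.raises(ConfigError):
        ValidationSpec(eps=0.0)
    with pytest.raises(ConfigError):
        ValidationSpec(min_pts=1)
    with pytest.raises(ConfigError):
        ValidationSpec(max_prop_single_cluster=0.0)
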