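"""Label-flip robustness and core-hydrophobicity analyses."""

import numpy as np
import pytest

import burialcode as bc
from burialcode.encodings import LabelSet
from burialcode.sasa import BurialVector

#: synthetic hydrophobicity scale so no literature values enter correctness
TOY_SCALE = bc.HydroScale(
    {t: (i % 7 - 3) / 3.0 for i, t in enumerate(
        ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
         "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"))},
    name="toy",
)


class TestFlipLabels:
    def test_p_zero_unchanged(self):
        bv = BurialVector(np.array([1, 0, 1, 0]))
        res = bc.flip_labels(bv, 0.0, seed=1)
        assert res.f_flip == 0.0
        np.testing.assert_array_equal(res.perturbed.labels, bv.labels)

    def test_p_one_all_flipped(self):
        bv = BurialVector(np.array([1, 0, 1, 1]))
        res = bc.flip_labels(bv, 1.0, seed=1)
        assert res.f_flip == 1.0
        np.testing.assert_array_equal(res.perturbed.labels, 1 - bv.labels)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_flip_fraction_binomial_statistics(self, p):
        n = 10_000
        bv = BurialVector(np.zeros(n, dtype=int))
        res = bc.flip_labels(bv, p, seed=42)
        assert abs(res.f_flip - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_seeded_reproducibility(self):
        bv = BurialVector(np.tile([1, 0], 50))
        a = bc.flip_labels(bv, 0.3, seed=5)
        b = bc.flip_labels(bv, 0.3, seed=5)
        np.testing.assert_array_equal(a.perturbed.labels, b.perturbed.labels)

    def test_composed_flip_fraction(self):
        """Two independent flips at p and q leave a net flip fraction of
        p(1-q) + q(1-p) in expectation."""
        n = 20_000
        p, q = 0.2, 0.3
        bv = BurialVector(np.zeros(n, dtype=int))
        once = bc.flip_labels(bv, p, seed=1)
        twice = bc.flip_labels(once.perturbed, q, seed=2)
        net = (twice.perturbed.labels != bv.labels).mean()
        expected = p * (1 - q) + q * (1 - p)
        assert abs(net - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            bc.flip_labels(BurialVector(np.array([0, 1])), 1.5)


class TestRobustnessCurve:
    def test_p_zero_reproduces_unperturbed_rho(self, benchmark):
        rows = bc.robustness_curve(benchmark, [0.0], n_repeats=2, seed=3,
                                   n_boot=300)
        from burialcode.similarity import phi_from_labels

        phis = []
        for t in benchmark.targets:
            nat = t.native_channels["burial"]
            for ls in t.decoy_channels["burial"]:
                phis.append(phi_from_labels(nat.labels, ls.labels, 2))
        direct = bc.flattened_spearman(np.array(phis), benchmark.all_lddt(),
                                       n_boot=300, seed=1)
        assert rows[0]["f_flip"] == 0.0
        assert rows[0]["rho"] == pytest.approx(direct, abs=0.03)

    def test_mean_flip_fraction_tracks_p(self, benchmark):
        rows = bc.robustness_curve(benchmark, [0.1, 0.4], n_repeats=6, seed=4,
                                   n_boot=200)
        for row in rows:
            assert row["f_flip"] == pytest.approx(row["p"], abs=0.08)


class TestExternalPredictorPoint:
    def test_perfect_prediction_zero_flips(self, benchmark):
        preds = [t.native_channels["burial"] for t in benchmark.targets]
        f_flip, rho = bc.external_predictor_point(benchmark, preds, n_boot=300)
        assert f_flip == 0.0
        assert rho > 0.5

    def test_planted_errors_counted_exactly(self, benchmark):
        preds = []
        k_planted = 0
        for t in benchmark.targets:
            labels = t.native_channels["burial"].labels.copy()
            labels[:2] = 1 - labels[:2]  # two planted errors per target
            k_planted += 2
            preds.append(LabelSet(labels, alphabet=(0, 1)))
        total = sum(t.n_residues for t in benchmark.targets)
        f_flip, _ = bc.external_predictor_point(benchmark, preds, n_boot=100)
        assert f_flip == pytest.approx(k_planted / total)

    def test_all_core_prediction_yields_defined_rho(self, benchmark):
        preds = [
            LabelSet(np.ones(t.n_residues, dtype=int), alphabet=(0, 1))
            for t in benchmark.targets
        ]
        f_flip, rho = bc.external_predictor_point(benchmark, preds, n_boot=100)
        assert np.isfinite(rho)
        assert 0.0 < f_flip < 1.0

    def test_length_mismatch_rejected(self, benchmark):
        preds = [LabelSet(np.zeros(3, dtype=int), alphabet=(0, 1))
                 for _ in benchmark.targets]
        with pytest.raises(ValueError):
            bc.external_predictor_point(benchmark, preds)


class TestCoreHydrophobicity:
    def test_all_surface_is_zero(self):
        bv = BurialVector(np.zeros(10, dtype=int))
        assert bc.core_hydrophobicity(bv, ["ALA"] * 10, TOY_SCALE) == 0.0

    def test_single_core_residue_one_term(self):
        labels = np.zeros(10, dtype=int)
        labels[4] = 1
        bv = BurialVector(labels)
        types = ["GLY"] * 10
        types[4] = "ILE"
        expected = TOY_SCALE["ILE"] / 10
        assert bc.core_hydrophobicity(bv, types, TOY_SCALE) == pytest.approx(expected)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(2)
        from burialcode.data import STANDARD_AA

        types = [STANDARD_AA[i] for i in rng.integers(0, 20, 30)]
        labels = rng.integers(0, 2, 30)
        bv = BurialVector(labels)
        expected = sum(TOY_SCALE[t] * b for t, b in zip(types, labels)) / 30
        assert bc.core_hydrophobicity(bv, types, TOY_SCALE) == pytest.approx(expected)

    def test_delta_antisymmetric(self):
        rng = np.random.default_rng(3)
        from burialcode.data import STANDARD_AA

        types = [STANDARD_AA[i] for i in rng.integers(0, 20, 25)]
        a = BurialVector(rng.integers(0, 2, 25))
        b = BurialVector(rng.integers(0, 2, 25))
        dab = bc.delta_core_hydrophobicity(a, b, types, TOY_SCALE)
        dba = bc.delta_core_hydrophobicity(b, a, types, TOY_SCALE)
        assert dab == pytest.approx(-dba)

    def test_extra_buried_hydrophobic_negative_sign(self):
        types = ["GLY"] * 5 + ["GLU"]
        native = BurialVector(np.array([0, 0, 0, 0, 0, 0]))
        model = BurialVector(np.array([0, 0, 0, 0, 0, 1]))  # buries a positive-h type
        assert TOY_SCALE["GLU"] > 0
        d = bc.delta_core_hydrophobicity(native, model, types, TOY_SCALE)
        assert d < 0

    def test_named_scales_cover_all_types(self):
        for name in ("eisenberg_consensus", "kyte_doolittle"):
            scale = bc.HydroScale.named(name)
            assert len(scale.values) == 20


class TestTypeRates:
    def test_always_surface_always_right(self):
        native = np.zeros(40, dtype=int)
        pred = np.zeros(40, dtype=int)
        rates = bc.type_rates(native, pred, ["SER"] * 40, TOY_SCALE)
        (row,) = rates
        assert row.p_core == 0.0 and row.entropy == 0.0 and row.accuracy == 1.0

    def test_half_core_one_bit(self):
        native = np.tile([0, 1], 20)
        pred = native.copy()
        (row,) = bc.type_rates(native, pred, ["LEU"] * 40, TOY_SCALE)
        assert row.entropy == pytest.approx(1.0)

    def test_quarter_core_entropy_closed_form(self):
        native = np.array([1, 0, 0, 0] * 10)
        (row,) = bc.type_rates(native, native, ["VAL"] * 40, TOY_SCALE)
        expected = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert row.entropy == pytest.approx(expected)

    def test_entropy_symmetric_and_maximal_at_half(self):
        from burialcode.perturb import _entropy_bits

        assert _entropy_bits(0.3) == pytest.approx(_entropy_bits(0.7))
        grid = np.linspace(0.01, 0.99, 99)
        values = [_entropy_bits(p) for p in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(0.5, abs=0.01)

    def test_accuracy_counts_mismatches(self):
        native = np.array([1, 1, 0, 0])
        pred = np.array([1, 0, 0, 1])
        (row,) = bc.type_rates(native, pred, ["PHE"] * 4, TOY_SCALE)
        assert row.accuracy == pytest.approx(0.5)
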