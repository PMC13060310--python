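"""Information accounting: iota/I bookkeeping, flattened bootstrap Spearman,
restraint subsampling and I* extraction."""

from dataclasses import dataclass, field

import numpy as np
import pytest

import burialcode as bc
from burialcode.encodings import LabelSet
from burialcode.info import CurvePoint, DegenerateCorrelationWarning


def binary(labels):
    return LabelSet(np.asarray(labels), alphabet=(0, 1))


@dataclass
class FakeTarget:
    """Minimal stand-in carrying exactly what subsampling consumes."""

    native_channels: dict
    decoy_channels: dict
    lddt: np.ndarray
    n_residues: int
    name: str = "fake"


@dataclass
class FakeBench:
    targets: list

    def all_lddt(self):
        return np.concatenate([t.lddt for t in self.targets])

    def native_label_sets(self, channel):
        return [t.native_channels[channel] for t in self.targets]


def balanced_bench(n=10_000, n_decoys=8, seed=0):
    """One target with a balanced binary native channel and decoys whose
    label agreement decays with an LDDT-like quality score."""
    rng = np.random.default_rng(seed)
    native = rng.permutation(np.repeat([0, 1], n // 2))
    lddt = np.linspace(0.12, 0.97, n_decoys)
    decoys = []
    for q in lddt:
        flip = rng.random(n) < (1 - q) * 0.5
        decoys.append(binary(np.where(flip, 1 - native, native)))
    return FakeBench([
        FakeTarget({"burial": binary(native)}, {"burial": decoys}, lddt, n)
    ])


class TestFitInformation:
    def test_balanced_corpus_one_bit_each(self):
        info = bc.fit_information([binary([0, 1] * 50)])
        np.testing.assert_allclose(info.information, [1.0, 1.0])

    def test_quarter_probability_closed_form(self):
        info = bc.fit_information([binary([1] + [0] * 3)])
        assert info.iota([1])[0] == pytest.approx(2.0)
        assert info.iota([0])[0] == pytest.approx(-np.log2(0.75))

    def test_pooled_counts_match_brute_force(self):
        rng = np.random.default_rng(1)
        corpus = [binary(rng.integers(0, 2, rng.integers(5, 40)))
                  for _ in range(7)]
        info = bc.fit_information(corpus)
        pooled = np.concatenate([ls.labels for ls in corpus])
        for x in (0, 1):
            assert info.probabilities[x] == pytest.approx((pooled == x).mean())

    def test_unseen_outcome_gets_pseudocount(self):
        info = bc.fit_information([binary([0, 0, 0, 0])])
        assert np.isfinite(info.information).all()
        assert info.probabilities[1] < info.probabilities[0]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            bc.fit_information([])


class TestFlattenedSpearman:
    def test_monotone_increasing_is_one(self):
        lddt = np.linspace(0.05, 0.95, 40)
        assert bc.flattened_spearman(lddt * 2, lddt, seed=0) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        lddt = np.linspace(0.05, 0.95, 40)
        assert bc.flattened_spearman(-lddt, lddt, seed=0) == pytest.approx(-1.0)

    def test_uniform_lddt_agrees_with_plain_spearman(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        lddt = rng.uniform(0, 1, 400)
        phi = lddt + rng.normal(0, 0.05, 400)
        flat = bc.flattened_spearman(phi, lddt, seed=1)
        plain = spearmanr(phi, lddt).statistic
        assert flat == pytest.approx(plain, abs=0.05)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        lddt = rng.uniform(0, 1, 300)
        phi = lddt + rng.normal(0, 0.1, 300)
        a = bc.flattened_spearman(phi, lddt, seed=2)
        b = bc.flattened_spearman(np.exp(3 * phi), lddt, seed=2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_tied_phi_degenerate_zero(self):
        lddt = np.linspace(0, 1, 30)
        with pytest.warns(DegenerateCorrelationWarning):
            assert bc.flattened_spearman(np.ones(30), lddt) == 0.0

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            bc.flattened_spearman([1.0, 2.0, 3.0], [0.51, 0.52, 0.53])


class TestSubsampleRestraints:
    def test_full_fraction_uses_every_position(self):
        bench = balanced_bench(n=2000)
        info = bc.fit_information(bench.native_label_sets("burial"))
        draw = bc.subsample_restraints(bench, "burial", 1.0, info, seed=0)
        assert draw.n_restraints == 2000
        assert draw.bits_per_residue == pytest.approx(1.0, abs=1e-6)
        # phi over all positions equals the direct full-channel phi
        t = bench.targets[0]
        direct = bc.phi(t.native_channels["burial"], t.decoy_channels["burial"][0])
        assert draw.phi_values[0] == pytest.approx(direct.value, abs=1e-12)

    def test_balanced_half_fraction_half_bit(self):
        bench = balanced_bench(n=10_000)
        info = bc.fit_information(bench.native_label_sets("burial"))
        draw = bc.subsample_restraints(bench, "burial", 0.5, info, seed=3)
        assert draw.bits_per_residue == pytest.approx(0.5, abs=0.01)

    def test_fixed_seed_reproduces_draw(self):
        bench = balanced_bench(n=500)
        info = bc.fit_information(bench.native_label_sets("burial"))
        d1 = bc.subsample_restraints(bench, "burial", 0.3, info, seed=9)
        d2 = bc.subsample_restraints(bench, "burial", 0.3, info, seed=9)
        np.testing.assert_array_equal(d1.selections[0], d2.selections[0])
        np.testing.assert_array_equal(d1.phi_values, d2.phi_values)

    def test_sampling_linearity_in_fraction(self):
        """E[I at fraction f] = f * I(1) for any channel."""
        bench = balanced_bench(n=10_000)
        info = bc.fit_information(bench.native_label_sets("burial"))
        full = bc.subsample_restraints(bench, "burial", 1.0, info, seed=0)
        for f in (0.1, 0.25, 0.6):
            draws = [
                bc.subsample_restraints(bench, "burial", f, info, seed=s)
                for s in range(5)
            ]
            mean_i = np.mean([d.bits_per_residue for d in draws])
            assert mean_i == pytest.approx(f * full.bits_per_residue, rel=0.02)

    def test_invalid_fraction_rejected(self):
        bench = balanced_bench(n=100)
        info = bc.fit_information(bench.native_label_sets("burial"))
        with pytest.raises(ValueError):
            bc.subsample_restraints(bench, "burial", 0.0, info)


class TestRhoVsICurve:
    def test_full_fraction_point_consistent_with_direct(self):
        bench = balanced_bench(n=2000)
        pts = bc.rho_vs_I_curve(bench, "burial", [1.0], n_repeats=2,
                                seed=5, n_boot=200)
        t = bench.targets[0]
        phis = np.array([
            bc.phi(t.native_channels["burial"], d).value
            for d in t.decoy_channels["burial"]
        ])
        direct = bc.flattened_spearman(phis, t.lddt, n_boot=200, seed=5)
        assert pts[0].rho == pytest.approx(direct, abs=0.05)
        assert pts[0].bits_per_residue == pytest.approx(1.0, abs=1e-6)

    def test_information_monotone_in_fraction(self):
        bench = balanced_bench(n=3000)
        pts = bc.rho_vs_I_curve(bench, "burial", [0.05, 0.3, 1.0],
                                n_repeats=4, seed=6, n_boot=200)
        bits = [p.bits_per_residue for p in pts]
        assert bits[0] < bits[1] < bits[2]

    def test_seeding_is_order_independent(self):
        bench = balanced_bench(n=800)
        both = bc.rho_vs_I_curve(bench, "burial", [0.2, 0.8], n_repeats=3,
                                 seed=11, n_boot=100)
        again = bc.rho_vs_I_curve(bench, "burial", [0.2, 0.8], n_repeats=3,
                                  seed=11, n_boot=100)
        for a, b in zip(both, again):
            assert a.bits_per_residue == b.bits_per_residue
            assert a.rho == b.rho


class TestIStar:
    def test_linear_interpolation(self):
        curve = [CurvePoint(0.5, 0.4, 0.85, 1), CurvePoint(1.0, 0.8, 0.95, 1)]
        assert bc.i_star(curve, 0.9) == pytest.approx(0.6)

    def test_never_crossing_is_absent(self):
        curve = [CurvePoint(0.5, 0.4, 0.5, 1), CurvePoint(1.0, 0.8, 0.7, 1)]
        assert bc.i_star(curve, 0.9) is None

    def test_first_point_above_threshold(self):
        curve = [CurvePoint(0.5, 0.4, 0.95, 1), CurvePoint(1.0, 0.8, 0.99, 1)]
        assert bc.i_star(curve, 0.9) == pytest.approx(0.4)

    def test_non_increasing_under_uniform_rho_boost(self):
        rng = np.random.default_rng(12)
        bits = np.sort(rng.uniform(0.1, 2.0, 6))
        rho = np.sort(rng.uniform(0.5, 0.95, 6))
        base = [CurvePoint(0, b, r, 1) for b, r in zip(bits, rho)]
        boosted = [CurvePoint(0, b, min(1.0, r + 0.05), 1)
                   for b, r in zip(bits, rho)]
        i0, i1 = bc.i_star(base), bc.i_star(boosted)
        if i1 is not None and i0 is not None:
            assert i1 <= i0 + 1e-12
        elif i0 is None:
            assert True  # boost can only create a crossing, never remove one

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            bc.i_star([])
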