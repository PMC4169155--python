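"""Frequency spectrum construction, projection and the sweep transform."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from qtlsweep import sfs as fs
from qtlsweep.sfs import SFSpectrum

from conftest import make_site


class TestSpectrumInvariants:
    def test_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SFSpectrum(4, np.array([0, 0.5, 0.1, 0.1, 0]))

    def test_non_extended_rejects_invariant_mass(self):
        probs = np.array([0.2, 0.4, 0.2, 0.2, 0.0])
        with pytest.raises(ValueError):
            SFSpectrum(4, probs, extended=False)
        SFSpectrum(4, probs, extended=True)  # fine when extended


class TestBuildSfs:
    def test_all_singletons(self):
        sites = [make_site(i, {"p": {"A": 3, "G": 1}}, outgroup="A") for i in range(3)]
        spec, diag = fs.build_sfs(sites, target_n=4)
        assert spec.probs[1] == pytest.approx(1.0)
        assert diag["used"] == 3

    def test_monomorphic_dropped_without_extension(self):
        sites = [make_site(1, {"p": {"A": 3, "G": 1}}, outgroup="A"),
                 make_site(2, {"p": {"A": 4}}, outgroup="A")]
        spec, diag = fs.build_sfs(sites, target_n=4)
        assert diag["used"] == 1

    def test_polarization_failure_counted(self):
        # outgroup base matches neither allele
        sites = [make_site(1, {"p": {"A": 2, "G": 2}}, outgroup="C"),
                 make_site(2, {"p": {"A": 3, "G": 1}}, outgroup="A")]
        spec, diag = fs.build_sfs(sites, target_n=4)
        assert diag["polarization_failed"] == 1

    def test_projection_matches_exhaustive_subsampling(self):
        """Mixed-coverage sites projected to n=4 agree with enumerating
        every subsample of the observed alleles."""
        # one site with 6 valid calls (4 derived), projected to 4
        sites = [make_site(1, {"p": {"A": 2, "G": 4}}, outgroup="A")]
        spec, _ = fs.build_sfs(sites, target_n=4, extended=True)
        pool = [1, 1, 1, 1, 0, 0]
        counts = np.zeros(5)
        for combo in itertools.combinations(range(6), 4):
            counts[sum(pool[i] for i in combo)] += 1
        counts /= counts.sum()
        np.testing.assert_allclose(spec.probs, counts, atol=1e-12)


class TestDownsample:
    def test_identity_at_same_size(self):
        spec = SFSpectrum.neutral(6)
        down = fs.downsample_sfs(spec, 6)
        np.testing.assert_allclose(down.probs, spec.probs, atol=1e-12)

    def test_singleton_class_splits(self):
        # n=4 all-singleton spectrum to m=2 keeps invariant classes:
        # a singleton is picked with prob 1/2 -> {0: 1/2, 1: 1/2}
        spec = SFSpectrum.from_class_dict(4, {1: 1.0}, extended=True)
        down = fs.downsample_sfs(spec, 2)
        np.testing.assert_allclose(down.probs, [0.5, 0.5, 0.0], atol=1e-12)

    def test_normalization_preserved(self):
        rng = np.random.default_rng(3)
        for n, m in [(8, 2), (8, 5), (12, 7)]:
            p = rng.uniform(0.01, 1, n + 1)
            p /= p.sum()
            spec = SFSpectrum(n, p, extended=True)
            assert fs.downsample_sfs(spec, m).probs.sum() == pytest.approx(1.0)

    def test_oversize_rejected(self):
        with pytest.raises(ValueError):
            fs.downsample_sfs(SFSpectrum.neutral(4), 5)


class TestExtendInvariantClasses:
    def _focal_reference(self):
        focal = [
            make_site(1, {"eu": {"A": 4}}, outgroup="A"),   # mono ancestral
            make_site(2, {"eu": {"G": 4}}, outgroup="A"),   # mono derived
            make_site(3, {"eu": {"A": 4}}, outgroup="A"),   # mono, ref mono too
            make_site(4, {"eu": {"A": 3, "G": 1}}, outgroup="A"),
        ]
        reference = [
            make_site(1, {"rg": {"A": 3, "G": 2}}, outgroup="A"),
            make_site(2, {"rg": {"G": 3, "A": 2}}, outgroup="A"),
            make_site(3, {"rg": {"A": 5}}, outgroup="A"),
            make_site(4, {"rg": {"A": 5}}, outgroup="A"),
        ]
        return focal, reference

    def test_reference_conditioned_classes(self):
        focal, reference = self._focal_reference()
        base, _ = fs.build_sfs(focal, target_n=4)
        ext = fs.extend_sfs_invariant_classes(base, focal, reference)
        assert ext.extended
        # 1 polymorphic site, 1 ancestral-invariant, 1 derived-invariant;
        # site 3 is reference-monomorphic and must NOT count
        np.testing.assert_allclose(ext.probs[[0, 1, 4]], [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_no_reference_is_identity(self):
        focal, _ = self._focal_reference()
        base, _ = fs.build_sfs(focal, target_n=4)
        out = fs.extend_sfs_invariant_classes(base, focal, None)
        assert out is base and not out.extended


class TestSweepTransform:
    def test_full_escape_is_identity(self):
        bg = SFSpectrum.from_class_dict(
            6, {0: 0.2, 1: 0.3, 2: 0.2, 3: 0.1, 4: 0.1, 5: 0.05, 6: 0.05}, extended=True
        )
        out = fs.sweep_transform_sfs(bg, 1.0)
        np.testing.assert_allclose(out.probs, bg.probs, atol=1e-12)

    def test_no_escape_fixes_or_loses_everything(self):
        bg = SFSpectrum.from_class_dict(5, {1: 0.5, 2: 0.3, 4: 0.2}, extended=True)
        out = fs.sweep_transform_sfs(bg, 0.0)
        derived_mass = sum(j * p / 5 for j, p in enumerate(bg.probs))
        assert out.probs[5] == pytest.approx(derived_mass)
        assert out.probs[0] == pytest.approx(1 - derived_mass)
        assert out.probs[1:5].sum() == pytest.approx(0.0, abs=1e-15)

    def test_requires_extended_background(self):
        with pytest.raises(ValueError):
            fs.sweep_transform_sfs(SFSpectrum.neutral(5), 0.5)

    def test_matches_exhaustive_enumeration(self):
        from qtlsweep.validation import sweep_transform_oracle_error

        assert sweep_transform_oracle_error(max_n=6) < 1e-10

    def test_continuity_in_escape_probability(self):
        bg = SFSpectrum.from_class_dict(
            8, {j: 1.0 / max(j, 1) for j in range(9)}, extended=True
        )
        t = fs.SweepTransform(bg)
        pe = np.linspace(0.0, 1.0, 400)
        mat = t.matrix(pe)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)
        steps = np.abs(np.diff(mat, axis=0)).max()
        assert steps < 0.02  # no jumps under fine discretization


class TestSweepSiteSampler:
    def test_far_field_matches_background(self):
        from qtlsweep.simulate import simulate_sweep_sfs_sites

        n = 8
        bg = SFSpectrum.from_class_dict(
            n, {0: 0.25, **{j: 0.6 / (j * sum(1 / k for k in range(1, n))) for j in range(1, n)},
                n: 0.15}, extended=True,
        )
        # alpha so large that p_escape ~ 1 everywhere: classes ~ bg
        pos, cls = simulate_sweep_sfs_sites(bg, 0.0, alpha=10.0, n_sites=5000,
                                            length=100000, seed=2)
        observed = np.bincount(cls, minlength=n + 1)
        expected = bg.probs * len(cls)
        keep = expected > 5
        stat = chisquare(observed[keep], expected[keep] * observed[keep].sum()
                         / expected[keep].sum())
        assert stat.pvalue > 0.01

    def test_center_sites_monomorphic(self):
        from qtlsweep.simulate import simulate_sweep_sfs_sites

        bg = SFSpectrum.from_class_dict(6, {0: 0.3, 1: 0.3, 3: 0.2, 6: 0.2}, extended=True)
        pos, cls = simulate_sweep_sfs_sites(bg, 50_000.0, alpha=1e-7, n_sites=400,
                                            length=100_000, seed=3)
        near = np.abs(pos - 50_000.0) < 2000
        assert near.sum() > 0
        assert np.isin(cls[near], [0, 6]).all()


class TestSfsTextIO:
    def test_round_trip(self, tmp_path):
        spec = SFSpectrum.from_class_dict(
            6, {0: 0.25, 1: 0.3, 2: 0.2, 5: 0.15, 6: 0.1}, extended=True
        )
        path = tmp_path / "bg.sfs"
        fs.write_sfs_text(spec, path)
        back = fs.read_sfs_text(path)
        assert back.n == 6 and back.extended
        np.testing.assert_allclose(back.probs, spec.probs, atol=1e-10)

    def test_polymorphic_only_not_extended(self, tmp_path):
        path = tmp_path / "bg.sfs"
        path.write_text("1\t0.5\n2\t0.3\n3\t0.2\n")
        back = fs.read_sfs_text(path, n=5)
        assert back.n == 5 and not back.extended
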