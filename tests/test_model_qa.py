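"""Model QA: background, PE-score, superposition, S-score, GDT, ranking."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from torsiongrid.binning import (ProbabilityProfile, UndefinedMetricError,
                                 angle_to_bin, make_scheme)
from torsiongrid.geometry import ANGLE_KINDS, compute_angles
from torsiongrid.model_qa import (BackgroundDistribution, DecoyScore,
                                  estimate_background, gdt_like,
                                  kabsch_superpose, pe_score, rank_models,
                                  s_score)
from torsiongrid.synthetic import (build_fragment, make_decoys,
                                   profile_from_angles)


@pytest.fixture(scope="module")
def corpus():
    return [compute_angles(build_fragment("H" * 20 + "E" * 10 + "C" * 10,
                                          seed=s)) for s in range(8)]


class TestEstimateBackground:
    def test_single_bin_corpus_no_pseudocount(self, scheme5):
        table = compute_angles(build_fragment("H" * 20, seed=0))
        bg = estimate_background([table], scheme5, pseudocount=0.0)
        phi_bin = angle_to_bin(-57.0, "phi", scheme5)
        assert bg.probs["phi"][phi_bin] == pytest.approx(1.0)

    def test_pseudocount_gives_strict_positivity(self, corpus, scheme5):
        bg = estimate_background(corpus, scheme5, pseudocount=1.0)
        for kind in ANGLE_KINDS:
            assert np.all(bg.probs[kind] > 0)
            assert bg.probs[kind].sum() == pytest.approx(1.0)

    def test_matches_histogram_oracle(self, corpus, scheme5):
        bg = estimate_background(corpus, scheme5, pseudocount=1.0)
        for kind in ANGLE_KINDS:
            K = scheme5.counts[kind]
            counts = np.zeros(K)
            for table in corpus:
                for v in table.values(kind)[table.mask(kind)]:
                    counts[angle_to_bin(v, kind, scheme5)] += 1
            want = (counts + 1.0) / (counts.sum() + K)
            assert np.allclose(bg.probs[kind], want, atol=1e-12)

    def test_empty_corpus_raises(self, scheme5):
        with pytest.raises(ValueError):
            estimate_background([], scheme5)

    def test_tsv_round_trip(self, corpus, scheme5):
        bg = estimate_background(corpus, scheme5)
        again = BackgroundDistribution.from_tsv(bg.to_tsv(), scheme5)
        for kind in ANGLE_KINDS:
            assert np.allclose(again.probs[kind], bg.probs[kind], atol=1e-9)


def uniform_background(scheme):
    return BackgroundDistribution(
        scheme=scheme,
        probs={k: np.full(scheme.counts[k], 1.0 / scheme.counts[k])
               for k in ANGLE_KINDS})


class TestPeScore:
    def test_zero_when_profile_equals_background(self, scheme5):
        angles = compute_angles(build_fragment("H" * 10, seed=1))
        bg = uniform_background(scheme5)
        prof = ProbabilityProfile(
            scheme=scheme5,
            blocks={k: np.full((10, scheme5.counts[k]), 1 / scheme5.counts[k])
                    for k in ANGLE_KINDS})
        assert pe_score(prof, angles, bg, "phi") == pytest.approx(0.0, abs=1e-9)

    def test_double_background_single_residue_ln2(self, scheme5):
        angles = compute_angles(build_fragment("H" * 4, seed=1))
        # keep exactly one defined phi residue
        angles.defined_phi[2:] = False
        angles.phi[2:] = np.nan
        bg = uniform_background(scheme5)
        blocks = {k: np.full((4, scheme5.counts[k]), 1 / scheme5.counts[k])
                  for k in ANGLE_KINDS}
        phi = np.full((4, 72), (1 - 2 / 72) / 71)
        b = angle_to_bin(angles.phi[1], "phi", scheme5)
        phi[1, b] = 2.0 / 72
        blocks["phi"] = phi
        prof = ProbabilityProfile(scheme=scheme5, blocks=blocks)
        assert pe_score(prof, angles, bg, "phi") == pytest.approx(np.log(2))

    def test_matches_naive_loop(self, rng, scheme5, corpus):
        angles = corpus[0]
        bg = estimate_background(corpus, scheme5)
        raw = rng.random((len(angles.phi), 72))
        blocks = {k: (lambda r: r / r.sum(1, keepdims=True))(
            rng.random((len(angles.phi), scheme5.counts[k])))
            for k in ANGLE_KINDS}
        prof = ProbabilityProfile(scheme=scheme5, blocks=blocks)
        for kind in ANGLE_KINDS:
            want = 0.0
            for i in range(len(angles.phi)):
                if not angles.mask(kind)[i]:
                    continue
                b = angle_to_bin(angles.values(kind)[i], kind, scheme5)
                want += np.log(max(prof.blocks[kind][i, b], 1e-8)
                               / bg.probs[kind][b])
            assert pe_score(prof, angles, bg, kind) == pytest.approx(want)

    def test_zero_probability_floored_not_inf(self, scheme5):
        angles = compute_angles(build_fragment("H" * 6, seed=1))
        bg = uniform_background(scheme5)
        blocks = {k: np.full((6, scheme5.counts[k]), 1 / scheme5.counts[k])
                  for k in ANGLE_KINDS}
        phi = np.zeros((6, 72))
        phi[:, 0] = 1.0  # everything far from the helix bin
        blocks["phi"] = phi
        prof = ProbabilityProfile(scheme=scheme5, blocks=blocks)
        score = pe_score(prof, angles, bg, "phi", eps=1e-8)
        assert np.isfinite(score)
        assert score == pytest.approx(5 * np.log(1e-8 * 72))

    def test_per_residue_mean_option(self, scheme5, corpus):
        angles = corpus[0]
        bg = estimate_background(corpus, scheme5)
        prof = profile_from_angles(angles, scheme5)
        total = pe_score(prof, angles, bg, "theta")
        mean = pe_score(prof, angles, bg, "theta", per_residue_mean=True)
        assert mean == pytest.approx(total / angles.defined_theta.sum())


class TestKabsch:
    def test_identity(self, mixed_chain):
        R, t, d = kabsch_superpose(mixed_chain.coords_CA, mixed_chain.coords_CA)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_pure_translation(self, mixed_chain):
        moved = mixed_chain.coords_CA + [5.0, 0.0, 0.0]
        _, _, d = kabsch_superpose(moved, mixed_chain.coords_CA)
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_recovers_applied_rotation(self, rng):
        # a large globular-ish fixture keeps the rotation well conditioned
        chain = build_fragment(("H" * 25 + "C" * 10 + "E" * 15 + "C" * 10) * 3,
                               seed=9)
        R_true = Rotation.random(random_state=rng).as_matrix()
        noisy = chain.coords_CA @ R_true.T + rng.normal(0, 0.1,
                                                        chain.coords_CA.shape)
        R, _, d = kabsch_superpose(noisy, chain.coords_CA)
        # R should undo R_true
        assert np.allclose(R @ R_true, np.eye(3), atol=1e-3)
        rmsd = np.sqrt(np.mean(d ** 2))
        assert rmsd < 3 * 0.1 * np.sqrt(3)

    def test_proper_rotation(self, mixed_chain, rng):
        noisy = mixed_chain.coords_CA + rng.normal(0, 1.0,
                                                   mixed_chain.coords_CA.shape)
        R, _, _ = kabsch_superpose(noisy, mixed_chain.coords_CA)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_not_increased_by_superposition(self, mixed_chain, rng):
        noisy = (mixed_chain.coords_CA
                 @ Rotation.random(random_state=rng).as_matrix().T
                 + rng.normal(0, 0.5, mixed_chain.coords_CA.shape) + 3.0)
        before = np.sqrt(np.mean(np.sum(
            (noisy - mixed_chain.coords_CA) ** 2, axis=1)))
        _, _, d = kabsch_superpose(noisy, mixed_chain.coords_CA)
        after = np.sqrt(np.mean(d ** 2))
        assert after <= before + 1e-9

    def test_invariant_to_prerotation(self, mixed_chain, rng):
        pre = Rotation.random(random_state=rng).as_matrix()
        _, _, d1 = kabsch_superpose(mixed_chain.coords_CA + rng.normal(
            0, 1, mixed_chain.coords_CA.shape), mixed_chain.coords_CA)
        rng2 = np.random.default_rng(42)
        noisy = mixed_chain.coords_CA + rng2.normal(
            0, 1, mixed_chain.coords_CA.shape)
        _, _, da = kabsch_superpose(noisy, mixed_chain.coords_CA)
        _, _, db = kabsch_superpose(noisy @ pre.T, mixed_chain.coords_CA)
        assert np.allclose(da, db, atol=1e-8)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.ones((2, 3)))


class TestSScore:
    @pytest.mark.parametrize("d,want", [(0.0, 1.0), (3.0, 0.5), (6.0, 0.2)])
    def test_closed_form(self, d, want):
        assert s_score(d) == pytest.approx(want)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 20, 100)
        s = s_score(d)
        assert np.all(np.diff(s) < 0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            s_score(-1.0)


class TestGdtLike:
    def test_identical_structures(self):
        assert gdt_like(np.zeros(30)) == 1.0

    def test_all_beyond_cutoffs(self):
        assert gdt_like(np.full(30, 10.0)) == 0.0

    def test_hand_counted_mixture(self):
        d = np.array([0.5] * 15 + [5.0] * 15)
        # cutoffs 1,2,4: half within; cutoff 8: all within
        assert gdt_like(d) == pytest.approx((0.5 + 0.5 + 0.5 + 1.0) / 4)

    def test_unmodeled_residues_penalized(self):
        d = np.zeros(15)
        assert gdt_like(d, n_native=30) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gdt_like(np.array([]))


class TestRankModels:
    def _decoys(self, pe, quality):
        return [DecoyScore(model_id=f"m{i}", pe_combined=p, gdt=q)
                for i, (p, q) in enumerate(zip(pe, quality))]

    def test_perfect_correlation(self):
        q = [0.2, 0.4, 0.6, 0.8]
        out = rank_models(self._decoys(q, q))
        assert out["pcc"] == pytest.approx(1.0)
        assert out["top1_quality"] == 0.8

    def test_anti_correlation(self):
        q = np.array([0.2, 0.4, 0.6, 0.8])
        out = rank_models(self._decoys(-q, q))
        assert out["pcc"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        pe = rng.random(10)
        q = rng.random(10)
        out = rank_models(self._decoys(pe, q))
        want = (np.mean(pe * q) - pe.mean() * q.mean()) / (pe.std() * q.std())
        assert out["pcc"] == pytest.approx(want)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedMetricError):
            rank_models(self._decoys([1.0, 1.0], [0.3, 0.7]))


class TestEndToEndRanking:
    def test_pe_tracks_decoy_quality(self):
        """PE-score vs GDT-like over a noise ladder: strong positive r.

        Uses the CA-trace angle theta, whose bin occupancy degrades
        gradually with coordinate noise (phi/psi decorrelate almost
        immediately under independent atomic noise).
        """
        from scipy.stats import pearsonr

        scheme = make_scheme(5.0)
        ss = ("H" * 25 + "C" * 8 + "E" * 12 + "C" * 8) * 2 + "H" * 14
        native = build_fragment(ss, seed=5)
        angles = compute_angles(native)
        prof = profile_from_angles(angles, kernel_sigma_deg=20.0)
        bg = estimate_background(
            [compute_angles(build_fragment(
                "".join(np.random.default_rng(s).choice(list("HEC"), 60)),
                seed=s)) for s in range(50)], scheme)
        pes, gdts = [], []
        for decoy, _ in make_decoys(native, [0.5, 1, 2, 4, 8],
                                    n_per_sigma=15, seed=11):
            da = compute_angles(decoy)
            pes.append(pe_score(prof, da, bg, "theta"))
            _, _, d = kabsch_superpose(decoy.coords_CA, native.coords_CA)
            gdts.append(gdt_like(d, n_native=len(native)))
        r = pearsonr(pes, gdts).statistic
        assert r >= 0.8
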