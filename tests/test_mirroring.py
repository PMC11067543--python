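"""The statistical-mirroring pipeline: preprocessing, mirror design,
end-to-end estimates, presets, classification, and the invariance
properties (permutation, scale, scaloc, pairing, set duplication)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statmirror.errors import InvalidArgumentError, ModalUndefinedError
from statmirror.mirroring import (
    MirroringConfig,
    center_data,
    classify_mirroring,
    design_mirror,
    named_preset,
    order_data,
    preset_names,
    run_mirroring,
    with_pairing,
)
from statmirror.optinalysis import psim_to_kc_alternates


class TestCenterData:
    def test_mean_absolute_positive_worked_example(self, sample6):
        out = center_data(sample6, "mean", "absolute_positive")
        np.testing.assert_allclose(
            np.round(out, 2), [2.06, 4.27, 4.16, 6.40, 0.82, 0.83]
        )
        assert (out >= 0).all()

    def test_none_is_identity(self, sample6):
        np.testing.assert_array_equal(center_data(sample6, "none"), sample6)

    def test_signed_mean_centering_sums_to_zero(self):
        out = center_data([1.0, 2.0, 3.0], "mean", "signed")
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])
        assert out.sum() == pytest.approx(0.0, abs=1e-12)

    def test_absolute_negative(self):
        out = center_data([1.0, 2.0, 3.0], "mean", "absolute_negative")
        assert (out <= 0).all()

    def test_mode_on_all_distinct_data_raises(self):
        with pytest.raises(ModalUndefinedError):
            center_data([1.0, 2.0, 3.0], "mode")

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            center_data([], "mean")


class TestOrderData:
    def test_worked_example_order(self, sample6):
        out = order_data(center_data(sample6, "mean", "absolute_positive"))
        np.testing.assert_allclose(
            np.round(out, 2), [0.82, 0.83, 2.06, 4.16, 4.27, 6.40]
        )

    def test_descending(self):
        np.testing.assert_array_equal(
            order_data([1.0, 3.0, 2.0], "descending"), [3.0, 2.0, 1.0]
        )

    def test_permutation_invariant(self, rng):
        x = rng.normal(size=20)
        np.testing.assert_array_equal(order_data(x), order_data(rng.permutation(x)))


class TestDesignMirror:
    def test_meanic_mirror_worked_example(self, sample6):
        transformed = order_data(center_data(sample6, "mean", "absolute_positive"))
        mirror = design_mirror(transformed, "mean")
        assert mirror.principal_value == pytest.approx(3.09)
        np.testing.assert_allclose(mirror.values, np.full(6, 3.09))

    def test_max_principal(self):
        mirror = design_mirror([1.0, 5.0, 2.0], "max")
        np.testing.assert_array_equal(mirror.values, [5.0, 5.0, 5.0])

    def test_reference_requires_value(self):
        with pytest.raises(InvalidArgumentError):
            design_mirror([1.0, 2.0], "reference")
        assert design_mirror([1.0, 2.0], "reference", ref=7.0).principal_value == 7.0

    def test_mode_with_ties(self):
        # ties broken toward the smallest value
        assert design_mirror([2.0, 2.0, 5.0, 5.0, 1.0], "mode").principal_value == 2.0


class TestRunMirroring:
    def test_absolute_meanic_worked_example(self, sample6, amm):
        res = run_mirroring(sample6, amm)
        assert res.kc == pytest.approx(0.927928, abs=5e-5)
        assert res.pprox == pytest.approx(0.8338, abs=5e-5)
        assert res.pdev == pytest.approx(0.1662, abs=5e-5)
        assert res.pdev == pytest.approx(1 - res.pprox, abs=1e-15)
        # the realized kc is one of its own bi-coefficients
        assert res.kc == pytest.approx(res.kc_alt1, abs=1e-12)

    def test_score_group_presets(self, scores4, amm, rmm):
        assert run_mirroring(scores4, amm).pprox == pytest.approx(0.9252, abs=5e-5)
        assert run_mirroring(scores4, amm).pdev == pytest.approx(0.0748, abs=5e-5)
        assert run_mirroring(scores4, rmm).pprox == pytest.approx(0.8384, abs=5e-5)

    def test_single_point_is_perfectly_proximal(self, rmm):
        res = run_mirroring([5.0], rmm)
        assert res.kc == pytest.approx(1.0)
        assert res.pprox == pytest.approx(1.0)

    def test_integral_meanic_degenerates_with_warning(self):
        cfg = named_preset("integral_meanic")
        with pytest.warns(RuntimeWarning):
            res = run_mirroring([1.0, 2.0, 3.0], cfg)
        assert res.kc == pytest.approx(0.0, abs=1e-12)

    def test_empty_data_rejected(self, amm):
        with pytest.raises(InvalidArgumentError):
            run_mirroring([], amm)


class TestPresets:
    def test_absolute_meanic_expansion(self):
        cfg = named_preset("absolute_meanic")
        assert (cfg.centering, cfg.absolute_mode, cfg.ordering, cfg.principal,
                cfg.pairing) == ("mean", "absolute_positive", "ascending", "mean",
                                 "head_to_head")

    def test_raw_meanic_expansion(self):
        cfg = named_preset("raw_meanic")
        assert cfg.centering == "none" and cfg.absolute_mode == "signed"

    def test_absolute_medianic_expansion(self):
        cfg = named_preset("absolute_medianic")
        assert cfg.centering == "median" and cfg.principal == "median"
        assert cfg.absolute_mode == "absolute_positive"

    def test_all_names_resolve(self):
        for name in preset_names():
            ref = 1.0 if "reference" in name else None
            assert named_preset(name, reference_value=ref) is not None

    def test_unknown_preset_rejected(self):
        with pytest.raises(InvalidArgumentError):
            named_preset("winsorized_meanic")


class TestClassification:
    def test_absolute_meanic_is_endo_scaloc(self):
        c = classify_mirroring(named_preset("absolute_meanic"))
        assert (c.statistical, c.invariance) == ("endo", "scaloc")

    def test_raw_meanic_is_endo_scale(self):
        c = classify_mirroring(named_preset("raw_meanic"))
        assert (c.statistical, c.invariance) == ("endo", "scale")

    def test_reference_mirroring_is_exo(self):
        c = classify_mirroring(named_preset("raw_reference", reference_value=3.0))
        assert c.statistical == "exo"


class TestInvarianceProperties:
    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=15),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, values, random):
        x = np.array(values)
        shuffled = list(values)
        random.shuffle(shuffled)
        for preset in ("raw_meanic", "absolute_meanic", "absolute_medianic"):
            cfg = named_preset(preset)
            a = run_mirroring(x, cfg)
            b = run_mirroring(np.array(shuffled), cfg)
            # identical up to summation order of the location statistic
            assert b.kc == pytest.approx(a.kc, rel=1e-12, abs=1e-12)
            assert b.pprox == pytest.approx(a.pprox, rel=1e-12, abs=1e-12)

    def test_scale_invariance_raw_presets(self, rng):
        for _ in range(20):
            x = rng.normal(5.0, 2.0, size=int(rng.integers(3, 25)))
            for preset in ("raw_meanic", "raw_medianic", "raw_maximalic"):
                cfg = named_preset(preset)
                base = run_mirroring(x, cfg).pprox
                for a in (0.1, 3.0, 250.0):
                    assert run_mirroring(a * x, cfg).pprox == pytest.approx(
                        base, abs=1e-10
                    )

    def test_scaloc_invariance_absolute_presets(self, rng):
        for _ in range(20):
            x = rng.normal(0.0, 3.0, size=int(rng.integers(3, 25)))
            for preset in ("absolute_meanic", "absolute_medianic"):
                cfg = named_preset(preset)
                base = run_mirroring(x, cfg).pprox
                for a, b in ((2.0, 5.0), (-3.0, 100.0), (0.25, -40.0), (-1.0, 0.0)):
                    assert run_mirroring(a * x + b, cfg).pprox == pytest.approx(
                        base, abs=1e-10
                    )

    def test_meanic_pairing_invariance_and_bicoefficient_duality(self, sample6, amm):
        h = run_mirroring(sample6, amm)
        t = run_mirroring(sample6, with_pairing(amm, "tail_to_tail"))
        assert t.pprox == pytest.approx(h.pprox, abs=1e-10)
        assert t.pdev == pytest.approx(h.pdev, abs=1e-10)
        # the two pairings realize the two bi-coefficients of one psim
        alts = psim_to_kc_alternates(h.pprox, h.n)
        assert sorted([h.kc, t.kc]) == pytest.approx(
            sorted([alts.kc_alt1, alts.kc_alt2]), abs=1e-10
        )
        assert t.kc == pytest.approx(1.084211, abs=5e-5)

    def test_non_meanic_pairing_variance(self):
        cfg = named_preset("raw_medianic")
        x = [1.0, 2.0, 10.0]
        h = run_mirroring(x, cfg)
        t = run_mirroring(x, with_pairing(cfg, "tail_to_tail"))
        assert h.pprox != pytest.approx(t.pprox, abs=1e-6)

    def test_set_duplication_invariance_meanic(self, scores4, amm, rmm):
        base_amm = run_mirroring(scores4, amm)
        base_rmm = run_mirroring(scores4, rmm)
        for c in (2, 3, 7, 50):
            dup = np.tile(scores4, c)
            for cfg, base in ((amm, base_amm), (rmm, base_rmm)):
                res = run_mirroring(dup, cfg)
                assert res.pprox == pytest.approx(base.pprox, abs=1e-10)
                assert res.pdev == pytest.approx(base.pdev, abs=1e-10)
            # the coefficient itself is NOT duplication-invariant
            assert run_mirroring(dup, amm).kc != pytest.approx(base_amm.kc, abs=1e-6)

    def test_probabilities_bounded(self, rng):
        presets = ("raw_meanic", "integral_meanic", "absolute_meanic",
                   "raw_medianic", "absolute_maximalic", "raw_minimalic")
        for _ in range(40):
            x = rng.normal(rng.uniform(-10, 10), rng.uniform(0.1, 10),
                           size=int(rng.integers(2, 30)))
            for preset in presets:
                res = run_mirroring(x, named_preset(preset))
                assert -1.0 - 1e-12 <= res.pprox <= 1.0 + 1e-12
                assert -1.0 - 1e-12 <= res.pdev <= 1.0 + 1e-12


def test_result_record_round_trips_config(sample6, amm):
    rec = run_mirroring(sample6, amm).as_record()
    assert rec["centering"] == "mean" and rec["n"] == 6
    assert set(rec) >= {"kc", "pprox", "pdev", "kc_alt1", "kc_alt2"}


def test_config_validation():
    with pytest.raises(InvalidArgumentError):
        MirroringConfig(centering="quantile")
    with pytest.raises(InvalidArgumentError):
        MirroringConfig(principal="reference")  # missing reference_value
    with pytest.raises(InvalidArgumentError):
        MirroringConfig(optiscale_k=0.0)
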