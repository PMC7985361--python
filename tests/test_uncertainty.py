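import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanbayes.errors import ValidationError
from ramanbayes.uncertainty import (
    EnsembleRecord,
    ProbabilityRecord,
    bin_quintile,
    build_ensemble_records,
    compute_flags,
    ensemble_variance,
    fit_boundary_poly,
)

TAGS = ("FPHW", "FP", "HW")


def record(tid, tag, probs):
    return ProbabilityRecord(target_id=tid, config_tag=tag, cycle_probs=np.asarray(probs))


def ens(tid, means, v_ra=(0.01, 0.01, 0.01), ver=None):
    vals = np.array(means)
    return EnsembleRecord(
        target_id=tid,
        mean_probs=dict(zip(TAGS, means)),
        v_ra=dict(zip(TAGS, v_ra)),
        V_ER=float(np.var(vals, ddof=1)) if ver is None else ver,
        max_prob=float(vals.max()),
        quintile_bin=bin_quintile(float(vals.max())),
    )


class TestProbabilityRecord:
    def test_mean_and_vra_are_sample_statistics(self):
        probs = [0.1, 0.2, 0.3, 0.4]
        r = record("t", "FP", probs)
        assert r.mean_prob == pytest.approx(0.25)
        assert r.V_RA == pytest.approx(np.var(probs, ddof=1))

    def test_identical_cycles_zero_variance(self):
        r = record("t", "FP", [0.7] * 10)
        assert r.V_RA == 0.0

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValidationError):
            record("t", "FP", [0.5, 1.2])


class TestEnsembleVariance:
    def test_identical_means_zero_ver(self):
        recs = [record("t", tag, [0.9, 0.9]) for tag in TAGS]
        e = ensemble_variance(recs)
        assert e.V_ER == 0.0
        assert e.max_prob == 0.9

    def test_sample_variance_of_three_config_means(self):
        # hand arithmetic: mean 0.430333..., squared deviations sum
        # 0.1962587, /2 -> 0.0981293
        recs = [
            record("s7", tag, [p, p])
            for tag, p in zip(TAGS, (0.141, 0.763, 0.387))
        ]
        e = ensemble_variance(recs)
        assert e.V_ER == pytest.approx(0.0981293, abs=5e-7)

    def test_max_prob_of_three_means(self):
        recs = [
            record("s1", tag, [p, p])
            for tag, p in zip(TAGS, (0.615, 0.871, 0.785))
        ]
        e = ensemble_variance(recs)
        assert e.max_prob == pytest.approx(0.871)
        assert e.quintile_bin == 5

    def test_missing_config_rejected(self):
        recs = [record("t", "FP", [0.5, 0.5]), record("t", "HW", [0.5, 0.5])]
        with pytest.raises(ValidationError):
            ensemble_variance(recs)

    def test_build_preserves_dataset_order(self):
        recs = []
        for tag in TAGS:
            for tid in ("b", "a"):
                recs.append(record(tid, tag, [0.5, 0.6]))
        out = build_ensemble_records(recs)
        assert [e.target_id for e in out] == ["b", "a"]


class TestComputeFlags:
    def test_all_equal_ver_no_flags(self):
        records = [ens(f"t{i}", (0.2, 0.3, 0.4)) for i in range(5)]
        compute_flags(records)
        assert not any(r.flag_VER for r in records)

    def test_single_extreme_ver_flagged(self):
        records = [ens(f"t{i}", (0.5, 0.5, 0.5), ver=0.001) for i in range(50)]
        records.append(ens("hot", (0.1, 0.9, 0.5), ver=0.2))
        compute_flags(records)
        flagged = [r.target_id for r in records if r.flag_VER]
        assert flagged == ["hot"]

    def test_flags_invariant_to_order(self):
        rng = np.random.default_rng(4)
        base = [
            ens(f"t{i}", tuple(rng.uniform(0, 1, 3)), v_ra=tuple(rng.uniform(0, 0.1, 3)))
            for i in range(20)
        ]
        shuffled = list(base)
        rng.shuffle(shuffled)
        compute_flags(base)
        flags_a = {r.target_id: (r.flag_VER, dict(r.flag_VRA)) for r in base}
        compute_flags(shuffled)
        flags_b = {r.target_id: (r.flag_VER, dict(r.flag_VRA)) for r in shuffled}
        assert flags_a == flags_b

    def test_flags_invariant_to_family_scaling(self):
        rng = np.random.default_rng(5)
        vras = [tuple(rng.uniform(0, 0.1, 3)) for _ in range(15)]
        a = [ens(f"t{i}", (0.2, 0.5, 0.8), v_ra=v) for i, v in enumerate(vras)]
        c = 37.5
        b = [
            ens(f"t{i}", (0.2, 0.5, 0.8), v_ra=tuple(c * x for x in v))
            for i, v in enumerate(vras)
        ]
        compute_flags(a)
        compute_flags(b)
        for ra, rb in zip(a, b):
            assert ra.flag_VRA == rb.flag_VRA

    def test_too_few_targets_rejected(self):
        with pytest.raises(ValidationError):
            compute_flags([ens("a", (0.1, 0.2, 0.3)), ens("b", (0.1, 0.2, 0.3))])


class TestFitBoundaryPoly:
    def test_zero_variance_no_crossings(self):
        p = np.linspace(0, 1, 20)
        fit = fit_boundary_poly(p, np.zeros_like(p))
        assert len(fit.crossings) == 0
        assert np.abs(np.polynomial.polynomial.polyval(p, fit.coefficients)).max() < 1e-10

    def test_symmetric_bump_crossings_symmetric_about_half(self):
        p = np.linspace(0, 1, 41)
        v = np.clip(0.09 - 0.9 * (p - 0.5) ** 2, 0.0, None)
        fit = fit_boundary_poly(p, v)
        assert len(fit.crossings) == 2
        assert fit.crossings[0] + fit.crossings[1] == pytest.approx(1.0, abs=1e-6)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 30)
        v = rng.uniform(0, 0.2, 30)
        fit = fit_boundary_poly(p, v)
        resid = v - np.polynomial.polynomial.polyval(p, fit.coefficients)
        design = np.vander(p, 6, increasing=True)
        assert np.abs(design.T @ resid).max() < 1e-8

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValidationError):
            fit_boundary_poly(np.full(10, 0.5), np.linspace(0, 1, 10))


class TestBinQuintile:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0, 1),
            (0.19999, 1),
            (0.2, 2),
            (0.21, 2),
            (0.4, 3),
            (0.6, 4),
            (0.79999, 4),
            (0.8, 5),
            (1.0, 5),
        ],
    )
    def test_bin_edges(self, p, expected):
        assert bin_quintile(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bin_quintile(1.2)
        with pytest.raises(ValidationError):
            bin_quintile(-0.1)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_every_probability_gets_exactly_one_bin(self, p):
        b = bin_quintile(p)
        assert 1 <= b <= 5
        lo = (b - 1) / 5.0
        hi = b / 5.0
        assert (lo <= p < hi) or (b == 5 and p <= 1.0)
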