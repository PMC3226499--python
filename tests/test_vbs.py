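"""Vascular bioactivity scoring and ToxPi profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvdc import (
    DEFAULT_TARGETS,
    DEFAULT_WEIGHTS,
    INACTIVE_UM,
    PotencyMatrix,
    VBSConfig,
    assay_feature_matrix,
    assay_unit_score,
    classify_pvdc,
    render_toxpi,
    score_matrix,
    toxpi_profiles,
    vbs_result,
)


class TestUnitScore:
    def test_sentinel_maps_to_zero(self):
        assert assay_unit_score(INACTIVE_UM) == 0.0

    def test_floor_saturates_at_one(self):
        cfg = VBSConfig()
        assert assay_unit_score(cfg.c_floor) == 1.0
        assert assay_unit_score(cfg.c_floor / 10) == 1.0

    def test_one_micromolar_closed_form(self):
        # log10(1e6 / 1) / log10(1e6 / 1e-3) = 6/9
        assert assay_unit_score(1.0) == pytest.approx(6 / 9)

    @pytest.mark.parametrize("bad", [0.0, -3.0, float("nan"), float("inf")])
    def test_nonpositive_or_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            assay_unit_score(bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.floats(1e-4, 1e6),
        factor=st.floats(1.01, 100.0),
    )
    def test_more_potent_never_scores_lower(self, p, factor):
        assert assay_unit_score(p / factor) >= assay_unit_score(p)


def _single_assay_annotations():
    """One assay per target, assay id equal to the target id."""
    from pvdc import AnnotationTable, AssayAnnotation

    return AnnotationTable(
        AssayAnnotation(assay_id=t, target_feature=t) for t in DEFAULT_TARGETS
    )


def _row(potencies: dict[str, float]) -> pd.Series:
    data = {t: potencies.get(t, INACTIVE_UM) for t in DEFAULT_TARGETS}
    return pd.Series(data, name="chem")


class TestVBS:
    def test_all_inactive_scores_zero(self):
        r = vbs_result(_row({}), _single_assay_annotations())
        assert r.vbs == 0.0
        assert all(v == 0.0 for v in r.target_scores.values())

    def test_single_active_target_equal_weights(self):
        cfg = VBSConfig(weights=(1.0,) * 6)
        r = vbs_result(_row({"CCL2_down": 1.0}), _single_assay_annotations(), cfg)
        assert r.vbs == pytest.approx(assay_unit_score(1.0, cfg))

    def test_weighted_sum_matches_dot_product(self, rng):
        ann = _single_assay_annotations()
        for _ in range(25):
            pot = {
                t: float(10 ** rng.uniform(-3, 2))
                for t in rng.choice(DEFAULT_TARGETS, size=3, replace=False)
            }
            r = vbs_result(_row(pot), ann)
            expected = sum(
                w * assay_unit_score(pot.get(t, INACTIVE_UM))
                for t, w in zip(DEFAULT_TARGETS, DEFAULT_WEIGHTS)
            )
            assert abs(r.vbs - expected) <= 1e-12

    def test_unmapped_target_rejected_by_name(self):
        from pvdc import AnnotationTable, AssayAnnotation

        ann = AnnotationTable(
            AssayAnnotation(assay_id=t, target_feature=t)
            for t in DEFAULT_TARGETS[:-1]
        )
        with pytest.raises(ValueError, match="uPAR_updown"):
            vbs_result(_row({}), ann)

    def test_monotone_in_potency(self, rng):
        ann = _single_assay_annotations()
        for _ in range(25):
            pot = {t: float(10 ** rng.uniform(-2, 2)) for t in DEFAULT_TARGETS[:4]}
            base = vbs_result(_row(pot), ann).vbs
            t = DEFAULT_TARGETS[int(rng.integers(4))]
            pot2 = dict(pot, **{t: pot[t] / 10})
            assert vbs_result(_row(pot2), ann).vbs >= base

    def test_invariant_to_added_inactive_assay_under_max(self):
        from pvdc import AnnotationTable, AssayAnnotation

        ann = _single_assay_annotations()
        extra = AnnotationTable(
            [
                *(
                    AssayAnnotation(assay_id=t, target_feature=t)
                    for t in DEFAULT_TARGETS
                ),
                AssayAnnotation(assay_id="CCL2_bis", target_feature="CCL2_down"),
            ]
        )
        pot = {"CCL2_down": 0.5, "TIE2_inhib": 7.0}
        row = _row(pot)
        row2 = pd.concat([row, pd.Series({"CCL2_bis": INACTIVE_UM})])
        row2.name = "chem"
        assert vbs_result(row2, extra).vbs == pytest.approx(
            vbs_result(row, ann).vbs
        )

    def test_weight_order_governs_swapped_activities(self):
        """Moving the more potent hit to a higher-weighted target raises VBS."""
        ann = _single_assay_annotations()
        hi, lo = DEFAULT_TARGETS[0], DEFAULT_TARGETS[3]
        strong, weak = 0.1, 50.0
        better = vbs_result(_row({hi: strong, lo: weak}), ann).vbs
        worse = vbs_result(_row({hi: weak, lo: strong}), ann).vbs
        assert better > worse


class TestClassifyPvdc:
    def test_published_cutoff_on_reference_screen(self, vascular_screen):
        _, meta = vascular_screen
        flags = classify_pvdc(meta["vbs"], cutoff=1.48)
        assert int(flags.sum()) == 11
        assert flags["Milbemectin"]  # VBS 1.49, inclusive rule
        assert not flags["Captan"]

    def test_all_equal_scores_all_classified(self):
        flags = classify_pvdc([2.0, 2.0, 2.0])
        assert flags.all()

    def test_mean_cutoff_splits_zero_ten(self):
        flags = classify_pvdc([0.0, 10.0])
        assert list(flags) == [False, True]

    def test_empty_without_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify_pvdc([])


class TestToxPi:
    @staticmethod
    def _scores(rng, n=3):
        from pvdc.simulate import GeneratorConfig, generate_hts

        cfg = GeneratorConfig(
            n_chemicals=n, n_assays=12, active_fraction=1.0,
            seed=int(rng.integers(2**20)),
        )
        m, ann, _ = generate_hts(cfg)
        return score_matrix(m, ann)

    def test_single_chemical_nonzero_slice_is_one(self):
        df = pd.DataFrame(
            {t: [0.0] for t in DEFAULT_TARGETS} | {"vbs": [1.0]},
            index=["only"],
        )
        df[DEFAULT_TARGETS[2]] = 0.4
        [profile] = toxpi_profiles(df)
        assert profile.slices[DEFAULT_TARGETS[2]][0] == 1.0

    def test_all_zero_slice_stays_zero(self):
        df = pd.DataFrame(
            {t: [0.0, 0.0] for t in DEFAULT_TARGETS} | {"vbs": [0.0, 0.0]},
            index=["a", "b"],
        )
        profiles = toxpi_profiles(df)
        assert all(v == 0.0 for p in profiles for v in p.values)

    def test_fractions_sum_to_one_and_max_normalization(self, rng):
        scores = self._scores(rng)
        profiles = toxpi_profiles(scores)
        for p in profiles:
            assert sum(p.fractions) == pytest.approx(1.0)
        # independently recompute slice maxima and vbs ordering
        for t in DEFAULT_TARGETS:
            col_max = scores[t].max()
            slice_vals = {p.chemical: p.slices[t][0] for p in profiles}
            if col_max > 0:
                assert max(slice_vals.values()) == pytest.approx(1.0)
                for chem, v in slice_vals.items():
                    assert v == pytest.approx(scores.at[chem, t] / col_max)
        expected_order = sorted(
            scores.index, key=lambda c: (-scores.at[c, "vbs"], c.casefold())
        )
        assert [p.chemical for p in profiles] == expected_order

    def test_render_writes_per_chemical_and_grid(self, rng, tmp_path):
        profiles = toxpi_profiles(self._scores(rng, n=3))
        written = render_toxpi(profiles, tmp_path)
        assert len(written) == 4  # 3 charts + grid sheet
        assert all(p.exists() and p.stat().st_size > 0 for p in written)

    def test_render_zero_profile_does_not_crash(self, tmp_path):
        df = pd.DataFrame(
            {t: [0.0] for t in DEFAULT_TARGETS} | {"vbs": [0.0]}, index=["z"]
        )
        written = render_toxpi(toxpi_profiles(df), tmp_path)
        assert written[0].exists()


class TestScoreMatrix:
    def test_feature_matrix_matches_elementwise_unit_score(self, rng):
        from conftest import random_matrix

        m = random_matrix(rng, 6, 5)
        F = assay_feature_matrix(m)
        for c in m.chemicals:
            for a in m.assays:
                assert F.loc[c, a] == pytest.approx(
                    assay_unit_score(float(m.values.loc[c, a]))
                )

    def test_rank_is_dense_and_ties_alphabetical(self):
        from pvdc import AnnotationTable, AssayAnnotation

        ann = AnnotationTable(
            AssayAnnotation(assay_id=t, target_feature=t) for t in DEFAULT_TARGETS
        )
        m = PotencyMatrix.from_records(
            ["b", "a", "c"],
            list(DEFAULT_TARGETS),
            {("b", "VEGFR2_down"): 1.0, ("a", "VEGFR2_down"): 1.0},
        )
        scores = score_matrix(m, ann)
        assert scores.at["a", "rank"] == 1  # tie with b, alphabetical
        assert scores.at["b", "rank"] == 2
        assert scores.at["c", "rank"] == 3
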